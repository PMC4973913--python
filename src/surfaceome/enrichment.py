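"""Intensity-binned GO enrichment by Fisher's exact test.

Proteins are ranked by intensity and cut into equal-sized bins (see
:func:`surfaceome.indices.rank_and_bin`); for every bin and every annotation
term a one-sided upper-tail hypergeometric test asks whether the term occurs
in the bin more often than expected under random draws from the universe of
identified proteins.  Enrichment is displayed as -log10(p), giving each
category a bar weighed for its explanatory power rather than a raw member
count.

Because the true abundance distribution of an annotation category within the
whole database is unknown, a uniform-universe p-value is only a relative
measure.  The two-sample remedy is :func:`compare_profiles`: compute the
same binned profile for an enriched sample and for a total-proteome sample
and compare the -log10(p) values bin by bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .indices import IntensityBin
from .io import AnnotationMap


def bin_term_test(k, bin_size, K, N):
    """Upper-tail hypergeometric probability P(X >= k).

    X ~ Hypergeom(population N, successes K, draws bin_size): the chance
    that at least ``k`` of the ``bin_size`` proteins of a bin carry the term
    when ``K`` of the ``N`` universe proteins do.  Accepts scalars or
    broadcastable arrays; returns a float for scalar input.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(bin_size, dtype=np.int64)
    K_ = np.asarray(K, dtype=np.int64)
    N_ = np.asarray(N, dtype=np.int64)
    if np.any(k < 0) or np.any(n > N_) or np.any(k > n) or np.any(k > K_) or np.any(K_ > N_):
        raise ValueError("require 0 <= k <= bin_size <= N and k <= K <= N")
    p = hypergeom.sf(k - 1, N_, K_, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class BinTermResult:
    """Fisher's exact test of one term in one intensity bin."""

    bin_index: int
    term: str
    k_in_bin: int
    bin_size: int
    K_in_universe: int
    N_universe: int
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


@dataclass
class BinEnrichmentProfile:
    """Per-bin, per-term enrichment results for one sample."""

    results: list[BinTermResult]
    terms: tuple[str, ...]
    bin_size: int
    universe: str
    adjust: str

    @property
    def n_bins(self) -> int:
        return 1 + max(r.bin_index for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bin_index": r.bin_index,
                "term": r.term,
                "k": r.k_in_bin,
                "bin_size": r.bin_size,
                "K": r.K_in_universe,
                "N": r.N_universe,
                "p": r.p_value,
                "neg_log10_p": r.neg_log10_p,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)


def _membership(
    accessions: Sequence[str],
    annotations: AnnotationMap,
    term: str,
    custom_sets: Mapping[str, frozenset[str] | set[str]] | None,
) -> int:
    if custom_sets and term in custom_sets:
        members = custom_sets[term]
        return sum(1 for a in accessions if a in members)
    return sum(1 for a in accessions if annotations.has_term(a, term))


def enrichment_profile(
    bins: Sequence[IntensityBin],
    annotations: AnnotationMap,
    terms: Sequence[str],
    universe: Literal["identified", "custom"] = "identified",
    universe_counts: tuple[int, Mapping[str, int]] | None = None,
    min_members: int = 2,
    adjust: Literal["none", "bonferroni"] = "bonferroni",
    custom_sets: Mapping[str, frozenset[str] | set[str]] | None = None,
) -> BinEnrichmentProfile:
    """Binned enrichment profile over a list of terms.

    Parameters
    ----------
    bins
        Output of :func:`surfaceome.indices.rank_and_bin`.
    annotations
        Accession -> GO terms / features; a term matches either kind.
    terms
        GO identifiers, feature names, or names of ``custom_sets`` entries
        (e.g. a caller-supplied "CD markers" accession list).
    universe
        ``"identified"`` (default): N = all proteins in the bins, K = term
        members among them — the per-sample universe.  ``"custom"``: N and
        per-term K taken from ``universe_counts`` = (N, {term: K}).
    min_members
        Terms with fewer than this many members in a bin are reported with
        p = 1 (default 2, mirroring common term-enrichment settings).
    adjust
        ``"bonferroni"`` multiplies each p by the number of terms tested per
        bin, capped at 1; applied within bins, not across them.

    A term absent from the universe (K = 0) yields p = 1 with a warning.
    """
    if not terms:
        raise ValueError("no terms to test")
    if not bins:
        raise ValueError("no bins")
    all_accessions = [a for b in bins for a in b.accessions]
    if universe == "identified":
        N = len(all_accessions)
        K_map = {t: _membership(all_accessions, annotations, t, custom_sets) for t in terms}
    elif universe == "custom":
        if universe_counts is None:
            raise ValueError("universe='custom' requires universe_counts")
        N, K_map = universe_counts[0], dict(universe_counts[1])
    else:
        raise ValueError(f"unknown universe: {universe!r}")

    results = []
    m = len(terms)
    for t in terms:
        K = K_map.get(t, 0)
        if K == 0:
            warnings.warn(f"term {t!r} absent from the universe; reporting p = 1")
    for b in bins:
        for t in terms:
            K = K_map.get(t, 0)
            k = _membership(b.accessions, annotations, t, custom_sets)
            if K == 0 or k < min_members:
                p = 1.0
            else:
                p = bin_term_test(k, len(b), K, N)
                if adjust == "bonferroni":
                    p = min(1.0, p * m)
            results.append(
                BinTermResult(
                    bin_index=b.bin_index,
                    term=t,
                    k_in_bin=k,
                    bin_size=len(b),
                    K_in_universe=K,
                    N_universe=N,
                    p_value=float(p),
                )
            )
    return BinEnrichmentProfile(
        results=results,
        terms=tuple(terms),
        bin_size=len(bins[0]),
        universe=universe,
        adjust=adjust,
    )


def compare_profiles(
    profile_enriched: BinEnrichmentProfile,
    profile_total: BinEnrichmentProfile,
    strict: bool = True,
) -> pd.DataFrame:
    """Pair two binned profiles and difference them on the -log10(p) scale.

    Rows are aligned by (bin_index, term); ``delta`` = enriched - total.
    The bin sizes and term lists must match.  With ``strict=True`` (default)
    differing bin counts raise; with ``strict=False`` unmatched trailing
    bins are kept and the missing side is NaN.
    """
    if profile_enriched.bin_size != profile_total.bin_size:
        raise ValueError(
            f"bin_size mismatch: {profile_enriched.bin_size} vs {profile_total.bin_size}"
        )
    if set(profile_enriched.terms) != set(profile_total.terms):
        raise ValueError("term lists differ between profiles")
    if strict and profile_enriched.n_bins != profile_total.n_bins:
        raise ValueError(
            f"bin count mismatch: {profile_enriched.n_bins} vs {profile_total.n_bins}"
        )
    a = profile_enriched.to_frame()[["bin_index", "term", "neg_log10_p"]].rename(
        columns={"neg_log10_p": "neg_log10_p_enriched"}
    )
    b = profile_total.to_frame()[["bin_index", "term", "neg_log10_p"]].rename(
        columns={"neg_log10_p": "neg_log10_p_total"}
    )
    out = a.merge(b, on=["bin_index", "term"], how="outer").sort_values(
        ["term", "bin_index"], ignore_index=True
    )
    out["delta"] = out["neg_log10_p_enriched"] - out["neg_log10_p_total"]
    return out


def plot_profile(profile: BinEnrichmentProfile, term: str, ax=None):
    """Bar chart of -log10(p) per intensity bin for one term."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = profile.to_frame()
    df = df[df["term"] == term]
    ax.bar(df["bin_index"], df["neg_log10_p"])
    ax.set_xlabel("intensity bin (decreasing abundance)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(term)
    return ax
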