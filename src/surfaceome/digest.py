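"""In-silico tryptic digestion and observable-peptide counting.

Trypsin cleaves C-terminally of lysine (K) and arginine (R); by the common
convention a site followed by proline (P) is suppressed (configurable).  A
protein's number of *observable* peptides (PO) is the number of distinct
digestion products, with up to ``max_missed_cleavages`` internal missed
sites, that survive a set of observability filters:

* peptide length (default 6-35 residues),
* charge proxy — 1 + count of K/R/H residues (basic sites plus the
  N-terminus),
* mean Kyte-Doolittle hydropathy (GRAVY), rejecting extreme hydrophobicity
  or hydrophilicity,
* predicted retention time, via a linear hydrophobicity-index model whose
  admissible interval can be estimated from an observed peptide/RT table
  (:func:`estimate_rt_limits`).

All filters are optional; length and missed-cleavage limits are on by
default.  Settings can be loaded from an INI file with sections mirroring
the filter groups (:func:`params_from_ini`).
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

_CLEAVE_AFTER = frozenset("KR")
_BASIC = frozenset("KRH")


def gravy(peptide: str) -> float:
    """Mean Kyte-Doolittle hydropathy; NaN if no residue is on the scale."""
    vals = [_KYTE_DOOLITTLE[a] for a in peptide if a in _KYTE_DOOLITTLE]
    return float(np.mean(vals)) if vals else float("nan")


def charge_proxy(peptide: str) -> int:
    """Nominal charge state: 1 (N-terminus) + number of K/R/H residues."""
    return 1 + sum(1 for a in peptide if a in _BASIC)


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its position and missed-cleavage count."""

    sequence: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices *after* which trypsin cleaves."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in _CLEAVE_AFTER and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    sequence: str,
    max_missed_cleavages: int = 2,
    proline_rule: bool = True,
) -> list[DigestPeptide]:
    """All tryptic products with 0..``max_missed_cleavages`` missed sites.

    Cleavage occurs after K or R except, when the proline rule is active,
    before P.  Unknown letters are tolerated and never cleaved.  The
    zero-missed-cleavage products partition the sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    sequence = sequence.upper()
    bounds = [0] + [s + 1 for s in cleavage_sites(sequence, proline_rule)] + [len(sequence)]
    out = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for mc in range(min(max_missed_cleavages, nfrag - 1 - i) + 1):
            start, end = bounds[i], bounds[i + 1 + mc]
            out.append(DigestPeptide(sequence[start:end], start, end, mc))
    return out


@dataclass(frozen=True)
class RtModel:
    """Linear retention-time predictor on the GRAVY hydrophobicity index."""

    intercept: float
    slope: float

    def predict(self, peptide: str) -> float:
        return self.intercept + self.slope * gravy(peptide)


@dataclass(frozen=True)
class ObservabilityParams:
    """Constraints defining which tryptic peptides count as observable."""

    min_length: int = 6
    max_length: int = 35
    max_missed_cleavages: int = 2
    gravy_range: tuple[float, float] | None = None
    charge_range: tuple[int, int] | None = None
    rt_range: tuple[float, float] | None = None
    rt_model: RtModel | None = field(default=None, compare=False)
    proline_rule: bool = True

    def __post_init__(self):
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.rt_range is not None and self.rt_model is None:
            object.__setattr__(self, "rt_model", RtModel(0.0, 1.0))

    def passes(self, peptide: str) -> bool:
        if not (self.min_length <= len(peptide) <= self.max_length):
            return False
        if self.gravy_range is not None:
            g = gravy(peptide)
            if not (self.gravy_range[0] <= g <= self.gravy_range[1]):
                return False
        if self.charge_range is not None:
            if not (self.charge_range[0] <= charge_proxy(peptide) <= self.charge_range[1]):
                return False
        if self.rt_range is not None:
            rt = self.rt_model.predict(peptide)
            if not (self.rt_range[0] <= rt <= self.rt_range[1]):
                return False
        return True


#: Parameter set with every filter disabled (raw product counting).
NO_FILTERS = ObservabilityParams(min_length=1, max_length=10**9)


def count_observable(
    sequence: str,
    params: ObservabilityParams = ObservabilityParams(),
    distinct: bool = True,
) -> int:
    """Number of observable tryptic peptides (PO) of one protein.

    Counts digestion products with at most ``params.max_missed_cleavages``
    missed sites that pass every enabled filter.  ``distinct=True`` (default)
    counts each peptide sequence once even if it occurs at several positions;
    ``distinct=False`` counts products positionally, in which case the
    unfiltered count follows the closed form (c+1) + c + (c-1) + ... for c
    cleavage sites.
    """
    products = digest(sequence, params.max_missed_cleavages, params.proline_rule)
    seqs = (p.sequence for p in products)
    if distinct:
        return sum(1 for s in set(seqs) if params.passes(s))
    return sum(1 for s in seqs if params.passes(s))


def po_table(
    sequences: dict[str, str],
    params: ObservabilityParams = ObservabilityParams(),
) -> dict[str, int]:
    """PO for every sequence of a FASTA-derived mapping."""
    return {acc: count_observable(seq, params) for acc, seq in sequences.items()}


def estimate_rt_limits(
    peptide_table: Sequence[tuple[str, float]],
    quantiles: tuple[float, float] = (0.01, 0.99),
) -> tuple[tuple[float, float], RtModel]:
    """Estimate admissible retention-time limits from observed peptides.

    Fits RT = a + b * GRAVY over the observed (peptide, RT) pairs — a proxy
    for the reversed-phase elution behaviour — and returns the central
    quantile interval (default 1st-99th percentile) of the fitted
    predictions, usable as ``rt_range``, together with the fitted model.
    Requires at least 10 observations.
    """
    if len(peptide_table) < 10:
        raise ValueError("need at least 10 peptide/RT observations")
    x = np.array([gravy(p) for p, _ in peptide_table], dtype=float)
    y = np.array([rt for _, rt in peptide_table], dtype=float)
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("need at least 10 peptide/RT observations with defined GRAVY")
    if np.ptp(y) == 0:
        warnings.warn("constant retention times: degenerate RT interval")
        model = RtModel(float(y[0]), 0.0)
        return (float(y[0]), float(y[0])), model
    if np.ptp(x) == 0:
        warnings.warn("constant GRAVY: RT model reduces to the mean")
        slope, intercept = 0.0, float(np.mean(y))
    else:
        slope, intercept = np.polyfit(x, y, 1)
    model = RtModel(float(intercept), float(slope))
    pred = intercept + slope * x
    lo, hi = np.quantile(pred, quantiles)
    return (float(lo), float(hi)), model


def params_from_ini(path: str | Path) -> ObservabilityParams:
    """Load observability settings from an INI file.

    Recognised sections/keys (all optional, defaults as in
    :class:`ObservabilityParams`)::

        [length]   min, max
        [cleavage] max_missed, proline_rule
        [gravy]    min, max
        [charge]   min, max
        [rt]       min, max, intercept, slope
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    p = ObservabilityParams()
    if cp.has_section("length"):
        p = replace(
            p,
            min_length=cp.getint("length", "min", fallback=p.min_length),
            max_length=cp.getint("length", "max", fallback=p.max_length),
        )
    if cp.has_section("cleavage"):
        p = replace(
            p,
            max_missed_cleavages=cp.getint(
                "cleavage", "max_missed", fallback=p.max_missed_cleavages
            ),
            proline_rule=cp.getboolean("cleavage", "proline_rule", fallback=p.proline_rule),
        )
    if cp.has_section("gravy"):
        p = replace(
            p,
            gravy_range=(cp.getfloat("gravy", "min"), cp.getfloat("gravy", "max")),
        )
    if cp.has_section("charge"):
        p = replace(
            p,
            charge_range=(cp.getint("charge", "min"), cp.getint("charge", "max")),
        )
    if cp.has_section("rt"):
        model = RtModel(
            cp.getfloat("rt", "intercept", fallback=0.0),
            cp.getfloat("rt", "slope", fallback=1.0),
        )
        p = replace(
            p,
            rt_range=(cp.getfloat("rt", "min"), cp.getfloat("rt", "max")),
            rt_model=model,
        )
    return p
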