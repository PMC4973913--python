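"""Label-free quantification indices and abundance classes.

Implements the index calculus used for semi-quantitative shotgun proteomics:

* **emPAI** — exponentially modified protein abundance index,
  ``10^(PN/PO)`` where PN is the number of identified peptides and PO the
  number of theoretically observable tryptic peptides.  The classical
  Ishihama form subtracts 1 (``10^x - 1``); here the plain power form is the
  default and the classical variant sits behind ``subtract_one=True``.
* **SAF/NSAF** — (normalized) spectral abundance factor: spectral counts per
  residue, rescaled so that the factors of one table sum to exactly 1.
* **iBAQ** — intensity-based absolute quantification: raw intensity divided
  by PO, log-transformed (base 10 by default).
* **Abundance classes** — log2 mean LFQ intensity cut at 18/23/28/33 into
  the labels ``-``, ``+``, ``++``, ``+++``, ``++++``; intervals are
  half-open, closed on the left, and not-detected proteins fall in ``-``.

The module also ranks proteins by intensity and partitions them into
equal-sized bins (default 50), the input of the binned enrichment analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinTable

#: log2 LFQ cut points between the five abundance classes.
CLASS_EDGES = (18.0, 23.0, 28.0, 33.0)

#: Class labels from lowest (not detected / sub-detection) to highest.
CLASS_LABELS = ("-", "+", "++", "+++", "++++")


class UndefinedIndexError(ValueError):
    """An index is undefined for the given inputs (e.g. PO = 0)."""


def compute_empai(pn: int, po: int, subtract_one: bool = False) -> float:
    """emPAI of one protein from identified (PN) and observable (PO) peptides.

    ``subtract_one=True`` selects the classical ``10^(PN/PO) - 1`` variant.
    PN > PO is tolerated with a warning, since an observability model may
    undercount.
    """
    if po < 1:
        raise UndefinedIndexError("emPAI undefined for PO = 0")
    if pn < 0:
        raise ValueError("PN must be non-negative")
    if pn > po:
        warnings.warn(f"PN ({pn}) exceeds PO ({po}); observability model may undercount")
    value = 10.0 ** (pn / po)
    return value - 1.0 if subtract_one else value


def compute_nsaf(table: ProteinTable) -> dict[str, float]:
    """Normalized spectral abundance factors for every protein of a table.

    ``NSAF_p = (SC_p/L_p) / sum_i (SC_i/L_i)``; the values sum to 1.
    """
    sc = table.df["sc"].to_numpy(float)
    length = table.df["length"].to_numpy(float)
    saf = sc / length
    total = saf.sum()
    if total <= 0:
        raise UndefinedIndexError("NSAF undefined: all spectral counts are zero")
    nsaf = saf / total
    return dict(zip(table.df["accession"], nsaf))


def compute_ibaq(mq: float, po: int, log_base: int = 10) -> float | None:
    """iBAQ: ``log(mq/po)``; returns None (not detected) when ``mq`` is 0."""
    if po < 1:
        raise UndefinedIndexError("iBAQ undefined for PO = 0")
    if mq < 0:
        raise ValueError("intensity must be non-negative")
    if mq == 0:
        return None
    if log_base not in (10, 2):
        raise ValueError("log_base must be 10 or 2")
    return math.log(mq / po, log_base)


def assign_abundance_class(mean_log2_lfq: float | None) -> str:
    """Map a log2 mean LFQ intensity to one of ``- + ++ +++ ++++``.

    Half-open, lower-closed intervals: [18,23) -> ``+``, [23,28) -> ``++``,
    [28,33) -> ``+++``; below 18 (or not detected) -> ``-``; >= 33 ->
    ``++++``.
    """
    if mean_log2_lfq is None or (
        isinstance(mean_log2_lfq, float) and math.isnan(mean_log2_lfq)
    ):
        return CLASS_LABELS[0]
    idx = int(np.searchsorted(CLASS_EDGES, mean_log2_lfq, side="right"))
    return CLASS_LABELS[idx]


def mean_log2_lfq(
    table: ProteinTable,
    experiments: Sequence[str] | None = None,
    log_of_mean: bool = True,
) -> pd.Series:
    """Per-protein log2 of the mean LFQ intensity across replicates.

    ``log_of_mean=True`` (default) averages the raw LFQ values first and
    takes log2 of the average; ``False`` averages the log2 values of the
    detected replicates instead.  Proteins never detected yield NaN.
    """
    lfq = table.lfq()
    if experiments is not None:
        lfq = lfq[list(experiments)]
    with np.errstate(divide="ignore"):
        if log_of_mean:
            out = np.log2(lfq.mean(axis=1))
        else:
            out = np.log2(lfq.where(lfq > 0)).mean(axis=1)
    return out.replace(-np.inf, np.nan)


@dataclass(frozen=True)
class IntensityBin:
    """One bin of the intensity ranking (members in descending order)."""

    bin_index: int
    accessions: tuple[str, ...]
    intensity_range: tuple[float, float]

    def __len__(self) -> int:
        return len(self.accessions)


def rank_and_bin(
    table: ProteinTable,
    bin_size: int = 50,
    statistic: Literal["sum_intensity", "mean_lfq"] = "sum_intensity",
) -> list[IntensityBin]:
    """Sort proteins by decreasing intensity and cut into bins of ``bin_size``.

    The ranking statistic is the summed raw intensity over all experiments
    (default) or the mean LFQ intensity.  Ties are broken by ascending
    accession, which makes the partition invariant to input row order.  All
    bins have exactly ``bin_size`` members except possibly the last.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(table) == 0:
        raise ValueError("cannot bin an empty table")
    if statistic == "sum_intensity":
        stat = table.mq().sum(axis=1)
    elif statistic == "mean_lfq":
        stat = table.lfq().mean(axis=1)
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")
    order = (
        pd.DataFrame({"stat": stat})
        .reset_index()
        .sort_values(["stat", "accession"], ascending=[False, True], kind="mergesort")
    )
    bins = []
    for b in range(0, len(order), bin_size):
        chunk = order.iloc[b : b + bin_size]
        bins.append(
            IntensityBin(
                bin_index=b // bin_size,
                accessions=tuple(chunk["accession"]),
                intensity_range=(float(chunk["stat"].min()), float(chunk["stat"].max())),
            )
        )
    return bins


def quantify(
    table: ProteinTable,
    po: Mapping[str, int] | None = None,
    empai_subtract_one: bool = False,
    ibaq_log_base: int = 10,
) -> pd.DataFrame:
    """Per-protein index summary for one table.

    Returns a DataFrame indexed by accession with columns ``pn``, ``sc``,
    ``length``, ``po`` (if supplied), ``empai``, ``nsaf``, ``ibaq``,
    ``mean_log2_lfq`` and ``abundance_class``.  iBAQ uses the summed raw
    intensity over experiments; abundance classes use the log2 of the mean
    LFQ intensity.  Proteins missing from ``po`` get NaN emPAI/iBAQ.
    """
    df = table.df.set_index("accession")
    out = pd.DataFrame(index=df.index)
    out["pn"] = df["pn"]
    out["sc"] = df["sc"]
    out["length"] = df["length"]
    nsaf = compute_nsaf(table)
    out["nsaf"] = [nsaf[a] for a in out.index]
    total_mq = table.mq().sum(axis=1)
    empai, ibaq = [], []
    for acc in out.index:
        p = po.get(acc) if po is not None else None
        if p is None or p < 1:
            empai.append(np.nan)
            ibaq.append(np.nan)
            continue
        empai.append(compute_empai(int(df.loc[acc, "pn"]), int(p), empai_subtract_one))
        v = compute_ibaq(float(total_mq.loc[acc]), int(p), ibaq_log_base)
        ibaq.append(np.nan if v is None else v)
    out["po"] = [po.get(a, np.nan) if po is not None else np.nan for a in out.index]
    out["empai"] = empai
    out["ibaq"] = ibaq
    mlog = mean_log2_lfq(table)
    out["mean_log2_lfq"] = mlog
    out["abundance_class"] = [
        assign_abundance_class(None if math.isnan(v) else v) for v in mlog
    ]
    return out
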