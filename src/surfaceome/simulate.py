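"""Synthetic data emulating label-free validation designs.

Three designs are covered:

* **Differential spike-in** (:func:`simulate_spike_in`): a small equimolar
  standard set spiked at controlled molar amounts (default 20, 6.7, 2.2,
  0.74 and 0.24 fmol, quadruplicate) into a large constant background
  proteome — the design used to probe a permutation-based differential test
  with known ground truth.
* **Dilution series** (:func:`simulate_dilution_series`): a few standard
  proteins measured over a grid spanning 500 amol to 500 pmol, to compare
  the dynamic range of count-based and intensity-based indices.
* **Staggered accuracy standard** (:func:`simulate_accuracy_standard`): one
  sample containing proteins at amounts staggered over several orders of
  magnitude (the UPS2-style design), for index-accuracy evaluation with
  :func:`evaluate_accuracy`.

Generative model (all parameters explicit, all draws seeded):

* intensity = molar amount x protein-specific response factor x log-normal
  replicate noise (coefficient of variation ``noise_cv``).  Response factors
  are drawn log-normally per protein to emulate peptide-response
  heterogeneity; in the dilution/accuracy designs the response additionally
  scales with the number of observable peptides (a protein's total MS
  signal is the sum over its peptides), which is exactly the component the
  iBAQ normalisation divides out.
* left-censored dropout: a cell is detected with probability
  ``logistic((log2 mu - log2 midpoint)/slope)`` of its noise-free intensity
  mu.  Detection events share a per-protein latent factor (Gaussian copula
  with correlation ``detection_correlation``), because technical replicates
  of one digest — especially with match-between-runs — lose a peptide
  species nearly all-or-none rather than independently per run.
* spectral counts follow a saturating (Michaelis-Menten-like) rate in
  intensity, scaled by the number of observable peptides, and identified
  peptide numbers follow a coupon-collector binomial in the counts; this
  makes count-based indices saturate earlier than intensity-based ones.

The generated tables use the internal TSV dialect, so every other module
consumes them unchanged; raw (MQ) and LFQ intensities are set equal, i.e.
the generator emulates already-normalized intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import pearsonr, spearmanr, theilslopes

from .io import ProteinTable

#: Spike amounts (fmol) of the differential standard series.
SPIKE_AMOUNTS_FMOL = (20.0, 6.7, 2.2, 0.74, 0.24)

#: Dilution grid in fmol: 500 amol and 5, 50, 500 fmol and 5, 50, 500 pmol.
DILUTION_GRID_FMOL = (0.5, 5.0, 50.0, 500.0, 5e3, 5e4, 5e5)


def _condition_label(amount_fmol: float) -> str:
    return f"fmol{amount_fmol:g}"


@dataclass(frozen=True)
class SpikeInDesign:
    """Study conditions of the differential spike-in benchmark."""

    n_background: int = 1500
    background_log10_mean: float = 10.5
    background_log10_sd: float = 1.2
    n_spike: int = 48
    spike_amounts_fmol: tuple[float, ...] = SPIKE_AMOUNTS_FMOL
    replicates: int = 4
    noise_cv: float = 0.2
    response_log10_mean: float = 9.0
    response_log10_sd: float = 0.3
    dropout_midpoint: float | None = 4e8
    dropout_slope: float = 0.4  # logistic slope in log2-intensity units
    detection_correlation: float = 0.8

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if any(a <= 0 for a in self.spike_amounts_fmol):
            raise ValueError("spike amounts must be positive")
        if not 0 <= self.detection_correlation < 1:
            raise ValueError("detection_correlation must be in [0, 1)")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(_condition_label(a) for a in self.spike_amounts_fmol)

    def experiments_of(self, condition: str) -> list[str]:
        return [f"{condition}_r{i + 1}" for i in range(self.replicates)]


@dataclass
class SpikeInTruth:
    """Ground truth of a spike-in simulation."""

    spike_accessions: tuple[str, ...]
    amounts_fmol: dict[str, float]  # condition -> spiked molar amount
    true_intensity: pd.DataFrame  # noise-free intensity, proteins x experiments
    dropout_mask: pd.DataFrame  # True where the cell was censored to 0
    response_factors: pd.Series  # per spike protein, intensity per fmol

    def fold_change(self, condition_a: str, condition_b: str) -> pd.Series:
        """True fold change a/b: amount ratio for spikes, 1 for background."""
        ratio = self.amounts_fmol[condition_a] / self.amounts_fmol[condition_b]
        fc = pd.Series(1.0, index=self.true_intensity.index)
        fc.loc[list(self.spike_accessions)] = ratio
        return fc


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def _detection(
    rng: np.random.Generator,
    mu: np.ndarray,  # noise-free intensities, proteins x cells
    midpoint: float | None,
    slope: float,
    rho: float,
) -> np.ndarray:
    """Boolean detected-mask with per-protein correlated detection events."""
    if midpoint is None:
        return np.ones_like(mu, dtype=bool)
    with np.errstate(divide="ignore"):
        p = expit((np.log2(np.maximum(mu, 1e-300)) - math.log2(midpoint)) / slope)
    z_protein = rng.standard_normal(mu.shape[0])[:, None]
    eps = rng.standard_normal(mu.shape)
    latent = math.sqrt(rho) * z_protein + math.sqrt(1.0 - rho) * eps
    return latent <= ndtri(np.clip(p, 1e-12, 1 - 1e-12))


def _counts(
    rng: np.random.Generator,
    intensity: np.ndarray,  # observed (post-dropout) proteins x cells
    po: np.ndarray,
    sc_rate: float = 3.0,
    half_sat: float = 1e10,
) -> tuple[np.ndarray, np.ndarray]:
    """Total spectral counts and identified-peptide numbers per protein."""
    lam = sc_rate * po[:, None] * intensity / (intensity + half_sat)
    sc = rng.poisson(lam).sum(axis=1)
    with np.errstate(over="ignore"):
        p_seen = 1.0 - np.exp(-sc / np.maximum(po, 1))
    pn = rng.binomial(po, p_seen)
    return sc, pn


def _assemble_table(
    accessions: Sequence[str],
    lengths: np.ndarray,
    pn: np.ndarray,
    sc: np.ndarray,
    intensity: np.ndarray,
    experiments: Sequence[str],
) -> ProteinTable:
    df = pd.DataFrame(
        {
            "accession": list(accessions),
            "description": "",
            "length": lengths.astype(int),
            "pn": pn.astype(int),
            "sc": sc.astype(int),
            "flags": "",
        }
    )
    for j, e in enumerate(experiments):
        df[f"mq:{e}"] = intensity[:, j]
        df[f"lfq:{e}"] = intensity[:, j]
    return ProteinTable(df)


def simulate_spike_in(
    design: SpikeInDesign = SpikeInDesign(), seed: int = 0
) -> tuple[ProteinTable, SpikeInTruth]:
    """Simulate the spike-in benchmark; fully determined by design and seed.

    Returns one table holding all conditions x replicates, plus the ground
    truth.  Proteins never detected in any sample are dropped from the table
    (a protein-group table only lists identified proteins) but kept in the
    truth object.
    """
    rng = np.random.default_rng(seed)
    spikes = [f"SPIKE{str(i + 1).zfill(3)}" for i in range(design.n_spike)]
    bg = [f"BG{str(i + 1).zfill(4)}" for i in range(design.n_background)]
    accessions = spikes + bg

    experiments = [e for c in design.conditions for e in design.experiments_of(c)]
    rf = 10.0 ** rng.normal(design.response_log10_mean, design.response_log10_sd, design.n_spike)
    bg_int = 10.0 ** rng.normal(
        design.background_log10_mean, design.background_log10_sd, design.n_background
    )

    mu = np.empty((len(accessions), len(experiments)))
    col = 0
    for amount in design.spike_amounts_fmol:
        for _ in range(design.replicates):
            mu[: design.n_spike, col] = amount * rf
            mu[design.n_spike :, col] = bg_int
            col += 1

    noisy = mu * _lognormal_noise(rng, design.noise_cv, mu.shape)
    detected = _detection(
        rng, mu, design.dropout_midpoint, design.dropout_slope, design.detection_correlation
    )
    observed = np.where(detected, noisy, 0.0)

    lengths = np.clip(np.round(10.0 ** rng.normal(2.65, 0.25, len(accessions))), 50, 5000)
    po = np.maximum((lengths / 12).astype(int), 1)
    sc, pn = _counts(rng, observed, po)

    truth = SpikeInTruth(
        spike_accessions=tuple(spikes),
        amounts_fmol={
            _condition_label(a): a for a in design.spike_amounts_fmol
        },
        true_intensity=pd.DataFrame(mu, index=accessions, columns=experiments),
        dropout_mask=pd.DataFrame(~detected, index=accessions, columns=experiments),
        response_factors=pd.Series(rf, index=spikes),
    )

    ever_seen = observed.any(axis=1)
    table = _assemble_table(
        [a for a, k in zip(accessions, ever_seen) if k],
        lengths[ever_seen],
        pn[ever_seen],
        sc[ever_seen],
        observed[ever_seen],
        experiments,
    )
    return table, truth


#: Default two-protein dilution standard: synthetic stand-ins for a large
#: serum albumin-like and a small casein-like protein (accession, length, PO).
DILUTION_STANDARDS = (("ALBU_SYN", 607, 40), ("CASB_SYN", 224, 12))


def simulate_dilution_series(
    amount_grid_fmol: Sequence[float] = DILUTION_GRID_FMOL,
    proteins: Sequence[tuple[str, int, int]] = DILUTION_STANDARDS,
    background: Sequence[tuple[str, int, int]] | None = None,
    replicates: int = 3,
    seed: int = 0,
    response_log10_mean: float = 5.5,
    response_log10_sd: float = 0.3,
    noise_cv: float = 0.2,
    sc_rate: float = 3.0,
    half_sat: float = 1e8,
) -> dict[float, ProteinTable]:
    """One table per molar amount of a dilution series.

    ``proteins`` are (accession, length, PO) triples diluted together;
    ``background`` proteins, if given, are present at a constant amount
    (100 fmol) in every table.  The per-protein response is
    PO x 10^Normal(response_log10_mean, response_log10_sd) per fmol (total
    signal scales with the number of observable peptides).  Spectral counts
    saturate with intensity (half-saturation ``half_sat``), so count-based
    indices flatten at the top of the grid while intensity stays
    proportional to input.
    """
    if any(a <= 0 for a in amount_grid_fmol):
        raise ValueError("amounts must be positive")
    if sorted(amount_grid_fmol) != list(amount_grid_fmol):
        raise ValueError("amount grid must be ascending")
    rng = np.random.default_rng(seed)
    allprot = list(proteins) + list(background or [])
    accs = [p[0] for p in allprot]
    lengths = np.array([p[1] for p in allprot], dtype=float)
    po = np.array([p[2] for p in allprot], dtype=int)
    rf = po * 10.0 ** rng.normal(response_log10_mean, response_log10_sd, len(allprot))

    out: dict[float, ProteinTable] = {}
    for amount in amount_grid_fmol:
        amounts = np.full(len(allprot), float(amount))
        if background:
            amounts[len(proteins) :] = 100.0
        mu = (amounts * rf)[:, None] * np.ones((1, replicates))
        observed = mu * _lognormal_noise(rng, noise_cv, mu.shape)
        sc, pn = _counts(rng, observed, po, sc_rate=sc_rate, half_sat=half_sat)
        experiments = [f"rep{i + 1}" for i in range(replicates)]
        out[float(amount)] = _assemble_table(accs, lengths, pn, sc, observed, experiments)
    return out


def ups2_amounts(n_proteins: int = 49) -> dict[str, float]:
    """Staggered amounts map of a UPS2-style accuracy standard.

    Six tiers spanning 0.5 to 50,000 fmol, eight proteins per tier (nine in
    the lowest to reach ``n_proteins``).
    """
    tiers = (5e4, 5e3, 5e2, 5e1, 5e0, 5e-1)
    out: dict[str, float] = {}
    i = 0
    while i < n_proteins:
        out[f"STD{str(i + 1).zfill(3)}"] = tiers[min(i // 8, len(tiers) - 1)]
        i += 1
    return out


def simulate_accuracy_standard(
    amounts_fmol: Mapping[str, float] | None = None,
    replicates: int = 4,
    seed: int = 0,
    response_log10_mean: float = 5.5,
    response_log10_sd: float = 0.3,
    noise_cv: float = 0.2,
    sc_rate: float = 3.0,
    half_sat: float = 1e8,
) -> tuple[ProteinTable, dict[str, float]]:
    """One staggered-amount sample (UPS2-style) plus its truth map.

    Per-protein response is PO x 10^Normal(response_log10_mean,
    response_log10_sd) per fmol, as in :func:`simulate_dilution_series`.
    """
    if amounts_fmol is None:
        amounts_fmol = ups2_amounts()
    rng = np.random.default_rng(seed)
    accs = list(amounts_fmol)
    amounts = np.array([amounts_fmol[a] for a in accs], dtype=float)
    lengths = np.clip(np.round(10.0 ** rng.normal(2.65, 0.25, len(accs))), 50, 5000)
    po = np.maximum((lengths / 12).astype(int), 1)
    rf = po * 10.0 ** rng.normal(response_log10_mean, response_log10_sd, len(accs))
    mu = (amounts * rf)[:, None] * np.ones((1, replicates))
    observed = mu * _lognormal_noise(rng, noise_cv, mu.shape)
    sc, pn = _counts(rng, observed, po, sc_rate=sc_rate, half_sat=half_sat)
    experiments = [f"rep{i + 1}" for i in range(replicates)]
    table = _assemble_table(accs, lengths, pn, sc, observed, experiments)
    return table, dict(amounts_fmol)


@dataclass(frozen=True)
class AccuracyReport:
    """Log-log agreement of a quantification index with known input amounts."""

    index: str
    versus: str
    pearson_r: float
    spearman_r: float
    slope: float
    max_outlier_orders: float
    dynamic_range_orders: float
    n_points: int
    n_proteins: int


_INDEX_CHOICES = ("pn", "empai", "sc", "nsaf", "mq", "lfq", "ibaq")


def _index_values(table: ProteinTable, index: str) -> pd.Series:
    from .indices import compute_nsaf

    df = table.df.set_index("accession")
    po = np.maximum((df["length"] / 12).astype(int), 1)
    if index == "pn":
        return df["pn"].astype(float)
    if index == "sc":
        return df["sc"].astype(float)
    if index == "empai":
        return 10.0 ** (df["pn"] / po)
    if index == "nsaf":
        return pd.Series(compute_nsaf(table))
    if index == "mq":
        return table.mq().mean(axis=1)
    if index == "lfq":
        return table.lfq().mean(axis=1)
    if index == "ibaq":
        return table.mq().mean(axis=1) / po
    raise ValueError(f"index must be one of {_INDEX_CHOICES}, got {index!r}")


def evaluate_accuracy(
    samples: Sequence[tuple[ProteinTable, Mapping[str, float]]],
    index: str,
    versus: str = "molar",
    outlier_tolerance: float = 0.5,
) -> AccuracyReport:
    """Regress log10(index) on log10(input amount) and summarise accuracy.

    ``samples`` pairs each table with its truth map (accession -> molar
    amount, fmol).  ``versus="mass"`` multiplies amounts by protein length
    (a molecular-weight proxy), the alternative normalisation under which
    intensity-type indices align better across proteins.

    Two designs are recognised automatically:

    * **dilution** (every protein measured at >= 2 distinct amounts):
      points are centred per protein — each protein contributes its own
      intercept/response factor — before pooling, so slope and correlation
      describe within-protein proportionality;
    * **staggered standard** (one amount per protein, UPS2-style): a single
      pooled regression across proteins, the absolute-quantification
      reading in which response heterogeneity shows up as outliers.

    The maximum outlier is the largest absolute deviation (orders of
    magnitude) from a robust trend line (Theil-Sen slope, median
    intercept), so it measures how far single values stray rather than how
    much they drag the fit.  The
    dynamic range is the span, in orders of input amount, over which the
    per-amount mean deviation stays within ``outlier_tolerance`` orders.
    """
    if index not in _INDEX_CHOICES:
        raise ValueError(f"index must be one of {_INDEX_CHOICES}, got {index!r}")
    if versus not in ("molar", "mass"):
        raise ValueError("versus must be 'molar' or 'mass'")
    xs, ys, prot = [], [], []
    for table, amounts in samples:
        vals = _index_values(table, index)
        lengths = table.df.set_index("accession")["length"]
        for acc, amount in amounts.items():
            if acc not in vals.index:
                continue
            v = vals.loc[acc]
            if v <= 0 or amount <= 0:
                continue
            x = amount * (lengths.loc[acc] if versus == "mass" else 1.0)
            xs.append(math.log10(x))
            ys.append(math.log10(v))
            prot.append(acc)
    pts = pd.DataFrame({"x": xs, "y": ys, "protein": prot})
    if pts["x"].nunique() < 3:
        raise ValueError("need data at >= 3 distinct input amounts")

    within = (pts.groupby("protein")["x"].nunique() >= 2).all()
    if within:
        cx = pts.groupby("protein")["x"].transform("mean")
        cy = pts.groupby("protein")["y"].transform("mean")
    else:
        cx = pts["x"].mean()
        cy = pts["y"].mean()
    xc, yc = pts["x"] - cx, pts["y"] - cy
    denom = float((xc**2).sum())
    slope = float((xc * yc).sum() / denom) if denom > 0 else float("nan")
    if xc.nunique() > 1 and yc.nunique() > 1:
        pear = float(pearsonr(xc, yc).statistic)
        spear = float(spearmanr(xc, yc).statistic)
    else:
        pear = spear = float("nan")

    # outliers measured against a robust trend (Theil-Sen slope, median
    # intercept), so one corrupted point deviates by its own full
    # displacement instead of dragging the line toward itself
    if xc.nunique() > 1:
        robust_slope = float(theilslopes(yc, xc).slope)
    else:
        robust_slope = slope
    resid0 = pts["y"] - robust_slope * pts["x"]
    if within:
        intercept = pts.assign(r=resid0).groupby("protein")["r"].transform("median")
    else:
        intercept = resid0.median()
    resid = resid0 - intercept
    max_outlier = float(resid.abs().max())

    per_amount = pts.assign(r=resid).groupby("x")["r"].mean()
    ok = per_amount[per_amount.abs() <= outlier_tolerance]
    dyn = float(ok.index.max() - ok.index.min()) if len(ok) >= 2 else 0.0

    return AccuracyReport(
        index=index,
        versus=versus,
        pearson_r=pear,
        spearman_r=spear,
        slope=slope,
        max_outlier_orders=max_outlier,
        dynamic_range_orders=dyn,
        n_points=len(pts),
        n_proteins=pts["protein"].nunique(),
    )
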