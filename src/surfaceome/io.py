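"""Protein-group table, annotation and sequence I/O.

Reads the tab-delimited protein-group tables written by MaxQuant
(``proteinGroups.txt``) as well as a simplified internal TSV dialect that the
other modules write and consume.  Annotation tables map UniProt accessions to
GO terms and to the boolean localisation/topology features consumed by the
cell-surface classifier (GPI anchor, transmembrane, signal peptide, plasma
membrane, extracellular space/region/matrix).

Conventions
-----------
* A missing or empty intensity cell is 0, and 0 means "not detected"
  throughout the package.
* Protein groups listing several accessions are keyed by the first (leading
  razor) accession.
* Column-name matching for the MaxQuant dialect is case-insensitive and can
  be overridden per column, because the dialect drifts between MaxQuant
  versions.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Categorical row flags used by MaxQuant to mark unreliable matches.
FLAGS = ("only_identified_by_site", "reverse", "contaminant")

#: Boolean annotation features recognised by the surface classifier.
FEATURES = ("GA", "TM", "SP", "PM", "ECS", "ECR", "ECM")

_GO_RE = re.compile(r"^GO:\d{7}$")

_TRUTHY = {"1", "+", "true", "yes", "y", "t"}


class TableFormatError(ValueError):
    """A protein-group table does not conform to the expected dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group: identity, counts and per-experiment intensities."""

    accession: str
    description: str
    length_L: int
    peptide_count_PN: int
    spectral_count_SC: int
    raw_intensity_MQ: Mapping[str, float]
    lfq_intensity: Mapping[str, float]
    flags: frozenset[str] = frozenset()


class ProteinTable:
    """A protein-group table held as a :class:`pandas.DataFrame`.

    Fixed columns are ``accession``, ``description``, ``length``, ``pn``,
    ``sc`` and ``flags`` (semicolon-joined subset of :data:`FLAGS`); raw and
    LFQ intensities live in ``mq:<experiment>`` / ``lfq:<experiment>``
    columns.  Experiment labels are identical for the raw and LFQ blocks.
    """

    FIXED = ("accession", "description", "length", "pn", "sc", "flags")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.FIXED if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing mandatory column(s): {missing}")
        mq = sorted(c[3:] for c in df.columns if c.startswith("mq:"))
        lfq = sorted(c[4:] for c in df.columns if c.startswith("lfq:"))
        if mq != lfq:
            raise TableFormatError(
                f"raw/LFQ experiment labels differ: {mq} vs {lfq}"
            )
        dup = df["accession"][df["accession"].duplicated()].tolist()
        if dup:
            raise TableFormatError(f"duplicate accession(s): {sorted(set(dup))}")
        if (df["length"] < 1).any():
            raise TableFormatError("protein length must be >= 1")
        self.df = df.reset_index(drop=True)
        self.experiments: tuple[str, ...] = tuple(mq)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinTable):
            return NotImplemented
        if self.experiments != other.experiments:
            return False
        a = self.df[list(self.columns())].reset_index(drop=True)
        b = other.df[list(self.columns())].reset_index(drop=True)
        return a.equals(b)

    def columns(self) -> tuple[str, ...]:
        inten = tuple(f"mq:{e}" for e in self.experiments) + tuple(
            f"lfq:{e}" for e in self.experiments
        )
        return self.FIXED + inten

    @property
    def accessions(self) -> pd.Series:
        return self.df["accession"]

    def mq(self) -> pd.DataFrame:
        """Raw intensities, proteins x experiments, indexed by accession."""
        out = self.df[[f"mq:{e}" for e in self.experiments]].copy()
        out.columns = list(self.experiments)
        out.index = pd.Index(self.df["accession"], name="accession")
        return out

    def lfq(self) -> pd.DataFrame:
        """LFQ intensities, proteins x experiments, indexed by accession."""
        out = self.df[[f"lfq:{e}" for e in self.experiments]].copy()
        out.columns = list(self.experiments)
        out.index = pd.Index(self.df["accession"], name="accession")
        return out

    def records(self) -> Iterator[ProteinRecord]:
        for _, row in self.df.iterrows():
            d = row.to_dict()
            yield ProteinRecord(
                accession=d["accession"],
                description=d["description"],
                length_L=int(d["length"]),
                peptide_count_PN=int(d["pn"]),
                spectral_count_SC=int(d["sc"]),
                raw_intensity_MQ={e: float(d[f"mq:{e}"]) for e in self.experiments},
                lfq_intensity={e: float(d[f"lfq:{e}"]) for e in self.experiments},
                flags=frozenset(f for f in str(d["flags"]).split(";") if f),
            )

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "ProteinTable":
        rows = []
        for r in records:
            row = {
                "accession": r.accession,
                "description": r.description,
                "length": r.length_L,
                "pn": r.peptide_count_PN,
                "sc": r.spectral_count_SC,
                "flags": ";".join(sorted(r.flags)),
            }
            row.update({f"mq:{e}": v for e, v in r.raw_intensity_MQ.items()})
            row.update({f"lfq:{e}": v for e, v in r.lfq_intensity.items()})
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def write(self, path: str | Path) -> None:
        """Write the table in the simple-tsv dialect.

        Floats are rendered with 6 significant digits ("%.6g"), which the
        round-trip property tests pin down.
        """
        self.df[list(self.columns())].to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def _lower_map(columns: Iterable[str]) -> dict[str, str]:
    return {c.lower().strip(): c for c in columns}


def _require(colmap: dict[str, str], *names: str) -> str:
    for n in names:
        if n.lower() in colmap:
            return colmap[n.lower()]
    raise TableFormatError(f"missing mandatory column: {names[0]!r}")


def _numeric(series: pd.Series) -> pd.Series:
    s = pd.to_numeric(series, errors="coerce").fillna(0.0)
    return s.clip(lower=0.0)


def read_protein_groups(
    path: str | Path,
    dialect: str = "maxquant",
    column_overrides: Mapping[str, str] | None = None,
) -> ProteinTable:
    """Read a protein-group table.

    Parameters
    ----------
    path
        Tab-delimited input file with a header row.
    dialect
        ``"maxquant"`` for ``proteinGroups.txt`` (peptide counts, MS/MS
        counts, per-experiment ``Intensity <exp>`` / ``LFQ intensity <exp>``
        columns and the three categorical flag columns) or ``"simple-tsv"``
        for the internal dialect written by :meth:`ProteinTable.write`.
    column_overrides
        Optional mapping from internal names (``accession``, ``description``,
        ``length``, ``pn``, ``sc``) to the actual column headers, for
        proteinGroups dialect drift.

    Missing intensity cells parse as 0 (not detected).
    """
    path = Path(path)
    if dialect == "simple-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"accession": str}, keep_default_na=False)
        df["description"] = df.get("description", "").astype(str)
        df["flags"] = df.get("flags", "").astype(str)
        for c in df.columns:
            if c.startswith(("mq:", "lfq:")):
                df[c] = _numeric(df[c])
        for c in ("length", "pn", "sc"):
            if c in df.columns:
                df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
        return ProteinTable(df)
    if dialect != "maxquant":
        raise ValueError(f"unknown dialect: {dialect!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = _lower_map(raw.columns)
    ov = {k: v for k, v in (column_overrides or {}).items()}

    def col(internal: str, *candidates: str) -> str:
        if internal in ov:
            return _require(colmap, ov[internal])
        return _require(colmap, *candidates)

    acc_col = col("accession", "Protein IDs", "Majority protein IDs")
    len_col = col("length", "Sequence length", "Sequence lengths")
    pn_col = col("pn", "Peptides", "Peptide counts (all)")
    sc_col = col("sc", "MS/MS count", "MS/MS Count")
    desc_col = None
    for cand in ("protein names", "fasta headers", "description"):
        if cand in colmap:
            desc_col = colmap[cand]
            break

    lfq_cols = {
        c[len("lfq intensity "):].strip(): c
        for c in raw.columns
        if c.lower().startswith("lfq intensity ")
    }
    if not lfq_cols:
        raise TableFormatError("missing mandatory column: 'LFQ intensity <experiment>'")
    mq_cols = {}
    for exp in lfq_cols:
        key = f"intensity {exp}".lower()
        if key not in colmap:
            raise TableFormatError(f"missing mandatory column: 'Intensity {exp}'")
        mq_cols[exp] = colmap[key]

    flag_cols = {
        "only_identified_by_site": _require(colmap, "Only identified by site"),
        "reverse": _require(colmap, "Reverse"),
        "contaminant": _require(colmap, "Contaminant", "Potential contaminant"),
    }

    df = pd.DataFrame()
    df["accession"] = raw[acc_col].str.split(";").str[0].str.strip()
    df["description"] = raw[desc_col].astype(str) if desc_col else ""
    length = pd.to_numeric(raw[len_col].str.split(";").str[0], errors="coerce")
    if length.isna().any():
        bad = df["accession"][length.isna()].tolist()
        raise TableFormatError(f"unparseable sequence length for: {bad}")
    df["length"] = length.astype(int)
    df["pn"] = pd.to_numeric(raw[pn_col].str.split(";").str[0], errors="coerce").fillna(0).astype(int)
    df["sc"] = pd.to_numeric(raw[sc_col], errors="coerce").fillna(0).astype(int)
    flags = []
    flag_frames = {name: raw[c].str.strip().str.lower() for name, c in flag_cols.items()}
    for i in range(len(raw)):
        flags.append(";".join(n for n in FLAGS if flag_frames[n].iat[i] in _TRUTHY))
    df["flags"] = flags
    for exp in sorted(lfq_cols):
        df[f"mq:{exp}"] = _numeric(raw[mq_cols[exp]])
        df[f"lfq:{exp}"] = _numeric(raw[lfq_cols[exp]])
    return ProteinTable(df)


def filter_categorical(table: ProteinTable) -> ProteinTable:
    """Drop rows flagged *only identified by site*, *reverse* or *contaminant*.

    Returns a new table; the input is not modified.  A row carrying several
    flags is removed once.  Idempotent.
    """
    keep = table.df["flags"].astype(str).str.len() == 0
    removed = int((~keep).sum())
    logger.info("filter_categorical: removed %d flagged row(s) of %d", removed, len(table))
    return ProteinTable(table.df[keep].reset_index(drop=True))


@dataclass
class AnnotationMap:
    """Accession -> GO-term set and boolean surface features.

    Accessions absent from the source file are absent from the map (they are
    *unannotated*, not annotated-with-the-empty-set).
    """

    go_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    features: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, accession: str) -> bool:
        return accession in self.go_terms or accession in self.features

    def is_annotated(self, accession: str) -> bool:
        return accession in self

    def terms(self, accession: str) -> frozenset[str]:
        if accession not in self:
            raise KeyError(f"unannotated accession: {accession}")
        return self.go_terms.get(accession, frozenset())

    def feats(self, accession: str) -> frozenset[str]:
        if accession not in self:
            raise KeyError(f"unannotated accession: {accession}")
        return self.features.get(accession, frozenset())

    def has_term(self, accession: str, term: str) -> bool:
        """Membership test against GO terms and feature flags alike."""
        return term in self.go_terms.get(accession, frozenset()) or term in self.features.get(
            accession, frozenset()
        )

    def update(self, other: "AnnotationMap") -> None:
        for acc, t in other.go_terms.items():
            self.go_terms[acc] = self.go_terms.get(acc, frozenset()) | t
        for acc, f in other.features.items():
            self.features[acc] = self.features.get(acc, frozenset()) | f


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read GO/feature annotations.

    Accepted formats, detected from the content:

    * GAF 2.x (comment lines starting with ``!``; columns 2 and 5 used),
    * two-column TSV ``accession<TAB>GO:nnnnnnn`` (no header),
    * wide TSV with header ``accession`` plus any subset of
      ``GA TM SP PM ECS ECR ECM`` (truthy cells: 1/+/true/yes) and an
      optional ``go_terms`` column with semicolon-separated GO identifiers.

    Duplicate (accession, term) pairs are collapsed; malformed GO identifiers
    are skipped with a warning; an empty file is an error.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("!", "#"))
    ]
    if not lines:
        raise ValueError(f"empty annotation file: {path}")

    amap = AnnotationMap()
    header = lines[0].split("\t")
    header_lower = [h.strip().lower() for h in header]
    if "accession" in header_lower and (
        set(f.lower() for f in FEATURES) & set(header_lower) or "go_terms" in header_lower
    ):
        # wide format
        acc_i = header_lower.index("accession")
        feat_idx = {f: header_lower.index(f.lower()) for f in FEATURES if f.lower() in header_lower}
        go_i = header_lower.index("go_terms") if "go_terms" in header_lower else None
        for ln in lines[1:]:
            parts = ln.split("\t")
            acc = parts[acc_i].strip()
            feats = frozenset(
                f for f, i in feat_idx.items() if i < len(parts) and parts[i].strip().lower() in _TRUTHY
            )
            amap.features[acc] = amap.features.get(acc, frozenset()) | feats
            if go_i is not None and go_i < len(parts):
                _add_terms(amap, acc, parts[go_i].split(";"))
        return amap

    for ln in lines:
        parts = ln.split("\t")
        if len(parts) >= 15:  # GAF 2.x row
            acc, term = parts[1].strip(), parts[4].strip()
        elif len(parts) >= 2:
            acc, term = parts[0].strip(), parts[1].strip()
        else:
            warnings.warn(f"skipping malformed annotation line: {ln!r}")
            continue
        _add_terms(amap, acc, [term])
    if not amap.go_terms and not amap.features:
        raise ValueError(f"no usable annotations in {path}")
    return amap


def _add_terms(amap: AnnotationMap, acc: str, terms: Iterable[str]) -> None:
    good = []
    for t in terms:
        t = t.strip()
        if not t:
            continue
        if _GO_RE.match(t):
            good.append(t)
        else:
            warnings.warn(f"skipping malformed GO identifier {t!r} for {acc}")
    if good:
        amap.go_terms[acc] = amap.go_terms.get(acc, frozenset()) | frozenset(good)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; keys are bare accessions.

    UniProt-style ``db|ACC|NAME`` headers are reduced to ``ACC``.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        out[acc] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out
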