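"""Boolean gene-ontology classifier for cell-surface proteins.

A protein counts as a cell-surface protein if it is GPI-anchored (GA) or a
transmembrane protein (TM) assigned to the plasma membrane (PM), or if it is
a signal-peptide-containing protein (SP) assigned to the extracellular
space (ECS), region (ECR) or matrix (ECM):

    is_surface = ((GA or TM) and PM) or (SP and (ECS or ECR or ECM))

The expression is monotone: it considers only positive evidence, so adding
features can never revoke a surface call.  Feature flags are consumed from
the annotation table as given; no topology prediction is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .indices import assign_abundance_class, mean_log2_lfq
from .io import AnnotationMap, ProteinTable

logger = logging.getLogger(__name__)

#: Matched-clause labels, tested in this order.
CLAUSES = ("GA&PM", "TM&PM", "SP&EC", "none")


@dataclass(frozen=True)
class SurfaceCall:
    """Classification of one protein, with per-group abundance classes."""

    accession: str
    is_surface: bool
    matched_clause: str
    abundance_class: Mapping[str, str] | None = None
    note: str = ""


def classify_surface(features: Iterable[str]) -> SurfaceCall:
    """Evaluate the Boolean surface expression on a feature set.

    Pure function of the set: order and duplication of features are
    irrelevant.  The first matching clause (GA&PM, TM&PM, then the
    signal-peptide clause) is recorded.
    """
    f = frozenset(features)
    unknown = f - {"GA", "TM", "SP", "PM", "ECS", "ECR", "ECM"}
    if unknown:
        raise ValueError(f"unknown feature flag(s): {sorted(unknown)}")
    if "GA" in f and "PM" in f:
        clause = "GA&PM"
    elif "TM" in f and "PM" in f:
        clause = "TM&PM"
    elif "SP" in f and f & {"ECS", "ECR", "ECM"}:
        clause = "SP&EC"
    else:
        clause = "none"
    return SurfaceCall(accession="", is_surface=clause != "none", matched_clause=clause)


def surface_list(
    table: ProteinTable,
    annotations: AnnotationMap,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[SurfaceCall]:
    """Classify every protein of a (categorically filtered) table.

    ``groups`` maps a sample-group name (e.g. ``"B"``, ``"T"``) to the
    experiment labels belonging to it; each group gets an abundance class
    from the log2 mean LFQ intensity over its experiments.  Unannotated
    proteins are classified ``is_surface=False`` with note ``"unannotated"``
    and counted in a warning log line.
    """
    if groups is None:
        groups = {"all": list(table.experiments)}
    class_by_group = {}
    for g, exps in groups.items():
        missing = [e for e in exps if e not in table.experiments]
        if missing:
            raise ValueError(f"group {g!r} references unknown experiment(s): {missing}")
        m = mean_log2_lfq(table, experiments=exps)
        class_by_group[g] = {
            acc: assign_abundance_class(None if pd.isna(v) else float(v))
            for acc, v in m.items()
        }

    calls = []
    n_unannotated = 0
    for acc in table.df["accession"]:
        classes = {g: class_by_group[g][acc] for g in groups}
        if not annotations.is_annotated(acc):
            n_unannotated += 1
            calls.append(
                SurfaceCall(acc, False, "none", abundance_class=classes, note="unannotated")
            )
            continue
        base = classify_surface(annotations.feats(acc))
        calls.append(
            SurfaceCall(acc, base.is_surface, base.matched_clause, abundance_class=classes)
        )
    if n_unannotated:
        logger.warning("surface_list: %d of %d protein(s) unannotated", n_unannotated, len(table))
    return calls


def calls_to_frame(calls: Sequence[SurfaceCall]) -> pd.DataFrame:
    """Tabular form: accession, is_surface, matched_clause, class_<group>."""
    rows = []
    for c in calls:
        row = {
            "accession": c.accession,
            "is_surface": c.is_surface,
            "matched_clause": c.matched_clause,
            "note": c.note,
        }
        for g, cls in (c.abundance_class or {}).items():
            row[f"class_{g}"] = cls
        rows.append(row)
    return pd.DataFrame(rows)
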