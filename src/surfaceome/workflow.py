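"""Configured end-to-end runs: load -> indices -> enrich -> classify -> difftest.

A :class:`RunConfig` (typically parsed from an INI file) names the inputs
and thresholds; :func:`run_workflow` executes the configured stage chain,
writes one TSV per stage plus a JSON provenance report (package version,
seeds, per-stage row counts), and is deterministic under a fixed
configuration.  Stages whose inputs are not configured are skipped; a
failing stage aborts the run with the stage name.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .difftest import ImputationParams, SamParams, run_differential
from .digest import ObservabilityParams, params_from_ini, po_table
from .enrichment import enrichment_profile
from .indices import quantify, rank_and_bin
from .io import filter_categorical, read_annotations, read_fasta, read_protein_groups
from .surface import calls_to_frame, surface_list

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A stage of the configured workflow failed."""


@dataclass
class RunConfig:
    """Paths, thresholds and seeds of one workflow run."""

    table: Path
    out_dir: Path
    dialect: str = "maxquant"
    annotations: Path | None = None
    fasta: Path | None = None
    settings_ini: Path | None = None  # observability settings for PO
    bin_size: int = 50
    terms: tuple[str, ...] = ()
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group
    min_valid: int = 3
    require_in: str = "any"
    fdr: float = 0.01
    s0: float = 0.2
    imputation_width: float = 0.3
    imputation_down_shift: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.table).exists():
            raise WorkflowError(f"config: table not found: {self.table}")
        for name in ("annotations", "fasta", "settings_ini"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise WorkflowError(f"config: {name} not found: {p}")
        if self.groups:
            names = set(self.groups.values())
            if len(names) != 2:
                raise WorkflowError(
                    f"config: difftest needs exactly 2 groups, got {sorted(names)}"
                )

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise WorkflowError(f"config file not found: {path}")
        paths = cp["paths"]
        cfg = cls(
            table=Path(paths["table"]),
            out_dir=Path(paths.get("out_dir", "surfaceome_out")),
            dialect=paths.get("dialect", "maxquant"),
            annotations=Path(paths["annotations"]) if "annotations" in paths else None,
            fasta=Path(paths["fasta"]) if "fasta" in paths else None,
            settings_ini=Path(paths["settings_ini"]) if "settings_ini" in paths else None,
        )
        if cp.has_section("indices"):
            cfg.bin_size = cp.getint("indices", "bin_size", fallback=cfg.bin_size)
        if cp.has_section("enrich"):
            terms = cp.get("enrich", "terms", fallback="")
            cfg.terms = tuple(t.strip() for t in terms.split(",") if t.strip())
        if cp.has_section("difftest"):
            d = cp["difftest"]
            if "groups_file" in d:
                cfg.groups = read_groups_file(d["groups_file"])
            elif "groups" in d:
                cfg.groups = parse_groups(d["groups"])
            cfg.min_valid = d.getint("min_valid", cfg.min_valid)
            cfg.require_in = d.get("require_in", cfg.require_in)
            cfg.fdr = d.getfloat("fdr", cfg.fdr)
            cfg.s0 = d.getfloat("s0", cfg.s0)
            cfg.imputation_width = d.getfloat("width", cfg.imputation_width)
            cfg.imputation_down_shift = d.getfloat("down_shift", cfg.imputation_down_shift)
            cfg.seed = d.getint("seed", cfg.seed)
        return cfg


def parse_groups(text: str) -> dict[str, str]:
    """Parse ``sample:group`` pairs separated by commas or semicolons."""
    out: dict[str, str] = {}
    for chunk in text.replace(";", ",").split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" not in chunk:
            raise WorkflowError(f"malformed group assignment: {chunk!r}")
        sample, group = chunk.split(":", 1)
        out[sample.strip()] = group.strip()
    return out


def read_groups_file(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample label TAB group name."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise WorkflowError(f"malformed groups line: {ln!r}")
        out[parts[0].strip()] = parts[1].strip()
    return out


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns the provenance report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    def _load():
        table = read_protein_groups(config.table, dialect=config.dialect)
        filtered = filter_categorical(table)
        filtered.write(out_dir / "table.tsv")
        report["stages"]["load"] = {
            "n_rows": len(table),
            "n_after_filter": len(filtered),
            "experiments": list(filtered.experiments),
        }
        return filtered

    table = stage("load")(_load)

    po = None
    if config.fasta is not None:

        def _po():
            params = (
                params_from_ini(config.settings_ini)
                if config.settings_ini
                else ObservabilityParams()
            )
            seqs = read_fasta(config.fasta)
            result = po_table(seqs, params)
            pd.Series(result, name="po").rename_axis("accession").to_csv(
                out_dir / "po.tsv", sep="\t"
            )
            report["stages"]["po"] = {"n_sequences": len(result)}
            return result

        po = stage("po")(_po)

    def _indices():
        q = quantify(table, po=po)
        q.to_csv(out_dir / "indices.tsv", sep="\t", float_format="%.6g")
        report["stages"]["indices"] = {"n_rows": len(q)}
        return q

    stage("indices")(_indices)

    annotations = None
    if config.annotations is not None:
        annotations = stage("annotations")(lambda: read_annotations(config.annotations))

    if annotations is not None and config.terms:

        def _enrich():
            bins = rank_and_bin(table, bin_size=config.bin_size)
            profile = enrichment_profile(bins, annotations, list(config.terms))
            profile.to_frame().to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            report["stages"]["enrich"] = {
                "n_bins": profile.n_bins,
                "terms": list(config.terms),
            }

        stage("enrich")(_enrich)

    if annotations is not None:

        def _classify():
            group_sets: Mapping[str, list[str]] | None = None
            if config.groups:
                group_sets = {}
                for sample, group in config.groups.items():
                    group_sets.setdefault(group, []).append(sample)
            calls = surface_list(table, annotations, groups=group_sets)
            frame = calls_to_frame(calls)
            frame.to_csv(out_dir / "surface.tsv", sep="\t", index=False)
            report["stages"]["classify"] = {
                "n_surface": int(frame["is_surface"].sum()),
                "n_total": len(frame),
            }

        stage("classify")(_classify)

    if config.groups:

        def _difftest():
            result, rep = run_differential(
                table,
                config.groups,
                min_valid=config.min_valid,
                require_in=config.require_in,  # type: ignore[arg-type]
                imputation=ImputationParams(
                    width=config.imputation_width,
                    down_shift=config.imputation_down_shift,
                    seed=config.seed,
                ),
                sam=SamParams(s0=config.s0, fdr=config.fdr, seed=config.seed),
            )
            result.table.to_csv(out_dir / "difftest.tsv", sep="\t", float_format="%.6g")
            result.threshold_curve.to_csv(
                out_dir / "threshold_curve.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report["stages"]["difftest"] = rep

        stage("difftest")(_difftest)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
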