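"""End-to-end pipeline: tables in, epitope/quantification/statistics tables out.

Stage order: read -> decoy/contaminant removal -> length window -> replicate
consistency -> (optional peptide-level background removal) -> alignment ->
coverage islands -> register-shift splits -> landscapes -> epitope calls ->
(default epitope-level background removal) -> relative quantification ->
optional two-group differential test.  Every stage logs its in/out counts
to a machine-readable TSV so dataset attrition is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .differential import (
    DifferentialConfig,
    log2_impute,
    permutation_fdr,
    results_to_frame,
)
from .epitope_core import (
    RegisterShiftRule,
    build_islands,
    build_landscape,
    call_epitope,
    map_peptides,
    overhang_summary,
    split_registers,
)
from .filtering import (
    FilterConfig,
    background_remove,
    length_filter,
    remove_flagged,
    replicate_filter,
)
from .io_tables import (
    TableDialect,
    read_design,
    read_evidence_table,
    read_peptide_table,
    read_proteome,
    write_epitope_table,
)
from .quantification import DENOMINATOR_POLICIES, build_epitope_matrix

logger = logging.getLogger("plateau")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending item."""


@dataclass
class PipelineConfig:
    peptide_table: str = ""
    evidence_table: str = ""  # used instead of peptide_table when set
    fasta: str = ""
    design: str = ""
    out_dir: str = "plateau_out"
    dialect: dict[str, str] = field(default_factory=dict)
    filters: FilterConfig = field(default_factory=FilterConfig)
    background_removal: bool = True
    min_epitope_length: int = 11
    jump_min: int = 5
    overlap_min: int = 11
    plateau_frac: float = 0.8
    multimap: str = "first"
    denominator: str = "post-qc"
    differential: DifferentialConfig | None = None
    group_a: str = ""
    group_b: str = ""
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.denominator not in DENOMINATOR_POLICIES:
            raise ValueError(
                f"denominator must be one of {DENOMINATOR_POLICIES}, "
                f"got {self.denominator!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        filters = raw.pop("filters", {})
        diff = raw.pop("differential", None)
        cfg = cls(**raw)
        if isinstance(filters, dict):
            cfg.filters = FilterConfig(**filters)
        if isinstance(diff, dict):
            cfg.differential = DifferentialConfig(**diff)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    epitopes: list
    matrix: Any
    counts: pd.DataFrame
    unmapped: list
    differential: pd.DataFrame | None
    overhangs: Any


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write all outputs under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    logger.addHandler(fh)
    counts: list[dict] = []

    def stage(name: str, n_in: int, n_out: int, note: str = "") -> None:
        counts.append({"stage": name, "n_in": n_in, "n_out": n_out, "note": note})
        logger.info("%s: %d -> %d %s", name, n_in, n_out, note)

    def guarded(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    dialect = TableDialect.from_mapping(config.dialect)
    if config.evidence_table:
        records = guarded("read", read_evidence_table, config.evidence_table, dialect)
    else:
        records = guarded("read", read_peptide_table, config.peptide_table, dialect)
    stage("read", len(records), len(records))
    proteome = guarded("read_proteome", read_proteome, config.fasta)
    design = guarded("read_design", read_design, config.design)

    flagged = remove_flagged(records)
    stage(
        "remove_flagged",
        len(records),
        len(flagged.kept),
        f"decoy={flagged.n_decoy};contaminant={flagged.n_contaminant}",
    )
    post_flag = flagged.kept
    post_qc = length_filter(post_flag, config.filters)
    stage("length_filter", len(post_flag), len(post_qc))

    rep = guarded("replicate_filter", replicate_filter, post_qc, design, config.filters)
    retained = rep.union
    stage("replicate_filter", len(post_qc), len(retained))

    if config.background_removal and config.filters.background_level == "peptide":
        bg = guarded("background_remove", background_remove, retained, design,
                     config.filters)
        stage("background_remove_peptide", len(retained), len(bg.kept),
              f"removed={len(bg.removed)}")
        retained = bg.kept

    mapping = guarded(
        "map_peptides", map_peptides, retained, proteome, config.multimap, design
    )
    stage("map_peptides", len(retained), len(mapping.aligned),
          f"unmapped={len(mapping.unmapped)}")

    islands = build_islands(mapping.aligned)
    stage("build_islands", len(mapping.aligned), len(islands))
    rule = RegisterShiftRule(jump_min=config.jump_min, overlap_min=config.overlap_min)
    leaves = [leaf for isl in islands for leaf in split_registers(isl, rule)]
    stage("split_registers", len(islands), len(leaves))
    epitopes = [
        call_epitope(
            leaf,
            build_landscape(leaf),
            min_epitope_length=config.min_epitope_length,
            plateau_frac=config.plateau_frac,
        )
        for leaf in leaves
    ]
    stage("call_epitopes", len(leaves), len(epitopes))

    if config.background_removal and config.filters.background_level == "epitope":
        bg = guarded("background_remove", background_remove, epitopes, design,
                     config.filters)
        stage("background_remove_epitope", len(epitopes), len(bg.kept),
              f"removed={len(bg.removed)}")
        epitopes = bg.kept

    denominator_records = {
        "post-qc": post_qc,
        "pre-filter": post_flag,
        "retained-only": retained,
    }[config.denominator]
    run_ids = [r for r in design.run_ids
               if any(rec.observed_in(r) for rec in denominator_records)]
    matrix = guarded(
        "quantify", build_epitope_matrix, epitopes, denominator_records, run_ids
    )
    stage("quantify", len(epitopes), len(matrix.epitope_ids))

    overhangs = overhang_summary(epitopes)

    diff_frame = None
    if config.differential is not None:
        if not (config.group_a and config.group_b):
            raise PipelineError(
                "stage 'differential' failed: group_a and group_b must be set"
            )
        runs_a = [r.run_id for r in design.runs_for_condition(config.group_a)
                  if r.run_id in matrix.run_ids]
        runs_b = [r.run_id for r in design.runs_for_condition(config.group_b)
                  if r.run_id in matrix.run_ids]
        if len(runs_a) < 2 or len(runs_b) < 2:
            raise PipelineError(
                f"stage 'differential' failed: conditions {config.group_a!r}/"
                f"{config.group_b!r} have fewer than 2 quantified runs"
            )
        sub = matrix.values[runs_a + runs_b]
        sub = sub.dropna(how="all")
        dense = log2_impute(sub, config.differential)
        results = guarded(
            "differential", permutation_fdr, dense, runs_a, runs_b,
            config.differential,
        )
        diff_frame = results_to_frame(results)
        diff_frame.to_csv(out_dir / "volcano.tsv", sep="\t", index=False)
        stage("differential", len(dense),
              int((diff_frame["significant"] == "+").sum()), "n_out=significant")

    write_epitope_table(epitopes, matrix, out_dir / "epitopes.tsv")
    matrix.to_tsv(out_dir / "matrix.tsv")
    pd.DataFrame(
        {
            "sequence": [u.record.sequence for u in mapping.unmapped],
            "proteins": [";".join(u.record.protein_ids) for u in mapping.unmapped],
            "reason": [u.reason for u in mapping.unmapped],
        }
    ).to_csv(out_dir / "unmapped.tsv", sep="\t", index=False)
    counts_df = pd.DataFrame(counts, columns=["stage", "n_in", "n_out", "note"])
    counts_df.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
    resolved = config.to_dict()
    resolved["version"] = __version__
    with open(out_dir / "config_resolved.yaml", "w") as fhc:
        yaml.safe_dump(resolved, fhc, sort_keys=True)
    logger.removeHandler(fh)
    fh.close()
    return PipelineResult(
        out_dir=out_dir,
        epitopes=epitopes,
        matrix=matrix,
        counts=counts_df,
        unmapped=mapping.unmapped,
        differential=diff_frame,
        overhangs=overhangs,
    )
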