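"""Quality-control cascade applied before epitope grouping.

Stages, in pipeline order: decoy/contaminant removal, peptide length window
(11-30 aa inclusive, matching the MHCII open-groove ligand range),
replicate-consistency filtering (a peptide must be seen in at least
``min_tech_reps`` technical replicates within *every* biological replicate of
a condition), and background removal against immunoprecipitation-control
runs (peptides eluted from MHCII-negative cells are treated as false
positives, either at the peptide or at the consensus-epitope level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_tables import PeptideRecord, RunDesign


class FilterConfigError(ValueError):
    """The filter configuration is inconsistent with the run design."""


@dataclass(frozen=True)
class FilterConfig:
    min_peptide_length: int = 11
    max_peptide_length: int = 30
    min_tech_reps: int = 2
    tech_reps_total: int = 3
    require_all_bio_reps: bool = True
    background_level: str = "epitope"  # or "peptide"

    def __post_init__(self) -> None:
        if not 1 <= self.min_tech_reps <= self.tech_reps_total:
            raise FilterConfigError(
                f"min_tech_reps must be in [1, {self.tech_reps_total}]"
            )
        if self.min_peptide_length > self.max_peptide_length:
            raise FilterConfigError("min_peptide_length > max_peptide_length")
        if self.background_level not in ("peptide", "epitope"):
            raise FilterConfigError(
                f"background_level must be 'peptide' or 'epitope', "
                f"got {self.background_level!r}"
            )


@dataclass
class FlagRemovalResult:
    kept: list[PeptideRecord]
    n_decoy: int
    n_contaminant: int


def remove_flagged(records: Sequence[PeptideRecord]) -> FlagRemovalResult:
    """Drop decoy (reverse-database) and known-contaminant identifications."""
    kept = [r for r in records if not (r.is_decoy or r.is_contaminant)]
    return FlagRemovalResult(
        kept=kept,
        n_decoy=sum(r.is_decoy for r in records),
        n_contaminant=sum(r.is_contaminant for r in records),
    )


def length_filter(
    records: Sequence[PeptideRecord], config: FilterConfig = FilterConfig()
) -> list[PeptideRecord]:
    """Keep peptides whose length lies inside the inclusive window."""
    lo, hi = config.min_peptide_length, config.max_peptide_length
    return [r for r in records if lo <= r.length <= hi]


@dataclass
class ReplicateFilterResult:
    """Per-condition survivors of the replicate-consistency rule.

    ``by_condition`` maps condition label -> records retained for that
    condition; ``union`` preserves input order and holds every record
    retained in at least one condition.
    """

    by_condition: dict[str, list[PeptideRecord]]
    union: list[PeptideRecord]


def _passes_condition(
    record: PeptideRecord, design: RunDesign, condition: str, config: FilterConfig
) -> bool:
    bio_reps = design.bio_reps(condition)
    for runs in bio_reps.values():
        n_obs = sum(record.observed_in(r.run_id) for r in runs)
        if n_obs < config.min_tech_reps:
            return False
    return True


def replicate_filter(
    records: Sequence[PeptideRecord],
    design: RunDesign,
    config: FilterConfig = FilterConfig(),
) -> ReplicateFilterResult:
    """Apply the technical/biological replicate-consistency rule.

    A peptide is retained for a condition iff within each biological
    replicate of that condition it was observed (intensity recorded) in at
    least ``min_tech_reps`` technical replicates.  With
    ``require_all_bio_reps`` False, observation in any single biological
    replicate (still at ``min_tech_reps`` technical depth) suffices.
    """
    for cond in design.conditions:
        for bio, runs in design.bio_reps(cond).items():
            if len(runs) < config.min_tech_reps:
                raise FilterConfigError(
                    f"condition {cond!r} bio rep {bio!r} has "
                    f"{len(runs)} technical replicates < min_tech_reps="
                    f"{config.min_tech_reps}"
                )
    by_condition: dict[str, list[PeptideRecord]] = {c: [] for c in design.conditions}
    union: list[PeptideRecord] = []
    for record in records:
        in_any = False
        for cond in design.conditions:
            if config.require_all_bio_reps:
                ok = _passes_condition(record, design, cond, config)
            else:
                ok = any(
                    sum(record.observed_in(r.run_id) for r in runs)
                    >= config.min_tech_reps
                    for runs in design.bio_reps(cond).values()
                )
            if ok:
                by_condition[cond].append(record)
                in_any = True
        if in_any:
            union.append(record)
    return ReplicateFilterResult(by_condition=by_condition, union=union)


@dataclass
class BackgroundRemovalResult:
    kept: list
    removed: list


def _item_records(item) -> Iterable[PeptideRecord]:
    members = getattr(item, "members", None)
    if members is not None:
        return [m.record for m in members]
    return [item]


def background_remove(
    items: Sequence,
    design: RunDesign,
    config: FilterConfig = FilterConfig(),
) -> BackgroundRemovalResult:
    """Remove items observed in any immunoprecipitation-control run.

    ``items`` are :class:`PeptideRecord` objects (peptide-level removal,
    applied before grouping) or consensus epitopes (epitope-level removal,
    the default: an epitope is background when *any* member peptide was
    observed in *any* control run).  A single control observation suffices;
    no intensity threshold is applied.
    """
    controls = design.control_runs
    if not controls:
        raise FilterConfigError(
            "background removal requested but the design has no IP-control runs"
        )
    kept, removed = [], []
    for item in items:
        seen = any(
            rec.observed_in(run)
            for rec in _item_records(item)
            for run in controls
        )
        (removed if seen else kept).append(item)
    return BackgroundRemovalResult(kept=kept, removed=removed)
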