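"""Consensus-epitope calling from nested-peptide intensity landscapes.

MHCII ligands occur as nested sets: exoprotease trimming produces length
variants that share the groove-bound core.  Each identified peptide is
placed on its parent protein by exact substring search; peptides whose
covered intervals are connected through overlaps form a *coverage island*.
Summing, per residue, the MS1 intensities of every peptide covering that
residue yields an intensity *landscape*; its plateau — the contiguous run of
residues around the maximum holding more than ``plateau_frac`` of the
maximal value — is the consensus epitope.

Because a groove can be occupied in alternative registers (e.g. CLIP1/2/3),
a single island may mix two epitopes.  Scanning members by N-terminal start
position, a jump of ``jump_min`` (default 5) residues to the next start
combined with an overlap of fewer than ``overlap_min`` (default 11)
residues between the two boundary peptides splits the island in two; the
rule recurses so each leaf holds a single register.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_tables import PeptideRecord, ProteomeIndex, RunDesign


@dataclass(frozen=True)
class AlignedPeptide:
    """A peptide located on its parent protein, 0-based half-open."""

    record: PeptideRecord
    accession: str
    start: int
    end: int
    total_intensity: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "AlignedPeptide") -> int:
        """Shared residue count of the two concrete peptide intervals."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class UnmappedPeptide:
    record: PeptideRecord
    reason: str


@dataclass
class MappingResult:
    aligned: list[AlignedPeptide]
    unmapped: list[UnmappedPeptide]


def map_peptides(
    records: Sequence[PeptideRecord],
    proteome: ProteomeIndex,
    multimap_policy: str = "first",
    design: RunDesign | None = None,
) -> MappingResult:
    """Place each peptide on its assigned protein(s) by exact substring search.

    ``multimap_policy`` ``"first"`` keeps only the first listed accession
    (MaxQuant's leading/razor protein) and its first matching site, avoiding
    double counting; ``"all"`` lets a peptide contribute to every matching
    site of every assigned protein.  Landscape weights are the peptide's
    summed intensity across all non-control runs when a design is given,
    otherwise across all runs.  Peptides absent from all assigned proteins
    are reported, never silently dropped.
    """
    if multimap_policy not in ("first", "all"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    weight_runs = design.sample_runs if design is not None else None
    aligned: list[AlignedPeptide] = []
    unmapped: list[UnmappedPeptide] = []
    for record in records:
        weight = record.total_intensity(weight_runs)
        hits: list[tuple[str, int]] = []
        missing_acc: list[str] = []
        for acc in record.protein_ids:
            entry = proteome.get(acc)
            if entry is None:
                missing_acc.append(acc)
                continue
            pos = entry.sequence.find(record.sequence)
            while pos != -1:
                hits.append((acc, pos))
                if multimap_policy == "first":
                    break
                pos = entry.sequence.find(record.sequence, pos + 1)
            if hits and multimap_policy == "first":
                break
        if not hits:
            reason = (
                "accession(s) not in proteome: " + ",".join(missing_acc)
                if missing_acc and len(missing_acc) == len(record.protein_ids)
                else "sequence not found in assigned protein(s)"
            )
            unmapped.append(UnmappedPeptide(record, reason))
            continue
        for acc, pos in hits:
            aligned.append(
                AlignedPeptide(
                    record=record,
                    accession=acc,
                    start=pos,
                    end=pos + record.length,
                    total_intensity=weight,
                )
            )
    return MappingResult(aligned=aligned, unmapped=unmapped)


@dataclass
class CoverageIsland:
    """Maximal protein region covered by a connected set of aligned peptides."""

    accession: str
    region_start: int
    region_end: int
    members: list[AlignedPeptide]
    island_id: str = ""
    register_branch: tuple[int, ...] = ()  # lineage of register-shift splits

    def __post_init__(self) -> None:
        self.members = sorted(self.members, key=lambda m: (m.start, m.end))
        if not self.island_id:
            self.island_id = f"{self.accession}:{self.region_start}-{self.region_end}"

    @property
    def length(self) -> int:
        return self.region_end - self.region_start

    def region_sequence(self) -> str:
        """Stitch the region's sequence from member peptides."""
        chars = [""] * self.length
        for m in self.members:
            for i, c in enumerate(m.record.sequence):
                chars[m.start + i - self.region_start] = c
        if "" in chars:
            raise ValueError(f"island {self.island_id} has uncovered residues")
        return "".join(chars)


def build_islands(aligned: Sequence[AlignedPeptide]) -> list[CoverageIsland]:
    """Group alignments into maximal 1x-coverage islands per protein.

    Two peptides join the same island iff their intervals are connected
    through members sharing at least one residue; abutting intervals with
    zero shared residues stay separate (half-open convention).
    """
    by_acc: dict[str, list[AlignedPeptide]] = {}
    for a in aligned:
        by_acc.setdefault(a.accession, []).append(a)
    islands: list[CoverageIsland] = []
    for acc in sorted(by_acc):
        members = sorted(by_acc[acc], key=lambda m: (m.start, m.end))
        group: list[AlignedPeptide] = []
        group_end = -1
        for m in members:
            if group and m.start >= group_end:
                islands.append(
                    CoverageIsland(acc, group[0].start, group_end, group)
                )
                group = []
            group.append(m)
            group_end = max(group_end, m.end)
        if group:
            islands.append(CoverageIsland(acc, group[0].start, group_end, group))
    return islands


@dataclass(frozen=True)
class RegisterShiftRule:
    """Jump/overlap thresholds for register-shift deconvolution."""

    jump_min: int = 5
    overlap_min: int = 11

    def __post_init__(self) -> None:
        if self.jump_min < 1 or self.overlap_min < 1:
            raise ValueError("jump_min and overlap_min must be >= 1")


def _boundary_overlap(members: list[AlignedPeptide], n: int, m: int) -> int:
    """Overlap between the last peptide starting at <= n and the first at m.

    Members are (start, end)-sorted; duplicate starts are collapsed to one
    position for jump detection, so 'last at <= n' is the longest peptide
    starting exactly at n and 'first at m' the shortest starting at m.
    """
    left = max((p for p in members if p.start == n), key=lambda p: p.end)
    right = min((p for p in members if p.start == m), key=lambda p: p.end)
    return left.overlap(right)


def split_registers(
    island: CoverageIsland, rule: RegisterShiftRule = RegisterShiftRule()
) -> list[CoverageIsland]:
    """Recursively segregate register-shifted nested sets.

    Scanning consecutive distinct start positions (n, n+m), the first pair
    with m >= ``jump_min`` whose boundary peptides share fewer than
    ``overlap_min`` residues splits the members into {start <= n} and
    {start >= n+m}; both groups are re-scanned.  Leaves are returned in
    protein order with their split lineage recorded.
    """
    members = island.members
    starts = sorted({p.start for p in members})
    for n, nxt in zip(starts, starts[1:]):
        if nxt - n < rule.jump_min:
            continue
        if _boundary_overlap(members, n, nxt) >= rule.overlap_min:
            continue
        left = [p for p in members if p.start <= n]
        right = [p for p in members if p.start >= nxt]
        leaves: list[CoverageIsland] = []
        for branch, group in enumerate((left, right)):
            child = CoverageIsland(
                accession=island.accession,
                region_start=min(p.start for p in group),
                region_end=max(p.end for p in group),
                members=group,
                island_id=f"{island.island_id}.{branch}",
                register_branch=island.register_branch + (branch,),
            )
            leaves.extend(split_registers(child, rule))
        return leaves
    return [island]


@dataclass
class Landscape:
    """Per-residue summed-intensity vector over a coverage island."""

    island: CoverageIsland
    values: np.ndarray

    @property
    def mass(self) -> float:
        return float(self.values.sum())


def build_landscape(island: CoverageIsland) -> Landscape:
    """Sum, per residue, the total intensity of every member covering it."""
    values = np.zeros(island.length, dtype=float)
    off = island.region_start
    for m in island.members:
        values[m.start - off : m.end - off] += m.total_intensity
    return Landscape(island=island, values=values)


@dataclass
class ConsensusEpitope:
    """A plateau-derived consensus epitope with its member nested set."""

    accession: str
    core_start: int  # 0-based half-open on the protein
    core_end: int
    core_sequence: str
    members: list[AlignedPeptide]
    mean_n_overhang: float
    mean_c_overhang: float
    register_shift_split: bool = False
    lineage: tuple[int, ...] = ()
    parent_island_id: str = ""
    degenerate: bool = False
    plateau_frac_used: float = 0.8

    @property
    def epitope_id(self) -> str:
        # 1-based inclusive coordinates, matching written outputs
        return f"{self.accession}:{self.core_start + 1}-{self.core_end}"

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start


def _plateau_bounds(values: np.ndarray, threshold: float) -> tuple[int, int]:
    """Maximal contiguous run of values > threshold containing the (leftmost) max."""
    peak = int(np.argmax(values))
    above = values > threshold
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak + 1
    while hi < len(values) and above[hi]:
        hi += 1
    return lo, hi


def call_epitope(
    island: CoverageIsland,
    landscape: Landscape | None = None,
    min_epitope_length: int = 11,
    plateau_frac: float = 0.8,
    frac_decrement: float = 0.05,
) -> ConsensusEpitope:
    """Call the consensus epitope of a (register-split) island.

    The core is the maximal contiguous run of residues containing the
    landscape maximum whose values are strictly greater than
    ``plateau_frac`` x max.  If shorter than ``min_epitope_length`` (11 =
    9-residue binding core plus one flank on each side), the fraction is
    lowered in fixed decrements until the core is long enough or the whole
    island is used.  Islands shorter than the minimum are flagged degenerate
    and returned whole.  Exactly one epitope is produced per leaf island.
    """
    if landscape is None:
        landscape = build_landscape(island)
    values = landscape.values
    seq = island.region_sequence()
    off = island.region_start
    frac = plateau_frac
    if island.length < min_epitope_length:
        lo, hi, degenerate = 0, island.length, True
    else:
        degenerate = False
        peak = float(values.max())
        lo, hi = _plateau_bounds(values, frac * peak)
        while hi - lo < min_epitope_length and frac > 0:
            frac = max(0.0, frac - frac_decrement)
            lo, hi = _plateau_bounds(values, frac * peak)
        if hi - lo < min_epitope_length:
            lo, hi = 0, island.length
    core_start, core_end = off + lo, off + hi
    n_over = [max(0, core_start - m.start) for m in island.members]
    c_over = [max(0, m.end - core_end) for m in island.members]
    return ConsensusEpitope(
        accession=island.accession,
        core_start=core_start,
        core_end=core_end,
        core_sequence=seq[lo:hi],
        members=list(island.members),
        mean_n_overhang=float(np.mean(n_over)),
        mean_c_overhang=float(np.mean(c_over)),
        register_shift_split=bool(island.register_branch),
        lineage=island.register_branch,
        parent_island_id=island.island_id,
        degenerate=degenerate,
        plateau_frac_used=frac,
    )


def call_epitopes(
    aligned: Sequence[AlignedPeptide],
    rule: RegisterShiftRule = RegisterShiftRule(),
    min_epitope_length: int = 11,
    plateau_frac: float = 0.8,
) -> list[ConsensusEpitope]:
    """Full grouping pass: islands -> register splits -> one epitope per leaf."""
    epitopes = []
    for island in build_islands(aligned):
        for leaf in split_registers(island, rule):
            epitopes.append(
                call_epitope(
                    leaf,
                    min_epitope_length=min_epitope_length,
                    plateau_frac=plateau_frac,
                )
            )
    return epitopes


@dataclass
class OverhangSummary:
    mean_n_overhang: float
    mean_c_overhang: float
    per_epitope: list[tuple[str, float, float]]  # (epitope_id, n, c)
    n_members: int


def overhang_summary(epitopes: Sequence[ConsensusEpitope]) -> OverhangSummary:
    """Dataset-wide mean N-/C-terminal overhangs over all member peptides."""
    n_vals: list[int] = []
    c_vals: list[int] = []
    per_ep = []
    for ep in epitopes:
        per_ep.append((ep.epitope_id, ep.mean_n_overhang, ep.mean_c_overhang))
        for m in ep.members:
            n_vals.append(max(0, ep.core_start - m.start))
            c_vals.append(max(0, m.end - ep.core_end))
    if not n_vals:
        return OverhangSummary(0.0, 0.0, per_ep, 0)
    return OverhangSummary(
        mean_n_overhang=float(np.mean(n_vals)),
        mean_c_overhang=float(np.mean(c_vals)),
        per_epitope=per_ep,
        n_members=len(n_vals),
    )
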