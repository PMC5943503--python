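"""Ground-truth immunopeptidome simulator.

Emulates the statistical structure the epitope-calling pipeline assumes:
nested peptide series produced by exoprotease trimming around a fixed
groove-bound core, register-shifted epitope pairs, log-normal MS1
intensities with per-epitope condition fold changes, a replicated run
design (conditions x biological x technical replicates plus IP-control
runs), per-cell missingness, and background binders planted on decoy
proteins so background removal has an unambiguous truth.

Overhangs are drawn per terminus from a truncated geometric distribution
(every simulated peptide contains the full planted core); the default
``trim_p`` of 0.375 gives a mean overhang of ~1.7 residues per terminus,
the magnitude observed in real MHCII elution data.  All randomness flows
through a single seeded generator, so a fixed config yields byte-identical
output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .epitope_core import ConsensusEpitope
from .io_tables import VALID_RESIDUES

_AMINO_ACIDS = np.array(sorted(VALID_RESIDUES))


class SimulationError(ValueError):
    """The requested scenario cannot be laid out on the configured proteins."""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_proteins: int = 10
    protein_length: tuple[int, int] = (250, 400)
    n_epitopes: int = 20
    core_length: int = 13
    trim_p: float = 0.375  # geometric success prob; mean overhang (1-p)/p ~ 1.67
    max_overhang: int = 6
    peptides_per_epitope: tuple[int, int] = (8, 14)
    intensity_log_mu: float = 16.0  # natural-log location of base MS1 intensity
    intensity_log_sigma: float = 0.8
    run_noise_sigma: float = 0.3
    conditions: tuple[str, ...] = ("condA", "condB")
    n_bio: int = 2
    n_tech: int = 3
    n_control_runs: int = 2
    missingness: float = 0.1
    n_background_peptides: int = 5
    background_in_samples: bool = True
    register_shift_fraction: float = 0.2  # fraction of epitopes in shifted pairs
    pair_core_gap: int = 3  # residues between a pair's cores
    pair_max_overhang: int = 2  # keeps planted pairs split-rule-valid
    n_regulated: int = 4
    fold_change: float = 4.0
    n_decoy_rows: int = 2
    n_contaminant_rows: int = 2
    jump_min: int = 5
    overlap_min: int = 11


@dataclass
class PlantedEpitope:
    epitope_id: str
    accession: str
    core_start: int  # 0-based half-open
    core_end: int
    core_sequence: str
    abundance: dict[str, float]  # condition -> expected raw MS1 level
    partner_id: str | None = None  # register-shift partner
    regulated: bool = False


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    proteins: dict[str, str]  # accession -> sequence (includes decoy proteins)
    peptide_rows: pd.DataFrame  # MaxQuant-dialect peptide table
    design_rows: pd.DataFrame
    truth_epitopes: list[PlantedEpitope]
    background_sequences: list[str]

    @property
    def run_ids(self) -> list[str]:
        return list(self.design_rows["run_id"])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA + peptides.tsv + design.tsv + truth.tsv; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteome.fasta",
            "peptides": out / "peptides.tsv",
            "design": out / "design.tsv",
            "truth": out / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for acc in sorted(self.proteins):
                fh.write(f">{acc} synthetic protein\n{self.proteins[acc]}\n")
        self.peptide_rows.to_csv(paths["peptides"], sep="\t", index=False)
        self.design_rows.to_csv(paths["design"], sep="\t", index=False)
        truth = pd.DataFrame(
            {
                "epitope_id": [t.epitope_id for t in self.truth_epitopes],
                "accession": [t.accession for t in self.truth_epitopes],
                "start": [t.core_start + 1 for t in self.truth_epitopes],
                "end": [t.core_end for t in self.truth_epitopes],
                "core": [t.core_sequence for t in self.truth_epitopes],
                "partner_id": [t.partner_id or "" for t in self.truth_epitopes],
                "regulated": ["+" if t.regulated else "" for t in self.truth_epitopes],
                **{
                    f"abundance {c}": [t.abundance[c] for t in self.truth_epitopes]
                    for c in self.config.conditions
                },
            }
        )
        truth.to_csv(paths["truth"], sep="\t", index=False)
        bg = pd.DataFrame({"background_peptide": self.background_sequences})
        paths["background"] = out / "background.tsv"
        bg.to_csv(paths["background"], sep="\t", index=False)
        return paths


def _make_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        for b in range(1, cfg.n_bio + 1):
            for t in range(1, cfg.n_tech + 1):
                rows.append(
                    {
                        "run_id": f"{cond}_b{b}_t{t}",
                        "condition": cond,
                        "bio_rep": f"b{b}",
                        "tech_rep": f"t{t}",
                        "is_control": "",
                    }
                )
    for i in range(1, cfg.n_control_runs + 1):
        rows.append(
            {
                "run_id": f"ctrl_{i}",
                "condition": "IPcontrol",
                "bio_rep": f"c{i}",
                "tech_rep": "t1",
                "is_control": "+",
            }
        )
    return pd.DataFrame(rows)


def _truncated_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    """Number of failures before first success, capped; 0 is the mode."""
    k = rng.geometric(p) - 1
    return int(min(k, cap))


def _layout_slots(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign each planted epitope (or pair) a non-overlapping protein slot."""
    n_pairs = int(round(cfg.register_shift_fraction * cfg.n_epitopes / 2))
    n_single = cfg.n_epitopes - 2 * n_pairs
    if n_single < 0:
        raise SimulationError("register_shift_fraction too large for n_epitopes")
    pair_width = 2 * cfg.core_length + cfg.pair_core_gap + 2 * cfg.max_overhang
    single_width = cfg.core_length + 2 * cfg.max_overhang
    gap = 5  # uncovered residues between neighbouring islands
    lengths = rng.integers(
        cfg.protein_length[0], cfg.protein_length[1] + 1, cfg.n_proteins
    )
    cursors = [cfg.max_overhang + 1] * cfg.n_proteins
    slots = []  # (protein index, start offset, is_pair)
    jobs = ["pair"] * n_pairs + ["single"] * n_single
    pi = 0
    for job in jobs:
        width = pair_width if job == "pair" else single_width
        placed = False
        for _ in range(cfg.n_proteins):
            if cursors[pi] + width + gap < lengths[pi] - cfg.max_overhang:
                slots.append((pi, cursors[pi], job == "pair"))
                cursors[pi] += width + gap
                placed = True
                pi = (pi + 1) % cfg.n_proteins
                break
            pi = (pi + 1) % cfg.n_proteins
        if not placed:
            raise SimulationError(
                "cannot place all epitopes: increase n_proteins or protein_length"
            )
    return lengths, slots


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset per the configured scenario."""
    cfg = config
    if not 0 <= cfg.missingness < 1:
        raise SimulationError("missingness must be in [0, 1)")
    if cfg.core_length + 2 * cfg.max_overhang > cfg.protein_length[0]:
        raise SimulationError("core plus overhangs exceeds minimum protein length")
    if cfg.core_length < 11:
        raise SimulationError("core_length below the 11-residue epitope minimum")
    rng = np.random.default_rng(cfg.seed)
    lengths, slots = _layout_slots(cfg, rng)
    proteins = {
        f"SYN{i:03d}": "".join(rng.choice(_AMINO_ACIDS, size=int(L)))
        for i, L in enumerate(lengths)
    }
    accs = sorted(proteins)
    design = _make_design(cfg)
    sample_runs = [r for r, c in zip(design["run_id"], design["is_control"]) if not c]
    control_runs = [r for r, c in zip(design["run_id"], design["is_control"]) if c]
    run_cond = dict(zip(design["run_id"], design["condition"]))

    # choose regulated epitopes (fold change applied to the last condition)
    regulated = set(
        rng.choice(cfg.n_epitopes, size=min(cfg.n_regulated, cfg.n_epitopes),
                   replace=False).tolist()
    )

    truth: list[PlantedEpitope] = []
    peptide_intervals: list[tuple[str, int, int, int]] = []  # (acc, start, end, ep idx)
    ep_idx = 0
    for pi, offset, is_pair in slots:
        acc = accs[pi]
        seq = proteins[acc]
        core_starts = [offset]
        caps = [cfg.max_overhang]
        if is_pair:
            core_starts.append(offset + cfg.core_length + cfg.pair_core_gap)
            caps = [cfg.pair_max_overhang, cfg.pair_max_overhang]
        ids = [f"ep{ep_idx + j:03d}" for j in range(len(core_starts))]
        for j, core_start in enumerate(core_starts):
            core_end = core_start + cfg.core_length
            base = float(np.exp(rng.normal(cfg.intensity_log_mu, 1.0)))
            abundance = {c: base for c in cfg.conditions}
            is_reg = ep_idx in regulated
            if is_reg:
                abundance[cfg.conditions[-1]] = base * cfg.fold_change
            truth.append(
                PlantedEpitope(
                    epitope_id=ids[j],
                    accession=acc,
                    core_start=core_start,
                    core_end=core_end,
                    core_sequence=seq[core_start:core_end],
                    abundance=abundance,
                    partner_id=(ids[1 - j] if is_pair else None),
                    regulated=is_reg,
                )
            )
            n_pep = int(rng.integers(*cfg.peptides_per_epitope, endpoint=True))
            for _ in range(n_pep):
                dn = _truncated_geometric(rng, cfg.trim_p, caps[j])
                dc = _truncated_geometric(rng, cfg.trim_p, caps[j])
                # keep lengths inside the 11-30 aa identification window
                while cfg.core_length + dn + dc > 30:
                    dn, dc = max(0, dn - 1), max(0, dc - 1)
                peptide_intervals.append((acc, core_start - dn, core_end + dc, ep_idx))
            ep_idx += 1

    # background binders live on dedicated decoy-source proteins
    background: list[tuple[str, str]] = []  # (accession, sequence)
    bg_len = 15
    for i in range(cfg.n_background_peptides):
        acc = f"BGP{i:03d}"
        prot = "".join(rng.choice(_AMINO_ACIDS, size=60))
        proteins[acc] = prot
        start = int(rng.integers(0, 60 - bg_len))
        background.append((acc, prot[start : start + bg_len]))

    # collapse duplicate peptide intervals: one table row per unique sequence
    truth_by_idx = {i: t for i, t in enumerate(truth)}
    by_seq: dict[str, dict] = {}
    for acc, s, e, idx in peptide_intervals:
        pep = proteins[acc][s:e]
        entry = by_seq.setdefault(pep, {"acc": acc, "idx": idx, "n": 0})
        entry["n"] += 1

    rows = []
    run_ids = list(design["run_id"])
    for pep in sorted(by_seq):
        entry = by_seq[pep]
        t = truth_by_idx[entry["idx"]]
        weight = float(np.exp(rng.normal(0.0, cfg.intensity_log_sigma))) * entry["n"]
        row = {
            "Sequence": pep,
            "Proteins": entry["acc"],
            "Leading razor protein": entry["acc"],
            "Reverse": "",
            "Potential contaminant": "",
        }
        for run in run_ids:
            cond = run_cond[run]
            if cond == "IPcontrol":
                row[f"Intensity {run}"] = ""
                continue
            if rng.random() < cfg.missingness:
                row[f"Intensity {run}"] = ""
                continue
            noise = float(np.exp(rng.normal(0.0, cfg.run_noise_sigma)))
            row[f"Intensity {run}"] = f"{t.abundance[cond] * weight * noise:.6g}"
        rows.append(row)

    for acc, pep in background:
        base = float(np.exp(rng.normal(cfg.intensity_log_mu, 1.0)))
        row = {
            "Sequence": pep,
            "Proteins": acc,
            "Leading razor protein": acc,
            "Reverse": "",
            "Potential contaminant": "",
        }
        for run in run_ids:
            in_controls = run in control_runs
            in_samples = cfg.background_in_samples and run in sample_runs
            if in_controls or in_samples:
                noise = float(np.exp(rng.normal(0.0, cfg.run_noise_sigma)))
                row[f"Intensity {run}"] = f"{base * noise:.6g}"
            else:
                row[f"Intensity {run}"] = ""
        rows.append(row)

    # decoy / contaminant rows exercising the flag filter
    for i in range(cfg.n_decoy_rows):
        pep = "".join(rng.choice(_AMINO_ACIDS, size=14))
        rows.append(
            {
                "Sequence": pep,
                "Proteins": f"REV__SYN{i:03d}",
                "Leading razor protein": f"REV__SYN{i:03d}",
                "Reverse": "+",
                "Potential contaminant": "",
                **{f"Intensity {r}": "1e6" for r in run_ids},
            }
        )
    for i in range(cfg.n_contaminant_rows):
        pep = "".join(rng.choice(_AMINO_ACIDS, size=14))
        rows.append(
            {
                "Sequence": pep,
                "Proteins": f"CON__KRT{i:02d}",
                "Leading razor protein": f"CON__KRT{i:02d}",
                "Reverse": "",
                "Potential contaminant": "+",
                **{f"Intensity {r}": "1e6" for r in run_ids},
            }
        )

    columns = [
        "Sequence",
        "Proteins",
        "Leading razor protein",
        "Reverse",
        "Potential contaminant",
    ] + [f"Intensity {r}" for r in run_ids]
    peptide_rows = pd.DataFrame(rows, columns=columns).fillna("")
    return SyntheticDataset(
        config=cfg,
        proteins=proteins,
        peptide_rows=peptide_rows,
        design_rows=design,
        truth_epitopes=truth,
        background_sequences=[p for _, p in background],
    )


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the four input files; returns their paths."""
    return simulate(config).write(out_dir)


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    n_truth: int
    n_called: int
    n_matched: int
    boundary_errors: list[tuple[str, int, int]]  # (epitope_id, start err, end err)
    pairs_total: int
    pairs_resolved: int
    missed: list[str]

    @property
    def mean_abs_boundary_error(self) -> float:
        if not self.boundary_errors:
            return float("nan")
        errs = [abs(s) + abs(e) for _, s, e in self.boundary_errors]
        return float(np.mean(errs)) / 2.0


def score_recovery(
    truth: Sequence[PlantedEpitope],
    called: Sequence[ConsensusEpitope],
    slack: int = 2,
) -> RecoveryReport:
    """Match called epitopes to planted ones within a per-terminus slack.

    A planted epitope is *detected* when some called epitope on the same
    protein has both boundary errors within ``slack`` residues; a planted
    register-shift pair is *resolved* when both partners are detected by
    distinct calls.
    """
    matched: dict[str, str] = {}  # truth id -> called epitope_id
    used: set[str] = set()
    boundary_errors = []
    for t in truth:
        best = None
        for ep in called:
            if ep.accession != t.accession or ep.epitope_id in used:
                continue
            s_err = ep.core_start - t.core_start
            e_err = ep.core_end - t.core_end
            if abs(s_err) <= slack and abs(e_err) <= slack:
                cost = abs(s_err) + abs(e_err)
                if best is None or cost < best[0]:
                    best = (cost, ep, s_err, e_err)
        if best is not None:
            _, ep, s_err, e_err = best
            matched[t.epitope_id] = ep.epitope_id
            used.add(ep.epitope_id)
            boundary_errors.append((t.epitope_id, s_err, e_err))
    pairs = {
        frozenset((t.epitope_id, t.partner_id))
        for t in truth
        if t.partner_id is not None
    }
    pairs_resolved = sum(
        1
        for pair in pairs
        if all(pid in matched for pid in pair)
        and len({matched[pid] for pid in pair}) == len(pair)
    )
    n_truth, n_called = len(truth), len(called)
    return RecoveryReport(
        recall=len(matched) / n_truth if n_truth else float("nan"),
        precision=len(used) / n_called if n_called else float("nan"),
        n_truth=n_truth,
        n_called=n_called,
        n_matched=len(matched),
        boundary_errors=boundary_errors,
        pairs_total=len(pairs),
        pairs_resolved=pairs_resolved,
        missed=[t.epitope_id for t in truth if t.epitope_id not in matched],
    )
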