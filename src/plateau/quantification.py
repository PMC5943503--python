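"""Label-free relative quantification of consensus epitopes.

An epitope's raw signal in a run is the sum of the MS1 intensities of its
member peptides observed in that run; dividing by the run's total MS1
intensity and scaling by 100 gives the *relative percent intensity*, which
is comparable across runs regardless of loading or instrument response.
The denominator can be computed over different record sets (see
``DENOMINATOR_POLICIES``); the default uses all peptides surviving
decoy/contaminant and length filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .epitope_core import ConsensusEpitope
from .io_tables import PeptideRecord

DENOMINATOR_POLICIES = ("post-qc", "pre-filter", "retained-only")


def epitope_run_intensity(epitope: ConsensusEpitope, run_id: str) -> float | None:
    """Summed member-peptide MS1 intensity in a run; None if never observed."""
    seen = {id(m.record): m.record for m in epitope.members}
    values = [
        r.intensities[run_id] for r in seen.values() if r.observed_in(run_id)
    ]
    if not values:
        return None
    return float(sum(values))


def run_total(records: Sequence[PeptideRecord], run_id: str) -> float:
    """Total MS1 intensity of a run over the given record set.

    A run with no observed intensity cannot normalize anything and is an
    error rather than a silent zero.
    """
    total = sum(r.intensities.get(run_id, 0.0) for r in records)
    if total <= 0:
        raise ValueError(f"run {run_id!r} has zero total intensity")
    return float(total)


def relative_intensity(
    epitope: ConsensusEpitope, run_id: str, total: float
) -> float | None:
    """Relative percent intensity: 100 x epitope signal / run total."""
    raw = epitope_run_intensity(epitope, run_id)
    if raw is None:
        return None
    return 100.0 * raw / total


@dataclass
class EpitopeMatrix:
    """Epitopes x runs table of relative percent intensities.

    ``values`` is a DataFrame (rows = epitope ids, columns = run ids) with
    NaN marking *not observed* — distinct from a true zero, which cannot
    occur (stored intensities are positive).  ``run_totals`` holds the
    per-run denominators.
    """

    values: pd.DataFrame
    run_totals: pd.Series
    epitopes: list[ConsensusEpitope]

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def epitope_ids(self) -> list[str]:
        return list(self.values.index)

    def value(self, epitope_id: str, run_id: str) -> float | None:
        v = self.values.at[epitope_id, run_id]
        return None if pd.isna(v) else float(v)

    def unassigned_fraction(self, run_id: str) -> float:
        """Percent of the run's total intensity not captured by any epitope."""
        assigned = float(np.nansum(self.values[run_id].to_numpy()))
        return 100.0 - assigned

    def condition_means(self, run_groups: dict[str, list[str]]) -> pd.DataFrame:
        """Mean relative intensity per condition, over runs with observed values."""
        out = {}
        for cond, runs in run_groups.items():
            out[cond] = self.values[runs].mean(axis=1, skipna=True)
        return pd.DataFrame(out)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "epitope_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col="epitope_id")


def build_epitope_matrix(
    epitopes: Sequence[ConsensusEpitope],
    denominator_records: Sequence[PeptideRecord],
    run_ids: Sequence[str],
) -> EpitopeMatrix:
    """Quantify every epitope across the given runs.

    ``denominator_records`` defines the per-run total MS1 intensity; choose
    it according to the denominator policy (the pipeline passes the
    post-QC record set by default).
    """
    epitopes = sorted(epitopes, key=lambda e: (e.accession, e.core_start, e.core_end))
    totals = {r: run_total(denominator_records, r) for r in run_ids}
    data = {
        run: [relative_intensity(ep, run, totals[run]) for ep in epitopes]
        for run in run_ids
    }
    values = pd.DataFrame(
        data, index=[ep.epitope_id for ep in epitopes], columns=list(run_ids),
        dtype=float,
    )
    return EpitopeMatrix(
        values=values,
        run_totals=pd.Series(totals, dtype=float),
        epitopes=list(epitopes),
    )
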