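"""Readers and writers for MaxQuant-dialect tables, FASTA proteomes and run designs.

The peptide-level input is a tab-separated table in the layout of MaxQuant's
``peptides.txt``: one row per identified peptide sequence, per-run MS1
intensities in columns sharing a common prefix (``"Intensity "`` by default),
and ``+``-flagged decoy / contaminant marker columns.  An evidence-level
reader is also provided; it aggregates evidence rows to peptide x run by
summation.  Column names are configurable through :class:`TableDialect` so
other search engines' exports can be mapped onto the same records.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: sentinel used for non-canonical FASTA residues (B, J, O, U, X, Z, ...);
#: it can never match a peptide residue, keeping alignment well defined.
NONCANONICAL_SENTINEL = "?"


class TableFormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for MaxQuant-style peptide/evidence tables."""

    sequence: str = "Sequence"
    proteins: str = "Proteins"
    leading_protein: str = "Leading razor protein"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "
    # evidence-table specifics
    run_column: str = "Raw file"
    intensity_column: str = "Intensity"

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str] | None) -> "TableDialect":
        if not mapping:
            return cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise TableFormatError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with per-run MS1 intensities and QC flags.

    ``intensities`` maps run id -> intensity; a run where the peptide was not
    observed is simply absent (zero intensities are never stored).
    """

    sequence: str
    protein_ids: tuple[str, ...]
    intensities: Mapping[str, float]
    is_contaminant: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"non-canonical residues {sorted(bad)} in peptide {self.sequence!r}"
            )
        if not self.protein_ids and not self.is_decoy:
            raise ValueError(f"peptide {self.sequence!r} has no protein assignment")
        for run, value in self.intensities.items():
            if not value > 0:
                raise ValueError(
                    f"non-positive intensity {value!r} stored for run {run!r}"
                )

    def observed_in(self, run_id: str) -> bool:
        return run_id in self.intensities

    @property
    def length(self) -> int:
        return len(self.sequence)

    def total_intensity(self, runs: Iterable[str] | None = None) -> float:
        if runs is None:
            return float(sum(self.intensities.values()))
        return float(sum(self.intensities.get(r, 0.0) for r in runs))


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    description: str = ""


@dataclass
class ProteomeIndex:
    """Accession -> protein lookup built from a FASTA file."""

    entries: dict[str, ProteinEntry]

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __getitem__(self, accession: str) -> ProteinEntry:
        return self.entries[accession]

    def get(self, accession: str) -> ProteinEntry | None:
        return self.entries.get(accession)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RunInfo:
    run_id: str
    condition: str
    biological_replicate: str
    technical_replicate: str
    is_ip_control: bool = False


@dataclass
class RunDesign:
    """Maps LC-MS/MS runs to condition / replicate structure / IP-control status."""

    runs: list[RunInfo]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if not ids:
            raise ValueError("run design contains no runs")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate run ids in design: {sorted(dupes)}")

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def control_runs(self) -> list[str]:
        return [r.run_id for r in self.runs if r.is_ip_control]

    @property
    def sample_runs(self) -> list[str]:
        return [r.run_id for r in self.runs if not r.is_ip_control]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            if not r.is_ip_control and r.condition not in seen:
                seen.append(r.condition)
        return seen

    def runs_for_condition(self, condition: str) -> list[RunInfo]:
        return [r for r in self.runs if r.condition == condition and not r.is_ip_control]

    def bio_reps(self, condition: str) -> dict[str, list[RunInfo]]:
        out: dict[str, list[RunInfo]] = {}
        for r in self.runs_for_condition(condition):
            out.setdefault(r.biological_replicate, []).append(r)
        return out


_TRUTHY = {"1", "true", "yes", "y", "+", "t"}


def _is_flagged(value: object) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in _TRUTHY


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect | Mapping[str, str] | None = None,
) -> list[PeptideRecord]:
    """Parse a peptides.txt-style table into :class:`PeptideRecord` objects.

    Intensity columns are discovered by the dialect's ``intensity_prefix``;
    the run id is the column name with the prefix stripped.  Zero, blank or
    NaN intensities are stored as *absent*.
    """
    if not isinstance(dialect, TableDialect):
        dialect = TableDialect.from_mapping(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.sequence, dialect.proteins):
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column {col!r} in {path}")
    run_cols = {
        c: c[len(dialect.intensity_prefix):]
        for c in df.columns
        if c.startswith(dialect.intensity_prefix)
        and c != dialect.intensity_prefix.strip()
    }
    records: list[PeptideRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = dict(zip(df.columns, row))
        is_decoy = dialect.reverse in df.columns and _is_flagged(row[dialect.reverse])
        is_cont = dialect.contaminant in df.columns and _is_flagged(
            row[dialect.contaminant]
        )
        proteins = tuple(
            p for p in str(row[dialect.proteins]).split(";") if p.strip()
        )
        if dialect.leading_protein in df.columns:
            lead = str(row[dialect.leading_protein]).strip()
            if lead:
                proteins = (lead,) + tuple(p for p in proteins if p != lead)
        intensities: dict[str, float] = {}
        for col, run_id in run_cols.items():
            cell = str(row[col]).strip()
            if cell in ("", "0", "NaN", "nan"):
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise TableFormatError(
                    f"unparsable intensity {cell!r} in column {col!r}, line {i}"
                ) from exc
            if value > 0:
                intensities[run_id] = value
        records.append(
            PeptideRecord(
                sequence=str(row[dialect.sequence]).strip().upper(),
                protein_ids=proteins,
                intensities=intensities,
                is_contaminant=is_cont,
                is_decoy=is_decoy,
            )
        )
    return records


def read_evidence_table(
    path: str | Path,
    dialect: TableDialect | Mapping[str, str] | None = None,
) -> list[PeptideRecord]:
    """Parse an evidence.txt-style table, summing evidence rows to peptide x run."""
    if not isinstance(dialect, TableDialect):
        dialect = TableDialect.from_mapping(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.sequence, dialect.proteins, dialect.run_column,
                dialect.intensity_column):
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column {col!r} in {path}")
    acc: dict[str, dict] = {}
    for i, row in df.iterrows():
        seq = str(row[dialect.sequence]).strip().upper()
        entry = acc.setdefault(
            seq,
            {
                "proteins": tuple(
                    p for p in str(row[dialect.proteins]).split(";") if p.strip()
                ),
                "intens": {},
                "decoy": False,
                "cont": False,
            },
        )
        if dialect.reverse in df.columns and _is_flagged(row[dialect.reverse]):
            entry["decoy"] = True
        if dialect.contaminant in df.columns and _is_flagged(row[dialect.contaminant]):
            entry["cont"] = True
        cell = str(row[dialect.intensity_column]).strip()
        if cell in ("", "0", "NaN", "nan"):
            continue
        try:
            value = float(cell)
        except ValueError as exc:
            raise TableFormatError(
                f"unparsable intensity {cell!r} at evidence line {i + 2}"
            ) from exc
        if value > 0:
            run = str(row[dialect.run_column]).strip()
            entry["intens"][run] = entry["intens"].get(run, 0.0) + value
    return [
        PeptideRecord(
            sequence=seq,
            protein_ids=e["proteins"],
            intensities=e["intens"],
            is_contaminant=e["cont"],
            is_decoy=e["decoy"],
        )
        for seq, e in acc.items()
    ]


_UNIPROT_HEADER = re.compile(r"^[a-z]{2}\|([^|]+)\|")


def default_accession_rule(header: str) -> str:
    """UniProt ``db|ACC|name`` middle token, else first whitespace token."""
    m = _UNIPROT_HEADER.match(header)
    if m:
        return m.group(1)
    return header.split()[0]


def read_proteome(path: str | Path, accession_rule=default_accession_rule) -> ProteomeIndex:
    """Load a FASTA proteome.

    Non-canonical residues (B, J, O, U, X, Z, *) are replaced by a sentinel
    character that never matches a peptide residue, so exact-substring
    alignment stays well defined without dropping the protein.
    """
    entries: dict[str, ProteinEntry] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        accession = accession_rule(rec.description)
        if accession in entries:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {accession!r}")
        seq = "".join(c if c in VALID_RESIDUES else NONCANONICAL_SENTINEL for c in seq)
        entries[accession] = ProteinEntry(accession, seq, rec.description)
    if n == 0:
        raise ValueError(f"no FASTA entries in {path}")
    return ProteomeIndex(entries)


def read_design(path: str | Path, strict: bool = True) -> RunDesign:
    """Read a tab-separated run-design table.

    Required columns: ``run_id``, ``condition``, ``bio_rep``, ``tech_rep``,
    ``is_control``.  With ``strict`` every non-control condition must have at
    least two biological replicates (the replicate-consistency filter is
    meaningless otherwise).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["run_id", "condition", "bio_rep", "tech_rep", "is_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"design file missing columns {missing}")
    runs = [
        RunInfo(
            run_id=str(r.run_id).strip(),
            condition=str(r.condition).strip(),
            biological_replicate=str(r.bio_rep).strip(),
            technical_replicate=str(r.tech_rep).strip(),
            is_ip_control=_is_flagged(r.is_control),
        )
        for r in df.itertuples(index=False)
    ]
    design = RunDesign(runs)
    if strict:
        for cond in design.conditions:
            if len(design.bio_reps(cond)) < 2:
                raise ValueError(
                    f"condition {cond!r} has fewer than 2 biological replicates"
                )
    return design


EPITOPE_TABLE_COLUMNS = [
    "accession",
    "epitope",
    "start",
    "end",
    "n_members",
    "member_peptides",
    "register_shift",
    "mean_n_overhang",
    "mean_c_overhang",
]


def write_epitope_table(epitopes, matrix, path: str | Path) -> None:
    """Write consensus epitopes plus per-run relative % intensities as TSV.

    Coordinates are written 1-based inclusive.  Rows are ordered by
    (accession, start) so identical inputs give byte-identical files.
    ``matrix`` may be ``None`` (no quantification columns) or an
    :class:`~plateau.quantification.EpitopeMatrix`.
    """
    run_ids = list(matrix.run_ids) if matrix is not None else []
    rows = []
    for ep in sorted(epitopes, key=lambda e: (e.accession, e.core_start, e.core_end)):
        row = {
            "accession": ep.accession,
            "epitope": ep.core_sequence,
            "start": ep.core_start + 1,
            "end": ep.core_end,
            "n_members": len(ep.members),
            "member_peptides": ";".join(
                sorted({m.record.sequence for m in ep.members})
            ),
            "register_shift": "+" if ep.register_shift_split else "",
            "mean_n_overhang": f"{ep.mean_n_overhang:.6g}",
            "mean_c_overhang": f"{ep.mean_c_overhang:.6g}",
        }
        for run in run_ids:
            value = matrix.value(ep.epitope_id, run)
            row[f"pct {run}"] = "" if value is None else f"{value:.10g}"
        rows.append(row)
    columns = EPITOPE_TABLE_COLUMNS + [f"pct {r}" for r in run_ids]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_epitope_table(path: str | Path) -> pd.DataFrame:
    """Read back a written epitope table (round-trip counterpart)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EPITOPE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"epitope table missing columns {missing}")
    for col in ("start", "end", "n_members"):
        df[col] = df[col].astype(int)
    for col in ("mean_n_overhang", "mean_c_overhang"):
        df[col] = df[col].astype(float)
    for col in df.columns:
        if col.startswith("pct "):
            df[col] = pd.to_numeric(df[col].replace("", "nan"))
    return df
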