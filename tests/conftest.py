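"""Shared fixtures: the CD74/CLIP worked example and small run designs."""

from __future__ import annotations

import numpy as np
import pytest

from plateau.io_tables import (
    PeptideRecord,
    ProteinEntry,
    ProteomeIndex,
    RunDesign,
    RunInfo,
)

# The classic CLIP-region nested set on the invariant chain (CD74, P04233):
# ten length variants trimmed around the shared groove-bound core.
CD74_PEPTIDES = [
    "KPVSKMRMATPLLMQALP",
    "KPPKPVSKMRMATPLLMQA",
    "KPPKPVSKMRMATPLLMQAL",
    "KPPKPVSKMRMATPLLMQALP",
    "KPPKPVSKMRMATPLLMQALPM",
    "KPVSKMRMATPLLMQA",
    "KPVSKMRMATPLLMQAL",
    "LPKPPKPVSKMRMATPLLMQAL",
    "LPKPPKPVSKMRMATPLLMQALPM",
    "RMATPLLMQALPM",
]
CD74_REGION = "LPKPPKPVSKMRMATPLLMQALPM"
CD74_CORE = "KPVSKMRMATPLLMQA"
# per-residue coverage of the region by the ten peptides at unit intensity
CD74_COVERAGE = [2, 2, 6, 6, 6, 9, 9, 9, 9, 9, 9,
                 10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 8, 5, 3]


@pytest.fixture
def cd74_proteome() -> ProteomeIndex:
    protein = "MHRRRS" + CD74_REGION + "GALANVAM"
    return ProteomeIndex({"P04233": ProteinEntry("P04233", protein)})


@pytest.fixture
def cd74_records() -> list[PeptideRecord]:
    return [
        PeptideRecord(seq, ("P04233",), {"r1": 1.0}) for seq in CD74_PEPTIDES
    ]


def make_design(
    conditions=("condA", "condB"), n_bio=2, n_tech=3, n_controls=2
) -> RunDesign:
    runs = [
        RunInfo(f"{c}_b{b}_t{t}", c, f"b{b}", f"t{t}")
        for c in conditions
        for b in range(1, n_bio + 1)
        for t in range(1, n_tech + 1)
    ]
    runs += [
        RunInfo(f"ctrl_{i}", "IPcontrol", f"c{i}", "t1", is_ip_control=True)
        for i in range(1, n_controls + 1)
    ]
    return RunDesign(runs)


@pytest.fixture
def design() -> RunDesign:
    return make_design()


def random_aligned_instance(rng: np.random.Generator):
    """A random small alignment instance on one protein (for oracle tests).

    Returns (protein sequence, list of AlignedPeptide).
    """
    from plateau.epitope_core import AlignedPeptide

    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    protein_len = int(rng.integers(40, 121))
    protein = "".join(rng.choice(alphabet, size=protein_len))
    n_pep = int(rng.integers(1, 31))
    aligned = []
    for _ in range(n_pep):
        length = int(rng.integers(11, 31))
        length = min(length, protein_len)
        start = int(rng.integers(0, protein_len - length + 1))
        weight = float(rng.uniform(0.5, 50.0))
        rec = PeptideRecord(
            protein[start : start + length], ("P1",), {"r1": weight}
        )
        aligned.append(
            AlignedPeptide(rec, "P1", start, start + length, weight)
        )
    return protein, aligned
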