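"""Alignment, islands, register splits, landscapes and plateau calling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plateau.epitope_core import (
    AlignedPeptide,
    CoverageIsland,
    RegisterShiftRule,
    build_islands,
    build_landscape,
    call_epitope,
    call_epitopes,
    map_peptides,
    overhang_summary,
    split_registers,
)
from plateau.io_tables import PeptideRecord, ProteinEntry, ProteomeIndex
from tests.conftest import (
    CD74_CORE,
    CD74_COVERAGE,
    CD74_REGION,
    random_aligned_instance,
)


def ap(protein: str, start: int, end: int, weight: float = 1.0) -> AlignedPeptide:
    rec = PeptideRecord(protein[start:end], ("P1",), {"r1": weight})
    return AlignedPeptide(rec, "P1", start, end, weight)


PROT = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(60))


class TestMapPeptides:
    def test_cd74_peptide_found_at_offset(self, cd74_proteome):
        rec = PeptideRecord("KPVSKMRMATPLLMQA", ("P04233",), {"r1": 1.0})
        out = map_peptides([rec], cd74_proteome)
        assert not out.unmapped
        a = out.aligned[0]
        protein = cd74_proteome["P04233"].sequence
        assert protein[a.start:a.end] == rec.sequence
        assert a.start == protein.find("KPVSKMRMATPLLMQA")

    def test_unfindable_peptide_reported_not_dropped(self, cd74_proteome):
        rec = PeptideRecord("WWWWWWWWWWW", ("P04233",), {"r1": 1.0})
        out = map_peptides([rec], cd74_proteome)
        assert out.aligned == []
        assert [u.record for u in out.unmapped] == [rec]

    def test_repeat_occurrence_policies(self):
        repeat = "ACDEFGHIKLMNP"
        protein = repeat + "WWWW" + repeat
        proteome = ProteomeIndex({"P1": ProteinEntry("P1", protein)})
        rec = PeptideRecord(repeat, ("P1",), {"r1": 1.0})
        first = map_peptides([rec], proteome, "first").aligned
        both = map_peptides([rec], proteome, "all").aligned
        assert [(a.start, a.end) for a in first] == [(0, 13)]
        assert {(a.start, a.end) for a in both} == {(0, 13), (17, 30)}

    def test_weight_excludes_control_runs(self, cd74_proteome):
        from tests.conftest import make_design

        design = make_design()
        rec = PeptideRecord(
            "KPVSKMRMATPLLMQA", ("P04233",),
            {"condA_b1_t1": 3.0, "ctrl_1": 100.0},
        )
        a = map_peptides([rec], cd74_proteome, design=design).aligned[0]
        assert a.total_intensity == 3.0


class TestBuildIslands:
    def test_overlapping_peptides_merge(self):
        islands = build_islands([ap(PROT, 0, 15), ap(PROT, 5, 20)])
        assert len(islands) == 1
        assert (islands[0].region_start, islands[0].region_end) == (0, 20)

    def test_distant_peptides_separate(self):
        islands = build_islands([ap(PROT, 0, 15), ap(PROT, 40, 55)])
        assert [(i.region_start, i.region_end) for i in islands] == [
            (0, 15), (40, 55)
        ]

    def test_abutting_intervals_stay_separate(self):
        islands = build_islands([ap(PROT, 0, 15), ap(PROT, 15, 30)])
        assert len(islands) == 2


class TestSplitRegisters:
    def test_jump_with_small_overlap_splits(self):
        members = [ap(PROT, 0, 14), ap(PROT, 1, 14),
                   ap(PROT, 8, 22), ap(PROT, 9, 22)]
        leaves = split_registers(build_islands(members)[0])
        assert len(leaves) == 2
        assert [{(m.start, m.end) for m in leaf.members} for leaf in leaves] == [
            {(0, 14), (1, 14)}, {(8, 22), (9, 22)}
        ]
        assert [leaf.register_branch for leaf in leaves] == [(0,), (1,)]

    def test_jump_with_large_overlap_does_not_split(self):
        members = [ap(PROT, 0, 20), ap(PROT, 8, 25)]
        leaves = split_registers(build_islands(members)[0])
        assert len(leaves) == 1

    def test_one_residue_steps_never_split(self):
        members = [ap(PROT, s, s + 14) for s in (0, 1, 2, 3)]
        leaves = split_registers(build_islands(members)[0])
        assert len(leaves) == 1

    def test_duplicate_starts_collapse_to_one_position(self):
        # three copies at start 0 then a jump: still a single jump event
        members = [ap(PROT, 0, 12), ap(PROT, 0, 13), ap(PROT, 0, 14),
                   ap(PROT, 7, 20)]
        leaves = split_registers(build_islands(members)[0])
        assert len(leaves) == 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_split_soundness_no_leaf_retains_qualifying_pair(self, seed):
        rng = np.random.default_rng(seed)
        _, aligned = random_aligned_instance(rng)
        rule = RegisterShiftRule()
        for island in build_islands(aligned):
            for leaf in split_registers(island, rule):
                starts = sorted({m.start for m in leaf.members})
                for n, nxt in zip(starts, starts[1:]):
                    if nxt - n < rule.jump_min:
                        continue
                    left = max((m for m in leaf.members if m.start == n),
                               key=lambda m: m.end)
                    right = min((m for m in leaf.members if m.start == nxt),
                                key=lambda m: m.end)
                    assert left.overlap(right) >= rule.overlap_min


class TestLandscape:
    def test_single_peptide_flat(self):
        island = build_islands([ap(PROT, 3, 18, 10.0)])[0]
        values = build_landscape(island).values
        assert np.array_equal(values, np.full(15, 10.0))

    def test_identical_intervals_add(self):
        island = build_islands([ap(PROT, 0, 15, 3.0), ap(PROT, 0, 15, 7.0)])[0]
        assert np.array_equal(build_landscape(island).values, np.full(15, 10.0))

    def test_mass_conservation_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            _, aligned = random_aligned_instance(rng)
            for island in build_islands(aligned):
                landscape = build_landscape(island)
                expected = sum(m.total_intensity * m.length for m in island.members)
                assert landscape.mass == pytest.approx(expected, rel=1e-9)

    def test_cd74_unit_coverage_vector(self, cd74_records, cd74_proteome):
        mapping = map_peptides(cd74_records, cd74_proteome)
        island = build_islands(mapping.aligned)[0]
        assert island.region_sequence() == CD74_REGION
        values = build_landscape(island).values
        assert values.astype(int).tolist() == CD74_COVERAGE


class TestCallEpitope:
    def test_flat_landscape_core_is_whole_peptide(self):
        island = build_islands([ap(PROT, 3, 18, 5.0)])[0]
        ep = call_epitope(island)
        assert (ep.core_start, ep.core_end) == (3, 18)
        assert ep.mean_n_overhang == 0.0 and ep.mean_c_overhang == 0.0

    def test_cd74_core_called_at_default_fraction(self, cd74_records,
                                                  cd74_proteome):
        mapping = map_peptides(cd74_records, cd74_proteome)
        epitopes = call_epitopes(mapping.aligned)
        assert len(epitopes) == 1
        assert epitopes[0].core_sequence == CD74_CORE
        assert not epitopes[0].degenerate

    def test_short_island_degenerate(self):
        # a 9-mer region cannot hold an 11-residue core
        rec = PeptideRecord("ACDEFGHIK", ("P1",), {"r1": 1.0})
        island = CoverageIsland("P1", 0, 9, [AlignedPeptide(rec, "P1", 0, 9, 1.0)])
        ep = call_epitope(island)
        assert ep.degenerate and (ep.core_start, ep.core_end) == (0, 9)

    def test_threshold_relaxation_reaches_min_length(self):
        # staggered stack: only 7 residues above 0.8*max, so the fraction
        # must be lowered until the core reaches 11 residues
        members = [ap(PROT, 10, 21), ap(PROT, 12, 23), ap(PROT, 14, 25)]
        ep = call_epitope(build_islands(members)[0])
        assert ep.core_length >= 11
        assert ep.plateau_frac_used < 0.8
        assert (ep.core_start, ep.core_end) == (12, 23)

    def test_leftmost_maximum_run_tie_break(self):
        # two residue-disjoint maxima of equal value: core from the left one
        members = [ap(PROT, 0, 12, 5.0), ap(PROT, 20, 32, 5.0),
                   ap(PROT, 10, 22, 1.0)]
        ep = call_epitope(build_islands(members)[0])
        assert ep.core_start == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(min_value=0.01, max_value=1e6))
    def test_scale_invariance_of_boundaries(self, seed, scale):
        rng = np.random.default_rng(seed)
        _, aligned = random_aligned_instance(rng)
        scaled = [AlignedPeptide(a.record, a.accession, a.start, a.end,
                                 a.total_intensity * scale) for a in aligned]
        for isl_a, isl_b in zip(build_islands(aligned), build_islands(scaled)):
            ep_a, ep_b = call_epitope(isl_a), call_epitope(isl_b)
            assert (ep_a.core_start, ep_a.core_end) == (ep_b.core_start,
                                                        ep_b.core_end)

    def test_raising_fraction_never_lengthens_core(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            _, aligned = random_aligned_instance(rng)
            for island in build_islands(aligned):
                if island.length < 25:
                    continue
                cores = {}
                for frac in (0.3, 0.5, 0.7, 0.9):
                    ep = call_epitope(island, plateau_frac=frac,
                                      min_epitope_length=1)
                    cores[frac] = ep.core_length
                assert cores[0.3] >= cores[0.5] >= cores[0.7] >= cores[0.9]
                checked += 1

    def test_every_aligned_peptide_in_exactly_one_epitope(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            _, aligned = random_aligned_instance(rng)
            epitopes = call_epitopes(aligned)
            seen = [id(m) for ep in epitopes for m in ep.members]
            assert sorted(seen) == sorted(id(a) for a in aligned)


class TestOverhangs:
    def test_members_equal_core_means_zero(self):
        island = build_islands([ap(PROT, 5, 16), ap(PROT, 5, 16)])[0]
        ep = call_epitope(island)
        summary = overhang_summary([ep])
        assert summary.mean_n_overhang == 0.0
        assert summary.mean_c_overhang == 0.0

    def test_symmetric_extension_arithmetic(self):
        # core [5,16); members [5,16) and [3,18) -> means 1.0 / 1.0
        island = build_islands([ap(PROT, 5, 16, 10.0), ap(PROT, 3, 18, 1.0)])[0]
        ep = call_epitope(island)
        assert (ep.core_start, ep.core_end) == (5, 16)
        assert ep.mean_n_overhang == 1.0 and ep.mean_c_overhang == 1.0

    def test_geometric_trimming_recovers_model_mean(self):
        # planted geometric(p=0.5) overhangs, capped at 6: the dataset-wide
        # mean must sit within 3 SE of the truncated-geometric expectation
        p, cap, n = 0.5, 6, 400
        rng = np.random.default_rng(3)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        core_start, core_end = 20, 33
        members = []
        draws = []
        for _ in range(n):
            dn = min(rng.geometric(p) - 1, cap)
            dc = min(rng.geometric(p) - 1, cap)
            draws += [dn, dc]
            members.append(ap(protein, core_start - dn, core_end + dc))
        ks = np.arange(0, cap + 1)
        pmf = (1 - p) ** ks * p
        pmf[-1] = 1 - pmf[:-1].sum()  # mass at the cap
        expected = float((ks * pmf).sum())
        var = float(((ks - expected) ** 2 * pmf).sum())
        se = np.sqrt(var / (2 * n))
        island = build_islands(members)[0]
        ep = call_epitope(island)
        assert (ep.core_start, ep.core_end) == (core_start, core_end)
        summary = overhang_summary([ep])
        for mean in (summary.mean_n_overhang, summary.mean_c_overhang):
            assert abs(mean - expected) < 3 * se
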