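# plateau

Consensus-epitope analysis for MHC class II immunopeptidomes.

Peptides eluted from MHCII molecules arrive as *nested sets*: endosomal
exoproteases trim the N- and C-termini of a groove-bound ligand, so one
epitope is typically identified as a dozen length variants (11–30 aa)
sharing a common core. Treating each variant as an independent analyte
fragments the signal and inflates multiple testing. `plateau` collapses
nested sets into **consensus epitopes** and carries label-free
quantification and differential testing at the epitope level.

## Method

1. **Alignment.** Each identified peptide is placed on its parent protein
   by exact substring search; connected covered intervals form *coverage
   islands*.
2. **Landscape.** Per residue *i* of an island, the landscape value is
   Σ of the total MS1 intensity of every member peptide covering *i*.
3. **Plateau call.** The consensus core is the maximal contiguous run of
   residues containing the landscape maximum with values > *f*·max
   (default *f* = 0.8), relaxed in steps of 0.05 until the core reaches the
   11-residue minimum (a 9-mer binding core plus one flank on each side).
4. **Register-shift deconvolution.** Ordering members by start position
   *n*, a jump of ≥ 5 residues to the next start, combined with < 11
   residues of overlap between the two boundary peptides, splits the island
   into two register groups; the rule recurses (think CLIP1/2/3 on the
   invariant chain).
5. **Quantification.** Epitope signal in a run = Σ member-peptide MS1
   intensities; dividing by the run's total MS1 intensity × 100 gives the
   *relative percent intensity*, comparable across runs.
6. **Differential testing.** Relative intensities are log2-transformed,
   missing values imputed with the global minimum, and each epitope scored
   with t = Δ/(se + s0) (s0 = 0.2); significance is calibrated by label
   permutations at FDR 0.01.

Upstream QC mirrors standard immunopeptidomics practice: decoy/contaminant
removal, an 11–30 aa length window, a replicate-consistency filter
(observed in ≥ 2 of 3 technical replicates within *every* biological
replicate of a condition), and removal of epitopes detected in
immunoprecipitation-control runs from MHCII-negative cells.

## Worked example

The ten CLIP-region length variants of the invariant chain (CD74, P04233)
at unit intensity (`python examples/worked_cd74.py`):

```
island region: LPKPPKPVSKMRMATPLLMQALPM
coverage     :  2  2  6  6  6  9  9  9  9  9  9 10 10 10 10 10 10 10 10 10 10  8  5  3
consensus core: KPVSKMRMATPLLMQA
protein coords: 12-27 (1-based)
mean overhangs: N 2.20  C 1.60 residues
```

All ten peptides cover the 16 residues `KPVSKMRMATPLLMQA`-region at depth
9–10; with the 0.8 threshold the plateau is exactly that shared core. The
overhang means say members extend on average ~2 residues beyond the core
N-terminally and ~1.6 C-terminally.

`python examples/synthetic_pipeline.py` runs the whole pipeline on a
simulated immunopeptidome with known truth (20 planted cores, 2
register-shifted pairs, 5 background binders, 4 condition-regulated
epitopes) and prints the per-stage count log, 100% core recovery, and the
volcano-table rows for the recovered regulated epitopes.

## Command line

```sh
plateau simulate --seed 1 --out sim/
plateau run --peptides sim/peptides.tsv --fasta sim/proteome.fasta \
            --design sim/design.tsv --out out/ \
            --group-a condA --group-b condB --seed 7
plateau group --peptides peptides.tsv --fasta proteome.fasta --out epitopes.tsv
plateau diff --matrix out/matrix.tsv --design sim/design.tsv \
             --group-a condA --group-b condB --seed 7 --out volcano.tsv
```

`run` writes `epitopes.tsv` (cores, members, overhangs, per-run relative %
intensities), `matrix.tsv`, `volcano.tsv`, `unmapped.tsv`, a per-stage
`counts.tsv`, and the resolved configuration.

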