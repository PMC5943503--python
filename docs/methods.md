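# Methods

## Data model and assumptions

The unit of input is an identified peptide with per-run MS1 intensities
(zero or blank = not observed; observed intensities are strictly positive).
The method assumes that nested peptides are exact substrings of a single
parent protein, that exoprotease trimming varies termini by a few residues
around a fixed groove-bound core, and that MS1 intensity is additive across
peptides — the per-residue landscape is a sum, so two half-overlapping
peptides count twice in their shared residues. No binding-motif or affinity
information is used.

Coordinates are 0-based half-open internally and 1-based inclusive in every
written table. Two peptides join a coverage island only when they share at
least one residue; abutting intervals stay separate.

## Plateau call

The core is the maximal contiguous run of residues containing the landscape
maximum whose values are **strictly** greater than `plateau_frac × max`
(default 0.8). Where the landscape rule is genuinely open, these choices
apply:

* **Boundary rule.** A fractional threshold rather than a derivative or
  step detector: it is scale-invariant (multiplying all intensities by a
  constant cannot move a boundary), reproduces the classic CD74/CLIP
  grouping under equal intensities, and has one interpretable knob.
* **Minimum length fallback.** If the run is shorter than
  `min_epitope_length` (default 11 = 9-residue binding core + 1 flank per
  side), the fraction drops in steps of 0.05 until the core is long enough,
  bottoming out at the whole island. Islands shorter than 11 residues are
  returned whole and flagged degenerate.
* **Ties.** With several equal-valued maxima the run containing the
  leftmost (most N-terminal) maximum is used — a determinism rule, not a
  biological claim.
* **One epitope per leaf island.** Multi-modal landscapes inside one
  register group are not re-split; the register rule is the only split.
  A consequence (known limitation): a peptide far from the plateau still
  belongs to that epitope's member list, and with strongly multi-modal
  intensity patterns a member may not overlap the final core.
* **Landscape weights** are each peptide's summed intensity over all
  non-control runs, so IP-control background signal cannot move epitope
  boundaries.

## Register-shift rule

Consecutive *distinct* start positions (duplicates collapse to one
position) are scanned N→C. A pair (n, n′) with n′ − n ≥ `jump_min` (5)
splits the island when the *boundary peptides* — the longest peptide
starting at n and the shortest starting at n′ — share fewer than
`overlap_min` (11) residues. The overlap is computed between those two
concrete intervals, not group envelopes, and the first qualifying pair
splits; both halves are re-scanned. After splitting, no leaf retains a
qualifying pair (tested as an invariant).

## Filters

* Decoy and contaminant flags remove a record outright.
* Length window 11–30 aa, both bounds inclusive.
* Replicate consistency: within **each** biological replicate of a
  condition the peptide must be observed in ≥ `min_tech_reps` (2) of the
  technical replicates. The per-biological-replicate reading is the
  strictest consistent interpretation; `require_all_bio_reps=False`
  selects the any-single-bio-rep alternative.
* Background: any observation in an IP-control run marks an item as
  background — no intensity threshold, because none is defensible without
  a noise model. Default level is the consensus epitope (applied after
  grouping: one tainted member removes the epitope); peptide-level removal
  before grouping is available.

## Quantification

Relative percent intensity = 100 × (Σ member intensities in run) / (run
total). The denominator policy decides the record set for the total:
`post-qc` (default; after decoy/contaminant and length filters, before
replicate filtering — the closest reading of "all MS1 intensity in the
measurement" that still excludes known artifacts), `pre-filter` (after
flag removal only), `retained-only` (replicate-filter survivors). Epitope
relative intensities plus the unassigned fraction close to 100% per run to
1e-9; missing (never-observed) cells are NaN, distinct from zero.
Condition summaries are means over runs with observed values; missing runs
are excluded, not zero-filled.

## Differential testing

Observed relative intensities are log2-transformed; missing cells take the
**global** minimum of the observed log2 values (one scalar for the matrix
— the literal minimum-observed-value rule; per-column imputation is a
deliberate non-feature). The statistic is t = (mean₂ − mean₁)/(se + s0)
with the Welch standard error and s0 = 0.2; p-values use
Welch–Satterthwaite degrees of freedom and are two-sided. With s0 = 0 the
statistic equals the ordinary Welch t-test to 1e-9 (tested against scipy).

FDR calibration permutes the group labels jointly across all items
(preserving inter-item correlation), 1000 rounds by default. The cutoff is
the smallest |t| at which (mean permutation exceedances per round)/
(observed exceedances) ≤ the target FDR; items at or above it are
significant. Group sizes smaller than needed for 1000 distinct relabelings
are handled by sampling permutations with replacement from the seeded
generator; a seed is mandatory and the pipeline refuses to default one
silently.

## Synthetic data generator

`SimulationConfig` defaults describe one fixed scenario used throughout
the tests: 20 planted 13-residue cores on 10 random proteins of 250–400
aa, 8–14 peptides per epitope, two conditions × 2 biological × 3 technical
replicates plus 2 IP-control runs, 10% missingness, 5 background binders
on dedicated decoy-source proteins, 20% of epitopes in register-shifted
pairs (core gap 3, so starts jump by 16 with ≤ 1 residue of boundary
overlap — valid splits by construction), and 4 epitopes with a 4-fold
change in the second condition.

Trimming draws each terminus overhang from a geometric distribution
(p = 0.375, capped at 6), giving a mean overhang of ~1.7 residues — the
magnitude seen in real MHCII elution data. Peptides always contain the
full planted core (extension-only trimming): nested sets in real data
share the groove-bound core, and truncation below the core would make the
planted truth ill-defined. Intensities are log-normal: per-epitope base
level (σ = 1 across epitopes), a per-peptide weight (σ = 0.8) fixed across
runs, and per-cell run noise (σ = 0.3). Background peptides appear in the
control runs and, by default, in all sample runs — they must survive the
replicate filter for epitope-level background removal to be exercised;
`background_in_samples=False` restricts them to controls.

What the simulator does **not** model: retention-time alignment /
match-between-runs artifacts, cleavage-motif (cathepsin) preferences,
chimeric or modified peptides, protein inference ambiguity (each peptide
has one source protein), and intensity-dependent missingness (missingness
is uniform). Pipeline recovery of planted truth therefore demonstrates
algorithmic correctness under the stated noise model, not robustness to
those real-data effects.

The repository's own recovery bar — ≥ 90% of planted cores within ±2
residues per terminus, all planted register pairs resolved — is evaluated
by `score_recovery` with greedy closest-match assignment.

## Numerical and degenerate cases

* A run with zero total intensity is an error, not a 0/0.
* Constant matrices produce zero significant calls (t = 0, p = 1).
* Variance-free groups: the moderated t falls back to diff/s0; with
  s0 = 0 and zero diff the statistic is 0 with p = 1.
* Non-canonical FASTA residues (B, J, O, U, X, Z) become a sentinel `?`
  that can never match a peptide residue.
* All row orders in written tables are sorted (accession, start), so
  identical inputs give byte-identical outputs.

## Problem sizes

Tests and the acceptance script run the default synthetic scenario
(~170 peptide rows, 14 runs), 200-instance oracle sweeps on proteins
≤ 120 aa, and 500-item × 12-run differential simulations at 1000
permutations — sizes chosen so the whole suite completes in seconds while
every code path, including the permutation machinery, runs at full
fidelity.
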