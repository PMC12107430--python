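# Methods

## Coordinate system and reference construct

All positions are 1-based, inclusive, in the numbering of the source viral
genome, so coordinates used in the field's literature (6029, 6218, …) apply
verbatim. The construct spans genomic 6006–6234 (229 nt): the IRES region
preceded by an extra 5′ G (assigned coordinate 6006) and followed by the
first translatable codon mutated to UAG at 6217–6219 for efficient RelE
cleavage, with UU at 6232–6233 equalizing the terminal triplet of cleaved
and full-length products. The cleavage position (6218) is the middle base of
the first codon — RelE cuts between the second and third A-site nucleotides
— and these relationships are enforced as construct invariants.

The package is sequence-generic: it accepts any single-record FASTA plus
landmarks. Because the viral sequence itself is not distributed here,
`synthetic_reference(seed)` builds a seeded random construct that carries
the fixed landmarks plus the wild-type base identities at positions named in
the literature (e.g. U at 6101, G at 6066, C at 6166), so published variant
labels parse against it. The analysis depends on coordinates and base
identities at mutated positions, not on the surrounding sequence, so this
stand-in exercises every pipeline stage faithfully; it is labelled synthetic
wherever it appears.

Internally all sequence is RNA (ACGU); FASTQ I/O uses the DNA alphabet with
conversion at the boundary, since sequencers emit DNA.

## Library designs and variant space

Three doped designs are built in: the single-mutant library over 6029–6216
(188 positions, 0.6% per alternative base, 1.8% total per position) and two
double-mutant libraries (ribosome-binding domains 6054–6073 + 6096–6170;
PKI region 6029–6036, 6043–6053, 6062–6067, 6074–6084, 6089–6096,
6165–6216) at 0.7% per alternative. Variants are identified by their sorted
substitution set, size 0 (wild type) to 2; enumeration yields 3·L single and
9·C(L,2) double variants for L design positions (564 singles for the study
single library; no published count is hard-coded). All mutagenized positions
lie 5′ of the cleavage position, so truncation never censors variant
identity — cleaved and full-length reads of a variant carry the same key.

## Forward model (simulator)

Each read draws a doped template: every design position is independently
substituted with probability 3 × the per-alternative rate, the alternative
chosen uniformly. Templates may exceed two substitutions; they inherit the
default kinetic truth and are later discarded by the mutation-count filter,
exactly as in the real analysis. Given the variant's truth (Y0, amplitude,
k), the read is emitted cleaved with probability
`(Y0 + amplitude·(1 − e^(−k·t)))/100` — truncated at 6218 — or full-length
otherwise, then receives a uniform-random 5-nt UMI and the adapter constant
`CTGTAGGCACCATCAAT` at its 3′ end (the ligation oligo's printed space is
read as a typographic break). Reads are single full-insert sense-strand
sequences with constant high quality; the real protocol's paired-end
merging, PCR duplication, and quality structure are deliberately not
modelled because the analysis depends only on insert identity and the 3′
terminus. Sequencing errors default to zero; an optional uniform
substitution-error rate exists to exercise the ≤2-mutation filter.

The zero-minute sample is simulated as `cleavage_fraction(truth, 0) = Y0`;
the wet protocol's distinct 0-min handling (RelE added after quenching) is
a biochemical detail outside the forward model.

Three additional modes support validation: a *variant mix* mode that emits
explicit per-variant read counts without doping (for scenarios targeting
specific mutants), a *gel mode* that returns Binomial(n_molecules)
percent-cleaved time courses directly, and an *exact mode* that allocates
cleaved counts as `round(n·fraction/100)` (round-half-even) with
deterministic UMIs, enabling bit-exact round-trip tests of the whole
pipeline. Per-sample seeds derive deterministically from one master seed, so
identical configurations reproduce byte-identical outputs.

## Read processing

Trimming is a suffix-anchored exact match of the adapter constant; the five
bases 5′ of it are the UMI and everything upstream is the insert. Reads
lacking the terminal constant (or a complete UMI) are discarded. Alignment
is anchored, ungapped, and substitution-only: the insert is compared
base-by-base to the equal-length reference prefix, the terminus is the
genomic coordinate of its last base, and mismatches are the substitutions.
This replaces a general-purpose trimmer/aligner with a deterministic exact
core, which is correct here because the library contains only point
substitutions anchored at the construct's 5′ end; anything longer than the
reference (would need gaps) is discarded as unalignable.

Classification follows the assay's printed rule: cleaved iff the terminus is
exactly 6218; full-length iff ≥6219. Termini short of 6218 (degradation
products) are discarded — the reporting rules leave their treatment open,
and discarding keeps the cleaved class strict. Reads with more than two
substitutions are discarded; substitutions outside the design intervals
still count toward the limit. UMIs are recorded but not used for collapsing
by default (no UMI deduplication is part of the assay's analysis); an
optional switch collapses identical (UMI, terminus, variant) triples.

## Quantification

Percent cleaved is `100 · n_cleaved / (n_cleaved + n_full)` per (variant,
replicate, timepoint). Cells with fewer than `min_total` = 50 reads are
suppressed — flagged and excluded from fitting — so unfittable low-coverage
cells are never confused with true 0% cleavage. The assay itself states no
coverage floor; 50 reads puts the binomial SE of a ~20% signal below ~6
percentage points and is configurable.

## Kinetic fitting

Time courses with ≥4 unsuppressed points including t = 0 are fit by bounded
nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective): Y0, amplitude ∈ [0, 100] %, k > 0 min⁻¹; initialization
Y0 ← first point, amplitude ← last − first (floored at 0), k ← 0.1 min⁻¹;
tolerances 1e-8. Points are sorted by time first, making the fit exactly
invariant to input ordering. Residuals are unweighted (percent values fit
directly), with optional binomial weighting by per-point coverage.
Degenerate constant courses get amplitude 0 with Y0 at the constant and k
pinned at its initialization with infinite SD and a `k_reliable=False` flag,
since k drops out of the model there.

Parameter SDs default to the asymptotic least-squares covariance
(Jacobian-based); a seeded residual-resampling bootstrap (default 200
draws) is available. Time courses that cannot be fit fall back to the
difference between the last and first time-point values as the amplitude
(negative values reported as-is), flagged as unconverged.

## Filters, nonfunctional calls, and fold changes

All thresholds are strict inequalities: amplitudes are reported when
sd(amplitude) < 10 percentage points (fallback amplitudes are kept in the
single-mutant amplitude surface, flagged); rate constants when
amplitude > 5 %, k < 0.7 min⁻¹, and sd(k) < k. Shrinking any threshold can
only shrink the kept set. A variant is called nonfunctional when its
amplitude is below 5 % in every replicate (indeterminate with fewer than
two replicates). Fold changes divide the mutant value by the wild-type
value within each replicate — only replicates where both pass the relevant
filter contribute; a zero wild-type value voids that replicate — then
average across replicates (SD with ddof = 1). Both the per-fit covariance
SD (used for filtering) and the across-replicate SD are emitted, since the
original screening SD's definition is ambiguous; a parameter with no
passing replicate is "not detectable". Wild type against itself is exactly
1 by construction.

## Report surfaces

The heatmap table holds one row per design position with the wild-type base
and the replicate-averaged amplitude for each of the three alternatives
(missing cells stay explicit NaN). The scatter table pairs each variant's
mean amplitude and rate fold changes, restricted to variants where both are
detectable. Dual-luciferase normalization divides each construct's mean
Fluc/Rluc ratio by the wild-type mean and propagates error as relative
errors in quadrature, `v·sqrt((s/m)² + (s_wt/m_wt)²)` — the standard choice
where the original propagation formula is unstated. Outputs are plain TSV
tables; rendering is left to the caller.

## Problem sizes and what the synthetic checks show

The recovery scenarios run at these sizes, chosen so each completes on one
core in minutes while keeping Monte-Carlo error well inside the quantity
checked: 200,000 doped templates for the substitution-rate check; 50,000
reads per timepoint (seven timepoints, 0–60 min) for full-pipeline
wild-type amplitude recovery; 10,000 molecules per timepoint in gel mode;
two replicates × two variants × 50,000 reads per timepoint per variant for
double-mutant fold-change recovery. The desk-scale analysis scripts narrow
the doped window to 20 positions (6096–6115) at the study doping rate
because per-variant kinetics at the full 188-position breadth require
study-scale sequencing depth.

Passing these checks shows that the pipeline's inference inverts its own
forward model without bias at realistic signal levels. It does not test
robustness to features the generator deliberately omits — sequencing-error
structure, PCR duplication, coverage imbalance across variants, ligation or
RT biases, or real extract kinetics deviating from single-exponential form
— so agreement with the synthetic truths is a statement about the analysis,
not about the biology.

## Known limitations

- Insertions/deletions and ≥3-substitution variants are out of scope by
  design; gapped reads are discarded rather than aligned.
- The exponential forward model is also the fitted model; model
  misspecification is not probed by the recovery scenarios.
- The bootstrap SD option refits per draw and is correspondingly slower;
  the covariance SD is the default everywhere.
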