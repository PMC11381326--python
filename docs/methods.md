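# Methods

## The measurement

Dimethyl sulfate (DMS) methylates the N1 of adenine and N3 of cytosine when
those nitrogens are solvent-accessible; during reverse transcription with a
mutation-tolerant RT the adducts are read out as mismatches, so the
per-position *mutation fraction* in sequencing reads is a population-average
reactivity. RNA tertiary contacts such as the GAAA tetraloop / tetraloop
receptor (TL/TLR) bury the N1 of their interacting adenines: when the contact
is formed, those probe adenines go quiet. Because contact formation is
Mg2+-dependent, titrating Mg2+ and watching the probe adenines turns a
chemical-probing experiment into a thermodynamic one.

qmapseq implements that pipeline for pooled one-pot libraries:

1. **Sample demultiplexing** by a 12-nt RT-primer barcode (RTB) at the 5'
   end of read 1, inclusive hamming threshold (default 4), ties rejected.
2. **Construct demultiplexing** by a unique internal helix barcode (default:
   7 base pairs of a designated helix). The forward-strand barcode is
   searched in the mate carrying the RNA 5'→3' within ±3 positions of its
   expected offset, the paired reverse-strand barcode in the other mate; a
   read pair is assigned only if exactly one construct matches within the
   allowed distance (default 1). Misassignment adds coherent noise to every
   downstream fraction, so ambiguity is always resolved by dropping the read.
3. **Profiling**: each mate is globally aligned to its known reference
   (match +2, mismatch −1, gap open −5, gap extend −1). Reads are
   demultiplexed to a single known amplicon first, so global alignment is
   exact and no external aligner is needed; equal-length reads with ≤ 4
   mismatches take a provably-optimal gapless fast path. Substitutions and
   deletions are mutations; positions within ±3 nt of an indel are ambiguous
   (the deleted position itself keeps its mutation call); calls under Phred
   25 are uninformative; overlapping mates that disagree are ambiguous (one
   molecule, one vote). Reads with more than 10% of positions mutated are
   discarded as chimeric/misassigned.
4. **Titration fitting**, below.

## Titration model

For each construct the probe reactivity r_i (unweighted mean mutation
fraction over the probe adenines) at Mg2+ concentration x_i is reduced to a
relative protection

    f_i = 1 − r_i / max_j(r_j),

which is 0 at the most reactive (least protected) point and approaches 1 at
full protection. Masked points (config-driven per condition, e.g. a known-bad
5 mM sample) are excluded before the maximum is taken. f is fitted with the
modified Hill form

    f(x) = A (x/K)^n / (1 + (x/K)^n),

by weighted nonlinear least squares (`scipy.optimize.curve_fit`), weights
from the binomial SE of r_i propagated through the transform (an unweighted
mode exists). Bounds: A ∈ (0, 1.2], n ∈ (0.2, 10], K ∈ [1e-3, 1e3] mM.
Initialization: A0 = max f, n0 = 1, K0 = the concentration whose f is
nearest A0/2; two perturbed starts guard against local minima, and
non-convergence of all three is a QC failure. The x = 0 point is included
(the model is exactly 0 there). A fitted K above the highest tested
concentration is reported as `below_detection`, not as a measurement.

Free energies use ΔG = −RT ln(K / 1 mM) with R = 1.987×10⁻³ kcal/(mol·K) and
T = 293.15 K (20 °C) by default. The mM convention is a unit choice that
shifts every ΔG by a constant; it cancels exactly in ΔΔG = ΔG_i − ΔG_ref,
the quantity used to compare constructs. Note the sign: a destabilized
construct has a *higher* K and therefore a *negative* ΔΔG against the
reference; magnitudes are quoted when speaking of "destabilized by".

### Bootstrap uncertainty

Errors come from a 100-replicate bootstrap: titration points are resampled
with replacement and refit from the point estimate. One subtlety matters:
every f_i shares the same normalizer max_j(r_j), which is itself a measured
quantity. Holding it fixed makes all replicates inherit one realization of
its noise and demonstrably understates the midpoint uncertainty (CI coverage
drops to ~60-75% in simulation). When per-point binomial SEs are available
the normalizer is therefore perturbed per replicate by a Gaussian draw of
its own SE before the transform is recomputed; with no SE information the
procedure reduces to plain case resampling (and on noiseless input returns
SE = 0). Parameter SEs are standard deviations over converged replicates;
the midpoint additionally gets a 95% percentile CI. More than 50% failed
replicates voids the fit.

### Single-point estimator

Across a mutant family at a fixed Mg2+ concentration, ln(probe reactivity)
is linearly related to the contact ΔG. `single_point_estimator` fits
ΔG = a + b·ln r by OLS (statsmodels) on constructs with known ΔG and returns
slope, intercept, R² and a predictor with prediction intervals. Constructs
with non-positive reactivity are excluded (log undefined).

## Synthetic data

The simulator is the package's ground-truth source. Its generative model is
the two-state docking interpretation: at concentration x a fraction
p(x) = A(x/K)^n/(1+(x/K)^n) of molecules have formed the contact; probe
adenines mutate at `protected_rate` (default 0.002) in docked molecules and
`unprotected_rate` (default 0.05) otherwise; non-probe positions mutate at
structure-class rates (unpaired A 0.05, unpaired C 0.03, paired and G/U
0.002) independent of Mg2+. Mutations are drawn once per molecule (both
mates report them); per-base sequencing error (default 0.001) is drawn
independently per mate. Read 1 carries the 12-nt RTB barcode then the sense
strand; read 2 is the reverse complement. Defaults were chosen to match the
reactivity scale of published TL/TLR probing data (wild-type probe
reactivity ~0.002 at saturating Mg2+, unpaired C's in the 0.02-0.06 range).

The default titration grid is 16 points: 0 mM plus 15 roughly log-spaced
concentrations up to 40 mM (0.05 … 40, including 5, 7.5, 10). A
profile-level shortcut draws binomial mutation counts directly at the model
rates, which makes large replication studies affordable.

What the simulator does **not** model: co-mutation correlation along a
single cDNA, indels by default (an optional path exercises the ambiguity
rules), PCR jackpotting, quality-score miscalibration, chimeras. Passing
recovery tests therefore demonstrates correctness of the analysis given the
two-state model, not robustness to every real-library artifact.

## Validation studies and their limits

`qmapseq.validation` (reported by `scripts/acceptance.py`) contains:

- closed-form ΔΔG of the three helix-insertion mutants recomputed from
  published midpoints, and the C-C mismatch reactivity ratio;
- **midpoint recovery**: 100 simulated titrations per setting over
  K ∈ {0.1, 0.22, 1, 5, 20} mM × n ∈ {1, 2} × A ∈ {0.9, 1.0} at depth 5000
  per condition. Pooled median relative error of K̂ is ~7%. Per-setting
  medians are ≤ ~8% for K ≤ 1 mM and degrade as K approaches the top of the
  grid: at K = 20 mM on a 0-40 mM grid the curve never saturates, amplitude
  and midpoint trade off, and a weighted Cramér-Rao computation gives
  σ_K/K ≈ 0.45 (n = 1) even with the reactivity scale known — an
  identifiability limit of the design, not of the estimator. Bootstrap-CI
  coverage stays ≥ 0.86 in every setting;
- **detection limit**: true K = 100 mM is flagged `below_detection` in
  ~100% of runs;
- **oracle agreement**: the windowed demultiplexer and the bit-vector
  caller agree exactly with exhaustive reference implementations on 1000
  randomized pairs; profiles from 10⁴ simulated read pairs recover the
  generating rates within 4 binomial SEs at every position.

Published results that require the deposited sequencing data (the measured
wild-type midpoint 0.22 ± 0.004 mM, the mutant midpoints, the R² values
0.64/0.68/0.77/0.96, the 98-variant selection and the eight trajectory
clusters) are documented here as the experiments the pipeline reproduces
end-to-end, but are not asserted by the test suite.

## QC and clustering

`qc_flags` marks constructs whose probing contradicts the two-state model:
`closing_pair_reactive` (tetraloop closing pair above 0.02 mutation fraction
at the highest Mg2+ — the loop context itself is perturbed),
`alternative_structure` (probe reactivity at saturating Mg2+ above 50% of
its 0-Mg2+ value with fitted amplitude < 0.5), and `below_detection`
passthrough. Thresholds are config-exposed defaults, not published
constants. `cluster_trajectories` groups per-nucleotide reactivity
trajectories with Ward linkage on Euclidean distances of row-max-normalized
rows — normalization makes grouping respond to the *shape* of the Mg2+
response; linkage, metric and k are user choices since no published values
exist for them.

## Numerical notes

- Hamming matching is case-insensitive; N counts as a mismatch everywhere.
- Weighted fits floor σ_f at 1e-4 to avoid infinite weight on the f = 0
  anchor point.
- Alignment traceback prefers mismatches over gaps, then 5'-most gap
  placement; the gapless fast path is used only where it is provably
  optimal (≤ 4 mismatches under the scoring above).
- All randomness flows through `numpy.random.Generator` seeded from
  user-supplied integers; FASTQ simulation is byte-reproducible.
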