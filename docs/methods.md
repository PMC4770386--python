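# Methods

## Turnover model

A pulsed-SILAC label swap splits each proteoform's MS signal into three
channels: L (reference), M (pre-existing protein, decaying) and H (newly
synthesised protein, accumulating). Under channel conservation
(M + H = L) the normalised fractions

    m = (M/L) / (M/L + H/L),    h = 1 − m

are the degradation and synthesis curves. Assuming first-order
degradation at rate k_deg in a culture diluting at ln(2)/t_cc (cell
doubling time t_cc), the degradation curve is

    m(t) = exp(B t),    B = −k_deg − ln(2)/t_cc.

Two read-outs are derived:

* **50% turnover time** t_turn = ln(1/2)/B — where degradation and
  synthesis curves cross (m = h = 1/2). Defined for any descending
  profile; for a non-degraded protein (k_deg = 0) it equals t_cc
  exactly, so t_cc is the natural reference line on a turnover
  distribution.
* **Half-life** t_half = ln(2)/k_deg with k_deg = −B − ln(2)/t_cc —
  degradation only, corrected for dilution. Fitted B values shallower
  than pure dilution give k_deg < 0; these are reported as t_half = ∞
  (loss is dominated by cell division), serialised as the literal
  string `Inf` in output tables.

No amino-acid recycling term is included: the three-channel design
measures complete label replacement directly, and a single-exponential
describes such data well. Two-phase decay models are out of scope.

### Fitting cascade

1. Proteoforms quantified in fewer than `min_timepoints` (default 3)
   timepoints are excluded.
2. B is estimated by nonlinear least squares on m in ratio space
   (`scipy.optimize.least_squares`, Levenberg-Marquardt), initialised
   from the log-linear slope of the positive m values. Fitting in ratio
   space rather than log space keeps the error model additive on the
   measured ratios; log-space fitting would up-weight the small-m tail.
   R² = 1 − SS_res/SS_tot with SS_tot about the mean of the observed m
   (the standard convention). A constant profile (SS_tot = 0) is a
   degenerate fit.
3. The exponential estimate is accepted when R² ≥ 0.8 and B < 0.
4. Otherwise, if the profile shows a descending trend (Spearman
   correlation of m against t is negative — the criterion is not
   otherwise quantified, so a rank correlation is the least parametric
   choice) and two consecutive observed points bracket m = 0.5, t_turn
   is the crossing of the chords through the two m points and the two h
   points; since h = 1 − m this is where the interpolated m equals 1/2.
   When noise produces several bracketing pairs the earliest is used
   (deterministic tie-break).
5. Everything else is `invalid` — a value, not an exception, so cohort
   tables keep one row per proteoform.

k_deg and t_half are always derived from the exponential B when one was
fitted, even when t_turn itself comes from the linear fallback.

Normalisation is applied unconditionally to each (M/L, H/L) pair; rows
where the raw channels violate conservation badly (|(M+H)/L − 1| > 0.5)
are flagged (`qc_flags`) but not dropped — the study design does not
state a rejection rule, and flagging preserves the information.

m values above 1 after noise are kept, not clipped: normalisation
guarantees m ≤ 1 only for non-negative ratios, and clipping would bias
the fit near t = 0. t = 0 itself is never observed (the experimental
grid starts at 0.5 h); m(0) = 1 is implied by the functional form.

The chord of a convex exponential always crosses 1/2 at or after the
true t_turn, so the linear estimate has a small positive bias — up to
~9% for turnover times near 2 h on the 7-point grid, zero when the
crossing falls on a grid point. Cohort-level agreement between the two
estimators is nonetheless very high (Pearson r ≈ 0.996 at noise
sigma 0.1; the acceptance script recomputes this).

### Subsampling diagnostic

`subsample_turnover` refits every k-point subset of a time course
(default k = 3), discards subsets with R² < 0.8 or B ≥ 0, and returns
the surviving turnover times — a box-plot-ready check of how few
observations suffice for a stable estimate.

### Doubling time

`doubling_time` fits ln(density) against time by least squares and
returns ln(2)/slope. A growth rate of 0.0288/h gives 24.07 h ≈ 24 h.

## N-terminus annotation

Classification is purely rule-based (1-based start positions):

| start | condition | category | iMet |
|---|---|---|---|
| 1 | — | dbTIS | retained |
| 2 | residue 2 cleavable | dbTIS | processed |
| 2 | residue 2 not cleavable | non-compliant | — |
| >2 | peptide starts with Met | aTIS | retained |
| >2 | preceding residue Met, first residue cleavable | aTIS | processed |
| >2 | otherwise | non-compliant | — |

The cleavable set (small gyration radius, methionine-aminopeptidase
substrates) is {A, V, S, T, C, G, P}. Some sources list the set without
serine; `ImetConfig` exposes the set so the narrower rule can be chosen.
Position-2 peptides with a non-cleavable residue 2 are flagged
non-compliant rather than silently kept, because retaining position-1/2
N-termini presumes processing-rule compliance. Non-compliant peptides
are candidate proteolytic products and are excluded from turnover
comparisons. The amino-acid alphabet is the standard 20 letters;
U/O/B/Z/X are rejected with a clear error.

`pair_proteoforms` emits every dbTIS×aTIS combination per gene (flagged
when a gene has more than one aTIS — there is no canonical pairing
convention for such genes) and retained/processed pairs sharing a start
codon; `select_mature_nterminus` keeps the form the processing rule
predicts. `assign_origin` labels each aTIS from its evidence flags with
precedence splicing-likely (database isoform match with transcript
support level ≤ 3) > alternative-initiation (Ribo-Seq, Nt-acetylation or
TrEMBL support) > splicing-poor > proteolysis-candidate (protease-
product database match with no translation evidence); any
translation-pointing evidence marks the record highly confident, so
adding evidence can never demote a record.

## Abundance and sequence features

* Mean spectral count: arithmetic mean over the timepoints where the
  proteoform was identified (missing timepoints excluded, not
  zero-filled).
* NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j), where L is the **mature**
  proteoform length (database length − start + 1): proteoforms are
  start-specific, so the truncated length is the right normaliser. The
  normalisation runs once over the full dataset of mean counts (a
  per-timepoint variant is not provided; mean counts are the abundance
  estimate used downstream).
* GRAVY: mean Kyte-Doolittle hydropathy over the first 2 or 10 residues
  (scale constants from Biopython's `ProtParamData.kd`).
* Intrinsic-disorder percentages and ubiquitination evidence enter as
  precomputed input columns; no predictor is reimplemented.

## Ribo-Seq TIS calling

Tracks are per-nucleotide P-site counts on transcript-local, 0-based,
half-open coordinates; the annotated start is the first nucleotide of
the start codon. P-site offsets from the 5′ read end are +12 (reads
≤ 30 nt), +13 (31–33 nt) and +14 (34 nt); reads outside 26–34 nt are
rejected upstream.

A position is called a TIS when (i) its LTM count reaches the category
minimum, (ii) it is an LTM local maximum within a 7-nt window (one codon
either side; ties break toward the 5′-most position — an arbitrary but
deterministic choice), and (iii) R = scale·(ltm/ltm_total −
chx/chx_total) reaches the category minimum:

| category | min count | min R |
|---|---|---|
| annotated start | 5 | 0.01 |
| CDS downstream | 15 | 0.15 |
| 5′UTR / 3′UTR / non-coding | 10 | 0.05 |

The local-maximum rule is stated for annotated starts; it is applied to
all categories by default (`local_max_all_categories`) for consistent
peak logic, and is configurable. The normalisation constant `scale`
defaults to 10^7 (per-10-million mapped P-sites) and is configurable —
R values are only comparable across datasets for a fixed scale.
Alignment, contaminant filtering and multi-mapping resolution are out of
scope; the module ingests already-offset count tracks.

`match_peptides_to_tis` flags a proteoform as Ribo-Seq-supported when a
passing call sits at the codon of its initiating Met — for
iMet-processed records (including position-2 peptides) the Met
immediately preceding the observed start residue.

## Comparative statistics

All comparisons are nonparametric. Mann-Whitney U (independent) and
Wilcoxon signed-rank (paired) p-values are exact for tie-free samples up
to n = 25 and for tied samples up to n = 8 per group (full mid-rank
permutation enumeration); larger samples use the normal approximation
with mid-ranks and tie-corrected variance. Identical paired samples have
no signed ranks and yield a flagged degenerate result instead of an
error.

The residue-group analysis groups proteoforms by their first one or two
residues, splitting iMet-susceptible N-termini into Met-retaining and
Met-cleaved subgroups, and runs Kruskal-Wallis plus two post-hoc
procedures: (a) the critical-difference-of-mean-ranks multiple
comparison — groups i, j deviate when |R̄_i − R̄_j| >
z_{1−α/(k(k−1))}·√(N(N+1)/12·(1/n_i + 1/n_j)), the Siegel & Castellan
construction — and (b) uncorrected pairwise two-sided Wilcoxon rank-sum
tests.

The complex-dispersion test evaluates, for each member i of a complex
with at least three quantified members, the absolute turnover
differences {|t_i − t_j| : j ≠ i} against the pairwise differences among
the remaining members with a one-sided Mann-Whitney test (greater) at
α = 0.05. The reference set excludes pairs involving the tested member,
so the candidate's own differences cannot contaminate the reference.
**Known limitation:** this per-member test is not calibrated under a
global null — the most extreme member of any homogeneous complex
genuinely has stochastically larger differences, so the member-level
false-flag rate is ~10–15% for complexes of 4–10 members rather than
5%. The test is a ranking heuristic for planted-outlier detection (where
its sensitivity is excellent: a 20 h shift in an otherwise tight complex
of 8 is found essentially always), not an error-controlled test; treat
flags on real complexes as candidates for inspection.

1D enrichment compares each category's member values against
non-members with a two-sided Mann-Whitney test, applies
Benjamini-Hochberg FDR across categories and labels the preferred
direction; categories with fewer than two members or non-members are
skipped with a log entry. The extreme-decile analysis applies the same
machinery to the bottom/top 10% of proteoforms by turnover.

The ubiquitination comparison contrasts dbTIS proteoforms with detected
ubiquitination sites against lysine-bearing dbTIS without evidence
(one-sided, faster turnover expected), and labels per-pair turnover
differences with a 2 h relevance threshold.

## Synthetic data

The generators emulate the study conditions so every stage is testable
with known truth:

* **Proteome** (`generate_proteome`): random sequences of 50–1000
  residues at rough human residue frequencies; a configurable fraction
  of genes carries a downstream aTIS whose Met offset is lognormal with
  median 52 residues (sigma 0.35); second residues follow the same
  frequencies, so iMet-cleavable and retaining N-termini both occur and
  the observable N-terminus follows deterministically from the
  processing rule. True 50% turnover times are lognormal (median 16 h,
  sigma 0.8, clipped to 0.5–60 h), spanning sub-hour to beyond the 48 h
  grid end; B = ln(1/2)/t_turn and k_deg = −B − ln(2)/t_cc, so slow
  proteoforms naturally land in the negative-k_deg / infinite-half-life
  branch. Turnover is drawn (rather than k_deg) because a positive
  degradation rate caps t_turn at t_cc and could not represent the slow
  tail. Mean spectral-count abundance is lognormal (median 20), with
  aTIS down-weighted by 0.5 to reflect their lower abundance.
* **pSILAC tables** (`simulate_psilac`): per timepoint, channel
  intensities with E[M/L] = exp(B t) and E[H/L] = 1 − exp(B t), each
  channel multiplied by mean-one lognormal noise (default sigma 0.1 —
  MS intensity noise is approximately multiplicative; the value is a
  plausible stand-in, not an instrument inference). Timepoints drop out
  independently (default 0.1). A configured fraction of profiles
  (default 0.02) follows a monotone logistic decay instead — steep
  enough to fail the R² ≥ 0.8 gate while still crossing 0.5, exercising
  the linear fallback. Spectral counts are Poisson around the true
  abundance. The default grid is the experimental one:
  0.5, 1.5, 4, 8, 12, 24, 48 h, with t_cc = 24 h.
* **Ribo tracks** (`simulate_ribotracks`): CHX = Poisson background over
  the CDS; LTM = a tenth of that background plus a deterministic peak of
  `peak_height` (default 50) reads at each planted initiation codon.
  Library totals default to 10^9 P-sites per treatment, standing for a
  full library of which the simulated transcripts are a small part.
  Transcript geometry: 60 nt 5′UTR + CDS (+ stop) + 30 nt 3′UTR.
* **Complexes** (`generate_complexes`): complexes of 3–10 members with
  turnover tight around a complex baseline (sd 1 h), one member shifted
  by `outlier_shift` hours in a configured fraction of complexes.

All generators take an explicit integer seed, own a private
`numpy.random.Generator`, and are bit-reproducible. What the synthetic
data does **not** model: raw spectra, chromatography, peptide-spectrum
matching and search-engine FDR, arginine-to-proline conversion, read
alignment and multi-mapping, or correlated (batch) noise — so green
tests demonstrate correctness of the computational rules and estimators
under the stated noise model, not robustness to every artefact of real
MS or sequencing data.

## Problem sizes used in the shipped checks

The acceptance script simulates 500 proteoforms on the 7-point grid
(the paired-estimator correlation stabilises well below that size);
parameter-recovery checks use 1000 proteoforms; dispersion-test checks
use 150 planted-outlier complexes of 8 and 1000 null complexes. These
sizes were chosen once as comfortably sufficient for the statistics
being checked.

## Pipeline

`run_pipeline` wires the stages in study order (annotate → kinetics →
features → TIS support → statistics), writes TSV outputs plus a
machine-readable `manifest.json` containing the effective configuration,
its hash, and the filter funnel (identified → ≥ min timepoints → valid
turnover, split by method), and is byte-deterministic given identical
inputs and seed. Logging goes to stderr; results never do.
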