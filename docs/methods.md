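# Methods

This note documents the models implemented in `cleavedrive`, the defaults
chosen where the design was open, what the synthetic-data generators do and
do not emulate, and the numerical conventions that affect results.

## The cleavage-fraction model

Each library molecule is transcribed and self-cleaves with a
sequence-specific probability that may depend on ligand. Sequencing reads
carry a 5' prefix recording the outcome: `Z` for cleaved (regenerated)
molecules, `W` for uncleaved. Because the two outcomes are amplified in
separate PCR arms with potentially different efficiencies, raw Z:W read
ratios are biased; referencing each arm to the spike-in pool, sequenced
through the same arms at a known fixed concentration, cancels the bias:

    c_s = (r_Z,s / r_Z,ref) / (r_W,s / r_W,ref + r_Z,s / r_Z,ref)

`c_s` is invariant to rescaling all four counts and lies in [0, 1] by
construction. When both sample counts are zero the fraction is undefined
and reported as missing. The `A` prefix, present among the spike-ins, takes
part only in reference accounting (it marks a second regeneration arm used
between selection stages), not in the fraction itself.

Absolute concentrations follow from the spike-ins: with 15 references at
18 pM each, the conversion is (15 × 18 pM) / total reference reads per
prefix and condition, so 2700 reference reads give 0.1 pM per read.

## Fold change and run normalization

Ligand response is quantified on the uncleaved fraction, the quantity
proportional to intact transcript (and hence to gene expression when the
switch is placed in a 3' UTR):

    f_s = k (1 − c_s,+ligand) / (1 − c_s,−ligand)

Only a small minority of sequences respond to any one ligand, so the run
median of the raw ratio is a null anchor; `k` is its reciprocal, making the
median fold change exactly 1.0. Defaults and conventions:

- Sequences with ≥ 30 reads in both conditions set `k` (the normalization
  should not be dominated by shot noise; 30 reads matches the depth floor
  used for switching tests). All sequences, filtered or not, then receive
  an `f_s`.
- Even-count medians are the mean of the two central order statistics.
- `c_minus = 1` makes the ratio undefined; such sequences get a missing
  `f_s` rather than an imputed one.
- `f_s > 1` means ligand suppresses cleavage (the ON-switch polarity the
  selection targets). Screening the opposite polarity is a matter of
  ranking by `1/f_s`; hit calling uses `f_s` only.

## Uncertainty and tests

**Bootstrap.** Read counts are the only noise source modeled. Each of B
(default 1000) replicates redraws the sequence's (cleaved, uncleaved)
counts and the reference (Z, W) counts from multinomials with observed
proportions and observed totals, recomputes `c_s` (and `f_s` across two
conditions), and the 5th/95th percentiles form a 90% interval. Reference
draws are clipped away from 0 so every replicate is well defined; with
realistic reference depths (thousands of reads) the clip never binds.
Resampling the references is a choice: they contribute real sampling noise
to `c_s` at low depth.

**Two-sample tests.** Replicate concordance and ligand switching are both
two-sided tests of equal cleavage proportions on the 2×2 table of
(cleaved, uncleaved) × (group). The test is Fisher's exact conditional
test, exact at the low counts typical after library constriction; above
10⁴ reads in every cell a chi-squared approximation is numerically
indistinguishable and used for speed. Replicate outliers are called at the
Bonferroni level `0.1/N` with a 100-read floor per sequence; switching
uses `1/N` with a 30-read floor.

**Hits.** A sequence is a candidate sensor when `f_s > 2.0`, its switching
p-value is below `1/N`, and it is not misassignment-flagged. The
misassignment filter flags any sequence whose total count is ≤ 1/100 of
another sequence within Levenshtein distance 1 — the signature of
amplification mutations crediting reads to the wrong sequence. Flagged
sequences stay in the table for inspection but cannot be hits.

## Read processing

Merging slides the reverse-complemented reverse read against the forward
read; candidates are overlaps ≥ 10 nt with mismatch fraction ≤ 0.1, the
lowest mismatch fraction wins, and ties resolve toward the **maximal
overlap**. The alternative (preferring the longer merged product) fails on
periodic amplicon cores, where shifted overlaps are also exact, so the
maximal-overlap rule is used. At mismatches the higher-quality base is
kept, forward winning exact ties.

Barcode and prefix matching default to exact: amplicon ends are
primer-derived and high quality, and the variable-length barcodes are
prefix-free by scheme validation. One-mismatch tolerance is opt-in; a read
matching two conditions under tolerance is left unassigned and tallied.
Edit distances are Levenshtein over ACGT; `N` matches nothing. Accession
integers are assigned in lexicographic core order, so tables are invariant
to read order.

The shipped `default_scheme()` is a synthetic fixture with the structural
properties of a real run — three distinguishable A-rich prefixes, an
A-rich suffix spacer, per-condition variable-length barcodes, 15 spike-ins
spanning five lengths and three prefixes at 18 pM — not the actual oligos
of any instrument run; any user scheme loads from YAML.

## The selection model

A selection round multiplies each member's abundance by its survival
weight — `c_minus` on cleaved-selection rounds (no ligand), `1 − c_plus`
on uncleaved rounds (ligand present) — and renormalizes. Amplification
factors are shared by all survivors and drop out of the composition, so
they are deliberately out of model. Expectation mode propagates the
weights exactly; stochastic mode draws M molecules multinomially each
round. Schedules are strings over `{Z, U}` (e.g. `"ZU"` alternating,
`"ZZU"` for a 2:1 cleaved:uncleaved bias used to push basal cleavage up).

Against the dominant background of conformationally bistable,
ligand-insensitive members (cleaving ~50% in both conditions, surviving
every round with weight 0.5), the per-round enrichment of a phenotype is
the geometric mean over one alternating cycle of its survival relative to
0.5. A perfect (1, 0) switch gains exactly 2× per round; a (1.0, 0.36)
switch gains 1.6×, and 1.6⁶⁰ > 10¹² — the compounding that makes
many-round automated runs productive despite the weak per-round advantage.

Mutation is modeled abstractly: each round a configurable fraction of every
member's mass spawns a variant with Gaussian-perturbed cleavage
probabilities. This suffices for its one analytic role — explaining
back-extrapolated initial fractions below the library's sampling floor —
without pretending to sequence-level realism.

**Enrichment fitting.** Observed per-round fractions are fit as
log f_n = log f₀ + n log η by weighted least squares, with delta-method
weights var(log f) ≈ (1 − f)/(reads · f) from the binomial proportion.
Zero-fraction rounds are dropped, not imputed. Whether to weight was an
open choice; weighting is standard for proportions spanning decades and
the noiseless case is unaffected (recovered to machine precision).

**Constriction.** Diluting to concentration c fM and sampling v µl gives
Poisson(c·10⁻¹⁵·N_A·v·10⁻⁶) molecules (8 fM, 1 µl ≈ 4818 ≈ 5×10³),
allocated multinomially by abundance. Avogadro is fixed at 6.022×10²³.

**Combinatorics.** The randomized-loop designs replace one ribozyme loop
with 30 or 60 degenerate bases and the other with 4–8, in two loop
orientations: 20 designs of 34–68 degenerate positions. Σ4^d ≈ 2×10⁴¹
(floor log₁₀ = 41); a fixed 25-mer in a 68-position design has 4⁴³ ≈
7.7×10²⁵ contexts (nearest order 10²⁶).

## Dose-response and kinetics

**EC₅₀.** The response model is a four-parameter logistic in log
concentration; the functional form was open and 4PL is the assay-standard
choice, with the no-ligand condition anchoring the bottom asymptote. Fits
are weighted least squares (`scipy.optimize.curve_fit`) with the EC₅₀
bounded to within four decades of the measured range and the Hill slope to
[0.1, 10]. A fitted EC₅₀ within 3× of the top measured concentration means
the plateau was not observed and the estimate is flagged as a one-sided
lower bound; a flat response is flagged unbounded. Responses moving
against the fitted direction by more than 3 standard errors set a
non-monotonicity warning.

**Langmuir kinetics.** Association follows
RU(t) = R_eq + (RU₀ − R_eq)e^(−(k_on C + k_off)t) with
R_eq = R_max C/(C + K_D); dissociation decays at k_off. The normalization
chain is reference-cell subtraction, then blank-cycle subtraction, then
subtraction of the blank-subtracted negative control, with linear
interpolation onto a common time grid. Kinetic fits share
(k_on, k_off, R_max) globally across ≥ 3 concentrations spanning ≥ 10×;
single-cycle mode chains associations in concentration order with
carried-over RU₀. The equilibrium route averages the final 5 s of each
association phase and fits the Langmuir isotherm in log C — a fixed-slope
sigmoid whose inflection is K_D; the binding model itself dictates the
shape, so no free slope is fitted. Rates are non-measurable when either
phase reaches 95% of its transition (ln 20 / rate, association evaluated
at the highest tested concentration) in 2 s or less; the boundary counts
as non-measurable. Mass-transport and bivalent models are out of scope.

## Reporter formulas

Gel lanes: f = [(I_cl − I_bg)/L_cl] / [(I_cl − I_bg)/L_cl +
(I_un − I_bg)/L_un]; staining scales with product length, so per-length
normalization recovers molar ratios. Negative background-subtracted
intensities clamp to zero with a warning. Fold change is
(1 − f₊)/(1 − f₋).

Flow cytometry: events are gated to transformed cells (mCherry > 10^3.2
and GFP > 10^3.1, linear units, configurable); F = mean over gated cells
of GFP/mCherry (the arithmetic mean, as the formula is written);
RFU = 100 × F_sample/F_control, so the inactive-ribozyme control reads
exactly 100. Viability/singlet gating is upstream of these formulas and
out of scope — synthetic events represent already-gated cells.

## Mutational scanning

Variants within edit distance 2 of the parent are decomposed by a
Levenshtein DP with full traceback. Positions are 1-based on the core;
insertions index the gap after position p (0…L). Equal-cost alignments
(e.g. indels in homopolymers) are resolved to the leftmost edit and
flagged ambiguous; the traceback prefers matches from the right, which
provably pushes edits leftward. Soundness (applying the script reproduces
the variant) is property-tested on random variants. Effect matrices have
L substitution rows (+ deletion column) and L+1 insertion rows × 4 bases;
duplicate observations of one cell aggregate by read-weighted mean.
Family clustering is average-linkage agglomerative clustering on pairwise
Levenshtein distances, cut at 25% of the median core length by default;
inputs are sorted by accession first so results are permutation-invariant.

## Synthetic data: what it does and does not emulate

The generators draw from exactly the statistical model the analysis
assumes: multinomial read allocation by abundance, binomial cleavage per
molecule, a fixed fraction of reads from spike-ins spread uniformly
(default 0.12, the count-level image of 15 × 18 pM spike-ins against a
~2 nM library), uniform substitution sequencing error (indel errors
opt-in), flat base quality, log-normal two-color fluorescence, Gaussian
sensorgram noise. They do **not** model PCR amplification bias between
arms, quality-score structure, chimeras, secondary-structure-dependent
regeneration efficiency, or instrument-specific artifacts. Passing tests
therefore demonstrate correctness of the estimators under their stated
assumptions and exact recovery of planted truth — not robustness to every
failure mode of real instruments.

Problem sizes used in the validation suite are chosen to make the
statistical claims sharp while keeping the suite quick: the planted-truth
recovery study runs 1000 sequences at ~10⁴ member reads per sequence per
condition at the count level (the same forward model the FASTQ path
implements; the FASTQ path itself is verified for exact round-trip
recovery at smaller scale), the bootstrap coverage study uses 500
simulations of 200-read sequences with B = 1000, and fit-recovery studies
use 10–40 seeds per setting.

## Known limitations

- The count-level generator ties reference reads to a fixed fraction
  rather than simulating competitive amplification from concentrations.
- Fisher's exact test is conservative at very low counts; the replicate
  outlier rate is correspondingly below nominal.
- The 4PL EC₅₀ and the Langmuir isotherm assume monotone, saturating
  responses; biphasic sensors are flagged, not modeled.
- Abstract-phenotype mutation cannot describe epistasis or
  sequence-specific mutational neighborhoods.
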