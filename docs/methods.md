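# Methods

## The model

`stressomics` analyses a short stress time course measured at four layers
of gene expression: RNA exon counts (`RNA`), ribosome-footprint CDS counts
(`RPF`, a proxy for translation), non-ribosomal protein-footprint UTR
counts (`POP`, a proxy for regulator binding), and protein intensities
(`PROT`).  Cells are sampled at 0, 1, 4 and 8 h after treatment, in two
replicates, under two stress conditions (an ER-stressor and an oxidative
stressor); the untreated 0 h sample is shared between conditions within a
replicate, mirroring a design in which all samples are collected at the
same time.

Because the layers are causally chained (protein output depends on RNA
input), each regulatory *level* is defined by subtracting an input layer
from an output layer on the natural-log scale, so that changes already
explained upstream cancel:

| level          | output | input    | interpretation                          |
|----------------|--------|----------|-----------------------------------------|
| `TRXP_RNADEG`  | RNA    | constant | transcription / RNA degradation          |
| `TRL`          | RPF    | RNA      | translation                              |
| `TRL_RNADEG`   | POP    | RNA      | regulator binding / RNA fate             |
| `TRL_PROTDEG`  | PROT   | RNA      | translation / protein degradation        |

A *regulatory event* is a step change of the level signal m(t) at one time
boundary.  The subtraction is the load-bearing assumption: a pure
transcription change moves output and input identically and leaves every
downstream level untouched (the package verifies this exactly in the
noise-free limit).

## Change-point statistic

For each gene g, boundary i (between consecutive observed times), and one
(level, condition, replicate) run:

- d_g(i) = m_g(t_{i+1}) − m_g(t_i), the adjacent difference;
- the per-boundary median of d over genes is removed, absorbing global
  responses (e.g. bulk translation shutdown) so scores measure
  gene-specific deviation; this centering is switchable off;
- the robust scale is s(i) = 1.4826 × MAD_g(d), a cross-gene empirical
  null per boundary;
- z = (d − median)/s, two-sided normal p, and Benjamini–Hochberg q over
  all genes × boundaries of the run.

The statistic is deliberately simple and fully specified: it trades the
original Bayesian rate-model treatment of this design for an exactly
testable standardized difference with the same operational contract
(per-gene, per-boundary, per-replicate scores carrying an FDR).  Its key
assumption is *exchangeable noise across genes*: the pooled MAD is a valid
null scale only when per-gene measurement variance is comparable.  Strongly
abundance-dependent variance (very low counts) inflates tail z-values; see
Limitations.

An *event* for (gene, level, condition, direction) requires every replicate
to show at least one boundary with q < 0.2 and the matching sign —
replicates may qualify at different boundaries, because the evidence for
*whether* a gene responds is firmer than for *when*.  A strict
same-boundary mode is available.  The event time is the mean across
replicates of the later endpoint t_{i+1} of each replicate's best-q
qualifying boundary (a step between t_i and t_{i+1} is first observable at
t_{i+1}).  A gene may carry both an up and a down event when both rules are
met independently.

## Normalization

- Sequencing layers: genes are kept when their summed count across all
  samples is ≥ 10 (a per-sample-minimum mode exists); depth is removed by
  median-of-ratios size factors (ratio of each sample's counts to the
  gene's geometric mean, median over all-positive genes).
- Protein: proteins missing in any sample or identified by fewer than two
  peptides in either replicate are dropped; within each stress condition
  the intensities are divided by the protein's geometric mean across that
  condition's samples and the per-sample size factor is the median of
  these ratios.  The shared 0 h samples participate in both conditions'
  geometric means.
- Log series: ln(count + 0.5) (the pseudocount handles zeros; the source
  procedure leaves zero handling unstated), centered per gene by the
  median over all samples of the layer/condition.
- The clustering matrix uses log10 ratios versus time 0, standardized per
  gene within each (layer, condition) block with the population SD
  (configurable to n−1); zero-SD blocks are set to 0 with a warning.
- Gaussian-process smoothing (squared-exponential kernel, lengthscale 4 h,
  signal variance = series sample variance floored at 1e−6, noise variance
  = 0.25 × signal) is available but OFF by default for 4-point series: the
  upstream tool's "standard settings" are not recoverable, so smoothing is
  an opt-in with stated defaults.  Because noise is a fixed fraction of
  signal variance, the posterior mean reduces to one linear smoother for
  all genes; a constant series is returned unchanged.
- Batch correction (surrogate-variable removal) is intentionally omitted:
  the synthetic data has no batch structure.

## Synthetic data

The generator is the package's test bed: it produces data with exactly the
statistical structure the analysis assumes, plus ground truth.

Latent log abundance per gene is Normal(μ0, σ0²) with μ0 chosen so the
median gene has ~100 reads/sample at a 5×10⁶-read library (the simulated
genes are a core-set-like subset of the transcriptome, so columns do not
sum to the library size), and σ0 = 0.5 natural-log units.  Events are
single steps of ±δ (default δ = 1) at one boundary, planted in 10% of
genes per level (disjoint gene sets across levels by default, so recovery
attribution is unambiguous), each event assigned one condition uniformly
except a 20% fraction planted in both conditions.  The cascade plants the
step into exactly the layers each level touches: transcription events into
all four layers; translation events into RPF and PROT; binding events into
POP only; protein-turnover events into PROT only.

Sequencing layers draw negative-binomial counts with variance m + φm²,
φ = 0.005 by default; protein intensities are log-normal with CV 0.10.
Setting φ or the CV to 0 yields the exact noise-free limit (values equal
expectations), used by the exactness tests.  Calibration rationale: the
emulated replicates are same-passage cell-culture time courses sequenced
deeply, for which near-Poisson overdispersion (φ ≈ 0.005) and ~10%
proteomic CV are realistic scales; σ0 = 0.5 reflects that a core set
quantified completely across four technologies is strongly
abundance-selected.  These three values, together with δ = 1, put the
planted effects in the statistic's detectable regime (design-point
operating characteristics: sensitivity ≈ 0.87, empirical FDR ≈ 0.03,
null called-gene rate ≈ 0.2%).

The coverage generator emits per-base read 5′-end tracks: protein-footprint
tracks carry a Gaussian peak (sd 20 nt, ~100 reads) at each annotated
structure midpoint over a uniform background; matched RNA tracks are
uniform.  Structures designated differential have the peak amplitude
multiplied by a stated fold (default 4) in the final-time samples.  The
junction generator draws inclusion reads Binomial(depth, ψ(t)); all
inclusion junctions of an event report the same draw (they tag the same
molecules) and exclusion junctions report the complement, so the PSI
estimator is unbiased for ψ.

What the generator does **not** emulate: batch effects, library-prep
biases, positional coverage bias, multi-mapping, isoform mixtures beyond
binary inclusion/exclusion, ramp-like (non-step) regulation, and
abundance-dependent dispersion trends.  Passing tests therefore certify
the statistical machinery under the stated model, not robustness to those
real-data features.

## Recovery accounting

Sensitivity is strict: a planted event must be re-called with matching
gene, level, condition and direction.  The empirical FDR is
cascade-aware: a called event counts as a false positive only when no
planted event predicts a signal at that level — a translation event
genuinely moves the protein layer, so a matching `TRL_PROTDEG` call is
explained, not spurious.  Time error is reported in hours and in
boundary-index units on the observed grid.

## Comparative statistics

Stress-specific/shared splits and concordance/discordance Venn counts are
tested with the exact hypergeometric upper tail over the core-gene
universe (the universe size is recorded in every output).  Category
enrichment uses Fisher's exact test per category (two-sided reported
alongside both one-sided variants, since depletion is as interpretable as
enrichment), BH-adjusted across categories; genes without a category pool
as `other`.  Clustering is complete linkage on 1 − Pearson correlation
with constant rows assigned zero correlation (warned).  The elbow curve
reports within-cluster SSE around centroids of the z-scored rows — for
rows standardized to mean 0/SD 1 this is proportional to the summed
(1 − r) against the centroid and, because hierarchical cuts are nested,
it is non-increasing in k; the suggested k maximizes the second
difference and is flagged unstable for structureless data.

## Structure occupancy

Windows are inclusive of both endpoints on 0-based transcript coordinates,
reads are counted by their 5′-end base (fragment-overlap counting is a
flag), and clipping at transcript bounds is recorded.  The transcribed
filter keeps structures with mean ±200 nt coverage ≥ 10 across untreated
samples; occupancy asks for ≥ 1 read in any sample within ±100 nt of the
midpoint.  Differential binding between two time points uses the exact
conditional binomial: given the structure's total n = c₀ + c₈, under no
change c₈ ~ Binomial(n, L₈/(L₀+L₈)); two-sided minimum-likelihood p,
BH across structures.  This is the minimal exact two-library test; it was
chosen because the upstream adjusted-p procedure is unspecified.  Metagene
peak location is estimated from the mean TPM profile after an 11-nt
centered moving average — single-base profiles are shot-noise limited
near a broad peak and the symmetric filter does not bias a symmetric
peak's argmax.  Motif positions are scanned as IUPAC consensus matches
(overlapping) with offsets relative to the midpoint; de-novo motif
discovery is out of scope.

## Splice events

Junction observations below 2 reads are dropped per sample (a pooled mode
exists), as are junctions touching no annotated exon boundary; a novel
exon therefore enters classification only when retained junctions support
both of its boundaries.  Classification is purely topological: skipping
needs the two-junction inclusion path plus the direct exclusion junction;
mutually exclusive exons need both two-junction paths with neither the
internal bridge nor the direct junction present; alternative 5′/3′ sites
are junction pairs sharing one end whose other ends are alternative
boundaries of one exon, suppressed when a skipping/mutually-exclusive
topology explains the pair (strand decides the 5′/3′ label).  PSI is the
mean of inclusion-junction counts over (mean inclusion + mean exclusion),
undefined at zero denominator.  The linked-event test takes a user-supplied
2×2 of phased molecule counts (how reads are phased across two distant
events is platform-specific and left to the caller) and reports Fisher
exact one- and two-sided p-values.

## Numerical choices and degenerate inputs

- BH is scipy's step-up implementation behind input validation; all exact
  tests are scipy's, cross-checked in the test suite against brute-force
  enumeration (hypergeometric exhaustively for N ≤ 12, Fisher for small
  tables, binomial for n ≤ 30, BH on 1,000 random vectors).
- `changepoint_scores` refuses runs with fewer than 50 genes (the
  cross-gene scale would be unstable) and raises on a zero robust scale;
  an explicit `scale_floor` lets deliberately noise-free data through.
- Event calling requires ≥ 2 replicates (the rule is undefined otherwise);
  zero-margin 2×2 tables return p = 1 with a warning; empty event sets
  give all-1 enrichment p-values.
- Problem sizes used by the shipped tests and the acceptance script —
  2,000 genes × 20 null seeds and × 10 recovery seeds, 100 structures,
  50 exon models — were chosen so each suite completes in well under a
  minute per component while keeping Monte-Carlo error small relative to
  the asserted margins.

## Known limitations

- The pooled per-boundary scale mis-calibrates genes whose counts are very
  low (abundance-dependent variance); with wide abundance spreads the
  empirical FDR of the both-replicate rule degrades.  A per-gene variance
  model would remove this but is beyond the present statistic.
- Single step changes only; ramps and multiple change points per gene are
  out of scope.
- Binary PSI ignores multi-isoform mixtures; junction phasing across two
  events must be provided by the caller.
- The hypergeometric universe is the analysis' own core gene set; with a
  different universe convention the overlap p-values shift accordingly
  (both conventions are supported).
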