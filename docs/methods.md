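# Methods

## The event class

A UA3E/AIDE event pairs a terminal exon *T* of a short isoform with the first
downstream exon of a longer isoform that shares the identical splice-donor
position immediately upstream of *T*. The catalog enforces three structural
rules, applied per gene after collapsing transcripts with identical exon
chains:

1. *T* must lie wholly inside the intron of the long isoform that starts at
   the shared donor (strictly between the donor and the downstream acceptor).
2. *T*'s acceptor must not be used as an internal-exon acceptor by any
   transcript of the gene — such exons are cassette exons, a different
   regulatory class.
3. The two acceptors must differ; terminal exons sharing one acceptor are
   tandem alternative-polyadenylation variants, not an A3E choice.

Transcripts sharing the gene but using a different donor upstream of *T* do
not form an event: requiring the identical donor isolates the 3′-terminal
choice from alternative 5′ splice-site usage. Only the first downstream exon
of the long isoform is recorded; further downstream exons carry no
information about the choice because both discriminating junctions start at
the shared donor.

Coordinates are 0-based half-open internally; GTF input is 1-based inclusive
and BED-style output 0-based half-open.

## ψ and ν

ψ is estimated from the two donor-anchored junction counts only
(ψ = 100·i/(i+e)); exon-body reads are ignored, which keeps the analysis
alignment-free and unbiased by isoform length. ψ is undefined (NaN) when both
junctions are zero; such samples are dropped from trajectories with the
per-event point count recorded.

The co-expression index is ν = exp(H) with H the Shannon entropy in nats of
the isoform proportion vector — natural logarithms are forced by the
convention that ν equals the isoform count for a uniform mixture (2 at
ψ = 50 %). ν is the Hill number of order 1, so it inherits its properties:
bounded by 1 and the isoform count, permutation-symmetric, and monotone in
the evenness of the mixture.

## Trend testing

ν is computed per replicate sample and Kendall τ-b is taken over all
(stage rank, ν) points; a flag switches to per-stage means. Replicate-level
points are the default because they give the rank test its sample size
without distributional assumptions; stage means discard within-stage
information. Developmental time enters only through stage rank, so the test
is invariant to the actual day values except for tie structure.

p values are exact (full permutation null) for n ≤ 8 without ties and the
tie-corrected normal approximation otherwise; BH adjustment runs across
events. Trend classes use τ > 0.4 with BH-adjusted p < 0.005 (increasing;
decreasing symmetric) — both thresholds configurable.

A constant-ν trajectory has no defined ordering; it is reported as τ = 0,
p = 1 with `tau_defined=False` rather than an error, so that degenerate
events stay visible in the output.

## Bimodality

The dip statistic is the minimal sup-norm distance between the empirical CDF
and any unimodal CDF (convex left of its mode, concave right, at most one
atom at the mode). It is computed by the greatest-convex-minorant /
least-concave-majorant sweep over a shrinking modal interval, tracking
deviations in ECDF step units and halving at the end; values therefore lie
in [1/(2n), 1/4], with samples of identical values returned as 0. The
implementation is validated in the test suite against an exact
linear-programming oracle that minimises the band half-width over unimodal
CDFs with the mode placed at each data point in turn.

The p value is Monte Carlo: the fraction of `n_boot` uniform(0,1) samples of
the same size whose dip reaches the observed one, with add-one smoothing
(b+1)/(n_boot+1). The null table is cached per (n, n_boot, seed), and the
test is fully deterministic given the seed. The uniform null is the standard
calibration choice for the dip; it is slightly conservative against
light-tailed unimodal alternatives.

## Differential usage

Replicate counts are pooled within stage (or condition) and consecutive
stage pairs — or each knockdown against control — are compared with Fisher's
exact test on the 2×2 junction table, Bonferroni-scaled over pairs within an
event and BH-adjusted across events, gated on a pooled |Δψ| ≥ 10 percentage
points. Knockdown dependence additionally requires the ψ shift to have the
same sign in both contrasts.

Plain pooling is anticonservative because biological replicates of splicing
ratios are overdispersed relative to the binomial. The models therefore
estimate the intraclass correlation ρ by method of moments from the
replicate-level inclusion counts and scale the pooled table by the design
effect 1 + (n̄−1)ρ before testing (n̄ the mean per-replicate junction total).
With ρ = 0 this reduces exactly to the plain pooled Fisher test. Under the
generator's null (constant ψ, ρ = 0.02, depth 100, 8 stages × 3 replicates)
the corrected test calls 0/200 events across seeds 1–10, where the
uncorrected test calls ≈ 40 %. The correction costs power against smooth
trajectories, which is intentional: gradual monotone changes are the trend
test's job; the pair test targets abrupt splicing changes.

Fisher's two-sided p uses the probability-mass rule (the sum of table
probabilities not exceeding the observed one); the reported odds ratio is
the sample odds ratio ad/bc with ∞ for a zero denominator and a positive
numerator and NaN for 0/0.

## Motif enrichment

Windows of `width` nt are centred on the UA3E 3′ splice site and split into
an intronic half (R4) and an exonic half (R5); the split is symmetric by
default and configurable. Scoring is presence/absence of each k-mer per
window (robust to window length and composition; a count-based binomial mode
exists), tested one-sided for over-representation in regulated windows with
BH adjustment across the motif set and regions tested separately or
combined.

The built-in motif set is all hexamers over {C, U} containing UCUU or CUCU —
a deterministic, enumerable stand-in for a polypyrimidine-tract-binding
consensus. Experimentally derived motif lists can be supplied as plain text
(one k-mer per line).

## Single cells

Marker presence is modelled as a count threshold (default ≥ 1): cells without
housekeeping (Gapdh) signal are excluded; NeuN⁺/Gfap⁻ cells are neurons,
NeuN⁻/Gfap⁺ astrocytes, everything else (including double positives) is
"other" and not analysed further. Per-cell ψ comes from the two isoform
counts; group summaries use medians, which are robust to the skew of ratio
estimates at low counts, and groups are compared with Welch's
unequal-variance t test.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:

* an 8-stage differentiation course (DIV −8 … DIV 28) with 3 replicates per
  stage; junction totals Poisson with mean 100 and inclusion counts
  beta-binomial with ρ = 0.02 (biological splicing replicates are
  overdispersed);
* planted events follow a logistic ψ trajectory from 5 % to 45 % — the
  halfway-switch motif — with steepness 0.6 stage ranks, chosen so the
  trajectory remains smooth while its largest consecutive-stage step
  (≈ 16 ψ points) constitutes a genuine splicing change under the pipeline's
  own |Δψ| ≥ 10 gate; flat events draw a constant baseline from 15–85 %;
* gene models with genuine event topology plus cassette-exon and tandem-APA
  decoys on random strands, one contig per gene;
* knockdown contrasts with ψ shifts of +20 (single) and +35 (double
  knockdown) of common sign at junction depth 300 (typical bulk coverage);
* windows of uniform random RNA with one hexamer planted at 60 % / 10 %
  class rates;
* cell populations of 72 neurons (ψ centred at 42.8 %), 18 astrocytes
  (4.5 %) and 33 other cells (uniform 10–70 %), ψ Gaussian on the logit
  scale (σ = 0.35), isoform counts binomial at Poisson depth 200.

Every generator is byte-reproducible given the config seed, and every
emitted record appears in a ground-truth table.

Deliberately not modelled: read-level artefacts (mapping bias, positional
coverage, mismapping between paralogous junctions), correlated trajectories
across events of one gene regulon, expression-level changes confounding
junction depth, and gel-image quantification noise in the single-cell assay.
Passing the recovery suites therefore demonstrates the statistics are
implemented and calibrated as specified, not that real RNA-seq of comparable
depth would yield the same sensitivity.

## Numerical choices and edge cases

* Proportion vectors must sum to 1 within 1e−9; 0·ln 0 := 0.
* Kendall switches from the exact to the asymptotic p value at n = 8 or at
  the first tie.
* Dip: ties are handled by the sweep directly (ECDF with taller steps);
  n < 2 or all-equal samples return 0.
* KDE uses Silverman's rule with a robust (IQR-aware) scale; zero-variance
  input falls back to a small fixed bandwidth and is flagged degenerate.
* Detectability: an event is detectable when ≥ 1 stage has every replicate's
  junction total ≥ 20 (replicate-mean rule available); both numbers are
  configurable and echoed in outputs.
* Windows running off a contig are truncated with a warning and the
  truncated lengths recorded.
* All pipeline randomness (the dip bootstrap, the simulators) flows from
  explicit seeds; nothing reads global RNG state.

## Problem sizes

The shipped defaults — 200 events, 8 × 3 samples, depth 100, 2000-sample dip
null, 100 + 100 windows, 123 cells — were chosen so a full pipeline run and
the complete test suite finish in about a minute on a laptop core while
leaving every recovery margin wide (trend sensitivity 1.0 at a 0.9
requirement, planted-motif rank 1 in 20/20 seeds at a 19/20 requirement).
Scaling `SimulationConfig` up is linear in events × samples.

## Known limitations

* The dispersion correction uses a single global ρ; strongly event-specific
  overdispersion would call for per-event shrinkage estimates.
* The consecutive-pair design has limited power against smooth monotone
  trajectories by construction (see above).
* The dip's uniform null is conservative for peaked unimodal distributions;
  p values near the decision boundary should be read with that in mind.
* ν for more than two isoforms is implemented but the junction model
  quantifies exactly two; multi-isoform ν requires externally supplied
  proportions.
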