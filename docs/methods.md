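# Methods

## Scope and units of analysis

The unit of quantification is the *terminal exon with tandem poly(A) sites*
(TETPS): a transcript's last exon to which at least two catalog sites are
assigned.  Coordinates are 0-based half-open (BED conventions) everywhere
internally; a cleavage site is a single base, and the cleavage position of
a multi-base catalog record is taken as its 3′-most base in transcript
orientation, since wider records represent cleavage clusters whose
representative position is the cleavage end.  Sites are assigned to the
exon interval extended by 200 nt at the 3′ end (distal sites frequently
map just past the annotated exon end); a site falling into the windows of
two same-strand exons goes to the exon with the nearest annotated 3′ end,
and the ambiguity is logged.  Exons overlapping any *other* annotated
transcript on the same strand are excluded; whether "other" should mean
"other gene" is genuinely open, so an optional transcript-to-gene map
relaxes the rule to cross-gene overlaps only (default: any other
transcript).  With unstranded libraries, exons overlapping an antisense
transcript are excluded too, because their coverage cannot be attributed
to one strand.

## Sample integrity

Degraded RNA biases coverage toward the 3′ end and corrupts
coverage-based usage estimates.  Per transcript we compute a transcript
integrity number (TIN) as 100·exp(H)/L, the exponential of the Shannon
entropy of the per-base coverage distribution normalized by transcript
length: uniform coverage scores 100, coverage concentrated on one base
tends to 0 with growing length.  A sample passes when the median TIN over
transcripts is at least 70 (configurable).  This is a re-implementation of
the uniformity statistic rather than a wrapper around an external QC tool;
the tests exercise the analytic limits and the gate, not parity with any
particular implementation's interpolation details.

## Coverage profiles

Profiles are per-sample, nucleotide-resolution, and oriented 5′→3′ in
transcript direction.  From alignments, overlapping mates of a pair
contribute one count per base (the union of their aligned blocks); with
unstranded protocols all reads at the locus are counted.  Each locus is
extended 200 nt past the 3′ end.  When the proximal site lies within
250 nt of the exon start there is too little upstream signal to evaluate
its step, so coverage from the upstream exon with the most spliced-read
support into the terminal exon is prepended, repeatedly while the
upstream span remains short of 250 nt and junction evidence exists.
Profiles can equally be supplied as a TSV of per-exon arrays, which is how
the synthetic generator feeds the pipeline.

## Distal site, gates

The most distal used site is identified on the *pooled* (summed over
samples) profile, walking 3′→5′: mean coverage in the 200 nt downstream of
the site must be (1) strictly lower than the mean over twice the read
length upstream (the longer upstream window stabilizes the estimate as
coverage decays toward the poly(A) site), and (2) at most 10% of the mean
within one read length of the exon start.  Strictness in (1) is not
specified anywhere authoritative; we use strictly-less, which only matters
on exactly-flat profiles.  An exon is then quantified only if at least one
catalog site lies 5′ of the distal site and the pooled mean coverage from
exon start to distal site exceeds 5.  The >5 gate is applied to the pooled
profile, consistent with the pooled distal-site step; per-sample means are
logged.

## Segmentation

For a region [lo, hi) and breakpoint b, MSE(l, r) is the mean squared
deviation from the segment mean (computed from prefix sums, O(1) per
candidate).  A candidate site (breakpoint = cleavage index + 1, so the
cleavage base belongs to the upstream segment) is *candidate used* in one
sample iff both segments are ≥ min_segment (100 nt), the downstream mean
is lower than the upstream mean, and (MSE_u + MSE_d)/MSE_t ≤ 0.5.  A
zero-variance region yields ratio 1 (no split can help) and is flagged.
The default threshold of 0.5 is the calibrated operating point of the
method; `apakit sweep` reproduces the calibration trade-off (number of
quantified exons versus replicate concordance) over thresholds 0.2–1.0 on
synthetic data.

Recursion over the region 5′ of the distal site: every catalog site inside
the current region is evaluated in every sample; a site needs support in
at least two replicates when two or more exist (a replicate whose region
has no coverage abstains rather than vetoes); sites within 200 nt of each
other chain into clusters from which only the best representative
competes; the accepted site is the one with the smallest **median MSE
ratio over its supporting samples**, ties broken 5′-most (deterministic,
and proximal steps constrain downstream segments most).  With a single
sample the same procedure runs with support 1 and the smallest *ratio*
(not absolute MSE) decides — the ratio is scale-free, which keeps the
single-sample rule consistent with the replicate rule.  The recursion
stops when no candidate qualifies.  A brute-force oracle in the test suite
re-implements these rules with direct slicing and confirms equality of the
chosen breakpoints on a thousand random noisy step arrays.

**Validity check.**  The same recursion run over *all* positions (not just
catalog sites) of each sample's profile must recover only breakpoints
within 200 nt upstream of (or at) a used site; otherwise the coverage
steps are driven by sites missing from the catalog, and that exon × sample
is excluded.

## Usage and normalization

Segment boundaries are the used-site breakpoints.  Raw usage of a
non-distal site is its segment mean minus the mean of the segment
immediately 3′; the distal site's raw usage is its own segment mean (its
downstream region is the 3′ extension, expected near zero).  A site
without support in a particular sample still gets quantified the same way,
but a negative difference is set to zero — the "zero rule": absence of a
step means no detectable usage, not negative usage.  Relative usage
normalizes raw values to sum to one per exon × sample; a zero total makes
relative usage undefined (emitted as missing).  RPM divides each raw value
by the per-sample sum over all quantified sites times 10⁶.

## Activity inference

Relative usage from 3′-end counts is R(p,s)/Σ_exon R; exons with all-zero
counts in a sample are excluded for that sample, and zero-count sites of
otherwise expressed exons receive a 0.5-read pseudocount so the log is
defined.  In RNA-seq (segmentation-derived) mode no pseudocount is used:
zero-usage sites are excluded from the fit for that sample, because the
quantifier has already decided the isoform is unused there.  Mode-specific
filters: 3′-seq requires ≥ 1 RPM in at least one sample for a site to
count as expressed; both modes exclude exons whose retained sites are
closer than 400 nt to one another, since ±200 nt windows around their
sites would overlap and positional attribution would be ambiguous.

K-mer counts are *excess* counts over a mononucleotide background:
observed sliding-window count minus (L−k+1)·Π f(base), with the base
frequencies estimated per window placement pooled across all sites of the
analysis set (a shared expectation; per-sequence mode is available and
differs mainly for extreme-composition windows).  Negative excess is
clamped to zero by default so counts stay count-like; a signed mode exists
behind a flag.

The fit: with L = log₂ U, subtract the per-site mean across samples (the
site's intrinsic affinity) and the per-exon mean within each sample (which
absorbs the within-exon normalizer — exactly so for a single k-mer, since
the log-sum term is constant within an exon × sample).  The response is
regressed on within-exon-centered counts, per sample, by least squares
through the origin; standard errors use RSS/(n − #exons − 1) per sample.
Counts with no within-exon contrast give an undefined activity (missing,
never zero).  Because of the across-sample centering, individual
activities are identified only up to the mean across samples;
between-condition *differences* are identified absolutely, and on data
generated exactly from the exponential model they are recovered to
machine precision (the test suite verifies this for |A| ≤ 0.5).

Z-scores: mean of (first − second) activity differences over condition
pairs, divided by the standard error propagated from the per-sample OLS
errors (works for two-replicate designs; an empirical across-pair SE is
available for ≥ 3 pairs).  Put the control condition first to match the
usual knock-down sign convention (a motif whose activity the regulator
enables shows positive z).  The SE is floored at 1e−12 so noiseless
degenerate fits yield large finite z rather than infinities.  Empirical
p-values shuffle the site→count association (one shared permutation per
shuffle across all k-mers, preserving between-k-mer correlation), with
p = (1 + #{|z_null| ≥ |z|})/(n_shuffles + 1), 100 shuffles by default;
under the null these p-values are uniform to binomial accuracy.

Everything is standardized to base-2 logarithms; activities are per motif
copy on the log₂ scale (a one-copy difference with A = 0.5 shifts the
usage ratio by 2^0.5).  Natural-log activities would differ by the factor
ln 2 only.

## Synthetic data

`simulate_coverage` inverts the quantification rule: a planted exon with
usages f has segment means C·(1 − cumulative f), dropping to zero after
the distal site, plus per-nucleotide Poisson noise (or truncated Gaussian
for stress tests).  Defaults: base coverage 20, two replicates,
inter-site segments of 300–600 nt, and proximal usage drawn from
0.70–0.90.  The usage range is chosen so the planted step height is about
five times the Poisson noise scale at the default coverage — the regime in
which a step is detectable at the 0.5 ratio threshold at all; weaker steps
at this depth are genuinely indistinguishable from noise by the MSE
criterion, and the threshold-sweep fixtures plant them deliberately.
What the generator does *not* emulate: positional autocorrelation of real
read coverage (reads span ~100 nt, so real noise is smoother), 3′ bias in
degraded samples, mappability gaps, and overlapping gene structures.
Passing recovery tests therefore demonstrates correctness of the
segmentation logic under the stated noise model, not performance on
adversarial real libraries.

`simulate_counts` draws site sequences from a uniform mononucleotide
background over ±200 nt, plants 0–2 copies (probabilities 0.45/0.40/0.15)
of a motif inside a chosen window — with rejection sampling so the window
contains *exactly* the requested copy number — and samples reads
multinomially per exon × sample at a given depth from usages proportional
to 2^(copies·A_condition).  Defaults: 200 exons × 2 sites, depth 100, two
conditions (control with the planted activity, knock-down with zero), two
replicates each.

## Problem sizes used in the validation suite

The bundled tests run the pipeline at 200 exons × 2 replicates for
coverage recovery, 10 seeded runs per activity sign at 200 exons / depth
100 for motif recovery, 50 seeds × 100 shuffles at 50 exons for
permutation calibration, and 1000 random arrays (length ≤ 2000) for the
segmentation oracle — sizes at which every statement above is checked
exactly or to the stated tolerance while the whole suite stays fast.

## Known limitations

* The segmentation assumes piecewise-constant coverage; strong intra-exon
  coverage waviness (GC bias, paralog multi-mapping) inflates segment MSEs
  and suppresses calls.
* Activities are fit one k-mer at a time; correlated motifs (e.g. a k-mer
  and its super-strings) produce correlated activities, and no joint or
  multivariate fit is attempted.
* The within-exon centering absorbs the log-sum normalizer exactly only
  per k-mer; simultaneous strong activities of several motifs would bias
  single-motif fits.
* De novo site discovery is out of scope: the all-positions segmentation
  exists only as a validity check, never as an output.
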