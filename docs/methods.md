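# Methods

This note documents the models, defaults and numerical choices behind
`hiclite`, and what the synthetic-data tests do and do not establish.

## Synthetic contact maps

The generator states an explicit probability model and samples from it, so
every downstream caller can be scored against exact ground truth.

The expected cis contact weight between bins *i*, *j* of one chromosome is a
product of independent factors:

```
w(i,j) = max(|i−j|, 1)^(−α)                      power-law distance decay
       × t            if i and j share a TAD      (t ≥ 1)
       × (1 ± c)      same / opposite compartment (0 ≤ c < 1)
       × 1 + (L−1)·exp(−(Δi²+Δj²)/h²)             near a loop anchor (L > 1,
                                                   half-width h in bins)
       × f            inside a group-effect locus (both bins in the interval)
```

Cis weights are normalized to `1 − trans_fraction` of total probability;
trans cells share the remaining mass uniformly (optionally with per-block
hotspots emulating a rearrangement's strengthened trans contacts). `N` valid
pairs are drawn multinomially from the normalized map; positions are uniform
within bins, strands uniform. Replicates are independent binomial thinnings
of a parent pair set; a two-group cohort gives group 2 the group-effect
factor in its expected map.

Defaults: `α = 1` (the canonical fractal-globule-like decay slope observed in
mammalian Hi-C over the sub-10 Mb range), `trans_fraction = 0.15` (cis
dominates in intact genomes), `t = 2`, `c = 0.4`, `L = 5`, loop half-width 1
bin. These are the stated worlds used by the test suite; they were chosen
once as realistic magnitudes and are not tuned to test outcomes.

What the generator does **not** emulate: restriction-fragment granularity,
ligation artifact classes, copy-number variation, mappability/GC bias along
the genome (bins are equally visible in expectation), sub-compartment
structure, or nested/hierarchical TADs. A green planted-truth test therefore
establishes algorithmic correctness at realistic signal-to-noise, not
robustness to every bias of real libraries.

## Binning and ICE balancing

Bins are 0-based half-open `[kB, (k+1)B)`; the whole genome lives in one
dense symmetric matrix with global bin offsets. Dense storage is a deliberate
choice over sparse upper-triangular: every targeted problem size is at most a
few thousand bins, and the window/convolution operations (insulation, loop
neighborhoods, smoothing) are simplest and fastest on dense arrays.

ICE masks the bottom 2% of bins by total coverage (plus all-zero bins), then
repeats `divide row/col i by s_i/mean(s)` until
`max_i |s_i/mean(s) − 1| < ε` (default 0.1) or 100 sweeps — the standard
ICED parameterisation. The accumulated divisor is the bias vector; masked
bins carry NaN bias and zero rows. The convergence metric is the maximum
relative deviation of row sums from their mean, which on test matrices
decreases monotonically.

## Map resolution

Per candidate bin size (1 Mb … 1 kb grid), per-bin coverage counts **pair
ends** (each valid pair contributes two). The bins are sorted by coverage in
descending order and the depth at the position `ceil(0.80·n_bins)` is the
decision statistic: the size is achieved when it reaches 1000. The 75th/90th
percentile depths and the fraction of bins above threshold are reported
alongside, so other readings of the percentile convention stay inspectable.
Counting one end per pair is available via `ends_per_pair=1`.

## Distance decay and O/E

Observed decay is the mean unmasked cis interaction per distance stratum
(default width 1 Mb; strata labelled 1 M, 2 M, …). Each stratum also records
its exact mean cell separation; the expected curve is a LOWESS fit
(`frac=0.3`, 2 robustifying iterations) of log observed against log mean
distance, exponentiated — strictly positive, and exact on pure power-law
input because the fitted relation is then exactly linear. The zero-distance
stratum keeps its observed mean as its expected value. RCP is the observed
per-chromosome curve normalized to unit sum. O/E divides each cis cell by
the expected value at its distance stratum; for fine-grained O/E the stratum
width is set to the bin size.

## Compartments

Per chromosome, the Pearson correlation matrix of the O/E columns (unmasked,
non-constant bins) is eigendecomposed; E1 is the eigenvector of the largest
eigenvalue, and that eigenvalue's share of total absolute eigenvalue mass is
reported as a confidence measure (structureless maps score low). Because the
eigenvector sign is arbitrary and the source convention is not fixed, E1 is
oriented per chromosome against a user-supplied covariate — gene density by
default, since the A compartment is gene-rich and GC content may not exist
for synthetic genomes. Switch detection requires within-group unanimity of
E1 signs (matching a 2-vs-2 design read strictly) and merges runs of at
least 3 switching bins; genes overlap regions by ≥ 1 bp. Both knobs are
configurable; the overlap rule is ours, chosen for being the least
parameterised.

## Insulation and TADs

`s_i` is the mean of the `w×w` submatrix of contacts crossing bin *i*
(window default 25 bins — roughly 0.5–1 Mb at 20–40 kb resolution; the tool
this mirrors does not print its window, so the value is exposed).
`I_i = log2(s_i/⟨s⟩)` is undefined where the window leaves the chromosome or
more than half its cells are masked; a window summing to zero yields −∞,
which is a maximally insulating locus, not an error. Boundaries are local
minima whose flanking-maxima contrast (Crane-style strength) reaches 0.1;
TADs are the intervals between consecutive boundaries of at least 3 bins.
Ties on plateau minima resolve to the first bin of the plateau.

## Loops and APA

Loop calling is a single-resolution simplification of the HiCCUPS idea: for
each candidate pixel in the 2-bin–2-Mb diagonal band of the balanced matrix,
four neighborhood expected values (donut R=5/r=2, lower-left, horizontal,
vertical) are formed as `(Σ neighborhood observed / Σ neighborhood
expected) × pixel expected`, mapped to count scale via the ICE biases, and
tested against a Poisson upper tail. BH correction replaces HiCCUPS'
lambda-chunked FDR, and there is no multi-resolution merging — the contract
here is planted-truth recovery with controlled null behavior, both of which
are tested. Loops must pass q ≤ 0.1 for donut and lower-left and fold ≥ 1.5
over all four neighborhoods; 8-connected significant pixels merge to the
strongest pixel.

APA averages `(2W+1)²` O/E submatrices over anchors (W=5), skipping anchors
within `2W` of the diagonal or the chromosome edge; the score is the center
over the mean of the lower-left `3×3` corner. Minus-reference differencing
subtracts aggregates cellwise and reports the score difference. Anchors may
be any pixel list — a reference sample's loop calls or its TAD-boundary
pairs; both usages are supported because the source convention is ambiguous.

## SCC

Both maps are smoothed by a Chebyshev-radius-2 mean filter (edges clipped to
existing cells); Pearson correlations per one-bin distance stratum up to
5 Mb are combined with the stratum-adjusted weights `N_d·sd(x)·sd(y)`.
Zero-variance strata are skipped. `SCC(X, X) = 1` holds exactly and the
statistic is invariant to positive scaling of either map.

## Differential interactions

Samples enter as **raw** binned counts: the joint cyclic-loess normalization
(3 cycles of per-sample LOWESS of `M = log2(IF+0.5) − mean log2(IF+0.5)`
against log distance, trend subtracted, totals rescaled to the cohort mean)
replaces ICE here, because balancing would smear a focal group effect across
whole matrix rows and distort both the effect estimate and the background.

The per-pixel test conditions on the pixel total: under the null all samples
share one mean, so the group-1 sum of a total *t* follows the conditional
law of a sum of `n1` negative-binomial draws given the total of `n1+n2`; the
p-value sums all split probabilities as or less likely than the observed
one, reducing to an exact binomial split when the dispersion is ~0.
Dispersion is estimated per 1 Mb distance stratum by method of moments on
pooled within-group variances (median across pixels, clipped at 0) — a
deliberate simplification of the cited exact-test machinery whose contract
(null calibration, planted power, conservative never liberal p-values) is
tested directly. Pixels at zero in every sample are excluded from testing;
totals above 1e5 use a normal approximation. M (log2 group-2/group-1 mean)
and D (distance) are retained per pixel for MD-composite export.

## Pipeline

`run_pipeline` sequences the stages deterministically from one YAML config
(sample sheet, genome, bin sizes — default 20 k/40 k/150 k/500 k/1 M with
the finest as analysis resolution — module parameter blocks, reference
sample). Comparison stages require ≥ 2 samples; switch/differential stages
require exactly two groups; anything else is skipped with a log notice.
Outputs use standard text formats (bedGraph, BED, BEDPE, TSV, zero-based
triplet matrices with a bins table, JSON report) and a sha256 manifest, so a
re-run with identical inputs is byte-identical.

## Known limitations

- Dense matrices cap practical genomes at ~10⁴ bins; chromosome-scale human
  analyses at 5 kb would need the sparse backend this package intentionally
  omits.
- The loop caller is single-resolution and BH-based; it is not a drop-in
  HiCCUPS replacement on deep real data.
- The exact test's stratum-level dispersion is coarse for cohorts larger
  than a few samples per group, where per-pixel empirical-Bayes shrinkage
  would be preferable.
- Compartment orientation needs a covariate; without one, labels are
  consistent within a run but their A/B polarity is arbitrary.
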