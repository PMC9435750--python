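# Methods

`admixdate` identifies, dates and describes admixture events in a target
population from *chromosome paintings*: per-haploid decompositions of the
genome into contiguous segments, each labelled with the donor group sharing
its most recent common ancestor, typically produced by an HMM painter with
`s` stochastic samples per haploid. The package does not run the painting
itself; its inputs are painting samples plus genome-wide *copying vectors*
(the average fraction of DNA each population matches to each donor group).

## Model

Consider a population formed `lam` generations ago by two sources A and B
contributing `alpha` and `1 - alpha` of its ancestry, randomly mating since.
For two loci at genetic distance `g` (Morgans) on one haploid, the chance
they descend from the same source decays exponentially in `g * lam`:

    P_AB(g) / (alpha (1 - alpha)) = 1 - exp(-g lam)
    P_AA(g) / alpha^2            = 1 + ((1 - alpha)/alpha) exp(-g lam)

Because the true sources are unobserved, the same quantities are formed for
pairs of *surrogate* populations (U, V): the probability that two segments at
distance `g` relate most recently to U and V, divided by the marginal
product `f_U f_V`. These *admixture probability curves* (coancestry curves)
decay for same-source surrogate pairs, rise for cross-source pairs, and all
share the rate `lam`. The fitted model per curve is

    P_hat_{UV}(g) ~ tau_{uv} + delta_{uv} exp(-g lam),

with the intercept `tau` estimated freely (it sits near 1 in practice), and
a two-date variant with two shared rates and two amplitudes per curve.

## Pipeline

1. **Donor-to-surrogate probabilities.** From the copying vectors of the
   surrogates, `p(U|d) = f_{U,d} / sum_U' f_{U',d}`: the probability that a
   segment painted by donor group `d` is most recently related to surrogate
   U. A donor matched by no surrogate is an error; after surrogate pruning
   the columns are renormalised over the retained set (a column that prunes
   to zero contributes nothing).

2. **Stochastic pair subsampling.** Rather than enumerating all segment
   pairs within `K = 30` cM, the genome is cut into bins of `X = 0.1` cM
   (segments assigned by midpoint) and each bin pair at distance
   `D = (j - i) X` contributes `Y_ij = N_i N_j exp(-gamma D)/c` pairs drawn
   without replacement (`gamma = 0.05`, `c = 8`), with randomised rounding
   of the fractional part so the expected sampling fraction is exact. Close,
   informative pairs are kept preferentially; overall ~6.3-6.5% of eligible
   pairs are drawn at the defaults. Same-bin segments are never compared,
   and pairs at `D <= 1` cM are excluded from fitting. Setting
   `gamma = 0, c = 1` reproduces the exhaustive pairing exactly and serves
   as the test oracle. The inner loop is a compiled kernel that visits
   candidates by geometric skips under a row-wise probability bound (valid
   because the weight is non-increasing in distance), making cost
   proportional to pairs drawn rather than pairs considered.

3. **Curves.** Each drawn pair adds the symmetrised probability product
   `(p(U|d_a) p(V|d_b) + p(U|d_b) p(V|d_a)) / 2` to its distance bin; bin
   means divided by `f_U f_V` give the scaled curves, where `f` is the
   segment-average surrogate probability from the same painting samples, so
   numerator and denominator share sampling noise. Internally pairs are
   reduced to an integer tensor of donor-pair counts per (chromosome,
   distance bin); curves for any surrogate set, chromosome reweighting or
   renormalised probability map are cheap tensor contractions, which is what
   makes bootstrap and jackknife refits inexpensive. Because counts are
   integers, accumulating per chromosome or per individual is bit-identical.

4. **Null-individual correction.** Segments of up to 100 individuals are
   pooled per (haploid, painting sample) and only cross-individual pairs are
   drawn; these cannot share an inherited ancestry tract, so their curve
   captures LD not attributable to admixture (bottlenecks). Main curves are
   divided bin-wise by the null curve. The pooled budget is divided by the
   number of pooled individuals so the null costs about as much as the main
   curves (the pooled lattice would otherwise grow with the square of the
   sample size). The correction is approximate by nature: a multiplicative
   artefact interacting with tract sharing leaves a residual component in
   the ratio, so the tests assert that the correction moves the date toward
   the truth, not that it restores it exactly.

5. **Automatic LD left-trim.** Strong within-population LD distorts the
   short-distance end. On the same-surrogate curve of the top-contributing
   surrogate, windows of W = 3, 5, ..., 13 bins slide right from the 1 cM
   grid point until the OLS slope first turns negative; each window records
   `x_l + ceil(W/2)` and the maximum over W (capped at half the fitted
   range) is removed from the left of every curve before fitting. For a
   curve that is already decreasing this still removes `ceil(13/2) = 7`
   bins — a deliberate cost of the safeguard.

6. **Date fitting.** For a candidate rate the per-curve `(tau, delta)` are
   profiled out in closed form; the 1-D search uses a 200-point log grid on
   [1, 400] generations refined by bounded minimisation to 1e-3. The
   two-date fit profiles three linear coefficients per curve and searches
   the ordered rate pair (coarse log grid, Nelder-Mead refinement,
   multistart); its improvement statistic `R2* = 1 - SSE_2 / SSE_1` is near
   zero under a single pulse and grows when two distinct pulses are present;
   `R2* > 0.2` together with a rate separation of at least 1.5x flags
   multiple dates. Bins enter unweighted; empty bins are excluded. If the
   fitted date exceeds 55 generations the whole analysis is rebuilt for
   pairs 1-5 cM apart at 0.05 cM resolution (most of an old signal has
   decayed by 5 cM; longer distances only add noise).

7. **Sources and alpha.** The fitted amplitudes form (up to noise) the
   rank-1 matrix `delta_{UV} = alpha(1-alpha) v_U v_V / (f_U f_V)` with
   `v = beta_A - beta_B` the difference of the source profiles in
   surrogate-probability space. The leading eigenpair recovers
   `sqrt(alpha(1-alpha)) v` exactly; the remaining degree of freedom — how
   that product splits between `alpha` and `|v|` — is resolved by requiring
   the implied profiles `beta = f +/- scaled v` to be representable as
   non-negative mixtures of the surrogate panel: `alpha` minimises the
   joint NNLS residual of the two profiles on the panel. (The alternative
   of extending `beta` maximally until a coordinate hits zero is exact only
   when each source is fully unrelated to some surrogate; under realistic,
   imperfect panels it is biased toward 0.5, which is why the
   representability rule is used.) The minority source is labelled so
   `alpha <= 0.5`; each profile is reported as its NNLS surrogate mixture.
   A non-positive leading eigenvalue marks the event *uncertain*; a rank-1
   residual above 20% of the matrix norm flags more than two sources
   (*one-date-multiway*).

8. **Iteration and pruning.** Five iterations alternate date fitting and
   source inference, after each dropping surrogates contributing less than
   0.5% of ancestry (contribution = `alpha`-weighted sum of the two source
   profiles) and renormalising the probability map; at least the top two
   surrogates are always kept so curves remain fittable. The retained set
   never grows.

9. **Uncertainty.** The chromosome bootstrap resamples the Z chromosome
   identities with replacement (the same multiset for every individual),
   reweights the count tensors and refits the date; R = 100 resamples give
   the percentile 95% CI. A run is classified *no admixture* when the floor
   of the minimum bootstrap date is 1 or the maximum reaches 400. Pair
   draws are not redrawn per replicate — the tensors are reused — so the CI
   reflects chromosome-level variation given the drawn pairs. The weighted
   delete-one-chromosome jackknife (SNP counts as weights, Busing-style
   formula; equal weights reduce it to the classic delete-one jackknife)
   provides a standard error usable even for a single target individual,
   and is expected to run larger than the bootstrap SD. Dates convert to
   calendar years as `y = 1960 - 28 (g + 1)` (28-year generations, average
   birth year 1960).

## Synthetic data

The simulator generates the painting data the pipeline consumes, with known
truth. Ancestry tracts per haploid chromosome have i.i.d. Exponential
lengths with rate `lam` per Morgan and carry the minority source with
probability `alpha`; within a tract, painted segments with Exponential
lengths of mean `1/rho` Morgans draw donor labels from the tract source's
copying profile. The `s` painting samples of a haploid share its tracts and
differ only in the painting noise, as stochastic repaints of one genome do.
Defaults are the standard study design: 20 diploids, 22 chromosomes of
150 cM (SNP weights proportional to length), `s = 10`, `rho = 100` per
Morgan (mean 1 cM segments, enough to populate every 0.1 cM bin up to
30 cM), date 30 generations, `alpha = 0.2`.

Source profiles are near-disjoint over 12 donor groups (95% of each
source's copying on its own six donors, 5% spread everywhere — real
populations never have perfectly exclusive ancestry). The surrogate panel
perturbs each source profile toward a flat Dirichlet draw in proportion
`jitter` (default 0.15), emulating the realistic case where the true
admixing sources are unsampled and only imperfect relatives are available.

Two-pulse scenarios first fragment the genome at the recent rate, assigning
outer tracts to the recent source with probability `alpha_recent`; older
tracts subdivide at rate `lam - lam_recent`, so the *net* correlation of the
old ancestry decays at the old date, as it does in a forward-in-time
history. The default recent source shares the majority source's donor
support with mirrored weights — a distinct population of the same broad
ancestry, which is the scenario the two-pulse design emulates.

A bottleneck-like mode adds a donor-bias field shared by all individuals,
piecewise constant on Exponential blocks: it inflates the main and the
cross-individual null curves with the same decaying component, which is
precisely the artefact the null division is designed to cancel.

**What the simulator does not emulate:** genuine coalescent haplotype
structure (painting segment lengths are memoryless rather than
ancestry-informative), donor misassignment correlated along the genome,
surrogate-panel asymmetries (a surrogate cannot match itself in real copying
vectors), recombination hotspots, and continuous or more-than-two-pulse
admixture. Passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to every
artefact of real paintings.

## Numerical choices and caveats

- Pair distance is the bin-centre separation `(j - i) X`, so the fitting
  grid is exact multiples of `X`; segment extent then shifts the *effective*
  distance by about the mean segment length, scaling every amplitude by
  roughly `exp(-lam / rho)`. This leaves the date unbiased (the factor is
  distance-independent) and slightly shrinks `delta`, which in turn nudges
  the NNLS-based `alpha` down by ~0.01-0.02 at the default granularity.
- Date estimates for old events (say > 55 generations) are noticeably
  noisier and the left-trim costs them signal; the package mirrors the
  standard behaviour of re-fitting such events on the 1-5 cM grid.
- Randomised rounding keeps the subsampling unbiased but makes every result
  a function of the seed; all entry points take explicit seeds, and the
  whole pipeline is bit-reproducible for a fixed seed.
- The two-date search enforces `lam_1 < lam_2` and collapses to the
  one-date result when the rates come within 1%, guaranteeing
  `SSE_2 <= SSE_1` and `R2* in [0, 1]`.
- Bins with zero sampled pairs (or zero null pairs) are excluded from the
  fit rather than imputed.
- Donor groups whose vectors of contributions to the surrogates correlate
  above 0.95 can optionally be merged (transitive closure, averaged
  columns, rows renormalised); off by default since it trades power for
  memory.

## Problem sizes used in the shipped checks

The recovery checks run 20 replicate cohorts at the default design with 100
bootstrap resamples each; the sampler calibration uses 10^4 segments on a
250 cM chromosome over 5 seeds; distribution-level tests use 10^4 tracts.
These sizes give comfortably sub-percent Monte-Carlo error on the medians
while keeping the full suite fast on a single CPU.
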