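# Methods

This note documents the models and procedures implemented in `callspace`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real recordings.

## 1. Acoustic features

Each isolated contact call is summarised by 17 spectro-temporal features
computed from a Hann-window spectrogram (512-point FFT, 50% overlap),
band-limited to 0.5–9 kHz by default — a band that brackets the 2–4 kHz
energy of budgerigar contact calls. The band-limited mean power spectrum is
treated as a probability distribution over frequency, giving its mean, SD,
median, Q25, Q75, IQR (= Q75 − Q25 by construction), skewness, kurtosis,
normalised Shannon entropy, and spectral flatness (geometric/arithmetic
mean of power). The temporal energy envelope yields a normalised time
entropy. The per-frame spectral peak defines a dominant-frequency track:
mean, min, max, range (= max − min), and a modulation index (cumulative
absolute dominant-frequency change divided by the dominant range; defined
as 0 when the range is 0). Frequencies are in kHz, duration in seconds,
entropies in [0, 1].

There is no single canonical 17-feature set in bioacoustics; this list is
fixed as the package's canonical set because the downstream stages only
require a consistent multivariate description of each call, not any
particular feature semantics. All features are invariant to amplitude
scaling (power ratios only) and to where in a longer file a selection sits;
degenerate inputs (silent audio, bands outside Nyquist) raise typed errors
rather than returning NaNs.

## 2. Acoustic space

All calls from all birds and blocks are embedded **jointly** with t-SNE
(perplexity 30 by default, PCA initialisation, fixed seed; features
z-scored first so no single unit dominates). A joint embedding is the only
choice under which areas and overlaps of different birds/blocks are
commensurable; per-flock embeddings would make IoU across subsets
meaningless. A PCA embedding is available behind the same interface as a
fast linear alternative; it is not used by the default pipeline.

A subset's "acoustic space" is the **95% highest-density region (HDR)** of
a product-Gaussian KDE evaluated on one shared grid: the joint embedding's
bounding box padded 5% per side, 200×200 cells. Bandwidths are per-axis
Silverman values, `h_i = sigma_i * n^(-1/6)` (the 2-D Silverman factor is
exactly 1). Cells are sorted by density descending (ties broken by flat
cell index) and accumulated until the captured mass first reaches the
level, inclusive; at level 1.0 the mask is every cell with nonzero density.
The 0.95 level is the standard utilization-distribution convention;
the level, grid resolution and padding are configurable. Density mass is
normalised to the mass the grid captures, so truncated Gaussian tails do
not bias the level. The HDR construction is validated against the closed
form for an isotropic Gaussian cloud: the 95% HDR area of the KDE is
`pi * chi2_0.95(2) * (sigma^2 + h^2)`, and the grid computation lands
within a fraction of a percent at n = 10^4.

**Rarefaction.** HDR area grows with sample size, so areas are compared at
equal call counts: the mean HDR area over 30 random subsets of 180 calls
(both configurable), drawn uniformly without replacement from a seeded
stream. When a subset has fewer calls than the target size the policy is
configurable: `error` (refuse) or `use-all` (one pseudo-subset of all
calls, flagged in the output). The pipeline default is `use-all`, which
keeps sparse but includable birds (≥ 6 final-block calls) in the analysis
while the flag records that their areas were not size-equalised.

**Overlap.** IoU of two occupancy masks on the identical grid; the
combined space of several birds is the cellwise union of their masks.
Union-of-masks versus pooling calls before the KDE is genuinely ambiguous
for the flockmates' combined space; the union is the default (the literal
reading of "combined area") and pooling is available behind
`flockmate_mode="pooled"`. IoU is checked exactly against brute-force cell
enumeration, and is symmetric and union-monotone by property test.

## 3. Vocal learning measures

Per bird, comparing the pre-flock baseline (block 1) with the final block
(block 5):

* `vocal_diversity = mean rarefied area(5) − mean rarefied area(1)` —
  signed, in grid units²;
* `vocal_plasticity = 1 − IoU(region_1, region_5)` in [0, 1];
* `vocal_convergence = IoU(region_5, union of flockmates' region_5)` in
  [0, 1].

Diversity uses the full rarefied means; the plasticity/convergence regions
are built from one rarefied subset per comparison drawn from the shared
seed stream (configurable to full-sample regions), so all three measures
see size-equalised data. Birds with fewer than 6 final-block calls are
excluded (exactly 6 is included); excluded birds carry an explicit reason
string and NaN measures. Blocks 2–4 are carried through the call tables but
not modelled: the final block is the biologically relevant endpoint because
it is closest in time to tissue collection.

## 4. FoxP2 expression

Per confocal image: expression proportion = FoxP2⁺ count / DAPI⁺ count
(FoxP2⁺ cells are only counted over DAPI⁺ cells, so the proportion is
bounded by construction and validated on load). Per section:
MMSt proportion / VSP proportion; per bird: mean of its two section ratios.
With two observers the default averages their counts per image before any
proportion is computed — dual counting existed for reliability, not because
one observer is authoritative — and `observer_policy="first"` restricts to
the first observer. Sections missing a region are dropped with a warning,
never imputed.

**Inter-observer reliability** is ICC(A,1): the single-measurement,
absolute-agreement intraclass correlation from the two-way ANOVA mean
squares,

```
ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),
```

with the standard F-distribution confidence interval for this case
(McGraw–Wong). Absolute agreement is the right flavour here because a
constant offset between observers is a real disagreement about expression
levels, and the implementation is checked to 1e−10 against a brute-force
ANOVA oracle and against `pingouin`'s independent implementation.

## 5. Group statistics

**t-tests.** Age-class comparisons of MMSt proportion, VSP proportion and
the MMSt/VSP ratio use the pooled-variance independent-samples t-test
(df = n1 + n2 − 2, two-sided, alpha 0.05). A summary-statistic variant
computes t from published group means and SEs,
`t = (m1 − m2)/sqrt(se1² + se2²)`, which coincides with the pooled test for
equal group sizes; it exists so printed group summaries can be checked
without raw data.

**Bayesian GLMs.** Each learning measure is modelled against the
mean-centered FoxP2 ratio, age class (0 = young, 1 = older, so negative
age estimates mean lower values in older adults), and their interaction.
Plasticity and convergence are Beta-distributed with a logit link
(mean–precision parameterisation, `a = mu*phi`, `b = (1−mu)*phi`);
diversity is normal with identity link. Beta responses are compressed onto
the open interval by `(y(n−1) + 0.5)/n` — the standard monotone boundary
transform — applied uniformly so ordering is preserved.

Priors are weakly informative: coefficients ~ normal(0, 5) on the logit
scale for Beta models; for the normal model the coefficient and dispersion
priors scale with the response SD (normal(0, 5·SD(y)), half-normal(5·SD(y))
on sigma), since diversity is measured in grid units² whose magnitude is
arbitrary — a fixed-width prior there would be accidentally informative.
The Beta precision gets a Gamma(2, rate 0.1) prior. All auxiliary scales
are sampled on the log scale with the Jacobian included.

Sampling uses an affine-invariant ensemble MCMC sampler (emcee) with
differential-evolution moves, which mix far better than stretch moves on
these correlated GLM posteriors. 32 walkers are treated as chains for
diagnostics (the standard arviz convention for ensemble samplers); defaults
are 10,000 warmup + 10,000 kept ensemble iterations, giving 320,000
posterior draws. Initialisation is a small seeded ball around the
(logit-)least-squares solution. Results report posterior medians, 95% HPD
intervals, split-R̂ and ESS per parameter; R̂ ≥ 1.01 or ESS below the
configured floor produce explicit warnings on the results object — never a
silent pass. An effect is flagged exactly when its 95% HPD excludes zero.
The normal-family posterior median approaches the least-squares solution as
n grows (checked at n = 500 within 5%), and simulation experiments measure
HPD coverage at zero effects (≈ nominal over 20 datasets) and power for a
−0.7 logit-scale age effect (≥ 80%).

## 6. Synthetic data generator

The generator emulates the assay structure: two age classes, six replicate
flocks per class, four birds per flock, five recording blocks. Each bird's
repertoire is a 2-D Gaussian mixture in a latent acoustic plane: bird means
~ N(0, 3² I) around the flock origin, call-type centers ~ N(bird mean,
1.2² I), 3 call types, within-type call noise SD 0.5. Two per-age rates
drive the dynamics:

* **convergence rate kappa ∈ [0, 1]** — from block 2 on every call-type
  center moves toward the (block-1) flock centroid by fraction kappa per
  block; kappa = 0 freezes the repertoire, kappa = 1 collapses all birds
  onto the centroid from block 2;
* **diversity trend delta > 0** — within-type scatter at block b is scaled
  by delta^(b−1), so delta > 1 grows the repertoire footprint and delta < 1
  shrinks it.

Defaults encode the qualitative study outcome (young: kappa 0.4, delta
1.15; older: kappa 0.25, delta 0.85) so a default synthetic run exhibits
the age contrasts the pipeline is meant to detect. Calls per bird and block
default to 220 — per-bird call counts are not published, and this value
exercises rarefaction at subset size 180.

Latent calls map to the 17 features through a fixed seeded linear map into
15 free channels followed by monotone transforms (softplus for positive
spreads, sigmoid for entropies), with the IQR and dominant range derived
from their parts. A pure linear map into all 17 features would violate the
feature-vector invariants the loader enforces; the monotone post-transforms
preserve the latent geometry (which is all the embedding consumes) while
guaranteeing valid tables. Observation noise (SD 0.05) is added on the raw
channels.

FoxP2 truth: per bird and region, a true proportion ~ N(class mean, 0.05)
clipped to (0.005, 0.995); class means default to 0.31/0.44 (young
MMSt/VSP) and 0.37/0.48 (older). Counts: DAPI = 150 cells per image,
FoxP2⁺ ~ Binomial(150, p) per section; observer 2 re-counts Binomial around
observer 1's realised proportion jittered by the observer-noise SD (0.02),
and zero noise reproduces observer 1's counts exactly. Every stream derives
from one seed via stage-keyed substreams, so all outputs are bit-identical
across reruns.

**What the generator does not emulate:** real call acoustics (no waveform
synthesis feeds the pipeline; the feature map is a geometric stand-in),
recording noise and detection errors, within-bird call-count variation
across blocks, repertoire turnover that is not a center shift or scale
change, and any spatial structure within brain sections. Passing the
recovery tests therefore shows the pipeline's *mathematics* — embedding,
density regions, rarefaction, the measure definitions, the GLM layer —
faithfully recovers known dynamics of this latent-mixture form; it does not
certify feature extraction quality on real recordings, which is covered
separately by the closed-form signal tests (pure tones, white noise).

## 7. Problem sizes and numerical choices

Ground-truth recovery experiments run at reduced size chosen so a full
recovery study completes in minutes on one core: one flock per replicate,
25 calls per bird and block, t-SNE at perplexity 15 with 400 iterations, a
120-cell grid, rarefaction 20×5, and short MCMC runs (24 walkers,
1000 + 1000 iterations) for the calibration experiments. The convergence
contrast (kappa 0.8 vs 0) uses 20 replicates per condition and a one-sided
Welch t-test at alpha 0.01; the diversity sign check uses 10 replicates per
delta condition. These sizes trade statistical resolution for runtime only;
all are parameters of `callspace.validation`.

Degenerate inputs raise typed errors throughout (`ConfigurationError`,
`ValidationError`, `InsufficientDataError`, `DegenerateDataError`,
`GridMismatchError`) rather than propagating NaNs: fewer than two distinct
points for a KDE, zero bandwidths, mismatched grids, incomplete rating
tables, zero pooled variance, out-of-range Beta responses.

## 8. Known limitations

* t-SNE areas have no absolute units; diversity is only comparable within
  one joint embedding. Numerical parity with any particular published area
  values is not attempted and not meaningful across embeddings.
* The exact feature set, density level and grid resolution of the original
  workflow are not published; the package fixes its own documented choices.
* The flockmates' "combined" space has two defensible readings (mask union
  vs pooled-call KDE); both are implemented, neither claimed original.
* ICC confidence intervals use the F-based approximation, which is known to
  be conservative at very small subject counts.
* With 8–24 birds per analysis, the GLMs are honest about uncertainty:
  intervals are wide, and single-run "significance" on synthetic data
  should be read accordingly.
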