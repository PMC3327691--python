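# Methods

## Scope

`cnvpower` quantifies how errors made by copy-number-variant (CNV) calling
algorithms degrade the power of quantitative-trait association tests, and
compares that degradation against the alternative of regressing the trait
directly on raw log R ratio (LRR) intensities. Everything is simulation- and
closed-form-based; no external data are required.

## The call-error model

At a single CNV locus the true integer copy number `X` lives on `{0,1,2,3,4}`,
with 2 the diploid reference. Genotype frequencies `g0..g4` follow
Hardy–Weinberg equilibrium over per-chromosome alleles (deletion = 0 copies,
normal = 1, duplication = 2); a diploid genotype is the sum of two independent
allele draws, and the deletion/duplication heterozygote (0 + 2) is a true
state 2. The default variant allele frequency is 0.1 per variant allele,
giving genotype frequencies (0.01, 0.18, 0.81, 0, 0) for a deletion-only
locus and (0.01, 0.16, 0.66, 0.16, 0.01) for the multiallelic locus.

Two call-error types are modelled:

* false negative (rate `nu_n`): a true non-reference state is called 2;
* false positive (rate `nu_p`): a true 2 is called non-reference, with the
  destination state drawn proportionally to the population genotype
  frequencies of the non-reference states, `g_k / (1 - g2)`.

Mis-assignment between two non-reference states (a deletion called as a
duplication) is deliberately out of scope; it is believed second-order for
association testing and would complicate the closed forms below.

Writing the called state as `X_o = X + Delta`, the moments of the call error
follow in closed form. With `S1 = sum_{k!=2} g_k (2-k)`,
`S2 = sum_{k!=2} g_k (2-k)^2` and `r = g2/(1-g2)`:

```
E[Delta]   = (nu_n - nu_p * r) * S1
E[Delta^2] = (nu_n + nu_p * r) * S2
Var(Delta) = E[Delta^2] - E[Delta]^2
```

These are validated three independent ways in the test suite: by direct
summation over the 25-cell joint table of `(X, X_o)`, by a Monte-Carlo
sampler at 10^6 draws, and against frozen reference grids of `sd(Delta)`
over `nu_n x nu_p`. Deletion-only and duplication-only loci at equal allele
frequency share `Var(Delta)` exactly (the error distribution is mirrored),
so one grid covers both.

## The LRR noise model

The theoretical LRR of a `c`-copy segment against a two-copy reference is
`log2(c/2)`: −1, 0, log2(3/2), 1 for one to four copies; the zero-copy value
diverges to −∞ in theory and is represented by a configurable finite floor
(default −2), since background intensity keeps observed values finite. Real
arrays attenuate these means; the `array` preset applies a damping factor of
0.5 and adds Gaussian noise `Delta_Z` with sd 0.15 (a typical estimate for
high-quality DNA), i.e. observed `Z_o = damping * Z + Delta_Z`. The
`theoretical` preset keeps damping 1. Every reproduced power number uses the
`array` preset.

Setting `Var(Delta) = 0.15^2` defines an equivalence contour in the
`(nu_n, nu_p)` square: error rates below it mean the caller injects *less*
variance than intensity noise. The contour solver treats `Var(Delta)` as a
quadratic in `nu_p` at each grid `nu_n` (step 0.001) and keeps the smaller
admissible root — the physically meaningful error rate; when `S1 ~ 0`
(symmetric multiallelic locus) the quadratic degenerates and is solved
linearly to avoid catastrophic cancellation.

## Power simulation

The trait is `Y = X*beta + eps`, `X` a binary carrier indicator,
`beta = 2.5`, `eps ~ N(0, sigma^2)` with `sigma^2` recomputed per carrier
frequency so `Var(Y) = 100` always; at carrier frequency 20% the CNV explains
exactly 1% of trait variance. Carriers are Bernoulli(freq) per subject
(n = 1000), the test is the two-sided OLS slope t-test at `alpha = 0.05`
(implemented vectorized through the equivalent F(1, n−2) statistic on the
squared sample correlation; cross-checked against statsmodels OLS), and
power is the significant fraction over replicates (default 10,000). A
replicate whose observed predictor is constant — e.g. every carrier missed —
cannot reject and counts as non-significant, which pins power to ~alpha·0 at
`nu_n = 1` rather than leaving it undefined.

Calls-based power degrades the predictor by flipping carriers with
probability `nu_n` and non-carriers with probability `nu_p`. LRR-based power
replaces the predictor by one noisy LRR draw per subject (carrier mean −0.5
for deletions, 0.5·log2(3/2) ≈ 0.292 for duplications; non-carrier mean 0;
sd 0.15). Because a single locus is tested, LRR power is invariant to CNV
size.

A closed-form oracle accompanies every simulation: the slope test has power
`P(F(1, n−2; lambda) > F_crit)` with `lambda = n R^2 / (1 − R^2)` and
`R^2 = rho^2 * R0^2`, where `R0^2` is the variance fraction explained by the
true indicator and `rho^2` the squared correlation between the true
indicator and the predictor actually used — `(1−nu_n)(1−p)/(1−p(1−nu_n))`
for error-prone calls (general two-rate form in `rho_sq_calls`), and the
classical attenuation `m^2 p(1−p)/(m^2 p(1−p)+sd^2)` for LRR. Simulated and
analytic power agree within Monte-Carlo error everywhere the suite checks.

The half-power false-negative rate (where power falls to half its
error-free value) is located on a `nu_n` grid of step 0.01 with 10,000
replicates per point; the empirical curve is first made monotone
non-increasing by isotonic regression, which suppresses grid-level noise in
the crossing. Analytic crossings are 0.560, 0.564 and 0.619 for carrier
frequencies 5%, 10% and 20%. At 1% frequency the baseline power sits near
the alpha floor and the ratio is unstable, so crossings are flagged
unreliable below baseline power `2*alpha`.

## Synthetic cohort and the caller surrogate

The cohort generator emulates the array experiment behind the recovery
analysis: 10,000 probes, 1 kb apart, on one chromosome; a CNV of 1–25
probes centered on the grid (`start = floor((n_probes − size)/2) + 1`);
exactly 200 of 1,000 subjects carrying it (chosen without replacement);
independent Gaussian LRR per cell with the `array` preset means and sd 0.15.
Matrices round-trip through PennCNV-style tab-delimited signal files.
What the generator does **not** emulate — GC waves, probe-specific noise,
B-allele frequencies, variable probe spacing, mosaic states — bounds what
passing tests say about real arrays: results transfer only insofar as real
noise is approximately independent Gaussian at comparable sd.

CNV calling is a 5-state homogeneous hidden Markov model decoded by
Viterbi: Gaussian emissions with means (−1.0, −0.5, 0, 0.2925, 0.45) and
sds 0.15; transition matrix with `stay_prob` on the diagonal and the rest
split evenly; initial mass 1e-4 per non-reference state. Maximal non-2 runs
in the decoded path become call segments. Viterbi is verified against
exhaustive enumeration over all 5^L paths on short instances, and calls are
deterministic given the input (argmax ties resolve to the lowest state).

`stay_prob` defaults to 0.99999. This was calibrated so the surrogate
reproduces the qualitative behaviour of production callers on this probe
grid: at 0.9999 the transition penalty (~2·log(2.5e-5)) is small enough
that 3-probe deletions are recovered ~20–25% of the time, whereas real
callers find sub-4-probe deletions essentially never; at 0.99999 deletions
of 1–3 probes and duplications of 1–4 probes are near zero, deletions above
7 probes exceed 90–98% recovery, and duplication recovery passes 90% only
near ~21 probes. Exact recovery values of any specific production caller
(which depend on its internal, version-specific parameters) are not a
target; only these qualitative features are.

A carrier counts as *recovered* when some called segment overlaps the true
region by at least one probe with a called state on the same side of 2 as
the truth (a deletion called over a true duplication does not count). The
overlap rule is a documented choice; recovery = 1 − `nu_n` by definition.

Composing the recovery curve (size → recovery) with the power curve
(`nu_n` → power) via `nu_n = 1 − recovery(size)` predicts power as a
function of CNV size; `end_to_end_power` verifies the composition with the
caller inside the replicate loop, and the two agree within Monte-Carlo
error.

## Problem sizes and numerical choices

Default experiment sizes mirror the study conditions (n = 1000 subjects,
10,000 replicates, 10,000 probes, 200 carriers). The test suite exercises
the same code paths at reduced sizes chosen for a laptop-class single-core
run: recovery curves on a 500-probe window around the CNV (the transition
penalty, and hence recovery, is essentially independent of flank length
beyond a few dozen probes), end-to-end power at 120-probe grids with a few
hundred replicates, and oracle-agreement checks at 2,000–4,000 replicates.
All tolerances are 3 Monte-Carlo standard errors unless the quantity is
deterministic, where agreement is exact (1e-12 for moment identities, three
printed decimals for the sd grids). Every random draw flows through a
caller-supplied `numpy.random.Generator` or an explicit seed; identical
seeds give bit-identical cohorts and result files.

## Known limitations

* Error rates are treated as locus-constant; real callers' rates vary with
  probe content, spacing and GC context.
* The third error type (non-reference mis-assignment) is excluded, so
  multiallelic results understate total call variance when both alleles are
  common and copy number is high.
* The LRR comparison tests a single known locus; genome-wide use of LRR
  would face a multiple-testing burden the calls-based approach shares only
  partially.
* The HMM surrogate uses distance-independent transitions (uniform 1-kb
  spacing); recovery on irregular grids is out of scope.
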