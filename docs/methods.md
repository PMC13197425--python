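# Methods

This note records the model, its numerical choices, and what the test
suite does and does not demonstrate.

## Diet mixing model

Consumer collagen tracers (δ¹³C, δ¹⁵N) are modeled per individual with
diet proportions `p` on the 4-simplex over {C₃ plants, C₄ plants,
terrestrial fauna, marine fauna}:

```
x_j | p ~ Normal( Σ_k p_k (μ_kj + λ_kj),  Σ_k p_k² (σ_kj² + τ_kj²) )
p ~ Dirichlet(1, 1, 1, 1)
```

`λ, τ` are trophic enrichment factor means/sds. Defaults (‰):
Δδ¹³C = 1.0 ± 0.0 for both faunal sources and 4.8 ± 0.5 for both plant
sources; Δδ¹⁵N = 3.0 ± 0.0 everywhere except marine fauna at 5.5 ± 0.5
(the standard South American human-diet set; overridable per
source/tracer). Zero-sd factors are exact constants.

The p²-weighted variance is the *process-error* form: individuals sit
between perfect dietary specialists and perfect integrators. A
residual additive error term is deliberately not included; the
process-only form is the stated default and the generator produces data
from the same likelihood, so recovery tests close the loop exactly.

**Source uncertainty.** Each source's (μ_k, Σ_k) gets a weak conjugate
normal-inverse-Wishart prior (κ₀ = 0.01, ν₀ = d + 2, Ψ₀ = 0.5 I,
μ₀ = sample mean) fitted to the *raw* source samples, and the sampler
redraws (μ_k, Σ_k) from that posterior at every sweep. This is a cut
model — source parameters are informed by source data only, not fed
back from consumers — which keeps the source fit honest when single
consumers are extreme, at the price of not being the exact joint
posterior. The consumer likelihood uses the marginal tracer variances
(the diagonal of the drawn Σ_k); the full covariance still shapes the
source-mean draws.

**Sampler.** Metropolis-within-Gibbs: an isometric-log-ratio random
walk on the simplex per consumer (target density includes the
Σ log p_k Jacobian), adaptive step during the first half (burn-in,
discarded), tuned to 20–50% acceptance and frozen afterwards. Three or
more chains are required; a fit is accepted only when the Gelman–Rubin
statistic is < 1.05 for every proportion. Runs are bit-reproducible
for a fixed (seed, configuration).

**Outputs.** The marine-fraction posterior is exported as a histogram
with 100 even percentage bins. A one-sample Kolmogorov–Smirnov test
against a normal with the draws' own moments (standard scipy p-value)
documents why: realistic marine posteriors are right-skewed and fail it
(p < 0.05), so carrying a mean ± sd forward would misstate the
calibration input.

**Collagen screening.** Faunal reference samples must have atomic C:N
in [3.1, 3.5], %C > 20, %N > 10; human samples C:N in [3.1, 3.4];
missing metrics fail the screen ("unreported QC").

## Calibration curves

Curves are tabulated (cal BP, ¹⁴C BP, σ) in the IntCal `.14c` dialect
and linearly interpolated (both μ and σ) between nodes; the internal
calendar scale is cal BP, reports use AD = 1950 − cal BP. A fixed
reservoir offset shifts a marine curve by `μ' = μ + ΔR` with
`σ' = √(σ² + σ_ΔR²)`; a free offset is a model parameter instead. The
per-individual mixture is

```
μ_mix(θ) = (1−m) μ_terr(θ) + m μ_marine(θ)
σ_mix²(θ) = (1−m)² σ_terr²(θ) + m² σ_marine²(θ)
```

— the variance rule treats the two curve errors as independent; OxCal's
internal propagation is not documented at this level, so this quadrature
is our stated choice, validated by oracle self-consistency.

Single-date calibration evaluates
`p(θ) ∝ N(age; μ(θ), σ_det² + σ_curve²(θ))` on a 1-year grid over the
curve span intersected with [−55, 5000] cal BP, normalizes by
summation, and trims where the likelihood is below 1e−12 of its
maximum. A determination whose best fit anywhere on the window is more
than 8σ away raises an error instead of returning a spurious density.

**Bundled curves are synthetic stand-ins.** The genuine SHCal20 and
Marine20 distribution files are not redistributable inside this
repository, so `tidechron/data/` ships smooth, monotone-trend
approximations through generic Holocene anchor points (SH offset ≈ 36
¹⁴C yr, surface-ocean reservoir ≈ 500 ¹⁴C yr, small deterministic
decadal wiggles, realistic σ levels), generated by
`scripts/make_bundled_curves.py`. They reproduce the *structure* of
real calibration (plateaus, non-normal densities, marine offsets) but
place absolute dates only to within a few decades of what the published
curves would give. Every closed-loop test is unaffected (truth and
inference share the curve); only absolute comparisons against published
calendar dates inherit the approximation, and `scripts/acceptance.py`
is the one place that makes such a comparison.

## Joint chronological model

Latent variables per dated individual: tissue date θ_i (uniform over
the model window, default AD 500–1800 ± slack), tissue-formation offset
o_i ~ N (defaults: second molar 11 ± 1 yr; vomer/sphenoid 15 ± 5 yr;
user-extensible; secondary dentine ignored), age at death
a_i ~ U(osteological interval). Derived: birth = θ + o, death =
birth − a (cal BP). Undated relatives (placeholders from the family
tree) carry a free birth date constrained only through the gaps.

Other parameters: per-marine-individual m_i with the (unnormalized)
histogram counts as a discrete prior on bin centers; a single global
ΔR ~ U(−600, 200) ¹⁴C yr by default (bounds are config: the default
generously covers the published Bayesian ΔR estimates for coastal
Peru); per-phase start/end boundaries with prior ∝ 1/(end−start) and
members iid uniform inside; for charcoal outliers a shared
u ~ U(0, 3) and per-date ε ~ Exp(1) truncated to (0, 10], the sample
pre-dating its context by ε·10^u years (one-sided, toward older ages).
Generational gaps enter as
`parent_birth_BP − child_birth_BP ~ N(24, 6)` (mother) or `N(28, 7)`
(father); chains through unsampled individuals compose additively
because the gaps are independent normals.

Repeat measurements of one event are pooled before modeling by
inverse-variance weighting with a χ² consistency report (warn at 5%).

**Sampler.** Single-site adaptive random walks with rejection of hard
order violations, plus three block moves that target the posterior's
stiff directions: (a) a rigid translation of every event and boundary,
(b) a ΔR proposal with compensating shifts `θ_i += m_i δ` of
marine-dated events (a volume-preserving, self-inverse map, so the
Hastings ratio is the posterior ratio), and (c) rigid translations of
each gap-linked family cluster. Event parameters also take occasional
uniform independence proposals over the window to jump between
calibration-curve modes. Initialization calibrates each date on the
terrestrial curve, then walks each stratigraphic sequence oldest-first,
nudging members younger than everything above them; remaining
violations are resolved by seeded jitter. Burn-in is the first half of
iterations; adaptation freezes at its end. Convergence is gated on
max R̂ < 1.05 (arviz rank-R̂); a parameter that accepts no move after
burn-in raises a tuning error.

**Agreement indices.** For each date,
`A_i = 100 Σ p_mod p_unmod / Σ p_unmod²` on the 1-year grid, where the
stand-alone density marginalizes the histogram prior and the ΔR prior
by Monte Carlo (60 prior draws); `A_model = 100 Π(A_i/100)^(1/√n)`;
dates with A_i < 60 are flagged. This is the classic 1995-style index;
OxCal's exact variant differs subtly across versions, so numeric
equality with published A_model values is approximate by construction.

## Pedigrees

Relatedness degrees are mapped from the kinship coefficient computed on
the tree, and only the exact non-inbred values classify (φ = 1/4 → 1st,
1/8 → 2nd, 1/16 → 3rd): inbreeding-inflated coefficients are out of
scope, and enumeration likewise rejects trees in which any child's
parents are related. Mitochondrial consistency is checked per maternal
component (union of mother–child links): all typed members must share a
haplotype; untyped individuals match anything. Enumeration does an
exhaustive depth-first search over parent assignments for ≤ 6 sampled
individuals plus ≤ 4 canonical placeholders whose sexes are inferred
from the roles they take, pruned by (sound) monotone kinship bounds and
incremental mt checks, deduplicated up to placeholder relabeling, with
a node budget guarding against blow-up. Every placeholder must be
load-bearing (≥ 1 child and either ≥ 2 children or a parent), which is
also what makes deduplication well-defined. All consistent trees are
returned; no likelihood ranking is attempted. Age-at-death intervals
are not used to orient parent–child edges (absolute birth dates are not
known at enumeration time), so a 1st-degree pair of unknown generation
order yields both orientations.

## Summaries

Medians and central (equal-tailed) 95% intervals on the AD scale,
rounded to the nearest 10 years (half away from zero); equal-tailed
rather than HPD so that multimodal densities still print one contiguous
range (HPD available as an option). Group KDEs lay a Gaussian kernel
with Silverman bandwidth (floored at 1 year) over the group members'
dates *at each retained MCMC iteration* and average across iterations
(subsampled to ≤ 1500 iterations), so chronological uncertainty widens
the summary instead of being smeared away. Diet-scenario sensitivity
is reported as per-individual median shifts between two fitted runs;
the comparison operates on fitted chains, so non-convergence surfaces
where the scenarios are fitted.

## Synthetic data

The generator draws ground truth and pushes it through the same
likelihoods the inference inverts, so closure tests are exact. Default
source moments (‰) are order-of-magnitude realistic for coastal Peru —
C₃ (−26.5, 4.0), C₄/maize (−11.5, 6.0), terrestrial fauna (−18.5, 6.0),
marine fauna (−12.5, 16.0), with sds 1–2 — configuration, not biology
claims. Diet proportions give the marine fraction a right-skewed
Beta(1.6, 4) marginal (farmers through fisherfolk); the compact family
preset draws family marine fractions from U(0.15, 0.45) because the
generational-gap experiment addresses the regime where stand-alone
calibrations are diet-limited. Osteological intervals are generated to
contain the true age at death, as a competent assessment would.

The `chincha-like` preset fixes the study conditions: 30 dated
individuals (13 in a middle-valley uniform phase, 13 in an ossuary
phase containing a family of four with three unsampled ancestors, 4 in
a stratified mortuary level), 13 non-human determinations in a
six-level room sequence of which two are old-wood charcoal, measurement
σ = 20 ¹⁴C yr, true ΔR = −300.

What passing closure tests shows: the implementation inverts its own
generative model at realistic sizes and noise levels. What it does not
show: robustness to real-data pathologies the generator omits —
collagen diagenesis, reservoir variation over time, mis-assigned
stratigraphy, non-normal measurement error, diet change over life.

## Problem sizes used by the checks

Diet recovery: 10 consumers, 3 chains × 20,000 sweeps. ΔR recovery: 5
replicates of the full pipeline (diet fit 3 × 12,000; joint model 3
chains × 8,000 sweeps over ~170 parameters), 95%-interval coverage of
the truth in ≥ 4 of 5. Single-date MCMC-vs-calibration: 200,000
retained draws, total variation < 0.02. Generational-gap experiment:
the compact family preset, dates-only model at fixed ΔR −300 ± 50,
3 × 8,000 sweeps, with/without gaps. These sizes give comfortable
margins on the quantities asserted while keeping the default test run
short.

## Known limitations

* The diet model's cut treatment of source parameters and
  diagonal-variance consumer likelihood are approximations; recovery,
  not numeric equivalence with other mixing-model software, is the
  contract.
* A single time-constant ΔR; no wiggle-matching; no trapezoidal
  boundaries; no post-bomb or Northern Hemisphere curves.
* OxCal emission covers only the statement subset this package uses and
  fails loudly on anything else; OxCal output files are not parsed.
* The pedigree search is exhaustive only within its stated bounds
  (≤ 6 sampled, ≤ 4 placeholders, non-inbred configurations).
* Absolute calendar dates computed on the bundled stand-in curves are
  approximations; substitute the genuine IntCal files for real work.
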