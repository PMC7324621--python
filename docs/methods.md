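# Methods

## Scene statistics

**Contrast operator.** Local contrast at scale σ is the Euclidean modulus of
a band-pass gradient pair: the difference between Gaussian first-derivative
filters at the centre scale σ and the surround scale 2σ, applied in x and y.
This centre–surround construction is non-oriented (the modulus is isotropic),
peaks *on* edges rather than on either side of them, and — being the modulus
of a zero-mean Gaussian pair under white-noise input — yields exactly
Rayleigh-distributed magnitudes on noise, which anchors the shape parameter
at γ = 2 for texture-like input. A plain `|DoG|` operator (zeroth order) is
available via `filter="dog"` for comparison; its even symmetry makes it
vanish on the edge itself, so it is not the default. An optional divisive
normalisation by the local mean luminance (surround-scale Gaussian average,
floored at 1 % of the image maximum) gives Weber-like contrast.

**Filter bank.** Five octave-spaced centre scales, σ = 1, 2, 4, 8, 16 px,
surround always 2σ. A border of one surround sigma (⌈2σ⌉ px) is excluded
from pooling because filter support is incomplete there. Pooling uses the
finest scale by default (`scale_policy="max"` takes the per-pixel maximum
over scales); exact zeros are dropped before fitting, and their count is
reported, because the Weibull density lives on x > 0.

**Weibull fit.** Maximum likelihood via the profile score in γ with β given
in closed form, `β(γ) = mean(x^γ)^(1/γ)`; the γ root is bracketed and solved
to 1e−8 on a log-geometric-mean-stabilised sample. The fit runs on the raw
pooled samples, never on binned histograms. CE := β̂, SC := γ̂. The
approximation route (`route="lgn"`) instead takes CE as the spatial mean of
contrast magnitude and SC by inverting the Weibull coefficient of variation,
`CV²(γ) = Γ(1+2/γ)/Γ(1+1/γ)² − 1`, at the empirical CV; it is rank-consistent
with the ML route (Spearman ρ ≥ 0.9 over the synthetic clutter axis) but not
numerically identical — the mean equals β·Γ(1+1/γ), so the two CE definitions
diverge where γ is far from 1.

## Stimulus design

Conditions are tertile bands with a 10 % guard gap (scenes in the gaps are
dropped) on the manipulated axis: the sum of z-scored SC and CE in joint
mode, or the raw statistic in the isolation modes. In isolation modes the
clamped statistic is first restricted to its middle band and then
*stratified*: every condition × animal group draws identical per-bin quotas
over eight quantile bins of the clamped statistic, because within-band
correlation with the manipulated statistic would otherwise pull the
conditions apart. Animal/non-animal matching inside each condition is
verified with a pooled-variance t-test on means and a Mann–Whitney z
(normal approximation with tie correction) on medians; selections are
redrawn until all four tests exceed p = 0.25, up to 1,000 attempts.
Schedules present every scene once per instruction in blocks of 20 trials
of constant instruction, block order shuffled, fixation drawn uniformly
from {350, 400, 450, 500, 550} ms (mean 450 ms), stimulus 100 ms.

## Drift-diffusion core

σ is fixed at 1 (scale convention); all drifts, boundaries and times are in
that convention's units and seconds. The first-passage density uses the
dual series representation with an automatic small-time/large-time switch;
the number of terms is chosen from the requested absolute tolerance
(default 1e−10 in the public API, 1e−8 inside MCMC). Per-trial likelihoods
are floored at 1e−300 so outlier RTs (including rt ≤ t0) keep the chain
finite rather than crashing it. Inter-trial variability parameters
(sv, sz, st) are not modelled; the starting point is fixed at a/2
(accuracy coding — upper boundary = correct).

The simulator is Euler–Maruyama with, by default, an exact Brownian-bridge
crossing test per step: the probability that the path crossed a boundary
inside a step even though both endpoints are interior is
`exp(−2 d₀ d₁ / dt)`, and sampling it removes the O(√dt) bias of discretely
monitored absorption (the test is skipped when that probability is below
e⁻³⁴). Unabsorbed paths past a 20 s cap are flagged as misses. With
dt = 1e−3 the driftless mean decision time matches the closed form z(a−z)
to ~0.1 %.

## Hierarchical model and sampler

Per subject s: drift intercepts `v_s[g]` (one per complexity condition if
the model splits them), log-boundaries `log a_s[g]` (per instruction and/or
condition), and `t0_s`, each drawn from group-level normals; `t0_s` is
truncated positive and its group updates include the truncation normaliser.
Regression coefficients are hierarchical too — subject-level values around
a group mean with a group SD — matching common practice for trial-level DDM
regressions; the reported coefficient (`beta_v_quad` etc.) is the group
mean. The squared regressor is centred, a pure reparameterisation that
decorrelates the quadratic coefficient from the drift intercept and was
necessary for acceptable mixing. Boundary regressions and intercepts live
on the log scale, so a > 0 under any covariate value.

Priors (documented defaults, all configurable): group drift means
N(0, 5); group log-boundary means N(log 1.5, 1); group t0 mean
N(0.3, 0.25); group SDs half-normal (1.0 for drift, 0.5 for log-boundary,
0.25 for t0, 0.5 for coefficient SDs); coefficient group means N(0, 5).

The sampler is Metropolis-within-Gibbs: conjugate Gibbs draws for every
group mean; adaptive random-walk Metropolis (target acceptance 0.44,
Robbins–Monro step-size adaptation) for group SDs, t0 hyperparameters,
and all subject-level parameters; and one parameter-expansion *rescale*
move per coefficient that multiplies the group SD and the subject
deviations jointly, which keeps the σ → 0 funnel mixing when the true
between-subject coefficient spread is zero. Group-level updates cost no
likelihood evaluations and are swept three times per iteration.
Adaptation runs only during a discarded tuning phase (default 400
iterations) plus the burn-in, so the retained trace satisfies detailed
balance. Chains are independent, seeded from a single `SeedSequence`, and
bit-reproducible.

**Diagnostics.** Rhat is the classic potential scale reduction factor
`sqrt(((n−1)/n·W + B/n)/W)` without splitting or rank-normalisation — the
form under which identical chains give √((n−1)/n) ≲ 1 and well-converged
fits land in a 0.98–1.02 band. DIC is `D̄ + pD` with `pD = D̄ − D(θ̄)`,
deviance `D = −2 log L`, and θ̄ the posterior mean of *all* sampled
parameters (subject- and group-level; log-boundaries averaged on the log
scale). Posterior predictive checks simulate the full trial table once per
posterior draw (default 500 draws) and average accuracy and RT deciles
(10/30/50/70/90) per condition × instruction × correctness.

**P convention.** `posterior_p` returns both tail masses. The reported P is
the mass on the side *opposite* the sign of the posterior mean — i.e. the
probability the effect has the other sign — which is how "a negative shift
in the posterior, P < 0.001" is conventionally read even when P is verbally
defined as the mass below zero. Both raw tails are always available.

**Model grids.** The condition ladder holds five models: everything fixed;
boundary split by instruction; plus drift and/or boundary split by
complexity condition. The regression grid crosses affected parameter
{v, a, both} × covariate {SC, CE} × form {linear, linear+quadratic} — 12
models plus the null; `include_quadratic_only=True` adds the quadratic-only
form for 18. SC and CE never appear in the same model: their strong
correlation would make coefficients unstable.

## Synthetic generators and what green tests establish

**Textures.** A mid-grey canvas receives n randomly placed elements (tanh
edge profiles with Gaussian taper, or Gaussian blobs) with signed lognormal
amplitudes. Two couplings keep the generator on the natural-scene manifold:
element amplitude is normalised by the square root of expected coverage so
dense textures do not saturate the luminance range, and the lognormal
spread shrinks with coverage (capped at 0.6 at the sparse end) so shape
parameters span roughly 0.3–2.0 — sparse compositions below 1, dense
textures near the Rayleigh limit — rather than collapsing toward 0. The
clutter→SC mapping is monotone (Spearman ρ ≥ 0.95 across five levels).

**Stat pools.** When only (CE, SC) values matter, pools are drawn directly:
SC uniform on (0.4, 2.2), log-CE increasing in SC with conditional scatter
0.35, giving an SC–CE correlation near 0.8 — the order reported for natural
image databases, and large enough overlap to clamp one statistic while
manipulating the other. Animal labels are independent Bernoulli(½) unless
the association knob is turned.

**Behaviour.** Subjects are drawn from group distributions (defaults:
μ_v = 1.5, σ_v = 0.3, boundaries 1.2/1.8 for speed/accurate with 0.12
log-SD, t0 = 0.30 ± 0.04 s, β₁ = 0, β₂ = −1) and every scheduled trial is
simulated through the DDM core. The default drift level puts error rates
near 10–15 %, as in this task's participant populations; μ_v = 1 would put
a typical simulated participant above the study's own exclusion thresholds.
Contaminant rates (fast guesses, misses) default to zero and exist only for
preprocessing tests.

These generators emulate the *structure* of the experiment, not its
content: no animal is ever rendered (labels are symbolic), the images are
element textures rather than photographs, and behaviour follows the DDM
exactly — there are no sequential effects, lapses, fatigue or
stimulus-specific memory. A green suite therefore establishes that the
statistics, the sampling design, the likelihood and the inference machinery
are internally correct and mutually consistent, and that model selection
and parameter recovery behave as designed *when the generating process is
the assumed one*; it does not certify the substantive findings on real
photographs or real observers, and published DIC differences computed on
the original behavioural data are out of reach at desk scale by design.

## Preprocessing

Trials faster than 100 ms are removed as fast guesses. Participants are
excluded for excessive errors by an absolute threshold (default 25 %)
and/or an SD rule (default mean + 2.8 SD), and for omission rates above
40 %; both error rules are supported because different experiments of this
paradigm used each, and every exclusion is logged with its reason. Misses
count toward omission rates, are dropped from likelihoods, and error rates
are computed over responded trials only. RT summaries use correct trials.

## Known limitations

- The Wiener density's series tolerance is absolute, not relative; in the
  extreme tails the floor dominates, which is intentional for MCMC
  robustness but makes log-densities below ~−690 uninformative.
- DIC uses plug-in posterior means; alternatives that integrate over the
  hierarchy (or WAIC/LOO) are not implemented.
- The random-walk sampler is tuned for the desk-scale problems in the test
  suite (≤ ~10 subjects, ≤ ~500 trials each); much larger datasets would
  favour a gradient-based sampler.
- Isolation-mode sampling requires genuine distributional overlap of the
  clamped statistic across bands; with correlation ≳ 0.95 between SC and CE
  the stratified quotas become infeasible and the sampler raises rather
  than silently unbalancing conditions.
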