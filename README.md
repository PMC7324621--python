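# sceneddm

Natural scenes differ systematically in their low-level contrast structure,
and observers' perceptual decisions differ with them. `sceneddm` links the
two ends of that chain in one tested library:

1. **Scene statistics.** The distribution of local contrast in a natural
   image is well described by a two-parameter Weibull distribution. Its
   scale β — *contrast energy* (CE) — measures overall contrast strength;
   its shape γ — *spatial coherence* (SC) — measures where the image falls
   on the sparse-to-cluttered axis: γ well below 1 for scenes dominated by a
   few salient edges (power-law histograms), γ near 2 for dense textures
   whose contrast moduli are Rayleigh/Gaussian-like. Both indices are
   computed from a multi-scale bank of non-oriented centre–surround
   contrast filters, emulating early (LGN-like) visual responses.
2. **Decision modelling.** Choices and response times in a speeded
   animal/non-animal categorisation task are modelled with a hierarchical
   drift-diffusion model (DDM): evidence accumulates from `z = a/2` with
   drift `v` and unit diffusion until it reaches 0 or `a`; the response time
   is the first-passage time plus a non-decision time `t0`. Trial-level
   regressions let drift (and boundary) depend on the scene's centred SC or
   CE with linear and quadratic terms — a negative quadratic coefficient is
   the *inverted-U*: information is extracted fastest from scenes of
   intermediate complexity. Boundary separation gets separate intercepts for
   speed vs accuracy instructions. Models are compared by DIC, convergence
   is checked with the Gelman–Rubin statistic, coefficients are tested by
   posterior tail mass (P), and posterior predictive checks compare observed
   accuracy and RT deciles with datasets simulated from the posterior.

Everything in between — sampling stimulus sets into low/medium/high
complexity conditions with animal/non-animal matching, building blocked
speed/accuracy trial schedules, preprocessing (fast guesses below 100 ms,
participant exclusion rules), and synthetic generators for images and
behaviour — is part of the package, so the full analysis runs without any
external data. The likelihood uses the standard dual series expansion of
the Wiener first-passage density; sampling is Metropolis-within-Gibbs with
conjugate updates for group means, all numba-compiled.

## A worked example

```python
from sceneddm import TextureParams, compute_scene_stats, generate_texture

sparse = generate_texture(TextureParams(n_elements=10, seed=1, shape=(128, 128)))
dense = generate_texture(TextureParams(n_elements=5000, seed=1, shape=(128, 128)))
for name, img in [("sparse", sparse), ("dense", dense)]:
    s = compute_scene_stats(img, scales=(1, 2, 4))
    print(name, round(s.CE, 5), round(s.SC, 3))
```

```
sparse 5e-05 0.266
dense 0.00433 1.853
```

Ten scattered elements give a heavy-tailed contrast histogram (SC = 0.27);
five thousand overlapping ones converge to a near-Gaussian texture
(SC = 1.85). Fitting the hierarchical model to behaviour simulated from a
known inverted-U truth (`examples/04_fit_hierarchical_model.py`, 5 subjects
× 240 trials, true β₁ = +0.3, β₂ = −1.0):

```
max group-level Rhat: 1.0090 (convergence band 0.98-1.02)
  beta_v_lin:  mean +0.311 [95% CI +0.054, +0.580], true +0.3, P(<0) = 0.0163
  beta_v_quad: mean -1.300 [95% CI -1.725, -0.864], true -1.0, P(>0) = 0.0000
```

The chains converge, both coefficients are recovered, and the quadratic
term is credibly negative — the inverted-U. The `examples/` directory has
one short script per capability (scene statistics, stimulus sampling, DDM
primitives, hierarchical fitting, the orchestrated pipeline); each prints
the numbers it computes and says what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the convergence benchmark from scratch: it simulates six
subjects × 240 trials from known group-level parameters through the real
stimulus-sampling and scheduling path, fits the matching hierarchical model
(4 chains × 1,000 iterations, burn 100) and writes the maximum group-level
Gelman–Rubin statistic to the JSON file named by `--out`.

## Layout

| module | contents |
| --- | --- |
| `sceneddm.scene_stats` | contrast filters, Weibull fit, CE/SC (two routes) |
| `sceneddm.stimulus` | condition sampling, matching tests, trial schedules |
| `sceneddm.ddm` | first-passage density, absorption, simulator, likelihood |
| `sceneddm.inference` | hierarchical model, MCMC, DIC, Rhat, P, PPC, model grids |
| `sceneddm.synth` | texture/pool generators, behaviour generator |
| `sceneddm.pipeline` | preprocessing, behavioural summaries, full analysis |
| `sceneddm.io` | image reading, statistics tables |

See `docs/methods.md` for the model, priors, numerical choices and the
limits of what the synthetic generators establish.
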