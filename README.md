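# lynxscr

Maximum-likelihood **spatial capture–recapture (SCR)** density estimation for
camera-trap surveys of elusive, wide-ranging carnivores, together with the
classical nonspatial closed-population estimators (M0, Mh) and the
MMDM/HMMDM effective-trapping-area density conversion used to compare the
two approaches. The package was built around the design of the Eurasian
lynx surveys in the French Jura mountains (paired-camera sites on a
checkerboard of 2.7 × 2.7 km cells, five-night capture occasions, multiple
study areas fitted with shared detection parameters) and ships a synthetic
generator for that design, since encounter data for endangered carnivores
are typically not distributable.

## The model

Each individual *i* carries a latent activity center *s<sub>i</sub>*.
Detection at trap *j* during an occasion is Bernoulli with half-normal
probability

> p<sub>ij</sub> = p₀ · exp(−d<sub>ij</sub>² / (2σ²))

where d<sub>ij</sub> is the Euclidean distance from *s<sub>i</sub>* to the
trap (meters), p₀ the detection probability for a trap at the activity
center, and σ the movement scale. Activity centers follow a homogeneous
Poisson point process with intensity *D* over a discrete state-space *S* —
the rectangle buffering the outermost traps by 15 km (≥ 2σ), gridded at
1.5 km. The session likelihood marginalizes each encounter history over the
pixels of *S*:

> −log L = −Σ<sub>i</sub> log Σ<sub>g</sub> D·a·P(y<sub>i</sub> | s<sub>g</sub>) + Σ<sub>g</sub> D·a·p·(s<sub>g</sub>) + log n!

with *a* the pixel area and p·(s) the probability of at least one detection
for a center at *s*. Multi-session surveys share (p₀, σ) within declared
groups while density is estimated per session; abundance is N̂ = D̂·A(S),
and a per-pixel density surface (posterior activity-center membership of
detected individuals plus the expected undetected intensity) sums exactly
to N̂.

For comparison, the nonspatial route drops all spatial information: M0 fits
a common detection probability, Mh uses Chao's lower-bound estimator for
individually varying detection, and abundance is converted to density by
dividing by the effective trapping area — the convex hull of the traps
dilated by the mean maximum distance moved (MMDM) or half of it (HMMDM),
with exact area A + P·w + πw².

## Worked example

Simulate one survey at realistic values (91 checkerboard sites, 13
occasions, p₀ = logit⁻¹(−2.34), σ = e⁸·⁸⁰ ≈ 6.6 km, ~30 individuals in the
buffered state-space), then fit both analyses:

```python
import numpy as np
from scipy.special import expit
from lynxscr import (SessionSet, SCRModel, build_state_space,
                     capture_frequencies, fit_m0, fit_mh_chao,
                     mmdm, effective_trapping_area, nonspatial_density)
from lynxscr.simulate import make_checkerboard_traps, simulate_scr

traps = make_checkerboard_traps(13, 14, n_occasions=13)   # 91 sites
ss = build_state_space(traps)                             # 15 km buffer, 1.5 km pixels
enc, truth = simulate_scr(traps, ss, p0=expit(-2.34), sigma=np.exp(8.80),
                          density=30 / ss.area, seed=1)

fit = SCRModel().fit(SessionSet([(traps, enc)]))
print(fit.summary_)

freq = capture_frequencies(enc)
N0, p_hat, se0, _ = fit_m0(freq)
Nh, seh = fit_mh_chao(freq)
m = mmdm(enc, traps)
eta = effective_trapping_area(traps, m)
print(nonspatial_density(N0, se0, eta))
```

Output (seed 1):

```
simulated N = 30 | detected n = 24
 n_individuals  abundance  abundance_se  density_100km2  density_se  p0_logit  p0_logit_se  log_sigma  log_sigma_se
            24     33.417         6.985           0.804       0.168    -2.302        0.135      8.685         0.057
M0: N = 24.0 (SE 0.9), p = 0.356
Mh (Chao): N = 28.2 (SE 4.9)
MMDM = 13.9 km; ETA(MMDM) = 3,569 km2; ETA(HMMDM) = 2,198 km2
M0 density (MMDM): 0.67 (SE 0.02) per 100 km2
Mh density (HMMDM): 1.28 (SE 0.22) per 100 km2
surface sum = 33.417, pixel max = 0.247
```

The SCR fit recovers the generating truth (N = 30 in a 4,158 km²
state-space is 0.72 per 100 km²; the estimate is 0.80 ± 0.17, with
logit p̂₀ = −2.30 and log σ̂ = 8.69 against truths −2.34 and 8.80). As is
typical, the M0 estimate sits below the SCR estimate — unmodeled spatial
heterogeneity biases it low — and the HMMDM conversion gives a higher
density than the MMDM one because it divides by a smaller area. The density
surface sums to the abundance estimate by construction.

A command-line interface wraps the same pipeline:

```sh
lynxscr simulate --seed 1 --out sim/
lynxscr fit config.yaml          # sessions, sharing groups, estimators
lynxscr report                   # study-wide tallies from a survey table
```

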