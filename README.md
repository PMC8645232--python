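# emlenkit

Circular-statistics toolkit for magnetic-compass orientation experiments
with migratory songbirds: Emlen-funnel data reduction, hypothesis tests on
circular samples, maximum-likelihood orientation-model selection, a
rank-based bootstrap comparison of directedness, and great-circle analysis
of ring recoveries — plus a seeded generator of complete synthetic
experiments so the whole pipeline can be exercised and validated without
field data.

## Who this is for

Behavioural ecologists running Emlen-funnel experiments (nocturnal
migrants tested in scratch-recording funnel cages under different cue
manipulations, e.g. head-mounted magnets vs. sham attachments) and anyone
who needs the standard circular-statistics workflow those studies use.

## What it computes

Each funnel test yields a scratch-mark count and two independent observer
readings of the bird's mean direction. Reduction applies the standard
discard rules — fewer than 35 marks ⇒ inactive; both observers calling the
marks random, one random call, or directional calls more than 30° apart ⇒
not oriented; otherwise the test direction is the circular mean of the two
alignment-corrected calls. Per bird and treatment, oriented tests are
averaged into an individual mean direction; birds directional at least
twice form the treatment's **group sample** of per-bird directions, the
unit of all inference.

On a circular sample θ₁…θₙ the package computes:

- mean direction α and mean resultant length r = |Σe^{iθ}|/n;
- **Rayleigh test** of uniformity, Z = n·r², with the classical series
  approximation for P;
- 95% confidence arcs for α (seeded percentile bootstrap, or the
  dispersion-based normal approximation);
- **Mardia–Watson–Wheeler** two-sample uniform-scores test,
  W ~ χ²(2 df) asymptotically;
- **ten-model ML selection**: every candidate is a constrained
  two-component von Mises mixture
  f(θ) = λ·vM(θ; q₁, κ₁) + (1−λ)·vM(θ; q₂, κ₂), from uniform (M1) through
  unimodal (M2A–C), axial (M3–M4) to general bimodal (M5A–B), compared by
  AICc = −2lnL + 2K + 2K(K+1)/(n−K−1) and Akaike weights;
- the **rank-based bootstrap**: resample a significantly oriented sample
  with replacement 100,000 times, rank the replicate r values, and read
  confidence limits at 1-based ranks 2500/97,500 (95%), 500/99,500 (99%)
  and 50/99,950 (99.9%); a non-oriented sample whose observed r falls
  below the lower limit is less directed at that confidence;
- **ring recoveries**: initial great-circle bearings and haversine
  distances (sphere, R = 6371 km) from ringing to recovery sites,
  filtered to same-year autumn recoveries beyond 250 km, summarized by
  circular mean and Rayleigh test.

## Worked example

```python
from emlenkit import (SimConfig, simulate_experiment, reduce_tests,
                      circ_mean_r, rayleigh_test_angles, select_models,
                      compare_directedness, BootstrapConfig)

ds = simulate_experiment(SimConfig(seed=7))       # 17 birds x 12 nights
outcomes, summaries, groups = reduce_tests(ds.funnel_tests())

for tr, g in groups.items():
    s, ray = circ_mean_r(g.directions), rayleigh_test_angles(g.directions)
    print(f"{tr}: n={s.n} mean={s.mean_direction:.1f} r={s.r:.2f} "
          f"Z={ray.Z:.2f} p={ray.p:.4f}")

sel = select_models(groups["control"].directions, seed=7)
print(sel.table()[["model_id", "K", "lnL", "AICc", "weight"]].head(3))

res = compare_directedness(groups["control"].directions,
                           circ_mean_r(groups["magnet"].directions).r,
                           BootstrapConfig(B=100_000, seed=7))
print(res.bounds[0.95], res.verdict)
```

prints (seed 7):

```
control: n=16 mean=143.7 r=0.72 Z=8.24 p=0.0001
magnet: n=17 mean=210.4 r=0.16 Z=0.43 p=0.6585
sham: n=15 mean=164.1 r=0.73 Z=8.07 p=0.0001
model_id  K        lnL      AICc   weight
     M2A  2 -19.611853 44.146783 0.625671
     M2C  3 -19.611853 47.223706 0.134339
     M4A  3 -19.611853 47.223706 0.134339
(0.5770584..., 0.8693663...) >99.9%
```

Read: of 204 simulated funnel tests, the 16 analyzable control birds are
significantly oriented toward the SE (mean 144°, r = 0.72, Rayleigh
p = 10⁻⁴) and best described by the unimodal model M2A (Akaike weight
0.63); the magnet arm is indistinguishable from uniform (p = 0.66), and
its r of 0.16 lies far below the control sample's bootstrap 95% interval
(0.58, 0.87), so the control birds are more directed with >99.9%
confidence.

The same analyses run from the shell on TSV/CSV inputs:

```bash
emlenkit simulate --seed 7 --out-dir sim      # synthetic tests.tsv + truth
emlenkit all --tests sim/tests.tsv --seed 7 --out-dir out
emlenkit recoveries --recoveries recoveries.csv
```

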