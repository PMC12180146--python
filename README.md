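# escapekin

Escape-response kinematic phenotyping of larval zebrafish from markerless
pose trajectories.

Dystrophin-deficient zebrafish larvae (*sapje*, *sapje-like*) are widely
used models of Duchenne muscular dystrophy, but their most physiologically
relevant phenotype — impaired mobility — is usually measured with coarse,
noisy assays. `escapekin` implements the high-resolution alternative: from
7-keypoint trajectories (TS, S1, S2, T1–T4) tracked at 1000 frames/s on
escaping larvae, it computes tail angular kinematics and center-of-mass
linear kinematics, partitions each escape response into its three
biomechanical stages, and derives a 31-variable biomarker table on which
repeatability, bootstrap effect-size, power, and genotype-classification
analyses run.

## The model

The larva is a chain of six linked body segments (head, swim bladder, and
four tail segments). Tail curvature is the scalar bend summary

```
kappa(t) = sum of the four tail joint angles  (degrees)
```

with each joint angle measured relative to its proximal neighbour (tail1
against the trunk axis S1→S2), so kappa equals the tail-tip orientation
relative to the trunk. Segment angles are LOESS-smoothed (span 0.10);
angular velocity omega(t) is the central finite difference of kappa;
rotation sign is standardized so the first major bend (the C-start) is
positive. Movement onset is the first post-stimulus frame where raw
curvature exceeds the preceding frame by 2% and keeps growing.

Stages follow the curvature sign: onset → first sign change is the
**stage 1 C-start**, → second sign change the **stage 2 power stroke**,
and the rest of the 60 ms analysis window the **stage 3 burst**. A *tail
stroke* is the excursion between successive curvature extremes (two
strokes = one tail beat). Linear kinematics track keypoint S2 as the COM
proxy on unfiltered coordinates — distance (path length), displacement,
speed = d(distance)/dt (LOESS span 0.7 for exit/peak readouts), velocity =
d(displacement)/dt, acceleration = d(velocity)/dt — all normalized to body
length (BL).

Every accepted trial yields exactly 31 variables (4 overall + 27
stage-specific); trials collapse to per-larva means, the unit for all
inference: repeatability coefficients (2.77 × within-subject SD), BCa
bootstrap contrasts (raw and Hedges' *g*, 5000 resamples, 99% CI),
noncentral-*t* power curves, and random-forest / linear-SVM genotype
classification with GINI / weight importance rankings. Five isometric
twitch metrics (peak force, contraction time, half-relaxation time,
maximal rates of tension development and relaxation) feed the same
classification machinery.

A forward simulator (`escapekin.simulate`) renders synthetic escape
responses — latency, C-start, power stroke, decaying burst, 64 µm keypoint
jitter — by inverting the analysis-side body model, with ground-truth
parameters for every trial, so the full pipeline is testable without
video.

## Worked example

```
$ escapekin simulate --preset both --n 8 --trials 3 --seed 17 --out cohort
wrote 48 trials to cohort
$ escapekin features cohort --out features.csv
wrote 48 trials -> features.csv; 16 larvae -> features_larva.csv
$ escapekin classify features_larva.csv --model rf --seed 17 --out clf.json
random_forest: AUROC=1.000 error=0.000
```

Contrasting the wild-type and mutant larvae on overall escape distance:

```python
import pandas as pd
from escapekin import effect_size_report

df = pd.read_csv("features_larva.csv")
ok = df[df.ok]
wt = ok.loc[ok.genotype == "+/+", "overall_distance"]
mut = ok.loc[ok.genotype == "-/-", "overall_distance"]
rep = effect_size_report(wt, mut, "wt vs mut", seed=17)
```

prints

```
overall distance: wt 3.49 BL (n=8), mut 2.56 BL (n=7)
deficit 0.93 BL (99% CI 0.81 to 1.08)
Hedges' g 7.86 (99% CI 5.41 to 12.31)
```

i.e. after 60 ms of escape swimming the simulated dystrophic larvae trail
their wild-type siblings by about one body length — the slowed tail
(lower angular velocity and stroke frequency, near-preserved stroke
amplitude) propagates into less distance, and the contrast is large in SD
units because within-genotype scatter is small.

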