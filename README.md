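# alloego

A physiologically constrained CNN + MLP model of how allocentric
(landmark-centred) and egocentric (eye-centred) visual information are
integrated for goal-directed saccades, together with the synthetic
cue-conflict task generators and the behavioral and neural analysis
suites used to characterise it.

The package is for computational/sensorimotor neuroscientists who want
to simulate the landmark-shift saccade paradigm end to end: generate
trials, train the network on arbitrary allocentric–egocentric
weightings, quantify the landmark influence on the decoded gaze
(allocentric weight), and run the reference-frame analysis of the
motor-layer units (nonparametric response-field fits scored by PRESS,
canonical and intermediate coordinate frames, shuffle test for spatial
tuning).

## The model in brief

Per trial, an *encoding* image (crossing-lines landmark + target square)
and a *decoding* image (landmark only, possibly shifted by **s**) are
rendered in retinal coordinates.  A fixed filter–rectify–filter front-end
(quadrature Gabor energy, divisive normalization, binomial pooling; two
repeated-filtering layers; a trained 16-weight feature pooling) turns
each image into a feature map.  The features plus a gain-modulated
Gaussian eye-position code (44 units) feed a sigmoid MLP whose output
layer is a 250-unit motor population; a fixed optimal-linear-estimator
read-out W = Q⁻¹C decodes the population into the 2-D saccade vector.
Training minimises  L = Σ (x_e − x_d)² + (y_e − y_d)²  between decoded
and true gaze displacement (Adam, lr 10⁻³, batch 32, ≤ 50 epochs,
validation-RMSE early stopping); the decoder weights never change.

Behavioral landmark influence is summarised by the allocentric weight

    AW = ((G − T) · (T′ − T)) / ‖T′ − T‖²,

0 for gaze on the target, 1 for gaze following the shift fully.  Unit
coordinate frames are identified by leave-one-out Gaussian-kernel
regression of activity on candidate positions (target / landmark / gaze,
screen or eye frame, and 30-step T–G and T–T′ continua), selecting the
lowest PRESS over a bandwidth grid.

## Worked example

Train on a noiseless 30%-allocentric scenario at reduced scale and
recover the weighting from the network's own gaze:

```python
import numpy as np
from alloego import (Canvas, GazeNetwork, ScenarioConfig,
                     generate_scenario, allocentric_weight)

cfg = ScenarioConfig(allocentric_weight=0.3, noise="none",
                     n_trials=10_000, seed=1,
                     canvas=Canvas(64, 100.0),
                     split_fractions=(0.8, 0.1, 0.1))
ds = generate_scenario(cfg)

net = GazeNetwork(n_hidden=50, random_state=0).fit(ds)
print("held-out R^2:", round(net.evaluate(ds, "test")["r2"], 3))

idx = ds.indices("test")
gaze = net.predict_gaze(ds, "test")
aw = allocentric_weight(gaze, ds.target[idx], ds.shift[idx])
print("recovered AW median:", round(aw.median, 3))
```

Output (a few minutes on one CPU core):

```
held-out R^2: 0.977
recovered AW median: 0.267
```

The network explains ~98% of the held-out gaze variance, and the median
allocentric weight of its own saccades sits near the 0.3 used to
generate the training data — the network has learned to weight the
landmark shift, not merely to find the target.

A command-line interface covers the same pipeline
(`alloego generate-data / train / evaluate / analyze-behavior /
analyze-units / run / report`); `alloego run -c config.yaml -o outdir`
executes generate → train → evaluate → analyze → report from a single
YAML config and writes HDF5/CSV/JSON artifacts plus a run manifest.

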