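# cbct4d

Simulation study of how gantry speed affects image quality, motion
fidelity and imaging dose in four-dimensional cone-beam CT (4DCBCT), the
respiratory-sorted volumetric imaging used for thoracic image-guided
radiotherapy.

At a fixed detector frame rate `F` (15 fps) and arc `theta` (360 deg), the
gantry speed `omega` sets the projection count of a scan,

    N = F * theta / omega,

so sweeping `omega` from 1 to 6 deg/s sweeps N from 5400 to 900 — and with
it the total mAs, the imaging dose, the noise (CNR), the bar-pattern
resolution (MTF), and the angular sampling available to each respiratory
phase bin. `cbct4d` reproduces this study in silico:

* an analytic Catphan-style QA phantom (bar patterns, a 1.0% low-contrast
  insert, a homogeneous section, density inserts including air) rides a
  platform moving with the breathing waveform
  `A(phi) = A0 (1 - cos 2 pi phi)^2` (3.0 cm excursion, 5 s period);
* a virtual cone-beam scanner (circular trajectory, flat panel,
  SAD 100 / SDD 150 cm) forward-projects the moving phantom at each frame
  and applies mAs-scaled Poisson photon noise;
* projections are retrospectively sorted into 4 or 10 respiratory phase
  bins using only a surrogate marker trace (peak-anchored phase, centered
  bins), then reconstructed per bin and as the all-projection average with
  FDK filtered backprojection;
* the measurement suite evaluates MTF / `f_max` (Gaussian fit, 10%
  crossing), CNR, uniformity index, HU sensitivity against a static
  baseline, air-insert excursion (with percent difference and RMSE against
  the 3.0 cm ground truth), square-root-of-mAs normalizations, and dose
  from a packaged measured rate table (2.30–5.18 x 10^-3 cGy/mAs by tissue
  position).

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Projection bookkeeping and dose for the six protocols:

```python
>>> import cbct4d as c
>>> [c.num_projections(15, 360, w) for w in (1, 2, 3, 4, 5, 6)]
[5400, 2700, 1800, 1350, 1080, 900]
>>> c.acquisition_time(360, 2.0)          # minutes
3.0
>>> proto = c.AcquisitionProtocol(gantry_speed=1.0, mas_per_projection=1.0585)
>>> round(c.total_mas(proto))             # mAs of the slowest scan
5716
>>> round(c.scan_dose(1, c.total_mas(proto)), 1)   # cGy, water position
16.3
```

A full surrogate-driven 10-phase excursion measurement at the fastest
gantry speed (noiseless desk-scale conditions, ~1 minute on one CPU):

```python
>>> from cbct4d.experiment import (excursion_study_config,
...                                measure_protocol_excursion)
>>> res = measure_protocol_excursion(excursion_study_config(seed=5),
...                                  omega=6.0, n_bins=10, seed=5)
>>> round(res.excursion, 4), round(res.percent_difference, 2)
(2.9946, -0.18)
```

The 3.0 cm programmed excursion is recovered to −0.18% from the
reconstructed phase volumes alone — the phantom's motion never enters the
sorting or measurement path, only the surrogate trace does.

The full study (all six gantry speeds, 4- and 10-phase sorting, every
metric, report CSV/JSON and optional figures) runs from the CLI:

```bash
cbct4d sweep --out-dir results/sweep --scale 0.1667 --seed 1 --plots
```

`simulate`, `sort`, `reconstruct` and `metrics` subcommands expose the
individual stages (HDF5 projections, CSV traces/assignments, NIfTI
volumes).

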