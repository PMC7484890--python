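# cinemv

Intrafraction motion monitoring on cine-MV portal images by superimposing
beam's-eye-view contours of planning ROIs.

During external-beam radiotherapy the only imager that is always available,
costs nothing extra and adds no dose is the electronic portal imaging device
(EPID) behind the patient: the treatment beam itself produces a continuous
stream of megavoltage images while the gantry rotates. `cinemv` turns that
stream into a motion-monitoring display for medical physicists and RTTs: it
projects the ROIs of a DICOM RTSTRUCT (targets, fiducial-marker margins)
onto the imager for every gantry angle ahead of time, then, frame by frame,
works out *which* projection belongs to each image and paints the contours
over it. If the imaged anatomy drifts out of its contour, the operator can
interrupt the beam.

## The model

Room coordinates put the linac isocenter at the origin; at gantry angle
θ the source sits at **S**(θ) = (SAD·sin θ, 0, SAD·cos θ) with SAD = 100 cm.
A point **O** projects onto the plane through the isocenter perpendicular to
the beam axis at

    u(θ) = SAD (Ox cos θ − Oz sin θ) / (SAD − Ox sin θ − Oz cos θ)

along the lateral (AB) axis, and analogously along the longitudinal (GT)
axis. The detector (1024 × 1024 pixels, 160 cm from the source, 25.6 cm
field of view at the isocenter, 0.25 mm per native pixel at isocenter scale)
is modelled as an ideal flat panel; projections are computed by casting one
ray per 2 × 2 detector group through a binary voxelization of the ROI on the
planning-CT lattice, at 0.5° steps over the full rotation.

Assigning a gantry angle to a frame is the subtle part. The panel reads its
two lateral halves column by column, outside-in, over one integration time
T = 433 ms, so the readout time of native column c for a frame stamped TS
(readout completion) is

    t(c) = TS − T + α(c)·T/511,  α(c) = c (c ≤ 511),  1023 − c (c ≥ 512)

while the machine reports its gantry angle only at ≈ 4 Hz. The assigned
angle for a ROI is obtained by interpolating the message stream at TS,
reading the precomputed projection centroid for that angle, converting its
column through t(c), and re-interpolating at that readout time. A
gantry-angle error ε displaces a projection by P(θ+ε) − P(θ) — up to 2.5 mm
per degree for objects near the panel edge — which is why this timing
correction matters.

A full synthetic acquisition generator (rolling-shutter ball-bearing
phantom frames, jittered message streams, panel sag, gain structure and
noise, with exported ground truth) makes the whole chain testable at the
desk, including the panel-position calibration that re-centers the beam
axis on the image center, pixel (511.5, 511.5).

## Worked example

```python
import cinemv as cm

# Synthetic planning export: 8-mm ball bearing 10 cm lateral / 5 cm
# longitudinal from the plan isocenter, two clockwise 360-degree arcs.
paths = cm.write_fixture_suite(cm.FixtureSpec.bb_validation(seed=1), "scratch/bb")
ct = cm.read_ct_geometry(paths["ct_dir"])
structures = cm.read_structure_set(paths["rtstruct"], ct)
plan = cm.read_plan(paths["rtplan"])

# Precompute the projected contours (720 angles) and simulate the fast arc.
pset = cm.precompute_set(structures, plan, ct)
cfg = cm.bb_validation_config(speed_deg_s=4.8, seed=7)   # ±50 ms message jitter
res = cm.simulate_arc(cfg)

report = cm.evaluate_accuracy(res.frames, res.messages, pset, "BB")
print(f"AB: mu={report.mu_ab_mm:+.3f} mm sigma={report.sigma_ab_mm:.3f} mm")
print(f"GT: mu={report.mu_gt_mm:+.3f} mm sigma={report.sigma_gt_mm:.3f} mm")
```

prints

```
AB: mu=-0.023 mm sigma=0.242 mm
GT: mu=-0.007 mm sigma=0.070 mm
```

i.e. over a 173-frame arc at 4.8°/s the contour tracks the ball bearing
with a systematic error of a few hundredths of a millimetre and a random
error well below one binned pixel (0.5 mm); the mean of the
polarity-adjusted AB errors would expose any systematic gantry-angle or
timing bias as a nonzero offset.

The same steps are available from the shell:

```bash
cinemv precompute --ct-dir scratch/bb/ct --rtstruct scratch/bb/rtstruct.dcm \
    --rtplan scratch/bb/rtplan.dcm --out scratch/pset.json
cinemv simulate --preset bb-validation --speed 4.8 --seed 7 --out scratch/acq
cinemv validate --frames-dir scratch/acq --messages scratch/acq/messages.csv \
    --projections scratch/pset.json --roi BB
cinemv check-field --rtplan scratch/bb/rtplan.dcm --margin-mm 5
```

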