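# caliper3d

Scale-invariant 3D linear measurements on volumetric medical images, with a
synthetic ultrasound calibration phantom, an automated caliper, and the
statistics used to compare measurement tools across readers.

## The problem

Viewers that render volumetric images inside a transform hierarchy — an
immersive (VR) viewer being the canonical case — let the user freely
translate, rotate and zoom the volume. A clinical linear measurement
(a caliper pair placed on anatomy, e.g. a left-ventricular dimension on 3D
echocardiography) must ride along with the volume, stay editable, and above
all keep reporting the *true anatomical distance in millimetres* no matter
how the volume is posed or zoomed. caliper3d implements that measurement
model headlessly, plus everything needed to evaluate such a tool without
access to readers or scanners: a calibration-phantom simulator with an
automated caliper, a multi-reader session simulator, and the comparison
statistics.

It is aimed at developers of 3D/VR medical-image viewers and at researchers
who need a reference implementation of scene-graph measurement semantics and
of observer-study evaluation machinery.

## The model

A measurement is a small subtree parented under the volume node, so it
tracks the volume's pose. Its endpoints may be temporarily re-parented to a
controller while being edited (grab/release), which makes volume-local
coordinates unreliable; the distance is therefore computed in world space
and corrected by the volume's accumulated zoom. With world positions
$w_s, w_e$ of the endpoints, reference-scale factor $S$ (the product of
uniform scales from the scene root down to the volume node) and $k$ mm per
world unit (default 1000, i.e. anatomy at metre scale):

$$d_\text{mm} = \frac{k \, \lVert w_e - w_s \rVert}{S}$$

This is invariant to any rigid motion and to any uniform zoom of the
volume, and remains correct mid-edit. Marker and label meshes are scaled by
$1/S$ so they keep constant on-screen size under zoom.

The phantom module renders cylindrical low-scatter inserts (4, 6, 10 mm
diameter by default) in a speckled background and measures them with a
full-width-at-half-contrast caliper: the intensity profile through the
insert centre is sampled, and each edge is the interpolated crossing of the
midpoint between the insert and background plateaus.

The evaluation module provides per-insert accuracy/precision summaries
(mean, sample SD, error versus truth, best-per-row flags), agreement of a
tool against a reference (mean ± SD of paired differences, count within a
2 mm threshold, OLS regression), two-sided paired t-tests
($t = \bar d / (s_d/\sqrt n)$, $\mathrm{df} = n-1$), and intra-user
variability (per user and tool, the SD of deviations from the
per-measurement cross-tool mean).

## Worked example

```python
import numpy as np
from caliper3d import (SceneNode, attach_volume, create_measurement,
                       set_uniform_scale, default_phantom_spec,
                       generate_phantom, caliper_table, build_session_plan,
                       default_truths, default_tool_models, simulate_observer,
                       paired_ttest_records, agreement)

# a noise-free calibration phantom, 0.2 mm voxels
spec = default_phantom_spec(spacing_mm=0.2, speckle=False)
image = generate_phantom(spec)

# measure the 10 mm insert by hand: 43 mm -> 53 mm through its centre
root = SceneNode("root")
vol = attach_volume(root, image)             # volume becomes the reference scale
m = create_measurement(vol, vol.mm_to_world((43.0, 12.0, 10.0)),
                       vol.mm_to_world((53.0, 12.0, 10.0)), id="cyst-10H")
print(m.refresh_label())                     # -> 10.0 mm
set_uniform_scale(vol, 2.5)                  # zoom the volume 2.5x
print(m.refresh_label())                     # -> 10.0 mm  (unchanged)

# automated caliper on all inserts
print(caliper_table(image, spec).round(3).to_string(index=False))

# simulate a 5-reader study and compare tools against the reference
plan = build_session_plan()                  # 26 tasks per reader
records = simulate_observer(plan, default_truths(plan),
                            default_tool_models(), seed=1, n_invalid=5)
for tool in ("Tomtec", "VR"):
    t = paired_ttest_records(records, tool, "QLAB")
    a = agreement(records, tool, "QLAB")
    print(f"{tool}: t({t.df}) = {t.t:+.3f}, p = {t.p:.3f}; "
          f"mean diff = {a.mean_diff_mm:+.2f} +/- {a.sd_diff_mm:.2f} mm")
```

Output:

```
10.0 mm
10.0 mm
 true_diameter_mm axis  measured_mm  error_mm
              4.0    H        3.980    -0.020
              4.0    V        3.980    -0.020
              6.0    H        5.996    -0.004
              6.0    V        5.996    -0.004
             10.0    H       10.000    -0.000
             10.0    V       10.000    -0.000
Tomtec: t(125) = -23.188, p = 0.000; mean diff = -1.56 +/- 0.75 mm
VR: t(125) = +4.348, p = 0.000; mean diff = +0.45 +/- 1.16 mm
```

The caliper recovers every insert diameter to well under one voxel; the
simulated screen-based 3D tool (Tomtec model, built-in −1.57 mm bias and
1 mm display precision) shows a significant negative offset against the
MPR reference, while the immersive-tool model sits slightly high with more
spread — the qualitative pattern such tool comparisons report.

The same operations are scriptable from a shell via the `caliper3d` CLI
(`phantom`, `measure`, `caliper`, `plan`, `simulate`, `evaluate`).

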