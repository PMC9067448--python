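"""Register the 3-D arterial model to a camera view and score the overlay.

Simulates the AR workflow: a phantom head provides the 3-D model (68
landmarks + artery centerlines), a pinhole camera renders the tracked 2-D
landmarks (with 1 px tracking noise), the camera pose is recovered by
Gauss-Newton reprojection minimization, the arteries are projected into
the view, and the projection is scored in millimetres against the exact
(noise-free) artery positions.
"""

import numpy as np

import arterymap as am
from arterymap.synthetic import (
    PhantomSpec,
    VesselSpec,
    default_vessel_paths,
    generate_phantom,
    make_default_camera,
    render_view,
)

center, axes = (30.0, 30.0, 30.0), (24.0, 26.0, 28.0)
spec = PhantomSpec(
    shape=(8, 8, 8), spacing=(10.0, 10.0, 10.0),  # geometry only, no raster needed
    head_center_mm=center, head_semiaxes_mm=axes,
    vessels=default_vessel_paths(center, axes),
)
_, truth = generate_phantom(spec)
camera = make_default_camera(truth, distance_mm=250.0)

view_landmarks, exact_curves = render_view(
    truth, camera, landmark_noise_px=1.0, seed=7
)
model_curves = [
    am.CenterlinePolyline(points=v.path_mm, label=str(v.label))
    for v in truth.vessels
]
reg = am.register_model_to_view(
    truth.landmarks3d, view_landmarks, camera, model_curves
)
print(f"mean landmark reprojection error: "
      f"{reg['mean_reprojection_error_px']:.2f} px (1 px tracking noise)")

# score each artery: distance from exact projected curve to the overlay,
# converted to mm at the face distance (Z / fx mm per pixel)
pixel_to_mm = 250.0 / camera.fx
marks = [(label, curve[len(curve) // 2]) for label, curve in exact_curves]
records = am.evaluate_projection_accuracy(
    reg["projected_curves"], marks, pixel_to_mm=pixel_to_mm
)
summary = am.group_statistics(records)
devs = [r.deviation_mm for r in records if r.visualized]
print(f"scored {len(devs)} arteries; mean overlay deviation "
      f"{np.mean(devs):.3f} mm, max {np.max(devs):.3f} mm")
# Sub-millimetre deviations mean the projected artery map lands on the
# true artery positions despite the noisy landmark tracking.
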