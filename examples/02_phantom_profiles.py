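"""Laminar depth profiles from a voxel-level cortical phantom.

Builds a cortical slab with a known depth-dependent T1 profile, renders
the MP2RAGEME images with noise, estimates the quantitative maps, computes
the distance-ratio cortical depth field, and extracts the 10-depth lOFC
profile with its three scalar metrics.  The extracted profile tracks the
built-in monotone T1 increase from the WM/GM boundary toward CSF; the AUC
is ~10x the mean, and the offset (depth-0 value) sits below the mean.
"""

import numpy as np

from laminarq import (
    AcquisitionParams,
    build_t1_lookup,
    compute_depth_field,
    compute_metrics,
    estimate_t1_map,
    extract_depth_profile,
    make_cortical_phantom,
    refine_roi_mask,
    render_subject_images,
)
from laminarq.phantom import GM

truth = make_cortical_phantom(grid_shape=(64, 64, 32))  # WM | GM | CSF slab
gm = truth.labels == GM
print(f"phantom: {truth.labels.shape} voxels at {truth.voxel_size} mm, "
      f"{gm.sum()} GM voxels")

params = AcquisitionParams()
images = render_subject_images(truth, params, noise_sd=0.01, seed=7)
t1_map = estimate_t1_map(images["uni"], build_t1_lookup(params))
err = t1_map.values[gm] - truth.t1_truth[gm]
print(f"T1 map vs truth in GM: RMSE = {np.sqrt(np.nanmean(err**2)):.1f} ms")

depth = compute_depth_field(truth.labels, truth.voxel_size)
mask = refine_roi_mask(truth.roi_mask("lOFC", "left"), gm, dilation_voxels=2)
profile = extract_depth_profile(
    t1_map, mask, depth, subject_id="sub-001", roi="lOFC", hemisphere="left"
)
print("depth bin centers:", np.round(profile.depths, 2))
print("T1 profile (ms):  ", np.round(profile.values, 1))
print("voxels per bin:   ", profile.n_voxels)

m = compute_metrics(profile)
print(f"mean = {m.mean_value:.2f} ms, AUC = {m.auc:.2f}, "
      f"offset = {m.offset:.2f} ms, AUC/mean = {m.auc / m.mean_value:.3f}")
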