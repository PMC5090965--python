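"""Voxelwise association of BPnd with a behavioral score.

Twenty synthetic BPnd maps (10 subjects x pre/post) get a planted negative
association in a 'caudate' block: scans with worse behavioral scores have
lower BPnd there.  After 2-mm Gaussian smoothing, a per-voxel GLM with the
global mean as covariate should localize a negative-t cluster inside the
planted block, and the residualized scatter at the peak voxel reproduces the
GLM t exactly.
"""

import numpy as np

from petlearn.voxelstats import (
    GlmDesign,
    fit_voxel_glm,
    gaussian_smooth,
    residualized_scatter,
    scatter_t,
    threshold_and_cluster,
)

rng = np.random.default_rng(7)
shape = (12, 12, 8)
caudate = np.zeros(shape, bool)
caudate[3:6, 4:8, 2:6] = True
striatum = np.zeros(shape, bool)
striatum[2:10, 3:9, 1:7] = True

score = rng.normal(0.0, 1.0, 20)            # e.g. errors to criterion, z-scored
imgs = []
for s in score:
    img = rng.normal(1.5, 0.15, shape)
    img[caudate] -= 0.25 * s                # worse score -> lower BPnd
    imgs.append(gaussian_smooth(img, fwhm_mm=2.0, voxel_size_mm=0.5))

res = fit_voxel_glm(imgs, GlmDesign(score=score), striatum)
print(f"GLM df = {res.df} (20 scans, 3 design columns)")

clusters = threshold_and_cluster(res, p_thresh=0.05, sign="negative")
print("\nNegative clusters at voxelwise p < 0.05 (uncorrected):")
print(clusters.to_string(index=False))

peak = clusters.iloc[0]
ijk = (int(peak.peak_i), int(peak.peak_j), int(peak.peak_k))
vox = np.array([img[ijk] for img in imgs])
pairs = residualized_scatter(vox, res.design_matrix, res.score_column)
print(f"\nPeak voxel {ijk}: t = {res.t_map[ijk]:.3f}; "
      f"t recomputed from the residualized scatter = {scatter_t(pairs, res.df):.3f}")
print(f"Peak inside planted caudate block: {bool(caudate[ijk])}")

print("\nA negative peak t inside the planted block mirrors the knockdown"
      " finding: lower receptor binding where behavior is worse.")
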