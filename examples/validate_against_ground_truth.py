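"""Validate automatic segmentation against the phantom's exact ground truth.

Treats the generator's ground truth as the reference reading and
computes the agreement measures used to validate automatic OCT
segmentation: per-A-scan contour distances, strut detection confusion
counts with similarity indexes, total/radial strut distances, and a
Bland–Altman comparison of lumen areas.
"""

import numpy as np

from octstent import (
    ConfusionCounts,
    PhantomSpec,
    bland_altman,
    circular_profile,
    generate_stack,
    match_struts,
    percentiles,
    segment_stack,
    similarity_indexes,
    strut_specificity,
)
from octstent.phantom import helical_stent_layout

n_frames = 30
spec = PhantomSpec(
    n_frames=n_frames,
    image_size=512,
    lumen_radius_profile=circular_profile(1200.0),
    strut_layout=helical_stent_layout(n_frames, struts_per_frame=10, twist_deg_per_frame=3.0),
    noise_sigma=8.0,
    seed=21,
)
stack, truth = generate_stack(spec)
result = segment_stack(stack, overlay_mask=truth.overlay_mask)

# contour agreement, per A-scan (same θ bin), in μm
dist = np.abs(
    np.stack([c.radius for c in result.contours]) - truth.lumen_radius
).ravel()
p25, p50, p75 = percentiles(dist)
print(f"contour distance percentiles : {p25:.1f} / {p50:.1f} / {p75:.1f} μm")

# strut agreement: nearest-neighbour matching per frame
tp = fp = fn = 0
totals, radials = [], []
for f in range(n_frames):
    m = match_struts(result.struts_on_frame(f), truth.struts_on_frame(f), 150.0)
    tp += m.counts.TP
    fp += m.counts.FP
    fn += m.counts.FN
    totals.extend(m.total_distances)
    radials.extend(m.radial_distances)
sim = similarity_indexes(ConfusionCounts(TP=tp, FP=fp, FN=fn))
print(f"strut sensitivity / Jaccard  : {sim.sensitivity:.1f}% / {sim.jaccard:.1f}%")
print(f"strut specificity            : {strut_specificity(fp, tp + fn):.1f}%")
print(f"strut total distance (median): {np.median(totals):.1f} μm "
      f"(radial {np.median(radials):.1f} μm)")

# lumen-area agreement, percentage differences
true_areas = np.array(
    [np.pi * (truth.lumen_radius[f] / 1000.0).mean() ** 2 for f in range(n_frames)]
)
ba = bland_altman(np.column_stack([result.lumen_areas, true_areas]), percent=True)
print(f"lumen area Bland–Altman      : bias {ba.mean_difference:+.2f}%, "
      f"LoA [{ba.lower_loa:+.2f}%, {ba.upper_loa:+.2f}%]")
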