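"""Segment AgNOR dots from a rendered field and compute the per-image record.

The segmentation rule is explicit: darkness threshold on mean RGB, green
chromogen exclusion, then a minimum-size filter.  Each surviving dot gets
an area, a diameters-ratio roundness, and a silhouette fractal dimension;
dots failing the value filter (zero area, degenerate roundness, FD = 1)
are excluded before any averaging.
"""

from agnorfract import SyntheticSpec, generate_image, measure_image

image, truth = generate_image(SyntheticSpec(seed=7, noise_sd=0.0, fixed_dot_count=True, stromal_dots_mean=0.0))
meas, objects = measure_image(
    image, nucleus_mask=truth.nucleus_mask, epithelium_mask=truth.epithelium_mask
)

print(f"rendered dots        : {len(truth.object_table)}")
print(f"segmented components : {meas.raw_dot_count}")
print(f"after value filter   : {meas.dot_count}")
print(f"mean dots / nucleus  : {meas.mean_dots_per_nucleus:.2f}")
print(f"density              : {meas.density:.0f} dots/mm^2")
print(f"total normalized area: {meas.total_normalized_area:.0f} ppm of image area")
print(f"mean roundness       : {meas.mean_roundness:.3f}  (major/minor axis, 1 = circle)")
print(f"mean silhouette FD   : {meas.mean_object_fd:.3f}  (smooth boundary ~ 1)")
print(f"skeleton-map FD      : {meas.skeleton_fd:.3f}  (spatial repartition of dots)")
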