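"""Box-counting calibration on shapes whose dimension is known in closed form.

A straight line is one-dimensional, a filled square two-dimensional, and
the Sierpinski triangle has dimension log3/log2 ~ 1.585.  The estimator
should land on each within a few hundredths; that is the evidence that
the slopes it later reports for AgNOR silhouettes mean what they claim.
"""

import numpy as np

from agnorfract import box_count_fd, make_reference_shape

line = make_reference_shape("line", length=512)
square = make_reference_shape("filled_square", side=512)
# order-7 triangle rasterized at 4 px per cell: fit above the cell cutoff
sierpinski = make_reference_shape("sierpinski", order=7, side=512)

print(f"line            fd = {box_count_fd(line).fd:.3f}   (expected 1.000)")
print(f"filled square   fd = {box_count_fd(square).fd:.3f}   (expected 2.000)")
res = box_count_fd(sierpinski, sizes=[4, 8, 16, 32, 64, 128])
print(f"sierpinski      fd = {res.fd:.3f}   (expected {np.log(3)/np.log(2):.3f})")
print(f"fit quality r^2 = {res.r_squared:.4f} over {res.n_scales} box sizes")
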