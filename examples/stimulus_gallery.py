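"""Build the retinotopic mapping stimuli and report their geometry.

Constructs the shared visual-field grid, a full 168-volume wedge scan
design with blanks, and single chequerboard / random-dot stereogram
frames, then prints the quantities that define them.
"""

import numpy as np

from stereoprf import chequerboard_frame, make_grid, rds_frame, scan_design

grid = make_grid(half_extent=10.0, pixels_per_degree=10)
print(f"grid: {grid.shape[0]}x{grid.shape[1]} pixels, centre pixel at (0, 0) deg")

design = scan_design("disparity", "wedge-ccw", grid)
print(f"wedge run: {len(design)} volumes at TR {design.frame_interval} s "
      f"({design.duration:.1f} s), {design.n_blank} blank volumes")

ecc = grid.eccentricity()
print(f"fixation cut-out honoured: {not design.masks[:, ecc < 0.5].any()}")

chq = chequerboard_frame(grid)
print(f"chequerboard mean luminance {chq.left.mean():+.4f} (mid-grey = 0)")

rng = np.random.default_rng(0)
frame = rds_frame(grid, design.masks[0], "correlated", disparity=0.2, rng=rng)
cover = (frame.left != 0).mean()
print(f"RDS frame: {len(frame.dots.positions)} dots, pixel coverage {cover:.2f} "
      "(target 0.40), right eye offset +0.2 deg inside the wedge")
# a correlated frame at zero disparity is binocularly identical; at 0.2 deg
# the aperture content is shifted half a disparity in each eye
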