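"""Shape of the column at the onset of self-weight buckling.

The first buckling mode y/y_max runs from 1 at the free end (tree top,
u = 0) to 0 at the ground (u = 1) and is remarkably insensitive to how the
weight is distributed.
"""

import numpy as np

from selfbuckle import cumulative_weight_shape, make_density_model, mode_shape

grid = np.linspace(0, 1, 6)
print("u = x/l_c:      " + "  ".join(f"{u:5.1f}" for u in grid))
for mid, n, wr in [("C", -1.0, None), ("C", 1.0, None), ("F", 0.5, 0.3)]:
    shape = cumulative_weight_shape(make_density_model(mid, n, wr))
    mode = mode_shape(shape, u_grid=grid)
    tag = f"{mid} n={n:+.1f}" + (f" W_R={wr}" if wr else "")
    print(f"{tag:15s} " + "  ".join(f"{y:5.3f}" for y in mode.deflection_ratio))

# All rows nearly coincide: like the first Euler mode of a long column,
# deflection grows monotonically from the clamped base to the free tip
# regardless of the density profile.
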