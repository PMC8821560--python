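"""Critical-height ratio f(n) for the four density models.

f(n) = xi_c(n) / (4C)^(1/3) compares a variable-density column with the
uniform one; it depends only on the distribution parameter n, not on the
material or radius.
"""

import numpy as np

from selfbuckle import height_ratio, ratio_extremes

for mid, (lo, hi) in [("A", (0, 3)), ("B", (0, 3)), ("C", (-1, 1)), ("D", (-1, 1))]:
    f_min, f_max = ratio_extremes(mid, (lo, hi), grid_steps=(31, 1))
    print(f"model {mid}: f ranges {f_min:.3f} .. {f_max:.3f} over n in [{lo}, {hi}]")

print()
print("model C curve (same total weight, linearly redistributed):")
for n in np.linspace(-1, 1, 5):
    print(f"  n = {n:+.1f}  f = {height_ratio('C', n):.4f}")

# f > 1 whenever weight sits low (n > 0 for C/D, n < 1 for A), i.e. a
# bottom-heavy column of the same total weight stands taller before buckling.
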