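"""Apply the three complexity-reduction transforms and compare variants.

A -> B homogenizes patch shapes (removes corridor-like margins),
B -> C interchanges types among same-size-class patches (scrambles
arrangement, keeps composition), C -> D interchanges types regardless of
size (changes composition).  The printed metrics show what each step
conserves: cover is stable through C and shifts at D, while same-type
separation (fragmentation) rises once arrangement is randomized.
"""

import numpy as np

import mosaicpop as mp

A = mp.generate_landscape(extent_cells=(120, 120), n_patches=300, seed=42,
                          field_margins=True)
variants = mp.make_variants(A, seed=7)

print("relative cover per habitat type (fractions of all cells):")
cov = {k: mp.relative_cover(v) for k, v in variants.items()}
print(f"{'type':18s}" + "".join(f"{k:>8s}" for k in "ABCD"))
for t in mp.HABITAT_TYPES:
    print(f"{t:18s}" + "".join(f"{cov[k].get(t, 0):8.3f}" for k in "ABCD"))

print("\nmedian same-type nearest-neighbour separation (cells):")
for k in "ABCD":
    sep = mp.same_type_separation(variants[k])
    vals = [v for t, v in sep.items() if t in mp.HABITAT_TYPES and np.isfinite(v)]
    print(f"  {k}: {np.median(vals):5.2f}")

d = (variants["B"].patches["area_cells"] - A.patches["area_cells"]).abs()
print(f"\nshape homogenization conserved areas exactly for {(d == 0).mean():.1%} "
      f"of patches (total drift {d.sum()} of {A.grid.size} cells); "
      "barrier cells are untouched in every variant.")
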