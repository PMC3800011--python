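"""Laplacian-streamline thickness on phantoms with analytic ground truth.

Builds three labelled volumes, solves Laplace's equation on the gray domain
and traces gradient streamlines: a 5 mm slab (truth 5 mm), an 8-12 mm
spherical shell (truth 4 mm), and two abutting 4 mm gyral banks that fuse
into one 8 mm domain unless the touching interface is labelled as an
enforced-separation wall.
"""

import numpy as np

from corthick.laplace import make_phantom, solve_laplace, streamline_thickness

for name, kwargs, truth in [
    ("slab (t=5 voxels, 1 mm)", dict(kind="slab", thickness_voxels=5), 5.0),
    ("spherical shell R1=8, R2=12 mm", dict(kind="spherical_shell",
                                            r1_mm=8, r2_mm=12), 4.0),
]:
    vol = make_phantom(**kwargs)
    field = solve_laplace(vol)
    thick = streamline_thickness(field)
    ok = thick.ok_values()
    print(f"{name}: median {np.median(ok):.3f} mm (truth {truth} mm), "
          f"{ok.size} gray voxels, solver {field.iterations} sweeps")

for sep in (False, True):
    vol = make_phantom("abutting_gyri", thickness_voxels=4,
                       cross_section=(12, 12), separation=sep)
    thick = streamline_thickness(solve_laplace(vol))
    label = "with separation wall" if sep else "without separation"
    print(f"abutting 4 mm banks {label}: median "
          f"{np.median(thick.ok_values()):.2f} mm")

print()
print("Without the wall the two banks merge and thickness doubles (8 mm);")
print("the enforced-separation label restores the true 4 mm for the bank")
print("with a white-matter boundary and excludes the other as 'boundary'.")
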