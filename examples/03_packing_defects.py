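"""Scan a constructed interface patch for lipid packing defects.

A 0.5×0.5 nm window of the upper leaflet is stripped of headgroup coverage,
exposing an aliphatic bead 0.15 nm below the surrounding glycerol level —
a deep packing defect of known position and area.
"""

import memflex as mx
from memflex.packing_defects import count_defects

topo, frame, ref, truth = mx.make_defect_patch(window=(1.0, 1.5, 1.0, 1.5),
                                               depth=0.15)
planted_area = truth.defects["area"]
grids = mx.scan_defects(frame, topo, ref, grid_spacing=0.1)
for leaflet, grid in grids.items():
    for cls, (n, area) in count_defects(grid).items():
        print(f"{leaflet}: {n} {cls} defect(s), total area {area:.2f} nm²")
print(f"planted: 1 deep defect of ~{planted_area:.2f} nm² in the upper leaflet")
# A defect cell is a grid point whose first solvent-side contact is an
# aliphatic atom; shallow means < 1 Å below the nearest glycerol, deep > 1 Å.
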