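"""Derive the planning structure set from a GTV and a critical OAR.

Builds a 15 mm spherical tumor with a GI organ abutting it, derives the
PTV (GTV + 5 mm), OAR_5mm (OAR + 5 mm) and the optimization target
PTV_OPT = PTV minus OAR_5mm, then samples the signed distance map that
drives the dose prediction features.
"""

import numpy as np

from kbdose import VoxelGrid, derive_structure_set, signed_distance_map, sphere_mask

grid = VoxelGrid((40, 40, 40), spacing=(2.0, 2.0, 2.0))
gtv = sphere_mask(grid, center_mm=(30, 40, 40), radius_mm=15)
oar = sphere_mask(grid, center_mm=(58, 40, 40), radius_mm=12)

structs = derive_structure_set(gtv, oar, margin=5.0)
for name in ("gtv", "ptv", "oar_crit", "oar_5mm", "ptv_opt"):
    print(f"{name:9s} volume = {getattr(structs, name).volume_cc:7.2f} cc")

# When the OAR sits close, OAR_5mm eats into the PTV: PTV_OPT < PTV, and
# some GTV voxels fall outside the optimization target (underdosed region).
outside = np.count_nonzero(structs.gtv.voxels & ~structs.ptv_opt.voxels)
print(f"GTV voxels outside PTV_OPT: {outside} of {structs.gtv.n_voxels}")

# Signed distance to OAR_5mm: negative = overlap, the key dose predictor.
sd = signed_distance_map(structs.oar_5mm)[structs.gtv.voxels]
print(f"GTV-to-OAR_5mm distance range: {sd.min():.1f} .. {sd.max():.1f} mm")
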