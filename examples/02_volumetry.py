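"""Hemispheric lesion volumetry with and without edema correction.

Space-occupying vasogenic edema inflates the ipsilateral hemisphere, so the
raw lesion/hemisphere ratio (%HLVuc) overstates the infarct. The corrected
form (%HLVec) subtracts the hemispheric swelling HVi - HVc before
normalizing to the unswollen (contralateral) hemisphere.
"""

from strokevol import (
    PhantomSpec,
    generate_phantom,
    landmarks_from_masks,
    percent_hlv_edema_corrected,
    percent_hlv_uncorrected,
    volumetry_for_animal,
)

# direct formula use on round numbers: 140 mm^3 lesion, 8% swelling
lv, hv_c, hv_i = 140.0, 500.0, 540.0
print(f"%HLVuc = {percent_hlv_uncorrected(lv, hv_c, hv_i):.2f} %")
print(f"%HLVec = {percent_hlv_edema_corrected(lv, hv_c, hv_i):.2f} %")
print("the corrected value is lower: 40 mm^3 of the apparent lesion is swelling\n")

# the same numbers from a voxelized phantom mask
spec = PhantomSpec(matrix=64, lesion_fraction=0.30, swelling_factor=0.08,
                   noise_model="none")
_, truth = generate_phantom(spec)
landmarks = landmarks_from_masks(truth.masks, spec.geometry)
vol, mls = volumetry_for_animal(truth.masks, spec.geometry, landmarks)
print(f"phantom: HVc={vol.hv_c:.1f}  HVi={vol.hv_i:.1f}  LV={vol.lv:.1f}  (mm^3)")
print(f"phantom: %HLVuc={vol.pct_hlv_uc:.2f}  %HLVec={vol.pct_hlv_ec:.2f}  "
      f"swelling={vol.swelling_mm3:.1f} mm^3")
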