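"""Bone mineralization density distribution (BMDD) from a qBSE image.

Generates a backscattered-electron image with carbon/aluminium calibration
patches, converts gray levels to calcium weight percent with the two-anchor
affine calibration, cuts three 50 x 50 um regions of interest and computes
Ca_mean and the BMDD full width at half maximum per ROI.
"""

import numpy as np

from osteoquant import qbse, synth

region = synth.QBSE_REGIONS["halo"]  # low-mineralized tissue near cavities
img = synth.gen_qbse_image(
    region.camean, region.sd, noise=synth.NoiseModel(detector_sd=200.0, seed=11)
)
ca_map, clip_fraction = qbse.calibrate(img.image, img.calibration)
rois = qbse.extract_rois(ca_map, img.roi_centers, img.pixel_size_um)

print(f"halo-region image, {img.image.shape[0]}x{img.image.shape[1]} px at "
      f"{img.pixel_size_um} um/px, clip fraction {clip_fraction:.4f}")
for i, roi in enumerate(rois):
    hist = qbse.bmdd(roi)
    print(f"  ROI {i}: Ca_mean = {hist.ca_mean:.2f} wt%   FWHM = {hist.fwhm:.2f} wt%")
print(f"  truth: Ca_mean = {region.camean}, FWHM = {region.fwhm}")
print()
print("Ca_mean is the average degree of mineralization; the FWHM measures")
print("its local heterogeneity - wider distributions mean more heterogeneous")
print("tissue, as found around resorption cavities in steroid-exposed bone.")
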