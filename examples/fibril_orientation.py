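"""Fibrillar orientation and load-induced reorientation.

Tracks the azimuthal spread (FWHM) of the third-order collagen reflection
across a loading sequence: the total azimuthal profile at the peak is
corrected by the mineral background estimated from two flanking q bands, and
the remaining collagen profile is fitted to a Gaussian without a baseline.
"""

from osteoquant import pipeline, synth

for preset in (synth.WT, synth.CRH):
    res = pipeline.analyze_orientation_sample(preset, seed=7)
    print(f"{preset.label}:")
    print(f"  unloaded orientation FWHM: {res['fwhm0']:.1f} deg"
          f"  (truth {preset.orientation_fwhm0})")
    print(f"  reorientation rate: {res['rate']:.1f} % FWHM change per % strain"
          f"  (truth {preset.reorientation_rate})")
    print(f"  regression r^2: {res['r_squared']:.3f}")

print()
print("Loading aligns fibrils toward the tensile axis, so the FWHM percent")
print("change is negative. The steroid-osteoporotic preset starts less")
print("oriented (larger FWHM) and reorients more slowly than wild type.")
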