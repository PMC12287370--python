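"""The flow-cytometry MFI transforms applied before plotting.

Noise-corrects raw median fluorescence intensities with the isotype
control, then shows the two presentation scales: absolute (log10) and
relative to the DMSO vehicle control (set to zero).
"""

import screenscore as ss

records = [
    ss.MFIRecord("Bcl-2", raw_mfi=5200.0, isotype_mfi=200.0, dmso_reference_mfi=4200.0),
    ss.MFIRecord("Bim", raw_mfi=1500.0, isotype_mfi=300.0, dmso_reference_mfi=700.0),
    ss.MFIRecord("Mcl-1", raw_mfi=450.0, isotype_mfi=400.0, dmso_reference_mfi=20.0),
]

print("marker   corrected   log10   vs DMSO")
for rec in records:
    corrected = ss.noise_correct(rec.raw_mfi, rec.isotype_mfi)
    dmso = ss.noise_correct(rec.dmso_reference_mfi + rec.isotype_mfi, rec.isotype_mfi)
    print(
        f"{rec.marker:8s} {corrected:9.0f} {ss.log10_mfi(corrected):7.2f} "
        f"{ss.relative_to_dmso(corrected, dmso):9.0f}"
    )
print(
    "\n'vs DMSO' is a plain difference of corrected MFIs, so the vehicle"
    "\ncontrol maps to exactly zero and decreases show as negative values."
)
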