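"""Uptake arithmetic on published per-sample measurements: stain-density
enhancement factors, gold-mass ratio tables and organ biodistribution.
"""

from sfhi import (
    biodistribution_summary, enhancement_factor, ratio_table, report_factor,
)

# Integrated optical density (a.u.) of immunofluorescence staining:
# targeted conjugate on tumor cells vs antibody and cell-line controls.
f10 = enhancement_factor(532.0, [38.0, 61.0])
f50 = enhancement_factor(1460.0, [192.0, 46.0])
print(f"10 nm conjugate stain enhancement: {f10:.2f} (reported {report_factor(f10)})")
print(f"50 nm conjugate stain enhancement: {f50:.2f} (reported {report_factor(f50)})")

# Tumor gold concentrations (ug/cm^3), targeted vs untargeted particles,
# with the matching liver concentration of each animal as a paired compartment.
t = ratio_table(
    {"Au-PEG tumor": 18.0, "FB50 tumor 1": 26.0, "FB50 tumor 2": 24.0},
    "Au-PEG tumor",
    sds={"Au-PEG tumor": 7.0, "FB50 tumor 1": 3.3, "FB50 tumor 2": 1.0},
    paired_compartment={"Au-PEG tumor": 25.0, "FB50 tumor 1": 23.0,
                        "FB50 tumor 2": 23.0},
)
print("tumor-to-reference ratios:", t.display())
print("tumor-to-own-liver ratios:", t.display_cross())

# Organ gold masses (pg) across the two injected animals.
bio = biodistribution_summary({
    "liver": [115.0, 38.0], "spleen": [30.0, 13.0],
    "kidneys": [3.0, 3.0], "lungs": [1.0, 0.0],
})
print("organ means:", bio["means"])
print("liver-to-organ factors (rounded):", bio["factors_rounded"])
print("-> targeted particles deliver ~1.3-1.45x more gold to tumors; the liver")
print("   dominates uptake, holding ~4x the spleen's gold mass.")
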