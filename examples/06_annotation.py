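"""Precursor-mass annotation of differential features.

Matches feature m/z values against a user-supplied reference compound list
at 20 ppm (precursor-only evidence; taxonomy fields pass through).
"""

import pandas as pd

from metabopanel import ReferenceCompound, annotate_table, mass_delta_ppm

references = [
    ReferenceCompound("PS(46:1)", 477.3466, super_class="Lipids and lipid-like molecules",
                      compound_class="Glycerophospholipids"),
    ReferenceCompound("Coniferyl alcohol", 181.0848, super_class="Benzenoids",
                      compound_class="Phenols"),
    ReferenceCompound("Indoleacrylic acid", 171.0632, super_class="Organoheterocyclic compounds",
                      compound_class="Indoles and derivatives"),
]

features = pd.DataFrame({
    "label": ["5.7625_477.3462", "5.2862_181.0855", "5.4391_171.0637", "9.1000_800.5000"],
    "rt": [5.7625, 5.2862, 5.4391, 9.1],
    "mz": [477.3462, 181.0855, 171.0637, 800.5],
})

annotated = annotate_table(features, references, tolerance_ppm=20.0)
print(annotated[["label", "annotation", "delta_ppm", "super_class", "evidence"]]
      .to_string(index=False))
print()
print(f"example delta: {mass_delta_ppm(181.0855, 181.0848):+.2f} ppm")
# delta_ppm is the signed mass accuracy (observed - theoretical); matches are
# precursor-only — no MS2 fragment evidence is modelled, so candidates are
# putative identifications, not confirmations.
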