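"""Generate a synthetic ovarian-tumour metabolomics study.

Builds a discovery + validation cohort pair sharing one feature model
(~1300 LC-MS features, four clinical groups, pooled QCs, a CA125-like
marker) and prints what was generated.
"""

from metabopanel import CohortSpec, generate_study

spec = CohortSpec(seed=1)
study = generate_study(spec)

table, meta, truth = study.table, study.meta, study.truth
print(f"features: {table.n_features}, samples: {table.n_samples} "
      f"(QCs: {len(meta.qc_ids)})")
print("group sizes (discovery):",
      meta.table[(meta.table.cohort == 'discovery') & ~meta.table.is_qc]
      .group.value_counts().to_dict())
print(f"zero (missing) fraction: {study.table.missing_mask().to_numpy().mean():.3f}")
print(f"planted differential features: {len(truth.differential_indices)}")
ca125 = meta.marker("ca125")
for g in ("normal", "malignant"):
    vals = ca125[meta.samples(groups=[g], cohort="discovery")]
    print(f"CA125 {g}: mean {vals.mean():.1f} U/mL, median {vals.median():.1f}")
# The marker is right-skewed within each group (log-normal), and tumour
# groups sit far above normals, as serum CA125 does in practice.
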