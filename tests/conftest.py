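import numpy as np
import pandas as pd
import pytest

from metabopanel import (
    CohortSpec,
    FeatureTable,
    SampleMetadata,
    generate_cohort,
    generate_qc_samples,
)


def make_table(values, labels=None, samples=None) -> FeatureTable:
    """Small feature table from a plain array."""
    values = np.asarray(values, dtype=float)
    labels = labels or [f"{i + 1}.0000_{100 + i}.0000" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=labels, columns=samples))


def make_meta(
    sample_ids, groups=None, cohort="discovery", qc_flags=None, **markers
) -> SampleMetadata:
    n = len(sample_ids)
    groups = groups or ["normal"] * n
    qc_flags = qc_flags or [g == "qc" for g in groups]
    df = pd.DataFrame(
        {
            "group": groups,
            "cohort": cohort,
            "batch": 0,
            "is_qc": qc_flags,
            "stage": pd.NA,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for name, vals in markers.items():
        df[name] = vals
    return SampleMetadata(df)


@pytest.fixture
def two_group_cohort():
    """Clean 40 vs 40 cohort with planted effects and QCs, fixed seed."""
    spec = CohortSpec(
        n_features=300,
        n_differential=20,
        seed=11,
        group_sizes={"normal": 40, "malignant": 40},
    )
    table, meta, truth = generate_cohort(spec)
    qc_t, qc_m = generate_qc_samples(spec, table)
    table = FeatureTable(
        pd.concat([table.intensities, qc_t.intensities], axis=1),
        table.features.copy(),
    )
    meta = SampleMetadata(pd.concat([meta.table, qc_m], axis=0))
    return spec, table, meta, truth
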