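"""Synthetic LC-MS metabolomics cohorts with known ground truth.

The generator emulates the statistical structure of a four-group
(normal / benign / borderline / malignant ovarian tumour) urine or plasma
untargeted-metabolomics study:

* log-normal feature intensities (log2 baseline ~ N(mean, sd) per feature,
  per-feature biological spread drawn from a uniform range);
* a minority of truly differential features carrying additive log2 offsets in
  the tumour groups, with the borderline group shifted independently of the
  benign->malignant axis;
* multiplicative batch effects;
* intensity-dependent missingness (logistic detection model, zeros encode
  missing) with a completely-at-random switch for ablation;
* pooled-QC samples — the mean of a random 20% sample subset with low
  multiplicative noise, one QC per 20 biological samples;
* an internal-standard feature spiked at constant level;
* a CA125-like clinical marker drawn per group from a moment-matched
  log-normal (right-skewed, truncated at zero), with FIGO-like stages for
  tumour samples.

Every random draw flows from the single spec seed, so outputs are bitwise
reproducible; the returned :class:`GroundTruth` suffices to score any
downstream selection without re-deriving the generative model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureTable, SampleMetadata, make_feature_label

#: discovery-cohort group sizes of the emulated study design
DEFAULT_GROUP_SIZES = {"normal": 40, "benign": 36, "borderline": 13, "malignant": 74}
#: validation-cohort group sizes (urine arm of the emulated design)
DEFAULT_VALIDATION_SIZES = {"normal": 40, "benign": 45, "borderline": 7, "malignant": 76}
#: CA125-like marker (U/mL): per-group (mean, sd) of the emulated population
DEFAULT_MARKER_PARAMS = {
    "normal": (8.35, 5.81),
    "benign": (83.45, 234.82),
    "borderline": (183.88, 326.63),
    "malignant": (1254.34, 1597.27),
}
#: FIGO stage frequencies for staged groups (NA = unstaged)
_STAGE_PROBS = {
    "borderline": {"I": 0.615, "II": 0.077, "III": 0.154, "NA": 0.154},
    "malignant": {"I": 0.108, "II": 0.122, "III": 0.675, "IV": 0.095},
}
#: internal-standard feature (exogenous quercetin-like spike), RT_mz label
INTERNAL_STANDARD_LABEL = "1.8607_303.0509"


class SpecError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    Defaults are the study conditions the package emulates: ~1300 features,
    discovery group sizes 40/36/13/74, a minority of differential features at
    |log2FC| = 2, a low detection-limit zero rate (~2%, emulating peak tables
    whose missing values were largely filled upstream), two batches, pooled
    QCs at ~5% dispersion, and clinically realistic CA125 group
    distributions (see DEFAULT_MARKER_PARAMS).
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_features: int = 1300
    n_differential: int = 65
    effect_log2fc: float = 2.0
    base_log2_mean: float = 17.0
    base_log2_sd: float = 2.0
    feature_sd_range: tuple[float, float] = (0.6, 1.4)
    missing_baseline: float = 0.02
    missing_slope: float = 2.0
    missing_at_random: bool = False
    qc_count: int | None = None          # default: one per 20 biological samples
    qc_noise_sd: float = 0.05            # log-scale multiplicative dispersion
    batch_count: int = 2
    batch_shift_sd: float = 0.3
    internal_standard: bool = True
    clinical_marker: str = "ca125"
    clinical_marker_params: dict = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_features:
            raise SpecError("n_differential cannot exceed n_features")
        if any(n < 0 for n in self.group_sizes.values()):
            raise SpecError("group sizes must be >= 0")
        if self.qc_noise_sd < 0 or self.batch_shift_sd < 0 or self.base_log2_sd < 0:
            raise SpecError("standard deviations must be >= 0")
        if not 0 <= self.missing_baseline < 1:
            raise SpecError("missing_baseline must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to score downstream selections against the truth."""

    differential_indices: np.ndarray       # indices into the feature list
    feature_labels: list[str]
    group_offsets: dict                    # group -> per-feature log2 offsets
    batch_of_sample: dict                  # sample id -> batch
    marker_params: dict
    seed: int

    @property
    def differential_labels(self) -> list[str]:
        return [self.feature_labels[i] for i in self.differential_indices]

    def true_log2fc(self, group_a: str, group_b: str) -> np.ndarray:
        """Planted log2FC of every feature for the contrast b - a."""
        off_a = self.group_offsets.get(group_a, np.zeros(len(self.feature_labels)))
        off_b = self.group_offsets.get(group_b, np.zeros(len(self.feature_labels)))
        return np.asarray(off_b) - np.asarray(off_a)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "differential_indices": self.differential_indices.tolist(),
            "feature_labels": self.feature_labels,
            "group_offsets": {g: np.asarray(v).tolist() for g, v in self.group_offsets.items()},
            "batch_of_sample": self.batch_of_sample,
            "marker_params": {g: list(v) for g, v in self.marker_params.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc))


def _lognormal_moment_matched(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and sd, truncated at 0."""
    if mean <= 0:
        raise SpecError("marker mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return np.maximum(rng.lognormal(mu, math.sqrt(sigma2), size=size), 0.0)


@dataclass
class _FeatureModel:
    """Feature-level generative parameters, shared by all cohorts of a study."""

    labels: list[str]
    rt: np.ndarray
    mz: np.ndarray
    base: np.ndarray            # per-feature log2 baseline
    sd: np.ndarray              # per-feature biological sd (log2)
    batch_shift: np.ndarray     # batch x feature log2 offsets
    group_offsets: dict
    differential: np.ndarray
    detection_threshold: float
    is_index: int | None        # internal-standard feature position


def _build_feature_model(spec: CohortSpec, rng: np.random.Generator) -> _FeatureModel:
    n = spec.n_features
    rt = rng.uniform(0.5, 12.5, size=n)
    mz = rng.uniform(100.0, 1200.0, size=n)
    labels = [make_feature_label(r, m) for r, m in zip(rt, mz)]
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    sd = rng.uniform(*spec.feature_sd_range, size=n)

    is_index = None
    if spec.internal_standard:
        is_index = 0
        labels[0] = INTERNAL_STANDARD_LABEL
        rt[0], mz[0] = (float(x) for x in INTERNAL_STANDARD_LABEL.split("_"))
        base[0] = spec.base_log2_mean + 2.0     # spiked well above detection
        sd[0] = 0.05                            # analytical noise only

    # detection limit placed at the missing_baseline quantile of baselines
    thr = float(np.quantile(base, spec.missing_baseline)) if spec.missing_baseline > 0 else -np.inf

    # differential features are drawn from the quantifiable feature space:
    # an effect planted on a feature that a -effect shift pushes below the
    # detection limit is unrecoverable by construction and carries no
    # information about the selection rules under test
    eligible = np.arange(n) if is_index is None else np.arange(1, n)
    quantifiable = base[eligible] >= thr + abs(spec.effect_log2fc) + 1.5
    if quantifiable.sum() >= spec.n_differential:
        eligible = eligible[quantifiable]
    differential = np.sort(
        rng.choice(eligible, size=spec.n_differential, replace=False)
    )
    offsets = {g: np.zeros(n) for g in spec.group_sizes}
    tumour_groups = [g for g in spec.group_sizes if g != "normal"]
    for g in tumour_groups:
        # independent sign per group: the borderline group in particular does
        # not sit on a benign->malignant gradient
        signs = rng.choice([-1.0, 1.0], size=spec.n_differential)
        offsets[g][differential] = signs * spec.effect_log2fc

    batch_shift = rng.normal(0.0, spec.batch_shift_sd, size=(spec.batch_count, n))
    if is_index is not None:
        batch_shift[:, is_index] = 0.0
    return _FeatureModel(
        labels=labels, rt=rt, mz=mz, base=base, sd=sd, batch_shift=batch_shift,
        group_offsets=offsets, differential=differential,
        detection_threshold=thr, is_index=is_index,
    )


def _sample_cohort(
    spec: CohortSpec,
    fm: _FeatureModel,
    group_sizes: dict,
    cohort: str,
    rng: np.random.Generator,
    id_prefix: str,
):
    n_feat = spec.n_features
    sample_ids, groups, batches = [], [], []
    for g, size in group_sizes.items():
        for i in range(size):
            sample_ids.append(f"{id_prefix}_{g}_{i + 1}")
            groups.append(g)
    n_samp = len(sample_ids)
    batches = (np.arange(n_samp) % spec.batch_count).tolist()

    log2x = np.empty((n_feat, n_samp))
    for j, (g, b) in enumerate(zip(groups, batches)):
        mean = fm.base + fm.group_offsets.get(g, 0.0) + fm.batch_shift[b]
        log2x[:, j] = rng.normal(mean, fm.sd)
    if fm.is_index is not None:
        # internal standard: no group/batch structure
        log2x[fm.is_index, :] = rng.normal(
            fm.base[fm.is_index], fm.sd[fm.is_index], size=n_samp
        )

    # missingness (zeros); MNAR logistic detection model by default
    if spec.missing_baseline > 0:
        if spec.missing_at_random:
            miss = rng.random(log2x.shape) < spec.missing_baseline
        else:
            p = 1.0 / (1.0 + np.exp(spec.missing_slope * (log2x - fm.detection_threshold)))
            miss = rng.random(log2x.shape) < p
        if fm.is_index is not None:
            miss[fm.is_index, :] = False
    else:
        miss = np.zeros(log2x.shape, dtype=bool)

    intens = np.exp2(log2x)
    intens[miss] = 0.0

    # clinical marker + stages
    marker = np.full(n_samp, np.nan)
    stage = np.array(["NA"] * n_samp, dtype=object)
    for g in set(groups):
        idx = [j for j, gg in enumerate(groups) if gg == g]
        params = spec.clinical_marker_params.get(g)
        if params is not None:
            marker[idx] = _lognormal_moment_matched(rng, params[0], params[1], len(idx))
        probs = _STAGE_PROBS.get(g)
        if probs is not None:
            stage[idx] = rng.choice(
                list(probs.keys()), size=len(idx), p=list(probs.values())
            )

    table = FeatureTable(
        pd.DataFrame(intens, index=fm.labels, columns=sample_ids),
        pd.DataFrame({"rt": fm.rt, "mz": fm.mz}, index=pd.Index(fm.labels)),
    )
    meta = pd.DataFrame(
        {
            "group": groups,
            "cohort": cohort,
            "batch": batches,
            "is_qc": False,
            "stage": [s if s != "NA" else pd.NA for s in stage],
            spec.clinical_marker: marker,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table, meta


def generate_cohort(
    spec: CohortSpec, cohort: str = "discovery"
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """One cohort with ``spec.group_sizes`` samples; fully seeded."""
    rng = np.random.default_rng(spec.seed)
    fm = _build_feature_model(spec, rng)
    table, meta = _sample_cohort(spec, fm, spec.group_sizes, cohort, rng, cohort[:4])
    truth = GroundTruth(
        differential_indices=fm.differential,
        feature_labels=fm.labels,
        group_offsets=fm.group_offsets,
        batch_of_sample=dict(zip(meta.index, meta["batch"])),
        marker_params=spec.clinical_marker_params,
        seed=spec.seed,
    )
    return table, SampleMetadata(meta), truth


def generate_null_cohort(
    spec: CohortSpec, cohort: str = "discovery"
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Same generative model with no planted effects (n_differential = 0)."""
    null_spec = CohortSpec(**{**spec.__dict__, "n_differential": 0})
    return generate_cohort(null_spec, cohort=cohort)


def generate_qc_samples(
    spec: CohortSpec,
    table: FeatureTable,
    seed: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Pooled-QC injections for an existing cohort.

    Pools a random 20% subset of the biological samples once; each QC is the
    pooled mean intensity under multiplicative log-normal noise
    (sd ``qc_noise_sd``), one QC per 20 biological samples.  Values below the
    pool's detection floor are deterministic zeros, so ``qc_noise_sd = 0``
    yields identical QC columns.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = table.n_samples
    if n < 5:
        raise SpecError("cohort too small to pool QC samples (need >= 5)")
    n_pool = max(1, int(round(0.2 * n)))
    pool_ids = rng.choice(np.arange(n), size=n_pool, replace=False)
    pooled = table.values[:, pool_ids].mean(axis=1)
    n_qc = spec.qc_count if spec.qc_count is not None else math.ceil(n / 20)
    noise = np.exp(rng.normal(0.0, spec.qc_noise_sd, size=(table.n_features, n_qc)))
    qc_vals = pooled[:, None] * noise
    qc_vals[pooled == 0.0, :] = 0.0
    qc_ids = [f"qc_{i + 1}" for i in range(n_qc)]
    qc_table = FeatureTable(
        pd.DataFrame(qc_vals, index=table.labels, columns=qc_ids),
        table.features.copy(),
    )
    qc_meta = pd.DataFrame(
        {
            "group": "qc",
            "cohort": "discovery",
            "batch": (np.arange(n_qc) % spec.batch_count),
            "is_qc": True,
            "stage": pd.NA,
            spec.clinical_marker: np.nan,
        },
        index=pd.Index(qc_ids, name="sample_id"),
    )
    return qc_table, qc_meta


@dataclass
class Study:
    """A discovery + validation study sharing one feature model, with QCs."""

    table: FeatureTable
    meta: SampleMetadata
    truth: GroundTruth


def generate_study(
    spec: CohortSpec,
    validation_sizes: dict | None = None,
    with_qc: bool = True,
) -> Study:
    """Discovery and validation cohorts drawn from one feature model (the
    i.i.d. transfer setting), concatenated into a single table/metadata pair
    with pooled-QC samples appended."""
    rng = np.random.default_rng(spec.seed)
    fm = _build_feature_model(spec, rng)
    t_disc, m_disc = _sample_cohort(spec, fm, spec.group_sizes, "discovery", rng, "disc")
    v_sizes = validation_sizes or DEFAULT_VALIDATION_SIZES
    v_sizes = {g: v_sizes.get(g, 0) for g in spec.group_sizes}
    t_val, m_val = _sample_cohort(spec, fm, v_sizes, "validation", rng, "val")

    intens = pd.concat([t_disc.intensities, t_val.intensities], axis=1)
    meta = pd.concat([m_disc, m_val], axis=0)
    table = FeatureTable(intens, t_disc.features.copy())
    if with_qc:
        qc_table, qc_meta = generate_qc_samples(spec, table, seed=spec.seed + 1)
        table = FeatureTable(
            pd.concat([table.intensities, qc_table.intensities], axis=1),
            table.features.copy(),
        )
        meta = pd.concat([meta, qc_meta], axis=0)
    truth = GroundTruth(
        differential_indices=fm.differential,
        feature_labels=fm.labels,
        group_offsets=fm.group_offsets,
        batch_of_sample=dict(zip(meta.index, meta["batch"])),
        marker_params=spec.clinical_marker_params,
        seed=spec.seed,
    )
    return Study(table=table, meta=SampleMetadata(meta), truth=truth)
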