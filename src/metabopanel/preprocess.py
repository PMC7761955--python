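"""Feature screening, imputation, normalization and QC diagnostics.

The standard untargeted-LC-MS cleanup chain, applied in this fixed order:

1. "80% rule" — drop features missing (zero) in >= 20% of biological samples;
2. QC repeatability — drop features whose coefficient of variation across
   pooled-QC injections exceeds 30%;
3. half-minimum imputation of remaining zeros (below-detection censoring);
4. median normalization of each sample to a common reference level;
5. log2 transform.

Missingness and the QC CV are always computed on the raw, pre-imputation
intensities; zeros are the only missing encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable, SampleMetadata


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Screening thresholds.

    missing_fraction_threshold
        Remove a feature when its missing fraction among non-QC samples is
        >= this value (default 0.20, the "80% rule").
    qc_cv_threshold
        Remove a feature when sd/mean over QC injections is strictly greater
        than this value (default 0.30).
    min_qc_observations
        Minimum number of non-missing QC values needed to estimate the CV;
        features with fewer are removed and reported separately.
    missingness_per_group
        Apply the 80% rule within each biological group (feature kept if it
        passes in any group) instead of over all non-QC samples.
    half_min_global
        Impute with half the global minimum positive intensity instead of the
        per-feature minimum.
    """

    missing_fraction_threshold: float = 0.20
    qc_cv_threshold: float = 0.30
    min_qc_observations: int = 3
    missingness_per_group: bool = False
    half_min_global: bool = False

    def __post_init__(self) -> None:
        for name in ("missing_fraction_threshold", "qc_cv_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class PreprocessReport:
    """Stage-by-stage accounting of a preprocessing run."""

    n_features_in: int = 0
    removed_missingness: int = 0
    removed_qc_cv: int = 0
    removed_qc_insufficient: int = 0
    n_imputed_values: int = 0
    reference_median: float = float("nan")
    n_features_out: int = 0
    config: PreprocessConfig | None = None
    stages: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"features_in: {self.n_features_in}",
            f"removed_missingness: {self.removed_missingness}",
            f"removed_qc_cv: {self.removed_qc_cv}",
            f"removed_qc_insufficient: {self.removed_qc_insufficient}",
            f"imputed_values: {self.n_imputed_values}",
            f"reference_median: {self.reference_median:.6g}",
            f"features_out: {self.n_features_out}",
        ]
        if self.config is not None:
            lines += [
                f"missing_fraction_threshold: {self.config.missing_fraction_threshold}",
                f"qc_cv_threshold: {self.config.qc_cv_threshold}",
                f"min_qc_observations: {self.config.min_qc_observations}",
            ]
        lines += [f"stage: {s}" for s in self.stages]
        return "\n".join(lines)


def filter_by_missingness(
    table: FeatureTable,
    meta: SampleMetadata,
    threshold: float = 0.20,
    per_group: bool = False,
    report: PreprocessReport | None = None,
) -> FeatureTable:
    """Apply the 80% rule: drop features missing in >= ``threshold`` of the
    biological (non-QC) samples."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    bio = table.sample_ids.intersection(meta.non_qc_ids)
    if len(bio) == 0:
        raise PreprocessError("no non-QC samples present; cannot assess missingness")
    zero = table.intensities[bio] == 0.0
    if per_group:
        groups = meta.table.loc[bio, "group"]
        keep = pd.Series(False, index=table.labels)
        for _, ids in groups.groupby(groups).groups.items():
            frac = zero[list(ids)].mean(axis=1)
            keep |= frac < threshold
    else:
        keep = zero.mean(axis=1) < threshold
    out = table.select_features(table.labels[keep])
    if report is not None:
        report.removed_missingness = int((~keep).sum())
        report.stages.append(
            f"missingness_filter threshold={threshold} removed={int((~keep).sum())}"
        )
    return out


def filter_by_qc_cv(
    table: FeatureTable,
    meta: SampleMetadata,
    cv_threshold: float = 0.30,
    min_qc_observations: int = 3,
    report: PreprocessReport | None = None,
) -> FeatureTable:
    """Drop features whose QC coefficient of variation (sd/mean, raw scale)
    is strictly greater than ``cv_threshold``.

    Missing QC values are excluded from the CV; features with fewer than
    ``min_qc_observations`` non-missing QC values are removed and counted
    separately in the report.
    """
    qc = table.sample_ids.intersection(meta.qc_ids)
    if len(qc) == 0:
        raise PreprocessError(
            "no QC samples present; skip the QC CV filter explicitly if intended"
        )
    vals = table.intensities[qc].to_numpy()
    obs = vals > 0
    n_obs = obs.sum(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        means = np.where(obs, vals, np.nan)
        mean = np.nanmean(means, axis=1)
        sd = np.nanstd(means, axis=1, ddof=1)
        cv = sd / mean
    insufficient = n_obs < min_qc_observations
    noisy = (~insufficient) & (cv > cv_threshold)
    keep = ~(insufficient | noisy)
    out = table.select_features(table.labels[keep])
    if report is not None:
        report.removed_qc_cv = int(noisy.sum())
        report.removed_qc_insufficient = int(insufficient.sum())
        report.stages.append(
            f"qc_cv_filter threshold={cv_threshold} removed={int(noisy.sum())} "
            f"insufficient_qc={int(insufficient.sum())}"
        )
    return out


def impute_half_min(
    table: FeatureTable,
    global_min: bool = False,
    report: PreprocessReport | None = None,
) -> FeatureTable:
    """Replace zeros with half the minimum positive intensity.

    Per feature by default; ``global_min`` uses half the table-wide minimum
    positive value for every feature.
    """
    vals = table.values.copy()
    pos = np.where(vals > 0, vals, np.inf)
    if global_min:
        fill = np.full(vals.shape[0], pos.min() / 2.0)
    else:
        fill = pos.min(axis=1) / 2.0
    all_missing = ~np.isfinite(fill)
    if all_missing.any():
        lbl = table.labels[np.where(all_missing)[0][0]]
        raise PreprocessError(
            f"feature {lbl!r} has no positive value; remove it before imputation"
        )
    zero = vals == 0.0
    vals[zero] = np.broadcast_to(fill[:, None], vals.shape)[zero]
    out = FeatureTable(
        pd.DataFrame(vals, index=table.labels, columns=table.sample_ids),
        table.features.copy(),
    )
    if report is not None:
        report.n_imputed_values = int(zero.sum())
        report.stages.append(f"impute_half_min imputed={int(zero.sum())}")
    return out


def normalize_median(
    table: FeatureTable, report: PreprocessReport | None = None
) -> FeatureTable:
    """Scale each sample so that all sample medians equal the reference
    (the median of the per-sample medians). Requires imputed (>0) data."""
    vals = table.values
    if (vals <= 0).any():
        raise PreprocessError("median normalization requires imputed, positive data")
    medians = np.median(vals, axis=0)
    reference = float(np.median(medians))
    scaled = vals * (reference / medians)[None, :]
    out = FeatureTable(
        pd.DataFrame(scaled, index=table.labels, columns=table.sample_ids),
        table.features.copy(),
    )
    if report is not None:
        report.reference_median = reference
        report.stages.append(f"normalize_median reference={reference:.6g}")
    return out


def log2_transform(
    table: FeatureTable, report: PreprocessReport | None = None
) -> FeatureTable:
    vals = table.values
    if (vals <= 0).any():
        rows, cols = np.where(vals <= 0)
        raise PreprocessError(
            f"nonpositive intensity at feature {table.labels[rows[0]]!r}, sample "
            f"{table.sample_ids[cols[0]]!r}: impute before log2"
        )
    out = FeatureTable(
        pd.DataFrame(np.log2(vals), index=table.labels, columns=table.sample_ids),
        table.features.copy(),
    )
    if report is not None:
        report.stages.append("log2_transform")
    return out


def compute_rsd(table: FeatureTable, meta: SampleMetadata, feature: str) -> float:
    """Relative standard deviation (%) of a feature over QC injections,
    on raw (pre-log) intensities; missing QC values are excluded."""
    if feature not in table.labels:
        raise PreprocessError(f"feature {feature!r} not in table")
    qc = table.sample_ids.intersection(meta.qc_ids)
    vals = table.intensities.loc[feature, qc].to_numpy(dtype=float)
    vals = vals[vals > 0]
    if len(vals) < 2:
        raise PreprocessError(
            f"need >=2 non-missing QC values for RSD of {feature!r}, got {len(vals)}"
        )
    return float(100.0 * np.std(vals, ddof=1) / np.mean(vals))


def preprocess_pipeline(
    table: FeatureTable,
    meta: SampleMetadata,
    config: PreprocessConfig | None = None,
    skip_qc_filter: bool = False,
) -> tuple[FeatureTable, PreprocessReport]:
    """Full cleanup chain: missingness filter -> QC CV filter -> half-min
    imputation -> median normalization -> log2. Returns the processed table
    and a stage-by-stage report."""
    config = config or PreprocessConfig()
    report = PreprocessReport(n_features_in=table.n_features, config=config)
    out = filter_by_missingness(
        table,
        meta,
        config.missing_fraction_threshold,
        per_group=config.missingness_per_group,
        report=report,
    )
    if skip_qc_filter:
        report.stages.append("qc_cv_filter skipped")
    else:
        out = filter_by_qc_cv(
            out, meta, config.qc_cv_threshold, config.min_qc_observations, report
        )
    out = impute_half_min(out, global_min=config.half_min_global, report=report)
    out = normalize_median(out, report=report)
    out = log2_transform(out, report=report)
    report.n_features_out = out.n_features
    return out, report
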