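"""Rank-based differential testing with FDR control and VIP-joint selection.

Per feature, a two-sided Wilcoxon/Mann-Whitney rank-sum test compares the two
groups of a comparison; p-values are adjusted across all tested features by
Benjamini-Hochberg step-up.  Effect size is the log2 fold change (difference
of group means on already-log2 data).  A feature is selected as a
differential putative metabolite when its VIP from the matching OPLS-DA model
exceeds 1 and, depending on the comparison mode, either FDR < 0.1
(``fdr_rule``) or raw p < 0.05 (``p_rule``) — all inequalities strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FeatureTable, SampleMetadata


class AnalysisError(ValueError):
    pass


def wilcoxon_rank_sum(
    values_a: np.ndarray, values_b: np.ndarray, method: str = "auto"
) -> float:
    """Two-sided rank-sum p-value.

    ``method="asymptotic"`` uses the tie-corrected normal approximation with
    continuity correction; ``"exact"`` enumerates (no ties only);
    ``"auto"`` picks exact for min group size <= 10 without ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each group needs >= 2 values for the rank-sum test")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:          # complete ties: no evidence either way
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise AnalysisError("p_values must be a non-empty 1-D array")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise AnalysisError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(case_log2, reference_log2) -> float:
    """mean(case) - mean(reference) on already-log2 values."""
    case = np.asarray(case_log2, dtype=float)
    ref = np.asarray(reference_log2, dtype=float)
    if len(case) == 0 or len(ref) == 0:
        raise AnalysisError("both groups must be non-empty")
    return float(case.mean() - ref.mean())


@dataclass
class ComparisonSpec:
    """A two-group contrast: ``group_a`` is the reference, ``group_b`` the
    case; log2FC is oriented case minus reference.

    ``mode``: ``"fdr_rule"`` (VIP>1 & FDR<0.1, used for normal-vs-tumour
    contrasts) or ``"p_rule"`` (VIP>1 & p<0.05, used for the tumour-subtype
    contrasts).  ``merge_borderline_into_malignant`` relabels borderline
    samples as malignant before selecting samples.

    A side may pool several groups by joining names with ``"+"``, e.g.
    ``group_b="benign+borderline+malignant"`` for a normal-vs-ovarian-tumour
    contrast.
    """

    group_a: str
    group_b: str
    mode: str = "fdr_rule"
    merge_borderline_into_malignant: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fdr_rule", "p_rule"):
            raise ValueError(f"mode must be 'fdr_rule' or 'p_rule', got {self.mode!r}")
        if set(self.groups_a()) & set(self.groups_b()):
            raise ValueError("comparison groups must be disjoint")
        if self.name is None:
            self.name = f"{self.group_a}_vs_{self.group_b}"

    def groups_a(self) -> list[str]:
        return self.group_a.split("+")

    def groups_b(self) -> list[str]:
        return self.group_b.split("+")

    def resolve_meta(self, meta: SampleMetadata) -> SampleMetadata:
        if self.merge_borderline_into_malignant:
            return meta.relabel_group("borderline", "malignant")
        return meta

    def sample_ids(self, meta: SampleMetadata, cohort: str | None = None):
        """(ids_a, ids_b) after optional borderline merge and cohort filter."""
        m = self.resolve_meta(meta)
        ids_a = m.samples(groups=self.groups_a(), cohort=cohort)
        ids_b = m.samples(groups=self.groups_b(), cohort=cohort)
        if len(ids_a) == 0 or len(ids_b) == 0:
            raise AnalysisError(
                f"comparison {self.name}: empty group "
                f"(|{self.group_a}|={len(ids_a)}, |{self.group_b}|={len(ids_b)})"
            )
        return ids_a, ids_b


#: differential-table output columns
DIFFERENTIAL_COLUMNS = [
    "label", "rt", "mz", "p_value", "fdr", "log2fc", "vip", "selected",
]


def differential_analysis(
    table: FeatureTable,
    meta: SampleMetadata,
    comparison: ComparisonSpec,
    vip: np.ndarray,
    cohort: str | None = "discovery",
    method: str = "auto",
) -> pd.DataFrame:
    """Per-feature rank-sum p, BH FDR, log2FC and VIP with the joint
    selection flag; ``table`` must already be preprocessed (log2 scale)."""
    vip = np.asarray(vip, dtype=float)
    if len(vip) != table.n_features:
        raise AnalysisError(
            f"VIP length {len(vip)} does not match {table.n_features} features"
        )
    ids_a, ids_b = comparison.sample_ids(meta, cohort=cohort)
    A = table.intensities[ids_a].to_numpy()
    B = table.intensities[ids_b].to_numpy()
    p = np.array([wilcoxon_rank_sum(A[i], B[i], method=method) for i in range(len(A))])
    fdr = bh_fdr(p)
    l2fc = B.mean(axis=1) - A.mean(axis=1)
    if comparison.mode == "fdr_rule":
        selected = (vip > 1.0) & (fdr < 0.1)
    else:
        selected = (vip > 1.0) & (p < 0.05)
    out = pd.DataFrame(
        {
            "label": table.labels,
            "rt": table.features["rt"].to_numpy(),
            "mz": table.features["mz"].to_numpy(),
            "p_value": p,
            "fdr": fdr,
            "log2fc": l2fc,
            "vip": vip,
            "selected": selected,
        }
    ).reset_index(drop=True)
    return out


def write_differential_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    cols = [c for c in DIFFERENTIAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep=sep, index=False)
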