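"""Biomarker-panel classification: SVM training, panel search, ROC transfer.

The workflow mirrors a discovery/validation biomarker study: candidate
features (the differential putative metabolites) are searched exhaustively —
subsets of up to ten features, ranked by mean 7-fold cross-validated AUC of a
radial-kernel SVM — the winning panel's probability cutoff is fixed on the
discovery cohort at the Youden-optimal ROC point, and the frozen model
(scaler, classifier, cutoff) is then applied unchanged to the validation
cohort.  Hybrid panels append a log2-transformed clinical marker (e.g. serum
CA125) as an extra column.

True exhaustion over every subset is capped by ``budget``; beyond it a seeded
greedy forward selection is used and flagged in the search result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .data import FeatureTable, SampleMetadata
from .multivariate import ModelError, Scaler, _stratified_folds


class ClassifierError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Sensitivity/specificity at every observed score threshold
    (predict positive when score >= threshold), plus rank-based AUC."""

    thresholds: np.ndarray        # distinct observed scores, descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ClassifierError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ClassifierError("both classes must be present for a ROC curve")
    thr = np.unique(scores)[::-1]
    pos, neg = scores[y == 1], scores[y == 0]
    sens = (pos[None, :] >= thr[:, None]).mean(axis=1)
    spec = (neg[None, :] < thr[:, None]).mean(axis=1)
    # rank-statistic AUC: equals Mann-Whitney U/(n_pos*n_neg), ties as 1/2
    auc = float(roc_auc_score(y, scores))
    return RocCurve(thresholds=thr, sensitivity=sens, specificity=spec, auc=auc)


def optimal_cutoff(roc: RocCurve) -> float:
    """Youden-optimal threshold (max sensitivity + specificity - 1) over the
    observed thresholds; ties broken toward higher specificity, then the
    larger threshold."""
    if len(roc.thresholds) < 2:
        raise ClassifierError("degenerate ROC: all scores identical")
    youden = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.thresholds, roc.specificity, youden))
    return float(roc.thresholds[order[-1]])


@dataclass
class EvaluationReport:
    """Performance of a frozen model on one cohort (or cohort subset)."""

    cohort: str
    n: int
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    subset: str | None = None

    def to_row(self) -> dict:
        return {
            "cohort": self.cohort,
            "n": self.n,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "subset": self.subset or "",
        }


def evaluate_scores(
    scores, labels, cutoff: float, cohort: str = "", subset: str | None = None
) -> EvaluationReport:
    """Confusion counts and sens/spec of ``score >= cutoff`` plus the
    cutoff-free AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("both classes must be present for evaluation")
    return EvaluationReport(
        cohort=cohort,
        n=len(y),
        auc=float(roc_auc_score(y, scores)),
        cutoff=cutoff,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        tp=tp, fp=fp, tn=tn, fn=fn,
        subset=subset,
    )


# ---------------------------------------------------------------------------
# SVM panel models
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    """A trained radial-kernel SVM over a feature panel, with the
    probability cutoff frozen on discovery data."""

    panel: list[str]
    gamma: float
    cost: float
    seed: int
    scaler: Scaler
    svc: SVC
    includes_clinical_marker: bool = False
    marker_name: str | None = None
    probability_cutoff: float | None = None

    def scores(self, X) -> np.ndarray:
        """Calibrated probability of the positive (coded-1) class."""
        Z = self.scaler.transform(np.asarray(X, dtype=float))
        proba = self.svc.predict_proba(Z)
        return proba[:, list(self.svc.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        if self.probability_cutoff is None:
            raise ClassifierError("cutoff not fixed; call set_cutoff_from first")
        return (self.scores(X) >= self.probability_cutoff).astype(int)

    def set_cutoff_from(self, X, y) -> float:
        """Fix the probability cutoff at the Youden optimum of the ROC on
        (X, y) — discovery data only, by contract."""
        roc = roc_curve(self.scores(X), y)
        self.probability_cutoff = optimal_cutoff(roc)
        return self.probability_cutoff


def train_svm(
    X,
    y,
    panel: Sequence[str] | None = None,
    gamma: float = 0.1,
    cost: float = 100.0,
    seed: int = 1000,
    includes_clinical_marker: bool = False,
    marker_name: str | None = None,
) -> PanelModel:
    """Pareto-scale the panel columns and fit a radial-kernel SVM with
    seeded Platt probability calibration; rerunning with the same seed
    reproduces identical probabilities."""
    if isinstance(X, pd.DataFrame):
        panel = list(X.columns) if panel is None else list(panel)
        X = X.to_numpy()
    elif panel is None:
        panel = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(X).all():
        raise ClassifierError("non-finite feature values in training matrix")
    if len(np.unique(y)) < 2:
        raise ClassifierError("training labels contain a single class")
    if gamma <= 0 or cost <= 0:
        raise ClassifierError("gamma and cost must be positive")
    scaler = Scaler(kind="pareto")
    Z = scaler.fit_transform(X)
    svc = SVC(
        kernel="rbf", gamma=gamma, C=cost, probability=True, random_state=seed
    )
    svc.fit(Z, y)
    return PanelModel(
        panel=list(panel),
        gamma=gamma,
        cost=cost,
        seed=seed,
        scaler=scaler,
        svc=svc,
        includes_clinical_marker=includes_clinical_marker,
        marker_name=marker_name,
    )


def evaluate(
    model: PanelModel,
    X_eval,
    y_eval,
    cohort: str = "validation",
    meta: SampleMetadata | None = None,
    sample_ids: Sequence[str] | None = None,
    subset_filter: Callable[[pd.Series], bool] | None = None,
    subset_label: str | None = None,
) -> EvaluationReport:
    """Apply the frozen scaler, classifier and cutoff to held-out data.

    ``subset_filter`` (a predicate over metadata rows, requiring ``meta`` and
    ``sample_ids`` aligned with the rows of ``X_eval``) restricts the
    evaluated samples, e.g. to early-stage (FIGO I-II) cancers.
    """
    if model.probability_cutoff is None:
        raise ClassifierError("model cutoff must be fixed before evaluation")
    X_eval = np.asarray(X_eval, dtype=float)
    y_eval = np.asarray(y_eval).astype(int)
    if subset_filter is not None:
        if meta is None or sample_ids is None:
            raise ClassifierError("subset_filter requires meta and sample_ids")
        def _as_bool(v):
            try:
                return bool(v)
            except (TypeError, ValueError):   # e.g. pd.NA from missing stage
                return False

        keep = np.array(
            [_as_bool(subset_filter(meta.table.loc[s])) for s in sample_ids]
        )
        if not keep.any():
            raise ClassifierError("subset_filter matched no samples")
        X_eval, y_eval = X_eval[keep], y_eval[keep]
    scores = model.scores(X_eval)
    return evaluate_scores(
        scores, y_eval, model.probability_cutoff, cohort=cohort, subset=subset_label
    )


# ---------------------------------------------------------------------------
# exhaustive panel search
# ---------------------------------------------------------------------------

@dataclass
class PanelSearchResult:
    panel: list[str]
    cv_auc: float
    method: str                   # "exhaustive" or "greedy_forward"
    n_evaluated: int
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def used_fallback(self) -> bool:
        return self.method == "greedy_forward"


def _cv_auc_subset(
    X: np.ndarray, y: np.ndarray, cols: Sequence[int], fold_of: np.ndarray,
    folds: int, gamma: float, cost: float,
) -> float:
    """Mean per-fold AUC of an RBF SVM on a column subset; pareto scaling
    refit inside each training fold."""
    aucs = []
    Xs = X[:, list(cols)]
    for k in range(folds):
        test = fold_of == k
        train = ~test
        scaler = Scaler(kind="pareto")
        try:
            Z_tr = scaler.fit_transform(Xs[train])
        except ModelError:       # constant column inside the fold
            return -np.inf
        svc = SVC(kernel="rbf", gamma=gamma, C=cost)
        svc.fit(Z_tr, y[train])
        s = svc.decision_function(scaler.transform(Xs[test]))
        if len(np.unique(y[test])) < 2:
            continue
        aucs.append(roc_auc_score(y[test], s))
    if not aucs:
        return -np.inf
    return float(np.mean(aucs))


def exhaustive_panel_search(
    candidates: Sequence[str],
    X,
    y,
    max_panel_size: int = 10,
    folds: int = 7,
    gamma: float = 0.1,
    cost: float = 100.0,
    seed: int = 1000,
    budget: int = 1_000_000,
    keep_scores: bool = True,
) -> PanelSearchResult:
    """Best feature panel by mean cross-validated AUC.

    Enumerates all subsets of sizes 1..``max_panel_size`` (sizes ascending,
    candidates in given order; the first subset attaining the best score
    wins).  When the subset count exceeds ``budget``, falls back to seeded
    greedy forward selection (recorded in the result), which stops growing
    the panel once a step no longer improves the CV AUC.
    """
    candidates = list(candidates)
    if not candidates:
        raise ClassifierError("empty candidate list")
    if isinstance(X, pd.DataFrame):
        missing = set(candidates) - set(X.columns)
        if missing:
            raise ClassifierError(f"candidates absent from X: {sorted(missing)[:5]}")
        X = X[candidates].to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    max_panel_size = min(max_panel_size, len(candidates))
    if max_panel_size < 1:
        raise ClassifierError("max_panel_size must be >= 1")
    n_min = min(int((y == 0).sum()), int((y == 1).sum()))
    if folds > n_min:
        raise ClassifierError(f"folds={folds} exceeds smallest class size {n_min}")
    fold_of = _stratified_folds(y.astype(float), folds, seed)

    n_subsets = sum(math.comb(len(candidates), k) for k in range(1, max_panel_size + 1))
    rows: list[dict] = []
    best_score, best_cols = -np.inf, None

    if n_subsets <= budget:
        method = "exhaustive"
        n_eval = 0
        for size in range(1, max_panel_size + 1):
            for cols in itertools.combinations(range(len(candidates)), size):
                score = _cv_auc_subset(X, y, cols, fold_of, folds, gamma, cost)
                n_eval += 1
                if keep_scores:
                    rows.append(
                        {"panel": tuple(candidates[c] for c in cols),
                         "size": size, "cv_auc": score}
                    )
                if score > best_score:
                    best_score, best_cols = score, cols
    else:
        method = "greedy_forward"
        n_eval = 0
        current: list[int] = []
        remaining = list(range(len(candidates)))
        while len(current) < max_panel_size and remaining:
            step_best, step_col = -np.inf, None
            for c in remaining:
                score = _cv_auc_subset(
                    X, y, current + [c], fold_of, folds, gamma, cost
                )
                n_eval += 1
                if score > step_best:
                    step_best, step_col = score, c
            if step_best <= best_score:     # no improvement: stop growing
                break
            current.append(step_col)
            remaining.remove(step_col)
            if keep_scores:
                rows.append(
                    {"panel": tuple(candidates[c] for c in current),
                     "size": len(current), "cv_auc": step_best}
                )
            best_score, best_cols = step_best, tuple(current)

    return PanelSearchResult(
        panel=[candidates[c] for c in best_cols],
        cv_auc=best_score,
        method=method,
        n_evaluated=n_eval,
        scores=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# clinical-marker and hybrid models
# ---------------------------------------------------------------------------

def assemble_matrix(
    table: FeatureTable,
    meta: SampleMetadata,
    panel: Sequence[str],
    sample_ids: Sequence[str],
    marker: str | None = None,
) -> tuple[pd.DataFrame, pd.Index, int]:
    """Samples x panel matrix from a processed (log2) table, optionally with
    a log2-transformed clinical-marker column appended.  Samples missing the
    marker are excluded; returns (matrix, kept ids, n_excluded)."""
    ids = pd.Index(sample_ids)
    missing_feats = pd.Index(panel).difference(table.labels)
    if len(missing_feats):
        raise ClassifierError(
            f"panel features absent from table: {missing_feats.tolist()[:5]}"
        )
    Xdf = table.intensities.loc[list(panel), ids].T
    n_excluded = 0
    if marker is not None:
        vals = meta.marker(marker).loc[ids]
        keep = vals.notna() & (vals > 0)
        n_excluded = int((~keep).sum())
        if keep.sum() == 0:
            raise ClassifierError(f"marker {marker!r} missing for all samples")
        Xdf = Xdf.loc[keep[keep].index]
        Xdf[marker] = np.log2(vals[keep].astype(float))
    return Xdf, Xdf.index, n_excluded


def hybrid_model(
    table: FeatureTable,
    meta: SampleMetadata,
    panel: Sequence[str],
    clinical_marker: str,
    sample_ids: Sequence[str],
    y,
    gamma: float = 0.1,
    cost: float = 10.0,
    seed: int = 520,
) -> tuple[PanelModel, pd.Index, int]:
    """Train an SVM on panel features plus the log2 clinical marker.

    Returns (model, sample ids actually used, n excluded for missing
    marker); ``y`` must be indexed like ``sample_ids``.
    """
    Xdf, kept, n_excl = assemble_matrix(
        table, meta, panel, sample_ids, marker=clinical_marker
    )
    y = pd.Series(np.asarray(y).astype(int), index=pd.Index(sample_ids)).loc[kept]
    model = train_svm(
        Xdf, y.to_numpy(), gamma=gamma, cost=cost, seed=seed,
        includes_clinical_marker=True, marker_name=clinical_marker,
    )
    return model, kept, n_excl


@dataclass
class MarkerRocResult:
    roc: RocCurve
    youden_cutoff: float
    at_youden: EvaluationReport
    at_fixed: EvaluationReport | None
    n_excluded: int


def clinical_marker_roc(
    meta: SampleMetadata,
    y,
    marker: str,
    sample_ids: Sequence[str],
    fixed_cutoff: float | None = None,
    cohort: str = "",
) -> MarkerRocResult:
    """ROC of a raw clinical-marker value (e.g. CA125 in U/mL) used directly
    as the score, with Youden and optionally a fixed clinical cutoff
    (e.g. 35 U/mL for CA125)."""
    ids = pd.Index(sample_ids)
    vals = meta.marker(marker).loc[ids].astype(float)
    y = pd.Series(np.asarray(y).astype(int), index=ids)
    keep = vals.notna()
    n_excl = int((~keep).sum())
    if keep.sum() == 0:
        raise ClassifierError(f"marker {marker!r} missing for all samples")
    vals, y = vals[keep], y[keep]
    roc = roc_curve(vals.to_numpy(), y.to_numpy())
    cut = optimal_cutoff(roc)
    at_youden = evaluate_scores(vals, y, cut, cohort=cohort, subset="youden")
    at_fixed = (
        evaluate_scores(vals, y, fixed_cutoff, cohort=cohort, subset="fixed")
        if fixed_cutoff is not None
        else None
    )
    return MarkerRocResult(roc, cut, at_youden, at_fixed, n_excl)
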