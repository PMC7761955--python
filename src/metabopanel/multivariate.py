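"""Multivariate pattern analysis: scaling, PCA, OPLS-DA, VIP, permutation test.

OPLS-DA (orthogonal projections to latent structures, discriminant flavour)
regresses a centered 0/1 class coding on the scaled feature matrix after
stripping a configurable number of components orthogonal to the class
direction, leaving a single predictive component.  Model quality is reported
as R2Y (explained class variance on the training fit) and Q2 (1 - PRESS/TSS
under stratified k-fold cross-validation with scaling refit inside each
training fold).  Overfitting risk is assessed by refitting under label
permutations: pQ2 is the add-one permutation p-value of the observed Q2.

Feature influence is the classic PLS "variable importance in projection"
(VIP); with a single predictive component VIP_j = sqrt(p) * |w_j| for the
normalized predictive weight vector w, so mean(VIP^2) = 1 and VIP > 1 marks
above-average contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SKPCA


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Column scaling fitted on training data and applied to held-out data.

    kind
        ``"unit_variance"`` divides centered columns by the sample sd,
        ``"pareto"`` by the square root of the sd (the chemometrics
        compromise between none and unit variance), ``"none"`` leaves them.
    """

    kind: str = "pareto"
    center: bool = True
    means_: np.ndarray | None = None
    divisors_: np.ndarray | None = None

    _KINDS = ("unit_variance", "pareto", "none")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ModelError("need a 2-D matrix with >=2 samples to fit scaling")
        self.means_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        if self.kind == "none":
            self.divisors_ = np.ones(X.shape[1])
            return self
        sd = X.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            idx = np.where(constant)[0]
            raise ModelError(
                f"constant feature(s) at column(s) {idx.tolist()[:10]}: cannot "
                f"apply {self.kind} scaling; drop them first"
            )
        self.divisors_ = sd if self.kind == "unit_variance" else np.sqrt(sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise ModelError("scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.means_) / self.divisors_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_scaling(X: np.ndarray, kind: str = "pareto", center: bool = True):
    """Fit a :class:`Scaler` and return ``(fitted_scaler, scaled_matrix)``."""
    scaler = Scaler(kind=kind, center=center)
    return scaler, scaler.fit_transform(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray           # samples x components
    loadings: np.ndarray         # features x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    scaler: Scaler


def fit_pca(
    X: np.ndarray, n_components: int, kind: str = "unit_variance", center: bool = True
) -> PcaResult:
    """PCA on the scaled matrix (unit-variance scaling by default)."""
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ModelError(
            f"n_components must be in [1, {limit}] for a {X.shape} matrix, "
            f"got {n_components}"
        )
    scaler, Z = fit_scaling(X, kind=kind, center=center)
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    return PcaResult(scores, pca.components_.T, pca.explained_variance_ratio_, scaler)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive component, binary response)."""

    n_orthogonal: int
    scaler: Scaler
    weights: np.ndarray                      # predictive weight vector (unit norm)
    loadings: np.ndarray                     # predictive loading vector
    scores: np.ndarray                       # predictive training scores
    q: float                                 # inner (y) loading
    ortho_weights: list[np.ndarray] = field(default_factory=list)
    ortho_loadings: list[np.ndarray] = field(default_factory=list)
    ortho_scores: list[np.ndarray] = field(default_factory=list)
    y_mean: float = 0.0
    r2y: float = float("nan")
    q2: float = float("nan")
    vip: np.ndarray | None = None
    cv_folds: int = 7
    seed: int = 0

    def _filter(self, Z: np.ndarray) -> np.ndarray:
        """Remove the orthogonal components from scaled data Z."""
        Z = Z.copy()
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            t_o = Z @ w_o
            Z -= np.outer(t_o, p_o)
        return Z

    def predictive_scores(self, X: np.ndarray) -> np.ndarray:
        """Predictive-component scores for new raw-scale data."""
        Z = self._filter(self.scaler.transform(X))
        return Z @ self.weights

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) dummy response for new data."""
        return self.predictive_scores(X) * self.q + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_response(X) >= 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "n_orthogonal": self.n_orthogonal,
            "scaling": {
                "kind": self.scaler.kind,
                "center": self.scaler.center,
                "means": self.scaler.means_.tolist(),
                "divisors": self.scaler.divisors_.tolist(),
            },
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "q": self.q,
            "ortho_weights": [w.tolist() for w in self.ortho_weights],
            "ortho_loadings": [p.tolist() for p in self.ortho_loadings],
            "y_mean": self.y_mean,
            "r2y": self.r2y,
            "q2": self.q2,
            "vip": None if self.vip is None else self.vip.tolist(),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ModelError("X must be samples x features with one label per sample")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ModelError(f"need exactly 2 classes, got {classes.tolist()}")
    y01 = (y == classes[1]).astype(float) if not np.all(np.isin(y, [0, 1])) else y.astype(float)
    return X, y01


def _opls_core(Z: np.ndarray, yc: np.ndarray, n_orthogonal: int):
    """O-PLS decomposition of scaled/centered Z against centered response."""
    w = Z.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ModelError("response carries no covariance with the features")
    w = w / nw
    Zres = Z.copy()
    ortho_w, ortho_p, ortho_t = [], [], []
    for _ in range(n_orthogonal):
        t = Zres @ w
        p = Zres.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:           # no orthogonal variation left
            break
        w_o = w_o / n_o
        t_o = Zres @ w_o
        p_o = Zres.T @ t_o / (t_o @ t_o)
        Zres = Zres - np.outer(t_o, p_o)
        ortho_w.append(w_o)
        ortho_p.append(p_o)
        ortho_t.append(t_o)
    # final single-component PLS on the filtered matrix
    w_pred = Zres.T @ yc
    w_pred = w_pred / np.linalg.norm(w_pred)
    t = Zres @ w_pred
    p = Zres.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return w_pred, t, p, q, ortho_w, ortho_p, ortho_t


def fit_oplsda(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    kind: str = "pareto",
    cv_folds: int = 7,
    seed: int = 0,
    compute_q2: bool = True,
) -> OplsModel:
    """Fit OPLS-DA with one predictive and ``n_orthogonal`` orthogonal
    components; fills R2Y, VIP, and (optionally) cross-validated Q2.

    The predictive component is oriented so the class coded 1 has positive
    mean score.
    """
    X, y01 = _validate_xy(X, y)
    if n_orthogonal < 0:
        raise ModelError("n_orthogonal must be >= 0")
    n_min = min(int((y01 == 0).sum()), int((y01 == 1).sum()))
    if compute_q2 and n_min < cv_folds:
        raise ModelError(
            f"each class needs >= cv_folds={cv_folds} members, smallest has {n_min}"
        )
    scaler, Z = fit_scaling(X, kind=kind)
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    w, t, p, q, ow, op, ot = _opls_core(Z, yc, n_orthogonal)
    # sign convention: class 1 on the positive side
    if t[y01 == 1].mean() < 0:
        w, t, p, q = -w, -t, -p, -q
    y_hat = t * q + y_mean
    r2y = 1.0 - float(((y01 - y_hat) ** 2).sum() / (yc ** 2).sum())
    model = OplsModel(
        n_orthogonal=n_orthogonal,
        scaler=scaler,
        weights=w,
        loadings=p,
        scores=t,
        q=q,
        ortho_weights=ow,
        ortho_loadings=op,
        ortho_scores=ot,
        y_mean=y_mean,
        r2y=r2y,
        cv_folds=cv_folds,
        seed=seed,
    )
    model.vip = compute_vip(model)
    if compute_q2:
        model.q2 = cross_validated_q2(
            X, y01, n_orthogonal=n_orthogonal, kind=kind, folds=cv_folds, seed=seed
        )
    return model


def compute_vip(model: OplsModel) -> np.ndarray:
    """Classic VIP over the predictive component(s); sum of VIP^2 = p."""
    if model.weights is None:
        raise ModelError("model is not fitted")
    w = model.weights
    p = len(w)
    # single predictive component: the SSY weighting cancels
    return np.sqrt(p) * np.abs(w)


def _stratified_folds(y01: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment, invariant to swapping the two class
    labels: one global shuffled order, fold = within-class rank mod folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y01))
    fold_of = np.empty(len(y01), dtype=int)
    for cls in np.unique(y01):
        members = order[y01[order] == cls]
        fold_of[members] = np.arange(len(members)) % folds
    return fold_of


def cross_validated_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    kind: str = "pareto",
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Q2 = 1 - PRESS/TSS under stratified k-fold CV of the dummy response.

    Scaling and all model components are re-estimated inside each training
    fold; PRESS accumulates squared held-out prediction errors; TSS is the
    total sum of squares of the centered dummy response.
    """
    X, y01 = _validate_xy(X, y)
    n_min = min(int((y01 == 0).sum()), int((y01 == 1).sum()))
    if folds > n_min:
        raise ModelError(f"folds={folds} exceeds smallest class size {n_min}")
    fold_of = _stratified_folds(y01, folds, seed)
    press = 0.0
    for k in range(folds):
        test = np.where(fold_of == k)[0]
        train = np.where(fold_of != k)[0]
        scaler, Z_tr = fit_scaling(X[train], kind=kind)
        y_tr = y01[train]
        y_mean = y_tr.mean()
        yc = y_tr - y_mean
        w, t, p, q, ow, op, _ = _opls_core(Z_tr, yc, n_orthogonal)
        Z_te = scaler.transform(X[test])
        for w_o, p_o in zip(ow, op):
            Z_te = Z_te - np.outer(Z_te @ w_o, p_o)
        y_hat = (Z_te @ w) * q + y_mean
        press += float(((y01[test] - y_hat) ** 2).sum())
    tss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    """Label-permutation assessment of OPLS-DA overfitting."""

    n_permutations: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float
    seed: int

    @property
    def overfit(self) -> bool:
        """Declared overfit when pQ2 >= 0.05 (permuted models do as well)."""
        return self.p_q2 >= 0.05


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    kind: str = "pareto",
    folds: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Refit the model under ``n_permutations`` label permutations.

    p-values use the add-one estimator
    ``p = (#{permuted stat >= observed} + 1) / (n_permutations + 1)``,
    so the smallest attainable p is ``1/(n_permutations + 1)``.
    """
    X, y01 = _validate_xy(X, y)
    rng = np.random.default_rng(seed)
    model = fit_oplsda(
        X, y01, n_orthogonal=n_orthogonal, kind=kind, cv_folds=folds, seed=seed
    )
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y01)
        m = fit_oplsda(
            X, y_perm, n_orthogonal=n_orthogonal, kind=kind, cv_folds=folds,
            seed=seed, compute_q2=True,
        )
        perm_r2y[i] = m.r2y
        perm_q2[i] = m.q2
    p_r2y = (float((perm_r2y >= model.r2y).sum()) + 1.0) / (n_permutations + 1.0)
    p_q2 = (float((perm_q2 >= model.q2).sum()) + 1.0) / (n_permutations + 1.0)
    return PermutationResult(
        n_permutations=n_permutations,
        observed_r2y=model.r2y,
        observed_q2=model.q2,
        permuted_r2y=perm_r2y,
        permuted_q2=perm_q2,
        p_r2y=p_r2y,
        p_q2=p_q2,
        seed=seed,
    )
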