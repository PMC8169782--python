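"""Two-class OPLS-DA with cross-validated Q2 and VIP marker selection.

Orthogonal projections to latent structures (OPLS) splits the X-variation
into a single y-predictive component and ``n_ortho`` components that are
uncorrelated with y.  For a binary class vector this is OPLS-DA; the
class labels are coded 0/1 and centered.

Algorithm (per orthogonal component, on centered/scaled X and y):

    w  = X'y / ||X'y||                (predictive weight)
    t  = X w
    p  = X't / (t't)
    w_o = p - (w'p) w,  normalized    (orthogonal weight)
    t_o = X w_o
    p_o = X't_o / (t_o't_o)
    X  <- X - t_o p_o'                (deflation)

and a final predictive component (w, t, p, q) on the filtered X.  By
construction y't_o = ||X'y|| (w'w_o) = 0, so each orthogonal score is
exactly uncorrelated with y.

Model quality: R2X (X-variance modeled by all components), R2Y (training
fit of y), and Q2Y (predictive fit under stratified k-fold CV with
scaling re-estimated inside each training split).  VIP scores are
computed over the predictive component, so that sum(VIP^2) equals the
number of features and VIP > 1 flags above-average influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalingSpec",
    "OplsModel",
    "fit_opls",
    "cross_validated_q2",
    "vip_scores",
    "select_markers",
    "permutation_validation",
]


@dataclass
class ScalingSpec:
    """Column centering/scaling learned on a training matrix.

    ``mode`` is 'uv' (unit variance), 'pareto' (sqrt of sd) or 'none'.
    Zero-variance columns get scale 1 so they stay (harmlessly) at zero
    after centering.
    """

    center: bool = True
    mode: str = "uv"
    means: np.ndarray | None = None
    scales: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "ScalingSpec":
        if self.mode not in ("uv", "pareto", "none"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        self.means = x.mean(axis=0) if self.center else np.zeros(x.shape[1])
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        if self.mode == "uv":
            self.scales = sd
        elif self.mode == "pareto":
            self.scales = np.sqrt(sd)
        else:
            self.scales = np.ones(x.shape[1])
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.means) / self.scales

    def fresh(self) -> "ScalingSpec":
        return ScalingSpec(center=self.center, mode=self.mode)


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (single predictive component)."""

    w: np.ndarray            # predictive weights, ||w|| = 1
    t: np.ndarray            # predictive scores
    p: np.ndarray            # predictive loadings
    q: float                 # y loading
    w_ortho: np.ndarray      # (n_ortho, n_features)
    t_ortho: np.ndarray      # (n_samples, n_ortho)
    p_ortho: np.ndarray      # (n_ortho, n_features)
    r2x: float
    r2y: float
    scaling: ScalingSpec
    y_mean: float
    classes: tuple = ("0", "1")
    feature_ids: list[str] = field(default_factory=list)
    q2y: float | None = None
    cv_folds: int | None = None
    cv_seed: int | None = None

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    @property
    def vip(self) -> np.ndarray:
        return vip_scores(self)

    def _filter(self, xs: np.ndarray) -> np.ndarray:
        """Remove the orthogonal variation from scaled data."""
        x = xs.copy()
        for wo, po in zip(self.w_ortho, self.p_ortho):
            to = x @ wo
            x -= np.outer(to, po)
        return x

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Continuous y-hat for new raw-scale rows of X."""
        xs = self.scaling.transform(np.asarray(x_new, dtype=float))
        t_new = self._filter(xs) @ self.w
        return t_new * self.q + self.y_mean

    def summary(self) -> dict:
        return {
            "n_ortho": int(self.n_ortho),
            "R2X": round(float(self.r2x), 6),
            "R2Y": round(float(self.r2y), 6),
            "Q2Y": None if self.q2y is None else round(float(self.q2y), 6),
            "cv_folds": self.cv_folds,
        }


def _encode_y(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes}")
    return (y == classes[1]).astype(float), classes


def fit_opls(
    x,
    y,
    n_ortho: int = 1,
    scaling: ScalingSpec | None = None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    ``x`` is samples x features (raw scale; centering/scaling is part of
    the model), ``y`` any two-valued label vector; the higher-sorted
    label is coded 1.  Sign convention: the class coded 1 has positive
    mean predictive score.
    """
    x = np.asarray(x, dtype=float)
    y01, classes = _encode_y(y)
    if x.ndim != 2 or x.shape[0] != y01.size:
        raise ValueError("x must be 2-D with one row per label")
    counts = [int((y01 == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 3:
        raise ValueError(f"each class needs >= 3 samples, got {counts}")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("X has no variance")

    scaling = (scaling or ScalingSpec()).fresh().fit(x)
    xs = scaling.transform(x)
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ss_x = float((xs**2).sum())
    ss_y = float((yc**2).sum())

    xf = xs.copy()
    w_os, t_os, p_os = [], [], []
    for _ in range(n_ortho):
        w = xf.T @ yc
        w /= np.linalg.norm(w)
        t = xf @ w
        p = xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = xf @ w_o
        p_o = xf.T @ t_o / (t_o @ t_o)
        xf = xf - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)

    w = xf.T @ yc
    w /= np.linalg.norm(w)
    t = xf @ w
    p = xf.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))

    # sign convention: class 1 on the positive side
    if t[y01 == 1].mean() < 0:
        w, t, p, q = -w, -t, -p, -q

    resid = xf - np.outer(t, p)
    r2x = 1.0 - float((resid**2).sum()) / ss_x
    yhat = t * q
    r2y = 1.0 - float(((yc - yhat) ** 2).sum()) / ss_y

    return OplsModel(
        w=w, t=t, p=p, q=q,
        w_ortho=np.array(w_os).reshape(len(w_os), x.shape[1]),
        t_ortho=np.array(t_os).T.reshape(x.shape[0], len(t_os)),
        p_ortho=np.array(p_os).reshape(len(p_os), x.shape[1]),
        r2x=r2x, r2y=r2y,
        scaling=scaling, y_mean=y_mean, classes=classes,
    )


def _stratified_folds(y01: np.ndarray, folds: int, rng: np.random.Generator):
    """Deterministic stratified fold assignment from the run seed."""
    assign = np.empty(y01.size, dtype=int)
    for v in (0.0, 1.0):
        idx = np.flatnonzero(y01 == v)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validated_q2(
    x,
    y,
    folds: int = 7,
    seed: int = 0,
    n_ortho: int = 1,
    scaling: ScalingSpec | None = None,
) -> float:
    """Q2Y by stratified k-fold cross-validation.

    Q2 = 1 - PRESS / SS(y_centered), with PRESS accumulated over
    held-out predictions; scaling and the model are re-estimated inside
    each training split.  ``folds = n_samples`` gives leave-one-out.
    """
    x = np.asarray(x, dtype=float)
    y01, _ = _encode_y(y)
    n = y01.size
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(y01, folds, rng)
    press = 0.0
    for k in range(folds):
        test = assign == k
        train = ~test
        if len(np.unique(y01[train])) < 2:
            raise ValueError(f"fold {k}: training split lost a class")
        model = fit_opls(x[train], y01[train], n_ortho=n_ortho, scaling=scaling)
        yhat = model.predict(x[test])
        press += float(((y01[test] - yhat) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ss


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component.

    With a single component and ||w|| = 1 this reduces to
    sqrt(n_features) * |w_j|, so sum(VIP^2) = n_features exactly.
    """
    w = model.w
    p_feat = w.size
    ssy = (model.t @ model.t) * model.q**2  # y-variance captured
    wa2 = (w / np.linalg.norm(w)) ** 2
    return np.sqrt(p_feat * wa2 * ssy / ssy)


def select_markers(model: OplsModel, threshold: float = 1.0) -> list[str]:
    """Feature ids with VIP strictly above ``threshold``, by VIP descending."""
    vip = vip_scores(model)
    ids = model.feature_ids or [str(i) for i in range(vip.size)]
    order = np.argsort(-vip, kind="stable")
    return [ids[i] for i in order if vip[i] > threshold]


def permutation_validation(
    x,
    y,
    n_perm: int = 100,
    seed: int = 0,
    folds: int = 7,
    n_ortho: int = 1,
) -> dict:
    """Label-permutation null for R2Y/Q2Y.

    Refits the model on ``n_perm`` random permutations of y and reports
    the null distributions plus the empirical p-value of the observed
    Q2Y (rank among permuted values, with the +1 correction).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    x = np.asarray(x, dtype=float)
    y01, _ = _encode_y(y)
    rng = np.random.default_rng(seed)
    obs_model = fit_opls(x, y01, n_ortho=n_ortho)
    obs_q2 = cross_validated_q2(x, y01, folds=folds, seed=seed, n_ortho=n_ortho)
    null_r2, null_q2 = [], []
    for _ in range(n_perm):
        yp = rng.permutation(y01)
        m = fit_opls(x, yp, n_ortho=n_ortho)
        null_r2.append(m.r2y)
        null_q2.append(
            cross_validated_q2(x, yp, folds=folds,
                               seed=int(rng.integers(2**31)), n_ortho=n_ortho))
    null_q2 = np.array(null_q2)
    p_emp = (1 + int((null_q2 >= obs_q2).sum())) / (n_perm + 1)
    return {
        "observed_r2y": float(obs_model.r2y),
        "observed_q2y": float(obs_q2),
        "null_r2y": [float(v) for v in null_r2],
        "null_q2y": [float(v) for v in null_q2],
        "p_q2y": float(p_emp),
    }
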