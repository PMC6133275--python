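"""SDM algorithms behind one fit/predict contract.

Two classic presence-only methods are implemented from scratch:

* Envelope Score — a quantitative rectilinear climate envelope: the score
  of a cell is the fraction of variables falling inside the min-max range
  of the training presences.
* Mahalanobis distance — distance to the presence centroid accounting for
  the covariance of the presences, with a pseudo-inverse fallback when the
  covariance matrix is ill-conditioned (the behaviour that matters under
  strong collinearity).

Two presence-versus-background learners stand in for the complex
parametric algorithm class (Maxent-style and SVM-style tools):

* LQ_BG — a regularized logistic model on linear + quadratic features,
  standardized by background statistics.
* KERNEL_BG — a radial-basis-function kernel classifier (Nystroem feature
  map + regularized logistic link); its decision score is rescaled to
  [0, 1] by min-max over the prediction extent.

Both stand-ins are honest substitutes, not re-implementations of the
original binaries; an adapter seam (any object with ``predict``) lets a
user plug external engines into the experiment runner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.kernel_approximation import Nystroem
from sklearn.linear_model import LogisticRegression

__all__ = [
    "EnvelopeModel",
    "MahalanobisModel",
    "LQBackgroundModel",
    "KernelBackgroundModel",
    "FittedSDM",
    "fit_envelope",
    "predict_envelope",
    "fit_mahalanobis",
    "predict_mahalanobis",
    "fit_lq_background",
    "fit_kernel_background",
    "fit_sdm",
    "predict_surface",
    "ALGORITHMS",
]

ALGORITHMS = ("ES", "MAHAL", "LQ_BG", "KERNEL_BG")


# ---------------------------------------------------------------------------
# Envelope Score

@dataclass
class EnvelopeModel:
    min_v: np.ndarray
    max_v: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_envelope(self, X)

    def params_dict(self) -> dict:
        return {"min": self.min_v.tolist(), "max": self.max_v.tolist()}


def fit_envelope(presence_env: np.ndarray) -> EnvelopeModel:
    X = np.atleast_2d(np.asarray(presence_env, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("envelope requires at least one presence")
    return EnvelopeModel(min_v=X.min(axis=0), max_v=X.max(axis=0))


def predict_envelope(model: EnvelopeModel, x: np.ndarray) -> np.ndarray:
    """Fraction of variables inside the training envelope, in {0, 1/V, ..., 1}."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != len(model.min_v):
        raise ValueError("dimension mismatch")
    inside = (X >= model.min_v) & (X <= model.max_v)
    score = inside.mean(axis=1)
    return score if np.ndim(x) > 1 else score[0]


# ---------------------------------------------------------------------------
# Mahalanobis distance

@dataclass
class MahalanobisModel:
    mean: np.ndarray
    cov: np.ndarray
    inv: np.ndarray
    inverse_kind: str  # "standard" | "pseudo"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_mahalanobis(self, X)

    def params_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "inverse_kind": self.inverse_kind}


def fit_mahalanobis(presence_env: np.ndarray, rcond_eps: float = 1e-10) -> MahalanobisModel:
    """Presence mean and covariance; pseudo-inverse when the reciprocal
    condition number of the covariance falls below ``rcond_eps``."""
    X = np.atleast_2d(np.asarray(presence_env, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("Mahalanobis requires at least two presences")
    m = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    sv = np.linalg.svd(S, compute_uv=False)
    rcond = sv.min() / sv.max() if sv.max() > 0 else 0.0
    if rcond < rcond_eps:
        inv = np.linalg.pinv(S, rcond=rcond_eps)
        kind = "pseudo"
    else:
        inv = np.linalg.inv(S)
        kind = "standard"
    return MahalanobisModel(mean=m, cov=S, inv=inv, inverse_kind=kind)


def mahalanobis_sq(model: MahalanobisModel, x: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != len(model.mean):
        raise ValueError("dimension mismatch")
    D = X - model.mean
    d2 = np.einsum("ij,jk,ik->i", D, model.inv, D)
    if d2.min() < -1e-8:
        raise ValueError(f"negative squared distance: {d2.min()}")
    return np.clip(d2, 0.0, None)


def predict_mahalanobis(model: MahalanobisModel, x: np.ndarray) -> np.ndarray:
    """Suitability = 1 / (1 + d).  Any strictly decreasing transform of the
    distance yields identical thresholded maps; this one is fixed for
    reproducibility."""
    d2 = mahalanobis_sq(model, x)
    s = 1.0 / (1.0 + np.sqrt(d2))
    return s if np.ndim(x) > 1 else s[0]


# ---------------------------------------------------------------------------
# Background learners

@dataclass
class LQBackgroundModel:
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    keep: np.ndarray  # features with nonzero background variance
    clf: LogisticRegression
    n_vars: int
    hinge_knots: np.ndarray | None = None  # (n_knots, V) or None

    def _features(self, X: np.ndarray) -> np.ndarray:
        F = np.hstack([X, X**2])
        if self.hinge_knots is not None:
            hinges = [np.clip(X - k, 0.0, None) for k in self.hinge_knots]
            F = np.hstack([F] + hinges)
        return (F[:, self.keep] - self.feat_mean) / self.feat_sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_vars:
            raise ValueError("dimension mismatch")
        return self.clf.predict_proba(self._features(X))[:, 1]

    @property
    def coef_norm(self) -> float:
        return float(np.linalg.norm(self.clf.coef_))

    def params_dict(self) -> dict:
        return {
            "coef": self.clf.coef_.ravel().tolist(),
            "intercept": float(self.clf.intercept_[0]),
        }


def fit_lq_background(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    regularization: float = 1.0,
    hinge: bool = False,
    n_hinge_knots: int = 4,
) -> LQBackgroundModel:
    """Penalized logistic presence-vs-background fit on {x, x^2} features.

    Features are standardized by background statistics; zero-variance
    features are dropped with a warning.  ``regularization`` is the L2
    penalty weight (larger = smaller coefficients).  With ``hinge=True``,
    per-variable hinge features at background quantile knots are appended.
    """
    P = np.atleast_2d(np.asarray(presence_env, dtype=float))
    B = np.atleast_2d(np.asarray(background_env, dtype=float))
    if P.shape[0] < 5:
        raise ValueError("need at least 5 presences")
    if B.shape[0] < 50:
        raise ValueError("need at least 50 background points")
    knots = None
    if hinge:
        qs = np.linspace(0.1, 0.9, n_hinge_knots)
        knots = np.quantile(B, qs, axis=0)
    raw = lambda X: (
        np.hstack([X, X**2])
        if knots is None
        else np.hstack([X, X**2] + [np.clip(X - k, 0.0, None) for k in knots])
    )
    FB = raw(B)
    sd = FB.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
    mean = FB[:, keep].mean(axis=0)
    sd = sd[keep]
    Xtr = np.vstack([raw(P), FB])[:, keep]
    Xtr = (Xtr - mean) / sd
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    clf = LogisticRegression(
        C=1.0 / regularization,
        class_weight="balanced",
        max_iter=2000,
        solver="lbfgs",
    )
    clf.fit(Xtr, y)
    return LQBackgroundModel(
        feat_mean=mean,
        feat_sd=sd,
        keep=keep,
        clf=clf,
        n_vars=P.shape[1],
        hinge_knots=knots,
    )


@dataclass
class KernelBackgroundModel:
    env_mean: np.ndarray
    env_sd: np.ndarray
    mapper: Nystroem
    clf: LogisticRegression
    n_vars: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw decision score (unbounded); rescaled to [0, 1] per surface
        by :func:`predict_surface`."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_vars:
            raise ValueError("dimension mismatch")
        Z = (X - self.env_mean) / self.env_sd
        return self.clf.decision_function(self.mapper.transform(Z))

    def params_dict(self) -> dict:
        return {"gamma": float(self.mapper.gamma), "n_components": self.mapper.n_components}


def fit_kernel_background(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    bandwidth: float = 1.0,
    regularization: float = 1.0,
    n_components: int = 200,
    seed: int = 0,
) -> KernelBackgroundModel:
    """Radial-kernel presence-vs-background classifier.

    Inputs are standardized by background statistics; the RBF kernel
    (gamma = 1 / (2 bandwidth^2 V)) is approximated by a Nystroem feature
    map and classified with a balanced, L2-penalized logistic link.  The
    decision score is a continuous suitability index.
    """
    P = np.atleast_2d(np.asarray(presence_env, dtype=float))
    B = np.atleast_2d(np.asarray(background_env, dtype=float))
    if P.shape[0] < 5:
        raise ValueError("need at least 5 presences")
    if B.shape[0] < 50:
        raise ValueError("need at least 50 background points")
    mean = B.mean(axis=0)
    sd = B.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = np.vstack([P, B])
    Z = (Xtr - mean) / sd
    gamma = 1.0 / (2.0 * bandwidth**2 * P.shape[1])
    mapper = Nystroem(
        gamma=gamma,
        n_components=min(n_components, Z.shape[0]),
        random_state=seed,
    )
    Phi = mapper.fit_transform(Z)
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    clf = LogisticRegression(
        C=1.0 / regularization, class_weight="balanced", max_iter=2000
    )
    clf.fit(Phi, y)
    return KernelBackgroundModel(
        env_mean=mean, env_sd=sd, mapper=mapper, clf=clf, n_vars=P.shape[1]
    )


# ---------------------------------------------------------------------------
# Common contract

@dataclass
class FittedSDM:
    """A fitted model plus the metadata the experiment runner needs."""

    algorithm_id: str
    predictor_set_id: str
    layer_names: list[str]
    model: object  # anything with .predict(X)
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def fit_sdm(
    algorithm_id: str,
    presence_env: np.ndarray,
    background_env: np.ndarray | None = None,
    predictor_set_id: str = "RAW",
    layer_names: list[str] | None = None,
    seed: int = 0,
    **kwargs,
) -> FittedSDM:
    """Dispatch to the requested algorithm under the common contract."""
    if algorithm_id == "ES":
        model = fit_envelope(presence_env)
    elif algorithm_id == "MAHAL":
        model = fit_mahalanobis(presence_env, **kwargs)
    elif algorithm_id == "LQ_BG":
        if background_env is None:
            raise ValueError("LQ_BG requires background_env")
        model = fit_lq_background(presence_env, background_env, **kwargs)
    elif algorithm_id == "KERNEL_BG":
        if background_env is None:
            raise ValueError("KERNEL_BG requires background_env")
        model = fit_kernel_background(presence_env, background_env, seed=seed, **kwargs)
    else:
        raise ValueError(f"unknown algorithm: {algorithm_id}")
    P = np.atleast_2d(presence_env)
    return FittedSDM(
        algorithm_id=algorithm_id,
        predictor_set_id=predictor_set_id,
        layer_names=list(layer_names or []),
        model=model,
        meta={
            "n_presence": P.shape[0],
            "n_background": 0 if background_env is None else len(background_env),
        },
    )


def predict_surface(model: FittedSDM, stack) -> "Layer":
    """Predict over all masked cells of a stack; returns a suitability Layer.

    KERNEL_BG decision scores are min-max rescaled to [0, 1] over the
    prediction extent (a monotone transform, so thresholded maps are
    unchanged)."""
    from .rasters import Layer

    if model.layer_names and list(stack.names) != model.layer_names:
        raise ValueError(
            f"stack layers {stack.names} do not match model's {model.layer_names}"
        )
    X = stack.env_matrix()
    s = np.asarray(model.predict(X), dtype=float)
    if model.algorithm_id == "KERNEL_BG":
        lo, hi = s.min(), s.max()
        s = (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5)
    vals = np.full(stack.grid.shape, np.nan)
    vals[stack.mask] = s
    return Layer(stack.grid, vals, stack.mask.copy())
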