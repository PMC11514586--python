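"""Partial least squares: NIPALS fit, exact LOO cross-validation, component
selection and PCA scores.

The reference fit is single-y NIPALS with deflation.  ``loo_q2`` is a naive
leave-one-out loop that refits the model from scratch for every fold - no
deflation shortcut is allowed to change a held-out prediction.  A covariance
based "improved kernel" algorithm (working only on X'X and X'y) is provided
as a fast path for design-sized cross-validation loops (FFD); it reproduces
the NIPALS regression vector to machine precision and is tested against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

SCALINGS = ("none", "autoscale", "pareto")
_RANK_TOL = 1e-10


class RankError(ValueError):
    pass


def _preprocess(X: np.ndarray, y: np.ndarray, scaling: str):
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    if scaling == "autoscale":
        x_scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        x_scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    else:
        x_scale = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_scale
    y_mean = float(np.mean(y))
    return Xs, y - y_mean, x_mean, x_scale, y_mean


@dataclass
class PLSModel:
    """Fitted PLS model with preprocessing constants in original units."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray      # W, (p, A)
    x_loadings: np.ndarray   # P, (p, A)
    y_loadings: np.ndarray   # q, (A,)
    scores: np.ndarray       # T, (n, A)
    n_components: int
    scaling: str = "autoscale"
    training_ids: list[str] = field(default_factory=list)

    @property
    def coef_scaled(self) -> np.ndarray:
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients in original descriptor units."""
        return self.coef_scaled / self.x_scale

    @property
    def intercept(self) -> float:
        return self.y_mean - float(self.x_mean @ self.coef)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return self.y_mean + ((X_new - self.x_mean) / self.x_scale) @ self.coef_scaled

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.y_mean + self.scores @ self.y_loadings

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None, variable_columns=None, config_hash=None):
        doc = {
            "format": "grindqsar-pls",
            "version": 1,
            "scaling": self.scaling,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coefficients": self.coef.tolist(),
            "training_ids": list(self.training_ids),
        }
        if variable_columns is not None:
            doc["variable_columns"] = list(variable_columns)
        if config_hash is not None:
            doc["config_hash"] = config_hash
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            with open(source) as fh:
                doc = json.load(fh)
        else:
            doc = source
        return cls(
            x_mean=np.array(doc["x_mean"]),
            x_scale=np.array(doc["x_scale"]),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"]),
            x_loadings=np.array(doc["x_loadings"]),
            y_loadings=np.array(doc["y_loadings"]),
            scores=np.array(doc["scores"]),
            n_components=int(doc["n_components"]),
            scaling=doc.get("scaling", "autoscale"),
            training_ids=doc.get("training_ids", []),
        )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            scaling: str = "autoscale", ids: list[str] | None = None) -> PLSModel:
    """NIPALS PLS1 with deflation.

    Raises :class:`RankError` (naming the achievable rank) when the centered,
    scaled X cannot support ``n_components`` latent variables, and
    ``ValueError`` for constant y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; PLS undefined")

    Xs, yc, x_mean, x_scale, y_mean = _preprocess(X, y, scaling)
    Xd, yd = Xs.copy(), yc.copy()
    n, p = Xs.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    scale0 = float(np.abs(Xs).sum()) + 1.0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < _RANK_TOL * scale0:
            raise RankError(
                f"requested {n_components} components but X supports only {a}")
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < _RANK_TOL:
            raise RankError(
                f"requested {n_components} components but X supports only {a}")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd -= t * qa
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    return PLSModel(x_mean, x_scale, y_mean, W, P, q, T, n_components,
                    scaling, list(ids) if ids is not None else [])


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation (naive refit; the definition)
# ---------------------------------------------------------------------------

def loo_predictions(X: np.ndarray, y: np.ndarray, n_components: int,
                    scaling: str = "autoscale") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 compounds")
    if n_components >= n - 1:
        raise ValueError("n_components must be < n - 1 for LOO")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_pls(X[keep], y[keep], n_components, scaling)
        preds[i] = model.predict(X[i])[0]
    return preds


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           scaling: str = "autoscale") -> tuple[float, float]:
    """LOO cross-validated Q2 and PRESS.

    PRESS is the sum of squared held-out prediction errors; Q2 = 1 -
    PRESS / sum((y - mean(y))^2).  Each fold's model is refit from scratch
    on the remaining n-1 compounds (including its centering constants).
    """
    y = np.asarray(y, dtype=float).ravel()
    preds = loo_predictions(X, y, n_components, scaling)
    press = float(np.sum((y - preds) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss, press


def select_components(X: np.ndarray, y: np.ndarray, a_max: int = 5,
                      scaling: str = "autoscale") -> tuple[int, list[float]]:
    """Pick the number of latent variables maximizing Q2(LOO); ties -> fewer.

    Returns ``(a_star, q2_per_a)``.  Warns when even the best Q2 is <= 0
    (no predictive structure).
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    q2s: list[float] = []
    for a in range(1, a_max + 1):
        try:
            q2, _ = loo_q2(X, y, a, scaling)
        except (RankError, ValueError):
            break
        q2s.append(q2)
    if not q2s:
        raise RankError("no usable components")
    best = int(np.argmax(q2s))  # first occurrence wins ties -> smaller A
    if q2s[best] <= 0:
        warnings.warn("best Q2(LOO) <= 0: y shows no predictive structure",
                      stacklevel=2)
    return best + 1, q2s


def pca_scores(X: np.ndarray, k: int,
               scaling: str = "autoscale") -> tuple[np.ndarray, np.ndarray]:
    """SVD-based PCA scores and explained-variance fractions on scaled X."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must lie in 1..{min(n, p)}")
    Xs, _, _, _, _ = _preprocess(X, np.zeros(n), scaling)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    frac = s ** 2 / np.sum(s ** 2)
    return U[:, :k] * s[:k], frac[:k]


# ---------------------------------------------------------------------------
# Covariance-based fast path (Dayal & MacGregor improved kernel, PLS1)
# ---------------------------------------------------------------------------

def kernel_pls_coef(XtX: np.ndarray, Xty: np.ndarray, n_components: int) -> np.ndarray:
    """Regression vector (scaled units) from X'X and X'y only."""
    p = len(Xty)
    A = n_components
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    b = Xty.astype(float).copy()
    used = 0
    for a in range(A):
        wn = np.linalg.norm(b)
        if wn < 1e-14:
            break
        w = b / wn
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        Ar = XtX @ r
        tt = float(r @ Ar)
        if tt < _RANK_TOL:
            break
        P[:, a] = Ar / tt
        q[a] = float(r @ b) / tt
        R[:, a] = r
        b = b - (tt * q[a]) * P[:, a]
        used = a + 1
    return R[:, :used] @ q[:used]


def cv_sdep_kernel(Xs: np.ndarray, yc: np.ndarray, n_components: int,
                   groups: list[np.ndarray],
                   XtX: np.ndarray | None = None,
                   Xty: np.ndarray | None = None) -> float:
    """Cross-validated SDEP = sqrt(PRESS/n) via covariance downdating.

    ``Xs``/``yc`` must already be centered/scaled (dataset-level constants);
    this is the speed path used inside design-sized FFD loops.
    """
    if XtX is None:
        XtX = Xs.T @ Xs
    if Xty is None:
        Xty = Xs.T @ yc
    press = 0.0
    for g in groups:
        Xg, yg = Xs[g], yc[g]
        coef = kernel_pls_coef(XtX - Xg.T @ Xg, Xty - Xg.T @ yg, n_components)
        press += float(np.sum((yg - Xg @ coef) ** 2))
    return float(np.sqrt(press / len(yc)))
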