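"""Internal/external model validation and the leverage applicability domain.

Internal statistics (training set): R2, PRESS, Q2(LOO), RMSEE.  Following
the convention adopted here, RMSEE is sqrt(PRESS/n) (a cross-validated
error); the conventional fitted-residual RMSE is reported separately as
``rmse_fit`` to avoid ambiguity.

External statistics (test set): R2pred (against the training mean), RMSEP,
and the Roy rm2 metric family built on the Golbraikh-Tropsha through-origin
regressions:

    k  = sum(y*yhat)/sum(y^2)        (yhat regressed on y through 0)
    k' = sum(y*yhat)/sum(yhat^2)     (y regressed on yhat through 0)
    r0^2  = 1 - sum((yhat - k*y)^2)  / sum((yhat - mean(yhat))^2)
    r0'^2 = 1 - sum((y - k'*yhat)^2) / sum((y - mean(y))^2)
    rm2   = r^2 * (1 - sqrt(r^2 - r0^2)),   rm2' with r0'^2

Applicability domain: leverage of a compound in the space of the selected
descriptors, h = 1/n + x_c' (Xc'Xc)^+ x_c, against the critical value
h* = 3(p+1)/n; a compound is outside the domain when h > h* or its absolute
standardized residual exceeds 3 (Williams plot).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    # internal
    r2: float | None = None
    press: float | None = None
    q2: float | None = None
    rmsee: float | None = None
    rmse_fit: float | None = None
    n_train: int | None = None
    # external
    r2_pred: float | None = None
    rmsep: float | None = None
    r2_test: float | None = None
    r02: float | None = None
    r0p2: float | None = None
    k: float | None = None
    k_prime: float | None = None
    rm2: float | None = None
    rm2_prime: float | None = None
    rm2_mean: float | None = None
    delta_rm2: float | None = None
    ratio_r0p2: float | None = None   # (r2 - r0'^2)/r2
    ratio_r02: float | None = None    # (r2 - r0^2)/r2, other orientation
    n_test: int | None = None
    # applicability domain
    h_star: float | None = None
    outlier_ids: list[str] | None = None

    def merged(self, other: "ValidationReport") -> "ValidationReport":
        data = asdict(self)
        for key, value in asdict(other).items():
            if value is not None:
                data[key] = value
        return ValidationReport(**data)

    def to_json(self, path=None, config_hash: str | None = None):
        doc = {k: v for k, v in asdict(self).items() if v is not None}
        doc["criteria"] = criteria_flags(self)
        if config_hash is not None:
            doc["config_hash"] = config_hash
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc

    def summary_table(self) -> str:
        """Two-column human-readable table of all populated quantities."""
        rows = [(k, f"{v:.3f}" if isinstance(v, float) else str(v))
                for k, v in asdict(self).items() if v is not None]
        flags = criteria_flags(self)
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Validation report", "-" * 30]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        lines += ["-" * 30]
        lines += [f"{k:<{width}}{'pass' if v else 'FAIL'}" for k, v in flags.items()]
        return "\n".join(lines)


def internal_validation(y_train, yhat_train, press_from_loo: float) -> ValidationReport:
    """Training-set statistics; PRESS comes from the LOO procedure."""
    y = np.asarray(y_train, dtype=float).ravel()
    yhat = np.asarray(yhat_train, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must be aligned")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 training compounds")
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        raise ValueError("zero variance in y")
    r2 = float(np.sum((yhat - y.mean()) ** 2)) / ss
    q2 = 1.0 - press_from_loo / ss
    return ValidationReport(
        r2=r2, press=float(press_from_loo), q2=q2,
        rmsee=float(np.sqrt(press_from_loo / n)),
        rmse_fit=float(np.sqrt(np.mean((y - yhat) ** 2))),
        n_train=n)


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        log.warning("zero variance in observed or predicted values; r2 set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _rm2(r2: float, r02: float) -> float:
    radicand = r2 - r02
    if radicand < 0:
        log.info("r2 < r0^2 by %.3g; radicand clamped at 0", -radicand)
        radicand = 0.0
    return r2 * (1.0 - np.sqrt(radicand))


def external_validation(y_test, yhat_test, ybar_train: float) -> ValidationReport:
    """Test-set statistics (R2pred, RMSEP, rm2 metric family)."""
    y = np.asarray(y_test, dtype=float).ravel()
    yhat = np.asarray(yhat_test, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must be aligned")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 test compounds")
    press = float(np.sum((y - yhat) ** 2))
    r2_pred = 1.0 - press / float(np.sum((y - ybar_train) ** 2))
    rmsep = float(np.sqrt(press / n))

    r2 = _pearson_r2(y, yhat)
    k = float(np.sum(y * yhat) / np.sum(y * y))
    k_prime = float(np.sum(y * yhat) / np.sum(yhat * yhat))
    ss_hat = float(np.sum((yhat - yhat.mean()) ** 2))
    ss_obs = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - float(np.sum((yhat - k * y) ** 2)) / ss_hat if ss_hat > 0 else 0.0
    r0p2 = 1.0 - float(np.sum((y - k_prime * yhat) ** 2)) / ss_obs if ss_obs > 0 else 0.0
    rm2 = _rm2(r2, r02)
    rm2_prime = _rm2(r2, r0p2)
    return ValidationReport(
        r2_pred=float(r2_pred), rmsep=rmsep, r2_test=r2,
        r02=float(r02), r0p2=float(r0p2), k=k, k_prime=k_prime,
        rm2=float(rm2), rm2_prime=float(rm2_prime),
        rm2_mean=float((rm2 + rm2_prime) / 2),
        delta_rm2=float(abs(rm2 - rm2_prime)),
        ratio_r0p2=float((r2 - r0p2) / r2) if r2 > 0 else None,
        ratio_r02=float((r2 - r02) / r2) if r2 > 0 else None,
        n_test=n)


# ---------------------------------------------------------------------------
# Applicability domain
# ---------------------------------------------------------------------------

@dataclass
class WilliamsData:
    table: pd.DataFrame      # id, leverage, std_residual, set, outside_ad
    h_star: float
    residual_threshold: float = 3.0

    @property
    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["outside_ad"], "id"].tolist()

    def to_csv(self, path, config_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash={config_hash}\n")
            fh.write(f"# h_star={self.h_star:.6f}\n")
            self.table.to_csv(fh, index=False)


def critical_leverage(n_train: int, p: int) -> float:
    """h* = 3(p+1)/n with p the number of selected descriptors."""
    if n_train <= 0 or p < 0:
        raise ValueError("invalid n or p")
    return 3.0 * (p + 1) / n_train


def leverages(X_train: np.ndarray, X_query: np.ndarray | None = None,
              include_intercept: bool = True) -> np.ndarray:
    """Leverage of query rows in the centered training descriptor space.

    ``include_intercept=False`` gives the SPSS-style centered leverage
    (without the 1/n term).  Singular covariance falls back to the
    pseudoinverse with the achieved rank logged.
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    G = Xc.T @ Xc
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[0]:
        log.warning("singular descriptor covariance: rank %d < %d, using "
                    "pseudoinverse", rank, G.shape[0])
    Ginv = np.linalg.pinv(G)
    Q = Xc if X_query is None else np.atleast_2d(np.asarray(X_query, float)) - mean
    h = np.einsum("ij,jk,ik->i", Q, Ginv, Q)
    if include_intercept:
        h = h + 1.0 / n
    return h


def applicability_domain(X_train: np.ndarray, ids_train: list[str],
                         std_residuals_train: np.ndarray,
                         X_test: np.ndarray | None = None,
                         ids_test: list[str] | None = None,
                         std_residuals_test: np.ndarray | None = None,
                         include_intercept: bool = True) -> WilliamsData:
    """Williams-plot data: leverage vs standardized residual per compound.

    ``X_*`` must be restricted to the selected ("key") descriptors; ``p`` for
    h* is their count.  Standardized residuals are supplied by the caller
    (prediction residuals divided by the training RMSEE, by this package's
    convention).
    """
    X_train = np.asarray(X_train, dtype=float)
    n, p = X_train.shape
    h_star = critical_leverage(n, p)
    h_train = leverages(X_train, None, include_intercept)
    frames = [pd.DataFrame({
        "id": list(ids_train), "leverage": h_train,
        "std_residual": np.asarray(std_residuals_train, float),
        "set": "train"})]
    if X_test is not None:
        h_test = leverages(X_train, X_test, include_intercept)
        frames.append(pd.DataFrame({
            "id": list(ids_test), "leverage": h_test,
            "std_residual": np.asarray(std_residuals_test, float),
            "set": "test"}))
    table = pd.concat(frames, ignore_index=True)
    table["outside_ad"] = ((table["leverage"] > h_star)
                           | (table["std_residual"].abs() > 3.0))
    return WilliamsData(table=table, h_star=h_star)


def plot_williams(wd: WilliamsData, path=None):
    """Williams plot (leverage vs standardized residual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, marker in (("train", "o"), ("test", "s")):
        sub = wd.table[wd.table["set"] == label]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker,
                       label=label, alpha=0.8)
    ax.axvline(wd.h_star, color="k", ls="--", lw=1, label="h*")
    for yv in (-wd.residual_threshold, wd.residual_threshold):
        ax.axhline(yv, color="r", ls=":", lw=1)
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Acceptance criteria of the validated-model checklist
# ---------------------------------------------------------------------------

def criteria_flags(report: ValidationReport) -> dict[str, bool]:
    """The ten pass/fail criteria; strict inequalities as printed.

    A model is declared valid only when every populated criterion passes.
    Criteria whose inputs are missing are omitted from the dict.
    """
    flags: dict[str, bool] = {}
    r = report
    if r.r2 is not None:
        flags["r2_gt_0.9"] = r.r2 > 0.9
    if r.q2 is not None:
        flags["q2_gt_0.5"] = r.q2 > 0.5
    if r.r2_pred is not None:
        flags["r2_pred_gt_0.6"] = r.r2_pred > 0.6
    if r.rmsep is not None and r.rmsee is not None:
        flags["rmsep_le_2rmsee"] = r.rmsep <= 2.0 * r.rmsee
    if r.rm2 is not None:
        flags["rm2_gt_0.5"] = r.rm2 > 0.5
    if r.rm2_prime is not None:
        flags["rm2_prime_gt_0.5"] = r.rm2_prime > 0.5
    if r.rm2_mean is not None:
        flags["rm2_mean_gt_0.5"] = r.rm2_mean > 0.5
    if r.delta_rm2 is not None:
        flags["delta_rm2_lt_0.2"] = r.delta_rm2 < 0.2
    if r.ratio_r0p2 is not None:
        flags["ratio_lt_0.1"] = r.ratio_r0p2 < 0.1
    if r.k_prime is not None:
        flags["k_prime_in_0.85_1.15"] = 0.85 <= r.k_prime <= 1.15
    flags["valid"] = all(flags.values())
    return flags
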