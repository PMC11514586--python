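"""Model/Results facade for GRIND-descriptor PLS QSAR.

`GrindPLS` is constructed from a descriptor matrix and an activity vector
(statsmodels-style: data in, `.fit()` out), optionally performing FFD
variable selection, latent-variable selection by LOO Q2, and producing a
`GrindPLSResults` object that carries coefficients, internal validation,
and methods for external validation, the applicability domain, prediction
and variable ranking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import pls, validation
from .feature_selection import FFDResult, ffd_select
from .grind import DescriptorMatrix, VariableMeta
from .interpret import VariableReportEntry, rank_variables, variable_report_frame
from .validation import ValidationReport, WilliamsData, applicability_domain, criteria_flags


class GrindPLS:
    """PLS QSAR model on GRIND descriptors.

    Parameters
    ----------
    endog : array-like
        Training activities (pIC50).
    exog : ndarray
        Training descriptor rows aligned with ``endog``.
    var_meta : list of VariableMeta, optional
        Per-column probe-pair/distance-bin metadata.
    ids : list of str, optional
        Compound identifiers.
    scaling : {"autoscale", "pareto", "none"}
        Column scaling applied before PLS (unit variance by default).
    """

    def __init__(self, endog, exog, var_meta: list[VariableMeta] | None = None,
                 ids: list[str] | None = None, scaling: str = "autoscale"):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog and exog must have matching rows")
        self.var_meta = var_meta
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(self.endog))]
        self.scaling = scaling

    @classmethod
    def from_descriptor_matrix(cls, dm: DescriptorMatrix, activities: pd.DataFrame,
                               ids: list[str] | None = None,
                               scaling: str = "autoscale") -> "GrindPLS":
        """Build from a DescriptorMatrix and an activity table (id, pIC50)."""
        use_ids = ids if ids is not None else dm.ids
        act = activities.set_index(activities["id"].astype(str))["pIC50"]
        y = act.loc[use_ids].to_numpy(dtype=float)
        X = dm.rows(use_ids)
        return cls(y, X, var_meta=dm.meta, ids=use_ids, scaling=scaling)

    def fit(self, n_components: int | None = None, a_max: int = 5,
            ffd: bool = False, ffd_seed: int = 0,
            ffd_kwargs: dict | None = None,
            min_nonzero_fraction: float = 0.0) -> "GrindPLSResults":
        """Fit, optionally after FFD variable selection.

        ``n_components=None`` selects the number of latent variables by
        maximizing LOO Q2 over ``1..a_max`` (ties to the smaller number).
        ``min_nonzero_fraction`` drops low-occupancy descriptor columns
        (nonzero in fewer than that fraction of training compounds) before
        any selection - sparse correlogram bins behave as near-indicator
        variables and only add cross-validation noise.
        """
        X = self.exog
        meta = self.var_meta
        selected = np.arange(X.shape[1])
        if min_nonzero_fraction > 0.0:
            occupancy = (X != 0).mean(axis=0)
            selected = selected[occupancy >= min_nonzero_fraction]
            X = X[:, selected]
            if meta is not None:
                meta = [meta[i] for i in selected]
        ffd_result: FFDResult | None = None
        if ffd:
            kwargs = dict(ffd_kwargs or {})
            a_ffd = kwargs.pop("n_components", 2)
            ffd_result = ffd_select(X, self.endog, n_components=a_ffd,
                                    seed=ffd_seed, scaling=self.scaling, **kwargs)
            selected = selected[ffd_result.retained]
            X = X[:, ffd_result.retained]
            if meta is not None:
                meta = [meta[i] for i in ffd_result.retained]

        q2_by_a: list[float] | None = None
        if n_components is None:
            n_components, q2_by_a = pls.select_components(
                X, self.endog, a_max=a_max, scaling=self.scaling)
        model = pls.fit_pls(X, self.endog, n_components,
                            scaling=self.scaling, ids=self.ids)
        q2, press = pls.loo_q2(X, self.endog, n_components, scaling=self.scaling)
        report = validation.internal_validation(
            self.endog, model.fittedvalues, press)
        return GrindPLSResults(self, model, selected, meta, report,
                               ffd_result=ffd_result, q2_by_a=q2_by_a)


class GrindPLSResults:
    """Fit results: estimates, diagnostics, validation and interpretation."""

    def __init__(self, model_spec: GrindPLS, plsfit: pls.PLSModel,
                 selected: np.ndarray, var_meta: list[VariableMeta] | None,
                 internal_report: ValidationReport,
                 ffd_result: FFDResult | None = None,
                 q2_by_a: list[float] | None = None):
        self.model = model_spec
        self.plsfit = plsfit
        self.selected = np.asarray(selected, dtype=int)
        self.var_meta = var_meta
        self.report = internal_report
        self.ffd_result = ffd_result
        self.q2_by_a = q2_by_a

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = ([m.column for m in self.var_meta] if self.var_meta is not None
                 else [f"x{i}" for i in self.selected])
        return pd.Series(self.plsfit.coef, index=names, name="coefficient")

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.plsfit.fittedvalues

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def n_components(self) -> int:
        return self.plsfit.n_components

    @property
    def rsquared(self) -> float:
        return self.report.r2

    @property
    def q2_loo(self) -> float:
        return self.report.q2

    # -- prediction / validation -------------------------------------------
    def _select(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == len(self.selected):
            return X
        if X.shape[1] == self.model.exog.shape[1]:
            return X[:, self.selected]
        raise ValueError(
            f"X has {X.shape[1]} columns; expected {len(self.selected)} "
            f"(selected) or {self.model.exog.shape[1]} (full)")

    def predict(self, exog: np.ndarray) -> np.ndarray:
        return self.plsfit.predict(self._select(exog))

    def validate_external(self, endog_test, exog_test) -> ValidationReport:
        """External validation merged with the internal statistics."""
        yhat = self.predict(exog_test)
        ext = validation.external_validation(endog_test, yhat,
                                             ybar_train=self.plsfit.y_mean)
        self.report = self.report.merged(ext)
        return self.report

    def williams(self, exog_test=None, endog_test=None,
                 ids_test=None, include_intercept: bool = True,
                 space: str = "descriptors") -> WilliamsData:
        """Applicability-domain data for the Williams plot.

        ``space="descriptors"`` computes leverage in the selected-descriptor
        space with p = number of selected variables (when that p approaches
        or exceeds n the leverage criterion becomes vacuous, h* >= 1);
        ``space="scores"`` uses the fitted latent-variable scores with
        p = number of components, the usual convention for PLS models.
        """
        rmsee = self.report.rmsee
        if not rmsee:
            raise ValueError("internal validation (RMSEE) missing")
        if space == "descriptors":
            X_train = self.model.exog[:, self.selected]
            to_space = self._select
        elif space == "scores":
            X_train = self.plsfit.scores
            pf = self.plsfit

            def to_space(X):
                Xs = (self._select(X) - pf.x_mean) / pf.x_scale
                R = pf.weights @ np.linalg.inv(pf.x_loadings.T @ pf.weights)
                return Xs @ R
        else:
            raise ValueError(f"unknown leverage space {space!r}")
        std_train = self.resid / rmsee
        X_test = std_test = None
        if exog_test is not None:
            X_test = to_space(exog_test)
            resid_test = (np.asarray(endog_test, float).ravel()
                          - self.predict(exog_test))
            std_test = resid_test / rmsee
        wd = applicability_domain(
            X_train, self.model.ids, std_train, X_test, ids_test, std_test,
            include_intercept=include_intercept)
        self.report = self.report.merged(ValidationReport(
            h_star=wd.h_star, outlier_ids=wd.outlier_ids))
        return wd

    # -- interpretation ----------------------------------------------------
    def rank_variables(self, top_n: int = 10) -> list[VariableReportEntry]:
        if self.var_meta is None:
            raise ValueError("variable metadata not available")
        return rank_variables(self.plsfit, self.var_meta, top_n)

    def summary(self, top_n: int = 10) -> str:
        lines = [
            "GRIND PLS QSAR results",
            "=" * 46,
            f"compounds (train)      {len(self.model.endog)}",
            f"descriptors (selected) {len(self.selected)}"
            + (f" of {self.model.exog.shape[1]}" if self.ffd_result else ""),
            f"latent variables       {self.n_components}",
            f"scaling                {self.plsfit.scaling}",
            "",
            self.report.summary_table(),
        ]
        if self.var_meta is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entries = self.rank_variables(top_n)
            if entries:
                lines += ["", f"top {len(entries)} variables by |coefficient|"]
                frame = variable_report_frame(entries)
                lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    @property
    def criteria(self) -> dict[str, bool]:
        return criteria_flags(self.report)
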