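"""Model interpretation: ranked signed variables, predictions, unit helpers.

A fitted model is turned into the kind of output a medicinal chemist reads:
the most influential descriptor variables, each annotated with its probe
pair and distance range (e.g. ``DRY-N1: 13.2–13.6 Å``) and labelled
favorable (positive coefficient: a more intense hot-spot pair at that
distance raises predicted pIC50) or unfavorable (negative coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grind import VariableMeta
from .pls import PLSModel


@dataclass
class VariableReportEntry:
    rank: int
    index: int
    block: str
    bin_low: float
    bin_high: float
    coefficient: float

    @property
    def sign(self) -> str:
        return "favorable" if self.coefficient > 0 else "unfavorable"

    @property
    def label(self) -> str:
        return f"{self.block}: {self.bin_low:g}–{self.bin_high:g} Å"


def rank_variables(model: PLSModel, meta: list[VariableMeta],
                   top_n: int = 10) -> list[VariableReportEntry]:
    """Top variables by |PLS coefficient|; exact zeros are excluded."""
    coef = model.coef
    if len(coef) != len(meta):
        raise ValueError("coefficient vector does not match variable metadata")
    nonzero = [i for i in range(len(coef)) if coef[i] != 0.0]
    if top_n > len(nonzero):
        warnings.warn(f"top_n={top_n} exceeds {len(nonzero)} nonzero "
                      "coefficients; truncated", stacklevel=2)
        top_n = len(nonzero)
    order = sorted(nonzero, key=lambda i: -abs(coef[i]))[:top_n]
    return [VariableReportEntry(rank=r + 1, index=meta[i].index,
                                block=meta[i].block, bin_low=meta[i].bin_low,
                                bin_high=meta[i].bin_high,
                                coefficient=float(coef[i]))
            for r, i in enumerate(order)]


def variable_report_frame(entries: list[VariableReportEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": e.rank, "variable": e.index, "label": e.label,
        "coefficient": e.coefficient, "effect": e.sign} for e in entries])


def predict(model: PLSModel, X_new: np.ndarray, columns: list[str] | None = None,
            model_columns: list[str] | None = None,
            in_ad: np.ndarray | None = None) -> pd.DataFrame:
    """Predict pIC50 for new descriptor rows.

    When both column lists are given they must match exactly; a mismatch
    raises an error listing the missing variables.
    """
    if columns is not None and model_columns is not None:
        missing = [c for c in model_columns if c not in columns]
        if missing:
            raise ValueError(f"descriptor columns missing: {missing}")
        order = [columns.index(c) for c in model_columns]
        X_new = np.asarray(X_new)[:, order]
    preds = model.predict(X_new)
    out = pd.DataFrame({"pIC50_pred": preds})
    if in_ad is not None:
        out["in_AD"] = np.asarray(in_ad, dtype=bool)
    return out


def ic50_to_pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 in mol/L)."""
    ic50_molar = np.asarray(ic50_molar, dtype=float)
    if np.any(ic50_molar <= 0):
        raise ValueError("IC50 must be positive")
    out = -np.log10(ic50_molar)
    return float(out) if out.ndim == 0 else out


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50` (returns mol/L)."""
    out = np.power(10.0, -np.asarray(pic50, dtype=float))
    return float(out) if out.ndim == 0 else out


def residual_table(predictions, observations, ids=None) -> pd.DataFrame:
    """Per-compound bookkeeping: predicted, experimental, exp - pred."""
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation vectors must align")
    table = pd.DataFrame({
        "pIC50_pred": pred,
        "pIC50_exp": obs,
        "exp_minus_pred": obs - pred,
    })
    if ids is not None:
        table.insert(0, "id", list(ids))
    return table
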