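"""Fractional-factorial-design (FFD) variable selection.

Variables enter a two-level (+1 keep / -1 drop) design together with a
fraction of phantom "dummy" variables that never enter any model.  Each
design row defines a reduced PLS model whose cross-validated SDEP is
recorded; the *effect* of a variable is the mean SDEP of runs keeping it
minus the mean SDEP of runs dropping it.  Dummy effects estimate the noise
level of that statistic, and a real variable is dropped when its effect
exceeds mean + 2*SD of the dummy effects, i.e. when keeping it demonstrably
worsens prediction.

The design is a seeded, column-balanced random two-level matrix with a
single fold-over (every run is paired with its mirror image), so every
factor is kept in exactly half of the runs and main effects are estimated
free of first-order confounding with run mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import _preprocess, cv_sdep_kernel


@dataclass
class FFDResult:
    retained: np.ndarray        # indices into the input X columns
    dropped: np.ndarray
    effects: np.ndarray         # per real variable, SDEP units
    dummy_effects: np.ndarray
    threshold: float            # mean + 2*SD of dummy effects
    sdep: np.ndarray            # per design run
    design: np.ndarray          # (n_runs, n_real + n_dummies), +/-1


def _make_groups(n: int, n_groups: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(g) for g in np.array_split(perm, n_groups)]


def ffd_select(X: np.ndarray, y: np.ndarray, n_components: int = 2,
               dummy_fraction: float = 0.2, n_runs: int | None = None,
               seed: int = 0, n_cv_groups: int = 5,
               scaling: str = "autoscale",
               design: np.ndarray | None = None) -> FFDResult:
    """Select variables by FFD; deterministic given ``seed``.

    ``n_runs`` is the number of base design rows before fold-over (default:
    smallest multiple of 4 that exceeds the number of real + dummy factors).
    A custom ``design`` matrix (runs x factors, entries +/-1, real columns
    first) may be supplied instead.  Zero-variance columns are dropped
    before the design is built and are never retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 8:
        raise ValueError("FFD needs at least 8 variables")
    rng = np.random.default_rng(seed)

    informative = np.flatnonzero(X.std(axis=0) > 0)
    V = len(informative)
    n_dummies = int(np.ceil(dummy_fraction * V))
    v_tot = V + n_dummies

    if design is None:
        if n_runs is None:
            n_runs = max(8, ((v_tot + 1 + 3) // 4) * 4)
        if n_runs < v_tot + 1:
            raise ValueError(
                f"n_runs={n_runs} cannot resolve {v_tot} factors (need >= {v_tot + 1})")
        half = n_runs // 2
        base = np.empty((n_runs, v_tot), dtype=int)
        for j in range(v_tot):
            col = np.array([1] * half + [-1] * (n_runs - half))
            base[:, j] = rng.permutation(col)
        design = np.vstack([base, -base])  # single fold-over
    else:
        design = np.asarray(design, dtype=int)
        if design.shape[1] != v_tot:
            raise ValueError("design must have one column per real+dummy factor")

    Xs, yc, *_ = _preprocess(X[:, informative], y, scaling)
    XtX_full = Xs.T @ Xs
    Xty_full = Xs.T @ yc
    groups = _make_groups(n, min(n_cv_groups, n), rng)

    sdep = np.empty(len(design))
    for r, row in enumerate(design):
        keep = np.flatnonzero(row[:V] == 1)
        if keep.size == 0:
            sdep[r] = np.sqrt(np.mean(yc ** 2))  # null model
            continue
        sub = np.ix_(keep, keep)
        sdep[r] = cv_sdep_kernel(
            Xs[:, keep], yc, min(n_components, keep.size),
            groups, XtX=XtX_full[sub], Xty=Xty_full[keep])

    kept_mask = design == 1
    mean_kept = (sdep @ kept_mask) / kept_mask.sum(axis=0)
    mean_dropped = (sdep @ ~kept_mask) / (~kept_mask).sum(axis=0)
    effects = mean_kept - mean_dropped  # >0: keeping the factor hurts SDEP

    real_effects = effects[:V]
    dummy_effects = effects[V:]
    threshold = float(dummy_effects.mean() + 2.0 * dummy_effects.std(ddof=1)) \
        if n_dummies > 1 else float("inf")
    drop_local = real_effects > threshold
    retained = informative[~drop_local]
    dropped = np.sort(np.concatenate(
        [informative[drop_local],
         np.setdiff1d(np.arange(p), informative)]))
    return FFDResult(retained=retained, dropped=dropped, effects=real_effects,
                     dummy_effects=dummy_effects, threshold=threshold,
                     sdep=sdep, design=design)
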