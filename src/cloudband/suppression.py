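"""Tuning-only and divisive surround-suppression response models.

The tuning-only model scales the center-site Gabor magnitudes ``c(o, b)``
(averaged over the five spatial frequencies) by a single factor ``w_t`` that
matches the grand mean of the measured responses ``a(o, b)``:

    w_t = mean(a) / mean(c),      tuning_only(o, b) = w_t * c(o, b).

The suppression model divides each center magnitude by a rectified surround
term before pooling:

    pred(o, b) = (1/n_F) * sum_f  w_c * m(o, f, b, xc, yc)
                                  --------------------------------
                                  1 + w_s * max(0, s(o, f, b) + t)

with ``s`` the mean magnitude of same-(o, f) filters in an annulus whose
inner/outer radii (lim_i < lim_o, both in 7.5-15 deg) are free parameters
alongside the center weight ``w_c >= 0``, surround weight ``w_s >= 0`` and
threshold ``t``.  Division acts on individual frame responses; predictions
are then averaged over spatial frequencies and frames.  The five parameters
are fitted to the measured per-orientation, per-condition means by bounded
Nelder-Mead simplex search, best of ``n_restarts`` random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DegenerateDataError, EmptySurroundError, FitFailureError
from .gabor import ResponseGrid

__all__ = [
    "SuppressionParams",
    "SuppressionBounds",
    "ModelFit",
    "center_response",
    "fit_scaling",
    "tuning_only_predict",
    "surround_average",
    "suppression_predict",
    "fit_suppression",
    "recruitment_fit",
    "r2_mean_corrected",
    "modulation_from_responses",
]


@dataclass(frozen=True)
class SuppressionParams:
    """The five surround-model parameters."""

    lim_i_deg: float
    lim_o_deg: float
    w_c: float
    w_s: float
    t: float

    def __post_init__(self) -> None:
        if not (self.lim_i_deg < self.lim_o_deg):
            raise ValueError("lim_i must be < lim_o")
        if self.w_c < 0 or self.w_s < 0:
            raise ValueError("w_c and w_s must be >= 0")


@dataclass(frozen=True)
class SuppressionBounds:
    """Box bounds used for fitting and for drawing random restarts."""

    lim_deg: tuple[float, float] = (7.5, 15.0)
    w_c: tuple[float, float] = (0.0, 100.0)
    w_s: tuple[float, float] = (0.0, 5000.0)
    t: tuple[float, float] = (-2.0, 2.0)

    def as_list(self):
        return [self.lim_deg, self.lim_deg, self.w_c, self.w_s, self.t]


@dataclass(frozen=True)
class ModelFit:
    """Result of a surround-model (or tuning-only) fit."""

    params: SuppressionParams | None
    predictions: np.ndarray           # (n_orientations, n_conditions)
    targets: np.ndarray
    orientations_deg: tuple
    conditions: tuple
    loss: float
    r2: float
    n_restarts: int = 0
    restart_losses: np.ndarray | None = None


def center_response(grid: ResponseGrid) -> np.ndarray:
    """``c(o)`` for one condition: center-site magnitudes averaged over the
    spatial frequencies and frames."""
    cy, cx = grid.center
    return grid.m[:, :, :, cy, cx].mean(axis=(1, 2))


def fit_scaling(a, c) -> float:
    """Grand-mean scaling from model magnitudes (AU) to measured amplitudes.

    ``w_t = mean(a) / mean(c)`` over all orientation bins and conditions.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if a.size != c.size:
        raise ValueError("a and c must be aligned over orientations x conditions")
    denom = c.mean()
    if denom == 0:
        raise DegenerateDataError("model center responses average to zero")
    return float(a.mean() / denom)


def tuning_only_predict(c, w_t: float) -> np.ndarray:
    """Scaled center responses, in measured-amplitude units."""
    return w_t * np.asarray(c, dtype=float)


def _surround_mask(n_sites: int, spacing_deg: float, lim_i_deg: float, lim_o_deg: float):
    c = (n_sites - 1) // 2
    idx = np.arange(n_sites)
    d_units = np.hypot(*np.meshgrid(idx - c, idx - c, indexing="ij"))
    lim_i_u = lim_i_deg / spacing_deg
    lim_o_u = lim_o_deg / spacing_deg
    return (d_units > lim_i_u) & (d_units < lim_o_u)


def surround_average(grid: ResponseGrid, lim_i_deg: float, lim_o_deg: float):
    """Mean same-(o, f) magnitude over the annulus; returns ``(s, |P|)``.

    ``s`` has shape ``(n_orientations, n_sfs, n_frames)``.  Site distances
    are strict inequalities (lim_i < d < lim_o) in grid units, degrees being
    converted through the grid spacing.
    """
    if lim_i_deg >= lim_o_deg:
        raise ValueError("lim_i must be < lim_o")
    mask = _surround_mask(grid.n_sites, grid.spacing_deg, lim_i_deg, lim_o_deg)
    n = int(mask.sum())
    if n == 0:
        raise EmptySurroundError(
            f"annulus ({lim_i_deg:.3g}, {lim_o_deg:.3g}) deg contains no grid sites"
        )
    s = grid.m[:, :, :, mask].mean(axis=3)
    return s, n


def suppression_predict(grid: ResponseGrid, params: SuppressionParams) -> np.ndarray:
    """Per-orientation model predictions for one condition's response grid.

    Division is applied per frame and per spatial frequency, then averaged
    over the five frequencies and finally over frames.
    """
    cy, cx = grid.center
    center = grid.m[:, :, :, cy, cx]                      # (o, f, t)
    s, _ = surround_average(grid, params.lim_i_deg, params.lim_o_deg)
    denom = 1.0 + params.w_s * np.maximum(0.0, s + params.t)
    per_frame = params.w_c * center / denom
    return per_frame.mean(axis=1).mean(axis=1)            # over f, then frames


def _predict_all(grids: dict, params: SuppressionParams) -> np.ndarray:
    return np.column_stack([suppression_predict(g, params) for g in grids.values()])


class _FastPredictor:
    """Precomputed center responses and distance-sorted surround prefix sums.

    Sorting sites by center distance once lets the annulus mean for any
    (lim_i, lim_o) be read off two cumulative sums, so each objective
    evaluation inside the simplex search is O(1) in the number of sites.
    """

    def __init__(self, grid: ResponseGrid):
        cy, cx = grid.center
        self.center = grid.m[:, :, :, cy, cx]              # (o, f, t)
        n = grid.n_sites
        c = (n - 1) // 2
        idx = np.arange(n)
        d = np.hypot(*np.meshgrid(idx - c, idx - c, indexing="ij")).ravel()
        order = np.argsort(d, kind="stable")
        self.d_sorted = d[order]
        flat = grid.m.reshape(*grid.m.shape[:3], n * n)[..., order]
        self.cums = np.concatenate(
            [np.zeros((*flat.shape[:3], 1)), np.cumsum(flat, axis=-1)], axis=-1)
        self.spacing = grid.spacing_deg

    def surround(self, lim_i_deg: float, lim_o_deg: float):
        lo = np.searchsorted(self.d_sorted, lim_i_deg / self.spacing, side="right")
        hi = np.searchsorted(self.d_sorted, lim_o_deg / self.spacing, side="left")
        count = hi - lo
        if count <= 0:
            raise EmptySurroundError("annulus contains no grid sites")
        return (self.cums[..., hi] - self.cums[..., lo]) / count, int(count)

    def predict(self, x: np.ndarray) -> np.ndarray:
        lim_i, lim_o, w_c, w_s, t = x
        s, _ = self.surround(lim_i, lim_o)
        denom = 1.0 + w_s * np.maximum(0.0, s + t)
        return (w_c * self.center / denom).mean(axis=1).mean(axis=1)


def fit_suppression(
    grids: dict,
    targets: np.ndarray,
    bounds: SuppressionBounds | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    maxiter: int = 2000,
    refine_annulus: bool = True,
) -> ModelFit:
    """Fit the five suppression parameters jointly across conditions.

    Parameters
    ----------
    grids : dict of condition label -> ResponseGrid
        All conditions are fitted at the same time; column order of
        ``targets`` follows the dict order.
    targets : array (n_orientations, n_conditions)
        Measured mean amplitudes per orientation bin and condition.
    bounds : SuppressionBounds
        Box bounds; annulus radii default to the 7.5-15 degree range.
    n_restarts : int
        Random uniform initializations; the best final loss wins.
    """
    bounds = bounds or SuppressionBounds()
    targets = np.asarray(targets, dtype=float)
    first = next(iter(grids.values()))
    if targets.shape != (len(first.orientations_deg), len(grids)):
        raise ValueError("targets must be (n_orientations, n_conditions)")

    box = bounds.as_list()
    penalty = 1e6
    predictors = [_FastPredictor(g) for g in grids.values()]

    def objective(x: np.ndarray) -> float:
        if x[0] >= x[1]:
            return penalty * (1.0 + x[0] - x[1])
        try:
            pred = np.column_stack([p.predict(x) for p in predictors])
        except EmptySurroundError:
            return penalty
        return float(np.mean((pred - targets) ** 2))

    rng = np.random.default_rng(seed)
    best_x, best_fun = None, np.inf
    losses = np.full(n_restarts, np.nan)
    opts = {"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14}
    for k in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in box])
        if x0[0] >= x0[1]:
            x0[0], x0[1] = x0[1], x0[0]
        if x0[0] == x0[1]:
            x0[1] = min(x0[1] + 1e-3, box[1][1])
        res = optimize.minimize(objective, x0, method="Nelder-Mead", bounds=box,
                                options=opts)
        losses[k] = res.fun
        if res.fun < penalty and res.fun < best_fun:
            best_x, best_fun = res.x, res.fun
    if best_x is None:
        raise FitFailureError("all restarts landed in infeasible parameter regions")
    # polish the winner: restart the simplex from it until no further progress
    for _ in range(5):
        res = optimize.minimize(objective, best_x, method="Nelder-Mead", bounds=box,
                                options=opts)
        if res.fun >= best_fun * (1.0 - 1e-12):
            break
        best_x, best_fun = res.x, res.fun

    if refine_annulus:
        # The annulus radii act on the loss only through the discrete set of
        # enclosed grid sites, leaving the simplex search blind on the
        # plateaus between two site distances.  Enumerate every distinct
        # annulus within bounds and refit the three continuous parameters.
        spacing = predictors[0].spacing
        d_deg = np.unique(np.round(predictors[0].d_sorted * spacing, 9))
        lo_b, hi_b = box[0]
        inner = d_deg[(d_deg > lo_b) & (d_deg < hi_b)]
        cand = np.concatenate([[lo_b], (inner[:-1] + inner[1:]) / 2.0, [hi_b]]) \
            if len(inner) > 1 else np.array([lo_b, hi_b])
        # neutral start: no suppression, w_c matching the target scale
        c_mean = float(np.mean([p.center.mean() for p in predictors]))
        w_c0 = float(np.clip(targets.mean() / max(c_mean, 1e-12),
                             box[2][0], box[2][1]))
        for _pass in range(2):
            improved = False
            for i in range(len(cand) - 1):
                for j in range(i + 1, len(cand)):
                    li, lo = float(cand[i]), float(cand[j])
                    try:
                        surrounds = [p.surround(li, lo)[0] for p in predictors]
                    except EmptySurroundError:
                        continue

                    def inner_obj(w, _s=surrounds):
                        w_c, w_s, t = w
                        pred = np.column_stack([
                            (w_c * p.center / (1.0 + w_s * np.maximum(0.0, s + t))
                             ).mean(axis=1).mean(axis=1)
                            for p, s in zip(predictors, _s)
                        ])
                        return float(np.mean((pred - targets) ** 2))

                    for start in (best_x[2:], np.array([w_c0, 1.0, 0.0])):
                        res = optimize.minimize(
                            inner_obj, start, method="Nelder-Mead", bounds=box[2:],
                            options={"maxiter": 600, "xatol": 1e-10, "fatol": 1e-14})
                        if res.fun < best_fun:
                            best_x = np.array([li, lo, *res.x])
                            best_fun = res.fun
                            improved = True
            if not improved:
                break
        # final deep polish of the winning annulus
        res = optimize.minimize(objective, best_x, method="Nelder-Mead", bounds=box,
                                options=opts)
        if res.fun < best_fun:
            best_x, best_fun = res.x, res.fun

    params = SuppressionParams(*best_x)
    pred = _predict_all(grids, params)
    r2 = r2_mean_corrected(targets.ravel(), pred.ravel())
    return ModelFit(
        params=params, predictions=pred, targets=targets,
        orientations_deg=tuple(first.orientations_deg), conditions=tuple(grids),
        loss=float(best_fun), r2=r2, n_restarts=n_restarts, restart_losses=losses,
    )


def recruitment_fit(response_modulation, recruitment_observed) -> float:
    """No-intercept least-squares slope translating response modulation into
    recruitment modulation: ``beta = sum(x*y) / sum(x^2)``."""
    x = np.asarray(response_modulation, dtype=float)
    y = np.asarray(recruitment_observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned over orientation bins")
    sx2 = np.sum(x**2)
    if sx2 == 0:
        raise DegenerateDataError("all-zero response modulation: slope undefined")
    return float(np.sum(x * y) / sx2)


def r2_mean_corrected(observed, predicted) -> float:
    """Coefficient of determination about the observed mean (may be < 0)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2 or obs.shape != pred.shape:
        raise ValueError("need aligned vectors of length >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateDataError("constant observations: R^2 undefined")
    ss_res = np.sum((obs - pred) ** 2)
    return float(1.0 - ss_res / ss_tot)


def modulation_from_responses(narrow, broad) -> np.ndarray:
    """Per-orientation response modulation, (broad - narrow)/(broad + narrow).

    Positive values mean stronger responses to the broadband stimulus; the
    same operator as the orientation modulation index, applied bin-wise.
    """
    rn = np.asarray(narrow, dtype=float)
    rb = np.asarray(broad, dtype=float)
    denom = rb + rn
    if np.any(denom == 0):
        raise DegenerateDataError("zero response sum: modulation undefined")
    return (rb - rn) / denom
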