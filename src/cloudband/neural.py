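"""Trial-based response quantification and selectivity/discrimination indices.

All operations consume a *trial table*: one row per (neuron, condition,
trial) holding a stimulus-window value and a 1-s baseline-window value, in
dF/F for calcium imaging or spikes/s for electrophysiology.  A neuron's
response amplitude to a condition is the median over trials of
(stimulus - baseline); responsiveness is a one-sided Mann-Whitney U test of
stimulus values against baseline values (p < 0.05).

Index suite:

* BW_SI (bandwidth selectivity): (R_band - mean(other two)) / (R_band +
  mean(other two)), with a 1000-fold label-shuffle null — real index above
  the 95th percentile marks band selectivity, below the 5th marks mixed
  selectivity for the other two bands.
* OMI / RMI: (R_broad - R_narrow) / (R_broad + R_narrow), positive when
  broadband stimulation drives stronger responses (or larger recruitment).
* SMI (surround modulation): (full-field - center) / (full-field + center);
  more negative means stronger surround inhibition.
* AUC / AUC_abs: rank-statistic ROC area between two response distributions,
  folded to |AUC - 0.5| * 2 for a preference-free discriminability scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "TRIAL_TABLE_COLUMNS",
    "NeuronResponseSummary",
    "SelectivityResult",
    "DiscriminationResult",
    "TuningCurve",
    "LMEResult",
    "trial_amplitudes",
    "summarize_neuron",
    "responsive_test",
    "bandwidth_selectivity",
    "shuffle_null_classification",
    "modulation_index",
    "surround_modulation_index",
    "roc_auc",
    "preferred_orientation",
    "sparse_noise_rf",
    "lme_regression",
]

#: Required columns of the trial-table CSV contract.
TRIAL_TABLE_COLUMNS = (
    "neuron_id", "condition_id", "trial_index", "baseline_value", "stim_value",
)
#: Optional columns carried through when present.
TRIAL_TABLE_OPTIONAL = ("animal_id", "session_id", "behavioral_state")


def trial_amplitudes(
    traces: np.ndarray,
    fs_hz: float,
    events: pd.DataFrame,
    stim_window_s: float = 2.0,
    baseline_window_s: float = 1.0,
) -> pd.DataFrame:
    """Extract per-trial stimulus/baseline values from continuous traces.

    Parameters
    ----------
    traces : array (n_neurons, n_samples)
        dF/F (or rate) traces at sampling rate ``fs_hz``.
    events : DataFrame with columns ``time_s`` and ``condition_id``
        Stimulus onsets.  The stimulus window is the first
        ``stim_window_s`` seconds after onset (2 s by default, matching the
        shortest stimulus duration used); the baseline window is the
        ``baseline_window_s`` seconds before onset.

    Returns a trial table with one row per neuron and trial.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_samples = traces.shape[1]
    rows = []
    counters: dict = {}
    for _, ev in events.iterrows():
        onset = int(round(ev["time_s"] * fs_hz))
        b0 = onset - int(round(baseline_window_s * fs_hz))
        s1 = onset + int(round(stim_window_s * fs_hz))
        if b0 < 0 or s1 > n_samples:
            raise IndexError("stimulus/baseline window falls outside the traces")
        cond = ev["condition_id"]
        k = counters.get(cond, 0)
        counters[cond] = k + 1
        base = traces[:, b0:onset].mean(axis=1)
        stim = traces[:, onset:s1].mean(axis=1)
        for n in range(traces.shape[0]):
            rows.append((n, cond, k, base[n], stim[n]))
    return pd.DataFrame(rows, columns=list(TRIAL_TABLE_COLUMNS))


@dataclass(frozen=True)
class NeuronResponseSummary:
    """Per-condition amplitudes and responsiveness of one neuron."""

    neuron_id: object
    amplitude: dict       # condition -> median over trials of (stim - baseline)
    p_value: dict         # condition -> one-sided Mann-Whitney p
    responsive: dict      # condition -> p < alpha
    labels: tuple         # e.g. ("common",) or ("narrow-only",)


def responsive_test(stim_values, baseline_values, alpha: float = 0.05):
    """One-sided Mann-Whitney U test that stimulus values exceed baseline.

    Returns ``(p_value, responsive_flag)``.  Exact enumeration is used for
    small tie-free samples, the tie/continuity-corrected normal
    approximation otherwise (an all-tied degenerate input warns and reports
    p = 1).
    """
    stim = np.asarray(stim_values, dtype=float)
    base = np.asarray(baseline_values, dtype=float)
    if stim.size < 3 or base.size < 3:
        raise InsufficientDataError("need at least 3 values per group")
    if np.all(stim == stim[0]) and np.all(base == stim[0]):
        warnings.warn("all values tied: responsiveness test is degenerate")
        return 1.0, False
    # exact enumeration where cheap and tie-free; tie/continuity-corrected
    # normal approximation otherwise
    has_ties = len(np.unique(np.concatenate([stim, base]))) < stim.size + base.size
    method = "exact" if (max(stim.size, base.size) <= 12 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(stim, base, alternative="greater", method=method)
    return float(res.pvalue), bool(res.pvalue < alpha)


def summarize_neuron(
    table: pd.DataFrame, neuron_id, alpha: float = 0.05
) -> NeuronResponseSummary:
    """Condition amplitudes, responsiveness flags and responder labels."""
    sub = table[table["neuron_id"] == neuron_id]
    if sub.empty:
        raise KeyError(f"neuron {neuron_id!r} not in table")
    amp, pv, resp = {}, {}, {}
    for cond, grp in sub.groupby("condition_id"):
        diff = grp["stim_value"].to_numpy() - grp["baseline_value"].to_numpy()
        amp[cond] = float(np.median(diff))
        p, flag = responsive_test(grp["stim_value"], grp["baseline_value"], alpha)
        pv[cond], resp[cond] = p, flag
    conds = list(resp)
    labels = []
    if all(resp.values()):
        labels.append("common")
    only = [c for c in conds if resp[c] and not any(resp[d] for d in conds if d != c)]
    labels.extend(f"{c}-only" for c in only)
    if not any(resp.values()):
        labels.append("nonresponsive")
    return NeuronResponseSummary(neuron_id, amp, pv, resp, tuple(labels))


def bandwidth_selectivity(Rn: float, Rm: float, Rb: float) -> dict:
    """BW_SI for each band against the mean of the other two.

    For nonnegative responses each index is bounded in [-1, 1].
    """
    out = {}
    for name, own, others in (
        ("narrow", Rn, (Rm, Rb)), ("mid", Rm, (Rn, Rb)), ("broad", Rb, (Rn, Rm)),
    ):
        rest = float(np.mean(others))
        denom = own + rest
        if denom == 0:
            raise DegenerateDataError("zero response sum: BW_SI undefined")
        out[name] = (own - rest) / denom
    return out


@dataclass(frozen=True)
class SelectivityResult:
    """Real BW_SI per band against its shuffle null."""

    bw_si: dict
    shuffle_low: dict     # 5th percentile per band
    shuffle_high: dict    # 95th percentile per band
    selective: dict       # band -> real index above the 95th percentile
    classification: str   # narrow / mid / broad / mixed-<pair> / nonselective
    n_shuffles: int
    seed: int


def shuffle_null_classification(
    responses: dict,
    n_shuffles: int = 1000,
    seed: int = 0,
    summary=np.median,
) -> SelectivityResult:
    """Bandwidth-selectivity classification against a label-shuffle null.

    ``responses`` maps the three band labels ("narrow", "mid", "broad") to
    per-trial response amplitudes.  Trial labels are permuted across the
    three conditions; band summaries (median by default) and BW_SI are
    recomputed per shuffle.  A real index above the 95th percentile of its
    null marks selectivity for that band; an index below the 5th percentile
    marks mixed selectivity for the other two bands.
    """
    bands = ("narrow", "mid", "broad")
    if set(responses) != set(bands):
        raise ValueError("responses must be keyed by 'narrow', 'mid', 'broad'")
    arrs = [np.asarray(responses[b], dtype=float) for b in bands]
    sizes = [a.size for a in arrs]
    if min(sizes) < 2:
        raise InsufficientDataError("need at least 2 trials per condition to permute")
    real = bandwidth_selectivity(*(summary(a) for a in arrs))

    pooled = np.concatenate(arrs)
    edges = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    # one permutation matrix, all shuffles at once
    idx = np.argsort(rng.random((n_shuffles, pooled.size)), axis=1)
    perm = pooled[idx]
    sums = [summary(perm[:, edges[i]:edges[i + 1]], axis=1) for i in range(3)]
    rn, rm, rb = sums
    null = {
        "narrow": (rn - (rm + rb) / 2) / (rn + (rm + rb) / 2),
        "mid": (rm - (rn + rb) / 2) / (rm + (rn + rb) / 2),
        "broad": (rb - (rn + rm) / 2) / (rb + (rn + rm) / 2),
    }
    low = {b: float(np.percentile(null[b], 5)) for b in bands}
    high = {b: float(np.percentile(null[b], 95)) for b in bands}
    selective = {b: bool(real[b] > high[b]) for b in bands}
    mixed = [b for b in bands if real[b] < low[b]]

    if any(selective.values()):
        winner = max((b for b in bands if selective[b]), key=lambda b: real[b])
        classification = winner
    elif mixed:
        worst = min(mixed, key=lambda b: real[b])
        pair = [b for b in bands if b != worst]
        classification = f"mixed-{pair[0]}+{pair[1]}"
    else:
        classification = "nonselective"
    return SelectivityResult(
        bw_si=real, shuffle_low=low, shuffle_high=high, selective=selective,
        classification=classification, n_shuffles=n_shuffles, seed=seed,
    )


def modulation_index(r_narrow: float, r_broad: float) -> float:
    """OMI/RMI: (broad - narrow) / (broad + narrow), in [-1, 1] for
    nonnegative responses."""
    denom = r_broad + r_narrow
    if denom == 0:
        raise DegenerateDataError("zero response sum: modulation index undefined")
    return float((r_broad - r_narrow) / denom)


def surround_modulation_index(r_fullfield: float, r_center: float) -> float:
    """SMI: (full-field - center) / (full-field + center).  Negative values
    indicate surround suppression; the more negative, the stronger."""
    denom = r_fullfield + r_center
    if denom == 0:
        raise DegenerateDataError("zero response sum: SMI undefined")
    return float((r_fullfield - r_center) / denom)


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    auc_abs: float


def roc_auc(values_a, values_b) -> DiscriminationResult:
    """ROC area between two samples: P(b > a) with half credit for ties.

    Computed from the Mann-Whitney U rank statistic; ``auc_abs`` folds the
    area to |AUC - 0.5| * 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    auc = float(u / (a.size * b.size))
    return DiscriminationResult(auc=auc, auc_abs=abs(auc - 0.5) * 2.0)


@dataclass(frozen=True)
class TuningCurve:
    """Orientation tuning from five sampled gratings."""

    orientations_deg: tuple
    responses: tuple
    preferred_deg: float | None
    depth: float
    tuned: bool | None


def preferred_orientation(
    responses,
    orientations_deg=(-45.0, -22.5, 0.0, 22.5, 45.0),
    population_median_depth: float | None = None,
) -> TuningCurve:
    """Preferred orientation by 1-degree linear interpolation of the curve.

    The preferred orientation is the argmax of the piecewise-linear
    interpolation; exact ties break to the orientation nearer 0, then to the
    more negative one.  ``tuned`` is depth (peak - trough of the sampled
    curve) above the population median depth, when that reference is given.
    """
    ori = np.asarray(orientations_deg, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if ori.size != resp.size or ori.size < 2:
        raise ValueError("need matching orientation/response samples")
    depth = float(resp.max() - resp.min())
    tuned = None if population_median_depth is None else bool(depth > population_median_depth)
    if depth == 0:
        return TuningCurve(tuple(ori), tuple(resp), None, depth, False if tuned is None else False)
    grid = np.arange(ori.min(), ori.max() + 0.5, 1.0)
    interp = np.interp(grid, ori, resp)
    peak = interp.max()
    candidates = grid[interp >= peak - 1e-12]
    # tie-break: nearest to 0 deg, then the more negative
    order = np.lexsort((candidates, np.abs(candidates)))
    pref = float(candidates[order[0]])
    return TuningCurve(tuple(ori), tuple(resp), pref, depth, tuned)


def sparse_noise_rf(
    table: pd.DataFrame,
    alpha: float = 0.05,
    square_deg: float = 12.0,
):
    """Receptive-field location and size from sparse-noise square responses.

    ``table`` holds one row per trial with columns ``row``, ``col``,
    ``stim_value``, ``baseline_value``.  Each screen location gets a
    one-sided Mann-Whitney test of stimulus against baseline; the RF center
    is the significant location with the largest median amplitude (row-major
    first on exact ties).  RF size is the equivalent diameter of the total
    significant area (each location covering ``square_deg`` squared degrees).

    Returns ``(center_or_None, pvalue_map, size_deg_or_None)``.
    """
    locs = sorted({(int(r), int(c)) for r, c in zip(table["row"], table["col"])})
    pmap: dict = {}
    amps: dict = {}
    for loc in locs:
        sub = table[(table["row"] == loc[0]) & (table["col"] == loc[1])]
        if len(sub) < 2:
            raise InsufficientDataError(f"location {loc} needs >= 2 presentations")
        p, _ = responsive_test(sub["stim_value"], sub["baseline_value"], alpha)
        pmap[loc] = p
        amps[loc] = float(np.median(sub["stim_value"].to_numpy()
                                    - sub["baseline_value"].to_numpy()))
    significant = [loc for loc in locs if pmap[loc] < alpha]
    if not significant:
        return None, pmap, None
    best = max(significant, key=lambda loc: (amps[loc], -loc[0], -loc[1]))
    area = len(significant) * square_deg**2
    size = 2.0 * np.sqrt(area / np.pi)
    return best, pmap, float(size)


@dataclass(frozen=True)
class LMEResult:
    """Mixed-effects regression of response modulation on neuron features."""

    fixed_effects: dict        # name -> coefficient
    t_values: dict
    random_intercept_var: float
    residual_var: float
    lrt_statistic: float
    lrt_p: float
    bonferroni_alpha: float
    method: str                # "mixedlm" or "ols-fallback"


def lme_regression(
    table: pd.DataFrame,
    response: str = "Rm",
    regressors: tuple = ("Sm", "Ot", "Cr"),
    group: str = "animal_id",
    n_planned_comparisons: int = 1,
    alpha: float = 0.05,
) -> LMEResult:
    """Random-animal-intercept regression with a likelihood-ratio test.

    Fits ``response ~ 1 + regressors`` with a random intercept per animal
    (ML, so the likelihood-ratio test between the full model and the
    animal-only model is valid).  With a single animal the random effect is
    degenerate and an ordinary least-squares fit is used instead (with a
    warning).  The Bonferroni-adjusted alpha for the declared number of
    planned comparisons is reported alongside.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    for col in (response, *regressors, group):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
        if col != group and not np.all(np.isfinite(table[col])):
            raise ValueError(f"non-finite values in {col!r}")
    y = table[response].to_numpy(dtype=float)
    X = sm.add_constant(table[list(regressors)].to_numpy(dtype=float))
    names = ("const", *regressors)
    groups = table[group].to_numpy()
    n_groups = len(np.unique(groups))
    dof = len(regressors)

    if n_groups < 2:
        warnings.warn("single animal: random intercept degenerate, using OLS")
        full = sm.OLS(y, X).fit()
        red = sm.OLS(y, X[:, :1]).fit()
        lrt = 2.0 * (full.llf - red.llf)
        return LMEResult(
            fixed_effects=dict(zip(names, full.params)),
            t_values=dict(zip(names, full.tvalues)),
            random_intercept_var=0.0, residual_var=float(full.scale),
            lrt_statistic=float(lrt), lrt_p=float(stats.chi2.sf(lrt, dof)),
            bonferroni_alpha=alpha / n_planned_comparisons, method="ols-fallback",
        )

    def fit_ml(endog, exog):
        # boundary variance estimates can produce singular Hessians; fall
        # back through derivative-free optimizers
        last = None
        for method in (None, "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kw = {} if method is None else {"method": method}
                    return MixedLM(endog, exog, groups=groups).fit(reml=False, **kw)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
                last = exc
        raise last

    full = fit_ml(y, X)
    red = fit_ml(y, X[:, :1])
    lrt = 2.0 * (full.llf - red.llf)
    k = len(names)
    var_u = float(np.asarray(full.cov_re).ravel()[0])
    method = "mixedlm"
    fixed = dict(zip(names, full.params[:k]))
    tvals = dict(zip(names, full.tvalues[:k]))
    ols = sm.OLS(y, X).fit()
    if full.llf <= ols.llf + 1e-6:
        # the random effect buys no likelihood: its MLE sits at the zero
        # boundary and the model reduces to OLS exactly
        fixed = dict(zip(names, ols.params))
        tvals = dict(zip(names, ols.tvalues))
        var_u = 0.0
        method = "mixedlm-boundary"
    return LMEResult(
        fixed_effects=fixed, t_values=tvals,
        random_intercept_var=var_u, residual_var=float(full.scale),
        lrt_statistic=float(lrt), lrt_p=float(stats.chi2.sf(max(lrt, 0.0), dof)),
        bonferroni_alpha=alpha / n_planned_comparisons, method=method,
    )
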