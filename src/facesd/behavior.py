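"""Behavioral serial-dependence pipeline.

Implements the full behavioral analysis path: derived trial columns
(inducer-target distance, signed adjustment error, distance-range bin),
trial exclusions, the clockwise-minus-counterclockwise median bias
statistic, participant-level bootstrap confidence intervals, and
nonparametric factorial inference via the aligned rank transform (ART) with
BIC-approximated Bayes factors.

Bias statistic
--------------
For every participant x visibility x distance-range cell, the bias is

    m = median(error | delta > 0) - median(error | delta < 0)

where ``delta`` is the signed circular inducer-target distance and ``error``
the signed adjustment error, both in morph steps.  Under this orientation a
pure attraction toward the inducer (errors in the direction of ``delta``)
gives m > 0 and a pure repulsion m < 0, i.e. positive = attractive,
negative = repulsive.  The opposite subtraction order is available through
``sign_convention="ccw_minus_cw"``; it flips every sign and nothing else.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphwheel import MorphWheel, adjustment_error, assign_distance_bin, signed_circular_distance

__all__ = [
    "add_derived_columns",
    "filter_trials",
    "bias_measure",
    "bootstrap_ci",
    "within_anova",
    "art_anova",
    "anova_bf",
    "sd_anova",
    "error_anova",
    "BIN_ORDER",
]

BIN_ORDER = ("close", "middle", "far")

#: Exclusion thresholds: self-paced adjustments slower than 15 s and gross
#: errors beyond +-60 morph steps are treated as off-task; inducer-target
#: distances of 0 or >= 70 steps fall outside the even close/middle/far bins.
RT_MAX_S = 15.0
MAX_ABS_ERROR = 60


def add_derived_columns(table: pd.DataFrame, wheel: MorphWheel | None = None) -> pd.DataFrame:
    """Attach ``delta``, ``error`` and ``bin`` columns to a trial table.

    ``delta`` is the signed circular distance of Face 1 relative to Face 2
    (positive = clockwise), ``error`` the signed circular distance of the
    response relative to Face 2, ``bin`` the distance-range label of
    ``delta``.
    """
    wheel = wheel or MorphWheel()
    required = {"face1", "face2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out = table.copy()
    n = wheel.n_points
    out["delta"] = signed_circular_distance(
        out["face1"].to_numpy(), out["face2"].to_numpy(), n
    )
    if "response" in out.columns:
        out["error"] = adjustment_error(
            out["response"].to_numpy(), out["face2"].to_numpy(), n
        )
    out["bin"] = assign_distance_bin(out["delta"].to_numpy(), n)
    return out


def filter_trials(
    table: pd.DataFrame,
    rt_max: float = RT_MAX_S,
    max_abs_error: int = MAX_ABS_ERROR,
) -> tuple[pd.DataFrame, dict]:
    """Flag excluded trials and report exclusion counts.

    Rows are flagged, never deleted.  Reasons, in priority order for the
    single ``exclusion_reason`` column: reaction time above ``rt_max``
    seconds (strict), absolute adjustment error above ``max_abs_error`` morph
    steps (strict), absolute inducer-target distance of 70 or more steps,
    and zero inducer-target distance (no clockwise/counterclockwise
    direction).  Idempotent.
    """
    for col in ("rt", "error", "delta"):
        if col not in table.columns:
            raise ValueError(f"trial table missing column '{col}'")
    out = table.copy()
    reasons = {
        "rt_gt_15s": out["rt"].to_numpy() > rt_max,
        "abs_error_gt_60": np.abs(out["error"].to_numpy()) > max_abs_error,
        "abs_delta_ge_70": np.abs(out["delta"].to_numpy()) >= 70,
        "delta_eq_0": out["delta"].to_numpy() == 0,
    }
    excluded = np.zeros(len(out), dtype=bool)
    reason_col = np.full(len(out), "", dtype=object)
    for name, mask in reasons.items():
        out[f"excluded_{name}"] = mask
        reason_col[(reason_col == "") & mask] = name
        excluded |= mask
    out["excluded"] = excluded
    out["exclusion_reason"] = reason_col

    n = len(out)
    report = {
        "n_trials": n,
        "n_excluded": int(excluded.sum()),
        "pct_excluded": 100.0 * excluded.sum() / n if n else 0.0,
        "per_reason": {
            name: {"n": int(m.sum()), "pct": 100.0 * m.sum() / n if n else 0.0}
            for name, m in reasons.items()
        },
        # performance-based exclusions only (the RT and gross-error rules);
        # the distance trims are a property of the binning, not of behavior
        "pct_excluded_performance": 100.0
        * (reasons["rt_gt_15s"] | reasons["abs_error_gt_60"]).sum() / n
        if n
        else 0.0,
    }
    return out, report


def bias_measure(
    table: pd.DataFrame,
    sign_convention: str = "cw_minus_ccw",
    group_cols=("participant", "visibility", "bin"),
) -> pd.DataFrame:
    """Per-cell serial-dependence bias: difference of median signed errors.

    For each cell (by default participant x visibility x distance range,
    excluded trials and the ``excluded`` distance bin dropped), computes the
    median signed adjustment error on clockwise-inducer trials (delta > 0)
    minus the median on counterclockwise trials (delta < 0), in morph steps.
    Positive values are attractive, negative repulsive.  Cells missing
    either direction get ``m = NaN`` with a warning and are dropped from
    downstream ANOVAs.
    """
    if sign_convention not in ("cw_minus_ccw", "ccw_minus_cw"):
        raise ValueError("sign_convention must be 'cw_minus_ccw' or 'ccw_minus_cw'")
    df = table
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df[df["bin"].isin(BIN_ORDER)]

    rows = []
    for keys, cell in df.groupby(list(group_cols), sort=True, observed=True):
        cw = cell.loc[cell["delta"] > 0, "error"]
        ccw = cell.loc[cell["delta"] < 0, "error"]
        if len(cw) == 0 or len(ccw) == 0:
            m = np.nan
        else:
            m = float(cw.median() - ccw.median())
            if sign_convention == "ccw_minus_cw":
                m = -m
        rows.append((*keys, m, len(cw), len(ccw)))
    out = pd.DataFrame(rows, columns=[*group_cols, "m", "n_cw", "n_ccw"])
    n_bad = int(out["m"].isna().sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} cell(s) lack clockwise or counterclockwise trials; "
            "their bias is undefined and they are dropped from ANOVAs"
        )
    return out


def bootstrap_ci(values, n_iter: int = 5000, level: float = 0.95, seed=None):
    """Percentile bootstrap CI of the mean, resampling participants.

    Returns ``(mean, lo, hi)``.  Participants (the exchangeable unit in a
    within-subject design) are resampled with replacement ``n_iter`` times;
    the interval is the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of
    the resampled means.  Deterministic given ``seed``.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("bootstrap_ci needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_iter, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(vals.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Fully-within-subjects factorial ANOVA and the aligned rank transform
# ---------------------------------------------------------------------------


def _pivot_to_array(df, dv, within, subject):
    """Pivot a long table to an array (subjects, L1, ..., Lk); must be a
    complete balanced design with one observation per subject x cell."""
    levels = [list(pd.unique(df[f])) for f in within]
    subjects = list(pd.unique(df[subject]))
    shape = (len(subjects), *[len(l) for l in levels])
    arr = np.full(shape, np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    l_idx = [{l: i for i, l in enumerate(lev)} for lev in levels]
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (s_idx[d[subject]], *[l_idx[j][d[f]] for j, f in enumerate(within)])
        if not np.isnan(arr[key]):
            raise ValueError("more than one observation per subject x cell; "
                             "aggregate before the ANOVA")
        arr[key] = d[dv]
    if np.isnan(arr).any():
        raise ValueError("incomplete design: some subject x cell combinations "
                         "are missing")
    return arr, subjects, levels


def _center(a, axis):
    return a - a.mean(axis=axis, keepdims=True)


def within_anova(df: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Fully-within-subjects factorial ANOVA (any number of within factors).

    Each effect is tested against its own effect-by-subject interaction,
    the classical repeated-measures error stratum:  for effect S,
    ``F = (SS_S / df_S) / (SS_{S x subject} / df_S (n-1))``.  Requires a
    complete balanced design with one value per subject x cell.  Returns a
    table with one row per main effect and interaction.
    """
    arr, subjects, levels = _pivot_to_array(df, dv, within, subject)
    n_subj = len(subjects)
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    k = len(within)
    if any(len(l) < 2 for l in levels):
        raise ValueError("every factor needs at least 2 levels")
    rows = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            others = [j for j in range(k) if j not in combo]
            g = arr
            for j in sorted(others, reverse=True):
                g = g.mean(axis=j + 1, keepdims=True)
            fx = g.mean(axis=0, keepdims=True)
            for j in combo:
                fx = _center(fx, j + 1)
            err = _center(g, 0)
            for j in combo:
                err = _center(err, j + 1)
            mult = np.prod([len(levels[j]) for j in others]) if others else 1.0
            ss_eff = n_subj * mult * float((fx**2).sum())
            ss_err = mult * float((err**2).sum())
            df1 = int(np.prod([len(levels[j]) - 1 for j in combo]))
            df2 = df1 * (n_subj - 1)
            if ss_err <= 1e-12 * max(ss_eff, 1.0):
                degenerate = True
                f = np.inf if ss_eff > 1e-12 else 0.0
                p = 0.0 if ss_eff > 1e-12 else 1.0
            else:
                degenerate = False
                f = (ss_eff / df1) / (ss_err / df2)
                p = float(stats.f.sf(f, df1, df2))
            rows.append(
                {
                    "effect": " * ".join(within[j] for j in combo),
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": p,
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def _aligned(arr, combo, k):
    """Align data for one effect: residuals from the full-factorial cell
    means plus that effect's estimated (inclusion-exclusion) contribution."""
    cell_means = arr.mean(axis=0, keepdims=True)
    est = cell_means
    others = [j for j in range(k) if j not in combo]
    for j in others:
        est = est.mean(axis=j + 1, keepdims=True)
    for j in combo:
        est = _center(est, j + 1)
    return arr - cell_means + est


def art_anova(
    df: pd.DataFrame,
    dv: str,
    within,
    subject: str,
    compute_bfs: bool = False,
) -> pd.DataFrame:
    """Nonparametric factorial repeated-measures ANOVA via aligned ranks.

    For each effect the responses are aligned (residuals from the cell means
    plus the effect's own estimated contribution), ranked across the whole
    table with average ranks on ties, and submitted to the within-subjects
    F test for that effect only; one aligned-rank pass per effect.  Optional
    ``BF10`` per effect from :func:`anova_bf` on the raw responses.
    """
    arr, subjects, levels = _pivot_to_array(df, dv, within, subject)
    k = len(within)
    if any(len(l) < 2 for l in levels):
        raise ValueError("every factor needs at least 2 levels")
    if np.allclose(arr, arr.flat[0]):
        raise ValueError("all responses are constant: degenerate design")
    rows = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            aligned = _aligned(arr, combo, k)
            ranks = stats.rankdata(aligned, method="average").reshape(arr.shape)
            rank_df = _array_to_long(ranks, subjects, levels, within, subject)
            table = within_anova(rank_df, "rank", within, subject)
            name = " * ".join(within[j] for j in combo)
            rows.append(table[table["effect"] == name].iloc[0].to_dict())
    out = pd.DataFrame(rows).reset_index(drop=True)
    if compute_bfs:
        out["BF10"] = [
            anova_bf(df, dv, within, subject, e) for e in out["effect"]
        ]
    return out


def _array_to_long(arr, subjects, levels, within, subject):
    index = pd.MultiIndex.from_product(
        [subjects, *levels], names=[subject, *within]
    )
    return pd.DataFrame({"rank": arr.ravel()}, index=index).reset_index()


def anova_bf(df: pd.DataFrame, dv: str, within, subject: str, effect: str) -> float:
    """BIC-approximated Bayes factor for one effect in a factorial design.

    Compares the linear model with the effect against the matched model
    without it (for an interaction, the null keeps the main effects; for a
    main effect, the null keeps the other effects of the same or lower order
    that do not contain it), both including fixed participant intercepts to
    absorb between-participant variance:
    ``BF10 = exp((BIC_null - BIC_full) / 2)``.  Closed-form and
    deterministic (Gaussian likelihood, least squares).
    """
    import statsmodels.formula.api as smf

    factors = effect.split(" * ")
    order = len(factors)
    all_effects = []
    k = len(within)
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            all_effects.append([within[j] for j in combo])
    target = sorted(factors)
    null_terms = [
        e
        for e in all_effects
        if len(e) <= order
        and sorted(e) != target
        and not set(target) <= set(e)
    ]
    full_terms = null_terms + [factors]

    def term_str(e):
        return ":".join(f"C({f})" for f in e)

    data = df.rename(columns={dv: "_dv"}).copy()

    def fit_bic(terms):
        rhs = " + ".join([f"C({subject})"] + [term_str(e) for e in terms])
        res = smf.ols(f"_dv ~ {rhs}", data).fit()
        if res.ssr <= 0 or not np.isfinite(res.llf):
            raise ValueError(
                f"singular/degenerate fit for terms {terms} (ssr={res.ssr})"
            )
        return float(res.bic)

    bic_full = fit_bic(full_terms)
    bic_null = fit_bic(null_terms)
    return float(np.exp((bic_null - bic_full) / 2.0))


def sd_anova(bias: pd.DataFrame, compute_bfs: bool = True) -> pd.DataFrame:
    """ART ANOVA of the bias measure with visibility and distance range as
    within-participant factors.

    Cells with undefined bias are dropped; since the within-subject F test
    needs a complete design, a participant missing any cell is excluded from
    the ANOVA entirely (with a warning).
    """
    cells = bias.dropna(subset=["m"])
    n_cells = cells.groupby("participant", observed=True).size()
    complete = n_cells[n_cells == n_cells.max()].index
    if len(complete) < len(n_cells):
        warnings.warn(
            f"{len(n_cells) - len(complete)} participant(s) with incomplete "
            "cells excluded from the ANOVA"
        )
    cells = cells[cells["participant"].isin(complete)]
    return art_anova(
        cells, "m", ["visibility", "bin"], "participant", compute_bfs=compute_bfs
    )


def error_anova(table: pd.DataFrame, compute_bfs: bool = True) -> pd.DataFrame:
    """Performance check: ART ANOVA of the mean absolute adjustment error per
    participant x visibility x distance-range cell."""
    df = table
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df[df["bin"].isin(BIN_ORDER)]
    cells = (
        df.assign(abs_error=df["error"].abs())
        .groupby(["participant", "visibility", "bin"], observed=True)["abs_error"]
        .mean()
        .reset_index()
    )
    return art_anova(
        cells, "abs_error", ["visibility", "bin"], "participant",
        compute_bfs=compute_bfs,
    )
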