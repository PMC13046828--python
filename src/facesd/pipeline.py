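"""End-to-end orchestration of the synthetic replication.

Glue between the generators and the analysis stages: simulate a study,
stream per-participant epochs through preprocessing into condition averages
(so the full channels x samples x trials tensor never has to be resident for
all participants at once), and run the behavioral, ERP, topographic and
brain-behavior stages with one master seed.

Seed policy: every stochastic stage derives its own child seed from the
master seed through :func:`numpy.random.SeedSequence.spawn`-style fixed
offsets, so stages are independently reproducible and the whole bundle is
deterministic given the configuration.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, erp, inference, synthdata, topography
from .config import RunConfig, save_config

__all__ = [
    "derive_seed",
    "participant_scales",
    "simulate_trials",
    "simulate_condition_averages",
    "run_behavior",
    "run_erp",
    "run_topography",
    "run_regression",
    "run_all",
]

# fixed per-stage offsets for child seeds
_STAGE = {"design": 1, "behavior": 2, "erp": 3, "latent": 4, "boot": 5, "cluster": 6}


def derive_seed(master: int, stage: str, extra: int = 0) -> int:
    """Deterministic child seed for a named stage (below 2**31)."""
    ss = np.random.SeedSequence([int(master), _STAGE.get(stage, 0), int(extra)])
    return int(ss.generate_state(1)[0] % (2**31))


def participant_scales(config: RunConfig):
    """Per-participant effect scales for behavior and ERP generation.

    With ``coupling == 0`` the two modalities draw independent multiplicative
    random effects from their models' ``participant_sd``.  With
    ``coupling > 0`` a single standard-normal latent z per participant
    drives both, with modality-specific gains: the bias pulls scale by
    ``1 + coupling * z`` and the LPP modulation by ``1 + coupling_erp * z``.
    The behavioral gain is larger than the ERP gain by default because the
    behavioral effect is the more heterogeneous quantity: this makes the
    group-level ERP effect large (d near 1) while the shared latent still
    carries a moderate brain-behavior correlation (R^2 near 1/3).
    """
    n = config.design.n_participants
    pids = list(range(1, n + 1))
    if config.coupling > 0:
        rng = np.random.default_rng(derive_seed(config.seed, "latent"))
        z = rng.standard_normal(n)
        b = dict(zip(pids, 1.0 + config.coupling * z))
        e = dict(zip(pids, 1.0 + config.coupling_erp * z))
        return b, e
    rng_b = np.random.default_rng(derive_seed(config.seed, "behavior", 1))
    rng_e = np.random.default_rng(derive_seed(config.seed, "erp", 1))
    b = 1.0 + config.response_model.participant_sd * rng_b.standard_normal(n)
    e = 1.0 + config.erp_model.participant_sd * rng_e.standard_normal(n)
    return dict(zip(pids, b)), dict(zip(pids, e))


def simulate_trials(config: RunConfig) -> pd.DataFrame:
    """Design + responses + derived columns + exclusion flags."""
    spec = synthdata.DesignSpec(
        **{
            **{f: getattr(config.design, f) for f in (
                "n_participants", "n_blocks", "trials_per_block",
                "visibility_split", "wheel")},
            "seed": derive_seed(config.seed, "design"),
        }
    )
    trials = synthdata.generate_trials(spec)
    b_scales, _ = participant_scales(config)
    trials = synthdata.simulate_responses(
        trials,
        config.response_model,
        derive_seed(config.seed, "behavior"),
        wheel=config.design.wheel,
        effect_scale=b_scales,
    )
    trials, _ = behavior.filter_trials(
        trials, config.analysis.rt_max_s, config.analysis.max_abs_error
    )
    return trials


def simulate_condition_averages(
    config: RunConfig, trials: pd.DataFrame, with_visibility: bool = True
):
    """Simulate and preprocess epochs participant by participant.

    Returns ``(avgs_by_bin, avgs_by_vis_bin)``: per-participant average
    waveforms by distance range and by visibility x distance range, already
    low-passed and baseline-corrected (linked-mastoid reference).  With
    ``with_visibility=False`` the second element is None.
    """
    _, e_scales = participant_scales(config)
    pieces_bin, pieces_visbin = [], []
    for p, sub in trials.groupby("participant", sort=True):
        epochs = synthdata.simulate_epochs(
            sub,
            config.erp_model,
            derive_seed(config.seed, "erp", int(p)),
            effect_scale={p: e_scales[p]},
        )
        epochs = erp.preprocess(
            epochs,
            config.analysis.lowpass_hz,
            config.analysis.filter_order,
            config.analysis.baseline_ms,
        )
        pieces_bin.append(
            erp.condition_erps(epochs, by=("bin",), keep=list(behavior.BIN_ORDER))
        )
        if with_visibility:
            pieces_visbin.append(
                erp.condition_erps(
                    epochs,
                    by=("visibility", "bin"),
                    keep=[(v, b) for v in ("high", "low") for b in behavior.BIN_ORDER],
                )
            )
    return (
        _concat_averages(pieces_bin),
        _concat_averages(pieces_visbin) if with_visibility else None,
    )


def _concat_averages(pieces):
    first = pieces[0]
    from dataclasses import replace

    return replace(
        first,
        data=np.concatenate([p.data for p in pieces], axis=0),
        participants=[pp for p in pieces for pp in p.participants],
        counts=pd.concat([p.counts for p in pieces], ignore_index=True),
    )


def run_behavior(config: RunConfig, trials: pd.DataFrame, compute_bfs=True) -> dict:
    """Exclusions, bias table, bootstrap CIs, ART ANOVAs."""
    filtered, report = behavior.filter_trials(
        trials, config.analysis.rt_max_s, config.analysis.max_abs_error
    )
    bias = behavior.bias_measure(
        filtered, sign_convention=config.analysis.bias_sign_convention
    )
    per_bin = (
        bias.dropna(subset=["m"])
        .groupby(["participant", "bin"], observed=True)["m"]
        .mean()
        .unstack("bin")
    )
    cis = {}
    for i, b in enumerate(behavior.BIN_ORDER):
        mean, lo, hi = behavior.bootstrap_ci(
            per_bin[b],
            config.analysis.n_boot,
            config.analysis.boot_level,
            derive_seed(config.seed, "boot", i),
        )
        cis[b] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    per_vis = (
        bias.dropna(subset=["m"])
        .groupby(["participant", "visibility"], observed=True)["m"]
        .mean()
        .unstack("visibility")
    )
    for i, v in enumerate(sorted(per_vis.columns)):
        mean, lo, hi = behavior.bootstrap_ci(
            per_vis[v],
            config.analysis.n_boot,
            config.analysis.boot_level,
            derive_seed(config.seed, "boot", 100 + i),
        )
        cis[f"visibility_{v}"] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return {
        "exclusions": report,
        "bias": bias,
        "bias_cis": cis,
        "sd_anova": behavior.sd_anova(bias, compute_bfs=compute_bfs),
        "error_anova": behavior.error_anova(filtered, compute_bfs=compute_bfs),
    }


def run_erp(
    config: RunConfig,
    avgs_by_bin,
    avgs_by_vis_bin=None,
    exploratory: bool = True,
    n_perm: int | None = None,
) -> dict:
    """Planned ROI cluster tests plus the exploratory all-channel scans."""
    n_perm = n_perm or config.analysis.n_perm
    out = {
        "roi": erp.roi_cluster_tests(
            avgs_by_bin,
            avgs_by_vis_bin,
            cluster_alpha=config.analysis.cluster_alpha,
            n_perm=n_perm,
            seed=derive_seed(config.seed, "cluster", 0),
            roi_mode=config.analysis.roi_mode,
        )
    }
    if exploratory:
        out["exploratory"] = erp.exploratory_cluster_scan(
            avgs_by_bin,
            cluster_alpha=config.analysis.cluster_alpha,
            n_perm=n_perm,
            seed=derive_seed(config.seed, "cluster", 1),
            adjacency_threshold=config.analysis.adjacency_threshold,
        )
    return out


def run_topography(config: RunConfig, avgs_by_bin, compute_bfs=True) -> pd.DataFrame:
    topo = topography.lpp_difference_topographies(avgs_by_bin)
    scaled = topography.vector_scale(
        topo, per_region=config.analysis.topo_per_region_scaling
    )
    return topography.topo_anova(scaled, compute_bfs=compute_bfs)


def run_regression(config: RunConfig, bias: pd.DataFrame, avgs_by_bin) -> dict:
    """Robust regression of behavioral on LPP difference scores, per contrast."""
    amps = erp.roi_amplitudes(avgs_by_bin, erp.ROI_SPECS["LPP"])
    out = {}
    for contrast in ("far", "close"):
        scores = inference.difference_scores(bias, amps, contrast)
        fit = inference.irls_regression(
            scores["d_erp"], scores["d_bias"], c=config.analysis.huber_c
        )
        out[f"{contrast}_vs_middle"] = {"scores": scores, "fit": fit}
    return out


def run_all(
    config: RunConfig,
    outdir=None,
    exploratory: bool = True,
    compute_bfs: bool = True,
    n_perm: int | None = None,
) -> dict:
    """The full synthetic replication: behavior, ERP, topography, regression.

    If ``outdir`` is given, writes the result bundle (CSV/JSON + the
    effective config) there.  Deterministic given ``config``.
    """
    trials = simulate_trials(config)
    results = {"behavior": run_behavior(config, trials, compute_bfs=compute_bfs)}
    avgs_bin, avgs_visbin = simulate_condition_averages(config, trials)
    results["erp"] = run_erp(
        config, avgs_bin, avgs_visbin, exploratory=exploratory, n_perm=n_perm
    )
    from .topography import DEFAULT_TOPO_SPEC

    topo_missing = [
        ch for ch in DEFAULT_TOPO_SPEC.channels
        if ch not in avgs_bin.channel_names
    ]
    if topo_missing:
        warnings.warn(
            f"topography stage skipped: channel(s) {topo_missing} not simulated"
        )
        results["topography"] = None
    else:
        results["topography"] = run_topography(
            config, avgs_bin, compute_bfs=compute_bfs
        )
    results["regression"] = run_regression(
        config, results["behavior"]["bias"], avgs_bin
    )
    results["trials"] = trials
    results["averages_by_bin"] = avgs_bin
    if outdir is not None:
        write_bundle(results, config, outdir)
    return results


def _cluster_records(res_dict):
    recs = []
    for key, clusters in res_dict.items():
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        if not clusters:
            recs.append({"test": label, "n_clusters": 0})
        for c in clusters:
            recs.append(
                {
                    "test": label,
                    "n_clusters": None,
                    **{k: v for k, v in c.to_dict().items() if k != "members"},
                }
            )
    return recs


def write_bundle(results: dict, config: RunConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    beh = results["behavior"]
    results["trials"].to_csv(out / "trials.csv", index=False)
    beh["bias"].to_csv(out / "bias.csv", index=False)
    beh["sd_anova"].to_csv(out / "sd_anova.csv", index=False)
    beh["error_anova"].to_csv(out / "error_anova.csv", index=False)
    if results["topography"] is not None:
        results["topography"].to_csv(out / "topography_anova.csv", index=False)
    summary = {
        "exclusions": beh["exclusions"],
        "bias_cis": beh["bias_cis"],
        "clusters": {
            section: _cluster_records(res)
            for section, res in results["erp"].items()
        },
        "regression": {
            k: {
                "slope": v["fit"].slope,
                "intercept": v["fit"].intercept,
                "F": v["fit"].F,
                "df": list(v["fit"].df),
                "p": v["fit"].p,
                "r2": v["fit"].r2,
                "r2_plain": v["fit"].r2_plain,
            }
            for k, v in results["regression"].items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
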