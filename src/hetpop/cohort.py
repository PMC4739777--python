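"""Multi-session cohorts: the across-"animal" layer of the analysis.

Group-level statements (effect sizes, AUC comparisons, regression
slopes, pre-stimulus predictability delta, pattern-consistency excess)
are made over a cohort of sessions, one summary point per session,
mirroring the across-animal meta-statistics of the experimental
design.  ``session_summary`` computes every per-session quantity the
group level consumes; ``cohort_summaries`` generates and summarizes a
seeded cohort.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .session import AnalysisConfig
from .synth import GeneratorConfig, generate_session
from .pipeline import PreprocessedSession, compute_metric_panel, \
    preprocess_session
from . import detection as ds
from . import metrics as pm


def session_summary(prep: PreprocessedSession,
                    config: Optional[AnalysisConfig] = None,
                    consistency_iterations: int = 100,
                    rng=None) -> dict:
    """Per-session quantities consumed by group-level statistics."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    panel = compute_metric_panel(prep)
    R = prep.responses
    outs = R.outcomes()
    cons = R.contrasts()
    rts = R.reaction_times()
    labels = ds.split_fast_slow(R)
    hits = outs == "hit"

    out: dict = {}
    out["cohens_d"] = {
        name: ds.effect_size_by_contrast(series.values, cons, outs)["mean"]
        for name, series in panel.items()}
    out["auc"] = {
        name: ds.auc_by_contrast(series.values, cons, outs)["mean"]
        for name in ("heterogeneity", "mean_dff")
        for series in (panel[name],)}
    out["rt_slope"] = {}
    for name in ("heterogeneity", "mean_dff"):
        try:
            out["rt_slope"][name] = ds.regress_metric_on_rt(
                panel[name].values[hits], rts[hits]).slope
        except ValueError:
            out["rt_slope"][name] = np.nan

    # per-response-type mean pre-stimulus metrics (one point per session)
    out["prestim_means"] = {}
    out["prestim_trials"] = {}
    for metric in ("heterogeneity", "mean_dff"):
        series = pm.prestim_metric(prep.dff, prep.frame_rate, R.trial_refs,
                                   prep.zscores, metric,
                                   config.prestim_window_s)
        vals = series.values
        by_type = {}
        trials_by_type = {}
        for lab in ("miss", "slow", "fast"):
            v = vals[(labels == lab) & np.isfinite(vals)]
            by_type[lab] = float(v.mean()) if v.size else np.nan
            trials_by_type[lab] = v
        out["prestim_means"][metric] = by_type
        out["prestim_trials"][metric] = trials_by_type

    cres = ds.pattern_consistency(R, prep.tuning, labels,
                                  shuffle_iterations=consistency_iterations,
                                  rng=rng,
                                  shuffle_scope="orientation_contrast")
    excess = {}
    for rtype in ("miss", "slow", "fast"):
        vals = [cres.real[(p, rtype)] - cres.shuffled[(p, rtype)]
                for p in ("preferred", "nonpreferred")]
        excess[rtype] = float(np.nanmean(vals))
    out["consistency_excess"] = excess
    return out


def cohort_summaries(n_sessions: int, base_seed: int,
                     generator_overrides: Optional[dict] = None,
                     analysis_config: Optional[AnalysisConfig] = None,
                     consistency_iterations: int = 100) -> list[dict]:
    """Generate and summarize ``n_sessions`` independent sessions.

    Session s uses generator seed ``base_seed * 1000 + s`` (kept below
    2**31) so cohorts for different base seeds never overlap.
    """
    analysis_config = analysis_config or AnalysisConfig(baseline_stride=8)
    overrides = dict(generator_overrides or {})
    summaries = []
    for s in range(n_sessions):
        seed = (base_seed * 1000 + s) % (2 ** 31 - 1)
        cfg = GeneratorConfig(seed=seed, **overrides)
        session, _ = generate_session(cfg)
        prep = preprocess_session(
            session, replace(analysis_config, rng_seed=seed))
        summaries.append(session_summary(
            prep, analysis_config,
            consistency_iterations=consistency_iterations, rng=seed + 1))
    return summaries


def recovery_stats(summaries: list[dict]) -> dict:
    """Group-level recovery quantities from a cohort of summaries."""
    def collect(path):
        vals = []
        for s in summaries:
            v = s
            for key in path:
                v = v[key]
            vals.append(v)
        return np.asarray(vals, float)

    d_het = collect(("cohens_d", "heterogeneity"))
    auc_het = collect(("auc", "heterogeneity"))
    auc_dff = collect(("auc", "mean_dff"))
    slope_het = collect(("rt_slope", "heterogeneity"))

    deltas = {}
    for metric in ("heterogeneity", "mean_dff"):
        fast = collect(("prestim_means", metric, "fast"))
        miss = collect(("prestim_means", metric, "miss"))
        ok = np.isfinite(fast) & np.isfinite(miss)
        if ok.sum() >= 2:
            deltas[metric] = ds.prestim_predictability_delta(
                fast[ok], miss[ok]).mean
        else:
            deltas[metric] = np.nan

    exc_miss = collect(("consistency_excess", "miss"))
    exc_hit = np.nanmean([collect(("consistency_excess", "slow")),
                          collect(("consistency_excess", "fast"))], axis=0)
    return {
        "mean_cohens_d_heterogeneity": float(np.nanmean(d_het)),
        "mean_auc_heterogeneity": float(np.nanmean(auc_het)),
        "mean_auc_dff": float(np.nanmean(auc_dff)),
        "mean_rt_slope_heterogeneity": float(np.nanmean(slope_het)),
        "delta_fast_vs_miss": deltas,
        "consistency_excess_hit": float(np.nanmean(exc_hit)),
        "consistency_excess_miss": float(np.nanmean(exc_miss)),
    }
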