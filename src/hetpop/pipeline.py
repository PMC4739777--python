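"""End-to-end orchestration: session -> preprocessing -> metrics ->
statistics, decoders, and geometry, with per-stage error isolation.

Every stochastic stage draws from a sub-stream derived from the one
config seed, so the full report is a pure function of (inputs, config,
seed) and individual stages remain reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .session import AnalysisConfig, SessionData, TEST_CONTRASTS
from .synth import GeneratorConfig, GroundTruth, generate_session
from . import preprocess as pp
from . import metrics as pm
from . import hitmod
from . import detection as ds
from . import decoding as dec
from . import geometry as geo


@dataclass
class AnalysisReport:
    summaries: dict = field(default_factory=dict)
    config: Optional[AnalysisConfig] = None
    seed: int = 0
    version: str = ""
    warnings: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": dataclasses.asdict(self.config) if self.config else None,
            "warnings": self.warnings,
            "errors": self.errors,
            "summaries": _jsonable(self.summaries),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


@dataclass
class PreprocessedSession:
    """Everything downstream stages consume."""

    responses: pp.TrialResponseMatrix
    zscores: pp.ZScoreMatrix
    tuning: pp.TuningAssignment
    dff: np.ndarray
    frame_rate: float
    qc: Optional[pp.QCReport] = None
    neuropil_r: Optional[np.ndarray] = None


def preprocess_session(session: SessionData,
                       config: Optional[AnalysisConfig] = None,
                       neuropil_subtract: bool = False,
                       ) -> PreprocessedSession:
    config = config or AnalysisConfig()
    fluor = session.soma_fluorescence
    neuropil_r = None
    qc = None
    if session.neuropil_fluorescence is not None:
        if neuropil_subtract:
            fluor, neuropil_r = pp.neuropil_correct(
                fluor, session.neuropil_fluorescence)
        qc = pp.discriminability_qc(session.soma_fluorescence,
                                    session.neuropil_fluorescence,
                                    session.frame_rate)
    dff, _ = pp.compute_dff(fluor, session.frame_rate,
                            config.baseline_window_s,
                            stride=config.baseline_stride)
    responses = pp.extract_trial_responses(session, dff, config)
    zscores = pp.zscore_responses(responses, scope=config.zscore_scope)
    tuning = pp.assign_preferred_orientation(responses)
    return PreprocessedSession(responses=responses, zscores=zscores,
                               tuning=tuning, dff=dff,
                               frame_rate=session.frame_rate, qc=qc,
                               neuropil_r=neuropil_r)


def compute_metric_panel(prep: PreprocessedSession) -> dict:
    """The per-trial metric series every comparison draws on."""
    z = prep.zscores
    R = prep.responses
    het = pm.heterogeneity(z)
    mhet = pm.multidim_heterogeneity(z)
    plike_mean, plike_spread = pm.pearson_like(z)
    var = pm.variance_metric(z)
    kurt = pm.sparseness_kurtosis(z)
    mean_dff = pm.MetricSeries("mean_dff", R.values.mean(axis=0),
                               units="dF/F")
    mean_z = pm.MetricSeries("mean_zscored", z.values.mean(axis=0),
                             units="SD")
    return {m.metric_name: m for m in
            (het, mhet, plike_mean, plike_spread, var, kurt,
             mean_dff, mean_z)}


def run_full_analysis(session: Optional[SessionData] = None,
                      truth: Optional[GroundTruth] = None,
                      generator_config: Optional[GeneratorConfig] = None,
                      config: Optional[AnalysisConfig] = None,
                      ) -> AnalysisReport:
    """Run every stage on a provided or generated session.

    A failure in one analysis records an error entry and does not abort
    the others.
    """
    config = config or AnalysisConfig()
    report = AnalysisReport(config=config, seed=config.rng_seed,
                            version=__version__)
    if session is None:
        generator_config = generator_config or GeneratorConfig(
            seed=config.rng_seed)
        session, truth = generate_session(generator_config)

    prep = preprocess_session(session, config)
    panel = compute_metric_panel(prep)
    R = prep.responses
    outs = R.outcomes()
    cons = R.contrasts()
    labels = ds.split_fast_slow(R)
    it = config.shuffle_iterations

    def stage(name, fn):
        try:
            report.summaries[name] = fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            report.errors[name] = f"{type(exc).__name__}: {exc}"

    stage("behavior", lambda: _behavior_summary(R))
    stage("effect_sizes", lambda: {
        name: ds.effect_size_by_contrast(series.values, cons, outs)
        for name, series in panel.items()})
    stage("roc", lambda: {
        name: ds.auc_by_contrast(series.values, cons, outs)
        for name, series in (("heterogeneity", panel["heterogeneity"]),
                             ("mean_dff", panel["mean_dff"]))})
    stage("rt_regression", lambda: _rt_regressions(panel, outs, R))
    stage("hit_modulation", lambda: _hitmod_summary(
        R, it.get("hit_modulation", 1000), config))
    stage("pattern_consistency", lambda: _consistency_summary(
        R, prep.tuning, labels, it.get("pattern_consistency", 100), config))
    stage("noise_correlations", lambda: _noise_summary(R, labels))
    stage("prestim_predictability", lambda: _prestim_summary(
        prep, labels, config))
    stage("presence_decoding", lambda: _presence_summary(
        R, prep.tuning, it.get("presence_similarity", 1000), config))
    stage("orientation_decoding", lambda: _orientation_summary(R, panel))
    stage("stimulus_type_decoding", lambda: _stimtype_summary(R))
    stage("geometry", lambda: _geometry_summary(R))
    return report


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _behavior_summary(R: pp.TrialResponseMatrix) -> dict:
    outs = R.outcomes()
    cons = R.contrasts()
    rates = {}
    for c in np.unique(cons):
        mask = cons == c
        responded = np.isin(outs[mask], ("hit", "false_alarm"))
        rates[float(c)] = float(responded.mean())
    n0 = int((cons == 0.0).sum())
    k0 = int(np.isin(outs[cons == 0.0], ("false_alarm",)).sum())
    n100 = int((cons == 100.0).sum())
    k100 = int((outs[cons == 100.0] == "hit").sum())
    return {
        "response_rate_by_contrast": rates,
        "probe0_ci": ds.clopper_pearson_ci(k0, n0) if n0 else None,
        "probe100_ci": ds.clopper_pearson_ci(k100, n100) if n100 else None,
        "significant_detection": (
            ds.significant_detection((k0, n0), (k100, n100))
            if n0 and n100 else None),
    }


def _rt_regressions(panel, outs, R) -> dict:
    """Per-metric OLS of trial metric on hit reaction times (this
    session); group-level inference over sessions lives in the
    analysis drivers."""
    rts = R.reaction_times()
    hits = outs == "hit"
    out = {}
    for name, series in panel.items():
        try:
            fit = ds.regress_metric_on_rt(series.values[hits], rts[hits])
            out[name] = {"slope": fit.slope, "r_squared": fit.r_squared,
                         "p": fit.p_value, "n": fit.n}
        except ValueError as exc:
            out[name] = {"error": str(exc)}
    return out


def _hitmod_summary(R, iterations, config) -> dict:
    psi = hitmod.hit_modulation_matrix(R)
    result = hitmod.decompose(psi, iterations=iterations,
                              rng=_substream(config.rng_seed, 1))
    return {
        "r_squared": result.r_squared,
        "shuffle_mean": result.shuffle_mean,
        "shuffle_sd": result.shuffle_sd,
        "significant": result.significant,
        "frac_modulated": result.frac_modulated_neurons,
        "frac_modulated_significant": result.frac_modulated_significant,
        "dropped_strata": psi.dropped_strata,
    }


def _consistency_summary(R, tuning, labels, iterations, config) -> dict:
    res = ds.pattern_consistency(R, tuning, labels,
                                 shuffle_iterations=iterations,
                                 rng=_substream(config.rng_seed, 2))
    return {"real": {f"{k[0]}/{k[1]}": v for k, v in res.real.items()},
            "shuffled": {f"{k[0]}/{k[1]}": v
                         for k, v in res.shuffled.items()}}


def _noise_summary(R, labels) -> dict:
    out = {}
    full = ds.noise_correlations(R)
    out["all_test_trials"] = full.mean_offdiag()
    for lab in ("fast", "slow"):
        mask = labels == lab
        if mask.sum() >= 12:
            out[lab] = ds.noise_correlations(R, subset_mask=mask
                                             ).mean_offdiag()
        else:
            out[lab] = None
    return out


def _prestim_summary(prep: PreprocessedSession, labels, config) -> dict:
    out = {}
    for metric in ("heterogeneity", "mean_dff"):
        series = pm.prestim_metric(prep.dff, prep.frame_rate,
                                   prep.responses.trial_refs,
                                   prep.zscores, metric,
                                   config.prestim_window_s)
        vals = series.values
        groups = {lab: vals[(labels == lab) & np.isfinite(vals)]
                  for lab in ("miss", "slow", "fast")}
        deltas = {}
        for r1, r2 in (("fast", "miss"), ("slow", "miss"), ("fast", "slow")):
            if groups[r1].size >= 2 and groups[r2].size >= 1:
                deltas[f"{r1}_vs_{r2}"] = ds.prestim_predictability_delta(
                    groups[r1], groups[r2]).mean
        predictive = None
        ok = np.isfinite(vals) & (labels != "")
        lab_ok = labels[ok]
        if all(np.sum(lab_ok == c) >= 3 for c in ("miss", "slow", "fast")):
            predictive = dec.predictive_decode_response_type(
                vals[ok], lab_ok).mean_index
        out[metric] = {
            "group_means": {k: (float(v.mean()) if v.size else None)
                            for k, v in groups.items()},
            "delta": deltas,
            "predictive_index": predictive,
        }
    return out


def _presence_summary(R, tuning, iterations, config) -> dict:
    result = dec.decode_stimulus_presence(R, tuning)
    rates = dec.presence_rate_by_contrast(result, R)
    outs = R.outcomes()
    cons = R.contrasts()
    behavior = {float(c): float(np.isin(
        outs[cons == c], ("hit", "false_alarm")).mean())
        for c in np.unique(cons)}
    shared = sorted(set(rates) & set(behavior))
    dvec = [rates[c] for c in shared]
    bvec = [behavior[c] for c in shared]
    sim = dec.presence_behavior_similarity(
        dvec, bvec, iterations=iterations,
        rng=_substream(config.rng_seed, 3))
    test = np.isin(cons, TEST_CONTRASTS) & np.isin(outs, ("hit", "miss"))
    decoded_present = np.array(
        [d == "present" for d in result.decoded[test]])
    chi2 = dec.chi_square_correspondence(decoded_present,
                                         outs[test] == "hit")
    return {"present_rate_by_contrast": rates,
            "behavior_rate_by_contrast": behavior,
            "similarity": sim,
            "chi2": {"chi2": chi2["chi2"], "p": chi2["p"]}}


def _orientation_summary(R, panel) -> dict:
    acc = dec.orientation_accuracy_by_contrast(R)
    split = {}
    cons = R.contrasts()
    for metric in ("mean_dff", "heterogeneity"):
        corrects, metric_vals, con_vals = [], [], []
        for c in np.unique(cons):
            try:
                res = dec.decode_orientation(R, c)
            except ValueError:
                continue
            mask = cons == c
            corrects.append(res.correct)
            metric_vals.append(panel[metric].values[mask])
            con_vals.append(np.full(int(mask.sum()), c))
        if corrects:
            split[metric] = dec.decoding_vs_metric_split(
                np.concatenate(corrects), np.concatenate(metric_vals),
                np.concatenate(con_vals))
    return {"accuracy_by_contrast": acc, "metric_split": split}


def _stimtype_summary(R) -> dict:
    result = dec.decode_stimulus_type(R)
    keep = result.strata["kept_mask"]
    outs = R.outcomes()[keep]
    by_outcome = dec.stimulus_type_accuracy_by_outcome(result, outs)
    return {"accuracy": result.accuracy,
            "by_outcome": by_outcome,
            "n_classes": len(result.classes)}


def _geometry_summary(R) -> dict:
    outs = R.outcomes()
    cons = R.contrasts()
    mask = np.isin(cons, TEST_CONTRASTS) & np.isin(outs, ("hit", "miss"))
    cloud = geo.PointCloud(points=R.values[:, mask].T,
                           labels=outs[mask])
    out = {}
    for lab in ("hit", "miss"):
        if (cloud.labels == lab).sum() >= 3:
            dd = geo.pairwise_distances(cloud, lab)
            out[f"{lab}_mean_distance"] = dd.mean
            out[f"{lab}_asymmetry"] = geo.asymmetry_by_mirroring(cloud, lab)
    if all((cloud.labels == lab).sum() >= 4 for lab in ("hit", "miss")):
        out["decoding"] = geo.hitmiss_decode_after_removal(cloud)
    return out
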