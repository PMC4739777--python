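"""Run the full single-session analysis battery on one session.

Executes every stage (metrics, hit modulation, detection statistics,
decoders, geometry) on the first cohort session and writes the complete
report to results/03_session_report.json.

Run from the repository root:  python analysis/03_session_report.py
"""

import json
from pathlib import Path

from hetpop import AnalysisConfig, GeneratorConfig, run_full_analysis

ROOT = Path(__file__).resolve().parents[1]
SEED = 1000


def main():
    cfg = AnalysisConfig(baseline_stride=8, rng_seed=SEED)
    gen = GeneratorConfig(n_neurons=60, n_blocks=3, seed=SEED)
    report = run_full_analysis(generator_config=gen, config=cfg)

    out = ROOT / "results" / "03_session_report.json"
    out.parent.mkdir(exist_ok=True)
    report.to_json(out)

    s = report.summaries
    print("single-session findings (seed %d):" % SEED)
    if "behavior" in s:
        rates = s["behavior"]["response_rate_by_contrast"]
        print("  response rate by contrast:",
              {k: round(v, 2) for k, v in rates.items()})
        print("  significant detection (CP CIs):",
              s["behavior"]["significant_detection"])
    if "effect_sizes" in s:
        print("  hit-miss Cohen's d: heterogeneity %.3f vs mean dF/F %.3f"
              % (s["effect_sizes"]["heterogeneity"]["mean"],
                 s["effect_sizes"]["mean_dff"]["mean"]))
    if "roc" in s:
        print("  ROC AUC: heterogeneity %.3f vs mean dF/F %.3f"
              % (s["roc"]["heterogeneity"]["mean"],
                 s["roc"]["mean_dff"]["mean"]))
    if "rt_regression" in s:
        het = s["rt_regression"]["heterogeneity"]
        print("  heterogeneity-vs-RT slope %.3f (R2 %.3f, p %.3g)"
              % (het["slope"], het["r_squared"], het["p"]))
    if "hit_modulation" in s:
        hm = s["hit_modulation"]
        print("  hit-modulation R2 (neuron/trial/both): "
              + "/".join("%.3f" % hm["r_squared"][m]
                         for m in ("neuron", "trial", "both")))
    if "orientation_decoding" in s:
        acc = s["orientation_decoding"]["accuracy_by_contrast"]
        print("  orientation decoding by contrast:",
              {k: (round(v, 2) if v == v else None) for k, v in acc.items()})
    if "geometry" in s and "decoding" in s["geometry"]:
        print("  hit/miss decoding after removal:",
              {k: round(v, 3) for k, v in s["geometry"]["decoding"].items()})
    for stage, err in report.errors.items():
        print(f"  [stage failed] {stage}: {err}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
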