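"""Across-session (group-level) statistics on the synthetic cohort.

One summary point per session, eight sessions, mirroring an
across-animal meta-analysis: hit/miss effect sizes, heterogeneity vs
mean-dF/F ROC AUC, heterogeneity-vs-reaction-time regression slopes,
pre-stimulus predictability (delta), and activation-pattern
consistency.  Writes results/04_group_stats.json.

Run from the repository root:  python analysis/04_group_statistics.py
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from hetpop.cohort import cohort_summaries, recovery_stats
from hetpop.detection import fdr_correct

ROOT = Path(__file__).resolve().parents[1]
BASE_SEED = 1
OVERRIDES = dict(n_neurons=60, n_blocks=3)


def main():
    summaries = cohort_summaries(8, BASE_SEED, OVERRIDES,
                                 consistency_iterations=100)
    stats = recovery_stats(summaries)

    d_het = [s["cohens_d"]["heterogeneity"] for s in summaries]
    d_dff = [s["cohens_d"]["mean_dff"] for s in summaries]
    auc_het = [s["auc"]["heterogeneity"] for s in summaries]
    auc_dff = [s["auc"]["mean_dff"] for s in summaries]
    slopes = [s["rt_slope"]["heterogeneity"] for s in summaries]

    t_d, p_d = sps.ttest_rel(d_het, d_dff)
    t_auc, p_auc = sps.ttest_rel(auc_het, auc_dff)
    t_sl, p_sl = sps.ttest_1samp(slopes, 0.0)
    p_adj = fdr_correct([p_d, p_auc, p_sl])

    print("group-level findings (n=8 sessions):")
    print(f"  hit-miss Cohen's d: heterogeneity {np.mean(d_het):.3f} "
          f"vs mean dF/F {np.mean(d_dff):.3f} "
          f"(paired t={t_d:.2f}, p_fdr={p_adj[0]:.3g})")
    print(f"  ROC AUC: heterogeneity {np.mean(auc_het):.3f} "
          f"vs mean dF/F {np.mean(auc_dff):.3f} "
          f"(paired t={t_auc:.2f}, p_fdr={p_adj[1]:.3g})")
    print(f"  heterogeneity-vs-RT slope: mean {np.mean(slopes):.3f} "
          f"(t={t_sl:.2f}, p_fdr={p_adj[2]:.3g})")
    print(f"  pre-stimulus delta fast-vs-miss: "
          f"heterogeneity {stats['delta_fast_vs_miss']['heterogeneity']:.3f}"
          f" vs mean dF/F {stats['delta_fast_vs_miss']['mean_dff']:.3f}")
    print(f"  pattern-consistency excess: hits "
          f"{stats['consistency_excess_hit']:.3f} vs miss "
          f"{stats['consistency_excess_miss']:.3f}")

    payload = {
        "cohort": {"n_sessions": 8, "base_seed": BASE_SEED, **OVERRIDES},
        "recovery": stats,
        "group_tests": {
            "cohens_d_het_vs_dff": {"t": float(t_d), "p_fdr": float(p_adj[0])},
            "auc_het_vs_dff": {"t": float(t_auc), "p_fdr": float(p_adj[1])},
            "rt_slope_vs_zero": {"t": float(t_sl), "p_fdr": float(p_adj[2])},
        },
        "per_session": {
            "cohens_d_heterogeneity": d_het,
            "cohens_d_mean_dff": d_dff,
            "auc_heterogeneity": auc_het,
            "auc_mean_dff": auc_dff,
            "rt_slope_heterogeneity": slopes,
        },
    }
    out = ROOT / "results" / "04_group_stats.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
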