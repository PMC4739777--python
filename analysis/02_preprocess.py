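"""Preprocess the cohort: dF/F0, QC, trial extraction, tuning.

Reads scratch/sessions/ (produced by 01_simulate.py), writes per-session
trial responses (long format) to scratch/responses/ and a QC summary to
results/02_qc_summary.tsv.

Run from the repository root:  python analysis/02_preprocess.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hetpop import AnalysisConfig, read_session
from hetpop.pipeline import preprocess_session

ROOT = Path(__file__).resolve().parents[1]


def main():
    sessions = sorted((ROOT / "scratch" / "sessions").glob("session_*"))
    if not sessions:
        raise SystemExit("no sessions found; run analysis/01_simulate.py first")
    resp_dir = ROOT / "scratch" / "responses"
    resp_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sessions:
        session = read_session(path)
        seed = int(path.name.split("_")[1])
        prep = preprocess_session(
            session, AnalysisConfig(baseline_stride=8, rng_seed=seed))
        R = prep.responses
        long = pd.DataFrame({
            "trial_index": np.repeat(
                [tr.trial_index for tr in R.trial_refs], R.n_neurons),
            "neuron": np.tile(R.neuron_ids, R.n_trials),
            "response": R.values.T.ravel(),
        })
        long.to_csv(resp_dir / f"{path.name}_responses.tsv", sep="\t",
                    index=False)
        rows.append({
            "session": path.name,
            "n_trials_kept": R.n_trials,
            "n_trials_excluded": len(R.excluded),
            "n_neurons": R.n_neurons,
            "n_consistent_neurons": int(prep.tuning.consistent.sum()),
            "n_qc_flagged": int(prep.qc.flagged.sum()) if prep.qc else 0,
        })
        print(f"{path.name}: kept {R.n_trials} trials "
              f"(excluded {len(R.excluded)} fast licks), "
              f"{int(prep.tuning.consistent.sum())}/{R.n_neurons} "
              "consistently tuned neurons")
    out = ROOT / "results" / "02_qc_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
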