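"""Session data model and on-disk formats.

A *session* is one imaging experiment: a neurons x frames fluorescence
matrix (optionally with a matched neuropil matrix), a frame rate, and an
ordered trial table for a go/no-go contrast-detection task with drifting
gratings (8 directions x 6 contrasts presented in randomized 48-trial
blocks).

On disk a session is a directory holding ``trials.tsv`` (one row per
trial) and ``fluorescence.h5`` (datasets ``/soma`` and optionally
``/neuropil``, attribute ``frame_rate_hz``).  A delimited-text fallback
(``soma.tsv`` / ``neuropil.tsv``) is supported for fully inspectable
fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

CONTRAST_LEVELS = (0.0, 0.5, 2.0, 8.0, 32.0, 100.0)
#: contrasts over which hit/miss comparisons are made
TEST_CONTRASTS = (0.5, 2.0, 8.0, 32.0)
DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))
ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)

OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")

TRIALS_COLUMNS = [
    "trial_index",
    "direction_deg",
    "contrast_pct",
    "onset_frame",
    "offset_frame",
    "outcome",
    "reaction_time_s",
    "block_index",
]


class SessionValidationError(ValueError):
    """Raised when a session violates the data-model invariants."""


def fold_direction_to_orientation(direction: float) -> float:
    """Fold a drifting-grating direction onto its orientation axis.

    Opposite motion directions share a grating orientation, so the eight
    task directions collapse onto four orientations (``direction mod
    180``).  Raises for directions outside ``[0, 360)``.
    """
    direction = float(direction)
    if not 0.0 <= direction < 360.0:
        raise ValueError(f"direction {direction} outside [0, 360)")
    return direction % 180.0


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the 8-direction x 6-contrast stimulus design."""

    direction: float
    contrast: float

    def __post_init__(self):
        if not 0.0 <= self.direction < 360.0:
            raise SessionValidationError(
                f"direction {self.direction} outside [0, 360)")
        if self.contrast not in CONTRAST_LEVELS:
            raise SessionValidationError(
                f"contrast {self.contrast} not in {CONTRAST_LEVELS}")

    @property
    def orientation(self) -> float:
        return self.direction % 180.0

    @property
    def is_probe(self) -> bool:
        """0%-contrast blank; its orientation carries no stimulus."""
        return self.contrast == 0.0


@dataclass
class TrialRecord:
    """One trial: condition, frame interval, outcome, reaction time.

    Frame indices are 0-based with half-open intervals ``[onset,
    offset)``.  ``analysis_offset_frame`` is the end of the response
    window actually analysed: the stimulus offset for hits, a
    duration-matched offset assigned during preprocessing for misses.
    """

    trial_index: int
    condition: StimulusCondition
    onset_frame: int
    offset_frame: int
    outcome: str
    reaction_time: Optional[float] = None
    block_index: int = 0
    excluded: bool = False
    exclusion_reason: str = ""
    analysis_offset_frame: Optional[int] = None

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise SessionValidationError(
                f"trial {self.trial_index}: unknown outcome {self.outcome!r}")
        if self.onset_frame >= self.offset_frame:
            raise SessionValidationError(
                f"trial {self.trial_index}: onset_frame {self.onset_frame} "
                f">= offset_frame {self.offset_frame}")
        if self.condition.contrast == 0.0:
            if self.outcome in ("hit", "miss"):
                raise SessionValidationError(
                    f"trial {self.trial_index}: outcome {self.outcome!r} "
                    "invalid for 0%-contrast probe")
        else:
            if self.outcome in ("false_alarm", "correct_rejection"):
                raise SessionValidationError(
                    f"trial {self.trial_index}: outcome {self.outcome!r} "
                    "only valid for 0%-contrast probes")
        if self.outcome in ("hit", "false_alarm"):
            if self.reaction_time is None:
                raise SessionValidationError(
                    f"trial {self.trial_index}: {self.outcome} requires a "
                    "reaction time")
            if not 0.0 < self.reaction_time <= 3.0:
                raise SessionValidationError(
                    f"trial {self.trial_index}: reaction time "
                    f"{self.reaction_time} outside (0, 3.0] s")

    @property
    def is_response(self) -> bool:
        return self.outcome in ("hit", "false_alarm")


@dataclass
class SessionData:
    """A full imaging session; the unit of every analysis."""

    frame_rate: float
    soma_fluorescence: np.ndarray
    trials: list[TrialRecord]
    neuropil_fluorescence: Optional[np.ndarray] = None

    def __post_init__(self):
        self.soma_fluorescence = np.asarray(self.soma_fluorescence, float)
        if self.soma_fluorescence.ndim != 2:
            raise SessionValidationError("soma_fluorescence must be 2-D")
        if self.n_neurons < 2:
            raise SessionValidationError("need at least 2 neurons")
        if self.frame_rate <= 0:
            raise SessionValidationError("frame_rate must be positive")
        if self.neuropil_fluorescence is not None:
            self.neuropil_fluorescence = np.asarray(
                self.neuropil_fluorescence, float)
            if self.neuropil_fluorescence.shape != self.soma_fluorescence.shape:
                raise SessionValidationError(
                    "neuropil shape "
                    f"{self.neuropil_fluorescence.shape} does not match soma "
                    f"{self.soma_fluorescence.shape}")
        for tr in self.trials:
            if tr.offset_frame > self.n_frames:
                raise SessionValidationError(
                    f"trial {tr.trial_index}: offset_frame {tr.offset_frame} "
                    f"beyond recording length {self.n_frames}")

    @property
    def n_neurons(self) -> int:
        return self.soma_fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.soma_fluorescence.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block_indices(self) -> list[int]:
        return sorted({tr.block_index for tr in self.trials})


@dataclass
class AnalysisConfig:
    """Knobs shared across the pipeline, with task-anchored defaults."""

    zscore_scope: str = "global"          # or "per_contrast"
    rt_exclusion_s: float = 0.150
    baseline_window_s: float = 30.0
    baseline_stride: int = 1
    prestim_window_s: float = 3.0
    shuffle_iterations: dict = field(default_factory=lambda: {
        "hit_modulation": 1000,
        "pattern_consistency": 100,
        "presence_similarity": 1000,
    })
    fdr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.zscore_scope not in ("global", "per_contrast"):
            raise ValueError(f"unknown zscore_scope {self.zscore_scope!r}")
        for name in ("rt_exclusion_s", "baseline_window_s", "prestim_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        rows.append({
            "trial_index": tr.trial_index,
            "direction_deg": tr.condition.direction,
            "contrast_pct": tr.condition.contrast,
            "onset_frame": tr.onset_frame,
            "offset_frame": tr.offset_frame,
            "outcome": tr.outcome,
            "reaction_time_s": np.nan if tr.reaction_time is None
            else tr.reaction_time,
            "block_index": tr.block_index,
        })
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise SessionValidationError(
            f"trial table missing columns: {sorted(missing)}")
    trials = []
    for _, row in df.iterrows():
        rt = row["reaction_time_s"]
        trials.append(TrialRecord(
            trial_index=int(row["trial_index"]),
            condition=StimulusCondition(
                direction=float(row["direction_deg"]),
                contrast=float(row["contrast_pct"])),
            onset_frame=int(row["onset_frame"]),
            offset_frame=int(row["offset_frame"]),
            outcome=str(row["outcome"]),
            reaction_time=None if pd.isna(rt) else float(rt),
            block_index=int(row["block_index"]),
        ))
    return trials


def write_session(session: SessionData, out_dir, text_fluorescence=False) -> Path:
    """Write trials.tsv + fluorescence.h5 (or .tsv fallback) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_to_frame(session.trials).to_csv(
        out_dir / "trials.tsv", sep="\t", index=False)
    if text_fluorescence:
        np.savetxt(out_dir / "soma.tsv", session.soma_fluorescence,
                   delimiter="\t")
        if session.neuropil_fluorescence is not None:
            np.savetxt(out_dir / "neuropil.tsv",
                       session.neuropil_fluorescence, delimiter="\t")
        with open(out_dir / "frame_rate.txt", "w") as fh:
            fh.write(f"{session.frame_rate!r}\n")
    else:
        with h5py.File(out_dir / "fluorescence.h5", "w") as fh:
            fh.create_dataset("soma", data=session.soma_fluorescence)
            if session.neuropil_fluorescence is not None:
                fh.create_dataset("neuropil",
                                  data=session.neuropil_fluorescence)
            fh.attrs["frame_rate_hz"] = session.frame_rate
    return out_dir


def read_session(session_dir) -> SessionData:
    """Read and validate a session directory written by :func:`write_session`."""
    session_dir = Path(session_dir)
    trials_path = session_dir / "trials.tsv"
    if not trials_path.exists():
        raise SessionValidationError(f"missing trial table {trials_path}")
    trials = trials_from_frame(pd.read_csv(trials_path, sep="\t"))

    h5_path = session_dir / "fluorescence.h5"
    neuropil = None
    if h5_path.exists():
        with h5py.File(h5_path, "r") as fh:
            soma = fh["soma"][:]
            if "neuropil" in fh:
                neuropil = fh["neuropil"][:]
            frame_rate = float(fh.attrs["frame_rate_hz"])
    else:
        soma_path = session_dir / "soma.tsv"
        if not soma_path.exists():
            raise SessionValidationError(
                f"no fluorescence.h5 or soma.tsv in {session_dir}")
        soma = np.loadtxt(soma_path, delimiter="\t", ndmin=2)
        np_path = session_dir / "neuropil.tsv"
        if np_path.exists():
            neuropil = np.loadtxt(np_path, delimiter="\t", ndmin=2)
        with open(session_dir / "frame_rate.txt") as fh:
            frame_rate = float(fh.read().strip())
    return SessionData(frame_rate=frame_rate, soma_fluorescence=soma,
                       trials=trials, neuropil_fluorescence=neuropil)


# ---------------------------------------------------------------------------
# Block-structure report
# ---------------------------------------------------------------------------

def validate_block_structure(session: SessionData) -> pd.DataFrame:
    """Per-block condition audit against the 48-trial design.

    Each repetition block should present each of the 48 (direction,
    contrast) conditions exactly once, yielding a 1:5 probe:stimulus
    ratio (8 of 48 trials at 0% contrast).  Report-only: one row per
    block with counts and deviation flags.
    """
    rows = []
    for block in session.block_indices():
        trs = [t for t in session.trials if t.block_index == block]
        conds = [(t.condition.direction, t.condition.contrast) for t in trs]
        n_probe = sum(1 for t in trs if t.condition.is_probe)
        expected = {(d, c) for d in DIRECTIONS for c in CONTRAST_LEVELS}
        rows.append({
            "block_index": block,
            "n_trials": len(trs),
            "n_unique_conditions": len(set(conds)),
            "n_probe_trials": n_probe,
            "complete_design": set(conds) == expected and len(conds) == 48,
            "deviates": not (len(trs) == 48 and len(set(conds)) == 48),
        })
    return pd.DataFrame(rows, columns=[
        "block_index", "n_trials", "n_unique_conditions", "n_probe_trials",
        "complete_design", "deviates"])
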