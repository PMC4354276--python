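"""Simulated experimental sessions and whole-group studies.

``run_cf_session`` reproduces the contrast-detection design: 300 2IFC
trials, five conditions (four flanker orientation offsets plus a
no-flanker baseline) randomly interleaved so that each aligned 5-trial
window contains every condition exactly once, each condition driven by
its own independent psi-method state.

``run_ci_session`` reproduces the contour-detection design per shape:
40 presentations of each of the seven jitter levels, arranged in four
blocks of 70 trials (10 per level per block, shuffled within block), with
per-trial gaze deviations recorded for the fixation filter; tolerances
come from the constant-stimuli logistic fit.

``run_group_study`` wraps both sessions for two groups (13 + 13 by
default), with the shape order counterbalanced across participant
indices, and bundles trial logs, thresholds and tolerances into one
:class:`StudyData`.

Presentation timing is recorded as session metadata but not simulated:
no analysis consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import (
    ObserverProfile,
    Participant,
    respond_cf,
    respond_ci,
    sample_gaze,
    sample_participant,
)
from .psi import PsiAdaptive, PsiConfig
from .psychometric import ConstantStimuliModel, ThresholdResult
from .stimuli.collinear import BASELINE, CF_OFFSETS
from .stimuli.contour import JITTER_LEVELS

__all__ = [
    "CF_CONDITIONS",
    "SESSION_TIMING",
    "StudyData",
    "run_cf_session",
    "run_ci_session",
    "run_group_study",
]

#: The five interleaved contrast-detection conditions.
CF_CONDITIONS = (BASELINE,) + CF_OFFSETS

#: Display timing constants (ms), recorded as metadata only.
SESSION_TIMING = {
    "cf_presentation_ms": 105,
    "ci_presentation_ms": 130,
    "ci_isi_ms": 505,
}

#: Trials per condition in a contrast-detection session.
CF_TRIALS_PER_CONDITION = 60

#: Contour-detection block structure: presentations per level and blocks.
CI_TRIALS_PER_LEVEL = 40
CI_BLOCKS = 4


def _simulate_2ifc(correct_response: bool, rng: np.random.Generator):
    """Draw the target interval and the implied response interval."""
    target_interval = int(rng.integers(1, 3))
    if correct_response:
        response_interval = target_interval
    else:
        response_interval = 3 - target_interval
    return target_interval, response_interval


def run_cf_session(
    participant: Participant,
    psi_config: PsiConfig | None = None,
    rng: np.random.Generator | int = 0,
    participant_id: str = "p0",
) -> tuple[pd.DataFrame, dict[object, ThresholdResult]]:
    """Run one 300-trial adaptive contrast-detection session.

    Returns the trial log and the final psi threshold estimate per
    condition (thresholds at the 81.6% correct level).
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    psi_config = psi_config or PsiConfig()
    states = {cond: PsiAdaptive(psi_config) for cond in CF_CONDITIONS}
    rows = []
    trial = 0
    for window in range(CF_TRIALS_PER_CONDITION):
        order = list(rng.permutation(len(CF_CONDITIONS)))
        for idx in order:
            cond = CF_CONDITIONS[idx]
            contrast = states[cond].select()
            correct = respond_cf(participant, cond, contrast, rng)
            states[cond].update(contrast, correct)
            target_interval, response_interval = _simulate_2ifc(correct, rng)
            rows.append(
                {
                    "experiment": "cf",
                    "participant": participant_id,
                    "trial": trial,
                    "block": window,
                    "condition": str(cond),
                    "level": contrast,
                    "target_interval": target_interval,
                    "response_interval": response_interval,
                    "correct": correct,
                    "gaze_deviation": np.nan,
                    "running_estimate": states[cond].estimate().threshold,
                }
            )
            trial += 1
    estimates = {cond: states[cond].estimate() for cond in CF_CONDITIONS}
    log = pd.DataFrame(rows)
    log.attrs["timing"] = SESSION_TIMING
    return log, estimates


def run_ci_session(
    participant: Participant,
    shapes=("lines", "square"),
    rng: np.random.Generator | int = 0,
    participant_id: str = "p0",
    record_gaze: bool = True,
) -> tuple[pd.DataFrame, dict[str, ThresholdResult]]:
    """Run constant-stimuli contour-detection sessions, one per shape.

    Each shape yields 280 trials: four blocks of 70, ten presentations of
    each of the seven jitter levels per block.  The per-shape jitter
    tolerance is the 75% point of the fitted logistic function.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    per_block = CI_TRIALS_PER_LEVEL // CI_BLOCKS
    rows = []
    results: dict[str, ThresholdResult] = {}
    for shape in shapes:
        trial = 0
        for block in range(CI_BLOCKS):
            levels = np.repeat(JITTER_LEVELS, per_block)
            rng.shuffle(levels)
            for level in levels:
                correct = respond_ci(participant, shape, float(level), rng)
                target_interval, response_interval = _simulate_2ifc(correct, rng)
                gaze = sample_gaze(participant, rng) if record_gaze else np.nan
                rows.append(
                    {
                        "experiment": "ci",
                        "participant": participant_id,
                        "trial": trial,
                        "block": block,
                        "condition": shape,
                        "level": float(level),
                        "target_interval": target_interval,
                        "response_interval": response_interval,
                        "correct": correct,
                        "gaze_deviation": gaze,
                        "running_estimate": np.nan,
                    }
                )
                trial += 1
        shape_trials = pd.DataFrame([r for r in rows if r["condition"] == shape])
        model = ConstantStimuliModel.from_trials(shape_trials)
        results[shape] = model.fit().threshold(0.75)
    log = pd.DataFrame(rows)
    log.attrs["timing"] = SESSION_TIMING
    return log, results


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    cf_trials: pd.DataFrame
    ci_trials: pd.DataFrame
    thresholds: pd.DataFrame  # participant, group, condition, threshold
    tolerances: pd.DataFrame  # participant, group, shape, tolerance
    participants: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        """Write the study as CSV tables plus a JSON manifest."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cf_trials.to_csv(out / "cf_trials.csv", index=False)
        self.ci_trials.to_csv(out / "ci_trials.csv", index=False)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        self.tolerances.to_csv(out / "tolerances.csv", index=False)
        self.participants.to_csv(out / "participants.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "StudyData":
        import json

        def read(path: Path) -> pd.DataFrame:
            try:
                return pd.read_csv(path)
            except pd.errors.EmptyDataError:
                return pd.DataFrame()

        out = Path(out_dir)
        return cls(
            cf_trials=read(out / "cf_trials.csv"),
            ci_trials=read(out / "ci_trials.csv"),
            thresholds=read(out / "thresholds.csv"),
            tolerances=read(out / "tolerances.csv"),
            participants=read(out / "participants.csv"),
            manifest=json.loads((out / "manifest.json").read_text()),
        )


def _shape_order(index: int, shapes: tuple) -> tuple:
    """Counterbalance shape order across participant indices.

    Two shapes alternate (even index: as given, odd: reversed); three
    shapes follow a Latin-square rotation.
    """
    k = len(shapes)
    if k <= 1:
        return tuple(shapes)
    if k == 2:
        return tuple(shapes) if index % 2 == 0 else tuple(reversed(shapes))
    rot = index % k
    return tuple(shapes[rot:] + shapes[:rot])


def run_group_study(
    profiles: dict[str, ObserverProfile],
    n_per_group: int = 13,
    seed: int = 0,
    shapes=("lines", "square"),
    psi_config: PsiConfig | None = None,
    run_cf: bool = True,
    run_ci: bool = True,
) -> StudyData:
    """Simulate a full two-group study.

    Parameters
    ----------
    profiles : dict
        Group label -> :class:`ObserverProfile`.
    n_per_group : int
        Participants per group (default 13).
    shapes : tuple
        Contour shapes per session; order is counterbalanced across
        participant indices.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    ss = np.random.SeedSequence(seed)
    cf_logs, ci_logs, thr_rows, tol_rows, part_rows = [], [], [], [], []
    for g_idx, (group, profile) in enumerate(sorted(profiles.items())):
        for i in range(n_per_group):
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(g_idx, i)
            )
            rng = np.random.default_rng(child)
            pid = f"{group}-{i:02d}"
            participant = sample_participant(profile, rng)
            part_rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "baseline_threshold": participant.baseline_threshold,
                    **{
                        f"facilitation_{o}": v
                        for o, v in sorted(participant.facilitation_db.items())
                    },
                    **{
                        f"tolerance_{s}": v
                        for s, v in sorted(participant.tolerance.items())
                    },
                }
            )
            if run_cf:
                log, estimates = run_cf_session(
                    participant, psi_config, rng, participant_id=pid
                )
                log["group"] = group
                cf_logs.append(log)
                for cond, est in estimates.items():
                    thr_rows.append(
                        {
                            "participant": pid,
                            "group": group,
                            "condition": str(cond),
                            "threshold": est.threshold,
                            "true_threshold": participant.cf_threshold(cond),
                        }
                    )
            if run_ci:
                order = _shape_order(i, tuple(shapes))
                log, results = run_ci_session(
                    participant, order, rng, participant_id=pid
                )
                log["group"] = group
                ci_logs.append(log)
                for shape, res in results.items():
                    tol_rows.append(
                        {
                            "participant": pid,
                            "group": group,
                            "shape": shape,
                            "tolerance": res.threshold,
                            "true_tolerance": participant.tolerance[shape],
                        }
                    )
    empty = pd.DataFrame()
    return StudyData(
        cf_trials=pd.concat(cf_logs, ignore_index=True) if cf_logs else empty,
        ci_trials=pd.concat(ci_logs, ignore_index=True) if ci_logs else empty,
        thresholds=pd.DataFrame(thr_rows),
        tolerances=pd.DataFrame(tol_rows),
        participants=pd.DataFrame(part_rows),
        manifest={
            "seed": seed,
            "n_per_group": n_per_group,
            "groups": sorted(profiles),
            "shapes": list(shapes),
            "timing": SESSION_TIMING,
        },
    )
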