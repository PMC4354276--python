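"""Parametric simulated 2IFC observers.

An :class:`ObserverProfile` describes a participant *group*: the mean and
between-subject SD of every psychometric parameter, for both tasks.
:func:`sample_participant` draws one participant's parameters from
truncated normal laws (tolerances for the contour shapes are drawn
jointly with an exchangeable between-shape correlation).  A participant
then answers trials via Bernoulli draws from their psychometric
functions:

* contrast detection: Weibull with a condition-specific threshold derived
  from the baseline threshold and the condition's facilitation in dB,
  ``alpha_cond = alpha_0 * 10**(-facilitation_db / 20)``;
* contour detection: decreasing logistic with midpoint equal to the
  participant's jitter tolerance for the shape.

Observers respond to the nominal stimulus level, not the rendered image;
the analyses are defined on nominal levels and an image-computable
observer is out of scope.  A half-normal per-trial gaze-deviation law,
scaled so that the profile's fixation rate of trials falls within the
1.5 deg criterion, supports the fixation filter.

Default NT-like and ASD-like profiles encoding the group means and SDs of
the emulated study ship as editable YAML fixtures under
``visint/data/profiles``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm, truncnorm

from .psychometric import LogisticPF, WeibullPF, logistic_p, weibull_p
from .stimuli.collinear import BASELINE, CF_OFFSETS

__all__ = [
    "ObserverProfile",
    "Participant",
    "load_profile",
    "sample_participant",
    "respond_cf",
    "respond_ci",
    "sample_gaze",
    "gaze_scale_for_rate",
]

#: Gaze criterion radius in degrees used by the fixation filter.
FIXATION_LIMIT_DEG = 1.5


@dataclass(frozen=True)
class ObserverProfile:
    """Group-level observer description (means and between-subject SDs)."""

    label: str
    baseline_threshold_mean: float
    baseline_threshold_sd: float
    facilitation_db_mean: dict  # offset (deg) -> dB
    facilitation_db_sd: dict
    tolerance_mean: dict  # shape -> deg
    tolerance_sd: dict
    weibull_slope: float = 3.0
    cf_lapse: float = 0.0
    logistic_spread: float = 8.0
    ci_lapse: float = 0.0
    tolerance_corr: float = 0.0
    fixation_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_threshold_mean <= 0:
            raise ValueError("baseline threshold mean must be > 0")
        if not 0.0 <= self.fixation_rate <= 1.0:
            raise ValueError("fixation_rate must lie in [0, 1]")
        if not -1.0 < self.tolerance_corr < 1.0:
            raise ValueError("tolerance_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class Participant:
    """One simulated participant: realized psychometric parameters."""

    label: str
    baseline_threshold: float
    facilitation_db: dict  # offset -> dB (baseline omitted; it is 0 by definition)
    tolerance: dict  # shape -> deg
    weibull_slope: float
    cf_lapse: float
    logistic_spread: float
    ci_lapse: float
    gaze_scale: float  # half-normal scale, deg; 0 = perfect fixation

    def cf_threshold(self, condition) -> float:
        """True contrast threshold for a flanker condition.

        The baseline condition has zero facilitation by definition;
        otherwise ``alpha = alpha_0 * 10**(-dB/20)``.
        """
        if condition == BASELINE:
            return self.baseline_threshold
        return self.baseline_threshold * 10.0 ** (
            -self.facilitation_db[int(condition)] / 20.0
        )

    def cf_pf(self, condition) -> WeibullPF:
        return WeibullPF(
            threshold=self.cf_threshold(condition),
            slope=self.weibull_slope,
            lapse=self.cf_lapse,
        )

    def ci_pf(self, shape: str) -> LogisticPF:
        return LogisticPF(
            midpoint=self.tolerance[shape],
            spread=self.logistic_spread,
            lapse=self.ci_lapse,
        )


def load_profile(source: str | Path) -> ObserverProfile:
    """Load a profile from a packaged name (``"nt"``, ``"asd"``,
    ``"nt_three_shape"``) or a YAML file path."""
    path = Path(source)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        text = path.read_text()
    else:
        text = (
            resources.files("visint.data.profiles")
            .joinpath(f"{source}.yaml")
            .read_text()
        )
    raw = yaml.safe_load(text)
    return ObserverProfile(
        label=raw["label"],
        baseline_threshold_mean=raw["baseline_threshold"]["mean"],
        baseline_threshold_sd=raw["baseline_threshold"]["sd"],
        facilitation_db_mean={
            int(k): v["mean"] for k, v in raw["facilitation_db"].items()
        },
        facilitation_db_sd={
            int(k): v["sd"] for k, v in raw["facilitation_db"].items()
        },
        tolerance_mean={k: v["mean"] for k, v in raw["tolerance"].items()},
        tolerance_sd={k: v["sd"] for k, v in raw["tolerance"].items()},
        weibull_slope=raw.get("weibull_slope", 3.0),
        cf_lapse=raw.get("cf_lapse", 0.0),
        logistic_spread=raw.get("logistic_spread", 8.0),
        ci_lapse=raw.get("ci_lapse", 0.0),
        tolerance_corr=raw.get("tolerance_corr", 0.0),
        fixation_rate=raw.get("fixation_rate", 1.0),
    )


def gaze_scale_for_rate(rate: float, limit: float = FIXATION_LIMIT_DEG) -> float:
    """Half-normal scale sigma such that P(deviation <= limit) = rate.

    The half-normal CDF is 2 Phi(x / sigma) - 1, so
    sigma = limit / Phi^-1((1 + rate) / 2).  rate -> 1 gives sigma -> 0
    (perfect fixation).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate >= 1.0:
        return 0.0
    if rate <= 0.0:
        return math.inf
    return limit / norm.ppf((1.0 + rate) / 2.0)


def _truncated_normal(mean, sd, lo, hi, rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_participant(
    profile: ObserverProfile, rng: np.random.Generator
) -> Participant:
    """Draw one participant's parameters from the group profile.

    Baseline thresholds are truncated to (0, 1]; per-shape tolerances are
    drawn from a joint normal with exchangeable correlation
    ``profile.tolerance_corr`` and truncated to (0, 90) by rejection;
    per-offset facilitation values are independent normals (no
    truncation: negative values mean suppression and are legitimate).
    Deterministic under a seeded generator.
    """
    alpha0 = _truncated_normal(
        profile.baseline_threshold_mean,
        profile.baseline_threshold_sd,
        1e-4,
        1.0,
        rng,
    )
    facilitation = {
        off: float(rng.normal(profile.facilitation_db_mean[off],
                              profile.facilitation_db_sd[off]))
        for off in profile.facilitation_db_mean
    }
    shapes = sorted(profile.tolerance_mean)
    means = np.array([profile.tolerance_mean[s] for s in shapes])
    sds = np.array([profile.tolerance_sd[s] for s in shapes])
    k = len(shapes)
    corr = np.full((k, k), profile.tolerance_corr)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    if np.all(sds == 0):
        draw = means.copy()
    else:
        for _ in range(1000):  # rejection keeps the joint law intact
            draw = rng.multivariate_normal(means, cov, method="eigh")
            if np.all((draw > 0) & (draw < 90)):
                break
        else:  # pragma: no cover - pathological profile
            draw = np.clip(draw, 1.0, 89.0)
    tolerance = {s: float(v) for s, v in zip(shapes, draw)}
    return Participant(
        label=profile.label,
        baseline_threshold=alpha0,
        facilitation_db=facilitation,
        tolerance=tolerance,
        weibull_slope=profile.weibull_slope,
        cf_lapse=profile.cf_lapse,
        logistic_spread=profile.logistic_spread,
        ci_lapse=profile.ci_lapse,
        gaze_scale=gaze_scale_for_rate(profile.fixation_rate),
    )


def respond_cf(
    participant: Participant,
    condition,
    target_contrast: float,
    rng: np.random.Generator,
) -> bool:
    """One 2IFC contrast-detection response: Bernoulli draw from the
    participant's Weibull function for that flanker condition."""
    p = weibull_p(participant.cf_pf(condition), target_contrast)
    return bool(rng.random() < p)


def respond_ci(
    participant: Participant,
    shape: str,
    jitter_level: float,
    rng: np.random.Generator,
) -> bool:
    """One 2IFC contour-detection response: Bernoulli draw from the
    participant's logistic function for that shape."""
    p = logistic_p(participant.ci_pf(shape), jitter_level)
    return bool(rng.random() < p)


def sample_gaze(
    participant: Participant, rng: np.random.Generator, size=None
):
    """Per-trial maximum gaze deviation (degrees), half-normal."""
    if participant.gaze_scale == 0.0:
        return 0.0 if size is None else np.zeros(size)
    draw = np.abs(rng.normal(0.0, participant.gaze_scale, size=size))
    return float(draw) if size is None else draw
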