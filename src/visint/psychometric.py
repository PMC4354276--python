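"""Psychometric functions and maximum-likelihood fitting.

Two parametric forms are used:

* a Weibull function of target contrast ``c`` for the contrast-detection
  task,

      P(correct | c) = gamma + (1 - gamma - delta) (1 - exp(-(c/alpha)**beta)),

  increasing in ``c``; with the 2IFC guess rate gamma = 0.5 and no lapses
  the probability at ``c = alpha`` is 0.5 + 0.5 (1 - 1/e) = 0.816, so the
  threshold parameter alpha marks the 81.6% correct level;

* a decreasing logistic function of orientation jitter ``j`` for the
  contour-detection task,

      P(correct | j) = gamma + (1 - gamma - delta) / (1 + exp((j - m)/s)),

  whose midpoint ``m`` is the 75% correct level when delta = 0.

:class:`ConstantStimuliModel` fits the logistic form to per-level binomial
counts by maximum likelihood (deterministic multi-start, bounded lapse)
and returns a results object carrying the estimates, the derived jitter
tolerance and a text summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import xlogy

__all__ = [
    "WeibullPF",
    "LogisticPF",
    "ThresholdResult",
    "weibull_p",
    "logistic_p",
    "threshold_at",
    "ConstantStimuliModel",
    "ConstantStimuliResults",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a psychometric fit is not identifiable."""


@dataclass(frozen=True)
class WeibullPF:
    """Weibull psychometric function (increasing, for contrast detection)."""

    threshold: float  # alpha, contrast at the 81.6% level when delta = 0
    slope: float = 3.0  # beta
    guess: float = 0.5  # gamma, fixed by 2IFC
    lapse: float = 0.0  # delta

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.slope <= 0:
            raise ValueError("threshold and slope must be > 0")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if not 0.0 <= self.guess < 1.0 - self.lapse:
            raise ValueError("guess must lie in [0, 1 - lapse)")

    def prob(self, contrast):
        return weibull_p(self, contrast)

    def threshold_at(self, criterion: float) -> float:
        return threshold_at(self, criterion)


@dataclass(frozen=True)
class LogisticPF:
    """Logistic psychometric function (decreasing, for jitter tolerance)."""

    midpoint: float  # m, degrees of jitter; the 75% point when delta = 0
    spread: float = 8.0  # s, degrees
    guess: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if not 0.0 <= self.lapse <= 0.06:
            raise ValueError("lapse must lie in [0, 0.06]")

    def prob(self, jitter):
        return logistic_p(self, jitter)

    def threshold_at(self, criterion: float) -> float:
        return threshold_at(self, criterion)


def weibull_p(pf: WeibullPF, contrast):
    """P(correct) under a Weibull psychometric function; contrast >= 0."""
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast must be >= 0")
    p = pf.guess + (1.0 - pf.guess - pf.lapse) * (
        1.0 - np.exp(-((c / pf.threshold) ** pf.slope))
    )
    return p if p.ndim else float(p)


def logistic_p(pf: LogisticPF, jitter):
    """P(correct) under the decreasing logistic psychometric function."""
    j = np.asarray(jitter, dtype=float)
    p = pf.guess + (1.0 - pf.guess - pf.lapse) / (
        1.0 + np.exp((j - pf.midpoint) / pf.spread)
    )
    return p if p.ndim else float(p)


def threshold_at(pf: WeibullPF | LogisticPF, criterion: float) -> float:
    """Stimulus level at which P(correct) equals ``criterion`` (closed form).

    Raises ``ValueError`` when the criterion is outside the achievable
    open interval (guess, 1 - lapse).
    """
    lo, hi = pf.guess, 1.0 - pf.lapse
    if not lo < criterion < hi:
        raise ValueError(
            f"criterion {criterion} outside the achievable range ({lo}, {hi})"
        )
    q = (criterion - pf.guess) / (1.0 - pf.guess - pf.lapse)
    if isinstance(pf, WeibullPF):
        return pf.threshold * (-math.log1p(-q)) ** (1.0 / pf.slope)
    return pf.midpoint + pf.spread * math.log(1.0 / q - 1.0)


@dataclass
class ThresholdResult:
    """A fitted threshold: the stimulus level at the criterion probability."""

    threshold: float
    criterion: float
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Constant-stimuli maximum-likelihood model


class ConstantStimuliModel:
    """Binomial MLE of the decreasing logistic psychometric function.

    Built from per-level counts of a method-of-constant-stimuli session
    (canonically 7 jitter levels x 40 trials).  The guess rate is fixed at
    0.5 (2IFC); midpoint, spread and a lapse bounded in [0, ``lapse_max``]
    are free.  ``fit`` maximizes the binomial log-likelihood from a fixed
    list of starting points, so fits are reproducible without seeds.

    Parameters
    ----------
    levels : array-like
        Stimulus levels (nominal jitter-range maxima, degrees).
    n_correct, n_trials : array-like
        Correct-response and total counts per level.
    """

    def __init__(
        self,
        levels,
        n_correct,
        n_trials,
        guess: float = 0.5,
        lapse_max: float = 0.06,
    ):
        self.levels = np.asarray(levels, dtype=float)
        self.n_correct = np.asarray(n_correct, dtype=float)
        self.n_trials = np.asarray(n_trials, dtype=float)
        if not (len(self.levels) == len(self.n_correct) == len(self.n_trials)):
            raise ValueError("levels, n_correct and n_trials must align")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_trials):
            raise ValueError("need 0 <= n_correct <= n_trials at every level")
        self.guess = guess
        self.lapse_max = lapse_max

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        level_col: str = "level",
        correct_col: str = "n_correct",
        total_col: str = "n_total",
        **kwargs,
    ) -> "ConstantStimuliModel":
        """Build from a count table with one row per stimulus level."""
        return cls(df[level_col], df[correct_col], df[total_col], **kwargs)

    @classmethod
    def from_trials(
        cls, trials: pd.DataFrame, level_col: str = "level",
        correct_col: str = "correct", **kwargs,
    ) -> "ConstantStimuliModel":
        """Aggregate a trial-by-trial log into per-level counts."""
        g = trials.groupby(level_col)[correct_col]
        counts = g.agg(["sum", "count"])
        return cls(counts.index, counts["sum"], counts["count"], **kwargs)

    # log-likelihood ------------------------------------------------------

    def loglike(self, params) -> float:
        """Binomial log-likelihood at params = (midpoint, spread, lapse)."""
        m, s, d = params
        if s <= 0 or not 0.0 <= d <= self.lapse_max:
            return -np.inf
        z = np.clip((self.levels - m) / s, -500.0, 500.0)
        p = self.guess + (1.0 - self.guess - d) / (1.0 + np.exp(z))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(
            np.sum(
                xlogy(self.n_correct, p)
                + xlogy(self.n_trials - self.n_correct, 1.0 - p)
            )
        )

    def _check_identifiable(self) -> None:
        phat = np.divide(
            self.n_correct,
            self.n_trials,
            out=np.full_like(self.n_correct, np.nan),
            where=self.n_trials > 0,
        )
        ok = self.n_trials > 0
        if np.all(phat[ok] <= self.guess):
            raise FitError(
                "non-identifiable: performance at or below chance at every level"
            )
        if np.all(phat[ok] >= 1.0):
            raise FitError("non-identifiable: all responses correct at every level")

    def fit(self) -> "ConstantStimuliResults":
        self._check_identifiable()
        lo, hi = float(self.levels.min()), float(self.levels.max())
        span = max(hi - lo, 1.0)
        bounds = [
            (lo - span, hi + span),
            (0.25, 4.0 * span),
            (0.0, self.lapse_max),
        ]
        # deterministic multi-start: midpoints across the tested range,
        # two spreads, lapse 0
        starts = [
            (m0, s0, 0.0)
            for m0 in np.linspace(lo + 0.1 * span, hi - 0.1 * span, 5)
            for s0 in (span / 10.0, span / 3.0)
        ]
        best = None
        for x0 in starts:
            res = minimize(
                lambda x: -self.loglike(x),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        m, s, d = best.x
        pf = LogisticPF(midpoint=float(m), spread=float(s),
                        guess=self.guess, lapse=float(d))
        return ConstantStimuliResults(
            model=self,
            pf=pf,
            llf=-float(best.fun),
            converged=bool(best.success),
            n_starts=len(starts),
        )


class ConstantStimuliResults:
    """Fit results: parameters, log-likelihood and derived thresholds."""

    def __init__(self, model, pf: LogisticPF, llf: float, converged: bool,
                 n_starts: int):
        self.model = model
        self.pf = pf
        self.llf = llf
        self.converged = converged
        self.n_starts = n_starts

    @property
    def params(self) -> dict:
        return {
            "midpoint": self.pf.midpoint,
            "spread": self.pf.spread,
            "guess": self.pf.guess,
            "lapse": self.pf.lapse,
        }

    def predict(self, levels=None):
        if levels is None:
            levels = self.model.levels
        return logistic_p(self.pf, levels)

    def threshold(self, criterion: float = 0.75) -> ThresholdResult:
        """Stimulus level at the criterion probability (default 75%)."""
        return ThresholdResult(
            threshold=threshold_at(self.pf, criterion),
            criterion=criterion,
            params=self.params,
            diagnostics={"llf": self.llf, "converged": self.converged},
        )

    def summary(self) -> str:
        lines = [
            "Constant-stimuli logistic fit (binomial MLE)",
            "-" * 46,
            f"levels:     {np.array2string(self.model.levels, precision=0)}",
            f"n trials:   {int(self.model.n_trials.sum())}",
            f"midpoint m: {self.pf.midpoint:8.3f} deg",
            f"spread s:   {self.pf.spread:8.3f} deg",
            f"lapse:      {self.pf.lapse:8.4f}",
            f"log-lik:    {self.llf:8.3f}",
            f"converged:  {self.converged}",
            f"75% jitter tolerance: {self.threshold(0.75).threshold:.2f} deg",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observed proportions and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.levels, m.n_correct / m.n_trials, "ko", label="observed")
        xs = np.linspace(m.levels.min(), m.levels.max(), 200)
        ax.plot(xs, self.predict(xs), "b-", label="fit")
        ax.axhline(0.75, color="gray", ls=":")
        ax.set_xlabel("orientation jitter (deg)")
        ax.set_ylabel("proportion correct")
        ax.set_ylim(0.4, 1.02)
        ax.legend()
        return ax
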