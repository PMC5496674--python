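"""Two-class broken-stick trajectory and its Gaussian observation likelihood.

The population contains two latent sub-groups.  Individuals in the *no-change*
class follow a single linear trend ``alpha + beta * t`` throughout follow-up.
Individuals in the *change* class follow the same trend up to a common
change-point ``c`` and thereafter decline with slope ``beta + delta``; the two
segments join continuously at ``c``, which forces the post-change intercept to
``alpha - delta * c``.  Observation error is i.i.d. Gaussian with precision
``tau`` (variance ``1 / tau``).

Everything in this module is pure computation; simulation and inference build
on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ShapeParams",
    "IndividualRecord",
    "mean_value",
    "log_likelihood",
]


@dataclass(frozen=True)
class ShapeParams:
    """Underlying trajectory parameters shared by all individuals.

    Parameters
    ----------
    alpha : float
        Intercept of the trajectory at ``t = 0``, in outcome units.
    beta : float
        Pre-change slope, outcome units per time unit.
    delta : float
        Change-magnitude: the increment added to the slope after the
        change-point.  Strictly negative — the direction of change
        (accelerated decline) is taken as known a priori.
    change_point : float
        Time ``c`` at which the change-class slope shifts; common to all
        individuals in the change class.
    tau : float
        Observation-error precision, ``tau = 1 / sigma**2``; must be positive.
    """

    alpha: float
    beta: float
    delta: float
    change_point: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.delta < 0:
            raise ValueError(f"delta must be strictly negative, got {self.delta}")
        if self.change_point < 0:
            raise ValueError(
                f"change_point must be non-negative, got {self.change_point}"
            )

    @property
    def sigma2(self) -> float:
        """Observation-error variance ``1 / tau``."""
        return 1.0 / self.tau

    @property
    def sigma(self) -> float:
        """Observation-error standard deviation ``1 / sqrt(tau)``."""
        return 1.0 / np.sqrt(self.tau)

    @property
    def alpha_change(self) -> float:
        """Derived intercept of the post-change segment, ``alpha - delta * c``.

        Chosen so the two branch means agree exactly at the change-point.
        """
        return self.alpha - self.delta * self.change_point


@dataclass
class IndividualRecord:
    """One individual's observations plus the simulation truth.

    ``label`` and ``dropped_out`` are generator-side truth; inference never
    reads them.
    """

    times: np.ndarray
    outcomes: np.ndarray
    label: int = 0
    dropped_out: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.times.ndim != 1 or self.outcomes.ndim != 1:
            raise ValueError("times and outcomes must be 1-D")
        if self.times.size != self.outcomes.size:
            raise ValueError("times and outcomes must have equal length")
        if self.times.size < 1:
            raise ValueError("an individual needs at least one observation")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


def mean_value(shape: ShapeParams, label: int, t):
    """Noise-free trajectory value at time(s) ``t`` for the given class label.

    For ``label == 0`` (no change), or for ``label == 1`` at ``t <= c``, the
    mean is ``alpha + beta * t``.  For ``label == 1`` past the change-point it
    is ``(alpha - delta * c) + (beta + delta) * t``, equivalently
    ``alpha + beta * t + delta * max(t - c, 0)``.

    Accepts scalar or array ``t``; returns the same shape.
    """
    t = np.asarray(t, dtype=float)
    base = shape.alpha + shape.beta * t
    if label:
        base = base + shape.delta * np.maximum(t - shape.change_point, 0.0)
    if base.ndim == 0:
        return float(base)
    return base


def _residuals(
    data: Iterable[IndividualRecord], shape: ShapeParams, labels: Sequence[int]
) -> np.ndarray:
    records = list(data)
    labels = np.asarray(labels)
    if labels.size != len(records):
        raise ValueError(
            f"labels ({labels.size}) must align with individuals ({len(records)})"
        )
    parts = [
        rec.outcomes - mean_value(shape, int(lab), rec.times)
        for rec, lab in zip(records, labels)
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def log_likelihood(
    data: Iterable[IndividualRecord], shape: ShapeParams, labels: Sequence[int]
) -> float:
    """Gaussian log-likelihood of all observations given the latent labels.

    Sums, over every observation of every individual, the normal log-density
    with mean :func:`mean_value` at that individual's label and precision
    ``shape.tau``.  All error terms are independent between and within
    individuals.

    ``data`` may be any iterable of :class:`IndividualRecord` (including a
    :class:`~cpdesign.simulate.LongitudinalDataset`).
    """
    if not shape.tau > 0:
        raise ValueError(f"tau must be positive, got {shape.tau}")
    resid = _residuals(data, shape, labels)
    return float(np.sum(stats.norm.logpdf(resid, scale=shape.sigma)))
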