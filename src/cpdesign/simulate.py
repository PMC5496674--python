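"""Synthetic longitudinal data under monotone MCAR drop-out.

A :class:`Scenario` fixes one cell of the simulation design: the underlying
two-class trajectory, the fixed observation schedule, the change-class
probability ``p_r``, and the drop-out probability ``p_d``.  Each individual
independently draws a latent class label and a drop-out indicator; dropped-out
individuals are observed only up to the single drop-out time ``t_d`` and never
return (monotone missingness).  Drop-out is independent of the label and of
the outcomes, i.e. missing completely at random.

True labels and drop-out flags are stored alongside the data for scoring
classification error, but are written to a separate "truth" table so that
fitting can be kept blind to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .model import IndividualRecord, ShapeParams, mean_value

__all__ = [
    "DEFAULT_TIMES",
    "DEFAULT_DROPOUT_TIME",
    "DEFAULT_SHAPE",
    "Scenario",
    "LongitudinalDataset",
    "simulate_dataset",
    "subset_first_k",
    "expected_post_cp_n",
    "write_dataset",
    "read_dataset",
]

#: Default observation schedule: five waves two time units apart.
DEFAULT_TIMES: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)

#: Default single drop-out time (the wave after which attrition can occur).
DEFAULT_DROPOUT_TIME: float = 4.0


def _default_shape() -> ShapeParams:
    # Cognitive-decline inspired defaults on an MMSE-like 0-30 scale:
    # intercept 25, decline one point/year, accelerated decline three
    # points/year past a change-point at year five.
    return ShapeParams(alpha=25.0, beta=-1.0, delta=-2.0, change_point=5.0, tau=0.2)


DEFAULT_SHAPE = _default_shape()


@dataclass(frozen=True)
class Scenario:
    """One simulation design cell.

    Parameters
    ----------
    n : int
        Number of individuals at the first wave.
    shape : ShapeParams
        Underlying two-class trajectory plus error precision.
    p_r : float
        Probability of change-class membership, in [0, 1].
    p_d : float
        Drop-out probability at ``t_d``, in [0, 1].
    times : sequence of float
        Fixed observation schedule shared by all individuals; first wave at 0.
    t_d : float
        The single drop-out time; must be one of ``times``.  Individuals who
        drop out have no observations after ``t_d``.
    seed : int
        Seed for the scenario's RNG stream.
    """

    n: int
    shape: ShapeParams = field(default_factory=_default_shape)
    p_r: float = 0.5
    p_d: float = 0.1
    times: Sequence[float] = DEFAULT_TIMES
    t_d: float = DEFAULT_DROPOUT_TIME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be at least 1, got {self.n}")
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must lie in [0, 1], got {self.p_r}")
        if not 0.0 <= self.p_d <= 1.0:
            raise ValueError(f"p_d must lie in [0, 1], got {self.p_d}")
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a non-empty 1-D schedule")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.any(np.isclose(times, self.t_d)):
            raise ValueError(f"t_d={self.t_d} must be one of the scheduled times")
        object.__setattr__(self, "times", tuple(float(t) for t in times))

    @property
    def schedule(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def retained_schedule(self) -> np.ndarray:
        """Observation times seen by an individual who drops out."""
        sched = self.schedule
        return sched[sched <= self.t_d + 1e-12]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "alpha": self.shape.alpha,
            "beta": self.shape.beta,
            "delta": self.shape.delta,
            "change_point": self.shape.change_point,
            "tau": self.shape.tau,
            "p_r": self.p_r,
            "p_d": self.p_d,
            "times": list(self.times),
            "t_d": self.t_d,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        shape = ShapeParams(
            alpha=d["alpha"],
            beta=d["beta"],
            delta=d["delta"],
            change_point=d["change_point"],
            tau=d["tau"],
        )
        return cls(
            n=int(d["n"]),
            shape=shape,
            p_r=float(d["p_r"]),
            p_d=float(d["p_d"]),
            times=tuple(d["times"]),
            t_d=float(d["t_d"]),
            seed=int(d["seed"]),
        )


@dataclass
class LongitudinalDataset:
    """Per-individual observation times and outcomes, in flattened form.

    Observations of individual ``i`` occupy the slice
    ``indptr[i]:indptr[i + 1]`` of ``times`` and ``outcomes``.  ``true_labels``
    and ``dropped_out`` are generator-side truth used only for scoring.
    """

    times: np.ndarray
    outcomes: np.ndarray
    indptr: np.ndarray
    true_labels: np.ndarray
    dropped_out: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int8)
        self.dropped_out = np.asarray(self.dropped_out, dtype=bool)
        if self.times.size != self.outcomes.size:
            raise ValueError("times and outcomes must have equal length")
        if self.indptr[0] != 0 or self.indptr[-1] != self.times.size:
            raise ValueError("indptr must span the flattened observations")
        n = self.indptr.size - 1
        if self.true_labels.size != n or self.dropped_out.size != n:
            raise ValueError("truth columns must align with individuals")

    @property
    def n(self) -> int:
        """Number of individuals."""
        return int(self.indptr.size - 1)

    def __len__(self) -> int:
        return self.n

    @property
    def n_obs(self) -> int:
        """Total number of observations."""
        return int(self.times.size)

    def individual(self, i: int) -> IndividualRecord:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return IndividualRecord(
            times=self.times[lo:hi],
            outcomes=self.outcomes[lo:hi],
            label=int(self.true_labels[i]),
            dropped_out=bool(self.dropped_out[i]),
        )

    def __iter__(self) -> Iterator[IndividualRecord]:
        return (self.individual(i) for i in range(self.n))

    @property
    def obs_individual(self) -> np.ndarray:
        """Individual index of each flattened observation."""
        return np.repeat(np.arange(self.n), np.diff(self.indptr))

    def to_frame(self) -> pd.DataFrame:
        """Long-format observations: individual_id, time, outcome."""
        return pd.DataFrame(
            {
                "individual_id": self.obs_individual,
                "time": self.times,
                "outcome": self.outcomes,
            }
        )

    def truth_frame(self) -> pd.DataFrame:
        """Companion truth table: individual_id, true_label, dropped_out."""
        return pd.DataFrame(
            {
                "individual_id": np.arange(self.n),
                "true_label": self.true_labels.astype(int),
                "dropped_out": self.dropped_out.astype(int),
            }
        )

    @classmethod
    def from_records(cls, records: Sequence[IndividualRecord]) -> "LongitudinalDataset":
        if not records:
            raise ValueError("need at least one individual")
        lengths = [rec.n_obs for rec in records]
        indptr = np.concatenate([[0], np.cumsum(lengths)])
        return cls(
            times=np.concatenate([rec.times for rec in records]),
            outcomes=np.concatenate([rec.outcomes for rec in records]),
            indptr=indptr,
            true_labels=np.array([rec.label for rec in records]),
            dropped_out=np.array([rec.dropped_out for rec in records]),
        )

    @classmethod
    def from_frames(
        cls, data: pd.DataFrame, truth: Optional[pd.DataFrame] = None
    ) -> "LongitudinalDataset":
        data = data.sort_values(["individual_id", "time"], kind="stable")
        ids = data["individual_id"].to_numpy()
        uniq, counts = np.unique(ids, return_counts=True)
        order = np.argsort(uniq)
        uniq, counts = uniq[order], counts[order]
        # re-sort rows so individuals appear in id order
        data = data.set_index("individual_id").loc[uniq].reset_index()
        indptr = np.concatenate([[0], np.cumsum(counts)])
        n = uniq.size
        labels = np.zeros(n, dtype=np.int8)
        dropped = np.zeros(n, dtype=bool)
        if truth is not None:
            truth = truth.set_index("individual_id").loc[uniq]
            labels = truth["true_label"].to_numpy().astype(np.int8)
            dropped = truth["dropped_out"].to_numpy().astype(bool)
        return cls(
            times=data["time"].to_numpy(dtype=float),
            outcomes=data["outcome"].to_numpy(dtype=float),
            indptr=indptr,
            true_labels=labels,
            dropped_out=dropped,
        )


def simulate_dataset(
    scenario: Scenario, rng: Optional[np.random.Generator] = None
) -> LongitudinalDataset:
    """Generate one dataset under the scenario's two-class drop-out model.

    For each individual independently: the latent label is Bernoulli(``p_r``),
    the drop-out indicator is Bernoulli(``p_d``) (independent of label and
    outcomes — MCAR), retained individuals are observed at every scheduled
    time while dropped-out individuals are observed only at times up to
    ``t_d``, and outcomes are the class trajectory mean plus independent
    Gaussian noise with precision ``tau``.

    The draw order (all labels, then all drop-out flags, then noise) is fixed,
    so a given ``(scenario, rng)`` pair is bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    shape = scenario.shape
    labels = (rng.random(n) < scenario.p_r).astype(np.int8)
    dropped = rng.random(n) < scenario.p_d

    full = scenario.schedule
    short = scenario.retained_schedule
    records = []
    for i in range(n):
        t = short if dropped[i] else full
        mu = mean_value(shape, int(labels[i]), t)
        y = mu + rng.normal(0.0, shape.sigma, size=t.size)
        records.append(
            IndividualRecord(times=t, outcomes=y, label=int(labels[i]),
                             dropped_out=bool(dropped[i]))
        )
    return LongitudinalDataset.from_records(records)


def subset_first_k(data: LongitudinalDataset, k: int) -> LongitudinalDataset:
    """Restrict to the first ``k`` individuals in generation order.

    Nested subsets of one simulated dataset are how sample size is varied
    within a replicate, preserving the within-replicate correlation across
    sample sizes.
    """
    if not 1 <= k <= data.n:
        raise ValueError(f"k must lie in [1, {data.n}], got {k}")
    stop = int(data.indptr[k])
    return LongitudinalDataset(
        times=data.times[:stop].copy(),
        outcomes=data.outcomes[:stop].copy(),
        indptr=data.indptr[: k + 1].copy(),
        true_labels=data.true_labels[:k].copy(),
        dropped_out=data.dropped_out[:k].copy(),
    )


def expected_post_cp_n(n: int, p_d: float) -> float:
    """Expected post-change-point sample size, ``n * (1 - p_d)``.

    The expected number of individuals still observed at the final wave —
    the univariate design metric combining first-wave sample size and
    attrition.
    """
    if not 0.0 <= p_d <= 1.0:
        raise ValueError(f"p_d must lie in [0, 1], got {p_d}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return n * (1.0 - p_d)


# ---------------------------------------------------------------------------
# File round-trip: data CSV + truth CSV + scenario JSON sidecar.
# ---------------------------------------------------------------------------

def write_dataset(
    data: LongitudinalDataset,
    prefix,
    scenario: Optional[Scenario] = None,
) -> dict:
    """Write ``<prefix>_data.csv``, ``<prefix>_truth.csv`` and, if a scenario
    is given, ``<prefix>_scenario.json``.  Returns the paths written.

    Truth columns live in their own file so a fitting run can read the data
    file alone and stay blind to the labels.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": prefix.with_name(prefix.name + "_data.csv"),
        "truth": prefix.with_name(prefix.name + "_truth.csv"),
    }
    data.to_frame().to_csv(paths["data"], index=False)
    data.truth_frame().to_csv(paths["truth"], index=False)
    if scenario is not None:
        paths["scenario"] = prefix.with_name(prefix.name + "_scenario.json")
        paths["scenario"].write_text(json.dumps(scenario.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_dataset(prefix, with_truth: bool = True) -> LongitudinalDataset:
    """Read a dataset written by :func:`write_dataset`.

    With ``with_truth=False`` the truth file is ignored and the truth columns
    are zero-filled — the blinded view used for fitting.
    """
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_name(prefix.name + "_data.csv"))
    truth = None
    if with_truth:
        truth_path = prefix.with_name(prefix.name + "_truth.csv")
        if truth_path.exists():
            truth = pd.read_csv(truth_path)
    return LongitudinalDataset.from_frames(data, truth)
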