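"""Posterior and classification summaries for design evaluation.

Per replicate: posterior medians and variances, the 95% highest-posterior-
density (HPD) interval length, the posterior probability of a meaningful
change-magnitude ``P(delta < h)``, and the AUROC of the per-individual
posterior change probabilities against the true labels.  Per scenario: the
mean absolute error of the posterior medians across replicates (the MAE),
the mean posterior variance, the mean HPD length (the average length
criterion, ALC), mean detection probabilities, and mean AUROCs — both over
all individuals and over the subset with observations past the change-point,
where classification is actually well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LongitudinalDataset, Scenario, expected_post_cp_n

__all__ = [
    "DEFAULT_DETECTION_THRESHOLDS",
    "ScenarioSummary",
    "mae_over_reps",
    "hpd_interval",
    "alc",
    "prob_below",
    "roc_curve",
    "auroc",
    "post_cp_indices",
    "replicate_stats",
    "aggregate_replicates",
    "summarize_scenario",
    "lowess_curve",
]

#: Detection thresholds ``h`` for P(delta < h): just below zero (existence of
#: a change-point), at the default true change-magnitude, and below it.
DEFAULT_DETECTION_THRESHOLDS: tuple = (-0.05, -2.0, -3.0)


def mae_over_reps(estimates: Sequence[float], truth: float) -> float:
    """Mean absolute deviation of per-replicate posterior medians from truth."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.mean(np.abs(estimates - truth)))


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> Tuple[float, float]:
    """Empirical shortest interval containing ``ceil(level * N)`` samples.

    The estimator sorts the draws and scans every contiguous window of the
    required size, returning the narrowest (ties broken by the smallest lower
    bound).  Reported as a single interval even when the posterior is
    multimodal, in which case its length overstates the concentrated mass.
    """
    samples = np.sort(np.asarray(samples, dtype=float))
    if samples.size < 20:
        raise ValueError(f"need at least 20 samples, got {samples.size}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    m = int(np.ceil(level * samples.size))
    if m >= samples.size:
        return float(samples[0]), float(samples[-1])
    widths = samples[m - 1 :] - samples[: samples.size - m + 1]
    j = int(np.argmin(widths))  # first minimum -> smallest lower bound
    return float(samples[j]), float(samples[j + m - 1])


def alc(samples: Sequence[float], level: float = 0.95) -> float:
    """Length of the ``level`` HPD interval of one chain's draws."""
    lo, hi = hpd_interval(samples, level)
    return hi - lo


def prob_below(samples: Sequence[float], h: float) -> float:
    """Fraction of retained draws strictly below the threshold ``h``."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean(samples < h))


def _check_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; AUROC is undefined")


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray]:
    """ROC curve from a threshold sweep over all distinct scores.

    Returns ``(fpr, tpr)`` arrays starting at (0, 0) and ending at (1, 1),
    with one point per distinct score (tied scores enter together).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    _check_both_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    # group tied scores
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([boundary + 1, [s.size]])
    tp = np.concatenate([[0], np.cumsum(lab)[ends - 1]])
    fp = np.concatenate([[0], np.cumsum(1 - lab)[ends - 1]])
    return fp / fp[-1], tp / tp[-1]


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Ties contribute half credit, which makes the statistic equal to the
    trapezoidal area under the swept ROC curve.  Raises on degenerate labels
    (a single class); summary aggregation records such replicates as missing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_both_classes(labels)
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def post_cp_indices(data: LongitudinalDataset, change_point: float) -> np.ndarray:
    """Indices of individuals with at least one observation past ``c``.

    Classification into change / no change is only well defined for these
    individuals; under MCAR drop-out before the change-point the rest carry
    no label information.
    """
    has_post = (data.times > change_point).astype(np.int64)
    counts = np.add.reduceat(has_post, data.indptr[:-1])
    counts[np.diff(data.indptr) == 0] = 0
    return np.flatnonzero(counts > 0)


def replicate_stats(
    chain,
    data: LongitudinalDataset,
    change_point: float,
    truth: Optional[dict] = None,
    h_values: Sequence[float] = DEFAULT_DETECTION_THRESHOLDS,
    level: float = 0.95,
) -> dict:
    """Per-replicate summary of one fitted chain against its dataset truth.

    Returns a flat dict with, per parameter: the posterior median, variance
    and HPD length; detection probabilities ``P(delta < h)`` for each ``h``;
    and AUROCs over all individuals, the post-change-point subset, and the
    dropped-out-before-``c`` subset (NaN where only one class is present).
    """
    out = {"n_fitted": chain.n_fitted}
    for p in ("alpha", "beta", "delta", "tau"):
        draws = chain.draws(p)
        out[f"median_{p}"] = float(np.median(draws))
        out[f"var_{p}"] = float(np.var(draws, ddof=1))
        out[f"alc_{p}"] = alc(draws, level)
    for h in h_values:
        out[f"detect_h{h:g}"] = prob_below(chain.draws_delta, h)

    scores = np.asarray(chain.label_prob, dtype=float)
    labels = np.asarray(data.true_labels).astype(int)
    post_idx = post_cp_indices(data, change_point)
    pre_mask = np.ones(data.n, dtype=bool)
    pre_mask[post_idx] = False
    out["n_post_cp"] = int(post_idx.size)
    for name, idx in (
        ("auroc_all", np.arange(data.n)),
        ("auroc_post_cp", post_idx),
        ("auroc_dropped", np.flatnonzero(pre_mask)),
    ):
        try:
            out[name] = auroc(scores[idx], labels[idx])
        except ValueError:
            out[name] = np.nan
    if truth:
        for p, val in truth.items():
            out[f"true_{p}"] = float(val)
    return out


@dataclass
class ScenarioSummary:
    """Aggregates of one scenario cell across replicates."""

    scenario_id: str
    tau: float
    p_d: float
    k: int
    expected_post_cp_n: float
    n_reps: int
    mae: dict = field(default_factory=dict)
    mean_variance: dict = field(default_factory=dict)
    mean_alc: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    auroc_all: float = np.nan
    auroc_post_cp: float = np.nan
    auroc_dropped: float = np.nan
    n_reps_auroc_all: int = 0
    n_reps_auroc_post_cp: int = 0
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "scenario_id": self.scenario_id,
            "tau": self.tau,
            "p_d": self.p_d,
            "k": self.k,
            "expected_post_cp_n": self.expected_post_cp_n,
            "n_reps": self.n_reps,
            "auroc_all": self.auroc_all,
            "auroc_post_cp": self.auroc_post_cp,
            "auroc_dropped": self.auroc_dropped,
            "n_reps_auroc_all": self.n_reps_auroc_all,
            "n_reps_auroc_post_cp": self.n_reps_auroc_post_cp,
        }
        for p in ("alpha", "beta", "delta", "tau"):
            row[f"mae_{p}"] = self.mae.get(p, np.nan)
            row[f"mean_var_{p}"] = self.mean_variance.get(p, np.nan)
            row[f"mean_alc_{p}"] = self.mean_alc.get(p, np.nan)
        for key, val in self.detection.items():
            row[key] = val
        row.update(self.extras)
        return row


def aggregate_replicates(
    stats_list: Sequence[dict],
    scenario: Scenario,
    k: int,
    scenario_id: str = "",
    h_values: Sequence[float] = DEFAULT_DETECTION_THRESHOLDS,
) -> ScenarioSummary:
    """Aggregate per-replicate stats dicts into a :class:`ScenarioSummary`.

    The MAE compares each replicate's posterior median to the scenario's true
    value (which varies across scenarios only for ``tau``); degenerate-label
    replicates enter the AUROC means as missing, reducing the effective
    replicate count for that cell.  Error-precision summaries are also
    reported relative to (scaled by) the true precision.
    """
    if not stats_list:
        raise ValueError("need at least one replicate")
    df = pd.DataFrame(stats_list)
    truth = {
        "alpha": scenario.shape.alpha,
        "beta": scenario.shape.beta,
        "delta": scenario.shape.delta,
        "tau": scenario.shape.tau,
    }
    summary = ScenarioSummary(
        scenario_id=scenario_id,
        tau=scenario.shape.tau,
        p_d=scenario.p_d,
        k=k,
        expected_post_cp_n=expected_post_cp_n(k, scenario.p_d),
        n_reps=len(df),
    )
    for p, true_val in truth.items():
        summary.mae[p] = mae_over_reps(df[f"median_{p}"], true_val)
        summary.mean_variance[p] = float(df[f"var_{p}"].mean())
        summary.mean_alc[p] = float(df[f"alc_{p}"].mean())
    # relative (scaled) precision summaries
    summary.extras["rel_mae_tau"] = summary.mae["tau"] / truth["tau"]
    summary.extras["rel_mean_var_tau"] = summary.mean_variance["tau"] / truth["tau"]
    summary.extras["rel_mean_alc_tau"] = summary.mean_alc["tau"] / truth["tau"]
    for h in h_values:
        key = f"detect_h{h:g}"
        if key in df:
            summary.detection[key] = float(df[key].mean())
    for name in ("auroc_all", "auroc_post_cp", "auroc_dropped"):
        col = df[name]
        setattr(summary, name, float(col.mean(skipna=True)))
        if name in ("auroc_all", "auroc_post_cp"):
            setattr(summary, f"n_reps_{name}", int(col.notna().sum()))
    return summary


def summarize_scenario(
    replicates: Iterable[tuple],
    scenario: Scenario,
    k: int,
    change_point: Optional[float] = None,
    scenario_id: str = "",
    h_values: Sequence[float] = DEFAULT_DETECTION_THRESHOLDS,
) -> ScenarioSummary:
    """Summarise per-replicate ``(chain, dataset)`` pairs for one cell.

    Thin wrapper that computes :func:`replicate_stats` for every pair and
    aggregates them; ``change_point`` defaults to the scenario's own.
    """
    c = scenario.shape.change_point if change_point is None else change_point
    stats_list = [
        replicate_stats(chain, data, c, h_values=h_values)
        for chain, data in replicates
    ]
    return aggregate_replicates(
        stats_list, scenario, k, scenario_id=scenario_id, h_values=h_values
    )


def lowess_curve(
    x: Sequence[float], y: Sequence[float], frac: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Locally weighted scatterplot smoother for trend curves over scenarios.

    Convenience wrapper around statsmodels' LOWESS with a configurable span;
    returns the smoothed ``(x, y)`` sorted by ``x``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(np.asarray(y, float), np.asarray(x, float), frac=frac)
    return fitted[:, 0], fitted[:, 1]
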