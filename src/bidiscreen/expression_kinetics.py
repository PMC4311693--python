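"""Time-course analytics for stimulation and transcription-shutoff series.

Covers the three kinetic questions of the study design: when a gene's
induction first becomes significant (replicate Student t-test plus a fold
floor), which member of a gene pair responds first, and how fast a
transcript decays once transcription is blocked (log-linear first-order
fit, half-life = ln2 / k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TimeCourse",
    "OnsetCall",
    "DecayFit",
    "two_sample_ttest",
    "detect_onset",
    "compare_onsets",
    "ratio_profile",
    "fit_decay",
]

_P_FLOOR = 5e-324  # smallest positive double; p-values stay in (0, 1]


@dataclass(frozen=True)
class TimeCourse:
    """Replicate measurements of one gene over a strictly increasing time grid.

    ``values[i]`` holds the replicate abundances at ``times[i]``.
    """

    gene: str
    times: tuple[float, ...]
    values: tuple[tuple[float, ...], ...]
    unit: str = "h"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(v < 0 for reps in self.values for v in reps):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "values", tuple(tuple(float(v) for v in reps) for reps in self.values)
        )

    def at(self, time: float) -> tuple[float, ...]:
        try:
            return self.values[self.times.index(time)]
        except ValueError as exc:
            raise KeyError(f"time {time} not in grid") from exc

    def means(self) -> np.ndarray:
        return np.array([float(np.mean(v)) for v in self.values])


@dataclass(frozen=True)
class OnsetCall:
    gene: str
    onset_time: Optional[float]
    pvalues: dict
    folds: dict


@dataclass(frozen=True)
class DecayFit:
    gene: str
    rate: float  # first-order decay constant, per unit time
    half_life: float  # ln2 / rate; inf when no measurable decay
    r_squared: float
    no_measurable_decay: bool = False


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> float:
    """Two-sided Student t-test p-value between two replicate groups.

    Equal-variance (classical Student) by default; ``welch=True`` drops the
    equal-variance assumption.  Degenerate zero-variance input with equal
    means yields p = 1 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else _P_FLOOR
    _, p = stats.ttest_ind(a, b, equal_var=not welch)
    return max(float(p), _P_FLOOR)


def detect_onset(
    tc: TimeCourse,
    baseline_time: float = 0.0,
    alpha: float = 0.05,
    min_fold: float = 1.5,
    *,
    welch: bool = False,
) -> OnsetCall:
    """Earliest time point whose rise over baseline is both statistically
    significant (t-test p < alpha) and at least ``min_fold``.

    Requiring the fold floor in addition to significance keeps
    significant-but-trivial shifts from being called an onset.
    """
    baseline = tc.at(baseline_time)
    if len(baseline) < 2:
        raise ValueError("baseline needs >= 2 replicates")
    pvalues: dict[float, float] = {}
    folds: dict[float, float] = {}
    onset = None
    base_mean = float(np.mean(baseline))
    for t, reps in zip(tc.times, tc.values):
        if t <= baseline_time:
            continue
        if len(reps) < 2:
            raise ValueError(f"time {t}: need >= 2 replicates for testing")
        p = two_sample_ttest(baseline, reps, welch=welch)
        fold = float(np.mean(reps)) / base_mean if base_mean > 0 else math.inf
        pvalues[t] = p
        folds[t] = fold
        if onset is None and p < alpha and fold >= min_fold:
            onset = t
    return OnsetCall(gene=tc.gene, onset_time=onset, pvalues=pvalues, folds=folds)


def compare_onsets(
    a: TimeCourse,
    b: TimeCourse,
    baseline_time: float = 0.0,
    alpha: float = 0.05,
    min_fold: float = 1.5,
) -> str:
    """Order the induction onsets of two series sharing a time grid.

    Returns one of ``a_first``, ``b_first``, ``tie``, ``undetermined``
    (the last when either series never reaches a significant rise).
    """
    if a.times != b.times:
        raise ValueError("time grids must match")
    oa = detect_onset(a, baseline_time, alpha, min_fold).onset_time
    ob = detect_onset(b, baseline_time, alpha, min_fold).onset_time
    if oa is None or ob is None:
        return "undetermined"
    if oa < ob:
        return "a_first"
    if ob < oa:
        return "b_first"
    return "tie"


def ratio_profile(
    a: TimeCourse, b: TimeCourse, *, delta_ct: bool = False
) -> list[float]:
    """Per-time ratio of replicate means a/b; NaN flags a zero denominator.

    With ``delta_ct=True`` the log2 of the ratio is returned instead (the
    qPCR delta-Ct convention: one cycle = factor 2).
    """
    if a.times != b.times:
        raise ValueError("time grids must match")
    out = []
    for ra, rb in zip(a.means(), b.means()):
        if rb <= 0:
            out.append(float("nan"))
        else:
            r = float(ra / rb)
            out.append(math.log2(r) if delta_ct else r)
    return out


def fit_decay(tc: TimeCourse) -> DecayFit:
    """First-order decay fit to a transcription-shutoff series.

    Ordinary least squares of ln(replicate-mean abundance) against time;
    rate is the negated slope and half-life ln2/rate.  A non-positive rate
    is flagged as no measurable decay (half-life inf) rather than an error.
    """
    if len(tc.times) < 3:
        raise ValueError("need >= 3 time points for a decay fit")
    means = tc.means()
    if (means <= 0).any():
        raise ValueError(
            "non-positive abundances; add a pseudocount before fitting decay"
        )
    t = np.asarray(tc.times)
    y = np.log(means)
    res = stats.linregress(t, y)
    rate = -float(res.slope)
    r2 = float(res.rvalue**2)
    if rate <= 0:
        return DecayFit(
            gene=tc.gene,
            rate=rate,
            half_life=math.inf,
            r_squared=r2,
            no_measurable_decay=True,
        )
    return DecayFit(gene=tc.gene, rate=rate, half_life=math.log(2) / rate, r_squared=r2)
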