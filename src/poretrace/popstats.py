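"""Population-level inference on per-event kinetic descriptors.

Implements the fitted quantities reported for the single-particle assay:
censored-exponential docking-lag fits, Gaussian flow-rate fits with t-based
confidence intervals, two-sample Kolmogorov-Smirnov comparison of flow-rate
populations split at a vesicle-diameter cutoff (mechanosensitivity), the
insertion probability as a function of vesicle size with Wilson binomial
intervals, and Welch t-tests on per-replicate scenario fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExponentialLagFit",
    "GaussianRateFit",
    "KSResult",
    "MechanoSplit",
    "GroupComparison",
    "fit_exponential_lag",
    "fit_gaussian_rates",
    "ks_two_sample",
    "mechanosensitivity_split",
    "insertion_probability_by_size",
    "compare_groups",
]


@dataclass(frozen=True)
class ExponentialLagFit:
    mean: float  # s
    ci_low: float
    ci_high: float
    n_events: int
    n_censored: int


@dataclass(frozen=True)
class GaussianRateFit:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class MechanoSplit:
    cutoff: float
    small: Optional[GaussianRateFit]
    large: Optional[GaussianRateFit]
    ks: Optional[KSResult]
    sufficient: bool


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    pvalue: float


def fit_exponential_lag(tau1_samples: Sequence[float],
                        censored_times: Sequence[float] = (),
                        conf: float = 0.95) -> ExponentialLagFit:
    """Censored-exponential MLE of the docking-lag mean.

    mean = (sum of all observed times, censored included) / #uncensored;
    the CI is a normal approximation on the log-mean (Fisher information of
    an exponential with d uncensored events gives SD(log mean) = 1/sqrt(d)).
    """
    obs = np.asarray(tau1_samples, dtype=float)
    cens = np.asarray(censored_times, dtype=float)
    if obs.size == 0:
        raise ValueError("need at least one uncensored docking event")
    if np.any(obs < 0) or (cens.size and np.any(cens < 0)):
        raise ValueError("times must be non-negative")
    total = obs.sum() + (cens.sum() if cens.size else 0.0)
    mean = total / obs.size
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z / math.sqrt(obs.size)
    return ExponentialLagFit(mean=float(mean),
                             ci_low=float(mean * math.exp(-half)),
                             ci_high=float(mean * math.exp(half)),
                             n_events=int(obs.size),
                             n_censored=int(cens.size))


def fit_gaussian_rates(kf_samples: Sequence[float],
                       conf: float = 0.95) -> GaussianRateFit:
    """Gaussian fit of a flow-rate sample: moments plus a t-interval for the
    mean (equivalent to the MLE on unbinned samples)."""
    x = np.asarray(kf_samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(0.5 + conf / 2.0, x.size - 1) * sd / math.sqrt(x.size)
    return GaussianRateFit(mean=mean, sd=sd, ci_low=mean - half,
                           ci_high=mean + half, n=int(x.size))


def ks_two_sample(sample_a: Sequence[float],
                  sample_b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |ECDF_a - ECDF_b|; the p-value uses the
    asymptotic Kolmogorov distribution at sqrt(n_e) * D with effective size
    n_e = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    n_e = a.size * b.size / (a.size + b.size)
    p = float(np.clip(special.kolmogorov(math.sqrt(n_e) * d), 0.0, 1.0))
    return KSResult(statistic=d, pvalue=p, n_a=int(a.size), n_b=int(b.size))


def mechanosensitivity_split(events: pd.DataFrame, cutoff_nm: float = 70.0,
                             kf_column: str = "kf",
                             size_column: str = "d_m_est_nm",
                             min_per_side: int = 2) -> MechanoSplit:
    """Split accepted flow rates at a diameter cutoff and compare the sides.

    Partitions rows by ``size_column`` above/below ``cutoff_nm``, fits a
    Gaussian to each side's ``kf_column`` and runs the KS comparison.  When
    either side has fewer than ``min_per_side`` events the result is flagged
    insufficient and no test is run.
    """
    df = events.dropna(subset=[kf_column, size_column])
    small = df.loc[df[size_column] <= cutoff_nm, kf_column].to_numpy()
    large = df.loc[df[size_column] > cutoff_nm, kf_column].to_numpy()
    if small.size < min_per_side or large.size < min_per_side:
        return MechanoSplit(cutoff=cutoff_nm,
                            small=(fit_gaussian_rates(small)
                                   if small.size >= 2 else None),
                            large=(fit_gaussian_rates(large)
                                   if large.size >= 2 else None),
                            ks=None, sufficient=False)
    return MechanoSplit(cutoff=cutoff_nm,
                        small=fit_gaussian_rates(small),
                        large=fit_gaussian_rates(large),
                        ks=ks_two_sample(small, large), sufficient=True)


def insertion_probability_by_size(events: pd.DataFrame,
                                  bin_edges: Sequence[float],
                                  size_column: str = "d_m_est_nm",
                                  conf: float = 0.95) -> pd.DataFrame:
    """P(insert | dock) per diameter bin with Wilson binomial intervals.

    Docked rows are those with an outcome other than ``undocked``; perforated
    rows have outcome ``docked_perforated``.  Bins with zero docked events
    are flagged (``p`` is NaN).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    docked = events[events["outcome"] != "undocked"]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = docked[(docked[size_column] >= lo)
                        & (docked[size_column] < hi)]
        n_dock = len(in_bin)
        n_perf = int((in_bin["outcome"] == "docked_perforated").sum())
        if n_dock == 0:
            rows.append({"bin_low_nm": lo, "bin_high_nm": hi, "n_docked": 0,
                         "n_perforated": 0, "p": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "empty": True})
            continue
        lo_ci, hi_ci = _wilson_interval(n_perf, n_dock, conf)
        rows.append({"bin_low_nm": lo, "bin_high_nm": hi, "n_docked": n_dock,
                     "n_perforated": n_perf, "p": n_perf / n_dock,
                     "ci_low": lo_ci, "ci_high": hi_ci, "empty": False})
    return pd.DataFrame(rows)


def _wilson_interval(successes: int, n: int, conf: float) -> Tuple[float, float]:
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = successes / n
    denom = 1.0 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def compare_groups(fractions_a: Sequence[float],
                   fractions_b: Sequence[float]) -> GroupComparison:
    """Welch two-sample t-test on per-replicate fractions, with SEM bars."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(t_stat):  # zero variance in both groups
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    return GroupComparison(
        mean_a=float(a.mean()), sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        mean_b=float(b.mean()), sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        t_statistic=float(t_stat), pvalue=float(p))
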