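"""Statistical analyses around the dominance-time models.

Contains the two-sample likelihood-ratio test for equality of Inverse
Gaussian parameters, the parametric-bootstrap precision study (median
relative/absolute estimation errors), the cumulative-history permutation
analysis for serial dependence, and rank-based group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hmm import DominanceSeries

__all__ = [
    "LRTResult",
    "PrecisionReport",
    "HistoryResult",
    "GroupCompareResult",
    "lrt_ig_equal",
    "bootstrap_precision",
    "cumulative_history_corr",
    "group_compare",
]

CHI2_95_DF2 = float(stats.chi2.ppf(0.95, 2))  # 5.991


@dataclass
class LRTResult:
    """Likelihood-ratio test of H0: two IG samples share (mu, sigma)."""

    Qn: float
    Qn_star: float
    S1: float
    S2: float
    S3: float
    S: float
    p_value: float
    reject: bool


def lrt_ig_equal(d1, d2, level: float = 0.05) -> LRTResult:
    """Two-sample test for equal Inverse Gaussian parameters.

    With mu_i the sample means, S_i = sum_j (1/d_ij - 1/mu_i) and
    S3 = n1/mu1 + n2/mu2 - n^2 (n1 mu1 + n2 mu2)^-1, the likelihood ratio
    is Q_n = prod_i (n/n_i)^{n_i/2} (S_i/S)^{n_i/2} with S = S1 + S2 + S3.
    The Bartlett-corrected statistic

        Q*_n = -2 (1 - (1/6)(1/n1 + 1/n2) - 1/(12 n)) log Q_n

    is approximately chi-square with two degrees of freedom under H0; the
    test rejects at level 5% when Q*_n exceeds its 95% quantile.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size < 2 or d2.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("dominance times must be positive")
    n1, n2 = d1.size, d2.size
    n = n1 + n2
    mu1, mu2 = float(d1.mean()), float(d2.mean())
    S1 = float(np.sum(1.0 / d1) - n1 / mu1)
    S2 = float(np.sum(1.0 / d2) - n2 / mu2)
    if S1 <= 0 or S2 <= 0:
        raise ValueError("degenerate sample (no reciprocal spread)")
    S3 = n1 / mu1 + n2 / mu2 - n**2 / (n1 * mu1 + n2 * mu2)
    S = S1 + S2 + S3
    logQn = 0.0
    for ni, Si in ((n1, S1), (n2, S2)):
        logQn += (ni / 2.0) * (math.log(n / ni) + math.log(Si / S))
    Qn = math.exp(logQn)
    Qn_star = -2.0 * (1.0 - (1.0 / 6.0) * (1.0 / n1 + 1.0 / n2) - 1.0 / (12.0 * n)) * logQn
    p = float(stats.chi2.sf(Qn_star, 2))
    return LRTResult(
        Qn=Qn,
        Qn_star=Qn_star,
        S1=S1,
        S2=S2,
        S3=S3,
        S=S,
        p_value=p,
        reject=Qn_star > stats.chi2.ppf(1.0 - level, 2),
    )


@dataclass
class PrecisionReport:
    """Median estimation errors from a parametric bootstrap.

    ``median_errors`` maps parameter name to the median RE (for means,
    standard deviations and borders) or AE (for probabilities and drifts)
    over the replicates that were fitted successfully; the study passes
    when the mean of the medians is below 0.25.
    """

    median_errors: dict
    passes: bool
    mean_error: float
    n_sim: int
    T: float
    seed: int | None
    n_failures: int = 0
    error_kind: dict = field(default_factory=dict)  # "RE" or "AE" per key


def bootstrap_precision(
    simulate,
    fit,
    true_params: dict,
    T: float,
    n_sim: int,
    seed=None,
    ae_keys: tuple = (),
    threshold: float = 0.25,
) -> PrecisionReport:
    """Parametric bootstrap of estimation precision.

    ``simulate(T, rng)`` must return a :class:`DominanceSeries` generated
    under ``true_params``; ``fit(series)`` must return a dict of estimates
    with the same keys as ``true_params`` (or raise, counting as a fit
    failure, which is reported and excluded from the medians).  Keys in
    ``ae_keys`` are scored with the absolute error |est - true|; all other
    keys use the relative error |est - true| / |true|.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    errors: dict = {k: [] for k in true_params}
    n_fail = 0
    for _ in range(n_sim):
        series = simulate(T, rng)
        try:
            est = fit(series)
        except Exception:
            n_fail += 1
            continue
        for k, true in true_params.items():
            e = abs(est[k] - true)
            if k not in ae_keys:
                e /= abs(true)
            errors[k].append(e)
    medians = {
        k: (float(np.median(v)) if v else math.nan) for k, v in errors.items()
    }
    mean_err = float(np.mean(list(medians.values())))
    return PrecisionReport(
        median_errors=medians,
        passes=bool(mean_err < threshold),
        mean_error=mean_err,
        n_sim=n_sim,
        T=T,
        seed=seed if isinstance(seed, int) else None,
        n_failures=n_fail,
        error_kind={k: ("AE" if k in ae_keys else "RE") for k in true_params},
    )


@dataclass
class HistoryResult:
    c_H: float
    p_perm: float | None
    n_perm: int
    tau: float


def _history_values(durations: np.ndarray, percepts, tau: float) -> np.ndarray:
    """Cumulative-history trace evaluated at each dominance-time onset.

    For each percept a leaky integrator h_p with time constant tau tracks
    past dominance of that percept (h_p relaxes toward 1 while p dominates
    and toward 0 otherwise); H_i is the trace of the *current* percept at
    the onset of dominance time i.
    """
    labels = sorted(set(percepts))
    h = {p: 0.0 for p in labels}
    H = np.empty(durations.size)
    for i, (d, p) in enumerate(zip(durations, percepts)):
        H[i] = h[p]
        decay = math.exp(-d / tau)
        for q in labels:
            target = 1.0 if q == p else 0.0
            h[q] = target + (h[q] - target) * decay
    return H


def cumulative_history_corr(
    series: DominanceSeries,
    tau: float | None = None,
    n_perm: int = 1000,
    seed=None,
) -> HistoryResult:
    """Pearson correlation c_H between dominance times and the cumulative
    perceptual history, with a permutation null.

    The history is an exponentially weighted trace (time constant ``tau``,
    defaulting to the subject's mean dominance time) of how much the
    currently dominant percept dominated recently.  Significance is
    assessed one-sidedly against ``n_perm`` permutations of the dominance
    times (the observed statistic is included in the null set); with
    ``n_perm = 0`` only c_H is returned.  Series with fewer than five
    dominance times are excluded from the analysis and raise ValueError.
    """
    d = series.durations
    if d.size < 5:
        raise ValueError("history analysis requires at least 5 dominance times")
    if series.percepts is None:
        raise ValueError("history analysis requires percept labels")
    if tau is None:
        tau = float(d.mean())
    H = _history_values(d, series.percepts, tau)
    c_obs = float(np.corrcoef(d, H)[0, 1])
    if n_perm == 0:
        return HistoryResult(c_H=c_obs, p_perm=None, n_perm=0, tau=tau)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count = 0
    for _ in range(n_perm):
        dp = rng.permutation(d)
        Hp = _history_values(dp, series.percepts, tau)
        if float(np.corrcoef(dp, Hp)[0, 1]) >= c_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return HistoryResult(c_H=c_obs, p_perm=float(p), n_perm=n_perm, tau=tau)


@dataclass
class GroupCompareResult:
    p_value: float
    medians: dict
    quartiles: dict  # group -> (25%, 75%)
    n: dict


def group_compare(values, labels) -> GroupCompareResult:
    """Two-sided Wilcoxon rank-sum comparison of a per-subject metric
    between two groups, with group medians and 25%/75% quantiles."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    split = {g: values[labels == g] for g in groups}
    for g, v in split.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    stat = stats.mannwhitneyu(split[groups[0]], split[groups[1]], alternative="two-sided")
    return GroupCompareResult(
        p_value=float(stat.pvalue),
        medians={g: float(np.median(v)) for g, v in split.items()},
        quartiles={
            g: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
            for g, v in split.items()
        },
        n={g: int(v.size) for g, v in split.items()},
    )
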