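"""One- and two-state Hidden Markov Models with Inverse-Gaussian emissions.

Continuous viewing of an ambiguous stimulus produces a unimodal sequence of
dominance times, modeled as i.i.d. IG(mu, sigma): the one-state model.
Intermittent viewing interleaves long "stable" and short "unstable" phases;
the two-state model places a hidden Markov chain on {S, U} with IG emissions
per state and transition probabilities ``p_SS``, ``p_UU``.

Estimation follows the classical scaled forward-backward/Baum-Welch scheme,
with the state-specific IG updates

    mu_j    <- sum_i gamma_j(i) d_i / sum_i gamma_j(i)
    sigma_j <- sqrt( mu_j^3 * sum_i gamma_j(i) (1/d_i - 1/mu_j)
                               / sum_i gamma_j(i) )

and the start distribution pinned to the stationary distribution of the
current transition matrix at every iteration (it is not a free parameter).
Model selection for a single response pattern runs Baum-Welch from a grid of
starting values and applies plausibility constraints that keep short
dominance times from contaminating the stable-state estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import (
    BarrierDriftParams,
    DegenerateSampleError,
    IGParams,
    ig_logpdf,
    ig_mle,
    ig_sample,
    ig_to_barrier,
)

__all__ = [
    "DominanceSeries",
    "TwoStateHMMParams",
    "ForwardBackwardResult",
    "StatePath",
    "OneStateFit",
    "StateCollapseError",
    "fit_one_state",
    "forward_backward",
    "baum_welch",
    "fit_two_state",
    "viterbi",
    "phi_S",
    "stationary_pi_S",
    "simulate_hmm",
]

STABLE, UNSTABLE = 0, 1  # state indices used throughout
STATE_LABELS = ("S", "U")


class StateCollapseError(RuntimeError):
    """One hidden state lost all posterior mass during EM."""


class UnderflowError(RuntimeError):
    """Both emission densities underflowed at some observation."""

    def __init__(self, index: int):
        super().__init__(f"emission densities underflow at observation {index}")
        self.index = index


@dataclass
class DominanceSeries:
    """A single subject/condition sequence of dominance times.

    ``durations`` are the times (s) between successive reported percept
    changes; ``percepts`` optionally carries the strictly alternating
    percept labels.  ``l_p``/``l_b`` are the presentation/blank lengths of
    an intermittent protocol (``l_b = 0`` encodes continuous viewing) and
    ``T`` the run length.  A final interval cut off by the end of the run
    may be stored in ``truncated_tail``; fitters ignore it.
    """

    durations: np.ndarray
    condition: str = "continuous"
    percepts: list | None = None
    l_p: float = 0.0
    l_b: float = 0.0
    T: float | None = None
    subject_id: str = ""
    run_id: str = ""
    truncated_tail: float | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.ndim != 1:
            raise ValueError("durations must be one-dimensional")
        if np.any(self.durations <= 0):
            raise ValueError("all dominance times must be positive")
        if self.percepts is not None:
            if len(self.percepts) != len(self.durations):
                raise ValueError("percepts must match durations in length")
            for a, b in zip(self.percepts, self.percepts[1:]):
                if a == b:
                    raise ValueError("percept labels must strictly alternate")

    @property
    def n(self) -> int:
        return int(self.durations.size)


@dataclass(frozen=True)
class TwoStateHMMParams:
    """Parameter set theta = (mu_S, sigma_S, mu_U, sigma_U, p_SS, p_UU, pi_S)."""

    mu_S: float
    sigma_S: float
    mu_U: float
    sigma_U: float
    p_SS: float
    p_UU: float
    pi_S: float | None = None  # None -> stationary distribution

    def __post_init__(self) -> None:
        for name in ("p_SS", "p_UU"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pi_S is not None and not 0.0 <= self.pi_S <= 1.0:
            raise ValueError(f"pi_S must lie in [0, 1], got {self.pi_S}")

    @property
    def stable(self) -> IGParams:
        return IGParams(self.mu_S, self.sigma_S)

    @property
    def unstable(self) -> IGParams:
        return IGParams(self.mu_U, self.sigma_U)

    def start_distribution(self) -> np.ndarray:
        pi = stationary_pi_S(self.p_SS, self.p_UU) if self.pi_S is None else self.pi_S
        return np.array([pi, 1.0 - pi])

    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [[self.p_SS, 1.0 - self.p_SS], [1.0 - self.p_UU, self.p_UU]]
        )

    def relabeled(self) -> "TwoStateHMMParams":
        """Swap labels if needed so that mu_S >= mu_U."""
        if self.mu_S >= self.mu_U:
            return self
        return TwoStateHMMParams(
            mu_S=self.mu_U,
            sigma_S=self.sigma_U,
            mu_U=self.mu_S,
            sigma_U=self.sigma_S,
            p_SS=self.p_UU,
            p_UU=self.p_SS,
            pi_S=None if self.pi_S is None else 1.0 - self.pi_S,
        )


@dataclass
class ForwardBackwardResult:
    alpha_tilde: np.ndarray  # (n, 2) scaled forward variables
    beta_tilde: np.ndarray  # (n, 2) scaled backward variables
    c: np.ndarray  # (n,) scaling constants
    gamma: np.ndarray  # (n, 2) state posteriors
    xi: np.ndarray  # (n-1, 2, 2) pairwise posteriors
    loglik: float


@dataclass
class StatePath:
    states: np.ndarray  # int array, 0 = S, 1 = U

    @property
    def labels(self) -> list:
        return [STATE_LABELS[s] for s in self.states]


@dataclass
class OneStateFit:
    """IG MLE of a single-state series plus its drift-diffusion equivalent."""

    ig: IGParams
    barrier: BarrierDriftParams
    state: str = "S"  # which regime the single state represents
    loglik: float = float("nan")


def stationary_pi_S(p_SS: float, p_UU: float) -> float:
    """Stationary probability of the stable state,

    pi_S = (p_UU - 1) / (p_SS + p_UU - 2),

    with the convention pi_S = 1 for an absorbing stable state and 0 for an
    absorbing unstable state; 0.5 when both are absorbing.
    """
    denom = p_SS + p_UU - 2.0
    if denom == 0.0:  # p_SS = p_UU = 1
        if p_SS == 1.0 and p_UU == 1.0:
            return 0.5
    if p_SS == 1.0:
        return 1.0
    if p_UU == 1.0:
        return 0.0
    return (p_UU - 1.0) / denom


def fit_one_state(series: DominanceSeries) -> OneStateFit:
    """IG maximum likelihood for a continuous run, with the (b, nu0) form."""
    ig = ig_mle(series.durations)
    from .distributions import ig_loglik

    return OneStateFit(
        ig=ig, barrier=ig_to_barrier(ig), loglik=ig_loglik(series.durations, ig)
    )


def _emission_densities(d: np.ndarray, params: TwoStateHMMParams) -> np.ndarray:
    """(n, 2) matrix of IG emission densities, computed via logs."""
    logf = np.column_stack(
        [ig_logpdf(d, params.stable), ig_logpdf(d, params.unstable)]
    )
    return np.exp(logf)


def forward_backward(
    series: DominanceSeries, params: TwoStateHMMParams
) -> ForwardBackwardResult:
    """Scaled forward-backward recursions.

    The forward pass uses alpha*_j(1) = pi_j f_j(d_1),
    c_i = alpha*_S(i) + alpha*_U(i), alpha~_j(i) = alpha*_j(i)/c_i and
    alpha*_j(i) = f_j(d_i) sum_k alpha~_k(i-1) p_kj; the backward pass
    beta~_j(n) = 1/c_n and
    beta~_j(i) = sum_k p_jk f_k(d_{i+1}) beta~_k(i+1) / c_i.
    The log-likelihood is sum_i log c_i.
    """
    d = series.durations
    n = d.size
    f = _emission_densities(d, params)
    P = params.transition_matrix()
    pi = params.start_distribution()

    alpha = np.empty((n, 2))
    c = np.empty(n)

    a_star = pi * f[0]
    c[0] = a_star.sum()
    if c[0] <= 0.0 or not np.isfinite(c[0]):
        raise UnderflowError(0)
    alpha[0] = a_star / c[0]
    for i in range(1, n):
        a_star = f[i] * (alpha[i - 1] @ P)
        c[i] = a_star.sum()
        if c[i] <= 0.0 or not np.isfinite(c[i]):
            raise UnderflowError(i)
        alpha[i] = a_star / c[i]

    beta = np.empty((n, 2))
    with np.errstate(over="raise"):
        try:
            beta[n - 1] = 1.0 / c[n - 1]
            for i in range(n - 2, -1, -1):
                beta[i] = (P @ (f[i + 1] * beta[i + 1])) / c[i]
        except FloatingPointError as exc:  # tiny scaling constants
            raise UnderflowError(i) from exc

    ab = alpha * beta
    ab_sum = ab.sum(axis=1, keepdims=True)
    if np.any(ab_sum <= 0.0) or not np.all(np.isfinite(ab_sum)):
        raise UnderflowError(int(np.argmin(ab_sum)))
    gamma = ab / ab_sum

    xi = np.empty((max(n - 1, 0), 2, 2))
    for i in range(n - 1):
        m = alpha[i][:, None] * P * (f[i + 1] * beta[i + 1])[None, :]
        xi[i] = m / m.sum()

    return ForwardBackwardResult(
        alpha_tilde=alpha,
        beta_tilde=beta,
        c=c,
        gamma=gamma,
        xi=xi,
        loglik=float(np.sum(np.log(c))),
    )


def baum_welch(
    series: DominanceSeries,
    init: TwoStateHMMParams,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[TwoStateHMMParams, list]:
    """EM iteration for the two-state model.

    Returns the final parameters (states relabeled so mu_S >= mu_U) and the
    log-likelihood trace.  Raises :class:`StateCollapseError` if one state's
    posterior mass vanishes or its IG update degenerates; callers fall back
    to the one-state model in that case.
    """
    d = series.durations
    if d.size < 2:
        raise ValueError("need at least two dominance times")
    params = init
    prev_params = init
    trace: list = []
    prev = -np.inf
    for _ in range(max_iter):
        fb = forward_backward(series, params)
        if fb.loglik < prev:
            # the stationary-pi replacement is not the EM-optimal start
            # update, so a sub-tolerance decrease can occur at convergence;
            # revert to the last parameters that improved the likelihood
            params = prev_params
            break
        trace.append(fb.loglik)
        if fb.loglik - prev < tol:
            break
        prev = fb.loglik
        prev_params = params

        gsum = fb.gamma.sum(axis=0)
        if np.any(gsum < 1e-10):
            raise StateCollapseError("posterior state mass vanished")
        # transition updates use gamma over i = 1..n-1 in the denominator
        gsum_t = fb.gamma[:-1].sum(axis=0)
        if np.any(gsum_t < 1e-10):
            raise StateCollapseError("posterior state mass vanished")
        xsum = fb.xi.sum(axis=0)
        p_SS = float(xsum[STABLE, STABLE] / gsum_t[STABLE])
        p_UU = float(xsum[UNSTABLE, UNSTABLE] / gsum_t[UNSTABLE])
        p_SS = min(max(p_SS, 0.0), 1.0)
        p_UU = min(max(p_UU, 0.0), 1.0)

        mus = (fb.gamma * d[:, None]).sum(axis=0) / gsum
        new = {}
        for j, key in ((STABLE, "S"), (UNSTABLE, "U")):
            mu_j = float(mus[j])
            spread = float((fb.gamma[:, j] * (1.0 / d - 1.0 / mu_j)).sum() / gsum[j])
            if spread <= 0 or not math.isfinite(spread):
                raise StateCollapseError(f"degenerate sigma update in state {key}")
            new[f"mu_{key}"] = mu_j
            new[f"sigma_{key}"] = math.sqrt(mu_j**3 * spread)

        params = TwoStateHMMParams(
            mu_S=new["mu_S"],
            sigma_S=new["sigma_S"],
            mu_U=new["mu_U"],
            sigma_U=new["sigma_U"],
            p_SS=p_SS,
            p_UU=p_UU,
            pi_S=None,  # stationary start distribution each iteration
        )
    return params.relabeled(), trace


def _mu_above(d: np.ndarray, thresh: float) -> float | None:
    """Mean of dominance times exceeding ``thresh`` (None if none do)."""
    sel = d[d > thresh]
    return float(sel.mean()) if sel.size else None


def _passes_constraints(params: TwoStateHMMParams, d: np.ndarray) -> bool:
    """Plausibility constraints on an accepted two-state fit.

    sigma_S must exceed 1 s (a single long outlier cannot form the stable
    state on its own); mu_S may not fall below 0.98 * mean of the d_i > 15 s
    (short dominance times must not drag down the stable mean); and mu_S
    must stay below 1.02 * mean of the d_i > 75 s (75 if none exceed 75 s).
    """
    if not params.sigma_S > 1.0:
        return False
    mu15 = _mu_above(d, 15.0)
    if mu15 is not None and params.mu_S < 0.98 * mu15:
        return False
    mu75 = _mu_above(d, 75.0)
    if mu75 is None:
        mu75 = 75.0
    if not params.mu_S < 1.02 * mu75:
        return False
    return True


def _one_state_fallback(series: DominanceSeries, state: str) -> OneStateFit:
    fit = fit_one_state(series)
    return replace(fit, state=state)


def fit_two_state(
    series: DominanceSeries,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Fit the two-state model over the standard starting-value grid.

    Baum-Welch runs from 100 starting points: ten equidistant stable means
    mu_S in [60, 0.95 max_i d_i] crossed with ten equidistant stable
    standard deviations sigma_S in [10, 1.1 mu_S], with fixed
    p_SS = p_UU = 0.5, mu_U = 4 s, sigma_U = 5 s.  The best-log-likelihood
    fit satisfying the constraints is returned.

    Runs whose dominance times are all longer than 30 s are reduced to the
    stable regime only (one-state IG fit, p_SS := 1); runs with all
    dominance times at most 30 s reduce to the unstable regime
    (p_UU := 1).  Returns either ``(TwoStateHMMParams, loglik)`` or an
    :class:`OneStateFit`.
    """
    d = series.durations
    if np.all(d > 30.0):
        return _one_state_fallback(series, "S")
    if np.all(d <= 30.0):
        return _one_state_fallback(series, "U")

    best = None
    best_ll = -np.inf
    mu_grid = np.linspace(60.0, 0.95 * float(d.max()), 10)
    for mu_s in mu_grid:
        if mu_s <= 0:
            continue
        for sig_s in np.linspace(10.0, 1.1 * mu_s, 10):
            try:
                init = TwoStateHMMParams(
                    mu_S=mu_s,
                    sigma_S=sig_s,
                    mu_U=4.0,
                    sigma_U=5.0,
                    p_SS=0.5,
                    p_UU=0.5,
                    pi_S=None,
                )
                fitted, trace = baum_welch(series, init, tol=tol, max_iter=max_iter)
            except (StateCollapseError, UnderflowError, ValueError):
                continue
            if not _passes_constraints(fitted, d):
                continue
            if trace and trace[-1] > best_ll:
                best, best_ll = fitted, trace[-1]
    if best is None:
        # no accepted grid point: fall back to whichever single regime
        # dominates the data
        state = "S" if float(np.median(d)) > 30.0 else "U"
        return _one_state_fallback(series, state)
    return best, best_ll


def viterbi(series: DominanceSeries, params: TwoStateHMMParams) -> StatePath:
    """Most probable hidden-state path; ties are broken toward S."""
    d = series.durations
    n = d.size
    logf = np.column_stack(
        [ig_logpdf(d, params.stable), ig_logpdf(d, params.unstable)]
    )
    with np.errstate(divide="ignore"):
        logP = np.log(params.transition_matrix())
        logpi = np.log(params.start_distribution())
    delta = logpi + logf[0]
    back = np.zeros((n, 2), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + logP  # cand[k, j]: from k to j
        # argmax with ties toward S (index 0): argmax takes the first max
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], [0, 1]] + logf[i]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return StatePath(states=states)


def phi_S(params: TwoStateHMMParams) -> float:
    """Expected long-run fraction of time spent in the stable state,

    phi_S = (1 - p_UU) mu_S / ((1 - p_UU) mu_S + (1 - p_SS) mu_U),

    with the conventions phi_S = 1 when the stable state is absorbing and
    phi_S = 0 when the unstable state is absorbing.
    """
    if params.p_SS == 1.0 and params.p_UU == 1.0:
        raise ValueError("phi_S undefined when both states are absorbing")
    if params.p_SS == 1.0:
        return 1.0
    if params.p_UU == 1.0:
        return 0.0
    num = (1.0 - params.p_UU) * params.mu_S
    return num / (num + (1.0 - params.p_SS) * params.mu_U)


def simulate_hmm(
    params: TwoStateHMMParams, T: float, seed=None
) -> tuple[DominanceSeries, StatePath]:
    """Simulate dominance times from the two-state model for a run of
    length ``T`` seconds.

    States follow the Markov chain from the start distribution; each
    dominance time is an IG draw from the state's emission law.  The
    interval cut by the end of the run is recorded as ``truncated_tail``
    and excluded from ``durations``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pi = params.start_distribution()
    emis = (params.stable, params.unstable)
    state = int(rng.random() >= pi[0])
    t = 0.0
    durations: list = []
    states: list = []
    trunc = None
    while True:
        dur = float(ig_sample(emis[state], 1, rng)[0])
        if t + dur > T:
            trunc = T - t
            break
        durations.append(dur)
        states.append(state)
        t += dur
        stay = params.p_SS if state == STABLE else params.p_UU
        if rng.random() >= stay:
            state = 1 - state
    series = DominanceSeries(
        durations=np.array(durations),
        condition="intermittent",
        T=T,
        truncated_tail=None if trunc is None else float(trunc),
    )
    return series, StatePath(states=np.array(states, dtype=int))
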