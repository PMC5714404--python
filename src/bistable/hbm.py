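"""Hierarchical Brownian Model (HBM) for bistable perception.

Continuous viewing (HBMc): perception is the first-passage dynamics of a
Brownian motion with drift ``+-nu0`` between borders ``+-b``; first hits
mark percept changes, so dominance times are IG(2b/nu0, sqrt(2b/nu0^3)).

Intermittent viewing (HBMi): the stimulus alternates between presentations
of length ``l_p`` and blanks of length ``l_b``.  The perception process P
keeps drift ``nu0`` during presentation but drifts ``nu_S`` (stable) or
``nu_U`` (unstable) during blanks, between state-specific borders ``b_S``
or ``b_U``; its mean drift per second is the blank/presentation average

    nu*_S = (l_b nu_S + l_p nu0) / (l_b + l_p)     (and likewise nu*_U).

A second, background Brownian motion B (mean drift ``+nu*_B`` while stable,
``-nu*_B`` while unstable, reset to 0 at every percept change) decides at
each percept change whether the hidden state persists:

    ptilde_SS(d) = P(stay stable  | duration d) = 1 - Phi_{nu*_B d, d}(btilde_S)
    ptilde_UU(d) = P(stay unstable| duration d) =     Phi_{-nu*_B d, d}(btilde_U)

so longer stable dominance times make staying stable more likely -- a
duration dependence the plain HMM cannot express.  Marginally, the position
of B at the end of an IG dominance time is Normal-Inverse-Gaussian, giving
closed-form state transition probabilities p*_SS, p*_UU.

The observed-data likelihood is a forward recursion with these
duration-dependent transitions; fitting maximizes it over a grid of
starting values with post-hoc plausibility constraints.  Derived
parameters (state-wise IG moments, transition probabilities, conditional
means before staying/leaving, the stable-time fraction phi*_S and the
alternation rate rho) translate the mechanistic parameters back to the
behavioural scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import quad
from scipy.special import ndtr

from .distributions import (
    IGParams,
    NIGSpec,
    ig_logpdf,
    ig_mle,
    ig_pdf,
    ig_sample,
    nig_cdf,
)
from .hmm import STABLE, UNSTABLE, DominanceSeries, StatePath, UnderflowError

__all__ = [
    "Timing",
    "HBMiParams",
    "DerivedHBMi",
    "PathSim",
    "HBMiFit",
    "mean_drifts",
    "decompose_drift",
    "ptilde_SS",
    "ptilde_UU",
    "marginal_transitions",
    "hbmi_loglik",
    "default_start_grid",
    "fit_hbmi",
    "derived_params",
    "mu_conditional",
    "phi_S_star",
    "alternation_rate",
    "rate_vs_blank",
    "simulate_hbmi_intervals",
    "simulate_hbm_path",
]


@dataclass(frozen=True)
class Timing:
    """Stimulation protocol: presentation length l_p, blank length l_b (s),
    run length T (s).  l_b = 0 encodes continuous presentation."""

    l_p: float
    l_b: float
    T: float | None = None

    def __post_init__(self) -> None:
        if self.l_b < 0 or self.l_p < 0:
            raise ValueError("l_p and l_b must be nonnegative")
        if self.l_b > 0 and self.l_p <= 0:
            raise ValueError("intermittent timing needs l_p > 0")


#: timing of the reference protocol: 0.6 s presentations, 0.8 s blanks
DEFAULT_TIMING = Timing(l_p=0.6, l_b=0.8)


@dataclass(frozen=True)
class HBMiParams:
    """HBMi parameter set Theta = (b_S, nu*_S, b_U, nu*_U, btilde_S,
    btilde_U, nu*_B), plus the start probability pi_S and, optionally, the
    presentation drift nu0 from the subject's continuous fit.

    One-regime reductions set the other regime's fields to None.
    """

    b_S: float | None = None
    nu_S_star: float | None = None
    b_U: float | None = None
    nu_U_star: float | None = None
    b_tilde_S: float | None = None
    b_tilde_U: float | None = None
    nu_B_star: float = 1.0
    pi_S: float = 0.5
    nu0: float | None = None

    def __post_init__(self) -> None:
        if self.has_stable:
            if not (self.b_S > 0 and self.nu_S_star > 0):
                raise ValueError("b_S and nu_S_star must be positive")
            if self.b_tilde_S is not None and self.b_tilde_S < 0:
                raise ValueError("b_tilde_S must be nonnegative")
        if self.has_unstable:
            if not (self.b_U > 0 and self.nu_U_star > 0):
                raise ValueError("b_U and nu_U_star must be positive")
        if not self.nu_B_star > 0:
            raise ValueError("nu_B_star must be positive")
        if not 0.0 <= self.pi_S <= 1.0:
            raise ValueError("pi_S must lie in [0, 1]")

    @property
    def has_stable(self) -> bool:
        return self.b_S is not None

    @property
    def has_unstable(self) -> bool:
        return self.b_U is not None

    @property
    def regime(self) -> str:
        if self.has_stable and self.has_unstable:
            return "both"
        return "stable" if self.has_stable else "unstable"

    @property
    def stable_ig(self) -> IGParams:
        """IG law of stable dominance times, IG(2b_S/nu*_S, sqrt(2b_S/nu*_S^3))."""
        return IGParams(
            2.0 * self.b_S / self.nu_S_star,
            math.sqrt(2.0 * self.b_S / self.nu_S_star**3),
        )

    @property
    def unstable_ig(self) -> IGParams:
        return IGParams(
            2.0 * self.b_U / self.nu_U_star,
            math.sqrt(2.0 * self.b_U / self.nu_U_star**3),
        )


@dataclass
class DerivedHBMi:
    """Behaviour-scale quantities derived from an HBMi parameter set."""

    mu_S_star: float = math.nan
    sigma_S_star: float = math.nan
    mu_U_star: float = math.nan
    sigma_U_star: float = math.nan
    p_SS_star: float = math.nan
    p_UU_star: float = math.nan
    cv_S_star: float = math.nan
    cv_U_star: float = math.nan
    phi_S_star: float = math.nan
    mu_S_plus: float = math.nan
    mu_S_minus: float = math.nan
    mu_U_plus: float = math.nan
    mu_U_minus: float = math.nan
    rho: float = math.nan


@dataclass
class PathSim:
    """Discretized sample path of the hierarchical model."""

    t: np.ndarray
    P: np.ndarray
    B: np.ndarray
    S: np.ndarray  # drift-sign process, +-1
    H: np.ndarray  # first-hitting (percept change) times
    states: np.ndarray  # hidden state per step, 0 = S, 1 = U


@dataclass
class HBMiFit:
    params: HBMiParams
    derived: DerivedHBMi
    loglik: float
    n_starts: int = 0
    n_accepted: int = 0
    fallback: str | None = None  # "stable", "unstable" or "no-valid-fit"


def mean_drifts(nu_raw: float, nu0: float, timing: Timing) -> float:
    """Blank/presentation time average, nu* = (l_b nu + l_p nu0)/(l_b + l_p)."""
    if timing.l_b == 0:
        if not math.isclose(nu_raw, nu0):
            raise ValueError("continuous timing (l_b = 0) requires nu_raw == nu0")
        return nu0
    return (timing.l_b * nu_raw + timing.l_p * nu0) / (timing.l_b + timing.l_p)


def decompose_drift(nu_star: float, nu0: float, timing: Timing) -> float:
    """Recover the blank-display drift from its starred average."""
    if timing.l_b == 0:
        return nu0
    return (nu_star * (timing.l_b + timing.l_p) - timing.l_p * nu0) / timing.l_b


def ptilde_SS(d, params: HBMiParams):
    """Probability of staying stable after a stable dominance time d,
    1 - Phi_{nu*_B d, d}(btilde_S); increasing in d for btilde_S > 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dominance time must be positive")
    return 1.0 - ndtr((params.b_tilde_S - params.nu_B_star * d) / np.sqrt(d))


def ptilde_UU(d, params: HBMiParams):
    """Probability of staying unstable after an unstable dominance time d,
    Phi_{-nu*_B d, d}(btilde_U)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dominance time must be positive")
    return ndtr((params.b_tilde_U + params.nu_B_star * d) / np.sqrt(d))


def marginal_transitions(params: HBMiParams) -> tuple[float, float]:
    """Marginal state transition probabilities (p*_SS, p*_UU).

    The background position at the end of an IG dominance time is NIG:
    X_S ~ NIG(0, sqrt(nu*_S^2 + nu*_B^2), nu*_B, 2 b_S) and p*_SS =
    P(X_S > btilde_S); X_U ~ NIG(0, sqrt(nu*_U^2 + nu*_B^2), -nu*_B,
    2 b_U) and p*_UU = P(X_U <= btilde_U).  Equals E[ptilde(D)] over the
    state's IG duration law.
    """
    p_SS = p_UU = math.nan
    if params.has_stable:
        spec = NIGSpec(
            loc=0.0,
            alpha=math.hypot(params.nu_S_star, params.nu_B_star),
            beta=params.nu_B_star,
            delta=2.0 * params.b_S,
        )
        p_SS = float(1.0 - nig_cdf(params.b_tilde_S, spec))
    if params.has_unstable:
        spec = NIGSpec(
            loc=0.0,
            alpha=math.hypot(params.nu_U_star, params.nu_B_star),
            beta=-params.nu_B_star,
            delta=2.0 * params.b_U,
        )
        p_UU = float(nig_cdf(params.b_tilde_U, spec))
    return p_SS, p_UU


def _forward_inputs(series: DominanceSeries, params: HBMiParams):
    d = series.durations
    logf = np.column_stack(
        [ig_logpdf(d, params.stable_ig), ig_logpdf(d, params.unstable_ig)]
    )
    pss = np.asarray(ptilde_SS(d, params))
    puu = np.asarray(ptilde_UU(d, params))
    return d, np.exp(logf), pss, puu


def hbmi_loglik(series: DominanceSeries, params: HBMiParams) -> float:
    """Scaled forward log-likelihood with duration-dependent transitions.

    alpha*_j(1) = pi_j f_j(d_1); for i > 1,
    alpha*_j(i) = f_j(d_i) sum_k alpha~_k(i-1) ptilde_kj(d_{i-1});
    log L = sum_i log c_i with c_i the scaling constants.
    """
    if params.regime != "both":
        raise ValueError("likelihood requires both regimes")
    d, f, pss, puu = _forward_inputs(series, params)
    n = d.size
    a = np.array([params.pi_S, 1.0 - params.pi_S]) * f[0]
    c0 = a.sum()
    if c0 <= 0.0 or not np.isfinite(c0):
        raise UnderflowError(0)
    loglik = math.log(c0)
    aS, aU = a[0] / c0, a[1] / c0
    for i in range(1, n):
        pS, pU = pss[i - 1], puu[i - 1]
        inS = aS * pS + aU * (1.0 - pU)
        inU = aS * (1.0 - pS) + aU * pU
        sS = f[i, 0] * inS
        sU = f[i, 1] * inU
        ci = sS + sU
        if ci <= 0.0 or not np.isfinite(ci):
            raise UnderflowError(i)
        loglik += math.log(ci)
        aS, aU = sS / ci, sU / ci
    return float(loglik)


# ---------------------------------------------------------------------------
# fitting


def _subset_moments(d: np.ndarray, thresh: float):
    sel = d[d > thresh]
    if sel.size < 2:
        return None, None
    mu = float(sel.mean())
    sd = float(sel.std(ddof=1))
    return mu, (sd if sd > 0 else None)


def default_start_grid(d: np.ndarray) -> list[HBMiParams]:
    """Starting values for the HBMi optimizer.

    (b_S, nu*_S) pairs are moment-matched from the means/SDs of the
    dominance times above 15 s and above 30 s (U = {mu_15, mu_30},
    O = {sigma_15, sigma_30, 1.15 sigma_30}); the remaining coordinates
    come from the sets b_U in {0.01, 0.05, 0.15} b_S,
    btilde_S in {b_S, 10 b_S}, nu*_U in {1.01, 3, 7} nu*_S,
    nu*_B in {0.1, 3} and btilde_U in {-3, 0, 3}.
    """
    mu15, sd15 = _subset_moments(d, 15.0)
    mu30, sd30 = _subset_moments(d, 30.0)
    mus = [m for m in {mu15, mu30} if m is not None]
    sds = [s for s in (sd15, sd30) if s is not None]
    sds += [1.15 * s for s in ([sd30] if sd30 is not None else sds[:1])]
    if not mus:  # no long dominance times: seed from the overall moments
        mus = [float(d.mean())]
    if not sds:
        sds = [max(float(d.std(ddof=1)), 1.0)]
    sds = sorted(set(sds))

    starts = []
    for mu in sorted(set(mus)):
        for sd in sds:
            b_S = 0.5 * math.sqrt(mu**3 / sd**2)
            nu_S = math.sqrt(mu) / sd
            for fb in (0.01, 0.05, 0.15):
                for bts in (b_S, 10.0 * b_S):
                    for fn in (1.01, 3.0, 7.0):
                        for nuB in (0.1, 3.0):
                            for btu in (-3.0, 0.0, 3.0):
                                starts.append(
                                    HBMiParams(
                                        b_S=b_S,
                                        nu_S_star=nu_S,
                                        b_U=fb * b_S,
                                        nu_U_star=fn * nu_S,
                                        b_tilde_S=bts,
                                        b_tilde_U=btu,
                                        nu_B_star=nuB,
                                    )
                                )
    return starts


_BTS_FLOOR = 1e-8  # log-transform floor for the nonnegative border btilde_S


def _pack(p: HBMiParams) -> np.ndarray:
    return np.array(
        [
            math.log(p.b_S),
            math.log(p.nu_S_star),
            math.log(p.b_U),
            math.log(p.nu_U_star),
            math.log(max(p.b_tilde_S, _BTS_FLOOR)),
            p.b_tilde_U,
            math.log(p.nu_B_star),
        ]
    )


def _unpack(x: np.ndarray, pi_S: float, nu0: float | None) -> HBMiParams:
    return HBMiParams(
        b_S=math.exp(x[0]),
        nu_S_star=math.exp(x[1]),
        b_U=math.exp(x[2]),
        nu_U_star=math.exp(x[3]),
        b_tilde_S=math.exp(x[4]),
        b_tilde_U=float(x[5]),
        nu_B_star=math.exp(x[6]),
        pi_S=pi_S,
        nu0=nu0,
    )


def _hbmc_like_fit(d: np.ndarray) -> tuple[float, float]:
    """Moment/ML fit of a single drift-diffusion regime: returns (b, nu*)."""
    from .distributions import ig_to_barrier

    bd = ig_to_barrier(ig_mle(d))
    return bd.b, bd.nu


def _start_pi_S(d: np.ndarray) -> float:
    """pi_S = 1 if the run opens with a long (>= 45 s) dominance time,
    0 if it opens with a short (<= 15 s) one, 0.5 otherwise."""
    if d[0] >= 45.0:
        return 1.0
    if d[0] <= 15.0:
        return 0.0
    return 0.5


def _passes_constraints(p: HBMiParams, d: np.ndarray, timing: Timing) -> bool:
    """Constraints A-F on an accepted fit."""
    if p.nu0 is not None:  # A) nu_U >= nu_S on the decomposed (blank) drifts
        nu_S = decompose_drift(p.nu_S_star, p.nu0, timing)
        nu_U = decompose_drift(p.nu_U_star, p.nu0, timing)
        if nu_U < nu_S:
            return False
    if not (0.0 <= p.b_U <= p.b_S):  # B
        return False
    if p.b_tilde_S < 0:  # C
        return False
    if not p.nu_B_star > 0:  # D
        return False
    mu15, sd15 = _subset_moments(d, 15.0)
    mu_star = 2.0 * p.b_S / p.nu_S_star
    if mu15 is not None and not mu_star >= 0.98 * mu15:  # E
        return False
    if sd15 is not None:
        sigma_star = math.sqrt(2.0 * p.b_S / p.nu_S_star**3)
        if not sigma_star < 1.20 * sd15:  # F
            return False
    return True


def fit_hbmi(
    series: DominanceSeries,
    timing: Timing = DEFAULT_TIMING,
    nu0: float | None = None,
    starts: list | None = None,
    n_optimize: int = 12,
    maxiter: int = 200,
) -> HBMiFit:
    """Constrained maximum-likelihood fit of the HBMi.

    The likelihood is maximized (quasi-Newton on log-transformed positive
    parameters, btilde_U unconstrained) from a grid of starting values;
    the best converged fit satisfying constraints A-F is returned.  To keep
    the cost bounded, only the ``n_optimize`` grid points with the highest
    initial likelihood are optimized (pass ``n_optimize=None`` to optimize
    from every start).

    Runs with all dominance times > 30 s reduce to the stable regime
    (btilde_S := 0, nu*_B := 10); runs with all dominance times <= 30 s
    reduce to the unstable regime (btilde_U := 1e10, nu*_B := 10).
    """
    d = series.durations
    if d.size < 2:
        raise ValueError("need at least two dominance times")

    if np.all(d > 30.0):
        b, nu = _hbmc_like_fit(d)
        p = HBMiParams(
            b_S=b, nu_S_star=nu, b_tilde_S=0.0, nu_B_star=10.0, pi_S=1.0, nu0=nu0
        )
        return HBMiFit(p, derived_params(p), math.nan, fallback="stable")
    if np.all(d <= 30.0):
        b, nu = _hbmc_like_fit(d)
        p = HBMiParams(
            b_U=b, nu_U_star=nu, b_tilde_U=1e10, nu_B_star=10.0, pi_S=0.0, nu0=nu0
        )
        return HBMiFit(p, derived_params(p), math.nan, fallback="unstable")

    pi_S = _start_pi_S(d)
    if starts is None:
        starts = default_start_grid(d)

    def negll(x: np.ndarray) -> float:
        try:
            p = _unpack(x, pi_S, nu0)
            return -hbmi_loglik(series, p)
        except (ValueError, OverflowError, UnderflowError):
            return 1e12

    scored = []
    for s in starts:
        x0 = _pack(s)
        v = negll(x0)
        if v < 1e12:
            scored.append((v, x0))
    scored.sort(key=lambda t: t[0])
    if n_optimize is not None:
        scored = scored[:n_optimize]

    best: HBMiParams | None = None
    best_ll = -np.inf
    n_accepted = 0
    for _, x0 in scored:
        res = optimize.minimize(
            negll, x0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6}
        )
        try:
            p = _unpack(res.x, pi_S, nu0)
        except (ValueError, OverflowError):
            continue
        if not _passes_constraints(p, d, timing):
            continue
        n_accepted += 1
        ll = -res.fun
        if ll > best_ll:
            best, best_ll = p, ll
    if best is None:
        # no accepted start: reduce to the regime that dominates the data
        b, nu = _hbmc_like_fit(d)
        if float(np.median(d)) > 30.0:
            p = HBMiParams(
                b_S=b, nu_S_star=nu, b_tilde_S=0.0, nu_B_star=10.0, pi_S=1.0, nu0=nu0
            )
        else:
            p = HBMiParams(
                b_U=b, nu_U_star=nu, b_tilde_U=1e10, nu_B_star=10.0, pi_S=0.0, nu0=nu0
            )
        return HBMiFit(
            p, derived_params(p), math.nan, len(starts), 0, fallback="no-valid-fit"
        )
    return HBMiFit(best, derived_params(best), best_ll, len(starts), n_accepted)


# ---------------------------------------------------------------------------
# derived quantities


def _tail_quad(integrand, ig: IGParams) -> float:
    """Adaptive quadrature of an IG-weighted integrand over (0, inf),
    split at the bulk of the mass to keep the tail resolved."""
    split = ig.mu + 12.0 * ig.sigma
    a, _ = quad(integrand, 0.0, split, epsabs=1e-10, limit=200)
    b, _ = quad(integrand, split, np.inf, epsabs=1e-10, limit=200)
    return a + b


def mu_conditional(params: HBMiParams, state: str, next_same: bool) -> float:
    """Expected dominance time in ``state`` conditional on whether the next
    dominance time stays in the same state.

    For the stable state: mu_S+ = (p*_SS)^-1 Int f_S(t) ptilde_SS(t) t dt
    (stay) and mu_S- = (1-p*_SS)^-1 Int f_S(t) (1-ptilde_SS(t)) t dt
    (switch), and analogously for the unstable state with ptilde_UU.
    Satisfies the total-expectation identity
    mu+ p + mu- (1-p) = mu* of the state's IG law.
    """
    if state == "S":
        ig = params.stable_ig
        stay_prob = marginal_transitions(params)[0]
        weight = lambda t: ptilde_SS(t, params)
    elif state == "U":
        ig = params.unstable_ig
        stay_prob = marginal_transitions(params)[1]
        weight = lambda t: ptilde_UU(t, params)
    else:
        raise ValueError("state must be 'S' or 'U'")
    p = stay_prob if next_same else 1.0 - stay_prob
    if not 0.0 < p:
        raise ValueError("conditioning event has zero probability")
    if next_same:
        integrand = lambda t: ig_pdf(t, ig) * weight(t) * t
    else:
        integrand = lambda t: ig_pdf(t, ig) * (1.0 - weight(t)) * t
    return float(_tail_quad(integrand, ig) / p)


def phi_S_star(params: HBMiParams) -> float:
    """Expected long-run fraction of time spent in the stable state,

    phi*_S = E[stable phase] / (E[stable phase] + E[unstable phase]) with
    E[stable phase] = p*_SS/(1-p*_SS) mu_S+ + mu_S- (and the analogue for
    the unstable state)."""
    if params.regime == "stable":
        return 1.0
    if params.regime == "unstable":
        return 0.0
    p_SS, p_UU = marginal_transitions(params)
    if p_SS >= 1.0:
        return 1.0
    if p_UU >= 1.0:
        return 0.0
    eS = p_SS / (1.0 - p_SS) * mu_conditional(params, "S", True) + mu_conditional(
        params, "S", False
    )
    eU = p_UU / (1.0 - p_UU) * mu_conditional(params, "U", True) + mu_conditional(
        params, "U", False
    )
    return eS / (eS + eU)


def derived_params(params: HBMiParams) -> DerivedHBMi:
    """All behaviour-scale quantities; one-regime inputs leave the missing
    state's fields as NaN (printed as NA)."""
    out = DerivedHBMi()
    p_SS, p_UU = marginal_transitions(params)
    if params.has_stable:
        ig = params.stable_ig
        out.mu_S_star, out.sigma_S_star = ig.mu, ig.sigma
        out.cv_S_star = ig.cv
        out.p_SS_star = p_SS
    if params.has_unstable:
        ig = params.unstable_ig
        out.mu_U_star, out.sigma_U_star = ig.mu, ig.sigma
        out.cv_U_star = ig.cv
        out.p_UU_star = p_UU

    if params.regime == "both":
        if 0.0 < p_SS < 1.0:
            out.mu_S_plus = mu_conditional(params, "S", True)
            out.mu_S_minus = mu_conditional(params, "S", False)
        else:
            out.mu_S_plus = out.mu_S_star
            out.mu_S_minus = math.nan
        if 0.0 < p_UU < 1.0:
            out.mu_U_plus = mu_conditional(params, "U", True)
            out.mu_U_minus = mu_conditional(params, "U", False)
        else:
            out.mu_U_plus = out.mu_U_star
            out.mu_U_minus = math.nan
        out.phi_S_star = phi_S_star(params)
        out.rho = alternation_rate_from(
            out.phi_S_star, out.mu_S_star, out.mu_U_star
        )
    elif params.regime == "stable":
        out.phi_S_star = 1.0
        out.mu_S_plus = out.mu_S_star
        out.rho = 1.0 / out.mu_S_star
    else:
        out.phi_S_star = 0.0
        out.mu_U_plus = out.mu_U_star
        out.rho = 1.0 / out.mu_U_star
    return out


def alternation_rate_from(phi_S: float, mu_S: float, mu_U: float) -> float:
    """rho = phi*_S/mu*_S + phi*_U/mu*_U (percept changes per second)."""
    terms = 0.0
    if phi_S > 0:
        terms += phi_S / mu_S
    if phi_S < 1:
        terms += (1.0 - phi_S) / mu_U
    return terms


def alternation_rate(params: HBMiParams) -> float:
    """Long-run percept alternation rate of the model (1/s)."""
    d = derived_params(params)
    return d.rho


def rate_vs_blank(
    b_S: float,
    b_U: float,
    b_tilde_S: float,
    b_tilde_U: float,
    nu_B: float,
    nu0: float,
    nu_S_fn,
    nu_U_fn,
    l_b_grid,
    l_p: float = 0.6,
):
    """Alternation rate as a function of blank-display length.

    ``nu_S_fn`` and ``nu_U_fn`` are user-supplied mean-drift functions of
    l_b; for each l_b on the grid the starred drifts are recomputed as the
    blank/presentation time averages and the full chain of derived
    quantities leads to rho(l_b).  A warning is issued where the mean
    stable drift turns nonpositive (l_b > l_p nu0 / nu_S), the regime the
    model is not designed for.
    """
    rhos = []
    for l_b in np.asarray(l_b_grid, dtype=float):
        timing = Timing(l_p=l_p, l_b=float(l_b))
        nu_S = float(nu_S_fn(l_b))
        nu_U = float(nu_U_fn(l_b))
        nu_S_star = mean_drifts(nu_S, nu0, timing)
        nu_U_star = mean_drifts(nu_U, nu0, timing)
        nu_B_star = l_b * nu_B / (l_b + l_p) if l_b > 0 else 1e-12
        if nu_S_star <= 0:
            warnings.warn(
                f"l_b={l_b:g} exceeds l_p*nu0/nu_S; mean stable drift nonpositive",
                RuntimeWarning,
            )
            rhos.append(math.nan)
            continue
        p = HBMiParams(
            b_S=b_S,
            nu_S_star=nu_S_star,
            b_U=b_U,
            nu_U_star=max(nu_U_star, 1e-12),
            b_tilde_S=b_tilde_S,
            b_tilde_U=b_tilde_U,
            nu_B_star=max(nu_B_star, 1e-12),
            nu0=nu0,
        )
        rhos.append(derived_params(p).rho)
    return np.asarray(rhos)


# ---------------------------------------------------------------------------
# simulation


def simulate_hbmi_intervals(
    params: HBMiParams, T: float, seed=None
) -> tuple[DominanceSeries, StatePath]:
    """Exact interval-level simulation of the HBMi.

    Per dominance time: draw the duration from the state's IG law, draw the
    background endpoint Normal(+-nu*_B d, d), compare with the state's
    background border to decide whether the hidden state persists, then
    reset.  The interval cut by the end of the run is dropped and recorded
    as ``truncated_tail``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if params.regime != "both":
        raise ValueError("interval simulation requires both regimes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    igs = (params.stable_ig, params.unstable_ig)
    state = STABLE if rng.random() < params.pi_S else UNSTABLE
    t = 0.0
    durations: list = []
    states: list = []
    trunc = None
    while True:
        dur = float(ig_sample(igs[state], 1, rng)[0])
        if t + dur > T:
            trunc = T - t
            break
        durations.append(dur)
        states.append(state)
        t += dur
        if state == STABLE:
            b_end = rng.normal(params.nu_B_star * dur, math.sqrt(dur))
            if not b_end > params.b_tilde_S:
                state = UNSTABLE
        else:
            b_end = rng.normal(-params.nu_B_star * dur, math.sqrt(dur))
            if not b_end <= params.b_tilde_U:
                state = STABLE
    series = DominanceSeries(
        durations=np.array(durations),
        condition="intermittent",
        l_p=DEFAULT_TIMING.l_p,
        l_b=DEFAULT_TIMING.l_b,
        T=T,
        truncated_tail=None if trunc is None else float(trunc),
    )
    return series, StatePath(states=np.array(states, dtype=int))


def simulate_hbm_path(
    params: HBMiParams,
    timing: Timing,
    dt: float = 1e-3,
    T: float = 240.0,
    seed=None,
    diffusion: float = 1.0,
) -> PathSim:
    """Euler-Maruyama sample path of the hierarchical model.

    With ``timing.l_b = 0`` this is the continuous model: drift ``+-nu0``
    between borders ``+-b_S`` and no background dynamics.  Otherwise the
    perception process P drifts with ``nu0`` during presentations and with
    the decomposed blank drift of the current hidden state during blanks,
    between the state's borders; the background process B accrues drift
    only during blanks (positive while stable, negative while unstable),
    decides the state at every border hit of P, and is reset to 0 there.
    At a state change P is reset to sgn(P) times the new border.

    ``diffusion`` scales the noise (0 gives the deterministic sawtooth with
    hitting interval 2 b / nu).
    """
    if params.nu0 is None:
        raise ValueError("path simulation requires nu0")
    intermittent = timing.l_b > 0
    if intermittent and dt > 0.1 * min(timing.l_p, timing.l_b):
        warnings.warn("dt is coarse relative to l_p/l_b", RuntimeWarning)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_steps = int(round(T / dt))
    t_grid = np.arange(n_steps + 1) * dt

    if intermittent:
        nu_S = decompose_drift(params.nu_S_star, params.nu0, timing)
        nu_U = decompose_drift(params.nu_U_star, params.nu0, timing)
        nu_B = params.nu_B_star * (timing.l_b + timing.l_p) / timing.l_b
        borders = (params.b_S, params.b_U)
        blank_drift = (nu_S, nu_U)
        cycle = timing.l_p + timing.l_b
    else:
        borders = (params.b_S, params.b_S)
        blank_drift = (params.nu0, params.nu0)
        nu_B = 0.0
        cycle = math.inf

    sqdt = math.sqrt(dt) * diffusion
    dW = rng.standard_normal(n_steps) * sqdt if diffusion else np.zeros(n_steps)
    dWb = rng.standard_normal(n_steps) * sqdt if diffusion else np.zeros(n_steps)

    state = STABLE if rng.random() < params.pi_S else UNSTABLE
    P = np.empty(n_steps + 1)
    B = np.empty(n_steps + 1)
    S = np.empty(n_steps + 1)
    states = np.empty(n_steps + 1, dtype=int)
    P[0] = -borders[state]
    B[0] = 0.0
    sgn = 1.0  # S_0 = +1: drift pushes toward +b
    S[0] = sgn
    states[0] = state
    hits: list = []

    for i in range(n_steps):
        t = t_grid[i]
        in_blank = intermittent and (t % cycle) >= timing.l_p
        drift_p = blank_drift[state] if in_blank else params.nu0
        p_new = P[i] + sgn * drift_p * dt + dW[i]
        if in_blank and intermittent:
            b_new = B[i] + (nu_B if state == STABLE else -nu_B) * dt + dWb[i]
        elif intermittent:
            b_new = B[i] + dWb[i]
        else:
            b_new = 0.0
        border = borders[state]
        if sgn * p_new >= border:  # reached the target border: percept change
            hits.append(t_grid[i + 1])
            if intermittent:
                if state == STABLE:
                    if not b_new > params.b_tilde_S:
                        state = UNSTABLE
                else:
                    if b_new > params.b_tilde_U:
                        state = STABLE
                b_new = 0.0
            p_new = math.copysign(borders[state], p_new)
            sgn = -math.copysign(1.0, p_new)
        P[i + 1] = p_new
        B[i + 1] = b_new
        S[i + 1] = sgn
        states[i + 1] = state

    return PathSim(
        t=t_grid, P=P, B=B, S=S, H=np.asarray(hits), states=states
    )
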