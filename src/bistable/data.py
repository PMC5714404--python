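"""Dominance-time I/O, response-stream conversion and synthetic cohorts.

The study design this package targets: two groups (29 patients, 32
healthy controls), each subject viewed an ambiguous
rotating sphere continuously for 240 s (button presses mark percept
changes) and intermittently for 1200 s (0.6 s presentations separated by
0.8 s blanks, percept reported on the 1.4 s grid; missing reports carried
forward from the preceding response).

The synthetic cohort generator emulates that structure: per subject a
continuous series is drawn from an HBMc (i.i.d. IG dominance times) and an
intermittent series from an HBMi, with group-level parameter distributions
reproducing the direction of the reported group differences (patients:
longer continuous dominance times, lower probability of staying stable,
slightly longer unstable dominance times).  Ground-truth parameters are
stored with each subject for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import IGParams, ig_sample
from .hbm import DEFAULT_TIMING, HBMiParams, simulate_hbmi_intervals
from .hmm import DominanceSeries

__all__ = [
    "ResponseStream",
    "CohortSpec",
    "Cohort",
    "SubjectRecord",
    "stream_to_dominance",
    "simulate_continuous",
    "generate_cohort",
    "read_dominance_csv",
    "write_dominance_csv",
]

SLOT = 1.4  # s, presentation + blank grid of the intermittent protocol

CSV_COLUMNS = ["subject_id", "group", "condition", "run_id", "duration_s", "percept"]


@dataclass
class ResponseStream:
    """Raw per-presentation responses.

    Continuous runs carry ``events``: strictly increasing button-press
    times (s) marking percept changes, with optional percept labels.
    Intermittent runs carry ``slots``: one reported percept per
    ``slot_length`` grid position, ``None`` marking a missing response.
    """

    condition: str
    T: float
    events: np.ndarray | None = None
    event_percepts: list | None = None
    slots: list | None = None
    slot_length: float = SLOT

    def __post_init__(self) -> None:
        if self.condition == "continuous":
            if self.events is None:
                raise ValueError("continuous stream requires events")
            self.events = np.asarray(self.events, dtype=float)
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("event timestamps must be strictly increasing")
        elif self.condition == "intermittent":
            if self.slots is None:
                raise ValueError("intermittent stream requires slots")
        else:
            raise ValueError(f"unknown condition {self.condition!r}")


def stream_to_dominance(stream: ResponseStream) -> DominanceSeries:
    """Convert a raw response stream to dominance times.

    Intermittent: missing slot reports are replaced by the preceding
    response (leading missing slots are dropped); a dominance time is the
    span between consecutive percept changes on the slot grid, and the
    final, still-ongoing span is kept as the truncated tail.

    Continuous: dominance times are the differences between successive
    button events; the leading span (before the first event, with no
    defined percept) is dropped, the span from the last event to the end
    of the run is the truncated tail.
    """
    if stream.condition == "intermittent":
        slots = list(stream.slots)
        # carry-forward imputation
        filled: list = []
        last = None
        for s in slots:
            if s is None:
                s = last
            filled.append(s)
            last = s if s is not None else last
        # drop leading undefined slots
        start = 0
        while start < len(filled) and filled[start] is None:
            start += 1
        filled = filled[start:]
        if not filled:
            raise ValueError("all responses missing")
        durations: list = []
        percepts: list = []
        run_len = 1
        for prev, cur in zip(filled, filled[1:]):
            if cur == prev:
                run_len += 1
            else:
                durations.append(run_len * stream.slot_length)
                percepts.append(prev)
                run_len = 1
        tail = run_len * stream.slot_length
        return DominanceSeries(
            durations=np.asarray(durations, dtype=float),
            percepts=percepts or None,
            condition="intermittent",
            l_p=0.6,
            l_b=0.8,
            T=stream.T,
            truncated_tail=tail,
        )

    ev = stream.events
    if ev.size < 2:
        raise ValueError("need at least two events to define a dominance time")
    durations = np.diff(ev)
    percepts = None
    if stream.event_percepts is not None:
        percepts = list(stream.event_percepts[:-1])
    return DominanceSeries(
        durations=durations,
        percepts=percepts,
        condition="continuous",
        T=stream.T,
        truncated_tail=float(stream.T - ev[-1]),
    )


def simulate_continuous(
    ig: IGParams, T: float, rng, percept_start: str = "L"
) -> DominanceSeries:
    """I.i.d. IG dominance times truncated at run length T, with
    alternating percept labels."""
    durations: list = []
    t = 0.0
    trunc = None
    while True:
        d = float(ig_sample(ig, 1, rng)[0])
        if t + d > T:
            trunc = T - t
            break
        durations.append(d)
        t += d
    labels = ["L", "R"] if percept_start == "L" else ["R", "L"]
    percepts = [labels[i % 2] for i in range(len(durations))]
    return DominanceSeries(
        durations=np.asarray(durations),
        percepts=percepts or None,
        condition="continuous",
        T=T,
        truncated_tail=trunc,
    )


@dataclass
class CohortSpec:
    """Hyper-parameters of the synthetic cohort.

    Group-level laws are log-normal over positive parameters.  Centers are
    placed near the worked-example subject fits of the study protocol so
    simulated patterns resemble real response patterns; the group effects
    encode the reported directions: patients have longer continuous
    dominance times, a higher stable->unstable propensity (larger
    background border relative to b_S, hence lower p*_SS) and slightly
    longer unstable dominance times.
    """

    n_patients: int = 29
    n_controls: int = 32
    T_continuous: float = 240.0
    T_intermittent: float = 1200.0
    l_p: float = 0.6
    l_b: float = 0.8
    # continuous: median mean dominance time (s) per group, log-sd, CV law
    mu_cont_center: dict = field(default_factory=lambda: {"control": 8.0, "patient": 13.0})
    mu_cont_logsd: float = 0.35
    cv_cont_center: float = 0.78
    cv_cont_logsd: float = 0.18
    # intermittent: stable/unstable IG moments and background geometry
    mu_S_center: float = 150.0
    mu_S_logsd: float = 0.35
    cv_S_center: float = 0.22
    cv_S_logsd: float = 0.25
    mu_U_center: dict = field(default_factory=lambda: {"control": 4.5, "patient": 6.0})
    mu_U_logsd: float = 0.25
    cv_U_center: float = 0.6
    cv_U_logsd: float = 0.2
    # background border relative to b_S: larger ratio -> smaller p*_SS
    btilde_ratio_center: dict = field(default_factory=lambda: {"control": 0.9, "patient": 1.8})
    btilde_ratio_logsd: float = 0.3
    b_tilde_U_center: float = 1.5
    b_tilde_U_logsd: float = 0.3
    nu_B_center: float = 0.5
    nu_B_logsd: float = 0.3


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    continuous: DominanceSeries
    intermittent: DominanceSeries
    truth_continuous: IGParams
    truth_intermittent: HBMiParams


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list

    def series(self, condition: str) -> list:
        attr = "continuous" if condition == "continuous" else "intermittent"
        return [getattr(s, attr) for s in self.subjects]

    def groups(self) -> list:
        return [s.group for s in self.subjects]


def _lognormal(rng, center: float, logsd: float) -> float:
    return float(center * math.exp(rng.normal(0.0, logsd)))


def _draw_subject(rng, spec: CohortSpec, group: str, subject_id: str) -> SubjectRecord:
    # continuous regime
    mu_c = _lognormal(rng, spec.mu_cont_center[group], spec.mu_cont_logsd)
    cv_c = _lognormal(rng, spec.cv_cont_center, spec.cv_cont_logsd)
    ig_c = IGParams(mu=mu_c, sigma=cv_c * mu_c)
    cont = simulate_continuous(ig_c, spec.T_continuous, rng)

    # intermittent regime: draw behavioural moments, map to borders/drifts
    mu_S = _lognormal(rng, spec.mu_S_center, spec.mu_S_logsd)
    cv_S = _lognormal(rng, spec.cv_S_center, spec.cv_S_logsd)
    mu_U = _lognormal(rng, spec.mu_U_center[group], spec.mu_U_logsd)
    cv_U = _lognormal(rng, spec.cv_U_center, spec.cv_U_logsd)
    sig_S, sig_U = cv_S * mu_S, cv_U * mu_U
    b_S = 0.5 * math.sqrt(mu_S**3 / sig_S**2)
    nu_S = math.sqrt(mu_S) / sig_S
    b_U = 0.5 * math.sqrt(mu_U**3 / sig_U**2)
    nu_U = math.sqrt(mu_U) / sig_U
    params = HBMiParams(
        b_S=b_S,
        nu_S_star=nu_S,
        b_U=b_U,
        nu_U_star=nu_U,
        b_tilde_S=_lognormal(rng, spec.btilde_ratio_center[group], spec.btilde_ratio_logsd)
        * b_S,
        b_tilde_U=_lognormal(rng, spec.b_tilde_U_center, spec.b_tilde_U_logsd),
        nu_B_star=_lognormal(rng, spec.nu_B_center, spec.nu_B_logsd),
        pi_S=0.5,
    )
    intermittent, _ = simulate_hbmi_intervals(params, spec.T_intermittent, rng)
    intermittent.l_p, intermittent.l_b = spec.l_p, spec.l_b
    intermittent.subject_id = subject_id
    cont.subject_id = subject_id
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        continuous=cont,
        intermittent=intermittent,
        truth_continuous=ig_c,
        truth_intermittent=params,
    )


def generate_cohort(spec: CohortSpec | None = None, seed=None) -> Cohort:
    """Generate a synthetic two-group cohort with ground truth.

    Per subject: one continuous run (i.i.d. IG dominance times) and one
    intermittent run (HBMi interval simulation).  Reproducible by seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    subjects = []
    for i in range(spec.n_controls):
        subjects.append(_draw_subject(rng, spec, "control", f"C{i + 1:03d}"))
    for i in range(spec.n_patients):
        subjects.append(_draw_subject(rng, spec, "patient", f"P{i + 1:03d}"))
    return Cohort(spec=spec, subjects=subjects)


def write_dominance_csv(cohort_or_series, path) -> None:
    """Write dominance series as tidy CSV (one row per dominance time)."""
    rows = []
    if isinstance(cohort_or_series, Cohort):
        items = []
        for s in cohort_or_series.subjects:
            items.append((s.subject_id, s.group, s.continuous))
            items.append((s.subject_id, s.group, s.intermittent))
    else:
        items = [(s.subject_id or f"S{i}", "", s) for i, s in enumerate(cohort_or_series)]
    for sid, group, series in items:
        for j, d in enumerate(series.durations):
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "condition": series.condition,
                    "run_id": series.run_id or "1",
                    "duration_s": float(d),
                    "percept": series.percepts[j] if series.percepts else "",
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_dominance_csv(path) -> list:
    """Read a tidy dominance-time CSV into a list of DominanceSeries.

    Validates the schema; malformed rows (missing columns, non-positive
    durations) raise ValueError naming the offending row indices.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "run_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("group", "percept")]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad = df.index[~(df["duration_s"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive duration_s in rows {bad}")
    out = []
    for (sid, cond, run), g in df.groupby(
        ["subject_id", "condition", "run_id"], sort=True
    ):
        percepts = None
        if "percept" in g.columns:
            vals = [p for p in g["percept"].fillna("").tolist()]
            if any(v != "" for v in vals):
                percepts = vals
        timing = DEFAULT_TIMING if cond == "intermittent" else None
        out.append(
            DominanceSeries(
                durations=g["duration_s"].to_numpy(),
                percepts=percepts,
                condition=str(cond),
                l_p=timing.l_p if timing else 0.0,
                l_b=timing.l_b if timing else 0.0,
                subject_id=str(sid),
                run_id=str(run),
            )
        )
    return out
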