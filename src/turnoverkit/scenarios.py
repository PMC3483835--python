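"""Composable experiment scenarios: timed perturbations and labeled pools.

A :class:`Scenario` is an ordered list of instantaneous multiplier steps
(translation block, transcription change, degradation change, isotope
label switch) applied to a system that starts, by default, at steady
state.  :func:`simulate` propagates the mRNA and the labeled/unlabeled
protein pools *analytically* across each piecewise-constant segment:
within a segment the mRNA relaxes exponentially to its new steady level
and each protein pool obeys a linear ODE with a single- plus
two-exponential closed form.  State is continuous across breakpoints, so
arbitrarily composed designs (CHX chase, Tet-off, siRNA knockdown,
degradation-inhibitor treatments, pulse-chase, SILAC medium switch) are
exact up to floating point — no step-size error.

The numeric integrator in :mod:`turnoverkit.reference` provides an
independent check of every trajectory produced here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kinetics import (
    LN2,
    DEGENERACY_RTOL,
    ParameterError,
    StateVector,
    TurnoverParams,
    rate_constants,
    steady_state,
)

__all__ = [
    "PERTURBATION_KINDS",
    "PRESET_NAMES",
    "Perturbation",
    "Scenario",
    "TimeCourse",
    "FoldChangeDecomposition",
    "simulate",
    "preset",
    "pulse_chase",
    "silac_switch",
    "predict_fold_change",
]

PERTURBATION_KINDS = frozenset(
    {
        "synthesis_multiplier",
        "transcription_multiplier",
        "degradation_multiplier",
        "label_switch",
    }
)

PRESET_NAMES = (
    "chx_chase",
    "tet_off",
    "sirna_knockdown",
    "degradation_inhibitor",
    "chx_plus_inhibitor",
)

TIMECOURSE_COLUMNS = ["time_h", "mrna", "protein_total", "protein_labeled", "protein_unlabeled"]


@dataclass(frozen=True)
class Perturbation:
    """One instantaneous step change at ``onset`` hours.

    ``synthesis_multiplier`` scales the translation rate R,
    ``transcription_multiplier`` scales the transcription rate (so the
    mRNA relaxes toward ``magnitude * M0`` with rate k_M),
    ``degradation_multiplier`` scales the degradation rate D (dilution V
    is untouched), and ``label_switch`` reroutes all new synthesis to the
    labeled pool (magnitude ignored).
    """

    onset: float
    kind: str
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ParameterError(
                f"unknown perturbation kind {self.kind!r}; expected one of {sorted(PERTURBATION_KINDS)}"
            )
        if not (math.isfinite(self.onset) and self.onset >= 0):
            raise ParameterError(f"onset must be >= 0 and finite, got {self.onset!r}")
        if self.kind != "label_switch" and not (
            math.isfinite(self.magnitude) and self.magnitude >= 0
        ):
            raise ParameterError(f"magnitude must be >= 0 and finite, got {self.magnitude!r}")


@dataclass(frozen=True)
class Scenario:
    """An ordered set of perturbations plus the times at which to sample."""

    perturbations: tuple = ()
    sampling_times: tuple = ()
    initial_condition: Optional[StateVector] = None

    def __post_init__(self) -> None:
        perts = tuple(sorted(self.perturbations, key=lambda p: p.onset))
        object.__setattr__(self, "perturbations", perts)
        times = tuple(float(t) for t in self.sampling_times)
        if any(not math.isfinite(t) or t < 0 for t in times):
            raise ParameterError("sampling_times must be non-negative and finite")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ParameterError("sampling_times must be sorted ascending")
        object.__setattr__(self, "sampling_times", times)
        n_label = sum(1 for p in perts if p.kind == "label_switch")
        if n_label > 1:
            raise ParameterError("at most one label_switch per scenario")

    @property
    def has_label_switch(self) -> bool:
        return any(p.kind == "label_switch" for p in self.perturbations)

    def with_sampling(self, times: Sequence[float]) -> "Scenario":
        return replace(self, sampling_times=tuple(times))


@dataclass(frozen=True)
class TimeCourse:
    """Noiseless trajectories of the mRNA and protein pools.

    ``protein_total`` is defined as the sum of the labeled and unlabeled
    pools, so label conservation holds by construction.
    """

    times: np.ndarray
    mrna: np.ndarray
    protein_labeled: np.ndarray
    protein_unlabeled: np.ndarray
    labeled_present: bool = False

    @property
    def protein_total(self) -> np.ndarray:
        return self.protein_labeled + self.protein_unlabeled

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "mrna": self.mrna,
                "protein_total": self.protein_total,
                "protein_labeled": self.protein_labeled,
                "protein_unlabeled": self.protein_unlabeled,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourse":
        missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"time-course table missing columns: {missing}")
        labeled = df["protein_labeled"].to_numpy(dtype=float)
        return cls(
            times=df["time_h"].to_numpy(dtype=float),
            mrna=df["mrna"].to_numpy(dtype=float),
            protein_labeled=labeled,
            protein_unlabeled=df["protein_unlabeled"].to_numpy(dtype=float),
            labeled_present=bool(np.any(labeled > 0)),
        )

    @classmethod
    def read_csv(cls, path) -> "TimeCourse":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class FoldChangeDecomposition:
    """P(t)/P0 under combined multipliers, split into its two causes.

    ``degradation_only`` is the fold change the degradation perturbation
    alone would produce (transcription held at baseline);
    ``synthesis_attributed`` is the residual factor ``total /
    degradation_only`` that must come from altered synthesis.
    """

    total: float
    degradation_only: float
    synthesis_attributed: float
    time: float

    def __float__(self) -> float:  # convenience: float(fc) == total
        return self.total


# ---------------------------------------------------------------------------
# segment-exact propagation


def _phi1(k: float, dt: float) -> float:
    """Integral of e^{-k tau} over [0, dt]."""
    if k == 0.0:
        return dt
    return -math.expm1(-k * dt) / k


def _phi2(k_m: float, k: float, dt: float) -> float:
    """Integral of e^{-k_m tau} * e^{-k (dt - tau)} over [0, dt].

    Equals (e^{-k_m dt} - e^{-k dt}) / (k - k_m) away from degeneracy,
    with limits dt * e^{-k dt} (k -> k_m) and phi1(k_m, dt) (k -> 0 is a
    special case of the generic branch, handled for exactness).
    """
    if k == 0.0:
        return _phi1(k_m, dt)
    scale = max(abs(k), abs(k_m))
    if abs(k - k_m) <= DEGENERACY_RTOL * scale:
        return dt * math.exp(-0.5 * (k + k_m) * dt)
    return (math.exp(-k_m * dt) - math.exp(-k * dt)) / (k - k_m)


def _advance_pool(
    p0: float, srate: float, m_seg0: float, m_inf: float, k_m: float, k: float, dt: float
) -> float:
    """Advance one protein pool by dt under synthesis srate * M(tau) and loss k."""
    return p0 * math.exp(-k * dt) + srate * (
        m_inf * _phi1(k, dt) + (m_seg0 - m_inf) * _phi2(k_m, k, dt)
    )


def _simulate_pools(
    params: TurnoverParams,
    perturbations: Sequence[Perturbation],
    times: Sequence[float],
    *,
    initial: Sequence[float],
    label_active: bool = False,
    labeled_degradation_multiplier: float = 1.0,
):
    """Piecewise-analytic propagation of (mRNA, labeled, unlabeled)."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ParameterError("no sampling times supplied")
    rc = rate_constants(params)
    m0_base = params.mrna_copies

    events = sorted(perturbations, key=lambda p: p.onset)
    horizon = float(t[-1])
    breakpoints = sorted({0.0, horizon} | {p.onset for p in events if p.onset <= horizon})
    for p in events:
        if p.onset > horizon:
            raise ParameterError(
                f"perturbation onset {p.onset} lies beyond the last sampling time {horizon}"
            )

    s_syn = s_txn = s_deg = 1.0
    labeled_on = bool(label_active)
    m, lab, unlab = (float(x) for x in initial)

    n = t.size
    out_m = np.empty(n)
    out_lab = np.empty(n)
    out_unlab = np.empty(n)
    idx = 0

    for j, seg_start in enumerate(breakpoints):
        for p in events:
            if p.onset == seg_start:
                if p.kind == "synthesis_multiplier":
                    s_syn = p.magnitude
                elif p.kind == "transcription_multiplier":
                    s_txn = p.magnitude
                elif p.kind == "degradation_multiplier":
                    s_deg = p.magnitude
                else:
                    labeled_on = not labeled_on
        while idx < n and t[idx] == seg_start:
            out_m[idx], out_lab[idx], out_unlab[idx] = m, lab, unlab
            idx += 1
        if j + 1 >= len(breakpoints):
            break
        seg_end = breakpoints[j + 1]

        m_inf = s_txn * m0_base
        srate = s_syn * params.translation_rate
        k_lab = rc.d * s_deg * labeled_degradation_multiplier + rc.v
        k_unlab = rc.d * s_deg + rc.v

        def state_at(dt, m=m, lab=lab, unlab=unlab):
            m_t = m_inf + (m - m_inf) * math.exp(-rc.k_m * dt)
            lab_t = _advance_pool(
                lab, srate if labeled_on else 0.0, m, m_inf, rc.k_m, k_lab, dt
            )
            unlab_t = _advance_pool(
                unlab, 0.0 if labeled_on else srate, m, m_inf, rc.k_m, k_unlab, dt
            )
            return m_t, lab_t, unlab_t

        while idx < n and seg_start < t[idx] < seg_end:
            out_m[idx], out_lab[idx], out_unlab[idx] = state_at(t[idx] - seg_start)
            idx += 1
        m, lab, unlab = state_at(seg_end - seg_start)

    return t, out_m, out_lab, out_unlab


# ---------------------------------------------------------------------------
# public operations


def simulate(
    scenario: Scenario,
    params: TurnoverParams,
    times: Optional[Sequence[float]] = None,
    *,
    labeled_degradation_multiplier: float = 1.0,
) -> TimeCourse:
    """Run a scenario from steady state (or an explicit initial condition).

    Sampling times default to ``scenario.sampling_times``; an explicit
    ``times`` argument overrides them.
    """
    sample_at = tuple(times) if times is not None else scenario.sampling_times
    if not sample_at:
        raise ParameterError("scenario has no sampling times")
    tarr = np.asarray(sample_at, dtype=float)
    if np.any(np.diff(tarr) < 0) or np.any(tarr < 0) or not np.all(np.isfinite(tarr)):
        raise ParameterError("sampling times must be sorted, non-negative and finite")

    if scenario.initial_condition is not None:
        if scenario.has_label_switch:
            raise ParameterError(
                "label_switch with an explicit non-steady initial condition is not supported"
            )
        init = (scenario.initial_condition.mrna, 0.0, scenario.initial_condition.protein)
    else:
        init = (params.mrna_copies, 0.0, steady_state(params))

    t, m, lab, unlab = _simulate_pools(
        params,
        scenario.perturbations,
        tarr,
        initial=init,
        labeled_degradation_multiplier=labeled_degradation_multiplier,
    )
    return TimeCourse(
        times=t,
        mrna=m,
        protein_labeled=lab,
        protein_unlabeled=unlab,
        labeled_present=scenario.has_label_switch,
    )


def preset(name: str, sampling_times: Sequence[float] = (), **options) -> Scenario:
    """Build one of the canonical experimental designs.

    Names and their knobs (all onsets default to 0 h):

    - ``chx_chase``: total translation block (synthesis_multiplier 0).
    - ``tet_off``: total transcription shutoff (transcription_multiplier 0).
    - ``sirna_knockdown``: transcription_multiplier ``residual_fraction``
      (default 0.2, the fraction of mRNA that survives knockdown), plus an
      optional ``translation_multiplier`` on the remaining mRNA.
    - ``degradation_inhibitor``: degradation_multiplier
      ``degradation_multiplier`` (default 0, a complete block) with an
      optional ``transcription_side_effect`` multiplier (default 1, i.e.
      none) modelling inhibitor-driven transcriptional upregulation.
    - ``chx_plus_inhibitor``: translation block plus degradation block.
    """
    onset = float(options.pop("onset", 0.0))
    perts: List[Perturbation] = []
    if name == "chx_chase":
        perts.append(Perturbation(onset, "synthesis_multiplier", 0.0))
    elif name == "tet_off":
        perts.append(Perturbation(onset, "transcription_multiplier", 0.0))
    elif name == "sirna_knockdown":
        f = float(options.pop("residual_fraction", 0.2))
        perts.append(Perturbation(onset, "transcription_multiplier", f))
        tm = options.pop("translation_multiplier", None)
        if tm is not None:
            perts.append(Perturbation(onset, "synthesis_multiplier", float(tm)))
    elif name == "degradation_inhibitor":
        g = float(options.pop("degradation_multiplier", 0.0))
        perts.append(Perturbation(onset, "degradation_multiplier", g))
        side = float(options.pop("transcription_side_effect", 1.0))
        if side != 1.0:
            perts.append(Perturbation(onset, "transcription_multiplier", side))
    elif name == "chx_plus_inhibitor":
        g = float(options.pop("degradation_multiplier", 0.0))
        perts.append(Perturbation(onset, "synthesis_multiplier", 0.0))
        perts.append(Perturbation(onset, "degradation_multiplier", g))
    else:
        raise ParameterError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    if options:
        raise ParameterError(f"unknown options for preset {name!r}: {sorted(options)}")
    return Scenario(perturbations=tuple(perts), sampling_times=tuple(sampling_times))


def pulse_chase(
    params: TurnoverParams,
    pulse_duration: float,
    chase_scenario: Scenario,
    *,
    times: Optional[Sequence[float]] = None,
    pulse_degradation_multiplier: float = 1.0,
    labeled_degradation_multiplier: float = 1.0,
) -> TimeCourse:
    """Pulse labeling of new synthesis followed by an unlabeled chase.

    During the pulse (duration hours, system otherwise at steady state)
    every newly made protein is labeled; at chase start (t = 0 of the
    returned time course) synthesis reverts to unlabeled and the chase
    scenario's perturbations apply.  ``pulse_degradation_multiplier``
    optionally scales D during the pulse, e.g. to emulate the
    starvation-induced acceleration of degradation that precedes
    radioactive labeling.
    """
    if not (math.isfinite(pulse_duration) and pulse_duration > 0):
        raise ParameterError(f"pulse_duration must be > 0, got {pulse_duration!r}")
    if chase_scenario.has_label_switch:
        raise ParameterError("label_switch inside the chase scenario: labels are set by the pulse")

    pulse_perts = []
    if pulse_degradation_multiplier != 1.0:
        pulse_perts.append(Perturbation(0.0, "degradation_multiplier", pulse_degradation_multiplier))
    _, m_end, lab_end, unlab_end = _simulate_pools(
        params,
        pulse_perts,
        [pulse_duration],
        initial=(params.mrna_copies, 0.0, steady_state(params)),
        label_active=True,
        labeled_degradation_multiplier=labeled_degradation_multiplier,
    )

    sample_at = tuple(times) if times is not None else chase_scenario.sampling_times
    if not sample_at:
        raise ParameterError("chase scenario has no sampling times")
    t, m, lab, unlab = _simulate_pools(
        params,
        chase_scenario.perturbations,
        sample_at,
        initial=(m_end[-1], lab_end[-1], unlab_end[-1]),
        label_active=False,
        labeled_degradation_multiplier=labeled_degradation_multiplier,
    )
    return TimeCourse(times=t, mrna=m, protein_labeled=lab, protein_unlabeled=unlab, labeled_present=True)


def silac_switch(params: TurnoverParams, times: Sequence[float]) -> TimeCourse:
    """Heavy-medium switch at t = 0 with the cell otherwise unperturbed.

    All pre-existing protein is light (unlabeled); all new synthesis is
    heavy (labeled).  The total stays at P0 while the light pool decays as
    exp(-k_P t) and the heavy pool fills in its complement — turnover read
    out at steady state.
    """
    t, m, lab, unlab = _simulate_pools(
        params,
        [],
        times,
        initial=(params.mrna_copies, 0.0, steady_state(params)),
        label_active=True,
    )
    return TimeCourse(times=t, mrna=m, protein_labeled=lab, protein_unlabeled=unlab, labeled_present=True)


def predict_fold_change(
    params: TurnoverParams,
    degradation_multiplier: float,
    transcription_multiplier: float,
    t: float,
) -> FoldChangeDecomposition:
    """Fold change P(t)/P0 under a degradation and/or transcription step.

    Starting from steady state, apply both multipliers at t = 0 and
    evaluate the relative abundance at ``t`` hours.  The decomposition
    separates what a pure degradation block could deliver (for a protein
    of half-life t_p it is bounded by ~1 + t * ln2 / t_p at short times)
    from the synthesis-side factor needed to explain the rest — e.g. a
    3-fold rise of a 40 h half-life protein within 8 h cannot come from
    blocked degradation alone.
    """
    for nm, val in (
        ("degradation_multiplier", degradation_multiplier),
        ("transcription_multiplier", transcription_multiplier),
    ):
        if not (math.isfinite(val) and val >= 0):
            raise ParameterError(f"{nm} must be >= 0 and finite, got {val!r}")
    if not (math.isfinite(t) and t >= 0):
        raise ParameterError(f"t must be >= 0 and finite, got {t!r}")

    p0 = steady_state(params)
    if p0 <= 0:
        raise ParameterError("steady-state abundance is zero; fold change undefined")

    def run(deg: float, txn: float) -> float:
        perts = [
            Perturbation(0.0, "degradation_multiplier", deg),
            Perturbation(0.0, "transcription_multiplier", txn),
        ]
        _, _, lab, unlab = _simulate_pools(
            params, perts, [t], initial=(params.mrna_copies, 0.0, p0)
        )
        return float((lab[-1] + unlab[-1]) / p0)

    total = run(degradation_multiplier, transcription_multiplier)
    deg_only = run(degradation_multiplier, 1.0)
    return FoldChangeDecomposition(
        total=total,
        degradation_only=deg_only,
        synthesis_attributed=total / deg_only if deg_only > 0 else float("nan"),
        time=float(t),
    )
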