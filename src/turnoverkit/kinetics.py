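"""Deterministic turnover kinetics of a single protein species.

The model tracks one mRNA pool and one protein pool per average cell:

    dM/dt = T(t) - k_M * M(t)
    dP/dt = R(t) * M(t) - (D(t) + V) * P(t)

where ``T`` is the transcription rate (mRNA molecules per hour), ``k_M``
the effective mRNA decay rate (chemical decay plus any dilution the user
folded into the measured mRNA half-life), ``R`` the translation rate
(protein molecules per mRNA per hour), ``D`` the first-order protein
degradation rate and ``V = ln2 / doubling_time`` the dilution rate from
cell growth (zero for non-dividing cells).

All half-lives and doubling times are in hours; rate constants in per
hour, converted via ``ln 2``.  The protein half-life supplied by the user
is the *degradation-only* half-life (``ln2 / D``); the effective removal
half-life ``ln2 / (D + V)`` is derived and reported alongside wherever an
estimate is produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

LN2 = math.log(2.0)

#: Relative tolerance below which the two-exponential transcription-shutoff
#: solution switches to its degenerate limit (k_M -> k_P).  The two-term form
#: suffers catastrophic cancellation when the rates coincide.
DEGENERACY_RTOL = 1e-9

__all__ = [
    "LN2",
    "ParameterError",
    "TurnoverParams",
    "RateConstants",
    "StateVector",
    "rate_constants",
    "steady_state",
    "solve_synthesis_block",
    "solve_transcription_shutoff",
]


class ParameterError(ValueError):
    """A turnover parameter violates its domain constraints."""


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise ParameterError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class TurnoverParams:
    """The five quantities that pin down one protein's turnover state.

    Parameters
    ----------
    mrna_copies
        Steady-state mRNA copy number per cell (M0).  May be zero.
    translation_rate
        Protein molecules produced per mRNA per hour (R).  May be zero.
    mrna_half_life
        Effective mRNA half-life in hours (chemical decay plus dilution as
        measured in a decay experiment); strictly positive.
    protein_half_life
        Degradation-only protein half-life in hours (``ln2 / D``);
        strictly positive.
    doubling_time
        Cell doubling time in hours, or ``None`` for non-dividing cells
        (dilution rate V = 0).
    """

    mrna_copies: float
    translation_rate: float
    mrna_half_life: float
    protein_half_life: float
    doubling_time: Union[float, None] = None

    def __post_init__(self) -> None:
        _require_nonnegative("mrna_copies", self.mrna_copies)
        _require_nonnegative("translation_rate", self.translation_rate)
        _require_positive("mrna_half_life", self.mrna_half_life)
        _require_positive("protein_half_life", self.protein_half_life)
        if self.doubling_time is not None:
            _require_positive("doubling_time", self.doubling_time)

    @property
    def dividing(self) -> bool:
        return self.doubling_time is not None


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants derived from :class:`TurnoverParams`.

    ``k_m`` is the mRNA decay rate, ``d`` the protein degradation rate,
    ``v`` the growth-dilution rate; the total protein removal rate
    ``k_p = d + v`` is exposed as a property so the identity holds exactly.
    All units are per hour.
    """

    k_m: float
    d: float
    v: float

    @property
    def k_p(self) -> float:
        return self.d + self.v

    @property
    def effective_half_life(self) -> float:
        """ln2 / (D + V): time for half the pool to be removed by any route."""
        return LN2 / self.k_p


@dataclass(frozen=True)
class StateVector:
    """A (mRNA, protein) state at one time point; copies/molecules per cell."""

    mrna: float
    protein: float
    time: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative("mrna", self.mrna)
        _require_nonnegative("protein", self.protein)
        if not math.isfinite(self.time):
            raise ParameterError(f"time must be finite, got {self.time!r}")


def rate_constants(params: TurnoverParams) -> RateConstants:
    """Convert half-lives and doubling time to per-hour rate constants."""
    v = 0.0 if params.doubling_time is None else LN2 / params.doubling_time
    return RateConstants(
        k_m=LN2 / params.mrna_half_life,
        d=LN2 / params.protein_half_life,
        v=v,
    )


def steady_state(params: TurnoverParams) -> float:
    """Steady-state protein abundance P0 = M0 * R / (D + V), molecules/cell."""
    rc = rate_constants(params)
    if rc.k_p <= 0:
        raise ParameterError("no removal process: D + V must be positive for a steady state")
    return params.mrna_copies * params.translation_rate / rc.k_p


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ParameterError("times must be non-negative and finite")
    return t


def solve_synthesis_block(params: TurnoverParams, t) -> np.ndarray:
    """Relative protein abundance P(t)/P0 after a total translation block.

    A saturating dose of a translation inhibitor (cycloheximide, emetine,
    anisomycin) sets R to zero at t = 0 with the system at steady state,
    leaving pure first-order removal: P(t)/P0 = exp(-k_P t).  This is the
    idealised chase curve whose log-slope is the effective removal rate.
    """
    t = _check_times(t)
    rc = rate_constants(params)
    return np.exp(-rc.k_p * t)


def solve_transcription_shutoff(params: TurnoverParams, t) -> np.ndarray:
    """Relative protein abundance P(t)/P0 after a total transcription shutoff.

    Models a Tet-off style experiment: transcription stops at t = 0, the
    mRNA decays as M0 exp(-k_M t), and the protein relaxes as the
    two-exponential

        P(t)/P0 = [k_P exp(-k_M t) - k_M exp(-k_P t)] / (k_P - k_M),

    or its degenerate limit (1 + k t) exp(-k t) when k_M ~= k_P.  The
    decline is always slower than exp(-k_P t): the decaying mRNA keeps
    feeding synthesis, which is exactly why an "apparent" half-life read
    off such a curve overestimates the true effective half-life.
    """
    t = _check_times(t)
    rc = rate_constants(params)
    return two_exponential_decay(rc.k_m, rc.k_p, t)


def two_exponential_decay(k_m: float, k_p: float, t) -> np.ndarray:
    """Evaluate [k_p e^(-k_m t) - k_m e^(-k_p t)]/(k_p - k_m) with its limit."""
    t = np.asarray(t, dtype=float)
    scale = max(abs(k_p), abs(k_m))
    if scale == 0.0:
        return np.ones_like(t)
    if abs(k_p - k_m) <= DEGENERACY_RTOL * scale:
        k = 0.5 * (k_p + k_m)
        return (1.0 + k * t) * np.exp(-k * t)
    return (k_p * np.exp(-k_m * t) - k_m * np.exp(-k_p * t)) / (k_p - k_m)
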