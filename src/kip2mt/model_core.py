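"""Closed-form relations of the antenna / positive-feedback model.

These are the deterministic identities that the stochastic machinery in
:mod:`kip2mt.simulate` must reproduce on average, and that the analysis
pipeline in :mod:`kip2mt.analysis` uses to convert estimated rates into
derived quantities (mean excursion distances, expected lengths, tubulin
on-rates).
"""

from __future__ import annotations

import numpy as np

from .params import (
    DIMERS_PER_UM,
    CouplingParams,
    DynamicsParams,
    MotorParams,
    UNBOUNDED,
    Unbounded,
)

__all__ = [
    "expected_length",
    "catastrophe_distance",
    "rescue_distance",
    "growth_rate_vs_length",
    "catastrophe_freq_vs_length",
    "antenna_end_flux",
    "kon_from_slope",
    "slope_from_kon",
]


def expected_length(d: DynamicsParams, t):
    """Expected length at time ``t`` (min) of a filament that grows at v+,
    catastrophes at rate f+-, and instantly resets to zero and regrows.

    Rescues and the finite shrinkage time are ignored, so the length is
    v+ times the age of a Poisson renewal process::

        E[L(t)] = (v+ / f+-) * (1 - exp(-t * f+-))

    with the f+- -> 0 limit v+ * t.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    f = d.catastrophe_freq
    if f == 0:
        out = d.growth_rate * t
    else:
        out = (d.growth_rate / f) * -np.expm1(-f * t)
    return out.item() if out.ndim == 0 else out


def catastrophe_distance(d: DynamicsParams) -> float | Unbounded:
    """Mean distance grown before a catastrophe: v+ / f+-.

    With f+- = 0 the excursion never terminates; returns the tagged
    :data:`~kip2mt.params.UNBOUNDED` value rather than infinity.
    """
    if d.catastrophe_freq == 0:
        return UNBOUNDED
    return d.growth_rate / d.catastrophe_freq


def rescue_distance(d: DynamicsParams) -> float | Unbounded:
    """Mean distance shrunk before a rescue: v- / f-+ (unbounded at f-+ = 0)."""
    if d.rescue_freq == 0:
        return UNBOUNDED
    return d.shrink_rate / d.rescue_freq


def _check_Lc(L, c):
    L = np.asarray(L, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(L < 0) or np.any(c < 0):
        raise ValueError("length and concentration must be >= 0")
    return L, c


def growth_rate_vs_length(L, c, p: CouplingParams = CouplingParams()):
    """Length- and concentration-dependent growth rate (um/min).

    v(L, c) = v0 + (vmax - v0) * cL / (A + cL).  Depends on (L, c) only
    through the antenna load cL; rises monotonically from v0 (no motor)
    and saturates at vmax.
    """
    L, c = _check_Lc(L, c)
    x = c * L
    out = p.v0 + (p.vmax - p.v0) * x / (p.A + x)
    return out.item() if out.ndim == 0 else out


def catastrophe_freq_vs_length(L, c, p: CouplingParams = CouplingParams()):
    """Length- and concentration-dependent catastrophe frequency (1/min).

    Mirrors the growth law downward: f(L, c) = f0 - (f0 - fmin) * cL/(A + cL).
    The saturating form is this package's model choice; the measurements
    establish the direction (catastrophe decreases with length in the
    presence of motors) and the two endpoints f0 and fmin.
    """
    L, c = _check_Lc(L, c)
    x = c * L
    out = p.f0 - (p.f0 - p.fmin) * x / (p.A + x)
    return out.item() if out.ndim == 0 else out


def antenna_end_flux(L, c, m: MotorParams = MotorParams()):
    """Steady-state arrival rate of motors at the plus end (motors/min).

    Motors land uniformly along a filament of length L at rate
    landing_rate * c per um, walk toward the plus end, and survive the
    trip from landing point x with probability exp(-(L - x)/run_length).
    Integrating over the lattice::

        J(L) = landing_rate * c * run_length * (1 - exp(-L/run_length))

    Linear in L for L << run_length (every landed motor arrives), and
    saturating at landing_rate * c * run_length for long filaments: the
    antenna regime and its processivity-limited ceiling.
    """
    L, c = _check_Lc(L, c)
    lam = m.run_length
    out = m.landing_rate * c * lam * -np.expm1(-L / lam)
    return out.item() if out.ndim == 0 else out


def kon_from_slope(slope: float, dimers_per_um: float = DIMERS_PER_UM) -> float:
    """Convert a growth-rate-vs-tubulin slope (um/min per uM) into a
    second-order association rate constant (1/uM/s)."""
    if not dimers_per_um > 0:
        raise ValueError("dimers_per_um must be > 0")
    return slope * dimers_per_um / 60.0


def slope_from_kon(kon: float, dimers_per_um: float = DIMERS_PER_UM) -> float:
    """Inverse of :func:`kon_from_slope`."""
    if not dimers_per_um > 0:
        raise ValueError("dimers_per_um must be > 0")
    return kon * 60.0 / dimers_per_um
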