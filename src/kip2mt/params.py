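"""Parameter containers for microtubule dynamic instability and Kip2 motor traffic.

Unit conventions
----------------
Lengths are micrometres and times are minutes throughout the package
internals.  The two motor dwell parameters (`end_residence`, `bleach_time`)
are specified in seconds, matching how such dwell times are reported in
single-molecule work; the simulators convert at the boundary.  Fields carry
their unit in the docstring rather than in the name, except where the unit
is seconds (noted explicitly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "DynamicsParams",
    "MotorParams",
    "CouplingParams",
    "TubulinKinetics",
    "Unbounded",
    "UNBOUNDED",
    "DIMERS_PER_UM",
]

#: Tubulin dimers per micrometre of microtubule: 13 protofilaments times
#: 125 dimers/um (8 nm axial rise per dimer).  Standard lattice geometry,
#: needed to convert growth-rate slopes (um/min per uM) into per-dimer
#: association rate constants (1/uM/s).
DIMERS_PER_UM = 1625.0


class Unbounded:
    """Tagged 'unbounded' value for mean excursion distances when the
    terminating event never occurs (frequency = 0).

    Distinct from float('inf') so that downstream code cannot confuse a
    genuinely unbounded quantity with a numerical overflow.  Converts to
    ``inf`` when coerced to float and prints as ``---`` in tables.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __float__(self) -> float:
        return math.inf

    def __repr__(self) -> str:
        return "unbounded"

    def __str__(self) -> str:
        return "---"


UNBOUNDED = Unbounded()


def _check_nonneg(obj, *names):
    for name in names:
        v = getattr(obj, name)
        if v is None:
            continue
        if not (v >= 0):
            raise ValueError(f"{type(obj).__name__}.{name} must be >= 0, got {v!r}")


def _check_pos(obj, *names):
    for name in names:
        v = getattr(obj, name)
        if v is None:
            continue
        if not (v > 0):
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class DynamicsParams:
    """The four dynamic-instability rates of one assay condition.

    Parameters
    ----------
    growth_rate : float
        Plus-end growth speed v+ (um/min).
    catastrophe_freq : float
        Growth->shrinkage switching frequency f+- (1/min).  Zero encodes
        the "catastrophes essentially never observed" regime.
    shrink_rate : float
        Shrinkage speed v- reported as a positive magnitude (um/min).
    rescue_freq : float
        Shrinkage->growth switching frequency (1/min).
    """

    growth_rate: float
    catastrophe_freq: float = 0.0
    shrink_rate: float = 0.0
    rescue_freq: float = 0.0

    def __post_init__(self):
        _check_nonneg(self, "growth_rate", "catastrophe_freq", "shrink_rate", "rescue_freq")


@dataclass(frozen=True)
class MotorParams:
    """Kip2 motor behaviour on and at the end of a microtubule.

    Defaults are the single-molecule numbers measured for Kip2-eGFP:
    lattice velocity 5.0 +/- 0.9 um/min, mean run length 4.1 um, plus-end
    residence ~30 s, photobleaching time constant 249 s, and an end pool
    that accommodates up to 12 motors.  On dynamic (GTP-tubulin) lattices
    the motor moves slower (2.1 um/min) but still faster than growth, so
    it reaches and tracks the plus end.

    `landing_rate` (per um of lattice, per nM motor, per minute) is not
    directly measured; the default 0.6 is calibrated so that the
    steady-state antenna occupancy ~ end_capacity * cL/(A + cL) reproduces
    the saturation constant A = 39.8 um*nM of the length-dependent growth
    law with the measured 30 s end residence (see docs/methods.md).
    """

    landing_rate: float = 0.6      # 1/(um * nM * min)
    velocity_lattice: float = 5.0  # um/min, stabilized lattice
    velocity_dynamic: float = 2.1  # um/min, dynamic lattice
    velocity_sd: float = 0.9       # um/min, between-molecule spread
    run_length: float = 4.1        # um, mean distance before detaching
    end_residence: float = 30.0    # s, mean plus-end dwell
    bleach_time: float = 249.0     # s, mean time to photobleach
    end_capacity: int = 12         # max motors in the plus-end pool

    def __post_init__(self):
        _check_pos(self, "landing_rate", "velocity_lattice", "velocity_dynamic",
                   "run_length", "end_residence", "bleach_time")
        _check_nonneg(self, "velocity_sd")
        if self.end_capacity < 1:
            raise ValueError("end_capacity must be >= 1")
        if self.velocity_dynamic > self.velocity_lattice:
            raise ValueError("velocity_dynamic must not exceed velocity_lattice")

    @property
    def detach_rate(self) -> float:
        """Lattice detachment rate (1/min) implied by exponential run lengths."""
        return self.velocity_dynamic / self.run_length

    @property
    def end_release_rate(self) -> float:
        """Plus-end release rate (1/min)."""
        return 60.0 / self.end_residence

    @property
    def bleach_rate(self) -> float:
        """Photobleaching rate (1/min)."""
        return 60.0 / self.bleach_time


@dataclass(frozen=True)
class CouplingParams:
    """How plus-end motor occupancy maps onto growth and catastrophe.

    The growth law is v(L, c) = v0 + (vmax - v0) * cL / (A + cL): growth
    accelerates from the motor-free rate v0 toward vmax as the product of
    motor concentration c (nM) and filament length L (um) saturates the
    plus end, with half-saturation at cL = A (um*nM).  Catastrophe mirrors
    it downward, f(L, c) = f0 - (f0 - fmin) * cL / (A + cL).

    Defaults are the porcine-tubulin values: v0 = 0.294, vmax = 1.03
    um/min, A = 39.8 um*nM from the length-binned growth fit; f0 = 0.166
    and fmin = 0.004 1/min are the motor-free and high-motor endpoints of
    the measured catastrophe frequencies.
    """

    v0: float = 0.294   # um/min
    vmax: float = 1.03  # um/min
    A: float = 39.8     # um*nM
    f0: float = 0.166   # 1/min
    fmin: float = 0.004  # 1/min

    def __post_init__(self):
        if not (self.vmax >= self.v0 >= 0):
            raise ValueError("need vmax >= v0 >= 0")
        if not (self.f0 >= self.fmin >= 0):
            raise ValueError("need f0 >= fmin >= 0")
        _check_pos(self, "A")


@dataclass(frozen=True)
class TubulinKinetics:
    """Tubulin association kinetics at the plus end.

    kon is the second-order association rate constant (1/uM/s) for free
    GTP-tubulin dimers; `intercept` is the extrapolated growth rate at
    zero tubulin (1/s, dimer units); `dimers_per_um` converts between
    filament-length and dimer-count bookkeeping.
    """

    kon: float
    intercept: float = 0.0
    kon_se: float = float("nan")
    intercept_se: float = float("nan")
    dimers_per_um: float = DIMERS_PER_UM
    intercept_consistent_with_zero: bool | None = None

    def __post_init__(self):
        _check_pos(self, "dimers_per_um")
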