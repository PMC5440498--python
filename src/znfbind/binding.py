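"""Closed-form two-state binding kinetics and equilibrium expressions.

The package models protein-DNA binding as a reversible bimolecular reaction

    P + D  <-- k_on / k_off -->  PD

with association rate constant ``k_on`` (M^-1 s^-1) and dissociation rate
constant ``k_off`` (s^-1).  Under pseudo-first-order conditions (protein in
large excess over sensor-bound DNA) the approach to equilibrium is a single
exponential with observed rate ``k_obs = c * k_on + k_off``, where ``c`` is
the protein concentration.  Everything downstream -- trace fitting, titration
isotherms, competition simulation -- consumes the expressions defined here.

Units are strict: concentrations in molar, times in seconds.  Reporting
helpers convert to the conventional nanomolar / hour scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NM",
    "RateConstants",
    "ExponentialCurve",
    "KineticSummary",
    "EquilibriumState",
    "observed_rate",
    "equilibrium_constant",
    "propagate_kd_error",
    "dissociation_halftime",
    "equilibration_halftime",
    "association_curve",
    "dissociation_curve",
    "fraction_bound_simple",
    "fraction_bound_depletion",
    "NO_DISSOCIATION",
]

#: one nanomolar, in molar
NM = 1e-9

#: sentinel returned by :func:`dissociation_halftime` when ``k_off == 0``
#: (an irreversible complex never reaches its half-life)
NO_DISSOCIATION = math.inf


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameter pair of the two-state binding reaction.

    Parameters
    ----------
    k_on : float
        Association rate constant, M^-1 s^-1.  Must be positive.
    k_off : float
        Dissociation rate constant, s^-1.  Non-negative; zero encodes an
        irreversible control.
    dk_on, dk_off : float, optional
        Standard errors of the rate constants, same units, default 0.
    """

    k_on: float
    k_off: float
    dk_on: float = 0.0
    dk_off: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on!r}")
        if self.k_off < 0:
            raise ValueError(f"k_off must be >= 0, got {self.k_off!r}")
        if self.dk_on < 0 or self.dk_off < 0:
            raise ValueError("standard errors must be >= 0")

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant k_off/k_on, molar."""
        return equilibrium_constant(self)

    def summary(self) -> "KineticSummary":
        return KineticSummary.from_rates(self)


@dataclass(frozen=True)
class ExponentialCurve:
    """Parameters of one exponential trace ``y = y0 + A*exp(-rate*(t-x0))``.

    ``y0`` is the asymptotic offset, ``A`` the amplitude (signed: negative
    for traces recovering upward), ``x0`` the time offset.  Dissociation
    curves carry an explicit time constant ``tau`` with ``k_off = 1/tau``;
    association curves leave ``tau`` as None because their decay rate is the
    concentration-dependent observed rate.
    """

    y0: float
    A: float
    x0: float = 0.0
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.tau is not None and not self.tau > 0:
            raise ValueError(f"tau must be > 0 where present, got {self.tau!r}")


@dataclass(frozen=True)
class KineticSummary:
    """Derived quantities of a kinetic measurement.

    ``K_D = k_off/k_on`` and ``t_half_off = ln2/k_off`` hold by construction
    (use :meth:`from_rates`); ``dK_D`` follows Gaussian error propagation.
    """

    rates: RateConstants
    K_D: float
    dK_D: float
    t_half_off: float

    @classmethod
    def from_rates(cls, rates: RateConstants) -> "KineticSummary":
        return cls(
            rates=rates,
            K_D=equilibrium_constant(rates),
            dK_D=propagate_kd_error(rates),
            t_half_off=dissociation_halftime(rates),
        )

    @property
    def K_D_nM(self) -> float:
        return self.K_D / NM

    @property
    def dK_D_nM(self) -> float:
        return self.dK_D / NM

    @property
    def t_half_off_hours(self) -> float:
        return self.t_half_off / 3600.0

    def __str__(self) -> str:
        r = self.rates
        return (
            f"k_on  = {r.k_on:.4g} +/- {r.dk_on:.2g} M^-1 s^-1\n"
            f"k_off = {r.k_off:.4g} +/- {r.dk_off:.2g} s^-1\n"
            f"K_D   = {self.K_D_nM:.4g} +/- {self.dK_D_nM:.2g} nM\n"
            f"t_1/2(off) = {self.t_half_off_hours:.4g} h"
        )


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium composition of a receptor/labeled-ligand mixture.

    ``fraction_bound`` is the percentage of the labeled DNA in complex,
    C / L_total * 100, i.e. what an EMSA band ratio reports.
    """

    R_total: float
    L_total: float
    C: float
    fraction_bound: float = field(default=0.0)

    def __post_init__(self) -> None:
        upper = min(self.R_total, self.L_total)
        # small numerical slack for solver round-off
        if self.C < -1e-15 or self.C > upper * (1 + 1e-9) + 1e-30:
            raise ValueError(
                f"complex concentration {self.C} outside [0, min(R, L)={upper}]"
            )


def observed_rate(c: float, rates: RateConstants) -> float:
    """Pseudo-first-order observed rate ``c*k_on + k_off`` (s^-1).

    ``c`` is the free protein concentration in molar; strictly increasing
    in ``c`` and equal to ``k_off`` at c=0.
    """
    if np.any(np.asarray(c) < 0):
        raise ValueError(f"concentration must be >= 0, got {c!r}")
    return c * rates.k_on + rates.k_off


def equilibrium_constant(rates: RateConstants) -> float:
    """Equilibrium dissociation constant ``K_D = k_off/k_on`` in molar."""
    return rates.k_off / rates.k_on


def propagate_kd_error(rates: RateConstants) -> float:
    """Standard error of K_D by Gaussian error propagation.

    dK_D = sqrt( (dk_off/k_on)^2 + (k_off*dk_on/k_on^2)^2 )
    """
    term_off = rates.dk_off / rates.k_on
    term_on = rates.k_off * rates.dk_on / rates.k_on**2
    return math.hypot(term_off, term_on)


def dissociation_halftime(rates: RateConstants) -> float:
    """Complex half-life ``t_1/2(off) = ln2 / k_off`` in seconds.

    Returns the :data:`NO_DISSOCIATION` sentinel (inf) for ``k_off == 0``
    so irreversible controls can flow through simulators unharmed.
    """
    if rates.k_off == 0:
        return NO_DISSOCIATION
    return math.log(2.0) / rates.k_off


def equilibration_halftime(c: float, rates: RateConstants) -> float:
    """Time to half-maximal complex, ``ln2 / (c*k_on + k_off)``, seconds.

    Reduces to :func:`dissociation_halftime` at c=0.  Used to choose
    incubation times (about 10x this halftime guarantees equilibrium).
    """
    k = observed_rate(c, rates)
    if k <= 0:
        raise ValueError("observed rate is zero; equilibration never completes")
    return math.log(2.0) / k


def association_curve(
    t: np.ndarray | float,
    c: float,
    rates: RateConstants,
    curve: ExponentialCurve,
) -> np.ndarray | float:
    """Association-phase response ``y0 + A*exp(-(t-x0)*(c*k_on + k_off))``."""
    k = observed_rate(c, rates)
    return curve.y0 + curve.A * np.exp(-(np.asarray(t, dtype=float) - curve.x0) * k)


def dissociation_curve(
    t: np.ndarray | float, curve: ExponentialCurve
) -> np.ndarray | float:
    """Dissociation-phase response ``y0 + A*exp(-(t-x0)/tau)``, k_off = 1/tau."""
    if curve.tau is None or curve.tau <= 0:
        raise ValueError("dissociation curve requires tau > 0")
    return curve.y0 + curve.A * np.exp(
        -(np.asarray(t, dtype=float) - curve.x0) / curve.tau
    )


def fraction_bound_simple(R: float, K_D: float) -> float:
    """Percent of trace ligand bound: ``100*R/(R+K_D)``.

    Valid when the labeled-DNA concentration is negligible against K_D,
    so receptor depletion by the complex can be ignored.  At R = K_D this
    is exactly 50%.
    """
    if K_D <= 0:
        raise ValueError(f"K_D must be > 0, got {K_D!r}")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("receptor concentration must be >= 0")
    out = 100.0 * R / (R + K_D)
    return float(out) if out.ndim == 0 else out


def fraction_bound_depletion(
    R_total: float, L_total: float, K_D: float
) -> EquilibriumState:
    """Solution binding isotherm with ligand depletion.

    Solves the mass-action equilibrium for total concentrations, i.e. the
    physically valid (minus) root of

        C^2 - (R + L + K_D) C + R L = 0,

    evaluated in the cancellation-free form ``C = 2RL / (S + sqrt(S^2-4RL))``
    with ``S = R + L + K_D``.  Reduces to :func:`fraction_bound_simple` as
    L -> 0 and to ``C = min(R, L)`` at K_D = 0.
    """
    if R_total < 0:
        raise ValueError("R_total must be >= 0")
    if not L_total > 0:
        raise ValueError("L_total must be > 0")
    if K_D < 0:
        raise ValueError("K_D must be >= 0")
    S = R_total + L_total + K_D
    disc = S * S - 4.0 * R_total * L_total
    if disc < 0:  # impossible for valid inputs; guards round-off pathologies
        raise ArithmeticError("negative discriminant in binding quadratic")
    denom = S + math.sqrt(disc)
    C = 0.0 if denom == 0 else 2.0 * R_total * L_total / denom
    C = min(C, R_total, L_total)
    return EquilibriumState(
        R_total=R_total,
        L_total=L_total,
        C=C,
        fraction_bound=100.0 * C / L_total,
    )
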