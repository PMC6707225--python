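"""Closed-form kinetics of the conformational-selection binding scheme.

The free protease pre-exists in two conformations — closed (E*, active site
inaccessible) and open (E, binding competent) — that interconvert with
first-order rates ``k12`` (E* -> E) and ``k21`` (E -> E*).  Ligand binds
only the open form with second-order rate ``kon`` and dissociates with
``koff``::

    E*  <-- k12/k21 -->  E  + L  <-- kon[L]/koff -->  E:L

Under pseudo-first-order conditions (ligand in excess over protein) the
return to equilibrium after mixing is bi-exponential.  This module provides
the two relaxation rates and their asymptotes, the rigid lock-and-key limit,
Arrhenius temperature scaling of the rate constants, fold-change comparison
with unit normalisation, and the derived allosteric quantities: the
interconversion time scale tau = 1/(k12 + k21) and the E*:E population
ratio k21/k12.

Units follow the stopped-flow convention: first-order rates in s^-1,
second-order rates in uM^-1 s^-1, activation energies in kcal/mol with the
gas constant in cal mol^-1 K^-1, temperatures in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GAS_CONSTANT_CAL",
    "T_REF_K",
    "RateConstants",
    "RelaxationPair",
    "ArrheniusParameterSet",
    "DerivedQuantities",
    "Asymptotes",
    "cs_relaxations",
    "cs_slow_relaxation",
    "lock_and_key_relaxation",
    "arrhenius_rate",
    "derived_quantities",
    "asymptotes",
    "fold_change",
    "format_population_ratio",
]

#: Gas constant in cal mol^-1 K^-1 (activation energies are in kcal/mol).
GAS_CONSTANT_CAL = 1.987

#: Default reference temperature, 15 degC, at which rate constants are quoted.
T_REF_K = 288.15

# Second-order rate units accepted by fold_change.
_SECOND_ORDER_UNITS = {"uM-1s-1": 1.0, "M-1s-1": 1e-6}
_FIRST_ORDER_UNITS = {"s-1": 1.0}


def _require_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """The four rate parameters of the conformational-selection scheme.

    Attributes
    ----------
    k12 : float
        Opening rate E* -> E, s^-1.
    k21 : float
        Closing rate E -> E*, s^-1.
    kon : float
        Second-order association rate to the open form, uM^-1 s^-1.
    koff : float
        Dissociation rate of the complex, s^-1 (0 for irreversible ligands).
    """

    k12: float
    k21: float
    kon: float
    koff: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative(k12=self.k12, k21=self.k21, kon=self.kon, koff=self.koff)

    @property
    def exchange_rate(self) -> float:
        """Total conformational exchange rate k12 + k21, s^-1."""
        return self.k12 + self.k21

    @property
    def fraction_open(self) -> float:
        """Equilibrium fraction of free protein in the open E form."""
        if self.exchange_rate == 0:
            raise ValueError("fraction_open undefined when k12 + k21 == 0")
        return self.k12 / self.exchange_rate


@dataclass(frozen=True)
class RelaxationPair:
    """Fast (alpha1) and slow (alpha2) relaxation rates, s^-1."""

    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        if not (self.alpha1 >= self.alpha2 >= 0):
            raise ValueError(
                f"relaxations must satisfy alpha1 >= alpha2 >= 0, "
                f"got ({self.alpha1!r}, {self.alpha2!r})"
            )


@dataclass(frozen=True)
class Asymptotes:
    """Limiting behaviour of the slow relaxation alpha2([L])."""

    alpha2_at_zero: float
    alpha2_at_infinity: float
    direction: Literal["increasing", "decreasing", "flat"]


@dataclass(frozen=True)
class DerivedQuantities:
    """Allosteric quantities derived from the conformational exchange rates."""

    tau_ms: float
    ratio_estar_to_e: float  # k21/k12; NaN when k12 == 0
    fraction_open: float
    ratio_label: str = field(default="", compare=False)


def cs_relaxations(rc: RateConstants, ligand: float) -> RelaxationPair:
    """Both relaxation rates of the scheme at ligand concentration ``ligand`` (uM).

    The rates are the two roots of

        2*alpha = k12 + k21 + kon[L] + koff
                  +/- sqrt((kon[L] + koff - k12 - k21)^2 + 4*k21*kon[L])

    evaluated in the cancellation-safe form: the fast root alpha1 takes the
    plus sign and the slow root follows from the product identity
    alpha1*alpha2 = koff*(k12 + k21) + k12*kon[L].
    """
    if not math.isfinite(ligand) or ligand < 0:
        raise ValueError(f"ligand concentration must be finite and >= 0, got {ligand!r}")
    x = rc.kon * ligand
    s = rc.k12 + rc.k21 + x + rc.koff
    disc = math.sqrt((x + rc.koff - rc.k12 - rc.k21) ** 2 + 4.0 * rc.k21 * x)
    alpha1 = 0.5 * (s + disc)
    product = rc.koff * (rc.k12 + rc.k21) + rc.k12 * x
    alpha2 = product / alpha1 if alpha1 > 0 else 0.0
    return RelaxationPair(alpha1, alpha2)


def cs_slow_relaxation(
    ligand: np.ndarray | float,
    k12: float,
    k21: float,
    kon: float,
    koff: float = 0.0,
) -> np.ndarray:
    """Vectorised slow relaxation alpha2([L]); the fitting model for titrations."""
    x = kon * np.asarray(ligand, dtype=float)
    s = k12 + k21 + x + koff
    disc = np.sqrt((x + koff - k12 - k21) ** 2 + 4.0 * k21 * x)
    alpha1 = 0.5 * (s + disc)
    product = koff * (k12 + k21) + k12 * x
    return np.divide(product, alpha1, out=np.zeros_like(alpha1), where=alpha1 > 0)


def lock_and_key_relaxation(kon: float, koff: float, ligand: float) -> float:
    """Single relaxation of rigid-body binding: alpha = koff + kon*[L]."""
    _require_nonnegative(kon=kon, koff=koff, ligand=ligand)
    return koff + kon * ligand


def arrhenius_rate(
    k0: float,
    Ea: float,
    T: float,
    T0: float = T_REF_K,
    R: float = GAS_CONSTANT_CAL,
) -> float:
    """Rate constant at temperature ``T`` from its value ``k0`` at ``T0``.

    k(T) = k0 * exp(-(Ea/R) * (1/T - 1/T0)), with ``Ea`` in kcal/mol and
    ``R`` in cal mol^-1 K^-1 (the factor 1000 reconciles the units).
    At T == T0 the exponent vanishes and k0 is returned exactly.
    """
    if T <= 0 or T0 <= 0:
        raise ValueError(f"temperatures must be positive, got T={T!r}, T0={T0!r}")
    if k0 < 0:
        raise ValueError(f"k0 must be >= 0, got {k0!r}")
    return k0 * math.exp(-(Ea * 1000.0 / R) * (1.0 / T - 1.0 / T0))


@dataclass(frozen=True)
class ArrheniusParameterSet:
    """Arrhenius law (k0 at T0, activation energy Ea) for each rate constant.

    Each of ``k12``, ``k21``, ``kon``, ``koff`` is a ``(k0, Ea)`` pair with
    k0 in the rate constant's own units and Ea in kcal/mol.
    """

    k12: tuple[float, float]
    k21: tuple[float, float]
    kon: tuple[float, float]
    koff: tuple[float, float] = (0.0, 0.0)
    T0: float = T_REF_K
    R: float = GAS_CONSTANT_CAL

    def __post_init__(self) -> None:
        if self.T0 <= 0 or self.R <= 0:
            raise ValueError("T0 and R must be positive")
        for name in ("k12", "k21", "kon", "koff"):
            k0, _ = getattr(self, name)
            if k0 < 0:
                raise ValueError(f"k0 for {name} must be >= 0, got {k0!r}")

    def at_temperature(self, T: float) -> RateConstants:
        """Evaluate all four rate constants at temperature ``T`` (K)."""
        return RateConstants(
            k12=arrhenius_rate(*self.k12, T, self.T0, self.R),
            k21=arrhenius_rate(*self.k21, T, self.T0, self.R),
            kon=arrhenius_rate(*self.kon, T, self.T0, self.R),
            koff=arrhenius_rate(*self.koff, T, self.T0, self.R),
        )


def format_population_ratio(k12: float, k21: float) -> str:
    """Render the E*:E ratio k21/k12 as 'n:1' or '1:n' with integer n.

    The larger side is divided by the smaller and rounded to the nearest
    integer, the field's usual presentation of conformational populations.
    """
    if k12 == 0 and k21 == 0:
        raise ValueError("population ratio undefined when both rates are 0")
    if k12 == 0:
        return "all E*"
    if k21 == 0:
        return "all E"
    if k21 >= k12:
        return f"{round(k21 / k12)}:1"
    return f"1:{round(k12 / k21)}"


def derived_quantities(rc: RateConstants) -> DerivedQuantities:
    """Interconversion time scale and E*/E partitioning of the free protein.

    tau (ms) = 1000/(k12 + k21); ratio_estar_to_e = k21/k12 (NaN when
    k12 == 0, i.e. the open form is never populated); fraction_open =
    k12/(k12 + k21).
    """
    if rc.exchange_rate <= 0:
        raise ValueError("tau undefined: k12 + k21 must be > 0")
    ratio = rc.k21 / rc.k12 if rc.k12 > 0 else math.nan
    return DerivedQuantities(
        tau_ms=1000.0 / rc.exchange_rate,
        ratio_estar_to_e=ratio,
        fraction_open=rc.fraction_open,
        ratio_label=format_population_ratio(rc.k12, rc.k21),
    )


def asymptotes(rc: RateConstants) -> Asymptotes:
    """Limits of the slow relaxation: alpha2(0) and alpha2(inf).

    alpha2(0) = min(koff, k12 + k21) — for reversible ligands with slow
    dissociation the intercept reports koff; alpha2(inf) = k12.  The profile
    rises when koff < k12, falls when koff > k12 and is flat when equal.
    """
    if rc.koff > rc.k12:
        direction: Literal["increasing", "decreasing", "flat"] = "decreasing"
    elif rc.koff < rc.k12:
        direction = "increasing"
    else:
        direction = "flat"
    return Asymptotes(
        alpha2_at_zero=min(rc.koff, rc.exchange_rate),
        alpha2_at_infinity=rc.k12,
        direction=direction,
    )


def fold_change(
    a: float,
    b: float,
    a_unit: str = "s-1",
    b_unit: str = "s-1",
) -> float:
    """Ratio a/b of two rate constants after unit normalisation.

    Both values must be first-order (``s-1``) or both second-order
    (``uM-1s-1`` / ``M-1s-1``); mixing orders is a dimensional error.
    """
    for order in (_FIRST_ORDER_UNITS, _SECOND_ORDER_UNITS):
        if a_unit in order and b_unit in order:
            a_norm = a * order[a_unit]
            b_norm = b * order[b_unit]
            break
    else:
        raise ValueError(
            f"incompatible or unknown units: {a_unit!r} vs {b_unit!r}; "
            f"supported: s-1, uM-1s-1, M-1s-1"
        )
    if b_norm <= 0:
        raise ValueError("fold change requires a positive denominator")
    return a_norm / b_norm
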