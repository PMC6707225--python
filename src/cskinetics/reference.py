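"""Published stopped-flow rate constants for PPACK binding to thrombin.

Literature reference values for wild-type thrombin and active-site mutants
at 15 degC (400 mM ChCl, 50 mM Tris, 0.1% PEG8000, pH 8.0), used as ground
truth for synthetic-data generation and as inputs for derived-quantity
recomputation.  Conformational-selection variants carry all four scheme
rates; the E217A and W215A/E217A mutants bind by a rigid lock-and-key
mechanism (the conformational equilibrium is frozen) and are characterised
by ``kon`` alone.
"""

from __future__ import annotations

from .core import ArrheniusParameterSet, RateConstants

__all__ = [
    "CS_VARIANTS",
    "CS_VARIANT_SE",
    "LOCK_AND_KEY_KON",
    "LOCK_AND_KEY_KON_SE",
    "SODIUM_LOCK_AND_KEY",
    "TEMPERATURE_GLOBAL_FIT",
    "GAUGE_PEAK_E_STAR",
    "GAUGE_PEAK_E",
    "variant_rate_constants",
]

#: Rate constants (k12, k21 s^-1; kon uM^-1 s^-1; koff s^-1) per variant.
CS_VARIANTS: dict[str, RateConstants] = {
    "wt": RateConstants(k12=56.0, k21=8.8, kon=1.5, koff=0.0),
    "S195A": RateConstants(k12=16.0, k21=3.8, kon=2.1, koff=4.6),
    "W215A": RateConstants(k12=51.0, k21=110.0, kon=1.2, koff=0.0),
    "E192A": RateConstants(k12=11.0, k21=19.0, kon=1.0, koff=0.0),
}

#: Reported standard errors on the constants above (same units, same keys).
CS_VARIANT_SE: dict[str, dict[str, float]] = {
    "wt": {"k12": 3.0, "k21": 0.3, "kon": 0.1, "koff": 0.0},
    "S195A": {"k12": 1.0, "k21": 0.8, "kon": 0.1, "koff": 0.2},
    "W215A": {"k12": 3.0, "k21": 10.0, "kon": 0.1, "koff": 0.0},
    "E192A": {"k12": 1.0, "k21": 1.0, "kon": 0.1, "koff": 0.0},
}

#: Second-order association rates (uM^-1 s^-1) for the lock-and-key mutants.
LOCK_AND_KEY_KON: dict[str, float] = {
    "E217A": 0.070,
    "W215A/E217A": 190e-6,  # reported as 190 M^-1 s^-1
}

LOCK_AND_KEY_KON_SE: dict[str, float] = {
    "E217A": 0.002,
    "W215A/E217A": 10e-6,
}

#: Wild-type in the presence of Na+ (fold rigidified, pure lock-and-key):
#: kon = 11 uM^-1 s^-1, koff = 0.
SODIUM_LOCK_AND_KEY: dict[str, float] = {"kon": 11.0, "koff": 0.0}

#: Global temperature fit (5-30 degC) for wild-type: (k0 at 288.15 K,
#: activation energy kcal/mol) per rate constant.  PPACK is irreversible,
#: so koff is identically zero.
TEMPERATURE_GLOBAL_FIT = ArrheniusParameterSet(
    k12=(45.0, 12.0),
    k21=(6.4, 37.0),
    kon=(1.1, 20.0),
    koff=(0.0, 0.0),
    T0=288.15,
)

#: Modal Calpha(G193)-Calpha(G216) gauge distances (Angstrom) of the closed
#: (E*) and open (E) active-site conformations across deposited structures.
GAUGE_PEAK_E_STAR = 8.3
GAUGE_PEAK_E = 12.2


def variant_rate_constants(name: str) -> RateConstants:
    """Scheme rate constants for ``name``; lock-and-key mutants are returned
    as a frozen single conformation (k12 = k21 = 0, all protein binding
    competent)."""
    if name in CS_VARIANTS:
        return CS_VARIANTS[name]
    if name in LOCK_AND_KEY_KON:
        return RateConstants(k12=0.0, k21=0.0, kon=LOCK_AND_KEY_KON[name], koff=0.0)
    raise KeyError(
        f"unknown variant {name!r}; known: "
        f"{sorted(CS_VARIANTS) + sorted(LOCK_AND_KEY_KON)}"
    )
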