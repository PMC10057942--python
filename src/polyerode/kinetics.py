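"""Pointwise rate laws of hydrolytic polyester degradation.

The model tracks two molar fields: the ester-group concentration Ce (immobile,
consumed by scission) and the monomer concentration Cm (mobile degradation
products).  Ester bonds are cleaved by a non-catalytic channel (rate k1) and an
autocatalytic channel driven by the acidic products (rate k2, sub-linear in Cm
through a dissociation exponent beta):

    dCe/dt = -(k1*Ce + k2*Ce*Cm**beta)

Every scission produces one mobile monomer, so the reaction part of the Cm
equation is the exact negation of the Ce rate.  As products leave, the matrix
porosity p = 1 - (Ce + Cm)/Ce0 grows and the monomer diffusivity rises
linearly, D = D0*(1 + alpha*p).

Temperature transfer of (k1, k2, D0) between accelerated-ageing and
physiological conditions uses the Arrhenius relation k(T) = A*exp(-Ea/(R*T)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .units import GAS_CONSTANT

__all__ = [
    "KineticParameters",
    "ArrheniusLaw",
    "ester_reaction_rate",
    "monomer_production_rate",
    "porosity",
    "monomer_diffusivity",
    "arrhenius_evaluate",
    "arrhenius_preexponential",
]


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic and transport parameters of the degradation model.

    Parameters
    ----------
    k1 : float
        Non-catalytic scission rate, 1/day.
    k2 : float
        Autocatalytic scission rate, m^3/mol/day.
    d0 : float
        Intrinsic monomer diffusivity in the undegraded polymer, m^2/day.
    ce0 : float
        Initial ester-group concentration, mol/m^3.
    beta : float
        Dissociation exponent of the autocatalytic term, in (0, 1].
    alpha : float
        Slope of the porosity-diffusivity relation, dimensionless, >= 0.
    temperature : float
        Temperature at which the set is valid, kelvin.

    Notes
    -----
    The literature is ambiguous on whether Ce counts ester *bonds* or ester
    *end groups*; the rate laws are agnostic as long as Ce0 is consistent
    with the value used during calibration.
    """

    k1: float
    k2: float
    d0: float
    ce0: float
    beta: float = 0.5
    alpha: float = 4.5
    temperature: float = 310.15

    def __post_init__(self) -> None:
        for name in ("k1", "ce0", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # k2 = 0 (no autocatalysis) and d0 = 0 (frozen transport) are valid
        # analytic limits used by the closed-form audits
        for name in ("k2", "d0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def replace(self, **changes) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ArrheniusLaw:
    """Arrhenius temperature dependence k(T) = A*exp(-Ea/(R*T)).

    ``a`` carries the units of the parameter it scales; ``ea`` is in J/mol.
    """

    ea: float
    a: float

    def __post_init__(self) -> None:
        if self.ea < 0:
            raise ValueError("activation energy must be non-negative")
        if self.a <= 0:
            raise ValueError("pre-exponential factor must be positive")

    def __call__(self, temperature: float) -> float:
        return arrhenius_evaluate(self, temperature)


def _check_concentrations(ce, cm) -> tuple[np.ndarray, np.ndarray]:
    ce = np.asarray(ce, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if np.any(ce < 0) or np.any(cm < 0):
        raise ValueError(
            "negative concentration passed to a rate law; the solver should "
            "clamp round-off negatives before evaluating kinetics"
        )
    return ce, cm


def ester_reaction_rate(ce, cm, params: KineticParameters):
    """Rate of change of the ester concentration, mol/m^3/day (<= 0).

    Returns ``-(k1*ce + k2*ce*cm**beta)``; zero iff ``ce`` is zero.
    Accepts scalars or arrays.
    """
    ce, cm = _check_concentrations(ce, cm)
    rate = -(params.k1 * ce + params.k2 * ce * cm**params.beta)
    return rate if rate.ndim else float(rate)


def monomer_production_rate(ce, cm, params: KineticParameters):
    """Reaction-only rate of monomer production, mol/m^3/day (>= 0).

    Exactly the negation of :func:`ester_reaction_rate`: each scission yields
    one monomer.  Transport is handled by the solvers, not here.
    """
    rate = ester_reaction_rate(ce, cm, params)
    return -rate


def porosity(ce, cm, ce0: float):
    """Erosion-induced porosity, 1 - (Ce + Cm)/Ce0, clamped to [0, 1].

    The raw expression can leave [0, 1] transiently under numerical error;
    clamping keeps the diffusivity inside its physical band.
    """
    if ce0 <= 0:
        raise ValueError("ce0 must be strictly positive")
    ce = np.asarray(ce, dtype=float)
    cm = np.asarray(cm, dtype=float)
    p = np.clip(1.0 - (ce + cm) / ce0, 0.0, 1.0)
    return p if p.ndim else float(p)


def monomer_diffusivity(ce, cm, params: KineticParameters):
    """State-dependent monomer diffusivity D0*(1 + alpha*p), m^2/day.

    Bounded in [D0, D0*(1 + alpha)] because the porosity is clamped.
    """
    p = porosity(ce, cm, params.ce0)
    d = params.d0 * (1.0 + params.alpha * np.asarray(p))
    return d if d.ndim else float(d)


def arrhenius_evaluate(law: ArrheniusLaw, temperature: float) -> float:
    """Evaluate an Arrhenius law at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return law.a * np.exp(-law.ea / (GAS_CONSTANT * temperature))


def arrhenius_preexponential(value_ref: float, t_ref: float, ea: float) -> ArrheniusLaw:
    """Build an Arrhenius law from a reference value at a reference temperature.

    Returns the law with ``a = value_ref*exp(Ea/(R*T_ref))`` so that
    evaluating it at ``t_ref`` reproduces ``value_ref`` exactly.
    """
    if value_ref <= 0 or t_ref <= 0:
        raise ValueError("value_ref and t_ref must be positive")
    a = value_ref * np.exp(ea / (GAS_CONSTANT * t_ref))
    return ArrheniusLaw(ea=ea, a=float(a))


def arrhenius_transfer(
    params: KineticParameters,
    activation_energies: Mapping[str, float],
    t_target: float,
) -> KineticParameters:
    """Rescale (k1, k2, d0) from ``params.temperature`` to ``t_target``.

    ``activation_energies`` maps parameter names ('k1', 'k2', 'd0') to Ea in
    J/mol; a missing key raises.  Ce0, beta and alpha are temperature
    independent in this model.
    """
    new = {}
    for name in ("k1", "k2", "d0"):
        try:
            ea = activation_energies[name]
        except KeyError as exc:
            raise KeyError(f"missing activation energy for {name!r}") from exc
        law = arrhenius_preexponential(getattr(params, name), params.temperature, ea)
        new[name] = arrhenius_evaluate(law, t_target)
    return params.replace(temperature=t_target, **new)
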