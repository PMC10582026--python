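"""Anthropometric derivations: BMI, fat mass, and the BIA injection point.

Fat mass is the two-compartment difference FM = BM - FFM, with FM% expressed
relative to body mass.  Fat-free mass from bioelectrical impedance is a
pluggable hook: population-specific BIA regressions have coefficients tied to
the device and reference method, so the caller supplies the equation.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Tuple

from .errors import ConfigurationError, DomainError

__all__ = ["bmi", "fat_mass", "ffm_from_bia"]


def bmi(body_mass: float, stature: float) -> float:
    """Body-mass index, kg m^-2 = body mass / stature squared."""
    if stature <= 0:
        raise DomainError(f"stature must be positive, got {stature}")
    if body_mass < 0:
        raise DomainError(f"body_mass must be nonnegative, got {body_mass}")
    return body_mass / stature**2


def fat_mass(body_mass: float, ffm: float) -> Tuple[float, float]:
    """Fat mass (kg) and fat mass as a percentage of body mass.

    Returns ``(fm_kg, fm_pct)`` with ``fm_kg = body_mass - ffm`` and
    ``fm_pct = 100 * fm_kg / body_mass``.
    """
    if body_mass <= 0:
        raise DomainError(f"body_mass must be positive, got {body_mass}")
    if not 0 < ffm <= body_mass:
        raise DomainError(
            f"ffm must satisfy 0 < ffm <= body_mass, got ffm={ffm}, body_mass={body_mass}"
        )
    fm_kg = body_mass - ffm
    return fm_kg, 100.0 * fm_kg / body_mass


def ffm_from_bia(
    impedance_inputs: Mapping,
    equation: Optional[Callable[[Mapping], float]] = None,
    body_mass: Optional[float] = None,
) -> float:
    """Fat-free mass (kg) from a user-supplied BIA regression.

    ``equation`` receives the impedance record and returns FFM in kg; the
    result is validated against the subject invariants (positive; not above
    ``body_mass`` when given).
    """
    if equation is None:
        raise ConfigurationError(
            "no BIA equation supplied; provide a callable mapping the impedance "
            "record to fat-free mass in kg (device/population-specific)"
        )
    ffm = float(equation(impedance_inputs))
    if ffm <= 0:
        raise DomainError(f"BIA equation returned non-positive FFM: {ffm}")
    if body_mass is not None and ffm > body_mass:
        raise DomainError(
            f"BIA equation returned FFM {ffm} kg above body mass {body_mass} kg"
        )
    return ffm
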