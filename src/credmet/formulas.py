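"""Elemental-formula arithmetic: carbon counts, monoisotopic masses, adducts.

Formula parsing and isotope masses are delegated to :mod:`pyteomics.mass`,
the standard mass-spectrometry mass calculator.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

from .config import PROTON_MASS, WATER_MASS

ADDUCTS = ("[M-H]-", "[M+H]+", "[M-H2O-H]-")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Raises
    ------
    ValueError
        If the formula cannot be parsed.
    """
    if not formula or not formula[0].isalpha():
        raise ValueError(f"unparseable formula: {formula!r}")
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise ValueError(f"unparseable formula: {formula!r}") from exc
    if not comp:
        raise ValueError(f"unparseable formula: {formula!r}")
    unknown = [el for el in comp if el.strip("0123456789") not in _pmass.nist_mass]
    if unknown:
        raise ValueError(f"unknown element(s) {unknown} in formula {formula!r}")
    return dict(comp)


def formula_carbon_count(formula: str) -> int:
    """Number of carbon atoms in a Hill-notation formula.

    >>> formula_carbon_count("C5H9NO4")
    5
    >>> formula_carbon_count("H2O")
    0
    """
    return parse_formula(formula).get("C", 0)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (exact) mass of a neutral formula, Da."""
    return float(_pmass.calculate_mass(formula=formula))


def adduct_mz(monoisotopic: float, adduct: str) -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass.

    Supported adducts: ``[M-H]-``, ``[M+H]+`` and the water-loss
    derivative ``[M-H2O-H]-``.
    """
    if adduct == "[M-H]-":
        return monoisotopic - PROTON_MASS
    if adduct == "[M+H]+":
        return monoisotopic + PROTON_MASS
    if adduct == "[M-H2O-H]-":
        return monoisotopic - WATER_MASS - PROTON_MASS
    raise ValueError(f"unknown adduct: {adduct!r}")


def adducts_for_polarity(polarity: str, include_water_loss: bool = False) -> tuple[str, ...]:
    """Default adduct set per ionization polarity."""
    if polarity == "negative":
        return ("[M-H]-", "[M-H2O-H]-") if include_water_loss else ("[M-H]-",)
    if polarity == "positive":
        return ("[M+H]+",)
    raise ValueError(f"unknown polarity: {polarity!r}")


def ppm_error(observed: float, reference: float) -> float:
    """Signed mass error of ``observed`` vs ``reference`` in ppm.

    The error is scaled by the reference m/z, matching how instrument
    mass accuracy scales.
    """
    return (observed - reference) / reference * 1e6
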