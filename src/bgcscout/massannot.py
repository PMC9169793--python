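"""Monoisotopic mass arithmetic for LC-MS formula assignment.

Supports the adduct arithmetic behind small-molecule identification calls:
parse an elemental formula, compute the monoisotopic (principal-isotope)
mass, add or subtract a proton for charged adducts (proton mass, not the
hydrogen-atom mass, so the electron is handled implicitly), optionally
subtract a water loss, and express the deviation of an observed m/z in
parts per million.  Element masses come from the NIST table shipped with
pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError

from .types import BgcscoutError

#: Proton mass in Da (CODATA); used for charged adducts.
PROTON = 1.00727646688
_WATER = 2 * _pmass.nist_mass["H"][0][0] + _pmass.nist_mass["O"][0][0]

SUPPORTED_ADDUCTS = ("M", "[M+H]+", "[M-H]-", "[M+H-H2O]+")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. C18H16O6."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts or all(v == 0 for v in self.counts.values()):
            raise BgcscoutError("formula must contain at least one atom")
        if any(v < 0 for v in self.counts.values()):
            raise BgcscoutError("negative element counts")

    @property
    def monoisotopic_mass(self) -> float:
        return sum(
            n * _pmass.nist_mass[el][0][0] for el, n in self.counts.items()
        )

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in sorted(self.counts.items())
        )


def parse_formula(s: str) -> ElementalFormula:
    """Parse a Hill-notation formula string ("C18H17O6" -> C:18, H:17, O:6)."""
    try:
        comp = _pmass.Composition(formula=s)
    except PyteomicsError as exc:
        raise BgcscoutError(f"cannot parse formula {s!r}: {exc}") from None
    counts = {el: int(n) for el, n in comp.items() if n}
    for el in counts:
        if el not in _pmass.nist_mass:
            raise BgcscoutError(f"unknown element {el!r} in formula {s!r}")
    return ElementalFormula(counts=counts)


def monoisotopic_mz(
    formula: ElementalFormula | str, adduct: str = "M"
) -> float:
    """Theoretical m/z of a formula under a (singly charged) adduct.

    "M" is the neutral monoisotopic mass; "[M+H]+" and "[M-H]-" add or
    subtract one proton; "[M+H-H2O]+" additionally subtracts a neutral
    water loss.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    m = formula.monoisotopic_mass
    if adduct == "M":
        return m
    if adduct == "[M+H]+":
        return m + PROTON
    if adduct == "[M-H]-":
        return m - PROTON
    if adduct == "[M+H-H2O]+":
        return m + PROTON - _WATER
    raise BgcscoutError(
        f"unsupported adduct {adduct!r}; supported: {SUPPORTED_ADDUCTS}"
    )


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative deviation of an observed m/z from theory, in ppm."""
    if theoretical <= 0:
        raise BgcscoutError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
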