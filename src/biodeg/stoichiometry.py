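"""Polymer elemental stoichiometry: Buswell coefficients, theoretical methane
potential (BMP) and theoretical oxygen demand (ThOD).

The Buswell balance converts one mole of an organic repeat unit CxHyOzNdSe
plus water into CH4, CO2, NH3 and H2S::

    CxHyOzNdSe + (x - y/4 - z/2 + 3d/4 + e/2) H2O ->
        (x/2 + y/8 - z/4 - 3d/8 - e/4) CH4
      + (x/2 - y/8 + z/4 + 3d/8 + e/4) CO2
      + d NH3 + e H2S

Conventions (chosen to bit-match the published tables this mirrors):

* atomic masses are the integers C=12, H=1, O=16, N=14, S=32; molecular
  oxygen is 31.9988 g/mol in the ThOD formula;
* the molar gas volume at STP is exactly 22.4 L/mol.

Note: some printed forms of the BMP formula show ``12z`` for oxygen in the
molar-mass denominator; that is a typographical erratum — only 16·z
reproduces the standard tabulated potentials (e.g. polycaprolactone,
22.4·3.75/114 = 0.7368 -> 0.74 L/g, whereas 12·z would give 0.79).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ATOMIC_MASS",
    "O2_MOLAR_MASS",
    "MOLAR_VOLUME_STP_L",
    "FormulaError",
    "UnsupportedFormulaError",
    "ElementalFormula",
    "BuswellCoefficients",
    "TheoreticalPotentials",
    "parse_formula",
    "buswell",
    "bmp_theoretical",
    "thod",
    "potentials",
    "load_registry",
    "PRESET_POLYMERS",
]

#: integer atomic masses (g/mol) used for the repeat-unit molar mass
ATOMIC_MASS = {"C": 12, "H": 1, "O": 16, "N": 14, "S": 32}

#: molar mass of O2 used by the ThOD formula, g/mol
O2_MOLAR_MASS = 31.9988

#: molar gas volume at standard temperature and pressure, L/mol
MOLAR_VOLUME_STP_L = 22.4


class FormulaError(ValueError):
    """Raised when a chemical-formula string cannot be parsed or validated."""


class UnsupportedFormulaError(ValueError):
    """Raised when a formula is outside an operation's analytic scope."""


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts of one repeat unit, restricted to C, H, O, N, S.

    Attributes
    ----------
    x, y, z, d, e
        Counts of C, H, O, N and S atoms respectively. ``x >= 1`` is
        enforced: a carbon-free "polymer" is rejected.
    """

    x: int
    y: int = 0
    z: int = 0
    d: int = 0
    e: int = 0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "d", "e"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise FormulaError(
                    f"atom count {name!r} must be a non-negative integer, got {v!r}"
                )
        if self.x < 1:
            raise FormulaError("formula has no carbon (x >= 1 required)")

    @property
    def mr(self) -> float:
        """Molar mass of the repeat unit in g/mol (integer atomic masses)."""
        return float(
            ATOMIC_MASS["C"] * self.x
            + ATOMIC_MASS["H"] * self.y
            + ATOMIC_MASS["O"] * self.z
            + ATOMIC_MASS["N"] * self.d
            + ATOMIC_MASS["S"] * self.e
        )

    def __str__(self) -> str:
        parts = []
        for sym, n in zip("CHONS", (self.x, self.y, self.z, self.d, self.e)):
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)


_TOKEN_RE = re.compile(r"([A-Za-z][a-z]?)([0-9]*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a repeat-unit formula string such as ``"C6H10O2"``.

    Only the element symbols C, H, O, N, S are accepted, each at most once,
    each with an optional positive integer count (absent = 1). Parentheses,
    hydrates and charges are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        if sym in counts:
            raise FormulaError(f"element {sym!r} appears more than once in {text!r}")
        n = int(num) if num else 1
        if n < 1:
            raise FormulaError(f"count for {sym!r} must be positive in {text!r}")
        counts[sym] = n
        pos = m.end()
    return ElementalFormula(
        x=counts.get("C", 0),
        y=counts.get("H", 0),
        z=counts.get("O", 0),
        d=counts.get("N", 0),
        e=counts.get("S", 0),
    )


@dataclass(frozen=True)
class BuswellCoefficients:
    """Stoichiometric coefficients (mol per mol repeat unit), exact rationals.

    ``water`` is consumed; ``ch4``, ``co2``, ``nh3`` and ``h2s`` are produced.
    ``flags`` carries warning-level notes (e.g. a formula too oxidized to
    yield methane); it never blocks the computation.
    """

    water: Fraction
    ch4: Fraction
    co2: Fraction
    nh3: Fraction
    h2s: Fraction
    flags: tuple[str, ...] = ()


def buswell(f: ElementalFormula) -> BuswellCoefficients:
    """Buswell stoichiometric coefficients for one repeat unit of ``f``."""
    x, y, z, d, e = (Fraction(v) for v in (f.x, f.y, f.z, f.d, f.e))
    ch4 = x / 2 + y / 8 - z / 4 - 3 * d / 8 - e / 4
    co2 = x / 2 - y / 8 + z / 4 + 3 * d / 8 + e / 4
    water = x - y / 4 - z / 2 + 3 * d / 4 + e / 2
    flags: tuple[str, ...] = ()
    if ch4 <= 0:
        flags = ("no_methane_yield: formula too oxidized to yield methane",)
    return BuswellCoefficients(
        water=water, ch4=ch4, co2=co2, nh3=Fraction(f.d), h2s=Fraction(f.e), flags=flags
    )


def bmp_theoretical(f: ElementalFormula) -> float:
    """Theoretical biochemical methane potential, L CH4 (STP) per g.

    Equals ``22.4 * ch4 / Mr`` with ``ch4`` the Buswell methane coefficient.
    Full precision; round only at report time.
    """
    return MOLAR_VOLUME_STP_L * float(buswell(f).ch4) / f.mr


def thod(f: ElementalFormula) -> float:
    """Theoretical oxygen demand, g O2 per g, for CcHhOo formulas.

    ``(31.9988 / Mr) * (c + 0.25 h - 0.5 o)``. Formulas containing N or S are
    outside this formula's stated scope and raise
    :class:`UnsupportedFormulaError`.
    """
    if f.d > 0 or f.e > 0:
        raise UnsupportedFormulaError(
            "ThOD formula is stated for CcHhOo only; "
            f"{f} contains N or S"
        )
    return (O2_MOLAR_MASS / f.mr) * (f.x + 0.25 * f.y - 0.5 * f.z)


@dataclass(frozen=True)
class TheoreticalPotentials:
    """Theoretical gas potentials of one polymer.

    ``bmp_theoric`` in L CH4 (STP) per g; ``thod`` in g O2 per g, or ``None``
    when the formula contains N or S (ThOD unsupported).
    """

    bmp_theoric: float
    thod: float | None = None
    flags: tuple[str, ...] = field(default=())


def potentials(f: ElementalFormula) -> TheoreticalPotentials:
    """Compute both theoretical potentials for a formula."""
    bus = buswell(f)
    try:
        th: float | None = thod(f)
        flags = bus.flags
    except UnsupportedFormulaError:
        th = None
        flags = bus.flags + ("thod_unsupported: formula contains N or S",)
    return TheoreticalPotentials(bmp_theoric=bmp_theoretical(f), thod=th, flags=flags)


#: built-in repeat-unit registry; cellulose is its anhydroglucose monomer
PRESET_POLYMERS = {
    "PE": "C2H4",
    "PET": "C10H8O4",
    "PCL": "C6H10O2",
    "cellulose": "C6H10O5",
}


def load_registry(path: str | Path | None = None) -> dict[str, ElementalFormula]:
    """Load a ``{name: formula}`` polymer registry.

    ``path`` may be a YAML or JSON file holding either a mapping
    ``name -> formula`` or a list of ``{name, formula}`` records. With no
    path, the packaged default registry (PE, PET, PCL, cellulose) is used.
    """
    if path is None:
        raw = resources.files("biodeg").joinpath("data/polymers.yaml").read_text()
        data = yaml.safe_load(raw)
    else:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    if isinstance(data, list):
        data = {rec["name"]: rec["formula"] for rec in data}
    if not isinstance(data, dict):
        raise FormulaError("registry must be a mapping or a list of records")
    return {name: parse_formula(formula) for name, formula in data.items()}
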