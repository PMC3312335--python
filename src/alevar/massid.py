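"""Exact-mass arithmetic for small-molecule identification.

Monoisotopic masses of molecular formulas, m/z of singly protonated or
sodiated cations, neutral-loss fragments, and ppm matching of observed
against calculated m/z — the arithmetic used to identify a metabolite
(e.g. the dithiolopyrrolone antibiotic holomycin, neutral C7H6N2O2S2)
from high-resolution ESI-MS data.

All cation m/z values are electron-mass corrected: the mass of the
removed electron (~5.486e-4 Da) is subtracted, which is required to
match high-resolution instruments at the fourth decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "IonSpec",
    "MzMatch",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_loss",
    "match_mz",
]

# Monoisotopic atomic masses (Da), CODATA/IUPAC values. Data, not logic:
# extend this table to support further elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907  # Da

# Supported adducts: label -> atom added to the neutral molecule. Charge
# is always +1 here.
_ADDUCT_ATOM = {"[M+H]+": "H", "[M+Na]+": "Na"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. C7H6N2O2S2.

    Counts are positive integers; an empty composition (mass zero) is
    allowed so that formula differences are closed under subtraction.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for elem, n in self.counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {elem!r}")
            if not isinstance(n, int) or n <= 0:
                raise ValueError(f"count for {elem} must be a positive integer, got {n!r}")

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            have = counts.get(elem, 0)
            if n > have:
                raise ValueError(
                    f"cannot remove {n} {elem} from formula with {have}"
                )
            if n == have:
                del counts[elem]
            else:
                counts[elem] = have - n
        return MolecularFormula(counts)

    def contains(self, other: "MolecularFormula") -> bool:
        return all(self.counts.get(e, 0) >= n for e, n in other.counts.items())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(
            self.counts,
            key=lambda e: (e != "C", e != "H", e),
        )
        return "".join(f"{e}{self.counts[e] if self.counts[e] > 1 else ''}" for e in order)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a plain formula string like ``C7H6N2O2S2`` (no parentheses)."""
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        if not m.group(0):
            break
        elem = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Monoisotopic mass in Da: sum of count x monoisotopic atomic mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


@dataclass(frozen=True)
class IonSpec:
    """A singly charged cation: full ion formula (adduct atom included).

    m/z = sum of atomic monoisotopic masses minus one electron mass.
    """

    formula: MolecularFormula
    label: str = ""
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only +1 ions are supported")

    @property
    def mz(self) -> float:
        return monoisotopic_mass(self.formula) - self.charge * ELECTRON_MASS


def ion_mz(neutral: MolecularFormula | str, adduct: str) -> float:
    """m/z of an adduct cation of a neutral molecule, to full precision.

    Supported adducts: ``[M+H]+`` and ``[M+Na]+``. The result is the
    neutral monoisotopic mass plus the adduct *atom* mass minus the
    electron mass. Round to 4 decimals for display.
    """
    if adduct not in _ADDUCT_ATOM:
        raise ValueError(f"unsupported adduct {adduct!r}")
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    atom = _ADDUCT_ATOM[adduct]
    return monoisotopic_mass(neutral) + MONOISOTOPIC_MASS[atom] - ELECTRON_MASS


def make_ion(neutral: MolecularFormula | str, adduct: str, label: str = "") -> IonSpec:
    """Build the IonSpec of an adduct cation (formula includes the adduct atom)."""
    if adduct not in _ADDUCT_ATOM:
        raise ValueError(f"unsupported adduct {adduct!r}")
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    ion_formula = neutral + MolecularFormula({_ADDUCT_ATOM[adduct]: 1})
    return IonSpec(formula=ion_formula, label=label or adduct)


def neutral_loss(ion: IonSpec, loss: MolecularFormula | str, label: str = "") -> IonSpec:
    """Fragment ion after loss of a neutral moiety (e.g. H2O, ketene C2H2O).

    The loss must be elementally contained in the ion; the fragment's m/z
    is lower by exactly the monoisotopic mass of the loss.
    """
    if isinstance(loss, str):
        loss = parse_formula(loss)
    if not ion.formula.contains(loss):
        raise ValueError(
            f"loss {loss} not contained in ion formula {ion.formula}"
        )
    frag = ion.formula - loss
    if not label:
        label = f"{ion.label} - {loss}" if ion.label else f"- {loss}"
    return IonSpec(formula=frag, label=label, charge=ion.charge)


@dataclass(frozen=True)
class MzMatch:
    ion: IonSpec
    observed: float
    calculated: float
    ppm: float


def match_mz(observed: float, candidates: list[IonSpec], tol_ppm: float) -> list[MzMatch]:
    """Candidates whose calculated m/z is within tol_ppm of the observation.

    Deviation is |observed - calculated| / calculated x 1e6; matches are
    returned sorted by increasing deviation.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    matches = []
    for ion in candidates:
        calc = ion.mz
        ppm = abs(observed - calc) / calc * 1e6
        if ppm <= tol_ppm:
            matches.append(MzMatch(ion=ion, observed=observed, calculated=calc, ppm=ppm))
    matches.sort(key=lambda m: m.ppm)
    return matches
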