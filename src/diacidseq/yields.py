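"""Mass and carbon bookkeeping for indigoidine production from diacid media.

Deterministic arithmetic connecting medium composition (mM of each diacid),
the colorimetric calibration curve (OD612 -> g/L indigoidine), the fraction
of medium carbon incorporated into product, and the percent of the
flux-balance maximum theoretical yield that fraction represents.

Formulas here are the neutral acids (succinic acid C4H6O4); the FBA module
uses ionized convention internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# CODATA standard atomic weights, two decimals
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.99,
    "K": 39.098,
    "Cl": 35.45,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

__all__ = [
    "parse_formula",
    "molar_mass",
    "CompoundSpec",
    "MediumMix",
    "diacid",
    "equimolar_mix",
    "CalibrationCurve",
    "medium_totals",
    "od612_to_titer",
    "carbon_incorporated",
    "percent_of_mty",
    "INDIGOIDINE",
]


def parse_formula(formula: str) -> dict[str, int]:
    """'C10H8N4O4' -> {'C': 10, 'H': 8, 'N': 4, 'O': 4}."""
    if not formula:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass(formula: str | dict[str, int]) -> float:
    """Molar mass in g/mol from standard atomic masses."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty formula")
    unknown = set(counts) - set(ATOMIC_MASS)
    if unknown:
        raise ValueError(f"unknown element symbols: {sorted(unknown)}")
    return sum(ATOMIC_MASS[el] * k for el, k in counts.items())


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    formula: str

    @property
    def element_counts(self) -> dict[str, int]:
        return parse_formula(self.formula)

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)

    @property
    def n_carbon(self) -> int:
        return self.element_counts.get("C", 0)


_DIACID_NAMES = {
    4: "succinic acid",
    5: "glutaric acid",
    6: "adipic acid",
    7: "pimelic acid",
    8: "suberic acid",
    9: "azelaic acid",
    10: "sebacic acid",
    11: "undecanedioic acid",
    12: "dodecanedioic acid",
}


def diacid(n: int) -> CompoundSpec:
    """The Cn alpha,omega-dicarboxylic acid, neutral formula CnH(2n-2)O4."""
    if n < 4:
        raise ValueError("diacids here start at C4 (succinic)")
    return CompoundSpec(_DIACID_NAMES.get(n, f"C{n} diacid"), f"C{n}H{2 * n - 2}O4")


INDIGOIDINE = CompoundSpec("indigoidine", "C10H8N4O4")

EQUIMOLAR_CHAINS = (4, 5, 6, 7, 8, 9, 10, 12)


@dataclass(frozen=True)
class MediumMix:
    """Diacid mixture: list of (compound, concentration mM)."""

    components: tuple[tuple[CompoundSpec, float], ...]

    def __post_init__(self) -> None:
        if any(conc < 0 for _, conc in self.components):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_pairs(cls, pairs) -> "MediumMix":
        return cls(tuple((c, float(mm)) for c, mm in pairs))


def equimolar_mix(conc_mm: float = 1.0, chains=EQUIMOLAR_CHAINS) -> MediumMix:
    """1 mM each of the C4-C10 and C12 diacids (the production medium)."""
    return MediumMix.from_pairs((diacid(n), conc_mm) for n in chains)


def medium_totals(medium: MediumMix) -> tuple[float, float]:
    """(total mass g/L, total carbon mmol/L) of the mixture."""
    total_mass = sum(conc * c.molar_mass / 1000.0 for c, conc in medium.components)
    total_carbon = sum(conc * c.n_carbon for c, conc in medium.components)
    return total_mass, total_carbon


@dataclass(frozen=True)
class CalibrationCurve:
    """Colorimetric standard curve: concentration (g/L) = slope*OD612 + intercept."""

    slope: float = 0.268
    intercept: float = -0.0109

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


def od612_to_titer(od: float, curve: CalibrationCurve = CalibrationCurve()) -> float:
    """Indigoidine titer in g/L from absorbance at 612 nm, clamped at 0."""
    if od < 0:
        raise ValueError("optical density must be >= 0")
    return max(0.0, curve.slope * od + curve.intercept)


def carbon_incorporated(titer_g_per_l: float, medium: MediumMix) -> float:
    """Fraction of the medium's carbon ending up in indigoidine.

    (titer / MW_indigoidine) mol/L * 10 carbons * 1000 -> mmol C/L, divided
    by the medium's total carbon in mmol/L.
    """
    if titer_g_per_l < 0:
        raise ValueError("titer must be >= 0")
    _, total_carbon = medium_totals(medium)
    if total_carbon <= 0:
        raise ValueError("medium contains no carbon")
    product_carbon = titer_g_per_l / INDIGOIDINE.molar_mass * INDIGOIDINE.n_carbon * 1000.0
    return product_carbon / total_carbon


def percent_of_mty(carbon_fraction: float, medium_mty_fraction: float) -> float:
    """Observed carbon incorporation as a percentage of the FBA ceiling."""
    if medium_mty_fraction <= 0:
        raise ValueError("medium MTY must be > 0")
    return 100.0 * carbon_fraction / medium_mty_fraction
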