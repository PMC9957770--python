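"""Compound registry and oxime-conjugate mass targeting.

Transamination converts an amino donor R-CH(NH2)-COOH into the keto acid
R-C(=O)-COOH.  On the elemental formula this is the net transform
``-NH3, +O`` (mass shift -1.031634 Da).  The keto product carries a ketone
that condenses with the aminooxy group of a perfluorous O-alkyloxyamine
probe, releasing water and forming an oxime detectable by laser-desorption
mass spectrometry.  The probe contributes a fixed m/z offset to every
conjugate, so the observed channel for any compound X is::

    m/z(X-oxime) = tag_contribution + M_mono(X) - M_mono(H2O)

Monoisotopic masses come from the NIST atomic mass table bundled with
:mod:`pyteomics` (``pyteomics.mass.nist_mass``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd
from pyteomics.mass import Composition, calculate_mass

__all__ = [
    "ElementalFormula",
    "CompoundKind",
    "TagWarning",
    "Compound",
    "ProbeSpec",
    "AdductTarget",
    "Collision",
    "FormulaError",
    "NotTransaminatableError",
    "NotTaggableError",
    "monoisotopic_mass",
    "transamination_product",
    "oxime_conjugate_mz",
    "build_target_panel",
    "detect_collisions",
    "load_compound_panel",
    "default_panel",
    "targets_to_frame",
    "WATER_MASS",
    "TRANSAMINATION_MASS_SHIFT",
]

WATER = Composition(formula="H2O")
WATER_MASS = calculate_mass(composition=WATER)  # 18.010565 Da

#: net mass change of the -NH3/+O deamination transform, in Da
TRANSAMINATION_MASS_SHIFT = calculate_mass(formula="O") - calculate_mass(formula="NH3")

INSTRUMENT_MZ_RANGE = (500.0, 2000.0)


class FormulaError(ValueError):
    """Raised for empty formulas or unknown element symbols."""


class NotTransaminatableError(ValueError):
    """Raised when a compound lacks a transferable primary amine."""


class NotTaggableError(ValueError):
    """Raised when a compound cannot form a stable oxime conjugate."""


class CompoundKind(str, Enum):
    alpha_amino_acid = "alpha_amino_acid"
    amine = "amine"
    keto_acid = "keto_acid"
    other = "other"


class TagWarning(str, Enum):
    none = "none"
    cyclizes = "cyclizes"
    no_stable_ketone = "no_stable_ketone"


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. ``C6H13NO2`` for leucine."""

    element_counts: Mapping[str, int]

    def __post_init__(self):
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("empty elemental formula")
        from pyteomics.mass import nist_mass

        for el, n in counts.items():
            if el not in nist_mass:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        try:
            comp = Composition(formula=formula)
        except Exception as exc:  # pyteomics raises PyteomicsError
            raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc
        return cls(dict(comp))

    def to_composition(self) -> Composition:
        return Composition(dict(self.element_counts))

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        comp = self.to_composition() - other.to_composition()
        if any(v < 0 for v in comp.values()):
            raise FormulaError(f"negative element count in {dict(comp)}")
        return ElementalFormula({k: v for k, v in comp.items() if v})

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        comp = self.to_composition() + other.to_composition()
        return ElementalFormula({k: v for k, v in comp.items() if v})

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(k for k in self.element_counts if k not in "CH")
        parts = []
        for el in order:
            n = self.element_counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da of an elemental formula.

    Sums count x monoisotopic atomic mass over the elements, using the
    NIST table shipped with pyteomics.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return calculate_mass(composition=formula.to_composition())


@dataclass(frozen=True)
class Compound:
    name: str
    formula: ElementalFormula
    kind: CompoundKind = CompoundKind.other
    tag_warning: TagWarning = TagWarning.none
    full_name: str = ""

    def __post_init__(self):
        m = self.formula.monoisotopic_mass
        if m <= 0:
            raise FormulaError(f"{self.name}: non-positive monoisotopic mass")
        if self.kind is CompoundKind.alpha_amino_acid and self.formula.element_counts.get("N", 0) < 1:
            raise FormulaError(f"{self.name}: alpha amino acid must contain nitrogen")

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.monoisotopic_mass


@dataclass(frozen=True)
class ProbeSpec:
    """Oxime probe mass bookkeeping.

    ``tag_mz_contribution`` is treated as the net additive contribution of
    the O-alkyloxyamine fluorous tag (m/z 793.2365), so that every
    conjugate appears at ``tag + M(compound) - M(H2O)``.  This convention
    reproduces the browsable channels for the leucine, tryptophan and
    histidine keto acids (905.3, 978.3, 929.3) to one decimal.
    """

    tag_mz_contribution: float = 793.2365
    condensation_loss: ElementalFormula = field(
        default_factory=lambda: ElementalFormula({"H": 2, "O": 1})
    )
    mz_tolerance: float = 0.05

    def __post_init__(self):
        if self.tag_mz_contribution <= self.condensation_loss.monoisotopic_mass:
            raise ValueError("tag contribution must exceed the condensation loss")


@dataclass
class Collision:
    other: "AdductTarget"
    delta_mz: float
    degenerate: bool = False  # product coincides with its own well's acceptor


@dataclass
class AdductTarget:
    """One oxime-conjugate m/z channel to extract from the image."""

    source_compound: Compound
    conjugate_mz: float
    role: str  # "product" | "acceptor"
    donor_name: str | None = None  # for product targets: the amino donor
    collisions: list[Collision] = field(default_factory=list)
    in_range: bool = True

    @property
    def name(self) -> str:
        if self.role == "product" and self.donor_name:
            return f"{self.donor_name}>{self.source_compound.name}"
        return self.source_compound.name


# ---------------------------------------------------------------------------
# core operations

_NH3 = ElementalFormula({"N": 1, "H": 3})
_O = ElementalFormula({"O": 1})


def transamination_product(donor: Compound) -> Compound:
    """Deaminated carbonyl product of an amino donor.

    Applies the net formula transform ``-NH3, +O`` (the amino group leaves
    with the transferred nitrogen; the carbon gains a carbonyl oxygen).
    Glutamine's product, alpha-ketoglutaramate, reversibly cyclizes to a
    lactam and is flagged accordingly.
    """
    counts = donor.formula.element_counts
    if counts.get("N", 0) < 1 or counts.get("H", 0) < 3:
        raise NotTransaminatableError(
            f"{donor.name}: no transferable primary amine (need N>=1, H>=3)"
        )
    if donor.tag_warning is TagWarning.no_stable_ketone:
        raise NotTransaminatableError(
            f"{donor.name}: flagged as yielding no stable ketone"
        )
    product_formula = (donor.formula - _NH3) + _O
    warning = TagWarning.cyclizes if donor.tag_warning is TagWarning.cyclizes else TagWarning.none
    return Compound(
        name=f"{donor.name}-keto",
        formula=product_formula,
        kind=CompoundKind.keto_acid,
        tag_warning=warning,
    )


def oxime_conjugate_mz(compound: Compound, probe: ProbeSpec | None = None) -> float:
    """m/z of the oxime conjugate: tag contribution + M(compound) - M(H2O)."""
    probe = probe or ProbeSpec()
    if compound.tag_warning is TagWarning.no_stable_ketone:
        raise NotTaggableError(f"{compound.name}: no stable carbonyl to tag")
    return (
        probe.tag_mz_contribution
        + compound.monoisotopic_mass
        - probe.condensation_loss.monoisotopic_mass
    )


def build_target_panel(
    donors: Iterable[Compound],
    acceptors: Iterable[Compound],
    probe: ProbeSpec | None = None,
) -> list[AdductTarget]:
    """Derive the m/z target list for a donor/acceptor screen.

    One *product* target per donor (the oxime conjugate of its
    transamination product) and one *acceptor* target per keto acceptor
    (the residual-substrate conjugate).  Targets are collision-checked at
    the probe tolerance and sorted by m/z.  Out-of-range targets are
    flagged via ``in_range``, never dropped.
    """
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        raise ValueError("donor and acceptor panels must be non-empty")
    probe = probe or ProbeSpec()

    targets: list[AdductTarget] = []
    for donor in donors:
        try:
            product = transamination_product(donor)
            mz = oxime_conjugate_mz(product, probe)
        except (NotTransaminatableError, NotTaggableError):
            continue
        targets.append(
            AdductTarget(
                source_compound=product, conjugate_mz=mz, role="product",
                donor_name=donor.name,
                in_range=INSTRUMENT_MZ_RANGE[0] <= mz <= INSTRUMENT_MZ_RANGE[1],
            )
        )
    for acc in acceptors:
        mz = oxime_conjugate_mz(acc, probe)
        targets.append(
            AdductTarget(
                source_compound=acc, conjugate_mz=mz, role="acceptor",
                in_range=INSTRUMENT_MZ_RANGE[0] <= mz <= INSTRUMENT_MZ_RANGE[1],
            )
        )
    targets.sort(key=lambda t: (t.conjugate_mz, t.role, t.name))
    detect_collisions(targets, probe.mz_tolerance)
    return targets


def detect_collisions(targets: list[AdductTarget], tolerance: float) -> list[tuple]:
    """Record every target pair closer than ``tolerance`` in m/z.

    A product target indistinguishable from an acceptor target is a
    *degenerate pair*: in a well pairing that donor with that acceptor the
    fractional conversion ratio is unidentifiable, and downstream scoring
    marks the well not-evaluable.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    for t in targets:
        t.collisions = []
    records = []
    for i, a in enumerate(targets):
        for b in targets[i + 1:]:
            d = abs(a.conjugate_mz - b.conjugate_mz)
            if d <= tolerance:
                degenerate = {a.role, b.role} == {"product", "acceptor"}
                a.collisions.append(Collision(b, d, degenerate))
                b.collisions.append(Collision(a, d, degenerate))
                records.append((a, b, d, "degenerate_pair" if degenerate else "collision"))
    return records


def degenerate_acceptors(target: AdductTarget) -> set[str]:
    """Names of acceptor compounds whose channel collides with this product."""
    return {
        c.other.source_compound.name
        for c in target.collisions
        if target.role == "product" and c.other.role == "acceptor"
    }


# ---------------------------------------------------------------------------
# panel I/O

def load_compound_panel(path_or_buf) -> dict[str, Compound]:
    """Load a compound panel CSV (name, formula, kind[, tag_warning])."""
    df = pd.read_csv(path_or_buf)
    required = {"name", "formula", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    panel: dict[str, Compound] = {}
    for row in df.itertuples(index=False):
        raw_warning = getattr(row, "tag_warning", "none")
        if not isinstance(raw_warning, str) or not raw_warning:
            raw_warning = "none"
        full_name = getattr(row, "full_name", "")
        panel[row.name] = Compound(
            name=row.name,
            formula=ElementalFormula.parse(row.formula),
            kind=CompoundKind(row.kind),
            tag_warning=TagWarning(raw_warning),
            full_name=full_name if isinstance(full_name, str) else "",
        )
    return panel


def default_panel() -> dict[str, Compound]:
    """The bundled screen panel: 31 amino donors plus the keto-acid set."""
    ref = importlib.resources.files("oximsi.data") / "compounds.csv"
    with ref.open() as fh:
        return load_compound_panel(fh)


def targets_to_frame(targets: list[AdductTarget]) -> pd.DataFrame:
    """Tidy table of a target panel (one row per m/z channel)."""
    rows = []
    for t in targets:
        warnings = []
        if t.source_compound.tag_warning is not TagWarning.none:
            warnings.append(t.source_compound.tag_warning.value)
        if not t.in_range:
            warnings.append("out_of_range")
        for c in t.collisions:
            kind = "degenerate_pair" if c.degenerate else "collision"
            warnings.append(f"{kind}:{c.other.name}")
        rows.append(
            {
                "name": t.name,
                "role": t.role,
                "donor": t.donor_name or "",
                "formula": str(t.source_compound.formula),
                "mass": t.source_compound.monoisotopic_mass,
                "conjugate_mz": t.conjugate_mz,
                "warnings": ";".join(warnings),
            }
        )
    return pd.DataFrame(rows)
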