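"""Lipid shorthand nomenclature, chemical formulas and the subclass ontology.

Widely targeted lipidomics platforms annotate each measured species with a
shorthand name such as ``PC (16:0_16:1)`` or ``Carnitine C3:0``: a subclass
token followed by the acyl chains written ``<carbons>:<double bonds>``.
This module parses those names, maps subclasses onto the six LIPID MAPS-style
categories (FA, GL, GP, PR, SP, ST), parses molecular formulas, and computes
monoisotopic masses, which is what vendor "molecular weight" columns report.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "LipidParseError",
    "LipidSpecies",
    "FattyAcidLabel",
    "load_ontology",
    "subclass_to_class",
    "parse_lipid_name",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "classify_fatty_acid",
    "load_marker_table",
]

LIPID_CLASSES = ("FA", "GL", "GP", "PR", "SP", "ST")

#: Monoisotopic atomic masses (Da) of the elements occurring in lipid formulas.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

_PROTON = 1.00727646688
_FORMATE = 44.99820285  # HCOO- : CHO2 minus an electron's worth is negligible at 2 dp


class LipidParseError(ValueError):
    """A lipid name, formula or fatty-acid shorthand could not be parsed."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation.

    ``chains`` holds ``(carbons, double_bonds)`` per acyl chain; the ``_`` and
    ``/`` chain separators are treated identically because sn-position is not
    resolved by the assay.
    """

    name: str
    subclass: str
    lipid_class: str
    chains: tuple[tuple[int, int], ...]
    formula: Mapping[str, int] | None = None
    ionization: str | None = None
    molecular_weight: float | None = None

    def __post_init__(self) -> None:
        for carbons, double_bonds in self.chains:
            if carbons < 1 or double_bonds < 0:
                raise ValueError(
                    f"invalid chain ({carbons}:{double_bonds}) in {self.name!r}"
                )
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.formula is not None and any(v <= 0 for v in self.formula.values()):
            raise ValueError("element counts must be positive")


@dataclass(frozen=True)
class FattyAcidLabel:
    """GC-style fatty-acid shorthand, e.g. ``C18:1n9c``."""

    shorthand: str
    carbons: int
    double_bonds: int
    saturation: str = field(init=False)

    def __post_init__(self) -> None:
        if self.double_bonds == 0:
            sat = "SFA"
        elif self.double_bonds == 1:
            sat = "MUFA"
        else:
            sat = "PUFA"
        object.__setattr__(self, "saturation", sat)


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("lipimark.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def load_ontology(path: str | None = None) -> dict[str, str]:
    """Load the subclass → class map (editable two-column CSV).

    The shipped file covers the subclasses commonly reported by targeted
    lipidomics panels; pass ``path`` to extend or replace it.
    """
    if path is None:
        rows = _read_packaged_csv("lipid_ontology.csv")
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    ontology: dict[str, str] = {}
    for row in rows:
        code, cls = row["subclass"].strip(), row["class"].strip()
        if cls not in LIPID_CLASSES:
            raise LipidParseError(f"ontology class {cls!r} not one of {LIPID_CLASSES}")
        ontology[code] = cls
    return ontology


_DEFAULT_ONTOLOGY: dict[str, str] | None = None


def _ontology(ontology: Mapping[str, str] | None) -> Mapping[str, str]:
    global _DEFAULT_ONTOLOGY
    if ontology is not None:
        return ontology
    if _DEFAULT_ONTOLOGY is None:
        _DEFAULT_ONTOLOGY = load_ontology()
    return _DEFAULT_ONTOLOGY


def subclass_to_class(subclass: str, ontology: Mapping[str, str] | None = None) -> str:
    """Map a subclass code (PC, TG, CAR, ...) to its lipid class."""
    table = _ontology(ontology)
    try:
        return table[subclass]
    except KeyError:
        known = ", ".join(sorted(table))
        raise LipidParseError(
            f"unknown lipid subclass {subclass!r}; known codes: {known}"
        ) from None


_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_CARNITINE_RE = re.compile(r"^Carnitine\s+C(\d+):(\d+)$", re.IGNORECASE)
_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*(?:-[OP])?)\s*\(([^()]+)\)$")


def parse_lipid_name(
    name: str,
    ontology: Mapping[str, str] | None = None,
    formula: str | None = None,
    ionization: str | None = None,
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Recognized shapes are ``SUBCLASS (c1:d1_c2:d2...)`` (``/`` also accepted
    as chain separator, ether ``-O`` / plasmalogen ``-P`` suffixes kept on the
    subclass) and ``Carnitine Cn:d`` which maps to subclass CAR.
    Unknown subclass tokens raise :class:`LipidParseError` naming the token.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    name = name.strip()

    m = _CARNITINE_RE.match(name)
    if m:
        chains = ((int(m.group(1)), int(m.group(2))),)
        subclass = "CAR"
    else:
        m = _NAME_RE.match(name)
        if not m:
            raise LipidParseError(f"unrecognized lipid name syntax: {name!r}")
        subclass = m.group(1)
        chain_field = m.group(2)
        chains_list = []
        for token in re.split(r"[_/]", chain_field):
            token = token.strip()
            cm = _CHAIN_RE.match(token)
            if not cm:
                raise LipidParseError(f"bad chain token {token!r} in {name!r}")
            chains_list.append((int(cm.group(1)), int(cm.group(2))))
        chains = tuple(chains_list)

    lipid_class = subclass_to_class(subclass, ontology)

    elements = parse_formula(formula) if formula else None
    mw = round(monoisotopic_mass(elements), 2) if elements else None
    return LipidSpecies(
        name=name,
        subclass=subclass,
        lipid_class=lipid_class,
        chains=chains,
        formula=elements,
        ionization=ionization,
        molecular_weight=mw,
    )


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula (e.g. ``C23H45NO4``) to an element→count map.

    Underscore-decorated vendor dialects (``C_23_H_45_NO_4_``) are accepted.
    Only elements with a known monoisotopic mass (C, H, N, O, P, S) are valid.
    """
    if not formula or not formula.strip():
        raise LipidParseError("empty formula")
    clean = formula.replace("_", "").strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(clean):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise LipidParseError(f"cannot parse formula {formula!r} at {clean[pos:]!r}")
        pos = m.end()
        element = m.group(1)
        if element not in MONOISOTOPIC_MASS:
            raise LipidParseError(f"unknown element {element!r} in {formula!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n <= 0:
            raise LipidParseError(f"non-positive count for {element} in {formula!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(clean):
        raise LipidParseError(f"cannot parse formula {formula!r} at {clean[pos:]!r}")
    return counts


def formula_to_string(elements: Mapping[str, int]) -> str:
    """Canonical Hill-order string: C, H, then remaining elements alphabetically."""
    order = [e for e in ("C", "H") if e in elements]
    order += sorted(e for e in elements if e not in ("C", "H"))
    return "".join(
        f"{e}{elements[e]}" if elements[e] != 1 else e for e in order
    )


def monoisotopic_mass(elements: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    try:
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in elements.items())
    except KeyError as exc:
        raise LipidParseError(f"unknown element {exc.args[0]!r}") from None


def adduct_mz(neutral_mass: float, ionization: str) -> float:
    """m/z of the common ESI adducts used by targeted lipidomics panels.

    Convenience only; downstream analysis works with neutral masses.
    """
    key = ionization.replace("−", "-").replace(" ", "")
    table = {
        "[M+H]+": neutral_mass + _PROTON,
        "[M-H]-": neutral_mass - _PROTON,
        "[M+COOH]-": neutral_mass + _FORMATE,
        "[M+HCOO]-": neutral_mass + _FORMATE,
    }
    try:
        return table[key]
    except KeyError:
        raise LipidParseError(f"unknown ionization model {ionization!r}") from None


_FA_RE = re.compile(r"^C(\d+):(\d+)(?:n\d+)?(?:[ct])?$")


def classify_fatty_acid(shorthand: str) -> FattyAcidLabel:
    """Classify GC fatty-acid shorthand into SFA / MUFA / PUFA.

    Saturation follows the double-bond count: 0 → SFA, 1 → MUFA, ≥2 → PUFA.
    Optional omega-position / cis-trans suffixes (``n9c``, ``n6``, ``n3``)
    are accepted and ignored for classification.
    """
    m = _FA_RE.match(shorthand.strip())
    if not m:
        raise LipidParseError(f"malformed fatty-acid shorthand {shorthand!r}")
    return FattyAcidLabel(
        shorthand=shorthand.strip(),
        carbons=int(m.group(1)),
        double_bonds=int(m.group(2)),
    )


def load_marker_table() -> list[LipidSpecies]:
    """The ten marker lipids shipped with the package (name, formula, adduct)."""
    species = []
    for row in _read_packaged_csv("marker_lipids.csv"):
        species.append(
            parse_lipid_name(
                row["name"], formula=row["formula"], ionization=row["ionization"]
            )
        )
    return species
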