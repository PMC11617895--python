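"""Lipid shorthand nomenclature parsing and the double-bond index.

Species are named at the sum-composition level, ``<CLASS> <carbons>:<double_bonds>``
(e.g. ``PC O-34:3``), where the ether/plasmalogen suffix (``O-`` / ``P-``) belongs to
the class token.  The double-bond index (DBI) of a species is its total number of
double bonds divided by the number *k* of side chains — k = 3 for triglycerides,
k = 1 for lyso-species, cholesteryl esters and acylcarnitines, and k = 2 for all
remaining (diacyl/ether diradyl) classes.  DBI is the per-chain unsaturation proxy
used for PUFA over-representation analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

#: The 14 quantified lipid classes (positive-mode direct-infusion panel).
LIPID_CLASSES: tuple[str, ...] = (
    "CAR", "CE", "DAG", "TAG", "Cer", "SM",
    "PE", "PE P-", "LPE", "PC", "PC O-", "LPC", "LPC O-", "PI",
)

#: Ether (plasmanyl "O-" / plasmenyl "P-") classes.
ETHER_CLASSES: frozenset[str] = frozenset({"PC O-", "PE P-", "LPC O-"})

#: Single-chain classes (lyso-species, cholesteryl esters, acylcarnitines).
_MONOACYL_CLASSES: frozenset[str] = frozenset({"LPC", "LPC O-", "LPE", "CE", "CAR"})


class LipidNameError(ValueError):
    """Raised when a shorthand name cannot be parsed."""


def chains_for_class(lipid_class: str) -> int:
    """Number of side chains *k* for a lipid class."""
    if lipid_class == "TAG":
        return 3
    if lipid_class in _MONOACYL_CLASSES:
        return 1
    return 2


@dataclass(frozen=True)
class LipidSpecies:
    """Structured annotation of one sum-composition lipid species."""

    name: str
    lipid_class: str
    carbons: int
    double_bonds: int
    ether: bool
    k_chains: int
    dbi: Fraction

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidNameError(f"unknown lipid class: {self.lipid_class!r}")
        if self.carbons < 0 or self.double_bonds < 0:
            raise LipidNameError("carbons and double bonds must be non-negative")
        if self.k_chains != chains_for_class(self.lipid_class):
            raise LipidNameError(
                f"k_chains {self.k_chains} inconsistent with class {self.lipid_class!r}"
            )
        if self.dbi != Fraction(self.double_bonds, self.k_chains):
            raise LipidNameError("dbi must equal double_bonds / k_chains")

    @property
    def canonical_name(self) -> str:
        return format_lipid_name(self.lipid_class, self.carbons, self.double_bonds)


# Class tokens sorted longest-first so "PC O-" wins over "PC".  Ether class
# tokens end in "-" and attach directly to the carbon count (PC O-34:3);
# plain classes are separated by whitespace (PC 38:6).
def _token_pattern(cls: str) -> str:
    # internal whitespace in a class token ("PC O-") may repeat on input
    return re.escape(cls).replace(r"\ ", r"\s+")


_ETHER_ALT = "|".join(
    _token_pattern(c) for c in sorted(ETHER_CLASSES, key=len, reverse=True)
)
_PLAIN_ALT = "|".join(
    _token_pattern(c)
    for c in sorted(set(LIPID_CLASSES) - ETHER_CLASSES, key=len, reverse=True)
)
_NAME_RE = re.compile(
    rf"^\s*(?:(?P<eth>{_ETHER_ALT})\s*|(?P<plain>{_PLAIN_ALT})\s+)"
    rf"(?P<c>\d+):(?P<d>\d+)\s*$"
)


def format_lipid_name(lipid_class: str, carbons: int, double_bonds: int) -> str:
    """Canonical shorthand: ether suffixes attach to C:D, plain classes use a space."""
    if lipid_class not in LIPID_CLASSES:
        raise LipidNameError(f"unknown lipid class: {lipid_class!r}")
    sep = "" if lipid_class.endswith("-") else " "
    return f"{lipid_class}{sep}{carbons}:{double_bonds}"


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse ``<CLASS> <carbons>:<double_bonds>`` into a :class:`LipidSpecies`.

    Repeated internal whitespace is tolerated; the emitted canonical name always
    uses a single space.  Raises :class:`LipidNameError` naming the offending
    token for unknown classes or malformed carbon:double-bond fields.
    """
    if not isinstance(name, str):
        raise LipidNameError(f"lipid name must be a string, got {type(name).__name__}")
    m = _NAME_RE.match(name)
    if m is None:
        # Diagnose which part failed for a useful message.
        tail = re.search(r"(\d+:\d+)\s*$", name)
        if tail is not None:
            cls_token = name[: tail.start()].strip()
            raise LipidNameError(f"unknown lipid class token: {cls_token!r}")
        raise LipidNameError(f"malformed carbon:double-bond field in {name!r}")
    lipid_class = re.sub(r"\s+", " ", m.group("eth") or m.group("plain"))
    carbons = int(m.group("c"))
    double_bonds = int(m.group("d"))
    k = chains_for_class(lipid_class)
    return LipidSpecies(
        name=format_lipid_name(lipid_class, carbons, double_bonds),
        lipid_class=lipid_class,
        carbons=carbons,
        double_bonds=double_bonds,
        ether=lipid_class in ETHER_CLASSES,
        k_chains=k,
        dbi=Fraction(double_bonds, k),
    )


def median_dbi(species: Sequence[LipidSpecies]) -> Fraction:
    """Median double-bond index of a non-empty species list.

    Even-length lists return the midpoint of the two central order statistics
    (exact rational arithmetic).
    """
    if len(species) == 0:
        raise ValueError("median_dbi requires a non-empty species list")
    values = sorted(s.dbi for s in species)
    n = len(values)
    if n % 2 == 1:
        return values[n // 2]
    return (values[n // 2 - 1] + values[n // 2]) / 2


def annotate_panel(names: Iterable[str]) -> pd.DataFrame:
    """Annotation table for a lipid panel.

    Columns: name, class, carbons, double_bonds, ether, k_chains, dbi
    (dbi as float for tabular export), indexed by canonical name.
    """
    rows = []
    for name in names:
        s = parse_lipid_name(name)
        rows.append(
            {
                "name": s.name,
                "class": s.lipid_class,
                "carbons": s.carbons,
                "double_bonds": s.double_bonds,
                "ether": s.ether,
                "k_chains": s.k_chains,
                "dbi": float(s.dbi),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("name", drop=False)
        df.index.name = None
    return df
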