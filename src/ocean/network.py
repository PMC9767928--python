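"""Domain types for compartmentalised metabolic reaction networks.

A :class:`ReactionNetwork` holds direction-resolved reactions over
compartment-tagged metabolite species.  Species identifiers carry the
compartment as a suffix (``glc_c``, ``glc_m``); ``base_name`` is the
compartment-free label used when footprints are collapsed for reporting.

The on-disk dialect is two CSV files, ``metabolites.csv`` (species_id,
base_name, compartment, formula) and ``reactions.csv`` (reaction_id,
reactants, products, direction, gpr), with reactant/product cells encoded
as semicolon-separated ``coef*species_id`` tokens — chosen so toy fixtures
stay hand-editable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, FormulaError, IntegrityError

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionNetwork",
    "atom_count_from_formula",
    "read_reaction_table",
    "write_reaction_table",
    "write_sif",
]

DIRECTIONS = ("forward", "backward", "reversible")

# element symbol followed by an optional multiplicity, e.g. C6 H12 O6
_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def atom_count_from_formula(formula: str) -> int:
    """Total number of atoms in an elemental formula string.

    ``"CO2"`` -> 3, ``"C6H13NO2"`` -> 22.  Raises :class:`FormulaError` on a
    string that is not a plain element-count formula (charges, parentheses
    and isotope markers are not supported).
    """
    if not isinstance(formula, str) or not formula:
        raise FormulaError(f"not a formula: {formula!r}")
    pos = 0
    total = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {formula!r} at position {pos}")
        total += int(m.group(2)) if m.group(2) else 1
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"malformed formula {formula!r} at position {pos}")
    return total


@dataclass(frozen=True)
class Metabolite:
    """A compartment-tagged metabolite species."""

    species_id: str
    base_name: str
    compartment: str
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            raise IntegrityError(f"metabolite {self.species_id!r} has empty compartment")

    @property
    def atom_count(self) -> int | None:
        """Atom count from the formula; ``None`` when absent or malformed.

        Species without a parseable formula keep an absent count and are
        never removed by the size filter (conservative treatment).
        """
        if self.formula is None:
            return None
        try:
            return atom_count_from_formula(self.formula)
        except FormulaError:
            return None


@dataclass(frozen=True)
class Reaction:
    """A direction-resolved reaction with stoichiometry and a gene rule.

    ``gpr`` is a boolean AND/OR expression over gene identifiers (may be
    empty).  Stoichiometric coefficients are validated and carried but do
    not influence graph construction.
    """

    reaction_id: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    direction: str = "forward"
    gpr: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise IntegrityError(
                f"reaction {self.reaction_id!r}: direction must be one of "
                f"{DIRECTIONS}, got {self.direction!r}"
            )
        for side in (self.reactants, self.products):
            for sid, coef in side:
                if coef <= 0:
                    raise IntegrityError(
                        f"reaction {self.reaction_id!r}: non-positive coefficient "
                        f"{coef} for {sid!r}"
                    )
        overlap = {s for s, _ in self.reactants} & {s for s, _ in self.products}
        if overlap:
            raise IntegrityError(
                f"reaction {self.reaction_id!r}: species on both sides: {sorted(overlap)}"
            )

    @property
    def reactant_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.reactants)

    @property
    def product_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.products)


@dataclass
class ReactionNetwork:
    """A validated collection of metabolites and reactions."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    def validate(self) -> "ReactionNetwork":
        dangling: list[str] = []
        for rxn in self.reactions.values():
            for sid in rxn.reactant_ids + rxn.product_ids:
                if sid not in self.metabolites:
                    dangling.append(f"{sid} (reaction {rxn.reaction_id})")
        if dangling:
            raise IntegrityError("dangling species references: " + ", ".join(sorted(dangling)))
        return self

    @classmethod
    def from_lists(
        cls, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]
    ) -> "ReactionNetwork":
        mets: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.species_id in mets:
                raise IntegrityError(f"duplicate species_id {m.species_id!r}")
            mets[m.species_id] = m
        rxns: dict[str, Reaction] = {}
        for r in reactions:
            if r.reaction_id in rxns:
                raise IntegrityError(f"duplicate reaction_id {r.reaction_id!r}")
            rxns[r.reaction_id] = r
        return cls(mets, rxns).validate()

    def base_names(self) -> dict[str, str]:
        """species_id -> compartment-free base name."""
        return {sid: m.base_name for sid, m in self.metabolites.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.metabolites == other.metabolites and self.reactions == other.reactions


def _parse_side(cell: object, reaction_id: str) -> tuple[tuple[str, float], ...]:
    """Parse a semicolon-separated ``coef*species`` cell; bare ids mean coef 1."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    out: list[tuple[str, float]] = []
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        if "*" in token:
            coef_s, _, sid = token.partition("*")
            try:
                coef = float(coef_s)
            except ValueError as exc:
                raise FormatError(
                    f"reaction {reaction_id!r}: bad coefficient in token {token!r}"
                ) from exc
        else:
            coef, sid = 1.0, token
        out.append((sid.strip(), coef))
    return tuple(out)


def _format_side(side: Sequence[tuple[str, float]]) -> str:
    return ";".join(
        sid if coef == 1 else f"{coef:g}*{sid}" for sid, coef in side
    )


_REACTION_COLS = ["reaction_id", "reactants", "products", "direction", "gpr"]
_METABOLITE_COLS = ["species_id", "base_name", "compartment", "formula"]


def read_reaction_table(
    path: str | Path,
    reactions_file: str = "reactions.csv",
    metabolites_file: str = "metabolites.csv",
) -> ReactionNetwork:
    """Read a network from a directory holding the two-CSV reaction table.

    Row order never affects the result.  Missing columns raise
    :class:`FormatError` naming the column; dangling references and duplicate
    ids raise :class:`IntegrityError`.  Malformed formulas are kept (the
    species retains an absent atom count) with a warning.
    """
    path = Path(path)
    met_df = pd.read_csv(path / metabolites_file, dtype=str).fillna("")
    rxn_df = pd.read_csv(path / reactions_file, dtype=str).fillna("")
    for col in _METABOLITE_COLS[:3]:
        if col not in met_df.columns:
            raise FormatError(f"{metabolites_file}: missing column {col!r}")
    if "formula" not in met_df.columns:
        met_df["formula"] = ""
    for col in _REACTION_COLS:
        if col not in rxn_df.columns:
            raise FormatError(f"{reactions_file}: missing column {col!r}")

    metabolites = []
    for row in met_df.itertuples(index=False):
        formula = row.formula or None
        if formula is not None:
            try:
                atom_count_from_formula(formula)
            except FormulaError:
                warnings.warn(
                    f"species {row.species_id!r}: unparseable formula {formula!r}; "
                    "atom count left absent",
                    stacklevel=2,
                )
        metabolites.append(
            Metabolite(row.species_id, row.base_name, row.compartment, formula)
        )
    reactions = [
        Reaction(
            row.reaction_id,
            _parse_side(row.reactants, row.reaction_id),
            _parse_side(row.products, row.reaction_id),
            row.direction or "forward",
            row.gpr,
        )
        for row in rxn_df.itertuples(index=False)
    ]
    return ReactionNetwork.from_lists(metabolites, reactions)


def write_reaction_table(
    network: ReactionNetwork,
    path: str | Path,
    reactions_file: str = "reactions.csv",
    metabolites_file: str = "metabolites.csv",
) -> None:
    """Write a network as the two-CSV reaction table (rows sorted by id)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    met_rows = [
        {
            "species_id": m.species_id,
            "base_name": m.base_name,
            "compartment": m.compartment,
            "formula": m.formula or "",
        }
        for m in sorted(network.metabolites.values(), key=lambda m: m.species_id)
    ]
    rxn_rows = [
        {
            "reaction_id": r.reaction_id,
            "reactants": _format_side(r.reactants),
            "products": _format_side(r.products),
            "direction": r.direction,
            "gpr": r.gpr,
        }
        for r in sorted(network.reactions.values(), key=lambda r: r.reaction_id)
    ]
    pd.DataFrame(met_rows, columns=_METABOLITE_COLS).to_csv(
        path / metabolites_file, index=False
    )
    pd.DataFrame(rxn_rows, columns=_REACTION_COLS).to_csv(
        path / reactions_file, index=False
    )


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write edges as 3-column tab-separated SIF, sorted by (source, target).

    The relation column is the constant ``"1"``: each row is either
    activation of an enzyme by its reactant or activation of a product by
    its enzyme.
    """
    rows = sorted(edges, key=lambda e: (e[0], e[2]))
    with open(path, "w") as fh:
        for src, rel, dst in rows:
            if rel != "1":
                raise FormatError(f"SIF relation must be '1', got {rel!r}")
            fh.write(f"{src}\t{rel}\t{dst}\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a 3-column SIF file back into an edge list."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            edges.append((parts[0], parts[1], parts[2]))
    return edges
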