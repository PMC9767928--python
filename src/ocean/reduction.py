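"""Accessory-metabolite filtering applied before graph construction.

Currency metabolites (cofactors, nucleotides), a few explicitly named small
molecules, species under four atoms and over-promiscuous species (reactants
of more than 100 reactions) short-circuit path tracing in metabolic graphs;
removing them keeps enzyme-metabolite distances biologically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import IntegrityError
from .network import Reaction, ReactionNetwork

__all__ = ["FilterConfig", "reactant_degree", "apply_filters", "load_species_list"]

DEFAULT_EXPLICIT_REMOVALS = frozenset({"CO2", "ITP", "IDP", "NADH"})


@dataclass
class FilterConfig:
    """Parameters of the accessory-metabolite filter.

    cofactor_classes
        Species ids flagged cofactor/nucleotide by an external class list
        (e.g. derived from KEGG BRITE); matched on species_id.
    explicit_removals
        Base names always removed; defaults to {CO2, ITP, IDP, NADH}.
    min_atoms
        Remove species whose atom count is known and below this (default 4).
    promiscuity_threshold
        Remove species used as a reactant by more than this many reactions
        (default 100), counted on the input network.
    """

    cofactor_classes: frozenset[str] = frozenset()
    explicit_removals: frozenset[str] = DEFAULT_EXPLICIT_REMOVALS
    min_atoms: int = 4
    promiscuity_threshold: int = 100

    def __post_init__(self) -> None:
        if self.min_atoms <= 0 or self.promiscuity_threshold <= 0:
            raise ValueError("filter thresholds must be positive")
        self.cofactor_classes = frozenset(self.cofactor_classes)
        self.explicit_removals = frozenset(self.explicit_removals)


def reactant_degree(network: ReactionNetwork, species_id: str) -> int:
    """Number of distinct reactions using the species as a reactant.

    Appearances as a product do not count; a reversible reaction counts once.
    """
    if species_id not in network.metabolites:
        raise IntegrityError(f"unknown species {species_id!r}")
    return sum(1 for r in network.reactions.values() if species_id in r.reactant_ids)


def _strip_species(rxn: Reaction, removed: set[str]) -> Reaction | None:
    reactants = tuple((s, c) for s, c in rxn.reactants if s not in removed)
    products = tuple((s, c) for s, c in rxn.products if s not in removed)
    if not reactants and not products:
        return None
    # a reaction keeping only one side still anchors its enzyme instances
    return Reaction(rxn.reaction_id, reactants, products, rxn.direction, rxn.gpr)


def apply_filters(
    network: ReactionNetwork, config: FilterConfig | None = None
) -> tuple[ReactionNetwork, pd.DataFrame]:
    """Remove accessory metabolites in a single pass.

    Returns the reduced network and a report DataFrame (species_id, rules)
    listing every removed species with the comma-joined rules that fired:
    ``cofactor_class``, ``explicit``, ``min_atoms``, ``promiscuity``.
    Promiscuity degrees are computed once, on the input network.
    """
    config = config or FilterConfig()
    degree = {
        sid: reactant_degree(network, sid) for sid in network.metabolites
    }
    removed: dict[str, list[str]] = {}
    for sid, met in network.metabolites.items():
        rules = []
        if sid in config.cofactor_classes:
            rules.append("cofactor_class")
        if met.base_name in config.explicit_removals:
            rules.append("explicit")
        count = met.atom_count
        if count is not None and count < config.min_atoms:
            rules.append("min_atoms")
        if degree[sid] > config.promiscuity_threshold:
            rules.append("promiscuity")
        if rules:
            removed[sid] = rules

    removed_set = set(removed)
    metabolites = {
        sid: m for sid, m in network.metabolites.items() if sid not in removed_set
    }
    reactions = {}
    for rid, rxn in network.reactions.items():
        stripped = _strip_species(rxn, removed_set)
        if stripped is not None:
            reactions[rid] = stripped

    report = pd.DataFrame(
        [
            {"species_id": sid, "rules": ",".join(rules)}
            for sid, rules in sorted(removed.items())
        ],
        columns=["species_id", "rules"],
    )
    return ReactionNetwork(metabolites, reactions).validate(), report


def load_species_list(path: str | Path) -> frozenset[str]:
    """Load a one-entry-per-line species list; '#' starts a comment."""
    entries = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                entries.add(line)
    return frozenset(entries)
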