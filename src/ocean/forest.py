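"""Enzyme instances, the bipartite instance graph, and the footprint forest.

Gene-reaction rules are expanded to disjunctive normal form; every OR
disjunct (a gene, or an AND-complex of genes) bound to one specific reaction
becomes an :class:`EnzymeInstance` — the unique root of one footprint tree.
Edges run reactant -> instance (the reactant must be present for the enzyme
to act) and instance -> product (the product depends on the enzyme), so
following edge direction walks down the flux and the reversed graph walks up
it.  Distances count reactions traversed: a direct product or reactant of
the root sits at distance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import GPRParseError, IntegrityError
from .network import ReactionNetwork

__all__ = [
    "EnzymeInstance",
    "expand_gpr",
    "parse_gpr",
    "build_instance_graph",
    "build_forest",
    "channel_forest",
    "graph_to_sif_edges",
    "graph_from_sif_edges",
    "forest_to_json",
    "forest_from_json",
]

# forest: {root_id: {species_id: {"down": int | None, "up": int | None}}}
Forest = dict[str, dict[str, dict[str, int | None]]]


@dataclass(frozen=True)
class EnzymeInstance:
    """A catalyst (gene or AND-complex) bound to one reaction (and direction)."""

    instance_id: str
    catalyst_members: frozenset[str]
    reaction_id: str

    def __post_init__(self) -> None:
        if not self.catalyst_members:
            raise IntegrityError(f"instance {self.instance_id!r} has no catalyst members")


def _tokenize_gpr(expr: str) -> list[str]:
    tokens: list[str] = []
    buf = ""
    for ch in expr:
        if ch in "()":
            if buf:
                tokens.append(buf)
                buf = ""
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append(buf)
                buf = ""
        else:
            buf += ch
    if buf:
        tokens.append(buf)
    return tokens


def parse_gpr(expr: str) -> frozenset[frozenset[str]]:
    """Parse an AND/OR gene rule into DNF: a set of gene-set disjuncts.

    ``"(g1 AND g2) OR g3"`` -> ``{{g1, g2}, {g3}}``.  AND binds tighter than
    OR; keywords are case-insensitive; anything else is a gene identifier.
    Empty expression -> empty set.
    """
    tokens = _tokenize_gpr(expr)
    if not tokens:
        return frozenset()
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str) -> GPRParseError:
        return GPRParseError(f"cannot parse gene rule {expr!r}: {msg}")

    def parse_or() -> frozenset[frozenset[str]]:
        nonlocal pos
        disjuncts = set(parse_and())
        while peek() is not None and peek().upper() == "OR":
            pos += 1
            disjuncts |= parse_and()
        return frozenset(disjuncts)

    def parse_and() -> frozenset[frozenset[str]]:
        nonlocal pos
        result = parse_atom()
        while peek() is not None and peek().upper() == "AND":
            pos += 1
            right = parse_atom()
            # distribute AND over the disjuncts of both sides
            result = frozenset(a | b for a in result for b in right)
        return result

    def parse_atom() -> frozenset[frozenset[str]]:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise fail("unexpected end of expression")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise fail("unbalanced parenthesis")
            pos += 1
            return inner
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise fail(f"unexpected token {tok!r}")
        pos += 1
        return frozenset({frozenset({tok})})

    result = parse_or()
    if pos != len(tokens):
        raise fail(f"trailing tokens {tokens[pos:]!r}")
    return result


def _instance_id(members: frozenset[str], reaction_id: str) -> str:
    return "+".join(sorted(members)) + "@" + reaction_id


def expand_gpr(reaction) -> list[EnzymeInstance]:
    """Expand a reaction's gene rule into enzyme instances.

    Each DNF disjunct becomes one instance; an AND-complex is a single
    entity with all its genes as members.  A reaction without a gene rule
    gets one synthetic ``orphan:<reaction_id>`` catalyst so spontaneous and
    transport steps still propagate distance.
    """
    dnf = parse_gpr(reaction.gpr)
    if not dnf:
        members = frozenset({f"orphan:{reaction.reaction_id}"})
        return [EnzymeInstance(_instance_id(members, reaction.reaction_id), members,
                               reaction.reaction_id)]
    return [
        EnzymeInstance(_instance_id(members, reaction.reaction_id), members,
                       reaction.reaction_id)
        for members in sorted(dnf, key=lambda m: "+".join(sorted(m)))
    ]


def build_instance_graph(network: ReactionNetwork) -> nx.DiGraph:
    """Build the bipartite directed enzyme-instance / metabolite graph.

    Backward reactions are oriented by swapping sides; a reversible reaction
    expands into two opposed instances (``@fwd`` and ``@bwd``), preserving
    the upstream/downstream semantics for both senses.
    """
    g = nx.DiGraph()
    for sid in sorted(network.metabolites):
        g.add_node(sid, kind="metabolite")
    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        for inst in expand_gpr(rxn):
            if rxn.direction == "forward":
                variants = [(inst.instance_id, rxn.reactant_ids, rxn.product_ids)]
            elif rxn.direction == "backward":
                variants = [(inst.instance_id, rxn.product_ids, rxn.reactant_ids)]
            else:  # reversible: two opposed instances
                variants = [
                    (inst.instance_id + "@fwd", rxn.reactant_ids, rxn.product_ids),
                    (inst.instance_id + "@bwd", rxn.product_ids, rxn.reactant_ids),
                ]
            for node_id, sources, targets in variants:
                g.add_node(
                    node_id,
                    kind="enzyme",
                    members=inst.catalyst_members,
                    reaction_id=rid,
                )
                for sid in sources:
                    g.add_edge(sid, node_id)
                for sid in targets:
                    g.add_edge(node_id, sid)
    return g


def enzyme_nodes(graph: nx.DiGraph) -> list[str]:
    return sorted(n for n, k in graph.nodes(data="kind") if k == "enzyme")


def metabolite_nodes(graph: nx.DiGraph) -> list[str]:
    return sorted(n for n, k in graph.nodes(data="kind") if k == "metabolite")


def _bfs_reaction_distances(graph: nx.DiGraph, source: str, offset: int) -> dict[str, int]:
    """Shortest reaction-step distance from ``source`` to every metabolite.

    On the bipartite graph the hop count to a metabolite determines the
    number of enzyme nodes on the path; ``offset`` converts hops to the
    reaction count (root enzyme counts as the first reaction).
    """
    hops = nx.single_source_shortest_path_length(graph, source)
    out = {}
    for node, h in hops.items():
        if h > 0 and graph.nodes[node]["kind"] == "metabolite":
            out[node] = (h + offset) // 2
    return out


def build_forest(graph: nx.DiGraph, roots: Iterable[str] | None = None) -> Forest:
    """Breadth-first footprint of every root: minimal down/up reaction distances.

    For each enzyme-instance root the directed graph gives ``down`` distances
    (products and their descendants) and the edge-reversed graph gives ``up``
    distances (reactants and their ancestors).  Unreachable species are
    absent; species on cycles through the root carry both entries.
    """
    if roots is None:
        roots = enzyme_nodes(graph)
    else:
        roots = list(roots)
        for r in roots:
            if r not in graph or graph.nodes[r].get("kind") != "enzyme":
                raise IntegrityError(f"unknown enzyme-instance root {r!r}")
    reverse = graph.reverse(copy=False)
    forest: Forest = {}
    for root in roots:
        down = _bfs_reaction_distances(graph, root, offset=1)
        up = _bfs_reaction_distances(reverse, root, offset=1)
        entry: dict[str, dict[str, int | None]] = {}
        for sid in sorted(set(down) | set(up)):
            entry[sid] = {"down": down.get(sid), "up": up.get(sid)}
        forest[root] = entry
    return forest


def channel_forest(
    graph: nx.DiGraph,
    root: str,
    seed_product: str | None = None,
    seed_reactant: str | None = None,
) -> Forest:
    """Footprint of one root restricted to a single reactant/product channel.

    When a reaction has several products (or reactants), the footprint can be
    rooted at one chosen direct product (downstream side) and/or one chosen
    direct reactant (upstream side) instead of the whole reaction; the
    unrestricted side falls back to the whole-root traversal.  The seed
    species itself sits at distance 1, exactly as in the full footprint.
    """
    if root not in graph or graph.nodes[root].get("kind") != "enzyme":
        raise IntegrityError(f"unknown enzyme-instance root {root!r}")
    reverse = graph.reverse(copy=False)
    if seed_product is not None:
        if not graph.has_edge(root, seed_product):
            raise IntegrityError(
                f"{seed_product!r} is not a direct product of {root!r}")
        down = _bfs_reaction_distances(graph, seed_product, offset=2)
        down[seed_product] = 1
    else:
        down = _bfs_reaction_distances(graph, root, offset=1)
    if seed_reactant is not None:
        if not graph.has_edge(seed_reactant, root):
            raise IntegrityError(
                f"{seed_reactant!r} is not a direct reactant of {root!r}")
        up = _bfs_reaction_distances(reverse, seed_reactant, offset=2)
        up[seed_reactant] = 1
    else:
        up = _bfs_reaction_distances(reverse, root, offset=1)
    entry = {
        sid: {"down": down.get(sid), "up": up.get(sid)}
        for sid in sorted(set(down) | set(up))
    }
    return {root: entry}


def graph_to_sif_edges(graph: nx.DiGraph) -> list[tuple[str, str, str]]:
    """Flatten the instance graph into (source, "1", target) SIF rows."""
    return [(u, "1", v) for u, v in graph.edges()]


def graph_from_sif_edges(edges: Iterable[tuple[str, str, str]]) -> nx.DiGraph:
    """Rebuild an instance graph from SIF rows.

    Node kinds are recovered from the id convention: enzyme-instance ids
    contain ``@`` (catalyst@reaction), metabolite species ids do not.
    """
    g = nx.DiGraph()
    for src, _, dst in edges:
        for node in (src, dst):
            if node not in g:
                g.add_node(node, kind="enzyme" if "@" in node else "metabolite")
        g.add_edge(src, dst)
    for u, v in g.edges():
        if g.nodes[u]["kind"] == g.nodes[v]["kind"]:
            raise IntegrityError(f"non-bipartite SIF edge {u!r} -> {v!r}")
    return g


def forest_to_json(forest: Forest, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(forest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def forest_from_json(path: str | Path) -> Forest:
    with open(path) as fh:
        return json.load(fh)
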