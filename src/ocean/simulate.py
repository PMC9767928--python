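"""Deterministic synthetic networks and abundance tables with known ground truth.

Every generator is a pure function of a :class:`FixtureSpec`; the integer
seed fully determines the output (numpy PCG64 generator).  Networks cover
the topologies the footprint machinery must handle (chains, branches,
cycles, promiscuous hubs, compartment duplication, AND/OR gene rules);
abundance tables plant a signed, distance-attenuated perturbation around a
chosen enzyme so that parameter-recovery tests have a known answer.

The planted effect reuses the same penalty**(d-1) dissipation law the
scorer applies, which makes recovery a closed loop: passing tests show the
pipeline is self-consistent, not that real metabolomes obey the law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import OceanError
from .forest import build_forest, build_instance_graph
from .network import Metabolite, Reaction, ReactionNetwork
from .stats import AbundanceMatrix
from .weights import signed_weights

__all__ = ["FixtureSpec", "make_network", "make_abundances", "default_planted_root"]

TOPOLOGIES = (
    "chain", "branch", "cycle", "hub_cofactor", "two_compartment",
    "complex_gpr", "random",
)

# generic 16-atom formula: big enough never to hit the 4-atom size filter
_BULK_FORMULA = "C6H10O5"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture (network + abundance matrix)."""

    topology: str = "chain"
    n_species: int = 5
    n_reactions: int | None = None
    seed: int = 0
    planted_enzyme: str | None = None
    effect_size: float = 0.0       # case-group shift in noise-sd units
    noise_sd: float = 0.25         # residual sd on the log2 scale
    n_samples: int = 6             # per group
    n_batches: int = 3
    batch_offsets: tuple[float, ...] | None = None
    n_qc: int = 3
    penalty: float = 0.8           # dissipation of the planted effect
    transport: bool = False        # two_compartment: add a transport reaction

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise OceanError(f"unknown topology {self.topology!r}")
        minimum = {"chain": 2, "branch": 4, "cycle": 3, "hub_cofactor": 4,
                   "two_compartment": 2, "complex_gpr": 4, "random": 3}
        if self.n_species < minimum[self.topology]:
            raise OceanError(
                f"{self.topology} needs >= {minimum[self.topology]} species")
        if self.n_samples < 2 or self.noise_sd <= 0:
            raise OceanError("need >= 2 samples per group and positive noise_sd")


def _met(i: int, comp: str = "c") -> Metabolite:
    return Metabolite(f"m{i:02d}_{comp}", f"m{i:02d}", comp, _BULK_FORMULA)


def _rxn(rid: str, sources: Sequence[str], targets: Sequence[str], gpr: str,
         direction: str = "forward") -> Reaction:
    return Reaction(rid, tuple((s, 1.0) for s in sources),
                    tuple((t, 1.0) for t in targets), direction, gpr)


def make_network(spec: FixtureSpec) -> ReactionNetwork:
    """Generate the requested topology; identical output for identical spec."""
    n = spec.n_species
    rng = np.random.default_rng(spec.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    if spec.topology == "chain":
        mets = [_met(i) for i in range(n)]
        rxns = [
            _rxn(f"r{i:02d}", [mets[i].species_id], [mets[i + 1].species_id], f"g{i:02d}")
            for i in range(n - 1)
        ]
    elif spec.topology == "branch":
        # m00 -> m01, then m01 feeds two branches of alternating species
        mets = [_met(i) for i in range(n)]
        rxns = [_rxn("r00", [mets[0].species_id], [mets[1].species_id], "g00")]
        left = [mets[1]] + mets[2::2]
        right = [mets[1]] + mets[3::2]
        for tag, branch in (("a", left), ("b", right)):
            for j in range(len(branch) - 1):
                rxns.append(
                    _rxn(f"r{tag}{j:02d}", [branch[j].species_id],
                         [branch[j + 1].species_id], f"g{tag}{j:02d}")
                )
    elif spec.topology == "cycle":
        mets = [_met(i) for i in range(n)]
        rxns = [
            _rxn(f"r{i:02d}", [mets[i].species_id],
                 [mets[(i + 1) % n].species_id], f"g{i:02d}")
            for i in range(n)
        ]
    elif spec.topology == "hub_cofactor":
        # chain over half the species, plus one hub consumed by many reactions
        chain_n = max(2, n // 2)
        mets = [_met(i) for i in range(n)]
        hub = Metabolite("hub_c", "hub", "c", _BULK_FORMULA)
        mets.append(hub)
        rxns = [
            _rxn(f"r{i:02d}", [mets[i].species_id], [mets[i + 1].species_id], f"g{i:02d}")
            for i in range(chain_n - 1)
        ]
        n_consumers = spec.n_reactions or 101
        others = mets[chain_n:-1] or mets[:1]
        for k in range(n_consumers):
            tgt = others[k % len(others)]
            src = mets[k % chain_n]
            if tgt.species_id == src.species_id:
                src = mets[(k + 1) % chain_n]
            rxns.append(
                _rxn(f"h{k:03d}", [hub.species_id, src.species_id],
                     [tgt.species_id], f"gh{k:03d}")
            )
    elif spec.topology == "two_compartment":
        mets = [_met(i, "c") for i in range(n)] + [_met(i, "m") for i in range(n)]
        for comp in ("c", "m"):
            rxns += [
                _rxn(f"r{comp}{i:02d}", [f"m{i:02d}_{comp}"], [f"m{i + 1:02d}_{comp}"],
                     f"g{comp}{i:02d}")
                for i in range(n - 1)
            ]
        if spec.transport:
            rxns.append(_rxn("t00", [f"m{n - 1:02d}_c"], ["m00_m"], ""))
    elif spec.topology == "complex_gpr":
        mets = [_met(i) for i in range(n)]
        gprs = ["g00 AND g01", "(g02 AND g03) OR g04", "g05", ""]
        rxns = [
            _rxn(f"r{i:02d}", [mets[i].species_id], [mets[i + 1].species_id],
                 gprs[i % len(gprs)])
            for i in range(n - 1)
        ]
    elif spec.topology == "random":
        mets = [_met(i) for i in range(n)]
        n_rxn = spec.n_reactions if spec.n_reactions is not None else max(3, n)
        attempts = 0
        k = 0
        while k < n_rxn and attempts < 50 * n_rxn:
            attempts += 1
            n_in = int(rng.integers(1, 3))
            n_out = int(rng.integers(1, 3))
            chosen = rng.choice(n, size=min(n, n_in + n_out), replace=False)
            sources = [mets[i].species_id for i in chosen[:n_in]]
            targets = [mets[i].species_id for i in chosen[n_in:n_in + n_out]]
            if not targets:
                continue
            direction = "reversible" if rng.random() < 0.15 else "forward"
            gpr = f"g{int(rng.integers(0, max(2, n)))}"
            rxns.append(_rxn(f"r{k:03d}", sources, targets, gpr, direction))
            k += 1
        if k < n_rxn:
            raise OceanError("could not generate requested number of reactions")

    return ReactionNetwork.from_lists(mets, rxns)


def default_planted_root(network: ReactionNetwork) -> str:
    """Middle enzyme instance of the graph (stable default perturbation site)."""
    from .forest import enzyme_nodes
    nodes = enzyme_nodes(build_instance_graph(network))
    return nodes[len(nodes) // 2]


def make_abundances(
    spec: FixtureSpec, network: ReactionNetwork
) -> tuple[AbundanceMatrix, dict]:
    """Simulate peak areas for every base name in the network.

    Log2 abundances are baseline ~ N(14, 1) per metabolite plus N(0,
    noise_sd) residuals; the case group is shifted by effect_size *
    noise_sd * w(root, m), where w is the signed dissipation weight of the
    planted enzyme (downstream up, upstream down, attenuated per reaction
    step).  Per-batch additive offsets apply to all samples of a batch; QC
    samples sit at the pooled mean of the design samples.  Returns the
    matrix and a ground-truth dict (root, per-metabolite shifts).
    """
    rng = np.random.default_rng(spec.seed + 1)
    base_names = sorted(set(network.base_names().values()))
    n_mets = len(base_names)

    shifts = pd.Series(0.0, index=base_names)
    root = spec.planted_enzyme
    if spec.effect_size != 0.0:
        if root is None:
            root = default_planted_root(network)
        graph = build_instance_graph(network)
        forest = build_forest(graph, roots=[root])
        w = signed_weights(forest, spec.penalty)
        w["base_name"] = w["species_id"].map(network.base_names())
        # strongest (largest-|w|) compartment representative defines the shift
        for base, grp in w.groupby("base_name"):
            idx = grp["weight"].abs().idxmax()
            shifts[base] = spec.effect_size * spec.noise_sd * float(grp.loc[idx, "weight"])

    baseline = rng.normal(14.0, 1.0, size=n_mets)
    if spec.batch_offsets is not None:
        if len(spec.batch_offsets) != spec.n_batches:
            raise OceanError("batch_offsets length must equal n_batches")
        offsets = np.asarray(spec.batch_offsets, float)
    else:
        offsets = rng.normal(0.0, 0.5, size=spec.n_batches)

    samples, groups, batches, is_qc, rows = [], [], [], [], []
    for gi, group in enumerate(("CASE", "CTRL")):
        for j in range(spec.n_samples):
            batch = j % spec.n_batches
            log2_abund = (
                baseline
                + (shifts.values if group == "CASE" else 0.0)
                + offsets[batch]
                + rng.normal(0.0, spec.noise_sd, size=n_mets)
            )
            samples.append(f"{group}_{j:02d}")
            groups.append(group)
            batches.append(f"B{batch}")
            is_qc.append(False)
            rows.append(np.exp2(log2_abund))
    design_rows = np.array(rows)
    pooled = np.log2(design_rows).mean(axis=0)
    for q in range(spec.n_qc):
        samples.append(f"QC_{q:02d}")
        groups.append("")
        batches.append(f"B{q % spec.n_batches}")
        is_qc.append(True)
        rows.append(np.exp2(pooled + rng.normal(0.0, 0.01, size=n_mets)))

    areas = pd.DataFrame(rows, index=pd.Index(samples, name="sample"), columns=base_names)
    design = pd.DataFrame(
        {"group": groups, "batch": batches, "is_qc": is_qc},
        index=pd.Index(samples, name="sample"),
    )
    truth = {
        "planted_root": root,
        "effect_size": spec.effect_size,
        "shifts": {b: float(s) for b, s in shifts.items() if s != 0.0},
    }
    return AbundanceMatrix(areas, design), truth
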