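"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from first principles (plain
dictionaries, exhaustive enumeration) and do not reuse the package's graph
or inference code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phylorecon.phylo import EdgeCPD, Phylogeny
from phylorecon.reactions import Molecule, Reaction, ReactionDB, parse_formula


# ---------------------------------------------------------------------------
# Independent gaplessness oracle (plain BFS over mapping pairs)


def gapless_violations(db: ReactionDB, accepted: set[str]) -> list[tuple[str, tuple]]:
    """Substrate atoms of accepted reactions not traceable to nutrient atoms.

    Reachability is recomputed here from the raw mapping pairs with a plain
    BFS, independent of the package's atom-graph code.
    """
    adj: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for rid in accepted:
        rxn = db.reactions[rid]
        for (sm, _, sa), (pm, _, pa) in db.mappings[rid].pairs:
            if rxn.direction in ("forward", "reversible"):
                adj.setdefault((sm, sa), set()).add((pm, pa))
            if rxn.direction in ("reverse", "reversible"):
                adj.setdefault((pm, pa), set()).add((sm, sa))
    frontier = [
        (mol, i + 1)
        for mol in db.nutrients
        for i in range(len(db.molecules[mol].atoms))
    ]
    seen = set(frontier)
    while frontier:
        u = frontier.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                frontier.append(v)

    violations = []
    for rid in sorted(accepted):
        rxn = db.reactions[rid]
        sides = []
        if rxn.direction in ("forward", "reversible"):
            sides.append(rxn.substrates)
        if rxn.direction in ("reverse", "reversible"):
            sides.append(rxn.products)
        mapped = {(sm, sa) for (sm, _, sa), _ in db.mappings[rid].pairs} | {
            (pm, pa) for _, (pm, _, pa) in db.mappings[rid].pairs
        }
        for side in sides:
            for mol, _ in side:
                for i in range(len(db.molecules[mol].atoms)):
                    atom = (mol, i + 1)
                    if atom in mapped and atom not in seen:
                        violations.append((rid, atom))
    return violations


# ---------------------------------------------------------------------------
# Brute-force joint-state enumeration for tree posteriors


def enumerate_posteriors(
    tree: Phylogeny,
    edge_cpds: dict[str, EdgeCPD],
    leaf_likelihoods: dict[str, tuple[float, float]],
    root_prior: float,
) -> dict[str, float]:
    nodes = tree.nodes
    totals = {n: 0.0 for n in nodes}
    z = 0.0
    for assignment in itertools.product((0, 1), repeat=len(nodes)):
        state = dict(zip(nodes, assignment))
        w = root_prior if state[tree.root] == 1 else 1.0 - root_prior
        for parent, child in tree.edges():
            w *= edge_cpds[child].transition(state[parent], state[child])
        for leaf, (l0, l1) in leaf_likelihoods.items():
            w *= l1 if state[leaf] == 1 else l0
        z += w
        for n in nodes:
            if state[n] == 1:
                totals[n] += w
    return {n: totals[n] / z for n in nodes}


def random_tree_instance(rng: np.random.Generator, max_nodes: int = 10):
    """A random rooted tree (possibly multifurcating) with random CPDs."""
    n = int(rng.integers(2, max_nodes + 1))
    parent = {"n0": None}
    for i in range(1, n):
        parent[f"n{i}"] = f"n{int(rng.integers(i))}"
    tree = Phylogeny(parent)
    cpds = {
        child: EdgeCPD(
            float(rng.uniform(0.02, 0.98)), float(rng.uniform(0.02, 0.98))
        )
        for _, child in tree.edges()
    }
    return tree, cpds


# ---------------------------------------------------------------------------
# Common fixtures


@pytest.fixture
def balanced_tree4() -> Phylogeny:
    """((l1,l2)a,(l3,l4)b)r — the classic 4-leaf balanced topology."""
    return Phylogeny(
        {"r": None, "a": "r", "b": "r", "l1": "a", "l2": "a", "l3": "b", "l4": "b"}
    )


@pytest.fixture
def toy_molecules() -> dict[str, Molecule]:
    formulas = {
        "GLC": "C6H12O6",
        "LAC": "C3H6O3",
        "PYR": "C3H4O3",
        "ETH": "C2H6O",
        "ACA": "C2H4O",
        "CO2": "CO2",
        "H2O": "H2O",
        "H+": "H",
        "H2CO3": "H2CO3",
    }
    return {m: Molecule(m, parse_formula(f)) for m, f in formulas.items()}


@pytest.fixture
def chain_db() -> ReactionDB:
    """Three-reaction linear chain N -> A -> B -> C over 2-carbon skeletons."""
    from phylorecon.reactions import greedy_map

    mols = {m: Molecule(m, {"C": 2}) for m in ("N", "A", "B", "C")}
    rxns = {
        "r1": Reaction("r1", (("N", 1),), (("A", 1),), frozenset({"1.1.1.1"}), "forward"),
        "r2": Reaction("r2", (("A", 1),), (("B", 1),), frozenset({"1.1.1.2"}), "forward"),
        "r3": Reaction("r3", (("B", 1),), (("C", 1),), frozenset({"1.1.1.3"}), "forward"),
    }
    maps = {rid: greedy_map(r, mols) for rid, r in rxns.items()}
    db = ReactionDB(mols, rxns, maps, {"N"})
    db.validate()
    return db
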