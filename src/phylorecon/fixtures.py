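"""Synthetic universes and simulated evidence for testing and benchmarking.

The generator produces a layered biosynthesis universe over carbon-skeleton
molecules: nutrients sit in layer zero, each later layer's metabolites are
built from earlier ones by mass-balanced condensation or cleavage reactions,
and the "spine" reactions producing every metabolite form a planted network
that is gapless by construction.  Decoy reactions recombine existing
metabolites and stand in for the false-positive part of a reaction database.
Evidence simulators then generate enzyme presence along a phylogeny (Bernoulli
gain/loss per edge) and class-conditional evidence scores per leaf, giving an
end-to-end testbed with the statistical structure the inference and
reconstruction phases assume — without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import EnzymeScoreTable
from .phylo import Phylogeny
from .reactions import AtomMapping, Molecule, Reaction, ReactionDB, greedy_map

__all__ = [
    "SyntheticUniverse",
    "ScoreDistributions",
    "SimulationConfig",
    "generate_universe",
    "random_tree",
    "simulate_evolution",
    "simulate_scores",
]


@dataclass
class SyntheticUniverse:
    """A reaction database plus the planted true (gapless) sub-network."""

    db: ReactionDB
    spine: set[str]  # reaction ids forming the planted gapless network
    decoys: set[str]

    @property
    def ec_of(self) -> dict[str, str]:
        return {
            rid: next(iter(r.ecs)) for rid, r in self.db.reactions.items() if r.ecs
        }


def _ec_label(i: int) -> str:
    # synthetic but structurally valid four-field EC numbers
    return f"{1 + i % 6}.{1 + (i // 6) % 9}.{1 + (i // 54) % 9}.{1 + i}"


def generate_universe(
    seed: int,
    *,
    n_layers: int = 4,
    mets_per_layer: int = 4,
    n_nutrients: int = 2,
    n_decoys: int = 10,
    max_carbon: int = 6,
) -> SyntheticUniverse:
    """Generate a layered, balanced, atom-mapped synthetic reaction universe.

    Every non-nutrient metabolite is produced by exactly one spine reaction
    whose substrates come from strictly earlier layers, so the spine is a
    gapless network over the nutrient set by construction.  Decoy reactions
    conserve carbon as well (condensations of existing metabolites into fresh
    dead-end products), so they are balanced and mappable but are never
    needed for connectivity.  All molecules are pure carbon skeletons, which
    keeps balancing exact and mappings total.
    """
    rng = np.random.default_rng(seed)
    molecules: dict[str, Molecule] = {}
    layers: list[list[str]] = []

    def add_molecule(name: str, carbons: int) -> None:
        molecules[name] = Molecule(name, {"C": carbons})

    nutrients = []
    layer0 = []
    for i in range(n_nutrients):
        name = f"NUT{i}"
        add_molecule(name, int(rng.integers(1, max_carbon + 1)))
        nutrients.append(name)
        layer0.append(name)
    layers.append(layer0)

    reactions: dict[str, Reaction] = {}
    mappings: dict[str, AtomMapping] = {}
    spine: set[str] = set()
    ec_counter = 0

    def carbons(mol: str) -> int:
        return molecules[mol].formula["C"]

    def add_reaction(rid: str, subs, prods, spontaneous=False) -> None:
        nonlocal ec_counter
        ecs = frozenset() if spontaneous else frozenset({_ec_label(ec_counter)})
        if not spontaneous:
            ec_counter += 1
        rxn = Reaction(rid, tuple(subs), tuple(prods), ecs, "forward")
        reactions[rid] = rxn
        mappings[rid] = greedy_map(rxn, molecules)

    met_counter = 0
    for layer in range(1, n_layers + 1):
        current: list[str] = []
        pool = [m for lyr in layers for m in lyr]
        for _ in range(mets_per_layer):
            name = f"M{met_counter}"
            met_counter += 1
            n_subs = int(rng.integers(1, min(3, len(pool)) + 1))
            subs = sorted(rng.choice(pool, size=n_subs, replace=False).tolist())
            total_c = sum(carbons(m) for m in subs)
            rid = f"R{len(reactions):03d}"
            if n_subs == 1 and carbons(subs[0]) >= 2 and rng.random() < 0.4:
                # cleavage: split one metabolite into the new one and a byproduct
                c_new = int(rng.integers(1, carbons(subs[0])))
                c_by = carbons(subs[0]) - c_new
                by = f"B{met_counter}"
                add_molecule(name, c_new)
                add_molecule(by, c_by)
                add_reaction(rid, [(subs[0], 1)], [(name, 1), (by, 1)])
            else:
                # condensation of all chosen substrates
                add_molecule(name, total_c)
                add_reaction(rid, [(m, 1) for m in subs], [(name, 1)])
            spine.add(rid)
            current.append(name)
        layers.append(current)

    decoys: set[str] = set()
    pool = sorted(set(molecules) - set(nutrients))
    for d in range(n_decoys):
        n_subs = int(rng.integers(1, 3))
        subs = sorted(rng.choice(pool, size=min(n_subs, len(pool)), replace=False).tolist())
        name = f"D{d}"
        add_molecule(name, sum(carbons(m) for m in subs))
        rid = f"R{len(reactions):03d}"
        add_reaction(rid, [(m, 1) for m in subs], [(name, 1)])
        decoys.add(rid)

    db = ReactionDB(molecules, reactions, mappings, set(nutrients))
    db.validate()
    return SyntheticUniverse(db, spine, decoys)


# ---------------------------------------------------------------------------
# Phylogeny and evidence simulation


def random_tree(n_leaves: int, seed: int, *, prefix: str = "sp") -> Phylogeny:
    """Random rooted bifurcating tree built by sequential leaf attachment."""
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = np.random.default_rng(seed)
    if n_leaves == 1:
        return Phylogeny({f"{prefix}0": None})
    parent: dict[str, str | None] = {"anc0": None}
    leaves = []
    for i in (0, 1):
        leaf = f"{prefix}{i}"
        parent[leaf] = "anc0"
        leaves.append(leaf)
    anc = 1
    for i in range(2, n_leaves):
        target = leaves[int(rng.integers(len(leaves)))]
        new_internal = f"anc{anc}"
        anc += 1
        parent[new_internal] = parent[target]
        parent[target] = new_internal
        leaf = f"{prefix}{i}"
        parent[leaf] = new_internal
        leaves.append(leaf)
    return Phylogeny(parent)


def simulate_evolution(
    tree: Phylogeny,
    ecs: Sequence[str],
    gain: float,
    loss: float,
    seed: int,
    *,
    root_prior: float = 0.5,
) -> pd.DataFrame:
    """Simulate enzyme presence along the tree: node x EC {0,1} matrix.

    The root draws presence from ``root_prior``; along each edge a present
    enzyme survives with probability ``1 - loss`` and an absent one appears
    with probability ``gain``.  This is exactly the generative process the
    edge CPDs of the inference phase parametrize.
    """
    for name, p in (("gain", gain), ("loss", loss), ("root_prior", root_prior)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = pd.DataFrame(0, index=tree.nodes, columns=list(ecs), dtype=int)
    n = len(ecs)
    states.loc[tree.root] = (rng.random(n) < root_prior).astype(int)
    for node in tree.nodes:
        for child in tree.children[node]:
            ps = states.loc[node].to_numpy()
            stay = rng.random(n) < (1.0 - loss)
            appear = rng.random(n) < gain
            states.loc[child] = np.where(ps == 1, stay, appear).astype(int)
    return states


@dataclass
class ScoreDistributions:
    """Class-conditional evidence score distributions (right-skewed defaults).

    Blast-style scores are gamma distributed (present: high mean; absent:
    small, mass near zero with a point mass at exactly 0 for "no hit");
    shared-fraction scores are beta distributed on [0, 1].
    """

    blast_present_shape: float = 6.0
    blast_present_scale: float = 60.0
    blast_absent_shape: float = 1.2
    blast_absent_scale: float = 30.0
    blast_absent_zero_frac: float = 0.3
    gtg_present_a: float = 5.0
    gtg_present_b: float = 2.0
    gtg_absent_a: float = 2.0
    gtg_absent_b: float = 5.0


@dataclass
class SimulationConfig:
    n_leaves: int = 12
    n_ecs: int = 150
    gain: float = 0.1
    loss: float = 0.2
    root_prior: float = 0.5
    mask_fraction: float = 0.5
    distributions: ScoreDistributions = field(default_factory=ScoreDistributions)


def simulate_scores(
    leaf_presence: pd.DataFrame,
    seed: int,
    *,
    distributions: ScoreDistributions | None = None,
    masked: Mapping[str, Sequence[str]] | None = None,
) -> EnzymeScoreTable:
    """Draw per-(leaf, EC) evidence scores from class-conditional distributions.

    ``leaf_presence`` is a leaf x EC {0,1} frame.  ``masked`` optionally maps
    a leaf to ECs whose evidence is suppressed (scores forced to 0, i.e. "no
    hit") — used by the poor-sequencing scenario.
    """
    d = distributions or ScoreDistributions()
    rng = np.random.default_rng(seed)
    rows = []
    for leaf in leaf_presence.index:
        hidden = set((masked or {}).get(leaf, ()))
        for ec in leaf_presence.columns:
            present = int(leaf_presence.loc[leaf, ec]) == 1
            if ec in hidden:
                blast, gtg = 0.0, 0.0
            elif present:
                blast = float(rng.gamma(d.blast_present_shape, d.blast_present_scale))
                gtg = float(rng.beta(d.gtg_present_a, d.gtg_present_b))
            else:
                if rng.random() < d.blast_absent_zero_frac:
                    blast = 0.0
                else:
                    blast = float(
                        rng.gamma(d.blast_absent_shape, d.blast_absent_scale)
                    )
                gtg = float(rng.beta(d.gtg_absent_a, d.gtg_absent_b))
            rows.append(
                {
                    "species": leaf,
                    "ec": ec,
                    "blast_score": blast,
                    "gtg_score": min(gtg, 1.0),
                }
            )
    return EnzymeScoreTable(pd.DataFrame(rows))
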