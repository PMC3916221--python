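"""Phase II: greedy assembly of a gapless, atom-traced metabolic network.

Every reaction is priced at ``-ln(p) + base_cost`` where ``p`` is the highest
posterior over its annotated enzymes (spontaneous reactions get a fixed
cost).  Starting from a nutrient set, reactions cheaper than the acceptance
threshold are considered in increasing order of estimated addition cost; a
reaction is added only when a gapless biosynthesis pathway producing all of
its substrate atoms can be found with total cost below the rejection
threshold.  Pathway search runs on the atom graph — nodes are
(molecule, atom index) pairs, edges follow validated atom mappings — so every
accepted reaction's substrate atoms are traceable to nutrient atoms through
actual atom transfer, which excludes biologically spurious shortcuts through
shared small molecules.
"""

from __future__ import annotations

import heapq
import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .reactions import AtomMapping, Reaction, ReactionDB

__all__ = [
    "CostTable",
    "PartialPathway",
    "Reconstruction",
    "reaction_costs",
    "build_atom_graph",
    "substrate_atoms",
    "estimate_addition_cost",
    "find_gapfill_pathway",
    "reconstruct",
    "export_sbml",
]

POSTERIOR_FLOOR = 1e-12

AtomNode = tuple[str, int]  # (molecule id, 1-based atom index)


@dataclass
class CostTable:
    """Per-reaction logarithmic costs derived from enzyme posteriors."""

    costs: dict[str, float]
    base_cost: float

    def __getitem__(self, rid: str) -> float:
        return self.costs[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.costs

    def __iter__(self):
        return iter(self.costs)


def reaction_costs(
    posteriors: Mapping[str, float],
    db: ReactionDB,
    base_cost: float = 1.0,
    spontaneous_cost: float = 2.0,
) -> CostTable:
    """Price each reaction from the posteriors of one species (tree node).

    ``cost = -ln(max posterior over annotated ECs) + base_cost``; reactions
    without any EC annotation get ``spontaneous_cost``.  Posteriors are
    floored at 1e-12 so costs stay finite; enzymes missing from the posterior
    table count as posterior 0 (floored).
    """
    if base_cost < 0 or spontaneous_cost < 0:
        raise ValueError("costs must be non-negative")
    out: dict[str, float] = {}
    for rid, rxn in db.reactions.items():
        if rxn.is_spontaneous:
            out[rid] = spontaneous_cost
        else:
            p = max(
                max(posteriors.get(ec, 0.0) for ec in rxn.ecs), POSTERIOR_FLOOR
            )
            out[rid] = -math.log(min(p, 1.0)) + base_cost
    return CostTable(out, base_cost)


# ---------------------------------------------------------------------------
# Atom graph


def build_atom_graph(
    db: ReactionDB, accepted: Iterable[str]
) -> nx.DiGraph:
    """Directed atom-transfer graph over the given reactions.

    Nodes are (molecule, atom index); each mapping pair of a reaction yields
    an edge from the substrate atom to the product atom.  Reversible
    reactions contribute edges in both directions, direction-constrained ones
    only the allowed direction.  Edge attribute ``reactions`` holds the set of
    reaction ids realizing the transfer.  Nutrient atoms are always present
    as nodes.
    """
    g = nx.DiGraph()
    for mol in sorted(db.nutrients):
        for idx in db.molecules[mol].atom_indices():
            g.add_node((mol, idx))
    for rid in sorted(set(accepted)):
        rxn = db.reactions[rid]
        if rid not in db.mappings:
            raise ValueError(f"accepted reaction {rid!r} has no atom mapping")
        mapping = db.mappings[rid]
        for (sm, _, sa), (pm, _, pa) in mapping.pairs:
            u: AtomNode = (sm, sa)
            v: AtomNode = (pm, pa)
            if rxn.direction in ("forward", "reversible"):
                _add_edge(g, u, v, rid)
            if rxn.direction in ("reverse", "reversible"):
                _add_edge(g, v, u, rid)
    return g


def _add_edge(g: nx.DiGraph, u: AtomNode, v: AtomNode, rid: str) -> None:
    if g.has_edge(u, v):
        g[u][v]["reactions"].add(rid)
    else:
        g.add_edge(u, v, reactions={rid})


def substrate_atoms(rxn: Reaction, db: ReactionDB) -> set[AtomNode]:
    """Tracked substrate atoms of a reaction, at molecule resolution.

    For reversible reactions both sides act as potential substrates, so all
    their atoms must be nutrient-traceable before the reaction can run in
    either direction; direction-constrained reactions only need the consumed
    side.  Only atoms covered by the reaction's mapping are tracked.
    """
    if rxn.id in db.mappings:
        mapped_sub = {(sm, sa) for (sm, _, sa), _ in db.mappings[rxn.id].pairs}
        mapped_prod = {(pm, pa) for _, (pm, _, pa) in db.mappings[rxn.id].pairs}
    else:
        mapped_sub = mapped_prod = None

    def side_atoms(side, mapped) -> set[AtomNode]:
        atoms: set[AtomNode] = set()
        for mol, _ in side:
            for idx in db.molecules[mol].atom_indices():
                node = (mol, idx)
                if mapped is None or node in mapped:
                    atoms.add(node)
        return atoms

    if rxn.direction == "forward":
        return side_atoms(rxn.substrates, mapped_sub)
    if rxn.direction == "reverse":
        return side_atoms(rxn.products, mapped_prod)
    return side_atoms(rxn.substrates, mapped_sub) | side_atoms(
        rxn.products, mapped_prod
    )


def _source_atoms(db: ReactionDB, accepted: Iterable[str]) -> set[AtomNode]:
    """Nutrient atoms plus product atoms of already-accepted reactions."""
    sources: set[AtomNode] = set()
    for mol in db.nutrients:
        for idx in db.molecules[mol].atom_indices():
            sources.add((mol, idx))
    for rid in accepted:
        rxn = db.reactions[rid]
        sides = [rxn.products]
        if rxn.direction == "reversible":
            sides.append(rxn.substrates)
        for side in sides:
            for mol, _ in side:
                for idx in db.molecules[mol].atom_indices():
                    sources.add((mol, idx))
    return sources


def _reachable_atoms(
    db: ReactionDB, reactions: set[str]
) -> set[AtomNode]:
    """Atoms reachable from nutrient atoms via the given reactions only."""
    g = build_atom_graph(db, reactions)
    seeds = [
        (mol, idx)
        for mol in db.nutrients
        for idx in db.molecules[mol].atom_indices()
    ]
    seen = set(seeds)
    frontier = list(seeds)
    while frontier:
        u = frontier.pop()
        for v in g.successors(u):
            if v not in seen:
                seen.add(v)
                frontier.append(v)
    return seen


# ---------------------------------------------------------------------------
# Cost estimation and pathway search


def _weighted_graph(
    graph: nx.DiGraph,
    costs: CostTable,
    free: set[str],
) -> nx.DiGraph:
    """Copy of the atom graph with scalar edge weights.

    An edge costs 0 when some reaction realizing it is already free (accepted
    or already a pathway member), else the cheapest realizing reaction's cost.
    Attribute ``best`` records that reaction (ties by id).
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        rids = data["reactions"]
        freebies = sorted(r for r in rids if r in free)
        if freebies:
            g.add_edge(u, v, weight=0.0, best=freebies[0])
        else:
            best = min(rids, key=lambda r: (costs[r], r))
            g.add_edge(u, v, weight=costs[best], best=best)
    return g


_SRC = ("__source__", 0)


def estimate_addition_cost(
    rxn: Reaction,
    accepted: set[str],
    graph: nx.DiGraph,
    costs: CostTable,
    db: ReactionDB,
) -> float:
    """Estimated cost of adding ``rxn``: sum over its substrate atoms of the
    cheapest reaction-path cost from nutrients / accepted products to the
    atom (already-accepted reactions cost 0; unreachable atom gives +inf).

    This is the ordering heuristic of the greedy assembly loop, not an exact
    gapfill cost: per-atom shortest paths may share reactions, whose cost is
    then counted once per atom.
    """
    targets = substrate_atoms(rxn, db)
    if not targets:
        return 0.0
    wg = _weighted_graph(graph, costs, set(accepted))
    sources = _source_atoms(db, accepted)
    for s in sorted(sources):
        if s in wg:
            wg.add_edge(_SRC, s, weight=0.0, best=None)
    if _SRC not in wg:
        return math.inf
    dist = nx.single_source_dijkstra_path_length(wg, _SRC, weight="weight")
    total = 0.0
    for atom in targets:
        if atom in sources:
            continue
        if atom not in dist:
            return math.inf
        total += dist[atom]
    return total


@dataclass(frozen=True)
class PartialPathway:
    """A set of reactions under construction as a gapfill pathway."""

    reactions: frozenset[str]
    cost: float

    @staticmethod
    def of(reactions: Iterable[str], costs: CostTable) -> "PartialPathway":
        rs = frozenset(reactions)
        return PartialPathway(rs, sum(costs[r] for r in rs))


def _flagged_atoms(
    target_atoms: set[AtomNode],
    pathway: frozenset[str],
    accepted: set[str],
    db: ReactionDB,
) -> set[AtomNode]:
    """Substrate atoms of the target reaction and all pathway members that are
    not yet connected to nutrients through accepted + pathway reactions."""
    need = set(target_atoms)
    for rid in pathway:
        need |= substrate_atoms(db.reactions[rid], db)
    reachable = _reachable_atoms(db, accepted | set(pathway))
    return {a for a in need if a not in reachable}


def find_gapfill_pathway(
    rxn: Reaction,
    accepted: set[str],
    db: ReactionDB,
    costs: CostTable,
    rho_reject: float,
    k: int = 5,
    budget: int = 10000,
) -> tuple[PartialPathway | None, str]:
    """Best-first search for a gapless biosynthesis pathway feeding ``rxn``.

    Partial pathways (reaction sets) live in a priority queue keyed by
    accumulated cost (each member's cost counted once, ties by reaction ids).
    The cheapest pathway is popped; if no substrate atom of the target
    reaction or of any member is disconnected from nutrients, it is complete
    and returned.  Otherwise the lexicographically first flagged atom is
    chosen and the pathway is expanded by each of the ``k`` cheapest linear
    reaction paths connecting nutrients (or accepted products) to that atom.
    Pathways costing more than ``rho_reject`` are pruned; the search stops
    after ``budget`` expansions.

    Returns ``(pathway, "ok")``, ``(None, "cost")`` when every completion
    exceeds the threshold, or ``(None, "search_limit")`` on budget exhaustion.
    """
    candidates = {
        rid
        for rid in db.reactions
        if rid != rxn.id
        and rid in costs
        and rid in db.mappings
        and "unbalanced" not in db.reactions[rid].flags
        and "no_formula" not in db.reactions[rid].flags
    }
    full_graph = build_atom_graph(db, candidates | accepted)
    target_atoms = substrate_atoms(rxn, db)

    counter = itertools.count()
    start = PartialPathway(frozenset(), 0.0)
    queue: list[tuple[float, tuple[str, ...], int, PartialPathway]] = [
        (0.0, (), next(counter), start)
    ]
    visited: set[frozenset[str]] = set()
    expansions = 0

    while queue:
        cost, _, _, pw = heapq.heappop(queue)
        if pw.reactions in visited:
            continue
        visited.add(pw.reactions)
        if cost > rho_reject:
            return None, "cost"
        flagged = _flagged_atoms(target_atoms, pw.reactions, accepted, db)
        if not flagged:
            return pw, "ok"
        expansions += 1
        if expansions > budget:
            return None, "search_limit"

        atom = min(flagged)
        free = accepted | set(pw.reactions)
        wg = _weighted_graph(full_graph, costs, free)
        sources = _source_atoms(db, accepted)
        for s in sorted(sources):
            if s in wg:
                wg.add_edge(_SRC, s, weight=0.0, best=None)
        if _SRC not in wg or atom not in wg:
            continue
        try:
            path_iter = nx.shortest_simple_paths(wg, _SRC, atom, weight="weight")
        except nx.NetworkXNoPath:
            continue
        for path in itertools.islice(path_iter, k):
            new_rids = set()
            for u, v in zip(path, path[1:]):
                rid = wg[u][v]["best"]
                if rid is not None and rid not in free:
                    new_rids.add(rid)
            new_set = pw.reactions | new_rids
            if new_set == pw.reactions:
                continue
            if new_set in visited:
                continue
            new_pw = PartialPathway.of(new_set, costs)
            if new_pw.cost > rho_reject:
                continue
            heapq.heappush(
                queue,
                (new_pw.cost, tuple(sorted(new_set)), next(counter), new_pw),
            )
    return None, "cost"


# ---------------------------------------------------------------------------
# Greedy reconstruction loop


@dataclass
class Reconstruction:
    """Assembled network for one species with per-reaction provenance."""

    species: str
    accepted: dict[str, str] = field(default_factory=dict)  # rid -> scored|gapfill
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (rid, reason)
    gap_flags: set[str] = field(default_factory=set)

    @property
    def scored(self) -> set[str]:
        return {r for r, p in self.accepted.items() if p == "scored"}

    @property
    def gapfills(self) -> set[str]:
        return {r for r, p in self.accepted.items() if p == "gapfill"}

    def ec_set(self, db: ReactionDB) -> set[str]:
        """Complete EC numbers carried by the accepted reactions."""
        ecs: set[str] = set()
        for rid in self.accepted:
            ecs |= db.reactions[rid].ecs
        return ecs


def reconstruct(
    db: ReactionDB,
    costs: CostTable,
    rho_accept: float,
    rho_reject: float,
    *,
    policy: str = "reject",
    k: int = 5,
    budget: int = 10000,
    species: str = "",
) -> Reconstruction:
    """Greedy gapless assembly for one species.

    Candidate reactions with cost <= ``rho_accept`` are attempted in
    increasing order of estimated addition cost (re-estimated after every
    accepted addition, ties by reaction id).  Each attempt searches for a
    gapfill pathway; on success the reaction and the pathway members are
    accepted (members costing more than ``rho_accept`` carry ``gapfill``
    provenance), on failure the reaction is rejected (``policy='reject'``) or
    added anyway with a gap flag (``policy='add_with_gap'``).
    """
    if policy not in ("reject", "add_with_gap"):
        raise ValueError(f"unknown policy {policy!r}")
    if not db.nutrients:
        raise ValueError("nutrient set is empty")
    recon = Reconstruction(species=species)
    accepted: set[str] = set()

    usable = {
        rid
        for rid, rxn in db.reactions.items()
        if rid in db.mappings
        and "unbalanced" not in rxn.flags
        and "no_formula" not in rxn.flags
    }
    pending = sorted(r for r in usable if r in costs and costs[r] <= rho_accept)
    graph = build_atom_graph(db, usable)

    while pending:
        estimates = {
            rid: estimate_addition_cost(
                db.reactions[rid], accepted, graph, costs, db
            )
            for rid in pending
        }
        rid = min(pending, key=lambda r: (estimates[r], r))
        pending.remove(rid)
        rxn = db.reactions[rid]

        if math.isinf(estimates[rid]):
            pathway, reason = None, "unreachable"
        else:
            pathway, reason = find_gapfill_pathway(
                rxn, accepted, db, costs, rho_reject, k=k, budget=budget
            )

        if pathway is not None:
            accepted.add(rid)
            recon.accepted[rid] = "scored"
            for member in sorted(pathway.reactions):
                if member in accepted:
                    continue
                accepted.add(member)
                recon.accepted[member] = (
                    "gapfill" if costs[member] > rho_accept else "scored"
                )
                if member in pending:
                    pending.remove(member)
        else:
            if policy == "reject":
                recon.rejected.append((rid, reason))
            else:
                accepted.add(rid)
                recon.accepted[rid] = "scored"
                recon.gap_flags.add(rid)
    return recon


# ---------------------------------------------------------------------------
# SBML export


def export_sbml(
    recon: Reconstruction,
    db: ReactionDB,
    costs: CostTable | None,
    path,
    posteriors: Mapping[str, float] | None = None,
) -> None:
    """Write the reconstruction as an SBML Level 3 document.

    Each reaction element is annotated (in its notes body) with its EC list,
    cost / best-enzyme posterior, provenance (scored vs gapfill), gap flag
    and the atom-map pairs, so the carbon trace survives the export.
    Construction order is sorted, so identical reconstructions produce
    byte-identical files.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(_sbml_id(recon.species) or "reconstruction")

    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)

    used_mols: set[str] = set(db.nutrients)
    for rid in recon.accepted:
        rxn = db.reactions[rid]
        used_mols.update(m for m, _ in rxn.substrates)
        used_mols.update(m for m, _ in rxn.products)
    for mol in sorted(used_mols):
        sp = model.createSpecies()
        sp.setId(_sbml_id(mol))
        sp.setCompartment("cell")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(mol in db.nutrients)
        sp.setConstant(False)

    for rid in sorted(recon.accepted):
        rxn = db.reactions[rid]
        sr = model.createReaction()
        sr.setId(_sbml_id(rid))
        sr.setReversible(rxn.direction == "reversible")
        sr.setFast(False)
        for mol, coef in rxn.substrates:
            ref = sr.createReactant()
            ref.setSpecies(_sbml_id(mol))
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        for mol, coef in rxn.products:
            ref = sr.createProduct()
            ref.setSpecies(_sbml_id(mol))
            ref.setStoichiometry(float(coef))
            ref.setConstant(True)
        notes = [
            f"<p>EC: {';'.join(sorted(rxn.ecs)) or 'spontaneous'}</p>",
            f"<p>provenance: {recon.accepted[rid]}</p>",
            f"<p>gap: {'yes' if rid in recon.gap_flags else 'no'}</p>",
        ]
        if costs is not None and rid in costs:
            notes.append(f"<p>cost: {costs[rid]:.6f}</p>")
        if posteriors is not None:
            best = max(
                (posteriors.get(ec, 0.0) for ec in rxn.ecs), default=None
            )
            if best is not None:
                notes.append(f"<p>posterior: {best:.6f}</p>")
        if rid in db.mappings:
            pair_txt = ";".join(
                f"{sm}.{so}.{sa}>{pm}.{po}.{pa}"
                for (sm, so, sa), (pm, po, pa) in db.mappings[rid].pairs
            )
            notes.append(f"<p>atom_map: {pair_txt}</p>")
        sr.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(notes)
            + "</body>"
        )

    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_id(raw: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if out and not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out
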