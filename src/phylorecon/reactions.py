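"""Reaction universe: parsing, filtering, mass balancing and atom mappings.

Reactions come from a KEGG-like flat file of stoichiometric equations with EC
annotations and direction constraints.  Before reconstruction each reaction is
mass-balanced by an integer program: existing reactant coefficients may only
grow (up to 15), water and protons may be added freely to either side, at most
one C1 unit (carbonic acid) may be added, and the total coefficient sum is
minimised.  Atom mappings (bijections from substrate atoms to product atoms
that preserve element labels) let downstream pathway search trace individual
atoms from nutrients to products.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = [
    "Molecule",
    "Reaction",
    "AtomMapping",
    "MappingReport",
    "ReactionDB",
    "parse_formula",
    "filter_general",
    "balance_reaction",
    "validate_mapping",
    "greedy_map",
    "read_molecules",
    "read_reactions",
    "read_mappings",
    "write_reactions",
]

MAX_COEF = 15
DEFAULT_ELEMENTS = ("C", "H", "O", "N", "S", "P")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Molecule:
    """A compound with an elemental formula and an indexed atom list.

    ``atoms[i]`` is the element label of atom ``i+1`` (atom indices are
    1-based).  When no explicit atom list is given it is derived from the
    formula in element order.
    """

    id: str
    formula: dict[str, int] = field(default_factory=dict)
    atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.atoms and self.formula:
            derived = []
            for el, n in self.formula.items():
                derived.extend([el] * n)
            object.__setattr__(self, "atoms", tuple(derived))
        for el in set(self.atoms):
            n_atoms = sum(1 for a in self.atoms if a == el)
            if el in self.formula and self.formula[el] != n_atoms:
                raise ValueError(
                    f"{self.id}: atom list has {n_atoms} x {el}, formula says "
                    f"{self.formula[el]}"
                )

    def atom_indices(self, elements: set[str] | None = None) -> list[int]:
        """1-based indices of atoms restricted to ``elements`` (all if None)."""
        return [
            i + 1
            for i, el in enumerate(self.atoms)
            if elements is None or el in elements
        ]


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with EC annotations and a direction constraint."""

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    ecs: frozenset[str] = frozenset()
    direction: str = "reversible"  # forward | reverse | reversible
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "reversible"):
            raise ValueError(f"{self.id}: bad direction {self.direction!r}")
        for mol, coef in (*self.substrates, *self.products):
            if coef < 1:
                raise ValueError(f"{self.id}: coefficient of {mol} must be >= 1")
        subs = {m for m, _ in self.substrates}
        prods = {m for m, _ in self.products}
        if subs & prods:
            raise ValueError(
                f"{self.id}: molecule(s) {sorted(subs & prods)} on both sides"
            )

    @property
    def is_spontaneous(self) -> bool:
        return not self.ecs

    def element_balance(self, molecules: Mapping[str, Molecule]) -> dict[str, int]:
        """products minus substrates, per element.

        The balancing helpers (water, protons, carbonic acid) have built-in
        formulas, so they resolve even when absent from the molecule table.
        """
        def formula(mol: str) -> dict[str, int]:
            if mol in molecules and molecules[mol].formula:
                return molecules[mol].formula
            if mol in _BUILTIN_FORMULAS:
                return _BUILTIN_FORMULAS[mol]
            raise KeyError(f"{self.id}: unknown molecule {mol!r}")

        bal: dict[str, int] = {}
        for mol, coef in self.products:
            for el, n in formula(mol).items():
                bal[el] = bal.get(el, 0) + coef * n
        for mol, coef in self.substrates:
            for el, n in formula(mol).items():
                bal[el] = bal.get(el, 0) - coef * n
        return bal

    def is_balanced(
        self, molecules: Mapping[str, Molecule], elements: Sequence[str] = DEFAULT_ELEMENTS
    ) -> bool:
        bal = self.element_balance(molecules)
        return all(bal.get(el, 0) == 0 for el in elements)


# substrate-side atom slot: (molecule id, occurrence 1..coef, atom index 1-based)
AtomRef = tuple[str, int, int]


@dataclass(frozen=True)
class AtomMapping:
    """Correspondence between substrate and product atom slots of a reaction."""

    reaction_id: str
    pairs: tuple[tuple[AtomRef, AtomRef], ...]


@dataclass
class MappingReport:
    ok: bool
    violations: list[str] = field(default_factory=list)


@dataclass
class ReactionDB:
    """Molecules, reactions, atom mappings and the nutrient set."""

    molecules: dict[str, Molecule] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    mappings: dict[str, AtomMapping] = field(default_factory=dict)
    nutrients: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mol, _ in (*rxn.substrates, *rxn.products):
                if mol not in self.molecules:
                    raise ValueError(f"{rxn.id}: unknown molecule {mol!r}")
        for rid in self.mappings:
            if rid not in self.reactions:
                raise ValueError(f"mapping references unknown reaction {rid!r}")
        for n in self.nutrients:
            if n not in self.molecules:
                raise ValueError(f"nutrient {n!r} is not a known molecule")

    def copy(self) -> "ReactionDB":
        return ReactionDB(
            dict(self.molecules),
            dict(self.reactions),
            dict(self.mappings),
            set(self.nutrients),
        )


def filter_general(db: ReactionDB, blacklist: Iterable[str]) -> ReactionDB:
    """Drop blacklisted "general" reactions (under-specified reactant classes)."""
    out = db.copy()
    for rid in sorted(set(blacklist)):
        if rid in out.reactions:
            del out.reactions[rid]
            out.mappings.pop(rid, None)
        else:
            warnings.warn(f"blacklisted reaction {rid!r} not in database")
    return out


# ---------------------------------------------------------------------------
# Mass balancing (integer program)

WATER = "H2O"
PROTON = "H+"
CARBONIC_ACID = "H2CO3"
_BUILTIN_FORMULAS = {WATER: {"H": 2, "O": 1}, PROTON: {"H": 1}, CARBONIC_ACID: {"C": 1, "H": 2, "O": 3}}


def balance_reaction(
    rxn: Reaction,
    molecules: Mapping[str, Molecule],
    *,
    elements: Sequence[str] = DEFAULT_ELEMENTS,
    max_coef: int = MAX_COEF,
    water: str = WATER,
    proton: str = PROTON,
    c1: str = CARBONIC_ACID,
) -> Reaction:
    """Mass-balance a reaction by integer programming.

    Each existing reactant keeps its identity; its coefficient is an integer
    bounded below by the original value and above by ``max_coef``.  Water and
    protons may additionally be added to either side (0..``max_coef``), and at
    most one C1 unit (carbonic acid) may be added in total.  Subject to
    element balance over ``elements``, the total coefficient sum is minimised.
    A reaction that cannot be balanced — or has a reactant with no formula —
    is returned flagged ``unbalanced`` (resp. ``no_formula``) and is excluded
    from reconstruction.
    """
    for mol, _ in (*rxn.substrates, *rxn.products):
        if mol not in molecules or not molecules[mol].formula:
            return replace(rxn, flags=rxn.flags | {"no_formula"})

    def formula_of(mol: str) -> dict[str, int]:
        if mol in molecules and molecules[mol].formula:
            return molecules[mol].formula
        return _BUILTIN_FORMULAS[mol]

    # variables: existing substrate coefs, existing product coefs,
    # then [water_sub, water_prod, proton_sub, proton_prod, c1_sub, c1_prod]
    entries: list[tuple[str, int, int]] = []  # (mol, orig coef, side: -1 sub / +1 prod)
    for mol, coef in rxn.substrates:
        entries.append((mol, coef, -1))
    for mol, coef in rxn.products:
        entries.append((mol, coef, +1))
    extras = [(water, -1), (water, +1), (proton, -1), (proton, +1), (c1, -1), (c1, +1)]
    n = len(entries) + len(extras)

    c_obj = np.ones(n)
    lb = np.array([coef for _, coef, _ in entries] + [0] * len(extras), dtype=float)
    ub = np.full(n, float(max_coef))
    ub[len(entries) + 4] = 1.0  # c1 additions are 0/1
    ub[len(entries) + 5] = 1.0

    rows = []
    for el in elements:
        row = np.zeros(n)
        for j, (mol, _, side) in enumerate(entries):
            row[j] = side * formula_of(mol).get(el, 0)
        for j, (mol, side) in enumerate(extras):
            row[len(entries) + j] = side * formula_of(mol).get(el, 0)
        rows.append(row)
    constraints = [LinearConstraint(np.array(rows), 0, 0)]
    # at most one C1 unit in total
    c1_row = np.zeros(n)
    c1_row[len(entries) + 4] = 1
    c1_row[len(entries) + 5] = 1
    constraints.append(LinearConstraint(c1_row, 0, 1))

    res = milp(
        c=c_obj,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if not res.success:
        return replace(rxn, flags=rxn.flags | {"unbalanced"})

    x = np.round(res.x).astype(int)
    subs: dict[str, int] = {}
    prods: dict[str, int] = {}
    for j, (mol, _, side) in enumerate(entries):
        (subs if side < 0 else prods)[mol] = (
            (subs if side < 0 else prods).get(mol, 0) + int(x[j])
        )
    for j, (mol, side) in enumerate(extras):
        if x[len(entries) + j] > 0:
            tgt = subs if side < 0 else prods
            tgt[mol] = tgt.get(mol, 0) + int(x[len(entries) + j])
    # adding the same helper to both sides is never optimal, but guard anyway
    for mol in set(subs) & set(prods):
        k = min(subs[mol], prods[mol])
        subs[mol] -= k
        prods[mol] -= k
        if subs[mol] == 0:
            del subs[mol]
        if prods[mol] == 0:
            del prods[mol]

    return replace(
        rxn,
        substrates=tuple(sorted(subs.items())),
        products=tuple(sorted(prods.items())),
        flags=rxn.flags | {"balanced"},
    )


# ---------------------------------------------------------------------------
# Atom mappings


def _atom_slots(
    side: Sequence[tuple[str, int]],
    molecules: Mapping[str, Molecule],
    elements: set[str] | None,
) -> list[tuple[AtomRef, str]]:
    """All (mol, occurrence, atom index) slots of one side with element labels."""
    slots = []
    for mol, coef in side:
        m = molecules[mol]
        for occ in range(1, coef + 1):
            for i, el in enumerate(m.atoms, start=1):
                if elements is None or el in elements:
                    slots.append(((mol, occ, i), el))
    return slots


def validate_mapping(
    rxn: Reaction,
    mapping: AtomMapping,
    molecules: Mapping[str, Molecule],
    *,
    elements: set[str] | None = None,
) -> MappingReport:
    """Check that a mapping is a label-preserving bijection over tracked atoms.

    ``elements=None`` tracks the elements actually present in the mapping's
    pairs (a carbon-only mapping of a full reaction is then valid as long as
    it covers every carbon exactly once).
    """
    violations: list[str] = []

    def element_of(ref: AtomRef) -> str | None:
        mol, occ, idx = ref
        if mol not in molecules:
            return None
        atoms = molecules[mol].atoms
        if not (1 <= idx <= len(atoms)):
            return None
        return atoms[idx - 1]

    if elements is None:
        elements = set()
        for s, p in mapping.pairs:
            for ref in (s, p):
                el = element_of(ref)
                if el is not None:
                    elements.add(el)

    seen_sub: set[AtomRef] = set()
    seen_prod: set[AtomRef] = set()
    for s, p in mapping.pairs:
        es, ep = element_of(s), element_of(p)
        if es is None or ep is None:
            violations.append(f"dangling atom reference {s} -> {p}")
            continue
        if es != ep:
            violations.append(f"element mismatch {s}({es}) -> {p}({ep})")
        if s in seen_sub:
            violations.append(f"substrate atom {s} mapped twice")
        if p in seen_prod:
            violations.append(f"product atom {p} mapped twice")
        seen_sub.add(s)
        seen_prod.add(p)

    want_sub = {ref for ref, _ in _atom_slots(rxn.substrates, molecules, elements)}
    want_prod = {ref for ref, _ in _atom_slots(rxn.products, molecules, elements)}
    for ref in sorted(want_sub - seen_sub):
        violations.append(f"substrate atom {ref} unmapped")
    for ref in sorted(want_prod - seen_prod):
        violations.append(f"product atom {ref} unmapped")
    for ref in sorted(seen_sub - want_sub):
        violations.append(f"mapped substrate atom {ref} not in reaction")
    for ref in sorted(seen_prod - want_prod):
        violations.append(f"mapped product atom {ref} not in reaction")
    return MappingReport(ok=not violations, violations=violations)


def greedy_map(
    rxn: Reaction,
    molecules: Mapping[str, Molecule],
    *,
    elements: set[str] | None = None,
) -> AtomMapping:
    """Element-wise greedy atom mapping (valid, not chemically optimal).

    Substrate and product atom slots of each element are listed in a fixed
    deterministic order and zipped.  Requires the per-element atom multisets
    of the two sides to match, i.e. the reaction must be balanced over the
    tracked elements.
    """
    subs = _atom_slots(rxn.substrates, molecules, elements)
    prods = _atom_slots(rxn.products, molecules, elements)
    by_el_sub: dict[str, list[AtomRef]] = {}
    by_el_prod: dict[str, list[AtomRef]] = {}
    for ref, el in subs:
        by_el_sub.setdefault(el, []).append(ref)
    for ref, el in prods:
        by_el_prod.setdefault(el, []).append(ref)
    if set(by_el_sub) != set(by_el_prod):
        raise ValueError(f"{rxn.id}: element sets differ between sides")
    pairs: list[tuple[AtomRef, AtomRef]] = []
    for el in sorted(by_el_sub):
        s_list, p_list = by_el_sub[el], by_el_prod[el]
        if len(s_list) != len(p_list):
            raise ValueError(
                f"{rxn.id}: {el} count differs ({len(s_list)} vs {len(p_list)}); "
                "reaction not balanced"
            )
        pairs.extend(zip(s_list, p_list))
    return AtomMapping(rxn.id, tuple(pairs))


# ---------------------------------------------------------------------------
# Flat-file formats


def read_molecules(path) -> dict[str, Molecule]:
    """``id<TAB>formula<TAB>atom_elements_csv`` (third column optional)."""
    out: dict[str, Molecule] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            mid, formula = parts[0], parts[1]
            atoms = tuple(parts[2].split(",")) if len(parts) > 2 and parts[2] else ()
            out[mid] = Molecule(mid, parse_formula(formula) if formula else {}, atoms)
    return out


_TERM_RE = re.compile(r"^(?:(\d+)\*)?(\S+)$")


def _parse_side(text: str, rid: str) -> tuple[tuple[str, int], ...]:
    terms = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"{rid}: malformed term {term!r}")
        terms.append((m.group(2), int(m.group(1) or 1)))
    return tuple(terms)


def read_reactions(path) -> dict[str, Reaction]:
    """``id<TAB>EC;EC<TAB>substrates<TAB>products<TAB>direction``."""
    out: dict[str, Reaction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            rid, ecs, subs, prods, direction = parts
            try:
                out[rid] = Reaction(
                    id=rid,
                    substrates=_parse_side(subs, rid),
                    products=_parse_side(prods, rid),
                    ecs=frozenset(e for e in ecs.split(";") if e),
                    direction=direction,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_reactions(reactions: Mapping[str, Reaction], path) -> None:
    def side(terms: tuple[tuple[str, int], ...]) -> str:
        return "+".join(f"{c}*{m}" if c != 1 else m for m, c in terms)

    with open(path, "w") as fh:
        for rid in sorted(reactions):
            r = reactions[rid]
            fh.write(
                f"{r.id}\t{';'.join(sorted(r.ecs))}\t{side(r.substrates)}\t"
                f"{side(r.products)}\t{r.direction}\n"
            )


def read_mappings(path) -> dict[str, AtomMapping]:
    """``rxn<TAB>sub_mol<TAB>occ<TAB>atom<TAB>prod_mol<TAB>occ<TAB>atom`` per pair."""
    pairs: dict[str, list[tuple[AtomRef, AtomRef]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns")
            rid, sm, so, sa, pm, po, pa = parts
            pairs.setdefault(rid, []).append(
                ((sm, int(so), int(sa)), (pm, int(po), int(pa)))
            )
    return {rid: AtomMapping(rid, tuple(p)) for rid, p in pairs.items()}


def write_mappings(mappings: Mapping[str, AtomMapping], path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(mappings):
            for (sm, so, sa), (pm, po, pa) in mappings[rid].pairs:
                fh.write(f"{rid}\t{sm}\t{so}\t{sa}\t{pm}\t{po}\t{pa}\n")
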