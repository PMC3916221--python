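"""Reaction universe: parsing, ILP balancing vs exhaustive search, atom maps."""

import itertools

import numpy as np
import pytest

from phylorecon.reactions import (
    DEFAULT_ELEMENTS,
    AtomMapping,
    Molecule,
    Reaction,
    ReactionDB,
    balance_reaction,
    filter_general,
    greedy_map,
    parse_formula,
    read_mappings,
    read_molecules,
    read_reactions,
    validate_mapping,
    write_mappings,
    write_reactions,
)

# ---------------------------------------------------------------------------
# Exhaustive balancing oracle


def exhaustive_balance_optimum(rxn, molecules, max_coef=15):
    """Minimal total coefficient sum over the full discrete space, or None.

    Enumerates every combination of existing coefficients (original..15) and
    solves the helper additions (water both sides, protons both sides, at
    most one carbonic acid) elementwise.  Independent of the ILP path.
    """
    helper = {
        "H2O": {"H": 2, "O": 1},
        "H+": {"H": 1},
        "H2CO3": {"C": 1, "H": 2, "O": 3},
    }
    entries = [(m, c, -1) for m, c in rxn.substrates] + [
        (m, c, +1) for m, c in rxn.products
    ]
    ranges = [range(c, max_coef + 1) for _, c, _ in entries]
    best = None
    for combo in itertools.product(*ranges):
        bal = {}
        for (mol, _, side), c in zip(entries, combo):
            for el, n in molecules[mol].formula.items():
                bal[el] = bal.get(el, 0) + side * c * n
        # helper additions: signed amounts (positive = product side)
        for c1 in (-1, 0, 1):
            resid = dict(bal)
            for el, n in helper["H2CO3"].items():
                resid[el] = resid.get(el, 0) + c1 * n
            # water fixes O, protons fix H; all other elements must be 0
            w = -resid.get("O", 0)
            resid["O"] = 0
            resid["H"] = resid.get("H", 0) + 2 * w
            p = -resid.get("H", 0)
            resid["H"] = 0
            if any(v != 0 for v in resid.values()):
                continue
            if abs(w) > max_coef or abs(p) > max_coef:
                continue
            total = sum(combo) + abs(w) + abs(p) + abs(c1)
            if best is None or total < best:
                best = total
    return best


def random_toy_reaction(rng, molecules):
    mols = sorted(molecules)
    n_sub = int(rng.integers(1, 3))
    n_prod = int(rng.integers(1, 3))
    chosen = rng.choice(mols, size=n_sub + n_prod, replace=False)
    subs = tuple((m, int(rng.integers(1, 3))) for m in chosen[:n_sub])
    prods = tuple((m, int(rng.integers(1, 3))) for m in chosen[n_sub:])
    return Reaction(f"T{rng.integers(1e6)}", subs, prods)


TOY_FORMULAS = {
    "A1": "CH4", "A2": "C2H6O", "A3": "C2H4O2", "A4": "C3H6O3",
    "A5": "C3H4O3", "A6": "C6H12O6", "A7": "CH2O", "A8": "C2H5NO2",
    "A9": "C4H6O4", "A10": "CO2",
}


@pytest.fixture
def toy_universe():
    return {m: Molecule(m, parse_formula(f)) for m, f in TOY_FORMULAS.items()}


class TestParseFormula:
    def test_basic(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}

    def test_implicit_one(self):
        assert parse_formula("CH4") == {"C": 1, "H": 4}

    def test_two_letter_elements(self):
        assert parse_formula("NaCl") == {"Na": 1, "Cl": 1}

    @pytest.mark.parametrize("bad", ["c6", "C6h12", "6C", "C6-"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestMolecule:
    def test_atoms_derived_from_formula(self):
        m = Molecule("x", {"C": 2, "O": 1})
        assert sorted(m.atoms) == ["C", "C", "O"]

    def test_inconsistent_atom_list_rejected(self):
        with pytest.raises(ValueError):
            Molecule("x", {"C": 2}, ("C", "C", "C"))


class TestFilterGeneral:
    def _db(self, n=10):
        mols = {"X": Molecule("X", {"C": 1}), "Y": Molecule("Y", {"C": 1})}
        rxns = {
            f"R{i}": Reaction(f"R{i}", (("X", 1),), (("Y", 1),)) for i in range(n)
        }
        return ReactionDB(mols, rxns)

    def test_empty_blacklist_is_identity(self):
        db = self._db()
        assert set(filter_general(db, []).reactions) == set(db.reactions)

    def test_unknown_id_warns_and_is_ignored(self):
        db = self._db()
        with pytest.warns(UserWarning):
            out = filter_general(db, ["nope"])
        assert len(out.reactions) == 10

    def test_two_of_ten_removed(self):
        out = filter_general(self._db(), ["R3", "R7"])
        assert len(out.reactions) == 8
        assert "R3" not in out.reactions


class TestBalanceReaction:
    def test_already_balanced_unchanged(self, toy_universe):
        rxn = Reaction("r", (("A6", 1),), (("A4", 2),))  # glucose -> 2 lactate
        out = balance_reaction(rxn, toy_universe)
        assert out.substrates == rxn.substrates
        assert out.products == rxn.products
        assert "balanced" in out.flags

    def test_balancing_is_idempotent(self, toy_universe):
        rxn = Reaction("r", (("A2", 1),), (("A3", 1),))
        once = balance_reaction(rxn, toy_universe)
        twice = balance_reaction(once, toy_universe)
        assert once.substrates == twice.substrates
        assert once.products == twice.products

    def test_missing_water_added(self, toy_universe):
        # A3 (C2H4O2) -> A2 (C2H6O): needs one O removed, two H added;
        # water on the substrate side leaves O2H6 vs O1H6... the solver must
        # find the cheapest helper combination and end balanced.
        rxn = Reaction("r", (("A6", 1),), (("A5", 2),))  # C6H12O6 -> 2 C3H4O3
        out = balance_reaction(rxn, toy_universe)
        assert "balanced" in out.flags
        assert out.is_balanced(toy_universe)
        # products gained 4 H relative to substrates: protons or water must appear
        helper_names = {m for m, _ in out.substrates + out.products}
        assert helper_names & {"H2O", "H+"}

    def test_single_c1_addition_is_optimal_when_one_carbon_missing(self, toy_universe):
        # A3 (C2H4O2) -> C3H6O4: one extra carbon on the product side; the
        # cheapest fix adds one carbonic acid (plus protons/water), cheaper
        # than scaling both sides to a common carbon multiple
        mols = dict(toy_universe)
        mols["Y"] = Molecule("Y", parse_formula("C3H6O4"))
        rxn = Reaction("r", (("A3", 1),), (("Y", 1),))
        out = balance_reaction(rxn, mols)
        assert "balanced" in out.flags
        assert dict(out.substrates).get("H2CO3", 0) == 1
        total = sum(c for _, c in out.substrates + out.products)
        assert total == exhaustive_balance_optimum(rxn, mols)

    def test_unresolvable_element_flags_unbalanced(self, toy_universe):
        # glycine -> lactate: nitrogen cannot come from water/protons/C1
        rxn = Reaction("r", (("A8", 1),), (("A4", 1),))
        out = balance_reaction(rxn, toy_universe)
        assert "unbalanced" in out.flags

    def test_missing_formula_flagged(self):
        mols = {"X": Molecule("X", {}), "Y": Molecule("Y", {"C": 1})}
        out = balance_reaction(Reaction("r", (("X", 1),), (("Y", 1),)), mols)
        assert "no_formula" in out.flags

    def test_output_always_elementwise_balanced(self, toy_universe):
        rng = np.random.default_rng(17)
        for _ in range(40):
            rxn = random_toy_reaction(rng, toy_universe)
            out = balance_reaction(rxn, toy_universe)
            if "balanced" in out.flags:
                assert out.is_balanced(toy_universe), out

    def test_ilp_matches_exhaustive_optimum(self, toy_universe):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(30):
            rxn = random_toy_reaction(rng, toy_universe)
            out = balance_reaction(rxn, toy_universe)
            want = exhaustive_balance_optimum(rxn, toy_universe)
            if want is None:
                assert "unbalanced" in out.flags
            else:
                assert "balanced" in out.flags
                got = sum(c for _, c in out.substrates + out.products)
                assert got == want
                checked += 1
        assert checked >= 5  # the generator must exercise feasible cases


class TestAtomMappings:
    def test_identity_mapping_passes(self):
        mols = {"A": Molecule("A", {"C": 2}), "B": Molecule("B", {"C": 2})}
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        mapping = AtomMapping(
            "r", ((("A", 1, 1), ("B", 1, 1)), (("A", 1, 2), ("B", 1, 2)))
        )
        assert validate_mapping(rxn, mapping, mols).ok

    def test_element_mismatch_reported_with_pair(self):
        mols = {
            "A": Molecule("A", {"C": 1, "O": 1}, ("C", "O")),
            "B": Molecule("B", {"C": 1, "O": 1}, ("O", "C")),
        }
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        bad = AtomMapping(
            "r", ((("A", 1, 1), ("B", 1, 1)), (("A", 1, 2), ("B", 1, 2)))
        )
        report = validate_mapping(rxn, bad, mols)
        assert not report.ok
        assert any("element mismatch" in v for v in report.violations)

    def test_incomplete_mapping_fails(self):
        mols = {"A": Molecule("A", {"C": 2}), "B": Molecule("B", {"C": 2})}
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        partial = AtomMapping("r", ((("A", 1, 1), ("B", 1, 1)),))
        report = validate_mapping(rxn, partial, mols)
        assert not report.ok

    def test_random_permutation_passes_iff_labels_match(self):
        rng = np.random.default_rng(9)
        mols = {
            "A": Molecule("A", {"C": 2, "O": 1}, ("C", "C", "O")),
            "B": Molecule("B", {"C": 2, "O": 1}, ("C", "O", "C")),
        }
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        for _ in range(20):
            perm = rng.permutation(3)
            mapping = AtomMapping(
                "r",
                tuple(
                    (("A", 1, i + 1), ("B", 1, int(j) + 1))
                    for i, j in enumerate(perm)
                ),
            )
            ok = all(
                mols["A"].atoms[i] == mols["B"].atoms[int(j)]
                for i, j in enumerate(perm)
            )
            assert validate_mapping(rxn, mapping, mols).ok == ok

    def test_greedy_map_isomerization(self):
        mols = {"A": Molecule("A", {"C": 3, "O": 2}), "B": Molecule("B", {"C": 3, "O": 2})}
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        mapping = greedy_map(rxn, mols)
        assert validate_mapping(rxn, mapping, mols).ok

    def test_greedy_map_two_substrates_covers_all_atoms(self):
        mols = {
            "A": Molecule("A", {"C": 2}),
            "B": Molecule("B", {"C": 3}),
            "P": Molecule("P", {"C": 5}),
        }
        rxn = Reaction("r", (("A", 1), ("B", 1)), (("P", 1),))
        mapping = greedy_map(rxn, mols)
        assert len(mapping.pairs) == 5
        assert validate_mapping(rxn, mapping, mols).ok

    def test_greedy_map_respects_coefficients(self):
        mols = {"A": Molecule("A", {"C": 1}), "P": Molecule("P", {"C": 2})}
        rxn = Reaction("r", (("A", 2),), (("P", 1),))
        mapping = greedy_map(rxn, mols)
        # both occurrences of A appear
        occs = {(s[0], s[1]) for s, _ in mapping.pairs}
        assert occs == {("A", 1), ("A", 2)}

    def test_greedy_map_rejects_unbalanced(self):
        mols = {"A": Molecule("A", {"C": 2}), "B": Molecule("B", {"C": 3})}
        rxn = Reaction("r", (("A", 1),), (("B", 1),))
        with pytest.raises(ValueError, match="not balanced"):
            greedy_map(rxn, mols)


class TestFlatFiles:
    def test_reaction_round_trip(self, tmp_path):
        rxns = {
            "R1": Reaction(
                "R1", (("GLC", 1),), (("LAC", 2),), frozenset({"1.1.1.1"}), "forward"
            ),
            "R2": Reaction("R2", (("A", 2), ("B", 1)), (("C", 1),)),
        }
        p = tmp_path / "rxns.tsv"
        write_reactions(rxns, p)
        back = read_reactions(p)
        assert back == rxns

    def test_molecule_file(self, tmp_path):
        p = tmp_path / "mols.tsv"
        p.write_text("GLC\tC6H12O6\nX\tCO2\tC,O,O\n")
        mols = read_molecules(p)
        assert mols["GLC"].formula == {"C": 6, "H": 12, "O": 6}
        assert mols["X"].atoms == ("C", "O", "O")

    def test_mapping_round_trip(self, tmp_path):
        mapping = {
            "R1": AtomMapping(
                "R1", ((("A", 1, 1), ("B", 1, 2)), (("A", 1, 2), ("B", 1, 1)))
            )
        }
        p = tmp_path / "maps.tsv"
        write_mappings(mapping, p)
        assert read_mappings(p) == mapping

    def test_malformed_reaction_line_reports_lineno(self, tmp_path):
        p = tmp_path / "rxns.tsv"
        p.write_text("R1\t1.1.1.1\tA\tB\n")  # missing direction column
        with pytest.raises(ValueError, match="line 1"):
            read_reactions(p)

    def test_same_molecule_both_sides_rejected(self):
        with pytest.raises(ValueError, match="both sides"):
            Reaction("r", (("A", 1),), (("A", 1),))
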