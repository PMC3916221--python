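"""Steady-state flux analyses of reconstructed models.

A reconstruction is turned into a stoichiometric LP model: internal reactions
with direction-derived flux bounds, uptake exchanges opened only for media
metabolites, secretion exchanges for boundary metabolites, and a biomass
pseudo-reaction consuming precursor metabolites in fixed proportions.  Yields
are LP maxima subject to S.v = 0; optional linear couplings enforce that CO2
production not exceed bicarbonate intake, and that the ATP/O ratio equal a
fixed value.  Gene knockouts follow complex-aware semantics: deleting a gene
inactivates every complex containing it, co-members left without any
functional complex are lost too, and a reaction is removed only when no
remaining functional gene carries any of its EC numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .reactions import Reaction

__all__ = [
    "StoichiometricModel",
    "ComplexMap",
    "GrowthCall",
    "build_model",
    "max_yield",
    "knockout_deletions",
    "predict_growth",
    "summarize_calls",
]

BIG = 1000.0
YIELD_TOL = 1e-6


@dataclass
class StoichiometricModel:
    """Metabolite x reaction stoichiometric matrix with flux bounds.

    ``coupling`` rows are extra linear inequality constraints A.v <= b over
    the same flux vector (used for the CO2/bicarbonate restriction); equality
    couplings (ATP/O) are rows of ``coupling_eq``.
    """

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective: str | None = None
    coupling: list[tuple[np.ndarray, float]] = field(default_factory=list)
    coupling_eq: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def index_of(self, reaction: str) -> int:
        return self.reactions.index(reaction)

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            list(self.metabolites),
            list(self.reactions),
            self.S.copy(),
            self.lb.copy(),
            self.ub.copy(),
            self.objective,
            [(a.copy(), b) for a, b in self.coupling],
            [(a.copy(), b) for a, b in self.coupling_eq],
        )

    def knock_out(self, reactions: Iterable[str]) -> "StoichiometricModel":
        out = self.copy()
        for rid in reactions:
            if rid in out.reactions:
                j = out.index_of(rid)
                out.lb[j] = 0.0
                out.ub[j] = 0.0
        return out


def _direction_bounds(direction: str, big: float = BIG) -> tuple[float, float]:
    if direction == "forward":
        return 0.0, big
    if direction == "reverse":
        return -big, 0.0
    return -big, big


def build_model(
    reactions: Mapping[str, Reaction],
    media: Mapping[str, float],
    biomass: Mapping[str, float],
    *,
    directions: Mapping[str, str] | None = None,
    secretion: Iterable[str] | str = "all",
    co2_id: str | None = None,
    bicarbonate_id: str | None = None,
    atp_o: tuple[str, str, float] | None = None,
    big: float = BIG,
) -> StoichiometricModel:
    """Assemble the LP model from a reaction set and media/biomass tables.

    ``media`` maps metabolite -> maximal uptake flux; only these metabolites
    get an uptake-capable exchange.  ``secretion`` ("all" or an explicit
    list) names metabolites with export-only exchanges, so mass-balanced
    byproducts have a sink.  ``biomass`` maps component -> stoichiometric
    coefficient of the growth pseudo-reaction; components absent from the
    network are dropped from the metabolite set, which leaves the biomass
    reaction structurally blocked (yield 0) rather than raising.
    ``directions`` overrides per-reaction direction constraints.
    ``co2_id``/``bicarbonate_id`` install the CO2-production <= bicarbonate-
    uptake coupling; ``atp_o = (atp_rxn, o2_exchange, ratio)`` installs the
    ATP/O flux-ratio equality.
    """
    mets: list[str] = sorted(
        {
            m
            for rxn in reactions.values()
            for m, _ in (*rxn.substrates, *rxn.products)
        }
    )
    met_idx = {m: i for i, m in enumerate(mets)}

    cols: list[str] = []
    coldata: list[dict[int, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []

    for rid in sorted(reactions):
        rxn = reactions[rid]
        col: dict[int, float] = {}
        for m, c in rxn.substrates:
            col[met_idx[m]] = col.get(met_idx[m], 0.0) - c
        for m, c in rxn.products:
            col[met_idx[m]] = col.get(met_idx[m], 0.0) + c
        direction = (directions or {}).get(rid, rxn.direction)
        lo, hi = _direction_bounds(direction, big)
        cols.append(rid)
        coldata.append(col)
        lbs.append(lo)
        ubs.append(hi)

    # exchanges: flux > 0 exports the metabolite, flux < 0 imports it
    secretable = set(mets) if secretion == "all" else set(secretion)
    for m in mets:
        uptake = float(media.get(m, 0.0))
        can_secrete = m in secretable
        if uptake <= 0 and not can_secrete:
            continue
        cols.append(f"EX_{m}")
        coldata.append({met_idx[m]: -1.0})
        lbs.append(-uptake if uptake > 0 else 0.0)
        ubs.append(big if can_secrete else 0.0)

    # biomass pseudo-reaction over components present in the network
    bm_col: dict[int, float] = {}
    for m, c in biomass.items():
        if m in met_idx and c != 0:
            bm_col[met_idx[m]] = bm_col.get(met_idx[m], 0.0) - float(c)
    cols.append("BIOMASS")
    coldata.append(bm_col)
    lbs.append(0.0)
    ubs.append(big)
    missing = [m for m in biomass if m not in met_idx]
    biomass_blocked = bool(missing) or not bm_col

    S = np.zeros((len(mets), len(cols)))
    for j, col in enumerate(coldata):
        for i, v in col.items():
            S[i, j] = v

    model = StoichiometricModel(mets, cols, S, np.array(lbs), np.array(ubs), "BIOMASS")
    if biomass_blocked:
        # a biomass component does not exist in the network: structurally
        # unproducible, force zero growth
        j = model.index_of("BIOMASS")
        model.ub[j] = 0.0

    if co2_id is not None and bicarbonate_id is not None:
        row = np.zeros(len(cols))
        ok = True
        for ex in (f"EX_{co2_id}", f"EX_{bicarbonate_id}"):
            if ex in model.reactions:
                row[model.index_of(ex)] = 1.0
            else:
                ok = False
        if ok:
            # export(CO2) + export(bicarb) <= 0, i.e. CO2 production cannot
            # exceed bicarbonate intake
            model.coupling.append((row, 0.0))

    if atp_o is not None:
        atp_rxn, o2_rxn, ratio = atp_o
        row = np.zeros(len(cols))
        row[model.index_of(atp_rxn)] = 1.0
        row[model.index_of(o2_rxn)] = ratio
        model.coupling_eq.append((row, 0.0))

    return model


def max_yield(
    model: StoichiometricModel, objective: str | None = None
) -> float:
    """LP maximum of an objective flux subject to S.v = 0 and bounds.

    ``objective`` is a reaction id (default the model's biomass reaction) or
    a metabolite id, in which case a temporary demand sink for that
    metabolite is maximised.  Values below 1e-6 are reported as 0; an
    unbounded objective raises, naming the objective as unconstrained.
    """
    m = model
    objective = objective or model.objective
    if objective is None:
        raise ValueError("no objective given and model has none")
    if objective not in m.reactions:
        if objective in m.metabolites:
            m = model.copy()
            col = np.zeros((len(m.metabolites), 1))
            col[m.metabolites.index(objective), 0] = -1.0
            m.S = np.hstack([m.S, col])
            m.reactions = m.reactions + [f"DM_{objective}"]
            m.lb = np.append(m.lb, 0.0)
            m.ub = np.append(m.ub, np.inf)
            m.coupling = [(np.append(a, 0.0), b) for a, b in m.coupling]
            m.coupling_eq = [(np.append(a, 0.0), b) for a, b in m.coupling_eq]
            objective = f"DM_{objective}"
        else:
            raise KeyError(f"objective {objective!r} is neither reaction nor metabolite")

    j = m.reactions.index(objective)
    c = np.zeros(len(m.reactions))
    c[j] = -1.0
    A_ub = np.array([a for a, _ in m.coupling]) if m.coupling else None
    b_ub = np.array([b for _, b in m.coupling]) if m.coupling else None
    A_eq = m.S
    b_eq = np.zeros(m.S.shape[0])
    if m.coupling_eq:
        A_eq = np.vstack([A_eq] + [a[None, :] for a, _ in m.coupling_eq])
        b_eq = np.append(b_eq, [b for _, b in m.coupling_eq])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(m.lb, m.ub)),
        method="highs",
    )
    if res.status == 3:
        raise ValueError(f"objective {objective!r} is unbounded; add an exchange bound")
    if res.status != 0:
        raise ValueError(f"LP failed for {objective!r}: {res.message}")
    value = -res.fun
    return 0.0 if value < YIELD_TOL else float(value)


# ---------------------------------------------------------------------------
# Complex-aware gene knockouts


@dataclass
class ComplexMap:
    """Gene/complex/EC/reaction association tables."""

    complex_genes: dict[str, set[str]]  # complex -> member genes
    gene_ecs: dict[str, set[str]]  # gene -> EC numbers
    ec_reactions: dict[str, set[str]]  # EC -> reaction ids

    def __post_init__(self) -> None:
        self.gene_complexes: dict[str, set[str]] = {}
        for cx, genes in self.complex_genes.items():
            for g in genes:
                self.gene_complexes.setdefault(g, set()).add(cx)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_ecs) | set(self.gene_complexes)

    @classmethod
    def from_frames(
        cls,
        complexes: pd.DataFrame,  # columns complex, gene
        annotations: pd.DataFrame,  # columns gene, ec
        reactions: Mapping[str, Reaction],
    ) -> "ComplexMap":
        cg: dict[str, set[str]] = {}
        for r in complexes.itertuples(index=False):
            cg.setdefault(str(r.complex), set()).add(str(r.gene))
        ge: dict[str, set[str]] = {}
        for r in annotations.itertuples(index=False):
            ge.setdefault(str(r.gene), set()).add(str(r.ec))
        er: dict[str, set[str]] = {}
        for rid, rxn in reactions.items():
            for ec in rxn.ecs:
                er.setdefault(ec, set()).add(rid)
        return cls(cg, ge, er)


def knockout_deletions(gene: str, cmap: ComplexMap) -> set[str]:
    """Reactions inactivated by deleting one gene, complex-aware.

    Deleting a gene kills every complex containing it.  A co-member gene is
    lost only if it belongs to at least one complex and no functional complex
    containing it remains.  A reaction is removed only if none of the
    remaining functional genes carries any EC associated with the reaction.
    """
    if gene not in cmap.genes:
        raise KeyError(f"unknown gene {gene!r}")
    dead_complexes = cmap.gene_complexes.get(gene, set())
    lost = {gene}
    for cx in dead_complexes:
        for member in cmap.complex_genes[cx]:
            if member == gene:
                continue
            remaining = cmap.gene_complexes[member] - dead_complexes
            if not remaining:
                lost.add(member)

    functional = cmap.genes - lost
    live_ecs = {ec for g in functional for ec in cmap.gene_ecs.get(g, set())}

    candidate_ecs = {ec for g in lost for ec in cmap.gene_ecs.get(g, set())}
    removed: set[str] = set()
    for ec in candidate_ecs:
        for rid in cmap.ec_reactions.get(ec, set()):
            rxn_ecs = {
                e for e, rids in cmap.ec_reactions.items() if rid in rids
            }
            if not (rxn_ecs & live_ecs):
                removed.add(rid)
    return removed


# ---------------------------------------------------------------------------
# Growth prediction


@dataclass(frozen=True)
class GrowthCall:
    """One knockout case: normalized predicted and observed growth, and the call.

    A prediction is correct when |predicted - observed| <= 0.5; the observed
    class (growth vs no-growth) is binarized at ``obs_threshold``.  Cases
    whose deletion set was empty are flagged trivial and excluded from
    headline metrics.
    """

    predicted: float
    observed: float
    call: str  # TP | FP | TN | FN
    trivial: bool = False


def predict_growth(
    wild_model: StoichiometricModel,
    deletions: Iterable[str],
    observed: float,
    *,
    obs_threshold: float = 0.5,
) -> GrowthCall:
    """Simulate a knockout and classify the growth prediction.

    Mutant growth is the biomass LP maximum with the deleted reactions'
    bounds closed, normalized by the wild-type maximum (which must be
    positive).
    """
    if not (0.0 <= observed <= 1.0):
        raise ValueError("observed growth must be normalized to [0, 1]")
    wild = max_yield(wild_model)
    if wild <= 0:
        raise ValueError("wild-type model cannot grow; check media and biomass")
    deletions = set(deletions)
    mutant = max_yield(wild_model.knock_out(deletions)) if deletions else wild
    predicted = min(1.0, mutant / wild)
    correct = abs(predicted - observed) <= 0.5
    obs_growth = observed > obs_threshold
    if obs_growth:
        call = "TP" if correct else "FN"
    else:
        call = "TN" if correct else "FP"
    return GrowthCall(predicted, observed, call, trivial=not deletions)


def summarize_calls(calls: Sequence[GrowthCall]) -> dict[str, float]:
    """Confusion counts and derived metrics over non-trivial calls."""
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for c in calls:
        if not c.trivial:
            counts[c.call] += 1
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        **{k: float(v) for k, v in counts.items()},
        "total": float(tp + fp + tn + fn),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }
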