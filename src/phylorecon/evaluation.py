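"""Evaluation machinery: EC-set comparison, ROC/AUC, and data perturbations.

Reconstructions are scored against a gold-standard enzyme (EC) set over a
declared EC universe.  Two perturbation protocols emulate hard reconstruction
scenarios: "poor sequencing" (randomly removing a fraction of a species'
protein sequences together with all their homology hits) and "distant
species" (replacing all strong homology scores with weak scores drawn from a
poorly characterised donor organism).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .evidence import (
    EnzymeScoreTable,
    HomologyHit,
    RemoteHomologyHit,
    is_complete_ec,
)

__all__ = [
    "EcSetComparison",
    "RocCurve",
    "compare_ec_sets",
    "roc_auc",
    "roc_auc_from_point_sets",
    "simulate_poor_sequencing",
    "simulate_distant_species",
]


@dataclass(frozen=True)
class EcSetComparison:
    """Confusion counts of a predicted EC set against a gold standard."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision_defined: bool = True

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.tpr
        return 2 * p * r / (p + r) if (p + r) else 0.0


def compare_ec_sets(
    predicted: Iterable[str], gold: Iterable[str], universe: Iterable[str]
) -> EcSetComparison:
    """Confusion counts over a declared EC universe.

    All three sets must contain only complete four-field EC numbers and
    ``predicted``/``gold`` must be subsets of ``universe``.  An empty
    prediction reports precision 0 with ``precision_defined=False``.
    """
    pred, gld, uni = set(predicted), set(gold), set(universe)
    for name, s in (("predicted", pred), ("gold", gld), ("universe", uni)):
        bad = [e for e in s if not is_complete_ec(e)]
        if bad:
            raise ValueError(f"{name} set contains partial ECs: {sorted(bad)[:5]}")
    if not pred <= uni or not gld <= uni:
        raise ValueError("predicted and gold sets must be subsets of the universe")
    tp = len(pred & gld)
    fp = len(pred - gld)
    fn = len(gld - pred)
    tn = len(uni) - tp - fp - fn
    return EcSetComparison(tp, fp, tn, fn, precision_defined=bool(pred))


@dataclass
class RocCurve:
    """A threshold-sweep ROC curve with trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_auc(
    scored_predictions: Mapping[str, float],
    gold: Iterable[str],
    universe: Iterable[str],
) -> RocCurve:
    """ROC over all distinct score thresholds; ECs missing a score get 0.

    Ties are grouped (one curve point per distinct score) and the AUC is the
    trapezoid area.  Constant scores give the degenerate two-point curve with
    AUC 0.5.
    """
    gld, uni = set(gold), set(universe)
    if not gld or gld == uni:
        raise ValueError("gold set must be a non-empty proper subset of universe")
    items = sorted(uni)
    y = np.array([1 if e in gld else 0 for e in items])
    s = np.array([float(scored_predictions.get(e, 0.0)) for e in items])
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if np.ptp(s) == 0:
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        return RocCurve(fpr, tpr, np.array([np.inf, s[0]]), 0.5)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return RocCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


def roc_auc_from_point_sets(
    point_sets: Sequence[tuple[set[str], float]],
    gold: Iterable[str],
    universe: Iterable[str],
) -> RocCurve:
    """ROC from explicit (predicted set, threshold) sweeps.

    Used for reconstruction-level sweeps, where each acceptance threshold
    yields a whole predicted EC set rather than a per-EC score.  Points are
    anchored at (0,0) and (1,1) and sorted by FPR before the trapezoid.
    """
    pts = [(0.0, 0.0), (1.0, 1.0)]
    thrs = [np.inf, -np.inf]
    for pred, thr in point_sets:
        cmpres = compare_ec_sets(pred, gold, universe)
        pts.append((cmpres.fpr, cmpres.tpr))
        thrs.append(thr)
    order = np.lexsort((np.array([p[1] for p in pts]), np.array([p[0] for p in pts])))
    fpr = np.array([pts[i][0] for i in order])
    tpr = np.array([pts[i][1] for i in order])
    thr = np.array([thrs[i] for i in order])
    return RocCurve(fpr, tpr, thr, float(np.trapezoid(tpr, fpr)))


# ---------------------------------------------------------------------------
# Perturbation protocols


def simulate_poor_sequencing(
    blast_hits: Sequence[HomologyHit],
    gtg_hits: Sequence[RemoteHomologyHit],
    species_of: Mapping[str, str],
    species_subset: Iterable[str],
    fraction: float,
    seed: int,
) -> tuple[list[HomologyHit], list[RemoteHomologyHit], set[str]]:
    """Emulate poor sequencing by deleting a random fraction of proteins.

    For each named species, ``floor(fraction * n)`` of its query sequences are
    chosen uniformly at random (seeded) and all their hits are dropped from
    both hit tables.  Returns the perturbed tables and the removed sequence
    set.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    targets = set(species_subset)
    known = set(species_of.values())
    unknown = targets - known
    if unknown:
        raise KeyError(f"species not found: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    removed: set[str] = set()
    for sp in sorted(targets):
        seqs = sorted(q for q, s in species_of.items() if s == sp)
        n_remove = int(np.floor(fraction * len(seqs)))
        if n_remove:
            removed.update(rng.choice(seqs, size=n_remove, replace=False).tolist())
    return (
        [h for h in blast_hits if h.query_seq not in removed],
        [h for h in gtg_hits if h.query_seq not in removed],
        removed,
    )


def simulate_distant_species(
    score_table: EnzymeScoreTable,
    species_subset: Iterable[str],
    donor_scores: pd.DataFrame,
    seed: int,
    *,
    blast_cap: float = 600.0,
    gtg_cap: float = 0.99,
) -> EnzymeScoreTable:
    """Emulate an evolutionary distant clade by capping strong scores.

    In the named species, every blast-style score above ``blast_cap`` and
    every shared-fraction score above ``gtg_cap`` is replaced by a value drawn
    uniformly from the donor pool restricted to values below the respective
    cap.  ``donor_scores`` needs columns ``blast_score`` and ``gtg_score``
    (e.g. the score rows of a poorly characterised organism).
    """
    targets = set(species_subset)
    blast_pool = donor_scores["blast_score"].to_numpy(dtype=float)
    gtg_pool = donor_scores["gtg_score"].to_numpy(dtype=float)
    blast_pool = blast_pool[blast_pool < blast_cap]
    gtg_pool = gtg_pool[gtg_pool < gtg_cap]
    rng = np.random.default_rng(seed)

    frame = score_table.frame.copy()
    in_subset = frame["species"].isin(targets)
    hi_blast = in_subset & (frame["blast_score"] > blast_cap)
    hi_gtg = in_subset & (frame["gtg_score"] > gtg_cap)
    if hi_blast.any():
        if blast_pool.size == 0:
            raise ValueError("donor pool has no blast scores below the cap")
        frame.loc[hi_blast, "blast_score"] = rng.choice(
            blast_pool, size=int(hi_blast.sum()), replace=True
        )
    if hi_gtg.any():
        if gtg_pool.size == 0:
            raise ValueError("donor pool has no gtg scores below the cap")
        frame.loc[hi_gtg, "gtg_score"] = rng.choice(
            gtg_pool, size=int(hi_gtg.sum()), replace=True
        )
    return EnzymeScoreTable(frame)
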