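"""Phase I: probabilistic enzyme-presence inference over a phylogeny.

Each enzyme (EC number) gets its own instance of a tree-structured Bayesian
network.  Node topology follows the rooted phylogeny: internal nodes are
hypothetical ancestral species, leaves are present species, and each leaf
additionally observes two evidence variables (a blast-style reciprocal score
and a remote-homology shared-feature fraction).  Presence transitions along
each edge are Bernoulli CPDs (gain / retention probabilities) estimated from
parsimony-imputed reference presence calls; evidence CPDs are four shared
Gaussian kernel density estimates (score | present, score | absent, for each
evidence channel).  Because the network is a tree, exact marginals are
obtained with a two-pass (upward / downward) belief-propagation schedule —
the polytree algorithm specialised to trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .evidence import EnzymeScoreTable

__all__ = [
    "Phylogeny",
    "EdgeCPD",
    "GaussianKDE",
    "EvidenceModel",
    "InferenceConfig",
    "fitch_parsimony",
    "estimate_edge_cpds",
    "fit_evidence_cpd",
    "posterior_inference",
    "naive_posteriors",
    "infer_all",
]


class Phylogeny:
    """A rooted tree with uniquely named nodes, child->parent edges.

    Node order is topological (root first), so a single forward sweep visits
    parents before children and a reverse sweep visits children first.
    """

    def __init__(self, parent: Mapping[str, str | None]):
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root: str = roots[0]
        self.parent: dict[str, str | None] = dict(parent)
        self.children: dict[str, list[str]] = {n: [] for n in parent}
        for n, p in parent.items():
            if p is not None:
                if p not in parent:
                    raise ValueError(f"parent {p!r} of {n!r} is not a node")
                self.children[p].append(n)
        for c in self.children.values():
            c.sort()
        # topological order, root first
        self.nodes: list[str] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            self.nodes.append(n)
            stack.extend(reversed(self.children[n]))
        if len(self.nodes) != len(parent):
            raise ValueError("tree contains a cycle or unreachable node")
        self.leaves: list[str] = [n for n in self.nodes if not self.children[n]]

    def edges(self) -> list[tuple[str, str]]:
        """(parent, child) pairs in topological order of the child."""
        return [(self.parent[n], n) for n in self.nodes if self.parent[n] is not None]

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool | None = None) -> "Phylogeny":
        """Parse a rooted newick tree; unnamed internal nodes get ``anc<i>`` labels."""
        if is_path is None:
            is_path = not source.lstrip().startswith("(")
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        parent: dict[str, str | None] = {}
        counter = 0
        names: dict[int, str] = {}
        for nd in tree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if not label:
                label = f"anc{counter}"
                counter += 1
            if label in parent:
                raise ValueError(f"duplicate node label {label!r}")
            names[id(nd)] = label
            parent[label] = names[id(nd.parent_node)] if nd.parent_node else None
        return cls(parent)

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            kids = self.children[node]
            if not kids:
                return node
            return "(" + ",".join(fmt(k) for k in kids) + ")" + node

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_parsimony(
    tree: Phylogeny, leaf_states: Mapping[str, int]
) -> tuple[dict[str, int], int]:
    """Minimum-change ancestral presence states for one enzyme.

    Dynamic programming over per-node change counts (exact on arbitrary,
    possibly multifurcating, rooted trees; equivalent to Fitch's set method
    on bifurcating trees).  Ties are broken deterministically: an ambiguous
    node copies its parent's state, and an ambiguous root is called absent.

    Returns the full node->state labeling and the minimal change count.
    """
    for leaf in tree.leaves:
        if leaf not in leaf_states:
            raise KeyError(f"leaf {leaf!r} missing a state")
        if leaf_states[leaf] not in (0, 1):
            raise ValueError(f"state of {leaf!r} must be 0 or 1")

    INF = float("inf")
    cost: dict[str, list[float]] = {}
    for node in reversed(tree.nodes):
        if tree.is_leaf(node):
            s = leaf_states[node]
            cost[node] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c0 = c1 = 0.0
            for child in tree.children[node]:
                cc = cost[child]
                c0 += min(cc[0], cc[1] + 1)
                c1 += min(cc[1], cc[0] + 1)
            cost[node] = [c0, c1]

    states: dict[str, int] = {}
    rc = cost[tree.root]
    # root tie resolved toward absent
    states[tree.root] = 0 if rc[0] <= rc[1] else 1
    for node in tree.nodes:
        for child in tree.children[node]:
            s = states[node]
            cc = cost[child]
            keep = cc[s]
            flip = cc[1 - s] + 1
            states[child] = s if keep <= flip else 1 - s
    changes = int(min(rc))
    return states, changes


# ---------------------------------------------------------------------------
# Edge CPDs


@dataclass(frozen=True)
class EdgeCPD:
    """Presence-transition probabilities along one child<-parent edge."""

    p_gain: float  # P(child present | parent absent)
    p_stay: float  # P(child present | parent present)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_gain <= 1.0 and 0.0 <= self.p_stay <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")

    def transition(self, parent_state: int, child_state: int) -> float:
        p1 = self.p_stay if parent_state == 1 else self.p_gain
        return p1 if child_state == 1 else 1.0 - p1


def estimate_edge_cpds(
    tree: Phylogeny,
    full_states: pd.DataFrame,
    pseudocount: float = 1.0,
    *,
    mode: str = "per_edge",
) -> dict[str, EdgeCPD]:
    """Estimate per-edge gain/retention CPDs from a full presence matrix.

    ``full_states`` is a node x EC {0,1} DataFrame covering every tree node
    (typically the parsimony-imputed reference calls).  Transition counts are
    pooled over ECs per edge (``mode='per_edge'``) or over all edges
    (``mode='global'``); pseudocounts keep probabilities strictly inside
    (0, 1).  Edges with no parent-absent (or no parent-present) observations
    fall back to the corresponding global estimate.

    Returns a map child-node -> :class:`EdgeCPD`.
    """
    if mode not in ("per_edge", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [n for n in tree.nodes if n not in full_states.index]
    if missing:
        raise ValueError(f"full_states missing nodes: {missing}")

    M = full_states.to_numpy()
    row = {n: i for i, n in enumerate(full_states.index)}
    per_edge: dict[str, tuple[int, int, int, int]] = {}
    g01 = g0 = g11 = g1 = 0
    for parent, child in tree.edges():
        ps = M[row[parent]]
        cs = M[row[child]]
        n0 = int((ps == 0).sum())
        n01 = int(((ps == 0) & (cs == 1)).sum())
        n1 = int((ps == 1).sum())
        n11 = int(((ps == 1) & (cs == 1)).sum())
        per_edge[child] = (n01, n0, n11, n1)
        g01 += n01
        g0 += n0
        g11 += n11
        g1 += n1

    pc = pseudocount

    def _rate(k: int, n: int, gk: int, gn: int) -> float:
        if n == 0 and pc == 0:
            # data-poor edge: fall back to global counts
            k, n = gk, gn
        return (k + pc) / (n + 2 * pc) if (n + 2 * pc) > 0 else 0.5

    out: dict[str, EdgeCPD] = {}
    for child, (n01, n0, n11, n1) in per_edge.items():
        if mode == "global":
            n01, n0, n11, n1 = g01, g0, g11, g1
        out[child] = EdgeCPD(
            p_gain=_rate(n01, n0, g01, g0), p_stay=_rate(n11, n1, g11, g1)
        )
    return out


# ---------------------------------------------------------------------------
# Evidence CPDs (kernel density estimates)


class GaussianKDE:
    """One-dimensional Gaussian kernel density with Silverman (nrd0) bandwidth.

    ``h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)``, with a floor of
    ``bw_floor_frac`` times the data range (or ``bw_floor_frac`` itself when
    the range is zero) so degenerate samples still yield a proper density.
    """

    def __init__(
        self,
        data: Sequence[float],
        bandwidth: float | None = None,
        bw_floor_frac: float = 1e-3,
    ):
        x = np.asarray(list(data), dtype=float)
        if x.size == 0:
            raise ValueError("KDE requires at least one data point")
        self.data = np.sort(x)
        if bandwidth is None:
            bandwidth = self._nrd0(self.data, bw_floor_frac)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = float(bandwidth)

    @staticmethod
    def _nrd0(x: np.ndarray, bw_floor_frac: float) -> float:
        n = x.size
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        q75, q25 = np.percentile(x, [75, 25])
        iqr = float(q75 - q25)
        spread_candidates = [v for v in (sd, iqr / 1.34) if v > 0]
        rng = float(x.max() - x.min())
        floor = bw_floor_frac * (rng if rng > 0 else 1.0)
        if not spread_candidates:
            return floor
        h = 0.9 * min(spread_candidates) * n ** (-1 / 5)
        return max(h, floor)

    def pdf(self, x) -> np.ndarray | float:
        xq = np.atleast_1d(np.asarray(x, dtype=float))
        z = (xq[:, None] - self.data[None, :]) / self.bandwidth
        d = np.exp(-0.5 * z * z).sum(axis=1) / (
            self.data.size * self.bandwidth * math.sqrt(2 * math.pi)
        )
        return d if np.ndim(x) else float(d[0])


def fit_evidence_cpd(
    scores_present: Sequence[float],
    scores_absent: Sequence[float],
    n_reg_points: int = 100,
    *,
    bw_floor_frac: float = 1e-3,
) -> tuple[GaussianKDE, GaussianKDE]:
    """Fit the (score | present) and (score | absent) densities for one channel.

    To guard against near-zero densities and overfitting, ``n_reg_points``
    regularization points placed uniformly on [0, max observed score] are
    appended to each class before fitting (the maximum is taken per class over
    its own observed scores).
    """
    def _augment(scores: Sequence[float]) -> list[float]:
        s = list(float(v) for v in scores)
        hi = max(s) if s else 1.0
        if hi <= 0:
            hi = 1.0
        if n_reg_points > 0:
            s.extend(np.linspace(0.0, hi, n_reg_points).tolist())
        if not s:
            raise ValueError("empty score list and no regularization points")
        return s

    return (
        GaussianKDE(_augment(scores_present), bw_floor_frac=bw_floor_frac),
        GaussianKDE(_augment(scores_absent), bw_floor_frac=bw_floor_frac),
    )


@dataclass
class EvidenceModel:
    """The four shared class-conditional score densities."""

    blast_present: GaussianKDE
    blast_absent: GaussianKDE
    gtg_present: GaussianKDE
    gtg_absent: GaussianKDE

    def leaf_likelihood(self, blast: float, gtg: float) -> tuple[float, float]:
        """(L_absent, L_present) for one leaf's observed scores."""
        l0 = self.blast_absent.pdf(blast) * self.gtg_absent.pdf(gtg)
        l1 = self.blast_present.pdf(blast) * self.gtg_present.pdf(gtg)
        return float(l0), float(l1)

    @classmethod
    def fit(
        cls,
        blast_present: Sequence[float],
        blast_absent: Sequence[float],
        gtg_present: Sequence[float],
        gtg_absent: Sequence[float],
        n_reg_points: int = 100,
        bw_floor_frac: float = 1e-3,
    ) -> "EvidenceModel":
        bp, ba = fit_evidence_cpd(
            blast_present, blast_absent, n_reg_points, bw_floor_frac=bw_floor_frac
        )
        gp, ga = fit_evidence_cpd(
            gtg_present, gtg_absent, n_reg_points, bw_floor_frac=bw_floor_frac
        )
        return cls(bp, ba, gp, ga)


# ---------------------------------------------------------------------------
# Exact inference


def _tree_posteriors(
    tree: Phylogeny,
    edge_cpds: Mapping[str, EdgeCPD],
    leaf_likelihoods: Mapping[str, tuple[float, float]],
    root_prior: float,
) -> dict[str, float]:
    """Exact presence marginals by upward/downward message passing.

    ``leaf_likelihoods[leaf] = (L_absent, L_present)``.  Messages are
    renormalised at every node, so arbitrarily scaled evidence densities are
    safe.  Returns P(present) per node.
    """
    prior = np.array([1.0 - root_prior, root_prior])

    # upward pass: lik[v][x] = P(evidence below v | state of v = x)
    lik: dict[str, np.ndarray] = {}
    up_msg: dict[str, np.ndarray] = {}  # message from child to its parent
    for node in reversed(tree.nodes):
        if tree.is_leaf(node):
            l0, l1 = leaf_likelihoods.get(node, (1.0, 1.0))
            vec = np.array([l0, l1], dtype=float)
        else:
            vec = np.ones(2)
            for child in tree.children[node]:
                vec = vec * up_msg[child]
        tot = vec.sum()
        if tot <= 0:
            raise ValueError(f"zero likelihood at node {node!r}")
        lik[node] = vec / tot
        p = tree.parent[node]
        if p is not None:
            cpd = edge_cpds[node]
            T = np.array(
                [
                    [cpd.transition(0, 0), cpd.transition(0, 1)],
                    [cpd.transition(1, 0), cpd.transition(1, 1)],
                ]
            )
            up_msg[node] = T @ lik[node]

    # downward pass: out[v][x] = P(state of v = x, evidence outside subtree v)
    out: dict[str, np.ndarray] = {tree.root: prior.copy()}
    post: dict[str, float] = {}
    for node in tree.nodes:
        marg = out[node] * lik[node]
        marg = marg / marg.sum()
        post[node] = float(marg[1])
        for child in tree.children[node]:
            parent_term = out[node].copy()
            # evidence at siblings (and, for leaves with evidence, the node itself)
            for sib in tree.children[node]:
                if sib != child:
                    parent_term = parent_term * up_msg[sib]
            if tree.is_leaf(node) and node in leaf_likelihoods:
                parent_term = parent_term * lik[node]
            cpd = edge_cpds[child]
            T = np.array(
                [
                    [cpd.transition(0, 0), cpd.transition(0, 1)],
                    [cpd.transition(1, 0), cpd.transition(1, 1)],
                ]
            )
            vec = T.T @ parent_term
            out[child] = vec / vec.sum()
    return post


def posterior_inference(
    tree: Phylogeny,
    edge_cpds: Mapping[str, EdgeCPD],
    evidence_model: EvidenceModel | None,
    scores: EnzymeScoreTable | None,
    ec: str,
    root_prior: float = 0.5,
) -> dict[str, float]:
    """Posterior probability of presence at every node for one enzyme.

    Leaves with no score row are treated as observed scores (0, 0) — "no hit"
    is informative evidence, not missing data.  With ``evidence_model=None``
    the model reduces to prior propagation through the edge CPDs.
    """
    if not (0.0 <= root_prior <= 1.0):
        raise ValueError("root_prior must lie in [0, 1]")
    leaf_lik: dict[str, tuple[float, float]] = {}
    if evidence_model is not None:
        for leaf in tree.leaves:
            b, g = scores.get(leaf, ec) if scores is not None else (0.0, 0.0)
            leaf_lik[leaf] = evidence_model.leaf_likelihood(b, g)
    return _tree_posteriors(tree, edge_cpds, leaf_lik, root_prior)


def naive_posteriors(
    evidence_model: EvidenceModel,
    scores: EnzymeScoreTable,
    species: str,
    ecs: Iterable[str],
    prior: float,
) -> dict[str, float]:
    """Single-node Bayesian classifier: evidence densities and a class prior only.

    This is the no-phylogeny baseline — each species is classified
    independently from its own two scores.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must lie strictly inside (0, 1)")
    out = {}
    for ec in ecs:
        b, g = scores.get(species, ec)
        l0, l1 = evidence_model.leaf_likelihood(b, g)
        num = prior * l1
        den = num + (1.0 - prior) * l0
        out[ec] = num / den
    return out


# ---------------------------------------------------------------------------
# Whole-table driver


@dataclass
class InferenceConfig:
    pseudocount: float = 1.0
    root_prior: float = 0.5
    n_reg_points: int = 100
    bw_floor_frac: float = 1e-3
    cpd_mode: str = "per_edge"


@dataclass
class InferenceResult:
    posteriors: pd.DataFrame  # node x EC
    edge_cpds: dict[str, EdgeCPD]
    evidence_model: EvidenceModel
    full_states: pd.DataFrame  # node x EC parsimony-imputed reference
    reference_prior: float  # leaf-level presence frequency in the reference

    def posterior(self, node: str, ec: str) -> float:
        return float(self.posteriors.loc[node, ec])

    def node_posteriors(self, node: str) -> dict[str, float]:
        return self.posteriors.loc[node].to_dict()


def infer_all(
    tree: Phylogeny,
    score_table: EnzymeScoreTable,
    reference_matrix: pd.DataFrame,
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Run phase I end to end.

    ``reference_matrix`` is a leaf x EC {0,1} DataFrame of reference presence
    calls (e.g. protein-signature based annotations).  The pipeline imputes
    ancestral reference states by parsimony per EC, estimates edge CPDs once
    from the full matrix, fits the four evidence densities globally by pooling
    leaf scores by reference class, then runs exact inference per EC over the
    union of reference and scored ECs.
    """
    config = config or InferenceConfig()
    missing = [l for l in tree.leaves if l not in reference_matrix.index]
    if missing:
        raise ValueError(f"reference matrix missing leaves: {missing}")

    ref_ecs = sorted(reference_matrix.columns)
    full = pd.DataFrame(0, index=tree.nodes, columns=ref_ecs, dtype=int)
    for ec in ref_ecs:
        leaf_states = {l: int(reference_matrix.loc[l, ec]) for l in tree.leaves}
        states, _ = fitch_parsimony(tree, leaf_states)
        full[ec] = [states[n] for n in tree.nodes]

    edge_cpds = estimate_edge_cpds(
        tree, full, pseudocount=config.pseudocount, mode=config.cpd_mode
    )

    bp: list[float] = []
    ba: list[float] = []
    gp: list[float] = []
    ga: list[float] = []
    n_present = 0
    for leaf in tree.leaves:
        for ec in ref_ecs:
            b, g = score_table.get(leaf, ec)
            if int(reference_matrix.loc[leaf, ec]) == 1:
                bp.append(b)
                gp.append(g)
                n_present += 1
            else:
                ba.append(b)
                ga.append(g)
    evidence_model = EvidenceModel.fit(
        bp, ba, gp, ga, n_reg_points=config.n_reg_points,
        bw_floor_frac=config.bw_floor_frac,
    )
    n_total = len(tree.leaves) * len(ref_ecs)
    reference_prior = (n_present + 1.0) / (n_total + 2.0)

    all_ecs = sorted(set(ref_ecs) | score_table.ecs)
    post = pd.DataFrame(0.0, index=tree.nodes, columns=all_ecs, dtype=float)
    for ec in all_ecs:
        marg = posterior_inference(
            tree, edge_cpds, evidence_model, score_table, ec, config.root_prior
        )
        post[ec] = [marg[n] for n in tree.nodes]
    return InferenceResult(post, edge_cpds, evidence_model, full, reference_prior)
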