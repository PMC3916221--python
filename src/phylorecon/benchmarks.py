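"""Seeded end-to-end benchmark scenarios on synthetic data.

Two scenarios mirror the hard reconstruction settings the method targets:

* **poor sequencing** — half of the evidence in a four-species clade is
  masked (scores forced to "no hit"); comparative inference should recover
  enzyme calls from the unmasked relatives, so its AUC should beat both the
  naive single-species Bayesian classifier and either evidence channel alone.

* **distant species** — strong evidence scores in a clade are replaced with
  weak draws from a poorly characterised donor; reconstruction-level
  gapfilling should then recover connectivity reactions that the posterior
  alone cannot, so the phase-II AUC should beat the phase-I AUC.

Both functions return plain dicts of AUCs so replicate means can be compared.
The AUCs are computed on the synthetic truth and are qualitative by design:
their orderings, not their absolute values, are the reproducible quantity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .evaluation import roc_auc, roc_auc_from_point_sets, simulate_distant_species
from .fixtures import (
    ScoreDistributions,
    generate_universe,
    random_tree,
    simulate_evolution,
    simulate_scores,
)
from .phylo import InferenceConfig, infer_all, naive_posteriors
from .reconstruction import reaction_costs, reconstruct

__all__ = ["poor_sequencing_benchmark", "distant_species_benchmark"]

BASE_COST = 1.0
SPONTANEOUS_COST = 2.0


def _synthetic_ecs(n: int) -> list[str]:
    return [f"{1 + i % 6}.{1 + (i // 6) % 9}.{1 + (i // 54) % 9}.{1 + i}" for i in range(n)]


def poor_sequencing_benchmark(
    seed: int,
    *,
    n_leaves: int = 12,
    n_ecs: int = 150,
    gain: float = 0.1,
    loss: float = 0.2,
    mask_fraction: float = 0.5,
    n_masked_species: int = 4,
) -> dict[str, float]:
    """One replicate of the poor-sequencing scenario.

    Enzyme presence evolves along a random tree; per-leaf evidence scores are
    drawn from the class-conditional distributions; in ``n_masked_species``
    leaves a random ``mask_fraction`` of enzymes loses its evidence entirely.
    AUCs against the true presence states are computed on the masked leaves
    for: phase-I posteriors, the naive (no-phylogeny) Bayesian classifier,
    and each evidence channel alone.
    """
    rng = np.random.default_rng(seed)
    tree = random_tree(n_leaves, int(rng.integers(2**31)))
    ecs = _synthetic_ecs(n_ecs)
    states = simulate_evolution(
        tree, ecs, gain, loss, int(rng.integers(2**31))
    )
    leaf_states = states.loc[tree.leaves]

    masked_species = tree.leaves[:n_masked_species]
    masked: dict[str, list[str]] = {}
    for sp in masked_species:
        n_hide = int(math.floor(mask_fraction * len(ecs)))
        masked[sp] = sorted(
            rng.choice(ecs, size=n_hide, replace=False).tolist()
        )
    scores = simulate_scores(
        leaf_states, int(rng.integers(2**31)), masked=masked
    )

    result = infer_all(tree, scores, leaf_states, InferenceConfig())

    eval_leaves = masked_species
    gold = {
        f"{sp}|{ec}"
        for sp in eval_leaves
        for ec in ecs
        if int(leaf_states.loc[sp, ec]) == 1
    }
    universe = {f"{sp}|{ec}" for sp in eval_leaves for ec in ecs}

    phase1 = {
        f"{sp}|{ec}": result.posterior(sp, ec) for sp in eval_leaves for ec in ecs
    }
    naive: dict[str, float] = {}
    for sp in eval_leaves:
        sp_post = naive_posteriors(
            result.evidence_model, scores, sp, ecs, result.reference_prior
        )
        naive.update({f"{sp}|{ec}": p for ec, p in sp_post.items()})
    blast_only = {
        f"{sp}|{ec}": scores.get(sp, ec)[0] for sp in eval_leaves for ec in ecs
    }
    gtg_only = {
        f"{sp}|{ec}": scores.get(sp, ec)[1] for sp in eval_leaves for ec in ecs
    }

    return {
        "phase1": roc_auc(phase1, gold, universe).auc,
        "naive": roc_auc(naive, gold, universe).auc,
        "blast": roc_auc(blast_only, gold, universe).auc,
        "gtg": roc_auc(gtg_only, gold, universe).auc,
    }


def distant_species_benchmark(
    seed: int,
    *,
    n_leaves: int = 8,
    n_perturbed: int = 4,
    blast_cap: float = 200.0,
    gtg_cap: float = 0.5,
    accept_grid: tuple[float, ...] = (
        0.9, 0.7, 0.5, 0.3, 0.15, 0.05, 0.02, 0.005, 0.001,
    ),
    reject_p: float = 1e-4,
) -> dict[str, float]:
    """One replicate of the distant-species scenario.

    A synthetic reaction universe is generated whose spine (the planted
    gapless biosynthesis network) is present in every species, while decoy
    enzymes evolve along the tree.  In a clade of ``n_perturbed`` leaves all
    strong scores are replaced by weak draws from a donor pool (the
    perturbation caps sit on the synthetic score scale).  The focal leaf's
    enzyme content is then predicted by phase-I posterior thresholding and by
    full phase-II reconstruction sweeping the acceptance threshold, and both
    are scored by ROC against the focal leaf's true enzyme set.
    """
    rng = np.random.default_rng(seed)
    universe = generate_universe(int(rng.integers(2**31)), n_decoys=14)
    db = universe.db
    ec_of = universe.ec_of
    spine_ecs = sorted(ec_of[r] for r in universe.spine)
    decoy_ecs = sorted(ec_of[r] for r in universe.decoys)

    tree = random_tree(n_leaves, int(rng.integers(2**31)))
    decoy_states = simulate_evolution(
        tree, decoy_ecs, 0.1, 0.2, int(rng.integers(2**31))
    )
    # the spine is core metabolism: present in every species
    states = decoy_states.copy()
    for ec in spine_ecs:
        states[ec] = 1
    leaf_states = states.loc[tree.leaves, sorted(states.columns)]

    scores = simulate_scores(leaf_states, int(rng.integers(2**31)))

    # donor pool: a poorly characterised organism has weak scores everywhere
    dists = ScoreDistributions()
    n_donor = 300
    donor = pd.DataFrame(
        {
            "blast_score": rng.gamma(
                dists.blast_absent_shape, dists.blast_absent_scale, size=n_donor
            ),
            "gtg_score": rng.beta(
                dists.gtg_absent_a, dists.gtg_absent_b, size=n_donor
            ),
        }
    )
    perturbed_species = tree.leaves[:n_perturbed]
    focal = perturbed_species[0]
    scores = simulate_distant_species(
        scores,
        perturbed_species,
        donor,
        int(rng.integers(2**31)),
        blast_cap=blast_cap,
        gtg_cap=gtg_cap,
    )

    result = infer_all(tree, scores, leaf_states, InferenceConfig())
    post = result.node_posteriors(focal)

    all_ecs = sorted(ec_of.values())
    gold = {ec for ec in all_ecs if int(leaf_states.loc[focal, ec]) == 1}

    phase1_points = [
        ({ec for ec in all_ecs if post.get(ec, 0.0) >= t}, t) for t in accept_grid
    ]
    auc1 = roc_auc_from_point_sets(phase1_points, gold, all_ecs).auc

    costs = reaction_costs(post, db, BASE_COST, SPONTANEOUS_COST)
    rho_reject = BASE_COST - math.log(reject_p)
    phase2_points = []
    for t in accept_grid:
        rho_accept = BASE_COST - math.log(t)
        recon = reconstruct(
            db, costs, rho_accept, rho_reject, policy="reject", species=focal
        )
        phase2_points.append((recon.ec_set(db) & set(all_ecs), t))
    auc2 = roc_auc_from_point_sets(phase2_points, gold, all_ecs).auc

    return {"phase1": auc1, "phase2": auc2}
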