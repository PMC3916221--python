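"""Per-(species, enzyme) homology evidence scores.

Raw homology-search output — reciprocal-search p-values and remote-homology
(trace-graph style) shared-feature fractions — is aggregated into one row of
evidence per species and EC number: the best reciprocal score and the best
shared-feature fraction over all hits whose target sequence is annotated with
that enzyme.  Missing combinations mean "no hit" and score zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

__all__ = [
    "HomologyHit",
    "RemoteHomologyHit",
    "EcAnnotation",
    "EnzymeScoreTable",
    "reciprocal_score",
    "evalue_to_pvalue",
    "enzyme_scores",
    "read_blast_hits",
    "read_gtg_hits",
    "read_annotation",
    "read_species_map",
    "read_score_table",
    "write_score_table",
    "is_complete_ec",
]

#: Smallest p-value admitted by the default scorer; avoids infinite scores.
P_FLOOR = 1e-300


def is_complete_ec(ec: str) -> bool:
    """True for a fully specified four-field EC number such as ``1.1.1.1``."""
    parts = ec.split(".")
    return len(parts) == 4 and all(p.isdigit() for p in parts)


@dataclass(frozen=True)
class HomologyHit:
    """One reciprocal-search hit with forward and reverse p-values."""

    query_seq: str
    target_seq: str
    p_forward: float
    p_reverse: float

    def __post_init__(self) -> None:
        for p in (self.p_forward, self.p_reverse):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value {p!r} outside [0, 1]")


@dataclass(frozen=True)
class RemoteHomologyHit:
    """One remote-homology hit scored as a shared-feature fraction."""

    query_seq: str
    target_seq: str
    shared_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError(
                f"shared_fraction {self.shared_fraction!r} outside [0, 1]"
            )


class EcAnnotation:
    """Map EC number -> set of annotated target sequence identifiers.

    Only complete four-field EC numbers are admitted; partial ECs raise at
    construction time.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._by_ec: dict[str, set[str]] = {}
        self._by_target: dict[str, set[str]] = {}
        if mapping:
            for ec, targets in mapping.items():
                for t in targets:
                    self.add(ec, t)

    def add(self, ec: str, target: str) -> None:
        if not is_complete_ec(ec):
            raise ValueError(f"partial or malformed EC number: {ec!r}")
        self._by_ec.setdefault(ec, set()).add(target)
        self._by_target.setdefault(target, set()).add(ec)

    def ecs_of(self, target: str) -> set[str]:
        return self._by_target.get(target, set())

    def targets_of(self, ec: str) -> set[str]:
        return self._by_ec.get(ec, set())

    @property
    def ecs(self) -> set[str]:
        return set(self._by_ec)

    @property
    def targets(self) -> set[str]:
        return set(self._by_target)

    def __len__(self) -> int:
        return len(self._by_ec)


def reciprocal_score(
    p_forward: float,
    p_reverse: float,
    *,
    epsilon: float = P_FLOOR,
    scorer: Callable[[float, float], float] | None = None,
) -> float:
    """Score a reciprocal search hit from its two p-values.

    The default scorer is ``-log10(pf) - log10(pr)`` with p-values floored at
    ``epsilon``.  Any replacement must be symmetric in its arguments and
    non-increasing in each p-value, so that a high score requires both
    directions of the search to be significant.
    """
    for p in (p_forward, p_reverse):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    if scorer is not None:
        return scorer(p_forward, p_reverse)
    pf = max(p_forward, epsilon)
    pr = max(p_reverse, epsilon)
    return -math.log10(pf) - math.log10(pr)


def evalue_to_pvalue(evalue: float) -> float:
    """Convert a search E-value to a p-value, ``p = 1 - exp(-E)``, capped at 1."""
    if evalue < 0:
        raise ValueError("E-value must be non-negative")
    return min(1.0, -math.expm1(-evalue))


@dataclass
class EnzymeScoreTable:
    """Evidence scores per (species, EC): best reciprocal and best remote score.

    Backed by a DataFrame with columns ``species, ec, blast_score, gtg_score``;
    combinations absent from the table score ``(0, 0)``.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "ec", "blast_score", "gtg_score"]
        )
    )

    def __post_init__(self) -> None:
        f = self.frame
        required = ["species", "ec", "blast_score", "gtg_score"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if f.duplicated(["species", "ec"]).any():
            raise ValueError("duplicate (species, ec) rows in score table")
        if len(f) and (f["blast_score"] < 0).any():
            raise ValueError("negative blast_score")
        if len(f) and ((f["gtg_score"] < 0) | (f["gtg_score"] > 1)).any():
            raise ValueError("gtg_score outside [0, 1]")
        self._index: dict[tuple[str, str], tuple[float, float]] = {
            (r.species, r.ec): (float(r.blast_score), float(r.gtg_score))
            for r in f.itertuples(index=False)
        }

    def get(self, species: str, ec: str) -> tuple[float, float]:
        return self._index.get((species, ec), (0.0, 0.0))

    @property
    def species(self) -> set[str]:
        return set(self.frame["species"])

    @property
    def ecs(self) -> set[str]:
        return set(self.frame["ec"])

    def __len__(self) -> int:
        return len(self.frame)


def enzyme_scores(
    blast_hits: Iterable[HomologyHit],
    gtg_hits: Iterable[RemoteHomologyHit],
    annotation: EcAnnotation,
    species_of: Mapping[str, str],
    *,
    scorer: Callable[[float, float], float] | None = None,
) -> EnzymeScoreTable:
    """Aggregate hits into per-(species, EC) best scores.

    For each species and EC the blast-style score is the maximum
    :func:`reciprocal_score` over hits whose query belongs to the species and
    whose target is annotated with the EC; the remote-homology score is the
    analogous maximum shared fraction.  Annotation targets never hit
    contribute nothing; queries with unknown species raise.
    """
    best: dict[tuple[str, str], list[float]] = {}

    def _bump(species: str, ec: str, col: int, value: float) -> None:
        cell = best.setdefault((species, ec), [0.0, 0.0])
        if value > cell[col]:
            cell[col] = value

    for hit in blast_hits:
        if hit.query_seq not in species_of:
            raise KeyError(f"query sequence {hit.query_seq!r} has no species")
        ecs = annotation.ecs_of(hit.target_seq)
        if not ecs:
            continue
        s = reciprocal_score(hit.p_forward, hit.p_reverse, scorer=scorer)
        for ec in ecs:
            _bump(species_of[hit.query_seq], ec, 0, s)

    for rhit in gtg_hits:
        if rhit.query_seq not in species_of:
            raise KeyError(f"query sequence {rhit.query_seq!r} has no species")
        ecs = annotation.ecs_of(rhit.target_seq)
        if not ecs:
            continue
        for ec in ecs:
            _bump(species_of[rhit.query_seq], ec, 1, rhit.shared_fraction)

    rows = [
        {"species": sp, "ec": ec, "blast_score": b, "gtg_score": g}
        for (sp, ec), (b, g) in sorted(best.items())
    ]
    frame = pd.DataFrame(rows, columns=["species", "ec", "blast_score", "gtg_score"])
    return EnzymeScoreTable(frame)


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in ("query", "target", "species", "ec")})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def read_blast_hits(path) -> list[HomologyHit]:
    frame = _read_tsv(path, ["query", "target", "p_forward", "p_reverse"])
    hits = []
    for i, r in enumerate(frame.itertuples(index=False), start=2):
        try:
            hits.append(
                HomologyHit(r.query, r.target, float(r.p_forward), float(r.p_reverse))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return hits


def read_gtg_hits(path) -> list[RemoteHomologyHit]:
    frame = _read_tsv(path, ["query", "target", "shared_fraction"])
    hits = []
    for i, r in enumerate(frame.itertuples(index=False), start=2):
        try:
            hits.append(RemoteHomologyHit(r.query, r.target, float(r.shared_fraction)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return hits


def read_annotation(path, *, known_targets: set[str] | None = None) -> EcAnnotation:
    frame = _read_tsv(path, ["ec", "target"])
    ann = EcAnnotation()
    for r in frame.itertuples(index=False):
        if known_targets is not None and r.target not in known_targets:
            warnings.warn(f"annotation references unknown target {r.target!r}; skipped")
            continue
        ann.add(r.ec, r.target)
    return ann


def read_species_map(path) -> dict[str, str]:
    frame = _read_tsv(path, ["query", "species"])
    out: dict[str, str] = {}
    for r in frame.itertuples(index=False):
        if r.query in out and out[r.query] != r.species:
            raise ValueError(f"sequence {r.query!r} mapped to two species")
        out[r.query] = r.species
    return out


def read_score_table(path) -> EnzymeScoreTable:
    frame = _read_tsv(path, ["species", "ec", "blast_score", "gtg_score"])
    frame["blast_score"] = frame["blast_score"].astype(float)
    frame["gtg_score"] = frame["gtg_score"].astype(float)
    return EnzymeScoreTable(frame)


def write_score_table(table: EnzymeScoreTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
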