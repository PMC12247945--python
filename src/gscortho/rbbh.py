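"""Tier-1 identity-threshold and tier-2 reciprocal-best-hit ortholog calls.

Tier 1 emulates a Compara-style confidence rule: a reference gene is called
present in a target species when its best forward hit reaches a percent
identity of at least ``min_identity`` (default 25, full-length convention).
Tier 2 is a pure reciprocal-best-hit criterion: a reference gene g and a
target gene h are orthologs iff h is g's best forward hit and g is h's best
reverse hit.  No identity threshold is applied at tier 2; the two tiers are
deliberately independent detection strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .homology import AlignmentHit, Scoring, search_all, score_matrix

__all__ = [
    "OrthologMap",
    "TierStatus",
    "best_hit",
    "call_tier1",
    "call_rbbh",
    "call_tier2",
    "forward_reverse_best",
]


@dataclass(frozen=True)
class TierStatus:
    """Presence call for one gene in one species at one detection tier."""

    gene_id: str
    species: str
    tier: int
    status: str  # "present" | "absent"

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2 or 3")
        if self.status not in ("present", "absent"):
            raise ValueError("status must be 'present' or 'absent'")


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs between a reference and a target species."""

    pairs: dict[str, str] = field(default_factory=dict)  # ref gene -> target gene
    unmatched_ref: set[str] = field(default_factory=set)
    provenance: dict[str, tuple[AlignmentHit, AlignmentHit]] = field(
        default_factory=dict
    )  # ref gene -> (forward hit, reverse hit)

    def __post_init__(self) -> None:
        tgts = list(self.pairs.values())
        if len(set(tgts)) != len(tgts):
            raise ValueError("a target gene appears in more than one pair")


def best_hit(query_id: str, hit_table: Mapping[str, list[AlignmentHit]]) -> AlignmentHit | None:
    """Maximal-score hit for a query under the homology tie-break rule.

    ``hit_table`` is the output of :func:`gscortho.homology.search_all`
    (hits per query already sorted by score desc, target_pid desc, target
    id).  Returns ``None`` for a query with no hits.
    """
    if query_id not in hit_table:
        raise KeyError(f"unknown gene id {query_id!r}")
    hits = hit_table[query_id]
    return hits[0] if hits else None


def forward_reverse_best(
    ref_proteome: Mapping[str, str],
    target_proteome: Mapping[str, str],
    scoring: Scoring = Scoring(),
) -> tuple[dict[str, list[AlignmentHit]], dict[str, list[AlignmentHit]]]:
    """Forward and reverse best-hit tables sharing one score matrix.

    With a symmetric substitution matrix the optimal local score is
    symmetric in its arguments, so the reverse search reuses the transposed
    forward score matrix instead of recomputing every alignment.
    """
    scores = score_matrix(ref_proteome, target_proteome, scoring)
    fwd = search_all(ref_proteome, target_proteome, scoring, keep_top=1, scores=scores)
    rev = search_all(
        target_proteome, ref_proteome, scoring, keep_top=1, scores=scores.T
    )
    return fwd, rev


def call_tier1(
    ref_proteome: Mapping[str, str],
    target_proteome: Mapping[str, str],
    species: str,
    min_identity: float = 25.0,
    scoring: Scoring = Scoring(),
    *,
    require_both: bool = False,
    hits: Mapping[str, list[AlignmentHit]] | None = None,
) -> list[TierStatus]:
    """Identity-threshold presence calls (tier 1).

    A gene is present iff its best forward hit reaches ``min_identity``
    percent identity on the query or the target length (``require_both``
    demands both).  The threshold is inclusive (>=).  Precomputed forward
    ``hits`` may be supplied.
    """
    if not ref_proteome or not target_proteome:
        raise ValueError("proteomes must be non-empty")
    if hits is None:
        hits = search_all(ref_proteome, target_proteome, scoring, keep_top=1)
    out = []
    for gene in ref_proteome:
        hit = best_hit(gene, hits)
        if hit is None:
            present = False
        elif require_both:
            present = hit.query_pid >= min_identity and hit.target_pid >= min_identity
        else:
            present = hit.query_pid >= min_identity or hit.target_pid >= min_identity
        out.append(TierStatus(gene, species, 1, "present" if present else "absent"))
    return out


def call_rbbh(
    ref_proteome: Mapping[str, str],
    target_proteome: Mapping[str, str],
    scoring: Scoring = Scoring(),
    *,
    tables: tuple[Mapping[str, list[AlignmentHit]], Mapping[str, list[AlignmentHit]]]
    | None = None,
) -> OrthologMap:
    """Reciprocal-best-hit ortholog pairs (tier 2).

    (g, h) is a pair iff h = best forward hit of g and g = best reverse hit
    of h.  Reference genes without a reciprocal partner land in
    ``unmatched_ref``.  Output is independent of input record order.
    """
    if not ref_proteome or not target_proteome:
        raise ValueError("proteomes must be non-empty")
    fwd, rev = tables if tables is not None else forward_reverse_best(
        ref_proteome, target_proteome, scoring
    )
    result = OrthologMap()
    for g in sorted(ref_proteome):
        fh = best_hit(g, fwd)
        if fh is None:
            result.unmatched_ref.add(g)
            continue
        rh = best_hit(fh.target_id, rev)
        if rh is not None and rh.target_id == g:
            result.pairs[g] = fh.target_id
            result.provenance[g] = (fh, rh)
        else:
            result.unmatched_ref.add(g)
    return result


def call_tier2(
    ref_gene_ids: Iterable[str],
    ortholog_maps: Mapping[str, OrthologMap],
) -> list[TierStatus]:
    """Presence calls from RBBH maps: present iff the gene has a pair."""
    out = []
    for sp, omap in ortholog_maps.items():
        known = set(omap.pairs) | omap.unmatched_ref
        for gene in ref_gene_ids:
            if known and gene not in known:
                raise KeyError(f"gene {gene!r} absent from the ortholog map for {sp}")
            status = "present" if gene in omap.pairs else "absent"
            out.append(TierStatus(gene, sp, 2, status))
    return out


def ortholog_map_to_table(omap: OrthologMap):
    """Pair table (ref_id, target_id, fwd_score, rev_score, fwd_target_pid)."""
    import pandas as pd

    rows = []
    for g, h in sorted(omap.pairs.items()):
        fh, rh = omap.provenance[g]
        rows.append(
            {
                "ref_id": g,
                "target_id": h,
                "fwd_score": fh.score,
                "rev_score": rh.score,
                "fwd_target_pid": fh.target_pid,
            }
        )
    return pd.DataFrame(
        rows, columns=["ref_id", "target_id", "fwd_score", "rev_score", "fwd_target_pid"]
    )
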