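"""Reporting layer: presence/absence matrices, breakdowns, and the pipeline.

Collapses per-tier verdicts into a binary genes x species presence/absence
matrix and derives the summary tables: per-species absence counts and
percentages, breakdowns by functional category or RNAi defect type, and
interaction-network co-absence counts.  ``run_pipeline`` chains the three
detection tiers end to end over a clade of assemblies and emits a
reproducible report bundle.

Collapse rule (default): ``present_rescued`` counts as present and only
``absent_confirmed`` counts as absent; ``unresolved`` verdicts collapse to
present, so reported absences are exactly the verified-absence class.  A
strict mode keeps unresolved as a third reported state instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .homology import Scoring
from .rbbh import TierStatus, call_rbbh, call_tier1, call_tier2, forward_reverse_best
from .synteny import FinalVerdict, evaluate_gene
from .synthetic_data import Clade

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMetadata",
    "collapse_verdicts",
    "per_species_percent",
    "category_breakdown",
    "network_coabsence",
    "PipelineResult",
    "run_pipeline",
    "write_report",
    "parse_config",
]

NO_CATEGORY = "No functional category"


@dataclass(frozen=True)
class GeneMetadata:
    """Functional annotation attached to a gene for reporting."""

    gene_id: str
    functional_category: str | None = None
    defect_type: str | None = None
    interactors: tuple[str, ...] = ()


DEFECT_TYPES = (
    "GSC loss (cell viability)",
    "GSC loss (agametic)",
    "differentiation defect",
    "oocyte-specific/late oogenesis",
)


def _round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (0.125 -> 0.13 at 2 decimals)."""
    factor = 10**decimals
    import math

    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def collapse_verdicts(
    verdicts: Iterable[FinalVerdict | TierStatus],
    strict: bool = False,
) -> pd.DataFrame:
    """Genes x species matrix of 'present'/'absent' cells.

    Accepts tier-3 verdicts (or tier statuses) and applies the collapse
    rule: rescued -> present, only confirmed absences -> absent; unresolved
    -> present unless ``strict``, in which case the cell keeps the value
    'unresolved'.
    """
    rows = []
    for v in verdicts:
        status = v.status
        if status in ("present", "present_rescued"):
            cell = "present"
        elif status in ("absent", "absent_confirmed"):
            cell = "absent"
        elif status == "unresolved":
            cell = "unresolved" if strict else "present"
        else:
            raise ValueError(f"unknown verdict status {status!r}")
        rows.append({"gene_id": v.gene_id, "species": v.species, "cell": cell})
    frame = pd.DataFrame(rows)
    matrix = frame.pivot_table(
        index="gene_id", columns="species", values="cell", aggfunc="first"
    )
    if matrix.isna().any().any():
        raise ValueError("matrix has unfilled (gene, species) cells")
    return matrix.sort_index()


def per_species_percent(
    matrix: pd.DataFrame, denominator: int, decimals: int = 2
) -> pd.DataFrame:
    """Absence count and percentage per species.

    ``percent = round(100 * count / denominator, decimals)``, rounding half
    away from zero.  The denominator is the size of the focal gene list,
    which may exceed the number of matrix rows when extra tracked genes are
    excluded from the denominators.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    counts = (matrix == "absent").sum(axis=0)
    if counts.max() > denominator:
        raise ValueError("denominator smaller than a per-species absence count")
    return pd.DataFrame(
        {
            "species": counts.index,
            "n_absent": counts.to_numpy(),
            "percent": [
                _round_half_away(100.0 * c / denominator, decimals) for c in counts
            ],
        }
    ).reset_index(drop=True)


def _metadata_frame(metadata: Iterable[GeneMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "functional_category": m.functional_category,
                "defect_type": m.defect_type,
                "interactors": list(m.interactors),
            }
            for m in metadata
        ],
        columns=["gene_id", "functional_category", "defect_type", "interactors"],
    )


def category_breakdown(
    matrix: pd.DataFrame,
    metadata: Iterable[GeneMetadata],
    group_by: str = "functional_category",
    decimals: int = 0,
) -> pd.DataFrame:
    """Per-category gene counts and percentage with >=1 absence.

    A gene counts as absent for its category when it is absent in at least
    one species.  Genes without a category are pooled into the
    '{NO_CATEGORY}' bucket.
    """
    if group_by not in ("functional_category", "defect_type"):
        raise ValueError("group_by must be 'functional_category' or 'defect_type'")
    meta = _metadata_frame(metadata).set_index("gene_id")
    absent_any = (matrix == "absent").any(axis=1)
    rows: dict[str, list[int]] = {}
    for gene in matrix.index:
        cat = meta[group_by].get(gene) if gene in meta.index else None
        cat = cat if cat else NO_CATEGORY
        n, a = rows.get(cat, [0, 0])
        rows[cat] = [n + 1, a + int(absent_any.get(gene, False))]
    return pd.DataFrame(
        [
            {
                "category": cat,
                "n_genes": n,
                "n_with_any_absence": a,
                "percent": _round_half_away(100.0 * a / n, decimals),
            }
            for cat, (n, a) in sorted(rows.items())
        ]
    )


def network_coabsence(
    matrix: pd.DataFrame, metadata: Iterable[GeneMetadata]
) -> pd.DataFrame:
    """Interaction-network absence counts for each focal absent gene.

    For every gene absent in >=1 species: the size of its interactor list,
    how many interactors are absent anywhere, and how many are absent in
    at least one species where the focal gene itself is absent.
    Interactors missing from the matrix are logged and skipped.
    """
    meta = {m.gene_id: m for m in metadata}
    absent = matrix == "absent"
    rows = []
    for gene in matrix.index:
        if not absent.loc[gene].any():
            continue
        interactors = meta[gene].interactors if gene in meta else ()
        known = []
        for i in interactors:
            if i in matrix.index:
                known.append(i)
            else:
                logger.warning("interactor %s of %s not in matrix; skipped", i, gene)
        focal_species = absent.columns[absent.loc[gene]]
        n_net_absent = sum(absent.loc[i].any() for i in known)
        n_coabsent = sum(absent.loc[i, focal_species].any() for i in known)
        rows.append(
            {
                "gene_id": gene,
                "network_size": len(interactors),
                "n_network_absent": int(n_net_absent),
                "n_same_species_coabsent": int(n_coabsent),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "network_size", "n_network_absent", "n_same_species_coabsent"],
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class PipelineResult:
    tier1: pd.DataFrame  # gene, species, tier, status
    tier2: pd.DataFrame
    tier3: pd.DataFrame  # gene, species, status (verdict vocabulary)
    verdicts: list[FinalVerdict]
    matrix: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _statuses_to_frame(statuses: Iterable[TierStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": s.gene_id, "species": s.species, "tier": s.tier, "status": s.status}
            for s in statuses
        ]
    )


def run_pipeline(
    clade: Clade,
    scoring: Scoring = Scoring(),
    min_identity: float = 25.0,
    k_anchors: int = 3,
    end_margin: int = 1000,
    min_fraction: float = 0.3,
    strict: bool = False,
) -> PipelineResult:
    """Run tiers 1-3 over a clade and collapse the verdict matrix.

    Tier 1 (identity threshold) and tier 2 (RBBH) share one score matrix
    per target species; tier 3 re-examines only tier-2 absences.  The
    manifest records parameters and per-species proteome checksums, and
    the tier-funnel invariant (tier-3 absences are a subset of tier-2
    absences) is asserted at run time.
    """
    ref = clade.reference
    targets = clade.species[1:]
    gene_ids = clade.gene_ids
    tier1: list[TierStatus] = []
    verdicts: list[FinalVerdict] = []
    maps = {}
    t0 = time.perf_counter()
    for sp in targets:
        asm = clade.assemblies[sp]
        if not asm.proteome:
            raise ValueError(f"species {sp} has an empty proteome")
        tables = forward_reverse_best(ref.proteome, asm.proteome, scoring)
        tier1.extend(
            call_tier1(
                ref.proteome, asm.proteome, sp, min_identity, scoring, hits=tables[0]
            )
        )
        maps[sp] = call_rbbh(ref.proteome, asm.proteome, scoring, tables=tables)
        logger.info("tier1+2 %s done in %.2fs", sp, time.perf_counter() - t0)
    tier2 = call_tier2(gene_ids, maps)
    tier2_by_key = {(s.gene_id, s.species): s.status for s in tier2}
    for sp in targets:
        asm = clade.assemblies[sp]
        for gene in gene_ids:
            verdicts.append(
                evaluate_gene(
                    gene,
                    sp,
                    tier2_by_key[(gene, sp)],
                    ref.annotation,
                    asm.annotation,
                    maps[sp],
                    asm.contigs,
                    ref.proteome[gene],
                    scoring,
                    k=k_anchors,
                    end_margin=end_margin,
                    min_fraction=min_fraction,
                )
            )
        logger.info("tier3 %s done in %.2fs", sp, time.perf_counter() - t0)

    tier2_absent = {k for k, v in tier2_by_key.items() if v == "absent"}
    tier3_absent = {
        (v.gene_id, v.species) for v in verdicts if v.status == "absent_confirmed"
    }
    assert tier3_absent <= tier2_absent, "tier-3 absences must be tier-2 absences"

    matrix = collapse_verdicts(verdicts, strict=strict)
    manifest = {
        "species": clade.species,
        "n_genes": len(gene_ids),
        "params": {
            "min_identity": min_identity,
            "k_anchors": k_anchors,
            "end_margin": end_margin,
            "min_fraction": min_fraction,
            "matrix": scoring.matrix,
            "gap_open": scoring.gap_open,
            "gap_extend": scoring.gap_extend,
            "strict": strict,
        },
        "sim_params": vars(clade.params),
        "proteome_sha1": {
            sp: hashlib.sha1(
                "".join(f">{k}\n{v}\n" for k, v in clade.assemblies[sp].proteome.items()).encode()
            ).hexdigest()
            for sp in clade.species
        },
        "n_tier2_absent": len(tier2_absent),
        "n_tier3_absent": len(tier3_absent),
    }
    return PipelineResult(
        tier1=_statuses_to_frame(tier1),
        tier2=_statuses_to_frame(tier2),
        tier3=pd.DataFrame(
            [
                {"gene_id": v.gene_id, "species": v.species, "tier": 3, "status": v.status}
                for v in verdicts
            ]
        ),
        verdicts=verdicts,
        matrix=matrix,
        manifest=manifest,
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Emit the report bundle: per-tier TSVs, 0/1 matrix, JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.tier1.to_csv(out / "tier1.tsv", sep="\t", index=False)
    result.tier2.to_csv(out / "tier2.tsv", sep="\t", index=False)
    result.tier3.to_csv(out / "tier3.tsv", sep="\t", index=False)
    binary = (result.matrix == "absent").astype(int)
    binary.to_csv(out / "absence_matrix.tsv", sep="\t")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def parse_config(path: str | Path) -> dict[str, str]:
    """Flat key=value config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
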