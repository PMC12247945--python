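"""Synthetic multi-species clades, polymorphism samples, and progeny counts.

Every stage of the ortholog presence/absence pipeline, the lineage-specific
McDonald-Kreitman test, and the fertility statistics can be exercised against
planted ground truth without downloading any real assembly:

* :func:`simulate_clade` emits per-species contig FASTA, gene annotations and
  proteomes for a clade in which a reference species carries every gene on a
  single chromosome in fixed order, and each other species independently
  loses genes, diverges in amino-acid sequence, and suffers assembly
  fragmentation that can split a gene across contigs (the contig-end artifact
  observed for real fragmented gene models).
* :func:`simulate_polymorphism` plants exact counts of synonymous and
  nonsynonymous polymorphisms (at controlled sample frequencies) and fixed
  differences against an ancestral coding sequence.
* :func:`simulate_fertility` draws negative-binomial progeny counts with
  designated all-zero sterile genotypes.

All generators are seeded and byte-identical across runs with equal
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .homology import write_fasta

__all__ = [
    "CladeSimParams",
    "CladeTruth",
    "Assembly",
    "Clade",
    "MKSimParams",
    "PolymorphismSample",
    "FertilitySimParams",
    "simulate_clade",
    "simulate_polymorphism",
    "simulate_fertility",
    "write_clade",
]

# ---------------------------------------------------------------------------
# Genetic-code helpers (standard nuclear code)

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AA_TO_CODONS
}
_BASES = "ACGT"


def _single_nt_neighbors(codon: str) -> list[tuple[int, str]]:
    """(offset, neighbor codon) for all nine single-nucleotide changes."""
    out = []
    for off in range(3):
        for b in _BASES:
            if b != codon[off]:
                out.append((off, codon[:off] + b + codon[off + 1 :]))
    return out


#: Sense codons having at least one synonymous single-nucleotide neighbor.
SYN_CAPABLE_CODONS: tuple[str, ...] = tuple(
    c
    for c in SENSE_CODONS
    if any(
        n not in STOP_CODONS and CODON_TO_AA[n] == CODON_TO_AA[c]
        for _, n in _single_nt_neighbors(c)
    )
)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, dropping a single trailing stop codon."""
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# Clade simulation

REFERENCE_SPECIES = "sp0"


@dataclass(frozen=True)
class CladeSimParams:
    """Knobs of the clade generator.

    ``subst_rate`` is the expected number of amino-acid substitutions per
    site accumulated by each non-reference species; ``frag_break_rate`` is
    the expected number of assembly breakpoints per 100 kb of chromosome,
    each landing inside a gene with probability ``gene_split_prob``.
    """

    n_genes: int = 50
    n_species: int = 4
    loss_prob: float = 0.1
    subst_rate: float = 0.1
    frag_break_rate: float = 0.5
    gene_split_prob: float = 0.5
    intergenic_len: int = 1000
    gene_len_codons: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if self.gene_len_codons < 1:
            raise ValueError("gene_len_codons must be positive")
        if self.intergenic_len < 1:
            raise ValueError("intergenic_len must be positive")
        for name in ("loss_prob", "gene_split_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.subst_rate < 0 or self.frag_break_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class CladeTruth:
    """Planted per-(gene, species) status and genomic coordinates.

    ``status`` maps (gene_id, species_id) to one of ``present_intact``,
    ``lost`` or ``split_across_contigs``; ``coordinates`` holds the largest
    emitted fragment for every non-lost gene (contig, start, end, strand).
    """

    status: dict[tuple[str, str], str] = field(default_factory=dict)
    coordinates: dict[tuple[str, str], tuple[str, int, int, str]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gene, sp), status in self.status.items():
            coord = self.coordinates.get((gene, sp))
            rows.append(
                {
                    "gene_id": gene,
                    "species": sp,
                    "status": status,
                    "contig": coord[0] if coord else "",
                    "start": coord[1] if coord else -1,
                    "end": coord[2] if coord else -1,
                    "strand": coord[3] if coord else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class Assembly:
    """One species' simulated assembly: contigs, gene models, proteome."""

    species: str
    contigs: dict[str, str]
    annotation: pd.DataFrame  # gene_id, contig, start, end, strand (0-based half-open)
    proteome: dict[str, str]


@dataclass
class Clade:
    params: CladeSimParams
    species: list[str]
    assemblies: dict[str, Assembly]
    truth: CladeTruth

    @property
    def reference(self) -> Assembly:
        return self.assemblies[self.species[0]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.reference.annotation["gene_id"])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA; translates to n_codons residues."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Amino-acid substitutions at the given per-site rate.

    Each substituted residue is replaced by a uniformly chosen different
    amino acid, re-encoded with a uniformly chosen codon for the new
    residue (the start codon is left untouched so the gene model survives).
    """
    if rate == 0:
        return cds
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    hit = np.flatnonzero(rng.random(len(codons) - 1) < rate) + 1  # skip ATG
    aas = sorted(AA_TO_CODONS)
    for i in hit:
        old_aa = CODON_TO_AA[codons[i]]
        choices = [a for a in aas if a != old_aa]
        new_aa = choices[rng.integers(len(choices))]
        syn = AA_TO_CODONS[new_aa]
        codons[i] = syn[rng.integers(len(syn))]
    return "".join(codons) + "TAA"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def simulate_clade(params: CladeSimParams) -> Clade:
    """Generate a clade of assemblies with planted ground truth.

    Species 0 is the reference: every gene intact, single contig, fixed gene
    order with fixed intergenic spacing.  Each other species independently
    loses each gene with ``loss_prob`` (a clean deletion of the gene body),
    accumulates amino-acid substitutions at ``subst_rate``, and is broken
    into contigs by a Poisson breakpoint process; a breakpoint lands inside
    a surviving gene with probability ``gene_split_prob``, leaving truncated
    fragments on the two resulting contigs.  Split genes keep annotation
    rows on each fragment but are dropped from the proteome, emulating gene
    models broken across contig ends.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    ref_cds = {g: _random_cds(rng, params.gene_len_codons) for g in gene_ids}
    strands = {g: ("+" if rng.random() < 0.5 else "-") for g in gene_ids}
    gene_len = 3 * (params.gene_len_codons + 1)

    truth = CladeTruth()
    species = [f"sp{i}" for i in range(params.n_species)]
    assemblies: dict[str, Assembly] = {}

    for s_idx, sp in enumerate(species):
        is_ref = s_idx == 0
        lost = {
            g: (not is_ref) and bool(rng.random() < params.loss_prob)
            for g in gene_ids
        }
        cds = {}
        for g in gene_ids:
            if lost[g]:
                continue
            cds[g] = (
                ref_cds[g]
                if is_ref
                else _mutate_cds(rng, ref_cds[g], params.subst_rate)
            )

        # Assemble the chromosome: spacer, gene, spacer, gene, ..., spacer.
        parts: list[str] = []
        pos = 0
        gene_intervals: dict[str, tuple[int, int]] = {}

        def _spacer() -> None:
            nonlocal pos
            seg = "".join(
                _BASES[i] for i in rng.integers(4, size=params.intergenic_len)
            )
            parts.append(seg)
            pos += len(seg)

        _spacer()
        for g in gene_ids:
            if lost[g]:
                continue
            seq = cds[g] if strands[g] == "+" else _revcomp(cds[g])
            gene_intervals[g] = (pos, pos + len(seq))
            parts.append(seq)
            pos += len(seq)
            _spacer()
        chrom = "".join(parts)

        # Poisson fragmentation; breakpoints at codon boundaries inside a
        # uniformly chosen surviving gene with prob gene_split_prob, else
        # uniform over intergenic space.
        cuts: list[int] = []
        if not is_ref and params.frag_break_rate > 0:
            n_bp = int(rng.poisson(params.frag_break_rate * len(chrom) / 1e5))
            present = [g for g in gene_ids if not lost[g]]
            for _ in range(n_bp):
                if present and rng.random() < params.gene_split_prob:
                    g = present[rng.integers(len(present))]
                    lo = max(1, params.gene_len_codons // 10)
                    hi = max(lo + 1, (9 * params.gene_len_codons) // 10)
                    start, _end = gene_intervals[g]
                    cuts.append(start + 3 * int(rng.integers(lo, hi)))
                else:
                    intervals = _intergenic_intervals(len(chrom), gene_intervals)
                    total = sum(b - a for a, b in intervals)
                    x = int(rng.integers(total))
                    for a, b in intervals:
                        if x < b - a:
                            cuts.append(a + x)
                            break
                        x -= b - a
        bounds = sorted({0, len(chrom), *cuts})
        contig_spans = list(zip(bounds[:-1], bounds[1:]))
        contigs = {
            f"{sp}_ctg{k}": chrom[a:b] for k, (a, b) in enumerate(contig_spans)
        }

        # Gene models per contig; genes overlapping >=2 contigs are split.
        ann_rows = []
        proteome: dict[str, str] = {}
        for g in gene_ids:
            if lost[g]:
                truth.status[(g, sp)] = "lost"
                continue
            gs, ge = gene_intervals[g]
            pieces = []
            for k, (a, b) in enumerate(contig_spans):
                lo, hi = max(gs, a), min(ge, b)
                if lo < hi:
                    pieces.append((f"{sp}_ctg{k}", lo - a, hi - a))
            for ctg, a, b in pieces:
                ann_rows.append(
                    {
                        "gene_id": g,
                        "contig": ctg,
                        "start": a,
                        "end": b,
                        "strand": strands[g],
                    }
                )
            if len(pieces) == 1:
                truth.status[(g, sp)] = "present_intact"
                proteome[g] = translate_cds(cds[g])
            else:
                truth.status[(g, sp)] = "split_across_contigs"
            big = max(pieces, key=lambda p: p[2] - p[1])
            truth.coordinates[(g, sp)] = (big[0], big[1], big[2], strands[g])
        annotation = pd.DataFrame(
            ann_rows, columns=["gene_id", "contig", "start", "end", "strand"]
        )
        assemblies[sp] = Assembly(sp, contigs, annotation, proteome)

    return Clade(params, species, assemblies, truth)


def _intergenic_intervals(
    length: int, gene_intervals: Mapping[str, tuple[int, int]]
) -> list[tuple[int, int]]:
    occupied = sorted(gene_intervals.values())
    out = []
    prev = 0
    for a, b in occupied:
        if prev < a:
            out.append((prev, a))
        prev = b
    if prev < length:
        out.append((prev, length))
    return out


def load_clade(run_dir: str | Path) -> Clade:
    """Rehydrate a clade from a :func:`write_clade` run directory."""
    from .homology import read_fasta

    run_dir = Path(run_dir)
    with open(run_dir / "params.json") as fh:
        meta = json.load(fh)
    species = meta.pop("species")
    params = CladeSimParams(**meta)
    truth = CladeTruth()
    tf = pd.read_csv(run_dir / "truth.tsv", sep="\t")
    for row in tf.itertuples(index=False):
        truth.status[(row.gene_id, row.species)] = row.status
        if row.status != "lost":
            truth.coordinates[(row.gene_id, row.species)] = (
                row.contig,
                int(row.start),
                int(row.end),
                row.strand,
            )
    assemblies = {}
    for sp in species:
        assemblies[sp] = Assembly(
            species=sp,
            contigs=read_fasta(run_dir / f"{sp}.contigs.fa"),
            annotation=pd.read_csv(run_dir / f"{sp}.annotation.tsv", sep="\t"),
            proteome=read_fasta(run_dir / f"{sp}.proteome.fa"),
        )
    return Clade(params, species, assemblies, truth)


def write_clade(clade: Clade, out_root: str | Path) -> Path:
    """Emit the clade under ``<out_root>/run_<seed>/`` (FASTA + TSV + JSON)."""
    run_dir = Path(out_root) / f"run_{clade.params.seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    for sp, asm in clade.assemblies.items():
        write_fasta(asm.contigs, run_dir / f"{sp}.contigs.fa")
        write_fasta(asm.proteome, run_dir / f"{sp}.proteome.fa")
        asm.annotation.to_csv(run_dir / f"{sp}.annotation.tsv", sep="\t", index=False)
    clade.truth.to_frame().to_csv(run_dir / "truth.tsv", sep="\t", index=False)
    with open(run_dir / "params.json", "w") as fh:
        json.dump(vars(clade.params) | {"species": clade.species}, fh, indent=2)
        fh.write("\n")
    return run_dir


# ---------------------------------------------------------------------------
# Polymorphism-sample simulation

@dataclass(frozen=True)
class MKSimParams:
    """Planted counts for a McDonald-Kreitman truth set.

    ``poly_freqs`` gives the sample frequency of the variant allele for each
    polymorphic site (synonymous sites first, then nonsynonymous); each
    frequency must be realizable as ``round(f * n_alleles)`` copies with at
    least one copy of each allele.
    """

    n_alleles: int = 10
    n_codons: int = 442
    n_syn_poly: int = 0
    n_nonsyn_poly: int = 0
    n_syn_div: int = 0
    n_nonsyn_div: int = 0
    poly_freqs: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError("n_alleles must be >= 2")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        counts = (self.n_syn_poly, self.n_nonsyn_poly, self.n_syn_div, self.n_nonsyn_div)
        if any(c < 0 for c in counts):
            raise ValueError("site counts must be non-negative")
        if sum(counts) > self.n_codons:
            raise ValueError("requested sites exceed n_codons")
        if len(self.poly_freqs) != self.n_syn_poly + self.n_nonsyn_poly:
            raise ValueError("poly_freqs length must equal the polymorphic site count")
        for f in self.poly_freqs:
            k = round(f * self.n_alleles)
            if not 1 <= k <= self.n_alleles - 1:
                raise ValueError(
                    f"frequency {f} not realizable with {self.n_alleles} alleles"
                )


@dataclass
class PolymorphismSample:
    """Aligned allele sample plus ancestor and the planted truth."""

    alleles: list[str]
    ancestor: str
    sites: pd.DataFrame  # codon, offset, kind, effect, freq
    planted: dict[str, int]  # Ps, Pn, Ds, Dn


def _pick_change(
    rng: np.random.Generator, base: str, synonymous: bool
) -> tuple[int, str] | None:
    opts = [
        (off, nb)
        for off, nb in _single_nt_neighbors(base)
        if nb not in STOP_CODONS
        and (CODON_TO_AA[nb] == CODON_TO_AA[base]) == synonymous
    ]
    if not opts:
        return None
    return opts[rng.integers(len(opts))]


def simulate_polymorphism(params: MKSimParams) -> PolymorphismSample:
    """Plant exact polymorphism/divergence counts in a coding alignment.

    Planted sites occupy distinct codons.  A polymorphic site segregates at
    exactly ``round(f * n_alleles)`` variant copies; a divergent site is
    fixed in the sample and differs from the ancestor.  The synonymous or
    nonsynonymous character of every planted change is verified against the
    standard genetic code before emission.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_alleles
    codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), params.n_codons)]

    total = (
        params.n_syn_poly + params.n_nonsyn_poly + params.n_syn_div + params.n_nonsyn_div
    )
    site_idx = rng.choice(params.n_codons, size=total, replace=False)
    classes = (
        [("polymorphic", "synonymous")] * params.n_syn_poly
        + [("polymorphic", "nonsynonymous")] * params.n_nonsyn_poly
        + [("divergent", "synonymous")] * params.n_syn_div
        + [("divergent", "nonsynonymous")] * params.n_nonsyn_div
    )
    freqs = list(params.poly_freqs) + [None] * (params.n_syn_div + params.n_nonsyn_div)

    allele_codons = [list(codons) for _ in range(n)]
    ancestor_codons = list(codons)
    rows = []
    planted = {"Ps": 0, "Pn": 0, "Ds": 0, "Dn": 0}
    for c, (kind, effect), f in zip(site_idx, classes, freqs):
        synonymous = effect == "synonymous"
        if synonymous and codons[c] not in SYN_CAPABLE_CODONS:
            repl = SYN_CAPABLE_CODONS[rng.integers(len(SYN_CAPABLE_CODONS))]
            ancestor_codons[c] = repl
            for al in allele_codons:
                al[c] = repl
        base = ancestor_codons[c]
        off, variant = _pick_change(rng, base, synonymous)
        assert (CODON_TO_AA[variant] == CODON_TO_AA[base]) == synonymous
        if kind == "divergent":
            for al in allele_codons:
                al[c] = variant
            planted["Ds" if synonymous else "Dn"] += 1
            rows.append(
                {"codon": int(c), "offset": off, "kind": kind, "effect": effect,
                 "freq": np.nan}
            )
        else:
            k = round(f * n)
            carriers = rng.choice(n, size=k, replace=False)
            for i in carriers:
                allele_codons[i][c] = variant
            planted["Ps" if synonymous else "Pn"] += 1
            rows.append(
                {"codon": int(c), "offset": off, "kind": kind, "effect": effect,
                 "freq": k / n}
            )

    return PolymorphismSample(
        alleles=["".join(al) for al in allele_codons],
        ancestor="".join(ancestor_codons),
        sites=pd.DataFrame(rows, columns=["codon", "offset", "kind", "effect", "freq"]),
        planted=planted,
    )


# ---------------------------------------------------------------------------
# Fertility-count simulation

@dataclass(frozen=True)
class FertilitySimParams:
    """Progeny-count generator: negative-binomial fertile genotypes plus
    designated sterile genotypes whose counts are forced to zero."""

    n_per_genotype: int = 20
    wt_mean: float = 50.0
    wt_dispersion: float = 5.0
    fertile_genotypes: tuple[str, ...] = ("wildtype",)
    sterile_genotypes: tuple[str, ...] = ("null",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ValueError("n_per_genotype must be >= 2")
        if self.wt_mean <= 0:
            raise ValueError("wt_mean must be positive")
        if self.wt_dispersion <= 0:
            raise ValueError("wt_dispersion must be positive")


def simulate_fertility(params: FertilitySimParams) -> dict[str, np.ndarray]:
    """Progeny counts per genotype.

    Fertile genotypes are NB(mean=wt_mean, dispersion=wt_dispersion) with
    variance ``mean + mean**2 / dispersion``; sterile genotypes are all
    zeros.
    """
    rng = np.random.default_rng(params.seed)
    k, m = params.wt_dispersion, params.wt_mean
    p = k / (k + m)
    out: dict[str, np.ndarray] = {}
    for g in params.fertile_genotypes:
        out[g] = rng.negative_binomial(k, p, size=params.n_per_genotype).astype(int)
    for g in params.sterile_genotypes:
        out[g] = np.zeros(params.n_per_genotype, dtype=int)
    return out


def fertility_to_frame(counts: Mapping[str, Sequence[int]], sex: str = "female") -> pd.DataFrame:
    """Long-format table (genotype, sex, progeny_count) for file interchange."""
    rows = [
        {"genotype": g, "sex": sex, "progeny_count": int(c)}
        for g, arr in counts.items()
        for c in arr
    ]
    return pd.DataFrame(rows)
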