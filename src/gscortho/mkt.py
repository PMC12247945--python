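"""Lineage-specific McDonald-Kreitman test with low-frequency filtering.

The test contrasts synonymous and nonsynonymous variation segregating
within a species (polymorphism, Ps/Pn) with variation fixed between the
species and its inferred common ancestor (divergence, Ds/Dn).  Under strict
neutrality Pn/Ps ~ Dn/Ds; an excess of nonsynonymous divergence signals
positive selection.  Derived statistics:

* Pearson chi-square on the 2x2 table (no continuity correction) and its
  1-df tail probability, plus the two-sided Fisher exact p-value,
* alpha = 1 - (Ds*Pn)/(Dn*Ps), the estimated proportion of amino-acid
  fixations driven by positive selection,
* NI = (Pn/Ps)/(Dn/Ds), the neutrality index.

Polymorphisms segregating below a frequency cutoff (default 12%, read as
minor-allele frequency) can be excluded before building the table: such
variants are enriched for slightly deleterious alleles not yet removed by
purifying selection, which otherwise inflate Pn and bias the test toward
conservation.

Divergence is lineage-specific: sites are polarized against a supplied
ancestral coding sequence (e.g. a codeml reconstruction); a simple
majority-rule parsimony fallback over (focal, sister, outgroup) is
provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .synthetic_data import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCall",
    "MKTable",
    "MKResult",
    "classify_sites",
    "filter_low_frequency",
    "build_table",
    "mk_test",
    "parsimony_ancestor",
]


@dataclass(frozen=True)
class SiteCall:
    """One classified nucleotide site.

    ``variant_freq`` is the sample frequency of the minor allele and is
    only defined for polymorphic sites.
    """

    codon: int
    offset: int  # 0-2 within the codon
    kind: str  # "polymorphic" | "divergent"
    effect: str  # "synonymous" | "nonsynonymous"
    variant_freq: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("polymorphic", "divergent"):
            raise ValueError("kind must be 'polymorphic' or 'divergent'")
        if self.effect not in ("synonymous", "nonsynonymous"):
            raise ValueError("effect must be 'synonymous' or 'nonsynonymous'")
        if (self.kind == "polymorphic") != (self.variant_freq is not None):
            raise ValueError("variant_freq defined iff the site is polymorphic")


@dataclass(frozen=True)
class MKTable:
    """2x2 contingency table: polymorphism/divergence x syn/nonsyn."""

    Ps: int
    Ds: int
    Pn: int
    Dn: int

    def __post_init__(self) -> None:
        if min(self.Ps, self.Ds, self.Pn, self.Dn) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class MKResult:
    table: MKTable
    chi2: float
    chi2_p: float
    fisher_p: float
    alpha: float | None
    ni: float | None


def _codon_effect(codon_a: str, codon_b: str) -> str:
    """synonymous/nonsynonymous character of a codon substitution."""
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} in coding context")
        if c not in CODON_TO_AA:
            raise ValueError(f"unrecognized codon {c!r}")
    return "synonymous" if CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b] else "nonsynonymous"


def classify_sites(
    alleles: Sequence[str],
    ancestor: str,
    *,
    skipped: list[int] | None = None,
) -> list[SiteCall]:
    """Classify every variable nucleotide position of a coding alignment.

    A position is *polymorphic* when two states segregate in the sample;
    the effect of the change is judged by substituting the minor state into
    the sample-majority codon.  A position is *divergent* when the sample
    is monomorphic but differs from the ancestor; its effect is judged in
    the ancestral codon context.  A position that is both segregating and
    ancestrally mismatched counts as polymorphic only (a segregating site
    is not a fixation).  Positions with more than two sample states are
    reported via ``skipped`` (and a logged warning) and excluded.
    """
    if len(alleles) < 2:
        raise ValueError("need at least two sampled alleles")
    length = len(ancestor)
    if any(len(a) != length for a in alleles):
        raise ValueError("alleles and ancestor must be aligned to equal length")
    if length % 3:
        raise ValueError("alignment length must be divisible by 3")
    n = len(alleles)
    calls: list[SiteCall] = []
    # Majority codon context per codon, used for polymorphic-effect calls.
    for pos in range(length):
        states = [a[pos] for a in alleles]
        counts: dict[str, int] = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
        if len(counts) > 2:
            logger.warning("site %d has >2 states; skipped", pos)
            if skipped is not None:
                skipped.append(pos)
            continue
        c0 = pos - pos % 3
        if len(counts) == 2:
            (major, _), (minor, k) = sorted(
                counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
            majority_codon = "".join(
                _majority_state([a[i] for a in alleles]) for i in range(c0, c0 + 3)
            )
            variant_codon = (
                majority_codon[: pos - c0] + minor + majority_codon[pos - c0 + 1 :]
            )
            calls.append(
                SiteCall(
                    codon=c0 // 3,
                    offset=pos - c0,
                    kind="polymorphic",
                    effect=_codon_effect(majority_codon, variant_codon),
                    variant_freq=k / n,
                )
            )
        else:
            state = states[0]
            if state != ancestor[pos]:
                anc_codon = ancestor[c0 : c0 + 3]
                derived = anc_codon[: pos - c0] + state + anc_codon[pos - c0 + 1 :]
                calls.append(
                    SiteCall(
                        codon=c0 // 3,
                        offset=pos - c0,
                        kind="divergent",
                        effect=_codon_effect(anc_codon, derived),
                    )
                )
    return calls


def _majority_state(column: Sequence[str]) -> str:
    # Ties resolve to the lexicographically smaller state, matching the
    # major/minor split used for polymorphic calls.
    counts: dict[str, int] = {}
    for s in column:
        counts[s] = counts.get(s, 0) + 1
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def filter_low_frequency(
    calls: Iterable[SiteCall], cutoff: float = 0.12
) -> list[SiteCall]:
    """Drop polymorphic calls below the frequency cutoff.

    The boundary is exclusive below: a site at exactly the cutoff is kept
    ("less than 12%" excluded).  Divergent calls pass through untouched.
    """
    if not 0.0 <= cutoff <= 0.5:
        raise ValueError("cutoff must lie in [0, 0.5]")
    return [
        c
        for c in calls
        if c.kind != "polymorphic" or c.variant_freq >= cutoff
    ]


def build_table(calls: Iterable[SiteCall]) -> MKTable:
    ps = pn = ds = dn = 0
    for c in calls:
        if c.kind == "polymorphic":
            if c.effect == "synonymous":
                ps += 1
            else:
                pn += 1
        else:
            if c.effect == "synonymous":
                ds += 1
            else:
                dn += 1
    return MKTable(Ps=ps, Ds=ds, Pn=pn, Dn=dn)


def mk_test(table: MKTable) -> MKResult:
    """Contingency statistics for an MK table.

    chi2 is the uncorrected Pearson statistic (closed form on the 2x2
    table) with a 1-df tail probability; fisher_p is the two-sided exact
    p-value.  alpha and NI are ``None`` when their denominators vanish.
    """
    a, b, c, d = table.Ps, table.Ds, table.Pn, table.Dn
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        chi2 = float("nan")
        chi2_p = float("nan")
    else:
        chi2 = n * (a * d - b * c) ** 2 / (
            margins[0] * margins[1] * margins[2] * margins[3]
        )
        chi2_p = float(stats.chi2.sf(chi2, df=1))
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    alpha = 1.0 - (table.Ds * table.Pn) / (table.Dn * table.Ps) if (
        table.Dn > 0 and table.Ps > 0
    ) else None
    ni = (
        (table.Pn / table.Ps) / (table.Dn / table.Ds)
        if (table.Ps > 0 and table.Ds > 0 and table.Dn > 0)
        else None
    )
    return MKResult(table, float(chi2), chi2_p, fisher_p, alpha, ni)


def parsimony_ancestor(focal: str, sister: str, outgroup: str) -> str:
    """Majority-rule parsimony ancestor of three aligned sequences.

    Per site the ancestral state is the majority among (focal, sister,
    outgroup); a three-way tie resolves to the outgroup state.
    """
    if not len(focal) == len(sister) == len(outgroup):
        raise ValueError("sequences must be aligned to equal length")
    out = []
    for f, s, o in zip(focal, sister, outgroup):
        if f == s or f == o:
            out.append(f)
        elif s == o:
            out.append(s)
        else:
            out.append(o)
    return "".join(out)
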