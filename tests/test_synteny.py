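import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from conftest import random_protein

from gscortho.rbbh import OrthologMap
from gscortho.synteny import (
    BlockLocation,
    evaluate_gene,
    final_verdict,
    flanking_anchors,
    locate_block,
    scan_span,
)
from gscortho.synthetic_data import CladeSimParams, simulate_clade, translate_cds


def annot(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])


def seven_gene_contig():
    return annot(
        [(f"g{i}", "chr1", 1000 + 2000 * i, 1300 + 2000 * i, "+") for i in range(7)]
    )


class TestFlankingAnchors:
    def test_interior_gene_gets_three_per_side(self):
        ctx = flanking_anchors("g3", seven_gene_contig())
        assert ctx.upstream == ("g2", "g1", "g0")
        assert ctx.downstream == ("g4", "g5", "g6")
        assert not ctx.ref_bounded_up and not ctx.ref_bounded_down

    def test_near_edge_gene_truncated_without_error(self):
        ctx = flanking_anchors("g1", seven_gene_contig())
        assert ctx.upstream == ("g0",)
        assert ctx.downstream == ("g2", "g3", "g4")
        assert ctx.ref_bounded_up

    def test_solo_gene_has_empty_anchor_lists(self):
        ctx = flanking_anchors("g0", annot([("g0", "c", 10, 50, "+")]))
        assert ctx.upstream == () and ctx.downstream == ()

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            flanking_anchors("nope", seven_gene_contig())


def identity_map(genes):
    return OrthologMap(pairs={g: g for g in genes})


class TestLocateBlock:
    def setup_method(self):
        self.ctx = flanking_anchors("g3", seven_gene_contig())

    def test_intact_block_in_reference_order(self):
        target = seven_gene_contig().replace("chr1", "tctg")
        target = target[target["gene_id"] != "g3"]
        block = locate_block(
            self.ctx, target, identity_map("g0 g1 g2 g4 g5 g6".split()),
            {"tctg": 20000},
        )
        assert block.contig == "tctg"
        assert block.span == (1300 + 2000 * 2, 1000 + 2000 * 4)
        assert block.order_consistent
        assert block.flags == frozenset()

    def test_inverted_block_is_still_order_consistent(self):
        L = 20000
        rows = [
            (f"g{i}", "tctg", L - (1300 + 2000 * i), L - (1000 + 2000 * i), "-")
            for i in [0, 1, 2, 4, 5, 6]
        ]
        block = locate_block(
            self.ctx, annot(rows), identity_map("g0 g1 g2 g4 g5 g6".split()),
            {"tctg": L},
        )
        assert block.order_consistent
        assert block.span is not None

    def test_shuffled_anchor_order_flagged_inconsistent(self):
        rows = seven_gene_contig().replace("chr1", "tctg")
        rows = rows[rows["gene_id"] != "g3"].copy()
        # Swap the genomic locations of g1 and g5.
        i1 = rows.index[rows["gene_id"] == "g1"][0]
        i5 = rows.index[rows["gene_id"] == "g5"][0]
        for col in ("start", "end"):
            rows.loc[i1, col], rows.loc[i5, col] = rows.loc[i5, col], rows.loc[i1, col]
        block = locate_block(
            self.ctx, rows, identity_map("g0 g1 g2 g4 g5 g6".split()), {"tctg": 20000}
        )
        assert not block.order_consistent

    def test_split_neighborhood_near_contig_end_flags(self):
        # Upstream anchors on contig A which ends 200 bp past the innermost
        # one; downstream anchors on contig B: the focal locus may sit in
        # the assembly gap.
        rows = [
            ("g0", "ctgA", 1000, 1300, "+"),
            ("g1", "ctgA", 3000, 3300, "+"),
            ("g2", "ctgA", 5000, 5300, "+"),
            ("g4", "ctgB", 1000, 1300, "+"),
            ("g5", "ctgB", 3000, 3300, "+"),
            ("g6", "ctgB", 5000, 5300, "+"),
        ]
        block = locate_block(
            self.ctx, annot(rows), identity_map("g0 g1 g2 g4 g5 g6".split()),
            {"ctgA": 5500, "ctgB": 20000},
        )
        assert block.span is None
        assert "anchors_split_across_contigs" in block.flags
        assert "near_contig_end" in block.flags

    def test_one_sided_mapping_flagged(self):
        rows = [
            ("g0", "tctg", 1000, 1300, "+"),
            ("g1", "tctg", 3000, 3300, "+"),
            ("g2", "tctg", 5000, 5300, "+"),
        ]
        block = locate_block(
            self.ctx, annot(rows), identity_map("g0 g1 g2".split()), {"tctg": 50000}
        )
        assert block.span is None
        assert "one_sided" in block.flags

    def test_no_mapped_anchor_yields_empty_location(self):
        block = locate_block(
            self.ctx, annot([]), OrthologMap(), {}
        )
        assert block.contig is None and block.span is None

    def test_reference_edge_bracketed_by_contig_boundary(self):
        ctx = flanking_anchors("g0", seven_gene_contig())
        assert ctx.upstream == ()
        rows = [(f"g{i}", "tctg", 1000 + 2000 * i, 1300 + 2000 * i, "+") for i in (1, 2, 3)]
        block = locate_block(ctx, annot(rows), identity_map(["g1", "g2", "g3"]), {"tctg": 20000})
        assert block.span == (0, 3000)  # contig start stands in for anchors


class TestScanSpan:
    def _gene(self, seed=0, n=100):
        clade = simulate_clade(
            CladeSimParams(n_genes=1, n_species=2, loss_prob=0.0, subst_rate=0.1,
                           frag_break_rate=0.0, gene_len_codons=n, seed=seed)
        )
        ref_prot = clade.reference.proteome["g0000"]
        diverged = clade.assemblies["sp1"].proteome["g0000"]
        asm = clade.assemblies["sp1"]
        row = asm.annotation.iloc[0]
        cds = asm.contigs[row.contig][row.start : row.end]
        if row.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        assert translate_cds(cds) == diverged
        return ref_prot, cds

    def _random_nt(self, rng, n):
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    @pytest.mark.parametrize("frame_shift,revcomp", [(0, False), (1, False), (2, True)])
    def test_planted_gene_found_in_any_frame(self, frame_shift, revcomp):
        rng = np.random.default_rng(3)
        prot, cds = self._gene(seed=4)
        if revcomp:
            cds = str(Seq(cds).reverse_complement())
        span = self._random_nt(rng, 500 + frame_shift) + cds + self._random_nt(rng, 500)
        hit = scan_span(span, prot)
        assert hit is not None
        assert hit.query_pid > 80  # 10% divergence planted

    def test_random_span_never_rescues(self):
        rng = np.random.default_rng(10)
        prot = random_protein(rng, 300)
        for _ in range(25):
            span = self._random_nt(rng, 5000)
            assert scan_span(span, prot) is None

    def test_tiny_span_returns_none(self):
        assert scan_span("", "MKLV" * 25) is None
        assert scan_span("AC", "MKLV" * 25) is None


class TestFinalVerdict:
    def _block(self, span=(0, 100), consistent=True, flags=frozenset()):
        return BlockLocation("c", span, consistent, frozenset(flags))

    def test_tier2_present_passes_through(self):
        v = final_verdict("g", "sp", "present", None, None)
        assert v.status == "present"

    def test_span_hit_rescues(self):
        from gscortho.homology import AlignmentHit

        hit = AlignmentHit("g", "frame+1", 100.0, 50, 50.0, 50.0, (0, 50), (0, 50))
        v = final_verdict("g", "sp", "absent", self._block(), hit)
        assert v.status == "present_rescued"

    def test_clean_empty_span_confirms_absence(self):
        v = final_verdict("g", "sp", "absent", self._block(), None)
        assert v.status == "absent_confirmed"

    @pytest.mark.parametrize(
        "block",
        [
            None,
            BlockLocation("c", None, True, frozenset({"one_sided"})),
            BlockLocation("c", (0, 10), False, frozenset()),
            BlockLocation("c", None, True, frozenset({"near_contig_end"})),
        ],
    )
    def test_degenerate_blocks_stay_unresolved(self, block):
        assert final_verdict("g", "sp", "absent", block, None).status == "unresolved"


class TestEvaluateGene:
    def test_planted_loss_with_intact_neighborhood_confirmed(self):
        clade = simulate_clade(
            CladeSimParams(n_genes=9, n_species=2, loss_prob=0.0,
                           frag_break_rate=0.0, subst_rate=0.1, seed=5)
        )
        ref = clade.reference
        tgt = clade.assemblies["sp1"]
        focal = "g0004"
        # Delete the focal gene from the target: drop its protein and
        # annotation but keep its DNA out of the picture by mapping anchors
        # only; the span scan will still see the gene sequence, so also
        # blank it out of the contig.
        row = tgt.annotation[tgt.annotation["gene_id"] == focal].iloc[0]
        ctg = tgt.contigs[row.contig]
        tgt.contigs[row.contig] = (
            ctg[: row.start] + "A" * (row.end - row.start) + ctg[row.end :]
        )
        tgt.annotation = tgt.annotation[tgt.annotation["gene_id"] != focal]
        del tgt.proteome[focal]
        omap = OrthologMap(pairs={g: g for g in tgt.proteome})
        verdict = evaluate_gene(
            focal, "sp1", "absent", ref.annotation, tgt.annotation, omap,
            tgt.contigs, ref.proteome[focal],
        )
        assert verdict.status == "absent_confirmed"

    def test_gene_still_present_in_span_is_rescued(self):
        clade = simulate_clade(
            CladeSimParams(n_genes=9, n_species=2, loss_prob=0.0,
                           frag_break_rate=0.0, subst_rate=0.1, seed=6)
        )
        ref = clade.reference
        tgt = clade.assemblies["sp1"]
        focal = "g0004"
        # The gene model was missed (absent at tier 2) but the sequence is
        # still in the assembly: the six-frame scan must find it.
        tgt.annotation = tgt.annotation[tgt.annotation["gene_id"] != focal]
        del tgt.proteome[focal]
        omap = OrthologMap(pairs={g: g for g in tgt.proteome})
        verdict = evaluate_gene(
            focal, "sp1", "absent", ref.annotation, tgt.annotation, omap,
            tgt.contigs, ref.proteome[focal],
        )
        assert verdict.status == "present_rescued"
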