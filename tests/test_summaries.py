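import filecmp

import numpy as np
import pandas as pd
import pytest

from gscortho.rbbh import TierStatus
from gscortho.summaries import (
    GeneMetadata,
    category_breakdown,
    collapse_verdicts,
    network_coabsence,
    parse_config,
    per_species_percent,
    run_pipeline,
    write_report,
)
from gscortho.synteny import FinalVerdict
from gscortho.synthetic_data import CladeSimParams, simulate_clade


def matrix_from(cells):
    """cells: dict gene -> dict species -> 'present'/'absent'."""
    return pd.DataFrame(cells).T.sort_index()


def planted_matrix(n_genes, absences, species=None):
    """All-present matrix with the given (gene_index, species) absences."""
    species = species or sorted({sp for _, sp in absences}) or ["spX"]
    data = {
        f"g{i:04d}": {sp: "present" for sp in species} for i in range(n_genes)
    }
    for i, sp in absences:
        data[f"g{i:04d}"][sp] = "absent"
    return matrix_from(data)


class TestCollapse:
    def _verdicts(self):
        return [
            FinalVerdict("a", "sp1", "present"),
            FinalVerdict("b", "sp1", "present_rescued"),
            FinalVerdict("c", "sp1", "absent_confirmed"),
            FinalVerdict("d", "sp1", "unresolved"),
        ]

    def test_default_collapse_counts_only_confirmed_absences(self):
        m = collapse_verdicts(self._verdicts())
        assert m.loc["b", "sp1"] == "present"
        assert m.loc["c", "sp1"] == "absent"
        assert m.loc["d", "sp1"] == "present"

    def test_strict_mode_keeps_unresolved_visible(self):
        m = collapse_verdicts(self._verdicts(), strict=True)
        assert m.loc["d", "sp1"] == "unresolved"

    def test_tier_statuses_accepted_directly(self):
        m = collapse_verdicts([TierStatus("a", "sp1", 2, "absent")])
        assert m.loc["a", "sp1"] == "absent"


class TestPerSpeciesPercent:
    @pytest.mark.parametrize(
        "count,denominator,decimals,expected",
        [
            (27, 366, 2, 7.38),
            (222, 366, 2, 60.66),
            (1, 366, 2, 0.27),
            (13, 366, 1, 3.6),
            (0, 366, 2, 0.0),
        ],
    )
    def test_reported_percentages(self, count, denominator, decimals, expected):
        matrix = planted_matrix(250 if count <= 250 else count, [(i, "spX") for i in range(count)])
        table = per_species_percent(matrix, denominator, decimals)
        assert table.loc[0, "n_absent"] == count
        assert table.loc[0, "percent"] == pytest.approx(expected)

    def test_rounding_is_half_away_from_zero(self):
        # 1/800 = 0.125%: half-away gives 0.13, banker's would give 0.12.
        matrix = planted_matrix(1, [(0, "spX")])
        assert per_species_percent(matrix, 800, 2).loc[0, "percent"] == 0.13

    def test_counts_sum_to_total_absent_cells(self):
        rng = np.random.default_rng(0)
        absences = {(int(i), f"sp{j}") for i, j in zip(rng.integers(0, 30, 25), rng.integers(1, 4, 25))}
        matrix = planted_matrix(30, absences)
        table = per_species_percent(matrix, 30)
        assert table["n_absent"].sum() == (matrix == "absent").to_numpy().sum()

    def test_bad_denominators_rejected(self):
        matrix = planted_matrix(5, [(0, "spX")])
        with pytest.raises(ValueError):
            per_species_percent(matrix, 0)
        with pytest.raises(ValueError):
            per_species_percent(planted_matrix(5, [(i, "spX") for i in range(5)]), 3)


class TestCategoryBreakdown:
    def _meta(self, cats):
        return [
            GeneMetadata(g, functional_category=c, defect_type=d)
            for g, c, d in cats
        ]

    def test_functional_category_percentages(self):
        # Kinetochore-and-spindle-like: 2 of 6 genes absent somewhere (33%);
        # proteasome-like: 0 of 15 (0%).
        absences = [(0, "sp1"), (1, "sp2")]
        matrix = planted_matrix(21, absences)
        meta = self._meta(
            [(f"g{i:04d}", "kinetochore", None) for i in range(6)]
            + [(f"g{i:04d}", "proteasome", None) for i in range(6, 21)]
        )
        table = category_breakdown(matrix, meta).set_index("category")
        assert table.loc["kinetochore", "percent"] == 33
        assert table.loc["kinetochore", "n_with_any_absence"] == 2
        assert table.loc["proteasome", "percent"] == 0

    def test_defect_type_percentages_at_two_decimals(self):
        absences = [(i, "sp1") for i in range(12)]
        matrix = planted_matrix(168, absences)
        meta = self._meta(
            [(f"g{i:04d}", None, "GSC loss (cell viability)") for i in range(168)]
        )
        table = category_breakdown(matrix, meta, "defect_type", decimals=2)
        assert table.set_index("category").loc["GSC loss (cell viability)", "percent"] == 7.14

    def test_uncategorized_genes_pooled(self):
        matrix = planted_matrix(4, [(0, "sp1")])
        meta = self._meta([("g0000", "x", None)])  # other 3 genes unknown
        table = category_breakdown(matrix, meta).set_index("category")
        assert table.loc["No functional category", "n_genes"] == 3

    def test_percentages_invariant_to_gene_order(self):
        absences = [(0, "sp1"), (5, "sp2")]
        matrix = planted_matrix(10, absences)
        meta = self._meta([(f"g{i:04d}", "c1" if i < 6 else "c2", None) for i in range(10)])
        t1 = category_breakdown(matrix, meta)
        t2 = category_breakdown(matrix.iloc[::-1], meta)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            category_breakdown(planted_matrix(2, [(0, "sp1")]), [], "nope")


class TestNetworkCoabsence:
    def test_empty_network_reports_zeros(self):
        matrix = planted_matrix(3, [(0, "sp1")])
        meta = [GeneMetadata("g0000", interactors=())]
        table = network_coabsence(matrix, meta).set_index("gene_id")
        assert tuple(table.loc["g0000"]) == (0, 0, 0)

    def test_same_species_coabsence_counted(self):
        # Focal g0 and interactor g1 both absent only in sp3.
        matrix = planted_matrix(3, [(0, "sp3"), (1, "sp3")])
        meta = [GeneMetadata("g0000", interactors=("g0001",))]
        table = network_coabsence(matrix, meta).set_index("gene_id")
        assert table.loc["g0000", "n_network_absent"] == 1
        assert table.loc["g0000", "n_same_species_coabsent"] == 1

    def test_other_species_absence_not_coabsent(self):
        matrix = planted_matrix(3, [(0, "sp1"), (1, "sp2")])
        meta = [GeneMetadata("g0000", interactors=("g0001",))]
        table = network_coabsence(matrix, meta).set_index("gene_id")
        assert table.loc["g0000", "n_network_absent"] == 1
        assert table.loc["g0000", "n_same_species_coabsent"] == 0

    def test_missing_interactors_skipped(self, caplog):
        matrix = planted_matrix(2, [(0, "sp1")])
        meta = [GeneMetadata("g0000", interactors=("ghost",))]
        table = network_coabsence(matrix, meta).set_index("gene_id")
        assert table.loc["g0000", "network_size"] == 1
        assert table.loc["g0000", "n_network_absent"] == 0


class TestPipeline:
    def test_lossless_clade_has_zero_absences_at_every_tier(self):
        clade = simulate_clade(
            CladeSimParams(n_genes=10, n_species=3, loss_prob=0.0,
                           subst_rate=0.05, frag_break_rate=0.0, seed=31)
        )
        result = run_pipeline(clade)
        assert (result.tier1["status"] == "present").all()
        assert (result.tier2["status"] == "present").all()
        assert (result.tier3["status"] == "present").all()
        assert (result.matrix == "present").all().all()

    def test_report_bundle_is_reproducible(self, tmp_path):
        params = CladeSimParams(n_genes=10, n_species=2, loss_prob=0.2,
                                subst_rate=0.1, frag_break_rate=0.0, seed=32)
        r1 = run_pipeline(simulate_clade(params))
        r2 = run_pipeline(simulate_clade(params))
        d1 = write_report(r1, tmp_path / "a")
        d2 = write_report(r2, tmp_path / "b")
        for name in sorted(p.name for p in d1.iterdir()):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_tier_funnel_recorded_in_manifest(self):
        clade = simulate_clade(
            CladeSimParams(n_genes=20, n_species=3, loss_prob=0.2,
                           subst_rate=0.1, frag_break_rate=0.0, seed=33)
        )
        result = run_pipeline(clade)
        assert result.manifest["n_tier3_absent"] <= result.manifest["n_tier2_absent"]


class TestConfig:
    def test_parse_key_values_with_comments(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("a = 1\n# note\nb=two  # trailing\n\n")
        assert parse_config(path) == {"a": "1", "b": "two"}

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "cfg"
        path.write_text("a = 1\nbroken\n")
        with pytest.raises(ValueError, match=":2"):
            parse_config(path)
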