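"""Expression / copy-number integration and lineage clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from methylpharm.core_stats import CorrelationResult, spearman
from methylpharm.data_io import DataValidationError
from methylpharm.integration import (
    LINEAGE_MARKERS,
    classify_regulatory_pattern,
    copy_number_screen,
    expression_response_correlations,
    lineage_clustering,
    marker_correlations,
    marker_expression,
    methylation_expression_correlations,
)

from _oracles import (
    SINGLE_LINKAGE_4POINT_HEIGHTS,
    UPGMA_4POINT_COORDS,
    UPGMA_4POINT_HEIGHTS,
)


def _cr(coefficient, p_value, method="spearman", n=66):
    return CorrelationResult(coefficient, p_value, n, method)


class TestRegulatoryPattern:
    def test_canonical_repression(self):
        # methylation silences the gene; expression drives resistance
        tag = classify_regulatory_pattern(
            _cr(-0.65, 1e-8), _cr(-0.84, 1e-10), _cr(0.5, 2e-5, "pearson"))
        assert tag == "canonical_repression"

    def test_expression_coupled_positive(self):
        tag = classify_regulatory_pattern(
            _cr(0.63, 1e-8), _cr(0.68, 1e-9), _cr(0.40, 8e-4, "pearson"))
        assert tag == "expression_coupled_positive"

    def test_undetermined_when_weak(self):
        tag = classify_regulatory_pattern(
            _cr(0.05, 0.7), _cr(-0.08, 0.5), _cr(0.02, 0.9, "pearson"))
        assert tag == "undetermined"

    def test_undetermined_below_min_abs(self):
        tag = classify_regulatory_pattern(
            _cr(-0.65, 1e-8), _cr(-0.25, 0.04), _cr(0.5, 2e-5, "pearson"))
        assert tag == "undetermined"

    def test_inconsistent_when_signs_clash(self):
        tag = classify_regulatory_pattern(
            _cr(-0.65, 1e-8), _cr(-0.84, 1e-10), _cr(-0.5, 2e-5, "pearson"))
        assert tag == "inconsistent"

    def test_invariant_to_resistance_sensitivity_relabel(self):
        """Flipping the sign of both drug legs (relabeling resistance as
        sensitivity) cannot change the classification."""
        a = classify_regulatory_pattern(
            _cr(-0.65, 1e-8), _cr(-0.84, 1e-10), _cr(0.5, 2e-5, "pearson"))
        b = classify_regulatory_pattern(
            _cr(0.65, 1e-8), _cr(-0.84, 1e-10), _cr(-0.5, 2e-5, "pearson"))
        assert a == b == "canonical_repression"


class TestLineageClustering:
    def _expr(self, coords):
        # six identical marker rows -> Euclidean distance is sqrt(6)*|x-y|;
        # scale down so heights match the 1-D hand computation
        rows = {m: np.asarray(coords) / np.sqrt(6) for m in LINEAGE_MARKERS}
        return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(coords))]).T

    def test_upgma_heights_match_hand_computation(self):
        res = lineage_clustering(self._expr(UPGMA_4POINT_COORDS))
        np.testing.assert_allclose(res.linkage[:, 2], UPGMA_4POINT_HEIGHTS,
                                   rtol=1e-12)
        assert np.all(np.diff(res.linkage[:, 2]) >= 0)

    def test_average_differs_from_single_linkage_on_chain(self):
        expr = self._expr(UPGMA_4POINT_COORDS)
        single = hierarchy.linkage(expr.T.to_numpy(), method="single")
        np.testing.assert_allclose(single[:, 2], SINGLE_LINKAGE_4POINT_HEIGHTS,
                                   rtol=1e-12)
        assert not np.allclose(UPGMA_4POINT_HEIGHTS, SINGLE_LINKAGE_4POINT_HEIGHTS)

    def test_duplicate_samples_merge_first_at_zero(self):
        res = lineage_clustering(self._expr([1.0, 1.0, 5.0, 9.0]))
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2]) == {0.0, 1.0}

    def test_two_archetypes_recovered(self, small_dataset):
        b = small_dataset.bundle
        res = lineage_clustering(b.expression, b.transcript_gene_map)
        cut = res.cut(2)
        truth = pd.Series(small_dataset.truth.lineage_labels)
        table = pd.crosstab(cut, truth[cut.index])
        # perfect separation up to label permutation
        assert (table.to_numpy() > 0).sum() == 2

    def test_missing_markers_listed(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["ASCL1"], columns=["s1", "s2"])
        with pytest.raises(DataValidationError, match="NEUROD1"):
            lineage_clustering(expr)

    def test_fewer_than_two_samples_rejected(self):
        expr = pd.DataFrame({m: [1.0] for m in LINEAGE_MARKERS},
                            index=["s1"]).T
        with pytest.raises(DataValidationError):
            lineage_clustering(expr)

    def test_clustering_invariant_under_sample_relabeling(self, small_dataset):
        b = small_dataset.bundle
        base = lineage_clustering(b.expression, b.transcript_gene_map).cut(2)
        perm = list(reversed(b.expression.columns))
        other = lineage_clustering(b.expression[perm], b.transcript_gene_map).cut(2)
        table = pd.crosstab(base, other[base.index])
        assert (table.to_numpy() > 0).sum() == 2

    def test_newick_contains_all_samples(self, small_dataset):
        b = small_dataset.bundle
        res = lineage_clustering(b.expression, b.transcript_gene_map)
        nwk = res.newick()
        assert nwk.endswith(";")
        for sample in res.sample_ids:
            assert sample in nwk


class TestMarkerCorrelations:
    def test_marker_against_itself(self, small_dataset):
        b = small_dataset.bundle
        markers = marker_expression(b.expression, b.transcript_gene_map)
        table = marker_correlations(markers.loc["ASCL1"], markers)
        row = table.set_index("marker").loc["ASCL1"]
        assert row["spearman_rho"] == pytest.approx(1.0)
        assert row["pearson_r"] == pytest.approx(1.0)

    def test_lineage_linked_methylation_tracks_marker(self, small_dataset,
                                                      small_pipeline):
        """Planted lineage methylation offsets show up as a strong
        correlation with the corresponding marker's expression."""
        b = small_dataset.bundle
        regions = small_pipeline["regions"]
        markers = marker_expression(b.expression, b.transcript_gene_map)
        rid = "ASCL1|TSS200"
        assert rid in regions.index
        table = marker_correlations(regions.loc[rid], markers)
        row = table.set_index("marker").loc["ASCL1"]
        # promoter methylation high where the marker is silenced
        assert row["spearman_rho"] < -0.5
        assert row["spearman_p"] < 1e-4


class TestExpressionIntegration:
    def test_transcript_equal_to_response(self, small_dataset, small_pipeline):
        response = small_pipeline["response"]
        agent = response.index[0]
        expr = pd.DataFrame([response.loc[agent]], index=["TXMIRROR"])
        table = expression_response_correlations(expr, response.loc[[agent]])
        assert table.iloc[0]["coefficient"] == pytest.approx(1.0)

    def test_planted_expression_response_coupling(self, small_dataset,
                                                  small_pipeline):
        truth = small_dataset.truth
        b = small_dataset.bundle
        response = small_pipeline["response"]
        gene = next(g for g, a in truth.archetypes.items()
                    if a == "canonical_repressive")
        tx = truth.planted_transcript[gene]
        agent = truth.target_agent[gene]
        table = expression_response_correlations(
            b.expression.loc[[tx]], response.loc[[agent]])
        assert abs(table.iloc[0]["coefficient"]) > 0.5

    def test_planted_repressive_meth_expr_negative(self, small_dataset,
                                                   small_pipeline):
        truth = small_dataset.truth
        b = small_dataset.bundle
        regions = small_pipeline["regions"]
        gene = next(g for g, a in truth.archetypes.items()
                    if a == "canonical_repressive")
        rid = f"{gene}|TSS200"
        table = methylation_expression_correlations(
            regions.loc[[rid]], pd.Series({rid: gene}),
            b.expression, b.transcript_gene_map)
        planted = table.loc[table["transcript"]
                            == truth.planted_transcript[gene]].iloc[0]
        assert planted["coefficient"] < -0.5
        assert planted["p_value"] < 1e-5

    def test_unrelated_transcript_uncorrelated(self, small_dataset,
                                               small_pipeline):
        truth = small_dataset.truth
        b = small_dataset.bundle
        regions = small_pipeline["regions"]
        null_genes = [g for g, a in truth.archetypes.items() if a == "null"]
        rhos = []
        for gene in null_genes:
            rid = f"{gene}|TSS200"
            if rid not in regions.index:
                continue
            table = methylation_expression_correlations(
                regions.loc[[rid]], pd.Series({rid: gene}),
                b.expression, b.transcript_gene_map)
            rhos.extend(table["coefficient"].tolist())
        assert len(rhos) >= 5
        assert np.median(np.abs(rhos)) < 0.3


class TestCopyNumberScreen:
    def test_cn_identical_to_expression(self):
        samples = [f"s{i}" for i in range(10)]
        vals = np.linspace(0, 1, 10)
        cn = pd.DataFrame([vals], index=["G1"], columns=samples)
        expr = pd.DataFrame([vals], index=["TX1"], columns=samples)
        meth = pd.DataFrame([vals[::-1]], index=["f1"], columns=samples)
        resp = pd.DataFrame([np.zeros(10) + np.arange(10) % 2],
                            index=["A1"], columns=samples)
        targets = pd.DataFrame([{"gene": "G1", "feature_id": "f1",
                                 "transcript": "TX1", "agent": "A1"}])
        table = copy_number_screen(cn, meth, expr, resp, targets)
        assert table.iloc[0]["cn_expr_rho"] == pytest.approx(1.0)
        assert not table.iloc[0]["cn_unexplained"]

    def test_planted_cn_driven_gene_recovered(self, small_dataset,
                                              small_pipeline):
        b = small_dataset.bundle
        truth = small_dataset.truth
        regions = small_pipeline["regions"]
        response = small_pipeline["response"]
        gene = truth.cn_genes[0]
        targets = pd.DataFrame([{
            "gene": gene, "feature_id": f"{gene}|Body",
            "transcript": truth.planted_transcript[gene],
            "agent": truth.target_agent[gene]}])
        table = copy_number_screen(b.copy_number, regions, b.expression,
                                   response, targets)
        assert table.iloc[0]["cn_meth_rho"] > 0.2
        assert table.iloc[0]["cn_expr_rho"] > 0.2
        assert not table.iloc[0]["cn_unexplained"]

    def test_cn_independent_gene_flagged_unexplained(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(33)]
        cn = pd.DataFrame([rng.normal(size=33)], index=["G1"], columns=samples)
        expr = pd.DataFrame([rng.normal(size=33)], index=["TX1"], columns=samples)
        meth = pd.DataFrame([rng.normal(size=33)], index=["f1"], columns=samples)
        resp = pd.DataFrame([rng.normal(size=33)], index=["A1"], columns=samples)
        targets = pd.DataFrame([{"gene": "G1", "feature_id": "f1",
                                 "transcript": "TX1", "agent": "A1"}])
        table = copy_number_screen(cn, meth, expr, resp, targets)
        assert table.iloc[0]["cn_unexplained"]

    def test_absent_gene_skipped(self):
        samples = ["s1", "s2", "s3"]
        cn = pd.DataFrame([[0.0, 0.1, 0.2]], index=["OTHER"], columns=samples)
        targets = pd.DataFrame([{"gene": "G1", "feature_id": "f1",
                                 "transcript": "TX1", "agent": "A1"}])
        table = copy_number_screen(cn, None, None, None, targets)
        assert len(table) == 0
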