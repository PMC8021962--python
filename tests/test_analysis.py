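"""Pearson machinery, correlation binning, plate ratios and modality check."""

import math

import numpy as np
import pandas as pd
import pytest

from cadhesion import (
    ExpressionRecord,
    SyntheticSpec,
    alar_basal_ratio,
    classify_correlation,
    cortex_subpallium_correlation,
    fisher_z_interval,
    gene_pair_correlation_by_age,
    generate_expression_table,
    generate_ish_cortex_matrix,
    generate_scrnaseq_clusters,
    heatmap_export,
    ish_scrnaseq_comparison,
    pearson,
)
from cadhesion.analysis import CorrelationMatrix
from cadhesion.errors import (
    ConstantVectorError,
    EmptyMatrixError,
    InsufficientDataError,
)


class TestPearson:
    def test_identical_vectors_correlate_perfectly(self):
        r, p, n = pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_negated_vector_gives_minus_one(self):
        r, _, _ = pearson([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 3/2, sd_x = 1, sd_y = sqrt(7/3) -> r = 1.5/sqrt(7/3)
        r, _, _ = pearson([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            xm, ym = x - x.mean(), y - y.mean()
            oracle = (xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym))
            assert pearson(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_p_value_is_t_transform_with_n_minus_2_dof(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r, p, n = pearson(x, y)
        t = r * math.sqrt((n - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-9)

    def test_pairwise_complete_drops_nan_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, np.nan, 3.0, 4.0, 5.0]
        assert pearson(x, y).n == 3

    def test_constant_vector_raises_not_zero(self):
        with pytest.raises(ConstantVectorError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_fewer_than_three_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson([1, 2], [3, 4])


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.86, "intermediate"),
            (0.95, "high"),
            (-0.2, "low"),
            (0.70, "intermediate"),  # half-open bins close the verbal gaps
            (0.90, "high"),
            (0.6999, "low"),
            (-1.0, "low"),
            (1.0, "high"),
        ],
    )
    def test_binning(self, r, expected):
        assert classify_correlation(r) == expected

    def test_monotone_and_total_over_range(self):
        order = {"low": 0, "intermediate": 1, "high": 2}
        labels = [order[classify_correlation(r)] for r in np.linspace(-1, 1, 401)]
        assert labels == sorted(labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_correlation(1.5)


class TestGenePairCorrelation:
    def test_exact_linear_dependence_gives_unit_r_each_age(self):
        records = []
        for age in ("E13.5", "P56"):
            for i in range(10):
                records.append(ExpressionRecord("Cdh2", f"S{i}", age, float(i + 1)))
                records.append(ExpressionRecord("Cdh13", f"S{i}", age, 2.0 * (i + 1)))
        out = gene_pair_correlation_by_age(records, "Cdh2", "Cdh13")
        assert set(out) == {"E13.5", "P56"}
        for res in out.values():
            assert res.r == pytest.approx(1.0)

    def test_target_correlation_recovered_within_fisher_interval(self):
        # n = 200 structures at target r = 0.86 -> 95% interval ~ [0.82, 0.89]
        spec = SyntheticSpec(
            seed=5,
            n_structures=200,
            ages=("E15.5",),
            target_correlations=(("Cdh2", "Cdh13", 0.86),),
        )
        records = generate_expression_table(spec)
        res = gene_pair_correlation_by_age(records, "Cdh2", "Cdh13")["E15.5"]
        lo, hi = fisher_z_interval(0.86, 200)
        assert lo == pytest.approx(0.82, abs=0.005)
        assert hi == pytest.approx(0.89, abs=0.005)
        assert lo <= res.r <= hi

    def test_missing_gene_omits_age_with_warning(self, caplog):
        records = [
            ExpressionRecord("Cdh2", f"S{i}", "P56", float(i)) for i in range(5)
        ]
        with caplog.at_level("WARNING"):
            out = gene_pair_correlation_by_age(records, "Cdh2", "Cdh13")
        assert out == {}


class TestCortexSubpallium:
    def test_planted_matching_nucleus_is_row_maximum(self, graph):
        rng = np.random.default_rng(3)
        panel = ["Cdh2", "Cdh13", "Cdh6", "Cdh9", "Cdh10", "Cdh7",
                 "Cdh12", "Cdh18", "Cdh20", "Cdh8", "Cdh11", "Cdh24"]
        records = []
        units = [s.id for s in graph.cortical_units()]
        nuclei = [s.id for s in graph.subpallial_nuclei()]
        planted_vec = rng.uniform(1, 20, size=len(panel))
        for structure in units + nuclei:
            if structure == units[0] or structure == nuclei[0]:
                vec = planted_vec  # identical panel vector in one pair
            else:
                vec = rng.uniform(1, 20, size=len(panel))
            for g, e in zip(panel, vec):
                records.append(ExpressionRecord(g, structure, "P56", float(e)))
        corr = cortex_subpallium_correlation(records, graph, panel)
        assert corr.r.shape == (54, len(nuclei))
        assert corr.r.at[units[0], nuclei[0]] == pytest.approx(1.0)
        assert corr.r.loc[units[0]].idxmax() == nuclei[0]

    def test_panel_permutation_invariance(self, graph, p56_records):
        panel = ["Cdh2", "Cdh13", "Cdh6", "Cdh9", "Cdh10", "Cdh7",
                 "Cdh12", "Cdh18", "Cdh20", "Cdh8", "Cdh11", "Cdh24"]
        a = cortex_subpallium_correlation(p56_records, graph, panel)
        b = cortex_subpallium_correlation(p56_records, graph, panel[::-1])
        pd.testing.assert_frame_equal(a.r, b.r)

    def test_self_paired_vectors_give_unit_correlation_diagonal(self, graph, p56_records):
        corr = cortex_subpallium_correlation(p56_records, graph)
        long = corr.to_long()
        assert set(long.columns) == {"row", "col", "r", "p", "n", "bin"}
        assert long["r"].between(-1, 1).all()

    def test_unit_with_excess_missing_panel_is_excluded(self, graph, caplog):
        panel = ["Cdh2", "Cdh13", "Cdh6", "Cdh9"]
        records = []
        units = [s.id for s in graph.cortical_units()]
        nuclei = [s.id for s in graph.subpallial_nuclei()]
        for structure in units + nuclei:
            genes = panel if structure != units[0] else panel[:1]  # 75% missing
            for i, g in enumerate(genes):
                records.append(
                    ExpressionRecord(g, structure, "P56", float(i + 1) * 1.7)
                )
        # remaining vectors vary across genes: add jitter per structure
        records = [
            ExpressionRecord(r.gene, r.structure_id, r.age,
                             r.energy * (1 + 0.1 * (hash(r.structure_id) % 7)))
            for r in records
        ]
        with caplog.at_level("WARNING"):
            corr = cortex_subpallium_correlation(records, graph, panel)
        assert units[0] not in corr.row_labels


class TestAlarBasalRatio:
    def _records(self, graph, alar_energy, basal_energy, gene="Cdh2", age="P56"):
        records = []
        for s in graph.select(level=5):
            if s.plate == "alar":
                records.append(ExpressionRecord(gene, s.id, age, alar_energy))
            elif s.plate == "basal":
                records.append(ExpressionRecord(gene, s.id, age, basal_energy))
        return records

    def test_equal_plates_sit_on_the_zero_line(self, graph):
        profile = alar_basal_ratio(self._records(graph, 3.0, 3.0), "Cdh2", "P56", graph)
        assert len(profile.values) == 19
        assert (profile.values == 0.0).all()

    def test_fourfold_basal_excess_is_minus_two(self, graph):
        profile = alar_basal_ratio(self._records(graph, 1.0, 4.0), "Cdh2", "P56", graph)
        assert (profile.values == -2.0).all()

    def test_zero_basal_gives_flagged_infinity(self, graph):
        profile = alar_basal_ratio(self._records(graph, 2.0, 0.0), "Cdh2", "P56", graph)
        assert np.isposinf(profile.values).all()
        assert profile.flags.all()

    def test_swapping_plates_negates_finite_values(self, graph):
        fwd = alar_basal_ratio(self._records(graph, 5.0, 2.0), "Cdh2", "P56", graph)
        rev = alar_basal_ratio(self._records(graph, 2.0, 5.0), "Cdh2", "P56", graph)
        assert np.allclose(fwd.values, -rev.values)

    def test_absent_gene_raises(self, graph):
        with pytest.raises(KeyError):
            alar_basal_ratio([], "Cdh2", "P56", graph)

    def test_profile_follows_anterior_posterior_order(self, graph):
        profile = alar_basal_ratio(self._records(graph, 1.0, 2.0), "Cdh2", "P56", graph)
        assert list(profile.values.index)[:3] == ["RSP", "CSP", "p3"]
        assert list(profile.values.index)[-1] == "r11"


class TestIshScrnaseqComparison:
    def test_identical_profiles_give_p_one(self):
        genes = ["Cdh2", "Cdh8", "Cdh11", "Actb"]
        matrix = pd.DataFrame(
            {"U1": [2.0, 4.0, 6.0, 2.0], "U2": [4.0, 8.0, 12.0, 4.0]}, index=genes
        )
        sc = pd.DataFrame(
            [
                {"cluster_id": f"C{i}", "class_label": "neuronal", "gene": g,
                 "mean_expression": v * (i + 1)}
                for i in range(3)
                for g, v in zip(genes, [2.0, 4.0, 6.0, 2.0])
            ]
        )
        result = ish_scrnaseq_comparison(matrix, sc)
        assert result.p_value == pytest.approx(1.0)
        assert np.allclose(result.ish_means, result.sc_means)

    def test_cluster_accounting_after_non_neuronal_removal(self):
        spec = SyntheticSpec(seed=2, ages=("P56",))
        sc = generate_scrnaseq_clusters(spec, n_clusters=377, n_non_neuronal=24)
        gene_means = {g: 5.0 for g in spec.genes}
        ish = generate_ish_cortex_matrix(spec, gene_means)
        result = ish_scrnaseq_comparison(
            ish, sc, non_neuronal_labels=["non-neuronal"]
        )
        assert result.n_clusters_used == 353

    def test_null_rejection_rate_is_near_nominal(self):
        # shared per-gene means on both sides with a noiseless reference
        # (noisy-reference normalisation induces a common shift across
        # genes, correlating the paired differences and inflating the
        # test; reference_sigma=0 yields independent differences)
        alpha, n_reps = 0.05, 100
        rejections = 0
        for rep in range(n_reps):
            spec = SyntheticSpec(seed=1000 + rep, ages=("P56",), noise_sigma=0.4)
            rng_means = np.random.default_rng(rep)
            gene_means = {g: float(5.0 * rng_means.lognormal(0, 0.5))
                          for g in spec.genes}
            sc = generate_scrnaseq_clusters(
                spec, n_clusters=40, n_non_neuronal=4, gene_means=gene_means,
                reference_sigma=0.0,
            )
            ish = generate_ish_cortex_matrix(spec, gene_means, reference_sigma=0.0)
            result = ish_scrnaseq_comparison(
                ish, sc, non_neuronal_labels=["non-neuronal"]
            )
            rejections += result.p_value < alpha
        # binomial(100, 0.05): central 99.9% mass well below 15
        assert rejections <= 15


class TestHeatmapExport:
    def test_small_matrix_renders(self, tmp_path):
        m = pd.DataFrame([[0.1, 0.9], [0.5, -0.2]], index=["a", "b"], columns=["c", "d"])
        out = tmp_path / "hm.svg"
        heatmap_export(m, out)
        assert out.stat().st_size > 0

    def test_rendering_is_byte_deterministic(self, tmp_path):
        m = pd.DataFrame([[0.1, 0.9], [0.5, -0.2]], index=["a", "b"], columns=["c", "d"])
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        heatmap_export(m, p1)
        heatmap_export(m, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_matrix_raises(self, tmp_path):
        with pytest.raises(EmptyMatrixError):
            heatmap_export(pd.DataFrame(), tmp_path / "x.svg")
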