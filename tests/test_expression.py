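"""Z-score computation, significance classification and dataset integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartomics import expression as expr
from heartomics.io import ExpressionProfile
from heartomics.simulate import SimulationConfig, generate_expression

from conftest import make_profile_df, make_ztable


def profile_from_values(values, dataset_id="D1"):
    return ExpressionProfile(dataset_id=dataset_id, data=make_profile_df(values))


class TestComputeZscores:
    def test_hand_computed_single_outlier(self):
        # values [0, 0, 0, 10]: mean 2.5, population SD sqrt(18.75)
        prof = profile_from_values({"G1": {"a": 0, "b": 0, "c": 0, "d": 10}})
        zt = expr.compute_zscores(prof)
        z = zt.data.set_index("cell_type")["z"]
        assert z[["a", "b", "c"]].values == pytest.approx([-0.5774] * 3, abs=1e-4)
        assert z["d"] == pytest.approx(1.7321, abs=1e-4)

    def test_two_cell_types_give_plus_minus_one(self):
        prof = profile_from_values({"G1": {"a": 1.0, "b": 3.0}})
        z = expr.compute_zscores(prof).data.set_index("cell_type")["z"]
        assert sorted(z.values) == pytest.approx([-1.0, 1.0])

    def test_constant_gene_is_undefined(self):
        prof = profile_from_values({"G1": {"a": 5.0, "b": 5.0, "c": 5.0}})
        zt = expr.compute_zscores(prof)
        assert (zt.data["class"] == "undefined").all()
        assert zt.data["z"].isna().all()

    def test_single_cell_type_rejected(self):
        prof = profile_from_values({"G1": {"a": 5.0}})
        with pytest.raises(ValueError, match=">=2 cell types"):
            expr.compute_zscores(prof)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=50, allow_nan=False), min_size=2, max_size=15
        )
    )
    def test_z_vector_standardized(self, values):
        """Every non-constant gene's z has mean 0 and population SD 1."""
        prof = profile_from_values({"G1": {f"ct{i:02d}": v for i, v in enumerate(values)}})
        z = expr.compute_zscores(prof).data["z"].to_numpy()
        if np.isnan(z).all():  # constant gene
            return
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (3.5, "over"),  # p = 4.653e-4 passes the conjunction
            (2.0, "ns"),  # p = 0.0455 fails p <= 0.001 despite z >= 2
            (-3.5, "under"),
            (-2.0, "ns"),
            (0.0, "ns"),
        ],
    )
    def test_conjunction_of_z_and_p_rules(self, z, expected):
        from scipy.stats import norm

        zt = make_ztable("D1", [("G1", "a", z, 2 * norm.sf(abs(z)), "ns", 80.0)])
        out = expr.classify_genes(zt)
        assert out.data["class"].iloc[0] == expected

    def test_threshold_monotonicity(self):
        """Raising z_hi or lowering p_max never adds significant genes."""
        rng = np.random.default_rng(3)
        from scipy.stats import norm

        zs = rng.normal(0, 2.5, 200)
        entries = [
            (f"G{i}", "a", z, 2 * norm.sf(abs(z)), "ns", 80.0) for i, z in enumerate(zs)
        ]
        zt = make_ztable("D1", entries)
        base = expr.classify_genes(zt, z_hi=2, z_lo=-2, p_max=0.05)
        sig_base = set(base.data.loc[base.data["class"] != "ns", "gene"])
        for z_hi, p_max in [(2.5, 0.05), (2, 0.01), (3, 0.001)]:
            tight = expr.classify_genes(zt, z_hi=z_hi, z_lo=-z_hi, p_max=p_max)
            sig = set(tight.data.loc[tight.data["class"] != "ns", "gene"])
            assert sig <= sig_base


class TestIntersectDatasets:
    def _sets(self, *gene_dicts):
        return [
            expr.SignificantGeneSet(dataset_id=f"D{i}", directions=d)
            for i, d in enumerate(gene_dicts)
        ]

    def test_plain_intersection(self):
        sets = self._sets(
            {"A": "over", "B": "over", "C": "over"},
            {"B": "over", "C": "over", "D": "over"},
            {"B": "over", "C": "over"},
        )
        out = expr.intersect_datasets(sets)
        assert out.genes == {"B", "C"}

    def test_identity(self):
        sets = self._sets({"A": "over", "B": "under"}, {"A": "over", "B": "under"})
        assert expr.intersect_datasets(sets).genes == {"A", "B"}

    def test_direction_conflict_excluded_or_mixed(self):
        sets = self._sets({"A": "over", "B": "over"}, {"A": "under", "B": "over"})
        strict = expr.intersect_datasets(sets, require_consistent_direction=True)
        assert strict.genes == {"B"}
        loose = expr.intersect_datasets(sets, require_consistent_direction=False)
        assert loose.directions["A"] == "mixed"

    def test_adding_a_dataset_never_grows_the_intersection(self):
        sets = self._sets({"A": "over", "B": "over"}, {"A": "over", "B": "over", "C": "over"})
        base = expr.intersect_datasets(sets).genes
        more = expr.intersect_datasets(sets + self._sets({"A": "over"})).genes
        assert more <= base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expr.intersect_datasets([])


class TestAssignCellTypes:
    def test_single_significant_cell_type(self):
        zts = [
            make_ztable(f"D{i}", [("G1", "cardiomyocytes", 3.5, 4.7e-4, "over", 80.0),
                                  ("G1", "fibroblasts", 0.1, 0.9, "ns", 80.0)])
            for i in range(3)
        ]
        ranked = expr.assign_cell_types("G1", zts)
        assert ranked[0][0] == "cardiomyocytes"

    def test_ranking_by_mean_abs_z(self):
        zt = make_ztable(
            "D1",
            [("G1", "mast cells", 3.1, 1e-4, "over", 80.0),
             ("G1", "fibroblasts", -2.4, 1e-4, "under", 80.0)],
        )
        # both significant somewhere; mast cells has the larger mean |z|
        ranked = expr.assign_cell_types("G1", [zt])
        assert [ct for ct, _ in ranked] == ["mast cells", "fibroblasts"]
        assert ranked[0][1] == pytest.approx(3.1)

    def test_exact_tie_breaks_lexicographically(self):
        zt = make_ztable(
            "D1",
            [("G1", "b_cells", 3.5, 1e-4, "over", 80.0),
             ("G1", "a_cells", -3.5, 1e-4, "under", 80.0)],
        )
        ranked = expr.assign_cell_types("G1", [zt])
        assert ranked[0][0] == "a_cells"
        assert {ct for ct, _ in ranked} == {"a_cells", "b_cells"}

    def test_absent_gene_rejected(self):
        zt = make_ztable("D1", [("G1", "a", 0.0, 1.0, "ns", 80.0)])
        with pytest.raises(KeyError):
            expr.assign_cell_types("G9", [zt])


class TestSummarizeCellTypes:
    def test_mean_z_and_pct_filter(self):
        zt = make_ztable(
            "D1",
            [
                ("G1", "cm", 3.0, 1e-4, "over", 80.0),
                ("G2", "cm", 4.0, 1e-5, "over", 90.0),
                ("G3", "cm", 5.0, 1e-6, "over", 40.0),  # fails pct > 50
                ("G1", "fb", 0.0, 1.0, "ns", 80.0),
                ("G2", "fb", 0.0, 1.0, "ns", 80.0),
                ("G3", "fb", 0.0, 1.0, "ns", 80.0),
            ],
        )
        integrated = expr.SignificantGeneSet(
            "integrated", {"G1": "over", "G2": "over", "G3": "over"}
        )
        out = expr.summarize_cell_types([zt], integrated, pct_min=50)
        cm = out[out["cell_type"] == "cm"].iloc[0]
        assert cm["mean_z"] == pytest.approx(3.5)  # G3 excluded from the mean
        assert cm["n_significant"] == 3
        fb = out[out["cell_type"] == "fb"].iloc[0]
        assert fb["n_significant"] == 0 and np.isnan(fb["mean_z"])

    def test_planted_markers_dominate_gene_counts(self):
        """Planted markers drive the per-cell-type assignment counts.

        The full 13-cell-type panel is kept: with fewer profiles per gene the
        one-outlier z ceiling sqrt(n_ct - 1) drops below the significance
        threshold and no call is possible at default thresholds.
        """
        cfg = SimulationConfig(
            n_datasets=2,
            n_genes=300,
            n_markers_per_cell_type=6,
        )
        profiles, truth = generate_expression(cfg, seed=5)
        zts = [expr.compute_zscores(p) for p in profiles]
        integrated = expr.intersect_datasets([expr.significant_genes(z) for z in zts])
        out = expr.summarize_cell_types(zts, integrated)
        counts = out.groupby("cell_type")["n_assigned"].first()
        # every cell type has 6 planted markers; each should recover ~6
        assert (counts >= 4).all()
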