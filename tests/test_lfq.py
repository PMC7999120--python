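import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import build_matrix, matrix_as_columns, matrix_as_rows
from pairedlfq.differential import differential_proteins
from pairedlfq.lfq import (
    LfqParams,
    aggregate_to_proteins,
    filter_quantifiable,
    impute_noise_floor,
    normalize_by_sample_median,
    run_lfq,
)


class TestNormalize:
    def test_identical_value_sets_are_left_unchanged(self):
        m = build_matrix({"c1": [10.0, 30.0], "t1": [10.0, 30.0]})
        out = normalize_by_sample_median(m)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_hand_computed_medians_and_scale_factors(self):
        # A = {10, 30} -> m_A = 20; B = {100, 300, 500} -> m_B = 300;
        # T = median{20, 300} = 160; A x8, B x(8/15)
        m = build_matrix({"c1": [10.0, 30.0, None], "t1": [100.0, 300.0, 500.0]})
        out = normalize_by_sample_median(m)
        np.testing.assert_allclose(out.intensities["c1"].dropna(), [80.0, 240.0])
        np.testing.assert_allclose(
            out.intensities["t1"], [160.0 / 3, 160.0, 800.0 / 3]
        )

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        m = build_matrix({s: rng.lognormal(3, 1, 20) for s in ["c1", "t1", "c2", "t2"]})
        once = normalize_by_sample_median(m)
        twice = normalize_by_sample_median(once)
        pd.testing.assert_frame_equal(twice.intensities, once.intensities)

    def test_matches_loop_based_oracle(self, small_simulation):
        _, m, _ = small_simulation
        out = normalize_by_sample_median(m)
        expected = oracles.brute_normalize(matrix_as_columns(m))
        for s in m.sample_ids:
            got = out.intensities[s].tolist()
            for g, e in zip(got, expected[s]):
                assert (e is None and np.isnan(g)) or g == pytest.approx(e, rel=1e-12)

    def test_all_missing_sample_is_an_error(self):
        m = build_matrix({"c1": [10.0, 30.0], "t1": [None, None]})
        with pytest.raises(ValueError, match="t1"):
            normalize_by_sample_median(m)


class TestFilterQuantifiable:
    def make(self, c_obs, t_obs, pclass="unique"):
        cols = {}
        for i in range(4):
            cols[f"c{i+1}"] = [10.0 if i < c_obs else None]
            cols[f"t{i+1}"] = [10.0 if i < t_obs else None]
        return build_matrix(cols, classes=[pclass])

    @pytest.mark.parametrize(
        "c_obs,t_obs,pclass,kept",
        [
            (2, 0, "unique", True),   # two values in one condition suffice
            (1, 1, "unique", False),  # neither condition reaches two
            (4, 4, "razor", True),    # razor class is quantifiable
            (4, 4, "other", False),   # non-unique/razor class is excluded
            (0, 3, "unique", True),
        ],
    )
    def test_quantifiability_rule(self, c_obs, t_obs, pclass, kept):
        m = self.make(c_obs, t_obs, pclass)
        out = filter_quantifiable(m, LfqParams())
        assert (len(out.peptide_ids) == 1) is kept

    def test_matches_loop_based_oracle_and_preserves_order(self, small_simulation):
        _, m, _ = small_simulation
        out = filter_quantifiable(m, LfqParams())
        expected = oracles.brute_filter(matrix_as_rows(m), m.condition_of)
        assert out.peptide_ids == expected


class TestImpute:
    def test_first_centile_of_evenly_spaced_values(self):
        # 101 observed values 1..101: the 1st percentile interpolates to 2
        cols = {"c1": [float(v) for v in range(1, 102)] + [None],
                "t1": [5.0] * 102}
        m = build_matrix(cols)
        out = impute_noise_floor(m, LfqParams())
        assert out.intensities["c1"].iloc[-1] == pytest.approx(2.0)

    def test_constant_sample_imputes_the_constant(self):
        m = build_matrix({"c1": [7.0, 7.0, None], "t1": [1.0, 2.0, 3.0]})
        out = impute_noise_floor(m, LfqParams())
        assert out.intensities["c1"].iloc[2] == 7.0

    def test_only_missing_cells_change_and_match_sort_oracle(self, small_simulation):
        _, m, _ = small_simulation
        m = filter_quantifiable(m, LfqParams())
        out = impute_noise_floor(m, LfqParams())
        mask = m.missing_mask
        # observed cells bit-identical
        assert (
            out.intensities.to_numpy()[~mask.to_numpy()]
            == m.intensities.to_numpy()[~mask.to_numpy()]
        ).all()
        assert not out.intensities.isna().any().any()
        for s in m.sample_ids:
            observed = m.intensities[s].dropna().tolist()
            noise = oracles.brute_percentile(observed, 1.0)
            imputed = out.intensities[s][mask[s]]
            assert np.allclose(imputed, noise)
            # the noise floor sits at or below the mass above the 1st centile
            above = sorted(observed)[int(np.ceil(0.01 * (len(observed) - 1))):]
            assert all(noise <= v for v in above)


class TestAggregate:
    def test_sums_peptides_and_drops_single_peptide_proteins(self):
        m = build_matrix(
            {"c1": [5.0, 7.0, 9.0], "t1": [1.0, 2.0, 3.0]},
            proteins=["P", "P", "Q"],
        )
        pm = aggregate_to_proteins(m, LfqParams())
        assert pm.protein_ids == ["P"]
        assert pm.intensities.loc["P", "c1"] == 12.0
        assert pm.n_quantified_peptides["P"] == 2

    def test_conservation_of_total_intensity(self, small_simulation):
        _, m, _ = small_simulation
        p = LfqParams()
        imputed = impute_noise_floor(filter_quantifiable(m, p), p)
        pm = aggregate_to_proteins(imputed, p)
        counts = imputed.leading_protein.value_counts()
        dropped = counts.index[counts < p.min_peptides_per_protein]
        dropped_rows = imputed.leading_protein.isin(dropped)
        for s in imputed.sample_ids:
            total = imputed.intensities[s].sum()
            kept = pm.intensities[s].sum()
            lost = imputed.intensities.loc[dropped_rows, s].sum()
            assert kept + lost == pytest.approx(total, rel=1e-9)

    def test_requires_imputed_input(self):
        m = build_matrix({"c1": [5.0, None], "t1": [1.0, 2.0]}, proteins=["P", "P"])
        with pytest.raises(ValueError, match="imputed"):
            aggregate_to_proteins(m, LfqParams())


class TestRunLfq:
    def test_composition_equals_manual_stages(self, small_simulation):
        _, m, _ = small_simulation
        p = LfqParams()
        pm, report = run_lfq(m, p)
        manual = aggregate_to_proteins(
            impute_noise_floor(
                filter_quantifiable(normalize_by_sample_median(m), p), p
            ),
            p,
        )
        pd.testing.assert_frame_equal(pm.intensities, manual.intensities)
        assert report["peptides"].is_monotonic_decreasing

    def test_empty_after_filter_gives_empty_result_and_report(self):
        m = build_matrix({"c1": [5.0], "t1": [6.0]}, classes=["other"])
        pm, report = run_lfq(m, LfqParams())
        assert len(pm.protein_ids) == 0
        assert report["stage"].tolist()[-1] == "proteins"

    def test_per_sample_rescaling_leaves_differential_calls_invariant(
        self, small_simulation
    ):
        _, m, _ = small_simulation
        rng = np.random.default_rng(7)
        scales = pd.Series(rng.uniform(0.2, 5.0, len(m.sample_ids)), index=m.sample_ids)
        scaled = m.replace_intensities(m.intensities * scales)
        pm1, _ = run_lfq(m)
        pm2, _ = run_lfq(scaled)
        # normalization equalizes columns up to one global factor (the
        # target T), so protein tables agree up to that common factor ...
        factor = pm2.intensities.iloc[0, 0] / pm1.intensities.iloc[0, 0]
        np.testing.assert_allclose(
            pm2.intensities.to_numpy(), factor * pm1.intensities.to_numpy(), rtol=1e-9
        )
        # ... and every downstream quantity is invariant
        r1 = differential_proteins(pm1)
        r2 = differential_proteins(pm2)
        np.testing.assert_allclose(r1["ratio"], r2["ratio"], rtol=1e-9)
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], rtol=1e-9, atol=0)
        assert r1["significant"].tolist() == r2["significant"].tolist()
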