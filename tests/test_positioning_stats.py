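"""Difference tables, per-direction summaries and the paired TOST
equivalence procedure (statsmodels as independent oracle)."""
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.weightstats import ttost_paired

from posequiv import (
    PairedRegResult,
    SixDoF,
    dof_differences,
    equivalence_report,
    summarize_differences,
    tost_paired,
)
from posequiv.errors import ValidationError


def _pair(case, ct, sct, modality="3D-CBCT", observer=None):
    return PairedRegResult(
        case=case,
        ct=SixDoF.from_array(ct),
        sct=SixDoF.from_array(sct),
        observer=observer,
        modality=modality,
    )


class TestDofDifferences:
    def test_identical_pairs_give_zero(self):
        pairs = [_pair(1, np.ones(6), np.ones(6))]
        table = dof_differences(pairs)
        assert (table["difference"] == 0).all()

    def test_sign_convention_sct_minus_ct(self):
        pairs = [_pair(1, np.zeros(6), [1, 0, 0, 0, 0, 0])]
        table = dof_differences(pairs)
        rl = table.loc[table["direction"] == "RL", "difference"].item()
        assert rl == 1.0

    def test_2d_roll_marked_unavailable(self):
        pairs = [_pair(1, np.zeros(6), np.zeros(6), modality="2D-orth", observer=1)]
        table = dof_differences(pairs)
        roll = table.loc[table["direction"] == "roll", "difference"]
        assert roll.isna().all()

    def test_missing_pair_member_named(self):
        bad = PairedRegResult.__new__(PairedRegResult)
        bad.case, bad.ct, bad.sct, bad.observer, bad.modality = 7, None, SixDoF(), None, "3D-CBCT"
        with pytest.raises(ValidationError, match="7"):
            dof_differences([bad])

    def test_generator_moments_recovered(self):
        from posequiv import sample_paired_registrations

        mean = np.array([0.4, 0.0, -0.7, 0.3, 0.0, 0.0])
        sd = np.full(6, 0.6)
        pairs = sample_paired_registrations(5000, 1, mean, sd, seed=3, modality="3D-CBCT")
        table = dof_differences(pairs)
        col = summarize_differences(table)
        tol = 3 * 0.6 / np.sqrt(5000)
        for direction, m in zip(("RL", "PA", "IS"), mean[:3]):
            row = col[col["direction"] == direction].iloc[0]
            assert row["mean"] == pytest.approx(m, abs=tol)


class TestSummarizeDifferences:
    def _table(self, values, direction="RL", modality="3D-CBCT"):
        return pd.DataFrame(
            {
                "case": range(len(values)),
                "observer": None,
                "modality": modality,
                "direction": direction,
                "difference": values,
            }
        )

    def test_basic_stats(self):
        out = summarize_differences(self._table([1.0, 2.0, 3.0]))
        row = out.iloc[0]
        assert (row["mean"], row["sd"], row["min"], row["max"]) == (2.0, 1.0, 1.0, 3.0)

    def test_single_value_sd_undefined(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            out = summarize_differences(self._table([1.5]))
        assert np.isnan(out.iloc[0]["sd"])

    def test_empty_direction_omitted_with_warning(self):
        table = self._table([np.nan, np.nan], direction="roll", modality="2D-orth")
        with pytest.warns(UserWarning, match="omitted"):
            out = summarize_differences(table)
        assert out.empty

    def test_simulated_moments(self, rng):
        vals = rng.normal(0.4, 0.7, size=10_000)
        row = summarize_differences(self._table(vals)).iloc[0]
        assert row["mean"] == pytest.approx(0.4, abs=3 * 0.7 / 100)
        assert row["sd"] == pytest.approx(0.7, abs=0.03)


class TestTostPaired:
    def test_tight_sample_is_equivalent(self, rng):
        d = rng.normal(0.0, 0.3, size=14)
        res = tost_paired(d)
        assert res.equivalent
        assert res.p_overall < 0.001
        # independent oracle
        p_sm, _, _ = ttost_paired(d, np.zeros(14), -1.0, 1.0)
        assert res.p_overall == pytest.approx(p_sm, abs=1e-10)

    def test_mean_outside_bounds_not_equivalent(self, rng):
        d = rng.normal(1.5, 0.4, size=20)
        res = tost_paired(d)
        assert not res.equivalent
        assert res.p_upper > 0.5

    def test_mean_at_bound_p_near_half(self, rng):
        n = 4000
        d = rng.normal(1.0, 0.5, size=n)
        d = d - d.mean() + 1.0  # centre the sample exactly at the bound
        res = tost_paired(d)
        assert res.p_upper == pytest.approx(0.5, abs=1e-6)
        assert not res.equivalent

    def test_agreement_with_statsmodels_on_random_data(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 60))
            d = rng.normal(rng.uniform(-2, 2), rng.uniform(0.05, 2.0), size=n)
            res = tost_paired(d)
            p_sm, (t1, p1, _), (t2, p2, _) = ttost_paired(d, np.zeros(n), -1.0, 1.0)
            assert res.p_lower == pytest.approx(p1, abs=1e-8)
            assert res.p_upper == pytest.approx(p2, abs=1e-8)
            assert res.p_overall == pytest.approx(p_sm, abs=1e-8)
            assert res.t_lower == pytest.approx(t1, abs=1e-8)
            assert res.t_upper == pytest.approx(t2, abs=1e-8)

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            inside = tost_paired([0.2, 0.2, 0.2])
        assert inside.equivalent and inside.p_overall == 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            outside = tost_paired([1.5, 1.5, 1.5])
        assert not outside.equivalent and outside.p_overall == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            tost_paired([1.0])
        with pytest.raises(ValidationError):
            tost_paired([0.1, 0.2], low=1.0, high=-1.0)

    def test_ci90_duality(self, rng):
        # equivalence at alpha=0.05 iff the 90% CI lies inside the bounds
        for _ in range(50):
            d = rng.normal(rng.uniform(-1.2, 1.2), rng.uniform(0.1, 1.0), 12)
            res = tost_paired(d)
            inside = res.bounds[0] < res.ci90[0] and res.ci90[1] < res.bounds[1]
            assert res.equivalent == inside


class TestEquivalenceReport:
    def _table(self, means, sd=0.3, n=14, modality="3D-CBCT", seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for direction, m in zip(("RL", "PA", "IS"), means):
            for case, v in enumerate(rng.normal(m, sd, size=n)):
                rows.append((case, None, modality, direction, v))
        return pd.DataFrame(
            rows, columns=["case", "observer", "modality", "direction", "difference"]
        )

    def test_zero_mean_noise_equivalent(self):
        report = equivalence_report(self._table([0.0, 0.0, 0.0]))
        assert report["3D-CBCT"]["pooled"].equivalent

    def test_one_offset_direction_fails_its_own_test(self):
        report = equivalence_report(self._table([0.0, 2.0, 0.0]))
        per = report["3D-CBCT"]["per_direction"]
        assert not per["PA"].equivalent
        assert per["RL"].equivalent and per["IS"].equivalent

    def test_observed_scale_differences_are_equivalent(self):
        # per-direction means/SDs at the scale measured for 3D bone-based
        # positioning: ~(0.1, 0.4, -0.7) mm means, 0.5-0.7 mm SDs, n=14
        rng = np.random.default_rng(7)
        rows = []
        for direction, m, s in zip(
            ("RL", "PA", "IS"), (0.1, 0.4, -0.7), (0.5, 0.7, 0.6)
        ):
            for case, v in enumerate(rng.normal(m, s, size=14)):
                rows.append((case, None, "3D-CBCT", direction, v))
        table = pd.DataFrame(
            rows, columns=["case", "observer", "modality", "direction", "difference"]
        )
        assert equivalence_report(table)["3D-CBCT"]["pooled"].equivalent

    def test_no_translation_rows_rejected(self):
        table = pd.DataFrame(
            [(1, None, "3D-CBCT", "pitch", 0.1)],
            columns=["case", "observer", "modality", "direction", "difference"],
        )
        with pytest.raises(ValidationError):
            equivalence_report(table)
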