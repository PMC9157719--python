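"""Repeatability and uptake-time statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import bh_stepup, wilcoxon_exact_enum

from dtpradiomics.stats import (
    bh_fdr,
    classify_all,
    classify_feature,
    icc_agreement_single,
    uptake_z,
    wilcoxon_signed_rank,
)


class TestICC:
    def test_perfect_agreement(self, rng):
        x = rng.uniform(1, 10, size=8)
        assert icc_agreement_single(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_systematic_offset_kills_agreement(self, rng):
        """Absolute-agreement ICC penalizes a retest offset >> spread."""
        x = rng.uniform(1, 2, size=8)
        icc = icc_agreement_single(np.column_stack([x, x + 100.0]))
        assert abs(icc) < 0.05

    def test_matches_pingouin_anova_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(10):
            x = rng.normal(10, 3, size=(6, 2))
            df = pd.DataFrame(
                {
                    "target": np.repeat(np.arange(6), 2),
                    "rater": np.tile([0, 1], 6),
                    "score": x.ravel(),
                }
            )
            res = pingouin.intraclass_corr(
                df, targets="target", raters="rater", ratings="score"
            )
            expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_agreement_single(x) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_agreement_single(np.ones((5, 2)))
        with pytest.raises(ValueError, match="3 subjects"):
            icc_agreement_single(np.array([[1.0, 2.0], [3.0, 4.0]]))


class TestWilcoxon:
    def test_no_signal_gives_p_one(self):
        x = np.arange(1.0, 9.0)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_six_concordant_pairs_exact_p(self):
        """n=6, all differences positive: two-sided exact p = 2/2^6."""
        x60 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x90 = x60 + np.array([0.5, 0.3, 0.8, 0.1, 0.9, 0.2])
        assert wilcoxon_signed_rank(x60, x90) == pytest.approx(0.03125)

    def test_exact_mode_matches_full_enumeration(self, rng):
        for n in (5, 6, 8, 10):
            for _ in range(5):
                d = rng.normal(0.3, 1.0, size=n)
                while np.unique(np.abs(d)).size < n or np.any(d == 0):
                    d = rng.normal(0.3, 1.0, size=n)
                x60 = rng.uniform(1, 5, size=n)
                p = wilcoxon_signed_rank(x60, x60 + d)
                assert p == pytest.approx(wilcoxon_exact_enum(d), abs=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.037])), [0.037])

    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_matches_stepup_oracle_and_permutation_equivariance(self, rng):
        p = rng.uniform(size=49)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
        assert np.all(q >= p)
        perm = rng.permutation(49)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)


class TestUptakeZ:
    def test_centering(self):
        """A lesion whose change equals mean(TRT60) has z = 0."""
        rf60_d1 = np.array([2.0, 3.0, 4.0])
        rf60_d2 = rf60_d1 + np.array([0.1, 0.2, 0.3])  # mean TRT60 = 0.2
        rf90_d1 = rf60_d1 + np.array([0.2, 0.5, 0.8])
        res = uptake_z(rf60_d1, rf90_d1, rf60_d2)
        assert res.z[0] == pytest.approx(0.0)

    def test_scale_and_shift_invariance(self, rng):
        rf60_d1 = rng.uniform(2, 10, 6)
        rf90_d1 = rf60_d1 * rng.uniform(1.0, 1.4, 6)
        rf60_d2 = rf60_d1 * rng.uniform(0.9, 1.1, 6)
        base = uptake_z(rf60_d1, rf90_d1, rf60_d2)
        scaled = uptake_z(2 * rf60_d1, 2 * rf90_d1, 2 * rf60_d2)
        np.testing.assert_allclose(scaled.z, base.z, rtol=1e-12)
        shifted = uptake_z(rf60_d1 + 5, rf90_d1 + 5, rf60_d2 + 5)
        np.testing.assert_allclose(shifted.z, base.z, rtol=1e-12)

    def test_four_lesion_spreadsheet_example(self):
        """Hand-worked example: TRT60 = (.2,-.1,.3,.4), deltas = (.5,.2,.9,.1)."""
        rf60_d1 = np.array([2.0, 3.0, 4.0, 5.0])
        rf90_d1 = np.array([2.5, 3.2, 4.9, 5.1])
        rf60_d2 = np.array([2.2, 2.9, 4.3, 5.4])
        # mean TRT60 = 0.2; sd = sqrt(0.14/3); z = (delta - 0.2)/sd
        sd = np.sqrt(0.14 / 3)
        expected = np.array([0.3, 0.0, 0.7, -0.1]) / sd
        res = uptake_z(rf60_d1, rf90_d1, rf60_d2)
        np.testing.assert_allclose(res.z, expected, rtol=1e-12, atol=1e-12)
        assert res.mean_z == pytest.approx(expected.mean())

    def test_degenerate_trt_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            uptake_z(np.array([1.0, 2.0]), np.array([2.0, 3.0]), np.array([1.5, 2.5]))


class TestClassify:
    @pytest.mark.parametrize(
        "icc60,icc90,q,mean_z,expected",
        [
            (0.95, 0.95, 0.01, 1.5, "DTP"),
            (0.95, 0.95, 0.01, -1.5, "DTP"),  # susceptibility uses |mean z|
            (0.85, 0.95, 0.01, 1.5, "DISCARDED"),
            (0.95, 0.89, 0.50, 0.1, "DISCARDED"),
            (0.90, 0.95, 0.01, 1.5, "DISCARDED"),  # gate is strict
            (0.95, 0.95, 0.30, 0.4, "CS2"),
            (0.95, 0.95, 0.01, 0.4, "CS1"),
            (0.95, 0.95, 0.30, 1.4, "CS1"),
        ],
    )
    def test_flowchart_rule(self, icc60, icc90, q, mean_z, expected):
        assert classify_feature(icc60, icc90, q, mean_z) == expected

    @settings(derandomize=True, max_examples=300)
    @given(
        icc60=st.floats(-1, 1), icc90=st.floats(-1, 1),
        q=st.floats(0, 1), mean_z=st.floats(-10, 10),
    )
    def test_outcomes_partition_the_domain(self, icc60, icc90, q, mean_z):
        """Every finite input lands in exactly one of the four use cases."""
        uc = classify_feature(icc60, icc90, q, mean_z)
        assert uc in ("DTP", "CS1", "CS2", "DISCARDED")
        repeatable = icc60 > 0.9 and icc90 > 0.9
        assert (uc == "DISCARDED") == (not repeatable)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_bh_adjusted_at_least_raw_and_capped(self, p):
        q = bh_fdr(np.asarray(p))
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)


def _toy_table(rng, n_lesions=8, drift=0.3, noise=0.05):
    rows = []
    base = rng.uniform(3, 12, n_lesions)
    for l in range(n_lesions):
        for day in (1, 2):
            for t in (60.0, 90.0):
                scale = 1.0 + drift * (t - 60.0) / 30.0
                val = base[l] * scale * (1 + noise * rng.standard_normal())
                rows.append(
                    {"lesion": l, "day": day, "time_min": t,
                     "feature": "CONV_SUVmean", "value": val}
                )
                rows.append(
                    {"lesion": l, "day": day, "time_min": t,
                     "feature": "SHAPE_volume_vx", "value": 100.0 + l + 0.01 * rng.standard_normal()}
                )
    return pd.DataFrame(rows)


class TestClassifyAll:
    def test_recovers_drifting_feature(self, rng):
        report = classify_all(_toy_table(rng))
        row = report.set_index("feature").loc["CONV_SUVmean"]
        assert row.use_case == "DTP"
        assert row.mean_z > 1

    def test_deterministic_given_table(self, rng):
        table = _toy_table(rng)
        r1 = classify_all(table)
        r2 = classify_all(table.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            r1.sort_values("feature").reset_index(drop=True),
            r2.sort_values("feature").reset_index(drop=True),
        )

    def test_type_i_error_control_under_null(self):
        """With no time effect, the FDR-flagged fraction stays near 5%."""
        rng = np.random.default_rng(11)
        n_feat, n_lesions = 49, 12
        flagged = 0
        total = 0
        for _ in range(200):
            p = np.empty(n_feat)
            for f in range(n_feat):
                x60 = rng.normal(10, 3, n_lesions)
                x90 = x60 + rng.normal(0, 0.5, n_lesions)
                p[f] = wilcoxon_signed_rank(x60, x90)
            flagged += int((bh_fdr(p) < 0.05).sum())
            total += n_feat
        assert flagged / total <= 0.05

    def test_incomplete_lesions_excluded(self, rng):
        table = _toy_table(rng)
        table = table[~((table.lesion == 0) & (table.day == 2) & (table.time_min == 90.0))]
        report = classify_all(table)  # still runs on the 7 complete lesions
        assert set(report.feature) == {"CONV_SUVmean", "SHAPE_volume_vx"}
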