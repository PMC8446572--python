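"""Network meta-analysis: CI back-transforms, pooling, graph solution."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oncocea as oc
from oncocea.nma import z_quantile


def est(a, b, y, se, endpoint="OS", trial=""):
    return oc.EffectEstimate(trial, a, b, endpoint, y, se)


class TestSeFromCi:
    @pytest.mark.parametrize(
        "point, low, high, expected",
        [(0.66, 0.46, 0.95, 0.1850), (0.59, 0.37, 0.94, 0.2379)],
    )
    def test_known_back_transforms(self, point, low, high, expected):
        assert oc.se_from_ci(point, low, high, 0.95) == pytest.approx(expected, abs=5e-5)

    def test_degenerate_and_invalid_cis_rejected(self):
        with pytest.raises(oc.EvidenceError):
            oc.se_from_ci(1.0, 1.0, 1.0, 0.95)
        with pytest.raises(oc.EvidenceError):
            oc.se_from_ci(0.5, -0.1, 0.9, 0.95)
        with pytest.raises(oc.EvidenceError):
            oc.se_from_ci(0.3, 0.5, 0.9, 0.95)  # point below low

    def test_z_quantile_at_95(self):
        assert z_quantile(0.95) == pytest.approx(1.959964, abs=1e-6)


class TestLogRrFromCounts:
    def test_equal_risks_give_zero_effect(self):
        e = oc.log_rr_from_counts(10, 100, 10, 100)
        assert e.log_effect == 0.0
        assert e.se == pytest.approx(np.sqrt(0.18), rel=1e-12)

    def test_doubled_risk(self):
        e = oc.log_rr_from_counts(30, 100, 15, 100)
        assert e.log_effect == pytest.approx(np.log(2), rel=1e-12)

    def test_zero_cell_rejected_without_explicit_correction(self):
        with pytest.raises(oc.EvidenceError, match="zero events"):
            oc.log_rr_from_counts(0, 100, 5, 100)
        corrected = oc.log_rr_from_counts(0, 100, 5, 100, continuity_correction=True)
        assert np.isfinite(corrected.log_effect) and corrected.se > 0


class TestPoolDirect:
    def test_single_estimate_is_identity(self):
        e = est("a", "c", -0.3, 0.2)
        pooled = oc.pool_direct([e])
        assert (pooled.log_effect, pooled.se) == (e.log_effect, e.se)

    def test_inverse_variance_closed_form(self):
        pooled = oc.pool_direct([est("a", "c", -0.3, 0.2), est("a", "c", -0.1, 0.4)])
        assert pooled.log_effect == pytest.approx(-0.26, rel=1e-12)
        assert pooled.se == pytest.approx(0.17889, abs=5e-6)

    def test_two_identical_estimates_halve_the_variance(self):
        pooled = oc.pool_direct([est("a", "c", 0.4, 0.3), est("a", "c", 0.4, 0.3)])
        assert pooled.log_effect == pytest.approx(0.4)
        assert pooled.se == pytest.approx(0.3 / np.sqrt(2), rel=1e-12)

    def test_mixed_comparisons_rejected(self):
        with pytest.raises(oc.EvidenceError, match="single ordered comparison"):
            oc.pool_direct([est("a", "c", 0.1, 0.2), est("b", "c", 0.1, 0.2)])


class TestNetworkEstimates:
    def test_star_indirect_contrast_closed_form(self):
        ev = [est("a", "c", -0.5, 0.2), est("b", "c", -0.2, 0.25)]
        r = oc.network_estimates(ev, "OS")
        assert r.log_effect("a", "b") == pytest.approx(-0.3, abs=1e-12)
        assert r.se("a", "b") == pytest.approx(0.32016, abs=5e-6)

    def test_single_comparison_has_no_heterogeneity(self):
        r = oc.network_estimates([est("a", "c", -0.5, 0.2)], "OS")
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.i_squared == 0.0

    def test_consistent_replicates_have_zero_q(self):
        r = oc.network_estimates(
            [est("a", "c", -0.5, 0.2, trial="t1"), est("a", "c", -0.5, 0.3, trial="t2")],
            "OS",
        )
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.i_squared == 0.0

    def test_i_squared_zero_whenever_q_below_df(self, rng):
        # mild noise on a replicated edge: Q small, never negative I^2
        for _ in range(20):
            y = rng.normal(-0.4, 0.02, size=3)
            ev = [est("a", "c", float(v), 0.5, trial=f"t{i}") for i, v in enumerate(y)]
            r = oc.network_estimates(ev, "OS")
            if r.Q <= r.df:
                assert r.i_squared == 0.0
            assert 0.0 <= r.i_squared <= 1.0

    def test_disconnected_network_rejected(self):
        ev = [est("a", "c", -0.5, 0.2), est("b", "d", -0.2, 0.25)]
        with pytest.raises(oc.EvidenceError, match="disconnected"):
            oc.network_estimates(ev, "OS")

    def test_multi_arm_trial_triggers_warning(self):
        ev = [
            est("a", "c", -0.5, 0.2, trial="trial1"),
            est("b", "c", -0.2, 0.25, trial="trial1"),
        ]
        with pytest.warns(UserWarning, match="multiple"):
            oc.network_estimates(ev, "OS")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.data())
    def test_league_table_antisymmetry(self, data):
        n_arms = data.draw(st.integers(2, 5))
        arms = [f"t{i}" for i in range(n_arms)]
        ev = []
        for i, a in enumerate(arms[1:], start=1):
            y = data.draw(st.floats(-1.5, 1.5))
            se = data.draw(st.floats(0.05, 0.8))
            ev.append(est(a, arms[0], y, se, trial=f"tr{i}"))
        r = oc.network_estimates(ev, "OS")
        m = r.log_effect_matrix
        assert np.allclose(m + m.T, 0.0, atol=1e-12)
        assert np.allclose(np.diag(m), 0.0, atol=1e-12)
        assert np.allclose(np.exp(m) * np.exp(m.T), 1.0, atol=1e-12)


def test_packaged_evidence_reproduces_reported_pfs_contrasts():
    """The five-trial table yields the reported indirect PFS comparisons."""
    ev = oc.read_evidence(oc.five_trials_path())
    r = oc.network_estimates(ev, "PFS")
    assert r.effect("pembrolizumab", "nivolumab") == pytest.approx(0.66, abs=0.01)
    assert r.effect("atezolizumab", "nivolumab") == pytest.approx(0.59, abs=0.01)
    lo, hi = r.ci("pembrolizumab", "nivolumab")
    assert lo == pytest.approx(0.46, abs=0.01)
    assert hi == pytest.approx(0.95, abs=0.01)


def test_evidence_reader_handles_both_row_kinds(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text(
        "trial,arm_a,arm_b,endpoint,effect,ci_low,ci_high,events_a,n_a,events_b,n_b\n"
        "t1,a,c,OS,0.8,0.6,1.05,,,,\n"
        "t2,b,c,SAE,,,,10,100,20,100\n"
    )
    ev = oc.read_evidence(path)
    assert len(ev) == 2
    assert ev[0].endpoint == "OS" and ev[0].effect == pytest.approx(0.8)
    assert ev[1].log_effect == pytest.approx(np.log(0.5), rel=1e-12)
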