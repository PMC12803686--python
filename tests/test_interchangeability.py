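"""IEC estimator, bootstrap CI and quality stratification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echointerchange import (
    DegenerateDataError,
    InsufficientDataError,
    IECResult,
    MethodModel,
    NotEstimable,
    Triad,
    bootstrap_iec_ci,
    compute_iec,
    iec_by_quality,
    simulate_triads,
)

from conftest import CART_CL1, CART_CLIN, HH_AI, make_cohort


def naive_iec(triads):
    """Two-loop reference implementation, independent of the vectorised path."""
    s_rr = s_tr = 0.0
    for tr in triads:
        s_rr += (tr.r1 - tr.r2) ** 2
        s_tr += ((tr.t - tr.r1) ** 2 + (tr.t - tr.r2) ** 2) / 2.0
    q_rr, q_tr = s_rr / len(triads), s_tr / len(triads)
    return (q_tr - q_rr) / (q_rr / 2.0), q_rr, q_tr


class TestComputeIEC:
    def test_hand_calculation(self):
        triads = [Triad("a", 50, 52, 48), Triad("b", 60, 58, 62)]
        iec, q_rr, q_tr = compute_iec(triads)
        assert (q_rr, q_tr) == (16.0, 4.0)
        assert iec == pytest.approx(-1.5)

    def test_test_equal_to_one_reference_gives_minus_one(self):
        triads = [Triad("a", 52, 52, 48), Triad("b", 58, 58, 62), Triad("c", 40, 40, 45)]
        iec, q_rr, q_tr = compute_iec(triads)
        assert iec == pytest.approx(-1.0)
        assert q_tr == pytest.approx(q_rr / 2.0)

    def test_replicated_triad_hand_calculation(self):
        # per patient: (r1-r2)^2 = 16, [(t-r1)^2 + (t-r2)^2]/2 = (4 + 36)/2 = 20
        triads = [Triad("a", 54, 52, 48), Triad("b", 54, 52, 48)]
        iec, q_rr, q_tr = compute_iec(triads)
        assert (q_rr, q_tr) == (16.0, 20.0)
        assert iec == pytest.approx(0.5)

    def test_fewer_than_two_triads_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_iec([Triad("a", 50, 52, 48)])

    def test_identical_references_everywhere_rejected(self):
        with pytest.raises(DegenerateDataError):
            compute_iec([Triad("a", 50, 52, 52), Triad("b", 60, 58, 58)])


finite = st.floats(min_value=5.0, max_value=90.0)


@st.composite
def triad_lists(draw):
    vals = draw(st.lists(st.tuples(finite, finite, finite), min_size=2, max_size=30))
    triads = [Triad(f"P{i}", *v) for i, v in enumerate(vals)]
    q_rr = np.mean([(tr.r1 - tr.r2) ** 2 for tr in triads])
    if q_rr <= 1e-9:
        triads[0] = Triad("P0", triads[0].t, 50.0, 60.0)
    return triads


class TestIECProperties:
    @settings(deadline=None, derandomize=True)
    @given(triad_lists(), st.sets(st.integers(0, 29)))
    def test_swapping_references_changes_nothing(self, triads, swap_idx):
        swapped = [tr.swapped() if i in swap_idx else tr for i, tr in enumerate(triads)]
        assert compute_iec(swapped) == pytest.approx(compute_iec(triads))

    @settings(deadline=None, derandomize=True)
    @given(triad_lists(), st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, triads, c):
        scaled = [Triad(tr.patient_id, c * tr.t, c * tr.r1, c * tr.r2) for tr in triads]
        iec0, q_rr0, q_tr0 = compute_iec(triads)
        iec1, q_rr1, q_tr1 = compute_iec(scaled)
        assert iec1 == pytest.approx(iec0, rel=1e-9)
        assert q_rr1 == pytest.approx(c**2 * q_rr0, rel=1e-9)
        assert q_tr1 == pytest.approx(c**2 * q_tr0, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(triad_lists())
    def test_lower_bound_and_oracle_agreement(self, triads):
        iec, q_rr, q_tr = compute_iec(triads)
        assert iec >= -2.0
        oracle = naive_iec(triads)
        assert iec == pytest.approx(oracle[0], rel=1e-12, abs=1e-12)
        assert q_rr == pytest.approx(oracle[1], rel=1e-12)
        assert q_tr == pytest.approx(oracle[2], rel=1e-12)


class TestBootstrap:
    def test_degenerate_distribution_gives_point_interval(self):
        # t identical to r1 for every patient: IEC = -1 in every resample
        triads = [Triad(f"P{i}", 50 + i, 50 + i, 55 + i) for i in range(12)]
        res = bootstrap_iec_ci(triads, n_boot=500, seed=0)
        assert res.iec == pytest.approx(-1.0)
        assert (res.ci_low, res.ci_high) == (pytest.approx(-1.0), pytest.approx(-1.0))
        assert res.interchangeable

    def test_ci_brackets_point_estimate_and_known_truth(self):
        m = MethodModel(0.0, 5.0)
        triads = simulate_triads(400, m, m, m, seed=23)  # population IEC = 0
        res = bootstrap_iec_ci(triads, n_boot=2000, seed=24)
        assert res.ci_low <= res.iec <= res.ci_high
        assert res.ci_low < 0.0 < res.ci_high
        assert abs(res.iec) < 0.3
        assert res.n_triads == 400 and res.n_degenerate == 0

    def test_bca_interval_close_to_percentile(self):
        m = MethodModel(0.0, 5.0)
        triads = simulate_triads(300, m, m, m, seed=31)
        pct = bootstrap_iec_ci(triads, n_boot=2000, seed=32)
        bca = bootstrap_iec_ci(triads, n_boot=2000, seed=32, method="bca")
        assert bca.ci_low == pytest.approx(pct.ci_low, abs=0.15)
        assert bca.ci_high == pytest.approx(pct.ci_high, abs=0.15)
        assert bca.ci_low <= bca.iec <= bca.ci_high

    def test_deterministic_given_seed(self):
        m = MethodModel(0.0, 5.0)
        triads = simulate_triads(50, m, m, m, seed=41)
        a = bootstrap_iec_ci(triads, n_boot=500, seed=7)
        b = bootstrap_iec_ci(triads, n_boot=500, seed=7)
        assert (a.iec, a.ci_low, a.ci_high) == (b.iec, b.ci_low, b.ci_high)

    def test_verdict_follows_threshold_rule(self):
        big = MethodModel(0.0, 15.0)
        small = MethodModel(0.0, 5.0)
        noisy = bootstrap_iec_ci(simulate_triads(300, big, small, small, seed=51),
                                 n_boot=500, seed=52)
        assert noisy.ci_high >= 0.25 and not noisy.interchangeable
        quiet = bootstrap_iec_ci(simulate_triads(300, MethodModel(0.0, 2.0), small, small,
                                                 seed=53), n_boot=500, seed=54)
        assert quiet.ci_high < 0.25 and quiet.interchangeable


class TestIECByQuality:
    def _cohort(self, qualities):
        rows = []
        rng = np.random.default_rng(61)
        for i, q in enumerate(qualities):
            pid = f"P{i}"
            base = 55 + rng.normal(0, 7)
            rows += [
                (pid, HH_AI, "lvef", base + rng.normal(0, 4), q),
                (pid, CART_CLIN, "lvef", base + rng.normal(0, 4), "good"),
                (pid, CART_CL1, "lvef", base + rng.normal(0, 4), "good"),
            ]
        return make_cohort(rows)

    def test_single_category_gives_single_entry(self):
        cohort = self._cohort(["good"] * 10)
        out = iec_by_quality(cohort, "lvef", HH_AI, (CART_CLIN, CART_CL1),
                             n_boot=300, seed=1)
        assert set(out) == {"good"}
        assert isinstance(out["good"], IECResult)

    def test_small_category_flagged_not_estimable(self):
        cohort = self._cohort(["good"] * 10 + ["poor"])
        out = iec_by_quality(cohort, "lvef", HH_AI, (CART_CLIN, CART_CL1),
                             n_boot=300, seed=1)
        assert isinstance(out["poor"], NotEstimable)
        assert out["poor"].n_triads == 1
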