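"""Dempster-Shafer machinery: rule, conflict, discounting, worked examples."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsefuse.errors import (
    InvalidInputError,
    TotalConflictError,
    UninformativeEvidenceError,
)
from drowsefuse.evidence_fusion import (
    FusionConfig,
    MassVector,
    belief_factors,
    bpa_from_outputs,
    combine_with_correction,
    conflict_degree,
    dempster_combine,
    discount_bpa,
    evidence_distance,
)
from drowsefuse.synthetic_data import fixtures

PRINTED_TOL = 0.005  # absorbs the 3-decimal rounding of the printed tables


def random_mass(rng, allow_theta=True):
    k = 4 if allow_theta else 3
    v = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3.0))
    return MassVector(*v) if k == 4 else MassVector(*v, 0.0)


mass_strategy = st.builds(
    lambda seed: random_mass(np.random.default_rng(seed)),
    st.integers(0, 2**31 - 1),
)


class TestBPA:
    def test_printed_network_outputs_normalise_to_printed_evidence(self):
        m = bpa_from_outputs([0.203, 0.763, 0.052])
        assert m.singletons == pytest.approx((0.199, 0.750, 0.051), abs=5e-4)

    def test_uniform_and_point_mass(self):
        assert bpa_from_outputs([1, 1, 1]).singletons == pytest.approx((1 / 3,) * 3)
        assert bpa_from_outputs([0, 0, 5]).singletons == (0.0, 0.0, 1.0)

    def test_negative_components_clamped(self):
        m = bpa_from_outputs([-0.5, 0.5, 0.5])
        assert m.singletons == pytest.approx((0.0, 0.5, 0.5))

    def test_all_nonpositive_signals_uninformative(self):
        with pytest.raises(UninformativeEvidenceError):
            bpa_from_outputs([-1.0, 0.0, -0.2])


class TestConflictAndCombination:
    def test_identical_point_masses_no_conflict(self):
        m = MassVector(1, 0, 0)
        assert conflict_degree(m, m) == 0.0

    def test_disjoint_point_masses_total_conflict(self):
        assert conflict_degree(MassVector(1, 0, 0), MassVector(0, 1, 0)) == 1.0
        with pytest.raises(TotalConflictError):
            dempster_combine(MassVector(1, 0, 0), MassVector(0, 1, 0))

    def test_printed_first_fusion_row(self):
        m1 = MassVector(0.228, 0.601, 0.171)
        m2 = MassVector(0.359, 0.516, 0.125)
        assert conflict_degree(m1, m2) == pytest.approx(0.587, abs=0.003)
        assert dempster_combine(m1, m2).mf == pytest.approx(0.751, abs=0.003)

    def test_vacuous_is_neutral(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_mass(rng)
            fused = dempster_combine(MassVector.vacuous(), m)
            assert fused.as_array() == pytest.approx(m.as_array(), abs=1e-12)

    def test_theta_mass_hand_example(self):
        m1 = MassVector(0.4, 0, 0, 0.6)
        m2 = MassVector(0.5, 0, 0, 0.5)
        fused = dempster_combine(m1, m2)
        # products: A1A1=.2, A1T=.2, TA1=.3, TT=.3; K=0
        assert fused.nf == pytest.approx(0.7)
        assert fused.theta == pytest.approx(0.3)

    def test_conflict_self_identity(self):
        # K(m, m) = 1 - sum m(A_i)^2 for theta-free masses
        rng = np.random.default_rng(9)
        for _ in range(50):
            m = random_mass(rng, allow_theta=False)
            s = np.asarray(m.singletons)
            assert conflict_degree(m, m) == pytest.approx(1.0 - float(s @ s), abs=1e-12)
            assert conflict_degree(m, m) <= 1.0 - float(s @ s) + 1e-12

    def test_brute_force_intersection_oracle(self):
        """Enumerate all 4x4 focal-set products on 1000 random pairs."""
        FOCALS = [frozenset({0}), frozenset({1}), frozenset({2}), frozenset({0, 1, 2})]
        rng = np.random.default_rng(77)
        for _ in range(1000):
            m1, m2 = random_mass(rng), random_mass(rng)
            a1, a2 = m1.as_array(), m2.as_array()
            raw = {f: 0.0 for f in FOCALS}
            K = 0.0
            for i, fi in enumerate(FOCALS):
                for j, fj in enumerate(FOCALS):
                    inter = fi & fj
                    if inter:
                        raw[inter] += a1[i] * a2[j]
                    else:
                        K += a1[i] * a2[j]
            assert conflict_degree(m1, m2) == pytest.approx(K, abs=1e-12)
            if K < 1 - 1e-9:
                fused = dempster_combine(m1, m2)
                expect = np.array(
                    [raw[FOCALS[0]], raw[FOCALS[1]], raw[FOCALS[2]], raw[FOCALS[3]]]
                ) / (1.0 - K)
                assert fused.as_array() == pytest.approx(expect, abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(m1=mass_strategy, m2=mass_strategy)
def test_combination_conserves_mass_and_commutes(m1, m2):
    if conflict_degree(m1, m2) >= 1 - 1e-9:
        return
    f12 = dempster_combine(m1, m2)
    f21 = dempster_combine(m2, m1)
    assert float(f12.as_array().sum()) == pytest.approx(1.0, abs=1e-9)
    assert f12.as_array() == pytest.approx(f21.as_array(), abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(m1=mass_strategy, m2=mass_strategy, m3=mass_strategy)
def test_combination_associative(m1, m2, m3):
    try:
        left = dempster_combine(dempster_combine(m1, m2), m3)
        right = dempster_combine(m1, dempster_combine(m2, m3))
    except TotalConflictError:
        return
    assert left.as_array() == pytest.approx(right.as_array(), abs=1e-9)


class TestDistanceAndBeliefFactors:
    def test_distance_examples(self):
        m = MassVector(0.5, 0.5, 0)
        assert evidence_distance(m, m) == 0.0
        assert evidence_distance(MassVector(1, 0, 0), MassVector(0, 1, 0)) == pytest.approx(1.0)

    def test_distance_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            d = evidence_distance(random_mass(rng), random_mass(rng))
            assert 0.0 <= d <= 1.0

    def test_identical_evidence_full_belief(self):
        m = MassVector(0.2, 0.5, 0.3)
        report = belief_factors([m, m])
        assert report.mean_confidences == pytest.approx([0.0, 0.0])
        assert report.belief_factors == pytest.approx([1.0, 1.0])

    def test_eta_endpoints_and_monotonicity(self):
        eta = lambda c: (1 - c) * np.exp(c)
        assert eta(0.0) == 1.0
        assert eta(1.0) == 0.0
        assert eta(0.2) > eta(0.5) > eta(0.9)
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(eta(grid)) < 0)

    def test_discount_examples(self):
        m = MassVector(0.5, 0.3, 0.2)
        assert discount_bpa(m, 1.0).as_array() == pytest.approx(m.as_array())
        assert discount_bpa(m, 0.0).theta == 1.0
        d = discount_bpa(m, 0.8)
        assert d.as_array() == pytest.approx([0.4, 0.24, 0.16, 0.2])
        with pytest.raises(InvalidInputError):
            discount_bpa(m, 1.5)


class TestGatedCombination:
    def test_low_conflict_plain_path(self):
        m = MassVector(1, 0, 0)
        fused, report = combine_with_correction(m, m)
        assert not report.corrected
        assert report.belief_factors == pytest.approx([1.0, 1.0])
        assert fused.nf == 1.0

    def test_printed_high_conflict_row_still_uncorrected(self):
        # K = 0.835 stays below the default gate of 0.9
        m1 = MassVector.from_unnormalized((0.127, 0.073, 0.811))
        m2 = MassVector.from_unnormalized((0.442, 0.551, 0.107))
        fused, report = combine_with_correction(m1, m2)
        assert not report.corrected
        assert report.K == pytest.approx(0.835, abs=0.003)
        assert fused.sf == pytest.approx(0.471, abs=0.003)

    def test_total_conflict_resolved_by_discounting(self):
        m1, m2 = MassVector(1, 0, 0), MassVector(0, 1, 0)
        fused, report = combine_with_correction(m1, m2, FusionConfig(conflict_threshold=0.5))
        assert report.corrected
        assert fused.theta > 0
        assert float(fused.as_array().sum()) == pytest.approx(1.0, abs=1e-9)


class TestWorkedExampleReplay:
    """Every self-consistent printed row reproduces within +-0.005."""

    def test_first_fusion_rows(self):
        wx = fixtures()
        for outputs, row in zip(wx.network_outputs, wx.first_fusion):
            if not row["consistent"]:
                continue
            m1 = bpa_from_outputs(outputs[0])
            m2 = bpa_from_outputs(outputs[1])
            assert m1.singletons == pytest.approx(row["m1"], abs=PRINTED_TOL)
            assert m2.singletons == pytest.approx(row["m2"], abs=PRINTED_TOL)
            assert conflict_degree(m1, m2) == pytest.approx(row["K"], abs=PRINTED_TOL)
            fused = dempster_combine(m1, m2)
            assert fused.singletons == pytest.approx(row["fused"], abs=PRINTED_TOL)

    def test_decision_fusion_rows(self):
        wx = fixtures()
        for row in wx.decision_fusion:
            if not row["consistent"]:
                continue
            inter = MassVector.from_unnormalized(row["inter"])
            prev = MassVector.from_unnormalized(row["prev"])
            assert conflict_degree(inter, prev) == pytest.approx(row["K"], abs=PRINTED_TOL)
            fused = dempster_combine(inter, prev)
            assert fused.singletons == pytest.approx(row["fused"], abs=PRINTED_TOL)

    def test_inconsistent_rows_flagged_by_rederivation(self):
        """The flags match an automated re-derivation of every row."""
        wx = fixtures()
        for outputs, row in zip(wx.network_outputs, wx.first_fusion):
            m1, m2 = bpa_from_outputs(outputs[0]), bpa_from_outputs(outputs[1])
            fused = dempster_combine(m1, m2)
            ok = (
                abs(conflict_degree(m1, m2) - row["K"]) <= PRINTED_TOL
                and max(abs(a - b) for a, b in zip(fused.singletons, row["fused"])) <= PRINTED_TOL
            )
            assert ok == row["consistent"]
        for row in wx.decision_fusion:
            inter = MassVector.from_unnormalized(row["inter"])
            prev = MassVector.from_unnormalized(row["prev"])
            fused = dempster_combine(inter, prev)
            ok = (
                abs(conflict_degree(inter, prev) - row["K"]) <= 0.01
                and max(abs(a - b) for a, b in zip(fused.singletons, row["fused"])) <= PRINTED_TOL
            )
            assert ok == row["consistent"]
        assert len(wx.flagged_rows) == 3
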