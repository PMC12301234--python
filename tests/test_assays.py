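"""Assay analysis tests: competition binning, footprinting protection calls,
tumor growth inhibition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panscreen import assays as A

BIN1 = ["SC52-002", "control-mAb"]
BIN2 = ["SC52-005", "SC52-011", "TB643-070", "TB758-030", "TB758-051"]


def competition_fixture(blocked_response=0.05, open_response=0.95):
    """Relative-response matrix for two mutually-blocking groups with no
    cross-competition between groups."""
    names = BIN1 + BIN2
    rows = {}
    for lig in names:
        rows[lig] = {an: (blocked_response
                          if (lig in BIN1) == (an in BIN1) else open_response)
                     for an in names}
    return pd.DataFrame(rows).T


class TestBinarize:
    def test_low_response_blocked(self):
        m = pd.DataFrame({"a": [0.10]}, index=["a"])
        assert bool(A.binarize_competition(m, 0.30).iloc[0, 0]) is True

    def test_high_response_open(self):
        m = pd.DataFrame({"a": [0.95]}, index=["a"])
        assert bool(A.binarize_competition(m, 0.30).iloc[0, 0]) is False

    def test_self_pair_blocks(self):
        m = competition_fixture()
        blocked = A.binarize_competition(m, 0.30)
        for ab in BIN1 + BIN2:
            assert bool(blocked.loc[ab, ab]) is True

    def test_missing_cell_stays_masked(self):
        m = competition_fixture()
        m.loc[BIN1[0], BIN2[0]] = np.nan
        blocked = A.binarize_competition(m, 0.30)
        assert pd.isna(blocked.loc[BIN1[0], BIN2[0]])

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            A.binarize_competition(competition_fixture(), 1.5)


class TestAssignBins:
    def test_two_bin_worked_example(self):
        """Two mutually-blocking groups (2 and 5 antibodies, no
        cross-blocking) resolve into exactly two bins with the stated
        memberships."""
        blocked = A.binarize_competition(competition_fixture(), 0.30)
        asg = A.assign_bins(blocked)
        assert asg.n_bins == 2
        groups = {tuple(asg.members(b)) for b in (1, 2)}
        assert groups == {tuple(sorted(BIN1)), tuple(sorted(BIN2))}

    def test_identity_only_blocking_gives_singletons(self):
        names = [f"ab{i}" for i in range(4)]
        m = pd.DataFrame(0.9, index=names, columns=names)
        np.fill_diagonal(m.values, 0.05)
        asg = A.assign_bins(A.binarize_competition(m, 0.30))
        assert asg.n_bins == 4

    def test_identical_rows_share_bin(self):
        blocked = A.binarize_competition(competition_fixture(), 0.30)
        asg = A.assign_bins(blocked)
        assert asg.bins[BIN2[0]] == asg.bins[BIN2[3]]

    def test_permutation_invariance(self):
        m = competition_fixture()
        ref = A.assign_bins(A.binarize_competition(m, 0.30)).bins
        rng = np.random.default_rng(0)
        for _ in range(3):
            rows = list(m.index)
            cols = list(m.columns)
            rng.shuffle(rows)
            rng.shuffle(cols)
            perm = A.assign_bins(A.binarize_competition(m.loc[rows, cols],
                                                        0.30)).bins
            assert perm == ref

    def test_symmetrization_by_or(self):
        # asymmetric observation: blocking seen in one orientation only
        names = ["x", "y"]
        m = pd.DataFrame([[0.05, 0.05], [0.95, 0.05]],
                         index=names, columns=names)
        asg = A.assign_bins(A.binarize_competition(m, 0.30))
        assert asg.n_bins == 1


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t statistic."""
    a, b = np.asarray(a), np.asarray(b)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestFootprint:
    BOUND = [0.10, 0.11, 0.09, 0.10]
    UNBOUND = [0.20, 0.21, 0.19, 0.20]

    def test_modification_fraction(self):
        assert A.modification_fraction(25, 100) == 0.25
        assert A.modification_fraction(100, 100) == 1.0
        assert A.modification_fraction(0, 100) == 0.0

    def test_modification_fraction_errors(self):
        with pytest.raises(ValueError):
            A.modification_fraction(1, 0)
        with pytest.raises(ValueError):
            A.modification_fraction(5, 4)

    def test_protection_call_with_t_oracle(self):
        res = A.footprint_test(self.BOUND, self.UNBOUND, alpha=0.05)
        assert res.percent_fold_change == pytest.approx(-50.0, abs=1e-9)
        assert res.call == "protected"
        assert res.t_statistic == pytest.approx(
            pooled_t_oracle(self.BOUND, self.UNBOUND), abs=1e-9)
        assert res.p_value < 0.05

    def test_identical_samples_unchanged(self):
        res = A.footprint_test([0.1, 0.2, 0.15], [0.1, 0.2, 0.15])
        assert res.percent_fold_change == 0.0 and res.call == "unchanged"

    def test_deprotection_direction(self):
        res = A.footprint_test(self.UNBOUND, self.BOUND)
        assert res.percent_fold_change > 0 and res.call == "deprotected"

    def test_swapping_states_negates_percent_and_preserves_p(self):
        fwd = A.footprint_test(self.BOUND, self.UNBOUND)
        rev = A.footprint_test(self.UNBOUND, self.BOUND)
        # -50% maps to +100%: signs flip, magnitude follows the new baseline
        assert math.copysign(1, fwd.percent_fold_change) == -math.copysign(
            1, rev.percent_fold_change)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_replicate_minimum(self):
        with pytest.raises(ValueError, match="replicates"):
            A.footprint_test([0.1], self.UNBOUND)

    def test_zero_unbound_mean_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            A.footprint_test([0.1, 0.2], [0.0, 0.0])

    def test_footprint_table_with_bh(self):
        rows = []
        for pid, (b, u) in {"p1": (self.BOUND, self.UNBOUND),
                            "p2": (self.UNBOUND, self.BOUND)}.items():
            for i, v in enumerate(b):
                rows.append({"peptide_id": pid, "state": "bound",
                             "replicate": i, "xic_modified": v * 100,
                             "xic_total": 100})
            for i, v in enumerate(u):
                rows.append({"peptide_id": pid, "state": "unbound",
                             "replicate": i, "xic_modified": v * 100,
                             "xic_total": 100})
        out = A.footprint_table(pd.DataFrame(rows), bh_correct=True)
        assert set(out["call"]) == {"protected", "deprotected"}
        assert "p_adjusted" in out


class TestTgi:
    def test_no_treated_growth_is_full_inhibition(self):
        assert A.compute_tgi(100, 100, 100, 1000) == pytest.approx(100.0)

    def test_equal_growth_is_zero(self):
        assert A.compute_tgi(100, 550, 100, 550) == pytest.approx(0.0)

    def test_half_growth_is_fifty(self):
        assert A.compute_tgi(100, 550, 100, 1000) == pytest.approx(50.0)

    def test_control_unchanged_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            A.compute_tgi(100, 200, 300, 300)

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_under_rescaling(self, c):
        base = A.compute_tgi(100, 550, 100, 1000)
        scaled = A.compute_tgi(100 * c, 550 * c, 100 * c, 1000 * c)
        assert scaled == pytest.approx(base, abs=1e-6)
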