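"""SRT scoring, grouping, RM-ANOVA, change rates and consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wmentropy as wm
from wmentropy.errors import (
    DegenerateInputError,
    EmptyInputError,
    PairingError,
    UndefinedChangeError,
)


def trials(rows):
    return pd.DataFrame(rows, columns=["accuracy", "rt", "mt"])


class TestSRT:
    def test_correct_trial_earns_residual_time(self):
        assert wm.srt_score(trials([(1, 0.5, 2.0)])) == pytest.approx(1.5)

    def test_incorrect_trial_loses_residual_time(self):
        assert wm.srt_score(trials([(0, 0.5, 2.0)])) == pytest.approx(-1.5)

    def test_hand_summation(self):
        t = trials([(1, 1.0, 3.0), (0, 2.5, 3.0), (1, 2.9, 3.0)])
        assert wm.srt_score(t) == pytest.approx(2.0 - 0.5 + 0.1)

    def test_non_response_contributes_zero(self):
        t = trials([(1, np.nan, 3.0), (1, 1.0, 3.0)])
        assert wm.srt_score(t) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            wm.srt_score(trials([]))

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 1),
                st.floats(0.0, 3.0),
            ),
            min_size=1,
            max_size=30,
        ),
        st.integers(1, 29),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_additivity_and_bounds(self, rows, split):
        t = trials([(a, r, 3.0) for a, r in rows])
        total = wm.srt_score(t)
        k = min(split, len(t) - 1) if len(t) > 1 else None
        if k:
            assert total == pytest.approx(
                wm.srt_score(t.iloc[:k]) + wm.srt_score(t.iloc[k:])
            )
        assert abs(total) <= t.mt.sum() + 1e-9


class TestGrouping:
    def scores(self, values, session=1):
        return pd.DataFrame(
            {"subject": range(1, len(values) + 1), "session": session, "srt": values}
        )

    def test_three_subject_example(self):
        out = wm.zscore_group(self.scores([1.0, 2.0, 3.0]))
        assert np.allclose(out.z, [-1, 0, 1])
        assert list(out.group) == ["low", "low", "high"]  # z = 0 is low (strict >)

    def test_symmetric_scores_give_symmetric_z(self):
        out = wm.zscore_group(self.scores([-5.0, -1.0, 1.0, 5.0]))
        assert np.allclose(np.sort(out.z), -np.sort(out.z)[::-1])

    def test_moments(self, rng):
        out = wm.zscore_group(self.scores(rng.normal(size=20)))
        assert abs(out.z.mean()) < 1e-12
        assert abs(out.z.std(ddof=1) - 1.0) < 1e-12

    def test_affine_invariance(self, rng):
        x = rng.normal(size=12)
        a = wm.zscore_group(self.scores(x))
        b = wm.zscore_group(self.scores(3.7 * x + 11.0))
        assert np.allclose(a.z, b.z)
        assert list(a.group) == list(b.group)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            wm.zscore_group(self.scores([2.0, 2.0, 2.0]))


def balanced_cells(rng, n_subjects=4):
    rows = []
    for s in range(1, n_subjects + 1):
        for hand in ("left", "right"):
            for load in (2, 4, 8):
                rows.append(
                    {
                        "subject": s,
                        "hand": hand,
                        "load": load,
                        "value": rng.normal() + 0.4 * np.log2(load),
                    }
                )
    return pd.DataFrame(rows)


def anova_ss_oracle(cells):
    """Textbook sums-of-squares decomposition for a two-way within design."""
    y = (
        cells.pivot_table(index="subject", columns=["hand", "load"], values="value")
        .to_numpy()
        .reshape(len(cells.subject.unique()), 2, 3)
    )
    n, A, B = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = n * B * ((m_a - grand) ** 2).sum()
    ss_as = B * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_b = n * A * ((m_b - grand) ** 2).sum()
    ss_bs = A * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_ab = n * (
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()
    f_a = (ss_a / (A - 1)) / (ss_as / ((A - 1) * (n - 1)))
    f_b = (ss_b / (B - 1)) / (ss_bs / ((B - 1) * (n - 1)))
    f_ab = (ss_ab / ((A - 1) * (B - 1))) / (ss_abs / ((A - 1) * (B - 1) * (n - 1)))
    eta = {
        "hand": ss_a / (ss_a + ss_as),
        "load": ss_b / (ss_b + ss_bs),
        "handxload": ss_ab / (ss_ab + ss_abs),
    }
    return {"hand": f_a, "load": f_b, "handxload": f_ab}, eta


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        cells = balanced_cells(rng)
        table = wm.rm_anova_2x3(cells).set_index("effect")
        f_oracle, eta_oracle = anova_ss_oracle(cells)
        for effect in ("hand", "load", "handxload"):
            assert table.loc[effect, "F"] == pytest.approx(
                f_oracle[effect], abs=1e-9
            )
            assert table.loc[effect, "partial_eta_sq"] == pytest.approx(
                eta_oracle[effect], abs=1e-9
            )

    def test_two_level_factor_is_spherical(self, rng):
        table = wm.rm_anova_2x3(balanced_cells(rng)).set_index("effect")
        assert table.loc["hand", "gg_epsilon"] == 1.0

    def test_identical_cells_give_zero_f(self):
        rows = []
        for s in range(1, 5):
            for hand in ("left", "right"):
                for load in (2, 4, 8):
                    rows.append(
                        {"subject": s, "hand": hand, "load": load, "value": float(s)}
                    )
        table = wm.rm_anova_2x3(pd.DataFrame(rows))
        assert (table.F == 0).all()
        assert (table.p == 1).all()

    def test_missing_cell_rejected(self, rng):
        cells = balanced_cells(rng).iloc[:-1]
        with pytest.raises(PairingError):
            wm.rm_anova_2x3(cells)

    def test_load_effect_detected_in_generated_behavior(self, cohort16):
        _, _, behavior, _ = cohort16
        cells = wm.cell_scores(behavior[behavior.session == 1])
        table = wm.rm_anova_2x3(cells).set_index("effect")
        assert table.loc["load", "p"] < 0.001  # load strongly affects scores
        assert table.loc["load", "partial_eta_sq"] > 0.3


class TestChangeRate:
    def test_no_change_is_zero(self):
        assert wm.change_rate(5.0, 5.0) == 0.0

    def test_doubling_example(self):
        assert wm.change_rate(1.0, 3.0) == pytest.approx(100.0)

    @given(
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=0.1, max_value=100.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert wm.change_rate(a, b) == pytest.approx(-wm.change_rate(b, a))

    def test_zero_sum_rejected(self):
        with pytest.raises(UndefinedChangeError):
            wm.change_rate(-2.0, 2.0)


class TestConsistency:
    def tables(self, srt1, srt2, sen1, sen2):
        n = len(srt1)
        scores = pd.DataFrame(
            {
                "subject": list(range(1, n + 1)) * 2,
                "session": [1] * n + [2] * n,
                "srt": list(srt1) + list(srt2),
            }
        )
        feats = pd.DataFrame(
            {
                "subject": list(range(1, n + 1)) * 2,
                "session": [1] * n + [2] * n,
                "channel": "FC4",
                "sen": list(sen1) + list(sen2),
            }
        )
        return scores, feats

    def test_all_improving_all_consistent(self):
        scores, feats = self.tables([1, 2, 3], [2, 3, 4], [1.0, 1.1, 1.2], [1.1, 1.2, 1.3])
        rep = wm.consistency_report(scores, feats, "FC4")
        assert rep.counts == {
            "increased": 3, "decreased": 0, "consistent": 3, "inconsistent": 0,
        }

    def test_sign_mismatch_counted_inconsistent(self):
        scores, feats = self.tables([1, 2], [2, 3], [1.0, 1.2], [1.1, 1.1])
        rep = wm.consistency_report(scores, feats, "FC4")
        assert rep.counts["inconsistent"] == 1
        assert not rep.table.loc[rep.table.subject == 2, "consistent"].iloc[0]

    def test_zero_change_flagged_inconsistent(self):
        scores, feats = self.tables([1, 2], [2, 3], [1.0, 1.1], [1.1, 1.1])
        rep = wm.consistency_report(scores, feats, "FC4")
        assert rep.zero_flagged == [2]
        assert rep.counts["inconsistent"] == 1

    def test_missing_session_rejected(self):
        scores, feats = self.tables([1, 2], [2, 3], [1.0, 1.1], [1.1, 1.2])
        broken = scores[~((scores.subject == 1) & (scores.session == 2))]
        with pytest.raises(PairingError):
            wm.consistency_report(broken, feats, "FC4")
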