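"""Aligned rank transform ANOVA, ART-C contrasts, chi-square plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from microstates.stats import (
    ARTDesign,
    Contrast,
    art_align_and_rank,
    art_anova,
    art_c_contrasts,
    chi_square_table,
)

TEMPLATES = ("A", "B", "C", "D")


def make_table(n_subj=12, conditions=("pre", "post"), targets=TEMPLATES,
               seed=0, effect_fn=None):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for c in conditions:
            for t in targets:
                mu = effect_fn(c, t) if effect_fn else 0.0
                rows.append({"subject": s, "condition": c, "target": t,
                             "value": mu + rng.standard_normal()})
    return pd.DataFrame(rows)


DESIGN = ARTDesign(response="value",
                   factors={"condition": ("pre", "post"), "target": TEMPLATES})


class TestAlignAndRank:
    def test_constant_data_all_midranks(self):
        df = make_table(n_subj=4)
        df["value"] = 5.0
        ranks = art_align_and_rank(df, DESIGN, ("condition",))
        assert np.all(ranks == (len(df) + 1) / 2.0)

    def test_single_factor_art_equals_plain_rank_anova(self):
        """With one factor there is nothing to strip: ART == rank ANOVA."""
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "condition": ["pre", "post"] * 10,
            "value": rng.standard_normal(20),
        })
        design = ARTDesign(response="value",
                           factors={"condition": ("pre", "post")})
        res = art_anova(df, design)
        ranks = sps.rankdata(df["value"])
        pre = ranks[(df["condition"] == "pre").to_numpy()]
        post = ranks[(df["condition"] == "post").to_numpy()]
        f_direct = sps.f_oneway(pre, post)
        assert res.table["F"].iloc[0] == pytest.approx(f_direct.statistic)
        assert res.table["p"].iloc[0] == pytest.approx(f_direct.pvalue)

    def test_non_target_effects_sum_to_zero_within_levels(self):
        df = make_table(seed=9, effect_fn=lambda c, t: 2.0 * (c == "post")
                        + {"A": 0, "B": 1, "C": 2, "D": 3}[t])
        y = df["value"].to_numpy()
        cell = df.groupby(["condition", "target"])["value"].transform("mean")
        aligned = (y - cell.to_numpy())  # residual part
        # full aligned response for the condition effect
        cond_mean = df.groupby("condition")["value"].transform("mean")
        grand = y.mean()
        full_aligned = aligned + (cond_mean.to_numpy() - grand)
        for t in TEMPLATES:
            sel = (df["target"] == t).to_numpy()
            assert abs(full_aligned[sel].sum()) < 1e-9

    def test_missing_cell_reported(self):
        df = make_table(n_subj=3)
        df = df[~((df["condition"] == "post") & (df["target"] == "D"))]
        with pytest.raises(ValueError, match="empty cells"):
            art_align_and_rank(df, DESIGN, ("condition",))

    def test_rank_order_invariance_to_monotone_transform(self):
        df = make_table(seed=4)
        df2 = df.copy()
        df2["value"] = np.exp(df2["value"])  # strictly monotone
        r1 = art_anova(df.assign(value=sps.rankdata(df["value"])), DESIGN)
        r2 = art_anova(df2.assign(value=sps.rankdata(df2["value"])), DESIGN)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestArtAnova:
    def test_null_calibration_small(self):
        """Type-I rate of the Condition effect near nominal alpha."""
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            df = make_table(n_subj=27, seed=3000 + i)
            res = art_anova(df, DESIGN, effects=[("condition",)])
            rejections += res.table["p"].iloc[0] <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_condition_effect_detected(self):
        df = make_table(n_subj=27, seed=1,
                        effect_fn=lambda c, t: 1.0 * (c == "post"))
        res = art_anova(df, DESIGN, effects=[("condition",)])
        assert res.table["p"].iloc[0] < 0.001

    def test_paper_scale_denominator_dfs(self):
        """27 subjects x 2 conditions x 4 templates reproduces df2 = 208,
        and the Side-augmented / pairs designs give 200, 312, 300."""
        from microstates.experiments import art_df_experiment
        dfs = art_df_experiment()
        assert dfs == {
            "df_denominator_metrics": 208,
            "df_denominator_metrics_side": 200,
            "df_denominator_pairs": 312,
            "df_denominator_pairs_side": 300,
        }

    def test_unknown_factor_level_rejected(self):
        df = make_table(n_subj=3)
        df.loc[0, "condition"] = "mid"
        with pytest.raises(ValueError, match="unlisted"):
            art_anova(df, DESIGN)


class TestArtCContrasts:
    def test_bonferroni_arithmetic_and_monotonicity(self):
        df = make_table(n_subj=27, seed=2,
                        effect_fn=lambda c, t: (c == "post") * (t in "BD") * -2.0)
        contrasts = [Contrast(("pre", t), ("post", t)) for t in TEMPLATES]
        ct = art_c_contrasts(df, DESIGN, ("condition", "target"), contrasts)
        np.testing.assert_allclose(
            ct["p_adj"], np.minimum(1.0, 4 * ct["p_raw"]))
        assert (ct["p_adj"] >= ct["p_raw"]).all()

    def test_selective_detection_of_planted_contrasts(self):
        df = make_table(n_subj=27, seed=8,
                        effect_fn=lambda c, t: (c == "post") * (t in "BD") * -2.0)
        contrasts = [Contrast(("pre", t), ("post", t)) for t in TEMPLATES]
        ct = art_c_contrasts(df, DESIGN, ("condition", "target"), contrasts)
        sig = {TEMPLATES[i] for i in ct.index if ct.loc[i, "p_adj"] <= 0.05}
        assert {"B", "D"} <= sig
        # the planted contrasts dominate the family
        order = ct["p_adj"].to_numpy().argsort()
        assert {TEMPLATES[i] for i in order[:2]} == {"B", "D"}

    def test_absent_level_rejected(self):
        df = make_table(n_subj=4)
        with pytest.raises(ValueError, match="absent cell"):
            art_c_contrasts(df, DESIGN, ("condition", "target"),
                            [Contrast(("pre", "E"), ("post", "E"))])


class TestChiSquare:
    def test_homogeneous_table(self):
        chi2, dof, p = chi_square_table([[5, 5], [5, 5]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_diagonal_table_closed_form(self):
        chi2, dof, p = chi_square_table([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[0, 0], [5, 5]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[1.5, 2], [3, 4]])
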