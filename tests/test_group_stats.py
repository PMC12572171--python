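"""Mann-Whitney U, effect size, BH-FDR and the dose covariate screen, each
checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as st_sci

from eegdfc import (
    effect_size_r,
    fdr_correct,
    mann_whitney_u,
    pearson_screen,
    run_group_analysis,
)
from eegdfc.as_metrics import CUMULANT_NAMES


def brute_force_mw_p(a, b):
    """Exact two-sided p by enumerating every labeling of the pooled data."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(a) + len(b)

    def u_of(idx):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        aa, bb = pooled[sel], pooled[~sel]
        return float(np.sum((aa[:, None] > bb[None, :])
                            + 0.5 * (aa[:, None] == bb[None, :])))

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


def bh_reference(p):
    """Textbook step-up: p * m / rank with cumulative-min enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestMannWhitney:
    def test_separated_samples(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_interleaved_samples_near_null(self):
        U, _ = mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert abs(U - 4.5) <= 1.5  # n1*n2/2 = 4.5

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(6), rng.standard_normal(8)
        U1, p1 = mann_whitney_u(a, b)
        U2, p2 = mann_whitney_u(b, a)
        assert U1 + U2 == pytest.approx(len(a) * len(b))
        assert p1 == pytest.approx(p2)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_enumeration(self):
        """For every partition with n1 + n2 <= 12, the exact p equals full
        enumeration over all labelings."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(n1, 13 - n1):
                a, b = rng.standard_normal(n1), rng.standard_normal(n2)
                _, p = mann_whitney_u(a, b)
                assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(30), rng.standard_normal(30) + 1.0
        _, p = mann_whitney_u(a, b)
        ref = st_sci.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestEffectSize:
    def test_null_center_is_zero(self):
        assert effect_size_r(50.0, 10, 10) == 0.0

    def test_maximal_u_zero(self):
        mu, sd = 50.0, np.sqrt(10 * 10 * 21 / 12)
        expected = (mu / sd) / np.sqrt(20)
        assert effect_size_r(0.0, 10, 10) == pytest.approx(expected)

    def test_swap_invariance(self):
        assert effect_size_r(12.0, 5, 8) == pytest.approx(
            effect_size_r(5 * 8 - 12.0, 8, 5))

    def test_all_tied_raises(self):
        with pytest.raises(ValueError):
            effect_size_r(4.5, 3, 3, pooled=np.ones(6))


class TestFdr:
    def test_textbook_example(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.integers(0, 1000))
    def test_matches_step_up_reference(self, ps, seed):
        """BH-adjusted values equal the independent step-up formula."""
        rng = np.random.default_rng(seed)
        p = np.concatenate([ps, rng.uniform(size=5)])
        assert np.allclose(fdr_correct(p), bh_reference(p), atol=1e-12)

    def test_families_adjusted_separately(self):
        p = [0.01, 0.02, 0.03, 0.04]
        fam = ["x", "x", "y", "y"]
        joint = fdr_correct(p)
        split = fdr_correct(p, family=fam)
        assert np.allclose(joint, 0.04)
        assert np.allclose(split[:2], bh_reference(p[:2]))
        assert np.allclose(split[2:], bh_reference(p[2:]))
        assert not np.allclose(joint, split)


def metric_frame(values_by_band, subject_ids, dose=None, group="SCZ"):
    rows = []
    for band, vals in values_by_band.items():
        for sid, v in zip(subject_ids, vals):
            row = {"subject_id": sid, "group": group, "band": band}
            row.update({m: v for m in CUMULANT_NAMES})
            rows.append(row)
    table = pd.DataFrame(rows)
    if dose is not None:
        table["chlorpromazine_equivalent"] = table["subject_id"].map(dose)
    return table


class TestPearsonScreen:
    def test_perfect_positive_and_negative(self):
        sids = [f"S{i}" for i in range(6)]
        vals = np.arange(6.0)
        table = metric_frame({"alpha": vals}, sids,
                             dose={s: float(i) for i, s in enumerate(sids)})
        out = pearson_screen(table, "chlorpromazine_equivalent")
        assert np.allclose(out["rho"], 1.0)
        table["chlorpromazine_equivalent"] *= -1
        out = pearson_screen(table, "chlorpromazine_equivalent")
        assert np.allclose(out["rho"], -1.0)

    def test_zero_variance_raises(self):
        sids = [f"S{i}" for i in range(5)]
        table = metric_frame({"alpha": np.ones(5)}, sids,
                             dose={s: float(i) for i, s in enumerate(sids)})
        with pytest.raises(ValueError):
            pearson_screen(table, "chlorpromazine_equivalent")

    def test_null_type_one_error_rate(self):
        """With metric independent of dose (n = 11), p < 0.05 in ~5% of
        1000 Monte-Carlo repetitions."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x, y = rng.standard_normal(11), rng.standard_normal(11)
            hits += st_sci.pearsonr(x, y).pvalue < 0.05
        assert 0.03 < hits / n_rep < 0.07


class TestRunGroupAnalysis:
    @staticmethod
    def cohort_table(rng, n_hc=10, n_scz=11, shift=0.0, dose=False):
        rows = []
        for band in ("delta", "theta", "alpha", "beta", "gamma"):
            for g, n, s in (("HC", n_hc, 0.0), ("SCZ", n_scz, shift)):
                for i in range(n):
                    row = {"subject_id": f"{g}{i}", "group": g, "band": band}
                    for m in CUMULANT_NAMES:
                        row[m] = rng.standard_normal() + (s if m == "mu" else 0)
                    if dose and g == "SCZ":
                        row["chlorpromazine_equivalent"] = rng.uniform(100, 900)
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_comparison_count(self, rng):
        res = run_group_analysis(self.cohort_table(rng), control="HC")
        assert len(res["comparisons"]) == 20  # 5 bands x 4 cumulants

    def test_effect_size_and_fdr_columns(self, rng):
        res = run_group_analysis(self.cohort_table(rng, shift=3.0), control="HC")
        c = res["comparisons"]
        assert ((c["r"] >= 0) & (c["r"] <= 1)).all()
        assert ((c["p_fdr"] >= 0) & (c["p_fdr"] <= 1)).all()
        mu_rows = c[c["cumulant"] == "mu"]
        assert (mu_rows["significance"] == "significant").all()

    def test_dose_screen_attached_for_patients_only(self, rng):
        res = run_group_analysis(self.cohort_table(rng, dose=True), control="HC")
        assert set(res["covariate_screens"]) == {"SCZ"}
        screen = res["covariate_screens"]["SCZ"]
        assert len(screen) == 20

    def test_missing_control_raises(self, rng):
        with pytest.raises(ValueError):
            run_group_analysis(self.cohort_table(rng), control="XX")
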