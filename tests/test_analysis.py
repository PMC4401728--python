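"""The signal-detection statistics, ANOVA machinery, and strategy
diagnostics, cross-checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from agl import (DependencyType, SDTCounts, SimulantConfig,
                 binomial_strategy_tests, block_counts, block_split, dprime,
                 full_report, independent_t, length_counts, mixed_anova_gg,
                 one_sample_t, simulate_cohort, simulate_guesser,
                 simulate_sdt_learner, simulate_strategist, tally_counts)
from agl.errors import AlignmentError, ConfigError

NESTED = DependencyType.NESTED


# -- d' ---------------------------------------------------------------------

def test_equal_counts_give_zero_dprime():
    for k in (1, 7, 60):
        assert dprime(SDTCounts(k, k, k, k)).d_prime == pytest.approx(0.0)


def test_dprime_frozen_quantile_values():
    # Phi^-1(90.5/121) - Phi^-1(30.5/121) and the perfect-responder value
    assert dprime(SDTCounts(90, 30, 30, 90)).d_prime == pytest.approx(1.336004264539147)
    assert dprime(SDTCounts(120, 0, 0, 120)).d_prime == pytest.approx(5.2821401136498745)


def test_dprime_antisymmetric_under_label_swap():
    rng = np.random.default_rng(0)
    for _ in range(50):
        h, m, fa, cr = rng.integers(0, 120, size=4)
        fwd = dprime(SDTCounts(h, m, fa, cr)).d_prime
        rev = dprime(SDTCounts(m, h, cr, fa)).d_prime
        assert fwd == pytest.approx(-rev)


def test_dprime_rejects_empty_margin_without_correction():
    with pytest.raises(ConfigError):
        dprime(SDTCounts(0, 0, 0, 0), cell_correction=0.0)


def test_correction_applied_unconditionally():
    # the 0.5 is added even when no cell is zero
    res = dprime(SDTCounts(90, 30, 30, 90))
    assert res.hit_rate == pytest.approx(90.5 / 121)
    assert res.fa_rate == pytest.approx(30.5 / 121)


# -- tallies and partitions -------------------------------------------------

def test_perfect_responder_tally(exp2_nested):
    log = simulate_sdt_learner(
        exp2_nested, SimulantConfig(policy="sdt_learner", sensitivity=100.0, seed=0))
    c = tally_counts(log, exp2_nested)
    assert (c.hits, c.misses, c.false_alarms, c.correct_rejections) == (120, 0, 0, 120)


def test_strategist_restricted_tallies(exp2_nested):
    log = simulate_strategist(exp2_nested, "first")
    s2 = tally_counts(log, exp2_nested, "S2")
    s1 = tally_counts(log, exp2_nested, "S1")
    assert (s2.hits, s2.misses, s2.false_alarms, s2.correct_rejections) == (120, 0, 40, 0)
    assert (s1.hits, s1.misses, s1.false_alarms, s1.correct_rejections) == (120, 0, 0, 40)


def test_block_split_sizes():
    assert [len(b) for b in block_split(360)] == [120, 120, 120]
    assert [len(b) for b in block_split(240)] == [80, 80, 80]
    with pytest.raises(ConfigError):
        block_split(100)


def test_partitions_conserve_totals(exp1_nested):
    log = simulate_sdt_learner(
        exp1_nested, SimulantConfig(policy="sdt_learner", sensitivity=1.0, seed=4))
    total = tally_counts(log, exp1_nested)
    for parts in (block_counts(log, exp1_nested),
                  list(length_counts(log, exp1_nested).values())):
        summed = SDTCounts()
        for c in parts:
            summed = summed + c
        assert summed == total


def test_length_cells_are_120_trials_each(exp1_nested):
    log = simulate_sdt_learner(
        exp1_nested, SimulantConfig(policy="sdt_learner", sensitivity=1.0, seed=4))
    cells = length_counts(log, exp1_nested)
    assert set(cells) == {"short", "medium", "long"}
    for c in cells.values():
        assert c.n_correct_trials == 60 and c.n_incorrect_trials == 60


def test_misaligned_log_raises(exp1_nested, exp2_nested):
    log = simulate_guesser(exp2_nested, SimulantConfig(policy="guesser", seed=0))
    with pytest.raises(AlignmentError):
        tally_counts(log, exp1_nested)


# -- t-tests ----------------------------------------------------------------

def test_one_sample_t_hand_computed():
    res = one_sample_t([1.0, 2.0, 3.0])  # mean 2, sd 1 -> t = 2*sqrt(3)
    assert res.t == pytest.approx(2 * np.sqrt(3))
    assert res.df == 2
    assert res.cohens_d == pytest.approx(2.0)


def test_one_sample_t_symmetric_values():
    res = one_sample_t([-1.0, 0.0, 1.0])
    assert res.t == pytest.approx(0.0)
    assert res.cohens_d == pytest.approx(0.0)


def test_t_df_conventions():
    rng = np.random.default_rng(1)
    assert one_sample_t(rng.normal(size=15)).df == 14
    assert independent_t(rng.normal(size=15), rng.normal(size=15)).df == 28
    assert independent_t(rng.normal(size=20), rng.normal(size=20)).df == 38


def test_independent_t_identical_groups():
    res = independent_t([1.0, 2.0, 3.0, 2.5], [1.0, 2.0, 3.0, 2.5])
    assert res.t == pytest.approx(0.0)


def test_zero_variance_rejected():
    with pytest.raises(ConfigError):
        one_sample_t([1.0, 1.0, 1.0])


# -- mixed ANOVA with GG correction -----------------------------------------

def _naive_mixed_anova(y, groups):
    """Independent sums-of-squares oracle written directly from cell means,
    plus the Greenhouse-Geisser epsilon from the pooled within-group
    covariance, composed entry by entry."""
    y = np.asarray(y, float)
    glabels = np.unique(groups)
    a, k = len(glabels), y.shape[1]
    n = y.shape[0] // a
    grand = y.mean()
    ss = {"between": 0.0, "within": 0.0, "inter": 0.0, "subj_err": 0.0, "win_err": 0.0}
    for g in glabels:
        yg = y[np.asarray(groups) == g]
        ss["between"] += k * n * (yg.mean() - grand) ** 2
        for row in yg:
            ss["subj_err"] += k * (row.mean() - yg.mean()) ** 2
    for j in range(k):
        ss["within"] += a * n * (y[:, j].mean() - grand) ** 2
    for g in glabels:
        yg = y[np.asarray(groups) == g]
        for j in range(k):
            ss["inter"] += n * (yg[:, j].mean() - yg.mean() - y[:, j].mean() + grand) ** 2
    for g in glabels:
        yg = y[np.asarray(groups) == g]
        for row in yg:
            for j in range(k):
                ss["win_err"] += (row[j] - row.mean() - yg[:, j].mean() + yg.mean()) ** 2
    # pooled covariance epsilon
    s = np.zeros((k, k))
    for g in glabels:
        yg = y[np.asarray(groups) == g]
        d = yg - yg.mean(axis=0)
        s += d.T @ d
    s /= y.shape[0] - a
    num = (k * (np.trace(s) / k - s.mean())) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum()
                     + k ** 2 * s.mean() ** 2)
    eps = min(max(num / den, 1 / (k - 1)), 1.0)
    return ss, eps


def test_all_equal_cells_give_zero_f():
    y = np.full((10, 3), 2.5)
    y += np.arange(10)[:, None] * 0.1  # subject offsets only
    tab = mixed_anova_gg(y, ["a"] * 5 + ["b"] * 5)
    assert tab.within.f == pytest.approx(0.0)
    assert tab.interaction.f == pytest.approx(0.0)
    assert tab.within.partial_eta_sq == pytest.approx(0.0)


def test_two_within_levels_have_epsilon_one():
    rng = np.random.default_rng(2)
    tab = mixed_anova_gg(rng.normal(size=(12, 2)), ["a"] * 6 + ["b"] * 6)
    assert tab.within.gg_epsilon == 1.0
    assert tab.within.df1_gg == tab.within.df1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_anova_agrees_with_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    n, k = 14, 3
    y = rng.normal(size=(2 * n, k)) + 0.7 * rng.normal(size=(2 * n, 1))
    y[:, 1] += 0.3  # some within effect
    y[n:] += 0.2    # some between effect
    groups = np.array(["a"] * n + ["b"] * n)
    tab = mixed_anova_gg(y, groups)
    ss, eps = _naive_mixed_anova(y, groups)
    assert tab.between.ss == pytest.approx(ss["between"], abs=1e-8)
    assert tab.within.ss == pytest.approx(ss["within"], abs=1e-8)
    assert tab.interaction.ss == pytest.approx(ss["inter"], abs=1e-8)
    assert tab.within.df2 * (tab.within.ss / tab.within.df1 / tab.within.f) == \
        pytest.approx(ss["win_err"], abs=1e-8)
    assert tab.within.gg_epsilon == pytest.approx(eps, abs=1e-8)
    assert tab.within.df1_gg == pytest.approx(eps * (k - 1), abs=1e-8)


@pytest.mark.parametrize("seed", [3, 4])
def test_anova_agrees_with_pingouin(seed):
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(seed)
    n, k = 10, 3
    y = rng.normal(size=(2 * n, k)) + rng.normal(size=(2 * n, 1))
    groups = np.array(["a"] * n + ["b"] * n)
    tab = mixed_anova_gg(y, groups, within_name="w", between_name="g")
    long = pd.DataFrame({"dv": y.ravel(),
                         "subj": np.repeat(np.arange(2 * n), k),
                         "w": np.tile(np.arange(k), 2 * n),
                         "g": np.repeat(groups, k)})
    ptab = pg.mixed_anova(long, dv="dv", within="w", subject="subj",
                          between="g").set_index("Source")
    for src, eff in (("g", tab.between), ("w", tab.within),
                     ("Interaction", tab.interaction)):
        assert eff.ss == pytest.approx(ptab.loc[src, "SS"], abs=1e-8)
        assert eff.f == pytest.approx(ptab.loc[src, "F"], abs=1e-8)
        assert eff.p == pytest.approx(ptab.loc[src, "p_unc"], abs=1e-8)
        assert eff.partial_eta_sq == pytest.approx(ptab.loc[src, "np2"], abs=1e-8)


def test_unbalanced_groups_rejected():
    with pytest.raises(ConfigError):
        mixed_anova_gg(np.zeros((5, 3)), ["a", "a", "a", "b", "b"])


# -- strategy diagnostics ---------------------------------------------------

def test_strategist_flagged_with_extreme_p(exp2_nested):
    log = simulate_strategist(exp2_nested, "first")
    flags = binomial_strategy_tests(log, exp2_nested)
    assert flags.first_pair_flag and not flags.last_pair_flag
    assert flags.p_values["S2"] == pytest.approx(2.0 ** -40)
    assert flags.yes_counts == {"S1": 0, "S2": 40, "S3": 0}
    assert not flags.yes_biased


def test_all_no_responder_not_flagged(exp2_nested):
    log = simulate_sdt_learner(
        exp2_nested, SimulantConfig(policy="sdt_learner", criterion=50.0, seed=0))
    flags = binomial_strategy_tests(log, exp2_nested)
    assert not flags.any_strategy and not flags.yes_biased


def test_strategy_tests_require_foil_design(exp1_nested):
    log = simulate_strategist(exp1_nested, "first")
    with pytest.raises(ConfigError):
        binomial_strategy_tests(log, exp1_nested)


# -- the full battery -------------------------------------------------------

def test_full_report_learner_cohort_significant():
    cohort = simulate_cohort(2, 20, SimulantConfig(policy="sdt_learner",
                                                   sensitivity=1.2),
                             master_seed=21)
    rep = full_report(cohort.logs, cohort.designs)
    for g in ("nested", "cross_serial"):
        assert rep.overall["one_sample"][g]["p"] < 0.001
        assert rep.overall["one_sample"][g]["df"] == 19
        assert rep.strategy["one_sample_d_first"][g]["p"] < 0.001
    assert rep.overall["between"]["df"] == 38
    assert rep.strategy["flagged"] == []
    assert rep.rerun_excluding_flagged["n_excluded"] == 0


def test_full_report_flags_embedded_strategist():
    mix = [SimulantConfig(policy="sdt_learner", sensitivity=1.2),
           SimulantConfig(policy="first_pair_strategist")]
    cohort = simulate_cohort(2, 6, mix, master_seed=5)
    rep = full_report(cohort.logs, cohort.designs)
    strategists = {l.participant_id for l in cohort.logs
                   if l.policy == "first_pair_strategist"}
    assert set(rep.strategy["flagged"]) == strategists
    assert rep.rerun_excluding_flagged["n_excluded"] == len(strategists)


def test_full_report_exp1_has_length_battery():
    cohort = simulate_cohort(1, 4, SimulantConfig(policy="sdt_learner",
                                                  sensitivity=1.0),
                             master_seed=13)
    rep = full_report(cohort.logs, cohort.designs)
    assert set(rep.lengths["anova"]) == {"group", "length", "group x length"}
    assert set(rep.lengths["follow_up_2x2"]) == {"short_vs_medium",
                                                 "short_vs_long",
                                                 "medium_vs_long"}
    assert set(rep.blocks["follow_up_2x2"]) == {"block1_vs_block2",
                                                "block1_vs_block3",
                                                "block2_vs_block3"}
    # 2x2 follow-ups are exempt from sphericity correction
    for tab in rep.blocks["follow_up_2x2"].values():
        assert tab["block"]["gg_epsilon"] == 1.0
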