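"""Signal-detection and strategy-diagnostic analysis of response logs.

The battery mirrors a standard auditory grammaticality-judgment analysis:

* per-participant sensitivity d' = Phi^-1(H) - Phi^-1(F) with 0.5 added to
  every one of hits/misses/false alarms/correct rejections before the
  rates are formed (applied unconditionally, for all participants);
  criterion c = -(Phi^-1(H) + Phi^-1(F))/2;
* d' per test block (three equal consecutive thirds of each participant's
  presentation order) and, for the three-length design, per sequence
  length;
* one-sample t-tests of group d' against zero with Cohen's d, and a
  pooled-variance independent-samples t between groups;
* 2 x 3 mixed ANOVAs (between: dependency group; within: block or length)
  with Greenhouse-Geisser correction and partial eta squared;
* strategy diagnostics for the foil-subset design: d'_first / d'_last
  (false-alarm rate restricted to the S2 / S3 foils), and per-participant
  one-sided exact binomial tests of yes-counts against 0.5 in each foil
  subset, flagging a participant as a first- (last-) pair strategist iff
  S2 (S3) is significant while the yes-bias control S1 is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import FOIL_SUBSETS, ExperimentDesign
from .errors import AlignmentError, ConfigError
from .grammar import DependencyType
from .simulate import ResponseLog


# ---------------------------------------------------------------------------
# counts and d'


@dataclass
class SDTCounts:
    hits: int = 0
    misses: int = 0
    false_alarms: int = 0
    correct_rejections: int = 0

    @property
    def n_correct_trials(self) -> int:
        return self.hits + self.misses

    @property
    def n_incorrect_trials(self) -> int:
        return self.false_alarms + self.correct_rejections

    def __add__(self, other: "SDTCounts") -> "SDTCounts":
        return SDTCounts(self.hits + other.hits, self.misses + other.misses,
                         self.false_alarms + other.false_alarms,
                         self.correct_rejections + other.correct_rejections)


def _scored(log: ResponseLog, design: ExperimentDesign):
    test = {t.index: t for t in design.test_trials}
    if sorted(r.trial_index for r in log.responses) != sorted(test):
        raise AlignmentError(
            f"log {log.participant_id!r} does not cover the design's test trials")
    return [(test[r.trial_index], r.answer) for r in log.responses]


def tally_counts(log: ResponseLog, design: ExperimentDesign,
                 restrict_foils: str = "all") -> SDTCounts:
    """Hit/miss/FA/CR tallies for one participant.

    Hits and misses always come from all correct trials; with
    ``restrict_foils`` in {S1, S2, S3} the false-alarm side counts only
    that foil subset (the strategy-restricted error rate behind d'_first
    and d'_last).
    """
    if restrict_foils not in ("all",) + FOIL_SUBSETS:
        raise ConfigError(f"restrict_foils must be 'all' or one of {FOIL_SUBSETS}")
    c = SDTCounts()
    for trial, yes in _scored(log, design):
        if trial.label == "correct":
            if yes:
                c.hits += 1
            else:
                c.misses += 1
        else:
            if restrict_foils != "all" and trial.foil_subset != restrict_foils:
                continue
            if yes:
                c.false_alarms += 1
            else:
                c.correct_rejections += 1
    return c


@dataclass
class DPrimeResult:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


def dprime(counts: SDTCounts, cell_correction: float = 0.5) -> DPrimeResult:
    """Corrected sensitivity and criterion.

    ``cell_correction`` is added to each of the four cells before rates are
    formed, keeping both normal quantiles finite even for perfect or empty
    cells.  With correction 0 and an empty margin the rates are undefined
    and a ConfigError is raised.
    """
    c = cell_correction
    n_sig = counts.n_correct_trials + 2 * c
    n_noise = counts.n_incorrect_trials + 2 * c
    if n_sig <= 0 or n_noise <= 0:
        raise ConfigError("undefined rates: empty margin with no cell correction")
    h = (counts.hits + c) / n_sig
    f = (counts.false_alarms + c) / n_noise
    if not (0 < h < 1 and 0 < f < 1):
        raise ConfigError("degenerate corrected rate; increase cell_correction")
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return DPrimeResult(zh - zf, -0.5 * (zh + zf), h, f)


# ---------------------------------------------------------------------------
# partitions


def block_split(n_test_trials: int, n_blocks: int = 3) -> list[range]:
    """Equal consecutive thirds of the test phase, by presentation position."""
    size, rem = divmod(n_test_trials, n_blocks)
    if rem:
        raise ConfigError(f"{n_test_trials} test trials not divisible into {n_blocks} blocks")
    return [range(b * size, (b + 1) * size) for b in range(n_blocks)]


def block_counts(log: ResponseLog, design: ExperimentDesign,
                 n_blocks: int = 3) -> list[SDTCounts]:
    """Per-block tallies using the participant's own presentation order."""
    scored = _scored(log, design)
    out = []
    for blk in block_split(len(scored), n_blocks):
        c = SDTCounts()
        for pos in blk:
            trial, yes = scored[pos]
            if trial.label == "correct":
                c.hits += yes
                c.misses += not yes
            else:
                c.false_alarms += yes
                c.correct_rejections += not yes
        out.append(c)
    return out


def length_counts(log: ResponseLog, design: ExperimentDesign) -> dict[str, SDTCounts]:
    """Tallies per sequence-length class (short/medium/long)."""
    out: dict[str, SDTCounts] = {}
    for trial, yes in _scored(log, design):
        c = out.setdefault(trial.length_class, SDTCounts())
        if trial.label == "correct":
            c.hits += yes
            c.misses += not yes
        else:
            c.false_alarms += yes
            c.correct_rejections += not yes
    return out


# ---------------------------------------------------------------------------
# t-tests


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float | None = None


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """One-sample t against ``mu0``; Cohen's d = (mean - mu0) / sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ConfigError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigError("zero variance")
    res = stats.ttest_1samp(x, mu0)
    return TTestResult(float(res.statistic), float(x.size - 1),
                       float(res.pvalue), float((x.mean() - mu0) / sd))


def independent_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t (df = n1 + n2 - 2)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("need at least 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    s_pool = math.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                       / (a.size + b.size - 2))
    if s_pool == 0:
        raise ConfigError("zero pooled variance")
    d = (a.mean() - b.mean()) / s_pool
    return TTestResult(float(res.statistic), float(a.size + b.size - 2),
                       float(res.pvalue), float(d))


# ---------------------------------------------------------------------------
# mixed ANOVA with Greenhouse-Geisser correction


@dataclass
class AnovaEffect:
    source: str
    ss: float
    df1: float
    df2: float
    f: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None  # within-subject effects only
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None


@dataclass
class AnovaTable:
    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect

    @property
    def effects(self) -> list[AnovaEffect]:
        return [self.between, self.within, self.interaction]


def _gg_epsilon_pooled(y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance
    of the repeated measures (the convention for split-plot designs)."""
    k = y.shape[1]
    if k <= 2:
        return 1.0
    n_total, n_groups = y.shape[0], len(np.unique(groups))
    s = np.zeros((k, k))
    for g in np.unique(groups):
        yg = y[groups == g]
        s += (yg.shape[0] - 1) * np.cov(yg, rowvar=False)
    s /= n_total - n_groups
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((s ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * grand ** 2)
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def mixed_anova_gg(d_matrix: np.ndarray | Sequence[Sequence[float]],
                   between_labels: Sequence,
                   within_name: str = "within",
                   between_name: str = "group") -> AnovaTable:
    """Split-plot (mixed) ANOVA: one between factor, one within factor.

    ``d_matrix`` is participants x within-levels (e.g. d' per block);
    ``between_labels`` assigns each row to a group.  Returns F, p, and
    partial eta squared for the between main effect (error: subjects
    within groups), the within main effect and the interaction (error:
    within x subjects); within-subject effects additionally carry the
    Greenhouse-Geisser epsilon and the epsilon-corrected dfs and p.
    """
    y = np.asarray(d_matrix, dtype=float)
    groups = np.asarray(between_labels)
    if y.ndim != 2 or y.shape[0] != groups.shape[0]:
        raise ConfigError("d_matrix rows must match between_labels")
    levels = np.unique(groups)
    sizes = {g: int((groups == g).sum()) for g in levels}
    if len(set(sizes.values())) != 1 or min(sizes.values()) < 2:
        raise ConfigError(f"unbalanced or degenerate between groups: {sizes}")
    n_total, k = y.shape
    a = len(levels)

    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)
    group_means = np.array([y[groups == g].mean() for g in levels])
    cell_means = np.array([y[groups == g].mean(axis=0) for g in levels])
    n_per = n_total // a

    ss_total = ((y - grand) ** 2).sum()
    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_between = k * n_per * ((group_means - grand) ** 2).sum()
    ss_subj_err = ss_subjects - ss_between
    ss_within_level = n_total * ((level_means - grand) ** 2).sum()
    ss_cells = n_per * ((cell_means - grand) ** 2).sum()
    ss_interaction = ss_cells - ss_between - ss_within_level
    ss_within_err = ss_total - ss_subjects - ss_within_level - ss_interaction

    df_between, df_subj_err = a - 1, n_total - a
    df_within, df_int = k - 1, (a - 1) * (k - 1)
    df_within_err = (n_total - a) * (k - 1)

    def effect(source, ss_eff, df1, ss_err, df2, eps=None):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(f, df1, df2)) if ms_err > 0 else 1.0
        np2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        e = AnovaEffect(source, float(ss_eff), float(df1), float(df2),
                        float(f), p, float(np2))
        if eps is not None:
            e.gg_epsilon = eps
            e.df1_gg = eps * df1
            e.df2_gg = eps * df2
            e.p_gg = float(stats.f.sf(f, e.df1_gg, e.df2_gg)) if ms_err > 0 else 1.0
        return e

    eps = _gg_epsilon_pooled(y, groups)
    return AnovaTable(
        between=effect(between_name, ss_between, df_between, ss_subj_err, df_subj_err),
        within=effect(within_name, ss_within_level, df_within, ss_within_err,
                      df_within_err, eps),
        interaction=effect(f"{between_name} x {within_name}", ss_interaction,
                           df_int, ss_within_err, df_within_err, eps),
    )


# ---------------------------------------------------------------------------
# strategy diagnostics


@lru_cache(maxsize=None)
def _binom_p_greater(k: int, n: int) -> float:
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)


@dataclass
class StrategyFlags:
    yes_counts: dict[str, int]
    n_per_subset: dict[str, int]
    p_values: dict[str, float]
    yes_biased: bool          # S1 significant
    first_pair_flag: bool     # S2 significant and S1 not
    last_pair_flag: bool      # S3 significant and S1 not
    alpha: float

    @property
    def any_strategy(self) -> bool:
        return self.first_pair_flag or self.last_pair_flag


def binomial_strategy_tests(log: ResponseLog, design: ExperimentDesign,
                            alpha: float = 0.05) -> StrategyFlags:
    """Per-participant exact binomial diagnostics on the three foil subsets.

    For each subset the yes-count among its foils is tested one-sided
    against 0.5 (excess yes).  A participant is flagged as using the
    first- (last-) element-pair strategy iff the S2 (S3) test is
    significant while S1 — whose foils satisfy neither shortcut and so
    index a general yes bias — is not.
    """
    if design.experiment != 2:
        raise ConfigError("strategy tests require a foil-subset (experiment 2) design")
    yes = {s: 0 for s in FOIL_SUBSETS}
    n = {s: 0 for s in FOIL_SUBSETS}
    for trial, answer in _scored(log, design):
        if trial.label == "incorrect":
            n[trial.foil_subset] += 1
            yes[trial.foil_subset] += answer
    if any(v == 0 for v in n.values()):
        raise AlignmentError("missing responses for at least one foil subset")
    p = {s: _binom_p_greater(yes[s], n[s]) for s in FOIL_SUBSETS}
    s1_sig = p["S1"] < alpha
    return StrategyFlags(yes, n, p, s1_sig,
                         first_pair_flag=(p["S2"] < alpha and not s1_sig),
                         last_pair_flag=(p["S3"] < alpha and not s1_sig),
                         alpha=alpha)


# ---------------------------------------------------------------------------
# the full battery


LENGTH_ORDER = ("short", "medium", "long")


def participant_measures(logs: Sequence[ResponseLog],
                         designs: dict[DependencyType, ExperimentDesign],
                         cell_correction: float = 0.5,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Flat per-participant table of every derived measure."""
    experiment = next(iter(designs.values())).experiment
    rows = []
    for log in logs:
        design = designs[log.group]
        overall = dprime(tally_counts(log, design), cell_correction)
        row: dict = {"participant_id": log.participant_id,
                     "group": log.group.value, "policy": log.policy,
                     "d_prime": overall.d_prime, "criterion": overall.criterion}
        for b, c in enumerate(block_counts(log, design), start=1):
            row[f"d_block{b}"] = dprime(c, cell_correction).d_prime
        if experiment == 1:
            for lc, c in length_counts(log, design).items():
                row[f"d_{lc}"] = dprime(c, cell_correction).d_prime
        else:
            row["d_first"] = dprime(tally_counts(log, design, "S2"),
                                    cell_correction).d_prime
            row["d_last"] = dprime(tally_counts(log, design, "S3"),
                                   cell_correction).d_prime
            flags = binomial_strategy_tests(log, design, alpha)
            for s in FOIL_SUBSETS:
                row[f"yes_{s}"] = flags.yes_counts[s]
                row[f"p_{s}"] = flags.p_values[s]
            row["yes_biased"] = flags.yes_biased
            row["first_pair_flag"] = flags.first_pair_flag
            row["last_pair_flag"] = flags.last_pair_flag
        rows.append(row)
    return pd.DataFrame(rows)


def _ttest_dict(res: TTestResult) -> dict:
    return {"t": res.t, "df": res.df, "p": res.p, "cohens_d": res.cohens_d}


def _anova_dict(tab: AnovaTable) -> dict:
    out = {}
    for e in tab.effects:
        d = {"SS": e.ss, "df1": e.df1, "df2": e.df2, "F": e.f, "p": e.p,
             "partial_eta_sq": e.partial_eta_sq}
        if e.gg_epsilon is not None:
            d.update({"gg_epsilon": e.gg_epsilon, "df1_gg": e.df1_gg,
                      "df2_gg": e.df2_gg, "p_gg": e.p_gg})
        out[e.source] = d
    return out


@dataclass
class AnalysisReport:
    experiment: int
    measures: pd.DataFrame
    overall: dict
    blocks: dict
    lengths: dict | None = None
    strategy: dict | None = None
    rerun_excluding_flagged: dict | None = None

    def to_dict(self) -> dict:
        out = {"experiment": self.experiment,
               "measures": self.measures.to_dict(orient="records"),
               "overall": self.overall, "blocks": self.blocks}
        if self.lengths is not None:
            out["lengths"] = self.lengths
        if self.strategy is not None:
            out["strategy"] = self.strategy
        if self.rerun_excluding_flagged is not None:
            out["rerun_excluding_flagged"] = self.rerun_excluding_flagged
        return out


def full_report(logs: Sequence[ResponseLog],
                designs: dict[DependencyType, ExperimentDesign],
                cell_correction: float = 0.5,
                alpha: float = 0.05,
                follow_ups: bool = True) -> AnalysisReport:
    """Run the complete battery on a cohort.

    Overall d' tests, block ANOVA, and — for the three-length design —
    the length ANOVA with 2x2 follow-ups; for the foil-subset design the
    strategy-restricted d' tests and per-participant binomial flags, plus
    a rerun of the overall tests excluding flagged participants.
    """
    experiment = next(iter(designs.values())).experiment
    df = participant_measures(logs, designs, cell_correction, alpha)
    if df["group"].nunique() < 1 or df.groupby("group").size().min() < 2:
        raise ConfigError("need at least 2 participants per group")

    block_cols = [c for c in df.columns if c.startswith("d_block")]
    overall = {"one_sample": {g: _ttest_dict(one_sample_t(df.loc[df.group == g, "d_prime"]))
                              for g in sorted(df.group.unique())}}
    groups = sorted(df.group.unique())
    if len(groups) == 2:
        overall["between"] = _ttest_dict(
            independent_t(df.loc[df.group == groups[0], "d_prime"],
                          df.loc[df.group == groups[1], "d_prime"]))
    blocks = {"anova": _anova_dict(mixed_anova_gg(df[block_cols].to_numpy(),
                                                  df["group"].to_numpy(),
                                                  within_name="block"))}
    if follow_ups and experiment == 1:
        fu = {}
        for i in range(len(block_cols)):
            for j in range(i + 1, len(block_cols)):
                fu[f"block{i + 1}_vs_block{j + 1}"] = _anova_dict(
                    mixed_anova_gg(df[[block_cols[i], block_cols[j]]].to_numpy(),
                                   df["group"].to_numpy(), within_name="block"))
        blocks["follow_up_2x2"] = fu

    lengths = strategy = rerun = None
    if experiment == 1:
        cols = [f"d_{lc}" for lc in LENGTH_ORDER if f"d_{lc}" in df.columns]
        lengths = {"anova": _anova_dict(mixed_anova_gg(df[cols].to_numpy(),
                                                       df["group"].to_numpy(),
                                                       within_name="length"))}
        if follow_ups:
            fu = {}
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    fu[f"{cols[i][2:]}_vs_{cols[j][2:]}"] = _anova_dict(
                        mixed_anova_gg(df[[cols[i], cols[j]]].to_numpy(),
                                       df["group"].to_numpy(), within_name="length"))
            lengths["follow_up_2x2"] = fu
    else:
        strategy = {"one_sample_d_first": {}, "one_sample_d_last": {},
                    "flagged": df.loc[df.first_pair_flag | df.last_pair_flag,
                                      "participant_id"].tolist()}
        for g in sorted(df.group.unique()):
            strategy["one_sample_d_first"][g] = _ttest_dict(
                one_sample_t(df.loc[df.group == g, "d_first"]))
            strategy["one_sample_d_last"][g] = _ttest_dict(
                one_sample_t(df.loc[df.group == g, "d_last"]))
        kept = df.loc[~(df.first_pair_flag | df.last_pair_flag)]
        if kept.groupby("group").size().min() >= 2:
            rerun = {"one_sample": {g: _ttest_dict(one_sample_t(kept.loc[kept.group == g, "d_prime"]))
                                    for g in sorted(kept.group.unique())}}
            kg = sorted(kept.group.unique())
            if len(kg) == 2 and all((kept.group == g).sum() >= 2 for g in kg):
                rerun["between"] = _ttest_dict(
                    independent_t(kept.loc[kept.group == kg[0], "d_prime"],
                                  kept.loc[kept.group == kg[1], "d_prime"]))
            rerun["n_excluded"] = int(len(df) - len(kept))

    return AnalysisReport(experiment, df, overall, blocks, lengths, strategy, rerun)
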