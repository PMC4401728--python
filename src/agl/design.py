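"""Trial-list construction for the two grammaticality-judgment experiments.

Experiment 1: 240 learning sequences (80 per length 4/6/8) of the trained
grammar, then 360 test sequences — 180 members of the trained grammar
(correct) and 180 members of the untrained grammar (incorrect), 60 per
length per label, one shared random order.  Experiment 2 keeps the learning
phase and replaces the test phase with 240 medium-length trials: 120
correct and 120 foils in three subsets of 40 built from fixed six-syllable
templates — S1 (untrained-grammar members), S2 (first-element-pair
preserved), S3 (last-element-pair preserved) — so that single-pair
shortcut strategies can be detected instead of rewarded.

A-category syllables are exactly counterbalanced across positions within
each length class (each syllable occupies each A position count/20 times);
the B-part is derived from the A-part by the grammar, so its position
tallies follow as a consequence.  Every sequence occurs at most once across
the whole design.  25% of learning trials are flagged as repeat probes
(alertness checks; recorded, not analyzed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigError, GenerationError
from .grammar import DependencyType, arrange_b_part, dependency_structure, is_member
from .lexicon import Lexicon, load_lexicon

LENGTH_CLASSES = {4: "short", 6: "medium", 8: "long"}

#: Foil templates, per trained grammar and subset: two rows per subset, each
#: an (a_order, b_order) pair of 1-based indices into the chosen pair
#: triple.  Row k of the six incorrect table rows is (subset, variant) =
#: ("S1",0),("S1",1),("S2",0),("S2",1),("S3",0),("S3",1).
FOIL_TEMPLATES: dict[DependencyType, dict[str, tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]]] = {
    DependencyType.NESTED: {
        "S1": (((1, 2, 3), (1, 2, 3)), ((3, 2, 1), (3, 2, 1))),
        "S2": (((1, 2, 3), (2, 3, 1)), ((1, 3, 2), (3, 2, 1))),
        "S3": (((1, 2, 3), (3, 1, 2)), ((2, 1, 3), (3, 2, 1))),
    },
    DependencyType.CROSS_SERIAL: {
        "S1": (((1, 2, 3), (3, 2, 1)), ((3, 2, 1), (1, 2, 3))),
        "S2": (((1, 2, 3), (1, 3, 2)), ((1, 3, 2), (1, 2, 3))),
        "S3": (((1, 2, 3), (2, 1, 3)), ((2, 1, 3), (1, 2, 3))),
    },
}

FOIL_SUBSETS = ("S1", "S2", "S3")


@dataclass
class DesignConfig:
    """All count parameters of a design; defaults are the study's."""

    learning_per_length: int = 80
    test_per_length_per_label: int = 60   # experiment 1
    exp2_correct: int = 120               # experiment 2
    exp2_per_subset: int = 40
    repeat_probe_rate: float = 0.25
    lengths: tuple[int, ...] = (4, 6, 8)
    exp2_length: int = 6

    def validate(self, lexicon_size: int = 20) -> None:
        for name in ("learning_per_length", "test_per_length_per_label",
                     "exp2_correct"):
            v = getattr(self, name)
            if v % lexicon_size:
                raise ConfigError(
                    f"{name}={v} not divisible by lexicon size {lexicon_size}: "
                    "exact counterbalance infeasible")
        if self.exp2_per_subset % 2:
            raise ConfigError("exp2_per_subset must be even (two templates per subset)")
        if not 0 <= self.repeat_probe_rate <= 1:
            raise ConfigError("repeat_probe_rate must be in [0, 1]")
        for L in self.lengths + (self.exp2_length,):
            if L % 2 or L < 2:
                raise ConfigError(f"sequence length {L} must be even and >= 2")


@dataclass
class Trial:
    """One stimulus presentation."""

    index: int                      # 0-based position within its phase
    sequence: tuple[str, ...]
    phase: str                      # "learning" | "test"
    length_class: str               # "short" | "medium" | "long"
    label: str                      # "correct" | "incorrect" | "n/a"
    foil_subset: str = "none"       # "none" | "S1" | "S2" | "S3"
    repeat_probe: bool = False
    grammar_of_sequence: DependencyType | None = None


@dataclass
class ExperimentDesign:
    experiment: int
    group: DependencyType           # trained grammar
    seed: int
    config: DesignConfig
    trials: list[Trial] = field(default_factory=list)

    @property
    def learning_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "learning"]

    @property
    def test_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "test"]


# ---------------------------------------------------------------------------
# counterbalanced assignment machinery


def _balanced_rows(rng: np.random.Generator, n_rows: int, n_positions: int,
                   items: Sequence[int],
                   seq_of: Callable[[int, tuple[int, ...]], tuple[str, ...] | None],
                   used: set[tuple[str, ...]],
                   max_restarts: int = 200) -> list[tuple[str, ...]]:
    """Build ``n_rows`` sequences whose row items are exactly balanced per
    column (each item appears n_rows/len(items) times in every position).

    Per-position multisets are seeded shuffles; rows violating a constraint
    (``seq_of`` returns None, or the realized sequence collides with ``used``
    or an earlier row of this batch) are repaired by swapping a cell with a
    later row in the same column, preserving column balance.  Restarts from
    fresh shuffles if repair fails.  Accepted sequences are added to ``used``.
    """
    per, rem = divmod(n_rows, len(items))
    if rem:
        raise ConfigError(f"{n_rows} rows not divisible by {len(items)} items")
    base = [it for it in items for _ in range(per)]
    for _ in range(max_restarts):
        cols = [list(rng.permutation(base)) for _ in range(n_positions)]
        batch: list[tuple[str, ...]] = []
        batch_set: set[tuple[str, ...]] = set()

        def realize(r: int) -> tuple[str, ...] | None:
            row = tuple(col[r] for col in cols)
            if len(set(row)) != len(row):
                return None
            seq = seq_of(r, row)
            if seq is None or seq in used or seq in batch_set:
                return None
            return seq

        ok = True
        for r in range(n_rows):
            seq = realize(r)
            if seq is None:
                for p in range(n_positions):
                    for r2 in range(r + 1, n_rows):
                        cols[p][r], cols[p][r2] = cols[p][r2], cols[p][r]
                        seq = realize(r)
                        if seq is not None:
                            break
                        cols[p][r], cols[p][r2] = cols[p][r2], cols[p][r]
                    if seq is not None:
                        break
            if seq is None:
                ok = False
                break
            batch.append(seq)
            batch_set.add(seq)
        if ok:
            used.update(batch_set)
            return batch
    raise GenerationError(
        f"could not build {n_rows} unique balanced sequences after {max_restarts} restarts")


def _rng(seed: int, group: DependencyType, *tags: int) -> np.random.Generator:
    gi = 0 if group is DependencyType.NESTED else 1
    return np.random.default_rng([seed, gi, *tags])


def _grammatical_block(rng, count, length, grammar, lexicon, used):
    """``count`` unique members of ``grammar`` at ``length``, A-part exactly
    counterbalanced."""
    n = length // 2

    def seq_of(_r, row):
        return arrange_b_part([lexicon.a_of(p) for p in row], grammar, lexicon)

    return _balanced_rows(rng, count, n, lexicon.pair_ids, seq_of, used)


# ---------------------------------------------------------------------------
# public builders


def build_learning_set(group: DependencyType, seed: int,
                       config: DesignConfig | None = None,
                       lexicon: Lexicon | None = None,
                       used: set[tuple[str, ...]] | None = None) -> list[Trial]:
    """Learning phase: trained-grammar members, counterbalanced per length
    class, shuffled into one seeded order, 25% flagged as repeat probes."""
    config = config or DesignConfig()
    lexicon = lexicon or load_lexicon()
    config.validate(len(lexicon))
    used = used if used is not None else set()
    rng = _rng(seed, group, 0)
    pool: list[tuple[str, tuple[str, ...]]] = []
    for length in config.lengths:
        for seq in _grammatical_block(rng, config.learning_per_length, length,
                                      group, lexicon, used):
            pool.append((LENGTH_CLASSES[length], seq))
    order = rng.permutation(len(pool))
    n_probes = int(config.repeat_probe_rate * len(pool))
    probe_at = set(rng.choice(len(pool), size=n_probes, replace=False).tolist())
    trials = []
    for i, j in enumerate(order):
        lc, seq = pool[j]
        trials.append(Trial(index=i, sequence=seq, phase="learning",
                            length_class=lc, label="n/a",
                            repeat_probe=i in probe_at,
                            grammar_of_sequence=group))
    return trials


def build_test_set_exp1(group: DependencyType, seed: int,
                        config: DesignConfig | None = None,
                        lexicon: Lexicon | None = None,
                        used: set[tuple[str, ...]] | None = None) -> list[Trial]:
    """Experiment-1 test phase: per length class, equal numbers of
    trained-grammar members (correct) and untrained-grammar members
    (incorrect), in one shared seeded random order."""
    config = config or DesignConfig()
    lexicon = lexicon or load_lexicon()
    config.validate(len(lexicon))
    used = used if used is not None else set()
    rng = _rng(seed, group, 1)
    pool: list[tuple[str, str, DependencyType, tuple[str, ...]]] = []
    for length in config.lengths:
        for label, grammar in (("correct", group), ("incorrect", group.other)):
            for seq in _grammatical_block(rng, config.test_per_length_per_label,
                                          length, grammar, lexicon, used):
                pool.append((LENGTH_CLASSES[length], label, grammar, seq))
    order = rng.permutation(len(pool))
    return [Trial(index=i, sequence=pool[j][3], phase="test",
                  length_class=pool[j][0], label=pool[j][1],
                  grammar_of_sequence=pool[j][2])
            for i, j in enumerate(order)]


def apply_foil_template(a_pairs: Sequence[int], subset: str, variant: int,
                        group: DependencyType,
                        lexicon: Lexicon | None = None) -> tuple[str, ...]:
    """Realize one incorrect-trial template with three distinct pairs.

    ``subset`` is S1/S2/S3 and ``variant`` 0 or 1 selects between the two
    printed rows per subset (table row k = 2*subset_index + variant + 1).
    The result violates the trained grammar; S2 rows keep its first
    dependency pair intact, S3 rows its last.
    """
    lexicon = lexicon or load_lexicon()
    if subset not in FOIL_SUBSETS:
        raise ConfigError(f"unknown foil subset {subset!r}")
    if variant not in (0, 1):
        raise ConfigError(f"variant must be 0 or 1, got {variant}")
    if len(a_pairs) != 3 or len(set(a_pairs)) != 3:
        raise ConfigError(f"need 3 distinct pair ids, got {a_pairs}")
    a_order, b_order = FOIL_TEMPLATES[group][subset][variant]
    return (tuple(lexicon.a_of(a_pairs[i - 1]) for i in a_order)
            + tuple(lexicon.b_of(a_pairs[i - 1]) for i in b_order))


def build_test_set_exp2(group: DependencyType, seed: int,
                        config: DesignConfig | None = None,
                        lexicon: Lexicon | None = None,
                        used: set[tuple[str, ...]] | None = None) -> list[Trial]:
    """Experiment-2 test phase: medium-length only; half correct, half foils
    in three subsets of equal size, the two templates per subset used
    equally often.  The stored order is seeded; presentation order is
    re-randomized per participant by the cohort simulator."""
    config = config or DesignConfig()
    lexicon = lexicon or load_lexicon()
    config.validate(len(lexicon))
    used = used if used is not None else set()
    rng = _rng(seed, group, 2)
    length = config.exp2_length
    lc = LENGTH_CLASSES[length]
    pool: list[Trial] = []
    for seq in _grammatical_block(rng, config.exp2_correct, length, group,
                                  lexicon, used):
        pool.append(Trial(0, seq, "test", lc, "correct",
                          grammar_of_sequence=group))
    n_pos = length // 2
    for subset in FOIL_SUBSETS:
        templates = FOIL_TEMPLATES[group][subset]

        def seq_of(r, row, templates=templates):
            a_order, b_order = templates[r % 2]
            # row is the realized A-part; invert a_order to recover the triple
            triple = [0] * 3
            for pos, idx in enumerate(a_order):
                triple[idx - 1] = row[pos]
            return (tuple(lexicon.a_of(p) for p in row)
                    + tuple(lexicon.b_of(triple[i - 1]) for i in b_order))

        for r, seq in enumerate(_balanced_rows(rng, config.exp2_per_subset,
                                               n_pos, lexicon.pair_ids,
                                               seq_of, used)):
            grammar = group.other if subset == "S1" else None
            pool.append(Trial(0, seq, "test", lc, "incorrect",
                              foil_subset=subset, grammar_of_sequence=grammar))
    order = rng.permutation(len(pool))
    return [dataclasses.replace(pool[j], index=i) for i, j in enumerate(order)]


def build_design(experiment: int, group: DependencyType, seed: int,
                 config: DesignConfig | None = None,
                 lexicon: Lexicon | None = None) -> ExperimentDesign:
    """Full design (learning + test) with cross-phase uniqueness."""
    if experiment not in (1, 2):
        raise ConfigError(f"experiment must be 1 or 2, got {experiment}")
    config = config or DesignConfig()
    lexicon = lexicon or load_lexicon()
    used: set[tuple[str, ...]] = set()
    learning = build_learning_set(group, seed, config, lexicon, used)
    if experiment == 1:
        test = build_test_set_exp1(group, seed, config, lexicon, used)
    else:
        test = build_test_set_exp2(group, seed, config, lexicon, used)
    return ExperimentDesign(experiment, group, seed, config, learning + test)


# ---------------------------------------------------------------------------
# validation


@dataclass
class DesignReport:
    violations: list[str]
    tallies: dict

    @property
    def valid(self) -> bool:
        return not self.violations


def _first_last_links(group: DependencyType, n: int) -> tuple[tuple[int, int], tuple[int, int]]:
    links = dependency_structure(n, group).links
    return links[0], links[-1]


def _pair_intact(seq: tuple[str, ...], link: tuple[int, int], lexicon: Lexicon) -> bool:
    a, b = link
    sa, sb = lexicon.lookup(seq[a]), lexicon.lookup(seq[b])
    return sa.category == "A" and sb.category == "B" and sa.pair_id == sb.pair_id


def verify_design(design: ExperimentDesign,
                  lexicon: Lexicon | None = None) -> DesignReport:
    """Audit a design against every structural claim it should satisfy.

    Reports (never raises): per-cell counts, sequence uniqueness, label
    soundness against the trained grammar, untrained-grammar identity of
    experiment-1 foils, repeat-probe placement and rate, A-position
    counterbalance tallies, and the per-subset foil properties of
    experiment 2.
    """
    lexicon = lexicon or load_lexicon()
    cfg = design.config
    group = design.group
    v: list[str] = []
    tallies: dict = {}

    seqs = [t.sequence for t in design.trials]
    n_dup = len(seqs) - len(set(seqs))
    if n_dup:
        v.append(f"{n_dup} duplicated sequence(s) across the design")

    learning, test = design.learning_trials, design.test_trials
    counts = {"learning": len(learning), "test": len(test)}
    tallies["phase_counts"] = counts

    # learning-phase structure
    per_length: dict[str, int] = {}
    for t in learning:
        per_length[t.length_class] = per_length.get(t.length_class, 0) + 1
        if t.label != "n/a":
            v.append(f"learning trial {t.index} has label {t.label!r}")
        if not is_member(t.sequence, group, lexicon):
            v.append(f"learning trial {t.index} is not a member of the trained grammar")
    tallies["learning_per_length"] = per_length
    for length in cfg.lengths:
        lc = LENGTH_CLASSES[length]
        if per_length.get(lc, 0) != cfg.learning_per_length:
            v.append(f"learning {lc}: {per_length.get(lc, 0)} trials, "
                     f"expected {cfg.learning_per_length}")
    n_probes = sum(t.repeat_probe for t in learning)
    expected_probes = int(cfg.repeat_probe_rate * len(learning))
    tallies["repeat_probes"] = n_probes
    if n_probes != expected_probes:
        v.append(f"{n_probes} repeat probes, expected {expected_probes}")
    if any(t.repeat_probe for t in test):
        v.append("repeat probe flagged in test phase")

    # counterbalance: A-syllable x position occupancy per length class
    cb: dict[str, dict] = {}
    for length in cfg.lengths:
        lc = LENGTH_CLASSES[length]
        n = length // 2
        occ = np.zeros((len(lexicon), n), dtype=int)
        for t in learning:
            if t.length_class == lc:
                for p in range(n):
                    occ[lexicon.pair_id(t.sequence[p]) - 1, p] += 1
        cb[lc] = occ
        expect = cfg.learning_per_length // len(lexicon)
        if occ.size and not (occ == expect).all():
            v.append(f"learning {lc}: A-position occupancy not uniform at {expect}")
    tallies["learning_counterbalance"] = {k: o.tolist() for k, o in cb.items()}

    # test-phase structure
    cell: dict[tuple[str, str], int] = {}
    subset_sizes: dict[str, int] = {}
    for t in test:
        cell[(t.length_class, t.label)] = cell.get((t.length_class, t.label), 0) + 1
        member = is_member(t.sequence, group, lexicon)
        if (t.label == "correct") != member:
            v.append(f"test trial {t.index}: label {t.label!r} inconsistent with membership")
        if t.label == "incorrect":
            if design.experiment == 1:
                if not is_member(t.sequence, group.other, lexicon):
                    v.append(f"test trial {t.index}: exp-1 foil not a member of the untrained grammar")
            else:
                subset_sizes[t.foil_subset] = subset_sizes.get(t.foil_subset, 0) + 1
                n = len(t.sequence) // 2
                first, last = _first_last_links(group, n)
                if t.foil_subset == "S1":
                    if not is_member(t.sequence, group.other, lexicon):
                        v.append(f"test trial {t.index}: S1 foil not a member of the untrained grammar")
                elif t.foil_subset == "S2":
                    if not _pair_intact(t.sequence, first, lexicon):
                        v.append(f"test trial {t.index}: S2 foil breaks the first dependency pair")
                elif t.foil_subset == "S3":
                    if not _pair_intact(t.sequence, last, lexicon):
                        v.append(f"test trial {t.index}: S3 foil breaks the last dependency pair")
                else:
                    v.append(f"test trial {t.index}: incorrect exp-2 trial without a foil subset")
        elif t.foil_subset != "none":
            v.append(f"test trial {t.index}: foil subset on a non-foil trial")
    tallies["test_cells"] = {f"{lc}/{lab}": c for (lc, lab), c in sorted(cell.items())}
    tallies["foil_subsets"] = subset_sizes

    if design.experiment == 1:
        for length in cfg.lengths:
            lc = LENGTH_CLASSES[length]
            for lab in ("correct", "incorrect"):
                got = cell.get((lc, lab), 0)
                if got != cfg.test_per_length_per_label:
                    v.append(f"test {lc}/{lab}: {got}, expected {cfg.test_per_length_per_label}")
    else:
        lc = LENGTH_CLASSES[cfg.exp2_length]
        if cell.get((lc, "correct"), 0) != cfg.exp2_correct:
            v.append(f"test correct: {cell.get((lc, 'correct'), 0)}, expected {cfg.exp2_correct}")
        for s in FOIL_SUBSETS:
            if subset_sizes.get(s, 0) != cfg.exp2_per_subset:
                v.append(f"foil subset {s}: {subset_sizes.get(s, 0)}, expected {cfg.exp2_per_subset}")
        if any(t.length_class != lc for t in test):
            v.append("exp-2 test trial with non-medium length")

    return DesignReport(v, tallies)
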