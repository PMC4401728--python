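"""Synthetic participants: parameterized response policies over a design.

No human data were deposited for this paradigm, so every analysis stage is
exercised with artificial responders of known construction:

* ``sdt_learner`` — equal-variance Gaussian signal detection.  A correct
  trial draws evidence from N(+d/2, 1), a foil from N(-d/2, 1), and the
  responder says yes above criterion c, so P(yes|correct) = Phi(d/2 - c)
  and P(yes|foil) = Phi(-d/2 - c).  This is the matched generative model
  for the d' estimator in the analysis battery: recovered d' converges to
  the generating sensitivity.  An optional per-block sensitivity increment
  emulates continued learning across the test phase.
* ``first_pair_strategist`` / ``last_pair_strategist`` — deterministic
  regular-language shortcuts: yes iff the inspected dependency pair of the
  trained grammar is intact, ignoring the rest of the sequence.
* ``guesser`` — yes with fixed probability regardless of content; the null
  model for chance-level performance (yes_rate 0.5 gives expected d' = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .design import DesignConfig, ExperimentDesign, Trial, build_design
from .errors import AlignmentError, ConfigError
from .grammar import DependencyType, dependency_structure
from .lexicon import Lexicon, load_lexicon

POLICIES = ("sdt_learner", "first_pair_strategist", "last_pair_strategist", "guesser")


@dataclass
class SimulantConfig:
    policy: str = "sdt_learner"
    sensitivity: float = 0.0          # generating d' (sdt_learner)
    criterion: float = 0.0            # response criterion c (sdt_learner)
    yes_rate: float = 0.5             # guesser only
    learning_slope: float | None = None  # added to sensitivity per test block
    seed: int = 0

    def validate(self) -> None:
        if self.policy not in POLICIES:
            raise ConfigError(f"unknown policy {self.policy!r}")
        if not 0.0 <= self.yes_rate <= 1.0:
            raise ConfigError(f"yes_rate must be in [0,1], got {self.yes_rate}")
        if self.sensitivity < 0:
            raise ConfigError(f"sensitivity must be >= 0, got {self.sensitivity}")


@dataclass
class Response:
    trial_index: int
    answer: bool  # True = "yes, follows the rule"


@dataclass
class ResponseLog:
    """One participant's yes/no judgments, in presentation order."""

    participant_id: str
    group: DependencyType
    policy: str
    responses: list[Response] = field(default_factory=list)

    @property
    def order(self) -> list[int]:
        return [r.trial_index for r in self.responses]


def _presentation(design: ExperimentDesign,
                  order: Sequence[int] | None) -> list[Trial]:
    test = design.test_trials
    if order is None:
        return test
    by_index = {t.index: t for t in test}
    if sorted(order) != sorted(by_index):
        raise AlignmentError("presentation order is not a permutation of the test trials")
    return [by_index[i] for i in order]


def simulate_sdt_learner(design: ExperimentDesign, cfg: SimulantConfig,
                         order: Sequence[int] | None = None,
                         participant_id: str = "sdt") -> ResponseLog:
    """Equal-variance Gaussian SDT responder; seeded, independent trials."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    trials = _presentation(design, order)
    n = len(trials)
    block_size = n // 3 if n >= 3 else n
    log = ResponseLog(participant_id, design.group, "sdt_learner")
    p_yes = np.empty(n)
    for pos, t in enumerate(trials):
        d = cfg.sensitivity
        if cfg.learning_slope is not None and block_size:
            d = d + cfg.learning_slope * min(pos // block_size, 2)
        mu = d / 2 if t.label == "correct" else -d / 2
        p_yes[pos] = mu - cfg.criterion
    answers = rng.random(n) < norm.cdf(p_yes)
    log.responses = [Response(t.index, bool(a)) for t, a in zip(trials, answers)]
    return log


def _strategy_link(group: DependencyType, n_pairs: int, which: str) -> tuple[int, int]:
    links = dependency_structure(n_pairs, group).links
    return links[0] if which == "first" else links[-1]


def simulate_strategist(design: ExperimentDesign, which: str,
                        lexicon: Lexicon | None = None,
                        order: Sequence[int] | None = None,
                        participant_id: str | None = None) -> ResponseLog:
    """Deterministic single-pair responder.

    Says yes iff the first (or last) dependency pair of the trained
    grammar's structure is intact in the presented sequence — the shortcut
    that achieves perfect accuracy on the experiment-1 test set and that
    the experiment-2 foil subsets are built to expose.
    """
    if which not in ("first", "last"):
        raise ConfigError(f"which must be 'first' or 'last', got {which!r}")
    lexicon = lexicon or load_lexicon()
    trials = _presentation(design, order)
    pid = participant_id or f"{which}_pair_strategist"
    log = ResponseLog(pid, design.group, f"{which}_pair_strategist")
    for t in trials:
        a, b = _strategy_link(design.group, len(t.sequence) // 2, which)
        sa, sb = lexicon.lookup(t.sequence[a]), lexicon.lookup(t.sequence[b])
        intact = (sa.category == "A" and sb.category == "B"
                  and sa.pair_id == sb.pair_id)
        log.responses.append(Response(t.index, intact))
    return log


def simulate_guesser(design: ExperimentDesign, cfg: SimulantConfig,
                     order: Sequence[int] | None = None,
                     participant_id: str = "guesser") -> ResponseLog:
    """Content-blind responder: yes with probability ``cfg.yes_rate``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    trials = _presentation(design, order)
    answers = rng.random(len(trials)) < cfg.yes_rate
    log = ResponseLog(participant_id, design.group, "guesser")
    log.responses = [Response(t.index, bool(a)) for t, a in zip(trials, answers)]
    return log


def _simulate_one(design, cfg, order, pid, lexicon):
    if cfg.policy == "sdt_learner":
        return simulate_sdt_learner(design, cfg, order, pid)
    if cfg.policy == "guesser":
        return simulate_guesser(design, cfg, order, pid)
    which = "first" if cfg.policy == "first_pair_strategist" else "last"
    return simulate_strategist(design, which, lexicon, order, pid)


@dataclass
class Cohort:
    experiment: int
    designs: dict[DependencyType, ExperimentDesign]
    logs: list[ResponseLog]
    manifest: dict


def make_design_factory(experiment: int,
                        config: DesignConfig | None = None,
                        lexicon: Lexicon | None = None
                        ) -> Callable[[DependencyType, int], ExperimentDesign]:
    """Default factory handed to :func:`simulate_cohort`."""

    def factory(group: DependencyType, seed: int) -> ExperimentDesign:
        return build_design(experiment, group, seed, config, lexicon)

    return factory


def simulate_cohort(design_factory: Callable[[DependencyType, int], ExperimentDesign] | int,
                    n_per_group: int,
                    policy_mix: SimulantConfig | Sequence[SimulantConfig],
                    master_seed: int,
                    groups: Sequence[DependencyType] = (DependencyType.NESTED,
                                                        DependencyType.CROSS_SERIAL),
                    lexicon: Lexicon | None = None) -> Cohort:
    """Simulate a full study: one design per group, ``n_per_group`` logs each.

    ``design_factory`` may be a callable ``(group, seed) -> design`` or an
    experiment number (1 or 2), in which case the default designs are
    built.  ``policy_mix`` is a single config applied to everyone or a
    sequence cycled over participants within each group.  All randomness —
    design seed, per-participant response seeds, and (experiment 2) fresh
    per-participant presentation orders — derives from ``master_seed``.
    """
    if isinstance(design_factory, int):
        design_factory = make_design_factory(design_factory)
    lexicon = lexicon or load_lexicon()
    if isinstance(policy_mix, SimulantConfig):
        policy_mix = [policy_mix]
    root = np.random.default_rng(master_seed)
    design_seed = int(root.integers(2**31))
    designs = {g: design_factory(g, design_seed) for g in groups}
    experiment = next(iter(designs.values())).experiment
    logs: list[ResponseLog] = []
    manifest: dict = {"master_seed": master_seed, "design_seed": design_seed,
                      "experiment": experiment, "n_per_group": n_per_group,
                      "participants": []}
    for g in groups:
        design = designs[g]
        test_indices = [t.index for t in design.test_trials]
        for i in range(n_per_group):
            base = policy_mix[i % len(policy_mix)]
            seed = int(root.integers(2**31))
            cfg = SimulantConfig(policy=base.policy, sensitivity=base.sensitivity,
                                 criterion=base.criterion, yes_rate=base.yes_rate,
                                 learning_slope=base.learning_slope, seed=seed)
            pid = f"{g.value}_{i + 1:03d}"
            if experiment == 2:
                order = [test_indices[k] for k in root.permutation(len(test_indices))]
            else:
                order = None  # one shared order: the design's own
            logs.append(_simulate_one(design, cfg, order, pid, lexicon))
            manifest["participants"].append(
                {"participant_id": pid, "group": g.value, "policy": cfg.policy,
                 "sensitivity": cfg.sensitivity, "criterion": cfg.criterion,
                 "yes_rate": cfg.yes_rate, "learning_slope": cfg.learning_slope,
                 "seed": seed})
    return Cohort(experiment, designs, logs, manifest)
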