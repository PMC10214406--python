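"""Ideal-observer expectations for exploration after a reversal.

After a reversal the agent must find the newly rewarded position among the
remaining candidates.  The ideal observer excludes every response it has
already found unrewarded (including the previously rewarded one, whose lack
of reward signalled the reversal) and samples the remaining candidates
uniformly without replacement.  With the *exploration bias*, candidates
belonging to the frequently rewarded set are exhausted first; only then are
the never/rarely rewarded positions tried.

The expected number of unrewarded exploration trials under this policy is
computed exactly by enumerating the decision tree of all exploration orders,
and can be cross-checked by Monte-Carlo simulation of the same policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ObserverScenario",
    "DecisionTree",
    "TreeNode",
    "build_tree",
    "tree_expectation",
    "expected_unrewarded_trials",
    "simulate_observer",
    "expectation_table",
]


@dataclass(frozen=True)
class ObserverScenario:
    """One previous/new reward configuration faced by the observer.

    Parameters
    ----------
    frequent, other
        The frequently rewarded position set F and the never/rarely rewarded
        set N.  The task uses ``|F| = 3`` and ``|N| = 2`` but the tree works
        for any sizes.
    previous
        Position rewarded in the preceding block; excluded from exploration.
    rewarded
        Newly rewarded position (must differ from ``previous``).
    bias
        Whether the observer restricts its first picks to the frequent set.
    """

    frequent: tuple[int, ...]
    other: tuple[int, ...]
    previous: int
    rewarded: int
    bias: bool

    def __post_init__(self) -> None:
        if set(self.frequent) & set(self.other):
            raise ValueError("frequent and other position sets overlap")
        if self.rewarded == self.previous:
            raise ValueError("newly rewarded position equals the previous one")
        pool = set(self.frequent) | set(self.other)
        if self.rewarded not in pool:
            raise ValueError("rewarded position not among the task positions")

    @property
    def candidates(self) -> tuple[int, ...]:
        """All positions the observer may explore (previous excluded)."""
        pool = [p for p in self.frequent + self.other if p != self.previous]
        if not pool:
            raise ValueError("empty candidate set")
        return tuple(pool)

    def in_bias(self, position: int) -> bool:
        return position in self.frequent


@dataclass
class TreeNode:
    """One state of the exploration: remaining candidates and trials so far."""

    remaining: tuple[int, ...]
    unrewarded_so_far: int
    probability: Fraction
    choice: int | None = None  # position chosen on the edge into this node
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DecisionTree:
    root: TreeNode
    scenario: ObserverScenario

    def leaves(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)


def _choice_set(scenario: ObserverScenario, remaining: Sequence[int]) -> list[int]:
    """Candidates the policy samples from at this node."""
    if scenario.bias:
        in_bias = [p for p in remaining if scenario.in_bias(p)]
        if in_bias:
            return in_bias
    return list(remaining)


def build_tree(scenario: ObserverScenario) -> DecisionTree:
    """Enumerate every exploration order the observer's policy allows.

    Each internal node uniformly samples (without replacement) from the
    in-bias candidates while any remain (biased observer) or from all
    remaining candidates (unbiased).  A branch terminates when the newly
    rewarded position is drawn; its leaf records the number of unrewarded
    draws made before that.
    """
    root = TreeNode(scenario.candidates, 0, Fraction(1))
    stack = [root]
    while stack:
        node = stack.pop()
        choices = _choice_set(scenario, node.remaining)
        p_edge = node.probability / len(choices)
        for pick in choices:
            if pick == scenario.rewarded:
                child = TreeNode((), node.unrewarded_so_far, p_edge, choice=pick)
            else:
                remaining = tuple(p for p in node.remaining if p != pick)
                child = TreeNode(
                    remaining, node.unrewarded_so_far + 1, p_edge, choice=pick
                )
                stack.append(child)
            node.children.append(child)
    return DecisionTree(root, scenario)


def tree_expectation(tree: DecisionTree) -> Fraction:
    """Probability-weighted mean leaf count (exact rational arithmetic)."""
    total = Fraction(0)
    mass = Fraction(0)
    for leaf in tree.leaves():
        total += leaf.probability * leaf.unrewarded_so_far
        mass += leaf.probability
    if mass != 1:
        raise AssertionError(f"leaf probabilities sum to {mass}, not 1")
    return total


_FREQUENT = (2, 3, 4)  # positions frequently rewarded in the task
_OTHER = (1, 5)  # never (or rarely) rewarded positions


def _category_weights(version: str, no_repeat_correction: bool) -> dict[tuple[str, str], Fraction]:
    """Probability of each (previous, new) reward-category pair.

    never
        Both blocks reward frequent positions with certainty.
    rarely
        Each 14-block part rewards each frequent position 4x and each rare
        position 1x, so the marginal category probabilities are 6/7 and 1/7.
        By default successive blocks are treated as category-independent;
        the optional correction conditions the new draw on the previous
        position being unavailable (blocks never repeat a position).
    """
    if version == "never":
        return {("F", "F"): Fraction(1)}
    if version != "rarely":
        raise ValueError(f"unknown version {version!r}")
    p_prev = {"F": Fraction(6, 7), "R": Fraction(1, 7)}
    if not no_repeat_correction:
        p_new = {"F": Fraction(6, 7), "R": Fraction(1, 7)}
        return {
            (a, b): p_prev[a] * p_new[b] for a in ("F", "R") for b in ("F", "R")
        }
    # 14-block part composition minus the previous position's share
    cond = {
        "F": {"F": Fraction(8, 10), "R": Fraction(2, 10)},
        "R": {"F": Fraction(12, 13), "R": Fraction(1, 13)},
    }
    return {
        (a, b): p_prev[a] * cond[a][b] for a in ("F", "R") for b in ("F", "R")
    }


def _scenario_for_categories(prev_cat: str, new_cat: str, bias: bool) -> ObserverScenario:
    previous = _FREQUENT[0] if prev_cat == "F" else _OTHER[0]
    if new_cat == "F":
        rewarded = next(p for p in _FREQUENT if p != previous)
    else:
        rewarded = next(p for p in _OTHER if p != previous)
    return ObserverScenario(_FREQUENT, _OTHER, previous, rewarded, bias)


def expected_unrewarded_trials(
    version: str, bias: bool, *, no_repeat_correction: bool = False
) -> float:
    """Expected unrewarded exploration trials for one experiment version.

    The expectation is the category-probability-weighted mean of the exact
    tree expectations over the possible (previous, new) reward-category
    pairs.  Within a category pair the expectation does not depend on which
    concrete positions are involved (the policy is exchangeable), so a
    single representative scenario per pair suffices.
    """
    weights = _category_weights(version, no_repeat_correction)
    value = Fraction(0)
    for (prev_cat, new_cat), w in weights.items():
        scenario = _scenario_for_categories(prev_cat, new_cat, bias)
        value += w * tree_expectation(build_tree(scenario))
    return float(value)


def simulate_observer(
    scenario: ObserverScenario, n_episodes: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo mean of unrewarded exploration trials under the policy.

    Independent oracle for :func:`build_tree`: simulates the sampling
    process directly instead of enumerating it.
    """
    if n_episodes <= 0:
        raise ValueError("n_episodes must be positive")
    total = 0
    for _ in range(n_episodes):
        remaining = list(scenario.candidates)
        unrewarded = 0
        while True:
            choices = _choice_set(scenario, remaining)
            pick = choices[rng.integers(len(choices))]
            if pick == scenario.rewarded:
                break
            remaining.remove(pick)
            unrewarded += 1
        total += unrewarded
    return total / n_episodes


def expectation_table(*, no_repeat_correction: bool = False) -> dict[str, float]:
    """All (version, bias) expectations, keyed ``"<version>_<bias|nobias>"``."""
    table = {}
    for version in ("never", "rarely"):
        for bias in (True, False):
            key = f"{version}_{'bias' if bias else 'nobias'}"
            table[key] = expected_unrewarded_trials(
                version, bias, no_repeat_correction=no_repeat_correction
            )
    return table
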