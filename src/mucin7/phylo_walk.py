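"""Neutral copy-number evolution as a random walk on a dated species tree.

The model follows the species phylogeny literally: a single ancestral copy
number starts at the root, and every ``step_myr`` million years each extant
lineage independently gains or loses ``rate_per_step`` copies with equal
probability. Descendant lineages share the trajectory of their ancestors up
to the divergence time. Terminal states are compared with observed
copy-number states through the variance across tips, tested one-sided with
a Wilcoxon rank-sum test (observed variation smaller than neutral).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .stats import rank_sum_test  # re-exported: the module's test entry point
from .trees import DatedTree, TreeNode, default_great_ape_tree

__all__ = [
    "WalkConfig",
    "WalkResult",
    "DEFAULT_OBSERVED_STATES",
    "simulate_walk",
    "variation_statistic",
    "observed_variation_set",
    "rank_sum_test",
    "neutrality_test",
    "default_great_ape_tree",
]

#: haploid PTS-repeat copy numbers observed in present-day great apes
DEFAULT_OBSERVED_STATES: dict[str, tuple[int, ...]] = {
    "Human": (5, 6),
    "Chimpanzee": (5,),
    "Gorilla": (4, 5),
    "Orangutan": (6, 7),
}

DEFAULT_RATES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)


@dataclass
class WalkConfig:
    """Parameters of the stepwise random walk.

    rate_per_step is the copy-number change per step (copies per Myr with
    the default 1-Myr step); integer_steps=True switches the ±rate step to
    a ±Poisson(rate) integer-valued variant for sensitivity analysis.
    """

    ancestral_state: float = 5.0
    rate_per_step: float = 1.0
    step_myr: float = 1.0
    n_reps: int = 1000
    floor: float = 0.0
    seed: int = 0
    integer_steps: bool = False

    def __post_init__(self) -> None:
        if self.rate_per_step < 0:
            raise ValueError("rate_per_step must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.step_myr <= 0:
            raise ValueError("step_myr must be positive")


@dataclass
class WalkResult:
    """Terminal (tip) and internal-node states of all replicates."""

    tips: dict[str, np.ndarray]
    node_states: dict[str, np.ndarray] = field(default_factory=dict)

    def variance_per_replicate(self) -> np.ndarray:
        """Sample variance (ddof=1) of the tip states, per replicate."""
        stacked = np.stack(list(self.tips.values()))
        return np.var(stacked, axis=0, ddof=1)


def _n_steps(length: float, step_myr: float) -> int:
    steps = length / step_myr
    rounded = round(steps)
    if abs(steps - rounded) > 1e-9:
        raise ValueError(
            f"branch length {length} Myr is not a multiple of the step "
            f"({step_myr} Myr); adjust step_myr"
        )
    return int(rounded)


def simulate_walk(tree: DatedTree, cfg: WalkConfig) -> WalkResult:
    """Run the copy-number random walk along ``tree`` for cfg.n_reps replicates.

    Returns per-tip terminal state arrays plus the state at every internal
    node (shared by all its descendants), fully determined by cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    result = WalkResult(tips={}, node_states={})

    def _walk_branch(state: np.ndarray, node: TreeNode) -> None:
        result.node_states[node.name] = state
        if node.is_leaf:
            result.tips[node.name] = state
            return
        for child in node.children:
            steps = _n_steps(node.age - child.age, cfg.step_myr)
            child_state = state.copy()
            for _ in range(steps):
                if cfg.integer_steps:
                    mag = rng.poisson(cfg.rate_per_step, size=cfg.n_reps)
                else:
                    mag = cfg.rate_per_step
                signs = rng.integers(0, 2, size=cfg.n_reps) * 2 - 1
                child_state = np.maximum(cfg.floor, child_state + mag * signs)
            _walk_branch(child_state, child)

    root_state = np.full(cfg.n_reps, float(cfg.ancestral_state))
    _walk_branch(root_state, tree.root)
    return result


def variation_statistic(states) -> float:
    """Sample variance (n−1 denominator) of tip copy-number states."""
    values = np.asarray(
        list(states.values()) if isinstance(states, dict) else states, dtype=float
    )
    if values.size < 2:
        raise ValueError("need at least two tips")
    return float(np.var(values, ddof=1))


def observed_variation_set(obs: dict[str, tuple]) -> list[float]:
    """Variance of every combination of per-tip observed allele states.

    Tips are taken in sorted-name order; the Cartesian product of their
    allele sets yields one variance per combination (8 for the default
    great-ape input).
    """
    tips = sorted(obs)
    for tip in tips:
        if not obs[tip]:
            raise ValueError(f"empty allele set for {tip}")
    return [
        variation_statistic(dict(zip(tips, combo)))
        for combo in itertools.product(*(obs[t] for t in tips))
    ]


def neutrality_test(
    tree: DatedTree | None = None,
    rates: tuple[float, ...] = DEFAULT_RATES,
    obs: dict[str, tuple] | None = None,
    *,
    ancestral_state: float = 5.0,
    n_reps: int = 1000,
    seed: int = 0,
    alternative: str = "less",
) -> dict[float, dict]:
    """Test observed copy-number variation against the neutral random walk.

    For each gain/loss rate, simulates ``n_reps`` replicates, computes the
    variance of the four terminal states per replicate, and compares the
    enumerated observed variances against that null with a one-sided
    rank-sum test (observed smaller, by default). Returns per-rate results.
    """
    tree = tree if tree is not None else default_great_ape_tree()
    obs = obs if obs is not None else DEFAULT_OBSERVED_STATES
    missing = set(obs) - set(tree.tip_names())
    if missing:
        raise ValueError(f"observed tips not in tree: {sorted(missing)}")
    observed_vars = observed_variation_set(obs)
    report: dict[float, dict] = {}
    for i, rate in enumerate(rates):
        cfg = WalkConfig(
            ancestral_state=ancestral_state,
            rate_per_step=rate,
            n_reps=n_reps,
            seed=seed + i,
        )
        walk = simulate_walk(tree, cfg)
        tip_states = {t: walk.tips[t] for t in sorted(obs)}
        sim_vars = np.var(np.stack(list(tip_states.values())), axis=0, ddof=1)
        pval = rank_sum_test(observed_vars, sim_vars, alternative=alternative)
        report[rate] = {
            "p_value": pval,
            "simulated_variances": sim_vars,
            "observed_variances": observed_vars,
        }
    return report
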