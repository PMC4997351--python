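"""Neutral copy-number polymorphism under a multispecies coalescent.

A Wright–Fisher multispecies coalescent generates a genealogy for samples
from several primate species; stepwise ±1 copy-number mutations (the
microsatellite mutation model) are dropped on the branches at a
population-scaled rate θ; optional truncation selection rejects replicates
containing copy numbers above a hard bound. The resulting null
distributions of within- and between-species copy-number variation are
compared against observed genotype tables over a grid of θ values.

Time is measured in Hudson-style coalescent units: the pairwise
coalescence rate in a population of the reference size is 1, mutations
arrive at rate θ/2 per unit branch length, and species divergence times
convert as t_coal = t_years / (generation_time · 4·Ne_ref). These choices
jointly give the classical identities E[TMRCA(2)] = 1 and E[pairwise
mutation count] = θ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import DatedTree, DEFAULT_HCG_NEWICK

DEFAULT_THETA_GRID: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.5)


def theta_from_k(k: float, ne: float = 1e4, gen_time: float = 25.0) -> float:
    """Population-scaled mutation rate θ = 4·Ne·(k·gen_time/10^6).

    ``k`` is the number of copy-number mutation events per million years;
    with the default human Ne = 10^4 and 25-year generations, θ = k.
    """
    if k <= 0 or ne <= 0 or gen_time <= 0:
        raise ValueError("k, ne and gen_time must all be positive")
    return 4.0 * ne * (k * gen_time / 1e6)


@dataclass
class PopModel:
    """Demography for the multispecies coalescent.

    ``tree`` is a dated species tree (ages in Myr). ``ne`` maps species
    (and optionally internal-node names) to effective sizes; unnamed
    ancestral populations default to ``ne_ref``. ``samples`` gives haploid
    sample counts per species.
    """

    tree: DatedTree
    samples: dict[str, int]
    ne: dict[str, float] = field(default_factory=dict)
    ne_ref: float = 1e4
    generation_time: float = 25.0

    def __post_init__(self) -> None:
        tips = set(self.tree.tip_names())
        unknown = set(self.samples) - tips
        if unknown:
            raise ValueError(f"samples for species not in tree: {sorted(unknown)}")
        for sp, n in self.samples.items():
            if n < 1:
                raise ValueError(f"need >=1 sample for {sp}")
        for name, ne in self.ne.items():
            if ne <= 0:
                raise ValueError(f"Ne must be positive for {name}")

    def pop_size(self, name: str) -> float:
        return self.ne.get(name, self.ne_ref)

    def age_to_coal(self, age_myr: float) -> float:
        """Convert a node age in Myr to coalescent units."""
        years = age_myr * 1e6
        return years / (self.generation_time * 4.0 * self.ne_ref)


def default_pop_model(samples_per_species: int = 6) -> PopModel:
    """Human/Chimpanzee/Gorilla model with paper defaults.

    Human Ne 10^4, chimpanzee Ne twice the human Ne, 25-year generations,
    splits at 5 and 8 Mya; six haplotypes per species by default (the
    genotyping threshold of more than 3 diploid individuals).
    """
    tree = DatedTree.from_newick(DEFAULT_HCG_NEWICK)
    return PopModel(
        tree=tree,
        samples={sp: samples_per_species for sp in tree.tip_names()},
        ne={"Human": 1e4, "Chimpanzee": 2e4, "Gorilla": 1e4},
        ne_ref=1e4,
    )


@dataclass
class GenealogyNode:
    """Binary coalescent-tree node; ``time`` in coalescent units."""

    time: float
    species: str | None = None  # set for tips
    children: list["GenealogyNode"] = field(default_factory=list)
    parent: "GenealogyNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.time - self.time


@dataclass
class Genealogy:
    root: GenealogyNode

    def tips(self) -> list[GenealogyNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def nodes(self) -> list[GenealogyNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def total_length(self) -> float:
        return sum(n.branch_length for n in self.nodes())

    def tmrca(self) -> float:
        return self.root.time


def simulate_genealogy(model: PopModel, rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy under the structured multispecies coalescent.

    Within each population carrying j lineages, the waiting time to the
    next coalescence is exponential with rate C(j,2)·(Ne_ref/Ne_pop);
    populations merge into their ancestor at the species divergence times.
    """
    # species-tree merge schedule, shallowest first
    events = sorted(model.tree.internal_nodes(), key=lambda n: n.age)
    name_of = {}  # TreeNode -> population name

    pops: dict[str, list[GenealogyNode]] = {}
    for leaf in model.tree.leaves():
        name_of[id(leaf)] = leaf.name
        n = model.samples.get(leaf.name, 0)
        pops[leaf.name] = [GenealogyNode(time=0.0, species=leaf.name) for _ in range(n)]

    def _coalesce_in_pop(pop: str, t_start: float, t_end: float) -> float:
        """Run coalescence in one population from t_start to t_end (inf ok)."""
        t = t_start
        lineages = pops[pop]
        rel = model.pop_size(pop) / model.ne_ref
        while len(lineages) > 1:
            j = len(lineages)
            rate = j * (j - 1) / 2.0 / rel
            wait = rng.exponential(1.0 / rate)
            if t + wait >= t_end:
                return t_end
            t += wait
            i1, i2 = sorted(rng.choice(j, size=2, replace=False))
            a, b = lineages[i1], lineages[i2]
            parent = GenealogyNode(time=t, children=[a, b])
            a.parent = b.parent = parent
            lineages[i2] = parent
            lineages.pop(i1)
        return t_end

    t_prev = 0.0
    for node in events:
        t_event = model.age_to_coal(node.age)
        if t_event < t_prev - 1e-12:
            raise ValueError("divergence times out of order")
        for pop in list(pops):
            _coalesce_in_pop(pop, t_prev, t_event)
        # merge the child populations of this species-tree node
        child_names = [name_of[id(c)] for c in node.children]
        merged: list[GenealogyNode] = []
        for cn in child_names:
            merged.extend(pops.pop(cn))
        name_of[id(node)] = node.name
        pops[node.name] = merged
        t_prev = t_event
    (final_pop,) = pops
    _coalesce_in_pop(final_pop, t_prev, np.inf)
    (root,) = pops[final_pop]
    return Genealogy(root=root)


def drop_mutations(
    g: Genealogy, theta: float, rng: np.random.Generator
) -> dict[int, int]:
    """Per-branch mutation counts, Poisson(θ/2 · branch length)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    counts: dict[int, int] = {}
    for node in g.nodes():
        if node.parent is not None:
            counts[id(node)] = int(rng.poisson(theta / 2.0 * node.branch_length))
    return counts


def stepwise_copy_number(
    g: Genealogy,
    mutation_counts: dict[int, int],
    root_cn: int,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """Propagate ±1 stepwise mutations root→tips; returns CNs per species.

    Each mutation adds +1 or −1 with probability ½; a tip's copy number is
    the root state plus the signed sum along its path, clipped at 0.
    """
    if root_cn < 1:
        raise ValueError("root_cn must be >= 1")
    out: dict[str, list[int]] = {}

    def _walk(node: GenealogyNode, state: int) -> None:
        m = mutation_counts.get(id(node), 0)
        if m:
            state += int(2 * rng.integers(0, 2, size=m).sum() - m)
        if node.is_tip:
            out.setdefault(node.species, []).append(max(0, state))
        else:
            for child in node.children:
                _walk(child, state)

    _walk(g.root, root_cn)
    return out


@dataclass
class SimulationResult:
    """Replicated copy-number samples plus rejection-sampling bookkeeping."""

    replicates: list[dict[str, list[int]]]
    attempts: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.replicates) / self.attempts


def simulate_copy_numbers(
    model: PopModel,
    theta: float,
    *,
    root_cn: int = 5,
    n_reps: int = 1000,
    seed: int = 0,
    max_cn: int | None = None,
) -> SimulationResult:
    """Full pipeline: genealogy → mutations → stepwise CNs, replicated.

    With ``max_cn`` set, truncation selection rejects and redraws any
    replicate containing a copy number above the bound (the new draw
    advances the same seeded stream, so the accepted sequence is
    reproducible). Aborts if the acceptance rate falls below 10^-4.
    """
    rng = np.random.default_rng(seed)
    replicates: list[dict[str, list[int]]] = []
    attempts = 0
    while len(replicates) < n_reps:
        attempts += 1
        g = simulate_genealogy(model, rng)
        muts = drop_mutations(g, theta, rng)
        sample = stepwise_copy_number(g, muts, root_cn, rng)
        if max_cn is not None and any(
            cn > max_cn for cns in sample.values() for cn in cns
        ):
            if attempts >= 10_000 and len(replicates) / attempts < 1e-4:
                raise RuntimeError(
                    f"truncation-selection acceptance rate below 1e-4 "
                    f"({len(replicates)}/{attempts}); lower theta or raise max_cn"
                )
            continue
        replicates.append(sample)
    return SimulationResult(replicates=replicates, attempts=attempts)


def variation_summary(
    sample: dict[str, list[int]],
    groups: dict[str, list[str]] | None = None,
    *,
    pooled_between: bool = False,
) -> dict[str, dict[str, float]]:
    """Within- and between-species copy-number variation of one sample.

    Within: sample variance (ddof=1) of the haploid CNs of each species.
    Between: variance of the per-species mean CNs for each named group
    (or, with ``pooled_between``, the variance pooling all haplotypes of
    the group's species).
    """
    within = {}
    for sp, cns in sample.items():
        if len(cns) < 2:
            raise ValueError(f"need >=2 haplotypes for {sp}")
        within[sp] = float(np.var(cns, ddof=1))
    if groups is None:
        groups = {"all": sorted(sample)} if len(sample) > 1 else {}
    between = {}
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {name!r} needs >=2 species")
        if pooled_between:
            pooled = [cn for sp in members for cn in sample[sp]]
            between[name] = float(np.var(pooled, ddof=1))
        else:
            means = [float(np.mean(sample[sp])) for sp in members]
            between[name] = float(np.var(means, ddof=1))
    return {"within": within, "between": between}


def haplotypes_from_genotypes(table: pd.DataFrame) -> dict[str, list[int]]:
    """Expand a diploid genotype table to per-species haploid CN lists.

    Expects columns species, individual, allele1, allele2.
    """
    required = {"species", "individual", "allele1", "allele2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    out: dict[str, list[int]] = {}
    for _, row in table.iterrows():
        out.setdefault(row["species"], []).extend(
            [int(row["allele1"]), int(row["allele2"])]
        )
    return out


def obs_vs_null_heatmap(
    obs: pd.DataFrame,
    model: PopModel,
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID,
    *,
    n_reps: int = 1000,
    root_cn: int = 5,
    max_cn: int | None = 12,
    seed: int = 0,
    groups: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed/expected variation ratios and empirical p-values per θ.

    Rows are comparisons ('within:SPECIES' and 'between:GROUP'), columns θ
    values. Each cell holds observed variation ÷ mean simulated variation;
    the companion frame holds the empirical one-sided p-value, the
    fraction of simulated values at or below the observed one (small p ⇒
    observed variation lower than the neutral expectation).
    """
    haplos = haplotypes_from_genotypes(obs)
    scored = {
        sp: cns
        for sp, cns in haplos.items()
        if len(cns) >= 6 and sp in model.samples
    }
    if not scored:
        raise ValueError(
            "no species with >=6 observed haplotypes that are also in the model"
        )
    if groups is None:
        eligible = [sp for sp in model.samples if sp in scored]
        groups = {"all": eligible} if len(eligible) >= 2 else {}
    obs_summary = variation_summary(scored, groups or None)
    rows = [f"within:{sp}" for sp in sorted(scored)] + [
        f"between:{g}" for g in sorted(groups)
    ]
    ratios = pd.DataFrame(index=rows, columns=list(theta_grid), dtype=float)
    pvals = pd.DataFrame(index=rows, columns=list(theta_grid), dtype=float)
    for k, theta in enumerate(theta_grid):
        sim = simulate_copy_numbers(
            model,
            theta,
            root_cn=root_cn,
            n_reps=n_reps,
            seed=seed + k,
            max_cn=max_cn,
        )
        null: dict[str, list[float]] = {row: [] for row in rows}
        for rep in sim.replicates:
            summary = variation_summary(rep, groups or None)
            for sp in sorted(scored):
                if sp in summary["within"]:
                    null[f"within:{sp}"].append(summary["within"][sp])
            for gname in sorted(groups):
                null[f"between:{gname}"].append(summary["between"][gname])
        for row in rows:
            kind, name = row.split(":", 1)
            observed = obs_summary[kind][name]
            sims = np.asarray(null[row])
            mean_sim = sims.mean()
            ratios.loc[row, theta] = observed / mean_sim if mean_sim > 0 else np.nan
            pvals.loc[row, theta] = float(np.mean(sims <= observed))
    return ratios, pvals


def observed_combinations(obs: dict[str, tuple]) -> list[dict[str, int]]:
    """Cartesian expansion of per-species allele sets (helper for tests)."""
    keys = sorted(obs)
    return [
        dict(zip(keys, combo)) for combo in itertools.product(*(obs[k] for k in keys))
    ]
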