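"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the three classes of real inputs the analyses
consume: mucin-like coding sequences with planted in-frame 69-nt repeat
arrays (GenBank-style CDS), diploid repeat copy-number genotype tables
with per-species allele ranges (PCR-genotyping panels), and gene × sample
expression matrices with a planted cluster of tissue-specific genes
(GTEx-like RPKM). Every generator is a pure function of (config, seed)
and returns a machine-readable truth sidecar; recovery tests consume only
the sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

# codon pools: repeat units are T/S/P-biased (each T/S is a potential
# O-glycosylation site); flanks avoid T/S so ts_fraction separates them
_TS_POOL = ["ACT", "ACC", "ACA", "TCT", "TCC", "AGC"]  # Thr/Ser
_P_POOL = ["CCT", "CCA"]
_OTHER_POOL = ["GCT", "CAA", "GAA", "GGT"]  # Ala/Gln/Glu/Gly
_FLANK_POOL = ["CTT", "GGA", "AAA", "GAT", "TTT", "ATG", "CGT", "GTT"]

_BASES = "ACGT"


def _random_unit(rng: np.random.Generator, n_codons: int, ts_weight: float) -> str:
    """A T/S/P-biased repeat unit; expected T+S codon share >= ts_weight."""
    pools = [_TS_POOL, _P_POOL, _OTHER_POOL]
    weights = [ts_weight, (1 - ts_weight) * 0.6, (1 - ts_weight) * 0.4]
    codons = []
    for _ in range(n_codons):
        pool = pools[rng.choice(3, p=np.array(weights) / sum(weights))]
        codons.append(pool[rng.integers(len(pool))])
    return "".join(codons)


def _random_flank(rng: np.random.Generator, n_nt: int) -> str:
    n_codons = n_nt // 3
    return "".join(
        _FLANK_POOL[rng.integers(len(_FLANK_POOL))] for _ in range(n_codons)
    )


def _n_matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


_STOPS = {"TAA", "TAG", "TGA"}


def _mutate(
    seq: str,
    positions: list[int],
    rng: np.random.Generator,
    events: list,
    tag: tuple,
) -> str:
    """Substitute each listed position to a different base, avoiding stops."""
    s = list(seq)
    for pos in positions:
        old = s[pos]
        codon_start = pos - pos % 3
        choices = []
        for b in _BASES:
            if b == old:
                continue
            s[pos] = b
            if "".join(s[codon_start : codon_start + 3]) not in _STOPS:
                choices.append(b)
        new = str(rng.choice(choices))
        s[pos] = new
        events.append((*tag, int(pos), old, new))
    return "".join(s)


@dataclass
class CdsFamilyConfig:
    """Configuration for the orthologous CDS family generator.

    ``copy_numbers`` plants per-species repeat copy numbers (defaults
    mirror the great-ape reference-genome range 5–7). ``ortholog_marks``
    private substitutions distinguish ancestral units from one another;
    ``subs_per_unit`` species-level substitutions accumulate on each
    ortholog independently (drawn at never-reused sites, so pairwise
    differences between orthologs add exactly — infinite-sites
    bookkeeping). ``burst`` maps species to a count of species-private
    duplicates of one unit, the recurrent-expansion signature.
    """

    species: tuple[str, ...] = ("Human", "Chimpanzee", "Gorilla", "Orangutan")
    copy_numbers: dict[str, int] = field(
        default_factory=lambda: {
            "Human": 6,
            "Chimpanzee": 5,
            "Gorilla": 5,
            "Orangutan": 7,
        }
    )
    unit_length_nt: int = 69
    flank5_nt: int = 60
    flank3_nt: int = 60
    ortholog_marks: int = 4
    subs_per_unit: int = 1
    burst: dict[str, int] = field(default_factory=dict)
    burst_marks: int = 6
    ts_weight: float = 0.55

    def __post_init__(self) -> None:
        for sp in self.species:
            if self.copy_numbers.get(sp, 0) < 1 and sp not in self.burst:
                raise ValueError(f"no copy number configured for {sp}")


def make_cds_family(cfg: CdsFamilyConfig, seed: int) -> dict:
    """Generate orthologous CDS with planted repeats and a truth sidecar.

    Returns {'sequences': {species: cds}, 'truth': {...}} where truth
    records per-species unit coordinates and sequences, copy numbers,
    every substitution event, and the ancestral unit sequences. Flank/unit
    boundaries are planted unambiguously (the 3 nt on either side of the
    array differ from the periodic continuation), so coordinates are
    identifiable.
    """
    rng = np.random.default_rng(seed)
    L = cfg.unit_length_nt
    n_codons = L // 3
    base = _random_unit(rng, n_codons, cfg.ts_weight)
    events: list = []

    n_anc = max(
        [cfg.copy_numbers.get(sp, 1) for sp in cfg.species]
        + [1]
    )
    # distinct marks per ancestral unit; each unit has its own pool of
    # never-reused sites for later species-level substitutions
    anc_units: list[str] = []
    unused_sites: list[list[int]] = []
    for j in range(n_anc):
        sites = list(rng.permutation(L))
        marks, rest = sites[: cfg.ortholog_marks], sites[cfg.ortholog_marks :]
        anc_units.append(
            _mutate(base, marks, rng, events, ("ancestor", j))
        )
        unused_sites.append(rest)

    sequences: dict[str, str] = {}
    truth_units: dict[str, list] = {}
    truth_cn: dict[str, int] = {}
    for sp in cfg.species:
        if sp in cfg.burst:
            n_copies = cfg.burst[sp]
            sites = list(rng.permutation(L))
            burst_unit = _mutate(
                anc_units[0], sites[: cfg.burst_marks], rng, events, ("burst", sp)
            )
            units = [burst_unit] * n_copies
        else:
            n_copies = cfg.copy_numbers[sp]
            units = []
            for j in range(n_copies):
                k = cfg.subs_per_unit
                take, unused_sites[j] = unused_sites[j][:k], unused_sites[j][k:]
                units.append(
                    _mutate(anc_units[j], take, rng, events, (sp, j))
                )
        flank5 = _random_flank(rng, cfg.flank5_nt)
        flank3 = _random_flank(rng, cfg.flank3_nt)
        # unambiguous boundaries: the flank edges must disagree with the
        # periodic continuation at >=2 of 3 nt on each side
        while _n_matches(flank5[-3:], base[-3:]) > 1:
            flank5 = _random_flank(rng, cfg.flank5_nt)
        while _n_matches(flank3[:3], base[:3]) > 1:
            flank3 = _random_flank(rng, cfg.flank3_nt)
        cds = flank5 + "".join(units) + flank3
        sequences[sp] = cds
        start = cfg.flank5_nt
        truth_units[sp] = [
            (start + i * L, start + (i + 1) * L, u) for i, u in enumerate(units)
        ]
        truth_cn[sp] = n_copies
    return {
        "sequences": sequences,
        "truth": {
            "base_unit": base,
            "ancestral_units": anc_units,
            "copy_numbers": truth_cn,
            "units": truth_units,
            "events": events,
            "unit_length_nt": L,
        },
    }


def make_detection_fixture(
    rng: np.random.Generator,
    *,
    unit_length_nt: int = 69,
    min_copies: int = 3,
    max_copies: int = 8,
    max_subs_per_unit: int = 6,
    flank_nt: int = 60,
    ts_weight: float = 0.55,
) -> dict:
    """One CDS with a planted tandem array, for detection-recovery tests.

    Copy number is uniform on [min_copies, max_copies]; each unit carries
    0..max_subs_per_unit substitutions (at 6 of 69 sites, per-unit identity
    to the array consensus stays >= 0.91). Returns the CDS and the planted
    coordinates.
    """
    L = unit_length_nt
    base = _random_unit(rng, L // 3, ts_weight)
    n_copies = int(rng.integers(min_copies, max_copies + 1))
    units = []
    for _ in range(n_copies):
        k = int(rng.integers(0, max_subs_per_unit + 1))
        pos = list(rng.choice(L, size=k, replace=False))
        units.append(_mutate(base, pos, rng, [], ("fixture", 0)))
    flank5 = _random_flank(rng, flank_nt)
    flank3 = _random_flank(rng, flank_nt)
    while _n_matches(flank5[-3:], base[-3:]) > 1:
        flank5 = _random_flank(rng, flank_nt)
    while _n_matches(flank3[:3], base[:3]) > 1:
        flank3 = _random_flank(rng, flank_nt)
    cds = flank5 + "".join(units) + flank3
    return {
        "cds": cds,
        "copy_number": n_copies,
        "start": flank_nt,
        "end": flank_nt + n_copies * L,
        "units": units,
    }


@dataclass
class GenotypeConfig:
    """Diploid genotype-table generator settings.

    Default allele sets mirror the observed great-ape haploid copy-number
    ranges (Human 5–6, Chimpanzee 5, Gorilla 4–5, Orangutan 6–7).
    ``heterozygous_species`` forces every individual of those species to
    carry both alleles of a 2-allele set (the all-heterozygous baboon
    pattern).
    """

    species_alleles: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "Human": (5, 6),
            "Chimpanzee": (5,),
            "Gorilla": (4, 5),
            "Orangutan": (6, 7),
        }
    )
    n_individuals: int = 4
    heterozygous_species: tuple[str, ...] = ()


def make_genotype_table(cfg: GenotypeConfig, seed: int) -> pd.DataFrame:
    """Sample a diploid genotype table (species, individual, allele1, allele2)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in sorted(cfg.species_alleles):
        alleles = cfg.species_alleles[sp]
        if not alleles:
            raise ValueError(f"empty allele set for {sp}")
        for i in range(cfg.n_individuals):
            if sp in cfg.heterozygous_species:
                if len(alleles) != 2:
                    raise ValueError(
                        f"heterozygous species {sp} needs exactly 2 alleles"
                    )
                a1, a2 = alleles
            else:
                a1, a2 = rng.choice(alleles, size=2, replace=True)
            rows.append(
                {
                    "species": sp,
                    "individual": f"{sp}_{i + 1}",
                    "allele1": int(a1),
                    "allele2": int(a2),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExpressionConfig:
    """Expression-matrix generator settings (GTEx-like layout).

    Defaults emulate the chromosome-4 scan: 3,600 genes with 36 planted
    tissue-specific genes, 10 of them in one contiguous cluster around the
    focal gene; 53 tissues (1 target + 52 others) with 5 samples each;
    log-normal noise; multiplicative fold-change in the target tissue.
    """

    n_genes: int = 3600
    n_tissues: int = 53
    samples_per_tissue: int = 5
    target_tissue: str = "minor salivary gland"
    chrom: str = "chr4"
    n_specific: int = 36
    cluster_size: int = 10
    cluster_start: int = 1800
    fold_change: float = 5.0
    sigma_log: float = 1.0
    focal_name: str = "MUC7"

    def __post_init__(self) -> None:
        if self.cluster_size > self.n_genes:
            raise ValueError("cluster larger than the chromosome gene count")
        if self.cluster_start + self.cluster_size > self.n_genes:
            raise ValueError("cluster extends past the gene order")
        if self.cluster_size > self.n_specific:
            raise ValueError("cluster_size cannot exceed n_specific")


def make_expression_matrix(
    cfg: ExpressionConfig, seed: int
) -> tuple[ExpressionMatrix, dict]:
    """Generate the matrix, tissue labels and truth sidecar.

    Baseline expression is log-normal per gene and sample; the planted
    specific genes (contiguous cluster plus scattered singletons) are
    up-shifted by ``fold_change`` in every target-tissue sample. With
    fold_change == 1 no signal is planted (calibration mode).
    """
    rng = np.random.default_rng(seed)
    n_samples = cfg.n_tissues * cfg.samples_per_tissue
    tissue_names = [cfg.target_tissue] + [
        f"tissue_{i:02d}" for i in range(1, cfg.n_tissues)
    ]
    sample_ids = []
    sample_tissue = []
    for t in tissue_names:
        for r in range(cfg.samples_per_tissue):
            sample_ids.append(f"{t}|s{r + 1}".replace(" ", "_"))
            sample_tissue.append(t)

    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    cluster_idx = list(range(cfg.cluster_start, cfg.cluster_start + cfg.cluster_size))
    focal_idx = cluster_idx[len(cluster_idx) // 2]
    genes[focal_idx] = cfg.focal_name

    n_scattered = cfg.n_specific - cfg.cluster_size
    outside = np.setdiff1d(np.arange(cfg.n_genes), cluster_idx)
    scattered = sorted(
        rng.choice(outside, size=n_scattered, replace=False).tolist()
    )
    specific_idx = sorted(cluster_idx + scattered)

    gene_means = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    noise = rng.lognormal(mean=0.0, sigma=cfg.sigma_log, size=(cfg.n_genes, n_samples))
    values = gene_means[:, None] * noise
    target_cols = np.asarray([t == cfg.target_tissue for t in sample_tissue])
    values[np.ix_(specific_idx, np.flatnonzero(target_cols))] *= cfg.fold_change

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        gene_info=pd.DataFrame(
            {"chrom": cfg.chrom, "position": np.arange(cfg.n_genes) * 10_000 + 1},
            index=genes,
        ),
        tissues=pd.Series(sample_tissue, index=sample_ids, name="tissue"),
    )
    truth = {
        "target_tissue": cfg.target_tissue,
        "specific_genes": [genes[i] for i in specific_idx],
        "cluster_genes": [genes[i] for i in cluster_idx],
        "cluster_span": (cfg.cluster_start, cfg.cluster_start + cfg.cluster_size),
        "focal_gene": genes[focal_idx],
        "fold_change": cfg.fold_change,
    }
    return matrix, truth
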