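"""Detection and divergence analysis of in-frame subexonic tandem repeats.

Mucin PTS repeats are tandem copies of a short in-frame unit (69 nt, 23
codons in MUC7) inside a single coding exon. This module locates such
units with a frame-constrained seed-and-extend search, quantifies the
threonine+serine content that determines O-glycosylation potential, and
partitions pairwise repeat divergence into synonymous and nonsynonymous
fractional counts (Nei–Gojobori pathway averaging). Clustering of the
pairwise-difference matrix and a nearest-neighbour recurrence score expose
species-private duplication bursts, the signature of recurrent repeat
expansion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from ._codon import pathway_counts, translate

_DNA = set("ACGTN")
_GAPS = set("-.")


@dataclass
class CodingSequence:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in {self.id}: {sorted(bad)}")


@dataclass
class RepeatAnnotation:
    """Tandem repeat units within one coding sequence.

    ``units`` are (start, end, sequence) with 0-based half-open coordinates
    on the CDS; all full units share ``unit_length_nt``. A trailing partial
    copy, if present, is stored separately and never counted as a unit.
    """

    source_id: str
    unit_length_nt: int = 69
    units: list[tuple[int, int, str]] = field(default_factory=list)
    partial_trailing: tuple[int, int, str] | None = None

    @property
    def copy_number(self) -> int:
        return len(self.units)

    def unit_sequences(self) -> list[str]:
        return [u[2] for u in self.units]


@dataclass
class DivergenceRecord:
    """Pairwise comparison of two equal-length, in-frame repeat units."""

    id_a: str
    id_b: str
    species_a: str
    species_b: str
    nt_diffs: int
    syn_diffs: float
    nonsyn_diffs: float
    aa_diffs: int
    ts_count_diff: int


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float  # NaN marks an undefined R² (zero-variance response)
    n: int


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class _Consensus:
    """Running per-position majority consensus over accepted units."""

    def __init__(self, unit: str) -> None:
        self.counts = [{c: 1} for c in unit]
        self.seq = unit

    def add(self, unit: str) -> None:
        new = []
        for i, c in enumerate(unit):
            self.counts[i][c] = self.counts[i].get(c, 0) + 1
            best = self.seq[i]
            if self.counts[i][c] > self.counts[i][best]:
                best = c
            new.append(best)
        self.seq = "".join(new)


def detect_repeats(
    cds: CodingSequence,
    unit_length_nt: int = 69,
    min_units: int = 2,
    min_identity: float = 0.8,
) -> RepeatAnnotation:
    """Find the longest frame-aligned tandem run of ``unit_length_nt`` units.

    Seed-and-extend: every codon-aligned start position seeds a candidate
    run; successive adjacent windows are accepted while their identity to
    the running consensus is at least ``min_identity``. The best run
    (most units, then leftmost) is returned; a trailing fragment matching
    the consensus prefix is flagged as partial, never counted. Sequences
    shorter than two units yield an empty annotation.
    """
    if unit_length_nt % 3:
        raise ValueError("unit_length_nt must be divisible by 3")
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.5, 1]")
    seq = cds.sequence
    L = unit_length_nt
    empty = RepeatAnnotation(source_id=cds.id, unit_length_nt=L)
    if len(seq) < 2 * L:
        return empty

    # best run = most units, then fewest total mismatches to the final
    # consensus (a frame- or period-shifted run of equal length drags flank
    # nucleotides into a window and pays for them here), then leftmost —
    # the conventional phase for an array with a trailing partial copy
    best = (0, 0, 0)
    best_start, best_count, best_consensus = -1, 0, None
    for start in range(0, len(seq) - 2 * L + 1, 3):
        consensus = _Consensus(seq[start : start + L])
        count = 1
        pos = start + L
        while pos + L <= len(seq):
            window = seq[pos : pos + L]
            if _identity(window, consensus.seq) < min_identity:
                break
            consensus.add(window)
            count += 1
            pos += L
        mismatches = sum(
            a != b
            for i in range(count)
            for a, b in zip(seq[start + i * L : start + (i + 1) * L], consensus.seq)
        )
        key = (count, -mismatches, -start)
        if key > best:
            best = key
            best_start, best_count, best_consensus = start, count, consensus

    if best_count < min_units:
        return empty
    units = [
        (best_start + i * L, best_start + (i + 1) * L, seq[best_start + i * L : best_start + (i + 1) * L])
        for i in range(best_count)
    ]
    ann = RepeatAnnotation(source_id=cds.id, unit_length_nt=L, units=units)
    tail_start = best_start + best_count * L
    tail = seq[tail_start : tail_start + L]
    if 3 <= len(tail) < L and _identity(tail, best_consensus.seq[: len(tail)]) >= min_identity:
        ann.partial_trailing = (tail_start, tail_start + len(tail), tail)
    return ann


def ts_fraction(protein: str) -> float:
    """Fraction of non-gap residues that are threonine or serine."""
    residues = [c for c in protein.upper() if c not in _GAPS]
    if not residues:
        raise ValueError("empty or all-gap protein sequence")
    return sum(c in "TS" for c in residues) / len(residues)


def _ts_count(protein: str) -> int:
    return sum(c in "TS" for c in protein)


def pairwise_divergence(
    unit_a: str,
    unit_b: str,
    *,
    id_a: str = "a",
    id_b: str = "b",
    species_a: str = "",
    species_b: str = "",
) -> DivergenceRecord:
    """Partitioned divergence between two equal-length in-frame units.

    Codon pairs are compared in frame; multi-hit codons are resolved by
    Nei–Gojobori pathway averaging, so ``syn_diffs + nonsyn_diffs`` equals
    the nucleotide Hamming distance exactly. Codon pairs containing a stop
    codon are excluded from all counts (with a warning) to keep that
    closure exact.
    """
    unit_a, unit_b = unit_a.upper(), unit_b.upper()
    if len(unit_a) != len(unit_b):
        raise ValueError("units have unequal lengths; pre-align them first")
    if len(unit_a) % 3:
        raise ValueError("unit length must be divisible by 3")
    nt = syn = nonsyn = aa = 0.0
    prot_a: list[str] = []
    prot_b: list[str] = []
    for i in range(0, len(unit_a), 3):
        ca, cb = unit_a[i : i + 3], unit_b[i : i + 3]
        aa_a, aa_b = translate(ca), translate(cb)
        if "*" in (aa_a, aa_b):
            warnings.warn(
                f"stop codon at nt {i} in {id_a}/{id_b}; codon excluded from counts"
            )
            continue
        prot_a.append(aa_a)
        prot_b.append(aa_b)
        d = sum(x != y for x, y in zip(ca, cb))
        nt += d
        if d:
            s, n = pathway_counts(ca, cb)
            syn += s
            nonsyn += n
            aa += aa_a != aa_b
    return DivergenceRecord(
        id_a=id_a,
        id_b=id_b,
        species_a=species_a,
        species_b=species_b,
        nt_diffs=int(nt),
        syn_diffs=syn,
        nonsyn_diffs=nonsyn,
        aa_diffs=int(aa),
        ts_count_diff=abs(_ts_count("".join(prot_a)) - _ts_count("".join(prot_b))),
    )


@dataclass
class DivergenceMatrix:
    """All-vs-all repeat-unit divergence with Species_Index labels (5′→3′)."""

    labels: list[str]
    species: list[str]
    nt: np.ndarray
    records: dict[tuple[str, str], DivergenceRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nt, index=self.labels, columns=self.labels)


def divergence_matrix(
    annotations: list[RepeatAnnotation],
    species: list[str] | None = None,
) -> DivergenceMatrix:
    """Assemble the symmetric pairwise nucleotide-difference matrix.

    Units are labelled ``Species_i`` with i counting from the 5′ end of
    each source sequence. Partial trailing copies are never included.
    """
    if species is None:
        species = [ann.source_id for ann in annotations]
    units: list[tuple[str, str, str]] = []  # (label, species, seq)
    for ann, sp in zip(annotations, species):
        for i, (_, _, seq) in enumerate(ann.units):
            units.append((f"{sp}_{i + 1}", sp, seq))
    if len(units) < 2:
        raise ValueError("need at least two repeat units in total")
    lengths = {len(u[2]) for u in units}
    if len(lengths) > 1:
        raise ValueError(f"mixed unit lengths {sorted(lengths)}")
    n = len(units)
    nt = np.zeros((n, n), dtype=float)
    records: dict[tuple[str, str], DivergenceRecord] = {}
    for i in range(n):
        for j in range(i + 1, n):
            rec = pairwise_divergence(
                units[i][2],
                units[j][2],
                id_a=units[i][0],
                id_b=units[j][0],
                species_a=units[i][1],
                species_b=units[j][1],
            )
            nt[i, j] = nt[j, i] = rec.nt_diffs
            records[(units[i][0], units[j][0])] = rec
    return DivergenceMatrix(
        labels=[u[0] for u in units],
        species=[u[1] for u in units],
        nt=nt,
        records=records,
    )


def cluster_repeats(matrix: DivergenceMatrix, n_clusters: int | None = None):
    """Average-linkage (UPGMA) hierarchical clustering of the units.

    Returns (linkage_matrix, flat_cluster_labels); the flat cut uses
    ``n_clusters`` groups (default: number of distinct species).
    """
    if matrix.nt.shape[0] < 2:
        raise ValueError("need at least two units to cluster")
    condensed = squareform(matrix.nt, checks=False)
    Z = linkage(condensed, method="average")
    if n_clusters is None:
        n_clusters = len(set(matrix.species))
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, flat


def recurrence_score(matrix: DivergenceMatrix) -> dict[str, float | None]:
    """Per-species fraction of units whose nearest neighbour is same-species.

    Nearest-neighbour ties are broken toward a different-species unit
    (conservative: lowers the score). 1.0 flags a fully species-private
    cluster — the signature of a lineage-specific duplication burst.
    Species with a single unit get ``None`` (score undefined).
    """
    species = np.asarray(matrix.species)
    if len(set(species)) < 2:
        raise ValueError("need at least two species")
    scores: dict[str, float | None] = {}
    n = len(species)
    for sp in sorted(set(species)):
        idx = np.flatnonzero(species == sp)
        if idx.size < 2:
            scores[sp] = None
            continue
        same = 0
        for i in idx:
            dists = matrix.nt[i].copy()
            dists[i] = np.inf
            best = dists.min()
            tied = np.flatnonzero(dists == best)
            # tie toward a different species
            if all(species[j] == sp for j in tied):
                same += 1
        scores[sp] = same / idx.size
    return scores


def _ols(x, y) -> RegressionSummary:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor; regression undefined")
    if np.var(y) == 0:
        # slope 0 through the constant; R² undefined by convention
        return RegressionSummary(slope=0.0, intercept=float(y[0]), r_squared=math.nan, n=x.size)
    res = linregress(x, y)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=x.size,
    )


def divergence_regressions(
    records: list[DivergenceRecord],
    copy_counts: dict[str, int] | None = None,
    ts_counts: dict[str, int] | None = None,
) -> dict[str, RegressionSummary]:
    """OLS summaries of the three divergence relationships.

    'nonsyn_vs_syn': nonsynonymous vs synonymous pairwise differences
    (strong correlation ⇒ near-neutral sequence turnover);
    'ts_vs_nt': T+S-count difference vs nucleotide differences (flat ⇒ the
    T/S content is preserved independently of divergence);
    'ts_vs_copies': total T+S count vs repeat copy number per species
    (requires ``copy_counts`` and ``ts_counts``).
    """
    out: dict[str, RegressionSummary] = {}
    out["nonsyn_vs_syn"] = _ols(
        [r.syn_diffs for r in records], [r.nonsyn_diffs for r in records]
    )
    out["ts_vs_nt"] = _ols(
        [r.nt_diffs for r in records], [r.ts_count_diff for r in records]
    )
    if copy_counts is not None and ts_counts is not None:
        keys = sorted(set(copy_counts) & set(ts_counts))
        out["ts_vs_copies"] = _ols(
            [copy_counts[k] for k in keys], [ts_counts[k] for k in keys]
        )
    return out
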