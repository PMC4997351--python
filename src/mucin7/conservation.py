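"""Protein-alignment conservation profiling across functional domains.

Per-column conservation is scored with the Jensen–Shannon divergence
between the column's residue distribution (with pseudocounts) and a
background amino-acid distribution — the Capra–Singh formulation, base-2
logs, naturally bounded in [0, 1]. Segment summaries average the column
scores over named functional domains (signal peptide, histatin-like
domain, glycosylated flanks, leucine-zipper region). A companion codon
alignment yields per-segment nonsynonymous/synonymous variation ratios
(Nei–Gojobori counting), optionally normalized by the whole-alignment
ratio so segments can be compared on a common scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._codon import pair_sites, pathway_counts, translate_codon

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# BLOSUM62 background amino-acid frequencies (order as AMINO_ACIDS),
# normalized to sum to 1.
_BLOSUM62_BG = np.array(
    [
        0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
        0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072,
    ]
)
BLOSUM62_BACKGROUND = _BLOSUM62_BG / _BLOSUM62_BG.sum()
UNIFORM_BACKGROUND = np.full(20, 1 / 20)

_GAPS = set("-.")


@dataclass
class ProteinAlignment:
    """Equal-length aligned protein sequences with species labels."""

    labels: list[str]
    sequences: list[str]
    codon_sequences: list[str] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal lengths")
        if len(self.labels) != len(self.sequences):
            raise ValueError("one label per sequence required")
        if self.codon_sequences is not None:
            (aa_len,) = lengths
            for cs in self.codon_sequences:
                if len(cs) != 3 * aa_len:
                    raise ValueError("codon alignment must have 3x the protein columns")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.sequences)


@dataclass
class SegmentMap:
    """Named half-open [start, end) intervals over alignment columns."""

    segments: dict[str, tuple[int, int]]

    def validate(self, n_columns: int) -> None:
        spans = sorted(self.segments.values())
        for (s, e) in spans:
            if not (0 <= s < e <= n_columns):
                raise ValueError(f"segment ({s}, {e}) outside alignment")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("segments overlap")


@dataclass
class ConservationProfile:
    scores: np.ndarray  # per-column, NaN = missing
    gap_fraction: np.ndarray
    gap_threshold: float = 0.3
    background: np.ndarray = field(default_factory=lambda: BLOSUM62_BACKGROUND)


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def jsd_column_score(
    column: str,
    background: np.ndarray | None = None,
    pseudocount: float | None = None,
    gap_threshold: float = 0.3,
) -> float:
    """Jensen–Shannon divergence of one alignment column from background.

    ``column`` is the stacked residues of the column (one character per
    sequence). The column distribution uses ``pseudocount`` (default
    1/n_sequences) on all 20 amino acids. Columns whose gap fraction
    exceeds ``gap_threshold``, or with fewer than two residues, return NaN.
    """
    q = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    q = q / q.sum()
    n = len(column)
    if n == 0:
        return math.nan
    residues = [c for c in column.upper() if c not in _GAPS and c in AMINO_ACIDS]
    gap_fraction = 1 - len(residues) / n
    if gap_fraction > gap_threshold or len(residues) < 2:
        return math.nan
    pc = 1.0 / n if pseudocount is None else pseudocount
    counts = np.full(20, pc)
    for c in residues:
        counts[AMINO_ACIDS.index(c)] += 1
    p = counts / counts.sum()
    return _jsd(p, q)


def conservation_profile(
    alignment: ProteinAlignment,
    background: np.ndarray | None = None,
    pseudocount: float | None = None,
    gap_threshold: float = 0.3,
) -> ConservationProfile:
    """Per-column JSD conservation scores for a whole alignment."""
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    scores = np.empty(alignment.n_columns)
    gaps = np.empty(alignment.n_columns)
    for i in range(alignment.n_columns):
        col = alignment.column(i)
        gaps[i] = sum(c in _GAPS for c in col) / len(col)
        scores[i] = jsd_column_score(col, bg, pseudocount, gap_threshold)
    return ConservationProfile(
        scores=scores, gap_fraction=gaps, gap_threshold=gap_threshold, background=bg
    )


def segment_conservation(
    profile: ConservationProfile, segments: SegmentMap
) -> dict[str, float]:
    """Mean conservation score per segment over non-missing columns."""
    segments.validate(len(profile.scores))
    out: dict[str, float] = {}
    for name, (s, e) in segments.segments.items():
        vals = profile.scores[s:e]
        vals = vals[~np.isnan(vals)]
        out[name] = float(vals.mean()) if vals.size else math.nan
    return out


def _pair_segment_counts(
    codon_a: str, codon_b: str
) -> tuple[float, float, float, float]:
    """(syn_diffs, nonsyn_diffs, syn_sites, nonsyn_sites) for one pair of
    aligned codon strings; gapped or stop-containing codon columns skipped."""
    sd = nd = ss = ns = 0.0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i : i + 3], codon_b[i : i + 3]
        if set(ca) & _GAPS or set(cb) & _GAPS:
            continue
        if translate_codon(ca) == "*" or translate_codon(cb) == "*":
            continue
        s_sites, n_sites = pair_sites(ca, cb)
        ss += s_sites
        ns += n_sites
        if ca != cb:
            s, n = pathway_counts(ca, cb)
            sd += s
            nd += n
    return sd, nd, ss, ns


def segment_ns_ratio(
    alignment: ProteinAlignment,
    segments: SegmentMap,
    *,
    normalize: str = "whole",
    exclude_segments: tuple[str, ...] = ("PTS-repeats",),
) -> dict[str, float]:
    """Per-segment normalized nonsynonymous/synonymous variation ratio.

    Over all sequence pairs and the segment's codon columns, counts are
    concatenated: ratio = (ΣNd/ΣN) ÷ (ΣSd/ΣS) with Nei–Gojobori fractional
    differences and site counts. Segments with no synonymous differences
    are reported as NaN. ``normalize`` is 'whole' (divide by the ratio over
    all included segments), 'max' (divide by the largest segment ratio) or
    'none'. Copy-number-variable repeat segments are excluded by name by
    default, since alignment there is unreliable.
    """
    if alignment.codon_sequences is None:
        raise ValueError("segment_ns_ratio requires a codon alignment")
    if normalize not in ("whole", "max", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    segments.validate(alignment.n_columns)
    included = {
        name: span
        for name, span in segments.segments.items()
        if name not in exclude_segments
    }

    def _raw_ratio(spans: list[tuple[int, int]]) -> float:
        sd = nd = ss = ns = 0.0
        for a, b in itertools.combinations(range(len(alignment.labels)), 2):
            for (s, e) in spans:
                ca = alignment.codon_sequences[a][3 * s : 3 * e]
                cb = alignment.codon_sequences[b][3 * s : 3 * e]
                d = _pair_segment_counts(ca, cb)
                sd += d[0]
                nd += d[1]
                ss += d[2]
                ns += d[3]
        if sd == 0 or ss == 0 or ns == 0:
            return math.nan
        return (nd / ns) / (sd / ss)

    raw = {name: _raw_ratio([span]) for name, span in included.items()}
    if normalize == "none":
        return raw
    if normalize == "whole":
        denom = _raw_ratio(list(included.values()))
    else:
        finite = [v for v in raw.values() if not math.isnan(v)]
        denom = max(finite) if finite else math.nan
    if denom is None or math.isnan(denom) or denom == 0:
        return {name: math.nan for name in raw}
    return {name: v / denom for name, v in raw.items()}
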