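"""Genetic-code utilities: pathway-averaged synonymous/nonsynonymous counting.

Implements the Nei–Gojobori (1986) convention for partitioning nucleotide
differences between two codons into synonymous and nonsynonymous fractional
counts. When codons differ at more than one position, every mutational
pathway (ordering of the single-nucleotide steps) is considered and the
per-step classifications are averaged over pathways; pathways passing
through a stop codon are excluded from the average.

The implementation sums per-pathway counts over the pathway tree with a
path-counting recursion (uniform weight per admissible complete pathway).
Tests compare it against a brute-force enumeration over explicit position
orderings.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"

#: codon -> amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)


def translate_codon(codon: str) -> str:
    """Translate one codon; '*' for stops, 'X' for codons with ambiguity."""
    codon = codon.upper()
    return GENETIC_CODE.get(codon, "X")


def translate(seq: str) -> str:
    """Translate an in-frame DNA string codon by codon (no stop trimming)."""
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) difference counts for a codon pair.

    Averages over all mutational pathways from ``codon_a`` to ``codon_b``;
    each single-nucleotide step is synonymous iff it preserves the encoded
    amino acid. Pathways through stop codons are pruned; if every pathway is
    blocked by stops (possible only for multi-step pairs), stop-traversing
    pathways are readmitted so the pair still receives a full partition.
    The two counts always sum to the Hamming distance of the codons.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must be length 3")
    return _pathway_counts(codon_a, codon_b, allow_stops=False)


def _pathway_counts(a: str, b: str, allow_stops: bool) -> tuple[float, float]:
    syn, nonsyn, n_paths = _path_sums(a, b, allow_stops)
    if n_paths == 0:
        # every pathway runs through a stop: readmit them all
        syn, nonsyn, n_paths = _path_sums(a, b, allow_stops=True)
    return (syn / n_paths, nonsyn / n_paths)


def _path_sums(a: str, b: str, allow_stops: bool) -> tuple[float, float, int]:
    """(Σ syn, Σ nonsyn, #pathways) over admissible complete pathways a→b."""
    if a == b:
        return (0.0, 0.0, 1)
    syn_tot = nonsyn_tot = 0.0
    paths = 0
    for pos in range(3):
        if a[pos] == b[pos]:
            continue
        step = a[:pos] + b[pos] + a[pos + 1 :]
        if not allow_stops and translate_codon(step) == "*" and step != b:
            continue
        s_rest, n_rest, c = _path_sums(step, b, allow_stops)
        if c == 0:
            continue
        if translate_codon(a) == translate_codon(step):
            syn_tot += c + s_rest
            nonsyn_tot += n_rest
        else:
            nonsyn_tot += c + n_rest
            syn_tot += s_rest
        paths += c
    return (syn_tot, nonsyn_tot, paths)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Nei–Gojobori (synonymous, nonsynonymous) site counts for one codon.

    Per position, the synonymous fraction is the share of synonymous changes
    among the three single-nucleotide changes that do not create a stop
    codon; each position contributes one site in total, so the two counts
    sum to 3.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    syn_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(mutant) == "*":
                continue
            valid += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if valid:
            syn_sites += syn / valid
    return (syn_sites, 3.0 - syn_sites)


def pair_sites(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) site counts of two codons (Nei–Gojobori)."""
    sa, na = codon_sites(codon_a)
    sb, nb = codon_sites(codon_b)
    return ((sa + sb) / 2.0, (na + nb) / 2.0)
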