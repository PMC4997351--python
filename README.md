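# mucin7 — evolution of copy-number-variable subexonic mucin repeats

`mucin7` is a toolkit for studying the evolution of *subexonic tandem
repeats* — repeat units contained entirely within one coding exon, so that
copy-number change alters the protein in frame. The motivating case is the
salivary mucin MUC7, whose 69-bp (23 amino acid) proline/threonine/serine-rich
(PTS) repeats carry the protein's O-glycosylation sites, vary in copy number
within and between primate species, and appear to have expanded recurrently
and under adaptive constraint. The package is aimed at molecular
evolutionists who want to run the same battery of analyses on their own
repeat-bearing genes, and every stage can be exercised end to end on
synthetic data with known ground truth.

It provides five analysis modules and a synthetic-data generator:

- **`mucin7.repeats`** — frame-constrained detection of in-frame tandem
  repeat units in a CDS; T+S content; pairwise repeat divergence partitioned
  into synonymous and nonsynonymous fractional counts by Nei–Gojobori
  pathway averaging (so syn + nonsyn equals the nucleotide Hamming distance
  exactly); UPGMA clustering of the pairwise-difference matrix; a
  nearest-neighbour *recurrence score* per species (1.0 = all of a species'
  units are closest to other units of the same species, the signature of a
  species-private duplication burst); OLS summaries of the divergence
  relationships.
- **`mucin7.phylo_walk`** — a neutral copy-number random walk on a dated
  species tree: every Δt = 1 Myr each lineage gains or loses *r* copies with
  probability ½ (r ∈ {0.5, 1.0, 1.5, 2.0}/Myr by default), lineages share
  their trajectory until divergence. The variance of the terminal states
  over 1,000 replicates is the neutral null against which observed
  copy-number variance is tested with a one-sided Wilcoxon rank-sum test.
- **`mucin7.coalescent`** — a multispecies Wright–Fisher coalescent with a
  stepwise (±1, microsatellite-style) mutation model at population-scaled
  rate θ = 4·Ne·μ, optional truncation selection rejecting replicates with
  copy numbers above a bound (default 12), and observed-vs-null variation
  ratios over a θ grid (within species, and between species as the variance
  of species means).
- **`mucin7.expression`** — per-gene tissue-specificity p-values (one-sided
  rank-sum of the target tissue's samples against all others), calling of
  the most significant 1% per chromosome, and a 15-gene sliding-window scan
  over chromosomal gene order to localize clusters of tissue-specific genes.
- **`mucin7.conservation`** — per-column Jensen–Shannon-divergence
  conservation scores of a protein alignment against a BLOSUM62 background
  (Capra–Singh formulation, base-2, bounded in [0, 1]) and per-segment
  normalized nonsynonymous/synonymous variation ratios from a codon
  alignment.
- **`mucin7.synth`** — generators for all inputs: orthologous CDS families
  with planted repeat arrays and per-event truth sidecars, diploid
  copy-number genotype tables, and GTEx-like expression matrices with a
  planted cluster of tissue-specific genes.

## Worked example

The headline analysis asks: is the observed cross-species variation in
great-ape PTS-repeat copy number compatible with neutral drift? The walk
starts from 5 copies in the great-ape ancestor 11 Mya (splits at 11, 8 and
5 Mya); observed haploid states are Human {5, 6}, Chimpanzee {5},
Gorilla {4, 5}, Orangutan {6, 7}.

```python
from mucin7.phylo_walk import neutrality_test

report = neutrality_test(n_reps=1000, seed=1)
for rate, res in report.items():
    print(f"rate {rate:.1f} copies/Myr: p = {res['p_value']:.3g}")
```

prints

```
rate 0.5 copies/Myr: p = 0.0105
rate 1.0 copies/Myr: p = 6.81e-06
rate 1.5 copies/Myr: p = 1.37e-06
rate 2.0 copies/Myr: p = 1.38e-06
```

Each p-value is the one-sided rank-sum probability that the 8 enumerated
observed copy-number variances are as small as they are relative to 1,000
neutral terminal-state variances: at gain/loss rates of 1 copy/Myr and
above the observed variation is far below the neutral expectation
(p < 10⁻⁵), i.e. cross-species copy number looks constrained; at the
slowest rate (0.5/Myr) the signal sits at the p ≈ 0.01 boundary and
fluctuates with the simulation seed.

The same analyses are scriptable from the shell; an end-to-end demo over
synthetic data (CDS family → repeat detection → divergence and recurrence →
both simulators → expression scan → conservation) is:

```bash
mucin pipeline --config configs/demo.yaml --out demo_out
```

Its manifest records, among other things, a recurrence score of 1.0 for the
planted burst species (all five of its repeat units are species-private
duplicates) and 0.0 for the species with purely orthologous repeats, and an
expression scan that places the planted focal gene in the maximal 15-gene
window.

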