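# Methods

This note documents the models, defaults and numerical conventions behind
each module, the design choices made where several conventions were
defensible, and what the synthetic-data generators do and do not emulate.

## Repeat detection (`mucin7.repeats.detect_repeats`)

Repeat arrays are located by a frame-constrained seed-and-extend search:
every codon-aligned position seeds a candidate run of adjacent
`unit_length_nt` windows (default 69 nt), and a window is appended while its
identity to the running per-position majority consensus is at least
`min_identity` (default 0.8; `min_units` default 2). Among candidate runs
the detector keeps the one with the most units, then the fewest total
mismatches to the final consensus — a frame- or period-shifted run of equal
length drags flanking nucleotides into a window and pays for them here —
and finally the leftmost start. The leftmost rule is also the convention
for arrays with a trailing partial copy, which make the phase genuinely
ambiguous (an array of k units plus a trailing partial is equally consistent
with a leading partial plus k units); the trailing fragment is reported
separately and never counted. Manually curated repeat calls cannot be
reconstructed algorithmically, so these thresholds are declared defaults,
not reconstructions of any particular curation.

Coordinates are 0-based half-open internally; 1-based only in human-readable
output.

## Divergence partitioning

Pairwise repeat divergence is computed codon-by-codon in frame (the units
are in-frame and equal-length, so no alignment is performed; unequal
lengths raise an error instructing the caller to pre-align). Multi-hit
codons are resolved by Nei–Gojobori pathway averaging: all orderings of the
differing positions are enumerated (via a path-counting recursion, checked
in the tests against explicit permutation enumeration), each single-step
change is classified synonymous or nonsynonymous, pathways through stop
codons are excluded, and counts are averaged uniformly over admissible
complete pathways. If every pathway is blocked by stops, stop-traversing
pathways are readmitted rather than leaving the pair unpartitioned. By
construction `syn + nonsyn` equals the nucleotide Hamming distance exactly;
this closure is kept exact by excluding stop-containing codon pairs from
*all* counts (with a warning), since a codon skipped only from the syn/nonsyn
partition would break it.

Clustering of the pairwise nucleotide-difference matrix uses average
linkage (UPGMA) via scipy; flat cuts default to the number of species. The
recurrence score of a species is the fraction of its units whose nearest
neighbour is a same-species unit, with distance ties broken *toward* a
different-species unit so the score is conservative. A score of 1.0 flags a
species-private cluster (recurrent duplication burst); species with one
unit get a missing score. Note that the score is only expected to be 0.0
for fully orthologous repeat sets when copy numbers are equal across
species — a species carrying surplus units necessarily has same-species
nearest neighbours for them.

Regression summaries are ordinary least squares (scipy `linregress`). A
zero-variance response yields slope 0 with R² reported as NaN (undefined)
rather than 0; a zero-variance predictor raises.

## Random-walk copy-number simulator (`mucin7.phylo_walk`)

The model is a discrete-time symmetric random walk along a dated species
tree: from the ancestral state (default 5 copies at the 11-Mya root of the
great-ape tree `(((Human:5,Chimpanzee:5),Gorilla:8),Orangutan:11)`), every
`step_myr` (default 1 Myr) each extant lineage moves ±`rate_per_step` with
probability ½, independently across lineages and steps; descendants share
their ancestors' trajectory until the divergence age. States are clipped at
a floor of 0 after each step (copy number cannot be negative; the floor is
configurable and can be disabled for checking the unclipped theory). At
rates 0.5 and 1.5 the literal step semantics produce fractional states;
these are kept as-is (an integer ±Poisson(rate) step variant is available
behind `integer_steps` for sensitivity analysis), and simulated states are
not rounded before the variance is computed.

"Variation" is the sample variance (n−1 denominator) of the terminal states
of the four tips. Because the subsequent test is rank-based, any monotone
alternative (SD, population variance) gives the same p-value. The observed
side is built by enumerating the Cartesian product of the per-tip observed
allele sets (2×1×2×2 = 8 variances for the default great-ape input) and
compared against the per-replicate simulated variances with a one-sided
Wilcoxon rank-sum test (observed smaller). With 8 vs 1,000 values this uses
the normal approximation with tie and continuity correction; small samples
use exact enumeration (below).

A caveat worth stating: at the slowest rate (0.5 copies/Myr) the one-sided
p-value under this literal model sits at the 0.01 boundary and crosses it
depending on the simulation seed; at 1.0–2.0 copies/Myr the result is
robustly p < 10⁻⁵.

## Rank-sum test (`mucin7.stats.rank_sum_test`)

Exact p-values are computed whenever C(n+m, n) ≤ 10⁶ (and n+m ≤ 512) by
dynamic programming over the pooled midrank multiset — doubling the
midranks makes them integers, and a subset-sum count gives the exact null
distribution of the rank sum, including ties. Larger samples use scipy's
asymptotic Mann–Whitney path (tie correction, continuity correction).
Two-sided p-values are twice the smaller tail, capped at 1. Two samples
with all values identical return p = 1 with a warning.

## Multispecies coalescent with stepwise mutations (`mucin7.coalescent`)

The genealogy simulator is a standard structured coalescent written against
Hudson-style scaling: with j lineages in a population of size Ne_pop, the
waiting time to the next coalescence is exponential with rate
C(j,2)·(Ne_ref/Ne_pop) per unit of coalescent time; populations merge into
their ancestor at the species divergence times, converted as
t_coal = t_years / (generation_time · 4·Ne_ref). Mutations fall on branches
as Poisson(θ/2 · length). These conventions jointly give the classical
identities E[TMRCA] = 1 for two samples in the reference population,
E[total tree length] = Σ 2/i, and E[pairwise mutation count] = θ, which the
acceptance tests verify by Monte Carlo; a cross-check against msprime (with
population size 4·Ne_ref at ploidy 1, which matches the per-generation pair
coalescence rate) confirms the demographic layer independently.

Each mutation shifts the copy number by ±1 with probability ½ (stepwise /
microsatellite model); a tip's copy number is the root state (default 5,
matching the random-walk analysis) plus the signed sum along its path,
clipped at 0. Truncation selection is implemented as replicate-level
rejection: any replicate containing a copy number above `max_cn`
(default 12, the highest copy number observed in primates) is discarded and
redrawn from the same seeded stream; the acceptance rate is recorded and
the run aborts below 10⁻⁴. This is the simplest scheme consistent with a
hard viability bound; it is not a fitness-weighted forward model.

The default demography covers Human, Chimpanzee and Gorilla (splits 5 and
8 Mya, human Ne 10⁴, chimpanzee Ne 2×10⁴, other species default to the
reference Ne, 25-year generations, six haplotypes per species — the
genotyping threshold of more than three diploid individuals). θ relates to
the per-Myr mutation-event rate k as θ = 4·Ne·(k·gen/10⁶), which is θ = k
at the human defaults; the default grid spans 0.2–5.5. Within-species
variation is the sample variance of a species' haploid copy numbers;
between-group variation is the variance of the species means (a pooled
variant is available behind `pooled_between`). The observed/expected
heatmap reports, per comparison and θ, the observed variation divided by
the mean simulated variation plus the empirical fraction of simulated
values at or below the observed one.

One structural property found while validating: if the cross-family null is
simulated with the deep Old World monkey divergence, the null between-group
variation always exceeds paper-like observed values, at every θ — a null
built from the shallow Human/Chimp/Gorilla reference demography is what
makes observed cross-family variation exceed expectation while
within-species variation stays below it. The qualitative acceptance test
therefore scores cross-family observations against the shallow-tree null,
which is also the demography the θ calibration is defined on.

## Expression scan (`mucin7.expression`)

Specificity is tested per sample (not per tissue mean): a gene's target
tissue samples against all other samples, one-sided rank-sum (target
greater). The scalar path handles ties and small samples exactly; the
vectorized batch path uses the normal approximation without tie correction,
which is exact in distribution for continuous expression values (the
calibration test verifies uniform null p-values, KS distance < 0.05 at
2,000 genes). "Most significant 1%" is interpreted as the smallest-p tail —
the literal opposite reading would flag the *least* specific genes — with
the cutoff at the k = ⌊n·q⌋-th smallest p-value and ties at the cutoff all
included, applied per chromosome. The window scan slides a 15-gene window
one gene at a time along chromosomal gene order and counts flagged genes;
the report includes the argmax window, the focal gene's best window, the
histogram of window counts, and an enrichment p comparing the focal
window's gene p-values against all other genes (p = 1 by convention when
nothing is flagged anywhere).

## Conservation profiling (`mucin7.conservation`)

Column conservation is the Jensen–Shannon divergence (base-2 logs, λ = ½,
hence bounded in [0, 1]) between the column's residue distribution — with a
pseudocount of 1/n_sequences on all 20 amino acids — and a background
distribution, BLOSUM62-derived frequencies by default (uniform available).
Columns with gap fraction above 0.3, or with fewer than two residues,
are missing. No window smoothing is applied.

Segment nonsynonymous/synonymous ratios use concatenated counts over all
sequence pairs and the segment's codon columns: fractional differences from
pathway averaging and Nei–Gojobori site counts (per position, the
synonymous fraction among non-stop single-nucleotide changes; three sites
per codon), so the segment ratio is (ΣNd/ΣN)/(ΣSd/ΣS). A pairwise-averaged
variant would weight pairs equally rather than by their divergence;
concatenation is the default because sparse segments make per-pair ratios
unstable. Segments with no synonymous differences are reported missing.
"Normalized" divides each segment's ratio by the whole-alignment ratio
(modes: none / whole-alignment / max-segment). Copy-number-variable repeat
segments are excluded by default (name `PTS-repeats`), since copy-number
change makes their alignment unreliable.

## Synthetic data (`mucin7.synth`)

The CDS generator plants a tandem array of 69-nt units between non-repetitive
flanks. Units are built from a T/S/P-biased codon pool (T+S codon share
≥ 40% by default) and flanks from a disjoint low-T/S pool, so the T+S
fraction separates repeat from flank. Ancestral units are distinguished by
`ortholog_marks` (default 4) private substitutions; species accumulate
`subs_per_unit` further substitutions per ortholog at never-reused sites,
so pairwise differences between orthologs equal the summed event counts
exactly (infinite-sites bookkeeping), and no substitution is allowed to
create a stop codon. Burst species carry identical species-private
duplicates of one unit. Flank/array boundaries are planted identifiably
(the 3 nt adjacent to the array disagree with its periodic continuation at
≥ 2 positions on each side); default copy numbers (5–7) mirror the great-ape
reference range. The generator does not emulate transition/transversion
bias, codon-usage realism, indels, or alignment error — so detection and
counting tests validate the bookkeeping, not robustness to misalignment.

Genotype tables sample diploid individuals (default 4 per species) from
per-species allele sets mirroring the observed great-ape ranges (Human 5–6,
Chimpanzee 5, Gorilla 4–5, Orangutan 6–7); an all-heterozygous mode
reproduces the small-sample pattern seen in baboons.

Expression matrices default to the chromosome-4-like geometry: 3,600 genes,
36 planted specific genes of which 10 form one contiguous cluster around
the focal gene, 53 tissues (one target + 52 others) × 5 samples, log-normal
baseline and noise (σ = 1 on the log scale), and a multiplicative
fold-change (default 5) in the target tissue. Fold-change 1 is the
calibration (no-signal) mode. At these settings individual cluster genes
are called with ≈ 70% sensitivity, but the argmax window localizes the
cluster essentially always — window localization, not per-gene calling, is
the recovery claim the scan is tested on. All generators are pure functions
of (config, seed) and emit machine-readable truth sidecars; recovery tests
consume only the sidecars.

## Problem sizes and determinism

Default analysis sizes — 1,000 walk replicates per rate, 10,000 replicates
for the coalescent closed-form anchors, 1,000 detection fixtures, 100
seeded expression scans — run in seconds to a few minutes on one CPU and
are the sizes the test suite uses. All stochastic stages take explicit
integer seeds (numpy `default_rng`); identical seed and configuration give
bit-identical outputs, including the rejection history of the truncation
sampler. The pipeline manifest records version, seed and configuration, so
a run is reconstructable from its manifest.

## Known limitations

- The repeat detector returns a single best run per sequence; genes with
  several disjoint repeat arrays would need per-region calls.
- The coalescent model has no migration, no recombination and a single
  locus; Ne is constant per branch.
- The stepwise model is symmetric (no gain/loss bias) with unit steps only.
- The random-walk test's rate-0.5 verdict is seed-sensitive at the 0.01
  threshold (see above); conclusions should rest on the full rate range.
- Conservation scoring assumes a trustworthy input alignment; alignment
  construction and curation are out of scope.
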