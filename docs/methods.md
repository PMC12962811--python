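# Methods

## The problem

A handful of enamel and collagen proteins (AMELX, ENAM, AMBN, MMP20, ODAM,
AMTN, AHSG, ALB, COL17A1, COL1A1, COL1A2, AMELY) are the only sequence-level
biomolecules recoverable from mammalian fossils older than about a million
years. How much do they actually say about the branching order of closely
related lineages? Two effects conspire against them: *incomplete lineage
sorting* (ILS) makes the true genealogy of any single locus disagree with the
population tree with probability `(2/3)·e^(−T)` for an internal branch of `T`
coalescent units, and the lossy map from DNA to amino acids removes most of
the variants that could resolve the genealogy at all. This package simulates
the whole situation with known ground truth and measures each stage: sequence
conservation, per-locus tree inference, and the behaviour of concatenation as
proteins accumulate.

## Coalescent simulator

The species tree is a fixed four-taxon shape `((a,b),c,outgroup)` with split
times `t1 ≤ t2 < t3` in coalescent units (time / 2N generations of a
reference population). Each species-tree branch is one population; per-branch
effective sizes enter as multiplicative factors on the pairwise coalescence
rate. Sampled lineages are followed backwards through the branch structure
with exponential waiting times (a structured coalescent); any number of
individuals per taxon is supported, so within-taxon polymorphism arises from
genuine terminal-branch coalescence rather than added noise.

Ground truth per locus: the topology class (concordant / two discordant
arrangements) and the ILS flag are defined on one reference lineage per taxon
— the ILS flag is set when the sister lineages fail to coalesce before `t2`.
With one lineage per taxon the discordance probability has the closed form
above; the simulator is tested against it at four values of `T` and
cross-checked against msprime on the same demography.

**Introgression** is represented at the haplotype level: a lineage sampled
inside an archaic haplotype lives in a private population from the present
back to the pulse time, at which point that population merges into the source
taxon's branch. For one sampled lineage per taxon this is distributionally
identical to reassigning the target lineage to the source branch with
probability *m* at the pulse; with several individuals it additionally
forbids an introgressed haplotype from coalescing with non-introgressed ones
more recently than the pulse, which is the correct genealogy of an
introgressed segment. Carrier tips are recorded exactly, which is what makes
the segment-table recovery checks exact. Pulse eligibility can be restricted
to individuals with given population-panel labels, emulating admixed vs
unadmixed present-day panels.

**Sequence evolution** is a simplified GY94-style codon process: each codon
position mutates at rate `mu` per coalescent unit, uniformly to one of the
three alternative bases; nonsynonymous proposals are accepted with relative
rate `omega`; proposed stop codons are rejected; per-codon relative rates
come from an optional profile (mean 1). At `omega = 1` (ignoring stop
rejection) this is exactly JC69 at rate `mu` per site, so a branch of length
`b` carries `mu·b` expected substitutions per neutral site (`3·mu·b` per
codon) — the documented scale between coalescent time and divergence.
Protein tips are exact standard-code translations of the exon DNA tips.
Loci may carry a neutral flank of `n_intron` sites evolved by exact JC69
endpoint sampling; the `intron+exon` data type is that flank concatenated
with the exon (real genes interleave introns; for information accounting
only the lengths and rates matter). One gene tree per locus — loci are
assumed short enough not to be broken by recombination.

## Presets (study conditions)

No split times or effective sizes are asserted as measured values; they are
stylized, chosen once from published hominid scales, and fixed:

| preset | taxa | t1, t2, t3 | internal T | mu | regime |
|---|---|---|---|---|---|
| hominid-like | Homo, Pan, Gorilla, Pongo | 2.4, 3.6, 6.4 | 1.2 | 2.6e-3 | ~20% true discordance, ~7–9 ingroup protein variants per locus |
| hominin-like | Neanderthal, Denisovan, Sapiens, Pan | 0.45, 0.50, 6.0 | 0.05 | 1.2e-3 | ~63% true discordance, roughly ten-fold fewer protein variants |

The twelve loci use the canonical-isoform lengths of the real proteins and a
stylized `omega` per locus mirroring the known conservation ranking
(collagens and AMELX strongly conserved near 0.03–0.05; ODAM and AMELY most
variable near 0.55–0.6). The per-coalescent-unit `mu` differs between
presets because a coalescent unit is `2N` generations and the hominin
reference `2N` is smaller. A `conserved_locus_models()` set (12 short loci,
`omega = 0.05`) provides the strong-purifying-selection regime for the
DNA-vs-protein comparisons. The hominin admixture scenario is a recent
Neanderthal-into-Sapiens pulse (t = 0.02) restricted to an "ADMIXED"
individual panel, with proportion 0.35–0.5 in the shipped configurations —
deliberately larger than genome-wide archaic ancestry so that panels of a
few individuals carry detectable signal.

What the generator does **not** emulate: peptide degradation and missingness
(sequences are complete by design), recombination within a locus, empirical
amino-acid exchangeabilities, codon usage bias, and more than four taxa.
Passing tests therefore demonstrate the logic of the pipeline under ILS and
admixture, not the error structure of real mass-spectrometry data.

## Conservation scoring

Per-column Shannon entropy in bits over observed state frequencies. Gaps are
excluded by default (`as_state` counts the gap as a state); `X`/`N` never
enter frequencies; an all-gap column scores 0 and is flagged. Summaries:
total (sum over sites), per-length (total / alignment width), and a
codon-corrected per-length score for cross-data-type comparison. The
divide-by-3 correction is applied to the nucleotide side by default with the
protein score kept intact; the converse convention is available as
`side="protein"` since both appear in the literature and they differ only by
a global factor of 3 on one side of the comparison.

The evolutionary-rate score replaces empirical-Bayes site-rate machinery
with the simplest estimator that preserves rankings: per site, the branch
lengths of a fixed fitted quartet tree are rescaled by a factor `r ≥ 0`
estimated by bounded maximum likelihood (JC69 / Poisson model), then
normalized to mean 1 across sites. It is validated against an exhaustive
grid search on single columns and used only at the ranking level.

Within-taxon diversity is handled by the resampling protocol: draw one
individual per taxon (independently per locus), score the quartet, repeat
(default 1,000 replicates), report the mean profile and the Monte-Carlo
standard error of the per-length score. With two individuals per taxon the
Monte-Carlo mean is checked against the exact average over all 16
combinations.

## Quartet maximum likelihood

Every tree in the pipeline has four leaves, so heuristic search is replaced
by exhaustive ML: for each of the three unrooted topologies, Felsenstein
pruning over collapsed site patterns with five branch lengths optimized by
cyclic bounded one-dimensional search (Brent, lengths in [0, 10], cycle
until the relative log-likelihood gain falls below 1e-8, at most 30 cycles).
Models are equal-rates multistate: JC69 for nucleotides, Poisson (uniform
frequencies and exchangeabilities) for amino acids — at hominid divergences
topology choice is driven by shared derived states, and the model is
pluggable. Gaps and ambiguity codes are missing data.

Numerical policy: a log-likelihood tie between the best two topologies
(ΔlnL < 1e-6) is a polytomy, never a random winner; likewise an internal
branch shorter than `min_length` (default 1e-6 substitutions/site) after
fitting, or bootstrap support below `min_support` (default 50%) when a
bootstrap was run. Pendant branches are never collapsed. Bootstrap support
is the percentage of column resamples (multinomial over patterns) whose
refitted ML topology recovers the same ingroup pair; polytomies carry no
support. The short-branch and support thresholds are this package's declared
defaults, not values asserted from elsewhere.

Classification roots the fitted quartet on the outgroup pendant edge; the
cherry excluding the outgroup is the resolved ingroup sister pair and maps
to `#1` (the reference pair), `#2`/`#3` (the third ingroup taxon paired with
the first / second reference-pair member), or `#4` (polytomy). A quartet
whose ML split pairs the outgroup with an ingroup taxon is not an error; its
rooted ingroup triplet is still well defined.

## Iterative concatenation experiment

For each N: sample N loci without replacement; draw one individual per taxon
— independently per locus by default (`per-rep` draws once per replicate);
concatenate the pre-aligned quartets with partition tracking; fit; optionally
bootstrap; collapse; classify; count ingroup variants (columns with ≥ 2
distinct non-gap, non-ambiguous states among the three ingroup rows —
outgroup-only variation is excluded). Per-N summaries report label
frequencies, variant box-plot statistics (type-7 linear-interpolation
quantiles; whiskers at `q25 − 1.5·IQR` and `q75 + 1.5·IQR`), and bootstrap
support grouped by (N, label) with polytomies excluded. The "consensus tree"
of a replicate is simply the tree of its concatenation; no separate
consensus algorithm exists. Replicates are driven by spawned substreams of a
single master seed, so every run is exactly reproducible.

Default problem sizes: the full experiment is specified at 1,000 replicates
per N; the shipped acceptance checks run 200 replicates on the N grid
{1, 4, 8, 12}, which bounds the Monte-Carlo error of a frequency near 0.9 at
about ±2% while keeping a complete run in minutes on one core. Bootstrap is
off (B = 0) in those runs — label frequencies do not require it.

## Introgression overlap analysis

Segments are BED-like rows (0-based half-open; a loader flag converts
1-based inclusive input) with individual, haplotype (0/1), ancestry, panel
and region labels. A haplotype carries the archaic version of a gene when
any of its segments overlaps the gene interval by ≥ 1 bp. Frequencies are
counted at chromosome level by default — distinct (individual, haplotype)
pairs over the panel's chromosome count — with an individual-level option;
the global row pools panels and therefore equals the size-weighted mean of
panel frequencies by construction. `synthetic_segment_table` lays the
panel's loci along one synthetic chromosome and emits one segment per
ground-truth carrier, so planted carrier frequencies are recovered exactly
(simulated individuals are haploid: one chromosome each).

## Design choices that were genuinely open

- **Aligner**: orthologs of closely related hominids are near-identical, so
  generated panels are emitted pre-aligned and the bespoke progressive
  affine-gap aligner (Gotoh three-matrix, pairwise-to-profile, guide order
  of decreasing identity, gap of length L costs `open + L·extend`) exists
  for unaligned input; its pairwise scores are verified against exhaustive
  alignment enumeration.
- **Missing taxa** abort concatenation rather than pad with gaps: the
  experiment's premise is four complete sequences per locus.
- **Individuals per locus**: redrawn per locus within a replicate by
  default, the literal reading of per-protein sampling; `per-rep` mode is
  provided.
- **Ground truth with many individuals** is defined on the first individual
  of each taxon; any other convention only relabels a set of loci whose
  within-taxon genealogy straddles a split.
- **Tie-breaking everywhere is deterministic** (lexicographic for ranking
  ties, polytomy for likelihood ties).

## Known limitations

- The Poisson/JC69 models ignore rate heterogeneity in *inference* (the
  generator has per-codon rate profiles); branch lengths are interpretable
  only at small divergences.
- The rate estimator is a point-ML rescaling, noisier than empirical-Bayes
  shrinkage for single columns; only rankings are claimed.
- Concatenation under ILS is known to be statistically inconsistent in parts
  of parameter space; this package measures that behaviour rather than
  correcting it (multispecies-coalescent inference is out of scope).
- The bone–dentin 28-protein expansion is available through the generator's
  generality (any locus list) but has no dedicated preset.
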