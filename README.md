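# paleoquartet

How much phylogeny fits in a handful of ancient proteins?

Only a dozen enamel and collagen proteins (AMELX, ENAM, AMBN, MMP20, ODAM,
AMTN, AHSG, ALB, COL17A1, COL1A1, COL1A2, AMELY) survive in fossils older
than about a million years, and they are exactly the kind of data that
phylogenetics finds hardest: short, strongly conserved, and sampled from
closely related lineages where *incomplete lineage sorting* (ILS) makes
individual gene trees disagree with the population tree. For an internal
branch of `T` coalescent units, a locus's genealogy is discordant with the
species tree with probability

```
P(discordant) = (2/3) · e^(−T)
```

and translating DNA to amino acids then throws away most of the variants
that could have resolved the genealogy anyway. `paleoquartet` is a
desk-scale laboratory for this situation, aimed at palaeoproteomics and
molecular-evolution researchers who want to know what a given set of
proteins *can* and *cannot* resolve before pointing a mass spectrometer at
a fossil. It provides:

- a **coalescent simulator** for four-taxon species trees (structured
  coalescent over the tree's branches, any number of individuals per taxon,
  archaic-introgression pulses at the haplotype level) with exact ground
  truth per locus, plus a GY94-style codon evolver with tunable purifying
  selection (dN/dS = omega) so protein panels have realistic conservation
  heterogeneity;
- **conservation scoring**: per-site Shannon entropy and a site-rate score
  under a fixed tree, with total / per-length / codon-corrected summaries,
  locus rankings, and the one-individual-per-taxon resampling protocol;
- **exhaustive quartet maximum likelihood** (`QuartetML(...).fit()` — all
  three unrooted topologies solved by Felsenstein pruning; JC69 for DNA,
  Poisson model for amino acids), with column bootstrap, collapse of short
  or unsupported internal branches into polytomies, and classification
  against a reference population tree as `#1` (concordant), `#2`/`#3`
  (alternative arrangements) or `#4` (polytomy);
- the **iterative concatenation experiment**: for each N, repeatedly sample
  N proteins and one individual per taxon, concatenate, infer, classify and
  count informative variants — the curve that says how many proteins you
  need;
- **introgression overlap analysis**: BED-like archaic-haplotype segment
  tables intersected with gene intervals, with chromosome-level carrier
  frequencies per population panel.

## Worked example

```python
import paleoquartet as pq

spec, loci = pq.hominid_like()          # Homo/Pan sister, Gorilla, Pongo outgroup
panel = pq.build_panel(spec, loci, individuals_per_taxon=3, rng_seed=11)

aln = panel.quartet_alignment("ENAM", {t: "i1" for t in spec.taxa})
result = pq.QuartetML(aln).fit()
result.bootstrap(B=100, rng_seed=0, outgroup="Pongo")
print(result.summary())
print("label:", result.collapse().classify(pq.ReferenceTreeSpec.hominid()))

res = pq.run_analysis(panel, [1, 4, 12], reps=50, rng_seed=0)
print(res.summary())
```

prints

```
Quartet maximum-likelihood fit
==================================
model:            poisson-aa
sites:            1142
topology:         ((Homo,Pan),(Gorilla,Pongo))
log-likelihood:   -3871.9689
  branch Homo         0.007034
  branch Pan          0.006152
  branch Gorilla      0.010578
  branch Pongo        0.022162
  branch internal     0.001742
bootstrap support: 88.0%
lnL by topology:  [-3871.969, -3879.353, -3879.353]
label: #1

Iterative concatenation analysis
========================================
replicates per N: 50   N grid: [1, 4, 12]

label frequencies (% of replicates):
  N=  1  #1  46.0%  #2   6.0%  #3   0.0%  #4  48.0%
  N=  4  #1  98.0%  #2   0.0%  #3   0.0%  #4   2.0%
  N= 12  #1 100.0%  #2   0.0%  #3   0.0%  #4   0.0%

ingroup variant counts:
  N=  1  mean    8.4  median    6.0  IQR [4.0, 10.0]
  N=  4  mean   35.6  median   35.0  IQR [25.2, 44.8]
  N= 12  mean  101.6  median  102.0  IQR [101.0, 102.0]
```

Reading this: the simulated ENAM quartet alone already recovers the
great-ape tree (`#1`) with 88% bootstrap support and a short but positive
internal branch. A *single* random protein, however, gives the right tree
in only 46% of draws — 48% of single-protein quartets are uninformative
polytomies — while four proteins almost always suffice and twelve are
decisive, by which point a concatenation carries ~100 ingroup amino-acid
variants. Swap in `pq.hominin_like()` (Neanderthal/Denisovan/modern human,
internal branch 0.05 coalescent units, ~10× fewer variants) and the same
experiment shows the polytomy fraction starting above 80% and the
concatenated tree at N=12 landing on whichever topology the panel's frozen
gene trees happen to favour — the regime in which more proteins do not
straightforwardly buy more truth.

There is also a CLI mirroring the library
(`paleoquartet simulate|entropy|rates|quartet|iterate|introgress|report`),
each run writing TSV outputs plus a manifest with parameters, seed and
input checksums.

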