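# kojigenomics

Comparative genomics of clonally domesticated koji moulds (*Aspergillus
oryzae* and its wild sister species *A. flavus*): who is related to whom, how
their chromosomes were shuffled before domestication, and what domestication
has done to their genes since.

Industrial koji strains fall into tight clades — groups whose concatenated
single-copy gene sequences differ by ≤ 0.01% — yet the clades themselves are
chromosomal mosaics of one another: walking along a chromosome, the clade a
strain most resembles switches block by block, the footprint of ancestral
recombination.  After clade divergence the strains were propagated clonally,
so mutations private to a clade are the signature of domestication.  This
package implements that entire analysis chain and a forward simulator that
generates mosaic genomes with full ground truth, so every stage is testable
end to end.

## What it computes

* **Clade structure** (`kojigenomics.clades`) — gap-containing columns are
  removed from every orthogroup alignment ("degapped gene sequences"), the
  orthogroups are concatenated, and pairwise p-distances
  *d(i,j) = #differing columns / columns* (N treated as a wildcard) are
  clustered by single linkage at a threshold (default 1e-4, i.e. 0.01%).
  A Saitou–Nei neighbor-joining tree over the same distances gives the
  between-clade topology.  Mating-type idiomorphs (MAT1-1 / MAT1-2) are
  detected by exact marker search on both strands, and MAT × clade linkage is
  checked: a clonal clade must be MAT-uniform.
* **Chromosomal mosaicism** (`kojigenomics.mosaic`) — per gene, a strain
  either is or is not exactly identical to each clade's majority-consensus
  reference; a sliding window (default 21 genes) along the reference gene
  order turns the 0/1 indicators into percent similarity scores, and the
  argmax clade per position is the "closest clade" track.  Genome shares
  (fraction of genes identical to each clade) and a two-clade mixture test
  (can the genome be covered ≥ 95% by two other clades, each contributing
  ≥ 10%?) summarise the track.
* **Mutation spectra** (`kojigenomics.mutspec`) — codon-level classification
  of differences against the clade consensus into synonymous, non-synonymous
  and gap mutations (distinct variants counted once; a run of consecutive gap
  codons is one indel event).  Enrichment is an odds ratio against a baseline
  spectrum, e.g. odds_nonsyn = (n_nonsyn/n_syn)_group / (n_nonsyn/n_syn)_baseline,
  with two-sided Fisher exact p-values computed by hypergeometric enumeration.
* **Copy number** (`kojigenomics.depthcnv`) — per-gene mean read depth,
  normalised by the strain's median gene depth, rounded half-up to an integer
  copy number; clade-wise tabulation of copy-number variability.
* **Simulator** (`kojigenomics.synthetic_data`) — diverged clade ancestors on
  a star phylogeny, clonal clade members with private domestication mutations
  (tunable non-synonymous/synonymous odds, single-codon deletions),
  recombinant mosaic strains with crossovers at gene junctions, Poisson read
  depth with integer CNVs, MAT markers — plus truth tables for all of it.

## Worked example

The published mutation counts for industrial strains (intra-clade), between
clades, and across the wild sister species are inputs to the odds analysis:

```python
from kojigenomics.mutspec import MutationTable, odds_vs_baseline

intra    = MutationTable(scope="intra_clade",      syn=265,    nonsyn=528,    gap=93)
inter    = MutationTable(scope="inter_clade",      syn=76_543, nonsyn=66_001, gap=1_795)
baseline = MutationTable(scope="baseline_species", syn=79_068, nonsyn=53_922, gap=1_336)

o = odds_vs_baseline(intra, baseline)
print(f"{o.odds_nonsyn:.3f} {o.odds_gap:.3f} {o.p_nonsyn:.2e} {o.p_gap:.2e}")
o = odds_vs_baseline(inter, baseline)
print(f"{o.odds_nonsyn:.3f} {o.odds_gap:.3f}")
```

prints

```
2.922 20.774 6.09e-49 3.80e-79
1.264 1.388
```

i.e. within clades — the domestication era — non-synonymous mutations are
2.9× and gap mutations 20.8× over-represented relative to synonymous ones
compared with the wild-species spectrum (both p ≪ 1e-10), while the
between-clade (pre-domestication) spectrum is only mildly enriched
(1.3× / 1.4×).  Domestication pressure selectively fixed function-changing
mutations.

The full synthetic analysis runs as a sequence of drivers from the
repository root, writing tables under `results/`:

```bash
python analysis/01_simulate.py   # emit the synthetic dataset (scratch/dataset)
python analysis/02_clades.py     # distances, clustering, NJ tree, MAT linkage
python analysis/03_mosaic.py     # closest-clade tracks of the recombinants
python analysis/04_mutspec.py    # mutation spectra and odds
python analysis/05_cnv.py        # copy-number calls vs truth
```

`02` reports a cluster partition identical to the simulated truth with
MAT × clade linkage consistent; `03` recovers ≈ 99% of donor labels and all
crossover breakpoints within ±10 genes for the recombinant queries; `04`
recovers the injected mutation counts exactly; `05` calls 4400/4400 gene
copy numbers correctly.

The same subcommands are available from a shell via the `kojigenomics` CLI
(`simulate`, `clades`, `mosaic`, `mutspec`, `cnv`); note the tree step is
neighbor joining, a desk-scale substitute for maximum-likelihood inference.

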