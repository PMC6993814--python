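# Methods

## The analysis model

The package treats a set of fungal strains as descendants of a small number
of diverged **clade ancestors**.  Three timescales structure everything:

1. **Ancestor divergence** — the clade ancestors accumulated substitutions
   relative to one another (order 1% per site).  Because the observed clades
   are near-simultaneous, ancestors are modelled on a star phylogeny.
2. **Ancestral recombination** — before clonal propagation, genomes were
   shuffled: a recombinant genome is a contiguous mosaic of ancestor-derived
   gene blocks.  The analysis unit is the gene, so crossovers are placed at
   gene junctions; within-gene breakpoints are out of scope.
3. **Domestication** — after clade divergence, strains were propagated
   clonally, so mutations private to a clade date from the domestication era.
   Their spectrum (non-synonymous and gap mutations relative to synonymous
   ones) is the signal of interest.

All stages operate on per-orthogroup aligned coding sequences over a common
strain set (the single-copy constraint), anchored to a reference chromosome
layout by a gene-order map.

## Stage-by-stage procedure and numerical choices

### Distances and clades

Degapping removes every alignment column carrying a gap in *any* strain; this
guarantees a rectangular, gap-free concatenated matrix and makes p-distances
comparable across strain pairs.  `N` is a wildcard in distance computation so
low-coverage ambiguity cannot inflate distances.  Clades are single-linkage
clusters at a p-distance threshold: single linkage is the weakest assumption
consistent with "all members within a dissimilarity bound", and it is
monotone in the threshold (clusters at a smaller threshold refine clusters at
a larger one — a tested invariant).

The threshold default is 1e-4 (0.01%), the bound observed for industrial
clades over multi-megabase concatenations.  The bound is scale-dependent:
on the bundled synthetic dataset the concatenation is only ~90 kb, where a
strain's handful of private mutations already amounts to ~1e-4 while
between-clade distances sit near 1e-2, so the analysis driver clusters at
1e-3.  Users analysing small gene panels should make the same adjustment.

Tree inference is Saitou–Nei neighbor joining over the p-distance matrix — a
deliberate desk-scale substitute for maximum-likelihood inference, adequate
for tight, well-separated clades and surfaced as such in the CLI help.
Numerical conventions: Q-matrix ties are broken by the smallest node-creation
index pair, so results are reproducible across platforms; a negative branch
length is clamped to zero with the deficit moved to its sister branch, so the
joined pair keeps its observed distance.

MAT typing is exact substring search of the two idiomorph markers and their
reverse complements over all contigs: exactly one marker found gives the
type, neither gives `unknown`, both give `ambiguous`.  The linkage check
excludes `unknown` from per-clade type sets; `ambiguous` is likewise
excluded (it is not a type) but ambiguous strains are listed in the report.

### Mosaicism

Per-gene identity is **exact string equality to the clade consensus
reference** (per-column majority, ties broken by the fixed symbol order
A < C < G < T < N < -).  Consensus is reproducible, degenerates correctly to
the single member for singleton clades, and equals the shared ancestor for
tight clades whose members carry only private mutations.  Columns gapped in
both query and reference are ignored (a shared deletion is not a
difference).

Scores are windowed means of the 0/1 indicators, in percent.  The window
(default 21 genes) is centered and **shrinks symmetrically near chromosome
ends** (half-width `min(window//2, i, n-1-i)`), keeping the change-point
location unbiased right up to the edges — with an asymmetrically truncated
window, a donor block shorter than half a window at a chromosome end could
never win the argmax.  Exact score ties are labelled `unassigned` rather
than an arbitrary clade, so no mosaic structure is fabricated.

The mixture test declares a strain a two-clade mixture only if the best clade
pair covers at least 95% of genes *and* each member of the pair individually
covers at least 10%.  The second clause prevents a single-donor genome from
being declared a "mixture" of its own donor plus a bystander; both thresholds
are parameters.

### Mutation spectra

Codon changes against the clade consensus are classified gap (any `-`), then
ambiguous (any `N`), then by the standard genetic code: same amino acid is
synonymous, different is non-synonymous; stops compare equal to stops and a
sense↔stop change is non-synonymous (function-changing by definition here).
Codons differing at several positions are classified by the net amino-acid
effect — path counting would require an evolutionary model the analysis does
not assume.

Counting is by **distinct variant**: the same alternate codon observed in
several clade members at one site is one mutation event (invariant to clade
size and matching the event interpretation of "mutations"); a per-occurrence
mode is available behind a flag.  A maximal run of consecutive gap codons in
one member is one gap mutation — a single indel event spanning several codons
must not be multiply counted.  Between-clade counts compare clade references
pairwise and sum over pairs, so a difference separating one clade from two
others counts twice.

Odds ratios divide the group's nonsyn/syn (or gap/syn) odds by the baseline's.
Fisher's exact test is two-sided by the "sum of tables no more probable than
the observed one" convention, with a relative tolerance of 1e-12 on the
probability comparison; the hypergeometric pmf is evaluated with scipy and
summed over the support, which is exact for the table sizes that occur here.
Above a total of 10^6 the test falls back to a normal approximation and says
so with a warning.  Zero synonymous counts make the odds undefined; an
optional continuity correction adds 0.5 to every cell of the odds (p-values
are always computed on the raw integer table).

### Copy number

Per-gene mean depth is averaged over the gene span (1-based, half-open);
positions absent from the depth track count as zero, so partial dropout
shows up as reduced copy number rather than being silently skipped.  The
normalisation constant is the **median** per-gene mean depth of the strain —
robust against the CNV genes themselves; chromosome-level normalisation was
considered and rejected because simulated CNVs are gene-scale.  Integer calls
are round-half-up; the continuous value is retained in the output.  Calls are
scale-invariant by construction (a tested invariant).  Repeat families
(transposons, rRNA, tRNA) violate the unique-mapping assumption behind
"normalised depth = copy number"; they are handled by an optional exclusion
list, not by mappability modelling.

## The simulator: what it emulates and what it does not

`SimConfig` defaults define the study conditions: 5 clades, 200 genes on two
chromosomes, 150 codons per gene, 1% ancestor divergence, 4 strains per
clade, 2 recombinant query strains with 3 crossovers each, ~2 substitution
events and ~1 single-codon deletion per strain, a non-synonymous odds
multiplier of 2.9 over neutral (mirroring the intra-clade enrichment observed
in domesticated strains), mean read depth 100, and a small clade-uniform CNV
panel (copies 0 and 2–4).  Substitutions are uniform over internal-codon
sites with a 2:1 transition:transversion event ratio (a generic fungal
default); start/stop codons are never touched and stop-creating replacements
are excluded, so every emitted gene is a valid CDS.

Mutation event positions within a clade are sampled distinct and
non-adjacent.  This makes each injected event an individually countable
distinct variant (and each gap a run of length one), which is what lets the
counting stage be scored *exactly* against truth; it also means the simulator
does not model recurrent or adjacent mutations.

Other real-data features deliberately not modelled: sequencing reads and
their error profiles (depth is Poisson per base, no mappability or GC
structure), ancestral/segregating indels (gaps arise only as domestication
events, so on synthetic data the baseline gap count is near zero and gap-odds
against a pooled baseline are inflated), within-gene recombination, unequal
clade ages (star phylogeny), and selection acting on specific genes.  Passing
the recovery tests therefore demonstrates the *analysis machinery* is
correct under the stated model — not that the model captures every property
of real draft genomes.

Everything emitted is a pure function of `SimConfig` (seed included); the
manifest checksums are stable across runs with the same seed.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise each stage at the scale where its statistics are
meaningful: donor-label and breakpoint recovery run the full study conditions
over 20 seeds (tests) / 10 seeds (acceptance script); exact mutation-count
replay uses 3-clade, 30-gene datasets over 3–5 seeds; copy-number recovery
uses 50 genes at mean depth 50 over 5–10 seeds (at 150-codon genes the
normalised depth has a relative standard error under 2%, so ≥ 95% correct
calls is expected with margin); Fisher oracle equivalence enumerates all
46,376 tables with total ≤ 30.

## Known limitations

* Neighbor joining, not maximum likelihood: adequate for clade structure at
  these divergences, but branch lengths are p-distance based and can be
  mildly underestimated at higher divergence (no multiple-hit correction).
* The closest-clade track cannot resolve donor blocks much shorter than half
  the smoothing window in the middle of a chromosome; such blocks exist in
  the simulations and account for the few percent of unrecovered breakpoints.
* The mixture test is a coverage heuristic, not a likelihood model; its two
  thresholds are exposed as parameters.
* Identity-based similarity saturates: once divergence is high enough that
  no gene is exactly identical, the track goes uninformative.  The statistic
  is designed for closely related clades (≲ a few percent divergence).
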