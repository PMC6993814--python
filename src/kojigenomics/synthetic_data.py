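"""Forward simulator for mosaic koji-mould genomes, with full ground truth.

The generator realises the statistical structure the downstream analyses
assume:

* a star phylogeny of diverged clade ancestors (the observed clades are
  near-simultaneous, so no tree shape among ancestors is modelled),
* tight clades: each clade's member strains descend clonally from their
  ancestor and differ only by private "domestication" mutations,
* recombinant query strains whose chromosomes are contiguous mosaics of the
  clade ancestors, switching donors only at gene junctions (the analysis unit
  is the gene),
* domestication mutations with a tunable non-synonymous/synonymous odds
  multiplier over the neutral expectation, plus frame-preserving single-codon
  deletions ("gap mutations"),
* integer copy-number variants expressed as Poisson read depth,
* a MAT idiomorph marker appended to each strain's assembly.

Everything is a pure function of the :class:`SimConfig` (seed included), and
the emitted dataset is accompanied by truth tables sufficient to score every
downstream analysis exactly.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MAT1_1,
    MAT1_2,
    AlignmentSet,
    DepthTrack,
    GeneAlignment,
    GeneOrderMap,
    reverse_complement,
    write_fasta,
)
from .mutspec import GENETIC_CODE, SENSE_CODONS, STOP_CODONS

CLADE_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]

# fixed 30 bp mating-type markers (stand-ins for the published MAT primers;
# long enough that a chance hit in a simulated genome is negligible)
MAT1_1_MARKER = "ATGCTTGACGGCTTCCAATGGAGACGTCTA"
MAT1_2_MARKER = "ATGAGGTCACCAGTTCGGATAACTGCGCAT"

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _neutral_ns_odds() -> float:
    """Nonsyn/syn odds of a uniform single-base change over sense codons.

    Stop-creating changes are excluded, matching the simulator's own
    substitution process.
    """
    syn = nonsyn = 0
    for codon in SENSE_CODONS:
        aa = GENETIC_CODE[codon]
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if GENETIC_CODE[alt] == "*":
                    continue
                if GENETIC_CODE[alt] == aa:
                    syn += 1
                else:
                    nonsyn += 1
    return nonsyn / syn


#: neutral non-synonymous/synonymous odds under uniform single-base changes
NEUTRAL_NS_ODDS = _neutral_ns_odds()

_SAME_AA_ALTS = {
    c: tuple(sorted(o for o in SENSE_CODONS if o != c and GENETIC_CODE[o] == GENETIC_CODE[c]))
    for c in SENSE_CODONS
}
_DIFF_AA_ALTS = {
    c: tuple(sorted(o for o in SENSE_CODONS if GENETIC_CODE[o] != GENETIC_CODE[c]))
    for c in SENSE_CODONS
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    ``gene_length`` counts codons including the ATG start and the stop, so a
    gene spans ``3 * gene_length`` bp.  ``divergence`` is the expected
    per-site substitution fraction between any two clade ancestors.
    ``intra_mut_rate`` and ``gap_rate`` are expected mutated codons / gap
    events per strain; ``target_ns_odds`` multiplies the neutral
    non-synonymous/synonymous odds of each substitution event.
    """

    n_clades: int = 5
    genes_per_chromosome: tuple = (100, 100)
    gene_length: int = 150
    divergence: float = 0.01
    n_strains_per_clade: int = 4
    n_recombinants: int = 2
    n_crossovers: int = 3
    intra_mut_rate: float = 2.0
    target_ns_odds: float = 2.9
    gap_rate: float = 1.0
    cnv_spec: Optional[tuple] = None  # ((og_id, clade, copy_number), ...) or None for a default
    mean_depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 2:
            raise ValueError("n_clades must be >= 2")
        if self.n_clades > len(CLADE_LABELS):
            raise ValueError("too many clades for single-letter labels")
        if not self.genes_per_chromosome or any(g < 1 for g in self.genes_per_chromosome):
            raise ValueError("genes_per_chromosome must be positive")
        if len(self.genes_per_chromosome) > len(ROMAN):
            raise ValueError("too many chromosomes")
        if self.gene_length < 10:
            raise ValueError("gene_length must be >= 10 codons")
        if not (0 < self.divergence <= 0.2):
            raise ValueError("divergence must lie in (0, 0.2]")
        if self.n_strains_per_clade < 1:
            raise ValueError("n_strains_per_clade must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        for rate in (self.intra_mut_rate, self.gap_rate):
            if rate < 0:
                raise ValueError("mutation rates must be non-negative")
        if self.target_ns_odds <= 0:
            raise ValueError("target_ns_odds must be positive")

    @property
    def n_genes(self) -> int:
        return int(sum(self.genes_per_chromosome))

    @property
    def clade_labels(self) -> tuple:
        return tuple(CLADE_LABELS[: self.n_clades])

    def og_ids(self) -> list:
        return [f"OG{i + 1:05d}" for i in range(self.n_genes)]

    def gene_map(self) -> GeneOrderMap:
        records = []
        k = 0
        for c, n in enumerate(self.genes_per_chromosome):
            for idx in range(1, n + 1):
                records.append((f"OG{k + 1:05d}", ROMAN[c], idx))
                k += 1
        return GeneOrderMap.from_records(records)

    def gene_spans(self) -> pd.DataFrame:
        """Reference layout: genes laid end to end per chromosome, no gaps."""
        bp = 3 * self.gene_length
        rows = []
        gm = self.gene_map()
        for chrom in gm.chromosomes():
            pos = 1
            for og in gm.ogs_on(chrom):
                rows.append({"og_id": og, "chromosome": chrom, "start": pos, "end": pos + bp})
                pos += bp
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class InjectedMutation:
    strain: str
    og_id: str
    codon_index: int  # 1-based within the gene
    kind: str  # syn | nonsyn | gap
    ref_codon: str
    alt_codon: str


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset."""

    donor: dict  # (strain, og_id) -> donor clade label
    breakpoints: dict  # strain -> [(chromosome, order_index of first gene after switch)]
    injected_mutations: list  # [InjectedMutation]
    true_copy_number: dict  # (strain, og_id) -> int
    true_mat: dict  # strain -> MAT1-1 | MAT1-2


@dataclass
class SimDataset:
    """In-memory simulated dataset plus its truth."""

    config: SimConfig
    gene_map: GeneOrderMap
    gene_spans: pd.DataFrame
    ancestors: dict  # clade -> og_id -> CDS
    alignments: AlignmentSet
    genomes: dict  # strain -> {contig name -> ungapped sequence}
    depth: dict  # strain -> DepthTrack
    truth: SimTruth
    clade_of: dict  # strain -> truth clade label (recombinants R1, R2, ...)

    @property
    def strains(self) -> list:
        return list(self.clade_of)


# ---------------------------------------------------------------------------
# ancestors
# ---------------------------------------------------------------------------


def _random_cds(config: SimConfig, rng: np.random.Generator) -> str:
    middle = rng.integers(0, len(SENSE_CODONS), size=config.gene_length - 2)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in middle) + stop


def _substitute_base(seq: list, pos: int, rng: np.random.Generator) -> None:
    """Apply a single substitution at bp `pos` with transition:transversion 2:1.

    Stop-creating replacements are excluded by resampling among the remaining
    alternatives (at least one non-stop alternative always exists).
    """
    old = seq[pos]
    alts = [_TRANSITION[old]] + [b for b in _BASES if b != old and b != _TRANSITION[old]]
    weights = np.array([4.0, 1.0, 1.0])  # P(transition) = 2/3: ts:tv event ratio 2:1
    codon_start = 3 * (pos // 3)
    while alts:
        w = weights / weights.sum()
        pick = rng.choice(len(alts), p=w)
        base = alts[pick]
        trial = seq[codon_start:pos] + [base] + seq[pos + 1 : codon_start + 3]
        if GENETIC_CODE["".join(trial)] != "*":
            seq[pos] = base
            return
        alts.pop(pick)
        weights = np.delete(weights, pick)
    raise AssertionError("no non-stop substitution available")  # unreachable


def simulate_ancestors(config: SimConfig, rng: Optional[np.random.Generator] = None) -> dict:
    """Clade-ancestor coding sequences on a star phylogeny.

    Each ancestor is the common root mutated at per-site rate ``divergence/2``
    (substitutions uniform over internal-codon sites with a 2:1
    transition:transversion event ratio), so any two ancestors sit at pairwise
    p-distance ~``divergence``.  Start and stop codons are never touched and
    no internal stop is ever created.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ogs = config.og_ids()
    root = {og: _random_cds(config, rng) for og in ogs}
    n_internal_bp = 3 * (config.gene_length - 2)
    ancestors: dict = {}
    for clade in config.clade_labels:
        genes: dict = {}
        for og in ogs:
            seq = list(root[og])
            n_sub = rng.binomial(n_internal_bp, config.divergence / 2.0)
            if n_sub:
                positions = rng.choice(n_internal_bp, size=n_sub, replace=False) + 3
                for pos in positions:
                    _substitute_base(seq, int(pos), rng)
            genes[og] = "".join(seq)
        ancestors[clade] = genes
    return ancestors


# ---------------------------------------------------------------------------
# recombinant strains
# ---------------------------------------------------------------------------


def _intra_chromosome_junctions(config: SimConfig) -> list:
    """Global gene indices g such that genes g-1 and g share a chromosome."""
    junctions = []
    g = 0
    for n in config.genes_per_chromosome:
        for j in range(1, n):
            junctions.append(g + j)
        g += n
    return junctions


def simulate_recombinant_strain(
    ancestors: Mapping[str, Mapping[str, str]],
    config: SimConfig,
    strain_id: str,
    rng: np.random.Generator,
    donor_pool: Optional[Sequence[str]] = None,
    n_crossovers: Optional[int] = None,
) -> tuple:
    """A mosaic genome: contiguous gene segments copied verbatim from donors.

    Crossover positions are uniform without replacement over intra-chromosome
    gene junctions; adjacent segments always have different donors.  Returns
    ``(genome, donors, breakpoints)`` where breakpoints list the
    (chromosome, order_index) of the first gene after each donor switch.
    """
    pool = list(donor_pool) if donor_pool is not None else list(ancestors)
    if len(pool) < 2:
        raise ValueError("recombination needs at least 2 donor clades")
    k = config.n_crossovers if n_crossovers is None else n_crossovers
    junctions = _intra_chromosome_junctions(config)
    if k >= len(junctions):
        raise ValueError(
            f"n_crossovers={k} must be below the number of gene junctions ({len(junctions)})"
        )
    order = config.gene_map().global_order()
    cuts = sorted(int(junctions[i]) for i in rng.choice(len(junctions), size=k, replace=False))
    donors_per_segment = []
    for _ in range(k + 1):
        if not donors_per_segment:
            donors_per_segment.append(pool[rng.integers(0, len(pool))])
        else:
            others = [c for c in pool if c != donors_per_segment[-1]]
            donors_per_segment.append(others[rng.integers(0, len(others))])
    genome: dict = {}
    donors: dict = {}
    breakpoints = []
    seg = 0
    for g, (og, chrom, idx) in enumerate(order):
        while seg < k and g >= cuts[seg]:
            seg += 1
        if seg > 0 and g == cuts[seg - 1]:
            breakpoints.append((chrom, idx))
        donor = donors_per_segment[seg]
        donors[og] = donor
        genome[og] = ancestors[donor][og]
    return genome, donors, breakpoints


# ---------------------------------------------------------------------------
# domestication mutations
# ---------------------------------------------------------------------------


def inject_domestication_mutations(
    genome: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    reserved: Optional[set] = None,
) -> tuple:
    """Inject private substitution and gap events into one strain's genome.

    Substitution events number ~Poisson(``intra_mut_rate``); each is
    synonymous or non-synonymous with event odds
    ``target_ns_odds * NEUTRAL_NS_ODDS`` and replaces the codon with a random
    same-amino-acid codon (syn) or different-amino-acid sense codon (nonsyn).
    Gap events (~Poisson(``gap_rate``)) delete one whole codon, emitted as
    ``---`` so alignment columns are preserved.

    ``reserved`` is a shared per-clade set of (og_id, codon_index) positions;
    events avoid reserved positions and their immediate codon neighbours, so
    every event in a clade is a distinct, non-adjacent variant — each injected
    mutation stays individually countable downstream.

    Returns ``(aligned_genome, events)`` where aligned_genome maps og_id to
    the gapped (column-preserving) sequence.
    """
    reserved = set() if reserved is None else reserved
    ogs = list(genome)
    codons = {og: [genome[og][i : i + 3] for i in range(0, len(genome[og]), 3)] for og in ogs}
    n_internal = config.gene_length - 2
    total = len(ogs) * n_internal

    odds = config.target_ns_odds * NEUTRAL_NS_ODDS
    p_nonsyn = odds / (1.0 + odds)

    n_sub = rng.poisson(config.intra_mut_rate)
    n_gap = rng.poisson(config.gap_rate)
    events = []

    def sample_position(require_syn_alt: bool) -> tuple:
        for _ in range(100_000):
            flat = int(rng.integers(0, total))
            og = ogs[flat // n_internal]
            ci = flat % n_internal + 1  # 0-based codon index, skipping ATG
            if any((og, ci + d) in reserved for d in (-1, 0, 1)):
                continue
            if require_syn_alt and not _SAME_AA_ALTS.get(codons[og][ci], ()):
                continue  # Met/Trp cannot host a synonymous change
            return og, ci
        raise RuntimeError("could not place a mutation event; genome too crowded")

    for _ in range(n_sub):
        kind = "nonsyn" if rng.random() < p_nonsyn else "syn"
        og, ci = sample_position(require_syn_alt=(kind == "syn"))
        ref = codons[og][ci]
        alts = _SAME_AA_ALTS[ref] if kind == "syn" else _DIFF_AA_ALTS[ref]
        alt = alts[rng.integers(0, len(alts))]
        codons[og][ci] = alt
        reserved.add((og, ci))
        events.append(
            InjectedMutation(
                strain="", og_id=og, codon_index=ci + 1, kind=kind, ref_codon=ref, alt_codon=alt
            )
        )

    for _ in range(n_gap):
        og, ci = sample_position(require_syn_alt=False)
        ref = codons[og][ci]
        codons[og][ci] = "---"
        reserved.add((og, ci))
        events.append(
            InjectedMutation(
                strain="", og_id=og, codon_index=ci + 1, kind="gap", ref_codon=ref, alt_codon="---"
            )
        )

    aligned = {og: "".join(codons[og]) for og in ogs}
    return aligned, events


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def simulate_depth(
    config: SimConfig,
    strain: str,
    copy_numbers: Mapping[str, int],
    rng: np.random.Generator,
) -> DepthTrack:
    """Per-base Poisson depth over the reference gene layout.

    Depth at every base of a gene is Poisson(``mean_depth`` x copy number);
    genes are laid end to end per chromosome with no intergenic gaps.
    """
    bp = 3 * config.gene_length
    frames = []
    gm = config.gene_map()
    for chrom in gm.chromosomes():
        ogs = gm.ogs_on(chrom)
        lam = np.repeat(
            [config.mean_depth * copy_numbers.get(og, 1) for og in ogs], bp
        )
        depth = rng.poisson(lam)
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position": np.arange(1, len(lam) + 1),
                    "depth": depth.astype(int),
                }
            )
        )
    return DepthTrack(strain=strain, frame=pd.concat(frames, ignore_index=True))


def default_cnv_spec(config: SimConfig) -> tuple:
    """A small deterministic CNV panel: duplications, an amplification, a deletion.

    Spread over distinct orthogroups and clades, mirroring the handful of
    clade-restricted copy-number differences seen among industrial strains.
    """
    ogs = config.og_ids()
    clades = config.clade_labels
    copies = (2, 3, 0, 4, 2, 3)
    step = max(1, len(ogs) // (len(copies) + 1))
    spec = []
    for i, cn in enumerate(copies):
        og = ogs[min((i + 1) * step, len(ogs) - 1)]
        spec.append((og, clades[i % len(clades)], cn))
    return tuple(spec)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _mat_contig(mat: str, rng: np.random.Generator) -> str:
    marker = MAT1_1_MARKER if mat == MAT1_1 else MAT1_2_MARKER
    if rng.random() < 0.5:
        marker = reverse_complement(marker)
    flank = lambda: "".join(_BASES[i] for i in rng.integers(0, 4, size=25))
    return flank() + marker + flank()


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate the full study dataset as a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    gm = config.gene_map()
    order = gm.global_order()
    ogs = [og for og, _, _ in order]
    ancestors = simulate_ancestors(config, rng)
    clades = config.clade_labels

    true_mat: dict = {}
    clade_mat = {c: (MAT1_1, MAT1_2)[rng.integers(0, 2)] for c in clades}

    aligned_genomes: dict = {}
    clade_of: dict = {}
    truth = SimTruth(
        donor={}, breakpoints={}, injected_mutations=[], true_copy_number={}, true_mat={}
    )

    for clade in clades:
        reserved: set = set()
        for i in range(1, config.n_strains_per_clade + 1):
            sid = f"{clade}-{i}"
            clade_of[sid] = clade
            true_mat[sid] = clade_mat[clade]
            aligned, events = inject_domestication_mutations(
                ancestors[clade], config, rng, reserved=reserved
            )
            aligned_genomes[sid] = aligned
            for og in ogs:
                truth.donor[(sid, og)] = clade
            truth.breakpoints[sid] = []
            truth.injected_mutations.extend(replace(e, strain=sid) for e in events)

    for j in range(1, config.n_recombinants + 1):
        sid = f"R-{j}"
        clade_of[sid] = sid
        true_mat[sid] = (MAT1_1, MAT1_2)[rng.integers(0, 2)]
        genome, donors, breakpoints = simulate_recombinant_strain(
            ancestors, config, sid, rng
        )
        aligned, events = inject_domestication_mutations(genome, config, rng, reserved=set())
        aligned_genomes[sid] = aligned
        for og in ogs:
            truth.donor[(sid, og)] = donors[og]
        truth.breakpoints[sid] = breakpoints
        truth.injected_mutations.extend(replace(e, strain=sid) for e in events)

    truth.true_mat = true_mat

    cnv_spec = config.cnv_spec if config.cnv_spec is not None else default_cnv_spec(config)
    strains = list(clade_of)
    for sid in strains:
        for og in ogs:
            truth.true_copy_number[(sid, og)] = 1
    for og, clade, cn in cnv_spec:
        if og not in set(ogs):
            raise ValueError(f"cnv_spec references unknown orthogroup {og!r}")
        for sid in strains:
            if clade_of[sid] == clade:
                truth.true_copy_number[(sid, og)] = int(cn)

    depth: dict = {}
    for sid in strains:
        copies = {og: truth.true_copy_number[(sid, og)] for og in ogs}
        depth[sid] = simulate_depth(config, sid, copies, rng)

    genomes: dict = {}
    for sid in strains:
        contigs: dict = {}
        for chrom in gm.chromosomes():
            contigs[chrom] = "".join(
                aligned_genomes[sid][og].replace("-", "") for og in gm.ogs_on(chrom)
            )
        contigs["MAT_locus"] = _mat_contig(true_mat[sid], rng)
        genomes[sid] = contigs

    alignments = AlignmentSet(
        alignments=tuple(
            GeneAlignment(og_id=og, sequences={s: aligned_genomes[s][og] for s in strains})
            for og in ogs
        ),
        strains=tuple(sorted(strains)),
    )

    return SimDataset(
        config=config,
        gene_map=gm,
        gene_spans=config.gene_spans(),
        ancestors=ancestors,
        alignments=alignments,
        genomes=genomes,
        depth=depth,
        truth=truth,
        clade_of=clade_of,
    )


def reconstruct_from_truth(dataset: SimDataset, strain: str) -> dict:
    """Replay the truth tables onto the ancestors to rebuild a strain's genes.

    Donor assignment plus the injected-mutation list must reproduce the
    emitted aligned sequences exactly — the simulator's conservation contract.
    """
    config = dataset.config
    out: dict = {}
    for og in config.og_ids():
        donor = dataset.truth.donor[(strain, og)]
        codons = [
            dataset.ancestors[donor][og][i : i + 3]
            for i in range(0, 3 * config.gene_length, 3)
        ]
        out[og] = codons
    for mut in dataset.truth.injected_mutations:
        if mut.strain != strain:
            continue
        out[mut.og_id][mut.codon_index - 1] = mut.alt_codon
    return {og: "".join(c) for og, c in out.items()}


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_dataset(config: SimConfig, output_dir) -> dict:
    """Write the simulated dataset to disk; returns {relative path: sha256}.

    Layout: ``alignments/<og>.fasta``, ``gene_map.tsv``, ``gene_spans.tsv``,
    ``depth/<strain>.tsv`` (samtools-depth dialect), ``genomes/<strain>.fasta``,
    ``markers.fasta`` and ``truth/*.tsv``, plus a ``manifest.tsv`` with
    checksums.  A partial write aborts and removes everything it created.
    """
    out = Path(output_dir)
    created_root = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def target(rel: str) -> Path:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        written.append(p)
        return p

    try:
        ds = simulate_dataset(config)
        for aln in ds.alignments:
            write_fasta(dict(aln.sequences), target(f"alignments/{aln.og_id}.fasta"))
        ds.gene_map.frame.to_csv(target("gene_map.tsv"), sep="\t", index=False)
        ds.gene_spans.to_csv(target("gene_spans.tsv"), sep="\t", index=False)
        for sid, track in ds.depth.items():
            track.frame.to_csv(target(f"depth/{sid}.tsv"), sep="\t", index=False, header=False)
        for sid, contigs in ds.genomes.items():
            write_fasta(contigs, target(f"genomes/{sid}.fasta"))
        write_fasta(
            {"MAT1-1": MAT1_1_MARKER, "MAT1-2": MAT1_2_MARKER}, target("markers.fasta")
        )

        pd.DataFrame(
            {"strain": list(ds.clade_of), "clade": list(ds.clade_of.values())}
        ).to_csv(target("truth/clades.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"strain": list(ds.truth.true_mat), "mat": list(ds.truth.true_mat.values())}
        ).to_csv(target("truth/mat.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(s, og, d) for (s, og), d in ds.truth.donor.items()],
            columns=["strain", "og_id", "donor"],
        ).to_csv(target("truth/donors.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                (s, chrom, idx)
                for s, bps in ds.truth.breakpoints.items()
                for chrom, idx in bps
            ],
            columns=["strain", "chromosome", "order_index"],
        ).to_csv(target("truth/breakpoints.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                (m.strain, m.og_id, m.codon_index, m.kind, m.ref_codon, m.alt_codon)
                for m in ds.truth.injected_mutations
            ],
            columns=["strain", "og_id", "codon_index", "kind", "ref_codon", "alt_codon"],
        ).to_csv(target("truth/mutations.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(s, og, cn) for (s, og), cn in ds.truth.true_copy_number.items()],
            columns=["strain", "og_id", "copy_number"],
        ).to_csv(target("truth/copy_number.tsv"), sep="\t", index=False)

        manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(written)}
        pd.DataFrame(
            {"file": list(manifest), "sha256": list(manifest.values())}
        ).to_csv(out / "manifest.tsv", sep="\t", index=False)
        return manifest
    except BaseException:
        if created_root:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in written:
                p.unlink(missing_ok=True)
        raise


# ---------------------------------------------------------------------------
# truth-recovery scoring
# ---------------------------------------------------------------------------


def donor_label_accuracy(dataset: SimDataset, strain: str, tracks) -> float:
    """Fraction of genes whose closest-clade label matches the true donor."""
    correct = total = 0
    for track in tracks:
        for og, label in zip(track.og_ids, track.closest):
            total += 1
            if label == dataset.truth.donor[(strain, og)]:
                correct += 1
    return correct / total


def breakpoint_recall(dataset: SimDataset, strain: str, tracks, tolerance: int = 10) -> float:
    """Fraction of true breakpoints with a track label change within +-tolerance genes."""
    from .mosaic import detect_label_changes

    changes = {t.chromosome: detect_label_changes(t) for t in tracks}
    true_bps = dataset.truth.breakpoints[strain]
    if not true_bps:
        return 1.0
    hit = 0
    for chrom, idx in true_bps:
        if any(abs(c - idx) <= tolerance for c in changes.get(chrom, [])):
            hit += 1
    return hit / len(true_bps)


# ---------------------------------------------------------------------------
# flat key=value config files (CLI)
# ---------------------------------------------------------------------------

_INT_FIELDS = {
    "n_clades", "gene_length", "n_strains_per_clade", "n_recombinants",
    "n_crossovers", "seed",
}
_FLOAT_FIELDS = {"divergence", "intra_mut_rate", "target_ns_odds", "gap_rate", "mean_depth"}


def parse_config_file(path) -> SimConfig:
    """Parse a flat key=value text file mirroring :class:`SimConfig`.

    Lists are comma-separated (``genes_per_chromosome=100,100``); CNV entries
    are ``og:clade:copies`` triplets separated by semicolons
    (``cnv_spec=OG00010:A:2;OG00020:B:0``).
    """
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key == "genes_per_chromosome":
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "cnv_spec":
            entries = []
            for item in value.split(";"):
                og, clade, cn = item.strip().split(":")
                entries.append((og, clade, int(cn)))
            kwargs[key] = tuple(entries)
        else:
            raise ValueError(f"{path}, line {lineno}: unknown config key {key!r}")
    return SimConfig(**kwargs)
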