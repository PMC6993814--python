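import math
from dataclasses import replace

import numpy as np
import pytest

from kojigenomics import core_io
from kojigenomics.mutspec import GENETIC_CODE
from kojigenomics.synthetic_data import (
    NEUTRAL_NS_ODDS,
    SimConfig,
    emit_dataset,
    inject_domestication_mutations,
    reconstruct_from_truth,
    simulate_ancestors,
    simulate_depth,
    simulate_recombinant_strain,
)

TINY = SimConfig(
    n_clades=3,
    genes_per_chromosome=(10, 10),
    gene_length=30,
    divergence=0.02,
    n_strains_per_clade=2,
    n_recombinants=1,
    n_crossovers=3,
    intra_mut_rate=0.5,
    gap_rate=0.5,
    mean_depth=40.0,
    seed=3,
)


def _pairwise_pdist(a: str, b: str) -> float:
    diff = sum(1 for x, y in zip(a, b) if x != y)
    return diff / len(a)


class TestAncestors:
    def test_pairwise_divergence_within_binomial_ci(self):
        # 50 genes x 200 codons = 30,000 sites per pair: the realised mean
        # p-distance must sit inside the binomial envelope around 1%
        cfg = SimConfig(
            n_clades=3,
            genes_per_chromosome=(50,),
            gene_length=200,
            divergence=0.01,
            seed=5,
        )
        anc = simulate_ancestors(cfg)
        dists = []
        labels = cfg.clade_labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a = "".join(anc[labels[i]][og] for og in cfg.og_ids())
                b = "".join(anc[labels[j]][og] for og in cfg.og_ids())
                dists.append(_pairwise_pdist(a, b))
        assert 0.0085 <= np.mean(dists) <= 0.0115

    def test_cds_structure_preserved(self):
        anc = simulate_ancestors(TINY)
        stops = {"TAA", "TAG", "TGA"}
        for clade in TINY.clade_labels:
            for og, seq in anc[clade].items():
                assert seq.startswith("ATG")
                assert seq[-3:] in stops
                internal = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
                assert not any(c in stops for c in internal)

    def test_vanishing_divergence_gives_identical_ancestors(self):
        cfg = replace(TINY, divergence=1e-9)
        anc = simulate_ancestors(cfg)
        first = anc[cfg.clade_labels[0]]
        for clade in cfg.clade_labels[1:]:
            assert anc[clade] == first

    def test_same_seed_is_bit_identical(self):
        assert simulate_ancestors(TINY) == simulate_ancestors(TINY)


class TestRecombination:
    def test_zero_crossovers_single_donor(self):
        anc = simulate_ancestors(TINY)
        rng = np.random.default_rng(0)
        genome, donors, bps = simulate_recombinant_strain(
            anc, TINY, "q", rng, n_crossovers=0
        )
        assert len(set(donors.values())) == 1
        assert bps == []

    def test_crossovers_partition_into_segments(self):
        anc = simulate_ancestors(TINY)
        rng = np.random.default_rng(1)
        genome, donors, bps = simulate_recombinant_strain(anc, TINY, "q", rng)
        assert len(bps) == TINY.n_crossovers
        order = [og for og, _, _ in TINY.gene_map().global_order()]
        seq = [donors[og] for og in order]
        segments = [seq[0]]
        for label in seq[1:]:
            if label != segments[-1]:
                segments.append(label)
        # segments cut only at the recorded breakpoints; adjacent donors differ
        assert len(segments) == TINY.n_crossovers + 1
        # each gene is copied verbatim from its donor's ancestral sequence
        for og in order:
            assert genome[og] == anc[donors[og]][og]

    def test_too_many_crossovers_rejected(self):
        anc = simulate_ancestors(TINY)
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="junctions"):
            simulate_recombinant_strain(anc, TINY, "q", rng, n_crossovers=100)

    def test_donor_shares_uniform_over_seeds(self):
        # Monte-Carlo over 200 rng streams: every clade takes ~1/3 of genes
        anc = simulate_ancestors(TINY)
        counts = {c: 0 for c in TINY.clade_labels}
        total = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            _, donors, _ = simulate_recombinant_strain(anc, TINY, "q", rng)
            for d in donors.values():
                counts[d] += 1
                total += 1
        for clade in TINY.clade_labels:
            assert abs(counts[clade] / total - 1 / 3) < 0.06


class TestMutationInjection:
    def test_realised_nonsyn_fraction_matches_target(self):
        # choose the odds multiplier so E[nonsyn]/E[syn] = 2, inject ~1000
        # events, and check the realised fraction within 3 binomial SE of 2/3
        cfg = SimConfig(
            n_clades=2,
            genes_per_chromosome=(100,),
            gene_length=100,
            divergence=0.01,
            intra_mut_rate=1000.0,
            gap_rate=0.0,
            target_ns_odds=2.0 / NEUTRAL_NS_ODDS,
            seed=9,
        )
        anc = simulate_ancestors(cfg)
        rng = np.random.default_rng(99)
        _, events = inject_domestication_mutations(anc["A"], cfg, rng)
        n_syn = sum(1 for e in events if e.kind == "syn")
        n_nonsyn = sum(1 for e in events if e.kind == "nonsyn")
        n = n_syn + n_nonsyn
        p_hat = n_nonsyn / n
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p_hat - 2 / 3) <= 3 * se

    def test_zero_rates_leave_genome_unchanged(self):
        cfg = replace(TINY, intra_mut_rate=0.0, gap_rate=0.0)
        anc = simulate_ancestors(cfg)
        rng = np.random.default_rng(4)
        aligned, events = inject_domestication_mutations(anc["A"], cfg, rng)
        assert events == []
        assert aligned == dict(anc["A"])

    def test_syn_events_preserve_protein(self, dataset):
        syn = [m for m in dataset.truth.injected_mutations if m.kind == "syn"]
        assert syn, "fixture config must produce at least one synonymous event"
        for m in syn:
            assert GENETIC_CODE[m.ref_codon] == GENETIC_CODE[m.alt_codon]
            assert m.ref_codon != m.alt_codon

    def test_gap_events_delete_whole_codons(self, dataset):
        gaps = [m for m in dataset.truth.injected_mutations if m.kind == "gap"]
        assert gaps
        for m in gaps:
            assert m.alt_codon == "---"


class TestDepthSimulation:
    def test_duplicated_gene_doubles_depth(self):
        cfg = SimConfig(
            n_clades=2, genes_per_chromosome=(5,), gene_length=200, mean_depth=100.0
        )
        rng = np.random.default_rng(12)
        og = cfg.og_ids()[2]
        track = simulate_depth(cfg, "s", {og: 2}, rng)
        spans = cfg.gene_spans().set_index("og_id")
        start, end = spans.loc[og, ["start", "end"]]
        sub = track.frame[
            (track.frame["position"] >= start) & (track.frame["position"] < end)
        ]
        assert 180 <= sub["depth"].mean() <= 220  # Poisson CI at 600 bp

    def test_zero_mean_depth_gives_zero_track(self):
        cfg = replace(TINY, mean_depth=0.0)
        rng = np.random.default_rng(0)
        track = simulate_depth(cfg, "s", {}, rng)
        assert (track.frame["depth"] == 0).all()

    def test_same_seed_gives_identical_track(self):
        cfg = TINY
        t1 = simulate_depth(cfg, "s", {}, np.random.default_rng(5))
        t2 = simulate_depth(cfg, "s", {}, np.random.default_rng(5))
        assert t1.frame.equals(t2.frame)


class TestDatasetContracts:
    def test_truth_replay_reproduces_emitted_sequences(self, dataset):
        for strain in dataset.strains:
            rebuilt = reconstruct_from_truth(dataset, strain)
            for og in dataset.config.og_ids():
                assert rebuilt[og] == dataset.alignments.get(og).sequences[strain]

    def test_gap_column_conservation(self, dataset):
        for strain in dataset.strains:
            n_gap_events = sum(
                1
                for m in dataset.truth.injected_mutations
                if m.strain == strain and m.kind == "gap"
            )
            n_dash = sum(
                aln.sequences[strain].count("-") for aln in dataset.alignments
            )
            assert n_dash == 3 * n_gap_events

    def test_degapped_frames_stay_in_frame_without_stops(self, dataset):
        stops = {"TAA", "TAG", "TGA"}
        for aln in dataset.alignments:
            for strain, seq in aln.sequences.items():
                cds = seq.replace("-", "")
                assert len(cds) % 3 == 0
                internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
                # nonsyn replacements exclude stop codons by construction
                assert not any(c in stops for c in internal)

    def test_recombinant_breakpoint_counts(self, dataset):
        cfg = dataset.config
        for strain, bps in dataset.truth.breakpoints.items():
            expected = cfg.n_crossovers if strain.startswith("R-") else 0
            assert len(bps) == expected


class TestEmission:
    def test_emitted_dataset_reads_back_end_to_end(self, tmp_path, small_config):
        out = tmp_path / "ds"
        manifest = emit_dataset(small_config, out)
        assert manifest
        aset = core_io.read_alignment_set(out / "alignments")
        assert len(aset) == small_config.n_genes
        gm = core_io.read_gene_map(out / "gene_map.tsv")
        assert gm.chromosomes() == ["I", "II"]
        core_io.read_gene_spans(out / "gene_spans.tsv")
        strain = aset.strains[0]
        track = core_io.read_depth_table(out / "depth" / f"{strain}.tsv", strain)
        assert len(track.frame) == small_config.n_genes * 3 * small_config.gene_length
        markers = core_io.read_fasta(out / "markers.fasta")
        assert set(markers) == {"MAT1-1", "MAT1-2"}

    def test_checksums_stable_for_same_seed(self, tmp_path, small_config):
        m1 = emit_dataset(small_config, tmp_path / "a")
        m2 = emit_dataset(small_config, tmp_path / "b")
        assert m1 == m2

    def test_different_seed_changes_content(self, tmp_path, small_config):
        m1 = emit_dataset(small_config, tmp_path / "a")
        m2 = emit_dataset(replace(small_config, seed=small_config.seed + 1), tmp_path / "b")
        assert m1 != m2
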