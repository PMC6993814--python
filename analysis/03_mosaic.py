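#!/usr/bin/env python
"""Chromosomal mosaicism scan of the recombinant query strains.

For each recombinant strain, computes per-gene identity to every clade
reference, the windowed closest-clade track along both chromosomes, the
genome share per clade, and the two-clade mixture verdict; then scores donor
labels and breakpoints against the simulator truth.
"""

from pathlib import Path

import pandas as pd

from kojigenomics import mosaic
from kojigenomics.core_io import CladeAssignment, read_alignment_set, read_gene_map

DATASET = Path("scratch/dataset")
RESULTS = Path("results")
WINDOW = 21


def main() -> None:
    aset = read_alignment_set(DATASET / "alignments")
    gene_map = read_gene_map(DATASET / "gene_map.tsv")
    truth = pd.read_csv(DATASET / "truth/clades.tsv", sep="\t")
    assignment = CladeAssignment(labels=dict(zip(truth["strain"], truth["clade"])))
    clade_labels = sorted(c for c in assignment.clades() if not c.startswith("R-"))
    queries = sorted(s for s in assignment.strains if s.startswith("R-"))

    donors = pd.read_csv(DATASET / "truth/donors.tsv", sep="\t")
    bps = pd.read_csv(DATASET / "truth/breakpoints.tsv", sep="\t")

    refs = mosaic.clade_references(aset, assignment, clade_labels)
    RESULTS.mkdir(exist_ok=True)
    share_rows, mixture_rows = [], []
    for strain in queries:
        profile = mosaic.identity_profile(strain, aset, refs)
        tracks = mosaic.mosaic_track(profile, gene_map, window=WINDOW)
        pd.concat([t.to_frame() for t in tracks], ignore_index=True).assign(
            strain=strain
        ).to_csv(RESULTS / f"03_mosaic_track_{strain}.tsv", sep="\t", index=False)

        share = mosaic.genome_share(profile)
        for clade, value in share.share.items():
            share_rows.append({"strain": strain, "clade": clade, "share": value})
        verdict = mosaic.mixture_test(profile)
        mixture_rows.append(
            {
                "strain": strain,
                "best_pair": "|".join(verdict.best_pair),
                "pair_coverage": round(verdict.best_pair_coverage, 4),
                "is_mixture": verdict.is_mixture,
            }
        )

        # score against truth
        true_donor = dict(
            zip(donors[donors["strain"] == strain]["og_id"],
                donors[donors["strain"] == strain]["donor"])
        )
        correct = total = 0
        for t in tracks:
            for og, label in zip(t.og_ids, t.closest):
                total += 1
                correct += label == true_donor[og]
        changes = {t.chromosome: mosaic.detect_label_changes(t) for t in tracks}
        strain_bps = bps[bps["strain"] == strain]
        hit = sum(
            1
            for _, row in strain_bps.iterrows()
            if any(abs(c - row["order_index"]) <= 10 for c in changes.get(row["chromosome"], []))
        )
        print(
            f"{strain}: donor labels correct {100 * correct / total:.1f}%; "
            f"breakpoints recovered {hit}/{len(strain_bps)} (+-10 genes); "
            f"top shares "
            + ", ".join(
                f"{c}={100 * share.share[c]:.0f}%"
                for c in sorted(share.share, key=share.share.get, reverse=True)[:3]
            )
        )

    pd.DataFrame(share_rows).to_csv(RESULTS / "03_genome_share.tsv", sep="\t", index=False)
    pd.DataFrame(mixture_rows).to_csv(RESULTS / "03_mixture.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
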