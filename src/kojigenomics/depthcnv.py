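"""Read-depth based gene copy-number estimation and intra-clade CNV detection.

Per-gene mean read depth, normalised by a strain-level constant (the median
per-gene mean depth, robust against the CNV genes themselves), is interpreted
directly as gene copy number: a single-copy gene normalises to ~1, a
duplicated gene to ~2, a deleted gene to ~0.  Integer calls use round-half-up;
the continuous value is retained for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CladeAssignment, DepthTrack


@dataclass(frozen=True)
class GeneDepth:
    """Depth summary for one (strain, orthogroup)."""

    strain: str
    og_id: str
    mean_depth: float
    normalized: float
    copy_number: int

    def __post_init__(self) -> None:
        if self.normalized < 0:
            raise ValueError("normalized depth must be non-negative")
        if self.copy_number != _round_half_up(self.normalized):
            raise ValueError("copy_number must equal round-half-up(normalized)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gene_mean_depth(depth_track: DepthTrack, gene_spans: pd.DataFrame) -> dict:
    """Mean per-base depth over each gene span (og_id -> float).

    Spans are 1-based half-open ``[start, end)``; positions absent from the
    track count as depth 0 (so a half-missing span halves the mean).  A span
    on a chromosome the track does not cover at all is an error.
    """
    track_chroms = {}
    for chrom, sub in depth_track.frame.groupby("chromosome", sort=False):
        track_chroms[chrom] = (
            sub["position"].to_numpy(),
            sub["depth"].to_numpy(dtype=float),
        )
    means: dict = {}
    for row in gene_spans.itertuples(index=False):
        if row.chromosome not in track_chroms:
            raise ValueError(
                f"gene {row.og_id}: chromosome {row.chromosome!r} absent from the "
                f"depth track of {depth_track.strain}"
            )
        pos, dep = track_chroms[row.chromosome]
        lo, hi = np.searchsorted(pos, [row.start, row.end])
        span = int(row.end) - int(row.start)
        means[row.og_id] = float(dep[lo:hi].sum() / span)
    return means


def normalize_depths(mean_depths: Mapping[str, float], strain: str) -> list:
    """Normalise per-gene mean depths to copy numbers for one strain.

    The normalisation constant is the median per-gene mean depth; at least
    10 genes are required for it to be meaningful, and a zero median means
    there is no usable coverage.
    """
    if len(mean_depths) < 10:
        raise ValueError(
            f"strain {strain}: need at least 10 genes to normalise, got {len(mean_depths)}"
        )
    median = float(np.median(list(mean_depths.values())))
    if median == 0:
        raise ValueError(f"strain {strain}: median gene depth is 0 (no usable coverage)")
    rows = []
    for og_id, mean in mean_depths.items():
        normalized = mean / median
        rows.append(
            GeneDepth(
                strain=strain,
                og_id=og_id,
                mean_depth=float(mean),
                normalized=normalized,
                copy_number=_round_half_up(normalized),
            )
        )
    return rows


@dataclass(frozen=True)
class CnvReport:
    """Per (orthogroup, clade) copy-number variability."""

    rows: pd.DataFrame  # og_id, clade, copy_numbers, intra_cladal_variable
    n_og_variable_1plus: int  # OGs variable within >= 1 clade
    n_og_variable_2plus: int  # OGs variable within >= 2 clades


def cnv_by_clade(gene_depths: Sequence[GeneDepth], assignment: CladeAssignment) -> CnvReport:
    """Distinct copy numbers per (orthogroup, clade) and variability flags."""
    calls: dict = {}
    for gd in gene_depths:
        clade = assignment.labels.get(gd.strain)
        if clade is None:
            raise ValueError(f"strain {gd.strain} has no clade label")
        calls.setdefault((gd.og_id, clade), set()).add(gd.copy_number)
    records = []
    variable_clades: dict = {}
    for (og_id, clade), copies in sorted(calls.items()):
        variable = len(copies) >= 2
        if variable:
            variable_clades.setdefault(og_id, set()).add(clade)
        records.append(
            {
                "og_id": og_id,
                "clade": clade,
                "copy_numbers": ",".join(str(c) for c in sorted(copies)),
                "intra_cladal_variable": variable,
            }
        )
    rows = pd.DataFrame(
        records,
        columns=["og_id", "clade", "copy_numbers", "intra_cladal_variable"],
    )
    n1 = sum(1 for v in variable_clades.values() if len(v) >= 1)
    n2 = sum(1 for v in variable_clades.values() if len(v) >= 2)
    return CnvReport(rows=rows, n_og_variable_1plus=n1, n_og_variable_2plus=n2)
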