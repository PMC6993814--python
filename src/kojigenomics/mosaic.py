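"""Chromosomal mosaicism: closest-clade scanning along gene order.

A recombinant genome carries contiguous blocks of genes inherited from
different ancestral clades.  The scan works at gene resolution: for every
orthogroup, a strain's aligned gene sequence either is or is not exactly
identical to each clade's reference (the per-column majority consensus of the
clade members).  Averaging those 0/1 indicators in a sliding window along the
reference gene order gives a per-clade similarity score in percent, and the
argmax clade per position is the "closest clade" track whose colour switches
mark ancestral recombination breakpoints.

A strain's overall share of genes identical to a clade's reference need not
sum to one over clades — a conserved gene can be identical to several clade
references at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import AlignmentSet, CladeAssignment, GeneOrderMap

DEFAULT_WINDOW = 21  # genes
UNASSIGNED = "unassigned"

#: fixed tie order for consensus columns
_CONSENSUS_ORDER = b"ACGTN-"


def clade_reference(
    alignment_set: AlignmentSet, assignment: CladeAssignment, clade: str
) -> dict:
    """Per-orthogroup majority-consensus reference sequence for one clade.

    Column ties are broken by the fixed order A < C < G < T < N < -; columns
    whose majority is a gap stay "-" in the reference.  A single-member clade's
    reference is that member's sequence.
    """
    members = assignment.members(clade)
    if not members:
        raise ValueError(f"clade {clade!r} has no members")
    refs: dict = {}
    for aln in alignment_set:
        arr = np.array(
            [np.frombuffer(aln.sequences[s].encode(), dtype="S1") for s in members]
        )
        counts = np.array([(arr == bytes([sym])).sum(axis=0) for sym in _CONSENSUS_ORDER])
        # argmax returns the first maximum, i.e. the earliest symbol in the tie order
        winner = np.argmax(counts, axis=0)
        refs[aln.og_id] = bytes(_CONSENSUS_ORDER[w] for w in winner).decode()
    return refs


def clade_references(
    alignment_set: AlignmentSet, assignment: CladeAssignment, clades=None
) -> dict:
    """References for several clades at once: clade -> og_id -> sequence."""
    if clades is None:
        clades = assignment.clades()
    return {c: clade_reference(alignment_set, assignment, c) for c in clades}


@dataclass(frozen=True)
class IdentityProfile:
    """Per-gene exact-identity indicators of one strain against clade references."""

    strain: str
    clades: tuple
    og_ids: tuple
    indicator: Mapping[tuple, int]  # (clade, og_id) -> 0/1

    def vector(self, clade: str, og_ids=None) -> np.ndarray:
        ogs = self.og_ids if og_ids is None else og_ids
        return np.array([self.indicator[(clade, og)] for og in ogs], dtype=float)


def identity_profile(
    query_strain: str, alignment_set: AlignmentSet, references: Mapping[str, Mapping[str, str]]
) -> IdentityProfile:
    """Indicator = 1 iff the query's aligned gene equals the clade reference.

    Columns gapped in BOTH the query and the reference are ignored before the
    comparison (a shared deletion is not a difference); any other mismatch,
    including a gap on one side only, breaks identity.
    """
    clades = tuple(references)
    og_ids = tuple(a.og_id for a in alignment_set)
    indicator: dict = {}
    for aln in alignment_set:
        if query_strain not in aln.sequences:
            raise ValueError(f"strain {query_strain!r} missing from orthogroup {aln.og_id}")
        q = np.frombuffer(aln.sequences[query_strain].encode(), dtype="S1")
        for clade in clades:
            try:
                ref = references[clade][aln.og_id]
            except KeyError:
                raise ValueError(
                    f"no reference for clade {clade!r}, orthogroup {aln.og_id}"
                ) from None
            r = np.frombuffer(ref.encode(), dtype="S1")
            keep = ~((q == b"-") & (r == b"-"))
            indicator[(clade, aln.og_id)] = int(bool((q[keep] == r[keep]).all()))
    return IdentityProfile(
        strain=query_strain, clades=clades, og_ids=og_ids, indicator=indicator
    )


@dataclass(frozen=True)
class MosaicTrack:
    """Windowed similarity scores and closest-clade labels along one chromosome."""

    strain: str
    chromosome: str
    window: int
    og_ids: tuple  # in order_index order
    scores: Mapping[str, np.ndarray]  # clade -> percent, aligned with og_ids
    closest: tuple  # clade label or "unassigned" per position

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chromosome": self.chromosome,
            "order_index": np.arange(1, len(self.og_ids) + 1),
            "og_id": list(self.og_ids),
        }
        for clade in self.scores:
            data[f"score_{clade}"] = self.scores[clade]
        data["closest"] = list(self.closest)
        return pd.DataFrame(data)


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over a window centered at each position, clipped at the ends.

    The window shrinks symmetrically near chromosome ends (half-width
    ``min(window//2, i, n-1-i)``), so it is always genuinely centered and the
    location of a score change stays unbiased right up to the edges.
    """
    n = len(values)
    half = np.minimum(window // 2, np.minimum(np.arange(n), np.arange(n)[::-1]))
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = idx - half
    hi = idx + half + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def mosaic_track(
    profile: IdentityProfile, gene_map: GeneOrderMap, window: int = DEFAULT_WINDOW
) -> list:
    """Closest-clade tracks for every chromosome in the gene map.

    ``score(clade, i)`` is 100x the mean identity indicator in the window of
    ``window`` genes centered at position ``i`` (clipped at chromosome ends);
    ``closest(i)`` is the argmax clade, with exact ties left "unassigned"
    rather than fabricating mosaic structure.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    tracks = []
    for chrom in gene_map.chromosomes():
        ogs = gene_map.ogs_on(chrom)
        missing = [og for og in ogs if (profile.clades[0], og) not in profile.indicator]
        if missing:
            raise ValueError(
                f"gene map lists orthogroups absent from the identity profile: {missing[:5]}"
            )
        w = window
        if w > len(ogs):
            w = len(ogs) if len(ogs) % 2 == 1 else len(ogs) - 1
            w = max(w, 1)
            warnings.warn(
                f"window {window} larger than chromosome {chrom} "
                f"({len(ogs)} genes); clipped to {w}"
            )
        scores = {
            clade: 100.0 * _windowed_mean(profile.vector(clade, ogs), w)
            for clade in profile.clades
        }
        mat = np.array([scores[c] for c in profile.clades])
        best = mat.max(axis=0)
        n_best = (mat == best).sum(axis=0)
        arg = mat.argmax(axis=0)
        closest = tuple(
            profile.clades[a] if k == 1 else UNASSIGNED for a, k in zip(arg, n_best)
        )
        tracks.append(
            MosaicTrack(
                strain=profile.strain,
                chromosome=chrom,
                window=w,
                og_ids=tuple(ogs),
                scores=scores,
                closest=closest,
            )
        )
    return tracks


@dataclass(frozen=True)
class ShareSummary:
    """Fraction of genes identical to each clade's reference, one strain."""

    strain: str
    share: Mapping[str, float]


def genome_share(profile: IdentityProfile) -> ShareSummary:
    """share(clade) = mean identity indicator over all orthogroups."""
    share = {
        clade: float(profile.vector(clade).mean()) for clade in profile.clades
    }
    return ShareSummary(strain=profile.strain, share=share)


@dataclass(frozen=True)
class MixtureVerdict:
    """Result of the two-clade mixture test for one strain."""

    strain: str
    best_pair: tuple
    best_pair_coverage: float
    pair_member_shares: tuple
    is_mixture: bool
    coverage_threshold: float
    min_member_share: float


def mixture_test(
    profile: IdentityProfile,
    coverage_threshold: float = 0.95,
    min_member_share: float = 0.10,
) -> MixtureVerdict:
    """Can this genome be expressed as a mixture of two other clades?

    For every unordered clade pair (X, Y), pair coverage is the fraction of
    genes identical to X's or Y's reference.  The strain is declared a mixture
    iff the best pair covers at least ``coverage_threshold`` of genes AND each
    member of the pair individually covers at least ``min_member_share`` —
    both donors must actually contribute, so a single-donor genome is never a
    "mixture" of itself plus a bystander.
    """
    clades = profile.clades
    if len(clades) < 2:
        raise ValueError("mixture test requires at least 2 candidate clades")
    vectors = {c: profile.vector(c) for c in clades}
    best_pair = None
    best_cov = -1.0
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            x, y = clades[i], clades[j]
            cov = float(np.mean((vectors[x] + vectors[y]) > 0))
            if cov > best_cov:
                best_cov = cov
                best_pair = (x, y)
    x, y = best_pair
    shares = (float(vectors[x].mean()), float(vectors[y].mean()))
    is_mixture = best_cov >= coverage_threshold and all(
        s >= min_member_share for s in shares
    )
    return MixtureVerdict(
        strain=profile.strain,
        best_pair=best_pair,
        best_pair_coverage=best_cov,
        pair_member_shares=shares,
        is_mixture=is_mixture,
        coverage_threshold=coverage_threshold,
        min_member_share=min_member_share,
    )


def detect_label_changes(track: MosaicTrack) -> list:
    """Positions (1-based order_index) where the closest-clade label switches.

    "unassigned" stretches are bridged: a change is counted between
    consecutive *assigned* labels, at the position of the later gene.
    """
    changes = []
    prev = None
    for pos, label in enumerate(track.closest, start=1):
        if label == UNASSIGNED:
            continue
        if prev is not None and label != prev:
            changes.append(pos)
        prev = label
    return changes
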