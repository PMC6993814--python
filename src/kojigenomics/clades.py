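"""Clade structure from concatenated single-copy gene alignments.

The analysis chain is: remove every alignment column containing a gap in any
strain ("degapping"), concatenate the degapped gene sequences over all
orthogroups, compute pairwise p-distances, and cluster strains whose
concatenated dissimilarity stays within a small threshold (0.01% by default,
the bound observed for industrial koji-mould clades).  A neighbor-joining
tree over the same distances gives the between-clade topology — a deliberate
desk-scale substitute for maximum-likelihood inference, surfaced as such in
the CLI help.

Mating-type (MAT) idiomorphs are detected by exact marker search on assembled
sequences, and MAT x clade linkage is checked: in clonally propagated clades
every member must carry the same idiomorph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .core_io import (
    MAT1_1,
    MAT1_2,
    MAT_AMBIGUOUS,
    MAT_UNKNOWN,
    AlignmentSet,
    CladeAssignment,
    reverse_complement,
)

DEFAULT_CLADE_THRESHOLD = 1e-4  # 0.01% concatenated dissimilarity


@dataclass(frozen=True)
class ConcatenatedMatrix:
    """Concatenated degapped gene sequences (one gap-free row per strain)."""

    strains: tuple
    columns: int
    matrix: Mapping[str, str]
    retained: Mapping[str, int]  # og_id -> retained column count
    skipped: tuple  # og_ids that lost every column

    def __post_init__(self) -> None:
        for s in self.strains:
            row = self.matrix[s]
            if len(row) != self.columns:
                raise ValueError(f"row for {s} has {len(row)} columns, expected {self.columns}")
            if "-" in row:
                raise ValueError(f"row for {s} still contains gap characters")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix with zero diagonal, values in [0, 1]."""

    strains: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.strains)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match strain count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any() or (self.d > 1).any():
            raise ValueError("distances must lie in [0, 1]")

    def value(self, a: str, b: str) -> float:
        i, j = self.strains.index(a), self.strains.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class MatMarkers:
    """The two mating-type marker sequences (e.g. the published MAT primers)."""

    mat1_1: str
    mat1_2: str

    def __post_init__(self) -> None:
        if not self.mat1_1 or not self.mat1_2:
            raise ValueError("MAT markers must be non-empty")
        if self.mat1_1 == self.mat1_2:
            raise ValueError("MAT1-1 and MAT1-2 markers must differ")


def concat_degapped(alignment_set: AlignmentSet) -> ConcatenatedMatrix:
    """Degap each alignment (drop columns gapped in ANY strain) and concatenate.

    Orthogroups are concatenated in lexicographic og_id order.  An orthogroup
    whose every column carries a gap is skipped with a warning and listed in
    the result.
    """
    strains = tuple(sorted(alignment_set.strains))
    pieces = {s: [] for s in strains}
    retained: dict = {}
    skipped = []
    for aln in sorted(alignment_set, key=lambda a: a.og_id):
        arr = np.array(
            [np.frombuffer(aln.sequences[s].encode(), dtype="S1") for s in strains]
        )
        keep = ~(arr == b"-").any(axis=0)
        kept = int(keep.sum())
        if kept == 0:
            warnings.warn(f"orthogroup {aln.og_id}: all columns gapped; skipped")
            skipped.append(aln.og_id)
            continue
        retained[aln.og_id] = kept
        sub = arr[:, keep]
        for i, s in enumerate(strains):
            pieces[s].append(sub[i].tobytes().decode())
    matrix = {s: "".join(pieces[s]) for s in strains}
    columns = len(next(iter(matrix.values()))) if matrix else 0
    return ConcatenatedMatrix(
        strains=strains,
        columns=columns,
        matrix=matrix,
        retained=retained,
        skipped=tuple(skipped),
    )


def pdistance(concat: ConcatenatedMatrix) -> DistanceMatrix:
    """Proportion of differing columns between every strain pair.

    ``N`` is a wildcard matching anything (low-coverage ambiguity must not
    inflate distances).
    """
    if concat.columns < 1:
        raise ValueError("cannot compute distances over zero columns")
    strains = concat.strains
    rows = np.array(
        [np.frombuffer(concat.matrix[s].encode(), dtype="S1") for s in strains]
    )
    is_n = rows == b"N"
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = (rows[i] != rows[j]) & ~is_n[i] & ~is_n[j]
            d[i, j] = d[j, i] = diff.sum() / concat.columns
    return DistanceMatrix(strains=strains, d=d)


def cluster_clades(distmat: DistanceMatrix, threshold: float = DEFAULT_CLADE_THRESHOLD) -> dict:
    """Single-linkage clusters at distance <= threshold.

    Returns strain -> clade label; clusters are labelled "C1", "C2", ... in
    order of their first-appearing strain, and singletons form their own
    clades.  Single linkage at a cutoff is exactly the connected components of
    the graph joining pairs within the threshold — the weakest assumption
    consistent with "dissimilarity within the bound".
    """
    strains = distmat.strains
    n = len(strains)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if distmat.d[i, j] <= threshold:
                parent[find(i)] = find(j)

    labels: dict = {}
    root_label: dict = {}
    counter = 0
    for i, s in enumerate(strains):
        r = find(i)
        if r not in root_label:
            counter += 1
            root_label[r] = f"C{counter}"
        labels[s] = root_label[r]
    return labels


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(distmat: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining over a p-distance matrix.

    Ties in the Q matrix are broken by the smallest (i, j) node-creation
    index pair; a negative branch length is clamped to zero with the deficit
    moved to its sister branch so the joined pair keeps its observed distance.
    Returns an unrooted dendropy tree (trifurcating at the final join).
    """
    names = list(distmat.strains)
    if len(names) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(names)
    next_id = 0
    nodes: dict = {}
    dist: dict = {}
    for name in names:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes[next_id] = node
        next_id += 1
    for i in range(len(names)):
        for j in range(len(names)):
            if i != j:
                dist[(i, j)] = float(distmat.d[i, j])

    active = list(range(len(names)))  # ascending == creation order

    def clamp(li: float, lj: float) -> tuple:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for a_pos in range(m):
            for b_pos in range(a_pos + 1, m):
                i, j = active[a_pos], active[b_pos]
                q = (m - 2) * dist[(i, j)] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = dist[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = new
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[(i, k)] + dist[(j, k)] - dij)
            dist[(u, k)] = dist[(k, u)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
        active.sort()

    a, b, c = active
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    root = dendropy.Node()
    for k, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# MAT typing
# ---------------------------------------------------------------------------


def mat_type(genome_sequences, markers: MatMarkers) -> str:
    """Detect the MAT idiomorph of an assembly by exact marker search.

    Both strands are searched.  Exactly one marker found -> its type; neither
    -> ``unknown``; both -> ``ambiguous`` (values, not errors).
    """
    if isinstance(genome_sequences, str):
        genome_sequences = [genome_sequences]
    seqs = [s.upper() for s in genome_sequences]

    def present(marker: str) -> bool:
        rc = reverse_complement(marker)
        return any(marker in s or rc in s for s in seqs)

    has1 = present(markers.mat1_1)
    has2 = present(markers.mat1_2)
    if has1 and has2:
        return MAT_AMBIGUOUS
    if has1:
        return MAT1_1
    if has2:
        return MAT1_2
    return MAT_UNKNOWN


@dataclass(frozen=True)
class MatLdReport:
    """Per-clade observed MAT types and the linkage verdict."""

    per_clade: Mapping[str, tuple]
    flagged: tuple  # clades with more than one observed MAT type
    ambiguous_strains: tuple
    all_consistent: bool


def mat_clade_ld(assignment: CladeAssignment) -> MatLdReport:
    """Check that every clade carries a single MAT idiomorph.

    ``unknown`` (and ``ambiguous``, which is not a type) are excluded from the
    per-clade type sets; a clade showing both MAT1-1 and MAT1-2 is flagged.
    """
    per_clade: dict = {}
    ambiguous = tuple(
        s for s in assignment.strains if assignment.mat[s] == MAT_AMBIGUOUS
    )
    for clade in assignment.clades():
        types = {
            assignment.mat[s]
            for s in assignment.members(clade)
            if assignment.mat[s] in (MAT1_1, MAT1_2)
        }
        per_clade[clade] = tuple(sorted(types))
    flagged = tuple(c for c, t in per_clade.items() if len(t) > 1)
    return MatLdReport(
        per_clade=per_clade,
        flagged=flagged,
        ambiguous_strains=ambiguous,
        all_consistent=not flagged,
    )
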