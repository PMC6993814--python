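"""Shared domain types and file readers/writers.

Every external format the pipeline touches lives here: aligned multi-FASTA
(one file per orthogroup, filename = orthogroup id), the gene-order TSV that
anchors orthogroups to a reference chromosome layout, samtools-depth-style
per-base depth TSVs, and Newick trees.

Readers validate aggressively and raise ``ValueError`` with messages naming
the offending file/record; nothing is silently coerced.  Coordinates follow
the samtools convention (1-based positions); all internal window arithmetic
is half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

#: permitted sequence characters after normalisation
DNA_ALPHABET = frozenset("ACGTN-")

MAT1_1 = "MAT1-1"
MAT1_2 = "MAT1-2"
MAT_UNKNOWN = "unknown"
MAT_AMBIGUOUS = "ambiguous"
MAT_VALUES = (MAT1_1, MAT1_2, MAT_UNKNOWN, MAT_AMBIGUOUS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_strain_name(name: str) -> str:
    if not name or re.search(r"\s", name):
        raise ValueError(f"invalid strain name {name!r}: must be non-empty without whitespace")
    return name


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAlignment:
    """One orthogroup's aligned coding sequences across strains.

    All sequences share the same column count; gaps are ``-``; ``N`` is an
    ambiguous base.  This is the unit of all mutation and identity analysis.
    """

    og_id: str
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.og_id:
            raise ValueError("og_id must be non-empty")
        if not self.sequences:
            raise ValueError(f"alignment {self.og_id}: no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.og_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValueError(f"alignment {self.og_id}: zero-length alignment")
        for sid, seq in self.sequences.items():
            _check_strain_name(sid)
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"alignment {self.og_id}, strain {sid}: "
                    f"characters outside A/C/G/T/N/-: {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns (bp)."""
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> frozenset:
        return frozenset(self.sequences)


@dataclass(frozen=True)
class AlignmentSet:
    """A collection of single-copy orthogroup alignments over a common strain set."""

    alignments: tuple
    strains: tuple

    def __post_init__(self) -> None:
        common = frozenset(self.strains)
        seen = set()
        for aln in self.alignments:
            if aln.og_id in seen:
                raise ValueError(f"duplicate orthogroup id {aln.og_id}")
            seen.add(aln.og_id)
            if aln.strains != common:
                raise ValueError(
                    f"alignment {aln.og_id} violates the single-copy constraint: "
                    f"strains {sorted(aln.strains ^ common)} differ from the common set"
                )

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self) -> int:
        return len(self.alignments)

    def get(self, og_id: str) -> GeneAlignment:
        for aln in self.alignments:
            if aln.og_id == og_id:
                return aln
        raise KeyError(og_id)

    @property
    def og_ids(self) -> list:
        return [a.og_id for a in self.alignments]


@dataclass(frozen=True)
class GeneOrderMap:
    """Orthogroups anchored to a reference chromosome layout.

    ``frame`` columns: og_id, chromosome, order_index (1-based, consecutive
    within each chromosome).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_gene_map(self.frame, source="gene map")

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.frame["chromosome"]))

    def ogs_on(self, chromosome: str) -> list:
        sub = self.frame[self.frame["chromosome"] == chromosome]
        return list(sub.sort_values("order_index")["og_id"])

    def global_order(self) -> list:
        """(og_id, chromosome, order_index) tuples, chromosome by chromosome."""
        out = []
        for chrom in self.chromosomes():
            for i, og in enumerate(self.ogs_on(chrom), start=1):
                out.append((og, chrom, i))
        return out

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "GeneOrderMap":
        frame = pd.DataFrame(records, columns=["og_id", "chromosome", "order_index"])
        return cls(frame)


def _validate_gene_map(frame: pd.DataFrame, source: str) -> None:
    required = {"og_id", "chromosome", "order_index"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    if frame["og_id"].duplicated().any():
        dup = frame.loc[frame["og_id"].duplicated(), "og_id"].iloc[0]
        raise ValueError(f"{source}: duplicate og_id {dup!r}")
    pairs = frame[["chromosome", "order_index"]]
    if pairs.duplicated().any():
        row = pairs.loc[pairs.duplicated()].iloc[0]
        raise ValueError(
            f"{source}: duplicate (chromosome, order_index) "
            f"({row['chromosome']}, {row['order_index']})"
        )
    for chrom, sub in frame.groupby("chromosome", sort=False):
        idx = sorted(int(i) for i in sub["order_index"])
        expected = list(range(1, len(idx) + 1))
        if idx != expected:
            gaps = sorted(set(expected) - set(idx)) or idx[:1]
            raise ValueError(
                f"{source}: chromosome {chrom}: order indices not consecutive "
                f"from 1 (gap at {gaps[0]})"
            )


@dataclass(frozen=True)
class DepthTrack:
    """Per-base read depth for one strain (samtools-depth dialect).

    ``frame`` columns: chromosome, position (1-based), depth.  Positions are
    strictly increasing within a chromosome.
    """

    strain: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_strain_name(self.strain)
        _validate_depth_frame(self.frame, source=f"depth track for {self.strain}")

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.frame["chromosome"]))


def _validate_depth_frame(frame: pd.DataFrame, source: str) -> None:
    required = {"chromosome", "position", "depth"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    if (frame["depth"] < 0).any():
        row = frame.loc[frame["depth"] < 0].iloc[0]
        raise ValueError(
            f"{source}: negative depth {row['depth']} at "
            f"{row['chromosome']}:{row['position']}"
        )
    for chrom, sub in frame.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        if len(pos) > 1 and not (pos[1:] > pos[:-1]).all():
            bad = pos[1:][~(pos[1:] > pos[:-1])][0]
            raise ValueError(
                f"{source}: positions not strictly increasing on {chrom} "
                f"(around position {bad})"
            )


@dataclass
class CladeAssignment:
    """Strain -> clade label, plus strain -> MAT idiomorph.

    Every strain carries both a clade label (possibly its own singleton) and a
    MAT value from {MAT1-1, MAT1-2, unknown, ambiguous}.
    """

    labels: dict
    mat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.labels:
            _check_strain_name(s)
            self.mat.setdefault(s, MAT_UNKNOWN)
        extra = set(self.mat) - set(self.labels)
        if extra:
            raise ValueError(f"MAT values for strains without a clade label: {sorted(extra)}")
        bad = {v for v in self.mat.values() if v not in MAT_VALUES}
        if bad:
            raise ValueError(f"invalid MAT values {sorted(bad)}; expected one of {MAT_VALUES}")

    @property
    def strains(self) -> list:
        return list(self.labels)

    def members(self, clade: str) -> list:
        return [s for s, c in self.labels.items() if c == clade]

    def clades(self) -> list:
        return list(dict.fromkeys(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": list(self.labels),
                "clade": [self.labels[s] for s in self.labels],
                "mat": [self.mat[s] for s in self.labels],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CladeAssignment":
        labels = dict(zip(frame["strain"], frame["clade"]))
        mat = dict(zip(frame["strain"], frame.get("mat", ["unknown"] * len(frame))))
        return cls(labels=labels, mat=mat)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict:
    """Read a FASTA file into an ``{id: sequence}`` mapping.

    Sequences are upper-cased, ``U`` is mapped to ``T``, and record ids are
    the first whitespace-delimited token of the header.  Characters outside
    ``{A,C,G,T,N,-}`` after normalisation are a hard error.
    """
    path = Path(path)
    out: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{path}, record {rec.id}: characters outside A/C/G/T/N/-: {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


_FASTA_SUFFIXES = (".fasta", ".fa", ".fna")


def read_alignment_set(directory) -> AlignmentSet:
    """Read a directory of per-orthogroup aligned FASTA files.

    Filenames (minus suffix) are the orthogroup ids.  Every file must contain
    the same strain set (the single-copy constraint); files whose strain set
    differs from the most common set are rejected with a listing.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _FASTA_SUFFIXES
    )
    if not files:
        raise ValueError(f"{directory}: no alignment FASTA files found")
    parsed = []
    for path in files:
        seqs = read_fasta(path)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            offending = sorted(seqs)
            raise ValueError(
                f"{path}: sequences of unequal length within one alignment "
                f"(ids: {', '.join(offending)})"
            )
        parsed.append((path, path.stem, seqs))

    strain_sets = Counter(frozenset(seqs) for _, _, seqs in parsed)
    # majority strain set; ties broken toward the larger set
    common = max(strain_sets, key=lambda s: (strain_sets[s], len(s)))
    offenders = [str(path) for path, _, seqs in parsed if frozenset(seqs) != common]
    if offenders:
        raise ValueError(
            "alignment files whose strain set differs from the common set "
            f"{sorted(common)}: " + ", ".join(offenders)
        )
    alignments = tuple(GeneAlignment(og_id=og, sequences=seqs) for _, og, seqs in parsed)
    return AlignmentSet(alignments=alignments, strains=tuple(sorted(common)))


def read_gene_map(path) -> GeneOrderMap:
    """Read the gene-order TSV (columns: og_id, chromosome, order_index)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"og_id": str, "chromosome": str})
    try:
        return GeneOrderMap(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_depth_table(path, strain: str) -> DepthTrack:
    """Read a samtools-depth style 3-column TSV (chrom, 1-based pos, depth)."""
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "position", "depth"],
        dtype={"chromosome": str},
    )
    if frame.empty:
        raise ValueError(f"{path}: empty depth table")
    for col in ("position", "depth"):
        if not pd.api.types.is_integer_dtype(frame[col]):
            raise ValueError(f"{path}: column {col!r} is not integer-valued")
    try:
        return DepthTrack(strain=strain, frame=frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_gene_spans(path) -> pd.DataFrame:
    """Read gene spans TSV (og_id, chromosome, start, end; 1-based, half-open)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"og_id": str, "chromosome": str})
    required = {"og_id", "chromosome", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (frame["end"] <= frame["start"]).any():
        bad = frame.loc[frame["end"] <= frame["start"]].iloc[0]
        raise ValueError(f"{path}: empty span for {bad['og_id']}")
    return frame


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a dendropy tree to Newick with branch lengths.

    Branch lengths are printed with 8 significant digits; leaf names with
    Newick metacharacters are quoted per the standard, so the output
    round-trips through any standard parser.
    """
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,  # quote rather than mangle names with spaces
        real_value_format_specifier=".8g",
    )
    return text.strip() + "\n"


def read_newick(text: str, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", taxon_namespace=taxon_namespace
    )
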