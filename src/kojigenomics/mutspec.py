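"""Codon-level mutation spectra: synonymous / non-synonymous / gap counting.

Mutations are counted against a "revised coding sequence" — the per-clade
(or per-species) majority consensus of the aligned genes.  A codon in one
member that differs from the reference codon is classified by the standard
genetic code: same amino acid -> synonymous, different -> non-synonymous,
any gap character -> gap, any N (and no gap) -> ambiguous.  Codons that
differ at several positions are classified by the net amino-acid effect.

Counting is by *distinct variant*: the same alternate codon observed in
several clade members at the same site is one mutation event, and a maximal
run of consecutive gap codons in one member is one gap mutation (a single
indel event should not be multiply counted).  A per-occurrence mode is
available behind the ``distinct`` flag.

The enrichment statistic is an odds ratio against a baseline spectrum
(e.g. the intra-species spectrum of the wild sister species): the odds of
non-synonymous vs synonymous counts in the group divided by the same odds in
the baseline, with a two-sided Fisher exact p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .core_io import AlignmentSet, CladeAssignment
from .mosaic import clade_reference

KIND_SYN = "syn"
KIND_NONSYN = "nonsyn"
KIND_GAP = "gap"
KIND_AMBIGUOUS = "ambiguous"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))


@dataclass(frozen=True)
class CodonChange:
    """One classified codon-level difference against the reference.

    For a gap run, ``codon_index`` is the first codon of the run and
    ``run_length`` its extent in codons; point changes have run_length 1.
    """

    og_id: str
    codon_index: int  # 1-based within the aligned gene
    ref_codon: str
    alt_codon: str
    kind: str
    run_length: int = 1
    carrier: str = ""  # strain (intra counting) or clade pair label (inter)


@dataclass
class MutationTable:
    """Aggregate syn/nonsyn/gap counts for one counting scope."""

    scope: str
    syn: int = 0
    nonsyn: int = 0
    gap: int = 0
    genes_with_syn: int = 0
    genes_with_nonsyn: int = 0
    genes_with_gap: int = 0

    def __post_init__(self) -> None:
        for name in ("syn", "nonsyn", "gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        for kind in ("syn", "nonsyn", "gap"):
            if getattr(self, f"genes_with_{kind}") > getattr(self, kind):
                raise ValueError(f"genes_with_{kind} exceeds the {kind} mutation count")


@dataclass(frozen=True)
class OddsResult:
    """Odds of nonsyn/syn (and gap/syn) in a group relative to a baseline."""

    numerator_scope: str
    baseline_scope: str
    odds_nonsyn: float
    odds_gap: float
    p_nonsyn: float
    p_gap: float


def classify_codon_change(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon substitution: gap > ambiguous > syn/nonsyn.

    Stops compare equal to stops; a sense<->stop change is non-synonymous
    (function-changing by definition here).
    """
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise ValueError(
            f"codons must have length 3, got {ref_codon!r} and {alt_codon!r}"
        )
    if "-" in ref_codon or "-" in alt_codon:
        return KIND_GAP
    if "N" in ref_codon or "N" in alt_codon:
        return KIND_AMBIGUOUS
    return KIND_SYN if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon] else KIND_NONSYN


def _codon_changes_vs_reference(og_id: str, ref: str, member: str, carrier: str) -> list:
    """Classified changes of one sequence against the reference, gap runs merged."""
    if len(ref) % 3 != 0:
        raise ValueError(f"orthogroup {og_id}: alignment columns not divisible by 3")
    r = np.frombuffer(ref.encode(), dtype="S1")
    m = np.frombuffer(member.encode(), dtype="S1")
    diff_cols = np.nonzero(r != m)[0]
    if diff_cols.size == 0:
        return []
    codon_idx = sorted(set(int(c) // 3 for c in diff_cols))
    raw = []
    for ci in codon_idx:
        ref_c = ref[3 * ci : 3 * ci + 3]
        alt_c = member[3 * ci : 3 * ci + 3]
        raw.append((ci, ref_c, alt_c, classify_codon_change(ref_c, alt_c)))
    changes = []
    i = 0
    while i < len(raw):
        ci, ref_c, alt_c, kind = raw[i]
        if kind != KIND_GAP:
            changes.append(
                CodonChange(
                    og_id=og_id,
                    codon_index=ci + 1,
                    ref_codon=ref_c,
                    alt_codon=alt_c,
                    kind=kind,
                    carrier=carrier,
                )
            )
            i += 1
            continue
        # merge a maximal run of consecutive gap codons into one event
        j = i
        while (
            j + 1 < len(raw)
            and raw[j + 1][3] == KIND_GAP
            and raw[j + 1][0] == raw[j][0] + 1
        ):
            j += 1
        changes.append(
            CodonChange(
                og_id=og_id,
                codon_index=ci + 1,
                ref_codon=ref_c,
                alt_codon=alt_c,
                kind=KIND_GAP,
                run_length=j - i + 1,
                carrier=carrier,
            )
        )
        i = j + 1
    return changes


def _variant_key(change: CodonChange) -> tuple:
    # distinct-variant identity: same site, same alternate content
    return (change.og_id, change.codon_index, change.run_length, change.alt_codon, change.kind)


def _tabulate(scope: str, changes: Sequence[CodonChange], distinct: bool) -> MutationTable:
    if distinct:
        seen = {}
        for ch in changes:
            seen.setdefault(_variant_key(ch), ch)
        counted = list(seen.values())
    else:
        counted = list(changes)
    table = MutationTable(scope=scope)
    genes: dict = {KIND_SYN: set(), KIND_NONSYN: set(), KIND_GAP: set()}
    for ch in counted:
        if ch.kind == KIND_SYN:
            table.syn += 1
        elif ch.kind == KIND_NONSYN:
            table.nonsyn += 1
        elif ch.kind == KIND_GAP:
            table.gap += 1
        else:
            continue  # ambiguous changes are listed but not tallied
        genes[ch.kind].add(ch.og_id)
    table.genes_with_syn = len(genes[KIND_SYN])
    table.genes_with_nonsyn = len(genes[KIND_NONSYN])
    table.genes_with_gap = len(genes[KIND_GAP])
    return table


def count_intra(
    alignment_set: AlignmentSet,
    assignment: CladeAssignment,
    clade: str,
    distinct: bool = True,
    references: Optional[Mapping[str, str]] = None,
) -> tuple:
    """Mutation spectrum of one clade's members against the clade consensus.

    Returns ``(MutationTable, [CodonChange, ...])``.  With ``distinct=True``
    (default) a shared derived allele counts once; ``distinct=False`` counts
    every member occurrence.
    """
    members = assignment.members(clade)
    if len(members) < 2:
        raise ValueError(f"clade {clade!r} needs at least 2 members for intra counting")
    refs = references or clade_reference(alignment_set, assignment, clade)
    changes = []
    for aln in alignment_set:
        ref = refs[aln.og_id]
        for member in members:
            changes.extend(
                _codon_changes_vs_reference(
                    aln.og_id, ref, aln.sequences[member], carrier=member
                )
            )
    return _tabulate(f"intra_clade:{clade}", changes, distinct), changes


def count_intra_all(
    alignment_set: AlignmentSet,
    assignment: CladeAssignment,
    clades=None,
    distinct: bool = True,
) -> tuple:
    """Intra-clade spectrum summed over every clade with >= 2 members."""
    if clades is None:
        clades = [c for c in assignment.clades() if len(assignment.members(c)) >= 2]
    total = MutationTable(scope="intra_clade")
    all_changes = []
    for clade in clades:
        table, changes = count_intra(alignment_set, assignment, clade, distinct=distinct)
        total = sum_tables("intra_clade", total, table)
        all_changes.extend(changes)
    return total, all_changes


def sum_tables(scope: str, *tables: MutationTable) -> MutationTable:
    out = MutationTable(scope=scope)
    for t in tables:
        out.syn += t.syn
        out.nonsyn += t.nonsyn
        out.gap += t.gap
        out.genes_with_syn += t.genes_with_syn
        out.genes_with_nonsyn += t.genes_with_nonsyn
        out.genes_with_gap += t.genes_with_gap
    return out


def count_inter(
    alignment_set: AlignmentSet,
    assignment: CladeAssignment,
    clades=None,
    references: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> MutationTable:
    """Between-clade spectrum: clade references compared pairwise, summed over pairs.

    A difference separating one clade from two others is counted in both pairs;
    gap runs count once per pair per run.
    """
    if clades is None:
        clades = [c for c in assignment.clades() if assignment.members(c)]
    if len(clades) < 2:
        raise ValueError("inter-clade counting needs at least 2 clades")
    if references is None:
        references = {c: clade_reference(alignment_set, assignment, c) for c in clades}
    changes = []
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            x, y = clades[i], clades[j]
            for aln in alignment_set:
                changes.extend(
                    _codon_changes_vs_reference(
                        aln.og_id,
                        references[x][aln.og_id],
                        references[y][aln.og_id],
                        carrier=f"{x}|{y}",
                    )
                )
    # each pairwise difference is its own event: no cross-pair deduplication
    return _tabulate("inter_clade", changes, distinct=False)


def count_baseline(
    alignment_set: AlignmentSet, species_strains: Sequence[str], distinct: bool = True
) -> tuple:
    """Intra-species spectrum of a baseline species (whole species as one group)."""
    strains = list(species_strains)
    if len(strains) < 2:
        raise ValueError("baseline counting needs at least 2 strains")
    assignment = CladeAssignment(labels={s: "baseline" for s in strains})
    sub = AlignmentSet(
        alignments=tuple(
            type(aln)(
                og_id=aln.og_id,
                sequences={s: aln.sequences[s] for s in strains},
            )
            for aln in alignment_set
        ),
        strains=tuple(sorted(strains)),
    )
    table, changes = count_intra(sub, assignment, "baseline", distinct=distinct)
    table.scope = "baseline_species"
    return table, changes


# ---------------------------------------------------------------------------
# odds and Fisher's exact test
# ---------------------------------------------------------------------------

_MIN_P = 5e-324  # smallest positive subnormal double: keeps p in (0, 1]


def fisher_exact(a: int, b: int, c: int, d: int, max_exact_total: int = 1_000_000) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value is the hypergeometric probability mass of all tables with the
    same margins whose probability does not exceed the observed table's
    (within relative tolerance 1e-12).  Above ``max_exact_total`` entries a
    normal approximation is used and flagged with a warning.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    if n > max_exact_total:
        warnings.warn(
            f"table total {n} exceeds {max_exact_total}; "
            "normal approximation used for the Fisher p-value"
        )
        mean = r1 * c1 / n
        var = r1 * (n - r1) * c1 * (n - c1) / (n**2 * (n - 1))
        z = (a - mean) / math.sqrt(var)
        p = 2 * float(stats.norm.sf(abs(z)))
        return min(1.0, max(p, _MIN_P))  # p is in (0, 1] by definition
    kmin = max(0, c1 - (n - r1))
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(k, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, max(p, _MIN_P))


def odds_vs_baseline(
    group: MutationTable, baseline: MutationTable, continuity_correction: bool = False
) -> OddsResult:
    """Odds ratios of the group's nonsyn/syn and gap/syn counts vs a baseline.

    ``odds_nonsyn = (group.nonsyn/group.syn) / (baseline.nonsyn/baseline.syn)``
    and analogously for gaps; p-values are two-sided Fisher exact tests on the
    corresponding 2x2 count tables.  Zero synonymous counts are an error
    unless ``continuity_correction`` adds 0.5 to every cell of the odds.
    """
    if (group.syn == 0 or baseline.syn == 0) and not continuity_correction:
        raise ValueError(
            "zero synonymous count; enable continuity_correction to add 0.5 to all cells"
        )
    h = 0.5 if continuity_correction else 0.0

    def odds(x: int, y: int) -> float:
        return ((x + h) / (group.syn + h)) / ((y + h) / (baseline.syn + h))

    return OddsResult(
        numerator_scope=group.scope,
        baseline_scope=baseline.scope,
        odds_nonsyn=odds(group.nonsyn, baseline.nonsyn),
        odds_gap=odds(group.gap, baseline.gap),
        p_nonsyn=fisher_exact(group.nonsyn, group.syn, baseline.nonsyn, baseline.syn),
        p_gap=fisher_exact(group.gap, group.syn, baseline.gap, baseline.syn),
    )
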