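"""Per-read allele assignment and editing-outcome classification.

Each aligned amplicon read is assigned to a parental allele via a
heterozygous diagnostic SNP, then classified as edited when an
insertion or deletion overlaps the edit window (protospacer + PAM by
default).  Optional outcome detectors cover homology-directed loxP
knock-ins (10-mer containment rule, with a loxP-specific SNP marking
donor-derived reads as indeterminate) and two-cut deletion junctions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .amplicon import OP_DEL, OP_INS, AlignedRead
from .stats import Chi2Result, ContingencyTable2x2, chi_squared_2x2

#: the canonical 34-nt Cre recombinase recognition sequence
LOXP_34 = "ATAACTTCGTATAGCATACATTATACGAAGTTAT"

ALLELE_A = "strain_a"
ALLELE_B = "strain_b"
INDETERMINATE = "indeterminate"
ALLELES = (ALLELE_A, ALLELE_B, INDETERMINATE)


@dataclass(frozen=True)
class LoxpSpec:
    """Knock-in geometry for a loxP HDR assay.

    ``insert_seq`` is the sequence the donor oligo introduces at the cut
    (the loxP 34-mer, possibly with extra linker bases); ``snp_offset``
    / ``snp_base`` locate the loxP-specific SNP on the amplicon
    reference — a base differing from both strain bases, used to flag
    donor-derived (hence allele-uninformative) reads.
    """

    insert_seq: str = LOXP_34
    snp_offset: int = -1
    snp_base: str = ""
    loxp_seq: str = LOXP_34


@dataclass(frozen=True)
class DeletionSpec:
    """Two-cut deletion assay geometry.

    The amplicon reference for such an assay is the *junction*
    reference: upstream-of-cut-1 fused to downstream-of-cut-2.
    ``junction_pos`` is the fusion coordinate on that reference;
    ``partner_cut_pos`` records the second cut's genomic position for
    bookkeeping only.
    """

    junction_pos: int
    partner_cut_pos: Optional[int] = None
    min_side_match: int = 10


@dataclass
class AmpliconTarget:
    """Everything needed to interpret reads from one amplicon."""

    name: str
    ref_seq: str
    protospacer_span: tuple[int, int]
    pam_span: tuple[int, int]
    snp_offset: int
    strain_a_base: str
    strain_b_base: str
    strain_a_label: str = "strain_a"
    strain_b_label: str = "strain_b"
    edit_window: Optional[tuple[int, int]] = None
    loxp: Optional[LoxpSpec] = None
    deletion: Optional[DeletionSpec] = None

    def __post_init__(self) -> None:
        if not (0 <= self.snp_offset < len(self.ref_seq)):
            raise ValueError(f"snp_offset {self.snp_offset} outside amplicon")
        if self.strain_a_base == self.strain_b_base:
            raise ValueError("strain bases must differ")
        if self.edit_window is None:
            self.edit_window = (
                min(self.protospacer_span[0], self.pam_span[0]),
                max(self.protospacer_span[1], self.pam_span[1]),
            )
        w0, w1 = self.edit_window
        p0, p1 = self.protospacer_span
        if not (w0 < p1 and w1 > p0):
            raise ValueError("edit window must overlap the protospacer")
        if self.loxp is not None and self.loxp.snp_offset >= 0:
            if self.loxp.snp_offset == self.snp_offset and self.loxp.snp_base in (
                self.strain_a_base,
                self.strain_b_base,
            ):
                raise ValueError(
                    "loxP SNP base must differ from both strain bases at its offset"
                )

    @property
    def cut_pos(self) -> int:
        """Expected blunt-cut position: between protospacer bases 17/18
        (3 bp 5' of the PAM)."""
        p0, p1 = self.protospacer_span
        if self.pam_span[0] >= p1:  # protospacer on forward reference strand
            return p1 - 3
        return p0 + 3


@dataclass
class ReadClassification:
    """Per-read verdict."""

    read_id: str
    allele: str
    edited: bool
    indels: list[tuple[str, int, int]] = field(default_factory=list)
    loxp_positive: bool = False
    junction: bool = False


@dataclass
class AlleleCounts:
    total: int = 0
    edited: int = 0
    loxp: int = 0
    junction: int = 0


@dataclass
class LocusSummary:
    """Per-allele read accounting for one locus.

    Percentages follow the published conventions: edited% per allele is
    over that allele's strain-specific reads; loxP% and junction% per
    strain are over the total (all mapped) reads.
    """

    name: str
    strain_a_label: str
    strain_b_label: str
    counts: dict[str, AlleleCounts]
    total_reads: int
    edited_pct: dict[str, Optional[float]]
    loxp_pct: dict[str, float]
    junction_pct: dict[str, float]
    indel_length_hist: dict[str, Counter]

    def conserved(self) -> bool:
        return sum(c.total for c in self.counts.values()) == self.total_reads


# ---------------------------------------------------------------------------
# indel placement ambiguity

def deletion_slide_range(ref: str, start: int, length: int) -> tuple[int, int]:
    """Reference interval a deletion can occupy among equal-score placements.

    A deletion slides one step when the base entering the gap equals the
    base leaving it (homopolymers/repeats).  Returns [lo, hi): the union
    of all equally optimal placements.
    """
    lo = start
    while lo > 0 and ref[lo - 1] == ref[lo + length - 1]:
        lo -= 1
    hi = start + length
    while hi < len(ref) and ref[hi] == ref[hi - length]:
        hi += 1
    return lo, hi


def insertion_slide_range(ref: str, pos: int, content: str) -> tuple[int, int]:
    """Range of insertion points with equal score (rotational sliding)."""
    lo = pos
    c = list(content)
    while lo > 0 and c[-1] == ref[lo - 1]:
        c = [ref[lo - 1]] + c[:-1]
        lo -= 1
    hi = pos
    c = list(content)
    while hi < len(ref) and c[0] == ref[hi]:
        c = c[1:] + [ref[hi]]
        hi += 1
    return lo, hi


def snp_obscured_by_indel(ref: str, snp_offset: int, kind: str, pos: int,
                          length: int, content: Optional[str] = None) -> bool:
    """True when an indel's equally optimal placements can involve the SNP.

    Besides sliding through repeats, an indel directly adjacent to the
    diagnostic base can trade places with it at equal score (the base
    swaps into or out of the gap against a substitution), so the
    adjacency margin of one base is included.  A read whose indel
    obscures the SNP this way has no well-defined allele.
    """
    if kind == OP_DEL:
        lo, hi = deletion_slide_range(ref, pos, length)
        return lo - 1 <= snp_offset < hi + 1
    lo, hi = insertion_slide_range(ref, pos, content or "")
    return lo - 1 <= snp_offset <= hi


# ---------------------------------------------------------------------------
# per-read classification


def _indels_with_content(read: AlignedRead):
    """Indel ops of a read, with inserted sequence content attached."""
    out = []
    read_pos = 0
    for op in read.ops:
        if op.kind == OP_INS:
            out.append((op, read.seq[read_pos : read_pos + op.length]))
            read_pos += op.length
        elif op.kind == OP_DEL:
            out.append((op, None))
        else:
            read_pos += op.length
    return out


def assign_allele(read: AlignedRead, target: AmpliconTarget) -> str:
    """Assign an aligned read to a parental allele via the diagnostic SNP.

    Returns ``strain_a`` / ``strain_b`` / ``indeterminate``.  A read is
    indeterminate when it does not cover the SNP, the SNP base is
    deleted, an indel's equally optimal placements reach the SNP (its
    identity is then alignment-dependent), the base matches the
    loxP-specific SNP (donor-derived), or it matches neither strain
    (likely sequencing error).
    """
    if target.loxp is not None and target.loxp.snp_offset >= 0:
        off = target.loxp.snp_offset
        if read.covers(off):
            base = read.base_at(off)
            if base == target.loxp.snp_base:
                return INDETERMINATE
    if not read.covers(target.snp_offset):
        return INDETERMINATE
    base = read.base_at(target.snp_offset)
    if base is None:  # deleted
        return INDETERMINATE
    for op, content in _indels_with_content(read):
        if snp_obscured_by_indel(
            target.ref_seq, target.snp_offset, op.kind, op.ref_pos,
            op.length, content,
        ):
            return INDETERMINATE
    if base == target.strain_a_base:
        return ALLELE_A
    if base == target.strain_b_base:
        return ALLELE_B
    return INDETERMINATE


def classify_edit(
    read: AlignedRead, target: AmpliconTarget
) -> tuple[bool, list[tuple[str, int, int]]]:
    """Edited flag plus the inventory of indels overlapping the window.

    A read is edited iff at least one insertion or deletion overlaps the
    edit window; substitutions never count.  Inventory entries are
    (kind, length, left-aligned reference position).
    """
    if read.amplicon_id != target.name:
        raise ValueError(
            f"read {read.read_id!r} aligned to {read.amplicon_id!r}, "
            f"not target {target.name!r}"
        )
    w0, w1 = target.edit_window
    inventory: list[tuple[str, int, int]] = []
    for op in read.ops:
        if op.kind == OP_DEL:
            if op.ref_pos < w1 and op.ref_pos + op.length > w0:
                inventory.append((op.kind, op.length, op.ref_pos))
        elif op.kind == OP_INS:
            if w0 < op.ref_pos < w1:
                inventory.append((op.kind, op.length, op.ref_pos))
    return bool(inventory), inventory


def detect_loxp(seq: str, loxp_seq: str = LOXP_34, k: int = 10,
                both_strands: bool = False) -> bool:
    """loxP containment rule: true iff any length-k substring of the loxP
    sequence occurs in the read (forward orientation by default)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(loxp_seq):
        raise ValueError("k exceeds the loxP sequence length")
    kmers = {loxp_seq[i : i + k] for i in range(len(loxp_seq) - k + 1)}
    if any(kmer in seq for kmer in kmers):
        return True
    if both_strands:
        from .genome_scan import revcomp

        rc = revcomp(seq)
        return any(kmer in rc for kmer in kmers)
    return False


def classify_deletion_read(
    read: AlignedRead, target: AmpliconTarget
) -> tuple[bool, str]:
    """Junction verdict plus allele for a two-cut deletion assay read.

    The read supports the deletion junction iff it aligns across the
    fusion coordinate with at least ``min_side_match`` matched bases on
    each side.  The allele is assigned from the junction reference's
    diagnostic SNP.
    """
    if target.deletion is None:
        raise ValueError(f"target {target.name!r} has no deletion geometry")
    jpos = target.deletion.junction_pos
    need = target.deletion.min_side_match
    left = right = 0
    for op in read.ops:
        if op.kind != "match":
            continue
        s, e = op.ref_pos, op.ref_pos + op.length
        left += max(0, min(e, jpos) - s)
        right += max(0, e - max(s, jpos))
    junction = left >= need and right >= need
    return junction, assign_allele(read, target)


def classify_read(read: AlignedRead, target: AmpliconTarget) -> ReadClassification:
    """Full per-read verdict combining allele, edit, loxP and junction calls."""
    allele = assign_allele(read, target)
    edited, inventory = classify_edit(read, target)
    loxp_pos = False
    if target.loxp is not None:
        loxp_pos = detect_loxp(read.seq, target.loxp.loxp_seq)
    junction = False
    if target.deletion is not None:
        junction, allele = classify_deletion_read(read, target)
    return ReadClassification(
        read_id=read.read_id,
        allele=allele,
        edited=edited,
        indels=inventory,
        loxp_positive=loxp_pos,
        junction=junction,
    )


# ---------------------------------------------------------------------------
# locus summary & allele-bias test


def summarize(
    classifications: Sequence[ReadClassification], target: AmpliconTarget
) -> LocusSummary:
    """Aggregate per-read verdicts into the per-locus accounting table."""
    if not classifications:
        raise ValueError(f"no classified reads for locus {target.name!r}")
    counts = {a: AlleleCounts() for a in ALLELES}
    hist: dict[str, Counter] = {OP_INS: Counter(), OP_DEL: Counter()}
    for c in classifications:
        ac = counts[c.allele]
        ac.total += 1
        if c.edited:
            ac.edited += 1
        if c.loxp_positive:
            ac.loxp += 1
        if c.junction:
            ac.junction += 1
        for kind, length, _pos in c.indels:
            hist[kind][length] += 1
    total = len(classifications)

    edited_pct: dict[str, Optional[float]] = {}
    loxp_pct: dict[str, float] = {}
    junction_pct: dict[str, float] = {}
    for allele in (ALLELE_A, ALLELE_B):
        ac = counts[allele]
        edited_pct[allele] = 100.0 * ac.edited / ac.total if ac.total else None
        loxp_pct[allele] = 100.0 * ac.loxp / total
        junction_pct[allele] = 100.0 * ac.junction / total

    return LocusSummary(
        name=target.name,
        strain_a_label=target.strain_a_label,
        strain_b_label=target.strain_b_label,
        counts=counts,
        total_reads=total,
        edited_pct=edited_pct,
        loxp_pct=loxp_pct,
        junction_pct=junction_pct,
        indel_length_hist=hist,
    )


def compare_alleles(
    summary: LocusSummary, yates: bool = False
) -> tuple[ContingencyTable2x2, Chi2Result]:
    """Chi-squared test of edited/unedited counts between the two alleles."""
    a = summary.counts[ALLELE_A]
    b = summary.counts[ALLELE_B]
    if a.total == 0 or b.total == 0:
        raise ValueError(
            "an allele has zero reads; use fisher_exact_2x2 on the raw counts"
        )
    table = ContingencyTable2x2(
        a=a.edited, b=b.edited, c=a.total - a.edited, d=b.total - b.edited
    )
    return table, chi_squared_2x2(table, yates=yates)
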