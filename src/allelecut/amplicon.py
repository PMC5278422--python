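"""Amplicon read processing: quality trimming, pair merging, glocal alignment.

The pipeline mirrors a standard MiSeq amplicon workflow: paired 300-nt
reads are quality-trimmed (Trimmomatic-style rules), merged on their
overlap (usearch-style: zero mismatches, minimum overlap), and each
merged read is aligned against the short amplicon reference with an
affine-gap alignment that is global in the read and local in the
reference (free reference end gaps), so partial amplicon coverage costs
nothing at the ends while internal indels are penalised.

Pre-aligned SAM is accepted as an alternative entry point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome_scan import revcomp

log = logging.getLogger(__name__)

READ_ALPHABET = frozenset("ACGTN")

OP_MATCH = "match"
OP_MISMATCH = "mismatch"
OP_INS = "insertion"
OP_DEL = "deletion"

#: read-consuming op kinds
_READ_OPS = {OP_MATCH, OP_MISMATCH, OP_INS}
#: reference-consuming op kinds
_REF_OPS = {OP_MATCH, OP_MISMATCH, OP_DEL}


@dataclass
class RawRead:
    """A read with per-base Phred quality scores (Phred+33 on disk)."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MergedRead:
    """Consensus of an overlapping read pair."""

    id: str
    seq: str
    quals: list[int]
    overlap_len: int


@dataclass(frozen=True)
class AlignmentOp:
    """One alignment operation at a reference offset.

    For insertions ``ref_pos`` is the reference position *before which*
    the read bases are inserted; insertions consume no reference.
    """

    kind: str
    length: int
    ref_pos: int


@dataclass
class AlignedRead:
    """A read aligned to one amplicon reference.

    ``ops`` are ordered 5'->3' on the reference; reference offsets are
    strictly increasing and the read-consuming op lengths sum to the
    read length.
    """

    read_id: str
    amplicon_id: str
    seq: str
    ref_start: int
    ref_end: int
    ops: list[AlignmentOp] = field(default_factory=list)

    def read_consumed(self) -> int:
        return sum(op.length for op in self.ops if op.kind in _READ_OPS)

    def covers(self, ref_pos: int) -> bool:
        """True if the alignment spans this reference position."""
        return self.ref_start <= ref_pos < self.ref_end

    def base_at(self, ref_pos: int) -> Optional[str]:
        """Read base aligned to ``ref_pos``; None if deleted in the read.

        Raises IndexError if the position is outside the aligned span.
        """
        if not self.covers(ref_pos):
            raise IndexError(f"position {ref_pos} outside aligned span")
        read_pos = 0
        ref = self.ref_start
        for op in self.ops:
            if op.kind == OP_INS:
                read_pos += op.length
                continue
            if ref <= ref_pos < ref + op.length:
                if op.kind == OP_DEL:
                    return None
                return self.seq[read_pos + (ref_pos - ref)]
            if op.kind in (OP_MATCH, OP_MISMATCH):
                read_pos += op.length
            ref += op.length
        raise IndexError(f"position {ref_pos} not reached by ops")  # pragma: no cover

    def indels(self) -> list[AlignmentOp]:
        return [op for op in self.ops if op.kind in (OP_INS, OP_DEL)]


# ---------------------------------------------------------------------------
# quality trimming


def _clip_adapters(read: RawRead, adapters: Sequence[str], min_overlap: int = 8):
    """Simplified adapter clipping: clip at the earliest position where a
    prefix of an adapter matches the read suffix with <=1 mismatch per
    10 nt of matched length."""
    seq = read.seq
    best = len(seq)
    for adapter in adapters:
        for i in range(len(seq) - min_overlap + 1):
            if i >= best:
                break
            n = min(len(adapter), len(seq) - i)
            allowed = n // 10
            diffs = 0
            for a, b in zip(seq[i : i + n], adapter[:n]):
                if a != b:
                    diffs += 1
                    if diffs > allowed:
                        break
            else:
                best = i
                break
    if best < len(seq):
        return RawRead(read.id, seq[:best], read.quals[:best])
    return read


def trim_quality(
    read: RawRead,
    leading: int = 5,
    trailing: int = 5,
    window: int = 10,
    window_min_mean: int = 30,
    min_len: int = 75,
    adapters: Optional[Sequence[str]] = None,
) -> Optional[RawRead]:
    """Quality-trim one read; returns None when it falls below ``min_len``.

    Rules applied in order (Trimmomatic semantics):

    1. optional adapter clipping (simplified suffix-overlap match);
    2. LEADING: drop 5' bases with quality < ``leading``;
    3. TRAILING: drop 3' bases with quality < ``trailing``;
    4. SLIDINGWINDOW: scan ``window``-base windows from the 5' end and
       cut at the first window whose mean quality < ``window_min_mean``,
       keeping leading bases of that window that individually reach the
       threshold;
    5. MINLEN: drop the read if shorter than ``min_len``.
    """
    if adapters:
        read = _clip_adapters(read, adapters)
    seq, quals = read.seq, read.quals

    lo = 0
    while lo < len(quals) and quals[lo] < leading:
        lo += 1
    hi = len(quals)
    while hi > lo and quals[hi - 1] < trailing:
        hi -= 1
    seq, quals = seq[lo:hi], quals[lo:hi]

    if window > 0 and len(quals) >= window:
        total = sum(quals[:window])
        cut = None
        for i in range(len(quals) - window + 1):
            if i > 0:
                total += quals[i + window - 1] - quals[i - 1]
            if total < window_min_mean * window:
                cut = i
                break
        if cut is not None:
            keep = cut
            while keep < len(quals) and quals[keep] >= window_min_mean:
                keep += 1
            seq, quals = seq[:keep], quals[:keep]

    if len(seq) < min_len:
        return None
    return RawRead(read.id, seq, quals)


# ---------------------------------------------------------------------------
# pair merging


def _truncate_at_qual(read: RawRead, trunc_qual: int) -> RawRead:
    """Truncate at the first base with quality <= ``trunc_qual``."""
    for i, q in enumerate(read.quals):
        if q <= trunc_qual:
            return RawRead(read.id, read.seq[:i], read.quals[:i])
    return read


def merge_pair(
    r1: RawRead,
    r2: RawRead,
    trunc_qual: int = 3,
    max_diffs: int = 0,
    min_overlap: int = 50,
) -> Optional[MergedRead]:
    """Merge a read pair on its 3' overlap; None when no overlap qualifies.

    Both mates are first truncated at the first base with quality <=
    ``trunc_qual``.  The longest ungapped overlap between r1 and the
    reverse complement of r2 with at most ``max_diffs`` mismatches and
    length >= ``min_overlap`` is taken; the consensus keeps the
    higher-quality base at disagreeing positions.
    """
    r1 = _truncate_at_qual(r1, trunc_qual)
    r2 = _truncate_at_qual(r2, trunc_qual)
    l1, l2 = len(r1), len(r2)
    if min(l1, l2) < min_overlap:
        return None

    s1 = r1.seq
    s2 = revcomp(r2.seq)
    q2 = r2.quals[::-1]

    for olen in range(min(l1, l2), min_overlap - 1, -1):
        tail = s1[l1 - olen :]
        head = s2[:olen]
        if max_diffs == 0:
            if tail != head:
                continue
            diffs = 0
        else:
            diffs = 0
            for a, b in zip(tail, head):
                if a != b:
                    diffs += 1
                    if diffs > max_diffs:
                        break
            if diffs > max_diffs:
                continue
        # build consensus over the overlap
        seq = list(s1[: l1 - olen])
        quals = list(r1.quals[: l1 - olen])
        for k in range(olen):
            b1, b2 = tail[k], head[k]
            p1, p2 = r1.quals[l1 - olen + k], q2[k]
            if b1 == b2:
                seq.append(b1)
                quals.append(max(p1, p2))
            elif p1 >= p2:
                seq.append(b1)
                quals.append(p1)
            else:
                seq.append(b2)
                quals.append(p2)
        seq += s2[olen:]
        quals += q2[olen:]
        return MergedRead(r1.id, "".join(seq), quals, overlap_len=olen)
    return None


# ---------------------------------------------------------------------------
# glocal alignment


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scores; a length-L gap scores open + (L-1)*extend."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


_ALIGNER_CACHE: dict[AlignScoring, object] = {}


def _get_aligner(scoring: AlignScoring):
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.open_gap_score = scoring.gap_open
        aligner.extend_gap_score = scoring.gap_extend
        # free end gaps on the reference (target) => glocal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligner.query_end_gap_score = 0.0
        _ALIGNER_CACHE[scoring] = aligner
    return aligner


def _ops_from_coordinates(coords, ref: str, read: str) -> tuple[int, int, list[AlignmentOp]]:
    """Convert a Biopython alignment coordinate table into an op list."""
    ops: list[AlignmentOp] = []
    ref_start = None
    ref_end = None
    tpos = coords[0]
    qpos = coords[1]
    n_steps = len(tpos) - 1
    for k in range(n_steps):
        t0, t1 = int(tpos[k]), int(tpos[k + 1])
        q0, q1 = int(qpos[k]), int(qpos[k + 1])
        dt, dq = t1 - t0, q1 - q0
        if dt and dq:
            # aligned diagonal block: split into match/mismatch runs
            run_kind = None
            run_len = 0
            run_start = t0
            for i in range(dt):
                kind = OP_MATCH if ref[t0 + i] == read[q0 + i] else OP_MISMATCH
                if kind == run_kind:
                    run_len += 1
                else:
                    if run_kind is not None:
                        ops.append(AlignmentOp(run_kind, run_len, run_start))
                    run_kind, run_len, run_start = kind, 1, t0 + i
            ops.append(AlignmentOp(run_kind, run_len, run_start))
            if ref_start is None:
                ref_start = t0
            ref_end = t1
        elif dt:
            # target consumed, query not: deletion in read — but at the
            # alignment ends this is just the unaligned reference overhang
            if q0 == 0 and not ops:
                continue
            if q0 == len(read):
                continue
            ops.append(AlignmentOp(OP_DEL, dt, t0))
            if ref_start is None:
                ref_start = t0
            ref_end = t1
        elif dq:
            ops.append(AlignmentOp(OP_INS, dq, t0))
            if ref_start is None:
                ref_start = t0
            ref_end = t0 if ref_end is None else ref_end
    if ref_start is None:  # read aligned entirely as an insertion
        ref_start = ref_end = int(tpos[0])
    # trim flanking deletions that survived (e.g. del adjacent to overhang)
    while ops and ops[0].kind == OP_DEL:
        ref_start = ops[0].ref_pos + ops[0].length
        ops.pop(0)
    while ops and ops[-1].kind == OP_DEL:
        ref_end = ops[-1].ref_pos
        ops.pop()
    return ref_start, ref_end, ops


def left_normalize(ops: list[AlignmentOp], ref: str, read: str) -> list[AlignmentOp]:
    """Shift indels as far left as the flanking sequence allows.

    A deletion of ref[i:i+L] moves to i-1 when ref[i-1] == ref[i+L-1]
    (and the preceding op donates the base); likewise for insertions on
    the read.  Score is preserved, making indel placement deterministic
    (left-aligned) regardless of the traceback order of the aligner.
    """
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        rp = 0
        positions = []
        for op in ops:
            positions.append(rp)
            if op.kind in _READ_OPS:
                rp += op.length
        for i in range(1, len(ops)):
            op = ops[i]
            prev = ops[i - 1]
            if op.kind not in (OP_INS, OP_DEL) or prev.kind not in (
                OP_MATCH,
                OP_MISMATCH,
            ):
                continue
            if op.kind == OP_DEL:
                s = op.ref_pos
                can = s > 0 and ref[s - 1] == ref[s + op.length - 1]
            else:
                p = positions[i]
                can = (
                    op.ref_pos > 0
                    and p > 0
                    and read[p - 1] == read[p + op.length - 1]
                    and ref[op.ref_pos - 1] == read[p - 1]
                )
            if not can:
                continue
            # donate one base from prev (must stay a match after shift)
            if prev.kind == OP_MISMATCH:
                continue
            new_prev = AlignmentOp(prev.kind, prev.length - 1, prev.ref_pos)
            shifted = AlignmentOp(op.kind, op.length, op.ref_pos - 1)
            # base that reappears on the right of the indel
            if op.kind == OP_DEL:
                tail = AlignmentOp(OP_MATCH, 1, op.ref_pos + op.length - 1)
            else:
                tail = AlignmentOp(OP_MATCH, 1, op.ref_pos - 1)
            new_ops = ops[: i - 1]
            if new_prev.length:
                new_ops.append(new_prev)
            new_ops.append(shifted)
            new_ops.append(tail)
            new_ops.extend(ops[i + 1 :])
            # merge adjacent same-kind ops
            merged: list[AlignmentOp] = []
            for o in new_ops:
                if (
                    merged
                    and merged[-1].kind == o.kind
                    and o.kind in (OP_MATCH, OP_MISMATCH)
                    and merged[-1].ref_pos + merged[-1].length == o.ref_pos
                ):
                    merged[-1] = AlignmentOp(
                        o.kind, merged[-1].length + o.length, merged[-1].ref_pos
                    )
                else:
                    merged.append(o)
            ops = merged
            changed = True
            break
    return ops


def align_glocal(
    read_seq: str,
    amplicon_seq: str,
    read_id: str = "read",
    amplicon_id: str = "amplicon",
    scoring: AlignScoring = AlignScoring(),
) -> AlignedRead:
    """Align a read to an amplicon: global in the read, free reference ends.

    Optimal under the affine-gap scoring; indels are reported
    left-aligned so placement is deterministic.
    """
    if not read_seq:
        raise ValueError("empty read")
    if not amplicon_seq:
        raise ValueError("empty amplicon reference")
    for label, s in (("read", read_seq), ("amplicon", amplicon_seq)):
        bad = set(s) - READ_ALPHABET
        if bad:
            raise ValueError(f"{label} contains invalid characters: {sorted(bad)}")

    # fast path: exact substring is always optimal (maximal match score,
    # zero penalties)
    idx = amplicon_seq.find(read_seq)
    if idx >= 0:
        return AlignedRead(
            read_id=read_id,
            amplicon_id=amplicon_id,
            seq=read_seq,
            ref_start=idx,
            ref_end=idx + len(read_seq),
            ops=[AlignmentOp(OP_MATCH, len(read_seq), idx)],
        )

    aligner = _get_aligner(scoring)
    aln = aligner.align(amplicon_seq, read_seq)[0]
    ref_start, ref_end, ops = _ops_from_coordinates(
        aln.coordinates, amplicon_seq, read_seq
    )
    ops = left_normalize(ops, amplicon_seq, read_seq)
    if ops:
        ref_start = ops[0].ref_pos
        last = ops[-1]
        ref_end = last.ref_pos + (last.length if last.kind in _REF_OPS else 0)
    aligned = AlignedRead(
        read_id=read_id,
        amplicon_id=amplicon_id,
        seq=read_seq,
        ref_start=ref_start,
        ref_end=ref_end,
        ops=ops,
    )
    consumed = aligned.read_consumed()
    if consumed != len(read_seq):  # pragma: no cover - internal consistency
        raise AssertionError(
            f"alignment consumed {consumed} of {len(read_seq)} read bases"
        )
    return aligned


def alignment_score(aligned: AlignedRead, scoring: AlignScoring = AlignScoring()) -> float:
    """Score an op list under the affine model (reference end gaps free)."""
    score = 0.0
    for op in aligned.ops:
        if op.kind == OP_MATCH:
            score += scoring.match * op.length
        elif op.kind == OP_MISMATCH:
            score += scoring.mismatch * op.length
        else:
            score += scoring.gap_open + scoring.gap_extend * (op.length - 1)
    return score


# ---------------------------------------------------------------------------
# SAM ingestion


def load_alignments(path, targets: dict) -> tuple[list[AlignedRead], dict]:
    """Load pre-aligned reads from a SAM file.

    ``targets`` maps reference names to objects exposing ``ref_seq``
    (e.g. AmpliconTarget).  Unmapped, secondary and supplementary
    records are skipped; counts are returned alongside the alignments.
    Soft-clipped bases are stripped from the stored sequence so the
    op/sequence bookkeeping covers exactly the aligned portion.
    """
    import pysam

    counts = {"loaded": 0, "unmapped": 0, "secondary": 0, "supplementary": 0,
              "unknown_reference": 0}
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        it = iter(fh)
        line_no = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise ValueError(
                    f"malformed SAM record after {line_no} alignment line(s) "
                    f"in {path}: {exc}"
                ) from exc
            line_no += 1
            try:
                if rec.is_unmapped:
                    counts["unmapped"] += 1
                    continue
                if rec.is_secondary:
                    counts["secondary"] += 1
                    continue
                if rec.is_supplementary:
                    counts["supplementary"] += 1
                    continue
                name = rec.reference_name
                target = targets.get(name)
                if target is None:
                    counts["unknown_reference"] += 1
                    continue
                ref_seq = target.ref_seq if hasattr(target, "ref_seq") else str(target)
                seq = rec.query_alignment_sequence
                if seq is None:
                    raise ValueError("record has no sequence")
                out.append(
                    _aligned_from_cigar(
                        rec.query_name, name, seq.upper(),
                        rec.reference_start, rec.cigartuples, ref_seq,
                    )
                )
                counts["loaded"] += 1
            except Exception as exc:
                raise ValueError(
                    f"malformed SAM record at alignment line {line_no} "
                    f"of {path}: {exc}"
                ) from exc
    log.info("SAM ingestion counts: %s", counts)
    return out, counts


# pysam cigar op codes
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_P, _CIG_EQ, _CIG_X = range(9)


def _aligned_from_cigar(read_id, amplicon_id, seq, ref_start, cigartuples, ref_seq):
    ops: list[AlignmentOp] = []
    rpos = ref_start
    qpos = 0
    for code, length in cigartuples:
        if code in (_CIG_S, _CIG_H, _CIG_P):
            continue  # soft-clips already stripped from seq
        if code in (_CIG_M, _CIG_EQ, _CIG_X):
            run_kind = None
            run_len = 0
            run_start = rpos
            for i in range(length):
                ref_base = ref_seq[rpos + i] if rpos + i < len(ref_seq) else "N"
                kind = OP_MATCH if ref_base == seq[qpos + i] else OP_MISMATCH
                if kind == run_kind:
                    run_len += 1
                else:
                    if run_kind is not None:
                        ops.append(AlignmentOp(run_kind, run_len, run_start))
                    run_kind, run_len, run_start = kind, 1, rpos + i
            ops.append(AlignmentOp(run_kind, run_len, run_start))
            rpos += length
            qpos += length
        elif code == _CIG_I:
            ops.append(AlignmentOp(OP_INS, length, rpos))
            qpos += length
        elif code in (_CIG_D, _CIG_N):
            ops.append(AlignmentOp(OP_DEL, length, rpos))
            rpos += length
        else:
            raise ValueError(f"unsupported CIGAR op code {code}")
    return AlignedRead(
        read_id=read_id,
        amplicon_id=amplicon_id,
        seq=seq,
        ref_start=ref_start,
        ref_end=rpos,
        ops=ops,
    )
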