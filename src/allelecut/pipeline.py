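"""End-to-end quantification: read pairs -> trimmed/merged reads ->
alignments -> per-read classifications -> locus summary.

This is the path behind the ``quantify`` subcommand; each stage is also
usable on its own (see :mod:`allelecut.amplicon` and
:mod:`allelecut.edit_counter`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .amplicon import (
    AlignedRead,
    AlignScoring,
    MergedRead,
    RawRead,
    align_glocal,
    alignment_score,
    load_alignments,
    merge_pair,
    trim_quality,
)
from .edit_counter import (
    AmpliconTarget,
    LocusSummary,
    ReadClassification,
    classify_read,
    summarize,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimParams:
    leading: int = 5
    trailing: int = 5
    window: int = 10
    window_min_mean: int = 30
    min_len: int = 75
    adapters: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class MergeParams:
    trunc_qual: int = 3
    max_diffs: int = 0
    min_overlap: int = 50


@dataclass
class ReadFates:
    """Bookkeeping of where read pairs go in the pipeline."""

    pairs_in: int = 0
    dropped_trim: int = 0
    unmerged: int = 0
    unassigned: int = 0
    classified: dict = field(default_factory=dict)


def trim_and_merge(
    pairs: Iterable[tuple[RawRead, RawRead]],
    trim: TrimParams = TrimParams(),
    merge: MergeParams = MergeParams(),
    fates: Optional[ReadFates] = None,
) -> list[MergedRead]:
    """Quality-trim both mates then merge; failures are counted, not kept."""
    merged: list[MergedRead] = []
    for r1, r2 in pairs:
        if fates is not None:
            fates.pairs_in += 1
        t1 = trim_quality(r1, trim.leading, trim.trailing, trim.window,
                          trim.window_min_mean, trim.min_len, trim.adapters)
        t2 = trim_quality(r2, trim.leading, trim.trailing, trim.window,
                          trim.window_min_mean, trim.min_len, trim.adapters)
        if t1 is None or t2 is None:
            if fates is not None:
                fates.dropped_trim += 1
            continue
        m = merge_pair(t1, t2, merge.trunc_qual, merge.max_diffs, merge.min_overlap)
        if m is None:
            if fates is not None:
                fates.unmerged += 1
            continue
        merged.append(m)
    return merged


def _pick_target(seq: str, targets: Sequence[AmpliconTarget],
                 scoring: AlignScoring) -> tuple[AmpliconTarget, AlignedRead]:
    best = None
    for t in targets:
        aln = align_glocal(seq, t.ref_seq, amplicon_id=t.name, scoring=scoring)
        s = alignment_score(aln, scoring)
        if best is None or s > best[0]:
            best = (s, t, aln)
    return best[1], best[2]


def quantify_pairs(
    pairs: Iterable[tuple[RawRead, RawRead]],
    targets: Sequence[AmpliconTarget],
    trim: TrimParams = TrimParams(),
    merge: MergeParams = MergeParams(),
    scoring: AlignScoring = AlignScoring(),
) -> tuple[dict[str, list[ReadClassification]], dict[str, LocusSummary], ReadFates]:
    """Run the full pipeline on read pairs against one or more targets.

    With multiple targets each merged read is assigned to the
    best-scoring reference.  Returns per-target classifications and
    summaries plus read-fate counts; targets with no reads get no
    summary.
    """
    if not targets:
        raise ValueError("no amplicon targets supplied")
    fates = ReadFates()
    merged = trim_and_merge(pairs, trim, merge, fates)
    per_target: dict[str, list[ReadClassification]] = {t.name: [] for t in targets}
    by_name = {t.name: t for t in targets}
    for m in merged:
        if len(targets) == 1:
            t = targets[0]
            aln = align_glocal(m.seq, t.ref_seq, read_id=m.id,
                               amplicon_id=t.name, scoring=scoring)
        else:
            t, aln = _pick_target(m.seq, targets, scoring)
            aln.read_id = m.id
        per_target[t.name].append(classify_read(aln, t))
    summaries = {}
    for name, cls in per_target.items():
        fates.classified[name] = len(cls)
        if cls:
            summaries[name] = summarize(cls, by_name[name])
    return per_target, summaries, fates


def quantify_sam(
    sam_path,
    targets: Sequence[AmpliconTarget],
) -> tuple[dict[str, list[ReadClassification]], dict[str, LocusSummary], dict]:
    """Classify pre-aligned reads from a SAM file (ingestion entry point)."""
    by_name = {t.name: t for t in targets}
    alignments, counts = load_alignments(sam_path, by_name)
    per_target: dict[str, list[ReadClassification]] = {t.name: [] for t in targets}
    for aln in alignments:
        per_target[aln.amplicon_id].append(classify_read(aln, by_name[aln.amplicon_id]))
    summaries = {
        name: summarize(cls, by_name[name])
        for name, cls in per_target.items()
        if cls
    }
    return per_target, summaries, counts
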