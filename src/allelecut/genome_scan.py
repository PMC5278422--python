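"""Genome-wide discovery of CRISPR/Cas9 target sites and strain-specific loci.

A candidate SpCas9 target site is any 23-nt window of the form
N20-NGG: a 20-nt protospacer followed by the NGG protospacer-adjacent
motif (PAM).  Every GG dinucleotide on either strand anchors one
candidate, provided the window has 21 nt of 5' context on that strand.

A *strain-specific* site is a candidate whose protospacer or PAM GG
contains a single-nucleotide variant distinguishing two strains, so a
guide RNA designed against one strain mismatches the other.  A variant
falling on the PAM N is not discriminating (N matches any base) and is
excluded.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: protospacer length + PAM length
WINDOW = 23
PROTOSPACER_LEN = 20
#: offset of the unconstrained PAM "N" base within the site window
PAM_N_OFFSET = 20

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One named nucleotide sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.name!r}")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.name!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CrisprSite:
    """One N20-NGG candidate site in forward genomic coordinates.

    ``protospacer`` and ``pam`` are read 5'->3' on the site strand; for
    minus-strand sites they are the reverse complement of the genomic
    window.  ``start``/``end`` are 0-based half-open and always satisfy
    ``end - start == 23``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW:
            raise ValueError("site window must span 23 nt")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not end in GG")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")

    @property
    def window_seq(self) -> str:
        return self.protospacer + self.pam

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.strand)


@dataclass(frozen=True)
class StrainVariant:
    """A biallelic SNV distinguishing two strains (0-based position)."""

    chrom: str
    pos: int
    strain_a_base: str
    strain_b_base: str
    strain_a_label: str = "strain_a"
    strain_b_label: str = "strain_b"

    def is_snv(self) -> bool:
        return (
            self.strain_a_base in "ACGT"
            and self.strain_b_base in "ACGT"
            and len(self.strain_a_base) == 1
            and len(self.strain_b_base) == 1
            and self.strain_a_base != self.strain_b_base
        )


@dataclass(frozen=True)
class StrainSpecificSite:
    """A candidate site discriminated by a strain SNV.

    ``offset_in_window`` is the variant's offset within the 23-nt window
    in site-strand orientation (0 = protospacer base farthest from the
    PAM).  ``distance_from_pam`` is 20..1 for protospacer hits and 0 for
    hits in the PAM GG.
    """

    site: CrisprSite
    variant: StrainVariant
    offset_in_window: int
    distance_from_pam: int
    in_pam: bool


@dataclass
class GeneModel:
    """A gene span with (possibly coding) exon intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r} has no exons")
        for s, e, _coding in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id!r}: exon [{s},{e}) outside span "
                    f"[{self.start},{self.end})"
                )
        merged = sorted((s, e) for s, e, _ in self.exons)
        for (s1, e1), (s2, _e2) in zip(merged, merged[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")

    @property
    def coding_exons(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, coding in self.exons if coding]


@dataclass(frozen=True)
class AnnotationSummary:
    """Counts of annotation features hit by strain-specific sites."""

    exon_hit_count: int
    gene_hit_count: int
    gene_any_count: int
    gene_flanking_count: int


# ---------------------------------------------------------------------------
# scanning


def scan_pam_sites(
    genome: GenomeSequence,
    pam: str = "NGG",
    drop_n: bool = True,
) -> list[CrisprSite]:
    """Enumerate every N20-NGG candidate site on both strands.

    Each GG dinucleotide is an independent anchor (a GGG run yields two
    anchors).  Sites whose 23-nt window contains an N are dropped when
    ``drop_n`` is true (the default): such guides are undesignable.
    Minus-strand sites are reported in forward coordinates with
    strand-oriented protospacer/PAM sequences.  Output is sorted by
    (chrom, start, strand) and deterministic.
    """
    if pam != "NGG":
        raise NotImplementedError("only the NGG PAM is supported")
    seq = genome.seq
    n = len(seq)
    sites: list[CrisprSite] = []

    # forward strand: GG at p anchors window [p-21, p+2)
    p = seq.find("GG", PROTOSPACER_LEN + 1)
    while p != -1:
        if p + 2 <= n:
            start = p - (PROTOSPACER_LEN + 1)
            window = seq[start : start + WINDOW]
            if not (drop_n and "N" in window):
                sites.append(
                    CrisprSite(
                        chrom=genome.name,
                        start=start,
                        end=start + WINDOW,
                        strand="+",
                        protospacer=window[:PROTOSPACER_LEN],
                        pam=window[PROTOSPACER_LEN:],
                    )
                )
        p = seq.find("GG", p + 1)

    # reverse strand: CC at p anchors window [p, p+23)
    p = seq.find("CC")
    while p != -1:
        if p + WINDOW <= n:
            window = seq[p : p + WINDOW]
            if not (drop_n and "N" in window):
                rc = revcomp(window)
                sites.append(
                    CrisprSite(
                        chrom=genome.name,
                        start=p,
                        end=p + WINDOW,
                        strand="-",
                        protospacer=rc[:PROTOSPACER_LEN],
                        pam=rc[PROTOSPACER_LEN:],
                    )
                )
        p = seq.find("CC", p + 1)

    sites.sort(key=CrisprSite.sort_key)
    return sites


def default_scorer(window: str) -> float:
    """Placeholder uniform scorer: every designable window scores 1.0.

    Guide-activity scoring schemes are heuristic and tool-specific, so
    scoring is pluggable; any callable mapping a 23-nt window to [0,1]
    can be supplied to :func:`score_site`.
    """
    return 1.0


def score_site(
    site: CrisprSite, scorer: Callable[[str], float] = default_scorer
) -> float:
    """Score a site with a pluggable scorer and store the result on it."""
    value = float(scorer(site.window_seq))
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"scorer returned {value!r}, outside [0,1]")
    site.score = value
    return value


# ---------------------------------------------------------------------------
# strain specificity


def _window_offset(site: CrisprSite, pos: int) -> int:
    """Offset of genomic position ``pos`` within the site window, read on
    the site strand (0 = 5'-most protospacer base)."""
    if site.strand == "+":
        return pos - site.start
    return (site.end - 1) - pos


def mark_strain_specific(
    sites: Sequence[CrisprSite],
    variants: Sequence[StrainVariant],
) -> list[StrainSpecificSite]:
    """Pair sites with the strain SNVs that make them discriminating.

    Emits one record per (site, variant) pair where the variant falls in
    the 20-nt protospacer or in either G of the PAM.  Variants at the PAM
    N position are excluded; non-SNV variants are skipped with a logged
    count.
    """
    clean: dict[str, list[tuple[int, StrainVariant]]] = {}
    rejected = 0
    for v in variants:
        if not v.is_snv():
            rejected += 1
            continue
        clean.setdefault(v.chrom, []).append((v.pos, v))
    if rejected:
        log.warning("skipped %d non-SNV variant(s)", rejected)
    for lst in clean.values():
        lst.sort(key=lambda t: t[0])

    out: list[StrainSpecificSite] = []
    for site in sites:
        lst = clean.get(site.chrom)
        if not lst:
            continue
        positions = [p for p, _ in lst]
        lo = bisect_left(positions, site.start)
        hi = bisect_right(positions, site.end - 1)
        for _pos, v in lst[lo:hi]:
            offset = _window_offset(site, v.pos)
            if offset == PAM_N_OFFSET:
                continue  # N matches any base: no discrimination
            if offset < PROTOSPACER_LEN:
                dist = PROTOSPACER_LEN - offset
                in_pam = False
            else:
                dist = 0
                in_pam = True
            out.append(
                StrainSpecificSite(
                    site=site,
                    variant=v,
                    offset_in_window=offset,
                    distance_from_pam=dist,
                    in_pam=in_pam,
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation


def annotate_sites(
    ss_sites: Sequence[StrainSpecificSite],
    genes: Sequence[GeneModel],
) -> AnnotationSummary:
    """Summarise strain-specific sites against gene models.

    A site "hits" an interval when its 23-nt window overlaps it.  An exon
    is *flanked* when at least one site lies entirely 5' of it and one
    entirely 3' of it, both windows contained in the gene span on the
    same chromosome (the geometry needed to excise the exon in cis).
    Counts are order-invariant; shared exons are counted once by
    (chrom, start, end).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ss in ss_sites:
        by_chrom.setdefault(ss.site.chrom, []).append((ss.site.start, ss.site.end))
    starts: dict[str, list[int]] = {}
    for chrom, wins in by_chrom.items():
        wins.sort()
        starts[chrom] = [w[0] for w in wins]

    def windows_overlapping(chrom: str, lo: int, hi: int) -> list[tuple[int, int]]:
        wins = by_chrom.get(chrom)
        if not wins:
            return []
        # any window with start < hi may overlap [lo, hi)
        idx = bisect_right(starts[chrom], hi - 1)
        return [w for w in wins[:idx] if w[1] > lo]

    exons_hit: set[tuple[str, int, int]] = set()
    genes_hit: set[str] = set()
    genes_any: set[str] = set()
    genes_flank: set[str] = set()

    for gene in genes:
        in_span = windows_overlapping(gene.chrom, gene.start, gene.end)
        if in_span:
            genes_any.add(gene.gene_id)
        contained = [w for w in in_span if gene.start <= w[0] and w[1] <= gene.end]
        for es, ee in gene.coding_exons:
            hit = any(w[0] < ee and w[1] > es for w in in_span)
            if hit:
                exons_hit.add((gene.chrom, es, ee))
                genes_hit.add(gene.gene_id)
            has_5p = any(w[1] <= es for w in contained)
            has_3p = any(w[0] >= ee for w in contained)
            if has_5p and has_3p:
                genes_flank.add(gene.gene_id)

    return AnnotationSummary(
        exon_hit_count=len(exons_hit),
        gene_hit_count=len(genes_hit),
        gene_any_count=len(genes_any),
        gene_flanking_count=len(genes_flank),
    )


# ---------------------------------------------------------------------------
# output


def write_sites(sites: Iterable[CrisprSite], path, header: str | None = None) -> None:
    """Write sites as 6-column BED (name = protospacer+PAM, score x1000)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.window_seq}\t"
                f"{round(s.score * 1000)}\t{s.strand}\n"
            )


def read_sites_bed(path) -> list[CrisprSite]:
    """Read sites back from the BED-6 written by :func:`write_sites`."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            sites.append(
                CrisprSite(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    protospacer=name[:PROTOSPACER_LEN],
                    pam=name[PROTOSPACER_LEN:],
                    score=int(score) / 1000,
                )
            )
    return sites
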