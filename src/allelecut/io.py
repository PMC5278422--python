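"""Readers and writers for the standard formats the toolkit touches.

FASTA/FASTQ go through Biopython, VCF through pysam; gene models are
accepted as BED12 or GFF3, strain variants as VCF or a minimal 4-column
TSV (chrom, 1-based pos, strain-A base, strain-B base).  Amplicon
targets are described in a flat TSV sheet, one row per locus.
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Iterator, Optional

from .amplicon import RawRead
from .edit_counter import (
    AmpliconTarget,
    DeletionSpec,
    LocusSummary,
    LoxpSpec,
    ReadClassification,
)
from .genome_scan import GeneModel, GenomeSequence, StrainVariant

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(GenomeSequence(name=rec.id, seq=str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(f"FASTA record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33 only)


def read_fastq(path) -> Iterator[RawRead]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            quals = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 62 for q in quals):
                raise ValueError(
                    f"read {title.split()[0]!r}: quality outside the Phred+33 "
                    "range (looks like Phred+64) — only Phred+33 is supported"
                )
            yield RawRead(title.split()[0], seq.upper(), quals)


def read_fastq_pairs(path1, path2) -> Iterator[tuple[RawRead, RawRead]]:
    for r1, r2 in zip(read_fastq(path1), read_fastq(path2), strict=True):
        yield r1, r2


def write_fastq(reads: Iterable[RawRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# strain variants (VCF v4.x or 4-column TSV)


def read_variants(
    path,
    strain_a_label: str = "strain_a",
    strain_b_label: str = "strain_b",
) -> list[StrainVariant]:
    """Read biallelic SNVs; indels and multi-allelic records are skipped
    with a logged count.  VCF positions are converted to 0-based; in VCF
    input strain A carries REF and strain B the first ALT."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.endswith(".vcf"):
        return _read_variants_vcf(path, strain_a_label, strain_b_label)
    return _read_variants_tsv(path, strain_a_label, strain_b_label)


def _read_variants_vcf(path, a_label, b_label) -> list[StrainVariant]:
    import pysam

    skipped = 0
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if (
                len(rec.ref) != 1
                or not rec.alts
                or len(rec.alts) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in "ACGT"
                or rec.alts[0] not in "ACGT"
            ):
                skipped += 1
                continue
            out.append(
                StrainVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    strain_a_base=rec.ref,
                    strain_b_base=rec.alts[0],
                    strain_a_label=a_label,
                    strain_b_label=b_label,
                )
            )
    if skipped:
        log.warning("skipped %d non-SNV/multi-allelic VCF record(s)", skipped)
    return out


def _read_variants_tsv(path, a_label, b_label) -> list[StrainVariant]:
    skipped = 0
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{line_no}: expected 4 columns")
            chrom, pos, a, b = fields[:4]
            if a not in "ACGT" or b not in "ACGT" or a == b:
                skipped += 1
                continue
            out.append(
                StrainVariant(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    strain_a_base=a,
                    strain_b_base=b,
                    strain_a_label=a_label,
                    strain_b_label=b_label,
                )
            )
    if skipped:
        log.warning("skipped %d non-SNV variant row(s)", skipped)
    return out


def write_variants_tsv(variants: Iterable[StrainVariant], path) -> None:
    """1-based 4-column TSV, the inverse of the TSV reader."""
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.strain_a_base}\t{v.strain_b_base}\n")


# ---------------------------------------------------------------------------
# gene models (BED12 or GFF3)


def read_genes(path) -> list[GeneModel]:
    path = str(path)
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
        else:
            return []
    if path.endswith((".gff", ".gff3")) or len(first.split("\t")) == 9:
        return _read_genes_gff3(path)
    return _read_genes_bed12(path)


def _read_genes_bed12(path) -> list[GeneModel]:
    """BED12: blocks are exons; a block is coding where it overlaps the
    thickStart..thickEnd region."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{line_no}: BED12 requires 12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = []
            for size, off in zip(sizes, offsets):
                es, ee = start + off, start + off + size
                coding = es < thick_e and ee > thick_s
                exons.append((es, ee, coding))
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons,
                )
            )
    return genes


def write_genes_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted((s, e) for s, e, _ in g.exons)
            coding = [(s, e) for s, e, c in sorted(g.exons) if c]
            thick_s = coding[0][0] if coding else g.start
            thick_e = coding[-1][1] if coding else g.start
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick_s}\t{thick_e}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def _gff3_attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_genes_gff3(path) -> list[GeneModel]:
    """Minimal GFF3: gene features define spans; exon features attach via
    Parent (through transcripts); CDS features mark exons as coding."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    parent_of: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int, bool]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}

    def resolve_gene(feature_id: str) -> Optional[str]:
        seen = set()
        cur = feature_id
        while cur is not None and cur not in seen:
            if cur in spans:
                return cur
            seen.add(cur)
            cur = parent_of.get(cur)
        return None

    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{line_no}: expected 9 GFF3 columns")
            rows.append(f)
    for f in rows:
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
        a = _gff3_attrs(attrs)
        if ftype == "gene":
            gid = a.get("ID", a.get("gene_id", f"{chrom}:{start}-{end}"))
            spans[gid] = (chrom, strand, int(start) - 1, int(end))
        elif "ID" in a and "Parent" in a:
            parent_of[a["ID"]] = a["Parent"].split(",")[0]
        if ftype in ("mRNA", "transcript") and "ID" in a and "Parent" in a:
            parent_of[a["ID"]] = a["Parent"].split(",")[0]
    for f in rows:
        _chrom, _src, ftype, start, end, _score, _strand, _frame, attrs = f
        if ftype not in ("exon", "CDS"):
            continue
        a = _gff3_attrs(attrs)
        parent = a.get("Parent", "").split(",")[0]
        gid = resolve_gene(parent) or resolve_gene(a.get("ID", ""))
        if gid is None:
            continue
        iv = (int(start) - 1, int(end))
        if ftype == "exon":
            exons.setdefault(gid, []).append((iv[0], iv[1], False))
        else:
            cds.setdefault(gid, []).append(iv)

    genes = []
    for gid, (chrom, strand, start, end) in spans.items():
        ex = exons.get(gid, [])
        if not ex:  # genes without exon rows: treat CDS as exons
            ex = [(s, e, True) for s, e in cds.get(gid, [])]
        else:
            cds_ivs = cds.get(gid, [])
            ex = [
                (s, e, any(s < ce and e > cs for cs, ce in cds_ivs))
                for s, e, _ in ex
            ]
        # merge duplicate exons across transcripts
        merged: dict[tuple[int, int], bool] = {}
        for s, e, c in ex:
            merged[(s, e)] = merged.get((s, e), False) or c
        ex = sorted((s, e, c) for (s, e), c in merged.items())
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, strand=strand,
                start=start, end=end, exons=ex,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# amplicon target sheet


_TARGET_COLUMNS = [
    "name", "ref_seq", "protospacer_start", "protospacer_end",
    "pam_start", "pam_end", "snp_offset", "strain_a_base", "strain_b_base",
    "strain_a_label", "strain_b_label", "edit_window_start", "edit_window_end",
    "loxp_insert_seq", "loxp_snp_offset", "loxp_snp_base",
    "junction_pos", "partner_cut_pos",
]


def read_targets(path) -> list[AmpliconTarget]:
    """Read the flat TSV target sheet (one row per amplicon locus)."""
    targets = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ValueError(f"target sheet {path} has no header with 'name'")
        for row in reader:
            def get(key, default=""):
                v = row.get(key, default)
                return "" if v in (None, ".", "") else v

            loxp = None
            if get("loxp_insert_seq"):
                loxp = LoxpSpec(
                    insert_seq=get("loxp_insert_seq"),
                    snp_offset=int(get("loxp_snp_offset", "-1") or -1),
                    snp_base=get("loxp_snp_base"),
                )
            deletion = None
            if get("junction_pos"):
                partner = get("partner_cut_pos")
                deletion = DeletionSpec(
                    junction_pos=int(get("junction_pos")),
                    partner_cut_pos=int(partner) if partner else None,
                )
            window = None
            if get("edit_window_start") and get("edit_window_end"):
                window = (int(get("edit_window_start")), int(get("edit_window_end")))
            targets.append(
                AmpliconTarget(
                    name=get("name"),
                    ref_seq=get("ref_seq").upper(),
                    protospacer_span=(
                        int(get("protospacer_start")), int(get("protospacer_end"))
                    ),
                    pam_span=(int(get("pam_start")), int(get("pam_end"))),
                    snp_offset=int(get("snp_offset")),
                    strain_a_base=get("strain_a_base"),
                    strain_b_base=get("strain_b_base"),
                    strain_a_label=get("strain_a_label") or "strain_a",
                    strain_b_label=get("strain_b_label") or "strain_b",
                    edit_window=window,
                    loxp=loxp,
                    deletion=deletion,
                )
            )
    return targets


def write_targets(targets: Iterable[AmpliconTarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TARGET_COLUMNS) + "\n")
        for t in targets:
            lox = t.loxp
            dele = t.deletion
            row = [
                t.name, t.ref_seq,
                str(t.protospacer_span[0]), str(t.protospacer_span[1]),
                str(t.pam_span[0]), str(t.pam_span[1]),
                str(t.snp_offset), t.strain_a_base, t.strain_b_base,
                t.strain_a_label, t.strain_b_label,
                str(t.edit_window[0]), str(t.edit_window[1]),
                lox.insert_seq if lox else ".",
                str(lox.snp_offset) if lox else ".",
                lox.snp_base if lox else ".",
                str(dele.junction_pos) if dele else ".",
                str(dele.partner_cut_pos) if dele and dele.partner_cut_pos is not None else ".",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_classifications(
    classifications: Iterable[ReadClassification], path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write("read_id\tallele\tedited\tindels\tloxp\tjunction\n")
        for c in classifications:
            inv = ";".join(f"{k}:{l}@{p}" for k, l, p in c.indels) or "."
            fh.write(
                f"{c.read_id}\t{c.allele}\t{int(c.edited)}\t{inv}\t"
                f"{int(c.loxp_positive)}\t{int(c.junction)}\n"
            )


def write_summary(summary: LocusSummary, path, header: str | None = None) -> None:
    """Per-locus accounting table; percentages to one decimal place."""

    def pct(v):
        return "." if v is None else f"{v:.1f}"

    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        fh.write(
            "locus\tclass\tlabel\ttotal_reads\tedited_reads\tedited_pct\t"
            "loxp_reads\tloxp_pct\tjunction_reads\tjunction_pct\n"
        )
        labels = {
            "strain_a": summary.strain_a_label,
            "strain_b": summary.strain_b_label,
            "indeterminate": "indeterminate",
        }
        for cls in ("strain_a", "strain_b", "indeterminate"):
            c = summary.counts[cls]
            ep = pct(summary.edited_pct.get(cls))
            lp = pct(summary.loxp_pct.get(cls))
            jp = pct(summary.junction_pct.get(cls))
            fh.write(
                f"{summary.name}\t{cls}\t{labels[cls]}\t{c.total}\t{c.edited}\t"
                f"{ep}\t{c.loxp}\t{lp}\t{c.junction}\t{jp}\n"
            )
        fh.write(
            f"{summary.name}\ttotal\t.\t{summary.total_reads}\t.\t.\t.\t.\t.\t.\n"
        )
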