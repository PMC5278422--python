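"""Synthetic inputs with ground truth for the whole toolkit.

Generates random genomes with strain SNVs and gene models for the
scanner, and paired amplicon reads for the quantification pipeline: a
diploid locus with a heterozygous diagnostic SNP inside a CRISPR target,
per-allele indel rates at the cut site, loxP knock-ins carrying a
loxP-specific SNP, deletion-junction amplicons, and uniform per-base
substitution error.  Every read is recorded in a ground-truth manifest
so downstream classifications can be checked exactly.

Defaults emulate a MiSeq amplicon experiment on a heterozygous cross: a
~260-nt amplicon sequenced with overlapping read pairs, a 50/50 allele
ratio, strongly biased per-allele edit rates (30% on the matched allele
vs 5% on the mismatched one), and a post-trimming substitution error
rate of 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .amplicon import RawRead, align_glocal
from .edit_counter import (
    LOXP_34,
    AmpliconTarget,
    DeletionSpec,
    LoxpSpec,
    assign_allele,
)
from .genome_scan import GeneModel, GenomeSequence, StrainVariant, revcomp

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for amplicon read simulation; probabilities are per read
    (rates) or per base (error_rate)."""

    seed: int = 0
    allele_ratio: float = 0.5
    edit_rate_a: float = 0.30
    edit_rate_b: float = 0.05
    indel_geometric_p: float = 0.5
    indel_max_len: int = 20
    insertion_fraction: float = 0.5
    loxp_rate: float = 0.0
    error_rate: float = 0.001
    read_length: int = 180
    base_quality: int = 37
    n_read_pairs: int = 10_000

    def __post_init__(self) -> None:
        for name in ("allele_ratio", "edit_rate_a", "edit_rate_b",
                     "insertion_fraction", "loxp_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.indel_geometric_p <= 1.0:
            raise ValueError("indel_geometric_p must be in (0,1]")
        if self.read_length < 1 or self.indel_max_len < 1:
            raise ValueError("lengths must be positive")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one simulated read pair.

    ``snp_assignable`` records whether the planted edit leaves the
    diagnostic SNP recoverable from the error-free fragment: False when
    the read is donor-derived (loxP) or when the indel removed the
    diagnostic base or made its identity alignment-ambiguous (indels
    at or sliding near the SNP have equally optimal placements that
    change which base sits at the SNP column).
    """

    read_id: str
    allele: str
    edit_kind: Optional[str] = None  # "insertion" / "deletion" / None
    edit_len: int = 0
    edit_pos: int = -1  # left-aligned reference position
    loxp: bool = False
    junction: bool = False
    snp_assignable: bool = True


# ---------------------------------------------------------------------------
# genome-level generators


def simulate_genome(length: int, gc_fraction: float = 0.4, seed: int = 0,
                    name: str = "chrSim") -> GenomeSequence:
    """Random genome over ACGT with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0,1]")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    seq = "".join(rng.choice(BASES, size=length, p=[at, gc, gc, at]))
    return GenomeSequence(name=name, seq=seq)


def simulate_strain_variants(
    genome: GenomeSequence,
    density: float = 0.001,
    seed: int = 0,
    strain_a_label: str = "strain_a",
    strain_b_label: str = "strain_b",
) -> list[StrainVariant]:
    """Place biallelic SNVs at Bernoulli(density) positions.

    Strain A carries the reference base, strain B a random alternative,
    emulating a scanned reference that matches one strain.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density outside [0,1]")
    rng = np.random.default_rng(seed)
    n = len(genome.seq)
    positions = np.flatnonzero(rng.random(n) < density)
    variants = []
    for pos in positions:
        ref = genome.seq[pos]
        if ref == "N":
            continue
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[rng.integers(0, 3)]
        variants.append(
            StrainVariant(
                chrom=genome.name,
                pos=int(pos),
                strain_a_base=ref,
                strain_b_base=alt,
                strain_a_label=strain_a_label,
                strain_b_label=strain_b_label,
            )
        )
    return variants


def simulate_gene_models(
    genome: GenomeSequence,
    n_genes: int = 20,
    seed: int = 0,
    mean_exons: int = 4,
) -> list[GeneModel]:
    """Non-overlapping gene models with coding exons, tiled along the genome."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pos = 0
    L = len(genome.seq)
    for i in range(n_genes):
        pos += int(rng.integers(200, 1000))
        n_ex = max(1, int(rng.poisson(mean_exons)))
        exons = []
        cursor = pos
        for _ in range(n_ex):
            ex_len = int(rng.integers(80, 300))
            if cursor + ex_len > L:
                break
            exons.append((cursor, cursor + ex_len, True))
            cursor += ex_len + int(rng.integers(100, 800))
        if not exons:
            break
        start, end = exons[0][0], exons[-1][1]
        if end > L:
            break
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=genome.name,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                exons=exons,
            )
        )
        pos = end
        if pos >= L:
            break
    return genes


# ---------------------------------------------------------------------------
# amplicon target construction


def make_target(
    seed: int = 0,
    name: str = "locus",
    amplicon_len: int = 260,
    protospacer_start: int = 100,
    snp_distance_from_pam: int = 7,
    with_loxp: bool = False,
    with_junction: bool = False,
    homology_arm: int = 33,
) -> AmpliconTarget:
    """Build a synthetic amplicon target with an embedded N20-NGG site.

    The diagnostic SNP sits in the protospacer at the requested distance
    from the PAM; the reference carries the strain-A base.  With
    ``with_loxp`` the donor design mirrors a loxP knock-in oligo: the
    34-nt loxP core flanked by ``homology_arm``-nt arms, with a
    loxP-specific third base at the diagnostic SNP position.  With
    ``with_junction`` the amplicon is treated as a two-cut deletion
    junction reference fused at the expected cut position.
    """
    if not 1 <= snp_distance_from_pam <= 20:
        raise ValueError("snp_distance_from_pam must be in 1..20")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(BASES, size=amplicon_len))
    p0 = protospacer_start
    p1 = p0 + 20
    pam = (p1, p1 + 3)
    if pam[1] > amplicon_len:
        raise ValueError("amplicon too short for protospacer + PAM")
    seq[p1 + 1] = "G"
    seq[p1 + 2] = "G"
    snp_offset = p1 - snp_distance_from_pam
    a_base = seq[snp_offset]
    b_base = rng.choice([b for b in "ACGT" if b != a_base])
    ref_seq = "".join(seq)

    loxp = None
    if with_loxp:
        third = next(b for b in "ACGT" if b not in (a_base, b_base))
        loxp = LoxpSpec(
            insert_seq=LOXP_34,
            snp_offset=snp_offset,
            snp_base=third,
            loxp_seq=LOXP_34,
        )
    deletion = None
    cut = p1 - 3
    if with_junction:
        deletion = DeletionSpec(junction_pos=cut)
    return AmpliconTarget(
        name=name,
        ref_seq=ref_seq,
        protospacer_span=(p0, p1),
        pam_span=pam,
        snp_offset=snp_offset,
        strain_a_base=str(a_base),
        strain_b_base=str(b_base),
        loxp=loxp,
        deletion=deletion,
    )


# ---------------------------------------------------------------------------
# amplicon read simulation


def _left_align_deletion(ref: str, start: int, length: int) -> int:
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_align_insertion(ref: str, pos: int, ins: str) -> int:
    ins = list(ins)
    while pos > 0 and ins[-1] == ref[pos - 1]:
        ins = [ref[pos - 1]] + ins[:-1]
        pos -= 1
    return pos


def _apply_errors(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0.0 or not seq:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_edited_amplicons(
    target: AmpliconTarget,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[tuple[RawRead, RawRead]], dict[str, ManifestEntry]]:
    """Simulate paired amplicon reads with planted editing outcomes.

    Each pair derives from allele A with probability ``allele_ratio``.
    Outcomes are mutually exclusive per read: a loxP knock-in (donor
    insert at the cut plus the loxP SNP) at ``loxp_rate``, else an indel
    at the cut at the allele's edit rate.  When the target carries
    deletion geometry every read is a junction read (the junction
    amplicon only amplifies deleted molecules).  Substitution errors are
    added per base; mates read the fragment from both ends.
    """
    rng = np.random.default_rng(config.seed)
    ref = target.ref_seq
    cut = target.cut_pos
    rl = config.read_length

    max_extra = config.indel_max_len
    if target.loxp is not None:
        max_extra = max(max_extra, len(target.loxp.insert_seq))
    if target.snp_offset >= rl and len(ref) - target.snp_offset > rl:
        raise ValueError("read length too short to cover the diagnostic SNP")
    if 2 * rl - (len(ref) + max_extra) < 1:
        raise ValueError(
            "read length too short: mates cannot overlap on the longest fragment"
        )

    templates = {
        "strain_a": ref[: target.snp_offset]
        + target.strain_a_base
        + ref[target.snp_offset + 1 :],
        "strain_b": ref[: target.snp_offset]
        + target.strain_b_base
        + ref[target.snp_offset + 1 :],
    }
    edit_rates = {"strain_a": config.edit_rate_a, "strain_b": config.edit_rate_b}

    pairs: list[tuple[RawRead, RawRead]] = []
    manifest: dict[str, ManifestEntry] = {}
    assignable_cache: dict[str, str] = {}

    def clean_read_assignable(frag: str, allele: str) -> bool:
        """Planted truth for SNP recoverability: classify the error-free
        fragment; recoverable iff the verdict is the source allele."""
        cached = assignable_cache.get(frag)
        if cached is None:
            aln = align_glocal(frag, ref, amplicon_id=target.name)
            cached = assign_allele(aln, target)
            assignable_cache[frag] = cached
        return cached == allele
    for i in range(config.n_read_pairs):
        read_id = f"{target.name}:{i:06d}"
        allele = "strain_a" if rng.random() < config.allele_ratio else "strain_b"
        frag = templates[allele]
        edit_kind = None
        edit_len = 0
        edit_pos = -1
        loxp_flag = False
        assignable = True

        if target.loxp is not None and rng.random() < config.loxp_rate:
            lox = target.loxp
            if lox.snp_offset >= 0:
                frag = (
                    frag[: lox.snp_offset] + lox.snp_base + frag[lox.snp_offset + 1 :]
                )
            frag = frag[:cut] + lox.insert_seq + frag[cut:]
            loxp_flag = True
            edit_kind = "insertion"
            edit_len = len(lox.insert_seq)
            edit_pos = _left_align_insertion(ref, cut, lox.insert_seq)
            assignable = False  # donor-derived SNP
        elif rng.random() < edit_rates[allele]:
            length = int(min(rng.geometric(config.indel_geometric_p),
                             config.indel_max_len))
            if rng.random() < config.insertion_fraction:
                ins = "".join(rng.choice(BASES, size=length))
                frag = frag[:cut] + ins + frag[cut:]
                edit_kind = "insertion"
                edit_pos = _left_align_insertion(ref, cut, ins)
            else:
                start = max(1, cut - length // 2)
                start = min(start, len(frag) - length - 1)
                frag = frag[:start] + frag[start + length :]
                edit_kind = "deletion"
                edit_pos = _left_align_deletion(ref, start, length)
            edit_len = length
            assignable = clean_read_assignable(frag, allele)

        r1_seq = _apply_errors(frag[:rl], rng, config.error_rate)
        r2_seq = _apply_errors(revcomp(frag[-rl:]), rng, config.error_rate)
        q = config.base_quality
        pairs.append(
            (
                RawRead(read_id, r1_seq, [q] * len(r1_seq)),
                RawRead(read_id, r2_seq, [q] * len(r2_seq)),
            )
        )
        manifest[read_id] = ManifestEntry(
            read_id=read_id,
            allele=allele,
            edit_kind=edit_kind,
            edit_len=edit_len,
            edit_pos=edit_pos,
            loxp=loxp_flag,
            junction=target.deletion is not None,
            snp_assignable=assignable,
        )
    return pairs, manifest


# ---------------------------------------------------------------------------
# writers


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write simulated pairs as two Phred+33 FASTQ files (R1/R2)."""
    from .io import write_fastq

    write_fastq((p[0] for p in pairs), path1)
    write_fastq((p[1] for p in pairs), path2)


def write_manifest(manifest: dict[str, ManifestEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tallele\tedit_kind\tedit_len\tedit_pos\tloxp\tjunction\t"
            "snp_assignable\n"
        )
        for entry in manifest.values():
            fh.write(
                f"{entry.read_id}\t{entry.allele}\t{entry.edit_kind or '.'}\t"
                f"{entry.edit_len}\t{entry.edit_pos}\t"
                f"{int(entry.loxp)}\t{int(entry.junction)}\t"
                f"{int(entry.snp_assignable)}\n"
            )


def read_manifest(path) -> dict[str, ManifestEntry]:
    manifest = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            (rid, allele, kind, length, pos, loxp, junction,
             assignable) = line.rstrip("\n").split("\t")
            manifest[rid] = ManifestEntry(
                read_id=rid,
                allele=allele,
                edit_kind=None if kind == "." else kind,
                edit_len=int(length),
                edit_pos=int(pos),
                loxp=bool(int(loxp)),
                junction=bool(int(junction)),
                snp_assignable=bool(int(assignable)),
            )
    return manifest
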