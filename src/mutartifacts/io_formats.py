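"""Genomic data model and readers/writers for FASTA, GFF3, VCF and BED.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive conventions of GFF3 and VCF happens only in this module.

Strand-resolved read support for a call travels in VCF through two custom
integer FORMAT fields, ``SRF`` and ``SRR`` (supporting reads on the forward
and reverse strand).  An absent field means the support is *unknown*, which
downstream quality filters treat as failing strand requirements — it is not
the same thing as zero reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from cyvcf2 import VCF
from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger("mutartifacts")

VALID_BASES = set("ACGTN")
FEATURE_TYPES = ("gene", "CDS", "intron", "exon", "TE", "centromere", "intergenic")

#: GFF3 ``type`` column spellings accepted for each internal feature type.
_GFF_TYPE_ALIASES = {
    "gene": "gene",
    "cds": "CDS",
    "intron": "intron",
    "exon": "exon",
    "te": "TE",
    "transposable_element": "TE",
    "centromere": "centromere",
    "intergenic": "intergenic",
}

SRF_HEADER = (
    '##FORMAT=<ID=SRF,Number=1,Type=Integer,'
    'Description="Reads supporting the alternate allele on the forward strand">'
)
SRR_HEADER = (
    '##FORMAT=<ID=SRR,Number=1,Type=Integer,'
    'Description="Reads supporting the alternate allele on the reverse strand">'
)


class GenomeAssembly:
    """A set of chromosome sequences (uppercase A/C/G/T/N)."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                logger.warning(
                    "chromosome %s: replacing %d non-ACGTN symbol kind(s) %s with N",
                    name, len(bad), sorted(bad),
                )
                seq = "".join(b if b in VALID_BASES else "N" for b in seq)
            self.chromosomes[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Sequence over the 0-based half-open window [start, end)."""
        return self.chromosomes[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.chromosomes[chrom][pos]

    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class GenomicInterval:
    """A typed, stranded interval; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "intergenic"
    attributes: Mapping[str, str] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class AnnotationSet:
    """Typed genomic intervals with per-chromosome interval indexes."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.feature_type)
        )
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for iv in self.intervals:
            key = (iv.chrom, iv.feature_type)
            self._trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, iv)

    def of_type(self, feature_type: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.feature_type == feature_type]

    def feature_types(self) -> set[str]:
        return {iv.feature_type for iv in self.intervals}

    def overlapping(
        self, chrom: str, start: int, end: int, feature_type: str | None = None
    ) -> list[GenomicInterval]:
        types = [feature_type] if feature_type else FEATURE_TYPES
        out = []
        for t in types:
            tree = self._trees.get((chrom, t))
            if tree:
                out.extend(hit.data for hit in tree.overlap(start, end))
        return sorted(out, key=lambda iv: (iv.start, iv.end))

    def contains(self, chrom: str, pos: int, feature_type: str) -> bool:
        tree = self._trees.get((chrom, feature_type))
        return bool(tree and tree.overlaps(pos, pos + 1))

    def total_bp(self, feature_type: str) -> int:
        """Total bp covered by the type (overlaps within a type merged)."""
        total = 0
        for (chrom, t), tree in self._trees.items():
            if t != feature_type:
                continue
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def extended(self, intervals: Iterable[GenomicInterval]) -> "AnnotationSet":
        return AnnotationSet(list(self.intervals) + list(intervals))


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class MutationCall:
    """One putative mutation in one sample.

    ``pos`` is the 0-based coordinate of the reference base for an SNV, or
    of the anchor base preceding the event for an indel (VCF convention,
    shifted to 0-based).  ``fwd_support``/``rev_support`` of ``None`` mean
    the strand evidence is unknown.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    fwd_support: int | None = None
    rev_support: int | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for s in (self.fwd_support, self.rev_support):
            if s is not None and s < 0:
                raise ValueError("read support must be >= 0")

    @property
    def var_class(self) -> str:
        return _variant_class(self.ref, self.alt)

    @property
    def total_support(self) -> int | None:
        if self.fwd_support is None or self.rev_support is None:
            return None
        return self.fwd_support + self.rev_support

    def key(self) -> tuple:
        """Identity including the carrying sample."""
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)

    def site_key(self) -> tuple:
        """Identity of the variant irrespective of sample."""
        return (self.chrom, self.pos, self.ref, self.alt)


class CallSet:
    """A labelled collection of calls, sorted and duplicate-free."""

    def __init__(self, label: str, calls: Iterable[MutationCall]):
        self.label = label
        seen: dict[tuple, MutationCall] = {}
        n_dup = 0
        for call in calls:
            if call.key() in seen:
                n_dup += 1
            else:
                seen[call.key()] = call
        if n_dup:
            logger.warning("callset %s: collapsed %d duplicate call(s)", label, n_dup)
        self.calls: list[MutationCall] = sorted(
            seen.values(), key=lambda c: (c.chrom, c.pos, c.ref, c.alt, c.sample_id)
        )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[MutationCall]:
        return iter(self.calls)

    def snvs(self) -> list[MutationCall]:
        return [c for c in self.calls if c.var_class == "SNV"]

    def samples(self) -> list[str]:
        return sorted({c.sample_id for c in self.calls})

    def subset(self, predicate, label: str | None = None) -> "CallSet":
        return CallSet(label or self.label, [c for c in self.calls if predicate(c)])

    def key_set(self) -> set[tuple]:
        return {c.key() for c in self.calls}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeAssembly:
    """Load a FASTA file into memory, folding to uppercase.

    Non-ACGTN symbols are replaced by N with a logged warning; duplicate
    record names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = Fasta(str(path), as_raw=True, sequence_always_upper=True,
                    duplicate_action="stop", build_index=True, rebuild=True)
    chromosomes = {name: str(records[name][:]) for name in records.keys()}
    records.close()
    if not chromosomes:
        raise ValueError(f"empty FASTA: {path}")
    return GenomeAssembly(chromosomes)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def synthesize_introns(genes: Sequence[GenomicInterval],
                       exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Introns = gene space minus exon space, per gene."""
    introns = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ex in exons:
        by_chrom.setdefault(ex.chrom, []).append(ex)
    for gene in genes:
        gid = gene.attributes.get("ID", "")
        gene_exons = sorted(
            (ex for ex in by_chrom.get(gene.chrom, [])
             if ex.start >= gene.start and ex.end <= gene.end
             and (not ex.attributes.get("Parent") or ex.attributes["Parent"] == gid)),
            key=lambda ex: ex.start,
        )
        cursor = gene.start
        for ex in gene_exons:
            if ex.start > cursor:
                introns.append(GenomicInterval(
                    gene.chrom, cursor, ex.start, gene.strand, "intron",
                    {"Parent": gid} if gid else {}))
            cursor = max(cursor, ex.end)
        if gene_exons and cursor < gene.end:
            introns.append(GenomicInterval(
                gene.chrom, cursor, gene.end, gene.strand, "intron",
                {"Parent": gid} if gid else {}))
    return introns


def synthesize_intergenic(genes: Sequence[GenomicInterval],
                          genome: GenomeAssembly) -> list[GenomicInterval]:
    """Intergenic = complement of gene space, tiling each chromosome."""
    out = []
    for chrom, length in genome.lengths.items():
        tree = IntervalTree()
        for g in genes:
            if g.chrom == chrom:
                tree.addi(g.start, g.end)
        tree.merge_overlaps()
        cursor = 0
        for iv in sorted(tree):
            if iv.begin > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.begin, ".", "intergenic"))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length, ".", "intergenic"))
    return out


def read_gff3(path: str | Path, genome: GenomeAssembly) -> AnnotationSet:
    """Read a GFF3 file, converting to 0-based half-open coordinates.

    Introns are synthesized from gene/exon features when absent, and
    intergenic intervals as the complement of gene space.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, gff_type, start1, end1, _score, strand, _frame, attrs = cols[:9]
            ftype = _GFF_TYPE_ALIASES.get(gff_type.lower())
            if ftype is None:
                continue  # feature type outside our vocabulary
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            start, end = int(start1) - 1, int(end1)  # 1-based incl -> 0-based half-open
            if end > genome.lengths[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: interval end {end} exceeds {chrom} length")
            intervals.append(GenomicInterval(
                chrom, start, end, strand if strand in "+-" else ".",
                ftype, _parse_gff_attributes(attrs)))
    genes = [iv for iv in intervals if iv.feature_type == "gene"]
    if not any(iv.feature_type == "intron" for iv in intervals):
        exons = [iv for iv in intervals if iv.feature_type in ("exon", "CDS")]
        intervals.extend(synthesize_introns(genes, exons))
    if not any(iv.feature_type == "intergenic" for iv in intervals):
        intervals.extend(synthesize_intergenic(genes, genome))
    return AnnotationSet(intervals)


def write_gff3(annotation: AnnotationSet, path: str | Path,
               skip_types: tuple[str, ...] = ("intergenic",)) -> None:
    """Write features back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in annotation.intervals:
            if iv.feature_type in skip_types:
                continue
            attrs = ";".join(f"{k}={v}" for k, v in iv.attributes.items()) or "."
            gff_type = "transposable_element" if iv.feature_type == "TE" else iv.feature_type
            fh.write("\t".join([
                iv.chrom, "mutartifacts", gff_type, str(iv.start + 1), str(iv.end),
                ".", iv.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, label: str) -> CallSet:
    """Read a VCF into a CallSet: one call per sample carrying a non-reference
    allele, with multi-allelic records decomposed per alternate allele.

    Strand support is read from the SRF/SRR FORMAT fields; missing fields are
    recorded as unknown (None), never as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = vcf.samples
    has_srf = "SRF" in (vcf.raw_header or "")
    has_srr = "SRR" in (vcf.raw_header or "")
    calls: list[MutationCall] = []
    n_malformed = 0
    for variant in vcf:
        try:
            alts = variant.ALT or []
            gts = variant.genotype.array() if samples else []
            srf = variant.format("SRF") if has_srf else None
            srr = variant.format("SRR") if has_srr else None
            for si, sample in enumerate(samples):
                carried = {a for a in gts[si][:-1] if a > 0}
                for alt_index in carried:
                    alt = alts[alt_index - 1]
                    f = None if srf is None else int(srf[si][0])
                    r = None if srr is None else int(srr[si][0])
                    # cyvcf2 encodes missing integers as large negatives
                    f = None if (f is not None and f < 0) else f
                    r = None if (r is not None and r < 0) else r
                    calls.append(MutationCall(
                        variant.CHROM, variant.POS - 1, variant.REF, alt,
                        sample, f, r))
        except Exception:  # malformed record: log, skip, count
            n_malformed += 1
            logger.warning("skipping malformed VCF record near %s:%s",
                           getattr(variant, "CHROM", "?"), getattr(variant, "POS", "?"))
    vcf.close()
    if n_malformed:
        logger.warning("%s: skipped %d malformed record(s)", path, n_malformed)
    return CallSet(label, calls)


def write_vcf(callset: CallSet, genome: GenomeAssembly, path: str | Path) -> None:
    """Write a CallSet to VCF v4.2 with SRF/SRR strand-support FORMAT fields.

    Raises if any call's ref allele mismatches the genome at its position.
    """
    for call in callset:
        expected = genome.sequence(call.chrom, call.pos, call.pos + len(call.ref))
        if expected != call.ref:
            raise ValueError(
                f"ref mismatch at {call.chrom}:{call.pos}: call has {call.ref!r}, "
                f"genome has {expected!r}")
    header = pysam.VariantHeader()
    header.add_line("##source=mutartifacts")
    for name, length in genome.lengths.items():
        header.contigs.add(name, length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(SRF_HEADER)
    header.add_line(SRR_HEADER)
    samples = callset.samples()
    for s in samples:
        header.add_sample(s)
    by_site: dict[tuple, list[MutationCall]] = {}
    for call in callset:
        by_site.setdefault(call.site_key(), []).append(call)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), carriers in sorted(by_site.items()):
            rec = out.new_record(contig=chrom, start=pos, alleles=(ref, alt))
            rec.qual = None
            carrier_map = {c.sample_id: c for c in carriers}
            for s in samples:
                c = carrier_map.get(s)
                if c is None:
                    rec.samples[s]["GT"] = (0, 0)
                else:
                    rec.samples[s]["GT"] = (0, 1)
                    if c.fwd_support is not None:
                        rec.samples[s]["SRF"] = c.fwd_support
                    if c.rev_support is not None:
                        rec.samples[s]["SRR"] = c.rev_support
            out.write(rec)


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Export intervals as 6-column BED (0-based half-open, as BED expects)."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
            name = iv.attributes.get("ID", iv.feature_type)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
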