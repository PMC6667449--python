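"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion happens only at
format boundaries (GTF is 1-based inclusive, BED/bedGraph are 0-based
half-open).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class Bed12ParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptRecord:
    """One assembled transcript: exons in 5'->3' transcript order.

    On '+' the exon list ascends genomically, on '-' it descends.
    """

    transcript_id: str
    gene_id: str
    sample_id: str
    exons: list[GenomicInterval]
    fpkm: float = 0.0
    coverage: float = 0.0

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        if self.fpkm < 0 or self.coverage < 0:
            raise ValueError(f"{self.transcript_id}: negative abundance")
        starts = [e.start for e in self.exons]
        if self.strand == "-":
            ordered = all(a > b for a, b in zip(starts, starts[1:]))
        else:
            ordered = all(a < b for a, b in zip(starts, starts[1:]))
        if not ordered:
            raise ValueError(
                f"{self.transcript_id}: exons not in 5'->3' transcript order"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exons_genomic(self) -> list[GenomicInterval]:
        """Exons in ascending genomic order regardless of strand."""
        return sorted(self.exons, key=lambda e: e.start)

    @property
    def span(self) -> tuple[int, int]:
        g = self.exons_genomic
        return g[0].start, g[-1].end


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str
    replicate: int = 1

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


class GenomeSequence:
    """Contig -> nucleotide string; out-of-bounds lookups are errors."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self._contigs[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"[{start}, {end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs


@dataclass
class DomainAnnotation:
    """A protein domain projected onto genomic coordinates (may span exons)."""

    gene_id: str
    domain_name: str
    instance_index: int
    intervals: list[GenomicInterval]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("domain needs >=1 interval")
        chroms = {i.chrom for i in self.intervals}
        strands = {i.strand for i in self.intervals}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError("domain intervals span multiple chroms/strands")
        self.intervals = sorted(self.intervals, key=lambda i: i.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.end > b.start:
                raise ValueError("overlapping domain intervals")

    @property
    def key(self) -> tuple[str, int]:
        return (self.domain_name, self.instance_index)

    @property
    def total_bp(self) -> int:
        return sum(len(i) for i in self.intervals)


@dataclass
class ReadChain:
    """Aligned blocks of one long read, ascending genomic order."""

    read_id: str
    blocks: list[GenomicInterval]

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("read needs >=1 block")
        chroms = {b.chrom for b in self.blocks}
        strands = {b.strand for b in self.blocks}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError("read blocks span multiple chroms/strands")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.read_id}: overlapping blocks")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive blocks as (start, end) pairs."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        )


# ---------------------------------------------------------------------------
# GTF (StringTie dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_SAMPLE_NAME_RE = re.compile(r"^(?P<tissue>.+?)_rep(?P<rep>\d+)$")


def sample_meta_from_name(name: str) -> SampleMeta:
    """Derive tissue/replicate from a sample name like ``liver_rep2``."""
    m = _SAMPLE_NAME_RE.match(name)
    if m:
        return SampleMeta(name, m.group("tissue"), int(m.group("rep")))
    return SampleMeta(name, name, 1)


def parse_gtf(
    path: str | Path, sample_id: str | None = None
) -> tuple[list[TranscriptRecord], SampleMeta]:
    """Parse a StringTie-style GTF into transcripts plus sample metadata.

    GTF 1-based inclusive coordinates become internal 0-based half-open.
    ``cov``/``FPKM`` attributes are read case-insensitively and default to 0
    (with a warning) when missing.  Transcripts with mixed strands, or with
    strand '.', are rejected and logged rather than raised.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem.removesuffix(".gtf")
    meta = sample_meta_from_name(sample_id)

    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    fpkm_of: dict[str, float] = {}
    cov_of: dict[str, float] = {}
    missing_abundance = False
    bad_strand: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields
            )
            if feature != "exon":
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
                ) from None
            attributes = {k.lower(): v for k, v in _ATTR_RE.findall(attrs)}
            if "transcript_id" not in attributes or "gene_id" not in attributes:
                raise GtfParseError("missing gene_id/transcript_id", lineno)
            tid = attributes["transcript_id"]
            if strand not in _STRANDS:
                bad_strand.add(tid)
                continue
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise GtfParseError(str(exc), lineno) from None
            exons.setdefault(tid, []).append(interval)
            gene_of[tid] = attributes["gene_id"]
            if "fpkm" in attributes:
                fpkm_of[tid] = float(attributes["fpkm"])
            if "cov" in attributes:
                cov_of[tid] = float(attributes["cov"])

    records: list[TranscriptRecord] = []
    for tid, ivals in exons.items():
        if tid in bad_strand:
            logger.warning("%s: transcript %s has missing strand; rejected", path, tid)
            continue
        if len({i.strand for i in ivals}) > 1 or len({i.chrom for i in ivals}) > 1:
            logger.warning("%s: transcript %s has mixed strands; rejected", path, tid)
            continue
        ivals = sorted(ivals, key=lambda i: i.start)
        if ivals[0].strand == "-":
            ivals = ivals[::-1]
        if tid not in fpkm_of and tid not in cov_of:
            missing_abundance = True
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene_of[tid],
                sample_id=sample_id,
                exons=ivals,
                fpkm=fpkm_of.get(tid, 0.0),
                coverage=cov_of.get(tid, 0.0),
            )
        )
    if missing_abundance:
        logger.warning("%s: some transcripts lack cov/FPKM; defaulting to 0", path)
    return records, meta


def write_gtf(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts back out as a StringTie-style exon GTF."""
    with open(path, "w") as fh:
        for tx in transcripts:
            span_start, span_end = tx.span
            base_attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'cov "{tx.coverage:.6f}"; FPKM "{tx.fpkm:.6f}";'
            )
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        "splicecat",
                        "transcript",
                        str(span_start + 1),
                        str(span_end),
                        ".",
                        tx.strand,
                        ".",
                        base_attrs,
                    ]
                )
                + "\n"
            )
            for n, exon in enumerate(tx.exons_genomic, start=1):
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            "splicecat",
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            base_attrs + f' exon_number "{n}";',
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_fasta(path: str | Path) -> GenomeSequence:
    """Read a (possibly multi-contig) FASTA into a GenomeSequence."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    return GenomeSequence(contigs)


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12 / bedGraph
# ---------------------------------------------------------------------------


def parse_bed12(path: str | Path) -> list[ReadChain]:
    """Parse a BED12 file into read chains (blocks reconstructed)."""
    chains: list[ReadChain] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise Bed12ParseError(f"line {lineno}: expected 12 fields")
            chrom = fields[0]
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            name = fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise Bed12ParseError(
                    f"line {lineno}: blockCount {block_count} does not match "
                    f"blockSizes/blockStarts"
                )
            blocks = []
            for size, offset in zip(sizes, starts):
                s = chrom_start + offset
                blocks.append(GenomicInterval(chrom, s, s + size, strand))
            if blocks[-1].end != chrom_end:
                raise Bed12ParseError(
                    f"line {lineno}: last block ends at {blocks[-1].end}, "
                    f"chromEnd is {chrom_end}"
                )
            try:
                chains.append(ReadChain(read_id=name, blocks=blocks))
            except ValueError as exc:
                raise Bed12ParseError(f"line {lineno}: {exc}") from None
    return chains


def bed12_line(
    chrom: str,
    blocks: list[GenomicInterval],
    name: str,
    score: int = 0,
    strand: str = "+",
    thick: tuple[int, int] | None = None,
    rgb: str = "0",
) -> str:
    blocks = sorted(blocks, key=lambda b: b.start)
    chrom_start = blocks[0].start
    chrom_end = blocks[-1].end
    if thick is None:
        thick = (chrom_start, chrom_start)
    sizes = ",".join(str(len(b)) for b in blocks) + ","
    offsets = ",".join(str(b.start - chrom_start) for b in blocks) + ","
    return "\t".join(
        [
            chrom,
            str(chrom_start),
            str(chrom_end),
            name,
            str(score),
            strand,
            str(thick[0]),
            str(thick[1]),
            rgb,
            str(len(blocks)),
            sizes,
            offsets,
        ]
    )


def write_bed12(chains: Iterable[ReadChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(
                bed12_line(chain.chrom, chain.blocks, chain.read_id, strand=chain.strand)
                + "\n"
            )


def parse_bedgraph(path: str | Path) -> dict[str, dict[int, float]]:
    """Expand a bedGraph into per-base depths per contig."""
    depth: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t")[:4]
            value = float(value_s)
            per_chrom = depth.setdefault(chrom, {})
            for pos in range(int(start_s), int(end_s)):
                per_chrom[pos] = value
    return depth


def write_bedgraph(
    depth: Mapping[str, Mapping[int, float]], path: str | Path
) -> None:
    """Write per-base depths as a run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(depth):
            positions = sorted(depth[chrom])
            if not positions:
                continue
            run_start = positions[0]
            run_value = depth[chrom][run_start]
            prev = run_start
            for pos in positions[1:]:
                value = depth[chrom][pos]
                if pos == prev + 1 and value == run_value:
                    prev = pos
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value:g}\n")
                run_start, run_value = pos, value
                prev = pos
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value:g}\n")


# ---------------------------------------------------------------------------
# Domain annotation TSV
# ---------------------------------------------------------------------------

DOMAIN_VOCABULARY = frozenset(
    ["SP", "SEA", "Ig", "GAIN", "GPS", "ICL3", "other"]
    + [f"TM{i}" for i in range(1, 8)]
)


def parse_domains_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain table (gene_id, domain, instance, chrom, start, end, strand).

    Rows sharing (gene_id, domain, instance) merge into one multi-interval
    annotation.
    """
    grouped: dict[tuple[str, str, int], list[GenomicInterval]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "domain", "instance", "chrom", "start", "end", "strand"}
        if not required <= set(idx):
            raise ValueError(f"domain table missing columns: {required - set(idx)}")
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            name = f[idx["domain"]]
            if name not in DOMAIN_VOCABULARY:
                raise ValueError(f"unknown domain name {name!r}")
            key = (f[idx["gene_id"]], name, int(f[idx["instance"]]))
            grouped.setdefault(key, []).append(
                GenomicInterval(
                    f[idx["chrom"]],
                    int(f[idx["start"]]),
                    int(f[idx["end"]]),
                    f[idx["strand"]],
                )
            )
    return [
        DomainAnnotation(gene_id=g, domain_name=d, instance_index=i, intervals=ivals)
        for (g, d, i), ivals in grouped.items()
    ]


def write_domains_tsv(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdomain\tinstance\tchrom\tstart\tend\tstrand\n")
        for dom in domains:
            for ival in dom.intervals:
                fh.write(
                    f"{dom.gene_id}\t{dom.domain_name}\t{dom.instance_index}\t"
                    f"{ival.chrom}\t{ival.start}\t{ival.end}\t{ival.strand}\n"
                )


# ---------------------------------------------------------------------------
# Catalog exports
# ---------------------------------------------------------------------------


def export_outputs(
    catalog,
    variants,
    path_prefix: str | Path,
    orfs: Mapping[str, object] | None = None,
    abundances: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the browser BED12 track and the catalog TSV tables.

    ``catalog`` is an :class:`~splicecat.exon_catalog.ExonCatalog`;
    ``variants`` an iterable of variant signatures.  ``orfs`` maps variant id
    -> OrfRecord (for thickStart/thickEnd) and ``abundances`` maps variant id
    -> VariantAbundance (for the 0-1000 score).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": prefix.with_suffix(".browser.bed"),
        "classes": prefix.with_suffix(".exon_classes.tsv"),
        "signatures": prefix.with_suffix(".signatures.tsv"),
    }

    with open(paths["bed"], "w") as fh:
        for variant in variants:
            exons = sorted(variant.exons, key=lambda e: e.start)
            thick = None
            if orfs is not None and variant.variant_id in orfs:
                orf = orfs[variant.variant_id]
                if orf is not None and orf.footprint:
                    thick = (orf.footprint[0].start, orf.footprint[-1].end)
            score = 0
            if abundances is not None and variant.variant_id in abundances:
                ab = abundances[variant.variant_id]
                score = int(round(1000 * max(ab.tissue_fractions.values())))
            fh.write(
                bed12_line(
                    exons[0].chrom,
                    exons,
                    variant.variant_id,
                    score=score,
                    strand=exons[0].strand,
                    thick=thick,
                )
                + "\n"
            )

    with open(paths["classes"], "w") as fh:
        fh.write(
            "class_number\trole\tchrom\tstart\tend\tstrand\tdonor\tacceptor\t"
            "annotated\ttss_positions\tn_members\n"
        )
        for cls in catalog.classes:
            rep = cls.representative
            fh.write(
                "\t".join(
                    [
                        str(cls.class_number),
                        cls.role,
                        rep.chrom,
                        str(rep.start),
                        str(rep.end),
                        rep.strand,
                        "" if cls.donor is None else str(cls.donor),
                        "" if cls.acceptor is None else str(cls.acceptor),
                        str(int(cls.annotated)),
                        ",".join(str(p) for p in sorted(cls.tss_positions)),
                        str(len(cls.members)),
                    ]
                )
                + "\n"
            )

    with open(paths["signatures"], "w") as fh:
        fh.write("variant_id\tgene_id\texon_numbers\tn_members\tmembers\n")
        for variant in variants:
            fh.write(
                "\t".join(
                    [
                        variant.variant_id,
                        variant.gene_id,
                        "-".join(str(n) for n in variant.exon_numbers),
                        str(len(variant.member_transcripts)),
                        ",".join(
                            f"{s}:{t}" for s, t in variant.member_transcripts
                        ),
                    ]
                )
                + "\n"
            )
    return paths
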