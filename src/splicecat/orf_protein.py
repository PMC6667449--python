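"""Spliced sequences, longest-ORF translation, domain overlay and product taxonomy.

A transcript's exon sequences are stitched into mRNA with a strand-aware
coordinate map, the longest AUG-initiated reading frame is translated, its
CDS is projected back onto the genome, protein domains are overlaid by
coding-base coverage, and the encoded product is classified as a full
receptor, soluble or membrane-anchored N-terminal fragment, C-terminal
fragment, or other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from splicecat.core_io import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    TranscriptRecord,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
TM_NAMES = tuple(f"TM{i}" for i in range(1, 8))
# domains that can make up an N terminus (upstream of the membrane anchor)
NTERM_DOMAIN_NAMES = frozenset({"SEA", "Ig", "other"})

CLASS_FULL = "FULL_RECEPTOR"
CLASS_SOLUBLE_NTF = "SOLUBLE_NTF"
CLASS_ANCHORED_NTF = "ANCHORED_NTF"
CLASS_CTF = "CTF"
CLASS_OTHER = "OTHER"

DEFAULT_MIN_CODONS = 30
DEFAULT_PRESENCE_THRESHOLD = 0.9


@dataclass
class SplicedTranscript:
    """mRNA sequence plus the bijective transcript<->genome position map."""

    mrna: str
    genomic_positions: list[int]  # genomic position of each mRNA base, 5'->3'
    chrom: str
    strand: str

    def __post_init__(self):
        if len(self.mrna) != len(self.genomic_positions):
            raise ValueError("coordinate map length != mRNA length")

    def __len__(self) -> int:
        return len(self.mrna)


@dataclass
class OrfRecord:
    """Longest open reading frame of a spliced transcript."""

    start: int  # transcript coords, 0-based
    end: int  # half-open; after the stop codon when present
    protein: str
    has_stop: bool
    footprint: list[GenomicInterval]

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")
        if not self.protein.startswith("M"):
            raise ValueError("protein must begin with M")


@dataclass
class DomainContent:
    """Per-domain coding coverage of one variant, in gene 5'->3' order."""

    entries: list[tuple[DomainAnnotation, float, bool]]

    def coverage(self, name: str, instance: int = 1) -> float:
        for dom, cov, _present in self.entries:
            if dom.domain_name == name and dom.instance_index == instance:
                return cov
        raise KeyError(f"no domain {name}/{instance}")

    def is_present(self, name: str, instance: int | None = None) -> bool:
        return any(
            present
            for dom, _cov, present in self.entries
            if dom.domain_name == name
            and (instance is None or dom.instance_index == instance)
        )

    @property
    def present_keys(self) -> list[tuple[str, int]]:
        return [dom.key for dom, _c, present in self.entries if present]

    @property
    def tm_count(self) -> int:
        return sum(1 for name in TM_NAMES if self.is_present(name))


@dataclass
class ProductClassification:
    product_class: str
    tm_count: int
    has_sp: bool
    has_gps: bool
    has_gain: bool


@dataclass
class GeneVariabilityFlags:
    ntf_domain_variability: bool = False
    soluble_ntf: bool = False
    anchored_ntf: bool = False
    ctf: bool = False
    tm7_variability: bool = False
    cterm_variability: bool = False

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.ntf_domain_variability,
            self.soluble_ntf,
            self.anchored_ntf,
            self.ctf,
            self.tm7_variability,
            self.cterm_variability,
        )


@dataclass
class ArchitectureSignature:
    region_name: str
    introns: tuple[tuple[int, int], ...]  # (codon offset within region, phase)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(
    genome: GenomeSequence, transcript: TranscriptRecord
) -> SplicedTranscript:
    """Stitch exon sequences into the 5'->3' mRNA with a coordinate map."""
    mrna_parts: list[str] = []
    positions: list[int] = []
    for exon in transcript.exons:  # already in 5'->3' transcript order
        seq = genome.fetch(exon.chrom, exon.start, exon.end)
        if transcript.strand == "+":
            mrna_parts.append(seq)
            positions.extend(range(exon.start, exon.end))
        else:
            mrna_parts.append(_revcomp(seq))
            positions.extend(range(exon.end - 1, exon.start - 1, -1))
    return SplicedTranscript(
        mrna="".join(mrna_parts),
        genomic_positions=positions,
        chrom=transcript.chrom,
        strand=transcript.strand,
    )


def longest_orf(
    spliced: SplicedTranscript | str, min_codons: int = DEFAULT_MIN_CODONS
) -> OrfRecord | None:
    """Longest AUG-initiated reading frame on the sense strand.

    The ORF ends at the first in-frame stop, or at the transcript end with
    ``has_stop=False`` (kept and marked incomplete).  Ties go to the 5'-most
    start.  Returns None when the longest protein is shorter than
    ``min_codons`` amino acids.
    """
    mrna = spliced if isinstance(spliced, str) else spliced.mrna
    n = len(mrna)
    best: tuple[int, int, bool] | None = None  # (aa_len, start, has_stop)
    pos = mrna.find("ATG")
    while pos != -1:
        aa_len = 0
        has_stop = False
        end = pos
        for i in range(pos, n - 2, 3):
            codon = mrna[i : i + 3]
            if codon in STOP_CODONS:
                has_stop = True
                end = i + 3
                break
            aa_len += 1
            end = i + 3
        if best is None or aa_len > best[0]:
            best = (aa_len, pos, has_stop)
        pos = mrna.find("ATG", pos + 1)
    if best is None or best[0] < min_codons:
        return None
    aa_len, start, has_stop = best
    end = start + 3 * aa_len + (3 if has_stop else 0)
    protein = str(Seq(mrna[start : start + 3 * aa_len]).translate())
    footprint: list[GenomicInterval] = []
    if not isinstance(spliced, str):
        footprint = _positions_to_intervals(
            spliced.genomic_positions[start:end], spliced.chrom, spliced.strand
        )
    return OrfRecord(
        start=start, end=end, protein=protein, has_stop=has_stop, footprint=footprint
    )


def _positions_to_intervals(
    positions: Sequence[int], chrom: str, strand: str
) -> list[GenomicInterval]:
    """Group genomic positions (in transcript order) into sorted intervals."""
    if not positions:
        return []
    runs: list[tuple[int, int]] = []
    run_start = prev = positions[0]
    step = 1 if strand == "+" else -1
    for pos in positions[1:]:
        if pos == prev + step:
            prev = pos
            continue
        runs.append((min(run_start, prev), max(run_start, prev) + 1))
        run_start = prev = pos
    runs.append((min(run_start, prev), max(run_start, prev) + 1))
    return sorted(
        (GenomicInterval(chrom, s, e, strand) for s, e in runs),
        key=lambda i: i.start,
    )


def map_orf_to_genome(
    spliced: SplicedTranscript, orf: OrfRecord
) -> list[GenomicInterval]:
    """Project the ORF's transcript range onto genomic CDS intervals."""
    if not (0 <= orf.start <= orf.end <= len(spliced)):
        raise ValueError("ORF outside transcript bounds")
    return _positions_to_intervals(
        spliced.genomic_positions[orf.start : orf.end], spliced.chrom, spliced.strand
    )


def build_orf(
    genome: GenomeSequence,
    transcript: TranscriptRecord,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> tuple[SplicedTranscript, OrfRecord | None]:
    """Convenience: spliced sequence plus longest ORF with genomic footprint."""
    spliced = spliced_sequence(genome, transcript)
    orf = longest_orf(spliced, min_codons=min_codons)
    return spliced, orf


def _overlap_bp(footprint: Sequence[GenomicInterval], ival: GenomicInterval) -> int:
    total = 0
    for f in footprint:
        if f.chrom != ival.chrom:
            continue
        lo = max(f.start, ival.start)
        hi = min(f.end, ival.end)
        if lo < hi:
            total += hi - lo
    return total


def domain_content(
    footprint: Sequence[GenomicInterval],
    domains: Sequence[DomainAnnotation],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> DomainContent:
    """Coverage of each annotated domain by the CDS footprint.

    coverage = covered domain bp / total domain bp; a domain is present iff
    coverage reaches the threshold.  Domains are reported in gene 5'->3'
    order.
    """
    if domains:
        strand = domains[0].intervals[0].strand
        ordered = sorted(
            domains,
            key=lambda d: d.intervals[0].start,
            reverse=(strand == "-"),
        )
    else:
        ordered = []
    entries = []
    for dom in ordered:
        covered = sum(_overlap_bp(footprint, ival) for ival in dom.intervals)
        coverage = covered / dom.total_bp
        entries.append((dom, coverage, coverage >= presence_threshold))
    return DomainContent(entries=entries)


def classify_product(content: DomainContent) -> ProductClassification:
    """Assign the product taxonomy from domain presence.

    Rules, in order: FULL_RECEPTOR (all seven TMs plus a signal peptide);
    SOLUBLE_NTF (signal peptide, >=1 N-terminal domain, no TM);
    ANCHORED_NTF (signal peptide, >=1 N-terminal domain, 1-6 TMs);
    CTF (no signal peptide, no N-terminal domain upstream of the GAIN
    domain, and GPS content or >=1 TM); otherwise OTHER.
    """
    tm_count = content.tm_count
    has_sp = content.is_present("SP")
    has_gps = content.is_present("GPS")
    has_gain = content.is_present("GAIN")
    upstream_nterm = any(
        present
        for dom, _c, present in content.entries
        if dom.domain_name in NTERM_DOMAIN_NAMES
    )
    # GAIN counts toward an N terminus for the NTF classes
    any_nterm = upstream_nterm or has_gain

    if tm_count == 7 and has_sp:
        product = CLASS_FULL
    elif has_sp and any_nterm and tm_count == 0:
        product = CLASS_SOLUBLE_NTF
    elif has_sp and any_nterm and 1 <= tm_count <= 6:
        product = CLASS_ANCHORED_NTF
    elif not has_sp and not upstream_nterm and (has_gps or tm_count >= 1):
        product = CLASS_CTF
    else:
        product = CLASS_OTHER
    return ProductClassification(
        product_class=product,
        tm_count=tm_count,
        has_sp=has_sp,
        has_gps=has_gps,
        has_gain=has_gain,
    )


def _tm_span(domains: Sequence[DomainAnnotation]) -> GenomicInterval | None:
    tm_intervals = [
        ival
        for dom in domains
        if dom.domain_name in TM_NAMES
        for ival in dom.intervals
    ]
    if not tm_intervals:
        return None
    return GenomicInterval(
        tm_intervals[0].chrom,
        min(i.start for i in tm_intervals),
        max(i.end for i in tm_intervals),
        tm_intervals[0].strand,
    )


def _clip_footprint(
    footprint: Sequence[GenomicInterval], start: int, end: int
) -> tuple[tuple[int, int], ...]:
    clipped = []
    for f in footprint:
        lo, hi = max(f.start, start), min(f.end, end)
        if lo < hi:
            clipped.append((lo, hi))
    return tuple(sorted(clipped))


def gene_variability_flags(
    variant_ids: Sequence[str],
    classifications: Mapping[str, ProductClassification],
    contents: Mapping[str, DomainContent],
    orfs: Mapping[str, OrfRecord | None],
    domains: Sequence[DomainAnnotation],
) -> GeneVariabilityFlags:
    """Per-gene variability flags derived from the abundant variants only.

    - soluble/anchored/ctf: any abundant variant of that product class;
    - ntf_domain_variability: signal-peptide-bearing variants disagree in the
      multiset of present domains upstream of GAIN;
    - tm7_variability: variants whose CDS spans the whole TM1-TM7 genomic
      region disagree inside it;
    - cterm_variability: variants whose CDS reaches the TM7 region disagree
      in the coding sequence 3' of TM7.
    """
    flags = GeneVariabilityFlags()
    classes = [classifications[v].product_class for v in variant_ids]
    flags.soluble_ntf = CLASS_SOLUBLE_NTF in classes
    flags.anchored_ntf = CLASS_ANCHORED_NTF in classes
    flags.ctf = CLASS_CTF in classes

    # N-terminal domain multiset, compared among SP-bearing variants
    nterm_multisets = set()
    for vid in variant_ids:
        if not classifications[vid].has_sp:
            continue
        multiset = tuple(
            sorted(
                key
                for key in contents[vid].present_keys
                if key[0] in NTERM_DOMAIN_NAMES
            )
        )
        nterm_multisets.add(multiset)
    flags.ntf_domain_variability = len(nterm_multisets) > 1

    span = _tm_span(domains)
    if span is not None:
        tm_footprints = set()
        cterm_footprints = set()
        tm7_doms = [d for d in domains if d.domain_name == "TM7"]
        strand = span.strand
        for vid in variant_ids:
            orf = orfs.get(vid)
            if orf is None or not orf.footprint:
                continue
            fp = orf.footprint
            lo, hi = fp[0].start, fp[-1].end
            if lo <= span.start and hi >= span.end:
                tm_footprints.add(_clip_footprint(fp, span.start, span.end))
            if tm7_doms:
                tm7_ival = tm7_doms[0].intervals[-1 if strand == "+" else 0]
                if _overlap_bp(fp, tm7_ival) > 0:
                    if strand == "+":
                        cterm_footprints.add(
                            _clip_footprint(fp, tm7_ival.end, 10**12)
                        )
                    else:
                        cterm_footprints.add(_clip_footprint(fp, 0, tm7_ival.start))
        flags.tm7_variability = len(tm_footprints) > 1
        flags.cterm_variability = len(cterm_footprints) > 1
    return flags


def architecture_signature(
    orf: OrfRecord,
    region: tuple[int, int],
    region_name: str = "GPS+7TM",
) -> ArchitectureSignature:
    """Intron positions inside a region's CDS as (codon offset, phase).

    ``region`` is a genomic (start, end) pair on the reference variant; the
    offsets count coding bases of the region from its 5' end.  Two genes
    share architecture iff their signatures are equal.
    """
    if not orf.footprint:
        raise ValueError("ORF has no genomic footprint")
    strand = orf.footprint[0].strand
    ordered = orf.footprint if strand == "+" else orf.footprint[::-1]
    positions: list[int] = []
    for ival in ordered:
        if strand == "+":
            positions.extend(range(ival.start, ival.end))
        else:
            positions.extend(range(ival.end - 1, ival.start - 1, -1))
    start, end = region
    in_region = [(i, p) for i, p in enumerate(positions) if start <= p < end]
    if not in_region:
        raise ValueError("region not covered by the reference CDS")
    introns = []
    step = 1 if strand == "+" else -1
    offset = 0
    prev_genomic = None
    for _cds_index, genomic in in_region:
        if prev_genomic is not None and genomic != prev_genomic + step:
            introns.append((offset // 3, offset % 3))
        offset += 1
        prev_genomic = genomic
    return ArchitectureSignature(region_name=region_name, introns=tuple(introns))
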