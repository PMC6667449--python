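"""Role-aware exon equivalence classes and numeric transcript signatures.

Exons observed across samples are merged into classes by role: first exons
("start") are identified by their 3' splice donor, last exons ("end") by
their 5' splice acceptor, and internal exons by exact coordinates.  Boundary
semantics are strand-aware: 5'/3' are transcript-relative, so on '-' the
donor of a start exon is its lower genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from splicecat.core_io import GenomicInterval, TranscriptRecord

ROLE_START = "start"
ROLE_INTERNAL = "internal"
ROLE_END = "end"
_ROLE_ORDER = {ROLE_START: 0, ROLE_INTERNAL: 1, ROLE_END: 2}


def exon_role(index: int, n_exons: int) -> str:
    """Role of the exon at transcript position ``index`` (5'->3')."""
    if index == 0:
        return ROLE_START
    if index == n_exons - 1:
        return ROLE_END
    return ROLE_INTERNAL


def donor_of(exon: GenomicInterval) -> int:
    """Genomic coordinate of the exon's 3' boundary (splice donor side)."""
    return exon.end if exon.strand == "+" else exon.start


def acceptor_of(exon: GenomicInterval) -> int:
    """Genomic coordinate of the exon's 5' boundary (splice acceptor side)."""
    return exon.start if exon.strand == "+" else exon.end


def tss_of(exon: GenomicInterval) -> int:
    """Genomic coordinate of the 5'-most transcribed position."""
    return exon.start if exon.strand == "+" else exon.end


@dataclass
class ExonClass:
    class_number: int
    role: str
    representative: GenomicInterval
    members: list[GenomicInterval]
    donor: int | None = None
    acceptor: int | None = None
    tss_positions: set[int] = field(default_factory=set)
    annotated: bool = False
    display_number: int = 0


@dataclass
class ExonCatalog:
    gene_id: str
    classes: list[ExonClass] = field(default_factory=list)
    display_numbering: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        self._start_by_donor: dict[int, ExonClass] = {}
        self._end_by_acceptor: dict[int, ExonClass] = {}
        self._internal_by_coords: dict[tuple[int, int], ExonClass] = {}
        for cls in self.classes:
            self._index(cls)

    def _index(self, cls: ExonClass) -> None:
        if cls.role == ROLE_START:
            self._start_by_donor[cls.donor] = cls
        elif cls.role == ROLE_END:
            self._end_by_acceptor[cls.acceptor] = cls
        else:
            rep = cls.representative
            self._internal_by_coords[(rep.start, rep.end)] = cls

    def lookup(self, exon: GenomicInterval, role: str) -> ExonClass:
        """Class of an observed exon occurrence; KeyError if absent."""
        if role == ROLE_START:
            return self._start_by_donor[donor_of(exon)]
        if role == ROLE_END:
            return self._end_by_acceptor[acceptor_of(exon)]
        return self._internal_by_coords[(exon.start, exon.end)]

    @property
    def start_classes(self) -> list[ExonClass]:
        return [c for c in self.classes if c.role == ROLE_START]

    @property
    def end_classes(self) -> list[ExonClass]:
        return [c for c in self.classes if c.role == ROLE_END]

    @property
    def internal_classes(self) -> list[ExonClass]:
        return [c for c in self.classes if c.role == ROLE_INTERNAL]


@dataclass
class VariantSignature:
    """A transcript variant as an ordered sequence of exon-class numbers."""

    gene_id: str
    exon_numbers: tuple[int, ...]
    start_class: int
    end_class: int
    member_transcripts: list[tuple[str, str]]
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.member_transcripts:
            raise ValueError("signature needs >=1 member transcript")
        if self.exon_numbers[0] != self.start_class:
            raise ValueError("first exon number must equal start_class")
        if self.exon_numbers[-1] != self.end_class:
            raise ValueError("last exon number must equal end_class")

    @property
    def variant_id(self) -> str:
        return f"{self.gene_id}:" + "-".join(str(n) for n in self.exon_numbers)


@dataclass
class NoveltyReport:
    counts: dict[str, tuple[int, int, int]]  # role -> (total, annotated, novel)

    def total(self, role: str) -> int:
        return self.counts[role][0]

    def annotated(self, role: str) -> int:
        return self.counts[role][1]

    def novel(self, role: str) -> int:
        return self.counts[role][2]


def _occurrences(
    transcripts: Iterable[TranscriptRecord],
) -> list[tuple[GenomicInterval, str]]:
    occ = []
    for tx in transcripts:
        n = len(tx.exons)
        if n == 1:
            # single-exon transcripts have a TSS and a 3' end but no junction
            occ.append((tx.exons[0], ROLE_START))
            occ.append((tx.exons[0], ROLE_END))
        else:
            for i, exon in enumerate(tx.exons):
                occ.append((exon, exon_role(i, n)))
    return occ


def build_exon_catalog(
    transcripts: Sequence[TranscriptRecord], gene_id: str
) -> ExonCatalog:
    """Merge exon occurrences of one gene into role-aware classes.

    Start classes are keyed by donor, end classes by acceptor, internal
    classes by exact coordinates.  Classes are numbered consecutively by the
    genomic start of their representative (union extent), ties broken by end,
    then by role order start < internal < end.
    """
    transcripts = [t for t in transcripts if t.gene_id == gene_id or gene_id is None]
    if not transcripts:
        return ExonCatalog(gene_id=gene_id)
    strands = {t.strand for t in transcripts}
    chroms = {t.chrom for t in transcripts}
    if len(strands) > 1 or len(chroms) > 1:
        raise ValueError(f"{gene_id}: transcripts on mixed chroms/strands")

    start_groups: dict[int, list[GenomicInterval]] = {}
    end_groups: dict[int, list[GenomicInterval]] = {}
    internal_groups: dict[tuple[int, int], list[GenomicInterval]] = {}
    for exon, role in _occurrences(transcripts):
        if role == ROLE_START:
            start_groups.setdefault(donor_of(exon), []).append(exon)
        elif role == ROLE_END:
            end_groups.setdefault(acceptor_of(exon), []).append(exon)
        else:
            internal_groups.setdefault((exon.start, exon.end), []).append(exon)

    classes: list[ExonClass] = []
    for donor, members in start_groups.items():
        rep = GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
            members[0].strand,
        )
        classes.append(
            ExonClass(
                class_number=0,
                role=ROLE_START,
                representative=rep,
                members=list(members),
                donor=donor,
                tss_positions={tss_of(m) for m in members},
            )
        )
    for acceptor, members in end_groups.items():
        rep = GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
            members[0].strand,
        )
        classes.append(
            ExonClass(
                class_number=0,
                role=ROLE_END,
                representative=rep,
                members=list(members),
                acceptor=acceptor,
            )
        )
    for (s, e), members in internal_groups.items():
        rep = members[0]
        classes.append(
            ExonClass(
                class_number=0,
                role=ROLE_INTERNAL,
                representative=rep,
                members=list(members),
                donor=donor_of(rep),
                acceptor=acceptor_of(rep),
            )
        )

    classes.sort(
        key=lambda c: (
            c.representative.start,
            c.representative.end,
            _ROLE_ORDER[c.role],
        )
    )
    for number, cls in enumerate(classes, start=1):
        cls.class_number = number

    # one display number per distinct (maximal) exon extent, shared by roles
    extents = sorted({(c.representative.start, c.representative.end) for c in classes})
    display = {extent: i for i, extent in enumerate(extents, start=1)}
    for cls in classes:
        cls.display_number = display[(cls.representative.start, cls.representative.end)]

    return ExonCatalog(gene_id=gene_id, classes=classes, display_numbering=display)


def encode_transcript(
    catalog: ExonCatalog, transcript: TranscriptRecord
) -> VariantSignature:
    """Encode one transcript as its ordered sequence of exon-class numbers."""
    n = len(transcript.exons)
    if n == 1:
        exon = transcript.exons[0]
        start_cls = catalog.lookup(exon, ROLE_START)
        end_cls = catalog.lookup(exon, ROLE_END)
        return VariantSignature(
            gene_id=catalog.gene_id,
            exon_numbers=(start_cls.class_number,),
            start_class=start_cls.class_number,
            end_class=start_cls.class_number,
            member_transcripts=[(transcript.sample_id, transcript.transcript_id)],
            exons=list(transcript.exons),
        )
    numbers = []
    for i, exon in enumerate(transcript.exons):
        numbers.append(catalog.lookup(exon, exon_role(i, n)).class_number)
    return VariantSignature(
        gene_id=catalog.gene_id,
        exon_numbers=tuple(numbers),
        start_class=numbers[0],
        end_class=numbers[-1],
        member_transcripts=[(transcript.sample_id, transcript.transcript_id)],
        exons=list(transcript.exons),
    )


def encode_transcripts(
    catalog: ExonCatalog, transcripts: Sequence[TranscriptRecord]
) -> list[VariantSignature]:
    """Encode all transcripts; identical signatures merge, pooling members."""
    merged: dict[tuple[int, ...], VariantSignature] = {}
    for tx in transcripts:
        sig = encode_transcript(catalog, tx)
        if sig.exon_numbers in merged:
            merged[sig.exon_numbers].member_transcripts.extend(
                sig.member_transcripts
            )
        else:
            merged[sig.exon_numbers] = sig
    return sorted(merged.values(), key=lambda s: s.exon_numbers)


def count_tss(catalog: ExonCatalog) -> tuple[int, int]:
    """(number of distinct TSS positions, number of start-exon classes)."""
    tss: set[int] = set()
    for cls in catalog.start_classes:
        tss |= cls.tss_positions
    return len(tss), len(catalog.start_classes)


def annotate_novelty(
    catalog: ExonCatalog, reference_exons: Sequence[GenomicInterval]
) -> NoveltyReport:
    """Flag classes matching a reference annotation and count novel ones.

    A start class is annotated iff some reference exon shares its donor; an
    end class iff some shares its acceptor; an internal class iff a reference
    exon matches both boundaries (exact coordinates).
    """
    ref_donors = {donor_of(e) for e in reference_exons}
    ref_acceptors = {acceptor_of(e) for e in reference_exons}
    ref_coords = {(e.start, e.end) for e in reference_exons}

    counts = {}
    for role, classes in (
        (ROLE_START, catalog.start_classes),
        (ROLE_END, catalog.end_classes),
        (ROLE_INTERNAL, catalog.internal_classes),
    ):
        annotated = 0
        for cls in classes:
            if role == ROLE_START:
                cls.annotated = cls.donor in ref_donors
            elif role == ROLE_END:
                cls.annotated = cls.acceptor in ref_acceptors
            else:
                rep = cls.representative
                cls.annotated = (rep.start, rep.end) in ref_coords
            annotated += cls.annotated
        counts[role] = (len(classes), annotated, len(classes) - annotated)
    return NoveltyReport(counts=counts)


@dataclass
class CondensedVariant:
    """A group of raw signatures sharing start/end classes and ORF footprint."""

    condensed_id: str
    gene_id: str
    representative: VariantSignature
    member_signatures: list[VariantSignature]
    abundance: float | None = None

    @property
    def member_variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.member_signatures]


def condense_variants(
    signatures: Sequence[VariantSignature],
    orfs: Mapping[str, object],
    abundances: Mapping[str, float] | None = None,
) -> list[CondensedVariant]:
    """Merge raw variants with identical start/end classes and ORF footprint.

    The result is a partition of the input; condensed abundance is the sum of
    member abundances.  Every signature must have an entry in ``orfs`` (value
    may be None for non-coding variants).
    """
    groups: dict[tuple, list[VariantSignature]] = {}
    for sig in signatures:
        if sig.variant_id not in orfs:
            raise KeyError(f"no ORF record for {sig.variant_id}")
        orf = orfs[sig.variant_id]
        footprint = (
            tuple((i.start, i.end) for i in orf.footprint) if orf is not None else None
        )
        key = (sig.start_class, sig.end_class, footprint)
        groups.setdefault(key, []).append(sig)

    condensed = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], str(k[2]))):
        members = sorted(groups[key], key=lambda s: s.exon_numbers)
        rep = max(members, key=lambda s: len(s.member_transcripts))
        abundance = None
        if abundances is not None:
            abundance = sum(abundances.get(s.variant_id, 0.0) for s in members)
        condensed.append(
            CondensedVariant(
                condensed_id=rep.variant_id,
                gene_id=rep.gene_id,
                representative=rep,
                member_signatures=members,
                abundance=abundance,
            )
        )
    return condensed
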