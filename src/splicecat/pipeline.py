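"""End-to-end per-gene orchestration shared by the CLI, tests and reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from splicecat import core_io, exon_catalog, orf_protein, quantification, reporting
from splicecat.core_io import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
)


@dataclass
class Thresholds:
    min_fraction: float = quantification.DEFAULT_MIN_FRACTION
    fpkm_cutoff: float = quantification.DEFAULT_FPKM_CUTOFF
    min_genes: int = quantification.DEFAULT_MIN_GENES
    min_codons: int = orf_protein.DEFAULT_MIN_CODONS
    presence_threshold: float = orf_protein.DEFAULT_PRESENCE_THRESHOLD
    percentile: float = 1.0
    end_tolerance: int = 10
    abundance_unit: str = "fpkm"


@dataclass
class GeneResult:
    gene_id: str
    catalog: exon_catalog.ExonCatalog
    signatures: list[exon_catalog.VariantSignature]
    quant: quantification.QuantMatrix
    abundances: list[quantification.VariantAbundance]
    abundant_ids: list[str]
    orfs: dict[str, orf_protein.OrfRecord | None]
    contents: dict[str, orf_protein.DomainContent]
    classifications: dict[str, orf_protein.ProductClassification]
    flags: orf_protein.GeneVariabilityFlags | None
    novelty: exon_catalog.NoveltyReport | None
    condensed: list[exon_catalog.CondensedVariant] = field(default_factory=list)
    row: reporting.GeneSummaryRow | None = None


def load_samples(
    gtf_paths: Sequence[str | Path],
) -> tuple[list[TranscriptRecord], list[SampleMeta]]:
    """Parse all per-sample GTFs (order never affects downstream results)."""
    transcripts: list[TranscriptRecord] = []
    metas: list[SampleMeta] = []
    for path in gtf_paths:
        records, meta = core_io.parse_gtf(path)
        transcripts.extend(records)
        metas.append(meta)
    return transcripts, metas


def run_gene(
    transcripts: Sequence[TranscriptRecord],
    samples: Sequence[SampleMeta],
    gene_id: str,
    genome: GenomeSequence | None = None,
    domains: Sequence[DomainAnnotation] = (),
    reference_exons: Sequence[GenomicInterval] = (),
    thresholds: Thresholds | None = None,
) -> GeneResult:
    """Catalog, quantify, translate and classify one gene's transcripts."""
    th = thresholds or Thresholds()
    gene_transcripts = [t for t in transcripts if t.gene_id == gene_id]
    catalog = exon_catalog.build_exon_catalog(gene_transcripts, gene_id)
    signatures = exon_catalog.encode_transcripts(catalog, gene_transcripts)

    quant = quantification.build_quant_matrix(
        signatures, gene_transcripts, samples, unit=th.abundance_unit
    )
    abundances = quantification.compute_variant_fractions(quant)
    abundant = quantification.filter_abundant(abundances, threshold=th.min_fraction)
    abundant_ids = [a.variant_id for a in abundant]

    orfs: dict[str, orf_protein.OrfRecord | None] = {}
    contents: dict[str, orf_protein.DomainContent] = {}
    classifications: dict[str, orf_protein.ProductClassification] = {}
    flags = None
    if genome is not None:
        by_id = {}
        for sig in signatures:
            sample_id, transcript_id = sig.member_transcripts[0]
            member = next(
                t
                for t in gene_transcripts
                if t.sample_id == sample_id and t.transcript_id == transcript_id
            )
            by_id[sig.variant_id] = member
        for sig in signatures:
            spliced, orf = orf_protein.build_orf(
                genome, by_id[sig.variant_id], min_codons=th.min_codons
            )
            orfs[sig.variant_id] = orf
            footprint = orf.footprint if orf is not None else []
            content = orf_protein.domain_content(
                footprint, list(domains), presence_threshold=th.presence_threshold
            )
            contents[sig.variant_id] = content
            classifications[sig.variant_id] = orf_protein.classify_product(content)
        if abundant_ids and domains:
            flags = orf_protein.gene_variability_flags(
                abundant_ids, classifications, contents, orfs, list(domains)
            )

    novelty = None
    if reference_exons:
        novelty = exon_catalog.annotate_novelty(catalog, list(reference_exons))
    else:
        novelty = exon_catalog.annotate_novelty(catalog, [])

    condensed = []
    if orfs:
        totals = {
            a.variant_id: sum(a.tissue_fractions.values()) for a in abundances
        }
        condensed = exon_catalog.condense_variants(signatures, orfs, totals)

    row = reporting.gene_summary_row(catalog, signatures, abundances, novelty)
    return GeneResult(
        gene_id=gene_id,
        catalog=catalog,
        signatures=signatures,
        quant=quant,
        abundances=abundances,
        abundant_ids=abundant_ids,
        orfs=orfs,
        contents=contents,
        classifications=classifications,
        flags=flags,
        novelty=novelty,
        condensed=condensed,
        row=row,
    )


def parse_reference_exons_tsv(path: str | Path) -> list[GenomicInterval]:
    """Read a reference exon table (chrom, start, end, strand)."""
    exons = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            exons.append(
                GenomicInterval(
                    f[idx["chrom"]],
                    int(f[idx["start"]]),
                    int(f[idx["end"]]),
                    f[idx["strand"]],
                )
            )
    return exons
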