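"""Ground-truthed synthetic loci, variants, expression, coverage and long reads.

Every generator is a pure function of (spec, seed).  Loci are built from a
codon alphabet that cannot form an ATG or an in-frame stop anywhere except
at the planted positions, so the longest-ORF machinery provably recovers
the planted reading frames and product classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from splicecat.core_io import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    SampleMeta,
    TranscriptRecord,
    write_domains_tsv,
    write_fasta,
    write_gtf,
)
from splicecat.quantification import QuantMatrix

ARCHETYPE_LATROPHILIN = "latrophilin-like"
ARCHETYPE_ADGRF = "adgrf-like"
ARCHETYPE_SPLIT = "split-ntf-ctf"
ARCHETYPES = (ARCHETYPE_LATROPHILIN, ARCHETYPE_ADGRF, ARCHETYPE_SPLIT)

CLASS_FULL = "FULL_RECEPTOR"
CLASS_SOLUBLE_NTF = "SOLUBLE_NTF"
CLASS_ANCHORED_NTF = "ANCHORED_NTF"
CLASS_CTF = "CTF"

# codons that are not stops/ATG, never start with TG and never end with AT:
# concatenated in frame they cannot form ATG at any offset, nor in-frame stops
_STOPS = {"TAA", "TAG", "TGA"}
SAFE_CODONS = tuple(
    codon
    for codon in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if codon not in _STOPS
    and codon != "ATG"
    and not codon.startswith("TG")
    and not codon.endswith("AT")
)

# protein layout in codon units: (name, instance, start codon, end codon)
DOMAIN_CODONS = (
    ("SP", 1, 0, 20),
    ("SEA", 1, 20, 60),
    ("Ig", 1, 60, 90),
    ("Ig", 2, 90, 120),
    ("GAIN", 1, 120, 165),
    ("GPS", 1, 165, 180),
    ("TM1", 1, 180, 200),
    ("TM2", 1, 200, 220),
    ("TM3", 1, 220, 240),
    ("TM4", 1, 240, 260),
    ("TM5", 1, 260, 280),
    ("TM6", 1, 280, 300),
    ("TM7", 1, 300, 320),
)
N_CODONS = 360  # SP..TM7 plus a 40-codon C-terminal tail

# codon indices at which a new coding exon begins
_SPLITS = {
    ARCHETYPE_LATROPHILIN: (20, 60, 90, 120, 165, 180, 200, 220, 240, 260, 280, 300, 320),
    ARCHETYPE_SPLIT: (20, 60, 90, 120, 165, 180, 200, 220, 240, 260, 280, 300, 320),
    # GPS and most of the 7TM inside one exon
    ARCHETYPE_ADGRF: (20, 60, 90, 120, 165, 325),
}


@dataclass(frozen=True)
class SyntheticLocusSpec:
    gene_id: str = "GENE1"
    contig: str = "chrSim"
    archetype: str = ARCHETYPE_LATROPHILIN
    promoter_count: int = 3
    utr5_length: int = 60
    utr3_length: int = 80
    utr_exon_length: int = 100
    intron_length_range: tuple[int, int] = (300, 1200)
    flank: int = 800

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.promoter_count < 1:
            raise ValueError("need >=1 promoter")


@dataclass
class SyntheticLocus:
    spec: SyntheticLocusSpec
    seed: int
    genome: GenomeSequence
    exons: dict[str, GenomicInterval]
    exon_seqs: dict[str, str]
    reference_chain: list[str]  # coding exon names, genomic order
    cds_blocks: list[tuple[int, int, int]]  # (cds nt start, cds nt end, genomic start)
    domains: list[DomainAnnotation]

    @property
    def gene_id(self) -> str:
        return self.spec.gene_id

    @property
    def contig(self) -> str:
        return self.spec.contig

    def cds_to_genomic(self, cds_pos: int) -> int:
        for start, end, genomic_start in self.cds_blocks:
            if start <= cds_pos < end:
                return genomic_start + (cds_pos - start)
        raise ValueError(f"CDS position {cds_pos} out of range")

    def promoter_prefix(self, promoter_index: int) -> list[str]:
        """Exon names prepended for the given promoter (0 = primary)."""
        if promoter_index == 0:
            return []
        name = f"utr_p{promoter_index + 1}"
        if name not in self.exons:
            raise ValueError(f"promoter {promoter_index} not available")
        return [name]


@dataclass
class PlantedVariant:
    name: str
    product_class: str
    exon_names: list[str]
    exons: list[GenomicInterval]
    promoter_index: int = 0

    def to_transcript(
        self, sample_id: str, fpkm: float, gene_id: str
    ) -> TranscriptRecord:
        return TranscriptRecord(
            transcript_id=self.name,
            gene_id=gene_id,
            sample_id=sample_id,
            exons=list(self.exons),  # '+' strand: genomic order is 5'->3'
            fpkm=fpkm,
            coverage=fpkm,
        )


def _random_utr(rng: np.random.Generator, length: int) -> str:
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[: i + 2] + "C" + seq[i + 3 :]
    # C at both ends: junction-spanning ATG/stop codons become impossible
    return "C" + seq[1:-1] + "C" if length >= 2 else "C" * length


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(SAFE_CODONS), size=n)
    return "".join(SAFE_CODONS[i] for i in idx)


def simulate_locus(spec: SyntheticLocusSpec, seed: int) -> SyntheticLocus:
    """Build a genome with planted exons, a valid full-length ORF and domains.

    The locus carries, besides the coding exon chain: alternative promoter
    UTR exons, an alternative 3' end exon after the GAIN-encoding exon (for
    soluble-NTF truncations), an internal-promoter start exon before the
    GPS-encoding exon (for CTF transcripts), an alternative end exon after
    TM1 (anchored NTF; multi-exon archetypes only), an in-frame insertion
    exon between TM5 and TM6 (ICL3 variability), and an alternative
    C-terminal coding exon.
    """
    rng = np.random.default_rng(seed)
    splits = _SPLITS[spec.archetype]
    multi_tm_exons = spec.archetype != ARCHETYPE_ADGRF

    # CDS with planted ATGs at codon 0 (full product) and codon 165 (CTF)
    codons = [_random_codons(rng, 1) for _ in range(N_CODONS)]
    codons[0] = "ATG"
    codons[165] = "ATG"
    cds = "".join(codons)

    ranges = list(zip((0,) + splits, splits + (N_CODONS,)))
    exon_specs: list[tuple[str, str, tuple[int, int] | None]] = []
    for k in range(1, spec.promoter_count):
        exon_specs.append((f"utr_p{k + 1}", _random_utr(rng, spec.utr_exon_length), None))
    for i, (a, b) in enumerate(ranges):
        seq = cds[3 * a : 3 * b]
        name = f"cds{a}"
        if i == 0:
            seq = _random_utr(rng, spec.utr5_length) + seq
        if i == len(ranges) - 1:
            seq = seq + "TAA" + _random_utr(rng, spec.utr3_length)
        if a == 165:  # exon carrying the GPS: specials go just upstream
            exon_specs.append(("sol_end", "TAA" + _random_utr(rng, spec.utr3_length), None))
            exon_specs.append(("ctf_start", _random_utr(rng, spec.utr_exon_length), None))
        if multi_tm_exons and a == 200:
            exon_specs.append(("anch_end", "TAA" + _random_utr(rng, spec.utr3_length), None))
        if multi_tm_exons and a == 280:
            exon_specs.append(("icl3_ins", _random_codons(rng, 10), None))
        exon_specs.append((name, seq, (a, b)))
    exon_specs.append(
        ("alt_end", _random_codons(rng, 20) + "TAA" + _random_utr(rng, spec.utr3_length), None)
    )

    lo, hi = spec.intron_length_range
    cursor = spec.flank
    placements: dict[str, tuple[int, str, tuple[int, int] | None]] = {}
    for i, (name, seq, cds_range) in enumerate(exon_specs):
        if i > 0:
            cursor += int(rng.integers(lo, hi))
        placements[name] = (cursor, seq, cds_range)
        cursor += len(seq)
    total = cursor + spec.flank

    bases = "ACGT"
    genome_list = list(
        "".join(bases[i] for i in rng.integers(0, 4, size=total))
    )
    exons: dict[str, GenomicInterval] = {}
    exon_seqs: dict[str, str] = {}
    cds_blocks: list[tuple[int, int, int]] = []
    for name, (start, seq, cds_range) in placements.items():
        genome_list[start : start + len(seq)] = list(seq)
        exons[name] = GenomicInterval(spec.contig, start, start + len(seq), "+")
        exon_seqs[name] = seq
        if cds_range is not None:
            a, b = cds_range
            offset = spec.utr5_length if a == 0 else 0
            cds_blocks.append((3 * a, 3 * b, start + offset))
    genome = GenomeSequence({spec.contig: "".join(genome_list)})

    locus = SyntheticLocus(
        spec=spec,
        seed=seed,
        genome=genome,
        exons=exons,
        exon_seqs=exon_seqs,
        reference_chain=[f"cds{a}" for a, _b in ranges],
        cds_blocks=sorted(cds_blocks),
        domains=[],
    )
    locus.domains = _project_domains(locus)
    return locus


def _project_domains(locus: SyntheticLocus) -> list[DomainAnnotation]:
    domains = []
    for name, instance, a, b in DOMAIN_CODONS:
        nt_start, nt_end = 3 * a, 3 * b
        intervals = []
        for block_start, block_end, genomic_start in locus.cds_blocks:
            lo = max(nt_start, block_start)
            hi = min(nt_end, block_end)
            if lo < hi:
                intervals.append(
                    GenomicInterval(
                        locus.contig,
                        genomic_start + (lo - block_start),
                        genomic_start + (hi - block_start),
                        "+",
                    )
                )
        domains.append(
            DomainAnnotation(
                gene_id=locus.gene_id,
                domain_name=name,
                instance_index=instance,
                intervals=intervals,
            )
        )
    return domains


def _chain(locus: SyntheticLocus, names: Sequence[str]) -> list[GenomicInterval]:
    return [locus.exons[n] for n in names]


def _allocate(class_mix: Mapping[str, float], n_variants: int) -> dict[str, int]:
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    raw = {c: p * n_variants for c, p in class_mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = n_variants - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1
    return counts


def simulate_variants(
    locus: SyntheticLocus,
    class_mix: Mapping[str, float],
    n_variants: int,
    seed: int = 0,
    include_icl3_insertion: bool = False,
    include_alt_cterm: bool = False,
    include_ig2_skip: bool = False,
) -> list[PlantedVariant]:
    """Realize the requested product-class mix as concrete exon chains.

    Variants within a class differ by promoter choice.  Optional extras
    plant an in-frame ICL3 insertion and an alternative C-terminal coding
    exon (both classify FULL_RECEPTOR but flag 7TM / C-terminal
    variability downstream).
    """
    chain = locus.reference_chain
    gain_index = chain.index("cds120")
    gps_index = gain_index + 1
    adgrf = locus.spec.archetype == ARCHETYPE_ADGRF
    n_promoters = locus.spec.promoter_count

    def builders(cls: str):
        if cls == CLASS_FULL:
            return [
                locus.promoter_prefix(p) + chain for p in range(n_promoters)
            ]
        if cls == CLASS_SOLUBLE_NTF:
            body = chain[: gain_index + 1] + ["sol_end"]
            return [locus.promoter_prefix(p) + body for p in range(n_promoters)]
        if cls == CLASS_ANCHORED_NTF:
            if adgrf:
                raise ValueError(
                    "ANCHORED_NTF unachievable: TM1 shares one exon with the "
                    "rest of the 7TM in this archetype"
                )
            tm1_index = chain.index("cds180")
            body = chain[: tm1_index + 1] + ["anch_end"]
            return [locus.promoter_prefix(p) + body for p in range(n_promoters)]
        if cls == CLASS_CTF:
            return [["ctf_start"] + chain[gps_index:]]
        raise ValueError(f"unknown product class {cls!r}")

    counts = _allocate(class_mix, n_variants)
    variants: list[PlantedVariant] = []
    for cls in sorted(counts):
        available = builders(cls)
        if counts[cls] > len(available):
            raise ValueError(
                f"{cls}: requested {counts[cls]} variants, only "
                f"{len(available)} distinct chains achievable"
            )
        for i in range(counts[cls]):
            names = available[i]
            variants.append(
                PlantedVariant(
                    name=f"{cls}_{i + 1}",
                    product_class=cls,
                    exon_names=list(names),
                    exons=_chain(locus, names),
                    promoter_index=i if cls == CLASS_FULL else 0,
                )
            )

    if include_icl3_insertion:
        if adgrf:
            raise ValueError("ICL3 insertion unachievable in this archetype")
        tm6_index = chain.index("cds280")
        names = chain[:tm6_index] + ["icl3_ins"] + chain[tm6_index:]
        variants.append(
            PlantedVariant(
                name="FULL_icl3",
                product_class=CLASS_FULL,
                exon_names=names,
                exons=_chain(locus, names),
            )
        )
    if include_alt_cterm:
        names = chain[:-1] + ["alt_end"]
        variants.append(
            PlantedVariant(
                name="FULL_altC",
                product_class=CLASS_FULL,
                exon_names=names,
                exons=_chain(locus, names),
            )
        )
    if include_ig2_skip:
        # in-frame skip of the Ig2-encoding exon: changes the N-terminal
        # domain multiset while keeping a full receptor product
        names = [n for n in chain if n != "cds90"]
        variants.append(
            PlantedVariant(
                name="FULL_igskip",
                product_class=CLASS_FULL,
                exon_names=names,
                exons=_chain(locus, names),
            )
        )
    return variants


@dataclass
class SimulatedExpression:
    samples: list[SampleMeta]
    transcripts: dict[str, list[TranscriptRecord]]  # sample_id -> records
    quant: QuantMatrix
    truth: dict[str, dict[str, float]]  # tissue -> variant name -> fraction
    gtf_paths: dict[str, Path] = field(default_factory=dict)


def simulate_expression(
    locus: SyntheticLocus,
    variants: Sequence[PlantedVariant],
    tissues: Sequence[str],
    replicates: int,
    dirichlet_alpha: float,
    seed: int = 0,
    noise_sigma: float = 0.2,
    gene_fpkm: float = 60.0,
    truth_fractions: Mapping[str, Sequence[float]] | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedExpression:
    """Tissue-level Dirichlet fractions, logistic-normal replicate jitter,
    written as StringTie-style GTFs with FPKM attributes when ``out_dir`` is
    given."""
    if not tissues or replicates < 1:
        raise ValueError("need >=1 tissue and >=1 replicate")
    rng = np.random.default_rng(seed)
    k = len(variants)
    names = [v.name for v in variants]

    truth: dict[str, np.ndarray] = {}
    for tissue in tissues:
        if truth_fractions is not None:
            vec = np.asarray(truth_fractions[tissue], dtype=float)
            vec = vec / vec.sum()
        else:
            vec = rng.dirichlet(np.full(k, dirichlet_alpha))
        truth[tissue] = vec

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    transcripts: dict[str, list[TranscriptRecord]] = {}
    for tissue in tissues:
        for rep in range(1, replicates + 1):
            sample_id = f"{tissue}_rep{rep}"
            samples.append(SampleMeta(sample_id, tissue, rep))
            logits = np.log(truth[tissue]) + rng.normal(0.0, noise_sigma, size=k)
            fractions = np.exp(logits - logits.max())
            fractions /= fractions.sum()
            columns[sample_id] = gene_fpkm * fractions
            transcripts[sample_id] = [
                v.to_transcript(sample_id, float(columns[sample_id][i]), locus.gene_id)
                for i, v in enumerate(variants)
            ]

    quant = QuantMatrix(
        values=pd.DataFrame(columns, index=names),
        samples=samples,
        gene_fpkm={s.sample_id: gene_fpkm for s in samples},
    )
    result = SimulatedExpression(
        samples=samples,
        transcripts=transcripts,
        quant=quant,
        truth={t: dict(zip(names, map(float, truth[t]))) for t in tissues},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, records in transcripts.items():
            path = out_dir / f"{sample_id}.gtf"
            write_gtf(records, path)
            result.gtf_paths[sample_id] = path
    return result


def ntf_ctf_positions(locus: SyntheticLocus) -> tuple[list[int], list[int]]:
    """Exonic CDS positions of the reference chain split at the GPS start."""
    gps = next(d for d in locus.domains if d.domain_name == "GPS")
    gps_start = gps.intervals[0].start
    ntf, ctf = [], []
    for block_start, block_end, genomic_start in locus.cds_blocks:
        for offset in range(block_end - block_start):
            pos = genomic_start + offset
            (ntf if pos < gps_start else ctf).append(pos)
    return ntf, ctf


def simulate_reads_and_coverage(
    locus: SyntheticLocus,
    variants: Sequence[PlantedVariant],
    n_reads: int = 30,
    truncated_fraction: float = 1 / 3,
    fold: float = 2.0,
    lam: float = 20.0,
    seed: int = 0,
):
    """Poisson coverage with an NTF/CTF mean ratio of ``fold`` plus long reads
    (full-length chains and 3'-truncated contiguous sub-chains).

    Returns (reads, depth, ntf_positions, ctf_positions).
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    from splicecat.core_io import ReadChain

    rng = np.random.default_rng(seed)
    ntf_pos, ctf_pos = ntf_ctf_positions(locus)
    depth: dict[int, float] = {}
    for pos, value in zip(ntf_pos, rng.poisson(lam, size=len(ntf_pos))):
        depth[pos] = float(value)
    for pos, value in zip(ctf_pos, rng.poisson(fold * lam, size=len(ctf_pos))):
        depth[pos] = float(value)

    n_truncated = int(round(n_reads * truncated_fraction))
    reads = []
    for i in range(n_reads):
        variant = variants[i % len(variants)]
        exons = sorted(variant.exons, key=lambda e: e.start)
        if i < n_reads - n_truncated or len(exons) < 2:
            blocks = exons
            label = "full"
        else:
            keep = int(rng.integers(1, len(exons)))
            blocks = exons[:keep]  # '+' strand: genomic prefix = 5' portion
            label = "trunc"
        reads.append(
            ReadChain(read_id=f"read{i:03d}_{label}_{variant.name}", blocks=list(blocks))
        )
    return reads, depth, ntf_pos, ctf_pos


# ---------------------------------------------------------------------------
# Strand mirroring (for symmetry tests)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def mirror_genome(genome: GenomeSequence, contig: str) -> GenomeSequence:
    seq = genome.fetch(contig, 0, genome.length(contig))
    return GenomeSequence({contig: seq.translate(_COMPLEMENT)[::-1]})


def mirror_interval(ival: GenomicInterval, length: int) -> GenomicInterval:
    return GenomicInterval(
        ival.chrom,
        length - ival.end,
        length - ival.start,
        "-" if ival.strand == "+" else "+",
    )


def mirror_transcript(tx: TranscriptRecord, length: int) -> TranscriptRecord:
    mirrored = [mirror_interval(e, length) for e in tx.exons]
    return TranscriptRecord(
        transcript_id=tx.transcript_id,
        gene_id=tx.gene_id,
        sample_id=tx.sample_id,
        exons=mirrored,
        fpkm=tx.fpkm,
        coverage=tx.coverage,
    )


def mirror_domain(dom: DomainAnnotation, length: int) -> DomainAnnotation:
    return DomainAnnotation(
        gene_id=dom.gene_id,
        domain_name=dom.domain_name,
        instance_index=dom.instance_index,
        intervals=[mirror_interval(i, length) for i in dom.intervals],
    )


def write_locus_bundle(
    locus: SyntheticLocus,
    variants: Sequence[PlantedVariant],
    expression: SimulatedExpression,
    out_dir: str | Path,
    reads=None,
    depth: Mapping[int, float] | None = None,
) -> dict[str, Path]:
    """Emit a self-contained directory: FASTA, GTFs, domains TSV, truth TSV,
    optional BED12 reads and bedGraph coverage."""
    from splicecat.core_io import write_bed12, write_bedgraph

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = out_dir / "genome.fa"
    seq = locus.genome.fetch(locus.contig, 0, locus.genome.length(locus.contig))
    write_fasta({locus.contig: seq}, paths["fasta"])

    paths["domains"] = out_dir / "domains.tsv"
    write_domains_tsv(locus.domains, paths["domains"])

    paths["reference_exons"] = out_dir / "reference_exons.tsv"
    with open(paths["reference_exons"], "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\n")
        for name in locus.reference_chain:
            e = locus.exons[name]
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\n")

    paths["truth"] = out_dir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("variant\tproduct_class\texons\t" + "\t".join(expression.truth) + "\n")
        for v in variants:
            fractions = "\t".join(
                f"{expression.truth[t][v.name]:.6f}" for t in expression.truth
            )
            fh.write(
                f"{v.name}\t{v.product_class}\t{','.join(v.exon_names)}\t{fractions}\n"
            )

    for sample_id, records in expression.transcripts.items():
        path = out_dir / f"{sample_id}.gtf"
        write_gtf(records, path)
        paths[f"gtf:{sample_id}"] = path

    if reads is not None:
        paths["reads"] = out_dir / "longreads.bed"
        write_bed12(reads, paths["reads"])
    if depth is not None:
        paths["coverage"] = out_dir / "coverage.bedgraph"
        write_bedgraph({locus.contig: depth}, paths["coverage"])
    return paths
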