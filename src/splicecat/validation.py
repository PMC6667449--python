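"""Orthogonal validations of the variant catalog.

Two independent checks: a coverage-asymmetry test between the N- and
C-terminal-fragment-encoding halves of a locus, and exon-chain matching of
long reads against the predicted variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from splicecat.core_io import ReadChain
from splicecat.exon_catalog import ExonCatalog, VariantSignature

CAT_IDENTICAL = "IDENTICAL"
CAT_TRUNCATED = "TRUNCATED"
CAT_SKIPPED = "SKIPPED_EXON"
CAT_NOVEL = "NOVEL_EXON"
CAT_NO_MATCH = "NO_MATCH"

CATEGORIES = (CAT_IDENTICAL, CAT_TRUNCATED, CAT_SKIPPED, CAT_NOVEL, CAT_NO_MATCH)

DEFAULT_PERCENTILE = 1.0
DEFAULT_END_TOLERANCE = 10


@dataclass
class CoverageTrack:
    """Sparse per-base depth over a locus."""

    sample_id: str
    depth: Mapping[int, float]  # position -> depth
    chrom: str = ""

    def depths_at(self, positions: Sequence[int]) -> np.ndarray:
        return np.asarray([self.depth.get(p, 0.0) for p in positions], dtype=float)


@dataclass
class AsymmetryResult:
    mean_ntf: float
    mean_ctf: float
    fold: float
    p_value: float
    n_ntf: int
    n_ctf: int
    n_excluded: int
    test: str = "two-sided Mann-Whitney rank-sum on per-base depths"


@dataclass
class ChainMatch:
    read_id: str
    category: str
    matched_variant: str | None = None


def coverage_asymmetry(
    track: CoverageTrack,
    ntf_positions: Sequence[int],
    ctf_positions: Sequence[int],
    percentile: float = DEFAULT_PERCENTILE,
    pooled_percentile: bool = True,
) -> AsymmetryResult:
    """Depth asymmetry between two exonic region position sets.

    Depths of both regions are pooled, the given percentile of the pooled
    values is computed, and positions below it are excluded (to remove
    rare-exon bias; ties at the threshold survive so a constant track is not
    emptied).  fold = mean(CTF)/mean(NTF); the p-value comes from a
    two-sided Mann-Whitney rank-sum comparison of the surviving per-base
    depths.  With ``pooled_percentile=False`` the exclusion threshold is
    computed per region instead.
    """
    ntf = track.depths_at(ntf_positions)
    ctf = track.depths_at(ctf_positions)
    if ntf.size == 0 or ctf.size == 0:
        raise ValueError("empty region")
    if pooled_percentile:
        threshold = float(np.percentile(np.concatenate([ntf, ctf]), percentile))
        thr_ntf = thr_ctf = threshold
    else:
        thr_ntf = float(np.percentile(ntf, percentile))
        thr_ctf = float(np.percentile(ctf, percentile))
    # ties at the threshold are kept: a constant track must survive exclusion
    kept_ntf = ntf[ntf >= thr_ntf]
    kept_ctf = ctf[ctf >= thr_ctf]
    n_excluded = (ntf.size - kept_ntf.size) + (ctf.size - kept_ctf.size)
    if kept_ntf.size == 0 or kept_ctf.size == 0:
        raise ValueError("region empty after percentile exclusion")
    mean_ntf = float(kept_ntf.mean())
    mean_ctf = float(kept_ctf.mean())
    if np.array_equal(np.sort(kept_ntf), np.sort(kept_ctf)):
        p_value = 1.0  # identical samples: rank-sum test is degenerate
    else:
        _stat, p_value = stats.mannwhitneyu(
            kept_ctf, kept_ntf, alternative="two-sided"
        )
    return AsymmetryResult(
        mean_ntf=mean_ntf,
        mean_ctf=mean_ctf,
        fold=mean_ctf / mean_ntf,
        p_value=float(p_value),
        n_ntf=int(kept_ntf.size),
        n_ctf=int(kept_ctf.size),
        n_excluded=int(n_excluded),
    )


def _variant_introns(variant: VariantSignature) -> tuple[tuple[int, int], ...]:
    exons = sorted(variant.exons, key=lambda e: e.start)
    return tuple((a.end, b.start) for a, b in zip(exons, exons[1:]))


def _is_contiguous_subchain(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    if not sub:
        return True
    n, m = len(sub), len(chain)
    return any(chain[i : i + n] == sub for i in range(m - n + 1))


def _is_subsequence(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    it = iter(chain)
    return all(any(intron == c for c in it) for intron in sub)


def match_read_chain(
    read: ReadChain,
    signatures: Sequence[VariantSignature],
    catalog: ExonCatalog,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> ChainMatch:
    """Compare a long read's intron chain to the predicted variants.

    Precedence: IDENTICAL (equal intron chain, terminal block boundaries
    within tolerance) > TRUNCATED (contiguous sub-chain) > SKIPPED_EXON
    (non-contiguous subsequence) > NOVEL_EXON (some read block overlaps no
    catalog exon extent) > NO_MATCH.  Internal junctions must match exactly;
    only the outer read ends are tolerance-free.
    """
    usable = [
        s
        for s in signatures
        if s.exons
        and s.exons[0].chrom == read.chrom
        and s.exons[0].strand == read.strand
    ]
    if not usable:
        return ChainMatch(read_id=read.read_id, category=CAT_NO_MATCH)

    read_introns = read.introns
    read_start = read.blocks[0].start
    read_end = read.blocks[-1].end

    for sig in usable:
        introns = _variant_introns(sig)
        if introns != read_introns:
            continue
        exons = sorted(sig.exons, key=lambda e: e.start)
        if (
            abs(read_start - exons[0].start) <= end_tolerance
            and abs(read_end - exons[-1].end) <= end_tolerance
        ):
            return ChainMatch(
                read_id=read.read_id,
                category=CAT_IDENTICAL,
                matched_variant=sig.variant_id,
            )
    for sig in usable:
        if _is_contiguous_subchain(read_introns, _variant_introns(sig)):
            return ChainMatch(
                read_id=read.read_id,
                category=CAT_TRUNCATED,
                matched_variant=sig.variant_id,
            )
    for sig in usable:
        if _is_subsequence(read_introns, _variant_introns(sig)):
            return ChainMatch(
                read_id=read.read_id,
                category=CAT_SKIPPED,
                matched_variant=sig.variant_id,
            )
    extents = [cls.representative for cls in catalog.classes]
    for block in read.blocks:
        if not any(block.overlaps(extent) for extent in extents):
            return ChainMatch(read_id=read.read_id, category=CAT_NOVEL)
    return ChainMatch(read_id=read.read_id, category=CAT_NO_MATCH)


def validate_with_longreads(
    reads: Sequence[ReadChain],
    signatures: Sequence[VariantSignature],
    catalog: ExonCatalog,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> tuple[list[ChainMatch], dict[str, int]]:
    """Match every read and aggregate counts per category."""
    matches = [
        match_read_chain(read, signatures, catalog, end_tolerance=end_tolerance)
        for read in reads
    ]
    summary = Counter(m.category for m in matches)
    return matches, {cat: summary.get(cat, 0) for cat in CATEGORIES}
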