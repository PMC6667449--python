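"""Per-gene summary rows, cohort aggregates, knockout reports, locus plots.

Summary rows mirror the layout of the published per-gene variant table
(counts of start/end/internal exon classes with annotated subsets, variant
counts, exon usage of abundant variants); cohort aggregates reproduce the
headline cross-gene means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from math import floor
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from splicecat.core_io import DomainAnnotation
from splicecat.exon_catalog import (
    ExonCatalog,
    NoveltyReport,
    ROLE_END,
    ROLE_INTERNAL,
    ROLE_START,
    VariantSignature,
)
from splicecat.orf_protein import GeneVariabilityFlags, OrfRecord
from splicecat.quantification import VariantAbundance

FLAG_COLUMNS = (
    "ntf_domain_variability",
    "soluble_ntf",
    "anchored_ntf",
    "ctf",
    "tm7_variability",
    "cterm_variability",
)


def round_half_away(x: float) -> int:
    """Round half away from zero (matches the headline integer phrasing)."""
    return int(floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class GeneSummaryRow:
    gene_id: str
    n_start: int
    n_start_annotated: int
    n_end: int
    n_end_annotated: int
    n_internal: int
    n_internal_annotated: int
    n_variants: int
    n_abundant: int
    n_exons_total: int
    n_exons_abundant: int
    mean_exons_abundant: float
    min_exons_abundant: int
    max_exons_abundant: int

    def __post_init__(self):
        if self.n_abundant > self.n_variants:
            raise ValueError("abundant variants cannot exceed total variants")

    @property
    def annotated_fraction_all(self) -> float:
        total = self.n_start + self.n_end + self.n_internal
        if total == 0:
            return 0.0
        annotated = (
            self.n_start_annotated + self.n_end_annotated + self.n_internal_annotated
        )
        return annotated / total


@dataclass
class CohortSummary:
    n_genes: int
    mean_variants: float
    mean_abundant: float
    mean_exons_per_abundant: float
    mean_start: float
    sd_start: float
    annotated_pct_all: float
    sd_annotated_pct_all: float
    annotated_pct_start: float
    annotated_pct_end: float
    annotated_pct_internal: float

    @property
    def headline_variants(self) -> int:
        return round_half_away(self.mean_variants)

    @property
    def headline_abundant(self) -> int:
        return round_half_away(self.mean_abundant)

    @property
    def headline_exons(self) -> int:
        return round_half_away(self.mean_exons_per_abundant)


@dataclass
class ClassificationSummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal, of genes flagged
    n_genes: int


def gene_summary_row(
    catalog: ExonCatalog,
    signatures: Sequence[VariantSignature],
    abundances: Sequence[VariantAbundance],
    novelty: NoveltyReport,
) -> GeneSummaryRow:
    """Assemble the per-gene row from full pipeline outputs."""
    abundant_ids = {a.variant_id for a in abundances if a.abundant}
    display_of = {c.class_number: c.display_number for c in catalog.classes}

    def distinct_exons(sigs):
        used = set()
        for sig in sigs:
            used |= {display_of[n] for n in sig.exon_numbers}
        return len(used)

    abundant_sigs = [s for s in signatures if s.variant_id in abundant_ids]
    exon_counts = [len(s.exon_numbers) for s in abundant_sigs]
    return GeneSummaryRow(
        gene_id=catalog.gene_id,
        n_start=novelty.total(ROLE_START),
        n_start_annotated=novelty.annotated(ROLE_START),
        n_end=novelty.total(ROLE_END),
        n_end_annotated=novelty.annotated(ROLE_END),
        n_internal=novelty.total(ROLE_INTERNAL),
        n_internal_annotated=novelty.annotated(ROLE_INTERNAL),
        n_variants=len(signatures),
        n_abundant=len(abundant_sigs),
        n_exons_total=distinct_exons(signatures),
        n_exons_abundant=distinct_exons(abundant_sigs),
        mean_exons_abundant=(float(np.mean(exon_counts)) if exon_counts else 0.0),
        min_exons_abundant=(min(exon_counts) if exon_counts else 0),
        max_exons_abundant=(max(exon_counts) if exon_counts else 0),
    )


def cohort_summary(rows: Sequence[GeneSummaryRow]) -> CohortSummary:
    """Cross-gene means (and sample SDs where reported)."""
    if not rows:
        raise ValueError("need >=1 gene row")

    def sample_sd(values):
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0

    def frac(annotated, total):
        return annotated / total if total else 0.0

    n_variants = [r.n_variants for r in rows]
    n_abundant = [r.n_abundant for r in rows]
    mean_exons = [r.mean_exons_abundant for r in rows]
    n_start = [r.n_start for r in rows]
    frac_all = [r.annotated_fraction_all for r in rows]
    frac_start = [frac(r.n_start_annotated, r.n_start) for r in rows]
    frac_end = [frac(r.n_end_annotated, r.n_end) for r in rows]
    frac_internal = [frac(r.n_internal_annotated, r.n_internal) for r in rows]

    return CohortSummary(
        n_genes=len(rows),
        mean_variants=float(np.mean(n_variants)),
        mean_abundant=float(np.mean(n_abundant)),
        mean_exons_per_abundant=float(np.mean(mean_exons)),
        mean_start=float(np.mean(n_start)),
        sd_start=sample_sd(n_start),
        annotated_pct_all=100 * float(np.mean(frac_all)),
        sd_annotated_pct_all=100 * sample_sd(frac_all),
        annotated_pct_start=100 * float(np.mean(frac_start)),
        annotated_pct_end=100 * float(np.mean(frac_end)),
        annotated_pct_internal=100 * float(np.mean(frac_internal)),
    )


def classification_summary(
    flags_per_gene: Mapping[str, GeneVariabilityFlags | Sequence[bool]],
) -> ClassificationSummary:
    """Column-wise percentage (1 decimal) of genes with each flag set."""
    n_genes = len(flags_per_gene)
    counts = dict.fromkeys(FLAG_COLUMNS, 0)
    for flags in flags_per_gene.values():
        values = (
            flags.as_tuple() if isinstance(flags, GeneVariabilityFlags) else flags
        )
        for column, value in zip(FLAG_COLUMNS, values):
            counts[column] += bool(value)
    percentages = {
        column: round(100 * counts[column] / n_genes, 1) if n_genes else 0.0
        for column in FLAG_COLUMNS
    }
    return ClassificationSummary(counts=counts, percentages=percentages, n_genes=n_genes)


# ---------------------------------------------------------------------------
# Knockout residual-transcript report
# ---------------------------------------------------------------------------

UNAFFECTED = "UNAFFECTED"
DISRUPTED = "DISRUPTED"


@dataclass
class KnockoutReport:
    deleted_exons: tuple[int, ...]
    status: dict[str, str]  # variant id -> UNAFFECTED / DISRUPTED
    frame_effect: dict[str, str]  # DISRUPTED variant id -> in_frame / frameshift

    @property
    def unaffected(self) -> list[str]:
        return [v for v, s in self.status.items() if s == UNAFFECTED]

    @property
    def disrupted(self) -> list[str]:
        return [v for v, s in self.status.items() if s == DISRUPTED]


def knockout_residual_report(
    catalog: ExonCatalog,
    signatures: Sequence[VariantSignature],
    orfs: Mapping[str, OrfRecord | None],
    deleted_exon_numbers: Sequence[int],
) -> KnockoutReport:
    """Partition variants by whether they contain any deleted exon.

    ``deleted_exon_numbers`` are display numbers.  For disrupted variants the
    deletion is in-frame when the deleted coding bases within the ORF sum to
    a multiple of 3, otherwise it shifts frame.
    """
    display_of = {c.class_number: c.display_number for c in catalog.classes}
    known = set(display_of.values())
    unknown = set(deleted_exon_numbers) - known
    if unknown:
        raise KeyError(f"unknown exon display numbers: {sorted(unknown)}")
    deleted = set(deleted_exon_numbers)

    status: dict[str, str] = {}
    frame_effect: dict[str, str] = {}
    for sig in signatures:
        hit_classes = [
            n for n in sig.exon_numbers if display_of[n] in deleted
        ]
        if not hit_classes:
            status[sig.variant_id] = UNAFFECTED
            continue
        status[sig.variant_id] = DISRUPTED
        orf = orfs.get(sig.variant_id)
        deleted_cds_bp = 0
        if orf is not None:
            by_number = {c.class_number: c for c in catalog.classes}
            for n in hit_classes:
                extent = by_number[n].representative
                for f in orf.footprint:
                    lo, hi = max(f.start, extent.start), min(f.end, extent.end)
                    if lo < hi:
                        deleted_cds_bp += hi - lo
        frame_effect[sig.variant_id] = (
            "in_frame" if deleted_cds_bp % 3 == 0 else "frameshift"
        )
    return KnockoutReport(
        deleted_exons=tuple(sorted(deleted)), status=status, frame_effect=frame_effect
    )


# ---------------------------------------------------------------------------
# Condensed locus plot
# ---------------------------------------------------------------------------

DEFAULT_INTRON_DISPLAY_WIDTH = 30.0
DEFAULT_ABUNDANCE_BINS = (0.01, 0.10, 0.50)
BIN_COLORS = ("#cfe3f5", "#8ab8e0", "#3d79b8", "#0b3d6e")  # <1%, 1-10%, 10-50%, >=50%


class CondensedAxis:
    """Piecewise-linear genomic -> display map: true exon widths, fixed-width
    introns.  Invertible on exonic positions."""

    def __init__(
        self,
        exon_extents: Sequence[tuple[int, int]],
        intron_width: float = DEFAULT_INTRON_DISPLAY_WIDTH,
    ):
        merged: list[list[int]] = []
        for start, end in sorted(exon_extents):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        if not merged:
            raise ValueError("need >=1 exon extent")
        self.segments: list[tuple[int, int, float]] = []  # (start, end, disp_start)
        self.intron_width = intron_width
        cursor = 0.0
        prev_end = None
        for start, end in merged:
            if prev_end is not None:
                cursor += intron_width
            self.segments.append((start, end, cursor))
            cursor += end - start
            prev_end = end
        self.display_span = cursor

    def to_display(self, pos: int) -> float:
        for i, (start, end, disp) in enumerate(self.segments):
            if start <= pos <= end:
                return disp + (pos - start)
            if pos < start:
                # inside the intron before this segment: interpolate
                prev_start, prev_end, prev_disp = self.segments[i - 1]
                gap = start - prev_end
                frac = (pos - prev_end) / gap
                return prev_disp + (prev_end - prev_start) + frac * self.intron_width
        if pos < self.segments[0][0]:
            return self.segments[0][2]
        return self.display_span

    def to_genomic(self, display: float) -> float:
        """Inverse map; exact on exonic positions."""
        for start, end, disp in self.segments:
            if disp <= display <= disp + (end - start):
                return start + (display - disp)
        raise ValueError("display coordinate not on an exonic segment")


@dataclass
class LocusPlotSpec:
    axis: CondensedAxis
    intron_width: float = DEFAULT_INTRON_DISPLAY_WIDTH
    abundance_bins: tuple[float, ...] = DEFAULT_ABUNDANCE_BINS
    bin_colors: tuple[str, ...] = BIN_COLORS


def abundance_bin(fraction: float, bins: Sequence[float] = DEFAULT_ABUNDANCE_BINS) -> int:
    index = 0
    for edge in bins:
        if fraction >= edge:
            index += 1
    return index


def plot_locus(
    catalog: ExonCatalog,
    variants: Sequence[VariantSignature],
    abundances: Mapping[str, VariantAbundance],
    orfs: Mapping[str, OrfRecord | None],
    domains: Sequence[DomainAnnotation],
    path: str | Path,
    intron_width: float = DEFAULT_INTRON_DISPLAY_WIDTH,
    bins: tuple[float, ...] = DEFAULT_ABUNDANCE_BINS,
) -> LocusPlotSpec:
    """Render the condensed-intron locus figure (deterministic layout).

    Top row: all exon extents.  Below: one row per variant and tissue,
    exons colored by the tissue's abundance bin, CDS drawn thick and UTR
    thin, grey columns spanning the domain regions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    extents = sorted(catalog.display_numbering)
    axis = CondensedAxis(extents, intron_width=intron_width)
    spec = LocusPlotSpec(axis=axis, intron_width=intron_width, abundance_bins=bins)

    tissues: list[str] = []
    for variant in variants:
        for tissue in abundances[variant.variant_id].tissue_fractions:
            if tissue not in tissues:
                tissues.append(tissue)
    rows = [(v, t) for v in variants for t in tissues]

    height = 1.2 + 0.28 * (len(rows) + 1)
    fig, ax = plt.subplots(figsize=(10, max(2.5, height)))
    y_top = len(rows) + 1.5

    for dom in domains:
        for ival in dom.intervals:
            x0 = axis.to_display(ival.start)
            x1 = axis.to_display(ival.end)
            ax.axvspan(x0, x1, color="#dddddd", zorder=0)
            ax.text(
                (x0 + x1) / 2,
                y_top + 0.55,
                dom.domain_name,
                ha="center",
                va="bottom",
                fontsize=6,
                color="#555555",
            )

    for start, end in extents:
        x0, x1 = axis.to_display(start), axis.to_display(end)
        ax.add_patch(
            Rectangle((x0, y_top - 0.25), x1 - x0, 0.5, color="#4477aa", zorder=2)
        )

    by_number = {c.class_number: c for c in catalog.classes}
    for row_index, (variant, tissue) in enumerate(rows):
        y = len(rows) - row_index
        fraction = abundances[variant.variant_id].tissue_fractions.get(tissue, 0.0)
        color = spec.bin_colors[abundance_bin(fraction, bins)]
        orf = orfs.get(variant.variant_id)
        cds = [(f.start, f.end) for f in orf.footprint] if orf else []
        exon_xs = []
        for number in variant.exon_numbers:
            extent = by_number[number].representative
            exon_xs.append((axis.to_display(extent.start), axis.to_display(extent.end)))
            for sub_start, sub_end in _split_cds(extent.start, extent.end, cds):
                x0, x1 = axis.to_display(sub_start), axis.to_display(sub_end)
                thick = any(s <= sub_start and sub_end <= e for s, e in cds)
                half = 0.30 if thick else 0.12
                ax.add_patch(
                    Rectangle((x0, y - half), x1 - x0, 2 * half, color=color, zorder=3)
                )
        x_min = min(x for x, _ in exon_xs)
        x_max = max(x for _, x in exon_xs)
        ax.plot([x_min, x_max], [y, y], color=color, lw=0.6, zorder=1)
        ax.text(
            -0.01 * axis.display_span,
            y,
            f"{variant.variant_id} [{tissue}]",
            ha="right",
            va="center",
            fontsize=6,
        )

    labels = ["<1%"] + [
        f"{int(a * 100)}-{int(b * 100)}%" for a, b in zip(bins, bins[1:])
    ] + [f">={int(bins[-1] * 100)}%"]
    handles = [
        Rectangle((0, 0), 1, 1, color=c) for c in spec.bin_colors[: len(labels)]
    ]
    ax.legend(handles, labels, loc="upper right", fontsize=6, title="abundance")
    ax.set_xlim(-0.15 * axis.display_span, 1.02 * axis.display_span)
    ax.set_ylim(0, y_top + 1.5)
    ax.set_yticks([])
    ax.set_xlabel("condensed locus coordinate")
    ax.set_title(catalog.gene_id)

    with plt.rc_context({"svg.hashsalt": "splicecat"}):
        fig.savefig(path, metadata=_deterministic_metadata(Path(path).suffix))
    plt.close(fig)
    return spec


def _deterministic_metadata(suffix: str) -> dict:
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return {}


def _split_cds(start: int, end: int, cds: list[tuple[int, int]]):
    """Split [start, end) at CDS boundaries so thick/thin runs are contiguous."""
    cuts = {start, end}
    for s, e in cds:
        if start < s < end:
            cuts.add(s)
        if start < e < end:
            cuts.add(e)
    ordered = sorted(cuts)
    return list(zip(ordered, ordered[1:]))


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("splicecat.fixtures") / name)


def load_gene_summary_fixture() -> list[GeneSummaryRow]:
    """The packaged 18-gene summary table as GeneSummaryRow objects."""
    df = pd.read_csv(_fixture_path("gene_summary_table.tsv"), sep="\t")
    rows = []
    for record in df.itertuples(index=False):
        rows.append(
            GeneSummaryRow(
                gene_id=record.gene_id,
                n_start=record.n_start,
                n_start_annotated=record.n_start_annotated,
                n_end=record.n_end,
                n_end_annotated=record.n_end_annotated,
                n_internal=record.n_internal,
                n_internal_annotated=record.n_internal_annotated,
                n_variants=record.n_variants,
                n_abundant=record.n_abundant,
                n_exons_total=record.n_exons_total,
                n_exons_abundant=record.n_exons_abundant,
                mean_exons_abundant=record.mean_exons_abundant,
                min_exons_abundant=record.min_exons_abundant,
                max_exons_abundant=record.max_exons_abundant,
            )
        )
    return rows


def load_variability_flags_fixture() -> dict[str, tuple[bool, ...]]:
    """The packaged 18-gene x 6-column flag matrix."""
    df = pd.read_csv(_fixture_path("variability_flags_table.tsv"), sep="\t")
    return {
        record.gene_id: tuple(
            bool(getattr(record, column)) for column in FLAG_COLUMNS
        )
        for record in df.itertuples(index=False)
    }
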