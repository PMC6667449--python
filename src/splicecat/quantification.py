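"""Inclusion gates and abundance rules.

Covers the derivation of the expression cutoff from per-sample FPKM medians,
library/gene inclusion gates, per-tissue variant fractions, and the >=1%
abundance filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from splicecat.core_io import SampleMeta

logger = logging.getLogger(__name__)

DEFAULT_FPKM_CUTOFF = 0.5
DEFAULT_MIN_GENES = 3
DEFAULT_MIN_FRACTION = 0.01


@dataclass
class QuantMatrix:
    """Variant x sample abundances plus gene-level FPKM per sample."""

    values: pd.DataFrame  # index: variant id, columns: sample id
    samples: list[SampleMeta]
    gene_fpkm: dict[str, float] = field(default_factory=dict)  # sample -> FPKM

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        sample_ids = {s.sample_id for s in self.samples}
        if set(self.values.columns) - sample_ids:
            raise ValueError("matrix columns not covered by sample metadata")

    def tissues(self) -> list[str]:
        seen = []
        for s in self.samples:
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen


@dataclass
class VariantAbundance:
    variant_id: str
    tissue_fractions: dict[str, float]  # tissue -> mean fraction over replicates
    abundant: bool = False

    @property
    def max_fraction(self) -> float:
        return max(self.tissue_fractions.values()) if self.tissue_fractions else 0.0


@dataclass
class InclusionReport:
    cutoff: float
    library_pass: dict[str, bool]
    library_reason: dict[str, str]
    gene_expressed: dict[str, bool]


def derive_fpkm_cutoff(per_sample_fpkm: Sequence[Sequence[float]]) -> float:
    """Per-sample median -> mean across samples -> ceiling at 0.1 granularity.

    An averaged median of 0.42 yields the 0.5 working cutoff.
    """
    if not per_sample_fpkm or any(len(v) == 0 for v in per_sample_fpkm):
        raise ValueError("every sample needs >=1 FPKM value")
    medians = [float(np.median(np.asarray(v, dtype=float))) for v in per_sample_fpkm]
    mean = float(np.mean(medians))
    return math.ceil(mean * 10 - 1e-9) / 10


def apply_inclusion_gates(
    samples: Sequence[SampleMeta],
    gene_fpkm: Mapping[str, Mapping[str, float]],
    panel_gene_ids: Sequence[str],
    cutoff: float = DEFAULT_FPKM_CUTOFF,
    min_genes: int = DEFAULT_MIN_GENES,
) -> InclusionReport:
    """Library and gene inclusion gates.

    ``gene_fpkm`` maps sample_id -> {gene_id: FPKM}.  A library passes iff
    strictly more than ``min_genes`` panel genes reach the cutoff in it.  A
    gene is "expressed" iff its replicate-mean FPKM reaches the cutoff in at
    least one tissue.
    """
    library_pass: dict[str, bool] = {}
    library_reason: dict[str, str] = {}
    for sample in samples:
        fpkms = gene_fpkm.get(sample.sample_id, {})
        n_hit = sum(1 for g in panel_gene_ids if fpkms.get(g, 0.0) >= cutoff)
        ok = n_hit > min_genes
        library_pass[sample.sample_id] = ok
        library_reason[sample.sample_id] = (
            f"{n_hit} panel genes with FPKM >= {cutoff} "
            f"({'passes' if ok else 'needs more than'} {min_genes})"
        )

    by_tissue: dict[str, list[SampleMeta]] = {}
    for sample in samples:
        by_tissue.setdefault(sample.tissue, []).append(sample)

    gene_expressed: dict[str, bool] = {}
    for gene in panel_gene_ids:
        expressed = False
        for tissue_samples in by_tissue.values():
            values = [
                gene_fpkm.get(s.sample_id, {}).get(gene, 0.0) for s in tissue_samples
            ]
            if values and float(np.mean(values)) >= cutoff:
                expressed = True
                break
        gene_expressed[gene] = expressed

    return InclusionReport(
        cutoff=cutoff,
        library_pass=library_pass,
        library_reason=library_reason,
        gene_expressed=gene_expressed,
    )


def build_quant_matrix(
    signatures: Sequence,
    transcripts: Sequence,
    samples: Sequence[SampleMeta],
    unit: str = "fpkm",
) -> QuantMatrix:
    """Variant x sample matrix by summing member-transcript abundances.

    ``signatures`` need ``variant_id`` and ``member_transcripts`` attributes;
    ``transcripts`` are the parsed records they were encoded from.  ``unit``
    selects the StringTie attribute ("fpkm" or "cov")."""
    if unit not in ("fpkm", "cov"):
        raise ValueError("unit must be 'fpkm' or 'cov'")
    value_of = {
        (t.sample_id, t.transcript_id): (t.fpkm if unit == "fpkm" else t.coverage)
        for t in transcripts
    }
    sample_ids = [s.sample_id for s in samples]
    data = np.zeros((len(signatures), len(sample_ids)))
    col = {sid: j for j, sid in enumerate(sample_ids)}
    for i, sig in enumerate(signatures):
        for sample_id, transcript_id in sig.member_transcripts:
            data[i, col[sample_id]] += value_of.get((sample_id, transcript_id), 0.0)
    gene_fpkm = {
        sid: float(
            sum(t.fpkm for t in transcripts if t.sample_id == sid)
        )
        for sid in sample_ids
    }
    return QuantMatrix(
        values=pd.DataFrame(
            data, index=[s.variant_id for s in signatures], columns=sample_ids
        ),
        samples=list(samples),
        gene_fpkm=gene_fpkm,
    )


def compute_variant_fractions(
    quant: QuantMatrix, samples: Sequence[SampleMeta] | None = None
) -> list[VariantAbundance]:
    """Per-tissue mean fractions of each variant within its gene.

    Per sample, fraction = variant abundance / total gene abundance; the
    tissue value is the arithmetic mean over that tissue's replicates.
    Samples with zero total abundance contribute no fraction (skipped with a
    warning); a gene with zero abundance in all samples is an error.
    """
    if samples is None:
        samples = quant.samples
    totals = quant.values.sum(axis=0)
    if float(totals.sum()) == 0.0:
        raise ValueError("gene has zero total abundance in all samples")

    usable: dict[str, list[str]] = {}
    for sample in samples:
        if sample.sample_id not in quant.values.columns:
            continue
        if float(totals[sample.sample_id]) == 0.0:
            logger.warning(
                "sample %s has zero total abundance; skipped", sample.sample_id
            )
            continue
        usable.setdefault(sample.tissue, []).append(sample.sample_id)

    fractions = quant.values.div(totals.replace(0.0, np.nan), axis=1)
    result = []
    for variant_id in quant.values.index:
        tissue_fractions = {}
        for tissue, sample_ids in usable.items():
            if sample_ids:
                tissue_fractions[tissue] = float(
                    fractions.loc[variant_id, sample_ids].mean()
                )
        result.append(
            VariantAbundance(variant_id=variant_id, tissue_fractions=tissue_fractions)
        )
    return result


def filter_abundant(
    abundances: Sequence[VariantAbundance],
    threshold: float = DEFAULT_MIN_FRACTION,
) -> list[VariantAbundance]:
    """Keep variants whose tissue-mean fraction reaches the threshold in at
    least one tissue (boundary value kept).  Sets the ``abundant`` flag on
    every input."""
    kept = []
    for ab in abundances:
        ab.abundant = any(f >= threshold for f in ab.tissue_fractions.values())
        if ab.abundant:
            kept.append(ab)
    return kept
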