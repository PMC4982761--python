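"""Averaged signal profiles: fixed-anchor 50-bp bins, scaled meta-gene, heatmaps.

Profiles are laid out 5'->3' in gene orientation; minus-strand genes are
mirrored so that "downstream" always reads left to right. Bin values are
tags per million mapped fragments per bin; gene averages weight every gene
equally. Bins that would cross a chromosome boundary are treated as missing
and the per-bin mean divides by the number of genes actually contributing.

The scaled meta-gene splits each gene body into a fixed number of
equal-width fractional slices and rescales each slice's normalised tag
count to a 50-bp-equivalent density, so flank bins and body slices share a
common scale: a uniformly covered gene is flat across the whole profile
regardless of its length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotations_io import GeneModel, StrandedCoverage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileSpec:
    """Layout of a binned profile.

    anchor: 'tss', 'tts', or 'scaled' (scaled gene body with flanks).
    upstream_bp / downstream_bp: flank lengths; must be multiples of bin_bp.
    body_bins: number of body slices in scaled mode.
    """

    anchor: str = "tts"
    upstream_bp: int = 1000
    downstream_bp: int = 5000
    bin_bp: int = 50
    body_bins: int = 60

    def __post_init__(self) -> None:
        if self.anchor not in ("tss", "tts", "scaled"):
            raise ValueError("anchor must be 'tss', 'tts' or 'scaled'")
        if self.bin_bp <= 0 or self.body_bins <= 0:
            raise ValueError("bin_bp and body_bins must be > 0")
        if self.upstream_bp % self.bin_bp or self.downstream_bp % self.bin_bp:
            raise ValueError("flank lengths must be multiples of bin_bp")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("flank lengths must be >= 0")

    @property
    def n_bins(self) -> int:
        flank = (self.upstream_bp + self.downstream_bp) // self.bin_bp
        if self.anchor == "scaled":
            return flank + self.body_bins
        return flank


@dataclass
class BinnedProfile:
    spec: ProfileSpec
    values: np.ndarray  # per-bin mean across genes, tags per million per bin
    n_genes: int
    n_genes_per_bin: np.ndarray

    def offsets_bp(self) -> np.ndarray:
        """Left edge of each bin relative to the anchor (flank bins only in
        scaled mode; body slices get fractional indices)."""
        up, b = self.spec.upstream_bp, self.spec.bin_bp
        if self.spec.anchor != "scaled":
            return np.arange(-up, self.spec.downstream_bp, b)
        left = np.arange(-up, 0, b)
        body = np.linspace(0, 1, self.spec.body_bins, endpoint=False)
        right = np.arange(0, self.spec.downstream_bp, b)
        return np.concatenate([left, body, right])


def _oriented_offsets(gene: GeneModel, anchor_pos: int, positions: np.ndarray) -> np.ndarray:
    """Strand-aware offsets of tag positions from an anchor coordinate.

    On the + strand a tag at p has offset p - anchor; on the - strand the
    mirror offset anchor - 1 - p, so offsets increase 5'->3' and the two
    strands are exact mirror images of one another.
    """
    if gene.span.strand == "+":
        return positions - anchor_pos
    return anchor_pos - 1 - positions


def per_gene_bins(
    gene: GeneModel,
    cov: StrandedCoverage,
    spec: ProfileSpec,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Fixed-anchor binned, per-million-normalised tag counts for one gene.

    Returns NaN for bins extending beyond the chromosome.
    """
    if spec.anchor == "scaled":
        raise ValueError("use scaled_gene_bins for scaled mode")
    anchor_pos = gene.tss if spec.anchor == "tss" else gene.tts
    pos = cov.positions(gene.span.chrom, gene.span.strand)
    off = _oriented_offsets(gene, anchor_pos, pos)
    edges = np.arange(-spec.upstream_bp, spec.downstream_bp + spec.bin_bp, spec.bin_bp)
    # keep bins half-open: np.histogram closes the rightmost bin
    off = off[(off >= edges[0]) & (off < edges[-1])]
    counts, _ = np.histogram(off, bins=edges)
    values = counts * (1e6 / cov.library_size)
    # mask bins lying (even partly) outside the chromosome
    if gene.span.strand == "+":
        gstart = anchor_pos + edges[:-1]
        gend = anchor_pos + edges[1:]
    else:
        gstart = anchor_pos - edges[1:]
        gend = anchor_pos - edges[:-1]
    bad = gstart < 0
    if chrom_length is not None:
        bad |= gend > chrom_length
    values = values.astype(float)
    values[bad] = np.nan
    return values


def scaled_gene_bins(
    gene: GeneModel,
    cov: StrandedCoverage,
    spec: ProfileSpec,
    chrom_length: int | None = None,
) -> np.ndarray | None:
    """Scaled-body profile for one gene: 50-bp flanks plus fractional body slices.

    Body slice values are normalised tags divided by slice width and
    rescaled to a 50-bp-equivalent bin. Returns None (caller skips) for
    genes shorter than body_bins bases.
    """
    if spec.anchor != "scaled":
        raise ValueError("spec.anchor must be 'scaled'")
    L = gene.span.length
    if L < spec.body_bins:
        return None
    pos = cov.positions(gene.span.chrom, gene.span.strand)
    # orientation: offsets from the TSS, increasing 5'->3'
    off = _oriented_offsets(gene, gene.tss, pos).astype(float)

    up_edges = np.arange(-spec.upstream_bp, 1, spec.bin_bp, dtype=float)
    body_edges = np.linspace(0.0, float(L), spec.body_bins + 1)
    down_edges = np.arange(
        float(L), float(L) + spec.downstream_bp + spec.bin_bp, spec.bin_bp, dtype=float
    )
    edges = np.concatenate([up_edges[:-1], body_edges, down_edges[1:]])
    off = off[(off >= edges[0]) & (off < edges[-1])]
    counts, _ = np.histogram(off, bins=edges)
    widths = np.diff(edges)
    values = counts * (1e6 / cov.library_size) * (spec.bin_bp / widths)

    # chromosome-boundary masking in genomic space
    if gene.span.strand == "+":
        gstart = gene.tss + edges[:-1]
        gend = gene.tss + edges[1:]
    else:
        gstart = gene.tss - edges[1:]
        gend = gene.tss - edges[:-1]
    bad = gstart < 0
    if chrom_length is not None:
        bad |= gend > chrom_length
    values = values.astype(float)
    values[bad] = np.nan
    return values


def _stack_profiles(
    genes: Sequence[GeneModel],
    cov: StrandedCoverage,
    spec: ProfileSpec,
    chrom_length: int | None,
) -> tuple[np.ndarray, int]:
    if len(genes) == 0:
        raise ValueError("need at least one gene to profile")
    rows = []
    skipped = 0
    for g in genes:
        if spec.anchor == "scaled":
            v = scaled_gene_bins(g, cov, spec, chrom_length)
            if v is None:
                skipped += 1
                continue
        else:
            v = per_gene_bins(g, cov, spec, chrom_length)
        rows.append(v)
    if skipped:
        logger.warning("scaled meta-gene: skipped %d genes shorter than body_bins", skipped)
    if not rows:
        raise ValueError("no gene was long enough to profile")
    return np.vstack(rows), skipped


def average_profile(
    genes: Sequence[GeneModel],
    cov: StrandedCoverage,
    spec: ProfileSpec,
    chrom_length: int | None = None,
) -> BinnedProfile:
    """Equal-weight mean profile across genes (NaN bins excluded per bin)."""
    mat, _ = _stack_profiles(genes, cov, spec, chrom_length)
    contributing = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(mat, axis=0)
    return BinnedProfile(
        spec=spec, values=means, n_genes=mat.shape[0], n_genes_per_bin=contributing
    )


def scaled_metagene(
    genes: Sequence[GeneModel],
    cov: StrandedCoverage,
    spec: ProfileSpec,
    chrom_length: int | None = None,
) -> BinnedProfile:
    """Average scaled-body meta-gene profile (flanks + equal-width body slices)."""
    if spec.anchor != "scaled":
        raise ValueError("spec.anchor must be 'scaled'")
    return average_profile(genes, cov, spec, chrom_length)


@dataclass
class MetageneMatrix:
    gene_ids: list[str]
    values: np.ndarray  # genes x bins, per-million-normalised
    spec: ProfileSpec

    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


def heatmap_matrix(
    genes: Sequence[GeneModel],
    cov: StrandedCoverage,
    anchor: str = "tss",
    halfspan: int = 4000,
    bin_bp: int = 50,
    order_fpkm: Mapping[str, float] | None = None,
    chrom_length: int | None = None,
) -> MetageneMatrix:
    """Per-gene binned signal centred on the anchor, rows by descending FPKM.

    With the default 4-kb halfspan and 50-bp bins each row has 160 columns.
    Column means equal the corresponding average profile by construction.
    """
    spec = ProfileSpec(
        anchor=anchor, upstream_bp=halfspan, downstream_bp=halfspan, bin_bp=bin_bp
    )
    order_fpkm = order_fpkm or {}
    ordered = sorted(
        genes, key=lambda g: (-order_fpkm.get(g.gene_id, 0.0), g.gene_id)
    )
    mat, _ = _stack_profiles(ordered, cov, spec, chrom_length)
    return MetageneMatrix(
        gene_ids=[g.gene_id for g in ordered], values=mat, spec=spec
    )
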