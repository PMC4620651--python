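"""Cross-taxon fixation filter for putative post-domestication variants.

Nominates loci where two taxon groups (e.g. European taurine vs indicine
cattle) are near-fixed (>= 95 %) for opposite alleles and the ancient sample
is homozygous for the second group's major allele, then restricts to
gene-proximal regions (exons, UTRs, and 5 kb flanks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FrequencyTable, locus_id

__all__ = [
    "GeneModel",
    "RegionCall",
    "pooled_group_frequency",
    "fixation_filter",
    "region_classify",
    "candidate_report",
    "RETAINED_CLASSES",
]

RETAINED_CLASSES = frozenset({"exon", "utr5", "utr3", "flank_up", "flank_down"})

# most specific class first
_PRIORITY = ["exon", "utr5", "utr3", "intron", "flank_up", "flank_down", "intergenic"]


@dataclass
class GeneModel:
    """A gene with 0-based half-open coordinates and optional sub-features."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: strand must be +, - or .")
        for lo, hi in self.exons + self.utr5 + self.utr3:
            if not (self.start <= lo < hi <= self.end):
                raise ValueError(f"{self.gene_id}: sub-feature outside gene bounds")


@dataclass
class RegionCall:
    region_class: str
    gene_id: str | None
    tied: bool = False


def _classify_against_gene(pos0: int, gene: GeneModel, flank_bp: int) -> str | None:
    """Region class of a 0-based position relative to one gene, or None."""
    if gene.start <= pos0 < gene.end:
        for lo, hi in gene.exons:
            if lo <= pos0 < hi:
                return "exon"
        for lo, hi in gene.utr5:
            if lo <= pos0 < hi:
                return "utr5"
        for lo, hi in gene.utr3:
            if lo <= pos0 < hi:
                return "utr3"
        return "intron" if (gene.exons or gene.utr5 or gene.utr3) else "exon"
    if flank_bp <= 0:
        return None
    before = gene.start - flank_bp <= pos0 < gene.start
    after = gene.end <= pos0 < gene.end + flank_bp
    if not (before or after):
        return None
    if gene.strand == ".":
        warnings.warn(
            f"{gene.gene_id}: strand-less model; flank labels follow "
            "coordinate order",
            stacklevel=2,
        )
        strand = "+"
    else:
        strand = gene.strand
    if strand == "+":
        return "flank_up" if before else "flank_down"
    return "flank_down" if before else "flank_up"


def region_classify(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    flank_bp: int = 5000,
) -> RegionCall:
    """Classify a 1-based variant position against sorted gene models.

    The most specific class wins (exon/UTR > intron > flank > intergenic);
    ties across overlapping genes go to the first gene in sorted order and
    are flagged. A gene without annotated sub-features counts as exonic
    throughout its body.
    """
    pos0 = pos - 1
    best: RegionCall = RegionCall("intergenic", None)
    best_rank = _PRIORITY.index("intergenic")
    tied = False
    for gene in genes:
        if gene.chrom != chrom:
            continue
        cls = _classify_against_gene(pos0, gene, flank_bp)
        if cls is None:
            continue
        rank = _PRIORITY.index(cls)
        if rank < best_rank:
            best = RegionCall(cls, gene.gene_id)
            best_rank = rank
            tied = False
        elif rank == best_rank and best.gene_id is not None:
            tied = True
    best.tied = tied
    return best


def pooled_group_frequency(
    freqs: FrequencyTable, group: Sequence[str]
) -> np.ndarray:
    """Alt-allele frequency pooling allele copies across a group's populations."""
    p = np.stack([freqs.column(pop) for pop in group], axis=1)
    n = np.stack([freqs.copies(pop) for pop in group], axis=1).astype(float)
    alt = np.nansum(p * n, axis=1)
    tot = np.where(np.isnan(p), 0.0, n).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, alt / np.maximum(tot, 1.0), np.nan)


def fixation_filter(
    freqs: FrequencyTable,
    group1: Sequence[str],
    group2: Sequence[str],
    ancient_dosage: np.ndarray,
    ancient_ploidy: int = 2,
    threshold: float = 0.95,
) -> tuple[np.ndarray, dict[str, int]]:
    """Indices of loci near-fixed for opposite alleles between two groups.

    A locus is retained when one group's frequency of allele X is >=
    ``threshold``, the other group's frequency of the complementary allele
    is >= ``threshold``, and the ancient sample is homozygous (all observed
    copies) for group2's major allele. Group frequencies pool allele copies
    across the group's populations. Loci with a missing group frequency or
    missing/heterozygous-incompatible ancient call are skipped and tallied.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    ancient_dosage = np.asarray(ancient_dosage, dtype=float)
    if ancient_dosage.shape != (freqs.n_loci,):
        raise ValueError("ancient dosages must align with the frequency table loci")
    p1 = pooled_group_frequency(freqs, group1)
    p2 = pooled_group_frequency(freqs, group2)
    callable_groups = ~(np.isnan(p1) | np.isnan(p2))
    # opposite near-fixation: group1 for alt & group2 for ref, or vice versa
    g1_alt = (p1 >= threshold) & (p2 <= 1 - threshold)
    g1_ref = (p1 <= 1 - threshold) & (p2 >= threshold)
    ancient_called = ~np.isnan(ancient_dosage)
    hom_ref = ancient_called & (ancient_dosage == 0)
    hom_alt = ancient_called & (ancient_dosage == ancient_ploidy)
    # ancient must be homozygous for group2's major allele
    keep = callable_groups & ancient_called & (
        (g1_alt & hom_ref) | (g1_ref & hom_alt)
    )
    skipped = {
        "missing_group_frequency": int((~callable_groups).sum()),
        "missing_ancient_call": int((callable_groups & ~ancient_called).sum()),
    }
    return np.nonzero(keep)[0], skipped


def candidate_report(
    freqs: FrequencyTable,
    survivor_idx: np.ndarray,
    group1_freq: np.ndarray,
    group2_freq: np.ndarray,
    ancient_dosage: np.ndarray,
    genes: Sequence[GeneModel],
    flank_bp: int = 5000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join fixation survivors with region classes, keeping gene-proximal ones.

    Returns the candidate table (one row per retained variant) and per-class
    counts over all survivors, including the discarded intron/intergenic
    classes.
    """
    rows = []
    class_counts: dict[str, int] = {c: 0 for c in _PRIORITY}
    for i in np.asarray(survivor_idx, dtype=int):
        locus = freqs.loci.iloc[i]
        call = region_classify(locus["chrom"], int(locus["pos"]), genes, flank_bp)
        class_counts[call.region_class] += 1
        if call.region_class not in RETAINED_CLASSES:
            continue
        rows.append(
            {
                "locus_id": locus_id(locus["chrom"], locus["pos"]),
                "chrom": locus["chrom"],
                "pos": int(locus["pos"]),
                "freq_group1": float(group1_freq[i]),
                "freq_group2": float(group2_freq[i]),
                "ancient_dosage": float(ancient_dosage[i]),
                "region_class": call.region_class,
                "gene_id": call.gene_id,
            }
        )
    columns = [
        "locus_id", "chrom", "pos", "freq_group1", "freq_group2",
        "ancient_dosage", "region_class", "gene_id",
    ]
    return pd.DataFrame(rows, columns=columns), class_counts
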