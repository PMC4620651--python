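"""Classification and tabulation of ancient-vs-reference sequence variants.

Builds the standard SNP/indel summary: counts stratified by zygosity and
transition/transversion class, per-cell database-membership percentages,
count-weighted means, and the genome-wide ti/tv ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import mutation_class

__all__ = [
    "VariantRecord",
    "VariantSummaryTable",
    "classify_variant",
    "tabulate",
    "table_from_cells",
    "titv_ratio",
    "apply_quality_filter",
]

_CELL_INDEX = ["variant_kind", "ancient_genotype", "mutation_class"]


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_kind: str  # snp / indel
    ancient_genotype: str  # heterozygous / homozygous
    mutation_class: str  # transition / transversion / not_applicable
    read_depth: int | None = None
    lod_score: float | None = None
    in_dbsnp: bool | None = None
    in_modern_panel: bool | None = None


def classify_variant(
    ref: str, alt: str, genotype: Sequence[str]
) -> tuple[str, str, str]:
    """Classify one variant -> (variant_kind, mutation_class, ancient_genotype).

    ``genotype`` is the pair of called ancient alleles (a single allele for a
    haploid call is accepted and treated as homozygous). Heterozygous means
    exactly one ancient allele differs from the reference; homozygous means
    all do.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt or not set(ref + alt) <= set("ACGT"):
        raise ValueError(f"alleles must be non-empty ACGT strings: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical — not a variant")
    kind = "snp" if len(ref) == 1 and len(alt) == 1 else "indel"
    mclass = mutation_class(ref, alt) if kind == "snp" else "not_applicable"
    alleles = [a.upper() for a in genotype]
    if not alleles:
        raise ValueError("empty genotype")
    n_nonref = sum(a != ref for a in alleles)
    if n_nonref == 0:
        raise ValueError(f"genotype {alleles} carries no non-reference allele")
    if len(alleles) == 1 or (n_nonref == len(alleles) and len(set(alleles)) == 1):
        zygosity = "homozygous"
    elif n_nonref == 1:
        zygosity = "heterozygous"
    else:
        # two distinct non-reference alleles: outside the biallelic scheme
        zygosity = "other"
    return kind, mclass, zygosity


@dataclass
class VariantSummaryTable:
    """Per-cell counts and membership percentages with derived summaries.

    ``cells`` is indexed by (variant_kind, ancient_genotype, mutation_class)
    and has columns count, pct_in_dbsnp, pct_in_modern_panel (percentages may
    be NaN when membership flags were unavailable). ``n_dropped`` counts
    records outside the biallelic heterozygous/homozygous scheme.
    """

    cells: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if list(self.cells.index.names) != _CELL_INDEX:
            raise ValueError(f"cells must be indexed by {_CELL_INDEX}")

    def total(self, kind: str) -> int:
        if kind not in self.cells.index.get_level_values("variant_kind"):
            return 0
        sub = self.cells.xs(kind, level="variant_kind")
        return int(sub["count"].sum())

    def homozygous_fraction(self, kind: str) -> float:
        sub = self.cells.xs(kind, level="variant_kind")
        hom = sub.xs("homozygous", level="ancient_genotype")["count"].sum()
        return float(hom / sub["count"].sum())

    def weighted_mean(self, kind: str, column: str) -> float:
        """Count-weighted mean of a per-cell percentage column."""
        sub = self.cells.xs(kind, level="variant_kind")
        ok = sub[column].notna()
        w = sub.loc[ok, "count"]
        return float((w * sub.loc[ok, column]).sum() / w.sum())


def tabulate(variants: Iterable[VariantRecord]) -> VariantSummaryTable:
    """Aggregate variant records into a :class:`VariantSummaryTable`.

    Cell percentages are computed from the raw membership flags; an empty
    input yields an empty table with zero totals.
    """
    rows = []
    dropped = 0
    for v in variants:
        if v.ancient_genotype not in ("heterozygous", "homozygous"):
            dropped += 1
            continue
        rows.append(
            (
                v.variant_kind,
                v.ancient_genotype,
                v.mutation_class,
                v.in_dbsnp,
                v.in_modern_panel,
            )
        )
    if not rows:
        cells = pd.DataFrame(
            columns=["count", "pct_in_dbsnp", "pct_in_modern_panel"],
            index=pd.MultiIndex.from_arrays([[], [], []], names=_CELL_INDEX),
        )
        return VariantSummaryTable(cells, dropped)
    df = pd.DataFrame(
        rows, columns=_CELL_INDEX + ["in_dbsnp", "in_modern_panel"]
    )
    grouped = df.groupby(_CELL_INDEX, sort=True)
    cells = grouped.size().rename("count").to_frame()
    for flag, col in (("in_dbsnp", "pct_in_dbsnp"), ("in_modern_panel", "pct_in_modern_panel")):
        cells[col] = grouped[flag].apply(
            lambda s: 100.0 * s.mean() if s.notna().all() else np.nan
        )
    return VariantSummaryTable(cells, dropped)


def table_from_cells(
    cells: Sequence[tuple[str, str, str, int, float | None, float | None]],
) -> VariantSummaryTable:
    """Build a summary table directly from published per-cell numbers.

    Each entry is (variant_kind, ancient_genotype, mutation_class, count,
    pct_in_dbsnp, pct_in_modern_panel); weighted means are then taken over
    the supplied (typically rounded, as-printed) percentages.
    """
    df = pd.DataFrame(
        cells,
        columns=_CELL_INDEX + ["count", "pct_in_dbsnp", "pct_in_modern_panel"],
    ).set_index(_CELL_INDEX)
    return VariantSummaryTable(df.astype(float).astype({"count": int}))


def titv_ratio(table: VariantSummaryTable) -> float:
    """Transition/transversion ratio over all SNP cells."""
    snp = table.cells.xs("snp", level="variant_kind")
    ti = snp.xs("transition", level="mutation_class")["count"].sum()
    tv = snp.xs("transversion", level="mutation_class")["count"].sum()
    if tv == 0:
        raise ValueError("no transversions — ti/tv undefined")
    return float(ti / tv)


def apply_quality_filter(
    variants: Sequence[VariantRecord],
    min_depth: int = 5,
    min_lod: float = 2.0,
    require_lod: bool = True,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Composite quality filter: depth >= min_depth AND LOD > min_lod.

    The depth bound is inclusive, the LOD bound exclusive. Returns the
    survivors plus before/after counts; a missing LOD score is an error
    unless ``require_lod=False`` (then only the depth condition applies).
    """
    kept = []
    for v in variants:
        if v.read_depth is None:
            raise ValueError(f"{v.chrom}:{v.pos}: missing read depth")
        if v.lod_score is None and require_lod:
            raise ValueError(
                f"{v.chrom}:{v.pos}: missing LOD score (use require_lod=False)"
            )
        if v.read_depth < min_depth:
            continue
        if v.lod_score is not None and not v.lod_score > min_lod:
            continue
        kept.append(v)
    counts = {"before": len(variants), "after": len(kept)}
    return kept, counts
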