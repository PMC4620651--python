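"""Sample-authenticity suite for a putatively ancient genome.

Four lines of evidence, mirroring standard ancient-DNA practice:

* contamination bounds from per-read allele classification at diagnostic
  SNPs (mitochondrial, or hemizygous-X for a male nuclear genome);
* molecular sex from the X/autosome read-depth ratio;
* fragment-length distribution of mapped inserts;
* terminal C->T / G->A deamination profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DiagnosticPanel, ReadObservationSet

__all__ = [
    "ContaminationEstimate",
    "SexAssignment",
    "FragmentLengthSummary",
    "DamageProfile",
    "estimate_contamination",
    "estimate_x_contamination",
    "infer_sex",
    "summarize_fragment_lengths",
    "damage_profile",
]


@dataclass
class ContaminationEstimate:
    informative_reads: int
    contaminant_reads: int
    mode: str  # "all_sites" or "transversions_only"
    interval_pct: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_reads <= self.informative_reads:
            raise ValueError("contaminant reads must lie in [0, informative reads]")

    @property
    def estimate_pct(self) -> float:
        return 100.0 * self.contaminant_reads / self.informative_reads


@dataclass
class SexAssignment:
    x_mean_depth: float
    autosomal_mean_depth: float
    call: str  # male / female / ambiguous

    @property
    def ratio(self) -> float:
        return self.x_mean_depth / self.autosomal_mean_depth


@dataclass
class FragmentLengthSummary:
    n_fragments: int
    median_bp: int
    fraction_in_range: dict[tuple[int, int], float]


@dataclass
class DamageProfile:
    """Terminal substitution rates conditioned on the reference base.

    ``rates`` has one row per (end, position, ref_base, read_base) with the
    observation count, the conditioning total and the rate; positions run
    1..k from the respective read end. Rates at positions with no
    conditioning observations are absent, not zero.
    """

    k_positions: int
    rates: pd.DataFrame
    totals: pd.DataFrame

    def rate(self, end: str, position: int, ref_base: str, read_base: str) -> float:
        tot = self.totals[
            (self.totals["end"] == end)
            & (self.totals["position"] == position)
            & (self.totals["ref_base"] == ref_base)
        ]
        if tot.empty:  # no conditioning observations: rate undefined, not 0
            return float("nan")
        sel = self.rates[
            (self.rates["end"] == end)
            & (self.rates["position"] == position)
            & (self.rates["ref_base"] == ref_base)
            & (self.rates["read_base"] == read_base)
        ]
        if sel.empty:
            return 0.0
        return float(sel["rate"].iloc[0])

    def ct_5prime(self, position: int) -> float:
        return self.rate("5p", position, "C", "T")

    def ga_3prime(self, position: int) -> float:
        return self.rate("3p", position, "G", "A")


def _classify_reads(
    reads: ReadObservationSet, panel: DiagnosticPanel
) -> tuple[int, int]:
    """Count informative and contaminant reads against a diagnostic panel.

    A read overlapping several panel loci counts once: contaminant if ANY
    overlapped locus shows a contaminant-class allele, informative if at
    least one overlapped locus shows either allele class. Reads showing
    neither class anywhere (third alleles from sequencing error) are
    uninformative and dropped.
    """
    endog = dict(zip(panel.locus_ids, panel.table["endogenous_allele"]))
    contam = {
        lid: set(alleles)
        for lid, alleles in zip(panel.locus_ids, panel.table["contaminant_alleles"])
    }
    obs = reads.observations
    obs = obs[obs["locus_id"].isin(endog)]
    if obs.empty:
        return 0, 0
    is_endog = np.fromiter(
        (a == endog[l] for l, a in zip(obs["locus_id"], obs["allele"])),
        dtype=bool,
        count=len(obs),
    )
    is_contam = np.fromiter(
        (a in contam[l] for l, a in zip(obs["locus_id"], obs["allele"])),
        dtype=bool,
        count=len(obs),
    )
    per_read = pd.DataFrame(
        {"read_id": obs["read_id"].to_numpy(), "e": is_endog, "c": is_contam}
    ).groupby("read_id", sort=False).any()
    informative = per_read[per_read["e"] | per_read["c"]]
    return len(informative), int(informative["c"].sum())


def estimate_contamination(
    reads: ReadObservationSet,
    panel: DiagnosticPanel,
    transversions_only: bool = False,
    interval_method: str | None = None,
) -> ContaminationEstimate:
    """Upper-bound contamination fraction from diagnostic-site read classes.

    Each read overlapping the panel is classified as endogenous or
    contaminant by the allele it carries; the estimate is the contaminant
    fraction of informative reads, in percent. ``transversions_only``
    restricts the panel to transversion-class loci, which are immune to
    post-mortem deamination artefacts. ``interval_method="jeffreys"`` adds a
    95 % Jeffreys binomial interval.
    """
    if len(panel.table) == 0:
        raise ValueError("empty diagnostic panel")
    if transversions_only:
        panel = panel.restrict("transversion")
    informative, contaminant = _classify_reads(reads, panel)
    if informative == 0:
        raise ValueError("no informative reads overlap the panel")
    interval = None
    if interval_method == "jeffreys":
        lo = stats.beta.ppf(0.025, contaminant + 0.5, informative - contaminant + 0.5)
        hi = stats.beta.ppf(0.975, contaminant + 0.5, informative - contaminant + 0.5)
        if contaminant == 0:
            lo = 0.0
        if contaminant == informative:
            hi = 1.0
        interval = (100.0 * lo, 100.0 * hi)
    elif interval_method is not None:
        raise ValueError(f"unknown interval method {interval_method!r}")
    mode = "transversions_only" if transversions_only else "all_sites"
    return ContaminationEstimate(informative, contaminant, mode, interval)


def estimate_x_contamination(
    reads: ReadObservationSet,
    panels: Mapping[str, DiagnosticPanel],
    sex: SexAssignment,
    interval_method: str | None = None,
) -> dict[str, ContaminationEstimate]:
    """Nuclear contamination from hemizygous-X diagnostic sites, per source.

    Valid only for a male sample: with one X copy, any read carrying a
    non-consensus diagnostic allele must be exogenous. ``panels`` maps each
    putative contaminating population to its own diagnostic panel; one
    estimate is returned per source.
    """
    if sex.call != "male":
        raise ValueError(
            f"X-hemizygosity contamination estimation requires a male sample; "
            f"sex call is {sex.call!r} (ratio {sex.ratio:.2f})"
        )
    return {
        source: estimate_contamination(reads, panel, interval_method=interval_method)
        for source, panel in panels.items()
    }


def infer_sex(
    depth_by_chrom: Mapping[str, float],
    autosome_list: Sequence[str],
    x_name: str = "X",
    male_max: float = 0.6,
    female_min: float = 0.8,
) -> SexAssignment:
    """Call sex from the ratio of X to mean autosomal fold-coverage.

    A male (one X) sits near 0.5, a female near 1.0; the gap between
    ``male_max`` and ``female_min`` is reported ambiguous rather than forced.
    """
    if x_name not in depth_by_chrom:
        raise ValueError(f"X chromosome {x_name!r} absent from depth table")
    autosomes = [c for c in autosome_list if c in depth_by_chrom]
    if not autosomes:
        raise ValueError("no autosomes present in depth table")
    auto_mean = float(np.mean([depth_by_chrom[c] for c in autosomes]))
    if auto_mean == 0:
        raise ValueError("autosomal mean depth is zero")
    ratio = depth_by_chrom[x_name] / auto_mean
    if ratio < male_max:
        call = "male"
    elif ratio > female_min:
        call = "female"
    else:
        call = "ambiguous"
    return SexAssignment(float(depth_by_chrom[x_name]), auto_mean, call)


def summarize_fragment_lengths(
    lengths: Sequence[int], ranges: Sequence[tuple[int, int]] = ((16, 150),)
) -> FragmentLengthSummary:
    """Median fragment length and inclusive per-range proportions.

    The median is the lower median for even counts, keeping the summary an
    observed length.
    """
    arr = np.sort(np.asarray(lengths, dtype=int))
    if arr.size == 0:
        raise ValueError("no fragment lengths supplied")
    median = int(arr[(arr.size - 1) // 2])
    fractions = {
        (lo, hi): float(np.mean((arr >= lo) & (arr <= hi))) for lo, hi in ranges
    }
    return FragmentLengthSummary(int(arr.size), median, fractions)


def damage_profile(reads: ReadObservationSet, k_positions: int = 25) -> DamageProfile:
    """Empirical terminal substitution rates from per-read mismatch tracks.

    For each end and distance d = 1..k, rate(X->Y, d) is the fraction of
    reads with reference base X at d whose read base is Y. Authentic ancient
    libraries show C->T inflation at the 5' end and G->A at the 3' end
    decaying into the read.
    """
    if reads.mismatches is None or reads.mismatches.empty:
        raise ValueError("read set carries no terminal mismatch track")
    mm = reads.mismatches
    mm = mm[mm["position"] <= k_positions]
    counts = (
        mm.groupby(["end", "position", "ref_base", "read_base"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = (
        mm.groupby(["end", "position", "ref_base"], sort=True)
        .size()
        .rename("total")
        .reset_index()
    )
    rates = counts.merge(totals, on=["end", "position", "ref_base"])
    rates["rate"] = rates["count"] / rates["total"]
    return DamageProfile(k_positions, rates, totals)
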