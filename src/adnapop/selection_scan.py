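"""Windowed HKA-style scan for selective sweeps.

Contrasts within-ingroup polymorphism (S) against fixed divergence from an
outgroup (Dv) in genomic windows. Absent selection the S:Dv ratio is
roughly constant genome-wide; a local deficit of polymorphism relative to
divergence is the footprint of a selective sweep. Each window's expected
counts come from the genome-wide totals excluding the window itself
(leave-one-out), the statistic is the 1-df chi-square form, and q-values are
Benjamini-Hochberg adjusted across testable windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeTable

__all__ = ["HKAWindow", "window_counts", "hka_scan", "bh_adjust", "tile_windows"]

WINDOW_COLUMNS = [
    "chrom", "start", "end", "L", "S", "Dv",
    "E_S", "E_Dv", "stat", "p", "q", "direction", "testable",
]


@dataclass
class HKAWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    L: int  # sites assessed
    S: int  # segregating within ingroup
    Dv: int  # fixed differences from outgroup
    E_S: float = float("nan")
    E_Dv: float = float("nan")
    stat: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    direction: str = ""
    testable: bool = True


def tile_windows(
    chrom_lengths: dict[str, int], width: int = 50_000
) -> pd.DataFrame:
    """Fixed-width tiling (0-based half-open) of each chromosome."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _site_classes(
    gt: GenotypeTable, ingroup_idx: list[int], outgroup_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (assessed, segregating, divergent) boolean arrays.

    A site is assessed when the outgroup carries an unambiguous single
    allele (haploid call, or homozygous diploid call) and at least one
    ingroup allele copy was observed. Segregating = both alleles present in
    the ingroup; divergent = ingroup monomorphic and its allele differs from
    the outgroup allele.
    """
    sub = gt.dosages[:, ingroup_idx]
    ploidy = gt.ploidy[ingroup_idx]
    obs = ~np.isnan(sub)
    copies = (obs * ploidy[None, :]).sum(axis=1)
    alt = np.nansum(sub, axis=1)
    out_dose = gt.dosages[:, outgroup_idx]
    out_ploidy = gt.ploidy[outgroup_idx]
    # outgroup allele: 0 = ref, 1 = alt; heterozygous diploid outgroup calls
    # carry no single allele and drop the site from L
    out_called = ~np.isnan(out_dose) & ((out_dose == 0) | (out_dose == out_ploidy))
    assessed = out_called & (copies > 0)
    seg = assessed & (alt > 0) & (alt < copies)
    mono_allele = np.where(alt == copies, 1.0, 0.0)  # valid only when monomorphic
    out_allele = np.where(out_dose == 0, 0.0, 1.0)
    div = assessed & ~seg & (mono_allele != out_allele)
    return assessed, seg, div


def window_counts(
    gt: GenotypeTable,
    ingroup_samples: Sequence[str],
    outgroup_sample: str,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-window HKA counts (L, S, Dv) for BED-style half-open windows.

    Windows with no assessed site are retained with zero counts and flagged
    untestable.
    """
    for col in ("chrom", "start", "end"):
        if col not in windows.columns:
            raise ValueError("windows need chrom/start/end columns")
    ingroup_idx = [gt.sample_index(s) for s in ingroup_samples]
    outgroup_idx = gt.sample_index(outgroup_sample)
    assessed, seg, div = _site_classes(gt, ingroup_idx, outgroup_idx)
    pos0 = gt.loci["pos"].to_numpy() - 1  # to 0-based
    chroms = gt.loci["chrom"].to_numpy()
    rows = []
    for w in windows.itertuples():
        in_w = (chroms == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        L = int((assessed & in_w).sum())
        S = int((seg & in_w).sum())
        Dv = int((div & in_w).sum())
        rows.append(
            {
                "chrom": w.chrom, "start": int(w.start), "end": int(w.end),
                "L": L, "S": S, "Dv": Dv, "E_S": np.nan, "E_Dv": np.nan,
                "stat": np.nan, "p": np.nan, "q": np.nan,
                "direction": "", "testable": L > 0,
            }
        )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def counts_frame(
    L: np.ndarray, S: np.ndarray, Dv: np.ndarray, chrom: str = "1"
) -> pd.DataFrame:
    """Assemble a windows frame from raw per-window counts (unit spacing)."""
    L = np.asarray(L, dtype=int)
    n = len(L)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n),
            "end": np.arange(1, n + 1),
            "L": L,
            "S": np.asarray(S, dtype=int),
            "Dv": np.asarray(Dv, dtype=int),
            "E_S": np.nan,
            "E_Dv": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "q": np.nan,
            "direction": "",
            "testable": L > 0,
        },
        columns=WINDOW_COLUMNS,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hka_scan(windows: pd.DataFrame) -> pd.DataFrame:
    """Fill stat/p/q/direction for windows carrying (L, S, Dv) counts.

    Expected counts for each window use genome totals with that window's own
    counts removed, so a strong sweep does not dilute its own null. Windows
    where a leave-one-out expectation is zero fall back to a Fisher exact
    test on the 2x2 (window vs rest) x (S vs Dv) table.
    """
    out = windows.copy().reset_index(drop=True)
    s = out["S"].to_numpy(dtype=float)
    dv = out["Dv"].to_numpy(dtype=float)
    s_tot, dv_tot = s.sum(), dv.sum()
    if s_tot <= 0 or dv_tot <= 0:
        raise ValueError("genome totals of S and Dv must both be positive")
    testable = out["testable"].to_numpy(dtype=bool) & ((s + dv) > 0)
    if testable.sum() < 2:
        raise ValueError("need >= 2 testable windows")
    s_rest, dv_rest = s_tot - s, dv_tot - dv
    rest = s_rest + dv_rest
    if np.any(testable & (rest <= 0)):
        raise ValueError("all counts concentrated in one window")
    rest = np.where(rest > 0, rest, np.nan)
    total_i = s + dv
    e_s = np.where(testable, total_i * s_rest / rest, np.nan)
    e_dv = np.where(testable, total_i * dv_rest / rest, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (s - e_s) ** 2 / e_s + (dv - e_dv) ** 2 / e_dv
        pvals = stats.chi2.sf(stat, df=1)
    degenerate = testable & ((e_s == 0) | (e_dv == 0))
    for i in np.nonzero(degenerate)[0]:
        table = np.array([[s[i], dv[i]], [s_rest[i], dv_rest[i]]], dtype=int)
        pvals[i] = stats.fisher_exact(table)[1]
        stat[i] = np.nan
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out["E_S"], out["E_Dv"] = e_s, e_dv
    out["stat"] = np.where(testable, stat, np.nan)
    out["p"] = np.where(testable, pvals, np.nan)
    q = np.full(len(out), np.nan)
    q[testable] = bh_adjust(pvals[testable])
    out["q"] = q
    direction = np.where(s < e_s, "polymorphism_deficit", "polymorphism_excess")
    out["direction"] = np.where(testable, direction, "")
    out["testable"] = testable
    return out
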