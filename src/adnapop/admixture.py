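"""Frequency-based admixture statistics with weighted block-jackknife errors.

Implements the ABBA/BABA D statistic for the four-population topology
(((P1, P2), A), O) and the three-population f3 test, both on population
allele frequencies, with significance from a delete-one-block weighted
jackknife over contiguous SNP blocks (robust to linkage).

With alt-allele frequencies p1, p2, pA, pO the per-site pattern weights in
the default, polarization-free form are

    ABBA = (1-p1) p2 pA (1-pO) + p1 (1-p2) (1-pA) pO
    BABA = p1 (1-p2) pA (1-pO) + (1-p1) p2 (1-pA) pO

and D = sum(ABBA - BABA) / sum(ABBA + BABA). D > 0 indicates excess allele
sharing between A and P2, D < 0 between A and P1. The f3 statistic for a
target X and sources (S1, S2) is the mean over sites of (x-a)(x-b), with an
optional finite-sample correction x(1-x)/(n_x - 1); a significantly negative
value indicates X is admixed between the sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FrequencyTable

__all__ = [
    "DStatResult",
    "F3Result",
    "BlockScheme",
    "contiguous_blocks",
    "block_jackknife",
    "d_statistic",
    "f3_statistic",
    "population_mean_d",
]


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    n_sites_used: int
    sum_abba: float
    sum_baba: float
    n_blocks: int
    p1: str
    p2: str
    ancient: str
    outgroup: str
    n_sites_skipped: int = 0


@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    n_sites_used: int
    n_blocks: int
    target: str
    source1: str
    source2: str
    bias_corrected: bool
    n_sites_skipped: int = 0


@dataclass
class BlockScheme:
    """Assignment of used loci to contiguous blocks with per-block weights."""

    labels: np.ndarray  # block index per used locus
    weights: np.ndarray  # informative sites per block

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.labels.size and self.weights.sum() != self.labels.size:
            raise ValueError("block weights must sum to the number of used loci")

    @property
    def n_blocks(self) -> int:
        return len(self.weights)


def contiguous_blocks(n_sites: int, block_size: int = 50) -> BlockScheme:
    """Blocks of ``block_size`` consecutive used SNPs (last block may be short)."""
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    labels = np.arange(n_sites) // block_size
    weights = np.bincount(labels) if n_sites else np.array([])
    return BlockScheme(labels, weights)


def block_jackknife(
    block_numerators: np.ndarray,
    block_denominators: np.ndarray,
    block_weights: np.ndarray,
) -> tuple[float, float, float]:
    """Weighted delete-one-block jackknife for a ratio statistic.

    Returns (estimate, se, z). The estimate is sum(num)/sum(den); the
    variance uses the delete-m_j jackknife with unequal block weights m_j
    (Busing's formula), which reduces to the ordinary delete-one jackknife
    when all weights are equal. With no between-block variation the standard
    error is exactly 0 and z is reported as ±inf (or NaN for a 0 estimate).
    """
    num = np.asarray(block_numerators, dtype=float)
    den = np.asarray(block_denominators, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    if not (num.shape == den.shape == m.shape):
        raise ValueError("blocks arrays must have identical shape")
    nonzero = m > 0
    num, den, m = num[nonzero], den[nonzero], m[nonzero]
    g = len(m)
    if g < 2:
        raise ValueError("need >= 2 blocks with nonzero weight")
    n = m.sum()
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        raise ValueError("no informative sites (zero denominator)")
    theta = tot_num / tot_den
    loo_den = tot_den - den
    if np.any(loo_den == 0):
        raise ValueError("all weight concentrated in one block")
    theta_loo = (tot_num - num) / loo_den
    h = n / m
    tau = h * theta - (h - 1.0) * theta_loo  # pseudovalues
    theta_j = g * theta - np.sum((1.0 - m / n) * theta_loo)
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = float(theta / se) if se > 0 else float(np.sign(theta) * np.inf)
    if se == 0 and theta == 0:
        z = float("nan")
    return float(theta), se, z


def _site_patterns(
    p1: np.ndarray, p2: np.ndarray, pa: np.ndarray, po: np.ndarray, polarize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (abba, baba, used-mask) under the chosen polarization rule."""
    used = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(pa) | np.isnan(po))
    if polarize:
        used &= (po == 0.0) | (po == 1.0)
    q1, q2, qa, qo = 1 - p1, 1 - p2, 1 - pa, 1 - po
    if polarize:
        abba = q1 * p2 * pa * qo
        baba = p1 * q2 * pa * qo
    else:
        abba = q1 * p2 * pa * qo + p1 * q2 * qa * po
        baba = p1 * q2 * pa * qo + q1 * p2 * qa * po
    return abba, baba, used


def d_statistic(
    freqs: FrequencyTable,
    p1: str,
    p2: str,
    ancient: str,
    outgroup: str,
    block_size: int = 50,
    polarize: bool = False,
) -> DStatResult:
    """ABBA/BABA D statistic for (((P1, P2), A), O) with jackknife z-score.

    Sites with a missing frequency in any of the four populations are
    skipped and tallied. The default symmetric form tolerates outgroup
    polymorphism; ``polarize=True`` instead keeps only sites where the
    outgroup is fixed and counts derived-allele patterns alone.
    """
    f1, f2 = freqs.column(p1), freqs.column(p2)
    fa, fo = freqs.column(ancient), freqs.column(outgroup)
    abba, baba, used = _site_patterns(f1, f2, fa, fo, polarize)
    abba, baba = abba[used], baba[used]
    n_used = int(used.sum())
    n_skipped = int(len(used) - n_used)
    scheme = contiguous_blocks(n_used, block_size)
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("no informative sites (ABBA + BABA sums to zero)")
    bnum = np.bincount(scheme.labels, weights=num, minlength=scheme.n_blocks)
    bden = np.bincount(scheme.labels, weights=den, minlength=scheme.n_blocks)
    d, se, z = block_jackknife(bnum, bden, scheme.weights)
    return DStatResult(
        d, se, z, n_used, float(abba.sum()), float(baba.sum()),
        scheme.n_blocks, p1, p2, ancient, outgroup, n_skipped,
    )


def f3_statistic(
    freqs: FrequencyTable,
    target: str,
    source1: str,
    source2: str,
    block_size: int = 50,
    bias_correction: bool = True,
) -> F3Result:
    """Three-population test f3(target; source1, source2) with jackknife z.

    The per-site term (x-a)(x-b) is averaged over sites; the finite-sample
    correction subtracts x(1-x)/(n_x-1), requiring at least 2 observed
    allele copies in the target at every used site.
    """
    x = freqs.column(target)
    a = freqs.column(source1)
    b = freqs.column(source2)
    used = ~(np.isnan(x) | np.isnan(a) | np.isnan(b))
    nx = freqs.copies(target).astype(float)
    if bias_correction:
        if np.any(used & (nx < 2)):
            raise ValueError(
                "bias correction requires >= 2 target allele copies per site"
            )
    term = (x - a) * (x - b)
    if bias_correction:
        term = term - x * (1 - x) / (nx - 1)
    term = term[used]
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no informative sites")
    scheme = contiguous_blocks(n_used, block_size)
    bnum = np.bincount(scheme.labels, weights=term, minlength=scheme.n_blocks)
    bden = scheme.weights.copy()  # mean over sites: denominator = site count
    f3, se, z = block_jackknife(bnum, bden, scheme.weights)
    return F3Result(
        f3, se, z, n_used, scheme.n_blocks, target, source1, source2,
        bias_correction, int(len(used) - n_used),
    )


def population_mean_d(
    freqs: FrequencyTable,
    p1_list: Sequence[str],
    p2_panel: Sequence[str],
    ancient: str,
    outgroup: str,
    block_size: int = 50,
    polarize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """D for every (P1, P2) pair plus the per-P1 mean over the P2 panel.

    Returns (pair_table, mean_table); the mean table is the input for a
    geographic summary of per-breed admixture signal.
    """
    if not p2_panel:
        raise ValueError("empty P2 panel")
    rows = []
    for pop1 in p1_list:
        for pop2 in p2_panel:
            r = d_statistic(freqs, pop1, pop2, ancient, outgroup, block_size, polarize)
            rows.append(
                (pop1, pop2, r.d, r.se, r.z, r.sum_abba, r.sum_baba,
                 r.n_sites_used, r.n_blocks)
            )
    pairs = pd.DataFrame(
        rows,
        columns=["p1", "p2", "d", "se", "z", "sum_abba", "sum_baba",
                 "n_sites", "n_blocks"],
    )
    means = (
        pairs.groupby("p1", sort=False)["d"].mean().rename("mean_d").reset_index()
    )
    return pairs, means
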