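"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* ``simulate_panel`` — multi-population biallelic genotype panels evolved by
  Balding-Nichols beta drift along the fixed tree (((P1, P2), A), O), with a
  tunable introgression fraction f from the divergent A ("aurochs") lineage
  into one test population. Drift in frequency space rather than a
  coalescent keeps the expected sign and magnitude of D and f3 analytically
  transparent at desk scale.
* ``simulate_ancient_reads`` — read-level observations at a diagnostic
  panel with a known modern-contamination fraction, truncated log-normal
  fragment lengths (median ~50 bp), and exponential-decay terminal C->T /
  G->A damage on endogenous reads.
* ``simulate_sweep_panel`` — windowed genotype panels where a chosen subset
  of windows has ingroup diversity suppressed by a known factor, divergence
  unchanged (the HKA sweep signature).

All generators are deterministic under a fixed seed and emit a truth record
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GenotypeTable, PopulationMap, ReadObservationSet, locus_id

__all__ = [
    "DemographyParams",
    "AncientReadParams",
    "simulate_panel",
    "simulate_ancient_reads",
    "simulate_sweep_panel",
]

_BASES = np.array(["A", "C", "G", "T"])

# Per-branch Balding-Nichols drift intensities for (((P1, P2), A), O):
# a deep outgroup (yak-like), a moderately diverged wild lineage, and
# closely related domestic test populations (breed-scale Fst ~ 0.05).
DEFAULT_DRIFT = {
    "O": 0.80,
    "mid": 0.10,   # root -> ancestor of ((P1, P2), A)
    "A": 0.20,
    "stem": 0.05,  # -> ancestor of (P1, P2)
    "P1": 0.05,
    "P2": 0.05,
}


@dataclass
class DemographyParams:
    """Parameters of the four-population drift simulation."""

    n_loci: int = 15_000  # mirrors a ~15k-SNP genotyping panel
    p0_low: float = 0.05  # ancestral frequency ~ Uniform(low, high)
    p0_high: float = 0.95
    drift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    introgression: float = 0.0  # fraction f of the target's ancestry from A
    target: str = "P2"
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"P1": 20, "P2": 20, "A": 1, "O": 20}
    )
    ancient_pseudo_haploid: bool = False  # A sampled as one allele per locus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if not 0.0 <= self.introgression <= 1.0:
            raise ValueError("introgression fraction must lie in [0, 1]")
        if self.target not in ("P1", "P2"):
            raise ValueError("introgression target must be P1 or P2")
        if set(self.drift) != set(DEFAULT_DRIFT):
            raise ValueError(f"drift must have keys {sorted(DEFAULT_DRIFT)}")
        if any(v < 0 or v >= 1 for v in self.drift.values()):
            raise ValueError("drift intensities must lie in [0, 1)")
        if set(self.sample_sizes) != {"P1", "P2", "A", "O"}:
            raise ValueError("sample_sizes must cover P1, P2, A, O")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be positive")
        if not 0 <= self.p0_low < self.p0_high <= 1:
            raise ValueError("need 0 <= p0_low < p0_high <= 1")


def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f == 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]  # fixed alleles stay fixed under drift
    out[interior] = rng.beta(a[interior], b[interior])
    return out


def simulate_panel(
    params: DemographyParams,
) -> tuple[GenotypeTable, PopulationMap, dict]:
    """Simulate genotypes for the four-population tree with introgression.

    Latent per-population frequencies evolve by beta drift down the tree;
    introgression replaces the target's frequency with
    (1-f) * p_target + f * p_A. Genotypes are binomial draws; the ancient
    population A may be emitted pseudo-haploid. The truth record carries all
    latent frequencies, f and the seed.
    """
    rng = np.random.default_rng(params.seed)
    d = params.drift
    p0 = rng.uniform(params.p0_low, params.p0_high, params.n_loci)
    p_o = _bn_drift(p0, d["O"], rng)
    p_mid = _bn_drift(p0, d["mid"], rng)
    p_a = _bn_drift(p_mid, d["A"], rng)
    p_stem = _bn_drift(p_mid, d["stem"], rng)
    p_p1 = _bn_drift(p_stem, d["P1"], rng)
    p_p2 = _bn_drift(p_stem, d["P2"], rng)
    f = params.introgression
    if f > 0:
        if params.target == "P1":
            p_p1 = (1 - f) * p_p1 + f * p_a
        else:
            p_p2 = (1 - f) * p_p2 + f * p_a
    latent = {"P1": p_p1, "P2": p_p2, "A": p_a, "O": p_o}

    sample_ids: list[str] = []
    pops: dict[str, str] = {}
    ploidies: list[int] = []
    columns: list[np.ndarray] = []
    for pop in ("P1", "P2", "A", "O"):
        ploidy = 1 if (pop == "A" and params.ancient_pseudo_haploid) else 2
        for k in range(params.sample_sizes[pop]):
            sid = f"{pop}_{k}"
            sample_ids.append(sid)
            pops[sid] = pop
            ploidies.append(ploidy)
            columns.append(rng.binomial(ploidy, latent[pop]).astype(float))
    dosages = np.column_stack(columns)
    ref = rng.integers(0, 4, params.n_loci)
    alt = (ref + rng.integers(1, 4, params.n_loci)) % 4
    loci = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, params.n_loci + 1) * 100,
            "ref_allele": _BASES[ref],
            "alt_allele": _BASES[alt],
        }
    )
    gt = GenotypeTable(sample_ids, loci, dosages, np.array(ploidies))
    pop_map = PopulationMap(pops, {p: p for p in ("P1", "P2", "A", "O")})
    truth = {
        "seed": params.seed,
        "introgression": f,
        "target": params.target,
        "latent_frequencies": latent,
        "ancestral_frequency": p0,
    }
    return gt, pop_map, truth


@dataclass
class AncientReadParams:
    """Parameters of the ancient-read simulator."""

    n_reads: int = 10_000
    contamination: float = 0.0
    length_median_bp: float = 50.0  # log-normal median, ancient-typical
    length_log_sd: float = 0.35
    min_length_bp: int = 16
    damage_max: float = 0.3     # terminal C->T / G->A rate at position 1
    damage_lambda: float = 0.5  # per-position decay of the damage rate
    seq_error: float = 0.001
    damage_k: int = 10  # terminal positions with an emitted mismatch track
    damage_on_contaminant: bool = False  # modern contaminant DNA is undamaged
    emit_lengths: bool = True
    emit_damage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must lie in [0, 1]")
        if not 0.0 <= self.damage_max <= 1.0 or not 0.0 <= self.seq_error <= 1.0:
            raise ValueError("damage_max and seq_error must lie in [0, 1]")
        if not 0.0 < self.damage_lambda < 1.0:
            raise ValueError("damage_lambda must lie in (0, 1)")
        if self.length_median_bp <= 0 or self.length_log_sd <= 0:
            raise ValueError("length model parameters must be positive")


def _apply_seq_error(
    bases: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each base to a uniformly chosen different base with prob ``rate``."""
    if rate == 0:
        return bases
    flip = rng.random(bases.size) < rate
    if flip.any():
        idx = np.searchsorted(_BASES, bases[flip])
        shift = rng.integers(1, 4, flip.sum())
        bases = bases.copy()
        bases[flip] = _BASES[(idx + shift) % 4]
    return bases


def simulate_ancient_reads(
    params: AncientReadParams,
    endogenous_haplotype: Mapping[str, str],
    contaminant_haplotype: Mapping[str, str],
) -> tuple[ReadObservationSet, dict]:
    """Simulate per-read allele observations at a diagnostic panel.

    Each read covers one uniformly chosen panel locus, is contaminant with
    probability c, carries the corresponding haplotype's allele subject to
    sequencing error, and (endogenous reads only, by default) receives
    exponential-decay C->T 5' and G->A 3' terminal damage in its mismatch
    track. Fragment lengths are truncated log-normal.
    """
    loci = sorted(endogenous_haplotype)
    if sorted(contaminant_haplotype) != loci:
        raise ValueError("haplotypes must define alleles at the same loci")
    if not loci:
        raise ValueError("empty haplotypes")
    rng = np.random.default_rng(params.seed)
    n = params.n_reads
    read_ids = np.array([f"r{i:07d}" for i in range(n)])
    is_contam = rng.random(n) < params.contamination
    which = rng.integers(0, len(loci), n)
    endo = np.array([endogenous_haplotype[l] for l in loci])
    cont = np.array([contaminant_haplotype[l] for l in loci])
    alleles = np.where(is_contam, cont[which], endo[which])
    alleles = _apply_seq_error(alleles, params.seq_error, rng)
    obs = pd.DataFrame(
        {
            "read_id": read_ids,
            "locus_id": np.array(loci, dtype=object)[which],
            "allele": alleles,
        }
    )

    lengths = None
    if params.emit_lengths:
        raw = rng.lognormal(np.log(params.length_median_bp), params.length_log_sd, n)
        short = raw < params.min_length_bp
        while short.any():  # truncate by resampling below the minimum
            raw[short] = rng.lognormal(
                np.log(params.length_median_bp), params.length_log_sd, short.sum()
            )
            short = raw < params.min_length_bp
        lengths = pd.DataFrame(
            {"read_id": read_ids, "length_bp": np.round(raw).astype(int)}
        )

    mismatches = None
    if params.emit_damage:
        k = params.damage_k
        d_rate = params.damage_max * params.damage_lambda ** np.arange(k)
        frames = []
        for end, damage_ref, damage_read in (("5p", "C", "T"), ("3p", "G", "A")):
            refs = _BASES[rng.integers(0, 4, (n, k))]
            reads = refs.copy()
            damaged = (
                (refs == damage_ref)
                & (rng.random((n, k)) < d_rate[None, :])
                & (params.damage_on_contaminant | ~is_contam)[:, None]
            )
            reads[damaged] = damage_read
            reads = _apply_seq_error(reads.ravel(), params.seq_error, rng).reshape(
                n, k
            )
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": np.repeat(read_ids, k),
                        "end": end,
                        "position": np.tile(np.arange(1, k + 1), n),
                        "ref_base": refs.ravel(),
                        "read_base": reads.ravel(),
                    }
                )
            )
        mismatches = pd.concat(frames, ignore_index=True)

    reads = ReadObservationSet(obs, lengths, mismatches)
    truth = {
        "seed": params.seed,
        "contamination": params.contamination,
        "n_contaminant": int(is_contam.sum()),
        "is_contaminant": is_contam,
        "damage_rates": params.damage_max
        * params.damage_lambda ** np.arange(params.damage_k),
    }
    return reads, truth


def simulate_sweep_panel(
    n_windows: int = 200,
    n_sweeps: int = 5,
    diversity_reduction: float = 10.0,
    window_size: int = 50_000,
    loci_per_window: int = 300,
    n_ingroup: int = 20,
    base_poly_rate: float = 0.5,
    base_div_rate: float = 0.10,
    seed: int = 0,
) -> tuple[GenotypeTable, pd.DataFrame, dict]:
    """Windowed ingroup+outgroup panel with planted low-diversity windows.

    Every window receives candidate sites at the same density; in sweep
    windows the per-site polymorphism probability is divided by
    ``diversity_reduction`` while the divergence probability is unchanged.
    Returns the genotype table (diploid ingroup samples plus a haploid
    outgroup sample named ``ancient``), the BED-style window table and a
    truth record listing the sweep window indices.
    """
    if n_sweeps > n_windows:
        raise ValueError("n_sweeps cannot exceed n_windows")
    if diversity_reduction < 1.0:
        raise ValueError("diversity_reduction must be >= 1")
    if base_poly_rate + base_div_rate > 1.0:
        raise ValueError("base polymorphism + divergence rates must be <= 1")
    rng = np.random.default_rng(seed)
    sweep_idx = np.sort(rng.choice(n_windows, size=n_sweeps, replace=False))
    is_sweep = np.zeros(n_windows, dtype=bool)
    is_sweep[sweep_idx] = True

    n_loci = n_windows * loci_per_window
    window_of = np.repeat(np.arange(n_windows), loci_per_window)
    poly_rate = np.where(
        is_sweep[window_of], base_poly_rate / diversity_reduction, base_poly_rate
    )
    u = rng.random(n_loci)
    is_poly = u < poly_rate
    is_div = ~is_poly & (u < poly_rate + base_div_rate)

    ingroup = np.zeros((n_loci, n_ingroup), dtype=float)
    if is_poly.any():
        p = rng.uniform(0.1, 0.9, int(is_poly.sum()))
        ingroup[is_poly] = rng.binomial(2, p[:, None], (int(is_poly.sum()), n_ingroup))
    outgroup = np.where(is_div, 1.0, 0.0)  # haploid: carries alt at divergent sites

    spacing = max(window_size // loci_per_window, 1)
    pos = (
        window_of * window_size
        + (np.arange(n_loci) % loci_per_window) * spacing
        + 1
    )
    ref = rng.integers(0, 4, n_loci)
    alt = (ref + rng.integers(1, 4, n_loci)) % 4
    loci = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref_allele": _BASES[ref],
            "alt_allele": _BASES[alt],
        }
    )
    sample_ids = [f"ing_{i}" for i in range(n_ingroup)] + ["ancient"]
    dosages = np.column_stack([ingroup, outgroup])
    ploidy = np.array([2] * n_ingroup + [1])
    gt = GenotypeTable(sample_ids, loci, dosages, ploidy)
    windows = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(n_windows) * window_size,
            "end": (np.arange(n_windows) + 1) * window_size,
        }
    )
    truth = {
        "seed": seed,
        "sweep_windows": sweep_idx,
        "diversity_reduction": diversity_reduction,
    }
    return gt, windows, truth
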