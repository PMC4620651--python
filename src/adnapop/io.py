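"""Readers, writers and core containers for genotype, frequency and read data.

All genomic coordinates carried by these containers are 1-based inclusive
(VCF convention); BED-style window and gene inputs are 0-based half-open and
are converted at the boundary by the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "PopulationMap",
    "FrequencyTable",
    "DiagnosticPanel",
    "ReadObservationSet",
    "ParseError",
    "read_genotype_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "allele_frequencies",
    "read_population_map",
    "write_population_map",
    "read_diagnostic_panel",
    "write_diagnostic_panel",
    "read_read_observations",
    "write_read_observations",
    "read_bed",
    "mutation_class",
    "locus_id",
]

_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))

LOCUS_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele"]


class ParseError(ValueError):
    """Raised when an on-disk file violates its documented schema."""


def locus_id(chrom, pos) -> str:
    """Canonical locus identifier ``chrom:pos`` (1-based position)."""
    return f"{chrom}:{int(pos)}"


def mutation_class(a: str, b: str) -> str:
    """Classify a substitution between single bases ``a`` and ``b``.

    Returns ``"transition"`` for A<->G / C<->T, ``"transversion"`` otherwise.
    """
    pair = frozenset((a.upper(), b.upper()))
    if len(pair) != 2 or not pair <= _BASES:
        raise ValueError(f"not a substitution between single bases: {a}/{b}")
    return "transition" if pair in _TRANSITIONS else "transversion"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Samples x biallelic loci with alt-allele dosages.

    ``dosages`` has shape (n_loci, n_samples); entries are 0..ploidy or NaN
    for a missing call. ``ploidy`` is per sample (2 for diploid calls, 1 for a
    pseudo-haploid sample such as a low-coverage ancient genome).
    """

    sample_ids: list[str]
    loci: pd.DataFrame  # columns chrom, pos, ref_allele, alt_allele
    dosages: np.ndarray
    ploidy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.ploidy is None:
            self.ploidy = np.full(len(self.sample_ids), 2, dtype=int)
        self.ploidy = np.asarray(self.ploidy, dtype=int)
        self.validate()

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if list(self.loci.columns[:4]) != LOCUS_COLUMNS:
            raise ValueError(f"locus table must have columns {LOCUS_COLUMNS}")
        if self.dosages.shape != (self.n_loci, self.n_samples):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({self.n_loci}, {self.n_samples})"
            )
        if len(self.ploidy) != self.n_samples:
            raise ValueError("ploidy must be per sample")
        for chrom, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        if (self.loci["ref_allele"] == self.loci["alt_allele"]).any():
            raise ValueError("ref_allele must differ from alt_allele")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > self.ploidy[None, :])
            frac = self.dosages != np.floor(self.dosages)
        if np.any(bad & ~np.isnan(self.dosages)) or np.any(
            frac & ~np.isnan(self.dosages)
        ):
            raise ValueError("dosages must be integers in 0..ploidy or NaN")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None


@dataclass
class PopulationMap:
    """sample -> population and population -> group labels."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in set(self.sample_to_pop.values()):
            self.pop_to_group.setdefault(pop, pop)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_pop.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == population]

    def populations_in_group(self, group: str) -> list[str]:
        return [p for p, g in self.pop_to_group.items() if g == group]

    def require_all(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.sample_to_pop]
        if missing:
            raise ValueError(f"samples without a population: {missing}")


@dataclass
class FrequencyTable:
    """Per population x locus alt-allele frequency and allele-copy count.

    ``freq[i, j]`` is the alt-allele frequency of population ``populations[j]``
    at locus ``i`` (NaN when no non-missing copies were observed there);
    ``n_copies`` is the matching count of observed allele copies.
    """

    populations: list[str]
    loci: pd.DataFrame
    freq: np.ndarray
    n_copies: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_copies = np.asarray(self.n_copies, dtype=int)
        shape = (len(self.loci), len(self.populations))
        if self.freq.shape != shape or self.n_copies.shape != shape:
            raise ValueError("freq/n_copies shape mismatch with loci/populations")
        with np.errstate(invalid="ignore"):
            if np.any((self.freq < 0) | (self.freq > 1)):
                raise ValueError("frequencies must lie in [0, 1]")
        if np.any(np.isnan(self.freq) != (self.n_copies == 0)):
            raise ValueError("frequency must be missing exactly when n_copies == 0")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def column(self, population: str) -> np.ndarray:
        try:
            j = self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None
        return self.freq[:, j]

    def copies(self, population: str) -> np.ndarray:
        j = self.populations.index(population)
        return self.n_copies[:, j]


@dataclass
class DiagnosticPanel:
    """Loci whose alleles discriminate the endogenous lineage from contaminants.

    ``table`` columns: chrom, pos, endogenous_allele, contaminant_alleles
    (list of bases), mutation_class. A locus is transversion-class only when
    every endogenous/contaminant pair is a transversion, so that it stays
    diagnostic in the presence of deamination-driven transition artefacts.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "chrom",
            "pos",
            "endogenous_allele",
            "contaminant_alleles",
            "mutation_class",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        for row in self.table.itertuples():
            contaminants = list(row.contaminant_alleles)
            if not contaminants:
                raise ValueError(f"locus {row.chrom}:{row.pos}: no contaminant allele")
            if row.endogenous_allele in contaminants:
                raise ValueError(
                    f"locus {row.chrom}:{row.pos}: endogenous allele "
                    "listed as contaminant"
                )
            classes = {
                mutation_class(row.endogenous_allele, c) for c in contaminants
            }
            expected = (
                "transversion" if classes == {"transversion"} else "transition"
            )
            if row.mutation_class != expected:
                raise ValueError(
                    f"locus {row.chrom}:{row.pos}: declared "
                    f"{row.mutation_class} but alleles imply {expected}"
                )

    @property
    def locus_ids(self) -> list[str]:
        return [locus_id(c, p) for c, p in zip(self.table["chrom"], self.table["pos"])]

    def restrict(self, mut_class: str) -> "DiagnosticPanel":
        sub = self.table[self.table["mutation_class"] == mut_class]
        if sub.empty:
            raise ValueError(f"no informative loci of class {mut_class!r}")
        return DiagnosticPanel(sub.copy())


@dataclass
class ReadObservationSet:
    """Per-read allele calls plus optional length and terminal-mismatch data.

    ``observations``: one row per (read, locus) with columns read_id,
    locus_id, allele. ``lengths``: read_id, length_bp. ``mismatches``: one row
    per (read, end, position) with columns read_id, end ("5p"/"3p"),
    position (1-based distance from that end), ref_base, read_base.
    """

    observations: pd.DataFrame
    lengths: pd.DataFrame | None = None
    mismatches: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        obs_cols = {"read_id", "locus_id", "allele"}
        if not obs_cols <= set(self.observations.columns):
            raise ValueError(f"observations need columns {sorted(obs_cols)}")
        self.observations = self.observations.reset_index(drop=True)
        if self.lengths is not None:
            if not {"read_id", "length_bp"} <= set(self.lengths.columns):
                raise ValueError("lengths need columns read_id, length_bp")
            if (self.lengths["length_bp"] <= 0).any():
                raise ValueError("fragment lengths must be positive")
            self.lengths = self.lengths.reset_index(drop=True)
        if self.mismatches is not None:
            mm_cols = {"read_id", "end", "position", "ref_base", "read_base"}
            if not mm_cols <= set(self.mismatches.columns):
                raise ValueError(f"mismatches need columns {sorted(mm_cols)}")
            if not set(self.mismatches["end"]) <= {"5p", "3p"}:
                raise ValueError("mismatch end must be 5p or 3p")
            self.mismatches = self.mismatches.reset_index(drop=True)

    @property
    def n_reads(self) -> int:
        return self.observations["read_id"].nunique()


# ---------------------------------------------------------------------------
# VCF / TSV readers and writers
# ---------------------------------------------------------------------------


def read_genotype_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeTable:
    """Read GT fields from a VCF 4.x file into a :class:`GenotypeTable`.

    Multiallelic records are dropped when ``biallelic_only`` (otherwise they
    raise), missing genotypes become NaN dosages, and loci are sorted by
    (chrom, pos). Duplicated (chrom, pos) records are an error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    seen: set[tuple] = set()
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if biallelic_only:
                continue
            raise ParseError(
                f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is multiallelic; "
                "pass biallelic_only=True to drop such records"
            )
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ParseError(f"{path}: duplicated record at {var.CHROM}:{var.POS}")
        seen.add(key)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dose = np.array([0.0, 1.0, np.nan, 2.0])[var.gt_types]
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_rows.append(dose)
    vcf.close()
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosages = (
        np.asarray(dosage_rows, dtype=float)
        if dosage_rows
        else np.empty((0, len(samples)))
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    return GenotypeTable(samples, loci.iloc[order], dosages[order])


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    """Read a TSV genotype matrix (rows = loci, columns = samples, 0/1/2/NA).

    The first four columns are chrom, pos, ref_allele, alt_allele; an optional
    ``#ploidy`` comment line declares per-sample ploidies.
    """
    path = Path(path)
    ploidy = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#ploidy\t"):
            ploidy = np.array([int(x) for x in first.strip().split("\t")[1:]])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    if list(df.columns[:4]) != LOCUS_COLUMNS:
        raise ParseError(f"{path}: first columns must be {LOCUS_COLUMNS}")
    samples = list(df.columns[4:])
    dosages = df[samples].to_numpy(dtype=float)
    return GenotypeTable(samples, df[LOCUS_COLUMNS], dosages, ploidy)


def write_genotype_tsv(gt: GenotypeTable, path: str | Path) -> None:
    df = gt.loci.copy()
    for j, s in enumerate(gt.sample_ids):
        col = gt.dosages[:, j]
        df[s] = pd.array(col, dtype="Int64")
    with open(path, "w") as fh:
        if not np.all(gt.ploidy == 2):
            fh.write("#ploidy\t" + "\t".join(str(p) for p in gt.ploidy) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def allele_frequencies(gt: GenotypeTable, pops: PopulationMap) -> FrequencyTable:
    """Population alt-allele frequencies: p = alt copies / observed copies."""
    pops.require_all(gt.sample_ids)
    populations = []
    seen = set()
    for s in gt.sample_ids:
        p = pops.sample_to_pop[s]
        if p not in seen:
            populations.append(p)
            seen.add(p)
    freq = np.empty((gt.n_loci, len(populations)))
    n_copies = np.empty_like(freq, dtype=int)
    for j, pop in enumerate(populations):
        idx = [gt.sample_index(s) for s in gt.sample_ids if pops.sample_to_pop[s] == pop]
        if not idx:
            raise ValueError(f"population {pop!r} has no samples")
        sub = gt.dosages[:, idx]
        obs = ~np.isnan(sub)
        copies = (obs * gt.ploidy[idx][None, :]).sum(axis=1)
        alt = np.nansum(sub, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
        freq[:, j] = p
        n_copies[:, j] = copies
    return FrequencyTable(populations, gt.loci, freq, n_copies)


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample", "population", "group"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: columns must be {expected}, got {list(df.columns)}")
    sample_to_pop = dict(zip(df["sample"], df["population"]))
    pop_to_group: dict[str, str] = {}
    for pop, grp in zip(df["population"], df["group"]):
        if pop in pop_to_group and pop_to_group[pop] != grp:
            raise ParseError(f"{path}: population {pop!r} mapped to two groups")
        pop_to_group[pop] = grp
    return PopulationMap(sample_to_pop, pop_to_group)


def write_population_map(pops: PopulationMap, path: str | Path) -> None:
    rows = [
        (s, p, pops.pop_to_group[p]) for s, p in pops.sample_to_pop.items()
    ]
    pd.DataFrame(rows, columns=["sample", "population", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_diagnostic_panel(path: str | Path) -> DiagnosticPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = ["chrom", "pos", "endogenous", "contaminant", "class"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: columns must be {expected}, got {list(df.columns)}")
    table = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "endogenous_allele": df["endogenous"],
            "contaminant_alleles": [c.split(",") for c in df["contaminant"]],
            "mutation_class": df["class"],
        }
    )
    return DiagnosticPanel(table)


def write_diagnostic_panel(panel: DiagnosticPanel, path: str | Path) -> None:
    t = panel.table
    pd.DataFrame(
        {
            "chrom": t["chrom"],
            "pos": t["pos"],
            "endogenous": t["endogenous_allele"],
            "contaminant": [",".join(c) for c in t["contaminant_alleles"]],
            "class": t["mutation_class"],
        }
    ).to_csv(path, sep="\t", index=False)


def read_read_observations(
    path: str | Path, mismatch_path: str | Path | None = None
) -> ReadObservationSet:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "locus_id": str})
    expected = ["read_id", "locus_id", "allele", "length"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: columns must be {expected}, got {list(df.columns)}")
    obs = df[["read_id", "locus_id", "allele"]]
    lengths = None
    with_len = df.dropna(subset=["length"])
    if len(with_len):
        lengths = (
            with_len.drop_duplicates("read_id")[["read_id", "length"]]
            .rename(columns={"length": "length_bp"})
            .astype({"length_bp": int})
        )
    mismatches = None
    if mismatch_path is not None:
        mm = pd.read_csv(mismatch_path, sep="\t", dtype={"read_id": str})
        mm_expected = ["read_id", "end", "position", "ref_base", "read_base"]
        if list(mm.columns) != mm_expected:
            raise ParseError(f"{mismatch_path}: columns must be {mm_expected}")
        mismatches = mm
    return ReadObservationSet(obs, lengths, mismatches)


def write_read_observations(
    reads: ReadObservationSet,
    path: str | Path,
    mismatch_path: str | Path | None = None,
) -> None:
    df = reads.observations.copy()
    if reads.lengths is not None:
        lut = dict(zip(reads.lengths["read_id"], reads.lengths["length_bp"]))
        df["length"] = pd.array(
            [lut.get(r) for r in df["read_id"]], dtype="Int64"
        )
    else:
        df["length"] = pd.array([None] * len(df), dtype="Int64")
    df.to_csv(path, sep="\t", index=False)
    if mismatch_path is not None and reads.mismatches is not None:
        reads.mismatches.to_csv(mismatch_path, sep="\t", index=False)


def read_bed(path: str | Path, n_fields: int = 3) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end (+name) rows."""
    names = ["chrom", "start", "end", "name", "score", "strand"][:n_fields]
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=names, dtype={"chrom": str}
    )
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: BED intervals must satisfy start < end")
    return df
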