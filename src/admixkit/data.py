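"""Genotype/haplotype containers, EIGENSTRAT and PLINK-text I/O, and QC filters.

The central container is :class:`GenotypeDataset`: a SNP-major dosage matrix
(alt-allele counts in {0,1,2}, ``-1`` for missing) together with a genetic map
(Morgans), physical positions (1-based bp) and per-sample population labels.
Every downstream statistic consumes this container or the phased
:class:`HaplotypeDataset` variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in the dosage matrix
MISSING: int = -1


class DataFormatError(ValueError):
    """Raised when an input file or container violates the format contract."""


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


def _with_ext(prefix: str | Path, ext: str) -> Path:
    """Append an extension without clobbering dots in the prefix."""
    return Path(f"{prefix}{ext}")


@dataclass
class GenotypeDataset:
    """SNP-major diploid dosages with genetic map and sample population labels.

    Parameters
    ----------
    snp_ids : array of str, shape (m,)
    chrom : array of str, shape (m,)
        Chromosome label per SNP; SNPs of one chromosome must be contiguous.
    genetic_pos : array of float, shape (m,)
        Genetic map position in Morgans, non-decreasing within a chromosome.
    physical_pos : array of int, shape (m,)
        1-based physical position in base pairs.
    alleles : array of str, shape (m, 2)
        Reference and alternate allele per SNP.
    dosages : array of int, shape (m, n)
        Count of alternate alleles per SNP per sample; ``-1`` marks missing.
    sample_ids, pop_labels : arrays of str, shape (n,)
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    genetic_pos: np.ndarray
    physical_pos: np.ndarray
    alleles: np.ndarray
    dosages: np.ndarray
    sample_ids: np.ndarray
    pop_labels: np.ndarray

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.physical_pos = np.asarray(self.physical_pos, dtype=np.int64)
        self.alleles = _as_str_array(self.alleles).reshape(-1, 2) if np.size(self.alleles) else np.empty((0, 2), dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = _as_str_array(self.sample_ids)
        self.pop_labels = _as_str_array(self.pop_labels)
        self._validate()

    def _validate(self):
        m = len(self.snp_ids)
        for name in ("chrom", "genetic_pos", "physical_pos"):
            if len(getattr(self, name)) != m:
                raise DataFormatError(f"{name} has length {len(getattr(self, name))}, expected {m}")
        if self.alleles.shape[0] != m:
            raise DataFormatError("alleles row count does not match SNP count")
        if self.dosages.shape != (m, len(self.sample_ids)):
            raise DataFormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"({m} SNPs, {len(self.sample_ids)} samples)")
        if len(self.pop_labels) != len(self.sample_ids):
            raise DataFormatError("pop_labels length does not match sample count")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise DataFormatError(f"dosages contain values outside {{0,1,2,missing}} at {int(bad.sum())} cells")
        for c in dict.fromkeys(self.chrom):
            g = self.genetic_pos[self.chrom == c]
            if np.any(np.diff(g) < 0):
                raise DataFormatError(f"genetic map not monotone within chromosome {c!r}")

    # ---- basic introspection -------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.pop_labels))

    def samples_in(self, pops: str | Sequence[str]) -> np.ndarray:
        """Column indices of samples whose population label is in ``pops``."""
        if isinstance(pops, str):
            pops = [pops]
        unknown = set(pops) - set(self.pop_labels)
        if unknown:
            raise KeyError(f"unknown population(s): {sorted(unknown)}")
        return np.flatnonzero(np.isin(self.pop_labels, list(pops)))

    def take_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.snp_ids[index], self.chrom[index], self.genetic_pos[index],
            self.physical_pos[index], self.alleles[index], self.dosages[index],
            self.sample_ids, self.pop_labels)

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.snp_ids, self.chrom, self.genetic_pos, self.physical_pos,
            self.alleles, self.dosages[:, index],
            self.sample_ids[index], self.pop_labels[index])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("snp_ids", "chrom", "physical_pos", "alleles",
                      "dosages", "sample_ids", "pop_labels")
        ) and np.allclose(self.genetic_pos, other.genetic_pos)


@dataclass
class HaplotypeDataset:
    """Phased haplotypes: two {0,1} columns per sample, same map as genotypes.

    Column ``2*i`` and ``2*i+1`` are the two haplotypes of sample ``i``.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    genetic_pos: np.ndarray
    physical_pos: np.ndarray
    alleles: np.ndarray
    haplotypes: np.ndarray  # (m, 2n) in {0,1}
    sample_ids: np.ndarray
    pop_labels: np.ndarray

    def __post_init__(self):
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.physical_pos = np.asarray(self.physical_pos, dtype=np.int64)
        self.alleles = _as_str_array(self.alleles).reshape(-1, 2) if np.size(self.alleles) else np.empty((0, 2), dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.sample_ids = _as_str_array(self.sample_ids)
        self.pop_labels = _as_str_array(self.pop_labels)
        if self.haplotypes.shape[1] != 2 * len(self.sample_ids):
            raise DataFormatError("haplotype count must be 2 x sample count")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise DataFormatError("haplotype alleles must be in {0,1}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def samples_in(self, pops: str | Sequence[str]) -> np.ndarray:
        if isinstance(pops, str):
            pops = [pops]
        unknown = set(pops) - set(self.pop_labels)
        if unknown:
            raise KeyError(f"unknown population(s): {sorted(unknown)}")
        return np.flatnonzero(np.isin(self.pop_labels, list(pops)))

    def take_samples(self, index: np.ndarray) -> "HaplotypeDataset":
        index = np.asarray(index)
        cols = np.column_stack([2 * index, 2 * index + 1]).ravel()
        return HaplotypeDataset(
            self.snp_ids, self.chrom, self.genetic_pos, self.physical_pos,
            self.alleles, self.haplotypes[:, cols],
            self.sample_ids[index], self.pop_labels[index])


@dataclass
class AlleleFrequencyTable:
    """Per-population alternate-allele frequencies with observed allele counts.

    ``freqs[i, k]`` is the alt frequency of SNP ``i`` in population ``k``;
    ``counts[i, k]`` the number of observed alleles (2 x non-missing samples).
    SNPs missing everywhere in a population carry frequency NaN and count 0.
    The genetic map travels along so block-jackknife blocks can be cut later.
    """

    pops: list[str]
    freqs: np.ndarray    # (m, npop) float
    counts: np.ndarray   # (m, npop) int
    snp_ids: np.ndarray
    chrom: np.ndarray
    genetic_pos: np.ndarray

    def __post_init__(self):
        self.pops = list(self.pops)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        ok = self.freqs[self.counts > 0]
        if ok.size and (np.nanmin(ok) < 0 or np.nanmax(ok) > 1):
            raise DataFormatError("allele frequencies outside [0,1]")

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[0]

    def freq(self, pop: str) -> np.ndarray:
        return self.freqs[:, self.pops.index(pop)]

    def count(self, pop: str) -> np.ndarray:
        return self.counts[:, self.pops.index(pop)]


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def read_eigenstrat(prefix: str | Path, genetic_units: str = "M") -> GenotypeDataset:
    """Read an EIGENSTRAT geno/snp/ind triplet.

    ``genetic_units`` may be ``"M"`` (Morgans, the EIGENSTRAT convention) or
    ``"cM"``; centimorgan maps are converted to Morgans on input.
    Genotype code 9 becomes a missing call.
    """
    prefix = Path(prefix)
    if genetic_units not in ("M", "cM"):
        raise ValueError("genetic_units must be 'M' or 'cM'")
    snp_rows = [ln.split() for ln in _read_lines(_with_ext(prefix, ".snp"))]
    ind_rows = [ln.split() for ln in _read_lines(_with_ext(prefix, ".ind"))]
    geno_rows = _read_lines(_with_ext(prefix, ".geno"))
    if len(geno_rows) != len(snp_rows):
        raise DataFormatError(
            f"geno has {len(geno_rows)} rows but snp file has {len(snp_rows)}")
    m, n = len(snp_rows), len(ind_rows)
    dosages = np.empty((m, n), dtype=np.int8)
    for i, row in enumerate(geno_rows):
        if len(row) != n:
            raise DataFormatError(
                f"geno row {i} has {len(row)} genotypes, expected {n}")
        vals = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
        if not np.isin(vals, (0, 1, 2, 9)).all():
            raise DataFormatError(f"invalid genotype character in geno row {i}")
        dosages[i] = np.where(vals == 9, MISSING, vals)
    snp_ids = [r[0] for r in snp_rows]
    chrom = [r[1] for r in snp_rows]
    gpos = np.array([float(r[2]) for r in snp_rows])
    if genetic_units == "cM":
        gpos = gpos / 100.0
    ppos = [int(r[3]) for r in snp_rows]
    alleles = [(r[4], r[5]) if len(r) >= 6 else ("A", "C") for r in snp_rows]
    sample_ids = [r[0] for r in ind_rows]
    pop_labels = [r[2] if len(r) >= 3 else "pop0" for r in ind_rows]
    return GenotypeDataset(snp_ids, chrom, gpos, ppos, alleles, dosages,
                           sample_ids, pop_labels)


def write_eigenstrat(data: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``data`` as an EIGENSTRAT geno/snp/ind triplet (Morgans in .snp)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno = np.where(data.dosages == MISSING, 9, data.dosages).astype(np.uint8) + ord("0")
    with open(_with_ext(prefix, ".geno"), "wb") as fh:
        for row in geno:
            fh.write(row.tobytes() + b"\n")
    with open(_with_ext(prefix, ".snp"), "w") as fh:
        for i in range(data.n_snps):
            fh.write(f"{data.snp_ids[i]}\t{data.chrom[i]}\t{data.genetic_pos[i]:.8f}"
                     f"\t{data.physical_pos[i]}\t{data.alleles[i, 0]}\t{data.alleles[i, 1]}\n")
    with open(_with_ext(prefix, ".ind"), "w") as fh:
        for j in range(data.n_samples):
            fh.write(f"{data.sample_ids[j]}\tU\t{data.pop_labels[j]}\n")


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def read_plink_text(prefix: str | Path, map_units: str = "cM") -> GenotypeDataset:
    """Read a PLINK text ped/map pair (optional import path).

    The .map genetic-distance column is conventionally cM; set
    ``map_units="M"`` if it already holds Morgans.  Allele coding: the first
    allele observed per SNP becomes ref, the other alt; ``0`` is missing.
    """
    prefix = Path(prefix)
    map_rows = [ln.split() for ln in _read_lines(_with_ext(prefix, ".map"))]
    chrom = [r[0] for r in map_rows]
    snp_ids = [r[1] for r in map_rows]
    gpos = np.array([float(r[2]) for r in map_rows])
    if map_units == "cM":
        gpos = gpos / 100.0
    ppos = [int(r[3]) for r in map_rows]
    m = len(map_rows)
    ped_rows = [ln.split() for ln in _read_lines(_with_ext(prefix, ".ped"))]
    n = len(ped_rows)
    sample_ids, pop_labels = [], []
    allele_pairs = np.empty((m, n, 2), dtype=object)
    for j, row in enumerate(ped_rows):
        if len(row) != 6 + 2 * m:
            raise DataFormatError(f"ped row {j}: expected {6 + 2 * m} fields, got {len(row)}")
        pop_labels.append(row[0])
        sample_ids.append(row[1])
        allele_pairs[:, j, 0] = row[6::2]
        allele_pairs[:, j, 1] = row[7::2]
    dosages = np.empty((m, n), dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    for i in range(m):
        obs = [a for a in allele_pairs[i].ravel() if a != "0"]
        uniq = list(dict.fromkeys(obs))
        if len(uniq) > 2:
            raise DataFormatError(f"SNP {snp_ids[i]}: more than two alleles")
        ref = uniq[0] if uniq else "A"
        alt = uniq[1] if len(uniq) > 1 else "C"
        alleles[i] = (ref, alt)
        for j in range(n):
            a, b = allele_pairs[i, j]
            if a == "0" or b == "0":
                dosages[i, j] = MISSING
            else:
                dosages[i, j] = (a == alt) + (b == alt)
    return GenotypeDataset(snp_ids, chrom, gpos, ppos, alleles, dosages,
                           sample_ids, pop_labels)


# ---------------------------------------------------------------------------
# allele frequencies and QC filters
# ---------------------------------------------------------------------------

def allele_frequencies(data: GenotypeDataset,
                       pops: Sequence[str] | None = None) -> AlleleFrequencyTable:
    """Alt-allele frequency per SNP per population.

    Frequency is the alt-dosage sum over non-missing calls divided by twice
    the non-missing sample count.  SNPs with no observed call in a population
    get count 0 and frequency NaN (flagged for downstream exclusion).
    """
    if pops is None:
        pops = data.populations
    m = data.n_snps
    freqs = np.full((m, len(pops)), np.nan)
    counts = np.zeros((m, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        cols = data.samples_in(pop)
        if cols.size == 0:
            raise KeyError(f"population {pop!r} has no samples")
        d = data.dosages[:, cols]
        obs = d != MISSING
        n_obs = obs.sum(axis=1)
        alt = np.where(obs, d, 0).sum(axis=1)
        counts[:, k] = 2 * n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, k] = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    return AlleleFrequencyTable(list(pops), freqs, counts, data.snp_ids,
                                data.chrom, data.genetic_pos)


def filter_missingness(data: GenotypeDataset, max_rate: float = 0.05) -> GenotypeDataset:
    """Drop samples, then SNPs, whose missing-call rate exceeds ``max_rate``.

    The sample pass runs first (fixed order, logged); SNP missingness is then
    evaluated on the surviving samples.
    """
    if not 0 <= max_rate <= 1:
        raise ValueError("max_rate must be in [0,1]")
    miss = data.dosages == MISSING
    keep_samples = np.flatnonzero(miss.mean(axis=0) <= max_rate) if data.n_snps else np.arange(data.n_samples)
    out = data.take_samples(keep_samples)
    logger.info("missingness filter: dropped %d/%d samples",
                data.n_samples - len(keep_samples), data.n_samples)
    if out.n_samples == 0:
        logger.warning("missingness filter removed every sample")
        return out.take_snps(np.arange(0))
    snp_miss = (out.dosages == MISSING).mean(axis=1)
    keep_snps = np.flatnonzero(snp_miss <= max_rate)
    logger.info("missingness filter: dropped %d/%d SNPs",
                out.n_snps - len(keep_snps), out.n_snps)
    return out.take_snps(keep_snps)


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Genotypic r^2 between all row pairs, pairwise-complete over samples."""
    k = d.shape[0]
    r2 = np.zeros((k, k))
    obs = d != MISSING
    for i in range(k):
        for j in range(i + 1, k):
            both = obs[i] & obs[j]
            if both.sum() < 2:
                continue
            x = d[i, both].astype(float)
            y = d[j, both].astype(float)
            vx, vy = x.var(), y.var()
            if vx == 0 or vy == 0:
                continue
            c = ((x - x.mean()) * (y - y.mean())).mean()
            r2[i, j] = r2[j, i] = c * c / (vx * vy)
    return r2


def ld_thin(data: GenotypeDataset, r2_max: float = 0.1,
            window: int = 50, step: int = 5) -> GenotypeDataset:
    """Greedy sliding-window LD pruning of SNPs with genotypic r^2 > ``r2_max``.

    Within each ``window``-SNP window (advanced by ``step`` SNPs) every pair of
    surviving SNPs with r^2 above the threshold loses its higher-index member.
    Passes repeat over the pruned set until stable, so the operation is
    idempotent and deterministic.
    """
    if data.n_snps < 2:
        return data
    alive = np.ones(data.n_snps, dtype=bool)
    chrom_slices = []
    start = 0
    for c in data.chromosomes:
        idx = np.flatnonzero(data.chrom == c)
        chrom_slices.append((idx[0], idx[-1] + 1))
        start = idx[-1] + 1
    changed = True
    while changed:
        changed = False
        for lo, hi in chrom_slices:
            live = np.flatnonzero(alive[lo:hi]) + lo
            for w0 in range(0, max(1, len(live) - 1), step):
                widx = live[w0:w0 + window]
                widx = widx[alive[widx]]
                if len(widx) < 2:
                    continue
                r2 = _pairwise_r2(data.dosages[widx])
                for a in range(len(widx)):
                    if not alive[widx[a]]:
                        continue
                    for b in range(a + 1, len(widx)):
                        if alive[widx[b]] and r2[a, b] > r2_max:
                            alive[widx[b]] = False
                            changed = True
    kept = np.flatnonzero(alive)
    logger.info("ld_thin: kept %d/%d SNPs", len(kept), data.n_snps)
    return data.take_snps(kept)


def genotypes_equal(a: GenotypeDataset, b: GenotypeDataset) -> bool:
    """Field-by-field equality of two datasets (round-trip checks)."""
    return a == b


def write_haplotype_eigenstrat(haps: HaplotypeDataset, prefix: str | Path) -> None:
    """EIGENSTRAT-style triplet with one {0,1} geno column per haplotype.

    The .ind file lists haplotype ids ``<sample>_h0`` / ``<sample>_h1`` so the
    phased matrix round-trips losslessly through the text format.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno = haps.haplotypes.astype(np.uint8) + ord("0")
    with open(_with_ext(prefix, ".geno"), "wb") as fh:
        for row in geno:
            fh.write(row.tobytes() + b"\n")
    with open(_with_ext(prefix, ".snp"), "w") as fh:
        for i in range(haps.n_snps):
            fh.write(f"{haps.snp_ids[i]}\t{haps.chrom[i]}\t{haps.genetic_pos[i]:.8f}"
                     f"\t{haps.physical_pos[i]}\t{haps.alleles[i, 0]}\t{haps.alleles[i, 1]}\n")
    with open(_with_ext(prefix, ".ind"), "w") as fh:
        for j in range(haps.n_samples):
            for h in (0, 1):
                fh.write(f"{haps.sample_ids[j]}_h{h}\tU\t{haps.pop_labels[j]}\n")


def read_haplotype_eigenstrat(prefix: str | Path,
                              genetic_units: str = "M") -> HaplotypeDataset:
    """Inverse of :func:`write_haplotype_eigenstrat`."""
    g = read_eigenstrat(prefix, genetic_units)
    if g.n_samples % 2 != 0:
        raise DataFormatError("haplotype file must have an even column count")
    if not np.isin(g.dosages, (0, 1)).all():
        raise DataFormatError("haplotype genotypes must be 0/1")
    sample_ids = [s[:-3] if s.endswith(("_h0", "_h1")) else s
                  for s in g.sample_ids[0::2]]
    return HaplotypeDataset(g.snp_ids, g.chrom, g.genetic_pos, g.physical_pos,
                            g.alleles, g.dosages.astype(np.int8),
                            sample_ids, g.pop_labels[0::2])
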