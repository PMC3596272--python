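"""Synthetic admixed-genome generator with known truth.

Two diverged ancestral pools are drawn under the Balding–Nichols model
(Beta-distributed population frequencies around a shared ancestral frequency,
differentiation parameter ``F``).  Admixed haplotypes carry a piecewise-
constant ancestry track along a multi-chromosome genetic map: breakpoints fall
as a Poisson process at rate ``t`` per Morgan for a pulse ``t`` generations
ago, and each segment's ancestry is an independent Bernoulli(alpha) draw, so
ancestry autocorrelation decays as ``exp(-t d)`` — the signal every dating
statistic in this package consumes.  Alleles are then drawn independently per
SNP given local ancestry (no background LD within pools).

Optional post-admixture founder events re-mate a small founder set forward in
time with crossovers at 1 per Morgan per meiosis, creating the long-range
allele-sharing and ROH excess of a bottlenecked population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import (MISSING, AlleleFrequencyTable, GenotypeDataset,
                   HaplotypeDataset)

#: allele-count placeholder for parametric (infinite-pool) frequency tables
TRUE_FREQ_COUNT = 2_000_000


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic admixture demography.

    Pulses are (time in generations, proportion contributed by pool A),
    ordered from oldest to most recent.  The first pulse founds the admixed
    population; each later pulse replaces a fraction of lineages with fresh
    pool-A material.  ``founder_event`` is an optional (time, n_founders)
    bottleneck applied after admixture.
    """

    n_chromosomes: int = 20
    chrom_length_m: float = 1.0
    n_snps: int = 200_000
    fst: float = 0.1
    pulses: list[tuple[float, float]] = field(default_factory=lambda: [(30.0, 0.8)])
    founder_event: tuple[float, int] | None = None
    founder_pop_size: int | None = None
    n_admixed_samples: int = 27
    n_reference_samples: int = 50
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0,1)")
        times = [t for t, _ in self.pulses]
        if any(t < 1 for t in times):
            raise ValueError("pulse times must be >= 1 generation")
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("pulse times must decrease toward the present")
        for _, a in self.pulses:
            if not 0 < a <= 1:
                raise ValueError("pulse proportions must be in (0,1]")
        if self.founder_event is not None:
            t, nf = self.founder_event
            if t < 1:
                raise ValueError("founder event time must be >= 1 generation")
            if nf < 2:
                raise ValueError("n_founders must be >= 2")

    # -- plain-text key=value round trip --------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            f"n_chromosomes={self.n_chromosomes}",
            f"chrom_length_m={self.chrom_length_m}",
            f"n_snps={self.n_snps}",
            f"fst={self.fst}",
            "pulses=" + ",".join(f"{t}:{a}" for t, a in self.pulses),
            "founder_event=" + ("none" if self.founder_event is None
                                 else f"{self.founder_event[0]}:{self.founder_event[1]}"),
            "founder_pop_size=" + ("none" if self.founder_pop_size is None
                                    else str(self.founder_pop_size)),
            f"n_admixed_samples={self.n_admixed_samples}",
            f"n_reference_samples={self.n_reference_samples}",
            f"missing_rate={self.missing_rate}",
            f"seed={self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "ScenarioConfig":
        kv = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            k, _, v = ln.partition("=")
            kv[k.strip()] = v.strip()
        pulses = [(float(t), float(a)) for t, a in
                  (p.split(":") for p in kv["pulses"].split(","))]
        fe = kv.get("founder_event", "none")
        founder = None if fe == "none" else (float(fe.split(":")[0]), int(fe.split(":")[1]))
        fps = kv.get("founder_pop_size", "none")
        return cls(
            n_chromosomes=int(kv["n_chromosomes"]),
            chrom_length_m=float(kv["chrom_length_m"]),
            n_snps=int(kv["n_snps"]),
            fst=float(kv["fst"]),
            pulses=pulses,
            founder_event=founder,
            founder_pop_size=None if fps == "none" else int(fps),
            n_admixed_samples=int(kv["n_admixed_samples"]),
            n_reference_samples=int(kv["n_reference_samples"]),
            missing_rate=float(kv["missing_rate"]),
            seed=int(kv["seed"]),
        )


@dataclass
class TruthTrack:
    """Ground-truth local ancestry: one {0,1} label per haplotype per SNP.

    Label 0 is pool A, 1 is pool B.  ``n_breakpoints`` counts the actual
    recombination breakpoints laid down per haplotype (including those that
    happen to join segments of equal ancestry, which per-SNP labels cannot
    show).
    """

    ancestry: np.ndarray          # (m, n_haplotypes) int8
    chrom: np.ndarray
    genetic_pos: np.ndarray
    n_breakpoints: np.ndarray     # per haplotype

    def mean_pool_a_fraction(self) -> float:
        return float((self.ancestry == 0).mean())

    def segments(self, hap: int) -> list[tuple[str, float, float, str]]:
        """Observed constant-ancestry runs as (chrom, start_M, end_M, label)."""
        out = []
        for c in dict.fromkeys(self.chrom):
            sel = self.chrom == c
            lab = self.ancestry[sel, hap]
            pos = self.genetic_pos[sel]
            cut = np.flatnonzero(np.diff(lab) != 0)
            starts = np.r_[0, cut + 1]
            ends = np.r_[cut, len(lab) - 1]
            for s, e in zip(starts, ends):
                out.append((c, float(pos[s]), float(pos[e]), "AB"[lab[s]]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\tchrom\tstart_M\tend_M\tancestry\n")
            for h in range(self.ancestry.shape[1]):
                for c, s, e, lab in self.segments(h):
                    fh.write(f"{h}\t{c}\t{s:.6f}\t{e:.6f}\t{lab}\n")


def _uniform_map(n_snps: int, n_chrom: int, length_m: float,
                 rng: np.random.Generator):
    """Sorted-uniform SNP positions over ``n_chrom`` chromosomes."""
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    chrom, gpos, ppos = [], [], []
    for c in range(n_chrom):
        pos = np.sort(rng.uniform(0, length_m, per[c]))
        chrom.append(np.full(per[c], str(c + 1), dtype=object))
        gpos.append(pos)
        ppos.append(np.round(pos * 1e8).astype(np.int64) + 1)  # ~1 cM/Mb
    return np.concatenate(chrom), np.concatenate(gpos), np.concatenate(ppos)


def simulate_ancestral_freqs(n_snps: int, F: float,
                             seed: int | np.random.Generator = 0,
                             p0: np.ndarray | None = None) -> AlleleFrequencyTable:
    """Draw diverged pool frequencies under the Balding–Nichols model.

    The shared ancestral frequency ``p0`` is uniform on [0.05, 0.95] and each
    pool's frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F): mean ``p0``, variance
    ``F p0 (1-p0)``.
    """
    if not 0 < F < 1:
        raise ValueError("F must be in (0,1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if p0 is None:
        p0 = rng.uniform(0.05, 0.95, n_snps)
    scale = (1.0 - F) / F
    pa = rng.beta(p0 * scale, (1 - p0) * scale)
    pb = rng.beta(p0 * scale, (1 - p0) * scale)
    freqs = np.column_stack([pa, pb, p0])
    counts = np.full_like(freqs, TRUE_FREQ_COUNT, dtype=np.int64)
    ids = np.array([f"snp{i}" for i in range(n_snps)], dtype=object)
    chrom = np.full(n_snps, "1", dtype=object)
    gpos = np.linspace(0, 1, n_snps, endpoint=False)
    return AlleleFrequencyTable(["ancA", "ancB", "ancestral"], freqs, counts,
                                ids, chrom, gpos)


def balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols drift step away from frequencies ``p``."""
    scale = (1.0 - F) / F
    q = np.clip(p, 1e-6, 1 - 1e-6)
    return rng.beta(q * scale, (1 - q) * scale)


def _ancestry_track(gpos_chrom: np.ndarray, length_m: float,
                    pulses: Sequence[tuple[float, float]],
                    rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Per-SNP ancestry labels for one haplotype on one chromosome.

    A single pulse (t, alpha) lays breakpoints at Poisson rate t per Morgan
    with iid Bernoulli(alpha) segment labels.  For a later pulse (t_k, beta)
    the haplotype is cut at rate t_k; each piece is fresh pool-A material
    with probability beta, and otherwise holds an *independent* stretch of
    the older process with its rates reduced by t_k (a breakpoint since the
    recent pulse joins two unrelated older-era haplotypes, so the older
    ancestry pattern must not persist across it).  This yields the
    genealogical two-pulse LD, a clean sum
    beta(1-beta)(1-a1)^2 e^(-t2 d) + (1-beta) a1 (1-a1) e^(-t1 d).
    """
    if len(pulses) == 1:
        t1, a1 = pulses[0]
        nb = rng.poisson(t1 * length_m)
        cuts = np.sort(rng.uniform(0, length_m, nb))
        seg_lab = (rng.random(nb + 1) >= a1).astype(np.int8)  # 0 = pool A
        return seg_lab[np.searchsorted(cuts, gpos_chrom)], nb
    t_k, beta = pulses[-1]
    older = [(t - t_k, a) for t, a in pulses[:-1]]
    nb = rng.poisson(t_k * length_m)
    cuts = np.sort(rng.uniform(0, length_m, nb))
    migrant = rng.random(nb + 1) < beta
    anc = np.zeros(len(gpos_chrom), dtype=np.int8)
    total_bp = nb
    bounds = np.searchsorted(gpos_chrom, cuts)
    starts = np.r_[0, bounds]
    ends = np.r_[bounds, len(gpos_chrom)]
    seg_edges = np.r_[0.0, cuts, length_m]
    for s, (lo, hi) in enumerate(zip(starts, ends)):
        if migrant[s] or hi <= lo:
            continue  # fresh pool-A material, or no SNPs in this piece
        inner, nb_in = _ancestry_track(gpos_chrom[lo:hi] - seg_edges[s],
                                       seg_edges[s + 1] - seg_edges[s],
                                       older, rng)
        anc[lo:hi] = inner
        total_bp += nb_in
    return anc, total_bp


def _draw_alleles(freqs_by_anc: np.ndarray, ancestry: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Bernoulli alleles given per-SNP pool frequencies and ancestry labels."""
    p = np.take_along_axis(freqs_by_anc, ancestry.astype(np.int64), axis=1)
    return (rng.random(ancestry.shape) < p).astype(np.int8)


def simulate_admixed_haplotypes(
        config: ScenarioConfig,
        freqs: AlleleFrequencyTable | None = None,
        rng: np.random.Generator | None = None,
        pop_label: str = "ADMIX",
        map_arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        ) -> tuple[HaplotypeDataset, TruthTrack]:
    """Simulate phased admixed haplotypes plus their ground-truth ancestry.

    If ``freqs`` (a table with pools ``ancA``/``ancB``) is omitted it is drawn
    from the config's ``fst`` and seed.  The map is sorted-uniform over
    ``n_chromosomes`` chromosomes of ``chrom_length_m`` Morgans unless
    ``map_arrays`` (chrom, genetic_pos, physical_pos) supplies one.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if map_arrays is None:
        chrom, gpos, ppos = _uniform_map(config.n_snps, config.n_chromosomes,
                                         config.chrom_length_m, rng)
    else:
        chrom, gpos, ppos = map_arrays
    if freqs is None:
        freqs = simulate_ancestral_freqs(config.n_snps, config.fst, rng)
    pool = np.column_stack([freqs.freq("ancA"), freqs.freq("ancB")])
    H = 2 * config.n_admixed_samples
    ancestry = np.empty((config.n_snps, H), dtype=np.int8)
    n_bp = np.zeros(H, dtype=np.int64)
    chrom_bounds = _chrom_bounds(chrom)
    for h in range(H):
        for lo, hi in chrom_bounds:
            anc, nb = _ancestry_track(gpos[lo:hi], config.chrom_length_m,
                                      config.pulses, rng)
            ancestry[lo:hi, h] = anc
            n_bp[h] += nb
    haplotypes = _draw_alleles(pool, ancestry, rng)
    ids = np.array([f"{pop_label}_{i}" for i in range(config.n_admixed_samples)], dtype=object)
    labels = np.full(config.n_admixed_samples, pop_label, dtype=object)
    snp_ids = np.array([f"snp{i}" for i in range(config.n_snps)], dtype=object)
    alleles = np.tile(np.array(["A", "C"], dtype=object), (config.n_snps, 1))
    haps = HaplotypeDataset(snp_ids, chrom, gpos, ppos, alleles, haplotypes,
                            ids, labels)
    truth = TruthTrack(ancestry, chrom, gpos, n_bp)
    return haps, truth


def simulate_pool_haplotypes(freqs: AlleleFrequencyTable, pool: str,
                             n_samples: int,
                             chrom: np.ndarray, gpos: np.ndarray,
                             ppos: np.ndarray,
                             rng: np.random.Generator,
                             pop_label: str | None = None) -> HaplotypeDataset:
    """Unadmixed haplotypes drawn iid from one ancestral pool's frequencies."""
    p = freqs.freq(pool)[:, None]
    hm = (rng.random((len(p), 2 * n_samples)) < p).astype(np.int8)
    label = pop_label or pool
    ids = np.array([f"{label}_{i}" for i in range(n_samples)], dtype=object)
    snp_ids = np.array([f"snp{i}" for i in range(len(p))], dtype=object)
    alleles = np.tile(np.array(["A", "C"], dtype=object), (len(p), 1))
    return HaplotypeDataset(snp_ids, chrom, gpos, ppos, alleles, hm, ids,
                            np.full(n_samples, label, dtype=object))


def _chrom_bounds(chrom: np.ndarray) -> list[tuple[int, int]]:
    out = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        out.append((int(idx[0]), int(idx[-1]) + 1))
    return out


def apply_founder_event(haps: HaplotypeDataset, time: float, n_founders: int,
                        seed: int | np.random.Generator = 0,
                        pop_size: int | None = None) -> HaplotypeDataset:
    """Bottleneck ``haps`` to ``n_founders`` individuals and re-mate forward.

    ``time`` generations of random mating follow the founding, with crossovers
    laid down as a Poisson process at 1 per Morgan per meiosis and a random
    starting phase.  The population size after founding is held at
    ``pop_size`` (default: the input sample count).
    """
    if time < 1:
        raise ValueError("time must be >= 1 generation")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_founders > haps.n_samples:
        raise ValueError("n_founders exceeds available individuals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pop_size = haps.n_samples if pop_size is None else pop_size
    bounds = _chrom_bounds(haps.chrom)
    founders = rng.choice(haps.n_samples, size=n_founders, replace=False)
    cols = np.column_stack([2 * founders, 2 * founders + 1]).ravel()
    cur = haps.haplotypes[:, cols]  # (m, 2*n_founders)
    gpos = haps.genetic_pos
    # per-gap odd-crossover-count probability: exact parity of a Poisson
    # process at rate 1 per Morgan, vectorized over all gametes at once
    flip_p = []
    for lo, hi in bounds:
        gaps = np.diff(gpos[lo:hi])
        flip_p.append(0.5 * (1.0 - np.exp(-2.0 * gaps)))
    for _ in range(int(round(time))):
        n_ind = cur.shape[1] // 2
        parents = np.array([rng.choice(n_ind, size=2, replace=False)
                            for _ in range(pop_size)])  # (pop_size, 2)
        gam_parent = parents.ravel()                    # one gamete per parent
        n_g = 2 * pop_size
        nxt = np.empty((haps.n_snps, n_g), dtype=np.int8)
        for (lo, hi), fp in zip(bounds, flip_p):
            flips = rng.random((hi - lo - 1, n_g)) < fp[:, None]
            parity = np.empty((hi - lo, n_g), dtype=np.int8)
            parity[0] = rng.integers(0, 2, n_g, dtype=np.int8)
            parity[1:] = (np.cumsum(flips, axis=0, dtype=np.int32) + parity[0]) % 2
            h0 = cur[lo:hi, 2 * gam_parent]
            h1 = cur[lo:hi, 2 * gam_parent + 1]
            nxt[lo:hi] = np.where(parity == 0, h0, h1)
        cur = nxt
    ids = np.array([f"{haps.pop_labels[0]}_fe{i}" for i in range(pop_size)], dtype=object)
    labels = np.full(pop_size, haps.pop_labels[0], dtype=object)
    return HaplotypeDataset(haps.snp_ids, haps.chrom, haps.genetic_pos,
                            haps.physical_pos, haps.alleles, cur, ids, labels)


def genotypes_from_haplotypes(haps: HaplotypeDataset, missing_rate: float = 0.0,
                              seed: int | np.random.Generator = 0) -> GenotypeDataset:
    """Collapse haplotype pairs to dosages, masking calls at ``missing_rate``."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0,1)")
    dos = (haps.haplotypes[:, 0::2] + haps.haplotypes[:, 1::2]).astype(np.int8)
    if missing_rate > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        mask = rng.random(dos.shape) < missing_rate
        dos = np.where(mask, np.int8(MISSING), dos)
    return GenotypeDataset(haps.snp_ids, haps.chrom, haps.genetic_pos,
                           haps.physical_pos, haps.alleles, dos,
                           haps.sample_ids, haps.pop_labels)


def concat_samples(*datasets: HaplotypeDataset) -> HaplotypeDataset:
    """Column-concatenate haplotype datasets sharing one SNP map."""
    first = datasets[0]
    return HaplotypeDataset(
        first.snp_ids, first.chrom, first.genetic_pos, first.physical_pos,
        first.alleles,
        np.concatenate([d.haplotypes for d in datasets], axis=1),
        np.concatenate([d.sample_ids for d in datasets]),
        np.concatenate([d.pop_labels for d in datasets]))


@dataclass
class ScenarioResult:
    """Everything a full synthetic scenario produces."""

    haps: HaplotypeDataset          # admixed + both reference pools
    genotypes: GenotypeDataset      # same samples, collapsed, with missingness
    truth: TruthTrack               # admixed haplotypes only
    true_freqs: AlleleFrequencyTable
    config: ScenarioConfig


def simulate_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run a complete scenario: pools, admixed panel, optional bottleneck.

    The output carries the admixed population (label ``ADMIX``) together with
    ``n_reference_samples`` unadmixed individuals from each pool (labels
    ``REFA``/``REFB``) on a shared map, plus the true pool frequencies and the
    admixed truth track.

    Pulse times always count generations before the present.  With a founder
    event at time T the pre-founding panel is simulated with pulse ages
    (t - T), aged T generations of random mating at the post-founding size,
    and the study cohort of ``n_admixed_samples`` is drawn from the expanded
    population; the truth track then describes the pre-founding panel, not
    the sampled cohort.  A non-bottlenecked admixed panel with the same pulse
    ages is added under the label ``ADMIXREF`` as the subtraction reference
    for founder dating.
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_ancestral_freqs(config.n_snps, config.fst, rng)
    if config.founder_event is not None:
        t, nf = config.founder_event
        if any(pt - t < 1 for pt, _ in config.pulses):
            raise ValueError("every pulse must predate the founder event")
        pre = replace(config, pulses=[(pt - t, a) for pt, a in config.pulses])
        admixed, truth = simulate_admixed_haplotypes(pre, freqs=freqs, rng=rng)
        pop_size = config.founder_pop_size or 20 * int(nf)
        if pop_size < config.n_admixed_samples:
            raise ValueError("post-founding population smaller than the sample")
        admixed = apply_founder_event(admixed, t, nf, rng, pop_size=pop_size)
        # sample the study cohort from the expanded population
        keep = np.sort(rng.choice(pop_size, size=config.n_admixed_samples,
                                  replace=False))
        admixed = admixed.take_samples(keep)
    else:
        admixed, truth = simulate_admixed_haplotypes(config, freqs=freqs, rng=rng)
    # matched non-bottlenecked panel: founder-dating subtraction reference
    admixref, _ = simulate_admixed_haplotypes(
        config, freqs=freqs, rng=rng, pop_label="ADMIXREF",
        map_arrays=(admixed.chrom, admixed.genetic_pos, admixed.physical_pos))
    # re-attach the admixed map to the frequency table
    freqs = AlleleFrequencyTable(freqs.pops, freqs.freqs, freqs.counts,
                                 admixed.snp_ids, admixed.chrom, admixed.genetic_pos)
    refa = simulate_pool_haplotypes(freqs, "ancA", config.n_reference_samples,
                                    admixed.chrom, admixed.genetic_pos,
                                    admixed.physical_pos, rng, "REFA")
    refb = simulate_pool_haplotypes(freqs, "ancB", config.n_reference_samples,
                                    admixed.chrom, admixed.genetic_pos,
                                    admixed.physical_pos, rng, "REFB")
    haps = concat_samples(admixed, refa, refb, admixref)
    geno = genotypes_from_haplotypes(haps, config.missing_rate, rng)
    return ScenarioResult(haps, geno, truth, freqs, config)


def simulate_admixture_graph(n_snps: int = 50_000, alpha: float = 0.8,
                             t_admix: float = 30.0, n_per_pop: int = 25,
                             n_admixed: int = 27, n_chromosomes: int = 20,
                             chrom_length_m: float = 1.0,
                             seed: int | np.random.Generator = 0) -> GenotypeDataset:
    """Five-population phylogeny with one admixed leaf, for f4-ratio tests.

    Topology (drift amounts as Balding-Nichols steps): an outgroup OUT splits
    first; the remaining lineage separates into an S-side clade (S and the
    hidden sister S') and a W-side clade containing REF and, below it, W and
    the hidden sister W'.  The admixed leaf X draws a fraction ``alpha`` of
    its ancestry from W' and the rest from S', in a single pulse ``t_admix``
    generations ago.  Because REF shares the W-side stem drift with W (and
    with X's W' ancestry) relative to S, the f4 ratio
    f4(OUT, REF; X, S) / f4(OUT, REF; W, S) has expectation ``alpha``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chrom, gpos, ppos = _uniform_map(n_snps, n_chromosomes, chrom_length_m, rng)
    p_root = rng.uniform(0.05, 0.95, n_snps)
    p_out = balding_nichols(p_root, 0.15, rng)
    p_ws = balding_nichols(p_root, 0.02, rng)
    p_w0 = balding_nichols(p_ws, 0.05, rng)    # West-side stem
    p_ref = balding_nichols(p_w0, 0.05, rng)
    p_wa = balding_nichols(p_w0, 0.02, rng)
    p_w = balding_nichols(p_wa, 0.02, rng)
    p_w2 = balding_nichols(p_wa, 0.02, rng)
    p_sa = balding_nichols(p_ws, 0.05, rng)    # South-side stem
    p_s = balding_nichols(p_sa, 0.02, rng)
    p_s2 = balding_nichols(p_sa, 0.02, rng)

    cols, ids, labels = [], [], []
    for name, p in (("OUT", p_out), ("REF", p_ref), ("W", p_w), ("S", p_s)):
        cols.append(rng.binomial(2, p[:, None], (n_snps, n_per_pop)).astype(np.int8))
        ids += [f"{name}_{i}" for i in range(n_per_pop)]
        labels += [name] * n_per_pop
    pool = np.column_stack([p_w2, p_s2])
    H = 2 * n_admixed
    anc = np.empty((n_snps, H), dtype=np.int8)
    for h in range(H):
        for lo, hi in _chrom_bounds(chrom):
            a, _ = _ancestry_track(gpos[lo:hi], chrom_length_m,
                                   [(t_admix, alpha)], rng)
            anc[lo:hi, h] = a
    hx = _draw_alleles(pool, anc, rng)
    cols.append((hx[:, 0::2] + hx[:, 1::2]).astype(np.int8))
    ids += [f"X_{i}" for i in range(n_admixed)]
    labels += ["X"] * n_admixed
    snp_ids = np.array([f"snp{i}" for i in range(n_snps)], dtype=object)
    alleles = np.tile(np.array(["A", "C"], dtype=object), (n_snps, 1))
    return GenotypeDataset(snp_ids, chrom, gpos, ppos, alleles,
                           np.concatenate(cols, axis=1), ids, labels)
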