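"""IBD segment detection and between-population sharing statistics.

Detection is a simplified seed-and-extend matcher over phased haplotypes:
exact-match seeds of a fixed number of consecutive sites (hashed per seed
word) are extended in both directions with zero mismatches, matches between
the four haplotype combinations of two individuals are collapsed to the
individual pair, and segments shorter than a minimum genetic length are
discarded.  The sharing statistic between populations I and J is the summed
segment length over all (i, j) pairs divided by the number of pairs, with a
capped bootstrap over individuals to control unequal group sizes and an
optional regression-based correction for confounding ancestry gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import HaplotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class IBDSegment:
    """A shared haplotype stretch between two individuals."""

    sample_i: str
    sample_j: str
    chrom: str
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class SharingMatrix:
    """Average pairwise IBD sharing (cM) per population pair."""

    pops: list[str]
    values: np.ndarray    # (k, k), symmetric
    n_pairs: np.ndarray   # (k, k)

    def entry(self, popI: str, popJ: str) -> float:
        return float(self.values[self.pops.index(popI), self.pops.index(popJ)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pop_i\tpop_j\tsharing_cm\tn_pairs\n")
            for a, pi in enumerate(self.pops):
                for b, pj in enumerate(self.pops[a:], start=a):
                    fh.write(f"{pi}\t{pj}\t{self.values[a, b]:.6g}\t{self.n_pairs[a, b]}\n")


def detect_ibd_segments(haps: HaplotypeDataset, seed_snps: int = 75,
                        min_cm: float = 3.0) -> list[IBDSegment]:
    """Seed-and-extend IBD detection on phased haplotypes, zero errors.

    Candidate haplotype pairs share at least one exact word of ``seed_snps``
    consecutive sites (words tile each chromosome); each candidate run is the
    maximal mismatch-free stretch around a shared word.  Runs from any of the
    four haplotype combinations of an individual pair are unioned; an
    individual against itself is never reported.
    """
    H = haps.haplotypes
    n_hap = H.shape[1]
    out: list[IBDSegment] = []
    for c in haps.chromosomes:
        sel = np.flatnonzero(haps.chrom == c)
        lo, hi = sel[0], sel[-1] + 1
        g_cm = haps.genetic_pos[lo:hi] * 100.0
        block = np.ascontiguousarray(H[lo:hi].T)  # (n_hap, m_c)
        m_c = hi - lo
        if m_c < seed_snps:
            continue
        pair_runs: dict[tuple[int, int], list[tuple[int, int]]] = {}
        cand: set[tuple[int, int]] = set()
        for w0 in range(0, m_c - seed_snps + 1, seed_snps):
            words = block[:, w0:w0 + seed_snps]
            key = np.ascontiguousarray(words).view(
                np.dtype((np.void, words.shape[1]))).ravel()
            order = np.argsort(key)
            ks = key[order]
            starts = np.flatnonzero(np.r_[True, ks[1:] != ks[:-1]])
            ends = np.r_[starts[1:], len(ks)]
            for s, e in zip(starts, ends):
                if e - s < 2:
                    continue
                grp = order[s:e]
                for a, b in combinations(sorted(grp), 2):
                    if a // 2 == b // 2:
                        continue  # same individual
                    cand.add((a, b))
        for a, b in cand:
            mism = np.flatnonzero(block[a] != block[b])
            bounds = np.r_[-1, mism, m_c]
            for s, e in zip(bounds[:-1] + 1, bounds[1:] - 1):
                if e - s + 1 < seed_snps:
                    continue
                # must fully contain an aligned seed word
                first = ((s + seed_snps - 1) // seed_snps) * seed_snps
                if first + seed_snps - 1 > e or first > m_c - seed_snps:
                    continue
                if g_cm[e] - g_cm[s] < min_cm:
                    continue
                ij = (min(a // 2, b // 2), max(a // 2, b // 2))
                pair_runs.setdefault(ij, []).append((s, e))
        for (i, j), runs in pair_runs.items():
            for s, e in _union_runs(runs):
                if g_cm[e] - g_cm[s] < min_cm:
                    continue
                out.append(IBDSegment(str(haps.sample_ids[i]),
                                      str(haps.sample_ids[j]), str(c),
                                      float(g_cm[s]), float(g_cm[e])))
    out.sort(key=lambda s: (s.sample_i, s.sample_j, s.chrom, s.start_cm))
    return out


def _union_runs(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = []
    for s, e in sorted(runs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def pair_sharing_totals(segments: list[IBDSegment]) -> dict[tuple[str, str], float]:
    """Total shared cM per unordered individual pair."""
    totals: dict[tuple[str, str], float] = {}
    for seg in segments:
        key = tuple(sorted((seg.sample_i, seg.sample_j)))
        totals[key] = totals.get(key, 0.0) + seg.length_cm
    return totals


def sharing_distance(segments: list[IBDSegment], popI: str, popJ: str,
                     sample_ids, pop_labels) -> float:
    """Average pairwise sharing (cM) between populations I and J.

    Sum of segment lengths over all (i in I, j in J) pairs divided by n*m,
    or by n(n-1)/2 within a population.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    pop_labels = np.asarray(pop_labels, dtype=object)
    ids_i = sample_ids[pop_labels == popI]
    ids_j = sample_ids[pop_labels == popJ]
    if len(ids_i) == 0 or len(ids_j) == 0:
        raise ValueError("empty population")
    if popI == popJ:
        n_pairs = len(ids_i) * (len(ids_i) - 1) / 2
    else:
        n_pairs = len(ids_i) * len(ids_j)
    if n_pairs == 0:
        raise ValueError("no pairs between the requested populations")
    set_i, set_j = set(ids_i), set(ids_j)
    total = 0.0
    for (a, b), cm in pair_sharing_totals(segments).items():
        if (a in set_i and b in set_j) or (a in set_j and b in set_i):
            total += cm
    return total / n_pairs


def sharing_matrix(segments: list[IBDSegment], sample_ids,
                   pop_labels) -> SharingMatrix:
    """Full symmetric sharing matrix over all populations present."""
    pop_labels = np.asarray(pop_labels, dtype=object)
    pops = list(dict.fromkeys(pop_labels))
    k = len(pops)
    vals = np.zeros((k, k))
    npair = np.zeros((k, k), dtype=np.int64)
    for a in range(k):
        for b in range(a, k):
            na = (pop_labels == pops[a]).sum()
            nb = (pop_labels == pops[b]).sum()
            npair[a, b] = npair[b, a] = na * (na - 1) // 2 if a == b else na * nb
            if npair[a, b] == 0:  # single-member group: within-sharing undefined
                vals[a, b] = vals[b, a] = np.nan
                continue
            vals[a, b] = vals[b, a] = sharing_distance(
                segments, pops[a], pops[b], sample_ids, pop_labels)
    return SharingMatrix(pops, vals, npair)


def bootstrap_sharing(segments: list[IBDSegment], sample_ids, pop_labels,
                      cap: int = 30, reps: int = 100,
                      seed: int | np.random.Generator = 0):
    """Bootstrap the sharing matrix drawing up to ``cap`` individuals per group.

    Groups at or under the cap are included whole in every replicate; a pair
    of such groups has no resampling variance, so its SE is reported as NaN
    (absent).  Returns (mean SharingMatrix, SE matrix).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sample_ids = np.asarray(sample_ids, dtype=object)
    pop_labels = np.asarray(pop_labels, dtype=object)
    pops = list(dict.fromkeys(pop_labels))
    sizes = {p: int((pop_labels == p).sum()) for p in pops}
    draws = []
    for _ in range(reps):
        chosen = []
        for p in pops:
            idx = np.flatnonzero(pop_labels == p)
            if sizes[p] > cap:
                idx = rng.choice(idx, size=cap, replace=False)
            chosen.append(idx)
        idx = np.concatenate(chosen)
        sm = sharing_matrix(_restrict(segments, set(sample_ids[idx])),
                            sample_ids[idx], pop_labels[idx])
        # reorder to the global pop order
        perm = [sm.pops.index(p) for p in pops]
        draws.append(sm.values[np.ix_(perm, perm)])
    draws = np.array(draws)
    mean = draws.mean(axis=0)
    se = draws.std(axis=0, ddof=1)
    under = np.array([sizes[p] <= cap for p in pops])
    se[np.ix_(under, under)] = np.nan
    npair = sharing_matrix(segments, sample_ids, pop_labels).n_pairs
    return SharingMatrix(pops, mean, npair), se


def _restrict(segments: list[IBDSegment], keep: set) -> list[IBDSegment]:
    return [s for s in segments if s.sample_i in keep and s.sample_j in keep]


def ancestry_corrected_sharing(segments: list[IBDSegment], sample_ids,
                               pop_labels, ancestry: dict,
                               covariate: str = "mean") -> SharingMatrix:
    """Residualize pairwise sharing on an ancestry covariate, re-aggregate.

    ``ancestry`` maps sample id to an ancestry proportion (for example from
    F4 Ratio Estimation).  Each unordered individual pair (zero-sharing pairs
    included) contributes one observation; sharing is regressed on the pair's
    mean ancestry (or ``product``/``min``), and residuals are averaged per
    population pair.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    pop_labels = np.asarray(pop_labels, dtype=object)
    totals = pair_sharing_totals(segments)
    xs, ys, keys = [], [], []
    for a, b in combinations(range(len(sample_ids)), 2):
        ia, ib = sample_ids[a], sample_ids[b]
        pa, pb = ancestry[ia], ancestry[ib]
        if covariate == "mean":
            x = (pa + pb) / 2.0
        elif covariate == "product":
            x = pa * pb
        elif covariate == "min":
            x = min(pa, pb)
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
        xs.append(x)
        ys.append(totals.get(tuple(sorted((ia, ib))), 0.0))
        keys.append((pop_labels[a], pop_labels[b]))
    xs, ys = np.array(xs), np.array(ys)
    if np.ptp(xs) == 0:
        raise ValueError("ancestry covariate is constant across pairs")
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    pops = list(dict.fromkeys(pop_labels))
    k = len(pops)
    vals = np.zeros((k, k))
    cnts = np.zeros((k, k), dtype=np.int64)
    for r, (pa, pb) in zip(resid, keys):
        a, b = pops.index(pa), pops.index(pb)
        vals[a, b] += r
        cnts[a, b] += 1
        if a != b:
            vals[b, a] += r
            cnts[b, a] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cnts > 0, vals / cnts, 0.0)
    return SharingMatrix(pops, vals, cnts)


def segments_to_tsv(segments: list[IBDSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_i\tsample_j\tchrom\tstart_cM\tend_cM\tlength_cM\n")
        for s in segments:
            fh.write(f"{s.sample_i}\t{s.sample_j}\t{s.chrom}\t"
                     f"{s.start_cm:.4f}\t{s.end_cm:.4f}\t{s.length_cm:.4f}\n")


def segments_from_tsv(path) -> list[IBDSegment]:
    """Import segments from a match-file TSV (external detector output)."""
    out = []
    with open(path) as fh:
        next(fh)
        for ln in fh:
            si, sj, c, s, e = ln.split()[:5]
            out.append(IBDSegment(si, sj, c, float(s), float(e)))
    return out
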