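"""Binned SNP-pair statistic engine.

Every decay-curve statistic in this package — weighted LD covariance, the
legacy correlation form and its normalization term, allele-sharing
autocorrelation — is an average over SNP pairs (x, y) on the same chromosome
of some per-pair quantity, binned by genetic separation.  This module
accumulates those sums with banded block matrix products (rows x, columns y
restricted to the distance band), keeping per-chromosome partial sums so that
delete-one-chromosome jackknives are free.

Pair covariances/correlations across columns (samples, or sample pairs) are
pairwise-complete under missing data: masked cross-products give per-pair
counts, means and variances exactly.
"""

from __future__ import annotations

import numpy as np

_BLOCK = 1024


def pair_bin_sums(X: np.ndarray, mask: np.ndarray | None,
                  chrom: np.ndarray, gpos: np.ndarray,
                  bin_width: float, d_max: float,
                  weights: np.ndarray | None = None,
                  stats: tuple[str, ...] = ("wcov",),
                  block: int = _BLOCK) -> tuple[list[str], dict[str, np.ndarray], np.ndarray]:
    """Accumulate per-pair statistics into genetic-distance bins.

    Parameters
    ----------
    X : (m, n) float matrix
        Per-SNP rows over n columns (dosages over samples, or allele-sharing
        values over sample pairs).  Missing entries may hold anything; they
        are governed by ``mask``.
    mask : (m, n) bool or None
        True where observed.  None means fully observed.
    stats : subset of {"wcov", "corr", "wz", "z2"}
        wcov: w_x w_y cov(x, y); corr: Pearson r(x, y); wz: w_x w_y r(x, y);
        z2: r(x, y)^2.
    Returns
    -------
    (chrom_labels, {stat: (n_chrom, n_bins) sums}, (n_chrom, n_bins) counts)
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    need_z = any(s in stats for s in ("corr", "wz", "z2"))
    need_w = any(s in stats for s in ("wcov", "wz"))
    if need_w and weights is None:
        raise ValueError("weights required for weighted statistics")
    if need_w and not np.any(weights):
        raise ValueError("weights are all zero")
    n_bins = int(np.ceil(d_max / bin_width))
    labels = list(dict.fromkeys(chrom))
    sums = {s: np.zeros((len(labels), n_bins)) for s in stats}
    counts = np.zeros((len(labels), n_bins), dtype=np.int64)
    complete = mask is None or bool(mask.all())
    n = X.shape[1]
    for ci, c in enumerate(labels):
        sel = np.flatnonzero(chrom == c)
        lo, hi = sel[0], sel[-1] + 1
        g = gpos[lo:hi]
        w = weights[lo:hi] if weights is not None else None
        if complete:
            Xc = X[lo:hi]
            mu = Xc.mean(axis=1)
            Z = Xc - mu[:, None]
            var = (Z * Z).sum(axis=1) / (n - 1)
            parts = (Z, var)
        else:
            Mc = mask[lo:hi].astype(np.float64)
            Xc = np.where(mask[lo:hi], X[lo:hi], 0.0)
            parts = (Xc, Mc, Xc * Xc)
        for i0 in range(0, hi - lo, block):
            i1 = min(i0 + block, hi - lo)
            j1 = int(np.searchsorted(g, g[i1 - 1] + d_max, side="right"))
            if j1 <= i0 + 1:
                continue
            d = g[None, i0:j1] - g[i0:i1, None]
            jj = np.arange(i0, j1)
            valid = (jj[None, :] > np.arange(i0, i1)[:, None]) & (d <= d_max)
            if not valid.any():
                continue
            bins = np.minimum((d / bin_width).astype(np.int64), n_bins - 1)
            if complete:
                Z, var = parts
                cov = (Z[i0:i1] @ Z[i0:j1].T) / (n - 1)
                if need_z:
                    denom = np.sqrt(np.outer(var[i0:i1], var[i0:j1]))
                    with np.errstate(invalid="ignore", divide="ignore"):
                        z = np.where(denom > 0, cov / denom, 0.0)
            else:
                Xm, Mc, X2 = parts
                N = Mc[i0:i1] @ Mc[i0:j1].T
                Sxy = Xm[i0:i1] @ Xm[i0:j1].T
                Sx = Xm[i0:i1] @ Mc[i0:j1].T
                Sy = Mc[i0:i1] @ Xm[i0:j1].T
                enough = N > 1
                with np.errstate(invalid="ignore", divide="ignore"):
                    cov = np.where(enough, (Sxy - Sx * Sy / N) / (N - 1), 0.0)
                valid = valid & enough
                if need_z:
                    Sxx = X2[i0:i1] @ Mc[i0:j1].T
                    Syy = Mc[i0:i1] @ X2[i0:j1].T
                    with np.errstate(invalid="ignore", divide="ignore"):
                        vx = np.where(enough, (Sxx - Sx * Sx / N) / (N - 1), 0.0)
                        vy = np.where(enough, (Syy - Sy * Sy / N) / (N - 1), 0.0)
                        denom = np.sqrt(vx * vy)
                        z = np.where(denom > 0, cov / denom, 0.0)
            vb = bins[valid]
            if need_w:
                ww = np.outer(w[i0:i1], w[i0:j1])
            for s in stats:
                if s == "wcov":
                    vals = (ww * cov)[valid]
                elif s == "corr":
                    vals = z[valid]
                elif s == "wz":
                    vals = (ww * z)[valid]
                elif s == "z2":
                    vals = (z * z)[valid]
                else:
                    raise ValueError(f"unknown statistic {s!r}")
                sums[s][ci] += np.bincount(vb, weights=vals, minlength=n_bins)
            counts[ci] += np.bincount(vb, minlength=n_bins)
    return labels, sums, counts


def brute_force_bins(X: np.ndarray, mask: np.ndarray | None,
                     chrom: np.ndarray, gpos: np.ndarray,
                     bin_width: float, d_max: float,
                     weights: np.ndarray | None = None,
                     stat: str = "wcov") -> tuple[np.ndarray, np.ndarray]:
    """Slow reference implementation: explicit double loop over SNP pairs.

    Defines the semantics the fast engine must reproduce; used as the oracle
    in tests and kept here so the contract lives next to the implementation.
    """
    n_bins = int(np.ceil(d_max / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    m = X.shape[0]
    for i in range(m):
        for j in range(i + 1, m):
            if chrom[i] != chrom[j]:
                continue
            d = gpos[j] - gpos[i]
            if d > d_max:
                continue
            if mask is None:
                both = np.ones(X.shape[1], bool)
            else:
                both = mask[i] & mask[j]
            if both.sum() < 2:
                continue
            x, y = X[i, both], X[j, both]
            cov = ((x - x.mean()) * (y - y.mean())).sum() / (both.sum() - 1)
            if stat == "wcov":
                val = weights[i] * weights[j] * cov
            else:
                sx = x.std(ddof=1)
                sy = y.std(ddof=1)
                z = cov / (sx * sy) if sx > 0 and sy > 0 else 0.0
                val = {"corr": z, "z2": z * z,
                       "wz": (weights[i] * weights[j] * z) if weights is not None else None}[stat]
            b = min(int(d / bin_width), n_bins - 1)
            sums[b] += val
            counts[b] += 1
    return sums, counts
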