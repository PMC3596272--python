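"""Per-SNP weights for the admixture-LD statistic.

Weights can be ancestral allele-frequency differences (when reference panels
for both sources exist) or SNP loadings from a PCA of reference panels, which
capture the same frequency differentiation when only one source — or only
admixed proxies — is available.  Because the dating statistic multiplies two
weights, its decay rate is invariant to the weights' sign and scale; PCA
loadings are therefore returned unit-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import MISSING, AlleleFrequencyTable, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Per-SNP weights driving the admixture-LD signal.

    ``values`` is aligned to the SNPs of the target dataset; SNPs without a
    usable weight (monomorphic in the reference, missing frequency) carry 0
    and so contribute nothing downstream.
    """

    values: np.ndarray
    provenance: str            # "freq-difference" | "pca-loading"
    axis: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path, snp_ids: np.ndarray) -> None:
        with open(path, "w") as fh:
            fh.write("snp_id\tweight\tprovenance\n")
            for s, w in zip(snp_ids, self.values):
                fh.write(f"{s}\t{w:.8g}\t{self.provenance}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightVector":
        vals, prov = [], "freq-difference"
        with open(path) as fh:
            next(fh)
            for ln in fh:
                parts = ln.split()
                vals.append(float(parts[1]))
                prov = parts[2]
        return cls(np.array(vals), prov)


def standardize_genotypes(data: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """SMARTPCA-style normalization of the dosage matrix.

    Per SNP: subtract the mean dosage and divide by sqrt(p(1-p)) with p the
    sample alt frequency; missing calls become 0 after centering.  Monomorphic
    (or all-missing) SNPs are dropped.  Returns ``(matrix, kept)`` where
    ``kept`` indexes the surviving SNPs in the input.
    """
    d = data.dosages.astype(float)
    obs = data.dosages != MISSING
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(obs, d, 0).sum(axis=1) / n_obs
    p = mean / 2.0
    sd = np.sqrt(p * (1 - p))
    kept = np.flatnonzero((n_obs > 0) & (sd > 0))
    if len(kept) < data.n_snps:
        logger.info("standardize_genotypes: dropped %d monomorphic/all-missing SNPs",
                    data.n_snps - len(kept))
    z = np.where(obs[kept], d[kept] - mean[kept, None], 0.0) / sd[kept, None]
    return z, kept


def pca_loadings(reference: GenotypeDataset, axis: int | None = None,
                 exclude_pops: list[str] | None = None,
                 n_axes: int = 10) -> WeightVector:
    """SNP loadings of a principal axis of the reference panel.

    The admixed target population should be excluded from the panel (pass its
    label in ``exclude_pops``).  When ``axis`` is None, the returned axis is
    the one (among the leading ``n_axes``) that maximizes between-population
    separation of sample scores — the analogue of picking the ancestry cline
    by eye.  Loadings are unit-norm; global sign is arbitrary and has no
    downstream effect.
    """
    panel = reference
    if exclude_pops:
        keep = np.flatnonzero(~np.isin(panel.pop_labels, exclude_pops))
        panel = panel.take_samples(keep)
    if panel.n_samples < 2:
        raise ValueError("need at least 2 reference samples for PCA")
    z, kept = standardize_genotypes(panel)
    n = panel.n_samples
    # sample-by-sample covariance keeps memory at n^2 regardless of SNP count
    cov = (z.T @ z) / len(kept)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_axes, n - 1)
    if axis is None:
        axis = int(np.argmax([_between_within_ratio(vecs[:, a], panel.pop_labels)
                              for a in range(k)]))
    v = vecs[:, axis]
    load = z @ v
    norm = np.linalg.norm(load)
    if norm == 0:
        raise ValueError("degenerate axis: zero loadings")
    full = np.zeros(reference.n_snps)
    full[kept] = load / norm
    return WeightVector(full, "pca-loading", axis)


def _between_within_ratio(scores: np.ndarray, labels: np.ndarray) -> float:
    groups = [scores[labels == g] for g in dict.fromkeys(labels)]
    if len(groups) < 2:
        return 0.0
    grand = scores.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return between / within if within > 0 else np.inf


def freq_difference_weights(freqs: AlleleFrequencyTable, popA: str,
                            popB: str) -> WeightVector:
    """w = pA - pB per SNP; SNPs with a missing frequency get weight 0."""
    w = freqs.freq(popA) - freqs.freq(popB)
    ok = np.isfinite(w) & (freqs.count(popA) > 0) & (freqs.count(popB) > 0)
    return WeightVector(np.where(ok, w, 0.0), "freq-difference")
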