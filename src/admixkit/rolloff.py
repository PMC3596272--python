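"""Admixture dating from the decay of weighted LD with genetic distance.

The statistic ``R(d)`` averages, over SNP pairs (x, y) at genetic separation
``d``, the sample covariance of dosages multiplied by the per-SNP weights
w(x)w(y) (ancestral frequency differences or PCA loadings).  Under a single
admixture pulse ``n`` generations ago, admixture LD — and with it R(d) —
decays as ``exp(-n d)``, so fitting ``A exp(-n d) + c`` dates the pulse; a sum
of two exponentials dates a two-pulse history.  Standard errors come from a
weighted delete-one-chromosome jackknife.

The covariance form is used throughout because the older correlation-form
statistic carries a normalization term that itself decays exponentially under
a strong post-admixture founder event (at roughly twice the event age),
dragging fitted dates downward; :func:`legacy_correlation_curve` exposes that
diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .data import MISSING, GenotypeDataset
from .fstats import JackknifeEstimate, jackknife_from_deletes
from .paircurve import pair_bin_sums
from .weights import WeightVector

logger = logging.getLogger(__name__)

#: default fit window and binning, Morgans (0.5-30 cM, 0.1 cM bins)
DEFAULT_BIN_W = 0.001
DEFAULT_D_MAX = 0.3
DEFAULT_D_MIN = 0.005

_SINGLE_STARTS = (5.0, 20.0, 50.0, 150.0, 400.0)
_TWO_PULSE_GRID = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)


@dataclass
class DecayCurve:
    """A binned statistic-versus-genetic-distance series.

    ``chrom_sums``/``chrom_counts`` hold per-chromosome partial sums so a
    chromosome can be deleted without re-scanning pairs.
    """

    d: np.ndarray              # bin centers, Morgans
    value: np.ndarray          # statistic per bin (NaN where empty)
    count: np.ndarray          # pair count per bin
    bin_width: float
    fit_window: tuple[float, float] | None = None
    chrom_labels: list[str] = field(default_factory=list)
    chrom_sums: np.ndarray | None = None    # (n_chrom, n_bins)
    chrom_counts: np.ndarray | None = None

    def drop_chromosome(self, label: str) -> "DecayCurve":
        i = self.chrom_labels.index(label)
        keep = [j for j in range(len(self.chrom_labels)) if j != i]
        sums = self.chrom_sums[keep].sum(axis=0)
        counts = self.chrom_counts[keep].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(counts > 0, sums / counts, np.nan)
        return DecayCurve(self.d, value, counts, self.bin_width, self.fit_window,
                          [self.chrom_labels[j] for j in keep],
                          self.chrom_sums[keep], self.chrom_counts[keep])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("d_morgans\tvalue\tn_pairs\n")
            for d, v, c in zip(self.d, self.value, self.count):
                fh.write(f"{d:.6f}\t{v:.8g}\t{c}\n")


@dataclass
class ExponentialFit:
    """Single-pulse fit A exp(-n d) + c."""

    n_generations: float
    amplitude: float
    affine: float
    se: float                  # curvature-based SE of n (jackknife preferred)
    fit_window: tuple[float, float]
    residual_norm: float
    signal: bool = True        # False when the fitted amplitude is negative


@dataclass
class TwoPulseFit:
    """Two-pulse fit A1 exp(-n1 d) + A2 exp(-n2 d) + c, with n1 > n2."""

    n1: float
    n2: float
    a1: float
    a2: float
    affine: float
    converged: bool
    degenerate: bool = False   # pulses indistinguishable (n1/n2 < 1.5)


def _curve_from_sums(labels, sums, counts, bin_width, d_max) -> DecayCurve:
    total_s = sums.sum(axis=0)
    total_c = counts.sum(axis=0)
    n_bins = len(total_c)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(total_c > 0, total_s / total_c, np.nan)
    return DecayCurve(centers, value, total_c, bin_width,
                      chrom_labels=list(labels), chrom_sums=sums,
                      chrom_counts=counts)


def weighted_ld_curve(data: GenotypeDataset, weights: WeightVector | np.ndarray,
                      bin_width: float = DEFAULT_BIN_W,
                      d_max: float = DEFAULT_D_MAX,
                      pop: str | None = None) -> DecayCurve:
    """Compute R(d): binned weighted dosage covariance vs genetic distance.

    Pairs are taken within chromosomes only; covariance is over individuals
    with both calls present.  ``pop`` restricts the sample columns to one
    population (the admixed target).
    """
    target = data if pop is None else data.take_samples(data.samples_in(pop))
    if target.n_samples < 2:
        raise ValueError("need at least 2 samples")
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if len(w) != target.n_snps:
        raise ValueError("weights not aligned to SNPs")
    X = target.dosages.astype(np.float64)
    obs = target.dosages != MISSING
    mask = None if obs.all() else obs
    labels, sums, counts = pair_bin_sums(X, mask, target.chrom,
                                         target.genetic_pos, bin_width, d_max,
                                         weights=w, stats=("wcov",))
    return _curve_from_sums(labels, sums["wcov"], counts, bin_width, d_max)


def legacy_correlation_curve(data: GenotypeDataset,
                             weights: WeightVector | np.ndarray,
                             bin_width: float = DEFAULT_BIN_W,
                             d_max: float = DEFAULT_D_MAX,
                             pop: str | None = None) -> tuple[DecayCurve, DecayCurve]:
    """Correlation-form statistic and its squared normalization term vs d.

    Returns ``(legacy, norm2)``: ``legacy`` bins the weighted SNP-pair
    correlation divided by the root mean squared correlation of its bin, and
    ``norm2`` is that mean squared correlation itself.  Without a bottleneck
    ``norm2`` is flat in d; a founder event g generations ago makes it decay
    approximately as exp(-2 g d), which is what biases correlation-form
    dates.  This reconstructs the documented behavior of the original
    normalization; its exact algebra is not restated here.
    """
    target = data if pop is None else data.take_samples(data.samples_in(pop))
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, float)
    X = target.dosages.astype(np.float64)
    obs = target.dosages != MISSING
    mask = None if obs.all() else obs
    labels, sums, counts = pair_bin_sums(X, mask, target.chrom,
                                         target.genetic_pos, bin_width, d_max,
                                         weights=w, stats=("wz", "z2"))
    norm2 = _curve_from_sums(labels, sums["z2"], counts, bin_width, d_max)
    total_c = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_wz = np.where(total_c > 0, sums["wz"].sum(axis=0) / total_c, np.nan)
        legacy_val = mean_wz / np.sqrt(norm2.value)
    legacy = DecayCurve(norm2.d, legacy_val, total_c, bin_width,
                        chrom_labels=list(labels), chrom_sums=sums["wz"],
                        chrom_counts=counts)
    return legacy, norm2


def _usable_bins(curve: DecayCurve, d_min: float, d_max: float | None):
    d_hi = d_max if d_max is not None else float(curve.d[-1] + curve.bin_width)
    sel = (curve.count > 0) & np.isfinite(curve.value) & \
          (curve.d >= d_min) & (curve.d <= d_hi)
    return curve.d[sel], curve.value[sel], curve.count[sel], d_hi


def fit_single_exponential(curve: DecayCurve, d_min: float = DEFAULT_D_MIN,
                           d_max: float | None = None) -> ExponentialFit:
    """Count-weighted nonlinear least squares of A exp(-n d) + c.

    Bins below ``d_min`` (default 0.5 cM, where background LD confounds
    admixture LD on real data) are excluded.  Multi-start initialization over
    decay rates {5, 20, 50, 150, 400} per Morgan guards against local optima.
    """
    d, y, cnt, d_hi = _usable_bins(curve, d_min, d_max)
    if len(d) < 5:
        raise ValueError(f"only {len(d)} usable bins in [{d_min}, {d_hi}]")
    sigma = 1.0 / np.sqrt(cnt)

    def model(x, a, n, c):
        return a * np.exp(-n * x) + c

    best = None
    for n0 in _SINGLE_STARTS:
        a0 = max(y[0] - y[-1], 1e-8)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, d, y, p0=(a0, n0, y[-1]),
                                       sigma=sigma, maxfev=20000,
                                       xtol=1e-10, ftol=1e-10)
        except RuntimeError:
            continue
        resid = np.linalg.norm((model(d, *popt) - y) / sigma)
        if best is None or resid < best[1]:
            best = (popt, resid, pcov)
    if best is None:
        raise RuntimeError("exponential fit failed from every start")
    (a, n, c), resid, pcov = best
    if n < 0:  # canonicalize a growing fit as negative signal
        a, n = -abs(a), abs(n)
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    # a decay faster than ~2 bins cannot be resolved on this grid: such fits
    # are one-bin spikes chasing noise, not signal
    resolvable = n <= 2.0 / curve.bin_width
    fit = ExponentialFit(float(n), float(a), float(c), se, (d_min, d_hi),
                         float(resid), signal=bool(a > 0 and resolvable))
    if a <= 0:
        logger.warning("fitted amplitude %.3g <= 0: no admixture-LD signal", a)
    elif not resolvable:
        logger.warning("fitted rate %.3g exceeds the bin resolution: "
                       "treated as no signal", n)
    return fit


def fit_two_pulse(curve: DecayCurve, d_min: float = DEFAULT_D_MIN,
                  d_max: float | None = None,
                  min_ratio: float = 1.5) -> TwoPulseFit:
    """Fit A1 exp(-n1 d) + A2 exp(-n2 d) + c over an ordered multi-start grid.

    Solutions are reported with n1 > n2.  If the best fit has n1/n2 below
    ``min_ratio`` the two pulses are not identifiable; the fit falls back to
    the single-pulse model with a warning (``degenerate=True``).
    """
    d, y, cnt, d_hi = _usable_bins(curve, d_min, d_max)
    if len(d) < 8:
        raise ValueError(f"only {len(d)} usable bins in [{d_min}, {d_hi}]")
    sigma = 1.0 / np.sqrt(cnt)

    def model(x, a1, n1, a2, n2, c):
        return a1 * np.exp(-n1 * x) + a2 * np.exp(-n2 * x) + c

    best = None
    span = max(y[0] - y[-1], 1e-8)
    for i, n1 in enumerate(_TWO_PULSE_GRID):
        for n2 in _TWO_PULSE_GRID[:i]:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(model, d, y,
                                        p0=(span / 2, n1, span / 2, n2, y[-1]),
                                        sigma=sigma, maxfev=20000,
                                        xtol=1e-10, ftol=1e-10)
            except RuntimeError:
                continue
            resid = np.linalg.norm((model(d, *popt) - y) / sigma)
            if best is None or resid < best[1]:
                best = (popt, resid)
    if best is None:
        raise RuntimeError("two-pulse fit failed from every start")
    a1, n1, a2, n2, c = best[0]
    if abs(n2) > abs(n1):
        a1, n1, a2, n2 = a2, n2, a1, n1
    n1, n2 = abs(n1), abs(n2)
    if n2 == 0 or n1 / max(n2, 1e-12) < min_ratio:
        logger.warning("two-pulse fit degenerate (n1=%.2f, n2=%.2f); "
                       "falling back to single pulse", n1, n2)
        single = fit_single_exponential(curve, d_min, d_max)
        return TwoPulseFit(single.n_generations, np.nan, single.amplitude,
                           0.0, single.affine, True, degenerate=True)
    return TwoPulseFit(float(n1), float(n2), float(a1), float(a2), float(c),
                       True)


def jackknife_date(data: GenotypeDataset, weights: WeightVector | np.ndarray,
                   bin_width: float = DEFAULT_BIN_W,
                   d_max: float = DEFAULT_D_MAX,
                   d_min: float = DEFAULT_D_MIN,
                   pop: str | None = None) -> JackknifeEstimate:
    """Admixture date with delete-one-chromosome jackknife standard error.

    Block weights are per-chromosome SNP counts; delete-one fits that fail to
    converge are excluded with a warning.
    """
    target = data if pop is None else data.take_samples(data.samples_in(pop))
    if len(target.chromosomes) < 2:
        raise ValueError("chromosome jackknife needs at least 2 chromosomes")
    curve = weighted_ld_curve(target, weights, bin_width, d_max)
    full = fit_single_exponential(curve, d_min, d_max).n_generations
    dels, wts = [], []
    for c in curve.chrom_labels:
        try:
            fit = fit_single_exponential(curve.drop_chromosome(c), d_min, d_max)
            dels.append(fit.n_generations)
        except (RuntimeError, ValueError):
            logger.warning("delete-%s fit failed; excluded from jackknife", c)
            dels.append(np.nan)
        wts.append(int((target.chrom == c).sum()))
    return jackknife_from_deletes(full, np.array(dels), np.array(wts),
                                  "chromosome")


def generations_to_years(n: float, gen_time: float = 29.0) -> float:
    """Convert generations to years (default 29 years per generation)."""
    if n <= 0:
        raise ValueError("generations must be positive")
    return n * gen_time


def years_interval(n: float, se: float, gen_time: float = 29.0,
                   round_to: int = 10) -> tuple[float, float]:
    """Reported calendar interval for n +/- se generations, rounded."""
    lo = generations_to_years(n - se, gen_time)
    hi = generations_to_years(n + se, gen_time)
    if round_to:
        lo = round(lo / round_to) * round_to
        hi = round(hi / round_to) * round_to
    return lo, hi
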