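"""Windowed population-genetic statistics.

Implements per-window nucleotide diversity pi, Watterson's thetaW, Tajima's D,
the two-population Weir–Cockerham (1984) FST with full finite-sample
corrections, the ancestral/introduced pi ratio, and linkage-disequilibrium
decay from unphased genotypes (squared Pearson correlation of 0/1/2 dosage
codes, Rogers–Huff style).

Missing data: per-site allele counts use the called alleles only.  For the
Tajima's D constants, which need a single sample size per window, n_eff is
the window's median called-allele count.  Undefined statistics propagate as
NaN, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from palmscan.io_core import (
    MISSING,
    ConfigurationError,
    GenomicWindow,
    GenotypeMatrix,
)

logger = logging.getLogger("palmscan")


# ---------------------------------------------------------------------------
# Site-level building blocks
# ---------------------------------------------------------------------------


def site_pi(alt_count: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity c(n-c)/C(n,2); NaN where n < 2."""
    c = np.asarray(alt_count, dtype=float)
    n = np.asarray(n_called, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = c * (n - c) / (n * (n - 1) / 2.0)
    out = np.where(n >= 2, out, np.nan)
    return out


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for sample size n alleles."""
    if n < 2:
        raise ConfigurationError("Tajima constants need n >= 2 alleles")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def wc_fst_components(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components a, b, c for two
    populations at one biallelic site.

    n1, n2: diploid individuals with calls; p1, p2: alt-allele frequencies;
    h1, h2: observed heterozygote frequencies.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        return np.nan, np.nan, np.nan
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    if n_c <= 0:
        return np.nan, np.nan, np.nan
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_variants(
    matrix: GenotypeMatrix,
    max_missing_fraction: float = 1.0,
    min_maf: float = 0.0,
) -> GenotypeMatrix:
    """Drop sites with too much missingness or too low minor-allele frequency.

    A site is removed when its missing-genotype fraction exceeds
    ``max_missing_fraction`` (strict: a fraction exactly at the threshold is
    kept, so e.g. 21 missing of 72 fails a 20/72 threshold while 20 passes)
    or when its minor-allele frequency over called alleles is below
    ``min_maf``.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ConfigurationError("max_missing_fraction must be in [0, 1]")
    miss_frac = np.mean(matrix.gt == MISSING, axis=1)
    n = matrix.n_called().astype(float)
    c = matrix.alt_count().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n > 0, c / n, np.nan)
    maf = np.fmin(freq, 1.0 - freq)
    keep_miss = miss_frac <= max_missing_fraction
    keep_maf = np.where(np.isnan(maf), False, maf >= min_maf) | (min_maf == 0)
    keep = keep_miss & keep_maf
    logger.info(
        "filter_variants: %d sites in, %d failed missingness, %d failed MAF, %d out",
        matrix.n_sites,
        int(np.sum(~keep_miss)),
        int(np.sum(keep_miss & ~keep_maf)),
        int(keep.sum()),
    )
    if keep.sum() == 0:
        logger.warning("filter_variants: no sites retained")
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# Windowed diversity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiversityWindowStats:
    window: GenomicWindow
    S: int
    pi: float  # per-bp
    theta_w: float  # per-bp
    tajima_d: float  # NaN iff S == 0
    n_eff: int


def window_diversity(
    matrix: GenotypeMatrix,
    windows: list[GenomicWindow],
    population: str | None = None,
) -> list[DiversityWindowStats]:
    """Per-window S, pi, Watterson's theta and Tajima's D for one population
    (or the full sample when ``population`` is None)."""
    sub = matrix.for_population(population) if population else matrix
    if sub.n_samples < 2:
        raise ConfigurationError("window_diversity needs >= 2 samples")
    n_called = sub.n_called()
    alt = sub.alt_count()
    pi_sites = site_pi(alt, n_called)
    seg = (alt > 0) & (alt < n_called)

    out = []
    for w in windows:
        m = sub.sites_in(w)
        S = int(np.sum(seg & m))
        pi_sum = float(np.nansum(pi_sites[m]))
        called_here = n_called[m & (n_called > 1)]
        n_eff = int(np.median(called_here)) if len(called_here) else sub.n_samples * 2
        if n_eff < 2:
            n_eff = 2
        k = tajima_constants(n_eff)
        theta_w = S / (k["a1"] * w.length)
        if S == 0:
            d = np.nan
        else:
            var = k["e1"] * S + k["e2"] * S * (S - 1)
            d = (pi_sum - S / k["a1"]) / np.sqrt(var) if var > 0 else np.nan
        out.append(
            DiversityWindowStats(w, S, pi_sum / w.length, theta_w, d, n_eff)
        )
    return out


# ---------------------------------------------------------------------------
# Windowed FST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstWindowStats:
    window: GenomicWindow
    sum_a: float
    sum_abc: float
    fst: float  # NaN when no usable sites
    n_sites_used: int


def _pop_site_arrays(matrix: GenotypeMatrix, population: str):
    sub = matrix.for_population(population)
    called = sub.gt != MISSING
    n_ind = called.sum(axis=1).astype(float)
    g = np.where(called, sub.gt, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = g.sum(axis=1) / (2.0 * n_ind)
        h = (sub.gt == 1).sum(axis=1) / n_ind
    return n_ind, p, h


def window_fst(
    matrix: GenotypeMatrix,
    windows: list[GenomicWindow],
    pop_a: str,
    pop_b: str,
) -> list[FstWindowStats]:
    """Weir–Cockerham ratio-of-sums FST per window.

    Sites monomorphic across both populations are skipped; negative per-site
    components are retained in the sums (standard estimator behavior).
    """
    for p in (pop_a, pop_b):
        if np.sum(matrix.populations == p) < 2:
            raise ConfigurationError(f"population {p!r} needs >= 2 samples")
    n1, p1, h1 = _pop_site_arrays(matrix, pop_a)
    n2, p2, h2 = _pop_site_arrays(matrix, pop_b)

    # vectorized W&C components across all sites
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    poly = ~((p_bar == 0) | (p_bar == 1))  # monomorphic across both -> skip
    usable = poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n_bar > 1) & (n_c > 0)

    out = []
    for w in windows:
        m = matrix.sites_in(w) & usable
        sa = float(a[m].sum())
        sabc = float((a[m] + b[m] + c[m]).sum())
        fst = sa / sabc if sabc != 0 else np.nan
        out.append(FstWindowStats(w, sa, sabc, fst, int(m.sum())))
    return out


def genome_fst(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Genome-wide ratio-of-sums Weir–Cockerham FST."""
    chroms = list(dict.fromkeys(matrix.chrom))
    windows = [
        GenomicWindow(c, 0, int(matrix.pos[matrix.chrom == c].max())) for c in chroms
    ]
    stats = window_fst(matrix, windows, pop_a, pop_b)
    sa = sum(s.sum_a for s in stats)
    sabc = sum(s.sum_abc for s in stats)
    return sa / sabc if sabc else np.nan


# ---------------------------------------------------------------------------
# pi ratio
# ---------------------------------------------------------------------------


def window_pi_ratio(
    div_anc: list[DiversityWindowStats],
    div_intro: list[DiversityWindowStats],
) -> pd.DataFrame:
    """Per-window ratio pi_ancestral / pi_introduced (theta_pi scan statistic).

    Windows where the denominator is 0 get NaN (excluded from quantiles
    downstream); log2 of the ratio is also reported.
    """
    if [d.window for d in div_anc] != [d.window for d in div_intro]:
        raise ConfigurationError("pi-ratio inputs use different window grids")
    rows = []
    for da, di in zip(div_anc, div_intro):
        if di.pi > 0:
            ratio = da.pi / di.pi
        else:
            ratio = np.nan
        rows.append(
            {
                "chrom": da.window.chrom,
                "start": da.window.start,
                "end": da.window.end,
                "pi_anc": da.pi,
                "pi_intro": di.pi,
                "pi_ratio": ratio,
                "log2_pi_ratio": np.log2(ratio) if ratio and ratio > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDBin:
    lo: int
    hi: int
    mean_r2: float
    n_pairs: int


@dataclass(frozen=True)
class LDDecay:
    bins: list
    half_decay_distance: float  # NaN when undefined


def _pairwise_r2(gt: np.ndarray, pos: np.ndarray, max_dist: int):
    """Distances and r^2 for all site pairs within max_dist (one chromosome).

    r^2 is the squared Pearson correlation of dosage codes over samples
    called at both sites (composite/Rogers–Huff LD for unphased data).
    """
    n_sites = len(pos)
    called = (gt != MISSING).astype(np.float64)
    g = np.where(gt == MISSING, 0, gt).astype(np.float64)
    g2 = g * g
    dists, r2s = [], []
    # one anchor site against all partners within range, in vectorised blocks;
    # pairwise-complete sums give the same r^2 as per-pair Pearson correlation
    for i in range(n_sites):
        j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        if j_hi <= i + 1:
            continue
        J = slice(i + 1, j_hi)
        n_ok = called[J] @ called[i]
        sx = called[J] @ g[i]
        sy = g[J] @ called[i]
        sxy = g[J] @ g[i]
        sxx = called[J] @ g2[i]
        syy = g2[J] @ called[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / n_ok
            var_x = sxx - sx * sx / n_ok
            var_y = syy - sy * sy / n_ok
            r2 = cov * cov / (var_x * var_y)
        keep = (n_ok >= 2) & (var_x > 0) & (var_y > 0)
        if not keep.any():
            continue
        dists.append((pos[i + 1 : j_hi] - pos[i])[keep])
        r2s.append(r2[keep])
    if not dists:
        return np.array([], dtype=int), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def ld_decay(
    matrix: GenotypeMatrix,
    population: str | None = None,
    max_dist: int = 100_000,
    bin_width: int = 1_000,
    min_maf: float = 0.02,
    smooth_bins: int = 3,
) -> LDDecay:
    """Binned mean r^2 vs distance and the half-decay distance.

    The half-decay distance is the smallest bin midpoint at which the
    (moving-average smoothed) mean r^2 falls to (r2_max + r2_floor)/2, where
    r2_floor is the mean over the last 10% of bins.
    """
    if max_dist <= 0:
        raise ConfigurationError("max_dist must be positive")
    sub = matrix.for_population(population) if population else matrix
    sub = filter_variants(sub, min_maf=min_maf)
    if sub.n_sites < 2:
        logger.warning("ld_decay: fewer than 2 sites after filters")
        return LDDecay([], np.nan)

    all_d, all_r2 = [], []
    for c in dict.fromkeys(sub.chrom):
        m = sub.chrom == c
        d, r2 = _pairwise_r2(sub.gt[m], sub.pos[m], max_dist)
        all_d.append(d)
        all_r2.append(r2)
    d = np.concatenate(all_d)
    r2 = np.concatenate(all_r2)
    if len(d) == 0:
        logger.warning("ld_decay: no site pairs within max_dist")
        return LDDecay([], np.nan)

    n_bins = int(np.ceil(max_dist / bin_width))
    idx = np.minimum(d // bin_width, n_bins - 1)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = [
        LDBin(k * bin_width, (k + 1) * bin_width, float(means[k]), int(counts[k]))
        for k in range(n_bins)
    ]

    valid = ~np.isnan(means)
    if valid.sum() < 2:
        return LDDecay(bins, np.nan)
    sm = pd.Series(means).rolling(smooth_bins, min_periods=1, center=True).mean().to_numpy()
    tail = max(1, int(np.ceil(valid.sum() * 0.1)))
    valid_idx = np.nonzero(valid)[0]
    floor = float(np.nanmean(sm[valid_idx[-tail:]]))
    peak = float(np.nanmax(sm[valid]))
    level = (peak + floor) / 2.0
    half = np.nan
    for k in valid_idx:
        if sm[k] <= level:
            half = (k + 0.5) * bin_width
            break
    return LDDecay(bins, half)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def diversity_to_frame(stats: list[DiversityWindowStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.window.chrom for s in stats],
            "start": [s.window.start for s in stats],
            "end": [s.window.end for s in stats],
            "S": [s.S for s in stats],
            "pi": [s.pi for s in stats],
            "theta_w": [s.theta_w for s in stats],
            "tajima_d": [s.tajima_d for s in stats],
            "n_eff": [s.n_eff for s in stats],
        }
    )


def fst_to_frame(stats: list[FstWindowStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.window.chrom for s in stats],
            "start": [s.window.start for s in stats],
            "end": [s.window.end for s in stats],
            "sum_a": [s.sum_a for s in stats],
            "sum_abc": [s.sum_abc for s in stats],
            "fst": [s.fst for s in stats],
            "n_sites_used": [s.n_sites_used for s in stats],
        }
    )
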