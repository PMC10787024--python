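"""Empirical-quantile outlier calling and outlier-intersection selection scan.

The scan follows the study design: windows in the top 5% of the empirical
distributions of both FST and the ancestral/introduced pi ratio are
intersected and merged into candidate regions; a region "deviates from
neutrality" when at least one of its windows is in the bottom 5% of Tajima's
D computed within the introduced population.  Genes overlapping a region by
at least 1 bp are reported as under putative selection.

The quantile rule is nearest-rank with inclusive ties: for the upper tail the
threshold is the value at ascending rank ceil((1-q)*m) and outliers are
values >= threshold; the lower tail mirrors it (rank m+1-ceil((1-q)*m),
values <= threshold).  Windows whose statistic is undefined are excluded from
the quantile and can never be outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from palmscan.io_core import ConfigurationError, GenomicWindow, FeatureRecord


@dataclass(frozen=True)
class OutlierCall:
    window: GenomicWindow
    statistic: str  # fst | pi_ratio | tajima_d
    value: float
    threshold: float
    is_outlier: bool


@dataclass
class SelectionRegion:
    chrom: str
    start: int
    end: int
    windows: list = field(default_factory=list)
    supporting: set = field(default_factory=set)
    tajima_supported: bool = False
    gene_ids: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Quantile thresholds
# ---------------------------------------------------------------------------


def empirical_threshold(values, tail: str, q: float) -> float:
    """Nearest-rank empirical tail threshold.

    ``tail`` is "upper" (outliers >= threshold) or "lower" (<= threshold);
    ``q`` is the tail mass (e.g. 0.05 for "top 5%").  NaNs are dropped first.
    """
    if not 0 < q < 1:
        raise ConfigurationError("q must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])
    m = len(v)
    if m == 0:
        raise ConfigurationError("no defined values to take a quantile of")
    if tail == "upper":
        rank = math.ceil((1.0 - q) * m)
    elif tail == "lower":
        rank = m + 1 - math.ceil((1.0 - q) * m)
    else:
        raise ConfigurationError(f"tail must be 'upper' or 'lower', got {tail!r}")
    rank = min(max(rank, 1), m)
    return float(v[rank - 1])


def call_outliers(
    windows: list[GenomicWindow],
    values,
    statistic: str,
    q: float = 0.05,
    tail: str = "upper",
) -> list[OutlierCall]:
    """Flag per-window outliers by the nearest-rank tail rule (ties included)."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(windows):
        raise ConfigurationError("one value per window required")
    thr = empirical_threshold(values, tail, q)
    calls = []
    for w, v in zip(windows, values):
        if np.isnan(v):
            flag = False
        elif tail == "upper":
            flag = v >= thr
        else:
            flag = v <= thr
        calls.append(OutlierCall(w, statistic, float(v), thr, bool(flag)))
    return calls


# ---------------------------------------------------------------------------
# Intersection and merging
# ---------------------------------------------------------------------------


def _grids_match(a: list[OutlierCall], b: list[OutlierCall]) -> bool:
    return [c.window for c in a] == [c.window for c in b]


def intersect_outliers(
    fst_calls: list[OutlierCall], ratio_calls: list[OutlierCall]
) -> list[GenomicWindow]:
    """Windows flagged outlier in BOTH scans (same window grid required)."""
    if not _grids_match(fst_calls, ratio_calls):
        raise ConfigurationError("outlier calls use different window grids")
    return [
        f.window
        for f, r in zip(fst_calls, ratio_calls)
        if f.is_outlier and r.is_outlier
    ]


def merge_regions(windows: list[GenomicWindow]) -> list[SelectionRegion]:
    """Merge overlapping or book-ended windows into maximal regions."""
    ordered = sorted(set(windows), key=lambda w: (w.chrom, w.start, w.end))
    regions: list[SelectionRegion] = []
    for w in ordered:
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.windows.append(w)
        else:
            regions.append(SelectionRegion(w.chrom, w.start, w.end, [w]))
    return regions


def region_summary(regions: list[SelectionRegion], genome_length: int | None = None):
    total = sum(r.length for r in regions)
    out = {"n_regions": len(regions), "total_length": total}
    if genome_length:
        out["genome_fraction"] = total / genome_length
    return out


def overlay_tajima(
    regions: list[SelectionRegion], tajima_calls: list[OutlierCall]
) -> list[SelectionRegion]:
    """Flag regions containing >= 1 lower-tail Tajima's D outlier window.

    ``tajima_calls`` must come from the introduced population.  D support is
    an overlay on the already-intersected regions, not a third intersection
    term.
    """
    outlier_windows = [c.window for c in tajima_calls if c.is_outlier]
    for r in regions:
        r.tajima_supported = any(
            w.chrom == r.chrom and r.start < w.end and w.start < r.end
            for w in outlier_windows
        )
    return regions


def genes_in_regions(
    regions: list[SelectionRegion], features: list[FeatureRecord]
) -> list[SelectionRegion]:
    """Attach gene ids overlapping each region by >= 1 bp (half-open)."""
    genes = [f for f in features if f.feature_class == "gene"]
    for r in regions:
        r.gene_ids = [
            g.id
            for g in genes
            if g.chrom == r.chrom and g.start < r.end and r.start < g.end
        ]
    return regions


# ---------------------------------------------------------------------------
# End-to-end scan
# ---------------------------------------------------------------------------


def run_scan(
    windows: list[GenomicWindow],
    fst_values,
    ratio_values,
    tajima_values,
    q: float = 0.05,
    features: list[FeatureRecord] | None = None,
) -> tuple[list[SelectionRegion], dict]:
    """FST and pi-ratio upper-tail intersection, merge, Tajima's D overlay,
    gene extraction.  Returns (regions, summary)."""
    fst_calls = call_outliers(windows, fst_values, "fst", q, "upper")
    ratio_calls = call_outliers(windows, ratio_values, "pi_ratio", q, "upper")
    tajima_calls = call_outliers(windows, tajima_values, "tajima_d", q, "lower")
    regions = merge_regions(intersect_outliers(fst_calls, ratio_calls))
    overlay_tajima(regions, tajima_calls)
    if features is not None:
        genes_in_regions(regions, features)
    summary = region_summary(regions)
    summary["n_tajima_supported"] = sum(r.tajima_supported for r in regions)
    summary["n_genes"] = sum(len(r.gene_ids) for r in regions)
    return regions, summary


def regions_to_bed_rows(regions: list[SelectionRegion]):
    """BED rows (chrom, start, end) + extra columns for write_bed."""
    intervals = [(r.chrom, r.start, r.end) for r in regions]
    extras = [
        (
            "fst,pi_ratio",
            "tajima" if r.tajima_supported else ".",
            len(r.gene_ids),
        )
        for r in regions
    ]
    return intervals, extras
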