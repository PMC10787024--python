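"""Tandem arrays, genome-landscape tracks, and chimeric-contig splitting.

Tandem arrays follow the defense-gene census rule: same-class genes on one
chromosome are chained while the intergenic distance (next start minus
previous end) is below a threshold (default 100 kb); chains of two or more
genes are arrays.  Landscape tracks are per-window gene density (midpoint
counts), repeat coverage fraction (interval union), and GC content, with
pairwise Pearson correlations.  Chimeric contigs are flagged when markers
from two or more linkage groups each exceed a marker-count threshold
("more than four"), and split at the midpoint of the largest inter-marker gap
at each linkage-group block boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palmscan.io_core import (
    ConfigurationError,
    FeatureRecord,
    GenomicWindow,
)

logger = logging.getLogger("palmscan")


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TandemArray:
    chrom: str
    gene_ids: tuple  # ordered by start
    start: int
    end: int
    family_counts: dict

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def detect_tandem_arrays(
    features: list[FeatureRecord],
    family_classes: set[str] | None = None,
    max_gap: int = 100_000,
    per_family: bool = False,
):
    """Chain family genes into tandem arrays.

    ``family_classes`` restricts to the given family labels (default: every
    gene with a family label).  With ``per_family`` the chaining runs within
    each family separately; by default all family genes are pooled (any two
    adjacent family genes < max_gap apart chain) and the family composition
    is reported per array.  Overlapping genes chain (distance treated as 0).

    Returns (arrays, summary) where summary reports the array count, size
    range, and the fraction of family genes located in arrays.
    """
    if max_gap <= 0:
        raise ConfigurationError("max_gap must be positive")
    genes = [
        f
        for f in features
        if f.feature_class == "gene"
        and f.family is not None
        and (family_classes is None or f.family in family_classes)
    ]
    groups: dict[tuple, list[FeatureRecord]] = {}
    for g in genes:
        key = (g.chrom, g.family) if per_family else (g.chrom,)
        groups.setdefault(key, []).append(g)

    arrays: list[TandemArray] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda f: (f.start, f.end, f.id))
        chain: list[FeatureRecord] = []
        for g in members:
            if chain:
                gap = g.start - chain[-1].end
                if gap < 0:
                    logger.info(
                        "overlapping genes %s / %s: distance treated as 0",
                        chain[-1].id,
                        g.id,
                    )
                    gap = 0
                if gap < max_gap:
                    chain.append(g)
                    continue
                _flush_chain(chain, arrays)
                chain = []
            chain.append(g)
        _flush_chain(chain, arrays)

    n_in_arrays = sum(a.size for a in arrays)
    summary = {
        "n_arrays": len(arrays),
        "min_size": min((a.size for a in arrays), default=0),
        "max_size": max((a.size for a in arrays), default=0),
        "n_family_genes": len(genes),
        "fraction_in_arrays": n_in_arrays / len(genes) if genes else np.nan,
    }
    return arrays, summary


def _flush_chain(chain, arrays) -> None:
    if len(chain) < 2:
        return
    fams: dict = {}
    for g in chain:
        fams[g.family] = fams.get(g.family, 0) + 1
    arrays.append(
        TandemArray(
            chain[0].chrom,
            tuple(g.id for g in chain),
            chain[0].start,
            max(g.end for g in chain),
            fams,
        )
    )


# ---------------------------------------------------------------------------
# Landscape tracks
# ---------------------------------------------------------------------------


@dataclass
class LandscapeTable:
    table: pd.DataFrame  # one row per window; track columns
    correlations: pd.DataFrame  # pairwise Pearson r, pairwise-complete


def _union_coverage(intervals: list[tuple[int, int]], start: int, end: int) -> int:
    """Covered bp of the interval union clipped to [start, end)."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in intervals if s < end and e > start
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def landscape_tracks(
    features: list[FeatureRecord],
    repeats: list[tuple[str, int, int]],
    genome: dict[str, str],
    windows: list[GenomicWindow],
    extra_track: dict | None = None,
) -> LandscapeTable:
    """Per-window gene density, repeat fraction, GC fraction (+ optional user
    track, e.g. recombination rate) and their Pearson correlation matrix.

    Gene density counts gene midpoints per window.  The chromosomes of
    ``windows`` must all be present in ``genome``.
    """
    missing = sorted({w.chrom for w in windows} - set(genome))
    if missing:
        raise ConfigurationError(f"chromosomes absent from genome: {missing}")
    gene_mid: dict[str, list[int]] = {}
    for f in features:
        if f.feature_class == "gene":
            gene_mid.setdefault(f.chrom, []).append(f.midpoint)
    for c in gene_mid:
        gene_mid[c] = np.sort(gene_mid[c])
    reps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in repeats:
        reps_by_chrom.setdefault(c, []).append((s, e))

    rows = []
    for w in windows:
        mids = gene_mid.get(w.chrom, np.array([]))
        n_genes = int(
            np.searchsorted(mids, w.end, "left") - np.searchsorted(mids, w.start, "left")
        )
        rep_bp = _union_coverage(reps_by_chrom.get(w.chrom, []), w.start, w.end)
        seq = genome[w.chrom][w.start : w.end]
        gc = (seq.count("G") + seq.count("C")) / len(seq) if seq else np.nan
        row = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "gene_density": n_genes,
            "repeat_fraction": rep_bp / w.length,
            "gc_fraction": gc,
        }
        if extra_track is not None:
            row["extra"] = extra_track.get((w.chrom, w.start), np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    track_cols = [c for c in table.columns if c not in ("chrom", "start", "end")]
    corr = table[track_cols].corr(method="pearson")  # pairwise-complete
    return LandscapeTable(table, corr)


# ---------------------------------------------------------------------------
# Chimeric contigs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigMarkerSet:
    contig: str
    offsets: tuple  # strictly increasing bp
    linkage_groups: tuple
    length: int

    def __post_init__(self):
        if len(self.offsets) != len(self.linkage_groups):
            raise ConfigurationError(f"{self.contig}: offsets/LG length mismatch")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ConfigurationError(f"{self.contig}: offsets not strictly increasing")


@dataclass(frozen=True)
class ChimeraVerdict:
    contig: str
    is_chimeric: bool
    lg_counts: dict
    split_offsets: tuple  # bp, empty when not chimeric


def marker_sets_from_frame(df: pd.DataFrame, contig_lengths: dict[str, int]):
    """Build ContigMarkerSets from a (marker, linkage_group, contig, offset)
    table."""
    sets = []
    for contig, grp in df.groupby("contig", sort=True):
        grp = grp.sort_values("offset")
        sets.append(
            ContigMarkerSet(
                contig,
                tuple(int(x) for x in grp["offset"]),
                tuple(grp["linkage_group"]),
                contig_lengths.get(contig, int(grp["offset"].max()) + 1),
            )
        )
    return sets


def detect_chimeras(
    marker_sets: list[ContigMarkerSet], min_minority: int = 5
) -> list[ChimeraVerdict]:
    """Flag contigs whose markers come from >= 2 linkage groups with at least
    ``min_minority`` markers each ("more than four"), and place one split at
    the midpoint of the largest gap between adjacent markers of different
    qualifying linkage groups at each block boundary.  Stray markers from
    non-qualifying groups are ignored.
    """
    verdicts = []
    for ms in marker_sets:
        counts: dict = {}
        for lg in ms.linkage_groups:
            counts[lg] = counts.get(lg, 0) + 1
        if not counts:
            logger.warning("contig %s has no markers", ms.contig)
            verdicts.append(ChimeraVerdict(ms.contig, False, {}, ()))
            continue
        qualifying = {lg for lg, n in counts.items() if n >= min_minority}
        if len(qualifying) < 2:
            verdicts.append(ChimeraVerdict(ms.contig, False, counts, ()))
            continue
        kept = [
            (off, lg)
            for off, lg in zip(ms.offsets, ms.linkage_groups)
            if lg in qualifying
        ]
        splits = []
        for (off_a, lg_a), (off_b, lg_b) in zip(kept, kept[1:]):
            if lg_a != lg_b:
                splits.append((off_a + off_b) // 2)
        verdicts.append(ChimeraVerdict(ms.contig, True, counts, tuple(splits)))
    return verdicts


def split_contigs(
    verdicts: list[ChimeraVerdict], contig_seqs: dict[str, str]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Split chimeric contigs at the verdict offsets.

    Returns (pieces, lift) where pieces maps piece name -> sequence
    (contig.1, contig.2, ... for split contigs; original name otherwise) and
    lift is an AGP-like table (piece, source, source_start, source_end).
    """
    pieces: dict[str, str] = {}
    lift_rows = []
    by_contig = {v.contig: v for v in verdicts}
    for contig, seq in contig_seqs.items():
        v = by_contig.get(contig)
        if v is None or not v.is_chimeric or not v.split_offsets:
            pieces[contig] = seq
            lift_rows.append((contig, contig, 0, len(seq)))
            continue
        for off in v.split_offsets:
            if not 0 < off < len(seq):
                raise ConfigurationError(
                    f"{contig}: split offset {off} outside sequence (len {len(seq)})"
                )
        bounds = [0, *sorted(v.split_offsets), len(seq)]
        for k, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            name = f"{contig}.{k}"
            pieces[name] = seq[s:e]
            lift_rows.append((name, contig, s, e))
    lift = pd.DataFrame(
        lift_rows, columns=["piece", "source", "source_start", "source_end"]
    )
    return pieces, lift
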