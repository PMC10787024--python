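"""Standard-format I/O, genomic windows, and the core genotype container.

Internal coordinates are 0-based half-open throughout; VCF (1-based) and GFF3
(1-based inclusive) conventions are converted at the I/O boundary.  Genotypes
are stored as alt-allele dosage codes 0/1/2 with -1 for missing; only
biallelic SNPs in diploid samples are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger("palmscan")

MISSING = -1


class PalmscanError(Exception):
    """Base class for palmscan errors."""


class ConfigurationError(PalmscanError):
    """Invalid parameters or inconsistent inputs."""


class ParseError(PalmscanError):
    """Malformed input file."""


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A window [start, end) on one chromosome.

    ``is_full`` distinguishes untruncated windows of the configured size from
    a truncated tail window; per-bp statistics are comparable only across full
    windows.
    """

    chrom: str
    start: int
    end: int
    is_full: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError(
                f"window start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class FeatureRecord:
    """A gene/repeat feature in 0-based half-open coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "gene"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError(
                f"feature {self.id}: start must precede end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ConfigurationError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenotypeMatrix:
    """Diploid genotype codes for N samples at biallelic SNP sites.

    Parameters
    ----------
    samples : list of sample identifiers.
    populations : population label per sample (same order as ``samples``).
    chrom, pos : per-site chromosome and 1-based position (VCF convention).
    ref, alt : per-site alleles.
    gt : (n_sites, n_samples) int8 array of alt-allele dosages 0/1/2,
        ``MISSING`` (-1) for uncalled genotypes.
    """

    def __init__(self, samples, populations, chrom, pos, ref, alt, gt):
        self.samples = list(samples)
        self.populations = np.asarray(populations, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.gt = np.asarray(gt, dtype=np.int8)
        if self.gt.ndim != 2 or self.gt.shape != (len(self.pos), len(self.samples)):
            raise ConfigurationError(
                f"genotype array shape {self.gt.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        if len(self.populations) != len(self.samples):
            raise ConfigurationError("one population label required per sample")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise PalmscanError(f"positions not strictly increasing on {c}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_called(self) -> np.ndarray:
        """Called-allele count per site (2 x non-missing genotypes)."""
        return 2 * np.sum(self.gt != MISSING, axis=1)

    def alt_count(self) -> np.ndarray:
        """Alt-allele count per site over called genotypes."""
        g = np.where(self.gt == MISSING, 0, self.gt)
        return g.sum(axis=1)

    def population_names(self):
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    # -- subsetting ----------------------------------------------------------

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.populations[idx],
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.gt[:, idx],
        )

    def for_population(self, population: str) -> "GenotypeMatrix":
        mask = self.populations == population
        if not mask.any():
            raise ConfigurationError(f"population {population!r} not present")
        return self.subset_samples(mask)

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples,
            self.populations,
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.gt[mask],
        )

    def sites_in(self, window: GenomicWindow) -> np.ndarray:
        """Boolean mask of sites inside a window (pos is 1-based)."""
        zero_based = self.pos - 1
        return (
            (self.chrom == window.chrom)
            & (zero_based >= window.start)
            & (zero_based < window.end)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.populations, other.populations)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path, population_map: dict[str, str]) -> GenotypeMatrix:
    """Read a VCF, keeping biallelic SNPs only.

    ``population_map`` maps every sample in the VCF to its population label;
    a sample missing from the map is a configuration error.  Multiallelic
    records, indels and non-SNP records are dropped (count logged).
    Genotype codes are alt-allele dosages; missing genotypes stay missing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in population_map]
    if missing_samples:
        raise ConfigurationError(
            f"samples absent from population map: {missing_samples}"
        )
    populations = [population_map[s] for s in samples]

    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or v.REF not in _SNP_ALLELES
            or v.ALT[0] not in _SNP_ALLELES
        ):
            n_dropped += 1
            continue
        ploidy = v.ploidy
        if ploidy != 2:
            raise ParseError(
                f"non-diploid record at {v.CHROM}:{v.POS} (ploidy {ploidy})"
            )
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(g)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    gt = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(samples, populations, chrom, pos, ref, alt, gt)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GT-only VCFv4.2. Byte-stable for a fixed matrix."""
    matrix._check_sorted()
    contigs = []
    for c in matrix.chrom:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=palmscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.gt[i])
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_population_map(path) -> dict[str, str]:
    """Read a two-column sample\tpopulation TSV with header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"population map {path} needs >= 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_REPEAT_TYPES = {
    "repeat_region",
    "transposable_element",
    "dispersed_repeat",
    "LTR_retrotransposon",
}


def read_gff3(path, family_attribute: str = "family") -> list[FeatureRecord]:
    """Parse a GFF3 into FeatureRecords (0-based half-open).

    The family label is taken from ``family_attribute`` in column 9 when
    present.  A malformed or inverted-coordinate line raises a ParseError
    naming the line number.
    """
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: malformed GFF3 at line {lineno}: {exc}")
            if f.end < f.start:
                raise ParseError(
                    f"{path}: end < start at line {lineno} ({f.start}..{f.end})"
                )
            if f.featuretype == "gene":
                fclass = "gene"
            elif f.featuretype in _REPEAT_TYPES:
                fclass = "repeat"
            else:
                fclass = "other"
            fam = f.attributes.get(family_attribute)
            fid = f.attributes.get("ID", [f"{f.seqid}:{f.start}-{f.end}"])[0]
            records.append(
                FeatureRecord(
                    id=fid,
                    chrom=f.seqid,
                    start=f.start - 1,  # GFF3 1-based inclusive -> half-open
                    end=f.end,
                    strand=f.strand or ".",
                    feature_class=fclass,
                    family=fam[0] if fam else None,
                )
            )
    return records


def write_gff3(features, path) -> None:
    """Write FeatureRecords as GFF3 (gene features; family in attributes)."""
    type_for = {"gene": "gene", "repeat": "repeat_region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.family:
                attrs += f";family={f.family}"
            fh.write(
                f"{f.chrom}\tpalmscan\t{type_for.get(f.feature_class, f.feature_class)}\t"
                f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+-column BED into (chrom, start, end) tuples (half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: BED line {lineno} has < 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path, extra_columns=None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            row = [chrom, str(start), str(end)]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def make_windows(
    chrom_lengths: dict[str, int],
    size: int,
    step: int | None = None,
    include_truncated: bool = False,
) -> list[GenomicWindow]:
    """Sliding windows over each chromosome.

    Full windows start at 0, step, 2*step, ... with start + size <= L; a final
    truncated window covering the tail is emitted only when
    ``include_truncated`` is set.  ``step`` defaults to ``size`` (disjoint
    windows).  ``step > size`` is rejected: it would leave uncovered gaps.
    """
    if step is None:
        step = size
    if size <= 0:
        raise ConfigurationError("window size must be positive")
    if step <= 0 or step > size:
        raise ConfigurationError(f"need 0 < step <= size, got step={step} size={size}")
    windows: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start + size <= length:
            windows.append(GenomicWindow(chrom, start, start + size, is_full=True))
            start += step
        if include_truncated and start < length:
            windows.append(GenomicWindow(chrom, start, length, is_full=False))
    return windows
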