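"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its config (including the seed): fixed
seed means byte-identical output.  The generators emulate the *statistical
structure* the downstream estimators assume — neutral site-frequency spectra,
Balding–Nichols population divergence, Jukes–Cantor-consistent synonymous
divergence, epoch-structured transposon families, twin-LTR divergence 2muT,
planted tandem arrays and planted chimeric contigs — not the mechanistic
detail of real genomes (no recombination maps, no coalescent trees, no
sequencing error).

Population model
----------------
Sites are placed uniformly; the per-region segregating-site count is
Poisson(theta * a1 * L) with a1 the harmonic number for the total allele
count n.  The derived-allele count i of each site follows the neutral SFS,
P(i) proportional to 1/i.  Without divergence (F = 0) exactly i derived
alleles are assigned uniformly at random among the 2N allele slots, which
makes E[pi] = E[thetaW] = theta and E[Tajima's D] ~ 0 per window.  With
divergence, each population's allele frequency is drawn from the
Balding–Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p = i/n and
genotypes are Binomial(2, p_pop) — the sampling model under which the
Weir–Cockerham estimator's expectation is ~F.

Selective sweeps are modeled in the introduced population only, as local
diversity reduction (site thinning by rho_sweep) plus a rare-variant skew
(frequency redraw from P(i) proportional to i**(-rare_skew); rare_skew = 1 is
the neutral shape).  rho_sweep = 1 with rare_skew = 1 is an exact no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from palmscan.io_core import (
    ConfigurationError,
    FeatureRecord,
    GenotypeMatrix,
    logger,
)

BASES = np.array(["A", "C", "G", "T"])

# codon prefixes whose third position is fully synonymous and whose first two
# positions admit no synonymous or stop-adjacent single-base change (Ala, Val,
# Thr, Pro); with this alphabet NG86 counts exactly one synonymous site per
# codon, making the generator's Jukes–Cantor inversion exact.
_FOURFOLD_PREFIXES = ["GC", "GT", "AC", "CC"]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _neutral_sfs_weights(n_alleles: int, skew: float = 1.0) -> np.ndarray:
    i = np.arange(1, n_alleles, dtype=float)
    w = i ** (-skew)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Two-population genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepRegion:
    """A planted sweep: diversity reduction + rare-variant skew in the
    introduced population over [start, end) of one chromosome."""

    chrom: str
    start: int
    end: int
    rho_sweep: float = 0.2
    rare_skew: float = 2.0

    def __post_init__(self):
        if not 0 < self.rho_sweep <= 1:
            raise ConfigurationError("rho_sweep must be in (0, 1]")
        if self.rare_skew < 1:
            raise ConfigurationError("rare_skew must be >= 1")


@dataclass(frozen=True)
class PopSimConfig:
    """Neutral-SFS two-population genotype simulation.

    theta is the per-bp scaled mutation rate; F the Balding–Nichols
    divergence; ld_block_bp optionally copies genotype vectors within blocks
    of that width to create local linkage (r^2 = 1 within a block).
    """

    theta: float = 0.001
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    n_anc: int = 20
    n_intro: int = 20
    F: float = 0.0
    sweeps: tuple = ()
    ld_block_bp: int | None = None
    pop_names: tuple = ("ancestral", "introduced")
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ConfigurationError("theta must be positive")
        if not 0 <= self.F < 1:
            raise ConfigurationError("F must be in [0, 1)")
        if self.n_anc < 1 or self.n_intro < 1:
            raise ConfigurationError("both populations need >= 1 diploid sample")
        for s in self.sweeps:
            L = self.chrom_lengths.get(s.chrom)
            if L is None or s.start < 0 or s.end > L or s.start >= s.end:
                raise ConfigurationError(
                    f"sweep region {s.chrom}:{s.start}-{s.end} outside chromosome"
                )


def simulate_two_pop_genotypes(config: PopSimConfig) -> GenotypeMatrix:
    """Simulate diploid genotypes for an ancestral and an introduced
    population (see module docstring for the model)."""
    rng = _rng(config.seed)
    n_dip = config.n_anc + config.n_intro
    n_alleles = 2 * n_dip
    a1 = np.sum(1.0 / np.arange(1, n_alleles))
    sfs_w = _neutral_sfs_weights(n_alleles)
    counts = np.arange(1, n_alleles)

    samples = [f"anc{j:03d}" for j in range(config.n_anc)] + [
        f"intro{j:03d}" for j in range(config.n_intro)
    ]
    populations = [config.pop_names[0]] * config.n_anc + [
        config.pop_names[1]
    ] * config.n_intro

    all_chrom, all_pos, all_gt = [], [], []
    for chrom, L in config.chrom_lengths.items():
        n_sites = rng.poisson(config.theta * a1 * L)
        n_sites = min(n_sites, L)
        pos = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1  # 1-based
        i_derived = rng.choice(counts, size=n_sites, p=sfs_w)

        if config.F == 0.0:
            # exactly i derived alleles among the 2N slots
            ranks = np.argsort(rng.random((n_sites, n_alleles)), axis=1).argsort(axis=1)
            alleles = (ranks < i_derived[:, None]).astype(np.int8)
            gt = alleles[:, 0::2] + alleles[:, 1::2]
        else:
            p = i_derived / n_alleles
            shape1 = p * (1 - config.F) / config.F
            shape2 = (1 - p) * (1 - config.F) / config.F
            gt = np.empty((n_sites, n_dip), dtype=np.int8)
            for sl, n_pop in (
                (slice(0, config.n_anc), config.n_anc),
                (slice(config.n_anc, n_dip), config.n_intro),
            ):
                p_pop = rng.beta(shape1, shape2)
                gt[:, sl] = rng.binomial(2, p_pop[:, None], size=(n_sites, n_pop))

        intro_sl = slice(config.n_anc, n_dip)
        n_intro_alleles = 2 * config.n_intro
        for sweep in config.sweeps:
            if sweep.chrom != chrom:
                continue
            in_sweep = (pos - 1 >= sweep.start) & (pos - 1 < sweep.end)
            idx = np.nonzero(in_sweep)[0]
            if sweep.rho_sweep < 1.0:
                killed = idx[rng.random(len(idx)) >= sweep.rho_sweep]
                gt[np.ix_(killed, range(config.n_anc, n_dip))] = 0
                idx = np.setdiff1d(idx, killed)
            if sweep.rare_skew > 1.0 and len(idx):
                w = _neutral_sfs_weights(n_intro_alleles, skew=sweep.rare_skew)
                i2 = rng.choice(np.arange(1, n_intro_alleles), size=len(idx), p=w)
                p2 = i2 / n_intro_alleles
                gt[idx, intro_sl] = rng.binomial(
                    2, p2[:, None], size=(len(idx), config.n_intro)
                )

        if config.ld_block_bp:
            block = (pos - 1) // config.ld_block_bp
            _, first = np.unique(block, return_index=True)
            anchor = first[np.searchsorted(block[first], block)]
            gt = gt[anchor]

        all_chrom.extend([chrom] * n_sites)
        all_pos.append(pos)
        all_gt.append(gt)

    pos = np.concatenate(all_pos) if all_pos else np.array([], dtype=int)
    gt = (
        np.vstack(all_gt)
        if all_gt
        else np.empty((0, n_dip), dtype=np.int8)
    )
    n_sites_total = len(pos)
    return GenotypeMatrix(
        samples,
        populations,
        all_chrom,
        pos,
        ["A"] * n_sites_total,
        ["T"] * n_sites_total,
        gt,
    )


# ---------------------------------------------------------------------------
# Coding-sequence pairs at chosen Ks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingPair:
    pair_id: str
    seq_a: str
    seq_b: str
    true_ks: float


def simulate_coding_pairs(
    n_pairs: int,
    true_ks_mixture: dict[float, float],
    codons_per_gene: int = 500,
    seed: int = 0,
) -> list[CodingPair]:
    """Homolog pairs whose NG86 Ks estimate is consistent for the drawn truth.

    Sequences use fourfold-degenerate codons only; third positions of one
    sequence are substituted with probability p = (3/4)(1 - exp(-(4/3)Ks)),
    the Jukes–Cantor forward map, so inverting it (as NG86 does) recovers Ks.
    """
    for ks, w in true_ks_mixture.items():
        if ks < 0 or not np.isfinite(ks):
            raise ConfigurationError(f"Ks component {ks} invalid (saturation)")
        if w <= 0:
            raise ConfigurationError("mixture weights must be positive")
    rng = _rng(seed)
    comps = np.array(sorted(true_ks_mixture))
    weights = np.array([true_ks_mixture[k] for k in comps])
    weights = weights / weights.sum()

    pairs = []
    for k in range(n_pairs):
        ks = float(rng.choice(comps, p=weights))
        p_sub = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * ks))
        prefixes = rng.choice(_FOURFOLD_PREFIXES, size=codons_per_gene)
        thirds = rng.choice(BASES, size=codons_per_gene)
        seq_a = "".join(pre + b for pre, b in zip(prefixes, thirds))
        hit = rng.random(codons_per_gene) < p_sub
        thirds_b = thirds.copy()
        for j in np.nonzero(hit)[0]:
            choices = [b for b in BASES if b != thirds[j]]
            thirds_b[j] = choices[rng.integers(3)]
        seq_b = "".join(pre + b for pre, b in zip(prefixes, thirds_b))
        pairs.append(CodingPair(f"pair{k:05d}", seq_a, seq_b, ks))
    return pairs


def write_paired_fasta(pairs, path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}_a true_ks={p.true_ks}\n{p.seq_a}\n")
            fh.write(f">{p.pair_id}_b true_ks={p.true_ks}\n{p.seq_b}\n")


# ---------------------------------------------------------------------------
# TE subfamilies with burst epochs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TESimConfig:
    """Transposon subfamilies whose copies come from discrete burst epochs.

    Each epoch is an expected *pairwise* identity between two copies of that
    epoch; per-copy divergence from the subfamily consensus is set by exactly
    inverting the two-branch substitution process (coincident-hit aware), so
    realized pairwise identity is unbiased for the epoch parameter.
    """

    n_subfamilies: int = 30
    copies_per_subfamily: int = 100
    consensus_length: int = 1000
    epoch_identities: tuple = (0.92, 0.82)
    epoch_weights: tuple = (0.5, 0.5)
    epoch_assignment: str = "subfamily"  # "subfamily": one burst per subfamily
    seed: int = 0

    def __post_init__(self):
        if len(self.epoch_identities) != len(self.epoch_weights):
            raise ConfigurationError("one weight per epoch identity required")
        if not np.isclose(sum(self.epoch_weights), 1.0):
            raise ConfigurationError("epoch weights must sum to 1")
        for ident in self.epoch_identities:
            if not 0.25 < ident <= 1.0:
                raise ConfigurationError(
                    f"epoch identity {ident} outside the reachable range (0.25, 1]"
                )
        if self.epoch_assignment not in ("subfamily", "copy"):
            raise ConfigurationError("epoch_assignment must be 'subfamily' or 'copy'")


@dataclass(frozen=True)
class TECopy:
    copy_id: str
    subfamily: str
    epoch: int  # index into epoch_identities (truth label)
    seq: str


def _per_copy_sub_prob(pairwise_identity: float) -> float:
    # solve (1-q)^2 + q^2/3 = I for the per-copy substitution probability q
    disc = 1.0 - (4.0 / 3.0) * (1.0 - pairwise_identity)
    return 0.75 * (1.0 - np.sqrt(disc))


def _mutate(seq_idx: np.ndarray, q: float, rng) -> np.ndarray:
    hit = rng.random(len(seq_idx)) < q
    out = seq_idx.copy()
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def simulate_te_subfamily(config: TESimConfig) -> dict[str, list[TECopy]]:
    """Simulate Copia-style subfamilies; copies carry their true epoch label.

    By default each subfamily is one burst: all its copies share a single
    epoch drawn with the mixture weights, which is what makes the pooled
    pairwise-identity distribution bimodal at the epoch identities (pairs of
    copies from different epochs would sit at an intermediate identity and
    wash the burst peaks out).  ``epoch_assignment="copy"`` draws an epoch
    per copy instead.
    """
    rng = _rng(config.seed)
    qs = [_per_copy_sub_prob(i) for i in config.epoch_identities]
    out: dict[str, list[TECopy]] = {}
    for s in range(config.n_subfamilies):
        name = f"subfam{s:03d}"
        consensus = rng.integers(0, 4, size=config.consensus_length)
        n_ep = len(config.epoch_identities)
        weights = np.asarray(config.epoch_weights)
        if config.epoch_assignment == "subfamily":
            epochs = np.full(
                config.copies_per_subfamily, rng.choice(n_ep, p=weights)
            )
        else:
            epochs = rng.choice(n_ep, size=config.copies_per_subfamily, p=weights)
        copies = []
        for c, ep in enumerate(epochs):
            seq_idx = _mutate(consensus, qs[ep], rng)
            copies.append(
                TECopy(
                    f"{name}_copy{c:03d}",
                    name,
                    int(ep),
                    "".join(BASES[seq_idx]),
                )
            )
        out[name] = copies
    return out


def write_te_fastas(subfamilies: dict[str, list[TECopy]], out_dir) -> list[str]:
    import os

    paths = []
    for name, copies in subfamilies.items():
        path = os.path.join(str(out_dir), f"{name}.fasta")
        with open(path, "w") as fh:
            for c in copies:
                fh.write(f">{c.copy_id} epoch={c.epoch}\n{c.seq}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Intact LTR elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTRSimConfig:
    """Intact LTR retrotransposons: both LTRs identical at insertion, then
    each accumulates substitutions at mu per site per year for T years, so
    expected twin divergence is ~2*mu*T (small-K regime)."""

    n_elements: int = 200
    ltr_length: int = 1000
    insertion_times: tuple = (1_000_000.0,)
    mu: float = 1.3e-8
    seed: int = 0

    def __post_init__(self):
        if self.mu <= 0:
            raise ConfigurationError("mu must be positive")
        for t in self.insertion_times:
            if t < 0:
                raise ConfigurationError("insertion times must be >= 0")


@dataclass(frozen=True)
class LTRElement:
    element_id: str
    ltr5: str
    ltr3: str
    true_time: float


def simulate_ltr_elements(config: LTRSimConfig) -> list[LTRElement]:
    rng = _rng(config.seed)
    times = np.resize(np.asarray(config.insertion_times, dtype=float), config.n_elements)
    elements = []
    for e in range(config.n_elements):
        q = config.mu * times[e]
        ancestral = rng.integers(0, 4, size=config.ltr_length)
        ltr5 = _mutate(ancestral, q, rng)
        ltr3 = _mutate(ancestral, q, rng)
        elements.append(
            LTRElement(
                f"ltr{e:04d}",
                "".join(BASES[ltr5]),
                "".join(BASES[ltr3]),
                float(times[e]),
            )
        )
    return elements


def write_ltr_outputs(elements, fasta_path, truth_path) -> None:
    with open(fasta_path, "w") as fh:
        for e in elements:
            fh.write(f">{e.element_id}_5p\n{e.ltr5}\n>{e.element_id}_3p\n{e.ltr3}\n")
    with open(truth_path, "w") as fh:
        fh.write("element\ttrue_time_years\n")
        for e in elements:
            fh.write(f"{e.element_id}\t{e.true_time:.1f}\n")


# ---------------------------------------------------------------------------
# Gene annotation with planted tandem arrays + landscape profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedArray:
    chrom: str
    family: str
    n_genes: int
    start: int
    gene_length: int = 2000
    gap: int = 20_000  # intra-array intergenic distance, must be < threshold

    @property
    def span(self) -> int:
        return self.n_genes * self.gene_length + (self.n_genes - 1) * self.gap


@dataclass(frozen=True)
class AnnotationSimConfig:
    """Gene/repeat/GC annotation with planted tandem arrays.

    Landscape profiles are given per window of ``profile_window`` bp:
    ``gene_counts`` background genes per window, ``repeat_fraction`` covered
    fraction per window (realized exactly as one interval per window), and
    ``gc_fraction`` per window (realized per-base).  Planted arrays must obey
    the tandem gap threshold and must not collide with each other or with
    planted singleton family genes.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000})
    profile_window: int = 100_000
    gene_counts: dict | None = None  # chrom -> per-window background gene counts
    repeat_fraction: dict | None = None  # chrom -> per-window covered fraction
    gc_fraction: dict | None = None  # chrom -> per-window GC fraction
    planted_arrays: tuple = ()
    family_singletons: tuple = ()  # (chrom, family, start) with gene_length below
    gene_length: int = 2000
    tandem_gap_threshold: int = 100_000
    seed: int = 0

    def __post_init__(self):
        spans = []
        for a in self.planted_arrays:
            if a.gap >= self.tandem_gap_threshold:
                raise ConfigurationError(
                    f"planted array gap {a.gap} >= threshold {self.tandem_gap_threshold}"
                )
            if a.chrom not in self.chrom_lengths or a.start + a.span > self.chrom_lengths[a.chrom]:
                raise ConfigurationError("planted array outside chromosome")
            spans.append((a.chrom, a.start, a.start + a.span))
        for chrom, _fam, start in self.family_singletons:
            spans.append((chrom, start, start + self.gene_length))
        spans.sort()
        for (c1, s1, e1), (c2, s2, _e2) in zip(spans, spans[1:]):
            if c1 == c2 and s2 < e1 + self.tandem_gap_threshold:
                raise ConfigurationError(
                    "planted family features closer than the tandem gap threshold"
                )


@dataclass
class AnnotationSim:
    features: list  # FeatureRecord (genes, with family labels where planted)
    repeats: list  # (chrom, start, end) half-open
    genome: dict  # chrom -> sequence string
    truth_arrays: list  # (chrom, family, [gene ids]) per planted array


def simulate_gene_annotation(config: AnnotationSimConfig) -> AnnotationSim:
    rng = _rng(config.seed)
    features: list[FeatureRecord] = []
    truth = []
    gid = 0

    for a in config.planted_arrays:
        ids = []
        pos = a.start
        for _ in range(a.n_genes):
            fid = f"gene{gid:05d}"
            features.append(
                FeatureRecord(fid, a.chrom, pos, pos + a.gene_length, "+", "gene", a.family)
            )
            ids.append(fid)
            pos += a.gene_length + a.gap
            gid += 1
        truth.append((a.chrom, a.family, ids))
    for chrom, fam, start in config.family_singletons:
        fid = f"gene{gid:05d}"
        features.append(
            FeatureRecord(fid, chrom, start, start + config.gene_length, "+", "gene", fam)
        )
        gid += 1

    repeats = []
    genome = {}
    for chrom, L in config.chrom_lengths.items():
        n_win = L // config.profile_window
        counts = (
            np.asarray(config.gene_counts[chrom])
            if config.gene_counts
            else np.full(n_win, 2)
        )
        for w in range(n_win):
            wstart = w * config.profile_window
            for _ in range(int(counts[w])):
                s = int(rng.integers(wstart, wstart + config.profile_window - config.gene_length))
                features.append(
                    FeatureRecord(f"gene{gid:05d}", chrom, s, s + config.gene_length, "+", "gene")
                )
                gid += 1
        if config.repeat_fraction is not None:
            fracs = np.asarray(config.repeat_fraction[chrom], dtype=float)
            for w in range(n_win):
                cov = int(round(fracs[w] * config.profile_window))
                if cov > 0:
                    s = w * config.profile_window
                    repeats.append((chrom, s, s + cov))
        gc = (
            np.asarray(config.gc_fraction[chrom], dtype=float)
            if config.gc_fraction is not None
            else np.full(n_win, 0.4)
        )
        seq_idx = np.empty(L, dtype=np.int8)
        for w in range(n_win + 1):
            s = w * config.profile_window
            e = min(L, s + config.profile_window)
            if s >= e:
                break
            frac = gc[min(w, n_win - 1)]
            is_gc = rng.random(e - s) < frac
            # G/C and A/T chosen equally within their class
            pick = rng.integers(0, 2, size=e - s)
            seq_idx[s:e] = np.where(is_gc, 1 + pick, np.where(pick == 0, 0, 3))
        genome[chrom] = "".join(BASES[seq_idx])

    features.sort(key=lambda f: (f.chrom, f.start))
    return AnnotationSim(features, repeats, genome, truth)


# ---------------------------------------------------------------------------
# Linkage markers with planted chimeras
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChimeraPlan:
    """Plant a chimera: block_sizes[k] markers of linkage group lg_names[k]
    laid left-to-right, with ``boundary_gap`` bp of marker-free sequence
    centred on each block boundary (made the largest gap on the contig)."""

    contig: str
    block_sizes: tuple = (6, 6)
    lg_names: tuple = ("LG1", "LG2")
    boundary_gap: int = 80_000


@dataclass(frozen=True)
class LinkageSimConfig:
    n_contigs: int = 20
    contig_length: int = 1_000_000
    markers_per_contig: int = 12
    n_linkage_groups: int = 5
    chimera_plans: tuple = ()
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for plan in self.chimera_plans:
            if any(b < 5 for b in plan.block_sizes):
                logger.warning(
                    "chimera plan for %s has a block < 5 markers: "
                    "undetectable by the >4-marker rule",
                    plan.contig,
                )
            if plan.boundary_gap >= self.contig_length // len(plan.block_sizes):
                raise ConfigurationError("boundary gap too large for contig")


def _spread_offsets(
    lo: int, hi: int, k: int, max_gap: int, rng, anchor: str = "lo"
) -> np.ndarray:
    """k strictly increasing offsets in [lo, hi) with all gaps < max_gap.

    When the full range cannot be spanned under the gap bound, the block is
    shrunk and anchored against the `anchor` end of the range, so that a
    planted boundary gap adjacent to that end keeps its intended width.
    """
    if k == 1:
        return np.array([int(rng.integers(lo, hi))])
    spacing = (hi - 1 - lo) / (k - 1)
    cap = max_gap / 1.5  # leaves room for jitter without breaching the bound
    if spacing > cap:
        span = cap * (k - 1)
        if anchor == "hi":
            lo = int(hi - 1 - span)
        else:
            hi = int(lo + span) + 1
    grid = np.linspace(lo, hi - 1, k)
    jitter = (grid[1] - grid[0]) * 0.2
    off = np.sort(grid + rng.uniform(-jitter, jitter, size=k)).astype(int)
    off = np.clip(off, lo, hi - 1)
    # enforce strict increase and the gap bound
    for j in range(1, k):
        if off[j] <= off[j - 1]:
            off[j] = off[j - 1] + 1
    if np.any(np.diff(off) >= max_gap):
        raise ConfigurationError("cannot place markers within gap bound")
    return off


def simulate_linkage_markers(config: LinkageSimConfig):
    """Marker table (marker, linkage_group, contig, offset) + truth.

    Returns (pandas.DataFrame, truth) where truth maps contig -> list of
    planted split boundaries (bp, gap centre), empty list when non-chimeric.
    """
    import pandas as pd

    rng = _rng(config.seed)
    plans = {p.contig: p for p in config.chimera_plans}
    rows = []
    truth: dict[str, list[int]] = {}
    lg_pool = [f"LG{k + 1}" for k in range(config.n_linkage_groups)]
    m = 0
    for c in range(config.n_contigs):
        contig = f"contig{c:03d}"
        plan = plans.get(contig)
        if plan is None:
            lg = lg_pool[c % config.n_linkage_groups]
            # gap bound keeps stray gaps below any planted boundary gap
            offs = _spread_offsets(
                0,
                config.contig_length,
                config.markers_per_contig,
                max(config.contig_length, 2),
                rng,
            )
            for off in offs:
                rows.append((f"m{m:05d}", lg, contig, int(off)))
                m += 1
            truth[contig] = []
        else:
            n_blocks = len(plan.block_sizes)
            seg = config.contig_length // n_blocks
            boundaries = []
            for b, (size, lg) in enumerate(zip(plan.block_sizes, plan.lg_names)):
                lo = b * seg + (plan.boundary_gap // 2 if b > 0 else 0)
                hi = (b + 1) * seg - (plan.boundary_gap // 2 if b < n_blocks - 1 else 0)
                offs = _spread_offsets(
                    lo, hi, size, plan.boundary_gap, rng,
                    anchor="hi" if b == 0 else "lo",
                )
                for off in offs:
                    rows.append((f"m{m:05d}", lg, contig, int(off)))
                    m += 1
                if b < n_blocks - 1:
                    boundaries.append((b + 1) * seg)
            truth[contig] = boundaries
        if config.noise_rate > 0:
            # flip some markers of this contig to a random other linkage group
            start = m - (config.markers_per_contig if plan is None else sum(plan.block_sizes))
            for j in range(start, m):
                if rng.random() < config.noise_rate:
                    name, lg, contig_, off = rows[j]
                    others = [x for x in lg_pool if x != lg]
                    rows[j] = (name, others[rng.integers(len(others))], contig_, off)
    df = pd.DataFrame(rows, columns=["marker", "linkage_group", "contig", "offset"])
    return df, truth
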