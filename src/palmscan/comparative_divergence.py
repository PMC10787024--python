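"""Homolog Ka/Ks, divergence-peak detection, TE burst profiling, LTR dating.

Ka/Ks uses the Nei–Gojobori (1986) counting method: fractional
synonymous/nonsynonymous sites per codon from all single-base changes,
observed differences resolved by averaging over all minimal substitution
pathways (pathways through stop codons excluded), and Jukes–Cantor correction
ps -> Ks = -(3/4) ln(1 - (4/3) ps).  Changes that would create a stop codon
are counted as nonsynonymous for site counting.

Pairwise identity between transposon copies (and between the twin LTRs of an
intact element) comes from Needleman–Wunsch global alignment with free end
gaps; identity is matched columns over aligned columns excluding terminal
overhangs, with internal gaps counting as non-matching columns.  Divergence
distributions are summarized by Gaussian-KDE mode detection.  Intact LTR
elements are dated by T = K / (2 mu).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from palmscan.io_core import ConfigurationError, PalmscanError

logger = logging.getLogger("palmscan")

_STOPS = set(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)
BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stops, None for ambiguous codons."""
    if codon in _STOPS:
        return "*"
    return _AA.get(codon)


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # terminal gaps free (semi-global): TE copies are often fragmentary
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[float, float]:
    """Needleman–Wunsch with free end gaps; returns (score, identity).

    Identity = matched columns / aligned columns between the first and last
    aligned pair (terminal overhangs excluded, internal gaps counted).
    """
    if not seq_a or not seq_b:
        raise ConfigurationError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(seq_a, seq_b)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return float(aln.score), 0.0
    aligned_cols = int(sum(e - s for s, e in t_blocks))
    n_match = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        n_match += sum(a == b for a, b in zip(seq_a[ts:te], seq_b[qs:qe]))
    t_core = int(t_blocks[-1][1] - t_blocks[0][0])
    q_core = int(q_blocks[-1][1] - q_blocks[0][0])
    n_cols = t_core + q_core - aligned_cols
    return float(aln.score), n_match / n_cols


def global_align_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    return global_align(seq_a, seq_b, match, mismatch, gap)[1]


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingAlignment:
    """A gapless pair of aligned coding sequences (codon columns with gaps or
    ambiguity removed at construction)."""

    pair_id: str
    seq_a: str
    seq_b: str

    @classmethod
    def from_aligned(cls, pair_id: str, seq_a: str, seq_b: str) -> "CodingAlignment":
        if len(seq_a) != len(seq_b):
            raise ConfigurationError(f"{pair_id}: aligned sequences differ in length")
        if len(seq_a) % 3:
            raise ConfigurationError(f"{pair_id}: alignment length not divisible by 3")
        a_clean, b_clean = [], []
        for k in range(0, len(seq_a), 3):
            ca, cb = seq_a[k : k + 3].upper(), seq_b[k : k + 3].upper()
            if set(ca) <= set(BASES) and set(cb) <= set(BASES):
                a_clean.append(ca)
                b_clean.append(cb)
        return cls(pair_id, "".join(a_clean), "".join(b_clean))

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for k in range(0, len(self.seq_a), 3):
            yield self.seq_a[k : k + 3], self.seq_b[k : k + 3]


@dataclass(frozen=True)
class KaKsEstimate:
    pair_id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float  # NaN when saturated
    ka: float
    saturated: bool


def codon_syn_sites(codon: str) -> float:
    """Fractional synonymous sites of a codon (NG86).

    Each position contributes (synonymous changes)/3; changes to stop codons
    count as nonsynonymous.
    """
    if codon in _STOPS:
        raise PalmscanError(f"stop codon {codon} has no site decomposition")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _translate(mut) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all minimal
    substitution pathways between two codons, skipping pathways that pass
    through a stop codon."""
    diff_pos = [k for k in range(3) if ca[k] != cb[k]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot, non_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        syn, non = 0.0, 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _translate(nxt) == _translate(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        # all pathways blocked by stops: count steps allowing stop intermediates
        for order in itertools.permutations(diff_pos):
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _translate(nxt) == _translate(cur):
                    syn_tot += 1
                else:
                    non_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, non_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a raw proportion of differences."""
    if p >= 0.75:
        return np.nan
    if p == 0.0:
        return 0.0
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def ng86_ka_ks(alignment: CodingAlignment) -> KaKsEstimate:
    """Nei–Gojobori (1986) Ka/Ks for one homolog pair.

    Raises PalmscanError on an internal stop codon (caller may skip the pair).
    """
    if alignment.n_codons == 0:
        raise ConfigurationError(f"{alignment.pair_id}: empty alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for idx, (ca, cb) in enumerate(alignment.codon_pairs()):
        if ca in _STOPS or cb in _STOPS:
            raise PalmscanError(
                f"{alignment.pair_id}: internal stop codon at codon {idx}"
            )
        s_a += codon_syn_sites(ca)
        s_b += codon_syn_sites(cb)
        dsyn, dnon = _pathway_counts(ca, cb)
        sd += dsyn
        nd += dnon
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * alignment.n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps >= 0.75
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KaKsEstimate(
        alignment.pair_id, s_sites, n_sites, sd, nd, ps, pn, ks, ka, saturated
    )


def batch_ka_ks(alignments) -> list[KaKsEstimate]:
    """NG86 over many pairs; pairs with internal stops are skipped and logged."""
    out = []
    for aln in alignments:
        try:
            out.append(ng86_ka_ks(aln))
        except PalmscanError as exc:
            logger.warning("skipping pair: %s", exc)
    return out


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSet:
    locations: tuple
    heights: tuple
    bandwidth: float


def detect_peaks(
    values,
    bandwidth: float | None = None,
    min_separation: float = 0.0,
    height_fraction: float = 0.1,
    grid_points: int = 1024,
    min_values: int = 50,
) -> PeakSet:
    """Modes of a distribution by Gaussian-KDE local maxima.

    Bandwidth defaults to Silverman's rule.  Modes below ``height_fraction``
    of the global density maximum are discarded as noise; remaining modes are
    greedily thinned (highest first, ties to the left) to ``min_separation``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < min_values:
        raise ConfigurationError(
            f"detect_peaks needs >= {min_values} finite values, got {len(v)}"
        )
    if np.ptp(v) == 0:
        return PeakSet((float(v[0]),), (np.inf,), 0.0)
    if bandwidth is None:
        kde = gaussian_kde(v, bw_method="silverman")
    else:
        kde = gaussian_kde(v, bw_method=bandwidth / v.std(ddof=1))
    bw = kde.factor * v.std(ddof=1)
    lo, hi = v.min() - 3 * bw, v.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    idx, _ = find_peaks(dens)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(dens))])
    keep = idx[dens[idx] >= height_fraction * dens.max()]
    order = sorted(keep, key=lambda k: (-dens[k], grid[k]))
    chosen: list[int] = []
    for k in order:
        if all(abs(grid[k] - grid[j]) >= min_separation for j in chosen):
            chosen.append(k)
    chosen.sort(key=lambda k: grid[k])
    return PeakSet(
        tuple(float(grid[k]) for k in chosen),
        tuple(float(dens[k]) for k in chosen),
        float(bw),
    )


# ---------------------------------------------------------------------------
# TE divergence profile
# ---------------------------------------------------------------------------


def te_divergence_profile(
    subfamily_seqs: dict[str, list[str]],
    pairs_cap: int = 30,
    seed: int = 0,
    min_separation: float = 0.04,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, PeakSet]:
    """Pooled pairwise-identity distribution across TE subfamilies.

    Within each subfamily up to ``pairs_cap`` random copy pairs are globally
    aligned; identities are pooled and modes detected.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    identities = []
    for name in sorted(subfamily_seqs):
        seqs = subfamily_seqs[name]
        if len(seqs) < 2:
            raise ConfigurationError(f"subfamily {name} has < 2 copies")
        n = len(seqs)
        all_pairs = n * (n - 1) // 2
        if all_pairs <= pairs_cap:
            pairs = list(itertools.combinations(range(n), 2))
        else:
            pairs = set()
            while len(pairs) < pairs_cap:
                i, j = rng.integers(n), rng.integers(n)
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
            pairs = sorted(pairs)
        for i, j in pairs:
            identities.append(global_align_identity(seqs[i], seqs[j]))
    identities = np.array(identities)
    peaks = detect_peaks(identities, bandwidth=bandwidth, min_separation=min_separation)
    return identities, peaks


# ---------------------------------------------------------------------------
# LTR insertion-time dating
# ---------------------------------------------------------------------------


def ltr_insertion_time(K, mu: float, jc_correct: bool = False):
    """Insertion time T = K / (2 mu) from twin-LTR divergence K.

    ``jc_correct`` applies the Jukes–Cantor multiple-hit correction to K
    first (off by default; K is small for intact elements).
    """
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ConfigurationError("divergence K must be >= 0")
    if mu <= 0:
        raise ConfigurationError("mu must be positive")
    if jc_correct:
        K = np.array([jukes_cantor(k) for k in np.atleast_1d(K)])
    T = K / (2.0 * mu)
    return float(T) if T.ndim == 0 else T


def date_ltr_elements(elements, mu: float, jc_correct: bool = False):
    """Twin-LTR divergence and ages for simulated/parsed LTR elements.

    Returns a list of dicts (element_id, K, T_years).
    """
    logger.info("dating %d LTR elements with mu=%.3g subs/site/year", len(elements), mu)
    out = []
    for e in elements:
        k = 1.0 - global_align_identity(e.ltr5, e.ltr3)
        out.append(
            {
                "element_id": e.element_id,
                "K": k,
                "T_years": ltr_insertion_time(k, mu, jc_correct),
            }
        )
    return out
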