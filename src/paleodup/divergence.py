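"""Codon-aware divergence estimation: Ks (Nei–Gojobori), 4dTv, peaks, dating.

Per homolog pair the proteins are globally aligned, the alignment is
back-translated onto the coding sequences, and two divergence statistics
are computed on the gap-free codon columns:

* **Ks** — synonymous substitutions per synonymous site, by the
  Nei–Gojobori (1986) counting method with the Jukes–Cantor multiple-hit
  correction ``Ks = -(3/4)·ln(1 - (4/3)·pS)``.  Codon pairs differing at
  more than one position are resolved by averaging over all minimal
  mutational pathways, excluding pathways that pass through stop codons.
* **4dTv** — the fraction of transversion differences at fourfold-degenerate
  third codon positions.  A site counts only when both codons belong to a
  fourfold-degenerate family and their first two bases are identical; an
  optional transversion-only multiple-hit correction
  ``-(1/2)·ln(1 - 2·4dTv)`` is available (raw is the default).

Mixture peaks in a Ks or 4dTv distribution mark episodes of simultaneous
gene duplication (whole-genome duplications); peak positions are dated with
the molecular-clock formula ``T = Ks / (2·r)`` where ``r`` is the synonymous
substitution rate per site per year (1.5e-8 for dicots).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .genome_io import Genome
from .homology import HomologPair

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "PeakEstimate",
    "DatedPeak",
    "DEFAULT_SYN_RATE",
    "backtranslate",
    "align_and_backtranslate",
    "ng86",
    "fourdtv",
    "estimate_pair",
    "divergence_table",
    "histogram_table",
    "detect_peaks",
    "date_peak",
]

DEFAULT_SYN_RATE = 1.5e-8  # synonymous substitutions / site / year (dicots)

BASES = "ACGT"
PURINES = frozenset("AG")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))

_CODON_TABLE: dict[str, str] = {}
for _c in ("".join(t) for t in itertools.product(BASES, repeat=3)):
    from Bio.Seq import Seq as _Seq

    _CODON_TABLE[_c] = str(_Seq(_c).translate())

SENSE_CODONS = tuple(c for c in _CODON_TABLE if c not in STOP_CODONS)

#: two-base prefixes whose four codons all encode the same amino acid
FOURFOLD_PREFIXES = frozenset(
    p
    for p in ("".join(t) for t in itertools.product(BASES, repeat=2))
    if len({_CODON_TABLE[p + b] for b in BASES}) == 1
)


@dataclass
class CodonAlignment:
    """Gap-free, unambiguous codon columns of an aligned homolog pair."""

    pair: HomologPair
    columns: list[tuple[str, str]]
    n_dropped: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.columns)


@dataclass
class DivergenceEstimate:
    """Ks and 4dTv statistics for one homolog pair."""

    pair: HomologPair
    n_codons: int = 0
    S: float = 0.0  # synonymous sites (fractional)
    N: float = 0.0  # nonsynonymous sites
    sd: float = 0.0  # synonymous differences
    nd: float = 0.0  # nonsynonymous differences
    pS: float = float("nan")
    ks: float = float("nan")
    ka: float = float("nan")
    saturated: bool = False
    n_4d: int = 0
    tv_4d: int = 0
    fourdtv: float = float("nan")
    fourdtv_corrected: float = float("nan")

    @property
    def fourdtv_defined(self) -> bool:
        return self.n_4d > 0


@dataclass
class PeakEstimate:
    """One mixture component of a divergence distribution."""

    statistic: str  # {"ks", "fourdtv"}
    mean: float
    weight: float
    sigma: float
    label: str | None = None  # {"alpha", "beta", "gamma"} once assigned


@dataclass
class DatedPeak:
    peak: PeakEstimate
    rate: float
    time_mya: float


# ---------------------------------------------------------------------------
# Nei–Gojobori site and difference counting


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of a sense codon.

    At each position, the fraction of the three single-base changes that
    preserve the amino acid; changes into stop codons count as
    nonsynonymous (they stay in the denominator of 3).
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        n_syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOP_CODONS and _CODON_TABLE[mut] == aa:
                n_syn += 1
        s += n_syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    For multi-position differences, all orderings of the single-base steps
    are enumerated; pathways visiting a stop codon are excluded (unless all
    are, in which case every pathway is used); counts are averaged over the
    admitted pathways.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    paths_with_stops: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt not in (c1, c2):
                through_stop = True
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                # amino acid of a stop treated as unlike any residue
                nd += 1
            elif _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (paths_with_stops if through_stop else paths).append((sd, nd))
    use = paths if paths else paths_with_stops
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def ng86(alignment: CodonAlignment) -> DivergenceEstimate:
    """Nei–Gojobori Ks/Ka estimate with Jukes–Cantor correction.

    ``S`` is the pathway-independent synonymous site count averaged between
    the two sequences; ``pS = sd/S`` is corrected as
    ``ks = -(3/4)·ln(1 - (4/3)·pS)``; the pair is flagged saturated when the
    log argument is non-positive (``pS >= 3/4``).
    """
    if alignment.n_codons == 0:
        raise ValueError("empty alignment")
    est = DivergenceEstimate(pair=alignment.pair, n_codons=alignment.n_codons)
    s1 = s2 = 0.0
    for c1, c2 in alignment.columns:
        s1 += _syn_sites(c1)
        s2 += _syn_sites(c2)
        sd, nd = _pair_differences(c1, c2)
        est.sd += sd
        est.nd += nd
    est.S = (s1 + s2) / 2.0
    est.N = 3.0 * alignment.n_codons - est.S
    est.pS = est.sd / est.S if est.S > 0 else float("nan")
    est.ks = _jukes_cantor(est.pS)
    est.saturated = not math.isfinite(est.ks)
    pn = est.nd / est.N if est.N > 0 else float("nan")
    est.ka = _jukes_cantor(pn)
    return est


def _jukes_cantor(p: float) -> float:
    if not math.isfinite(p):
        return float("nan")
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float("inf")  # saturated
    return -0.75 * math.log(arg)


# ---------------------------------------------------------------------------
# 4dTv


def fourdtv(alignment: CodonAlignment, est: DivergenceEstimate | None = None) -> DivergenceEstimate:
    """Transversion rate at fourfold-degenerate third positions.

    A third-position site is counted iff both codons belong to a
    fourfold-degenerate family and share their first two bases; among those
    sites, transversions (purine <-> pyrimidine differences) are counted.
    Undefined (NaN, ``n_4d = 0``) when no such site exists.
    """
    if alignment.n_codons == 0:
        raise ValueError("empty alignment")
    est = est or DivergenceEstimate(pair=alignment.pair, n_codons=alignment.n_codons)
    n_4d = tv = 0
    for c1, c2 in alignment.columns:
        if c1[:2] != c2[:2] or c1[:2] not in FOURFOLD_PREFIXES:
            continue
        n_4d += 1
        if c1[2] != c2[2] and (c1[2] in PURINES) != (c2[2] in PURINES):
            tv += 1
    est.n_4d = n_4d
    est.tv_4d = tv
    if n_4d > 0:
        est.fourdtv = tv / n_4d
        arg = 1.0 - 2.0 * est.fourdtv
        est.fourdtv_corrected = -0.5 * math.log(arg) if arg > 0 else float("inf")
    return est


# ---------------------------------------------------------------------------
# Alignment and back-translation


def backtranslate(
    aligned1: str,
    aligned2: str,
    cds1: str,
    cds2: str,
    pair: HomologPair,
) -> CodonAlignment:
    """Map an aligned protein pair back onto codons.

    ``aligned1``/``aligned2`` are gapped protein strings of equal length;
    each CDS must be exactly 3x its ungapped protein length.  Columns with a
    gap on either side, any non-ACGT base, or a stop codon are dropped and
    counted in ``n_dropped``.
    """
    if len(aligned1) != len(aligned2):
        raise ValueError("aligned strings differ in length")
    for gid, aligned, cds in ((pair.a, aligned1, cds1), (pair.b, aligned2, cds2)):
        n_res = len(aligned) - aligned.count("-")
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"gene {gid}: CDS length {len(cds)} != 3 x {n_res} aligned residues"
            )
    columns: list[tuple[str, str]] = []
    n_dropped = 0
    i1 = i2 = 0
    for a1, a2 in zip(aligned1, aligned2):
        codon1 = cds1[3 * i1 : 3 * i1 + 3] if a1 != "-" else None
        codon2 = cds2[3 * i2 : 3 * i2 + 3] if a2 != "-" else None
        i1 += a1 != "-"
        i2 += a2 != "-"
        if codon1 is None or codon2 is None:
            n_dropped += 1
            continue
        if any(b not in BASES for b in codon1 + codon2) or codon1 in STOP_CODONS or codon2 in STOP_CODONS:
            n_dropped += 1
            continue
        columns.append((codon1, codon2))
    return CodonAlignment(pair=pair, columns=columns, n_dropped=n_dropped)


_GLOBAL_ALIGNER: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _GLOBAL_ALIGNER = aligner
    return _GLOBAL_ALIGNER


def align_and_backtranslate(
    pair: HomologPair, protein1: str, protein2: str, cds1: str, cds2: str
) -> CodonAlignment:
    """Globally align two proteins (BLOSUM62, affine gaps) and back-translate."""
    aligner = _global_aligner()
    alphabet = str(aligner.substitution_matrix.alphabet)
    p1 = "".join(c if c in alphabet else "X" for c in protein1)
    p2 = "".join(c if c in alphabet else "X" for c in protein2)
    aln = aligner.align(p1, p2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    return backtranslate(a1, a2, cds1, cds2, pair)


def estimate_pair(
    pair: HomologPair, protein1: str, protein2: str, cds1: str, cds2: str
) -> DivergenceEstimate:
    """Full divergence estimate (Ks and 4dTv) for one homolog pair."""
    aln = align_and_backtranslate(pair, protein1, protein2, cds1, cds2)
    if aln.n_codons == 0:
        raise ValueError(f"empty alignment for pair ({pair.a}, {pair.b})")
    est = ng86(aln)
    return fourdtv(aln, est)


# ---------------------------------------------------------------------------
# Batch driver


def divergence_table(pairs: list[HomologPair], genomes: list[Genome]) -> pd.DataFrame:
    """Per-pair divergence estimates as a tidy table (one row per pair)."""
    index: dict[str, tuple[str, str]] = {}
    for gm in genomes:
        for g in gm.genes():
            index[g.gene_id] = (g.protein, g.cds)
    rows = []
    for p in pairs:
        if p.a not in index or p.b not in index:
            missing = p.a if p.a not in index else p.b
            raise KeyError(f"pair references unknown gene {missing}")
        prot1, cds1 = index[p.a]
        prot2, cds2 = index[p.b]
        est = estimate_pair(p, prot1, prot2, cds1, cds2)
        rows.append(
            {
                "a": p.a,
                "b": p.b,
                "kind": p.kind,
                "n_codons": est.n_codons,
                "S": est.S,
                "sd": est.sd,
                "pS": est.pS,
                "ks": est.ks,
                "ka": est.ka,
                "saturated": est.saturated,
                "n_4d": est.n_4d,
                "tv_4d": est.tv_4d,
                "fourdtv": est.fourdtv,
                "fourdtv_corrected": est.fourdtv_corrected,
            }
        )
    columns = [
        "a", "b", "kind", "n_codons", "S", "sd", "pS", "ks", "ka",
        "saturated", "n_4d", "tv_4d", "fourdtv", "fourdtv_corrected",
    ]
    return pd.DataFrame(rows, columns=columns)


def histogram_table(values, bin_width: float = 0.01) -> pd.DataFrame:
    """Plot-ready histogram of a divergence statistic."""
    values = np.asarray([v for v in np.asarray(values, dtype=float) if np.isfinite(v)])
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    n_bins = max(1, int(math.ceil((values.max() + 1e-12) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, n_bins * bin_width))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# Peak detection and dating

PEAK_LABELS = ("alpha", "beta", "gamma")


def detect_peaks(
    values,
    statistic: str = "ks",
    max_components: int = 4,
    seed: int = 1729,
    cap: float = 5.0,
    method: str = "gmm",
    min_values: int = 30,
) -> list[PeakEstimate]:
    """Find mixture peaks in a Ks or 4dTv distribution.

    Ks values are log-transformed before fitting (mixture components of a
    Ks distribution are approximately log-normal); 4dTv is fitted on the raw
    scale.  A Gaussian mixture is fitted for k = 1..max_components and the
    component count chosen by BIC; peaks are returned with ascending means
    (back-transformed to the Ks scale, mean = exp(mu)) and the top-3-weight
    components labeled alpha/beta/gamma in ascending mean order.

    Saturated/undefined entries and values above ``cap`` are removed first;
    fewer than ``min_values`` remaining raises (use ``method="kde"`` — a
    Gaussian kernel density with Silverman bandwidth and local-maxima
    calling — for sparse data).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals) & (vals <= cap)]
    log_scale = statistic == "ks"
    if log_scale:
        vals = vals[vals > 1e-6]
    else:
        vals = vals[vals >= 0]
    if vals.size < min_values and method != "kde":
        raise ValueError(
            f"only {vals.size} usable values (< {min_values}); "
            "use method='kde' for sparse data"
        )
    if vals.size == 0:
        raise ValueError("no usable values")
    if np.ptp(vals) == 0:
        return [PeakEstimate(statistic=statistic, mean=float(vals[0]), weight=1.0, sigma=0.0)]

    x = np.log(vals) if log_scale else vals

    if method == "kde":
        peaks = _kde_peaks(x, statistic, log_scale)
    else:
        peaks = _gmm_peaks(x, statistic, log_scale, max_components, seed)

    peaks.sort(key=lambda p: p.mean)
    top3 = sorted(sorted(peaks, key=lambda p: -p.weight)[:3], key=lambda p: p.mean)
    for label, p in zip(PEAK_LABELS, top3):
        p.label = label
    return peaks


def _gmm_peaks(
    x: np.ndarray, statistic: str, log_scale: bool, max_components: int, seed: int
) -> list[PeakEstimate]:
    X = x.reshape(-1, 1)
    best = None
    best_bic = np.inf
    k_max = min(max_components, len(np.unique(x)))
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(n_components=k, n_init=3, random_state=seed)
        gmm.fit(X)
        bic = gmm.bic(X)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gmm
    assert best is not None
    peaks = []
    for mu, var, w in zip(best.means_[:, 0], best.covariances_[:, 0, 0], best.weights_):
        mean = float(np.exp(mu)) if log_scale else float(mu)
        peaks.append(
            PeakEstimate(statistic=statistic, mean=mean, weight=float(w), sigma=float(np.sqrt(var)))
        )
    return peaks


def _kde_peaks(x: np.ndarray, statistic: str, log_scale: bool) -> list[PeakEstimate]:
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    maxima = argrelmax(dens)[0]
    if maxima.size == 0:
        maxima = np.array([int(np.argmax(dens))])
    # basin boundaries at the minima between adjacent maxima
    bounds = [grid[0]]
    for i, j in zip(maxima[:-1], maxima[1:]):
        seg = dens[i:j]
        bounds.append(grid[i + int(np.argmin(seg))])
    bounds.append(grid[-1])
    peaks = []
    for m, lo, hi in zip(maxima, bounds[:-1], bounds[1:]):
        members = x[(x >= lo) & (x <= hi)]
        w = members.size / x.size
        sigma = float(np.std(members)) if members.size else 0.0
        mean = float(np.exp(grid[m])) if log_scale else float(grid[m])
        peaks.append(PeakEstimate(statistic=statistic, mean=mean, weight=w, sigma=sigma))
    return peaks


def date_peak(peak: PeakEstimate, rate: float = DEFAULT_SYN_RATE) -> DatedPeak:
    """Date a Ks peak with the molecular clock: T = Ks / (2·rate), in MY.

    ``rate`` is the synonymous substitution rate per site per year.
    """
    if peak.statistic != "ks":
        raise ValueError("only Ks peaks can be dated with a synonymous clock")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return DatedPeak(peak=peak, rate=rate, time_mya=peak.mean / (2.0 * rate) / 1e6)
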