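"""Maximal-segment clusters of column scores and their significance.

Column scores x_i (one per alignment column, nonnegative) are turned into
increments y_i = x_i - g with a gap penalty g = rho * mean(x).  The
Ruzzo-Tompa algorithm extracts all maximal scoring segments of y; each
segment is a candidate cluster of motifs with a shared positional
preference relative to the TSS.  With rho > 1 the increments have negative
mean, placing the local score in the Karlin-Altschul logarithmic regime,
where the best segment score is asymptotically Gumbel and

    p = 1 - exp(-K n exp(-lambda * S))

bounds the tail probability of a segment score S.  lambda is the unique
positive root of the empirical moment equation mean(exp(lambda*y)) = 1;
K defaults to the Poissonian upper bound 1, which makes the p-value
deliberately conservative.  A seeded permutation p-value (redistributing
the observed hit scores uniformly over columns) is the calibrated
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .block import CoordinateMap
from .motifs import ColumnScores

DEFAULT_RHO = 1.4
DEFAULT_K = 1.0


@dataclass
class ClusterConfig:
    """Knobs of the cluster statistic.

    rho : normalized gap penalty, must exceed 1 (logarithmic regime).
    K : Karlin-Altschul prefactor; 1 is the conservative Poisson bound.
    """

    rho: float = DEFAULT_RHO
    K: float = DEFAULT_K
    n_permutations: int = 199
    seed: int = 0
    alpha: float = 0.05
    column_sum_policy: str = "positive_sum"
    background_mode: str = "context2"

    def __post_init__(self) -> None:
        if self.rho <= 1:
            raise ValueError("rho must be > 1 (logarithmic regime)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Segment:
    """Half-open run of columns [start, stop) with its segment score."""

    start: int
    stop: int
    score: float


@dataclass(frozen=True)
class KarlinParams:
    lam: float
    n: int
    g: float


@dataclass
class Cluster:
    """One maximal segment for one TF/strand, with descriptors."""

    tf_name: str
    strand: str
    start: int
    stop: int
    score: float
    p_value: float
    from_bp: int
    to_bp: int
    spread: int
    n_hits: int
    pct_multiple_motifs: float
    hit_seq: np.ndarray = field(repr=False)
    hit_col: np.ndarray = field(repr=False)
    hit_score: np.ndarray = field(repr=False)
    gene_group: frozenset[str] | None = None

    @property
    def key(self) -> str:
        return f"{self.tf_name}:{self.from_bp:+d}:{self.to_bp:+d}:{self.strand}"

    @staticmethod
    def parse_key(key: str) -> tuple[str, int, int, str]:
        tf, frm, to, strand = key.rsplit(":", 3)
        return tf, int(frm), int(to), strand


def gap_penalty(x: np.ndarray, rho: float = DEFAULT_RHO) -> float:
    """g = rho * mean column score (the TF-specific normalization)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.any(x > 0):
        raise ValueError("all-zero column scores: no signal to normalize")
    return float(rho * x.mean())


def ruzzo_tompa(x: np.ndarray, g: float) -> list[Segment]:
    """All maximal scoring segments of the increments x_i - g.

    Implements the Ruzzo-Tompa linear-time algorithm on y = x - g.
    Segments are disjoint, have strictly positive scores, and zero-scoring
    extensions are excluded (strict cumulative min/max at the endpoints).
    """
    y = np.asarray(x, dtype=float) - g
    segs: list[list[float]] = []  # [L, R, start, stop] in cumulative terms
    c = 0.0
    for k in range(len(y)):
        v = y[k]
        if v <= 0:
            c += v
            continue
        L, R, i, j = c, c + v, k, k + 1
        c = R
        while True:
            idx = None
            for t in range(len(segs) - 1, -1, -1):
                if segs[t][0] < L:
                    idx = t
                    break
            if idx is None or segs[idx][1] >= R:
                segs.append([L, R, i, j])
                break
            L, i = segs[idx][0], segs[idx][2]
            del segs[idx:]
    return [Segment(int(i), int(j), float(R - L)) for L, R, i, j in segs]


def karlin_lambda(x: np.ndarray, g: float) -> KarlinParams:
    """Positive root of the empirical moment equation mean(exp(lam*y)) = 1.

    Requires mean(y) < 0 (guaranteed by rho > 1) and max(y) > 0, otherwise
    no positive root exists.
    """
    y = np.asarray(x, dtype=float) - g
    n = len(y)
    if y.mean() >= 0:
        raise ValueError(
            "mean(x - g) >= 0: outside the logarithmic regime (need rho > 1)"
        )
    if y.max() <= 0:
        raise ValueError("max(x - g) <= 0: no positive excursions to calibrate")

    logn = np.log(n)

    def h(lam: float) -> float:
        return logsumexp(lam * y) - logn

    hi = 1.0
    while h(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - pathological scaling
            raise RuntimeError("failed to bracket lambda")
    lo = hi / 2.0 if hi > 1.0 else 1e-12
    while lo > 1e-12 and h(lo) > 0:
        lo /= 2.0
    lam = brentq(h, lo, hi, xtol=1e-15, rtol=1e-12)
    return KarlinParams(float(lam), n, float(g))


def cluster_pvalue(score: float, params: KarlinParams, K: float = DEFAULT_K) -> float:
    """Karlin-Altschul tail bound for a maximal segment score."""
    if score <= 0:
        raise ValueError("segment score must be positive")
    p = -np.expm1(-K * params.n * np.exp(-params.lam * score))
    return float(min(max(p, 5e-324), 1.0))


def permutation_pvalue(
    column_scores: ColumnScores,
    g: float,
    observed_max_score: float,
    n_perm: int = 199,
    seed: int = 0,
) -> float:
    """Permutation p-value of the best segment score.

    The null preserves the number and magnitude of the observed motif
    scores but redistributes each hit's column i.i.d. uniformly over the
    alignment; each replicate rebuilds the column scores and reruns
    Ruzzo-Tompa.  Add-one rule: p = (1 + #{replicate >= observed}) /
    (n_perm + 1).
    """
    scores = column_scores.hit_score
    L = len(column_scores.x)
    if len(scores) == 0:
        return 1.0
    if observed_max_score <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    tol = 1e-12
    for _ in range(n_perm):
        cols = rng.integers(0, L, size=len(scores))
        x = np.bincount(cols, weights=scores, minlength=L)
        segs = ruzzo_tompa(x, g)
        best = max((s.score for s in segs), default=0.0)
        if best >= observed_max_score - tol:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def describe_cluster(
    segment: Segment,
    hits: ColumnScores,
    coord_map: CoordinateMap,
    tf_name: str | None = None,
    p_value: float = float("nan"),
) -> Cluster:
    """Attach bp coordinates and motif descriptors to a maximal segment.

    ``From``/``To`` are the bp coordinates of the segment's first and last
    columns; spread is the number of columns (equal to To - From + 1 for
    segments not straddling the TSS, where no position 0 exists).  A
    sequence contributing m motifs to the cluster contributes m - 1
    "multiple motifs"; pct_multiple_motifs is their fraction of all
    cluster motifs.
    """
    if segment.stop <= segment.start:
        raise ValueError("empty segment")
    inside = hits.hits_in(segment.start, segment.stop)
    n_hits = inside.n_hits
    if n_hits:
        counts = np.bincount(inside.hit_seq)
        counts = counts[counts > 0]
        pct_multiple = float((counts - 1).sum() / counts.sum())
    else:
        pct_multiple = 0.0
    return Cluster(
        tf_name=tf_name or hits.tf_name,
        strand=hits.strand,
        start=segment.start,
        stop=segment.stop,
        score=segment.score,
        p_value=p_value,
        from_bp=coord_map.col_to_coord(segment.start),
        to_bp=coord_map.col_to_coord(segment.stop - 1),
        spread=segment.stop - segment.start,
        n_hits=n_hits,
        pct_multiple_motifs=pct_multiple,
        hit_seq=inside.hit_seq,
        hit_col=inside.hit_col,
        hit_score=inside.hit_score,
    )


def segment_pvalue(
    x: np.ndarray,
    g: float,
    segment: Segment,
    K: float = DEFAULT_K,
    fallback: KarlinParams | None = None,
) -> float:
    """Karlin-Altschul p-value for one segment with a leave-one-out null fit.

    The moment equation estimates the *null* score distribution, so the
    columns of the segment under test are excluded from the fit: a strong
    signal segment would otherwise dominate its own null calibration and
    cap lambda * score near ln(n), making any dominant cluster look
    insignificant.  The p-value itself still uses the full column count n.
    When the tested segment was the only positive excursion no null
    calibration remains; the full-data fit (or p = 1) is the conservative
    fallback.
    """
    loo = np.delete(np.asarray(x, dtype=float), np.s_[segment.start:segment.stop])
    try:
        params = karlin_lambda(loo, g)
    except ValueError:
        if fallback is None:
            return 1.0
        params = fallback
    params = KarlinParams(params.lam, len(x), g)
    return cluster_pvalue(segment.score, params, K)


def detect_clusters(
    scores: ColumnScores,
    coord_map: CoordinateMap,
    config: ClusterConfig | None = None,
) -> tuple[list[Cluster], KarlinParams | None]:
    """Full cluster path for one TF/strand: gap penalty, Ruzzo-Tompa,
    leave-one-out Karlin-Altschul p-values, descriptors.

    Returns all maximal segments as clusters (unfiltered; thresholding is
    the caller's concern) plus the full-data Karlin parameters, or
    ``([], None)`` when the column scores carry no positive excursion.
    """
    config = config or ClusterConfig()
    x = scores.x
    if not np.any(x > 0):
        return [], None
    g = gap_penalty(x, config.rho)
    if (x - g).max() <= 0:
        return [], None
    params = karlin_lambda(x, g)
    segments = ruzzo_tompa(x, g)
    clusters = [
        describe_cluster(
            seg, scores, coord_map,
            p_value=segment_pvalue(x, g, seg, config.K, fallback=params),
        )
        for seg in segments
    ]
    clusters.sort(key=lambda c: (c.p_value, c.start))
    return clusters, params
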