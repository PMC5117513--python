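"""JASPAR count matrices, PSSMs, and promoter-block scanning.

Scanning convention: every admissible window of every sequence is scored
with the natural-log odds of the motif model against the local background
(see :mod:`tssclust.background`).  A "motif" is any window with a strictly
positive score.  Position and score are assigned to the motif's 3' base:
on the plus strand that is the right end of the window, on the minus
strand the left end (reported in plus-strand column numbering), so that
clusters on either strand live in the same coordinate system.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import motifs as bio_motifs

from .background import BackgroundModel, site_log_prob
from .block import ALPHABET, PromoterBlock, _CODE

MAX_JASPAR_WIDTH = 21

COLUMN_SUM_POLICIES = ("positive_sum", "clamped_total")


@dataclass
class CountMatrix:
    """Nucleotide count matrix for one transcription factor.

    ``counts`` has shape (4, w) with rows in A, C, G, T order.
    """

    tf_name: str
    matrix_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, w)")
        if self.counts.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column needs at least one positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class Pssm:
    """Position-specific probabilities derived from counts (pseudo-count 0.5)."""

    tf_name: str
    probabilities: np.ndarray  # (4, w), columns sum to 1
    pseudocount: float = 0.5

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_probabilities(self) -> np.ndarray:
        return np.log(self.probabilities)

    def reverse_complement(self) -> "Pssm":
        return Pssm(self.tf_name, self.probabilities[::-1, ::-1].copy(),
                    self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """One positive-scoring window, positioned at its 3' base."""

    sequence_index: int
    strand: str
    col3p: int
    width: int
    score: float


@dataclass
class ColumnScores:
    """Per-column aggregate motif scores for one TF on one strand.

    Hits are stored as parallel arrays (sequence index, 3'-base column,
    score) for speed; ``hits`` materializes them as :class:`MotifHit`
    records on demand.
    """

    tf_name: str
    strand: str
    width: int
    x: np.ndarray
    hit_seq: np.ndarray
    hit_col: np.ndarray
    hit_score: np.ndarray
    policy: str = "positive_sum"

    @property
    def n_hits(self) -> int:
        return len(self.hit_score)

    @property
    def hits(self) -> list[MotifHit]:
        return [
            MotifHit(int(s), self.strand, int(c), self.width, float(v))
            for s, c, v in zip(self.hit_seq, self.hit_col, self.hit_score)
        ]

    def hits_in(self, start: int, stop: int) -> "ColumnScores":
        """Restriction of the hit arrays to columns in [start, stop)."""
        m = (self.hit_col >= start) & (self.hit_col < stop)
        return ColumnScores(self.tf_name, self.strand, self.width, self.x,
                            self.hit_seq[m], self.hit_col[m],
                            self.hit_score[m], self.policy)


# ---------------------------------------------------------------------------
# parsing and matrix arithmetic


def read_jaspar(pfm_source: str | Path) -> list[CountMatrix]:
    """Parse JASPAR pfm records (bracketed or bare-row dialect).

    Accepts a path or raw text; returns one :class:`CountMatrix` per
    record with rows normalized to A, C, G, T order.
    """
    p = Path(str(pfm_source))
    text = p.read_text() if p.exists() else str(pfm_source)
    records = bio_motifs.parse(io.StringIO(text), "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
        out.append(CountMatrix(m.name or m.matrix_id, m.matrix_id or "", counts))
    if not out:
        raise ValueError("no pfm records found")
    return out


def counts_to_pssm(cm: CountMatrix, pseudocount: float = 0.5) -> Pssm:
    """Dirichlet-smoothed probabilities: (count + pc) / (colsum + 4 pc)."""
    denom = cm.counts.sum(axis=0) + 4 * pseudocount
    return Pssm(cm.tf_name, (cm.counts + pseudocount) / denom, pseudocount)


def matrix_descriptors(cm: CountMatrix, pseudocount: float = 0.5) -> dict[str, float]:
    """GC content, information content (bits), and reverse-palindromicity.

    Palindromicity is the Pearson correlation between the flattened PSSM
    and its reverse complement; 1 for a perfectly reverse-palindromic
    matrix.
    """
    p = counts_to_pssm(cm, pseudocount).probabilities
    gc = float(p[[1, 2], :].sum() / cm.width)
    ic = float((2 + (p * np.log2(p)).sum(axis=0)).sum())
    rc = p[::-1, ::-1]
    a, b = p.ravel(), rc.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        pal = 1.0  # uniform matrix equals its own reverse complement
    else:
        pal = float(np.corrcoef(a, b)[0, 1])
    return {
        "gc_content": gc,
        "information_content_bits": ic,
        "palindromicity": pal,
    }


# ---------------------------------------------------------------------------
# scanning


def _motif_logp(codes: np.ndarray, logmat: np.ndarray) -> np.ndarray:
    """(n, L-w+1) motif log-probability for every window start."""
    n, L = codes.shape
    w = logmat.shape[1]
    out = np.zeros((n, L - w + 1))
    for j in range(w):
        out += logmat[codes[:, j:L - w + 1 + j], j]
    return out


def _site_starts(strand: str, cols: np.ndarray, w: int) -> np.ndarray:
    """Map 3'-base columns to window start positions."""
    return cols - w + 1 if strand == "+" else cols


def admissible_columns(L: int, w: int, strand: str) -> tuple[int, int]:
    """Half-open range of columns a width-w motif's 3' base can occupy."""
    return (w - 1, L) if strand == "+" else (0, L - w + 1)


def scan_block(
    block: PromoterBlock,
    pssm: Pssm,
    bg_model: BackgroundModel,
    strand: str = "+",
    column_sum_policy: str = "positive_sum",
    mode: str = "context2",
) -> ColumnScores:
    """Score every admissible window on one strand; aggregate per column.

    The background block is chosen by the scored (3'-base) column.  Column
    scores follow ``column_sum_policy``:

    - ``positive_sum`` (default): x_i = sum of positive (motif) scores in
      column i;
    - ``clamped_total``: x_i = max(0, sum of all raw scores in column i).
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if column_sum_policy not in COLUMN_SUM_POLICIES:
        raise ValueError(f"unknown column_sum_policy {column_sum_policy!r}")
    codes = block.codes
    n, L = codes.shape
    w = pssm.width
    if w > L:
        raise ValueError("motif wider than alignment")

    logmat = pssm.log_probabilities if strand == "+" else \
        pssm.reverse_complement().log_probabilities
    motif_ll = _motif_logp(codes, logmat)  # indexed by window start p

    c_lo, c_hi = admissible_columns(L, w, strand)
    raw = np.full((n, L), np.nan)

    ctx3 = codes[:, :-2].astype(np.int64) * 16 + codes[:, 1:-1] * 4 + codes[:, 2:]

    for b in range(bg_model.n_blocks):
        cs, ce = b * bg_model.block_size, min((b + 1) * bg_model.block_size, L)
        lo, hi = max(cs, c_lo), min(ce, c_hi)
        if lo >= hi:
            continue
        cols = np.arange(lo, hi)
        starts = _site_starts(strand, cols, w)
        p0, p1 = int(starts[0]), int(starts[-1]) + 1
        t0, t1 = p0, min(L, p1 - 1 + w + 3)
        cond = bg_model.cond_logp(codes, t0, t1, b)
        cum = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(cond, axis=1)], axis=1
        )
        # numerator: chain logp of site plus (possibly truncated) right flank
        r_len = np.minimum(3, L - (starts + w))
        ends = starts + w + r_len
        num = cum[:, ends - t0] - cum[:, starts - t0]

        # denominator: log P(right flank | left context, gap w)
        den = np.zeros((n, len(cols)))
        if mode == "context2":
            k_len = np.minimum(3, starts)
            for r in range(0, 4):
                for k in range(0, 4):
                    sel = np.flatnonzero((r_len == r) & (k_len == k))
                    if len(sel) == 0 or r == 0:
                        continue
                    D = bg_model.log_denominator(b, w, r, k)
                    ps = starts[sel]
                    if k == 3:
                        lidx = ctx3[:, ps - 3]
                    elif k == 0:
                        lidx = np.zeros((n, len(ps)), dtype=np.int64)
                    else:
                        lidx = np.zeros((n, len(ps)), dtype=np.int64)
                        for u in range(k):
                            lidx = lidx * 4 + codes[:, ps - k + u]
                    if r == 3:
                        ridx = ctx3[:, ps + w]
                    else:
                        ridx = np.zeros((n, len(ps)), dtype=np.int64)
                        for u in range(r):
                            ridx = ridx * 4 + codes[:, ps + w + u]
                    den[:, sel] = D[lidx, ridx]
        elif mode == "left":
            # drop the right-flank part of the numerator instead
            num = cum[:, starts + w - t0] - cum[:, starts - t0]
        else:
            raise ValueError(f"unknown mode {mode!r}")

        raw[:, lo:hi] = motif_ll[:, p0:p1] - (num - den)

    # hits and column aggregation
    valid = ~np.isnan(raw)
    pos = valid & (raw > 0)
    hit_seq, hit_col = np.nonzero(pos)
    hit_score = raw[hit_seq, hit_col]

    if column_sum_policy == "positive_sum":
        x = np.bincount(hit_col, weights=hit_score, minlength=L)
    else:
        totals = np.where(valid, raw, 0.0).sum(axis=0)
        x = np.maximum(totals, 0.0)
    return ColumnScores(pssm.tf_name, strand, w, x,
                        hit_seq.astype(np.int64), hit_col.astype(np.int64),
                        hit_score, column_sum_policy)


def score_site(
    pssm: Pssm,
    bg_model: BackgroundModel,
    block: PromoterBlock,
    seq_index: int,
    strand: str,
    col3p: int,
    mode: str = "context2",
) -> float:
    """Log-odds score of a single window, identified by its 3'-base column.

    Slow per-site reference path; :func:`scan_block` computes the same
    quantity vectorized (the test suite cross-checks the two).
    """
    w = pssm.width
    L = block.length
    start = col3p - w + 1 if strand == "+" else col3p
    if start < 0 or start + w > L:
        raise ValueError("site out of range")
    seq = block.sequences[seq_index]
    window = seq[start:start + w]
    left = seq[max(0, start - 3):start]
    right = seq[start + w:start + w + 3]
    logmat = pssm.log_probabilities if strand == "+" else \
        pssm.reverse_complement().log_probabilities
    site_ll = sum(logmat[_CODE[c], j] for j, c in enumerate(window))
    b = bg_model.block_of(col3p)
    bg_ll = site_log_prob(bg_model, window, left, right, mode, block_index=b)
    return float(site_ll - bg_ll)


def hits_to_bed(scores: ColumnScores, block: PromoterBlock) -> str:
    """Hits as BED-like TSV: 0-based half-open plus-strand intervals."""
    lines = ["#seq_index\tstart\tend\tgene\tscore\tstrand"]
    w = scores.width
    for s, c, v in zip(scores.hit_seq, scores.hit_col, scores.hit_score):
        start = c - w + 1 if scores.strand == "+" else c
        lines.append(
            f"{s}\t{start}\t{start + w}\t{block.gene_ids[s]}\t{v:.4f}\t{scores.strand}"
        )
    return "\n".join(lines) + "\n"
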