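"""Position-varying Markov background models for promoter alignments.

Base composition changes systematically along a promoter (GC-rich close to
the TSS, AT-rich further out), so a single background model would bias
motif log-odds scores by position.  The model here re-estimates a 3rd-order
Markov chain for every ``block_size``-column block of the alignment, fitting
each chain to a window that extends the block far enough 5' that any motif
whose 3' base falls in the block lies inside the window, plus a 3-letter
context on each side.  With the defaults (block 23, left pad 24 = 21-column
maximum motif width + 3, right pad 3) the window is 50 columns.

Site probabilities come in two flavours:

``left``
    the plain chain probability of the site letters conditioned on the
    3 letters 5' of the site.

``context2``
    the probability of the site conditioned on *both* flanking triples,
    obtained by exact Bayes conditioning under the fitted chain:

        P(site | left, right) = P(site | left) * P(right | end-of-site)
                                / P(right | left, gap = w)

    where the denominator marginalizes over all 4^w length-w interveners
    via w-step propagation of the 64x64 3-mer transfer matrix.  Summed over
    all 4^w sites this is exactly 1, which the test suite checks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .block import PromoterBlock, _CODE

DEFAULT_BLOCK_SIZE = 23
DEFAULT_PAD_LEFT = 24
DEFAULT_PAD_RIGHT = 3
DEFAULT_PSEUDOCOUNT = 0.5


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


class BackgroundModel:
    """Piecewise 3rd-order Markov background fitted per alignment block.

    Parameters
    ----------
    counts : (n_blocks, 4, 4, 4, 4) array
        Raw 4-mer counts per block (no pseudocount); axis order is the
        4-mer letters 5'->3'.
    block_size : int
        Number of alignment columns sharing one transition table.
    length : int
        Alignment length L; ``block_of`` maps columns 0..L-1 to blocks.
    pseudocount : float
        Added to every 4-mer count before normalization (keeps all
        transition probabilities strictly positive).
    """

    def __init__(
        self,
        counts: np.ndarray,
        block_size: int,
        length: int,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        window_pads: tuple[int, int] = (DEFAULT_PAD_LEFT, DEFAULT_PAD_RIGHT),
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 5 or counts.shape[1:] != (4, 4, 4, 4):
            raise ValueError("counts must have shape (n_blocks, 4, 4, 4, 4)")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        self.counts = counts
        self.block_size = int(block_size)
        self.length = int(length)
        self.pseudocount = float(pseudocount)
        self.window_pads = tuple(window_pads)
        self._cache: dict = {}

    # -- geometry ----------------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[0]

    @property
    def block_starts(self) -> np.ndarray:
        return np.arange(self.n_blocks) * self.block_size

    def block_of(self, col: int) -> int:
        if not 0 <= col < self.length:
            raise ValueError(f"column {col} outside alignment")
        return col // self.block_size

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(cls, length: int, block_size: int = DEFAULT_BLOCK_SIZE,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "BackgroundModel":
        """Model with zero counts everywhere: every transition is 1/4."""
        n_blocks = -(-length // block_size)
        return cls(np.zeros((n_blocks, 4, 4, 4, 4)), block_size, length, pseudocount)

    # -- tables ------------------------------------------------------------

    def _memo(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def transition_table(self, b: int, order: int = 3) -> np.ndarray:
        """(4^order, 4) conditional P(next | previous ``order`` letters).

        Lower orders come from marginalizing the pseudocounted 4-mer
        counts over the most distant context letters; they back the
        edge-of-sequence fallback where a full 3-letter context does not
        exist.  Every row sums to 1.
        """
        def build():
            cnt = self.counts[b] + self.pseudocount
            for _ in range(3 - order):
                cnt = cnt.sum(axis=0)
            cnt = cnt.reshape(4 ** order, 4)
            return cnt / cnt.sum(axis=1, keepdims=True)
        return self._memo(("trans", b, order), build)

    def log_transition_table(self, b: int, order: int = 3) -> np.ndarray:
        return self._memo(
            ("logtrans", b, order), lambda: np.log(self.transition_table(b, order))
        )

    def context_marginal(self, b: int) -> np.ndarray:
        """(64,) marginal distribution of 3-mer contexts within the window."""
        def build():
            m = (self.counts[b] + self.pseudocount).sum(axis=3).reshape(64)
            return m / m.sum()
        return self._memo(("marg3", b), build)

    def transfer_matrix(self, b: int) -> np.ndarray:
        """64x64 one-step matrix on 3-mer states (a,b,c) -> (b,c,d)."""
        def build():
            P = self.transition_table(b, 3)
            M = np.zeros((64, 64))
            s = np.arange(64)
            for d in range(4):
                M[s, (s % 16) * 4 + d] = P[s, d]
            return M
        return self._memo(("transfer", b), build)

    def flank_emission(self, b: int, r: int) -> np.ndarray:
        """(64, 4^r) probability of emitting an r-letter flank from a state."""
        if not 0 <= r <= 3:
            raise ValueError("flank length must be 0..3")
        def build():
            if r == 0:
                return np.ones((64, 1))
            P = self.transition_table(b, 3)
            prev = self.flank_emission(b, r - 1)  # (64, 4^(r-1))
            out = np.empty((64, 4 ** r))
            s = np.arange(64)
            step = 4 ** (r - 1)
            for d in range(4):
                nxt = (s % 16) * 4 + d
                out[:, d * step:(d + 1) * step] = P[s, d, None] * prev[nxt]
            return out
        return self._memo(("emit", b, r), build)

    def _matrix_power(self, b: int, w: int) -> np.ndarray:
        def build():
            if w == 0:
                return np.eye(64)
            return self._matrix_power(b, w - 1) @ self.transfer_matrix(b)
        return self._memo(("Mpow", b, w), build)

    def _partial_context_weights(self, b: int, k: int) -> np.ndarray:
        """(4^k, 64): P(full 3-mer state | observed last k letters)."""
        def build():
            marg = self.context_marginal(b)
            if k == 3:
                return np.eye(64)
            out = np.zeros((4 ** k, 64))
            s = np.arange(64)
            suffix = s % (4 ** k) if k > 0 else np.zeros(64, dtype=int)
            for j in range(4 ** k):
                mask = suffix == j
                tot = marg[mask].sum()
                out[j, mask] = marg[mask] / tot
            return out
        return self._memo(("partial", b, k), build)

    def log_denominator(self, b: int, w: int, r: int, k: int = 3) -> np.ndarray:
        """(4^k, 4^r) log P(r-letter right flank | k-letter left context, gap w).

        ``w`` is the site width being marginalized out.  ``k < 3`` handles
        sites so close to the sequence start that the left triple is
        truncated; the missing state letters are marginalized under the
        window's 3-mer distribution.
        """
        def build():
            D = self._matrix_power(b, w) @ self.flank_emission(b, r)
            if k < 3:
                D = self._partial_context_weights(b, k) @ D
            return np.log(D)
        return self._memo(("denom", b, w, r, k), build)

    # -- conditional log-probabilities ------------------------------------

    def cond_logp(self, codes: np.ndarray, t0: int, t1: int, b: int) -> np.ndarray:
        """(n, t1-t0) log P(codes[:, t] | preceding letters) under block ``b``.

        Positions t < 3 fall back to the order-t marginalized table.
        """
        n = codes.shape[0]
        out = np.empty((n, t1 - t0))
        lo = max(t0, 3)
        if lo < t1:
            logp3 = self.log_transition_table(b, 3)
            ctx = (
                codes[:, lo - 3:t1 - 3].astype(np.int64) * 16
                + codes[:, lo - 2:t1 - 2] * 4
                + codes[:, lo - 1:t1 - 1]
            )
            out[:, lo - t0:] = logp3[ctx, codes[:, lo:t1]]
        for t in range(t0, min(t1, 3)):
            tab = self.log_transition_table(b, t)
            ctx = np.zeros(n, dtype=np.int64)
            for u in range(t):
                ctx = ctx * 4 + codes[:, u]
            out[:, t - t0] = tab[ctx, codes[:, t]]
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "block_size": self.block_size,
            "length": self.length,
            "pseudocount": self.pseudocount,
            "window_pads": list(self.window_pads),
            "counts": self.counts.reshape(self.n_blocks, 256).tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BackgroundModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        counts = np.array(d["counts"]).reshape(-1, 4, 4, 4, 4)
        return cls(counts, d["block_size"], d["length"], d["pseudocount"],
                   tuple(d["window_pads"]))


def fit_background(
    block: PromoterBlock,
    block_size: int = DEFAULT_BLOCK_SIZE,
    window_pad_left: int = DEFAULT_PAD_LEFT,
    window_pad_right: int = DEFAULT_PAD_RIGHT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BackgroundModel:
    """Fit the piecewise background to a promoter block.

    For each ``block_size``-column block the fitting window spans
    ``[start - window_pad_left, end + window_pad_right)`` clipped at the
    alignment edges; 4-mer counts are pooled over all sequences across the
    window and pseudocounted.
    """
    codes = block.codes
    L = block.length
    n_blocks = -(-L // block_size)
    if L < 4:
        raise ValueError("alignment too short for a 3rd-order model")

    idx4 = (
        codes[:, :-3].astype(np.int64) * 64
        + codes[:, 1:-2] * 16
        + codes[:, 2:-1] * 4
        + codes[:, 3:]
    )
    counts = np.zeros((n_blocks, 256))
    for b in range(n_blocks):
        cs = b * block_size
        ce = min(cs + block_size, L)
        wlo = max(0, cs - window_pad_left)
        whi = min(L, ce + window_pad_right)
        if whi - wlo < 4:
            raise ValueError(f"window for block {b} shorter than 4 columns")
        counts[b] = np.bincount(idx4[:, wlo:whi - 3].ravel(), minlength=256)
    return BackgroundModel(
        counts.reshape(n_blocks, 4, 4, 4, 4), block_size, L, pseudocount,
        (window_pad_left, window_pad_right),
    )


def _roll_logp(model: BackgroundModel, b: int, state: list[int], letters) -> float:
    """Chain log-probability of ``letters`` given a rolling <=3-letter state."""
    ll = 0.0
    st = list(state)[-3:]
    for c in letters:
        order = len(st)
        tab = model.log_transition_table(b, order)
        ctx = 0
        for u in st:
            ctx = ctx * 4 + u
        ll += tab[ctx, c]
        st = (st + [c])[-3:]
    return ll


def site_log_prob(
    model: BackgroundModel,
    site: str,
    left_triple: str = "",
    right_triple: str = "",
    mode: str = "context2",
    block_index: int = 0,
) -> float:
    """Background log-probability of a candidate site.

    ``left_triple``/``right_triple`` are the up-to-3-letter flanks; shorter
    flanks (sequence edges) drop to the matching lower-order conditioning.
    ``mode='left'`` conditions on the left flank only; ``mode='context2'``
    conditions on both flanks as described in the module docstring.
    """
    if mode not in ("left", "context2"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(left_triple) > 3 or len(right_triple) > 3:
        raise ValueError("flanks are at most 3 letters")
    s = [_CODE[c] for c in site.upper()]
    lf = [_CODE[c] for c in left_triple.upper()]
    rf = [_CODE[c] for c in right_triple.upper()]
    if not s:
        raise ValueError("empty site")
    b = block_index
    w = len(s)

    ll_site = _roll_logp(model, b, lf, s)
    if mode == "left":
        return float(ll_site)

    r = len(rf)
    ll_right = _roll_logp(model, b, lf + s, rf)
    if r == 0:
        return float(ll_site)
    k = len(lf)
    lidx = 0
    for u in lf:
        lidx = lidx * 4 + u
    ridx = 0
    for u in rf:
        ridx = ridx * 4 + u
    denom = model.log_denominator(b, w, r, k)[lidx, ridx]
    return float(ll_site + ll_right - denom)
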