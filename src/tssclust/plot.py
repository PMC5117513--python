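"""Grayscale rendering of gene-group intersection p-values.

The matrix view mirrors the convention of intersection heatmaps in
promoter studies: lower triangle only (the matrix is symmetric), diagonal
omitted (self-intersections are meaningless), rows sorted alphabetically
by TF and then by p-value.  Gray level encodes the p-value: 0 -> black,
1 -> white, and the significance threshold maps to exactly 50% gray, so
darker-than-mid cells are significant at a glance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def pvalue_to_gray(p, threshold: float) -> np.ndarray:
    """Piecewise-linear map with anchors 0 -> 0.0, threshold -> 0.5, 1 -> 1.0."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    lower = 0.5 * p / threshold
    upper = 0.5 + 0.5 * (p - threshold) / (1 - threshold)
    return np.where(p <= threshold, lower, upper)


def _row_order(keys: list[str]) -> list[str]:
    # alphabetical on TF, then by From coordinate for determinism
    def split(k: str):
        tf, frm, to, strand = k.rsplit(":", 3)
        return (tf, int(frm), int(to), strand)
    return sorted(set(keys), key=split)


def render_intersection_matrix(
    intersections: pd.DataFrame,
    threshold: float,
    path: str | Path | None = None,
    mode: str = "p_right",
) -> np.ndarray:
    """Lower-triangle grayscale matrix of intersection p-values.

    Returns the (k, k) gray-level array (NaN above and on the diagonal);
    writes a PNG when ``path`` is given.
    """
    if mode not in ("p_right", "p_left"):
        raise ValueError("mode must be 'p_right' or 'p_left'")
    if len(intersections) == 0:
        raise ValueError("need at least one intersection (>= 2 clusters)")
    keys = _row_order(list(intersections.key_a) + list(intersections.key_b))
    index = {k: i for i, k in enumerate(keys)}
    k = len(keys)
    gray = np.full((k, k), np.nan)
    for row in intersections.itertuples():
        i, j = index[row.key_a], index[row.key_b]
        lo, hi = (j, i) if i > j else (i, j)
        gray[hi, lo] = pvalue_to_gray(getattr(row, mode), threshold)

    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, k * 0.25),) * 2)
        masked = np.ma.masked_invalid(gray)
        ax.imshow(masked, cmap="gray", vmin=0.0, vmax=1.0)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"gene-group intersections ({mode})")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return gray
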