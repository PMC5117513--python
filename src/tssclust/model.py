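"""Model/Results interface for positional motif-cluster analysis.

:class:`PositionalClusterModel` holds the data (a TSS-anchored promoter
block and a set of count matrices) and the analysis configuration;
``fit()`` runs background fitting, two-strand scanning, and cluster
detection for every matrix, returning a :class:`ClusterResults` that
carries the cluster estimates, their p-values, gene groups, intersection
tests, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .background import BackgroundModel, fit_background
from .block import PromoterBlock, read_promoter_block
from .clusters import Cluster, ClusterConfig, KarlinParams, detect_clusters
from .genegroups import (
    GeneGroup,
    bonferroni_threshold,
    cluster_gene_group,
    export_gene_lists,
    intersection_table,
)
from .motifs import CountMatrix, counts_to_pssm, read_jaspar, scan_block

CLUSTER_COLUMNS = [
    "tf", "strand", "cluster_p", "from_bp", "to_bp", "spread",
    "pct_multiple_motifs", "n_hits", "n_genes", "score", "key",
]


class PositionalClusterModel:
    """Positional clustering of TF motifs in a TSS-anchored block.

    Parameters
    ----------
    block : PromoterBlock
        The anchored alignment with its sequence -> gene mapping.
    matrices : sequence of CountMatrix
        TF count matrices to scan (JASPAR-style nucleotide counts).
    config : ClusterConfig, optional
        rho, K, thresholds, column-sum policy, background mode.
    background : BackgroundModel, optional
        Pre-fitted background; fitted from the block when omitted.
    """

    def __init__(
        self,
        block: PromoterBlock,
        matrices: Sequence[CountMatrix],
        config: ClusterConfig | None = None,
        background: BackgroundModel | None = None,
    ):
        if not matrices:
            raise ValueError("at least one count matrix is required")
        self.block = block
        self.matrices = list(matrices)
        self.config = config or ClusterConfig()
        self.background = background

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        metadata: str | Path,
        pfm: str | Path,
        tss_col: int = 2000,
        config: ClusterConfig | None = None,
    ) -> "PositionalClusterModel":
        block = read_promoter_block(fasta, metadata, tss_col)
        return cls(block, read_jaspar(pfm), config)

    def fit(self, strands: Sequence[str] = ("+", "-")) -> "ClusterResults":
        """Scan every matrix on the requested strands and detect clusters."""
        bg = self.background or fit_background(self.block)
        cmap = self.block.coords
        cfg = self.config
        clusters: list[Cluster] = []
        karlin: dict[tuple[str, str], KarlinParams] = {}
        scan_store: dict[tuple[str, str], object] = {}
        for cm in sorted(self.matrices, key=lambda m: (m.tf_name, m.matrix_id)):
            pssm = counts_to_pssm(cm)
            for strand in strands:
                scores = scan_block(
                    self.block, pssm, bg, strand,
                    cfg.column_sum_policy, cfg.background_mode,
                )
                found, params = detect_clusters(scores, cmap, cfg)
                clusters.extend(found)
                if params is not None:
                    karlin[(cm.tf_name, strand)] = params
                scan_store[(cm.tf_name, strand)] = scores
        return ClusterResults(self, bg, clusters, karlin, scan_store,
                              list(strands))


@dataclass
class ClusterResults:
    """Fitted clusters plus downstream gene-group machinery."""

    model: PositionalClusterModel
    background: BackgroundModel
    clusters: list[Cluster]
    karlin: dict
    scans: dict = field(repr=False)
    strands: list[str] = field(default_factory=lambda: ["+", "-"])

    # -- thresholds --------------------------------------------------------

    @property
    def n_cluster_tests(self) -> int:
        return len(self.model.matrices) * len(self.strands)

    @property
    def cluster_threshold(self) -> float:
        """Bonferroni threshold over matrices x strands at config alpha."""
        return bonferroni_threshold(self.model.config.alpha,
                                    self.n_cluster_tests)

    # -- tables ------------------------------------------------------------

    def frame(self, threshold: float | None = None) -> pd.DataFrame:
        """Cluster table (all clusters, or those at ``threshold``)."""
        blk = self.model.block
        rows = []
        for c in self.clusters:
            if threshold is not None and c.p_value > threshold:
                continue
            rows.append({
                "tf": c.tf_name, "strand": c.strand, "cluster_p": c.p_value,
                "from_bp": c.from_bp, "to_bp": c.to_bp, "spread": c.spread,
                "pct_multiple_motifs": c.pct_multiple_motifs,
                "n_hits": c.n_hits,
                "n_genes": len({blk.gene_ids[int(s)] for s in c.hit_seq}),
                "score": c.score, "key": c.key,
            })
        df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
        return df.sort_values(["cluster_p", "tf", "strand"],
                              ignore_index=True)

    def significant_clusters(self, threshold: float | None = None) -> list[Cluster]:
        thr = self.cluster_threshold if threshold is None else threshold
        keep = [c for c in self.clusters if c.p_value <= thr]
        return sorted(keep, key=lambda c: (c.p_value, c.tf_name, c.strand))

    # -- gene groups and intersections ------------------------------------

    def gene_groups(self, threshold: float | None = None) -> list[GeneGroup]:
        return [
            cluster_gene_group(c, self.model.block)
            for c in self.significant_clusters(threshold)
        ]

    @property
    def universe(self) -> frozenset[str]:
        """The dataset's own genes (never a global catalogue)."""
        return frozenset(self.model.block.gene_ids)

    def intersections(
        self,
        threshold: float | None = None,
        alpha: float | None = None,
        two_sided_correction: bool = False,
    ) -> pd.DataFrame:
        """Fisher tests of all unordered gene-group pairs, Bonferroni-flagged."""
        alpha = self.model.config.alpha if alpha is None else alpha
        groups = [g for g in self.gene_groups(threshold) if g.size >= 1]
        return intersection_table(groups, self.universe, alpha,
                                  two_sided_correction)

    def export_gene_lists(self, destination: str | Path,
                          threshold: float | None = None) -> list[Path]:
        return export_gene_lists(self.gene_groups(threshold), destination)

    # -- reporting ---------------------------------------------------------

    def summary(self, threshold: float | None = None) -> str:
        cfg = self.model.config
        thr = self.cluster_threshold if threshold is None else threshold
        sig = self.significant_clusters(thr)
        blk = self.model.block
        lines = [
            "Positional motif-cluster analysis",
            "=" * 49,
            f"sequences: {blk.n}   genes: {blk.n_genes}   "
            f"columns: {blk.length} (TSS at column {blk.tss_col})",
            f"matrices: {len(self.model.matrices)}   strands: "
            f"{','.join(self.strands)}   rho: {cfg.rho}   K: {cfg.K}",
            f"cluster threshold (Bonferroni {cfg.alpha} / "
            f"{self.n_cluster_tests}): {thr:.3g}",
            f"significant clusters: {len(sig)}",
            "",
        ]
        df = self.frame(thr)
        if len(df):
            lines.append(df.to_string(
                index=False,
                formatters={"cluster_p": "{:.3g}".format,
                            "pct_multiple_motifs": "{:.3f}".format,
                            "score": "{:.2f}".format},
            ))
        else:
            lines.append("(no clusters at this threshold)")
        return "\n".join(lines) + "\n"

    def to_tsv(self, path: str | Path, threshold: float | None = None) -> Path:
        path = Path(path)
        self.frame(threshold).to_csv(path, sep="\t", index=False)
        return path

    def plot_intersections(self, path: str | Path | None = None,
                           threshold: float | None = None,
                           mode: str = "p_right"):
        from .plot import render_intersection_matrix
        inter = self.intersections(threshold)
        thr = inter.attrs.get("bonferroni_threshold", 0.05)
        return render_intersection_matrix(inter, thr, path=path, mode=mode)
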