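"""Pipeline orchestration: config, full runs, and rho tuning.

``run_pipeline`` is the batch entry point: it loads a block and matrices,
fits the model, thresholds the clusters, runs the intersection tests, and
writes deterministic TSV/JSON outputs plus a run manifest containing
every parameter needed for a bit-exact rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .block import read_promoter_block
from .clusters import ClusterConfig
from .model import PositionalClusterModel
from .motifs import read_jaspar

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str
    matrices: str
    outdir: str
    tss_col: int = 2000
    rho: float = 1.4
    K: float = 1.0
    alpha: float = 0.05
    column_sum_policy: str = "positive_sum"
    background_mode: str = "context2"
    strands: tuple[str, ...] = ("+", "-")
    cluster_threshold: float | None = None  # None -> Bonferroni alpha/(m*strands)
    two_sided_intersection_correction: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "strands" in d:
            d["strands"] = tuple(d["strands"])
        return cls(**d)

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(
            rho=self.rho, K=self.K, seed=self.seed, alpha=self.alpha,
            column_sum_policy=self.column_sum_policy,
            background_mode=self.background_mode,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Full run: scan -> clusters -> gene groups -> intersections -> files.

    Empty-but-valid results (no significant clusters) are not an error:
    the downstream tables are written empty with a notice in the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    block = read_promoter_block(config.fasta, config.metadata, config.tss_col)
    matrices = read_jaspar(config.matrices)
    model = PositionalClusterModel(block, matrices, config.cluster_config())
    results = model.fit(config.strands)

    thr = (results.cluster_threshold if config.cluster_threshold is None
           else config.cluster_threshold)
    cluster_path = out / "clusters.tsv"
    results.to_tsv(cluster_path, threshold=thr)
    sig = results.significant_clusters(thr)

    inter = results.intersections(
        thr, config.alpha, config.two_sided_intersection_correction
    )
    inter_path = out / "intersections.tsv"
    inter.to_csv(inter_path, sep="\t", index=False)

    gene_dir = out / "gene_groups"
    if sig:
        results.export_gene_lists(gene_dir, thr)

    manifest = {
        "config": asdict(config),
        "counts": {
            "sequences": block.n,
            "genes": block.n_genes,
            "matrices": len(matrices),
            "hits": int(sum(s.n_hits for s in results.scans.values())),
            "clusters_total": len(results.clusters),
            "clusters_significant": len(sig),
            "pairs_tested": len(inter),
            "pairs_significant": int(inter["significant"].sum()) if len(inter) else 0,
        },
        "cluster_threshold": thr,
        "notice": None if sig else "no significant clusters at threshold",
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.txt").write_text(results.summary(thr))
    logger.info("pipeline done: %s", manifest["counts"])
    return {"results": results, "manifest": manifest, "outdir": out}


def tune_rho(
    block,
    matrices,
    rho_grid,
    base_config: ClusterConfig | None = None,
    threshold: float | None = None,
    max_spread: int = 10,
) -> pd.DataFrame:
    """Median significant-cluster spread and count along a rho grid.

    Recommends the smallest rho whose median spread is <= ``max_spread``
    columns (tight positional preference); the recommendation is stored in
    ``df.attrs['recommended_rho']``.
    """
    rho_grid = list(rho_grid)
    if any(r <= 1 for r in rho_grid):
        raise ValueError("all rho values must exceed 1")
    base = base_config or ClusterConfig()
    rows = []
    for rho in sorted(rho_grid):
        cfg = ClusterConfig(
            rho=rho, K=base.K, seed=base.seed, alpha=base.alpha,
            column_sum_policy=base.column_sum_policy,
            background_mode=base.background_mode,
        )
        res = PositionalClusterModel(block, matrices, cfg).fit()
        thr = res.cluster_threshold if threshold is None else threshold
        sig = res.significant_clusters(thr)
        spreads = [c.spread for c in sig]
        rows.append({
            "rho": rho,
            "n_significant": len(sig),
            "median_spread": float(np.median(spreads)) if spreads else np.nan,
        })
    df = pd.DataFrame(rows)
    ok = df[df.median_spread <= max_spread]
    df.attrs["recommended_rho"] = float(ok.rho.iloc[0]) if len(ok) else None
    return df
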