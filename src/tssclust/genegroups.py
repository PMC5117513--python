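"""Cluster gene-groups and enrichment of their pairwise intersections.

Each cluster's motifs come from sequences, and each sequence maps to a
gene; the distinct genes contributing at least one motif to a cluster form
its *gene group*.  If two TFs bind within the same regulatory module, the
module's presence enriches the intersection of the two gene groups beyond
chance, which a right-tailed Fisher exact test detects against the
dataset's own gene universe (never a global gene catalogue, to avoid
importing selection biases).  The left tail serves only as a negative
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .block import PromoterBlock
from .clusters import Cluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneGroup:
    """Distinct genes whose sequences contribute motifs to one cluster."""

    cluster_key: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class IntersectionResult:
    """2x2 contingency and Fisher tails for a pair of gene groups.

    a = |A & B|, b = |A - B|, c = |B - A|, d = rest of the universe.
    """

    key_a: str
    key_b: str
    a: int
    b: int
    c: int
    d: int
    p_right: float
    p_left: float
    significant_after_bonferroni: bool = False


def cluster_gene_group(cluster: Cluster, block: PromoterBlock) -> GeneGroup:
    """Genes of the sequences with >= 1 motif inside the cluster segment."""
    genes = frozenset(block.gene_ids[int(s)] for s in cluster.hit_seq)
    return GeneGroup(cluster.key, genes)


def fisher_intersection(
    group_a: GeneGroup,
    group_b: GeneGroup,
    universe: Iterable[str],
) -> IntersectionResult:
    """Exact hypergeometric tails for the overlap of two gene groups.

    With X ~ Hypergeom(N=|universe|, K=|A|, n=|B|) and observed overlap a:
    p_right = P(X >= a), p_left = P(X <= a).
    """
    uni = frozenset(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not group_a.genes <= uni or not group_b.genes <= uni:
        raise ValueError("gene group not contained in the universe")
    N = len(uni)
    ka, kb = group_a.size, group_b.size
    a = len(group_a.genes & group_b.genes)
    dist = hypergeom(N, ka, kb)
    p_right = float(min(max(dist.sf(a - 1), 5e-324), 1.0))
    p_left = float(min(max(dist.cdf(a), 5e-324), 1.0))
    return IntersectionResult(
        group_a.cluster_key, group_b.cluster_key,
        a, ka - a, kb - a, N - ka - kb + a,
        p_right, p_left,
    )


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test threshold alpha / m for family-wise error control."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def pair_count(k_groups: int) -> int:
    """Number of unordered pairs among k groups: k(k-1)/2."""
    if k_groups < 0:
        raise ValueError("k_groups must be >= 0")
    return k_groups * (k_groups - 1) // 2


def expected_false_positives(m_tests: int, p_threshold: float) -> float:
    """Expected count of uniform p-values below the threshold: m * pi."""
    if not 0 <= p_threshold < 1:
        raise ValueError("p_threshold must lie in [0, 1)")
    return m_tests * p_threshold


def intersection_table(
    groups: Sequence[GeneGroup],
    universe: Iterable[str],
    alpha: float = 0.05,
    two_sided_correction: bool = False,
) -> pd.DataFrame:
    """All unordered pairwise intersection tests, Bonferroni-flagged.

    ``two_sided_correction=True`` divides alpha by 2m instead of m (the
    stricter arithmetic that also budgets for the left-tailed control).
    Self-intersections are excluded.  Long format: one row per pair with
    the contingency cells, both tails, and the significance flag for the
    right tail.
    """
    m = pair_count(len(groups))
    rows = []
    if m == 0:
        return pd.DataFrame(
            columns=["key_a", "key_b", "a", "b", "c", "d",
                     "p_right", "p_left", "significant"]
        )
    thr = bonferroni_threshold(alpha, 2 * m if two_sided_correction else m)
    for ga, gb in combinations(groups, 2):
        r = fisher_intersection(ga, gb, universe)
        rows.append({
            "key_a": r.key_a, "key_b": r.key_b,
            "a": r.a, "b": r.b, "c": r.c, "d": r.d,
            "p_right": r.p_right, "p_left": r.p_left,
            "significant": r.p_right <= thr,
        })
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_threshold"] = thr
    df.attrs["m_tests"] = m
    return df


def export_gene_lists(
    groups: Sequence[GeneGroup] | Mapping[str, GeneGroup],
    destination: str | Path,
) -> list[Path]:
    """One plain-text file of sorted unique gene IDs per cluster group."""
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    if not groups:
        raise ValueError("no gene groups to export")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    for g in groups:
        fname = g.cluster_key.replace(":", "_").replace("+", "p").replace("-", "m")
        path = dest / f"{fname}.txt"
        if not g.genes:
            logger.warning("gene group %s is empty", g.cluster_key)
        path.write_text("".join(f"{gene}\n" for gene in sorted(g.genes)))
        written.append(path)
    return written
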