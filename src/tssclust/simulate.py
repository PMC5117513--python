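"""Synthetic promoter blocks with known planted truth.

The generators here stand in for a large TSS-anchored promoter collection
(tens of thousands of cDNA-derived 3001-bp sequences mapping redundantly
onto thousands of genes), which cannot ship with the package.  They
emulate its structural features:

- fixed-length sequences over {A,C,G,T} anchored on a TSS column;
- many-to-one sequence -> gene redundancy (several promoter records per
  gene);
- position-varying composition (optional GC enrichment toward the TSS);
- planted regulatory modules (RMs): co-occurring motif sites at fixed
  offsets from the TSS in a carrier subset of genes;
- two negative controls: fully random blocks, and "random with offsets"
  blocks in which groups of sequences are offset copies of shared source
  strings, reproducing the sequence-overlap structure of real promoter
  collections without any planted signal.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .block import ALPHABET, PromoterBlock
from .motifs import CountMatrix, counts_to_pssm

_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


def _decode(row: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in row)


@dataclass(frozen=True)
class RmMember:
    """One motif site of a regulatory module.

    ``offset_bp`` is the bp coordinate (no position 0) of the site's
    3' base: the right end of the window on the plus strand, the left end
    on the minus strand.
    """

    matrix: CountMatrix
    strand: str
    offset_bp: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.offset_bp == 0:
            raise ValueError("there is no position 0")


@dataclass(frozen=True)
class RmSpec:
    members: tuple[RmMember, ...]
    carrier_fraction: float = 0.3
    offset_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must lie in (0, 1]")
        if not self.members:
            raise ValueError("an RM needs at least one member")


@dataclass(frozen=True)
class PlantedSite:
    sequence_index: int
    gene_id: str
    tf_name: str
    strand: str
    col3p: int  # scored column: right window end on '+', left end on '-'
    start: int  # plus-strand window start column
    site: str  # letters as written on the plus strand


@dataclass
class SyntheticStudy:
    """A block with its planted ground truth."""

    block: PromoterBlock
    truth: list[PlantedSite]
    rm_spec: RmSpec | None
    carriers: frozenset[str]
    seed: int

    def truth_consistent(self) -> bool:
        """Do the block letters still equal every planted write?"""
        for t in self.truth:
            seq = self.block.sequences[t.sequence_index]
            if seq[t.start:t.start + len(t.site)] != t.site:
                return False
        return True

    def truth_frame(self):
        import pandas as pd
        return pd.DataFrame([vars(t) for t in self.truth])


# ---------------------------------------------------------------------------
# matrices


def synthetic_count_matrix(
    width: int,
    information: float = 0.85,
    total: int = 100,
    seed: int = 0,
    name: str = "SYN",
) -> CountMatrix:
    """Count matrix with a random consensus and controllable sharpness.

    ``information`` is the probability mass on the consensus base in each
    column (0.25 = uninformative, ~1 = near-deterministic); the remainder
    is split evenly.  Useful for exercising scanning and descriptors
    without an external matrix collection.
    """
    if not 0.25 <= information < 1:
        raise ValueError("information must lie in [0.25, 1)")
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=width)
    counts = np.full((4, width), total * (1 - information) / 3)
    counts[consensus, np.arange(width)] = total * information
    return CountMatrix(name, f"SYN{seed:04d}", counts)


# ---------------------------------------------------------------------------
# background blocks


def _chain_probs(transitions: np.ndarray | None) -> np.ndarray:
    if transitions is None:
        return np.full((64, 4), 0.25)
    t = np.asarray(transitions, dtype=float)
    if t.shape != (64, 4) or (t < 0).any():
        raise ValueError("transitions must be a nonnegative (64, 4) table")
    rows = t.sum(axis=1)
    if not np.all(rows > 0):
        raise ValueError("every transition row needs positive mass")
    return t / rows[:, None]


def generate_background_block(
    n_seq: int,
    length: int = 3001,
    tss_col: int | None = None,
    transitions: np.ndarray | None = None,
    gc_gradient: float = 0.0,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> PromoterBlock:
    """Sample a block from a 3rd-order chain, optionally GC-enriched at TSS.

    With ``gc_gradient = gamma`` in (0, 1], the per-column base
    distribution is mixed toward a pure-GC distribution with a weight that
    rises linearly from 0 at the alignment edges to gamma at the TSS
    column, emulating GC-rich proximal promoters.
    """
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0 <= gc_gradient <= 1:
        raise ValueError("gc_gradient must lie in [0, 1]")
    tss_col = length // 2 if tss_col is None else tss_col
    table = _chain_probs(transitions)
    rng = np.random.default_rng(seed)
    gc_dist = np.array([0.0, 0.5, 0.5, 0.0])

    codes = np.empty((n_seq, length), dtype=np.uint8)
    ctx = np.zeros(n_seq, dtype=np.int64)
    max_dist = max(tss_col, length - 1 - tss_col, 1)
    for t in range(length):
        probs = table[ctx]
        if gc_gradient > 0:
            m = gc_gradient * (1 - abs(t - tss_col) / max_dist)
            probs = (1 - m) * probs + m * gc_dist
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_seq) * cum[:, -1]
        draw = (u[:, None] >= cum).sum(axis=1)
        codes[:, t] = draw
        ctx = (ctx * 4 + draw) % 64

    seqs = [_decode(codes[k]) for k in range(n_seq)]
    if gene_ids is None:
        gene_ids = [f"g{k:05d}" for k in range(n_seq)]
    if len(gene_ids) != n_seq:
        raise ValueError("gene_ids must match n_seq")
    return PromoterBlock(seqs, list(gene_ids), tss_col)


def redundant_gene_ids(
    n_genes: int, copies_range: tuple[int, int] = (1, 5), seed: int = 0
) -> list[str]:
    """Gene labels with 1..k promoter records per gene (cDNA redundancy)."""
    rng = np.random.default_rng(seed)
    lo, hi = copies_range
    out: list[str] = []
    for k in range(n_genes):
        out.extend([f"g{k:05d}"] * int(rng.integers(lo, hi + 1)))
    return out


# ---------------------------------------------------------------------------
# planting regulatory modules


def _member_window(member: RmMember, col3p: int) -> tuple[int, int]:
    w = member.matrix.width
    return (col3p - w + 1, col3p + 1) if member.strand == "+" else (col3p, col3p + w)


def plant_rm(
    block: PromoterBlock,
    rm_spec: RmSpec,
    seed: int = 0,
) -> SyntheticStudy:
    """Write RM member sites into a carrier fraction of genes.

    Carrier genes are drawn without replacement; in every sequence of a
    carrier gene, each member site is sampled column-wise from the
    member's PSSM (so weak instances occur, exercising false negatives),
    reverse-complemented for minus-strand members, and written with its
    3' base at the specified offset (plus optional Gaussian jitter).
    Overlapping planted windows within one sequence are an error.
    """
    rng = np.random.default_rng(seed)
    cmap = block.coords
    genes = list(dict.fromkeys(block.gene_ids))
    n_carriers = max(1, round(rm_spec.carrier_fraction * len(genes)))
    carriers = frozenset(rng.choice(genes, size=n_carriers, replace=False))

    pssms = [counts_to_pssm(m.matrix) for m in rm_spec.members]
    codes = block.codes.copy()
    truth: list[PlantedSite] = []
    for k, gene in enumerate(block.gene_ids):
        if gene not in carriers:
            continue
        occupied: list[tuple[int, int]] = []
        for member, pssm in zip(rm_spec.members, pssms):
            base_col = cmap.coord_to_col(member.offset_bp)
            col = base_col
            if rm_spec.offset_jitter_sd > 0:
                col += int(round(rng.normal(0, rm_spec.offset_jitter_sd)))
            lo, hi = _member_window(member, col)
            if lo < 0 or hi > block.length:
                raise ValueError(
                    f"planted window for {member.matrix.tf_name} does not fit"
                )
            if any(lo < o_hi and o_lo < hi for o_lo, o_hi in occupied):
                raise ValueError("overlapping planted windows in one sequence")
            occupied.append((lo, hi))
            w = member.matrix.width
            u = rng.random(w)
            cum = np.cumsum(pssm.probabilities, axis=0)
            site = (u[None, :] >= cum).sum(axis=0)
            plus = site if member.strand == "+" else _COMP[site[::-1]]
            codes[k, lo:hi] = plus
            truth.append(PlantedSite(
                sequence_index=k, gene_id=gene, tf_name=member.matrix.tf_name,
                strand=member.strand, col3p=col, start=lo, site=_decode(plus),
            ))
    new_block = PromoterBlock(
        [_decode(codes[k]) for k in range(block.n)],
        list(block.gene_ids), block.tss_col,
    )
    return SyntheticStudy(new_block, truth, rm_spec, carriers, seed)


# ---------------------------------------------------------------------------
# negative controls


def generate_random_with_offsets(
    block: PromoterBlock,
    max_offset: int = 500,
    seed: int = 0,
) -> PromoterBlock:
    """Negative control reproducing sequence overlaps without signal.

    Sequences sharing a gene become windows, at uniform offsets within
    +/- ``max_offset`` bp, into one shared random source string, so the
    within-gene overlap structure of a real promoter collection is kept
    while all motif signal is destroyed.
    """
    rng = np.random.default_rng(seed)
    L = block.length
    groups: dict[str, list[int]] = {}
    for k, g in enumerate(block.gene_ids):
        groups.setdefault(g, []).append(k)
    seqs: list[str | None] = [None] * block.n
    for gene, members in groups.items():
        source = rng.integers(0, 4, size=L + 2 * max_offset, dtype=np.uint8)
        for k in members:
            delta = int(rng.integers(-max_offset, max_offset + 1))
            start = max_offset + delta
            seqs[k] = _decode(source[start:start + L])
    return PromoterBlock(list(seqs), list(block.gene_ids), block.tss_col)


# ---------------------------------------------------------------------------
# study I/O


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """FASTA + record->gene metadata + planted-truth TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "block.fasta"
    meta = out / "metadata.tsv"
    truth = out / "truth.tsv"
    blk = study.block
    with fasta.open("w") as fh:
        for k, s in enumerate(blk.sequences):
            fh.write(f">seq{k:05d}\n{s}\n")
    meta.write_text(
        "".join(f"seq{k:05d}\t{g}\n" for k, g in enumerate(blk.gene_ids))
    )
    with truth.open("w") as fh:
        fh.write("sequence_index\tgene_id\ttf_name\tstrand\tcol3p\tstart\tsite\n")
        for t in study.truth:
            fh.write(f"{t.sequence_index}\t{t.gene_id}\t{t.tf_name}\t"
                     f"{t.strand}\t{t.col3p}\t{t.start}\t{t.site}\n")
    return {"fasta": fasta, "metadata": meta, "truth": truth}


def study_from_config(source: str | Path, seed: int | None = None) -> SyntheticStudy:
    """Build a study from a YAML spec (sizes, RM members, background).

    Keys: n_genes, copies_range, length, tss_col, gc_gradient, seed, and
    rm: {carrier_fraction, offset_jitter_sd, members: [{width,
    information, strand, offset_bp, name}, ...]}.
    """
    cfg = yaml.safe_load(Path(source).read_text())
    seed = cfg.get("seed", 0) if seed is None else seed
    gene_ids = redundant_gene_ids(
        cfg["n_genes"], tuple(cfg.get("copies_range", (1, 1))), seed=seed
    )
    blk = generate_background_block(
        n_seq=len(gene_ids),
        length=cfg.get("length", 3001),
        tss_col=cfg.get("tss_col"),
        gc_gradient=cfg.get("gc_gradient", 0.0),
        gene_ids=gene_ids,
        seed=seed,
    )
    rm_cfg = cfg.get("rm")
    if not rm_cfg:
        return SyntheticStudy(blk, [], None, frozenset(), seed)
    members = tuple(
        RmMember(
            synthetic_count_matrix(
                m["width"], m.get("information", 0.85),
                seed=seed + i, name=m.get("name", f"SYN{i}"),
            ),
            m.get("strand", "+"),
            m["offset_bp"],
        )
        for i, m in enumerate(rm_cfg["members"])
    )
    spec = RmSpec(members, rm_cfg.get("carrier_fraction", 0.3),
                  rm_cfg.get("offset_jitter_sd", 0.0))
    return plant_rm(blk, spec, seed=seed + 1)
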