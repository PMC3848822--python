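"""Pairwise genome similarity from homolog groups with the min-copy rule.

The number of similar genes S_ij between genomes i and j sums, over every
homolog group, the smaller of the two genomes' copy numbers in that group
(a genome with 2 copies compared against one with 4 contributes 2).  The
fractional matrix divides each entry by the gene count of the *column*
genome, F[i][j] = S_ij / G_j, so each pairwise comparison yields two
asymmetric similarity values: a tiny genome's column is near 1 everywhere,
its row near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Genome, HomologGroupSet


@dataclass
class SimilarityMatrix:
    """Shared-gene counts and column-normalised fractions for a genome set.

    ``S`` is symmetric with S[i][i] = G_i; ``F`` is generally asymmetric
    with a fixed diagonal of 1.0 and satisfies F[i][j]*G_j == F[j][i]*G_i.
    """

    genome_ids: list[str]
    S: np.ndarray  # (n, n) int, shared-gene counts
    F: np.ndarray  # (n, n) float, S[i][j] / G[j]
    G: np.ndarray  # (n,) int, genes per genome

    def index_of(self, genome_id: str) -> int:
        try:
            return self.genome_ids.index(genome_id)
        except ValueError:
            raise KeyError(f"genome {genome_id!r} not in matrix") from None

    def fraction(self, row_genome: str, col_genome: str) -> float:
        return float(self.F[self.index_of(row_genome), self.index_of(col_genome)])

    def reorder(self, order: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns permuted into ``order``."""
        if sorted(order) != sorted(self.genome_ids):
            missing = set(self.genome_ids) ^ set(order)
            raise ValueError(
                f"order is not a permutation of the matrix genomes; "
                f"mismatch: {sorted(missing)}"
            )
        idx = [self.genome_ids.index(g) for g in order]
        return SimilarityMatrix(
            genome_ids=list(order),
            S=self.S[np.ix_(idx, idx)].copy(),
            F=self.F[np.ix_(idx, idx)].copy(),
            G=self.G[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=self.genome_ids, columns=self.genome_ids)


def shared_gene_count(hgs: HomologGroupSet, a: str, b: str) -> int:
    """Min-copy shared gene count between genomes ``a`` and ``b``.

    Sums min(copies_a, copies_b) over all homolog groups.  Groups private to
    one genome contribute 0; singleton genes are invisible to the group set
    and contribute nothing.
    """
    if a == b:
        raise ValueError("shared_gene_count is defined for distinct genomes")
    known = hgs.genomes
    for g in (a, b):
        if g not in known:
            raise KeyError(f"genome {g!r} has no genes in the homolog group set")
    total = 0
    for group_id in hgs.groups_of_genome(a):
        cb = hgs.copies(group_id, b)
        if cb:
            total += min(hgs.copies(group_id, a), cb)
    return total


def similarity_matrix(
    hgs: HomologGroupSet, genomes: Sequence[Genome]
) -> SimilarityMatrix:
    """Compute the full S and F matrices for a genome set.

    The diagonal of F is fixed at 1.0 by definition rather than computed
    from groups (group sets omit singleton genes, so a computed
    self-similarity would be artifactually below 1); S[i][i] = G_i.
    """
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_ids in genome list")
    G = np.array([g.G for g in genomes], dtype=int)
    if (G == 0).any():
        empty = [gid for gid, n in zip(ids, G) if n == 0]
        raise ValueError(f"genomes with zero genes (division undefined): {empty}")
    n = len(ids)
    S = np.zeros((n, n), dtype=int)
    grouped = [hgs.groups_of_genome(gid) for gid in ids]
    for i in range(n):
        S[i, i] = G[i]
        for j in range(i + 1, n):
            total = 0
            for group_id in grouped[i] & grouped[j]:
                total += min(hgs.copies(group_id, ids[i]), hgs.copies(group_id, ids[j]))
            S[i, j] = S[j, i] = total
    F = S / G[np.newaxis, :]  # column j divided by G_j
    np.fill_diagonal(F, 1.0)
    return SimilarityMatrix(genome_ids=ids, S=S, F=F, G=G)


def write_heatmap_table(
    m: SimilarityMatrix,
    path: str | Path,
    order: Sequence[str] | None = None,
    png: str | Path | None = None,
) -> None:
    """Write the fraction matrix as TSV (and optionally a PNG heatmap).

    ``order`` — e.g. the leaf order of a ribosomal-protein tree — must be a
    permutation of the matrix's genomes; both axes use it.
    """
    mm = m.reorder(order) if order is not None else m
    df = mm.to_frame()
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="genome")
    if png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mm.F, cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(mm.genome_ids)), mm.genome_ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(mm.genome_ids)), mm.genome_ids, fontsize=6)
        fig.colorbar(im, ax=ax, label="shared genes / column genome size")
        fig.tight_layout()
        fig.savefig(png, dpi=150)
        plt.close(fig)


def read_heatmap_table(path: str | Path) -> pd.DataFrame:
    """Re-read a fraction-matrix TSV written by :func:`write_heatmap_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)
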