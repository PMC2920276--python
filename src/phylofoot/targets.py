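"""Selection of a group of target genomes.

Prokaryotic cis-regulatory systems evolve too fast for sequence-based
phylogenies to track them, so genomes are compared by the repertoire of
transcription-factor families they encode: each genome is a presence/absence
bit vector over TF families, pairwise Hamming distances feed a
neighbor-joining tree, and the target group is the largest clade around a
seed genome in which every pair of genomes still shares at least half of
their TFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "TFPresenceMatrix",
    "read_tf_table",
    "tf_presence_matrix",
    "hamming_matrix",
    "neighbor_joining",
    "shared_tf_fraction",
    "select_target_group",
]


@dataclass
class TFPresenceMatrix:
    genomes: list[str]
    tf_families: list[str]
    bits: np.ndarray  # (n_genomes, n_families) of 0/1

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome ids")
        if len(set(self.tf_families)) != len(self.tf_families):
            raise ValueError("duplicate TF family ids")
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    def tf_set(self, genome_id: str) -> set[str]:
        row = self.bits[self.genomes.index(genome_id)]
        return {f for f, b in zip(self.tf_families, row) if b}


def read_tf_table(path) -> pd.DataFrame:
    """Read a (genome_id, tf_family_id) pair TSV with a '#'-header line."""
    from .genome import _read_tsv

    return _read_tsv(path, ["genome_id", "tf_family_id"])


def tf_presence_matrix(tf_table: pd.DataFrame, genome_ids: list[str]) -> TFPresenceMatrix:
    """Bit matrix over the given genomes from a (genome, family) pair table.

    A genome absent from the table gets an all-zero row with a warning.
    """
    families = sorted(tf_table["tf_family_id"].unique())
    fam_index = {f: j for j, f in enumerate(families)}
    bits = np.zeros((len(genome_ids), len(families)), dtype=np.int8)
    present = set(tf_table["genome_id"])
    for i, g in enumerate(genome_ids):
        if g not in present:
            warnings.warn(f"genome {g} absent from TF table; all-zero row")
    for g, f in zip(tf_table["genome_id"], tf_table["tf_family_id"]):
        if g in genome_ids:
            bits[genome_ids.index(g), fam_index[f]] = 1
    return TFPresenceMatrix(list(genome_ids), families, bits)


def hamming_matrix(m: TFPresenceMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise Hamming distances (count of differing TF families)."""
    b = m.bits.astype(np.int32)
    d = np.abs(b[:, None, :] - b[None, :, :]).sum(axis=2)
    return list(m.genomes), d.astype(float)


def neighbor_joining(ids: list[str], d: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining, deterministic given input order.

    Ties in the Q criterion break toward the smallest (i, j) index pair;
    negative branch lengths are clamped to zero. Returns an unrooted tree
    as a scikit-bio ``TreeNode`` (trifurcating root).
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 0:
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [TreeNode(name=i) for i in ids]
    d = d.copy()
    active = list(range(n))  # indices into rows of d; stable order

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair on ties: lexicographic scan over the upper triangle
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lb = dij - la
        parent = TreeNode()
        ca, cb = nodes[active[a]], nodes[active[b]]
        ca.length = max(0.0, la)
        cb.length = max(0.0, lb)
        parent.extend([ca, cb])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for k_pos, k in enumerate(active):
            if k_pos in (a, b):
                continue
            new_row[k] = 0.5 * (sub[a, k_pos] + sub[b, k_pos] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        hi, lo = max(a, b), min(a, b)
        del active[hi], active[lo]
        active.append(d.shape[0] - 1)

    a, b, c = active
    root = TreeNode()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        child = nodes[x]
        child.length = max(0.0, 0.5 * (d[x, y] + d[x, z] - d[y, z]))
        root.append(child)
    return root


def shared_tf_fraction(g1: str, g2: str, m: TFPresenceMatrix) -> float:
    """Fraction of TF families shared by two genomes.

    |TF(g1) ∩ TF(g2)| divided by the smaller repertoire size — the
    conservative, symmetric reading of "shares at least 50% of its TFs".
    """
    s1, s2 = m.tf_set(g1), m.tf_set(g2)
    if not s1 or not s2:
        warnings.warn(f"empty TF set for {g1 if not s1 else g2}; fraction defined as 1")
        return 1.0
    return len(s1 & s2) / min(len(s1), len(s2))


def select_target_group(
    tree: TreeNode, m: TFPresenceMatrix, seed_genome: str, min_shared: float = 0.5
) -> set[str]:
    """Largest clade around ``seed_genome`` whose genomes all pairwise share
    at least ``min_shared`` of their TFs.

    The tree is midpoint-rooted and candidate groups are the nested clades on
    the walk from the seed leaf toward the root; the walk stops before the
    first clade containing a violating pair.
    """
    names = {t.name for t in tree.tips()}
    if seed_genome not in names:
        raise ValueError(f"seed {seed_genome} not in tree")
    rooted = tree.copy()
    try:
        rooted = rooted.root_at_midpoint()
    except Exception:  # zero-length or degenerate trees: keep given rooting
        pass

    def ok(group: set[str]) -> bool:
        gs = sorted(group)
        return all(
            shared_tf_fraction(a, b, m) >= min_shared
            for i, a in enumerate(gs)
            for b in gs[i + 1:]
        )

    node = next(t for t in rooted.tips() if t.name == seed_genome)
    best = {seed_genome}
    while node is not None:
        clade = {t.name for t in node.tips()} or {node.name}
        if not ok(clade):
            break
        best = clade
        node = node.parent
    return best
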