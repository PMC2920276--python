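"""Motif representation and the motif–motif similarity metric.

A motif is a set of equal-length aligned sites summarized by

* a frequency matrix ``F`` of per-column base counts,
* a column probability matrix ``p(b, i) = (f(b, i) + δ·q(b)) / (n + δ)``
  with pseudocount mass δ spread by background composition, and
* a profile matrix ``P(b, i) = log2(p(b, i) / q(b))`` — the standard
  position-specific log-odds against the background ``q``.

Two motifs are compared by scoring the profile of one against the column
base proportions of the other over every ungapped offset in both
orientations. A column is *aligned* when its cross-score exceeds a
threshold τ; among the offsets achieving the maximum number of aligned
columns, the score is the aligned-column cross-score total normalized by
the maximum attainable total, so a perfect match scores 1. The symmetric
similarity is the mean of the two directional scores, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Site, reverse_complement

__all__ = [
    "BackgroundModel",
    "Motif",
    "frequency_matrix",
    "profile_matrix",
    "information_content",
    "alignment_score",
    "directional_score",
    "motif_similarity",
    "pairwise_similarity",
    "write_meme",
    "read_meme",
    "DEFAULT_COLUMN_THRESHOLD",
]

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G

# Per-column cross-score threshold τ of the alignment rule: a column counts
# as aligned only when its cross-score exceeds one bit (half the DNA maximum).
# Calibrated by simulation (see docs/methods.md): at τ = 1.0, >99% of random
# 16-mer motif pairs (5 sites each, uniform background) score below 0.2, and
# pairs of unrelated sampler-derived footprinting motifs — which share
# low-complexity structure and score far above truly random pairs — fall
# below the G1 cutoff range while within-regulon pairs stay well above it.
DEFAULT_COLUMN_THRESHOLD = 1.0


@dataclass(frozen=True)
class BackgroundModel:
    """Base composition of the background sequences."""

    q: np.ndarray  # (4,) probabilities for A, C, G, T

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,) or (q <= 0).any() or not np.isclose(q.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        object.__setattr__(self, "q", q)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, seqs) -> "BackgroundModel":
        """Composition of the given sequences and their reverse complements
        (hence strand-symmetric); N bases are ignored."""
        counts = np.ones(4)  # one pseudo-observation per base
        for s in seqs:
            for c in s.upper():
                i = _INDEX.get(c)
                if i is not None:
                    counts[i] += 1
                    counts[_COMP[i]] += 1
        return cls(counts / counts.sum())


def encode(seq: str) -> np.ndarray:
    return np.array([_INDEX[c] for c in seq], dtype=np.int8)


def frequency_matrix(
    sites: list[Site] | list[str], background: BackgroundModel, delta: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base counts F and pseudocounted probabilities p.

    ``p(b, i) = (f(b, i) + δ·q(b)) / (n + δ)``. Sites must be equal-length
    and N-free (sites containing N are discarded before motif construction).
    """
    seqs = [s.seq if isinstance(s, Site) else s for s in sites]
    if not seqs:
        raise ValueError("zero sites")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sites have unequal lengths")
    if any("N" in s for s in seqs):
        raise ValueError("sites containing N must be discarded before motif construction")
    codes = np.stack([encode(s) for s in seqs])  # (n, L)
    F = np.zeros((4, L))
    for b in range(4):
        F[b] = (codes == b).sum(axis=0)
    n = len(seqs)
    p = (F + delta * background.q[:, None]) / (n + delta)
    return F, p


def profile_matrix(p: np.ndarray, background: BackgroundModel) -> np.ndarray:
    """Log-odds profile ``P(b, i) = log2(p(b, i) / q(b))``."""
    return np.log2(p / background.q[:, None])


@dataclass
class Motif:
    """A set of aligned sites with its derived matrices."""

    id: str
    sites: list[Site]
    background: BackgroundModel
    delta: float = 1.0
    origin: tuple = ()  # (coor_id, finder, rank) or a stage tag
    F: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.F, self.p = frequency_matrix(self.sites, self.background, self.delta)
        self.P = profile_matrix(self.p, self.background)

    @property
    def width(self) -> int:
        return self.F.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def fhat(self) -> np.ndarray:
        """Column base proportions (counts / n, no pseudocount)."""
        return self.F / self.n_sites

    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.p.argmax(axis=0))

    def reverse_complement(self) -> "Motif":
        rc_sites = [
            Site(genome_id=s.genome_id, start=s.start, end=s.end,
                 strand="-" if s.strand == "+" else "+",
                 seq=reverse_complement(s.seq), source=s.source)
            for s in self.sites
        ]
        return Motif(id=self.id + "_rc", sites=rc_sites, background=self.background,
                     delta=self.delta, origin=self.origin)


def information_content(motif: Motif, background: BackgroundModel | None = None) -> float:
    """Total information content Σ_i Σ_b p(b,i)·log2(p(b,i)/q(b)) in bits."""
    q = (background or motif.background).q
    return float((motif.p * np.log2(motif.p / q[:, None])).sum())


def _rc_matrices(P, fhat, maxc):
    return P[_COMP][:, ::-1], fhat[_COMP][:, ::-1], maxc[::-1]


def alignment_score(
    P_x: np.ndarray,
    fhat_y: np.ndarray,
    offset: int,
    tau: float = DEFAULT_COLUMN_THRESHOLD,
) -> tuple[int, float]:
    """Score one ungapped offset of motif y's frequencies against motif x's
    profile.

    Column ``i`` of x pairs with column ``i - offset`` of y. Returns the
    number of aligned columns (per-column cross-score > τ) and the score:
    the aligned-column cross-score total normalized by the maximum score
    attainable by the whole profile (Σ_i max_b P_x(b, i) over ALL columns
    of x, which a full-width perfect match achieves), so chance agreements
    over partial overlaps stay small.
    """
    Lx, Ly = P_x.shape[1], fhat_y.shape[1]
    lo, hi = max(0, offset), min(Lx, Ly + offset)
    if hi <= lo:
        raise ValueError("offset gives no overlap")
    xc = slice(lo, hi)
    yc = slice(lo - offset, hi - offset)
    c = (P_x[:, xc] * fhat_y[:, yc]).sum(axis=0)
    aligned = c > tau
    n_cols = int(aligned.sum())
    if n_cols == 0:
        return 0, 0.0
    den = P_x.max(axis=0).sum()  # max_b P >= 0 per column, so den >= 0
    if den <= 0:
        return n_cols, 0.0
    return n_cols, float(c[aligned].sum() / den)


def directional_score(
    P_x: np.ndarray, fhat_y: np.ndarray, tau: float = DEFAULT_COLUMN_THRESHOLD
) -> float:
    """s(P_x, F_y): over all ungapped offsets, restrict to those with the
    maximum number of aligned columns and return the best normalized score
    among them (ties resolved toward the smallest offset).

    All offsets are scored in one vectorized pass; ``alignment_score`` is
    the single-offset reference this must agree with.
    """
    Lx, Ly = P_x.shape[1], fhat_y.shape[1]
    n_off = Lx + Ly - 1
    pad = np.zeros((4, Lx - 1)) if Lx > 1 else np.zeros((4, 0))
    fy = np.concatenate([pad, fhat_y, pad], axis=1)
    # offset o (from -(Ly-1) to Lx-1): x column i pairs y column i-o
    offsets = np.arange(-(Ly - 1), Lx)  # ascending
    idx = np.arange(Lx)[None, :] - offsets[:, None] + (Lx - 1)
    valid = (idx >= Lx - 1) & (idx < Lx - 1 + Ly)
    c = np.einsum("bi,boi->oi", P_x, fy[:, idx], optimize=True)
    aligned = (c > tau) & valid
    n_cols = aligned.sum(axis=1)
    den = P_x.max(axis=0).sum()
    if den <= 0:
        return 0.0
    scores = np.where(aligned, c, 0.0).sum(axis=1) / den
    scores[n_cols == 0] = 0.0
    best = int(max(range(n_off), key=lambda o: (n_cols[o], scores[o], -o)))
    return float(scores[best]) if n_cols[best] > 0 else 0.0


def motif_similarity(
    M_x: Motif, M_y: Motif, tau: float = DEFAULT_COLUMN_THRESHOLD
) -> float:
    """Symmetric similarity S(M_x, M_y) ∈ [0, 1].

    S = ½·[s(P_x, F_y) + s(P_y, F_x)], evaluated for both the forward and
    the reverse-complement orientation of M_y, keeping the larger value.
    """
    Px, fx = M_x.P, M_x.fhat
    Py, fy = M_y.P, M_y.fhat
    maxc_y = Py.max(axis=0)
    s_fwd = 0.5 * (directional_score(Px, fy, tau) + directional_score(Py, fx, tau))
    Py_rc, fy_rc, _ = _rc_matrices(Py, fy, maxc_y)
    s_rev = 0.5 * (directional_score(Px, fy_rc, tau) + directional_score(Py_rc, fx, tau))
    return float(np.clip(max(s_fwd, s_rev), 0.0, 1.0))


def _directional_matrix(
    P: np.ndarray, maxc: np.ndarray, fhat: np.ndarray, tau: float, block: int = 256
) -> np.ndarray:
    """s(P_i, F_j) for all pairs of equal-width motifs, blocked over rows.

    P, fhat: (N, 4, L); maxc: (N, L). Returns (N, N).
    """
    N, _, L = P.shape
    out = np.zeros((N, N))
    for start in range(0, N, block):
        sl = slice(start, min(start + block, N))
        Pb = P[sl]
        mb = maxc[sl]
        best_n = np.full((Pb.shape[0], N), -1, dtype=np.int16)
        best_s = np.zeros((Pb.shape[0], N))
        for offset in range(-(L - 1), L):
            lo, hi = max(0, offset), min(L, L + offset)
            xc = slice(lo, hi)
            yc = slice(lo - offset, hi - offset)
            c = np.einsum("xbi,ybi->xyi", Pb[:, :, xc], fhat[:, :, yc], optimize=True)
            aligned = c > tau
            n = aligned.sum(axis=2, dtype=np.int16)
            num = np.where(aligned, c, 0.0).sum(axis=2)
            den = mb.sum(axis=1)[:, None]  # full-width maximum per x profile
            s = np.where((n > 0) & (den > 0), num / np.maximum(den, 1e-12), 0.0)
            better = (n > best_n) | ((n == best_n) & (s > best_s))
            best_n = np.where(better, n, best_n)
            best_s = np.where(better, s, best_s)
        out[sl] = best_s
    return out


def pairwise_similarity(
    motifs: list[Motif], tau: float = DEFAULT_COLUMN_THRESHOLD
) -> np.ndarray:
    """All-pairs similarity matrix.

    Equal-width motif pools (the input-motif stage) use a vectorized blocked
    computation; mixed widths fall back to the per-pair metric.
    """
    N = len(motifs)
    widths = {m.width for m in motifs}
    if len(widths) == 1 and N > 2:
        P = np.stack([m.P for m in motifs])
        fhat = np.stack([m.fhat for m in motifs])
        maxc = P.max(axis=1)
        s_fwd = _directional_matrix(P, maxc, fhat, tau)
        P_rc = P[:, _COMP, ::-1]
        fhat_rc = fhat[:, _COMP, ::-1]
        t = _directional_matrix(P, maxc, fhat_rc, tau)
        # s(P_rc(y), F_x) = s(P_y, F_rc(x)) by relabeling, i.e. t transposed
        S = np.maximum(0.5 * (s_fwd + s_fwd.T), 0.5 * (t + t.T))
        return np.clip(S.astype(float), 0.0, 1.0)
    S = np.zeros((N, N))
    for i in range(N):
        S[i, i] = motif_similarity(motifs[i], motifs[i], tau)
        for j in range(i + 1, N):
            S[i, j] = S[j, i] = motif_similarity(motifs[i], motifs[j], tau)
    return S


def write_meme(path, motifs: list[Motif], background: BackgroundModel) -> None:
    """Write motifs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {q:.3f}" for b, q in zip(BASES, background.q)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= {m.n_sites}\n"
            )
            for col in m.p.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[tuple[str, np.ndarray]]:
    """Read a MEME minimal motif file; returns (motif id, column probability
    matrix of shape (4, w)) tuples."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF"):
            mid = line.split()[1]
            while not lines[i].startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(i + 1, i + 1 + w):
                rows.append([float(v) for v in lines[j].split()])
            out.append((mid, np.array(rows).T))
            i += w
        i += 1
    return out
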