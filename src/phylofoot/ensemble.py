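"""Ensemble motif finding over COOR sequence sets.

Phylogenetic footprinting works best when several motif finders each
contribute their top predictions: true sites tend to be found repeatedly
while spurious calls rarely recur. Finders are plugged in through the
:class:`FinderAdapter` contract; the default adapter is a built-in Gibbs
sampler, and external tools (MEME, BioProspector, ...) can be wired in via
subprocess adapters without the pipeline ever requiring them.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import Site, reverse_complement
from .motifs import BackgroundModel, Motif, information_content
from .orthology import SequenceSet

__all__ = [
    "FinderAdapter",
    "BuiltinGibbsSampler",
    "EnsembleConfig",
    "run_ensemble",
    "collect_input_motifs",
    "stable_seed",
]

log = logging.getLogger(__name__)

_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def stable_seed(global_seed: int, *tags: str) -> int:
    """Deterministic per-(tag...) seed below 2^31."""
    h = zlib.crc32("/".join(tags).encode())
    return (int(global_seed) * 1_000_003 + h) % (2**31 - 1)


class FinderAdapter:
    """Contract for a motif finder.

    ``find`` returns at most ``n_results`` motifs ordered best-first, each
    with at least two sites drawn from the input sequences, deterministically
    given ``seed``. ``fixed_width`` adapters honour the requested width;
    auto-range adapters may choose a width inside the requested range.
    """

    name: str = "adapter"
    fixed_width: bool = True

    def find(self, sequences: list[Site], width: int, n_results: int, seed: int) -> list[Motif]:
        raise NotImplementedError

    def find_auto(
        self, sequences: list[Site], widths: range, n_results: int, seed: int,
        width_step: int = 1,
    ) -> list[Motif]:
        raise NotImplementedError


def _window_site(entry: Site, pos: int, width: int, window_strand: str) -> Site:
    """Genomic Site of a width-window at ``pos`` of ``entry.seq`` (forward)
    or of its reverse complement (``window_strand`` '-')."""
    seq = entry.seq if window_strand == "+" else reverse_complement(entry.seq)
    sub = seq[pos: pos + width]
    # orientation of the window relative to the genome
    flip = (entry.strand == "-") != (window_strand == "-")
    strand = "-" if flip else "+"
    if entry.strand == "+":
        if window_strand == "+":
            gstart = entry.start + pos
        else:
            gstart = entry.end - pos - width
    else:
        if window_strand == "+":
            gstart = entry.end - pos - width
        else:
            gstart = entry.start + pos
    return Site(genome_id=entry.genome_id, start=gstart, end=gstart + width,
                strand=strand, seq=sub, source=entry.source)


@dataclass
class _SeqWindows:
    entry: Site
    codes: np.ndarray        # (n_windows, width) int8
    meta: list[tuple[int, str]]  # (pos, window_strand)


def _windows(entry: Site, width: int) -> _SeqWindows | None:
    seqs = {"+": entry.seq, "-": reverse_complement(entry.seq)}
    codes, meta = [], []
    for strand in "+-":
        s = seqs[strand]
        enc = np.array([_INDEX.get(c, -1) for c in s], dtype=np.int8)
        for pos in range(len(s) - width + 1):
            win = enc[pos: pos + width]
            if (win >= 0).all():  # windows containing N are unusable
                codes.append(win)
                meta.append((pos, strand))
    if not codes:
        return None
    return _SeqWindows(entry=entry, codes=np.stack(codes), meta=meta)


class BuiltinGibbsSampler(FinderAdapter):
    """Site-sampling Gibbs motif search (one site per sequence, both strands).

    Random restarts, per-sequence resampling proportional to the PWM
    likelihood ratio, best restart kept by total information content.
    Subsequent results come from re-runs with previously found windows
    masked out.
    """

    fixed_width = False

    def __init__(self, name: str = "gibbs", restarts: int = 3, iterations: int = 40,
                 delta: float = 1.0):
        self.name = name
        self.restarts = restarts
        self.iterations = iterations
        self.delta = delta

    # -- single search ----------------------------------------------------
    def _search(
        self,
        sw: list[_SeqWindows],
        banned: list[np.ndarray],
        width: int,
        q: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[float, list[tuple[int, int]]] | None:
        """One full Gibbs search; returns (score, [(seq index, window index)])."""
        usable = [i for i, b in enumerate(banned) if (~b).any()]
        if len(usable) < 2:
            return None
        ar = np.arange(width)
        log2q = np.log2(q)[:, None]
        best_score, best_assign = -np.inf, None
        for _ in range(self.restarts):
            choice = {}
            for i in usable:
                ok = np.flatnonzero(~banned[i])
                choice[i] = int(ok[rng.integers(len(ok))])
            counts = np.zeros((4, width))
            for i in usable:
                counts[sw[i].codes[choice[i]], ar] += 1  # column indices unique
            n_here = len(usable) - 1
            for _sweep in range(self.iterations):
                changed = False
                for i in usable:
                    counts[sw[i].codes[choice[i]], ar] -= 1
                    logodds = np.log2(counts + self.delta * q[:, None]) \
                        - np.log2(n_here + self.delta) - log2q
                    scores = logodds[sw[i].codes, ar].sum(axis=1)
                    scores[banned[i]] = -np.inf
                    prob = np.exp2(np.clip(scores - scores.max(), -30, 0))
                    cum = np.cumsum(prob)
                    new = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                    new = min(new, len(cum) - 1)
                    if new != choice[i]:
                        changed = True
                    choice[i] = new
                    counts[sw[i].codes[new], ar] += 1
                if not changed and _sweep >= 2:
                    break
            # greedy polish: move each site to its best window
            for i in usable:
                counts[sw[i].codes[choice[i]], ar] -= 1
                logodds = np.log2(counts + self.delta * q[:, None]) \
                    - np.log2(n_here + self.delta) - log2q
                scores = logodds[sw[i].codes, ar].sum(axis=1)
                scores[banned[i]] = -np.inf
                choice[i] = int(scores.argmax())
                counts[sw[i].codes[choice[i]], ar] += 1
            n = len(usable)
            p = (counts + self.delta * q[:, None]) / (n + self.delta)
            score = float((p * np.log2(p / q[:, None])).sum())
            if score > best_score:
                best_score = score
                best_assign = [(i, choice[i]) for i in usable]
        if best_assign is None:
            return None
        return best_score, best_assign

    def find(self, sequences: list[Site], width: int, n_results: int, seed: int) -> list[Motif]:
        if any(len(s) < width for s in sequences):
            raise ValueError("every sequence must be at least as long as the motif width")
        sw = [w for w in (_windows(s, width) for s in sequences) if w is not None]
        if len(sw) < 2:
            return []
        q = BackgroundModel.from_sequences([s.seq for s in sequences])
        rng = np.random.default_rng(seed)
        banned = [np.zeros(len(w.meta), dtype=bool) for w in sw]
        motifs = []
        for rank in range(n_results):
            res = self._search(sw, banned, width, q.q, rng)
            if res is None:
                break
            score, assign = res
            sites = []
            for i, widx in assign:
                pos, strand = sw[i].meta[widx]
                sites.append(_window_site(sw[i].entry, pos, width, strand))
            if len(sites) < 2:
                break
            motifs.append(
                Motif(id=f"{self.name}_r{rank}", sites=sites, background=q,
                      origin=(self.name, rank))
            )
            # mask: ban windows overlapping a found site by more than half width
            found = {(s.genome_id, s.start, s.end) for s in sites}
            for i, w in enumerate(sw):
                starts = np.array([
                    _site_start(w.entry, pos, width, strand) for pos, strand in w.meta
                ])
                for gid, fs, fe in found:
                    if w.entry.genome_id != gid:
                        continue
                    ov = np.minimum(starts + width, fe) - np.maximum(starts, fs)
                    banned[i] |= ov > width // 2
        return motifs

    def find_auto(
        self, sequences: list[Site], widths: range, n_results: int, seed: int,
        width_step: int = 1,
    ) -> list[Motif]:
        """Best motif per width, ranked by information content in excess of a
        same-size random baseline; returns the overall top ``n_results``."""
        candidates = []
        for k, width in enumerate(widths[::width_step]):
            if all(len(s) >= width for s in sequences):
                found = self.find(sequences, width, 1, stable_seed(seed, f"w{width}"))
                for m in found:
                    baseline = _random_ic_baseline(m.n_sites, width, self.delta)
                    candidates.append((information_content(m) - baseline, k, m))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        return [m for _, _, m in candidates[:n_results]]


def _site_start(entry: Site, pos: int, width: int, window_strand: str) -> int:
    if entry.strand == "+":
        return entry.start + pos if window_strand == "+" else entry.end - pos - width
    return entry.end - pos - width if window_strand == "+" else entry.start + pos


def _random_ic_baseline(n: int, width: int, delta: float) -> float:
    """Expected total IC of a motif of n uniform-random sites (analytic
    chi-square approximation per column, shrunk by the pseudocount)."""
    per_col = 3.0 / (2.0 * np.log(2) * max(n, 2)) * (n / (n + delta)) ** 2
    return float(per_col * width)


@dataclass
class EnsembleConfig:
    """Which finders fill which slots, and at what motif width.

    The default emulates a five-tool ensemble contributing 15+10+5+5+5 = 40
    input motifs of width 16 per sequence set, with the built-in sampler
    standing in every slot.
    """

    slots: list[tuple[FinderAdapter, int]] = field(default_factory=lambda: [
        (BuiltinGibbsSampler(name=f"gibbs{i}"), k)
        for i, k in enumerate((15, 10, 5, 5, 5))
    ])
    width: int = 16
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(k for _, k in self.slots)


def run_ensemble(seq_set: SequenceSet, config: EnsembleConfig) -> list[Motif]:
    """All slot adapters' top-k motifs for one COOR sequence set, tagged with
    (coor id, finder name, rank). A failing adapter is logged and skipped."""
    sequences = [site for _, site in seq_set.entries]
    out = []
    for adapter, top_k in config.slots:
        seed = stable_seed(config.seed, seq_set.coor_id, adapter.name)
        try:
            found = adapter.find(sequences, config.width, top_k, seed)
        except Exception as exc:  # adapter failure must not sink the set
            log.warning("adapter %s failed on %s: %s", adapter.name, seq_set.coor_id, exc)
            continue
        for rank, m in enumerate(found):
            m.id = f"{seq_set.coor_id}|{adapter.name}|{rank}"
            m.origin = (seq_set.coor_id, adapter.name, rank)
            out.append(m)
    return out


def collect_input_motifs(
    sets: list[SequenceSet], config: EnsembleConfig
) -> list[Motif]:
    """The flat collection of input motifs over all COOR sequence sets."""
    motifs = []
    for ss in sets:
        motifs.extend(run_ensemble(ss, config))
    return motifs
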