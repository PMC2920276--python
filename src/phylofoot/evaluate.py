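"""Recovery, specificity and saturation statistics.

Predictions are judged against a table of known sites: a known site is
*recovered* when some predicted site on the same genome overlaps it by at
least 9 bases (the package's one overlap convention: "more than eight"),
and a known motif is recovered by a cluster when the cluster holds at
least 20% of the motif's known sites. Uniqueness of predictions uses the
same more-than-eight-bases rule, transitively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome import KnownSiteTable, Site
from .clustering import ScoredCluster

__all__ = [
    "site_recovered",
    "recovery_percent",
    "motif_recovered",
    "unique_site_count",
    "lower_bound_specificity",
    "RecoveryReport",
    "recovery_report",
    "cumulative_curves",
    "saturation_rank",
    "enrichment_pvalue",
]


def site_recovered(predicted: Site, known: Site, min_overlap: int = 9) -> bool:
    """Same genome and genomic overlap of at least ``min_overlap`` bases
    (strand-agnostic)."""
    return predicted.overlap(known) >= min_overlap


def _any_recovered(known: Site, predicted: list[Site], min_overlap: int = 9) -> bool:
    return any(site_recovered(p, known, min_overlap) for p in predicted)


def recovery_percent(n_recovered: int, n_total: int) -> int:
    """Integer percent, rounded half-up (printing convention)."""
    if not 0 <= n_recovered <= n_total or n_total <= 0:
        raise ValueError("need 0 <= n_recovered <= n_total with n_total > 0")
    return int(np.floor(100.0 * n_recovered / n_total + 0.5))


def motif_recovered(
    cluster_sites: list[Site], known_motif_sites: list[Site],
    frac: float = 0.2, min_overlap: int = 9,
) -> bool:
    """A known motif counts as recovered by a cluster when at least ``frac``
    of its known sites are recovered by the cluster's sites."""
    if not known_motif_sites:
        raise ValueError("known motif with no sites")
    hits = sum(_any_recovered(k, cluster_sites, min_overlap) for k in known_motif_sites)
    return hits >= frac * len(known_motif_sites)


def unique_site_count(sites: list[Site], overlap_threshold: int = 8) -> int:
    """Number of equivalence classes of sites under transitive grouping of
    same-genome pairs overlapping by more than ``overlap_threshold`` bases."""
    by_genome: dict[str, list[Site]] = {}
    for s in sites:
        by_genome.setdefault(s.genome_id, []).append(s)
    count = 0
    for group in by_genome.values():
        group.sort(key=lambda s: (s.start, s.end))
        cur_end = None
        cur_start = None
        for s in group:
            if cur_end is None:
                cur_start, cur_end = s.start, s.end
                count += 1
            elif min(cur_end, s.end) - max(cur_start, s.start) > overlap_threshold:
                cur_end = max(cur_end, s.end)
            else:
                cur_start, cur_end = s.start, s.end
                count += 1
    return count


def lower_bound_specificity(n_known_recovered: int, n_unique_predicted: int) -> int:
    """Predicted known sites over unique predicted sites, as an integer
    percent — a lower bound because unknown true sites count against it."""
    if n_unique_predicted <= 0:
        raise ValueError("no predictions")
    return int(np.floor(100.0 * n_known_recovered / n_unique_predicted + 0.5))


@dataclass
class RecoveryReport:
    """Funnel of known-site counts through the pipeline stages."""

    known_sites_total: int
    known_sites_extracted: int
    known_sites_footprint: int
    known_sites_clustered: int
    known_motifs_total: int
    known_motifs_recovered: int

    def __post_init__(self) -> None:
        funnel = (self.known_sites_total, self.known_sites_extracted,
                  self.known_sites_footprint, self.known_sites_clustered)
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise ValueError("recovery funnel must be non-increasing")


def recovery_report(
    known: KnownSiteTable,
    extracted_regions: list[Site],
    input_sites: list[Site],
    cluster_sites: list[Site],
    min_overlap: int = 9,
) -> RecoveryReport:
    """Count known sites surviving each stage: inside the extracted upstream
    regions, recovered by the footprinting input motifs, recovered by the
    final clusters — and known motifs recovered overall."""
    all_known = known.all_sites()
    in_regions = [k for k in all_known if _any_recovered(k, extracted_regions, min(min_overlap, len(k)))]
    by_footprint = [k for k in in_regions if _any_recovered(k, input_sites, min_overlap)]
    by_cluster = [k for k in by_footprint if _any_recovered(k, cluster_sites, min_overlap)]
    motifs = known.motif_names()
    n_motifs_rec = sum(
        motif_recovered(cluster_sites, known.sites_of(name), min_overlap=min_overlap)
        for name in motifs
    )
    return RecoveryReport(
        known_sites_total=len(all_known),
        known_sites_extracted=len(in_regions),
        known_sites_footprint=len(by_footprint),
        known_sites_clustered=len(by_cluster),
        known_motifs_total=len(motifs),
        known_motifs_recovered=n_motifs_rec,
    )


def cumulative_curves(
    ranked_clusters: list[ScoredCluster],
    known: KnownSiteTable,
    min_overlap: int = 9,
) -> pd.DataFrame:
    """Per-rank cumulative statistics of a genome's ranked clusters.

    Columns: rank, sites_recovered (cumulative known sites recovered),
    motifs_recovered (cumulative known motifs recovered) and unique_sites
    (cumulative unique predicted sites); all monotone non-decreasing."""
    if not ranked_clusters:
        raise ValueError("no clusters")
    all_known = known.all_sites()
    motif_names = known.motif_names()
    rows = []
    pool: list[Site] = []
    for r, cluster in enumerate(sorted(ranked_clusters, key=lambda c: c.rank), start=1):
        pool = pool + cluster.sites
        sites_rec = sum(_any_recovered(k, pool, min_overlap) for k in all_known)
        motifs_rec = sum(
            motif_recovered(pool, known.sites_of(n), min_overlap=min_overlap)
            for n in motif_names
        )
        rows.append({
            "rank": r,
            "sites_recovered": sites_rec,
            "motifs_recovered": motifs_rec,
            "unique_sites": unique_site_count(pool),
        })
    return pd.DataFrame(rows)


def saturation_rank(curve: pd.Series, window: int = 20, epsilon: float = 0.01) -> int:
    """Smallest rank at which the curve enters its saturation phase.

    Saturation is declared when the mean per-rank gain over the next
    ``window`` ranks falls below ``epsilon`` times the current cumulative
    value; returns the last rank if that never happens."""
    values = np.asarray(curve, dtype=float)
    if values.size == 0:
        raise ValueError("empty curve")
    n = len(values)
    for r in range(n):
        upto = min(n - 1, r + window)
        span = upto - r
        if span == 0:
            break
        gain = (values[upto] - values[r]) / span
        if values[r] > 0 and gain < epsilon * values[r]:
            return r + 1
    return n


def enrichment_pvalue(
    n_unique_predicted: int,
    n_known_in_predictions: int,
    n_candidate_sites: int,
    n_known_total: int,
) -> float:
    """Hypergeometric tail probability that drawing ``n_unique_predicted``
    sites from ``n_candidate_sites`` candidates (of which ``n_known_total``
    are known) yields at least ``n_known_in_predictions`` known ones."""
    return float(hypergeom.sf(
        n_known_in_predictions - 1, n_candidate_sites, n_known_total, n_unique_predicted
    ))
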