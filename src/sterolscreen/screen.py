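"""Presence/absence screening of protein clusters against a metabolite call.

Implements the discovery funnel for metabolite-linked enzymes: every cluster
of homologous proteins is scored by how well its detection across samples
predicts a binary metabolite readout (sensitivity and specificity against,
e.g., fecal coprostanol), low-prevalence clusters are dropped, candidates are
filtered at strict sensitivity/specificity cutoffs, and the survivors are
prioritized by homology to proteomes of implicated organisms and to
biochemically characterized enzymes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqcluster import Cluster, SequenceRecord

__all__ = [
    "AssociationScore",
    "QueryHit",
    "score_cluster",
    "screen_clusters",
    "filter_candidates",
    "map_queries",
    "prioritize",
]


@dataclass(frozen=True)
class AssociationScore:
    """Confusion counts of cluster detection vs metabolite detection.

    Sensitivity and specificity are ``nan`` when their denominator is zero
    (no positive or no negative samples), never silently 0.
    """

    cluster_id: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) > 0 else math.nan

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fp) / self.n if self.n > 0 else math.nan


@dataclass(frozen=True)
class QueryHit:
    query_id: str
    cluster_id: str
    member_id: str
    identity: float
    coverage: float


def score_cluster(detected, metabolite, cluster_id: str = "") -> AssociationScore:
    """Confusion counts for one cluster's detection vector vs the metabolite call."""
    det = np.asarray(detected, dtype=bool)
    pos = np.asarray(metabolite, dtype=bool)
    if det.shape != pos.shape:
        raise ValueError(f"length mismatch: {det.shape} vs {pos.shape}")
    if det.size == 0:
        raise ValueError("need at least one paired sample")
    return AssociationScore(
        cluster_id=cluster_id,
        tp=int(np.sum(det & pos)),
        fp=int(np.sum(det & ~pos)),
        tn=int(np.sum(~det & ~pos)),
        fn=int(np.sum(~det & pos)),
    )


def screen_clusters(
    detection: pd.DataFrame,
    calls: pd.Series,
    min_prevalence: float = 0.01,
) -> pd.DataFrame:
    """Score every cluster on the paired-sample intersection.

    Parameters
    ----------
    detection:
        Cluster-by-sample boolean matrix.
    calls:
        Per-sample boolean metabolite detection, indexed by sample id.
        Samples present in only one of the two inputs are excluded
        (intersection semantics).
    min_prevalence:
        Clusters detected in fewer than this fraction of paired samples are
        excluded (the catalog-wide screen keeps clusters with at least 1%
        prevalence by default).

    Returns
    -------
    DataFrame with one row per retained cluster (tp/fp/tn/fn, sensitivity,
    specificity, prevalence), sorted by specificity then sensitivity,
    descending.
    """
    paired = detection.columns.intersection(calls.index)
    if len(paired) == 0:
        raise ValueError("no samples have both metagenomic and metabolomic data")
    det = detection[paired].astype(bool)
    pos = calls.loc[paired].astype(bool)
    rows = []
    for cluster_id in det.index:
        score = score_cluster(det.loc[cluster_id].to_numpy(), pos.to_numpy(), cluster_id)
        if score.prevalence < min_prevalence:
            continue
        rows.append(
            {
                "cluster_id": score.cluster_id,
                "tp": score.tp,
                "fp": score.fp,
                "tn": score.tn,
                "fn": score.fn,
                "sensitivity": score.sensitivity,
                "specificity": score.specificity,
                "prevalence": score.prevalence,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "tp", "fp", "tn", "fn", "sensitivity", "specificity",
                 "prevalence"],
    )
    return table.sort_values(
        ["specificity", "sensitivity"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def filter_candidates(
    scores: pd.DataFrame,
    min_sensitivity: float = 0.3,
    min_specificity: float = 0.9,
) -> pd.DataFrame:
    """Retain clusters with sensitivity and specificity *strictly* above the cutoffs.

    The defaults mirror the >0.3 sensitivity / >0.9 specificity candidate
    definition; rows with undefined ratios are dropped.
    """
    keep = (scores["sensitivity"] > min_sensitivity) & (scores["specificity"] > min_specificity)
    return scores[keep.fillna(False)].reset_index(drop=True)


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


#: Minimal raw local-alignment score for a reportable hit. Like any
#: heuristic homology search, alignments below this floor are not reported;
#: a hit meeting the laxest cutoffs used here (25% identity over half a
#: query) scores well above it, while unrelated protein pairs stay below.
MIN_LOCAL_SCORE = 75.0


def local_alignment_stats(
    query: str, target: str, min_score: float = MIN_LOCAL_SCORE
) -> tuple[float, float]:
    """Best local (Smith-Waterman, BLOSUM62) alignment of query vs target.

    Returns ``(identity, coverage)`` with identity measured over alignment
    columns and coverage as the aligned span of the query over its length,
    mimicking ublast-style reporting. ``(0, 0)`` when no alignment reaches
    ``min_score``.
    """
    aligner = _local_aligner()
    if aligner.score(target, query) < min_score:
        return 0.0, 0.0
    try:
        alignments = aligner.align(target, query)
        if len(alignments) == 0:
            return 0.0, 0.0
        aln = alignments[0]
    except (IndexError, OverflowError):
        return 0.0, 0.0
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return 0.0, 0.0
    identity = counts.identities / columns
    q_segments = aln.aligned[1]
    span = q_segments[-1][1] - q_segments[0][0]
    return identity, span / len(query)


def map_queries(
    queries: list[SequenceRecord],
    clusters: list[Cluster],
    member_sequences: dict[str, SequenceRecord],
    min_identity: float,
    min_coverage: float = 0.5,
) -> list[QueryHit]:
    """Map query proteins onto clusters of homologous proteins.

    A hit is reported per (query, cluster) whose best member alignment meets
    both thresholds; the best member maximizes identity, with ties broken by
    coverage and then lexicographic member id. Typical cutoffs are 50%/50%
    for isolate-proteome queries and the more inclusive 25%/50% for
    characterized-enzyme queries.
    """
    hits: list[QueryHit] = []
    for query in queries:
        for cluster in clusters:
            best: QueryHit | None = None
            for member_id in sorted(cluster.members):
                member = member_sequences[member_id]
                identity, coverage = local_alignment_stats(query.residues, member.residues)
                if identity < min_identity or coverage < min_coverage:
                    continue
                candidate = QueryHit(query.id, cluster.cluster_id, member_id,
                                     identity, coverage)
                if best is None or (candidate.identity, candidate.coverage) > (
                    best.identity, best.coverage
                ):
                    best = candidate
            if best is not None:
                hits.append(best)
    return hits


def prioritize(
    candidates: pd.DataFrame,
    genome_hits: list[QueryHit],
    enzyme_hits: list[QueryHit],
) -> pd.DataFrame:
    """Rank score-passing candidates by converging lines of evidence.

    Tier 1: cluster passes the score filter and is hit by both an
    isolate-proteome query and a characterized-enzyme query; tier 2: exactly
    one hit type; tier 3: score filter only. Within a tier, candidates sort
    by specificity then sensitivity, descending.
    """
    genome_clusters = {h.cluster_id for h in genome_hits}
    enzyme_clusters = {h.cluster_id for h in enzyme_hits}
    report = candidates.copy()
    report["has_genome_hit"] = report["cluster_id"].isin(genome_clusters)
    report["has_enzyme_hit"] = report["cluster_id"].isin(enzyme_clusters)
    n_hits = report["has_genome_hit"].astype(int) + report["has_enzyme_hit"].astype(int)
    report["tier"] = 3 - n_hits
    report = report.sort_values(
        ["tier", "specificity", "sensitivity"],
        ascending=[True, False, False],
        kind="mergesort",
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report
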