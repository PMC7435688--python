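"""Non-redundant catalog construction by greedy identity clustering.

Builds the two clustering stages used for gene-catalog analysis of shotgun
metagenomes: a nucleotide stage (typically >=95% identity / >=90% coverage of
the shorter sequence) that collapses redundant gene predictions, and a protein
stage (strictly >50% amino-acid identity) that groups divergent homologs into
clusters of homologous proteins, treated downstream as one functional unit.
Also provides length-normalized TPM abundances and the cluster-by-sample
detection matrix (a cluster is detected in a sample when any member gene has
TPM > 0).

Identity here follows the CD-HIT convention: identical aligned residues
divided by the length of the *shorter* sequence, measured on a global
affine-gap alignment (match +1, mismatch 0, gap open 10 / extend 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "SequenceRecord",
    "AlignmentIdentity",
    "Cluster",
    "AbundanceMatrix",
    "pairwise_identity",
    "greedy_cluster",
    "compute_tpm",
    "detection_matrix",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NT_ALPHABET = set("ACGTUN")

# Tiny match bonus breaks score ties toward the alignment with the most
# identities, so the reported identity is well defined among co-optimal
# alignments (and matches a lexicographic (score, matches) DP oracle).
_MATCH = 1.0 + 1e-6


@dataclass(frozen=True)
class SequenceRecord:
    """A gene or protein sequence with an optional origin label."""

    id: str
    residues: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentIdentity:
    """Identity and coverage of a pairwise alignment, both over the shorter sequence."""

    identity: float
    coverage_shorter: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage_shorter <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


@dataclass
class Cluster:
    cluster_id: str
    representative: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _MATCH
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _bound_aligner() -> Align.PairwiseAligner:
    # Near-zero gap penalties: the optimal score upper-bounds the number of
    # identical residues achievable under *any* gap scheme (see greedy_cluster).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.01
    aligner.extend_gap_score = -0.01
    return aligner


def _check_alphabet(residues: str, alphabet: str, label: str) -> None:
    allowed = AA_ALPHABET if alphabet == "aa" else NT_ALPHABET
    bad = set(residues.upper()) - allowed
    if bad:
        raise ValueError(
            f"sequence {label!r} contains characters {sorted(bad)} outside the "
            f"{alphabet} alphabet"
        )


def pairwise_identity(a: str, b: str, alphabet: str = "aa") -> AlignmentIdentity:
    """Global-alignment identity and coverage over the shorter sequence.

    Parameters
    ----------
    a, b:
        Sequences in the same alphabet (``"aa"`` or ``"nt"``).

    Returns
    -------
    AlignmentIdentity
        ``identity`` is identical aligned residues / length of the shorter
        sequence; ``coverage_shorter`` is the fraction of the shorter
        sequence's residues aligned opposite residues (not gaps).
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    _check_alphabet(a, alphabet, "a")
    _check_alphabet(b, alphabet, "b")
    aln = _global_aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    shorter = min(len(a), len(b))
    identity = counts.identities / shorter
    coverage = (counts.identities + counts.mismatches) / shorter
    return AlignmentIdentity(identity=min(identity, 1.0), coverage_shorter=min(coverage, 1.0))


def _identity_upper_bound(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    # With gap penalty eps, score* >= M_opt - eps * (gap columns) and gap
    # columns <= len(a) + len(b), so M_opt <= score* + eps * (la + lb).
    score = aligner.score(a, b)
    return (score + 0.01 * (len(a) + len(b))) / min(len(a), len(b))


def greedy_cluster(
    sequences: list[SequenceRecord],
    min_identity: float,
    min_coverage: float,
    alphabet: str = "aa",
    strict: bool = False,
) -> list[Cluster]:
    """Greedy incremental clustering in CD-HIT style.

    Sequences are sorted longest-first (ties broken lexicographically by id);
    each sequence joins the first existing representative it matches at
    ``min_identity`` / ``min_coverage`` (``>=`` by default, strictly ``>``
    when ``strict=True``, matching the protein-stage ">50% aa identity"
    wording), otherwise it founds a new cluster. The output partitions the
    input.

    A conservative prefilter skips the full affine-gap alignment when a cheap
    near-zero-gap-penalty pass proves the identity threshold is unreachable;
    it can never skip a pair that would pass.
    """
    if not (0.0 < min_identity <= 1.0) or not (0.0 < min_coverage <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    ordered = sorted(sequences, key=lambda r: (-r.length, r.id))
    bound = _bound_aligner()

    def passes(x: float, threshold: float) -> bool:
        return x > threshold if strict else x >= threshold

    clusters: list[Cluster] = []
    reps: list[SequenceRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if not passes(_identity_upper_bound(bound, rec.residues, rep.residues), min_identity):
                continue
            aln = pairwise_identity(rec.residues, rep.residues, alphabet=alphabet)
            if passes(aln.identity, min_identity) and passes(aln.coverage_shorter, min_coverage):
                cluster.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(cluster_id=f"cluster_{len(clusters):05d}", representative=rec.id,
                        members=[rec.id])
            )
            reps.append(rec)
    return clusters


@dataclass
class AbundanceMatrix:
    """Gene-by-sample read counts with gene lengths and optional TPM."""

    counts: pd.DataFrame
    lengths: pd.Series
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValueError(f"genes without length information: {missing[:5]}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")


def compute_tpm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Fill the TPM matrix: per-length read rates scaled to one million per sample.

    Samples with no reads at all get an all-zero TPM column rather than a
    division error.
    """
    rates = matrix.counts.div(matrix.lengths, axis=0)
    totals = rates.sum(axis=0)
    scale = pd.Series(np.where(totals > 0, 1e6 / totals.replace(0, np.nan), 0.0),
                      index=totals.index)
    matrix.tpm = rates.mul(scale, axis=1).fillna(0.0)
    return matrix


def detection_matrix(matrix: AbundanceMatrix, clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster-by-sample boolean detection: any member gene with TPM > 0."""
    if matrix.tpm is None:
        matrix = compute_tpm(matrix)
    tpm = matrix.tpm
    rows = {}
    for cluster in clusters:
        missing = [m for m in cluster.members if m not in tpm.index]
        if missing:
            raise KeyError(
                f"cluster {cluster.cluster_id} member gene {missing[0]!r} "
                "is absent from the abundance matrix"
            )
        rows[cluster.cluster_id] = (tpm.loc[cluster.members] > 0).any(axis=0)
    return pd.DataFrame(rows, index=tpm.columns).T


def all_pairs_identity(
    sequences: list[SequenceRecord], alphabet: str = "aa"
) -> dict[tuple[str, str], AlignmentIdentity]:
    """Exhaustive pairwise identities; intended for small inputs and audits."""
    out = {}
    for a, b in itertools.combinations(sequences, 2):
        out[(a.id, b.id)] = pairwise_identity(a.residues, b.residues, alphabet=alphabet)
    return out
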