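#!/usr/bin/env python
"""Cluster the protein catalog and build TPM and detection matrices.

Reads the bundle from results/study/, groups proteins into clusters of
homologous proteins by greedy clustering at strictly >50% amino-acid
identity and >=50% coverage of the shorter sequence, computes per-sample TPM
from the read counts, and derives the cluster-by-sample detection matrix
(any member gene with TPM > 0).
"""

from pathlib import Path

import pandas as pd

from sterolscreen.seqcluster import (
    AbundanceMatrix,
    compute_tpm,
    detection_matrix,
    greedy_cluster,
)
from sterolscreen.simdata import read_study_bundle

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = read_study_bundle(ROOT / "study")
    clusters = greedy_cluster(study.proteins, 0.5, 0.5, alphabet="aa", strict=True)
    matrix = compute_tpm(AbundanceMatrix(study.counts, study.gene_lengths))
    detection = detection_matrix(matrix, clusters)

    out = ROOT / "catalog"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(c.cluster_id, c.representative, m) for c in clusters for m in c.members],
        columns=["cluster_id", "representative", "member"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    matrix.tpm.to_csv(out / "tpm.tsv", sep="\t", index_label="gene")
    detection.astype(int).to_csv(out / "detection.tsv", sep="\t", index_label="cluster")

    sizes = pd.Series([len(c.members) for c in clusters])
    print(f"{len(study.proteins)} proteins -> {len(clusters)} clusters "
          f"(largest {sizes.max()} members, {int((sizes > 1).sum())} multi-member)")
    print(f"wrote clusters.tsv, tpm.tsv, detection.tsv to {out}")


if __name__ == "__main__":
    main()
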