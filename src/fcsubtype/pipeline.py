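"""End-to-end convenience wrappers chaining the pipeline stages.

The canonical flow: simulate (or load) per-subject data -> Pearson
connectomes -> upper-triangle FC vectors -> autoencoder embedding of the
AD subjects -> Ward clustering with joint Silhouette / Davies-Bouldin
selection of k -> subtype labels -> intra-network FC and node-wise graph
statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, simulate_cohort
from .connectome import ConnectivityMatrix, correlation_matrix, vectorize_upper
from .io import TimeSeriesMatrix
from .subtyping import (AutoencoderConfig, ClusterAssignment, LatentEmbedding,
                        pca_embedding, select_k, train_autoencoder)

logger = logging.getLogger("fcsubtype")

__all__ = [
    "cohort_connectomes",
    "feature_matrix",
    "embed_subjects",
    "cluster_subjects",
    "assign_subtype_labels",
    "subtype_cohort",
]

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII", 9: "IX"}


def cohort_connectomes(cohort: Cohort) -> list[ConnectivityMatrix]:
    """Pearson connectome per subject (identity for matrix-mode cohorts)."""
    out = []
    for s in cohort.subjects:
        if isinstance(s.data, TimeSeriesMatrix):
            out.append(correlation_matrix(s.data))
        else:
            out.append(s.data)
    return out


def feature_matrix(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack upper-triangle FC vectors into a subjects x features matrix."""
    vecs = [vectorize_upper(cm) for cm in matrices]
    return np.vstack([v.values for v in vecs]), [v.subject_id for v in vecs]


def embed_subjects(X: np.ndarray, subject_ids: list[str], seed: int,
                   method: str = "autoencoder", latent_dim: int = 16,
                   **ae_kwargs) -> LatentEmbedding:
    if method == "autoencoder":
        cfg = AutoencoderConfig(input_dim=X.shape[1], latent_dim=latent_dim,
                                seed=seed, **ae_kwargs)
        _, emb = train_autoencoder(X, cfg, subject_ids=subject_ids)
        return emb
    if method == "pca":
        return pca_embedding(X, latent_dim, subject_ids=subject_ids)
    raise ValueError(f"unknown embedding method {method!r}")


def cluster_subjects(matrices: list[ConnectivityMatrix], seed: int,
                     k_min: int = 2, k_max: int = 9,
                     method: str = "autoencoder", latent_dim: int = 16,
                     **ae_kwargs) -> ClusterAssignment:
    """Embed FC vectors and select the best Ward clustering over k."""
    X, ids = feature_matrix(matrices)
    emb = embed_subjects(X, ids, seed, method=method, latent_dim=latent_dim, **ae_kwargs)
    assignment = select_k(emb, k_min, k_max)
    logger.info("clustering: n=%d selected k=%d (silhouette=%.3f, DB=%.3f)",
                len(ids), assignment.k, *assignment.quality[assignment.k])
    return assignment


def assign_subtype_labels(meta: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Replace the AD diagnosis by per-cluster subtype labels.

    Cluster 1 (the largest) becomes subtype_I, cluster 2 subtype_II, and
    so on; subjects absent from the assignment (the CN group) keep their
    group label.
    """
    mapping = {sid: f"subtype_{_ROMAN.get(int(lab), str(lab))}"
               for sid, lab in zip(assignment.subject_ids, assignment.labels)}
    out = meta.copy()
    out["group"] = [mapping.get(sid, grp) for sid, grp in zip(out["subject_id"], out["group"])]
    return out


def subtype_cohort(spec: CohortSpec, mode: str = "timeseries",
                   method: str = "autoencoder", k_min: int = 2, k_max: int = 9,
                   **ae_kwargs) -> tuple[Cohort, list[ConnectivityMatrix], ClusterAssignment]:
    """Simulate a cohort and run the subtyping stage on its AD subjects.

    Only subjects whose diagnosis is AD (both planted subtypes) enter the
    clustering, mirroring a case-only subtyping analysis; CN subjects are
    carried through for the downstream group comparisons.
    """
    cohort = simulate_cohort(spec, mode=mode)
    matrices = cohort_connectomes(cohort)
    ad_ids = {s.subject_id for s in cohort.subjects if s.true_group != "CN"}
    ad_matrices = [cm for cm in matrices if cm.subject_id in ad_ids]
    assignment = cluster_subjects(ad_matrices, seed=spec.seed, k_min=k_min,
                                  k_max=k_max, method=method, **ae_kwargs)
    return cohort, matrices, assignment
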