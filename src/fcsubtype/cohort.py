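"""Synthetic cohort generator with two planted AD subtypes.

The generator emulates the qualitative FC structure reported for
clustering-derived AD subtypes: a CN (cognitively normal) group, a
"malignant" subtype I whose functional connectivity is attenuated across
the whole brain, and a "benign" subtype II whose connectivity is
attenuated only in edges touching the limbic system (LS), optionally with
a mild compensatory boost of within-Visual and within-Default-Mode
connectivity.

The template connectome is a block-constant correlation matrix over the
7-network partition (within-network r > between-network r).  Subtype
effects multiply off-diagonal entries; the result is repaired to the
nearest valid correlation matrix by eigenvalue clipping followed by
re-normalisation to a unit diagonal.  Subjects are then realised either
as multivariate-normal time series whose sample correlation converges to
the template, or as the template plus symmetric element-wise noise.

Subject metadata (age, sex, education, MMSE, RAVLT scores) is drawn from
group-specific normal distributions; the defaults are the published
group means/SDs of the cohort this generator emulates.  Metadata is
independent of the FC draw given the group, which keeps FC-cognition
correlation nulls well-defined.

The attenuation magnitudes themselves are assumptions (no quantitative
effect sizes are published); they are tunable on :class:`CohortSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .errors import NonPSDError, UnknownGroupError
from .io import TimeSeriesMatrix, default_parcellation
from .network_fc import NetworkPartition

logger = logging.getLogger("fcsubtype")

__all__ = [
    "GROUPS",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "nearest_psd_correlation",
    "make_template_fc",
    "apply_subtype_effect",
    "simulate_subject",
    "simulate_metadata",
    "simulate_cohort",
]

GROUPS = ("CN", "subtype_I", "subtype_II")

# group -> {column: (mean, sd)} plus P(male); published cohort summaries
METADATA_PARAMS: dict[str, dict] = {
    "subtype_I": {
        "age": (73.36, 8.24), "education": (15.80, 2.50), "mmse": (22.55, 3.29),
        "ravlt_immediate": (23.18, 7.48), "ravlt_learning": (1.77, 1.73),
        "ravlt_forgetting": (4.75, 1.91), "p_male": 29 / 60,
    },
    "subtype_II": {
        "age": (74.22, 7.16), "education": (15.41, 2.56), "mmse": (22.86, 2.85),
        "ravlt_immediate": (22.23, 6.29), "ravlt_learning": (1.95, 1.56),
        "ravlt_forgetting": (4.68, 1.81), "p_male": 15 / 22,
    },
    "CN": {
        "age": (70.74, 6.74), "education": (16.94, 2.02), "mmse": (29.14, 0.90),
        "ravlt_immediate": (49.62, 8.77), "ravlt_learning": (6.60, 2.43),
        "ravlt_forgetting": (3.54, 3.03), "p_male": 21 / 50,
    },
}


@dataclass
class CohortSpec:
    """All tunables of the generator; defaults are the study conditions.

    ``n_regions`` defaults to the 60-region desk scale (7 networks of
    8-9 regions); the full 360-region scale is a parameter, not a
    different code path.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"subtype_I": 20, "subtype_II": 10, "CN": 15})
    n_regions: int = 60
    n_timepoints: int = 200
    base_within_network_r: float = 0.5
    base_between_network_r: float = 0.15
    global_attenuation_I: float = 0.7
    limbic_attenuation_II: float = 0.6
    compensation_boost_II: float = 1.1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.base_between_network_r < self.base_within_network_r < 1):
            raise ValueError("need 0 < between_r < within_r < 1")
        if not (0 < self.global_attenuation_I <= 1):
            raise ValueError("global_attenuation_I must be in (0, 1]")
        if not (0 < self.limbic_attenuation_II <= 1):
            raise ValueError("limbic_attenuation_II must be in (0, 1]")
        if self.compensation_boost_II < 1:
            raise ValueError("compensation_boost_II must be >= 1")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise UnknownGroupError(f"unknown group(s) in n_per_group: {sorted(unknown)}")


@dataclass
class SyntheticSubject:
    """One simulated subject; ``true_group`` is kept for recovery scoring."""

    subject_id: str
    true_group: str
    metadata: dict
    data: TimeSeriesMatrix | ConnectivityMatrix


@dataclass
class Cohort:
    spec: CohortSpec
    parcellation: pd.DataFrame
    subjects: list[SyntheticSubject]

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([s.metadata for s in self.subjects])

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": s.subject_id, "true_group": s.true_group}
                             for s in self.subjects])

    @property
    def partition(self) -> NetworkPartition:
        return NetworkPartition.from_parcellation(self.parcellation)


def nearest_psd_correlation(m: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues below zero are clipped, then rows/columns are rescaled to
    restore the unit diagonal.  This preserves block structure well for
    the mildly indefinite matrices the generator produces.
    """
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() >= -tol:
        out = m.copy()
    else:
        out = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.diag(out).copy()
    if np.any(d <= 0):
        raise NonPSDError("matrix is not repairable to a correlation matrix (zero diagonal)")
    scale = 1.0 / np.sqrt(d)
    out = out * scale[:, None] * scale[None, :]
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def make_template_fc(spec: CohortSpec, partition: NetworkPartition,
                     region_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Block-constant template: within-network r vs between-network r."""
    if region_labels is None:
        region_labels = sorted(partition.membership)
    if len(region_labels) != spec.n_regions:
        raise ValueError("partition does not cover n_regions")
    nets = np.asarray([partition.membership[r] for r in region_labels])
    same = nets[:, None] == nets[None, :]
    r = np.where(same, spec.base_within_network_r, spec.base_between_network_r)
    np.fill_diagonal(r, 1.0)
    r = nearest_psd_correlation(r)
    return ConnectivityMatrix("template", r, list(region_labels))


def apply_subtype_effect(template: ConnectivityMatrix, group: str, spec: CohortSpec,
                         partition: NetworkPartition) -> ConnectivityMatrix:
    """Impose the group's FC signature on the template.

    CN: unchanged.  Subtype I: every off-diagonal entry multiplied by
    ``global_attenuation_I``.  Subtype II: entries with at least one
    endpoint in LS multiplied by ``limbic_attenuation_II``; within-VN and
    within-DMN entries multiplied by ``compensation_boost_II`` and clipped
    to (-1, 1).  The result is repaired to the nearest correlation matrix.
    """
    if group not in GROUPS:
        raise UnknownGroupError(f"unknown group {group!r}; expected one of {GROUPS}")
    r = template.r.copy()
    off = ~np.eye(template.n, dtype=bool)
    if group == "subtype_I":
        r[off] *= spec.global_attenuation_I
    elif group == "subtype_II":
        nets = np.asarray([partition.membership[lab] for lab in template.region_labels])
        in_ls = nets == "LS"
        touch_ls = (in_ls[:, None] | in_ls[None, :]) & off
        r[touch_ls] *= spec.limbic_attenuation_II
        for boosted in ("VN", "DMN"):
            in_b = nets == boosted
            within = (in_b[:, None] & in_b[None, :]) & off
            r[within] = np.clip(r[within] * spec.compensation_boost_II, -0.999, 0.999)
    r = nearest_psd_correlation(r)
    return ConnectivityMatrix(template.subject_id, r, list(template.region_labels))


def _psd_factor(r: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise NonPSDError(f"template is not PSD (min eigenvalue {w.min():.3g})")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_subject(template: ConnectivityMatrix, spec: CohortSpec, mode: str,
                     rng: np.random.Generator, subject_id: str = "S000",
                     true_group: str = "CN") -> SyntheticSubject:
    """Realise one subject from a group template.

    ``mode='timeseries'`` draws ``n_timepoints`` samples from a zero-mean
    multivariate normal with covariance equal to the template, so the
    sample Pearson matrix converges to the template as the series grows.
    ``mode='matrix'`` perturbs the template with symmetric N(0, noise_sd)
    noise and re-repairs to a correlation matrix.
    """
    if mode == "timeseries":
        factor = _psd_factor(template.r)
        z = rng.standard_normal((spec.n_timepoints, template.n)) @ factor.T
        data: TimeSeriesMatrix | ConnectivityMatrix = TimeSeriesMatrix(
            subject_id, z.T, list(template.region_labels))
    elif mode == "matrix":
        n = template.n
        noise = rng.standard_normal((n, n)) * spec.noise_sd
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        r = nearest_psd_correlation(template.r + noise) if spec.noise_sd > 0 else template.r.copy()
        data = ConnectivityMatrix(subject_id, r, list(template.region_labels))
    else:
        raise ValueError(f"mode must be 'timeseries' or 'matrix', got {mode!r}")
    meta = simulate_metadata(true_group, rng, subject_id=subject_id)
    return SyntheticSubject(subject_id, true_group, meta, data)


def simulate_metadata(group: str, rng: np.random.Generator,
                      subject_id: str = "S000",
                      params: dict | None = None) -> dict:
    """Draw one metadata record from the group's score distributions.

    The recorded ``group`` is the pre-clustering diagnosis (CN or AD);
    the subtype only enters through which distributions are sampled.
    """
    if group not in METADATA_PARAMS:
        raise UnknownGroupError(f"unknown group {group!r}")
    p = {**METADATA_PARAMS[group], **(params or {})}
    draw = {k: rng.normal(*p[k]) for k in ("age", "education", "mmse",
                                           "ravlt_immediate", "ravlt_learning",
                                           "ravlt_forgetting")}
    return {
        "subject_id": subject_id,
        "group": "CN" if group == "CN" else "AD",
        "age": float(np.clip(draw["age"], 40.0, 110.0)),
        "sex": "M" if rng.random() < p["p_male"] else "F",
        "education": float(max(draw["education"], 0.0)),
        "mmse": float(np.clip(draw["mmse"], 0.0, 30.0)),
        "ravlt_immediate": float(max(draw["ravlt_immediate"], 0.0)),
        "ravlt_learning": float(max(draw["ravlt_learning"], 0.0)),
        "ravlt_forgetting": float(max(draw["ravlt_forgetting"], 0.0)),
    }


def simulate_cohort(spec: CohortSpec, mode: str = "timeseries",
                    parcellation: pd.DataFrame | None = None) -> Cohort:
    """Generate the full cohort: data + metadata, deterministic in spec.seed."""
    if parcellation is None:
        parcellation = default_parcellation(spec.n_regions)
    partition = NetworkPartition.from_parcellation(parcellation)
    labels = list(parcellation["region_label"])
    template = make_template_fc(spec, partition, labels)
    templates = {g: apply_subtype_effect(template, g, spec, partition) for g in GROUPS}
    rng = np.random.default_rng(spec.seed)
    subjects: list[SyntheticSubject] = []
    i = 0
    for group in GROUPS:
        for _ in range(spec.n_per_group.get(group, 0)):
            sid = f"S{i:03d}"
            subjects.append(simulate_subject(templates[group], spec, mode, rng,
                                             subject_id=sid, true_group=group))
            i += 1
    logger.info("simulated cohort: %d subjects, %d regions, mode=%s, seed=%d",
                len(subjects), spec.n_regions, mode, spec.seed)
    return Cohort(spec=replace(spec), parcellation=parcellation, subjects=subjects)
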