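"""Functional-network partition, intra-network FC, and group statistics.

Regions are partitioned into the seven canonical resting-state systems
(Visual, Somatomotor, Dorsal Attention, Ventral Attention, Limbic,
Frontoparietal, Default Mode).  The integrity of each system in one
subject is summarised by the intra-network FC: the mean absolute
correlation over distinct region pairs inside the system,

    IntraFC_X = 2 * sum_{i<j in X} |r_ij| / (n_X (n_X - 1)),

a value in [0, 1].  The sum runs over unordered pairs so that the
statistic is exactly a mean of |r|; summing ordered pairs under the same
normalising factor would double it past 1.

Group differences in demographics and intra-network FC use the classical
trio: one-way ANOVA for age, a chi-squared test on the sex contingency
table, and Kruskal-Wallis for education and the cognitive scores.
FC-covariate associations are plain Pearson correlations with two-sided
t-based p-values; no multiplicity correction is applied here (the graph
module owns FDR for its node-wise family).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectivityMatrix
from .errors import ZeroVarianceError

__all__ = [
    "NETWORK_NAMES",
    "NetworkPartition",
    "intra_network_fc",
    "intra_fc_table",
    "group_difference_tests",
    "correlate_fc_with_covariate",
    "pearson_p_from_r",
]

#: Fixed display/order convention for the 7 functional systems.
NETWORK_NAMES: tuple[str, ...] = ("VN", "SN", "DAN", "VAN", "LS", "FN", "DMN")


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one of the 7 networks."""

    membership: dict[str, str]
    network_names: tuple[str, ...] = NETWORK_NAMES

    def __post_init__(self) -> None:
        unknown = set(self.membership.values()) - set(self.network_names)
        if unknown:
            raise ValueError(f"membership uses networks outside the vocabulary: {sorted(unknown)}")

    @classmethod
    def from_parcellation(cls, parcellation: pd.DataFrame) -> "NetworkPartition":
        return cls(dict(zip(parcellation["region_label"], parcellation["network"])))

    @property
    def sizes(self) -> dict[str, int]:
        out = {name: 0 for name in self.network_names}
        for net in self.membership.values():
            out[net] += 1
        return out

    def regions_of(self, network: str) -> list[str]:
        return [r for r, net in self.membership.items() if net == network]

    def indices_of(self, network: str, region_labels: list[str]) -> np.ndarray:
        members = {r for r, net in self.membership.items() if net == network}
        return np.asarray([i for i, lab in enumerate(region_labels) if lab in members], dtype=int)


def intra_network_fc(cm: ConnectivityMatrix, part: NetworkPartition) -> dict[str, float]:
    """Mean |r| over distinct within-network region pairs, per network.

    Returns a dict keyed by network name in the fixed order.  Any network
    represented in the matrix by fewer than 2 regions is an error: the
    statistic is undefined for a single region.
    """
    missing = set(part.membership) - set(cm.region_labels)
    if missing:
        raise ValueError(f"partition regions absent from matrix: {sorted(missing)[:5]} ...")
    out: dict[str, float] = {}
    for net in part.network_names:
        idx = part.indices_of(net, cm.region_labels)
        n_x = idx.size
        if n_x < 2:
            raise ValueError(f"network {net} has {n_x} region(s); need at least 2")
        block = np.abs(cm.r[np.ix_(idx, idx)])
        iu = np.triu_indices(n_x, k=1)
        out[net] = float(block[iu].mean())
    return out


def intra_fc_table(matrices: list[ConnectivityMatrix], part: NetworkPartition,
                   groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Long-format table of intra-network FC: one row per subject x network."""
    rows = []
    for cm in matrices:
        vals = intra_network_fc(cm, part)
        for net in part.network_names:
            rows.append({
                "subject_id": cm.subject_id,
                "group": (groups or {}).get(cm.subject_id, ""),
                "network": net,
                "intra_fc": vals[net],
            })
    return pd.DataFrame(rows)


# which test Table-1-style columns receive
_TEST_MAP = {
    "age": "anova",
    "sex": "chi2",
    "education": "kruskal",
    "mmse": "kruskal",
    "ravlt_immediate": "kruskal",
    "ravlt_learning": "kruskal",
    "ravlt_forgetting": "kruskal",
}


def group_difference_tests(df: pd.DataFrame, group_col: str = "group",
                           columns: list[str] | None = None,
                           test_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Omnibus tests of group differences, one row per column tested.

    Continuous normal-assumed columns get one-way ANOVA, categorical
    columns a chi-squared test on the contingency table, ordinal/score
    columns Kruskal-Wallis.  Columns where every group is constant are
    flagged (``degenerate=True``, NaN statistics) rather than crashed.
    """
    test_map = {**_TEST_MAP, **(test_map or {})}
    columns = columns if columns is not None else [c for c in df.columns if c in test_map]
    groups = [g for _, g in df.groupby(group_col, sort=False)]
    if sum(len(g) > 0 for g in groups) < 2:
        raise ValueError("need at least 2 nonempty groups")
    rows = []
    for col in columns:
        test = test_map.get(col, "kruskal")
        samples = [g[col].dropna().to_numpy() for g in groups]
        degenerate = False
        if test == "chi2":
            tab = pd.crosstab(df[group_col], df[col])
            if tab.shape[1] < 2:
                stat, p, degenerate = np.nan, np.nan, True
            else:
                stat, p, _, _ = stats.chi2_contingency(tab.to_numpy())
        else:
            pooled = np.concatenate(samples)
            if np.ptp(pooled) == 0:
                stat, p, degenerate = np.nan, np.nan, True
            elif test == "anova":
                stat, p = stats.f_oneway(*samples)
            else:
                stat, p = stats.kruskal(*samples)
        rows.append({"column": col, "test": test, "statistic": float(stat) if stat == stat else np.nan,
                     "p_value": float(p) if p == p else np.nan, "degenerate": degenerate})
    return pd.DataFrame(rows)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r at sample size n.

    Uses the exact t transform t = r * sqrt((n-2) / (1-r^2)) with n-2
    degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_fc_with_covariate(table: pd.DataFrame, meta: pd.DataFrame,
                                covariate: str, group: str) -> pd.DataFrame:
    """Pearson correlation of intra-network FC with a covariate, per network.

    Restricted to one group; missing covariate values are dropped pairwise.
    Returns one row per network with r, the t-based two-sided p, and n.
    """
    merged = table.merge(meta[["subject_id", covariate]], on="subject_id", how="left")
    merged = merged[merged["group"] == group]
    rows = []
    for net, sub in merged.groupby("network", sort=False):
        sub = sub.dropna(subset=[covariate, "intra_fc"])
        n = len(sub)
        if n < 3:
            raise ValueError(f"network {net}: only {n} complete pairs (need >= 3)")
        x = sub[covariate].to_numpy(dtype=float)
        y = sub["intra_fc"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ZeroVarianceError(f"covariate {covariate} is constant within group {group}")
        if np.ptp(y) == 0:
            raise ZeroVarianceError(f"intra_fc is constant for network {net} in group {group}")
        r, p = stats.pearsonr(x, y)
        rows.append({"group": group, "network": net, "covariate": covariate,
                     "pearson_r": float(r), "p_value": float(p), "n": n})
    return pd.DataFrame(rows)
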