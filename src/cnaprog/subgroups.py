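"""Unsupervised subgrouping and survival comparison.

Samples are clustered on the reduced region-level log2 matrix (chrX regions
excluded by default, since X copy number reflects germline sex rather than
somatic biology on a female-reference platform) with Euclidean distance and
Ward's minimum-variance linkage.  The tree is cut at a user-chosen k (the
primary analysis uses the top-level two-way split) and the resulting
clusters are compared on progression-free and overall survival with
Kaplan-Meier curves, the two-sided log-rank test, and a Cox proportional
hazards fit.  KM/log-rank/Cox delegate to lifelines; the contract is the
returned numbers.

Note the deliberate circularity of the design being reproduced: survival is
tested on the same cohort used to form the clusters, which inflates the
type-I error of the log-rank test relative to its nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .segment import ReducedMatrix


def ward_cluster(
    reduced: ReducedMatrix | np.ndarray,
    exclude_chrX: bool = True,
    probe_weighted: bool = True,
) -> np.ndarray:
    """Ward/Euclidean agglomerative linkage over samples.

    Accepts a ReducedMatrix (regions x samples; chrX regions droppable) or
    a plain samples x features array.  By default regions are weighted by
    their probe counts so distances match the probe-resolution reduced
    profiles; ``probe_weighted=False`` gives each region unit weight.
    Returns the scipy linkage matrix.
    """
    if isinstance(reduced, ReducedMatrix):
        feats = reduced.sample_features(
            exclude_chrX=exclude_chrX, probe_weighted=probe_weighted
        )
    else:
        feats = np.asarray(reduced, dtype=float)
    if feats.shape[0] < 2:
        raise ValueError("clustering requires at least 2 samples")
    return linkage(feats, method="ward", metric="euclidean")


def cut_k(tree: np.ndarray, k: int, sample_ids: list[str] | None = None) -> pd.Series:
    """Cut the linkage tree into k clusters.

    Labels are 1..k ordered by cluster size (descending), ties broken by
    the first member's sample index.
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = fcluster(tree, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    return pd.Series(labels, index=sample_ids, name="cluster")


def tree_to_newick(tree: np.ndarray, sample_ids: list[str]) -> str:
    """Newick text of the dendrogram with merge heights as branch lengths."""
    root = to_tree(tree)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{sample_ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(root, root.dist) + ";"


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve: columns time, survival, at_risk."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_
    ev = kmf.event_table
    df = pd.DataFrame(
        {
            "time": surv.index.to_numpy(),
            "survival": surv.iloc[:, 0].to_numpy(),
            "at_risk": ev["at_risk"].reindex(surv.index).to_numpy(),
        }
    )
    return df.reset_index(drop=True)


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-sided (multivariate) log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        if events[groups == g].sum() == 0:
            raise ValueError(f"group {g!r} has no observed events; log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def ph_fit(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit.

    Returns per covariate: hazard_ratio, ci_low, ci_high, p.
    """
    cov = covariates.copy()
    const = [c for c in cov.columns if cov[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    df = cov.assign(_time=np.asarray(times, dtype=float), _event=np.asarray(events))
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    summ = cph.summary
    return pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )


@dataclass
class SurvivalComparison:
    endpoint: str  # "PFS" | "OS"
    km_by_group: dict  # group label -> KM frame
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    group_sizes: dict

    def summary_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "group_sizes": {str(k): int(v) for k, v in self.group_sizes.items()},
            "median_survival": {
                str(g): _km_median(df) for g, df in self.km_by_group.items()
            },
        }


def _km_median(km: pd.DataFrame) -> float | None:
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else None


def compare_survival(
    clinical: pd.DataFrame, labels: pd.Series, endpoint: str = "PFS"
) -> SurvivalComparison:
    """KM + log-rank + Cox (binary group indicator vs the first cluster)."""
    prefix = endpoint.lower()
    cl = clinical.set_index("sample").loc[labels.index]
    times = cl[f"{prefix}_months"].to_numpy(dtype=float)
    events = cl[f"{prefix}_event"].to_numpy()
    groups = labels.to_numpy()
    stat, p = logrank(times, events, groups)
    km = {
        g: km_estimate(times[groups == g], events[groups == g])
        for g in np.unique(groups)
    }
    ref = np.unique(groups)[0]
    hr_df = ph_fit(times, events, pd.DataFrame({"group": (groups != ref).astype(int)}))
    hr = float(hr_df.loc["group", "hazard_ratio"])
    ci = (float(hr_df.loc["group", "ci_low"]), float(hr_df.loc["group", "ci_high"]))
    sizes = {g: int((groups == g).sum()) for g in np.unique(groups)}
    return SurvivalComparison(endpoint, km, stat, p, hr, ci, sizes)
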