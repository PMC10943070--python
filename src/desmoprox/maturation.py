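"""Maturation-state analysis of proximity profiles.

Each prey that is significant (BFDR <= threshold) in at least one of the
bait x condition datasets gets a binary significance profile over all eight
datasets.  Profiles are clustered hierarchically (average linkage on the
Jaccard distance) and every prey is classified by adhesion state:

constant
    significant in at least one Ca2+-dependent and one hyper-adhesive dataset
calcium_dependent
    significant only while desmosomes are Ca2+-dependent
hyper_adhesive
    significant only in the mature, Ca2+-independent state

Bait-sharing counts merge the two plakoglobin termini into a single bait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
import statsmodels.api as sm

from .errors import InputError, ParameterError, StatisticsError
from .scoring import ND
from .simulate import DEFAULT_BAITS, DEFAULT_CONDITIONS

#: baits merged into one for sharing counts (two termini of the same protein)
PG_TERMINI = ("PG-N", "PG-C")
PG_MERGED = "PG"

CATEGORY_CONSTANT = "constant"
CATEGORY_CA = "calcium_dependent"
CATEGORY_HYPER = "hyper_adhesive"


def dataset_label(bait: str, condition: str) -> str:
    return f"{bait}|{condition}"


def dataset_order(baits=DEFAULT_BAITS, conditions=DEFAULT_CONDITIONS) -> list[str]:
    return [dataset_label(b, c) for b in baits for c in conditions]


@dataclass
class ProfileSet:
    """Per-prey binary significance vectors plus matched fold changes.

    ``binary``: preys x datasets 0/1 DataFrame (every row has >= 1 one).
    ``log2fc``: same shape, NaN where the prey was not detected.
    """

    binary: pd.DataFrame
    log2fc: pd.DataFrame
    baits: tuple = DEFAULT_BAITS
    conditions: tuple = DEFAULT_CONDITIONS

    @property
    def preys(self) -> list[str]:
        return self.binary.index.tolist()

    def datasets_for(self, condition: str) -> list[str]:
        return [dataset_label(b, condition) for b in self.baits]

    def significant_in_condition(self, condition: str) -> set:
        cols = self.datasets_for(condition)
        mask = self.binary[cols].sum(axis=1) > 0
        return set(self.binary.index[mask])

    def bait_preys(self, bait: str, merge_pg: bool = True) -> set:
        """Preys significant for a bait in any condition; with merge_pg the
        two plakoglobin termini count as one bait."""
        if merge_pg and bait == PG_MERGED:
            baits = [b for b in self.baits if b in PG_TERMINI]
        else:
            baits = [bait]
        cols = [
            dataset_label(b, c) for b in baits for c in self.conditions
        ]
        mask = self.binary[cols].sum(axis=1) > 0
        return set(self.binary.index[mask])

    def merged_baits(self) -> list[str]:
        out, seen_pg = [], False
        for b in self.baits:
            if b in PG_TERMINI:
                if not seen_pg:
                    out.append(PG_MERGED)
                    seen_pg = True
            else:
                out.append(b)
        return out


def binarize_profiles(
    scores: pd.DataFrame,
    threshold: float = 0.05,
    baits=DEFAULT_BAITS,
    conditions=DEFAULT_CONDITIONS,
) -> ProfileSet:
    """Build profiles for every prey significant in >= 1 dataset.

    Dataset order is fixed (bait-major over the two conditions).  The
    ``log2fc`` panel carries the scored fold change where the prey was
    detected in that dataset, NaN otherwise.
    """
    order = dataset_order(baits, conditions)
    df = scores.copy()
    df["dataset"] = [
        dataset_label(b, c) for b, c in zip(df["bait"], df["condition"])
    ]
    sig = df[df["bfdr"] <= threshold]
    keep_preys = sorted(set(sig["prey"]))
    binary = pd.DataFrame(0, index=keep_preys, columns=order, dtype=int)
    for _, row in sig.iterrows():
        binary.loc[row["prey"], row["dataset"]] = 1
    fc = (
        df.pivot_table(index="prey", columns="dataset", values="log2fc", aggfunc="mean")
        .reindex(index=keep_preys, columns=order)
    )
    binary.index.name = fc.index.name = "prey"
    return ProfileSet(binary=binary, log2fc=fc, baits=tuple(baits), conditions=tuple(conditions))


def jaccard_distance(a, b) -> float:
    """1 - |a AND b| / |a OR b| on equal-length binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError("profile vectors differ in length")
    if not a.any() or not b.any():
        raise InputError("all-zero profile has no Jaccard distance")
    union = np.logical_or(a, b).sum()
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


@dataclass
class ClusterAssignment:
    """prey -> cluster index (contiguous from 1, ordered by dendrogram leaves)."""

    labels: pd.Series
    linkage: np.ndarray
    leaf_order: list
    k: int

    def sizes(self) -> dict:
        return self.labels.value_counts().sort_index().to_dict()


def cluster_preys(
    profiles: ProfileSet, k: int = 11, method: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering on the Jaccard distance matrix (UPGMA default).

    Profiles are canonically ordered by prey ID before linkage, so the result
    is invariant to input order.  The dendrogram is cut into exactly ``k``
    clusters; cluster indices follow dendrogram leaf order.
    """
    n = len(profiles.preys)
    if n < 2:
        raise ParameterError("need >= 2 profiles to cluster")
    if k > n:
        raise ParameterError(f"k={k} exceeds number of profiles ({n})")
    binary = profiles.binary.sort_index()
    X = binary.to_numpy(dtype=bool)
    dist = pdist(X, metric="jaccard")
    Z = sch.linkage(dist, method=method)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    leaves = sch.leaves_list(Z)
    # relabel contiguously in leaf order
    relabel: dict = {}
    for leaf in leaves:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    labels = pd.Series(
        [relabel[c] for c in raw], index=binary.index, name="cluster"
    )
    leaf_preys = [binary.index[i] for i in leaves]
    return ClusterAssignment(labels=labels, linkage=Z, leaf_order=leaf_preys, k=k)


def categorize_maturation(
    profiles: ProfileSet, clusters: ClusterAssignment | None = None
) -> pd.DataFrame:
    """Classify every profiled prey by adhesion state and count shared baits.

    Returns columns ``prey, category, n_baits, cluster`` (cluster NaN when no
    assignment is supplied).  The bait-sharing count merges the plakoglobin
    termini.
    """
    ca_cond, hyper_cond = profiles.conditions
    in_ca = profiles.significant_in_condition(ca_cond)
    in_hyper = profiles.significant_in_condition(hyper_cond)
    merged = profiles.merged_baits()
    bait_sets = {b: profiles.bait_preys(b) for b in merged}
    rows = []
    for prey in profiles.preys:
        if prey in in_ca and prey in in_hyper:
            category = CATEGORY_CONSTANT
        elif prey in in_ca:
            category = CATEGORY_CA
        else:
            category = CATEGORY_HYPER
        n_baits = sum(prey in s for s in bait_sets.values())
        rows.append(dict(prey=prey, category=category, n_baits=n_baits))
    calls = pd.DataFrame(rows, columns=["prey", "category", "n_baits"])
    if clusters is not None:
        calls["cluster"] = calls["prey"].map(clusters.labels)
    else:
        calls["cluster"] = np.nan
    return calls


def heatmap_matrix(profiles: ProfileSet, clusters: ClusterAssignment) -> pd.DataFrame:
    """Fold-change matrix (preys x datasets) in dendrogram leaf order.

    NaN cells mean the prey was not detected in that dataset; text export
    renders them as "N.D.".
    """
    return profiles.log2fc.loc[clusters.leaf_order]


def write_heatmap(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy().astype(object)
    out = out.where(out.notna(), ND)
    out.to_csv(path, sep="\t")


@dataclass
class ScatterFit:
    """Per-prey enrichment in one condition vs the other plus an OLS fit."""

    points: pd.DataFrame  # prey, x (first condition), y (second condition)
    slope: float
    intercept: float
    conf_lower: np.ndarray  # pointwise 95% band at the observed x, x-sorted
    conf_upper: np.ndarray
    x_sorted: np.ndarray


def scatter_pairs(
    scores: pd.DataFrame,
    bait: str,
    conditions=DEFAULT_CONDITIONS,
) -> ScatterFit:
    """Paired per-prey enrichment across the two adhesion states for one bait,
    with an ordinary least-squares line and pointwise 95% confidence band."""
    ca_cond, hyper_cond = conditions
    sub = scores[scores["bait"] == bait]
    x = sub[sub["condition"] == ca_cond].set_index("prey")["log2fc"]
    y = sub[sub["condition"] == hyper_cond].set_index("prey")["log2fc"]
    shared = x.dropna().index.intersection(y.dropna().index).sort_values()
    if len(shared) < 3:
        raise StatisticsError(
            f"need >= 3 preys detected in both conditions for bait {bait!r}, found {len(shared)}"
        )
    points = pd.DataFrame({"prey": shared, "x": x[shared].values, "y": y[shared].values})
    X = sm.add_constant(points["x"].to_numpy())
    fit = sm.OLS(points["y"].to_numpy(), X).fit()
    order = np.argsort(points["x"].to_numpy())
    xs = points["x"].to_numpy()[order]
    pred = fit.get_prediction(sm.add_constant(xs))
    band = pred.conf_int(alpha=0.05)
    return ScatterFit(
        points=points,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        conf_lower=band[:, 0],
        conf_upper=band[:, 1],
        x_sorted=xs,
    )
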