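"""Bootstrap hierarchical clustering of samples on their ICR CpG profiles.

Samples are compared by Pearson correlation distance ``d = 1 − r`` over
their CpG profiles and agglomerated with complete linkage.  Cluster
stability is scored by feature (CpG-column) bootstrap: resample the columns
with replacement, rebuild the tree, and report for each cluster of the
original tree the fraction of bootstrap trees containing exactly the same
leaf set — the ordinary bootstrap probability (BP) of pvclust.  The
multiscale AU correction is not implemented.

The agglomeration itself is scipy's; this module owns the distance, the
bootstrap scoring, tree export (newick, merge table) and the heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import InputError, UndefinedCorrelationError


def pearson_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ``1 − Pearson r`` between sample rows; range [0, 2].

    ``profiles``: samples × CpGs.  A constant profile has undefined
    correlation and is rejected by name.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise InputError("need at least 2 samples and 2 probes")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("non-finite values in profiles")
    sd = X.std(axis=1)
    for sample_id, s in zip(profiles.index, sd):
        if s == 0.0:
            raise UndefinedCorrelationError(str(sample_id))
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """A complete-linkage tree over samples.

    ``merges``: scipy linkage matrix (each row: child a, child b, height,
    size).  Internal node ``k`` of the merge list has id ``n + k``.
    """

    merges: np.ndarray
    labels: list[str]
    linkage: str = "complete"
    distance: str = "pearson"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.dendrogram(self.merges, no_plot=True)["leaves"]
        return [self.labels[i] for i in order]

    def cluster_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for k, (a, b, _h, _c) in enumerate(self.merges):
            s = sets[int(a)] | sets[int(b)]
            sets[n + k] = s
            out.append(s)
        return out

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.merges)
        M = squareform(d)
        return pd.DataFrame(M, index=self.labels, columns=self.labels)

    def cut(self, k: int) -> dict[str, int]:
        """Cut into exactly ``k`` groups; labels 1..k stable by leaf order."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise InputError(f"k={k} outside [1, {n}]")
        raw = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        relabel: dict[int, int] = {}
        for lab in self.leaf_order():
            r = int(raw[self.labels.index(lab)])
            if r not in relabel:
                relabel[r] = len(relabel) + 1
        return {lab: relabel[int(raw[i])] for i, lab in enumerate(self.labels)}

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for k, (_a, _b, h, _c) in enumerate(self.merges):
            height[n + k] = float(h)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            a, b, h, _ = self.merges[node - n]
            parts = []
            for child in (int(a), int(b)):
                bl = float(h) - height[child]
                parts.append(f"{render(child)}:{bl:.6g}")
            return "(" + ",".join(parts) + ")"

        return render(n + len(self.merges) - 1) + ";"

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["child_a", "child_b", "height", "size"]
        )


def complete_linkage(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage tree from a square distance table."""
    D = distances.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise InputError("NaN in distance table")
    if D.shape[0] != D.shape[1]:
        raise InputError("distance table must be square")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(merges=Z, labels=[str(x) for x in distances.index])


@dataclass
class ClusterConsistency:
    """Bootstrap proportions per cluster of the original tree."""

    proportions: Mapping[frozenset[str], float]
    n_bootstrap: int
    seed: int
    resample_unit: str = "cpg_columns"

    def min_over(self, clusters: Sequence[frozenset[str]]) -> float:
        return min(self.proportions.get(frozenset(c), 0.0) for c in clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_size": len(s),
                "bootstrap_proportion": p,
                "members": ";".join(sorted(s)),
            }
            for s, p in self.proportions.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["cluster_size", "members"]
        ).reset_index(drop=True)


def bootstrap_consistency(
    profiles: pd.DataFrame, n_bootstrap: int = 1000, seed: int = 0
) -> ClusterConsistency:
    """Feature-bootstrap cluster support (pvclust-style BP).

    Resamples the CpG columns with replacement (same count), rebuilds the
    complete-linkage tree each time, and reports for every cluster of the
    original tree the fraction of bootstrap trees containing that exact
    leaf set.  The root always scores 1.
    """
    if profiles.shape[1] < 2:
        raise InputError("need at least 2 CpG columns to bootstrap")
    tree = complete_linkage(pearson_distance(profiles))
    original = tree.cluster_leaf_sets()
    counts = dict.fromkeys(original, 0)
    rng = np.random.default_rng(seed)
    X = profiles.to_numpy(dtype=float)
    labels = [str(x) for x in profiles.index]
    n_cols = X.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_cols, n_cols)
        Xb = X[:, cols]
        sd = Xb.std(axis=1)
        # a resample can make a profile constant; such trees support no cluster
        if (sd == 0.0).any():
            continue
        Db = 1.0 - np.corrcoef(Xb)
        Zb = hierarchy.linkage(squareform(np.clip((Db + Db.T) / 2.0, 0, 2),
                                          checks=False), method="complete")
        boot_sets = set(Dendrogram(Zb, labels).cluster_leaf_sets())
        for s in counts:
            if s in boot_sets:
                counts[s] += 1
    props = {s: c / n_bootstrap for s, c in counts.items()}
    return ClusterConsistency(props, n_bootstrap, seed)


def plot_heatmap(
    profiles: pd.DataFrame,
    tree: Dendrogram,
    path: str | Path,
    manifest: pd.DataFrame | None = None,
) -> None:
    """Static heatmap: samples in dendrogram order, CpGs in genomic order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = tree.leaf_order()
    cols = list(profiles.columns)
    if manifest is not None:
        pos = manifest.loc[cols, "pos"].astype(int)
        cols = list(pos.sort_values().index)
    M = profiles.loc[order, cols]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * len(cols)), max(4, 0.18 * len(order)))
    )
    im = ax.imshow(M.to_numpy(), aspect="auto", cmap="RdYlBu_r", vmin=0, vmax=1)
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=90, fontsize=5)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=5)
    fig.colorbar(im, ax=ax, label="methylation fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
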