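"""Post-inference analyses: peak–age association, age-bin pseudobulk,
and the clock-accessibility phylogeny of cell clusters.

The phylogeny treats each cell cluster's mean accessibility profile
over the reference clock-like peaks as a point; Euclidean distances
between cluster profiles feed a neighbor-joining tree, re-rooted with
the cluster of minimal mean inferred age as outgroup — the cluster
closest to the mitotic ground state anchors the birth sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import PeakMatrix
from .model import correlate_peaks_with_age

logger = logging.getLogger(__name__)


def associate(
    matrix: PeakMatrix, age: np.ndarray, z_cutoff: float = 3.0
) -> pd.DataFrame:
    """Per-peak Pearson r vs age with scaled Z and a |Z| significance flag.

    Unlike reference expansion, association keeps both signs: peaks
    closing with age are flagged when |Z| exceeds the cutoff.
    """
    r, z = correlate_peaks_with_age(matrix, age)
    return pd.DataFrame(
        {
            "peak": [str(iv) for iv in matrix.peak_intervals],
            "r": r,
            "z": z,
            "significant": np.abs(z) > z_cutoff,
        }
    )


def pseudobulk_by_age_bin(
    matrix: PeakMatrix,
    age: np.ndarray,
    labels: np.ndarray | list[str],
    n_bins: int = 100,
) -> pd.DataFrame:
    """Mean accessibility per (age bin, phenotype) group.

    Ages in [0, 1] are mapped to bins ``floor(age * n_bins)`` clipped to
    [0, n_bins - 1]; each peak's counts are averaged over the cells of
    every occupied (bin, phenotype) group. Returns a long-format frame
    indexed by (bin, phenotype) with one column per peak.
    """
    age = np.asarray(age, dtype=float)
    if np.any((age < 0) | (age > 1)):
        raise ValueError("ages must lie in [0, 1]")
    labels = np.asarray(labels)
    bins = np.clip(np.floor(age * n_bins).astype(int), 0, n_bins - 1)
    X = matrix.dense()
    frames = []
    df_groups = pd.DataFrame({"bin": bins, "phenotype": labels})
    for (b, ph), idx in df_groups.groupby(["bin", "phenotype"], sort=True).groups.items():
        cols = np.asarray(idx, dtype=int)
        frames.append(
            {
                "bin": int(b),
                "phenotype": ph,
                "n_cells": len(cols),
                **{
                    str(iv): m
                    for iv, m in zip(matrix.peak_intervals, X[:, cols].mean(axis=1))
                },
            }
        )
    return pd.DataFrame(frames).set_index(["bin", "phenotype"])


@dataclass
class ClusterTree:
    """Neighbor-joining tree over cell clusters, rooted at the youngest."""

    tree: TreeNode
    root_label: str
    leaf_labels: list[str]
    distances: pd.DataFrame

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")


def _cluster_profiles(
    matrix: PeakMatrix, ref_idx: np.ndarray, cluster_labels: np.ndarray
) -> tuple[list[str], np.ndarray]:
    labels = np.asarray(cluster_labels)
    names = sorted(map(str, set(labels.tolist())))
    X = matrix.dense()[np.asarray(ref_idx, dtype=int), :]
    profiles = np.stack(
        [X[:, labels.astype(str) == name].mean(axis=1) for name in names]
    )
    return names, profiles


def build_cluster_tree(
    matrix: PeakMatrix,
    ref_idx: np.ndarray,
    age: np.ndarray,
    cluster_labels: np.ndarray | list[str],
) -> ClusterTree:
    """Neighbor-joining tree of cluster mean clock-accessibility profiles.

    Per-cluster mean profiles over the reference peaks give a Euclidean
    distance matrix; neighbor joining builds the topology (negative NJ
    branch lengths are clamped to zero with a warning) and the tree is
    re-rooted with the minimal-mean-age cluster as outgroup.
    """
    labels = np.asarray(cluster_labels).astype(str)
    age = np.asarray(age, dtype=float)
    if labels.shape[0] != matrix.n_cells or age.shape[0] != matrix.n_cells:
        raise ValueError("need one age and one cluster label per cell")
    names, profiles = _cluster_profiles(matrix, ref_idx, labels)
    if len(names) < 3:
        raise ValueError("tree undefined for fewer than 3 clusters")
    diff = profiles[:, None, :] - profiles[None, :, :]
    dm = np.sqrt((diff**2).sum(axis=2))
    dm = (dm + dm.T) / 2.0
    np.fill_diagonal(dm, 0.0)
    tree = nj(DistanceMatrix(dm, ids=names))
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        logger.warning("clamped %d negative NJ branch lengths to 0", n_neg)
    mean_age = {name: float(age[labels == name].mean()) for name in names}
    root_label = min(names, key=lambda name: (mean_age[name], name))
    # root on the branch above the outgroup leaf (midpoint of that branch)
    rooted = tree.root_at(tree.find(root_label), above=0.5)
    return ClusterTree(
        tree=rooted,
        root_label=root_label,
        leaf_labels=names,
        distances=pd.DataFrame(dm, index=names, columns=names),
    )
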