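"""Beta diversity, ordination and permutation tests for community structure.

Distances (Bray-Curtis on relative abundances, branch-length-weighted
UniFrac on a phylogeny) feed principal coordinate analysis for ordination
and a permutational multivariate ANOVA (the adonis-style pseudo-F) for
hypothesis tests; per-taxon differential abundance uses Kruskal-Wallis
with Bonferroni or Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from statsmodels.stats.multitest import multipletests

from saltmarsh.tables import CountTable


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


@dataclass
class PCoAResult:
    """Classical metric scaling of a distance matrix.

    ``coordinates`` has one row per sample and one column per retained
    (positive-eigenvalue) axis; ``eigenvalues`` includes the negative ones
    so non-Euclidean distortion is visible; ``proportion_explained``
    divides each positive eigenvalue by the total absolute eigenvalue mass,
    so the fractions sum to at most 1.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _relative(counts: np.ndarray) -> np.ndarray:
    counts = counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("sample with zero total reads")
    return counts / totals


def bray_curtis(table: CountTable, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples:
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]."""
    if len(table.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    x = _relative(table.counts) if normalize else table.counts.astype(float)
    if not normalize and np.any(x.sum(axis=0) == 0):
        raise ValueError("sample with zero total reads")
    d = squareform(pdist(x.T, metric="braycurtis"))
    return DistanceMatrix(d, ids=list(table.sample_ids))


def weighted_unifrac(table: CountTable, tree: TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac distance between samples on a rooted tree.

    Branch lengths are weighted by the difference in the relative-abundance
    mass of the subtree below each branch; the normalized variant divides by
    the maximum attainable value so distances lie in [0, 1].
    """
    leaves = {leaf.name for leaf in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    return beta_diversity(
        "weighted_unifrac", table.counts.T, ids=list(table.sample_ids),
        taxa=list(table.taxon_ids), tree=tree, normalized=normalized,
    )


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Principal coordinate analysis (classical metric scaling).

    Eigendecomposes the double-centred Gram matrix -J D^2 J / 2; coordinates
    come from the positive eigenvalues only, sorted descending.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (dm ** 2) @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    frac = np.where(eigval > 0, eigval, 0.0) / np.abs(eigval).sum()
    return PCoAResult(list(d.ids), coords, eigval, frac[pos])


def _gower_center(dm: np.ndarray) -> np.ndarray:
    n = dm.shape[0]
    a = -0.5 * dm ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def permanova(d: DistanceMatrix, labels: Sequence, n_perm: int = 999,
              seed: int | np.random.Generator = 0,
              factor: str = "factor",
              strata: Sequence | None = None) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between / (a - 1)) / (SS_within / (N - a)) with the sums
    of squares decomposed from squared inter-sample distances; the p-value
    is (#{F_perm >= F_obs} + 1) / (n_perm + 1) under random relabeling, so
    it can never be exactly zero.

    ``strata`` restricts the relabeling to permutations within each stratum
    (e.g. habitat-month blocks). Use it when a balanced nuisance factor
    structures the distances: unrestricted permutation is then conservative
    for the tested factor, while within-stratum permutation keeps the null
    exchangeable.
    """
    labels = np.asarray(labels)
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError("one label per sample required")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    levels, idx = np.unique(labels, return_inverse=True)
    a = len(levels)
    sizes = np.bincount(idx)
    if a < 2 or np.any(sizes < 2):
        raise ValueError("need >= 2 groups with >= 2 samples each")

    sq = dm ** 2
    ss_total = sq[np.triu_indices(n, 1)].sum() / n

    def f_stats(assign: np.ndarray) -> np.ndarray:
        """Pseudo-F for each row of a (n_perm x n) assignment matrix."""
        ss_within = np.zeros(assign.shape[0])
        for g in range(a):
            b = (assign == g).astype(float)
            ss_within += np.einsum("pi,ij,pj->p", b, sq, b) / (2.0 * sizes[g])
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("one stratum per sample required")
        stratum_members = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    f_obs = float(f_stats(idx[None, :])[0])
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 2000))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # each row is an independent random permutation of the labels
        if strata is None:
            perms = idx[np.argsort(rng.random((m, n)), axis=1)]
        else:
            perms = np.tile(idx, (m, 1))
            for members in stratum_members:
                order = np.argsort(rng.random((m, members.size)), axis=1)
                perms[:, members] = idx[members][order]
        count += int(np.sum(f_stats(perms) >= f_obs))
        done += m
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(factor, float(f_obs), float(p), n_perm, n, a)


def kruskal_wallis_per_taxon(table: CountTable, groups: Sequence,
                             normalize: bool = True) -> pd.DataFrame:
    """Kruskal-Wallis rank test of each taxon's (relative) abundance across
    groups. Taxa constant across all samples get H = 0, p = 1. Returns a
    DataFrame indexed by taxon with columns ``H`` and ``p``."""
    groups = np.asarray(groups)
    if len(groups) != len(table.sample_ids):
        raise ValueError("one group label per sample required")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    x = _relative(table.counts) if normalize else table.counts.astype(float)
    records = {}
    for i, taxon in enumerate(table.taxon_ids):
        vals = [x[i, groups == g] for g in levels]
        if np.ptp(x[i]) == 0:
            records[taxon] = {"H": 0.0, "p": 1.0}
        else:
            h, p = stats.kruskal(*vals)
            records[taxon] = {"H": float(h), "p": float(p)}
    return pd.DataFrame.from_dict(records, orient="index")


def adjust_pvalues(p: Sequence[float],
                   method: Literal["bonferroni", "bh"] = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, m*p)) or
    Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]
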