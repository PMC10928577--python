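"""Phylogenetic covariance and non-Bayesian signal statistics.

Trees are :class:`dendropy.Tree` objects. Under Brownian motion a trait
evolving along a rooted tree with branch lengths induces a tip covariance
matrix C whose entry (i, j) is the shared path length from the root to the
most recent common ancestor of tips i and j; the diagonal holds root-to-tip
distances. Blomberg's K compares the observed ratio of non-phylogenetic to
phylogenetic mean squared error against its Brownian-motion expectation:
K = 1 under Brownian motion, > 1 when close relatives resemble each other
more than Brownian motion predicts, < 1 when less.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class PhyloCovariance:
    """Tip-by-tip shared-branch-length matrix with its tip label order."""

    matrix: np.ndarray
    labels: list[str]

    def submatrix(self, labels) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels))


def vcv_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion variance-covariance matrix of the tips.

    C[i, j] = root-to-MRCA(i, j) path length; C[i, i] = root-to-tip distance.
    """
    if tree.is_rooted is False:
        raise ValueError("tree must be rooted to define a tip covariance matrix")
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    n = len(labels)
    index = {id(lf): i for i, lf in enumerate(leaves)}

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        el = nd.edge.length if nd.edge.length is not None else 0.0
        if el < 0:
            raise ValueError("negative branch length")
        depth[id(nd)] = depth[id(nd.parent_node)] + el

    C = np.zeros((n, n))
    tips_below: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[id(nd)]
            tips_below[id(nd)] = [i]
            C[i, i] = depth[id(nd)]
            continue
        child_tips = [tips_below.pop(id(ch)) for ch in nd.child_nodes()]
        d = depth[id(nd)]
        for a in range(len(child_tips)):
            for b in range(a + 1, len(child_tips)):
                ia = np.asarray(child_tips[a])
                ib = np.asarray(child_tips[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tips_below[id(nd)] = [i for grp in child_tips for i in grp]
    return PhyloCovariance(C, labels)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda scaling: off-diagonals multiplied by lam, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = np.asarray(C, float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class BlombergResult:
    K: float
    p_perm: float
    n_perm: int


def _as_trait_vector(traits, labels: list[str]) -> np.ndarray:
    """Align a trait mapping/Series/DataFrame(species,value) to tip order."""
    if isinstance(traits, pd.DataFrame):
        traits = traits.set_index("species")["value"]
    if isinstance(traits, dict):
        traits = pd.Series(traits)
    if isinstance(traits, pd.Series):
        missing = [l for l in labels if l not in traits.index]
        extra = [l for l in traits.index if l not in labels]
        if missing or extra:
            raise ValueError(
                f"species mismatch between tree and traits; missing from "
                f"traits: {missing}, absent from tree: {extra}"
            )
        return traits.loc[labels].to_numpy(float)
    y = np.asarray(traits, float)
    if len(y) != len(labels):
        raise ValueError("trait vector length does not match tip count")
    return y


def blomberg_k(
    tree: dendropy.Tree,
    traits,
    n_perm: int = 1000,
    seed: int = 0,
) -> BlombergResult:
    """Blomberg's K with a tip-label permutation test.

    K = [MSE0/MSE] / E[MSE0/MSE] where, with a-hat the phylogenetic GLS mean,
    MSE0 is the ordinary mean squared deviation from a-hat and MSE the
    C-weighted one; the expectation term is [tr(C) - n/(1'C^-1 1)]/(n-1).
    Significance is the proportion of tip permutations whose K is at least
    the observed K, with the observed statistic counted in the null set.
    """
    cov = vcv_from_tree(tree)
    n = len(cov.labels)
    if n < 4:
        raise ValueError("need at least 4 species")
    y = _as_trait_vector(traits, cov.labels)
    C = cov.matrix
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc

    one = np.ones(n)
    a = Cinv @ one
    denom = float(one @ a)
    expected = (np.trace(C) - n / denom) / (n - 1)

    def k_batch(Y: np.ndarray) -> np.ndarray:
        # Y: (n, B) trait columns
        ahat = (a @ Y) / denom
        D = Y - ahat
        mse0 = np.einsum("ib,ib->b", D, D) / (n - 1)
        mse = np.einsum("ib,ib->b", D, Cinv @ D) / (n - 1)
        return (mse0 / mse) / expected

    k_obs = float(k_batch(y[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    k_null = k_batch(y[perms].T)
    p = (1 + int(np.sum(k_null >= k_obs))) / (n_perm + 1)
    return BlombergResult(K=k_obs, p_perm=p, n_perm=n_perm)


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the samples."""
    if not 0.0 < prob < 1.0 and prob != 1.0:
        raise ValueError("prob must lie in (0, 1]")
    s = np.sort(np.asarray(samples, float))
    n = len(s)
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R-hat across >= 2 equal-length chains.

    Uses the pooled-variance estimator var+ = (n-1)/n W + B/n and reports
    sqrt(var+/W) floored at 1 (values below 1 arise only from finite-sample
    noise, and exactly-identical chains then give exactly 1).
    """
    chains = [np.asarray(c, float) for c in chains]
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    n = len(chains[0])
    if any(len(c) != n for c in chains):
        raise ValueError("chains must have equal length")
    if n < 50:
        raise ValueError("chains too short for a stable diagnostic (need >= 50)")
    means = np.array([c.mean() for c in chains])
    W = float(np.mean([c.var(ddof=1) for c in chains]))
    B = n * float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return max(1.0, float(np.sqrt(var_plus / W)))
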