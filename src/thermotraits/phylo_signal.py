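"""Phylogenetic signal and ancestral states of continuous traits.

The thermal optimum of growth is a heritable quantity: closely related
isolates tend to have similar Topt.  This module quantifies that signal on
a rooted, branch-length-bearing phylogeny using two standard statistics,

* Pagel's lambda — a multiplier on the off-diagonal of the Brownian-motion
  phylogenetic covariance matrix, estimated by maximum likelihood on [0, 1]
  and tested against lambda = 0 with a likelihood-ratio test (chi-square,
  1 df);
* Blomberg's K — the ratio of the observed to the Brownian-expected
  mean-squared-error ratio, with a tip-shuffling permutation test;

and reconstructs ancestral trait values at internal nodes under Brownian
motion by generalized least squares (each node treated as an additional
zero-length tip of the multivariate-normal model).

Trees are `dendropy` objects; traits are mappings from tip label to value.
Topt is conventionally log-transformed (natural log of the Celsius value)
before signal estimation because its distribution across isolates is
right-skewed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SignalEstimate",
    "ASRResult",
    "parse_newick",
    "write_newick",
    "tip_labels",
    "phylo_covariance",
    "node_covariance_row",
    "align_trait",
    "estimate_lambda",
    "blomberg_k",
    "ancestral_states_bm",
]


@dataclass
class SignalEstimate:
    """A phylogenetic-signal statistic with its test."""

    statistic: str  # "lambda" or "K"
    value: float
    p_value: float | None
    n_tips: int
    log_likelihood: float | None = None  # lambda only
    log_likelihood_null: float | None = None
    n_permutations: int | None = None  # K only
    seed: int | None = None


@dataclass
class ASRResult:
    """Brownian-motion ancestral state reconstruction."""

    node_states: dict[str, float]
    node_variances: dict[str, float]
    sigma2_hat: float
    root_state: float


# ---------------------------------------------------------------------------
# tree I/O and covariance


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {', '.join(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                "missing branch length on edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'}"
            )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to newick with branch lengths."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def phylo_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion covariance matrix of the tips (shared path lengths).

    Entry (i, j) is the root-to-MRCA distance of tips i and j; the diagonal
    holds root-to-tip distances.  Polytomies are handled naturally.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    cov = np.zeros((n, n))
    # accumulate shared depth clade by clade: every pair of tips descending
    # through different children of a node has that node as its MRCA
    index = {leaf: i for i, leaf in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [index[node]]
            continue
        children = [c._tipset for c in node.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        cov[i, j] = cov[j, i] = depths[node]
        merged = [i for ts in children for i in ts]
        node._tipset = merged
    for leaf in leaves:
        cov[index[leaf], index[leaf]] = depths[leaf]
    for node in tree.postorder_node_iter():
        if hasattr(node, "_tipset"):
            del node._tipset
    return pd.DataFrame(cov, index=labels, columns=labels)


def node_covariance_row(tree: dendropy.Tree, node: dendropy.Node) -> pd.Series:
    """Covariance of an internal node's state with every tip.

    cov(node, tip) = depth of the MRCA of the node and that tip, i.e. the
    node's own depth for tips descending from it.
    """
    depths = _node_depths(tree)
    ancestors = []
    u = node
    while u is not None:
        ancestors.append(u)
        u = u.parent_node
    anc_set = {id(a): depths[a] for a in ancestors}
    out = {}
    for leaf in tree.leaf_node_iter():
        v = leaf
        while id(v) not in anc_set:
            v = v.parent_node
        out[leaf.taxon.label] = anc_set[id(v)]
    return pd.Series(out)


def align_trait(
    tree: dendropy.Tree,
    trait: "pd.Series | dict[str, float]",
    transform: str = "identity",
    strict: bool = True,
) -> pd.Series:
    """Align a trait vector to the tree's tips, optionally log-transforming.

    ``transform`` is ``"identity"`` or ``"log"`` (natural log; values must
    be positive).  In strict mode any mismatch between tree tips and trait
    keys is an error; otherwise unmatched entries are dropped with a
    warning (but every tip must still be covered).
    """
    trait = pd.Series(trait, dtype=float)
    labels = tip_labels(tree)
    missing = [l for l in labels if l not in trait.index]
    extra = [k for k in trait.index if k not in labels]
    if missing:
        raise ValueError(f"trait values missing for tips: {', '.join(missing)}")
    if extra:
        if strict:
            raise ValueError(f"trait keys not on the tree: {', '.join(extra)}")
        logger.warning("dropping %d trait entries not on the tree", len(extra))
    x = trait.loc[labels]
    if x.isna().any():
        raise ValueError("trait contains missing values")
    if transform == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive trait values")
        x = np.log(x)
    elif transform != "identity":
        raise ValueError(f"unknown transform: {transform!r}")
    return x


# ---------------------------------------------------------------------------
# signal statistics


def _lambda_transform(cov: np.ndarray, lam: float) -> np.ndarray:
    c = cov * lam
    np.fill_diagonal(c, np.diag(cov))
    return c


def _gls_loglik(x: np.ndarray, cov: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of an MVN with mean mu*1 and covariance
    sigma2 * cov; returns (logL, mu_hat, sigma2_hat)."""
    n = len(x)
    cf = linalg.cho_factor(cov, lower=True)
    ones = np.ones(n)
    ci_x = linalg.cho_solve(cf, x)
    ci_1 = linalg.cho_solve(cf, ones)
    mu = float(ones @ ci_x) / float(ones @ ci_1)
    r = x - mu
    sigma2 = float(r @ linalg.cho_solve(cf, r)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 <= 0:
        # constant trait: degenerate, likelihood unbounded; report +inf-free
        return math.inf, mu, 0.0
    ll = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdet + n)
    return ll, mu, sigma2


def estimate_lambda(
    tree: dendropy.Tree,
    trait: "pd.Series | dict[str, float]",
    transform: str = "identity",
) -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    lambda scales the off-diagonal of the phylogenetic covariance matrix;
    the multivariate-normal likelihood (mean and rate profiled out by GLS)
    is maximised over lambda in [0, 1] and compared with the lambda = 0
    (star-phylogeny) model via 2*(l1 - l0) against chi-square(1 df).
    """
    x = align_trait(tree, trait, transform=transform).to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 tips required")
    cov = phylo_covariance(tree).to_numpy()

    def negll(lam: float) -> float:
        try:
            ll, _, _ = _gls_loglik(x, _lambda_transform(cov, lam))
        except linalg.LinAlgError as exc:
            raise RuntimeError(f"singular covariance at lambda={lam}: {exc}")
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the bounded optimiser never evaluates the exact endpoints; snap to
    # whichever endpoint improves the likelihood
    for endpoint in (0.0, 1.0):
        ll_end = -negll(endpoint)
        if ll_end >= ll_hat - 1e-10 and abs(lam_hat - endpoint) < 1e-4:
            lam_hat, ll_hat = endpoint, max(ll_hat, ll_end)
    ll0 = -negll(0.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SignalEstimate(
        statistic="lambda",
        value=lam_hat,
        p_value=p,
        n_tips=n,
        log_likelihood=ll_hat,
        log_likelihood_null=ll0,
    )


def _k_statistic(x: np.ndarray, cov: np.ndarray, cho, ci_1: np.ndarray,
                 expected_ratio: float) -> float:
    n = len(x)
    ones = np.ones(n)
    mu = float(ones @ linalg.cho_solve(cho, x)) / float(ones @ ci_1)
    r = x - mu
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ linalg.cho_solve(cho, r)) / (n - 1)
    if mse == 0:
        return math.inf
    return (mse0 / mse) / expected_ratio


def blomberg_k(
    tree: dendropy.Tree,
    trait: "pd.Series | dict[str, float]",
    n_permutations: int | None = 999,
    seed: int | None = None,
    transform: str = "identity",
) -> SignalEstimate:
    """Blomberg's K with a tip-shuffling permutation test.

    K is the observed MSE0/MSE ratio (tip variance about the phylogenetic
    mean over the GLS variance) divided by its Brownian-motion expectation
    (tr(V) - n / sum(V^-1)) / (n - 1); K = 1 is the Brownian level.  The
    one-sided upper-tail p-value counts permutations (plus the observed
    arrangement) with K at least as large as observed.  Pass
    ``n_permutations=None`` to skip the test (p is then ``None``).
    """
    x = align_trait(tree, trait, transform=transform).to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 tips required")
    if n_permutations is not None and n_permutations < 99:
        raise ValueError("use at least 99 permutations (or None to skip)")
    cov = phylo_covariance(tree).to_numpy()
    cho = linalg.cho_factor(cov, lower=True)
    ones = np.ones(n)
    ci_1 = linalg.cho_solve(cho, ones)
    expected = (float(np.trace(cov)) - n / float(ones @ ci_1)) / (n - 1)
    k_obs = _k_statistic(x, cov, cho, ci_1, expected)

    p = None
    if n_permutations is not None:
        rng = np.random.default_rng(seed)
        hits = 1  # the observed arrangement counts
        for _ in range(n_permutations):
            k_perm = _k_statistic(rng.permutation(x), cov, cho, ci_1, expected)
            if k_perm >= k_obs:
                hits += 1
        p = hits / (n_permutations + 1)
    return SignalEstimate(
        statistic="K",
        value=k_obs,
        p_value=p,
        n_tips=n,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ancestral states


def ancestral_states_bm(
    tree: dendropy.Tree,
    trait: "pd.Series | dict[str, float]",
    transform: str = "identity",
) -> ASRResult:
    """Maximum-likelihood ancestral states under Brownian motion.

    Each internal node is treated as an extra zero-length tip of the
    multivariate normal defined by the phylogenetic covariance; its state
    estimate is the GLS prediction

        a_u = mu + c_u' V^-1 (x - mu)

    with mu the GLS phylogenetic mean and c_u the node-tip covariance row,
    and its variance includes the uncertainty of mu.  Internal nodes are
    labelled ``node{i}`` in preorder (the root is ``node0``) unless they
    already carry labels.
    """
    x_s = align_trait(tree, trait, transform=transform)
    x = x_s.to_numpy()
    n = len(x)
    if n < 2:
        raise ValueError("at least 2 tips required")
    cov_df = phylo_covariance(tree)
    cov = cov_df.to_numpy()
    try:
        cho = linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise RuntimeError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(n)
    ci_x = linalg.cho_solve(cho, x)
    ci_1 = linalg.cho_solve(cho, ones)
    denom = float(ones @ ci_1)
    mu = float(ones @ ci_x) / denom
    r = x - mu
    ci_r = linalg.cho_solve(cho, r)
    sigma2 = float(r @ ci_r) / n

    depths = _node_depths(tree)
    states: dict[str, float] = {}
    variances: dict[str, float] = {}
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        label = node.label or f"node{i}"
        c_u = node_covariance_row(tree, node).loc[cov_df.index].to_numpy()
        a_u = mu + float(c_u @ ci_r)
        ci_c = linalg.cho_solve(cho, c_u)
        mean_adj = (1.0 - float(ones @ ci_c)) ** 2 / denom
        var_u = sigma2 * max(
            0.0, depths[node] - float(c_u @ ci_c) + mean_adj
        )
        states[label] = a_u
        variances[label] = var_u

    root_label = tree.seed_node.label or "node0"
    return ASRResult(
        node_states=states,
        node_variances=variances,
        sigma2_hat=sigma2,
        root_state=states[root_label],
    )
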