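"""Phylogenetically controlled trait correlation under Brownian motion.

Species traits cannot be treated as independent observations; shared ancestry
induces covariance proportional to shared branch length. Felsenstein's
standardized independent contrasts remove that covariance under a Brownian
model, and the correlation of two traits' contrast series (through the
origin) is the ML estimate of the evolutionary correlation. The evidence
statistic for correlated versus independent bivariate Brownian motion is the
likelihood-ratio statistic -k·ln(1 - rho^2) in ML mode, or, mirroring the
Bayes-factor convention 2·Δ(log harmonic-mean likelihood), a seeded
Metropolis chain in MCMC mode. Evidence classes: weak (< 2), positive (2-5),
strong (5-10), very strong (> 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import logsumexp


@dataclass
class CorrelationEvidence:
    statistic: float
    rho_hat: float
    evidence_class: str
    mode: str
    k: int                  # number of contrasts
    infinite: bool = False  # |rho_hat| = 1


def evidence_class(statistic: float) -> str:
    if statistic < 2:
        return "weak"
    if statistic <= 5:
        return "positive"
    if statistic <= 10:
        return "strong"
    return "very strong"


def load_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


def _prepared_tree(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.resolve_polytomies()  # arbitrary resolution with zero-length branches
    return t


def independent_contrasts(tree: dendropy.Tree, trait: dict) -> np.ndarray:
    """Standardized Felsenstein contrasts of a tip-keyed trait dict.

    Each of the n - 1 contrasts is the difference of the two daughter values
    divided by sqrt of its expected variance (sum of gap-adjusted branch
    lengths). Polytomies are resolved arbitrarily with zero-length branches.
    Raises ValueError naming any tip/trait mismatches.
    """
    t = _prepared_tree(tree)
    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = tips - set(trait)
    extra = set(trait) - tips
    if missing or extra:
        raise ValueError(
            f"tip/trait mismatch: missing traits for {sorted(missing)}, "
            f"traits without tips {sorted(extra)}")
    contrasts = []
    state = {}  # node -> (value, accumulated variance)
    for node in t.postorder_node_iter():
        bl = node.edge.length or 0.0
        if node.is_leaf():
            state[node] = (float(trait[node.taxon.label]), bl)
            continue
        children = node.child_nodes()
        x1, v1 = state[children[0]]
        x2, v2 = state[children[1]]
        var = v1 + v2
        if var <= 0:
            contrasts.append(0.0 if x1 == x2 else np.inf * np.sign(x1 - x2))
            state[node] = (0.5 * (x1 + x2), bl)
            continue
        contrasts.append((x1 - x2) / np.sqrt(var))
        xnode = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 \
            else (x1 if v2 > 0 else x2)
        state[node] = (xnode, bl + v1 * v2 / var)
    return np.array(contrasts)


def _contrast_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Correlation of two contrast series through the origin."""
    denom = np.sqrt((u ** 2).sum() * (v ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((u * v).sum() / denom, -1.0, 1.0))


def _bm_loglik(S: np.ndarray, k: int, s1: float, s2: float,
               rho: float) -> float:
    """Log-likelihood of k bivariate standardized contrasts ~ N(0, R)."""
    det = s1 * s2 * (1.0 - rho ** 2)
    if det <= 0:
        return -np.inf
    inv00 = s2 / det
    inv11 = s1 / det
    inv01 = -rho * np.sqrt(s1 * s2) / det
    tr = inv00 * S[0, 0] + inv11 * S[1, 1] + 2 * inv01 * S[0, 1]
    return -0.5 * k * (2 * np.log(2 * np.pi) + np.log(det)) - 0.5 * tr


def _harmonic_mean_loglik(S, k, correlated: bool, rng, steps: int,
                          burnin_frac: float = 0.1) -> float:
    """Log harmonic-mean likelihood from a Metropolis chain.

    Parameters are (log s1, log s2[, atanh rho]); flat priors on these
    transformed scales within wide bounds.
    """
    theta = np.array([np.log(S[0, 0] / k), np.log(S[1, 1] / k), 0.0])
    dim = 3 if correlated else 2

    def ll(th):
        rho = np.tanh(th[2]) if correlated else 0.0
        return _bm_loglik(S, k, np.exp(th[0]), np.exp(th[1]), rho)

    cur = ll(theta)
    kept = []
    scale = 0.15
    burn = int(steps * burnin_frac)
    for i in range(steps):
        prop = theta.copy()
        j = rng.integers(dim)
        prop[j] += rng.normal(0, scale)
        if abs(prop[0]) > 30 or abs(prop[1]) > 30 or abs(prop[2]) > 8:
            new = -np.inf
        else:
            new = ll(prop)
        if np.log(rng.random()) < new - cur:
            theta, cur = prop, new
        if i >= burn:
            kept.append(cur)
    kept = np.array(kept)
    # log harmonic mean: log m - logsumexp(-ll)
    return float(np.log(len(kept)) - logsumexp(-kept))


def bm_correlation_evidence(tree, trait_x: dict, trait_y: dict,
                            mode: str = "ml", seed=None,
                            mcmc_steps: int = 100_000) -> CorrelationEvidence:
    """Evidence for correlated Brownian evolution of two traits on a tree.

    ML mode: statistic = -k·ln(1 - rho_hat^2), the likelihood-ratio statistic
    of correlated vs independent bivariate Brownian motion, with rho_hat the
    through-origin correlation of the contrast series. MCMC mode: statistic =
    2·(log harmonic-mean likelihood of the correlated model - independent
    model) from seeded Metropolis chains.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 4:
        raise ValueError("need at least 4 tips")
    u = independent_contrasts(tree, trait_x)
    v = independent_contrasts(tree, trait_y)
    k = len(u)
    rho = _contrast_correlation(u, v)
    if abs(rho) >= 1.0:
        return CorrelationEvidence(np.inf, rho, "very strong", mode, k,
                                   infinite=True)
    if mode == "ml":
        stat = -k * np.log(1.0 - rho ** 2)
    elif mode == "mcmc":
        rng = np.random.default_rng(seed)
        S = np.array([[(u ** 2).sum(), (u * v).sum()],
                      [(u * v).sum(), (v ** 2).sum()]])
        hm_c = _harmonic_mean_loglik(S, k, True, rng, mcmc_steps)
        hm_s = _harmonic_mean_loglik(S, k, False, rng, mcmc_steps)
        stat = 2.0 * (hm_c - hm_s)
    else:
        raise ValueError("mode must be 'ml' or 'mcmc'")
    return CorrelationEvidence(float(stat), rho, evidence_class(stat),
                               mode, k)


def trait_table_on_tree(tree, table, columns=None):
    """Intersect a species-indexed DataFrame with tree tips.

    Species absent from the tree (or tips without rows) are dropped with a
    warning; returns (pruned_tree, aligned_table).
    """
    import warnings

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    have = set(table.index)
    common = sorted(tips & have)
    dropped = sorted((tips | have) - set(common))
    if dropped:
        warnings.warn(f"dropping species without both tree and traits: "
                      f"{dropped}")
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(common)
    sub = table.loc[common, columns] if columns else table.loc[common]
    return t, sub
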