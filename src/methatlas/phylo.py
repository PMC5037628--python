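"""Cross-species statistics: PGLS under Brownian motion, Bonferroni
control, and TE-proximity Fisher enrichment.

Species are not independent observations: closely related species are
more alike.  Phylogenetic generalized least squares (PGLS) corrects a
regression of one species-level trait on another by giving the
residuals the Brownian-motion covariance implied by the phylogeny —
``V[i, j]`` is the shared branch length from the root down to the most
recent common ancestor of tips i and j.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def brownian_covariance(tree, tips=None) -> pd.DataFrame:
    """Brownian-motion covariance matrix of tip values on a tree.

    V[i][j] is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths.  Branch lengths must be
    non-negative; a missing root edge counts as zero.
    """
    t = _as_tree(tree)
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    labels = []
    depth = {}
    below: dict = {}
    # node depths from the root
    for node in t.preorder_node_iter():
        el = node.edge.length or 0.0
        depth[node] = (depth[node.parent_node] if node.parent_node else 0.0) + el
    order = {}
    for node in t.leaf_node_iter():
        label = node.taxon.label if node.taxon else str(node)
        order[label] = len(labels)
        labels.append(label)
    n = len(labels)
    V = np.zeros((n, n))
    for node in t.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else str(node)
            i = order[label]
            below[node] = [i]
            V[i, i] = depth[node]
        else:
            kids = [below[c] for c in node.child_nodes()]
            merged = []
            for a_i, a in enumerate(kids):
                for b in kids[a_i + 1 :]:
                    for i in a:
                        for j in b:
                            V[i, j] = V[j, i] = depth[node]
                merged.extend(a)
            below[node] = merged
    df = pd.DataFrame(V, index=labels, columns=labels)
    if tips is not None:
        tips = list(tips)
        missing = set(tips) - set(labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        df = df.loc[tips, tips]
    return df


@dataclass
class PGLSResult:
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    df: int


def pgls_fit(x, y, V, allow_pinv: bool = False) -> PGLSResult:
    """GLS regression of y on x with error covariance V.

    beta = (X' V^-1 X)^-1 X' V^-1 y with X = [1, x]; the slope p-value
    comes from a t-statistic with n - 2 degrees of freedom using the
    unbiased GLS residual variance.  With V = c*I this reduces exactly
    to ordinary least squares.  A singular V raises unless
    ``allow_pinv`` opts into a pseudo-inverse (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    V = np.asarray(V, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if V.shape != (n, n):
        raise ValueError("V must be n x n")
    X = np.column_stack([np.ones(n), x])
    try:
        L = np.linalg.cholesky(V)
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
    except np.linalg.LinAlgError:
        if not allow_pinv:
            raise
        import warnings

        warnings.warn("V is singular; using pseudo-inverse")
        Vi = np.linalg.pinv(V)
        # whiten via symmetric square root of the pseudo-inverse
        w, U = np.linalg.eigh(Vi)
        W = U @ np.diag(np.sqrt(np.clip(w, 0, None))) @ U.T
        Xw = W @ X
        yw = W @ y
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    t = float(beta[1] / se) if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof))
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=se,
        t_stat=t,
        p_value=p,
        df=dof,
    )


def pgls_trait_test(traits: pd.DataFrame, tree, x: str, y: str) -> PGLSResult:
    """PGLS of trait ``y`` on trait ``x`` with tree-derived covariance."""
    V = brownian_covariance(tree, tips=list(traits.index))
    return pgls_fit(traits[x].to_numpy(), traits[y].to_numpy(), V.to_numpy())


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def te_enrichment(
    gene_classes: pd.Series,
    te_flags: pd.DataFrame,
    classes=("gbM", "mCHG", "mCHH"),
    positions=("upstream", "within", "downstream"),
) -> pd.DataFrame:
    """Fisher's exact TE enrichment per gene class and position.

    Each class is tested against the background of *all* genes: the
    2x2 table crosses (class members vs all genes) with (TE-flagged vs
    not).  Two-sided, so depletion registers as well as enrichment.
    Empty classes are skipped with a diagnostic row.
    """
    gene_classes = gene_classes.reindex(te_flags.index)
    n_all = len(te_flags)
    rows = []
    for cls in classes:
        members = te_flags[gene_classes == cls]
        for pos in positions:
            if len(members) == 0:
                rows.append(
                    {
                        "gene_class": cls,
                        "position": pos,
                        "n_class": 0,
                        "odds_ratio": np.nan,
                        "p_value": np.nan,
                        "note": "empty class",
                    }
                )
                continue
            a = int(members[pos].sum())
            b = len(members) - a
            c = int(te_flags[pos].sum())
            d = n_all - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            if b * c > 0:
                odds = (a * d) / (b * c)
            elif a * d > 0:
                odds = np.inf  # degenerate cell: all class genes flagged
            else:
                odds = np.nan
            rows.append(
                {
                    "gene_class": cls,
                    "position": pos,
                    "n_class": len(members),
                    "n_flagged": a,
                    "background_flagged": c,
                    "odds_ratio": float(odds),
                    "p_value": float(p),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
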