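"""Cross-species comparative statistics.

Phylogenetically independent contrasts (Felsenstein), PIC-corrected
correlations, Ne-dissimilarity vs. phylogenetic distance (Mantel),
lifestyle rank-sum contrasts, and the PCA / correlation-network summary of
the species trait table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import ranksums, spearmanr, t as t_dist

from .io import Lifestyle
from .treeutil import index_tree, patristic_distances


@dataclass
class ContrastSet:
    node_ids: list[str]
    contrasts: np.ndarray
    standardizing_lengths: np.ndarray  # b_i + b_j per contrast


def _prepare_tree(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    keep = [tx for tx in t.taxon_namespace if tx.label in taxa]
    if len(keep) < len(taxa):
        have = {tx.label for tx in t.taxon_namespace}
        raise ValueError(f"tree lacks taxa: {sorted(taxa - have)}")
    t.retain_taxa(keep)
    t.resolve_polytomies()
    # zero/missing branch lengths break the standardization: replace with
    # the 1st percentile of positive lengths
    pos = [e.length for e in t.edges() if e.length and e.length > 0]
    floor = float(np.percentile(pos, 1)) if pos else 1e-8
    for e in t.edges():
        if e.head_node.parent_node is not None and not (e.length and e.length > 0):
            e.length = floor
    return t


def pic_contrasts(tree: dendropy.Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's independent contrasts for one trait.

    Leaves without trait values are pruned.  At each internal node of the
    (resolved, bifurcating) tree the contrast is (x_i - x_j)/sqrt(b_i+b_j);
    the nodal value is the b-weighted average and the parent branch is
    extended by b_i*b_j/(b_i+b_j).
    """
    taxa = {k for k, v in trait.items() if v is not None and math.isfinite(v)}
    if len(taxa) < 2:
        raise ValueError("need >= 2 species with trait values")
    t = _prepare_tree(tree, taxa)
    ti = index_tree(t)
    x = np.zeros(ti.n_nodes)
    b = ti.blen.astype(float).copy()
    node_ids, contrasts, stds = [], [], []
    for i in ti.postorder:
        kids = ti.children[i]
        if not kids:
            x[i] = trait[ti.leaf_labels[i]]
            continue
        if len(kids) != 2:  # resolved above; defensive
            raise RuntimeError("non-binary node after polytomy resolution")
        a, c = kids
        vs = b[a] + b[c]
        contrasts.append((x[a] - x[c]) / math.sqrt(vs))
        stds.append(vs)
        node_ids.append(f"n{i}")
        x[i] = (x[a] / b[a] + x[c] / b[c]) / (1 / b[a] + 1 / b[c])
        b[i] += b[a] * b[c] / vs
    return ContrastSet(node_ids, np.asarray(contrasts), np.asarray(stds))


def _pearson_through_origin(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Correlation constrained through the origin with its two-sided p."""
    denom = math.sqrt(float((u * u).sum() * (v * v).sum()))
    if denom == 0:
        return math.nan, math.nan
    r = float((u * v).sum()) / denom
    n = len(u)
    df = n - 1
    if df < 1 or abs(r) >= 1:
        return r, 0.0 if abs(r) >= 1 else math.nan
    ts = r * math.sqrt(df / (1 - r * r))
    p = 2 * t_dist.sf(abs(ts), df)
    return r, float(p)


def pic_correlation(
    tree: dendropy.Tree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlation of two traits over matched PIC contrasts.

    ``spearman``: rank correlation of the contrast pairs (the style of
    "Spearman's rho, PIC correction").  ``pearson``: correlation through
    the origin, the orthodox PIC statistic.
    """
    shared = {
        k for k in x
        if k in y
        and x[k] is not None and y[k] is not None
        and math.isfinite(x[k]) and math.isfinite(y[k])
    }
    if len(shared) < 4:
        raise ValueError("need >= 4 species shared between traits")
    t = _prepare_tree(tree, shared)
    cx = pic_contrasts(t, {k: x[k] for k in shared})
    cy = pic_contrasts(t, {k: y[k] for k in shared})
    assert cx.node_ids == cy.node_ids
    if method == "pearson":
        r, p = _pearson_through_origin(cx.contrasts, cy.contrasts)
    elif method == "spearman":
        r, p = spearmanr(cx.contrasts, cy.contrasts)
        r, p = float(r), float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, p, len(cx.contrasts)


def ne_dissimilarity_vs_distance(
    tree: dendropy.Tree,
    ne: Mapping[str, float],
    permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """|Ne_i - Ne_j| against patristic distance over all species pairs.

    Emits the plain Spearman rho/p over pairs plus a Mantel permutation p
    (pairs are not independent).  rho is None when either vector is
    constant.
    """
    species = sorted(k for k, v in ne.items() if v is not None and math.isfinite(v))
    if len(species) < 3:
        raise ValueError("need >= 3 species")
    t = _prepare_tree(tree, set(species))
    labels, dmat = patristic_distances(t)
    pos = {s: i for i, s in enumerate(labels)}
    dists, dissim = [], []
    for a, b in combinations(species, 2):
        dists.append(dmat[pos[a], pos[b]])
        dissim.append(abs(ne[a] - ne[b]))
    dists = np.asarray(dists)
    dissim = np.asarray(dissim)
    out = {"pairs": list(combinations(species, 2)), "distance": dists, "dissimilarity": dissim}
    if np.ptp(dissim) == 0 or np.ptp(dists) == 0:
        out.update(rho=None, p_value=None, mantel_p=None)
        return out
    rho, p = spearmanr(dists, dissim)
    out.update(rho=float(rho), p_value=float(p))

    # Mantel permutation on the species labels of the dissimilarity side
    rng = np.random.default_rng(seed)
    n = len(species)
    dis_mat = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(species)}
    for (a, b), v in zip(out["pairs"], dissim):
        dis_mat[idx[a], idx[b]] = dis_mat[idx[b], idx[a]] = v
    d_full = np.zeros((n, n))
    for (a, b), v in zip(out["pairs"], dists):
        d_full[idx[a], idx[b]] = d_full[idx[b], idx[a]] = v
    iu = np.triu_indices(n, 1)
    obs = spearmanr(d_full[iu], dis_mat[iu]).statistic
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r = spearmanr(d_full[iu], dis_mat[perm][:, perm][iu]).statistic
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
    out["mantel_p"] = (hits + 1) / (permutations + 1)
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def lifestyle_comparison(
    table: pd.DataFrame,
    value_column: str = "ne_relative",
    min_group: int = 3,
    exclude: tuple[str, ...] = (Lifestyle.PLANT_PATHOGEN.value, Lifestyle.UNKNOWN.value),
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between lifestyle groups.

    Returns a long-format frame (group_a, group_b, n_a, n_b, p, stars,
    p_holm).  Plant pathogens (ambiguous lifestyle) and unknowns are
    excluded; groups below ``min_group`` species are skipped.
    """
    df = table.dropna(subset=[value_column])
    df = df[~df["lifestyle"].isin(exclude)]
    groups = {
        name: g[value_column].to_numpy()
        for name, g in df.groupby("lifestyle")
        if len(g) >= min_group
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 lifestyle groups with enough species")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        stat, p = ranksums(groups[a], groups[b])
        rows.append({"group_a": a, "group_b": b, "n_a": len(groups[a]),
                     "n_b": len(groups[b]), "statistic": float(stat),
                     "p": float(p), "stars": _stars(p)})
    out = pd.DataFrame(rows)
    # Holm adjustment alongside the raw p values
    order = np.argsort(out["p"].values)
    m = len(out)
    holm = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * out["p"].values[i])
        holm[i] = min(1.0, running)
    out["p_holm"] = holm
    return out


def pca_and_network(
    table: pd.DataFrame,
    columns: Optional[list[str]] = None,
    p_cutoff: float = 0.01,
) -> dict:
    """PCA of z-scored quantitative traits plus the Spearman network.

    Returns loadings, explained variance ratios, the Spearman correlation
    and p-value matrices, and the retained network edges (p <= cutoff,
    weight -log10(p)).  Constant columns are dropped; rows with missing
    values are dropped per analysis.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    num = table[columns].astype(float)
    keep = [c for c in columns if num[c].dropna().nunique() > 1]
    if len(keep) < 3:
        raise ValueError("need >= 3 non-constant numeric columns")
    complete = num[keep].dropna()
    z = (complete - complete.mean()) / complete.std(ddof=1)
    cov = np.cov(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    explained = evals / evals.sum()

    k = len(keep)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    edges = []
    for i, j in combinations(range(k), 2):
        sub = num[[keep[i], keep[j]]].dropna()
        r, p = spearmanr(sub[keep[i]], sub[keep[j]])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
        if p <= p_cutoff:
            edges.append((keep[i], keep[j], float(r), float(-math.log10(max(p, 1e-300)))))
    return {
        "columns": keep,
        "loadings": pd.DataFrame(evecs, index=keep,
                                 columns=[f"PC{i+1}" for i in range(k)]),
        "explained_variance_ratio": explained,
        "spearman_rho": pd.DataFrame(rho, index=keep, columns=keep),
        "spearman_p": pd.DataFrame(pmat, index=keep, columns=keep),
        "edges": edges,
        "n_rows_pca": len(complete),
    }
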