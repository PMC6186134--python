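"""Per-branch gene gain/loss inference and turnover vs. selection efficiency.

Gene family presence/absence evolves as a two-state continuous-time Markov
chain (absent->present at the gain rate, present->absent at the loss rate).
Rates are fitted by maximum likelihood with Felsenstein pruning over all
families, conditioning on families being observable (present in >=1
strain).  Per-branch events are called from marginal ancestral posteriors
at a certainty threshold; turnover T = gains/losses per branch is then
correlated with a per-branch dS/dN obtained from marginal nucleotide-level
ancestral reconstruction and NG86 counting on core-genome fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .codon import CODON_INDEX, N_SITES, NONSYN_DIFFS, S_SITES, SYN_DIFFS
from .io import GeneFamilyMatrix
from .treeutil import TreeIndex, index_tree

_LOG_RATE_BOUNDS = (-12.0, 6.0)
DEFAULT_THRESHOLD = 0.2
FRAGMENT_LENGTH = 150_000


@dataclass
class GainLossModel:
    """Fitted gene gain/loss model.

    ``gain_rate`` is the genome-wide intensity of new-family gains per unit
    branch length (infinitely-many-genes convention); ``loss_rate`` is the
    per-family loss rate; ``root_intensity`` the expected number of families
    present at the root.  ``root_prior`` is the probability that a randomly
    chosen observable family originated at the root.
    """

    gain_rate: float
    loss_rate: float
    root_prior: float
    log_likelihood: float
    root_intensity: float = 0.0
    n_families: int = 1
    at_boundary: bool = False

    @property
    def per_family_gain_rate(self) -> float:
        """Gain intensity apportioned per observed family (for the two-state
        chain used in ancestral reconstruction)."""
        return self.gain_rate / max(self.n_families, 1)


@dataclass
class BranchFluxRecord:
    branch_id: str
    gains: float
    losses: float
    turnover: Optional[float]
    branch_dsdn: Optional[float] = None
    n_gain_events: int = 0
    n_loss_events: int = 0
    branch_length: float = 0.0


def _transition_matrices(ti: TreeIndex, gain: float, loss: float) -> np.ndarray:
    """2x2 transition matrix for the edge above every node. State 0=absent."""
    r = gain + loss
    t = ti.blen
    if r <= 0:
        return np.tile(np.eye(2), (ti.n_nodes, 1, 1))
    e = np.exp(-r * t)
    P = np.empty((ti.n_nodes, 2, 2))
    P[:, 0, 0] = (loss + gain * e) / r
    P[:, 0, 1] = gain * (1 - e) / r
    P[:, 1, 0] = loss * (1 - e) / r
    P[:, 1, 1] = (gain + loss * e) / r
    return P


def _node_names(ti: TreeIndex) -> list[str]:
    """Stable branch ids: leaf label, or sorted leaf-set-derived internal id."""
    names: list[str] = [""] * ti.n_nodes
    below: list[list[str]] = [[] for _ in range(ti.n_nodes)]
    for i in ti.postorder:
        if not ti.children[i]:
            names[i] = ti.leaf_labels[i] or f"leaf{i}"
            below[i] = [names[i]]
        else:
            for k in ti.children[i]:
                below[i].extend(below[k])
            below[i].sort()
            names[i] = f"node[{below[i][0]}..{below[i][-1]}|{len(below[i])}]"
    return names


def _leaf_partials(ti: TreeIndex, matrix: GeneFamilyMatrix) -> np.ndarray:
    """(n_nodes, n_fam, 2) conditional likelihood array initialized at leaves."""
    strain_pos = {s: i for i, s in enumerate(matrix.strain_ids)}
    n_fam = len(matrix.family_ids)
    up = np.ones((ti.n_nodes, n_fam, 2))
    for node, lab in enumerate(ti.leaf_labels):
        if lab is None:
            continue
        if lab not in strain_pos:
            raise ValueError(f"tree leaf {lab!r} absent from family matrix")
        present = matrix.presence[strain_pos[lab]].astype(bool)
        up[node, :, 0] = ~present
        up[node, :, 1] = present
    return up


def _pruning_up(ti: TreeIndex, up: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Run the upward pass in place; returns messages M[k] = P_k @ up[k]."""
    msg = np.empty_like(up)
    for i in ti.postorder:
        kids = ti.children[i]
        if not kids:
            msg[i] = up[i] @ P[i].T
            continue
        acc = np.ones_like(up[i])
        for k in kids:
            acc *= msg[k]
        up[i] = acc
        msg[i] = acc @ P[i].T if ti.parent[i] >= 0 else acc
    return msg


def gain_loss_log_likelihood(
    tree: dendropy.Tree | TreeIndex,
    matrix: GeneFamilyMatrix,
    gain_rate: float,
    loss_rate: float,
) -> float:
    """Observable-conditioned log-likelihood of the presence/absence matrix."""
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    P = _transition_matrices(ti, gain_rate, loss_rate)
    r = gain_rate + loss_rate
    prior = np.array([loss_rate / r, gain_rate / r]) if r > 0 else np.array([0.5, 0.5])

    up = _leaf_partials(ti, matrix)
    _pruning_up(ti, up, P)
    lik = up[ti.root] @ prior
    if np.any(lik <= 0):
        return -np.inf

    # probability a family is absent from every leaf (unobservable)
    ghost = GeneFamilyMatrix(
        matrix.strain_ids, ["ghost"],
        np.zeros((len(matrix.strain_ids), 1), dtype=np.int8),
    )
    up0 = _leaf_partials(ti, ghost)
    _pruning_up(ti, up0, P)
    p_unobs = float(up0[ti.root, 0] @ prior)
    if p_unobs >= 1.0:
        return -np.inf
    return float(np.log(lik).sum() - len(matrix.family_ids) * math.log1p(-p_unobs))


def _img_structures(ti: TreeIndex, matrix: GeneFamilyMatrix):
    """Static per-family arrays used by the gain/loss Poisson-field likelihood."""
    strain_pos = {s: i for i, s in enumerate(matrix.strain_ids)}
    n_fam = len(matrix.family_ids)
    present = np.zeros((ti.n_nodes, n_fam), dtype=bool)
    for node, lab in enumerate(ti.leaf_labels):
        if lab is None:
            continue
        if lab not in strain_pos:
            raise ValueError(f"tree leaf {lab!r} absent from family matrix")
        present[node] = matrix.presence[strain_pos[lab]].astype(bool)
    count_below = np.zeros((ti.n_nodes, n_fam), dtype=np.int64)
    for i in ti.postorder:
        if not ti.children[i]:
            count_below[i] = present[i]
        else:
            for k in ti.children[i]:
                count_below[i] += count_below[k]
    total = count_below[ti.root]
    if np.any(total == 0):
        raise ValueError("matrix contains families absent from every strain")
    return present, count_below, total


def img_log_likelihood(
    tree: dendropy.Tree | TreeIndex,
    matrix: GeneFamilyMatrix,
    root_intensity: float,
    gain_rate: float,
    loss_rate: float,
    _structures=None,
) -> float:
    """Poisson-random-field log-likelihood of observed family patterns.

    New families arise along branches with intensity ``gain_rate`` per unit
    length (each gain creates a novel family); Poisson(``root_intensity``)
    families exist at the root; each family is lost at ``loss_rate``
    (re-gain of a lost family has probability zero, matching the
    infinitely-many-genes convention).  Conditioned on observability via
    the Poisson-field normalizer over non-empty patterns.
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    present, count_below, total = (
        _structures if _structures is not None else _img_structures(ti, matrix)
    )
    l = max(loss_rate, 1e-12)
    surv = np.exp(-l * ti.blen)
    n_fam = present.shape[1]

    A = np.zeros((ti.n_nodes, n_fam))  # P(pattern below i | present at i)
    Q = np.zeros(ti.n_nodes)           # P(all-absent below i | present at i)
    empty_below = count_below == 0
    for i in ti.postorder:
        if not ti.children[i]:
            A[i] = present[i]
            Q[i] = 0.0
            continue
        acc = np.ones(n_fam)
        q = 1.0
        for k in ti.children[i]:
            acc *= surv[k] * A[k] + (1 - surv[k]) * empty_below[k]
            q *= surv[k] * Q[k] + (1 - surv[k])
        A[i] = acc
        Q[i] = q

    # expected-count intensity of each observed pattern
    mu = root_intensity * A[ti.root]
    norm = root_intensity * (1.0 - Q[ti.root])
    if gain_rate > 0:
        for c in range(ti.n_nodes):
            if ti.parent[c] < 0:
                continue
            w = -np.expm1(-l * ti.blen[c]) / l  # integral of survival along edge
            contained = count_below[c] == total
            mu = mu + gain_rate * w * A[c] * contained
            norm += gain_rate * w * (1.0 - Q[c])
    if np.any(mu <= 0):
        return -np.inf
    return float(np.log(mu).sum() - norm)


def fit_gain_loss_rates(
    tree: dendropy.Tree | TreeIndex,
    matrix: GeneFamilyMatrix,
    n_restarts: int = 100,
    seed: int = 0,
) -> GainLossModel:
    """ML gain/loss rates; best of ``n_restarts`` random initializations.

    Ties are broken by highest likelihood, then lowest gain rate.
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    if not matrix.family_ids:
        raise ValueError("no gene families to fit")
    rng = np.random.default_rng(seed)
    structures = _img_structures(ti, matrix)
    n_fam = len(matrix.family_ids)

    def nll(x: np.ndarray) -> float:
        rho, lam, loss = np.exp(x)
        ll = img_log_likelihood(ti, matrix, rho, lam, loss, _structures=structures)
        return -ll if np.isfinite(ll) else 1e12

    lo, hi = _LOG_RATE_BOUNDS
    log_nfam = math.log(max(n_fam, 2))
    best = None
    starts = np.column_stack([
        rng.uniform(0.0, log_nfam + 1.0, size=max(1, n_restarts)),
        rng.uniform(-3.0, 3.0, size=max(1, n_restarts)),
        rng.uniform(-3.0, 1.5, size=max(1, n_restarts)),
    ])
    bounds = [(lo, log_nfam + 3.0), (lo, hi), (lo, hi)]
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300})
        key = (-res.fun, -res.x[1])
        if best is None or key > best[0]:
            best = (key, res)
    res = best[1]
    rho, lam, loss = np.exp(res.x)
    at_boundary = bool(
        np.any(np.abs(res.x - np.array([b[0] for b in bounds])) < 1e-6)
        or np.any(np.abs(res.x - np.array([b[1] for b in bounds])) < 1e-6)
    )
    root_share = _root_share(ti, rho, lam, loss)
    return GainLossModel(
        gain_rate=float(lam),
        loss_rate=float(loss),
        root_prior=float(root_share),
        log_likelihood=float(-res.fun),
        root_intensity=float(rho),
        n_families=n_fam,
        at_boundary=at_boundary,
    )


def _root_share(ti: TreeIndex, rho: float, lam: float, loss: float) -> float:
    """P(random observable family originated at the root)."""
    l = max(loss, 1e-12)
    surv = np.exp(-l * ti.blen)
    Q = np.zeros(ti.n_nodes)
    for i in ti.postorder:
        if ti.children[i]:
            q = 1.0
            for k in ti.children[i]:
                q *= surv[k] * Q[k] + (1 - surv[k])
            Q[i] = q
    from_root = rho * (1 - Q[ti.root])
    from_gain = 0.0
    for c in range(ti.n_nodes):
        if ti.parent[c] >= 0:
            w = -np.expm1(-l * ti.blen[c]) / l
            from_gain += lam * w * (1 - Q[c])
    denom = from_root + from_gain
    return from_root / denom if denom > 0 else 0.5


def ancestral_posteriors(
    tree: dendropy.Tree | TreeIndex,
    matrix: GeneFamilyMatrix,
    model: GainLossModel,
) -> np.ndarray:
    """Marginal presence posterior per node and family: (n_nodes, n_fam).

    Leaf posteriors equal the observations.  Node order follows the
    :class:`TreeIndex` used (pass one for stable indexing).
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    P = _transition_matrices(ti, model.per_family_gain_rate, model.loss_rate)
    prior = np.array([1 - model.root_prior, model.root_prior])

    up = _leaf_partials(ti, matrix)
    msg = _pruning_up(ti, up, P)

    n_fam = len(matrix.family_ids)
    outside = np.ones((ti.n_nodes, n_fam, 2))
    outside[ti.root] = prior
    for i in ti.postorder[::-1]:
        for k in ti.children[i]:
            sib = outside[i].copy()
            for k2 in ti.children[i]:
                if k2 != k:
                    sib *= msg[k2]
            outside[k] = sib @ P[k]
    post = outside * up
    norm = post.sum(axis=2, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm
    return post[:, :, 1]


def event_call_matrices(
    posteriors: np.ndarray,
    tree: dendropy.Tree | TreeIndex,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n_nodes, n_fam) gain/loss call matrices at certainty 1-threshold.

    Rows for the root are all False (no branch above it).
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    certain = 1.0 - threshold
    gains = np.zeros_like(posteriors, dtype=bool)
    losses = np.zeros_like(posteriors, dtype=bool)
    for i in range(ti.n_nodes):
        p = ti.parent[i]
        if p < 0:
            continue
        child, parent = posteriors[i], posteriors[p]
        gains[i] = (parent <= threshold) & (child >= certain)
        losses[i] = (parent >= certain) & (child <= threshold)
    return gains, losses


def branch_events(
    posteriors: np.ndarray,
    tree: dendropy.Tree | TreeIndex,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[BranchFluxRecord]:
    """Call per-branch gains/losses at certainty 1 - threshold.

    A gain on the branch to child c is called when P(parent absent) and
    P(child present) are both >= 1 - threshold; losses symmetrically.
    Rates are event counts divided by branch length (undefined on
    zero-length branches, turnover then flagged).
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    names = _node_names(ti)
    gain_mat, loss_mat = event_call_matrices(posteriors, ti, threshold)
    records = []
    for i in range(ti.n_nodes):
        p = ti.parent[i]
        if p < 0:
            continue
        n_gain = int(gain_mat[i].sum())
        n_loss = int(loss_mat[i].sum())
        b = ti.blen[i]
        if b > 0:
            g, l = n_gain / b, n_loss / b
            turnover = g / l if l > 0 else None
        else:
            g = l = math.nan
            turnover = None
        records.append(
            BranchFluxRecord(
                branch_id=names[i],
                gains=g,
                losses=l,
                turnover=turnover,
                n_gain_events=n_gain,
                n_loss_events=n_loss,
                branch_length=float(b),
            )
        )
    return records


# ---------------------------------------------------------------------------
# per-branch dS/dN from marginal nucleotide ancestral reconstruction


def _jc_matrices(ti: TreeIndex) -> np.ndarray:
    P = np.empty((ti.n_nodes, 4, 4))
    for i in range(ti.n_nodes):
        t = max(ti.blen[i], 0.0)
        same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        diff = (1.0 - same) / 3.0
        P[i] = np.full((4, 4), diff)
        np.fill_diagonal(P[i], same)
    return P


_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reconstruct_ancestral_sequences(
    tree: dendropy.Tree | TreeIndex,
    alignment: dict[str, str],
) -> dict[int, str]:
    """MAP marginal ancestral nucleotide sequence at every internal node.

    JC69 with the tree's branch lengths; gaps/ambiguity enter as uniform
    leaf likelihoods.  Returns node-index -> sequence (leaves included,
    equal to their observed sequences with ambiguity resolved by MAP).
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    P = _jc_matrices(ti)
    ids = ti.leaf_index
    L = len(next(iter(alignment.values())))
    up = np.ones((ti.n_nodes, L, 4))
    for lab, node in ids.items():
        seq = alignment[lab].upper()
        arr = np.array([_NT_CODE.get(c, -1) for c in seq])
        known = arr >= 0
        up[node][known] = 0.0
        up[node][known, arr[known]] = 1.0
    msg = np.empty_like(up)
    for i in ti.postorder:
        kids = ti.children[i]
        if kids:
            acc = np.ones((L, 4))
            for k in kids:
                acc *= msg[k]
            acc /= acc.max(axis=1, keepdims=True)  # guard underflow
            up[i] = acc
        msg[i] = up[i] @ P[i].T

    outside = np.ones((ti.n_nodes, L, 4))
    outside[ti.root] = 0.25
    for i in ti.postorder[::-1]:
        for k in ti.children[i]:
            sib = outside[i].copy()
            for k2 in ti.children[i]:
                if k2 != k:
                    sib *= msg[k2]
            sib /= sib.max(axis=1, keepdims=True)
            outside[k] = sib @ P[k]
    post = outside * up
    states = post.argmax(axis=2)
    lut = np.array(list("ACGT"))
    return {i: "".join(lut[states[i]]) for i in range(ti.n_nodes)}


def _branch_ng86(parent_seq: str, child_seq: str) -> tuple[float, float, float, float]:
    """(syn sites, nonsyn sites, syn diffs, nonsyn diffs) between two
    in-frame sequences, skipping non-sense codons."""
    ia = np.array([CODON_INDEX.get(parent_seq[i:i + 3], -1) for i in range(0, len(parent_seq), 3)])
    ib = np.array([CODON_INDEX.get(child_seq[i:i + 3], -1) for i in range(0, len(child_seq), 3)])
    ok = (ia >= 0) & (ib >= 0)
    ia, ib = ia[ok], ib[ok]
    if ia.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    s = 0.5 * (S_SITES[ia] + S_SITES[ib]).sum()
    n = 0.5 * (N_SITES[ia] + N_SITES[ib]).sum()
    return float(s), float(n), float(SYN_DIFFS[ia, ib].sum()), float(NONSYN_DIFFS[ia, ib].sum())


def _fragment_starts(length: int, fragment_length: int) -> list[int]:
    """Start offsets of the codon-aligned fragments covering an alignment."""
    frag = max(3, (fragment_length // 3) * 3)
    return list(range(0, length, frag)) or [0]


def branch_dsdn(
    tree: dendropy.Tree | TreeIndex,
    core_alignment: dict[str, str],
    fragment_length: int = FRAGMENT_LENGTH,
) -> dict[str, Optional[float]]:
    """Per-branch dS/dN averaged over core-genome fragments.

    The alignment is cut into ``fragment_length``-bp fragments (codon
    boundaries respected; a shorter alignment is one fragment).  Within each
    fragment, ancestral sequences are reconstructed and NG86 proportions
    counted along every branch; a fragment contributes a branch value when
    both dS and dN are positive.  Branches with no usable fragment map to
    ``None``.
    """
    ti = tree if isinstance(tree, TreeIndex) else index_tree(tree)
    names = _node_names(ti)
    L = len(next(iter(core_alignment.values())))
    frag = max(3, (fragment_length // 3) * 3)
    starts = _fragment_starts(L, fragment_length)
    values: dict[str, list[float]] = {names[i]: [] for i in range(ti.n_nodes) if ti.parent[i] >= 0}
    for start in starts:
        sub = {k: v[start:start + frag] for k, v in core_alignment.items()}
        if len(next(iter(sub.values()))) < 3:
            continue
        anc = reconstruct_ancestral_sequences(ti, sub)
        for i in range(ti.n_nodes):
            p = ti.parent[i]
            if p < 0:
                continue
            s, n, sd, nd = _branch_ng86(anc[p], anc[i])
            if s <= 0 or n <= 0 or sd <= 0 or nd <= 0:
                continue
            ds, dn = sd / s, nd / n
            values[names[i]].append(ds / dn)
    return {k: (float(np.mean(v)) if v else None) for k, v in values.items()}


def attach_branch_dsdn(
    records: list[BranchFluxRecord],
    dsdn: dict[str, Optional[float]],
) -> None:
    for rec in records:
        rec.branch_dsdn = dsdn.get(rec.branch_id)


def turnover_correlation(
    records: list[BranchFluxRecord],
) -> tuple[Optional[float], Optional[float], str]:
    """Spearman correlation of turnover T vs branch dS/dN across branches.

    Returns (rho, p, category) where category is positive_significant,
    nonsignificant, or negative_significant at p < 0.05; species with
    fewer than 4 usable branches get (None, None, "skipped").
    """
    pts = [
        (r.turnover, r.branch_dsdn)
        for r in records
        if r.turnover is not None and r.branch_dsdn is not None
    ]
    if len(pts) < 4:
        return None, None, "skipped"
    t, d = zip(*pts)
    if len(set(t)) < 2 or len(set(d)) < 2:
        return None, None, "skipped"
    rho, p = spearmanr(t, d)
    if math.isnan(rho):
        return None, None, "skipped"
    if p < 0.05:
        cat = "positive_significant" if rho > 0 else "negative_significant"
    else:
        cat = "nonsignificant"
    return float(rho), float(p), cat
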