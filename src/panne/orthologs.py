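"""Ortholog identification, strain QC, BRH family clustering, pan/core genome.

The ortholog/paralog verdict follows the distance-to-center rule: a rank-1
hit is an ortholog when its log10 e-value is closer to the median log10
e-value of rank-1 hits than to the mean log10 e-value of rank>=2 hits.
Families are connected components of the accepted best-reciprocal-hit graph
(identity >= 70%, coverage >= 80% of both proteins).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .divergence import harmonic_number
from .io import GeneFamilyMatrix, HitTable, ValidationError

MIN_EVALUE = 1e-300  # floor applied before taking log10
QC_MIN_ORTHOLOGS = 42
QC_MYCOPLASMA_TOLERANCE = 4
DEDUP_DISTANCE = 0.00005
MAX_STRAINS = 400
MIN_STRAINS = 15
IDENTITY_THRESHOLD = 70.0
COVERAGE_THRESHOLD = 0.80
CORE_THRESHOLD = 0.85
PS_SUBSAMPLE_K = 13


class Verdict(str, enum.Enum):
    ORTHOLOG = "ortholog"
    PARALOG = "paralog"


@dataclass
class OrthologCall:
    gene_id: str
    strain_id: str
    protein_id: str
    e_value: float
    verdict: Verdict


def _log10e(e_value: float) -> float:
    return math.log10(max(e_value, MIN_EVALUE))


def classify_orthologs(hits: HitTable) -> list[OrthologCall]:
    """Verdict for every rank-1 hit of every universal gene.

    Rank-1 hits are potential orthologs; rank>=2 hits are confirmed
    paralogs.  With no confirmed paralogs for a gene, every potential
    ortholog is accepted.  Ties in the distance rule go to paralog
    (conservative).  Deterministic and order-invariant.
    """
    if not hits.records:
        raise ValueError("empty hit table")
    by_gene: dict[str, dict] = {}
    for r in hits.records:
        g = by_gene.setdefault(r.query_gene, {"o": [], "p": []})
        (g["o"] if r.rank == 1 else g["p"]).append(r)
    calls: list[OrthologCall] = []
    for gene in sorted(by_gene):
        grp = by_gene[gene]
        potentials = grp["o"]
        if not potentials:
            continue  # gene absent from the species
        o_logs = np.array([_log10e(r.e_value) for r in potentials])
        m_o = float(np.median(o_logs))
        if grp["p"]:
            m_p = float(np.mean([_log10e(r.e_value) for r in grp["p"]]))
        else:
            m_p = None
        for r in sorted(potentials, key=lambda r: (r.strain_id, r.protein_id)):
            x = _log10e(r.e_value)
            if m_p is None or abs(x - m_o) < abs(x - m_p):
                verdict = Verdict.ORTHOLOG
            else:
                verdict = Verdict.PARALOG
            calls.append(
                OrthologCall(gene, r.strain_id, r.protein_id, r.e_value, verdict)
            )
    return calls


def qc_filter_strains(
    calls: Sequence[OrthologCall],
    n_universal: int = 44,
    mycoplasma: bool = False,
) -> list[str]:
    """Strains retained by the universal-gene completeness check.

    A strain is kept when it carries >= 42 accepted universal orthologs
    (>= 40 for Mycoplasma, where four missing proteins are tolerated).
    """
    tolerance = QC_MYCOPLASMA_TOLERANCE if mycoplasma else 44 - QC_MIN_ORTHOLOGS
    required = n_universal - tolerance
    counts: dict[str, int] = {}
    for c in calls:
        if c.verdict is Verdict.ORTHOLOG:
            counts[c.strain_id] = counts.get(c.strain_id, 0) + 1
    return sorted(s for s, n in counts.items() if n >= required)


def dedup_and_subsample(
    strain_ids: Sequence[str],
    distances: np.ndarray,
    max_strains: int = MAX_STRAINS,
    min_strains: int = MIN_STRAINS,
    seed: int = 0,
    dedup_threshold: float = DEDUP_DISTANCE,
) -> list[str]:
    """Remove near-identical strains, cap the sample, apply the size floor.

    While any pair is closer than ``dedup_threshold``, one member of the
    closest pair (ascending distance, then lexical ids) is removed uniformly
    at random.  Surviving strains beyond ``max_strains`` are randomly
    subsampled.  Fewer than ``min_strains`` survivors excludes the species
    (empty list).  Deterministic under ``seed``.
    """
    distances = np.asarray(distances, dtype=float)
    n = len(strain_ids)
    if distances.shape != (n, n):
        raise ValidationError("distance matrix shape does not match strain ids")
    if not np.allclose(distances, distances.T):
        raise ValidationError("distance matrix is not symmetric")
    rng = np.random.default_rng(seed)
    alive = list(range(n))
    while True:
        pairs = [
            (distances[i, j], strain_ids[i], strain_ids[j], i, j)
            for ai, i in enumerate(alive)
            for j in alive[ai + 1:]
            if distances[i, j] < dedup_threshold
        ]
        if not pairs:
            break
        _, _, _, i, j = min(pairs)
        alive.remove(i if rng.random() < 0.5 else j)
    if len(alive) > max_strains:
        alive = sorted(rng.choice(alive, size=max_strains, replace=False))
    if len(alive) < min_strains:
        return []
    return [strain_ids[i] for i in alive]


@dataclass
class PairHit:
    """One directed protein-vs-protein comparison."""

    protein_a: str
    protein_b: str
    percent_identity: float
    coverage_a: float  # aligned fraction of protein_a
    coverage_b: float


def cluster_brh_families(
    pairwise_hits: Sequence[PairHit],
    protein_strain: dict[str, str],
) -> GeneFamilyMatrix:
    """Protein families by transitive closure of accepted reciprocal best hits.

    A directed hit a->b is "best" when no other hit from a into b's strain
    has higher identity.  A pair is accepted iff best in both directions,
    identity >= 70% and both coverages >= 80%.  Singleton proteins form
    singleton families; a family with two members from one strain is
    flagged paralogous.
    """
    seen_strain: dict[str, str] = {}
    for h in pairwise_hits:
        for p in (h.protein_a, h.protein_b):
            if p not in protein_strain:
                raise ValidationError(f"protein {p!r} has no strain assignment")
        for p, s in ((h.protein_a, protein_strain[h.protein_a]),
                     (h.protein_b, protein_strain[h.protein_b])):
            prev = seen_strain.setdefault(p, s)
            if prev != s:
                raise ValidationError(f"protein {p!r} mapped to two strains")

    # best directed hit per (source protein, target strain), by identity
    best: dict[tuple[str, str], PairHit] = {}
    for h in pairwise_hits:
        key = (h.protein_a, protein_strain[h.protein_b])
        cur = best.get(key)
        if cur is None or (h.percent_identity, h.protein_b) > (
            cur.percent_identity,
            cur.protein_b,
        ):
            best[key] = h

    graph = nx.Graph()
    graph.add_nodes_from(protein_strain)
    for (a, _), h in best.items():
        b = h.protein_b
        back = best.get((b, protein_strain[a]))
        if back is None or back.protein_b != a:
            continue
        if h.percent_identity < IDENTITY_THRESHOLD:
            continue
        if h.coverage_a < COVERAGE_THRESHOLD or h.coverage_b < COVERAGE_THRESHOLD:
            continue
        graph.add_edge(a, b)

    strain_ids = sorted(set(protein_strain.values()))
    strain_pos = {s: i for i, s in enumerate(strain_ids)}
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    family_ids = [f"fam{i:05d}" for i in range(len(components))]
    presence = np.zeros((len(strain_ids), len(components)), dtype=np.int8)
    members: dict[str, list[tuple[str, str]]] = {}
    paralogous: dict[str, bool] = {}
    for j, comp in enumerate(components):
        fid = family_ids[j]
        mem = [(protein_strain[p], p) for p in comp]
        members[fid] = mem
        strains = [s for s, _ in mem]
        paralogous[fid] = len(strains) != len(set(strains))
        for s in strains:
            presence[strain_pos[s], j] = 1
    return GeneFamilyMatrix(
        strain_ids=strain_ids,
        family_ids=family_ids,
        presence=presence,
        family_members=members,
        paralogous_flags=paralogous,
    )


@dataclass
class PanGenomeSummary:
    n_strains: int
    n_pan: int
    alpha: float
    p_normalized: float
    core_family_ids: list[str]
    ps_subsampled: Optional[int] = None


def pan_genome_stats(matrix: GeneFamilyMatrix) -> PanGenomeSummary:
    """N_pan, the harmonic normalizer alpha, and P = N_pan / alpha."""
    n = len(matrix.strain_ids)
    if n < 2:
        raise ValueError("pan-genome statistics need >= 2 strains")
    n_pan = len(matrix.family_ids)
    alpha = harmonic_number(n)
    return PanGenomeSummary(
        n_strains=n,
        n_pan=n_pan,
        alpha=alpha,
        p_normalized=n_pan / alpha,
        core_family_ids=core_genome(matrix),
    )


def subsample_pan(
    matrix: GeneFamilyMatrix,
    core_distances: np.ndarray,
    k: int = PS_SUBSAMPLE_K,
    seed: int = 0,
) -> Optional[int]:
    """Pan-genome size of the k most divergent strains (Ps).

    Recursively discards one member (uniformly at random) of the closest
    pair on the core-genome distance matrix until k strains remain, then
    counts families with at least one surviving member.  Returns ``None``
    when the species has fewer than k strains.
    """
    n = len(matrix.strain_ids)
    if n < k:
        return None
    dist = np.asarray(core_distances, dtype=float)
    if dist.shape != (n, n):
        raise ValidationError("core distance matrix shape mismatch")
    rng = np.random.default_rng(seed)
    alive = list(range(n))
    while len(alive) > k:
        best = min(
            (dist[i, j], matrix.strain_ids[i], matrix.strain_ids[j], i, j)
            for ai, i in enumerate(alive)
            for j in alive[ai + 1:]
        )
        _, _, _, i, j = best
        alive.remove(i if rng.random() < 0.5 else j)
    sub = matrix.presence[alive, :]
    return int((sub.any(axis=0)).sum())


def core_genome(matrix: GeneFamilyMatrix, threshold: float = CORE_THRESHOLD) -> list[str]:
    """Families present in >= threshold of strains, excluding paralogous ones."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = matrix.presence_fraction()
    return [
        fid
        for j, fid in enumerate(matrix.family_ids)
        if frac[j] >= threshold and not matrix.paralogous_flags.get(fid, False)
    ]


def jc_distance_matrix(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Jukes-Cantor nucleotide distances on an alignment (dedup plumbing).

    Sites with non-ACGT characters in either sequence of a pair are skipped.
    Saturated pairs get distance 10 (effectively "very far").
    """
    ids = sorted(sequences)
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    arrs = {k: np.frombuffer(sequences[k].upper().encode(), dtype="S1") for k in ids}
    valid = {k: np.isin(arrs[k], acgt) for k in ids}
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            ok = valid[ids[i]] & valid[ids[j]]
            m = int(ok.sum())
            if m == 0:
                d = 10.0
            else:
                p = float((a[ok] != b[ok]).sum()) / m
                d = 10.0 if p >= 0.75 else -0.75 * math.log1p(-4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    return ids, dist
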