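"""Synthetic multi-species datasets with known ground truth.

Everything downstream of the raw-genome processing (which this package does
not perform) can be exercised on data produced here: coalescent strain
genealogies with tunable diversity, codon sequences evolved under a
controlled dN/dS, gene-content histories with logged gain/loss events,
recombination tracts that inject homoplasy, and paralog-contaminated hit
tables.  All generators are deterministic under a fixed seed; species draw
from documented substreams of the global seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .codon import NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, is_transition, translate
from .flux import _node_names
from .io import (
    GeneFamilyMatrix,
    HitRecord,
    HitTable,
    Lifestyle,
    SpeciesMetadata,
    write_fasta,
    write_hit_table,
    write_metadata,
    write_newick,
    write_presence_matrix,
)
from .treeutil import TreeIndex, index_tree, parse_newick, to_newick


@dataclass
class SimulationConfig:
    n_species: int = 1
    strains_per_species: int = 15
    theta_per_site: float = 0.05
    omega: float = 0.2
    kappa: float = 2.0
    n_universal_genes: int = 44
    n_codons_per_gene: int = 100
    n_core_codons: Optional[int] = None
    root_gene_count: int = 200
    gain_rate: float = 1.0
    loss_rate: float = 2.0
    recombination_events: int = 0
    recombination_tract: int = 300
    paralog_fraction: float = 0.0
    seed: int = 0
    # optional per-species parameter grids (length n_species)
    omega_per_species: Optional[Sequence[float]] = None
    theta_per_species: Optional[Sequence[float]] = None
    gain_rate_per_species: Optional[Sequence[float]] = None
    lifestyle_per_species: Optional[Sequence[str]] = None
    mutation_rate: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.omega <= 1):
            raise ValueError("omega must be in (0, 1]")
        if self.theta_per_site <= 0:
            raise ValueError("theta_per_site must be positive")
        if self.strains_per_species < 15:
            raise ValueError("strains_per_species must be >= 15")
        if self.loss_rate <= 0 and self.gain_rate > 0:
            raise ValueError("gain without loss diverges on an infinite horizon")
        if not (0 <= self.paralog_fraction < 1):
            raise ValueError("paralog_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    true_trees: dict[str, str] = field(default_factory=dict)  # species -> newick
    true_omega: dict[str, float] = field(default_factory=dict)
    true_theta: dict[str, float] = field(default_factory=dict)
    gene_event_log: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    recombination_log: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    lifestyles: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coalescent genealogy


def simulate_strain_genealogy(
    n_strains: int,
    theta_per_site: float,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Kingman coalescent genealogy scaled to substitutions per site.

    Coalescent times are in units of the (haploid) population size; branch
    lengths are multiplied by theta/2 so the expected distance between two
    random strains equals ``theta_per_site``.
    """
    if n_strains < 2:
        raise ValueError("need >= 2 strains")
    if theta_per_site <= 0:
        raise ValueError("theta_per_site must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = theta_per_site / 2.0

    # (newick fragment, time of node) per active lineage
    active: list[tuple[str, float]] = [(f"s{i:03d}", 0.0) for i in range(n_strains)]
    now = 0.0
    while len(active) > 1:
        k = len(active)
        now += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ta), (nb, tb) = active[i], active[j]
        merged = (
            f"({na}:{(now - ta) * scale:.12g},{nb}:{(now - tb) * scale:.12g})",
            now,
        )
        active = [a for idx, a in enumerate(active) if idx not in (i, j)]
        active.append(merged)
    return parse_newick(active[0][0] + ";")


# ---------------------------------------------------------------------------
# codon sequence evolution (MG94-like mechanistic process)


def _codon_rate_tables(omega: float, kappa: float):
    """Per-codon neighbor targets and rates, normalized so a neutral
    four-fold site accumulates one substitution per unit branch length."""
    k = len(SENSE_CODONS)
    targets = np.full((k, 9), -1, dtype=np.int64)
    rates = np.zeros((k, 9))
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    norm = 2.0 + kappa
    for i, codon in enumerate(SENSE_CODONS):
        slot = 0
        for pos in range(3):
            for alt in NUCLEOTIDES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1:]
                if mutant in STOP_CODONS:
                    slot += 1
                    continue
                rate = (kappa if is_transition(codon[pos], alt) else 1.0) / norm
                if translate(mutant) != translate(codon):
                    rate *= omega
                targets[i, slot] = idx[mutant]
                rates[i, slot] = rate
                slot += 1
    total = rates.sum(axis=1)
    cum = np.cumsum(rates, axis=1)
    return targets, rates, total, cum


def _evolve_codons_branch(
    codons: np.ndarray,
    t: float,
    tables,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gillespie evolution of independent codons for time t."""
    targets, _, total, cum = tables
    out = codons.copy()
    remaining = np.full(out.shape, float(t))
    active = np.nonzero(remaining > 0)[0]
    while active.size:
        rate = total[out[active]]
        wait = rng.exponential(1.0 / rate)
        hit = wait < remaining[active]
        idx = active[hit]
        remaining[active] -= np.where(hit, wait, remaining[active])
        if idx.size:
            u = rng.random(idx.size) * total[out[idx]]
            choice = (cum[out[idx]] < u[:, None]).sum(axis=1)
            out[idx] = targets[out[idx], choice]
        active = idx
    return out


def evolve_codon_alignment(
    tree: dendropy.Tree,
    omega: float,
    kappa: float,
    n_codons: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve in-frame, gapless codon sequences down a tree.

    Single-nucleotide events carry rate multipliers kappa (transitions) and
    omega (nonsynonymous changes); mutations to stops have rate zero.  The
    root sequence is uniform over sense codons.  Branch lengths are in
    expected substitutions per neutral site.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    ti = index_tree(tree)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = _codon_rate_tables(omega, kappa)
    seqs_idx: dict[int, np.ndarray] = {}
    root = ti.root
    seqs_idx[root] = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    for i in ti.postorder[::-1]:  # preorder
        p = ti.parent[i]
        if p < 0:
            continue
        seqs_idx[i] = _evolve_codons_branch(seqs_idx[p], ti.blen[i], tables, rng)
    out = {}
    for node, lab in enumerate(ti.leaf_labels):
        if lab is not None:
            out[lab] = "".join(SENSE_CODONS[c] for c in seqs_idx[node])
    return out


def simulate_neutral_sites(
    tree: dendropy.Tree,
    n_sites: int,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray]:
    """Evolve independent neutral nucleotide sites (JC69) down a tree.

    Returns (sorted leaf labels, characters matrix n_leaves x n_sites) —
    the shape watterson_theta consumes.  Branch lengths are substitutions
    per site.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ti = index_tree(tree)
    states: dict[int, np.ndarray] = {ti.root: rng.integers(0, 4, size=n_sites)}
    for i in ti.postorder[::-1]:
        p = ti.parent[i]
        if p < 0:
            continue
        t = ti.blen[i]
        p_change = 0.75 * -math.expm1(-4.0 * t / 3.0)
        parent_states = states[p]
        change = rng.random(n_sites) < p_change
        shift = rng.integers(1, 4, size=n_sites)
        child = parent_states.copy()
        child[change] = (parent_states[change] + shift[change]) % 4
        states[i] = child
    labels = sorted(ti.leaf_index)
    lut = np.frombuffer(b"ACGT", dtype="S1")
    mat = np.stack([lut[states[ti.leaf_index[lab]]] for lab in labels])
    return labels, mat.astype("U1")


def simulate_brownian_traits(
    tree: dendropy.Tree,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_traits: int = 1,
    correlation: float = 0.0,
) -> list[dict[str, float]]:
    """Brownian-motion trait evolution on a tree (PIC calibration plumbing).

    Increments on a branch of length b have variance sigma^2 * b; multiple
    traits share a per-branch correlation.  Returns one leaf->value map per
    trait.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ti = index_tree(tree)
    cov = np.full((n_traits, n_traits), correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    vals = np.zeros((ti.n_nodes, n_traits))
    for i in ti.postorder[::-1]:
        p = ti.parent[i]
        if p < 0:
            continue
        step = chol @ rng.normal(size=n_traits)
        vals[i] = vals[p] + sigma * math.sqrt(max(ti.blen[i], 0.0)) * step
    return [
        {lab: float(vals[node, j]) for lab, node in ti.leaf_index.items()}
        for j in range(n_traits)
    ]


# ---------------------------------------------------------------------------
# gene content


def simulate_gene_content(
    tree: dendropy.Tree,
    root_gene_count: int,
    gain_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[GeneFamilyMatrix, list[tuple[str, str, str]]]:
    """Gain/loss history of gene families along a tree.

    Per branch, Poisson(gain_rate * length) gains each create a brand-new
    family (re-gain is never simulated); each family present at the parent
    is lost with probability 1 - exp(-loss_rate * length).  Returns the
    leaf presence/absence matrix and the full (family, branch, event) log.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be nonnegative")
    if gain_rate > 0 and loss_rate <= 0:
        raise ValueError("gain without loss diverges on an infinite horizon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ti = index_tree(tree)
    names = _node_names(ti)
    families: list[str] = [f"fam{i:05d}" for i in range(root_gene_count)]
    present: dict[int, set[str]] = {ti.root: set(families)}
    log: list[tuple[str, str, str]] = []
    p_loss_cache: dict[float, float] = {}
    for i in ti.postorder[::-1]:
        p = ti.parent[i]
        if p < 0:
            continue
        b = float(ti.blen[i])
        inherited = set()
        p_loss = p_loss_cache.setdefault(b, -math.expm1(-loss_rate * b))
        for fam in sorted(present[p]):
            if loss_rate > 0 and rng.random() < p_loss:
                log.append((fam, names[i], "loss"))
            else:
                inherited.add(fam)
        n_gain = rng.poisson(gain_rate * b) if gain_rate > 0 else 0
        for _ in range(n_gain):
            fam = f"fam{len(families):05d}"
            families.append(fam)
            inherited.add(fam)
            log.append((fam, names[i], "gain"))
        present[i] = inherited
    strain_ids = sorted(ti.leaf_index)
    presence = np.zeros((len(strain_ids), len(families)), dtype=np.int8)
    fam_pos = {f: j for j, f in enumerate(families)}
    for s_idx, lab in enumerate(strain_ids):
        for fam in present[ti.leaf_index[lab]]:
            presence[s_idx, fam_pos[fam]] = 1
    # drop families observed nowhere (unobservable in real data)
    observed = presence.any(axis=0)
    matrix = GeneFamilyMatrix(
        strain_ids=strain_ids,
        family_ids=[f for f, keep in zip(families, observed) if keep],
        presence=presence[:, observed],
    )
    return matrix, log


# ---------------------------------------------------------------------------
# recombination


def inject_recombination(
    alignment: dict[str, str],
    tree: dendropy.Tree,
    n_events: int,
    tract_length: int,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, str], list[tuple[int, str, str]]]:
    """Copy contiguous tracts between random strain pairs.

    Each event copies ``tract_length`` consecutive sites from a random
    donor onto a random recipient; every polymorphic transferred site is
    logged as (site_index, donor, recipient).
    """
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    length = len(next(iter(alignment.values())))
    if tract_length < 1 or tract_length > length:
        raise ValueError("tract_length must be in [1, alignment length]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = sorted(alignment)
    seqs = {k: list(v) for k, v in alignment.items()}
    log: list[tuple[int, str, str]] = []
    for _ in range(n_events):
        donor, recipient = rng.choice(len(ids), size=2, replace=False)
        donor, recipient = ids[donor], ids[recipient]
        start = int(rng.integers(0, length - tract_length + 1))
        for site in range(start, start + tract_length):
            if seqs[recipient][site] != seqs[donor][site]:
                seqs[recipient][site] = seqs[donor][site]
                log.append((site, donor, recipient))
    return {k: "".join(v) for k, v in seqs.items()}, log


# ---------------------------------------------------------------------------
# hit tables


def make_hit_table(
    n_strains: int,
    n_universal: int,
    paralog_fraction: float,
    seed: int | np.random.Generator = 0,
    ortholog_log10e: float = -80.0,
    paralog_log10e: float = -12.0,
    log10e_sd: float = 3.0,
    paralog_hit_prob: float = 0.5,
) -> tuple[HitTable, dict[tuple[str, str], str]]:
    """Rank-1 hit per (gene, strain) with optional paralog contamination.

    log10 e-values are drawn from an "ortholog" normal and a weaker
    "paralog" normal; with probability ``paralog_fraction`` the rank-1 hit
    is a paralog.  Rank-2 paralog hits are emitted for a random subset of
    strains so the classifier always has a confirmed-paralog distribution.
    All e-values respect the 1e-5 threshold by construction.
    """
    if not (0 <= paralog_fraction < 1):
        raise ValueError("paralog_fraction must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def evalue(mean: float) -> float:
        draw = min(rng.normal(mean, log10e_sd), -5.5)
        return float(10.0 ** max(draw, -299.0))

    records: list[HitRecord] = []
    truth: dict[tuple[str, str], str] = {}
    for g in range(n_universal):
        gene = f"gene{g:02d}"
        for s in range(n_strains):
            strain = f"s{s:03d}"
            is_paralog = rng.random() < paralog_fraction
            mean = paralog_log10e if is_paralog else ortholog_log10e
            records.append(
                HitRecord(gene, strain, f"{strain}_p{g:02d}", evalue(mean), 1)
            )
            truth[(gene, strain)] = "paralog" if is_paralog else "ortholog"
            if rng.random() < paralog_hit_prob:
                records.append(
                    HitRecord(gene, strain, f"{strain}_q{g:02d}",
                              evalue(paralog_log10e), 2)
                )
    return HitTable(records), truth


# ---------------------------------------------------------------------------
# full dataset


def _species_params(config: SimulationConfig, i: int) -> tuple[float, float, str]:
    omega = (config.omega_per_species[i]
             if config.omega_per_species is not None else config.omega)
    theta = (config.theta_per_species[i]
             if config.theta_per_species is not None else config.theta_per_site)
    lifestyle = (config.lifestyle_per_species[i]
                 if config.lifestyle_per_species is not None else "unknown")
    return omega, theta, lifestyle


def generate_dataset(
    config: SimulationConfig,
    out_dir: Path,
) -> tuple[list[str], GroundTruth]:
    """Write a full multi-species dataset in the on-disk species layout.

    Returns the species ids and the ground truth (also serialized under
    ``<out_dir>/ground_truth/``).  Byte-identical across runs with the
    same config.
    """
    out_dir = Path(out_dir)
    truth = GroundTruth()
    species_ids = []
    n_core = config.n_core_codons or config.n_universal_genes * config.n_codons_per_gene
    for i in range(config.n_species):
        rng = np.random.default_rng([config.seed, i])  # per-species substream
        sid = f"species{i:03d}"
        species_ids.append(sid)
        omega, theta, lifestyle = _species_params(config, i)
        tree = simulate_strain_genealogy(config.strains_per_species, theta, rng)
        n_uni = config.n_universal_genes * config.n_codons_per_gene
        universal = evolve_codon_alignment(tree, omega, config.kappa, n_uni, rng)
        core = evolve_codon_alignment(tree, omega, config.kappa, n_core, rng)
        if config.recombination_events:
            universal, rec_log = inject_recombination(
                universal, tree, config.recombination_events,
                config.recombination_tract, rng,
            )
        else:
            rec_log = []
        gain = (config.gain_rate_per_species[i]
                if config.gain_rate_per_species is not None else config.gain_rate)
        matrix, event_log = simulate_gene_content(
            tree, config.root_gene_count, gain, config.loss_rate, rng
        )
        hits, _ = make_hit_table(
            config.strains_per_species, config.n_universal_genes,
            config.paralog_fraction, rng,
        )

        sdir = out_dir / sid
        sdir.mkdir(parents=True, exist_ok=True)
        write_fasta(universal, sdir / "universal.aln.fasta")
        write_fasta(core, sdir / "core.aln.fasta")
        write_newick(tree, sdir / "tree.nwk")
        write_presence_matrix(matrix, sdir / "families.tsv")
        write_metadata(
            sid,
            SpeciesMetadata(
                lifestyle=Lifestyle(lifestyle),
                mutation_rate=config.mutation_rate,
            ),
            sdir / "metadata.txt",
        )
        write_hit_table(hits, sdir / "hits.tsv")

        truth.true_trees[sid] = to_newick(tree)
        truth.true_omega[sid] = omega
        truth.true_theta[sid] = theta
        truth.gene_event_log[sid] = event_log
        truth.recombination_log[sid] = rec_log
        truth.lifestyles[sid] = lifestyle

    gt_dir = out_dir / "ground_truth"
    gt_dir.mkdir(parents=True, exist_ok=True)
    with open(gt_dir / "params.tsv", "w") as fh:
        fh.write("species_id\ttrue_omega\ttrue_theta\tlifestyle\n")
        for sid in species_ids:
            fh.write(f"{sid}\t{truth.true_omega[sid]}\t{truth.true_theta[sid]}"
                     f"\t{truth.lifestyles[sid]}\n")
    with open(gt_dir / "gene_events.tsv", "w") as fh:
        fh.write("species_id\tfamily_id\tbranch_id\tevent\n")
        for sid in species_ids:
            for fam, branch, event in truth.gene_event_log[sid]:
                fh.write(f"{sid}\t{fam}\t{branch}\t{event}\n")
    with open(gt_dir / "recombination.tsv", "w") as fh:
        fh.write("species_id\tsite_index\tdonor\trecipient\n")
        for sid in species_ids:
            for site, donor, recipient in truth.recombination_log[sid]:
                fh.write(f"{sid}\t{site}\t{donor}\t{recipient}\n")
    for sid in species_ids:
        (gt_dir / f"{sid}.true.nwk").write_text(truth.true_trees[sid] + "\n")
    return species_ids, truth
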