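import numpy as np
import pytest

from panne.io import HitRecord, HitTable, ValidationError
from panne.orthologs import (
    PairHit,
    Verdict,
    classify_orthologs,
    cluster_brh_families,
    core_genome,
    dedup_and_subsample,
    jc_distance_matrix,
    pan_genome_stats,
    qc_filter_strains,
    subsample_pan,
)
from panne.io import GeneFamilyMatrix


def _hits(records):
    return HitTable([HitRecord(*r) for r in records])


def _e(log10e):
    return 10.0 ** log10e


class TestClassifyOrthologs:
    def test_no_paralogs_all_ortholog(self):
        hits = _hits([
            ("g1", "s1", "p1", _e(-80), 1),
            ("g1", "s2", "p2", _e(-78), 1),
            ("g1", "s3", "p3", _e(-75), 1),
        ])
        calls = classify_orthologs(hits)
        assert all(c.verdict is Verdict.ORTHOLOG for c in calls)

    def test_distance_rule(self):
        # potential orthologs median -80, paralog mean -10, candidate -70
        hits = _hits([
            ("g1", "s1", "p1", _e(-90), 1),
            ("g1", "s2", "p2", _e(-80), 1),
            ("g1", "s3", "p3", _e(-70), 1),
            ("g1", "s1", "q1", _e(-10), 2),
            ("g1", "s2", "q2", _e(-10), 2),
        ])
        calls = {c.strain_id: c.verdict for c in classify_orthologs(hits)}
        assert calls["s3"] is Verdict.ORTHOLOG  # |-70+80|=10 < |-70+10|=60

    def test_paralog_like_candidate_rejected(self):
        hits = _hits([
            ("g1", "s1", "p1", _e(-80), 1),
            ("g1", "s2", "p2", _e(-80), 1),
            ("g1", "s3", "p3", _e(-12), 1),  # close to paralog mean -10
            ("g1", "s1", "q1", _e(-10), 2),
        ])
        calls = {c.strain_id: c.verdict for c in classify_orthologs(hits)}
        assert calls["s3"] is Verdict.PARALOG

    def test_tie_breaks_to_paralog(self):
        # median_o = -80, mean_p = -40, candidate -60 equidistant
        hits = _hits([
            ("g1", "s1", "p1", _e(-80), 1),
            ("g1", "s2", "p2", _e(-80), 1),
            ("g1", "s3", "p3", _e(-60), 1),
            ("g1", "s1", "q1", _e(-40), 2),
        ])
        calls = {c.strain_id: c.verdict for c in classify_orthologs(hits)}
        # candidate at -60 pulls the ortholog median to -80 (odd count)
        assert calls["s3"] is Verdict.PARALOG

    def test_permutation_invariant_and_idempotent(self, rng):
        records = [
            ("g1", f"s{i}", f"p{i}", _e(-80 + 0.1 * i), 1) for i in range(10)
        ] + [("g1", f"s{i}", f"q{i}", _e(-11 - 0.2 * i), 2) for i in range(5)]
        base = classify_orthologs(_hits(records))
        for _ in range(3):
            perm = [records[i] for i in rng.permutation(len(records))]
            assert classify_orthologs(_hits(perm)) == base


class TestQcFilter:
    def _calls(self, n_orthologs, strain="s1"):
        return [
            type("C", (), {"strain_id": strain, "verdict": Verdict.ORTHOLOG})()
            for _ in range(n_orthologs)
        ]

    def test_41_excluded(self):
        assert qc_filter_strains(self._calls(41)) == []

    def test_42_retained(self):
        assert qc_filter_strains(self._calls(42)) == ["s1"]

    def test_40_mycoplasma_retained(self):
        assert qc_filter_strains(self._calls(40), mycoplasma=True) == ["s1"]
        assert qc_filter_strains(self._calls(39), mycoplasma=True) == []

    def test_full_complement(self):
        assert qc_filter_strains(self._calls(44)) == ["s1"]


class TestDedupSubsample:
    def test_near_identical_pair_one_removed(self):
        ids = [f"s{i}" for i in range(16)]
        d = np.ones((16, 16)) * 0.01
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 0.00004
        kept = dedup_and_subsample(ids, d, seed=5)
        assert len(kept) == 15
        assert ("s0" in kept) != ("s1" in kept)

    def test_threshold_not_triggered_at_exact_value(self):
        ids = ["a", "b"] + [f"s{i}" for i in range(14)]
        d = np.ones((16, 16)) * 0.01
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 0.00005  # not < threshold
        assert len(dedup_and_subsample(ids, d)) == 16

    def test_subsample_to_max(self, rng):
        n = 450
        ids = [f"s{i}" for i in range(n)]
        d = rng.uniform(0.001, 0.01, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        kept = dedup_and_subsample(ids, d, seed=3)
        assert len(kept) == 400

    def test_species_excluded_below_min(self):
        ids = [f"s{i}" for i in range(14)]
        d = np.ones((14, 14)) * 0.01
        np.fill_diagonal(d, 0)
        assert dedup_and_subsample(ids, d) == []

    def test_asymmetric_matrix_rejected(self):
        d = np.zeros((2, 2))
        d[0, 1] = 1.0
        with pytest.raises(ValidationError):
            dedup_and_subsample(["a", "b"], d)

    def test_deterministic_under_seed(self, rng):
        ids = [f"s{i}" for i in range(30)]
        d = rng.uniform(0, 0.0001, size=(30, 30))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        a = dedup_and_subsample(ids, d, seed=7)
        b = dedup_and_subsample(ids, d, seed=7)
        assert a == b


class TestBrhClustering:
    def _strains(self, mapping):
        return mapping

    def test_identity_threshold(self):
        strains = {"a1": "sA", "b1": "sB"}
        hits = [
            PairHit("a1", "b1", 69.9, 0.9, 0.9),
            PairHit("b1", "a1", 69.9, 0.9, 0.9),
        ]
        m = cluster_brh_families(hits, strains)
        assert len(m.family_ids) == 2  # rejected: two singletons

    def test_coverage_threshold_both_sides(self):
        strains = {"a1": "sA", "b1": "sB"}
        hits = [
            PairHit("a1", "b1", 95.0, 0.9, 0.79),
            PairHit("b1", "a1", 95.0, 0.79, 0.9),
        ]
        assert len(cluster_brh_families(hits, strains).family_ids) == 2

    def test_transitivity_chain(self):
        strains = {"A": "s1", "B": "s2", "C": "s3"}
        hits = [
            PairHit("A", "B", 90, 0.9, 0.9), PairHit("B", "A", 90, 0.9, 0.9),
            PairHit("B", "C", 90, 0.9, 0.9), PairHit("C", "B", 90, 0.9, 0.9),
        ]
        m = cluster_brh_families(hits, strains)
        assert len(m.family_ids) == 1
        assert len(m.family_members[m.family_ids[0]]) == 3

    def test_no_hits_singletons(self):
        strains = {f"p{i}": f"s{i}" for i in range(5)}
        m = cluster_brh_families([], strains)
        assert len(m.family_ids) == 5

    def test_reciprocality_required(self):
        strains = {"A": "s1", "B": "s2", "X": "s2"}
        # A's best hit in s2 is X, so A-B is not reciprocal
        hits = [
            PairHit("A", "X", 95, 0.9, 0.9),
            PairHit("A", "B", 90, 0.9, 0.9),
            PairHit("B", "A", 90, 0.9, 0.9),
        ]
        m = cluster_brh_families(hits, strains)
        assert len(m.family_ids) == 3

    def test_paralog_flag(self):
        strains = {"A": "s1", "B": "s2", "B2": "s2"}
        hits = [
            PairHit("A", "B", 95, 0.9, 0.9), PairHit("B", "A", 95, 0.9, 0.9),
            PairHit("B", "B2", 95, 0.9, 0.9), PairHit("B2", "B", 95, 0.9, 0.9),
        ]
        m = cluster_brh_families(hits, strains)
        fam = [f for f in m.family_ids if len(m.family_members[f]) == 3]
        assert fam and m.paralogous_flags[fam[0]]

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValidationError):
            cluster_brh_families([PairHit("A", "B", 95, 0.9, 0.9)], {"A": "s1"})

    def test_matches_union_find_oracle(self, rng):
        # brute-force union-find over accepted pairs on random instances
        for trial in range(10):
            n = int(rng.integers(5, 50))
            strains = {f"p{i}": f"s{i % 7}" for i in range(n)}
            hits = []
            accepted = []
            for _ in range(n * 2):
                i, j = rng.integers(0, n, size=2)
                if i == j or strains[f"p{i}"] == strains[f"p{j}"]:
                    continue
                ident = float(rng.uniform(60, 100))
                cov = float(rng.uniform(0.7, 1.0))
                hits.append(PairHit(f"p{i}", f"p{j}", ident, cov, cov))
                hits.append(PairHit(f"p{j}", f"p{i}", ident, cov, cov))
            m = cluster_brh_families(hits, strains)

            # oracle: recompute accepted reciprocal-best pairs, then union-find
            best = {}
            for h in hits:
                key = (h.protein_a, strains[h.protein_b])
                if key not in best or (h.percent_identity, h.protein_b) > (
                    best[key].percent_identity, best[key].protein_b
                ):
                    best[key] = h
            parent = {p: p for p in strains}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for (a, _), h in best.items():
                b = h.protein_b
                back = best.get((b, strains[a]))
                if (back is not None and back.protein_b == a
                        and h.percent_identity >= 70
                        and h.coverage_a >= 0.8 and h.coverage_b >= 0.8):
                    parent[find(a)] = find(b)
            oracle = {}
            for p in strains:
                oracle.setdefault(find(p), set()).add(p)
            ours = {frozenset(p for _, p in m.family_members[f]) for f in m.family_ids}
            assert ours == {frozenset(v) for v in oracle.values()}


class TestPanGenome:
    def _matrix(self, presence, paralogous=None):
        n, k = presence.shape
        fids = [f"f{j}" for j in range(k)]
        return GeneFamilyMatrix(
            strain_ids=[f"s{i}" for i in range(n)],
            family_ids=fids,
            presence=presence,
            paralogous_flags={f: False for f in fids} | (paralogous or {}),
        )

    def test_two_strains(self):
        m = self._matrix(np.ones((2, 100), dtype=np.int8))
        s = pan_genome_stats(m)
        assert s.alpha == 1.0 and s.p_normalized == 100.0

    def test_harmonic_13(self):
        m = self._matrix(np.ones((13, 10), dtype=np.int8))
        assert pan_genome_stats(m).alpha == pytest.approx(3.103211, abs=1e-6)

    def test_four_strains_eleven_families(self):
        m = self._matrix(np.ones((4, 11), dtype=np.int8))
        assert pan_genome_stats(m).p_normalized == pytest.approx(6.0, rel=1e-12)

    def test_single_strain_rejected(self):
        m = self._matrix(np.ones((1, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            pan_genome_stats(m)

    def test_core_threshold(self):
        pres = np.ones((14, 3), dtype=np.int8)
        pres[:2, 0] = 0   # 12/14 = 85.7% -> core
        pres[:3, 1] = 0   # 11/14 = 78.6% -> not core
        m = self._matrix(pres)
        assert core_genome(m) == ["f0", "f2"]

    def test_core_excludes_paralogous(self):
        pres = np.ones((10, 1), dtype=np.int8)
        m = self._matrix(pres, paralogous={"f0": True})
        assert core_genome(m) == []

    def test_core_monotone_in_threshold(self, rng):
        pres = (rng.random((20, 50)) < 0.8).astype(np.int8)
        m = self._matrix(pres)
        sizes = [len(core_genome(m, th)) for th in (0.5, 0.7, 0.85, 0.95, 1.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestSubsamplePan:
    def _matrix(self, presence):
        n, k = presence.shape
        return GeneFamilyMatrix(
            strain_ids=[f"s{i}" for i in range(n)],
            family_ids=[f"f{j}" for j in range(k)],
            presence=presence,
        )

    def test_no_removal_when_n_equals_k(self):
        pres = np.eye(13, dtype=np.int8)
        m = self._matrix(pres)
        d = np.ones((13, 13)) - np.eye(13)
        assert subsample_pan(m, d, k=13) == 13

    def test_clone_removed_first(self):
        # 14 strains, strains 0/1 are clones (distance ~0)
        pres = np.ones((14, 5), dtype=np.int8)
        d = np.ones((14, 14))
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1e-9
        m = self._matrix(pres)
        # removing down to 13 must drop one of the clone pair
        for seed in range(5):
            rng_removed = subsample_pan(m, d, k=13, seed=seed)
            assert rng_removed == 5  # all families survive regardless

    def test_private_families_do_not_count(self):
        # strain 0 holds a private family and is a clone of strain 1
        pres = np.zeros((14, 2), dtype=np.int8)
        pres[:, 0] = 1
        pres[0, 1] = 1
        d = np.ones((14, 14))
        np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = 1e-9
        m = self._matrix(pres)
        results = {subsample_pan(m, d, k=13, seed=s) for s in range(20)}
        assert results == {1, 2}  # 1 when strain 0 was dropped

    def test_unavailable_below_k(self):
        pres = np.ones((5, 3), dtype=np.int8)
        m = self._matrix(pres)
        assert subsample_pan(m, np.zeros((5, 5)), k=13) is None


class TestJcDistances:
    def test_identical_zero(self):
        ids, d = jc_distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d[0, 1] == 0.0

    def test_symmetric_positive(self):
        ids, d = jc_distance_matrix({"a": "ACGTACGTAC", "b": "ACGTACGTAT"})
        assert d[0, 1] == d[1, 0] > 0
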