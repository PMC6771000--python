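import math

import numpy as np
import pytest

from oracles import oracle_accumulation_medians, oracle_spearman
from panlin.clustering import Cluster, ClusterParams, ClusterSet, greedy_cluster
from panlin.pangenome import (
    AccumulationCurve,
    accumulation,
    filter_unique,
    heaps_fit,
    partition,
    unique_vs_distance,
)
from panlin.sequence_io import SeqRecord, read_newick
from panlin.synthetic_data import mutate_sequence, random_protein


def make_cs(presences, genome_ids):
    """Build a ClusterSet directly from per-cluster genome-presence sets."""
    clusters = [Cluster(cluster_id=i, representative=f"c{i}_m0",
                        members=[f"c{i}_m{j}" for j in range(len(gs))],
                        genomes_present=set(gs))
                for i, gs in enumerate(presences)]
    n = sum(len(c.members) for c in clusters)
    return ClusterSet(clusters=clusters, params=ClusterParams(), n_input=n)


class TestPartition:
    def test_core_and_unique(self):
        gids = ["g1", "g2", "g3"]
        cs = make_cs([{"g1", "g2", "g3"}, {"g2"}, {"g1", "g3"}], gids)
        p = partition(cs, gids)
        assert p.core == {0}
        assert p.unique_by_genome["g2"] == {1}
        assert p.accessory == {2}

    def test_classes_disjoint_and_exhaustive(self):
        gids = [f"g{i}" for i in range(4)]
        rng = np.random.default_rng(0)
        presences = []
        for _ in range(30):
            k = int(rng.integers(1, 5))
            presences.append(set(rng.choice(gids, size=k, replace=False)))
        cs = make_cs(presences, gids)
        p = partition(cs, gids)
        all_ids = p.core | p.accessory | p.unique
        assert all_ids == set(range(30))
        assert len(p.core) + len(p.accessory) + len(p.unique) == 30

    def test_single_genome_all_core(self):
        cs = make_cs([{"g1"}, {"g1"}], ["g1"])
        p = partition(cs, ["g1"])
        assert p.core == {0, 1}
        assert not p.unique

    def test_empty_error(self):
        cs = make_cs([], ["g1"])
        with pytest.raises(ValueError):
            partition(cs, ["g1"])

    def test_synthetic_truth_recovery(self, small_pangenome):
        sim = small_pangenome
        gids = sim.genome_ids()
        recs = [r for g in gids for r in sim.proteomes[g]]
        cs = greedy_cluster(recs)
        p = partition(cs, gids)
        core_truth, acc_truth, uniq_truth = sim.truth.class_counts()
        assert len(p.core) == core_truth
        assert len(p.accessory) == acc_truth
        assert {g: len(s) for g, s in p.unique_by_genome.items()} == uniq_truth


class TestFilterUnique:
    def _two_genome_setup(self, rng, planted_divergence):
        a_seqs = [random_protein(rng, 120) for _ in range(3)]
        b_seqs = [random_protein(rng, 120) for _ in range(3)]
        proteomes = {
            "gA": [SeqRecord(id=f"a{i}", seq=s, genome_id="gA")
                   for i, s in enumerate(a_seqs)],
            "gB": [SeqRecord(id=f"b{i}", seq=s, genome_id="gB")
                   for i, s in enumerate(b_seqs)],
        }
        if planted_divergence is not None:
            hom = mutate_sequence(
                SeqRecord(id="planted", seq=a_seqs[0], genome_id="gB"),
                planted_divergence, rng)
            proteomes["gB"].append(hom)
        # every protein its own (unique) cluster, regardless of homology
        recs = proteomes["gA"] + proteomes["gB"]
        clusters = [Cluster(cluster_id=i, representative=r.id, members=[r.id],
                            genomes_present={r.genome_id})
                    for i, r in enumerate(recs)]
        cs = ClusterSet(clusters=clusters, params=ClusterParams(),
                        n_input=len(recs),
                        genome_of={r.id: r.genome_id for r in recs})
        p = partition(cs, ["gA", "gB"])
        return cs, p, proteomes

    def test_identical_copy_reclassified(self, rng):
        cs, p, prot = self._two_genome_setup(rng, planted_divergence=0.0)
        newp, events = filter_unique(p, cs, prot)
        assert len(events) >= 1
        a0_cluster = cs.membership()["a0"]
        assert a0_cluster in newp.accessory
        assert a0_cluster not in newp.unique

    def test_no_hit_retained(self, rng):
        cs, p, prot = self._two_genome_setup(rng, planted_divergence=None)
        newp, events = filter_unique(p, cs, prot)
        assert events == []
        assert newp.unique == p.unique

    def test_partition_stays_exhaustive_and_unique_never_grows(self, rng):
        cs, p, prot = self._two_genome_setup(rng, planted_divergence=0.1)
        newp, _ = filter_unique(p, cs, prot)
        before = p.core | p.accessory | p.unique
        after = newp.core | newp.accessory | newp.unique
        assert before == after
        assert len(newp.unique) <= len(p.unique)

    def test_identity_threshold_flip(self, rng):
        """Reclassification flips exactly at the identity threshold: use the
        observed identity of a planted homolog as the cutoff."""
        from panlin.align_core import align_local
        cs, p, prot = self._two_genome_setup(rng, planted_divergence=0.3)
        rep = prot["gA"][0]
        planted = prot["gB"][-1]
        obs = align_local(rep, planted, identity_policy="alignment",
                          db_size=sum(len(r.seq) for r in prot["gB"]))
        ident = obs.identity_pct
        a0 = cs.membership()["a0"]
        newp_at, _ = filter_unique(p, cs, prot, identity_min=ident)
        assert a0 in newp_at.accessory  # >= is inclusive at the boundary
        newp_above, _ = filter_unique(p, cs, prot, identity_min=ident + 1e-6)
        assert a0 in newp_above.unique


class TestAccumulation:
    def test_single_genome(self):
        cs = make_cs([{"g1"}, {"g1"}, {"g1"}], ["g1"])
        curve = accumulation(cs, ["g1"], R=5, seed=0)
        assert curve.pan_median[0] == 3
        assert curve.core_median[0] == 3
        assert curve.pan_iqr[0] == 0

    def test_identical_genomes_flat(self):
        gids = ["g1", "g2", "g3"]
        cs = make_cs([set(gids)] * 4, gids)
        curve = accumulation(cs, gids, R=10, seed=1)
        assert np.all(curve.pan_median == 4)
        assert np.all(curve.core_median == 4)

    def test_monotone_within_every_ordering(self, small_pangenome):
        sim = small_pangenome
        gids = sim.genome_ids()
        recs = [r for g in gids for r in sim.proteomes[g]]
        cs = greedy_cluster(recs)
        curve = accumulation(cs, gids, R=20, seed=2)
        assert np.all(np.diff(curve.pan_trajectories, axis=1) >= 0)
        assert np.all(np.diff(curve.core_trajectories, axis=1) <= 0)

    def test_seeded_reproducibility(self):
        gids = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(3)
        presences = [set(rng.choice(gids, size=int(rng.integers(1, 7)),
                                    replace=False)) for _ in range(40)]
        cs = make_cs(presences, gids)
        c1 = accumulation(cs, gids, R=25, seed=9)
        c2 = accumulation(cs, gids, R=25, seed=9)
        assert np.array_equal(c1.pan_trajectories, c2.pan_trajectories)

    def test_exhaustive_enumeration_matches_oracle(self):
        gids = ["g1", "g2", "g3", "g4"]
        rng = np.random.default_rng(4)
        presences = [set(rng.choice(gids, size=int(rng.integers(1, 5)),
                                    replace=False)) for _ in range(25)]
        cs = make_cs(presences, gids)
        sets = [frozenset(cs.presence_sets(gids)[g]) for g in gids]
        pan_med, core_med = oracle_accumulation_medians(sets)
        curve = accumulation(cs, gids, R=math.factorial(4), seed=0)
        assert list(curve.pan_median) == pytest.approx(pan_med)
        assert list(curve.core_median) == pytest.approx(core_med)

    def test_r_zero_error(self):
        cs = make_cs([{"g1"}], ["g1"])
        with pytest.raises(ValueError):
            accumulation(cs, ["g1"], R=0)


class TestHeapsFit:
    @staticmethod
    def power_law_curve(kappa, alpha, G):
        n_new = kappa * np.arange(2, G + 1, dtype=float) ** (-alpha)
        pan = np.concatenate([[1000.0], 1000.0 + np.cumsum(n_new)])
        return AccumulationCurve(
            k=np.arange(1, G + 1), pan_median=pan,
            pan_iqr=np.zeros(G), core_median=np.full(G, 500.0),
            core_iqr=np.zeros(G), R=1, seed=0)

    def test_exact_power_law_recovery(self):
        fit = heaps_fit(self.power_law_curve(kappa=120.0, alpha=0.7, G=12))
        assert fit.kappa == pytest.approx(120.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.7, abs=1e-6)
        assert fit.verdict == "open"
        assert fit.gamma == pytest.approx(0.3, abs=1e-6)

    def test_closing_power_law(self):
        fit = heaps_fit(self.power_law_curve(kappa=50.0, alpha=1.6, G=12))
        assert fit.alpha == pytest.approx(1.6, abs=1e-6)
        assert fit.verdict == "closed"

    def test_constant_novelty_open(self):
        # constant new clusters per genome -> alpha ~ 0 -> open
        pan = 100.0 + 10.0 * np.arange(10)
        curve = AccumulationCurve(k=np.arange(1, 11), pan_median=pan,
                                  pan_iqr=np.zeros(10),
                                  core_median=np.full(10, 50.0),
                                  core_iqr=np.zeros(10), R=1, seed=0)
        fit = heaps_fit(curve)
        assert fit.verdict == "open"
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)

    def test_saturating_closed(self):
        pan = np.array([100.0, 110.0, 110.0, 110.0, 110.0])
        curve = AccumulationCurve(k=np.arange(1, 6), pan_median=pan,
                                  pan_iqr=np.zeros(5),
                                  core_median=np.full(5, 50.0),
                                  core_iqr=np.zeros(5), R=1, seed=0)
        fit = heaps_fit(curve)
        assert fit.verdict == "closed"

    def test_non_monotone_error(self):
        pan = np.array([100.0, 120.0, 110.0])
        curve = AccumulationCurve(k=np.arange(1, 4), pan_median=pan,
                                  pan_iqr=np.zeros(3),
                                  core_median=np.full(3, 50.0),
                                  core_iqr=np.zeros(3), R=1, seed=0)
        with pytest.raises(ValueError):
            heaps_fit(curve)


class TestUniqueVsDistance:
    def _partition_with_counts(self, counts):
        gids = [f"g{i}" for i in range(len(counts))]
        unique = {g: set(range(sum(counts[:i]), sum(counts[:i + 1])))
                  for i, (g, _) in enumerate(zip(gids, counts))}
        from panlin.pangenome import PangenomePartition
        return PangenomePartition(core=set(), accessory=set(),
                                  unique_by_genome=unique,
                                  n_genomes=len(gids), genome_ids=gids), gids

    def test_perfect_monotone(self):
        counts = [1, 2, 3, 4, 5]
        p, gids = self._partition_with_counts(counts)
        tips = ",".join(f"{g}:{0.1 * (i + 1):.3f}" for i, g in enumerate(gids))
        tree = read_newick(f"({tips},anchor:0.0);")
        rho, pval = unique_vs_distance(p, tree)
        assert rho == pytest.approx(1.0)
        assert pval < 0.05

    def test_anti_monotone(self):
        counts = [5, 4, 3, 2, 1]
        p, gids = self._partition_with_counts(counts)
        tips = ",".join(f"{g}:{0.1 * (i + 1):.3f}" for i, g in enumerate(gids))
        tree = read_newick(f"({tips},anchor:0.0);")
        rho, _ = unique_vs_distance(p, tree)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_oracle(self):
        counts = [3, 3, 1, 7, 7, 2, 5, 5, 5, 0]
        dists = [0.2, 0.3, 0.1, 0.9, 0.8, 0.2, 0.5, 0.5, 0.6, 0.05]
        p, gids = self._partition_with_counts(counts)
        tips = ",".join(f"{g}:{d}" for g, d in zip(gids, dists))
        tree = read_newick(f"({tips},anchor:0.0);")
        rho, _ = unique_vs_distance(p, tree)
        assert rho == pytest.approx(oracle_spearman(counts, dists))

    def test_too_few_genomes(self):
        p, gids = self._partition_with_counts([1, 2, 3])
        tree = read_newick("(g0:1,g1:2,g2:3);")
        with pytest.raises(ValueError, match="insufficient"):
            unique_vs_distance(p, tree)
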