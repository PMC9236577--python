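import numpy as np
import pytest

from svphylo.model import validate_solution
from svphylo.simulate import (
    ConfigError,
    Event,
    SimConfig,
    add_read_noise,
    realize_profiles,
    simulate_cohort,
    simulate_events,
    simulate_mixture,
    simulate_tree,
)


class TestTree:
    def test_two_leaves_unique_topology(self):
        t = simulate_tree(2, 0)
        assert t.N == 3 and t.validate() == []
        assert set(t.children(t.root)) == {0, 1}

    def test_binary_shape_at_n5(self):
        t = simulate_tree(5, 1)
        assert t.N == 9
        out = t.E.sum(axis=1)
        assert all(out[i] == 0 for i in range(5))
        assert all(out[i] == 2 for i in range(5, 9))

    def test_rejects_single_leaf(self):
        with pytest.raises(ConfigError):
            simulate_tree(1, 0)

    def test_uniform_over_labeled_topologies_at_n4(self):
        """Of the 15 labeled topologies on 4 leaves, 3 are balanced (p=0.2)."""
        rng = np.random.default_rng(2024)
        n_bal = 0
        n_draws = 4000
        for _ in range(n_draws):
            t = simulate_tree(4, rng)
            ch = t.children(t.root)
            balanced = all(c >= 4 for c in ch)  # both children internal
            n_bal += balanced
        p = n_bal / n_draws
        se = np.sqrt(0.2 * 0.8 / n_draws)
        assert abs(p - 0.2) < 5 * se, p


class TestEvents:
    def test_zero_rates_empty_log(self):
        t = simulate_tree(3, 0)
        cfg = SimConfig.toy(n_leaves=3, lambda_total=0.0, snv_rate=0.0)
        assert simulate_events(t, cfg, 0) == []

    def test_event_type_ratio_dup_to_inv(self):
        t = simulate_tree(2, 0)
        cfg = SimConfig(n_leaves=2, lambda_total=10000, snv_rate=0.0)
        evs = simulate_events(t, cfg, 1)
        kinds = np.array([e.kind for e in evs])
        n_dup, n_inv = (kinds == "dup").sum(), (kinds == "inv").sum()
        ratio = n_dup / n_inv
        assert 1.7 < ratio < 2.3, ratio  # weights 2:2:1:1

    def test_dup_multiplicity_uniform_2_to_6(self):
        t = simulate_tree(2, 0)
        cfg = SimConfig(n_leaves=2, lambda_total=6000, snv_rate=0.0)
        mults = [e.mult for e in simulate_events(t, cfg, 2) if e.kind == "dup"]
        counts = np.bincount(mults, minlength=7)[2:7]
        assert counts.min() > 0 and set(np.unique(mults)) <= {2, 3, 4, 5, 6}
        assert counts.max() / counts.min() < 1.3

    def test_per_branch_mode_places_on_every_edge(self):
        t = simulate_tree(4, 3)
        cfg = SimConfig.toy(n_leaves=4, lambda_branch=30.0, snv_rate=0.0)
        evs = simulate_events(t, cfg, 3)
        edges_hit = {e.edge for e in evs}
        all_edges = set(zip(*map(list, np.nonzero(t.E))))
        assert edges_hit == {(int(i), int(j)) for i, j in all_edges}


class TestRealize:
    def test_single_deletion_semantics(self):
        t = simulate_tree(2, 0)
        cfg = SimConfig.toy(n_leaves=2)
        ev = Event(0, "del", (2, 0), allele=0, chrom=0, start=1_000_000, end=2_000_000)
        prof, panel, tree, info = realize_profiles(t, [ev], cfg, 0)
        assert panel.l == 2 and panel.r >= 3
        v = panel.n_variants
        s = panel.segment_of
        # deleted span: allele-1 copy 0 in leaf 0, 1 elsewhere
        deleted = (panel.segments["start"] == 1_000_000).idxmax()
        assert prof.C[0, v + deleted] == 0
        assert prof.C[1, v + deleted] == 1 and prof.C[2, v + deleted] == 1
        # both junction breakpoints have copy 1 in leaf 0 only
        assert np.array_equal(prof.C[:, :2].sum(axis=1), [2, 0, 0])
        assert np.array_equal(prof.D, [1, 1])  # allele 0 = first allele

    def test_duplication_multiplies_preexisting_snv(self):
        t = simulate_tree(2, 0)
        cfg = SimConfig.toy(n_leaves=2)
        evs = [
            Event(0, "snv", (2, 0), allele=0, chrom=0, start=1_500_000, end=1_500_000),
            Event(1, "dup", (2, 0), allele=0, chrom=0, start=1_000_000, end=2_000_000, mult=3),
        ]
        prof, panel, tree, info = realize_profiles(t, evs, cfg, 0)
        snv_col = panel.l  # single SNV
        assert prof.C[0, snv_col] == 3  # rode the (only) duplicated copy
        s = panel.segment_of[snv_col]
        assert prof.C[0, panel.n_variants + s] == 3

    def test_variant_copies_bounded_by_allele_segment_copies(self, make_cohort):
        for seed in range(8):
            gt = make_cohort(seed=seed, n_leaves=3, lambda_total=8, snv_rate=10)
            gam = gt.profiles.gamma(gt.panel)
            v = gt.panel.n_variants
            allele = np.where(gt.profiles.D == 1, 0, 1)
            lim = gam[:, np.arange(v), allele]
            assert np.all(gt.profiles.C[:, :v] <= lim)


class TestMixtureAndNoise:
    def test_rows_on_simplex_and_dirichlet_mean(self):
        prof_C = np.ones((3, 4))
        from svphylo.model import CloneProfiles

        prof = CloneProfiles(C=prof_C, D=np.zeros(0, dtype=np.int8), c_max=10)
        freqs, F = simulate_mixture(prof, 8000, seed=0)
        assert np.allclose(freqs.U.sum(axis=1), 1.0)
        mean = freqs.U.mean(axis=0)
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / 8000)  # Dirichlet(1,1,1) moments
        assert np.all(np.abs(mean - 1 / 3) < 6 * se)

    def test_noiseless_f_is_exact_mixture(self, make_cohort):
        gt = make_cohort(seed=5)
        assert np.array_equal(gt.F_true, gt.freqs.U @ gt.profiles.C)

    def test_high_depth_limit_recovers_noiseless(self, make_cohort):
        gt = make_cohort(seed=6, m_samples=2)
        cfg = SimConfig.toy(n_leaves=2, read_depth=1e6)
        Fn, rc, nz = add_read_noise(gt.F_true, gt.panel, cfg, seed=1)
        denom = np.where(gt.F_true > 0.05, gt.F_true, 1.0)
        assert np.all(np.abs(Fn - gt.F_true) / denom < 0.01)

    def test_zero_vaf_stays_exactly_zero(self, make_cohort):
        gt = make_cohort(seed=8, m_samples=3)
        Fn, rc, nz = add_read_noise(gt.F_true, gt.panel, gt.config, seed=2)
        v = gt.panel.n_variants
        zero = gt.F_true[:, :v] == 0
        assert np.all(Fn[:, :v][zero] == 0)


class TestDeterminismAndValidity:
    def test_identical_seed_identical_cohort(self):
        cfg = SimConfig.toy(n_leaves=3, m_samples=3, lambda_total=5, snv_rate=6, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.profiles.C, b.profiles.C)
        assert np.array_equal(a.tree.E, b.tree.E)
        assert np.array_equal(a.obs.F, b.obs.F)
        assert a.panel.variant_ids() == b.panel.variant_ids()

    def test_ground_truths_satisfy_all_invariants(self):
        """Simulated truths validate cleanly across many configurations."""
        rng = np.random.default_rng(123)
        for i in range(25):
            cfg = SimConfig.toy(
                n_leaves=int(rng.integers(2, 5)),
                m_samples=int(rng.integers(1, 5)),
                lambda_total=float(rng.uniform(1, 8)),
                snv_rate=float(rng.uniform(1, 10)),
                c_max=8,
                seed=int(rng.integers(1 << 30)),
            )
            gt = simulate_cohort(cfg)
            rep = validate_solution(gt.panel, gt.tree, gt.profiles, gt.freqs)
            assert rep.ok, (i, rep.violations)
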