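"""Polarity-invariant clustering, KL selection, meta-clustering, labeling."""

import numpy as np
import pytest

from microstates.clustering import (
    TemplateSet,
    canonical_label,
    cluster_maps,
    dispersion_curve,
    krzanowski_lai,
    meta_cluster,
)
from microstates.gfp import extract_peak_maps, find_gfp_peaks, global_field_power
from microstates.maps import canonical_templates, polarity_corr, unit_gfp
from microstates.simulate import SimulationConfig, make_dipolar_templates, simulate


class TestPolarityCorr:
    def test_self_and_antipodal(self, rng):
        u = rng.standard_normal(19)
        assert polarity_corr(u, u)[0] == pytest.approx(1.0)
        r, a = polarity_corr(u, -u)
        assert r == pytest.approx(-1.0)
        assert a == pytest.approx(1.0)

    def test_hand_computed_value_on_sparse_maps(self):
        u = np.zeros(19); u[0], u[1] = 1.0, -1.0
        v = np.zeros(19); v[1], v[2] = 1.0, -1.0
        r, a = polarity_corr(u, v)
        assert r == pytest.approx(-0.5)
        assert a == pytest.approx(0.5)

    def test_zero_map_rejected(self, rng):
        with pytest.raises(ValueError):
            polarity_corr(np.zeros(19), rng.standard_normal(19))


class TestClusterMaps:
    def test_exact_two_template_recovery(self, montage, rng):
        t = make_dipolar_templates(montage, 2, seed=0)
        signs = rng.choice([-1.0, 1.0], size=40)
        amps = rng.uniform(1.0, 10.0, size=40)
        v = (signs * amps)[:, None] * t[rng.integers(2, size=40)]
        res = cluster_maps(v, 2, n_restarts=10, seed=0, montage=montage)
        assert res.explained_variance == pytest.approx(100.0)
        for tpl in res.template_set.templates:
            best = max(polarity_corr(tpl, t[j])[1] for j in range(2))
            assert best == pytest.approx(1.0)

    def test_k1_is_principal_direction(self, montage, rng):
        v = rng.standard_normal((30, 19))
        v -= v.mean(axis=1, keepdims=True)
        res = cluster_maps(v, 1, n_restarts=1, seed=0, montage=montage)
        vals, vecs = np.linalg.eigh(v.T @ v)
        assert polarity_corr(res.template_set.templates[0], vecs[:, -1])[1] == \
            pytest.approx(1.0)

    def test_k_larger_than_map_count_rejected(self, montage, rng):
        v = rng.standard_normal((3, 19))
        with pytest.raises(ValueError):
            cluster_maps(v, 4, montage=montage)

    def test_polarity_invariance_of_solution(self, montage, rng):
        v = rng.standard_normal((60, 19))
        v -= v.mean(axis=1, keepdims=True)
        flip = rng.choice([-1.0, 1.0], size=60)[:, None]
        a = cluster_maps(v, 3, n_restarts=10, seed=4, montage=montage)
        b = cluster_maps(v * flip, 3, n_restarts=10, seed=4, montage=montage)
        assert a.explained_variance == pytest.approx(b.explained_variance)
        assert a.dispersion == pytest.approx(b.dispersion)
        for ta in a.template_set.templates:
            assert max(polarity_corr(ta, tb)[1]
                       for tb in b.template_set.templates) == pytest.approx(1.0)

    def test_explained_variance_non_decreasing_in_k(self, montage, rng):
        v = rng.standard_normal((80, 19))
        _, ev, _ = dispersion_curve(v, range(1, 7), montage=montage,
                                    n_restarts=10, seed=0)
        evs = [ev[k] for k in sorted(ev)]
        assert all(b >= a - 1e-6 for a, b in zip(evs, evs[1:]))

    def test_dispersion_non_increasing_in_k(self, montage, rng):
        v = rng.standard_normal((80, 19))
        disp, _, _ = dispersion_curve(v, range(1, 7), montage=montage,
                                      n_restarts=10, seed=0)
        ws = [disp[k] for k in sorted(disp)]
        assert all(b <= a + 1e-6 for a, b in zip(ws, ws[1:]))


class TestKrzanowskiLai:
    def test_sharp_elbow_detected(self):
        # constructed dispersion with a single sharp elbow at k=4
        w = {1: 100.0, 2: 60.0, 3: 35.0, 4: 8.0, 5: 7.2, 6: 6.6, 7: 6.1,
             8: 5.7, 9: 5.4, 10: 5.15, 11: 4.95, 12: 4.8}
        kl, chosen, fallback = krzanowski_lai(w, n_features=19)
        assert chosen == 4
        assert not fallback
        assert kl[4] == max(kl.values())

    def test_geometric_dispersion_falls_back_to_global_max(self):
        w = {k: 0.8**k for k in range(1, 13)}
        _, chosen, fallback = krzanowski_lai(w, n_features=19)
        assert fallback

    def test_too_few_ks_rejected(self):
        with pytest.raises(ValueError):
            krzanowski_lai({1: 3.0, 2: 2.0, 3: 1.0}, n_features=19)

    def test_simulation_selects_true_k(self, montage):
        """Seeded 10-min simulations with 4 planted templates choose k=4."""
        hits = 0
        for seed in range(3):
            rec, _ = simulate(SimulationConfig(duration=600.0, seed=100 + seed))
            pm = extract_peak_maps(rec, find_gfp_peaks(global_field_power(rec)))
            disp, _, _ = dispersion_curve(pm, range(1, 13), montage=montage,
                                          n_restarts=5, seed=seed)
            _, chosen, _ = krzanowski_lai(disp, 19)
            hits += chosen == 4
        assert hits == 3


class TestMetaCluster:
    def test_identical_sets_reproduced(self, montage):
        t = make_dipolar_templates(montage, 4, seed=0)
        sets = [TemplateSet(templates=t, labels=tuple("ABCD"), montage=montage)
                for _ in range(5)]
        out = meta_cluster(sets, 4, n_restarts=10, seed=0)
        for tpl in out.templates:
            assert max(polarity_corr(tpl, t[j])[1] for j in range(4)) == \
                pytest.approx(1.0)

    def test_sign_flipped_copies_equivalent(self, montage):
        t = make_dipolar_templates(montage, 4, seed=0)
        a = TemplateSet(templates=t, labels=tuple("ABCD"), montage=montage)
        b = TemplateSet(templates=-t, labels=tuple("ABCD"), montage=montage)
        out = meta_cluster([a, b], 4, n_restarts=10, seed=0)
        for tpl in out.templates:
            assert max(polarity_corr(tpl, t[j])[1] for j in range(4)) == \
                pytest.approx(1.0)

    def test_mixed_k_rejected(self, montage):
        t4 = make_dipolar_templates(montage, 4, seed=0)
        t3 = t4[:3]
        sets = [TemplateSet(templates=t4, labels=tuple("ABCD"), montage=montage),
                TemplateSet(templates=t3, labels=tuple("ABC"), montage=montage)]
        with pytest.raises(ValueError, match="mixed"):
            meta_cluster(sets, 4)

    def test_noisy_subject_sets_recover_truth(self, montage, rng):
        truth = make_dipolar_templates(montage, 4, seed=0)
        sets = []
        for _ in range(10):
            noisy = np.stack([unit_gfp(truth[j] + 0.15 * rng.standard_normal(19))
                              for j in range(4)])
            sets.append(TemplateSet(templates=noisy, labels=tuple("ABCD"),
                                    montage=montage))
        out = meta_cluster(sets, 4, n_restarts=20, seed=1)
        for j in range(4):
            assert max(polarity_corr(truth[j], tpl)[1]
                       for tpl in out.templates) >= 0.97


class TestCanonicalLabel:
    def test_canonical_maps_are_fixed_point(self, montage):
        refs = canonical_templates(montage)
        ts = TemplateSet(templates=refs, labels=("T1", "T2", "T3", "T4"),
                         montage=montage)
        out = canonical_label(ts)
        assert out.labels == ("A", "B", "C", "D")
        for i, lab in enumerate("ABCD"):
            assert polarity_corr(out[lab], refs[i])[0] == pytest.approx(1.0)

    def test_permutation_and_sign_invariance(self, montage, rng):
        refs = canonical_templates(montage)
        perm = rng.permutation(4)
        flip = rng.choice([-1.0, 1.0], size=4)[:, None]
        ts = TemplateSet(templates=refs[perm] * flip,
                         labels=("W", "X", "Y", "Z"), montage=montage)
        out = canonical_label(ts)
        assert out.labels == ("A", "B", "C", "D")
        for i, lab in enumerate("ABCD"):
            assert polarity_corr(out[lab], refs[i])[1] == pytest.approx(1.0)

    def test_extra_templates_get_residual_letters(self, montage):
        t = make_dipolar_templates(montage, 6, seed=3)
        ts = TemplateSet(templates=t, labels=tuple("UVWXYZ"), montage=montage)
        out = canonical_label(ts)
        assert set(out.labels) == set("ABCDEF")
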