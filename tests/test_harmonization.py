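"""Harmonization transforms: isometry, mean relocation, equivalences."""

import numpy as np
import pytest

from spdharm import (
    Cohort,
    SimulationConfig,
    Subject,
    airm_distance,
    airm_frechet_mean,
    compute_lambda,
    generate_cohort,
    generate_commuting_sites,
    global_mean_lerm,
    harmonize,
    lerm_distance,
    lerm_frechet_mean,
    matrix_exp,
    matrix_log,
    pairwise_distances,
    pt_harmonize,
    rlet,
    site_means_lerm,
    transport_to_reference,
    whiten,
    is_spd,
)

from conftest import random_spd


def intra_site_distances(cohort, metric_fn):
    out = {}
    for k in cohort.sites:
        mats = cohort.matrices(site=k)
        out[k] = np.array([metric_fn(mats[i], mats[j])
                           for i in range(len(mats))
                           for j in range(i + 1, len(mats))])
    return out


class TestSiteMeans:
    def test_identical_matrices(self):
        cohort = Cohort([Subject("a", "s1", "plus", np.eye(2)),
                         Subject("b", "s1", "minus", np.eye(2))])
        np.testing.assert_allclose(site_means_lerm(cohort)["s1"], np.eye(2))

    def test_diagonal_geometric_mean(self):
        cohort = Cohort([Subject("a", "s1", "plus", np.diag([1.0, 4.0])),
                         Subject("b", "s1", "minus", np.diag([4.0, 1.0]))])
        np.testing.assert_allclose(site_means_lerm(cohort)["s1"],
                                   np.diag([2.0, 2.0]), atol=1e-12)

    def test_matches_per_site_lerm_mean(self, small_cohort):
        means = site_means_lerm(small_cohort)
        for k in small_cohort.sites:
            np.testing.assert_allclose(
                means[k], lerm_frechet_mean(small_cohort.matrices(site=k)),
                atol=1e-12)

    def test_global_mean_weights_sites_equally(self):
        # sites contribute equally regardless of subject counts
        means = {"a": np.diag([1.0, 1.0]),
                 "b": np.diag([np.e ** 2, np.e ** 2])}
        np.testing.assert_allclose(global_mean_lerm(means),
                                   np.diag([np.e, np.e]), atol=1e-12)

    def test_single_site_global_mean(self, rng):
        S = random_spd(rng, 3)
        np.testing.assert_allclose(global_mean_lerm({"only": S}), S,
                                   atol=1e-10)


class TestWhitening:
    def test_single_matrix_site_maps_to_identity(self, rng):
        S = random_spd(rng, 3)
        cohort = Cohort([Subject("a", "s1", "plus", S)])
        out, _ = whiten(cohort)
        np.testing.assert_allclose(out.subjects[0].matrix, np.eye(3),
                                   atol=1e-10)

    def test_site_means_relocate_to_identity(self, small_cohort):
        out, report = whiten(small_cohort)
        for k, d in report.site_mean_to_target.items():
            assert d < 1e-6
        # recompute independently of the report
        for k in out.sites:
            mean = airm_frechet_mean(out.matrices(site=k)).mean
            assert airm_distance(mean, np.eye(out.dim)) < 1e-6

    def test_intra_site_airm_distances_preserved(self, small_cohort):
        out, report = whiten(small_cohort)
        pre = intra_site_distances(small_cohort, airm_distance)
        post = intra_site_distances(out, airm_distance)
        for k in pre:
            np.testing.assert_allclose(pre[k], post[k], atol=1e-8)
        assert report.max_intra_site_distortion < 1e-8

    def test_outputs_remain_spd(self, small_cohort):
        out, _ = whiten(small_cohort)
        assert all(is_spd(s.matrix) for s in out.subjects)


class TestParallelTransport:
    def test_reference_equals_site_mean_is_identity_transform(self, rng):
        mats = [random_spd(rng, 3) for _ in range(3)]
        mean = airm_frechet_mean(mats).mean
        out = transport_to_reference(mats, mean, mean)
        for a, b in zip(mats, out):
            np.testing.assert_allclose(a, b, atol=1e-8 * np.linalg.norm(a))

    def test_identity_reference_equals_whitening(self, rng):
        from spdharm import matrix_inv_sqrt
        mats = [random_spd(rng, 3) for _ in range(4)]
        mean = airm_frechet_mean(mats).mean
        out = transport_to_reference(mats, mean, np.eye(3))
        w = matrix_inv_sqrt(mean)
        for M, T in zip(mats, out):
            np.testing.assert_allclose(T, w @ M @ w, atol=1e-8)

    def test_transported_mean_hits_reference(self, rng):
        mats = [random_spd(rng, 4) for _ in range(4)]
        mean = airm_frechet_mean(mats).mean
        ref = random_spd(rng, 4)
        out = transport_to_reference(mats, mean, ref)
        new_mean = airm_frechet_mean(out).mean
        np.testing.assert_allclose(new_mean, ref,
                                   atol=1e-6 * np.linalg.norm(ref))

    def test_commuting_mean_and_reference_closed_form(self):
        # diagonal site mean and reference: C = (ref/mean)^{1/2} entrywise
        mean = np.diag([1.0, 4.0])
        ref = np.diag([4.0, 1.0])
        mats = [np.diag([2.0, 2.0]), np.diag([1.0, 8.0])]
        C = np.diag(np.sqrt(np.diag(ref) / np.diag(mean)))
        expected = [C @ M @ C for M in mats]
        out = transport_to_reference(mats, mean, ref)
        for a, b in zip(expected, out):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_single_site_collapses_to_whitening(self, rng):
        mats = [random_spd(rng, 3) for _ in range(4)]
        cohort = Cohort([Subject(f"s{i}", "one", "plus", M)
                         for i, M in enumerate(mats)])
        via_pt, _ = pt_harmonize(cohort)
        via_mw, _ = whiten(cohort)
        for a, b in zip(via_pt.subjects, via_mw.subjects):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-6)

    def test_equivalence_to_whitening_on_commuting_cohort(self):
        synthetic = generate_commuting_sites(SimulationConfig(
            dim=5, n_sites=3, n_per_site_per_condition=4, seed=3))
        via_pt, _ = pt_harmonize(synthetic.cohort)
        via_mw, _ = whiten(synthetic.cohort)
        for a, b in zip(via_pt.subjects, via_mw.subjects):
            assert np.linalg.norm(a.matrix - b.matrix) < 1e-6

    def test_divergence_from_whitening_on_generic_cohort(self, small_cohort):
        via_pt, _ = pt_harmonize(small_cohort)
        via_mw, _ = whiten(small_cohort)
        gap = max(np.linalg.norm(a.matrix - b.matrix)
                  for a, b in zip(via_pt.subjects, via_mw.subjects))
        assert gap > 1e-6

    def test_intra_site_distances_preserved(self, small_cohort):
        out, report = pt_harmonize(small_cohort)
        pre = intra_site_distances(small_cohort, airm_distance)
        post = intra_site_distances(out, airm_distance)
        for k in pre:
            np.testing.assert_allclose(pre[k], post[k], atol=1e-8)
        assert report.max_intra_site_distortion < 1e-8


class TestRlet:
    def test_no_op_when_site_means_equal_global_mean(self, rng):
        # symmetric construction: two sites that are mirror images in log space
        L = rng.normal(size=(3, 3)); L = L + L.T
        cohort = Cohort([
            Subject("a1", "s1", "plus", matrix_exp(L)),
            Subject("a2", "s1", "minus", matrix_exp(-L)),
            Subject("b1", "s2", "plus", matrix_exp(L)),
            Subject("b2", "s2", "minus", matrix_exp(-L)),
        ])
        out, _ = rlet(cohort)
        for pre, post in zip(cohort.subjects, out.subjects):
            np.testing.assert_allclose(pre.matrix, post.matrix, atol=1e-10)

    def test_site_means_relocate_to_global_mean(self, biased_cohort):
        cohort = biased_cohort.cohort
        target = global_mean_lerm(site_means_lerm(cohort))
        out, report = rlet(cohort, target="global_mean")
        for k in out.sites:
            mean = lerm_frechet_mean(out.matrices(site=k))
            assert lerm_distance(mean, target) < 1e-8
        assert max(report.site_mean_to_target.values()) < 1e-8

    def test_identity_target_zeroes_site_log_means(self, biased_cohort):
        out, _ = rlet(biased_cohort.cohort, target="identity")
        for k in out.sites:
            logs = [matrix_log(M) for M in out.matrices(site=k)]
            np.testing.assert_allclose(np.mean(logs, axis=0),
                                       np.zeros_like(logs[0]), atol=1e-10)

    def test_intra_site_lerm_distances_exactly_preserved(self, biased_cohort):
        cohort = biased_cohort.cohort
        out, report = rlet(cohort)
        pre = intra_site_distances(cohort, lerm_distance)
        post = intra_site_distances(out, lerm_distance)
        for k in pre:
            np.testing.assert_allclose(pre[k], post[k], atol=1e-8)
        assert report.max_intra_site_distortion < 1e-8

    def test_global_and_identity_targets_share_distance_matrix(
            self, biased_cohort):
        cohort = biased_cohort.cohort
        out_g, _ = rlet(cohort, target="global_mean", compute_report=False)
        out_i, _ = rlet(cohort, target="identity", compute_report=False)
        D_g, _ = pairwise_distances(out_g, "lerm")
        D_i, _ = pairwise_distances(out_i, "lerm")
        np.testing.assert_allclose(D_g, D_i, atol=1e-10)

    def test_lambda_scales_intra_site_distances(self, small_cohort):
        sites = small_cohort.sites
        lambdas = {k: (2.0 if i == 0 else 1.0)
                   for i, k in enumerate(sites)}
        out, report = rlet(small_cohort, lambdas=lambdas)
        pre = intra_site_distances(small_cohort, lerm_distance)
        post = intra_site_distances(out, lerm_distance)
        np.testing.assert_allclose(post[sites[0]], 2.0 * pre[sites[0]],
                                   atol=1e-8)
        np.testing.assert_allclose(post[sites[1]], pre[sites[1]], atol=1e-8)
        # site means still relocate to the global mean
        assert max(report.site_mean_to_target.values()) < 1e-8

    def test_nonpositive_lambda_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="positive"):
            rlet(small_cohort,
                 lambdas={k: 0.0 for k in small_cohort.sites})

    def test_outputs_remain_spd(self, biased_cohort):
        out, _ = rlet(biased_cohort.cohort)
        assert all(is_spd(s.matrix) for s in out.subjects)


class TestComputeLambda:
    def test_equal_dispersion_gives_unit_lambda(self):
        synthetic = generate_cohort(SimulationConfig(
            dim=4, n_sites=3, n_per_site_per_condition=6,
            site_scale=0.0, site_dispersion=0.2, seed=5))
        lambdas = compute_lambda(synthetic.cohort)
        for v in lambdas.values():
            assert v == pytest.approx(1.0, abs=0.35)

    def test_two_site_hand_computation(self):
        # engineered mean intra-site LERM distances 1 and 3 -> λ = (2, 2/3)
        def pair(scale, site, tag):
            L = np.zeros((2, 2))
            L[0, 1] = L[1, 0] = scale / np.sqrt(2) / 2
            return [Subject(f"{tag}1", site, "plus", matrix_exp(L)),
                    Subject(f"{tag}2", site, "minus", matrix_exp(-L))]

        cohort = Cohort(pair(1.0, "s1", "a") + pair(3.0, "s2", "b"))
        lambdas = compute_lambda(cohort)
        assert lambdas["s1"] == pytest.approx(2.0, abs=1e-10)
        assert lambdas["s2"] == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_rescaling_equalizes_mean_dispersion(self):
        synthetic = generate_cohort(SimulationConfig(
            dim=5, n_sites=4, n_per_site_per_condition=5,
            site_scale=0.3, site_dispersion=(0.05, 0.1, 0.2, 0.4), seed=11))
        cohort = synthetic.cohort
        out, _ = harmonize(cohort, "rlet_rescaled", lambdas="auto",
                           compute_report=False)
        post = intra_site_distances(out, lerm_distance)
        means = [np.mean(v) for v in post.values()]
        assert max(means) - min(means) < 1e-6

    def test_small_site_rejected(self):
        cohort = Cohort([Subject("a", "s1", "plus", np.eye(2)),
                         Subject("b", "s2", "plus", np.eye(2)),
                         Subject("c", "s2", "minus", 2 * np.eye(2))])
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_lambda(cohort)


class TestHarmonizeDispatchAndQualitative:
    @pytest.mark.parametrize("method", ["mw", "pt", "rlet_global",
                                        "rlet_identity"])
    def test_dispatch_produces_spd_cohort(self, small_cohort, method):
        out, report = harmonize(small_cohort, method)
        assert len(out) == len(small_cohort)
        assert report.max_intra_site_distortion < 1e-8
        assert all(is_spd(s.matrix) for s in out.subjects)

    @pytest.mark.parametrize("method,metric", [
        ("mw", "airm"), ("rlet_global", "lerm")])
    def test_inter_site_distances_reduced(self, method, metric):
        from spdharm import block_summary
        synthetic = generate_cohort(SimulationConfig(
            dim=8, n_sites=3, n_per_site_per_condition=5,
            site_scale=0.6, site_dispersion=0.1, seed=33))
        cohort = synthetic.cohort
        out, _ = harmonize(cohort, method, compute_report=False)
        D0, o0 = pairwise_distances(cohort, metric)
        D1, o1 = pairwise_distances(out, metric)
        s0 = block_summary(D0, o0)
        s1 = block_summary(D1, o1)
        inter0 = s0.loc[s0.kind == "inter", "mean_distance"].mean()
        inter1 = s1.loc[s1.kind == "inter", "mean_distance"].mean()
        assert inter1 < inter0
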