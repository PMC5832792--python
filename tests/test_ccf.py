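"""CCF computation, joint clustering, cluster classification and the
clonality verdict."""

import numpy as np
import pytest

from hchc_clonality import (
    CcfCluster,
    CcfObservation,
    OriginTestResult,
    SharingSummary,
    SimConfig,
    build_ccf_observations,
    classify_clusters,
    clonality_verdict,
    cluster_ccf,
    compute_ccf,
    estimate_multiplicity,
    pooled_mle_ccf,
    simulate_patient,
)


class TestMultiplicityAndCcf:
    @pytest.mark.parametrize(
        "alt,depth,purity,cn,expected_m",
        [
            (25, 100, 0.5, 2, 1),   # clonal het at 50% purity -> raw 1.0
            (50, 100, 1.0, 2, 1),   # VAF 0.5 pure diploid
            (90, 100, 1.0, 2, 2),   # VAF 0.9 pure diploid -> both copies
            (0, 100, 0.5, 2, 1),    # zero alt clamps to the floor
            (100, 100, 1.0, 3, 3),  # saturated VAF clamps to c_t
        ],
    )
    def test_multiplicity_arithmetic(self, alt, depth, purity, cn, expected_m):
        assert estimate_multiplicity(alt, depth, purity, cn) == expected_m

    @pytest.mark.parametrize(
        "alt,depth,purity,cn,m,expected",
        [
            (25, 100, 0.5, 2, 1, 1.0),   # clonal diploid case
            (10, 100, 0.5, 2, 1, 0.4),
            (0, 100, 0.5, 2, 1, 0.0),
        ],
    )
    def test_ccf_arithmetic(self, alt, depth, purity, cn, m, expected):
        ccf, flagged = compute_ccf(alt, depth, purity, cn, m)
        assert ccf == pytest.approx(expected)
        assert not flagged

    def test_ccf_above_one_is_flagged_and_capped(self):
        ccf, flagged = compute_ccf(80, 100, 0.5, 2, 1)  # raw 3.2
        assert ccf == 1.5 and flagged

    def test_zero_purity_errors(self):
        with pytest.raises(ValueError):
            compute_ccf(10, 100, 0.0, 2, 1)


def _obs(i, alt_a, alt_b, depth=100, purity=1.0, cn=2, m=1):
    a = purity * m / (purity * cn + (1 - purity) * 2)
    return CcfObservation(
        key=("1", 1000 + i, "C", "T"),
        alt=(alt_a, alt_b),
        depth=(depth, depth),
        purity=(purity, purity),
        total_cn=(cn, cn),
        multiplicity=(m, m),
        ccf_point=(min(alt_a / depth / a, 1.5), min(alt_b / depth / a, 1.5)),
    )


def _planted(seed, n_per=30, depth=100):
    rng = np.random.default_rng(seed)
    obs = []
    i = 0
    for phi_a, phi_b in [(1, 1), (1, 0), (0, 1)]:
        for _ in range(n_per):
            obs.append(
                _obs(i, int(rng.binomial(depth, 0.5 * phi_a)),
                     int(rng.binomial(depth, 0.5 * phi_b)), depth=depth)
            )
            i += 1
    return obs


class TestClusterCcf:
    def test_single_clonal_cluster_recovered(self):
        rng = np.random.default_rng(4)
        obs = [_obs(i, int(rng.binomial(100, 0.5)), int(rng.binomial(100, 0.5)))
               for i in range(40)]
        clusters = classify_clusters(cluster_ccf(obs, k_max=4, seed=0))
        assert len(clusters) == 1
        c = clusters[0]
        assert abs(c.phi_a - 1.0) < 0.05 and abs(c.phi_b - 1.0) < 0.05
        assert c.location == "off_axis" and c.n_members == 40

    def test_planted_three_cluster_recovery(self):
        clusters = classify_clusters(cluster_ccf(_planted(seed=12), k_max=8, seed=0))
        assert len(clusters) == 3
        locs = {c.location for c in clusters}
        assert locs == {"off_axis", "axis_a", "axis_b"}
        for truth_a, truth_b in [(1, 1), (1, 0), (0, 1)]:
            assert any(
                abs(c.phi_a - truth_a) < 0.1 and abs(c.phi_b - truth_b) < 0.1
                for c in clusters
            )

    def test_k1_limit_equals_pooled_mle_closed_form(self):
        rng = np.random.default_rng(0)
        obs = [_obs(i, int(rng.binomial(100, 0.30)), int(rng.binomial(100, 0.22)),
                    purity=0.7) for i in range(50)]
        c = cluster_ccf(obs, k_max=1, seed=0)[0]
        mle_a, mle_b = pooled_mle_ccf(obs)
        assert abs(c.phi_a - mle_a) < 1e-6
        assert abs(c.phi_b - mle_b) < 1e-6

    def test_em_loglik_monotone_in_debug_mode(self):
        cluster_ccf(_planted(seed=3), k_max=3, seed=0, debug=True)  # asserts internally

    def test_component_swap_symmetry(self):
        obs = _planted(seed=8)
        swapped = [
            CcfObservation(
                key=o.key, alt=o.alt[::-1], depth=o.depth[::-1],
                purity=o.purity[::-1], total_cn=o.total_cn[::-1],
                multiplicity=o.multiplicity[::-1], ccf_point=o.ccf_point[::-1],
            )
            for o in obs
        ]
        ca = classify_clusters(cluster_ccf(obs, k_max=4, seed=0))
        cb = classify_clusters(cluster_ccf(swapped, k_max=4, seed=0))
        da = {tuple(sorted(c.members)): (round(c.phi_a, 2), round(c.phi_b, 2), c.location)
              for c in ca}
        db = {tuple(sorted(c.members)): (round(c.phi_a, 2), round(c.phi_b, 2), c.location)
              for c in cb}
        assert set(da) == set(db)
        flip = {"axis_a": "axis_b", "axis_b": "axis_a",
                "off_axis": "off_axis", "origin": "origin"}
        for mem, (pa, pb, loc) in da.items():
            pa2, pb2, loc2 = db[mem]
            assert (pa2, pb2) == (pb, pa) and loc2 == flip[loc]

    def test_too_few_mutations_advises_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            cluster_ccf([_obs(0, 50, 50)] * 3, k_max=2, seed=0)


class TestClassifyClusters:
    def _c(self, pa, pb):
        return CcfCluster(phi_a=pa, phi_b=pb, weight=1.0, members=[("1", 1, "C", "T")])

    @pytest.mark.parametrize(
        "pa,pb,expected",
        [
            (0.9, 0.8, "off_axis"),
            (0.9, 0.05, "axis_a"),
            (0.05, 0.9, "axis_b"),
            (0.1, 0.1, "origin"),  # boundary: strict inequality at tau
            (0.05, 0.05, "origin"),
        ],
    )
    def test_locations(self, pa, pb, expected):
        (c,) = classify_clusters([self._c(pa, pb)], tau=0.1)
        assert c.location == expected

    def test_tau_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_clusters([self._c(1, 1)], tau=0.6)


def _sharing(n_ub=80, pid="P1"):
    return SharingSummary(patient_id=pid, n_ubiquitous=n_ub, n_private_a=20,
                          n_private_b=30, labels={})


def _origin(p, obs=80, support=None):
    if support is None:
        support = "supports_monoclonal" if p < 1e-6 else "supports_independent"
    return OriginTestResult(expected_shared=0.001, observed_shared=obs,
                            p_value=p, verdict_support=support)


class TestClonalityVerdict:
    def test_monoclonal_requires_offaxis_cluster_and_tiny_p(self):
        big_off = CcfCluster(1.0, 1.0, 0.5, [("1", i, "C", "T") for i in range(40)],
                             location="off_axis")
        v = clonality_verdict(_sharing(), _origin(1e-100), [big_off])
        assert v.verdict == "monoclonal"
        # same clusters but inconclusive p -> ambiguous
        v2 = clonality_verdict(_sharing(), _origin(0.01, support="inconclusive"), [big_off])
        assert v2.verdict == "ambiguous"

    def test_independent_needs_support_and_no_offaxis(self):
        axis = [
            CcfCluster(1.0, 0.0, 0.5, [("1", i, "C", "T") for i in range(40)],
                       location="axis_a"),
            CcfCluster(0.0, 1.0, 0.5, [("2", i, "C", "T") for i in range(40)],
                       location="axis_b"),
        ]
        v = clonality_verdict(_sharing(0), _origin(1.0, obs=0), axis)
        assert v.verdict == "independent"

    def test_small_offaxis_cluster_does_not_flip_independent(self):
        noise = CcfCluster(0.5, 0.4, 0.05, [("1", 5, "C", "T")], location="off_axis")
        v = clonality_verdict(_sharing(0), _origin(1.0, obs=0), [noise])
        assert v.verdict == "independent"

    def test_simulated_verdicts_match_generator_truth(self):
        mono, _ = simulate_patient(SimConfig(seed=31, patient_id="M"))
        ind, _ = simulate_patient(
            SimConfig(origin="independent", n_branch_a=120, n_branch_b=120,
                      seed=32, patient_id="I")
        )
        from hchc_clonality import run_patient

        assert run_patient(mono)["verdict"]["verdict"] == "monoclonal"
        assert run_patient(ind)["verdict"]["verdict"] == "independent"


def test_build_observations_forces_absent_mutations_to_zero_alt(noise_free_pair):
    pair, truth = noise_free_pair
    obs = build_ccf_observations(pair)
    assert len(obs) == len(truth.mutations)
    by_cluster = dict(zip(map(tuple, truth.mutations[["chrom", "pos"]].values),
                          truth.mutations["cluster"]))
    for o in obs:
        cluster = by_cluster[(o.key[0], o.key[1])]
        if cluster == "branch_a":
            assert o.alt[1] == 0 and o.alt[0] > 0
        elif cluster == "branch_b":
            assert o.alt[0] == 0 and o.alt[1] > 0
        else:
            assert o.alt[0] > 0 and o.alt[1] > 0
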