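"""Spectra, NMF extraction and cosine matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hchc_clonality import (
    CHANNELS_96,
    SimConfig,
    SpectrumMatrix,
    build_spectrum,
    compare_components,
    cosine_similarity,
    match_signatures,
    nmf_extract,
    read_catalog,
    simulate_patient,
    synthetic_signature_catalog,
    write_catalog,
)
from hchc_clonality.signatures import channel_index, channel_mutation

from conftest import make_variant


class TestChannels:
    def test_purine_reference_is_reverse_complemented(self):
        # G>A with context TGA == C>T with context TCA on the other strand
        assert channel_index("G", "A", "TGA") == channel_index("C", "T", "TCA")
        v = make_variant("S1", ref="G", alt="A", context="TGA")
        spec = build_spectrum([v])
        assert spec.counts.loc["S1", "T[C>T]A"] == 1

    def test_channel_mapping_roundtrip(self):
        for i in range(96):
            ref, alt, ctx = channel_mutation(i)
            assert channel_index(ref, alt, ctx) == i

    def test_context_ref_disagreement_errors(self):
        with pytest.raises(ValueError, match="middle base"):
            channel_index("C", "T", "AAA")


class TestBuildSpectrum:
    def test_counts_conserve_usable_snvs(self, monoclonal_pair):
        pair, _ = monoclonal_pair
        variants = list(pair.variants_a) + list(pair.variants_b)
        spec = build_spectrum(variants, mode="ninety_six")
        n_snvs = sum(1 for v in variants if v.is_snv and v.context)
        assert spec.counts.values.sum() + spec.n_excluded == n_snvs
        # per-sample conservation
        for sid in (pair.component_a, pair.component_b):
            expected = sum(1 for v in variants if v.sample_id == sid and v.is_snv and v.context)
            assert spec.counts.loc[sid].sum() == expected

    def test_fractions_sum_to_one(self, monoclonal_pair):
        pair, _ = monoclonal_pair
        spec = build_spectrum(list(pair.variants_a), mode="ninety_six")
        np.testing.assert_allclose(spec.fractions.sum(axis=1).values, 1.0, atol=1e-9)

    def test_ct_dominated_sample_has_modal_ct_class(self):
        pair, _ = simulate_patient(SimConfig(seed=13, patient_id="P1"))
        spec = build_spectrum(list(pair.variants_a), mode="six")
        assert spec.counts.loc[pair.component_a].idxmax() == "C>T"

    def test_no_contexts_at_all_is_an_error(self):
        v = make_variant("S1", context="")
        with pytest.raises(ValueError, match="context"):
            build_spectrum([v], mode="ninety_six")


class TestNmf:
    def test_rank_one_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        w0 = rng.dirichlet(np.ones(96))
        h0 = rng.uniform(50, 200, size=6)
        V = np.outer(w0, h0)
        counts = pd.DataFrame(V.T, index=[f"s{i}" for i in range(6)], columns=list(CHANNELS_96))
        spec = SpectrumMatrix(counts=counts, mode="ninety_six")
        sigs = nmf_extract(spec, k=1, n_restarts=5, seed=0)
        assert cosine_similarity(sigs.W.values[:, 0], w0) > 0.99999
        assert sigs.reconstruction_error < 1e-3 * np.linalg.norm(V)

    def test_deterministic_given_seed(self, monoclonal_pair):
        pair, _ = monoclonal_pair
        spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
        a = nmf_extract(spec, k=2, n_restarts=3, seed=7)
        b = nmf_extract(spec, k=2, n_restarts=3, seed=7)
        assert a.W.equals(b.W) and a.H.equals(b.H)

    def test_monotone_objective_in_debug_mode(self, monoclonal_pair):
        pair, _ = monoclonal_pair
        spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
        nmf_extract(spec, k=2, n_restarts=2, seed=0, debug=True)  # asserts internally

    def test_matches_sklearn_reconstruction_error(self, monoclonal_pair):
        """Independent cross-check: our MU solver reaches the same Frobenius
        error as scikit-learn's NMF on the same matrix."""
        from sklearn.decomposition import NMF

        pair, _ = monoclonal_pair
        spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
        ours = nmf_extract(spec, k=2, n_restarts=10, seed=0)
        V = spec.counts.values.T.astype(float)
        sk = NMF(n_components=2, solver="mu", init="random", random_state=0,
                 max_iter=2000, tol=1e-8).fit(V)
        sk_err = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert ours.reconstruction_error <= sk_err * 1.02

    def test_permutation_of_samples_permutes_exposures_only(self, monoclonal_pair):
        pair, _ = monoclonal_pair
        spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
        perm = spec.counts.iloc[::-1]
        spec_p = SpectrumMatrix(counts=perm.sort_index(), mode="ninety_six")
        a = nmf_extract(spec, k=2, n_restarts=5, seed=1)
        b = nmf_extract(spec_p, k=2, n_restarts=5, seed=1)
        # sample order is sorted on construction, so W and H agree exactly
        assert np.allclose(a.W.values, b.W.values)

    def test_all_zero_matrix_errors(self):
        counts = pd.DataFrame(
            np.zeros((2, 96), dtype=int), index=["a", "b"], columns=list(CHANNELS_96)
        )
        spec = SpectrumMatrix(counts=counts, mode="ninety_six")
        with pytest.raises(ValueError, match="all-zero"):
            nmf_extract(spec, k=1)


class TestCosine:
    def test_identical_and_disjoint(self):
        u = np.zeros(96); u[0] = 3.0
        v = np.zeros(96); v[1] = 5.0
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity(u, v) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        u = np.zeros(96); u[:2] = 1.0
        v = np.zeros(96); v[0] = 1.0
        assert cosine_similarity(u, v) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(3), np.ones(3))

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, alpha):
        rng = np.random.default_rng(5)
        u, v = rng.uniform(0, 1, 96), rng.uniform(0, 1, 96)
        assert cosine_similarity(alpha * u, v) == pytest.approx(cosine_similarity(u, v))


class TestMatchSignatures:
    def _sigset(self, W):
        from hchc_clonality import SignatureSet

        ids = [f"DN{i+1}" for i in range(W.shape[1])]
        return SignatureSet(
            W=pd.DataFrame(W, index=list(CHANNELS_96), columns=ids),
            H=pd.DataFrame(np.ones((W.shape[1], 1)), index=ids, columns=["s"]),
            reconstruction_error=0.0,
            k=W.shape[1],
        )

    def test_exact_catalog_signature_matches_at_cosine_one(self):
        cat = synthetic_signature_catalog()
        sigset = self._sigset(cat[["S4"]].values)
        m = match_signatures(sigset, cat)
        row = m.table.iloc[0]
        assert row.best_match == "S4" and row.cosine == pytest.approx(1.0) and row.matched

    def test_blended_signature_matches_dominant_component(self):
        cat = synthetic_signature_catalog()
        w = 0.95 * cat["S4"].values + 0.05 * cat["S1"].values
        w = w / w.sum()
        m = match_signatures(self._sigset(w[:, None]), cat)
        row = m.table.iloc[0]
        assert row.best_match == "S4"
        # oracle: direct dot-product formula
        expected = float(w @ cat["S4"].values / (np.linalg.norm(w) * np.linalg.norm(cat["S4"])))
        assert row.cosine == pytest.approx(expected)

    def test_novel_signatures_stay_unmatched(self):
        cat = synthetic_signature_catalog(n_signatures=5)
        rng = np.random.default_rng(99)
        # three spiky processes orthogonal-ish to the catalog
        W = np.zeros((96, 3))
        for j, ch in enumerate([(7, 11), (23, 55), (70, 91)]):
            W[list(ch), j] = 0.5
        m = match_signatures(self._sigset(W), cat)
        assert not m.table["matched"].any()

    def test_catalog_in_wrong_channel_order_is_rejected(self):
        cat = synthetic_signature_catalog()
        scrambled = cat.iloc[::-1]
        sigset = self._sigset(cat[["S1"]].values)
        with pytest.raises(ValueError, match="channel"):
            match_signatures(sigset, scrambled)


def test_catalog_roundtrip(tmp_path):
    cat = synthetic_signature_catalog(n_signatures=4)
    p = tmp_path / "cat.csv"
    write_catalog(cat, p)
    back = read_catalog(p)
    np.testing.assert_allclose(back.values, cat.values)
    assert list(back.columns) == list(cat.columns)


class TestCompareComponents:
    def test_identical_mutation_sets_give_cosine_one(self):
        va = [make_variant("P1_HCC", pos=100 + i, context="ACG") for i in range(5)]
        vb = [make_variant("P1_iCCA", pos=100 + i, context="ACG") for i in range(5)]
        from hchc_clonality import PatientPair

        pair = PatientPair("P1", "P1_HCC", "P1_iCCA", 0.7, 0.7,
                           variants={"P1_HCC": va, "P1_iCCA": vb})
        spec = build_spectrum(va + vb)
        assert compare_components(spec, [pair])["P1"] == pytest.approx(1.0)

    def test_same_mixture_samples_are_near_identical(self):
        """Two components drawn from one signature mixture, ~500 SNVs each."""
        pair, _ = simulate_patient(
            SimConfig(n_trunk=0, n_branch_a=500, n_branch_b=500, origin="independent",
                      seed=3, patient_id="P1")
        )
        spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
        assert compare_components(spec, [pair])["P1"] >= 0.95

    def test_monoclonal_components_more_similar_than_independent(self):
        """Shared trunks pull component spectra together: with per-patient
        signature mixtures, paired monoclonal components are more similar
        than independently drawn ones on average."""
        cos_mono, cos_ind = [], []
        for seed in range(15):
            for origin, store, trunk, branch in (
                ("monoclonal", cos_mono, 120, 40),
                ("independent", cos_ind, 0, 160),
            ):
                pair, _ = simulate_patient(
                    SimConfig(origin=origin, n_trunk=trunk, n_branch_a=branch,
                              n_branch_b=branch, seed=seed, patient_id="X")
                )
                spec = build_spectrum(list(pair.variants_a) + list(pair.variants_b))
                store.append(compare_components(spec, [pair])["X"])
        assert np.mean(cos_mono) > np.mean(cos_ind)

    def test_zero_snv_component_reported_missing(self):
        from hchc_clonality import PatientPair

        va = [make_variant("P1_HCC", pos=100, context="ACG")]
        pair = PatientPair("P1", "P1_HCC", "P1_iCCA", 0.7, 0.7, variants={"P1_HCC": va})
        spec = build_spectrum(va)
        assert compare_components(spec, [pair])["P1"] is None
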