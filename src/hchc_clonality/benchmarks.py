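"""Parameter-recovery benchmarks run against simulated ground truth.

Each function generates data with the synthetic-tumor module, runs the
corresponding analysis stage, and measures recovery. They back both the
acceptance test suite and the standalone acceptance script; every function
is deterministic given its seed.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from . import ccf as ccf_mod
from . import sharing as sharing_mod
from . import signatures as sig_mod
from .datatypes import PatientPair
from .simulate import (
    SimConfig,
    draw_cohort_exposures,
    simulate_patient,
    synthetic_signature_catalog,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# 1. Sharing partition exactness in the noise-free limit
# ---------------------------------------------------------------------------


def sharing_exactness(n_patients: int = 5, seed: int = 0) -> dict:
    """Noise-free simulations (depth 1e4, purity 1, no CNVs): the recovered
    (ubiquitous, private_a, private_b) triple must equal generator truth."""
    n_exact = 0
    for i, s in enumerate(_child_seeds(seed, n_patients)):
        rng = np.random.default_rng(s)
        cfg = SimConfig(
            n_trunk=int(rng.integers(29, 109)),
            n_branch_a=int(rng.integers(20, 80)),
            n_branch_b=int(rng.integers(20, 80)),
            purity_a=1.0,
            purity_b=1.0,
            mean_depth=1e4,
            silent_fraction=0.0,
            n_cnv_shared=0,
            n_cnv_private=0,
            seed=s,
            patient_id=f"NF{i}",
        )
        pair, truth = simulate_patient(cfg)
        summary = sharing_mod.classify_sharing(pair)
        counts = truth.cluster_counts()
        recovered = (summary.n_ubiquitous, summary.n_private_a, summary.n_private_b)
        expected = (
            counts.get("trunk", 0),
            counts.get("branch_a", 0) + counts.get("subclone_a", 0),
            counts.get("branch_b", 0) + counts.get("subclone_b", 0),
        )
        n_exact += recovered == expected
    return {"n_exact": n_exact, "n_patients": n_patients,
            "exact_rate": n_exact / n_patients}


# ---------------------------------------------------------------------------
# 2. Origin-test calibration against Monte-Carlo collision simulation
# ---------------------------------------------------------------------------

_CALIBRATION_CASES = (  # (n_a, n_b, L, observed) giving lambda 0.1, 1, 5
    (1000, 1000, 10_000_000, 1),
    (1000, 1000, 1_000_000, 3),
    (1000, 1000, 200_000, 10),
)


def origin_test_calibration(seed: int = 0, n_draws: int = 100_000) -> dict:
    """Analytic Poisson tail vs the collision-simulation oracle; the worst
    ratio over lambda in {0.1, 1, 5} must stay within a factor of 2."""
    ratios = []
    for i, (n_a, n_b, L, obs) in enumerate(_CALIBRATION_CASES):
        p = sharing_mod.independent_origin_test(n_a, n_b, obs, L).p_value
        p_mc = sharing_mod.origin_test_mc_oracle(
            n_a, n_b, obs, L, n_draws=n_draws, seed=seed + i
        )
        ratios.append(max(p / p_mc, p_mc / p))
    return {"max_ratio": float(max(ratios)), "ratios": [float(r) for r in ratios],
            "n_draws": n_draws}


# ---------------------------------------------------------------------------
# 3. Origin classification over a mixed cohort
# ---------------------------------------------------------------------------


def _patient_verdict(pair: PatientPair, seed: int) -> str:
    summary = sharing_mod.classify_sharing(pair)
    origin = sharing_mod.independent_origin_test(
        summary.n_present_a, summary.n_present_b, summary.n_ubiquitous
    )
    obs = ccf_mod.build_ccf_observations(pair)
    clusters = ccf_mod.classify_clusters(ccf_mod.cluster_ccf(obs, seed=seed))
    return ccf_mod.clonality_verdict(summary, origin, clusters).verdict


def origin_classification(n_patients: int = 100, seed: int = 0) -> dict:
    """50/50 monoclonal (trunk drawn from the 29-108 ubiquitous range seen
    in real two-component cohorts) vs independent patients; accuracy of the
    combined clonality verdict."""
    seeds = _child_seeds(seed, n_patients)
    n_correct = 0
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        monoclonal = i % 2 == 0
        if monoclonal:
            cfg = SimConfig(
                n_trunk=int(rng.integers(29, 109)),
                n_branch_a=int(rng.integers(30, 90)),
                n_branch_b=int(rng.integers(30, 90)),
                seed=s,
                patient_id=f"M{i}",
            )
        else:
            cfg = SimConfig(
                origin="independent",
                n_branch_a=int(rng.integers(60, 160)),
                n_branch_b=int(rng.integers(60, 160)),
                seed=s,
                patient_id=f"I{i}",
            )
        pair, _ = simulate_patient(cfg)
        verdict = _patient_verdict(pair, seed=s)
        n_correct += verdict == ("monoclonal" if monoclonal else "independent")
    return {"n_correct": n_correct, "n_patients": n_patients,
            "accuracy": n_correct / n_patients}


# ---------------------------------------------------------------------------
# 4. Signature recovery by NMF
# ---------------------------------------------------------------------------


def signature_recovery(
    n_seeds: int = 20, seed: int = 0, n_restarts: int = 30, threshold: float = 0.9
) -> dict:
    """Cohorts of 7 patients (14 samples, >=300 SNVs each) generated from 3
    catalog signatures; NMF at k=3 must match every generator signature at
    the stated cosine. Reports the fraction of seeds fully recovered."""
    catalog = synthetic_signature_catalog()
    C = catalog[["S1", "S2", "S3"]].values
    n_ok = 0
    worst = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        exposures = draw_cohort_exposures(7, ["S1", "S2", "S3"], rng)
        variants = []
        for p, w in enumerate(exposures):
            cfg = SimConfig(
                patient_id=f"P{p + 1}",
                n_trunk=150,
                n_branch_a=160,
                n_branch_b=160,
                signature_weights=w,
                seed=int(rng.integers(2**31)),
            )
            pair, _ = simulate_patient(cfg, catalog=catalog)
            variants += list(pair.variants_a) + list(pair.variants_b)
        spectrum = sig_mod.build_spectrum(variants, mode="ninety_six")
        sigs = sig_mod.nmf_extract(spectrum, k=3, n_restarts=n_restarts, seed=s)
        W = sigs.W.values
        cos = np.array(
            [[sig_mod.cosine_similarity(W[:, i], C[:, j]) for j in range(3)]
             for i in range(3)]
        )
        ri, cj = linear_sum_assignment(-cos)
        matched = cos[ri, cj]
        worst.append(float(matched.min()))
        n_ok += bool((matched >= threshold).all())
    return {"n_ok": n_ok, "n_seeds": n_seeds, "recovery_rate": n_ok / n_seeds,
            "worst_cosine": min(worst)}


# ---------------------------------------------------------------------------
# 5. CCF cluster parameter recovery
# ---------------------------------------------------------------------------


def _planted_observations(seed: int, n_per: int = 30, depth: int = 100):
    rng = np.random.default_rng(seed)
    obs = []
    i = 0
    for phi_a, phi_b in ((1, 1), (1, 0), (0, 1)):
        for _ in range(n_per):
            alt_a = int(rng.binomial(depth, 0.5 * phi_a))
            alt_b = int(rng.binomial(depth, 0.5 * phi_b))
            obs.append(
                ccf_mod.CcfObservation(
                    key=("1", 1000 + i, "C", "T"),
                    alt=(alt_a, alt_b),
                    depth=(depth, depth),
                    purity=(1.0, 1.0),
                    total_cn=(2, 2),
                    multiplicity=(1, 1),
                    ccf_point=(min(2 * alt_a / depth, 1.5), min(2 * alt_b / depth, 1.5)),
                )
            )
            i += 1
    return obs


def ccf_recovery(n_seeds: int = 50, seed: int = 0, tol: float = 0.1) -> dict:
    """Planted clusters at (1,1), (1,0), (0,1), 30 mutations each at depth
    100: BIC must select K=3 with every CCF within ``tol`` of truth."""
    n_ok = 0
    for s in _child_seeds(seed, n_seeds):
        clusters = ccf_mod.cluster_ccf(_planted_observations(s), k_max=8, seed=s)
        ok = len(clusters) == 3 and all(
            any(abs(c.phi_a - ta) < tol and abs(c.phi_b - tb) < tol for c in clusters)
            for ta, tb in ((1, 1), (1, 0), (0, 1))
        )
        n_ok += ok
    return {"n_ok": n_ok, "n_seeds": n_seeds, "recovery_rate": n_ok / n_seeds}


# ---------------------------------------------------------------------------
# 6. K=1 closed-form limit
# ---------------------------------------------------------------------------


def k1_closed_form(seed: int = 0, n_mutations: int = 50, depth: int = 100) -> dict:
    """Max |EM - closed form| for a single diploid cluster."""
    rng = np.random.default_rng(seed)
    obs = []
    a = 0.7 / 2.0  # purity 0.7, diploid, multiplicity 1
    for i in range(n_mutations):
        alt_a = int(rng.binomial(depth, 0.30))
        alt_b = int(rng.binomial(depth, 0.22))
        obs.append(
            ccf_mod.CcfObservation(
                key=("1", i + 1, "C", "T"),
                alt=(alt_a, alt_b),
                depth=(depth, depth),
                purity=(0.7, 0.7),
                total_cn=(2, 2),
                multiplicity=(1, 1),
                ccf_point=(min(alt_a / depth / a, 1.5), min(alt_b / depth / a, 1.5)),
            )
        )
    cluster = ccf_mod.cluster_ccf(obs, k_max=1, seed=seed)[0]
    mle_a, mle_b = ccf_mod.pooled_mle_ccf(obs)
    return {
        "max_abs_diff": float(max(abs(cluster.phi_a - mle_a), abs(cluster.phi_b - mle_b))),
        "n_mutations": n_mutations,
    }


# ---------------------------------------------------------------------------
# 7. SMG calibration
# ---------------------------------------------------------------------------


def exact_binom_sf(x: int, n: int, p: float) -> float:
    """P(X >= x), X ~ Binomial(n, p), via exact rational arithmetic over the
    complementary lower sum (only x terms)."""
    if x <= 0:
        return 1.0
    pf = Fraction(p).limit_denominator(10**12)
    q = 1 - pf
    term = q**n
    lower = term
    for k in range(1, x):
        term = term * (n - k + 1) * pf / (k * q)
        lower += term
    return float(1 - lower)


def smg_null_calibration(
    n_genes: int = 200, n_seeds: int = 50, seed: int = 0,
    coding_length: int = 1500, n_samples: int = 14, mu: float = 5e-6, fdr: float = 0.1,
) -> dict:
    """Under the null every gene mutates at the background rate; the mean
    fraction flagged significant at the stated FDR must not exceed
    fdr + 3 standard errors. Also reports the worst binomial-tail deviation
    from the exact-arithmetic oracle."""
    from .smg import smg_test

    lengths = {f"G{i}": coding_length for i in range(n_genes)}
    fracs = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        counts = {
            g: int(rng.binomial(coding_length * n_samples, mu)) for g in lengths
        }
        df = smg_test(counts, lengths, mu=mu, n_samples=n_samples, fdr=fdr)
        fracs.append(float(df["significant"].mean()))
    fracs = np.array(fracs)
    se = float(fracs.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0

    # tail oracle agreement on a representative grid of counts
    n_trials = coding_length * n_samples
    tail_diffs = [
        abs(float(stats.binom.sf(x - 1, n_trials, 1e-6)) - exact_binom_sf(x, n_trials, 1e-6))
        for x in (1, 2, 3, 5)
    ]
    return {
        "mean_significant_fraction": float(fracs.mean()),
        "bound": fdr + 3 * se,
        "n_genes": n_genes,
        "n_seeds": n_seeds,
        "max_tail_oracle_diff": float(max(tail_diffs)),
    }


# ---------------------------------------------------------------------------
# 8. Format fidelity
# ---------------------------------------------------------------------------


def roundtrip_fidelity(seed: int = 0, tmpdir=None) -> dict:
    """Write-then-read equality for variants, CNVs, integrations and the
    Newick output (reparsed with an independent reader)."""
    import tempfile
    from pathlib import Path

    from . import io as vio
    from . import trees as trees_mod

    pair, _ = simulate_patient(SimConfig(seed=seed, patient_id="RT"))
    summary = sharing_mod.classify_sharing(pair)
    tree = trees_mod.build_tree(summary)

    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        d = Path(d)
        variants = list(pair.variants_a) + list(pair.variants_b)
        vio.write_variants(variants, d / "v.tsv")
        v_ok = vio.read_variants(d / "v.tsv") == variants
        cnvs = list(pair.cnvs_a) + list(pair.cnvs_b)
        vio.write_cnvs(cnvs, d / "c.tsv")
        c_ok = vio.read_cnvs(d / "c.tsv") == cnvs
        sites = list(pair.integrations_a) + list(pair.integrations_b)
        vio.write_integrations(sites, d / "i.tsv")
        i_ok = vio.read_integrations(d / "i.tsv") == sites

    nwk = trees_mod.write_newick(tree)
    try:
        import dendropy

        dt = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {leaf.taxon.label: int(leaf.edge.length)
                   for leaf in dt.leaf_node_iter()}
        newick_ok = lengths == {"HCC": tree.branch_a_length, "iCCA": tree.branch_b_length}
    except ImportError:  # pragma: no cover
        newick_ok = nwk.endswith("NORMAL;")
    return {
        "variants_ok": bool(v_ok),
        "cnvs_ok": bool(c_ok),
        "integrations_ok": bool(i_ok),
        "newick_ok": bool(newick_ok),
        "all_ok": bool(v_ok and c_ok and i_ok and newick_ok),
    }
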