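"""Cancer-cell-fraction computation, joint 2D clustering and the clonality
verdict.

The VAF of a mutation carried by a fraction ``phi`` of tumor cells, at
multiplicity m on local tumor copy number c_t in a sample of purity rho, is

    VAF = phi * rho * m / (rho * c_t + (1 - rho) * 2)

Inverting this maps allele counts to CCF points. Mutations are then
clustered *jointly* across the two tumor components with a finite binomial
mixture: cluster k has one CCF per component (phi_a, phi_b); the alt count
of mutation i in sample s is Binomial(depth_is, xi_is(phi_ks)) with xi the
forward VAF transform above. Fitting is EM with a grid-plus-bounded-refine
M-step, the number of clusters is selected by BIC over 1..k_max, and
initialization is a seeded k-means++-style draw on the CCF points — a
deterministic desk-scale stand-in for Dirichlet-process samplers such as
PyClone, which BIC-pruning of K approximates.

Mutations observed in only one component are force-included in the other
with alt = 0 at that component's median depth: clusters on a component's
axis (present in one component, absent in the other) are only observable
when absence itself is data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .datatypes import PatientPair, SomaticVariant, VariantKey
from .sharing import OriginTestResult, SharingSummary

_EPS = 1e-9


def estimate_multiplicity(alt: int, depth: int, purity: float, total_cn: int) -> int:
    """Round the purity/copy-number-scaled VAF to an integer multiplicity,
    clamped to [1, c_t]."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if total_cn < 1:
        raise ValueError("total_cn must be >= 1")
    raw = (alt / depth) * (purity * total_cn + (1.0 - purity) * 2.0) / purity
    return int(min(max(round(raw), 1), total_cn))


def compute_ccf(
    alt: int, depth: int, purity: float, total_cn: int, multiplicity: int
) -> tuple[float, bool]:
    """Point CCF of one observation, clipped to [0, 1.5].

    Returns (ccf, flagged) where ``flagged`` marks values above 1 —
    usually a miscalled multiplicity or copy number rather than a real
    super-clonal fraction, so they are preserved (capped at 1.5) rather
    than truncated to 1.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    if depth <= 0:
        return 0.0, False
    ccf = (alt / depth) * (purity * total_cn + (1.0 - purity) * 2.0) / (
        purity * multiplicity
    )
    return min(ccf, 1.5), ccf > 1.0


@dataclass
class CcfObservation:
    """Paired read-count observation of one mutation across both components."""

    key: VariantKey
    alt: tuple[int, int]
    depth: tuple[int, int]
    purity: tuple[float, float]
    total_cn: tuple[int, int]
    multiplicity: tuple[int, int]
    ccf_point: tuple[float, float]
    gene: str = ""


def _local_cn(segments, chrom: str, pos: int) -> int:
    for seg in segments:
        if seg.chrom == chrom and seg.contains(pos):
            return max(seg.total_cn, 1)
    return 2


def build_ccf_observations(
    pair: PatientPair, min_alt_either: int = 1
) -> list[CcfObservation]:
    """Assemble paired observations over the union of the pair's SNV keys.

    A key present in only one component contributes alt = 0 at the partner
    component's median depth (multiplicity 1), so axis clusters are
    representable. Indels are excluded (their VAFs are not comparable under
    the binomial read model used here).
    """
    per_comp: list[dict[VariantKey, SomaticVariant]] = []
    for vs in (pair.variants_a, pair.variants_b):
        per_comp.append({v.key: v for v in vs if v.is_snv})
    med_depth = []
    for comp in per_comp:
        depths = [v.depth for v in comp.values() if v.depth > 0]
        med_depth.append(int(np.median(depths)) if depths else 100)
    purities = (pair.purity_a, pair.purity_b)
    cnv_lists = (pair.cnvs_a, pair.cnvs_b)

    keys = sorted(set(per_comp[0]) | set(per_comp[1]))
    out: list[CcfObservation] = []
    for key in keys:
        chrom, pos, _, _ = key
        alt, depth, cns, mult, ccfs = [], [], [], [], []
        gene = ""
        best_alt = 0
        for s in range(2):
            v = per_comp[s].get(key)
            c_t = _local_cn(cnv_lists[s], chrom, pos)
            if v is not None:
                a, d = v.alt_count, max(v.depth, 1)
                gene = gene or v.gene
                best_alt = max(best_alt, a)
            else:
                a, d = 0, med_depth[s]
            m = estimate_multiplicity(a, d, purities[s], c_t)
            ccf, _ = compute_ccf(a, d, purities[s], c_t, m)
            alt.append(a)
            depth.append(d)
            cns.append(c_t)
            mult.append(m)
            ccfs.append(ccf)
        if best_alt < min_alt_either:
            continue
        out.append(
            CcfObservation(
                key=key,
                alt=(alt[0], alt[1]),
                depth=(depth[0], depth[1]),
                purity=purities,
                total_cn=(cns[0], cns[1]),
                multiplicity=(mult[0], mult[1]),
                ccf_point=(ccfs[0], ccfs[1]),
                gene=gene,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Finite binomial-mixture EM
# ---------------------------------------------------------------------------


@dataclass
class CcfCluster:
    """One mixture component: a CCF per tumor component plus its members."""

    phi_a: float
    phi_b: float
    weight: float
    members: list[VariantKey]
    location: str | None = None  # off_axis | axis_a | axis_b | origin

    @property
    def n_members(self) -> int:
        return len(self.members)


def _binom_loglik_matrix(
    alt: np.ndarray, depth: np.ndarray, a_coef: np.ndarray, phis: np.ndarray
) -> np.ndarray:
    """log P(alt | phi_k) summed over the two samples; (n, K)."""
    # xi[i, s, k] = a_coef[i, s] * phi[k, s]
    xi = np.clip(a_coef[:, :, None] * phis.T[None, :, :], _EPS, 1 - _EPS)
    ll = alt[:, :, None] * np.log(xi) + (depth - alt)[:, :, None] * np.log1p(-xi)
    return ll.sum(axis=1)


def _binom_const(alt: np.ndarray, depth: np.ndarray) -> float:
    return float(
        np.sum(gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1))
    )


def _mstep_phi(
    alt: np.ndarray,
    depth: np.ndarray,
    a: np.ndarray,
    resp: np.ndarray,
    n_stages: int = 5,
) -> float:
    """Maximize sum_i resp_i * log Binom(alt_i | depth_i, a_i * phi) over
    phi in [0, 1]: staged vectorized grid refinement plus a final parabolic
    step (the weighted log-likelihood is concave in phi, so the bracketed
    minimum is global)."""
    walt = resp * alt
    wrest = resp * (depth - alt)

    def nll_grid(phis: np.ndarray) -> np.ndarray:
        xi = np.clip(a[:, None] * phis[None, :], _EPS, 1 - _EPS)
        return -(walt[:, None] * np.log(xi) + wrest[:, None] * np.log1p(-xi)).sum(axis=0)

    lo, hi = 0.0, 1.0
    for _ in range(n_stages):
        grid = np.linspace(lo, hi, 41)
        vals = nll_grid(grid)
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        if hi - lo < 1e-9:
            return float(grid[j])
    # parabolic interpolation through the bracketing triple
    x = np.linspace(lo, hi, 3)
    y = nll_grid(x)
    denom = (y[0] - 2 * y[1] + y[2])
    if denom <= 0:
        return float(x[1])
    step = 0.5 * (y[0] - y[2]) / denom * (x[1] - x[0])
    return float(min(max(x[1] + step, lo), hi))


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on the 2D CCF points."""
    n = len(points)
    centers = [points[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((points - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(points[int(rng.integers(n))])
            continue
        centers.append(points[int(rng.choice(n, p=d2 / total))])
    return np.clip(np.array(centers), 0.0, 1.0)


def _fit_mixture(
    alt: np.ndarray,
    depth: np.ndarray,
    a_coef: np.ndarray,
    points: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    debug: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = len(alt)
    phis = _kmeanspp_init(points, k, rng)
    pi = np.full(k, 1.0 / k)
    const = _binom_const(alt, depth)
    prev_ll = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_member = _binom_loglik_matrix(alt, depth, a_coef, phis)
        weighted = log_member + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(weighted, axis=1)
        ll = float(norm.sum()) + const
        if debug and ll < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(weighted - norm[:, None])
        if ll - prev_ll < tol * (1.0 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        pi = resp.mean(axis=0)
        for kk in range(k):
            r = resp[:, kk]
            if r.sum() < 1e-10:
                continue
            for s in range(2):
                # coarse in-loop updates; full precision in the final polish
                phis[kk, s] = _mstep_phi(alt[:, s], depth[:, s], a_coef[:, s], r,
                                         n_stages=2)
    # polish converged CCFs at full precision and refresh the likelihood
    for kk in range(k):
        r = resp[:, kk]
        if r.sum() < 1e-10:
            continue
        for s in range(2):
            phis[kk, s] = _mstep_phi(alt[:, s], depth[:, s], a_coef[:, s], r)
    log_member = _binom_loglik_matrix(alt, depth, a_coef, phis)
    weighted = log_member + np.log(np.maximum(pi, 1e-300))
    norm = logsumexp(weighted, axis=1)
    resp = np.exp(weighted - norm[:, None])
    prev_ll = float(norm.sum()) + const
    return phis, pi, resp, prev_ll


def cluster_ccf(
    observations: Sequence[CcfObservation],
    k_max: int = 8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
    debug: bool = False,
) -> list[CcfCluster]:
    """Cluster mutations jointly over the two components; K chosen by BIC.

    Deterministic given ``seed``. Requires at least 5 mutations with
    positive depth in at least one component; pooled (multi-patient)
    analysis is advised below that.
    """
    obs = list(observations)
    usable = [o for o in obs if max(o.depth) > 0]
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} usable mutations; at least 5 are required — "
            "consider pooling mutations across patients"
        )
    alt = np.array([o.alt for o in obs], dtype=float)
    depth = np.array([o.depth for o in obs], dtype=float)
    a_coef = np.array(
        [
            [
                o.purity[s]
                * o.multiplicity[s]
                / (o.purity[s] * o.total_cn[s] + (1 - o.purity[s]) * 2.0)
                for s in range(2)
            ]
            for o in obs
        ]
    )
    points = np.clip(np.array([o.ccf_point for o in obs]), 0.0, 1.0)
    n = len(obs)

    best = None
    master = np.random.default_rng(seed)
    rngs = master.spawn(max(k_max, 1))
    for k in range(1, min(k_max, n) + 1):
        phis, pi, resp, ll = _fit_mixture(
            alt, depth, a_coef, points, k, rngs[k - 1], max_iter, tol, debug
        )
        n_params = 2 * k + (k - 1)
        bic = -2.0 * ll + n_params * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, phis, pi, resp)
    _, phis, pi, resp = best  # type: ignore[misc]

    assignment = np.argmax(resp, axis=1)
    clusters: list[CcfCluster] = []
    for kk in range(len(pi)):
        members = [obs[i].key for i in range(n) if assignment[i] == kk]
        if not members:
            continue
        clusters.append(
            CcfCluster(
                phi_a=float(phis[kk, 0]),
                phi_b=float(phis[kk, 1]),
                weight=float(len(members) / n),
                members=members,
            )
        )
    clusters.sort(key=lambda c: -c.n_members)
    return clusters


def classify_clusters(clusters: Sequence[CcfCluster], tau: float = 0.1) -> list[CcfCluster]:
    """Attach axis/off-axis locations: off-axis means both CCFs exceed
    ``tau`` (mutations truly present in both components)."""
    if not 0.0 < tau < 0.5:
        raise ValueError("tau must be in (0, 0.5)")
    for c in clusters:
        if c.phi_a > tau and c.phi_b > tau:
            c.location = "off_axis"
        elif c.phi_a > tau >= c.phi_b:
            c.location = "axis_a"
        elif c.phi_b > tau >= c.phi_a:
            c.location = "axis_b"
        else:
            c.location = "origin"
    return list(clusters)


# ---------------------------------------------------------------------------
# Verdict
# ---------------------------------------------------------------------------


@dataclass
class ClonalityVerdict:
    """Patient-level call with the evidence that produced it."""

    patient_id: str
    verdict: str  # monoclonal | independent | ambiguous
    sharing_p_value: float
    largest_off_axis: int
    spectra_cosine: float | None
    thresholds: dict = field(default_factory=dict)


def clonality_verdict(
    sharing: SharingSummary,
    origin: OriginTestResult,
    clusters: Sequence[CcfCluster],
    spectra_cosine: float | None = None,
    min_cluster: int = 10,
    p_threshold: float = 1e-6,
) -> ClonalityVerdict:
    """Combine the three evidence streams into one patient-level verdict.

    *monoclonal*: an off-axis cluster with at least ``min_cluster``
    mutations AND an origin-test p-value below ``p_threshold``.
    *independent*: the origin test supports independence and no off-axis
    cluster reaches ``min_cluster`` members. Anything else is ambiguous.
    """
    off_axis_sizes = [c.n_members for c in clusters if c.location == "off_axis"]
    largest = max(off_axis_sizes, default=0)
    if largest >= min_cluster and origin.p_value < p_threshold:
        verdict = "monoclonal"
    elif origin.verdict_support == "supports_independent" and largest < min_cluster:
        verdict = "independent"
    else:
        verdict = "ambiguous"
    return ClonalityVerdict(
        patient_id=sharing.patient_id,
        verdict=verdict,
        sharing_p_value=origin.p_value,
        largest_off_axis=largest,
        spectra_cosine=spectra_cosine,
        thresholds={"min_cluster": min_cluster, "p_threshold": p_threshold},
    )


def pooled_mle_ccf(observations: Sequence[CcfObservation]) -> tuple[float, float]:
    """Closed-form K=1 CCF estimate per component, pooled over mutations.

    When every mutation in a component shares one VAF coefficient a (same
    purity, diploid, multiplicity 1), the binomial MLE of a single cluster
    CCF in that component is sum(alt) / (a * sum(depth)), capped at 1.
    Used as the analytic oracle for the K=1 limit of the EM fit.
    """
    out = []
    for s in range(2):
        a_vals = {
            round(
                o.purity[s] * o.multiplicity[s]
                / (o.purity[s] * o.total_cn[s] + (1 - o.purity[s]) * 2.0),
                12,
            )
            for o in observations
        }
        if len(a_vals) != 1:
            raise ValueError("pooled MLE requires a shared VAF coefficient")
        a = a_vals.pop()
        tot_alt = sum(o.alt[s] for o in observations)
        tot_depth = sum(o.depth[s] for o in observations)
        out.append(min(tot_alt / (a * tot_depth), 1.0))
    return out[0], out[1]
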