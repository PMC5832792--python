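"""Ubiquitous/private classification and the independent-origin test.

A mutation is *ubiquitous* when its sample-independent key
(chrom, pos, ref, alt) is present in both tumor components with adequate
read support, and *private* otherwise; the private fraction over the key
union quantifies intratumor heterogeneity. CNV segments are *common* when
breakpoint-identical with the same direction (the strict 100%-reciprocal-
overlap rule; a relaxed reciprocal-overlap parameter is exposed).
Integration sites match within a breakpoint-jitter tolerance.

The independent-origin test asks how many shared mutation keys two
*unrelated* tumors would show: with n_a and n_b somatic point mutations
scattered over an exome of L positions, the chance-collision count is
approximately Poisson with rate n_a·n_b/L, so tens of shared mutations in
a ~30 Mb exome is astronomically unlikely under independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    CnvSegment,
    IntegrationSite,
    NONSYNONYMOUS_EFFECTS,
    PatientPair,
    SomaticVariant,
    VariantKey,
)


@dataclass
class SharingSummary:
    """Partition of a patient's mutation keys into ubiquitous/private."""

    patient_id: str
    n_ubiquitous: int
    n_private_a: int
    n_private_b: int
    labels: dict[VariantKey, str]  # key -> "ubiquitous" | "private_a" | "private_b"
    genes: dict[VariantKey, str] = field(default_factory=dict)
    n_present_a: int = 0  # keys passing the presence filter in each component
    n_present_b: int = 0

    @property
    def private_fraction(self) -> float:
        denom = self.n_ubiquitous + self.n_private_a + self.n_private_b
        if denom == 0:
            return 0.0
        return (self.n_private_a + self.n_private_b) / denom


@dataclass
class CnvSharingSummary:
    """Matched common CNV pairs plus private counts per component."""

    patient_id: str
    n_common: int
    n_private_a: int
    n_private_b: int
    matched: list[tuple[CnvSegment, CnvSegment]]


@dataclass
class OriginTestResult:
    """Poisson-collision test of the shared-mutation count under independence."""

    expected_shared: float
    observed_shared: int
    p_value: float
    verdict_support: str  # supports_monoclonal | inconclusive | supports_independent


def _present_keys(
    variants: Iterable[SomaticVariant],
    effect_filter: frozenset[str] | set[str],
    min_alt: int,
    min_vaf: float,
) -> set[VariantKey]:
    keys: set[VariantKey] = set()
    for v in variants:
        if effect_filter and v.effect not in effect_filter:
            continue
        if v.alt_count < min_alt:
            continue
        if min_vaf > 0 and v.vaf < min_vaf:
            continue
        keys.add(v.key)
    return keys


def classify_sharing(
    pair: PatientPair,
    effect_filter: frozenset[str] | set[str] | None = NONSYNONYMOUS_EFFECTS,
    min_alt: int = 3,
    min_vaf: float = 0.0,
) -> SharingSummary:
    """Label every mutation key of the pair as ubiquitous or private.

    Presence in a component requires at least ``min_alt`` supporting reads
    (default 3, guarding against noise-driven false sharing) and optionally
    a minimum VAF. ``effect_filter`` defaults to nonsynonymous SNV classes;
    pass ``None`` to keep every effect class. The labels partition the key
    union exactly.
    """
    if effect_filter is None:
        effect_filter = set()
    keys_a = _present_keys(pair.variants_a, effect_filter, min_alt, min_vaf)
    keys_b = _present_keys(pair.variants_b, effect_filter, min_alt, min_vaf)
    ubiquitous = keys_a & keys_b
    labels: dict[VariantKey, str] = {}
    for k in ubiquitous:
        labels[k] = "ubiquitous"
    for k in keys_a - ubiquitous:
        labels[k] = "private_a"
    for k in keys_b - ubiquitous:
        labels[k] = "private_b"
    genes: dict[VariantKey, str] = {}
    for v in list(pair.variants_a) + list(pair.variants_b):
        if v.key in labels and v.gene:
            genes.setdefault(v.key, v.gene)
    return SharingSummary(
        patient_id=pair.patient_id,
        n_ubiquitous=len(ubiquitous),
        n_private_a=len(keys_a - ubiquitous),
        n_private_b=len(keys_b - ubiquitous),
        labels=labels,
        genes=genes,
        n_present_a=len(keys_a),
        n_present_b=len(keys_b),
    )


# ---------------------------------------------------------------------------
# CNV sharing
# ---------------------------------------------------------------------------


def _check_non_overlapping(segs: Sequence[CnvSegment]) -> None:
    by_chrom: dict[str, list[CnvSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for prev, cur in zip(group, group[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"sample {prev.sample_id}: overlapping CNV segments on chrom "
                    f"{chrom}: [{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def _reciprocal_overlap(a: CnvSegment, b: CnvSegment) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def common_cnvs(
    segs_a: Sequence[CnvSegment],
    segs_b: Sequence[CnvSegment],
    patient_id: str = "",
    min_reciprocal_overlap: float = 1.0,
) -> CnvSharingSummary:
    """Match CNV segments between components by the common-CNV rule.

    A pair is common when the segments lie on the same chromosome, change
    copy number in the same direction (gain with gain, loss with loss), and
    their reciprocal overlap reaches ``min_reciprocal_overlap`` (default
    1.0: identical intervals, as produced by window-quantized callers).
    Matching is greedy 1-to-1 in coordinate order; each segment is used at
    most once.
    """
    _check_non_overlapping(segs_a)
    _check_non_overlapping(segs_b)
    a_sorted = sorted(segs_a, key=lambda s: (s.chrom, s.start))
    b_sorted = sorted(segs_b, key=lambda s: (s.chrom, s.start))
    used_b: set[int] = set()
    matched: list[tuple[CnvSegment, CnvSegment]] = []
    for a in a_sorted:
        if a.state == "neutral":
            continue
        for j, b in enumerate(b_sorted):
            if j in used_b or b.chrom != a.chrom or b.state != a.state:
                continue
            if _reciprocal_overlap(a, b) >= min_reciprocal_overlap:
                used_b.add(j)
                matched.append((a, b))
                break
    n_events_a = sum(1 for s in segs_a if s.state != "neutral")
    n_events_b = sum(1 for s in segs_b if s.state != "neutral")
    return CnvSharingSummary(
        patient_id=patient_id,
        n_common=len(matched),
        n_private_a=n_events_a - len(matched),
        n_private_b=n_events_b - len(matched),
        matched=matched,
    )


# ---------------------------------------------------------------------------
# Integration-site sharing
# ---------------------------------------------------------------------------


def shared_integrations(
    sites_a: Sequence[IntegrationSite],
    sites_b: Sequence[IntegrationSite],
    tolerance_bp: int = 500,
) -> list[tuple[IntegrationSite, IntegrationSite]]:
    """Greedy nearest matching of integration sites within ``tolerance_bp``.

    Breakpoint assembly jitters by up to a few hundred bases between
    samples; two sites on the same chromosome within the tolerance count
    as one shared integration event.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    candidates = [
        (abs(a.pos - b.pos), i, j)
        for i, a in enumerate(sites_a)
        for j, b in enumerate(sites_b)
        if a.chrom == b.chrom and abs(a.pos - b.pos) <= tolerance_bp
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[IntegrationSite, IntegrationSite]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((sites_a[i], sites_b[j]))
    return out


# ---------------------------------------------------------------------------
# Independent-origin test
# ---------------------------------------------------------------------------


def independent_origin_test(
    n_a: int,
    n_b: int,
    observed_shared: int,
    exome_size_bp: int = 30_000_000,
    p_threshold: float = 1e-6,
) -> OriginTestResult:
    """Upper-tail Poisson test of the shared-mutation count.

    Null model: two independent tumors place n_a and n_b mutations
    uniformly over ``exome_size_bp`` positions, so the shared count is
    (to excellent approximation) Poisson with rate n_a·n_b/L. The p-value
    is P(X >= observed_shared); p below ``p_threshold`` supports a
    monoclonal origin, an observed count at or below the chance expectation
    supports independence, anything else is inconclusive.
    """
    if min(n_a, n_b, observed_shared) < 0:
        raise ValueError("counts must be non-negative")
    if exome_size_bp <= 0:
        raise ValueError("exome_size_bp must be positive")
    if observed_shared > min(n_a, n_b):
        raise ValueError(
            f"observed_shared={observed_shared} exceeds min(n_a, n_b)="
            f"{min(n_a, n_b)}: impossible overlap"
        )
    lam = n_a * n_b / exome_size_bp
    p_value = float(stats.poisson.sf(observed_shared - 1, lam))  # P(X >= obs)
    if p_value < p_threshold:
        verdict = "supports_monoclonal"
    elif observed_shared <= lam:
        verdict = "supports_independent"
    else:
        verdict = "inconclusive"
    return OriginTestResult(
        expected_shared=lam,
        observed_shared=observed_shared,
        p_value=p_value,
        verdict_support=verdict,
    )


def origin_test_mc_oracle(
    n_a: int,
    n_b: int,
    observed_shared: int,
    exome_size_bp: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the origin-test p-value by direct collision
    simulation.

    Fixing component A's n_a positions (uniform placement makes any fixed
    set equivalent) and drawing component B's n_b positions uniformly
    without replacement, the collision count per draw is a hypergeometric
    variate; each draw simulates one random position set and counts
    collisions. Returns the fraction of draws with at least
    ``observed_shared`` collisions.
    """
    rng = np.random.default_rng(seed)
    counts = rng.hypergeometric(n_a, exome_size_bp - n_a, n_b, size=n_draws)
    return float(np.mean(counts >= observed_shared))
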