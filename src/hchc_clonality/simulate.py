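"""Synthetic paired-tumor generator with known clonal ground truth.

The study system is a combined liver tumor whose two microdissected
components (HCC and iCCA) either descend from one transformed clone
(monoclonal: a shared trunk of mutations plus private branches) or arose
independently (no trunk; any key shared between components is a positional
coincidence). The generator emulates the whole observable cascade:

* somatic SNV positions drawn uniformly without replacement from an exome
  coordinate space (default 30 Mb) laid out over 22 chromosomes;
* each mutation's substitution/context identity drawn from a mixture of
  reference signatures and reverse-mapped to (ref, alt, trinucleotide);
* cluster structure — trunk at CCF (1,1), clonal private branches at CCF 1
  on one axis, optional subclones at CCF ~ U(0.2, 0.6);
* read counts via depth ~ Poisson(mean_depth) and
  alt ~ Binomial(depth, VAF) with VAF = ccf·rho·m / (rho·c_t + (1-rho)·2)
  using the local copy-number state (the same likelihood the CCF clustering
  stage inverts);
* shared CNV segments with identical breakpoints in both components plus
  private segments, and shared/private HBV integration sites.

A variant row is emitted for a sample only when the sampled alt count is at
least 1, mimicking a somatic caller; contexts are generated directly in
pyrimidine-normalized space. All randomness derives from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CnvSegment,
    IntegrationSite,
    PatientPair,
    SampleManifest,
    SomaticVariant,
)
from .signatures import CHANNELS_96, channel_mutation
from . import io as vio

N_CHROMS = 22


# ---------------------------------------------------------------------------
# Synthetic reference catalog
# ---------------------------------------------------------------------------


def synthetic_signature_catalog(n_signatures: int = 30, seed: int = 20180301) -> pd.DataFrame:
    """A deterministic synthetic 96-channel signature catalog.

    This is a stand-in constructed by this package, not a published
    reference catalog: the first three signatures are given recognizable
    shapes (CpG-focused C>T, dominating the default mixture so simulated
    cohorts show the C:G>T:A-predominant spectrum typical of liver cancer;
    a C>A-heavy and a T>C-heavy process), and the remainder are sparse
    Dirichlet draws. Columns sum to 1 and carry ids S1..Sn.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(CHANNELS_96)
    sigs = np.empty((n_ch, n_signatures))

    def shaped(hot: np.ndarray, hot_mass: float) -> np.ndarray:
        w = rng.uniform(0.2, 1.0, n_ch)
        w = (1.0 - hot_mass) * w / w.sum()
        h = rng.uniform(0.5, 1.0, hot.sum())
        w[hot] += hot_mass * h / h.sum()
        return w

    idx = np.arange(n_ch)
    sub = idx // 16  # substitution class per channel
    three = idx % 4  # 3' base index (A,C,G,T)
    sigs[:, 0] = shaped((sub == 2) & (three == 2), 0.75)  # C>T at NpCpG
    sigs[:, 1] = shaped(sub == 0, 0.70)  # C>A
    sigs[:, 2] = shaped(sub == 4, 0.70)  # T>C
    for j in range(3, n_signatures):
        sigs[:, j] = rng.dirichlet(np.full(n_ch, 0.25))
    cols = [f"S{j + 1}" for j in range(n_signatures)]
    return pd.DataFrame(sigs, index=list(CHANNELS_96), columns=cols)


def draw_cohort_exposures(
    n_patients: int,
    signature_ids: Sequence[str],
    rng: np.random.Generator,
    alpha: float = 0.5,
    min_dominant: float = 0.8,
    max_tries: int = 1000,
) -> list[dict[str, float]]:
    """Per-patient signature exposures for a simulated cohort.

    Draws sparse Dirichlet(alpha) mixtures and redraws until every
    signature dominates (exposure >= ``min_dominant``) in at least one
    patient — the situation in real cohorts where an extracted process is
    actually detectable; a process with near-zero exposure everywhere is
    unrecoverable by construction, whatever the method.
    """
    k = len(signature_ids)
    for _ in range(max_tries):
        w = rng.dirichlet(np.full(k, alpha), size=n_patients)
        if all((w[:, j] >= min_dominant).any() for j in range(k)):
            return [dict(zip(signature_ids, map(float, row))) for row in w]
    raise RuntimeError(
        "could not draw exposures with every signature dominant somewhere; "
        "increase n_patients or lower min_dominant"
    )


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of one simulated patient.

    Defaults mirror the architecture of a typical combined-liver-tumor
    exome: ~160 mutations per patient split into a trunk of 70 shared
    mutations and private branches of 45 each (private fraction 0.56),
    sequencing depth ~150x, tumor purity 0.7, a minority of shared CNV
    segments, and HBV integration shared between components in a minority
    of patients.
    """

    origin: str = "monoclonal"  # "monoclonal" | "independent"
    n_trunk: int = 70
    n_branch_a: int = 45
    n_branch_b: int = 45
    subclone_fraction: float = 0.0
    purity_a: float = 0.7
    purity_b: float = 0.7
    mean_depth: float = 150.0
    signature_weights: dict[str, float] | None = None  # catalog id -> weight
    n_cnv_shared: int = 5
    n_cnv_private: int = 30
    p_shared_integration: float = 0.15
    n_private_integrations: int = 1
    silent_fraction: float = 0.3
    exome_size_bp: int = 30_000_000
    seed: int = 0
    patient_id: str = "SIM1"

    def __post_init__(self) -> None:
        if self.origin not in ("monoclonal", "independent"):
            raise ValueError(f"unknown origin mode {self.origin!r}")
        if self.origin == "independent":
            self.n_trunk = 0  # no shared ancestor, no trunk
        for name in ("n_trunk", "n_branch_a", "n_branch_b", "n_cnv_shared",
                     "n_cnv_private", "n_private_integrations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.subclone_fraction < 1.0:
            raise ValueError("subclone_fraction must be in [0, 1)")
        if not 0.0 <= self.p_shared_integration <= 1.0:
            raise ValueError("p_shared_integration must be in [0, 1]")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError("silent_fraction must be in [0, 1]")
        for name, p in (("purity_a", self.purity_a), ("purity_b", self.purity_b)):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.mean_depth <= 0 or self.exome_size_bp <= 0:
            raise ValueError("mean_depth and exome_size_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth of one simulated patient.

    ``mutations`` has one row per distinct mutation with columns chrom, pos,
    ref, alt, gene, effect, cluster, ccf_a, ccf_b, signature. CNV and
    integration truths carry shared/private labels. Trunk rows always have
    ccf_a = ccf_b = 1.
    """

    origin: str
    mutations: pd.DataFrame
    cnv_labels: list[tuple[CnvSegment, str]]  # (segment, "shared"|"private")
    integration_labels: list[tuple[IntegrationSite, str]]

    def cluster_counts(self, nonsilent_only: bool = False) -> dict[str, int]:
        df = self.mutations
        if nonsilent_only:
            df = df[df["effect"] != "silent"]
        return df["cluster"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _chrom_of(gpos: np.ndarray, exome_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Map global exome coordinates to (chrom index 0-21, 1-based position)."""
    chrom_len = -(-exome_size // N_CHROMS)  # ceil
    ci = np.minimum(gpos // chrom_len, N_CHROMS - 1)
    pos = gpos - ci * chrom_len + 1
    return ci.astype(int), pos.astype(int)


def _draw_mutation_identities(
    rng: np.random.Generator,
    n: int,
    catalog: pd.DataFrame,
    weights: Mapping[str, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel indices and originating-signature ids for n mutations."""
    if weights is None:
        cols = list(catalog.columns[:3])
        weights = dict(zip(cols, (0.6, 0.25, 0.15)))
    w = np.array([float(weights.get(c, 0.0)) for c in catalog.columns])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("signature_weights must be non-negative with positive sum")
    w = w / w.sum()
    sig_idx = rng.choice(len(w), size=n, p=w)
    probs = catalog.values / catalog.values.sum(axis=0)
    channels = np.empty(n, dtype=int)
    for j in np.unique(sig_idx):
        mask = sig_idx == j
        channels[mask] = rng.choice(96, size=mask.sum(), p=probs[:, j])
    return channels, np.asarray(catalog.columns)[sig_idx]


def _simulate_cnvs(
    rng: np.random.Generator, config: SimConfig, sample_a: str, sample_b: str
) -> tuple[dict[str, list[CnvSegment]], list[tuple[CnvSegment, str]]]:
    """Non-overlapping segments per sample; shared ones breakpoint-identical."""
    chrom_len = -(-config.exome_size_bp // N_CHROMS)
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def place(samples: list[str]) -> tuple[int, int, int] | None:
        for _ in range(200):
            ci = int(rng.integers(0, N_CHROMS))
            length = int(rng.integers(5, 31)) * 10_000  # 50-300 kb, 10 kb grid
            if length >= chrom_len:
                continue
            start = int(rng.integers(0, (chrom_len - length) // 10_000)) * 10_000
            end = start + length
            if all(
                end <= s or start >= e
                for smp in samples
                for (s, e) in occupied.get((smp, ci), [])
            ):
                for smp in samples:
                    occupied.setdefault((smp, ci), []).append((start, end))
                return ci, start, end
        return None

    def make(sample: str, ci: int, start: int, end: int) -> CnvSegment:
        gain = rng.random() < 0.6
        cn = int(rng.integers(3, 6)) if gain else 1
        return CnvSegment(
            sample_id=sample,
            chrom=str(ci + 1),
            start=start,
            end=end,
            state="gain" if gain else "loss",
            total_cn=cn,
        )

    cnvs: dict[str, list[CnvSegment]] = {sample_a: [], sample_b: []}
    labels: list[tuple[CnvSegment, str]] = []
    n_shared = config.n_cnv_shared if config.origin == "monoclonal" else 0
    for _ in range(n_shared):
        spot = place([sample_a, sample_b])
        if spot is None:
            continue
        ci, start, end = spot
        gain = rng.random() < 0.6
        cn = int(rng.integers(3, 6)) if gain else 1
        for smp in (sample_a, sample_b):
            seg = CnvSegment(
                sample_id=smp, chrom=str(ci + 1), start=start, end=end,
                state="gain" if gain else "loss", total_cn=cn,
            )
            cnvs[smp].append(seg)
            labels.append((seg, "shared"))
    for smp in (sample_a, sample_b):
        for _ in range(config.n_cnv_private):
            spot = place([smp])
            if spot is None:
                continue
            ci, start, end = spot
            seg = make(smp, ci, start, end)
            cnvs[smp].append(seg)
            labels.append((seg, "private"))
    for smp in cnvs:
        cnvs[smp].sort(key=lambda s: (int(s.chrom), s.start))
    return cnvs, labels


def _local_cn(cnvs: Sequence[CnvSegment], chrom: str, pos: int) -> int:
    for seg in cnvs:
        if seg.chrom == chrom and seg.contains(pos):
            return max(seg.total_cn, 1)  # a retained mutation needs >= 1 copy
    return 2


def expected_vaf(ccf: float, purity: float, total_cn: int, multiplicity: int = 1) -> float:
    """VAF of a mutation at cancer-cell fraction ``ccf`` given purity and
    local tumor copy number (normal cells contribute two reference copies)."""
    return ccf * purity * multiplicity / (purity * total_cn + (1.0 - purity) * 2.0)


# ---------------------------------------------------------------------------
# Patient and cohort simulation
# ---------------------------------------------------------------------------


def simulate_patient(
    config: SimConfig, catalog: pd.DataFrame | None = None
) -> tuple[PatientPair, SimTruth]:
    """Generate one patient pair plus its ground truth.

    Deterministic given ``config.seed``: the same config yields identical
    output on every run.
    """
    if catalog is None:
        catalog = synthetic_signature_catalog()
    rng = np.random.default_rng(config.seed)
    sample_a = f"{config.patient_id}_HCC"
    sample_b = f"{config.patient_id}_iCCA"

    n_sub_a = int(round(config.subclone_fraction * config.n_branch_a))
    n_sub_b = int(round(config.subclone_fraction * config.n_branch_b))
    n_a_tot = config.n_branch_a
    n_b_tot = config.n_branch_b
    n_total = config.n_trunk + n_a_tot + n_b_tot
    if n_total > config.exome_size_bp:
        raise ValueError(
            f"requested {n_total} mutations exceeds {config.exome_size_bp} exome positions"
        )

    # --- positions ---------------------------------------------------------
    if config.origin == "monoclonal":
        gpos = rng.choice(config.exome_size_bp, size=n_total, replace=False)
        gpos_a = gpos[config.n_trunk : config.n_trunk + n_a_tot]
        gpos_b = gpos[config.n_trunk + n_a_tot :]
        gpos_trunk = gpos[: config.n_trunk]
    else:  # independent: each component accumulates its own mutations
        gpos_trunk = np.empty(0, dtype=int)
        gpos_a = rng.choice(config.exome_size_bp, size=n_a_tot, replace=False)
        gpos_b = rng.choice(config.exome_size_bp, size=n_b_tot, replace=False)

    sub_ccf_a = float(rng.uniform(0.2, 0.6))
    sub_ccf_b = float(rng.uniform(0.2, 0.6))

    records: list[dict] = []

    def add_block(gp: np.ndarray, cluster: str, ccf_a: float, ccf_b: float) -> None:
        n = len(gp)
        if n == 0:
            return
        chans, sigs = _draw_mutation_identities(rng, n, catalog, config.signature_weights)
        ci, pos = _chrom_of(gp, config.exome_size_bp)
        silent = rng.random(n) < config.silent_fraction
        for i in range(n):
            ref, alt, context = channel_mutation(int(chans[i]))
            records.append(
                {
                    "chrom": str(ci[i] + 1),
                    "pos": int(pos[i]),
                    "ref": ref,
                    "alt": alt,
                    "context": context,
                    "gene": f"G{int(gp[i]) // 30_000:06d}",
                    "effect": "silent" if silent[i] else "missense",
                    "cluster": cluster,
                    "ccf_a": ccf_a,
                    "ccf_b": ccf_b,
                    "signature": sigs[i],
                }
            )

    add_block(gpos_trunk, "trunk", 1.0, 1.0)
    add_block(gpos_a[: n_a_tot - n_sub_a], "branch_a", 1.0, 0.0)
    add_block(gpos_a[n_a_tot - n_sub_a :], "subclone_a", sub_ccf_a, 0.0)
    add_block(gpos_b[: n_b_tot - n_sub_b], "branch_b", 1.0, 0.0)
    add_block(gpos_b[n_b_tot - n_sub_b :], "subclone_b", sub_ccf_b, 0.0)
    # branch_b/subclone_b act on component B: swap the axes set above
    for r in records:
        if r["cluster"] in ("branch_b", "subclone_b"):
            r["ccf_a"], r["ccf_b"] = r["ccf_b"], r["ccf_a"]

    truth_df = pd.DataFrame.from_records(records)

    # --- CNVs (needed before read sampling for local copy number) ----------
    cnvs, cnv_labels = _simulate_cnvs(rng, config, sample_a, sample_b)

    # --- read sampling ------------------------------------------------------
    variants: dict[str, list[SomaticVariant]] = {sample_a: [], sample_b: []}
    for sample, ccf_col, purity in (
        (sample_a, "ccf_a", config.purity_a),
        (sample_b, "ccf_b", config.purity_b),
    ):
        segs = cnvs[sample]
        for r in records:
            ccf = r[ccf_col]
            if ccf <= 0.0:
                continue
            c_t = _local_cn(segs, r["chrom"], r["pos"])
            vaf = expected_vaf(ccf, purity, c_t)
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            alt = int(rng.binomial(depth, min(vaf, 1.0)))
            if alt < 1:
                continue  # a caller reports nothing without alt support
            variants[sample].append(
                SomaticVariant(
                    patient_id=config.patient_id,
                    sample_id=sample,
                    chrom=r["chrom"],
                    pos=r["pos"],
                    ref=r["ref"],
                    alt=r["alt"],
                    gene=r["gene"],
                    effect=r["effect"],
                    ref_count=depth - alt,
                    alt_count=alt,
                    context=r["context"],
                )
            )

    # --- integrations -------------------------------------------------------
    integrations: dict[str, list[IntegrationSite]] = {sample_a: [], sample_b: []}
    int_labels: list[tuple[IntegrationSite, str]] = []
    if config.origin == "monoclonal" and rng.random() < config.p_shared_integration:
        ci, pos = _chrom_of(np.array([rng.integers(0, config.exome_size_bp)]),
                            config.exome_size_bp)
        for smp in (sample_a, sample_b):
            site = IntegrationSite(sample_id=smp, chrom=str(ci[0] + 1), pos=int(pos[0]))
            integrations[smp].append(site)
            int_labels.append((site, "shared"))
    for smp in (sample_a, sample_b):
        for _ in range(config.n_private_integrations):
            ci, pos = _chrom_of(np.array([rng.integers(0, config.exome_size_bp)]),
                                config.exome_size_bp)
            site = IntegrationSite(sample_id=smp, chrom=str(ci[0] + 1), pos=int(pos[0]))
            integrations[smp].append(site)
            int_labels.append((site, "private"))

    pair = PatientPair(
        patient_id=config.patient_id,
        component_a=sample_a,
        component_b=sample_b,
        purity_a=config.purity_a,
        purity_b=config.purity_b,
        variants=variants,
        cnvs=cnvs,
        integrations=integrations,
    )
    truth = SimTruth(
        origin=config.origin,
        mutations=truth_df,
        cnv_labels=cnv_labels,
        integration_labels=int_labels,
    )
    return pair, truth


def simulate_cohort(
    configs: Sequence[SimConfig],
    seed: int | None = None,
    catalog: pd.DataFrame | None = None,
) -> list[tuple[PatientPair, SimTruth]]:
    """Simulate a cohort; per-patient seeds derive from ``seed`` when given."""
    configs = list(configs)
    if seed is not None:
        rng = np.random.default_rng(seed)
        child_seeds = rng.integers(0, 2**31 - 1, size=len(configs))
        configs = [
            dataclasses.replace(c, seed=int(s)) for c, s in zip(configs, child_seeds)
        ]
    return [simulate_patient(c, catalog=catalog) for c in configs]


# ---------------------------------------------------------------------------
# Writing simulator output in the analysis input formats
# ---------------------------------------------------------------------------


def write_cohort_inputs(
    cohort: Sequence[tuple[PatientPair, SimTruth]], outdir
) -> dict[str, Path]:
    """Write a simulated cohort as the exact TSV inputs the analysis reads:
    variants.tsv, cnvs.tsv, integrations.tsv, manifest.tsv (plus
    truth.tsv per patient for parameter-recovery work)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_variants, all_cnvs, all_sites, manifest_rows = [], [], [], []
    for pair, truth in cohort:
        for sid in (pair.component_a, pair.component_b):
            all_variants.extend(pair.variants.get(sid, []))
            all_cnvs.extend(pair.cnvs.get(sid, []))
            all_sites.extend(pair.integrations.get(sid, []))
        manifest_rows.extend(
            [
                {"patient_id": pair.patient_id, "sample_id": pair.component_a,
                 "component": "HCC", "purity": pair.purity_a},
                {"patient_id": pair.patient_id, "sample_id": pair.component_b,
                 "component": "iCCA", "purity": pair.purity_b},
                {"patient_id": pair.patient_id,
                 "sample_id": f"{pair.patient_id}_N", "component": "normal",
                 "purity": ""},
            ]
        )
        truth.mutations.to_csv(
            outdir / f"{pair.patient_id}_truth.tsv", sep="\t", index=False
        )
    paths = {
        "variants": outdir / "variants.tsv",
        "cnvs": outdir / "cnvs.tsv",
        "integrations": outdir / "integrations.tsv",
        "manifest": outdir / "manifest.tsv",
    }
    vio.write_variants(all_variants, paths["variants"])
    vio.write_cnvs(all_cnvs, paths["cnvs"])
    vio.write_integrations(all_sites, paths["integrations"])
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def write_test_fasta(path, seed: int = 0, n_chroms: int = 2, length: int = 200) -> None:
    """Emit a tiny random FASTA (with .fai sidecar on first use) for
    exercising context annotation; synthetic, not a genome."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for c in range(1, n_chroms + 1):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            fh.write(f">{c}\n{seq}\n")
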