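"""Readers and writers for the standard input/output formats.

Variant tables come either as VCF 4.x (allele depths from FORMAT/AD, or an
INFO-level AD as fallback) or as a tab-delimited table with an explicit
header. CNV segments are BED-like (0-based half-open), integration sites and
the sample manifest are headered TSVs. All chromosome names are normalized
to a single dialect by stripping any leading ``chr``; mitochondrial records
are dropped.

Round-trip guarantee: writing any variant/CNV/integration collection with
the ``write_*`` functions and reading it back reproduces the collection
field by field.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    CnvSegment,
    IntegrationSite,
    PatientPair,
    SampleManifest,
    SomaticVariant,
)

logger = logging.getLogger(__name__)

_MITO = {"M", "MT"}

VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "ref_count",
    "alt_count",
    "context",
]


def normalize_chrom(chrom: str) -> str | None:
    """Strip any ``chr`` prefix; return None for mitochondrial contigs."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c in _MITO:
        return None
    return c


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def _check_duplicates(variants: Sequence[SomaticVariant], source: str) -> None:
    seen: set[tuple] = set()
    for v in variants:
        ident = (v.sample_id, v.chrom, v.pos, v.ref, v.alt)
        if ident in seen:
            raise ValueError(f"{source}: duplicate variant {ident}")
        seen.add(ident)


def _read_variants_tsv(path: Path) -> list[SomaticVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: variant table missing required columns {sorted(missing)} "
            "(allele depths must be explicit, never inferred)"
        )
    has_effect = "effect" in df.columns
    if not has_effect:
        logger.warning(
            "%s: no effect column; defaulting all SNVs to 'missense'", path
        )
    out: list[SomaticVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = row._asdict()
        try:
            chrom = normalize_chrom(d["chrom"])
            if chrom is None:
                continue
            out.append(
                SomaticVariant(
                    patient_id=d.get("patient_id", ""),
                    sample_id=d.get("sample_id", ""),
                    chrom=chrom,
                    pos=int(d["pos"]),
                    ref=d["ref"].upper(),
                    alt=d["alt"].upper(),
                    gene=d.get("gene", ""),
                    effect=d["effect"] if has_effect and d.get("effect") else "missense",
                    ref_count=int(d["ref_count"]),
                    alt_count=int(d["alt_count"]),
                    context=d.get("context", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed variant record at line {i}: {exc}") from exc
    return out


def _read_variants_vcf(
    path: Path, patient_id: str = "", sample_id: str | None = None
) -> list[SomaticVariant]:
    import pysam

    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        use_sample = sample_id or (vcf_samples[0] if vcf_samples else "")
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            if chrom is None:
                continue
            ad = None
            if vcf_samples:
                target = sample_id if sample_id in vcf_samples else vcf_samples[0]
                fmt = rec.samples[target]
                if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
                    ad = list(fmt["AD"])
            if ad is None and "AD" in rec.info:
                ad = list(rec.info["AD"])
            if ad is None:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks allele depths "
                    "(FORMAT/AD or INFO/AD); refusing to substitute zeros"
                )
            alts = rec.alts or ()
            if len(ad) < 1 + len(alts):
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} AD has "
                    f"{len(ad)} entries for {len(alts)} alt allele(s)"
                )
            for j, alt in enumerate(alts):  # split multi-allelics
                out.append(
                    SomaticVariant(
                        patient_id=patient_id,
                        sample_id=use_sample,
                        chrom=chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=str(alt).upper(),
                        ref_count=int(ad[0]),
                        alt_count=int(ad[1 + j]),
                    )
                )
    return out


def read_variants(
    path,
    format: str | None = None,
    patient_id: str = "",
    sample_id: str | None = None,
) -> list[SomaticVariant]:
    """Read somatic variants from a VCF or a headered TSV.

    ``format`` is inferred from the file suffix when omitted. VCF records
    are split into one variant per alt allele; positions stay 1-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        variants = _read_variants_vcf(path, patient_id=patient_id, sample_id=sample_id)
    elif format == "tsv":
        variants = _read_variants_tsv(path)
    else:
        raise ValueError(f"unknown variant format {format!r}")
    _check_duplicates(variants, str(path))
    return variants


def write_variants(variants: Iterable[SomaticVariant], path) -> None:
    rows = [
        {
            "patient_id": v.patient_id,
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "effect": v.effect,
            "ref_count": v.ref_count,
            "alt_count": v.alt_count,
            "context": v.context,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trinucleotide context annotation
# ---------------------------------------------------------------------------


def annotate_context(
    variants: Sequence[SomaticVariant], reference
) -> tuple[list[SomaticVariant], int]:
    """Attach the reference 3-mer centered on each SNV position.

    Returns the annotated collection and the number of SNVs whose stated
    reference base disagreed with the FASTA; those are flagged
    (``ref_mismatch=True``) so spectra exclude them. Indels pass through
    unchanged.
    """
    from dataclasses import replace

    from pyfaidx import Fasta

    fasta = Fasta(str(reference), as_raw=True, sequence_always_upper=True)
    names = set(fasta.keys())

    def contig(chrom: str) -> str:
        for cand in (chrom, f"chr{chrom}"):
            if cand in names:
                return cand
        raise ValueError(f"chromosome {chrom!r} absent from FASTA {reference}")

    out: list[SomaticVariant] = []
    n_mismatch = 0
    for v in variants:
        if not v.is_snv:
            out.append(v)
            continue
        seq = str(fasta[contig(v.chrom)][v.pos - 2 : v.pos + 1])
        if len(seq) < 3 or seq[1] != v.ref:
            n_mismatch += 1
            out.append(replace(v, context="", ref_mismatch=True))
        else:
            out.append(replace(v, context=seq))
    if n_mismatch:
        logger.warning("annotate_context: %d SNVs mismatched the reference", n_mismatch)
    return out, n_mismatch


# ---------------------------------------------------------------------------
# CNV segments (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "total_cn"]


def read_cnvs(path, sample_id: str | None = None) -> list[CnvSegment]:
    """Read CNV segments from a headered 6-column TSV or a headerless
    5-column BED-like file (chrom, start, end, state, total_cn) — the
    latter requires ``sample_id``."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("sample_id"):
        df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if df.shape[1] == 5:
            if sample_id is None:
                raise ValueError(
                    f"{path}: headerless 5-column CNV table needs an explicit sample_id"
                )
            df.insert(0, "sample_id", sample_id)
        df.columns = CNV_COLUMNS
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        chrom = normalize_chrom(d["chrom"])
        if chrom is None:
            continue
        try:
            out.append(
                CnvSegment(
                    sample_id=d["sample_id"],
                    chrom=chrom,
                    start=int(d["start"]),
                    end=int(d["end"]),
                    state=d["state"],
                    total_cn=int(d["total_cn"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed CNV record at line {i}: {exc}") from exc
    return out


def write_cnvs(segments: Iterable[CnvSegment], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "state": s.state,
            "total_cn": s.total_cn,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Integration sites and manifest
# ---------------------------------------------------------------------------

INTEGRATION_COLUMNS = ["sample_id", "chrom", "pos"]


def read_integrations(path) -> list[IntegrationSite]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(INTEGRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: integration table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        if chrom is None:
            continue
        out.append(IntegrationSite(sample_id=row.sample_id, chrom=chrom, pos=int(row.pos)))
    return out


def write_integrations(sites: Iterable[IntegrationSite], path) -> None:
    rows = [{"sample_id": s.sample_id, "chrom": s.chrom, "pos": s.pos} for s in sites]
    pd.DataFrame(rows, columns=INTEGRATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sample_id": str})
    return SampleManifest(table=df)


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_pairs(
    manifest: SampleManifest,
    variants: Sequence[SomaticVariant],
    cnvs: Sequence[CnvSegment] = (),
    integrations: Sequence[IntegrationSite] = (),
    strict: bool = True,
) -> list[PatientPair]:
    """Group per-sample data into PatientPairs keyed by the manifest.

    Every data record must reference a manifest sample. A patient lacking
    either tumor component is rejected (``strict=True`` raises; otherwise
    it is skipped with a warning).
    """
    known = set(manifest.sample_ids)
    for coll, kind in ((variants, "variant"), (cnvs, "CNV"), (integrations, "integration")):
        for rec in coll:
            if rec.sample_id not in known:
                raise ValueError(f"{kind} references unknown sample_id {rec.sample_id!r}")
    _check_duplicates(list(variants), "assemble_pairs")

    by_sample_v: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_sample_v.setdefault(v.sample_id, []).append(v)
    by_sample_c: dict[str, list[CnvSegment]] = {}
    for s in cnvs:
        by_sample_c.setdefault(s.sample_id, []).append(s)
    by_sample_i: dict[str, list[IntegrationSite]] = {}
    for s in integrations:
        by_sample_i.setdefault(s.sample_id, []).append(s)

    pairs: list[PatientPair] = []
    for pid in manifest.patient_ids:
        comp = manifest.tumor_samples(pid)
        if "HCC" not in comp or "iCCA" not in comp:
            msg = (
                f"patient {pid!r} lacks both tumor components "
                f"(found: {sorted(comp)}); an HCC and an iCCA sample are required"
            )
            if strict:
                raise ValueError(msg)
            logger.warning("%s — skipped", msg)
            continue
        (sa, pa), (sb, pb) = comp["HCC"], comp["iCCA"]
        pair = PatientPair(
            patient_id=pid,
            component_a=sa,
            component_b=sb,
            purity_a=pa,
            purity_b=pb,
        )
        for sid in (sa, sb):
            if sid in by_sample_v:
                pair.variants[sid] = by_sample_v[sid]
            if sid in by_sample_c:
                pair.cnvs[sid] = by_sample_c[sid]
            if sid in by_sample_i:
                pair.integrations[sid] = by_sample_i[sid]
        pairs.append(pair)
    return pairs
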