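"""Internal data model for two-component tumor analyses.

A patient contributes exactly two tumor samples — the hepatocellular (HCC)
and cholangiocellular (iCCA) components microdissected from one combined
liver tumor — plus a matched normal used upstream for somatic calling.
Everything downstream (sharing, spectra, CCF clustering, trees) operates on
these records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: recognised functional effect classes for somatic variants
EFFECTS = frozenset(
    {
        "missense",
        "nonsense",
        "splice",
        "silent",
        "frameshift_indel",
        "inframe_indel",
        "other",
    }
)

#: effect classes counted as nonsynonymous SNVs in sharing / tree analyses
NONSYNONYMOUS_EFFECTS = frozenset({"missense", "nonsense", "splice"})

#: sample-independent identity of a variant
VariantKey = tuple[str, int, str, str]

_DNA = set("ACGT")


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call in one sample.

    ``context`` is the reference 3-mer centered on ``pos`` (empty string if
    unknown); ``ref_mismatch`` flags variants whose stated reference allele
    disagreed with the FASTA during context annotation — such variants are
    excluded from spectra.
    """

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = "missense"
    ref_count: int = 0
    alt_count: int = 0
    context: str = ""
    ref_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if self.context and (
            len(self.context) != 3 or not set(self.context) <= _DNA
        ):
            raise ValueError(f"context must be a 3-mer over ACGT, got {self.context!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0


_CNV_STATES = ("gain", "neutral", "loss")


@dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment for one sample; 0-based half-open coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    total_cn: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.state not in _CNV_STATES:
            raise ValueError(f"unknown CNV state {self.state!r}")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        expected = "gain" if self.total_cn > 2 else ("loss" if self.total_cn < 2 else "neutral")
        if self.state != expected:
            raise ValueError(
                f"state {self.state!r} inconsistent with total_cn={self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass(frozen=True)
class IntegrationSite:
    """A viral (HBV) integration breakpoint in the host genome, 1-based."""

    sample_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class PatientPair:
    """The two tumor components of one patient plus per-sample data.

    ``component_a`` is the HCC sample, ``component_b`` the iCCA sample.
    ``variants``/``cnvs``/``integrations`` are keyed by sample id; absent
    data kinds simply miss the key.
    """

    patient_id: str
    component_a: str
    component_b: str
    purity_a: float
    purity_b: float
    variants: dict[str, list[SomaticVariant]] = field(default_factory=dict)
    cnvs: dict[str, list[CnvSegment]] = field(default_factory=dict)
    integrations: dict[str, list[IntegrationSite]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in (("purity_a", self.purity_a), ("purity_b", self.purity_b)):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {p}")
        if self.component_a == self.component_b:
            raise ValueError("the two components must be distinct samples")

    @property
    def variants_a(self) -> list[SomaticVariant]:
        return self.variants.get(self.component_a, [])

    @property
    def variants_b(self) -> list[SomaticVariant]:
        return self.variants.get(self.component_b, [])

    @property
    def cnvs_a(self) -> list[CnvSegment]:
        return self.cnvs.get(self.component_a, [])

    @property
    def cnvs_b(self) -> list[CnvSegment]:
        return self.cnvs.get(self.component_b, [])

    @property
    def integrations_a(self) -> list[IntegrationSite]:
        return self.integrations.get(self.component_a, [])

    @property
    def integrations_b(self) -> list[IntegrationSite]:
        return self.integrations.get(self.component_b, [])

    def purity_of(self, sample_id: str) -> float:
        if sample_id == self.component_a:
            return self.purity_a
        if sample_id == self.component_b:
            return self.purity_b
        raise KeyError(sample_id)


_COMPONENTS = ("HCC", "iCCA", "normal")


@dataclass
class SampleManifest:
    """Cohort layout: one row per sample with patient, component and purity."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "sample_id", "component", "purity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids in manifest: {sorted(set(dupes))}")
        bad = set(self.table["component"]) - set(_COMPONENTS)
        if bad:
            raise ValueError(f"unknown component labels: {sorted(bad)}")
        tumors = self.table[self.table["component"] != "normal"]
        purities = pd.to_numeric(tumors["purity"], errors="coerce")
        if purities.isna().any() or not ((purities > 0) & (purities <= 1)).all():
            bad_ids = tumors.loc[
                purities.isna() | ~((purities > 0) & (purities <= 1)), "sample_id"
            ]
            raise ValueError(
                f"tumor samples need purity in (0, 1]: {sorted(bad_ids)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        seen: list[str] = []
        for pid in self.table["patient_id"]:
            if pid not in seen:
                seen.append(pid)
        return seen

    def tumor_samples(self, patient_id: str) -> dict[str, tuple[str, float]]:
        """Map component label -> (sample_id, purity) for one patient."""
        sub = self.table[
            (self.table["patient_id"] == patient_id)
            & (self.table["component"] != "normal")
        ]
        return {
            row.component: (row.sample_id, float(row.purity))
            for row in sub.itertuples()
        }


def variant_keys(variants: Iterable[SomaticVariant]) -> set[VariantKey]:
    return {v.key for v in variants}


def genes_by_key(variants: Iterable[SomaticVariant]) -> dict[VariantKey, str]:
    out: dict[VariantKey, str] = {}
    for v in variants:
        if v.gene:
            out.setdefault(v.key, v.gene)
    return out
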