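import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")

from hchc_clonality import (
    PatientPair,
    SimConfig,
    SomaticVariant,
    simulate_patient,
)


def make_variant(sample_id, chrom="1", pos=100, ref="C", alt="T", **kw):
    kw.setdefault("patient_id", "P1")
    kw.setdefault("ref_count", 50)
    kw.setdefault("alt_count", 20)
    return SomaticVariant(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def make_pair(keys_a, keys_b, patient_id="P1", purity=0.7, alt_count=20, **variant_kw):
    """Pair from explicit key lists [(chrom,pos,ref,alt), ...] per component."""
    pair = PatientPair(
        patient_id=patient_id,
        component_a=f"{patient_id}_HCC",
        component_b=f"{patient_id}_iCCA",
        purity_a=purity,
        purity_b=purity,
    )
    for sid, keys in ((pair.component_a, keys_a), (pair.component_b, keys_b)):
        pair.variants[sid] = [
            make_variant(sid, chrom=c, pos=p, ref=r, alt=a,
                         patient_id=patient_id, alt_count=alt_count, **variant_kw)
            for (c, p, r, a) in keys
        ]
    return pair


@pytest.fixture
def monoclonal_pair():
    """A default monoclonal simulated patient (seeded, deterministic)."""
    return simulate_patient(SimConfig(seed=11, patient_id="P1"))


@pytest.fixture
def noise_free_pair():
    """Infinite-depth-limit patient: purity 1, depth 1e4, no CNVs, no silent."""
    cfg = SimConfig(
        n_trunk=80,
        n_branch_a=20,
        n_branch_b=30,
        purity_a=1.0,
        purity_b=1.0,
        mean_depth=1e4,
        silent_fraction=0.0,
        n_cnv_shared=0,
        n_cnv_private=0,
        seed=5,
        patient_id="NF1",
    )
    return simulate_patient(cfg)
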