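"""Significantly mutated genes, driver-catalog overlap and predisposition
screening.

The SMG test compares each gene's nonsilent mutation count against a single
cohort-wide background mutation rate: with background rate mu (mutations
per base pair per sample) and coding length L_g, the null count over
n_samples is Binomial(L_g * n_samples, mu), tested by its upper tail and
corrected across genes by Benjamini-Hochberg. This is a deliberate
single-rate simplification of convolution-based SMG tests (per-category
rates for transitions/transversions/CpG are out of scope) and is
calibration-tested under the null.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SomaticVariant

logger = logging.getLogger(__name__)


def background_rate(
    variants: Iterable[SomaticVariant], callable_mb: float, n_samples: int
) -> float:
    """Cohort background mutation rate: somatic SNVs per callable bp per
    sample. ``callable_mb`` is the capture size in megabases (50 for a
    standard whole-exome capture)."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    n_snvs = sum(1 for v in variants if v.is_snv)
    if n_snvs == 0:
        logger.warning("background_rate: zero SNVs; returning 0")
    return n_snvs / (callable_mb * 1e6 * n_samples)


def smg_test(
    gene_counts: Mapping[str, int],
    coding_lengths: Mapping[str, int],
    mu: float,
    n_samples: int,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Binomial upper-tail SMG test with BH correction.

    One row per tested gene: observed nonsilent count, p-value
    P(Binomial(L_g * n_samples, mu) >= x_g), BH q-value, and the
    significance flag at ``fdr``. Genes without a coding length are
    skipped with a warning.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    rows = []
    for gene, x in gene_counts.items():
        L = coding_lengths.get(gene)
        if L is None or L <= 0:
            logger.warning("smg_test: gene %s has no coding length; skipped", gene)
            continue
        n_trials = int(L) * int(n_samples)
        p = float(stats.binom.sf(x - 1, n_trials, mu)) if x > 0 else 1.0
        rows.append(
            {
                "gene": gene,
                "coding_length_bp": int(L),
                "observed_nonsilent": int(x),
                "n_samples": int(n_samples),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "coding_length_bp", "observed_nonsilent", "n_samples", "p_value"],
    )
    if len(df):
        reject, q, _, _ = multipletests(df["p_value"].values, alpha=fdr, method="fdr_bh")
        df["q_value"] = np.maximum(q, df["p_value"].values)  # q >= p by definition
        df["significant"] = reject
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def gene_nonsilent_counts(variants: Iterable[SomaticVariant]) -> dict[str, int]:
    """Distinct nonsilent mutation events per gene (one per key per sample)."""
    counts: dict[str, int] = {}
    seen: set[tuple] = set()
    for v in variants:
        if v.effect == "silent" or not v.gene:
            continue
        ident = (v.sample_id, v.key)
        if ident in seen:
            continue
        seen.add(ident)
        counts[v.gene] = counts.get(v.gene, 0) + 1
    return counts


def driver_overlap(
    mutated_genes: Iterable[str], catalogs: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Case-insensitive intersection of mutated genes with each driver
    catalog, plus the union over catalogs under the key ``"union"``."""
    mutated = {g.upper() for g in mutated_genes if g}
    out: dict[str, list[str]] = {}
    union: set[str] = set()
    for name, genes in catalogs.items():
        cat = {g.upper(): g for g in genes}
        if not cat:
            logger.warning("driver_overlap: catalog %s is empty", name)
        hits = sorted(cat[g] for g in mutated & set(cat))
        out[name] = hits
        union.update(h.upper() for h in hits)
    out["union"] = sorted(union)
    return out


def predisposing_screen(
    germline_genes: Iterable[str], predisposition_list: Iterable[str]
) -> list[str]:
    """Germline-mutated genes present in the predisposition catalog
    (case-insensitive, reported with the catalog's capitalization)."""
    canon = {g.upper(): g for g in predisposition_list}
    hits = {canon[g.upper()] for g in germline_genes if g and g.upper() in canon}
    return sorted(hits)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_coding_lengths(path) -> dict[str, int]:
    """Two-column TSV (gene, coding length in bp)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "bp"], comment="#")
    return dict(zip(df["gene"].astype(str), df["bp"].astype(int)))
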