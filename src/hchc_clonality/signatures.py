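"""Mutation spectra and mutational-signature extraction.

Spectra are built in the standard pyrimidine-normalized channel space: 6
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) or 96 channels obtained
by crossing each class with the 16 flanking-base combinations of the
trinucleotide context. De-novo signatures are extracted by non-negative
matrix factorization (Frobenius loss, multiplicative updates, multiple
seeded restarts) and compared against a reference catalog by cosine
similarity; a cosine above 0.9 is conventionally read as "same process",
while signatures below that threshold are candidate novel processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import PatientPair, SomaticVariant

logger = logging.getLogger(__name__)

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _make_channels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: canonical 96-channel order: substitution class, then 5' base, then 3' base
CHANNELS_96: tuple[str, ...] = _make_channels()
CHANNELS_6: tuple[str, ...] = SUBSTITUTIONS

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}


def normalize_snv(ref: str, alt: str, context: str = "") -> tuple[str, str, str]:
    """Map an SNV to pyrimidine-reference strand (reverse-complementing
    ref, alt and context when the reference base is a purine)."""
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = revcomp(context) if context else ""
    return ref, alt, context


def channel_index(ref: str, alt: str, context: str) -> int:
    """96-channel index of an SNV given its reference 3-mer context."""
    ref, alt, context = normalize_snv(ref, alt, context)
    if context[1] != ref:
        raise ValueError(f"context {context!r} middle base != ref {ref!r}")
    sub = f"{ref}>{alt}"
    return (
        _SUB_INDEX[sub] * 16
        + BASES.index(context[0]) * 4
        + BASES.index(context[2])
    )


def channel_mutation(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`channel_index`: (ref, alt, context) in pyrimidine space."""
    sub = SUBSTITUTIONS[index // 16]
    five = BASES[(index % 16) // 4]
    three = BASES[index % 4]
    return sub[0], sub[2], f"{five}{sub[0]}{three}"


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------


@dataclass
class SpectrumMatrix:
    """Per-sample mutation counts over the 6 or 96 canonical channels."""

    counts: pd.DataFrame  # samples x channels, non-negative integers
    mode: str  # "six" | "ninety_six"
    n_excluded: int = 0  # SNVs dropped (no context / ref mismatch)

    def __post_init__(self) -> None:
        expected = CHANNELS_6 if self.mode == "six" else CHANNELS_96
        if tuple(self.counts.columns) != tuple(expected):
            raise ValueError("spectrum columns are not in canonical channel order")
        if (self.counts.values < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def fractions(self) -> pd.DataFrame:
        """Row-normalized spectrum; rows with zero SNVs stay all-zero."""
        totals = self.counts.sum(axis=1)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=0)


def build_spectrum(
    variants: Iterable[SomaticVariant], mode: str = "ninety_six"
) -> SpectrumMatrix:
    """Bin SNVs into the canonical substitution channels, one row per sample.

    Purine-reference SNVs are reverse-complemented before binning. In
    96-channel mode SNVs without a context (or flagged as reference
    mismatches) are excluded; the excluded count is logged and recorded.
    """
    if mode not in ("six", "ninety_six"):
        raise ValueError(f"unknown spectrum mode {mode!r}")
    channels = CHANNELS_6 if mode == "six" else CHANNELS_96
    per_sample: dict[str, np.ndarray] = {}
    n_excluded = 0
    n_used = 0
    for v in variants:
        if not v.is_snv:
            continue
        if v.ref_mismatch:
            n_excluded += 1
            continue
        row = per_sample.setdefault(v.sample_id, np.zeros(len(channels), dtype=int))
        if mode == "six":
            ref, alt, _ = normalize_snv(v.ref, v.alt)
            row[_SUB_INDEX[f"{ref}>{alt}"]] += 1
        else:
            if not v.context:
                n_excluded += 1
                continue
            row[channel_index(v.ref, v.alt, v.context)] += 1
        n_used += 1
    if mode == "ninety_six" and n_used == 0:
        raise ValueError(
            "no SNVs with trinucleotide context available for a 96-channel spectrum"
        )
    if n_excluded:
        logger.info("build_spectrum: excluded %d SNVs without usable context", n_excluded)
    counts = pd.DataFrame.from_dict(per_sample, orient="index", columns=list(channels))
    counts = counts.sort_index()
    return SpectrumMatrix(counts=counts, mode=mode, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# NMF signature extraction
# ---------------------------------------------------------------------------


@dataclass
class SignatureSet:
    """De-novo signatures W (channels x k, columns sum to 1) and exposures H."""

    W: pd.DataFrame
    H: pd.DataFrame
    reconstruction_error: float
    k: int

    def __post_init__(self) -> None:
        if (self.W.values < 0).any() or (self.H.values < 0).any():
            raise ValueError("signature factors must be non-negative")
        colsums = self.W.sum(axis=0).values
        if not np.allclose(colsums[colsums > 0], 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")


def _mu_nmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    debug: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run minimizing ||V - WH||_F."""
    eps = 1e-12
    m, n = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    prev = np.linalg.norm(V - W @ H)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(V - W @ H)
        if debug and err > prev + 1e-9 * (1.0 + prev):
            raise AssertionError("NMF objective increased across an update")
        if prev - err < tol * max(prev, 1.0):
            prev = err
            break
        prev = err
    return W, H, prev


def nmf_extract(
    spectrum: SpectrumMatrix,
    k: int = 3,
    n_restarts: int = 50,
    max_iter: int = 2000,
    seed: int = 0,
    tol: float = 1e-8,
    debug: bool = False,
) -> SignatureSet:
    """Extract ``k`` signatures from a count spectrum by seeded NMF.

    Runs ``n_restarts`` random initializations and keeps the factorization
    with the lowest Frobenius reconstruction error; deterministic given
    ``seed``. Signature columns are normalized to sum to 1 with the scale
    absorbed into the exposures H.
    """
    V = spectrum.counts.values.T.astype(float)  # channels x samples
    if not V.any():
        raise ValueError("cannot factorize an all-zero spectrum")
    if k < 1 or k > min(V.shape):
        raise ValueError(f"k={k} outside [1, {min(V.shape)}]")
    master = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for child in master.spawn(n_restarts):
        W, H, err = _mu_nmf(V, k, child, max_iter, tol, debug)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best  # type: ignore[misc]
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    sig_ids = [f"DN{i + 1}" for i in range(k)]
    return SignatureSet(
        W=pd.DataFrame(W, index=list(spectrum.channels), columns=sig_ids),
        H=pd.DataFrame(H, index=sig_ids, columns=list(spectrum.counts.index)),
        reconstruction_error=float(err),
        k=k,
    )


def nmf_rank_scan(
    spectrum: SpectrumMatrix,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_restarts: int = 10,
    max_iter: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction error as a function of the number of signatures."""
    rows = []
    for k in k_range:
        s = nmf_extract(spectrum, k=k, n_restarts=n_restarts, max_iter=max_iter, seed=seed)
        rows.append({"k": k, "reconstruction_error": s.reconstruction_error})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cosine similarity and catalog matching
# ---------------------------------------------------------------------------


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (||u|| ||v||); raises on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class SignatureMatch:
    """Best-catalog match per extracted signature."""

    table: pd.DataFrame  # columns: signature, best_match, cosine, matched
    threshold: float


def match_signatures(
    extracted: SignatureSet, catalog: pd.DataFrame, threshold: float = 0.9
) -> SignatureMatch:
    """Match each extracted signature to its argmax-cosine catalog entry.

    The catalog must carry the canonical 96 channel labels as its index;
    labels are validated, never assumed from position.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if list(catalog.index) != list(CHANNELS_96):
        raise ValueError(
            "catalog channel labels do not match the canonical 96-channel order"
        )
    rows = []
    C = catalog.values.astype(float)
    for sig_id in extracted.W.columns:
        w = extracted.W[sig_id].values
        cosines = np.array([cosine_similarity(w, C[:, j]) for j in range(C.shape[1])])
        j = int(np.argmax(cosines))
        rows.append(
            {
                "signature": sig_id,
                "best_match": catalog.columns[j],
                "cosine": float(cosines[j]),
                "matched": bool(cosines[j] > threshold),
            }
        )
    return SignatureMatch(table=pd.DataFrame(rows), threshold=threshold)


def compare_components(
    spectrum: SpectrumMatrix, pairs: Sequence[PatientPair]
) -> dict[str, float | None]:
    """Cosine between the two components' spectra, per patient.

    A component with zero usable SNVs yields ``None`` for that patient
    (reported as missing rather than an error).
    """
    fractions = spectrum.fractions
    out: dict[str, float | None] = {}
    for pair in pairs:
        a, b = pair.component_a, pair.component_b
        if a not in fractions.index or b not in fractions.index:
            out[pair.patient_id] = None
            continue
        ua, ub = fractions.loc[a].values, fractions.loc[b].values
        if not ua.any() or not ub.any():
            out[pair.patient_id] = None
            continue
        out[pair.patient_id] = cosine_similarity(ua, ub)
    return out


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------


def read_catalog(path) -> pd.DataFrame:
    """Read a signature catalog CSV: first column channel labels, one column
    per signature. Channel order is validated against the canonical order."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(CHANNELS_96):
        raise ValueError(
            f"catalog {path} channel labels do not match the canonical order"
        )
    if (df.values < 0).any():
        raise ValueError("catalog entries must be non-negative")
    return df


def write_catalog(catalog: pd.DataFrame, path) -> None:
    if list(catalog.index) != list(CHANNELS_96):
        raise ValueError("refusing to write a catalog in non-canonical channel order")
    catalog.to_csv(path, index_label="channel")
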