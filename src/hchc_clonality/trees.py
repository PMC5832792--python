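"""Per-patient trunk/branch phylogenies.

Each patient yields a two-leaf tree: the trunk carries the ubiquitous
nonsynonymous mutations (acquired before the components diverged), and the
two branches carry each component's private mutations. Branch and trunk
lengths equal the mutation counts (1 mutation = 1 unit); driver genes are
annotated on the edge where their mutation resides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datatypes import VariantKey
from .sharing import SharingSummary

logger = logging.getLogger(__name__)


@dataclass
class PatientTree:
    """Two-leaf mutation tree with integer mutation-count edge lengths."""

    patient_id: str
    trunk_length: int
    branch_a_length: int
    branch_b_length: int
    trunk_drivers: list[str] = field(default_factory=list)
    branch_a_drivers: list[str] = field(default_factory=list)
    branch_b_drivers: list[str] = field(default_factory=list)


def build_tree(sharing: SharingSummary) -> PatientTree:
    """Copy the sharing partition into edge lengths.

    An all-zero partition produces a degenerate star tree (emitted with a
    warning rather than an error, so empty patients do not break cohorts).
    """
    if sharing.n_ubiquitous + sharing.n_private_a + sharing.n_private_b == 0:
        logger.warning(
            "patient %s: no mutations pass the filter; emitting a degenerate star tree",
            sharing.patient_id,
        )
    return PatientTree(
        patient_id=sharing.patient_id,
        trunk_length=sharing.n_ubiquitous,
        branch_a_length=sharing.n_private_a,
        branch_b_length=sharing.n_private_b,
    )


def build_tree_ccf_gated(
    sharing: SharingSummary,
    observations,
    ccf_threshold: float = 0.05,
) -> PatientTree:
    """Copy-number-aware variant of :func:`build_tree`.

    A mutation contributes to an edge only where its point CCF exceeds
    ``ccf_threshold``: above it in both components -> trunk, above it in
    exactly one -> that branch. This replaces raw presence/absence with
    purity- and copy-number-adjusted presence; no published algorithm
    exists for the copy-number-aware tree, so this gate is the package's
    explicit stand-in. Only mutations in the sharing partition are counted.
    """
    keyed = {o.key: o for o in observations}
    trunk = branch_a = branch_b = 0
    for key in sharing.labels:
        o = keyed.get(key)
        if o is None:
            continue
        in_a = o.ccf_point[0] > ccf_threshold
        in_b = o.ccf_point[1] > ccf_threshold
        if in_a and in_b:
            trunk += 1
        elif in_a:
            branch_a += 1
        elif in_b:
            branch_b += 1
    return PatientTree(
        patient_id=sharing.patient_id,
        trunk_length=trunk,
        branch_a_length=branch_a,
        branch_b_length=branch_b,
    )


def annotate_drivers(
    tree: PatientTree,
    labels: Mapping[VariantKey, str],
    genes: Mapping[VariantKey, str],
    driver_genes: Iterable[str],
) -> PatientTree:
    """Place driver genes on the edge carrying their mutation.

    A gene from ``driver_genes`` lands on the trunk when its mutation is
    ubiquitous and on the matching branch when private; each edge lists a
    gene at most once (case-insensitive matching, reported symbols as given
    in the driver list).
    """
    canon = {g.upper(): g for g in driver_genes}
    edges: dict[str, list[str]] = {"ubiquitous": [], "private_a": [], "private_b": []}
    for key, label in labels.items():
        gene = genes.get(key, "")
        if gene and gene.upper() in canon:
            edges[label].append(canon[gene.upper()])
    tree.trunk_drivers = sorted(set(edges["ubiquitous"]))
    tree.branch_a_drivers = sorted(set(edges["private_a"]))
    tree.branch_b_drivers = sorted(set(edges["private_b"]))
    return tree


def write_newick(tree: PatientTree) -> str:
    """Newick text for one patient tree.

    Shape: the normal (germline) root leads through the trunk to the most
    recent common ancestor of the components, which splits into the HCC and
    iCCA leaves; lengths are integer mutation counts.
    """
    return (
        f"((HCC:{tree.branch_a_length},iCCA:{tree.branch_b_length})"
        f"MRCA:{tree.trunk_length})NORMAL;"
    )


def write_cohort_newick(trees: Sequence[PatientTree], path) -> None:
    """One Newick string per line, cohort order preserved."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


def write_driver_table(trees: Sequence[PatientTree], path) -> None:
    import pandas as pd

    rows = []
    for t in trees:
        for edge, drivers in (
            ("trunk", t.trunk_drivers),
            ("branch_HCC", t.branch_a_drivers),
            ("branch_iCCA", t.branch_b_drivers),
        ):
            for g in drivers:
                rows.append({"patient_id": t.patient_id, "edge": edge, "gene": g})
    pd.DataFrame(rows, columns=["patient_id", "edge", "gene"]).to_csv(
        path, sep="\t", index=False
    )
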