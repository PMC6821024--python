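"""Rearrangement-type classifier for bothid gene orders.

The four observed types differ only in the arrangement of the control
region(s), tRNA-D and the L-strand 8-gene cluster Q-A-C-Y-S1-ND6-E-P
in the span between tRNA-T and the wrap to tRNA-F:

* Type I:   D - CR - (Q A C Y S1 ND6 E P)
* Type II:  CR - (Q A C Y S1) - D - (ND6 E P)
* Type III: CR1 - (Q A C Y S1) - D - (ND6 E P) - CR2
* Type IV:  (Q A C Y S1) - D - (ND6 E P) - CR

tRNA-V shuffling (12S-16S-V-L1 instead of 12S-V-16S-L1) is orthogonal
to the type and reported separately.  Classification looks only at
gene/CR topology — spacers and the O_L position are ignored — and an
order matching no template is refused as "unclassified" rather than
forced into the nearest type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import (
    GenomeArrangement,
    arrangements_equal,
    canonical_teleost_order,
)
from .vocab import PROTEIN_GENES, RRNA_GENES, TRNA_GENES

__all__ = ["TypeCall", "classify", "classify_all"]

_ALL_GENES = set(PROTEIN_GENES) | set(RRNA_GENES) | set(TRNA_GENES)

# tail templates between tRNA-T (exclusive) and tRNA-F (exclusive);
# "CR" matches any control feature
_TEMPLATES: dict[str, tuple[str, ...]] = {
    "I": ("D", "CR", "Q", "A", "C", "Y", "S1", "ND6", "E", "P"),
    "II": ("CR", "Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P"),
    "III": ("CR", "Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P", "CR"),
    "IV": ("Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P", "CR"),
}

_CLUSTER = ("Q", "A", "C", "Y", "S1", "ND6", "E", "P")


@dataclass
class TypeCall:
    label: str  # I | II | III | IV | ancestral | unclassified
    d_inside_cluster: bool = False
    cr_count: int = 0
    v_shuffled: bool = False
    l_cluster: tuple[str, ...] = field(default_factory=tuple)


def classify(a: GenomeArrangement) -> TypeCall:
    """Assign a monomeric 37-gene order to Type I-IV, ancestral, or
    unclassified.

    Raises ``ValueError`` when genes are missing (classification is
    refused, the missing names are reported).
    """
    present = {f.name for f in a.genes()}
    missing = _ALL_GENES - present
    if missing:
        raise ValueError(
            "cannot classify, missing genes: " + ", ".join(sorted(missing))
        )
    cr_count = sum(1 for f in a.features if f.category == "control")

    # local 12S/16S/V order
    riborder = [f.name for f in a.features if f.name in ("12S", "16S", "V", "L1")]
    v_shuffled = riborder == ["12S", "16S", "V", "L1"]

    if not v_shuffled and arrangements_equal(a, canonical_teleost_order()):
        return TypeCall(
            "ancestral",
            d_inside_cluster=False,
            cr_count=cr_count,
            v_shuffled=False,
        )

    # extract the span between T and F (circular), CRs normalized
    names = [
        ("CR" if f.category == "control" else f.name)
        for f in a.features
        if f.is_gene or f.category == "control"
    ]
    try:
        t_idx = names.index("T")
        f_idx = names.index("F")
    except ValueError:  # pragma: no cover - all genes checked above
        return TypeCall("unclassified", cr_count=cr_count, v_shuffled=v_shuffled)
    n = len(names)
    tail = []
    i = (t_idx + 1) % n
    while i != f_idx:
        tail.append(names[i])
        i = (i + 1) % n
    tail_t = tuple(tail)

    label = "unclassified"
    for lab, template in _TEMPLATES.items():
        if tail_t == template:
            label = lab
            break

    # D is "inside the cluster" when both its gene neighbors belong to
    # the 8-gene cluster (computed structurally, not from the label)
    gene_names = [f.name for f in a.genes()]
    d_pos = gene_names.index("D")
    d_left = gene_names[d_pos - 1]
    d_right = gene_names[(d_pos + 1) % len(gene_names)]
    d_inside = d_left in _CLUSTER and d_right in _CLUSTER

    l_cluster = tuple(x for x in tail_t if x in _CLUSTER or x == "D")
    return TypeCall(
        label=label,
        d_inside_cluster=d_inside,
        cr_count=cr_count,
        v_shuffled=v_shuffled,
        l_cluster=l_cluster if label != "unclassified" else tuple(),
    )


def classify_all(
    arrangements: dict[str, GenomeArrangement]
) -> pd.DataFrame:
    """Classify a species -> arrangement map into a tidy table.

    Columns: species, type, d_inside_cluster, cr_count, v_shuffled,
    l_cluster (hyphen-joined).  The table's ``attrs["summary"]`` maps
    each label to its member species.
    """
    rows = []
    summary: dict[str, list[str]] = {}
    for sp, arr in arrangements.items():
        call = classify(arr)
        rows.append(
            {
                "species": sp,
                "type": call.label,
                "d_inside_cluster": call.d_inside_cluster,
                "cr_count": call.cr_count,
                "v_shuffled": call.v_shuffled,
                "l_cluster": "-".join(call.l_cluster),
            }
        )
        summary.setdefault(call.label, []).append(sp)
    df = pd.DataFrame(
        rows,
        columns=[
            "species",
            "type",
            "d_inside_cluster",
            "cr_count",
            "v_shuffled",
            "l_cluster",
        ],
    )
    df.attrs["summary"] = summary
    return df
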