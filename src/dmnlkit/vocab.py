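"""Controlled vocabulary for vertebrate mitochondrial features.

A typical fish mitogenome carries 37 genes (13 protein-coding, 2 rRNA,
22 tRNA), one control region (CR) and the light-strand replication
origin (O_L).  All but nine genes lie on the heavy strand; ND6 and the
tRNAs N, Q, A, C, Y, S1, E and P are light-strand encoded.

tRNAs are named by single-letter amino-acid code; the two isoacceptor
pairs follow standard vertebrate usage: S1 = tRNA-Ser(UCN),
S2 = tRNA-Ser(AGY), L1 = tRNA-Leu(UUR), L2 = tRNA-Leu(CUN).
"""

from __future__ import annotations

PROTEIN_GENES = (
    "ND1", "ND2", "COI", "COII", "COIII", "ATP6", "ATP8",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CytB",
)

RRNA_GENES = ("12S", "16S")

TRNA_GENES = (
    "F", "V", "L1", "I", "Q", "M", "W", "A", "N", "C", "Y",
    "S1", "D", "K", "G", "R", "H", "S2", "L2", "E", "T", "P",
)

CONTROL_FEATURES = ("CR", "CR1", "CR2")
ORIGIN_FEATURES = ("OL",)
SPACER_FEATURES = ("SPACER",)

#: Light-strand encoded genes (transcriptional polarity L).
L_STRAND_GENES = frozenset({"ND6", "Q", "A", "N", "C", "Y", "S1", "E", "P"})

GENE_CATEGORIES = frozenset({"protein", "rRNA", "tRNA"})

CATEGORY_OF = {}
for _g in PROTEIN_GENES:
    CATEGORY_OF[_g] = "protein"
for _g in RRNA_GENES:
    CATEGORY_OF[_g] = "rRNA"
for _g in TRNA_GENES:
    CATEGORY_OF[_g] = "tRNA"
for _g in CONTROL_FEATURES:
    CATEGORY_OF[_g] = "control"
for _g in ORIGIN_FEATURES:
    CATEGORY_OF[_g] = "origin"
for _g in SPACER_FEATURES:
    CATEGORY_OF[_g] = "spacer"

VOCABULARY = frozenset(CATEGORY_OF)


def default_strand(name: str) -> str:
    """H/L transcriptional polarity of a named feature.

    Control regions, O_L and spacers are reported as H by convention;
    they are excluded from strand counts.
    """
    if name in L_STRAND_GENES:
        return "L"
    return "H"
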