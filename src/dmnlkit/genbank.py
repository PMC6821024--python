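"""GenBank flat-file reader for annotated mitogenomes.

Maps CDS / tRNA / rRNA / D-loop / rep_origin features of a GenBank
record onto the package's controlled vocabulary through a bundled
synonym table, producing an :class:`~dmnlkit.annotated.AnnotatedSequence`
ready for O_L detection, spacer tracing and classification.  This is
an optional input path for user-supplied real records — nothing in
the package's own fixtures or tests depends on it.
"""

from __future__ import annotations

import re
from typing import Optional

from Bio import SeqIO

from .annotated import AnnotatedSequence, SeqFeatureRec

__all__ = ["SYNONYMS", "read_genbank", "map_product"]

#: Lower-cased product/gene qualifier → controlled-vocabulary name.
#: Keys are matched after squeezing whitespace/hyphens; anticodon
#: parentheses are significant for the Ser/Leu isoacceptors.
SYNONYMS: dict[str, str] = {
    # protein-coding
    "nd1": "ND1", "nadh dehydrogenase subunit 1": "ND1", "nad1": "ND1",
    "nd2": "ND2", "nadh dehydrogenase subunit 2": "ND2", "nad2": "ND2",
    "nd3": "ND3", "nadh dehydrogenase subunit 3": "ND3", "nad3": "ND3",
    "nd4": "ND4", "nadh dehydrogenase subunit 4": "ND4", "nad4": "ND4",
    "nd4l": "ND4L", "nadh dehydrogenase subunit 4l": "ND4L", "nad4l": "ND4L",
    "nd5": "ND5", "nadh dehydrogenase subunit 5": "ND5", "nad5": "ND5",
    "nd6": "ND6", "nadh dehydrogenase subunit 6": "ND6", "nad6": "ND6",
    "cox1": "COI", "coi": "COI", "cytochrome c oxidase subunit i": "COI",
    "cytochrome c oxidase subunit 1": "COI", "co1": "COI",
    "cox2": "COII", "coii": "COII", "cytochrome c oxidase subunit ii": "COII",
    "cytochrome c oxidase subunit 2": "COII", "co2": "COII",
    "cox3": "COIII", "coiii": "COIII",
    "cytochrome c oxidase subunit iii": "COIII",
    "cytochrome c oxidase subunit 3": "COIII", "co3": "COIII",
    "atp6": "ATP6", "atpase subunit 6": "ATP6", "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase subunit 8": "ATP8", "atp synthase f0 subunit 8": "ATP8",
    "cytb": "CytB", "cob": "CytB", "cytochrome b": "CytB",
    "cytochrome b apoenzyme": "CytB",
    # rRNA
    "12s ribosomal rna": "12S", "12s rrna": "12S", "rrns": "12S",
    "s rrna": "12S", "small subunit ribosomal rna": "12S",
    "16s ribosomal rna": "16S", "16s rrna": "16S", "rrnl": "16S",
    "l rrna": "16S", "large subunit ribosomal rna": "16S",
    # tRNAs (one-letter amino-acid subscripts of the vocabulary)
    "trna phe": "F", "trna f": "F",
    "trna val": "V", "trna v": "V",
    "trna leu(uur)": "L1", "trna l(uur)": "L1", "trna leu (uur)": "L1",
    "trna leu(cun)": "L2", "trna l(cun)": "L2", "trna leu (cun)": "L2",
    "trna ile": "I", "trna i": "I",
    "trna gln": "Q", "trna q": "Q",
    "trna met": "M", "trna m": "M",
    "trna trp": "W", "trna w": "W",
    "trna ala": "A", "trna a": "A",
    "trna asn": "N", "trna n": "N",
    "trna cys": "C", "trna c": "C",
    "trna tyr": "Y", "trna y": "Y",
    "trna ser(ucn)": "S1", "trna s(ucn)": "S1", "trna ser (ucn)": "S1",
    "trna ser(agy)": "S2", "trna s(agy)": "S2", "trna ser (agy)": "S2",
    "trna ser(agn)": "S2",
    "trna asp": "D", "trna d": "D",
    "trna lys": "K", "trna k": "K",
    "trna gly": "G", "trna g": "G",
    "trna arg": "R", "trna r": "R",
    "trna his": "H", "trna h": "H",
    "trna glu": "E", "trna e": "E",
    "trna thr": "T", "trna t": "T",
    "trna pro": "P", "trna p": "P",
    # control / origin
    "d loop": "CR", "control region": "CR", "putative control region": "CR",
    "cr": "CR", "control region 1": "CR1", "control region 2": "CR2",
    "origin of l strand replication": "OL",
    "origin of light strand replication": "OL",
    "l strand replication origin": "OL", "ol": "OL", "o l": "OL", "rep origin": "OL",
}

_SQUEEZE = re.compile(r"[\s_\-]+")


def _norm_qualifier(text: str) -> str:
    return _SQUEEZE.sub(" ", text.strip().lower())


def map_product(text: str) -> Optional[str]:
    """Controlled-vocabulary name for a product/gene qualifier, or
    None when unrecognized."""
    return SYNONYMS.get(_norm_qualifier(text))


_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature")


def read_genbank(path, strict: bool = True) -> AnnotatedSequence:
    """Read one GenBank record into an :class:`AnnotatedSequence`.

    Only CDS/tRNA/rRNA/D-loop/rep_origin features (and misc_features
    whose qualifiers resolve to a vocabulary name) are kept; others
    are ignored.  With ``strict`` (default), a kept feature whose
    product/gene/note qualifiers cannot be mapped raises ``ValueError``
    naming the qualifier; with ``strict=False`` it is skipped.
    """
    record = SeqIO.read(path, "genbank")
    recs: list[SeqFeatureRec] = []
    for feat in record.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        if feat.type == "D-loop":
            name: Optional[str] = "CR"
        elif feat.type == "rep_origin":
            name = "OL"
        else:
            name = None
        quals = []
        for key in ("product", "gene", "note", "standard_name"):
            quals.extend(feat.qualifiers.get(key, []))
        for q in quals:
            mapped = map_product(q)
            if mapped is not None:
                name = mapped
                break
        if name is None:
            if feat.type == "misc_feature":
                continue
            if strict:
                raise ValueError(
                    f"cannot map {feat.type} feature with qualifiers "
                    f"{quals!r} to the controlled vocabulary"
                )
            continue
        strand = "L" if feat.location.strand == -1 else "H"
        recs.append(
            SeqFeatureRec(
                name=name,
                strand=strand,
                start=int(feat.location.start),
                end=int(feat.location.end),
            )
        )
    # relabel duplicate control regions positionally as CR1/CR2
    crs = [i for i, r in enumerate(recs) if r.name == "CR"]
    if len(crs) == 2:
        for label, i in zip(("CR1", "CR2"), crs):
            r = recs[i]
            recs[i] = SeqFeatureRec(label, r.strand, r.start, r.end)
    recs.sort(key=lambda r: r.start)
    return AnnotatedSequence(seq=str(record.seq).upper(), features=recs)
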