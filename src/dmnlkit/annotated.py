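"""Annotated nucleotide sequences: the substrate for sequence-level
feature detection and the synthetic-genome generator.

Coordinates are 0-based, half-open, on the forward strand of a
circular molecule; a feature whose ``end`` exceeds the sequence length
wraps around the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .vocab import CATEGORY_OF, VOCABULARY

__all__ = ["SeqFeatureRec", "AnnotatedSequence", "load_annotated"]


@dataclass(frozen=True)
class SeqFeatureRec:
    name: str
    strand: str  # H | L
    start: int
    end: int  # half-open; may exceed len(seq) to indicate wrap
    copy_tag: str = "plain"
    provenance: Optional[str] = None

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise ValueError(f"unknown feature name {self.name!r}")
        if self.end < self.start:
            raise ValueError("end < start (use end > len for wrapping)")

    @property
    def category(self) -> str:
        return CATEGORY_OF[self.name]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedSequence:
    """Circular nucleotide sequence plus feature coordinates.

    ``ground_truth`` optionally records generator decisions (planted
    hairpin location and mode, repeat array, true spacer sources and
    remnant lengths) for parameter-recovery tests.
    """

    seq: str
    features: list[SeqFeatureRec] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Circular slice: [start, end) with wrap-around."""
        n = len(self.seq)
        start %= n
        end = start + (end - start)
        if end <= n:
            return self.seq[start : end]
        return self.seq[start:] + self.seq[: end - n]

    def feature(self, name: str, copy_tag: str = "plain") -> SeqFeatureRec:
        for f in self.features:
            if f.name == name and f.copy_tag == copy_tag:
                return f
        raise KeyError(f"feature {name!r} ({copy_tag}) not annotated")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def feature_seq(self, f: SeqFeatureRec) -> str:
        return self.slice(f.start, f.end)

    # -- text output ----------------------------------------------------------

    def to_fasta(self, path, header: str = "synthetic_mitogenome") -> None:
        with open(path, "w") as fh:
            fh.write(f">{header} length={len(self.seq)} circular\n")
            for i in range(0, len(self.seq), 70):
                fh.write(self.seq[i : i + 70] + "\n")

    def to_gff3(self, path, seqid: str = "synthetic_mitogenome") -> None:
        type_of = {
            "protein": "CDS",
            "rRNA": "rRNA",
            "tRNA": "tRNA",
            "control": "D_loop",
            "origin": "rep_origin",
            "spacer": "region",
        }
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {seqid} 1 {len(self.seq)}\n")
            for f in self.features:
                strand = "+" if f.strand == "H" else "-"
                attrs = f"ID={f.name};Name={f.name}"
                if f.copy_tag == "prime":
                    attrs += ";copy=prime"
                if f.provenance:
                    attrs += f";provenance={f.provenance}"
                fh.write(
                    f"{seqid}\tdmnlkit\t{type_of[f.category]}\t"
                    f"{f.start + 1}\t{f.end}\t.\t{strand}\t.\t{attrs}\n"
                )


def load_annotated(fasta_path, gff3_path) -> AnnotatedSequence:
    """Rebuild an :class:`AnnotatedSequence` from the package's own
    FASTA + GFF3 output (feature names from the Name attribute)."""
    seq_lines = []
    with open(fasta_path) as fh:
        for line in fh:
            if line.startswith(">"):
                if seq_lines:
                    raise ValueError("multi-record FASTA not supported")
                continue
            seq_lines.append(line.strip())
    seq = "".join(seq_lines).upper()
    feats: list[SeqFeatureRec] = []
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 columns")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise ValueError(f"{gff3_path}:{lineno}: missing Name attribute")
            feats.append(
                SeqFeatureRec(
                    name=name,
                    strand="H" if cols[6] == "+" else "L",
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    copy_tag=attrs.get("copy", "plain"),
                    provenance=attrs.get("provenance"),
                )
            )
    return AnnotatedSequence(seq=seq, features=feats)
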