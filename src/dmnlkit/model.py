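"""Circular gene-order model for mitochondrial genomes.

The central object is :class:`GenomeArrangement`: a circular, ordered
list of stranded features.  Gene orders at this layer are pure
sequences — no base coordinates; sequence realizations live in
:mod:`dmnlkit.synth`.

Besides the data model this module provides the canonical (ancestral)
teleost gene order, the 13 observed bothid gene orders used throughout
the package, rotation-invariant equality, strand counts, and a tabular
gene-order file format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .vocab import (
    CATEGORY_OF,
    GENE_CATEGORIES,
    VOCABULARY,
    default_strand,
)

__all__ = [
    "GeneFeature",
    "GenomeArrangement",
    "canonical_teleost_order",
    "bothid_fixture",
    "BOTHID_SPECIES",
    "SPECIES_TYPE",
    "arrangements_equal",
    "strand_counts",
    "read_arrangement",
    "write_arrangement",
]


@dataclass(frozen=True)
class GeneFeature:
    """One feature on the circular genome.

    ``copy_tag`` distinguishes the two monomer copies inside a dimer
    ("plain" vs "prime"); observed monomeric genomes are all plain.
    ``provenance`` names the degenerated source gene and is only
    meaningful for spacers.
    """

    name: str
    strand: str = "H"
    copy_tag: str = "plain"
    provenance: Optional[str] = None
    length_bp: Optional[int] = None

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise ValueError(f"unknown feature name: {self.name!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.copy_tag not in ("plain", "prime"):
            raise ValueError(f"copy_tag must be plain or prime, got {self.copy_tag!r}")
        if self.provenance is not None and self.category != "spacer":
            raise ValueError("provenance is only allowed on spacers")
        if self.length_bp is not None and self.length_bp <= 0:
            raise ValueError("length_bp must be positive")

    @property
    def category(self) -> str:
        return CATEGORY_OF[self.name]

    @property
    def is_gene(self) -> bool:
        return self.category in GENE_CATEGORIES

    def with_tag(self, copy_tag: str) -> "GeneFeature":
        return dataclasses.replace(self, copy_tag=copy_tag)

    def label(self) -> str:
        """Display label; prime copies get a trailing apostrophe."""
        return self.name + ("'" if self.copy_tag == "prime" else "")


@dataclass(frozen=True)
class GenomeArrangement:
    """A circular, ordered sequence of features.

    Equality of circular orders is rotation-invariant (see
    :func:`arrangements_equal`); internally the feature list is
    linearized at ``anchor`` (default tRNA-F) for stable display and
    serialization.
    """

    features: tuple[GeneFeature, ...]
    anchor: str = "F"
    is_dimer: bool = False

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_features(
        cls,
        features: Iterable[GeneFeature],
        anchor: str = "F",
        is_dimer: bool = False,
    ) -> "GenomeArrangement":
        arr = cls(tuple(features), anchor=anchor, is_dimer=is_dimer)
        return arr.canonicalized()

    def canonicalized(self) -> "GenomeArrangement":
        """Rotate so the anchor feature (plain copy) comes first.

        Falls back to the lexicographically smallest feature name if
        the anchor is absent; empty arrangements pass through.
        """
        if not self.features:
            return self
        idx = None
        for i, f in enumerate(self.features):
            if f.name == self.anchor and f.copy_tag == "plain":
                idx = i
                break
        if idx is None:
            idx = min(range(len(self.features)), key=lambda i: self.features[i].name)
        return dataclasses.replace(
            self, features=self.features[idx:] + self.features[:idx]
        )

    # -- queries --------------------------------------------------------------

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def genes(self) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.is_gene)

    def gene_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.genes())

    def names(self, include_spacers: bool = False) -> tuple[str, ...]:
        return tuple(
            f.name
            for f in self.features
            if include_spacers or f.category != "spacer"
        )

    def index_of(self, name: str, copy_tag: str = "plain") -> int:
        for i, f in enumerate(self.features):
            if f.name == name and f.copy_tag == copy_tag:
                return i
        raise KeyError(f"feature {name!r} ({copy_tag}) not in arrangement")

    def rotated(self, k: int) -> "GenomeArrangement":
        """Rotate left by k positions (circular; equality unaffected)."""
        n = len(self.features)
        if n == 0:
            return self
        k %= n
        return dataclasses.replace(
            self, features=self.features[k:] + self.features[:k]
        )

    def validate(self) -> None:
        """Check copy-tag multiplicity invariants; raise ValueError on failure."""
        seen: dict[tuple[str, str], int] = {}
        for f in self.features:
            if f.category == "spacer":
                continue
            key = (f.name, f.copy_tag)
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > 1:
                raise ValueError(f"duplicate feature {f.name} ({f.copy_tag})")
            if not self.is_dimer and f.copy_tag != "plain":
                raise ValueError(f"prime copy {f.name} in a monomer")


# ---------------------------------------------------------------------------
# Canonical teleost order and bothid gene orders
# ---------------------------------------------------------------------------

#: Ancestral teleost gene order, linearized at tRNA-F.  Strands follow
#: the standard vertebrate assignment (ND6 plus tRNAs Q, A, N, C, Y,
#: S1, E, P on the light strand).
CANONICAL_ORDER: tuple[str, ...] = (
    "F", "12S", "V", "16S", "L1", "ND1", "I", "Q", "M", "ND2",
    "W", "A", "N", "OL", "C", "Y", "COI", "S1", "D", "COII",
    "K", "ATP8", "ATP6", "COIII", "G", "ND3", "R", "ND4L", "ND4",
    "H", "S2", "L2", "ND5", "ND6", "E", "CytB", "T", "P", "CR",
)

# Shared heavy-strand block of all 13 rearranged bothid orders: the
# canonical order with Q, A, C, Y, S1, ND6, E, P and D removed, keeping
# tRNA-N (light strand) and O_L in place between W and COI.
_BOTHID_H_BLOCK: tuple[str, ...] = (
    "F", "12S", "V", "16S", "L1", "ND1", "I", "M", "ND2", "W",
    "N", "OL", "COI", "COII", "K", "ATP8", "ATP6", "COIII", "G",
    "ND3", "R", "ND4L", "ND4", "H", "S2", "L2", "ND5", "CytB", "T",
)

# Tail (from tRNA-T to the wrap at tRNA-F) per rearrangement type.
_TYPE_TAIL: dict[str, tuple[str, ...]] = {
    "I": ("D", "CR", "Q", "A", "C", "Y", "S1", "ND6", "E", "P"),
    "II": ("CR", "Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P"),
    "III": ("CR1", "Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P", "CR2"),
    "IV": ("Q", "A", "C", "Y", "S1", "D", "ND6", "E", "P", "CR"),
}

#: The 13 bothid species, by the abbreviation used in the field, with
#: their rearrangement type and whether tRNA-V is shuffled.
SPECIES_TYPE: dict[str, tuple[str, bool]] = {
    "C.az": ("I", False),   # Crossorhombus azureus
    "C.ko": ("I", False),   # Crossorhombus kobensis
    "C.va": ("I", False),   # Crossorhombus valderostratus
    "B.my": ("II", False),  # Bothus myriaster
    "A.po": ("II", False),  # Arnoglossus polyspilus
    "C.lu": ("II", False),  # Chascanopsetta lugubris
    "G.p": ("III", False),  # Grammatobothus polyophthalmus
    "A.t": ("III", False),  # Arnoglossus tenuis
    "L.g": ("III", False),  # Lophonectes gallus
    "L.l": ("III", False),  # Laeops lanceolata
    "P.i": ("III", False),  # Psettina iijimae
    "B.pa": ("IV", False),  # Bothus pantherinus
    "A.in": ("IV", True),   # Asterorhombus intermedius (tRNA-V shuffled)
}

BOTHID_SPECIES: tuple[str, ...] = tuple(SPECIES_TYPE)


def _build(names: Sequence[str], is_dimer: bool = False) -> GenomeArrangement:
    feats = [GeneFeature(n, strand=default_strand(n)) for n in names]
    return GenomeArrangement.from_features(feats, is_dimer=is_dimer)


def canonical_teleost_order() -> GenomeArrangement:
    """The ancestral gene order of typical fish, linearized at tRNA-F.

    Contains the 37 genes plus one CR and the O_L (located between
    tRNA-N and tRNA-C inside the WANCY cluster).
    """
    return _build(CANONICAL_ORDER)


def bothid_fixture(species_code: str) -> GenomeArrangement:
    """Observed rearranged gene order of one of the 13 bothids.

    Parameters
    ----------
    species_code:
        One of ``BOTHID_SPECIES`` (e.g. ``"G.p"`` for
        *Grammatobothus polyophthalmus*, ``"C.az"`` for
        *Crossorhombus azureus*).
    """
    try:
        type_label, v_shuffled = SPECIES_TYPE[species_code]
    except KeyError:
        raise KeyError(
            f"unknown species code {species_code!r}; expected one of "
            + ", ".join(BOTHID_SPECIES)
        ) from None
    names = list(_BOTHID_H_BLOCK) + list(_TYPE_TAIL[type_label])
    if v_shuffled:
        # 12S-V-16S-L1  ->  12S-16S-V-L1
        names.remove("V")
        names.insert(names.index("L1"), "V")
    return _build(names)


# ---------------------------------------------------------------------------
# Equality and counting
# ---------------------------------------------------------------------------

def _signature(a: GenomeArrangement, include_spacers: bool, use_tags: bool):
    out = []
    for f in a.features:
        if f.category == "spacer" and not include_spacers:
            continue
        if use_tags:
            out.append((f.name, f.strand, f.copy_tag))
        else:
            out.append((f.name, f.strand))
    return out


def arrangements_equal(
    a: GenomeArrangement,
    b: GenomeArrangement,
    include_spacers: bool = False,
) -> bool:
    """Rotation-invariant equality of two circular arrangements.

    Compares the (name, strand) sequence of the two circular orders
    under every rotation; spacers are ignored unless
    ``include_spacers``.  Copy tags are ignored for monomers and
    compared for dimers.
    """
    if a.is_dimer != b.is_dimer:
        raise ValueError("cannot compare a monomer with a dimer")
    use_tags = a.is_dimer
    sa = _signature(a, include_spacers, use_tags)
    sb = _signature(b, include_spacers, use_tags)
    if len(sa) != len(sb):
        return False
    if not sa:
        return True
    # rotation check by doubling
    doubled = sa + sa
    n = len(sa)
    return any(doubled[i : i + n] == sb for i in range(n))


def strand_counts(a: GenomeArrangement) -> tuple[int, int]:
    """(H, L) counts over genes only (CR/O_L/spacers excluded)."""
    h = sum(1 for f in a.genes() if f.strand == "H")
    l = sum(1 for f in a.genes() if f.strand == "L")
    return h, l


# ---------------------------------------------------------------------------
# Tabular gene-order file format
# ---------------------------------------------------------------------------
#
# One feature per line, tab-separated: NAME STRAND(+/-) CATEGORY
# [PROVENANCE] [LENGTH_BP]; '.' marks an absent optional field; '#'
# starts a comment; the header line "#circular anchor=<NAME>" records
# the linearization anchor.  The +/- strand convention maps to H/L,
# matching GenBank complement semantics.

_STRAND_TO_SYMBOL = {"H": "+", "L": "-"}
_SYMBOL_TO_STRAND = {"+": "H", "-": "L", "−": "L"}


def write_arrangement(a: GenomeArrangement, path_or_file) -> None:
    if hasattr(path_or_file, "write"):
        fh = path_or_file
        close = False
    else:
        fh = open(path_or_file, "w")
        close = True
    try:
        fh.write(f"#circular anchor={a.anchor}\n")
        if a.is_dimer:
            fh.write("#dimer\n")
        for f in a.features:
            prov = f.provenance if f.provenance else "."
            length = str(f.length_bp) if f.length_bp else "."
            tag = "" if f.copy_tag == "plain" else "\tprime"
            fh.write(
                f"{f.name}\t{_STRAND_TO_SYMBOL[f.strand]}\t{f.category}"
                f"\t{prov}\t{length}{tag}\n"
            )
    finally:
        if close:
            fh.close()


def read_arrangement(path) -> GenomeArrangement:
    anchor = "F"
    is_dimer = False
    feats: list[GeneFeature] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("circular"):
                    for tok in body.split():
                        if tok.startswith("anchor="):
                            anchor = tok.split("=", 1)[1]
                elif body == "dimer":
                    is_dimer = True
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"line {lineno}: malformed line {line!r}")
            name, symbol = cols[0], cols[1]
            if name not in VOCABULARY:
                raise ValueError(f"line {lineno}: unknown gene token {name!r}")
            if symbol not in _SYMBOL_TO_STRAND:
                raise ValueError(f"line {lineno}: bad strand symbol {symbol!r}")
            provenance = None
            length_bp = None
            copy_tag = "plain"
            if len(cols) >= 4 and cols[3] not in (".", ""):
                provenance = cols[3]
            if len(cols) >= 5 and cols[4] not in (".", ""):
                length_bp = int(cols[4])
            if len(cols) >= 6 and cols[5] == "prime":
                copy_tag = "prime"
            feat = GeneFeature(
                name,
                strand=_SYMBOL_TO_STRAND[symbol],
                copy_tag=copy_tag,
                provenance=provenance,
                length_bp=length_bp,
            )
            if feat.category != "spacer":
                key = (name, copy_tag)
                if key in seen and not is_dimer:
                    raise ValueError(
                        f"line {lineno}: duplicate gene {name!r} in monomer"
                    )
                if key in seen:
                    raise ValueError(
                        f"line {lineno}: duplicate gene {name!r} ({copy_tag})"
                    )
                seen.add(key)
            feats.append(feat)
    return GenomeArrangement.from_features(feats, anchor=anchor, is_dimer=is_dimer)
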