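"""Intergenic-spacer provenance tracing.

Under the DMNL model every gene that stops being transcribed
degenerates in place, so each intergenic spacer of a rearranged
genome should sit exactly where the model predicts a degenerated gene
— and its candidate source genes are the degenerated genes that
collapsed between the same pair of surviving neighbors.  This module
predicts those loci from a variant config, matches them against an
annotated genome's observed gaps, and produces a per-species census
of unique spacers.

A "unique intergenic spacer" is operationalized as a per-species gap
of >= 2 bp at a DMNL-predicted locus.  Gaps known from non-rearranged
flatfishes (and the tRNA-V shuffle gaps of *A. intermedius*) carry no
DMNL signal and are listed in ``EXCLUDED_LOCI``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .annotated import AnnotatedSequence
from .classify import classify
from .dmnl import DmnlVariantConfig, run_dmnl
from .model import GenomeArrangement, GeneFeature, canonical_teleost_order
from .vocab import CATEGORY_OF

__all__ = [
    "SpacerTrace",
    "EXCLUDED_LOCI",
    "LOCUS_IDS",
    "predict_spacer_loci",
    "match_observed",
    "census",
    "CensusResult",
    "arrangement_from_annotated",
]


@dataclass
class SpacerTrace:
    """A predicted (optionally observed) spacer locus.

    ``locus`` is the pair of surviving flanking features;
    ``candidate_sources`` the degenerated gene(s) whose remnant the
    spacer is; multi-element source lists express the ambiguity of
    neighboring genes collapsing into one gap and are never resolved
    by guessing.
    """

    locus: tuple[str, str]
    candidate_sources: list[str]
    observed_length_bp: Optional[int] = None
    locus_id: Optional[str] = None


def _norm(name: str) -> str:
    """Collapse CR1/CR2 to CR for locus bookkeeping."""
    return "CR" if CATEGORY_OF.get(name) == "control" else name


def _norm_locus(locus: tuple[str, str]) -> tuple[str, str]:
    return (_norm(locus[0]), _norm(locus[1]))


#: Gaps with no relationship to the DMNL process: the three
#: 12S/16S/V/L1-region gaps created by tRNA-V shuffling, the double-A
#: between tRNA-H and tRNA-S2, and gaps also present in non-rearranged
#: teleost mitogenomes.
EXCLUDED_LOCI: frozenset[tuple[str, str]] = frozenset(
    {
        ("12S", "16S"),
        ("16S", "V"),
        ("V", "L1"),
        ("H", "S2"),
        ("ND1", "I"),
        ("M", "ND2"),
        ("COIII", "G"),
    }
)

#: Fixed locus-numbering table (fourteen loci: 1-12 plus the repeated
#: loci 6' and 10'), keyed on CR-normalized (left, right) neighbors.
LOCUS_IDS: dict[tuple[str, str], str] = {
    ("I", "M"): "1",
    ("W", "N"): "2",
    ("N", "COI"): "3",
    ("OL", "COI"): "3",
    ("COI", "COII"): "4",
    ("ND5", "CytB"): "5",
    ("T", "CR"): "6",
    ("T", "D"): "6",
    ("D", "CR"): "6'",
    ("CR", "Q"): "7",
    ("Q", "A"): "8",
    ("A", "C"): "9",
    ("Y", "S1"): "10",
    ("S1", "D"): "10'",
    ("D", "ND6"): "11",
    ("S1", "ND6"): "11",
    ("T", "Q"): "7",  # Type IV: CR1 degenerated wholly, merging into locus 7
    # locus 12 is the region around tRNA-P; its (sometimes long)
    # remnants may derive from CytB/T copies or from a degenerated CR
    ("E", "P"): "12",
    ("P", "CR"): "12",
    ("P", "F"): "12",
    ("CR", "F"): "12",
}


def _locus_id(locus: tuple[str, str]) -> Optional[str]:
    return LOCUS_IDS.get(_norm_locus(locus))


def predict_spacer_loci(config: DmnlVariantConfig) -> list[SpacerTrace]:
    """Spacer loci implied by one DMNL variant, in genome order.

    Runs the DMNL engine from the canonical order and merges runs of
    consecutive degenerated genes that collapse between the same pair
    of surviving neighbors into one locus whose ``candidate_sources``
    lists them all.
    """
    res = run_dmnl(canonical_teleost_order(), config)
    arr = res.final_with_spacers
    traces: list[SpacerTrace] = []
    feats = arr.features
    n = len(feats)
    i = 0
    while i < n:
        if feats[i].category != "spacer":
            i += 1
            continue
        j = i
        sources = []
        while j < n and feats[j].category == "spacer":
            sources.append(feats[j].provenance)
            j += 1
        left = feats[i - 1].name if i > 0 else feats[n - 1].name
        right = feats[j % n].name
        # de-duplicate while preserving order (plain + prime copies of
        # the same gene collapse to one source name)
        seen: list[str] = []
        for s in sources:
            if s not in seen:
                seen.append(s)
        trace = SpacerTrace(locus=(left, right), candidate_sources=seen)
        trace.locus_id = _locus_id(trace.locus)
        traces.append(trace)
        i = j
    # fresh labels for loci outside the bundled numbering
    fresh = 0
    for t in traces:
        if t.locus_id is None:
            fresh += 1
            t.locus_id = f"x{fresh}"
    return traces


def arrangement_from_annotated(
    annotated: AnnotatedSequence,
) -> GenomeArrangement:
    """Order-level view of an annotated genome (spacers dropped)."""
    feats = [
        GeneFeature(f.name, strand=f.strand)
        for f in sorted(annotated.features, key=lambda f: f.start)
        if f.category != "spacer"
    ]
    return GenomeArrangement.from_features(feats)


def observed_gaps(
    annotated: AnnotatedSequence,
) -> dict[tuple[str, str], int]:
    """Inter-feature gap lengths keyed by CR-normalized neighbors.

    Gaps are measured between consecutive annotated non-spacer
    features on the circle; overlapping features (declared design,
    e.g. an O_L recruiting tRNA-N bases) yield gap 0.
    """
    feats = [
        f
        for f in sorted(annotated.features, key=lambda f: f.start)
        if f.category != "spacer"
    ]
    L = len(annotated.seq)
    out: dict[tuple[str, str], int] = {}
    for i, f in enumerate(feats):
        g = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            gap = g.start - f.end
        else:
            gap = (g.start - f.end) % L
        out[(_norm(f.name), _norm(g.name))] = max(0, gap)
    return out


def match_observed(
    predicted: list[SpacerTrace],
    annotated: AnnotatedSequence,
    expected_type: Optional[str] = None,
    min_len: int = 2,
) -> list[SpacerTrace]:
    """Fill ``observed_length_bp`` at each predicted locus.

    A predicted locus acquires an observed length when the annotated
    genome shows an inter-feature gap >= ``min_len`` between the same
    (CR-normalized) neighbors; loci with no such gap keep
    ``observed_length_bp`` absent, meaning the source gene disappeared
    entirely.  When ``expected_type`` is given, the annotated genome's
    gene order must classify to it.
    """
    if expected_type is not None:
        call = classify(arrangement_from_annotated(annotated))
        if call.label != expected_type:
            raise ValueError(
                f"annotated genome classifies as {call.label}, "
                f"expected {expected_type}"
            )
    gaps = observed_gaps(annotated)
    out = []
    for t in predicted:
        length = gaps.get(_norm_locus(t.locus))
        matched = SpacerTrace(
            locus=t.locus,
            candidate_sources=list(t.candidate_sources),
            observed_length_bp=length if length and length >= min_len else None,
            locus_id=t.locus_id,
        )
        out.append(matched)
    return out


@dataclass
class CensusResult:
    """Unique-spacer census over a cohort."""

    table: pd.DataFrame  # species, locus_id, left, right, length_bp, candidate_sources
    per_species: dict[str, int] = field(default_factory=dict)
    total_unique: int = 0
    locus_length_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)


def census(traced: dict[str, list[SpacerTrace]]) -> CensusResult:
    """Count unique spacers (per-species occupied loci) over a cohort.

    A spacer is counted once per (species, locus) with an observed
    length; ``locus_length_ranges`` gives the min/max observed length
    per locus id across species.
    """
    rows = []
    per_species: dict[str, int] = {}
    ranges: dict[str, tuple[int, int]] = {}
    for sp, traces in traced.items():
        count = 0
        for t in traces:
            if t.observed_length_bp is None:
                continue
            count += 1
            rows.append(
                {
                    "species": sp,
                    "locus_id": t.locus_id,
                    "left": t.locus[0],
                    "right": t.locus[1],
                    "length_bp": t.observed_length_bp,
                    "candidate_sources": ";".join(t.candidate_sources),
                }
            )
            lo, hi = ranges.get(t.locus_id, (t.observed_length_bp, t.observed_length_bp))
            ranges[t.locus_id] = (
                min(lo, t.observed_length_bp),
                max(hi, t.observed_length_bp),
            )
        per_species[sp] = count
    table = pd.DataFrame(
        rows,
        columns=[
            "species",
            "locus_id",
            "left",
            "right",
            "length_bp",
            "candidate_sources",
        ],
    )
    return CensusResult(
        table=table,
        per_species=per_species,
        total_unique=len(rows),
        locus_length_ranges=ranges,
    )
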