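"""Sequence-level detectors around the rearranged WANCY region and
the control regions.

O_L — the light-strand replication origin — is normally a short
stem-loop between tRNA-N and tRNA-C.  After the bothid rearrangement
removed tRNA-C/Y from the neighborhood, the stem-loop must form from
whatever sequence remains between tRNA-N and COI, possibly recruiting
a few bases of tRNA-N itself, or (when the spacer is only ~7-14 bp)
from the middle of tRNA-N.  :func:`detect_ol` implements that cascade.

Hairpin scoring is combinatorial (stem length, then mismatches) over
Watson-Crick pairs with optional G·T wobbles — the structures involved
are short canonical stems, so no thermodynamic model is used.

The control-region detectors are :func:`scan_tas` (TAS core
ACAT-n-TGTA) and :func:`find_tandem_repeats` (3'-end tandem arrays,
e.g. tens of copies of a ~22 bp motif).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

from .annotated import AnnotatedSequence

__all__ = [
    "HairpinParams",
    "HairpinResult",
    "RepeatResult",
    "TasHit",
    "MOTIF5_TOKENS",
    "MOTIF3_TOKEN",
    "find_hairpin",
    "detect_ol",
    "scan_motifs",
    "find_tandem_repeats",
    "scan_tas",
    "dot_bracket",
]

#: Conserved 5'-flank motifs of bothid/flatfish O_L stems.
MOTIF5_TOKENS = ("GGTGG", "GGGGG", "GCCGG")
#: Conserved 3'-flank motif shared by nine bothid O_L structures.
MOTIF3_TOKEN = "TAGA"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}
_VALID = set("ACGT")


@dataclass(frozen=True)
class HairpinParams:
    min_stem: int = 8
    #: O_L-like stems are short; capping the stem keeps the search
    #: cheap and avoids reporting implausibly long quasi-palindromes
    max_stem: int = 15
    min_loop: int = 3
    max_loop: int = 15
    max_mismatch: int = 1
    allow_gu: bool = True
    #: width of the centered tRNA-N window for the last cascade step
    trnaN_middle_window: int = 26
    #: flank width for conserved-motif scanning
    motif_window: int = 8


@dataclass
class HairpinResult:
    """A detected stem-loop (positions 0-based half-open on the
    searched sequence)."""

    start: int
    end: int
    stem_len_bp: int
    loop_len_nt: int
    mismatches: int
    gu_pairs: int
    motif5: Optional[str] = None
    motif3: Optional[str] = None
    mode: str = "spacer_only"
    trnaN_bases_used: int = 0


class TasHit(NamedTuple):
    start: int
    middle: str


@dataclass
class RepeatResult:
    motif: str
    period_bp: int
    copies: float
    start: int
    end: int


def _check_nt(seq: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")


def find_hairpin(
    seq: str, params: HairpinParams = HairpinParams()
) -> Optional[HairpinResult]:
    """Best qualifying stem-loop in ``seq``, or None.

    Exhaustive search over all (position, stem length, loop length)
    combinations; a candidate qualifies when every stem position pairs
    Watson-Crick (or G·T when allowed) except for at most
    ``max_mismatch`` internal mismatches, the stem is at least
    ``min_stem`` long, and the loop length lies in
    [``min_loop``, ``max_loop``].  The best candidate has the maximal
    stem, then the fewest mismatches, then the leftmost position.
    """
    seq = seq.upper()
    _check_nt(seq)
    n = len(seq)
    if n < 2 * params.min_stem + params.min_loop:
        return None
    best: Optional[HairpinResult] = None
    max_stem = min(params.max_stem, (n - params.min_loop) // 2)
    for stem in range(max_stem, params.min_stem - 1, -1):
        if best is not None and best.stem_len_bp >= stem:
            break
        for loop in range(params.min_loop, params.max_loop + 1):
            span = 2 * stem + loop
            if span > n:
                continue
            for i in range(0, n - span + 1):
                mism = 0
                gu = 0
                ok = True
                for k in range(stem):
                    a = seq[i + k]
                    b = seq[i + span - 1 - k]
                    if (a, b) in _WC:
                        continue
                    if params.allow_gu and (a, b) in _GU:
                        gu += 1
                        continue
                    mism += 1
                    if mism > params.max_mismatch:
                        ok = False
                        break
                if not ok:
                    continue
                cand = HairpinResult(
                    start=i,
                    end=i + span,
                    stem_len_bp=stem,
                    loop_len_nt=loop,
                    mismatches=mism,
                    gu_pairs=gu,
                )
                if best is None or (
                    (cand.stem_len_bp, -cand.mismatches, -cand.start)
                    > (best.stem_len_bp, -best.mismatches, -best.start)
                ):
                    best = cand
    return best


def detect_ol(
    annotated: AnnotatedSequence, params: HairpinParams = HairpinParams()
) -> Optional[HairpinResult]:
    """O_L stem-loop search between tRNA-N and COI, with fallbacks.

    Mode cascade (each step only runs if the previous found nothing):

    1. ``spacer_only`` — the intergenic sequence between the tRNA-N
       boundary and COI alone;
    2. ``spacer_plus_trnaN_3prime`` — the spacer extended by 3, then
       4, then 5 bases of tRNA-N from the boundary shared with the
       spacer (the gene's 3' side in the convention of the O_L
       diagrams);
    3. ``trnaN_middle`` — a centered window inside tRNA-N (default
       26 nt), for genomes whose spacer is too short to fold at all.

    Coordinates of the returned hairpin are absolute genome positions;
    conserved flank motifs are annotated via :func:`scan_motifs`.
    """
    try:
        trna_n = annotated.feature("N")
        coi = annotated.feature("COI")
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    L = len(annotated.seq)
    gap_start = trna_n.end % L
    gap_len = (coi.start - gap_start) % L
    spacer = annotated.slice(gap_start, gap_start + gap_len)

    hp = find_hairpin(spacer, params)
    if hp is not None:
        hp.mode = "spacer_only"
        hp.start = (gap_start + hp.start) % L
        hp.end = hp.start + hp.stem_len_bp * 2 + hp.loop_len_nt
        return scan_motifs(annotated, hp, params)

    for k in (3, 4, 5):
        window_start = (trna_n.end - k) % L
        window = annotated.slice(window_start, window_start + k + gap_len)
        hp = find_hairpin(window, params)
        if hp is not None:
            hp.mode = "spacer_plus_trnaN_3prime"
            hp.trnaN_bases_used = k
            hp.start = (window_start + hp.start) % L
            hp.end = hp.start + hp.stem_len_bp * 2 + hp.loop_len_nt
            return scan_motifs(annotated, hp, params)

    width = params.trnaN_middle_window
    mid = (trna_n.start + trna_n.length // 2) % L
    win_start = (mid - width // 2) % L
    window = annotated.slice(win_start, win_start + width)
    # a short window cannot hold the default stem; adapt the minimum
    # so an O_L-like structure inside tRNA-N remains findable
    inner = params
    if width < 2 * params.min_stem + params.min_loop:
        inner = replace(params, min_stem=max(4, (width - params.min_loop) // 2))
    hp = find_hairpin(window, inner)
    if hp is not None:
        hp.mode = "trnaN_middle"
        hp.trnaN_bases_used = width
        hp.start = (win_start + hp.start) % L
        hp.end = hp.start + hp.stem_len_bp * 2 + hp.loop_len_nt
        return scan_motifs(annotated, hp, params)
    return None


def scan_motifs(
    annotated: AnnotatedSequence,
    around: HairpinResult,
    params: HairpinParams = HairpinParams(),
) -> HairpinResult:
    """Annotate conserved flank motifs next to a located hairpin.

    ``motif5`` is set when GGTGG, GGGGG or GCCGG occurs within
    ``motif_window`` nucleotides 5' of the stem; ``motif3`` when TAGA
    occurs within the window 3' of the stem.  The windows extend 3 nt
    into the stem on each side: the conserved motifs sit at the stem
    base and the mismatch-tolerant search may absorb a motif edge into
    the reported stem.
    """
    w = params.motif_window
    L = len(annotated.seq)
    upstream = annotated.slice(around.start - w, around.start + 3)
    downstream = annotated.slice(around.end % L - 3, around.end % L + w)
    around.motif5 = next((m for m in MOTIF5_TOKENS if m in upstream), None)
    around.motif3 = MOTIF3_TOKEN if MOTIF3_TOKEN in downstream else None
    return around


def find_tandem_repeats(
    seq: str, min_period: int = 10, min_copies: int = 3
) -> list[RepeatResult]:
    """Maximal exact tandem arrays, non-overlapping, longest first.

    For each candidate period p, positions where seq[i] == seq[i+p]
    are chained into maximal runs; a run of length r spans an array of
    r + p bases, i.e. (r + p) / p copies (reported to one decimal).
    Arrays shorter than ``min_copies`` copies are discarded; when
    candidate arrays overlap, the longest (then smallest-period) one
    wins.
    """
    seq = seq.upper()
    _check_nt(seq)
    n = len(seq)
    candidates: list[RepeatResult] = []
    max_period = n // min_copies
    for p in range(min_period, max_period + 1):
        i = 0
        while i < n - p:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            j = i
            while j < n - p and seq[j] == seq[j + p]:
                j += 1
            run = j - i  # matched positions; array spans run + p bases
            copies = (run + p) / p
            if copies >= min_copies:
                candidates.append(
                    RepeatResult(
                        motif=seq[i : i + p],
                        period_bp=p,
                        copies=round(copies, 1),
                        start=i,
                        end=i + run + p,
                    )
                )
            i = j + 1
    candidates.sort(key=lambda r: (-(r.end - r.start), r.period_bp, r.start))
    chosen: list[RepeatResult] = []
    for cand in candidates:
        if all(
            cand.end <= c.start or cand.start >= c.end for c in chosen
        ):
            chosen.append(cand)
    return chosen


def scan_tas(seq: str) -> list[TasHit]:
    """All matches of the TAS core ACAT-n-TGTA (any middle base).

    Returns (start, middle-base) hits; overlapping matches are all
    reported.
    """
    seq = seq.upper()
    _check_nt(seq)
    return [
        TasHit(m.start(), m.group(1))
        for m in re.finditer(r"(?=ACAT([ACGT])TGTA)", seq)
    ]


def dot_bracket(hp: HairpinResult) -> str:
    """Dot-bracket sketch of a hairpin: '(' stem, '.' loop, ')' stem."""
    return (
        "(" * hp.stem_len_bp + "." * hp.loop_len_nt + ")" * hp.stem_len_bp
    )
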