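"""Synthetic annotated mitogenomes with recorded ground truth.

The generator realizes any :class:`~dmnlkit.model.GenomeArrangement`
as a nucleotide sequence with feature coordinates, planting the
sequence features the detectors look for — an O_L stem-loop with the
conserved flank motifs, a TAS core and a 3'-end tandem-repeat array in
each control region — and can simulate DMNL degeneration at the
sequence level, truncating every non-transcribed gene to a remnant of
its own sequence.  Every placement decision is recorded in
``ground_truth`` so parameter-recovery tests have an exact oracle.

Gene sequences are random nucleotides at a configurable GC fraction
(no codon or cloverleaf structure — annotation realism is not a
goal); lengths come from a canonical vertebrate gene-length table so a
monomer lands near 16-17 kb and a dimer near twice that.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotated import AnnotatedSequence, SeqFeatureRec
from .dmnl import DmnlVariantConfig, dimerize, nonrandom_loss
from .model import GenomeArrangement, canonical_teleost_order, arrangements_equal
from .rearrange import translocate, shuffle_v
from .seqfeatures import (
    HairpinParams,
    detect_ol,
    find_hairpin,
    MOTIF5_TOKENS,
    MOTIF3_TOKEN,
)

__all__ = [
    "CANONICAL_GENE_LENGTHS",
    "SynthParams",
    "synth_sequence",
    "evolve_degeneration",
    "write_ground_truth",
]

#: Typical vertebrate mitochondrial gene lengths (bp); tRNAs are
#: sampled from ``SynthParams.trna_len_range`` instead.
CANONICAL_GENE_LENGTHS: dict[str, int] = {
    "ND1": 975,
    "ND2": 1046,
    "COI": 1551,
    "COII": 691,
    "ATP8": 168,
    "ATP6": 684,
    "COIII": 786,
    "ND3": 349,
    "ND4L": 297,
    "ND4": 1381,
    "ND5": 1839,
    "ND6": 522,
    "CytB": 1141,
    "12S": 950,
    "16S": 1700,
}

_TAS_CORE = "ACATCTGTA"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; ``seed`` is mandatory for reproducibility.

    Defaults emulate the features reported for bothid mitogenomes:
    spacer remnants of 2-88 bp with occasional complete disappearance,
    long 155-511 bp remnants where a whole control region degenerated,
    a ~900 bp CR carrying a TAS core and 35 copies of a 22 bp tandem
    motif at its 3' end, and an O_L hairpin formed from the tRNA-N/COI
    spacer with ~4 recruited tRNA-N bases.
    """

    seed: int
    trna_len_range: tuple[int, int] = (65, 75)
    cr_len: int = 900
    gc: float = 0.45
    # spacer remnants left by degeneration
    spacer_len_range: tuple[int, int] = (2, 88)
    long_remnant_range: tuple[int, int] = (155, 511)
    long_remnant_prob: float = 0.75  # applies to degenerated CRs only
    disappear_prob: float = 0.15
    # control-region tandem array
    repeat_motif_len: int = 22
    repeat_copies: int = 35
    # planted O_L hairpin
    hairpin_stem: int = 10
    hairpin_loop: int = 5
    ol_mode: str = "spacer_plus_trnaN_3prime"
    trnaN_overlap: int = 4  # bases of tRNA-N recruited (3-5)
    ol_spacer_len: int = 40  # tRNA-N..COI spacer in spacer-based modes
    ol_spacer_len_middle: int = 7  # short spacer forcing the middle mode
    motif5: str = MOTIF5_TOKENS[0]  # GGTGG
    motif3: str = MOTIF3_TOKEN
    plant_motifs: bool = True

    def __post_init__(self):
        if self.ol_mode not in (
            "spacer_only",
            "spacer_plus_trnaN_3prime",
            "trnaN_middle",
        ):
            raise ValueError(f"bad ol_mode {self.ol_mode!r}")
        if not 3 <= self.trnaN_overlap <= 5:
            raise ValueError("trnaN_overlap must be 3-5")


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def _make_hairpin(rng: np.random.Generator, stem: int, loop: int, gc: float) -> str:
    arm = _rand_seq(rng, stem, gc)
    return arm + _rand_seq(rng, loop, gc) + _revcomp(arm)


def _sample_len(rng: np.random.Generator, name: str, p: SynthParams) -> int:
    if name in CANONICAL_GENE_LENGTHS:
        return CANONICAL_GENE_LENGTHS[name]
    return int(rng.integers(p.trna_len_range[0], p.trna_len_range[1] + 1))


def _cr_seq(rng: np.random.Generator, p: SynthParams, gt: dict) -> str:
    """Control region: pad + TAS core + pad + 3' tandem array."""
    array = ""
    if p.repeat_copies >= 1:
        motif = _rand_seq(rng, p.repeat_motif_len, p.gc)
        array = motif * p.repeat_copies
        gt["repeat"] = {
            "motif": motif,
            "period": p.repeat_motif_len,
            "copies": p.repeat_copies,
        }
    pad_total = max(20, p.cr_len - len(array) - len(_TAS_CORE))
    pad1 = pad_total // 4
    seq = (
        _rand_seq(rng, pad1, p.gc)
        + _TAS_CORE
        + _rand_seq(rng, pad_total - pad1, p.gc)
        + array
    )
    gt["tas_offset"] = pad1
    if array:
        gt["repeat"]["offset"] = len(seq) - len(array)
    return seq


def synth_sequence(
    a: GenomeArrangement, p: SynthParams
) -> AnnotatedSequence:
    """Realize an arrangement as an annotated circular sequence.

    Each control region receives a TAS core and (when configured) a
    3'-end tandem array; the O_L locus is realized as a planted
    stem-loop per ``p.ol_mode`` — possibly recruiting the 3'-side
    bases of the neighboring tRNA-N or sitting in the middle of
    tRNA-N.  For monomeric arrangements the generator verifies with
    :func:`~dmnlkit.seqfeatures.detect_ol` that the planted structure
    is recoverable (and, when O_L directly abuts COI, recoverable in
    the planted mode), resampling a bounded number of times; the same
    seed always yields the same output.
    """
    for attempt in range(40):
        rng = np.random.default_rng([p.seed % (2**31), attempt])
        out = _synth_once(a, p, rng)
        if _verify_ol(a, p, out):
            return out
    raise RuntimeError(
        "could not realize a sequence satisfying the O_L constraints; "
        "check hairpin/window parameters"
    )


def _ol_context(a: GenomeArrangement):
    """(has_ol, ol_abuts_coi): layout facts steering O_L realization."""
    names = [f.name for f in a.features if f.category != "spacer"]
    if "OL" not in names:
        return False, False
    i = names.index("OL")
    return True, names[(i + 1) % len(names)] == "COI"


def _synth_once(
    a: GenomeArrangement, p: SynthParams, rng: np.random.Generator
) -> AnnotatedSequence:
    has_ol, ol_abuts_coi = _ol_context(a)
    # the middle mode only makes sense when the spacer is short; the
    # spacer-based modes need the long spacer
    mode = p.ol_mode if ol_abuts_coi else "spacer_only"

    chunks: list[str] = []
    recs: list[SeqFeatureRec] = []
    gt: dict = {"ol": [], "spacers": [], "crs": []}
    pos = 0
    pending_ol: Optional[dict] = None  # overlap bookkeeping for N

    feats = list(a.features)
    for idx, f in enumerate(feats):
        if f.category == "control":
            cr_gt: dict = {"name": f.name, "copy_tag": f.copy_tag}
            seq = _cr_seq(rng, p, cr_gt)
            cr_gt["start"] = pos
            cr_gt["tas_pos"] = pos + cr_gt.pop("tas_offset")
            if "repeat" in cr_gt:
                cr_gt["repeat"]["start"] = pos + cr_gt["repeat"].pop("offset")
            gt["crs"].append(cr_gt)
        elif f.category == "origin":
            seq, ol_gt = _realize_ol(rng, p, mode, chunks, recs, pos)
            ol_gt["copy_tag"] = f.copy_tag
            gt["ol"].append(ol_gt)
            # OL feature covers the hairpin span (may overlap tRNA-N by
            # declared design in the overlap and middle modes)
            recs.append(
                SeqFeatureRec("OL", "H", ol_gt["start"], ol_gt["end"], f.copy_tag)
            )
            chunks.append(seq)
            pos += len(seq)
            continue
        elif f.category == "spacer":
            length = _spacer_length(rng, p, f.provenance)
            seq = _rand_seq(rng, length, p.gc)
            gt["spacers"].append(
                {"source": f.provenance, "copy_tag": f.copy_tag, "length": length}
            )
            if length:
                recs.append(
                    SeqFeatureRec(
                        "SPACER", "H", pos, pos + length, f.copy_tag, f.provenance
                    )
                )
            chunks.append(seq)
            pos += length
            continue
        else:
            seq = _rand_seq(rng, _sample_len(rng, f.name, p), p.gc)

        recs.append(
            SeqFeatureRec(f.name, f.strand, pos, pos + len(seq), f.copy_tag)
        )
        chunks.append(seq)
        pos += len(seq)

    return AnnotatedSequence(seq="".join(chunks), features=recs, ground_truth=gt)


def _spacer_length(
    rng: np.random.Generator, p: SynthParams, provenance: Optional[str]
) -> int:
    if rng.random() < p.disappear_prob:
        return 0
    if provenance == "CR" and rng.random() < p.long_remnant_prob:
        lo, hi = p.long_remnant_range
    else:
        lo, hi = p.spacer_len_range
    return int(rng.integers(lo, hi + 1))


def _realize_ol(
    rng: np.random.Generator,
    p: SynthParams,
    mode: str,
    chunks: list[str],
    recs: list[SeqFeatureRec],
    pos: int,
) -> tuple[str, dict]:
    """Build the O_L region; may rewrite the 3' end of the preceding
    tRNA-N chunk (overlap and middle modes)."""
    loop = p.hairpin_loop
    hp_params = HairpinParams()
    if mode == "spacer_only":
        stem = p.hairpin_stem
        m5 = p.motif5 if p.plant_motifs else ""
        m3 = p.motif3 if p.plant_motifs else ""
        for _ in range(200):
            hp = _make_hairpin(rng, stem, loop, p.gc)
            pad = max(0, p.ol_spacer_len - len(hp) - len(m5) - len(m3))
            seq = m5 + hp + m3 + _rand_seq(rng, pad, p.gc)
            found = find_hairpin(seq, hp_params)
            # the reported structure must overlap the planted one; the
            # search may extend the stem into the flanks via wobbles
            # and the mismatch budget, but no more than the 3 nt the
            # motif scanner tolerates
            if (
                found is not None
                and found.start >= len(m5) - 3
                and found.end <= len(m5) + len(hp) + 3
                and not (
                    found.end <= len(m5)
                    or found.start >= len(m5) + len(hp)
                )
            ):
                break
        return seq, {
            "mode": mode,
            "span": len(hp),
            "start": pos + len(m5),
            "end": pos + len(m5) + len(hp),
            "stem": stem,
            "loop": loop,
            "trnaN_bases_used": 0,
        }
    if mode == "spacer_plus_trnaN_3prime":
        # the structure must genuinely need the recruited bases: the
        # stem equals the detector minimum (dropping one terminal pair
        # leaves it unrecognizable) and the loop sits at most one base
        # above the detector minimum, otherwise the mismatch allowance
        # would let a truncated stem regrow inward through the loop
        stem = hp_params.min_stem
        loop = min(loop, hp_params.min_loop + 1)
        k = p.trnaN_overlap
        m5 = p.motif5 if p.plant_motifs else ""
        m3 = p.motif3 if p.plant_motifs else ""
        for _ in range(200):
            hp = _make_hairpin(rng, stem, loop, p.gc)
            n_tail = m5 + hp[:k]
            inner = hp[k:]
            pad = max(0, p.ol_spacer_len - len(inner) - len(m3))
            spacer = inner + m3 + _rand_seq(rng, pad, p.gc)
            # emulate the detection cascade: nothing in the spacer
            # alone, nothing with fewer recruited bases, the planted
            # stem with exactly k
            if find_hairpin(spacer, hp_params) is not None:
                continue
            shorter_hit = any(
                find_hairpin(n_tail[-kk:] + spacer, hp_params) is not None
                for kk in range(3, k)
            )
            if shorter_hit:
                continue
            found = find_hairpin(n_tail[-k:] + spacer, hp_params)
            if found is not None and found.start == 0 and found.stem_len_bp == stem:
                break
        n_seq = chunks[-1]
        n_seq = n_seq[: len(n_seq) - len(n_tail)] + n_tail
        chunks[-1] = n_seq
        return spacer, {
            "mode": mode,
            "span": len(hp),
            "start": pos - k,
            "end": pos - k + len(hp),
            "stem": stem,
            "loop": loop,
            "trnaN_bases_used": k,
        }
    # trnaN_middle: embed the hairpin centered in the preceding tRNA-N
    window = HairpinParams().trnaN_middle_window
    stem = min(p.hairpin_stem, (window - loop) // 2)
    hp = _make_hairpin(rng, stem, loop, p.gc)
    n_seq = chunks[-1]
    n_rec = recs[-1]
    mid = len(n_seq) // 2
    off = mid - len(hp) // 2
    n_seq = n_seq[:off] + hp + n_seq[off + len(hp):]
    chunks[-1] = n_seq
    start = n_rec.start + off
    spacer = _rand_seq(rng, p.ol_spacer_len_middle, p.gc)
    return spacer, {
        "mode": mode,
        "span": len(hp),
        "start": start,
        "end": start + len(hp),
        "stem": stem,
        "loop": loop,
        "trnaN_bases_used": window,
    }


def _verify_ol(
    a: GenomeArrangement, p: SynthParams, out: AnnotatedSequence
) -> bool:
    """Planted O_L must be what the detector recovers (monomers only)."""
    has_ol, ol_abuts_coi = _ol_context(a)
    if not has_ol or a.is_dimer or not ol_abuts_coi:
        # in canonical-layout genomes whole genes separate O_L from
        # COI; the cascade semantics are only defined for the
        # rearranged layout, so recoverability is not enforced
        return True
    planted = out.ground_truth["ol"][0]
    hp = detect_ol(out)
    if hp is None:
        return False
    overlaps = not (
        hp.end <= planted["start"] or hp.start >= planted["end"]
    )
    if not overlaps:
        return False
    if ol_abuts_coi:
        if hp.mode != planted["mode"]:
            return False
        if (
            planted["mode"] == "spacer_plus_trnaN_3prime"
            and hp.trnaN_bases_used != planted["trnaN_bases_used"]
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# Sequence-level DMNL degeneration
# ---------------------------------------------------------------------------

def evolve_degeneration(
    dimer_seq: AnnotatedSequence,
    config: DmnlVariantConfig,
    p: SynthParams,
) -> AnnotatedSequence:
    """Degenerate a realized canonical dimer per one DMNL variant.

    Surviving genes keep their sequence from ``dimer_seq``; every
    degenerated gene (and, in Type IV, the whole CR1) is truncated to
    a random contiguous slice of its own sequence — length sampled
    from ``p.spacer_len_range`` (``p.long_remnant_range`` for CRs),
    or zero with ``p.disappear_prob`` — so remnants are detectably
    homologous to their sources in principle, though tracing uses only
    position.  The tRNA-D translocation and optional tRNA-V shuffle
    are applied at sequence level.  ``ground_truth["spacers"]`` maps
    every locus to its true source gene(s) and remnant length.
    """
    arr = _tagged_arrangement(dimer_seq)
    canon_dimer = dimerize(canonical_teleost_order())
    if not arrangements_equal(arr, canon_dimer):
        raise ValueError("dimer_seq does not realize a canonical-order dimer")
    if config.d_timing == "before":
        raise ValueError(
            "pre-dimerization tRNA-D moves must be applied before "
            "synthesizing the dimer"
        )
    res = nonrandom_loss(arr, config)
    interim = res.final_with_spacers  # copy tags intact
    if config.d_timing == "after":
        d_tag = next(
            f.copy_tag for f in interim.features if f.name == "D"
        )
        interim = translocate(interim, "D", config.d_target, copy_tag=d_tag)
    if config.v_shuffle:
        v_tag = next(f.copy_tag for f in interim.features if f.name == "V")
        interim = translocate(interim, "V", ("16S", "L1"), copy_tag=v_tag)

    rng = np.random.default_rng([p.seed % (2**31), 917])
    chunks: list[str] = []
    recs: list[SeqFeatureRec] = []
    gt: dict = {"spacers": [], "config": config.type_label}
    pos = 0
    feats = list(interim.features)
    n = len(feats)

    def _neighbor(i: int, step: int) -> str:
        for s in range(1, n):
            g = feats[(i + s * step) % n]
            if g.category != "spacer":
                return g.name
        return "?"

    for i, f in enumerate(feats):
        if f.category == "spacer":
            source_name = "CR" if f.provenance == "CR" else f.provenance
            src = dimer_seq.feature(source_name, f.copy_tag)
            length = _spacer_length(rng, p, f.provenance)
            length = min(length, src.length)
            seq = ""
            if length:
                off = int(rng.integers(0, src.length - length + 1))
                seq = dimer_seq.feature_seq(src)[off : off + length]
                recs.append(
                    SeqFeatureRec(
                        "SPACER", "H", pos, pos + length, f.copy_tag, f.provenance
                    )
                )
            gt["spacers"].append(
                {
                    "locus": (_neighbor(i, -1), _neighbor(i, +1)),
                    "source": f.provenance,
                    "copy_tag": f.copy_tag,
                    "length": length,
                }
            )
        else:
            lookup = "CR" if f.category == "control" else f.name
            src = dimer_seq.feature(lookup, f.copy_tag)
            seq = dimer_seq.feature_seq(src)
            recs.append(
                SeqFeatureRec(f.name, f.strand, pos, pos + len(seq), "plain")
            )
        chunks.append(seq)
        pos += len(seq)
    return AnnotatedSequence(
        seq="".join(chunks), features=recs, ground_truth=gt
    )


def write_ground_truth(annotated: AnnotatedSequence, path) -> None:
    """Flatten ``ground_truth`` to dotted key = value lines.

    Lists become index-suffixed keys (``ol.0.mode``), tuples are
    comma-joined; the format is meant for diffing and spot checks, not
    round-tripping.
    """

    def _emit(fh, prefix: str, value) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                _emit(fh, f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(value, (list, tuple)) and any(
            isinstance(v, (dict, list, tuple)) for v in value
        ):
            for i, v in enumerate(value):
                _emit(fh, f"{prefix}.{i}", v)
        elif isinstance(value, (list, tuple)):
            fh.write(f"{prefix} = {','.join(str(v) for v in value)}\n")
        else:
            fh.write(f"{prefix} = {value}\n")

    with open(path, "w") as fh:
        fh.write("# generator ground truth\n")
        _emit(fh, "", annotated.ground_truth)


def _tagged_arrangement(annotated: AnnotatedSequence) -> GenomeArrangement:
    from .model import GeneFeature

    feats = [
        GeneFeature(f.name, strand=f.strand, copy_tag=f.copy_tag)
        for f in sorted(annotated.features, key=lambda f: f.start)
        if f.category != "spacer"
    ]
    return GenomeArrangement.from_features(feats, is_dimer=True)
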