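"""The Dimer-Mitogenome and Non-Random Loss (DMNL) engine.

The DMNL model explains genomic-scale mitochondrial rearrangement
without invoking many independent gene moves:

1. two monomer mitogenomes fuse head-to-tail into a circular dimer
   (74 genes, two control regions, two O_L loci);
2. transcription initiates at the four promoters (HSP/LSP in one CR,
   HSP'/LSP' in the other); H-strand transcripts terminate at the TAS
   of the next CR, L-strand transcripts at the first tRNA-L1 copy;
3. one CR's promoter pair loses function by mutation, so the genes it
   alone transcribed are no longer expressed;
4. every non-transcribed gene degenerates to a short intergenic spacer
   (or disappears), leaving a rearranged 37-gene monomer in which the
   light-strand genes form the contiguous 8-gene cluster
   Q-A-C-Y-S1-ND6-E-P;
5. exception: the tRNA-N copy adjacent to the surviving COI is
   retained instead of the transcription-expected N' copy, because the
   gene sits where the O_L stem-loop must form (see
   :mod:`dmnlkit.seqfeatures`).

The four observed bothid arrangement types differ only in control
region survival and in when/where tRNA-D is translocated; both are
parameterized by :class:`DmnlVariantConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .model import GenomeArrangement, GeneFeature
from .rearrange import translocate, shuffle_v

__all__ = [
    "Promoter",
    "TranscriptionUnit",
    "DmnlVariantConfig",
    "DmnlResult",
    "config_for_type",
    "read_config",
    "write_config",
    "default_promoters",
    "dimerize",
    "transcription_units",
    "nonrandom_loss",
    "run_dmnl",
]


@dataclass
class Promoter:
    """One of the four transcription promoters of the dimer."""

    id: str  # HSP | LSP | HSP_prime | LSP_prime
    strand: str  # H | L
    host_cr: int  # feature index of the hosting CR in the dimer
    functional: bool = True


@dataclass
class TranscriptionUnit:
    promoter_id: str
    strand: str
    covered: list[int]  # feature positions from promoter to terminator


@dataclass(frozen=True)
class DmnlVariantConfig:
    """Parameters selecting one of the four DMNL variants.

    ``lost_promoters`` names the promoter pair that loses function
    (the default is the pair of the first-copy CR; which physical CR
    loses function is a model assumption, not an observation).
    ``cr_mode`` controls control-region survival: ``retain_both``
    (Type III, both CRs persist), ``retain_one`` (Types I/II, the CR
    between tRNA-T and the L-strand cluster persists) or
    ``retain_one_full_loss`` (Type IV, that CR degenerates wholly and
    only the CR after tRNA-P remains).  ``d_timing`` is when tRNA-D
    translocates (``None`` = leave D where the loss process puts it);
    ``d_target`` is its destination adjacency in the final order.
    """

    type_label: str  # I | II | III | IV
    lost_promoters: frozenset[str] = frozenset({"HSP", "LSP"})
    cr_mode: str = "retain_one"
    d_timing: Optional[str] = "after"  # before | after | None
    d_target: tuple[str, str] = ("S1", "ND6")
    v_shuffle: bool = False

    def __post_init__(self):
        if self.type_label not in ("I", "II", "III", "IV"):
            raise ValueError(f"bad type_label {self.type_label!r}")
        if self.cr_mode not in (
            "retain_both",
            "retain_one",
            "retain_one_full_loss",
        ):
            raise ValueError(f"bad cr_mode {self.cr_mode!r}")
        if self.d_timing not in ("before", "after", None):
            raise ValueError(f"bad d_timing {self.d_timing!r}")
        if self.v_shuffle and self.type_label != "IV":
            raise ValueError("v_shuffle is only observed in Type IV")


def config_for_type(
    type_label: str,
    d_timing: Optional[str] = "after",
    v_shuffle: bool = False,
) -> DmnlVariantConfig:
    """Canonical config for each rearrangement type.

    Type I moves tRNA-D outside the L-strand cluster (between tRNA-T
    and the CR); Types II-IV move it inside, between S1 and ND6.
    """
    cr_mode = {
        "I": "retain_one",
        "II": "retain_one",
        "III": "retain_both",
        "IV": "retain_one_full_loss",
    }[type_label]
    d_target = ("T", "CR") if type_label == "I" else ("S1", "ND6")
    return DmnlVariantConfig(
        type_label=type_label,
        cr_mode=cr_mode,
        d_timing=d_timing,
        d_target=d_target,
        v_shuffle=v_shuffle,
    )


def write_config(config: DmnlVariantConfig, path) -> None:
    """Serialize a variant config as key = value lines."""
    with open(path, "w") as fh:
        fh.write("# DMNL variant configuration\n")
        fh.write(f"type_label = {config.type_label}\n")
        fh.write(
            "lost_promoters = "
            + ",".join(sorted(config.lost_promoters))
            + "\n"
        )
        fh.write(f"cr_mode = {config.cr_mode}\n")
        fh.write(f"d_timing = {config.d_timing or 'none'}\n")
        fh.write(f"d_target = {config.d_target[0]},{config.d_target[1]}\n")
        fh.write(f"v_shuffle = {'true' if config.v_shuffle else 'false'}\n")


def read_config(path) -> DmnlVariantConfig:
    """Parse a key = value variant-config file written by
    :func:`write_config` (order-insensitive; '#' comments allowed)."""
    fields: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    try:
        type_label = fields.pop("type_label")
    except KeyError:
        raise ValueError(f"{path}: missing required key 'type_label'")
    kwargs: dict = {"type_label": type_label}
    if "lost_promoters" in fields:
        kwargs["lost_promoters"] = frozenset(
            p.strip() for p in fields.pop("lost_promoters").split(",") if p.strip()
        )
    if "cr_mode" in fields:
        kwargs["cr_mode"] = fields.pop("cr_mode")
    if "d_timing" in fields:
        timing = fields.pop("d_timing")
        kwargs["d_timing"] = None if timing.lower() == "none" else timing
    if "d_target" in fields:
        parts = [p.strip() for p in fields.pop("d_target").split(",")]
        if len(parts) != 2:
            raise ValueError(f"{path}: d_target needs two comma-separated names")
        kwargs["d_target"] = (parts[0], parts[1])
    if "v_shuffle" in fields:
        kwargs["v_shuffle"] = fields.pop("v_shuffle").lower() in ("true", "1", "yes")
    if fields:
        raise ValueError(f"{path}: unknown keys {sorted(fields)}")
    return DmnlVariantConfig(**kwargs)


@dataclass
class DmnlResult:
    """Outcome of a DMNL run.

    ``final`` is the surviving 37-gene monomer with copy tags cleared;
    ``final_with_spacers`` additionally carries one provenance-tagged
    SPACER feature per degenerated gene at its residual locus;
    ``degenerated`` lists (label, (left, right)) of each lost gene and
    its final locus between surviving neighbors.
    """

    final: GenomeArrangement
    final_with_spacers: GenomeArrangement
    degenerated: list[tuple[str, tuple[str, str]]]
    event_log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def dimerize(a: GenomeArrangement) -> GenomeArrangement:
    """Fuse two copies of a monomer head-to-tail into a circular dimer.

    Copy 1 keeps ``copy_tag="plain"``; copy 2 becomes ``"prime"``.
    The order within each copy is preserved; the result has two CRs,
    two O_L loci and 74 genes.
    """
    if a.is_dimer:
        raise ValueError("input is already a dimer")
    n_cr = sum(1 for f in a.features if f.category == "control")
    if n_cr != 1:
        raise ValueError(f"monomer must contain exactly one CR, found {n_cr}")
    plain = [f.with_tag("plain") for f in a.features]
    prime = [f.with_tag("prime") for f in a.features]
    return dataclasses.replace(
        a, features=tuple(plain + prime), is_dimer=True
    ).canonicalized()


def default_promoters(dimer: GenomeArrangement) -> list[Promoter]:
    """The four promoters, assigned to the two CRs by copy tag."""
    promoters = []
    for i, f in enumerate(dimer.features):
        if f.category != "control":
            continue
        suffix = "" if f.copy_tag == "plain" else "_prime"
        promoters.append(Promoter(f"HSP{suffix}", "H", i))
        promoters.append(Promoter(f"LSP{suffix}", "L", i))
    if len(promoters) != 4:
        raise ValueError("dimer must contain exactly two CRs")
    return promoters


def transcription_units(
    dimer: GenomeArrangement, promoters: list[Promoter]
) -> list[TranscriptionUnit]:
    """Transcription spans of the functional promoters.

    H-strand units run forward from the host CR to the TAS of the next
    CR reached; L-strand units run backward to the first tRNA-L1 copy.
    A gene is transcribed iff it lies on the unit's strand within some
    functional unit's span.
    """
    n = len(dimer.features)
    units = []
    for p in promoters:
        if not p.functional:
            continue
        covered = []
        if p.strand == "H":
            stop = lambda f: f.category == "control"  # TAS sits in the CR
            step = +1
        else:
            stop = lambda f: f.name == "L1"
            step = -1
        i = p.host_cr
        for _ in range(n):
            i = (i + step) % n
            f = dimer.features[i]
            covered.append(i)
            if stop(f):
                break
        else:
            raise ValueError(f"no terminator reachable from {p.id}")
        units.append(TranscriptionUnit(p.id, p.strand, covered))
    return units


def _transcribed_positions(
    dimer: GenomeArrangement, units: list[TranscriptionUnit]
) -> set[int]:
    out: set[int] = set()
    for u in units:
        for i in u.covered:
            f = dimer.features[i]
            if f.is_gene and f.strand == u.strand:
                out.add(i)
    return out


def nonrandom_loss(
    dimer: GenomeArrangement, config: DmnlVariantConfig
) -> DmnlResult:
    """Degenerate every gene the surviving promoters do not transcribe.

    Applies the tRNA-N retention rule (the N copy immediately upstream
    of the surviving COI is kept regardless of transcription), keeps
    the O_L locus adjacent to the retained N, and resolves CR survival
    per ``config.cr_mode``.  Degenerated genes become provenance-tagged
    SPACER features in ``final_with_spacers`` and are absent from
    ``final``.
    """
    if not dimer.is_dimer:
        raise ValueError("nonrandom_loss requires a dimer")
    n = len(dimer.features)
    promoters = default_promoters(dimer)
    for p in promoters:
        p.functional = p.id not in config.lost_promoters
    units = transcription_units(dimer, [p for p in promoters if p.functional])
    transcribed = _transcribed_positions(dimer, units)
    log = [
        "lose-promoters: " + ", ".join(sorted(config.lost_promoters)),
        f"degenerate: {sum(1 for i in range(n) if dimer.features[i].is_gene) - len(transcribed)} genes not transcribed",
    ]

    surviving = set(transcribed)

    # tRNA-N retention: keep the N copy immediately upstream (H sense)
    # of the surviving COI copy; degenerate the other copy.
    coi = [i for i in surviving if dimer.features[i].name == "COI"]
    if len(coi) == 1:
        coi_idx = coi[0]
        for step in range(1, n):
            j = (coi_idx - step) % n
            f = dimer.features[j]
            if f.name == "N":
                retained_n = j
                break
        for i in range(n):
            if dimer.features[i].name == "N":
                if i == retained_n:
                    surviving.add(i)
                else:
                    surviving.discard(i)
        log.append(
            "retain tRNA-N copy adjacent to surviving COI "
            f"({dimer.features[retained_n].label()}), not the "
            "transcription-expected copy"
        )
        # O_L: the replication origin adjacent to the retained N persists.
        for i in range(n):
            if dimer.features[i].name == "OL":
                near_n = any(
                    dimer.features[(i - s) % n].name == "N"
                    and (i - s) % n == retained_n
                    for s in range(1, 4)
                )
                if near_n:
                    surviving.add(i)
                else:
                    surviving.discard(i)

    # Control regions
    cr_positions = [
        i for i, f in enumerate(dimer.features) if f.category == "control"
    ]

    def prev_surviving_gene(i: int) -> str:
        for step in range(1, n):
            j = (i - step) % n
            if j in surviving and dimer.features[j].is_gene:
                return dimer.features[j].name
        return "?"

    # The CR ending the surviving L-strand cluster (previous surviving
    # gene = tRNA-P) versus the CR closing the H-strand block.  Keying
    # on P is robust to tRNA-D having been pre-translocated near the
    # other CR.
    cr_after_p = [i for i in cr_positions if prev_surviving_gene(i) == "P"]
    cr_after_h = [i for i in cr_positions if i not in cr_after_p]
    if config.cr_mode == "retain_both":
        surviving.update(cr_positions)
    elif config.cr_mode == "retain_one":
        surviving.update(cr_after_h)
        log.append("retain CR between the H-strand block and the L-strand cluster")
    else:  # retain_one_full_loss (Type IV)
        surviving.update(cr_after_p)
        log.append("degenerate whole CR1; single CR remains after tRNA-P")

    # Build the post-loss arrangement: survivors in place, degenerated
    # genes as provenance-tagged spacers, the dropped CR (Types I/II)
    # removed outright (its sequence persists only as non-coding DNA,
    # which the order layer does not track as a gene remnant).
    feats: list[GeneFeature] = []
    for i, f in enumerate(dimer.features):
        if i in surviving:
            feats.append(f)
        elif f.is_gene or f.category == "control":
            # degenerated genes and CRs persist as residual non-coding
            # sequence; only the non-surviving O_L vanishes outright
            feats.append(
                GeneFeature(
                    "SPACER",
                    strand="H",
                    copy_tag=f.copy_tag,
                    provenance="CR" if f.category == "control" else f.name,
                )
            )
    interim = _relabel_crs(
        dataclasses.replace(
            dimer, features=tuple(feats), is_dimer=True
        ).canonicalized()
    )
    return DmnlResult(
        final=_strip(interim),
        final_with_spacers=interim,
        degenerated=_degenerated_loci(interim),
        event_log=log,
    )


def _strip(a: GenomeArrangement) -> GenomeArrangement:
    """Drop spacers, clear copy tags, return a plain monomer."""
    feats = tuple(
        f.with_tag("plain") for f in a.features if f.category != "spacer"
    )
    return dataclasses.replace(
        a, features=feats, is_dimer=False
    ).canonicalized()


def _degenerated_loci(
    a: GenomeArrangement,
) -> list[tuple[str, tuple[str, str]]]:
    """(source label, (left, right surviving neighbors)) per spacer."""
    n = len(a.features)
    out = []
    for i, f in enumerate(a.features):
        if f.category != "spacer":
            continue
        left = right = "?"
        for step in range(1, n):
            g = a.features[(i - step) % n]
            if g.category != "spacer":
                left = g.name
                break
        for step in range(1, n):
            g = a.features[(i + step) % n]
            if g.category != "spacer":
                right = g.name
                break
        label = f.provenance + ("'" if f.copy_tag == "prime" else "")
        out.append((label, (left, right)))
    return out


def _relabel_crs(a: GenomeArrangement) -> GenomeArrangement:
    """Name the two CRs of a two-CR arrangement CR1/CR2.

    CR1 is the copy directly upstream of the L-strand cluster (next
    gene tRNA-Q), matching the naming of the two large non-coding
    regions of Type III genomes.
    """
    controls = [i for i, f in enumerate(a.features) if f.category == "control"]
    if len(controls) != 2:
        return a
    feats = list(a.features)
    n = len(feats)

    def next_gene(i):
        for s in range(1, n):
            g = feats[(i + s) % n]
            if g.is_gene:
                return g.name
        return "?"

    for i in controls:
        new = "CR1" if next_gene(i) == "Q" else "CR2"
        feats[i] = dataclasses.replace(feats[i], name=new)
    return dataclasses.replace(a, features=tuple(feats))


def run_dmnl(
    start: GenomeArrangement, config: DmnlVariantConfig
) -> DmnlResult:
    """Run the full DMNL process from a monomeric gene order.

    Orchestrates: optional pre-dimerization tRNA-D translocation
    (``d_timing="before"``; the move lands between tRNA-T and tRNA-P so
    the Type I final order arises without a post-loss move), then
    dimerization, non-random loss, the optional post-loss tRNA-D
    translocation to ``config.d_target``, and the optional tRNA-V
    shuffle.  The result classifies as ``config.type_label``.
    """
    log: list[str] = []
    work = start
    if config.d_timing == "before":
        work = translocate(work, "D", ("T", "P"))
        log.append("translocate-D (before loss): between T and P")
    dimer = dimerize(work)
    log.append("dimerize: head-to-tail dimer, 74 genes, 2 CRs")
    res = nonrandom_loss(dimer, config)
    log.extend(res.event_log)
    # clear copy tags on survivors (observed genomes are untagged);
    # spacers keep their tag so provenance labels can mark prime copies
    interim = _untag_survivors(res.final_with_spacers)

    def d_at_target(arr: GenomeArrangement) -> bool:
        names = [f.name for f in arr.features if f.category != "spacer"]
        i = names.index("D")
        left = names[i - 1]
        right = names[(i + 1) % len(names)]
        want_l, want_r = config.d_target
        left_ok = left == want_l or (want_l == "CR" and left in ("CR", "CR1", "CR2"))
        right_ok = right == want_r or (want_r == "CR" and right in ("CR", "CR1", "CR2"))
        return left_ok and right_ok

    if config.d_timing == "after" or (
        config.d_timing == "before" and not d_at_target(interim)
    ):
        interim = translocate(interim, "D", config.d_target)
        log.append(
            f"translocate-D (after loss): between "
            f"{config.d_target[0]} and {config.d_target[1]}"
        )
    if config.v_shuffle:
        interim = shuffle_v(interim)
        log.append("shuffle-V: 12S-16S-V-L1")
    return DmnlResult(
        final=_strip(interim),
        final_with_spacers=interim,
        degenerated=_degenerated_loci(interim),
        event_log=log,
    )


def _untag_survivors(a: GenomeArrangement) -> GenomeArrangement:
    feats = tuple(
        f if f.category == "spacer" else f.with_tag("plain")
        for f in a.features
    )
    return dataclasses.replace(a, features=feats, is_dimer=False).canonicalized()
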