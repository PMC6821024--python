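"""Gene-movement operators and translocation-timing parsimony.

Bothid mitogenomes show only two of the three animal rearrangement
kinds — shuffling (a local move) and translocation (a long-range move);
no inversions.  Both are modeled here as single-gene moves on a
circular arrangement.  :func:`scenario_search` asks, for an observed
gene order, how many tRNA-D translocations are needed to reach it when
the move happens before versus after the non-random loss step, and
:func:`parsimony_verdict` turns the two counts into a timing call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .model import GenomeArrangement, GeneFeature, arrangements_equal

__all__ = [
    "RearrangementEvent",
    "ScenarioResult",
    "UNREACHABLE",
    "translocate",
    "shuffle_v",
    "scenario_search",
    "parsimony_verdict",
]

#: Sentinel event count for scenarios that cannot reach the observed order.
UNREACHABLE = float("inf")


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # "translocation" | "shuffling"
    gene: str
    from_locus: tuple[str, str]
    to_locus: tuple[str, str]

    def __str__(self) -> str:
        return (
            f"{self.kind} {self.gene}: "
            f"{self.from_locus[0]}|{self.from_locus[1]} -> "
            f"{self.to_locus[0]}|{self.to_locus[1]}"
        )


@dataclass
class ScenarioResult:
    """Minimal-event reconstruction for one tRNA-D timing."""

    timing: str  # "before" | "after"
    events: list[RearrangementEvent] = field(default_factory=list)
    event_count: float = UNREACHABLE
    reaches_observed: bool = False


def _nonspacer_positions(a: GenomeArrangement) -> list[int]:
    return [i for i, f in enumerate(a.features) if f.category != "spacer"]


def _neighbors(a: GenomeArrangement, idx: int) -> tuple[str, str]:
    """Names of the nearest non-spacer features either side of idx."""
    n = len(a.features)
    left = right = "?"
    for step in range(1, n):
        f = a.features[(idx - step) % n]
        if f.category != "spacer":
            left = f.name
            break
    for step in range(1, n):
        f = a.features[(idx + step) % n]
        if f.category != "spacer":
            right = f.name
            break
    return left, right


def translocate(
    a: GenomeArrangement,
    gene: str,
    to_locus: tuple[str, str],
    copy_tag: str = "plain",
) -> GenomeArrangement:
    """Move ``gene`` so it sits immediately after ``to_locus[0]``.

    ``to_locus`` is a (left, right) adjacency of non-spacer feature
    names; the gene is inserted directly after the left neighbor (any
    spacer remnants at the locus end up downstream of the moved gene).
    Strand is unchanged; all other adjacencies are preserved.
    """
    idx = a.index_of(gene, copy_tag)
    feat = a.features[idx]
    left_name, right_name = to_locus
    if left_name == gene or right_name == gene:
        raise ValueError(f"target locus {to_locus} lies inside {gene}")
    rest = list(a.features[:idx] + a.features[idx + 1 :])
    try:
        insert_after = next(
            i
            for i, f in enumerate(rest)
            if f.name == left_name and f.category != "spacer"
        )
    except StopIteration:
        raise ValueError(f"locus {to_locus}: {left_name!r} not in arrangement")
    # validate the adjacency: next non-spacer after left must be right
    n = len(rest)
    nxt = next(
        rest[(insert_after + s) % n].name
        for s in range(1, n + 1)
        if rest[(insert_after + s) % n].category != "spacer"
    )
    if nxt != right_name:
        raise ValueError(
            f"{left_name!r}|{right_name!r} is not an adjacency "
            f"(found {left_name!r}|{nxt!r})"
        )
    rest.insert(insert_after + 1, feat)
    return dataclasses.replace(a, features=tuple(rest)).canonicalized()


def shuffle_v(a: GenomeArrangement) -> GenomeArrangement:
    """Shuffle tRNA-V from between 12S and 16S to between 16S and L1.

    Requires the 12S-V-16S adjacency (possibly with spacers in
    between); produces the 12S-16S-V-L1 local order seen in
    *Asterorhombus intermedius*.
    """
    names = [f.name for f in a.features if f.category != "spacer"]
    try:
        i = names.index("12S")
    except ValueError:
        raise ValueError("12S-V-16S pattern absent") from None
    n = len(names)
    if not (names[(i + 1) % n] == "V" and names[(i + 2) % n] == "16S"):
        raise ValueError("12S-V-16S pattern absent")
    return translocate(a, "V", ("16S", "L1"))


# ---------------------------------------------------------------------------
# Timing parsimony for the tRNA-D translocation
# ---------------------------------------------------------------------------

def _adjacencies(a: GenomeArrangement, exclude_gene: str) -> list[tuple[str, str]]:
    """All (left, right) non-spacer adjacencies not involving exclude_gene."""
    names = [f.name for f in a.features if f.category != "spacer"]
    out = []
    n = len(names)
    for i in range(n):
        left, right = names[i], names[(i + 1) % n]
        if exclude_gene in (left, right):
            continue
        out.append((left, right))
    return out


def _search_moves(
    current: GenomeArrangement,
    observed: GenomeArrangement,
    gene: str,
    depth_left: int,
    events_so_far: list[RearrangementEvent],
) -> Optional[list[RearrangementEvent]]:
    """Depth-limited breadth-first search over insertion loci of one gene."""
    if arrangements_equal(current, observed):
        return list(events_so_far)
    if depth_left == 0:
        return None
    frontier: list[tuple[GenomeArrangement, list[RearrangementEvent]]] = [
        (current, list(events_so_far))
    ]
    for _depth in range(depth_left):
        nxt: list[tuple[GenomeArrangement, list[RearrangementEvent]]] = []
        for arr, evs in frontier:
            idx = arr.index_of(gene)
            from_locus = _neighbors(arr, idx)
            for locus in _adjacencies(arr, gene):
                moved = translocate(arr, gene, locus)
                ev = RearrangementEvent("translocation", gene, from_locus, locus)
                if arrangements_equal(moved, observed):
                    return evs + [ev]
                nxt.append((moved, evs + [ev]))
        frontier = nxt
    return None


def scenario_search(
    observed: GenomeArrangement,
    config,
    max_events: int = 3,
) -> list[ScenarioResult]:
    """Minimal tRNA-D translocation scenarios for both timings.

    For timing "after", the non-random loss runs on the unmodified
    ancestral order and tRNA-D is moved afterwards; for timing
    "before", tRNA-D is first moved in the monomer (one event), the
    loss process runs, and further post-loss moves may follow.  Only
    tRNA-D translocations are counted; dimerization, promoter loss,
    degeneration and the tRNA-V shuffle are steps of the loss model
    itself, not rearrangement events.

    Returns one :class:`ScenarioResult` per timing with the minimal
    event count (``event_count`` is the ``UNREACHABLE`` sentinel when
    the observed order cannot be reached within ``max_events``).
    """
    from .dmnl import run_dmnl  # local import to avoid a module cycle
    from .model import canonical_teleost_order

    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    canonical = canonical_teleost_order()
    results = []

    # -- after: loss first, then 0..max_events D moves
    base_cfg = dataclasses.replace(config, d_timing=None)
    res_after = run_dmnl(canonical, base_cfg)
    found = _search_moves(res_after.final, observed, "D", max_events, [])
    after = ScenarioResult(timing="after")
    if found is not None:
        after.events = found
        after.event_count = len(found)
        after.reaches_observed = True
    results.append(after)

    # -- before: one pre-dimerization D move, then loss, then 0..max-1 more.
    # Iterative deepening over the total event count guarantees minimality.
    d_idx = canonical.index_of("D")
    d_from = _neighbors(canonical, d_idx)
    pre_runs: list[tuple[RearrangementEvent, GenomeArrangement]] = []
    for locus in _adjacencies(canonical, "D"):
        pre = translocate(canonical, "D", locus)
        try:
            res = run_dmnl(pre, base_cfg)
        except ValueError:
            # e.g. D parked inside 12S-V-16S blocks the tRNA-V shuffle
            continue
        pre_ev = RearrangementEvent("translocation", "D", d_from, locus)
        pre_runs.append((pre_ev, res.final))
    best: Optional[list[RearrangementEvent]] = None
    for total in range(1, max_events + 1):
        for pre_ev, final in pre_runs:
            found = _search_moves(final, observed, "D", total - 1, [pre_ev])
            if found is not None:
                best = found
                break
        if best is not None:
            break
    before = ScenarioResult(timing="before")
    if best is not None:
        before.events = best
        before.event_count = len(best)
        before.reaches_observed = True
    results.append(before)
    return results


def parsimony_verdict(results: list[ScenarioResult]) -> str:
    """Compare before/after minimal counts: "after", "before", "tie" or
    "unresolved" (both timings unreachable)."""
    by_timing = {r.timing: r for r in results}
    a = by_timing["after"].event_count
    b = by_timing["before"].event_count
    if a == UNREACHABLE and b == UNREACHABLE:
        return "unresolved"
    if a < b:
        return "after"
    if b < a:
        return "before"
    return "tie"
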