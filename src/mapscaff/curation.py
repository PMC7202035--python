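"""Detect and correct misassembled scaffolds from genetic-map evidence.

A scaffold whose physical regions map to different linkage groups (or to
genetically distant positions on one group) is a chimera candidate; the
A–B–A pattern — concordant outer regions flanking a foreign inner region —
is a nested misassembly.  Correction is deliberately conservative: a
scaffold is only ever split inside an inter-contig N gap, never inside a
contig.  When the conflict interval contains no gap the event stays
unresolved and the scaffold is merely flagged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .anchoring import PhysicalRegion
from .assembly_model import AssemblySeq, ContigInterval
from ._util import round_half_up

INTERCHROMOSOMAL = "interchromosomal"
INTRACHROMOSOMAL_DISTANT = "intrachromosomal_distant"
NESTED = "nested"


@dataclass(frozen=True)
class ChimeraEvent:
    scaffold_id: str
    kind: str
    left_region: PhysicalRegion
    right_region: PhysicalRegion
    inner_region: PhysicalRegion | None = None
    search_intervals: tuple[tuple[int, int], ...] = ()
    resolved: bool = False
    split_gaps: tuple[tuple[int, int], ...] = ()

    @property
    def split_positions(self) -> list[int]:
        return [g[0] for g in self.split_gaps]


def _conflicting(a: PhysicalRegion, b: PhysicalRegion, max_cM_span: float) -> str | None:
    if a.linkage_group != b.linkage_group:
        return INTERCHROMOSOMAL
    if abs(b.cM_mid - a.cM_mid) > max_cM_span:
        return INTRACHROMOSOMAL_DISTANT
    return None


def detect_chimeras(regions: Sequence[PhysicalRegion],
                    max_cM_span: float = 20.0) -> list[ChimeraEvent]:
    """Scan each scaffold's ordered regions for misassembly signatures.

    Nested events (A–B–A with concordant outer regions) are recognised
    first and consume their inner region; remaining adjacent conflicting
    pairs become interchromosomal or distant intrachromosomal events.
    """
    by_scaf: dict[str, list[PhysicalRegion]] = defaultdict(list)
    for r in regions:
        by_scaf[r.scaffold_id].append(r)
    events: list[ChimeraEvent] = []
    for sid in sorted(by_scaf):
        rs = sorted(by_scaf[sid], key=lambda r: r.start)
        inner_consumed: set[int] = set()
        i = 0
        while i <= len(rs) - 3:
            a, b, c = rs[i], rs[i + 1], rs[i + 2]
            outer_ok = _conflicting(a, c, max_cM_span) is None
            inner_bad = _conflicting(a, b, max_cM_span) is not None
            if outer_ok and inner_bad:
                events.append(ChimeraEvent(
                    sid, NESTED, a, c, inner_region=b,
                    search_intervals=((a.end, b.start), (b.end, c.start))))
                inner_consumed.add(i + 1)
                i += 2
            else:
                i += 1
        for j in range(len(rs) - 1):
            if j in inner_consumed or j + 1 in inner_consumed:
                continue
            kind = _conflicting(rs[j], rs[j + 1], max_cM_span)
            if kind is not None:
                events.append(ChimeraEvent(
                    sid, kind, rs[j], rs[j + 1],
                    search_intervals=((rs[j].end, rs[j + 1].start),)))
    return events


def resolve_breakpoint(event: ChimeraEvent,
                       contigs: Sequence[ContigInterval]) -> ChimeraEvent:
    """Pick, per search interval, the inter-contig gap nearest its midpoint.

    All intervals must contain a gap for the event to resolve; a gap-free
    interval leaves the event unresolved (the scaffold is flagged, never
    cut inside a contig).
    """
    gaps = [(a.end, b.start) for a, b in zip(contigs, contigs[1:])]
    chosen: list[tuple[int, int]] = []
    for lo, hi in event.search_intervals:
        mid = (lo + hi) / 2.0
        candidates = [g for g in gaps if g[1] > lo and g[0] < hi]
        if not candidates:
            return replace(event, resolved=False, split_gaps=())
        best = min(candidates, key=lambda g: abs((g[0] + g[1]) / 2.0 - mid))
        chosen.append(best)
    return replace(event, resolved=True, split_gaps=tuple(chosen))


def apply_splits(assembly: Sequence[AssemblySeq],
                 events: Sequence[ChimeraEvent],
                 ) -> tuple[list[AssemblySeq], list[dict]]:
    """Split scaffolds at their resolved gaps; returns (assembly, provenance).

    A scaffold with k split gaps becomes k+1 children named ``<id>.1`` ..
    ``<id>.k+1``; the N gap at each cut is removed from both children, so
    non-N bases are conserved exactly.  A nested event's two cuts excise
    the inner segment as its own child, free to re-enter anchoring.
    Provenance rows map every child back to its parent interval.
    """
    cuts: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for e in events:
        if e.resolved:
            cuts[e.scaffold_id].extend(e.split_gaps)
    out: list[AssemblySeq] = []
    provenance: list[dict] = []
    for s in assembly:
        if s.id not in cuts:
            out.append(s)
            continue
        gaps = sorted(set(cuts[s.id]))
        for (a1, b1), (a2, b2) in zip(gaps, gaps[1:]):
            if b1 > a2:
                raise ValueError(f"overlapping split gaps on {s.id}: "
                                 f"({a1},{b1}) and ({a2},{b2})")
        bounds = [0] + [x for g in gaps for x in g] + [len(s.seq)]
        child_no = 0
        for lo, hi in zip(bounds[0::2], bounds[1::2]):
            if hi <= lo:
                continue
            child_no += 1
            cid = f"{s.id}.{child_no}"
            out.append(AssemblySeq(cid, s.seq[lo:hi]))
            provenance.append({"child": cid, "parent": s.id,
                               "parent_start": lo, "parent_end": hi,
                               "strand": "+"})
    return out, provenance


def chimeric_fraction(labels: Mapping[str, Iterable[str]]) -> float:
    """Percent of sequences whose reference hits span >= 2 chromosomes.

    ``labels`` maps each sequence id to the chromosome labels of its hits;
    sequences with at least one hit form the denominator.
    """
    with_hits = {sid: set(chroms) for sid, chroms in
                 ((sid, list(chroms)) for sid, chroms in labels.items())
                 if chroms}
    if not with_hits:
        raise ValueError("no sequences with labeled hits")
    multi = sum(1 for chroms in with_hits.values() if len(chroms) >= 2)
    return round_half_up(100.0 * multi / len(with_hits), 1)


def events_tsv(events: Sequence[ChimeraEvent]) -> str:
    lines = ["scaffold\tkind\tleft_group\tleft_cM\tright_group\tright_cM\t"
             "search_intervals\tresolved\tsplit_positions"]
    for e in events:
        ivals = ";".join(f"{a + 1}-{b}" for a, b in e.search_intervals)
        splits = ";".join(str(p + 1) for p in e.split_positions) or "-"
        lines.append(f"{e.scaffold_id}\t{e.kind}\t"
                     f"{e.left_region.linkage_group}\t{e.left_region.cM_mid:g}\t"
                     f"{e.right_region.linkage_group}\t{e.right_region.cM_mid:g}\t"
                     f"{ivals}\t{str(e.resolved).lower()}\t{splits}")
    return "\n".join(lines) + "\n"


def provenance_tsv(rows: Sequence[dict]) -> str:
    lines = ["child\tparent\tparent_start\tparent_end\tstrand"]
    for r in rows:
        lines.append(f"{r['child']}\t{r['parent']}\t{r['parent_start'] + 1}\t"
                     f"{r['parent_end']}\t{r['strand']}")
    return "\n".join(lines) + "\n"
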