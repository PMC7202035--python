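"""Anchor scaffolds to chromosomes from marker placements.

The pipeline stage between marker placement and pseudomolecule building:

1. :func:`filter_inconsistent_markers` — drop locally discordant placements
   (pairs closer than 1 kb whose genetic order contradicts the scaffold's
   physical trend), iterated to a fixpoint.
2. :func:`cluster_regions` — group a scaffold's placements into *physical
   regions*: maximal runs that stay on one linkage group with bounded
   physical gaps and bounded genetic jumps.  Regions are the unit of
   reliability filtering and of chimera logic.
3. :func:`filter_regions` — discard single-marker regions and regions
   shorter than 1 kb.
4. :func:`assign_chromosome` / :func:`orient_scaffold` /
   :func:`order_chromosome` — majority-support chromosome call, rank
   correlation orientation, and genetic-position ordering.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genetic_map import GeneticMarker, MarkerPlacement

UNANCHORED = "UNANCHORED"


@dataclass(frozen=True)
class PhysicalRegion:
    """A run of mutually consistent placements on one scaffold."""

    scaffold_id: str
    start: int
    end: int
    linkage_group: str
    cM_min: float
    cM_max: float
    cM_mid: float
    marker_ids: tuple[str, ...]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold_id: str
    chromosome: str               # linkage group, or UNANCHORED
    order_key: float              # weighted median cM along the chromosome
    orientation: str              # '+', '-' or 'unknown'
    supporting_markers: int
    conflict_flag: bool


def _marker_lookup(markers: Sequence[GeneticMarker]) -> dict[str, GeneticMarker]:
    return {m.id: m for m in markers}


def _by_scaffold(placements: Sequence[MarkerPlacement],
                 ) -> dict[str, list[MarkerPlacement]]:
    out: dict[str, list[MarkerPlacement]] = defaultdict(list)
    for p in placements:
        out[p.scaffold_id].append(p)
    for sid in out:
        out[sid].sort(key=lambda p: (p.position, p.marker_id))
    return out


def _trend_sign(pls: Sequence[MarkerPlacement],
                mk: Mapping[str, GeneticMarker]) -> int:
    """Sign of the Kendall correlation between bp and cM (0 if undecided)."""
    pos = [p.position for p in pls]
    cm = [mk[p.marker_id].genetic_pos for p in pls]
    if len(set(cm)) < 2 or len(set(pos)) < 2:
        return 0
    tau = stats.kendalltau(pos, cm).statistic
    if not np.isfinite(tau) or tau == 0:
        return 0
    return 1 if tau > 0 else -1


def filter_inconsistent_markers(placements: Sequence[MarkerPlacement],
                                markers: Sequence[GeneticMarker],
                                window: int = 1000,
                                ) -> tuple[list[MarkerPlacement], list[MarkerPlacement]]:
    """Drop placements in local physical/genetic order conflicts.

    Within each scaffold, a pair of same-linkage-group placements closer
    than ``window`` bp conflicts when the sign of (Δposition × ΔcM) opposes
    the scaffold's dominant trend (a reverse-oriented scaffold has a
    uniformly negative trend, which is order, not conflict).  The
    lower-confidence member — fewer trend-concordant neighbours, then lower
    identity, then the later id — is removed, and the rule is re-applied
    until no conflict remains.
    """
    mk = _marker_lookup(markers)
    kept = list(placements)
    discarded: list[MarkerPlacement] = []
    while True:
        by_scaf = _by_scaffold(kept)
        to_drop: set[str] = set()
        for pls in by_scaf.values():
            groups: dict[str, list[MarkerPlacement]] = defaultdict(list)
            for p in pls:
                groups[mk[p.marker_id].linkage_group].append(p)
            for gp in groups.values():
                trend = _trend_sign(gp, mk)
                if trend == 0:
                    trend = 1  # no dominant direction: read as forward
                concord = {p.marker_id: 0 for p in gp}
                conflicts: list[tuple[MarkerPlacement, MarkerPlacement]] = []
                for i in range(len(gp)):
                    for j in range(i + 1, len(gp)):
                        a, b = gp[i], gp[j]
                        dcm = mk[b.marker_id].genetic_pos - mk[a.marker_id].genetic_pos
                        dpos = b.position - a.position
                        s = np.sign(dcm) * np.sign(dpos) * trend
                        if s > 0:
                            concord[a.marker_id] += 1
                            concord[b.marker_id] += 1
                        elif s < 0 and abs(dpos) < window:
                            conflicts.append((a, b))
                for a, b in conflicts:
                    if a.marker_id in to_drop or b.marker_id in to_drop:
                        continue
                    loser = min(
                        (a, b),
                        key=lambda p: (concord[p.marker_id], p.identity,
                                       # later ids lose ties
                                       tuple(-ord(c) for c in p.marker_id)),
                    )
                    to_drop.add(loser.marker_id)
        if not to_drop:
            return kept, discarded
        discarded.extend(p for p in kept if p.marker_id in to_drop)
        kept = [p for p in kept if p.marker_id not in to_drop]


def cluster_regions(placements: Sequence[MarkerPlacement],
                    markers: Sequence[GeneticMarker],
                    max_phys_gap: int = 500_000,
                    max_cM_jump: float = 5.0) -> list[PhysicalRegion]:
    """Scan each scaffold's placements into physical regions.

    A new region starts when the linkage group changes, the physical gap to
    the previous marker exceeds ``max_phys_gap`` bp, or the genetic jump
    exceeds ``max_cM_jump`` cM.
    """
    mk = _marker_lookup(markers)
    regions: list[PhysicalRegion] = []

    def flush(sid: str, run: list[MarkerPlacement]) -> None:
        cms = [mk[p.marker_id].genetic_pos for p in run]
        regions.append(PhysicalRegion(
            sid, run[0].position, run[-1].position,
            mk[run[0].marker_id].linkage_group,
            min(cms), max(cms), float(np.median(cms)),
            tuple(p.marker_id for p in run)))

    for sid, pls in sorted(_by_scaffold(placements).items()):
        run: list[MarkerPlacement] = []
        for p in pls:
            if run:
                prev = run[-1]
                new_group = mk[p.marker_id].linkage_group != mk[prev.marker_id].linkage_group
                far = p.position - prev.position > max_phys_gap
                jump = abs(mk[p.marker_id].genetic_pos
                           - mk[prev.marker_id].genetic_pos) > max_cM_jump
                if new_group or far or jump:
                    flush(sid, run)
                    run = []
            run.append(p)
        if run:
            flush(sid, run)
    return regions


def filter_regions(regions: Sequence[PhysicalRegion],
                   min_markers: int = 2, min_len: int = 1000,
                   ) -> tuple[list[PhysicalRegion], list[PhysicalRegion]]:
    """Drop single-marker regions and regions spanning < ``min_len`` bp."""
    kept, dropped = [], []
    for r in regions:
        if r.n_markers < min_markers or r.length < min_len:
            dropped.append(r)
        else:
            kept.append(r)
    return kept, dropped


def _weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if cum[idx] == half and idx + 1 < len(v):
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


def assign_chromosome(scaffold_id: str, regions: Sequence[PhysicalRegion],
                      ) -> ScaffoldAssignment:
    """Majority-marker-support chromosome call for one scaffold.

    Ties between linkage groups, or fewer than two supporting markers,
    leave the scaffold unanchored; any minority-group region raises the
    conflict flag (a chimera candidate for curation).
    """
    support: dict[str, int] = defaultdict(int)
    for r in regions:
        support[r.linkage_group] += r.n_markers
    best = max(support.values())
    winners = sorted(g for g, n in support.items() if n == best)
    conflict = len(support) > 1
    if len(winners) > 1:
        return ScaffoldAssignment(scaffold_id, UNANCHORED, float("nan"),
                                  "unknown", 0, True)
    chrom = winners[0]
    own = [r for r in regions if r.linkage_group == chrom]
    n_support = sum(r.n_markers for r in own)
    if n_support < 2:
        return ScaffoldAssignment(scaffold_id, UNANCHORED, float("nan"),
                                  "unknown", n_support, conflict)
    key = _weighted_median([r.cM_mid for r in own],
                           [r.n_markers for r in own])
    return ScaffoldAssignment(scaffold_id, chrom, key, "unknown",
                              n_support, conflict)


def orient_scaffold(placements: Sequence[MarkerPlacement],
                    markers: Sequence[GeneticMarker]) -> str:
    """Orientation from the rank correlation of bp against cM.

    '+' when cM increases with position, '-' when it decreases; 'unknown'
    with fewer than two distinct cM values or a zero correlation.
    """
    if len(placements) < 2:
        return "unknown"
    mk = _marker_lookup(markers)
    sign = _trend_sign(sorted(placements, key=lambda p: p.position), mk)
    return {1: "+", -1: "-", 0: "unknown"}[sign]


def assign_scaffolds(regions: Sequence[PhysicalRegion],
                     placements: Sequence[MarkerPlacement],
                     markers: Sequence[GeneticMarker],
                     ) -> list[ScaffoldAssignment]:
    """Assign and orient every scaffold that has at least one kept region.

    Orientation uses only the placements of markers belonging to the
    winning chromosome's regions.
    """
    by_scaf: dict[str, list[PhysicalRegion]] = defaultdict(list)
    for r in regions:
        by_scaf[r.scaffold_id].append(r)
    pl_by_id = {p.marker_id: p for p in placements}
    out: list[ScaffoldAssignment] = []
    for sid in sorted(by_scaf):
        a = assign_chromosome(sid, by_scaf[sid])
        if a.chromosome != UNANCHORED:
            own = [pl_by_id[m] for r in by_scaf[sid]
                   if r.linkage_group == a.chromosome
                   for m in r.marker_ids if m in pl_by_id]
            a = replace(a, orientation=orient_scaffold(own, markers))
        out.append(a)
    return out


def order_chromosome(assignments: Sequence[ScaffoldAssignment],
                     scaffold_lengths: Mapping[str, int],
                     ) -> dict[str, list[ScaffoldAssignment]]:
    """Deterministic per-chromosome ordering by genetic position.

    Ascending order key; ties broken by descending scaffold length, then
    lexicographic id.  Unanchored scaffolds are excluded.
    """
    out: dict[str, list[ScaffoldAssignment]] = defaultdict(list)
    for a in assignments:
        if a.chromosome != UNANCHORED:
            out[a.chromosome].append(a)
    for chrom in out:
        out[chrom].sort(key=lambda a: (a.order_key,
                                       -scaffold_lengths[a.scaffold_id],
                                       a.scaffold_id))
    return dict(sorted(out.items()))


def regions_tsv(kept: Sequence[PhysicalRegion],
                dropped: Sequence[PhysicalRegion] = ()) -> str:
    lines = ["scaffold\tstart\tend\tgroup\tcM_min\tcM_max\tn_markers\tkept"]
    for flag, rs in (("yes", kept), ("no", dropped)):
        for r in rs:
            lines.append(f"{r.scaffold_id}\t{r.start + 1}\t{r.end + 1}\t"
                         f"{r.linkage_group}\t{r.cM_min:g}\t{r.cM_max:g}\t"
                         f"{r.n_markers}\t{flag}")
    return "\n".join(lines) + "\n"


def assignments_tsv(ordered: Mapping[str, Sequence[ScaffoldAssignment]],
                    unanchored: Sequence[ScaffoldAssignment] = ()) -> str:
    lines = ["scaffold\tchromosome\torder_index\torientation\tn_markers\tflags"]
    for chrom, assigns in ordered.items():
        for i, a in enumerate(assigns):
            flags = "conflict" if a.conflict_flag else "-"
            lines.append(f"{a.scaffold_id}\t{chrom}\t{i}\t{a.orientation}\t"
                         f"{a.supporting_markers}\t{flags}")
    for a in unanchored:
        flags = "conflict" if a.conflict_flag else "-"
        lines.append(f"{a.scaffold_id}\t{UNANCHORED}\t-\t{a.orientation}\t"
                     f"{a.supporting_markers}\t{flags}")
    return "\n".join(lines) + "\n"
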