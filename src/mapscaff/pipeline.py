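"""End-to-end convenience drivers composing the pipeline stages.

These wrappers exist for scripts and the CLI; each stage remains
independently usable and tested through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import anchoring, curation, genetic_map, pseudomolecule
from .assembly_model import AssemblySeq, segment_contigs


@dataclass
class AnchorResult:
    placements: list
    orphans: list[str]
    discarded: list
    regions_kept: list
    regions_dropped: list
    assignments: list
    ordered: dict[str, list]
    unanchored: list = field(default_factory=list)


def anchor_assembly(assembly: Sequence[AssemblySeq],
                    markers: Sequence[genetic_map.GeneticMarker],
                    min_identity: float = 90.0, min_coverage: float = 90.0,
                    seed_k: int = 15, window: int = 1000,
                    max_phys_gap: int = 500_000, max_cM_jump: float = 5.0,
                    min_markers: int = 2, min_len: int = 1000,
                    placements: Sequence[genetic_map.MarkerPlacement] | None = None,
                    orphans: Sequence[str] | None = None,
                    ) -> AnchorResult:
    """Place markers (unless given), filter, cluster, assign and order."""
    if placements is None:
        placements, orphans = genetic_map.place_markers(
            markers, assembly, min_identity, min_coverage, seed_k)
    kept_pl, discarded = anchoring.filter_inconsistent_markers(
        placements, markers, window)
    regions = anchoring.cluster_regions(kept_pl, markers,
                                        max_phys_gap, max_cM_jump)
    regions_kept, regions_dropped = anchoring.filter_regions(
        regions, min_markers, min_len)
    assignments = anchoring.assign_scaffolds(regions_kept, kept_pl, markers)
    lengths = {s.id: s.length for s in assembly}
    ordered = anchoring.order_chromosome(assignments, lengths)
    unanchored = [a for a in assignments
                  if a.chromosome == anchoring.UNANCHORED]
    return AnchorResult(list(placements), list(orphans or []), discarded,
                        regions_kept, regions_dropped, assignments, ordered,
                        unanchored)


def curate_assembly(assembly: Sequence[AssemblySeq],
                    regions: Sequence[anchoring.PhysicalRegion],
                    max_cM_span: float = 20.0, min_gap_run: int = 10,
                    ) -> tuple[list[AssemblySeq], list[curation.ChimeraEvent], list[dict]]:
    """Detect chimeras, resolve breakpoints at gaps and split."""
    events = curation.detect_chimeras(regions, max_cM_span)
    contigs = {s.id: segment_contigs(s, min_gap_run) for s in assembly}
    resolved = [curation.resolve_breakpoint(e, contigs[e.scaffold_id])
                for e in events]
    new_assembly, provenance = curation.apply_splits(assembly, resolved)
    return new_assembly, resolved, provenance


def build_from_anchoring(assembly: Sequence[AssemblySeq],
                         result: AnchorResult, gap_len: int = 100,
                         ) -> tuple[list[pseudomolecule.ChromosomeBuild], list[str]]:
    return pseudomolecule.build_pseudomolecules(assembly, result.ordered,
                                                gap_len)
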