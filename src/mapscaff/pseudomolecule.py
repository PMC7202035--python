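"""Build chromosome pseudomolecules and emit/parse AGP 2.1 layouts.

A pseudomolecule is the ordered, oriented concatenation of a chromosome's
anchored scaffolds, joined by fixed-length N spacers; everything left over
is concatenated (longest first) into a single ``chrUn``.  The AGP file is
the authoritative description of the layout: rebuilding each object from
the AGP plus the component FASTA reproduces the emitted sequence
bit-exactly, and :func:`read_agp` validates coordinate continuity while
doing so.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .anchoring import ScaffoldAssignment, UNANCHORED
from .assembly_model import AssemblySeq, reverse_complement

UNANCHORED_OBJECT = "chrUn"


@dataclass(frozen=True)
class ChromosomeBuild:
    chromosome: str
    components: tuple[tuple[str, str], ...]   # (scaffold_id, orientation)
    gap_len: int
    sequence: str
    agp_rows: tuple[tuple, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


def _chrom_name(label: str, prefix: str = "chr", pad: int = 2) -> str:
    """chr-style object name: numeric labels are zero-padded."""
    m = re.fullmatch(r"(?:chr)?0*(\d+)", str(label))
    if m:
        return f"{prefix}{int(m.group(1)):0{pad}d}"
    return str(label)


def _build_one(name: str, parts: Sequence[tuple[str, str]],
               seqs: Mapping[str, str], gap_len: int) -> ChromosomeBuild:
    pieces: list[str] = []
    rows: list[tuple] = []
    pos = 0  # 0-based running object coordinate
    for i, (sid, orient) in enumerate(parts):
        if i > 0:
            rows.append((name, pos + 1, pos + gap_len, len(rows) + 1, "U",
                         gap_len, "scaffold", "yes", "map"))
            pieces.append("N" * gap_len)
            pos += gap_len
        seq = seqs[sid]
        emitted = "-" if orient == "-" else "+"
        pieces.append(reverse_complement(seq) if emitted == "-" else seq)
        rows.append((name, pos + 1, pos + len(seq), len(rows) + 1, "W",
                     sid, 1, len(seq), emitted))
        pos += len(seq)
    return ChromosomeBuild(name, tuple(parts), gap_len, "".join(pieces),
                           tuple(rows))


def build_pseudomolecules(assembly: Sequence[AssemblySeq],
                          ordered: Mapping[str, Sequence[ScaffoldAssignment]],
                          gap_len: int = 100,
                          chr_prefix: str = "chr",
                          ) -> tuple[list[ChromosomeBuild], list[str]]:
    """Assemble pseudomolecules plus one concatenated unanchored object.

    ``ordered`` maps each chromosome to its ordered assignments (as
    produced by :func:`mapscaff.anchoring.order_chromosome`).  Every
    scaffold must be used at most once; scaffolds referenced nowhere are
    pooled, longest first, into ``chrUn``.  Components with orientation
    ``-`` are reverse-complemented; unknown orientations are emitted as
    ``+`` and reported in the returned flag list.

    Returns (builds, unknown-orientation scaffold ids).
    """
    seqs = {s.id: s.seq for s in assembly}
    used: set[str] = set()
    unknown_flags: list[str] = []
    builds: list[ChromosomeBuild] = []
    for chrom in ordered:
        parts: list[tuple[str, str]] = []
        for a in ordered[chrom]:
            sid = a.scaffold_id
            if sid in used:
                raise ValueError(f"scaffold {sid!r} referenced more than once")
            if sid not in seqs:
                raise ValueError(f"scaffold {sid!r} not present in assembly")
            used.add(sid)
            if a.orientation == "unknown":
                unknown_flags.append(sid)
            parts.append((sid, a.orientation if a.orientation == "-" else "+"))
        builds.append(_build_one(_chrom_name(chrom, chr_prefix), parts,
                                 seqs, gap_len))
    leftover = sorted((s for s in assembly if s.id not in used),
                      key=lambda s: (-s.length, s.id))
    if leftover:
        builds.append(_build_one(UNANCHORED_OBJECT,
                                 [(s.id, "+") for s in leftover],
                                 seqs, gap_len))
    return builds, unknown_flags


def write_agp(builds: Sequence[ChromosomeBuild]) -> str:
    """Serialize builds as AGP v2.1 (1-based inclusive coordinates)."""
    lines = ["##agp-version\t2.1"]
    for b in builds:
        for row in b.agp_rows:
            lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"


def read_agp(text: str, components: Mapping[str, str] | Sequence[AssemblySeq],
             ) -> dict[str, str]:
    """Rebuild object sequences from AGP text plus component sequences.

    Validates that object coordinates abut exactly and that W-row spans
    match their component lengths; errors name the offending row number.
    """
    if not isinstance(components, Mapping):
        components = {s.id: s.seq for s in components}
    objects: dict[str, list[str]] = {}
    expect_pos: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise ValueError(f"AGP row {lineno}: expected 9 columns, got {len(f)}")
        obj, beg, end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
        nxt = expect_pos.get(obj, 1)
        if beg != nxt:
            raise ValueError(f"AGP row {lineno}: object {obj!r} coordinate "
                             f"skip (expected {nxt}, found {beg})")
        if end < beg:
            raise ValueError(f"AGP row {lineno}: end before begin")
        if ctype == "W":
            cid, cbeg, cend, orient = f[5], int(f[6]), int(f[7]), f[8]
            if cid not in components:
                raise ValueError(f"AGP row {lineno}: unknown component {cid!r}")
            seq = components[cid][cbeg - 1:cend]
            if len(seq) != end - beg + 1:
                raise ValueError(f"AGP row {lineno}: component span "
                                 f"{len(seq)} != object span {end - beg + 1}")
            if orient == "-":
                seq = reverse_complement(seq)
            objects.setdefault(obj, []).append(seq)
        elif ctype in ("U", "N"):
            gap_len = int(f[5])
            if gap_len != end - beg + 1:
                raise ValueError(f"AGP row {lineno}: gap length {gap_len} != "
                                 f"object span {end - beg + 1}")
            objects.setdefault(obj, []).append("N" * gap_len)
        else:
            raise ValueError(f"AGP row {lineno}: unsupported component type "
                             f"{ctype!r}")
        expect_pos[obj] = end + 1
    return {obj: "".join(parts) for obj, parts in objects.items()}
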