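"""Genetic map model and placement of marker tag sequences on scaffolds.

A genetic map is a table of markers, each with a linkage group (chromosome
label), a genetic position in centimorgans and, optionally, a short tag
sequence — the genomic context of a GBS/SNP marker.  Placement locates each
tag on the draft assembly, either by an internal exact-k-mer-seed /
ungapped-extension search (:func:`place_markers`) or by ingesting
BLAST-style tabular hits (:func:`load_placements`).  Both paths apply the
same identity/coverage thresholds (>=90/90 by default) and the same strict
best-hit policy: a marker whose top-scoring hits tie across distinct loci
is an orphan, never placed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assembly_model import AssemblySeq, reverse_complement

#: two accepted hits on the same scaffold closer than this collapse to one
#: locus (tandem micro-repeat tolerance)
SAME_LOCUS_BP = 100


@dataclass(frozen=True)
class GeneticMarker:
    """One mapped marker: linkage group, cM position, optional tag."""

    id: str
    linkage_group: str
    genetic_pos: float
    tag_seq: str | None = None

    def __post_init__(self) -> None:
        if self.genetic_pos < 0:
            raise ValueError(f"marker {self.id!r}: negative cM position")


@dataclass(frozen=True)
class MarkerPlacement:
    """An accepted location of a marker tag on one scaffold."""

    marker_id: str
    scaffold_id: str
    position: int          # 0-based start of the aligned tag
    strand: str            # '+' or '-'
    identity: float        # percent matches over aligned length
    coverage: float        # percent of the tag aligned
    score: float


@dataclass(frozen=True)
class Hit:
    """A raw candidate alignment, before best-hit selection."""

    marker_id: str
    scaffold_id: str
    position: int
    strand: str
    identity: float
    coverage: float
    score: float
    aligned_len: int
    mismatches: int


def load_genetic_map(path: str | Path) -> list[GeneticMarker]:
    """Read a marker table (TSV or CSV) into markers sorted by (group, cM).

    Required columns: ``marker_id``, ``linkage_group``, ``cM``; optional
    ``tag_seq``.  Duplicate marker ids and negative cM values are errors.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype={"marker_id": str, "linkage_group": str})
    missing = {"marker_id", "linkage_group", "cM"} - set(df.columns)
    if missing:
        raise ValueError(f"genetic map {path}: missing columns {sorted(missing)}")
    if df["marker_id"].duplicated().any():
        dups = df["marker_id"][df["marker_id"].duplicated()].iloc[0]
        raise ValueError(f"genetic map {path}: duplicate marker id {dups!r}")
    has_tags = "tag_seq" in df.columns
    markers = [
        GeneticMarker(
            row.marker_id, row.linkage_group, float(row.cM),
            (None if not has_tags or pd.isna(row.tag_seq) else str(row.tag_seq).upper()),
        )
        for row in df.itertuples()
    ]
    markers.sort(key=lambda m: (m.linkage_group, m.genetic_pos, m.id))
    return markers


def write_map(markers: Iterable[GeneticMarker], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tlinkage_group\tcM\ttag_seq\n")
        for m in markers:
            fh.write(f"{m.id}\t{m.linkage_group}\t{m.genetic_pos:g}\t{m.tag_seq or ''}\n")


class ScaffoldIndex:
    """Exact k-mer index over an assembly, reusable across marker searches."""

    def __init__(self, assembly: Sequence[AssemblySeq], k: int = 15):
        self.k = k
        self.seqs = {s.id: s.seq for s in assembly}
        index: dict[str, list[tuple[str, int]]] = {}
        for s in assembly:
            seq = s.seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((s.id, i))
        self._index = index

    def seed_hits(self, tag: str) -> set[tuple[str, int]]:
        """Candidate (scaffold, tag-start) positions implied by seed matches."""
        out: set[tuple[str, int]] = set()
        for i in range(0, len(tag) - self.k + 1):
            for sid, p in self._index.get(tag[i:i + self.k], ()):
                out.add((sid, p - i))
        return out


def _evaluate(tag: str, scaffold: str, start: int) -> tuple[int, int, int] | None:
    """Ungapped comparison of a tag at a candidate offset.

    Returns (matches, aligned_len, clipped_start) or None when nothing
    overlaps the scaffold.
    """
    a = max(start, 0)
    b = min(start + len(tag), len(scaffold))
    if b <= a:
        return None
    toff = a - start
    window = scaffold[a:b]
    sub = tag[toff:toff + (b - a)]
    matches = sum(1 for x, y in zip(sub, window) if x == y and x != "N")
    return matches, b - a, a


def search_tag(marker_id: str, tag: str, index: ScaffoldIndex,
               min_identity: float, min_coverage: float) -> list[Hit]:
    """All threshold-passing ungapped hits of a tag, both strands."""
    hits: list[Hit] = []
    for strand, query in (("+", tag), ("-", reverse_complement(tag))):
        for sid, start in index.seed_hits(query):
            ev = _evaluate(query, index.seqs[sid], start)
            if ev is None:
                continue
            matches, alen, pos = ev
            identity = 100.0 * matches / alen
            coverage = 100.0 * alen / len(tag)
            if identity >= min_identity and coverage >= min_coverage:
                hits.append(Hit(marker_id, sid, pos, strand, identity,
                                coverage, float(matches), alen, alen - matches))
    return hits


def _collapse_same_locus(hits: list[Hit]) -> list[Hit]:
    """Merge hits on one scaffold within SAME_LOCUS_BP, keeping the best."""
    out: list[Hit] = []
    for sid in {h.scaffold_id for h in hits}:
        group = sorted((h for h in hits if h.scaffold_id == sid),
                       key=lambda h: h.position)
        cluster: list[Hit] = []
        for h in group:
            if cluster and h.position - cluster[-1].position > SAME_LOCUS_BP:
                out.append(max(cluster, key=lambda x: x.score))
                cluster = []
            cluster.append(h)
        if cluster:
            out.append(max(cluster, key=lambda x: x.score))
    return out


def select_best(hits: list[Hit]) -> Hit | None:
    """Unique top-scoring locus, or None when absent/ambiguous."""
    if not hits:
        return None
    hits = _collapse_same_locus(hits)
    best = max(h.score for h in hits)
    top = [h for h in hits if h.score == best]
    if len(top) > 1:
        return None
    return top[0]


def place_markers(markers: Sequence[GeneticMarker],
                  assembly: Sequence[AssemblySeq] | ScaffoldIndex,
                  min_identity: float = 90.0, min_coverage: float = 90.0,
                  seed_k: int = 15,
                  ) -> tuple[list[MarkerPlacement], list[str]]:
    """Place marker tags on an assembly; returns (placements, orphan ids).

    Orphans are markers with no threshold-passing hit or with tied best
    hits at distinct loci.  Markers lacking a tag, or with a tag shorter
    than the seed size, are skipped with a warning and listed as orphans.
    """
    index = assembly if isinstance(assembly, ScaffoldIndex) \
        else ScaffoldIndex(assembly, seed_k)
    placements: list[MarkerPlacement] = []
    orphans: list[str] = []
    for m in markers:
        if not m.tag_seq or len(m.tag_seq) < index.k:
            warnings.warn(f"marker {m.id!r}: tag missing or shorter than "
                          f"seed size {index.k}; skipped")
            orphans.append(m.id)
            continue
        best = select_best(search_tag(m.id, m.tag_seq, index,
                                      min_identity, min_coverage))
        if best is None:
            orphans.append(m.id)
        else:
            placements.append(MarkerPlacement(
                m.id, best.scaffold_id, best.position, best.strand,
                best.identity, best.coverage, best.score))
    return placements, orphans


BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


def load_placements(path: str | Path, markers: Sequence[GeneticMarker],
                    min_identity: float = 90.0, min_coverage: float = 90.0,
                    ) -> tuple[list[MarkerPlacement], list[str]]:
    """Ingest 12-column BLAST tabular hits and apply the placement policy.

    Coverage is the aligned length over the marker tag length; a subject
    range with ``sstart > send`` encodes the minus strand.  Best-hit and
    ambiguity handling match :func:`place_markers` (score = bitscore).
    """
    tag_len = {m.id: (len(m.tag_seq) if m.tag_seq else None) for m in markers}
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits_by_marker: dict[str, list[Hit]] = {}
    for row in df.itertuples():
        qid = str(row.qseqid)
        if qid not in tag_len:
            raise ValueError(f"hit for unknown marker id {qid!r}")
        tlen = tag_len[qid]
        if tlen is None:
            raise ValueError(f"marker {qid!r} has hits but no tag length")
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        alen = int(row.length)
        coverage = 100.0 * alen / tlen
        identity = float(row.pident)
        if identity < min_identity or coverage < min_coverage:
            continue
        hits_by_marker.setdefault(qid, []).append(Hit(
            qid, str(row.sseqid), min(sstart, send) - 1, strand, identity,
            coverage, float(row.bitscore), alen, int(row.mismatch)))
    placements: list[MarkerPlacement] = []
    orphans: list[str] = []
    for m in markers:
        best = select_best(hits_by_marker.get(m.id, []))
        if best is None:
            orphans.append(m.id)
        else:
            placements.append(MarkerPlacement(
                m.id, best.scaffold_id, best.position, best.strand,
                best.identity, best.coverage, best.score))
    return placements, orphans


def hits_to_blast6(hits: Iterable[Hit], tag_lens: dict[str, int]) -> str:
    """Serialize internal hits as BLAST outfmt-6 rows (bitscore := score)."""
    lines = []
    for h in hits:
        qstart, qend = 1, h.aligned_len
        if h.strand == "+":
            sstart, send = h.position + 1, h.position + h.aligned_len
        else:
            sstart, send = h.position + h.aligned_len, h.position + 1
        lines.append("\t".join(str(x) for x in (
            h.marker_id, h.scaffold_id, f"{h.identity:.2f}", h.aligned_len,
            h.mismatches, 0, qstart, qend, sstart, send, 1e-30, h.score)))
    return "\n".join(lines) + ("\n" if lines else "")


def placements_tsv(placements: Sequence[MarkerPlacement],
                   orphans: Sequence[str]) -> str:
    """Placements table: 1-based positions, status accepted/orphan."""
    lines = ["marker\tscaffold\tpos\tstrand\tidentity\tcoverage\tstatus"]
    for p in placements:
        lines.append(f"{p.marker_id}\t{p.scaffold_id}\t{p.position + 1}\t"
                     f"{p.strand}\t{p.identity:.2f}\t{p.coverage:.2f}\taccepted")
    for mid in orphans:
        lines.append(f"{mid}\t-\t-\t-\t-\t-\torphan")
    return "\n".join(lines) + "\n"
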