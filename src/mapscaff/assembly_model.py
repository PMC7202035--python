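"""Assembly data model, FASTA I/O, contig segmentation and summary statistics.

The unit of everything downstream is the :class:`AssemblySeq`: a named
scaffold (or contig) over the alphabet {A,C,G,T,N}.  Scaffolds carry runs of
Ns separating their constituent contigs; :func:`segment_contigs` recovers
that decomposition, which is where misassembly splitting is later allowed to
cut.  The statistics battery (N50, GC excluding Ns, length-class profile,
percent-of-genome, read depth) mirrors the summary tables used to validate
chromosome-level assemblies.

Coordinates are 0-based half-open internally; emitted tables are 1-based
inclusive.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._util import ratio_percent, round_half_up

_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default length-class bin edges (bp), matching the usual <10 kb / 10–100 kb
#: / 100 kb–1 Mb / >=1 Mb presentation of scaffold-length profiles
DEFAULT_BIN_EDGES = (0, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class AssemblySeq:
    """A named assembly sequence (scaffold or contig)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ContigInterval:
    """A maximal non-gap stretch of a scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyStats:
    n_seqs: int
    total_len: int
    n50: int
    min_len: int
    max_len: int
    n_count: int
    gc_excl_n: float


@dataclass(frozen=True)
class LengthClassProfile:
    bin_edges: tuple[int, ...]
    covered_len_per_bin: tuple[int, ...]
    seq_count_per_bin: tuple[int, ...]

    @property
    def pct_len_per_bin(self) -> tuple[float, ...]:
        total = sum(self.covered_len_per_bin)
        return tuple(ratio_percent(c, total) for c in self.covered_len_per_bin)

    @property
    def pct_count_per_bin(self) -> tuple[float, ...]:
        total = sum(self.seq_count_per_bin)
        return tuple(ratio_percent(c, total) for c in self.seq_count_per_bin)


def clean_sequence(raw: str, *, name: str = "?") -> str:
    """Uppercase and coerce non-ACGTN characters (IUPAC codes etc.) to N."""
    s = raw.upper()
    if _NON_ACGTN.search(s):
        warnings.warn(
            f"sequence {name!r}: characters outside ACGTN coerced to N",
            stacklevel=2,
        )
        s = _NON_ACGTN.sub("N", s)
    return s


def read_fasta(path: str | Path) -> list[AssemblySeq]:
    """Read a FASTA file into a list of :class:`AssemblySeq`.

    Record ids are the first whitespace-delimited header token.  Duplicate
    ids and empty files are errors; characters outside {A,C,G,T,N} are
    coerced to N with a warning.
    """
    records: list[AssemblySeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(AssemblySeq(rec.id, clean_sequence(str(rec.seq), name=rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[AssemblySeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def segment_contigs(seq: AssemblySeq, min_gap_run: int = 10) -> list[ContigInterval]:
    """Decompose a scaffold into contig intervals separated by N gaps.

    N runs shorter than ``min_gap_run`` are absorbed into the surrounding
    contig; leading and trailing N runs of any length belong to no contig.
    An all-N sequence yields an empty list.
    """
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    s = seq.seq
    cuts: list[tuple[int, int]] = []
    for m in re.finditer("N+", s):
        terminal = m.start() == 0 or m.end() == len(s)
        if terminal or (m.end() - m.start()) >= min_gap_run:
            cuts.append((m.start(), m.end()))
    intervals: list[ContigInterval] = []
    prev = 0
    for a, b in cuts:
        if a > prev:
            intervals.append(ContigInterval(seq.id, prev, a, len(intervals)))
        prev = b
    if prev < len(s):
        intervals.append(ContigInterval(seq.id, prev, len(s), len(intervals)))
    return intervals


def gap_runs(seq: AssemblySeq, min_gap_run: int = 10) -> list[tuple[int, int]]:
    """Inter-contig N gaps (0-based half-open) between consecutive contigs."""
    contigs = segment_contigs(seq, min_gap_run)
    return [(a.end, b.start) for a, b in zip(contigs, contigs[1:])]


def gc_content_excluding_n(seqs: Iterable[AssemblySeq | str]) -> float:
    """GC percent over called bases only (Ns excluded), unrounded."""
    gc = acgt = 0
    for s in seqs:
        text = s.seq if isinstance(s, AssemblySeq) else s
        gc += text.count("G") + text.count("C")
        acgt += len(text) - text.count("N")
    if acgt == 0:
        raise ValueError("no called (non-N) bases in input")
    return 100.0 * gc / acgt


def n50(lengths: Sequence[int]) -> int:
    """Largest L with at least half the total length in sequences >= L."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(2 * cum, total))
    return int(arr[idx])


def assembly_summary(assembly: Sequence[AssemblySeq]) -> AssemblyStats:
    if not assembly:
        raise ValueError("empty assembly")
    lengths = [s.length for s in assembly]
    n_total = sum(s.seq.count("N") for s in assembly)
    return AssemblyStats(
        n_seqs=len(assembly),
        total_len=sum(lengths),
        n50=n50(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        n_count=n_total,
        gc_excl_n=round_half_up(gc_content_excluding_n(assembly), 1),
    )


def length_class_profile(lengths: Sequence[int],
                         bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
                         ) -> LengthClassProfile:
    """Covered length and sequence count per length class.

    Bins are ``[e0,e1), [e1,e2), ..., [e_last, inf)``; edges must ascend.
    """
    edges = [int(e) for e in bin_edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    arr = np.asarray(lengths, dtype=np.int64)
    idx = np.digitize(arr, edges[1:], right=False)  # bin index per sequence
    nbins = len(edges)
    covered = [int(arr[idx == b].sum()) for b in range(nbins)]
    counts = [int((idx == b).sum()) for b in range(nbins)]
    return LengthClassProfile(tuple(edges), tuple(covered), tuple(counts))


def percent_of_genome(observed_len: int, estimated_size: int,
                      decimals: int = 1, mode: str = "half_up") -> float | int:
    """Observed assembly span as a percent of an estimated genome size."""
    return ratio_percent(observed_len, estimated_size, decimals, mode)


def read_depth(total_bases: int, genome_size: int) -> int:
    """Sequencing depth as an integer fold-coverage (floor division)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return int(total_bases) // int(genome_size)


def stats_tsv(stats: AssemblyStats) -> str:
    """Render a summary-statistics table (one row name + value per line)."""
    rows = [
        ("Number of sequences", stats.n_seqs),
        ("Total length (bp)", stats.total_len),
        ("N50 (bp)", stats.n50),
        ("Minimum length (bp)", stats.min_len),
        ("Maximum length (bp)", stats.max_len),
        ("Number of Ns (bp)", stats.n_count),
        ("GC content wo Ns (%)", stats.gc_excl_n),
    ]
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def profile_tsv(profile: LengthClassProfile) -> str:
    lines = ["bin_low\tbin_high\tn_seqs\tcovered_bp\tpct_len\tpct_count"]
    edges = list(profile.bin_edges) + ["inf"]
    for i in range(len(profile.bin_edges)):
        lines.append("\t".join(str(x) for x in (
            edges[i], edges[i + 1],
            profile.seq_count_per_bin[i], profile.covered_len_per_bin[i],
            profile.pct_len_per_bin[i], profile.pct_count_per_bin[i],
        )))
    return "\n".join(lines) + "\n"
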