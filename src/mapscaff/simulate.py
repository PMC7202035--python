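"""Synthetic fixtures with ground truth for every pipeline stage.

Generates multi-chromosome genomes, monotone-with-noise genetic maps with
marker tag sequences, fragmented scaffold assemblies with injected
chimeric joins and nested insertions (always at inter-contig gaps, as real
scaffolding artefacts are), shotgun reads at a stated depth and error
rate, and non-overlapping variant sets — each with a serialisable truth
record.  All randomness fans out from a single seed through stable
per-operation substreams, so adding one fixture never perturbs another.

Gap runs inserted between contigs are pure insertions — no genome bases
are deleted — so the non-N content of a fragmented assembly reconstructs
each chromosome exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import substream
from .assembly_model import AssemblySeq, reverse_complement
from .genetic_map import GeneticMarker
from .polishing import VariantRecord, SNP, INSERTION, DELETION, MULTIPLE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated fixture set."""

    scaffolds: dict[str, dict] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    markers: dict[str, dict] = field(default_factory=dict)
    reads: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def true_chromosome(self, scaffold_id: str) -> str | None:
        """The single source chromosome of a scaffold, or None if chimeric."""
        parts = self.scaffolds[scaffold_id]["parts"]
        chroms = {p["chrom"] for p in parts}
        return parts[0]["chrom"] if len(chroms) == 1 else None


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def simulate_genome(n_chrom: int, chrom_lens: Sequence[int],
                    gc: float = 0.44, seed: int = 0) -> list[AssemblySeq]:
    """I.i.d.-base genome with the stated GC, ids chr01..chrNN."""
    if len(chrom_lens) != n_chrom:
        raise ValueError("chrom_lens must have n_chrom entries")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    out = []
    for i, L in enumerate(chrom_lens):
        if L <= 0:
            raise ValueError("chromosome lengths must be positive")
        rng = substream(seed, f"genome/chr{i + 1}")
        out.append(AssemblySeq(f"chr{i + 1:02d}", _random_bases(rng, int(L), gc)))
    return out


def simulate_map(genome: Sequence[AssemblySeq], markers_per_mb: float = 100.0,
                 cM_per_mb: float = 4.0, cM_noise_sd: float = 0.0,
                 tag_len: int = 100, seed: int = 0,
                 ) -> tuple[list[GeneticMarker], TruthTable]:
    """Markers at Poisson density with genome-substring tags.

    Genetic position is ``cM_per_mb`` times the physical megabase position
    plus Gaussian noise, clamped to stay non-decreasing along each
    chromosome; the noiseless (monotone) truth is retained per marker.
    """
    if markers_per_mb <= 0:
        raise ValueError("marker density must be positive")
    truth = TruthTable()
    markers: list[GeneticMarker] = []
    half = tag_len // 2
    for chrom in genome:
        rng = substream(seed, f"map/{chrom.id}")
        n = rng.poisson(markers_per_mb * chrom.length / 1e6)
        lo, hi = half, chrom.length - (tag_len - half)
        if hi <= lo:
            continue
        positions = np.sort(rng.choice(np.arange(lo, hi), size=min(int(n), hi - lo),
                                       replace=False))
        true_cm = cM_per_mb * positions / 1e6
        cm = true_cm + (rng.normal(0.0, cM_noise_sd, size=len(positions))
                        if cM_noise_sd > 0 else 0.0)
        cm = np.maximum.accumulate(np.maximum(cm, 0.0))
        for i, pos in enumerate(positions):
            mid = f"{chrom.id}_m{i + 1:05d}"
            tag = chrom.seq[pos - half:pos - half + tag_len]
            markers.append(GeneticMarker(mid, chrom.id, float(cm[i]), tag))
            truth.markers[mid] = {"chrom": chrom.id, "pos": int(pos),
                                  "tag_start": int(pos - half),
                                  "true_cM": float(true_cm[i])}
    return markers, truth


def _cut_lengths(rng: np.random.Generator, total: int, mean: int,
                 minimum: int) -> list[int]:
    """Partition ``total`` into exponential-ish pieces of at least ``minimum``."""
    lens: list[int] = []
    left = total
    while left > 0:
        ln = max(minimum, int(rng.exponential(mean)))
        if left - ln < minimum:
            ln = left
        lens.append(min(ln, left))
        left -= lens[-1]
    return lens


def _piece_to_parts(piece: dict, genome_seqs: dict[str, str],
                    gap_run_len: int) -> tuple[str, dict]:
    """Render one single-chromosome piece: contig slices joined by N runs."""
    chrom = piece["chrom"]
    segs = piece["contigs"]
    seq = ("N" * gap_run_len).join(genome_seqs[chrom][a:b] for a, b in segs)
    if piece["orientation"] == "-":
        seq = reverse_complement(seq)
    part = {"chrom": chrom, "orientation": piece["orientation"],
            "segments": [[int(a), int(b)] for a, b in segs]}
    return seq, part


def fragment_assembly(genome: Sequence[AssemblySeq],
                      mean_scaffold_len: int = 100_000,
                      mean_contig_len: int | None = None,
                      gap_run_len: int = 100,
                      chimera_rate: float = 0.0,
                      nested_rate: float = 0.0,
                      p_revcomp: float = 0.5,
                      min_piece_len: int = 2_000,
                      seed: int = 0,
                      ) -> tuple[list[AssemblySeq], TruthTable]:
    """Fragment a genome into scaffolds with optional injected misassemblies.

    Each chromosome is cut into pieces (mean ``mean_scaffold_len``), each
    piece into contigs (mean ``mean_contig_len``) joined by N runs of
    ``gap_run_len``.  With probability ``chimera_rate`` a piece is joined,
    at a gap, to a piece from a different chromosome; with ``nested_rate``
    a piece from a different chromosome is inserted between two of a
    host's contigs, flanked by gaps.  Every event is recorded in the truth
    table with its junction gap coordinates in final scaffold coordinates.
    """
    if not 0 <= chimera_rate < 1 or not 0 <= nested_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if mean_contig_len is None:
        mean_contig_len = max(mean_scaffold_len // 4, 2_000)
    rng = substream(seed, "fragment_assembly")
    genome_seqs = {g.id: g.seq for g in genome}

    pieces: list[dict] = []
    for g in genome:
        pos = 0
        for ln in _cut_lengths(rng, g.length, mean_scaffold_len, min_piece_len):
            cpos = pos
            contigs = []
            for cl in _cut_lengths(rng, ln, mean_contig_len,
                                   max(min_piece_len // 4, 500)):
                contigs.append((cpos, cpos + cl))
                cpos += cl
            pieces.append({"chrom": g.id, "start": pos, "end": pos + ln,
                           "contigs": contigs,
                           "orientation": "-" if rng.random() < p_revcomp else "+"})
            pos += ln

    order = rng.permutation(len(pieces))
    available = [pieces[i] for i in order]
    truth = TruthTable()
    scaffolds: list[AssemblySeq] = []

    def take_foreign(chrom: str) -> dict | None:
        for idx, cand in enumerate(available):
            if cand["chrom"] != chrom:
                return available.pop(idx)
        return None

    serial = 0
    while available:
        host = available.pop(0)
        serial += 1
        sid = f"scf{serial:05d}"
        r = rng.random()
        event: dict | None = None
        if r < chimera_rate:
            partner = take_foreign(host["chrom"])
            if partner is not None:
                seq_a, part_a = _piece_to_parts(host, genome_seqs, gap_run_len)
                seq_b, part_b = _piece_to_parts(partner, genome_seqs, gap_run_len)
                gap_start = len(seq_a)
                seq = seq_a + "N" * gap_run_len + seq_b
                part_a.update(scaf_start=0, scaf_end=len(seq_a))
                part_b.update(scaf_start=gap_start + gap_run_len, scaf_end=len(seq))
                event = {"kind": "chimera", "scaffold": sid,
                         "gaps": [[gap_start, gap_start + gap_run_len]]}
                truth.scaffolds[sid] = {"parts": [part_a, part_b],
                                        "gap_run_len": gap_run_len}
                truth.events.append(event)
                scaffolds.append(AssemblySeq(sid, seq))
                continue
        elif r < chimera_rate + nested_rate and len(host["contigs"]) >= 2:
            donor = take_foreign(host["chrom"])
            if donor is not None:
                split_at = int(rng.integers(1, len(host["contigs"])))
                left = dict(host, contigs=host["contigs"][:split_at])
                right = dict(host, contigs=host["contigs"][split_at:])
                seq_l, part_l = _piece_to_parts(left, genome_seqs, gap_run_len)
                seq_d, part_d = _piece_to_parts(donor, genome_seqs, gap_run_len)
                seq_r, part_r = _piece_to_parts(right, genome_seqs, gap_run_len)
                g1 = len(seq_l)
                g2 = g1 + gap_run_len + len(seq_d)
                seq = seq_l + "N" * gap_run_len + seq_d + "N" * gap_run_len + seq_r
                part_l.update(scaf_start=0, scaf_end=g1)
                part_d.update(scaf_start=g1 + gap_run_len, scaf_end=g2)
                part_r.update(scaf_start=g2 + gap_run_len, scaf_end=len(seq))
                event = {"kind": "nested", "scaffold": sid,
                         "gaps": [[g1, g1 + gap_run_len],
                                  [g2, g2 + gap_run_len]]}
                truth.scaffolds[sid] = {"parts": [part_l, part_d, part_r],
                                        "gap_run_len": gap_run_len}
                truth.events.append(event)
                scaffolds.append(AssemblySeq(sid, seq))
                continue
        seq, part = _piece_to_parts(host, genome_seqs, gap_run_len)
        part.update(scaf_start=0, scaf_end=len(seq))
        truth.scaffolds[sid] = {"parts": [part], "gap_run_len": gap_run_len}
        scaffolds.append(AssemblySeq(sid, seq))
    return scaffolds, truth


def simulate_reads(genome: Sequence[AssemblySeq], depth: float = 30.0,
                   read_len: int = 150, error_rate: float = 0.0,
                   seed: int = 0, with_truth: bool = False,
                   ) -> list[tuple[str, str]] | tuple[list[tuple[str, str]], TruthTable]:
    """Uniform shotgun reads with i.i.d. substitution errors.

    Returns (read id, sequence) pairs totalling ~``depth`` × genome size;
    start positions are uniform, strands random.
    """
    if depth <= 0 or read_len <= 0:
        raise ValueError("depth and read_len must be positive")
    total_len = sum(g.length for g in genome)
    n_reads = int(round(depth * total_len / read_len))
    rng = substream(seed, "reads")
    weights = np.array([max(g.length - read_len + 1, 0) for g in genome], float)
    if weights.sum() == 0:
        raise ValueError("every chromosome is shorter than read_len")
    weights /= weights.sum()
    chrom_idx = rng.choice(len(genome), size=n_reads, p=weights)
    strands = rng.random(n_reads) < 0.5
    n_err = rng.binomial(read_len, error_rate, size=n_reads) \
        if error_rate > 0 else np.zeros(n_reads, dtype=int)
    reads: list[tuple[str, str]] = []
    truth = TruthTable()
    for i in range(n_reads):
        g = genome[chrom_idx[i]]
        start = int(rng.integers(0, g.length - read_len + 1))
        seq = g.seq[start:start + read_len]
        strand = "-" if strands[i] else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        if n_err[i]:
            b = bytearray(seq, "ascii")
            for p in rng.choice(read_len, size=n_err[i], replace=False):
                cur = b[p]
                choices = [x for x in b"ACGT" if x != cur]
                b[p] = choices[int(rng.integers(3))]
            seq = b.decode("ascii")
        rid = f"read{i + 1:07d}"
        reads.append((rid, seq))
        if with_truth:
            truth.reads.append({"id": rid, "chrom": g.id, "start": start,
                                "strand": strand, "n_errors": int(n_err[i])})
    return (reads, truth) if with_truth else reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _pick_base(rng: np.random.Generator, exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def simulate_variants(contig: AssemblySeq, n_snp: int, n_ins: int,
                      n_del: int, n_multi: int, seed: int = 0,
                      max_indel: int = 5, spacing: int = 60,
                      ) -> tuple[list[VariantRecord], str]:
    """Non-overlapping variants plus the independently constructed edit truth.

    Sites are placed on a jittered grid so no two records overlap.  Indel
    alleles are chosen to be left-align unambiguous (the inserted/deleted
    segment differs from its right context at the first base), so an
    anchored diff of edited-vs-original recovers the applied set exactly.
    The edited truth sequence is spliced together left-to-right here,
    independently of :func:`mapscaff.polishing.apply_consensus`.
    """
    rng = substream(seed, "variants")
    n_total = n_snp + n_ins + n_del + n_multi
    seq = contig.seq
    slots = list(range(2, len(seq) - spacing - max_indel - 2, spacing))
    if n_total > len(slots):
        raise ValueError(f"contig too short for {n_total} variants "
                         f"(room for {len(slots)})")
    chosen = np.sort(rng.choice(len(slots), size=n_total, replace=False))
    classes = [SNP] * n_snp + [INSERTION] * n_ins + [DELETION] * n_del \
        + [MULTIPLE] * n_multi
    rng.shuffle(classes)
    records: list[VariantRecord] = []
    for slot_i, cls in zip(chosen, classes):
        p0 = slots[slot_i] + int(rng.integers(0, spacing // 3))  # 0-based
        if cls == SNP:
            ref = seq[p0]
            records.append(VariantRecord(contig.id, p0 + 1, ref,
                                         (_pick_base(rng, ref),)))
        elif cls == INSERTION:
            anchor = seq[p0]
            first = _pick_base(rng, seq[p0 + 1])
            ins = first + "".join(_pick_base(rng, "")
                                  for _ in range(int(rng.integers(0, max_indel))))
            records.append(VariantRecord(contig.id, p0 + 1, anchor,
                                         (anchor + ins,)))
        elif cls == DELETION:
            # slide right past any homopolymer so the deletion cannot
            # left-shift: the deleted segment must differ from its right
            # context at the first base
            dlen = None
            for shift in range(spacing // 3):
                q = p0 + shift
                for cand in rng.permutation(np.arange(1, max_indel + 1)):
                    if seq[q + 1] != seq[q + 1 + int(cand)]:
                        dlen = int(cand)
                        break
                if dlen is not None:
                    p0 = q
                    break
            assert dlen is not None, "unbroken homopolymer across a whole slot"
            ref = seq[p0:p0 + 1 + dlen]
            records.append(VariantRecord(contig.id, p0 + 1, ref, (seq[p0],)))
        else:  # multiple: multi-allelic; the first (applied) allele is a SNP
            ref = seq[p0]
            alt1 = _pick_base(rng, ref)
            records.append(VariantRecord(contig.id, p0 + 1, ref,
                                         (alt1, ref + _pick_base(rng, ""))))
    records.sort(key=lambda v: v.pos)
    # splice the edited truth left-to-right
    out: list[str] = []
    cursor = 0
    for v in records:
        out.append(seq[cursor:v.pos - 1])
        out.append(v.alts[0])
        cursor = v.end
    out.append(seq[cursor:])
    return records, "".join(out)


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n")
        for v in records:
            fh.write(f"{v.contig_id}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\n")
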