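"""Consensus polishing: classify variant records and apply them to contigs.

Long-read contigs carry systematic base errors; mapping accurate short
reads back and calling variants against the contigs yields a correction
set that is folded into the sequence as a consensus.  This module consumes
those records (a minimal VCF-like table), classifies each correction
(SNP / insertion / deletion / multiple), applies them with exact
coordinate bookkeeping, and reproduces the standard correction-accounting
summary (counts and percentages per class).

The inverse route, :func:`diff_consensus`, recovers an applied edit set by
anchored comparison of the original and edited sequence — the independent
check that application was coordinate-exact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from ._util import round_half_up

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"
MULTIPLE = "multiple"
CLASSES = (SNP, INSERTION, DELETION, MULTIPLE)


def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """Class of a correction record.

    Multi-allelic records are ``multiple``; otherwise length comparison of
    the single ALT against REF decides: equal → SNP (substitution of any
    width), longer → insertion, shorter → deletion.  Empty alleles are an
    error — indels must use the anchored-base representation.
    """
    if not ref:
        raise ValueError("empty REF allele")
    if not alts:
        raise ValueError("record with no ALT allele")
    if any(not a for a in alts):
        raise ValueError("empty ALT allele: use anchored-base representation")
    if len(alts) > 1:
        return MULTIPLE
    a = alts[0]
    if len(a) == len(ref):
        return SNP
    return INSERTION if len(a) > len(ref) else DELETION


@dataclass(frozen=True)
class VariantRecord:
    contig_id: str
    pos: int                 # 1-based position of the first REF base
    ref: str
    alts: tuple[str, ...]

    @property
    def variant_class(self) -> str:
        return classify_variant(self.ref, self.alts)

    @property
    def end(self) -> int:
        """1-based inclusive end of the REF span."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class CorrectionSummary:
    counts: dict[str, int]
    percents: dict[str, float | None]
    total: int


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal VCF reader: CHROM POS ID REF ALT; remaining columns ignored."""
    records: list[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"VCF line with fewer than 5 columns: {line!r}")
            chrom, pos, _vid, ref, alt = f[:5]
            alts = tuple(a.upper() for a in alt.split(","))
            records.append(VariantRecord(chrom, int(pos), ref.upper(), alts))
    return records


def apply_consensus(seq: str, variants: Sequence[VariantRecord]) -> str:
    """Apply non-overlapping variants to one contig sequence.

    REF alleles are verified against the sequence; overlapping records and
    REF mismatches are errors.  Multi-allelic records apply their first
    ALT.  Edits run in descending position order so earlier coordinates
    stay valid; the output length equals the input plus the summed indel
    deltas.
    """
    ordered = sorted(variants, key=lambda v: v.pos)
    for a, b in zip(ordered, ordered[1:]):
        if a.end >= b.pos:
            raise ValueError(f"overlapping variants at {a.contig_id}:{a.pos} "
                             f"and {b.contig_id}:{b.pos}")
    out = seq
    for v in reversed(ordered):
        if v.end > len(seq):
            raise ValueError(f"variant at {v.contig_id}:{v.pos} extends past "
                             f"contig end ({len(seq)} bp)")
        found = seq[v.pos - 1:v.end]
        if found != v.ref:
            raise ValueError(f"REF mismatch at {v.contig_id}:{v.pos}: "
                             f"expected {v.ref!r}, found {found!r}")
        out = out[:v.pos - 1] + v.alts[0] + out[v.end:]
    return out


def summarize_corrections(variants: Sequence[VariantRecord] | dict[str, int],
                          ) -> CorrectionSummary:
    """Counts and half-up one-decimal percentages per correction class.

    Accepts either classified records or a precomputed ``{class: count}``
    mapping (the form printed in assembly reports).
    """
    if isinstance(variants, dict):
        counts = {c: int(variants.get(c, 0)) for c in CLASSES}
    else:
        tally = Counter(v.variant_class for v in variants)
        counts = {c: tally.get(c, 0) for c in CLASSES}
    total = sum(counts.values())
    if total == 0:
        percents: dict[str, float | None] = {c: None for c in CLASSES}
    else:
        percents = {c: round_half_up(100.0 * counts[c] / total, 1)
                    for c in CLASSES}
    return CorrectionSummary(counts, percents, total)


def summary_tsv(summary: CorrectionSummary) -> str:
    lines = ["class\tcount\tpercent"]
    for c in CLASSES:
        pct = "-" if summary.percents[c] is None else f"{summary.percents[c]:.1f}"
        lines.append(f"{c}\t{summary.counts[c]}\t{pct}")
    lines.append(f"total\t{summary.total}\t-")
    return "\n".join(lines) + "\n"


def diff_consensus(original: str, edited: str, contig_id: str = "seq",
                   window: int = 20, max_shift: int = 200,
                   ) -> list[VariantRecord]:
    """Recover an anchored edit set by resynchronising two sequences.

    Scans both sequences in lockstep; at each mismatch it searches for the
    smallest combined skip (di, de) after which a ``window``-length block
    matches again, preferring balanced skips (substitutions).  Equal skips
    yield a substitution record, unbalanced skips an anchored insertion or
    deletion.  Exact for edit sets whose sites are separated by more than
    ``window`` bases and whose indels do not left-shift into their context.
    """
    def anchored(i: int, j: int) -> bool:
        w = min(window, len(original) - i, len(edited) - j)
        if w <= 0:  # ran off an end: accept only if both ends align
            return (len(original) - i) == (len(edited) - j)
        return original[i:i + w] == edited[j:j + w]

    out: list[VariantRecord] = []
    i = j = 0
    while i < len(original) or j < len(edited):
        if i < len(original) and j < len(edited) and original[i] == edited[j]:
            i += 1
            j += 1
            continue
        hit = None
        for total in range(1, 2 * max_shift):
            # balanced skips first: a substitution is the simplest story
            splits = sorted(range(0, total + 1),
                            key=lambda di: abs(2 * di - total))
            for di in splits:
                de = total - di
                if i + di <= len(original) and j + de <= len(edited) \
                        and anchored(i + di, j + de):
                    hit = (di, de)
                    break
            if hit:
                break
        if hit is None:
            raise ValueError(f"could not resynchronise sequences near "
                             f"position {i} of {contig_id!r}")
        di, de = hit
        if di == de:
            out.append(VariantRecord(contig_id, i + 1, original[i:i + di],
                                     (edited[j:j + de],)))
        elif di < de:  # insertion, anchored on the previous base
            ins = edited[j:j + (de - di)]
            if di:
                out.append(VariantRecord(contig_id, i + 1, original[i:i + di],
                                         (original[i:i + di],)))
            out.append(VariantRecord(contig_id, i, original[i - 1],
                                     (original[i - 1] + ins,)))
        else:
            dele = original[i:i + (di - de)]
            out.append(VariantRecord(contig_id, i, original[i - 1] + dele,
                                     (original[i - 1],)))
        i += di
        j += de
    return out
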