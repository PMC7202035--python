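"""Canonical k-mer spectra and genome-size estimation.

The genome size of an unassembled read set is estimated from its k-mer
frequency distribution: error k-mers pile up at low multiplicity, genuine
single-copy k-mers form a peak at the effective k-mer coverage depth d,
and the genome size is (k-mers above the error valley) / d.  Counting is
exact and in-memory (2-bit packed, canonical = min of a k-mer and its
reverse complement), sized for desk-scale genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class KmerHistogram:
    """Distribution of k-mer multiplicities: counts[m] = distinct k-mers
    observed exactly m times."""

    k: int
    counts: dict[int, int]
    total_kmers: int

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ms = np.array(sorted(self.counts), dtype=np.int64)
        return ms, np.array([self.counts[int(m)] for m in ms], dtype=np.int64)


def kmer_histogram(reads: Iterable[str], k: int = 25) -> KmerHistogram:
    """Exact canonical k-mer multiplicity histogram over a read set.

    Windows containing N (or any non-ACGT character) are skipped; reads
    shorter than k contribute nothing (warned).  k up to 32 is supported
    by the 2-bit packing.
    """
    if not 1 <= k <= 32:
        raise ValueError("k must be in 1..32")
    reads = list(reads)
    if any(len(r) < k for r in reads):
        warnings.warn(f"{sum(len(r) < k for r in reads)} read(s) shorter "
                      f"than k={k} contribute no k-mers")
    # Join reads with an N separator: any window spanning a boundary is
    # automatically invalidated, so one vectorised pass covers everything.
    blob = "N".join(r.upper() for r in reads)
    a = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
    code = _CODE[a]
    n = len(a) - k + 1
    if n <= 0:
        return KmerHistogram(k, {}, 0)
    invalid = (code == 255)
    c = np.where(invalid, 0, code).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j:j + n]
        rev |= (np.uint64(3) - c[j:j + n]) << np.uint64(2 * j)
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32),
                      mode="valid") > 0
    canon = np.minimum(fwd, rev)[~bad]
    if canon.size == 0:
        return KmerHistogram(k, {}, 0)
    _, mult = np.unique(canon, return_counts=True)
    spectrum = np.bincount(mult)
    counts = {int(m): int(spectrum[m]) for m in np.nonzero(spectrum)[0]}
    return KmerHistogram(k, counts, int(canon.size))


def estimate_genome_size(hist: KmerHistogram,
                         smooth_window: int = 3) -> int:
    """Genome size from the spectrum: valley-excluded total over peak depth.

    Scanning multiplicity upward on a 3-bin-smoothed spectrum, the first
    local minimum is the error valley; the coverage peak d is the modal
    multiplicity beyond it, refined to the local centroid; the estimate is
    Σ_{m >= valley} m·counts[m] / d.
    Raises when no valley/peak structure exists (too-shallow coverage) or
    the peak sits below multiplicity 4.
    """
    if not hist.counts:
        raise ValueError("empty k-mer histogram")
    max_m = max(hist.counts)
    raw = np.zeros(max_m + 2, dtype=np.float64)
    for m, c in hist.counts.items():
        raw[m] = c
    kernel = np.ones(smooth_window) / smooth_window
    raw[0] = raw[1]  # edge pad: multiplicity 0 is unobservable, not zero
    sm = np.convolve(raw, kernel, mode="same")
    # valley: the first multiplicity where the smoothed spectrum turns from
    # non-increasing to increasing (m=1 qualifies when the spectrum rises
    # from the start, i.e. an essentially error-free read set)
    valley = None
    for m in range(1, max_m):
        if sm[m + 1] > sm[m] and (m == 1 or sm[m] <= sm[m - 1]):
            valley = m
            break
    if valley is None:
        raise ValueError("no error valley / coverage peak in the spectrum; "
                         "deeper coverage is needed for a size estimate")
    tail = {m: c for m, c in hist.counts.items() if m >= valley}
    if not tail:
        raise ValueError("no k-mers beyond the error valley")
    peak = valley + int(np.argmax(sm[valley:max_m + 1]))
    if peak < 4:
        raise ValueError(f"coverage peak at multiplicity {peak} (< 4) is too "
                         f"shallow for a reliable estimate")
    # refine the integer mode to the local centroid: robust to sparse or
    # comb-like spectra (e.g. exactly duplicated read sets)
    half = max(2, peak // 8)
    lo, hi = max(valley, peak - half), min(max_m, peak + half)
    ms = np.arange(lo, hi + 1)
    ws = raw[lo:hi + 1]
    d = float((ms * ws).sum() / ws.sum())
    total = sum(m * c for m, c in tail.items())
    return int(round(total / d))


def histogram_tsv(hist: KmerHistogram) -> str:
    """Two-column spectrum (multiplicity, distinct k-mers), plotter-ready."""
    lines = ["multiplicity\tcount"]
    for m in sorted(hist.counts):
        lines.append(f"{m}\t{hist.counts[m]}")
    return "\n".join(lines) + "\n"
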