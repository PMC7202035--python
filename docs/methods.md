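# Methods

This note documents the models, rules and numerical choices behind
`mapscaff`, the assumptions they rest on, and what the synthetic fixtures
do and do not demonstrate about real data.

## Data model and coordinates

An assembly is a list of named sequences over {A,C,G,T,N}.  All internal
coordinates are 0-based half-open; every emitted table and AGP file is
1-based inclusive.  Characters outside the alphabet (IUPAC ambiguity
codes) are coerced to N with a warning rather than rejected, since
third-party FASTA commonly contains them.

A scaffold decomposes into contigs separated by N runs.  Runs shorter
than `min_gap_run` (default 10 bp, the common AGP practice for
distinguishing gaps from ambiguous base calls) are absorbed into the
surrounding contig; leading/trailing runs belong to no contig.  The
decomposition is lossless: contigs plus recorded gap runs reconstruct the
scaffold exactly, which is what licenses "split only at gaps" curation.

## Statistics battery

N50 is the largest L such that sequences of length ≥ L hold at least half
the total bases, computed by descending cumulative sum.  GC content is
reported over called bases only.  Percent-of-genome reporting exposes
both half-up rounding (the convention of abstracts and most table cells)
and truncation, because published summaries mix the two; fold-coverage
(`read_depth`) uses floor division, the only convention consistent with
standard read-depth tables when checked against both platforms at once.
Length-class profiles bin scaffold lengths into `[e_i, e_{i+1})` classes
with a final open-ended class, reporting covered length and sequence
count per class plus percent helpers.

## Marker placement

Marker tags are short (~100 bp) genomic contexts of SNP markers.  The
internal aligner is exact k-mer seeding (default k = 15) over both
strands followed by ungapped evaluation of the full tag at each implied
offset — tags this short are not usefully gapped, and the acceptance
thresholds in the field are expressed only as identity and coverage.
Identity is percent matches over the aligned span, coverage the aligned
span over the tag length; both default to ≥90%.  Coverage is computed
against the marker (query), the standard BLAST usage for marker mapping.

Best-hit policy is strict: accepted hits on one scaffold within 100 bp
collapse to the best (tandem micro-repeats), and any remaining tie on the
top score across distinct loci orphans the marker.  A conservative
placement loses a few markers but avoids false anchors, which matter far
more downstream.  The BLAST outfmt-6 ingestion path applies the identical
thresholds and tie policy with bitscore as the score, so internal and
external placements are interchangeable.

## Local consistency filtering

Markers whose 1 kb-scale local order contradicts the map are discarded
before region building.  The rule is applied relative to each scaffold's
dominant trend (the sign of Kendall's tau between bp and cM of its
same-linkage-group placements): a uniformly decreasing scaffold is
reverse-oriented, not inconsistent, so only pairs within 1000 bp whose
sign product opposes the dominant trend count as conflicts.  Within a
conflicting pair the member with fewer trend-concordant neighbours (then
lower identity, then the later id) is dropped, and the rule re-runs to a
fixpoint.  An alternative reading of "inconsistent positions within
1000 bp" — a 1 kb merge radius during clustering — was considered and
rejected because it cannot express single rogue markers inside an
otherwise consistent run.

## Physical regions, anchoring, ordering, orientation

Placements on one scaffold, scanned in physical order, break into regions
when the linkage group changes, the physical gap exceeds `max_phys_gap`
(default 500 kb) or the genetic jump exceeds `max_cM_jump` (default
5 cM).  Published map-anchoring pipelines typically report only the outcome
of their clustering, not the rule, so both thresholds are configurable; the
defaults behave sensibly on synthetic data (one region per clean
scaffold at rice-like 4 cM/Mb recombination).  Regions with a single
marker or spanning under 1 kb are unreliable and dropped.

A scaffold's chromosome is the linkage group with the largest total
marker support; ties, or fewer than two supporting markers, leave it
unanchored, and any minority-group region raises a conflict flag (the
chimera candidate set).  The ordering key along a chromosome is the
marker-count-weighted median of the supporting regions' median cM —
median rather than mean so one mis-mapped region cannot drag a scaffold.
Orientation is the sign of Kendall's tau between bp and cM; scaffolds
with fewer than two distinct cM values (co-segregating markers) are
`unknown`, emitted as '+' in layouts but flagged, matching AGP practice
for unknown orientation.  Ordering ties break by descending scaffold
length then id, keeping builds deterministic.

## Chimera detection and correction

Adjacent kept regions on one scaffold define events: different linkage
groups → interchromosomal; same group but >`max_cM_span` (default 20 cM,
configurable — manual curation workflows rarely state a number) → distant intrachromosomal; an A–B–A pattern with concordant
outer regions → nested, with the inner region excised.  Breakpoints are
resolved to the inter-contig N gap nearest the midpoint of the interval
between the conflicting regions.  If the interval contains no gap the
event stays unresolved and the scaffold is only flagged — the toolkit
never cuts inside a contig, so called bases are never lost or
fabricated.  Splitting removes the gap Ns at the cut and names children
`<id>.1..k+1` with full provenance; nested inner segments become
independent children that re-enter anchoring on their own evidence
rather than being spliced into another scaffold.

The `chimeric_fraction` metric — percent of sequences whose
reference-alignment labels span ≥2 chromosomes — consumes labelings
produced elsewhere (e.g. whole-genome aligners); producing those
alignments is out of scope here.

## Pseudomolecules and AGP

Ordered, oriented scaffolds are joined with `gap_len` N spacers (default
100 bp; published pseudomolecule builds rarely state their joining gap
size, and assembly-level N counts are dominated by within-scaffold gaps).  Minus components are reverse-complemented.  Unanchored scaffolds
concatenate longest-first into `chrUn` with the same spacer.  AGP 2.1
rows alternate W (component) and U (gap: `scaffold/yes/map`) records;
the reader validates abutting object coordinates and component spans,
naming the offending row, and rebuilds objects bit-exactly — the
round-trip is property-tested over random layouts.

## Consensus polishing

Correction records follow VCF conventions (1-based, anchored-base
indels).  Classes: >1 ALT → `multiple` (correction accountings name
"multiple polymorphisms" without defining them; the multi-allelic
reading is implemented — the alternative, clustered MNPs, is noted as a
known open reading), else equal/longer/shorter ALT vs REF → SNP /
insertion / deletion.  Application verifies every REF against the
sequence, rejects overlapping records outright (reproducibility over
permissiveness), applies the first ALT of multi-allelic records
(deterministic haploid-consensus behaviour), and edits in descending
position order so coordinates stay valid.  The inverse route,
`diff_consensus`, re-derives an edit set by resynchronising original and
edited sequence on 20 bp anchor windows; it is exact when edit sites are
separated by more than the window and indels do not left-shift into
their context, which the variant simulator guarantees by construction.

## k-mer genome size

Canonical k-mers (lexicographic minimum of a window and its reverse
complement, 2-bit packed, k ≤ 32, default 25) are counted exactly and
in memory; windows containing N are skipped.  Reads are joined with an N
separator so one vectorised pass handles the whole set.  The estimator
finds the error valley — the first local minimum of the 3-bin-smoothed
spectrum, with the unobservable multiplicity-0 bin edge-padded — then
the coverage peak d as the modal multiplicity beyond the valley refined
to a local centroid (robust to sparse or comb-like spectra such as
exactly duplicated read sets), and returns Σ_{m ≥ valley} m·counts[m]/d.
Shallow or flat spectra (peak below multiplicity 4) raise an error
rather than returning a meaningless number.  No heterozygosity or repeat
mixture model is fitted; on a homozygous simulated genome the dominant
residual bias is true k-mers destroyed by read errors (≈3% at 1% error,
30×), which is within the method's expected envelope.

## Synthetic fixtures and their limits

The simulator emulates the study conditions the toolkit is tested under:
i.i.d. genomes at a stated GC (default 0.44, rice-like); Poisson marker
densities with cM = 4 × Mb (a typical rice recombination scale) plus
optional Gaussian cM noise clamped to stay monotone; fragmentation into
exponential-length scaffolds and contigs with N gap runs inserted (not
substituted, so non-N content is conserved exactly and truth
reconstruction is bit-exact); chimeric joins and nested insertions
placed at gaps with per-event truth; uniform reads with i.i.d.
substitution errors; and non-overlapping variant sets whose edited truth
is spliced independently of the consensus applier.  All randomness fans
out from one seed via stable per-fixture substreams, so fixtures are
byte-reproducible and adding one never perturbs another.

What passing these tests shows: the algorithms are coordinate-exact,
conservative where the evidence is ambiguous, and recover planted
structure perfectly under clean, dense-marker conditions and correctly
under moderate noise.  What they do not show: behaviour under real
repeat structure (segmental duplications create legitimate ambiguous
placements), real long-read error profiles (homopolymer indels, not
i.i.d. substitutions), heterozygosity in the k-mer spectrum, or genetic
maps with genotyping error beyond Gaussian cM noise.  Problem sizes in
the test and acceptance runs (0.3–1.5 Mb genomes, hundreds of markers,
10 estimator seeds at 500 kb/30×) were chosen as the smallest scales at
which every property is meaningfully exercised.

## Known limitations

* Single genetic map only; no multi-map weighted consensus ordering.
* No alignment-based chimera detection against an external reference.
* Orientation needs ≥2 distinct cM values; co-segregating scaffolds stay
  unknown and rely on curators.
* Exact in-memory k-mer counting is desk-scale; full sequencing runs of
  large genomes need disk-based counters.
* The minimal VCF reader deliberately ignores genotype and quality
  fields; records are assumed pre-filtered.
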