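# mapscaff

Genetic-map-guided scaffold anchoring and assembly finishing for draft
genome assemblies.

Hybrid assemblies of plant genomes (e.g. linked-read scaffolds merged with
nanopore contigs) arrive as a bag of scaffolds: long, but unordered,
unoriented, and contaminated with chimeric joins where the assembler fused
sequence from different chromosomes.  Given a genetic linkage map — markers
with a linkage group, a centimorgan position and a short tag sequence —
`mapscaff` performs the computational stages that turn such a draft into
chromosome pseudomolecules:

* **Marker placement** — seed-and-extend (or ingested BLAST tabular) mapping
  of marker tags onto scaffolds with ≥90% identity and ≥90% coverage
  thresholds and a strict unique-best-hit policy.
* **Physical regions and anchoring** — placements are clustered per scaffold
  into *physical regions* (maximal runs consistent in linkage group, with
  bounded physical gaps and genetic jumps); unreliable regions
  (single-marker, or spanning <1 kb) are dropped; scaffolds are assigned to
  the chromosome with majority marker support, ordered by the
  marker-weighted median cM, and oriented by the sign of the rank
  correlation between bp and cM.
* **Misassembly curation** — adjacent regions on one scaffold that disagree
  (different linkage groups, >20 cM apart, or an A–B–A nested pattern)
  define chimera events; scaffolds are split only inside inter-contig N
  gaps (the gap nearest the conflict midpoint), never inside a contig.
* **Pseudomolecules + AGP** — ordered, oriented scaffolds are joined with
  100 bp N spacers into one sequence per chromosome plus a concatenated
  `chrUn`; the layout is emitted as AGP 2.1 with a bit-exact round-trip.
* **Consensus polishing** — VCF-like correction records (SNP / insertion /
  deletion / multi-allelic) are verified against the sequence, applied with
  exact coordinate bookkeeping, and summarised per class.
* **k-mer genome size** — canonical 25-mer spectra; genome size =
  Σ_{m ≥ valley} m·counts[m] / d, where the valley is the first local
  minimum of the smoothed spectrum and d the coverage-peak depth.
* **Assembly statistics** — N50, GC excluding Ns, N content, length-class
  profiles, percent-of-genome and fold-coverage reporting.
* **Synthetic fixtures** — `mapscaff.simulate` generates genomes, maps,
  fragmented assemblies with injected chimeric/nested misassemblies, reads
  and variant sets, each with a ground-truth table, so the whole pipeline
  is testable without any external data.

## Worked example

Each script in `examples/` exercises one capability end to end.
`examples/02_place_and_anchor.py` simulates a 2×400 kb genome, fragments
it into scaffolds, and anchors them back:

```
177 markers placed, 2 orphaned (no hit, ambiguous locus, or tag spanning a gap)
24 physical regions kept, 7 dropped (single-marker or <1 kb)
chr01: 11 scaffolds anchored in genetic order (11 on their true chromosome); ...
chr02: 13 scaffolds anchored in genetic order (13 on their true chromosome); ...
0 scaffolds left unanchored (fewer than 2 supporting markers)
```

Every anchored scaffold lands on its true chromosome, in genetic order,
with its true orientation — the parameter-recovery property the test suite
asserts.  `examples/03_curate_chimeras.py` shows an injected
inter-chromosomal join being detected and split exactly inside its
junction gap with non-N bases conserved, and
`examples/06_genome_size.py` recovers a 200 kb genome within a few percent
from 30× reads at 1% error.

A thin CLI mirrors the library (`mapscaff stats|place|anchor|curate|build|
polish|kmersize|simulate`); run `mapscaff --help` for usage.

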