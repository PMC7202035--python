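"""Genetic-map loading and marker tag placement."""

import numpy as np
import pytest

from mapscaff import genetic_map as gm
from mapscaff.assembly_model import AssemblySeq, reverse_complement

from conftest import random_dna


class TestLoadGeneticMap:
    def _write(self, tmp_path, text, name="map.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_well_formed_sorted(self, tmp_path):
        p = self._write(tmp_path,
                        "marker_id\tlinkage_group\tcM\ttag_seq\n"
                        "m3\tchr1\t9.5\tACGTACGTACGTACGTACGT\n"
                        "m1\tchr1\t2.0\tACGTACGTACGTACGTACGT\n"
                        "m2\tchr2\t1.0\tACGTACGTACGTACGTACGT\n")
        markers = gm.load_genetic_map(p)
        assert [m.id for m in markers] == ["m1", "m3", "m2"]
        assert markers[0].genetic_pos == 2.0

    def test_duplicate_id_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "marker_id\tlinkage_group\tcM\n"
                        "m1\tchr1\t2.0\nm1\tchr1\t3.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            gm.load_genetic_map(p)

    def test_negative_cm_rejected(self, tmp_path):
        p = self._write(tmp_path,
                        "marker_id\tlinkage_group\tcM\nm1\tchr1\t-2.0\n")
        with pytest.raises(ValueError):
            gm.load_genetic_map(p)

    def test_missing_column_rejected(self, tmp_path):
        p = self._write(tmp_path, "marker_id\tcM\nm1\t2.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            gm.load_genetic_map(p)

    def test_csv_accepted(self, tmp_path):
        p = self._write(tmp_path,
                        "marker_id,linkage_group,cM\nm1,chr1,2.0\n", "m.csv")
        assert gm.load_genetic_map(p)[0].linkage_group == "chr1"


def _scaffold_with_tag(rng, tag, at, total=2000):
    seq = random_dna(rng, total)
    return AssemblySeq("s1", seq[:at] + tag + seq[at + len(tag):])


class TestPlaceMarkers:
    def test_verbatim_tag_exact_placement(self):
        rng = np.random.default_rng(10)
        tag = random_dna(rng, 100)
        scaf = _scaffold_with_tag(rng, tag, 700)
        m = gm.GeneticMarker("m1", "chr1", 1.0, tag)
        placements, orphans = gm.place_markers([m], [scaf])
        assert orphans == []
        p = placements[0]
        assert (p.scaffold_id, p.position, p.strand) == ("s1", 700, "+")
        assert p.identity == 100.0 and p.coverage == 100.0

    def test_two_substitutions_match_sliding_window_oracle(self):
        rng = np.random.default_rng(11)
        tag = random_dna(rng, 100)
        scaf = _scaffold_with_tag(rng, tag, 500)
        mutated = list(tag)
        for i in (10, 60):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        m = gm.GeneticMarker("m1", "chr1", 1.0, "".join(mutated))
        placements, orphans = gm.place_markers([m], [scaf])
        assert orphans == []
        p = placements[0]
        # brute-force sliding-window Hamming alignment over both strands
        best = max(
            ((pos, strand,
              sum(a == b for a, b in zip(q, scaf.seq[pos:pos + 100])))
             for strand, q in (("+", m.tag_seq),
                               ("-", reverse_complement(m.tag_seq)))
             for pos in range(len(scaf.seq) - 99)),
            key=lambda t: t[2])
        assert (p.position, p.strand) == (best[0], best[1])
        assert p.identity == pytest.approx(98.0)

    def test_duplicated_locus_is_orphan(self):
        rng = np.random.default_rng(12)
        tag = random_dna(rng, 100)
        seq = random_dna(rng, 500) + tag + random_dna(rng, 500) + tag \
            + random_dna(rng, 500)
        m = gm.GeneticMarker("m1", "chr1", 1.0, tag)
        placements, orphans = gm.place_markers([m], [AssemblySeq("s1", seq)])
        assert placements == [] and orphans == ["m1"]

    def test_below_identity_threshold_is_orphan(self):
        rng = np.random.default_rng(13)
        tag = random_dna(rng, 100)
        scaf = _scaffold_with_tag(rng, tag, 300)
        mutated = list(tag)
        for i in range(0, 33, 3):  # 11 substitutions -> identity 89 < 90
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        m = gm.GeneticMarker("m1", "chr1", 1.0, "".join(mutated))
        placements, orphans = gm.place_markers([m], [scaf])
        assert orphans == ["m1"]

    def test_short_tag_skipped_with_warning(self):
        m = gm.GeneticMarker("m1", "chr1", 1.0, "ACGT")
        with pytest.warns(UserWarning, match="shorter than"):
            placements, orphans = gm.place_markers(
                [m], [AssemblySeq("s1", "ACGT" * 100)])
        assert orphans == ["m1"]

    def test_own_tags_place_at_true_coordinates(self, small_genome, small_map):
        """Extracted tags (no mutations) all return home, strand '+'."""
        markers, truth = small_map
        sample = markers[::7]
        placements, orphans = gm.place_markers(sample, small_genome)
        placed = {p.marker_id: p for p in placements}
        for m in sample:
            if m.id in orphans:
                continue  # a tag duplicated by chance elsewhere
            p = placed[m.id]
            t = truth.markers[m.id]
            assert (p.scaffold_id, p.position) == (t["chrom"], t["tag_start"])
            assert p.strand == "+" and p.identity == 100.0
        assert len(placed) >= 0.95 * len(sample)

    def test_revcomp_tags_same_position_minus_strand(self, small_genome,
                                                     small_map):
        markers, truth = small_map
        sample = markers[:10]
        flipped = [gm.GeneticMarker(m.id, m.linkage_group, m.genetic_pos,
                                    reverse_complement(m.tag_seq))
                   for m in sample]
        fwd, _ = gm.place_markers(sample, small_genome)
        rev, _ = gm.place_markers(flipped, small_genome)
        fwd_by = {p.marker_id: p for p in fwd}
        for p in rev:
            q = fwd_by[p.marker_id]
            assert (p.scaffold_id, p.position) == (q.scaffold_id, q.position)
            assert {p.strand, q.strand} == {"+", "-"}


class TestLoadPlacements:
    HEADER_TAG = "ACGT" * 25

    def _markers(self):
        return [gm.GeneticMarker("m1", "chr1", 1.0, self.HEADER_TAG),
                gm.GeneticMarker("m2", "chr1", 2.0, self.HEADER_TAG)]

    def _hit(self, qid="m1", sid="s1", pident=95.0, length=95,
             sstart=101, send=195, bitscore=180.0):
        return (f"{qid}\t{sid}\t{pident}\t{length}\t2\t0\t1\t{length}\t"
                f"{sstart}\t{send}\t1e-40\t{bitscore}")

    def test_passing_hit_accepted(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._hit() + "\n")
        placements, orphans = gm.load_placements(p, self._markers())
        assert [pl.marker_id for pl in placements] == ["m1"]
        assert placements[0].position == 100  # 0-based
        assert orphans == ["m2"]

    def test_identity_below_threshold_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._hit(pident=89.9) + "\n")
        placements, orphans = gm.load_placements(p, self._markers())
        assert placements == [] and set(orphans) == {"m1", "m2"}

    def test_minus_strand_from_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._hit(sstart=195, send=101) + "\n")
        placements, _ = gm.load_placements(p, self._markers())
        assert placements[0].strand == "-"
        assert placements[0].position == 100

    def test_equal_bitscore_two_scaffolds_is_orphan(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._hit(sid="s1") + "\n" + self._hit(sid="s2") + "\n")
        placements, orphans = gm.load_placements(p, self._markers())
        assert "m1" in orphans and placements == []

    def test_unknown_marker_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self._hit(qid="mystery") + "\n")
        with pytest.raises(ValueError, match="unknown marker"):
            gm.load_placements(p, self._markers())

    def test_agrees_with_internal_search(self, tmp_path, small_genome,
                                         small_map):
        """Feeding place_markers' own hits through the tabular path yields
        the same accepted/orphan split."""
        markers, _ = small_map
        sample = [m for m in markers[::11]]
        index = gm.ScaffoldIndex(small_genome, 15)
        hits = []
        for m in sample:
            hits.extend(gm.search_tag(m.id, m.tag_seq, index, 90, 90))
        p = tmp_path / "hits.tsv"
        p.write_text(gm.hits_to_blast6(hits, {m.id: len(m.tag_seq)
                                              for m in sample}))
        direct, orphans_direct = gm.place_markers(sample, small_genome)
        loaded, orphans_loaded = gm.load_placements(p, sample)
        assert {x.marker_id for x in direct} == {x.marker_id for x in loaded}
        assert set(orphans_direct) == set(orphans_loaded)
        d = {x.marker_id: x for x in direct}
        for pl in loaded:
            assert (pl.scaffold_id, pl.position, pl.strand) == \
                (d[pl.marker_id].scaffold_id, d[pl.marker_id].position,
                 d[pl.marker_id].strand)
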