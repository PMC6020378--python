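"""PAM scanning, candidate enumeration and pair-dataset assembly.

The scan and enumeration are verified against a deliberately naive
brute-force oracle (character loops over both strands); a larger seeded
genome receives the same treatment in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from guidenet.encoder import (GUIDE_LEN, NUCLEOTIDES, GuideSequence,
                              reverse_complement)
from guidenet.offtarget import (assemble_pair_dataset, enumerate_candidates,
                                mismatch_profile, scan_pam_sites,
                                split_leave_guides_out)
from .conftest import random_guide_sequence


def brute_force_pam_sites(genome):
    """Oracle: per-window character checks on both strands."""
    sites = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for i in range(len(seq) - GUIDE_LEN + 1):
            window = seq[i: i + GUIDE_LEN]
            if "N" in window:
                continue
            if window[21:23] == "GG":
                sites.append((chrom, i, "+", window))
            rc = reverse_complement(window)
            if rc[21:23] == "GG":
                sites.append((chrom, i, "-", rc))
    return sites


class TestScan:
    def test_single_planted_tgg_site(self):
        seq = "A" * 20 + "TGG" + "AA"  # only offset 0 carries ..TGG
        sites = scan_pam_sites({"chr1": seq})
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].sequence23) == (0, "A" * 20 + "TGG")

    def test_too_short_sequence_gives_empty_stream(self):
        assert scan_pam_sites({"chr1": "ACGT" * 5}) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_pam_sites({})

    def test_windows_with_n_skipped_and_counted(self):
        seq = "A" * 10 + "N" + "A" * 9 + "TGG"
        sites, report = scan_pam_sites({"chr1": seq}, return_report=True)
        assert sites == []
        assert report["windows_skipped_n"] >= 1

    def test_matches_brute_force_oracle_both_strands(self, small_genome):
        sites = scan_pam_sites(small_genome)
        got = [(s.chrom, s.start, s.strand, s.sequence23) for s in sites]
        assert sorted(got) == sorted(brute_force_pam_sites(small_genome))

    def test_strand_symmetry_under_reverse_complement(self, small_genome):
        chrom, seq = next(iter(small_genome.items()))
        sites = scan_pam_sites({chrom: seq})
        flipped = scan_pam_sites({chrom: reverse_complement(seq)})
        L = len(seq)
        remapped = sorted((L - s.end, "-" if s.strand == "+" else "+",
                           s.sequence23) for s in flipped)
        assert remapped == sorted((s.start, s.strand, s.sequence23)
                                  for s in sites)


class TestMismatchProfile:
    def test_identical_strings_empty_profile(self, rng):
        g = random_guide_sequence(rng)
        assert mismatch_profile(g.sequence, g.sequence) == []

    def test_single_g_to_c_substitution_at_16(self, rng):
        g = "G" * 21 + "GG"
        site = g[:15] + "C" + g[16:]
        assert mismatch_profile(g, site) == [(16, "G", "C")]

    def test_profile_length_equals_direct_hamming(self, rng):
        for _ in range(25):
            a = random_guide_sequence(rng).sequence
            b = random_guide_sequence(rng).sequence
            direct = sum(x != y for x, y in zip(a[:20], b[:20]))
            assert len(mismatch_profile(a, b)) == direct

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_profile("ACGT", "ACGT")


class TestEnumerate:
    def test_planted_guide_found_at_zero_mismatches(self, rng):
        guide = random_guide_sequence(rng)
        genome_seq = ("T" * 200 + guide.sequence[:20] + "AGG" + "T" * 200)
        cands = enumerate_candidates(
            GuideSequence(guide.sequence[:20] + "AGG"), {"chr1": genome_seq},
            max_mm=0)
        assert any(c.mismatch_count == 0 and c.site.start == 200
                   for c in cands)

    def test_max_mm_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            enumerate_candidates(random_guide_sequence(rng), {"chr1": "A" * 30},
                                 max_mm=7)

    def test_strata_match_brute_force(self, small_genome, rng):
        guide = random_guide_sequence(rng)
        cands = enumerate_candidates(guide, small_genome, max_mm=6)
        # oracle: distances over all brute-force PAM sites
        counts = np.zeros(7, int)
        for _, _, _, seq23 in brute_force_pam_sites(small_genome):
            d = sum(x != y for x, y in zip(guide.sequence[:20], seq23[:20]))
            if d <= 6:
                counts[d] += 1
        got = np.zeros(7, int)
        for c in cands:
            got[c.mismatch_count] += 1
            assert len(c.mismatch_profile) == c.mismatch_count
        assert np.array_equal(got, counts)


class TestAssembly:
    def _setup(self, rng, n_candidates=20):
        guide = random_guide_sequence(rng)
        genome_seq = "T" * 100 + guide.sequence[:20] + "AGG" + "T" * 2000
        genome = {"chr1": genome_seq}
        cands = enumerate_candidates(guide, genome, max_mm=6)
        return guide, cands

    def test_single_detection_among_candidates(self, rng):
        guide, cands = self._setup(rng)
        assert cands
        hit = cands[0].site
        det = pd.DataFrame([{"guide_id": "g1", "chrom": hit.chrom,
                             "start": hit.start, "strand": hit.strand,
                             "assay": "synthetic-detect",
                             "indel_frequency": 0.12}])
        records, unmatched = assemble_pair_dataset({"g1": guide},
                                                   {"g1": cands}, det)
        labels = [r.detected for r in records]
        assert sum(labels) == 1 and len(records) == len(cands)
        pos = records[labels.index(1)]
        assert pos.indel_frequency == 0.12 and pos.assay == "synthetic-detect"
        assert not unmatched

    def test_empty_detection_table_all_negative(self, rng):
        guide, cands = self._setup(rng)
        records, unmatched = assemble_pair_dataset({"g1": guide}, {"g1": cands})
        assert all(r.detected == 0 for r in records) and not unmatched

    def test_duplicate_detection_rows_single_positive(self, rng):
        guide, cands = self._setup(rng)
        hit = cands[0].site
        row = {"guide_id": "g1", "chrom": hit.chrom, "start": hit.start,
               "strand": hit.strand, "assay": "a", "indel_frequency": 0.2}
        records, _ = assemble_pair_dataset({"g1": guide}, {"g1": cands},
                                           pd.DataFrame([row, row]))
        assert sum(r.detected for r in records) == 1

    def test_unmatched_detection_reported_not_dropped(self, rng):
        guide, cands = self._setup(rng)
        det = pd.DataFrame([{"guide_id": "g1", "chrom": "chr9", "start": 1,
                             "strand": "+", "assay": "a",
                             "indel_frequency": 0.3}])
        records, unmatched = assemble_pair_dataset({"g1": guide},
                                                   {"g1": cands}, det)
        assert len(unmatched) == 1 and unmatched[0]["chrom"] == "chr9"
        assert sum(r.detected for r in records) == 0


class TestLeaveGuidesOut:
    def _records(self, rng, n_guides=10, per_guide=6):
        from guidenet.offtarget import OffTargetPairRecord
        from guidenet.encoder import EncodedPair, encode_guide
        recs = []
        for g in range(n_guides):
            guide = random_guide_sequence(rng)
            pair = encode_guide(guide)
            for _ in range(per_guide):
                recs.append(OffTargetPairRecord(
                    pair=EncodedPair(pair, pair), detected=0,
                    guide_id=f"sg{g:02d}"))
        return recs

    def test_held_out_guides_entirely_in_test(self, rng):
        recs = self._records(rng)
        train, test = split_leave_guides_out(recs, k_guides=3, seed=5)
        test_ids = {r.guide_id for r in test}
        assert len(test_ids) == 3
        assert not test_ids & {r.guide_id for r in train}
        assert len(train) + len(test) == len(recs)

    def test_leave_one_guide_out(self, rng):
        recs = self._records(rng, n_guides=4)
        _, test = split_leave_guides_out(recs, k_guides=1, seed=5)
        assert len({r.guide_id for r in test}) == 1

    def test_k_too_large_rejected(self, rng):
        recs = self._records(rng, n_guides=3)
        with pytest.raises(ValueError):
            split_leave_guides_out(recs, k_guides=3, seed=0)
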