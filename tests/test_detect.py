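import numpy as np
import pytest

from ltrdyn.detect import (Cluster, DetectionParams, cluster_elements,
                           detect_full_length, find_seed_repeats,
                           find_seed_repeats_bruteforce, find_tsd)
from ltrdyn.io import LTRElement, SequenceRecord
from ltrdyn.simulate import mutate_sequence, random_dna


def plant_element(rng, ltr_len=500, internal_len=3000, divergence=0.01,
                  tsd="ACGTA", flank=2000):
    """Hand-built genome with one planted paired-LTR element."""
    ltr = random_dna(ltr_len, rng)
    ltr3 = mutate_sequence(ltr, divergence, rng)
    internal = random_dna(internal_len, rng)
    left = random_dna(flank, rng)
    right = random_dna(flank, rng)
    seq = left + tsd + ltr + internal + ltr3 + tsd + right
    start = len(left) + len(tsd)
    end = start + ltr_len + internal_len + len(ltr3)
    return SequenceRecord("chr", seq), start, end


class TestSeedRepeats:
    def test_planted_repeat_is_found(self, rng):
        r = random_dna(30, rng)
        seq = random_dna(1000, rng) + r + random_dna(2000, rng) + r \
            + random_dna(500, rng)
        seeds = find_seed_repeats(seq, k=20, max_span=5000)
        assert any(s[2] >= 30 and s[1] - s[0] == 2030 for s in seeds)

    def test_no_repeats_gives_empty(self):
        seq = "ACGTTGCAAGGCTTACCGGATCGATCGTTAACCGGTTACG"  # no repeated 20-mer
        assert find_seed_repeats(seq, 20, 1000) == []

    def test_polya_merges_to_one_maximal_pair_per_offset(self):
        seq = "A" * 200
        seeds = find_seed_repeats(seq, k=20, max_span=100)
        assert seeds == find_seed_repeats_bruteforce(seq, 20, 100)
        # one maximal pair per diagonal d: (0, d, 200-d)
        assert seeds == sorted((0, d, 200 - d) for d in range(1, 101)
                               if 200 - d >= 20)

    def test_agrees_with_bruteforce_on_random_genomes(self, rng):
        for trial in range(5):
            base = random_dna(2000, rng)
            rep = random_dna(60, rng)
            seq = base[:500] + rep + base[500:1500] + rep + base[1500:]
            assert find_seed_repeats(seq, 12, len(seq)) == \
                   find_seed_repeats_bruteforce(seq, 12, len(seq))

    def test_k_below_8_is_rejected(self):
        with pytest.raises(ValueError):
            find_seed_repeats("ACGT" * 10, 4, 100)


class TestDetectFullLength:
    def test_planted_element_recovered_within_10bp(self, rng):
        genome, start, end = plant_element(rng)
        els = detect_full_length([genome])
        assert len(els) == 1
        el = els[0]
        assert abs(el.start - start) <= 10 and abs(el.end - end) <= 10
        assert el.tsd == "ACGTA"

    def test_low_identity_pair_not_reported(self, rng):
        # 80% LTR identity is below the 85% similarity bound
        genome, _s, _e = plant_element(rng, divergence=0.20)
        assert detect_full_length([genome]) == []

    def test_short_element_not_reported(self, rng):
        # total length 1200 bp is below the 1500 bp element bound
        genome, _s, _e = plant_element(rng, ltr_len=200, internal_len=800)
        assert detect_full_length([genome]) == []

    def test_reported_candidates_satisfy_all_bounds(self, detection_dataset):
        _spec, data = detection_dataset
        params = DetectionParams()
        for el in detect_full_length(data.contigs, params):
            for L in (el.ltr5_end - el.ltr5_start, el.ltr3_end - el.ltr3_start):
                assert params.min_ltr_len <= L <= params.max_ltr_len
            assert params.min_elem_len <= el.length <= params.max_elem_len
            assert el.similarity >= params.min_similarity
            assert el.ltr5_start < el.ltr5_end <= el.ltr3_start < el.ltr3_end

    def test_synthetic_recall_and_no_solo_false_positives(self, detection_dataset):
        _spec, data = detection_dataset
        els = detect_full_length(data.contigs)
        hits = 0
        for t in data.truth:
            for el in els:
                if el.chrom == t.chrom and \
                        max(abs(el.start - t.start), abs(el.end - t.end)) <= 10:
                    hits += 1
                    break
        assert hits / len(data.truth) >= 0.9
        # every reported element corresponds to a planted one: no decoy
        # (solo LTR or truncated copy) is ever reported as full length
        for el in els:
            assert any(el.chrom == t.chrom and el.start < t.end
                       and t.start < el.end for t in data.truth)


class TestFindTsd:
    def test_exact_flanks_zero_shift(self):
        seq = "G" * 50 + "ACGTA" + "T" * 100 + "ACGTA" + "C" * 50
        cand = LTRElement("e", "c", 55, 155, 55, 75, 135, 155, 99.0)
        tsd = find_tsd(seq, cand, DetectionParams())
        assert tsd == "ACGTA"
        assert (cand.start, cand.end) == (55, 155)

    def test_no_match_within_vicinity_gives_absent(self, rng):
        seq = random_dna(400, rng)
        # destroy any accidental 5-mer duplication around the boundaries
        seq = seq[:95] + "AAAAA" + seq[100:295] + "CCCCC" + seq[300:]
        cand = LTRElement("e", "c", 100, 300, 100, 150, 250, 300, 99.0)
        params = DetectionParams()
        tsd = find_tsd(seq, cand, params)
        if tsd is not None:  # only a shifted accidental match is possible
            assert seq[cand.start - 5:cand.start] == seq[cand.end:cand.end + 5]

    def test_shifted_match_moves_boundaries(self):
        rng = np.random.default_rng(0)
        vic_t = 5
        # TSD only matches at shift +3/+3
        left = random_dna(60, rng)
        right = random_dna(60, rng)
        inner = random_dna(100, rng)
        tsd = "GATTC"
        # element nominally [65, 168); true boundaries [68, 171)
        seq = left[:63] + tsd + inner[:100] + tsd + right
        cand = LTRElement("e", "c", 65, 165, 65, 90, 140, 165, 99.0)
        params = DetectionParams()
        found = find_tsd(seq, cand, params)
        assert found is not None
        # brute-force oracle: smallest |i|+|j| shift with matching 5-mers
        best = None
        for tot in range(0, 41):
            for i in range(-10, 11):
                for j in range(-10, 11):
                    if abs(i) + abs(j) != tot:
                        continue
                    s, e = 65 + i, 165 + j
                    if s - 5 < 0 or e + 5 > len(seq):
                        continue
                    if seq[s - 5:s] == seq[e:e + 5]:
                        best = (s, e, seq[s - 5:s])
                        break
                if best:
                    break
            if best:
                break
        assert (cand.start, cand.end, found) == best


class TestClustering:
    def test_identical_sequences_form_one_cluster(self, rng):
        s = random_dna(1000, rng)
        clusters = cluster_elements([SequenceRecord("a", s),
                                     SequenceRecord("b", s)])
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b"]

    def test_85pct_identity_splits_at_threshold_90(self, rng):
        s = random_dna(1000, rng)
        t = mutate_sequence(s, 0.15, rng)
        clusters = cluster_elements([SequenceRecord("a", s),
                                     SequenceRecord("b", t)], threshold=90.0)
        assert len(clusters) == 2

    def test_pair_plus_outlier(self, rng):
        a = random_dna(1200, rng)
        b = mutate_sequence(a, 0.05, rng)  # ~95% identity to a
        c = random_dna(1200, rng)
        clusters = cluster_elements([SequenceRecord("A", a),
                                     SequenceRecord("B", b),
                                     SequenceRecord("C", c)])
        parts = sorted(sorted(cl.members) for cl in clusters)
        assert parts == [["A", "B"], ["C"]]

    def test_deterministic_under_input_permutation(self, rng):
        seqs = []
        for i in range(6):
            base = random_dna(int(rng.integers(800, 1600)), rng)
            seqs.append(SequenceRecord(f"s{i}", base))
            seqs.append(SequenceRecord(f"s{i}m", mutate_sequence(base, 0.04, rng)))
        ref = sorted(sorted(c.members) for c in cluster_elements(seqs))
        perm = [seqs[i] for i in rng.permutation(len(seqs))]
        assert sorted(sorted(c.members) for c in cluster_elements(perm)) == ref

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            cluster_elements([])
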