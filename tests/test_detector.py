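"""Structural LTR detection: candidate pairs, validation, genome-wide calls."""

import numpy as np
import pytest
from Bio import Align

from palm_ltr.detector import (DetectorParams, Rejection, detect,
                               find_candidate_pairs, validate_element)
from palm_ltr.mutation import mutate, random_sequence
from palm_ltr.synthetic import ElementSpec, build_element, generate_background


def _planted_repeat(repeat_len=500, spacer=4000, divergence=0.0, seed=0):
    rng = np.random.default_rng(seed)
    left = random_sequence(3000, 0.45, rng)
    right = random_sequence(3000, 0.45, rng)
    ltr = random_sequence(repeat_len, 0.45, rng)
    ltr2 = mutate(ltr, divergence, 2.0, rng) if divergence else ltr
    inner = random_sequence(spacer, 0.45, rng)
    seq = left + ltr + inner + ltr2 + right
    a = (3000, 3000 + repeat_len)
    b = (a[1] + spacer, a[1] + spacer + repeat_len)
    return seq, a, b


class TestCandidatePairs:
    def test_exact_repeat_found_with_exact_coordinates(self):
        seq, a, b = _planted_repeat()
        cands = find_candidate_pairs(seq)
        assert len(cands) == 1
        c = cands[0]
        assert c.identity == 1.0
        assert abs(c.ltr5[0] - a[0]) <= 2 and abs(c.ltr5[1] - a[1]) <= 2
        assert abs(c.ltr3[0] - b[0]) <= 2 and abs(c.ltr3[1] - b[1]) <= 2

    def test_diverged_repeat_identity_matches_alignment_oracle(self):
        seq, a, b = _planted_repeat(divergence=0.10, seed=3)
        cands = find_candidate_pairs(seq)
        assert len(cands) == 1
        c = cands[0]
        aligner = Align.PairwiseAligner()       # full unbanded DP oracle
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -1.0
        aln = aligner.align(seq[c.ltr5[0]:c.ltr5[1]],
                            seq[c.ltr3[0]:c.ltr3[1]])[0]
        sa, sb = str(aln[0]), str(aln[1])
        ident = sum(x == y and x != "-" for x, y in zip(sa, sb)) / len(sa)
        assert abs(c.identity - ident) <= 0.03

    def test_random_sequence_yields_no_credible_candidates(self):
        seq = generate_background(100_000, seed=11)
        cands = find_candidate_pairs(seq)
        assert not [c for c in cands
                    if c.identity >= 0.8 and c.ltr5[1] - c.ltr5[0] >= 100]

    def test_short_sequence_returns_empty(self):
        assert find_candidate_pairs("ACGT" * 30) == []

    def test_inconsistent_params_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_pairs("A" * 5000,
                                 DetectorParams(min_ltr=500, max_ltr=100))


class TestValidation:
    def test_oversized_element_rejected_as_too_long(self):
        seq, _, _ = _planted_repeat(repeat_len=800, spacer=11_500)
        cands = find_candidate_pairs(seq, DetectorParams(max_span=14_000))
        assert len(cands) == 1
        res = validate_element(cands[0], seq,
                               DetectorParams(max_span=14_000))
        assert isinstance(res, Rejection) and res.reason == "too_long"

    def test_low_identity_rejected(self):
        seq, _, _ = _planted_repeat(divergence=0.10, seed=5)
        cands = find_candidate_pairs(seq)
        res = validate_element(cands[0], seq,
                               DetectorParams(min_identity=0.99))
        assert isinstance(res, Rejection) and res.reason == "low_identity"

    def test_planted_element_accepted_with_exact_tsd(self, trna_library):
        truth = build_element(ElementSpec(tsd_length=5), 8)
        rng = np.random.default_rng(88)
        left = random_sequence(2000, 0.45, rng)
        right = random_sequence(2000, 0.45, rng)
        tsd = "ACGTA"
        seq = left + tsd + truth.sequence + tsd + right
        cands = find_candidate_pairs(seq)
        assert len(cands) == 1
        res = validate_element(cands[0], seq, trna_lib=trna_library)
        assert not isinstance(res, Rejection)
        assert res.tsd == tsd
        assert res.start == 2005 and res.end == 2005 + len(truth.sequence)
        assert res.pbs is not None and res.ppt is not None

    def test_coordinates_outside_sequence_error(self):
        seq, _, _ = _planted_repeat()
        cands = find_candidate_pairs(seq)
        cands[0].ltr3 = (len(seq), len(seq) + 500)
        with pytest.raises(ValueError):
            validate_element(cands[0], seq)


class TestDetect:
    def test_empty_genome(self):
        elements, report = detect({})
        assert elements == [] and report.n_candidates == 0

    def test_recovers_planted_elements_with_tight_boundaries(self,
                                                             small_study):
        elements, _ = detect(small_study.genome)
        recovered = 0
        for t in small_study.elements:
            for e in elements:
                if e.scaffold == t.scaffold and abs(e.start - t.start) <= 5 \
                        and abs(e.end - t.end) <= 5:
                    recovered += 1
                    break
        assert recovered >= 0.9 * len(small_study.elements)

    def test_invariant_to_scaffold_order_and_line_wrapping(self, tmp_path,
                                                           small_study):
        from palm_ltr.io import read_fasta
        genome = small_study.genome
        p = tmp_path / "wrapped.fa"
        with open(p, "w") as fh:          # reversed order, 37-column wrap
            for name in sorted(genome, reverse=True):
                fh.write(f">{name}\n")
                seq = genome[name]
                for i in range(0, len(seq), 37):
                    fh.write(seq[i:i + 37] + "\n")
        reloaded = read_fasta(p)
        a, _ = detect(genome)
        b, _ = detect(reloaded)
        key = [(e.scaffold, e.start, e.end, round(e.identity, 6))
               for e in a]
        assert key == [(e.scaffold, e.start, e.end, round(e.identity, 6))
                       for e in b]

    def test_overlapping_calls_resolved_to_one(self):
        # two copies of the same LTR produce nested repeat interpretations
        rng = np.random.default_rng(21)
        ltr = random_sequence(400, 0.45, rng)
        seq = random_sequence(2000, 0.45, rng) + ltr + \
            random_sequence(1500, 0.45, rng) + ltr + \
            random_sequence(1500, 0.45, rng) + ltr + \
            random_sequence(2000, 0.45, rng)
        elements, _ = detect({"s": seq})
        for i, e1 in enumerate(elements):
            for e2 in elements[i + 1:]:
                assert not (e1.start < e2.end and e2.start < e1.end)

    def test_no_false_positives_on_random_sequence(self):
        for seed in (101, 102):
            genome = {"r": generate_background(200_000, seed=seed)}
            elements, _ = detect(genome)
            assert elements == []

    def test_accepted_elements_respect_length_and_identity_bounds(
            self, small_study):
        params = DetectorParams()
        elements, _ = detect(small_study.genome, params)
        assert elements
        for e in elements:
            assert e.length <= params.max_element_length
            assert e.identity >= params.min_identity
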