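"""Synthetic-genome generator: backgrounds, elements, planting, reads."""

import numpy as np
import pytest
from scipy.linalg import expm

from palm_ltr.dating import date_element
from palm_ltr.synthetic import (ElementSpec, build_element,
                                generate_background, plant_elements,
                                simulate_reads)


class TestBackground:
    def test_no_n_when_fraction_zero(self):
        seq = generate_background(1000, n_run_fraction=0.0, seed=1)
        assert len(seq) == 1000 and "N" not in seq

    def test_gc_within_binomial_noise(self):
        n = 1_000_000
        seq = generate_background(n, gc=0.5, seed=2)
        gc = (seq.count("G") + seq.count("C")) / n
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_deterministic(self):
        assert generate_background(5000, seed=3) == \
            generate_background(5000, seed=3)

    def test_n_runs_cover_requested_fraction(self):
        seq = generate_background(200_000, n_run_fraction=0.2, seed=4)
        assert abs(seq.count("N") / len(seq) - 0.2) < 0.03

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0)


class TestBuildElement:
    def test_zero_divergence_gives_identical_ltrs(self):
        t = build_element(ElementSpec(divergence_age=0.0), 1)
        assert t.sequence[t.ltr5[0]:t.ltr5[1]] == \
            t.sequence[t.ltr3[0]:t.ltr3[1]]

    def test_total_length_invariant(self):
        spec = ElementSpec(ltr_length=400, internal_length=3500)
        t = build_element(spec, 2)
        assert len(t.sequence) == spec.total_length

    def test_gag_only_element_is_non_autonomous(self):
        spec = ElementSpec(superfamily="NA", domain_list=("GAG",),
                           internal_length=1000)
        assert spec.truth_superfamily == "NA"

    def test_na_with_rt_rejected(self):
        with pytest.raises(ValueError):
            ElementSpec(superfamily="NA", domain_list=("GAG", "RT"))

    def test_domains_too_long_for_internal_rejected(self):
        with pytest.raises(ValueError):
            build_element(ElementSpec(internal_length=500), 3)

    def test_ltr_divergence_matches_k2p_expectation(self):
        """Observed LTR mismatch fraction agrees with the substitution model.

        The oracle computes the expected mismatch fraction from the matrix
        exponential of the K2P rate generator — an independent route from
        the closed forms used by the simulator.
        """
        k, ts_tv, L, reps = 0.10, 2.0, 1000, 100
        alpha = k * ts_tv / (ts_tv + 1.0)
        beta = k / (2.0 * (ts_tv + 1.0))
        # rows/cols A,G,C,T: transitions A<->G and C<->T at rate alpha
        q = np.array([[0, alpha, beta, beta],
                      [alpha, 0, beta, beta],
                      [beta, beta, 0, alpha],
                      [beta, beta, alpha, 0]], dtype=float)
        np.fill_diagonal(q, -q.sum(axis=1))
        p_mat = expm(q)
        expected_mismatch = 1.0 - np.mean(np.diag(p_mat))
        obs = []
        for seed in range(reps):
            spec = ElementSpec(divergence_age=k, ltr_length=L,
                               internal_length=200, superfamily="NA",
                               domain_list=(), has_pbs=False, has_ppt=False,
                               tg_ca=False)
            t = build_element(spec, seed)
            a = t.sequence[t.ltr5[0]:t.ltr5[1]]
            b = t.sequence[t.ltr3[0]:t.ltr3[1]]
            obs.append(np.mean([x != y for x, y in zip(a, b)]))
        sd = np.sqrt(expected_mismatch * (1 - expected_mismatch) / (L * reps))
        assert abs(np.mean(obs) - expected_mismatch) < 3 * sd

    def test_dating_recovers_planted_divergence(self):
        ks = []
        for seed in range(40):
            spec = ElementSpec(divergence_age=0.10, ltr_length=1000,
                               internal_length=200, superfamily="NA",
                               domain_list=(), has_pbs=False, has_ppt=False,
                               tg_ca=False)
            t = build_element(spec, seed)
            est = date_element("e", t.sequence[t.ltr5[0]:t.ltr5[1]],
                               t.sequence[t.ltr3[0]:t.ltr3[1]])
            ks.append(est.k)
        assert abs(np.mean(ks) - 0.10) / 0.10 < 0.05


class TestPlanting:
    def test_truth_coordinates_match_string_search(self, small_study):
        sg = small_study
        for e in sg.elements[:3]:
            seq = sg.genome[e.scaffold]
            assert seq[e.start:e.end] == e.truth.sequence
            assert seq.index(e.truth.sequence) == e.start

    def test_tsd_flanks_identical(self, small_study):
        for e in small_study.elements:
            seq = small_study.genome[e.scaffold]
            t = e.truth.spec.tsd_length
            assert seq[e.start - t:e.start] == seq[e.end:e.end + t] == e.tsd

    def test_elements_do_not_overlap(self, small_study):
        by_scaffold = {}
        for e in small_study.elements:
            by_scaffold.setdefault(e.scaffold, []).append((e.start, e.end))
        for ivs in by_scaffold.values():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_reconstruction_of_planted_sequences(self, small_study):
        rebuilt = "".join(
            small_study.genome[e.scaffold][e.start:e.end]
            for e in small_study.elements)
        original = "".join(e.truth.sequence for e in small_study.elements)
        assert rebuilt == original

    def test_copia_avoids_gene_dense_windows(self):
        bg = {"s": generate_background(2_000_000, seed=9)}
        specs = [ElementSpec(superfamily="Copia", internal_length=3000,
                             ltr_length=300) for _ in range(40)]
        sg = plant_elements(bg, specs, placement_bias=0.95, seed=10,
                            n_genes=120)
        length = len(sg.genome["s"])
        win = 200_000
        edges = np.arange(0, length + win, win)
        copia = np.histogram([e.start for e in sg.elements], bins=edges)[0]
        genes = np.histogram([g[1] for g in sg.genes], bins=edges)[0]
        assert np.corrcoef(copia, genes)[0, 1] < 0

    def test_insufficient_room_reports_unplaced(self):
        bg = {"s": generate_background(10_000, seed=1)}
        specs = [ElementSpec(internal_length=3000) for _ in range(5)]
        with pytest.raises(ValueError, match="insufficient room"):
            plant_elements(bg, specs, seed=2)


class TestReads:
    def _library(self):
        return {f"E{i}": generate_background(2000, seed=50 + i)
                for i in range(2)}

    def test_error_free_reads_are_substrings(self):
        lib = self._library()
        reads = simulate_reads(lib, {"E0": 1.0}, read_length=80,
                               n_reads=200, error_rate=0.0, seed=1)
        assert all(seq in lib["E0"] for _, seq, _ in reads)

    def test_nine_to_one_levels_recovered(self):
        lib = self._library()
        reads = simulate_reads(lib, {"E0": 9.0, "E1": 1.0}, read_length=80,
                               n_reads=10_000, error_rate=0.0, seed=2)
        n0 = sum(1 for rid, _, _ in reads if rid.endswith("E0"))
        sd = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(n0 - 9000) < 3 * sd

    def test_same_seed_reproduces_reads(self):
        lib = self._library()
        args = (lib, {"E0": 2.0, "E1": 1.0}, 80, 500, 0.01)
        assert simulate_reads(*args, seed=7) == simulate_reads(*args, seed=7)

    def test_zero_total_level_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads(self._library(), {"E0": 0.0}, 80, 100)
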