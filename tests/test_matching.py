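import numpy as np
import pytest

import homospec as hs
from homospec.masses import WATER
from homospec.matching import SearchConfig, _candidate_ranges
from homospec._kernels import score_protein
from homospec.model import (
    DeconvolutedSpectrum,
    Modification,
    ProteinRecord,
    ProteomeDB,
    Proteoform,
)

from conftest import naive_one_shift


def spectrum_of(precursor, frags, sid="S"):
    return DeconvolutedSpectrum(sid, precursor, np.sort(np.asarray(frags, float)))


class TestLadders:
    def test_prefix_masses_examples(self):
        assert hs.prefix_masses("GG").round(5).tolist() == [57.02146]
        pm = hs.prefix_masses("EPPLSQETFS")
        assert pm.size == 9
        assert pm[4] - pm[3] == pytest.approx(87.03203, abs=1e-5)
        assert hs.prefix_masses("A").size == 0
        assert (np.diff(pm) > 0).all()

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            hs.prefix_masses("AXB")

    def test_unmodified_equals_prefix_ladder(self):
        seg = "EPPLSQETFS"
        np.testing.assert_allclose(
            hs.theoretical_fragments(seg, None, ("N",)), hs.prefix_masses(seg)
        )

    def test_series_sizes(self):
        seg = "EPPLSQETFS"
        assert hs.theoretical_fragments(seg, None, ("N",)).size == 9
        assert hs.theoretical_fragments(seg, None, ("N", "C")).size == 18

    def test_phospho_shift_matches_printed_value(self):
        """N-terminal fragments spanning the phosphoserine move by 79.97 Da."""
        seg = "EPPLSQETFS"
        plain = hs.theoretical_fragments(seg, None, ("N",))
        mod = hs.theoretical_fragments(seg, (5, hs.PHOSPHO), ("N",))
        shift = np.round(mod - plain, 2)
        assert shift[:4].tolist() == [0.0] * 4
        assert shift[4:].tolist() == [79.97] * 5


class TestMatchCount:
    def test_trivial_cases(self):
        theo = hs.prefix_masses("EPPLSQETFS")
        assert hs.match_count([], theo, 15.0) == 0
        assert hs.match_count(theo, theo, 15.0) == theo.size

    def test_ppm_boundary(self):
        assert hs.match_count([1000.016], [1000.0], 15.0) == 0
        assert hs.match_count([1000.014], [1000.0], 15.0) == 1

    def test_greedy_consumes_each_peak_once(self):
        # one observed peak between two close theoretical masses
        assert hs.match_count([1000.0], [999.999, 1000.001], 15.0) == 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            hs.match_count([1.0], [1.0], -1.0)

    def test_score_non_increasing_as_tolerance_shrinks(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            theo = np.sort(rng.uniform(100, 5000, 40))
            obs = np.sort(theo * (1 + rng.normal(0, 8e-6, 40)))[rng.random(40) < 0.7]
            counts = [hs.match_count(obs, theo, t) for t in (30.0, 15.0, 8.0, 2.0)]
            assert counts == sorted(counts, reverse=True)


class TestOneShiftAlign:
    def test_phospho_worked_example(self, toy_db):
        pf = Proteoform("P1", 1, 10, Modification(5, hs.PHOSPHO))
        sp = hs.simulate_spectrum(pf, toy_db, ("N",), 1.0, 0.0, seed=1)
        score, delta, interval = hs.one_shift_align(sp, "EPPLSQETFS", 15.0, ("N",))
        assert score == 9
        assert round(delta, 2) == 79.97
        assert interval == (5, 5)

    def test_zero_delta_equals_plain_match_count(self, small_proteome):
        rng = np.random.default_rng(7)
        for i in range(500):
            pf = hs.sample_proteoforms(small_proteome, 1, (0.2, 0.2), seed=i)[0]
            sp = hs.simulate_spectrum(
                pf, small_proteome, ("N", "C"), float(rng.uniform(0.2, 1.0)), 2.0, seed=i
            )
            seg = pf.segment(small_proteome)
            score, delta, interval = hs.one_shift_align(sp, seg, 15.0)
            assert delta == 0.0 and interval is None
            merged = hs.theoretical_fragments(seg, None, ("N", "C"))
            assert score == hs.match_count(sp.fragment_masses, merged, 15.0)

    def test_interval_extends_to_terminus_without_bounding_match(self):
        seg = "ACDEFGHIKL"  # length 10
        pm = hs.prefix_masses(seg)
        segmass = pm[-1] + hs.RESIDUE_MASS["L"] + WATER
        sp = spectrum_of(segmass + 50.0, pm[:2])  # only sites 1-2, unshifted
        score, delta, interval = hs.one_shift_align(sp, seg, 15.0, ("N",))
        assert score == 2
        assert interval == (3, 10)

    def test_empty_segment_rejected(self, toy_db):
        sp = spectrum_of(500.0, [100.0])
        with pytest.raises(ValueError):
            hs.one_shift_align(sp, "")

    def test_agrees_with_split_enumeration_oracle(self):
        """Exhaustive split-site enumeration on short random segments."""
        rng = np.random.default_rng(23)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for case in range(300):
            L = int(rng.integers(2, 9))
            seg = "".join(rng.choice(aas, L))
            segmass = sum(hs.RESIDUE_MASS[a] for a in seg) + WATER
            delta = float(rng.choice([0.0, 42.01, 79.966, -57.02, 114.04]))
            theo = hs.theoretical_fragments(
                seg, (int(rng.integers(1, L + 1)), delta) if delta else None
            )
            keep = rng.random(theo.size) < 0.7
            obs = np.sort(np.concatenate([theo[keep], rng.uniform(50, 2000, 3)]))
            obs = obs[obs > 0]
            prec = segmass + delta
            obs = obs[obs < prec]
            sp = spectrum_of(prec, obs)
            got = hs.one_shift_align(sp, seg, 15.0)
            want = naive_one_shift(obs, prec, seg, 15.0)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1], abs=1e-9)
            assert got[2] == want[2]


class TestSearchDatabase:
    def test_kernel_agrees_with_reference_scoring(self, small_proteome):
        cfg = SearchConfig()
        checked = 0
        for t in range(20):
            pf = hs.sample_proteoforms(
                small_proteome, 1, (0.1, 0.1), [("p", hs.PHOSPHO)], 0.5, seed=200 + t
            )[0]
            sp = hs.simulate_spectrum(
                pf, small_proteome, peak_keep_probability=0.6, mass_error_ppm=3.0, seed=t
            )
            for rec in small_proteome:
                P = small_proteome.prefix_masses(rec.protein_id)
                s_arr, j_lo, j_hi = _candidate_ranges(P, sp.precursor_mass, cfg)
                starts, ends, scores, deltas = score_protein(
                    P, s_arr, j_lo, j_hi, sp.fragment_masses, sp.precursor_mass,
                    cfg.tol_ppm, True, True, WATER,
                )
                for k in range(0, starts.size, 5):
                    seg = rec.sequence[starts[k] - 1 : ends[k]]
                    score, delta, _ = hs.one_shift_align(sp, seg, cfg.tol_ppm)
                    assert score == scores[k]
                    assert delta == pytest.approx(deltas[k], abs=1e-9)
                    checked += 1
        assert checked > 200

    def test_recovers_true_segment_on_clean_spectra(self, small_proteome):
        """Noise-free, dropout-free spectra identify the generating
        proteoform's exact segment in at least 99% of 200 cases."""
        pfs = hs.sample_proteoforms(
            small_proteome, 200, (0.1, 0.1), [("phospho", hs.PHOSPHO)], 0.5, seed=4
        )
        ok = 0
        for i, pf in enumerate(pfs):
            sp = hs.simulate_spectrum(pf, small_proteome, seed=i, spectrum_id=f"S{i}")
            prsm = hs.search_database(sp, small_proteome)
            ok += (
                prsm.protein_id == pf.protein_id
                and prsm.start == pf.start
                and prsm.end == pf.end
            )
        assert ok >= 198

    def test_exhaustive_candidate_oracle_on_tiny_db(self):
        """The returned PrSM is the best over every candidate segment,
        verified by scoring all of them with the public operation."""
        db = hs.generate_reference_proteome(2, (30, 40), seed=9)
        cfg = SearchConfig(max_start_trim_fraction=0.4, max_end_trim_fraction=0.4,
                           min_segment_length=5)
        for i in range(20):
            pf = hs.sample_proteoforms(db, 1, (0.2, 0.2), seed=300 + i, min_length=8)[0]
            sp = hs.simulate_spectrum(pf, db, peak_keep_probability=0.7, seed=i)
            prsm = hs.search_database(sp, db, cfg)
            best = None
            for rec in sorted(db, key=lambda r: r.protein_id):
                L = len(rec.sequence)
                for start in range(1, L + 1):
                    for end in range(start + 4, L + 1):
                        seg = rec.sequence[start - 1 : end]
                        mass = sum(hs.RESIDUE_MASS[a] for a in seg) + WATER
                        if abs(sp.precursor_mass - mass) > cfg.max_delta:
                            continue
                        if start > 1 + 0.4 * L or end < L - 0.4 * L:
                            continue
                        score, delta, _ = hs.one_shift_align(sp, seg, cfg.tol_ppm)
                        key = (-score, abs(delta), rec.protein_id, start, end)
                        if best is None or key < best:
                            best = key
            assert prsm.score == -best[0]
            assert (prsm.protein_id, prsm.start, prsm.end) == (best[2], best[3], best[4])

    def test_sentinel_when_nothing_mass_compatible(self, toy_db):
        sp = spectrum_of(60000.0, [500.0])
        prsm = hs.search_database(sp, toy_db)
        assert prsm.score == 0 and prsm.protein_id == ""

    def test_tie_break_prefers_smaller_protein_id(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        db = ProteomeDB([ProteinRecord("P2", seq), ProteinRecord("P1", seq)])
        pf = Proteoform("P1", 1, 25)
        sp = hs.simulate_spectrum(pf, db, seed=1)
        assert hs.search_database(sp, db).protein_id == "P1"


class TestDecoysAndFdr:
    def test_decoy_preserves_residue_multiset(self, small_proteome):
        decoys = hs.build_decoy_db(small_proteome, seed=1)
        for rec, dec in zip(small_proteome, decoys):
            assert dec.protein_id == "DECOY_" + rec.protein_id
            assert sorted(dec.sequence) == sorted(rec.sequence)

    def test_degenerate_shuffle_and_determinism(self):
        db = ProteomeDB([ProteinRecord("P1", "AAAA")])
        assert hs.build_decoy_db(db, seed=3).records[0].sequence == "AAAA"
        a = hs.build_decoy_db(hs.generate_reference_proteome(3, (30, 30), 1), seed=5)
        b = hs.build_decoy_db(hs.generate_reference_proteome(3, (30, 30), 1), seed=5)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_decoy_id_collision_rejected(self):
        db = ProteomeDB([ProteinRecord("P1", "ACDE" * 5), ProteinRecord("DECOY_P1", "ACDE" * 5)])
        with pytest.raises(ValueError):
            hs.build_decoy_db(db, seed=1)

    def _prsms(self, targets, decoys):
        out = [
            hs.PrSM(f"T{i}", "P", 1, 2, s, 0.0) for i, s in enumerate(targets)
        ] + [
            hs.PrSM(f"D{i}", "DECOY_P", 1, 2, s, 0.0, is_decoy=True)
            for i, s in enumerate(decoys)
        ]
        return out

    def test_threshold_scan_example(self):
        accepted = hs.filter_fdr(self._prsms([10, 9, 8], [9]), 0.34)
        assert sorted(p.score for p in accepted) == [8, 9, 10]

    def test_no_decoys_accepts_all_targets(self):
        accepted = hs.filter_fdr(self._prsms([5, 3, 2], []), 0.01)
        assert len(accepted) == 3

    def test_level_one_accepts_positive_scores_only(self):
        accepted = hs.filter_fdr(self._prsms([4, 0], [2]), 1.0)
        assert [p.score for p in accepted] == [4]

    def test_invalid_level_rejected(self):
        for level in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                hs.filter_fdr([], level)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            targets = rng.integers(1, 30, 40).tolist()
            decoys = rng.integers(1, 25, 15).tolist()
            level = float(rng.choice([0.01, 0.05, 0.2, 0.5]))
            res = hs.fdr_threshold(self._prsms(targets, decoys), level)
            best = None
            for tau in sorted(set(targets) | set(decoys) | {1}):
                n_t = sum(t >= tau for t in targets)
                n_d = sum(d >= tau for d in decoys)
                if n_d / max(1, n_t) <= level:
                    best = tau
                    break
            if best is None:
                assert res.threshold == float("inf")
            else:
                assert res.threshold == best
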