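"""Digestion, candidate enumeration, spectrum matching, hybrid detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xlassist import synth, xlsearch
from xlassist.chem import BS3, PeptideSpec, mass_to_mz, pair_mass, peptide_mass
from xlassist.examples_support import TOY_PROTEIN, toy_crosslink_pairs
from xlassist.xlsearch import (
    ENZYME_SITES,
    SearchSettings,
    SpectrumRecord,
    digest,
    detect_hybrids,
    enumerate_candidates,
    filter_top_peaks,
    precursor_match,
    reactive_positions,
    read_fasta,
    read_mgf,
    score_match,
    search_spectra,
    best_matches,
    theoretical_fragments,
    write_mgf,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _brute_force_digest(seq: str, max_missed: int) -> set[tuple[int, str]]:
    """Oracle: substring enumeration filtered by cleavage-site rules."""
    sites = set("KRFWYLM")
    cut_ok = [True] + [False] * (len(seq) - 1) + [True]  # boundary before index i
    for i in range(1, len(seq)):
        if seq[i - 1] in sites and seq[i] != "P":
            cut_ok[i] = True
    out = set()
    for i in range(len(seq)):
        for j in range(i + 2, len(seq) + 1):  # min peptide length 2
            if not (cut_ok[i] and cut_ok[j]):
                continue
            internal = sum(1 for k in range(i + 1, j) if cut_ok[k])
            if internal <= max_missed:
                out.add((i + 1, seq[i:j]))
    return out


class TestDigest:
    def test_proline_rule_example(self):
        peps = digest("AKPGRSF", SearchSettings(max_missed_cleavages=0))
        assert {p.sequence for p in peps} == {"AKPGR", "SF"}

    def test_zero_missed_partition(self):
        seq = TOY_PROTEIN
        peps = digest(seq, SearchSettings(max_missed_cleavages=0, min_peptide_length=1))
        zero = sorted(peps, key=lambda p: p.start)
        assert "".join(p.sequence for p in zero) == seq

    def test_chymotryptic_peptide_observed(self):
        # the published oligomer table lists VEVEEDGQLKSL, a chymotryptic
        # C-terminal leucine product with two internal missed cleavages
        carrier = "MAKVEVEEDGQLKSLTINGKR"
        peps = digest(carrier, SearchSettings())
        assert "VEVEEDGQLKSL" in {p.sequence for p in peps}

    def test_empty_enzyme_set_returns_protein(self):
        peps = digest("MKTAYIAK", SearchSettings(enzymes=()))
        assert [p.sequence for p in peps] == ["MKTAYIAK"]

    @given(st.text(alphabet=AA, min_size=4, max_size=40),
           st.integers(min_value=0, max_value=2))
    def test_oracle_equivalence(self, seq, missed):
        got = {
            (p.start, p.sequence)
            for p in digest(seq, SearchSettings(max_missed_cleavages=missed))
        }
        assert got == _brute_force_digest(seq, missed)


class TestReactivePositions:
    def test_cterm_cleavage_lysine_not_reactive(self):
        p = PeptideSpec("SAK", "prot", start=5)
        assert reactive_positions(p, protein_length=100) == []

    def test_protein_cterm_lysine_reactive(self):
        p = PeptideSpec("SAK", "prot", start=98)
        assert reactive_positions(p, protein_length=100) == [100]

    def test_protein_nterm_alpha_amine(self):
        p = PeptideSpec("MAR", "prot", start=1)
        assert reactive_positions(p, protein_length=100) == [1]


class TestEnumerate:
    def test_single_k_peptides_pair_once(self):
        a = PeptideSpec("AKAR", "p", start=5)  # internal K6 only
        b = PeptideSpec("GLKGR", "p", start=20)  # internal K22 only
        cands = enumerate_candidates([a, b])
        pairs = [c for c in cands if c.kind == "crosslink"]
        assert len(pairs) == 3  # a-b, a-a, b-b (one reactive site each)
        kinds = {c.kind for c in cands}
        assert kinds == {"crosslink", "deadend"}

    def test_no_reactive_amine_no_candidates(self):
        p = PeptideSpec("GLAR", "p", start=10)
        assert enumerate_candidates([p]) == []

    def test_same_to_same_candidate_is_legal(self):
        p = PeptideSpec("SLKSA", "p", start=187)
        pairs = [c for c in enumerate_candidates([p]) if c.kind == "crosslink"]
        assert len(pairs) == 1
        assert pairs[0].pair.link_pos_a == pairs[0].pair.link_pos_b == 189

    def test_looplink_requires_two_amines(self, toy_candidates):
        for c in toy_candidates:
            if c.kind == "looplink":
                rp = reactive_positions(c.peptide, protein_length=len(TOY_PROTEIN))
                assert len(rp) >= 2


class TestTopPeaks:
    def test_filters_and_preserves_order(self, rng):
        mz = np.sort(rng.uniform(100, 2000, 200))
        inten = rng.exponential(100, 200)
        s = SpectrumRecord("t", 500.0, 3, mz, inten)
        f = filter_top_peaks(s, 125)
        assert len(f.mz) == 125
        assert np.all(np.diff(f.mz) > 0)
        assert f.intensity.min() >= np.sort(inten)[::-1][124] - 1e-12

    def test_small_spectrum_unchanged(self, rng):
        s = SpectrumRecord("t", 500.0, 3, np.linspace(100, 900, 50), np.ones(50))
        assert filter_top_peaks(s, 125) is s

    def test_idempotent(self, rng):
        mz = np.sort(rng.uniform(100, 2000, 300))
        s = SpectrumRecord("t", 500.0, 3, mz, rng.exponential(1, 300))
        once = filter_top_peaks(s, 125)
        twice = filter_top_peaks(once, 125)
        assert np.array_equal(once.mz, twice.mz)


class TestPrecursorMatch:
    def _spectrum_for(self, cand, charge=3, ppm_offset=0.0):
        mz = mass_to_mz(cand.neutral_mass, charge) * (1 + ppm_offset * 1e-6)
        return SpectrumRecord("s", mz, charge, np.array([200.0]), np.array([1.0]))

    def test_exact_mass_matches_near_zero_ppm(self, toy_candidates):
        cand = next(c for c in toy_candidates if c.kind == "crosslink")
        ms = precursor_match(self._spectrum_for(cand), [cand])
        assert ms and abs(ms[0].ppm) < 1e-6

    def test_offset_50ppm_no_match(self, toy_candidates):
        cand = next(c for c in toy_candidates if c.kind == "crosslink")
        assert precursor_match(self._spectrum_for(cand, ppm_offset=50.0), [cand]) == []

    def test_charge_2_skipped(self, toy_candidates):
        cand = toy_candidates[0]
        assert precursor_match(self._spectrum_for(cand, charge=2), [cand]) == []

    def test_missing_charge_warns_and_skips(self, toy_candidates):
        s = SpectrumRecord("s", 800.0, None, np.array([200.0]), np.array([1.0]))
        with pytest.warns(UserWarning):
            assert precursor_match(s, toy_candidates) == []

    def test_no_match_ever_beyond_tolerance(self, toy_candidates, rng):
        settings = SearchSettings()
        for _ in range(50):
            mz = rng.uniform(300, 1500)
            s = SpectrumRecord("f", mz, int(rng.integers(3, 6)),
                               np.array([200.0]), np.array([1.0]))
            for m in precursor_match(s, toy_candidates, settings):
                assert abs(m.ppm) <= settings.ms1_ppm


class TestFragments:
    def test_y1_of_cterm_lysine(self):
        # unlinked C-terminal lysine: y1 = K residue + water + proton
        pairs = toy_crosslink_pairs(1, seed=7)
        pair = pairs[0]
        frags = theoretical_fragments(pair, max_fragment_charge=1)
        pa = pair.peptide_a
        if pa.sequence.endswith("K") and pair.link_pos_a != pa.end:
            y1 = next(f.mz for f in frags if f.ion == "A.y1+1")
            assert y1 == pytest.approx(128.09496 + 18.010565 + 1.0072765, abs=1e-4)

    def test_by_complementarity(self):
        a = PeptideSpec("AKGLSR", "p", start=1)
        b = PeptideSpec("VLKDER", "p", start=20)
        pair = xlsearch.CrosslinkedPair(a, b, 2, 22, BS3)
        frags = {f.ion: f.mz for f in theoretical_fragments(pair, max_fragment_charge=1)}
        total = pair_mass(pair)
        n = len(a.sequence)
        for i in range(1, n):
            s = frags[f"A.b{i}+1"] + frags[f"A.y{n - i}+1"]
            # exactly one of the pair carries partner+bridge, so the sum is
            # the full crosslinked-pair mass plus two protons
            assert s == pytest.approx(total + 2 * 1.00727646688, abs=1e-6)

    def test_bion_before_link_site_has_no_linker(self):
        a = PeptideSpec("AGKLR", "p", start=1)
        b = PeptideSpec("VKDER", "p", start=20)
        pair = xlsearch.CrosslinkedPair(a, b, 3, 21, BS3)
        frags = {f.ion: f.mz for f in theoretical_fragments(pair, max_fragment_charge=1)}
        plain_b2 = 71.03711 + 57.02146 + 1.00727646688
        assert frags["A.b2+1"] == pytest.approx(plain_b2, abs=1e-4)
        assert frags["A.b3+1"] > plain_b2 + 200  # spans link: carries partner


class TestScoring:
    @staticmethod
    def _distinct_pair(candidates):
        return next(
            c for c in candidates
            if c.kind == "crosslink"
            and c.pair.peptide_a.sequence != c.pair.peptide_b.sequence
        )

    def _self_spectrum(self, cand):
        frags = theoretical_fragments(cand, max_fragment_charge=2)
        mz = np.unique(np.round([f.mz for f in frags], 6))
        return SpectrumRecord("s", mass_to_mz(cand.neutral_mass, 4), 4,
                              mz, np.full(len(mz), 2000.0))

    def test_self_match_is_clean(self, toy_candidates):
        cand = self._distinct_pair(toy_candidates)
        s = self._self_spectrum(cand)
        frags = theoretical_fragments(cand, max_fragment_charge=2)
        sc = score_match(s, frags)
        assert sc.both_peptides
        assert sc.unexplained_fraction == 0.0
        assert sc.score > 0.9

    def test_single_peptide_spectrum_fails_both_flag(self, toy_candidates):
        cand = self._distinct_pair(toy_candidates)
        frags = theoretical_fragments(cand, max_fragment_charge=2)
        b_mz = {round(f.mz, 6) for f in frags if f.peptide_index == 1}
        only_a = [f for f in frags
                  if f.peptide_index == 0 and round(f.mz, 6) not in b_mz]
        mz = np.unique(np.round([f.mz for f in only_a], 6))
        s = SpectrumRecord("s", 900.0, 4, mz, np.full(len(mz), 2000.0))
        sc = score_match(s, frags)
        assert not sc.both_peptides

    def test_score_monotone_in_tolerance(self, toy_candidates, rng):
        cand = next(c for c in toy_candidates if c.kind == "crosslink")
        frags = theoretical_fragments(cand, max_fragment_charge=2)
        mz = np.array([f.mz for f in frags]) + rng.normal(0, 0.02, len(frags))
        s = SpectrumRecord("s", 900.0, 4, np.sort(mz), np.full(len(mz), 1000.0))
        scores = [
            score_match(s, frags, SearchSettings(ms2_da=tol)).score
            for tol in (0.2, 0.1, 0.05, 0.02, 0.01)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestRecovery:
    def test_simulated_spectra_recovered_top_ranked(self, toy_candidates):
        """>=95% of 100 simulated crosslink spectra identified top-ranked."""
        pairs = (toy_crosslink_pairs(60, seed=5) * 2)[:100]
        spectra, truth = synth.simulate_spectra(pairs, seed=6)
        matches = search_spectra(spectra, toy_candidates)
        best = best_matches(matches)
        ok = 0
        for row in truth.itertuples():
            m = best.get(row.scan)
            if m is None or m.candidate.kind != "crosslink":
                continue
            p = m.candidate.pair
            if {(p.link_pos_a, p.link_pos_b), (p.link_pos_b, p.link_pos_a)} & {
                (row.pos_a, row.pos_b)
            }:
                ok += 1
        assert ok >= 95

    def test_isotope_state_spacing(self, toy_candidates):
        from xlassist.chem import N15_SHIFT_PER_N

        cand = next(c for c in toy_candidates if c.kind == "crosslink")
        states = cand.isotope_states(labeling=True)
        na, nb = cand.n_nitrogens
        assert states["15/14"] == pytest.approx(N15_SHIFT_PER_N * na)
        assert states["14/15"] == pytest.approx(N15_SHIFT_PER_N * nb)
        assert states["15/15"] == pytest.approx(N15_SHIFT_PER_N * (na + nb))


class TestHybrids:
    def _run(self, exchange, seed, toy_candidates):
        pairs = toy_crosslink_pairs(6, seed=2)
        spectra, _ = synth.simulate_exchange_experiment(pairs, exchange=exchange, seed=seed)
        return search_spectra(spectra, toy_candidates, labeling=True)

    def test_exchange_vs_control_verdicts(self, toy_candidates):
        mixed = self._run(True, 3, toy_candidates)
        control = self._run(False, 4, toy_candidates)
        v = detect_hybrids(mixed, control)
        assert v.exchange
        assert v.hybrids_mixed and not v.hybrids_control
        # swapped: hybrids in neither condition -> no exchange
        v2 = detect_hybrids(control, control)
        assert not v2.exchange

    def test_all_14n_has_no_hybrids(self, toy_candidates):
        pairs = toy_crosslink_pairs(4, seed=9)
        spectra, _ = synth.simulate_spectra(pairs, seed=9)
        matches = search_spectra(spectra, toy_candidates, labeling=True)
        v = detect_hybrids(matches, [], labeling_enabled=True)
        assert not v.hybrids_mixed and not v.exchange

    def test_labeling_disabled_rejected(self):
        with pytest.raises(ValueError):
            detect_hybrids([], [], labeling_enabled=False)


class TestIO:
    def test_mgf_round_trip(self, rng):
        mz = np.sort(rng.uniform(100, 1800, 30))
        s = SpectrumRecord("scan=1", 812.34, 3, mz, rng.exponential(500, 30))
        back = read_mgf(write_mgf([s]))
        assert len(back) == 1
        assert back[0].charge == 3
        assert back[0].precursor_mz == pytest.approx(812.34)
        assert np.allclose(back[0].mz, s.mz)

    def test_fasta(self):
        seqs = read_fasta(">a desc\nMKTAY\nIAK\n>b\nGGG\n")
        assert seqs == {"a": "MKTAYIAK", "b": "GGG"}
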