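import numpy as np
import pytest
from hypothesis import given, strategies as st

from sdpsearch.config import SearchConfig
from sdpsearch.digestion import IndexEntry, PeptideIndex, build_peptide_index
from sdpsearch.formats_io import ProteinRecord, Spectrum
from sdpsearch.masses import PROTON
from sdpsearch.scoring import (
    candidate_window,
    rank_psms,
    score_spectrum_alg1,
    score_spectrum_micsdp,
    sdp,
)
from sdpsearch.theoretical import BinnedSpectrum, fragment_mzs


def dense_sdp(a, b):
    """Brute-force sum(c_i * t_i) over dense boolean vectors."""
    n = int(max(a.max(initial=-1), b.max(initial=-1))) + 1
    va = np.zeros(n, dtype=int)
    vb = np.zeros(n, dtype=int)
    va[a] = 1
    vb[b] = 1
    return int((va * vb).sum())


def binned(indices, width=0.5):
    return BinnedSpectrum(np.array(sorted(indices), dtype=np.int64), width)


bin_sets = st.sets(st.integers(0, 300), max_size=50)


class TestSdp:
    @pytest.mark.parametrize(
        "c,t,expected",
        [
            ({1, 2, 3, 4, 5}, {1, 2, 3, 4, 5}, 5),  # self-match = peak count
            ({1, 2}, {3, 4}, 0),
            ({100, 200, 300, 400}, {200, 400, 500}, 2),
        ],
    )
    def test_known_overlaps(self, c, t, expected):
        assert sdp(binned(c), binned(t)) == expected

    def test_bin_width_mismatch_is_error(self):
        with pytest.raises(ValueError):
            sdp(binned({1}, 0.5), binned({1}, 0.2))

    @given(a=bin_sets, b=bin_sets)
    def test_equals_dense_brute_force(self, a, b):
        ca, cb = binned(a), binned(b)
        got = sdp(ca, cb)
        assert got == dense_sdp(ca.bins, cb.bins)
        assert got == sdp(cb, ca)  # symmetry
        assert sdp(ca, ca) == len(a)

    @given(a=bin_sets, b=bin_sets, extra=st.integers(0, 300))
    def test_adding_matching_peak_never_decreases(self, a, b, extra):
        base = sdp(binned(a), binned(b | {extra}))
        grown = sdp(binned(a | {extra}), binned(b | {extra}))
        assert grown >= base


def toy_index(masses):
    entries = [
        IndexEntry(f"PEP{i}", m, (("P1", 0, 0),)) for i, m in enumerate(masses)
    ]
    return PeptideIndex(entries, np.asarray(masses, dtype=float))


class TestCandidateWindow:
    def test_interior_window(self):
        w = candidate_window(toy_index([500, 600, 700, 800]), 650.0, 60.0)
        assert (w.lo, w.hi) == (1, 3)  # {600, 700}

    def test_zero_tolerance_no_exact_match(self):
        w = candidate_window(toy_index([500, 600, 700, 800]), 650.0, 0.0)
        assert len(w) == 0

    @pytest.mark.parametrize("query", [100.0, 2000.0])
    def test_out_of_range_is_empty(self, query):
        assert len(candidate_window(toy_index([500, 600, 700]), query, 50.0)) == 0

    @given(
        masses=st.lists(st.floats(50, 5000, allow_nan=False), min_size=0, max_size=60),
        query=st.floats(0, 6000, allow_nan=False),
        tol=st.floats(0, 100, allow_nan=False),
    )
    def test_equals_linear_scan_oracle(self, masses, query, tol):
        masses = sorted(masses)
        w = candidate_window(toy_index(masses), query, tol)
        oracle = [i for i, m in enumerate(masses) if abs(m - query) <= tol]
        assert list(range(w.lo, w.hi)) == oracle

    @given(
        masses=st.lists(st.floats(50, 5000, allow_nan=False), min_size=1, max_size=40),
        query=st.floats(0, 6000, allow_nan=False),
        tol=st.floats(0, 50, allow_nan=False),
        widen=st.floats(0, 50, allow_nan=False),
    )
    def test_widening_tolerance_never_shrinks(self, masses, query, tol, widen):
        index = toy_index(sorted(masses))
        w1 = candidate_window(index, query, tol)
        w2 = candidate_window(index, query, tol + widen)
        assert w2.lo <= w1.lo and w2.hi >= w1.hi


def spectrum_for(sequence, charge=2, mz_error=0.0, peaks=None, source_index=0):
    from sdpsearch.digestion import peptide_mass

    mass = peptide_mass(sequence)
    mz = (mass + charge * PROTON) / charge + mz_error
    if peaks is None:
        peaks = [(m, 1.0) for m in fragment_mzs(sequence)]
    return Spectrum(f"sp-{sequence}", mz, charge, peaks, source_index)


class TestRankPsms:
    def entries(self, n, mass=800.0):
        return [IndexEntry(f"SEQ{i}", mass + i, (("P1", 0, 0),)) for i in range(n)]

    def test_scores_rank_descending_zero_dropped(self):
        e = self.entries(3)
        s = spectrum_for("PEPTIDEK")
        psms = rank_psms([(e[0], 4), (e[1], 2), (e[2], 0)], k=10, spectrum=s)
        assert [(p.rank, p.sdp_score) for p in psms] == [(1, 4), (2, 2)]

    def test_tie_broken_by_smaller_mass_delta(self):
        s = spectrum_for("PEPTIDEK")
        target = s.precursor_neutral_mass
        near = IndexEntry("ZZZZ", target + 0.1, (("P1", 0, 0),))
        far = IndexEntry("AAAA", target + 2.0, (("P1", 0, 0),))
        psms = rank_psms([(far, 3), (near, 3)], k=10, spectrum=s)
        assert [p.peptide_sequence for p in psms] == ["ZZZZ", "AAAA"]

    def test_all_zero_scores_empty(self):
        s = spectrum_for("PEPTIDEK")
        assert rank_psms([(e, 0) for e in self.entries(3)], 5, s) == []

    def test_k_truncates(self):
        s = spectrum_for("PEPTIDEK")
        psms = rank_psms([(e, 5) for e in self.entries(7)], k=3, spectrum=s)
        assert [p.rank for p in psms] == [1, 2, 3]


def prefilled_index(bin_lists, masses, width=0.5):
    index = toy_index(masses)
    index._bin_width = width
    index._bin_cache = {
        i: np.array(sorted(b), dtype=np.int64) for i, b in enumerate(bin_lists)
    }
    return index


class TestScoringAlgorithms:
    config = SearchConfig(min_peptide_length=1, fixed_mods=())

    def test_perfect_match_ranks_first_with_maximal_score(self):
        proteins = [ProteinRecord("P1", "", "GGAMKTESTDIGEKSSSR")]
        index = build_peptide_index(proteins, self.config)
        s = spectrum_for("TESTDIGEK")
        psms = score_spectrum_alg1(s, index, self.config)
        assert psms[0].peptide_sequence == "TESTDIGEK"
        assert psms[0].sdp_score == 2 * (len("TESTDIGEK") - 1)

    def test_out_of_window_precursor_gives_empty_list(self):
        index = build_peptide_index([ProteinRecord("P1", "", "GGAMKPEPTIDEK")], self.config)
        s = spectrum_for("PEPTIDEK", mz_error=500.0)
        assert score_spectrum_alg1(s, index, self.config) == []
        assert score_spectrum_micsdp(s, index, self.config) == []

    @pytest.mark.parametrize("scorer", [score_spectrum_alg1, score_spectrum_micsdp])
    def test_hand_built_overlaps(self, scorer):
        """Three candidates with bin overlaps 4, 2, 0 -> scores [4, 2]."""
        c_bins = {10, 20, 30, 40}
        index = prefilled_index(
            [{10, 20, 30, 40}, {10, 20, 99}, {77, 88}],
            masses=[900.0, 900.1, 900.2],
        )
        peaks = [((b + 0.25) * 0.5, 1.0) for b in sorted(c_bins)]
        s = Spectrum("s", (900.0 + 2 * PROTON) / 2, 2, peaks, 0)
        psms = scorer(s, index, self.config)
        assert [p.sdp_score for p in psms] == [4, 2]
        assert [p.rank for p in psms] == [1, 2]

    @given(seed=st.integers(0, 10_000))
    def test_micsdp_identical_to_reference(self, seed):
        """The fused single-pass scorer reproduces the two-pass reference
        field-for-field on randomized databases and spectra."""
        rng = np.random.default_rng(seed)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        proteins = [
            ProteinRecord(f"P{j}", "", "".join(rng.choice(aas, size=rng.integers(20, 60))))
            for j in range(3)
        ]
        index = build_peptide_index(proteins, self.config)
        if not len(index):
            return
        entry = index.entries[rng.integers(0, len(index))]
        frags = fragment_mzs(entry.sequence)
        keep = rng.random(len(frags)) > 0.3
        peaks = [(m, 1.0) for m, k in zip(frags, keep) if k]
        peaks += [(float(m), 1.0) for m in rng.uniform(100, 1500, 5)]
        charge = int(rng.integers(2, 4))
        s = Spectrum(
            "s",
            (entry.neutral_mass + charge * PROTON) / charge + rng.uniform(-0.5, 0.5),
            charge,
            sorted(peaks),
            0,
        )
        assert score_spectrum_micsdp(s, index, self.config) == \
            score_spectrum_alg1(s, index, self.config)
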