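import itertools

import numpy as np
import pytest

import amdmotif as am
from amdmotif import GappedConsensus
from amdmotif.degenerate import (
    _search_round,
    _search_round_greedy,
    enumerate_degenerations,
    extend_core,
    pad_core,
    select_degenerate,
)
from amdmotif.iupac import CONSISTENT_CODES, NON_N_CODES

from conftest import random_set


def _stats(core, fg, bg):
    c, _ = am.count_instances(core, fg)
    n, _ = am.count_instances(core, bg)
    return am.enrichment_stats(c, n, fg.total_length, bg.total_length)


class TestDegenerationRule:
    def test_consistent_codes_for_each_base(self):
        assert set(CONSISTENT_CODES["A"]) == set("AMRWVHDN")
        for b in "ACGT":
            codes = CONSISTENT_CODES[b]
            assert len(codes) == 8
            assert b in codes and "N" in codes


class TestEnumerateDegenerations:
    def test_total_candidate_count(self):
        core = GappedConsensus("ACGNNTGC")
        n = sum(1 for _ in enumerate_degenerations(core))
        assert n == sum(
            len(list(itertools.combinations(range(6), k))) * 7**k
            for k in range(5)
        )
        assert n == 43_653

    def test_zero_changes_yields_original_only(self):
        core = GappedConsensus("ACGTGC")
        out = list(enumerate_degenerations(core, max_changed=0))
        assert out == [core]

    def test_gap_untouched_and_codes_consistent(self):
        core = GappedConsensus("ACGNNNTGC")
        seen = set()
        for cand in enumerate_degenerations(core, max_changed=2):
            assert cand.pattern[3:6] == "NNN"
            for orig, new in zip("ACGTGC", cand.pattern[:3] + cand.pattern[6:]):
                assert new in CONSISTENT_CODES[orig]
            assert cand.pattern not in seen
            seen.add(cand.pattern)

    def test_non_core_input_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_degenerations(GappedConsensus("ACGNNTGCA")))
        with pytest.raises(ValueError):
            list(enumerate_degenerations(GappedConsensus("ACRNNTGC")))


class TestSelectDegenerate:
    def _split_fixture(self):
        # 30 ACGTAG + 30 ACGTAC planted: optimal degeneration ends in S
        rng = np.random.default_rng(123)
        fgs = ["".join("ACGT"[i] for i in rng.choice(4, 200)) for _ in range(100)]
        for i in range(60):
            site = "ACGTAG" if i < 30 else "ACGTAC"
            fgs[i] = fgs[i][:50] + site + fgs[i][56:]
        fg = am.SequenceSet.from_strings(fgs, "fg")
        bg = random_set(rng, 400, 200, prefix="bg")
        return fg, bg

    def test_split_base_selects_s_code(self):
        fg, bg = self._split_fixture()
        core = GappedConsensus("ACGTAG")
        st0 = _stats(core, fg, bg)
        best, stats = select_degenerate(core, st0, fg, bg)
        assert best.pattern[-1] == "S"
        assert stats.Z > st0.Z and stats.F > st0.F

    def test_no_improvement_returns_original(self):
        # exact-plant foreground with background devoid of consistent hits:
        # any degeneration can only dilute, so the core survives unchanged
        rng = np.random.default_rng(42)
        fg = am.SequenceSet.from_strings(
            ["ACGTAG" * 10 for _ in range(3)], "fg"
        )
        bg = random_set(rng, 40, 120, prefix="bg")
        core = GappedConsensus("ACGTAG")
        st0 = _stats(core, fg, bg)
        best, stats = select_degenerate(core, st0, fg, bg)
        assert best == core and stats is st0

    def test_returned_z_never_below_input(self):
        rng = np.random.default_rng(8)
        for trial in range(3):
            fg = random_set(rng, 5, 150, prefix=f"f{trial}")
            bg = random_set(rng, 20, 150, prefix=f"b{trial}")
            core = GappedConsensus("ACGNNTGC")
            st0 = _stats(core, fg, bg)
            _, stats = select_degenerate(core, st0, fg, bg)
            assert stats.Z >= st0.Z

    def test_matches_naive_enumeration(self):
        # exhaustive cross-check at max_changed=2 (778 candidates)
        rng = np.random.default_rng(77)
        fg = random_set(rng, 6, 100, prefix="f")
        bg = random_set(rng, 12, 100, prefix="b")
        core = GappedConsensus("ACGNTGC")
        st0 = _stats(core, fg, bg)
        best, stats = select_degenerate(core, st0, fg, bg, max_changed=2)
        naive_best = None
        for cand in enumerate_degenerations(core, max_changed=2):
            s = _stats(cand, fg, bg)
            if s.F > st0.F and s.Z > st0.Z:
                key = (-s.Z, cand.pattern)
                if naive_best is None or key < naive_best[0]:
                    naive_best = (key, cand, s)
        if naive_best is None:
            assert best == core
        else:
            assert best.pattern == naive_best[1].pattern
            assert stats.C == naive_best[2].C
            assert stats.N_bg == naive_best[2].N_bg


class TestPadCore:
    @pytest.mark.parametrize("gap", range(15))
    def test_padded_span_parity(self, gap):
        core = GappedConsensus.from_triplets("ACG", gap, "TGC")
        padded = pad_core(core)
        assert padded.span == (20 if gap % 2 == 0 else 19)
        assert padded.span % 2 == gap % 2 == (padded.span % 2)
        # symmetric padding, informative content centered
        assert padded.pattern.strip("N").startswith("ACG")

    def test_gap0_pads_seven_each_side(self):
        padded = pad_core(GappedConsensus("ACGTGC"))
        assert padded.pattern == "N" * 7 + "ACGTGC" + "N" * 7

    def test_gap1_pads_six_each_side(self):
        padded = pad_core(GappedConsensus("ACGNTGC"))
        assert padded.pattern == "N" * 6 + "ACGNTGC" + "N" * 6

    def test_overlong_core_rejected(self):
        with pytest.raises(ValueError):
            pad_core(GappedConsensus("ACG" + "N" * 15 + "TGC"))


class TestExtendCore:
    def _planted(self, seed=4):
        rng = np.random.default_rng(seed)
        fgs = ["".join("ACGT"[i] for i in rng.choice(4, 200)) for _ in range(50)]
        for i in range(40):
            fgs[i] = fgs[i][:60] + "TTGACG" + fgs[i][66:]
        fg = am.SequenceSet.from_strings(fgs, "fg")
        bgs = []
        while len(bgs) < 200:
            s = "".join("ACGT"[i] for i in rng.choice(4, 200))
            if "TTGACG" not in s and "CGTCAA" not in s:
                bgs.append(s)
        bg = am.SequenceSet.from_strings(bgs, "bg")
        return fg, bg

    def test_no_signal_no_extension(self):
        # background devoid of core matches: every variant ties at Z=0,
        # so the unextended padded form must be returned
        fg, bg = self._planted()
        core = GappedConsensus("TTGACG")
        ext = extend_core(core, fg, bg)
        assert ext.pattern == pad_core(core).pattern

    def test_informative_positions_preserved(self):
        rng = np.random.default_rng(6)
        fg = random_set(rng, 10, 150, prefix="f")
        bg = random_set(rng, 40, 150, prefix="b")
        core = GappedConsensus("ACGNNTGC")
        ext = extend_core(core, fg, bg)
        padded = pad_core(core)
        assert ext.span == padded.span
        for i, c in enumerate(padded.pattern):
            if c != "N":
                assert ext.pattern[i] == c

    def test_matches_naive_enumeration_single_round(self):
        rng = np.random.default_rng(31)
        fgs = ["".join("ACGT"[i] for i in rng.choice(4, 80)) for _ in range(8)]
        for i in range(6):
            fgs[i] = fgs[i][:30] + "TTGACGTCAA" + fgs[i][40:]
        fg = am.SequenceSet.from_strings(fgs, "fg")
        bg = random_set(rng, 32, 80, prefix="b")
        pattern = "NNGACGTCNN"
        best_pat, best_stats = _search_round(pattern, fg, bg, max_changed=2)
        Lf, Lb = fg.total_length, bg.total_length
        best = None
        npos = [i for i, c in enumerate(pattern) if c == "N"]
        for k in (1, 2):
            for pos in itertools.combinations(npos, k):
                for codes in itertools.product(NON_N_CODES, repeat=k):
                    letters = list(pattern)
                    for p, c in zip(pos, codes):
                        letters[p] = c
                    pat = "".join(letters)
                    s = _stats(GappedConsensus(pat), fg, bg)
                    key = (-s.Z, pat)
                    if best is None or key < best[0]:
                        best = (key, pat, s)
        st0 = _stats(GappedConsensus(pattern), fg, bg)
        expected = best[1] if best[2].Z > st0.Z else pattern
        assert best_pat == expected
        if best_pat != pattern:
            assert best_stats.C == best[2].C
            assert best_stats.N_bg == best[2].N_bg

    def test_greedy_fallback_preserves_contract(self):
        rng = np.random.default_rng(15)
        fg = random_set(rng, 8, 120, prefix="f")
        bg = random_set(rng, 32, 120, prefix="b")
        core = GappedConsensus("ACGNTGC")
        ext = extend_core(core, fg, bg, exact_limit=10)  # force greedy
        padded = pad_core(core)
        assert ext.span == padded.span
        for i, c in enumerate(padded.pattern):
            if c != "N":
                assert ext.pattern[i] == c

    def test_pipeline_z_monotonicity(self):
        fg, bg, _ = am.generate_dataset(
            am.PlantSpec(motif="TTGACGTCAA", seed=3, n_seqs=60, seq_length=300)
        )
        cores = am.select_primary_cores(fg, bg, max_gap=4, top_k=3)
        for core, st0 in cores:
            deg, st1 = select_degenerate(core, st0, fg, bg)
            assert st1.Z >= st0.Z
            ext = extend_core(deg, fg, bg, max_changed=2)
            # compare in the padded frame: extension must never lose z-score
            st2 = _stats(ext, fg, bg)
            padded_stats = _stats(pad_core(deg), fg, bg)
            assert st2.Z >= padded_stats.Z - 1e-9
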