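"""Knapsack table and mass-constrained beam search, checked against
brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from denovoms.chemistry import WATER, ResidueVocabulary, mz_from_mass, ppm_diff
from denovoms.knapsack import (
    build_table,
    is_continuable,
    knapsack_beam_search,
)
from denovoms.model import AutoregressiveSequencer, ModelConfig
from denovoms.ms_io import Spectrum
from denovoms import nn


def small_vocab(letters="GA"):
    from denovoms.chemistry import RESIDUE_MASSES

    masses = {l: RESIDUE_MASSES[l] for l in letters}
    return ResidueVocabulary(tokens=tuple(sorted(letters)), masses=masses)


def brute_force_sums(vocab, max_mass, max_len=6):
    """All residue-multiset sums <= max_mass (the enumeration oracle)."""
    masses = [vocab.masses[t] for t in vocab.tokens]
    sums = {0.0}
    frontier = [0.0]
    for _ in range(max_len):
        nxt = []
        for s in frontier:
            for m in masses:
                v = s + m
                if v <= max_mass and not any(abs(v - u) < 1e-9 for u in sums):
                    sums.add(v)
                    nxt.append(v)
        frontier = nxt
    return sorted(sums)


class TestBuildTable:
    def test_reachable_set_matches_enumeration(self):
        vocab = small_vocab("GA")
        table = build_table(vocab, max_mass=200.0, resolution=0.0005)
        expected = brute_force_sums(vocab, 200.0)
        for v in expected:
            assert table.reachable[table.bin_of(v)], f"{v} should be reachable"
        # spot-check some non-sums
        for v in [10.0, 100.0, 130.0, 199.0]:
            assert not any(abs(v - u) < 0.01 for u in expected)
            assert not table.reachable[table.bin_of(v)]

    def test_bin_zero_reachable(self, vocab):
        table = build_table(vocab, max_mass=300.0)
        assert table.reachable[0]

    def test_closure_under_residue_addition(self, vocab):
        table = build_table(vocab, max_mass=500.0)
        rng = np.random.default_rng(0)
        hits = np.flatnonzero(table.reachable)
        for b in rng.choice(hits, size=200):
            for tok, rb in table.residue_bins.items():
                if b + rb < table.n_bins:
                    assert table.reachable[b + rb]

    def test_invalid_parameters_rejected(self, vocab):
        with pytest.raises(ValueError):
            build_table(vocab, max_mass=100.0)  # below largest residue
        with pytest.raises(ValueError):
            build_table(vocab, max_mass=500.0, resolution=0.0)

    def test_cache_round_trip(self, tmp_path):
        vocab = small_vocab("GAK")
        t1 = build_table(vocab, max_mass=300.0, cache_dir=tmp_path)
        t2 = build_table(vocab, max_mass=300.0, cache_dir=tmp_path)
        np.testing.assert_array_equal(t1.reachable, t2.reachable)


@pytest.fixture(scope="module")
def table():
    return build_table(small_vocab("GA"), max_mass=2000.0)


class TestIsContinuable:
    def test_zero_remaining_true(self, table):
        assert is_continuable(0.0, table, 50.0, 1000.0)

    def test_negative_beyond_window_false(self, table):
        assert not is_continuable(-1.0, table, 50.0, 1000.0)

    def test_single_residue_reachable(self, table):
        assert is_continuable(57.0215, table, 50.0, 1000.0)

    def test_unreachable_gap(self, table):
        assert not is_continuable(100.0, table, 50.0, 1000.0)


class _FixedScorer:
    """Stand-in model with fixed (spectrum-independent) random logits."""

    def __init__(self, vocab, rng, max_len=6):
        self.vocab = vocab
        self.token_index = vocab.index()
        self.config = ModelConfig.toy(max_peptide_len=max_len)
        n = len(vocab)
        # logits depend on the previous token only (a seeded Markov scorer)
        self.table_logits = rng.normal(0.0, 2.0, size=(n, n))

    def encode_spectrum(self, spectra):
        from denovoms.model import EncodedSpectrum

        return EncodedSpectrum(
            memory=nn.Tensor(np.zeros((len(spectra), 1, 4), np.float32)),
            pad_mask=np.zeros((len(spectra), 1), dtype=bool),
        )

    def next_token_logits(self, encoded, prefixes):
        B, L = prefixes.shape
        prev = prefixes[:, -1] if L else np.full(B, self.token_index[self.vocab.sos])
        return self.table_logits[prev].astype(np.float64)


def exhaustive_best(scorer, target, window, max_len=6):
    """Enumerate every mass-valid sequence and score it with the scorer
    (the independent oracle for beam search)."""
    vocab = scorer.vocab
    idx = scorer.token_index

    def row_logp(prev_id):
        return nn.log_softmax_np(scorer.table_logits[prev_id].astype(np.float64))

    best = None
    for length in range(1, max_len + 1):
        for combo in itertools.product(vocab.tokens, repeat=length):
            mass = sum(vocab.masses[t] for t in combo)
            if abs(mass - target) > window:
                continue
            ids = [idx[t] for t in combo]
            prev = idx[vocab.sos]
            score = 0.0
            for i in ids:
                score += float(row_logp(prev)[i])
                prev = i
            key = (-score, tuple(ids))
            if best is None or key < best[0]:
                best = (key, combo)
    return best


class TestBeamSearch:
    def test_toy_example_two_glycines(self):
        vocab = small_vocab("GA")
        table = build_table(vocab, max_mass=600.0)
        rng = np.random.default_rng(0)
        scorer = _FixedScorer(vocab, rng)
        target = 2 * vocab.masses["G"]  # 114.04292 residue mass
        spec = Spectrum(
            "t", np.array([100.0]), np.array([1.0]),
            mz_from_mass(target + WATER, 2), 2,
        )
        pred = knapsack_beam_search(scorer, spec, table, beam_size=4)
        assert pred is not None
        assert pred.peptide == ("G", "G")

    def test_mass_window_always_satisfied(self):
        vocab = small_vocab("GAKP")
        table = build_table(vocab, max_mass=1000.0)
        rng = np.random.default_rng(1)
        for trial in range(20):
            scorer = _FixedScorer(vocab, np.random.default_rng(trial))
            target = float(rng.uniform(200.0, 700.0))
            spec = Spectrum(
                "t", np.array([100.0]), np.array([1.0]),
                mz_from_mass(target + WATER, 2), 2,
            )
            pred = knapsack_beam_search(scorer, spec, table, beam_size=3)
            if pred is not None:
                mass = sum(vocab.masses[t] for t in pred.peptide)
                assert ppm_diff(mass, target) <= 50.0

    def test_beam_one_equals_greedy_with_masking(self):
        vocab = small_vocab("GA")
        table = build_table(vocab, max_mass=600.0)
        scorer = _FixedScorer(vocab, np.random.default_rng(3))
        target = 3 * vocab.masses["A"]
        spec = Spectrum(
            "t", np.array([100.0]), np.array([1.0]),
            mz_from_mass(target + WATER, 2), 2,
        )
        b1 = knapsack_beam_search(scorer, spec, table, beam_size=1)
        # greedy reference: at each step take the best feasible token
        idx = scorer.token_index
        window = 50e-6 * target
        tokens, remaining, prev = [], target, idx[vocab.sos]
        for _ in range(6):
            if abs(remaining) <= window:
                break
            row = scorer.table_logits[prev]
            order = np.argsort(-row)
            for tid in order:
                tok = {v: k for k, v in idx.items()}.get(int(tid))
                if tok in vocab.masses and is_continuable(
                    remaining - vocab.masses[tok], table, 50.0, target
                ):
                    tokens.append(tok)
                    remaining -= vocab.masses[tok]
                    prev = int(tid)
                    break
        assert b1 is not None
        assert list(b1.peptide)[::-1] == tokens  # rtl output reversed

    def test_oracle_equivalence_over_random_instances(self):
        """Beam search equals exhaustive enumeration of mass-valid
        sequences on >= 50 seeded toy instances."""
        vocab = small_vocab("GASPVK")  # 6 residues
        table = build_table(vocab, max_mass=1200.0)
        n_checked = 0
        for seed in range(75):
            rng = np.random.default_rng(seed)
            scorer = _FixedScorer(vocab, rng)
            # target: a random composition of <= 4 residues (guaranteed valid)
            toks = rng.choice(vocab.tokens, size=rng.integers(2, 5))
            target = float(sum(vocab.masses[t] for t in toks))
            window = 50e-6 * target
            oracle = exhaustive_best(scorer, target, window, max_len=6)
            spec = Spectrum(
                "t", np.array([100.0]), np.array([1.0]),
                mz_from_mass(target + WATER, 2), 2,
            )
            pred = knapsack_beam_search(scorer, spec, table, beam_size=64, max_len=6)
            assert (pred is None) == (oracle is None)
            if pred is not None:
                n_checked += 1
                expected = oracle[1]
                got = tuple(pred.peptide[::-1])  # decoding order
                assert got == expected, f"seed {seed}: {got} vs {expected}"
        assert n_checked >= 50

    def test_score_weakly_monotone_in_beam_width(self):
        vocab = small_vocab("GASP")
        table = build_table(vocab, max_mass=900.0)
        rng = np.random.default_rng(7)
        for trial in range(10):
            scorer = _FixedScorer(vocab, np.random.default_rng(100 + trial))
            toks = rng.choice(vocab.tokens, size=3)
            target = float(sum(vocab.masses[t] for t in toks))
            spec = Spectrum(
                "t", np.array([100.0]), np.array([1.0]),
                mz_from_mass(target + WATER, 2), 2,
            )
            scores = []
            for B in (1, 2, 8, 32):
                pred = knapsack_beam_search(scorer, spec, table, beam_size=B, max_len=6)
                scores.append(None if pred is None else pred.log_prob)
            present = [s for s in scores if s is not None]
            assert all(b >= a - 1e-9 for a, b in zip(present, present[1:]))
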