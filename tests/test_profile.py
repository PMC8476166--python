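"""Profile construction and scoring semantics, checked against the
exhaustive path-enumeration oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthocomplete.datasets import MarkerFamily
from orthocomplete.profile import (
    AMINO_ACIDS,
    DegenerateProfileError,
    build_profile,
    encode,
    score_sequence,
    search,
)

from .oracle import brute_force_bits


def family(seeds, marker_id="m1", cutoff=10.0):
    mean = sum(len(s.replace("-", "")) for s in seeds) / len(seeds)
    return MarkerFamily(marker_id, tuple(seeds), cutoff, mean, 0.0)


class TestBuildProfile:
    def test_ungapped_alignment_keeps_every_column(self):
        prof = build_profile(family(["ACDEFGH"] * 4))
        assert prof.match_columns == 7

    def test_majority_gap_column_dropped(self):
        seeds = ["A-CD", "A-CD", "AACD", "A-CD"]  # column 2: 3/4 gaps
        prof = build_profile(family(seeds))
        assert prof.match_columns == 3

    def test_single_sequence_add_one_smoothing(self):
        prof = build_profile(family(["W"]))
        bg = 1.0 / 20
        expected_hit = math.log((2 / 21) / bg)
        expected_other = math.log((1 / 21) / bg)
        w = AMINO_ACIDS.index("W")
        assert prof.emissions[0, w] == pytest.approx(expected_hit)
        assert prof.emissions[0, 0] == pytest.approx(expected_other)
        # emission distribution sums to one before log-odds conversion
        probs = np.exp(prof.emissions[0, :-1]) * bg
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_gap_alignment_is_degenerate(self):
        seeds = ["--", "--", "AA", "AA"]  # every column half-gapped
        with pytest.raises(DegenerateProfileError):
            build_profile(family(seeds))


class TestScoreSequence:
    def test_empty_protein_is_no_hit(self):
        prof = build_profile(family(["ACDEF"]))
        assert score_sequence(prof, "") is None

    def test_forward_at_least_viterbi(self, rng):
        prof = build_profile(family(["ACDEFGHIK", "ACDEFGHIK", "ACEEFGHIK"]))
        for _ in range(25):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 30)))
            v = score_sequence(prof, seq, mode="viterbi").bit_score
            f = score_sequence(prof, seq, mode="forward").bit_score
            assert f >= v - 1e-9

    def test_envelope_within_target_and_consistent(self, rng):
        prof = build_profile(family(["ACDEFGHIKLMNPQ"]))
        for _ in range(20):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 40)))
            hit = score_sequence(prof, seq)
            assert 1 <= hit.env_start <= hit.env_end <= len(seq)
            assert hit.aligned_length == hit.env_end - hit.env_start + 1

    def test_unknown_residues_score_as_background(self):
        prof = build_profile(family(["ACDEF"]))
        h_x = score_sequence(prof, "XXXXX")
        # a pure-wildcard target can collect at most the entry emission of 0
        assert h_x.bit_score == pytest.approx(0.0, abs=1e-9)

    def test_seed_scores_higher_than_random_background(self, rng):
        seed = "MKLVNACDEFGHIKWQRSTY"
        prof = build_profile(family([seed]))
        self_score = score_sequence(prof, seed).bit_score
        wins = 0
        for _ in range(100):
            decoy = "".join(rng.choice(list(AMINO_ACIDS), size=len(seed)))
            if self_score > score_sequence(prof, decoy).bit_score:
                wins += 1
        assert wins == 100


def _random_case(rng, max_m=4, max_len=5):
    m = int(rng.integers(1, max_m + 1))
    n_seeds = int(rng.integers(1, 4))
    seeds = [
        "".join(rng.choice(list(AMINO_ACIDS), size=m)) for _ in range(n_seeds)
    ]
    target = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, max_len + 1))))
    return build_profile(family(seeds)), target


class TestOracleAgreement:
    """Forward and viterbi must equal exhaustive path enumeration exactly."""

    def test_sweep_small_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            prof, target = _random_case(rng)
            x = encode(target)
            vit_o, fwd_o = brute_force_bits(prof.emissions, x)
            vit = score_sequence(prof, target, mode="viterbi").bit_score
            fwd = score_sequence(prof, target, mode="forward").bit_score
            assert vit == pytest.approx(vit_o, abs=1e-9)
            assert fwd == pytest.approx(fwd_o, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        m=st.integers(1, 4),
        seed_txt=st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=4),
        target=st.text(alphabet=AMINO_ACIDS + "X", min_size=1, max_size=5),
    )
    def test_property_small_cases(self, m, seed_txt, target):
        prof = build_profile(family([seed_txt[:m]]))
        x = encode(target)
        vit_o, fwd_o = brute_force_bits(prof.emissions, x)
        assert score_sequence(prof, target).bit_score == pytest.approx(vit_o, abs=1e-9)
        assert score_sequence(prof, target, mode="forward").bit_score == pytest.approx(
            fwd_o, abs=1e-9
        )


class TestSearch:
    def test_true_ortholog_found_at_high_sensitivity(self, zero_bundle, zero_dataset):
        target_sp = zero_bundle.species[4]
        hits = search(zero_dataset, zero_bundle.gene_sets[target_sp], sensitivity=7.0)
        for marker in zero_dataset.markers:
            best = max(hits[marker.marker_id], key=lambda h: h.bit_score)
            assert best.bit_score >= marker.score_cutoff
            assert best.sequence_id == zero_bundle.truth[target_sp][marker.marker_id]

    def test_diverged_ortholog_is_top_hit(self, star_bundle, star_dataset):
        target_sp = star_bundle.species[4]
        hits = search(star_dataset, star_bundle.gene_sets[target_sp], sensitivity=7.0)
        for marker in star_dataset.markers:
            best = max(hits[marker.marker_id], key=lambda h: h.bit_score)
            assert best.sequence_id == star_bundle.truth[target_sp][marker.marker_id]

    def test_sensitivity_monotonicity(self, star_bundle, star_dataset):
        proteins = star_bundle.gene_sets[star_bundle.species[4]]
        recovered = []
        for s in (1.0, 3.0, 4.5, 6.0, 7.0):
            hits = search(star_dataset, proteins, sensitivity=s)
            recovered.append(
                {
                    (m, h.sequence_id)
                    for m, hs in hits.items()
                    for h in hs
                }
            )
        for lo, hi in zip(recovered, recovered[1:]):
            assert lo <= hi

    def test_random_proteins_stay_below_reporting_floor(self, star_dataset, rng):
        n_with_hits = 0
        for _ in range(100):
            decoys = {
                f"d{i}": "".join(rng.choice(list(AMINO_ACIDS), size=80)) for i in range(3)
            }
            hits = search(star_dataset, decoys, sensitivity=7.0)
            if any(hs for hs in hits.values()):
                n_with_hits += 1
        assert n_with_hits <= 5

    def test_hits_invariant_under_renaming_and_padding(self, star_bundle, star_dataset, rng):
        proteins = dict(star_bundle.gene_sets[star_bundle.species[4]])
        base = search(star_dataset, proteins, sensitivity=7.0)
        renamed = {f"renamed_{k}": v for k, v in proteins.items()}
        padded = dict(renamed)
        padded["junk"] = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        again = search(star_dataset, padded, sensitivity=7.0)
        for m in base:
            scores_a = sorted(round(h.bit_score, 6) for h in base[m])
            scores_b = sorted(
                round(h.bit_score, 6) for h in again[m] if h.sequence_id != "junk"
            )
            assert scores_a == scores_b

    def test_empty_collection_gives_empty_result(self, star_dataset):
        hits = search(star_dataset, {}, sensitivity=4.5)
        assert all(not v for v in hits.values())
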