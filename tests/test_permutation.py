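import collections

import numpy as np
import pytest

from rdna4c import (
    GenomicInterval,
    InsufficientDataError,
    ParameterError,
    StateAnnotation,
    StateSegment,
    ValidationError,
    overlap_null,
    shuffle_states,
    state_enrichment,
)
from rdna4c.permutation import SHUFFLE_SCHEMES, proportions_z_test
from _oracles import random_states


def seg(start, end, state, chrom="c"):
    return StateSegment(GenomicInterval(chrom, start, end), state)


def length_label_multiset(states, chrom=None):
    out = collections.Counter()
    for s in states.segments():
        if chrom is None or s.interval.chrom == chrom:
            out[(len(s.interval), s.state)] += 1
    return out


class TestOverlapNull:
    def test_full_draw_overlaps_completely(self):
        universe = [f"g{i}" for i in range(30)]
        s = overlap_null(universe, universe[:10], k=30, n_shuffles=50, seed=1)
        # every draw contains the whole universe, so overlap = 10/30
        assert s.mean == pytest.approx(10 / 30)
        assert s.sd == pytest.approx(0, abs=1e-12)

    def test_matches_hypergeometric_closed_form(self):
        n_univ, k_ref, k_draw, n = 1000, 120, 80, 3000
        universe = [f"g{i}" for i in range(n_univ)]
        s = overlap_null(universe, universe[:k_ref], k=k_draw, n_shuffles=n, seed=2)
        # closed-form overlap-count moments, as fractions of the drawn list
        mean_c = k_draw * k_ref / n_univ
        var_c = (
            k_draw * k_ref * (n_univ - k_ref) * (n_univ - k_draw)
            / (n_univ**2 * (n_univ - 1))
        )
        mc_se_mean = np.sqrt(var_c / n) / k_draw
        assert s.mean == pytest.approx(mean_c / k_draw, abs=3 * mc_se_mean)
        # sd of sd estimate ~ sd / sqrt(2(n-1))
        sd_frac = np.sqrt(var_c) / k_draw
        assert s.sd == pytest.approx(sd_frac, abs=3 * sd_frac / np.sqrt(2 * (n - 1)))

    def test_empirical_p_when_observed_beats_all_draws(self):
        universe = [f"g{i}" for i in range(50)]
        s = overlap_null(
            universe, universe[:5], k=5, n_shuffles=100, seed=3, observed=1.01
        )
        assert s.empirical_p == pytest.approx(1 / 101)

    def test_duplicate_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_null(["a", "a", "b"], ["a"], k=1, n_shuffles=5, seed=0)

    def test_k_larger_than_universe_rejected(self):
        with pytest.raises(ParameterError):
            overlap_null(["a", "b"], ["a"], k=3, n_shuffles=5, seed=0)

    def test_deterministic_under_seed(self):
        universe = [f"g{i}" for i in range(100)]
        a = overlap_null(universe, universe[:20], 30, 200, seed=9)
        b = overlap_null(universe, universe[:20], 30, 200, seed=9)
        assert (a.mean, a.sd, a.min, a.max) == (b.mean, b.sd, b.min, b.max)


class TestShuffleSchemes:
    def test_label_shuffle_keeps_coordinates_and_label_multiset(self, rng):
        states = random_states(rng, {"c1": 30_000, "c2": 20_000})
        out = shuffle_states(states, "label_shuffle", seed=4)
        for chrom in states.chromosomes():
            s0, e0, l0 = states.arrays()[chrom]
            s1, e1, l1 = out.arrays()[chrom]
            assert np.array_equal(s0, s1) and np.array_equal(e0, e1)
        all_labels = lambda st: sorted(
            lab for _, _, labs in st.arrays().values() for lab in labs
        )
        assert all_labels(out) == all_labels(states)

    def test_segment_shuffle_two_segment_enumeration(self):
        states = StateAnnotation([seg(0, 10, 1), seg(10, 30, 2)])
        seen = set()
        for s in range(20):
            out = shuffle_states(states, "segment_shuffle", seed=s)
            order = tuple(
                (len(x.interval), x.state) for x in out.segments()
            )
            seen.add(order)
            starts = [x.interval.start for x in out.segments()]
            assert starts[0] == 0  # rebuilt cumulatively from the chromosome start
        assert seen <= {((10, 1), (20, 2)), ((20, 2), (10, 1))}
        assert len(seen) == 2

    @pytest.mark.parametrize(
        "scheme", ["segment_shuffle", "coord_and_state_shuffle"]
    )
    def test_genome_wide_length_label_multiset_preserved(self, scheme, rng):
        # scheme (a) moves labels across unequal segments, so only (b) and
        # (c) can preserve the (length, label) pairing
        states = random_states(rng, {"c1": 40_000, "c2": 25_000, "c3": 10_000})
        out = shuffle_states(states, scheme, seed=11)
        assert length_label_multiset(out) == length_label_multiset(states)

    def test_segment_shuffle_preserves_per_chromosome_multiset(self, rng):
        states = random_states(rng, {"c1": 40_000, "c2": 25_000})
        out = shuffle_states(states, "segment_shuffle", seed=12)
        for chrom in states.chromosomes():
            assert length_label_multiset(out, chrom) == length_label_multiset(
                states, chrom
            )

    def test_total_length_per_state_preserved(self, rng):
        states = random_states(rng, {"c1": 50_000})
        for scheme in ("segment_shuffle", "coord_and_state_shuffle"):
            out = shuffle_states(states, scheme, seed=13)
            assert out.state_lengths() == states.state_lengths()

    def test_unknown_scheme_rejected(self, rng):
        states = random_states(rng, {"c": 10_000})
        with pytest.raises(ParameterError):
            shuffle_states(states, "bogus", seed=0)


class TestProportionsTest:
    def test_worked_value(self):
        z, p = proportions_z_test(0.3, 1_000, 0.25, 10_000)
        assert z == pytest.approx(3.461, abs=0.002)
        assert p < 0.001


class TestStateEnrichment:
    def test_planted_enrichment_hits_floor_p(self, default_sim):
        manifest = default_sim["manifest"]
        sites = [iv for t in manifest.contact_genes.values() for iv in t.sites]
        res = state_enrichment(
            sites, default_sim["states"], "label_shuffle", n_shuffles=200, seed=5
        )
        row = res.state_row(1)
        assert row["p_enrich"] == pytest.approx(1 / 201)
        assert row["z"] > 5

    def test_no_assignable_sites_errors(self):
        states = StateAnnotation([seg(0, 1_000, 1)])
        with pytest.raises(InsufficientDataError):
            state_enrichment(
                [GenomicInterval("other", 0, 100)], states, "label_shuffle", 10
            )

    def test_deterministic_under_seed(self, rng):
        states = random_states(rng, {"c": 30_000})
        sites = [GenomicInterval("c", i * 500, i * 500 + 100) for i in range(20)]
        a = state_enrichment(sites, states, "segment_shuffle", 50, seed=6)
        b = state_enrichment(sites, states, "segment_shuffle", 50, seed=6)
        assert a.table.equals(b.table)

    def test_null_sites_not_flagged(self, rng):
        # uniform random sites on uniform random states: no tiny p-values
        states = random_states(rng, {"c": 100_000}, mean_len=2_000)
        sites = [
            GenomicInterval("c", int(s), int(s) + 150)
            for s in rng.integers(0, 99_000, 40)
        ]
        res = state_enrichment(sites, states, "label_shuffle", n_shuffles=99, seed=7)
        assert (res.table["p_enrich"] > 0.01).all()
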