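import numpy as np
import pytest

from rdna4c import (
    CapacityError,
    ContactParams,
    GenomicInterval,
    ParameterError,
    default_genome_spec,
    simulate_annotation,
    simulate_contact_tracks,
    simulate_expression_counts,
    simulate_signal_track,
)
from rdna4c.synthetic import GenomeSpec, TruthManifest


class TestAnnotationGenerator:
    def test_no_genes_still_tiles_states(self):
        spec = default_genome_spec(seed=1)
        genes, repeats, states = simulate_annotation(spec, n_genes=0, n_repeats=0)
        assert len(genes) == 0
        total = sum(
            int((e - s).sum()) for s, e, _ in states.arrays().values()
        )
        assert total == sum(spec.chromosomes.values())

    def test_state_tiling_has_no_gaps_or_overlaps(self):
        spec = default_genome_spec(seed=2)
        _, _, states = simulate_annotation(spec, seed=2)
        for chrom, (starts, ends, labels) in states.arrays().items():
            assert starts[0] == 0
            assert ends[-1] == spec.chromosomes[chrom]
            assert np.array_equal(starts[1:], ends[:-1])
            assert ((labels >= 1) & (labels <= 9)).all()

    def test_genes_pairwise_disjoint_per_base(self):
        spec = GenomeSpec(
            chromosomes={f"c{i}": 1_000_000 for i in range(4)},
            bait=GenomicInterval("c0", 950_000, 1_000_000),
            seed=3,
        )
        genes, _, _ = simulate_annotation(spec, n_genes=200, seed=3)
        assert len(genes) == 200
        for chrom in spec.chromosomes:
            cover = np.zeros(spec.chromosomes[chrom], dtype=np.int8)
            for g in genes:
                if g.interval.chrom == chrom:
                    cover[g.interval.start : g.interval.end] += 1
            assert cover.max() <= 1

    def test_fixed_seed_reproducible(self):
        spec = default_genome_spec(seed=4)
        a = simulate_annotation(spec, seed=4)
        b = simulate_annotation(spec, seed=4)
        assert [g.interval for g in a[0]] == [g.interval for g in b[0]]
        assert [r.interval for r in a[1]] == [r.interval for r in b[1]]
        assert list(a[2].segments()) == list(b[2].segments())

    def test_capacity_error_when_genome_too_small(self):
        spec = GenomeSpec(
            chromosomes={"c": 20_000}, bait=GenomicInterval("c", 15_000, 20_000)
        )
        with pytest.raises(CapacityError):
            simulate_annotation(spec, n_genes=100, n_repeats=0)


class TestContactGenerator:
    def test_same_seed_identical_tracks(self, default_sim):
        spec = default_sim["spec"]
        tracks2, manifest2 = simulate_contact_tracks(
            spec,
            default_sim["genes"],
            default_sim["repeats"],
            default_sim["states"],
            seed=120,
        )
        for key, track in default_sim["tracks"].items():
            assert track.records == tracks2[key].records
        assert manifest2.contact_genes.keys() == default_sim["manifest"].contact_genes.keys()

    def test_track_invariants_hold(self, default_sim):
        for track in default_sim["tracks"].values():
            # ContactTrack construction validates sortedness/disjointness;
            # also check counts are integers
            assert all(float(r.value).is_integer() for r in track.records)

    def test_planted_sites_within_assignment_reach(self, default_sim):
        genes = default_sim["genes"]
        for gid, truth in default_sim["manifest"].contact_genes.items():
            body = genes[gid].interval
            for s in truth.sites:
                assert s.chrom == body.chrom
                assert s.start >= body.start - 2_500
                assert s.end <= body.end + 2_500

    def test_decoys_fully_inside_repeats(self, default_sim):
        repeats = default_sim["repeats"]
        for decoy in default_sim["manifest"].repeat_contacts:
            assert any(r.interval.contains(decoy) for r in repeats)

    def test_planted_sites_never_inside_repeats(self, default_sim):
        repeats = default_sim["repeats"]
        for truth in default_sim["manifest"].contact_genes.values():
            for s in truth.sites:
                assert not any(r.interval.contains(s) for r in repeats)

    def test_zero_dispersion_counts_are_poisson(self):
        spec = default_genome_spec(seed=6)
        genes, repeats, states = simulate_annotation(spec, seed=6)
        params = ContactParams(
            dispersion=0.0, latent_sigma=0.0, n_background=800, background_mean=50.0,
            n_retained=0, n_lost=0, n_gained=0, n_up=0, n_down=0, n_repeat_decoys=0,
        )
        tracks, _ = simulate_contact_tracks(
            spec, genes, repeats, states, params=params, seed=6
        )
        values = np.array([r.value for r in tracks["control_rep1"].records])
        assert len(values) >= 700
        ratio = values.var(ddof=1) / values.mean()
        # variance/mean ~ 1 for Poisson; 3-SE band for the dispersion index
        se = np.sqrt(2 / (len(values) - 1))
        assert abs(ratio - 1) <= 3 * se

    def test_nb_moments_match_specification(self):
        rng_mean, alpha = 400.0, 0.1
        spec = default_genome_spec(seed=7)
        genes, repeats, states = simulate_annotation(spec, seed=7)
        params = ContactParams(
            dispersion=alpha, latent_sigma=0.0, n_background=1_000,
            background_mean=rng_mean,
            n_retained=0, n_lost=0, n_gained=0, n_up=0, n_down=0, n_repeat_decoys=0,
        )
        tracks, _ = simulate_contact_tracks(
            spec, genes, repeats, states, params=params, seed=7
        )
        values = np.array([r.value for r in tracks["hs_rep1"].records])
        n = len(values)
        assert n >= 900
        target_var = rng_mean + alpha * rng_mean**2
        se_mean = np.sqrt(target_var / n)
        assert values.mean() == pytest.approx(rng_mean, abs=3 * se_mean)
        assert values.var(ddof=1) == pytest.approx(target_var, rel=0.25)

    def test_invalid_nb_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ContactParams(site_mean=-5)
        with pytest.raises(ParameterError):
            ContactParams(dispersion=-0.1)


class TestExpressionGenerator:
    def test_two_reps_make_four_columns(self, default_sim):
        counts, _ = simulate_expression_counts(
            default_sim["genes"], {}, n_reps=2, seed=8
        )
        assert counts.counts.shape[1] == 4
        assert sorted(set(counts.conditions.values())) == ["control", "heat_shock"]

    def test_null_conditions_exchangeable(self, default_sim):
        counts, _ = simulate_expression_counts(
            default_sim["genes"], {}, n_reps=2, seed=9
        )
        mat = counts.counts
        ctrl = mat[[c for c in mat if "control" in c]].mean(axis=1)
        hs = mat[[c for c in mat if "hs" in c]].mean(axis=1)
        rel = ((hs - ctrl) / (ctrl + hs) * 2).mean()
        assert abs(rel) < 0.03

    def test_planted_lfc2_gives_fourfold_ratio(self):
        gene_ids = [f"g{i}" for i in range(200)]
        counts, manifest = simulate_expression_counts(
            gene_ids, {g: 2.0 for g in gene_ids}, n_reps=2, seed=10
        )
        mat = counts.counts
        ratio = (
            mat[["rna_hs_rep1", "rna_hs_rep2"]].to_numpy().mean()
            / mat[["rna_control_rep1", "rna_control_rep2"]].to_numpy().mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.15)
        assert manifest.de_genes == {g: 2.0 for g in gene_ids}

    def test_unknown_de_gene_rejected(self, default_sim):
        with pytest.raises(ParameterError):
            simulate_expression_counts(default_sim["genes"], {"nope": 1.0})


class TestSignalGenerator:
    def test_baseline_only_constant(self):
        spec = default_genome_spec()
        track = simulate_signal_track(spec, [], baseline=2.5)
        values = {r.value for r in track.records}
        assert values == {2.5}
        covered = sum(len(r.interval) for r in track.records)
        assert covered == sum(spec.chromosomes.values())

    def test_single_bump_max(self):
        spec = default_genome_spec()
        track = simulate_signal_track(
            spec,
            [GenomicInterval("chr2L", 49_900, 50_100)],
            baseline=1.0,
            bump_height=7.0,
        )
        assert max(r.value for r in track.records) == pytest.approx(8.0)

    def test_overlapping_bumps_additive(self):
        spec = default_genome_spec()
        a = GenomicInterval("chr2L", 49_900, 50_100)
        b = GenomicInterval("chr2L", 50_000, 50_200)
        track = simulate_signal_track(spec, [a, b], baseline=1.0, bump_height=4.0,
                                      bump_width=500)
        # direct summation oracle at a point covered by both bumps
        probe = 50_050
        expected = 1.0
        for s in (a, b):
            lo = s.midpoint - 250
            if lo <= probe < lo + 500:
                expected += 4.0
        at_probe = [
            r.value
            for r in track.records
            if r.interval.chrom == "chr2L" and r.interval.start <= probe < r.interval.end
        ]
        assert at_probe == [pytest.approx(expected)]
        assert expected == 9.0


class TestTruthManifest:
    def test_json_round_trip(self, default_sim, tmp_path):
        manifest = default_sim["manifest"]
        p = tmp_path / "m.json"
        manifest.to_json(str(p))
        back = TruthManifest.from_json(str(p))
        assert back.contact_genes.keys() == manifest.contact_genes.keys()
        for gid in manifest.contact_genes:
            assert back.contact_genes[gid].sites == manifest.contact_genes[gid].sites
            assert back.contact_genes[gid].category == manifest.contact_genes[gid].category
        assert back.repeat_contacts == manifest.repeat_contacts
        assert back.enriched_states == manifest.enriched_states

    def test_expected_gene_sets_follow_categories(self, default_sim):
        manifest = default_sim["manifest"]
        ctrl = manifest.expected_contact_genes("control", 100)
        hs = manifest.expected_contact_genes("heat_shock", 100)
        for gid, truth in manifest.contact_genes.items():
            if truth.category == "gained":
                assert gid not in ctrl and gid in hs
            elif truth.category == "lost":
                assert gid in ctrl and gid not in hs
            elif truth.category == "retained":
                assert gid in ctrl and gid in hs
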