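"""Synthetic-data generators: determinism and truth-table round trips."""

import io

import numpy as np
import pytest

from auxphase import (
    DESimConfig,
    NucleiSimConfig,
    OrthoSimConfig,
    PromoterSimConfig,
    RepeatConfig,
    parse_orthogroups,
    scan_hexamers,
    scan_repeat_configurations,
    segment_nuclei,
    simulate_de_tables,
    simulate_nuclei_image,
    simulate_orthogroups,
    simulate_promoters,
    simulate_vein_counts,
)


class TestSimulatePromoters:
    def test_same_seed_byte_identical(self):
        cfg = PromoterSimConfig(n_fg=20, n_bg=30, seed=5)
        assert simulate_promoters(cfg).sequences == simulate_promoters(cfg).sequences

    def test_planted_repeat_is_recoverable(self):
        cfg = PromoterSimConfig(
            n_fg=15, n_bg=10, planted_config=("DR", 7), fg_rate=1.0, bg_rate=0.0, seed=3
        )
        sim = simulate_promoters(cfg)
        for gid in sim.foreground:
            configs = scan_repeat_configurations(scan_hexamers(sim.sequences[gid]))
            assert RepeatConfig("DR", 7) in configs

    def test_planted_single_hexamer_at_recorded_position(self):
        cfg = PromoterSimConfig(n_fg=10, n_bg=5, fg_rate=1.0, bg_rate=0.0, seed=2)
        sim = simulate_promoters(cfg)
        planted = sim.truth[sim.truth["feature"] != ""]
        for row in planted.itertuples():
            pos = int(row.position)
            assert sim.sequences[row.gene_id][pos : pos + 6] == "TGTCGG"

    def test_zero_rates_leave_truth_empty(self):
        cfg = PromoterSimConfig(n_fg=5, n_bg=5, fg_rate=0.0, bg_rate=0.0, seed=1)
        sim = simulate_promoters(cfg)
        assert (sim.truth["feature"] == "").all()

    def test_too_short_promoter_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            PromoterSimConfig(promoter_length=30, planted_config=("DR", 25))


class TestSimulateDeTables:
    def test_same_seed_identical(self):
        cfg = DESimConfig(n_genes=300, n_responsive=100, seed=4)
        t1, _ = simulate_de_tables(cfg)
        t2, _ = simulate_de_tables(cfg)
        for gen in t1:
            assert t1[gen].equals(t2[gen])

    def test_planted_gap_matches_config(self):
        cfg = DESimConfig(
            n_genes=200, n_responsive=50,
            mock_mu={"gametophyte": 4.0, "sporophyte": 3.0}, seed=1,
        )
        _, truth = simulate_de_tables(cfg)
        assert truth.attrs["planted_amplitude_gap"] == pytest.approx(1.0)

    def test_realized_up_fraction_near_planted(self):
        cfg = DESimConfig(n_genes=3000, n_responsive=2000, up_fraction=0.75, seed=6)
        _, truth = simulate_de_tables(cfg)
        realized = (truth.loc[truth["responsive"], "direction"] == "up").mean()
        assert abs(realized - 0.75) < 0.03

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            DESimConfig(n_replicates=1)


class TestSimulateOrthogroups:
    def test_round_trip_parses_losslessly(self):
        sim = simulate_orthogroups(OrthoSimConfig(n_og=50, seed=2))
        table = parse_orthogroups(io.StringIO(sim.tsv_text))
        assert len(table.groups) == 50
        assert table.species == ("ceratopteris", "marchantia")

    def test_deg_lists_map_back_to_chosen_orthogroups(self):
        sim = simulate_orthogroups(OrthoSimConfig(n_og=80, deg_overlap_rate=0.4, seed=3))
        table = parse_orthogroups(io.StringIO(sim.tsv_text))
        for sp in table.species:
            mapping = table.gene_to_group(sp)
            chosen = set(sim.truth.loc[sim.truth[f"deg_{sp}"], "orthogroup"])
            assert {mapping[g] for g in sim.deg_lists[sp]} == chosen

    def test_core_is_shared_across_species(self):
        sim = simulate_orthogroups(OrthoSimConfig(n_og=80, deg_overlap_rate=0.5, seed=4))
        core = sim.truth[sim.truth["core"]]
        for sp in ("ceratopteris", "marchantia"):
            assert core[f"deg_{sp}"].all()

    def test_same_seed_identical(self):
        cfg = OrthoSimConfig(n_og=40, seed=9)
        assert simulate_orthogroups(cfg).tsv_text == simulate_orthogroups(cfg).tsv_text


class TestSimulateVeinCounts:
    def test_poisson_mean_recovery(self):
        counts, _ = simulate_vein_counts(
            {"mock": (10, 5, 2, 3)}, dispersion=0.0, n_leaves=200, seed=1
        )
        assert abs(counts["touch"].mean() - 10) < 3 * np.sqrt(10 / 200)

    def test_same_seed_identical(self):
        a, _ = simulate_vein_counts({"g": (5, 5, 5, 5)}, n_leaves=10, seed=3)
        b, _ = simulate_vein_counts({"g": (5, 5, 5, 5)}, n_leaves=10, seed=3)
        assert a.equals(b)

    def test_all_zero_means_rejected(self):
        with pytest.raises(ValueError):
            simulate_vein_counts({"g": (0, 0, 0, 0)})


class TestSimulateNucleiImage:
    def test_two_clean_nuclei_have_disc_area(self):
        cfg = NucleiSimConfig(n_nuclei=2, radius=6, noise_cv=0.0, seed=5)
        img_a, _, _ = simulate_nuclei_image(cfg)
        rois = segment_nuclei(img_a, min_area=30)
        # rasterized disc: pixels with r^2 <= radius^2 around integer center
        disc_area = sum(
            1
            for dr in range(-6, 7)
            for dc in range(-6, 7)
            if dr * dr + dc * dc <= 36
        )
        assert len(rois) == 2
        assert all(r.area == disc_area for r in rois)

    def test_same_seed_identical_images(self):
        cfg = NucleiSimConfig(n_nuclei=10, seed=7)
        a1, b1, _ = simulate_nuclei_image(cfg)
        a2, b2, _ = simulate_nuclei_image(cfg)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            simulate_nuclei_image(NucleiSimConfig(n_nuclei=500, radius=10, shape=(100, 100)))
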