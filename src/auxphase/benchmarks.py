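"""Recovery experiments run on the synthetic generators.

Each function plants a known signal with one generator, runs the matching
analysis stage, and reports how well the signal is recovered.  They are the
workhorses behind the analysis drivers and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometrics import nuclear_intensity_summary, segment_nuclei
from .motifs import (
    RepeatConfig,
    hexamer_enrichment_table,
    repeat_configs_by_gene,
    repeat_enrichment_table,
)
from .orthogroups import map_set_to_orthogroups, overlap_enrichment, parse_orthogroups
from .profiles import amplitude_decomposition, classify_degs
from .simulate import (
    DESimConfig,
    NucleiSimConfig,
    OrthoSimConfig,
    PromoterSimConfig,
    simulate_de_tables,
    simulate_nuclei_image,
    simulate_orthogroups,
    simulate_promoters,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2**31 derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def planted_syntax_recovery(
    seed: int,
    n_seeds: int = 100,
    planted_config: tuple[str, int] = ("DR", 7),
    planted_hexamer: str = "TGTCGG",
    n_fg: int = 150,
    n_bg: int = 1000,
    fg_rate: float = 0.4,
    bg_rate: float = 0.05,
) -> pd.DataFrame:
    """Plant a spaced hexamer repeat and ask whether enrichment recovers it.

    Planting a repeat of ``planted_hexamer`` puts two copies of the hexamer
    in each selected promoter, so one planting simultaneously enriches the
    single hexamer and the (orientation, spacer) configuration.  Per
    simulation seed, the minimum-p hexamer of the 16 and the minimum-p
    consensus configuration of the 78 are recorded.
    """
    target_config = RepeatConfig(*planted_config)
    rows = []
    for run_seed in _child_seeds(seed, n_seeds):
        sim = simulate_promoters(
            PromoterSimConfig(
                n_fg=n_fg, n_bg=n_bg, fg_rate=fg_rate, bg_rate=bg_rate,
                planted_hexamer=planted_hexamer, planted_config=planted_config,
                seed=run_seed,
            )
        )
        hex_records = hexamer_enrichment_table(sim.fg_sequences, sim.bg_sequences)
        top_hexamer = hex_records[0].feature
        rep_records = repeat_enrichment_table(
            repeat_configs_by_gene(sim.fg_sequences),
            repeat_configs_by_gene(sim.bg_sequences),
        )
        top_config = rep_records[0].feature
        rows.append(
            dict(
                seed=run_seed,
                top_hexamer=top_hexamer,
                top_hexamer_p=hex_records[0].p_value,
                hexamer_recovered=top_hexamer == planted_hexamer,
                top_config=f"{top_config.orientation}_{top_config.spacer}",
                top_config_p=rep_records[0].p_value,
                config_recovered=top_config == target_config,
            )
        )
    return pd.DataFrame(rows)


def de_profile_recovery(
    seed: int,
    config: DESimConfig | None = None,
    alpha: float = 0.05,
    k: int = 20,
) -> dict:
    """Classify simulated DE tables and recover the planted response structure.

    Reports, per generation, the DEG up fraction among planted-responsive
    genes (truth-restricted, so the emulated null's false positives do not
    dilute the planted binomial signal), the realized truth-table up
    fraction, top-k mock/treated means and the mean log2 fold change of up
    DEGs; plus the recovered between-generation amplitude gap (difference of
    top-k mock means) against the planted gap.
    """
    if config is None:
        config = DESimConfig(seed=seed)
    elif config.seed != seed:
        config = DESimConfig(**{**config.__dict__, "seed": seed})
    tables, truth = simulate_de_tables(config)
    responsive_ids = set(truth.loc[truth["responsive"], "gene_id"])
    out: dict = {
        "planted_amplitude_gap": truth.attrs["planted_amplitude_gap"],
        "truth_up_fraction": float(
            (truth.loc[truth["responsive"], "direction"] == "up").mean()
        ),
        "n_responsive": int(truth["responsive"].sum()),
        "generations": {},
    }
    mock_means = {}
    for generation, table in tables.items():
        classified = classify_degs(table, alpha=alpha)
        on_truth = classified[classified["gene_id"].isin(responsive_ids)]
        deg = on_truth[on_truth["deg_class"].isin(["up", "down"])]
        up = classified[classified["deg_class"] == "up"]
        decomp = amplitude_decomposition(classified, k=k, direction="up")
        mock_means[generation] = decomp.top_mock_mean
        out["generations"][generation] = dict(
            recovered_up_fraction=float((deg["deg_class"] == "up").mean()),
            n_deg_on_truth=len(deg),
            mean_up_l2fc=float(up["log2fc"].mean()),
            top_mock_mean=decomp.top_mock_mean,
            top_treated_mean=decomp.top_treated_mean,
            bottom_mock_mean=decomp.bottom_mock_mean,
            mock_rank_p=decomp.mock_p,
        )
    gens = list(tables)
    if len(gens) == 2:
        out["recovered_amplitude_gap"] = float(abs(mock_means[gens[0]] - mock_means[gens[1]]))
        low_gen = min(gens, key=lambda g: config.mock_mu[g])
        high_gen = max(gens, key=lambda g: config.mock_mu[g])
        out["low_mock_generation"] = low_gen
        out["low_mock_has_larger_fc"] = bool(
            out["generations"][low_gen]["mean_up_l2fc"]
            > out["generations"][high_gen]["mean_up_l2fc"]
        )
    return out


def ortho_overlap_power(
    seed: int, n_seeds: int = 100, deg_overlap_rate: float = 0.5, n_og: int = 500
) -> pd.DataFrame:
    """Simulate orthogroup tables with planted joint DEG membership and test
    the overlap; reports the hypergeometric p per seed."""
    import io

    rows = []
    for run_seed in _child_seeds(seed, n_seeds):
        sim = simulate_orthogroups(
            OrthoSimConfig(n_og=n_og, deg_overlap_rate=deg_overlap_rate, seed=run_seed)
        )
        table = parse_orthogroups(io.StringIO(sim.tsv_text))
        sp_a, sp_b = table.species[:2]
        set_a, _ = map_set_to_orthogroups(sim.deg_lists[sp_a], sp_a, table)
        set_b, _ = map_set_to_orthogroups(sim.deg_lists[sp_b], sp_b, table)
        universe = table.groups_with_species(sp_a, sp_b)
        res = overlap_enrichment(set_a & universe, set_b & universe, universe)
        rows.append(
            dict(seed=run_seed, overlap=res.n_overlap, expected=res.expected,
                 p_value=res.p_value)
        )
    return pd.DataFrame(rows)


def nuclei_ratio_recovery(
    seed: int, n_seeds: int = 100, group_ratio: float = 2.0, min_area: int = 30
) -> pd.DataFrame:
    """Simulate nuclei image pairs and recover the planted intensity ratio
    by segmentation + median-intensity summary."""
    rows = []
    for run_seed in _child_seeds(seed, n_seeds):
        img_a, img_b, _truth = simulate_nuclei_image(
            NucleiSimConfig(group_ratio=group_ratio, seed=run_seed)
        )
        rois_a = segment_nuclei(img_a, min_area=min_area)
        rois_b = segment_nuclei(img_b, min_area=min_area)
        summary = nuclear_intensity_summary(rois_a, rois_b)
        rows.append(
            dict(seed=run_seed, n_a=summary.n_a, n_b=summary.n_b,
                 ratio=summary.ratio, rank_test_p=summary.rank_test_p)
        )
    return pd.DataFrame(rows)
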