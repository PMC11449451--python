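"""Seeded synthetic inputs with the statistical structure the analyses assume.

Each generator emulates one class of study input — promoter sets with planted
AuxRE singles or spaced repeats, DESeq2-style DE tables with a controlled
activation:repression ratio and generation-specific repression depth,
orthogroup tables with controlled cross-species DEG overlap, vein feature-
point counts, and nuclei images with a controlled group intensity ratio —
and returns a truth table recording every planted feature, so recovery by
the corresponding analysis stage is testable without any download.

A single root seed expands into independent per-component child streams via
``numpy.random.SeedSequence(seed, spawn_key=(component,))`` with fixed
component numbers, so adding a generator never perturbs the others' output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoters import reverse_complement

# fixed spawn-key component numbers (never renumber)
_PROMOTERS, _DE, _ORTHO, _VEINS, _NUCLEI = 1, 2, 3, 4, 5

_BASES = np.array(list("ACGT"))


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


# ---------------------------------------------------------------------------
# promoters with planted AuxRE syntax


@dataclass(frozen=True)
class PromoterSimConfig:
    """Foreground/background promoter sets with planted TGTCNN features.

    When ``planted_config`` is given, each selected promoter receives a
    spaced repeat of ``planted_hexamer`` with that (orientation, spacer);
    otherwise a single hexamer copy is planted.  Selection happens with
    probability ``fg_rate`` per foreground and ``bg_rate`` per background
    promoter.
    """

    n_fg: int = 150
    n_bg: int = 1000
    promoter_length: int = 600
    gc_content: float = 0.4
    planted_hexamer: str = "TGTCGG"
    planted_config: tuple[str, int] | None = None
    fg_rate: float = 0.4
    bg_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fg_rate <= 1 and 0 <= self.bg_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        insert = 6
        if self.planted_config is not None:
            orientation, spacer = self.planted_config
            if orientation not in {"DR", "IR", "ER"}:
                raise ValueError("planted_config orientation must be DR, IR or ER")
            if spacer < 0:
                raise ValueError("planted_config spacer must be >= 0")
            insert = 12 + spacer
        if self.promoter_length < insert:
            raise ValueError(
                f"promoter_length {self.promoter_length} too short for a "
                f"{insert} bp planted feature"
            )


@dataclass(frozen=True)
class SimulatedPromoters:
    sequences: dict[str, str]
    foreground: tuple[str, ...]
    background: tuple[str, ...]
    truth: pd.DataFrame

    @property
    def fg_sequences(self) -> dict[str, str]:
        return {g: self.sequences[g] for g in self.foreground}

    @property
    def bg_sequences(self) -> dict[str, str]:
        return {g: self.sequences[g] for g in self.background}


def _random_sequences(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=(n, length), p=p)
    letters = _BASES[codes]
    return ["".join(row) for row in letters]


def _planted_insert(cfg: PromoterSimConfig, rng: np.random.Generator) -> str:
    hexamer = cfg.planted_hexamer
    if cfg.planted_config is None:
        return hexamer
    orientation, spacer = cfg.planted_config
    spacer_seq = "".join(
        rng.choice(list("ACGT"), size=spacer, p=[(1 - cfg.gc_content) / 2,
                                                cfg.gc_content / 2,
                                                cfg.gc_content / 2,
                                                (1 - cfg.gc_content) / 2])
    ) if spacer else ""
    rc = reverse_complement(hexamer)
    if orientation == "DR":
        left, right = hexamer, hexamer
    elif orientation == "IR":  # convergent: + then -
        left, right = hexamer, rc
    else:  # ER, divergent: - then +
        left, right = rc, hexamer
    return left + spacer_seq + right


def simulate_promoters(config: PromoterSimConfig) -> SimulatedPromoters:
    """Generate foreground/background promoter FASTA-ready sequences.

    Background composition is i.i.d. at the configured GC content; planted
    features overwrite a uniformly chosen stretch and are recorded in the
    truth table (gene_id, is_foreground, feature, position).
    """
    rng = _rng(config.seed, _PROMOTERS)
    fg_ids = tuple(f"fg_{i:05d}" for i in range(config.n_fg))
    bg_ids = tuple(f"bg_{i:05d}" for i in range(config.n_bg))
    seqs = _random_sequences(
        rng, config.n_fg + config.n_bg, config.promoter_length, config.gc_content
    )
    sequences = dict(zip(fg_ids + bg_ids, seqs))

    if config.planted_config is None:
        feature_name = config.planted_hexamer
    else:
        orientation, spacer = config.planted_config
        feature_name = f"{orientation}_{spacer}:{config.planted_hexamer}"

    truth_rows = []
    for gid, rate, is_fg in [(g, config.fg_rate, True) for g in fg_ids] + [
        (g, config.bg_rate, False) for g in bg_ids
    ]:
        planted = bool(rng.random() < rate)
        position = -1
        if planted:
            insert = _planted_insert(config, rng)
            position = int(rng.integers(0, config.promoter_length - len(insert) + 1))
            s = sequences[gid]
            sequences[gid] = s[:position] + insert + s[position + len(insert):]
        truth_rows.append(
            dict(gene_id=gid, is_foreground=is_fg,
                 feature=feature_name if planted else "", position=position)
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedPromoters(
        sequences=sequences, foreground=fg_ids, background=bg_ids, truth=truth
    )


# ---------------------------------------------------------------------------
# differential-expression tables


@dataclass(frozen=True)
class DESimConfig:
    """Two-generation DE tables with planted direction ratio and amplitude gap.

    ``mock_mu`` gives the generation-level mock (repressed-state) mean of
    responsive genes on the log2 scale; the generation with the lower value
    emulates the sporophyte's deeper repression.  Induced-state gene means
    are drawn once and shared across generations, so the planted amplitude
    gap equals the difference in ``mock_mu``.  Defaults follow the reported
    top-20 activated-gene expression levels (mock 3.78 vs 2.76, treated ~7
    log2 units) with replicate noise typical of strongly expressed genes.
    """

    n_genes: int = 10000
    n_responsive: int = 2000
    up_fraction: float = 0.75
    mock_mu: Mapping[str, float] = field(
        default_factory=lambda: {"gametophyte": 3.78, "sporophyte": 2.76}
    )
    treated_mu: float = 7.0
    treated_spread: float = 1.0  # gene-level sd of induced means (log2)
    sd: float = 0.25  # replicate-level noise sd (log2)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responsive > self.n_genes:
            raise ValueError("n_responsive cannot exceed n_genes")
        if not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def simulate_de_tables(config: DESimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit one DESeq2-style table per generation plus the truth table.

    Responsive genes are up with probability ``up_fraction``; up genes sit at
    the generation's mock level and rise to a shared gene-specific induced
    level under treatment, down genes do the reverse.  Adjusted p-values are
    emulated (tiny for responsive genes, uniform for null genes) rather than
    fitted — this is a stand-in for a DE model, not a DE method.
    """
    rng = _rng(config.seed, _DE)
    n, m = config.n_genes, config.n_responsive
    gene_ids = [f"g_{i:06d}" for i in range(n)]
    responsive = np.zeros(n, dtype=bool)
    responsive[:m] = True
    is_up = np.zeros(n, dtype=bool)
    is_up[:m] = rng.random(m) < config.up_fraction

    induced = config.treated_mu + rng.normal(0.0, config.treated_spread, size=n)
    baseline = rng.normal(5.0, 1.5, size=n)  # null genes
    padj = np.where(
        responsive, 10.0 ** (-rng.uniform(3.0, 10.0, size=n)), rng.uniform(0.0, 1.0, size=n)
    )

    tables: dict[str, pd.DataFrame] = {}
    for generation in config.mock_mu:
        mock_level = np.where(
            responsive,
            np.where(is_up, config.mock_mu[generation], induced),
            baseline,
        )
        treated_level = np.where(
            responsive,
            np.where(is_up, induced, config.mock_mu[generation]),
            baseline,
        )
        # observed condition means: average of n_replicates iid N(level, sd)
        mock_obs = mock_level + rng.normal(0.0, config.sd, size=(config.n_replicates, n)).mean(axis=0)
        treated_obs = treated_level + rng.normal(
            0.0, config.sd, size=(config.n_replicates, n)
        ).mean(axis=0)
        tables[generation] = pd.DataFrame(
            dict(
                gene_id=gene_ids,
                log2fc=treated_obs - mock_obs,
                padj=padj,
                norm_expr_mock=mock_obs,
                norm_expr_treated=treated_obs,
            )
        )
    truth = pd.DataFrame(
        dict(
            gene_id=gene_ids,
            responsive=responsive,
            direction=np.where(responsive, np.where(is_up, "up", "down"), "none"),
            induced_mean=induced,
        )
    )
    mus = list(config.mock_mu.values())
    truth.attrs["planted_amplitude_gap"] = float(max(mus) - min(mus)) if len(mus) > 1 else 0.0
    return tables, truth


# ---------------------------------------------------------------------------
# orthogroup tables with controlled DEG overlap


@dataclass(frozen=True)
class OrthoSimConfig:
    n_og: int = 500
    species: tuple[str, ...] = ("ceratopteris", "marchantia")
    deg_overlap_rate: float = 0.0
    set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.deg_overlap_rate <= 1:
            raise ValueError("deg_overlap_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedOrthogroups:
    tsv_text: str
    deg_lists: dict[str, tuple[str, ...]]
    truth: pd.DataFrame


def simulate_orthogroups(config: OrthoSimConfig) -> SimulatedOrthogroups:
    """Orthogroup TSV plus per-species DEG gene lists with controlled overlap.

    A fraction ``deg_overlap_rate`` of each species' DEG orthogroups is drawn
    from a shared core (planted joint responsiveness); the rest is drawn
    independently, so rate 0 reproduces the independence baseline.
    """
    rng = _rng(config.seed, _ORTHO)
    counts = rng.choice([0, 1, 2, 3], size=(config.n_og, len(config.species)),
                        p=[0.1, 0.5, 0.25, 0.15])
    og_ids = [f"OG{i:05d}" for i in range(config.n_og)]
    gene_counter = {sp: 0 for sp in config.species}
    members: dict[str, dict[str, list[str]]] = {}
    for i, og in enumerate(og_ids):
        row = {}
        for j, sp in enumerate(config.species):
            ids = []
            for _ in range(counts[i, j]):
                ids.append(f"{sp}_g{gene_counter[sp]:06d}")
                gene_counter[sp] += 1
            row[sp] = ids
        members[og] = row

    eligible = {
        sp: [og for og in og_ids if members[og][sp]] for sp in config.species
    }
    joint = [og for og in og_ids if all(members[og][sp] for sp in config.species)]
    core_n = int(round(config.deg_overlap_rate * config.set_size))
    core_n = min(core_n, len(joint))
    core = list(rng.choice(joint, size=core_n, replace=False)) if core_n else []

    deg_lists: dict[str, tuple[str, ...]] = {}
    chosen_ogs: dict[str, list[str]] = {}
    for sp in config.species:
        pool = [og for og in eligible[sp] if og not in set(core)]
        fill_n = min(config.set_size - core_n, len(pool))
        fill = list(rng.choice(pool, size=fill_n, replace=False)) if fill_n else []
        ogs = sorted(core + fill)
        chosen_ogs[sp] = ogs
        deg_lists[sp] = tuple(
            members[og][sp][int(rng.integers(0, len(members[og][sp])))] for og in ogs
        )

    lines = ["orthogroup\t" + "\t".join(config.species)]
    for og in og_ids:
        lines.append(og + "\t" + "\t".join(", ".join(members[og][sp]) for sp in config.species))
    tsv_text = "\n".join(lines) + "\n"

    truth = pd.DataFrame(
        dict(
            orthogroup=og_ids,
            core=[og in set(core) for og in og_ids],
            **{f"deg_{sp}": [og in set(chosen_ogs[sp]) for og in og_ids] for sp in config.species},
        )
    )
    return SimulatedOrthogroups(tsv_text=tsv_text, deg_lists=deg_lists, truth=truth)


# ---------------------------------------------------------------------------
# vein feature-point counts


def simulate_vein_counts(
    group_means: Mapping[str, Sequence[float]],
    dispersion: float = 0.0,
    n_leaves: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-leaf (T, E, B, X) counts around per-group means.

    Counts are independent negative binomial (gamma-Poisson) with the given
    dispersion, collapsing to Poisson at dispersion 0.  ``group_means`` maps
    group name to the four mean counts in T, E, B, X order.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for group, means in group_means.items():
        means = np.asarray(means, dtype=float)
        if means.shape != (4,):
            raise ValueError(f"group {group!r}: expected 4 means (T, E, B, X)")
        if (means < 0).any() or means.sum() == 0:
            raise ValueError(f"group {group!r}: means must be non-negative, not all zero")
    rng = _rng(seed, _VEINS)
    rows = []
    for group in group_means:
        means = np.asarray(group_means[group], dtype=float)
        for i in range(n_leaves):
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
            else:
                lam = means
            t, e, b, x = (int(v) for v in rng.poisson(lam))
            rows.append(dict(leaf_id=f"{group}_leaf{i:03d}", group=group,
                             touch=t, end=e, brk=b, exit=x))
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [dict(group=g, mean_touch=m[0], mean_end=m[1], mean_brk=m[2], mean_exit=m[3],
              dispersion=dispersion)
         for g, m in ((g, np.asarray(m, float)) for g, m in group_means.items())]
    )
    return counts, truth


# ---------------------------------------------------------------------------
# nuclei images


@dataclass(frozen=True)
class NucleiSimConfig:
    n_nuclei: int = 50
    radius: int = 6
    base_intensity: float = 100.0
    group_ratio: float = 2.0
    noise_cv: float = 0.05
    shape: tuple[int, int] = (400, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


def _place_discs(rng: np.random.Generator, cfg: NucleiSimConfig) -> list[tuple[int, int]]:
    h, w = cfg.shape
    margin = cfg.radius + 1
    min_sep = 2 * cfg.radius + 2
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < cfg.n_nuclei:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei in {cfg.shape}"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def _render(cfg: NucleiSimConfig, rng: np.random.Generator,
            centers: list[tuple[int, int]], intensities: np.ndarray) -> np.ndarray:
    h, w = cfg.shape
    img = np.abs(rng.normal(0.0, cfg.base_intensity * 0.01, size=(h, w)))
    rr, cc = np.mgrid[0:h, 0:w]
    for (r0, c0), val in zip(centers, intensities):
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= cfg.radius**2
        img[disc] = val
    return img


def simulate_nuclei_image(config: NucleiSimConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """A pair of greyscale images whose group-b nuclei are ``group_ratio``
    times brighter than group-a, with lognormal per-nucleus variation.

    Returns ``(image_a, image_b, truth)``; truth records every nucleus
    center and intensity plus the planted ratio.
    """
    rng = _rng(config.seed, _NUCLEI)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    def noise(n: int) -> np.ndarray:
        if sigma == 0:
            return np.ones(n)
        return rng.lognormal(-sigma**2 / 2, sigma, size=n)  # unit-mean multiplier

    centers_a = _place_discs(rng, config)
    centers_b = _place_discs(rng, config)
    int_a = config.base_intensity * noise(config.n_nuclei)
    int_b = config.base_intensity * config.group_ratio * noise(config.n_nuclei)
    img_a = _render(config, rng, centers_a, int_a)
    img_b = _render(config, rng, centers_b, int_b)
    truth = pd.DataFrame(
        dict(
            group=["a"] * config.n_nuclei + ["b"] * config.n_nuclei,
            row=[c[0] for c in centers_a + centers_b],
            col=[c[1] for c in centers_a + centers_b],
            intensity=np.concatenate([int_a, int_b]),
        )
    )
    truth.attrs["group_ratio"] = config.group_ratio
    return img_a, img_b, truth
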