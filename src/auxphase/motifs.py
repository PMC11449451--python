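"""AuxRE hexamer scanning, spaced-repeat syntax, and gene-level Fisher enrichment.

The auxin response element (AuxRE) is analyzed as the 16 TGTCNN hexamers: a
fixed TGTC core plus two free bases.  Because ARF transcription factors bind
cooperatively as dimers, pairs of hexamers separated by a short spacer are
classified by orientation: DR (direct repeat, both copies on the same strand),
IR (inverted/convergent, cores pointing at each other) and ER
(everted/divergent, cores pointing away).  Enrichment of a feature in a
foreground promoter set against a background is measured at the gene level:
a gene either has (>=1 occurrence) or lacks the feature, and the 2x2 gene
count table is tested with a one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .promoters import reverse_complement

_IUPAC = set("ACGTRYSWKMBDHVN")
_ACGT = set("ACGT")

HEXAMERS: tuple[str, ...] = tuple(
    sorted("TGTC" + a + b for a in "ACGT" for b in "ACGT")
)

ORIENTATIONS: tuple[str, ...] = ("DR", "IR", "ER")


@dataclass(frozen=True, order=True)
class HexamerOccurrence:
    """A strand-aware hexamer hit; the hexamer is always written core-first."""

    gene_id: str
    offset: int
    strand_rel: str  # '+': reads TGTCNN on the given sequence; '-': on its revcomp
    hexamer: str

    def __post_init__(self) -> None:
        if not self.hexamer.startswith("TGTC"):
            raise ValueError(f"hexamer must start with the TGTC core, got {self.hexamer}")
        if self.strand_rel not in {"+", "-"}:
            raise ValueError("strand_rel must be '+' or '-'")


@dataclass(frozen=True, order=True)
class RepeatConfig:
    """An (orientation, spacer) repeat descriptor, optionally hexamer-resolved."""

    orientation: str
    spacer: int
    hexamer_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.spacer < 0:
            raise ValueError("spacer must be non-negative")


@dataclass(frozen=True)
class EnrichmentRecord:
    """A gene-level 2x2 contingency with its exact one-sided p-value."""

    feature: object
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p_value: float

    @property
    def fg_fraction(self) -> float:
        return self.fg_with / self.fg_total

    @property
    def bg_fraction(self) -> float:
        return self.bg_with / self.bg_total

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value))


def scan_hexamers(sequence: str, gene_id: str = "", core: str = "TGTC") -> list[HexamerOccurrence]:
    """Find every complete-footprint core hexamer on either strand.

    A '+' occurrence reads ``core + NN`` on the given sequence; a '-'
    occurrence reads it on the reverse complement, and is reported at the
    footprint's left edge on the given sequence with the hexamer written
    core-first.  Overlapping occurrences are all reported; any non-ACGT base
    inside a footprint voids the match.
    """
    seq = sequence.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    rc_core = reverse_complement(core)
    k = len(core)
    hits: list[HexamerOccurrence] = []

    i = seq.find(core)
    while i != -1:
        if i + 6 <= len(seq):
            hexamer = seq[i : i + 6]
            if set(hexamer) <= _ACGT:
                hits.append(HexamerOccurrence(gene_id, i, "+", hexamer))
        i = seq.find(core, i + 1)

    # On the reverse strand the footprint ends with the reverse-complemented
    # core, so its left edge sits (6 - k) bases before the rc-core match.
    j = seq.find(rc_core)
    while j != -1:
        i = j - (6 - k)
        if i >= 0 and i + 6 <= len(seq):
            footprint = seq[i : i + 6]
            if set(footprint) <= _ACGT:
                hits.append(HexamerOccurrence(gene_id, i, "-", reverse_complement(footprint)))
        j = seq.find(rc_core, j + 1)

    hits.sort(key=lambda h: (h.offset, h.strand_rel))
    return hits


def fisher_exact_enrichment(
    fg_with: int,
    fg_total: int,
    bg_with: int,
    bg_total: int,
    alternative: str = "greater",
) -> float:
    """One-sided Fisher exact p for gene-level over-representation.

    Equivalent to the hypergeometric tail: draw ``fg_total`` genes from the
    pooled ``fg_total + bg_total`` of which ``fg_with + bg_with`` carry the
    feature; p = P[X >= fg_with] (or <= for ``alternative='less'``).
    """
    for name, v in (("fg_with", fg_with), ("fg_total", fg_total),
                    ("bg_with", bg_with), ("bg_total", bg_total)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    if fg_total == 0 or bg_total == 0:
        raise ValueError("fg_total and bg_total must be positive")
    if fg_with > fg_total or bg_with > bg_total:
        raise ValueError("'with' counts cannot exceed totals")
    n_pool = fg_total + bg_total
    k_pool = fg_with + bg_with
    if alternative == "greater":
        p = float(hypergeom.sf(fg_with - 1, n_pool, k_pool, fg_total))
    elif alternative == "less":
        p = float(hypergeom.cdf(fg_with, n_pool, k_pool, fg_total))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def _check_fg_bg(fg: Mapping[str, object], bg: Mapping[str, object]) -> None:
    if not fg:
        raise ValueError("empty foreground set")
    shared = set(fg) & set(bg)
    if shared:
        raise ValueError(f"genes present in both foreground and background: {sorted(shared)[:5]}")


def hexamer_presence(promoters: Mapping[str, str], core: str = "TGTC") -> dict[str, set[str]]:
    """Per-gene set of hexamers present (either strand) in each promoter."""
    return {
        gid: {occ.hexamer for occ in scan_hexamers(seq, gid, core=core)}
        for gid, seq in promoters.items()
    }


def hexamer_enrichment_table(
    fg_promoters: Mapping[str, str],
    bg_promoters: Mapping[str, str],
    core: str = "TGTC",
) -> list[EnrichmentRecord]:
    """Gene-level enrichment of all 16 TGTCNN hexamers, sorted by p-value."""
    _check_fg_bg(fg_promoters, bg_promoters)
    fg_sets = hexamer_presence(fg_promoters, core)
    bg_sets = hexamer_presence(bg_promoters, core)
    fg_total, bg_total = len(fg_promoters), len(bg_promoters)
    records = []
    for hexamer in HEXAMERS:
        fg_with = sum(1 for s in fg_sets.values() if hexamer in s)
        bg_with = sum(1 for s in bg_sets.values() if hexamer in s)
        p = fisher_exact_enrichment(fg_with, fg_total, bg_with, bg_total)
        records.append(EnrichmentRecord(hexamer, fg_with, fg_total, bg_with, bg_total, p))
    records.sort(key=lambda r: (r.p_value, str(r.feature)))
    return records


def scan_repeat_configurations(
    occurrences: Sequence[HexamerOccurrence],
    min_spacer: int = 0,
    max_spacer: int = 25,
    with_pairs: bool = False,
) -> set[RepeatConfig]:
    """Distinct repeat configurations among one gene's hexamer occurrences.

    Every ordered pair of non-overlapping occurrences (left footprint before
    right footprint) whose spacer ``right.offset - left.offset - 6`` lies in
    ``[min_spacer, max_spacer]`` contributes a config.  Orientation: DR when
    both strands agree, IR for (+, -) (convergent cores), ER for (-, +)
    (divergent cores).  Output is a presence set, not a multiset.
    """
    configs: set[RepeatConfig] = set()
    occ = sorted(occurrences, key=lambda h: h.offset)
    for a in range(len(occ)):
        for b in range(a + 1, len(occ)):
            left, right = occ[a], occ[b]
            spacer = right.offset - (left.offset + 6)
            if spacer < min_spacer or spacer > max_spacer:
                continue
            if left.strand_rel == right.strand_rel:
                orientation = "DR"
            elif left.strand_rel == "+":
                orientation = "IR"
            else:
                orientation = "ER"
            configs.add(RepeatConfig(orientation, spacer))
            if with_pairs:
                configs.add(RepeatConfig(orientation, spacer, (left.hexamer, right.hexamer)))
    return configs


def repeat_configs_by_gene(
    promoters: Mapping[str, str],
    min_spacer: int = 0,
    max_spacer: int = 25,
    core: str = "TGTC",
    with_pairs: bool = False,
) -> dict[str, set[RepeatConfig]]:
    """Scan each promoter and return its set of repeat configurations."""
    return {
        gid: scan_repeat_configurations(
            scan_hexamers(seq, gid, core=core), min_spacer, max_spacer, with_pairs
        )
        for gid, seq in promoters.items()
    }


def repeat_enrichment_table(
    fg_configs: Mapping[str, set[RepeatConfig]],
    bg_configs: Mapping[str, set[RepeatConfig]],
    min_spacer: int = 0,
    max_spacer: int = 25,
    include_pairs: bool = False,
) -> list[EnrichmentRecord]:
    """Gene-level enrichment of every (orientation, spacer) configuration.

    At consensus level this is 3 orientations x (max_spacer - min_spacer + 1)
    spacers (78 records for the 0-25 default), reported whether or not any
    gene carries the config.  Hexamer-resolved pair records are appended when
    ``include_pairs`` and the input sets carry pair-level configs.
    """
    _check_fg_bg(fg_configs, bg_configs)
    fg_total, bg_total = len(fg_configs), len(bg_configs)
    universe: list[RepeatConfig] = [
        RepeatConfig(orientation, spacer)
        for orientation in ORIENTATIONS
        for spacer in range(min_spacer, max_spacer + 1)
    ]
    if include_pairs:
        seen = {
            c for s in list(fg_configs.values()) + list(bg_configs.values())
            for c in s if c.hexamer_pair is not None
        }
        universe.extend(sorted(seen))
    records = []
    for config in universe:
        fg_with = sum(1 for s in fg_configs.values() if config in s)
        bg_with = sum(1 for s in bg_configs.values() if config in s)
        p = fisher_exact_enrichment(fg_with, fg_total, bg_with, bg_total)
        records.append(EnrichmentRecord(config, fg_with, fg_total, bg_with, bg_total, p))
    records.sort(key=lambda r: (r.p_value, str(r.feature)))
    return records


def enrichment_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records; adds Benjamini-Hochberg q-values.

    Reported p-values are raw (one-sided); the q column is an auxiliary
    BH correction across the records in the frame.
    """
    records = list(records)
    rows = []
    for r in records:
        feature = r.feature
        if isinstance(feature, RepeatConfig):
            name = f"{feature.orientation}_{feature.spacer}"
            if feature.hexamer_pair:
                name += "_" + "/".join(feature.hexamer_pair)
        else:
            name = str(feature)
        rows.append(
            dict(
                feature=name,
                fg_with=r.fg_with,
                fg_total=r.fg_total,
                bg_with=r.bg_with,
                bg_total=r.bg_total,
                fg_fraction=r.fg_fraction,
                bg_fraction=r.bg_fraction,
                p_value=r.p_value,
                neg_log10_p=r.neg_log10_p,
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
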