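"""Cross-species set comparison in orthogroup space.

Gene (or phosphoprotein) identifiers are mapped to OrthoFinder-style
orthogroups and compared as sets of orthogroups, so that species with very
different gene counts become commensurable.  Overlap of two sets is judged
against the hypergeometric null on a shared universe of orthogroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)


@dataclass
class OrthogroupTable:
    """orthogroup_id -> {species -> gene ids}; genes keep their first assignment."""

    groups: dict[str, dict[str, list[str]]]
    species: tuple[str, ...]

    def gene_to_group(self, species: str) -> dict[str, str]:
        if species not in self.species:
            raise KeyError(f"unknown species {species!r}; known: {self.species}")
        mapping: dict[str, str] = {}
        for og_id, members in self.groups.items():
            for gid in members.get(species, []):
                mapping.setdefault(gid, og_id)
        return mapping

    def groups_with_species(self, *species: str) -> set[str]:
        """Orthogroups containing at least one gene from every named species."""
        return {
            og_id
            for og_id, members in self.groups.items()
            if all(members.get(sp) for sp in species)
        }


def parse_orthogroups(source: Union[str, Path, IO[str], Iterable[str]]) -> OrthogroupTable:
    """Parse an orthogroup TSV: first column orthogroup id, one column per
    species holding comma-separated gene ids (empty cell = no members).

    A gene id listed under two orthogroups keeps its first assignment (warned).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_orthogroups(fh)
    lines = iter(source)
    try:
        header = next(lines).rstrip("\n").split("\t")
    except StopIteration:
        raise ValueError("empty orthogroup table") from None
    species = tuple(h.strip() for h in header[1:])
    if not species:
        raise ValueError("orthogroup table header names no species columns")
    groups: dict[str, dict[str, list[str]]] = {}
    seen: dict[str, dict[str, str]] = {sp: {} for sp in species}
    for lineno, line in enumerate(lines, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(species) + 1:
            raise ValueError(
                f"ragged orthogroup row at line {lineno}: "
                f"expected {len(species) + 1} columns, got {len(cells)}"
            )
        og_id = cells[0].strip()
        if og_id in groups:
            raise ValueError(f"duplicate orthogroup id {og_id!r} at line {lineno}")
        members: dict[str, list[str]] = {}
        for sp, cell in zip(species, cells[1:]):
            ids = [g.strip() for g in cell.split(",") if g.strip()]
            kept = []
            for gid in ids:
                prior = seen[sp].get(gid)
                if prior is not None:
                    log.warning(
                        "%s gene %s already in %s; keeping first assignment", sp, gid, prior
                    )
                    continue
                seen[sp][gid] = og_id
                kept.append(gid)
            members[sp] = kept
        groups[og_id] = members
    return OrthogroupTable(groups=groups, species=species)


def map_set_to_orthogroups(
    id_set: Iterable[str], species: str, table: OrthogroupTable
) -> tuple[set[str], set[str]]:
    """Convert gene ids to the distinct orthogroups containing them.

    Returns ``(orthogroup set, unmapped ids)``.
    """
    mapping = table.gene_to_group(species)
    ids = set(id_set)
    mapped = {mapping[g] for g in ids if g in mapping}
    unmapped = {g for g in ids if g not in mapping}
    return mapped, unmapped


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two orthogroup sets against the hypergeometric null."""

    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    p_value: float
    unmapped_a: int = 0
    unmapped_b: int = 0

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.universe_size


def overlap_enrichment(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Exact hypergeometric upper-tail test of overlap between two sets.

    Under the null, ``set_a`` is a uniform draw of its size from the universe;
    p = P[overlap >= observed] with ``set_b`` fixed.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not u:
        raise ValueError("universe must be non-empty")
    stray = sorted((a | b) - u)
    if stray:
        raise ValueError(f"ids outside the universe: {stray[:10]}")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(u), len(b), len(a)))
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_overlap=k, universe_size=len(u), p_value=min(1.0, p)
    )


def venn_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exact multi-set region counts (up to 5 sets), one row per membership
    pattern, for Venn/upset-style reporting."""
    names = list(sets)
    if not 1 <= len(names) <= 5:
        raise ValueError("venn_counts supports 1-5 sets")
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            rows.append(
                dict(
                    members="&".join(combo),
                    degree=r,
                    exclusive=len(inside - outside),
                    total=len(inside),
                )
            )
    return pd.DataFrame(rows)
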