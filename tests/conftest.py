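"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: hypergeometric
tails are summed with big-integer binomials, and repeat configurations are
re-derived by a quadratic brute force over explicit string comparisons.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hypergeom_upper_tail(k: int, n_pool: int, k_pool: int, n_draw: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(n_pool, k_pool, n_draw), exact
    big-integer arithmetic."""
    lo = max(k, 0, n_draw - (n_pool - k_pool))
    hi = min(k_pool, n_draw)
    num = sum(math.comb(k_pool, i) * math.comb(n_pool - k_pool, n_draw - i)
              for i in range(lo, hi + 1))
    return num / math.comb(n_pool, n_draw)


def brute_force_occurrences(seq: str) -> list[tuple[int, str, str]]:
    """All (offset, strand, core-first hexamer) footprints, by direct
    string comparison at every position."""
    hits = []
    for i in range(len(seq) - 5):
        footprint = seq[i : i + 6]
        if any(b not in _COMP for b in footprint):
            continue
        if footprint.startswith("TGTC"):
            hits.append((i, "+", footprint))
        if rc(footprint).startswith("TGTC"):
            hits.append((i, "-", rc(footprint)))
    return hits


def brute_force_configs(seq: str, min_spacer: int = 0, max_spacer: int = 25) -> set[tuple[str, int]]:
    """All (orientation, spacer) pairs by quadratic all-pairs enumeration."""
    occ = brute_force_occurrences(seq)
    configs = set()
    for i1, s1, _ in occ:
        for i2, s2, _ in occ:
            spacer = i2 - i1 - 6
            if spacer < min_spacer or spacer > max_spacer:
                continue
            if s1 == s2:
                orientation = "DR"
            elif s1 == "+":
                orientation = "IR"
            else:
                orientation = "ER"
            configs.add((orientation, spacer))
    return configs


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def tiny_genome():
    """A deterministic 12 kb single-chromosome genome."""
    rng = np.random.default_rng(20240901)
    return {"chr1": random_dna(rng, 12000)}


@pytest.fixture
def tiny_gff(tmp_path):
    """Two genes (one per strand) with mRNA and CDS children."""
    text = "\n".join(
        [
            "##gff-version 3",
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA",
            "chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=geneA.1;Parent=geneA",
            "chr1\tsrc\tCDS\t1201\t1800\t.\t+\t0\tID=cdsA;Parent=geneA.1",
            "chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=geneB",
            "chr1\tsrc\tmRNA\t5001\t6000\t.\t-\t.\tID=geneB.1;Parent=geneB",
            "chr1\tsrc\tCDS\t5101\t5900\t.\t-\t0\tID=cdsB;Parent=geneB.1",
        ]
    )
    path = tmp_path / "tiny.gff3"
    path.write_text(text + "\n")
    return path
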