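#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Emits, under results/fixtures/: foreground/background promoter FASTA with a
planted (DR,7) TGTCGG repeat, per-generation DE tables, an orthogroup table
with planted joint DEG membership, vein feature-point counts, and a pair of
nuclei images with a planted 2.0 intensity ratio — each with its truth table.
"""

from pathlib import Path

import numpy as np
import tifffile

from auxphase import (
    DESimConfig,
    NucleiSimConfig,
    OrthoSimConfig,
    PromoterSimConfig,
    simulate_de_tables,
    simulate_nuclei_image,
    simulate_orthogroups,
    simulate_promoters,
    simulate_vein_counts,
)

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sim = simulate_promoters(PromoterSimConfig(planted_config=("DR", 7), seed=SEED))
    with open(OUT / "promoters.fa", "w") as fh:
        for gid, seq in sim.sequences.items():
            fh.write(f">{gid}\n{seq}\n")
    (OUT / "foreground.txt").write_text("\n".join(sim.foreground) + "\n")
    sim.truth.to_csv(OUT / "promoters_truth.tsv", sep="\t", index=False)
    planted = (sim.truth["feature"] != "").sum()
    print(f"promoters: {len(sim.sequences)} sequences, {planted} planted repeats")

    tables, truth = simulate_de_tables(DESimConfig(seed=SEED))
    for generation, df in tables.items():
        df.to_csv(OUT / f"de_{generation}.tsv", sep="\t", index=False)
    truth.to_csv(OUT / "de_truth.tsv", sep="\t", index=False)
    print(f"DE tables: {', '.join(tables)} ({len(truth)} genes each)")

    ortho = simulate_orthogroups(OrthoSimConfig(deg_overlap_rate=0.5, seed=SEED))
    (OUT / "orthogroups.tsv").write_text(ortho.tsv_text)
    for sp, ids in ortho.deg_lists.items():
        (OUT / f"degs_{sp}.txt").write_text("\n".join(ids) + "\n")
    ortho.truth.to_csv(OUT / "ortho_truth.tsv", sep="\t", index=False)
    print(f"orthogroups: {len(ortho.truth)} groups, planted overlap rate 0.5")

    veins, vtruth = simulate_vein_counts(
        {"mock": (10, 5, 2, 3), "npa": (4, 8, 5, 2)}, n_leaves=20, seed=SEED
    )
    veins.to_csv(OUT / "veins.tsv", sep="\t", index=False)
    vtruth.to_csv(OUT / "veins_truth.tsv", sep="\t", index=False)
    print(f"veins: {len(veins)} leaves in {veins['group'].nunique()} groups")

    img_a, img_b, ntruth = simulate_nuclei_image(NucleiSimConfig(seed=SEED))
    tifffile.imwrite(OUT / "nuclei_1n.tif", img_a.astype(np.float32))
    tifffile.imwrite(OUT / "nuclei_2n.tif", img_b.astype(np.float32))
    ntruth.to_csv(OUT / "nuclei_truth.tsv", sep="\t", index=False)
    print(f"nuclei: image pair, planted intensity ratio {ntruth.attrs['group_ratio']}")


if __name__ == "__main__":
    main()
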