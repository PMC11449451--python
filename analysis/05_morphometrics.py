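#!/usr/bin/env python
"""Vein-network indices and nuclear-intensity ploidy quantification.

Computes cardinality/connectivity/continuity per simulated leaf, compares
treatment vs control with the F-then-t two-stage rule, then segments the
simulated nuclei image pair and estimates the group intensity ratio.
Expected outcome: the treated group shows fewer, less connected veins, and
the recovered nuclear ratio is close to the planted 2.0 (a 2N:1N doubling).
"""

from pathlib import Path

import pandas as pd
import tifffile

from auxphase import (
    VeinPointCounts,
    compare_index_groups,
    nuclear_intensity_summary,
    segment_nuclei,
    vein_indices,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fixtures = BASE / "fixtures"
    out = BASE / "morphometrics"
    out.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(fixtures / "veins.tsv", sep="\t")
    indices = pd.DataFrame(
        [
            vars(
                vein_indices(
                    VeinPointCounts(r.leaf_id, int(r.touch), int(r.end), int(r.brk), int(r.exit))
                )
            )
            for r in counts.itertuples()
        ]
    )
    indices["group"] = counts["group"].to_numpy()
    ctrl = indices[indices["group"] == "mock"]
    for key in ("cardinality_abs", "connectivity", "continuity"):
        mean = ctrl[key].mean()
        indices["rel_" + key.removesuffix("_abs")] = indices[key] / mean
    indices.to_csv(out / "vein_indices.tsv", sep="\t", index=False)
    rows = []
    for key in ("cardinality_abs", "connectivity", "continuity"):
        res = compare_index_groups(
            ctrl[key], indices.loc[indices["group"] == "npa", key]
        )
        rows.append(dict(index=key, mean_mock=res.mean_a, mean_npa=res.mean_b,
                         flavor=res.test_flavor, f_p=res.variance_test_p,
                         t_p=res.mean_test_p))
        print(
            f"{key}: mock {res.mean_a:.3f} vs NPA {res.mean_b:.3f} "
            f"({res.test_flavor} t p = {res.mean_test_p:.3g})"
        )
    pd.DataFrame(rows).to_csv(out / "vein_comparison.tsv", sep="\t", index=False)

    rois_1n = segment_nuclei(tifffile.imread(fixtures / "nuclei_1n.tif"))
    rois_2n = segment_nuclei(tifffile.imread(fixtures / "nuclei_2n.tif"))
    summary = nuclear_intensity_summary(rois_1n, rois_2n)
    pd.DataFrame(
        [dict(group=g, label=r.label, area=r.area, mean_intensity=r.mean_intensity)
         for g, rois in (("1n", rois_1n), ("2n", rois_2n)) for r in rois]
    ).to_csv(out / "nuclei_rois.tsv", sep="\t", index=False)
    print(
        f"nuclei: {summary.n_a} vs {summary.n_b} ROIs, median intensity ratio "
        f"{summary.ratio:.3f} (rank-sum p = {summary.rank_test_p:.3g})"
    )


if __name__ == "__main__":
    main()
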