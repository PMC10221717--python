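#!/usr/bin/env python
"""Infectious-titer quantification by single-cell droplet PCR.

Simulates whole infected cells encapsulated in droplets with a
cell-marker (β-actin) channel and a viral channel, then compares the two
titer estimators: the double-positive count (overestimates under
free-RNA contamination) and the linkage statistic (robust to free viral
RNA). Also traces the linkage-MOI correlation. Tables land in
results/single_cell/.
"""

from pathlib import Path

from dropquant import run_scenario
from dropquant.presets import (
    REFERENCE_INFECTIOUS_TITER,
    moi_sweep_spec,
    single_cell_titer_spec,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "single_cell"
SEEDS = tuple(range(1, 21))


def main() -> None:
    truth = REFERENCE_INFECTIOUS_TITER
    print(f"reference infectious titer: {truth:.3e} iu/mL")

    print("== Clean assay (no free RNA, MOI ~0.087) ==")
    report = run_scenario(
        single_cell_titer_spec(SEEDS, with_free_rna=False), out_dir=OUT / "clean"
    )
    for col in ("eq1_titer", "eq2_titer"):
        vals = report.results[col]
        print(f"  {col}: {vals.mean():.3e} +/- {vals.sem():.2e} iu/mL "
              f"({vals.mean() / truth:.1%} of reference)")

    print("== Contaminated assay (free beta-actin and viral RNA) ==")
    report = run_scenario(
        single_cell_titer_spec(SEEDS, with_free_rna=True), out_dir=OUT / "contaminated"
    )
    eq1, eq2 = report.results["eq1_titer"], report.results["eq2_titer"]
    print(f"  double-positive estimator: {eq1.mean():.3e} +/- {eq1.sem():.2e} iu/mL "
          f"({eq1.mean() / truth:.1f}x reference)")
    print(f"  linkage estimator:         {eq2.mean():.3e} +/- {eq2.sem():.2e} iu/mL "
          f"({eq2.mean() / truth:.1%} of reference)")
    print("  -> free viral RNA creates double positives without infection; the\n"
          "     linkage statistic subtracts the random co-encapsulation excess")

    print("== Linkage vs MOI ==")
    report = run_scenario(moi_sweep_spec(seeds=(1, 2, 3)), out_dir=OUT / "moi_sweep")
    table = report.results.groupby("moi")["linkage_copies_per_ul"].agg(["mean", "sem"])
    print(table.to_string())


if __name__ == "__main__":
    main()
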