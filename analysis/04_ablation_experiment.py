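#!/usr/bin/env python
"""Simulated neuronal loss: why CNR is extracted within a fixed atlas volume.

Half the cohort loses the caudal half of the nucleus. Averaging contrast
over each subject's own suprathreshold voxels hides the loss (the
segmentation simply shrinks around the surviving bright core), whereas
averaging within the fixed atlas template registers it — the volumetric-bias
control motivating atlas-based extraction. Writes results/ablation.tsv.
"""

from pathlib import Path

import pandas as pd

from coeruleus.phantom import PhantomConfig
from coeruleus.pipeline import ablation_comparison, run_recovery_experiment

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    config = PhantomConfig(n_subjects=20, seed=1, ablate_caudal_fraction=0.5)
    report = run_recovery_experiment(config)
    cohort = report["_tables"]["cohort"]
    comp = ablation_comparison(cohort)

    summary = cohort.groupby("ablated")[["atlas5_cnr_collapsed", "seg_cnr", "segmented_mm3"]].mean()
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "ablation.tsv", sep="\t")
    print(summary.round(3).to_string())
    print(f"\natlas-based CNR drop (intact - ablated):        {comp['atlas5_cnr_drop']:.3f}")
    print(f"segmentation-restricted CNR drop:               {comp['seg_cnr_drop']:.3f}")
    ratio = comp["atlas5_cnr_drop"] / max(abs(comp["seg_cnr_drop"]), 1e-9)
    print(f"the fixed-volume extraction is {ratio:.1f}x more sensitive to the loss")


if __name__ == "__main__":
    main()
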