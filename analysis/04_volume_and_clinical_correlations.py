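#!/usr/bin/env python
"""Correlate per-class FN/FA with brain volumes and clinical measures.

Within each disease group, correlates the six stratified outcomes with the
14 global and 16 deep grey-matter volume features and with lesion volume,
EDSS and disease duration (Pearson, or Spearman when a normality pre-check
fails; BH-FDR per table). The expected pattern: short-range FN negative,
long-range FN positive against volumes.
"""

from pathlib import Path

from tractstrata.pipeline import (
    RunConfig,
    compute_summaries,
    correlate_clinical,
    correlate_volumes,
    load_cohort,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(input_dir=str(ROOT / "cohort"), seed=20220)
    cohort = load_cohort(cfg)
    _, summaries = compute_summaries(cohort)

    vol = correlate_volumes(summaries, cohort.volumes)
    vol.to_csv(ROOT / "volume_correlations.csv", index=False)
    fn_sig = vol.query("metric == 'fn' and p_fdr < 0.05")
    print(f"{len(fn_sig)}/{len(vol)} volume correlations significant at FDR 0.05")
    for disease in ("RRMS", "NMOSD"):
        for cls in ("fn_short", "fn_long"):
            sub = fn_sig.query("disease == @disease and cls == @cls")
            if len(sub):
                print(f"  {disease} {cls}: {len(sub)} features, "
                      f"mean r = {sub['r'].mean():+.3f}")

    clin = correlate_clinical(summaries)
    clin.to_csv(ROOT / "clinical_correlations.csv", index=False)
    sig = clin[clin["p_fdr"] < 0.05]
    print(f"\n{len(sig)}/{len(clin)} clinical correlations significant at FDR 0.05")


if __name__ == "__main__":
    main()
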