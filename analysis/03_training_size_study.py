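"""Fit the full model zoo and study accuracy vs training-set size.

For every surrogate combination (7 two-signal models, 3 three-signal
models, plus the no-model baseline) this fits the linear correspondence
model on evenly spaced training subsets of n = 20..6 building-set frames
in 4-fold cross-validation, evaluates the deformation field error on the
held-out test frames, and writes the long-format results, fold-averaged
summaries and training-size curves.
"""

import pathlib
import sys

import numpy as np

from cinemotion.plots import training_size_curves
from cinemotion.study import StudyConfig, qualitative_metrics, run_study

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "training_size"


def main(seed: int = 1) -> None:
    out = run_study(StudyConfig(), seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    out["results"].to_csv(OUT / "results.csv", index=False)
    out["summary"].to_csv(OUT / "summary.csv", index=False)
    training_size_curves(out["summary"], OUT / "mean_dfe_curves.png")
    training_size_curves(out["summary"], OUT / "p95_dfe_curves.png", stat="p95_dfe_mm")

    m = qualitative_metrics(out["summary"])
    print(f"no-model baseline mean DFE: {m['baseline_mean_dfe_mm']:.2f} mm (evaluation mask)")
    print("fold-averaged mean DFE at n = 10 training images:")
    for model, dfe in sorted(m["model_mean_dfe_mm"].items(), key=lambda kv: kv[1]):
        print(f"  {model:25s} {dfe:.2f} mm   ({dfe / m['baseline_mean_dfe_mm']:.0%} of baseline)")
    rho = np.mean(list(m["spearman_by_model"].values()))
    print(f"mean Spearman rho(n, DFE) over models: {rho:+.2f} (negative = more data helps)")
    print(f"3-signal / 2-signal mean DFE at n = 6: {m['threesig_over_twosig_at_n6']:.2f}")
    print(f"wrote results and curves under {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
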