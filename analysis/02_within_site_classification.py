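#!/usr/bin/env python
"""Within-dataset classification: does combining directions add information?

Runs LOOCV on the reference cohort for each feature set (increased,
decreased, both), searches the p-threshold grid, and attaches
permutation (B = 1000) and sign-test significance to the combined
model.  The question of interest: does the accuracy of "both" exceed
each single-direction mode, i.e. do increased edges carry information
beyond the decreased ones?

Writes results/within_site.json and prints the accuracy table.
"""

import importlib.util
import json
import sys
from pathlib import Path

from cpmsvm import loocv, kfold_cv, permutation_test, sign_test, threshold_search

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("sim_study", HERE / "01_simulate_study.py")
sim_study = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim_study)

RESULTS = HERE.parent / "results"


def main() -> None:
    _, cohort, _, seeds = sim_study.study_components()
    doc = {"seed": sim_study.SEED, "n": cohort.n_subjects, "modes": {}}
    print(f"LOOCV on n={cohort.n_subjects} (threshold p < 0.05):")
    for mode in ("increased", "decreased", "both"):
        out = loocv(cohort, mode, 0.05)
        doc["modes"][mode] = {"loocv_accuracy": out.accuracy,
                              "confusion": out.confusion.tolist()}
        print(f"  {mode:>9s}: accuracy = {out.accuracy:.3f}")
    best, table = threshold_search(cohort, "both")
    doc["threshold_search"] = {str(t): o.accuracy for t, o in table.items()}
    doc["best_threshold"] = best
    print(f"threshold search (both): best p < {best}")
    out = loocv(cohort, "both", best)
    perm = permutation_test(cohort, "both", best, B=1000, seed=seeds[3])
    sp = sign_test(out.predictions, out.labels)
    kf = kfold_cv(cohort, "both", best, k=10, seed=seeds[3])
    doc["both_significance"] = {
        "permutation_p": perm.p_value, "sign_test_p": sp,
        "kfold10_accuracy": kf.accuracy,
    }
    print(f"both: permutation p = {perm.p_value:.4g}, sign test p = {sp:.3g}, "
          f"10-fold accuracy = {kf.accuracy:.3f}")
    gain = doc["modes"]["both"]["loocv_accuracy"] - max(
        doc["modes"]["increased"]["loocv_accuracy"],
        doc["modes"]["decreased"]["loocv_accuracy"],
    )
    print(f"finding: combining directions changes accuracy by {gain:+.3f} "
          "over the best single direction")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "within_site.json").write_text(json.dumps(doc, indent=2) + "\n")
    print(f"wrote {RESULTS / 'within_site.json'}")


if __name__ == "__main__":
    main()
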