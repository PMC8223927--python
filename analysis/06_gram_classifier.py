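#!/usr/bin/env python
"""Gram-group prediction from sequence features with a random forest.

Fits both models — the four physicochemical descriptors alone, and the
extended set adding length, hit count and the signal-peptide flag — on a
stratified 75/25 split, reports test-set ROC/threshold metrics and Gini
importances.
"""

from pathlib import Path

import pandas as pd

from lysinscape import classify

OUT = Path("results/analysis")
SEED = 7


def main() -> None:
    feats = pd.read_csv(OUT / "features.tsv", sep="\t")
    for name in ("physchem4", "extended7"):
        report = classify.fit_evaluate(
            feats, classify.ClassifierConfig(features=name, seed=SEED)
        )
        report.roc.to_csv(OUT / f"roc_{name}.tsv", sep="\t", index=False)
        report.importances.rename("gini_decrease").to_csv(
            OUT / f"importances_{name}.tsv", sep="\t"
        )
        print(f"{name}: AUC={report.auc:.3f} accuracy={report.accuracy:.3f} "
              f"sens={report.sensitivity:.3f} spec={report.specificity:.3f} "
              f"threshold={report.best_threshold:.3f} "
              f"cv_acc={report.cv_scores.mean():.3f}")
        print("  importance ranking:", " > ".join(classify.rank_importance(report)))


if __name__ == "__main__":
    main()
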