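"""Out-of-bag random-forest classification between each pair of groups.

Fits the 2/3-bootstrap OOB forest (500 trees, m_try 5) on the 25-feature
table for the three pairwise contrasts and writes one JSON report per
contrast plus a VIMP table. The expected pattern mirrors the clinical
one: both Lewy-body-like vs Alzheimer-like contrasts classify well, the
two Lewy-body-like groups much less so.
"""

import sys
from pathlib import Path

import pandas as pd

from qeeg.classify import random_forest_oob
from qeeg.features import frame_to_features

ROOT = Path(__file__).resolve().parents[1]
SEED = 7
PAIRS = [("dlb", "ad"), ("mixed", "ad"), ("mixed", "dlb")]


def main() -> None:
    path = ROOT / "results" / "features.csv"
    if not path.exists():
        print("run analysis/02_extract_features.py first", file=sys.stderr)
        return 1
    df = pd.read_csv(path)
    results = ROOT / "results"
    vimp_rows = {}
    for k, (pos, neg) in enumerate(PAIRS):
        feats = frame_to_features(df[df.group.isin((pos, neg))])
        rep = random_forest_oob(feats, n_tree=500, m_try=5, seed=SEED + k,
                                positive_label=pos)
        rep.to_json(results / f"classifier_{pos}_vs_{neg}.json")
        vimp_rows[f"{pos} vs {neg}"] = rep.vimp
        top = ", ".join(f"{name} ({v:.3f})" for name, v in rep.top_vimp(3))
        print(f"{pos} vs {neg}: accuracy {rep.accuracy:.2f} "
              f"(sensitivity {rep.sensitivity:.2f}, specificity {rep.specificity:.2f})")
        print(f"  top VIMP: {top}")
    pd.DataFrame(vimp_rows).rename_axis("feature").to_csv(results / "vimp.csv")


if __name__ == "__main__":
    sys.exit(main())
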