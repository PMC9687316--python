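#!/usr/bin/env python
"""Summarize the docked scores of the BBM fragment-partner complexes.

Averages the five reported engine scores per BBM fragment (the scores are
inputs; only the summary is computed here).

Finding: fragment 1 averages -647.1, fragment 2 -612.7; the strongest
single score is AGLI5-frag1 against BBM fragment 2 (-795.3).
"""

from importlib import resources
from pathlib import Path

import pandas as pd

from boomdock.cluster import summarize_scores

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    with resources.files("boomdock.data").joinpath("hex_scores.tsv").open() as fh:
        scores = pd.read_csv(fh, sep="\t")
    summary = (scores.groupby("fragment")["score"]
               .apply(lambda s: round(summarize_scores(list(s)), 1))
               .rename("average_score").reset_index())
    OUT.mkdir(exist_ok=True)
    summary.to_csv(OUT / "docked_score_summary.tsv", sep="\t", index=False)
    print(scores.to_string(index=False))
    print()
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
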