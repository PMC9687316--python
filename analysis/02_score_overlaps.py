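#!/usr/bin/env python
"""Score each peptide-BBM complex by overlap with the DNA-binding sites.

The BBM residues reported at each peptide-complex interface are counted
against the fragment's DNA-binding residue range (210-276 for fragment 1,
312-370 for fragment 2).

Finding: P1 (dock16) overlaps the fragment-1 DNA-binding site at 13
residues, the maximum; P2 (dock10), P3 and P7 follow at 12.
"""

from pathlib import Path

import pandas as pd

from boomdock.mimetics import score_bundled_peptides

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for s in score_bundled_peptides():
        rows.append({
            "peptide": s.peptide_id, "pose": s.pose_id,
            "site": f"{s.site.start}-{s.site.end}",
            "overlap_count": s.count,
            "overlapping_residues": ",".join(map(str, sorted(s.overlapping))),
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "overlap_scores.tsv", sep="\t", index=False)
    print(table[["peptide", "pose", "site", "overlap_count"]].to_string(index=False))
    best = table.loc[table.overlap_count.idxmax()]
    print(f"\nbest overlap: {best.peptide} ({best.pose}) with "
          f"{best.overlap_count} residues inside {best.site}")


if __name__ == "__main__":
    main()
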