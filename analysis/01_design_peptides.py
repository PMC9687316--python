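#!/usr/bin/env python
"""Design interface-derived peptide mimetics from the partner-protein
residue lists of the two BBM-fragment complexes.

Parses the bundled interfacial residue tables, extracts maximal stretches
with isolated single-residue gaps, bridges each gap with glycine, keeps
candidates of >= 8 residues and writes the candidate table and FASTA.

Finding: seven candidates qualify (P1-P7), the longest a 12-residue LEC1
stretch (131-142) and the shortest four 8-residue stretches, including the
triple-bridged LEC2 peptide LGRGVGPK.
"""

from pathlib import Path

import pandas as pd

from boomdock.mimetics import (bundled_residue_lists, extract_stretches,
                               peptides_fasta, select_peptides)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    lists = bundled_residue_lists()
    for lst in lists:
        for repair in lst.repairs:
            print(f"note: {lst.source} ({lst.fragment}): {repair}")

    stretches = pd.DataFrame(
        [{"source": lst.source, "fragment": lst.fragment, "start": s.start,
          "end": s.end, "length": s.length, "n_gaps": len(s.gaps)}
         for lst in lists for s in extract_stretches(lst)])
    peptides = select_peptides(lists, min_len=8)

    OUT.mkdir(exist_ok=True)
    stretches.to_csv(OUT / "interface_stretches.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": p.id, "sequence": p.sequence, "length": p.length,
          "source": p.source, "fragment": p.fragment, "start": p.start,
          "end": p.end, "gaps": ",".join(map(str, p.gaps)) or "-"}
         for p in peptides]).to_csv(OUT / "peptides.tsv", sep="\t", index=False)
    (OUT / "peptides.fasta").write_text(peptides_fasta(peptides))

    print(f"\n{len(stretches)} stretches across {len(lists)} residue lists; "
          f"{len(peptides)} candidates of length >= 8:")
    for p in peptides:
        print(f"  {p.id}: {p.sequence:14s} ({p.source}, {p.fragment}, "
              f"{p.start}-{p.end}, {len(p.gaps)} bridged gap(s))")


if __name__ == "__main__":
    main()
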