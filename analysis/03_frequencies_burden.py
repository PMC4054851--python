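#!/usr/bin/env python
"""Frequency and burden analysis, on both the packaged reference matrix and
the called simulated cohort of step 02.

Reproduces the printed-table chain (19 high-frequency sites covering 22
genes, 16 on 3p / 3 on 3q; top frequency 57%; five samples with MD in more
than 9 of the 19 sites) and reports the same statistics for the simulated
cohort. Writes results/analysis/frequency_table.tsv and burden.tsv.
"""

from pathlib import Path

import pandas as pd

from notimeth import datasets, io
from notimeth.frequency import (
    arm_counts,
    count_distinct_genes,
    frequency_table,
    sample_burden,
    select_high_frequency,
)

OUT = Path("results/analysis")


def report(name, matrix, sites):
    table = frequency_table(matrix, sites)
    selected = select_high_frequency(table, min_count=4)
    annotated = [f.site for f in selected if f.site is not None]
    arms = arm_counts(annotated)
    burden = sample_burden(matrix, [f.clone_id for f in selected], 9)
    flagged = [b.sample_id for b in burden if b.flagged]
    print(f"[{name}]")
    print(f"  high-frequency sites (>=4/23 MD): {len(selected)}")
    if annotated and len(annotated) == len(selected):
        print(f"  distinct genes: {count_distinct_genes(selected)}")
    print(f"  arm split of annotated selected sites (3p, 3q): {arms}")
    top = selected[0]
    print(f"  top site {top.clone_id}: {top.percent}% ({top.md_count}/{top.n_samples})")
    print(f"  samples with MD in >9 selected sites: {len(flagged)} {flagged}")
    return table, burden


def main() -> None:
    sites = datasets.high_frequency_sites()
    ref = datasets.reference_call_matrix()
    table, burden = report("reference matrix", ref, sites)
    rows = [
        {"clone_id": f.clone_id, "md_count": f.md_count,
         "n_samples": f.n_samples, "percent": f.percent}
        for f in table
    ]
    pd.DataFrame(rows).to_csv(OUT / "frequency_table.tsv", sep="\t", index=False)
    pd.DataFrame([b.__dict__ for b in burden]).to_csv(OUT / "burden.tsv", sep="\t", index=False)

    called_path = OUT / "call_matrix.tsv"
    if called_path.exists():
        called = io.read_call_matrix(called_path)
        report("simulated cohort (called)", called, sites)
    else:
        print("(run 01 and 02 first to add the simulated-cohort comparison)")


if __name__ == "__main__":
    main()
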