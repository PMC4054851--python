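#!/usr/bin/env python
"""Regenerate the packaged synthetic cohort call matrix.

The study's per-sample hybridization table is not published, so the
packaged fixture ``src/notimeth/data/cohort_calls_synthetic.tsv`` is a
deterministic construction satisfying every published marginal constraint
at once:

- per-site MD counts of the 19 high-frequency sites
  (13,10,10,8,8,7,6,6,5x5,4x6 out of 23);
- exactly five samples (#8, 11, 16, 17, 22) with MD in more than 9 of 19;
- 18 of 23 samples positive under the 2-of-6 marker rule (78% sensitivity);
- MD at the bisulfite-validated sample/gene cells.

Cell-level detail beyond the constraints is arbitrary (greedy fill).
Running this script rewrites the fixture byte-identically.
"""

import sys
from pathlib import Path

import numpy as np

CLONES = [
    "NL1-CJ4R (C)", "NL6-FJ5R (C)", "NL3-CA11RS", "NLJ-003RD", "NL3003R (U)",
    "NRLA404R (U)", "NR1-XM13C", "NL1-BA6R", "NR1-AN24RS", "NL3A006R (D)",
    "NL3A001R (D)", "NR1-NC7RS", "NR1-NJ9R (C)", "HSJ4-AB7R (C)", "NL4-DP2RS",
    "NL4-AP18R (C)", "NL4-BC8R (C)", "NL1A079R (D)", "NR1-PD1R",
]
ROW = [13, 10, 10, 8, 8, 7, 6, 6, 5, 5, 5, 5, 5, 4, 4, 4, 4, 4, 4]
COL = {1: 5, 2: 1, 3: 4, 4: 5, 5: 5, 6: 1, 7: 4, 8: 12, 9: 1, 10: 4,
       11: 11, 12: 1, 13: 4, 14: 1, 15: 4, 16: 10, 17: 13, 18: 4, 19: 4,
       20: 4, 21: 5, 22: 10, 23: 4}
FLAG = {8, 11, 16, 17, 22}            # burden-flagged samples, > 9 of 19
NEG = {2, 6, 9, 12, 14}               # panel-negative samples, one MD each
# bisulfite-validated (row, sample) cells that must carry MD
FORCED = [(0, 22), (1, 5), (1, 17), (2, 4), (2, 16), (3, 8), (3, 16), (3, 21),
          (5, 1), (5, 5)]
# per-column quota of MD cells within the six panel rows (sums to 56)
PQ = {8: 5, 11: 5, 16: 5, 17: 6, 22: 4,
      1: 3, 3: 3, 4: 2, 5: 3, 7: 3, 10: 2, 13: 2, 15: 2, 18: 2, 19: 2,
      20: 2, 21: 3, 23: 2}


def build() -> str:
    assert sum(ROW) == sum(COL.values()) == 117
    assert sum(PQ.values()) == sum(ROW[:6])
    m = np.zeros((19, 23), dtype=int)
    for r, s in FORCED:
        m[r, s - 1] = 1

    def fill(rows, quota):
        for r in rows:
            need = ROW[r] - m[r].sum()
            cap = {j: quota[j] - m[rows, j - 1].sum() for j in quota}
            order = sorted((j for j in cap if cap[j] > 0 and m[r, j - 1] == 0),
                           key=lambda j: (-cap[j], j))
            for j in order[:need]:
                m[r, j - 1] = 1
            assert m[r].sum() == ROW[r]

    fill(list(range(6)), PQ)
    fill(list(range(6, 19)), {j: COL[j] - PQ.get(j, 0) for j in COL})

    assert (m.sum(axis=1) == np.array(ROW)).all()
    assert (m.sum(axis=0) == np.array([COL[j] for j in range(1, 24)])).all()
    burden = m.sum(axis=0)
    assert {j + 1 for j in range(23) if burden[j] > 9} == FLAG
    positive = {j + 1 for j in range(23) if m[:6, j].sum() >= 2}
    assert len(positive) == 18 and not (positive & NEG)

    tokens = np.where(m == 1, "MD", "RET").astype(object)
    # two no-information cells and one amplification call for realism,
    # placed where they cannot move any of the constrained counts
    for r, s, t in [(8, 3, "NA"), (13, 19, "NA"), (16, 7, "AD")]:
        assert tokens[r, s - 1] == "RET"
        tokens[r, s - 1] = t
    lines = ["clone_id\t" + "\t".join(f"S{j:02d}" for j in range(1, 24))]
    lines += [c + "\t" + "\t".join(tokens[i]) for i, c in enumerate(CLONES)]
    return "\n".join(lines) + "\n"


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src/notimeth/data/cohort_calls_synthetic.tsv"
    text = build()
    if out.exists() and out.read_text() == text:
        print(f"{out} already up to date")
        sys.exit(0)
    out.write_text(text, encoding="utf-8")
    print(f"wrote {out}")
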