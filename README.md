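# notimeth

Analysis pipeline for **chromosome-3 NotI-microarray methylation/deletion
profiling of clear cell renal cell carcinoma (ccRCC)**, with the downstream
statistics that turn hybridization data into biomarker candidates:
per-site event frequencies, per-sample burden, a k-of-m methylation marker
panel, efficiency-corrected qPCR expression, and bisulfite-clone
concordance — all exercisable end to end on synthetic data that emulates
the study design (23 paired tumor/normal hybridizations on a 180-clone
array, six replicate spots per clone, E. coli negative controls).

## The science in brief

NotI cuts only the unmethylated recognition site `GCGGCCGC`, which sits
inside CpG islands. Hybridizing NotI-enriched tumor and normal DNA from
the same patient onto an array of NotI-flanking genomic clones therefore
reports promoter **methylation and/or deletion (MD)** as a drop in the
tumor channel, and amplification/demethylation (AD) as a gain. Per site
and pair, the pipeline computes

```
net  = max(foreground - background, 0)            per spot
value = median over >= 4 unflagged replicates     per clone and channel
M    = log2(net_tumor / net_normal), median-centred per array
call = MD if M <= -0.58, AD if M >= +0.58, else RET
```

Downstream, MD frequencies over the cohort select high-frequency sites
(≥ 4/23 events), localize them by chromosome arm, and flag high-burden
samples (MD in > 9 of the 19 selected sites). A six-marker panel
(*NKIRAS1/RPL15, LRRN1, LRRC3B, CTDSPL, GORASP1/TTC21A, VHL*) classifies a
sample as ccRCC when **at least 2 of the 6 markers are MD**; its ranking
quality is the Gini coefficient 2·AUC − 1 on the integer marker count.
mRNA levels are quantified by the efficiency-corrected paired ratio

```
R = 2^[log2(1+E_tar)·Ct_tar − log2(1+E_ref)·Ct_ref] (normal)
    ───────────────────────────────────────────────
    2^[log2(1+E_tar)·Ct_tar − log2(1+E_ref)·Ct_ref] (tumor)
```

(geometric mean over the reference genes GUSB and RPN1; changes are
significant at 2-fold), and bisulfite clone matrices settle whether an MD
call reflects methylation (NotI-site CpGs methylated in a majority of
clones) or likely deletion.

## Worked example

```python
from notimeth import datasets
from notimeth.frequency import (arm_counts, count_distinct_genes,
                                sample_burden, select_high_frequency)
from notimeth.panel import evaluate_panel
import pandas as pd

freqs = datasets.site_frequencies()          # the 19 printed sites
sel = select_high_frequency(freqs, min_count=4)
print(len(sel), count_distinct_genes(sel), arm_counts([f.site for f in sel]))
# 19 22 (16, 3)      19 sites, 22 genes, 16 on 3p vs 3 on 3q

m = datasets.reference_call_matrix()         # synthetic 19 x 23 cohort matrix
neg = pd.DataFrame("RET", index=m.index, columns=[f"N{i}" for i in range(23)])
metrics = evaluate_panel(m, neg, datasets.six_marker_panel())
print(metrics.tp, round(100 * metrics.sensitivity))
# 18 78             18 of 23 tumors recognized: 78% sensitivity

burden = sample_burden(m, [f.clone_id for f in sel], burden_threshold=9)
print([b.sample_id for b in burden if b.flagged])
# ['S08', 'S11', 'S16', 'S17', 'S22']       5 high-burden samples
```

The cohort matrix here is a *synthetic reconstruction*: the study's
per-sample table is not published, so the packaged matrix is built to
satisfy every published marginal (per-site counts, burden, panel
sensitivity, bisulfite-validated cells) — see `docs/methods.md`.

## Analysis scripts

The `analysis/` directory is a numbered narrative over the library; each
script prints what it found and writes tables under `results/analysis/`:

1. `01_simulate_cohort.py` — simulate the 23-pair, 180-clone cohort with
   planted site frequencies
2. `02_call_states.py` — call states, measure agreement with planted truth
3. `03_frequencies_burden.py` — frequency/arm/burden chain on the
   reference matrix and the simulated cohort
4. `04_marker_panel.py` — panel evaluation under two negative-cohort
   models plus exhaustive 6-of-19 subset search
5. `05_qpcr_expression.py` — simulated qPCR cohort, summaries, stage tests
6. `06_bisulfite.py` — clone-matrix verdicts vs array calls
7. `07_report.py` — one-command pipeline run with a reproducibility manifest

A `notimeth` CLI exposes the same steps (`simulate`, `call`, `frequencies`,
`burden`, `panel-eval`, `panel-search`, `qpcr`, `bisulfite`, `report`).

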