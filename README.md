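# sfrgsn

Edge-biomarker discovery from group-specific differential-correlation
networks, for multi-group classification of cancer stages or subtypes from
bulk RNA-seq.

## The problem

Single-gene markers often separate tumor from normal but blur the
*boundaries between stages*. This package implements a network alternative:
the marker is a **gene pair (edge)** whose co-expression is rewired in a
specific clinical group. Given an expression matrix, group labels (one group
designated normal/reference) and a protein–protein interaction (PPI) edge
list, the pipeline:

1. **CPM-filters** low-expression genes (CPM > 2 in ≥ half the samples) and
   moves to log2(CPM+1).
2. Builds a **sample-specific network** for every disease sample: for each
   PPI pair, the perturbation `ΔPCC = PCC_{n+1} − PCC_n` that the sample
   induces on the reference cohort's Pearson correlation, keeping edges
   significant under the scaled statistic `T = ΔPCC(n−1)/(1−PCC_n²)`
   referred to its normal-product null (p < 0.05).
3. Aggregates each group's samples into a **group-specific network**,
   `w(e) = Σᵢ ΔPCCᵢ(e) / N` with zero-fill for absent edges, restricted to
   the PPI.
4. **Pre-screens** the union of each group's top-50 edges with
   random-forest Gini-gain importance (top 50 kept).
5. Runs **recursive feature elimination** with cross-validated F1 recorded
   at feature counts 1..10, and stops via the **cost-benefit ratio**
   `CBR(k) = 100·PR/(INF·UFC)` — the F1 gain in percentage points per added
   feature — selecting the count just before CBR first drops below 0.5.

Evaluation is stratified 10-fold: every fold selects its own features on
training data only and scores its held-out samples; the final biomarker set
comes from fold-averaged group networks.

## Worked example

The CBR stopping rule replayed on the published lung-adenocarcinoma staging
curve (`python examples/04_cbr_on_published_curves.py`):

```
LUAD stages:
  k :       1        2        3        4        5        6        7        8        9       10
  F1:   48.74    86.25    91.26    92.50    93.31    96.15    96.85    96.91    97.49    97.88
  CBR:      -  37.5090   5.0047   1.2493   0.8039   2.8448   0.6980   0.0550   0.5868   0.3869
  optimal feature count: 7 (matches the reported count), F1 there 96.8517%
```

Reading it: adding the 2nd feature buys 37.5 F1 percentage points, the 8th
buys 0.055 — the first value below 0.5 — so the scan stops and 7 edges are
the selected biomarker panel.

End-to-end on synthetic data (`python examples/05_crossval_pipeline.py`,
three disease groups, one planted rewired+shifted edge each):

```
fold  k*  test-F1%  selected edges
   0   3    100.00  [('g04', 'g05'), ('g02', 'g46'), ('g02', 'g03')]
   1   4    100.00  [('g04', 'g05'), ('g00', 'g01'), ('g02', 'g03'), ('g02', 'g46')]
   2   3    100.00  [('g02', 'g03'), ('g04', 'g05'), ('g00', 'g01')]
   3   3     83.12  [('g00', 'g01'), ('g04', 'g05'), ('g02', 'g03')]
   4   2     94.41  [('g04', 'g05'), ('g02', 'g03')]

mean held-out macro-F1: 95.50% (inner RFECV estimate 95.59%)
final biomarkers (from fold-averaged group networks): [('g04', 'g05'), ('g00', 'g01')]
```

The held-out F1 says the selected edges generalize; the planted pairs
dominating the selections says the right edges were found.

## Examples

One short script per capability under `examples/`:

| script | shows |
|---|---|
| `01_simulate_dataset.py` | generating expression/labels/PPI with planted rewiring |
| `02_ssn_and_gsn.py` | per-sample ΔPCC edges and group-network weights |
| `03_screening_and_selection.py` | importance pre-screening, the F1/CBR table and the stop |
| `04_cbr_on_published_curves.py` | the CBR rule replayed on published staging/subtype curves |
| `05_crossval_pipeline.py` | the full leak-free cross-validated pipeline |

## Acceptance script

`scripts/acceptance.py` recomputes the published cost-benefit cells from
their printed F1 inputs by running `compute_cbr_series`, and writes one JSON
object mapping target ids to values:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical model, the normal-product null
of the ΔPCC statistic, parameter defaults, what the synthetic generator
does and does not emulate, and the power limits of single-sample
correlation perturbation at desk scale.
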