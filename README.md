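# autocmap

Association networks from tabular biomarker data via the **Auto
Contractive Map** (AutoCM) and minimum-spanning-tree *semantic
connectivity maps*.

## The problem

Immunological studies of multiple sclerosis (MS) measure panels of
flow-cytometry markers — percentages of cytokine- or transcription-factor-
positive cell subsets (CD4+IL25+, CD4+RORC/γτ+, CD14+IL6+, …) — across
clinical phenotypes: relapsing-remitting (RR), benign (BB), secondary
progressive (SP), primary progressive (PP) MS and healthy controls (HC).
Pairwise statistics miss the many-to-many, non-linear structure of such
panels. This package infers and visualizes that structure:

1. **Complement coding.** Each marker is min-max scaled to [0, 1] over the
   cohort, x' = (x − min)/(max − min), and paired with its complement
   1 − x'. The two poles, named `high <marker>` and `low <marker>`, can
   occupy different positions in a non-linear map. Eleven markers become
   22 variables; the phenotype label adds five binary indicators (27 total).
2. **AutoCM training.** An unsupervised three-layer network with weights
   bounded by a contraction constant C. For a record m_s ∈ [0, 1]^N:

       m_h[i] = m_s[i]·(1 − v[i]/C)                    (hidden)
       Net[i] = Σ_j w[i,j]·m_h[j]/C
       m_t[i] = m_h[i]·(1 − Net[i]/C)                  (output)
       Δv[i]  = (m_s[i] − m_h[i])·(1 − v[i]/C)
       Δw[i,j]= (m_h[i] − m_t[i])·(1 − w[i,j]/C)·m_h[j]

   Both deltas are non-negative, so v and w grow monotonically within
   [0, C]; training is deterministic and stops when the mean |Δw| per
   epoch falls below tolerance. The trained w reads directly as a matrix
   of many-to-many association strengths.
3. **Distances and the map.** d = C − w_sym turns strong associations into
   short distances; the minimum spanning tree keeps the N − 1 strongest
   links needed to connect all variables. Edges carry link strengths
   ls = w_sym/C ∈ [0, 1]; node degree in the tree is the hub score.

Because no patient-level dataset is publicly deposited for this design,
the package ships a **synthetic cohort generator** that emulates the
five-group study (30/26/33/14/42 subjects) with planted phenotype–marker
effects and latent-factor correlation blocks, so the whole pipeline is
testable against known ground truth.

## Worked example

```
$ autocmap run --design default --seed 7 --out demo
pipeline complete (converged, 5 epochs); 11 artifacts in demo
```

`demo/` now contains the simulated cohort (`cohort.csv`, 145 subjects),
the scaled 27-variable dataset (`scaled.csv` + `variables.json`
provenance), the trained model (`model.json`), the distance and
link-strength matrices, and the map as GraphML/DOT/TSV plus a hub table:

```
$ head -4 demo/hubs.tsv
node    polarity        hub_degree
low CD4+IL25+   low     18
low CD4+IL9+    low     4
low CD4+GATA+   low     3
```

The dominant hub is `low CD4+IL25+`: the generator lowers CD4+IL25+ in
SP, PP and HC (89 of 145 subjects), so low IL-25 co-occurs with most of
the cohort's other signals and organizes the tree — in the map the SP,
PP and HC phenotype nodes all attach to it, while RR sits on the
high-IL25 side. The tree has exactly 26 edges for 27 nodes; edge labels
in `demo/map.dot` show link strengths truncated to two decimals, full
precision is in `demo/edges.tsv`.

The same pipeline runs on real data (`autocmap run --input cohort.csv
--out DIR`) given a CSV with columns `subject_id`, `phenotype` and the
11 marker columns, and each stage is also available separately
(`autocmap simulate | preprocess | train | map`) or as library functions.

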