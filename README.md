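# silacprm

Quantitative kinome profiling by SILAC parallel-reaction monitoring (PRM),
as a tested, fully scripted pipeline. The intended users are targeted-
proteomics analysts who want the numerical core of a Skyline-style SILAC-PRM
workflow — transition-level peak integration, spectral-library dot-product
(dotp) gating, label-swap reconciliation and fold-change calling — as an
importable library with a synthetic-data generator for validation, plus the
downstream quartile logrank survival screen used to ask whether
differentially expressed kinases are prognostic.

## The method

A PRM kinome assay targets up to 4 tryptic peptides per kinase, each
monitored through its 4–6 most abundant y-ion transitions. With SILAC,
light and heavy forms of each peptide ([¹³C₆,¹⁵N₂]-Lys +8.014199 Da,
[¹³C₆]-Arg +6.020129 Da) co-elute, and the expression ratio between two
cell states is estimated per peptide as

&nbsp;&nbsp;&nbsp;&nbsp;*r* = Σⱼ area(heavy, transition *j*) / Σⱼ area(light, transition *j*),

with transition areas integrated over a shared peak window. Two gates
replace manual chromatogram review:

- **dotp** — cosine similarity between the observed transition-area vector
  and the library's reference relative intensities, required to be ≥ 0.7 in
  both channels;
- **co-elution** — all transition apexes of both channels within a
  retention-time tolerance (default 5 s).

Forward (heavy = metastatic) and reverse (heavy = primary) labeling
replicates are reconciled by orienting each measurement to
log₂(metastatic/primary) (negating reverse-labeled log-ratios), averaging
peptides within a replicate and replicates within a protein. Replicate
precision is summarized as the RSD of linear-scale replicate protein
ratios, and proteins with |mean log₂| ≥ log₂ 1.5 are called up/down.
Kinases quantified in every cell-line pair form the kinome fold-change
matrix with per-class (protein/lipid/nucleotide/carbohydrate/other) counts.

The survival screen stratifies patients into top and bottom quartiles of
each gene's expression and compares the groups with the standard two-group
logrank test (χ², 1 df), flagging genes at unadjusted p < 0.05 — the
convention of single-gene prognosis screens.

Because raw vendor data are not needed to validate any of this arithmetic,
the package ships a generator that simulates transition chromatograms with
known ground truth: co-eluting Gaussian light/heavy peaks on a 2 s cycle,
abundances spanning 4 orders of magnitude, log-normal noise, and optional
retention-shifted interference peaks that the gates must reject.

## Worked example

The `analysis/` scripts run the full study on synthetic data (seed 1):
a shared 80-kinase library, three cell-line pairs with their own true fold
changes, 2 forward + 2 reverse replicates for pair A and 1 + 1 for pairs B
and C, 5% interference:

```
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_differential_expression.py
python analysis/04_survival_screen.py
```

which prints, among other lines:

```
pairA_forward1: 184/194 peptides pass the gates
pairA: consistency 96.9%, fwd/rev R2 0.973, dynamic range 4.51 orders, truth recovery slope 0.996 (R2 0.997)
kinases quantified in all pairs: 80
up-regulated calls per pair: {'pairA': 20, 'pairB': 23, 'pairC': 20}
screened 80 kinases in 300 simulated patients
planted prognostic kinases recovered: 3/3 ['KIN0001', 'KIN0014', 'KIN0039']
```

Reading: 10 of 194 peptides fail the gates in a typical run (the simulated
interference plus an occasional noisy trace); 96.9% of peptides show the
same fold-change direction in forward and reverse labeling; the passing
peptides span 4.5 orders of signal; protein-level log₂ estimates track the
simulated truth with slope ≈ 1; and the three kinases given a planted
hazard effect (rate ratio 3 in the top expression quartile) are all
recovered by the logrank screen. Protein tables, QC JSON, the kinome
matrix, class counts and the screen land in `results/`.

The same workflow is available as a single command
(`silacprm run-demo --seed 1 --out demo/`), and the individual stages as
`silacprm simulate | quantify | diffexp | survival`.

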