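# glucostore

Blood glucose is cleared after a glucose load by two distinct hypoglycemic
effects: an **insulin-dependent** one (GLUT4-type uptake into muscle, rising
slowly as insulin accumulates) and an **insulin-independent** one — *glucose
effectiveness* — in which elevated glucose promotes its own disposal,
transiently, into a storage pool (liver/interstitial diffusion) that
saturates. `glucostore` implements a kinetic model that separates the two
effects over time during a mouse **hyperglycemic clamp**, fits the model to
per-mouse clamp records, and tracks how its parameters change with
diet-induced obesity. A synthetic-cohort generator stands in for the animal
experiments, so the whole pipeline is testable end to end.

## The model

State variables: blood glucose `G` (mg/dL), blood insulin `I` (ng/mL), a
transient glucose store `stG` with capacity `k7` (mg/dL-equivalent), and
cumulative glucose uptake `AG`:

```
dG/dt   = k1/(1 + I + k8·G) − k2·G·I − k5·G·(k7 − stG) + f(t)
dI/dt   = k3·G − k4·I
dstG/dt = k5·G·(k7 − stG) − k6·stG·I
dAG/dt  = k2·G·I − k1/(1 + I + k8·G) + k5·G·(k7 − stG)
```

where `f(t)` is the exogenous glucose infusion (mg/dL/min). The six fluxes
are endogenous glucose production (suppressed by insulin and glucose),
insulin-dependent uptake, insulin secretion, insulin clearance,
insulin-independent uptake into the store, and insulin-dependent consumption
of the store. Infused mass is conserved exactly: at all times
`∫f·V = ΔG·V + AG·V` with `V` the circulating blood volume (72 mL/kg).

Per-mouse fitting minimizes the summed squared residuals of three
mean-normalized streams — glucose at the dense clamp grid, insulin at the
sparse sampling grid, and cumulative uptake reconstructed from the recorded
doses — using a self-adaptive evolutionary-programming global search in
log10 space followed by bounded trust-region least squares. Group analysis
applies IQR outlier fences, pairwise Welch's *t* with Benjamini–Hochberg
adjustment, Williams' step-down trend test (Monte-Carlo null), and Spearman
correlation.

## Worked example

```bash
glucostore cohort --spec scaled_down --n-per-group 4 --seed 7 --out demo/data
glucostore fit --data demo/data --out demo/params.csv --seed 7 \
    --population 24 --generations 20
glucostore stats --params demo/params.csv \
    --group-order CD14wk,HFD18wk,HFD36wk --out-dir demo/stats --seed 7
```

The first command simulates 12 mice (chow-fed controls plus 18- and 36-week
high-fat-diet groups) through closed-loop clamps at fasting + 200 mg/dL and
writes the four-file CSV layout (glucose, insulin, doses, body weights).
The second fits every mouse, printing one line per mouse such as

```
m001 (CD14wk): rss=0.182
m002 (CD14wk): rss=0.1762
...
wrote parameter table to demo/params.csv
```

where `rss` is the final normalized residual sum of squares (values well
below 1 mean the three streams are reproduced to within measurement noise).
The third emits `summaries.csv` (per-group quartiles/means of each
parameter), `pairwise.csv` (Welch+BH, with significance stars), and
`trend.csv`, whose rows for e.g. `k5` look like

```
parameter,group,direction,tbar,p_mc,rejected
k5,HFD18wk,decreasing,-5.931,1.80e-04,True
k5,HFD36wk,decreasing,-9.104,3.00e-05,True
```

i.e. glucose effectiveness (`k5`) declines monotonically with age under
high-fat diet — the trend statistic `tbar` compares the isotonic
(amalgamated) group mean against the chow-fed control, and `p_mc` is its
seeded Monte-Carlo tail probability.

In Python the same machinery is available directly:

```python
from glucostore.cohort import REFERENCE_CD
from glucostore.protocols import InfusionProtocol, run_clamp, decompose_fluxes

traj = run_clamp(REFERENCE_CD, InfusionProtocol(mode="clamp", body_weight=27.0,
                                                initial_rate=0.15))
dec = decompose_fluxes(traj)          # 10-min flux integrals at 10..180 min
print(dec.to_frame())
```

which shows the signature time course: the insulin-independent integral
(flux 5) is over an order of magnitude larger in the first 10 minutes than
at the end, while the insulin-dependent integral (flux 2) rises
monotonically throughout.

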