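# tiqspr

Degree-based topological indices, QSPR regression and multi-criteria drug
ranking, built around a published study of 22 dry-eye-disease (DED) drugs.

Chemical graph theory models a molecule as a simple graph of its heavy atoms;
a *topological index* condenses that graph into one number. The eleven
indices here are all sums over bonds `uv` of a function of the endpoint
degrees `(d_u, d_v)`:

| id | index | per-edge term |
|----|-------|----------------|
| M1 / M2 | first / second Zagreb | `d_u + d_v` / `d_u d_v` |
| H  | harmonic | `2/(d_u + d_v)` |
| HM | hyper-Zagreb | `(d_u + d_v)^2` |
| F  | forgotten | `d_u^2 + d_v^2` |
| ABC | atom-bond connectivity | `sqrt((d_u + d_v - 2)/(d_u d_v))` |
| R  | Randić | `1/sqrt(d_u d_v)` |
| SC | sum-connectivity | `1/sqrt(d_u + d_v)` |
| GA | geometric–arithmetic | `2 sqrt(d_u d_v)/(d_u + d_v)` |
| SO | Sombor | `sqrt(d_u^2 + d_v^2)` |
| N  | Nirmala | `sqrt(d_u + d_v)` |

Because each term depends only on degrees, the *edge partition* — the count
`n_{a,b}` of bonds per degree pair — is a sufficient statistic, and the exact
identity `HM = F + 2·M2` holds. The package covers the full analysis chain:

* **molgraph** — edge-list parsing, degree computation, edge partitions, and
  *partition recovery*: reconstructing an integer edge partition from a row of
  printed index values (branch-and-bound; the integer indices M1, M2, F are
  matched exactly, the others select among candidates). This makes tabulated
  index rows auditable even when the underlying structure isn't published.
* **indices** — the eleven indices from partitions or graphs.
* **fixtures** — the study's tables packaged verbatim as CSV/JSON (22 drugs ×
  7 physicochemical properties with 5 missing cells; 22 × 11 indices; the 7
  regression model specs; the Diclofenac graph). Printed rows violating the
  `HM = F + 2·M2` identity are flagged by a validator, never edited.
* **qspr** — Pearson correlation screening with pairwise deletion,
  enter-method multiple linear regression `Y = c + Σ b_i I_i` (all regressors
  kept; listwise deletion on the response only), fit statistics
  (`r = √R²`, `SE = √(SSE/(n−k−1))`, `RMSE = √(SSE/n)`, F, p), prediction.
* **mcdm** — TOPSIS (closeness `C = D⁻/(D⁺+D⁻)` after weighted vector
  normalisation) and VIKOR (group utility S, regret R, compromise `Q`),
  with equal / ratio weight schemes and explicit missing-value policies.
* **synthetic** — seeded generators: bounded-degree connected random graphs,
  linear structure–property datasets with known truth, and decision matrices
  with planted dominant/dominated alternatives.

## Worked example

```python
from tiqspr import fixtures
from tiqspr.indices import compute_all
from tiqspr.molgraph import edge_partition

graph = fixtures.diclofenac_graph()          # 19 heavy atoms, 20 bonds
partition = edge_partition(graph)
print(partition.counts)
print(compute_all(partition).round(3))
```

prints the Diclofenac edge partition `{(1,3): 4, (2,2): 5, (2,3): 8,
(3,3): 3}` and

```
M1      94.000
M2     107.000
H        8.700
HM     452.000
F      238.000
ABC     14.458
R        9.075
SC       9.302
GA      19.302
SO      68.364
N       43.237
```

— the molecule's descriptor vector (e.g. M1 = 94 is the sum of `d_u + d_v`
over the 20 bonds). Refitting the polarizability model on the packaged
tables (`examples/qspr_models.py`) gives `n = 21, r = 0.995, R² = 0.991,
RMSE = 1.459`, and ranking the 22 drugs on the index matrix
(`examples/rank_drugs.py`) puts Tacrolimus first with TOPSIS closeness
`C = 1.0000000` (it is maximal on every criterion) and Cyclosporine last
with `C = 0`; every per-property VIKOR weighting reproduces the same
extremes (`Q = 0` and `Q = 1`).

Each script in `examples/` is a short narrative of one capability:
index computation, hidden-partition recovery, QSPR refits, drug ranking,
and synthetic-data validation. The `tiqspr` command exposes the same
stages (`tiqspr reproduce --out-dir reproduction` recomputes every result
table and a deviations report in one run).

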