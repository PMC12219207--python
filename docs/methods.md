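# Methods

## Molecular graphs and indices

Molecules are hydrogen-suppressed simple graphs: vertices are heavy atoms,
edges are bonds, bond order/charge/geometry are ignored. This convention is
fixed by the packaged Diclofenac worked example (C14H11Cl2NO2 → 19 vertices,
20 edges). Degrees are always derived from edges, never stored. Maximum
degree 4 (the organic valence bound) is the chemistry-mode assumption;
`MolecularGraph.validate_chemistry` warns rather than errors on violations,
and disconnected graphs are likewise a warning, since every index formula
remains well defined on them.

All eleven indices are sums of per-edge terms in the endpoint degrees, so the
edge partition `n_{a,b}` is a sufficient statistic and computation is exact
up to double-precision summation. Two exact identities are used as internal
checks throughout: `HM = F + 2·M2` (per-edge binomial expansion) and
`M1 = Σ_v d_v²`. The ABC term at a (1,1) edge — an isolated two-atom
molecule, which cannot occur in the packaged drugs — is taken as its limit 0
with a warning inside whole-graph sums, and is a domain error when requested
directly. Comparisons against printed tables round half-away-from-zero to 3
decimals, the tables' precision; one unit in the last printed digit is
tolerated because the source tables occasionally truncate instead of round
(e.g. the Diclofenac Sombor value, exactly 68.3636, printed 68.363).

## Partition recovery

Only one drug's graph is published; the other 21 drugs exist in the data
only as index rows. `recover_partition` inverts an index row into integer
degree-pair counts: a depth-first enumeration matches M1, M2 and F exactly
(HM is implied by the identity and checked on input), pruning each branch
with two-sided interval bounds — every remaining unit of the M1 budget must
contribute between the minimum and maximum per-unit ratio of each remaining
index over the remaining degree pairs. Among exact integer matches, the
squared deviation over the seven non-integer indices is minimised; ties
break lexicographically on the count vector and uniqueness of the optimum is
reported. The pruning window widens in stages (0.05 → 0.6 → 2 → 8), and a
stage's optimum is accepted only when its residual is ≤ tol², which
certifies it as the global optimum (any excluded vector deviates by more
than tol in some index). Rows whose printed integer indices are mutually
inconsistent raise an infeasibility error carrying the best near-miss
residual from a bounded relaxed search (M1 exact, everything else soft).
Recovery of the 16 consistent rows plus the near-misses of the 5 flagged
rows runs in about a minute; round trips on graphs of ≤ 25 edges take
milliseconds because full-precision targets keep the window tight.

## The packaged study data

The source tables are shipped verbatim, as published: transcription
preserves every printed cell, including five index rows that violate
`HM = F + 2·M2` as printed (Ketorolac −108, Lifitegrast −24,
Methylprednisolone +4, Rimexolone −48, Tacrolimus +27) and anomalies such as
Cyclosporine's 102.09 g/mol molecular weight. A validator reports these;
nothing corrects them, so every downstream number is reproducible against
the publication. Partition recovery shows most violations are isolated
typos — e.g. the Ketorolac row admits a unique integer partition matching
every other column, with implied HM 510 against the printed 402. Missing
property cells use the explicit `NA` sentinel; serialisation round-trips the
packaged files byte for byte.

## Regression conventions

Enter-method OLS: every regressor of a model's published set is kept
regardless of significance. Missing data: listwise deletion on the response
only (the index table is complete), which reproduces each model's published
sample size (21 or 22). Statistics are computed from SSE/SST with
`r = +√R²`, `SE = √(SSE/(n−k−1))` and `RMSE = √(SSE/n)` — the only
(SE, RMSE) convention pair consistent with every published (SE, RMSE, n)
triple, e.g. `2.057² · 10/21 ≈ 1.419²`; the source never defines either.
The F statistic uses `(R²/k)/((1−R²)/(n−k−1))` with the upper-tail p from
the F(k, n−k−1) distribution; published p values are rounded upper bounds
and are compared as bounds. Regressors enter on their raw scales. The ten
regressors are strongly collinear, so individual refit coefficients are
stable only to order of magnitude while fitted values, predictions and RMSE
are stable — the package's reproduction checks therefore gate on sample
sizes, RMSE of the two best-measured models (molar refractivity and
polarizability) and predictions, not on coefficients. Predictions use the
full-precision refit coefficients and are produced for all 22 drugs,
including those excluded from a fit because their measured response is
missing.

## Ranking configuration

All criteria are treated as beneficial: the drug maximal on every criterion
(Tacrolimus) must rank first, which matches every published ranking table.
The default decision matrix is the 22 × 11 **index table**. This choice is
forced numerically: with equal weights on the index matrix, TOPSIS
reproduces the published closeness column to within ~0.03 per drug, whereas
any property-matrix configuration deviates by up to 0.17; and the published
Cyclosporine regret value 0.093951 equals exactly the largest
ratio-normalised absolute correlation of the boiling-point row, pinning the
per-property VIKOR runs to the index matrix with correlation-ratio weights
(computed at run time from the correlation screen, not hard-coded). TOPSIS
defaults to equal weights; VIKOR to `v = 0.5` (the balanced compromise; the
source is silent). Exact per-cell reproduction of the published score
tables is not attainable — the source does not state its matrix, weights or
missing-data handling, and its printed Cyclosporine D⁻ is nonzero, which no
complete-minimum matrix can produce — so the package's guarantees are the
configuration-robust extremes plus oracle equivalence of both formula
chains on random matrices.

The property matrix remains available as a decision-matrix source with three
explicit missing-cell policies: `predicted` (refit-model prediction for the
property, computed at run time), `mean` (column mean) and `drop-criterion`
(discard incomplete columns, leaving MR and MV). Every substitution is
logged and recorded on the matrix. Rank ties break by score and then
alternative name, so ranks are reproducible; VIKOR reports the standard
acceptable-advantage (`Q₂ − Q₁ ≥ 1/(m−1)`) and acceptable-stability (best by
Q also best by S or R) flags.

## Synthetic data

The generators emulate the structural assumptions of the analysis, not real
chemistry. Graphs: a random spanning tree grown under the degree cap, plus
independent extra edges accepted only when both endpoints stay within the
cap — connected and degree-bounded by construction, but with no valence,
aromaticity or ring-statistics realism. QSPR datasets: responses exactly
linear in a chosen index subset with additive Gaussian noise (default two
regressors, σ = 1, 50 compounds of 8–20 vertices) — linearity is an
assumption of the method, so passing recovery and coverage tests validates
the estimator under its own model, not the linearity of real
structure–property relations. Decision matrices: uniform positive cells
with optional planted dominant (1.1 × column max) and dominated (0.9 × min)
alternatives. Every generator is a pure function of its seed.

The statistical validation uses a fixed synthetic design of 40 compounds
with 500 noise replicates for the 95% coefficient-interval coverage check
(pooled over intercept and two slopes; Monte-Carlo standard error ≈ 0.6%),
and 100–200 seeded graphs for the identity and round-trip suites — sizes
chosen to make the whole suite run in seconds on one core while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

* Index rows that are inconsistent as printed cannot be inverted to a
  partition; the package reports them rather than guessing corrections.
* The regression layer implements exactly the published protocol — no
  stepwise selection, regularisation or cross-validation — and inherits its
  weaknesses (severe regressor collinearity, n ≈ 21).
* SMILES/structure ingestion is out of scope; graphs enter as edge lists.
* The ranking defaults reproduce the published tables' configuration as far
  as it can be inferred; per-cell score agreement beyond the documented
  extremes is not guaranteed.
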