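# mediprod

Causal mediation analysis via the **product method**: point and interval
estimation of the natural indirect effect (NIE), natural direct effect (NDE),
total effect (TE) and mediation proportion (MP = NIE/TE) from two regressions —
an outcome model that includes the mediator, and a mediator model — for all
four continuous/binary outcome–mediator combinations:

| Case | Outcome     | Mediator    | Scale           | Expressions                    |
|------|-------------|-------------|-----------------|--------------------------------|
| 1    | continuous  | continuous  | difference      | closed form                    |
| 2    | continuous  | binary      | difference      | closed form                    |
| 3    | binary      | continuous  | log odds ratio  | exact (Gauss–Hermite), rare-outcome approximation, probit approximation (s = 1/1.6) |
| 4    | binary      | binary      | log odds ratio  | exact (binary enumeration), rare-outcome approximation |

Binary-outcome cases include *exact* expressions that do not rely on a rare
outcome: case 3 evaluates one-dimensional logistic-normal integrals by
Gauss–Hermite quadrature (40 nodes by default), and case 4 marginalises the
potential-outcome means over the binary mediator exactly (the printed closed
forms are evaluated as a cross-check of the enumeration).

Model coefficients are estimated by solving the estimating equations with
canonical working variances (ordinary least squares / logistic scoring), with
robust sandwich covariances by default (model-based optionally).  The outcome-
and mediator-model estimates are asymptotically uncorrelated, so the joint
parameter covariance is block diagonal; NIE and MP variances follow from the
multivariate delta method (central finite-difference gradients), with 1.96
Wald intervals.  A nonparametric pairs bootstrap (percentile 95% intervals,
reproducible per-resample seed substreams) is provided as the alternative.

A simulation engine calibrates generator coefficients to hit target (TE, MP)
exactly through the case-specific *exact* expressions (closed forms for
continuous outcomes; a 2-D root-find for binary outcomes), generates data
(including heteroskedastic and skewed-gamma mediator errors and an optional
binary confounder), and reports operating characteristics: median percent
bias, delta/bootstrap coverage rates with a binomial-band flag, and the
variance ratio.

## Command line

Analyse a delimited table (header row; binary columns coded 0/1; categorical
covariates must be pre-expanded to indicators):

```sh
mediate --data study.csv --outcome Y --mediator M --exposure X \
        --binary-outcome 1 --binary-mediator 0 \
        --covariate-outcome C1,C2 --covariate-mediator C1 \
        --x0 0 --x1 1 --c-outcome mode --c-mediator mode \
        --boot 1 -R 1000 --seed 7 --out report.json
```

For a binary outcome both the approximate (rare-outcome) and exact blocks are
printed, each with point estimates, delta-method SEs and 95% CIs, and optional
percentile-bootstrap CIs.  Every flag can instead be given in a flat YAML
config (`--config analysis.yaml`); explicit flags override the file.
Conditioning values for covariates default to 0, or use `mode` for each
covariate's most frequent value.

Run a replication study from a flat scenario file:

```sh
cat > scenario.yaml <<EOF
case: 1
n: 1000
te: [0.25, 0.5, 1.0]
mp: [0.05, 0.2, 0.5]
reps: 5000
seed: 1
EOF
mediate-simulate --scenario scenario.yaml --out-prefix results/case1
```

List-valued `te`/`mp`/`n` expand into a grid; a `prevalences:` list runs a
baseline-outcome-prevalence sweep (cases 3–4) comparing exact vs approximate
estimators.  Outputs are a TSV table (one row per scenario × variant ×
measure) and a JSON report.

## Package layout

- `mediprod.data` — `Dataset` container and `read_table` (delimited text).
- `mediprod.fitting` — estimating-equation fits, sandwich covariance,
  `assemble_theta` (block-diagonal joint covariance).
- `mediprod.measures` — NIE/NDE/TE/MP for all cases and expression variants;
  quadrature and enumeration kernels.
- `mediprod.uncertainty` — delta method, Wald intervals, percentile bootstrap.
- `mediprod.simulate` — calibration solvers, data generators, replication
  studies, prevalence sweeps.
- `mediprod.cli` — `mediate` and `mediate-simulate` entry points.
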