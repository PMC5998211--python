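# metamark

A tested, reusable pipeline for two-class targeted-metabolomics biomarker
discovery from peak-area feature tables:

1. **Preprocessing** — per-batch, per-marker RMS normalization (divide each
   marker within each batch by the root-mean-square of that block), log
   transform (base 10/2/e), and pareto scaling (mean-center, divide by the
   square root of the sample standard deviation).
2. **PLS-DA + VIP** — NIPALS partial least squares against a centered 0/1
   class response; per-depth cumulative VIP scores and a global VIP
   (max over depths), with threshold-based marker shortlisting.
3. **Univariate ROC** — per-marker Mann–Whitney AUC (midrank ties), full
   ROC curves, Low/High direction calls and box-plot summaries.
4. **SBS** — sequential backward selection: random forests scored by
   out-of-bag error, iteratively dropping the least important surviving
   markers; subset chosen by OOB-error minimum with an optional
   one-standard-error parsimony rule.
5. **MCCV** — Monte Carlo cross-validation (default N = 50 stratified
   train/test splits) with per-split pareto fitting and per-split SBS;
   aggregates marker rank frequencies, VIP-like importance scores,
   direction calls, the test-AUC distribution and a vertically averaged
   composite ROC curve.
6. **Synthetic cohorts** — a seeded log-normal generator with planted
   signed effects, multiplicative batch factors and Gaussian log-noise, so
   the whole pipeline is exercisable (and recovery is scorable) without
   any external data.

## CLI

Each stage is a subcommand operating on plain CSV; `all` chains them:

```bash
metamark simulate --seed 1 --out cohort.csv
metamark preprocess --input cohort.csv --out processed.csv
metamark plsda --input processed.csv --components 3 --vip-threshold 2.0 --out pls/
metamark univariate --input processed.csv --out univariate.csv
metamark select --input processed.csv --n-trees 500 --out sbs/
metamark mccv --input cohort.csv --n-iterations 50 --out mccv/
metamark all --synthetic --seed 1 --out run/          # everything at once
metamark all --config run.yaml --out run/             # YAML-configured
```

Feature-table CSV schema: `sample_id, group, batch, <marker_1>, ...` with
groups `case`/`control` (aliases `OC`/`CNTRL` accepted). `metamark all`
writes the processed table, VIP report, univariate report, SBS trace,
MCCV marker summary, composite ROC, test-AUC distribution and a YAML
manifest (config + seed + versions) that suffices to reproduce the run.
Note that `mccv` consumes the **raw** table: pareto constants are
refitted inside every split to avoid test-set leakage (batch
normalization, an acquisition-level correction, is applied up front).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence for AUC, VIP normalization, preprocessing invariants, marker
recovery and null calibration of the MCCV, end-to-end determinism). The
Monte Carlo criteria use reduced forest sizes to fit a single-CPU budget.

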