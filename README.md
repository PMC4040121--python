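# mlcqtl

QTL mapping for **multiple connected biparental families** of doubled-haploid
(DH) lines, from multi-environment field plots to a cross-validated multi-QTL
model. The package covers the full analysis chain:

1. **Phenotypic analysis** — REML variance components per developmental stage,
   entry-mean heritability, and best linear unbiased estimates (BLUEs) of the
   genotype means across environments.
2. **Genome scan** — composite interval mapping generalised to several
   families at once, with family-specific allele-substitution effects and
   marker cofactors; genome-wide LOD thresholds by within-family permutation.
3. **Multi-QTL model** — QTL calling with LOD-1 support intervals, a joint
   final fit, and the proportion of genotypic variance (p_G) attributed to
   each QTL.
4. **Cross-validation** — stratified k-fold CV of the whole detection
   pipeline, quantifying the upward bias of p_G estimated on the detection
   data (relative bias between estimation and test sets).
5. **Epistasis** — a two-dimensional scan for pairwise interactions with a
   region-based multiple-testing correction.
6. **Simulation** — a generator for synthetic multi-family DH datasets
   (linkage map, meioses, field trials) used for validation and examples.

## Model

For lines from `F` families with family incidence `J`, entry means `Y`
(BLUEs) are scanned position by position:

```
Y = J m  +  X(q) b(q)  +  Σ_c X(c) b(c)  +  e
```

where `X(q)` holds the expected reference-allele counts at the tested
position `q` — computed from the flanking markers with the Haldane mapping
function — one column per family that segregates there, `b(q)` are
family-specific allele-substitution effects, and the `X(c)` are marker
cofactors selected by BIC (cofactors within 10 cM of `q` are excluded). The
evidence at `q` is `LOD = n · ln(RSS_reduced / RSS_full) / (2 ln 10)`.

Heritability on an entry-mean basis uses
`h² = σ²_G / (σ²_G + σ²_GxE / E + σ²_e / (E·R))` with `E` environments and
mean replication `R`.

## Quick start (CLI)

Each stage is a subcommand reading and writing plain TSV tables; `mlcqtl all`
chains them from one YAML config and writes a `manifest.json` with SHA-256
checksums and per-stage child seeds, so any run is reproducible bit for bit.

```bash
cat > run.yaml <<'YAML'
simulate:
  chromosomes: [[C1, 100], [C2, 100], [C3, 100], [C4, 100], [C5, 100]]
  marker_spacing: 10
  families:
    - [DH06, 50, P1, P2]
    - [DH07, 50, P1, P3]
    - [EAW74, 60, P4, P5]
    - [EAW78, 60, P6, P7]
  n_environments: 4
  plots_per_environment: 240
scan:      {step: 2, n_perm: 200, alpha: 0.10}
cv:        {runs: 5, k: 5}
epistasis: {step: 10}
YAML

mlcqtl all --config run.yaml --out out --seed 42
```

This simulates 220 DH lines in four connected families (three developmental
stages PH1–PH3), estimates variance components and BLUEs, scans each stage,
matches QTL across stages, cross-validates stage PH1 and scans it for
epistasis — about 10 s on one CPU. Representative output (seed 42):

```
$ column -t out/cv_summary_PH1.tsv      # (comment header stripped)
statistic      PH1
QTL_DS         6.0        QTL detected on the full data set
p_G-DS         96.5       % genotypic variance they explain there
QTL_ES         4.0        mean QTL count over 25 estimation sets
p_G-ES         89.1       mean % on the estimation sets
p_G-TS         80.4       mean % re-assessed on the held-out test sets
Relative bias  9.7        100 (p_G-ES - p_G-TS) / p_G-ES
```

and the per-stage QTL table (`out/qtl_PH1.tsv`) lists peak position, LOD-1
support interval, LOD, p_G and one allele-substitution effect per family
(NaN where a family does not segregate).

Single stages run standalone, e.g.

```bash
mlcqtl simulate --config sim.yaml --out data --seed 5
mlcqtl pheno    --plots data/plots.tsv --out pheno
mlcqtl scan     --blues pheno/blues.tsv --geno data/genotypes.tsv \
                --map data/map.tsv --fam data/families.tsv \
                --stage PH1 --h2 0.9 --out scan1
mlcqtl cv ... ; mlcqtl epistasis ... ; mlcqtl compare --qtl scan1/qtl_PH1.tsv ...
```

## Python API

```python
import numpy as np
from mlcqtl import simpop
from mlcqtl.phenostats import compute_blues, variance_table
from mlcqtl.crossval import detect_qtl, run_cv

cfg = simpop.default_config(seed=1)          # 21 chromosomes, 647 lines
ds = simpop.simulate_dataset(cfg)
blues = compute_blues(ds.plots)
vt = variance_table(ds.plots, blues=blues)   # sigma_G2 ... h2 per stage
y = blues.stage_values("PH1", ds.genotypes.line_ids)
qtl, model, thr = detect_qtl(y, ds.genotypes, ds.linkage_map, ds.families,
                             h2=float(vt.loc["h2", "PH1"]), seed=1)
cv = run_cv(y, ds.genotypes, ds.linkage_map, ds.families,
            h2=float(vt.loc["h2", "PH1"]), n_runs=20, seed=1)
```

Lower-level building blocks live in `mlcqtl.linkage` (mapping functions,
expected allele counts, per-position design blocks), `mlcqtl.mcqtl`
(`ScanEngine`, cofactor selection, permutation thresholds, QTL calling),
`mlcqtl.epistasis` and `mlcqtl.iomodel` (file formats and validation).

## Reproducibility and testing

* All randomness flows from a single seed through `numpy.random.SeedSequence`
  derivation; re-running any command with the same config and seed reproduces
  identical output bytes (checked in the test suite via the manifest
  checksums).
* `tests/test_acceptance.py` holds the acceptance criteria: arithmetic
  identities, a brute-force oracle for the expected-allele-count formula, an
  independent interval-mapping implementation the scan must match to 1e-8,
  type-I-error calibration of the permutation threshold, recovery of a
  calibrated major QTL, the cross-validation bias direction, and epistasis
  power/null behaviour. One null-rate assertion is a known, documented
  failure of the region-based correction (see `docs/methods.md`).
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  writes the two deterministic heritability target values.

See `docs/methods.md` for the statistical methods, model assumptions,
numerical choices and simulator defaults.
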