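"""Fivefold cross-validation of the QTL detection pipeline.

QTL are detected on each estimation set (4/5 of every family,
stratified), the proportion of genotypic variance they explain is
recorded on the estimation set (p_G-ES, adjusted R^2 of the multi-QTL
fit over heritability) and re-assessed on the held-out test set (p_G-TS,
squared Pearson correlation between the genotypic scores predicted from
estimation-set effects and the observed test-set entry means, within
families, divided by heritability).  The gap is reported as the relative
bias, 100 (p_G-ES - p_G-TS) / p_G-ES, and detection stability as the
frequency of estimation sets hitting each 5 cM sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iomodel import FamilyAssignment, GenotypeMatrix
from .mcqtl import (
    ScanEngine, call_qtl, fit_final_model, permutation_threshold,
    select_cofactors,
)

__all__ = [
    "CVResult", "FrequencyDistribution", "make_folds", "run_cv",
    "relative_bias", "qtl_frequency", "detect_qtl",
]


def relative_bias(pg_es, pg_ts):
    """Shrinkage from estimation to test set: 100 (p_G-ES - p_G-TS) / p_G-ES.

    Reported to one decimal; undefined (NaN) when p_G-ES is zero.
    """
    if pg_es == 0:
        return float("nan")
    return round(100.0 * (pg_es - pg_ts) / pg_es, 1)


def make_folds(families: FamilyAssignment, line_ids, k=5, n_runs=1, seed=0
               ) -> np.ndarray:
    """Stratified fold assignments, shape (n_runs, n_lines), values 0..k-1.

    Within each run every family is split into k near-equal parts
    (sizes differ by at most one line), so no fold loses a family.
    """
    codes = families.codes_for(line_ids)
    n = codes.size
    rng = np.random.default_rng(seed)
    out = np.empty((n_runs, n), dtype=int)
    for r in range(n_runs):
        for f in range(codes.max() + 1):
            sel = np.flatnonzero(codes == f)
            if sel.size < k:
                raise ValueError(
                    f"family index {f} has {sel.size} lines, fewer than k={k}")
            perm = rng.permutation(sel.size)
            out[r, sel[perm]] = np.arange(sel.size) % k
    return out


def _subset_genotypes(genotypes: GenotypeMatrix, mask) -> GenotypeMatrix:
    return GenotypeMatrix(genotypes.frame.loc[mask])


def detect_qtl(y, genotypes, linkage_map, families, h2, threshold=None,
               step_cM=1.0, n_perm=200, alpha=0.10, seed=0,
               select=True, cofactors=None):
    """One full detection pass: cofactors, scan, threshold, calling, final fit.

    Returns (qtl_list, final_model, threshold_used).
    """
    if select and cofactors is None:
        cofactors = select_cofactors(y, genotypes, linkage_map, families)
    eng = ScanEngine(genotypes, linkage_map, families, cofactors=cofactors,
                     step_cM=step_cM)
    if threshold is None:
        threshold = permutation_threshold(
            y, genotypes, linkage_map, families, n_perm=n_perm, alpha=alpha,
            seed=seed, engine=eng)
    profile = eng.lod_profile(np.asarray(y, dtype=float), with_effects=True)
    qtl = call_qtl(profile, threshold)
    model = fit_final_model(y, qtl, genotypes, linkage_map, families, h2)
    return qtl, model, threshold


@dataclass
class CVResult:
    """Cross-validation summary for one stage."""

    qtl_ds: int            # QTL detected on the full data set
    pg_ds: float           # % genotypic variance, full data set
    qtl_es: float          # mean QTL count over estimation sets
    pg_es: float           # mean % over estimation sets
    pg_ts: float           # mean % on the corresponding test sets
    bias: float            # relative bias, %
    per_run: pd.DataFrame  # run-level means (columns: run, qtl_es, pg_es, pg_ts)
    records: list          # (run, fold, [QTLResult, ...]) detection records
    threshold: float

    def __post_init__(self):
        if self.qtl_ds < 0:
            raise ValueError("counts must be >= 0")


def _centered_corr2(pred, obs, codes):
    """Squared Pearson correlation after centring both vectors within family."""
    p = pred.astype(float).copy()
    o = obs.astype(float).copy()
    for f in np.unique(codes):
        sel = codes == f
        p[sel] -= p[sel].mean()
        o[sel] -= o[sel].mean()
    sp_, so = p.std(), o.std()
    if sp_ == 0 or so == 0:
        return 0.0
    return float(np.corrcoef(p, o)[0, 1] ** 2)


def run_cv(blues_y, genotypes, linkage_map, families, h2, k=5, n_runs=20,
           seed=0, step_cM=1.0, threshold=None, n_perm=200, alpha=0.10,
           refit_threshold=False, select=True) -> CVResult:
    """k-fold cross-validation of the detection pipeline (see module docstring).

    By default the genome-wide threshold is computed once on the full
    data and reused inside every estimation set (``refit_threshold``
    recomputes it per estimation set).  ``n_runs`` independent
    replications of the k folds give n_runs * k estimation sets.
    """
    y = np.asarray(blues_y, dtype=float)
    line_ids = genotypes.line_ids
    codes = families.codes_for(line_ids)

    qtl_full, model_full, threshold = detect_qtl(
        y, genotypes, linkage_map, families, h2, threshold=threshold,
        step_cM=step_cM, n_perm=n_perm, alpha=alpha, seed=seed, select=select)

    folds = make_folds(families, line_ids, k=k, n_runs=n_runs, seed=seed + 1)
    records = []
    rows = []
    for r in range(n_runs):
        run_counts, run_es, run_ts = [], [], []
        for fold in range(k):
            ts_mask = folds[r] == fold
            es_mask = ~ts_mask
            g_es = _subset_genotypes(genotypes, es_mask)
            g_ts = _subset_genotypes(genotypes, ts_mask)
            thr = None if refit_threshold else threshold
            qtl, model, _ = detect_qtl(
                y[es_mask], g_es, linkage_map, families, h2, threshold=thr,
                step_cM=step_cM, n_perm=n_perm, alpha=alpha,
                seed=seed + 1000 * r + fold, select=select)
            records.append((r, fold, qtl))
            run_counts.append(len(qtl))
            run_es.append(model.total_p_g)
            if qtl:
                pred = model.predict(g_ts, linkage_map, families)
                r2 = _centered_corr2(pred, y[ts_mask], codes[ts_mask])
                run_ts.append(100.0 * r2 / h2)
            else:
                run_ts.append(0.0)
        rows.append((r, np.mean(run_counts), np.mean(run_es), np.mean(run_ts)))

    per_run = pd.DataFrame(rows, columns=["run", "qtl_es", "pg_es", "pg_ts"])
    pg_es = float(per_run["pg_es"].mean())
    pg_ts = float(per_run["pg_ts"].mean())
    return CVResult(
        qtl_ds=len(qtl_full), pg_ds=model_full.total_p_g,
        qtl_es=float(per_run["qtl_es"].mean()), pg_es=pg_es, pg_ts=pg_ts,
        bias=relative_bias(pg_es, pg_ts), per_run=per_run, records=records,
        threshold=threshold,
    )


@dataclass
class FrequencyDistribution:
    """Detection frequency per sliding genome window across estimation sets."""

    table: pd.DataFrame  # chromosome, window_start, window_end, frequency
    n_sets: int


def qtl_frequency(records, linkage_map, window_cM=5.0, slide_cM=1.0
                  ) -> FrequencyDistribution:
    """Fraction of estimation sets with >= 1 declared peak in each window.

    ``records`` is the detection-record list from run_cv: tuples whose
    last element is a list of QTLResult.
    """
    n_sets = len(records)
    peaks = {}
    for rec in records:
        qtl = rec[-1]
        for q in qtl:
            peaks.setdefault(q.chromosome, []).append((id(rec), q.position))
    rows = []
    tab = linkage_map.table
    for chrom in linkage_map.chromosomes:
        length = linkage_map.chromosome_length(chrom)
        starts = np.arange(0.0, max(length - window_cM, 0.0) + 1e-9, slide_cM)
        chrom_peaks = peaks.get(chrom, [])
        for s in starts:
            e = s + window_cM
            hit_sets = {rid for rid, p in chrom_peaks if s - 1e-9 <= p <= e + 1e-9}
            rows.append((chrom, float(s), float(e), len(hit_sets) / n_sets))
    return FrequencyDistribution(
        pd.DataFrame(rows, columns=["chromosome", "window_start", "window_end",
                                    "frequency"]),
        n_sets,
    )
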