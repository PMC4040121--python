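"""Plot-level phenotypic analysis for multi-environment trials.

Variance components are estimated by REML under the full random model

    y = mu + genotype + environment + genotype x environment + error,

entry-mean heritability as the ratio of genotypic to phenotypic variance
of an entry mean, and across-environment entry means (BLUEs) with the
genotype fixed and environment / G-by-E random.  The REML fit maximises
the residual likelihood through the mixed-model equations: with
variance ratios lambda_k = sigma_k^2 / sigma_e^2 and W = [X Z],

    M(lambda) = W'W + diag(0, 1/lambda_k I),
    -2 l_R(lambda) = (n-p) log sigma_e^2(lambda) + sum_k q_k log lambda_k
                     + log|M(lambda)| + const,

profiled over sigma_e^2, which keeps every evaluation a single sparse
factorisation even for thousands of plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .iomodel import BlueTable, PlotTable

__all__ = [
    "VarianceComponents",
    "estimate_variance_components",
    "entry_mean_heritability",
    "compute_blues",
    "stage_r2",
    "family_parent_contrast",
    "blue_summary",
]

log = logging.getLogger(__name__)

_LOGLAM_BOUNDS = (-23.0, 16.0)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_gxe2: float
    sigma_e2: float
    n_env: int
    mean_replication: float
    h2: float = float("nan")
    sigma_env2: float = float("nan")

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_gxe2", "sigma_e2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if np.isnan(self.h2):
            self.h2 = entry_mean_heritability(self)


def entry_mean_heritability(vc: VarianceComponents) -> float:
    """h^2 = sG2 / (sG2 + sGxE2/E + se2/(E*R)) on an entry-mean basis."""
    E, R = vc.n_env, vc.mean_replication
    if E * R == 0:
        raise ValueError("n_env * mean_replication must be > 0")
    denom = vc.sigma_g2 + vc.sigma_gxe2 / E + vc.sigma_e2 / (E * R)
    if denom == 0:
        return 0.0
    return vc.sigma_g2 / denom


def _factor_codes(values):
    levels, codes = np.unique(np.asarray(values), return_inverse=True)
    return levels, codes


def _indicator(codes, n_levels, n) -> sp.csr_matrix:
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _reml_fit(y, X, Zs, x0=None):
    """Maximise the residual likelihood over variance ratios.

    Parameters: y (n,), X dense/sparse fixed design with p columns,
    Zs list of (name, sparse Z).  Returns dict name -> sigma^2 plus
    'error' for the residual component.
    """
    n = y.size
    X = sp.csr_matrix(X)
    p = X.shape[1]
    W = sp.hstack([X] + [Z for _, Z in Zs], format="csr")
    WtW = (W.T @ W).tocsc()
    Wty = W.T @ y
    yty = float(y @ y)
    q_sizes = [Z.shape[1] for _, Z in Zs]

    def objective(loglam):
        lam = np.exp(loglam)
        dvec = np.zeros(WtW.shape[0])
        start = p
        for k, q in enumerate(q_sizes):
            dvec[start:start + q] = 1.0 / lam[k]
            start += q
        M = (WtW + sp.diags(dvec)).tocsc()
        lu = splu(M)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        theta = lu.solve(Wty)
        sse = max(yty - float(theta @ Wty), 1e-12 * max(yty, 1.0))
        sig_e = sse / (n - p)
        return (n - p) * np.log(sig_e) + float(np.dot(q_sizes, loglam)) + logdet

    k = len(Zs)
    if x0 is None:
        x0 = np.zeros(k)
    res = scipy.optimize.minimize(
        objective, x0, method="Nelder-Mead",
        bounds=[_LOGLAM_BOUNDS] * k,
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
    )
    lam = np.exp(res.x)
    # recompute sigma_e at the optimum
    dvec = np.zeros(WtW.shape[0])
    start = p
    for kk, q in enumerate(q_sizes):
        dvec[start:start + q] = 1.0 / lam[kk]
        start += q
    lu = splu((WtW + sp.diags(dvec)).tocsc())
    theta = lu.solve(Wty)
    sse = max(yty - float(theta @ Wty), 0.0)
    sig_e = sse / (n - p)
    out = {"error": sig_e}
    for (name, _), l in zip(Zs, lam):
        s = l * sig_e
        if s < 1e-7 * max(sig_e, 1e-12) or l <= np.exp(_LOGLAM_BOUNDS[0] + 1e-6):
            if s > 0:
                log.warning("variance component %s truncated at zero (%.3g)", name, s)
            s = 0.0
        out[name] = s
    out["_theta"] = theta
    out["_loglik"] = -0.5 * res.fun
    return out


def _stage_data(plots: PlotTable, stage, include_checks: bool):
    frame = plots.frame
    if not include_checks:
        frame = frame.loc[~frame["is_check"]]
    y = frame[stage].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    frame, y = frame.loc[ok], y[ok]
    return frame, y


def estimate_variance_components(plots: PlotTable, stage, include_checks=True,
                                 block_effect=False) -> VarianceComponents:
    """REML variance components for one stage under the full random model.

    Genotype, environment and genotype-by-environment effects are all
    random; negative components are truncated at zero (with a warning).
    ``block_effect`` adds a random replicate-within-environment term as a
    reduced stand-in for the incomplete-block field layout.
    """
    if plots.n_environments < 2:
        raise ValueError("G x E not estimable: need >= 2 environments")
    frame, y = _stage_data(plots, stage, include_checks)
    n = y.size
    _, g_codes = _factor_codes(frame["entry"])
    _, e_codes = _factor_codes(frame["environment"])
    ge_codes = g_codes * (e_codes.max() + 1) + e_codes
    _, ge_codes = _factor_codes(ge_codes)
    Zs = [
        ("genotype", _indicator(g_codes, g_codes.max() + 1, n)),
        ("environment", _indicator(e_codes, e_codes.max() + 1, n)),
        ("gxe", _indicator(ge_codes, ge_codes.max() + 1, n)),
    ]
    if block_effect:
        _, b_codes = _factor_codes(
            frame["environment"].astype(str) + "/" + frame["replicate"].astype(str))
        Zs.append(("block", _indicator(b_codes, b_codes.max() + 1, n)))
    X = np.ones((n, 1))
    fit = _reml_fit(y - y.mean(), X, Zs)

    non_check = plots.frame.loc[~plots.frame["is_check"]]
    n_entries = non_check["entry"].nunique()
    E = plots.n_environments
    mean_rep = len(non_check) / (n_entries * E)
    return VarianceComponents(
        sigma_g2=fit["genotype"], sigma_gxe2=fit["gxe"], sigma_e2=fit["error"],
        n_env=E, mean_replication=mean_rep, sigma_env2=fit["environment"],
    )


def compute_blues(plots: PlotTable, stage=None, vc=None, include_checks=True,
                  keep_checks=False) -> BlueTable:
    """Across-environment entry means with genotype fixed, env and G x E random.

    Solves the mixed-model equations at the variance ratios implied by
    ``vc`` (estimated on the fly when not given).  In the balanced
    complete case this reduces to the simple entry mean.  Checks inform
    the environmental terms but are dropped from the output unless
    ``keep_checks``.
    """
    stages = plots.stages if stage is None else [stage]
    cols = {}
    entries_out = None
    for st in stages:
        vcs = vc if vc is not None else estimate_variance_components(plots, st, include_checks)
        frame, y = _stage_data(plots, st, include_checks)
        n = y.size
        g_levels, g_codes = _factor_codes(frame["entry"])
        _, e_codes = _factor_codes(frame["environment"])
        ge_codes = g_codes * (e_codes.max() + 1) + e_codes
        _, ge_codes = _factor_codes(ge_codes)
        X = _indicator(g_codes, len(g_levels), n)
        se2 = max(vcs.sigma_e2, 1e-10 * max(float(np.var(y)), 1e-6))
        lam_env = np.clip((vcs.sigma_env2 if np.isfinite(vcs.sigma_env2) else 0.0) / se2,
                          1e-8, 1e12)
        lam_ge = np.clip(vcs.sigma_gxe2 / se2, 1e-8, 1e6)
        # sum-to-zero contrast coding removes the grand-mean confounding
        # between the fixed genotype block and the environment block, which
        # otherwise makes the equations singular in the sigma_e -> 0 limit
        n_env = e_codes.max() + 1
        H = sp.csr_matrix(np.vstack([np.eye(n_env - 1), -np.ones(n_env - 1)]))
        Z_env = _indicator(e_codes, n_env, n) @ H
        Z_ge = _indicator(ge_codes, ge_codes.max() + 1, n)
        W = sp.hstack([X, Z_env, Z_ge], format="csr")
        dvec = np.concatenate([
            np.zeros(X.shape[1]),
            np.full(Z_env.shape[1], 1.0 / lam_env),
            np.full(Z_ge.shape[1], 1.0 / lam_ge),
        ])
        M = (W.T @ W + sp.diags(dvec)).tocsc()
        lu = splu(M)
        Wty = W.T @ y
        theta = lu.solve(Wty)
        # one step of iterative refinement for the near-singular sigma_e -> 0 limit
        theta += lu.solve(Wty - M @ theta)
        blues = pd.Series(theta[: len(g_levels)], index=g_levels)
        check_ids = set(plots.frame.loc[plots.frame["is_check"], "entry"])
        if not keep_checks:
            blues = blues.loc[[g for g in g_levels if g not in check_ids]]
        cols[st] = blues
        entries_out = blues.index
    return BlueTable(pd.DataFrame(cols).loc[entries_out])


def blue_summary(blues: BlueTable) -> pd.DataFrame:
    """Min / mean / max of the entry means per stage (summary-table layout)."""
    f = blues.frame
    return pd.DataFrame({"Min": f.min(), "Mean": f.mean(), "Max": f.max()}).T


def stage_r2(blues: BlueTable) -> pd.DataFrame:
    """Stage x stage matrix of squared Pearson correlations of the entry means."""
    return blues.frame.corr() ** 2


def family_parent_contrast(blues: BlueTable, families, parent_values, stage,
                           sigma2_entry=0.0) -> pd.DataFrame:
    """Family DH mean vs midparent mean, with a two-sided z test per family.

    ``parent_values`` maps parent id -> entry-mean phenotype.  The
    standard error combines the sampling variance of the family mean
    (from the observed spread of its entry means, which already contains
    the entry-mean error) with the measurement error of the two parents
    (``sigma2_entry``; pass 0 to treat the parents as known).  Under a
    purely additive architecture the expected contrast is zero; a
    directional deviation indicates epistasis (or dominance, absent in
    DH material).
    """
    vals = blues.stage_values(stage)
    codes = families.codes_for(blues.line_ids)
    rows = []
    for f, fam in enumerate(families.family_ids):
        v = vals[codes == f]
        p1, p2 = families.parents(fam)
        if p1 not in parent_values or p2 not in parent_values:
            continue
        midparent = 0.5 * (parent_values[p1] + parent_values[p2])
        contrast = float(np.mean(v)) - midparent
        se = float(np.sqrt(np.var(v, ddof=1) / v.size + sigma2_entry / 2.0))
        z = contrast / se if se > 0 else np.inf * np.sign(contrast)
        pval = 2.0 * norm.sf(abs(z))
        rows.append((fam, contrast, se, pval))
    return pd.DataFrame(rows, columns=["family", "contrast", "se", "p_value"]
                        ).set_index("family")


def variance_table(plots: PlotTable, blues: BlueTable | None = None,
                   include_checks=True) -> pd.DataFrame:
    """Per-stage summary in the usual trial-report layout.

    Rows: Min / Mean / Max of the entry means, the three variance
    components and the entry-mean heritability.
    """
    stages = plots.stages
    out = {}
    for st in stages:
        vc = estimate_variance_components(plots, st, include_checks)
        b = blues if blues is not None else compute_blues(plots, st, vc=vc,
                                                          include_checks=include_checks)
        v = b.stage_values(st)
        out[st] = {
            "Min": float(np.min(v)), "Mean": float(np.mean(v)), "Max": float(np.max(v)),
            "sigma_G2": vc.sigma_g2, "sigma_GxE2": vc.sigma_gxe2,
            "sigma_e2": vc.sigma_e2, "h2": round(vc.h2, 2),
        }
    return pd.DataFrame(out)
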