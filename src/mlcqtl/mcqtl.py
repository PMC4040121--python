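"""Multiple-line cross composite interval mapping.

The scan model is a fixed-effects Gaussian regression of the entry means
on family means plus family-specific expected allele counts:

    Y = J M + X_q B_q + sum_{c != q} X_c B_c + eps

with J the N x P family-incidence matrix, X_q the N x P matrix of
expected reference-allele counts at the tested position (columns of
non-segregating families dropped) and X_c the analogous cofactor blocks.
The presence of a QTL is judged by a likelihood-ratio test computed from
residual sums of squares, LR = n log(RSS_reduced / RSS_full), reported
as LOD = LR / (2 ln 10).  Cofactors closer than 10 cM to the tested
position are excluded from the model at that position.

Genome-wide significance comes from a permutation test that reshuffles
the entry means within each family (preserving family mean structure
under the null); QTL are called as local profile maxima above the
threshold with a 1.0 LOD fall-off support interval, and the proportion
of genotypic variance explained is the adjusted R^2 of the simultaneous
multi-QTL fit divided by the entry-mean heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .linkage import DesignBlock, ScanGrid, build_design_block, build_scan_grid

__all__ = [
    "CofactorSet", "ScanProfile", "QTLResult", "FinalModel", "ScanEngine",
    "select_cofactors", "genome_scan", "lod_at_position",
    "permutation_threshold", "call_qtl", "fit_final_model",
    "match_qtl_across_stages", "StageMatch",
]

LOD_SCALE = 2.0 * np.log(10.0)
_RSS_FLOOR = 1e-12


@dataclass
class CofactorSet:
    """Markers retained as background covariates by stepwise selection."""

    table: pd.DataFrame  # columns: marker, chromosome, position, criterion

    def __len__(self):
        return len(self.table)

    @property
    def markers(self):
        return list(self.table["marker"])


@dataclass
class ScanProfile:
    """Per-position LOD values with family-specific effect estimates."""

    table: pd.DataFrame  # chromosome, position, lod, df, effect_<family>...
    family_ids: list

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class QTLResult:
    chromosome: str
    position: float
    support: tuple          # (lo, hi) cM, LOD fall-off 1.0
    lod: float
    effects: dict           # family id -> allele-substitution effect (NaN if not segregating)
    p_g: float = float("nan")   # % of genotypic variance, filled by the final fit

    def __post_init__(self):
        lo, hi = self.support
        if not (lo - 1e-9 <= self.position <= hi + 1e-9):
            raise ValueError("support interval must contain the peak")


def _orth(X, col_scale=None, rtol=1e-8):
    """Orthonormal basis of col(X) with a rank tolerance tied to column scale."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    ref = max(float(np.max(s)), float(col_scale) if col_scale else 0.0, 1e-30)
    return U[:, s > rtol * ref]


def _residual_basis(C, Q, rtol=1e-7):
    """Orthonormal basis of the part of col(C) outside col(Q)."""
    scale = float(np.linalg.norm(C, ord=2)) if C.size else 0.0
    R = C - Q @ (Q.T @ C)
    return _orth(R, col_scale=scale, rtol=rtol)


class ScanEngine:
    """Precomputed genome-scan machinery for one dataset and cofactor set.

    Builds, for every grid position, orthonormal bases of the reduced
    (family means + admissible cofactors) and full (plus the position's
    segregating-family columns) design spaces, so that LOD profiles for
    many phenotype vectors (e.g. permutations) cost two small matrix
    products per position.
    """

    def __init__(self, genotypes, linkage_map, families, cofactors=None,
                 grid=None, step_cM=1.0, exclusion_cM=10.0):
        self.linkage_map = linkage_map
        self.families = families
        self.family_ids = families.family_ids
        self.grid = grid if grid is not None else build_scan_grid(linkage_map, step_cM)
        self.J = families.incidence(genotypes.line_ids)
        self.n = self.J.shape[0]
        self.exclusion_cM = exclusion_cM

        self.blocks = [
            build_design_block((c, p), genotypes, linkage_map, families)
            for c, p in self.grid
        ]
        self._cof = []
        if cofactors is not None and len(cofactors):
            for _, row in cofactors.table.iterrows():
                blk = build_design_block((row["chromosome"], row["position"]),
                                         genotypes, linkage_map, families)
                self._cof.append((row["chromosome"], row["position"], blk.columns()))
        self._bases = []
        for blk in self.blocks:
            cof_cols = [c for ch, p, c in self._cof
                        if not (ch == blk.chromosome
                                and abs(p - blk.position) < exclusion_cM)]
            X_red = np.hstack([self.J] + cof_cols) if cof_cols else self.J
            pos_cols = blk.columns()
            Q_red = _orth(X_red)
            if pos_cols.shape[1]:
                extra = _residual_basis(pos_cols, Q_red)
                Q_full = np.hstack([Q_red, extra])
            else:
                Q_full = Q_red
            self._bases.append((Q_red, Q_full, pos_cols.shape[1]))

    # -- likelihood machinery -------------------------------------------------

    def lod_profile(self, y, with_effects=False) -> ScanProfile:
        # centring changes nothing in exact arithmetic (the intercept lies in
        # col(J)) but avoids catastrophic cancellation in yty - a'a
        y = np.asarray(y, dtype=float)
        y = y - y.mean()
        yty = float(y @ y)
        rows = []
        effects = []
        for blk, (Q_red, Q_full, df) in zip(self.blocks, self._bases):
            if df == 0:
                lod = 0.0
            else:
                a_r = Q_red.T @ y
                a_f = Q_full.T @ y
                rss_r = max(yty - float(a_r @ a_r), _RSS_FLOOR * max(yty, 1.0))
                rss_f = max(yty - float(a_f @ a_f), _RSS_FLOOR * max(yty, 1.0))
                lod = self.n * np.log(rss_r / rss_f) / LOD_SCALE
            rows.append((blk.chromosome, blk.position, max(lod, 0.0), df))
            if with_effects:
                effects.append(self._effects_at(blk, Q_red, y))
        tab = pd.DataFrame(rows, columns=["chromosome", "position", "lod", "df"])
        if with_effects:
            eff = pd.DataFrame(effects, columns=[f"effect_{f}" for f in self.family_ids])
            tab = pd.concat([tab, eff], axis=1)
        return ScanProfile(tab, list(self.family_ids))

    def _effects_at(self, blk: DesignBlock, Q_red, y):
        """Per-family allele-substitution effects after adjusting for the
        reduced model (family means + cofactors)."""
        out = np.full(len(self.family_ids), np.nan)
        cols = blk.columns()
        if cols.shape[1] == 0:
            return out
        y_res = y - Q_red @ (Q_red.T @ y)
        C_res = cols - Q_red @ (Q_red.T @ cols)
        coef, *_ = np.linalg.lstsq(C_res, y_res, rcond=None)
        out[np.flatnonzero(blk.segregating)] = coef
        return out

    def max_lod(self, Y) -> np.ndarray:
        """Genome-wide maximum LOD for each column of Y (vectorised)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Y = Y - Y.mean(axis=0)  # see lod_profile: numerical guard only
        yty = np.einsum("ij,ij->j", Y, Y)
        best = np.zeros(Y.shape[1])
        floor = _RSS_FLOOR * np.maximum(yty, 1.0)
        for (Q_red, Q_full, df) in self._bases:
            if df == 0:
                continue
            A_r = Q_red.T @ Y
            A_f = Q_full.T @ Y
            rss_r = np.maximum(yty - np.einsum("ij,ij->j", A_r, A_r), floor)
            rss_f = np.maximum(yty - np.einsum("ij,ij->j", A_f, A_f), floor)
            lod = self.n * np.log(rss_r / rss_f) / LOD_SCALE
            np.maximum(best, lod, out=best)
        return best


def lod_at_position(y, design_block: DesignBlock, J, cofactor_columns=()):
    """LOD and per-family effects for a single position (functional form).

    ``cofactor_columns`` must already respect the 10 cM exclusion rule.
    Returns (lod, effects array over all families, df).
    """
    y = np.asarray(y, dtype=float)
    y = y - y.mean()  # see ScanEngine.lod_profile: numerical guard only
    n = y.size
    cols = design_block.columns()
    X_red = np.hstack([J] + [c for c in cofactor_columns if c.size]) \
        if cofactor_columns else J
    Q_red = _orth(X_red)
    effects = np.full(design_block.n_families, np.nan)
    if cols.shape[1] == 0:
        return 0.0, effects, 0
    Q_full = np.hstack([Q_red, _residual_basis(cols, Q_red)])
    yty = float(y @ y)
    a_r, a_f = Q_red.T @ y, Q_full.T @ y
    rss_r = max(yty - float(a_r @ a_r), _RSS_FLOOR * max(yty, 1.0))
    rss_f = max(yty - float(a_f @ a_f), _RSS_FLOOR * max(yty, 1.0))
    lod = max(n * np.log(rss_r / rss_f) / LOD_SCALE, 0.0)
    y_res = y - Q_red @ a_r
    C_res = cols - Q_red @ (Q_red.T @ cols)
    coef, *_ = np.linalg.lstsq(C_res, y_res, rcond=None)
    effects[np.flatnonzero(design_block.segregating)] = coef
    return lod, effects, int(cols.shape[1])


def select_cofactors(blues_y, genotypes, linkage_map, families,
                     criterion="bic", min_sep_cM=1.0, max_steps=40) -> CofactorSet:
    """Stepwise forward-backward marker selection against the family-means model.

    Candidates are all mapped markers (as family-specific design blocks);
    admission is governed by the Schwarz/Bayesian information criterion
    (``criterion='aic'`` switches the penalty to 2 per parameter).  No
    two selected cofactors may lie within ``min_sep_cM`` of each other,
    and a candidate whose columns add no dimension beyond the current
    model (e.g. a duplicated marker) is never admitted.  Deterministic
    for fixed input.
    """
    y = np.asarray(blues_y, dtype=float)
    n = y.size
    pen = np.log(n) if criterion == "bic" else 2.0
    J = families.incidence(genotypes.line_ids)
    tab = linkage_map.table

    cand = []
    for _, row in tab.iterrows():
        blk = build_design_block((row["chromosome"], row["position"]),
                                 genotypes, linkage_map, families)
        cols = blk.columns()
        if cols.shape[1]:
            cand.append((row["marker"], row["chromosome"], row["position"], cols))
    if not cand:
        return CofactorSet(pd.DataFrame(
            columns=["marker", "chromosome", "position", "criterion"]))

    def fit(idx_list):
        X = np.hstack([J] + [cand[i][3] for i in idx_list]) if idx_list else J
        Q = _orth(X)
        r = y - Q @ (Q.T @ y)
        rss = max(float(r @ r), _RSS_FLOOR)
        return Q, rss, Q.shape[1]

    selected: list[int] = []
    admit_val: dict[int, float] = {}
    Q, rss, k = fit(selected)
    ic = n * np.log(rss / n) + pen * k

    for _ in range(max_steps):
        changed = False
        # forward
        y_res = y - Q @ (Q.T @ y)
        rss_cur = max(float(y_res @ y_res), _RSS_FLOOR)
        best = None
        for i, (m, ch, pos, cols) in enumerate(cand):
            if i in selected:
                continue
            if any(cand[j][1] == ch and abs(cand[j][2] - pos) < min_sep_cM
                   for j in selected):
                continue
            U = _residual_basis(cols, Q)
            if U.shape[1] == 0:
                continue
            gain = float(np.sum((U.T @ y_res) ** 2))
            ic_new = n * np.log(max(rss_cur - gain, _RSS_FLOOR) / n) \
                + pen * (k + U.shape[1])
            if ic_new < ic - 1e-9 and (best is None or ic_new < best[0]):
                best = (ic_new, i, U)
        if best is not None:
            ic, i, U = best
            selected.append(i)
            admit_val[i] = ic
            Q = np.hstack([Q, U])
            k = Q.shape[1]
            changed = True
        # backward
        if len(selected) > 1:
            drop_best = None
            for i in selected:
                rest = [j for j in selected if j != i]
                _, rss_i, k_i = fit(rest)
                ic_i = n * np.log(rss_i / n) + pen * k_i
                if ic_i < ic - 1e-9 and (drop_best is None or ic_i < drop_best[0]):
                    drop_best = (ic_i, i)
            if drop_best is not None:
                ic, i = drop_best
                selected.remove(i)
                Q, rss, k = fit(selected)
                changed = True
        if not changed:
            break

    rows = [(cand[i][0], cand[i][1], cand[i][2], admit_val.get(i, np.nan))
            for i in selected]
    rows.sort(key=lambda r: (str(r[1]), r[2]))
    return CofactorSet(pd.DataFrame(
        rows, columns=["marker", "chromosome", "position", "criterion"]))


def genome_scan(blues_y, genotypes, linkage_map, families, cofactors=None,
                grid=None, step_cM=1.0, with_effects=True) -> ScanProfile:
    """LOD profile over the whole genome (see ScanEngine for the model)."""
    eng = ScanEngine(genotypes, linkage_map, families, cofactors=cofactors,
                     grid=grid, step_cM=step_cM)
    return eng.lod_profile(np.asarray(blues_y, dtype=float), with_effects=with_effects)


def _family_permutations(families, line_ids, n_perm, seed):
    """Index matrix (n, n_perm): each column permutes lines within family."""
    codes = families.codes_for(line_ids)
    rng = np.random.default_rng(seed)
    n = codes.size
    idx = np.tile(np.arange(n)[:, None], (1, n_perm))
    for f in range(codes.max() + 1):
        sel = np.flatnonzero(codes == f)
        for b in range(n_perm):
            idx[sel, b] = sel[rng.permutation(sel.size)]
    return idx


def permutation_threshold(blues_y, genotypes, linkage_map, families, n_perm,
                          alpha, seed, cofactors=None, grid=None, step_cM=1.0,
                          refit_cofactors=False, engine=None) -> float:
    """Genome-wide (1 - alpha) LOD threshold from within-family permutations.

    The entry means are permuted within each family so the family-mean
    structure is preserved under the null; the threshold is the empirical
    (1 - alpha) quantile of the per-permutation maximum LOD.  By default
    cofactors are held fixed across permutations; ``refit_cofactors``
    redoes the stepwise selection inside every permutation.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(blues_y, dtype=float)
    idx = _family_permutations(families, genotypes.line_ids, n_perm, seed)
    if refit_cofactors:
        maxl = np.empty(n_perm)
        for b in range(n_perm):
            yb = y[idx[:, b]]
            cof_b = select_cofactors(yb, genotypes, linkage_map, families)
            eng_b = ScanEngine(genotypes, linkage_map, families, cofactors=cof_b,
                               grid=grid, step_cM=step_cM)
            maxl[b] = eng_b.max_lod(yb)[0]
    else:
        eng = engine if engine is not None else ScanEngine(
            genotypes, linkage_map, families, cofactors=cofactors,
            grid=grid, step_cM=step_cM)
        maxl = eng.max_lod(y[idx])
    return float(np.quantile(maxl, 1.0 - alpha))


def call_qtl(profile: ScanProfile, threshold, merge_cM=10.0, drop=1.0):
    """Declare QTL from a scan profile.

    Local maxima exceeding the threshold are kept; peaks within
    ``merge_cM`` of each other on one chromosome are merged keeping the
    higher; the support interval is the contiguous region around the
    peak with LOD >= peak - ``drop``.
    """
    out = []
    tab = profile.table
    eff_cols = [c for c in tab.columns if c.startswith("effect_")]
    for chrom, grp in tab.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        lod = grp["lod"].to_numpy()
        m = lod.size
        peaks = [i for i in range(m)
                 if lod[i] > threshold
                 and (i == 0 or lod[i] >= lod[i - 1])
                 and (i == m - 1 or lod[i] > lod[i + 1])]
        peaks.sort(key=lambda i: -lod[i])
        kept = []
        for i in peaks:
            if all(abs(pos[i] - pos[j]) > merge_cM for j in kept):
                kept.append(i)
        for i in sorted(kept):
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - drop:
                lo -= 1
            hi = i
            while hi < m - 1 and lod[hi + 1] >= lod[i] - drop:
                hi += 1
            effects = {}
            if eff_cols:
                row = grp.iloc[i]
                effects = {c[len("effect_"):]: float(row[c]) for c in eff_cols}
            out.append(QTLResult(
                chromosome=chrom, position=float(pos[i]),
                support=(float(pos[lo]), float(pos[hi])),
                lod=float(lod[i]), effects=effects))
    return out


@dataclass
class FinalModel:
    """Simultaneous multi-QTL fit and its genotypic-variance accounting.

    ``total_p_g`` and the per-QTL values are percentages of the
    genotypic variance: adjusted R^2 (relative to the family-means-only
    baseline) divided by the entry-mean heritability.
    """

    positions: list            # [(chromosome, cM), ...]
    family_ids: list
    beta_families: np.ndarray  # (P,) family means
    coefs: list                # per QTL: (segregating family indices, coefficients)
    r2_adj: float
    total_p_g: float
    per_qtl_p_g: list
    h2: float

    def predict(self, genotypes, linkage_map, families) -> np.ndarray:
        """Genotypic score for new lines from the fitted family means and effects."""
        J = families.incidence(genotypes.line_ids)
        yhat = J @ self.beta_families
        for (chrom, pos), (fam_idx, coef) in zip(self.positions, self.coefs):
            blk = build_design_block((chrom, pos), genotypes, linkage_map, families)
            M = blk.matrix()
            for f, c in zip(fam_idx, coef):
                yhat += M[:, f] * c
        return yhat


def fit_final_model(blues_y, qtl_list, genotypes, linkage_map, families,
                    h2) -> FinalModel:
    """Fit all declared QTL jointly and apportion the genotypic variance.

    R^2 is measured against the family-means-only baseline; the adjusted
    value uses R^2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1) with p the
    number of QTL-effect parameters.  Per-QTL shares are drop-one
    differences of adjusted R^2, clipped at zero.
    """
    y = np.asarray(blues_y, dtype=float)
    n = y.size
    J = families.incidence(genotypes.line_ids)
    Q0 = _orth(J)
    r0 = y - Q0 @ (Q0.T @ y)
    rss0 = max(float(r0 @ r0), _RSS_FLOOR)

    blocks = [build_design_block((q.chromosome, q.position), genotypes,
                                 linkage_map, families) for q in qtl_list]
    cols = [b.columns() for b in blocks]

    def adj_r2(use):
        X = np.hstack([J] + [cols[i] for i in use]) if use else J
        Q = _orth(X)
        r = y - Q @ (Q.T @ y)
        rss = max(float(r @ r), _RSS_FLOOR)
        p = Q.shape[1] - Q0.shape[1]
        if n - p - 1 <= 0:
            raise ValueError("model saturated: too many QTL parameters")
        r2 = 1.0 - rss / rss0
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    all_idx = list(range(len(qtl_list)))
    r2a_full = adj_r2(all_idx) if all_idx else 0.0
    total_pg = 100.0 * r2a_full / h2
    per = []
    for i in all_idx:
        r2a_wo = adj_r2([j for j in all_idx if j != i])
        per.append(max(100.0 * (r2a_full - r2a_wo) / h2, 0.0))
    for q, pg in zip(qtl_list, per):
        q.p_g = pg

    # coefficients of the full fit, for prediction
    X = np.hstack([J] + cols) if cols else J
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefs = []
    off = J.shape[1]
    for b, c in zip(blocks, cols):
        k = c.shape[1]
        coefs.append((np.flatnonzero(b.segregating), beta[off:off + k].copy()))
        off += k
    return FinalModel(
        positions=[(q.chromosome, q.position) for q in qtl_list],
        family_ids=list(families.family_ids),
        beta_families=beta[: J.shape[1]].copy(),
        coefs=coefs, r2_adj=r2a_full, total_p_g=total_pg,
        per_qtl_p_g=per, h2=h2,
    )


@dataclass
class StageMatch:
    """Clusters of QTL matched across stages plus Venn counts and p_G paths."""

    clusters: list        # per cluster: dict stage -> [QTLResult]
    venn: dict            # tuple(sorted stage names) -> count
    p_g: pd.DataFrame     # clusters x stages, % genotypic variance (0 when absent)


def match_qtl_across_stages(stage_qtl: dict, window_cM=10.0) -> StageMatch:
    """Link QTL from different stages within ``window_cM`` on one chromosome.

    Linking is transitive (single-linkage clusters); the boundary is
    inclusive, so peaks exactly ``window_cM`` apart are linked and peaks
    farther apart (e.g. 10 vs 21 cM with a 10 cM window) are not.
    """
    stages = list(stage_qtl)
    nodes = [(s, i) for s in stages for i in range(len(stage_qtl[s]))]
    parent = {u: u for u in nodes}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u, v):
        parent[find(u)] = find(v)

    for a in range(len(nodes)):
        sa, ia = nodes[a]
        qa = stage_qtl[sa][ia]
        for b in range(a + 1, len(nodes)):
            sb, ib = nodes[b]
            if sa == sb:
                continue
            qb = stage_qtl[sb][ib]
            if qa.chromosome == qb.chromosome and \
                    abs(qa.position - qb.position) <= window_cM + 1e-9:
                union(nodes[a], nodes[b])

    groups = {}
    for u in nodes:
        groups.setdefault(find(u), []).append(u)
    clusters, venn, labels, pg_rows = [], {}, [], []
    for members in groups.values():
        cl = {}
        for s, i in members:
            cl.setdefault(s, []).append(stage_qtl[s][i])
        clusters.append(cl)
        key = tuple(sorted(cl, key=stages.index))
        venn[key] = venn.get(key, 0) + 1
        any_q = next(iter(cl.values()))[0]
        mean_pos = np.mean([q.position for qs in cl.values() for q in qs])
        labels.append(f"{any_q.chromosome}@{mean_pos:.1f}")
        pg_rows.append([
            float(np.nansum([q.p_g for q in cl.get(s, [])])) if s in cl else 0.0
            for s in stages
        ])
    pg = pd.DataFrame(pg_rows, index=labels, columns=stages)
    order = np.argsort(labels)
    clusters = [clusters[i] for i in order]
    pg = pg.iloc[order]
    return StageMatch(clusters=clusters, venn=venn, p_g=pg)
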