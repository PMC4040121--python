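"""Two-dimensional genome scan for pairwise epistatic QTL.

The additive scan model is extended with a second locus and their
interaction: Y = J M + X_q B_q + X_q' B_q' + X_qq' B_qq' + eps, where
the interaction block uses centred main-effect codes, per family
(X_q - 1) elementwise-times (X_q' - 1), so that in a balanced DH family
the interaction column is orthogonal in expectation to both main-effect
columns and the interaction estimate is decoupled from the main effects.
The interaction is judged by a likelihood-ratio test against the model
with both main effects but no interaction, with degrees of freedom equal
to the number of families segregating at both loci.

Genome-wide multiplicity follows the region-count argument: assuming two
independently segregating regions per linkage group, the per-test
alpha is alpha / C(2L, 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .linkage import build_design_block, build_scan_grid
from .mcqtl import _orth, _residual_basis, _RSS_FLOOR

__all__ = [
    "EpistasisResult", "interaction_test", "epistasis_threshold",
    "epistasis_scan",
]


@dataclass
class EpistasisResult:
    locus1: tuple          # (chromosome, cM)
    locus2: tuple
    lr: float
    p_value: float
    df: int
    effects: dict          # family id -> interaction effect (NaN if untestable)
    p_g: float = float("nan")   # % genotypic variance of the interaction term

    def __post_init__(self):
        # canonical unordered pair
        if (str(self.locus1[0]), self.locus1[1]) > (str(self.locus2[0]), self.locus2[1]):
            self.locus1, self.locus2 = self.locus2, self.locus1


def _interaction_columns(block_q, block_q2):
    """Per-family products of centred expected counts; families segregating
    at both loci only.  Returns (columns, family indices)."""
    both = block_q.segregating & block_q2.segregating
    fams = np.flatnonzero(both)
    z1 = block_q.counts - 1.0
    z2 = block_q2.counts - 1.0
    cols = np.zeros((z1.size, fams.size))
    for j, f in enumerate(fams):
        sel = block_q.family_codes == f
        cols[sel, j] = z1[sel] * z2[sel]
    return cols, fams


def interaction_test(blues_y, block_q, block_q2, J, family_ids,
                     cofactor_columns=(), h2=None, rss_baseline=None):
    """LR test of the interaction between two loci, given both main effects.

    ``cofactor_columns`` must already exclude cofactors within 10 cM of
    either locus.  Returns an EpistasisResult; when no family segregates
    at both loci the pair is untestable (df 0, p-value 1).
    """
    y = np.asarray(blues_y, dtype=float)
    y = y - y.mean()  # numerical guard; the intercept lies in col(J)
    n = y.size
    int_cols, fams = _interaction_columns(block_q, block_q2)
    parts = [J, block_q.columns(), block_q2.columns()] + \
        [c for c in cofactor_columns if c.size]
    X_red = np.hstack([p for p in parts if p.size])
    Q_red = _orth(X_red)
    effects = np.full(len(family_ids), np.nan)
    loc1 = (block_q.chromosome, block_q.position)
    loc2 = (block_q2.chromosome, block_q2.position)
    if fams.size == 0:
        return EpistasisResult(loc1, loc2, 0.0, 1.0, 0,
                               dict(zip(family_ids, effects)))
    U = _residual_basis(int_cols, Q_red)
    df = U.shape[1]
    yty = float(y @ y)
    a_r = Q_red.T @ y
    rss_r = max(yty - float(a_r @ a_r), _RSS_FLOOR * max(yty, 1.0))
    a_u = U.T @ y
    rss_f = max(rss_r - float(a_u @ a_u), _RSS_FLOOR * max(yty, 1.0))
    lr = max(n * np.log(rss_r / rss_f), 0.0)
    p = float(chi2.sf(lr, df)) if df > 0 else 1.0
    # interaction coefficients after adjusting for the reduced model
    y_res = y - Q_red @ a_r
    C_res = int_cols - Q_red @ (Q_red.T @ int_cols)
    coef, *_ = np.linalg.lstsq(C_res, y_res, rcond=None)
    effects[fams] = coef
    res = EpistasisResult(loc1, loc2, lr, max(p, np.finfo(float).tiny), df,
                          dict(zip(family_ids, effects)))
    if h2 is not None and rss_baseline is not None and df > 0:
        p_red = Q_red.shape[1] - np.linalg.matrix_rank(J)
        r2a_red = _adj_r2(rss_r, rss_baseline, n, p_red)
        r2a_full = _adj_r2(rss_f, rss_baseline, n, p_red + df)
        res.p_g = max(100.0 * (r2a_full - r2a_red) / h2, 0.0)
    return res


def _adj_r2(rss, rss0, n, p):
    r2 = 1.0 - rss / rss0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def epistasis_threshold(n_linkage_groups, alpha=0.05) -> float:
    """Per-test p-value threshold: alpha / C(2L, 2) region pairs."""
    if n_linkage_groups < 1:
        raise ValueError("need at least one linkage group")
    n_tests = max(comb(2 * n_linkage_groups, 2), 1)
    return alpha / n_tests


def epistasis_scan(blues_y, genotypes, linkage_map, families, h2,
                   grid_step_cM=5.0, threshold=None, alpha=0.05,
                   cofactors=None, min_same_chrom_cM=30.0, merge_cM=10.0,
                   marker_only=False):
    """Scan all admissible locus pairs for significant interactions.

    Pairs lie on different chromosomes, or at least ``min_same_chrom_cM``
    apart on the same one (closer pairs have collinear expected counts).
    Significant pairs are reduced to local 2-D maxima: pairs within
    ``merge_cM`` in both coordinates keep only the smallest p-value.
    Returns the surviving EpistasisResult list sorted by p-value.
    """
    y = np.asarray(blues_y, dtype=float)
    n = y.size
    J = families.incidence(genotypes.line_ids)
    if threshold is None:
        threshold = epistasis_threshold(len(linkage_map.chromosomes), alpha)
    if marker_only:
        tab = linkage_map.table
        positions = list(zip(tab["chromosome"], tab["position"]))
    else:
        positions = list(build_scan_grid(linkage_map, grid_step_cM))
    blocks = [build_design_block(p, genotypes, linkage_map, families)
              for p in positions]

    Q0 = _orth(J)
    r0 = y - Q0 @ (Q0.T @ y)
    rss0 = max(float(r0 @ r0), _RSS_FLOOR)

    cof = []
    if cofactors is not None and len(cofactors):
        for _, row in cofactors.table.iterrows():
            blk = build_design_block((row["chromosome"], row["position"]),
                                     genotypes, linkage_map, families)
            cof.append((row["chromosome"], row["position"], blk.columns()))

    hits = []
    m = len(blocks)
    for i in range(m):
        bi = blocks[i]
        if not bi.segregating.any():
            continue
        for j in range(i + 1, m):
            bj = blocks[j]
            if bi.chromosome == bj.chromosome and \
                    abs(bi.position - bj.position) < min_same_chrom_cM:
                continue
            if not (bi.segregating & bj.segregating).any():
                continue
            cof_cols = [c for ch, p, c in cof
                        if not (ch == bi.chromosome and abs(p - bi.position) < 10.0)
                        and not (ch == bj.chromosome and abs(p - bj.position) < 10.0)]
            res = interaction_test(y, bi, bj, J, families.family_ids,
                                   cofactor_columns=cof_cols, h2=h2,
                                   rss_baseline=rss0)
            if res.df > 0 and res.p_value < threshold:
                hits.append(res)

    # keep 2-D local maxima: merge pairs close in both coordinates
    hits.sort(key=lambda r: r.p_value)
    kept = []
    for r in hits:
        merged = False
        for k in kept:
            same = (r.locus1[0] == k.locus1[0] and r.locus2[0] == k.locus2[0]
                    and abs(r.locus1[1] - k.locus1[1]) <= merge_cM
                    and abs(r.locus2[1] - k.locus2[1]) <= merge_cM)
            swapped = (r.locus1[0] == k.locus2[0] and r.locus2[0] == k.locus1[0]
                       and abs(r.locus1[1] - k.locus2[1]) <= merge_cM
                       and abs(r.locus2[1] - k.locus1[1]) <= merge_cM)
            if same or swapped:
                merged = True
                break
        if not merged:
            kept.append(r)
    return kept


def pairs_table(results) -> pd.DataFrame:
    """Flat table of significant pairs (chord-plot friendly: positions + weight)."""
    rows = [
        (r.locus1[0], r.locus1[1], r.locus2[0], r.locus2[1], r.lr, r.p_value,
         r.df, r.p_g)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "chromosome1", "position1", "chromosome2", "position2",
        "lr", "p_value", "df", "p_g"])
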