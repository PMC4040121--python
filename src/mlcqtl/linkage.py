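"""Genetic-map mathematics for doubled-haploid (DH) populations.

Provides mapping functions (Haldane, Kosambi), conditional expected
reference-allele counts at arbitrary genome positions given flanking
marker genotypes, and construction of the family-structured design
blocks used by the multi-family QTL scan.

A DH line carries two identical copies of a single recombinant gamete,
so marker genotypes are coded as 0 or 2 copies of a per-marker reference
allele and the latent genotype at an untyped position is fully described
by the probability that the gamete carries the reference allele there.
Conditioning uses the two nearest informative flanking markers and
assumes no crossover interference (Haldane), so recombination events in
the two flanking intervals are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "haldane",
    "inverse_haldane",
    "kosambi",
    "expected_allele_count",
    "DesignBlock",
    "build_design_block",
    "ScanGrid",
    "build_scan_grid",
]


def haldane(d):
    """Map distance in cM -> recombination fraction, no interference.

    r = (1 - exp(-2d/100)) / 2
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def inverse_haldane(r):
    """Recombination fraction -> cM under the Haldane map function."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return d if d.ndim else float(d)


def kosambi(d):
    """Kosambi map function (interference-aware), cM -> recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return r if r.ndim else float(r)


def _check_r(r, name):
    if not (0.0 <= r < 0.5):
        raise ValueError(f"{name} must lie in [0, 0.5), got {r}")


def expected_allele_count(left_code, right_code, r1, r2, fallback_freq=0.5):
    """Expected number of reference alleles (0..2) at a position in a DH line.

    Parameters
    ----------
    left_code, right_code
        Observed codes (0, 2 or NaN) at the nearest informative flanking
        markers.  NaN means no informative flank on that side.
    r1, r2
        Recombination fractions between the position and the left /
        right flank respectively.
    fallback_freq
        Reference-allele frequency used when both flanks are missing
        (e.g. the within-family frequency at the nearest typed marker).

    Returns
    -------
    float in [0, 2]: ``2 * P(gamete carries reference allele | flanks)``.
    """
    _check_r(r1, "r1")
    _check_r(r2, "r2")
    left_missing = left_code is None or (isinstance(left_code, float) and np.isnan(left_code))
    right_missing = right_code is None or (isinstance(right_code, float) and np.isnan(right_code))
    if left_missing and right_missing:
        return 2.0 * float(fallback_freq)
    if left_missing:
        p = (1.0 - r2) if right_code == 2 else r2
        return 2.0 * p
    if right_missing:
        p = (1.0 - r1) if left_code == 2 else r1
        return 2.0 * p
    # both flanks observed; r12 = chance the two flanks are recombinant
    r12 = r1 + r2 - 2.0 * r1 * r2
    if left_code == 2 and right_code == 2:
        p = (1.0 - r1) * (1.0 - r2) / (1.0 - r12)
    elif left_code == 0 and right_code == 0:
        p = r1 * r2 / (1.0 - r12)
    else:
        if r12 == 0.0:  # inconsistent flanks at zero distance; uninformative
            return 1.0
        if left_code == 2:  # reference on the left, alternative on the right
            p = (1.0 - r1) * r2 / r12
        else:
            p = r1 * (1.0 - r2) / r12
    return 2.0 * p


def _expected_counts_grouped(left, right, r1, r2):
    """Vectorised expected counts for lines sharing the same flank distances.

    ``left``/``right`` are arrays of observed codes (no NaN here).
    """
    r12 = r1 + r2 - 2.0 * r1 * r2
    out = np.empty(left.shape, dtype=float)
    both_ref = (left == 2) & (right == 2)
    both_alt = (left == 0) & (right == 0)
    disc_l = (left == 2) & (right == 0)
    disc_r = (left == 0) & (right == 2)
    out[both_ref] = 2.0 * (1.0 - r1) * (1.0 - r2) / (1.0 - r12)
    out[both_alt] = 2.0 * r1 * r2 / (1.0 - r12)
    if r12 == 0.0:
        out[disc_l | disc_r] = 1.0
    else:
        out[disc_l] = 2.0 * (1.0 - r1) * r2 / r12
        out[disc_r] = 2.0 * r1 * (1.0 - r2) / r12
    return out


@dataclass
class DesignBlock:
    """Expected reference-allele counts at one genome position, by family.

    Conceptually an N x P matrix (lines x families) with the line's
    expected count in its own family's column and zeros elsewhere; stored
    compactly as the count vector plus family codes.  Families whose
    parents do not segregate at the position carry no information and
    are flagged so the scan can drop their columns.
    """

    chromosome: str
    position: float
    counts: np.ndarray          # (N,) expected counts in [0, 2]
    family_codes: np.ndarray    # (N,) integer family index
    family_ids: list            # family labels, order defines columns
    segregating: np.ndarray     # (P,) bool

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def matrix(self) -> np.ndarray:
        """Dense N x P design matrix (all families)."""
        out = np.zeros((self.counts.size, self.n_families))
        out[np.arange(self.counts.size), self.family_codes] = self.counts
        return out

    def columns(self, center: bool = False) -> np.ndarray:
        """N x k matrix keeping only segregating families' columns.

        With ``center=True`` the counts are shifted by -1 so that the two
        homozygous classes sit at -1/+1; used for epistatic interaction
        coding.
        """
        keep = np.flatnonzero(self.segregating)
        vals = self.counts - 1.0 if center else self.counts
        out = np.zeros((self.counts.size, keep.size))
        for j, f in enumerate(keep):
            sel = self.family_codes == f
            out[sel, j] = vals[sel]
        return out


def build_design_block(position, genotypes, linkage_map, families) -> DesignBlock:
    """Expected allele counts for every line at ``position`` = (chromosome, cM).

    At a typed marker the observed code is used directly.  Elsewhere the
    count is the conditional expectation given the nearest non-missing
    flanking markers of the line (walking outwards past missing calls,
    accumulating Haldane distance).  A line with no informative flank on
    either side falls back to twice the within-family reference-allele
    frequency at the nearest marker.
    """
    chrom, pos = position
    tab = linkage_map.table
    on_chrom = np.flatnonzero((tab["chromosome"] == chrom).to_numpy())
    if on_chrom.size == 0:
        raise ValueError(f"chromosome {chrom!r} not on map")
    mpos = tab["position"].to_numpy()[on_chrom]
    if pos < mpos[0] - 1e-9 or pos > mpos[-1] + 1e-9:
        raise ValueError(f"position {pos} off chromosome {chrom} [{mpos[0]}, {mpos[-1]}]")

    G = genotypes.values  # (N, M) float with NaN for missing
    n = G.shape[0]
    fam_codes = families.codes_for(genotypes.line_ids)
    fam_ids = families.family_ids
    counts = np.empty(n, dtype=float)

    # exact marker hit
    hit = np.flatnonzero(np.abs(mpos - pos) <= 1e-6)
    exact_col = on_chrom[hit[0]] if hit.size else None

    left_local = int(np.searchsorted(mpos, pos + 1e-9) - 1)   # last marker <= pos
    right_local = int(np.searchsorted(mpos, pos - 1e-9))      # first marker >= pos

    # family reference-allele frequency at the nearest marker (fallback)
    nearest_local = left_local if (left_local >= 0 and (right_local >= mpos.size or pos - mpos[left_local] <= mpos[min(right_local, mpos.size - 1)] - pos)) else min(right_local, mpos.size - 1)
    nearest_col = on_chrom[max(nearest_local, 0)]
    fam_freq = np.full(len(fam_ids), 0.5)
    col = G[:, nearest_col]
    for f in range(len(fam_ids)):
        v = col[fam_codes == f]
        v = v[~np.isnan(v)]
        if v.size:
            fam_freq[f] = float(np.mean(v)) / 2.0

    filled = np.zeros(n, dtype=bool)
    if exact_col is not None:
        obs = G[:, exact_col]
        ok = ~np.isnan(obs)
        counts[ok] = obs[ok]
        filled |= ok

    todo = np.flatnonzero(~filled)
    if todo.size:
        # per line: nearest non-missing flank index on each side
        lidx = np.full(n, -1, dtype=int)
        ridx = np.full(n, -1, dtype=int)
        scan_left = left_local if exact_col is None else left_local - 1
        scan_right = right_local if exact_col is None else right_local + 1
        fast = (
            scan_left >= 0 and scan_right < mpos.size
            and not np.isnan(G[todo, on_chrom[scan_left]]).any()
            and not np.isnan(G[todo, on_chrom[scan_right]]).any()
        )
        if fast:  # complete flanking data: one flank pair for every line
            lidx[todo] = scan_left
            ridx[todo] = scan_right
        else:
            for i in todo:
                j = scan_left
                while j >= 0 and np.isnan(G[i, on_chrom[j]]):
                    j -= 1
                lidx[i] = j
                j = scan_right
                while j < mpos.size and np.isnan(G[i, on_chrom[j]]):
                    j += 1
                ridx[i] = j if j < mpos.size else -1
        # group lines by (left, right) flank pair for vectorised evaluation
        key = lidx[todo] * (mpos.size + 1) + ridx[todo]
        for k in np.unique(key):
            sel = todo[key == k]
            li, ri = lidx[sel[0]], ridx[sel[0]]
            if li < 0 and ri < 0:
                counts[sel] = 2.0 * fam_freq[fam_codes[sel]]
            elif li < 0:
                r2 = haldane(mpos[ri] - pos)
                obs = G[sel, on_chrom[ri]]
                counts[sel] = np.where(obs == 2, 2.0 * (1.0 - r2), 2.0 * r2)
            elif ri < 0:
                r1 = haldane(pos - mpos[li])
                obs = G[sel, on_chrom[li]]
                counts[sel] = np.where(obs == 2, 2.0 * (1.0 - r1), 2.0 * r1)
            else:
                r1 = haldane(pos - mpos[li])
                r2 = haldane(mpos[ri] - pos)
                counts[sel] = _expected_counts_grouped(
                    G[sel, on_chrom[li]], G[sel, on_chrom[ri]], r1, r2
                )

    seg = np.zeros(len(fam_ids), dtype=bool)
    for f in range(len(fam_ids)):
        v = counts[fam_codes == f]
        if v.size and (np.nanmax(v) - np.nanmin(v)) > 1e-9:
            seg[f] = True
    return DesignBlock(
        chromosome=chrom, position=float(pos), counts=counts,
        family_codes=fam_codes, family_ids=list(fam_ids), segregating=seg,
    )


@dataclass
class ScanGrid:
    """Ordered genome-scan evaluation positions."""

    chromosomes: np.ndarray  # (K,) object
    positions: np.ndarray    # (K,) float, cM

    def __len__(self) -> int:
        return self.positions.size

    def __iter__(self):
        return iter(zip(self.chromosomes, self.positions))


def build_scan_grid(linkage_map, step_cM: float = 1.0) -> ScanGrid:
    """Union of marker positions and a ``step_cM`` lattice per chromosome.

    Positions closer than 1e-6 cM are merged; every marker position is
    always included.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be > 0")
    chroms, poss = [], []
    tab = linkage_map.table
    for chrom in linkage_map.chromosomes:
        mp = tab.loc[tab["chromosome"] == chrom, "position"].to_numpy()
        lattice = np.arange(mp[0], mp[-1] + 1e-9, step_cM)
        allp = np.sort(np.concatenate([mp, lattice]))
        keep = np.concatenate([[True], np.diff(allp) > 1e-6])
        allp = allp[keep]
        chroms.extend([chrom] * allp.size)
        poss.append(allp)
    return ScanGrid(np.array(chroms, dtype=object), np.concatenate(poss))


def orth_basis(X: np.ndarray, rcond: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    return scipy.linalg.orth(X, rcond=rcond)
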