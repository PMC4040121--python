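"""Synthetic multi-family doubled-haploid mapping populations.

Emulates the study design the pipeline targets: several connected
biparental DH families genotyped on a shared consensus map, a
stage-indexed QTL architecture (shared, stage-specific and epistatic
loci), and multi-environment field trials laid out as partially
replicated designs with common checks.  Every downstream stage of the
pipeline can therefore be tested against known truth.

DH meiosis is modelled as a single recombinant F1 gamete, doubled:
crossovers fall independently in each inter-marker interval with the
Haldane probability r = (1 - exp(-2d/100)) / 2 (Kosambi available as an
option for genotype generation).  Genotypes are coded as 0/2 copies of a
per-marker reference allele, the allele carried by the globally
designated reference parent (the first parent of the first family).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .iomodel import (
    LinkageMap, GenotypeMatrix, FamilyAssignment, PlotTable, BlueTable,
)
from .linkage import haldane, kosambi

__all__ = [
    "FamilySpec", "TrueQTL", "EpistaticPair", "SimConfig", "Dataset",
    "make_consensus_map", "simulate_dh_family", "genetic_values",
    "realized_locus",
    "simulate_field_trial", "simulate_dataset", "simulate_entry_means",
    "default_config", "standard_truth", "write_dataset",
]

DEFAULT_STAGE_MEANS = (62.8, 105.7, 102.9)  # cm, awns-visible / flowering / early dough


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class FamilySpec:
    family: str
    size: int
    parent1: str
    parent2: str


@dataclass
class TrueQTL:
    """A simulated additive locus with family- and stage-specific effects.

    ``effects[f, s]`` is the allele-substitution effect (trait units per
    reference-allele copy) of the locus in family ``f`` at stage ``s``.
    A family whose parents carry the same allele at the locus must have
    effect 0 at all stages (enforced by the generator, which forces the
    founder alleles to match the zero/non-zero pattern of each row).
    """

    chromosome: str
    position: float
    effects: np.ndarray  # (n_families, n_stages)

    def __post_init__(self):
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))


@dataclass
class EpistaticPair:
    """Two loci with family/stage-specific interaction effects (product of +-1 codes)."""

    chromosome1: str
    position1: float
    chromosome2: str
    position2: float
    effects: np.ndarray  # (n_families, n_stages)

    def __post_init__(self):
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))


@dataclass
class SimConfig:
    chromosome_spec: list            # [(label, length_cM), ...]
    marker_spacing: float
    family_spec: list                # [FamilySpec, ...]
    true_qtl: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)
    n_environments: int = 4
    plots_per_environment: int = 960
    check_fraction: float = 0.03
    n_checks: int = 3
    sigma_gxe: float = 12.0          # trait-units^2, scale of the field trials
    sigma_e: float = 6.0
    sigma_env: float = 25.0
    stage_count: int = 3
    stage_means: tuple = DEFAULT_STAGE_MEANS
    missing_rate: float = 0.0
    mapping_function: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        if not self.chromosome_spec:
            raise ConfigError("chromosome_spec is empty")
        if self.marker_spacing <= 0:
            raise ConfigError("marker_spacing must be > 0")
        lengths = dict(self.chromosome_spec)
        if any(l <= 0 for l in lengths.values()):
            raise ConfigError("chromosome lengths must be > 0")
        for fs in self.family_spec:
            if fs.size < 1:
                raise ConfigError(f"family {fs.family!r} has size < 1")
        for q in self.true_qtl:
            if q.chromosome not in lengths:
                raise ConfigError(f"QTL on undeclared chromosome {q.chromosome!r}")
            if not (0 <= q.position <= lengths[q.chromosome]):
                raise ConfigError(f"QTL position {q.position} off chromosome {q.chromosome}")
            if q.effects.shape != (len(self.family_spec), self.stage_count):
                raise ConfigError("QTL effects matrix must be families x stages")
        for pr in self.epistatic_pairs:
            for c, p in ((pr.chromosome1, pr.position1), (pr.chromosome2, pr.position2)):
                if c not in lengths or not (0 <= p <= lengths[c]):
                    raise ConfigError(f"epistatic locus ({c}, {p}) off map")
            if pr.effects.shape != (len(self.family_spec), self.stage_count):
                raise ConfigError("interaction effects matrix must be families x stages")
        if min(self.sigma_gxe, self.sigma_e, self.sigma_env) < 0:
            raise ConfigError("variance components must be >= 0")
        if len(self.stage_means) < self.stage_count:
            raise ConfigError("stage_means shorter than stage_count")

    @property
    def stage_names(self) -> list:
        return [f"PH{s + 1}" for s in range(self.stage_count)]


def make_consensus_map(chromosome_spec, marker_spacing, seed=0, jitter=0.0) -> LinkageMap:
    """Evenly spaced markers per chromosome, first at 0 cM, last at the length.

    ``jitter`` (fraction of the spacing, < 0.5) perturbs interior marker
    positions while keeping them strictly increasing.
    """
    if marker_spacing <= 0:
        raise ConfigError("marker_spacing must be > 0")
    if not chromosome_spec:
        raise ConfigError("chromosome_spec is empty")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chromosome_spec:
        pos = np.arange(0.0, length + 1e-9, marker_spacing)
        if pos[-1] < length - 1e-9:
            pos = np.append(pos, length)
        pos = pos.copy()
        if jitter > 0 and pos.size > 2:
            pos[1:-1] += rng.uniform(-jitter, jitter, pos.size - 2) * marker_spacing
            pos[1:-1] = np.sort(pos[1:-1])
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_m{i:03d}", chrom, round(float(p), 6)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position"]))


def _map_function(name):
    if name == "haldane":
        return haldane
    if name == "kosambi":
        return kosambi
    raise ConfigError(f"unknown mapping function {name!r}")


def simulate_dh_family(linkage_map, parent1_haplo, parent2_haplo, n_lines, seed,
                       ref_alleles=None, line_prefix="L", mapping_function="haldane"
                       ) -> GenotypeMatrix:
    """Generate DH lines from the cross of two founder haplotypes.

    Each line is one recombinant F1 gamete, doubled.  Crossovers per
    inter-marker interval are independent with the chosen map-function
    probability.  Genotypes are coded 0/2 copies of the reference allele
    (``ref_alleles``, defaulting to parent 1's haplotype).
    """
    if n_lines < 1:
        raise ConfigError("n_lines must be >= 1")
    h1 = np.asarray(parent1_haplo)
    h2 = np.asarray(parent2_haplo)
    m = linkage_map.n_markers
    if h1.size != m or h2.size != m:
        raise ConfigError("founder haplotypes must cover all markers")
    ref = h1 if ref_alleles is None else np.asarray(ref_alleles)
    mapfun = _map_function(mapping_function)
    rng = np.random.default_rng(seed)

    tab = linkage_map.table
    gamete = np.empty((n_lines, m), dtype=h1.dtype)
    for chrom in linkage_map.chromosomes:
        idx = np.flatnonzero((tab["chromosome"] == chrom).to_numpy())
        pos = tab["position"].to_numpy()[idx]
        k = idx.size
        r = mapfun(np.diff(pos)) if k > 1 else np.empty(0)
        start = rng.random(n_lines) < 0.5
        rec = rng.random((n_lines, k - 1)) < r
        phase = np.empty((n_lines, k), dtype=bool)
        phase[:, 0] = start
        if k > 1:
            phase[:, 1:] = np.logical_xor.accumulate(rec, axis=1) ^ start[:, None]
        gamete[:, idx] = np.where(phase, h2[idx], h1[idx])
    codes = 2.0 * (gamete == ref)
    lines = [f"{line_prefix}{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(pd.DataFrame(codes, index=lines, columns=linkage_map.markers))


def _nearest_marker_index(linkage_map, chrom, pos):
    tab = linkage_map.table
    idx = np.flatnonzero((tab["chromosome"] == chrom).to_numpy())
    if idx.size == 0:
        raise ConfigError(f"chromosome {chrom!r} not on map")
    mpos = tab["position"].to_numpy()[idx]
    return int(idx[np.argmin(np.abs(mpos - pos))])


def realized_locus(linkage_map, chromosome, position):
    """Where a configured truth locus actually sits: its nearest marker.

    ``genetic_values`` assigns every truth locus the genotype of the
    nearest simulated marker, so oracles measuring detection distance
    should use this position, not the nominal one.
    """
    j = _nearest_marker_index(linkage_map, chromosome, position)
    row = linkage_map.table.iloc[j]
    return row["chromosome"], float(row["position"])


def genetic_values(genotypes, family_assignment, true_qtl, epistatic_pairs, stage,
                   linkage_map) -> np.ndarray:
    """Genotypic value of every line at one stage.

    g_i = sum_q a[fam(i), stage] * z_iq + sum_pairs w[fam(i), stage] * z_iq * z_iq'
    with z = genotype code - 1 in {-1, +1}; each locus takes the genotype
    of its nearest simulated marker.
    """
    n_stages = true_qtl[0].effects.shape[1] if true_qtl else (
        epistatic_pairs[0].effects.shape[1] if epistatic_pairs else stage + 1)
    if not (0 <= stage < n_stages):
        raise IndexError(f"stage {stage} out of range [0, {n_stages})")
    G = genotypes.values
    fam = family_assignment.codes_for(genotypes.line_ids)
    g = np.zeros(G.shape[0])
    for q in true_qtl:
        j = _nearest_marker_index(linkage_map, q.chromosome, q.position)
        z = np.nan_to_num(G[:, j] - 1.0)
        g += q.effects[fam, stage] * z
    for pr in epistatic_pairs:
        j1 = _nearest_marker_index(linkage_map, pr.chromosome1, pr.position1)
        j2 = _nearest_marker_index(linkage_map, pr.chromosome2, pr.position2)
        z1 = np.nan_to_num(G[:, j1] - 1.0)
        z2 = np.nan_to_num(G[:, j2] - 1.0)
        g += pr.effects[fam, stage] * z1 * z2
    return g


def simulate_field_trial(genetic_by_stage, config: SimConfig, seed,
                         line_ids=None) -> PlotTable:
    """Multi-environment partially replicated trial around given genotypic values.

    Each plot value is y = mu_s + g_is + u_e + (gu)_ies + eps, with fixed
    (centred) environment offsets u_e, independent Gaussian G-by-E and
    plot errors.  Checks are replicated in every environment; a rotating
    subset of entries receives a second plot per environment so the mean
    replication lands between 1 and 2.
    """
    g = np.atleast_2d(np.asarray(genetic_by_stage, dtype=float))
    if g.shape[0] == config.stage_count and g.shape[1] != config.stage_count:
        g = g.T  # accept stages x lines too
    n, n_stages = g.shape
    if n_stages != config.stage_count:
        raise ConfigError("genetic values must have one column per stage")
    if line_ids is None:
        line_ids = [f"L{i + 1:04d}" for i in range(n)]
    E, P = config.n_environments, config.plots_per_environment
    if P < n:
        raise ConfigError(f"plots_per_environment ({P}) smaller than entry count ({n})")
    rng = np.random.default_rng(seed)

    n_check_plots = min(int(round(config.check_fraction * P)), P - n)
    n_checks = config.n_checks if n_check_plots >= config.n_checks else 0
    g_sd = max(float(np.std(g)), 1.0)
    check_g = rng.normal(0.0, g_sd, size=(n_checks, n_stages))
    check_ids = [f"CHK{i + 1}" for i in range(n_checks)]

    n_extra = P - n - (n_check_plots if n_checks else 0)
    perm = rng.permutation(n)

    u = rng.normal(0.0, np.sqrt(config.sigma_env), size=E)
    u -= u.mean()
    mu = np.asarray(config.stage_means[:n_stages], dtype=float)

    all_ids = list(line_ids) + check_ids
    all_g = np.vstack([g, check_g]) if n_checks else g
    gxe = rng.normal(0.0, np.sqrt(config.sigma_gxe), size=(len(all_ids), E, n_stages))

    rows, values = [], []
    for e in range(E):
        env = f"E{e + 1}"
        # one plot for every entry
        reps = {i: 1 for i in range(n)}
        plots = [(i, 1) for i in range(n)]
        # second plots for a rotating subset (partial replication)
        for k in range(n_extra):
            i = int(perm[(e * n_extra + k) % n])
            reps[i] = reps.get(i, 1) + 1
            plots.append((i, reps[i]))
        # check plots, evenly split
        for c in range(n_checks):
            share = n_check_plots // n_checks + (1 if c < n_check_plots % n_checks else 0)
            for rep in range(1, share + 1):
                plots.append((n + c, rep))
        for i, rep in plots:
            eps = rng.normal(0.0, np.sqrt(config.sigma_e), size=n_stages)
            y = mu + all_g[i] + u[e] + gxe[i, e] + eps
            rows.append((all_ids[i], i >= n, env, rep))
            values.append(y)
    frame = pd.DataFrame(rows, columns=["entry", "is_check", "environment", "replicate"])
    vals = pd.DataFrame(np.asarray(values), columns=config.stage_names)
    return PlotTable(pd.concat([frame, vals], axis=1))


def _force_founder_alleles(haplos, linkage_map, config):
    """Pin founder alleles near each true locus to its segregation pattern.

    For every QTL (and epistatic locus) and family: parents must differ
    at the nearest marker iff the family has a non-zero effect there.
    Raises on contradictory requirements between families sharing parents.
    """
    forced = {}  # (parent, marker_index) -> allele

    def _set(parent, j, allele):
        key = (parent, j)
        if key in forced and forced[key] != allele:
            raise ConfigError(
                f"conflicting founder-allele requirements for parent {parent!r} "
                f"at marker index {j}"
            )
        forced[key] = allele
        haplos[parent][j] = allele

    loci = [(q.chromosome, q.position, q.effects) for q in config.true_qtl]
    for pr in config.epistatic_pairs:
        loci.append((pr.chromosome1, pr.position1, pr.effects))
        loci.append((pr.chromosome2, pr.position2, pr.effects))
    for chrom, pos, eff in loci:
        j = _nearest_marker_index(linkage_map, chrom, pos)
        for f, fs in enumerate(config.family_spec):
            segregates = bool(np.any(eff[f] != 0.0))
            p1, p2 = fs.parent1, fs.parent2
            a1 = forced.get((p1, j))
            a2 = forced.get((p2, j))
            if segregates:
                if a1 is None and a2 is None:
                    _set(p1, j, 1), _set(p2, j, 0)
                elif a1 is None:
                    _set(p1, j, 1 - a2)
                elif a2 is None:
                    _set(p2, j, 1 - a1)
                elif a1 == a2:
                    raise ConfigError(
                        f"family {fs.family!r} requires segregation at ({chrom}, {pos}) "
                        "but its parents are pinned to the same allele")
            else:
                if a1 is None and a2 is None:
                    a = int(haplos[p1][j])
                    _set(p1, j, a), _set(p2, j, a)
                elif a1 is None:
                    _set(p1, j, a2)
                elif a2 is None:
                    _set(p2, j, a1)
                elif a1 != a2:
                    raise ConfigError(
                        f"family {fs.family!r} must be monomorphic at ({chrom}, {pos}) "
                        "but its parents are pinned to different alleles")


@dataclass
class Truth:
    """The simulated ground truth kept alongside a dataset for oracles."""

    true_qtl: list
    epistatic_pairs: list
    genetic: np.ndarray      # (N, stages) genotypic values
    stage_means: tuple

    def to_json(self) -> str:
        payload = {
            "stage_means": list(self.stage_means),
            "qtl": [
                {"chromosome": q.chromosome, "position": q.position,
                 "effects": q.effects.tolist()} for q in self.true_qtl
            ],
            "epistatic_pairs": [
                {"chromosome1": p.chromosome1, "position1": p.position1,
                 "chromosome2": p.chromosome2, "position2": p.position2,
                 "effects": p.effects.tolist()} for p in self.epistatic_pairs
            ],
        }
        return json.dumps(payload, indent=1)


@dataclass
class Dataset:
    linkage_map: LinkageMap
    genotypes: GenotypeMatrix
    families: FamilyAssignment
    plots: PlotTable
    truth: Truth
    config: SimConfig


def simulate_dataset(config: SimConfig) -> Dataset:
    """Run the full generator: map, founders, DH families, trials."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(config.family_spec))]
    lmap = make_consensus_map(config.chromosome_spec, config.marker_spacing, seeds[0])

    rng = np.random.default_rng(seeds[1])
    parents = list(dict.fromkeys(
        p for fs in config.family_spec for p in (fs.parent1, fs.parent2)))
    haplos = {p: rng.integers(0, 2, size=lmap.n_markers) for p in parents}
    _force_founder_alleles(haplos, lmap, config)
    ref = haplos[config.family_spec[0].parent1].copy()

    frames, fam_rows = [], []
    for k, fs in enumerate(config.family_spec):
        gm = simulate_dh_family(
            lmap, haplos[fs.parent1], haplos[fs.parent2], fs.size,
            seeds[4 + k], ref_alleles=ref, line_prefix=f"{fs.family}_",
            mapping_function=config.mapping_function,
        )
        frames.append(gm.frame)
        fam_rows.extend(
            (l, fs.family, fs.parent1, fs.parent2) for l in gm.line_ids)
    genotypes = GenotypeMatrix(pd.concat(frames, axis=0))
    families = FamilyAssignment(
        pd.DataFrame(fam_rows, columns=["line", "family", "parent1", "parent2"]))

    g = np.column_stack([
        genetic_values(genotypes, families, config.true_qtl,
                       config.epistatic_pairs, s, lmap)
        for s in range(config.stage_count)
    ])
    plots = simulate_field_trial(g, config, seeds[2], line_ids=list(genotypes.line_ids))

    if config.missing_rate > 0:
        rng2 = np.random.default_rng(seeds[3])
        mask = rng2.random(genotypes.frame.shape) < config.missing_rate
        frame = genotypes.frame.mask(mask)
        genotypes = GenotypeMatrix(frame)

    truth = Truth(config.true_qtl, config.epistatic_pairs, g,
                  tuple(config.stage_means[: config.stage_count]))
    return Dataset(lmap, genotypes, families, plots, truth, config)


def simulate_entry_means(dataset: Dataset, h2: float, seed=0) -> BlueTable:
    """Entry-mean phenotypes at a target within-family entry-mean heritability.

    Adds Gaussian noise to the true genotypic values so that
    h2 = V_gw / (V_gw + sigma^2) where V_gw is the family-mean-centred
    genotypic variance.  A fast stand-in for the full field-trial +
    variance-analysis path when only the mapping stages are exercised.
    """
    if not (0 < h2 <= 1):
        raise ConfigError("h2 must lie in (0, 1]")
    g = dataset.truth.genetic
    fam = dataset.families.codes_for(dataset.genotypes.line_ids)
    rng = np.random.default_rng(seed)
    out = {}
    for s, name in enumerate(dataset.config.stage_names):
        gs = g[:, s].copy()
        centred = gs - np.array([gs[fam == f].mean() for f in range(dataset.families.n_families)])[fam]
        v_gw = float(np.var(centred))
        sigma2 = v_gw * (1.0 - h2) / h2
        noise = rng.normal(0.0, np.sqrt(sigma2), size=gs.size) if sigma2 > 0 else 0.0
        out[name] = dataset.truth.stage_means[s] + gs + noise
    return BlueTable(pd.DataFrame(out, index=dataset.genotypes.line_ids))


def standard_truth(chromosomes, family_spec, stage_count=3, n_qtl=10,
                   major_share=0.45, major_family=-1, seed=0):
    """The default truth set: 10 additive QTL plus 2 epistatic pairs.

    Reproduces the qualitative architecture the pipeline is designed to
    recover: a few loci shared across all stages, several stage-specific
    small loci, one locus whose effect doubles from the first to the last
    stage, two weak epistatic pairs, and one major locus segregating in a
    single family whose allele-substitution effect is calibrated
    analytically (unlinked loci, var(z) = 1 within a family) so that it
    contributes ``major_share`` of the family-mean-centred genotypic
    variance at every stage.

    The calibration assumes the major locus is unlinked to every other
    truth locus, so (given at least two chromosomes) its chromosome is
    reserved: all other loci are placed on the remaining ones.
    """
    rng = np.random.default_rng(seed)
    n_fam = len(family_spec)
    sizes = np.array([fs.size for fs in family_spec], dtype=float)
    wts = sizes / sizes.sum()
    chroms = list(chromosomes)
    # chromosome 0 hosts only the major locus when there is a choice
    others = chroms[1:] if len(chroms) > 1 else chroms
    used = []  # (chromosome, position) of already placed loci

    def place(i, frac, pool=None):
        # keep loci >= 15 cM apart on a chromosome so each gets its own
        # nearest marker (and its own founder-allele constraint)
        pool = others if pool is None else pool
        chrom, length = pool[i % len(pool)]
        pos = round(frac * length, 1)
        for _ in range(100):
            if all(c != chrom or abs(p - pos) >= 15.0 for c, p in used):
                break
            pos = round((pos + 17.0) % max(length - 5.0, 1.0), 1)
        used.append((chrom, pos))
        return chrom, pos

    qtl = []
    # growing locus: present in most families, effect doubles stage 1 -> last
    chrom, pos = place(1, 0.55)
    eff = np.zeros((n_fam, stage_count))
    for f in range(n_fam - 1):
        base = rng.choice([-1, 1]) * 1.2
        eff[f] = base * np.linspace(1.0, 2.0, stage_count)
    qtl.append(TrueQTL(chrom, pos, eff))
    # small loci: mixture of shared and stage-specific
    for i in range(2, n_qtl):
        chrom, pos = place(i, 0.15 + 0.55 * ((i * 7) % 10) / 10.0)
        eff = np.zeros((n_fam, stage_count))
        fams = rng.choice(n_fam, size=rng.integers(1, n_fam + 1), replace=False)
        if i % 3 == 0:
            stages = range(stage_count)               # shared across stages
        elif i % 3 == 1:
            stages = [int(rng.integers(0, stage_count))]   # stage-specific
        else:
            s0 = int(rng.integers(0, max(stage_count - 1, 1)))
            stages = [s0, min(s0 + 1, stage_count - 1)]    # two adjacent stages
        for f in fams:
            a = rng.choice([-1, 1]) * rng.uniform(0.8, 1.8)
            for s in stages:
                eff[f, s] = a
        qtl.append(TrueQTL(chrom, pos, eff))

    pairs = []
    for k in range(2):
        c1, p1 = place(3 + k, 0.8)
        c2, p2 = place(6 + k, 0.25)
        eff = np.zeros((n_fam, stage_count))
        fams = rng.choice(n_fam, size=2, replace=False)
        for f in fams:
            eff[f] = rng.choice([-1, 1]) * 0.8
        pairs.append(EpistaticPair(c1, p1, c2, p2, eff))

    # major locus, one family only, calibrated per stage to the target share
    mf = major_family % n_fam
    chrom, pos = place(0, 0.5, pool=chroms)
    eff = np.zeros((n_fam, stage_count))
    for s in range(stage_count):
        v_other = float(np.sum(wts * (np.sum([q.effects[:, s] ** 2 for q in qtl], axis=0)
                                      + np.sum([p.effects[:, s] ** 2 for p in pairs], axis=0))))
        a2 = major_share / (1.0 - major_share) * v_other / wts[mf]
        eff[mf, s] = np.sqrt(a2)
    qtl.insert(0, TrueQTL(chrom, pos, eff))
    return qtl, pairs


def default_config(seed=0, **overrides) -> SimConfig:
    """The study-scale default: 21 chromosomes, 4 DH families of 647 lines.

    Genomes A, B and R with 7 chromosomes each (120 cM, markers every
    5 cM), families of 131/120/200/196 lines with one shared parent
    between the first two, 4 environments of 960 plots in a partially
    replicated layout, and the standard truth set with the major locus
    segregating only in the largest late family (the 'EAW78' analogue).
    """
    chromosome_spec = [(f"{g}{i}", 120.0) for g in "ABR" for i in range(1, 8)]
    family_spec = [
        FamilySpec("DH06", 131, "P1", "P2"),
        FamilySpec("DH07", 120, "P1", "P3"),
        FamilySpec("EAW74", 200, "P4", "P5"),
        FamilySpec("EAW78", 196, "P6", "P7"),
    ]
    qtl, pairs = standard_truth(chromosome_spec, family_spec, seed=seed)
    cfg = dict(
        chromosome_spec=chromosome_spec, marker_spacing=5.0,
        family_spec=family_spec, true_qtl=qtl, epistatic_pairs=pairs,
        sigma_gxe=12.0, sigma_e=6.0, sigma_env=25.0, seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def write_dataset(dataset: Dataset, outdir, seed=None) -> dict:
    """Write map/genotype/family/plot tables plus the truth JSON; returns paths."""
    from pathlib import Path
    from .iomodel import write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / "map.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "families": outdir / "families.tsv",
        "plots": outdir / "plots.tsv",
        "truth": outdir / "truth.json",
    }
    write_table(dataset.linkage_map, paths["map"], seed=seed)
    write_table(dataset.genotypes, paths["genotypes"], seed=seed)
    write_table(dataset.families, paths["families"], seed=seed)
    write_table(dataset.plots, paths["plots"], seed=seed)
    paths["truth"].write_text(dataset.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
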