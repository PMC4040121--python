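"""Shared builders and fixtures for the mlcqtl test suite.

``build_population`` generates genotypes only (no phenotypic truth): every
family crosses two fully complementary founders, so each family segregates
at every marker.  It is the workhorse for null simulations and for tests
that construct phenotypes directly from marker codes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mlcqtl.iomodel import FamilyAssignment, GenotypeMatrix
from mlcqtl.simpop import (
    FamilySpec, SimConfig, TrueQTL, make_consensus_map, simulate_dataset,
    simulate_dh_family, standard_truth,
)

# family sizes of the four-family study design the package defaults emulate
STUDY_SIZES = [131, 120, 200, 196]


def build_population(chromosomes, sizes, seed, spacing=10.0):
    """Multi-family DH genotypes with complementary founders (no QTL truth).

    Returns (linkage_map, genotypes, families).  The map is deterministic
    (seed 0); ``seed`` drives founders and meiosis.
    """
    lmap = make_consensus_map(chromosomes, spacing, seed=0)
    rng = np.random.default_rng(seed)
    frames, fam_rows = [], []
    for k, n in enumerate(sizes):
        fam, p1, p2 = f"F{k + 1}", f"P{2 * k + 1}", f"P{2 * k + 2}"
        h1 = rng.integers(0, 2, lmap.n_markers)
        gm = simulate_dh_family(lmap, h1, 1 - h1, n, int(rng.integers(2**31)),
                                ref_alleles=h1, line_prefix=f"{fam}_")
        frames.append(gm.frame)
        fam_rows.extend((l, fam, p1, p2) for l in gm.line_ids)
    genotypes = GenotypeMatrix(pd.concat(frames, axis=0))
    families = FamilyAssignment(pd.DataFrame(
        fam_rows, columns=["line", "family", "parent1", "parent2"]))
    return lmap, genotypes, families


def study_families():
    """The four connected families of the default study design."""
    return [
        FamilySpec("DH06", 131, "P1", "P2"),
        FamilySpec("DH07", 120, "P1", "P3"),
        FamilySpec("EAW74", 200, "P4", "P5"),
        FamilySpec("EAW78", 196, "P6", "P7"),
    ]


def small_config(seed=11, **overrides):
    """Desk-scale simulation config: 3 chromosomes, 3 families of 40 lines."""
    chroms = [("C1", 80.0), ("C2", 80.0), ("C3", 80.0)]
    fams = [FamilySpec("FA", 40, "P1", "P2"),
            FamilySpec("FB", 40, "P1", "P3"),
            FamilySpec("FC", 40, "P4", "P5")]
    qtl = [
        TrueQTL("C1", 30.0, np.array([[2.0, 2.0, 2.0],
                                      [-1.5, -1.5, -1.5],
                                      [0.0, 0.0, 0.0]])),
        TrueQTL("C2", 50.0, np.array([[0.0, 0.0, 0.0],
                                      [1.0, 1.2, 1.4],
                                      [1.0, 1.0, 1.0]])),
    ]
    cfg = dict(chromosome_spec=chroms, marker_spacing=10.0, family_spec=fams,
               true_qtl=qtl, plots_per_environment=140, seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated desk-scale dataset shared across read-only tests."""
    return simulate_dataset(small_config())
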