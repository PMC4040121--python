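"""Canonical data containers, delimited-text I/O and cross-validation checks.

All pipeline stages exchange five objects: the linkage map, the DH
genotype matrix (0/2 coded), the line-to-family assignment, the
plot-level multi-environment phenotype table and the table of
across-environment entry means (BLUEs).  Readers validate on load and
reject malformed records with coordinates rather than coercing them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ValidationError",
    "LinkageMap",
    "GenotypeMatrix",
    "FamilyAssignment",
    "PlotTable",
    "BlueTable",
    "read_map",
    "read_genotypes",
    "read_families",
    "read_plots",
    "read_blues",
    "write_table",
    "validate_dataset",
]


class ValidationError(ValueError):
    """Raised when an input file or object violates a structural invariant."""


@dataclass
class LinkageMap:
    """Ordered markers with chromosome labels and cM positions."""

    table: pd.DataFrame  # columns: marker, chromosome, position

    def __post_init__(self):
        t = self.table
        required = {"marker", "chromosome", "position"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"map missing columns {sorted(missing)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValidationError(f"duplicated marker id {dup!r}")
        for chrom, grp in t.groupby("chromosome", sort=False):
            d = np.diff(grp["position"].to_numpy())
            if np.any(d <= 0):
                i = int(np.flatnonzero(d <= 0)[0])
                raise ValidationError(
                    f"positions not strictly increasing on {chrom} near "
                    f"{grp['marker'].iloc[i + 1]!r}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosome_length(self, chrom) -> float:
        p = self.table.loc[self.table["chromosome"] == chrom, "position"]
        if p.empty:
            raise KeyError(chrom)
        return float(p.max())

    def marker_position(self, marker_id):
        row = self.table.loc[self.table["marker"] == marker_id]
        if row.empty:
            raise KeyError(marker_id)
        return row["chromosome"].iloc[0], float(row["position"].iloc[0])


@dataclass
class GenotypeMatrix:
    """DH lines x markers, codes in {0, 2} (NaN = missing)."""

    frame: pd.DataFrame  # index: line ids, columns: marker ids, float values

    def __post_init__(self):
        vals = self.frame.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-DH genotype code {vals[i, j]!r} at line "
                f"{self.frame.index[i]!r}, marker {self.frame.columns[j]!r}"
            )
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicated line id {dup!r}")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def line_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.frame.columns.to_numpy()

    def aligned_to(self, linkage_map: LinkageMap) -> "GenotypeMatrix":
        """Reorder marker columns to map order; unknown markers are an error."""
        missing = set(self.frame.columns) - set(linkage_map.markers)
        if missing:
            raise ValidationError(f"markers absent from map: {sorted(missing)[:5]}")
        return GenotypeMatrix(self.frame.loc[:, list(linkage_map.markers)])


@dataclass
class FamilyAssignment:
    """line -> family mapping plus each family's parents (J of the scan model)."""

    table: pd.DataFrame  # columns: line, family, parent1, parent2

    def __post_init__(self):
        if self.table["line"].duplicated().any():
            dup = self.table.loc[self.table["line"].duplicated(), "line"].iloc[0]
            raise ValidationError(f"line {dup!r} assigned to more than one family")
        self._fam_ids = list(dict.fromkeys(self.table["family"]))
        self._code = {f: i for i, f in enumerate(self._fam_ids)}
        self._line_fam = dict(zip(self.table["line"], self.table["family"]))

    @property
    def family_ids(self) -> list:
        return self._fam_ids

    @property
    def n_families(self) -> int:
        return len(self._fam_ids)

    def parents(self, family) -> tuple:
        row = self.table.loc[self.table["family"] == family].iloc[0]
        return row["parent1"], row["parent2"]

    def codes_for(self, line_ids) -> np.ndarray:
        try:
            return np.array([self._code[self._line_fam[l]] for l in line_ids])
        except KeyError as e:
            raise ValidationError(f"line {e.args[0]!r} has no family assignment")

    def family_sizes(self) -> dict:
        return dict(self.table["family"].value_counts(sort=False))

    def incidence(self, line_ids) -> np.ndarray:
        """N x P 0/1 family-membership matrix (J)."""
        codes = self.codes_for(line_ids)
        J = np.zeros((len(line_ids), self.n_families))
        J[np.arange(len(line_ids)), codes] = 1.0
        return J


@dataclass
class PlotTable:
    """Plot-level phenotypes: entry, is_check, environment, replicate, stages."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"entry", "is_check", "environment", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"plot table missing columns {sorted(missing)}")
        key = self.frame[["entry", "environment", "replicate"]]
        if key.duplicated().any():
            row = self.frame.loc[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate plot (entry={row['entry']!r}, environment="
                f"{row['environment']!r}, replicate={row['replicate']!r})"
            )

    @property
    def stages(self) -> list:
        fixed = {"entry", "is_check", "environment", "replicate"}
        return [c for c in self.frame.columns if c not in fixed]

    @property
    def environments(self) -> list:
        return list(dict.fromkeys(self.frame["environment"]))

    @property
    def n_environments(self) -> int:
        return len(self.environments)


@dataclass
class BlueTable:
    """Across-environment entry means (BLUEs), one row per line, per-stage columns."""

    frame: pd.DataFrame  # index: line ids

    def __post_init__(self):
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicated line id {dup!r} in BLUE table")

    @property
    def stages(self) -> list:
        return list(self.frame.columns)

    @property
    def line_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def stage_values(self, stage, line_ids=None) -> np.ndarray:
        col = self.frame[stage]
        if line_ids is not None:
            col = col.loc[line_ids]
        return col.to_numpy(dtype=float)


def _read_delimited(path) -> pd.DataFrame:
    """Read TSV/CSV with delimiter sniffing; '#' lines are comments."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_map(path) -> LinkageMap:
    df = _read_delimited(path)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    aliases = {"marker_id": "marker", "chrom": "chromosome", "position_cm": "position",
               "pos": "position", "cm": "position"}
    df = df.rename(columns=aliases)
    return LinkageMap(df[["marker", "chromosome", "position"]])


def read_genotypes(path, linkage_map: LinkageMap | None = None) -> GenotypeMatrix:
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    geno = GenotypeMatrix(df.astype(float))
    if linkage_map is not None:
        geno = geno.aligned_to(linkage_map)
    return geno


def read_families(path) -> FamilyAssignment:
    df = _read_delimited(path)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    df = df.rename(columns={"line_id": "line", "family_id": "family"})
    for col in ("parent1", "parent2"):
        if col not in df.columns:
            df[col] = ""
    return FamilyAssignment(df[["line", "family", "parent1", "parent2"]])


def read_plots(path) -> PlotTable:
    df = _read_delimited(path)
    df = df.rename(columns={c: (c.lower() if c.lower() in
                                {"entry", "is_check", "environment", "replicate"} else c)
                            for c in df.columns})
    df["is_check"] = df["is_check"].astype(bool)
    return PlotTable(df)


def read_blues(path) -> BlueTable:
    df = _read_delimited(path)
    return BlueTable(df.set_index(df.columns[0]))


def write_table(obj, path, seed=None, note=None) -> None:
    """Write any container (or DataFrame) as TSV with a provenance comment line."""
    if isinstance(obj, LinkageMap):
        df, index = obj.table, False
    elif isinstance(obj, GenotypeMatrix):
        df, index = obj.frame.rename_axis("line"), True
    elif isinstance(obj, FamilyAssignment):
        df, index = obj.table, False
    elif isinstance(obj, (PlotTable,)):
        df, index = obj.frame, False
    elif isinstance(obj, BlueTable):
        df, index = obj.frame.rename_axis("line"), True
    else:
        df, index = obj, False
    buf = io.StringIO()
    seed_note = "" if seed is None else f" seed={seed}"
    extra = "" if note is None else f" {note}"
    buf.write(f"# mlcqtl {__version__}{seed_note}{extra}\n")
    df.to_csv(buf, sep="\t", index=index)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


@dataclass
class ValidationReport:
    issues: list          # (severity, message)

    @property
    def errors(self):
        return [m for s, m in self.issues if s == "error"]

    @property
    def warnings(self):
        return [m for s, m in self.issues if s != "error"]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(linkage_map, genotypes, families, blues=None) -> ValidationReport:
    """Cross-check line sets and per-family marker informativeness.

    Hard error when the genotype and family line sets are disjoint;
    otherwise collects named issues (missing lines, monomorphic
    chromosomes per family, missingness summary).
    """
    issues = []
    geno_lines = set(genotypes.line_ids)
    fam_lines = set(families.table["line"])
    if not geno_lines & fam_lines:
        raise ValidationError("genotype and family line sets are disjoint")
    for l in sorted(geno_lines - fam_lines)[:20]:
        issues.append(("error", f"line {l!r} genotyped but not assigned to a family"))
    if blues is not None:
        blue_lines = set(blues.line_ids)
        for l in sorted(geno_lines - blue_lines)[:20]:
            issues.append(("warning", f"line {l!r} has no BLUE value"))
        for l in sorted(blue_lines - geno_lines)[:20]:
            issues.append(("warning", f"line {l!r} has BLUEs but no genotype"))

    G = genotypes.values
    miss = float(np.isnan(G).mean())
    issues.append(("info", f"overall genotype missingness {miss:.3%}"))
    assigned = np.array([l in fam_lines for l in genotypes.line_ids])
    G = G[assigned]
    codes = families.codes_for(genotypes.line_ids[assigned])
    tab = linkage_map.table
    for f, fam in enumerate(families.family_ids):
        sub = G[codes == f]
        if not sub.size:
            continue
        with np.errstate(invalid="ignore"):
            poly = np.nanmax(sub, axis=0) != np.nanmin(sub, axis=0)
        for chrom in linkage_map.chromosomes:
            sel = (tab["chromosome"] == chrom).to_numpy()
            n_poly = int(np.nansum(poly[sel]))
            if n_poly == 0:
                issues.append(("info", f"family {fam!r} monomorphic on chromosome {chrom}"))
    return ValidationReport(issues)
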