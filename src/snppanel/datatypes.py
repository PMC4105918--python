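"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as counts of the panel-wide minor allele (0, 1, 2;
-1 for missing).  The minor allele is fixed once, at load or simulation
time, over the whole dataset: subsetting individuals or populations never
re-orients calls, so per-population frequencies of the panel-minor allele
may exceed 0.5 (they are folded to [0, 0.5] only where a MAF statistic
requires it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeDataset:
    """Diploid biallelic SNP calls for individuals grouped into populations.

    Parameters
    ----------
    individual_ids : list of str
    population_labels : list of str, one per individual
    locus_ids : list of str, unique
    calls : int array (n_individuals, n_loci), entries in {0, 1, 2, -1}
    metadata : free-form annotations (lineage assignments, precedence
        flags, hatchery/natural origin, ...)
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls rows")
        if len(self.population_labels) != n:
            raise ValueError("every individual needs a population label")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length does not match calls columns")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"call at individual {self.individual_ids[i]!r}, locus "
                f"{self.locus_ids[j]!r} outside {{0,1,2,missing}}"
            )

    # -- basic structure -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.population_labels))

    def population_indices(self) -> dict[str, np.ndarray]:
        labels = np.asarray(self.population_labels)
        return {p: np.flatnonzero(labels == p) for p in self.populations}

    # -- subsetting (orientation is preserved, never recomputed) ---------
    def subset_individuals(self, mask_or_index) -> "GenotypeDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            individual_ids=[self.individual_ids[i] for i in idx],
            population_labels=[self.population_labels[i] for i in idx],
            calls=self.calls[idx, :],
            metadata=dict(self.metadata),
        )

    def subset_loci(self, loci: list[str]) -> "GenotypeDataset":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise KeyError(f"loci not in panel: {missing}")
        idx = np.array([pos[l] for l in loci], dtype=int)
        return replace(
            self,
            locus_ids=list(loci),
            calls=self.calls[:, idx],
            metadata=dict(self.metadata),
        )

    def subset_populations(self, pops) -> "GenotypeDataset":
        keep = set(pops)
        mask = np.array([p in keep for p in self.population_labels])
        return self.subset_individuals(mask)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, columns=self.locus_ids)
        df.insert(0, "population", self.population_labels)
        df.insert(0, "individual", self.individual_ids)
        return df


MONTHS = [f"{m:02d}" for m in range(1, 13)]
GEO_COLUMNS = ["latitude", "longitude", "elevation", "migration_distance"]
MONTHLY_COLUMNS = (
    [f"tmax_{m}" for m in MONTHS]
    + [f"tmin_{m}" for m in MONTHS]
    + [f"precip_{m}" for m in MONTHS]
)


@dataclass
class EnvironmentTable:
    """Per-population geography and PRISM-style monthly climate normals.

    One row per population: latitude/longitude (decimal degrees),
    elevation (m), migration distance from a fixed origin (km), and
    twelve monthly mean-max / mean-min temperatures (degC) and monthly
    precipitation totals (mm).  Seasonal and annual aggregates are added
    by :func:`snppanel.assoc.seasonal_aggregate`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "population" not in df.columns:
            raise ValueError("environment table needs a 'population' column")
        if df["population"].duplicated().any():
            dup = df.loc[df["population"].duplicated(), "population"].tolist()
            raise ValueError(f"duplicate population rows: {dup}")
        for col in GEO_COLUMNS + MONTHLY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"environment table missing column {col!r}")
        core = df[GEO_COLUMNS + MONTHLY_COLUMNS]
        if core.isna().any().any():
            bad = core.columns[core.isna().any()].tolist()
            raise ValueError(f"missing values in environment columns {bad}")
        self.table = df.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return self.table["population"].tolist()

    def monthly(self, kind: str) -> pd.DataFrame:
        """12-column monthly block, kind in {'tmax','tmin','precip'}."""
        cols = [f"{kind}_{m}" for m in MONTHS]
        return self.table[cols]

    def variable(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"no environment variable {name!r}")
        return pd.Series(
            self.table[name].to_numpy(), index=self.table["population"].to_numpy()
        )

    def subset(self, pops) -> "EnvironmentTable":
        keep = self.table["population"].isin(list(pops))
        return EnvironmentTable(self.table.loc[keep].reset_index(drop=True))


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # fst | nei | stream_km | env_abs_diff | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric (tol 1e-12)")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major over i>j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels], dtype=int)
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
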