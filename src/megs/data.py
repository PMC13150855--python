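"""Domain containers and file I/O for genotypes, phenotypes and daily
environmental series.

Genotypes are additive dosages in {0, 1, 2} (missing allowed before
imputation); phenotypes are long-format (genotype, environment, trait,
value) records where NA marks a masked cell rather than a dropped one;
environmental series are daily factor values per environment, harmonized to
the day range and factor set shared by every environment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing dosage before imputation
MISSING_DOSAGE = -9


class DataValidationError(ValueError):
    """A file or container violates a domain invariant."""


@dataclass
class GenotypeMatrix:
    """n x p additive genotype dosages with sample and marker identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique individual identifiers (rows).
    marker_ids : list of str
        Ordered, unique marker identifiers (columns).
    dosages : ndarray of shape (n, p)
        Minor-allele counts in {0, 1, 2}; ``MISSING_DOSAGE`` marks missing
        entries prior to imputation.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise DataValidationError(
                f"dosage rows ({n}) != number of sample ids ({len(self.sample_ids)})"
            )
        if p != len(self.marker_ids):
            raise DataValidationError(
                f"dosage columns ({p}) != number of marker ids ({len(self.marker_ids)})"
            )
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("duplicate sample ids")
        if len(set(self.marker_ids)) != p:
            raise DataValidationError("duplicate marker ids")
        observed = self.dosages[self.dosages != MISSING_DOSAGE]
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.nonzero(
                (self.dosages != MISSING_DOSAGE)
                & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
            )
            raise DataValidationError(
                f"dosage not in {{0,1,2}} at row {rows[0]} "
                f"(sample {self.sample_ids[rows[0]]}), column {cols[0]} "
                f"(marker {self.marker_ids[cols[0]]}): {self.dosages[rows[0], cols[0]]}"
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING_DOSAGE).any())

    def subset(self, sample_ids: list[str]) -> "GenotypeMatrix":
        """Row-subset preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.marker_ids), self.dosages[rows])

    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages with the marker mean rounded to {0,1,2}."""
        d = self.dosages.copy()
        mask = d == MISSING_DOSAGE
        for j in np.nonzero(mask.any(axis=0))[0]:
            col = d[:, j]
            obs = col[col != MISSING_DOSAGE]
            if obs.size == 0:
                raise DataValidationError(
                    f"marker {self.marker_ids[j]} has no observed dosages to impute from"
                )
            col[col == MISSING_DOSAGE] = np.clip(np.rint(obs.mean()), 0, 2)
        return GenotypeMatrix(list(self.sample_ids), list(self.marker_ids), d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.marker_ids)


@dataclass
class PhenoTable:
    """Long-format genotype x environment phenotype records.

    One row per (genotype, environment, trait); ``value`` is NaN for a
    masked cell (e.g. an environment deliberately hidden from fitting).
    """

    records: pd.DataFrame  # columns: genotype, environment, trait, value

    def __post_init__(self) -> None:
        required = ["genotype", "environment", "trait", "value"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise DataValidationError(f"phenotype table missing columns: {missing}")
        self.records = self.records[required].copy()
        self.records["value"] = pd.to_numeric(self.records["value"], errors="coerce")
        dup = self.records.duplicated(subset=["genotype", "environment", "trait"])
        if dup.any():
            keys = self.records.loc[dup, ["genotype", "environment", "trait"]]
            raise DataValidationError(
                "duplicate (genotype, environment, trait) records: "
                + "; ".join(map(str, keys.itertuples(index=False, name=None)))
            )

    @property
    def environment_ids(self) -> list[str]:
        return list(pd.unique(self.records["environment"]))

    @property
    def genotype_ids(self) -> list[str]:
        return list(pd.unique(self.records["genotype"]))

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.records["trait"]))

    def for_trait(self, trait: str) -> "PhenoTable":
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present (have {self.traits})")
        return PhenoTable(sub.reset_index(drop=True))

    def observed(self) -> pd.DataFrame:
        """Rows with a non-missing value."""
        return self.records.dropna(subset=["value"])

    def mask_environment(self, environment: str) -> "PhenoTable":
        """Set every value in one environment to NA (novel-environment mode)."""
        rec = self.records.copy()
        rec.loc[rec["environment"] == environment, "value"] = np.nan
        return PhenoTable(rec)

    def wide(self, trait: str | None = None) -> pd.DataFrame:
        """Genotype x environment value matrix for a single trait."""
        rec = self.records
        if trait is not None:
            rec = rec[rec["trait"] == trait]
        elif rec["trait"].nunique() > 1:
            raise ValueError("multiple traits present; specify one")
        return rec.pivot(index="genotype", columns="environment", values="value")


@dataclass
class EnvSeries:
    """Daily environmental-factor series, harmonized across environments.

    Stored long: one row per (environment, day, factor). After
    harmonization every environment covers the identical 1-based day range
    and the identical factor set.
    """

    data: pd.DataFrame  # columns: environment, day, factor, value

    def __post_init__(self) -> None:
        required = ["environment", "day", "factor", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise DataValidationError(f"environment series missing columns: {missing}")
        self.data = self.data[required].copy()
        self.data["day"] = self.data["day"].astype(int)
        self.data["value"] = pd.to_numeric(self.data["value"])
        dup = self.data.duplicated(subset=["environment", "day", "factor"])
        if dup.any():
            raise DataValidationError("duplicate (environment, day, factor) rows")

    @property
    def environment_ids(self) -> list[str]:
        return list(pd.unique(self.data["environment"]))

    @property
    def factors(self) -> list[str]:
        return list(pd.unique(self.data["factor"]))

    @property
    def day_range(self) -> tuple[int, int]:
        return int(self.data["day"].min()), int(self.data["day"].max())

    def harmonized(self) -> "EnvSeries":
        """Restrict to the shared day range and shared factor set.

        Keeps days present in every environment and factors present in
        every environment; an environment left with zero overlapping days
        is an error.
        """
        d = self.data
        envs = list(pd.unique(d["environment"]))
        lo = max(d.loc[d["environment"] == e, "day"].min() for e in envs)
        hi = min(d.loc[d["environment"] == e, "day"].max() for e in envs)
        if lo > hi:
            raise DataValidationError(
                "environments share no overlapping days; cannot harmonize"
            )
        factor_sets = [set(d.loc[d["environment"] == e, "factor"]) for e in envs]
        shared = set.intersection(*factor_sets)
        dropped = set(d["factor"]) - shared
        if dropped:
            warnings.warn(
                f"factors not present in all environments dropped: {sorted(dropped)}",
                stacklevel=2,
            )
        if not shared:
            raise DataValidationError("no factor is present in every environment")
        out = d[(d["day"] >= lo) & (d["day"] <= hi) & d["factor"].isin(shared)]
        return EnvSeries(out.reset_index(drop=True))

    def factor_matrix(self, factor: str) -> pd.DataFrame:
        """Environment x day value matrix for one factor."""
        sub = self.data[self.data["factor"] == factor]
        if sub.empty:
            raise KeyError(f"factor {factor!r} not present (have {self.factors})")
        return sub.pivot(index="environment", columns="day", values="value")

    def subset_environments(self, environments: list[str]) -> "EnvSeries":
        sub = self.data[self.data["environment"].isin(environments)]
        return EnvSeries(sub.reset_index(drop=True))


@dataclass
class EnvIndex:
    """A scalar environmental index: one factor, one day window, one value
    per environment, centred against the across-environment mean.

    The centred value ``x_j = e_j - centre`` is what both frameworks
    consume; novel environments are centred with the *training* centre.
    """

    factor_name: str
    window: tuple[int, int]  # inclusive (start_day, end_day)
    raw_index: dict[str, float]  # environment -> e_j (window mean, factor units)
    r2: float = np.nan
    centre: float = field(init=False)
    centred_index: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        start, end = self.window
        if start > end:
            raise DataValidationError(f"window start {start} > end {end}")
        if not np.isnan(self.r2) and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise DataValidationError(f"r2 {self.r2} outside [0, 1]")
        self.centre = float(np.mean(list(self.raw_index.values())))
        self.centred_index = {e: v - self.centre for e, v in self.raw_index.items()}

    def x(self, environment: str) -> float:
        """Centred index for one environment."""
        return self.centred_index[environment]

    def extend(self, raw_values: dict[str, float]) -> "EnvIndex":
        """Add novel environments, centring them with the existing centre."""
        out = EnvIndex(self.factor_name, self.window, dict(self.raw_index), self.r2)
        # keep training centre: append manually
        for env, e_j in raw_values.items():
            out.raw_index[env] = e_j
            out.centred_index[env] = e_j - self.centre
        out.centre = self.centre
        return out

    def to_frame(self) -> pd.DataFrame:
        envs = list(self.raw_index)
        return pd.DataFrame(
            {
                "environment": envs,
                "factor": self.factor_name,
                "start_day": self.window[0],
                "end_day": self.window[1],
                "e_j": [self.raw_index[e] for e in envs],
                "x_j": [self.centred_index[e] for e in envs],
                "r2": self.r2,
            }
        )


@dataclass
class VarianceComponents:
    """Genetic, genotype-by-environment and residual variances from a
    balanced MET, with the design's environment count L and replicate
    count R."""

    Vg: float
    Vge: float
    Ve: float
    L: int
    R: int

    def __post_init__(self) -> None:
        if min(self.Vg, self.Vge, self.Ve) < 0:
            raise DataValidationError("variance components must be >= 0")
        if self.L < 1 or self.R < 1:
            raise DataValidationError("L and R must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PLINK_META_COLS = 6  # FID IID PAT MAT SEX PHENOTYPE


def read_genotypes(path, format: str = "tsv_matrix", impute: bool = False) -> GenotypeMatrix:
    """Read an additive dosage matrix.

    Parameters
    ----------
    path : str or Path
        ``tsv_matrix``: header row = marker ids, first column = sample id.
        ``plink_raw``: space-delimited PLINK ``--recode A`` export with six
        leading metadata columns; sample id taken from IID.
    impute : bool
        If True, missing dosages (NA or empty) are mean-imputed per marker
        (rounded to the nearest of 0/1/2); if False, any missing dosage is
        an error.
    """
    if format == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        sample_ids = [str(s) for s in df.index]
        marker_ids = [str(c) for c in df.columns]
        raw = df.to_numpy()
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        if df.shape[1] <= _PLINK_META_COLS:
            raise DataValidationError(
                f"PLINK RAW file has {df.shape[1]} columns; expected > {_PLINK_META_COLS}"
            )
        sample_ids = [str(s) for s in df.iloc[:, 1]]  # IID
        marker_ids = [str(c) for c in df.columns[_PLINK_META_COLS:]]
        raw = df.iloc[:, _PLINK_META_COLS:].to_numpy()
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    n, p = raw.shape
    dosages = np.empty((n, p), dtype=float)
    for i in range(n):
        for j in range(p):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "NA", "nan"):
                dosages[i, j] = MISSING_DOSAGE
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise DataValidationError(
                    f"non-numeric dosage {cell!r} at row {i} col {j}"
                ) from exc
            if v not in (0.0, 1.0, 2.0):
                raise DataValidationError(
                    f"dosage not in {{0,1,2}} at row {i} (sample {sample_ids[i]}), "
                    f"col {j} (marker {marker_ids[j]}): {cell!r}"
                )
            dosages[i, j] = v

    gm = GenotypeMatrix(sample_ids, marker_ids, dosages)
    if gm.has_missing:
        if not impute:
            raise DataValidationError(
                "missing dosages present; pass impute=True for per-marker mean imputation"
            )
        logger.info("imputing missing dosages by per-marker rounded mean")
        gm = gm.impute_mean()
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame().astype(int)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_phenotypes(path) -> PhenoTable:
    """Read TSV ``genotype  environment  trait  value`` (NA allowed)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"genotype": str, "environment": str, "trait": str},
        na_values=["NA"],
    )
    return PhenoTable(df)


def write_phenotypes(pheno: PhenoTable, path) -> None:
    pheno.records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_env_series(path, harmonize: bool = True) -> EnvSeries:
    """Read TSV ``environment  day  factor  value``; by default harmonize
    to the day range and factor set shared by all environments."""
    df = pd.read_csv(path, sep="\t", dtype={"environment": str, "factor": str})
    series = EnvSeries(df)
    return series.harmonized() if harmonize else series


def write_env_series(series: EnvSeries, path) -> None:
    series.data.to_csv(path, sep="\t", index=False)


def write_env_index(index: EnvIndex, path) -> None:
    index.to_frame().to_csv(path, sep="\t", index=False)


def read_env_index(path) -> EnvIndex:
    """Read an index file written by :func:`write_env_index`."""
    df = pd.read_csv(path, sep="\t", dtype={"environment": str, "factor": str})
    required = {"environment", "factor", "start_day", "end_day", "e_j"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"index file missing columns: {sorted(missing)}")
    factor = df["factor"].iloc[0]
    window = (int(df["start_day"].iloc[0]), int(df["end_day"].iloc[0]))
    raw = dict(zip(df["environment"], df["e_j"].astype(float)))
    r2 = float(df["r2"].iloc[0]) if "r2" in df.columns else np.nan
    return EnvIndex(factor, window, raw, r2)
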