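"""Environmental-index search (CERIS).

CERIS — critical environmental regressor through informed search — scans
every (environmental factor, day window) pair on a step grid, summarizes
each environment by the factor's window mean e_j, regresses the
environment-mean phenotype on e_j across environments, and keeps the
candidate with the highest coefficient of determination R². The winning
window mean, centred by its across-environment average, is the scalar
environmental index both prediction frameworks consume.

With only two environments any non-constant factor fits the two
environment means perfectly, so searches require at least three
environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from megs.data import EnvIndex, EnvSeries, PhenoTable


@dataclass
class CerisSearchResult:
    """Outcome of an exhaustive index search.

    Attributes
    ----------
    best : EnvIndex
        The argmax-R² candidate (ties broken by earlier start, then
        shorter window, then factor name).
    table : DataFrame
        One row per enumerated (factor, start_day, end_day) with columns
        ``r`` (signed Pearson correlation) and ``r2``.
    """

    best: EnvIndex
    table: pd.DataFrame


def env_means(
    pheno: PhenoTable, genotype_subset: list[str] | None = None
) -> dict[str, float]:
    """Per-environment mean phenotype over (a subset of) genotypes.

    During cross-validation the subset is the training genotypes, so the
    index search never sees held-out phenotypes.
    """
    rec = pheno.observed()
    if genotype_subset is not None:
        rec = rec[rec["genotype"].isin(set(genotype_subset))]
    means = rec.groupby("environment")["value"].mean()
    empty = [e for e in pheno.environment_ids if e not in means.index]
    if empty:
        raise ValueError(
            f"environments with zero usable phenotype records: {empty}"
        )
    return {str(e): float(v) for e, v in means.items()}


def window_mean(
    series: EnvSeries, factor: str, window: tuple[int, int]
) -> dict[str, float]:
    """Per-environment mean of ``factor`` over days in the inclusive window."""
    start, end = window
    lo, hi = series.day_range
    if start < lo or end > hi or start > end:
        raise ValueError(
            f"window ({start}, {end}) outside harmonized day range ({lo}, {hi})"
        )
    mat = series.factor_matrix(factor)
    cols = [d for d in mat.columns if start <= d <= end]
    sub = mat[cols]
    if sub.isna().any().any():
        raise ValueError(f"factor {factor!r} has missing days inside window {window}")
    return {str(e): float(v) for e, v in sub.mean(axis=1).items()}


def _regress_r(y: np.ndarray, e: np.ndarray) -> float:
    """Signed Pearson correlation of env-mean phenotype on index; 0 when
    the index is constant across environments (degenerate candidate)."""
    if np.ptp(e) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(e, y)[0, 1])


def search_index(
    series: EnvSeries,
    env_pheno_means: dict[str, float],
    min_width: int = 7,
    step: int = 1,
) -> CerisSearchResult:
    """Exhaustive (factor, start, end) grid search for the best index.

    Enumerates every window with ``end - start + 1 >= min_width`` whose
    start and end lie on the ``step`` grid anchored at the first
    harmonized day, for every factor; fits a simple linear regression of
    environment-mean phenotype on the per-environment window mean and
    returns the candidate with the highest R².
    """
    envs = sorted(env_pheno_means)
    m = len(envs)
    if m < 3:
        raise ValueError(
            f"index search needs >= 3 environments, got {m}: with two "
            "environments any non-constant factor fits perfectly"
        )
    missing = [e for e in envs if e not in series.environment_ids]
    if missing:
        raise ValueError(f"environments without series data: {missing}")
    if min_width < 1 or step < 1:
        raise ValueError("min_width and step must be >= 1")

    series = series.subset_environments(envs)
    lo, hi = series.day_range
    y = np.array([env_pheno_means[e] for e in envs])

    starts = range(lo, hi + 1, step)
    rows = []
    best_key = None  # (-r2, start, width, factor) lexicographic min
    best = None
    for factor in sorted(series.factors):
        mat = series.factor_matrix(factor).loc[envs]
        days = np.asarray(mat.columns)
        vals = mat.to_numpy()  # m x D
        # prefix sums for O(1) window means
        csum = np.concatenate([np.zeros((len(envs), 1)), np.cumsum(vals, axis=1)], axis=1)
        day_pos = {int(d): i for i, d in enumerate(days)}
        for start in starts:
            for end in range(start + min_width - 1, hi + 1, step):
                i0, i1 = day_pos[start], day_pos[end]
                e_j = (csum[:, i1 + 1] - csum[:, i0]) / (i1 - i0 + 1)
                r = _regress_r(y, e_j)
                r2 = r * r
                rows.append((factor, start, end, r, r2))
                key = (-r2, start, end - start + 1, factor)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (factor, start, end, e_j, r2)

    table = pd.DataFrame(rows, columns=["factor", "start_day", "end_day", "r", "r2"])
    factor, start, end, e_j, r2 = best
    if r2 == 0.0:
        warnings.warn(
            "every candidate index is uncorrelated with the environment "
            "means (all R² = 0); returning the first grid candidate",
            stacklevel=2,
        )
    index = EnvIndex(
        factor_name=factor,
        window=(start, end),
        raw_index={e: float(v) for e, v in zip(envs, e_j)},
        r2=float(r2),
    )
    return CerisSearchResult(best=index, table=table)
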