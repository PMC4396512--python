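"""Fitness computation from field-trial plant records.

Absolute fitness per plant is total fruit count (fruits + flowers + buds)
times mean silique length, times survival when survivorship is included;
non-survivors score 0 with survivorship and are missing without it.
Relative fitness per genotype x environment supports two conventions:
dividing by the population mean within the environment (default) or by the
Col-0 reference genotype's mean.  Mean normalization rescales genotype
means so every environment averages to the grand mean, which puts
environments of different productivity on one scale.  Genetic correlations
between traits use genotype means within an environment (Pearson and
Spearman).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "absolute_fitness",
    "fitness_table",
    "relative_fitness",
    "mean_normalize",
    "genetic_correlations",
]

#: columns a PlantRecord table must carry
PLANT_RECORD_COLUMNS = (
    "environment", "treatment", "plot", "block", "genotype",
    "tfc", "silique_length", "survival",
)


def absolute_fitness(
    records: pd.DataFrame, include_survivorship: bool = True
) -> pd.Series:
    """Per-plant absolute fitness, aligned to ``records``.

    With survivorship: TFC x silique length x survival (exactly 0 for
    non-survivors).  Without: TFC x silique length for survivors, missing
    otherwise.  Plants with missing survival are excluded (NaN) either way.
    """
    tfc = records["tfc"]
    length = records["silique_length"]
    surv = records["survival"]
    if (tfc.dropna() < 0).any() or (length.dropna() <= 0).any():
        raise ValueError("tfc must be >= 0 and silique_length > 0")
    survived = surv == 1
    if ((tfc.isna() | length.isna()) & survived).any():
        raise ValueError("tfc and silique_length required for survivors")
    fit = pd.Series(np.nan, index=records.index, dtype=float)
    fit[survived] = tfc[survived] * length[survived]
    if include_survivorship:
        fit[surv == 0] = 0.0
    return fit


def fitness_table(records: pd.DataFrame) -> pd.DataFrame:
    """Genotype x environment fitness summary.

    Adds per-plant fitness both ways, then aggregates unweighted genotype
    means per environment with relative fitness (both conventions) and
    mean-normalized values for the with-survivorship measure.
    """
    rec = records.copy()
    rec["fitness_with_surv"] = absolute_fitness(rec, include_survivorship=True)
    rec["fitness_wo_surv"] = absolute_fitness(rec, include_survivorship=False)
    means = (
        rec.groupby(["environment", "genotype"], observed=True)[
            ["fitness_with_surv", "fitness_wo_surv"]
        ]
        .mean()
        .reset_index()
    )
    for col in ("fitness_with_surv", "fitness_wo_surv"):
        m = means.set_index(["environment", "genotype"])[col]
        means[f"rel_{col}_popmean"] = relative_fitness(
            m, convention="population_mean"
        ).values
        means[f"rel_{col}_col0"] = relative_fitness(
            m, convention="col0_reference"
        ).values
    means["norm_fitness_with_surv"] = mean_normalize(
        means.set_index(["environment", "genotype"])["fitness_with_surv"]
    ).values
    return means


def _check_env_genotype_index(means: pd.Series) -> None:
    if not isinstance(means.index, pd.MultiIndex) or means.index.names != [
        "environment", "genotype",
    ]:
        raise ValueError(
            "expected a Series indexed by (environment, genotype)"
        )


def relative_fitness(
    genotype_env_means: pd.Series,
    convention: str = "population_mean",
    reference: str = "Col-0",
) -> pd.Series:
    """Relative fitness per genotype x environment.

    population_mean: each genotype mean divided by the unweighted mean of
    genotype means within its environment (so relative fitness averages to
    exactly 1 per environment).  col0_reference: divided by the reference
    genotype's mean in that environment, making the reference 1 everywhere.
    """
    _check_env_genotype_index(genotype_env_means)
    m = genotype_env_means
    if convention == "population_mean":
        denom = m.groupby(level="environment").transform("mean")
    elif convention == "col0_reference":
        ref = m.xs(reference, level="genotype")
        denom = m.index.get_level_values("environment").map(ref)
        denom = pd.Series(np.asarray(denom, dtype=float), index=m.index)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if (np.asarray(denom) <= 0).any() or denom.isna().any():
        raise ValueError("relative fitness denominator must be > 0")
    return m / denom


def mean_normalize(genotype_env_means: pd.Series) -> pd.Series:
    """Rescale genotype means so each environment averages to the grand mean.

    Each value is divided by its environment's (unweighted genotype-mean)
    average and multiplied by the grand mean of those averages.  Idempotent:
    normalizing twice changes nothing.
    """
    _check_env_genotype_index(genotype_env_means)
    m = genotype_env_means
    env_means = m.groupby(level="environment").mean()
    if (env_means <= 0).any():
        raise ValueError("environment means must be > 0")
    grand = env_means.mean()
    denom = m.groupby(level="environment").transform("mean")
    return m / denom * grand


def genetic_correlations(
    genotype_means: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait x trait correlation matrix over genotype means, with p values.

    Rows of ``genotype_means`` are genotypes (>= 3), columns are traits.
    Returns (R, p); constant traits yield NaN entries (flagged by NaN).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if len(genotype_means) < 3:
        raise ValueError("need at least 3 genotypes")
    traits = list(genotype_means.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = genotype_means[traits[i]].to_numpy(dtype=float)
            y = genotype_means[traits[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            elif method == "pearson":
                rij, pij = stats.pearsonr(x, y)
            else:
                rij, pij = stats.spearmanr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )
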