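"""Split-plot linear mixed model for field traits.

The field design applies treatment to whole plots (rows of blocks) within
an environment, with every genotype replicated once per block.  The model
is

    trait ~ Genotype * Environment * Treatment + (1 | Plot)

with plots nested in treatment x environment.  The single plot variance
component is estimated by restricted maximum likelihood, profiled over the
variance ratio theta = sigma2_plot / sigma2_residual (all other quantities
have closed forms given theta, via Woodbury identities on cross-products,
so each profile evaluation costs only a q x q solve for q plots).

Fixed terms are tested with Type II sums of squares from nested
generalized-least-squares fits at the estimated variance components: each
term is compared against the model holding every term that does not
contain it.  The random plot effect is tested by a REML likelihood ratio
against the plot-free model on the 1/2 chi2_0 + 1/2 chi2_1 mixture.
Denominator degrees of freedom follow the containment rule by default
(whole-plot terms - those involving only Environment and Treatment - are
tested in the plot stratum); a pure-residual convention is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SplitPlotDesign",
    "ModelFit",
    "fit_split_plot",
    "lsmeans",
    "dunnett_vs_control",
    "tukey_all_pairs",
    "env_correlations",
    "compact_letter_display",
]

FACTORS = ("genotype", "environment", "treatment")
#: model terms in marginality order, as tuples of factor names
TERMS: tuple[tuple[str, ...], ...] = (
    ("genotype",),
    ("environment",),
    ("treatment",),
    ("genotype", "environment"),
    ("genotype", "treatment"),
    ("environment", "treatment"),
    ("genotype", "environment", "treatment"),
)
#: terms constant within a plot; tested in the plot stratum (containment)
WHOLE_PLOT_TERMS = {("environment",), ("treatment",), ("environment", "treatment")}


@dataclass(frozen=True)
class SplitPlotDesign:
    """Factor sizes of the split-plot field trial.

    Defaults reproduce the published layout: 17 genotypes, 3 environments,
    2 treatments, 2 plots per environment x treatment and 10 blocks per
    plot, i.e. 40 blocks per environment, 120 blocks and 12 plots in all,
    with every genotype exactly once per block.
    """

    n_genotypes: int = 17
    n_environments: int = 3
    n_treatments: int = 2
    plots_per_env_treatment: int = 2
    blocks_per_plot: int = 10

    def __post_init__(self) -> None:
        for name in (
            "n_genotypes", "n_environments", "n_treatments",
            "plots_per_env_treatment", "blocks_per_plot",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_plots(self) -> int:
        return (
            self.n_environments * self.n_treatments
            * self.plots_per_env_treatment
        )

    @property
    def n_blocks(self) -> int:
        return self.n_plots * self.blocks_per_plot

    @property
    def blocks_per_environment(self) -> int:
        return (
            self.n_treatments * self.plots_per_env_treatment
            * self.blocks_per_plot
        )

    @property
    def n_plants(self) -> int:
        return self.n_blocks * self.n_genotypes

    def genotype_labels(self) -> list[str]:
        from .pathway_model import TABLE2_GENOTYPE_NAMES

        if self.n_genotypes <= len(TABLE2_GENOTYPE_NAMES):
            return list(TABLE2_GENOTYPE_NAMES[: self.n_genotypes])
        extra = [
            f"G{i:02d}" for i in range(self.n_genotypes - len(TABLE2_GENOTYPE_NAMES))
        ]
        return list(TABLE2_GENOTYPE_NAMES) + extra

    def layout(self) -> pd.DataFrame:
        """One row per plant: environment, treatment, plot, block, genotype."""
        rows = []
        genotypes = self.genotype_labels()
        plot_id = 0
        for e in range(self.n_environments):
            env = f"ENV{e + 1}"
            for t in range(self.n_treatments):
                trt = ("control", "pesticide")[t % 2]
                for _ in range(self.plots_per_env_treatment):
                    plot_id += 1
                    for b in range(self.blocks_per_plot):
                        block = f"P{plot_id:02d}B{b + 1:02d}"
                        for g in genotypes:
                            rows.append(
                                (env, trt, f"P{plot_id:02d}", block, g)
                            )
        return pd.DataFrame(
            rows, columns=["environment", "treatment", "plot", "block", "genotype"]
        )


@dataclass
class ModelFit:
    """Fitted split-plot model: ANOVA table, variance components, coefs."""

    trait: str
    anova: pd.DataFrame  # per fixed term: df, SS, MS, F, p, denom_df
    var_plot: float
    var_residual: float
    theta: float
    plot_lrt_chi2: float
    plot_lrt_p: float
    converged: bool
    n_obs: int
    residual_df: int
    plot_df: int
    denominator: str
    # internals for marginal means / contrasts
    beta: np.ndarray = field(repr=False, default=None)
    cov_beta: np.ndarray = field(repr=False, default=None)
    cell_rows: np.ndarray = field(repr=False, default=None)
    cell_index: pd.DataFrame = field(repr=False, default=None)
    profile: dict = field(repr=False, default_factory=dict)


def _dummies(series: pd.Series, levels: list) -> np.ndarray:
    """Drop-first treatment coding."""
    arr = np.zeros((len(series), len(levels) - 1))
    codes = pd.Categorical(series, categories=levels).codes
    for j in range(1, len(levels)):
        arr[:, j - 1] = codes == j
    return arr


def _build_design(data: pd.DataFrame, levels: dict[str, list]):
    """Full-factorial fixed-effect matrix with treatment coding.

    Returns (X, column_term_ids) where column_term_ids[j] is the index into
    TERMS of the term owning column j (-1 for the intercept).
    """
    base = {f: _dummies(data[f], levels[f]) for f in FACTORS}
    cols = [np.ones((len(data), 1))]
    owners = [-1]
    for ti, term in enumerate(TERMS):
        mats = [base[f] for f in term]
        m = mats[0]
        for other in mats[1:]:
            m = np.einsum("ij,ik->ijk", m, other).reshape(len(data), -1)
        cols.append(m)
        owners.extend([ti] * m.shape[1])
    return np.hstack(cols), np.array(owners)


class _RemlProblem:
    """Cross-product cache for profiled REML with one variance component."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.XtX = X.T @ X
        self.XtZ = X.T @ Z
        self.ZtZ = Z.T @ Z
        self.Xty = X.T @ y
        self.Zty = Z.T @ y
        self.yty = float(y @ y)

    def gls_pieces(self, theta: float):
        """(X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V|) at V = I + theta ZZ'."""
        if theta == 0.0:
            return self.XtX, self.Xty, self.yty, 0.0
        A = np.eye(self.q) + theta * self.ZtZ
        Ainv_ZtX = np.linalg.solve(A, self.XtZ.T)
        Ainv_Zty = np.linalg.solve(A, self.Zty)
        XtVX = self.XtX - theta * self.XtZ @ Ainv_ZtX
        XtVy = self.Xty - theta * self.XtZ @ Ainv_Zty
        ytVy = self.yty - theta * float(self.Zty @ Ainv_Zty)
        sign, logdetV = np.linalg.slogdet(A)
        return XtVX, XtVy, ytVy, logdetV

    def neg2_reml(self, theta: float) -> float:
        XtVX, XtVy, ytVy, logdetV = self.gls_pieces(theta)
        beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
        rss = ytVy - float(beta @ XtVy)
        nmp = self.n - np.linalg.matrix_rank(XtVX)
        sigma2 = rss / nmp
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return (
            nmp * (1.0 + np.log(2 * np.pi * sigma2))
            + logdetV
            + logdet_XtVX
        )

    def rss_rank(self, theta: float, cols: np.ndarray):
        """Weighted RSS and rank for the column subset at fixed theta."""
        XtVX, XtVy, ytVy, _ = self.gls_pieces(theta)
        sub = XtVX[np.ix_(cols, cols)]
        suby = XtVy[cols]
        beta, _, rank, _ = np.linalg.lstsq(sub, suby, rcond=None)
        return ytVy - float(beta @ suby), int(rank)


def fit_split_plot(
    data: pd.DataFrame,
    trait: str,
    denominator: str = "containment",
    theta_max: float = 1e4,
    fix_theta: float | None = None,
) -> ModelFit:
    """Fit the split-plot mixed model for one trait and build its ANOVA.

    ``data`` needs columns genotype, environment, treatment, plot and the
    trait; rows with a missing trait are dropped.  ``denominator`` selects
    the F-test denominator df convention for whole-plot terms:
    "containment" (plot stratum) or "residual".  ``fix_theta`` pins the
    plot/residual variance ratio instead of profiling it (0 gives the
    ordinary least-squares analysis).
    """
    if denominator not in ("containment", "residual"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    df = data.dropna(subset=[trait]).copy()
    if len(df) == 0:
        raise ValueError("no non-missing observations")
    y = df[trait].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError(f"trait {trait!r} is constant")
    levels = {f: sorted(df[f].unique()) for f in FACTORS}
    per_cell = df.groupby(["environment", "treatment"], observed=True)["plot"]
    if (per_cell.nunique() < 2).any():
        raise ValueError(
            "need >= 2 plots per environment x treatment to separate the "
            "plot variance from treatment effects"
        )
    X, owners = _build_design(df, levels)
    plots = sorted(df["plot"].unique())
    Z = _dummies(df["plot"], ["__none__"] + plots)  # full indicator, q cols
    prob = _RemlProblem(y, X, Z)

    # one-dimensional REML profile over the variance ratio
    f0 = prob.neg2_reml(0.0)
    if fix_theta is not None:
        if fix_theta < 0:
            raise ValueError("fix_theta must be >= 0")
        theta = float(fix_theta)
        fopt = prob.neg2_reml(theta)
        converged = True
        nfev = 1
    else:
        res = optimize.minimize_scalar(
            prob.neg2_reml,
            bounds=(0.0, theta_max),
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(res.x) if res.fun < f0 else 0.0
        fopt = min(float(res.fun), f0)
        converged = bool(res.success)
        nfev = int(res.nfev)

    XtVX, XtVy, ytVy, _ = prob.gls_pieces(theta)
    beta, _, rank_full, _ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
    rss_full = ytVy - float(beta @ XtVy)
    n = len(y)
    resid_df = n - rank_full
    sigma2 = rss_full / resid_df
    var_plot = theta * sigma2
    cov_beta = sigma2 * np.linalg.pinv(XtVX)

    lrt = max(f0 - fopt, 0.0)
    plot_p = 0.5 * float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0

    # plot-stratum denominator: plots minus whole-plot fixed effects
    wp_cols = np.array([
        owners[j] == -1 or TERMS[owners[j]] in WHOLE_PLOT_TERMS
        for j in range(X.shape[1])
    ])
    rank_wp = np.linalg.matrix_rank(XtVX[np.ix_(wp_cols, wp_cols)])
    plot_df = max(prob.q - rank_wp, 1)

    rows = []
    all_cols = np.arange(X.shape[1])
    for ti, term in enumerate(TERMS):
        # Type II: compare against the model with every non-containing term
        keep = np.array([
            owners[j] == -1
            or not set(term) <= set(TERMS[owners[j]])
            or owners[j] == ti
            for j in all_cols
        ])
        without = keep & (owners != ti)
        rss_with, rank_with = prob.rss_rank(theta, np.flatnonzero(keep))
        rss_wo, rank_wo = prob.rss_rank(theta, np.flatnonzero(without))
        ss = max(rss_wo - rss_with, 0.0)
        term_df = rank_with - rank_wo
        ms = ss / term_df if term_df else np.nan
        fstat = ms / sigma2 if term_df else np.nan
        if denominator == "containment" and term in WHOLE_PLOT_TERMS:
            den_df = plot_df
        else:
            den_df = resid_df
        pval = float(stats.f.sf(fstat, term_df, den_df)) if term_df else np.nan
        rows.append({
            "term": ":".join(f.capitalize() for f in term),
            "df": term_df,
            "SS": ss,
            "MS": ms,
            "F": fstat,
            "p": pval,
            "denom_df": den_df,
        })
    anova = pd.DataFrame(rows).set_index("term")

    # cell grid for marginal means
    cells = pd.DataFrame(
        list(itertools.product(*[levels[f] for f in FACTORS])),
        columns=list(FACTORS),
    )
    cell_rows, _ = _build_design(cells, levels)

    return ModelFit(
        trait=trait,
        anova=anova,
        var_plot=var_plot,
        var_residual=sigma2,
        theta=theta,
        plot_lrt_chi2=lrt,
        plot_lrt_p=plot_p,
        converged=converged,
        n_obs=n,
        residual_df=resid_df,
        plot_df=plot_df,
        denominator=denominator,
        beta=beta,
        cov_beta=cov_beta,
        cell_rows=cell_rows,
        cell_index=cells,
        profile={"neg2_reml": fopt, "neg2_reml_theta0": f0,
                 "optimizer": {"success": converged, "nit": nfev}},
    )


def _lsmean_contrasts(fit: ModelFit, factors: tuple[str, ...]):
    """Equal-weight marginal contrast rows, one per level combination."""
    cells = fit.cell_index
    groups = cells.groupby(list(factors), observed=True, sort=True)
    labels, rows = [], []
    for name, idx in groups.groups.items():
        c = fit.cell_rows[np.asarray(idx)].mean(axis=0)
        labels.append(name if isinstance(name, tuple) else (name,))
        rows.append(c)
    return labels, np.array(rows)


def lsmeans(fit: ModelFit, factors: str | tuple[str, ...]) -> pd.DataFrame:
    """Model-based marginal means (LSMeans) with standard errors.

    Predictions for each level of ``factors`` averaged over all levels of
    the remaining fixed factors with equal weights; on balanced complete
    data these equal arithmetic cell means.
    """
    if isinstance(factors, str):
        factors = (factors,)
    unknown = set(factors) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors {unknown}")
    labels, C = _lsmean_contrasts(fit, tuple(factors))
    est = C @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, fit.cov_beta, C))
    out = pd.DataFrame(labels, columns=list(factors))
    out["lsmean"] = est
    out["se"] = se
    return out


def dunnett_vs_control(
    fit: ModelFit,
    factor: str = "genotype",
    control: str = "Col-0",
    method: str = "simulation",
    reps: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Many-to-one comparisons of LSMeans against a control level.

    simulation: family-wise adjusted p from the joint normal distribution
    of the standardized contrasts (correlation from the fitted coefficient
    covariance; ``seed`` required).  bonferroni: raw two-sided t p-values
    multiplied by the number of comparisons, capped at 1.
    """
    labels, C = _lsmean_contrasts(fit, (factor,))
    names = [l[0] for l in labels]
    if control not in names:
        raise ValueError(f"control level {control!r} not present")
    ci = names.index(control)
    keep = [i for i in range(len(names)) if i != ci]
    L = C[keep] - C[ci]
    est = L @ fit.beta
    cov = L @ fit.cov_beta @ L.T
    se = np.sqrt(np.diag(cov))
    tstat = est / se
    raw = 2 * stats.t.sf(np.abs(tstat), fit.residual_df)
    k = len(keep)
    if method == "bonferroni":
        adj = np.minimum(raw * k, 1.0)
    elif method == "simulation":
        if seed is None:
            raise ValueError("simulation method requires a seed")
        corr = cov / np.outer(se, se)
        rng = np.random.default_rng(seed)
        # eigen square root tolerates the deficient rank of k contrasts
        w, V = np.linalg.eigh(corr)
        root = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        draws = rng.standard_normal((reps, k)) @ root.T
        maxabs = np.abs(draws).max(axis=1)
        adj = np.array([
            (np.count_nonzero(maxabs >= abs(t)) + 1) / (reps + 1)
            for t in tstat
        ])
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({
        factor: [names[i] for i in keep],
        "estimate": est,
        "se": se,
        "t": tstat,
        "p_raw": raw,
        "p_adjusted": adj,
    })


def tukey_all_pairs(
    fit: ModelFit, factor: str = "genotype", alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise LSMean comparisons with studentized-range adjustment.

    Returns the pairwise table and a compact letter display: levels that
    share a letter are not significantly different at ``alpha``.
    """
    labels, C = _lsmean_contrasts(fit, (factor,))
    names = [l[0] for l in labels]
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    sig_pairs = []
    for i, j in itertools.combinations(range(k), 2):
        c = C[i] - C[j]
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        t = est / se
        p = float(stats.studentized_range.sf(
            abs(t) * np.sqrt(2), k, fit.residual_df
        ))
        rows.append({
            "level_1": names[i], "level_2": names[j],
            "estimate": est, "se": se, "t": t, "p_adjusted": p,
        })
        if p <= alpha:
            sig_pairs.append((names[i], names[j]))
    letters = compact_letter_display(names, sig_pairs)
    return pd.DataFrame(rows), letters


def compact_letter_display(
    levels: list[str], significant_pairs: list[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment from significant pairs."""
    groups: list[set[str]] = [set(levels)]
    for a, b in significant_pairs:
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            ga, gb = g - {a}, g - {b}
            for new in (ga, gb):
                if new and not any(new <= other for other in groups):
                    groups.append(new)
    groups = [g for g in groups if not any(
        g < other for other in groups if g is not other
    )]
    groups.sort(key=lambda g: sorted(levels.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lvl: "" for lvl in levels}
    for gi, g in enumerate(groups):
        letter = alphabet[gi % len(alphabet)] * (gi // len(alphabet) + 1)
        for lvl in g:
            out[lvl] += letter
    return out


def env_correlations(
    genotype_env_means: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise between-environment correlations of genotype means.

    ``genotype_env_means`` is indexed by (environment, genotype); each
    environment pair is correlated over the genotypes they share (>= 3).
    """
    wide = genotype_env_means.unstack(level="environment")
    envs = list(wide.columns)
    rows = []
    for e1, e2 in itertools.combinations(envs, 2):
        sub = wide[[e1, e2]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 shared genotypes for {e1}/{e2}")
        x, y = sub[e1].to_numpy(), sub[e2].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("constant genotype means in an environment")
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"env_1": e1, "env_2": e2, "R": r, "p": p,
                     "n": len(sub)})
    return pd.DataFrame(rows)
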