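"""Synthetic field trials and accession panels.

Every analysis stage in this package is exercised on generated data with
the statistical structure the field experiment assumes:

* :func:`generate_trial` emulates the split-plot trial — one plant of each
  genotype per block, blocks nested in plots, plots in treatment x
  environment — with additive genotype / environment / treatment /
  genotype-x-environment / plot / residual effects on the log scale for
  fruit count (fitness is non-negative and right-skewed), normal silique
  length, Bernoulli survival, an ordinal 0-10 leaf-damage score from a
  thresholded latent normal, and GSL profiles from the forward pathway
  model under multiplicative lognormal noise.  The genotype-by-environment
  standard deviation is the fluctuating-selection knob.

* :func:`generate_accession_panel` emulates a collection of natural inbred
  accessions: multi-locus haplotypes drawn from per-locus allele
  frequencies under linkage equilibrium (optionally enriched for chosen
  haplotypes), expanded to GSL profiles via the forward model plus noise,
  with the true genotypes emitted alongside.

All randomness flows from a mandatory integer seed; identical seeds give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .field_model import SplitPlotDesign
from .haplotype_caller import MINUS, PLUS
from .pathway_model import (
    DEFAULT_PARAMS,
    STRUCTURES,
    GslGenotype,
    GslProfile,
    PathwayParams,
    predict_profile,
)

__all__ = [
    "TrialConfig",
    "PanelConfig",
    "generate_trial",
    "generate_accession_panel",
    "profiles_to_frame",
]

#: per-trait effect sizes: (genotype SD, environment SD, treatment SD,
#: genotype x environment SD, plot SD, residual SD)
_DEFAULT_TRAIT_SD = {
    # log-scale effects; exp(mu)=100 fruits, strong G and GxE, weak T
    "log_tfc": dict(mu=np.log(100.0), genotype=0.25, environment=0.10,
                    treatment=0.02, gxe=0.25, plot=0.05, residual=0.45),
    # mm; modest genotype differences
    "silique_length": dict(mu=12.0, genotype=0.8, environment=0.3,
                           treatment=0.05, gxe=0.5, plot=0.2, residual=1.5),
    # latent scale for the 0-10 damage score
    "leaf_damage_latent": dict(mu=1.8, genotype=0.5, environment=0.8,
                               treatment=0.1, gxe=0.6, plot=0.3, residual=1.2),
    # days to flower
    "flowering_time": dict(mu=28.0, genotype=2.0, environment=3.0,
                           treatment=0.2, gxe=1.5, plot=0.5, residual=3.0),
}


@dataclass(frozen=True)
class TrialConfig:
    """Design sizes, per-trait effect SDs and GSL noise for one trial."""

    design: SplitPlotDesign = field(default_factory=SplitPlotDesign)
    trait_sd: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_TRAIT_SD.items()
    })
    survival_rate: float = 0.9
    survival_gxe_logit_sd: float = 0.5
    gsl_noise_cv: float = 0.2
    # per-environment multiplicative scaling of total aliphatic GSL
    env_gsl_scale: tuple[float, ...] = (1.0, 0.8, 1.2)
    pathway_params: PathwayParams = DEFAULT_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival_rate <= 1.0:
            raise ValueError("survival_rate must be in [0, 1]")
        if self.gsl_noise_cv < 0:
            raise ValueError("gsl_noise_cv must be >= 0")
        for trait, sds in self.trait_sd.items():
            for k, v in sds.items():
                if k != "mu" and v < 0:
                    raise ValueError(f"{trait}.{k} must be >= 0")
        if len(self.env_gsl_scale) < self.design.n_environments:
            raise ValueError("need one GSL scale per environment")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv**2)))


def generate_trial(config: TrialConfig) -> pd.DataFrame:
    """Simulate one split-plot field trial; one row per plant.

    Columns: design coordinates, tfc, silique_length, survival,
    leaf_damage, flowering_time, fitness-ready measurements, plus one
    column per GSL structure (pmol/mm^2).  Non-survivors carry missing
    tfc/silique/GSL values.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    tbl = design.layout()
    genotypes = design.genotype_labels()
    envs = sorted(tbl["environment"].unique())
    trts = sorted(tbl["treatment"].unique())
    plots = sorted(tbl["plot"].unique())

    gi = tbl["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    ei = tbl["environment"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    ti = tbl["treatment"].map({t: i for i, t in enumerate(trts)}).to_numpy()
    pi = tbl["plot"].map({p: i for i, p in enumerate(plots)}).to_numpy()
    n = len(tbl)

    def trait_values(name: str) -> np.ndarray:
        sd = config.trait_sd[name]
        g = rng.normal(0, sd["genotype"], len(genotypes))
        e = rng.normal(0, sd["environment"], len(envs))
        t = rng.normal(0, sd["treatment"], len(trts))
        ge = rng.normal(0, sd["gxe"], (len(genotypes), len(envs)))
        p = rng.normal(0, sd["plot"], len(plots))
        eps = rng.normal(0, sd["residual"], n)
        return sd["mu"] + g[gi] + e[ei] + t[ti] + ge[gi, ei] + p[pi] + eps

    tfc = np.round(np.exp(trait_values("log_tfc")))
    silique = np.clip(trait_values("silique_length"), 1.0, None)
    latent = trait_values("leaf_damage_latent")
    leaf_damage = np.clip(np.round(latent), 0, 10).astype(int)
    flowering = np.clip(trait_values("flowering_time"), 1.0, None)

    base_logit = np.log(config.survival_rate / (1 - config.survival_rate)) \
        if config.survival_rate < 1 else np.inf
    ge_logit = rng.normal(0, config.survival_gxe_logit_sd,
                          (len(genotypes), len(envs)))
    p_surv = 1.0 / (1.0 + np.exp(-(base_logit + ge_logit[gi, ei]))) \
        if np.isfinite(base_logit) else np.ones(n)
    survival = (rng.random(n) < p_surv).astype(int)

    # GSL profiles: forward-model means x environment scale x lognormal noise
    from .pathway_model import genotype_from_name

    struct_ids = list(STRUCTURES)
    mean_mat = np.zeros((len(genotypes), len(struct_ids)))
    for i, g in enumerate(genotypes):
        try:
            geno = genotype_from_name(g)
        except ValueError:
            geno = genotype_from_name("Col-0")
            geno = replace(geno, label=g)
        prof = predict_profile(geno, config.pathway_params)
        for j, sid in enumerate(struct_ids):
            mean_mat[i, j] = prof.get(sid)
    sigma = _lognormal_sigma(config.gsl_noise_cv)
    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, (n, len(struct_ids)))) \
        if sigma > 0 else np.ones((n, len(struct_ids)))
    env_scale = np.asarray(config.env_gsl_scale)[ei]
    gsl = mean_mat[gi] * env_scale[:, None] * noise

    out = tbl.copy()
    out["tfc"] = tfc
    out["silique_length"] = silique
    out["survival"] = survival
    out["leaf_damage"] = leaf_damage
    out["flowering_time"] = flowering
    for j, sid in enumerate(struct_ids):
        out[sid] = gsl[:, j]
    dead = out["survival"] == 0
    out.loc[dead, ["tfc", "silique_length"] + struct_ids] = np.nan
    return out


# ---------------------------------------------------------------------------
# accession panels

#: default functional-allele frequencies for panel simulation (AOP is the
#: three-state locus); deliberately intermediate, as natural GSL variation is
_DEFAULT_LOCUS_FREQS: dict[str, dict[str, float]] = {
    "MYB28": {PLUS: 0.95, MINUS: 0.05},
    "MYB29": {PLUS: 0.90, MINUS: 0.10},
    "MAM1": {PLUS: 0.60, MINUS: 0.40},
    "GSOX": {PLUS: 0.90, MINUS: 0.10},
    "AOP": {"AOP2": 0.40, "AOP3": 0.25, "null": 0.35},
    "GSOH": {PLUS: 0.60, MINUS: 0.40},
}
PANEL_LOCI = tuple(_DEFAULT_LOCUS_FREQS)


@dataclass(frozen=True)
class PanelConfig:
    """Accession-panel simulation settings (n defaults to the 144 panel)."""

    n_accessions: int = 144
    locus_freqs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_LOCUS_FREQS.items()
    })
    # multiplies the linkage-equilibrium probability of chosen full
    # haplotypes (keyed by state tuple over PANEL_LOCI); renormalized
    enrichment: dict = field(default_factory=dict)
    noise_cv: float = 0.2
    field_mode: bool = False  # panels are chamber-grown by default
    pathway_params: PathwayParams = DEFAULT_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("n_accessions must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for locus, dist in self.locus_freqs.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9 or min(dist.values()) < 0:
                raise ValueError(f"{locus}: frequencies must sum to 1, >= 0")
        for mult in self.enrichment.values():
            if mult < 0:
                raise ValueError("enrichment multipliers must be >= 0")


def _haplotype_space(locus_freqs: dict) -> tuple[list[tuple[str, ...]], np.ndarray]:
    import itertools

    loci = list(locus_freqs)
    states = [list(locus_freqs[l].items()) for l in loci]
    keys, probs = [], []
    for combo in itertools.product(*states):
        keys.append(tuple(s for s, _ in combo))
        probs.append(float(np.prod([p for _, p in combo])))
    return keys, np.asarray(probs)


def _haplotype_to_genotype(hap: tuple[str, ...], label: str) -> GslGenotype:
    """Expand a six-locus haplotype to a concrete nine-gene genotype.

    A non-functional GSOX locus is realized as a gsox1 knockout (the choice
    is phenotypically irrelevant: the forward model keys on the locus).
    """
    h = dict(zip(PANEL_LOCI, hap))
    return GslGenotype(
        label=label,
        myb28=h["MYB28"] == PLUS,
        myb29=h["MYB29"] == PLUS,
        mam1=h["MAM1"] == PLUS,
        gsox1=h["GSOX"] == PLUS,
        gsox3=True,
        aop2=h["AOP"] == "AOP2",
        aop3=h["AOP"] == "AOP3",
        gsoh=h["GSOH"] == PLUS,
        esp=False,
    )


def generate_accession_panel(
    config: PanelConfig,
) -> tuple[list[GslProfile], pd.DataFrame]:
    """Simulate accession GSL profiles plus the true haplotype table.

    Haplotypes are drawn from the product of per-locus frequencies, with
    optional enrichment multipliers applied to chosen haplotypes before
    renormalization; profiles come from the forward model under
    multiplicative lognormal noise (CV = ``noise_cv``).
    """
    rng = np.random.default_rng(config.seed)
    keys, probs = _haplotype_space(config.locus_freqs)
    if config.enrichment:
        probs = probs.copy()
        index = {k: i for i, k in enumerate(keys)}
        for hap, mult in config.enrichment.items():
            if hap not in index:
                raise ValueError(f"enriched haplotype {hap} not in state space")
            probs[index[hap]] *= mult
        probs = probs / probs.sum()
    draws = rng.choice(len(keys), size=config.n_accessions, p=probs)

    params = config.pathway_params.with_field_mode(config.field_mode)
    sigma = _lognormal_sigma(config.noise_cv)
    profiles: list[GslProfile] = []
    truth_rows = []
    for i, d in enumerate(draws):
        label = f"ACC{i + 1:03d}"
        geno = _haplotype_to_genotype(keys[d], label)
        mean = predict_profile(geno, params)
        conc = {}
        for sid, v in mean.concentrations.items():
            if sigma > 0:
                v = v * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            conc[sid] = v
        profiles.append(GslProfile(concentrations=conc, sample_id=label))
        truth_rows.append(
            {"sample_id": label, **dict(zip(PANEL_LOCI, keys[d])),
             "allele_string": geno.allele_string}
        )
    return profiles, pd.DataFrame(truth_rows)


def profiles_to_frame(profiles: list[GslProfile]) -> pd.DataFrame:
    """Sample x structure concentration table (absent structures are 0)."""
    struct_ids = list(STRUCTURES)
    rows = [
        {"sample_id": p.sample_id, **{s: p.get(s) for s in struct_ids}}
        for p in profiles
    ]
    return pd.DataFrame(rows).set_index("sample_id")
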