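"""Multi-locus haplotype frequencies under the linkage-equilibrium null.

From a panel of seven-locus haplotype calls this module estimates
single-locus allele frequencies (NA excluded), derives the expected
multi-locus haplotype distribution as the product of per-locus marginals
(the no-selection, no-structure null), and tests observed against expected
counts with a global chi-squared statistic plus per-haplotype binomial
deviations.

Haplotypes are keyed on observable states: loci hidden by epistasis carry
NA, and the expected mass of an NA-keyed haplotype is the sum over its
expansions.  The collapse of full multi-locus states onto observable keys
mirrors the caller's epistasis rules, so the observable cells partition
the state space and the expected distribution sums to one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .haplotype_caller import LOCI, MINUS, NA, PLUS, HaplotypeCall

__all__ = [
    "AlleleFrequencies",
    "FreqTestResult",
    "allele_frequencies",
    "expected_haplotype_frequencies",
    "observed_vs_expected_test",
    "observable_collapse",
]

# states a locus can take in a full (uncollapsed) multi-locus genotype
LOCUS_STATES: dict[str, tuple[str, ...]] = {
    "MYB28": (PLUS, MINUS),
    "MYB29": (PLUS, MINUS),
    "MAM1": (PLUS, MINUS),
    "GSOX": (PLUS, MINUS),
    "AOP": ("AOP2", "AOP3", "null"),
    "GSOH": (PLUS, MINUS),
    "ESP": (PLUS, MINUS),
}


@dataclass
class AlleleFrequencies:
    """Per-locus state distributions estimated from non-NA calls.

    ``dist[locus]`` maps each observed state to its frequency; ``n[locus]``
    is the number of informative (non-NA) calls behind it.  Loci with zero
    informative calls appear in ``undefined``.
    """

    dist: dict[str, dict[str, float]]
    n: dict[str, int]
    undefined: tuple[str, ...] = ()
    n_panel: int = 0

    def functional(self, locus: str) -> float:
        """Frequency of the functional allele (AOP: AOP2 or AOP3)."""
        d = self.dist[locus]
        if locus == "AOP":
            return d.get("AOP2", 0.0) + d.get("AOP3", 0.0)
        return d.get(PLUS, 0.0)


def allele_frequencies(calls: list[HaplotypeCall]) -> AlleleFrequencies:
    """Single-locus state frequencies; NA calls are excluded per locus."""
    if not calls:
        raise ValueError("empty panel")
    dist: dict[str, dict[str, float]] = {}
    n: dict[str, int] = {}
    undefined = []
    for i, locus in enumerate(LOCI):
        counts: dict[str, int] = {}
        for call in calls:
            state = call.key()[i]
            if state == NA:
                continue
            counts[state] = counts.get(state, 0) + 1
        total = sum(counts.values())
        n[locus] = total
        if total == 0:
            undefined.append(locus)
            dist[locus] = {}
        else:
            dist[locus] = {s: c / total for s, c in counts.items()}
    return AlleleFrequencies(
        dist=dist, n=n, undefined=tuple(undefined), n_panel=len(calls)
    )


def observable_collapse(state: dict[str, str]) -> tuple[str, ...]:
    """Project a full multi-locus state onto its observable haplotype key.

    Epistasis rules: a myb28 myb29 double null hides MAM1, GSOX, AOP and
    GSOH; GSOH is hidden unless AOP carries the AOP2 allele in a
    4C-dominant (functional MAM1) background, since only that combination
    produces its but-3-enyl substrate; ESP is never observable from the
    intact profile.
    """
    s = dict(state)
    if s["MYB28"] == MINUS and s["MYB29"] == MINUS:
        for locus in ("MAM1", "GSOX", "AOP", "GSOH"):
            s[locus] = NA
    if s["AOP"] != "AOP2" or s["MAM1"] != PLUS:
        s["GSOH"] = NA
    s["ESP"] = NA
    return tuple(s[locus] for locus in LOCI)


def expected_haplotype_frequencies(
    freqs: AlleleFrequencies,
    loci: tuple[str, ...] = LOCI,
    collapse=observable_collapse,
) -> dict[tuple[str, ...], float]:
    """Expected haplotype distribution under independence of loci.

    Enumerates the product space of per-locus states, assigns each full
    state the product of its marginal frequencies, and aggregates through
    ``collapse`` so that NA-keyed (epistatically hidden) haplotypes receive
    the summed mass of their expansions.  Loci not in ``loci`` (or with
    undefined frequencies, e.g. the never-observable ESP) are fixed at NA.
    """
    active = [
        locus for locus in loci
        if locus not in freqs.undefined and freqs.dist.get(locus)
    ]
    for locus in active:
        total = sum(freqs.dist[locus].values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"{locus}: frequencies sum to {total}, not 1")
    expected: dict[tuple[str, ...], float] = {}
    state_sets = [list(freqs.dist[locus].items()) for locus in active]
    for combo in itertools.product(*state_sets):
        full = {locus: NA for locus in LOCI}
        p = 1.0
        for locus, (state, prob) in zip(active, combo):
            full[locus] = state
            p *= prob
        key = collapse(full) if collapse is not None else tuple(
            full[locus] for locus in LOCI
        )
        expected[key] = expected.get(key, 0.0) + p
    return expected


@dataclass
class FreqTestResult:
    observed: dict[tuple[str, ...], int]
    expected: dict[tuple[str, ...], float]  # expected counts, sum = n_panel
    global_chi2: float
    global_df: int
    global_p: float
    per_haplotype: dict[tuple[str, ...], dict] = field(default_factory=dict)
    n_panel: int = 0
    mode: str = "asymptotic"
    mc_reps: int = 0
    seed: int | None = None
    infinite_cells: tuple[tuple[str, ...], ...] = ()


def _chi2_stat(obs: np.ndarray, exp: np.ndarray) -> float:
    mask = exp > 0
    return float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())


def _freqs_from_counts(
    keys: list[tuple[str, ...]], counts: np.ndarray
) -> AlleleFrequencies:
    """Allele frequencies from haplotype-key counts (NA excluded)."""
    dist: dict[str, dict[str, float]] = {}
    n: dict[str, int] = {}
    undefined = []
    for i, locus in enumerate(LOCI):
        c: dict[str, float] = {}
        for key, cnt in zip(keys, counts):
            if key[i] != NA and cnt:
                c[key[i]] = c.get(key[i], 0) + int(cnt)
        total = sum(c.values())
        n[locus] = int(total)
        if total == 0:
            undefined.append(locus)
            dist[locus] = {}
        else:
            dist[locus] = {s: v / total for s, v in c.items()}
    return AlleleFrequencies(
        dist=dist, n=n, undefined=tuple(undefined),
        n_panel=int(counts.sum()),
    )


def _refit_chi2_stats(
    keys: list[tuple[str, ...]], sims: np.ndarray, n: int,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Chi-squared statistics of resampled panels with re-fitted null.

    Vectorized parametric bootstrap: for each resampled panel the per-locus
    state frequencies and the induced expected counts are re-derived before
    the statistic is computed.  For a haplotype inside the null support the
    collapsed expectation equals the product of the marginal frequencies of
    its non-NA states (the sum over its expansions); keys outside the
    support (``support`` False) are unreachable under the null and carry
    zero expectation.
    """
    if support is None:
        support = np.ones(len(keys), dtype=bool)
    keys = [k for k, s in zip(keys, support) if s]
    sims = sims[:, support]
    # enumerate the (locus, state) pairs present in the key set
    pairs: list[tuple[int, str]] = sorted(
        {(i, k[i]) for k in keys for i in range(len(LOCI)) if k[i] != NA}
    )
    pair_index = {p: j for j, p in enumerate(pairs)}
    n_keys, n_pairs = len(keys), len(pairs)
    # membership[k, j] = 1 if key k contains pair j
    membership = np.zeros((n_keys, n_pairs))
    for ki, k in enumerate(keys):
        for i in range(len(LOCI)):
            if k[i] != NA:
                membership[ki, pair_index[(i, k[i])]] = 1.0
    # per-locus normalizer: columns of the same locus share a denominator
    locus_of_pair = np.array([p[0] for p in pairs])
    state_counts = sims @ membership  # (reps, n_pairs)
    locus_totals = np.zeros_like(state_counts)
    for i in np.unique(locus_of_pair):
        cols = locus_of_pair == i
        locus_totals[:, cols] = state_counts[:, cols].sum(
            axis=1, keepdims=True
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(locus_totals > 0, state_counts / locus_totals, 0.0)
        log_freqs = np.where(freqs > 0, np.log(freqs), -np.inf)
        # -inf stays -inf through the product only where membership == 1
        log_e = np.where(
            (membership[None, :, :] * np.isneginf(log_freqs)[:, None, :]).any(
                axis=2
            ),
            -np.inf,
            np.nan_to_num(log_freqs, neginf=0.0) @ membership.T,
        )
        e = n * np.exp(log_e)  # (reps, n_keys)
        contrib = np.where(e > 0, (sims - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    return contrib.sum(axis=1)


def observed_vs_expected_test(
    observed: dict[tuple[str, ...], int],
    expected: dict[tuple[str, ...], float] | AlleleFrequencies,
    n: int | None = None,
    mode: str = "montecarlo",
    reps: int = 10_000,
    seed: int | None = None,
    refit_frequencies: bool = True,
) -> FreqTestResult:
    """Goodness-of-fit of observed haplotype counts to the independence null.

    ``expected`` is either a probability distribution over haplotype keys
    (summing to 1) or an :class:`AlleleFrequencies`, in which case the
    expected distribution is derived here.  All cells with positive
    expectation enter the global statistic, unobserved ones with O = 0.

    mode="asymptotic" refers the statistic to a chi-squared distribution
    with df = (#cells with E > 0) - 1 - (#estimated locus frequencies);
    mode="montecarlo" (default; ``seed`` required) resamples panels from
    the expected distribution, re-deriving the allele frequencies and the
    expected distribution on every resample when ``refit_frequencies`` is
    set, which makes the resampled statistic an honest parametric
    bootstrap of the fitted null.

    Per-haplotype deviations use a two-sided binomial test on each cell,
    reported raw (used for the over/under classification) and
    Bonferroni-adjusted.
    """
    if mode not in ("asymptotic", "montecarlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(expected, AlleleFrequencies):
        n_estimated = sum(
            max(len(expected.dist[locus]) - 1, 0) for locus in LOCI
        )
        expected_dist = expected_haplotype_frequencies(expected)
    else:
        expected_dist = dict(expected)
        n_estimated = 0
    if n is None:
        n = sum(observed.values())
    if n <= 0:
        raise ValueError("panel size n must be > 0")
    total_p = sum(expected_dist.values())
    if not math.isclose(total_p, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"expected distribution sums to {total_p}, not 1")

    keys = sorted(set(expected_dist) | set(observed))
    exp = np.array([expected_dist.get(k, 0.0) * n for k in keys])
    obs = np.array([float(observed.get(k, 0)) for k in keys])
    infinite = tuple(
        k for k, e, o in zip(keys, exp, obs) if e == 0 and o > 0
    )

    chi2 = _chi2_stat(obs, exp)
    n_cells = int((exp > 0).sum())
    df = max(n_cells - 1 - n_estimated, 1)

    if mode == "asymptotic":
        p = float(stats.chi2.sf(chi2, df))
        if infinite:
            p = 0.0  # impossible cells observed: flagged, null rejected
        mc_reps = 0
    else:
        if seed is None:
            raise ValueError("montecarlo mode requires a seed")
        rng = np.random.default_rng(seed)
        probs = exp / exp.sum()
        sims = rng.multinomial(n, probs, size=reps).astype(float)
        if refit_frequencies:
            stats_sim = _refit_chi2_stats(keys, sims, n, support=exp > 0)
        else:
            mask = exp > 0
            stats_sim = (
                (sims[:, mask] - exp[mask]) ** 2 / exp[mask]
            ).sum(axis=1)
        p = float((np.count_nonzero(stats_sim >= chi2 - 1e-12) + 1)
                  / (reps + 1))
        mc_reps = reps

    per_hap: dict[tuple[str, ...], dict] = {}
    n_tests = len(keys)
    for k, e, o in zip(keys, exp, obs):
        cell_p = expected_dist.get(k, 0.0)
        if cell_p > 0:
            raw = float(stats.binomtest(int(o), n, cell_p).pvalue)
        else:
            raw = 0.0 if o > 0 else 1.0
        direction = "over" if o > e else ("under" if o < e else "none")
        per_hap[k] = {
            "observed": int(o),
            "expected": float(e),
            "direction": direction,
            "p_raw": raw,
            "p_bonferroni": min(1.0, raw * n_tests),
        }

    return FreqTestResult(
        observed={k: int(observed.get(k, 0)) for k in keys},
        expected={k: float(e) for k, e in zip(keys, exp)},
        global_chi2=chi2,
        global_df=df,
        global_p=p,
        per_haplotype=per_hap,
        n_panel=n,
        mode=mode,
        mc_reps=mc_reps,
        seed=seed,
        infinite_cells=infinite,
    )
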