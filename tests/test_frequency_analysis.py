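"""Allele frequencies, linkage-equilibrium expectations, chi-squared test."""

import itertools

import numpy as np
import pytest

from glucotype import (
    allele_frequencies,
    expected_haplotype_frequencies,
    observed_vs_expected_test,
    round_trip,
)
from glucotype.frequency_analysis import (
    AlleleFrequencies,
    observable_collapse,
)
from glucotype.haplotype_caller import LOCI, MINUS, NA, PLUS, AlleleCall, HaplotypeCall
from glucotype.pathway_model import TABLE2_GENOTYPES


def _call(states: dict) -> HaplotypeCall:
    base = {
        "MYB28": PLUS, "MYB29": PLUS, "MAM1": PLUS, "GSOX": PLUS,
        "AOP": "null", "GSOH": NA, "ESP": NA,
    }
    base.update(states)
    calls = {}
    for locus in LOCI:
        s = base[locus]
        if locus == "AOP":
            sub = s
            state = NA if s == NA else (MINUS if s == "null" else PLUS)
            calls[locus] = AlleleCall(
                state, evidence="" if state == NA else "x", sub=sub
            )
        else:
            calls[locus] = AlleleCall(s, evidence="" if s == NA else "x")
    return HaplotypeCall(calls=calls)


class TestAlleleFrequencies:
    def test_all_plus_gives_one(self):
        calls = [_call({}) for _ in range(10)]
        freqs = allele_frequencies(calls)
        assert freqs.functional("MYB28") == 1.0
        assert freqs.n["MYB28"] == 10

    def test_na_excluded_from_both_sides(self):
        calls = (
            [_call({"MAM1": PLUS}) for _ in range(4)]
            + [_call({"MAM1": MINUS}) for _ in range(4)]
            + [_call({"MAM1": NA}) for _ in range(2)]
        )
        freqs = allele_frequencies(calls)
        assert freqs.functional("MAM1") == 0.5
        assert freqs.n["MAM1"] == 8

    def test_uninformative_locus_flagged(self):
        calls = [_call({}) for _ in range(3)]
        freqs = allele_frequencies(calls)
        assert "ESP" in freqs.undefined

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            allele_frequencies([])

    def test_table2_gsoh_frequency(self):
        """12 of the 17 laboratory genotypes carry a functional GSOH."""
        from glucotype.haplotype_caller import expected_call

        plus = sum(g.gsoh for g in TABLE2_GENOTYPES.values())
        assert plus == 12
        assert plus / 17 == pytest.approx(12 / 17)


class TestExpectedFrequencies:
    def test_two_loci_half_half(self):
        freqs = AlleleFrequencies(
            dist={
                "MYB28": {PLUS: 0.5, MINUS: 0.5},
                "MYB29": {PLUS: 0.5, MINUS: 0.5},
            },
            n={"MYB28": 10, "MYB29": 10},
        )
        exp = expected_haplotype_frequencies(
            freqs, loci=("MYB28", "MYB29"), collapse=None
        )
        on = {k: v for k, v in exp.items()}
        assert len(on) == 4
        assert all(v == pytest.approx(0.25) for v in on.values())

    def test_three_locus_hand_product(self):
        freqs = AlleleFrequencies(
            dist={
                "MYB28": {PLUS: 0.9, MINUS: 0.1},
                "MYB29": {PLUS: 0.5, MINUS: 0.5},
                "MAM1": {PLUS: 0.2, MINUS: 0.8},
            },
            n={"MYB28": 10, "MYB29": 10, "MAM1": 10},
        )
        exp = expected_haplotype_frequencies(
            freqs, loci=("MYB28", "MYB29", "MAM1"), collapse=None
        )
        key = tuple(
            {"MYB28": PLUS, "MYB29": MINUS, "MAM1": MINUS}.get(l, NA)
            for l in LOCI
        )
        assert exp[key] == pytest.approx(0.9 * 0.5 * 0.8)

    def test_distribution_sums_to_one_with_collapse(self):
        dist = {
            "MYB28": {PLUS: 0.9, MINUS: 0.1},
            "MYB29": {PLUS: 0.8, MINUS: 0.2},
            "MAM1": {PLUS: 0.6, MINUS: 0.4},
            "GSOX": {PLUS: 0.9, MINUS: 0.1},
            "AOP": {"AOP2": 0.4, "AOP3": 0.2, "null": 0.4},
            "GSOH": {PLUS: 0.5, MINUS: 0.5},
        }
        freqs = AlleleFrequencies(dist=dist, n={l: 100 for l in dist})
        exp = expected_haplotype_frequencies(freqs)
        assert sum(exp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_collapsed_mass_equals_sum_of_expansions(self):
        """An NA-keyed haplotype inherits the mass of its hidden states."""
        dist = {
            "MYB28": {PLUS: 0.7, MINUS: 0.3},
            "MYB29": {PLUS: 0.8, MINUS: 0.2},
            "MAM1": {PLUS: 0.6, MINUS: 0.4},
            "GSOX": {PLUS: 0.9, MINUS: 0.1},
            "AOP": {"AOP2": 0.4, "AOP3": 0.2, "null": 0.4},
            "GSOH": {PLUS: 0.5, MINUS: 0.5},
        }
        freqs = AlleleFrequencies(dist=dist, n={l: 100 for l in dist})
        exp = expected_haplotype_frequencies(freqs)
        # the fully-hidden double-MYB-knockout cell collects p28- * p29-
        hidden = tuple(
            {"MYB28": MINUS, "MYB29": MINUS}.get(l, NA) for l in LOCI
        )
        assert exp[hidden] == pytest.approx(0.3 * 0.2)
        # a null-AOP cell marginalizes GSOH
        cell = {
            "MYB28": PLUS, "MYB29": PLUS, "MAM1": PLUS, "GSOX": PLUS,
            "AOP": "null", "GSOH": NA, "ESP": NA,
        }
        key = tuple(cell[l] for l in LOCI)
        assert exp[key] == pytest.approx(0.7 * 0.8 * 0.6 * 0.9 * 0.4)

    def test_undefined_locus_is_marginalized(self):
        freqs = AlleleFrequencies(
            dist={"MYB28": {PLUS: 1.0}, "MYB29": {}},
            n={"MYB28": 5, "MYB29": 0},
            undefined=("MYB29",),
        )
        exp = expected_haplotype_frequencies(
            freqs, loci=("MYB28", "MYB29"), collapse=None
        )
        assert sum(exp.values()) == pytest.approx(1.0)


class TestChiSquared:
    def _two_state_keys(self):
        a = tuple(PLUS if l == "MYB28" else NA for l in LOCI)
        b = tuple(MINUS if l == "MYB28" else NA for l in LOCI)
        return a, b

    def test_perfect_fit_gives_zero(self):
        a, b = self._two_state_keys()
        res = observed_vs_expected_test(
            {a: 5, b: 5}, {a: 0.5, b: 0.5}, mode="asymptotic"
        )
        assert res.global_chi2 == 0
        assert res.global_p == pytest.approx(1.0)
        assert all(v["direction"] == "none" for v in res.per_haplotype.values())

    def test_hand_computed_statistic(self):
        a, b = self._two_state_keys()
        res = observed_vs_expected_test(
            {a: 8, b: 2}, {a: 0.5, b: 0.5}, mode="asymptotic"
        )
        assert res.global_chi2 == pytest.approx(3.6)
        assert res.per_haplotype[a]["direction"] == "over"
        assert res.per_haplotype[b]["direction"] == "under"

    def test_bruteforce_oracle_small_panels(self):
        """Global statistic equals an explicit loop over all cells."""
        rng = np.random.default_rng(7)
        loci = ("MYB28", "MYB29", "MAM1", "GSOX")
        for trial in range(5):
            p = rng.uniform(0.2, 0.8, size=4)
            dist = {
                l: {PLUS: p[i], MINUS: 1 - p[i]} for i, l in enumerate(loci)
            }
            freqs = AlleleFrequencies(dist=dist, n={l: 50 for l in loci})
            exp = expected_haplotype_frequencies(freqs, loci=loci, collapse=None)
            n = 60
            counts = rng.multinomial(n, list(exp.values()))
            observed = dict(zip(exp.keys(), (int(c) for c in counts)))
            res = observed_vs_expected_test(
                observed, exp, mode="asymptotic"
            )
            # independent oracle: enumerate the 16 cells by hand
            chi2 = 0.0
            for states in itertools.product([PLUS, MINUS], repeat=4):
                key = tuple(
                    dict(zip(loci, states)).get(l, NA) for l in LOCI
                )
                e = n * np.prod([
                    dist[l][s] for l, s in zip(loci, states)
                ])
                o = observed.get(key, 0)
                chi2 += (o - e) ** 2 / e
            assert res.global_chi2 == pytest.approx(chi2)

    def test_montecarlo_reproducible_and_valid(self):
        a, b = self._two_state_keys()
        r1 = observed_vs_expected_test(
            {a: 8, b: 2}, {a: 0.5, b: 0.5}, mode="montecarlo",
            reps=2000, seed=11, refit_frequencies=False,
        )
        r2 = observed_vs_expected_test(
            {a: 8, b: 2}, {a: 0.5, b: 0.5}, mode="montecarlo",
            reps=2000, seed=11, refit_frequencies=False,
        )
        assert r1.global_p == r2.global_p
        # binomial(10, .5) two-sided tail for 8/2 is ~0.109
        assert 0.03 < r1.global_p < 0.25

    def test_impossible_cell_flagged(self):
        a, b = self._two_state_keys()
        c = tuple(PLUS if l == "MYB29" else NA for l in LOCI)
        res = observed_vs_expected_test(
            {a: 5, b: 3, c: 2}, {a: 0.5, b: 0.5}, mode="asymptotic"
        )
        assert c in res.infinite_cells
        assert res.global_p == 0.0

    def test_montecarlo_requires_seed(self):
        a, b = self._two_state_keys()
        with pytest.raises(ValueError, match="seed"):
            observed_vs_expected_test(
                {a: 5, b: 5}, {a: 0.5, b: 0.5}, mode="montecarlo", seed=None
            )

    def test_expected_counts_sum_to_panel(self):
        a, b = self._two_state_keys()
        res = observed_vs_expected_test(
            {a: 7, b: 3}, {a: 0.6, b: 0.4}, mode="asymptotic"
        )
        assert sum(res.expected.values()) == pytest.approx(res.n_panel)
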