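"""Inverse inference: GSL profile -> seven-locus haplotype call.

Assigns a functional (+), non-functional (-) or NA state at the seven GSL
loci (MYB28, MYB29, MAM1, GSOX, AOP, GSOH, ESP) from a leaf GSL profile.
NA means "unobservable due to epistasis": e.g. GSOH acts on but-3-enyl,
which only exists when AOP2 is functional, so GSOH cannot be scored in an
AOP-null background; and nothing downstream of the MYBs can be scored in a
myb28 myb29 double knockout, which makes no aliphatic GSL at all.

The AOP locus carries a sub-state (AOP2 / AOP3 / null / NA) because its two
alternate alleles produce chemically distinct products.  ESP acts on GSL
activation products, not the intact profile, and is always reported NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .pathway_model import (
    DEFAULT_PARAMS,
    STRUCTURES,
    GslGenotype,
    GslProfile,
    PathwayParams,
    predict_profile,
    total_aliphatic,
)

__all__ = [
    "PLUS", "MINUS", "NA",
    "LOCI",
    "AlleleCall",
    "HaplotypeCall",
    "CallerThresholds",
    "call_haplotype",
    "haplotype_name",
    "expected_call",
    "round_trip",
]

PLUS, MINUS, NA = "+", "-", "NA"
LOCI = ("MYB28", "MYB29", "MAM1", "GSOX", "AOP", "GSOH", "ESP")

# Col-0 reference state used for canonical haplotype names
_COL0_STATE = {
    "MYB28": PLUS, "MYB29": PLUS, "MAM1": PLUS, "GSOX": PLUS,
    "AOP": MINUS,  # null at both AOP2 and AOP3
    "GSOH": PLUS, "ESP": MINUS,
}
_NAME_TOKENS = {
    ("MYB28", MINUS): "myb28",
    ("MYB29", MINUS): "myb29",
    ("MAM1", MINUS): "gsm1",
    ("GSOX", MINUS): "gsox",
    ("GSOH", MINUS): "gsoh",
    ("ESP", PLUS): "ESP",
}


@dataclass
class AlleleCall:
    state: str  # PLUS | MINUS | NA
    evidence: str = ""
    sub: str | None = None  # AOP locus only: AOP2 | AOP3 | null | NA

    def __post_init__(self) -> None:
        if self.state not in (PLUS, MINUS, NA):
            raise ValueError(f"invalid allele state {self.state!r}")
        if self.state != NA and not self.evidence:
            raise ValueError("evidence required for a definite call")


@dataclass
class HaplotypeCall:
    calls: dict[str, AlleleCall]
    name: str = ""
    chemotype: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if tuple(sorted(self.calls)) != tuple(sorted(LOCI)):
            raise ValueError(f"calls must cover exactly the loci {LOCI}")

    def state(self, locus: str) -> str:
        return self.calls[locus].state

    @property
    def aop_sub(self) -> str:
        return self.calls["AOP"].sub or NA

    def key(self) -> tuple[str, ...]:
        """Hashable state tuple (AOP keyed by sub-state) for frequency work."""
        return tuple(
            self.aop_sub if locus == "AOP" else self.calls[locus].state
            for locus in LOCI
        )


@dataclass(frozen=True)
class CallerThresholds:
    """Numeric decision thresholds (artifact choices; units pmol/mm^2).

    ``amount_breaks`` separate the 0 / 50% / 75% / 100% total-aliphatic
    classes as fractions of ``reference_total`` (Col-0-equivalent total);
    the defaults are midpoints between the calibrated class ratios.
    """

    detection_limit: float = 0.5
    dominance_ratio: float = 2.0
    amount_breaks: tuple[float, float, float] = (0.05, 0.625, 0.875)
    reference_total: float | None = None

    def __post_init__(self) -> None:
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.dominance_ratio <= 1:
            raise ValueError("dominance_ratio must be > 1")
        b = self.amount_breaks
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("amount_breaks must be strictly increasing in (0,1)")
        if self.reference_total is not None and self.reference_total <= 0:
            raise ValueError("reference_total must be > 0")


DEFAULT_THRESHOLDS = CallerThresholds(
    reference_total=DEFAULT_PARAMS.reference_total_aliphatic
)


def _present(profile: GslProfile, sid: str, limit: float) -> bool:
    return profile.get(sid) >= limit


def call_haplotype(
    profile: GslProfile, thresholds: CallerThresholds = DEFAULT_THRESHOLDS
) -> HaplotypeCall:
    """Assign the seven-locus haplotype for one GSL profile.

    Decision rules, in order:

    1. aliphatic total below detection -> myb28- myb29-, downstream loci NA;
    2. total-aliphatic class vs the reference separates MYB28/MYB29 calls,
       with absence of long-chain GSL (while short chains are present)
       forcing MYB28 non-functional;
    3. MAM1 from 3C vs 4C dominance (derived structures count toward their
       precursor chain class);
    4. AOP sub-state from alkenyl / OH-propyl products, null when MSO
       dominates with neither;
    5. GSOH from OH-but-3-enyl, scorable only when but-3-enyl exists;
    6. GSOX from residual MT structures;
    7. ESP is never observable from the intact profile.
    """
    ref = thresholds.reference_total
    if ref is None or ref <= 0:
        raise ValueError(
            "thresholds.reference_total must be a positive Col-0-equivalent "
            "total aliphatic"
        )
    lim = thresholds.detection_limit
    calls: dict[str, AlleleCall] = {}

    total = total_aliphatic(profile)
    ratio = total / ref

    # chain-class totals; products count toward their precursor class
    c3 = sum(
        profile.get(s) for s in ("3MSO", "3MT", "Allyl", "OH-Propyl")
    )
    c4 = sum(
        profile.get(s)
        for s in ("4MSO", "4MT", "But-3-enyl", "OH-But-3-enyl")
    )
    long_total = sum(profile.get(s) for s in ("5MSO", "6MSO", "7MSO", "8MSO"))
    long_present = long_total >= lim
    short_present = (c3 + c4) >= lim

    if total < max(lim, thresholds.amount_breaks[0] * ref):
        # rule 1: below detection -> double MYB knockout, downstream NA
        ev = f"total aliphatic {total:.3g} below detection"
        calls["MYB28"] = AlleleCall(MINUS, ev)
        calls["MYB29"] = AlleleCall(MINUS, ev)
        for locus in ("MAM1", "GSOX", "GSOH"):
            calls[locus] = AlleleCall(NA)
        calls["AOP"] = AlleleCall(NA, sub=NA)
        calls["ESP"] = AlleleCall(NA)
        return _finish(calls, profile, ratio, thresholds)

    # rule 2: MYB pair from long-chain presence and the amount class
    b0, b1, b2 = thresholds.amount_breaks
    if ratio < b1:
        amount_class = "50%"
    elif ratio < b2:
        amount_class = "75%"
    else:
        amount_class = "100%"

    myb28_long = PLUS if long_present else (MINUS if short_present else NA)
    myb28_amount = MINUS if amount_class == "50%" else PLUS
    if myb28_long == myb28_amount or myb28_long == NA:
        state = myb28_amount if myb28_long == NA else myb28_long
        calls["MYB28"] = AlleleCall(
            state,
            f"long-chain {'present' if long_present else 'absent'}, "
            f"aliphatic class {amount_class}",
        )
        myb29 = {"50%": PLUS, "75%": MINUS, "100%": PLUS}[amount_class]
        if state == MINUS and amount_class != "50%":
            # long-chain says myb28-, but the total is not in the 50% class
            calls["MYB29"] = AlleleCall(NA)
        else:
            calls["MYB29"] = AlleleCall(myb29, f"aliphatic class {amount_class}")
    else:
        # conflicting evidence: tie -> NA, not a guess
        calls["MYB28"] = AlleleCall(NA)
        calls["MYB29"] = AlleleCall(NA)

    # rule 3: MAM1 from chain-length dominance
    if c4 >= thresholds.dominance_ratio * max(c3, lim / 10):
        calls["MAM1"] = AlleleCall(PLUS, f"4C {c4:.3g} dominates 3C {c3:.3g}")
    elif c3 >= thresholds.dominance_ratio * max(c4, lim / 10):
        calls["MAM1"] = AlleleCall(MINUS, f"3C {c3:.3g} dominates 4C {c4:.3g}")
    else:
        calls["MAM1"] = AlleleCall(NA)

    # rule 4: AOP sub-state from modification products
    alkenyl = any(
        _present(profile, s, lim)
        for s in ("Allyl", "But-3-enyl", "OH-But-3-enyl")
    )
    ohp = _present(profile, "OH-Propyl", lim)
    mso_short = profile.get("3MSO") + profile.get("4MSO")
    if alkenyl:
        calls["AOP"] = AlleleCall(PLUS, "alkenyl GSL present", sub="AOP2")
    elif ohp:
        calls["AOP"] = AlleleCall(PLUS, "OH-propyl GSL present", sub="AOP3")
    elif mso_short >= lim:
        calls["AOP"] = AlleleCall(MINUS, "MSO dominates, no conversion products",
                                  sub="null")
    else:
        calls["AOP"] = AlleleCall(NA, sub=NA)

    # rule 5: GSOH needs its but-3-enyl substrate (i.e. functional AOP2)
    butenyl = _present(profile, "But-3-enyl", lim)
    oh_butenyl = _present(profile, "OH-But-3-enyl", lim)
    if oh_butenyl:
        calls["GSOH"] = AlleleCall(PLUS, "OH-but-3-enyl present")
    elif butenyl:
        calls["GSOH"] = AlleleCall(MINUS, "but-3-enyl present, no OH product")
    else:
        calls["GSOH"] = AlleleCall(NA)

    # rule 6: GSOX from MT accumulation
    mt = any(_present(profile, s, lim) for s in ("3MT", "4MT"))
    informative = mso_short >= lim or alkenyl
    if mt:
        calls["GSOX"] = AlleleCall(MINUS, "MT GSL accumulates")
    elif informative:
        calls["GSOX"] = AlleleCall(PLUS, "MSO/alkenyl present without MT")
    else:
        calls["GSOX"] = AlleleCall(NA)

    # rule 7
    calls["ESP"] = AlleleCall(NA)

    return _finish(calls, profile, ratio, thresholds)


def _finish(
    calls: dict[str, AlleleCall],
    profile: GslProfile,
    ratio: float,
    thresholds: CallerThresholds,
) -> HaplotypeCall:
    hap = HaplotypeCall(calls=calls, sample_id=profile.sample_id)
    hap.chemotype = _chemotype(hap, profile, ratio, thresholds)
    hap.name = haplotype_name(hap)
    return hap


def _chemotype(
    hap: HaplotypeCall,
    profile: GslProfile,
    ratio: float,
    thresholds: CallerThresholds,
) -> str:
    b0, b1, b2 = thresholds.amount_breaks
    if ratio < b0:
        return "0"
    amount = "50%" if ratio < b1 else ("75%" if ratio < b2 else "100%")
    chain = {PLUS: "4C", MINUS: "3C", NA: "NA"}[hap.state("MAM1")]
    lim = thresholds.detection_limit
    if _present(profile, "OH-But-3-enyl", lim):
        mod = "OH-alkenyl"
    elif _present(profile, "OH-Propyl", lim):
        mod = "OH-propyl"
    elif _present(profile, "Allyl", lim) or _present(profile, "But-3-enyl", lim):
        mod = "alkenyl"
    else:
        mod = "MSO"
    return f"{chain}-{mod}-{amount}"


def haplotype_name(call: HaplotypeCall) -> str:
    """Canonical Col-0-referenced name; depends on states only.

    Deviations from the Col-0 state are listed in locus order (lowercase for
    loss of function, AOP2/AOP3/ESP for gain); NA is rendered explicitly as
    e.g. "GSOH(NA)", except at ESP where NA is the uninformative norm.  A
    call matching Col-0 at every locus is named "Col-0".
    """
    tokens: list[str] = []
    for locus in LOCI:
        state = call.state(locus)
        if locus == "AOP":
            sub = call.aop_sub
            if sub in ("AOP2", "AOP3"):
                tokens.append(sub)
            elif sub == NA:
                tokens.append("AOP(NA)")
            continue  # null is the Col-0 reference state
        if state == NA:
            if locus != "ESP":
                tokens.append(f"{locus}(NA)")
            continue
        if state != _COL0_STATE[locus]:
            tokens.append(_NAME_TOKENS[(locus, state)])
    return "/".join(tokens) if tokens else "Col-0"


def expected_call(
    genotype: GslGenotype, field_mode: bool = False
) -> dict[str, str]:
    """Observable locus states implied by a true genotype (epistasis rules).

    The AOP entry is the sub-state (AOP2/AOP3/null/NA).  GSOH needs its
    but-3-enyl substrate, which exists only when AOP2 is functional AND the
    4C class dominates (functional MAM1): in a 3C background AOP2 makes
    allyl instead, so GSOH stays hidden.  GSOX is only observable in
    chamber mode, where MT accumulates when either GSOX gene is knocked
    out; the locus-level state is functional iff both genes are.
    """
    if not genotype.myb28 and not genotype.myb29:
        return {
            "MYB28": MINUS, "MYB29": MINUS,
            "MAM1": NA, "GSOX": NA, "AOP": NA, "GSOH": NA, "ESP": NA,
        }
    gsoh_visible = genotype.aop2 and genotype.mam1
    exp = {
        "MYB28": PLUS if genotype.myb28 else MINUS,
        "MYB29": PLUS if genotype.myb29 else MINUS,
        "MAM1": PLUS if genotype.mam1 else MINUS,
        "AOP": "AOP2" if genotype.aop2 else ("AOP3" if genotype.aop3 else "null"),
        "GSOH": (PLUS if genotype.gsoh else MINUS) if gsoh_visible else NA,
        "ESP": NA,
    }
    if field_mode:
        exp["GSOX"] = PLUS  # MT never accumulates in the field
    else:
        exp["GSOX"] = PLUS if (genotype.gsox1 and genotype.gsox3) else MINUS
    return exp


def round_trip(
    genotype: GslGenotype,
    params: PathwayParams = DEFAULT_PARAMS,
    thresholds: CallerThresholds | None = None,
    field_mode: bool = False,
) -> dict:
    """Forward-predict a profile, call it back, and score per-locus agreement.

    A locus matches when the call equals the expected observable state (NA
    exactly where epistasis makes the true allele invisible).  Defaults to
    chamber mode, where the GSOX locus is informative.
    """
    params = params.with_field_mode(field_mode)
    if thresholds is None:
        thresholds = CallerThresholds(
            reference_total=params.reference_total_aliphatic
        )
    profile = predict_profile(genotype, params)
    call = call_haplotype(profile, thresholds)
    expected = expected_call(genotype, field_mode=field_mode)
    per_locus = {}
    for locus in LOCI:
        got = call.aop_sub if locus == "AOP" else call.state(locus)
        per_locus[locus] = {
            "expected": expected[locus],
            "called": got,
            "match": got == expected[locus],
        }
    return {
        "genotype": genotype.label,
        "per_locus": per_locus,
        "n_match": sum(v["match"] for v in per_locus.values()),
        "n_loci": len(LOCI),
        "all_match": all(v["match"] for v in per_locus.values()),
        "call": call,
    }
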