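"""Forward model of aliphatic glucosinolate (GSL) chemotypes.

Maps a multi-locus genotype over the eight manipulated GSL genes (MYB28,
MYB29, MAM1, GSOX1, GSOX3, AOP2, AOP3, GSOH, ESP; AOP2/AOP3 are alternate
alleles of the single AOP locus) to the leaf GSL profile it produces.

The model is deliberately rule based rather than kinetic: the MYB
transcription factors scale the aliphatic class pools multiplicatively,
MAM1 decides which short chain-length class (3C vs 4C) dominates, and the
side-chain modification enzymes (AOP2/AOP3, GSOH, GSOX1/3) redistribute
mass within a chain class without changing the aliphatic total.  Indole
GSLs are carried as a passive pool that no aliphatic gene touches.

Default parameters are calibrated so that, relative to wild-type Col-0,
the myb28 single knockout retains 50% and the myb29 knockout 75% of total
aliphatic GSL, and any myb28 knockout loses the long-chain pool entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GslGenotype",
    "GslStructure",
    "GslProfile",
    "PathwayParams",
    "STRUCTURES",
    "ALIPHATIC_STRUCTURES",
    "INDOLE_STRUCTURES",
    "TABLE2_GENOTYPES",
    "genotype_from_name",
    "genotype_from_allele_string",
    "predict_structures",
    "predict_profile",
    "total_aliphatic",
    "total_indole",
]

ALLELE_ORDER = (
    "myb28", "myb29", "mam1", "gsox1", "gsox3", "aop2", "aop3", "gsoh", "esp",
)


@dataclass(frozen=True)
class GslStructure:
    """One GSL chemical structure (canonical short name)."""

    id: str
    chain_class: str  # short3C | short4C | long | indole
    mod_class: str    # MT | MSO | alkenyl | OH-alkenyl | OH-propyl | indole

    def __post_init__(self) -> None:
        if (self.chain_class == "indole") != (self.mod_class == "indole"):
            raise ValueError(
                f"{self.id}: chain_class is indole iff mod_class is indole"
            )


def _registry() -> dict[str, GslStructure]:
    structs = [
        # methylsulfinyl (MSO)
        GslStructure("3MSO", "short3C", "MSO"),
        GslStructure("4MSO", "short4C", "MSO"),
        GslStructure("5MSO", "long", "MSO"),
        GslStructure("6MSO", "long", "MSO"),
        GslStructure("7MSO", "long", "MSO"),
        GslStructure("8MSO", "long", "MSO"),
        # methylthio (MT) precursors, only seen when GSOX activity is reduced
        GslStructure("3MT", "short3C", "MT"),
        GslStructure("4MT", "short4C", "MT"),
        # alkenyl and hydroxylated products
        GslStructure("Allyl", "short3C", "alkenyl"),
        GslStructure("But-3-enyl", "short4C", "alkenyl"),
        GslStructure("OH-But-3-enyl", "short4C", "OH-alkenyl"),
        GslStructure("OH-Propyl", "short3C", "OH-propyl"),
        # indoles (passive pool)
        GslStructure("I3M", "indole", "indole"),
        GslStructure("4MI3M", "indole", "indole"),
        GslStructure("NMI3M", "indole", "indole"),
    ]
    return {s.id: s for s in structs}


STRUCTURES: dict[str, GslStructure] = _registry()
ALIPHATIC_STRUCTURES = tuple(
    s.id for s in STRUCTURES.values() if s.chain_class != "indole"
)
INDOLE_STRUCTURES = tuple(
    s.id for s in STRUCTURES.values() if s.chain_class == "indole"
)

# how the long-chain pool splits across 5-8C MSO; 8MSO dominates (the only
# long structure the literature quantifies), the rest are trace fractions
_LONG_WEIGHTS = {"5MSO": 0.10, "6MSO": 0.10, "7MSO": 0.20, "8MSO": 0.60}


@dataclass(frozen=True)
class GslGenotype:
    """Allelic state (functional / non-functional) at the eight GSL genes.

    ``True`` means a functional allele.  At most one of ``aop2``/``aop3``
    may be functional: they are alternate alleles at the single AOP locus
    and Col-0 is null at both.
    """

    label: str
    myb28: bool
    myb29: bool
    mam1: bool
    gsox1: bool
    gsox3: bool
    aop2: bool
    aop3: bool
    gsoh: bool
    esp: bool

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("genotype label must be non-empty")
        if self.aop2 and self.aop3:
            raise ValueError(
                f"{self.label}: AOP2 and AOP3 are alternate alleles of one "
                "locus; at most one can be functional"
            )

    @property
    def allele_string(self) -> str:
        """Ordered +/- string over the nine genes (see ALLELE_ORDER)."""
        return "".join("+" if getattr(self, g) else "-" for g in ALLELE_ORDER)


@dataclass
class GslProfile:
    """Leaf GSL concentrations (pmol/mm^2) keyed by structure id."""

    concentrations: dict[str, float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        for sid, amount in self.concentrations.items():
            if sid not in STRUCTURES:
                raise ValueError(f"unknown GSL structure id: {sid!r}")
            if amount < 0:
                raise ValueError(f"{sid}: negative concentration {amount}")

    def get(self, sid: str) -> float:
        if sid not in STRUCTURES:
            raise ValueError(f"unknown GSL structure id: {sid!r}")
        return self.concentrations.get(sid, 0.0)

    def nonzero_structures(self) -> set[str]:
        return {s for s, v in self.concentrations.items() if v > 0}


@dataclass(frozen=True)
class PathwayParams:
    """Tunable parameters of the forward model.

    Pools are wild-type class totals in pmol/mm^2 leaf; multipliers are the
    fraction of a class pool RETAINED after loss of function of the given
    MYB; conversions are the fraction of precursor converted by a
    functional modification enzyme.
    """

    base_short3C: float = 3.0
    base_short4C: float = 17.0
    base_long: float = 2.0
    # retained fractions under loss of function, calibrated so that the
    # aliphatic totals of myb28 / myb29 are 50% / 75% of Col-0
    myb28_short_mult: float = 0.55
    myb28_long_mult: float = 0.0
    myb29_short_mult: float = 0.725
    myb29_long_mult: float = 1.0
    aop_conversion: float = 1.0
    gsoh_conversion: float = 0.8
    gsox_conversion: float = 0.7
    indole_base: dict[str, float] = field(
        default_factory=lambda: {"I3M": 3.0, "4MI3M": 0.5, "NMI3M": 0.5}
    )
    field_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("base_short3C", "base_short4C", "base_long"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "myb28_short_mult", "myb28_long_mult",
            "myb29_short_mult", "myb29_long_mult",
            "aop_conversion", "gsoh_conversion", "gsox_conversion",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for sid, v in self.indole_base.items():
            if sid not in INDOLE_STRUCTURES:
                raise ValueError(f"indole_base has non-indole structure {sid}")
            if v < 0:
                raise ValueError(f"indole_base[{sid}] must be >= 0")

    @property
    def reference_total_aliphatic(self) -> float:
        """Total aliphatic GSL of wild-type Col-0 under these parameters."""
        return self.base_short3C + self.base_short4C + self.base_long

    def with_field_mode(self, field_mode: bool) -> "PathwayParams":
        return replace(self, field_mode=field_mode)


DEFAULT_PARAMS = PathwayParams()


def genotype_from_name(name: str) -> GslGenotype:
    """Build a genotype from a Col-0-referenced name such as "myb28/AOP2".

    Lowercase tokens knock a gene out relative to Col-0; the gain-of-function
    tokens AOP2, AOP3 and ESP switch the corresponding gene on.  Col-0 itself
    is functional at MYB28, MYB29, MAM1, GSOX1, GSOX3 and GSOH and null at
    AOP2, AOP3 and ESP.  "gsm1" is the historical name of the mam1 knockout.
    """
    state = dict(
        myb28=True, myb29=True, mam1=True, gsox1=True, gsox3=True,
        aop2=False, aop3=False, gsoh=True, esp=False,
    )
    if name != "Col-0":
        for token in name.split("/"):
            key = {
                "myb28": ("myb28", False),
                "myb29": ("myb29", False),
                "gsm1": ("mam1", False),
                "mam1": ("mam1", False),
                "gsox1": ("gsox1", False),
                "gsox3": ("gsox3", False),
                "gsoh": ("gsoh", False),
                "AOP2": ("aop2", True),
                "AOP3": ("aop3", True),
                "ESP": ("esp", True),
            }.get(token)
            if key is None:
                raise ValueError(f"unknown genotype token {token!r} in {name!r}")
            state[key[0]] = key[1]
    return GslGenotype(label=name, **state)


def genotype_from_allele_string(alleles: str, label: str = "") -> GslGenotype:
    """Parse an ordered +/- string over the nine genes (ALLELE_ORDER)."""
    if len(alleles) != len(ALLELE_ORDER) or set(alleles) - {"+", "-"}:
        raise ValueError(
            f"allele string must be {len(ALLELE_ORDER)} of '+'/'-', got {alleles!r}"
        )
    state = {g: c == "+" for g, c in zip(ALLELE_ORDER, alleles)}
    return GslGenotype(label=label or alleles, **state)


# the 17-genotype laboratory population: single, double and triple mutants
# on the Col-0 background recreating natural variation at the seven loci
TABLE2_GENOTYPE_NAMES = (
    "Col-0", "myb28", "myb29", "gsm1", "gsox1", "gsox3",
    "AOP2", "AOP2/gsoh", "gsoh",
    "myb28/gsoh", "myb28/gsm1", "myb28/AOP2",
    "myb29/gsm1", "myb29/AOP2/gsoh",
    "myb28/myb29", "myb28/myb29/gsoh", "ESP",
)
TABLE2_GENOTYPES: dict[str, GslGenotype] = {
    name: genotype_from_name(name) for name in TABLE2_GENOTYPE_NAMES
}


def predict_profile(
    genotype: GslGenotype, params: PathwayParams = DEFAULT_PARAMS
) -> GslProfile:
    """Noise-free mean GSL profile for a genotype.

    Rule order: MYB scaling of the class pools -> MAM1 chain-length split
    (the dominant short class receives base_short4C/(base_short3C +
    base_short4C) of the short pool) -> AOP2/AOP3 and GSOH conversions on
    the dominant-class MSO -> GSOX/MT partition (chamber mode only).
    Conversions redistribute within a chain class, so the aliphatic total
    is untouched by them.
    """
    conc: dict[str, float] = {}

    # --- aliphatic pools under MYB regulation -------------------------------
    short_pool = params.base_short3C + params.base_short4C
    long_pool = params.base_long
    if not genotype.myb28:
        short_pool *= params.myb28_short_mult
        long_pool *= params.myb28_long_mult
    if not genotype.myb29:
        short_pool *= params.myb29_short_mult
        long_pool *= params.myb29_long_mult
    if not genotype.myb28 and not genotype.myb29:
        short_pool = 0.0
        long_pool = 0.0

    # --- chain elongation: MAM1 decides the dominant short class ------------
    base_total_short = params.base_short3C + params.base_short4C
    dom_frac = (
        params.base_short4C / base_total_short if base_total_short > 0 else 0.0
    )
    if genotype.mam1:
        pool_4c = short_pool * dom_frac
        pool_3c = short_pool * (1.0 - dom_frac)
        dominant = "short4C"
    else:
        pool_3c = short_pool * dom_frac
        pool_4c = short_pool * (1.0 - dom_frac)
        dominant = "short3C"

    # --- side-chain modification within each short class --------------------
    mso3, mso4 = pool_3c, pool_4c
    if genotype.aop2:
        # converts MSO of the dominant chain class to the alkenyl product
        if dominant == "short4C":
            converted = mso4 * params.aop_conversion
            mso4 -= converted
            butenyl = converted
            allyl = 0.0
        else:
            converted = mso3 * params.aop_conversion
            mso3 -= converted
            allyl = converted
            butenyl = 0.0
    else:
        allyl = butenyl = 0.0
    if genotype.aop3:
        # acts only on 3C MSO, never on 4MSO
        converted = mso3 * params.aop_conversion
        mso3 -= converted
        conc["OH-Propyl"] = converted
    if genotype.gsoh and butenyl > 0:
        oh = butenyl * params.gsoh_conversion
        butenyl -= oh
        conc["OH-But-3-enyl"] = oh
    conc["Allyl"] = allyl
    conc["But-3-enyl"] = butenyl

    # --- GSOX: in chamber mode a knocked-out GSOX leaves an MT fraction -----
    chamber = not params.field_mode
    if chamber and not (genotype.gsox1 and genotype.gsox3):
        mt_frac = 1.0 - params.gsox_conversion
        conc["3MT"] = mso3 * mt_frac
        conc["4MT"] = mso4 * mt_frac
        mso3 *= params.gsox_conversion
        mso4 *= params.gsox_conversion
    conc["3MSO"] = mso3
    conc["4MSO"] = mso4

    for sid, w in _LONG_WEIGHTS.items():
        conc[sid] = long_pool * w

    # --- indoles: passive pool, always present ------------------------------
    for sid in INDOLE_STRUCTURES:
        conc[sid] = params.indole_base.get(sid, 0.0)

    conc = {sid: v for sid, v in conc.items() if v > 0}
    return GslProfile(concentrations=conc, sample_id=genotype.label)


def predict_structures(
    genotype: GslGenotype,
    field_mode: bool = True,
    params: PathwayParams = DEFAULT_PARAMS,
) -> set[str]:
    """Qualitative chemotype: structure ids with nonzero predicted amount."""
    prof = predict_profile(genotype, params.with_field_mode(field_mode))
    return prof.nonzero_structures()


def total_aliphatic(profile: GslProfile) -> float:
    """Sum of all non-indole GSL structures (pmol/mm^2)."""
    return sum(
        v for sid, v in profile.concentrations.items()
        if STRUCTURES[sid].chain_class != "indole"
    )


def total_indole(profile: GslProfile) -> float:
    """Sum of the indole GSL structures (pmol/mm^2)."""
    return sum(
        v for sid, v in profile.concentrations.items()
        if STRUCTURES[sid].chain_class == "indole"
    )
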