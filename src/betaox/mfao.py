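"""Construction of the mitochondrial beta-oxidation network instance.

The network: a cytosolic activated C16 substrate enters through the
carnitine shuttle (CPT1 -> CACT -> CPT2), then repeated oxidation cycles
shorten the acyl-CoA by two carbons.  Four acyl-CoA dehydrogenases
(VLCAD/LCAD/MCAD/SCAD) with overlapping chain specificity feed two
branches: the trifunctional protein (MTP) lumps hydratase, dehydrogenase
and thiolase for C8+ substrates, while the short-chain branch
(CROT -> M/SCHAD -> MCKAT) covers C4-C16.  Acetyl-CoA is a clamped sink.

Two conserved moieties are declared: mitochondrial free CoA plus all
variable CoA esters, and mitochondrial carnitine plus acyl-carnitine.
Because acetyl-CoA is clamped, reactions that transfer an acetyl unit to
it (MCKAT, MTP) are written with net regeneration of free CoA -- the
acetyl unit leaves the modelled pool carrying no CoA bookkeeping.  This
is the unique stoichiometric convention under which the declared CoA
moiety is exactly conserved *and* nonzero-flux steady states exist; free
CoA still enters those rate laws kinetically as a co-substrate.
"""

from __future__ import annotations

from .core import (
    KineticModel,
    ModelConfigurationError,
    Moiety,
    RateLaw,
    Reaction,
    Species,
)

#: chain lengths handled per enzyme in the full (C16-start) instance
ENZYME_RANGES: dict[str, tuple[int, ...]] = {
    "CPT1": (16,),
    "CACT": (16,),
    "CPT2": (16,),
    "VLCAD": (12, 14, 16),
    "LCAD": (8, 10, 12, 14, 16),
    "MCAD": (4, 6, 8, 10, 12),
    "SCAD": (4, 6),
    "CROT": (4, 6, 8, 10, 12, 14, 16),
    "MSCHAD": (4, 6, 8, 10, 12, 14, 16),
    "MCKAT": (4, 6, 8, 10, 12, 14, 16),
    "MTP": (8, 10, 12, 14, 16),
}

ACYL_DEHYDROGENASES = ("VLCAD", "LCAD", "MCAD", "SCAD")

SUBSTRATE_PARAMETER = "conc_C16AcylCoACYT"


def acyl(n: int) -> str:
    return f"C{n}AcylCoAMAT"


def enoyl(n: int) -> str:
    return f"C{n}EnoylCoAMAT"


def hydroxy(n: int) -> str:
    return f"C{n}HydroxyacylCoAMAT"


def keto(n: int) -> str:
    return f"C{n}KetoacylCoAMAT"


def enzyme_chains(enzyme: str, start_chain: int = 16) -> tuple[int, ...]:
    """Chain lengths an enzyme handles in an instance starting at ``start_chain``."""
    base = ENZYME_RANGES[enzyme]
    if enzyme in ("CPT1", "CACT", "CPT2"):
        return (start_chain,)
    if enzyme in ACYL_DEHYDROGENASES and start_chain < 16:
        # shuttle delivers the start chain; dehydrogenase coverage shifts
        # down with it so every chain keeps at least one dehydrogenase
        return tuple(n for n in base if n <= start_chain)
    return tuple(n for n in base if n <= start_chain)


def _chain_list(start_chain: int) -> list[int]:
    if start_chain % 2 or not 4 <= start_chain <= 16:
        raise ModelConfigurationError(
            f"start chain length {start_chain} not even in [4, 16]"
        )
    return list(range(4, start_chain + 2, 2))


def default_parameters(start_chain: int = 16) -> dict:
    """Curated default parameterization of the full network.

    Values printed in the source study are used verbatim: Keq of M/SCHAD
    (2.17e-4), Keq of CROT (3.13), MCKAT Km for C4-/C6-ketoacyl-CoA
    (12.4 / 6.7 uM) and sf_MCKAT C4/C6 (0.49 / 1).  All other constants
    are plausible defaults tuned so that the instance reproduces the
    qualitative substrate-overload phenotype (flux decline, C4/C6 ester
    accumulation, CoA depletion); they are not the deposited values.
    """
    chains = _chain_list(start_chain)

    def per_chain(values: dict[int, float]) -> dict[int, float]:
        return {n: v for n, v in values.items() if n in chains}

    sub = f"C{start_chain}AcylCoACYT"
    car_c = f"C{start_chain}AcylCarCYT"
    car_m = f"C{start_chain}AcylCarMAT"
    acyl_m = acyl(start_chain)

    p: dict = {
        "start_chain": start_chain,
        "boundary": {
            sub: 0.1,
            "CarCYT": 500.0,
            "CoACYT": 40.0,
            "NADMAT": 250.0,
            "NADHMAT": 15.625,
            "FADMAT": 100.0,
            "FADH2MAT": 10.0,
            "AcetylCoAMAT": 20.0,
        },
        "totals": {"CoA": 2500.0, "Car": 500.0},
        "enzymes": {},
    }
    enz = p["enzymes"]

    enz["CPT1"] = {
        "vmax": 45.0,
        "keq": 0.45,
        "sf": {start_chain: 1.0},
        "km": {sub: 25.0, "CarCYT": 120.0, car_c: 25.0, "CoACYT": 40.0},
    }
    enz["CACT"] = {
        "vmax": 1500.0,
        "keq": 1.0,
        "sf": {start_chain: 1.0},
        "km": {car_c: 15.0, "CarMAT": 500.0, car_m: 15.0, "CarCYT": 500.0},
    }
    enz["CPT2"] = {
        "vmax": 800.0,
        "keq": 2.2,
        "sf": {start_chain: 1.0},
        "km": {car_m: 15.0, "CoAMAT": 250.0, acyl_m: 25.0, "CarMAT": 500.0},
    }

    # low-affinity, moderate-capacity dehydrogenases: standing acyl-CoA
    # pools grow with load and feed the thiolase's competitive site
    dh_keq = 6.0
    dh_specs = {
        "VLCAD": (300.0, {12: 0.6, 14: 0.8, 16: 1.0}, {12: 60.0, 14: 50.0, 16: 40.0}),
        "LCAD": (
            200.0,
            {8: 0.4, 10: 0.65, 12: 0.85, 14: 1.0, 16: 0.75},
            {8: 90.0, 10: 70.0, 12: 60.0, 14: 50.0, 16: 60.0},
        ),
        "MCAD": (
            350.0,
            {4: 0.3, 6: 0.65, 8: 1.0, 10: 0.85, 12: 0.55},
            {4: 150.0, 6: 80.0, 8: 60.0, 10: 60.0, 12: 70.0},
        ),
        "SCAD": (250.0, {4: 1.0, 6: 0.55}, {4: 80.0, 6: 120.0}),
    }
    for name, (vmax, sf, km_acyl) in dh_specs.items():
        rng = enzyme_chains(name, start_chain)
        if not rng:
            continue
        km = {}
        for n in rng:
            km[acyl(n)] = km_acyl.get(n, 60.0)
            km[enoyl(n)] = 0.5 * km_acyl.get(n, 60.0)
        km["FADMAT"] = 50.0
        km["FADH2MAT"] = 25.0
        enz[name] = {
            "vmax": vmax,
            "keq": dh_keq,
            "sf": per_chain(sf),
            "km": km,
        }

    crot_rng = enzyme_chains("CROT", start_chain)
    enz["CROT"] = {
        "vmax": 3000.0,
        "keq": 3.13,  # printed value
        "sf": {n: 1.0 for n in crot_rng},
        "km": {
            **{enoyl(n): 25.0 + 1.5 * (n - 4) for n in crot_rng},
            **{hydroxy(n): 45.0 + 1.5 * (n - 4) for n in crot_rng},
        },
    }

    schad_rng = enzyme_chains("MSCHAD", start_chain)
    enz["MSCHAD"] = {
        "vmax": 3000.0,
        "keq": 2.17e-4,  # printed value
        "sf": {n: (1.0 if n <= 10 else 0.8) for n in schad_rng},
        "km": {
            **{hydroxy(n): 30.0 for n in schad_rng},
            **{keto(n): 30.0 for n in schad_rng},
            "NADMAT": 60.0,
            "NADHMAT": 30.0,
        },
    }

    # thiolase: high raw capacity; flux decline arises from competitive
    # occupation of the acyl site by accumulating acyl-CoA esters
    kat_rng = enzyme_chains("MCKAT", start_chain)
    kat_sf = {4: 0.49, 6: 1.0, 8: 0.9, 10: 0.8, 12: 0.7, 14: 0.6, 16: 0.5}
    kat_km_keto = {4: 12.4, 6: 6.7, 8: 8.0, 10: 9.0, 12: 10.0, 14: 11.0, 16: 12.0}
    kat_km_acyl = {4: 7.4, 6: 6.4, 8: 7.4, 10: 5.8, 12: 4.8, 14: 3.7}
    kat_km = {keto(n): kat_km_keto[n] for n in kat_rng}
    for n in kat_rng:
        if n >= 6:
            kat_km[acyl(n - 2)] = kat_km_acyl[n - 2]
    kat_km["AcetylCoAMAT"] = 150.0
    kat_km["CoAMAT"] = 15.0
    enz["MCKAT"] = {
        "vmax": 6000.0,
        "keq": 1.0e4,
        "sf": {n: kat_sf[n] for n in kat_rng},
        "km": kat_km,
    }

    mtp_rng = enzyme_chains("MTP", start_chain)
    if mtp_rng:
        mtp_km = {enoyl(n): 8.0 + 1.0 * (n - 8) for n in mtp_rng}
        for n in mtp_rng:
            mtp_km[acyl(n - 2)] = 40.0
        mtp_km.update(
            {"NADMAT": 60.0, "NADHMAT": 50.0, "CoAMAT": 60.0, "AcetylCoAMAT": 150.0}
        )
        enz["MTP"] = {
            "vmax": 600.0,
            "keq": 7.0,
            "sf": {n: v for n, v in {8: 0.6, 10: 0.8, 12: 1.0, 14: 0.9, 16: 0.8}.items() if n in mtp_rng},
            "km": mtp_km,
        }
    return p


def _enzyme_param(params: dict, enzyme: str, chain: int):
    try:
        spec = params["enzymes"][enzyme]
        return spec["vmax"], spec["keq"], spec["sf"][chain], spec["km"]
    except KeyError as exc:
        raise ModelConfigurationError(
            f"missing parameter for enzyme {enzyme} chain C{chain}: {exc}"
        ) from exc


def build_mfao_topology(params: dict | None = None, name: str = "mfao") -> KineticModel:
    """Assemble the network as a validated :class:`KineticModel`.

    Parameters
    ----------
    params
        Nested parameter dictionary as produced by
        :func:`default_parameters` (boundary concentrations, moiety
        totals, and per-enzyme Vmax/Keq/sf/Km).  Defaults to the curated
        default set for a C16 start.
    """
    params = params if params is not None else default_parameters()
    start = int(params.get("start_chain", 16))
    chains = _chain_list(start)
    boundary = params["boundary"]
    totals = params["totals"]

    sub = f"C{start}AcylCoACYT"
    car_c = f"C{start}AcylCarCYT"
    car_m = f"C{start}AcylCarMAT"

    species: list[Species] = []

    def add(name_, cls, comp, chain=None, fixed=False, value=0.0):
        species.append(
            Species(name_, cls, comp, chain_length=chain, fixed=fixed, value=value)
        )

    # boundary pools
    add(sub, "acyl-CoA", "cytosol", start, fixed=True, value=boundary[sub])
    add("CarCYT", "cofactor", "cytosol", fixed=True, value=boundary["CarCYT"])
    add("CoACYT", "cofactor", "cytosol", fixed=True, value=boundary["CoACYT"])
    for nm in ("NADMAT", "NADHMAT", "FADMAT", "FADH2MAT", "AcetylCoAMAT"):
        add(nm, "cofactor", "mitochondrion", fixed=True, value=boundary[nm])
    # shuttle intermediates
    add(car_c, "acyl-carnitine", "cytosol", start, value=0.0)
    add(car_m, "acyl-carnitine", "mitochondrion", start, value=0.0)
    add("CarMAT", "cofactor", "mitochondrion", value=totals["Car"])
    add("CoAMAT", "cofactor", "mitochondrion", value=totals["CoA"])
    # CoA-ester ladders
    for n in chains:
        add(acyl(n), "acyl-CoA", "mitochondrion", n)
        add(enoyl(n), "enoyl-CoA", "mitochondrion", n)
        add(hydroxy(n), "hydroxyacyl-CoA", "mitochondrion", n)
        add(keto(n), "ketoacyl-CoA", "mitochondrion", n)

    reactions: list[Reaction] = []

    def law(enzyme, chain, substrates, products, acyl_site, cofactor_site):
        vmax, keq, sf, km_all = _enzyme_param(params, enzyme, chain)
        ligs = set(substrates) | set(products) | set(acyl_site) | set(cofactor_site)
        try:
            km = {lig: km_all[lig] for lig in ligs}
        except KeyError as exc:
            raise ModelConfigurationError(
                f"missing Km for enzyme {enzyme} chain C{chain}: {exc}"
            ) from exc
        groups = {"acyl": tuple(acyl_site)}
        if cofactor_site:
            groups["cofactor"] = tuple(cofactor_site)
        return RateLaw(
            sf=sf,
            vmax=vmax,
            keq=keq,
            km=km,
            substrates=substrates,
            products=products,
            site_groups=groups,
        )

    # carnitine shuttle
    reactions.append(
        Reaction(
            "vcpt1",
            "CPT1",
            start,
            {sub: -1, "CarCYT": -1, car_c: +1, "CoACYT": +1},
            law("CPT1", start, {sub: 1, "CarCYT": 1}, {car_c: 1, "CoACYT": 1},
                (sub, car_c), ("CarCYT", "CoACYT")),
        )
    )
    reactions.append(
        Reaction(
            "vcact",
            "CACT",
            start,
            {car_c: -1, "CarMAT": -1, car_m: +1, "CarCYT": +1},
            law("CACT", start, {car_c: 1, "CarMAT": 1}, {car_m: 1, "CarCYT": 1},
                (car_c, car_m), ("CarMAT", "CarCYT")),
        )
    )
    reactions.append(
        Reaction(
            "vcpt2",
            "CPT2",
            start,
            {car_m: -1, "CoAMAT": -1, acyl(start): +1, "CarMAT": +1},
            law("CPT2", start, {car_m: 1, "CoAMAT": 1}, {acyl(start): 1, "CarMAT": 1},
                (car_m, acyl(start)), ("CoAMAT", "CarMAT")),
        )
    )

    # acyl-CoA dehydrogenases
    for enzyme in ACYL_DEHYDROGENASES:
        rng = enzyme_chains(enzyme, start)
        if enzyme not in params["enzymes"] or not rng:
            continue
        site = tuple(acyl(m) for m in rng) + tuple(enoyl(m) for m in rng)
        for n in rng:
            reactions.append(
                Reaction(
                    f"v{enzyme.lower()}C{n}",
                    enzyme,
                    n,
                    {acyl(n): -1, "FADMAT": -1, enoyl(n): +1, "FADH2MAT": +1},
                    law(enzyme, n, {acyl(n): 1, "FADMAT": 1},
                        {enoyl(n): 1, "FADH2MAT": 1}, site, ("FADMAT", "FADH2MAT")),
                )
            )

    # crotonase
    crot_rng = enzyme_chains("CROT", start)
    crot_site = tuple(enoyl(m) for m in crot_rng) + tuple(hydroxy(m) for m in crot_rng)
    for n in crot_rng:
        reactions.append(
            Reaction(
                f"vcrotC{n}",
                "CROT",
                n,
                {enoyl(n): -1, hydroxy(n): +1},
                law("CROT", n, {enoyl(n): 1}, {hydroxy(n): 1}, crot_site, ()),
            )
        )

    # M/SCHAD
    schad_rng = enzyme_chains("MSCHAD", start)
    schad_site = tuple(hydroxy(m) for m in schad_rng) + tuple(keto(m) for m in schad_rng)
    for n in schad_rng:
        reactions.append(
            Reaction(
                f"vmschadC{n}",
                "MSCHAD",
                n,
                {hydroxy(n): -1, "NADMAT": -1, keto(n): +1, "NADHMAT": +1},
                law("MSCHAD", n, {hydroxy(n): 1, "NADMAT": 1},
                    {keto(n): 1, "NADHMAT": 1}, schad_site, ("NADMAT", "NADHMAT")),
            )
        )

    # MCKAT: thiolysis; the acetyl unit leaves via the clamped sink, so
    # the net stoichiometry regenerates the free CoA consumed kinetically
    kat_rng = enzyme_chains("MCKAT", start)
    kat_site = (
        tuple(keto(m) for m in kat_rng)
        + tuple(acyl(m - 2) for m in kat_rng if m >= 6)
        + ("AcetylCoAMAT",)
    )
    for n in kat_rng:
        if n == 4:
            stoich = {keto(4): -1, "CoAMAT": +1, "AcetylCoAMAT": +2}
            prods = {"AcetylCoAMAT": 2}
        else:
            stoich = {keto(n): -1, acyl(n - 2): +1, "AcetylCoAMAT": +1}
            prods = {acyl(n - 2): 1, "AcetylCoAMAT": 1}
        reactions.append(
            Reaction(
                f"vmckatC{n}",
                "MCKAT",
                n,
                stoich,
                law("MCKAT", n, {keto(n): 1, "CoAMAT": 1}, prods,
                    kat_site, ("CoAMAT",)),
            )
        )

    # MTP (lumped hydratase + dehydrogenase + thiolase, C8+)
    mtp_rng = enzyme_chains("MTP", start)
    if mtp_rng and "MTP" in params["enzymes"]:
        mtp_site = (
            tuple(enoyl(m) for m in mtp_rng)
            + tuple(acyl(m - 2) for m in mtp_rng)
            + ("AcetylCoAMAT",)
        )
        for n in mtp_rng:
            reactions.append(
                Reaction(
                    f"vmtpC{n}",
                    "MTP",
                    n,
                    {enoyl(n): -1, "NADMAT": -1, acyl(n - 2): +1,
                     "NADHMAT": +1, "AcetylCoAMAT": +1},
                    law("MTP", n,
                        {enoyl(n): 1, "NADMAT": 1, "CoAMAT": 1},
                        {acyl(n - 2): 1, "NADHMAT": 1, "AcetylCoAMAT": 1},
                        mtp_site, ("NADMAT", "NADHMAT", "CoAMAT")),
                )
            )

    coa_members = ("CoAMAT",) + tuple(
        f(n) for n in chains for f in (acyl, enoyl, hydroxy, keto)
    )
    moieties = [
        Moiety("CoA", coa_members, totals["CoA"], pivot="CoAMAT"),
        Moiety("Car", ("CarMAT", car_m), totals["Car"], pivot="CarMAT"),
    ]

    model = KineticModel(
        species,
        reactions,
        moieties,
        name=name,
        flux_readout="vcact",
        nadh_species="NADHMAT",
        metadata={
            "start_chain": start,
            "substrate_parameter": f"conc_{sub}",
            "promiscuity_removed": [],
        },
    )
    violations = model.validate()
    if violations:
        raise ModelConfigurationError(
            "constructed model fails validation: " + "; ".join(violations)
        )
    return model


def substrate_parameter(model: KineticModel) -> str:
    """Name of the scan parameter holding the cytosolic substrate level."""
    return model.metadata.get("substrate_parameter", SUBSTRATE_PARAMETER)
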