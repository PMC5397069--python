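"""Seeded generators for synthetic pathway instances.

Two families: randomized beta-oxidation ladders sharing the full
instance's topology (for end-to-end pipeline tests without any external
model file), and tiny reversible Michaelis-Menten chains whose control
coefficients have closed-form solutions (oracles for the control
analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import KineticModel, ModelConfigurationError, RateLaw, Reaction, Species
from .mfao import build_mfao_topology, default_parameters

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Sampling ranges and anchors for the ladder generator.

    Kms are drawn log-uniformly (uM), Vmax log-uniformly (uM/min) and
    chain-specificity factors uniformly.  Equilibrium constants are fixed
    per reaction class; the hydroxyacyl-dehydrogenase and crotonase
    classes default to the literature values carried by the full
    instance, which the randomized ladders keep so the characteristic
    ketoacyl << hydroxyacyl accumulation pattern is preserved.
    """

    start_chain: int = 16
    seed: int | None = None
    km_range: tuple[float, float] = (1.0, 100.0)
    vmax_range: tuple[float, float] = (10.0, 1000.0)
    sf_range: tuple[float, float] = (0.3, 1.0)
    keq_by_class: dict = field(
        default_factory=lambda: {"MSCHAD": 2.17e-4, "CROT": 3.13}
    )
    #: None keeps each enzyme class's curated equilibrium constant; a float
    #: overrides every class not listed in ``keq_by_class``.  A uniform
    #: Keq of 1 makes thiolysis against the clamped acetyl-CoA pool
    #: reversible enough to drive the pathway backwards, so "keep
    #: curated" is the default.
    keq_other: float | None = None
    coa_total: float = 2500.0
    car_total: float = 500.0

    def __post_init__(self) -> None:
        if self.start_chain % 2 or not 4 <= self.start_chain <= 16:
            raise ModelConfigurationError(
                f"start chain {self.start_chain} not even in [4, 16]"
            )


#: printed anchors kept fixed in every generated ladder
_ANCHORED_SF = {("MCKAT", 4): 0.49, ("MCKAT", 6): 1.0}
_ANCHORED_KM = {("MCKAT", "C4KetoacylCoAMAT"): 12.4, ("MCKAT", "C6KetoacylCoAMAT"): 6.7}


def generate_ladder(config: GeneratorConfig | None = None) -> KineticModel:
    """Generate a randomized full-oxidation ladder.

    Same topology, boundary pools and conserved moieties as the curated
    instance for the configured start chain; Vmax/sf/Km randomized within
    the configured ranges.  Same seed, same model (bit-identical
    serialization).
    """
    config = config or GeneratorConfig()
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**32))
        logger.warning("no seed given; drew seed %d", seed)
    rng = np.random.default_rng(seed)

    params = default_parameters(config.start_chain)
    params["totals"]["CoA"] = config.coa_total
    params["totals"]["Car"] = config.car_total

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for enzyme in sorted(params["enzymes"]):
        spec = params["enzymes"][enzyme]
        spec["vmax"] = log_uniform(*config.vmax_range)
        fallback = spec["keq"] if config.keq_other is None else config.keq_other
        spec["keq"] = config.keq_by_class.get(enzyme, fallback)
        for chain in sorted(spec["sf"]):
            spec["sf"][chain] = _ANCHORED_SF.get(
                (enzyme, chain),
                float(rng.uniform(*config.sf_range)),
            )
        for ligand in sorted(spec["km"]):
            spec["km"][ligand] = _ANCHORED_KM.get(
                (enzyme, ligand), log_uniform(*config.km_range)
            )

    model = build_mfao_topology(params, name=f"ladder-C{config.start_chain}-s{seed}")
    model.metadata["generator"] = {
        "seed": seed,
        "start_chain": config.start_chain,
    }
    return model


def generate_linear_chain(
    n_enzymes: int,
    params: dict | None = None,
    seed: int | None = None,
) -> KineticModel:
    """A linear chain of reversible Michaelis-Menten steps.

    ``S0 -E1-> X1 -E2-> ... -En-> P`` with clamped boundary substrate S0
    and product P.  Supported sizes: 2 and 3 enzymes.  ``params`` may
    override ``vmax``/``keq``/``km`` lists and the boundary values;
    otherwise moderately asymmetric defaults (or seeded draws) are used.
    """
    if n_enzymes not in (2, 3):
        raise ModelConfigurationError("linear chains support 2 or 3 enzymes only")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if seed is not None:
        vmax = list(np.exp(rng.uniform(np.log(50.0), np.log(500.0), n_enzymes)))
        km = list(np.exp(rng.uniform(np.log(5.0), np.log(50.0), 2 * n_enzymes)))
    else:
        vmax = [100.0, 70.0, 130.0][:n_enzymes]
        km = [10.0, 25.0, 15.0, 40.0, 8.0, 30.0][: 2 * n_enzymes]
    vmax = list(params.get("vmax", vmax))
    km = list(params.get("km", km))
    keq = list(params.get("keq", [10.0] * n_enzymes))
    s0 = float(params.get("s0", 50.0))
    p_end = float(params.get("p", 1.0))

    names = ["S0"] + [f"X{i}" for i in range(1, n_enzymes)] + ["P"]
    species = [Species("S0", "other", "cytosol", fixed=True, value=s0)]
    for i in range(1, n_enzymes):
        species.append(Species(f"X{i}", "other", "cytosol", value=1.0))
    species.append(Species("P", "other", "cytosol", fixed=True, value=p_end))

    reactions = []
    for i in range(n_enzymes):
        sub, prod = names[i], names[i + 1]
        km_s, km_p = km[2 * i], km[2 * i + 1]
        law = RateLaw(
            sf=1.0,
            vmax=vmax[i],
            keq=keq[i],
            km={sub: km_s, prod: km_p},
            substrates={sub: 1},
            products={prod: 1},
            site_groups={"site": (sub, prod)},
        )
        reactions.append(
            Reaction(f"v{i + 1}", f"E{i + 1}", None, {sub: -1, prod: +1}, law)
        )

    model = KineticModel(
        species,
        reactions,
        moieties=[],
        name=f"chain-{n_enzymes}",
        flux_readout=reactions[-1].rid,
        nadh_species="",
    )
    violations = model.validate()
    if violations:
        raise ModelConfigurationError("; ".join(violations))
    return model
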