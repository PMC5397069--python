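"""Core representation of promiscuous-enzyme kinetic models.

A model is a set of species (variable or clamped), reactions carrying a
generalized reversible rate law with competitive binding-site groups, a
stoichiometry matrix, and conserved moieties.  Units are micromolar (uM)
and minutes throughout.

The rate law implemented here is the generalized reversible
Michaelis-Menten form in which every CoA-ester ligand an enzyme touches
-- substrates and products of all chain lengths -- competes within one
binding-site group, while redox/acyl-carrier cofactors form a second,
independent group::

    v = alpha * sf * Vmax
        * (prod_s ([S]/Km_S)^n  -  prod_p [P]^n / (prod_s Km_S^n * Keq))
        / prod_groups (1 + sum_ligands [X]/Km_X)

``alpha`` is the partition factor introduced when promiscuity is removed
(1.0 in untreated models).  The net rate is zero exactly when the
mass-action ratio equals ``Keq``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SPECIES_CLASSES = (
    "acyl-CoA",
    "enoyl-CoA",
    "hydroxyacyl-CoA",
    "ketoacyl-CoA",
    "acyl-carnitine",
    "cofactor",
    "other",
)

COMPARTMENTS = ("cytosol", "mitochondrion")

#: concentrations more negative than this trigger a warning before clipping
DEFAULT_CLIP_FLOOR = 1e-12


class ModelConfigurationError(ValueError):
    """Raised when a model or rate law is structurally inconsistent."""


@dataclass
class Species:
    """One chemical species.

    Parameters
    ----------
    name
        Unique identifier, e.g. ``"C16AcylCoAMAT"``.
    species_class
        One of :data:`SPECIES_CLASSES`.
    compartment
        ``"cytosol"`` or ``"mitochondrion"``.
    chain_length
        Acyl chain length in carbons (even, 4..16) for chain species,
        ``None`` for cofactors.
    fixed
        ``True`` for clamped boundary species.
    value
        Initial concentration for variable species, clamped concentration
        for fixed ones (uM).
    """

    name: str
    species_class: str = "other"
    compartment: str = "mitochondrion"
    chain_length: int | None = None
    fixed: bool = False
    value: float = 0.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species_class": self.species_class,
            "compartment": self.compartment,
            "chain_length": self.chain_length,
            "fixed": self.fixed,
            "value": float(self.value),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Species":
        return cls(
            name=d["name"],
            species_class=d.get("species_class", "other"),
            compartment=d.get("compartment", "mitochondrion"),
            chain_length=d.get("chain_length"),
            fixed=bool(d.get("fixed", False)),
            value=float(d.get("value", 0.0)),
        )


@dataclass
class RateLaw:
    """Generalized reversible-competitive rate law.

    ``substrates`` and ``products`` map ligand names to their kinetic
    exponents in the forward / reverse numerator terms.  ``km`` holds one
    Michaelis constant per ligand; the same constant doubles as the
    competitive inhibition constant in the denominator.  ``site_groups``
    partitions the denominator ligands into independent binding-site
    factors (typically an acyl-ester site and a cofactor site); ligands
    appearing only there act as pure competitive inhibitors.
    """

    sf: float
    vmax: float
    keq: float
    km: dict[str, float]
    substrates: dict[str, int]
    products: dict[str, int]
    site_groups: dict[str, tuple[str, ...]]
    alpha: float = 1.0

    def ligands(self) -> list[str]:
        """All species entering the law, numerator or denominator."""
        seen: dict[str, None] = {}
        for name in (*self.substrates, *self.products):
            seen.setdefault(name)
        for group in self.site_groups.values():
            for name in group:
                seen.setdefault(name)
        return list(seen)

    def group_of(self, ligand: str) -> str | None:
        for gname, members in self.site_groups.items():
            if ligand in members:
                return gname
        return None

    def validate(self, context: str = "") -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        where = f" in {context}" if context else ""
        out = []
        if not (0.0 < self.sf <= 1.0):
            out.append(f"sf={self.sf} outside (0, 1]{where}")
        if not self.vmax > 0:
            out.append(f"Vmax={self.vmax} not positive{where}")
        if not self.keq > 0:
            out.append(f"Keq={self.keq} not positive{where}")
        if not (0.0 < self.alpha <= 1.0):
            out.append(f"alpha={self.alpha} outside (0, 1]{where}")
        for name, km in self.km.items():
            if not km > 0:
                out.append(f"Km[{name}]={km} not positive{where}")
        for name in (*self.substrates, *self.products):
            if name not in self.km:
                out.append(f"numerator ligand {name} has no Km{where}")
            ngroups = sum(name in g for g in self.site_groups.values())
            if ngroups != 1:
                out.append(
                    f"numerator ligand {name} in {ngroups} site groups "
                    f"(expected exactly 1){where}"
                )
        for gname, members in self.site_groups.items():
            for name in members:
                if name not in self.km:
                    out.append(f"site-group '{gname}' ligand {name} has no Km{where}")
        return out

    # -- evaluation ----------------------------------------------------

    def rate(self, conc: dict[str, float]) -> float:
        """Evaluate the law at the given ligand concentrations (uM/min)."""
        try:
            fwd = 1.0
            km_scale = 1.0
            for name, n in self.substrates.items():
                fwd *= (conc[name] / self.km[name]) ** n
                km_scale *= self.km[name] ** n
            rev = 1.0
            for name, n in self.products.items():
                rev *= conc[name] ** n
            rev /= km_scale * self.keq
            denom = 1.0
            for members in self.site_groups.values():
                denom *= 1.0 + sum(conc[m] / self.km[m] for m in members)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ModelConfigurationError(f"unknown ligand {exc} in rate law") from exc
        return self.alpha * self.sf * self.vmax * (fwd - rev) / denom

    def elasticity(self, conc: dict[str, float], ligand: str) -> float:
        """Analytic scaled elasticity d ln|v| / d ln [ligand] at ``conc``.

        Derived from the closed form of the law; cross-validated against
        finite differences and symbolic differentiation in the test suite.
        """
        if ligand not in self.km:
            return 0.0
        x = conc[ligand]
        fwd = 1.0
        km_scale = 1.0
        for name, n in self.substrates.items():
            fwd *= (conc[name] / self.km[name]) ** n
            km_scale *= self.km[name] ** n
        rev = 1.0
        for name, n in self.products.items():
            rev *= conc[name] ** n
        rev /= km_scale * self.keq
        net = fwd - rev
        if net == 0.0:
            raise ZeroDivisionError("elasticity undefined at zero net rate")
        n_s = self.substrates.get(ligand, 0)
        n_p = self.products.get(ligand, 0)
        eps = (n_s * fwd - n_p * rev) / net
        gname = self.group_of(ligand)
        if gname is not None:
            members = self.site_groups[gname]
            dg = 1.0 + sum(conc[m] / self.km[m] for m in members)
            eps -= (x / self.km[ligand]) / dg
        return eps

    def to_dict(self) -> dict:
        return {
            "sf": float(self.sf),
            "vmax": float(self.vmax),
            "keq": float(self.keq),
            "alpha": float(self.alpha),
            "km": {k: float(v) for k, v in self.km.items()},
            "substrates": dict(self.substrates),
            "products": dict(self.products),
            "site_groups": {k: list(v) for k, v in self.site_groups.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateLaw":
        return cls(
            sf=float(d["sf"]),
            vmax=float(d["vmax"]),
            keq=float(d["keq"]),
            alpha=float(d.get("alpha", 1.0)),
            km={k: float(v) for k, v in d["km"].items()},
            substrates={k: int(v) for k, v in d["substrates"].items()},
            products={k: int(v) for k, v in d["products"].items()},
            site_groups={k: tuple(v) for k, v in d["site_groups"].items()},
        )


@dataclass
class Reaction:
    """A reaction instance: enzyme, chain length, stoichiometry, rate law.

    ``stoich`` is the *net* stoichiometry over all species (fixed species
    included, so boundary fluxes remain readable); the ODE right-hand side
    only applies the rows of variable species.  Kinetic substrates and
    products live on the rate law and may differ from the net
    stoichiometry (e.g. free CoA acting as a thiolase co-substrate while
    being stoichiometrically regenerated through the clamped acetyl-CoA
    sink).
    """

    rid: str
    enzyme: str
    chain_length: int | None
    stoich: dict[str, float]
    law: RateLaw

    def to_dict(self) -> dict:
        return {
            "rid": self.rid,
            "enzyme": self.enzyme,
            "chain_length": self.chain_length,
            "stoich": {k: float(v) for k, v in self.stoich.items()},
            "law": self.law.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(
            rid=d["rid"],
            enzyme=d["enzyme"],
            chain_length=d.get("chain_length"),
            stoich={k: float(v) for k, v in d["stoich"].items()},
            law=RateLaw.from_dict(d["law"]),
        )


@dataclass
class Moiety:
    """A conserved sum of variable species.

    ``pivot`` names the member eliminated algebraically during
    moiety-reduced steady-state solving (e.g. free CoA).
    """

    name: str
    members: tuple[str, ...]
    total: float
    pivot: str = ""

    def __post_init__(self) -> None:
        if not self.pivot:
            self.pivot = self.members[0]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "members": list(self.members),
            "total": float(self.total),
            "pivot": self.pivot,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Moiety":
        return cls(
            name=d["name"],
            members=tuple(d["members"]),
            total=float(d["total"]),
            pivot=d.get("pivot", ""),
        )


@dataclass
class ModelState:
    """Concentrations of the variable species at one time point."""

    time: float
    concentrations: dict[str, float]

    def vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.concentrations[n] for n in names], dtype=float)


class _CompiledRates:
    """Index-based fast evaluator for all reaction rates of a model."""

    def __init__(self, model: "KineticModel") -> None:
        idx = {name: i for i, name in enumerate(model.species_order)}
        self.n_species = len(model.species_order)
        self.terms = []
        for rxn in model.reactions:
            law = rxn.law
            pref = law.alpha * law.sf * law.vmax
            sub_i = np.array([idx[n] for n in law.substrates], dtype=np.intp)
            sub_e = np.array(list(law.substrates.values()), dtype=float)
            sub_k = np.array([law.km[n] for n in law.substrates], dtype=float)
            prod_i = np.array([idx[n] for n in law.products], dtype=np.intp)
            prod_e = np.array(list(law.products.values()), dtype=float)
            km_scale = float(np.prod(sub_k**sub_e)) * law.keq
            groups = []
            for members in law.site_groups.values():
                g_i = np.array([idx[n] for n in members], dtype=np.intp)
                g_k = np.array([law.km[n] for n in members], dtype=float)
                groups.append((g_i, 1.0 / g_k))
            self.terms.append((pref, sub_i, sub_e, sub_k, prod_i, prod_e, km_scale, groups))

    def __call__(self, full_conc: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.terms))
        for j, (pref, sub_i, sub_e, sub_k, prod_i, prod_e, km_scale, groups) in enumerate(
            self.terms
        ):
            fwd = np.prod((full_conc[sub_i] / sub_k) ** sub_e) if sub_i.size else 1.0
            rev = np.prod(full_conc[prod_i] ** prod_e) if prod_i.size else 1.0
            denom = 1.0
            for g_i, g_invk in groups:
                denom *= 1.0 + float(full_conc[g_i] @ g_invk)
            out[j] = pref * (fwd - rev / km_scale) / denom
        return out


class KineticModel:
    """Species, reactions, conserved moieties and the ODE right-hand side."""

    def __init__(
        self,
        species: list[Species],
        reactions: list[Reaction],
        moieties: list[Moiety] | None = None,
        name: str = "model",
        flux_readout: str | None = None,
        nadh_species: str = "NADHMAT",
        metadata: dict | None = None,
        clip_floor: float = DEFAULT_CLIP_FLOOR,
    ) -> None:
        self.name = name
        self.species = {sp.name: sp for sp in species}
        if len(self.species) != len(species):
            raise ModelConfigurationError("duplicate species names")
        self.reactions = list(reactions)
        self.moieties = list(moieties or [])
        #: reaction id whose rate is reported as the pathway flux J
        self.flux_readout = flux_readout or (reactions[-1].rid if reactions else None)
        self.nadh_species = nadh_species
        self.metadata = dict(metadata or {})
        self.clip_floor = clip_floor
        self._cache: dict = {}

    # -- bookkeeping ---------------------------------------------------

    @property
    def species_order(self) -> list[str]:
        return list(self.species)

    @property
    def variable_names(self) -> list[str]:
        return [n for n, sp in self.species.items() if not sp.fixed]

    @property
    def fixed_names(self) -> list[str]:
        return [n for n, sp in self.species.items() if sp.fixed]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.rid for r in self.reactions]

    @property
    def enzymes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.enzyme)
        return list(seen)

    def reactions_of(self, enzyme: str) -> list[Reaction]:
        out = [r for r in self.reactions if r.enzyme == enzyme]
        if not out:
            raise ModelConfigurationError(f"unknown enzyme {enzyme!r}")
        return out

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.rid == rid:
                return r
        raise ModelConfigurationError(f"unknown reaction {rid!r}")

    def invalidate(self) -> None:
        """Drop compiled caches after any parameter or structural edit."""
        self._cache.clear()

    def copy(self) -> "KineticModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- matrices ------------------------------------------------------

    def stoichiometry_matrix(self, variable_only: bool = True) -> np.ndarray:
        key = ("N", variable_only)
        if key not in self._cache:
            rows = self.variable_names if variable_only else self.species_order
            ridx = {n: i for i, n in enumerate(rows)}
            mat = np.zeros((len(rows), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for name, coeff in rxn.stoich.items():
                    i = ridx.get(name)
                    if i is not None:
                        mat[i, j] = coeff
            self._cache[key] = mat
        return self._cache[key]

    def _compiled(self) -> _CompiledRates:
        if "rates" not in self._cache:
            self._cache["rates"] = _CompiledRates(self)
        return self._cache["rates"]

    def full_concentrations(self, x: np.ndarray) -> np.ndarray:
        """Embed a variable-species vector into the full species vector."""
        if "embed" not in self._cache:
            order = self.species_order
            var_pos = np.array(
                [i for i, n in enumerate(order) if not self.species[n].fixed], dtype=np.intp
            )
            base = np.array(
                [self.species[n].value if self.species[n].fixed else 0.0 for n in order]
            )
            self._cache["embed"] = (var_pos, base)
        var_pos, base = self._cache["embed"]
        full = base.copy()
        full[var_pos] = x
        return full

    # -- evaluation ----------------------------------------------------

    def _clip(self, x: np.ndarray) -> np.ndarray:
        if np.any(x < -self.clip_floor):
            # warn once per compiled lifetime, then stay quiet
            if not self._cache.get("clip_warned"):
                self._cache["clip_warned"] = True
                logger.warning(
                    "clipping negative concentrations (min %.3e) to 0 in model %s",
                    float(np.min(x)),
                    self.name,
                )
        return np.maximum(x, 0.0)

    def rates(self, x: np.ndarray) -> np.ndarray:
        """All reaction rates at variable-species concentrations ``x``."""
        x = self._clip(np.asarray(x, dtype=float))
        return self._compiled()(self.full_concentrations(x))

    def rates_dict(self, state: ModelState) -> dict[str, float]:
        v = self.rates(state.vector(self.variable_names))
        return dict(zip(self.reaction_ids, v))

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Time derivatives of the variable species (uM/min)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.variable_names),):
            raise ModelConfigurationError(
                f"state dimension {x.shape} does not match "
                f"{len(self.variable_names)} variable species"
            )
        return self.stoichiometry_matrix() @ self.rates(x)

    def rhs_state(self, state: ModelState) -> dict[str, float]:
        d = self.rhs(state.vector(self.variable_names))
        return dict(zip(self.variable_names, d))

    def default_state(self) -> ModelState:
        return ModelState(
            0.0, {n: float(self.species[n].value) for n in self.variable_names}
        )

    # -- parameters ----------------------------------------------------

    def parameter_names(self) -> list[str]:
        """Canonical scan/perturbation parameter names.

        ``Vmax_<enzyme>``, ``Keq_<enzyme>``, ``sf_<enzyme>_C<n>``,
        ``Km_<enzyme>_<ligand>``, ``conc_<fixed species>`` and
        ``total_<moiety>``.  Per-enzyme parameters are shared across the
        enzyme's chain-length reactions (checked at harvest time).
        """
        names: list[str] = []
        for enz in self.enzymes:
            rxns = self.reactions_of(enz)
            names.append(f"Vmax_{enz}")
            names.append(f"Keq_{enz}")
            for r in rxns:
                if r.chain_length is not None:
                    names.append(f"sf_{enz}_C{r.chain_length}")
            ligands: dict[str, None] = {}
            for r in rxns:
                for lig in r.law.km:
                    ligands.setdefault(lig)
            names.extend(f"Km_{enz}_{lig}" for lig in ligands)
        names.extend(f"conc_{n}" for n in self.fixed_names)
        names.extend(f"total_{m.name}" for m in self.moieties)
        return names

    def _resolve_parameter(self, name: str):
        if name.startswith("conc_"):
            sp = self.species.get(name[5:])
            if sp is None or not sp.fixed:
                raise ModelConfigurationError(f"unknown fixed species for {name!r}")
            return ("conc", sp)
        if name.startswith("total_"):
            for m in self.moieties:
                if m.name == name[6:]:
                    return ("total", m)
            raise ModelConfigurationError(f"unknown moiety for {name!r}")
        if name.startswith("Vmax_"):
            return ("vmax", self.reactions_of(name[5:]))
        if name.startswith("Keq_"):
            return ("keq", self.reactions_of(name[4:]))
        if name.startswith("sf_"):
            enz, _, chain = name[3:].rpartition("_C")
            for r in self.reactions_of(enz):
                if r.chain_length == int(chain):
                    return ("sf", [r])
            raise ModelConfigurationError(f"no chain C{chain} reaction for {name!r}")
        if name.startswith("Km_"):
            rest = name[3:]
            for enz in self.enzymes:
                if rest.startswith(enz + "_"):
                    lig = rest[len(enz) + 1 :]
                    rxns = [r for r in self.reactions_of(enz) if lig in r.law.km]
                    if not rxns:
                        raise ModelConfigurationError(
                            f"enzyme {enz} has no ligand {lig!r} for {name!r}"
                        )
                    return ("km", (rxns, lig))
        raise ModelConfigurationError(f"unknown parameter {name!r}")

    def get_parameter(self, name: str) -> float:
        kind, target = self._resolve_parameter(name)
        if kind == "conc":
            return float(target.value)
        if kind == "total":
            return float(target.total)
        if kind == "vmax":
            vals = {r.law.vmax for r in target}
        elif kind == "keq":
            vals = {r.law.keq for r in target}
        elif kind == "sf":
            vals = {r.law.sf for r in target}
        else:  # km
            rxns, lig = target
            vals = {r.law.km[lig] for r in rxns}
        if len(vals) != 1:
            raise ModelConfigurationError(f"parameter {name!r} is not shared consistently")
        return float(next(iter(vals)))

    def set_parameter(self, name: str, value: float) -> None:
        value = float(value)
        kind, target = self._resolve_parameter(name)
        if kind == "conc":
            target.value = value
        elif kind == "total":
            target.total = value
        elif kind == "vmax":
            for r in target:
                r.law.vmax = value
        elif kind == "keq":
            for r in target:
                r.law.keq = value
        elif kind == "sf":
            for r in target:
                r.law.sf = value
        else:
            rxns, lig = target
            for r in rxns:
                r.law.km[lig] = value
        self.invalidate()

    # -- validation ----------------------------------------------------

    def validate(self) -> list[str]:
        """Check all structural invariants; return violation messages."""
        out: list[str] = []
        for sp in self.species.values():
            if sp.species_class not in SPECIES_CLASSES:
                out.append(f"species {sp.name}: unknown class {sp.species_class!r}")
            if sp.compartment not in COMPARTMENTS:
                out.append(f"species {sp.name}: unknown compartment {sp.compartment!r}")
            if sp.chain_length is not None and (
                sp.chain_length % 2 != 0 or not 4 <= sp.chain_length <= 16
            ):
                out.append(
                    f"species {sp.name}: chain length {sp.chain_length} not even in [4, 16]"
                )
            if sp.value < 0:
                out.append(f"species {sp.name}: negative concentration {sp.value}")
        for rxn in self.reactions:
            out.extend(rxn.law.validate(context=rxn.rid))
            for name in (*rxn.stoich, *rxn.law.ligands()):
                if name not in self.species:
                    out.append(f"reaction {rxn.rid}: unknown species {name!r}")
        n_var = self.stoichiometry_matrix()
        vidx = {n: i for i, n in enumerate(self.variable_names)}
        moiety_members: dict[str, int] = {}
        for m in self.moieties:
            vec = np.zeros(len(self.variable_names))
            for name in m.members:
                if name not in vidx:
                    out.append(f"moiety {m.name}: member {name!r} is not a variable species")
                    continue
                vec[vidx[name]] = 1.0
                moiety_members[name] = moiety_members.get(name, 0) + 1
            if m.pivot not in m.members:
                out.append(f"moiety {m.name}: pivot {m.pivot!r} not a member")
            residual = vec @ n_var
            bad = np.flatnonzero(np.abs(residual) > 1e-9)
            for j in bad:
                out.append(
                    f"moiety {m.name}: not conserved by reaction "
                    f"{self.reactions[j].rid} (net {residual[j]:+g})"
                )
        coa_classes = {"acyl-CoA", "enoyl-CoA", "hydroxyacyl-CoA", "ketoacyl-CoA"}
        for sp in self.species.values():
            if (
                not sp.fixed
                and sp.compartment == "mitochondrion"
                and sp.species_class in coa_classes
                and self.moieties
                and moiety_members.get(sp.name, 0) != 1
            ):
                out.append(
                    f"species {sp.name}: variable mitochondrial CoA ester in "
                    f"{moiety_members.get(sp.name, 0)} moieties (expected 1)"
                )
        # rates finite at a strictly positive probe state
        if not out:
            probe = np.ones(len(self.variable_names))
            v = self.rates(probe)
            if not np.all(np.isfinite(v)):
                bad = [self.reactions[j].rid for j in np.flatnonzero(~np.isfinite(v))]
                out.append(f"non-finite rate at positive probe state: {bad}")
        return out

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "flux_readout": self.flux_readout,
            "nadh_species": self.nadh_species,
            "metadata": dict(self.metadata),
            "species": [sp.to_dict() for sp in self.species.values()],
            "reactions": [r.to_dict() for r in self.reactions],
            "moieties": [m.to_dict() for m in self.moieties],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            species=[Species.from_dict(s) for s in d["species"]],
            reactions=[Reaction.from_dict(r) for r in d["reactions"]],
            moieties=[Moiety.from_dict(m) for m in d.get("moieties", [])],
            name=d.get("name", "model"),
            flux_readout=d.get("flux_readout"),
            nadh_species=d.get("nadh_species", "NADHMAT"),
            metadata=d.get("metadata", {}),
        )

    def to_yaml(self, path=None) -> str | None:
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "KineticModel":
        import os

        import yaml

        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(source))


def promiscuous_rate(law: RateLaw, conc: dict[str, float]) -> float:
    """Evaluate one promiscuous rate law at explicit concentrations.

    Thin functional wrapper around :meth:`RateLaw.rate`; raises
    :class:`ModelConfigurationError` for unknown ligands and surfaces the
    law's own validation errors for non-positive constants.
    """
    errors = law.validate()
    if errors:
        raise ModelConfigurationError("; ".join(errors))
    return law.rate(conc)
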