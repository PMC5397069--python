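"""SBML import/export for kinetic models.

Export writes SBML Level 3 with the full kinetic law as MathML and a
JSON annotation per reaction (and per model) carrying the structured
rate-law description, so that re-import is lossless.  Import first looks
for those annotations; foreign SBML files are mapped by naming
convention (``Vmax``/``sf``/``Km``/``Keq`` parameter prefixes together
with a species-id mapping table) and any construct that cannot be mapped
raises :class:`SBMLImportError` naming the element.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from xml.sax import saxutils

from .core import KineticModel, Moiety, RateLaw, Reaction, Species

logger = logging.getLogger(__name__)

_NOTES_PREFIX = "betaox-json:"


class SBMLImportError(RuntimeError):
    """Raised when an SBML construct cannot be mapped onto the model."""


def _require_libsbml():
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment guard
        raise SBMLImportError(
            "python-libsbml is required for SBML input/output"
        ) from exc
    return libsbml


def _formula(rxn: Reaction) -> str:
    law = rxn.law
    fwd = " * ".join(
        f"({lig} / {law.km[lig]})^{n}" if n != 1 else f"({lig} / {law.km[lig]})"
        for lig, n in law.substrates.items()
    ) or "1"
    km_scale = " * ".join(
        f"{law.km[lig]}^{n}" if n != 1 else f"{law.km[lig]}"
        for lig, n in law.substrates.items()
    ) or "1"
    rev_num = " * ".join(
        f"{lig}^{n}" if n != 1 else f"{lig}" for lig, n in law.products.items()
    ) or "0"
    denom_parts = []
    for members in law.site_groups.values():
        inner = " + ".join(f"{lig} / {law.km[lig]}" for lig in members)
        denom_parts.append(f"(1 + {inner})" if inner else "1")
    denom = " * ".join(denom_parts) or "1"
    return (
        f"{law.alpha} * {law.sf} * {law.vmax} * "
        f"(({fwd}) - ({rev_num}) / (({km_scale}) * {law.keq})) / ({denom})"
    )


def export_sbml(model: KineticModel, path: str) -> None:
    """Write the model as SBML L3V2 (plain-text XML)."""
    libsbml = _require_libsbml()
    doc = libsbml.SBMLDocument(3, 2)
    sbml_model = doc.createModel()
    sbml_model.setId(model.name.replace("-", "_").replace(",", "_"))
    meta = {
        "flux_readout": model.flux_readout,
        "nadh_species": model.nadh_species,
        "metadata": model.metadata,
        "moieties": [m.to_dict() for m in model.moieties],
    }
    sbml_model.setNotes(
        f"<body xmlns='http://www.w3.org/1999/xhtml'><pre>{_NOTES_PREFIX}"
        f"{json.dumps(meta)}</pre></body>"
    )
    for comp_id in ("cytosol", "mitochondrion"):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)
    for sp in model.species.values():
        s = sbml_model.createSpecies()
        s.setId(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialConcentration(float(sp.value))
        s.setBoundaryCondition(bool(sp.fixed))
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setNotes(
            f"<body xmlns='http://www.w3.org/1999/xhtml'><pre>{_NOTES_PREFIX}"
            f"{json.dumps(sp.to_dict())}</pre></body>"
        )
    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(rxn.rid)
        r.setReversible(True)
        r.setNotes(
            f"<body xmlns='http://www.w3.org/1999/xhtml'><pre>{_NOTES_PREFIX}"
            f"{json.dumps(rxn.to_dict())}</pre></body>"
        )
        for name, coeff in rxn.stoich.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(name)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        for lig in rxn.law.ligands():
            if lig not in rxn.stoich:
                mod = r.createModifier()
                mod.setSpecies(lig)
        kl = r.createKineticLaw()
        ast = libsbml.parseL3Formula(_formula(rxn))
        if ast is None:  # pragma: no cover - formula is machine-generated
            raise SBMLImportError(f"could not build kinetic law for {rxn.rid}")
        kl.setMath(ast)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:  # pragma: no cover
        raise SBMLImportError(f"failed to write SBML to {path}")


def _notes_payload(element) -> dict | None:
    notes = element.getNotesString() if element.isSetNotes() else ""
    if _NOTES_PREFIX not in notes:
        return None
    payload = notes.split(_NOTES_PREFIX, 1)[1]
    payload = payload.split("</pre>", 1)[0]
    payload = saxutils.unescape(payload, {"&quot;": '"', "&apos;": "'"})
    return json.loads(payload)


def load_name_map() -> dict[str, dict]:
    """Species-id mapping table for the deposited model (TSV resource)."""
    out: dict[str, dict] = {}
    text = (
        resources.files("betaox").joinpath("data/vaneunen6_names.tsv").read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sbml_id, canonical, cls, chain = line.split("\t")
        out[sbml_id] = {
            "canonical": canonical,
            "species_class": cls,
            "chain_length": int(chain) if chain not in ("", "NA") else None,
        }
    return out


def import_sbml(path: str) -> KineticModel:
    """Read an SBML file into a :class:`KineticModel`.

    Files written by :func:`export_sbml` round-trip exactly.  Foreign
    files are mapped by convention; unmappable constructs raise
    :class:`SBMLImportError` listing the offending elements.
    """
    libsbml = _require_libsbml()
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLImportError(f"invalid SBML in {path}: " + "; ".join(msgs[:5]))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLImportError(f"{path} contains no model")
    with open(path, "rb") as fh:
        checksum = hashlib.sha256(fh.read()).hexdigest()
    logger.info(
        "importing SBML model id=%s from %s (sha256=%s)",
        sbml_model.getId(),
        path,
        checksum,
    )

    meta = _notes_payload(sbml_model)
    if meta is not None:
        model = _import_native(sbml_model, meta)
    else:
        model = _import_foreign(sbml_model)
    model.metadata.setdefault("provenance", {})
    model.metadata["provenance"].update(
        {"sbml_id": sbml_model.getId(), "sha256": checksum, "path": str(path)}
    )
    violations = model.validate()
    if violations:
        logger.warning(
            "imported model has %d validation issue(s): %s",
            len(violations),
            "; ".join(violations[:5]),
        )
    return model


def _import_native(sbml_model, meta: dict) -> KineticModel:
    species = []
    for i in range(sbml_model.getNumSpecies()):
        payload = _notes_payload(sbml_model.getSpecies(i))
        if payload is None:
            raise SBMLImportError(
                f"species {sbml_model.getSpecies(i).getId()} lacks a structured note"
            )
        species.append(Species.from_dict(payload))
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        payload = _notes_payload(sbml_model.getReaction(i))
        if payload is None:
            raise SBMLImportError(
                f"reaction {sbml_model.getReaction(i).getId()} lacks a structured note"
            )
        reactions.append(Reaction.from_dict(payload))
    return KineticModel(
        species,
        reactions,
        moieties=[Moiety.from_dict(m) for m in meta.get("moieties", [])],
        name=sbml_model.getId(),
        flux_readout=meta.get("flux_readout"),
        nadh_species=meta.get("nadh_species", "NADHMAT"),
        metadata=meta.get("metadata", {}),
    )


#: ligands routed to the cofactor binding-site factor during foreign import
_COFACTOR_SITE = {
    "NADMAT", "NADHMAT", "FADMAT", "FADH2MAT",
    "CoAMAT", "CoACYT", "CarMAT", "CarCYT",
}


def _import_foreign(sbml_model) -> KineticModel:
    """Best-effort mapping of a foreign (deposited-style) SBML model.

    Requires parameters following the ``V<enzyme>`` / ``sf<enzyme>C<n>``
    / ``Km<enzyme><ligand>`` / ``Keq<enzyme>`` naming convention used by
    the online deposition (matched case-insensitively, local parameters
    overriding global ones) and species ids present in the shipped
    mapping table.  Modifier species become competitive-site ligands.
    Every construct that fails to map is collected and reported at once.
    """
    name_map = load_name_map()
    unmapped: list[str] = []
    species: list[Species] = []
    canonical: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        info = name_map.get(s.getId())
        if info is None:
            unmapped.append(f"species:{s.getId()}")
            continue
        canonical[s.getId()] = info["canonical"]
        species.append(
            Species(
                name=info["canonical"],
                species_class=info["species_class"],
                compartment=(
                    "cytosol"
                    if info["canonical"].endswith("CYT")
                    else "mitochondrion"
                ),
                chain_length=info["chain_length"],
                fixed=bool(s.getBoundaryCondition() or s.getConstant()),
                value=float(s.getInitialConcentration() or 0.0),
            )
        )

    global_params = {
        sbml_model.getParameter(i).getId().lower(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions: list[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = r.getId()
        enz, chain = _parse_reaction_id(rid)
        params = dict(global_params)
        kl = r.getKineticLaw()
        if kl is not None:
            for j in range(kl.getNumLocalParameters()):
                lp = kl.getLocalParameter(j)
                params[lp.getId().lower()] = lp.getValue()
            for j in range(kl.getNumParameters()):
                lp = kl.getParameter(j)
                params[lp.getId().lower()] = lp.getValue()

        def lookup(*candidates, _params=params, _rid=rid):
            for cand in candidates:
                if cand.lower() in _params:
                    return _params[cand.lower()]
            unmapped.append(f"parameter:{_rid}:{candidates[0]}")
            return None

        subs, prods, stoich = {}, {}, {}
        bad_species = False
        for ref, sign, target in (
            *(((r.getReactant(j)), -1, subs) for j in range(r.getNumReactants())),
            *(((r.getProduct(j)), +1, prods) for j in range(r.getNumProducts())),
        ):
            sid = ref.getSpecies()
            if sid not in canonical:
                unmapped.append(f"speciesReference:{rid}:{sid}")
                bad_species = True
                continue
            name = canonical[sid]
            coeff = ref.getStoichiometry() or 1.0
            target[name] = int(round(coeff))
            stoich[name] = stoich.get(name, 0.0) + sign * coeff
        modifiers = []
        for j in range(r.getNumModifiers()):
            sid = r.getModifier(j).getSpecies()
            if sid not in canonical:
                unmapped.append(f"modifierSpeciesReference:{rid}:{sid}")
                bad_species = True
                continue
            modifiers.append(canonical[sid])
        if bad_species:
            continue

        vmax = lookup(f"V{enz}", f"Vmax{enz}", f"V{enz}C{chain}" if chain else f"V{enz}")
        keq = lookup(f"Keq{enz}", f"Keq{enz}C{chain}" if chain else f"Keq{enz}")
        sf = params.get(f"sf{enz}c{chain}".lower(), 1.0) if chain else 1.0
        km = {}
        ligands = list(dict.fromkeys([*subs, *prods, *modifiers]))
        inv_canonical = {v: k for k, v in canonical.items()}
        for lig in ligands:
            sid = inv_canonical[lig]
            val = lookup(f"Km{enz}{sid}", f"Km{enz}{lig}")
            if val is not None:
                km[lig] = float(val)
        if vmax is None or keq is None or len(km) != len(ligands):
            continue
        acyl_site = tuple(l for l in ligands if l not in _COFACTOR_SITE)
        cof_site = tuple(l for l in ligands if l in _COFACTOR_SITE)
        groups = {"acyl": acyl_site}
        if cof_site:
            groups["cofactor"] = cof_site
        reactions.append(
            Reaction(
                rid,
                enz.upper(),
                chain,
                stoich,
                RateLaw(
                    sf=float(sf),
                    vmax=float(vmax),
                    keq=float(keq),
                    km=km,
                    substrates=subs,
                    products=prods,
                    site_groups=groups,
                ),
            )
        )

    if unmapped:
        raise SBMLImportError(
            "unmapped SBML constructs: " + ", ".join(sorted(set(unmapped)))
        )
    coa_members = tuple(
        sp.name
        for sp in species
        if not sp.fixed
        and sp.compartment == "mitochondrion"
        and (
            sp.species_class in
            ("acyl-CoA", "enoyl-CoA", "hydroxyacyl-CoA", "ketoacyl-CoA")
            or sp.name == "CoAMAT"
        )
    )
    moieties = []
    if "CoAMAT" in coa_members:
        total = sum(sp.value for sp in species if sp.name in coa_members)
        moieties.append(Moiety("CoA", coa_members, total, pivot="CoAMAT"))
    car_members = tuple(
        sp.name
        for sp in species
        if not sp.fixed
        and sp.compartment == "mitochondrion"
        and (sp.species_class == "acyl-carnitine" or sp.name == "CarMAT")
    )
    if "CarMAT" in car_members and len(car_members) > 1:
        total = sum(sp.value for sp in species if sp.name in car_members)
        moieties.append(Moiety("Car", car_members, total, pivot="CarMAT"))
    return KineticModel(
        species,
        reactions,
        moieties=moieties,
        name=sbml_model.getId() or "imported",
        flux_readout=next(
            (rx.rid for rx in reactions if rx.enzyme == "CACT"),
            reactions[-1].rid if reactions else None,
        ),
        nadh_species="NADHMAT",
    )


def _parse_reaction_id(rid: str) -> tuple[str, int | None]:
    """Split a reaction id like ``vmcadC4`` into (``mcad``, 4)."""
    stem = rid[1:] if rid.lower().startswith("v") else rid
    chain = None
    if "C" in stem:
        head, _, tail = stem.rpartition("C")
        if tail.isdigit():
            return head, int(tail)
    return stem, chain
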