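"""Active-site occupancy and per-chain flux breakdowns."""

from __future__ import annotations

import pandas as pd

from .core import KineticModel, ModelConfigurationError, ModelState


def _acyl_site(model: KineticModel, enzyme: str):
    """The enzyme's acyl-ester site ligands and Kms (union over reactions)."""
    ligands: dict[str, float] = {}
    for rxn in model.reactions_of(enzyme):
        for lig in rxn.law.site_groups.get("acyl", ()):
            km = rxn.law.km[lig]
            prev = ligands.setdefault(lig, km)
            if prev != km:
                raise ModelConfigurationError(
                    f"enzyme {enzyme}: inconsistent Km for {lig} across reactions"
                )
    if not ligands:
        raise ModelConfigurationError(f"enzyme {enzyme} has no acyl site group")
    return ligands


def active_site_occupancy(
    model: KineticModel,
    state: ModelState,
    enzyme: str,
    normalized: bool = True,
) -> pd.DataFrame:
    """Fraction of the enzyme's acyl site occupied by each ligand.

    Under the default normalized convention
    ``Occ_j = ([Xj]/Km_j) / (1 + sum_k [Xk]/Km_k)`` the occupancies plus
    the free-site fraction sum to exactly 1.  ``normalized=False``
    evaluates the literal variant in which the ligand's own term is
    counted both alone and inside the competitor sum, which breaks the
    normalization and is retained for comparison only.
    """
    ligands = _acyl_site(model, enzyme)
    full = model.full_concentrations(state.vector(model.variable_names))
    conc = dict(zip(model.species_order, full))
    terms = {lig: conc[lig] / km for lig, km in ligands.items()}
    denom_all = 1.0 + sum(terms.values())
    rows = []
    for lig, term in terms.items():
        denom = denom_all if normalized else denom_all + term
        sp = model.species[lig]
        rows.append(
            {
                "ligand": lig,
                "occupancy": term / denom,
                "species_class": sp.species_class,
                "chain_length": sp.chain_length,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["enzyme"] = enzyme
    df.attrs["free_fraction"] = 1.0 / denom_all
    df.attrs["normalized"] = normalized
    return df


def occupancy_groups(occ: pd.DataFrame) -> dict[str, float]:
    """Grouped occupancy summary used for the thiolase readout.

    Groups: combined C4+C6 acyl-CoA, all other acyl-CoA esters,
    all ketoacyl-CoA substrates, and the remainder.
    """
    acyl_short = acyl_other = keto = other = 0.0
    for _, row in occ.iterrows():
        if row["species_class"] == "acyl-CoA":
            if row["chain_length"] in (4, 6):
                acyl_short += row["occupancy"]
            else:
                acyl_other += row["occupancy"]
        elif row["species_class"] == "ketoacyl-CoA":
            keto += row["occupancy"]
        else:
            other += row["occupancy"]
    return {
        "C4+C6 acyl-CoA": acyl_short,
        "other acyl-CoA": acyl_other,
        "ketoacyl-CoA": keto,
        "other": other,
        "free": occ.attrs["free_fraction"],
    }


def flux_breakdown(model: KineticModel, fluxes: dict[str, float]) -> pd.DataFrame:
    """Per-(enzyme, chain) flux table with branch shares per chain length."""
    rows = []
    for rxn in model.reactions:
        rows.append(
            {
                "reaction": rxn.rid,
                "enzyme": rxn.enzyme,
                "chain_length": rxn.chain_length,
                "flux": fluxes[rxn.rid],
            }
        )
    df = pd.DataFrame(rows)
    totals = df.groupby("enzyme")["flux"].sum().rename("enzyme_total")
    df = df.merge(totals, on="enzyme")
    # branch share: of the enoyl-consuming routes per chain length
    branch = df[df["enzyme"].isin(["MTP", "MCKAT"])]
    chain_tot = branch.groupby("chain_length")["flux"].transform("sum")
    df["branch_share"] = float("nan")
    df.loc[branch.index, "branch_share"] = branch["flux"] / chain_tot
    return df
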