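"""In-silico removal of enzyme promiscuity.

For each treated reaction the cross-chain competitor terms are deleted
from the binding-site denominator (own substrates and products are
retained) and the rate is rescaled by a partition factor
``alpha = 1 / n_reactions`` of the enzyme, representing an even split of
the enzyme pool over dedicated single-chain fractions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import KineticModel, ModelConfigurationError
from .simulate import FluxPeak, find_flux_peak, scan

logger = logging.getLogger(__name__)


def partition_factor(model: KineticModel, enzyme: str) -> float:
    """alpha = 1 / number of reactions the enzyme catalyses."""
    return 1.0 / len(model.reactions_of(enzyme))


def remove_promiscuity(model: KineticModel, enzymes) -> KineticModel:
    """Return a variant model with promiscuity removed from ``enzymes``.

    Idempotent: enzymes already treated (recorded in
    ``metadata["promiscuity_removed"]``) are left untouched, so applying
    the surgery twice equals applying it once.
    """
    if isinstance(enzymes, str):
        enzymes = [enzymes]
    enzymes = list(enzymes)
    for enz in enzymes:
        model.reactions_of(enz)  # raises for unknown enzymes
    variant = model.copy()
    already = set(variant.metadata.get("promiscuity_removed", []))
    treat = [e for e in enzymes if e not in already]
    for enz in treat:
        rxns = variant.reactions_of(enz)
        alpha = 1.0 / len(rxns)
        for rxn in rxns:
            law = rxn.law
            own = set(law.substrates) | set(law.products)
            law.site_groups = {
                gname: tuple(lig for lig in members if lig in own)
                for gname, members in law.site_groups.items()
            }
            law.km = {lig: km for lig, km in law.km.items() if lig in own}
            law.alpha = alpha
    variant.metadata["promiscuity_removed"] = sorted(already | set(treat))
    variant.name = f"{model.name}-nopromisc-" + ",".join(
        variant.metadata["promiscuity_removed"]
    )
    variant.invalidate()
    violations = variant.validate()
    if violations:  # pragma: no cover - surgery preserves validity
        raise ModelConfigurationError(
            "surgery produced an invalid model: " + "; ".join(violations)
        )
    return variant


def variant_scan_suite(
    model: KineticModel,
    parameter: str,
    grid,
    per_enzyme: bool = True,
    descending_check: bool = False,
) -> tuple[pd.DataFrame, dict[str, FluxPeak]]:
    """Flux curves for the canonical promiscuity-variant comparison.

    Variants: the full model, the fully de-promiscuized model, each
    single enzyme de-promiscuized (optional), and the complementary
    "only MCKAT promiscuous" model.  Returns an aligned table of uptake
    fluxes and the flux-peak location per variant.
    """
    promiscuous = [e for e in model.enzymes if len(model.reactions_of(e)) > 1]
    variants: dict[str, KineticModel] = {"full": model}
    variants["none"] = remove_promiscuity(model, promiscuous)
    if per_enzyme:
        for enz in promiscuous:
            variants[f"except_{enz}"] = remove_promiscuity(model, [enz])
    if "MCKAT" in promiscuous:
        variants["only_MCKAT"] = remove_promiscuity(
            model, [e for e in promiscuous if e != "MCKAT"]
        )
    grid = np.asarray(list(grid), dtype=float)
    out = pd.DataFrame({"param_value": grid})
    peaks: dict[str, FluxPeak] = {}
    for label, variant in variants.items():
        table = scan(variant, parameter, grid, descending_check=descending_check)
        out[f"J_{label}"] = table["J_uptake"].to_numpy()
        out[f"converged_{label}"] = table["converged"].to_numpy()
        peaks[label] = find_flux_peak(table, variant, parameter)
    out.attrs["variants"] = {
        k: v.metadata.get("promiscuity_removed", []) for k, v in variants.items()
    }
    return out, peaks
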