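"""Stoichiometric modeling of dicarboxylate catabolism and indigoidine yield.

Builds the pathway modifications — diacid transport, CoA ligation,
β-oxidation to succinyl-CoA (even chains) or glutaryl-CoA (odd chains), the
decarboxylative glutaryl-CoA degradation route, and NRPS indigoidine
synthesis from two L-glutamines — onto a stoichiometric model and computes
the maximum theoretical carbon yield (MTY) of indigoidine per substrate by
linear programming.

Two model sources share the modification code: a small self-contained core
template (TCA cycle, glyoxylate shunt, lumped respiration with configurable
P/O ratios and H+/ATP synthase stoichiometry, ammonium assimilation) that
runs without any download, and any SBML Level 3 FBC genome-scale model
loaded with :func:`load_sbml`.

Formula convention: metabolites carry BiGG-style ionized formulas
(succinate = C4H4O4), so every non-boundary reaction is element-balanced
against the standard cofactor formulas; the audit is enforced at build time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import cobra
import pandas as pd
from cobra import Metabolite, Model, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "build_core_template",
    "knockout_atp_maintenance",
    "add_diacid_pathway",
    "add_indigoidine_module",
    "solve_mty",
    "medium_mty",
    "load_sbml",
    "write_sbml",
    "audit_element_balance",
    "MTYResult",
    "INDIGOIDINE_CARBONS",
]

INDIGOIDINE_CARBONS = 10
BOUND = 1000.0

# BiGG-style ionized formulas for the shared species
_FORMULAS = {
    "h": "H",
    "h2o": "H2O",
    "co2": "CO2",
    "o2": "O2",
    "pi": "HO4P",
    "ppi": "HO7P2",
    "nh4": "H4N",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "amp": "C10H12N5O7P",
    "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
    "fad": "C27H31N9O15P2",
    "fadh2": "C27H33N9O15P2",
    "coa": "C21H32N7O16P3S",
    "accoa": "C23H34N7O17P3S",
    "oaa": "C4H2O5",
    "cit": "C6H5O7",
    "icit": "C6H5O7",
    "akg": "C5H4O5",
    "succoa": "C25H35N7O19P3S",
    "succ": "C4H4O4",
    "fum": "C4H2O4",
    "mal__L": "C4H4O5",
    "pyr": "C3H3O3",
    "glx": "C2HO3",
    "glu__L": "C5H8NO4",
    "gln__L": "C5H10N2O3",
    "b2coa": "C25H36N7O17P3S",
    "3hbcoa": "C25H38N7O18P3S",
    "aacoa": "C25H36N7O18P3S",
    "ind": "C10H8N4O4",
}


def _diacid_formula(n: int) -> str:
    # dianion of the Cn alpha,omega-diacid
    return f"C{n}H{2 * n - 4}O4"


def _diacyl_coa_formula(n: int) -> str:
    # mono-CoA thioester of the Cn diacid (free carboxylate deprotonated)
    return f"C{n + 21}H{2 * n + 27}N7O19P3S"


def _met(model: Model, mid: str, compartment: str = "c", formula: str | None = None) -> Metabolite:
    if mid in model.metabolites:
        return model.metabolites.get_by_id(mid)
    m = Metabolite(mid, formula=formula or _FORMULAS.get(mid.removesuffix("_e")), compartment=compartment)
    model.add_metabolites([m])
    return m


def _rxn(model: Model, rid: str, stoich: dict[str, float], lb: float = 0.0, ub: float = BOUND) -> Reaction:
    """Add a reaction by metabolite-id stoichiometry; idempotent on id."""
    if rid in model.reactions:
        return model.reactions.get_by_id(rid)
    r = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([r])
    r.add_metabolites({model.metabolites.get_by_id(mid): coef for mid, coef in stoich.items()})
    return r


def audit_element_balance(model: Model, skip_prefixes: tuple[str, ...] = ("BIOMASS",)) -> dict[str, dict]:
    """Per-element mass-balance check of every non-boundary reaction.

    Returns ``{reaction_id: imbalance}`` for violations; empty dict = clean.
    """
    violations: dict[str, dict] = {}
    for r in model.reactions:
        if r.boundary or r.id.startswith(skip_prefixes):
            continue
        imbalance = r.check_mass_balance()
        imbalance.pop("charge", None)  # charges are not assigned in the core template
        if any(abs(v) > 1e-9 for v in imbalance.values()):
            violations[r.id] = imbalance
    return violations


def _assert_balanced(model: Model) -> None:
    violations = audit_element_balance(model)
    if violations:
        raise ValueError(f"element-imbalanced reactions: {violations}")


def build_core_template(
    po_nadh: float = 2.5,
    po_fadh2: float = 1.5,
    h_per_atp: float = 4.0,
    include_biomass_sink: bool = False,
) -> Model:
    """Self-contained, element-balanced core network.

    TCA cycle, glyoxylate shunt (which doubles as the anaplerotic route),
    electron transport lumped into proton-pumping NADH/FADH2 oxidases, an
    ATP synthase importing ``h_per_atp`` periplasmic protons per ATP, and
    ammonium assimilation via glutamate dehydrogenase + glutamine
    synthetase. Exchanges: O2/NH4/Pi/H2O uptake, CO2 secretion only, a free
    cytosolic proton sink for hydrogen bookkeeping. The proton-motive force
    lives entirely in the periplasmic proton ``h_e``, which has no free
    exchange — it must be pumped.

    There is no ATP-maintenance reaction in the template (it would be
    knocked out for yield estimation anyway) and the biomass sink is off by
    default.
    """
    model = Model("diacid_core")
    for mid in _FORMULAS:
        if mid in ("b2coa", "3hbcoa", "aacoa", "ind"):
            continue  # added by the pathway/indigoidine builders
        _met(model, mid)
    _met(model, "h_e", compartment="e", formula="H")

    # --- TCA cycle ---
    _rxn(model, "CS", {"accoa": -1, "h2o": -1, "oaa": -1, "cit": 1, "coa": 1, "h": 1})
    _rxn(model, "ACONT", {"cit": -1, "icit": 1}, lb=-BOUND)
    _rxn(model, "ICDHx", {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1})
    _rxn(model, "AKGDH", {"akg": -1, "coa": -1, "nad": -1, "co2": 1, "nadh": 1, "succoa": 1})
    _rxn(model, "SUCOAS", {"atp": -1, "coa": -1, "succ": -1, "adp": 1, "pi": 1, "succoa": 1}, lb=-BOUND)
    _rxn(model, "SUCDi", {"fad": -1, "succ": -1, "fadh2": 1, "fum": 1})
    _rxn(model, "FUM", {"fum": -1, "h2o": -1, "mal__L": 1}, lb=-BOUND)
    _rxn(model, "MDH", {"mal__L": -1, "nad": -1, "h": 1, "nadh": 1, "oaa": 1}, lb=-BOUND)

    # --- cataplerosis: C4 intermediates to acetyl-CoA (malic enzyme + PDH) ---
    _rxn(model, "ME1", {"mal__L": -1, "nad": -1, "co2": 1, "nadh": 1, "pyr": 1})
    _rxn(model, "PDH", {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1})

    # --- glyoxylate shunt (anaplerosis from acetyl-CoA) ---
    _rxn(model, "ICL", {"icit": -1, "glx": 1, "succ": 1})
    _rxn(model, "MALS", {"accoa": -1, "glx": -1, "h2o": -1, "coa": 1, "h": 1, "mal__L": 1})

    # --- nitrogen assimilation ---
    _rxn(model, "GDH", {"akg": -1, "nadh": -1, "nh4": -1, "h": -1, "glu__L": 1, "h2o": 1, "nad": 1})
    _rxn(model, "GLNS", {"atp": -1, "glu__L": -1, "nh4": -1, "adp": 1, "gln__L": 1, "h": 1, "pi": 1})

    # --- lumped respiration: pump 4*(P/O) periplasmic protons per NADH/FADH2
    p_nadh = h_per_atp * po_nadh
    p_fadh2 = h_per_atp * po_fadh2
    _rxn(model, "NADH_OX", {"nadh": -1, "h": -(p_nadh + 1), "o2": -0.5, "nad": 1, "h2o": 1, "h_e": p_nadh})
    _rxn(model, "FADH2_OX", {"fadh2": -1, "h": -p_fadh2, "o2": -0.5, "fad": 1, "h2o": 1, "h_e": p_fadh2})
    _rxn(
        model,
        "ATPS4",
        {"adp": -1, "pi": -1, "h_e": -h_per_atp, "atp": 1, "h2o": 1, "h": h_per_atp - 1},
    )
    # uncoupled proton re-entry: dissipates PMF in excess of ATP demand but
    # can never create it (irreversible inward)
    _rxn(model, "HLEAK", {"h_e": -1, "h": 1})

    # --- phosphate housekeeping ---
    _rxn(model, "PPA", {"h2o": -1, "ppi": -1, "h": 1, "pi": 2})
    _rxn(model, "ADK1", {"amp": -1, "atp": -1, "adp": 2}, lb=-BOUND)

    # --- boundaries ---
    for mid, lb, ub in (
        ("o2", -BOUND, BOUND),
        ("co2", 0.0, BOUND),  # secretion only: carbon enters via substrates
        ("nh4", -BOUND, BOUND),
        ("pi", -BOUND, BOUND),
        ("h2o", -BOUND, BOUND),
    ):
        r = model.add_boundary(model.metabolites.get_by_id(mid), type="sink", reaction_id=f"EX_{mid}")
        r.bounds = (lb, ub)
    model.add_boundary(model.metabolites.get_by_id("h"), type="sink")  # SK_h, reversible

    if include_biomass_sink:
        for mid in ("accoa", "akg"):
            sk = model.add_boundary(model.metabolites.get_by_id(mid), type="sink", reaction_id=f"BIOMASS_SK_{mid}")
            sk.bounds = (0.0, BOUND)

    _assert_balanced(model)
    return model


def knockout_atp_maintenance(model: Model, reaction_id: str = "ATPM") -> Model:
    """Zero both bounds of the non-growth ATP maintenance reaction.

    Maintenance energy is irrelevant to a theoretical-yield ceiling. A model
    without the reaction (e.g. the core template) is returned unchanged with
    a warning. Idempotent.
    """
    if reaction_id in model.reactions:
        model.reactions.get_by_id(reaction_id).bounds = (0.0, 0.0)
    else:
        warnings.warn(f"no {reaction_id!r} reaction in model {model.id}; nothing to knock out")
    return model


def n_beta_oxidation_rounds(n: int) -> int:
    """Rounds from the Cn diacyl-CoA to succinyl-CoA (even) / glutaryl-CoA (odd)."""
    return (n - 4) // 2 if n % 2 == 0 else (n - 5) // 2


def _diacyl_coa_id(n: int) -> str:
    return "succoa" if n == 4 else f"dcacoa{n}"


def add_diacid_pathway(model: Model, n: int) -> Model:
    """Add transport, CoA ligation, and β-oxidation for the Cn diacid.

    Transport: C4-C6 diacids enter by 2-proton symport; C7+ by an ABC
    importer hydrolyzing 2 ATP. Activation is an AMP-forming CoA ligase
    (with pyrophosphate hydrolysis already in the template). β-oxidation
    rounds release one acetyl-CoA each, terminating at succinyl-CoA for even
    chains and glutaryl-CoA for odd chains; glutaryl-CoA is consumed by the
    decarboxylative route (oxidative decarboxylation to crotonyl-CoA + CO2,
    then hydration/oxidation/thiolysis to two acetyl-CoA). Succinate (C4)
    needs no activation here — it enters the TCA cycle directly. Idempotent
    per chain length.
    """
    if not 4 <= n <= 12:
        raise ValueError(f"chain length must be in 4..12, got {n}")

    ext = f"dca{n}_e"
    _met(model, ext, compartment="e", formula=_diacid_formula(n))
    if f"EX_{ext}" not in model.reactions:
        model.add_boundary(model.metabolites.get_by_id(ext), type="exchange").bounds = (0.0, 0.0)

    cyt = "succ" if n == 4 else f"dca{n}"
    _met(model, cyt, formula=_diacid_formula(n))

    if n <= 6:
        _rxn(model, f"DCAt{n}", {ext: -1, "h_e": -2, cyt: 1, "h": 2})
    else:
        _rxn(
            model,
            f"DCAabc{n}",
            {ext: -1, "atp": -2, "h2o": -2, cyt: 1, "adp": 2, "pi": 2, "h": 2},
        )

    if n >= 5:
        # AMP-forming CoA ligase on one carboxylate
        acyl = _diacyl_coa_id(n)
        _met(model, acyl, formula=_diacyl_coa_formula(n))
        _rxn(model, f"DCAL{n}", {cyt: -1, "atp": -1, "coa": -1, acyl: 1, "amp": 1, "ppi": 1})

    # β-oxidation down to succinyl-CoA (even) or glutaryl-CoA (odd)
    terminal = 4 if n % 2 == 0 else 5
    for k in range(n, terminal, -2):
        upper, lower = _diacyl_coa_id(k), _diacyl_coa_id(k - 2)
        _met(model, upper, formula=_diacyl_coa_formula(k))
        _met(model, lower, formula=_diacyl_coa_formula(k - 2))
        _rxn(
            model,
            f"BOX{k}",
            {
                upper: -1, "fad": -1, "nad": -1, "coa": -1, "h2o": -1,
                lower: 1, "accoa": 1, "fadh2": 1, "nadh": 1, "h": 1,
            },
        )

    if n % 2 == 1:
        _add_glutarate_route(model)

    _assert_balanced(model)
    return model


def _add_glutarate_route(model: Model) -> None:
    """Decarboxylative glutaryl-CoA degradation to two acetyl-CoA."""
    for mid in ("b2coa", "3hbcoa", "aacoa"):
        _met(model, mid)
    gcoa = _diacyl_coa_id(5)
    _met(model, gcoa, formula=_diacyl_coa_formula(5))
    _rxn(model, "GCDH", {gcoa: -1, "fad": -1, "h": -1, "b2coa": 1, "co2": 1, "fadh2": 1})
    _rxn(model, "ECOAH_B2", {"b2coa": -1, "h2o": -1, "3hbcoa": 1}, lb=-BOUND)
    _rxn(model, "HACD_3HB", {"3hbcoa": -1, "nad": -1, "aacoa": 1, "h": 1, "nadh": 1}, lb=-BOUND)
    _rxn(model, "ACACT", {"aacoa": -1, "coa": -1, "accoa": 2}, lb=-BOUND)


def add_indigoidine_module(model: Model, atp_per_gln: float = 1.0) -> Model:
    """NRPS condensation of two L-glutamines into indigoidine.

    ``atp_per_gln`` is the adenylation cost per glutamine (default 1,
    hydrolyzed to ADP + Pi for accounting). Oxygen uptake balances the
    oxidation to the conjugated pigment; the net reaction with the default
    cost is 2 gln + 2 O2 + 2 ATP -> indigoidine + 4 H2O + 2 ADP + 2 Pi + 2 H.
    A demand reaction ``DM_ind`` exports the product.
    """
    if atp_per_gln < 0:
        raise ValueError("atp_per_gln must be >= 0")
    if "gln__L" not in model.metabolites:
        raise ValueError("model lacks L-glutamine; cannot add indigoidine synthesis")
    _met(model, "ind")
    a = float(atp_per_gln)
    stoich = {
        "gln__L": -2.0,
        "o2": -2.0,
        "atp": -2 * a,
        "ind": 1.0,
        "h2o": 6.0 - 2 * a,
        "adp": 2 * a,
        "pi": 2 * a,
        "h": 2 * a,
    }
    if "IND_SYN" in model.reactions:
        model.remove_reactions(["IND_SYN"])
    _rxn(model, "IND_SYN", {k: v for k, v in stoich.items() if v != 0})
    if "DM_ind" not in model.reactions:
        model.add_boundary(model.metabolites.get_by_id("ind"), type="demand")
    _assert_balanced(model)
    return model


@dataclass
class MTYResult:
    """Maximum theoretical carbon yield of indigoidine from one substrate."""

    substrate: str
    chain_length: int
    carbon_yield: float  # carbons in indigoidine per substrate carbon
    indigoidine_flux: float
    status: str
    atp_per_gln: float | None = None
    fluxes: pd.Series | None = field(default=None, repr=False)


def solve_mty(
    model: Model,
    chain_length: int,
    uptake: float = 1.0,
    exchange_id: str | None = None,
    objective_id: str = "DM_ind",
) -> MTYResult:
    """Maximize indigoidine export with substrate uptake fixed at ``uptake``.

    carbon_yield = 10 * v_indigoidine / (n * uptake) for a Cn substrate
    (indigoidine has 10 carbons). All other diacid exchanges stay closed.
    """
    ex_id = exchange_id or f"EX_dca{chain_length}_e"
    if ex_id not in model.reactions:
        raise ValueError(f"substrate exchange {ex_id!r} not in model; add the pathway first")
    if objective_id not in model.reactions:
        raise ValueError(f"objective reaction {objective_id!r} not in model")
    with model:
        model.reactions.get_by_id(ex_id).bounds = (-uptake, -uptake)
        model.objective = objective_id
        sol = model.optimize()
        if sol.status != "optimal":
            raise RuntimeError(
                f"LP not optimal for {ex_id} (status={sol.status}); "
                f"check pathway additions and exchange bounds"
            )
        v_ind = float(sol.fluxes[objective_id])
        fluxes = sol.fluxes.copy()
    if uptake == 0:
        carbon_yield = 0.0
    else:
        carbon_yield = INDIGOIDINE_CARBONS * v_ind / (chain_length * uptake)
    if not -1e-6 <= carbon_yield <= 1 + 1e-6:
        raise RuntimeError(f"carbon yield {carbon_yield} outside [0, 1]: model leaks carbon")
    return MTYResult(
        substrate=ex_id,
        chain_length=chain_length,
        carbon_yield=min(max(carbon_yield, 0.0), 1.0),
        indigoidine_flux=v_ind,
        status=sol.status,
        fluxes=fluxes,
    )


def medium_mty(results: dict[int, MTYResult | float], medium) -> float:
    """Carbon-mole-weighted average MTY over a medium's diacid mixture.

    ``medium`` is a :class:`~diacidseq.yields.MediumMix`; every compound must
    have an entry in ``results`` keyed by its carbon count.
    """
    weights = []
    yields = []
    for compound, conc_mm in medium.components:
        res = results.get(compound.n_carbon)
        if res is None:
            raise KeyError(f"no MTY result for C{compound.n_carbon} ({compound.name})")
        y = res.carbon_yield if isinstance(res, MTYResult) else float(res)
        weights.append(conc_mm * compound.n_carbon)
        yields.append(y)
    total = sum(weights)
    if total <= 0:
        raise ValueError("medium contains no carbon")
    return sum(w * y for w, y in zip(weights, yields)) / total


def build_production_model(
    chains=(4, 5, 6, 7, 8, 9, 10, 12),
    atp_per_gln: float = 1.0,
    po_nadh: float = 2.5,
    po_fadh2: float = 1.5,
    h_per_atp: float = 4.0,
    base_model: Model | None = None,
) -> Model:
    """Core template (or a loaded model) with all requested diacid pathways,
    the indigoidine module, and ATP maintenance knocked out."""
    if base_model is None:
        model = build_core_template(po_nadh=po_nadh, po_fadh2=po_fadh2, h_per_atp=h_per_atp)
    else:
        model = base_model
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the core template has no ATPM
        knockout_atp_maintenance(model)
    for n in chains:
        add_diacid_pathway(model, n)
    add_indigoidine_module(model, atp_per_gln=atp_per_gln)
    return model


def load_sbml(path) -> Model:
    """Read an SBML Level 3 FBC model; the same modification operations
    (knockouts, pathway additions) then apply to it."""
    return cobra.io.read_sbml_model(str(path))


def write_sbml(model: Model, path) -> None:
    cobra.io.write_sbml_model(model, str(path))
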