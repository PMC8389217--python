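"""The PhoBR two-component-system models: full (29 reactions) and reduced.

Full model
----------
PhoR is a homodimeric histidine kinase represented by three phosphorylation
states (DiPhoR, DiPhoRp, DiPhoRpp).  Autophosphorylation (r01-r04, scaled
by the external-Pi fold change fc) feeds two phosphotransfer routes to the
response regulator PhoB via explicit PhoR-PhoB complexes (r05-r10).
Phosphorylated PhoB dimerises into the active transcription factor DiPhoBpp
(r11-r12); unphosphorylated PhoR dimers act as a phosphatase on PhoBp
through a Michaelis-type complex (r13-r15).  DiPhoBpp binds the phoA and
phoBR promoters (r16-r19, scaled by the promoter-design folds bf/uf);
active promoters transcribe mRNA and mRNA is translated into PhoA, PhoB
and PhoR (r20-r24); mRNAs and proteins are degraded or diluted (r25-r29).

The numeric rate constants bundled here are a synthetic re-parameterisation:
they are chosen once inside physiological *E. coli* ranges (mRNA half-lives
of minutes, ~1 h dilution, sub-second-to-minute promoter kinetics) and
calibrated so the network reaches equilibrium well before 16,200 s and
spans partial promoter occupancy across fc in {0.1, 0.3, 1.0}.

Reduced model
-------------
The quasi-steady-state reduction collapses PhoR to a two-state variable
(PhoR/PhoRp), eliminates the PhoR-PhoB complexes in favour of effective
bimolecular constants, and removes mRNA by assuming it is fast: lumped
expression constants equal translation-rate x transcription-rate / mRNA
decay.  Because a PhoR dimer presents two phosphatase-competent monomers
while the reduced two-state unit presents one, the naive per-unit
dephosphorylation constant k3 underestimates the full model's phosphatase
capacity; the documented calibration multiplier (default 2) restores the
steady-state balance.  10 species, 2 promoter conservation laws, hence an
8-dimensional independent ODE system.
"""

from __future__ import annotations

import numpy as np

from .crn import (
    COPIES_PER_UM,
    ConservationLaw,
    CRNModel,
    Reaction,
    Species,
)

__all__ = [
    "FULL_PARAMS",
    "FULL_INITIAL",
    "build_full_model",
    "build_reduced_model",
    "reduced_params_from_full",
]

#: Rate constants of the full model, keyed by reaction id.
#: Units: s^-1 for first-order, uM^-1 s^-1 for second-order reactions.
FULL_PARAMS = {
    # PhoR autophosphorylation (fc-scaled) and reverse
    "r01": 0.05,   # DiPhoR   -> DiPhoRp          [fc]
    "r02": 0.01,   # DiPhoRp  -> DiPhoR
    "r03": 0.035,  # DiPhoRp  -> DiPhoRpp         [fc]
    "r04": 0.01,   # DiPhoRpp -> DiPhoRp
    # phosphotransfer to PhoB through explicit complexes
    "r05": 0.1,    # DiPhoRpp + PhoB -> C_RppB
    "r06": 0.5,    # C_RppB -> DiPhoRpp + PhoB
    "r07": 1.0,    # C_RppB -> DiPhoRp + PhoBp
    "r08": 0.1,    # DiPhoRp + PhoB -> C_RpB
    "r09": 0.5,    # C_RpB -> DiPhoRp + PhoB
    "r10": 1.0,    # C_RpB -> DiPhoR + PhoBp
    # PhoBp dimerisation
    "r11": 0.2,    # 2 PhoBp -> DiPhoBpp
    "r12": 0.1,    # DiPhoBpp -> 2 PhoBp
    # phosphatase activity of unphosphorylated PhoR
    "r13": 0.05,   # DiPhoR + PhoBp -> C_RB
    "r14": 0.5,    # C_RB -> DiPhoR + PhoBp
    "r15": 1.0,    # C_RB -> DiPhoR + PhoB
    # TF-promoter binding/unbinding (bf/uf-scaled)
    "r16": 1.8,    # DiPhoBpp + pPhoA -> pPhoAa   [bf]
    "r17": 0.1,    # pPhoAa -> DiPhoBpp + pPhoA   [uf]
    "r18": 1.8,    # DiPhoBpp + pPhoB -> pPhoBa   [bf]
    "r19": 0.1,    # pPhoBa -> DiPhoBpp + pPhoB   [uf]
    # transcription and translation
    "r20": 0.03,   # pPhoAa -> pPhoAa + mRNAa
    "r21": 0.01,   # pPhoBa -> pPhoBa + mRNAb
    "r22": 0.08,   # mRNAa -> mRNAa + PhoA
    "r23": 0.2,    # mRNAb -> mRNAb + PhoB
    "r24": 0.04,   # mRNAb -> mRNAb + DiPhoR
    # degradation / dilution
    "r25": 0.03,    # mRNAa -> 0
    "r26": 0.005,   # mRNAb -> 0
    "r27": 3.0e-4,  # PhoA -> 0
    "r28": 3.0e-4,  # PhoB -> 0
    "r29": 3.0e-4,  # DiPhoR -> 0
}

#: Initial concentrations (uM) of the non-promoter species: free protein
#: pools unphosphorylated, no complexes, no mRNA, no product protein.
FULL_INITIAL = {
    "DiPhoR": 1.0,
    "PhoB": 5.0,
}

_FULL_REACTIONS = [
    ("r01", {"DiPhoR": 1}, {"DiPhoRp": 1}, "fc"),
    ("r02", {"DiPhoRp": 1}, {"DiPhoR": 1}, "none"),
    ("r03", {"DiPhoRp": 1}, {"DiPhoRpp": 1}, "fc"),
    ("r04", {"DiPhoRpp": 1}, {"DiPhoRp": 1}, "none"),
    ("r05", {"DiPhoRpp": 1, "PhoB": 1}, {"C_RppB": 1}, "none"),
    ("r06", {"C_RppB": 1}, {"DiPhoRpp": 1, "PhoB": 1}, "none"),
    ("r07", {"C_RppB": 1}, {"DiPhoRp": 1, "PhoBp": 1}, "none"),
    ("r08", {"DiPhoRp": 1, "PhoB": 1}, {"C_RpB": 1}, "none"),
    ("r09", {"C_RpB": 1}, {"DiPhoRp": 1, "PhoB": 1}, "none"),
    ("r10", {"C_RpB": 1}, {"DiPhoR": 1, "PhoBp": 1}, "none"),
    ("r11", {"PhoBp": 2}, {"DiPhoBpp": 1}, "none"),
    ("r12", {"DiPhoBpp": 1}, {"PhoBp": 2}, "none"),
    ("r13", {"DiPhoR": 1, "PhoBp": 1}, {"C_RB": 1}, "none"),
    ("r14", {"C_RB": 1}, {"DiPhoR": 1, "PhoBp": 1}, "none"),
    ("r15", {"C_RB": 1}, {"DiPhoR": 1, "PhoB": 1}, "none"),
    ("r16", {"DiPhoBpp": 1, "pPhoA": 1}, {"pPhoAa": 1}, "bf"),
    ("r17", {"pPhoAa": 1}, {"DiPhoBpp": 1, "pPhoA": 1}, "uf"),
    ("r18", {"DiPhoBpp": 1, "pPhoB": 1}, {"pPhoBa": 1}, "bf"),
    ("r19", {"pPhoBa": 1}, {"DiPhoBpp": 1, "pPhoB": 1}, "uf"),
    ("r20", {"pPhoAa": 1}, {"pPhoAa": 1, "mRNAa": 1}, "none"),
    ("r21", {"pPhoBa": 1}, {"pPhoBa": 1, "mRNAb": 1}, "none"),
    ("r22", {"mRNAa": 1}, {"mRNAa": 1, "PhoA": 1}, "none"),
    ("r23", {"mRNAb": 1}, {"mRNAb": 1, "PhoB": 1}, "none"),
    ("r24", {"mRNAb": 1}, {"mRNAb": 1, "DiPhoR": 1}, "none"),
    ("r25", {"mRNAa": 1}, {}, "none"),
    ("r26", {"mRNAb": 1}, {}, "none"),
    ("r27", {"PhoA": 1}, {}, "none"),
    ("r28", {"PhoB": 1}, {}, "none"),
    ("r29", {"DiPhoR": 1}, {}, "none"),
]

#: ordered species roster of the full model
_FULL_SPECIES = [
    "DiPhoR", "DiPhoRp", "DiPhoRpp",
    "PhoB", "PhoBp", "DiPhoBpp",
    "C_RppB", "C_RpB", "C_RB",
    "pPhoA", "pPhoAa", "pPhoB", "pPhoBa",
    "mRNAa", "mRNAb", "PhoA",
]


def build_full_model(
    params: dict | None = None,
    promoter_copies: int = 10,
    volume: float = 1.0,
    initial: dict | None = None,
) -> CRNModel:
    """Construct the 29-reaction PhoBR network as a :class:`CRNModel`.

    ``promoter_copies`` sets the conserved total of each promoter (10
    plasmids by default; 1 at one-tenth volume for the single-cell
    switch experiment).  A missing rate constant raises ``KeyError``
    naming the reaction id.
    """
    params = dict(FULL_PARAMS if params is None else params)
    init = dict(FULL_INITIAL if initial is None else initial)
    prom_conc = promoter_copies / (COPIES_PER_UM * volume)
    conc = {name: init.get(name, 0.0) for name in _FULL_SPECIES}
    conc["pPhoA"] = prom_conc
    conc["pPhoB"] = prom_conc
    species = [Species(n, initial_concentration=conc[n]) for n in _FULL_SPECIES]
    reactions = []
    for rid, reac, prod, tag in _FULL_REACTIONS:
        if rid not in params:
            raise KeyError(f"missing rate constant for reaction {rid}")
        reactions.append(Reaction(rid, reac, prod, params[rid], tag))
    laws = [
        ConservationLaw(("pPhoA", "pPhoAa"), promoter_copies),
        ConservationLaw(("pPhoB", "pPhoBa"), promoter_copies),
    ]
    model = CRNModel(
        model_id="phobr_full",
        species=species,
        reactions=reactions,
        volume=volume,
        conservation_laws=laws,
    )
    # promoters must start at exactly the conserved copy number
    for law in model.conservation_laws:
        free = law.species[0]
        idx = model.index(free)
        if model.species[idx].initial_copies != promoter_copies:
            from dataclasses import replace

            model.species[idx] = replace(
                model.species[idx], initial_copies=promoter_copies
            )
    return model


def reduced_params_from_full(
    params: dict | None = None, k3_multiplier: float = 2.0
) -> dict:
    """Derive the reduced model's constants from the full parameter set.

    * two-state kinase: activation/deactivation keep the per-step
      autophosphorylation constants (q01 = r01, q02 = r02);
    * complex elimination: effective bimolecular phosphotransfer
      kt = r05 * r07/(r06 + r07) (quasi-equilibrium of the complex), and
      per-unit phosphatase k3 = r13 * r15/(r14 + r15), multiplied by
      ``k3_multiplier`` to account for the two phosphatase-competent
      monomers of the PhoR dimer;
    * mRNA elimination (QSSA): lumped expression constants
      s = translation * transcription / mRNA-decay.
    """
    p = dict(FULL_PARAMS if params is None else params)
    return {
        "q01": p["r01"],                                  # PhoR -> PhoRp [fc]
        "q02": p["r02"],                                  # PhoRp -> PhoR
        "q03": p["r05"] * p["r07"] / (p["r06"] + p["r07"]),  # transfer
        # per-monomer phosphatase site: half the dimer's association rate
        "q04": k3_multiplier * (p["r13"] / 2) * p["r15"] / (p["r14"] + p["r15"]),
        "q05": p["r11"],
        "q06": p["r12"],
        "q07": p["r16"],
        "q08": p["r17"],
        "q09": p["r18"],
        "q10": p["r19"],
        "q11": p["r22"] * p["r20"] / p["r25"],            # pPhoAa -> +PhoA
        "q12": p["r23"] * p["r21"] / p["r26"],            # pPhoBa -> +PhoB
        "q13": p["r24"] * p["r21"] / p["r26"],            # pPhoBa -> +PhoR
        "q14": p["r27"],
        "q15": p["r28"],
        "q16": p["r29"],
    }


_REDUCED_REACTIONS = [
    ("q01", {"PhoR": 1}, {"PhoRp": 1}, "fc"),
    ("q02", {"PhoRp": 1}, {"PhoR": 1}, "none"),
    ("q03", {"PhoRp": 1, "PhoB": 1}, {"PhoR": 1, "PhoBp": 1}, "none"),
    ("q04", {"PhoR": 1, "PhoBp": 1}, {"PhoR": 1, "PhoB": 1}, "none"),
    ("q05", {"PhoBp": 2}, {"DiPhoBpp": 1}, "none"),
    ("q06", {"DiPhoBpp": 1}, {"PhoBp": 2}, "none"),
    ("q07", {"DiPhoBpp": 1, "pPhoA": 1}, {"pPhoAa": 1}, "bf"),
    ("q08", {"pPhoAa": 1}, {"DiPhoBpp": 1, "pPhoA": 1}, "uf"),
    ("q09", {"DiPhoBpp": 1, "pPhoB": 1}, {"pPhoBa": 1}, "bf"),
    ("q10", {"pPhoBa": 1}, {"DiPhoBpp": 1, "pPhoB": 1}, "uf"),
    ("q11", {"pPhoAa": 1}, {"pPhoAa": 1, "PhoA": 1}, "none"),
    ("q12", {"pPhoBa": 1}, {"pPhoBa": 1, "PhoB": 1}, "none"),
    ("q13", {"pPhoBa": 1}, {"pPhoBa": 1, "PhoR": 1}, "none"),
    ("q14", {"PhoA": 1}, {}, "none"),
    ("q15", {"PhoB": 1}, {}, "none"),
    ("q16", {"PhoR": 1}, {}, "none"),
]

_REDUCED_SPECIES = [
    "PhoR", "PhoRp", "PhoB", "PhoBp", "DiPhoBpp",
    "pPhoA", "pPhoAa", "pPhoB", "pPhoBa", "PhoA",
]


def build_reduced_model(
    params: dict | None = None,
    promoter_copies: int = 10,
    volume: float = 1.0,
    k3_multiplier: float = 2.0,
    initial: dict | None = None,
) -> CRNModel:
    """Construct the reduced two-state-kinase model from full parameters.

    ``params`` is the *full* model's parameter set; the reduced constants
    are derived by :func:`reduced_params_from_full`.  ``k3_multiplier``
    is the documented dimer-site calibration on PhoBp dephosphorylation
    (2 restores the full model's steady state; 1 leaves the uncalibrated
    reduction testable).
    """
    q = reduced_params_from_full(params, k3_multiplier=k3_multiplier)
    init = dict(FULL_INITIAL if initial is None else initial)
    prom_conc = promoter_copies / (COPIES_PER_UM * volume)
    conc = {name: 0.0 for name in _REDUCED_SPECIES}
    conc["PhoR"] = init.get("DiPhoR", init.get("PhoR", 0.0))
    conc["PhoB"] = init.get("PhoB", 0.0)
    conc["pPhoA"] = prom_conc
    conc["pPhoB"] = prom_conc
    species = [Species(n, initial_concentration=conc[n]) for n in _REDUCED_SPECIES]
    reactions = []
    for rid, reac, prod, tag in _REDUCED_REACTIONS:
        if rid not in q:
            raise KeyError(f"missing rate constant for reaction {rid}")
        reactions.append(Reaction(rid, reac, prod, q[rid], tag))
    laws = [
        ConservationLaw(("pPhoA", "pPhoAa"), promoter_copies),
        ConservationLaw(("pPhoB", "pPhoBa"), promoter_copies),
    ]
    model = CRNModel(
        model_id="phobr_reduced",
        species=species,
        reactions=reactions,
        volume=volume,
        conservation_laws=laws,
    )
    from dataclasses import replace

    for law in model.conservation_laws:
        idx = model.index(law.species[0])
        if model.species[idx].initial_copies != promoter_copies:
            model.species[idx] = replace(
                model.species[idx], initial_copies=promoter_copies
            )
    return model


# -- bundled model files ---------------------------------------------------

_DATA_DIR = None


def data_dir():
    """Directory holding the bundled model-definition files."""
    global _DATA_DIR
    if _DATA_DIR is None:
        from pathlib import Path

        _DATA_DIR = Path(__file__).parent / "data"
    return _DATA_DIR


def load_bundled(name: str) -> CRNModel:
    """Load a bundled model file: ``"full"`` or ``"reduced"``."""
    from .crn import load_model

    path = data_dir() / f"phobr_{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no bundled model {name!r} at {path}")
    return load_model(path)
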