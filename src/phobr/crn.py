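"""Mass-action chemical reaction networks: species, reactions, propensities.

The data model is deliberately small: a :class:`CRNModel` is an ordered list
of species plus a list of mass-action reactions of total order at most two,
together with the cell volume and any copy-number conservation laws.  Rate
constants are stored in deterministic units (s^-1 for first order,
uM^-1 s^-1 for second order, uM s^-1 for zeroth order) and converted to
stochastic propensity constants at evaluation time via the cell volume.

Reactions carry a ``scaling_tag`` so that environment (``fc``, the fold
change on sensor-kinase autophosphorylation standing in for external
inorganic phosphate) and synthetic promoter strength (``bf``/``uf``, folds
on transcription-factor binding/unbinding) can be applied without rebuilding
the network.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "COPIES_PER_UM",
    "Species",
    "Reaction",
    "ConservationLaw",
    "CRNModel",
    "ScalingFactors",
    "concentration_to_counts",
    "counts_to_concentration",
    "propensity",
    "apply_scaling",
    "check_conservation",
    "load_model",
    "save_model",
]

AVOGADRO = 6.02214076e23
#: copies per (uM * um^3): 1e-6 mol/L * N_A /L * 1e-15 L/um^3
COPIES_PER_UM = AVOGADRO * 1e-6 * 1e-15

VALID_TAGS = ("none", "fc", "bf", "uf")


def concentration_to_counts(conc: float, volume: float) -> int:
    """Convert a concentration in uM to an integer copy number.

    Parameters
    ----------
    conc : float
        Concentration in uM (>= 0).
    volume : float
        Cell volume in um^3 (> 0).

    Returns
    -------
    int
        ``round(conc * N_A * 1e-21 * volume)`` -- the nearest whole number
        of molecules.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return int(round(conc * COPIES_PER_UM * volume))


def counts_to_concentration(counts: float, volume: float) -> float:
    """Inverse of :func:`concentration_to_counts` (uM from copies)."""
    if counts < 0:
        raise ValueError(f"counts must be >= 0, got {counts}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return counts / (COPIES_PER_UM * volume)


@dataclass(frozen=True)
class Species:
    """A chemical species with its initial condition.

    ``initial_concentration`` (uM) is authoritative; ``initial_copies`` is
    the rounded copy number at the model volume and is filled in by
    :class:`CRNModel` when absent.
    """

    name: str
    initial_concentration: float = 0.0
    initial_copies: int | None = None

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ValueError(f"{self.name}: initial concentration < 0")
        if self.initial_copies is not None and self.initial_copies < 0:
            raise ValueError(f"{self.name}: initial copies < 0")


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometric coefficients.  Total reactant order must be <= 2.
    """

    id: str
    reactants: dict
    products: dict
    rate_constant: float
    scaling_tag: str = "none"

    def __post_init__(self):
        if self.scaling_tag not in VALID_TAGS:
            raise ValueError(
                f"{self.id}: scaling_tag {self.scaling_tag!r} not in {VALID_TAGS}"
            )
        if self.rate_constant < 0:
            raise ValueError(f"{self.id}: negative rate constant")
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if not (isinstance(coeff, (int, np.integer)) and coeff > 0):
                    raise ValueError(
                        f"{self.id}: stoichiometric coefficient of {name} "
                        f"must be a positive integer, got {coeff!r}"
                    )
        if self.order > 2:
            raise ValueError(
                f"{self.id}: total reactant order {self.order} > 2 unsupported"
            )

    @property
    def order(self) -> int:
        return int(sum(self.reactants.values()))

    def net_change(self, name: str) -> int:
        return self.products.get(name, 0) - self.reactants.get(name, 0)


@dataclass(frozen=True)
class ConservationLaw:
    """A set of species whose summed copy number is invariant."""

    species: tuple
    total_copies: int

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))


@dataclass(frozen=True)
class ScalingFactors:
    """The (fc, bf, uf) condition triple.

    fc scales sensor-kinase autophosphorylation (external Pi proxy; 1 = full
    starvation, 0 = Pi replete), bf scales TF-promoter binding, uf scales
    TF-promoter unbinding.  (1, 1, 1) is the control condition.
    """

    fc: float = 1.0
    bf: float = 1.0
    uf: float = 1.0

    def __post_init__(self):
        for attr in ("fc", "bf", "uf"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    def combine(self, other: "ScalingFactors") -> "ScalingFactors":
        return ScalingFactors(
            self.fc * other.fc, self.bf * other.bf, self.uf * other.uf
        )


@dataclass
class CRNModel:
    """A simulatable mass-action reaction network.

    Attributes
    ----------
    model_id : str
        Short identifier recorded on trajectories.
    species : list of Species
        Ordered; the order fixes state-vector layout everywhere.
    reactions : list of Reaction
    volume : float
        Cell volume in um^3.
    conservation_laws : list of ConservationLaw
    """

    model_id: str
    species: list
    reactions: list
    volume: float = 1.0
    conservation_laws: list = field(default_factory=list)

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self._index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for name in list(rxn.reactants) + list(rxn.products):
                if name not in self._index:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown species {name!r}"
                    )
        # fill in initial copy numbers from concentrations where absent
        filled = []
        for s in self.species:
            if s.initial_copies is None:
                s = replace(
                    s,
                    initial_copies=concentration_to_counts(
                        s.initial_concentration, self.volume
                    ),
                )
            filled.append(s)
        self.species = filled
        for law in self.conservation_laws:
            self._validate_law(law)

    def _validate_law(self, law: ConservationLaw) -> None:
        for name in law.species:
            if name not in self._index:
                raise ValueError(f"conservation law references unknown species {name!r}")
        for rxn in self.reactions:
            net = sum(rxn.net_change(name) for name in law.species)
            if net != 0:
                raise ValueError(
                    f"conservation law over {law.species} broken by reaction {rxn.id}"
                )

    # -- indexing ---------------------------------------------------------
    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- state vectors ----------------------------------------------------
    def initial_counts(self) -> np.ndarray:
        return np.array([s.initial_copies for s in self.species], dtype=np.int64)

    def initial_concentrations(self) -> np.ndarray:
        return np.array(
            [s.initial_concentration for s in self.species], dtype=float
        )

    # -- stoichiometry ----------------------------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix S (n_species x n_reactions)."""
        S = np.zeros((self.n_species, len(self.reactions)), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.reactants.items():
                S[self._index[name], j] -= coeff
            for name, coeff in rxn.products.items():
                S[self._index[name], j] += coeff
        return S

    def with_reactions(self, reactions: list) -> "CRNModel":
        out = _copy.copy(self)
        out.reactions = list(reactions)
        out.__post_init__()
        return out


def propensity(reaction: Reaction, state: np.ndarray, volume: float,
               index: dict) -> float:
    """Stochastic propensity (events/s) of one reaction in a copy-number state.

    First order: ``k * x``.  Heterobimolecular: ``k/(N_A V) * xA * xB`` with
    k in uM^-1 s^-1.  Homodimerisation ``2A -> ...``: stochastic constant
    ``2k/(N_A V)`` over ``x(x-1)/2`` reactant pairs.  Zeroth order
    (k in uM s^-1): ``k * N_A V``.
    """
    scale = COPIES_PER_UM * volume
    k = reaction.rate_constant
    if np.any(state < 0):
        raise ValueError("negative copy number in state")
    items = list(reaction.reactants.items())
    if reaction.order == 0:
        return k * scale
    if reaction.order == 1:
        name, _ = items[0]
        return k * state[index[name]]
    # order 2
    if len(items) == 1:  # 2A -> ...
        x = state[index[items[0][0]]]
        return (2.0 * k / scale) * (x * (x - 1) / 2.0)
    xa = state[index[items[0][0]]]
    xb = state[index[items[1][0]]]
    return (k / scale) * xa * xb


def apply_scaling(model: CRNModel, s: ScalingFactors) -> CRNModel:
    """Return a copy of *model* with tagged rate constants multiplied.

    fc-tagged reactions are scaled by ``s.fc``, bf-tagged by ``s.bf``,
    uf-tagged by ``s.uf``; untagged reactions are untouched.  The input
    model is not mutated.
    """
    factor = {"none": 1.0, "fc": s.fc, "bf": s.bf, "uf": s.uf}
    scaled = [
        replace(r, rate_constant=r.rate_constant * factor[r.scaling_tag])
        for r in model.reactions
    ]
    return model.with_reactions(scaled)


def check_conservation(model: CRNModel, traj, tol: float = 0.0):
    """Check every conservation law along a trajectory.

    Parameters
    ----------
    model : CRNModel
    traj : Trajectory
        Must expose ``states`` (n_times x n_species) and ``species`` names
        ordered as in the model.
    tol : float
        Allowed absolute deviation (0 for SSA paths, ~10*atol for ODE).

    Returns
    -------
    (bool, float)
        Whether all laws hold within *tol*, and the maximum deviation seen.
    """
    states = np.asarray(traj.states, dtype=float)
    max_dev = 0.0
    for law in model.conservation_laws:
        for name in law.species:
            if name not in model._index:
                raise ValueError(f"unknown species {name!r} in conservation law")
        cols = [model.index(name) for name in law.species]
        totals = states[:, cols].sum(axis=1)
        max_dev = max(max_dev, float(np.abs(totals - totals[0]).max()))
    return max_dev <= tol, max_dev


# -- model files -----------------------------------------------------------

def _model_to_dict(model: CRNModel) -> dict:
    return {
        "model_id": model.model_id,
        "volume_um3": float(model.volume),
        "species": [
            {
                "name": s.name,
                "initial_concentration_uM": float(s.initial_concentration),
                "initial_copies": int(s.initial_copies),
            }
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "rate": float(r.rate_constant),
                "scaling_tag": r.scaling_tag,
            }
            for r in model.reactions
        ],
        "conservation_laws": [
            {"species": list(law.species), "total_copies": int(law.total_copies)}
            for law in model.conservation_laws
        ],
    }


def _model_from_dict(d: dict) -> CRNModel:
    species = [
        Species(
            name=s["name"],
            initial_concentration=float(s.get("initial_concentration_uM", 0.0)),
            initial_copies=s.get("initial_copies"),
        )
        for s in d["species"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            reactants={k: int(v) for k, v in (r.get("reactants") or {}).items()},
            products={k: int(v) for k, v in (r.get("products") or {}).items()},
            rate_constant=float(r["rate"]),
            scaling_tag=r.get("scaling_tag", "none"),
        )
        for r in d["reactions"]
    ]
    laws = [
        ConservationLaw(tuple(law["species"]), int(law["total_copies"]))
        for law in d.get("conservation_laws", [])
    ]
    return CRNModel(
        model_id=d["model_id"],
        species=species,
        reactions=reactions,
        volume=float(d.get("volume_um3", 1.0)),
        conservation_laws=laws,
    )


def save_model(model: CRNModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> CRNModel:
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))
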