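"""Small reaction networks with closed-form stationary statistics.

These validate the simulator and the noise metrics end to end: the SSA,
the grid sampling and the CV/FF estimators must reproduce analytic means
and Fano factors of

* a birth-death process (Poisson stationary law, FF = 1),
* a one-copy telegraph promoter driving mRNA (super-Poissonian FF),
* N independent two-state promoters (binomial active count, FF = 1 - p),

the last being the mechanism behind the FF <= 1 bound for active-promoter
copy numbers in the PhoBR analysis.

Rate constants here are given directly on the copy-number scale, so the
oracle models use volume such that 1 uM corresponds to whatever the copies
convention implies; all oracle reactions are zeroth or first order, which
makes the volume irrelevant to the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .crn import COPIES_PER_UM, ConservationLaw, CRNModel, Reaction, Species

__all__ = ["OracleModel", "birth_death", "telegraph_promoter", "n_copy_promoter"]


@dataclass(frozen=True)
class OracleModel:
    """A CRN bundled with its analytic stationary facts.

    ``facts`` maps species name -> {"mean": ..., "variance": ..., "ff": ...}
    and ``formulas`` records the generating expressions as text.
    """

    model: CRNModel
    facts: dict
    formulas: dict = field(default_factory=dict)


def birth_death(k: float, gamma: float) -> OracleModel:
    """Birth-death process: 0 -> X at k copies/s, X -> 0 at gamma /s.

    Stationary law is Poisson(k/gamma): mean k/gamma, FF = 1.
    """
    if k <= 0 or gamma <= 0:
        raise ValueError("k and gamma must be > 0")
    volume = 1.0
    # zeroth-order deterministic constant in uM/s giving k events/s
    k_det = k / (COPIES_PER_UM * volume)
    model = CRNModel(
        model_id="oracle_birth_death",
        species=[Species("X", initial_copies=0)],
        reactions=[
            Reaction("birth", {}, {"X": 1}, k_det),
            Reaction("death", {"X": 1}, {}, gamma),
        ],
        volume=volume,
    )
    lam = k / gamma
    return OracleModel(
        model=model,
        facts={"X": {"mean": lam, "variance": lam, "ff": 1.0}},
        formulas={"X": "Poisson(k/gamma): mean = var = k/gamma, FF = 1"},
    )


def telegraph_promoter(
    k_on: float, k_off: float, k_tx: float, d: float
) -> OracleModel:
    """One gene copy switching off<->on, transcribing only when on.

    Stationary mRNA mean = (k_tx/d) * k_on/(k_on+k_off);
    FF = 1 + k_tx*k_off / ((k_on+k_off) * (k_on+k_off+d)).
    """
    if min(k_on, k_off, k_tx, d) <= 0:
        raise ValueError("all rates must be > 0")
    model = CRNModel(
        model_id="oracle_telegraph",
        species=[
            Species("Goff", initial_copies=1),
            Species("Gon", initial_copies=0),
            Species("M", initial_copies=0),
        ],
        reactions=[
            Reaction("on", {"Goff": 1}, {"Gon": 1}, k_on),
            Reaction("off", {"Gon": 1}, {"Goff": 1}, k_off),
            Reaction("tx", {"Gon": 1}, {"Gon": 1, "M": 1}, k_tx),
            Reaction("deg", {"M": 1}, {}, d),
        ],
        conservation_laws=[ConservationLaw(("Goff", "Gon"), 1)],
        volume=1.0,
    )
    p = k_on / (k_on + k_off)
    mean = k_tx / d * p
    ff = 1.0 + k_tx * k_off / ((k_on + k_off) * (k_on + k_off + d))
    return OracleModel(
        model=model,
        facts={
            "M": {"mean": mean, "variance": ff * mean, "ff": ff},
            "Gon": {"mean": p, "variance": p * (1 - p), "ff": 1 - p},
        },
        formulas={
            "M": "mean = (k_tx/d) k_on/(k_on+k_off); "
                 "FF = 1 + k_tx k_off/((k_on+k_off)(k_on+k_off+d))",
            "Gon": "Bernoulli(p), p = k_on/(k_on+k_off): FF = 1-p",
        },
    )


def n_copy_promoter(N: int, k_on: float, k_off: float) -> OracleModel:
    """N independent two-state promoters; active count is Binomial(N, p).

    p = k_on/(k_on+k_off); mean Np, variance Np(1-p), FF = 1-p <= 1.
    Decreasing k_off (slower unbinding) raises p and lowers FF -- the
    mechanism by which slow-unbinding promoter designs suppress
    active-promoter noise.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    model = CRNModel(
        model_id="oracle_n_copy_promoter",
        species=[
            Species("Poff", initial_copies=N),
            Species("Pon", initial_copies=0),
        ],
        reactions=[
            Reaction("bind", {"Poff": 1}, {"Pon": 1}, k_on),
            Reaction("unbind", {"Pon": 1}, {"Poff": 1}, k_off),
        ],
        conservation_laws=[ConservationLaw(("Poff", "Pon"), N)],
        volume=1.0,
    )
    p = k_on / (k_on + k_off)
    return OracleModel(
        model=model,
        facts={
            "Pon": {"mean": N * p, "variance": N * p * (1 - p), "ff": 1 - p}
        },
        formulas={"Pon": "Binomial(N, p), p = k_on/(k_on+k_off): FF = 1-p"},
    )
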