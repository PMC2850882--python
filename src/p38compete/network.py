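"""Mass-action reaction networks for p38 substrate competition.

The base scheme is a random-order bi-substrate mechanism: active p38
reversibly binds ATP (independently of everything else) and reversibly
binds one protein substrate (MK2 or ATF2); the ternary complex undergoes an
irreversible catalysis step releasing phospho-substrate, ADP and the free
enzyme.  Five alternate mechanisms extend this scheme:

#1  substrate inhibition — phospho-MK2 and phospho-ATF2 rebind the enzyme
    (dead-end) at the same rates as the unphosphorylated substrates;
#2  phospho-MK2 binds free ATF2 (at the p38-ATF2 affinity), blocking it;
#3  MK2 turnover leaves the enzyme in an altered state p38* with a
    10-fold weakened ATP affinity;
#4  as #3 but with a 10-fold weakened ATF2 affinity;
#5  as #3 but with a 10-fold reduced ATF2 catalytic rate.

Inhibitors are either *classical* (equal affinity K_I for every enzyme
form) or *substrate selective*: affinity K_I for the MK2-bound forms and a
reduced affinity K_I/(1-f) elsewhere, where f in [0, 1] is the selectivity.
Because a selective compound stabilises the p38-MK2 complex, the MK2
dissociation rate from every inhibitor-bound complex is multiplied by
(1-f); this is exactly the correction required for microscopic
reversibility (every closed binding cycle has unit product of equilibrium
constants), and :func:`p38compete.thermo.check_thermodynamic_cycles`
verifies it.

Networks are built generatively: enzyme states are enumerated as
(enzyme variant, ATP bound?, substrate slot, inhibitor bound?) and every
legal single-ligand association is emitted as one reversible reaction, so
detailed balance holds by construction.  All stoichiometries are one.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .params import KineticParameters

__all__ = [
    "Mechanism",
    "MechanismConfig",
    "InhibitorSpec",
    "CompetitorSpec",
    "Species",
    "ReactionDef",
    "NetworkModel",
    "ConfigurationError",
    "build_network",
]


class ConfigurationError(ValueError):
    """An inconsistent mechanism/inhibitor configuration was requested."""


class Mechanism(str, enum.Enum):
    """Reaction-scheme variants for the dual-substrate system."""

    BASE = "base"
    SUBSTRATE_INHIBITION = "substrate_inhibition"      # 1
    PMK2_BINDS_ATF2 = "pmk2_binds_atf2"                # 2
    ALTERED_ATP = "altered_atp"                        # 3
    ALTERED_ATF2_AFFINITY = "altered_atf2_affinity"    # 4
    ALTERED_KCAT = "altered_kcat"                      # 5


#: Mechanisms that convert the enzyme to the altered state p38* at the MK2
#: catalysis step.
ALTERED_MECHANISMS = frozenset(
    {Mechanism.ALTERED_ATP, Mechanism.ALTERED_ATF2_AFFINITY, Mechanism.ALTERED_KCAT}
)


@dataclass(frozen=True)
class MechanismConfig:
    """Selects exactly one reaction-scheme variant (no stacking)."""

    variant: Mechanism = Mechanism.BASE

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Mechanism(self.variant))


@dataclass(frozen=True)
class InhibitorSpec:
    """A p38 inhibitor compound.

    ``ki`` is the affinity (nM) for the preferred target: every enzyme form
    for a classical compound, the MK2-bound forms for a substrate-selective
    one.  ``selectivity_f`` in [0, 1]: 0 = no selectivity, 1 = perfect
    selectivity (the compound then does not bind non-MK2 forms at all).
    ``atp_mode='competitive'`` forbids simultaneous ATP and compound
    binding; ``'noncompetitive'`` allows it with unchanged ATP affinity.
    """

    ki: float = 1.0
    selectivity_f: float = 0.0
    inhibitor_class: str = "classical"
    atp_mode: str = "noncompetitive"

    def __post_init__(self) -> None:
        if not (self.ki > 0):
            raise ConfigurationError(f"ki must be > 0, got {self.ki!r}")
        if self.inhibitor_class not in ("classical", "substrate_selective"):
            raise ConfigurationError(
                f"unknown inhibitor_class {self.inhibitor_class!r}"
            )
        if self.atp_mode not in ("competitive", "noncompetitive"):
            raise ConfigurationError(f"unknown atp_mode {self.atp_mode!r}")
        if not (0.0 <= self.selectivity_f <= 1.0):
            raise ConfigurationError(
                f"selectivity_f must lie in [0, 1], got {self.selectivity_f!r}"
            )
        if self.inhibitor_class == "classical" and self.selectivity_f != 0.0:
            raise ConfigurationError(
                "a classical inhibitor has selectivity_f = 0 by definition"
            )


@dataclass(frozen=True)
class CompetitorSpec:
    """A generic weak competing substrate (peptide-4 analog).

    Modeled as a third substrate with its own affinity and catalytic rate
    and no altered-state induction.
    """

    kd_uM: float = 40.0
    kcat: float = 1.0

    @property
    def kd_nM(self) -> float:
        return self.kd_uM * 1e3


# --------------------------------------------------------------------------
# species / reactions
# --------------------------------------------------------------------------

#: moiety composition of the elementary name parts; "ADO" is the adenosine
#: moiety shared by ATP, ADP and every ATP-bound complex.
_PART_MOIETY = {
    "p38": "p38",
    "p38*": "p38",
    "ATP": "ADO",
    "ADP": "ADO",
    "ATF2": "ATF2",
    "pATF2": "ATF2",
    "MK2": "MK2",
    "pMK2": "MK2",
    "I": "I",
    "PEP": "PEP",
    "pPEP": "PEP",
}


def composition_of(name: str) -> dict[str, int]:
    """Moiety composition of a species name like ``"p38*:ATP:MK2:I"``.

    Multisite phosphoforms (``"ATF2_p2"``) count as one substrate moiety.
    """
    comp: dict[str, int] = {}
    for part in name.split(":"):
        if part in _PART_MOIETY:
            m = _PART_MOIETY[part]
        elif "_p" in part and part.split("_p")[0] in _PART_MOIETY:
            m = _PART_MOIETY[part.split("_p")[0]]
        else:
            raise ValueError(f"unknown species part {part!r} in {name!r}")
        comp[m] = comp.get(m, 0) + 1
    return comp


@dataclass
class Species:
    """A named chemical species with its conserved-moiety composition."""

    name: str
    composition: Mapping[str, int] = field(default_factory=dict)
    initial: float = 0.0  # nM

    def __post_init__(self) -> None:
        if not self.composition:
            self.composition = composition_of(self.name)


@dataclass
class ReactionDef:
    """One mass-action reaction; ``kr is None`` marks it irreversible.

    Reactants/products are (species name, stoichiometry) pairs; all
    stoichiometries in the generated networks are 1.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kf: float
    kr: Optional[float] = None
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.kr is not None


class NetworkModel:
    """Species + mass-action reactions; the simulatable object.

    Provides the stoichiometry matrix, conserved-moiety bookkeeping and a
    compiled right-hand side / Jacobian for stiff integration.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[ReactionDef],
        provenance: Optional[dict] = None,
    ) -> None:
        self.species = list(species)
        self.reactions = list(reactions)
        self.provenance = dict(provenance or {})
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for nm, _ in (*r.reactants, *r.products):
                if nm not in self._index:
                    raise ValueError(f"reaction {r.name!r} uses unknown species {nm!r}")
        for s in self.species:
            if not (s.initial >= 0):
                raise ValueError(f"negative initial concentration for {s.name}")
        self._compiled = None

    # ---- basic accessors ------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def set_initial(self, name: str, value: float) -> None:
        if value < 0:
            raise ValueError("initial concentrations must be >= 0")
        self.species[self._index[name]].initial = float(value)

    def set_initials(self, values: Mapping[str, float]) -> None:
        for k, v in values.items():
            self.set_initial(k, v)

    def initial_vector(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    # ---- stoichiometry / conservation -----------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer stoichiometry matrix S (species x reactions), net
        change per unit forward extent."""
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for nm, nu in r.reactants:
                S[self._index[nm], j] -= nu
            for nm, nu in r.products:
                S[self._index[nm], j] += nu
        return S

    def conserved_moieties(self) -> dict[str, np.ndarray]:
        """Named integer weight vectors (one per moiety present) that are
        exactly conserved: w @ S == 0 with integer arithmetic."""
        keys = sorted({m for s in self.species for m in s.composition})
        return {
            m: np.array([s.composition.get(m, 0) for s in self.species], dtype=np.int64)
            for m in keys
        }

    def verify_conservation(self) -> None:
        """Raise if any moiety weight vector is not in the left null space
        of the stoichiometry matrix (exact integer test)."""
        S = self.stoichiometry_matrix()
        for m, w in self.conserved_moieties().items():
            resid = w @ S
            if np.any(resid != 0):
                bad = [self.reactions[j].name for j in np.nonzero(resid)[0]]
                raise AssertionError(f"moiety {m!r} not conserved by {bad}")

    def moiety_total(self, moiety: str, state: np.ndarray) -> float:
        w = self.conserved_moieties()[moiety]
        return float(w @ state)

    # ---- mass-action RHS -------------------------------------------------
    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        n = len(self.species)
        i1, i2, ks, cols = [], [], [], []
        Scols = []
        for r in self.reactions:
            # forward direction
            idxs = []
            for nm, nu in r.reactants:
                idxs.extend([self._index[nm]] * nu)
            if len(idxs) > 2:
                raise NotImplementedError("mass-action order > 2 not supported")
            col = np.zeros(n)
            for nm, nu in r.reactants:
                col[self._index[nm]] -= nu
            for nm, nu in r.products:
                col[self._index[nm]] += nu
            i1.append(idxs[0] if idxs else n)
            i2.append(idxs[1] if len(idxs) > 1 else n)
            ks.append(r.kf)
            Scols.append(col)
            if r.reversible and r.kr:
                idxs = []
                for nm, nu in r.products:
                    idxs.extend([self._index[nm]] * nu)
                if len(idxs) > 2:
                    raise NotImplementedError("mass-action order > 2 not supported")
                i1.append(idxs[0] if idxs else n)
                i2.append(idxs[1] if len(idxs) > 1 else n)
                ks.append(r.kr)
                Scols.append(-col)
        self._compiled = (
            np.array(i1),
            np.array(i2),
            np.array(ks, dtype=float),
            np.column_stack(Scols) if Scols else np.zeros((n, 0)),
        )
        return self._compiled

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Mass-action time derivative at state ``y`` (nM, nM/s)."""
        i1, i2, k, S = self._compile()
        if y.shape[-1] != len(self.species):
            raise ValueError(
                f"state has {y.shape[-1]} entries, network has {len(self.species)} species"
            )
        ye = np.append(y, 1.0)
        rates = k * ye[i1] * ye[i2]
        return S @ rates

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        i1, i2, k, S = self._compile()
        n = len(self.species)
        ye = np.append(y, 1.0)
        m = len(k)
        D = np.zeros((m, n + 1))
        rows = np.arange(m)
        np.add.at(D, (rows, i1), k * ye[i2])
        np.add.at(D, (rows, i2), k * ye[i1])
        return S @ D[:, :n]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        prov = self.provenance.get("mechanism", "custom")
        return (
            f"<NetworkModel {prov}: {len(self.species)} species, "
            f"{len(self.reactions)} reactions>"
        )


# --------------------------------------------------------------------------
# generative builder
# --------------------------------------------------------------------------

_EnzState = tuple[str, bool, Optional[str], bool]  # (enzyme, atp, substrate, inhibited)


def _state_name(st: _EnzState) -> str:
    enz, atp, sub, inh = st
    parts = [enz]
    if atp:
        parts.append("ATP")
    if sub is not None:
        parts.append(sub)
    if inh:
        parts.append("I")
    return ":".join(parts)


def build_network(
    params: KineticParameters | None = None,
    mechanism: MechanismConfig | Mechanism | str = Mechanism.BASE,
    inhibitor: Optional[InhibitorSpec] = None,
    competitor: Optional[CompetitorSpec] = None,
    *,
    catalysis: bool = True,
    apply_reversibility_correction: bool = True,
) -> NetworkModel:
    """Construct the mass-action network for one configuration.

    Parameters
    ----------
    params : kinetic constants (reference defaults when omitted).
    mechanism : one of the six scheme variants.
    inhibitor : optional compound specification.
    competitor : optional generic weak substrate (peptide analog).
    catalysis : set False to build a binding-only network (no product
        species), used for equilibrium cross-checks.
    apply_reversibility_correction : when False, the (1-f) factor on MK2
        dissociation from inhibitor-bound complexes is deliberately
        omitted — the network then violates detailed balance, which
        :func:`p38compete.thermo.check_thermodynamic_cycles` flags.  For
        diagnostics only.

    All initial concentrations are zero; set them from an assay protocol.
    """
    params = params or KineticParameters()
    if not isinstance(mechanism, MechanismConfig):
        mechanism = MechanismConfig(Mechanism(mechanism))
    mech = mechanism.variant

    kon_p = params.kon_protein_nM
    kon_s = params.kon_small_nM
    f = inhibitor.selectivity_f if inhibitor is not None else 0.0
    selective = inhibitor is not None and inhibitor.inhibitor_class == "substrate_selective"

    enzymes = ["p38"] + (["p38*"] if mech in ALTERED_MECHANISMS else [])
    subs: list[str] = ["ATF2", "MK2"]
    if mech is Mechanism.SUBSTRATE_INHIBITION:
        subs += ["pATF2", "pMK2"]
    if competitor is not None:
        subs += ["PEP"]

    def mk2_like(sub: Optional[str]) -> bool:
        return sub in ("MK2", "pMK2")

    def state_ok(st: _EnzState) -> bool:
        enz, atp, sub, inh = st
        if inh and inhibitor is None:
            return False
        if inh and inhibitor.atp_mode == "competitive" and atp:
            return False
        # perfect selectivity: the compound cannot occupy non-MK2 forms
        if inh and selective and f == 1.0 and not mk2_like(sub):
            return False
        return True

    def kd_atp(enz: str) -> float:
        kd = params.kd_atp_nM
        if enz == "p38*" and mech is Mechanism.ALTERED_ATP:
            kd *= params.altered_factor
        return kd

    def kd_sub(enz: str, sub: str, inh: bool) -> float:
        if sub in ("ATF2", "pATF2"):
            kd = params.kd_atf2_nM
            if enz == "p38*" and mech is Mechanism.ALTERED_ATF2_AFFINITY:
                kd *= params.altered_factor
        elif sub in ("MK2", "pMK2"):
            kd = params.kd_mk2_nM
            if inh and selective and apply_reversibility_correction:
                kd *= 1.0 - f
        elif sub == "PEP":
            kd = competitor.kd_nM
        else:  # pragma: no cover - defensive
            raise ValueError(sub)
        return kd

    def kd_inh(sub: Optional[str]) -> Optional[float]:
        ki = inhibitor.ki
        if not selective:
            return ki
        if mk2_like(sub):
            return ki
        if f == 1.0:
            return None  # no binding to non-MK2 forms at all
        return ki / (1.0 - f)

    states = [
        st
        for st in itertools.product(
            enzymes, (False, True), [None, *subs], (False, True)
        )
        if state_ok(st)
    ]
    state_set = set(states)
    reactions: list[ReactionDef] = []

    def add(reactants, products, kf, kr, name):
        reactions.append(
            ReactionDef(
                tuple((n, 1) for n in reactants),
                tuple((n, 1) for n in products),
                kf,
                kr,
                name,
            )
        )

    for st in states:
        enz, atp, sub, inh = st
        nm = _state_name(st)
        # ATP association
        if not atp and (tgt := (enz, True, sub, inh)) in state_set:
            add([nm, "ATP"], [_state_name(tgt)], kon_s, kd_atp(enz) * kon_s,
                f"{nm} + ATP")
        # substrate association
        if sub is None:
            for x in subs:
                if (tgt := (enz, atp, x, inh)) in state_set:
                    add([nm, x], [_state_name(tgt)], kon_p,
                        kd_sub(enz, x, inh) * kon_p, f"{nm} + {x}")
        # inhibitor association
        if inhibitor is not None and not inh and (tgt := (enz, atp, sub, True)) in state_set:
            kd = kd_inh(sub)
            if kd is not None:
                add([nm, "I"], [_state_name(tgt)], kon_s, kd * kon_s, f"{nm} + I")
        # catalysis (inhibitor-bound complexes are dead)
        if catalysis and atp and not inh and sub in ("ATF2", "MK2", "PEP"):
            if sub == "ATF2":
                kcat = params.kcat_atf2
                if enz == "p38*" and mech is Mechanism.ALTERED_KCAT:
                    kcat /= params.altered_factor
                enz_out, prod = enz, "pATF2"
            elif sub == "MK2":
                kcat = params.kcat_mk2
                enz_out = "p38*" if mech in ALTERED_MECHANISMS else enz
                prod = "pMK2"
            else:
                kcat, enz_out, prod = competitor.kcat, enz, "pPEP"
            add([nm], [enz_out, prod, "ADP"], kcat, None, f"{nm} -> {prod}")

    # mechanism #2: phospho-MK2 sequesters free ATF2 at the p38-ATF2 affinity
    if mech is Mechanism.PMK2_BINDS_ATF2:
        add(["pMK2", "ATF2"], ["pMK2:ATF2"], kon_p,
            params.kd_atf2_nM * kon_p, "pMK2 + ATF2")

    names: list[str] = []
    seen: set[str] = set()

    def note(n: str) -> None:
        if n not in seen:
            seen.add(n)
            names.append(n)

    # stable ordering: free species first, then enzyme states
    for n in ("p38", "ATP", "ADP", "ATF2", "MK2", "pATF2", "pMK2"):
        note(n)
    if inhibitor is not None:
        note("I")
    if competitor is not None:
        note("PEP")
        note("pPEP")
    for r in reactions:
        for n, _ in (*r.reactants, *r.products):
            note(n)

    # drop species that participate in no reaction (e.g. product species of
    # a binding-only build)
    used = {n for r in reactions for n, _ in (*r.reactants, *r.products)}
    names = [n for n in names if n in used]

    model = NetworkModel(
        [Species(n) for n in names],
        reactions,
        provenance={
            "mechanism": mech.value,
            "inhibitor": None if inhibitor is None else vars(inhibitor) | {},
            "competitor": None if competitor is None else vars(competitor) | {},
            "catalysis": catalysis,
            "reversibility_correction": apply_reversibility_correction,
        },
    )
    model.verify_conservation()
    return model
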