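"""In-silico assay protocols: time courses, single/dual substrate assays,
inhibitor dose-responses, the virtual-compound titration, the MK2 titration
and the two-stage immunoprecipitation experiment.

The default protocol mirrors the biochemical assay: 0.5 nM active p38,
50 uM ATP, 100 nM ATF2 and 10 nM MK2 in one well; phospho-MK2 is read at
30 min and phospho-ATF2 at 120 min (each within the linear range of the
corresponding plate assay).  Dose-response signals are normalised to the
zero-dose (vehicle) well of the same configuration, i.e. reported as a
fraction of the maximal signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .network import (
    ALTERED_MECHANISMS,
    CompetitorSpec,
    InhibitorSpec,
    Mechanism,
    MechanismConfig,
    NetworkModel,
    build_network,
)
from .params import KineticParameters
from .simulate import SolverOptions, TimeCourse, simulate_timecourse

__all__ = [
    "AssayProtocol",
    "DoseResponse",
    "default_dose_grid",
    "simulate_protocol",
    "run_assay",
    "mk2_titration",
    "virtual_compound_p38",
    "virtual_compound_assay",
    "ip_two_stage",
    "dose_responses_to_frame",
]

#: default readout times (s): phospho-MK2 at 30 min, phospho-ATF2 at 2 h.
DEFAULT_READOUTS = {"pMK2": 1800.0, "pATF2": 7200.0}


@dataclass(frozen=True)
class AssayProtocol:
    """Initial concentrations and readout plan for one experiment."""

    p38_nM: float = 0.5
    atp_uM: float = 50.0
    atf2_nM: float = 100.0
    mk2_nM: float = 10.0
    competitor: Optional[CompetitorSpec] = None
    competitor_uM: float = 0.0
    readouts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_READOUTS)
    )

    def __post_init__(self) -> None:
        for f_ in ("p38_nM", "atp_uM", "atf2_nM", "mk2_nM", "competitor_uM"):
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")

    # -- canonical variants ---------------------------------------------
    @classmethod
    def dual(cls, **kw) -> "AssayProtocol":
        return cls(**kw)

    @classmethod
    def single_atf2(cls, **kw) -> "AssayProtocol":
        kw.setdefault("readouts", {"pATF2": DEFAULT_READOUTS["pATF2"]})
        return cls(mk2_nM=0.0, **kw)

    @classmethod
    def single_mk2(cls, **kw) -> "AssayProtocol":
        kw.setdefault("readouts", {"pMK2": DEFAULT_READOUTS["pMK2"]})
        return cls(atf2_nM=0.0, **kw)

    def with_(self, **changes) -> "AssayProtocol":
        return replace(self, **changes)

    def initials(self) -> dict[str, float]:
        ini = {
            "p38": self.p38_nM,
            "ATP": self.atp_uM * 1e3,
            "ATF2": self.atf2_nM,
            "MK2": self.mk2_nM,
        }
        if self.competitor is not None:
            ini["PEP"] = self.competitor_uM * 1e3
        return ini

    @property
    def horizon(self) -> float:
        return max(self.readouts.values())


@dataclass
class DoseResponse:
    """Raw and normalised readouts on a dose grid for one species."""

    species: str
    doses: np.ndarray          # nM, ascending, first entry 0
    raw: np.ndarray            # nM of phospho-species at the readout time
    normalized: np.ndarray     # fraction of the zero-dose signal
    readout_time: float
    meta: dict = field(default_factory=dict)
    replicates: Optional[np.ndarray] = None  # (n_doses, n_replicates), normalised

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")


def default_dose_grid(ki: float, n: int = 12) -> np.ndarray:
    """Log-spaced dose grid spanning [ki/100, ki*1e4] plus dose 0 (nM)."""
    return np.concatenate([[0.0], np.geomspace(ki / 100.0, ki * 1e4, n)])


# --------------------------------------------------------------------------
# core runners
# --------------------------------------------------------------------------


def simulate_protocol(
    protocol: AssayProtocol,
    params: KineticParameters | None = None,
    mechanism: Mechanism | MechanismConfig | str = Mechanism.BASE,
    inhibitor: Optional[InhibitorSpec] = None,
    inhibitor_dose_nM: float = 0.0,
    t_eval: Optional[Sequence[float]] = None,
    network: Optional[NetworkModel] = None,
    solver: SolverOptions = SolverOptions(),
    horizon: Optional[float] = None,
) -> TimeCourse:
    """Build (or reuse) the network for a configuration and integrate one
    well of the assay."""
    if network is None:
        network = build_network(
            params, mechanism, inhibitor, competitor=protocol.competitor
        )
    ini = protocol.initials()
    if inhibitor is not None:
        ini["I"] = inhibitor_dose_nM
    elif inhibitor_dose_nM:
        raise ValueError("a dose was given without an inhibitor spec")
    horizon = horizon or protocol.horizon
    if t_eval is None:
        times = sorted({0.0, *protocol.readouts.values(), horizon})
        t_eval = np.array(times)
    return simulate_timecourse(network, horizon, ini, t_eval=t_eval, solver=solver)


def run_assay(
    protocol: AssayProtocol,
    params: KineticParameters | None = None,
    mechanism: Mechanism | MechanismConfig | str = Mechanism.BASE,
    inhibitor: Optional[InhibitorSpec] = None,
    doses: Optional[Sequence[float]] = None,
    solver: SolverOptions = SolverOptions(),
) -> dict[str, DoseResponse]:
    """Simulate an inhibitor dose-response: one integration per dose,
    readouts at the per-species times, normalised to the zero-dose well.

    Returns one :class:`DoseResponse` per readout species of the protocol.
    """
    if inhibitor is None:
        raise ValueError("run_assay needs an inhibitor; use simulate_protocol otherwise")
    doses = np.asarray(
        default_dose_grid(inhibitor.ki) if doses is None else doses, dtype=float
    )
    if doses[0] != 0.0:
        doses = np.concatenate([[0.0], doses])
    network = build_network(params, mechanism, inhibitor, competitor=protocol.competitor)
    readings: dict[str, list[float]] = {sp: [] for sp in protocol.readouts}
    for dose in doses:
        tc = simulate_protocol(
            protocol, params, mechanism, inhibitor, dose,
            network=network, solver=solver,
        )
        for sp, t_read in protocol.readouts.items():
            readings[sp].append(tc.value(sp, t_read))
    out: dict[str, DoseResponse] = {}
    for sp, t_read in protocol.readouts.items():
        raw = np.array(readings[sp])
        if raw[0] <= 0:
            raise ValueError(
                f"zero-dose signal for {sp} is 0; cannot normalise "
                "(is the substrate present in this protocol?)"
            )
        out[sp] = DoseResponse(
            species=sp,
            doses=doses,
            raw=raw,
            normalized=raw / raw[0],
            readout_time=t_read,
            meta={
                "mechanism": MechanismConfig(Mechanism(mechanism)).variant.value
                if not isinstance(mechanism, MechanismConfig)
                else mechanism.variant.value,
                "inhibitor_class": inhibitor.inhibitor_class,
                "atp_mode": inhibitor.atp_mode,
                "ki_nM": inhibitor.ki,
                "selectivity_f": inhibitor.selectivity_f,
                "assay": "single" if (protocol.mk2_nM == 0 or protocol.atf2_nM == 0) else "dual",
            },
        )
    return out


def mk2_titration(
    protocol: AssayProtocol,
    params: KineticParameters | None = None,
    mechanism: Mechanism | MechanismConfig | str = Mechanism.BASE,
    mk2_levels: Sequence[float] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    solver: SolverOptions = SolverOptions(),
) -> pd.DataFrame:
    """Phospho-ATF2 at its readout time as a function of total MK2.

    The level-0 entry is exactly the single-substrate (ATF2-only) value.
    """
    mk2_levels = np.asarray(mk2_levels, dtype=float)
    if np.any(mk2_levels < 0):
        raise ValueError("mk2_levels must be >= 0")
    network = build_network(params, mechanism, competitor=protocol.competitor)
    t_read = protocol.readouts.get("pATF2", DEFAULT_READOUTS["pATF2"])
    rows = []
    for mk2 in mk2_levels:
        p = protocol.with_(mk2_nM=float(mk2), readouts={"pATF2": t_read})
        tc = simulate_protocol(p, params, mechanism, network=network, solver=solver)
        rows.append({"mk2_nM": float(mk2), "pATF2_nM": tc.value("pATF2", t_read)})
    return pd.DataFrame(rows)


def virtual_compound_p38(dose: float, ki: float, p38_total: float) -> float:
    """Effective free p38 after titration by an idealised inhibitor.

    The bound fraction follows the binding isotherm dose/(dose + K_I);
    the returned value re-initialises assay simulations at reduced enzyme.
    """
    if not (ki > 0):
        raise ValueError("ki must be > 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return p38_total * (1.0 - dose / (dose + ki))


def virtual_compound_assay(
    protocol: AssayProtocol,
    params: KineticParameters | None = None,
    mechanism: Mechanism | MechanismConfig | str = Mechanism.BASE,
    doses: Optional[Sequence[float]] = None,
    ki: float = 1.0,
    solver: SolverOptions = SolverOptions(),
) -> dict[str, DoseResponse]:
    """Dose-response of the 'virtual compound': each dose lowers the p38
    initial condition by the binding isotherm and the assay is re-run."""
    doses = np.asarray(default_dose_grid(ki) if doses is None else doses, dtype=float)
    if doses[0] != 0.0:
        doses = np.concatenate([[0.0], doses])
    network = build_network(params, mechanism, competitor=protocol.competitor)
    readings: dict[str, list[float]] = {sp: [] for sp in protocol.readouts}
    for dose in doses:
        p = protocol.with_(p38_nM=virtual_compound_p38(dose, ki, protocol.p38_nM))
        tc = simulate_protocol(p, params, mechanism, network=network, solver=solver)
        for sp, t_read in protocol.readouts.items():
            readings[sp].append(tc.value(sp, t_read))
    out = {}
    for sp, t_read in protocol.readouts.items():
        raw = np.array(readings[sp])
        out[sp] = DoseResponse(
            species=sp,
            doses=doses,
            raw=raw,
            normalized=raw / raw[0],
            readout_time=t_read,
            meta={
                "mechanism": Mechanism(mechanism).value
                if not isinstance(mechanism, MechanismConfig)
                else mechanism.variant.value,
                "inhibitor_class": "virtual",
                "ki_nM": ki,
                "assay": "dual" if (protocol.mk2_nM and protocol.atf2_nM) else "single",
            },
        )
    return out


def ip_two_stage(
    params: KineticParameters | None = None,
    mechanism: Mechanism | MechanismConfig | str = Mechanism.BASE,
    mk2_levels: Sequence[float] = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0),
    stage1_duration: float = 3600.0,
    stage2_duration: float = 7200.0,
    p38_nM: float = 5.0,
    atp_uM: float = 50.0,
    atf2_nM: float = 100.0,
    solver: SolverOptions = SolverOptions(),
) -> pd.DataFrame:
    """Simulated analog of the pull-down experiment.

    Stage 1: 5 nM p38 + ATP + varying MK2 (no ATF2) for ``stage1_duration``
    seconds.  The enzyme is then captured and washed: every p38-containing
    complex dissociates to its free enzyme form (p38 or the altered p38*),
    and all MK2/phospho-MK2/nucleotide species are discarded.  Stage 2:
    the recovered enzyme reacts with fresh ATP and 100 nM ATF2 and
    phospho-ATF2 is read after ``stage2_duration`` seconds.

    With the base mechanism the carried-over enzyme is all plain p38, so
    the result is independent of the stage-1 MK2 dose; the altered-state
    mechanisms (#3-5) transfer a memory of the MK2 exposure.
    """
    mech = (
        mechanism.variant
        if isinstance(mechanism, MechanismConfig)
        else Mechanism(mechanism)
    )
    network = build_network(params, mech)
    stage1 = AssayProtocol(
        p38_nM=p38_nM, atp_uM=atp_uM, atf2_nM=0.0, mk2_nM=0.0,
        readouts={"pMK2": stage1_duration},
    )
    rows = []
    for mk2 in mk2_levels:
        tc1 = simulate_protocol(
            stage1.with_(mk2_nM=float(mk2)), params, mech,
            network=network, solver=solver, horizon=stage1_duration,
        )
        end = tc1.terminal
        carried = {"p38": 0.0, "p38*": 0.0}
        for i, sp in enumerate(network.species):
            n_enz = sp.composition.get("p38", 0)
            if n_enz:
                target = "p38*" if sp.name.startswith("p38*") else "p38"
                # clamp tiny negative solver excursions
                carried[target] += n_enz * max(float(end[i]), 0.0)
        stage2 = AssayProtocol(
            p38_nM=0.0, atp_uM=atp_uM, atf2_nM=atf2_nM, mk2_nM=0.0,
            readouts={"pATF2": stage2_duration},
        )
        ini = stage2.initials()
        ini["p38"] = carried["p38"]
        if "p38*" in network:
            ini["p38*"] = carried["p38*"]
        tc2 = simulate_timecourse(
            network, stage2_duration, ini,
            t_eval=[0.0, stage2_duration], solver=solver,
        )
        rows.append(
            {
                "mk2_stage1_nM": float(mk2),
                "p38_carried_nM": carried["p38"],
                "p38star_carried_nM": carried["p38*"],
                "pATF2_nM": tc2.value("pATF2", stage2_duration),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# tabular export
# --------------------------------------------------------------------------


def dose_responses_to_frame(
    responses: Mapping[str, DoseResponse] | Sequence[DoseResponse],
    assay_id: str = "",
) -> pd.DataFrame:
    """Flatten dose-responses into the standard CSV schema.

    Columns: assay_id, mechanism, inhibitor_class, species, dose_nM,
    replicate, raw_nM, normalized.  Row order is deterministic (species,
    then dose, then replicate).
    """
    if isinstance(responses, Mapping):
        responses = [responses[k] for k in sorted(responses)]
    rows = []
    for dr in responses:
        mech = dr.meta.get("mechanism", "")
        icls = dr.meta.get("inhibitor_class", "")
        if dr.replicates is None:
            for d, r, nz in zip(dr.doses, dr.raw, dr.normalized):
                rows.append((assay_id, mech, icls, dr.species, d, 0, r, nz))
        else:
            for i, d in enumerate(dr.doses):
                for j in range(dr.replicates.shape[1]):
                    rows.append(
                        (assay_id, mech, icls, dr.species, d, j,
                         dr.raw[i], dr.replicates[i, j])
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "assay_id", "mechanism", "inhibitor_class", "species",
            "dose_nM", "replicate", "raw_nM", "normalized",
        ],
    )
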