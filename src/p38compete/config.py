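"""Run configuration: YAML-backed, validated, hashable.

A fully-defaulted :class:`RunConfig` reproduces the reference assay setup
(reference constants, 0.5 nM p38 / 50 uM ATP / 100 nM ATF2 / 10 nM MK2,
readouts at 30 and 120 min).  Unknown keys are rejected.  Concentration
fields carry explicit unit suffixes; outputs are always in nM.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .assays import AssayProtocol
from .network import InhibitorSpec, Mechanism
from .params import KineticParameters

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsConfig(_Strict):
    kd_atp_uM: float = 67.0
    kd_atf2_uM: float = 38.0
    kd_mk2_nM: float = 20.0
    kcat_atf2: float = 1.2
    kcat_mk2: float = 2.4
    kon_protein: float = 1e6
    kon_small: float = 1e7
    altered_factor: float = 10.0

    def build(self) -> KineticParameters:
        return KineticParameters(**self.model_dump())


class InhibitorConfig(_Strict):
    ki_nM: float = 1.0
    selectivity_f: float = 0.0
    inhibitor_class: str = "classical"
    atp_mode: str = "noncompetitive"

    def build(self) -> InhibitorSpec:
        return InhibitorSpec(
            ki=self.ki_nM,
            selectivity_f=self.selectivity_f,
            inhibitor_class=self.inhibitor_class,
            atp_mode=self.atp_mode,
        )


class ProtocolConfig(_Strict):
    p38_nM: float = 0.5
    atp_uM: float = 50.0
    atf2_nM: float = 100.0
    mk2_nM: float = 10.0
    pmk2_readout_s: float = 1800.0
    patf2_readout_s: float = 7200.0

    def build(self) -> AssayProtocol:
        readouts = {}
        if self.mk2_nM > 0:
            readouts["pMK2"] = self.pmk2_readout_s
        if self.atf2_nM > 0:
            readouts["pATF2"] = self.patf2_readout_s
        return AssayProtocol(
            p38_nM=self.p38_nM, atp_uM=self.atp_uM,
            atf2_nM=self.atf2_nM, mk2_nM=self.mk2_nM,
            readouts=readouts or dict.fromkeys(["pATF2"], self.patf2_readout_s),
        )


class DoseGridConfig(_Strict):
    n_points: int = 12
    lo_factor: float = 1e-2
    hi_factor: float = 1e4


class SolverConfig(_Strict):
    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-6


class RunConfig(_Strict):
    """Top-level configuration for CLI runs."""

    params: ParamsConfig = Field(default_factory=ParamsConfig)
    mechanism: Mechanism = Mechanism.BASE
    inhibitor: Optional[InhibitorConfig] = None
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    doses: DoseGridConfig = Field(default_factory=DoseGridConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    outdir: str = "p38compete_out"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML config file (defaults when ``path`` is None).

    Unknown keys raise a validation error.
    """
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
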