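"""Synthetic assay data with plate-readout statistics.

Electrochemiluminescence plate readouts have multiplicative error:
IC50 tables for such assays quote fold ("x 1.2") uncertainties.  The noise
model therefore replaces each clean observation y by replicate draws
``y * exp(eps)`` with ``eps ~ Normal(0, ln(geometric_sd))``; zero signals
stay exactly zero.  Replicate counts default to the figure-legend
conventions: n = 2 for compound dose-responses, n = 4 for time courses.

:func:`generate_benchmark_suite` writes a deterministic bundle of CSV
fixtures covering every figure-class experiment so every downstream stage
is testable without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .assays import (
    AssayProtocol,
    DoseResponse,
    dose_responses_to_frame,
    default_dose_grid,
    ip_two_stage,
    mk2_titration,
    run_assay,
    simulate_protocol,
    virtual_compound_assay,
)
from .multisite import MultisiteConfig, run_multisite_assay
from .network import InhibitorSpec
from .params import KineticParameters
from .simulate import TimeCourse

__all__ = ["NoiseModel", "attach_noise", "generate_benchmark_suite"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise.

    ``geometric_sd`` is the fold-error (>= 1); 1 means noise-free
    replication.  Identical seeds give byte-identical datasets.
    """

    geometric_sd: float = 1.2
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometric_sd < 1.0:
            raise ValueError("geometric_sd must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def attach_noise(
    clean: Union[DoseResponse, TimeCourse, np.ndarray, Sequence[float]],
    noise: NoiseModel,
) -> Union[DoseResponse, np.ndarray]:
    """Replicate ``clean`` observations under the noise model.

    For a :class:`DoseResponse` a copy is returned with ``replicates``
    filled (shape n_doses x n_replicates, on the normalised scale).  For a
    :class:`TimeCourse` or plain array the replicate array is returned
    directly with a new leading replicate axis.
    """
    rng = np.random.default_rng(noise.seed)
    sigma = float(np.log(noise.geometric_sd))

    def draw(values: np.ndarray) -> np.ndarray:
        eps = rng.normal(0.0, sigma, size=(noise.n_replicates, *values.shape))
        return values[None, ...] * np.exp(eps)

    if isinstance(clean, DoseResponse):
        reps = draw(np.asarray(clean.normalized)).T  # (n_doses, n_reps)
        out = DoseResponse(
            species=clean.species,
            doses=clean.doses.copy(),
            raw=clean.raw.copy(),
            normalized=clean.normalized.copy(),
            readout_time=clean.readout_time,
            meta=dict(clean.meta, noise_gsd=noise.geometric_sd, noise_seed=noise.seed),
        )
        out.replicates = reps
        return out
    if isinstance(clean, TimeCourse):
        return draw(clean.y)
    return draw(np.asarray(clean, dtype=float))


# --------------------------------------------------------------------------
# fixture bundle
# --------------------------------------------------------------------------

#: archetypal compounds exercised by the benchmark bundle
ARCHETYPES = {
    "classical_potent": InhibitorSpec(ki=1.0, inhibitor_class="classical"),
    "classical_weak": InhibitorSpec(ki=1e3, inhibitor_class="classical"),
    "substrate_selective": InhibitorSpec(
        ki=1.0, selectivity_f=0.99, inhibitor_class="substrate_selective"
    ),
}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Scale knobs for the fixture bundle (defaults keep it light)."""

    n_doses: int = 9
    mechanisms: tuple[str, ...] = ("base", "altered_atf2_affinity")
    mk2_levels: tuple[float, ...] = (0.0, 2.0, 10.0, 50.0)
    multisite_grid: tuple[tuple[int, int], ...] = ((1, 1), (2, 3))
    noise: NoiseModel = NoiseModel(geometric_sd=1.2, n_replicates=2, seed=0)


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_benchmark_suite(
    outdir: Union[str, Path],
    config: BenchmarkConfig | None = None,
    seed: int = 0,
    params: KineticParameters | None = None,
) -> dict:
    """Write the CSV fixture bundle and its JSON manifest.

    Each figure-class experiment is emitted noise-free and (where a
    dose-response) with attached replicate noise.  The manifest records
    seeds and sha256 checksums; the noise-free files depend only on the
    solver settings, so two different seeds differ only in the noisy files.
    """
    config = config or BenchmarkConfig()
    params = params or KineticParameters()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = replace(config.noise, seed=seed)
    manifest: dict = {"seed": seed, "noise": vars(noise) | {}, "files": {}}

    def emit(name: str, df: pd.DataFrame) -> None:
        manifest["files"][name] = _write_csv(df, outdir / name)

    # 1. base time course (Figure-3B-style, n = 4 noisy replicates)
    tc = simulate_protocol(
        AssayProtocol(), params, t_eval=np.linspace(0, 7200, 25)
    )
    emit("timecourse_base.csv", tc.to_frame())
    reps = attach_noise(tc, replace(noise, n_replicates=4))
    noisy = []
    for j in range(4):
        d = tc.to_frame().melt("time_s", var_name="species", value_name="raw_nM")
        d["raw_nM"] = reps[j].T.reshape(-1, order="F")
        d["replicate"] = j
        noisy.append(d)
    emit("timecourse_base_noisy.csv", pd.concat(noisy, ignore_index=True))

    # 2. inhibitor dose-responses, single and dual
    doses = default_dose_grid(1.0, config.n_doses)
    frames_clean, frames_noisy = [], []
    for mech in config.mechanisms:
        for cname, spec in ARCHETYPES.items():
            d = default_dose_grid(spec.ki, config.n_doses)
            for pname, proto in (
                ("dual", AssayProtocol.dual()),
                ("single_atf2", AssayProtocol.single_atf2()),
                ("single_mk2", AssayProtocol.single_mk2()),
            ):
                drs = run_assay(proto, params, mech, spec, d)
                aid = f"{mech}/{cname}/{pname}"
                frames_clean.append(dose_responses_to_frame(drs, aid))
                noisy_drs = {k: attach_noise(v, noise) for k, v in drs.items()}
                frames_noisy.append(dose_responses_to_frame(noisy_drs, aid))
    emit("dose_responses.csv", pd.concat(frames_clean, ignore_index=True))
    emit("dose_responses_noisy.csv", pd.concat(frames_noisy, ignore_index=True))

    # 3. virtual compound (dual assay)
    for mech in config.mechanisms:
        drs = virtual_compound_assay(AssayProtocol(), params, mech, doses, ki=1.0)
        emit(
            f"virtual_compound_{mech}.csv",
            dose_responses_to_frame(drs, f"{mech}/virtual"),
        )

    # 4. MK2 titration
    for mech in config.mechanisms:
        emit(
            f"mk2_titration_{mech}.csv",
            mk2_titration(AssayProtocol(), params, mech, config.mk2_levels),
        )

    # 5. immunoprecipitation two-stage experiment
    for mech in config.mechanisms:
        emit(
            f"ip_two_stage_{mech}.csv",
            ip_two_stage(params, mech, mk2_levels=config.mk2_levels),
        )

    # 6. multisite sweep
    frames = []
    for (na, nm) in config.multisite_grid:
        drs = run_multisite_assay(
            MultisiteConfig(na, nm), params, ARCHETYPES["substrate_selective"],
            doses=default_dose_grid(1.0, config.n_doses),
        )
        df = dose_responses_to_frame(drs, f"multisite/{na}x{nm}")
        df["n_atf2_sites"] = na
        df["n_mk2_sites"] = nm
        frames.append(df)
    emit("multisite_dose_responses.csv", pd.concat(frames, ignore_index=True))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
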