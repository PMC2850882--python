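"""Kinetic parameters and unit conventions.

Internal units throughout the package are **nanomolar** for concentrations,
**seconds** for time, and therefore nM^-1 s^-1 for bimolecular rate
constants.  This keeps state variables of order 0.1-1e5 at the 0.5 nM
enzyme scale of the assays and avoids underflow.  User-facing fields keep
the conventional literature units (uM for the weak affinities, M^-1 s^-1
for association rates) and are converted once at the boundary.

The default constants describe active p38 MAPK acting on its substrates
MK2 (tight binder, K_D = 20 nM) and ATF2 (weak binder, K_D = 38 uM) in a
random-order bi-substrate mechanism with ATP (K_D = 67 uM).  All forward
(association) rates are taken as diffusion limited: 1e6 M^-1 s^-1 for
protein-protein steps and 1e7 M^-1 s^-1 for the small species (ATP and
inhibitor compounds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "KineticParameters",
    "derive_rate_constants",
    "LITERATURE_KCAT_MK2",
    "InvalidParameterError",
]

#: Literature value for the p38->MK2 catalytic rate (s^-1).  The default in
#: :class:`KineticParameters` is the in-house measurement (2.4 s^-1); this
#: alternative is kept for sensitivity analyses.
LITERATURE_KCAT_MK2 = 0.17


class InvalidParameterError(ValueError):
    """A kinetic parameter is outside its physical domain."""


@dataclass(frozen=True)
class KineticParameters:
    """Rate and affinity constants for the p38/MK2/ATF2 network.

    Parameters
    ----------
    kd_atp_uM : ATP-p38 dissociation constant (uM).
    kd_atf2_uM : ATF2-p38 dissociation constant (uM).
    kd_mk2_nM : MK2-p38 dissociation constant (nM).
    kcat_atf2 : catalytic rate for ATF2 phosphorylation (s^-1).
    kcat_mk2 : catalytic rate for MK2 phosphorylation (s^-1).
    kon_protein : association rate for protein-protein steps (M^-1 s^-1).
    kon_small : association rate for ATP/compound steps (M^-1 s^-1).
    altered_factor : fold-change applied by the altered-p38 mechanisms
        (#3-5).  For #3/#4 the corresponding K_D is *multiplied* by this
        factor (affinity weakened); for #5 kcat_atf2 is *divided* by it.
        Values < 1 invert the direction.
    """

    kd_atp_uM: float = 67.0
    kd_atf2_uM: float = 38.0
    kd_mk2_nM: float = 20.0
    kcat_atf2: float = 1.2
    kcat_mk2: float = 2.4
    kon_protein: float = 1e6
    kon_small: float = 1e7
    altered_factor: float = 10.0

    def __post_init__(self) -> None:
        for field in (
            "kd_atp_uM",
            "kd_atf2_uM",
            "kd_mk2_nM",
            "kcat_atf2",
            "kcat_mk2",
            "kon_protein",
            "kon_small",
            "altered_factor",
        ):
            value = getattr(self, field)
            if not (value > 0):
                raise InvalidParameterError(
                    f"{field} must be strictly positive, got {value!r}"
                )

    # ---- internal-unit views -------------------------------------------
    @property
    def kd_atp_nM(self) -> float:
        return self.kd_atp_uM * 1e3

    @property
    def kd_atf2_nM(self) -> float:
        return self.kd_atf2_uM * 1e3

    @property
    def kon_protein_nM(self) -> float:
        """Protein-protein association rate in nM^-1 s^-1."""
        return self.kon_protein * 1e-9

    @property
    def kon_small_nM(self) -> float:
        """ATP/compound association rate in nM^-1 s^-1."""
        return self.kon_small * 1e-9

    def with_(self, **changes) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def derive_rate_constants(kd_nM: float, kon_M: float) -> tuple[float, float]:
    """Split a dissociation constant into (kon, koff) under the
    diffusion-limited forward-rate convention.

    Parameters
    ----------
    kd_nM : dissociation constant in nM.
    kon_M : association rate in M^-1 s^-1.

    Returns
    -------
    (kon_nM, koff) : association rate in nM^-1 s^-1 and dissociation rate
        in s^-1, such that ``koff / kon_nM == kd_nM`` exactly.

    Examples
    --------
    >>> derive_rate_constants(20.0, 1e6)[1]      # MK2-p38, K_D = 20 nM
    0.02
    >>> derive_rate_constants(67e3, 1e7)[1]      # ATP-p38, K_D = 67 uM
    670.0
    """
    if not (kd_nM > 0):
        raise InvalidParameterError(f"kd must be > 0, got {kd_nM!r}")
    if not (kon_M > 0):
        raise InvalidParameterError(f"kon must be > 0, got {kon_M!r}")
    kon_nM = kon_M * 1e-9
    koff = kd_nM * kon_nM
    return kon_nM, koff
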