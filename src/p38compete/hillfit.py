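"""Four-parameter logistic (Hill) fitting and derived potency metrics.

IC50s are estimated by least squares on log10(dose) with the model

    y(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill)

which is the standard sigmoidal dose-response parameterisation.  The zero
dose cannot sit on a log axis; it is excluded from the fit and used only
for normalisation upstream.  Uncertainties on IC50 are reported as
geometric (fold) standard errors derived from the covariance of
log10(IC50), matching the "x-fold" error convention of plate-assay IC50
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "HillFit",
    "FitNotConverged",
    "fit_hill",
    "selectivity_ratio",
    "round_selectivity",
    "shift_factor",
    "molecules_to_uM",
    "SelectivityReport",
]

AVOGADRO = 6.02214076e23

#: minimum normalised-response span below which a 4PL fit is meaningless
MIN_SPAN = 0.2


class FitNotConverged(RuntimeError):
    """Raised when a caller demands a converged fit that does not exist."""


@dataclass
class HillFit:
    """Result of a 4-parameter logistic fit.

    ``converged`` is the typed sentinel: when False every numeric field is
    None and ``reason`` explains the failure — no fabricated numbers.
    ``censored`` flags an IC50 beyond the largest tested dose, reported as
    "> max dose".
    """

    converged: bool
    ic50: Optional[float] = None          # nM
    top: Optional[float] = None
    bottom: Optional[float] = None
    hill_slope: Optional[float] = None
    gsd_fold: Optional[float] = None      # geometric SE of IC50, as a fold
    censored: bool = False
    max_dose: Optional[float] = None
    residual_rms: Optional[float] = None
    reason: str = ""
    meta: dict = field(default_factory=dict)

    def ic50_or_raise(self) -> float:
        if not self.converged or self.ic50 is None:
            raise FitNotConverged(self.reason or "fit did not converge")
        return self.ic50

    def report_ic50(self) -> str:
        if not self.converged:
            return f"n.c. ({self.reason})"
        if self.censored:
            return f">{self.max_dose:g}"
        return f"{self.ic50:g}"


def _model(logd, top, bottom, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logic50)))


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    constrain_bottom: bool = False,
) -> HillFit:
    """Fit a 4PL curve to normalised responses.

    Parameters
    ----------
    doses : concentrations (nM); a leading zero dose is dropped from the
        fit.  At least 5 distinct positive doses are required.
    responses : normalised signals, one per dose (replicate-averaged) or a
        flat array aligned with ``doses``.
    weights : optional least-squares weights per point.
    constrain_bottom : pin bottom = 0 instead of fitting it (>= 0 bound).

    Returns a :class:`HillFit`; flat or non-monotone data yield the
    non-convergence sentinel rather than an arbitrary number.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must align")
    keep = d > 0
    d, y = d[keep], y[keep]
    w = None if weights is None else np.asarray(weights, dtype=float)[keep]
    if np.unique(d).size < 5:
        return HillFit(False, reason="fewer than 5 distinct positive doses")
    span = float(y.max() - y.min())
    if span < MIN_SPAN:
        return HillFit(False, reason=f"response span {span:.3g} < {MIN_SPAN}; no inhibition")

    logd = np.log10(d)
    p = lmfit.Parameters()
    p.add("top", value=float(np.median(y[logd <= np.quantile(logd, 0.25)])), min=0.0)
    if constrain_bottom:
        p.add("bottom", value=0.0, vary=False)
    else:
        p.add("bottom", value=max(float(y.min()), 0.0), min=0.0)
    half = 0.5 * (y.max() + y.min())
    p.add("logic50", value=float(logd[np.argmin(np.abs(y - half))]))
    p.add("hill", value=1.0, min=0.05, max=10.0)

    def resid(pars):
        r = y - _model(logd, pars["top"], pars["bottom"], pars["logic50"], pars["hill"])
        return r if w is None else r * w

    try:
        res = lmfit.minimize(resid, p, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit internal failures
        return HillFit(False, reason=f"optimizer failure: {exc}")
    if not res.success:
        return HillFit(False, reason=str(res.message))
    pars = res.params
    top, bottom = float(pars["top"]), float(pars["bottom"])
    if bottom > top:
        return HillFit(False, reason="fitted bottom above top (rising curve)")
    logic50 = float(pars["logic50"])
    ic50 = 10.0 ** logic50
    stderr = pars["logic50"].stderr
    if stderr is None or not np.isfinite(stderr):
        # a parameter pinned at its bound (typically bottom = 0) voids the
        # covariance estimate; refit with it frozen to recover the IC50 error
        p2 = res.params.copy()
        p2["bottom"].vary = False
        try:
            res2 = lmfit.minimize(resid, p2, method="leastsq")
            stderr = res2.params["logic50"].stderr
        except Exception:  # pragma: no cover
            stderr = None
    gsd = float(10.0 ** stderr) if stderr is not None and np.isfinite(stderr) else None
    max_dose = float(d.max())
    return HillFit(
        converged=True,
        ic50=ic50,
        top=top,
        bottom=bottom,
        hill_slope=float(pars["hill"]),
        gsd_fold=gsd,
        censored=ic50 > max_dose,
        max_dose=max_dose,
        residual_rms=float(np.sqrt(np.mean(np.asarray(res.residual) ** 2))),
        meta={"nfev": int(res.nfev)},
    )


# --------------------------------------------------------------------------
# derived metrics
# --------------------------------------------------------------------------


def selectivity_ratio(
    ic50_atf2: float,
    ic50_mk2: float,
    atf2_censored: bool = False,
    mk2_censored: bool = False,
) -> tuple[float, bool]:
    """Substrate selectivity IC50_ATF2 / IC50_MK2.

    Returns (value, lower_bound) where ``lower_bound`` is True when the
    ATF2 IC50 was censored ("> max dose"), so the selectivity is itself a
    lower bound (reported with a ">").
    """
    if not (ic50_atf2 > 0 and ic50_mk2 > 0):
        raise ValueError("IC50s must be strictly positive")
    return ic50_atf2 / ic50_mk2, bool(atf2_censored and not mk2_censored)


def round_selectivity(value: float) -> float:
    """Reporting rounding for selectivity ratios: 2 significant figures,
    capped at 2 decimal places (0.0333 -> 0.03, 0.119 -> 0.12, 17.09 -> 17)."""
    if value <= 0:
        raise ValueError("selectivity must be > 0")
    sig2 = float(f"{value:.2g}")
    return round(sig2, 2)


def shift_factor(ic50_single: float, ic50_dual: float) -> float:
    """Fold left-shift between assay formats: IC50_single / IC50_dual.

    > 1 means the dual-substrate assay is more potent (left-shifted).
    """
    if not (ic50_single > 0 and ic50_dual > 0):
        raise ValueError("IC50s must be strictly positive")
    return ic50_single / ic50_dual


def molecules_to_uM(n_molecules: float, cell_volume_pl: float) -> float:
    """Convert a per-cell copy number into a concentration (uM).

    c = n / (N_A * V); cell volumes are given in picolitres (e.g. 1.09 pl
    for U937, 0.97 pl for Thp-1, 0.38 pl for PBMC).
    """
    if n_molecules < 0:
        raise ValueError("molecule count must be >= 0")
    if not (cell_volume_pl > 0):
        raise ValueError("cell volume must be > 0")
    molar = n_molecules / (AVOGADRO * cell_volume_pl * 1e-12)
    return molar * 1e6


@dataclass
class SelectivityReport:
    """Selectivity and single->dual shift for one compound."""

    ic50_atf2: float
    ic50_mk2: float
    atf2_censored: bool = False
    mk2_censored: bool = False
    ic50_atf2_single: Optional[float] = None
    ic50_mk2_single: Optional[float] = None

    @property
    def selectivity(self) -> float:
        return selectivity_ratio(
            self.ic50_atf2, self.ic50_mk2, self.atf2_censored, self.mk2_censored
        )[0]

    @property
    def selectivity_is_lower_bound(self) -> bool:
        return selectivity_ratio(
            self.ic50_atf2, self.ic50_mk2, self.atf2_censored, self.mk2_censored
        )[1]

    @property
    def shift_atf2(self) -> Optional[float]:
        if self.ic50_atf2_single is None:
            return None
        return shift_factor(self.ic50_atf2_single, self.ic50_atf2)

    @property
    def shift_mk2(self) -> Optional[float]:
        if self.ic50_mk2_single is None:
            return None
        return shift_factor(self.ic50_mk2_single, self.ic50_mk2)

    def formatted_selectivity(self) -> str:
        v = round_selectivity(self.selectivity)
        return f">{v:g}" if self.selectivity_is_lower_bound else f"{v:g}"
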