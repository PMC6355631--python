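"""Patlak one-tissue-compartment modelling of irreversible tracer uptake.

For a tracer that does not back-diffuse from tissue to blood during the
measurement, the tissue and arterial concentration curves obey

    C_t(t) / C_a(t) = K_i * [ integral_0^t C_a(tau) dtau / C_a(t) ] + V_b,

a straight line in the transformed coordinates.  The slope K_i is the influx
constant — the volume of blood cleared of contrast per unit time per tissue
mass — and, in the no-backflux one-compartment model, the intercept V_b is
the cerebral blood volume (CBV).  Only the late, linear part of the plot is
fitted (by default the last two-thirds of the frames), allowing the arterial
concentration to reach a quasi-steady state.

Reported units assume a brain tissue density rho (default 1 g ml^-1):
K_i in ml (100 g)^-1 min^-1 and CBV in ml (100 g)^-1, i.e. 100x the raw
slope (ml ml^-1 min^-1) and intercept (ml ml^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .aif import Aif

__all__ = ["PatlakPoints", "PatlakResult", "PatlakModel", "patlak_points", "fit_patlak"]

#: Arterial points below this fraction of the AIF peak are excluded
#: (division-by-near-zero protection).
DEFAULT_C_MIN = 0.05
#: Fraction of (trailing) frames entering the line fit.
DEFAULT_FIT_FRACTION = 2.0 / 3.0


@dataclass
class PatlakPoints:
    """Patlak-transformed points.

    ``x_min`` is the integrated arterial concentration normalized to the
    instantaneous arterial concentration (units: minutes); ``y`` is the
    instantaneous tissue/arterial concentration ratio (dimensionless).
    """

    x_min: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return self.x_min.shape[0]


@dataclass
class PatlakResult:
    """Patlak line-fit estimates in reporting units.

    ki : influx constant, ml (100 g)^-1 min^-1
    cbv : blood volume (intercept), ml (100 g)^-1
    r2 : coefficient of determination of the line fit
    n_fit : number of points entering the fit
    slope_raw / intercept_raw : ml ml^-1 min^-1 and ml ml^-1
    ki_se / cbv_se : standard errors in reporting units
    """

    ki: float
    cbv: float
    r2: float
    n_fit: int
    slope_raw: float
    intercept_raw: float
    ki_se: float = np.nan
    cbv_se: float = np.nan
    name: str = ""

    def summary(self) -> str:
        lines = [
            f"Patlak one-compartment fit{f' [{self.name}]' if self.name else ''}",
            "-" * 46,
            f"K_i   {self.ki:12.5f}  (SE {self.ki_se:.5f})  ml/100g/min",
            f"CBV   {self.cbv:12.5f}  (SE {self.cbv_se:.5f})  ml/100g",
            f"r^2   {self.r2:12.5f}",
            f"n_fit {self.n_fit:8d}",
        ]
        return "\n".join(lines)


class FitError(RuntimeError):
    """Raised when too few usable Patlak points remain for a line fit."""


def patlak_points(
    ct: np.ndarray,
    aif: Aif,
    time_min: np.ndarray | None = None,
    c_min: float = DEFAULT_C_MIN,
) -> PatlakPoints:
    """Transform a tissue curve and AIF into Patlak coordinates.

    The running integral of C_a is computed with the trapezoidal rule from
    the first frame (pre-injection frames contribute ~0).  Points where
    ``C_a(t) < c_min * max(C_a)``, or where either concentration is not
    finite, are flagged invalid.

    Parameters
    ----------
    ct : (n_frames,) tissue concentration (mM).
    aif : arterial input function on the same time axis.
    time_min : optional explicit tissue time axis; must match the AIF's.
    """
    ct = np.asarray(ct, dtype=float)
    ca = aif.conc_mM
    if ct.shape != ca.shape:
        raise ValueError("tissue curve and AIF must have the same length")
    if time_min is not None and not np.allclose(np.asarray(time_min), aif.time_min):
        raise ValueError("tissue curve and AIF time axes differ")
    t = aif.time_min

    finite = np.isfinite(ct) & np.isfinite(ca)
    ca_peak = np.nanmax(ca) if np.any(finite) else 0.0
    valid = finite & (ca >= c_min * ca_peak) & (ca > 0)

    cum = integrate.cumulative_trapezoid(np.where(np.isfinite(ca), ca, 0.0), t, initial=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, cum / ca, np.nan)
        y = np.where(valid, ct / ca, np.nan)
    return PatlakPoints(x_min=x, y=y, valid=valid)


class PatlakModel:
    """Patlak plot model for one tissue curve against an AIF.

    Parameters
    ----------
    ct : (n_frames,) tissue concentration curve (mM), typically a
        region-mean curve (voxelwise fitting is noise-sensitive).
    aif : arterial input function on the same time axis.
    fit_fraction : trailing fraction of frames entering the line fit
        (default 2/3).  The restriction indexes *frames* — it is applied
        before validity filtering, since its purpose (steady-state arterial
        concentration) is a statement about time.
    c_min : AIF validity threshold relative to its peak.
    density : tissue density rho in g ml^-1 used for unit conversion.
    """

    def __init__(
        self,
        ct: np.ndarray,
        aif: Aif,
        fit_fraction: float = DEFAULT_FIT_FRACTION,
        c_min: float = DEFAULT_C_MIN,
        density: float = 1.0,
        name: str = "",
    ):
        if not 0 < fit_fraction <= 1:
            raise ValueError("fit_fraction must lie in (0, 1]")
        self.ct = np.asarray(ct, dtype=float)
        self.aif = aif
        self.fit_fraction = fit_fraction
        self.c_min = c_min
        self.density = density
        self.name = name
        self.points = patlak_points(self.ct, aif, c_min=c_min)

    def fit(self) -> PatlakResult:
        n = len(self.points)
        start = n - int(round(self.fit_fraction * n))
        sel = np.zeros(n, dtype=bool)
        sel[start:] = True
        sel &= self.points.valid
        x = self.points.x_min[sel]
        y = self.points.y[sel]
        if x.size < 3:
            raise FitError(
                f"Patlak fit{f' [{self.name}]' if self.name else ''}: "
                f"only {x.size} usable points (need >= 3)"
            )
        # OLS line fit.
        xm, ym = x.mean(), y.mean()
        sxx = float(((x - xm) ** 2).sum())
        sxy = float(((x - xm) * (y - ym)).sum())
        slope = sxy / sxx
        intercept = ym - slope * xm
        resid = y - (slope * x + intercept)
        ss_res = float((resid**2).sum())
        ss_tot = float(((y - ym) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = x.size - 2
        sigma2 = ss_res / dof if dof > 0 else np.nan
        slope_se = np.sqrt(sigma2 / sxx)
        intercept_se = np.sqrt(sigma2 * (1.0 / x.size + xm**2 / sxx))
        scale = 100.0 / self.density
        return PatlakResult(
            ki=scale * slope,
            cbv=scale * intercept,
            r2=r2,
            n_fit=int(x.size),
            slope_raw=slope,
            intercept_raw=intercept,
            ki_se=scale * slope_se,
            cbv_se=scale * intercept_se,
            name=self.name,
        )


def fit_patlak(
    points_or_ct: PatlakPoints | np.ndarray,
    aif: Aif | None = None,
    fit_fraction: float = DEFAULT_FIT_FRACTION,
    c_min: float = DEFAULT_C_MIN,
    density: float = 1.0,
    name: str = "",
) -> PatlakResult:
    """Fit the Patlak line and report K_i and CBV.

    Accepts either pre-computed :class:`PatlakPoints` or a raw tissue curve
    plus its AIF.
    """
    if isinstance(points_or_ct, PatlakPoints):
        pts = points_or_ct
        model = PatlakModel.__new__(PatlakModel)
        model.points = pts
        model.fit_fraction = fit_fraction
        model.density = density
        model.name = name
        return PatlakModel.fit(model)
    if aif is None:
        raise ValueError("an AIF is required when passing a raw tissue curve")
    return PatlakModel(
        points_or_ct, aif, fit_fraction=fit_fraction, c_min=c_min, density=density, name=name
    ).fit()
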