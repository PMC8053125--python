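"""Equilibrium binding analysis: modified-Hill fits and Mg2+ profiles.

Binding is read out as quenching of the ligand's fluorescence while the RNA
is titrated at a fixed probe concentration.  The quench fraction
``(F0 - F)/F0`` rises with binding and is fitted with the modified Hill
isotherm

    response(x) = B_max * x^h / (K_D^h + x^h)

whose half-saturation point is the apparent dissociation constant K_D and
whose slope parameter h is used descriptively (for Mg2+-dependence profiles
it reports the apparent cooperativity of folding into the binding-competent
state).  Probe depletion is ignored, exactly as the isotherm does; an exact
1:1 depletion-corrected alternative is available behind a flag for
sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class TitrationCurve:
    """One titration: titrant concentration versus dimensionless response."""

    titrant_conc: np.ndarray
    response: np.ndarray
    probe_conc_nM: float = 50.0
    titrant_label: str = "RNA"
    titrant_unit: str = "nM"
    response_kind: str = "quench_fraction"  # or "emission_ratio" (raw F/F0)

    def __post_init__(self) -> None:
        self.titrant_conc = np.asarray(self.titrant_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.titrant_conc.shape != self.response.shape:
            raise InputError("concentration and response arrays must match")
        if np.any(self.titrant_conc < 0):
            raise InputError("titrant concentrations must be non-negative")
        if np.any(np.diff(self.titrant_conc) <= 0):
            raise InputError("titrant concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise InputError("responses must be finite")

    def as_quench_fraction(self) -> "TitrationCurve":
        """Convert a raw emission-ratio curve (F/F0, decreasing) to quench fraction."""
        if self.response_kind == "quench_fraction":
            return self
        return TitrationCurve(
            titrant_conc=self.titrant_conc,
            response=1.0 - self.response,
            probe_conc_nM=self.probe_conc_nM,
            titrant_label=self.titrant_label,
            titrant_unit=self.titrant_unit,
            response_kind="quench_fraction",
        )


@dataclass
class HillFit:
    """Modified-Hill fit: K_D, Hill slope h, and maximum binding B_max."""

    kd: float
    h: float
    bmax: float
    kd_se: float = float("nan")
    h_se: float = float("nan")
    bmax_se: float = float("nan")
    rss: float = float("nan")
    success: bool = True
    flags: list[str] = field(default_factory=list)
    titrant_unit: str = "nM"


def hill_model(
    x: np.ndarray | float, kd: float, h: float, bmax: float
) -> np.ndarray | float:
    """Modified Hill isotherm ``B_max x^h / (K_D^h + x^h)``."""
    if kd <= 0:
        raise ConfigurationError(f"K_D must be positive, got {kd}")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InputError("titrant concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        xh = np.where(x_arr > 0, x_arr**h, 0.0)
    out = bmax * xh / (kd**h + xh)
    return float(out) if np.isscalar(x) else out


def binding_quadratic(
    x: np.ndarray, kd: float, bmax: float, probe: float
) -> np.ndarray:
    """Exact 1:1 bound fraction with probe depletion (no Hill slope).

    ``bound/probe`` from the quadratic root of
    ``(x - b)(probe - b) = K_D b``; used as a sensitivity alternative when
    the probe concentration is not negligible against K_D.
    """
    x = np.asarray(x, dtype=float)
    s = x + probe + kd
    bound = 0.5 * (s - np.sqrt(s**2 - 4.0 * x * probe))
    return bmax * bound / probe


def fit_hill(
    curve: TitrationCurve,
    fix_h: float | None = None,
    use_depletion: bool = False,
) -> HillFit:
    """Least-squares modified-Hill fit of a titration curve.

    Initial guesses: ``B_max`` = max response, ``K_D`` = concentration at
    half-max response, ``h`` = 1.  ``fix_h`` pins the Hill slope;
    ``use_depletion`` switches to the exact 1:1 quadratic model (h absent).
    """
    curve = curve.as_quench_fraction()
    x, y = curve.titrant_conc, curve.response
    flags: list[str] = []
    if x.size < 5:
        flags.append("fewer than 5 titration points")
        logger.warning("fit_hill: only %d points; expect wide standard errors", x.size)

    ymax = float(y.max())
    if ymax <= 0 or not np.any(y > 3 * max(np.std(y[: max(2, x.size // 4)]), 1e-3)):
        return HillFit(
            kd=float("nan"), h=float("nan"), bmax=float("nan"),
            success=False, flags=flags + ["no binding detected (flat response)"],
            titrant_unit=curve.titrant_unit,
        )

    half = 0.5 * ymax
    above = np.nonzero(y >= half)[0]
    kd0 = float(x[above[0]]) if above.size else float(np.median(x[x > 0]))
    if kd0 <= 0:
        kd0 = float(np.min(x[x > 0]))
    if not (y.min() < half < ymax):
        flags.append("half-saturation not bracketed by the data")

    rising = np.all(np.diff(_smooth(y)) > -3 * _noise_scale(y))
    if not rising:
        flags.append("response not monotone beyond noise")

    try:
        if use_depletion:
            probe = curve.probe_conc_nM
            popt, pcov = curve_fit(
                lambda x, kd, bmax: binding_quadratic(x, kd, bmax, probe),
                x, y, p0=(kd0, ymax), bounds=([1e-12, 0], [np.inf, np.inf]),
                maxfev=20000,
            )
            kd, bmax = popt
            h, h_se = 1.0, float("nan")
            kd_se, bmax_se = np.sqrt(np.diag(pcov))
        elif fix_h is not None:
            popt, pcov = curve_fit(
                lambda x, kd, bmax: hill_model(x, kd, fix_h, bmax),
                x, y, p0=(kd0, ymax), bounds=([1e-12, 0], [np.inf, np.inf]),
                maxfev=20000,
            )
            kd, bmax = popt
            h, h_se = float(fix_h), 0.0
            kd_se, bmax_se = np.sqrt(np.diag(pcov))
        else:
            popt, pcov = curve_fit(
                hill_model, x, y, p0=(kd0, 1.0, ymax),
                bounds=([1e-12, 0.05, 0], [np.inf, 50.0, np.inf]), maxfev=20000,
            )
            kd, h, bmax = popt
            kd_se, h_se, bmax_se = np.sqrt(np.diag(pcov))
    except (RuntimeError, ValueError) as exc:
        return HillFit(
            kd=float("nan"), h=float("nan"), bmax=float("nan"),
            success=False, flags=flags + [f"fit failed: {exc}"],
            titrant_unit=curve.titrant_unit,
        )

    if use_depletion:
        resid = y - binding_quadratic(x, kd, bmax, curve.probe_conc_nM)
    else:
        resid = y - hill_model(x, kd, h, bmax)
    if "half-saturation not bracketed by the data" in flags:
        flags.append("wide-SE")
    return HillFit(
        kd=float(kd), h=float(h), bmax=float(bmax),
        kd_se=float(kd_se), h_se=float(h_se), bmax_se=float(bmax_se),
        rss=float(resid @ resid), flags=flags, titrant_unit=curve.titrant_unit,
    )


def _smooth(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return y
    return np.convolve(y, np.ones(3) / 3.0, mode="valid")


def _noise_scale(y: np.ndarray) -> float:
    if y.size < 3:
        return 0.0
    return float(np.std(np.diff(y)) / np.sqrt(2.0)) + 1e-12


def kd_vs_mg_profile(
    entries: Sequence[tuple[float, HillFit]],
) -> pd.DataFrame:
    """Apparent K_D versus Mg2+ concentration from per-level Hill fits.

    Non-binding levels (failed fits) are kept as rows with ``binding=False``
    and NaN K_D.  The fold change between the largest and smallest K_D among
    binding levels is stored in ``df.attrs['kd_fold_change']``.
    """
    if len(entries) < 1:
        raise InputError("profile requires at least one Mg2+ level")
    rows = []
    for mg, fit in entries:
        rows.append(
            {
                "mg_mM": float(mg),
                "kd": fit.kd,
                "kd_se": fit.kd_se,
                "h": fit.h,
                "binding": bool(fit.success),
            }
        )
    df = pd.DataFrame(rows).sort_values("mg_mM").reset_index(drop=True)
    binding_kd = df.loc[df["binding"], "kd"].to_numpy()
    if binding_kd.size >= 2 and np.nanmin(binding_kd) > 0:
        df.attrs["kd_fold_change"] = float(np.nanmax(binding_kd) / np.nanmin(binding_kd))
    else:
        df.attrs["kd_fold_change"] = float("nan")
    return df
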