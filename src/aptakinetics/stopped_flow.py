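"""Stopped-flow fluorescence analysis: preprocessing, k_obs/k_on, global fits.

The measured quantity is the ligand's own fluorescence, quenched on binding.
Traces are recorded as emission versus time after rapid mixing of receptor
RNA with ligand at several ligand concentrations, averaged over repeated
shots, baseline-corrected and normalized so that every trace decays from 1
(all ligand free) toward 0 (binding equilibrium reached).

Three analysis levels are provided:

* mono-exponential fitting of single traces (observed rate ``k_obs``) and the
  linear regression of ``k_obs`` against ligand concentration whose slope is
  the apparent association rate ``k_on``;
* global nonlinear fitting of a full mass-action scheme to all traces of a
  concentration series simultaneously, with shared rate constants;
* AIC/BIC discrimination between candidate schemes fitted to the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from . import kinetics
from .errors import ConfigurationError, FitConvergenceError, InputError

logger = logging.getLogger(__name__)

#: Fraction of trailing points used as the baseline/plateau estimate.
BASELINE_FRACTION = 0.05

#: Plateau check: relative drift over the last decile above this flags the trace.
PLATEAU_DRIFT_LIMIT = 0.02


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class StoppedFlowTrace:
    """One preprocessed (averaged, baseline-corrected, normalized) trace."""

    time_s: np.ndarray
    signal: np.ndarray
    ligand_conc_uM: float
    receptor_conc_uM: float
    n_averaged: int = 1
    plateau_warning: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape:
            raise InputError("time and signal arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise InputError("trace time grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise InputError("trace signal contains non-finite values")
        if self.ligand_conc_uM <= 0:
            raise InputError("ligand concentration must be positive")


@dataclass
class TraceSeries:
    """Traces sharing one receptor concentration, one per ligand concentration."""

    traces: list[StoppedFlowTrace]
    label: str = ""

    def __post_init__(self) -> None:
        if len({t.receptor_conc_uM for t in self.traces}) > 1:
            raise InputError("all traces of a series must share the receptor concentration")

    @property
    def receptor_conc_uM(self) -> float:
        return self.traces[0].receptor_conc_uM

    @property
    def ligand_concs_uM(self) -> list[float]:
        return [t.ligand_conc_uM for t in self.traces]

    @property
    def n_points(self) -> int:
        return int(sum(t.signal.size for t in self.traces))


@dataclass
class ObservableMap:
    """Fluorescence response of ligand-containing species.

    Free ligand responds with 1 by definition; complexed ligand responds with
    a factor in [0, 1] (0 = fully quenched, the default for both complexes).
    """

    responses: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0

    def response(self, species: str) -> float:
        value = self.responses.get(species, 0.0)
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(
                f"response factor for {species!r} must lie in [0, 1], got {value}"
            )
        return value


@dataclass
class MonoExpFit:
    """offset + amplitude * exp(-k_obs t) least-squares fit of one trace."""

    k_obs: float
    amplitude: float
    offset: float
    rss: float
    k_obs_se: float = float("nan")
    success: bool = True
    message: str = ""


@dataclass
class PseudoFirstOrderResult:
    """k_obs values per ligand concentration and their linear regression."""

    ligand_concs_uM: np.ndarray
    k_obs: np.ndarray
    k_on: float          # slope, 1/(uM s)
    intercept: float     # apparent off-rate, 1/s
    k_on_se: float
    intercept_se: float
    excluded: list[int] = field(default_factory=list)  # saturating points


@dataclass
class GlobalFitResult:
    """Rate constants from a simultaneous fit of one scheme to a whole series."""

    scheme_id: str
    rates: dict[str, float]
    rate_se: dict[str, float]
    responses: dict[str, float]
    response_se: dict[str, float]
    rss: float
    rmsd: float
    n_points: int
    n_parameters: int
    n_starts: int
    seed: int
    success: bool
    at_bounds: list[str] = field(default_factory=list)
    message: str = ""
    label: str = ""
    trace_scales: list[float] = field(default_factory=list)

    def rates_paper_labels(self) -> dict[str, float]:
        return {
            kinetics.paper_symbol(self.scheme_id, sym): val
            for sym, val in self.rates.items()
        }


@dataclass
class ModelComparisonRow:
    scheme_id: str
    rmsd: float
    aic: float
    bic: float
    delta_aic: float
    delta_bic: float
    n_parameters: int
    label: str = ""


@dataclass
class ModelComparisonTable:
    rows: list[ModelComparisonRow]
    n_points: int
    indistinguishable: list[str] = field(default_factory=list)

    def best(self, criterion: str = "bic") -> ModelComparisonRow:
        key = {"aic": lambda r: r.aic, "bic": lambda r: r.bic}[criterion]
        return min(self.rows, key=key)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "scheme": r.scheme_id,
                    "RMSD": r.rmsd,
                    "AIC": r.aic,
                    "BIC": r.bic,
                    "dAIC": r.delta_aic,
                    "dBIC": r.delta_bic,
                    "p": r.n_parameters,
                }
                for r in self.rows
            ]
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_contract(signal: np.ndarray) -> np.ndarray:
    """Baseline-correct and normalize: plateau -> 0, first point -> 1.

    Baseline is the mean of the final 5% of points; the result is invariant
    under any affine map ``a*x + b`` (a > 0) of the input.
    """
    signal = np.asarray(signal, dtype=float)
    n_tail = max(1, int(round(BASELINE_FRACTION * signal.size)))
    baseline = float(np.mean(signal[-n_tail:]))
    shifted = signal - baseline
    scale = shifted[0]
    if abs(scale) < 1e-12:
        return shifted
    return shifted / scale


def preprocess(
    raw_signals: Sequence[np.ndarray],
    time_s: np.ndarray,
    ligand_conc_uM: float,
    receptor_conc_uM: float,
) -> StoppedFlowTrace:
    """Average repeated shots, subtract the baseline, normalize to [1 -> 0].

    The plateau is checked on the last decile: if the linear drift across it
    exceeds 2% of the normalized amplitude the trace is flagged (equilibrium
    possibly not reached within the recorded window).
    """
    if len(raw_signals) < 1:
        raise InputError("preprocess requires at least one raw trace")
    time_s = np.asarray(time_s, dtype=float)
    stack = np.vstack([np.asarray(s, dtype=float) for s in raw_signals])
    if stack.shape[1] != time_s.size:
        raise InputError("raw traces must share the common time grid")
    mean_signal = stack.mean(axis=0)
    normalized = normalize_contract(mean_signal)

    n_decile = max(2, int(round(0.1 * normalized.size)))
    t_tail, s_tail = time_s[-n_decile:], normalized[-n_decile:]
    slope = np.polyfit(t_tail, s_tail, 1)[0]
    drift = abs(slope * (t_tail[-1] - t_tail[0]))
    warning = bool(drift > PLATEAU_DRIFT_LIMIT)
    if warning:
        logger.warning(
            "preprocess: plateau drift %.3g over last decile exceeds %.3g "
            "(L=%g uM); equilibrium may not be reached",
            drift, PLATEAU_DRIFT_LIMIT, ligand_conc_uM,
        )
    return StoppedFlowTrace(
        time_s=time_s,
        signal=normalized,
        ligand_conc_uM=ligand_conc_uM,
        receptor_conc_uM=receptor_conc_uM,
        n_averaged=len(raw_signals),
        plateau_warning=warning,
    )


# ---------------------------------------------------------------------------
# Mono-exponential k_obs and k_on regression
# ---------------------------------------------------------------------------

def fit_monoexponential(trace: StoppedFlowTrace) -> MonoExpFit:
    """Least-squares fit of ``offset + amplitude * exp(-k_obs t)``.

    The initial rate guess is ``ln 2 / t_half`` with ``t_half`` the time at
    which the signal first crosses half of its total decay.
    """
    t, s = trace.time_s, trace.signal
    offset0 = float(np.mean(s[-max(1, int(round(BASELINE_FRACTION * s.size))):]))
    amp0 = float(s[0] - offset0)
    if amp0 <= 0:
        return MonoExpFit(
            k_obs=float("nan"), amplitude=amp0, offset=offset0, rss=float("nan"),
            success=False, message="trace does not decay (non-positive amplitude)",
        )
    half = offset0 + 0.5 * amp0
    below = np.nonzero(s <= half)[0]
    t_half = t[below[0]] if below.size and t[below[0]] > 0 else t[-1] / 2
    k0 = np.log(2.0) / t_half

    def model(t, offset, amplitude, k_obs):
        return offset + amplitude * np.exp(-k_obs * t)

    try:
        popt, pcov = curve_fit(
            model, t, s, p0=(offset0, amp0, k0),
            bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return MonoExpFit(
            k_obs=float("nan"), amplitude=amp0, offset=offset0, rss=float("nan"),
            success=False, message=f"mono-exponential fit failed: {exc}",
        )
    resid = s - model(t, *popt)
    return MonoExpFit(
        k_obs=float(popt[2]),
        amplitude=float(popt[1]),
        offset=float(popt[0]),
        rss=float(np.sum(resid**2)),
        k_obs_se=float(np.sqrt(pcov[2, 2])),
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept and their standard errors for an OLS line."""
    n = x.size
    X = np.column_stack([x, np.ones(n)])
    coef, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = max(n - 2, 1)
    cov = rss / dof * np.linalg.inv(X.T @ X)
    return float(coef[0]), float(coef[1]), float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


def kon_regression(series: TraceSeries) -> PseudoFirstOrderResult:
    """k_obs per concentration and the linear fit whose slope is ``k_on``.

    Points that deviate from the line with an externally studentized residual
    above 3 (saturation of ``k_obs`` at high ligand excess) are excluded from
    the slope with a logged note.
    """
    fits = [(t.ligand_conc_uM, fit_monoexponential(t)) for t in series.traces]
    good = [(c, f) for c, f in fits if f.success]
    if len(good) < 3:
        raise InputError(
            f"k_on regression requires >= 3 successful mono-exponential fits, "
            f"got {len(good)}"
        )
    concs = np.array([c for c, _ in good])
    kobs = np.array([f.k_obs for _, f in good])

    excluded: list[int] = []
    keep = np.ones(concs.size, dtype=bool)
    if concs.size >= 4:
        # one pass of externally studentized residuals against the line
        stud = _external_studentized(concs, kobs)
        flag = np.abs(stud) > 3.0
        if np.any(flag):
            excluded = list(np.nonzero(flag)[0])
            keep = ~flag
            logger.warning(
                "kon_regression: excluding %d saturating point(s) at L=%s uM "
                "(studentized residual > 3)",
                len(excluded), concs[flag].tolist(),
            )
    slope, intercept, slope_se, intercept_se = _ols_line(concs[keep], kobs[keep])
    return PseudoFirstOrderResult(
        ligand_concs_uM=concs,
        k_obs=kobs,
        k_on=slope,
        intercept=intercept,
        k_on_se=slope_se,
        intercept_se=intercept_se,
        excluded=excluded,
    )


def _external_studentized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out studentized residuals of y against an OLS line in x."""
    n = x.size
    out = np.zeros(n)
    for i in range(n):
        mask = np.arange(n) != i
        slope, intercept, *_ = _ols_line(x[mask], y[mask])
        pred = slope * x[i] + intercept
        resid = y[mask] - (slope * x[mask] + intercept)
        dof = max(mask.sum() - 2, 1)
        s = np.sqrt(float(resid @ resid) / dof)
        # prediction variance at x[i] from the leave-one-out fit
        xm = x[mask]
        sxx = float(np.sum((xm - xm.mean()) ** 2))
        lever = 1.0 + 1.0 / mask.sum() + (x[i] - xm.mean()) ** 2 / sxx
        # floor the scatter estimate: on (near-)exact data s is pure round-off
        # and would turn numerical dust into spurious outliers
        floor = 1e-9 * max(float(np.max(np.abs(y))), 1.0)
        out[i] = (y[i] - pred) / (max(s, floor) * np.sqrt(lever))
    return out


# ---------------------------------------------------------------------------
# Model signal prediction
# ---------------------------------------------------------------------------

def predict_signal(
    scheme: kinetics.ReactionScheme | str,
    rates: kinetics.RateSet,
    observable: ObservableMap,
    ligand_conc_uM: float,
    receptor_conc_uM: float,
    time_s: np.ndarray,
) -> np.ndarray:
    """Model fluorescence on a trace's grid, under the preprocessing contract.

    The raw model signal is the response-weighted free plus complexed ligand
    divided by total ligand; it is then passed through the same
    baseline/normalization transform applied to measured traces, so model and
    data are directly comparable.
    """
    scheme = kinetics._as_scheme(scheme)
    init = kinetics.initial_state(scheme, receptor_conc_uM, ligand_conc_uM, rates)
    traj = kinetics.simulate(scheme, rates, init, time_s)
    raw = _raw_signal(scheme, observable, traj.concentrations, ligand_conc_uM)
    return normalize_contract(raw)


def _raw_signal(
    scheme: kinetics.ReactionScheme,
    observable: ObservableMap,
    conc: np.ndarray,
    L0: float,
) -> np.ndarray:
    """(free ligand + sum of response-weighted complexes)/L0 + baseline."""
    names = scheme.species_names
    signal = conc[..., names.index(scheme.ligand_name)].astype(float).copy()
    for name in scheme.complex_names:
        r = observable.response(name)
        if r != 0.0:
            signal += r * conc[..., names.index(name)]
    return observable.baseline + signal / L0


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------

@dataclass
class GlobalFitOptions:
    """Options of :func:`global_fit`."""

    n_starts: int = 20
    seed: int = 0
    bounds: tuple[float, float] = (1e-3, 1e3)
    fit_responses: bool = False
    #: fixed response factors per complex species when fit_responses is off
    #: (default: all complexes fully quenched)
    responses: Mapping[str, float] | None = None
    fit_trace_scales: bool = True
    dead_time_s: float = 0.0
    rtol: float = 1e-8
    atol: float = 1e-10
    explore_max_nfev: int = 120
    polish_max_nfev: int = 2000


def _apply_dead_time(series: TraceSeries, dead_time_s: float) -> TraceSeries:
    if dead_time_s <= 0:
        return series
    traces = []
    for t in series.traces:
        mask = t.time_s >= dead_time_s
        traces.append(
            StoppedFlowTrace(
                time_s=t.time_s[mask] - t.time_s[mask][0],
                signal=t.signal[mask],
                ligand_conc_uM=t.ligand_conc_uM,
                receptor_conc_uM=t.receptor_conc_uM,
                n_averaged=t.n_averaged,
                plateau_warning=t.plateau_warning,
            )
        )
    return TraceSeries(traces=traces, label=series.label)


def _series_predictor(
    scheme: kinetics.ReactionScheme,
    series: TraceSeries,
    observable_responses_free: bool,
    rtol: float,
    atol: float,
    fixed_responses: Mapping[str, float] | None = None,
):
    """Build theta -> concatenated model signal for all traces of a series.

    theta holds log10 rate constants followed (optionally) by the free
    response factors of the complex species.
    """
    rate_syms = scheme.rate_symbols
    n_rates = len(rate_syms)
    complexes = scheme.complex_names
    grids = [t.time_s for t in series.traces]
    common = all(
        g.shape == grids[0].shape and np.array_equal(g, grids[0]) for g in grids
    )
    R0 = series.receptor_conc_uM
    ligand_concs = series.ligand_concs_uM

    def predict(theta: np.ndarray) -> list[np.ndarray]:
        rates = {sym: 10.0 ** theta[i] for i, sym in enumerate(rate_syms)}
        if observable_responses_free:
            responses = dict(zip(complexes, theta[n_rates:]))
        else:
            responses = dict(fixed_responses or {})
        obs = ObservableMap(responses=responses)
        initials = [
            kinetics.initial_state(scheme, R0, L0, rates) for L0 in ligand_concs
        ]
        pieces = []
        if common:
            conc = kinetics.simulate_batch(
                scheme, rates, initials, grids[0], rtol=rtol, atol=atol
            )
            for j, L0 in enumerate(ligand_concs):
                raw = _raw_signal(scheme, obs, conc[:, j, :], L0)
                pieces.append(normalize_contract(raw))
        else:
            for init, L0, grid in zip(initials, ligand_concs, grids):
                traj = kinetics.simulate(scheme, rates, init, grid, rtol=rtol, atol=atol)
                raw = _raw_signal(scheme, obs, traj.concentrations, L0)
                pieces.append(normalize_contract(raw))
        return pieces

    return predict


def _profile_scales(
    pieces: list[np.ndarray], data_pieces: list[np.ndarray]
) -> np.ndarray:
    """Per-trace amplitude scales minimizing ||s_j m_j - d_j||^2 in closed form."""
    scales = np.ones(len(pieces))
    for j, (m, d) in enumerate(zip(pieces, data_pieces)):
        denom = float(m @ m)
        if denom > 0:
            scales[j] = float(np.clip((m @ d) / denom, 0.5, 2.0))
    return scales


def global_fit(
    scheme: kinetics.ReactionScheme | str,
    series: TraceSeries,
    options: GlobalFitOptions | None = None,
) -> GlobalFitResult:
    """Fit one scheme to every trace of a series simultaneously.

    Rate constants are shared across traces and optimized in log10 space
    within the option bounds.  The best of ``n_starts`` log-uniform random
    starts (drawn from the option seed) is polished and reported; standard
    errors come from the linearized covariance at the optimum,
    ``sqrt(diag(RSS/(n-p) * (J^T J)^-1))`` with J taken with respect to the
    natural (linear) parameters.

    With ``fit_trace_scales`` (default) a multiplicative amplitude scale per
    trace is profiled out in closed form alongside the shared rates.  The
    normalization contract anchors each measured trace on its own noisy
    first point and baseline window, which perturbs the trace's overall
    scale; the nuisance scales absorb that perturbation instead of letting
    it bias the rate constants.  The scales count as free parameters in
    ``n_parameters`` and in the covariance.
    """
    scheme = kinetics._as_scheme(scheme)
    opts = options or GlobalFitOptions()
    series = _apply_dead_time(series, opts.dead_time_s)
    if len({t.ligand_conc_uM for t in series.traces}) < 2:
        raise InputError("global fit requires >= 2 distinct ligand concentrations")

    data_pieces = [t.signal for t in series.traces]
    data = np.concatenate(data_pieces)
    n = data.size
    n_traces = len(data_pieces)
    rate_syms = scheme.rate_symbols
    n_rates = len(rate_syms)
    complexes = scheme.complex_names
    n_resp = len(complexes) if opts.fit_responses else 0
    n_scales = n_traces if opts.fit_trace_scales else 0
    p = n_rates + n_resp + n_scales

    predict = _series_predictor(
        scheme, series, opts.fit_responses, opts.rtol, opts.atol,
        fixed_responses=opts.responses,
    )

    def model_vector(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pieces = predict(theta)
        if opts.fit_trace_scales:
            scales = _profile_scales(pieces, data_pieces)
        else:
            scales = np.ones(n_traces)
        return np.concatenate([s * m for s, m in zip(scales, pieces)]), scales

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            return model_vector(theta)[0] - data
        except Exception as exc:  # integrator failure at absurd parameters
            logger.debug("global_fit residual failure at theta=%s: %s", theta, exc)
            return np.full(n, 1e3)

    lo, hi = np.log10(opts.bounds[0]), np.log10(opts.bounds[1])
    lower = np.concatenate([np.full(n_rates, lo), np.zeros(n_resp)])
    upper = np.concatenate([np.full(n_rates, hi), np.ones(n_resp)])

    rng = np.random.default_rng(opts.seed)
    starts = rng.uniform(lo, hi, size=(opts.n_starts, n_rates))
    if n_resp:
        starts = np.hstack([starts, rng.uniform(0, 1, size=(opts.n_starts, n_resp))])

    best = None
    diagnostics = []
    for i, theta0 in enumerate(starts):
        try:
            res = least_squares(
                residuals, theta0, bounds=(lower, upper),
                max_nfev=opts.explore_max_nfev, method="trf",
            )
        except Exception as exc:
            diagnostics.append(f"start {i}: failed ({exc})")
            continue
        diagnostics.append(f"start {i}: cost {res.cost:.6g}")
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(
            "all multi-starts failed:\n" + "\n".join(diagnostics)
        )
    # polish the winning start without the exploration budget cap
    best = least_squares(
        residuals, best.x, bounds=(lower, upper), max_nfev=opts.polish_max_nfev,
        method="trf",
    )

    theta = best.x
    resid = best.fun
    rss = float(resid @ resid)
    rmsd = float(np.sqrt(rss / n))
    rates = {sym: 10.0 ** theta[i] for i, sym in enumerate(rate_syms)}

    # Covariance from the full Jacobian (rates, responses and nuisance
    # scales) at the optimum, by forward differences at fixed optimal scales.
    n_theta = n_rates + n_resp
    pieces_opt = predict(theta)
    scales_opt = (
        _profile_scales(pieces_opt, data_pieces)
        if opts.fit_trace_scales
        else np.ones(n_traces)
    )

    def scaled_model(th: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [s * m for s, m in zip(scales_opt, predict(th))]
        )

    m0 = scaled_model(theta)
    J = np.empty((n, p))
    step = 1e-6
    for i in range(n_theta):
        th = theta.copy()
        th[i] += step
        J[:, i] = (scaled_model(th) - m0) / step
    if opts.fit_trace_scales:
        offset = 0
        for j, m in enumerate(pieces_opt):
            col = np.zeros(n)
            col[offset: offset + m.size] = m
            J[:, n_theta + j] = col
            offset += m.size
    # chain rule log10(k) -> k for the rate columns
    for i, sym in enumerate(rate_syms):
        J[:, i] /= rates[sym] * np.log(10.0)
    dof = max(n - p, 1)
    try:
        cov = rss / dof * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        se = np.full(p, float("nan"))

    at_bounds = []
    for i, sym in enumerate(rate_syms):
        if theta[i] - lower[i] < 1e-6 or upper[i] - theta[i] < 1e-6:
            at_bounds.append(sym)
    if at_bounds:
        logger.warning("global_fit(%s): parameter(s) at bounds: %s",
                       scheme.id, at_bounds)

    responses = (
        dict(zip(complexes, (float(v) for v in theta[n_rates:])))
        if opts.fit_responses
        else {name: float((opts.responses or {}).get(name, 0.0)) for name in complexes}
    )
    response_se = (
        dict(zip(complexes, (float(v) for v in se[n_rates: n_rates + n_resp])))
        if opts.fit_responses
        else {}
    )
    return GlobalFitResult(
        trace_scales=[float(s) for s in scales_opt],
        scheme_id=scheme.id,
        rates={sym: float(rates[sym]) for sym in rate_syms},
        rate_se={sym: float(se[i]) for i, sym in enumerate(rate_syms)},
        responses=responses,
        response_se=response_se,
        rss=rss,
        rmsd=rmsd,
        n_points=n,
        n_parameters=p,
        n_starts=opts.n_starts,
        seed=opts.seed,
        success=bool(best.success),
        at_bounds=at_bounds,
        message=str(best.message),
        label=series.label,
    )


# ---------------------------------------------------------------------------
# Model discrimination
# ---------------------------------------------------------------------------

def information_criteria(rss: float, n: int, p: int) -> tuple[float, float]:
    """Least-squares AIC and BIC: ``n ln(RSS/n) + 2p`` and ``n ln(RSS/n) + p ln n``."""
    base = n * np.log(rss / n)
    return float(base + 2 * p), float(base + p * np.log(n))


def compare_models(
    fits: Sequence[GlobalFitResult], use_aicc: bool = False
) -> ModelComparisonTable:
    """Rank candidate schemes fitted to the identical dataset by AIC and BIC.

    Models within |dAIC| < 2 of the best are reported as indistinguishable
    rather than crowning a single winner.  ``use_aicc`` switches to the
    small-sample corrected AIC.
    """
    if not fits:
        raise InputError("compare_models requires at least one fit")
    n_values = {f.n_points for f in fits}
    if len(n_values) > 1:
        raise InputError(
            f"fits compare different datasets (n_points = {sorted(n_values)})"
        )
    n = fits[0].n_points
    rows = []
    for f in fits:
        aic, bic = information_criteria(f.rss, n, f.n_parameters)
        if use_aicc:
            k = f.n_parameters
            aic += 2 * k * (k + 1) / max(n - k - 1, 1)
        rows.append(
            ModelComparisonRow(
                scheme_id=f.scheme_id, rmsd=f.rmsd, aic=aic, bic=bic,
                delta_aic=0.0, delta_bic=0.0, n_parameters=f.n_parameters,
                label=f.label,
            )
        )
    aic_min = min(r.aic for r in rows)
    bic_min = min(r.bic for r in rows)
    for r in rows:
        r.delta_aic = r.aic - aic_min
        r.delta_bic = r.bic - bic_min
    indist = [r.scheme_id for r in rows if r.delta_aic < 2.0]
    return ModelComparisonTable(
        rows=rows, n_points=n,
        indistinguishable=indist if len(indist) > 1 else [],
    )
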