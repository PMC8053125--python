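"""Synthetic data generation for all three experiment types.

The generators emulate the statistical structure the fitters assume:

* stopped-flow series — deterministic mass-action kinetics passed through
  the fluorescence observable, per-shot Gaussian noise, shot averaging and
  the standard preprocessing contract;
* TCSPC histograms — multi-exponential expected counts, Poisson-sampled per
  channel;
* titrations — Hill isotherm responses with Gaussian noise.

All randomness flows from an explicit seed; there is no global random state.
The ``paper()`` experiment designs carry the reference study conditions
(2 uM RNA mixed with 4-20 uM ligand, 25 shots averaged per concentration,
50 nM probe in titrations), and the ``RATE_PRESETS`` / ``LIFETIME_PRESETS``
tables carry the published rate-constant and lifetime sets for the three
aptamer candidates (A, preRS, RS) so that tests and examples reference
presets rather than retyped numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import kinetics
from .decay import DecayHistogram, decay_model
from .errors import ConfigurationError
from .stopped_flow import (
    ObservableMap,
    StoppedFlowTrace,
    TraceSeries,
    _raw_signal,
    normalize_contract,
    preprocess,
)
from .titration import TitrationCurve, hill_model

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Noise and design specifications
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Noise model: Gaussian per-point sigma or Poisson total counts."""

    kind: str = "gaussian"
    sigma: float = 0.01
    total_counts: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.total_counts < 1:
            raise ConfigurationError("total_counts must be >= 1")


@dataclass
class StoppedFlowDesign:
    """Concentration series layout of a stopped-flow experiment."""

    receptor_conc_uM: float = 2.0
    ligand_concs_uM: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0)
    duration_s: float = 2.0
    n_points: int = 200
    shots_per_concentration: int = 25

    @classmethod
    def paper(cls) -> "StoppedFlowDesign":
        """Reference design: 2 uM RNA, 2-10 ligand equivalents, 25 shots."""
        return cls()

    @property
    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_s, self.n_points)


@dataclass
class TCSPCDesign:
    """Histogram layout of a photon-counting experiment."""

    channel_width_ns: float = 0.025
    n_channels: int = 2048
    background_counts: float = 0.0

    @classmethod
    def paper(cls) -> "TCSPCDesign":
        return cls()

    @property
    def time_grid_ns(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.channel_width_ns


@dataclass
class TitrationDesign:
    """Titrant grid and probe concentration of a titration experiment."""

    titrant_concs: tuple[float, ...] = ()
    probe_conc_nM: float = 50.0
    titrant_label: str = "RNA"
    titrant_unit: str = "nM"

    @classmethod
    def paper_rna(cls) -> "TitrationDesign":
        """12 log-spaced RNA concentrations 1-500 nM at the 50 nM probe."""
        return cls(
            titrant_concs=tuple(np.geomspace(1.0, 500.0, 12)),
            probe_conc_nM=50.0, titrant_label="RNA", titrant_unit="nM",
        )

    @classmethod
    def paper_mg(cls) -> "TitrationDesign":
        """12 log-spaced Mg2+ concentrations 0.05-10 mM."""
        return cls(
            titrant_concs=tuple(np.geomspace(0.05, 10.0, 12)),
            probe_conc_nM=50.0, titrant_label="Mg2+", titrant_unit="mM",
        )


# ---------------------------------------------------------------------------
# Published parameter presets
# ---------------------------------------------------------------------------

#: Rate constants of the three aptamer candidates under each fitted scheme
#: (bimolecular rates in 1/(uM s), unimolecular in 1/s).  The one-step RS
#: back-rate was indistinguishable from zero (< 1e-6 1/s) and is stored as 0.
RATE_PRESETS: dict[str, tuple[str, dict[str, float]]] = {
    "A-model1": ("model1", {"k1": 7.78, "km1": 0.33}),
    "preRS-model1": ("model1", {"k1": 3.61, "km1": 0.09}),
    "RS-model1": ("model1", {"k1": 5.21, "km1": 0.0}),
    "A-model4": ("model4", {"k1": 10.0, "km1": 1.6, "k2": 4.0, "km2": 2.3}),
    "A-model5": ("model5", {"k1": 10.0, "km1": 0.8, "k2": 6.0}),
    "preRS-model4": ("model4", {"k1": 4.33, "km1": 5.7, "k2": 13.2, "km2": 0.06}),
    "preRS-model5": ("model5", {"k1": 4.31, "km1": 5.4, "k2": 12.1}),
    "RS-model4": ("model4", {"k1": 7.6, "km1": 3.1, "k2": 23.0, "km2": 0.27}),
    "RS-model5": ("model5", {"k1": 7.62, "km1": 2.9, "k2": 23.0}),
}

#: Fluorescence lifetime structure (tau_ns, amplitude_pct) of the free ligand
#: and of each ligand-aptamer complex in the selection buffer.
LIFETIME_PRESETS: dict[str, tuple[tuple[float, float], ...]] = {
    "CFX": ((1.28, 65.0), (2.92, 35.0)),
    "CFX@A": ((0.64, 77.0), (2.48, 14.0), (6.5, 9.0)),
    "CFX@preRS": ((0.43, 53.0), (2.22, 37.0), (6.3, 10.0)),
    "CFX@RS": ((0.49, 58.0), (1.90, 36.0), (8.3, 6.0)),
}

#: Mono-exponential lifetime of the ligand in cation-free solution (ns).
CFX_LIFETIME_NO_CATIONS_NS = 1.3

#: Titration truths: minimal apparent K_D of aptamer A at high Mg2+ (nM) and
#: the Hill coefficient of its Mg2+-dependence, with the synthetic midpoint
#: placed between the two lowest measured Mg2+ levels.
KD_MIN_A_NM = 13.0
MG_HILL_COEFFICIENT_A = 4.6
MG_MIDPOINT_MM = 0.8


def get_rate_preset(name: str) -> tuple[kinetics.ReactionScheme, dict[str, float]]:
    """Return (scheme, rates) for a named candidate/model preset."""
    try:
        scheme_id, rates = RATE_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown rate preset {name!r}; available: {', '.join(sorted(RATE_PRESETS))}"
        ) from None
    return kinetics.get_scheme(scheme_id), dict(rates)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_stopped_flow(
    scheme: kinetics.ReactionScheme | str,
    rates: kinetics.RateSet,
    design: StoppedFlowDesign | None = None,
    observable: ObservableMap | None = None,
    noise: NoiseSpec | None = None,
    label: str = "",
) -> TraceSeries:
    """Simulate a full stopped-flow concentration series.

    Each ligand concentration is simulated deterministically, mapped through
    the observable and the normalization contract, corrupted with independent
    per-shot Gaussian noise, shot-averaged, and preprocessed exactly like
    measured data.  Noise is added on the normalized-signal scale (traces
    spanning 1 -> 0): the instrument gain is adjusted so that every trace of
    a series has a comparable raw amplitude, so the per-shot noise level is
    best expressed relative to that common amplitude.
    """
    scheme = kinetics._as_scheme(scheme)
    design = design or StoppedFlowDesign.paper()
    observable = observable or ObservableMap()
    noise = noise or NoiseSpec(kind="gaussian", sigma=0.0, seed=0)
    if noise.kind != "gaussian":
        raise ConfigurationError("stopped-flow noise must be gaussian (shot noise regime)")
    rng = np.random.default_rng(noise.seed)
    grid = design.time_grid
    traces = []
    for L0 in design.ligand_concs_uM:
        init = kinetics.initial_state(scheme, design.receptor_conc_uM, L0, rates)
        traj = kinetics.simulate(scheme, rates, init, grid)
        raw = _raw_signal(scheme, observable, traj.concentrations, L0)
        clean = normalize_contract(raw)
        shots = [
            clean + rng.normal(0.0, noise.sigma, size=clean.shape)
            if noise.sigma > 0 else clean.copy()
            for _ in range(design.shots_per_concentration)
        ]
        traces.append(
            preprocess(shots, grid, L0, design.receptor_conc_uM)
        )
    return TraceSeries(traces=traces, label=label or scheme.id)


def gen_stopped_flow_preset(
    preset: str,
    design: StoppedFlowDesign | None = None,
    noise: NoiseSpec | None = None,
) -> TraceSeries:
    """Series from a named candidate/model rate preset (fully quenched complexes)."""
    scheme, rates = get_rate_preset(preset)
    return gen_stopped_flow(scheme, rates, design=design, noise=noise, label=preset)


def gen_tcspc(
    components: Sequence[tuple[float, float]],
    design: TCSPCDesign | None = None,
    noise: NoiseSpec | None = None,
    irf: np.ndarray | None = None,
) -> DecayHistogram:
    """Poisson-sampled multi-exponential decay histogram.

    ``components`` is a sequence of (lifetime_ns, amplitude_pct) pairs; the
    expected channel counts are scaled so that their sum equals the requested
    total counts before Poisson sampling.
    """
    design = design or TCSPCDesign.paper()
    noise = noise or NoiseSpec(kind="poisson", total_counts=1_000_000, seed=0)
    if noise.kind != "poisson":
        raise ConfigurationError("TCSPC noise is photon counting; use kind='poisson'")
    taus = np.array([c[0] for c in components], dtype=float)
    amps = np.array([c[1] for c in components], dtype=float)
    if np.any(taus <= 0) or np.any(amps < 0):
        raise ConfigurationError("lifetimes must be positive, amplitudes non-negative")
    t = design.time_grid_ns
    expected = decay_model(t, amps, taus, design.background_counts, irf)
    expected *= noise.total_counts / expected.sum()
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(expected)
    return DecayHistogram(
        channel_time_ns=t, counts=counts,
        background=design.background_counts, irf=irf,
    )


def gen_tcspc_preset(
    preset: str,
    design: TCSPCDesign | None = None,
    noise: NoiseSpec | None = None,
) -> DecayHistogram:
    """Histogram from a named lifetime preset (free ligand or a complex)."""
    try:
        components = LIFETIME_PRESETS[preset]
    except KeyError:
        raise ConfigurationError(
            f"unknown lifetime preset {preset!r}; available: "
            f"{', '.join(sorted(LIFETIME_PRESETS))}"
        ) from None
    return gen_tcspc(components, design=design, noise=noise)


def gen_titration(
    kd: float,
    h: float,
    bmax: float,
    design: TitrationDesign,
    noise: NoiseSpec | None = None,
) -> TitrationCurve:
    """Hill-isotherm titration curve with Gaussian response noise."""
    noise = noise or NoiseSpec(kind="gaussian", sigma=0.0, seed=0)
    if noise.kind != "gaussian":
        raise ConfigurationError("titration noise must be gaussian")
    x = np.asarray(design.titrant_concs, dtype=float)
    if x.size == 0:
        raise ConfigurationError("titration design has an empty titrant grid")
    if not (x.min() <= kd <= x.max()):
        logger.warning(
            "gen_titration: K_D=%g %s lies outside the titrant grid [%g, %g]",
            kd, design.titrant_unit, x.min(), x.max(),
        )
    rng = np.random.default_rng(noise.seed)
    y = hill_model(x, kd, h, bmax)
    if noise.sigma > 0:
        y = y + rng.normal(0.0, noise.sigma, size=x.shape)
    return TitrationCurve(
        titrant_conc=x, response=y,
        probe_conc_nM=design.probe_conc_nM,
        titrant_label=design.titrant_label,
        titrant_unit=design.titrant_unit,
    )


# ---------------------------------------------------------------------------
# Derived observables used in calibration checks
# ---------------------------------------------------------------------------

def equilibration_time(
    trace: StoppedFlowTrace, fraction: float = 0.05
) -> float:
    """First time after which the normalized signal stays within ``fraction``
    of its plateau (0 by the preprocessing contract).

    The 5% default mimics the by-eye judgement of when a displayed trace has
    reached its equilibrium level.
    """
    outside = np.abs(trace.signal) > fraction
    if not np.any(outside):
        return float(trace.time_s[0])
    last_outside = int(np.nonzero(outside)[0][-1])
    if last_outside + 1 >= trace.time_s.size:
        return float("inf")
    return float(trace.time_s[last_outside + 1])
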