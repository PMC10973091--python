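"""Synthetic assay-data generation with known ground truth.

Every recording type consumed by the analysis stages can be simulated here:
eight-to-nine-point agonist and blocker concentration-response series with
multiplicative lognormal noise, biexponential deactivation traces with an
exponential onset and Gaussian baseline noise, paired control/MTSEA
steady-state currents, Na+ and Ba2+ current-voltage families with a
configurable reversal-potential shift, and linear beta-lactamase absorbance
ramps.  Presets encode wild-type GluN1/GluN2A and GluN1/GluN2B receptors plus
representative gain- and loss-of-function variants, so that a full per-variant
panel can be produced and pushed end to end through fitting, scoring and
classification with the generating truth available for comparison.

All generators are deterministic under a fixed seed and accept either a seed
or a ``numpy.random.Generator``; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import (ConcentrationResponseSeries, hill_agonist_response,
                            hill_inhibitor_response)
from .kinetics import CurrentTrace
from .channel_props import MtseaMeasurement, DEFAULT_GAMMA_RATIO
from .permeability import IVFamily, DEFAULT_VOLTAGE_STEPS_MV

__all__ = [
    "GroundTruthProfile",
    "SimulationConfig",
    "PRESETS",
    "default_concentration_series",
    "generate_concentration_response",
    "generate_deactivation_trace",
    "generate_deactivation_panel",
    "generate_mtsea_pair",
    "generate_mtsea_panel",
    "generate_iv_family",
    "generate_absorbance_series",
    "generate_expression_wells",
    "generate_variant_panel",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(-sigma ** 2 / 2, sigma, size)


@dataclass
class GroundTruthProfile:
    """Generating-side truth for one receptor construct.

    Concentrations are uM, times ms, voltages mV.  ``noise_cv`` is the
    per-measurement coefficient of variation for steady-state readouts
    (MTSEA pairs, per-cell kinetic/expression scatter); ``cr_noise_cv``
    is the per-point residual scatter of composite concentration-response
    curves, which is considerably smaller than the cell-to-cell scatter
    because responses are normalized within each cell.
    """

    construct_id: str
    ec50_glu: float
    ec50_gly: float
    hill_glu: float = 1.2
    hill_gly: float = 1.2
    ic50_mg: float = 19.0
    hill_mg: float = 1.0
    po_max: float = 0.24
    tau_fast: float = 30.0
    tau_slow: float = 100.0
    frac_fast: float = 0.8
    peak_current: float = 150.0   # pA/pF
    surface_ratio: float = 1.0
    ph_ratio: float = 0.43        # I(pH 6.8) / I(pH 7.6)
    vrev_shift_ba: float = 12.1   # mV
    noise_cv: float = 0.2
    baseline_sd: float = 2.0      # pA/pF, trace sample noise
    cr_noise_cv: float = 0.06
    tau_cell_cv: Optional[float] = 0.25
    vrev_na: float = 0.0          # mV, reversal in Na+ solution
    conductance: float = 0.02     # nA/mV chord conductance of the I-V family
    iv_noise_sd: float = 0.015    # nA, additive noise on difference currents
    ba_inward_scale: float = 1.0  # suppression of inward Ba2+ current
    gamma_ratio: float = DEFAULT_GAMMA_RATIO
    desens_plateau: Optional[float] = None  # steady/peak for prolonged traces

    def __post_init__(self) -> None:
        for name in ("ec50_glu", "ec50_gly", "ic50_mg", "hill_glu", "hill_gly",
                     "hill_mg", "tau_fast", "tau_slow", "peak_current"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.po_max <= 1:
            raise ValueError("po_max must be in (0, 1]")
        if not 0 <= self.frac_fast <= 1:
            raise ValueError("frac_fast must be in [0, 1]")
        if self.tau_fast > self.tau_slow:
            # canonical order: the "fast" component is the shorter tau
            self.tau_fast, self.tau_slow = self.tau_slow, self.tau_fast
            self.frac_fast = 1.0 - self.frac_fast
        if self.tau_cell_cv is None:
            self.tau_cell_cv = self.noise_cv

    @property
    def tau_weighted(self) -> float:
        return self.frac_fast * self.tau_fast + (1 - self.frac_fast) * self.tau_slow

    @property
    def mtsea_potentiation(self) -> float:
        return self.gamma_ratio / self.po_max


@dataclass
class SimulationConfig:
    """Shared acquisition settings for the generators."""

    seed: int = 0
    n_cells: int = 12
    concentration_series_um: Optional[Sequence[float]] = None
    voltage_steps_mv: Sequence[float] = DEFAULT_VOLTAGE_STEPS_MV
    sample_interval_ms: float = 1.0
    trace_duration_ms: Optional[float] = None  # None: 5.5 tau_slow past offset
    application_start_ms: float = 20.0
    application_duration_ms: float = 6.0
    rise_time_10_90_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.concentration_series_um is not None:
            c = np.asarray(self.concentration_series_um, dtype=float)
            if c.size < 4 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
                raise ValueError("concentration series must be >=4 strictly "
                                 "increasing positive values")
        v = np.asarray(self.voltage_steps_mv, dtype=float)
        if v.min() >= 0 or v.max() <= 0:
            raise ValueError("voltage steps must bracket a driving-force "
                             "sign change")
        if self.n_cells < 1 or self.sample_interval_ms <= 0:
            raise ValueError("invalid cell count or sample interval")


def default_concentration_series(potency_um: float) -> np.ndarray:
    """Half-log spacing spanning 0.01x to 100x the potency (9 points)."""
    if potency_um <= 0:
        raise ValueError("potency must be positive")
    return potency_um * np.logspace(-2, 2, 9)


# ---------------------------------------------------------------------------
# concentration-response
# ---------------------------------------------------------------------------

def generate_concentration_response(profile: GroundTruthProfile,
                                    config: SimulationConfig,
                                    mode: str = "agonist",
                                    ligand: str = "glutamate",
                                    rng=None) -> list[ConcentrationResponseSeries]:
    """Simulate per-cell concentration-response series for one ligand.

    Responses follow the agonist or inhibitor Hill curve of the profile,
    expressed as percent of fitted maximum and multiplied by mean-one
    lognormal noise with CV ``profile.cr_noise_cv``.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if mode == "agonist":
        if ligand == "glutamate":
            potency, slope = profile.ec50_glu, profile.hill_glu
        elif ligand == "glycine":
            potency, slope = profile.ec50_gly, profile.hill_gly
        else:
            raise ValueError(f"unknown agonist ligand {ligand!r}")
        curve = lambda c: hill_agonist_response(c, potency, slope)
    elif mode == "inhibitor":
        potency, slope = profile.ic50_mg, profile.hill_mg
        curve = lambda c: hill_inhibitor_response(c, potency, slope, 0.0)
    else:
        raise ValueError("mode must be 'agonist' or 'inhibitor'")
    if potency <= 0:
        raise ValueError("potency must be positive")

    concs = (np.asarray(config.concentration_series_um, dtype=float)
             if config.concentration_series_um is not None
             else default_concentration_series(potency))
    ideal = curve(concs)
    out = []
    for i in range(config.n_cells):
        noise = _lognormal_factors(rng, profile.cr_noise_cv, concs.size)
        out.append(ConcentrationResponseSeries(
            construct_id=profile.construct_id,
            ligand=ligand if mode == "agonist" else "Mg",
            cell_id=f"{profile.construct_id}-c{i:03d}",
            concentrations_um=concs,
            responses_pct=ideal * noise,
        ))
    return out


# ---------------------------------------------------------------------------
# deactivation traces
# ---------------------------------------------------------------------------

def generate_deactivation_trace(profile: GroundTruthProfile,
                                config: SimulationConfig,
                                rng=None,
                                tau_scale: float = 1.0,
                                peak_scale: float = 1.0,
                                cell_id: str = "c000",
                                prolonged: bool = False) -> CurrentTrace:
    """Simulate one agonist-evoked current trace.

    A single-exponential onset (10-90% rise time from the config) precedes
    either a biexponential decay starting at agonist removal, or, with
    ``prolonged=True``, a desensitizing plateau followed by the decay.
    Gaussian baseline noise of SD ``profile.baseline_sd`` is added to every
    sample.  The trace must resolve the fast component: a sample interval at
    or above ``tau_fast`` is rejected as undersampled.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    tf = profile.tau_fast * tau_scale
    ts = profile.tau_slow * tau_scale
    peak = profile.peak_current * peak_scale
    dt = config.sample_interval_ms
    if dt >= tf:
        raise ValueError("sample interval must be below tau_fast (undersampled)")

    t_on = config.application_start_ms
    app_dur = (1500.0 if prolonged else config.application_duration_ms)
    t_off = t_on + app_dur
    duration = (config.trace_duration_ms if config.trace_duration_ms is not None
                else t_off + 5.5 * ts)
    if duration < 5 * ts:
        raise ValueError("trace duration must be at least 5x tau_slow")

    t = np.arange(0.0, duration + dt / 2, dt)
    y = np.zeros_like(t)
    tau_rise = config.rise_time_10_90_ms / np.log(9.0)

    rise = (t >= t_on) & (t <= t_off)
    onset = 1.0 - np.exp(-(t[rise] - t_on) / tau_rise)
    onset /= 1.0 - np.exp(-min(app_dur, 10 * tau_rise) / tau_rise)
    if prolonged and profile.desens_plateau is not None:
        # sag from peak toward the desensitized plateau during application
        plateau = profile.desens_plateau
        sag = plateau + (1 - plateau) * np.exp(-np.clip(t[rise] - t_on - 5 * tau_rise,
                                                        0, None) / (app_dur / 5))
        y[rise] = peak * np.minimum(onset, sag)
    else:
        y[rise] = peak * np.minimum(onset, 1.0)

    decay = t > t_off
    level = y[rise][-1] if rise.any() else peak
    y[decay] = level * (profile.frac_fast * np.exp(-(t[decay] - t_off) / tf)
                        + (1 - profile.frac_fast) * np.exp(-(t[decay] - t_off) / ts))
    if profile.baseline_sd > 0:
        y = y + rng.normal(0.0, profile.baseline_sd, t.size)
    return CurrentTrace(cell_id=cell_id, time_ms=t, current=y,
                        application_window_ms=(t_on, t_off),
                        construct_id=profile.construct_id)


def generate_deactivation_panel(profile: GroundTruthProfile,
                                config: SimulationConfig,
                                n_cells: Optional[int] = None,
                                rng=None) -> list[CurrentTrace]:
    """Simulate a panel of cells with lognormal cell-to-cell kinetic scatter.

    Each cell's time constants are scaled by a common mean-one lognormal
    factor (CV ``profile.tau_cell_cv``) and its peak by an independent factor
    (CV ``profile.noise_cv``), reproducing the across-cell spread of weighted
    tau seen in real recordings.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_cells if n_cells is None else n_cells
    traces = []
    for i in range(n):
        tau_scale = float(_lognormal_factors(rng, profile.tau_cell_cv, 1)[0])
        peak_scale = float(_lognormal_factors(rng, profile.noise_cv, 1)[0])
        traces.append(generate_deactivation_trace(
            profile, config, rng=rng, tau_scale=tau_scale,
            peak_scale=peak_scale, cell_id=f"{profile.construct_id}-k{i:03d}"))
    return traces


# ---------------------------------------------------------------------------
# MTSEA potentiation pairs
# ---------------------------------------------------------------------------

def generate_mtsea_pair(profile: GroundTruthProfile, rng=None,
                        base_current_na: float = 1.0,
                        cell_id: str = "m000") -> MtseaMeasurement:
    """Simulate one control/MTSEA steady-state current pair.

    The potentiation ratio equals gamma_ratio / po_max times multiplicative
    lognormal noise (CV ``profile.noise_cv``); both currents are positive.
    The noise factor divides the ratio (equivalently, it multiplies the
    implied open probability with mean one), so the per-pair open-probability
    estimate is unbiased under the generating model.
    """
    rng = _as_rng(rng)
    i_control = base_current_na * float(_lognormal_factors(rng, profile.noise_cv, 1)[0])
    potentiation = profile.mtsea_potentiation / float(
        _lognormal_factors(rng, profile.noise_cv, 1)[0])
    return MtseaMeasurement(cell_id=cell_id, i_control=i_control,
                            i_mtsea=i_control * potentiation,
                            gamma_ratio=profile.gamma_ratio)


def generate_mtsea_panel(profile: GroundTruthProfile, n_cells: int,
                         rng=None) -> list[MtseaMeasurement]:
    rng = _as_rng(rng)
    return [generate_mtsea_pair(profile, rng=rng,
                                cell_id=f"{profile.construct_id}-m{i:03d}")
            for i in range(n_cells)]


# ---------------------------------------------------------------------------
# current-voltage families
# ---------------------------------------------------------------------------

def generate_iv_family(profile: GroundTruthProfile, config: SimulationConfig,
                       solution: str = "Na", rng=None,
                       cell_id: str = "iv000") -> IVFamily:
    """Simulate an agonist-evoked difference-current I-V family.

    Currents are chord-conductance linear in the driving force,
    ``g * (V - V_rev)``, with ``V_rev`` shifted by ``vrev_shift_ba`` in the
    Ba2+ solution, optional suppression of inward Ba2+ current, and additive
    Gaussian instrumentation noise.  Outward current is positive.
    """
    if solution not in ("Na", "Ba"):
        raise ValueError("solution must be 'Na' or 'Ba'")
    rng = _as_rng(config.seed if rng is None else rng)
    v = np.asarray(config.voltage_steps_mv, dtype=float)
    vrev = profile.vrev_na + (profile.vrev_shift_ba if solution == "Ba" else 0.0)
    i = profile.conductance * (v - vrev)
    if solution == "Ba" and profile.ba_inward_scale != 1.0:
        i = np.where(i < 0, i * profile.ba_inward_scale, i)
    if profile.iv_noise_sd > 0:
        i = i + rng.normal(0.0, profile.iv_noise_sd, v.size)
    return IVFamily(cell_id=cell_id, solution=solution,
                    voltages_mv=v, currents_na=i)


# ---------------------------------------------------------------------------
# beta-lactamase absorbance ramps
# ---------------------------------------------------------------------------

def generate_absorbance_series(rate_per_min: float, duration_min: float = 30.0,
                               noise_sd: float = 0.0, rng=None,
                               interval_min: float = 1.0,
                               offset: float = 0.05) -> pd.DataFrame:
    """Linear absorbance ramp read once per minute, plus Gaussian noise."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(rng)
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    a = offset + rate_per_min * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"time_min": t, "absorbance": a})


def generate_expression_wells(profile: GroundTruthProfile, rng=None,
                              wt_surface_rate: float = 2.0e-3,
                              total_rate: float = 4.0e-3,
                              n_wells: int = 3,
                              noise_sd: float = 2.0e-4) -> pd.DataFrame:
    """Simulate paired surface/total reporter wells for one construct.

    The construct's surface rate is the wild-type surface rate scaled by its
    ``surface_ratio``; total rates are shared, so the downstream ratio of
    ratios recovers ``surface_ratio``.
    """
    rng = _as_rng(rng)
    frames = []
    for compartment, rate in (("surface", wt_surface_rate * profile.surface_ratio),
                              ("total", total_rate)):
        for w in range(n_wells):
            df = generate_absorbance_series(rate, noise_sd=noise_sd, rng=rng)
            df.insert(0, "well_id", f"{profile.construct_id}-{compartment[0]}{w}")
            df.insert(1, "compartment", compartment)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "construct_id", profile.construct_id)
    return out


# ---------------------------------------------------------------------------
# full panels
# ---------------------------------------------------------------------------

def generate_variant_panel(profiles: Iterable[GroundTruthProfile],
                           config: SimulationConfig,
                           rng=None,
                           out_dir: Optional[str | Path] = None) -> dict:
    """Compose all five generators into a per-variant dataset.

    Returns a dict of tidy DataFrames keyed ``cr_series``, ``traces``,
    ``mtsea``, ``iv`` and ``expression`` matching the on-disk CSV schemas;
    when ``out_dir`` is given each table is also written there.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    cr_rows, trace_rows, mtsea_rows, iv_rows, expr_frames = [], [], [], [], []
    for profile in profiles:
        for mode, ligand in (("agonist", "glutamate"), ("agonist", "glycine"),
                             ("inhibitor", "Mg")):
            for s in generate_concentration_response(profile, config, mode,
                                                     ligand, rng=rng):
                for c, r in zip(s.concentrations_um, s.responses_pct):
                    cr_rows.append((s.cell_id, s.construct_id, s.ligand, c, r))
        for trace in generate_deactivation_panel(profile, config, rng=rng):
            for t, i in zip(trace.time_ms, trace.current):
                trace_rows.append((trace.construct_id, trace.cell_id, t, i))
        for m in generate_mtsea_panel(profile, config.n_cells, rng=rng):
            mtsea_rows.append((profile.construct_id, m.cell_id,
                               m.i_control, m.i_mtsea))
        for k in range(config.n_cells):
            for solution in ("Na", "Ba"):
                fam = generate_iv_family(profile, config, solution, rng=rng,
                                         cell_id=f"{profile.construct_id}-iv{k:03d}")
                for v, i in zip(fam.voltages_mv, fam.currents_na):
                    iv_rows.append((profile.construct_id, fam.cell_id,
                                    solution, v, i))
        expr_frames.append(generate_expression_wells(profile, rng=rng))

    panel = {
        "cr_series": pd.DataFrame(cr_rows, columns=[
            "cell_id", "construct_id", "ligand", "concentration_uM",
            "response_pct"]),
        "traces": pd.DataFrame(trace_rows, columns=[
            "construct_id", "cell_id", "time_ms", "current_pA"]),
        "mtsea": pd.DataFrame(mtsea_rows, columns=[
            "construct_id", "cell_id", "i_control_nA", "i_mtsea_nA"]),
        "iv": pd.DataFrame(iv_rows, columns=[
            "construct_id", "cell_id", "solution", "voltage_mV", "current_nA"]),
        "expression": pd.concat(expr_frames, ignore_index=True),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in panel.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return panel


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _wt_2a() -> GroundTruthProfile:
    return GroundTruthProfile(
        construct_id="WT GluN1/2A", ec50_glu=3.5, ec50_gly=1.2,
        ic50_mg=19.0, po_max=0.24,
        tau_fast=30.0, tau_slow=100.0, frac_fast=0.8,   # tau_w = 44 ms
        peak_current=153.0, surface_ratio=1.0, ph_ratio=0.43,
        vrev_shift_ba=12.1)


def _wt_2b() -> GroundTruthProfile:
    return GroundTruthProfile(
        construct_id="WT GluN1/2B", ec50_glu=1.2, ec50_gly=0.39,
        ic50_mg=22.0, po_max=0.033,
        tau_fast=262.0, tau_slow=1048.0, frac_fast=2.0 / 3.0,  # tau_w = 524 ms
        peak_current=55.0, surface_ratio=1.0, ph_ratio=0.16,
        vrev_shift_ba=12.1)


def _gof_2a() -> GroundTruthProfile:
    # modelled on a strong gain-of-function pore variant: higher agonist
    # potency and open probability, slower deactivation, positive Ba2+ shift
    return GroundTruthProfile(
        construct_id="GoF GluN2A-like", ec50_glu=0.53, ec50_gly=0.26,
        ic50_mg=33.0, po_max=0.9,
        tau_fast=500.0, tau_slow=1500.0, frac_fast=0.609,  # tau_w ~ 891 ms
        peak_current=43.0, surface_ratio=1.2, ph_ratio=0.82,
        vrev_shift_ba=16.1)


def _lof_2a() -> GroundTruthProfile:
    # modelled on a loss-of-function variant: lower potency and open
    # probability, faster deactivation
    return GroundTruthProfile(
        construct_id="LoF GluN1-like", ec50_glu=8.6, ec50_gly=2.0,
        ic50_mg=21.0, po_max=0.046,
        tau_fast=15.0, tau_slow=55.0, frac_fast=0.8,  # tau_w = 23 ms
        peak_current=191.0, surface_ratio=0.45, ph_ratio=0.21,
        vrev_shift_ba=12.1)


PRESETS: dict[str, GroundTruthProfile] = {}


def get_preset(name: str, **overrides) -> GroundTruthProfile:
    """Fresh copy of a named preset, optionally with fields overridden."""
    factories = {
        "WT-GluN1/2A": _wt_2a, "WT GluN1/2A": _wt_2a,
        "WT-GluN1/2B": _wt_2b, "WT GluN1/2B": _wt_2b,
        "GoF-GluN2A-like": _gof_2a, "LoF-GluN1-like": _lof_2a,
    }
    if name not in factories:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(set(factories))}")
    profile = factories[name]()
    return replace(profile, **overrides) if overrides else profile


for _name in ("WT-GluN1/2A", "WT-GluN1/2B", "GoF-GluN2A-like", "LoF-GluN1-like"):
    PRESETS[_name] = get_preset(_name)
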