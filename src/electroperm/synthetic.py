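"""Synthetic raw-data generators emulating the experimental inputs.

Every generator is the exact inverse of its analysis model at zero noise,
so the full pipeline is testable end to end without any measured data:

* monolayer dye-uptake traces: single-exponential uptake with group-specific
  resealing time constants and plateaus (urothelial cancer lines T24 and
  UM-UC-3 vs normal lines SV-HUC-1 and HBLAK, at 0/2/5 mM Ca2+ and three
  field levels);
* spheroid datasets: per-spheroid mean cell size, final dye uptake
  calibrated to a target Pearson correlation with size, and saturating
  projected-area swelling traces;
* morphometry tables: lognormal cell-size populations for monolayer ROIs
  and tissue-microarray cores (cancer cells larger than normal);
* AFM force maps: 5x5 grids of Hertzian approach curves whose underlying
  modulus decays exponentially to a plateau after exposure.

Sizes, resealing time constants and plateaus are positive, right-skewed
biological quantities and are drawn lognormal (parameterized by arithmetic
mean and CV); trace noise is additive Gaussian.  Entries flagged
``paper=False`` in the group tables are interpolated defaults for conditions
whose values were not reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .mechanics import ForceCurve, hertz_force, solve_decay_from_losses
from .traces import FluorescenceTrace

__all__ = [
    "GeneratorConfig",
    "SpheroidDataset",
    "ForceMapSeries",
    "generate_uptake_traces",
    "generate_spheroid_dataset",
    "generate_swelling_traces",
    "generate_morphometry",
    "generate_force_maps",
    "MONOLAYER_GROUPS",
    "SPHEROID_GROUPS",
    "STIFFNESS_GROUPS",
]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draw(s) with the given arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


# -- monolayer dye-uptake group table ---------------------------------------
# tau_s: resealing time constant; f_final: mean baseline-subtracted
# fluorescence (a.u.) at the end of the 180-s acquisition, at 11.5 kV/cm.
# The f_final scale is anchored at SV-HUC-1 = 100 per Ca2+ condition; cancer
# cell entries encode the reported fold differences (e.g. T24 6.1x SV-HUC-1
# at 5 mM).  paper=False marks interpolated values.
MONOLAYER_GROUPS: dict[tuple[str, float], dict] = {
    ("T24", 0.0): {"tau_s": 130.0, "f_final": 510.0, "paper": True},
    ("T24", 2.0): {"tau_s": 84.0, "f_final": 480.0, "paper": True},
    ("T24", 5.0): {"tau_s": 86.0, "f_final": 610.0, "paper": True},
    ("UM-UC-3", 0.0): {"tau_s": 115.0, "f_final": 390.0, "paper": True},
    ("UM-UC-3", 2.0): {"tau_s": 75.0, "f_final": 430.0, "paper": True},
    ("UM-UC-3", 5.0): {"tau_s": 75.0, "f_final": 450.0, "paper": True},
    ("SV-HUC-1", 0.0): {"tau_s": 70.0, "f_final": 100.0, "paper": False},
    ("SV-HUC-1", 2.0): {"tau_s": 62.0, "f_final": 100.0, "paper": False},
    ("SV-HUC-1", 5.0): {"tau_s": 60.0, "f_final": 100.0, "paper": False},
    ("HBLAK", 0.0): {"tau_s": 75.0, "f_final": 120.0, "paper": False},
    ("HBLAK", 2.0): {"tau_s": 68.0, "f_final": 200.0, "paper": False},
    ("HBLAK", 5.0): {"tau_s": 65.0, "f_final": 127.0, "paper": False},
}

#: Uptake scaling at the lower field levels (kV/cm); resealing tau is
#: field-independent.  11.5 -> 10 kV/cm is a 1.2-2x reduction, 8 kV/cm ~3x.
FIELD_SCALE: dict[float, float] = {11.5: 1.0, 10.0: 0.6, 8.0: 0.33}

# -- spheroid group table -----------------------------------------------------
# mean_cell_area_um2 drives the size-uptake correlation; swell_pct is the
# percent projected-area increase 10 min post-exposure (0 mM Ca2+);
# area0_um2 the baseline projected spheroid area.  Entries without reported
# values are marked paper=False.
SPHEROID_GROUPS: dict[str, dict] = {
    "SV-HUC-1": {"mean_cell_area_um2": 90.0, "swell_pct": 12.0, "area0_um2": 2.44e5,
                 "tau_uptake_s": 100.0, "paper_swell": True},
    "RT4": {"mean_cell_area_um2": 115.0, "swell_pct": 42.0, "area0_um2": 2.0e5,
            "tau_uptake_s": 150.0, "paper_swell": True},
    "PDO-154": {"mean_cell_area_um2": 105.0, "swell_pct": 14.0, "area0_um2": 1.8e5,
                "tau_uptake_s": 140.0, "paper_swell": True},
    "PDO-270": {"mean_cell_area_um2": 125.0, "swell_pct": 17.0, "area0_um2": 1.9e5,
                "tau_uptake_s": 140.0, "paper_swell": False},
    "PDO-319": {"mean_cell_area_um2": 100.0, "swell_pct": 21.0, "area0_um2": 1.30e5,
                "tau_uptake_s": 140.0, "paper_swell": True},
}

# -- stiffness-decay group table (0 mM Ca2+) ---------------------------------
# (plateau fraction, decay constant in min) solved from the two reported
# percent losses of initial stiffness; baseline modulus back-computed from
# the reported 10-min modulus and the model's 10-min value.
_P_RT4, _TAU_RT4 = solve_decay_from_losses(50.0, 4.0, 59.0, 10.0)
_P_SV, _TAU_SV = solve_decay_from_losses(26.0, 4.0, 29.0, 10.0)
STIFFNESS_GROUPS: dict[str, dict] = {
    "RT4": {
        "plateau_fraction": _P_RT4,
        "tau_decay_min": _TAU_RT4,
        "baseline_pa": 401.8 / (_P_RT4 + (1 - _P_RT4) * math.exp(-10.0 / _TAU_RT4)),
    },
    "SV-HUC-1": {
        "plateau_fraction": _P_SV,
        "tau_decay_min": _TAU_SV,
        "baseline_pa": 1218.5 / (_P_SV + (1 - _P_SV) * math.exp(-10.0 / _TAU_SV)),
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all generators.

    Monolayer acquisition: one frame every 3 s for 180 s, pulses delivered
    10 s in, ~50 a.u. pre-exposure baseline, per-trace noise 5% of the
    plateau, between-replicate CV 15%.  Spheroid acquisition: one frame
    every 10 s; exposure 30 s after acquisition start and a 10-min
    post-exposure window.  Correlation target r = 0.36 at n = 45.
    """

    seed: int = 0
    # monolayer acquisition
    sampling_interval: float = 3.0
    duration: float = 180.0
    exposure_time: float = 10.0
    baseline: float = 50.0
    trace_noise_sd: float = 0.05  # fraction of the plateau
    replicate_cv: float = 0.15
    # spheroid acquisition
    spheroid_sampling_interval: float = 10.0
    spheroid_exposure_time: float = 30.0
    spheroid_window: float = 600.0  # post-exposure observation, s
    tau_swell_s: float = 180.0
    swell_cv: float = 0.10
    swell_trace_noise: float = 0.005  # fraction of baseline area
    target_r: float = 0.36
    correlation_noise_scale: float = 1.0
    cell_area_cv: float = 0.12
    # morphometry
    monolayer_area_um2: dict = dc_field(
        default_factory=lambda: {"T24": 720.0, "UM-UC-3": 720.0, "SV-HUC-1": 400.0, "HBLAK": 400.0}
    )
    tma_area_um2: dict = dc_field(
        default_factory=lambda: {"normal": 90.7, "primary_tumor": 111.8, "lymph_node_met": 111.8}
    )
    tma_form_factor: dict = dc_field(
        default_factory=lambda: {"normal": 0.804, "primary_tumor": 0.815, "lymph_node_met": 0.815}
    )
    n_rois: int = 18
    n_tmas: int = 9
    tma_class_cores: dict = dc_field(
        default_factory=lambda: {"normal": 47, "primary_tumor": 66, "lymph_node_met": 56}
    )
    # AFM
    spring_constant: float = 0.04
    tip_radius: float = 1.0e-6
    poisson_ratio: float = 0.5
    map_cv: float = 0.10  # multiplicative modulus noise within a map
    spheroid_modulus_cv: float = 0.15
    deflection_noise_m: float = 1.0e-9

    @property
    def spheroid_duration(self) -> float:
        return self.spheroid_exposure_time + self.spheroid_window

    @property
    def spheroid_t_eval(self) -> float:
        """Evaluation time (s from acquisition start), 10 min post-exposure."""
        return self.spheroid_exposure_time + self.spheroid_window


DEFAULT_CONFIG = GeneratorConfig()


# ---------------------------------------------------------------------------
# monolayer uptake traces
# ---------------------------------------------------------------------------

def _uptake_values(times, t0, amplitude, tau):
    out = np.zeros_like(times)
    post = times >= t0
    out[post] = amplitude * -np.expm1(-(times[post] - t0) / tau)
    return out


def generate_uptake_traces(
    config: GeneratorConfig = DEFAULT_CONFIG,
    groups: list[tuple[str, float, float]] | None = None,
    n_per_group: int = 20,
    seed: int | None = None,
) -> list[FluorescenceTrace]:
    """Monolayer dye-uptake traces for (cell_line, ca_mM, field_kv_cm) groups.

    Per replicate, tau and the end-of-acquisition uptake are drawn lognormal
    around the group defaults (CV ``replicate_cv``); the emitted trace is a
    constant pre-exposure baseline plus the saturating-exponential model
    plus Gaussian noise of ``trace_noise_sd`` x plateau.
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be > 0")
    if groups is None:
        groups = [(cl, ca, 11.5) for (cl, ca) in MONOLAYER_GROUPS]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = np.arange(0.0, config.duration + config.sampling_interval / 2, config.sampling_interval)
    t0 = config.exposure_time
    traces = []
    for cell_line, ca, field_kv in groups:
        try:
            params = MONOLAYER_GROUPS[(cell_line, float(ca))]
        except KeyError:
            raise KeyError(f"no group defaults for ({cell_line}, {ca} mM)") from None
        try:
            scale = FIELD_SCALE[float(field_kv)]
        except KeyError:
            raise KeyError(f"no field scaling for {field_kv} kV/cm") from None
        f_final = params["f_final"] * scale
        for i in range(n_per_group):
            tau = float(_lognormal(rng, params["tau_s"], config.replicate_cv))
            f_i = float(_lognormal(rng, f_final, config.replicate_cv))
            amplitude = f_i / -math.expm1(-(times[-1] - t0) / tau)
            values = config.baseline + _uptake_values(times, t0, amplitude, tau)
            if config.trace_noise_sd > 0:
                values = values + rng.normal(0.0, config.trace_noise_sd * amplitude, times.shape)
            traces.append(
                FluorescenceTrace(
                    times=times.copy(),
                    values=values,
                    exposure_time=t0,
                    meta={
                        "trace_id": f"{cell_line}_{ca:g}mM_{field_kv:g}kVcm_r{i:02d}",
                        "kind": "uptake",
                        "cell_line": cell_line,
                        "ca_mM": float(ca),
                        "field_level": float(field_kv),
                        "replicate_id": i,
                        "true_tau_s": tau,
                        "true_amplitude": amplitude,
                    },
                )
            )
    return traces


# ---------------------------------------------------------------------------
# spheroid dataset: sizes + uptake + swelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroidDataset:
    """Per-spheroid sizes/uptake table plus the underlying traces."""

    sizes: pd.DataFrame  # spheroid_id, group, mean_cell_area_um2, final_fluorescence
    uptake_traces: list[FluorescenceTrace]
    swelling_traces: list[FluorescenceTrace]


def _mixture_area_sd(config: GeneratorConfig) -> float:
    """Population SD of per-spheroid mean cell area over the group mixture."""
    means = np.array([g["mean_cell_area_um2"] for g in SPHEROID_GROUPS.values()])
    variances = (means * config.cell_area_cv) ** 2
    grand = means.mean()
    return math.sqrt(float(np.mean(variances + means**2) - grand**2))


def generate_swelling_traces(
    group: str,
    n: int = 10,
    config: GeneratorConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> list[FluorescenceTrace]:
    """Saturating projected-area swelling traces for one spheroid group.

    a(t) = a0 (1 + g (1 - exp(-(t - t0)/tau_swell))) for t past exposure,
    with g calibrated per spheroid so the percent change 10 min
    post-exposure matches the group target in expectation.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    params = SPHEROID_GROUPS[group]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = config.spheroid_sampling_interval
    times = np.arange(0.0, config.spheroid_duration + dt / 2, dt)
    t0 = config.spheroid_exposure_time
    sat = -math.expm1(-config.spheroid_window / config.tau_swell_s)
    traces = []
    for i in range(n):
        a0 = float(_lognormal(rng, params["area0_um2"], config.cell_area_cv))
        g_i = float(_lognormal(rng, params["swell_pct"] / 100.0 / sat, config.swell_cv))
        growth = np.zeros_like(times)
        post = times >= t0
        growth[post] = g_i * -np.expm1(-(times[post] - t0) / config.tau_swell_s)
        values = a0 * (1.0 + growth)
        if config.swell_trace_noise > 0:
            values = values + rng.normal(0.0, config.swell_trace_noise * a0, times.shape)
        traces.append(
            FluorescenceTrace(
                times=times.copy(),
                values=values,
                exposure_time=t0,
                meta={
                    "trace_id": f"{group}_area_r{i:02d}",
                    "kind": "area",
                    "cell_line": group,
                    "ca_mM": 0.0,
                    "replicate_id": i,
                    "true_swell_pct": 100.0 * g_i * sat,
                },
            )
        )
    return traces


def generate_spheroid_dataset(
    config: GeneratorConfig = DEFAULT_CONFIG,
    n: int = 45,
    seed: int | None = None,
) -> SpheroidDataset:
    """Spheroid-level dataset: mean cell sizes, dye uptake and swelling.

    ``n`` spheroids are split evenly over the five groups.  Final
    fluorescence is linear in mean cell area plus Gaussian noise whose SD is
    solved from the target Pearson correlation (default r = 0.36), so the
    population correlation matches the target; ``correlation_noise_scale``
    rescales that noise (0 gives a deterministic line, sample r = 1).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(config.target_r) >= 1.0:
        raise ValueError("target correlation must satisfy |r| < 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    group_names = list(SPHEROID_GROUPS)
    counts = [n // len(group_names)] * len(group_names)
    for j in range(n - sum(counts)):
        counts[j] += 1

    beta = 1.0  # a.u. per um^2; arbitrary fluorescence scale
    sigma_area = _mixture_area_sd(config)
    sigma_eps = (
        beta * sigma_area * math.sqrt(1.0 / config.target_r**2 - 1.0)
        * config.correlation_noise_scale
    )

    rows, uptake_traces = [], []
    dt = config.spheroid_sampling_interval
    times = np.arange(0.0, config.spheroid_duration + dt / 2, dt)
    t0 = config.spheroid_exposure_time
    sid = 0
    for group, count in zip(group_names, counts):
        params = SPHEROID_GROUPS[group]
        for _ in range(count):
            area = float(_lognormal(rng, params["mean_cell_area_um2"], config.cell_area_cv))
            fluor = beta * area + (rng.normal(0.0, sigma_eps) if sigma_eps > 0 else 0.0)
            rows.append(
                {
                    "spheroid_id": f"sph{sid:03d}",
                    "group": group,
                    "mean_cell_area_um2": area,
                    "final_fluorescence": fluor,
                }
            )
            tau_u = params["tau_uptake_s"]
            amp = max(fluor, 0.01 * params["mean_cell_area_um2"]) / -math.expm1(
                -config.spheroid_window / tau_u
            )
            values = config.baseline + _uptake_values(times, t0, amp, tau_u)
            if config.trace_noise_sd > 0:
                values = values + rng.normal(0.0, config.trace_noise_sd * amp, times.shape)
            uptake_traces.append(
                FluorescenceTrace(
                    times=times.copy(),
                    values=values,
                    exposure_time=t0,
                    meta={
                        "trace_id": f"sph{sid:03d}_uptake",
                        "kind": "uptake",
                        "cell_line": group,
                        "ca_mM": 2.0,
                        "replicate_id": sid,
                    },
                )
            )
            sid += 1
    swelling = []
    for group, count in zip(group_names, counts):
        swelling.extend(
            generate_swelling_traces(group, count, config, seed=int(rng.integers(2**31)))
        )
    return SpheroidDataset(pd.DataFrame(rows), uptake_traces, swelling)


# ---------------------------------------------------------------------------
# morphometry tables
# ---------------------------------------------------------------------------

def _sample_form_factor(rng, mean, sd, size):
    """Beta-distributed form factors on (0, 1] with the given mean and sd."""
    if not (0 < mean <= 1):
        raise ValueError("form factor mean must be in (0, 1]")
    if sd == 0:
        return np.full(size, mean)
    var = sd**2
    conc = mean * (1 - mean) / var - 1.0
    a, b = mean * conc, (1 - mean) * conc
    return np.clip(rng.beta(a, b, size=size), 1e-6, 1.0)


def generate_morphometry(
    config: GeneratorConfig = DEFAULT_CONFIG,
    kind: str = "monolayer",
    seed: int | None = None,
    form_factor_sd: float = 0.05,
    cells_per_core: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-cell morphometry records; returns (records, weights-or-None).

    ``monolayer``: 18 ROIs per cell line, 40-80 cells each, lognormal areas
    around the line means (cancer lines 1.8x normal).  ``tma``: 9 arrays
    with the class core counts split deterministically across arrays; the
    weights table gives cores per array.  Perimeters are derived from area
    and a Beta-sampled form factor via perimeter = sqrt(4 pi area / FF), so
    forcing FF = 1 yields exact circles.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if kind == "monolayer":
        rows = []
        for cell_line, mean_area in config.monolayer_area_um2.items():
            for roi in range(config.n_rois):
                n_cells = int(rng.integers(40, 81))
                roi_mean = float(_lognormal(rng, mean_area, 0.08))
                areas = _lognormal(rng, roi_mean, 0.25, size=n_cells)
                ffs = _sample_form_factor(rng, 0.81, form_factor_sd, n_cells)
                perims = np.sqrt(4.0 * np.pi * areas / ffs)
                aspect = _lognormal(rng, 1.5, 0.15, size=n_cells)
                major = 2.0 * np.sqrt(areas * aspect / np.pi)
                minor = 2.0 * np.sqrt(areas / (aspect * np.pi))
                for c in range(n_cells):
                    rows.append(
                        {
                            "roi_id": f"{cell_line}_roi{roi:02d}",
                            "cell_id": f"{cell_line}_roi{roi:02d}_c{c:03d}",
                            "cell_line": cell_line,
                            "area_um2": areas[c],
                            "perimeter_um": perims[c],
                            "major_um": major[c],
                            "minor_um": minor[c],
                        }
                    )
        return pd.DataFrame(rows), None
    if kind == "tma":
        rows, weights = [], {f"tma{t:d}": 0 for t in range(1, config.n_tmas + 1)}
        for cls, total_cores in config.tma_class_cores.items():
            base, extra = divmod(total_cores, config.n_tmas)
            mean_area = config.tma_area_um2[cls]
            mean_ff = config.tma_form_factor[cls]
            for t in range(config.n_tmas):
                tma_id = f"tma{t + 1:d}"
                n_cores = base + (1 if t < extra else 0)
                weights[tma_id] += n_cores
                for core in range(n_cores):
                    core_mean = float(_lognormal(rng, mean_area, 0.05))
                    areas = _lognormal(rng, core_mean, 0.30, size=cells_per_core)
                    ffs = _sample_form_factor(rng, mean_ff, form_factor_sd, cells_per_core)
                    perims = np.sqrt(4.0 * np.pi * areas / ffs)
                    for c in range(cells_per_core):
                        rows.append(
                            {
                                "tma_id": tma_id,
                                "core_id": f"{tma_id}_{cls}_core{core:02d}",
                                "tissue_class": cls,
                                "cell_id": f"{tma_id}_{cls}_core{core:02d}_c{c:03d}",
                                "area_um2": areas[c],
                                "perimeter_um": perims[c],
                            }
                        )
        wdf = pd.DataFrame(
            [{"tma_id": k, "n_cores": v} for k, v in weights.items()]
        )
        return pd.DataFrame(rows), wdf
    raise ValueError(f"unknown morphometry kind: {kind!r}")


# ---------------------------------------------------------------------------
# AFM force maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceMapSeries:
    """Force maps of one spheroid over post-exposure timepoints.

    ``timepoints_min[0]`` must be 0 (the pre-exposure baseline map);
    ``maps[i]`` holds the 25 approach curves of the map at timepoint i.
    """

    spheroid_id: str
    group: str
    timepoints_min: np.ndarray
    maps: list[list[ForceCurve]]
    true_baseline_pa: float


def _hertz_curve(
    rng: np.random.Generator | None,
    young_modulus: float,
    config: GeneratorConfig,
    contact_z: float,
    n_pre: int = 60,
    n_post: int = 120,
    delta_max_frac: float = 0.8,
) -> ForceCurve:
    """One synthetic approach curve with the given true modulus."""
    delta = np.linspace(0.0, delta_max_frac * config.tip_radius, n_post + 1)[1:]
    force = hertz_force(delta, young_modulus, config.tip_radius, config.poisson_ratio)
    defl_post = force / config.spring_constant
    z_post = contact_z + delta + defl_post
    z_pre = np.linspace(contact_z - 1.0e-6, contact_z, n_pre)
    z = np.concatenate([z_pre, z_post])
    defl = np.concatenate([np.zeros(n_pre), defl_post])
    if rng is not None and config.deflection_noise_m > 0:
        defl = defl + rng.normal(0.0, config.deflection_noise_m, z.shape)
    return ForceCurve(
        piezo_displacement=z,
        deflection=defl,
        spring_constant=config.spring_constant,
        tip_radius=config.tip_radius,
        poisson_ratio=config.poisson_ratio,
        meta={"true_young_modulus": young_modulus, "true_contact": contact_z},
    )


def generate_force_maps(
    group: str,
    timepoints_min=(0.0, 1.0, 4.0, 7.0, 10.0),
    n_spheroids: int = 1,
    config: GeneratorConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    noiseless: bool = False,
    grid: int = 5,
) -> list[ForceMapSeries]:
    """Synthetic AFM force-map time series for one spheroid group.

    The true modulus follows E(t) = E0 (p + (1-p) exp(-t/tau_decay)); each
    timepoint yields a ``grid x grid`` map of Hertzian approach curves with
    multiplicative map-level modulus noise, randomized contact points and
    additive deflection noise.  ``noiseless=True`` disables every noise
    source (fixed E0, fixed contact), giving exact model output.
    """
    params = STIFFNESS_GROUPS[group]
    if params["baseline_pa"] <= 0:
        raise ValueError("baseline modulus must be > 0")
    timepoints = np.asarray(timepoints_min, dtype=float)
    if timepoints[0] != 0.0:
        raise ValueError("timepoints must start at 0 (pre-exposure baseline)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p, tau = params["plateau_fraction"], params["tau_decay_min"]
    out = []
    for s in range(n_spheroids):
        e0 = (
            params["baseline_pa"]
            if noiseless
            else float(_lognormal(rng, params["baseline_pa"], config.spheroid_modulus_cv))
        )
        maps = []
        for t in timepoints:
            e_true = e0 * (p + (1.0 - p) * math.exp(-t / tau))
            curves = []
            for _ in range(grid * grid):
                if noiseless:
                    e_i, zc, curve_rng = e_true, 1.0e-6, None
                else:
                    e_i = float(_lognormal(rng, e_true, config.map_cv))
                    zc = float(rng.uniform(0.8e-6, 1.2e-6))
                    curve_rng = rng
                curves.append(_hertz_curve(curve_rng, e_i, config, zc))
            maps.append(curves)
        out.append(
            ForceMapSeries(
                spheroid_id=f"{group}_sph{s:02d}",
                group=group,
                timepoints_min=timepoints,
                maps=maps,
                true_baseline_pa=e0,
            )
        )
    return out
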