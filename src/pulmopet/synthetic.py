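"""Synthetic dynamic-PET phantoms with known ground truth.

Every downstream stage — VOI morphology, TAC extraction, model fitting,
cohort statistics — is validated against data generated here, because real
patient PET is not redistributable.  The generator emulates:

* a gamma-variate right-ventricle bolus input with an optional
  recirculation plateau, low noise and a single clear peak;
* lobe tissue TACs produced by the *analytic* convolution solution of the
  compartment model plus volume-fraction mixing (independent of the
  discrete fitting recursion, so it can serve as its oracle);
* a small voxel grid holding ellipsoidal lung lobes, a right ventricle
  with a hot cavity inside a cooler wall, vessel tubes crossing the upper
  lobes, and air pockets placed deep in the lobe interiors;
* the 24-frame acquisition (14x5 s, 3x10 s, 3x20 s, 4x30 s) starting 30 s
  after injection start, with frame values computed as time-averages of
  the continuous signal over each frame;
* a patient cohort (age, sex, weight, BMI) with configurable subgroup
  effects on pulmonary blood flow.

Noise is Gaussian with standard deviation proportional to
sqrt(signal / frame duration), mimicking reconstructed-PET count
statistics without modelling reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .frames import PAPER_PROTOCOL, FrameSchedule, make_frame_schedule
from .kinetics import KineticParams, forward_analytic
from .tac import DynamicImage, TimeActivityCurve
from .voi import LOBE_NAMES, RV_NAME, VESSEL_NAMES, BinaryMask, erode

__all__ = [
    "InputFunctionSpec",
    "GroundTruth",
    "PatientRecord",
    "PhantomConfig",
    "CohortEffects",
    "make_frame_schedule",
    "generate_input_function",
    "simulate_lobe_tac",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_LOBE_KINETICS",
]

ALL_LOBES_LABEL = "ALL"

#: Per-lobe generating kinetics (reported units: K1 mL/min/cm^3, k2 /min).
#: Flow is lowest in the right lower lobe and much higher in the upper
#: lobes; the partition coefficient K1/k2 sits near 0.2 everywhere, the
#: air fraction near 11% and the blood fraction at a few percent.
DEFAULT_LOBE_KINETICS: dict[str, dict[str, float]] = {
    "LLL": {"k1_per_min": 1.09, "k2_per_min": 4.15, "va": 0.11, "vb": 0.013, "j": 0},
    "RLL": {"k1_per_min": 0.98, "k2_per_min": 4.05, "va": 0.11, "vb": 0.031, "j": 1},
    "RML": {"k1_per_min": 1.90, "k2_per_min": 10.9, "va": 0.13, "vb": 0.021, "j": 1},
    "LUL": {"k1_per_min": 1.54, "k2_per_min": 8.81, "va": 0.11, "vb": 0.019, "j": 1},
    "RUL": {"k1_per_min": 2.66, "k2_per_min": 15.0, "va": 0.11, "vb": 0.032, "j": 2},
}


def _params_from_reported(d: dict[str, float]) -> KineticParams:
    return KineticParams(
        k1_per_s=d["k1_per_min"] / 60.0,
        k2_per_s=d["k2_per_min"] / 60.0,
        va=d.get("va", 0.0),
        vb=d.get("vb", 0.0),
        delay_s=int(d.get("j", 0)),
    )


@dataclass(frozen=True)
class InputFunctionSpec:
    """Shape of the right-ventricle bolus input.

    The noiseless shape is a gamma-variate starting at ``onset_s``,
    peaking at ``peak_time_s``, plus an optional recirculation plateau of
    ``tail_fraction`` of the peak rising after the peak.  The final
    noiseless curve is rescaled so its maximum equals ``peak_value``.
    """

    peak_time_s: float = 45.0
    peak_value: float = 90.0       # kBq/mL
    onset_s: float = 25.0
    sharpness: float = 4.0         # gamma-variate alpha; larger = narrower bolus
    tail_fraction: float = 0.12    # recirculation plateau as a fraction of peak
    tail_rise_s: float = 40.0
    noise_sd: float = 0.5          # kBq/mL

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not (0 <= self.tail_fraction < 1):
            raise ValueError("tail fraction must lie in [0, 1)")
        if not (0 <= self.onset_s < self.peak_time_s):
            raise ValueError("onset must precede the peak")
        if self.sharpness <= 0 or self.peak_value <= 0:
            raise ValueError("sharpness and peak value must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the phantom was generated from."""

    lobe_params: dict[str, KineticParams]
    input_tac: TimeActivityCurve
    air_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "lobes": {
                name: {
                    "K1_mL_min_cm3": p.k1_per_min,
                    "k2_per_min": p.k2_per_min,
                    "V_A": p.va,
                    "V_B": p.vb,
                    "j_s": p.delay_s,
                }
                for name, p in self.lobe_params.items()
            },
            "air_fraction": self.air_fraction,
            "input": {
                "times_s": self.input_tac.times_s.tolist(),
                "values": self.input_tac.values.tolist(),
            },
        }


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient with known per-lobe blood flow."""

    id: str
    sex: str                      # "female" | "male"
    age: float                    # years
    weight: float                 # kg
    height_m: float
    pbf: dict[str, float] = field(default_factory=dict)  # lobe -> K1 mL/min/cm^3

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.age <= 0 or self.weight <= 0 or self.height_m <= 0:
            raise ValueError("age, weight and height must be positive")

    @property
    def bmi(self) -> float:
        return self.weight / self.height_m**2


def generate_input_function(
    spec: InputFunctionSpec,
    grid: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> TimeActivityCurve:
    """Sample the bolus input on a time grid.

    The curve is non-negative, zero at t = 0, unimodal before the
    recirculation plateau, and deterministic given the seed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0 or (len(grid) > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("time grid must start at 0 and increase strictly")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tau = (grid - spec.onset_s) / (spec.peak_time_s - spec.onset_s)
    tau = np.clip(tau, 0.0, None)
    alpha = spec.sharpness
    shape = tau**alpha * np.exp(alpha * (1.0 - tau))  # peaks at 1 when tau = 1
    post_peak = np.clip(grid - spec.peak_time_s, 0.0, None)
    shape = shape + spec.tail_fraction * (1.0 - np.exp(-post_peak / spec.tail_rise_s))
    peak = shape.max()
    if peak > 0:
        shape = shape * (spec.peak_value / peak)
    values = shape
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=len(grid))
        values = np.clip(values, 0.0, None)
        values[grid == 0.0] = 0.0
    kind = "uniform-1s" if _is_uniform_1s(grid) else "irregular"
    return TimeActivityCurve(grid, values, kind=kind, name="RV input")


def _is_uniform_1s(grid: np.ndarray) -> bool:
    return len(grid) > 1 and np.allclose(np.diff(grid), 1.0)


def simulate_lobe_tac(
    params: KineticParams,
    input_tac: TimeActivityCurve,
    dt: float = 0.05,
    out_times: np.ndarray | None = None,
) -> TimeActivityCurve:
    """Ground-truth lobe PET signal from the analytic convolution solution.

    Evaluates C_T = K1 * C_B(t - j) (x) exp(-k2 t) by fine quadrature and
    mixes it with the (delayed) blood signal via the volume fractions.
    Independent of the discrete fitting recursion; this is the oracle the
    fitter is tested against.
    """
    if params.va + params.vb >= 1.0:
        raise ValueError("V_A + V_B must be < 1 for signal synthesis")
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must lie in (0, 1] seconds")
    times = input_tac.times_s if out_times is None else np.asarray(out_times, float)
    ct = forward_analytic(
        params, input_tac.times_s, input_tac.values, out_times=times, dt=dt
    )
    tp, vp = input_tac.times_s, input_tac.values
    if tp[0] > 0:
        tp = np.concatenate([[0.0], tp])
        vp = np.concatenate([[0.0], vp])
    cb_shifted = np.interp(times - params.delay_s, tp, vp, left=0.0)
    values = params.vb * cb_shifted + params.tissue_weight * ct
    kind = "uniform-1s" if _is_uniform_1s(times) else "irregular"
    return TimeActivityCurve(times, values, kind=kind, name="lobe C_PET")


def _frame_average(
    fine_t: np.ndarray, fine_v: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Time-average of a continuous signal over each acquisition frame."""
    integral = np.concatenate(
        [[0.0], cumulative_trapezoid(fine_v, fine_t)]
    )
    start = np.interp(schedule.start_times_s, fine_t, integral)
    end = np.interp(schedule.end_times_s, fine_t, integral)
    return (end - start) / np.asarray(schedule.durations_s)


# ---------------------------------------------------------------------------
# Phantom geometry


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise of a synthetic phantom.

    The grid is deliberately small and the geometry simplified (ellipsoid
    lobes, spherical RV, cylindrical vessels): what downstream stages need
    is the topology — vessels crossing upper lobes, a hot RV cavity inside
    a cooler wall, air pockets deep inside lobes — not anatomy.
    """

    shape: tuple[int, int, int] = (48, 48, 72)
    voxel_size_mm: tuple[float, float, float] = (3.3, 3.3, 3.0)
    schedule_spec: tuple[tuple[int, float], ...] = PAPER_PROTOCOL
    start_s: float = 30.0
    lobe_kinetics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOBE_KINETICS.items()}
    )
    input_spec: InputFunctionSpec = InputFunctionSpec()
    air_fraction: float = 0.11     # zero-signal voxels deep inside each lobe
    noise_scale: float = 0.0       # sd = noise_scale * sqrt(signal / duration)
    include_vessels: bool = True
    rv_wall_activity_fraction: float = 0.25
    simulation_dt_s: float = 0.1


def _ellipsoid(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return acc <= 1.0


def _cylinder_z(shape, cx, cy, radius, z0, z1) -> np.ndarray:
    gx, gy = np.ogrid[0 : shape[0], 0 : shape[1]]
    disc = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[:, :, z0:z1] = disc[:, :, None]
    return out


def _phantom_masks(config: PhantomConfig) -> dict[str, BinaryMask]:
    """Lay out lobes, RV and vessels on the voxel grid."""
    nx, ny, nz = config.shape
    if min(nx, ny, nz) < 24:
        raise ValueError("phantom grid must be at least 24 voxels per axis")

    def frac(fx, fy, fz):
        return (fx * nx, fy * ny, fz * nz)

    masks: dict[str, np.ndarray] = {}
    # left lung (x < centre), two lobes; right lung, three lobes
    masks["LUL"] = _ellipsoid(config.shape, frac(0.28, 0.5, 0.70), frac(0.14, 0.22, 0.16))
    masks["LLL"] = _ellipsoid(config.shape, frac(0.28, 0.5, 0.32), frac(0.15, 0.24, 0.18))
    masks["RUL"] = _ellipsoid(config.shape, frac(0.72, 0.5, 0.72), frac(0.14, 0.22, 0.14))
    masks["RML"] = _ellipsoid(config.shape, frac(0.72, 0.5, 0.48), frac(0.13, 0.20, 0.10))
    masks["RLL"] = _ellipsoid(config.shape, frac(0.72, 0.5, 0.22), frac(0.15, 0.24, 0.14))
    # keep lobes disjoint in generation order (upper wins where they touch)
    taken = np.zeros(config.shape, dtype=bool)
    for name in LOBE_NAMES:
        masks[name] = masks[name] & ~taken
        taken |= masks[name]
    # right ventricle between the lungs, low in the chest
    rv_outer = _ellipsoid(config.shape, frac(0.5, 0.5, 0.30), frac(0.10, 0.12, 0.10))
    masks[RV_NAME] = rv_outer & ~taken
    # vessels: thin tubes running through the upper lobes
    if config.include_vessels:
        for name, fx in zip(VESSEL_NAMES, (0.24, 0.68, 0.32, 0.76)):
            tube = _cylinder_z(
                config.shape, fx * nx, 0.5 * ny, max(1.2, 0.03 * nx),
                int(0.55 * nz), int(0.92 * nz),
            )
            masks[name] = tube
    else:
        for name in VESSEL_NAMES:
            masks[name] = np.zeros(config.shape, dtype=bool)
    for name, arr in masks.items():
        if not arr.any() and name in LOBE_NAMES + (RV_NAME,):
            raise ValueError(f"phantom geometry error: mask {name!r} is empty")
    return {
        name: BinaryMask(arr, config.voxel_size_mm, name) for name, arr in masks.items()
    }


def generate_phantom(
    config: PhantomConfig = PhantomConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[DynamicImage, dict[str, BinaryMask], GroundTruth]:
    """Voxelise a dynamic phantom: image + masks + the generating truth.

    Frame values are time-averages of the continuous signal over each
    frame.  Voxels deep inside each lobe are re-assigned to air (zero
    signal) until roughly ``air_fraction`` of the lobe volume is air;
    vessel and RV-cavity voxels carry the blood signal; RV wall voxels a
    scaled-down copy of it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = make_frame_schedule(config.schedule_spec, start_s=config.start_s)
    masks = _phantom_masks(config)

    t_end = schedule.end_times_s[-1]
    fine_t = np.arange(0.0, t_end + config.simulation_dt_s, config.simulation_dt_s)
    input_tac = generate_input_function(config.input_spec, fine_t, rng)

    lobe_params = {
        name: _params_from_reported(config.lobe_kinetics[name]) for name in LOBE_NAMES
    }
    cb_frames = _frame_average(fine_t, input_tac.values, schedule)

    image = np.zeros(config.shape + (schedule.n_frames,), dtype=float)
    for name in LOBE_NAMES:
        lobe_tac = simulate_lobe_tac(
            lobe_params[name], input_tac, dt=config.simulation_dt_s
        )
        frames = _frame_average(fine_t, lobe_tac.values, schedule)
        mask = masks[name].data
        image[mask] = frames
        if config.air_fraction > 0:
            interior = erode(masks[name], 4).data
            n_air = int(round(config.air_fraction * mask.sum()))
            pool = np.flatnonzero(interior.ravel())
            if n_air > 0 and len(pool) > 0:
                chosen = rng.choice(pool, size=min(n_air, len(pool)), replace=False)
                flat = image.reshape(-1, schedule.n_frames)
                flat[chosen] = 0.0

    rv = masks[RV_NAME]
    # the cavity must stay below the percentile cut of the input-TAC rule
    # (a tenth of the RV) so the hot blood pool, not the wall, is selected
    cavity = erode(rv, 3).data
    if not cavity.any():
        raise ValueError(
            "phantom geometry error: the RV erodes away entirely on this "
            "grid; use at least ~40x40x56 voxels so a blood-pool cavity "
            "remains inside the ventricle wall"
        )
    wall = rv.data & ~cavity
    image[cavity] = cb_frames
    image[wall] = config.rv_wall_activity_fraction * cb_frames
    if config.include_vessels:
        for name in VESSEL_NAMES:
            image[masks[name].data] = cb_frames

    if config.noise_scale > 0:
        durations = np.asarray(schedule.durations_s)
        sd = config.noise_scale * np.sqrt(np.clip(image, 0.0, None) / durations)
        image = image + rng.normal(size=image.shape) * sd

    dyn = DynamicImage(image, schedule, config.voxel_size_mm)
    truth = GroundTruth(lobe_params, input_tac, air_fraction=config.air_fraction)
    return dyn, masks, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortEffects:
    """Subgroup effects on the all-lobes pulmonary blood flow.

    ``base_pbf`` is the population mean K1 (mL/min/cm^3); additive shifts
    apply to female patients and to patients aged >= 65; ``between_sd`` is
    the between-patient standard deviation.  With all shifts zero the
    subgroup PBF distributions are exchangeable.
    """

    base_pbf: float = 1.21
    female_shift: float = 0.0
    over65_shift: float = 0.0
    between_sd: float = 0.6
    lobe_scale: dict[str, float] = field(
        default_factory=lambda: {
            "LLL": 0.90, "RLL": 0.81, "RML": 1.57, "LUL": 1.27, "RUL": 2.20,
        }
    )

    def __post_init__(self) -> None:
        if self.between_sd < 0:
            raise ValueError("between-patient sd must be non-negative")


def generate_cohort(
    n: int = 103,
    effects: CohortEffects | None = None,
    seed: int | np.random.Generator = 0,
    n_female: int | None = None,
    age_mean: float = 64.8,
    age_sd: float = 9.33,
    age_range: tuple[float, float] = (30.0, 83.0),
    include_tacs: bool = False,
    noise_sd: float = 0.0,
) -> list[tuple[PatientRecord, dict[str, TimeActivityCurve]]]:
    """Draw a reproducible synthetic cohort.

    Each patient gets demographics (sex, age, weight, height / BMI) and a
    per-lobe ground-truth PBF built from the patient-level PBF and fixed
    lobe scale factors.  ``n_female`` fixes the sex split exactly (default:
    56 of 103, scaled to n).  With ``include_tacs`` the per-lobe measured
    TACs (analytic model + optional Gaussian noise, on the 1 s grid) are
    generated too; otherwise the TAC dict is empty, which keeps large
    statistical calibration runs cheap.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    effects = effects or CohortEffects()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_female is None:
        n_female = int(round(n * 56 / 103))
    if not (0 <= n_female <= n):
        raise ValueError("n_female must lie in [0, n]")
    sexes = ["female"] * n_female + ["male"] * (n - n_female)

    grid = np.arange(0.0, 281.0)
    cohort: list[tuple[PatientRecord, dict[str, TimeActivityCurve]]] = []
    for i, sex in enumerate(sexes):
        age = float(np.clip(rng.normal(age_mean, age_sd), *age_range))
        height = float(rng.normal(1.64 if sex == "female" else 1.78, 0.06))
        bmi = float(np.clip(rng.normal(27.0, 4.0), 17.0, 45.0))
        weight = bmi * height**2
        pbf_all = effects.base_pbf + rng.normal(0.0, effects.between_sd)
        if sex == "female":
            pbf_all += effects.female_shift
        if age >= 65:
            pbf_all += effects.over65_shift
        pbf_all = max(pbf_all, 0.05)
        pbf = {lobe: pbf_all * s for lobe, s in effects.lobe_scale.items()}
        pbf[ALL_LOBES_LABEL] = pbf_all
        record = PatientRecord(
            id=f"P{i:03d}", sex=sex, age=age, weight=weight, height_m=height, pbf=pbf
        )
        tacs: dict[str, TimeActivityCurve] = {}
        if include_tacs:
            input_tac = generate_input_function(InputFunctionSpec(), grid, rng)
            for lobe in LOBE_NAMES:
                base = DEFAULT_LOBE_KINETICS[lobe]
                params = KineticParams(
                    k1_per_s=pbf[lobe] / 60.0,
                    k2_per_s=pbf[lobe] / 60.0 / 0.2,  # partition coefficient 0.2
                    va=base["va"],
                    vb=base["vb"],
                    delay_s=int(base["j"]),
                )
                tac = simulate_lobe_tac(params, input_tac, dt=0.1, out_times=grid)
                if noise_sd > 0:
                    noisy = np.clip(
                        tac.values + rng.normal(0.0, noise_sd, size=len(grid)), 0.0, None
                    )
                    noisy[0] = 0.0
                    tac = tac.with_values(noisy)
                tacs[lobe] = replace(tac, name=lobe)
            tacs["input"] = input_tac
        cohort.append((record, tacs))
    return cohort
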