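"""End-to-end pipeline: synthetic data -> ODBA -> HMM -> UD -> seascape.

The pipeline chains every stage of the analysis on a synthetic
individual: a central-place-foraging track detected on a receiver
array, a raw 20-Hz accelerometer record whose per-second activity is
driven by a covariate 2-state hidden Markov process, the HMM fit and
diel activity curve, the space-time Brownian-bridge utilization
distribution, their fusion into an activity seascape, the central-place
displacement series, and the bioenergetics scenario comparison.  All
randomness derives from one seed; a rerun with the same configuration
is numerically identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accel as accel_mod
from . import energetics as en
from . import hmm as hmm_mod
from . import io as io_mod
from . import movement as mv
from . import seascape as sc
from . import synthetic as syn

logger = logging.getLogger("seascapes")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name in the message."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of the synthetic end-to-end run.

    Defaults reproduce the study conditions at desk scale: a 30-day
    track with ~3-km nocturnal excursions, a 100 m x 100 m x 10 min
    voxel grid, 300-m location error, the 4-h initial trim, the
    100-detection filter, and the grey-reef-shark energetics scenario
    (38.3-kg shark, Q10 of 1.65 and 3.0, 0.5 degC diel temperature
    cycle, 5-10 % nocturnal speed increase).
    """

    seed: int = 0
    # track + detections
    n_days: int = 30
    day_radius: float = 200.0
    night_excursion_dist: float = 3000.0
    excursion_start: float = 19.0
    excursion_end: float = 5.0
    speed_mean: float = 0.6
    track_step_s: float = 60.0
    receiver_spacing: float = 500.0
    receiver_extent: float = 3500.0
    detection_range: float = 300.0
    ping_interval_s: float = 120.0
    min_detections: int = 100
    # accelerometry / HMM
    odba_hours: float = 14.0
    accel_fs: float = 20.0
    gravity_window_s: float = 3.0
    trim_hours: float = 4.0
    harmonic_order: int = 1
    use_tide: bool = True
    n_restarts: int = 3
    n_boot: int = 200
    # generating HMM (1-s scale): low/high activity gamma ODBA states
    gen_shape: tuple[float, float] = (2.0, 3.0)
    gen_rate: tuple[float, float] = (40.0, 15.0)
    gen_beta12_intercept: float = -2.2
    gen_beta12_night: float = 1.0
    gen_beta21_intercept: float = -1.2
    gen_beta21_night: float = -0.8
    # voxel grid + bridges
    cell_m: float = 100.0
    tbin_minutes: int = 10
    grid_margin_m: float = 500.0
    sigma_loc: float = 300.0
    max_gap_h: float = 12.0
    tide_level: str = "high"
    # energetics
    shark_length_cm: float = 144.0  # ~38.3 kg under the length-mass allometry
    t_ref_c: float = 28.0
    temp_peak_to_trough_c: float = 0.5
    temp_peak_hour: float = 2.0
    speed_scenario_mean_ms: float = 0.57
    speed_swing_fraction: float = 0.07
    speed_peak_hour: float = 2.5
    q10_values: tuple[float, ...] = (1.65, 3.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gen_shape", "gen_rate", "q10_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _diel_harmonics(hour_peak: float, magnitude: float) -> tuple[float, float]:
    """(sin, cos) coefficients of a single harmonic peaking at ``hour_peak``."""
    w = 2.0 * np.pi / 24.0
    return magnitude * np.sin(w * hour_peak), magnitude * np.cos(w * hour_peak)


def generating_hmm_spec(config: PipelineConfig) -> hmm_mod.HMMSpec:
    """The data-generating HMM implied by the configuration.

    The high-activity state is favoured at night: the 1->2 switching
    probability peaks near the excursion midpoint, the 2->1 probability
    in the early afternoon.
    """
    design = hmm_mod.CovariateDesign(
        harmonic_order=config.harmonic_order,
        tidal_levels=hmm_mod.TIDAL_LEVELS if config.use_tide else (),
    )
    p = design.n_columns
    night_mid = (
        config.excursion_start + ((config.excursion_end - config.excursion_start) % 24) / 2
    ) % 24
    b12 = np.zeros(p)
    b21 = np.zeros(p)
    b12[0] = config.gen_beta12_intercept
    b21[0] = config.gen_beta21_intercept
    if config.harmonic_order >= 1:
        s, c = _diel_harmonics(night_mid, config.gen_beta12_night)
        b12[1], b12[2] = s, c
        s, c = _diel_harmonics(night_mid, config.gen_beta21_night)
        b21[1], b21[2] = s, c
    if config.use_tide:
        # mild tidal modulation of the switching probability
        b12[-3:] = [0.3, -0.2, 0.1]
        b21[-3:] = [-0.1, 0.2, -0.1]
    return hmm_mod.HMMSpec(
        densities=hmm_mod.StateDensities(np.array(config.gen_shape), np.array(config.gen_rate)),
        transitions=hmm_mod.TransitionModel(b12, b21),
        design=design,
        delta=np.array([0.5, 0.5]),
    )


def synthesize_raw_accel(
    odba_per_s: np.ndarray, fs: float, seed: int
) -> accel_mod.RawAccel:
    """A 20-Hz tri-axial record whose per-second ODBA tracks a target.

    Gravity sits on the z axis; each axis carries a sinusoidal dynamic
    component (distinct tail-beat-scale frequencies and random phases)
    scaled so the expected ODBA of each second equals the target.
    """
    n_sec = odba_per_s.size
    nps = int(round(fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n_sec * nps) / fs
    amp = np.repeat(odba_per_s, nps) * (np.pi / 6.0)  # E|sin| = 2/pi per axis
    freqs = (1.1, 1.7, 2.3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    dyn = [amp * np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)]
    return accel_mod.RawAccel(
        timestamps=t, ax=dyn[0], ay=dyn[1], az=1.0 + dyn[2]
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the artifact bundle into ``outdir``.

    Returns a dict of artifact paths plus in-memory results.  Output
    bundle: receivers/detections CSVs, ODBA CSV, HMM fit JSON, activity
    curve CSV, UD netCDF, seascape netCDF, displacement CSV, energetics
    report, provenance JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # --- stage: simulate movement -----------------------------------------
    stage = "simulate"
    try:
        params = syn.CPFParams(
            day_radius=config.day_radius,
            night_excursion_dist=config.night_excursion_dist,
            excursion_start=config.excursion_start,
            excursion_end=config.excursion_end,
            step_interval=config.track_step_s,
            speed_mean=config.speed_mean,
            seed=config.seed,
        )
        track = syn.simulate_cpf_track(params, config.n_days)
        array = syn.make_receiver_grid(
            config.receiver_spacing, config.receiver_extent, config.detection_range
        )
        det = syn.simulate_detections(
            track, array, config.ping_interval_s, seed=config.seed + 1
        )
        logger.info("simulated %d detections on %d receivers", len(det), len(array))
        io_mod.write_receivers_csv(array, outdir / "receivers.csv")
        io_mod.write_detections_csv(det, outdir / "detections.csv")
        artifacts["receivers"] = outdir / "receivers.csv"
        artifacts["detections"] = outdir / "detections.csv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: detection filter ------------------------------------------
    stage = "min_detection_filter"
    retained, report = sc.min_detection_filter([det], min_n=config.min_detections)
    provenance["detection_filter"] = {k: v for k, v in report.items()}
    if not retained:
        raise PipelineError(
            stage,
            f"individual {det.individual_id!r} has {len(det)} detections "
            f"(< {config.min_detections}); nothing to analyse",
        )
    det = retained[0]

    # --- stage: accelerometry ----------------------------------------------
    stage = "odba"
    try:
        n_sec = int(config.odba_hours * 3600)
        gen_spec = generating_hmm_spec(config)
        sec_t = np.arange(n_sec, dtype=float)
        sec_hours = (sec_t / 3600.0) % 24.0
        sec_tide = syn.tide_state(sec_t) if config.use_tide else None
        target_odba, true_states = syn.simulate_odba_hmm(
            gen_spec, sec_hours, sec_tide, seed=config.seed + 2, timestamps=sec_t
        )
        raw = synthesize_raw_accel(target_odba.odba, config.accel_fs, config.seed + 3)
        _, dyn = accel_mod.separate_gravity(raw, window=config.gravity_window_s)
        odba_native = accel_mod.compute_odba(dyn, raw.timestamps)
        odba_1s = accel_mod.block_average(odba_native, block=1.0)
        odba_1s = accel_mod.trim_initial(odba_1s, hours=config.trim_hours)
        io_mod.write_odba_csv(odba_1s, outdir / "odba.csv")
        artifacts["odba"] = outdir / "odba.csv"
        logger.info("ODBA series: %d one-second values after %g-h trim", len(odba_1s), config.trim_hours)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: HMM fit ------------------------------------------------------
    stage = "fit_hmm"
    try:
        hours = (odba_1s.timestamps / 3600.0) % 24.0
        tide = syn.tide_state(odba_1s.timestamps) if config.use_tide else None
        fit = hmm_mod.fit_hmm(
            odba_1s.odba,
            hours,
            tide,
            design=gen_spec.design,
            n_restarts=config.n_restarts,
            seed=config.seed + 4,
        )
        hmm_mod.save_fit(fit, outdir / "hmm_fit.json")
        artifacts["hmm_fit"] = outdir / "hmm_fit.json"
        curve = hmm_mod.activity_curve(
            fit,
            tide=config.tide_level if config.use_tide else None,
            n_boot=config.n_boot,
            seed=config.seed + 5,
        )
        io_mod.write_activity_curve_csv(curve, outdir / "activity_curve.csv")
        artifacts["activity_curve"] = outdir / "activity_curve.csv"
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: utilization distribution ------------------------------------
    stage = "ud"
    try:
        margin = config.grid_margin_m
        grid = mv.VoxelGrid.from_extent(
            det.x.min() - margin,
            det.x.max() + margin,
            det.y.min() - margin,
            det.y.max() + margin,
            cell=config.cell_m,
            tbin_minutes=config.tbin_minutes,
        )
        sigma_m2 = mv.estimate_motion_variance(det, config.sigma_loc)
        bridge = mv.BridgeParams(
            sigma_loc=config.sigma_loc, sigma_m2=sigma_m2, max_gap=config.max_gap_h * 3600.0
        )
        volume = mv.spacetime_ud(det, grid, bridge)
        volume.to_netcdf(outdir / "ud.nc")
        artifacts["ud"] = outdir / "ud.nc"
        provenance["sigma_m2"] = sigma_m2
        logger.info("space-time UD on %dx%dx%d voxels, sigma_m2=%.3g", grid.nx, grid.ny, grid.n_tbins, sigma_m2)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: seascape ------------------------------------------------------
    stage = "seascape"
    try:
        planar = mv.planar_ud(volume)
        place = sc.central_place_udcontour(planar, individual_id=det.individual_id)
        seascape = sc.fuse_activity(volume, curve)
        seascape.to_netcdf(outdir / "seascape.nc")
        artifacts["seascape"] = outdir / "seascape.nc"
        with open(outdir / "central_place.json", "w") as fh:
            json.dump(place.to_geojson_dict(), fh)
        artifacts["central_place"] = outdir / "central_place.json"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: displacement ---------------------------------------------------
    stage = "displacement"
    try:
        disp = sc.displacement_series(det, place)
        disp.to_csv(outdir / "displacement.csv")
        artifacts["displacement"] = outdir / "displacement.csv"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: energetics -------------------------------------------------------
    stage = "energetics"
    try:
        shark = en.SharkMorphometrics(config.shark_length_cm)
        hours24 = np.arange(24.0)
        amp_t = config.temp_peak_to_trough_c / 2.0
        temp_obs = config.t_ref_c + amp_t * np.cos(
            2 * np.pi * (hours24 - config.temp_peak_hour) / 24.0
        )
        amp_u = config.speed_scenario_mean_ms * config.speed_swing_fraction / 2.0
        speed = config.speed_scenario_mean_ms + amp_u * np.cos(
            2 * np.pi * (hours24 - config.speed_peak_hour) / 24.0
        )
        rows = []
        comparisons = {}
        for q10 in config.q10_values:
            obs = en.EnergyScenario(
                temp_obs, speed, config.t_ref_c, q10,
                speed_mean_ms=config.speed_scenario_mean_ms, name=f"observed_q10_{q10}",
            )
            static = en.EnergyScenario(
                np.full(24, config.t_ref_c), speed, config.t_ref_c, q10,
                speed_mean_ms=config.speed_scenario_mean_ms, name=f"static_q10_{q10}",
            )
            p_obs = en.diel_energy_profile(shark, obs)
            p_static = en.diel_energy_profile(shark, static)
            comparisons[q10] = en.compare_scenarios(p_obs, p_static)
            for h in range(24):
                rows.append(
                    {
                        "q10": q10,
                        "hour": h,
                        "rate_observed": p_obs.rate_mgO2_h[h],
                        "rate_static": p_static.rate_mgO2_h[h],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "energetics.csv", index=False)
        with open(outdir / "energetics_report.txt", "w") as fh:
            fh.write(
                f"Shark: {config.shark_length_cm} cm TL, {shark.mass_kg:.1f} kg, "
                f"RMR at {config.t_ref_c} degC = "
                f"{en.routine_metabolic_rate(shark.mass_kg):.1f} mg O2/h\n"
            )
            for q10, cmp in comparisons.items():
                fh.write(
                    f"Q10={q10}: paired t = {cmp['t']:.4g}, df = {cmp['df']}, "
                    f"p = {cmp['p']:.3g}\n"
                )
        artifacts["energetics"] = outdir / "energetics.csv"
        artifacts["energetics_report"] = outdir / "energetics_report.txt"
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    artifacts["provenance"] = outdir / "provenance.json"

    return {
        "artifacts": artifacts,
        "track": track,
        "detections": det,
        "fit": fit,
        "curve": curve,
        "volume": volume,
        "planar": planar,
        "central_place": place,
        "seascape": seascape,
        "displacement": disp,
        "energetics": comparisons,
        "true_states": true_states,
        "generating_spec": gen_spec,
    }
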