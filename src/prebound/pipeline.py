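"""Config-driven pipeline tying the stages together.

A run is described by a YAML mapping with one block per requested stage
(``synth``, ``ramd_sim``, ``cvs``, ``detect``, ``interactions``, ``pmf``);
stages execute in that canonical order, read either files named in their
block or the outputs of earlier stages, and write plain-text outputs into
the run directory.  Every run emits a manifest (config hash, seeds, paths,
package version, per-stage timings); re-running an identical config with
identical seeds reproduces the stochastic stages bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, load_profile
from .collective_variables import CVSeries, compute_cv_series
from .state_analysis import (
    SmoothingParams,
    StateThresholds,
    detect_prebound_visit,
    moving_average,
)
from .structure_io import read_trajectory_csv, write_trajectory_csv
from .synthetic_data import (
    DwellPlan,
    DwellSegment,
    TwoStateTrajectoryPlan,
    generate_dwell_series,
    generate_two_state_trajectory,
    generate_umbrella_samples,
    template_reference_spec,
)
from .toy_ramd import RAMDParams, ToyLandscape, run_ramd
from .interaction_analysis import hbond_frequencies
from .wham import BootstrapScheme, barrier_and_minima, bootstrap_pmf

logger = logging.getLogger("prebound.pipeline")

STAGES = ("synth", "ramd_sim", "cvs", "detect", "interactions", "pmf")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    outputs: list[str]
    timings_s: dict[str, float]
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "outputs": self.outputs,
            "timings_s": self.timings_s,
            "package_version": self.version,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _thresholds_from_profile(profile: dict) -> StateThresholds:
    block = profile["state_analysis"]
    return StateThresholds(
        prebound_low=block["prebound_low_nm"],
        prebound_high=block["prebound_high_nm"],
        bound_center=block["bound_center_nm"],
        dissociated_above=block["dissociated_above_nm"],
        min_dwell_ns=block["min_dwell_ns"],
    )


def _stage_synth(block: dict, outdir: Path, profile: dict) -> list[str]:
    outputs = []
    if "dwell" in block:
        cfg = block["dwell"]
        segments = tuple(
            DwellSegment(s["state"], s["duration_ns"], s["level_nm"], s["noise_sd_nm"])
            for s in cfg["segments"]
        )
        plan = DwellPlan(segments=segments, stride_ps=cfg.get("stride_ps", 2.0),
                         seed=cfg.get("seed", 0))
        series = generate_dwell_series(plan)
        path = outdir / "dwell_series.csv"
        pd.DataFrame({"time_ps": series.times, "r_nm": series.r}).to_csv(path, index=False)
        truth_path = outdir / "dwell_truth.json"
        with open(truth_path, "w") as fh:
            json.dump({"prebound_intervals_ps": series.true_intervals}, fh, indent=2)
        outputs += [str(path), str(truth_path)]
    if "traj" in block:
        cfg = block["traj"]
        plan = TwoStateTrajectoryPlan.defaults(
            n_frames_per_state=cfg.get("n_frames_per_state", 50), seed=cfg.get("seed", 0)
        )
        traj, truth = generate_two_state_trajectory(plan)
        path = outdir / "two_state_traj.csv"
        write_trajectory_csv(traj, path)
        labels_path = outdir / "two_state_labels.csv"
        pd.DataFrame({"label": truth.labels, "r_planted_nm": truth.r}).to_csv(
            labels_path, index=False
        )
        outputs += [str(path), str(labels_path)]
    if not outputs:
        raise PipelineError("synth block must contain a 'dwell' and/or 'traj' sub-block")
    return outputs


def _stage_ramd(block: dict, outdir: Path, profile: dict) -> list[str]:
    ramd_cfg = profile["ramd"]
    landscape = ToyLandscape.from_profile(profile["toy_landscape"])
    n_seeds = block.get("n_seeds", 1)
    base_seed = block.get("seed", 0)
    params_common = dict(
        force_magnitude=block.get("force_magnitude", ramd_cfg["force_magnitude_kjmol_nm"]),
        evaluation_interval_fs=ramd_cfg["evaluation_interval_fs"],
        displacement_threshold_nm=ramd_cfg["displacement_threshold_nm"],
        max_time_ns=block.get("max_time_ns", ramd_cfg["max_time_ns"]),
        dissociation_cutoff_nm=ramd_cfg["dissociation_cutoff_nm"],
        timestep_fs=ramd_cfg["timestep_fs"],
        temperature_K=ramd_cfg["temperature_K"],
        friction_per_ps=ramd_cfg["friction_per_ps"],
        mass_amu=ramd_cfg["mass_amu"],
        snapshot_ps=ramd_cfg["snapshot_ps"],
    )
    logger.info(
        "biased runs: force %.0f kJ/(mol nm), interval %.0f fs, threshold %.4f nm, cap %.0f ns",
        params_common["force_magnitude"], params_common["evaluation_interval_fs"],
        params_common["displacement_threshold_nm"], params_common["max_time_ns"],
    )
    outputs = []
    events = {}
    for i in range(n_seeds):
        params = RAMDParams(seed=base_seed + i, **params_common)
        run = run_ramd(landscape, params)
        path = outdir / f"ramd_run_{i:03d}.csv"
        run.write_csv(path)
        outputs.append(str(path))
        events[f"run_{i:03d}"] = {
            "seed": params.seed,
            "dissociation_time_ns": run.dissociation_time_ns,
            "n_redirections": int(len(run.redirection_times_ps)),
        }
    events_path = outdir / "ramd_events.json"
    with open(events_path, "w") as fh:
        json.dump(events, fh, indent=2, sort_keys=True)
    outputs.append(str(events_path))
    return outputs


def _stage_cvs(block: dict, outdir: Path, profile: dict) -> list[str]:
    traj_path = Path(block.get("traj", outdir / "two_state_traj.csv"))
    if not traj_path.exists():
        raise PipelineError(f"cvs stage: trajectory {traj_path} not found")
    from .synthetic_data import make_ligand_body, make_receptor_body

    topology = make_receptor_body().topology + make_ligand_body().topology
    traj = read_trajectory_csv(traj_path, topology)
    series = compute_cv_series(traj, template_reference_spec())
    path = outdir / "cv_series.csv"
    series.write_csv(path, degrees=block.get("degrees", False))
    return [str(path)]


def _stage_detect(block: dict, outdir: Path, profile: dict) -> list[str]:
    series_path = Path(block.get("series", outdir / "dwell_series.csv"))
    if not series_path.exists():
        raise PipelineError(f"detect stage: series {series_path} not found")
    df = pd.read_csv(series_path)
    window = block.get("smoothing_window_ps", profile["state_analysis"]["smoothing_window_ps"])
    logger.info("dwell detection: smoothing window %.0f ps, band %.2f-%.2f nm, min dwell %.1f ns",
                window, profile["state_analysis"]["prebound_low_nm"],
                profile["state_analysis"]["prebound_high_nm"],
                profile["state_analysis"]["min_dwell_ns"])
    smoothed = moving_average(df["time_ps"].to_numpy(), df["r_nm"].to_numpy(),
                              SmoothingParams(window_ps=window))
    report = detect_prebound_visit(
        df["time_ps"].to_numpy(), smoothed, _thresholds_from_profile(profile)
    )
    path = outdir / "dwell_report.json"
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return [str(path)]


def _stage_interactions(block: dict, outdir: Path, profile: dict) -> list[str]:
    traj_path = Path(block.get("traj", outdir / "two_state_traj.csv"))
    if not traj_path.exists():
        raise PipelineError(f"interactions stage: trajectory {traj_path} not found")
    from .synthetic_data import LIGAND_CHAIN, RECEPTOR_CHAIN, make_ligand_body, make_receptor_body

    topology = make_receptor_body().topology + make_ligand_body().topology
    traj = read_trajectory_csv(traj_path, topology)
    logger.info("interaction analysis: contact cutoff %.2f nm, report threshold %.2f",
                profile["interactions"]["contact_cutoff_nm"],
                profile["interactions"]["hbond_report_threshold"])
    table = hbond_frequencies(
        traj, RECEPTOR_CHAIN, LIGAND_CHAIN,
        report_threshold=profile["interactions"]["hbond_report_threshold"],
    )
    path = outdir / "hbond_frequencies.csv"
    table.frequencies.rename("frequency").to_csv(path, index_label="label")
    return [str(path)]


def _stage_pmf(block: dict, outdir: Path, profile: dict) -> list[str]:
    umbrella = profile["umbrella"]
    logger.info("umbrella analysis: %d windows, k %.0f kJ/(mol nm^2), T %.0f K",
                len(umbrella["centers_nm"]), umbrella["force_constant_kjmol_nm2"],
                umbrella["temperature_K"])
    if "windows" in block:
        manifest = pd.read_csv(block["windows"])
        from .wham import UmbrellaWindow, WindowSet

        windows = []
        for _, row in manifest.iterrows():
            samples = pd.read_csv(row["path"])["xi_nm"].to_numpy()
            windows.append(UmbrellaWindow(row["center_nm"], row["force_constant"], samples))
        window_set = WindowSet(windows, temperature=umbrella["temperature_K"])
    else:
        gen = block.get("generate", {})
        barrier = gen.get("barrier_kjmol", 12.0)
        well_sep = gen.get("well_centers_nm", (0.30, 0.60))
        width = gen.get("well_width_nm", 0.05)
        depth_pre = gen.get("prebound_offset_kjmol", 2.0)

        def potential(xi):
            xi = np.asarray(xi, dtype=float)
            return (
                -barrier * np.exp(-((xi - well_sep[0]) ** 2) / (2 * width**2))
                - (barrier - depth_pre) * np.exp(-((xi - well_sep[1]) ** 2) / (2 * width**2))
            )

        window_set = generate_umbrella_samples(
            potential,
            umbrella["centers_nm"],
            umbrella["force_constant_kjmol_nm2"],
            n_per_window=gen.get("n_per_window", 2000),
            seed=block.get("seed", 0),
            temperature=umbrella["temperature_K"],
        )
    profile_mean, _ = bootstrap_pmf(
        window_set, BootstrapScheme(n_segments=umbrella["bootstrap_segments"])
    )
    path = outdir / "pmf.csv"
    profile_mean.write_csv(path)
    report = barrier_and_minima(profile_mean)
    report_path = outdir / "pmf_barrier.json"
    with open(report_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return [str(path), str(report_path)]


_STAGE_RUNNERS = {
    "synth": _stage_synth,
    "ramd_sim": _stage_ramd,
    "cvs": _stage_cvs,
    "detect": _stage_detect,
    "interactions": _stage_interactions,
    "pmf": _stage_pmf,
}


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute the stages named in *config*, in canonical order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = load_profile(config.get("profile", "trypsin_bpti"))
    unknown = set(config) - set(STAGES) - {"profile"}
    if unknown:
        raise PipelineError(f"unknown stage(s) {sorted(unknown)}; stages are {list(STAGES)}")
    outputs: list[str] = []
    timings: dict[str, float] = {}
    seeds: dict[str, int] = {}
    for stage in STAGES:
        if stage not in config:
            continue
        block = config[stage] or {}
        if "seed" in block:
            seeds[stage] = block["seed"]
        t0 = time.perf_counter()
        outputs += _STAGE_RUNNERS[stage](block, outdir, profile)
        timings[stage] = round(time.perf_counter() - t0, 4)
        logger.info("stage %s finished in %.2f s", stage, timings[stage])
    manifest = RunManifest(
        config_hash=config_hash(config), seeds=seeds, outputs=outputs, timings_s=timings
    )
    manifest.write(outdir / "manifest.json")
    return manifest
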