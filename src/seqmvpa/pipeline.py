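"""End-to-end orchestration of the simulated study.

``run_full_analysis`` simulates a group, runs the three decoders on both
trial phases, runs the prewhitened geometry analysis with its simulated
no-switch baseline, runs a volumetric searchlight demonstration, and writes a
consolidated report.  Stages cache their artifacts on disk (CSV/NIfTI/JSON)
so they can be re-run independently; all randomness derives from one seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datasets import PHASES, PREPARATION, complete_design_labels
from .decoding import decode_subject, make_factorized_folds, crossvalidated_accuracy
from .experiments import _signal_cube_mask
from .geometry import (
    crossnobis_rdm,
    cross_phase_statistic,
    simulate_cross_phase_baseline,
    test_against_baseline,
)
from .searchlight import define_searchlights, group_t_map, run_searchlight
from .simulate import (
    SimulationConfig,
    embed_in_volume,
    estimate_snr,
    simulate_group,
    simulate_subject_patterns,
)
from .stats import DegenerateTestError, one_sample_t

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of the full simulated analysis."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    decode_shrinkage: float | str = "auto"
    decode_bonferroni_m: int = 6  # phase (2) x classifier (3)
    geometry_shrinkage: float | str = "auto"
    n_baseline_sims: int = 100
    geometry_bonferroni_m: int = 7
    searchlight_mask_shape: tuple[int, int, int] = (8, 8, 8)
    searchlight_signal_shape: tuple[int, int, int] = (4, 4, 4)
    searchlight_n_subjects: int = 12
    searchlight_target_size: int = 160
    searchlight_max_radius_mm: float = 6.0
    searchlight_t_threshold: float = 3.48
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig(**sim), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.load_yaml(path))


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list:
    sim_dir = outdir / "simulation"
    sim_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    datasets = simulate_group(sim_cfg)
    for s, ds in enumerate(datasets, start=1):
        io.dataset_to_csv(ds, sim_dir / f"subject_{s:02d}.csv")
    io.save_yaml(dataclasses.asdict(sim_cfg), sim_dir / "simulation_config.yaml")
    return datasets


def _load_subjects(outdir: Path) -> list:
    sim_dir = outdir / "simulation"
    files = sorted(sim_dir.glob("subject_*.csv"))
    if not files:
        raise StageError("simulate stage has not been run (no subject CSVs)")
    return [io.dataset_from_csv(f) for f in files]


def stage_decode(cfg: PipelineConfig, outdir: Path, datasets=None) -> pd.DataFrame:
    datasets = _load_subjects(outdir) if datasets is None else datasets
    dec_dir = outdir / "decoding"
    dec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    cache: dict = {}
    for s, ds in enumerate(datasets, start=1):
        for phase in PHASES:
            results = decode_subject(
                ds, phase, shrinkage=cfg.decode_shrinkage, folds_cache=cache
            )
            for decoder, res in results.items():
                rows.append(
                    {
                        "subject": s,
                        "phase": phase,
                        "decoder": decoder,
                        "accuracy": res.accuracy,
                        "z": res.z_score,
                        "chance": res.chance,
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(dec_dir / "decoding_results.csv", index=False, float_format=_FLOAT_FMT)

    group_rows = []
    for (phase, decoder), grp in table.groupby(["phase", "decoder"]):
        row = {"phase": phase, "decoder": decoder}
        try:
            res = one_sample_t(
                grp["z"].to_numpy(), mu=0.0, tails="one",
                bonferroni_m=cfg.decode_bonferroni_m,
            )
            row.update(
                t=res.t, df=res.df, p_uncorrected=res.p_uncorrected,
                p_corrected=res.p_corrected, cohens_d=res.cohens_d,
                bonferroni_m=res.bonferroni_m,
            )
        except DegenerateTestError:
            # all subjects at the same value (e.g. at ceiling): flag, don't abort
            row.update(
                t=np.nan, df=len(grp) - 1, p_uncorrected=np.nan,
                p_corrected=np.nan, cohens_d=np.nan,
                bonferroni_m=cfg.decode_bonferroni_m,
            )
        group_rows.append(row)
    group = pd.DataFrame(group_rows)
    group.to_csv(dec_dir / "group_stats.csv", index=False, float_format=_FLOAT_FMT)
    return group


def stage_geometry(cfg: PipelineConfig, outdir: Path, datasets=None) -> dict:
    datasets = _load_subjects(outdir) if datasets is None else datasets
    geo_dir = outdir / "geometry"
    geo_dir.mkdir(parents=True, exist_ok=True)

    rdm_sum = None
    stats = []
    snr = {phase: [] for phase in PHASES}
    for ds in datasets:
        rdm = crossnobis_rdm(ds, shrinkage=cfg.geometry_shrinkage)
        rdm_sum = rdm.distances if rdm_sum is None else rdm_sum + rdm.distances
        stats.append(cross_phase_statistic(ds, shrinkage=cfg.geometry_shrinkage))
        for phase in PHASES:
            snr[phase].append(estimate_snr(ds, phase))
    rdm.distances = rdm_sum / len(datasets)
    io.rdm_to_csv(rdm, geo_dir / "group_mean_rdm.csv")
    per_subject = pd.DataFrame(
        {
            "subject": np.arange(1, len(datasets) + 1),
            "normalized_distance": [s.normalized_distance for s in stats],
            "within_phase_grand_mean": [s.within_phase_grand_mean for s in stats],
        }
    )
    per_subject.to_csv(
        geo_dir / "cross_phase_per_subject.csv", index=False, float_format=_FLOAT_FMT
    )

    snr_prep = float(np.mean(snr[PREPARATION]))
    snr_prod = float(np.mean(snr["production"]))
    sim = cfg.simulation
    base_seed = int(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0] % (2**31))
    common = dict(
        n_voxels=sim.n_voxels,
        n_runs=sim.n_runs,
        snr_prep=max(snr_prep, 1e-3),
        snr_prod=max(snr_prod, 1e-3),
        n_sims=cfg.n_baseline_sims,
        shrinkage=cfg.geometry_shrinkage,
        # run effects add a common per-run vector that cancels in the
        # centered geometry, so the baseline can always realize the target
        # SNR with var_r = 0 (any target stays feasible)
        var_r=0.0,
    )
    baseline = simulate_cross_phase_baseline(switch=False, seed=base_seed, **common)
    reference = simulate_cross_phase_baseline(switch=True, seed=base_seed + 1, **common)
    res = test_against_baseline(
        per_subject["normalized_distance"].to_numpy(),
        baseline.mean,
        bonferroni_m=cfg.geometry_bonferroni_m,
    )
    summary = {
        "normalized_distance_mean": float(per_subject["normalized_distance"].mean()),
        "baseline_no_switch_mean": baseline.mean,
        "baseline_no_switch_sd": baseline.sd,
        "reference_switch_mean": reference.mean,
        "reference_switch_sd": reference.sd,
        "snr_prep": snr_prep,
        "snr_prod": snr_prod,
        "t": res.t,
        "df": res.df,
        "p_uncorrected": res.p_uncorrected,
        "p_corrected": res.p_corrected,
        "cohens_d": res.cohens_d,
        "bonferroni_m": res.bonferroni_m,
    }
    _json_dump(summary, geo_dir / "cross_phase_summary.json")
    return summary


def stage_searchlight(cfg: PipelineConfig, outdir: Path) -> dict:
    sl_dir = outdir / "searchlight"
    sl_dir.mkdir(parents=True, exist_ok=True)
    mask, signal_region = _signal_cube_mask(
        cfg.searchlight_mask_shape, cfg.searchlight_signal_shape, cfg.voxel_size_mm
    )
    io.save_mask(mask, sl_dir / "mask.nii")
    io.save_mask(signal_region, sl_dir / "signal_region.nii")
    searchlights = define_searchlights(
        mask, cfg.searchlight_target_size, cfg.searchlight_max_radius_mm
    )
    sim = dataclasses.replace(
        cfg.simulation,
        n_voxels=signal_region.n_voxels,
        phase_offset=0.0,
    )
    folds = make_factorized_folds(
        complete_design_labels(sim.n_runs), "order", PREPARATION
    )

    def order_z(sub):
        return crossvalidated_accuracy(sub, folds, cfg.decode_shrinkage).z_score

    maps = []
    root = np.random.SeedSequence([cfg.seed, 2])
    for child in root.spawn(cfg.searchlight_n_subjects):
        rng = np.random.default_rng(child)
        ds = simulate_subject_patterns(sim, rng=rng)
        vol = embed_in_volume(ds, mask, signal_region, rng=rng)
        maps.append(run_searchlight(vol, mask, searchlights, order_z))
    tmap, clusters = group_t_map(maps, t_threshold=cfg.searchlight_t_threshold)
    io.save_map(tmap, cfg.voxel_size_mm, sl_dir / "group_t_map.nii")
    pd.DataFrame(
        [
            {
                "extent": c.size,
                "peak_t": c.peak_t,
                "peak_x": c.peak_voxel[0],
                "peak_y": c.peak_voxel[1],
                "peak_z": c.peak_voxel[2],
            }
            for c in clusters
        ],
        columns=["extent", "peak_t", "peak_x", "peak_y", "peak_z"],
    ).to_csv(sl_dir / "clusters.csv", index=False, float_format=_FLOAT_FMT)
    return {
        "n_searchlights": len(searchlights),
        "n_clusters": len(clusters),
        "largest_extent": clusters[0].size if clusters else 0,
        "t_threshold": cfg.searchlight_t_threshold,
    }


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    report: dict = {"seed": cfg.seed}
    dec = outdir / "decoding" / "group_stats.csv"
    if dec.exists():
        report["decoding"] = pd.read_csv(dec).to_dict(orient="records")
    geo = outdir / "geometry" / "cross_phase_summary.json"
    if geo.exists():
        report["geometry"] = json.loads(geo.read_text())
    clusters = outdir / "searchlight" / "clusters.csv"
    if clusters.exists():
        tab = pd.read_csv(clusters)
        report["searchlight"] = {
            "n_clusters": int(len(tab)),
            "largest_extent": int(tab["extent"].max()) if len(tab) else 0,
        }
    _json_dump(report, outdir / "report.json")
    return report


def run_full_analysis(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; artifacts land under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        datasets = stage_simulate(cfg, outdir)
    except Exception as exc:
        raise StageError(f"simulate stage failed: {exc}") from exc
    for name, fn in (
        ("decode", lambda: stage_decode(cfg, outdir, datasets)),
        ("geometry", lambda: stage_geometry(cfg, outdir, datasets)),
        ("searchlight", lambda: stage_searchlight(cfg, outdir)),
        ("report", lambda: stage_report(cfg, outdir)),
    ):
        logger.info("running %s stage", name)
        try:
            result = fn()
        except Exception as exc:
            raise StageError(f"{name} stage failed: {exc}") from exc
    return result
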