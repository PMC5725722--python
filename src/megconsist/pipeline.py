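"""Configuration-driven orchestration of the full consistency experiment.

One experiment: for each synthetic subject, generate coupled narrowband
sources and sensor epochs once; beamform them under the true ("native")
anatomy and under displaced ("template") anatomies at each configured
displacement level; compute relative power, PLI adjacency matrices and
network metrics per epoch and band; and compare conditions with ICC(3,1),
Bland-Altman limits, and the distance-vs-power-ICC correlation.

The sensor data are shared between conditions (as in a real study, where the
recording is fixed and only the co-registration changes); only the assumed
source geometry differs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bands import BandDefinition, CLASSICAL_BANDS, check_contiguous
from .beamformer import VirtualElectrodeSet, atlas_beamform, voxel_distance
from .consistency import (
    distance_vs_icc,
    global_consistency,
    regional_consistency,
)
from .network import network_metrics, pli_adjacency
from .spectral import relative_power
from .synthetic import (
    Conductor,
    Coupling,
    SensorArray,
    SourceModel,
    generate_sources,
    perturb_anatomy,
    project_to_sensors,
    spiral_sensor_array,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "validate_config",
    "run_experiment",
    "desk_scale_config",
    "default_couplings",
]

logger = logging.getLogger("megconsist")

_CONFIG_KEYS = {
    "n_subjects", "n_rois", "voxels_per_roi", "n_channels", "fs", "epoch_len",
    "n_epochs", "bands", "couplings", "snr", "displacement_mm", "mode",
    "methods", "modularity_runs", "lam", "seed", "n_seeds", "output_dir",
    "log_level", "conductor_radius",
}


@dataclass
class ExperimentConfig:
    """Validated experiment parameters (defaults mirror the acquisition setup:
    151 channels, 625 Hz, 4096-sample epochs, 78 ROIs, six classical bands)."""

    n_subjects: int = 17
    n_rois: int = 78
    voxels_per_roi: int = 8
    n_channels: int = 151
    fs: float = 625.0
    epoch_len: int = 4096
    n_epochs: int = 45
    bands: tuple[BandDefinition, ...] = CLASSICAL_BANDS
    couplings: tuple[Coupling, ...] = ()   # empty -> random default graph
    snr: float = 5.0
    displacement_mm: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0)
    mode: str = "per_voxel"
    methods: tuple[str, ...] = ("peak", "centroid")
    modularity_runs: int = 100
    lam: float = 0.01
    seed: int = 0
    n_seeds: int = 1
    output_dir: str | None = None
    log_level: str = "INFO"
    conductor_radius: float = 90.0

    @property
    def conductor(self) -> Conductor:
        return Conductor(radius=self.conductor_radius)


@dataclass
class ExperimentResult:
    """All consistency tables of one experiment run."""

    regional_icc: pd.DataFrame
    global_icc: pd.DataFrame
    distances: pd.DataFrame
    distance_power_corr: pd.DataFrame
    config: ExperimentConfig
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def validate_config(raw: Mapping | None = None) -> ExperimentConfig:
    """Build an ExperimentConfig from a raw mapping, injecting defaults.

    Unknown keys, bands above Nyquist, negative displacements and degenerate
    counts are rejected with messages naming the offending key.
    """
    raw = dict(raw or {})
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    if "bands" in raw:
        bands = tuple(
            b if isinstance(b, BandDefinition) else BandDefinition(*b)
            for b in raw.pop("bands")
        )
    else:
        bands = CLASSICAL_BANDS
    if "couplings" in raw:
        couplings = tuple(
            c if isinstance(c, Coupling) else Coupling(**c)
            for c in raw.pop("couplings")
        )
    else:
        couplings = ()
    for key in ("displacement_mm", "methods"):
        if key in raw:
            raw[key] = tuple(raw[key])

    cfg = ExperimentConfig(bands=bands, couplings=couplings, **raw)

    check_contiguous(cfg.bands)
    for b in cfg.bands:
        if b.f_high > cfg.fs / 2:
            raise ValueError(
                f"bands: band {b.name!r} upper edge {b.f_high} Hz exceeds "
                f"Nyquist {cfg.fs / 2} Hz (fs={cfg.fs})"
            )
    if any(d < 0 for d in cfg.displacement_mm):
        raise ValueError("displacement_mm: displacements must be >= 0")
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if cfg.n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if cfg.snr <= 0:
        raise ValueError("snr must be > 0")
    unknown_m = set(cfg.methods) - {"peak", "centroid"}
    if unknown_m:
        raise ValueError(f"methods: unknown {sorted(unknown_m)}")
    band_names = {b.name for b in cfg.bands}
    for c in cfg.couplings:
        if c.band not in band_names:
            raise ValueError(f"couplings: unknown band {c.band!r}")
    return cfg


def desk_scale_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale study conditions for the displacement sweep.

    5 subjects, 20 ROIs of 4 voxels, 60 channels, 10 epochs of 1024 samples
    at 625 Hz, theta and beta bands, SNR 5, displacements 0/5/15/30 mm,
    peak-voxel method, 3 modularity runs per epoch. Small enough to run the
    whole sweep on one CPU in minutes while exercising every stage.
    """
    return validate_config(
        {
            "n_subjects": 5,
            "n_rois": 20,
            "voxels_per_roi": 4,
            "n_channels": 60,
            "epoch_len": 1024,
            "n_epochs": 10,
            "bands": [("theta", 4.0, 8.0), ("beta", 13.0, 30.0)],
            "displacement_mm": (0.0, 5.0, 15.0, 30.0),
            "methods": ("peak",),
            "modularity_runs": 3,
            "snr": 5.0,
            "seed": seed,
        }
    )


def default_couplings(
    n_rois: int,
    bands: Sequence[BandDefinition],
    seed: int,
    strength: float = 0.8,
) -> tuple[Coupling, ...]:
    """Random disjoint-pair coupling graph, one matching per band.

    ROIs are randomly matched into n_rois // 2 pairs per band, each with a
    random non-zero phase lag (magnitude in [pi/8, 7pi/8], random sign) and
    the given strength, so every band carries genuine lagged interactions
    that the PLI can detect.
    """
    rng = np.random.default_rng(seed)
    out: list[Coupling] = []
    for band in bands:
        perm = rng.permutation(np.arange(1, n_rois + 1))
        for a, b in zip(perm[0::2], perm[1::2]):
            lag = rng.uniform(np.pi / 8, 7 * np.pi / 8) * rng.choice([-1.0, 1.0])
            out.append(Coupling(int(a), int(b), band.name, float(lag), strength))
    return tuple(out)


# ---------------------------------------------------------------------------
# per-condition measure extraction
# ---------------------------------------------------------------------------

def _modularity_seed(base_seed: int, subject: int, band_idx: int, epoch: int) -> int:
    # independent of condition/displacement so identical matrices get identical Q
    ss = np.random.SeedSequence((base_seed, subject, band_idx, epoch))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def condition_measures(
    ves: VirtualElectrodeSet,
    cfg: ExperimentConfig,
    subject: int,
    condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regional and global measure tables for one reconstructed condition.

    Regional (per ROI, epoch, band): relative power, nodal mean PLI, MST
    degree. Global (per band, epoch-averaged): mean relative power, mean
    PLI, weighted clustering, path length, modularity Q, module count, MST
    leaf fraction and diameter.
    """
    regional_rows: list[dict] = []
    global_acc: dict[tuple[str, str], list[float]] = {}

    for band_idx, band in enumerate(cfg.bands):
        series = ves.series[band.name]          # (R, S, E)
        series_bb = ves.broadband[band.name]    # (R, S, E)
        n_rois, _, n_epochs = series.shape
        relpow = relative_power(series_bb, band, cfg.fs, axis=1)  # (R, E)

        for e in range(n_epochs):
            adj = pli_adjacency(series[:, :, e], band=band.name, epoch_id=e,
                                condition_tag=condition)
            seed = _modularity_seed(cfg.seed, subject, band_idx, e)
            nm = network_metrics(adj, modularity_runs=cfg.modularity_runs, seed=seed)
            node_pli = adj.node_mean()

            for roi in range(1, n_rois + 1):
                base = {
                    "subject": subject, "condition": condition,
                    "band": band.name, "roi": roi, "epoch": e,
                }
                regional_rows.append({**base, "measure": "power",
                                      "value": float(relpow[roi - 1, e])})
                regional_rows.append({**base, "measure": "pli",
                                      "value": float(node_pli[roi - 1])})
                regional_rows.append({**base, "measure": "mst_degree",
                                      "value": float(nm.mst_degree[roi - 1])})

            epoch_globals = {
                "power": float(relpow[:, e].mean()),
                "pli": adj.global_mean(),
                "clustering": nm.cw,
                "path_length": nm.lw,
                "modularity": nm.q,
                "n_modules": nm.n_modules,
                "mst_leaf_fraction": nm.leaf_fraction,
                "mst_diameter": float(nm.diameter),
            }
            for measure, value in epoch_globals.items():
                global_acc.setdefault((band.name, measure), []).append(value)

    global_rows = [
        {
            "subject": subject, "condition": condition, "band": band_name,
            "measure": measure, "value": float(np.mean(vals)),
        }
        for (band_name, measure), vals in global_acc.items()
    ]
    return pd.DataFrame(regional_rows), pd.DataFrame(global_rows)


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig, output_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full template-vs-native consistency experiment.

    For every subject the source model and sensor epochs are generated once;
    the native reconstruction is computed once per method; each displacement
    level gets its own perturbed anatomy and template reconstruction. The
    consistency layer is evaluated separately per (method, displacement).
    """
    t_start = time.time()
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    out = Path(output_dir or cfg.output_dir) if (output_dir or cfg.output_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    conductor = cfg.conductor
    sensors = spiral_sensor_array(cfg.n_channels, conductor)
    n_samples = cfg.epoch_len * cfg.n_epochs
    subj_seeds = (
        np.random.SeedSequence(cfg.seed).generate_state(cfg.n_subjects * 4)
        .reshape(cfg.n_subjects, 4) % (2 ** 31)
    )

    regional_frames: list[pd.DataFrame] = []
    global_frames: list[pd.DataFrame] = []
    distance_rows: list[dict] = []
    stage = "setup"
    manifest: dict = {
        "config": _config_dict(cfg),
        "config_hash": config_hash(cfg),
        "version": __version__,
        "subject_seeds": subj_seeds.tolist(),
        "stages": [],
    }

    try:
        for subj in range(cfg.n_subjects):
            stage = f"simulate_subject_{subj}"
            couplings = cfg.couplings or default_couplings(
                cfg.n_rois, cfg.bands, seed=int(subj_seeds[subj, 0])
            )
            model = generate_sources(
                n_rois=cfg.n_rois,
                voxels_per_roi=cfg.voxels_per_roi,
                n_samples=n_samples,
                fs=cfg.fs,
                couplings=couplings,
                bands=cfg.bands,
                conductor=conductor,
                seed=int(subj_seeds[subj, 1]),
            )
            epochs = project_to_sensors(
                model, sensors, conductor, snr=cfg.snr, n_epochs=cfg.n_epochs,
                seed=int(subj_seeds[subj, 2]), condition_tag="native",
            )
            logger.info("subject %d: simulated %d epochs", subj, cfg.n_epochs)

            for method in cfg.methods:
                stage = f"beamform_native_s{subj}_{method}"
                ve_native = atlas_beamform(
                    epochs, model, sensors, cfg.bands, method=method,
                    lam=cfg.lam, condition_tag="native",
                )
                reg_n, glob_n = condition_measures(ve_native, cfg, subj, "native")

                for lvl, disp in enumerate(cfg.displacement_mm):
                    stage = f"beamform_template_s{subj}_{method}_d{disp}"
                    template = perturb_anatomy(
                        model, disp, mode=cfg.mode,
                        seed=int((subj_seeds[subj, 3] + lvl) % (2 ** 31)),
                    )
                    ve_templ = atlas_beamform(
                        epochs, template, sensors, cfg.bands, method=method,
                        lam=cfg.lam, condition_tag="template",
                    )
                    reg_t, glob_t = condition_measures(ve_templ, cfg, subj, "template")

                    # native rows are re-tagged per displacement level so each
                    # level's consistency tables pair against the same native data
                    for part, frames in (
                        ((reg_n, reg_t), regional_frames),
                        ((glob_n, glob_t), global_frames),
                    ):
                        for df in part:
                            tagged = df.copy()
                            tagged["method"] = method
                            tagged["displacement_mm"] = disp
                            frames.append(tagged)

                    for band in cfg.bands:
                        pos_n = ve_native.rep_position[band.name]
                        pos_t = ve_templ.rep_position[band.name]
                        for roi in range(1, cfg.n_rois + 1):
                            distance_rows.append(
                                {
                                    "method": method, "displacement_mm": disp,
                                    "subject": subj, "band": band.name, "roi": roi,
                                    "distance_mm": voxel_distance(
                                        pos_n[roi - 1], pos_t[roi - 1]
                                    ),
                                }
                            )
                    manifest["stages"].append({"stage": stage, "t": time.time() - t_start})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    stage = "consistency"
    regional_all = pd.concat(regional_frames, ignore_index=True)
    global_all = pd.concat(global_frames, ignore_index=True)
    distances = pd.DataFrame(distance_rows)

    reg_icc_frames, glob_icc_frames, corr_frames = [], [], []
    for method in cfg.methods:
        for disp in cfg.displacement_mm:
            sel_r = regional_all[
                (regional_all["method"] == method)
                & (regional_all["displacement_mm"] == disp)
            ]
            sel_g = global_all[
                (global_all["method"] == method)
                & (global_all["displacement_mm"] == disp)
            ]
            reg_icc = regional_consistency(sel_r)
            glob_icc = global_consistency(sel_g)
            for df in (reg_icc, glob_icc):
                df["method"] = method
                df["displacement_mm"] = disp
            reg_icc_frames.append(reg_icc)
            glob_icc_frames.append(glob_icc)

            sel_d = distances[
                (distances["method"] == method)
                & (distances["displacement_mm"] == disp)
            ]
            mean_d = (
                sel_d.groupby(["band", "roi"], as_index=False)["distance_mm"].mean()
            )
            power_icc = reg_icc[reg_icc["measure"] == "power"][["band", "roi", "icc"]]
            if not power_icc.empty:
                corr = distance_vs_icc(mean_d, power_icc)
                if not corr.empty:
                    corr["method"] = method
                    corr["displacement_mm"] = disp
                    corr_frames.append(corr)

    result = ExperimentResult(
        regional_icc=pd.concat(reg_icc_frames, ignore_index=True),
        global_icc=pd.concat(glob_icc_frames, ignore_index=True),
        distances=distances,
        distance_power_corr=(
            pd.concat(corr_frames, ignore_index=True) if corr_frames else pd.DataFrame()
        ),
        config=cfg,
        manifest=manifest,
    )

    if out is not None:
        _write_outputs(result, out)
    manifest["elapsed_s"] = time.time() - t_start
    return result


def mean_global_icc_by_displacement(result: ExperimentResult,
                                    method: str | None = None) -> pd.Series:
    """Mean global ICC (over measures and bands) per displacement level."""
    g = result.global_icc
    if method is not None:
        g = g[g["method"] == method]
    return g.groupby("displacement_mm")["icc"].mean()


def pooled_distance_power_corr(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Distance-vs-power-ICC correlation pooled over sweep runs and levels.

    Each (run, method, displacement level, ROI) contributes one point: the
    ROI's mean representative-voxel distance and its pooled-epoch relative
    power ICC. Pooling across displacement levels exposes the negative
    distance-consistency relationship that single levels, with their narrow
    distance range, resolve only weakly. Returns one row per band.
    """
    from .consistency import pearson as _pearson

    points: list[pd.DataFrame] = []
    for run_idx, res in enumerate(results):
        mean_d = (
            res.distances.groupby(
                ["method", "displacement_mm", "band", "roi"], as_index=False
            )["distance_mm"].mean()
        )
        power = res.regional_icc[res.regional_icc["measure"] == "power"][
            ["method", "displacement_mm", "band", "roi", "icc"]
        ]
        merged = mean_d.merge(power, on=["method", "displacement_mm", "band", "roi"])
        merged["run"] = run_idx
        points.append(merged)
    pooled = pd.concat(points, ignore_index=True)
    rows = []
    for band, sub in pooled.groupby("band", sort=True):
        r, p = _pearson(sub["distance_mm"].to_numpy(), sub["icc"].to_numpy())
        rows.append({"band": band, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    files = {
        "regional_icc.csv": result.regional_icc,
        "global_icc.csv": result.global_icc,
        "distances.csv": result.distances,
        "distance_power_corr.csv": result.distance_power_corr,
    }
    digests = {}
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    result.manifest["output_digests"] = digests
    result.manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["bands"] = [[b.name, b.f_low, b.f_high] for b in cfg.bands]
    d["couplings"] = [asdict(c) for c in cfg.couplings]
    return d


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_dict(cfg), sort_keys=True).encode()
    ).hexdigest()
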