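"""File I/O, configuration and the end-to-end pipeline.

Image stacks travel as multi-page TIFF (pages grouped per height, page order
= time within each height) with a YAML sidecar holding the acquisition
metadata and a ground-truth CSV when the stack is synthetic. Bead traces are
plain CSV. All coordinates are 0-based with x = column and y = row; heights
are μm, time is s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import defocus, filopodia, force, kymograph, stats
from .synthetic import (
    BeadSimConfig,
    BeadTrace,
    ImageStackSequence,
    ImagingConfig,
    MotilityParams,
    StackGroundTruth,
    generate_bead_trace,
    generate_filopodium_tracks,
    generate_lamellipodium_stack,
)

log = logging.getLogger("gcmotility")

__all__ = [
    "write_stack",
    "read_stack",
    "write_bead_trace",
    "read_bead_trace",
    "PipelineConfig",
    "run_pipeline",
]

BEAD_COLUMNS = ["t_s", "qpd_x_nm", "qpd_y_nm", "qpd_z_nm", "stage_x_nm", "stage_y_nm"]


def write_stack(path: str | Path, stack: ImageStackSequence) -> None:
    """Write a stack as multi-page TIFF + YAML sidecar (+ ground-truth CSV)."""
    path = Path(path)
    cfg = stack.config
    pages = [
        stack.frames[t][h].astype(np.float32)
        for h in cfg.heights_um
        for t in range(stack.n_frames)
    ]
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {
        "pixel_um": cfg.pixel_um,
        "frame_interval_s": cfg.frame_interval_s,
        "heights_um": list(cfg.heights_um),
        "image_shape": list(cfg.image_shape),
        "background_level": cfg.background_level,
        "defocus_blur_per_um": cfg.defocus_blur_per_um,
        "n_frames": stack.n_frames,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    if stack.ground_truth is not None:
        gt = stack.ground_truth
        pd.DataFrame(
            {
                "frame": np.arange(stack.n_frames),
                "true_edge_um": gt.true_edge_um,
                "true_height_um": gt.true_height_um,
            }
        ).to_csv(path.with_suffix(".truth.csv"), index=False)


def read_stack(path: str | Path) -> ImageStackSequence:
    """Read a multi-page TIFF + sidecar back into an ImageStackSequence.

    The page count must equal n_heights × n_frames; a mismatch is an error
    naming the expected and found counts.
    """
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cfg = ImagingConfig(
        pixel_um=meta["pixel_um"],
        frame_interval_s=meta["frame_interval_s"],
        heights_um=tuple(meta["heights_um"]),
        image_shape=tuple(meta["image_shape"]),
        background_level=meta.get("background_level", 100.0),
        defocus_blur_per_um=meta.get("defocus_blur_per_um", 0.3),
    )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_heights = len(cfg.heights_um)
    if pages.shape[0] % n_heights != 0:
        raise ValueError(
            f"page count mismatch: found {pages.shape[0]} pages, expected a "
            f"multiple of {n_heights} heights"
        )
    n_frames = pages.shape[0] // n_heights
    if "n_frames" in meta and meta["n_frames"] != n_frames:
        raise ValueError(
            f"page count mismatch: found {n_frames} frames, sidecar says {meta['n_frames']}"
        )
    frames = []
    for t in range(n_frames):
        frames.append(
            {
                h: pages[hi * n_frames + t].astype(float)
                for hi, h in enumerate(cfg.heights_um)
            }
        )
    gt = None
    truth_path = path.with_suffix(".truth.csv")
    if truth_path.exists():
        df = pd.read_csv(truth_path)
        gt = StackGroundTruth(
            params=None,
            base_um=float(df["true_edge_um"].iloc[0]),
            true_edge_um=df["true_edge_um"].to_numpy(),
            true_height_um=df["true_height_um"].to_numpy(),
        )
    return ImageStackSequence(frames=frames, config=cfg, ground_truth=gt)


def write_bead_trace(path: str | Path, trace: BeadTrace) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t_s,
            "qpd_x_nm": trace.qpd_xyz_nm[:, 0],
            "qpd_y_nm": trace.qpd_xyz_nm[:, 1],
            "qpd_z_nm": trace.qpd_xyz_nm[:, 2],
            "stage_x_nm": trace.stage_xy_nm[:, 0],
            "stage_y_nm": trace.stage_xy_nm[:, 1],
        }
    ).to_csv(path, index=False)


def read_bead_trace(path: str | Path, config: BeadSimConfig) -> BeadTrace:
    df = pd.read_csv(path)
    missing = [c for c in BEAD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bead trace CSV missing columns: {missing}")
    return BeadTrace(
        t_s=df["t_s"].to_numpy(),
        qpd_xyz_nm=df[["qpd_x_nm", "qpd_y_nm", "qpd_z_nm"]].to_numpy(),
        stage_xy_nm=df[["stage_x_nm", "stage_y_nm"]].to_numpy(),
        config=config,
    )


_KNOWN_KEYS = {
    "seed",
    "outdir",
    "stages",
    "imaging",
    "motility",
    "bead",
    "filopodia",
    "algorithm",
    "conditions",
}
_KNOWN_ALGO_KEYS = {
    "sigma_small",
    "sigma_large",
    "dog_k",
    "smooth_window",
    "min_period_s",
    "focus_tol",
    "height_threshold",
    "floor_pn",
    "min_duration_s",
    "merge_gap_s",
    "away_vector",
    "search_radius_px",
}


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end run. Unknown keys rejected."""

    seed: int = 0
    outdir: str = "gcmotility_out"
    stages: tuple[str, ...] = ("simulate", "kymo", "height", "force", "filo", "stats")
    imaging: dict = field(default_factory=dict)
    motility: dict = field(default_factory=dict)
    bead: dict = field(default_factory=dict)
    filopodia: dict = field(default_factory=dict)
    algorithm: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.algorithm) - _KNOWN_ALGO_KEYS
        if bad:
            raise ValueError(f"unknown algorithm keys: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run the requested stages end to end; failures of one stage are
    recorded and the remaining independent stages still run.

    Returns a results bundle (per-stage outputs, errors, output paths); all
    CSV outputs and the run log land in ``config.outdir`` and carry the
    config hash.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    results: dict = {"config_hash": digest, "errors": {}, "warnings": []}
    run_log: list[str] = [f"config_hash: {digest}", f"seed: {config.seed}"]

    algo = dict(config.algorithm)
    stack = None
    bead_trace = None
    filo_truths = filo_movie = None

    if "simulate" in config.stages:
        # The three generators are independent; one failing (e.g. a missing
        # stiffness in the bead config) must not block the imaging stages.
        try:
            img_cfg = ImagingConfig(**config.imaging)
            params = MotilityParams(seed=config.seed, **config.motility)
            stack = generate_lamellipodium_stack(params, img_cfg)
            write_stack(outdir / f"stack_{digest}.tif", stack)
            results["simulate"] = {"n_frames": stack.n_frames}
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            results["errors"]["simulate"] = str(exc)
            log.error("simulate (imaging) failed: %s", exc)
        try:
            bead_cfg = BeadSimConfig(seed=config.seed, **config.bead)
            bead_trace = generate_bead_trace(bead_cfg)
            write_bead_trace(outdir / f"bead_{digest}.csv", bead_trace)
        except Exception as exc:  # noqa: BLE001
            results["errors"]["simulate.bead"] = str(exc)
            log.error("simulate (bead) failed: %s", exc)
        try:
            filo_kwargs = dict(config.filopodia) or {
                "n": 3,
                "rate_um_s": 0.10,
                "max_len_um": 3.36,
                "frame_interval_s": 2.0,
            }
            filo_truths, filo_movie = generate_filopodium_tracks(
                seed=config.seed, **filo_kwargs
            )
        except Exception as exc:  # noqa: BLE001
            results["errors"]["simulate.filo"] = str(exc)
            log.error("simulate (filopodia) failed: %s", exc)

    if "kymo" in config.stages and stack is not None:
        try:
            metrics, profile, kymo = kymograph.analyze_stack(
                stack,
                sigma_small=algo.get("sigma_small", 1.0),
                sigma_large=algo.get("sigma_large", 3.0),
                k=algo.get("dog_k", 2.0),
                smooth_window=algo.get("smooth_window", 3),
                min_period_s=algo.get("min_period_s", 20.0),
            )
            results["kymo"] = metrics
            results["warnings"] += profile.warnings
            pd.DataFrame(
                [
                    {
                        "line_id": 0,
                        "T_s": metrics.period_s,
                        "dl_um": metrics.persistence_um,
                        "dxdt_um_s": metrics.retro_rate_um_s,
                        "n_cycles": metrics.n_cycles,
                        "config_hash": digest,
                    }
                ]
            ).to_csv(outdir / f"cycle_metrics_{digest}.csv", index=False)
            tifffile.imwrite(
                outdir / f"kymograph_{digest}.tif", kymo.data.astype(np.float32)
            )
        except Exception as exc:  # noqa: BLE001
            results["errors"]["kymo"] = str(exc)
            log.error("kymo stage failed: %s", exc)

    if "height" in config.stages and stack is not None:
        try:
            series = defocus.fractional_height_series(
                stack, tol=algo.get("focus_tol")
            )
            results["height"] = series
            long = []
            for hi, h in enumerate(series.heights_um):
                for ti, t in enumerate(series.times_s):
                    long.append(
                        {
                            "t_s": t,
                            "height_um": h,
                            "fraction": series.fractions[hi, ti],
                            "flagged": bool(series.flagged[ti]),
                            "config_hash": digest,
                        }
                    )
            pd.DataFrame(long).to_csv(
                outdir / f"fractional_height_{digest}.csv", index=False
            )
        except Exception as exc:  # noqa: BLE001
            results["errors"]["height"] = str(exc)
            log.error("height stage failed: %s", exc)

    if "force" in config.stages and bead_trace is not None:
        try:
            ft = force.force_trace(bead_trace)
            events = force.analyze_events(
                ft,
                away_vector=tuple(algo.get("away_vector", (1.0, 0.0, 0.0))),
                floor_pn=algo.get("floor_pn", 1.0),
                min_duration_s=algo.get("min_duration_s", 2.0),
                merge_gap_s=algo.get("merge_gap_s", 1.0),
            )
            results["force"] = events
            results["warnings"] += ft.flags
            pd.DataFrame(
                {
                    "t_s": ft.t_s,
                    "F_x": ft.force_pn[:, 0],
                    "F_y": ft.force_pn[:, 1],
                    "F_z": ft.force_pn[:, 2],
                    "comp_x_nm": ft.compensated_xy_nm[:, 0],
                    "comp_y_nm": ft.compensated_xy_nm[:, 1],
                }
            ).to_csv(outdir / f"force_{digest}.csv", index=False)
            pd.DataFrame(
                [
                    {
                        "start_s": e.window_s[0],
                        "end_s": e.window_s[1],
                        "behaviour": e.behaviour,
                        "max_force_pn": e.max_force_pn,
                        "config_hash": digest,
                    }
                    for e in events
                ]
            ).to_csv(outdir / f"events_{digest}.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            results["errors"]["force"] = str(exc)
            log.error("force stage failed: %s", exc)

    if "filo" in config.stages and filo_movie is not None:
        try:
            fi_cfg = dict(config.filopodia)
            pixel_um = fi_cfg.get("pixel_um", 0.1)
            dt = fi_cfg.get("frame_interval_s", 2.0)
            seeds = [t.tip_at(0.0, pixel_um) for t in filo_truths]
            bases = [t.base_px for t in filo_truths]
            tracks = filopodia.track_tips(
                filo_movie,
                seeds,
                bases_px=bases,
                pixel_um=pixel_um,
                frame_interval_s=dt,
                search_radius_px=algo.get("search_radius_px", 10.0),
            )
            rows, summary = [], []
            for fid, tr in enumerate(tracks):
                for ti, t in enumerate(tr.times_s):
                    rows.append(
                        {
                            "filo_id": fid,
                            "t_s": t,
                            "tip_x": tr.tip_px[ti, 1],
                            "tip_y": tr.tip_px[ti, 0],
                            "length_um": tr.lengths_um[ti],
                        }
                    )
                summary.append(
                    {
                        "filo_id": fid,
                        "max_length_um": filopodia.max_length(tr),
                        "rate_um_s": filopodia.protrusion_rate_filo(tr),
                        "config_hash": digest,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / f"filo_tracks_{digest}.csv", index=False)
            pd.DataFrame(summary).to_csv(
                outdir / f"filo_summary_{digest}.csv", index=False
            )
            results["filo"] = summary
        except Exception as exc:  # noqa: BLE001
            results["errors"]["filo"] = str(exc)
            log.error("filo stage failed: %s", exc)

    if "stats" in config.stages:
        try:
            groups: dict[str, dict[str, list]] = {}
            if "kymo" in results and not isinstance(results.get("kymo"), dict):
                m = results["kymo"]
                groups.setdefault("run", {})["period_s"] = [m.period_s]
                groups["run"]["persistence_um"] = [m.persistence_um]
                groups["run"]["retro_rate_um_s"] = [m.retro_rate_um_s]
            if results.get("filo"):
                groups.setdefault("run", {})["filo_rate_um_s"] = [
                    s["rate_um_s"] for s in results["filo"]
                ]
            if groups:
                table = stats.summary_table(
                    groups,
                    units={
                        "period_s": "s",
                        "persistence_um": "um",
                        "retro_rate_um_s": "um/s",
                        "filo_rate_um_s": "um/s",
                    },
                )
                table["config_hash"] = digest
                table.to_csv(outdir / f"summary_{digest}.csv", index=False)
                results["stats"] = table
        except Exception as exc:  # noqa: BLE001
            results["errors"]["stats"] = str(exc)
            log.error("stats stage failed: %s", exc)

    run_log += [f"error[{k}]: {v}" for k, v in results["errors"].items()]
    run_log += [f"warning: {w}" for w in results["warnings"]]
    (outdir / f"run_{digest}.log").write_text("\n".join(run_log) + "\n")
    return results
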