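"""Stage orchestration: simulate -> reslice -> train -> score -> report.

Each stage reads its inputs from the run's output directory (or from the
objects produced by an earlier stage in the same call), writes its documented
artifacts there, and records every file in the run manifest together with the
config hash, the seed, and stage durations.  Reruns with identical config and
seed reproduce the score CSVs bit for bit.

Stage layout under ``output_dir``::

    phantoms/subjXX[_lumen|_thrombus].nii, subjXX_centerline.txt, labels.csv
    stacks/subjXX.nii + subjXX_manifest.csv
    model/checkpoint.npz, loss_history.csv
    scores/per_slice.csv, per_subject.csv, partition.json
    report/latent_grid.png, track_subjXX.png
    manifest.json
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from . import phantom as ph
from . import reslice as rs
from . import scoring as sc
from . import vae
from .config import RunConfig
from .types import CrossSection, SliceLabel

log = logging.getLogger("flvae")

STAGES = ("simulate", "reslice", "train", "score", "report")


class PipelineError(RuntimeError):
    pass


def _subject_ids(cfg: RunConfig) -> List[str]:
    n_d, n_c = cfg.phantom.n_dissected, cfg.phantom.n_control
    return ([f"dissected{i + 1:02d}" for i in range(n_d)]
            + [f"control{i + 1:02d}" for i in range(n_c)])


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage '{stage}': missing upstream artifact {path}")
    return path


def simulate(cfg: RunConfig, out: Path) -> List[Path]:
    """Generate the synthetic cohort (volumes or slice stacks)."""
    seed0 = cfg.stage_seed("simulate")
    pcfg = cfg.phantom
    written: List[Path] = []
    labels_rows = []
    if pcfg.mode == "volumes":
        pdir = out / "phantoms"
        pdir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(_subject_ids(cfg)):
            label = SliceLabel(pcfg.dissected_label) if sid.startswith("dissected") \
                else SliceLabel.NO_FL
            vp = ph.make_phantom_volume(pcfg.spec, pcfg.slices_per_subject,
                                        seed=seed0 + i, label=label)
            written += fio.save_volume_phantom(vp, pdir / sid)
            labels_rows.append((sid, label.value))
        lab = pdir / "labels.csv"
        pd.DataFrame(labels_rows, columns=["subject_id", "label"]).to_csv(lab,
                                                                          index=False)
        written.append(lab)
    elif pcfg.mode == "slices":
        sdir = out / "stacks"
        sdir.mkdir(parents=True, exist_ok=True)
        n = pcfg.slices_per_subject
        for i, sid in enumerate(_subject_ids(cfg)):
            if sid.startswith("dissected"):
                n_part = int(round(pcfg.partial_fraction * n))
                counts = {SliceLabel(pcfg.dissected_label): n - n_part,
                          SliceLabel.PARTIAL_FL: n_part}
                if SliceLabel(pcfg.dissected_label) is SliceLabel.PARTIAL_FL:
                    counts = {SliceLabel.PARTIAL_FL: n}
            else:
                counts = {SliceLabel.NO_FL: n}
            slices, table = ph.make_phantom_cohort(pcfg.spec, counts,
                                                   seed=seed0 + i, subject_id=sid)
            centered = [rs.apply_mask_and_center(s) for s in slices]
            written += fio.save_stack(centered, sdir / sid)
            table.to_csv(sdir / f"{sid}_labels.csv", index=False)
            written.append(sdir / f"{sid}_labels.csv")
    else:
        raise PipelineError(f"unknown phantom mode {pcfg.mode!r}")
    return written


def reslice_stage(cfg: RunConfig, out: Path) -> List[Path]:
    """Perpendicular reslicing of simulated volumes into centered stacks."""
    if cfg.phantom.mode == "slices":
        log.info("reslice: phantom mode 'slices' already produced stacks; skipping")
        return []
    pdir = _require(out / "phantoms", "reslice")
    sdir = out / "stacks"
    sdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    rcfg = cfg.reslice
    for sid in _subject_ids(cfg):
        _require(pdir / f"{sid}.nii", "reslice")
        vp = fio.load_volume_phantom(pdir / sid)
        cl = rs.resample_centerline(vp.centerline_truth, rcfg.step_mm)
        frames = rs.compute_frames(cl)
        sections = rs.extract_cross_sections(
            vp.intensities, vp.spacing_mm, cl, frames, rcfg.fov_mm, rcfg.grid_n,
            lumen_mask=vp.lumen_mask, thrombus_mask=vp.thrombus_mask,
            subject_id=sid)
        if (rcfg.window_lo, rcfg.window_hi) != (0.0, 1.0):
            sections = [rs.normalize_intensity(s, rcfg.window_lo, rcfg.window_hi)
                        for s in sections]
        centered = [rs.apply_mask_and_center(s) for s in sections]
        written += fio.save_stack(centered, sdir / sid)
    return written


def _load_all_stacks(cfg: RunConfig, out: Path, stage: str):
    sdir = _require(out / "stacks", stage)
    images: List[CrossSection] = []
    for sid in _subject_ids(cfg):
        _require(sdir / f"{sid}.nii", stage)
        images += fio.load_stack(sdir / sid)
    return images


def train_stage(cfg: RunConfig, out: Path) -> List[Path]:
    """Train the VAE on all subjects' stacks and checkpoint it."""
    images = _load_all_stacks(cfg, out, "train")
    vcfg = vae.VAEConfig(seed=cfg.stage_seed("train"),
                         **{k: v for k, v in vars(cfg.vae).items()})
    log.info("training VAE on %d images for %d epochs", len(images), vcfg.epochs)
    params = vae.train(images, vcfg)
    mdir = out / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    ckpt = mdir / "checkpoint.npz"
    vae.save_checkpoint(params, ckpt)
    hist = mdir / "loss_history.csv"
    params.loss_history_frame().to_csv(hist, index=False)
    return [ckpt, hist]


def score_stage(cfg: RunConfig, out: Path) -> List[Path]:
    """Embed all stacks, fit the latent partition, write score tables."""
    ckpt = _require(out / "model" / "checkpoint.npz", "score")
    params = vae.load_checkpoint(ckpt)
    images = _load_all_stacks(cfg, out, "score")
    points = sc.embed_dataset(params, images)
    areas = [sc.foreground_area(im) for im in images]
    axis = cfg.scoring.axis
    if axis == "auto":
        axis = sc.select_axis(points)
        log.info("auto-selected latent axis %d for partitioning", axis)
    partition = sc.fit_partition(points, mode=cfg.scoring.mode,
                                 x0_fixed=cfg.scoring.x0_fixed,
                                 foreground_areas=areas, axis=int(axis),
                                 model_fingerprint=params.fingerprint)
    scdir = out / "scores"
    scdir.mkdir(parents=True, exist_ok=True)
    df = sc.scores_frame(points, partition, images, cfg.scoring.colormap_bins)
    per_slice = scdir / "per_slice.csv"
    df.to_csv(per_slice, index=False)
    summary = (df.groupby("subject_id", sort=True)["ts"]
               .agg(n_slices="size", mean_ts="mean").reset_index())
    per_subject = scdir / "per_subject.csv"
    summary.to_csv(per_subject, index=False)
    pjson = scdir / "partition.json"
    pjson.write_text(partition.to_json())
    return [per_slice, per_subject, pjson]


def report_stage(cfg: RunConfig, out: Path) -> List[Path]:
    """Render the decoder latent grid and per-subject score tracks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ckpt = _require(out / "model" / "checkpoint.npz", "report")
    per_slice = _require(out / "scores" / "per_slice.csv", "report")
    params = vae.load_checkpoint(ckpt)
    rdir = out / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    written = []

    panel = vae.latent_grid_panel(params, -3.0, 3.0, n=15)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(panel, cmap="gray", extent=(-3, 3, 3, -3))
    ax.set_xlabel("latent x")
    ax.set_ylabel("latent y")
    grid_png = rdir / "latent_grid.png"
    fig.savefig(grid_png, dpi=120)
    plt.close(fig)
    written.append(grid_png)

    df = pd.read_csv(per_slice)
    bins = cfg.scoring.colormap_bins
    for sid, g in df.groupby("subject_id"):
        fig, ax = plt.subplots(figsize=(8, 1.6))
        track = g.sort_values("slice_index")["ts"].to_numpy()[None, :]
        im = ax.imshow(track, aspect="auto", cmap="jet", vmin=0, vmax=1,
                       interpolation="nearest")
        ax.set_yticks([])
        ax.set_xlabel("slice index")
        ax.set_title(f"{sid}: mean ts = {g['ts'].mean():.3f}")
        fig.colorbar(im, ax=ax, label=f"thrombus score ({bins} bins)")
        p = rdir / f"track_{sid}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written


_STAGE_FN = {"simulate": simulate, "reslice": reslice_stage, "train": train_stage,
             "score": score_stage, "report": report_stage}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    bad = sorted(set(stages) - set(STAGES))
    if bad:
        raise PipelineError(f"unknown stage(s): {', '.join(bad)}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    for stage in [s for s in STAGES if s in set(stages)]:
        t0 = time.time()
        log.info("running stage '%s'", stage)
        files = _STAGE_FN[stage](cfg, out)
        manifest["stages"][stage] = {
            "duration_s": round(time.time() - t0, 3),
            "outputs": sorted(str(Path(f).relative_to(out)) for f in files),
        }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
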