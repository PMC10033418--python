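"""Staged pipeline: each stage consumes prior artifacts by documented names.

Artifact filenames (inside the output directory):

    simulate         -> grayscale.tif, classes.tif, instances_truth.tif,
                        instance_table.csv
    segment-train    -> model.npz, loss_history.csv   (needs simulate)
    segment-predict  -> classes_pred.tif              (needs model + grayscale)
    segment-eval     -> seg_metrics.csv               (needs prediction + truth)
    instances        -> instances.tif                 (mitochondria labels from
                        classes_pred.tif if present, else classes.tif)
    morph            -> morphometry.csv               (needs instances)
    distance         -> distances.csv, morphometry.csv updated (needs instances
                        + a nucleus mask from classes)
    motility         -> motility.csv                  (self-contained synthetic
                        series from the config)
    compartments     -> contacts.csv, compartments.csv (needs instances +
                        classes for nucleus and droplets)
    phenotype        -> phenotypes.csv                (needs uptake.csv in the
                        output directory)

A manifest (manifest.json) records the config hash, seeds, package and
library versions and any warnings; rerunning with an identical config
reproduces identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartments import (TracerMeasurement, classify_compartments, classify_tracer_uptake,
                           detect_contacts, quantify_lipid_droplets)
from .config import PipelineConfig, dump_config, load_config
from .grids import VolumeGrid
from .io import read_volume, write_volume
from .morphometry import label_components, measure_components
from .motility import analyze_motility
from .nn import build_model, predict_mask, train_model
from .nn.model import load_model, save_model
from .segmentation import evaluate_segmentation
from .spatial import mito_nucleus_distances_3d
from .synthetic import generate_cell_volume, generate_motility_series

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "segment-train", "segment-predict", "segment-eval", "instances",
          "morph", "distance", "motility", "compartments", "phenotype")


class MissingArtifactError(FileNotFoundError):
    pass


def _need(out: Path, name: str, producer: str) -> Path:
    p = out / name
    if not p.exists():
        raise MissingArtifactError(
            f"missing artifact {name!r}: run the {producer!r} stage first")
    return p


def run_pipeline(config, stages, out_dir) -> Path:
    """Run the requested stages in canonical order; returns the artifact dir."""
    cfg: PipelineConfig = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in stages]
    vs = tuple(cfg.scene.voxel_size_nm)
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for stage in ordered:
            _RUNNERS[stage](cfg, out, vs)
        caught = [str(w.message) for w in wlist]

    manifest = {
        "config_sha256": hashlib.sha256(dump_config(cfg).encode()).hexdigest(),
        "stages": ordered,
        "seeds": {"scene": cfg.scene.seed, "net": cfg.net.seed,
                  "train": cfg.train.seed, "motility": cfg.motility.seed},
        "versions": {"mitomap": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(dump_config(cfg))
    return out


def _stage_simulate(cfg, out, vs):
    gray, truth = generate_cell_volume(cfg.scene.to_scene_spec())
    write_volume(out / "grayscale.tif", gray)
    write_volume(out / "classes.tif", truth.class_volume)
    write_volume(out / "instances_truth.tif", truth.instance_volume)
    truth.instance_table.to_csv(out / "instance_table.csv", index=False)


def _train_slices(cfg, out, vs):
    gray = read_volume(_need(out, "grayscale.tif", "simulate"), vs)
    classes = read_volume(_need(out, "classes.tif", "simulate"), vs)
    f = cfg.net.max_downsampling_factor
    nz = gray.shape[0]
    picks = sorted(set(int(i) for i in np.linspace(0, nz - 1, 4)))
    h = (gray.shape[1] // f) * f
    w = (gray.shape[2] // f) * f
    data = []
    for k in picks:
        img = np.asarray(gray.data[k, :h, :w], dtype=np.float32)
        lab = np.asarray(classes.data[k, :h, :w])
        lab = np.where(lab == 3, 0, lab)  # droplets count as background for the net
        data.append((img, lab.astype(np.int64)))
    return data


def _stage_segment_train(cfg, out, vs):
    data = _train_slices(cfg, out, vs)
    model = build_model(cfg.net.to_net_config())
    model, history = train_model(model, data, cfg.train.to_train_config())
    save_model(model, out / "model.npz")
    pd.DataFrame({"epoch": np.arange(1, len(history) + 1), "loss": history}).to_csv(
        out / "loss_history.csv", index=False)


def _stage_segment_predict(cfg, out, vs):
    model = load_model(_need(out, "model.npz", "segment-train"))
    gray = read_volume(_need(out, "grayscale.tif", "simulate"), vs)
    f = model.config.max_downsampling_factor
    h = (gray.shape[1] // f) * f
    w = (gray.shape[2] // f) * f
    stack = np.asarray(gray.data[:, :h, :w], dtype=np.float32)
    pred = predict_mask(model, stack)
    full = np.zeros(gray.shape, dtype=np.uint8)
    full[:, :h, :w] = pred
    write_volume(out / "classes_pred.tif", VolumeGrid(full, vs))


def _stage_segment_eval(cfg, out, vs):
    pred = read_volume(_need(out, "classes_pred.tif", "segment-predict"), vs)
    truth = read_volume(_need(out, "classes.tif", "simulate"), vs)
    t = np.where(np.asarray(truth.data) == 3, 0, np.asarray(truth.data))
    rows = []
    for k in range(pred.shape[0]):
        m = evaluate_segmentation(pred.data[k], t[k])
        rows.append(dict(slice=k, dice=m.dice, iou=m.iou,
                         precision=m.precision, recall=m.recall))
    m = evaluate_segmentation(np.asarray(pred.data), t)
    rows.append(dict(slice="macro", dice=m.dice, iou=m.iou,
                     precision=m.precision, recall=m.recall))
    pd.DataFrame(rows).to_csv(out / "seg_metrics.csv", index=False)


def _stage_instances(cfg, out, vs):
    src = out / "classes_pred.tif"
    if not src.exists():
        src = _need(out, "classes.tif", "simulate")
    classes = read_volume(src, vs)
    mito = classes.like((np.asarray(classes.data) == 2).astype(np.uint8))
    labels = label_components(mito, connectivity=cfg.instances.connectivity)
    write_volume(out / "instances.tif", labels)


def _stage_morph(cfg, out, vs):
    labels = read_volume(_need(out, "instances.tif", "instances"), vs)
    records = measure_components(labels)
    df = pd.DataFrame([dict(
        instance_id=r.instance_id, voxel_count=r.voxel_count, volume_um3=r.volume,
        surface_area_um2=r.surface_area, length_um=r.length, sphericity=r.sphericity,
        centroid_x_um=r.centroid[0], centroid_y_um=r.centroid[1],
        centroid_z_um=r.centroid[2]) for r in records])
    df.to_csv(out / "morphometry.csv", index=False)


def _stage_distance(cfg, out, vs):
    labels = read_volume(_need(out, "instances.tif", "instances"), vs)
    classes = read_volume(_need(out, "classes.tif", "simulate"), vs)
    nucleus = classes.like(np.asarray(classes.data) == 1)
    dists = mito_nucleus_distances_3d(labels, nucleus, mode=cfg.distance.mode)
    df = pd.DataFrame(sorted(dists.items()), columns=["instance_id", "nucleus_distance_um"])
    df.to_csv(out / "distances.csv", index=False)
    morph_path = out / "morphometry.csv"
    if morph_path.exists():
        morph = pd.read_csv(morph_path)
        morph = morph.merge(df, on="instance_id", how="left")
        morph.to_csv(morph_path, index=False)


def _stage_motility(cfg, out, vs):
    mc = cfg.motility
    series, v_true = generate_motility_series(
        {"shape": (128, 128), "n_blobs": 6, "blob_radius": 5},
        mc.velocity_px_per_frame, n_frames=mc.n_frames, dt_s=mc.dt_s, seed=mc.seed)
    res = analyze_motility(series)
    row = dict(true_velocity_px_per_frame=v_true, slope_per_s=res.slope,
               intercept=res.intercept,
               excluded="|".join(f"{n}:{why}" for n, why in res.excluded_frames))
    for n in sorted(res.ratios):
        row[f"ratio_frame_{n}"] = res.ratios[n]
    pd.DataFrame([row]).to_csv(out / "motility.csv", index=False)


def _stage_compartments(cfg, out, vs):
    labels = read_volume(_need(out, "instances.tif", "instances"), vs)
    classes = read_volume(_need(out, "classes.tif", "simulate"), vs)
    arr = np.asarray(classes.data)
    nucleus = classes.like(arr == 1)
    ld_mask = classes.like((arr == 3).astype(np.uint8))
    ld_labels = label_components(ld_mask, connectivity=cfg.instances.connectivity)
    params = cfg.contacts.to_contact_params()
    flags = detect_contacts(labels, ld_labels, nucleus, params)
    flags, pct = classify_compartments(flags, params)
    flags.to_csv(out / "contacts.csv", index=False)
    _, ld_totals = quantify_lipid_droplets(ld_labels)
    summary = dict(pct_PNM=pct["PNM"], pct_PDM=pct["PDM"], pct_CM=pct["CM"],
                   n_mitochondria=len(flags), ld_count=ld_totals["count"],
                   ld_total_volume_um3=ld_totals["total_volume_um3"],
                   ld_contact_max_nm=params.ld_contact_max,
                   pnm_distance_max_nm=params.pnm_distance_max)
    pd.DataFrame([summary]).to_csv(out / "compartments.csv", index=False)


def _stage_phenotype(cfg, out, vs):
    path = out / "uptake.csv"
    if not path.exists():
        raise MissingArtifactError(
            "missing artifact 'uptake.csv': place an uptake table (columns tracer, "
            "tumour_uptake, heart_uptake) in the output directory first")
    df = pd.read_csv(path)
    out_rows = []
    for _, row in df.iterrows():
        m = TracerMeasurement(row["tracer"], row["tumour_uptake"], row["heart_uptake"])
        out_rows.append(dict(tracer=m.tracer, tumour_uptake=m.tumour_uptake,
                             heart_uptake=m.heart_uptake, ratio=m.ratio,
                             phenotype=classify_tracer_uptake(m)))
    pd.DataFrame(out_rows).to_csv(out / "phenotypes.csv", index=False)


_RUNNERS = {
    "simulate": _stage_simulate,
    "segment-train": _stage_segment_train,
    "segment-predict": _stage_segment_predict,
    "segment-eval": _stage_segment_eval,
    "instances": _stage_instances,
    "morph": _stage_morph,
    "distance": _stage_distance,
    "motility": _stage_motility,
    "compartments": _stage_compartments,
    "phenotype": _stage_phenotype,
}
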