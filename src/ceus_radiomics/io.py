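"""On-disk study layout.

Sequences are multi-page 32-bit float TIFF (one page per frame), masks
single-page 8-bit TIFF, per-scan metadata and ground truth a JSON
sidecar, and the study manifest a CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import CEUSSequence, GroundTruth, ROIMask, ScanRecord, Study


def write_sequence(seq: CEUSSequence, path: Path) -> None:
    tifffile.imwrite(path, seq.frames.astype(np.float32))


def read_sequence(path: Path, meta: dict) -> CEUSSequence:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return CEUSSequence(frames=frames.astype(np.float32),
                        frame_rate=float(meta["frame_rate"]),
                        destruction_frame=int(meta["destruction_frame"]),
                        scan_id=meta.get("scan_id", ""),
                        mouse_id=meta.get("mouse_id", ""),
                        model_label=meta.get("model_label", ""),
                        position_id=meta.get("position_id", ""))


def write_mask(mask: np.ndarray, path: Path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8) * 255)


def read_mask(path: Path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_study(study: Study, out_dir: str | Path) -> Path:
    """Write every scan of a study plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in study.scans:
        seq = rec.seq
        stem = seq.scan_id or f"scan{len(rows):03d}"
        seq_path = out / f"{stem}.tif"
        write_sequence(seq, seq_path)
        roi_paths = []
        for roi in rec.rois:
            p = out / f"{stem}_{roi.user_id}.tif"
            write_mask(roi.mask, p)
            roi_paths.append(p.name)
        truth_mask_path = out / f"{stem}_truth_vessels.tif"
        write_mask(rec.truth.true_vessel_mask, truth_mask_path)
        meta = dict(scan_id=seq.scan_id, mouse_id=seq.mouse_id,
                    model_label=seq.model_label, position_id=seq.position_id,
                    dataset=rec.dataset, frame_rate=seq.frame_rate,
                    destruction_frame=seq.destruction_frame,
                    true_beta=rec.truth.true_beta, true_rbv=rec.truth.true_rbv,
                    true_network_length=rec.truth.true_network_length,
                    true_artifact_frames=sorted(rec.truth.true_artifact_frames),
                    roi_files=roi_paths, sequence_file=seq_path.name,
                    truth_vessel_file=truth_mask_path.name)
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=1))
        rows.append(dict(scan_id=seq.scan_id, mouse_id=seq.mouse_id,
                         model_label=seq.model_label, position_id=seq.position_id,
                         dataset=rec.dataset, sequence_file=seq_path.name,
                         sidecar=f"{stem}.json"))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_study(manifest_path: str | Path) -> Study:
    """Load a study written by :func:`write_study`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    study = Study()
    for _, row in df.iterrows():
        meta = json.loads((root / row["sidecar"]).read_text())
        seq = read_sequence(root / meta["sequence_file"], meta)
        rois = [ROIMask(read_mask(root / p), user_id=Path(p).stem.split("_")[-1])
                for p in meta["roi_files"]]
        truth = GroundTruth(
            true_vessel_mask=read_mask(root / meta["truth_vessel_file"]),
            true_beta=float(meta["true_beta"]),
            true_rbv=float(meta["true_rbv"]),
            true_network_length=int(meta["true_network_length"]),
            true_artifact_frames=frozenset(meta["true_artifact_frames"]))
        study.scans.append(ScanRecord(seq=seq, truth=truth, rois=rois,
                                      dataset=int(meta["dataset"])))
    return study
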