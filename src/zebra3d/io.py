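"""File formats: poses (CSV/JSON), dot observations (CSV), image stacks.

Pose CSV columns: the 22 adjustable parameters in their canonical order
(x0, y0, z0, theta0, dtheta1..8, phi0, dphi1..8, gamma0) plus ``length``;
angles in radians, positions and length in mm. Dot-observation CSV
columns: dot_id, camera, medium (air|water), x_px, y_px.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .body import FishPose
from .ensemble import PoseEnsemble

__all__ = [
    "POSE_COLUMNS",
    "poses_to_frame",
    "frame_to_poses",
    "save_poses_csv",
    "load_poses_csv",
    "save_pose_json",
    "load_pose_json",
    "save_dot_observations",
    "load_dot_observations",
    "save_training_set",
    "load_training_set",
    "write_image_stack",
    "read_image_stack",
]

POSE_COLUMNS = (["x0", "y0", "z0", "theta0"]
                + [f"dtheta{i}" for i in range(1, 9)] + ["phi0"]
                + [f"dphi{i}" for i in range(1, 9)] + ["gamma0", "length"])


def poses_to_frame(poses: list[FishPose] | PoseEnsemble) -> pd.DataFrame:
    if isinstance(poses, PoseEnsemble):
        poses = poses.poses
    rows = [np.concatenate([p.to_vector(), [p.length]]) for p in poses]
    return pd.DataFrame(rows, columns=POSE_COLUMNS)


def frame_to_poses(df: pd.DataFrame) -> list[FishPose]:
    missing = set(POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    return [FishPose.from_vector(row[:22].to_numpy(dtype=float),
                                 length=float(row["length"]))
            for _, row in df[POSE_COLUMNS].iterrows()]


def save_poses_csv(path: str, poses) -> None:
    poses_to_frame(poses).to_csv(path, index=False)


def load_poses_csv(path: str) -> list[FishPose]:
    return frame_to_poses(pd.read_csv(path))


def save_pose_json(path: str, pose: FishPose) -> None:
    doc = dict(zip(POSE_COLUMNS, np.concatenate([pose.to_vector(),
                                                 [pose.length]]).tolist()))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_pose_json(path: str) -> FishPose:
    with open(path) as fh:
        doc = json.load(fh)
    vec = np.array([doc[c] for c in POSE_COLUMNS[:22]])
    return FishPose.from_vector(vec, length=float(doc["length"]))


def save_dot_observations(path: str, obs) -> None:
    """Write a DotGridObservation as the long-format dot CSV."""
    rows = []
    for cam in range(len(obs.pixels_air)):
        for medium, pix in (("air", obs.pixels_air[cam]),
                            ("water", obs.pixels_water[cam])):
            for n, (x, y) in enumerate(pix):
                rows.append((int(obs.dot_ids[n]), cam, medium, x, y))
    pd.DataFrame(rows, columns=["dot_id", "camera", "medium", "x_px", "y_px"]) \
        .to_csv(path, index=False)


def load_dot_observations(path: str):
    """Read the dot CSV back into per-camera air/water pixel arrays.

    Returns (dot_ids, pixels_air, pixels_water), each pixels list indexed
    by camera.
    """
    df = pd.read_csv(path)
    cams = sorted(df["camera"].unique())
    ids = np.sort(df["dot_id"].unique())
    out = {"air": [], "water": []}
    for medium in ("air", "water"):
        for cam in cams:
            sub = df[(df.camera == cam) & (df.medium == medium)] \
                .set_index("dot_id").loc[ids]
            out[medium].append(sub[["x_px", "y_px"]].to_numpy(dtype=float))
    return ids, out["air"], out["water"]


def save_training_set(directory: str, examples, seed: int | None = None) -> str:
    """Write training examples as per-example PNGs plus JSON annotations.

    Layout: ``ex{i:06d}_cam{c}.png`` for the three views,
    ``ex{i:06d}.json`` with keypoints/crop origins, and a ``manifest.csv``
    tying them together. Returns the manifest path.
    """
    import os

    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, ex in enumerate(examples):
        stem = f"ex{i:06d}"
        for c, img in enumerate(ex.images):
            iio.imwrite(f"{directory}/{stem}_cam{c}.png", img)
        doc = {"keypoints": ex.keypoints.tolist()}
        if ex.crop_origins is not None:
            doc["crop_origins"] = np.asarray(ex.crop_origins).tolist()
        if ex.pose is not None:
            doc["pose"] = ex.pose.to_vector().tolist()
            doc["length"] = ex.pose.length
        with open(f"{directory}/{stem}.json", "w") as fh:
            json.dump(doc, fh)
        rows.append((i, stem, seed))
    manifest = f"{directory}/manifest.csv"
    pd.DataFrame(rows, columns=["example_id", "stem", "seed"]) \
        .to_csv(manifest, index=False)
    return manifest


def load_training_set(directory: str):
    """Read a training set written by save_training_set."""
    import imageio.v3 as iio

    from .synthesis import TrainingExample

    df = pd.read_csv(f"{directory}/manifest.csv")
    out = []
    for _, row in df.iterrows():
        stem = row["stem"]
        images = np.stack([iio.imread(f"{directory}/{stem}_cam{c}.png")
                           for c in range(3)])
        with open(f"{directory}/{stem}.json") as fh:
            doc = json.load(fh)
        pose = None
        if "pose" in doc:
            pose = FishPose.from_vector(np.array(doc["pose"]),
                                        length=doc.get("length", 4.0))
        crop = (np.array(doc["crop_origins"])
                if "crop_origins" in doc else None)
        out.append(TrainingExample(images, np.array(doc["keypoints"]),
                                   pose, crop))
    return out


def write_image_stack(path: str, images: np.ndarray) -> None:
    """8-bit grayscale TIFF stack (multi-frame) or single PNG."""
    import imageio.v3 as iio

    images = np.asarray(images)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, images.astype(np.uint8))
    else:
        iio.imwrite(path, images.astype(np.uint8))


def read_image_stack(path: str) -> np.ndarray:
    if path.endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
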