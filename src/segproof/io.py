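"""File formats: label images, boundary maps, scene bundles, tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .graph_core import SuperpixelLabeling
from .synthdata import SceneSpec


def read_label_image(path) -> SuperpixelLabeling:
    """Label image from PNG (16-bit), TIFF (integer), or HDF5 ("labels")."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            arr = f["labels"][()]
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return SuperpixelLabeling(np.asarray(arr).astype(np.int64))


def write_label_image(path, labels: SuperpixelLabeling) -> None:
    path = Path(path)
    arr = labels.labels
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=arr)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.int32))
    else:
        import imageio.v3 as iio

        if arr.max() > np.iinfo(np.uint16).max:
            raise ValueError("label ids exceed 16-bit PNG range")
        iio.imwrite(path, arr.astype(np.uint16))


def read_boundary_map(path) -> np.ndarray:
    """Boundary map from TIFF float or HDF5 ("boundary")."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return f["boundary"][()]
    import tifffile

    return tifffile.imread(path)


def write_boundary_map(path, boundary: np.ndarray) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("boundary", data=np.asarray(boundary, dtype=np.float32))
    else:
        import tifffile

        tifffile.imwrite(path, np.asarray(boundary, dtype=np.float32))


def write_table_h5(path, table) -> None:
    """Pairwise connection table as sparse triplets; tau kept in metadata."""
    import h5py

    pairs = sorted(table.strengths)
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=np.array([p[0] for p in pairs], dtype=np.int64))
        f.create_dataset("v", data=np.array([p[1] for p in pairs], dtype=np.int64))
        f.create_dataset(
            "strength", data=np.array([table.strengths[p] for p in pairs])
        )
        f.attrs["tau"] = table.tau
        f.attrs["fingerprint"] = table.fingerprint


def read_table_h5(path):
    import h5py

    from .connectivity import PairwiseConnectionTable

    with h5py.File(path, "r") as f:
        strengths = {
            (int(u), int(v)): float(s)
            for u, v, s in zip(f["u"][()], f["v"][()], f["strength"][()])
        }
        return PairwiseConnectionTable(
            strengths, float(f.attrs["tau"]), str(f.attrs["fingerprint"])
        )


def write_bundle(
    path,
    gt: SuperpixelLabeling,
    sp: SuperpixelLabeling,
    boundary: np.ndarray,
    spec: Optional[SceneSpec] = None,
) -> None:
    """Scene bundle: HDF5 with gt/sp/boundary plus a JSON spec sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("gt", data=gt.labels)
        f.create_dataset("sp", data=sp.labels)
        f.create_dataset("boundary", data=np.asarray(boundary, dtype=np.float64))
    if spec is not None:
        path.with_suffix(".json").write_text(json.dumps(asdict(spec), indent=2))


def read_bundle(path) -> Tuple[SuperpixelLabeling, SuperpixelLabeling, np.ndarray, Optional[SceneSpec]]:
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        gt = SuperpixelLabeling(f["gt"][()].astype(np.int64))
        sp = SuperpixelLabeling(f["sp"][()].astype(np.int64))
        boundary = f["boundary"][()]
    sidecar = path.with_suffix(".json")
    spec = None
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        doc["shape"] = tuple(doc["shape"])
        spec = SceneSpec(**doc)
    return gt, sp, boundary, spec
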