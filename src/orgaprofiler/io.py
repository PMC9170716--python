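"""Persistence for stacks, masks, layouts, feature tables and factor models.

Image stacks travel as multi-page TIFF (pages = channel x z) or HDF5 groups
with a ``pixels`` dataset laid out channel x z x y x x; label masks as 16-bit
TIFF; tabular artefacts as delimited text; factor models as an HDF5 group
holding scores, per-view loadings and the scaling state.  Every writer leaves
a small JSON manifest next to binary outputs recording seed and parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .factors import FactorModel, ViewScaling
from .imaging import ImageStack
from .synthetic_data import PlateLayout


def write_manifest(path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=str))


# -- image stacks -----------------------------------------------------------


def save_stack_tiff(path, stack: ImageStack) -> None:
    c, z, y, x = stack.pixels.shape
    pages = stack.pixels.reshape(c * z, y, x).astype(np.float32)
    tifffile.imwrite(path, pages, metadata={"channels": list(stack.channels), "n_z": z})


def load_stack_tiff(path, channels=("dna", "actin", "permeability"), n_z: int = 16) -> ImageStack:
    pages = tifffile.imread(path)
    c = len(channels)
    return ImageStack(pages.reshape(c, n_z, *pages.shape[-2:]), tuple(channels))


def save_stack_hdf5(path, stack: ImageStack, key: str = "stack") -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group(key)
        if "pixels" in grp:
            del grp["pixels"]
        grp.create_dataset("pixels", data=stack.pixels.astype(np.float32))
        grp.attrs["channels"] = ",".join(stack.channels)
        grp.attrs["pixel_size"] = stack.pixel_size
        grp.attrs["z_step"] = stack.z_step


def load_stack_hdf5(path, key: str = "stack") -> ImageStack:
    with h5py.File(path, "r") as f:
        grp = f[key]
        return ImageStack(
            grp["pixels"][()],
            tuple(grp.attrs["channels"].split(",")),
            float(grp.attrs["pixel_size"]),
            float(grp.attrs["z_step"]),
        )


def save_mask_tiff(path, mask: np.ndarray) -> None:
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(path, mask.astype(np.uint16))


def load_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


# -- tables -----------------------------------------------------------------


def save_layout(path, layout: PlateLayout) -> None:
    df = layout.wells.copy()
    df.insert(0, "plate_id", layout.plate_id)
    df.to_csv(path, index=False)


def load_layout(path) -> PlateLayout:
    df = pd.read_csv(path)
    plate_id = str(df.pop("plate_id").iloc[0])
    return PlateLayout(plate_id, df)


def read_gmt(path) -> dict[str, set]:
    """Gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# -- factor models ----------------------------------------------------------


def save_factor_model(path, model: FactorModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["k"] = model.k
        f.create_dataset("scores", data=model.scores.to_numpy())
        f.create_dataset("samples", data=np.array(model.scores.index, dtype="S"))
        ve = f.create_dataset("variance_explained", data=model.variance_explained.to_numpy())
        ve.attrs["views"] = ",".join(model.variance_explained.columns)
        for view, w in model.loadings.items():
            grp = f.create_group(f"loadings/{view}")
            grp.create_dataset("w", data=w.to_numpy())
            grp.create_dataset("features", data=np.array(w.index, dtype="S"))
            if model.scaling and view in model.scaling:
                sc = model.scaling[view]
                grp.create_dataset("scale_mean", data=sc.mean.to_numpy())
                grp.create_dataset("scale_sd", data=sc.sd.to_numpy())
                grp.attrs["view_factor"] = sc.view_factor


def load_factor_model(path) -> FactorModel:
    with h5py.File(path, "r") as f:
        k = int(f.attrs["k"])
        samples = [s.decode() for s in f["samples"][()]]
        fnames = [f"F{j + 1}" for j in range(k)]
        scores = pd.DataFrame(f["scores"][()], index=samples, columns=fnames)
        views = f["variance_explained"].attrs["views"].split(",")
        ve = pd.DataFrame(f["variance_explained"][()], index=fnames, columns=views)
        loadings, scaling = {}, {}
        for view in f["loadings"]:
            grp = f[f"loadings/{view}"]
            feats = [s.decode() for s in grp["features"][()]]
            loadings[view] = pd.DataFrame(grp["w"][()], index=feats, columns=fnames)
            if "scale_mean" in grp:
                scaling[view] = ViewScaling(
                    pd.Series(grp["scale_mean"][()], index=feats),
                    pd.Series(grp["scale_sd"][()], index=feats),
                    float(grp.attrs["view_factor"]),
                )
    return FactorModel(
        k=k, scores=scores, loadings=loadings, noise_variance={},
        variance_explained=ve, scaling=scaling or None,
    )
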