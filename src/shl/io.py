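"""HDF5 persistence for dictionaries, gain states, patches and images."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .coding import Dictionary, SparseCode, build_gram
from .homeostasis import GainState, Variant
from .images import ImageSet, PatchBatch

__all__ = [
    "save_dictionary",
    "load_dictionary",
    "save_gain_state",
    "load_gain_state",
    "save_patch_batch",
    "load_patch_batch",
    "save_imageset",
    "load_imageset",
    "codes_to_csv",
]

_GAIN_ATTRS = ("p0", "eta_h", "alpha_h", "alpha_ols", "p_floor")


def save_dictionary(path: str | Path, dictionary: Dictionary) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("atoms", data=dictionary.atoms)
        if dictionary.patch_size is not None:
            d.attrs["patch_size"] = dictionary.patch_size


def load_dictionary(path: str | Path) -> Dictionary:
    with h5py.File(path, "r") as f:
        atoms = f["atoms"][()]
        ps = f["atoms"].attrs.get("patch_size")
    return build_gram(atoms, patch_size=None if ps is None else int(ps))


def save_gain_state(path: str | Path, state: GainState) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = state.variant.value
        f.attrs["N"] = state.N
        f.attrs["n0"] = state.n0
        for name in _GAIN_ATTRS:
            f.attrs[name] = getattr(state, name)
        if state.sigma_g2 is not None:
            f.attrs["sigma_g2"] = state.sigma_g2
        for name in ("gamma", "p", "V", "grid", "table"):
            arr = getattr(state, name)
            if arr is not None:
                f.create_dataset(name, data=arr)


def load_gain_state(path: str | Path) -> GainState:
    with h5py.File(path, "r") as f:
        state = GainState(
            variant=Variant(f.attrs["variant"]),
            N=int(f.attrs["N"]),
            n0=int(f.attrs["n0"]),
            p0=float(f.attrs["p0"]),
            eta_h=float(f.attrs["eta_h"]),
            alpha_h=float(f.attrs["alpha_h"]),
            sigma_g2=float(f.attrs["sigma_g2"]) if "sigma_g2" in f.attrs else None,
            alpha_ols=float(f.attrs["alpha_ols"]),
            p_floor=float(f.attrs["p_floor"]),
        )
        for name in ("gamma", "p", "V", "grid", "table"):
            if name in f:
                setattr(state, name, f[name][()])
    return state


def save_patch_batch(path: str | Path, batch: PatchBatch, seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("patches")
        g.create_dataset("data", data=batch.data)
        g.create_dataset("mask", data=batch.mask)
        g.attrs["patch_size"] = batch.patch_size
        if seed is not None:
            g.attrs["seed"] = seed


def load_patch_batch(path: str | Path) -> PatchBatch:
    with h5py.File(path, "r") as f:
        g = f["patches"]
        return PatchBatch(
            data=g["data"][()],
            patch_size=int(g.attrs["patch_size"]),
            mask=g["mask"][()].astype(bool),
        )


def save_imageset(path: str | Path, imageset: ImageSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("images")
        g.attrs["source_tag"] = imageset.source_tag
        for i, im in enumerate(imageset.images):
            g.create_dataset(f"{i:05d}", data=im)


def load_imageset(path: str | Path) -> ImageSet:
    with h5py.File(path, "r") as f:
        g = f["images"]
        images = [g[k][()] for k in sorted(g.keys())]
        return ImageSet(images=images, source_tag=str(g.attrs["source_tag"]))


def codes_to_csv(path: str | Path, codes: list[SparseCode]) -> None:
    """Export codes as coordinate-format triplets (sample, atom, value)."""
    with open(path, "w") as f:
        f.write("sample,atom,value\n")
        for k, code in enumerate(codes):
            for i, v in zip(code.indices, code.values):
                f.write(f"{k},{i},{v!r}\n")
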