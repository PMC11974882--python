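"""HDF5 and CSV persistence for phantom datasets and spectra."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .forward import AcquisitionScheme, ParameterGrid, Spectrum
from .inversion import InversionConfig, Spectrum2D
from .phantom import CompartmentSpec, PhantomConfig, VoxelDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "signals_to_csv",
    "spectrum2d_to_csv",
    "save_spectrum",
    "load_spectrum",
]


def _config_to_json(config: PhantomConfig) -> str:
    return json.dumps({
        "class_specs": [[vars(c) for c in specs]
                        for specs in config.class_specs],
        "voxels_per_class": config.voxels_per_class,
        "snr": config.snr,
        "noise_model": config.noise_model,
        "inversion": {"lam": config.inversion.lam,
                      "regularizer": config.inversion.regularizer},
        "seed": config.seed,
        "n_subjects_per_class": config.n_subjects_per_class,
    })


def _grid_to_h5(group: h5py.Group, grid: ParameterGrid) -> None:
    group.attrs["t1_s"] = grid.t1
    group.attrs["t2_s"] = grid.t2
    group.attrs["d_um2_per_ms"] = grid.d


def _grid_from_h5(group: h5py.Group) -> ParameterGrid:
    return ParameterGrid(t1=np.asarray(group.attrs["t1_s"]),
                         t2=np.asarray(group.attrs["t2_s"]),
                         d=np.asarray(group.attrs["d_um2_per_ms"]))


def save_dataset(path, dataset: VoxelDataset) -> None:
    """Write a VoxelDataset (signals, 2-D spectra, labels, truth,
    provenance) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signals", data=dataset.signals)
        h5.create_dataset("labels", data=dataset.labels)
        h5.create_dataset("truth", data=dataset.truth)
        h5.create_dataset("subjects", data=dataset.subjects)
        grp = h5.create_group("spectra2d")
        for pair, block in dataset.spectra2d.items():
            grp.create_dataset(pair, data=block)
        h5.create_dataset("scheme", data=dataset.config.scheme.entries)
        _grid_to_h5(h5, dataset.config.grid)
        h5.attrs["config_json"] = _config_to_json(dataset.config)
        h5.attrs["failed_voxels"] = np.asarray(dataset.failed_voxels,
                                               dtype=int)


def load_dataset(path) -> VoxelDataset:
    """Read a VoxelDataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as h5:
        meta = json.loads(h5.attrs["config_json"])
        config = PhantomConfig(
            class_specs=tuple(
                tuple(CompartmentSpec(**c) for c in specs)
                for specs in meta["class_specs"]),
            voxels_per_class=meta["voxels_per_class"],
            grid=_grid_from_h5(h5),
            scheme=AcquisitionScheme(np.asarray(h5["scheme"])),
            snr=meta["snr"],
            noise_model=meta["noise_model"],
            inversion=InversionConfig(**meta["inversion"]),
            seed=meta["seed"],
            n_subjects_per_class=meta["n_subjects_per_class"],
        )
        return VoxelDataset(
            signals=np.asarray(h5["signals"]),
            spectra2d={pair: np.asarray(h5["spectra2d"][pair])
                       for pair in h5["spectra2d"]},
            labels=np.asarray(h5["labels"]),
            truth=np.asarray(h5["truth"]),
            subjects=np.asarray(h5["subjects"]),
            config=config,
            failed_voxels=list(np.asarray(h5.attrs["failed_voxels"])),
        )


def signals_to_csv(path, signals: np.ndarray) -> None:
    """One voxel per row, one acquisition per column."""
    cols = [f"acq_{i}" for i in range(signals.shape[1])]
    pd.DataFrame(signals, columns=cols).to_csv(path, index=False)


def spectrum2d_to_csv(path, spec2d: Spectrum2D) -> None:
    """Matrix CSV with the two axis-node vectors as header row/column."""
    frame = pd.DataFrame(spec2d.weights,
                         index=spec2d.axis1_nodes,
                         columns=spec2d.axis2_nodes)
    frame.to_csv(path, index_label=spec2d.pair)


def save_spectrum(path, spectrum: Spectrum) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("weights", data=spectrum.weights)
        h5.attrs["normalized"] = spectrum.normalized
        _grid_to_h5(h5, spectrum.grid)


def load_spectrum(path) -> Spectrum:
    with h5py.File(path, "r") as h5:
        return Spectrum(_grid_from_h5(h5), np.asarray(h5["weights"]),
                        normalized=bool(h5.attrs["normalized"]))
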