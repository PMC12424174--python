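"""HDF5 import/export of density matrices and geminal models.

Schema (one group per object):

``DensityMatrixSet`` group:
  attrs: ``label``, ``n_elec``, ``flavor``, ``convention``
  datasets: ``orbitals`` (nao x m), ``gamma1``/``gamma2``/``gamma3``
  (spinorbital tensors, interleaved spin so = 2*spatial + spin, index order
  lower-string then upper-string, factorial-free normalization).

``GeminalModel`` group:
  datasets ``orbitals_K`` (int index list) and ``coefficients_K`` per
  geminal K = 0, 1, ...

These files let external multireference codes feed monomer density matrices
into the exchange engine, or consume the ones computed here.
"""

from __future__ import annotations

import h5py
import numpy as np

from .rdms import DensityMatrixSet, GeminalModel


def save_density_matrices(path, dm: DensityMatrixSet, group: str = "rdm") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.attrs["label"] = dm.label
        g.attrs["n_elec"] = dm.n_elec
        g.attrs["flavor"] = dm.flavor
        g.attrs["convention"] = dm.convention
        g.create_dataset("orbitals", data=dm.orbitals)
        for k, gamma in dm.gammas.items():
            g.create_dataset(f"gamma{k}", data=gamma)


def load_density_matrices(path, group: str = "rdm") -> DensityMatrixSet:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        gammas = {}
        for name, ds in g.items():
            if name.startswith("gamma"):
                gammas[int(name[5:])] = np.array(ds)
        return DensityMatrixSet(
            label=str(g.attrs["label"]),
            n_elec=int(g.attrs["n_elec"]),
            orbitals=np.array(g["orbitals"]),
            gammas=gammas,
            flavor=str(g.attrs["flavor"]),
            convention=str(g.attrs["convention"]),
        )


def save_geminal_model(path, model: GeminalModel, group: str = "geminal") -> None:
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        for i, (orbs, coefs) in enumerate(zip(model.orbital_sets,
                                              model.coefficients)):
            g.create_dataset(f"orbitals_{i}", data=np.asarray(orbs, dtype=np.int64))
            g.create_dataset(f"coefficients_{i}", data=np.asarray(coefs))


def load_geminal_model(path, group: str = "geminal") -> GeminalModel:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        n = len([k for k in g if k.startswith("orbitals_")])
        orbital_sets = [list(map(int, g[f"orbitals_{i}"])) for i in range(n)]
        coefficients = [np.array(g[f"coefficients_{i}"]) for i in range(n)]
    return GeminalModel(orbital_sets, coefficients)
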