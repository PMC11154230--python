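"""Readers and writers for ensembles, fingerprints, and distance matrices.

Ensembles travel as delimited text (one column per parameter, optional
``log_posterior`` column) or HDF5 with the same layout (datasets ``values``,
``parameter_names``, optional ``log_posterior``).  Fingerprints are a
delimited integer matrix (rows = ensemble members, columns = time points)
with a companion JSON registry mapping each label to its canonical edge
list.  Distance matrices persist as a dense ``.npy`` array plus a JSON index
file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .dominance import DynamicFingerprint, SubnetworkRegistry
from .modes import DistanceMatrix
from .network import ParameterEnsemble, ReactionNetwork

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "write_fingerprints",
    "read_fingerprints",
    "write_distance_matrix",
    "read_distance_matrix",
]

LOGP_COLUMN = "log_posterior"


def _validate_frame(df: pd.DataFrame, net: ReactionNetwork | None) -> list[str]:
    param_cols = [c for c in df.columns if c != LOGP_COLUMN]
    if net is not None:
        missing = [p for p in net.parameter_names if p not in param_cols]
        if missing:
            raise ValueError(f"ensemble is missing parameter column(s): {missing}")
        param_cols = list(net.parameter_names)
    values = df[param_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("ensemble contains NaN parameter values")
    if np.any(values <= 0):
        bad = [param_cols[j] for j in np.unique(np.argwhere(values <= 0)[:, 1])]
        raise ValueError(f"non-positive rate values in column(s): {bad}")
    return param_cols


def read_ensemble(path: str | Path,
                  net: ReactionNetwork | None = None) -> ParameterEnsemble:
    """Load a parameter ensemble from delimited text or HDF5.

    A ``log_posterior`` column, when present, becomes normalized weights via
    max-subtracted exponentiation.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in f["parameter_names"][()]]
            values = np.asarray(f["values"])
            logp = np.asarray(f[LOGP_COLUMN]) if LOGP_COLUMN in f else None
        df = pd.DataFrame(values, columns=names)
        if logp is not None:
            df[LOGP_COLUMN] = logp
    else:
        header = path.read_text().split("\n", 1)[0]
        sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    param_cols = _validate_frame(df, net)
    logp = df[LOGP_COLUMN].to_numpy(dtype=float) if LOGP_COLUMN in df.columns \
        else None
    return ParameterEnsemble.from_array(
        df[param_cols].to_numpy(dtype=float), param_cols, log_posterior=logp)


def write_ensemble(ensemble: ParameterEnsemble, path: str | Path) -> None:
    """Write an ensemble in the same layout read_ensemble consumes."""
    path = Path(path)
    names = ensemble.parameter_names()
    values = ensemble.to_array(names)
    logp = [v.log_posterior for v in ensemble.vectors]
    has_logp = all(lp is not None for lp in logp)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=values)
            f.create_dataset("parameter_names",
                             data=np.array(names, dtype="S"))
            if has_logp:
                f.create_dataset(LOGP_COLUMN, data=np.asarray(logp, dtype=float))
    else:
        df = pd.DataFrame(values, columns=names)
        if has_logp:
            df[LOGP_COLUMN] = logp
        df.to_csv(path, index=False, float_format="%.17g")


def write_fingerprints(fps: Sequence[DynamicFingerprint], path: str | Path,
                       registry: SubnetworkRegistry | None = None,
                       registry_path: str | Path | None = None) -> None:
    """Fingerprint matrix as delimited integers (+ optional registry JSON)."""
    mat = np.array([fp.labels for fp in fps], dtype=np.int64)
    df = pd.DataFrame(mat,
                      index=[fp.parameter_index for fp in fps])
    df.index.name = "ensemble_index"
    df.to_csv(path)
    if registry is not None:
        registry.save(registry_path
                      or Path(path).with_suffix(".registry.json"))


def read_fingerprints(path: str | Path) -> list[DynamicFingerprint]:
    df = pd.read_csv(path, index_col="ensemble_index")
    return [DynamicFingerprint(row.to_numpy(dtype=np.int64), int(idx))
            for idx, row in df.iterrows()]


def write_distance_matrix(dm: DistanceMatrix, path: str | Path,
                          indices: Sequence[int] | None = None) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), dm.values)
    index = list(indices) if indices is not None else list(range(dm.n))
    path.with_suffix(".index.json").write_text(json.dumps(index))


def read_distance_matrix(path: str | Path) -> tuple[DistanceMatrix, list[int]]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    index_file = path.with_suffix(".index.json")
    indices = json.loads(index_file.read_text()) if index_file.exists() \
        else list(range(len(values)))
    return DistanceMatrix(values), indices
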