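"""Reading and writing connectivity matrices, patterns and instance bundles.

Dense matrices travel as CSV or ``.npy``; sparse connectivity as Matrix
Market (``.mtx``).  Entries are raw synaptic weights — no header semantics
beyond the array shape.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .channel import ChannelSpec
from .netgen import Instance
from .priors import PriorSpec

__all__ = ["load_matrix", "save_matrix", "save_instance", "load_instance_params"]


def load_matrix(path: str | Path) -> np.ndarray:
    """Load a dense matrix from .csv, .npy or .mtx (by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return np.loadtxt(path, delimiter=",", ndmin=2)
    if suffix == ".npy":
        return np.load(path)
    if suffix == ".mtx":
        m = mmread(str(path))
        return m.toarray() if sparse.issparse(m) else np.asarray(m)
    raise ValueError(f"unsupported matrix format {suffix!r} (use .csv, .npy or .mtx)")


def save_matrix(M: np.ndarray, path: str | Path) -> None:
    """Write a matrix as .csv, .npy, or sparse .mtx (by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, M, delimiter=",")
    elif suffix == ".npy":
        np.save(path, M)
    elif suffix == ".mtx":
        mmwrite(str(path), sparse.coo_matrix(M))
    else:
        raise ValueError(
            f"unsupported matrix format {suffix!r} (use .csv, .npy or .mtx)"
        )


def save_instance(inst: Instance, outdir: str | Path, fmt: str = "csv") -> None:
    """Write connectivity, patterns and a JSON hyper-parameter sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_matrix(inst.connectivity, outdir / f"connectivity.{fmt}")
    save_matrix(inst.patterns, outdir / "patterns.csv")
    meta = {
        "prior": inst.prior.to_dict(),
        "channel": inst.channel.to_dict(),
        "N": inst.n_neurons,
        "P": inst.n_patterns,
        "seed": inst.seed,
    }
    with open(outdir / "instance.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_instance_params(path: str | Path) -> tuple[PriorSpec, ChannelSpec, dict]:
    """Read the JSON sidecar back into spec objects (plus the raw dict)."""
    with open(path) as fh:
        meta = json.load(fh)
    return (
        PriorSpec.from_dict(meta["prior"]),
        ChannelSpec.from_dict(meta["channel"]),
        meta,
    )
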