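"""File formats: node-by-time matrices, partitions, timecourses, manifests.

Conventions: node and cluster ids are 1-based in every file, 0-based in
memory.  The TSV matrix format has a header row of timestamps in seconds;
the binary format is raw little-endian float64 with a JSON sidecar
recording shape and TR.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import NodeTimecourses

__all__ = [
    "read_matrix",
    "write_matrix_tsv",
    "write_matrix_binary",
    "read_partition",
    "write_partition",
    "write_coassignment",
    "write_timecourses",
    "write_manifest",
    "read_nifti",
]


def write_matrix_tsv(path: str | Path, data: NodeTimecourses) -> None:
    df = pd.DataFrame(
        data.Y,
        index=np.arange(1, data.n_nodes + 1),
        columns=[f"{t:.6f}" for t in data.times],
    )
    df.to_csv(path, sep="\t", index_label="node")


def write_matrix_binary(path: str | Path, data: NodeTimecourses) -> None:
    path = Path(path)
    data.Y.astype("<f8").tofile(path)
    tr = float(data.times[1] - data.times[0]) if data.n_times > 1 else 1.0
    sidecar = {
        "shape": list(data.Y.shape),
        "dtype": "<f8",
        "tr": tr,
        "t0": float(data.times[0]),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_matrix(path: str | Path) -> NodeTimecourses:
    """Read a node-by-time matrix from TSV (header of timestamps) or raw
    binary with JSON sidecar, dispatching on the sidecar's presence."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        Y = np.fromfile(path, dtype=meta.get("dtype", "<f8")).reshape(
            meta["shape"]
        )
        t0 = meta.get("t0", 0.0)
        times = t0 + np.arange(Y.shape[1]) * meta["tr"]
        return NodeTimecourses(Y, times)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        times = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as err:
        raise ValueError("TSV header must hold numeric timestamps") from err
    Y = df.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("matrix contains missing or non-numeric cells")
    return NodeTimecourses(Y, times)


def write_partition(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    pd.DataFrame(
        {"node_id": np.arange(1, len(labels) + 1), "cluster_id": labels + 1}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    order = np.argsort(df["node_id"].to_numpy())
    return df["cluster_id"].to_numpy()[order] - 1


def write_coassignment(path: str | Path, coassign: np.ndarray) -> None:
    np.savetxt(path, coassign, delimiter="\t", fmt="%.6f")


def write_timecourses(path: str | Path, timecourses: dict[int, dict]) -> None:
    """Cluster-by-time table with posterior mean and 95% interval columns."""
    rows = []
    z = 1.959964
    for cid in sorted(timecourses):
        tc = timecourses[cid]
        mean, var = tc["mean"], tc["var"]
        sd = np.sqrt(var)
        for t in range(len(mean)):
            rows.append(
                (cid + 1, t, mean[t], mean[t] - z * sd[t], mean[t] + z * sd[t])
            )
    pd.DataFrame(
        rows, columns=["cluster_id", "t_index", "mean", "ci_lower", "ci_upper"]
    ).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **fields) -> None:
    import caesar

    payload = {"caesar_version": caesar.__version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_edge_list(path: str | Path) -> tuple[int, np.ndarray]:
    """TSV with columns (node_a, node_b[, distance]); 1-based node ids.
    Returns (n_nodes, edges as 0-based int array)."""
    df = pd.read_csv(path, sep="\t")
    edges = df.iloc[:, :2].to_numpy(dtype=np.int64) - 1
    if edges.min() < 0:
        raise ValueError("node ids must be 1-based positive integers")
    return int(edges.max()) + 1, edges


def read_triangles(path: str | Path) -> np.ndarray:
    """TSV with three 1-based node-index columns; returns 0-based triples."""
    df = pd.read_csv(path, sep="\t")
    tri = df.iloc[:, :3].to_numpy(dtype=np.int64) - 1
    if tri.min() < 0:
        raise ValueError("node ids must be 1-based positive integers")
    return tri


def read_nifti(path: str | Path, mask_path: str | Path) -> NodeTimecourses:
    """Flatten masked voxels of a 4-D NIfTI image to the node axis.

    Requires nibabel (optional extra); TR is taken from the header zooms.
    """
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover
        raise ImportError("NIfTI ingestion requires nibabel") from err
    img = nib.load(str(path))
    mask = nib.load(str(mask_path)).get_fdata() > 0
    data = img.get_fdata()
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    Y = data[mask]  # (n_voxels, T)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    times = np.arange(Y.shape[1]) * tr
    return NodeTimecourses(Y, times)
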