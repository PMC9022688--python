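"""File I/O: NIfTI volumes, TSV matrices, FSL-style bval/bvec, and a
plain-text streamline format (blank-line-separated blocks of x y z)."""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def write_matrix_tsv(path, matrix: np.ndarray, ids=None) -> None:
    matrix = np.asarray(matrix)
    if ids is None:
        ids = [str(i) for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix_tsv(path, require_symmetric: bool = False) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is {M.shape}, expected square")
    if require_symmetric and not np.allclose(M, M.T):
        raise ValueError(f"{path}: matrix is not symmetric")
    return M, [str(c) for c in df.columns]


def write_timecourses_tsv(path, tcs: np.ndarray, component_ids=None) -> None:
    """(T, K) time courses, one column per component."""
    if component_ids is None:
        component_ids = [f"comp{k}" for k in range(tcs.shape[1])]
    pd.DataFrame(tcs, columns=component_ids).to_csv(path, sep="\t", index=False)


def read_timecourses_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_bval_bvec(bval_path, bvec_path, b_values: np.ndarray, b_vectors: np.ndarray) -> None:
    """FSL convention: one row of b-values; three rows of vector components."""
    np.savetxt(bval_path, np.asarray(b_values)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(b_vectors).T, fmt="%.8f")


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style files; non-unit vectors on b>0 rows are normalized
    with a warning."""
    b = np.loadtxt(bval_path).ravel()
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3:
        g = g.T
    if g.shape != (len(b), 3):
        raise ValueError(
            f"{bvec_path}: expected 3x{len(b)} vectors to match {bval_path}"
        )
    nz = b > 0
    norms = np.linalg.norm(g[nz], axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{bvec_path}: zero vector on a b>0 measurement")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn(f"{bvec_path}: normalizing non-unit b-vectors", stacklevel=2)
        g = g.copy()
        g[nz] = g[nz] / norms[:, None]
    return b, g


def write_streamlines_text(path, streamlines: list[np.ndarray]) -> None:
    """One streamline per block; one 'x y z' point per line; blank line
    between blocks."""
    with open(path, "w") as fh:
        for i, line in enumerate(streamlines):
            if i:
                fh.write("\n")
            for p in line:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_streamlines_text(path) -> list[np.ndarray]:
    blocks: list[list[list[float]]] = [[]]
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            if blocks[-1]:
                blocks.append([])
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 'x y z', got {line!r}")
        blocks[-1].append([float(v) for v in parts])
    return [np.asarray(b) for b in blocks if b]
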