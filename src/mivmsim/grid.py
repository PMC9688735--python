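"""Tensor-product rectilinear grids.

All solvers in this package operate on axis-aligned rectilinear meshes: a cell
``(i, j, k)`` spans ``[xf[i], xf[i+1]] x [yf[j], yf[j+1]] x [zf[k], zf[k+1]]``.
Grids may be graded (non-uniform spacing per axis) so that the floor layer
holding the cumulus-oocyte complexes can be refined without refining the whole
2 mL chamber.  Coordinates are SI metres, right-handed, origin at the
chamber-floor centre, z up.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np


class RectilinearGrid:
    """An axis-aligned structured mesh defined by its face coordinates."""

    def __init__(self, xf: Sequence[float], yf: Sequence[float], zf: Sequence[float]):
        self.xf = np.asarray(xf, dtype=float)
        self.yf = np.asarray(yf, dtype=float)
        self.zf = np.asarray(zf, dtype=float)
        for name, f in (("xf", self.xf), ("yf", self.yf), ("zf", self.zf)):
            if f.ndim != 1 or f.size < 2:
                raise ValueError(f"{name} must be a 1-D array of >= 2 face coordinates")
            if np.any(np.diff(f) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    # --- sizes -----------------------------------------------------------
    @property
    def nx(self) -> int:
        return self.xf.size - 1

    @property
    def ny(self) -> int:
        return self.yf.size - 1

    @property
    def nz(self) -> int:
        return self.zf.size - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    # --- spacings and centres -------------------------------------------
    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.yf)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.zf)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[:-1] + self.xf[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yf[:-1] + self.yf[1:])

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.zf[:-1] + self.zf[1:])

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centre coordinates broadcast to the full (nx, ny, nz) shape."""
        return np.meshgrid(self.xc, self.yc, self.zc, indexing="ij")

    def cell_volumes(self) -> np.ndarray:
        return (
            self.dx[:, None, None] * self.dy[None, :, None] * self.dz[None, None, :]
        )

    def spacing(self, axis: int) -> np.ndarray:
        return (self.dx, self.dy, self.dz)[axis]

    # --- export ----------------------------------------------------------
    def write_vtk(self, path, cell_data: Mapping[str, np.ndarray] | None = None) -> None:
        """Write the grid (and optional per-cell scalar fields) as legacy ASCII VTK.

        The legacy RECTILINEAR_GRID format is written directly: it is a small,
        stable text format readable by ParaView/VisIt and keeps this package
        free of mesh-IO dependencies.
        """
        cell_data = cell_data or {}
        lines = [
            "# vtk DataFile Version 3.0",
            "mivmsim rectilinear grid",
            "ASCII",
            "DATASET RECTILINEAR_GRID",
            f"DIMENSIONS {self.nx + 1} {self.ny + 1} {self.nz + 1}",
            f"X_COORDINATES {self.nx + 1} double",
            " ".join(f"{v:.9g}" for v in self.xf),
            f"Y_COORDINATES {self.ny + 1} double",
            " ".join(f"{v:.9g}" for v in self.yf),
            f"Z_COORDINATES {self.nz + 1} double",
            " ".join(f"{v:.9g}" for v in self.zf),
        ]
        if cell_data:
            lines.append(f"CELL_DATA {self.n_cells}")
            for name, arr in cell_data.items():
                a = np.asarray(arr)
                if a.shape != self.shape:
                    raise ValueError(f"cell field {name!r} has shape {a.shape}, expected {self.shape}")
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                # VTK expects x fastest: transpose to (z, y, x) then ravel C-order
                flat = np.nan_to_num(a, nan=-1.0).transpose(2, 1, 0).ravel()
                lines.extend(
                    " ".join(f"{v:.9g}" for v in flat[i : i + 6]) for i in range(0, flat.size, 6)
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def graded_axis(segments: Iterable[tuple[float, float, float]]) -> np.ndarray:
    """Build face coordinates from ``(start, stop, target_spacing)`` segments.

    Each segment is divided into an integer number of uniform cells whose size
    is as close as possible to the requested spacing, so stated breakpoints
    (material interfaces, insert tops, the box assembly gap) always coincide
    with mesh faces.
    """
    faces: list[np.ndarray] = []
    prev_stop = None
    for start, stop, h in segments:
        if stop <= start:
            continue
        if h <= 0:
            raise ValueError("target spacing must be positive")
        if prev_stop is not None and abs(start - prev_stop) > 1e-12:
            raise ValueError("axis segments must be contiguous")
        n = max(1, int(round((stop - start) / h)))
        seg = np.linspace(start, stop, n + 1)
        faces.append(seg if prev_stop is None else seg[1:])
        prev_stop = stop
    if not faces:
        raise ValueError("no non-empty segments")
    return np.concatenate(faces)
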