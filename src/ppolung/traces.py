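"""Interlobar fissure traces.

A trace set is the manual input of the lobe-splitting step: on a subset of
axial slices, an ordered polyline marks where one interlobar boundary crosses
that slice. Each polyline is tagged with the lobe pair it separates,
``(lobe_above, lobe_below)`` — "above" meaning the anatomically superior lobe
of the pair.

Orientation convention: the superior lobe lies on the *positive* side of the
polyline, where the sign of a point is the z-component of the cross product of
the traversal direction with the vector to the point (in-plane axes x, y).
Equivalently: walking along the polyline in vertex order, ``lobe_above`` is on
your left. Points exactly on the polyline belong to ``lobe_below``.

On-disk format: CSV with one row per vertex —
``slice_index, boundary_id, vertex_index, x, y`` where ``boundary_id`` is
``"<lobe_above>-<lobe_below>"`` (e.g. ``"LUL-LLL"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import LOBE_LABELS, side_of
from .errors import ParameterError, TraceInconsistencyError, ValidationError

__all__ = ["TracePolyline", "FissureTraceSet"]


@dataclass
class TracePolyline:
    """One interlobar boundary polyline on one axial slice."""

    slice_index: int
    lobe_above: str
    lobe_below: str
    vertices: np.ndarray  # (N, 2) float array of (x, y) in voxel coordinates

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ParameterError("polyline needs an (N>=2, 2) vertex array of (x, y)")
        for lobe in (self.lobe_above, self.lobe_below):
            if lobe not in LOBE_LABELS:
                raise ParameterError(f"unknown lobe {lobe!r}")
        if side_of(self.lobe_above) != side_of(self.lobe_below):
            raise ParameterError(
                f"boundary {self.boundary_id} spans both lungs; fissures are one-sided"
            )

    @property
    def boundary_id(self) -> str:
        return f"{self.lobe_above}-{self.lobe_below}"

    @property
    def side(self) -> str:
        return side_of(self.lobe_above)


@dataclass
class FissureTraceSet:
    """All traced polylines for one study."""

    polylines: list[TracePolyline] = field(default_factory=list)

    def add(self, polyline: TracePolyline) -> None:
        self.polylines.append(polyline)

    def boundaries(self) -> dict[str, list[TracePolyline]]:
        """Group polylines by boundary id; within each boundary, sort by slice.

        Sorting here makes the downstream label map independent of the order
        in which rows appear in the trace file.
        """
        out: dict[str, list[TracePolyline]] = {}
        for p in self.polylines:
            out.setdefault(p.boundary_id, []).append(p)
        for bid, plist in out.items():
            plist.sort(key=lambda p: p.slice_index)
            seen = set()
            for p in plist:
                if p.slice_index in seen:
                    raise TraceInconsistencyError(
                        f"boundary {bid} traced twice on slice {p.slice_index}"
                    )
                seen.add(p.slice_index)
        return out

    def to_csv(self, path) -> None:
        rows = []
        for p in self.polylines:
            for i, (x, y) in enumerate(p.vertices):
                rows.append(
                    {
                        "slice_index": p.slice_index,
                        "boundary_id": p.boundary_id,
                        "vertex_index": i,
                        "x": x,
                        "y": y,
                    }
                )
        pd.DataFrame(rows, columns=["slice_index", "boundary_id", "vertex_index", "x", "y"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "FissureTraceSet":
        df = pd.read_csv(path)
        required = {"slice_index", "boundary_id", "vertex_index", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"trace CSV missing columns: {sorted(missing)}")
        traces = cls()
        for (slice_index, boundary_id), grp in df.groupby(["slice_index", "boundary_id"], sort=True):
            grp = grp.sort_values("vertex_index")
            try:
                above, below = str(boundary_id).split("-")
            except ValueError as exc:
                raise ValidationError(f"malformed boundary_id {boundary_id!r}") from exc
            traces.add(
                TracePolyline(
                    slice_index=int(slice_index),
                    lobe_above=above,
                    lobe_below=below,
                    vertices=grp[["x", "y"]].to_numpy(dtype=float),
                )
            )
        return traces
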