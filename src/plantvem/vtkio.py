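"""Legacy-ASCII VTK snapshot export.

Two snapshot flavors: the cell polygons with per-cell scalars (inhibitor
concentration, expansion rate), and the triangulated in-plane walls with
per-element fiber vectors. Legacy VTK is a simple line-oriented text
format, written directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .mechanics import MechanicalSystem
from .tissue import Tissue

__all__ = ["write_vtk_cells", "write_vtk_elements"]


def _header(lines, title):
    lines += ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET POLYDATA"]


def write_vtk_cells(tissue: Tissue, path,
                    scalars: Optional[Dict[str, Dict[int, float]]] = None) -> None:
    """Cell polygons with optional per-cell scalar fields (dicts keyed by
    cell id, e.g. inhibitor concentration b or expansion rate)."""
    vids = sorted({v for c in tissue.cells.values() for v in c.boundary})
    idx = {vid: k for k, vid in enumerate(vids)}
    lines: list = []
    _header(lines, "plantvem cells")
    lines.append(f"POINTS {len(vids)} double")
    for vid in vids:
        x, y = tissue.vertices[vid].pos
        lines.append(f"{x:.9g} {y:.9g} 0")
    cids = sorted(tissue.cells)
    size = sum(len(tissue.cells[c].boundary) + 1 for c in cids)
    lines.append(f"POLYGONS {len(cids)} {size}")
    for cid in cids:
        b = tissue.cells[cid].boundary
        lines.append(" ".join([str(len(b))] + [str(idx[v]) for v in b]))
    scalars = dict(scalars or {})
    scalars.setdefault("b", {cid: tissue.cells[cid].b for cid in cids})
    lines.append(f"CELL_DATA {len(cids)}")
    for name, field in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        for cid in cids:
            lines.append(f"{field.get(cid, 0.0):.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_elements(tissue: Tissue, path) -> None:
    """Triangular in-plane wall elements with current fiber vectors."""
    system = MechanicalSystem(tissue)
    lines: list = []
    _header(lines, "plantvem elements")
    lines.append(f"POINTS {system.n} double")
    for k in range(system.n):
        x, y = system.x0[k]
        lines.append(f"{x:.9g} {y:.9g} 0")
    tri = system.tri
    lines.append(f"POLYGONS {len(tri)} {4 * len(tri)}")
    for t in tri:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    if len(tri):
        a1, a2, _ = system.current_fibers()
        lines.append(f"CELL_DATA {len(tri)}")
        for name, a in (("fiber1", a1), ("fiber2", a2)):
            lines.append(f"VECTORS {name} double")
            for vec in a:
                lines.append(f"{vec[0]:.9g} {vec[1]:.9g} 0")
    Path(path).write_text("\n".join(lines) + "\n")
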