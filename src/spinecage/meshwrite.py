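"""Mesh and field export: Abaqus INP, ASCII VTK, NRRD fields, material CSV.

The INP writer emits C3D4 elements, one *SOLID SECTION per material set and
*ELASTIC, TYPE=ANISOTROPIC blocks (21 lower-triangle constants in Abaqus
column order).  The reader parses the same dialect back (nodes, elements,
sets and anisotropic elastic blocks) — enough for round-tripping models
produced by this package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .tetmesh import TetMesh
from .volume import ImageVolume, write_volume

# Abaqus anisotropic order: D1111,D1122,D2222,D1133,D2233,D3333,D1112,...
# i.e. lower triangle of the 6x6 Voigt matrix, column-major by row count
_ABQ_ORDER = [(i, j) for i in range(6) for j in range(i + 1)]


def stiffness_to_abaqus(C: np.ndarray) -> list[float]:
    return [float(C[i, j]) for i, j in _ABQ_ORDER]


def abaqus_to_stiffness(vals: list[float]) -> np.ndarray:
    C = np.zeros((6, 6))
    for (i, j), v in zip(_ABQ_ORDER, vals):
        C[i, j] = C[j, i] = v
    return C


def write_inp(
    path: str | Path,
    mesh: TetMesh,
    materials: np.ndarray | None = None,
    max_materials: int = 512,
) -> None:
    """Write the mesh (and optional per-element stiffness, MPa) as Abaqus INP.

    Distinct stiffness matrices become materials; with more than
    ``max_materials`` unique matrices an error is raised (quantize first).
    """
    lines = ["*HEADING", "spinecage export", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.8g}, {y:.8g}, {z:.8g}")
    lines.append("*ELEMENT, TYPE=C3D4")
    for e, conn in enumerate(mesh.elements, start=1):
        a, b, c, d = conn + 1
        lines.append(f"{e}, {a}, {b}, {c}, {d}")
    for name, els in mesh.element_sets.items():
        lines.append(f"*ELSET, ELSET={name}")
        lines.extend(_chunks((np.asarray(els) + 1).tolist()))
    for name, nds in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        lines.extend(_chunks((np.asarray(nds) + 1).tolist()))

    if materials is not None:
        materials = np.asarray(materials)
        if materials.ndim == 2:
            materials = np.broadcast_to(materials, (mesh.n_elements, 6, 6))
        keys = np.round(materials, 6).reshape(len(materials), -1)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        if len(uniq) > max_materials:
            raise ValueError(
                f"{len(uniq)} distinct materials exceed max_materials="
                f"{max_materials}; quantize the stiffness field first"
            )
        for mid in range(len(uniq)):
            els = np.where(inv == mid)[0] + 1
            lines.append(f"*ELSET, ELSET=MAT{mid}")
            lines.extend(_chunks(els.tolist()))
            lines.append(f"*SOLID SECTION, ELSET=MAT{mid}, MATERIAL=MATERIAL{mid}")
        for mid, row in enumerate(uniq):
            C = row.reshape(6, 6)
            lines.append(f"*MATERIAL, NAME=MATERIAL{mid}")
            lines.append("*ELASTIC, TYPE=ANISOTROPIC")
            vals = stiffness_to_abaqus(C)
            for s in range(0, 21, 8):
                lines.append(", ".join(f"{v:.8g}" for v in vals[s : s + 8]))
    Path(path).write_text("\n".join(lines) + "\n")


def _chunks(ids: list, per_line: int = 12) -> list[str]:
    return [
        ", ".join(str(v) for v in ids[s : s + per_line])
        for s in range(0, len(ids), per_line)
    ]


def read_inp(path: str | Path) -> tuple[TetMesh, dict]:
    """Parse nodes, C3D4 elements, sets and anisotropic elastic blocks."""
    nodes, elems = [], []
    element_sets: dict[str, list[int]] = {}
    node_sets: dict[str, list[int]] = {}
    materials: dict[str, np.ndarray] = {}
    sections: list[tuple[str, str]] = []  # (elset, material)
    mode = None
    current = None
    mat_vals: list[float] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            u = line.upper()
            if mode == "elastic" and current is not None:
                materials[current] = abaqus_to_stiffness(mat_vals)
            mode = None
            if u.startswith("*NODE"):
                mode = "node"
            elif u.startswith("*ELEMENT"):
                mode = "element"
            elif u.startswith("*ELSET"):
                name = _kw(line, "ELSET")
                current = name
                element_sets[name] = []
                mode = "elset"
            elif u.startswith("*NSET"):
                name = _kw(line, "NSET")
                current = name
                node_sets[name] = []
                mode = "nset"
            elif u.startswith("*SOLID SECTION"):
                sections.append((_kw(line, "ELSET"), _kw(line, "MATERIAL")))
            elif u.startswith("*MATERIAL"):
                current = _kw(line, "NAME")
            elif u.startswith("*ELASTIC"):
                mode = "elastic"
                mat_vals = []
            continue
        vals = [v for v in line.replace(",", " ").split() if v]
        if mode == "node":
            nodes.append([float(v) for v in vals[1:4]])
        elif mode == "element":
            elems.append([int(v) - 1 for v in vals[1:5]])
        elif mode == "elset":
            element_sets[current].extend(int(v) - 1 for v in vals)
        elif mode == "nset":
            node_sets[current].extend(int(v) - 1 for v in vals)
        elif mode == "elastic":
            mat_vals.extend(float(v) for v in vals)
    if mode == "elastic" and current is not None:
        materials[current] = abaqus_to_stiffness(mat_vals)
    mesh = TetMesh(
        nodes=np.array(nodes),
        elements=np.array(elems, dtype=np.int64),
        element_sets={k: np.array(v) for k, v in element_sets.items()},
        node_sets={k: np.array(v) for k, v in node_sets.items()},
    )
    per_element = None
    if sections and materials:
        per_element = np.zeros((mesh.n_elements, 6, 6))
        for elset, matname in sections:
            els = mesh.element_sets.get(elset)
            C = materials.get(matname)
            if els is not None and C is not None:
                per_element[els] = C
    return mesh, {"materials": materials, "per_element": per_element}


def _kw(line: str, key: str) -> str:
    for part in line.split(","):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip().upper() == key:
                return v.strip()
    raise ValueError(f"keyword {key} not found in {line!r}")


def write_vtu(
    path: str | Path,
    mesh: TetMesh,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal ASCII VTK XML (.vtu) writer for tet meshes with cell data."""
    n, m = mesh.n_nodes, mesh.n_elements
    out = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    out.append(" ".join(f"{v:.8g}" for v in mesh.nodes.ravel()))
    out += ["</DataArray>", "</Points>", "<Cells>",
            '<DataArray type="Int64" Name="connectivity" format="ascii">']
    out.append(" ".join(str(v) for v in mesh.elements.ravel()))
    out += ["</DataArray>", '<DataArray type="Int64" Name="offsets" format="ascii">']
    out.append(" ".join(str(4 * (i + 1)) for i in range(m)))
    out += ["</DataArray>", '<DataArray type="UInt8" Name="types" format="ascii">']
    out.append(" ".join("10" for _ in range(m)))
    out += ["</DataArray>", "</Cells>"]

    def _data_block(data: dict, kind: str):
        blk = [f"<{kind}>"]
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            blk.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            blk.append(" ".join(f"{v:.8g}" for v in arr.ravel()))
            blk.append("</DataArray>")
        blk.append(f"</{kind}>")
        return blk

    if cell_data:
        out += _data_block(cell_data, "CellData")
    if point_data:
        out += _data_block(point_data, "PointData")
    out += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(out) + "\n")


def export_fabric(fab, spacing, origin, outdir: str | Path) -> dict[str, Path]:
    """Write DA, R, flags and eigenvector components as NRRD volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    fields = {
        "DA.nrrd": fab.DA,
        "R.nrrd": fab.R,
        "isotropic_flag.nrrd": fab.isotropic.astype(np.uint8),
    }
    for c, name in enumerate("xyz"):
        fields[f"e1_{name}.nrrd"] = fab.eigenvectors[..., c, 0]
    for name, arr in fields.items():
        p = outdir / name
        write_volume(ImageVolume(np.asarray(arr), spacing, origin), p)
        paths[name] = p
    return paths


def material_summary_csv(path: str | Path, materials: np.ndarray, labels) -> None:
    """Per-label summary of axial stiffness entries (MPa)."""
    labels = np.asarray(labels)
    rows = ["label,n_elements,C11_mean,C22_mean,C33_mean,C44_mean"]
    for lab in np.unique(labels):
        sel = labels == lab
        C = materials[sel]
        rows.append(
            f"{lab},{sel.sum()},{C[:,0,0].mean():.6g},{C[:,1,1].mean():.6g},"
            f"{C[:,2,2].mean():.6g},{C[:,3,3].mean():.6g}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
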