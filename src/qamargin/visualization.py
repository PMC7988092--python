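"""Traffic-light histogram and 3-D projection of margins.

Two graphical outputs accompany the numerical summary: a histogram of the
1 mm margin substrata, bars coloured by traffic-light class, and a 3-D
surface map in which every ablation-surface voxel carries the signed
margin of its nearest included tumor-surface voxel, so critical
(negative-margin) regions show up as an orange patch on the ablation
surface.  Rendering is headless: the histogram goes to an image file, the
surface map to a legacy-VTK ASCII polydata file for external viewers.

The projection rule — nearest included tumor-surface voxel, spacing-aware,
ties resolved toward the smallest (most pessimistic) margin — is this
package's definition; it guarantees that an orange area on the ablation
surface corresponds to actually uncovered tumor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_model import AblationCase, AllExcludedError
from .qam_core import MarginDistribution, extract_surface
from .reporting import QAMSummary, classify

__all__ = [
    "CLASS_COLORS",
    "SurfaceColorMap",
    "plot_histogram",
    "project_margins",
    "write_surface_mesh",
    "read_surface_mesh",
]

CLASS_COLORS = {"orange": "#e66101", "yellow": "#fdb863", "green": "#1a9641"}
_CLASS_CODE = {"orange": 0, "yellow": 1, "green": 2}


@dataclass(frozen=True)
class SurfaceColorMap:
    """Ablation-surface voxel positions with projected margin scalars."""

    vertices: np.ndarray  # (N, 3) positions in mm
    scalar: np.ndarray  # (N,) signed margin in mm
    labels: tuple  # (N,) traffic-light label per vertex


def plot_histogram(summary: QAMSummary, path, title: str = "") -> Path:
    """Bar chart of the substrata percentages, coloured by class."""
    path = Path(path)
    centers = [c for c, _ in summary.bins]
    pcts = [p for _, p in summary.bins]
    colors = [
        CLASS_COLORS[classify(c, summary.class_low, summary.class_high).label]
        for c in centers
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, pcts, width=0.9 * summary.bin_width, color=colors,
           edgecolor="black", linewidth=0.4)
    ax.set_xlabel("ablation margin (mm)")
    ax.set_ylabel("tumor surface (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)
    return path


def project_margins(case: AblationCase, dist: MarginDistribution) -> SurfaceColorMap:
    """Assign to every ablation-surface voxel the margin of its nearest
    included tumor-surface voxel (ties: smallest margin)."""
    if dist.margins.size == 0:
        raise AllExcludedError("no included tumor surface voxels to project")
    spacing = np.asarray(case.spacing)
    abl_surface = extract_surface(case.ablation)
    verts_idx = abl_surface.indices
    verts = verts_idx * spacing
    tum_pts = dist.included.indices * spacing
    margins = np.asarray(dist.margins, dtype=float)

    scalar = np.empty(len(verts), dtype=float)
    # block-wise exact nearest neighbour with pessimistic tie-break
    block = 2048
    for start in range(0, len(verts), block):
        chunk = verts[start : start + block]
        d2 = (
            (chunk[:, None, :] - tum_pts[None, :, :]) ** 2
        ).sum(axis=2)
        dmin = d2.min(axis=1, keepdims=True)
        tied = d2 <= dmin + 1e-9
        scalar[start : start + block] = np.where(tied, margins[None, :], np.inf).min(axis=1)

    labels = tuple(classify(s).label for s in scalar)
    return SurfaceColorMap(vertices=verts, scalar=scalar, labels=labels)


def write_surface_mesh(cmap: SurfaceColorMap, path) -> Path:
    """Write the surface map as legacy-VTK ASCII polydata.

    One vertex cell per surface voxel, with point data ``qam_mm`` (signed
    margin, float) and ``qam_class`` (0 orange / 1 yellow / 2 green).
    Readable by ParaView and other VTK-based viewers.
    """
    path = Path(path)
    n = len(cmap.vertices)
    lines = [
        "# vtk DataFile Version 3.0",
        "qamargin surface margins",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{x:.6g} {y:.6g} {z:.6g}" for x, y, z in cmap.vertices]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS qam_mm float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.6g}" for v in cmap.scalar]
    lines.append("SCALARS qam_class int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(_CLASS_CODE[lab]) for lab in cmap.labels]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_surface_mesh(path) -> SurfaceColorMap:
    """Re-read a polydata file written by :func:`write_surface_mesh`."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts, scalars, codes = [], [], []
    n = 0
    for line in it:
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            verts = [tuple(float(t) for t in next(it).split()) for _ in range(n)]
        elif line.startswith("SCALARS qam_mm"):
            next(it)  # LOOKUP_TABLE
            scalars = [float(next(it)) for _ in range(n)]
        elif line.startswith("SCALARS qam_class"):
            next(it)
            codes = [int(next(it)) for _ in range(n)]
    code_to_label = {v: k for k, v in _CLASS_CODE.items()}
    return SurfaceColorMap(
        vertices=np.asarray(verts, dtype=float),
        scalar=np.asarray(scalars, dtype=float),
        labels=tuple(code_to_label[c] for c in codes),
    )
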