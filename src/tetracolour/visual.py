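"""Tetrahedral colour-space model for tetrachromatic (avian) vision.

A stimulus spectrum is reduced to four receptor quantum catches, normalised
by the catches for an adapting background (von Kries adaptation), and the
four relative catches (summing to one) are embedded as barycentric weights
of a regular tetrahedron: the colour locus.

Vertex convention
-----------------
The tetrahedron is regular with unit circumradius and centroid at the
origin. Receptors are ordered short -> long wavelength; the vertex of the
longest-wavelength receptor sits exactly on the +x axis at (1, 0, 0), and
the other three lie in the plane x = -1/3. The achromatic point (equal
stimulation of all four receptors) is the origin. This convention is fixed
for the whole package; the tetrahedron volume used as the occupancy
baseline is derived from it, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import WAVELENGTH_GRID, ReflectanceSpectrum, read_spectra

__all__ = [
    "tetrahedron_vertices",
    "VisualSystem",
    "QuantumCatchVector",
    "ColourLocus",
    "quantum_catches",
    "to_locus",
    "load_visual_system",
    "builtin_visual_system",
    "builtin_illuminant",
    "builtin_background",
    "barycentric_weights",
    "read_loci_csv",
    "write_loci_csv",
]

VISITATION_CLASSES = ("insect", "bird", "both")


def tetrahedron_vertices() -> np.ndarray:
    """Vertices of the colour tetrahedron, rows ordered short -> long
    wavelength receptor. Regular, unit circumradius, centroid at origin;
    the long-wavelength vertex is (1, 0, 0)."""
    r = 2.0 * np.sqrt(2.0) / 3.0
    angles = np.array([np.pi / 2, 7 * np.pi / 6, 11 * np.pi / 6])
    verts = np.empty((4, 3))
    verts[:3, 0] = -1.0 / 3.0
    verts[:3, 1] = r * np.cos(angles)
    verts[:3, 2] = r * np.sin(angles)
    verts[3] = (1.0, 0.0, 0.0)
    return verts


@dataclass(frozen=True)
class VisualSystem:
    """Four receptor sensitivity curves plus tetrahedron geometry.

    Curves must share one wavelength grid, be non-negative, and peak in
    strictly ascending wavelength order (index 0 = shortest-wavelength
    receptor).
    """

    name: str
    sensitivities: tuple[ReflectanceSpectrum, ...]
    vertices: np.ndarray = field(default_factory=tetrahedron_vertices)

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 4:
            raise ValueError(
                f"a visual system needs exactly 4 receptor curves, got {len(self.sensitivities)}"
            )
        grid = self.sensitivities[0].wavelengths
        peaks = []
        for s in self.sensitivities:
            if not s.on_grid(grid):
                raise ValueError("receptor curves are not on a common grid")
            if np.any(s.reflectance < 0):
                raise ValueError(f"negative sensitivity in receptor {s.label!r}")
            if s.reflectance.max() <= 0:
                raise ValueError(f"receptor {s.label!r} is identically zero")
            peaks.append(grid[int(np.argmax(s.reflectance))])
        if not np.all(np.diff(peaks) > 0):
            raise ValueError(
                f"receptor peaks must be strictly ascending short->long, got {peaks}"
            )
        verts = np.asarray(self.vertices, dtype=float)
        if verts.shape != (4, 3):
            raise ValueError("vertices must be a 4x3 array")
        d = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=-1)
        edges = d[np.triu_indices(4, 1)]
        if not np.allclose(edges, edges[0], rtol=1e-9):
            raise ValueError("tetrahedron vertices are not pairwise equidistant")
        if not np.allclose(verts.mean(axis=0), 0.0, atol=1e-9):
            raise ValueError("tetrahedron centroid is not at the origin")
        verts.setflags(write=False)
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "sensitivities", tuple(self.sensitivities))

    @property
    def grid(self) -> np.ndarray:
        return self.sensitivities[0].wavelengths

    @property
    def peak_wavelengths(self) -> np.ndarray:
        g = self.grid
        return np.array([g[int(np.argmax(s.reflectance))] for s in self.sensitivities])

    def tetrahedron_volume(self) -> float:
        """Volume of the full colour tetrahedron under this vertex geometry."""
        v = self.vertices
        return float(abs(np.linalg.det(v[1:] - v[0])) / 6.0)


@dataclass(frozen=True)
class QuantumCatchVector:
    """Four receptor quantum catches and their normalised (sum-to-one)
    relative values."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,):
            raise ValueError(f"expected 4 quantum catches, got shape {q.shape}")
        if np.any(q < 0) or not np.all(np.isfinite(q)):
            raise ValueError("quantum catches must be finite and non-negative")
        if q.sum() <= 0:
            raise ValueError("all quantum catches are zero; relative catches undefined")
        q.setflags(write=False)
        object.__setattr__(self, "q", q)

    @property
    def relative(self) -> np.ndarray:
        rel = self.q / self.q.sum()
        assert abs(rel.sum() - 1.0) < 1e-12
        return rel


@dataclass(frozen=True)
class ColourLocus:
    """A species' position in the colour tetrahedron."""

    species: str
    xyz: np.ndarray
    visitation: str | None = None
    subgroup: str | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")
        if self.visitation is not None and self.visitation not in VISITATION_CLASSES:
            raise ValueError(
                f"visitation must be one of {VISITATION_CLASSES}, got {self.visitation!r}"
            )
        xyz.setflags(write=False)
        object.__setattr__(self, "xyz", xyz)


def quantum_catches(
    s: ReflectanceSpectrum,
    vs: VisualSystem,
    illuminant: ReflectanceSpectrum,
    background: ReflectanceSpectrum,
) -> QuantumCatchVector:
    """Von Kries-adapted quantum catches of the four receptors.

    For receptor i, the catch is the integral of R_i * S * I over
    wavelength, divided by the same integral with the background
    reflectance in place of S. Trapezoidal quadrature on the shared grid.
    """
    grid = vs.grid
    for other, what in ((s, "stimulus"), (illuminant, "illuminant"), (background, "background")):
        if not other.on_grid(grid):
            raise ValueError(f"{what} spectrum is not on the visual system's grid")
    q = np.empty(4)
    for i, recep in enumerate(vs.sensitivities):
        ri = recep.reflectance * illuminant.reflectance
        denom = np.trapezoid(ri * background.reflectance, grid)
        if denom <= 0:
            raise ValueError(
                f"zero background catch for receptor {i}; von Kries adaptation undefined"
            )
        q[i] = np.trapezoid(ri * s.reflectance, grid) / denom
    if q.sum() <= 0:
        raise ValueError(
            f"stimulus {s.label!r} yields zero catch in every receptor (dark stimulus)"
        )
    return QuantumCatchVector(q)


def to_locus(
    q: QuantumCatchVector,
    vs: VisualSystem,
    species: str = "",
    visitation: str | None = None,
    subgroup: str | None = None,
) -> ColourLocus:
    """Barycentric embedding of the relative catches: xyz = sum_i rel_i * vertex_i."""
    xyz = vs.vertices.T @ q.relative
    return ColourLocus(species=species, xyz=xyz, visitation=visitation, subgroup=subgroup)


def barycentric_weights(vs: VisualSystem, xyz: np.ndarray) -> np.ndarray:
    """Invert the embedding: the four barycentric weights of a point
    (sum to one; all >= 0 iff the point is inside the tetrahedron)."""
    A = np.vstack([vs.vertices.T, np.ones(4)])
    b = np.append(np.asarray(xyz, dtype=float), 1.0)
    return np.linalg.solve(A, b)


def load_visual_system(path: str | Path, name: str = "custom") -> VisualSystem:
    """Load a four-column sensitivity CSV (wavelength + four receptor
    columns, short -> long) and resample onto the standard grid."""
    curves = read_spectra(path)
    if len(curves) != 4:
        raise ValueError(
            f"sensitivity file must have exactly 4 receptor columns, got {len(curves)}"
        )
    curves = [c.resample(WAVELENGTH_GRID) for c in curves]
    return VisualSystem(name=name, sensitivities=tuple(curves))


def _data_path(fname: str):
    return resources.files("tetracolour.data").joinpath(fname)


def builtin_visual_system(name: str) -> VisualSystem:
    """Packaged average sensitivity curves for the two avian colour-vision
    classes: ``'VS'`` (violet-sensitive) or ``'UVS'`` (ultraviolet-sensitive).

    The curves are regenerated from a published visual-pigment template
    (see ``scripts/generate_builtin_data.py``) and approximate published
    average receptor sensitivities.
    """
    key = name.upper()
    if key not in ("VS", "UVS"):
        raise ValueError(f"unknown visual system {name!r}; expected 'VS' or 'UVS'")
    with resources.as_file(_data_path(f"{key.lower()}_sensitivities.csv")) as p:
        return load_visual_system(p, name=key)


def builtin_illuminant() -> ReflectanceSpectrum:
    """Packaged standard-daylight irradiance table, 6500 K colour temperature."""
    with resources.as_file(_data_path("illuminant_d65.csv")) as p:
        return read_spectra(p)[0].resample(WAVELENGTH_GRID)


def builtin_background() -> ReflectanceSpectrum:
    """Packaged leaf-green adapting background reflectance."""
    with resources.as_file(_data_path("leaf_background.csv")) as p:
        return read_spectra(p)[0].resample(WAVELENGTH_GRID)


def read_loci_csv(path: str | Path) -> list[ColourLocus]:
    """Read loci from CSV with columns ``species,x,y,z[,visitation][,subgroup]``."""
    df = pd.read_csv(path, comment="#")
    required = {"species", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"loci CSV must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        vis = row.get("visitation")
        sub = row.get("subgroup")
        out.append(
            ColourLocus(
                species=str(row["species"]),
                xyz=np.array([row["x"], row["y"], row["z"]], dtype=float),
                visitation=None if pd.isna(vis) else str(vis),
                subgroup=None if pd.isna(sub) else str(sub),
            )
        )
    return out


def write_loci_csv(loci: list[ColourLocus], path: str | Path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "species": [l.species for l in loci],
            "x": [l.xyz[0] for l in loci],
            "y": [l.xyz[1] for l in loci],
            "z": [l.xyz[2] for l in loci],
            "visitation": [l.visitation if l.visitation is not None else "" for l in loci],
            "subgroup": [l.subgroup if l.subgroup is not None else "" for l in loci],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
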