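"""Friction (cost) surfaces for landscape permeability.

A friction grid assigns every raster cell a relative traversal cost;
impassable cells (sea, full barriers) carry an infinite sentinel.  The
cost rules mirror the candidate models explored in refugial landscape
genetics: flat land costs 1, terrain ruggedness (TRI) is added
everywhere, and each geographic feature class can independently be
omitted, treated as a full barrier, or costed:

===================  =============================
class                cost when "costed"
===================  =============================
river                TRI + 1
glacier              max(TRI + 1) + 1
desert               max(TRI + 1) + 1
swamp                max(TRI + 1) + 1
bosporus             1 (opens a sea corridor)
channel              1 (opens a sea corridor)
riverside_desert     TRI + 1 (overrides desert)
===================  =============================

``max(TRI + 1)`` is evaluated over the passable land cells of the grid.
Overlap precedence: barriers > riverside_desert > costed surfaces > base.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Raster",
    "FeatureLayer",
    "FrictionModel",
    "FrictionGrid",
    "FEATURE_MODES",
    "read_ascii_grid",
    "write_ascii_grid",
    "terrain_ruggedness",
    "assemble_friction",
    "enumerate_models",
]

IMPASSABLE = np.inf

#: allowed modes per feature class; straits flip from sea to a cost-1
#: corridor when costed, surface classes get a surcharge or a barrier.
FEATURE_MODES: dict[str, tuple[str, ...]] = {
    "river": ("omit", "barrier", "costed"),
    "glacier": ("omit", "barrier", "costed"),
    "desert": ("omit", "barrier", "costed"),
    "swamp": ("omit", "barrier", "costed"),
    "bosporus": ("omit", "barrier", "costed"),
    "channel": ("omit", "barrier", "costed"),
    "riverside_desert": ("omit", "costed"),
}
_STRAITS = ("bosporus", "channel")
_SURCHARGE = ("glacier", "desert", "swamp")  # costed => max(TRI+1) + 1


@dataclass
class Raster:
    """Rectangular grid with a projected-km georeference.

    ``(x0, y0)`` is the outer (top-left) corner of cell (0, 0); the center
    of cell (row, col) sits at ``(x0 + (col + .5) h, y0 - (row + .5) h)``
    with ``h = cell_size``.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        h = self.cell_size
        return self.x0 + (col + 0.5) * h, self.y0 - (row + 0.5) * h

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell whose center is nearest to the point (x, y)."""
        h = self.cell_size
        col = int(round((x - self.x0) / h - 0.5))
        row = int(round((self.y0 - y) / h - 0.5))
        return row, col

    def like(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.x0, self.y0, self.cell_size, self.nodata)


@dataclass
class FeatureLayer:
    """Boolean presence mask for one feature class, aligned with elevation."""

    feature_class: str
    mask: Raster

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_MODES and self.feature_class != "land":
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        self.mask.values = self.mask.values.astype(bool)


@dataclass(frozen=True)
class FrictionModel:
    """One candidate cost model: a mode per feature class.

    Land (cost 1) and the additive TRI term are always present.  A class
    absent from ``modes`` is omitted.  A class cannot be both barrier and
    costed, which the single-mode mapping enforces by construction.
    """

    modes: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_dict(cls, modes: dict[str, str]) -> "FrictionModel":
        for klass, mode in modes.items():
            if klass not in FEATURE_MODES:
                raise ValueError(f"unknown feature class {klass!r}")
            if mode not in FEATURE_MODES[klass]:
                raise ValueError(f"mode {mode!r} not allowed for {klass!r}")
        return cls(tuple(sorted(modes.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.modes)

    def mode(self, klass: str) -> str:
        return dict(self.modes).get(klass, "omit")

    @property
    def included_classes(self) -> list[str]:
        return [k for k, m in self.modes if m != "omit"]

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FrictionModel":
        return cls.from_dict(json.loads(text))

    def __str__(self) -> str:  # compact provenance tag
        inc = [f"{k}={m}" for k, m in self.modes if m != "omit"]
        return "tri" + ("+" + "+".join(inc) if inc else "")


@dataclass
class FrictionGrid:
    """Per-cell traversal cost; impassable cells are +inf (never a large
    finite number)."""

    cost: Raster
    model: FrictionModel | None = None

    @property
    def passable(self) -> np.ndarray:
        return np.isfinite(self.cost.values)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | os.PathLike) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[tokens[0].lower()] = float(tokens[1])
            else:
                rows.append(np.array(tokens, dtype=float))
    values = np.vstack(rows)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: body shape {values.shape} != header "
                         f"({nrows}, {ncols})")
    h = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    return Raster(
        values=values,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * h,  # ESRI stores the lower-left corner
        cell_size=h,
        nodata=nodata,
    )


def write_ascii_grid(raster: Raster, path: str | os.PathLike) -> None:
    nrows, ncols = raster.shape
    vals = np.where(np.isfinite(raster.values.astype(float)),
                    raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0 - nrows * raster.cell_size:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Terrain ruggedness
# ---------------------------------------------------------------------------

def terrain_ruggedness(elevation: Raster) -> Raster:
    """Terrain Ruggedness Index: per cell, the mean absolute elevation
    difference to its up-to-8 valid neighbors.

    Edge cells use the neighbors they have; nodata cells propagate to
    nodata and are excluded as neighbors.
    """
    z = elevation.values.astype(float)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("elevation must have at least 2x2 cells")
    valid = np.isfinite(z) & (z != elevation.nodata)
    if not valid.any():
        logger.warning("terrain_ruggedness: all-nodata input")
        return elevation.like(np.full(z.shape, np.nan))

    zz = np.where(valid, z, 0.0)
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(z, np.nan)
            sv = np.zeros(z.shape, dtype=bool)
            rs = slice(max(dr, 0), z.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), z.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
            shifted[rd, cd] = zz[rs, cs]
            sv[rd, cd] = valid[rs, cs]
            diff = np.abs(z - shifted)
            total += np.where(sv & valid, diff, 0.0)
            count += (sv & valid)
    with np.errstate(invalid="ignore"):
        tri = np.where(valid & (count > 0), total / np.maximum(count, 1), np.nan)
    return elevation.like(tri)


# ---------------------------------------------------------------------------
# Friction assembly and model enumeration
# ---------------------------------------------------------------------------

def assemble_friction(
    elevation: Raster,
    layers: dict[str, FeatureLayer] | list[FeatureLayer],
    model: FrictionModel,
) -> FrictionGrid:
    """Build the cost surface for one candidate model.

    Base cost on land is TRI + 1; sea (cells outside the ``land`` layer,
    if one is given) is impassable unless a strait class in mode "costed"
    opens a cost-1 corridor.  Surface classes in mode "costed" get the
    ceiling cost max(TRI + 1) + 1 (glacier/desert/swamp) or TRI + 1
    (river, riverside_desert); mode "barrier" makes their cells
    impassable.  Riverside-in-desert cells override desert.
    """
    if isinstance(layers, list):
        layers = {l.feature_class: l for l in layers}
    for name, layer in layers.items():
        if not layer.mask.aligned_with(elevation):
            raise ValueError(f"feature layer {name!r} is not aligned with elevation")

    tri = terrain_ruggedness(elevation).values
    base = tri + 1.0
    land = layers["land"].mask.values if "land" in layers else np.ones(
        elevation.shape, dtype=bool
    )
    cost = np.where(land, base, IMPASSABLE)

    passable_land = land & np.isfinite(base)
    if not passable_land.any():
        raise ValueError("no passable land cells")
    ceiling = float(np.nanmax(base[passable_land])) + 1.0

    def mask_of(klass: str) -> np.ndarray | None:
        layer = layers.get(klass)
        return None if layer is None else layer.mask.values

    # costed surfaces (lowest precedence among overrides)
    for klass in _SURCHARGE:
        m = mask_of(klass)
        if m is not None and model.mode(klass) == "costed":
            cost = np.where(m & land, ceiling, cost)
    m = mask_of("river")
    if m is not None and model.mode("river") == "costed":
        cost = np.where(m & land, base, cost)
    for klass in _STRAITS:
        m = mask_of(klass)
        if m is not None and model.mode(klass) == "costed":
            cost = np.where(m, 1.0, cost)  # opens a corridor across sea

    # riverside-in-desert overrides costed surfaces
    m = mask_of("riverside_desert")
    if m is not None and model.mode("riverside_desert") == "costed":
        cost = np.where(m & land, base, cost)

    # barriers win over everything
    for klass, modes in FEATURE_MODES.items():
        if "barrier" not in modes:
            continue
        m = mask_of(klass)
        if m is not None and model.mode(klass) == "barrier":
            cost = np.where(m, IMPASSABLE, cost)

    return FrictionGrid(cost=elevation.like(cost), model=model)


def enumerate_models(classes: list[str] | tuple[str, ...]) -> list[FrictionModel]:
    """All non-conflicting mode assignments over ``classes``.

    Each tri-state class contributes {omit, barrier, costed}; riverside
    in desert only {omit, costed}.  Land and TRI are implicit in every
    model.  The full 7-class set yields 3^6 * 2 = 1458 models.
    """
    classes = [c for c in classes if c != "land"]
    for c in classes:
        if c not in FEATURE_MODES:
            raise ValueError(f"unknown feature class {c!r}")
    choices = [FEATURE_MODES[c] for c in classes]
    models = []
    for combo in itertools.product(*choices):
        modes = {c: m for c, m in zip(classes, combo) if m != "omit"}
        models.append(FrictionModel.from_dict(modes))
    return models
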