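"""Space-time grids and tagged field arrays.

A :class:`SpatioTemporalGrid` describes a regular (x[, y], t) lattice on the
flattened cortical sheet; a :class:`Field` is a real array living on such a
grid with a quantity tag (neural drive ``z``, inflow ``F``, blood mass ``xi``,
pressure ``P``, dHb ``Q``, BOLD ``y``, or a velocity component) and a units
tag.  Array layout is ``(nx, nt)`` for 1-D space and ``(ny, nx, nt)`` for 2-D;
time is always the last axis.

The spatial origin sits at the center of the x axis (x = 0 on the stimulus
centerline) and t = 0 at the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["SpatioTemporalGrid", "Field", "GridMismatchError"]

_QUANTITIES = {"z", "F", "xi", "P", "Q", "y", "vx", "vy"}


class GridMismatchError(ValueError):
    """Fields defined on incompatible grids were combined."""


@dataclass(frozen=True)
class SpatioTemporalGrid:
    """Regular lattice in space and time.

    Parameters
    ----------
    dx : float
        Spatial step (mm); isotropic in x and y.
    dt : float
        Temporal step (s).
    nx, ny, nt : int
        Number of samples; ``ny = 1`` means 1-D space.
    """

    dx: float
    dt: float
    nx: int
    nt: int
    ny: int = 1

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.nx < 2 or self.nt < 2 or self.ny < 1:
            raise ValueError("grid must have at least 2 samples in x and t")

    # -- coordinates -------------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        """x coordinates (mm), centered so x = 0 lies on a sample."""
        return (np.arange(self.nx) - self.nx // 2) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.dx

    @property
    def t(self) -> np.ndarray:
        """t coordinates (s), starting at 0."""
        return np.arange(self.nt) * self.dt

    @property
    def is_1d(self) -> bool:
        return self.ny == 1

    @property
    def shape(self) -> tuple:
        return (self.nx, self.nt) if self.is_1d else (self.ny, self.nx, self.nt)

    @property
    def extent_x(self) -> float:
        return self.nx * self.dx

    @property
    def duration(self) -> float:
        return self.nt * self.dt

    def cfl_dt(self, v_beta: float) -> float:
        """Largest stable explicit time step dx / v_beta for wave speed v_beta (mm/s)."""
        return self.dx / v_beta

    def with_shape(self, nx=None, ny=None, nt=None) -> "SpatioTemporalGrid":
        return SpatioTemporalGrid(
            dx=self.dx, dt=self.dt,
            nx=self.nx if nx is None else nx,
            nt=self.nt if nt is None else nt,
            ny=self.ny if ny is None else ny,
        )


@dataclass
class Field:
    """Real-valued quantity sampled on a :class:`SpatioTemporalGrid`."""

    values: np.ndarray
    grid: SpatioTemporalGrid
    quantity: str = "y"
    units: str = ""
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"unknown quantity tag {self.quantity!r}; expected one of {sorted(_QUANTITIES)}")
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"field shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must all be finite")

    def same_grid(self, other: "Field") -> bool:
        return self.grid == other.grid

    def copy_with(self, values: np.ndarray, quantity: str | None = None,
                  units: str | None = None, **meta) -> "Field":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Field(values=values, grid=self.grid,
                     quantity=self.quantity if quantity is None else quantity,
                     units=self.units if units is None else units,
                     meta=new_meta)

    def to_xarray(self):
        """Optional xarray view (lazy import; xarray is not a hard dependency)."""
        import xarray as xr

        g = self.grid
        if g.is_1d:
            return xr.DataArray(self.values, dims=("x", "t"),
                                coords={"x": g.x, "t": g.t},
                                name=self.quantity, attrs={"units": self.units})
        return xr.DataArray(self.values, dims=("y", "x", "t"),
                            coords={"y": g.y, "x": g.x, "t": g.t},
                            name=self.quantity, attrs={"units": self.units})
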