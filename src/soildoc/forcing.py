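"""The forcing contract of the column simulator.

A :class:`ForcingSeries` is a uniform-step record of every driver the
soil column needs: per-layer soil temperature and moisture, the three
water export fluxes (surface runoff, sub-surface runoff, drainage),
litter carbon input and vegetation cover, plus an optional NPP series
carried through for budget bookkeeping.  The class validates its
invariants on construction (no gaps, no NaNs, non-negative water and
litter, saturation fraction in [0, 1]) so the simulator can trust it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ForcingError

__all__ = ["ForcingSeries", "FORCING_SCALAR_COLUMNS", "forcing_layer_columns"]

#: Scalar (non-layered) CSV column names, in schema order.
FORCING_SCALAR_COLUMNS = (
    "surf_runoff_kg_m2",
    "sub_runoff_kg_m2",
    "drainage_kg_m2",
    "litter_gc_m2",
    "veg_cover",
)


def forcing_layer_columns(n_layers: int) -> list[str]:
    """Per-layer CSV column names for an n-layer forcing schema."""
    cols = []
    for stem in ("tsoil_k", "water_kg_m2", "sat_frac"):
        cols.extend(f"{stem}_l{i + 1}" for i in range(n_layers))
    return cols


@dataclass
class ForcingSeries:
    """Uniform-dt driver record for one soil column.

    Shapes: per-layer arrays are ``(n_steps, n_layers)``; scalar drivers
    are ``(n_steps,)``.  Water amounts in kg H₂O m⁻² (per step for the
    export fluxes), temperature in K, litter in g C m⁻² per step.
    """

    start: np.datetime64
    dt: float  # seconds
    t_soil: np.ndarray
    water: np.ndarray
    sat_frac: np.ndarray
    surf_runoff: np.ndarray
    sub_runoff: np.ndarray
    drainage: np.ndarray
    litter: np.ndarray
    veg_cover: np.ndarray
    npp: np.ndarray | None = field(default=None)  # g C m-2 yr-1, bookkeeping only

    def __post_init__(self) -> None:
        self.start = np.datetime64(self.start, "s")
        if self.dt <= 0:
            raise ForcingError("dt must be positive")
        for name in ("t_soil", "water", "sat_frac"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
        for name in ("surf_runoff", "sub_runoff", "drainage", "litter", "veg_cover"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.npp is not None:
            self.npp = np.atleast_1d(np.asarray(self.npp, dtype=float))

        n, L = self.t_soil.shape
        for name in ("water", "sat_frac"):
            if getattr(self, name).shape != (n, L):
                raise ForcingError(f"{name} must have shape {(n, L)}")
        for name in ("surf_runoff", "sub_runoff", "drainage", "litter", "veg_cover"):
            if getattr(self, name).shape != (n,):
                raise ForcingError(f"{name} must have shape {(n,)}")
        if self.npp is not None and self.npp.shape != (n,):
            raise ForcingError(f"npp must have shape {(n,)}")

        for name in ("t_soil", "water", "sat_frac", "surf_runoff", "sub_runoff",
                     "drainage", "litter", "veg_cover"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr).reshape(n, -1).all(axis=1))[0])
                raise ForcingError(f"non-finite value in forcing field {name!r} at step {bad}")
        if np.any(self.t_soil <= 0):
            raise ForcingError("soil temperature must be positive (kelvin)")
        for name in ("water", "surf_runoff", "sub_runoff", "drainage", "litter"):
            if np.any(getattr(self, name) < 0):
                raise ForcingError(f"forcing field {name!r} must be non-negative")
        if np.any((self.sat_frac < 0) | (self.sat_frac > 1)):
            raise ForcingError("sat_frac must lie in [0, 1]")
        if np.any((self.veg_cover < 0) | (self.veg_cover > 1)):
            raise ForcingError("veg_cover must lie in [0, 1]")

    # ------------------------------------------------------------------ basic
    @property
    def n_steps(self) -> int:
        return self.t_soil.shape[0]

    @property
    def n_layers(self) -> int:
        return self.t_soil.shape[1]

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.start + (np.arange(self.n_steps) * self.dt).astype("timedelta64[s]"))

    @property
    def dt_days(self) -> float:
        return self.dt / 86400.0

    def __len__(self) -> int:
        return self.n_steps

    # ------------------------------------------------------------- transforms
    def repeat(self, n_cycles: int) -> "ForcingSeries":
        """Tile this series n_cycles times (a repeatable climatology)."""
        if n_cycles < 1:
            raise ForcingError("n_cycles must be >= 1")

        def tile(a: np.ndarray | None) -> np.ndarray | None:
            return None if a is None else np.concatenate([a] * n_cycles, axis=0)

        return replace(
            self,
            t_soil=tile(self.t_soil), water=tile(self.water), sat_frac=tile(self.sat_frac),
            surf_runoff=tile(self.surf_runoff), sub_runoff=tile(self.sub_runoff),
            drainage=tile(self.drainage), litter=tile(self.litter),
            veg_cover=tile(self.veg_cover), npp=tile(self.npp),
        )

    def scale_runoff(self, factor: float) -> "ForcingSeries":
        """Uniformly scale all three water export fluxes (sensitivity sweeps)."""
        if factor < 0:
            raise ForcingError("runoff scale factor must be non-negative")
        return replace(
            self,
            surf_runoff=self.surf_runoff * factor,
            sub_runoff=self.sub_runoff * factor,
            drainage=self.drainage * factor,
        )

    def subset(self, start: int, stop: int) -> "ForcingSeries":
        """Contiguous step range [start, stop) as a new series."""
        def cut(a: np.ndarray | None):
            return None if a is None else a[start:stop]

        return replace(
            self,
            start=self.start + np.timedelta64(int(start * self.dt), "s"),
            t_soil=cut(self.t_soil), water=cut(self.water), sat_frac=cut(self.sat_frac),
            surf_runoff=cut(self.surf_runoff), sub_runoff=cut(self.sub_runoff),
            drainage=cut(self.drainage), litter=cut(self.litter),
            veg_cover=cut(self.veg_cover), npp=cut(self.npp),
        )

    # ------------------------------------------------------------------ views
    def annual_runoff(self) -> float:
        """Mean total water export, kg H₂O m⁻² yr⁻¹."""
        steps_per_year = 365.0 * 86400.0 / self.dt
        total = self.surf_runoff.sum() + self.sub_runoff.sum() + self.drainage.sum()
        return float(total / self.n_steps * steps_per_year)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to the documented CSV schema (one row per step)."""
        data: dict[str, np.ndarray] = {}
        for stem, arr in (("tsoil_k", self.t_soil), ("water_kg_m2", self.water),
                          ("sat_frac", self.sat_frac)):
            for i in range(self.n_layers):
                data[f"{stem}_l{i + 1}"] = arr[:, i]
        data["surf_runoff_kg_m2"] = self.surf_runoff
        data["sub_runoff_kg_m2"] = self.sub_runoff
        data["drainage_kg_m2"] = self.drainage
        data["litter_gc_m2"] = self.litter
        data["veg_cover"] = self.veg_cover
        if self.npp is not None:
            data["npp_gc_m2_yr"] = self.npp
        return pd.DataFrame(data, index=self.times.rename("time"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForcingSeries":
        """Rebuild from the documented CSV schema; validates gaps and columns."""
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ForcingError("forcing dataframe needs a DatetimeIndex named 'time'")
        if len(df) < 2:
            raise ForcingError("forcing needs at least two steps to define dt")
        deltas = np.diff(df.index.values).astype("timedelta64[s]").astype(float)
        dt = deltas[0]
        gaps = np.flatnonzero(deltas != dt)
        if gaps.size:
            intervals = [f"{df.index[g]} -> {df.index[g + 1]}" for g in gaps[:5]]
            raise ForcingError(f"forcing has time gaps at: {', '.join(intervals)}")

        n_layers = sum(c.startswith("tsoil_k_l") for c in df.columns)
        if n_layers == 0:
            raise ForcingError("missing per-layer column 'tsoil_k_l1'")
        needed = forcing_layer_columns(n_layers) + list(FORCING_SCALAR_COLUMNS)
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ForcingError(f"missing forcing columns: {missing}")

        def layered(stem: str) -> np.ndarray:
            return df[[f"{stem}_l{i + 1}" for i in range(n_layers)]].to_numpy(dtype=float)

        return cls(
            start=np.datetime64(df.index[0].to_datetime64(), "s"),
            dt=float(dt),
            t_soil=layered("tsoil_k"),
            water=layered("water_kg_m2"),
            sat_frac=layered("sat_frac"),
            surf_runoff=df["surf_runoff_kg_m2"].to_numpy(dtype=float),
            sub_runoff=df["sub_runoff_kg_m2"].to_numpy(dtype=float),
            drainage=df["drainage_kg_m2"].to_numpy(dtype=float),
            litter=df["litter_gc_m2"].to_numpy(dtype=float),
            veg_cover=df["veg_cover"].to_numpy(dtype=float),
            npp=df["npp_gc_m2_yr"].to_numpy(dtype=float) if "npp_gc_m2_yr" in df.columns else None,
        )
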