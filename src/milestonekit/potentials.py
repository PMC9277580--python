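"""Analytic toy potentials for the stochastic dynamics engine.

Each potential exposes ``energy(x)`` / ``gradient(x)`` (kcal/mol and
kcal/mol/Å, positions in Å) plus a compact ``(kind_code, params_array)``
encoding consumed by the compiled integrator kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlatPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "RadialHarmonicPotential",
    "TabulatedPotential1D",
    "potential_from_config",
]

FLAT, HARMONIC, DOUBLE_WELL, RADIAL_HARMONIC, TABULATED_1D = 0, 1, 2, 3, 4


class ToyPotential:
    kind_code: int

    def energy(self, x) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params_array(self) -> np.ndarray:
        return np.zeros(1)

    def check_gradient(self, x, h: float = 1e-6, rtol: float = 1e-4) -> bool:
        """Finite-difference consistency of gradient with energy."""
        x = np.asarray(x, dtype=float)
        grad = self.gradient(x)
        num = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        scale = max(1.0, float(np.max(np.abs(grad))), float(np.max(np.abs(num))))
        return bool(np.max(np.abs(grad - num)) / scale < rtol)

    def to_config(self) -> dict:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class FlatPotential(ToyPotential):
    """Zero potential (free diffusion)."""

    kind_code = FLAT

    def energy(self, x) -> float:
        return 0.0

    def gradient(self, x) -> np.ndarray:
        return np.zeros_like(np.asarray(x, dtype=float))

    def to_config(self) -> dict:
        return {"kind": "flat"}


@dataclass(frozen=True)
class HarmonicPotential(ToyPotential):
    """U = k/2 |x - center|^2, k in kcal mol^-1 Å^-2."""

    k: float
    center: tuple[float, ...] = (0.0,)
    kind_code = HARMONIC

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.center, dtype=float)
        return float(0.5 * self.k * np.sum((x - c) ** 2))

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.center, dtype=float)
        return self.k * (x - c)

    def params_array(self) -> np.ndarray:
        return np.array([self.k, *self.center], dtype=float)

    def to_config(self) -> dict:
        return {"kind": "harmonic", "k": self.k, "center": list(self.center)}


@dataclass(frozen=True)
class DoubleWellPotential(ToyPotential):
    """1-D symmetric double well U = h ((x^2 - a^2)/a^2)^2.

    ``h`` is the barrier height (kcal/mol) at x = 0; minima sit at x = ±a Å.
    Acts on the first coordinate only.
    """

    barrier_height: float
    well_position: float
    kind_code = DOUBLE_WELL

    def energy(self, x) -> float:
        x0 = float(np.asarray(x, dtype=float).ravel()[0])
        a2 = self.well_position**2
        return float(self.barrier_height * ((x0 * x0 - a2) / a2) ** 2)

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        x0 = float(x.ravel()[0])
        a2 = self.well_position**2
        g.ravel()[0] = 4.0 * self.barrier_height * x0 * (x0 * x0 - a2) / (a2 * a2)
        return g

    def params_array(self) -> np.ndarray:
        return np.array([self.barrier_height, self.well_position], dtype=float)

    def to_config(self) -> dict:
        return {
            "kind": "double-well",
            "barrier_height": self.barrier_height,
            "well_position": self.well_position,
        }


@dataclass(frozen=True)
class RadialHarmonicPotential(ToyPotential):
    """U = k/2 (|x| - r0)^2 — a spherical-shell well in 3-D."""

    k: float
    r0: float
    kind_code = RADIAL_HARMONIC

    def energy(self, x) -> float:
        r = float(np.linalg.norm(np.asarray(x, dtype=float)))
        return float(0.5 * self.k * (r - self.r0) ** 2)

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        r = float(np.linalg.norm(x))
        if r == 0.0:
            return np.zeros_like(x)
        return self.k * (r - self.r0) * x / r

    def params_array(self) -> np.ndarray:
        return np.array([self.k, self.r0], dtype=float)

    def to_config(self) -> dict:
        return {"kind": "radial-harmonic", "k": self.k, "r0": self.r0}


class TabulatedPotential1D(ToyPotential):
    """Piecewise-linear 1-D potential on a uniform grid (first coordinate).

    Outside the grid the potential continues with the edge slope.
    """

    kind_code = TABULATED_1D

    def __init__(self, x_grid, u_grid):
        x_grid = np.asarray(x_grid, dtype=float)
        u_grid = np.asarray(u_grid, dtype=float)
        if x_grid.size != u_grid.size or x_grid.size < 2:
            raise ValueError("grids must have equal length >= 2")
        dx = np.diff(x_grid)
        if not np.allclose(dx, dx[0]):
            raise ValueError("x grid must be uniform")
        self.x0 = float(x_grid[0])
        self.dx = float(dx[0])
        self.u = u_grid.copy()

    def _segment(self, x0: float) -> tuple[int, float]:
        i = int(np.clip(np.floor((x0 - self.x0) / self.dx), 0, self.u.size - 2))
        slope = (self.u[i + 1] - self.u[i]) / self.dx
        return i, slope

    def energy(self, x) -> float:
        x0 = float(np.asarray(x, dtype=float).ravel()[0])
        i, slope = self._segment(x0)
        return float(self.u[i] + slope * (x0 - (self.x0 + i * self.dx)))

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        _, slope = self._segment(float(x.ravel()[0]))
        g.ravel()[0] = slope
        return g

    def params_array(self) -> np.ndarray:
        return np.concatenate(([self.x0, self.dx, float(self.u.size)], self.u))

    def to_config(self) -> dict:
        xs = self.x0 + self.dx * np.arange(self.u.size)
        return {"kind": "tabulated-1d", "x": xs.tolist(), "u": self.u.tolist()}


def potential_from_config(config: dict) -> ToyPotential:
    """Build a potential from its dict/YAML description."""
    kind = config.get("kind", "flat")
    if kind == "flat":
        return FlatPotential()
    if kind == "harmonic":
        return HarmonicPotential(k=float(config["k"]), center=tuple(config.get("center", (0.0,))))
    if kind == "double-well":
        return DoubleWellPotential(
            barrier_height=float(config["barrier_height"]),
            well_position=float(config["well_position"]),
        )
    if kind == "radial-harmonic":
        return RadialHarmonicPotential(k=float(config["k"]), r0=float(config["r0"]))
    if kind == "tabulated-1d":
        return TabulatedPotential1D(config["x"], config["u"])
    raise ValueError(f"unknown potential kind: {kind!r}")
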