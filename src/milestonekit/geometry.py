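"""Collective variables, level-set milestones, and Voronoi-cell models.

A milestoning model partitions a collective-variable (CV) space with an
ordered set of interfaces ("milestones").  Each milestone is the zero level
set of a boundary function that is negative on the interior side and
positive outside.  The regions between consecutive milestones are the
Voronoi cells within which confined (MMVT) trajectories are run.

Two automated constructors cover the common cases:

``build_spherical_model``
    Concentric spherical milestones defined by the distance between the
    centres of mass of two particle groups (for toy systems: a fixed site
    anchor and a diffusing particle).  ``n`` radii produce ``n`` milestones
    and ``n - 1`` bounded shell cells.

``build_linear_model``
    Milestones at fixed positions along a single coordinate, for
    one-dimensional toy potentials.

Conventions (used consistently by the engine and the analysis layer):

* cells are indexed ``0 .. n_cells-1`` from innermost outward;
* milestone ``i`` separates cells ``i-1`` and ``i`` (so cell ``i`` is
  bounded below by milestone ``i`` and above by milestone ``i+1``);
* the innermost milestone is the "bound" milestone and the outermost the
  "bulk"-facing milestone;
* a CV value exactly on a level set is classified as crossed/outside by the
  engine, while :func:`locate_cell` breaks the tie toward the inner cell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "BOUND",
    "BULK",
    "CollectiveVariable",
    "BoundaryFunction",
    "Milestone",
    "Cell",
    "MilestoneModel",
    "build_spherical_model",
    "build_linear_model",
    "boundary_value",
    "locate_cell",
]

#: Marker for the bulk/BD region beyond the outermost milestone.
BULK = "bulk"
#: Marker for the bound region inside the innermost milestone.
BOUND = "bound"


class ModelValidationError(ValueError):
    """Raised when a milestoning model or its configuration is invalid."""


def _as_configuration(configuration) -> np.ndarray:
    conf = np.asarray(configuration, dtype=float)
    if conf.size == 0:
        raise ValueError("empty configuration")
    if conf.ndim == 1:
        conf = conf[None, :]
    if conf.ndim != 2:
        raise ValueError(f"configuration must be (n_particles, ndim), got shape {conf.shape}")
    return conf


@dataclass(frozen=True)
class CollectiveVariable:
    """A scalar function of particle coordinates.

    kinds
    -----
    ``spherical-distance``
        Distance between the centre of mass of ``group_a`` and of
        ``group_b``.  The groups must be non-empty and disjoint.
    ``planar``
        Signed distance of the COM of ``group_a`` along a unit normal
        (``parameters`` = normal components), i.e. a planar interface CV.
    ``linear-combination``
        Sum of ``parameters[k] * x[group_a[k], axis]`` over the particles of
        ``group_a`` (``axis`` fixed to 0); the workhorse for 1-D toys.
    ``rmsd-to-reference``
        RMSD of ``group_a`` coordinates to a reference structure stored in
        ``parameters`` (flattened).
    """

    kind: str
    group_a: tuple[int, ...]
    group_b: tuple[int, ...] = ()
    parameters: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in (
            "spherical-distance",
            "planar",
            "linear-combination",
            "rmsd-to-reference",
        ):
            raise ModelValidationError(f"unknown CV kind: {self.kind!r}")
        if not self.group_a:
            raise ModelValidationError("group_a must be non-empty")
        if self.kind == "spherical-distance":
            if not self.group_b:
                raise ModelValidationError("distance CV requires non-empty group_b")
            if set(self.group_a) & set(self.group_b):
                raise ModelValidationError("group_a and group_b must be disjoint")

    def evaluate(self, configuration) -> float:
        conf = _as_configuration(configuration)
        if self.kind == "spherical-distance":
            com_a = conf[list(self.group_a)].mean(axis=0)
            com_b = conf[list(self.group_b)].mean(axis=0)
            value = float(np.linalg.norm(com_a - com_b))
        elif self.kind == "planar":
            normal = np.asarray(self.parameters, dtype=float)
            normal = normal / np.linalg.norm(normal)
            com_a = conf[list(self.group_a)].mean(axis=0)
            value = float(com_a @ normal)
        elif self.kind == "linear-combination":
            coeffs = np.asarray(self.parameters, dtype=float)
            value = float(np.sum(coeffs * conf[list(self.group_a), 0]))
        else:  # rmsd-to-reference
            ref = np.asarray(self.parameters, dtype=float).reshape(len(self.group_a), -1)
            diff = conf[list(self.group_a)] - ref
            value = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
        if not np.isfinite(value):
            raise ValueError("CV evaluated to a non-finite value")
        return value


@dataclass(frozen=True)
class BoundaryFunction:
    """Level set ``direction * (cv - threshold) = 0``.

    With ``direction = +1`` (the canonical milestone orientation) the value
    is negative on the inner side (cv below threshold) and positive outside.
    """

    cv: CollectiveVariable
    threshold: float
    direction: int = 1

    def value(self, configuration) -> float:
        return self.direction * (self.cv.evaluate(configuration) - self.threshold)


@dataclass(frozen=True)
class Milestone:
    """One interface; separates exactly two regions (cells or markers)."""

    id: int
    boundary: BoundaryFunction
    neighbor_cells: tuple = (BOUND, BULK)

    @property
    def threshold(self) -> float:
        return self.boundary.threshold


@dataclass(frozen=True)
class Cell:
    """Region between two consecutive milestones."""

    id: int
    bounding_milestones: frozenset
    anchor_point: float  # CV-space coordinate strictly interior
    lower_milestone: int = -1
    upper_milestone: int = -1


@dataclass
class MilestoneModel:
    """Ordered milestones partitioning a CV space into cells.

    Parameters
    ----------
    milestones, cells
        Ordered inner-to-outer.
    temperature
        Simulation temperature in K.
    geometry
        ``"spherical"`` (CV = radial distance) or ``"linear"`` (CV = x).
    ndim
        Dimensionality of the toy particle coordinates.
    """

    milestones: list[Milestone]
    cells: list[Cell]
    temperature: float
    geometry: str = "spherical"
    ndim: int = 3
    bound_milestone_id: int = 0
    bulk_milestone_id: int = field(default=-1)

    def __post_init__(self):
        if self.bulk_milestone_id < 0:
            self.bulk_milestone_id = len(self.milestones) - 1
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        thr = self.thresholds
        if len(thr) < 2:
            raise ModelValidationError("a model needs at least 2 milestones")
        if np.any(np.diff(thr) <= 0):
            raise ModelValidationError(f"milestone thresholds must be strictly increasing: {thr}")
        if self.geometry == "spherical" and thr[0] <= 0:
            raise ModelValidationError("spherical milestone radii must be positive")
        if self.temperature <= 0:
            raise ModelValidationError("temperature must be positive")
        ids = [m.id for m in self.milestones]
        if ids != list(range(len(ids))):
            raise ModelValidationError("milestone ids must be 0..n-1 in order")
        if len(self.cells) != len(self.milestones) - 1:
            raise ModelValidationError("cell count must be len(milestones) - 1")
        for cell in self.cells:
            for mid in (cell.lower_milestone, cell.upper_milestone):
                bf = self.cell_boundary_value(cell.anchor_point, mid, cell.id)
                if bf >= 0:
                    raise ModelValidationError(
                        f"anchor of cell {cell.id} not strictly interior to milestone {mid}"
                    )

    # -- basic accessors -----------------------------------------------
    @property
    def thresholds(self) -> np.ndarray:
        return np.array([m.threshold for m in self.milestones], dtype=float)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_milestones(self) -> int:
        return len(self.milestones)

    def cell_bounds(self, cell_id: int) -> tuple[float, float]:
        cell = self.cells[cell_id]
        thr = self.thresholds
        return float(thr[cell.lower_milestone]), float(thr[cell.upper_milestone])

    # -- CV helpers ------------------------------------------------------
    def cv_value(self, x) -> float:
        """CV value of a single toy-particle position (engine convention)."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("empty configuration")
        if self.geometry == "spherical":
            return float(np.linalg.norm(x))
        return float(x[0])

    def cell_boundary_value(self, cv_or_position, milestone_id: int, cell_id: int | None = None) -> float:
        """Signed boundary function of one milestone, negative inside a cell.

        If ``cell_id`` is given and the milestone is that cell's lower bound
        the sign is flipped so the cell interior is negative.
        """
        cv = self._coerce_cv(cv_or_position)
        thr = self.milestones[milestone_id].threshold
        value = cv - thr
        if cell_id is not None and self.cells[cell_id].lower_milestone == milestone_id:
            value = -value
        return float(value)

    def _coerce_cv(self, cv_or_position) -> float:
        if np.isscalar(cv_or_position):
            return float(cv_or_position)
        arr = np.asarray(cv_or_position, dtype=float)
        if arr.ndim == 2:
            # full multi-particle configuration: use the model's CV
            return self.milestones[0].boundary.cv.evaluate(arr)
        return self.cv_value(arr)

    def locate_cell(self, cv_or_position):
        """Map a point to its cell id, or ``BOUND``/``BULK`` markers.

        A point exactly on a milestone is assigned to the inner region.
        """
        cv = self._coerce_cv(cv_or_position)
        thr = self.thresholds
        if cv <= thr[0]:
            return BOUND
        if cv > thr[-1]:
            return BULK
        # first milestone with threshold >= cv; cell index is that - 1
        idx = int(np.searchsorted(thr, cv, side="left"))
        return idx - 1

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.geometry,
            "thresholds": [float(t) for t in self.thresholds],
            "temperature": float(self.temperature),
            "ndim": int(self.ndim),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MilestoneModel":
        kind = data.get("kind", "spherical")
        thresholds = data.get("thresholds") or data.get("radii") or data.get("positions")
        if thresholds is None:
            raise ModelValidationError("model config requires 'radii', 'positions' or 'thresholds'")
        temperature = float(data.get("temperature", 298.15))
        ndim = int(data.get("ndim", 3 if kind == "spherical" else 1))
        if kind == "spherical":
            return build_spherical_model(thresholds, temperature=temperature, ndim=ndim)
        if kind == "linear":
            return build_linear_model(thresholds, temperature=temperature, ndim=ndim)
        raise ModelValidationError(f"unknown model kind: {kind!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "MilestoneModel":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "MilestoneModel":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def model_hash(self) -> str:
        """Stable content hash used to tie collision logs to their model."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _chain_model(thresholds, temperature, geometry, ndim, cv) -> MilestoneModel:
    thr = np.asarray(thresholds, dtype=float)
    if thr.size < 2:
        raise ModelValidationError("need at least 2 milestone thresholds")
    if np.any(np.diff(thr) <= 0):
        raise ModelValidationError(f"thresholds must be strictly increasing: {thr.tolist()}")
    milestones = []
    n = thr.size
    for i, t in enumerate(thr):
        inner = BOUND if i == 0 else i - 1
        outer = BULK if i == n - 1 else i
        milestones.append(
            Milestone(id=i, boundary=BoundaryFunction(cv, float(t)), neighbor_cells=(inner, outer))
        )
    cells = []
    for i in range(n - 1):
        cells.append(
            Cell(
                id=i,
                bounding_milestones=frozenset({i, i + 1}),
                anchor_point=float(0.5 * (thr[i] + thr[i + 1])),
                lower_milestone=i,
                upper_milestone=i + 1,
            )
        )
    return MilestoneModel(
        milestones=milestones,
        cells=cells,
        temperature=float(temperature),
        geometry=geometry,
        ndim=ndim,
    )


def build_spherical_model(radii: Sequence[float], temperature: float = 298.15, ndim: int = 3) -> MilestoneModel:
    """Concentric spherical milestones at the given radii (Å).

    ``n`` strictly increasing positive radii produce ``n`` milestones and
    ``n - 1`` shell-shaped cells; the innermost milestone is the bound
    milestone, the outermost faces the bulk/BD region.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size and radii[0] <= 0:
        raise ModelValidationError("spherical radii must be positive")
    # Two-row configuration convention: row 0 = site anchor, row 1 = ligand.
    cv = CollectiveVariable(kind="spherical-distance", group_a=(0,), group_b=(1,))
    return _chain_model(radii, temperature, "spherical", ndim, cv)


def build_linear_model(positions: Sequence[float], temperature: float = 298.15, ndim: int = 1) -> MilestoneModel:
    """Milestones at fixed positions along a single coordinate (Å)."""
    cv = CollectiveVariable(kind="linear-combination", group_a=(0,), parameters=(1.0,))
    return _chain_model(positions, temperature, "linear", ndim, cv)


def boundary_value(configuration, milestone: Milestone) -> float:
    """Signed level-set value of a milestone for a configuration.

    Negative strictly inside (inner side), positive outside, zero exactly on
    the milestone (classified as crossed by the engine).
    """
    return milestone.boundary.value(configuration)


def locate_cell(configuration, model: MilestoneModel):
    """Cell id containing a configuration, or the ``BOUND``/``BULK`` marker."""
    return model.locate_cell(configuration)
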