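"""Simplified glabrous-skin tissue model.

Geometry is a layered 10 x 10 x 9 mm box (skin on top of subcutaneous
adipose tissue on top of cortical bone) with three collinear circular
surface electrodes, and straight 51-node axon paths representing
mechanoreceptive Abeta fibers at 1 mm depth.

Coordinate convention: right-handed mm coordinates with the origin at a
bottom corner of the box; z increases toward the skin surface at z = 9 mm,
so "depth 1 mm" means z = 8 mm.  The electrode row runs along x with the
grounded electrode centred on the top face at (5, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12

#: Tabulated carrier frequencies for the dielectric data, Hz.
PROPERTY_FREQUENCIES_HZ = (1000.0, 2000.0, 3000.0, 4000.0)

# Low-frequency dielectric data for the three tissues of the model
# (IT'IS-style tabulation at the four carriers).  Conductivity in S/m,
# relative permittivity dimensionless.
_CONDUCTIVITY_S_PER_M = {
    "skin": (0.200e-3, 0.200e-3, 0.200e-3, 0.201e-3),
    "SAT": (42.7e-3, 42.5e-3, 42.3e-3, 41.7e-3),
    "bone": (20.2e-3, 20.2e-3, 20.3e-3, 20.3e-3),
}
_REL_PERMITTIVITY = {
    "skin": (1.14e3, 1.14e3, 1.14e3, 1.13e3),
    "SAT": (19.3e3, 8.26e3, 4.97e3, 3.28e3),
    "bone": (2.70e3, 1.70e3, 1.25e3, 0.995e3),
}

Orientation = Literal["x", "y", "z"]
SweepAxis = Literal["x", "y"]


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue at one frequency."""

    conductivity: float  # S/m
    relative_permittivity: float  # dimensionless

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        if self.relative_permittivity <= 0:
            raise ValueError("relative permittivity must be positive")


@dataclass(frozen=True)
class ElectrodeSpec:
    """A circular surface electrode on the top face of the model."""

    center: tuple[float, float]  # (x, y) mm on the top surface
    diameter: float  # mm
    role: Literal["ground", "stim1", "stim2"]


@dataclass(frozen=True)
class AxonPath:
    """A straight axon path of equally spaced sampling nodes."""

    orientation: Orientation
    node_positions: np.ndarray  # (n_nodes, 3), mm
    node_spacing: float  # mm
    axon_id: int

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def length(self) -> float:
        """Path length in mm."""
        return self.node_spacing * (self.n_nodes - 1)

    def lateral_position(self, sweep_axis: SweepAxis) -> float:
        """Coordinate of this axon along the array sweep axis, mm."""
        axis = {"x": 0, "y": 1}[sweep_axis]
        return float(self.node_positions[0, axis])


@dataclass(frozen=True)
class TissueModel:
    """Layered box model with electrodes and the dielectric table."""

    domain_extent: tuple[float, float, float]  # mm
    layer_boundaries: tuple[tuple[str, tuple[float, float]], ...]
    electrode_set: tuple[ElectrodeSpec, ...]
    property_table: dict = field(default_factory=dict)

    def tissue_at(self, z: float) -> str:
        """Name of the tissue layer containing height z (mm).

        Points exactly on an interface belong to the layer above it, and
        the top surface belongs to the top layer.
        """
        for name, (z_lo, z_hi) in self.layer_boundaries:
            if z_lo <= z < z_hi:
                return name
        top_name, (_, z_top) = max(self.layer_boundaries, key=lambda it: it[1][1])
        if z == z_top:
            return top_name
        raise ValueError(f"z = {z} mm lies outside the tissue stack")

    @property
    def ground_electrode(self) -> ElectrodeSpec:
        (gnd,) = [e for e in self.electrode_set if e.role == "ground"]
        return gnd

    def electrode(self, role: str) -> ElectrodeSpec:
        (e,) = [e for e in self.electrode_set if e.role == role]
        return e


def default_skin_model() -> TissueModel:
    """Build the default glabrous-skin model.

    10 x 10 x 9 mm box; bone 1.5 mm at the bottom, SAT 5.9 mm, skin
    1.6 mm at the top; three 1 mm electrodes along x with 2 mm spacing,
    the central one (the ground) at the footprint centre.
    """
    layers = (
        ("bone", (0.0, 1.5)),
        ("SAT", (1.5, 7.4)),
        ("skin", (7.4, 9.0)),
    )
    electrodes = (
        ElectrodeSpec(center=(3.0, 5.0), diameter=1.0, role="stim1"),
        ElectrodeSpec(center=(5.0, 5.0), diameter=1.0, role="ground"),
        ElectrodeSpec(center=(7.0, 5.0), diameter=1.0, role="stim2"),
    )
    table = {
        name: [
            (f, TissueProperties(_CONDUCTIVITY_S_PER_M[name][i],
                                 _REL_PERMITTIVITY[name][i]))
            for i, f in enumerate(PROPERTY_FREQUENCIES_HZ)
        ]
        for name in _CONDUCTIVITY_S_PER_M
    }
    return TissueModel(
        domain_extent=(10.0, 10.0, 9.0),
        layer_boundaries=layers,
        electrode_set=electrodes,
        property_table=table,
    )


def material_properties(tissue: str, f: float,
                        model: TissueModel | None = None) -> TissueProperties:
    """Dielectric properties of a tissue at frequency f (Hz).

    Exact tabulated values at the tabulated carriers and linear
    interpolation in f between adjacent carriers.  Frequencies outside
    the tabulated range [1, 4] kHz are an error.
    """
    table = (model or default_skin_model()).property_table
    if tissue not in table:
        raise KeyError(f"unknown tissue {tissue!r}; expected one of {sorted(table)}")
    freqs = np.array([row[0] for row in table[tissue]])
    if not (freqs[0] <= f <= freqs[-1]):
        raise ValueError(
            f"frequency {f} Hz outside tabulated range "
            f"[{freqs[0]:g}, {freqs[-1]:g}] Hz")
    sig = np.array([row[1].conductivity for row in table[tissue]])
    eps = np.array([row[1].relative_permittivity for row in table[tissue]])
    return TissueProperties(
        conductivity=float(np.interp(f, freqs, sig)),
        relative_permittivity=float(np.interp(f, freqs, eps)),
    )


def complex_admittance(props: TissueProperties, f: float) -> complex:
    """Complex admittance sigma* = sigma + j 2 pi f eps0 eps_r, S/m.

    Its magnitude sqrt(sigma^2 + (2 pi f eps)^2) is the effective
    admittance combining conductive and capacitive current paths.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    return complex(props.conductivity,
                   2.0 * np.pi * f * EPSILON_0 * props.relative_permittivity)


# Geometry constants of the axon arrays (mm).
AXON_LENGTH = 5.0
AXON_NODE_SPACING = 0.1
N_AXON_NODES = 51
AXON_PITCH = 0.1
AXON_DEPTH = 1.0  # below the skin surface
SUBVOLUME_LO = 2.5  # central 5 x 5 x 5 mm subvolume, lateral bounds
SUBVOLUME_HI = 7.5

#: Index of the reference axon (path through (5.0, 5.0, 8.0) mm) in each
#: default 51-axon array.
REFERENCE_AXON_INDEX = 25

_VALID_COMBINATIONS = {("x", "y"), ("y", "x"), ("z", "y"), ("z", "x")}


def build_axon_array(orientation: Orientation, sweep_axis: SweepAxis,
                     model: TissueModel | None = None,
                     stride: int = 1) -> list[AxonPath]:
    """Build one of the four axon array conditions.

    Skin-parallel (x- or y-oriented) axons lie in the plane 1 mm below
    the skin surface; skin-perpendicular (z-oriented) axons run through
    the depth of the central subvolume with one node at 1 mm depth.
    Arrays are at 0.1 mm pitch across the central 5 mm; ``stride`` thins
    the array to every stride-th lateral position for scaled-down runs.
    """
    if (orientation, sweep_axis) not in _VALID_COMBINATIONS:
        raise ValueError(
            f"invalid array condition ({orientation!r} oriented, swept along "
            f"{sweep_axis!r}); valid: x/y, y/x, z/y, z/x")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    model = model or default_skin_model()
    z_top = model.domain_extent[2]
    z_axon_plane = z_top - AXON_DEPTH

    along = np.arange(N_AXON_NODES) * AXON_NODE_SPACING + SUBVOLUME_LO
    lateral = np.arange(0, N_AXON_NODES, stride) * AXON_PITCH + SUBVOLUME_LO

    paths: list[AxonPath] = []
    for axon_id, lat in enumerate(lateral):
        pos = np.empty((N_AXON_NODES, 3))
        if orientation == "x":
            pos[:, 0] = along
            pos[:, 1] = lat
            pos[:, 2] = z_axon_plane
        elif orientation == "y":
            pos[:, 0] = lat
            pos[:, 1] = along
            pos[:, 2] = z_axon_plane
        else:  # z-oriented: spans skin surface down to 5 mm depth
            pos[:, 0] = 5.0 if sweep_axis == "y" else lat
            pos[:, 1] = lat if sweep_axis == "y" else 5.0
            pos[:, 2] = np.arange(N_AXON_NODES) * AXON_NODE_SPACING + (
                z_top - AXON_LENGTH)
        pos.setflags(write=False)
        paths.append(AxonPath(orientation=orientation, node_positions=pos,
                              node_spacing=AXON_NODE_SPACING, axon_id=axon_id))
    return paths


def reference_axon(orientation: Orientation, sweep_axis: SweepAxis,
                   model: TissueModel | None = None) -> AxonPath:
    """The array member whose path contains (5.0, 5.0, 8.0) mm."""
    arr = build_axon_array(orientation, sweep_axis, model)
    return arr[REFERENCE_AXON_INDEX]
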