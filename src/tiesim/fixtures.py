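"""Deterministic toy inputs for validation and tests.

All fixtures are generated programmatically: a homogeneous half-space
model for comparison with the analytic point-source formula, a tiny
grid for the time-domain oracle, a hand-computed AP raster with known
PF/PI, and a step-function gain-to-count oracle for the scaling search.
"""

from __future__ import annotations

import numpy as np

from tiesim.tissue import (
    ElectrodeSpec,
    TissueModel,
    TissueProperties,
    PROPERTY_FREQUENCIES_HZ,
)


def _uniform_model(name: str, extent: tuple, electrodes: tuple,
                   sigma: float, eps_r: float) -> TissueModel:
    table = {name: [(f, TissueProperties(sigma, eps_r))
                    for f in PROPERTY_FREQUENCIES_HZ]}
    return TissueModel(domain_extent=extent,
                       layer_boundaries=((name, (0.0, extent[2])),),
                       electrode_set=electrodes,
                       property_table=table)


def make_fixture(name: str):
    """Build one of the named deterministic fixtures.

    - ``homogeneous-halfspace``: uniform 8 x 8 x 8 mm medium
      (sigma = 0.1 S/m, negligible permittivity) with a small surface
      source disc and a well-separated surface ground disc; dict with
      the model, sigma, and the source/ground centres.  Near the source
      the field matches the surface point-source formula (source plus
      ground-sink superposition, constant offset removed).
    - ``tiny-grid``: uniform 1 x 1 x 1 mm medium with skin-like
      dispersion, three 0.2 mm electrodes; for the 11^3-node
      time-domain oracle.
    - ``synthetic-raster``: AP counts [1, 0, 2, 3, 2, 0, 4] at 0.1 mm
      pitch, with the hand-computed activation structure.
    - ``step-count-oracle``: gain -> count function equal to 3 iff
      gain >= 0.5.
    """
    if name == "homogeneous-halfspace":
        sigma = 0.1
        model = _uniform_model(
            "medium", (8.0, 8.0, 8.0),
            (ElectrodeSpec(center=(2.0, 4.0), diameter=0.5, role="stim1"),
             ElectrodeSpec(center=(6.0, 4.0), diameter=1.0, role="ground"),
             ElectrodeSpec(center=(4.0, 1.0), diameter=0.5, role="stim2")),
            sigma=sigma, eps_r=1.0)
        return {"model": model, "sigma": sigma,
                "source_mm": np.array([2.0, 4.0, 8.0]),
                "ground_mm": np.array([6.0, 4.0, 8.0])}
    if name == "tiny-grid":
        model = _uniform_model(
            "medium", (1.0, 1.0, 1.0),
            (ElectrodeSpec(center=(0.2, 0.5), diameter=0.2, role="stim1"),
             ElectrodeSpec(center=(0.5, 0.5), diameter=0.2, role="ground"),
             ElectrodeSpec(center=(0.8, 0.5), diameter=0.2, role="stim2")),
            sigma=0.2e-3, eps_r=1.14e3)
        return {"model": model, "spacing": 0.1}
    if name == "synthetic-raster":
        counts = np.array([1, 0, 2, 3, 2, 0, 4])
        positions = np.arange(7) * 0.1
        return {"counts": counts, "positions": positions,
                "expected_primary": np.array([6]),
                "expected_thr": 2.4, "expected_pf": 0.0, "expected_pi": 4}
    if name == "step-count-oracle":
        return {"count_fn": lambda k: 3 if k >= 0.5 else 0, "step_at": 0.5,
                "target": 3}
    raise KeyError(f"unknown fixture {name!r}")
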