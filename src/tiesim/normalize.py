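"""Amplitude normalization by the reference-axon criterion.

To compare conditions fairly across carriers and orientations, the
stimulus amplitude is scaled by S(f_c, f_b): the minimum gain
k in [1e-4, 10] at which the reference axon (the array member passing
through (5.0, 5.0, 8.0) mm) fires at least N_AP,ref = f_b * T_w APs in
the evaluation window.  At the reference beat of 30 Hz and T_w = 0.1 s
the target is exactly 3 APs.

Because AP count versus gain can be non-monotone at high carriers
(conduction block), the search first scans log-spaced gains to find the
lowest sign change and then bisects in log-gain space to 0.1% relative
tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from tiesim.stimulus import StimulusSpec, scaled


class UnattainableGainError(RuntimeError):
    """The target AP count is not reached anywhere in the gain range."""


@dataclass(frozen=True)
class ScalingSearchSpec:
    """Search range, tolerance and target of the gain search."""

    n_ap_ref: int
    k_min: float = 1e-4
    k_max: float = 10.0
    rel_tol: float = 1e-3  # 0.1% relative tolerance on k
    scan_points_per_decade: int = 13

    def __post_init__(self) -> None:
        if not 0 < self.k_min < self.k_max:
            raise ValueError("need 0 < k_min < k_max")
        if self.n_ap_ref < 0:
            raise ValueError("target AP count must be non-negative")


def nap_ref(fb: float, tw: float) -> int:
    """Target AP count N_AP,ref = f_b * T_w for the reference axon."""
    if fb < 0 or tw <= 0:
        raise ValueError("need fb >= 0 and tw > 0")
    prod = fb * tw
    if abs(prod - round(prod)) > 1e-9:
        raise ValueError(f"f_b * T_w = {prod} is not an integer")
    return round(prod)


def scaling_factor(count_fn: Callable[[float], int],
                   spec: ScalingSearchSpec) -> float:
    """Minimum gain at which ``count_fn`` reaches the target count.

    ``count_fn(k)`` must deterministically return the reference axon's
    AP count at gain k.  A coarse log-spaced scan locates the lowest
    upward crossing of the target; log-space bisection then narrows the
    bracket to the relative tolerance.  Non-monotone counts beyond the
    first crossing are reported as a warning; minimality is re-checked
    just below the returned gain.
    """
    target = spec.n_ap_ref
    if target == 0:
        return spec.k_min

    n_dec = np.log10(spec.k_max / spec.k_min)
    n_pts = max(int(np.ceil(n_dec * spec.scan_points_per_decade)) + 1, 2)
    ks = np.logspace(np.log10(spec.k_min), np.log10(spec.k_max), n_pts)
    hits = np.array([count_fn(k) >= target for k in ks])
    if not hits.any():
        raise UnattainableGainError(
            f"AP count never reaches {target} for k in "
            f"[{spec.k_min:g}, {spec.k_max:g}] (physiological ceiling)")
    first = int(np.argmax(hits))
    if np.any(~hits[first:]):
        warnings.warn("AP count vs gain is non-monotone above the first "
                      "crossing (possible conduction block)", stacklevel=2)

    if first == 0:
        hi = ks[0]
    else:
        lo, hi = ks[first - 1], ks[first]
        while hi / lo > 1.0 + spec.rel_tol:
            mid = np.sqrt(lo * hi)
            if count_fn(mid) >= target:
                hi = mid
            else:
                lo = mid
    probe = hi * (1.0 - 2.0 * spec.rel_tol)
    if probe >= spec.k_min and count_fn(probe) >= target:
        warnings.warn("count at S*(1 - 2 tol) still reaches the target; "
                      "the count is non-monotone at the bracket",
                      stacklevel=2)
    return float(hi)


def apply_normalization(scalings: dict, conditions: list,
                        base: StimulusSpec | None = None) -> dict:
    """Scaled stimulus for every (f_c, f_b, orientation) condition.

    ``scalings`` maps (f_c, orientation) to the gain computed at the
    30 Hz reference beat; every beat at that carrier/orientation shares
    it.  Returns {(fc, fb, orientation): StimulusSpec}.
    """
    from dataclasses import replace

    base = base or StimulusSpec()
    out = {}
    for fc, fb, orientation in conditions:
        key = (fc, orientation)
        if key not in scalings:
            raise KeyError(
                f"missing reference scaling for f_c = {fc} Hz, "
                f"orientation {orientation!r}")
        spec = replace(base, f1=fc, f2=fc + fb)
        out[(fc, fb, orientation)] = scaled(spec, scalings[key])
    return out
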