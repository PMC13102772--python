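"""Action-potential detection and tactile perception metrics.

APs are upward threshold crossings of the membrane potential grouped
into propagating waves.  An AP counts toward an axon's tally only when
it initiates inside the evaluation window and evaluation region (outside
the temporal and spatial guards) and its wave reaches one of the axon
ends - the outer boundaries of the spatial guard regions - before the
end of the run.

From per-axon counts the activated set A, the activation threshold
N_AP,thr (mean count over A), contiguous supra-threshold regions, and
the primary region R are derived.  The perceived field PF is the spatial
length of R and the perceived intensity PI the total AP count within R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tiesim.cable import MembraneTrace, SimConfig
from tiesim.field import AxonPotentialSeries

#: Maximum time (ms) between threshold crossings at neighbouring nodes
#: for them to belong to the same propagating wave.  Conduction across
#: one 0.1 mm node interval takes well under 0.5 ms for this fiber, and
#: HH refractoriness keeps distinct APs several ms apart.
WAVE_ASSOCIATION_MS = 1.0


@dataclass(frozen=True)
class APEvent:
    """One detected AP wave on one axon."""

    axon_id: int
    initiation_node: int
    initiation_time: float  # ms
    reached_guard: bool  # wave reached an axon end (guard outer boundary)
    counted: bool  # passes all guard rules


@dataclass(frozen=True)
class ActivationSummary:
    """Per-axon counts and the derived activation structure."""

    counts: np.ndarray  # N_AP per axon
    positions: np.ndarray  # axon lateral positions, mm
    activated: np.ndarray  # indices of A = {i : N_AP(i) >= 1}
    n_ap_thr: float  # mean N_AP over A (nan when A empty)
    regions: tuple  # tuple of index arrays, contiguous supra-threshold runs
    primary_region: np.ndarray  # indices of R (may be empty)

    @property
    def n_secondary_regions(self) -> int:
        """Qualifying regions other than the primary one."""
        return max(len(self.regions) - 1, 0) if self.primary_region.size else 0


@dataclass(frozen=True)
class PerceptResult:
    """Perceived-field length and perceived intensity for one condition."""

    pf: float  # mm
    pi: int  # AP count
    secondary_peaks: bool


def _node_crossings(vm: np.ndarray, times: np.ndarray,
                    thr: float) -> list[np.ndarray]:
    """Per-node upward crossing times (ms), linearly interpolated."""
    below = vm[:, :-1] < thr
    above = vm[:, 1:] >= thr
    out = []
    dt = times[1] - times[0]
    for i in range(vm.shape[0]):
        idx = np.where(below[i] & above[i])[0]
        frac = (thr - vm[i, idx]) / (vm[i, idx + 1] - vm[i, idx])
        out.append(times[idx] + frac * dt)
    return out


def detect_aps(trace: MembraneTrace,
               config: SimConfig | None = None) -> list[APEvent]:
    """Detect AP waves on one axon and apply the guard counting rules.

    Upward crossings of the -20 mV threshold are grouped into waves by
    greedy spatiotemporal association (a crossing joins a wave that has
    already crossed a neighbouring node within ~1 ms).  Each wave yields
    one event; the event is counted when its initiation (earliest
    crossing) falls inside the evaluation window and region and the wave
    reaches either axon end within the run.
    """
    config = config or SimConfig()
    n_nodes = trace.vm.shape[0]
    crossings = _node_crossings(trace.vm, trace.times, config.v_thr)

    # flatten and sort by time
    flat = [(t, i) for i, ts in enumerate(crossings) for t in ts]
    flat.sort()

    last_wave = np.full(n_nodes, -1, dtype=int)
    last_time = np.full(n_nodes, -np.inf)
    waves: list[dict] = []
    for t, i in flat:
        wid = -1
        best = -np.inf
        for j in (i - 1, i + 1):
            if 0 <= j < n_nodes and last_wave[j] >= 0 \
                    and t - last_time[j] <= WAVE_ASSOCIATION_MS \
                    and last_time[j] > best:
                wid = last_wave[j]
                best = last_time[j]
        if wid < 0:
            wid = len(waves)
            waves.append({"t0": t, "node0": i, "nodes": set()})
        w = waves[wid]
        w["nodes"].add(i)
        if t < w["t0"]:
            w["t0"], w["node0"] = t, i
        last_wave[i] = wid
        last_time[i] = t

    ng = config.guard_nodes(n_nodes, trace.node_spacing)
    t0_ms = config.t_guard * 1e3
    t_end_ms = t0_ms + config.t_window * 1e3
    events = []
    for w in waves:
        reached = 0 in w["nodes"] or (n_nodes - 1) in w["nodes"]
        in_window = t0_ms <= w["t0"] <= t_end_ms
        in_region = ng <= w["node0"] <= n_nodes - 1 - ng
        events.append(APEvent(axon_id=trace.axon_id,
                              initiation_node=w["node0"],
                              initiation_time=w["t0"],
                              reached_guard=reached,
                              counted=reached and in_window and in_region))
    return events


def count_aps(trace: MembraneTrace, config: SimConfig | None = None) -> int:
    """Number of counted APs on one axon."""
    return sum(e.counted for e in detect_aps(trace, config))


def _window_slice(n_times: int, config: SimConfig) -> slice:
    """Columns of a series belonging to the evaluation window."""
    if n_times == config.n_window:
        return slice(None)
    n_total = 2 * config.n_guard + config.n_window + 1
    if n_times == n_total:
        return slice(config.n_guard, config.n_guard + config.n_window)
    raise ValueError(
        f"series has {n_times} samples; expected the {config.n_window}-sample "
        f"window or the full {n_total}-sample run")


def ve_rms(series: AxonPotentialSeries,
           config: SimConfig | None = None) -> np.ndarray:
    """Per-node RMS of V_e over the evaluation window, mV."""
    config = config or SimConfig()
    sl = _window_slice(series.ve.shape[1], config)
    win = series.ve[:, sl]
    if win.shape[1] == 0:
        raise ValueError("empty evaluation window")
    return np.sqrt(np.mean(win**2, axis=1))


def af_max(series: AxonPotentialSeries, dr: float,
           config: SimConfig | None = None) -> np.ndarray:
    """Per-node max |second spatial difference of V_e| over the window.

    Units mV/mm2; end nodes use the sealed-end mirror treatment.
    """
    from tiesim.cable import activating_drive

    config = config or SimConfig()
    if series.ve.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    sl = _window_slice(series.ve.shape[1], config)
    d2 = activating_drive(series.ve[:, sl].T, dr)  # (n_t, n_nodes)
    return np.abs(d2).max(axis=0)


def summarize_activation(counts, positions) -> ActivationSummary:
    """Derive A, N_AP,thr, contiguous regions and the primary region.

    ``counts`` are per-axon AP counts and ``positions`` the axon
    coordinates along the sweep axis (uniform pitch).  Qualifying axons
    have N_AP at least the mean count over the activated set; contiguous
    runs of qualifying axons at adjacent positions form regions.  The
    primary region is the one containing the global maximum count, ties
    broken by length then by smallest starting index.
    """
    counts = np.asarray(counts, dtype=int)
    positions = np.asarray(positions, dtype=float)
    if counts.shape != positions.shape:
        raise ValueError("counts and positions must align")
    order = np.argsort(positions)
    counts = counts[order]
    positions = positions[order]

    activated = np.where(counts >= 1)[0]
    empty = np.array([], dtype=int)
    if activated.size == 0:
        return ActivationSummary(counts=counts, positions=positions,
                                 activated=empty, n_ap_thr=float("nan"),
                                 regions=(), primary_region=empty)
    thr = float(counts[activated].mean())
    qualifying = activated[counts[activated] >= thr]

    regions = []
    run = [qualifying[0]]
    for i in qualifying[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            regions.append(np.array(run))
            run = [i]
    regions.append(np.array(run))

    global_max = counts[qualifying].max()
    candidates = [r for r in regions if counts[r].max() == global_max]
    best_len = max(len(r) for r in candidates)
    candidates = [r for r in candidates if len(r) == best_len]
    primary = min(candidates, key=lambda r: r[0])
    return ActivationSummary(counts=counts, positions=positions,
                             activated=activated, n_ap_thr=thr,
                             regions=tuple(regions), primary_region=primary)


def perceived_field(summary: ActivationSummary) -> float:
    """PF: spatial length x_max - x_min of the primary region, mm."""
    r = summary.primary_region
    if r.size <= 1:
        return 0.0
    return float(summary.positions[r].max() - summary.positions[r].min())


def perceived_intensity(summary: ActivationSummary) -> int:
    """PI: total AP count over the primary region."""
    r = summary.primary_region
    return int(summary.counts[r].sum()) if r.size else 0


def percept(summary: ActivationSummary) -> PerceptResult:
    """PF, PI and the secondary-region flag for one condition."""
    return PerceptResult(pf=perceived_field(summary),
                         pi=perceived_intensity(summary),
                         secondary_peaks=summary.n_secondary_regions > 0)
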