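"""Respiratory surrogates, amplitude binning and 4D series assembly.

Models the acquisition side of respiratory-correlated 4D MRI: an internal
navigator tracking the diaphragm dome (the phantom's analytic position, by
construction exact) and a concurrent external bellows whose signal is a
lagged, amplitude-distorted, noisy copy of the navigator.  Slices are
acquired round-robin and sorted into amplitude bins whose edges divide the
range of a 10-second training prefix of the surrogate into equal intervals.
Rebinning the same slice events with the bellows signal mis-assigns a
fraction of slices, producing the through-plane discontinuities typical of
externally-binned 4D reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grid import ContourMask, PhaseVolume
from .synthetic import PhantomConfig


class DegenerateBinningError(ValueError):
    """Raised when the training trace has zero amplitude range."""


class AcquisitionCoverageError(RuntimeError):
    """Raised when some (slice, bin) cell can never be filled."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(
            f"acquisition cannot fill {len(self.cells)} (slice, bin) cells; "
            f"first missing: {self.cells[0]}"
        )


@dataclass(frozen=True)
class BreathingModel:
    """Quasi-periodic breathing: per-cycle amplitude/period jitter around a
    (1 - cos)/2 waveform.  irregularity = 0 gives a strictly periodic trace."""

    period_s: float = 4.0
    irregularity: float = 0.0

    def __post_init__(self):
        if self.period_s <= 0:
            raise ValueError("breathing period must be positive")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")


@dataclass
class SurrogateTrace:
    """Per-acquisition-event surrogate samples.

    navigator_mm is the diaphragm-dome SI displacement (0 = full exhalation)
    and equals the phantom's analytic dome position at each event time.
    """

    times: np.ndarray
    navigator_mm: np.ndarray
    bellows_signal: np.ndarray
    slice_index: np.ndarray
    n_slices: int
    amplitude_mm: float
    dt_s: float
    training_s: float = 10.0

    def training_mask(self) -> np.ndarray:
        return self.times < self.training_s


def _cycle_waveform(times: np.ndarray, amplitude_mm: float,
                    model: BreathingModel,
                    rng: Optional[np.random.Generator]) -> np.ndarray:
    """Evaluate the breathing displacement at arbitrary times >= t0 < 0."""
    t_max = float(times.max()) + 2 * model.period_s
    starts = [-2.0 * model.period_s]
    periods = []
    amps = []
    while starts[-1] < t_max:
        if model.irregularity > 0 and rng is not None:
            per = model.period_s * max(0.3, 1.0 + model.irregularity * rng.standard_normal())
            amp = amplitude_mm * float(
                np.clip(1.0 + model.irregularity * rng.standard_normal(), 0.4, 1.15)
            )
        else:
            per = model.period_s
            amp = amplitude_mm
        periods.append(per)
        amps.append(amp)
        starts.append(starts[-1] + per)
    starts_arr = np.asarray(starts[:-1])
    periods_arr = np.asarray(periods)
    amps_arr = np.asarray(amps)
    idx = np.searchsorted(starts_arr, times, side="right") - 1
    idx = np.clip(idx, 0, len(periods_arr) - 1)
    tau = (times - starts_arr[idx]) / periods_arr[idx]
    return amps_arr[idx] * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def simulate_surrogates(config: PhantomConfig,
                        breathing: Optional[BreathingModel] = None,
                        bellows_lag_s: float = 0.3,
                        distortion_gamma: float = 1.3,
                        bellows_noise: float = 0.0,
                        seed=0,
                        dt_s: float = 0.25,
                        training_s: float = 10.0,
                        max_events: int = 200_000,
                        require_fill: bool = True,
                        ) -> SurrogateTrace:
    """Simulate the slice-acquisition event stream with both surrogates.

    The bellows is the navigator delayed by ``bellows_lag_s``, passed through
    the monotone amplitude distortion s -> A (s/A)^gamma, plus additive
    Gaussian noise.  Events (round-robin over slices, one every ``dt_s``)
    accumulate until every (slice, amplitude-bin) cell is filled for both
    surrogates, guaranteeing that both series can be assembled.
    """
    breathing = breathing or BreathingModel()
    n_slices = int(config.grid_shape[2])
    n_bins = int(config.n_phases)
    amp = float(config.diaphragm_amplitude_right_mm)
    if amp <= 0:
        raise ValueError("navigator amplitude must be positive")
    rng = np.random.default_rng(seed)

    times = dt_s * np.arange(max_events)
    # one jitter stream evaluated on the union of both time axes keeps the
    # lagged bellows sampling the same breathing realization
    all_t = np.concatenate([times, times - bellows_lag_s])
    wave = _cycle_waveform(all_t, amp, breathing, rng)
    nav = wave[:max_events]
    nav_lagged = wave[max_events:]
    bell = amp * np.power(np.maximum(nav_lagged, 0.0) / amp, distortion_gamma)
    if bellows_noise > 0:
        bell = bell + rng.normal(0.0, bellows_noise, size=bell.shape)
    slices = np.arange(max_events) % n_slices

    trace = SurrogateTrace(times, nav, bell, slices, n_slices, amp, dt_s, training_s)
    if not require_fill:
        return trace

    # truncate at the first event index where both bin-slice tables are full
    nav_bins = amplitude_bin(nav, n_bins, training=nav[trace.training_mask()])
    bell_bins = amplitude_bin(bell, n_bins, training=bell[trace.training_mask()])
    filled = np.zeros((2, n_slices, n_bins), dtype=bool)
    complete_at = -1
    need = 2 * n_slices * n_bins
    count = 0
    for e in range(max_events):
        s = slices[e]
        for row, b in ((0, nav_bins[e]), (1, bell_bins[e])):
            if not filled[row, s, b]:
                filled[row, s, b] = True
                count += 1
        if count == need:
            complete_at = e
            break
    if complete_at < 0:
        missing = [
            ("navigator" if r == 0 else "bellows", int(s), int(b))
            for r, s, b in zip(*np.nonzero(~filled))
        ]
        raise AcquisitionCoverageError(missing)
    n = complete_at + 1
    return SurrogateTrace(times[:n], nav[:n], bell[:n], slices[:n],
                          n_slices, amp, dt_s, training_s)


def amplitude_bin(values: np.ndarray, n_bins: int,
                  training: Optional[np.ndarray] = None) -> np.ndarray:
    """Assign each sample to an equal-width amplitude bin.

    Bin edges divide [min, max] of the training samples (default: all
    samples) into ``n_bins`` equal intervals; intervals are left-closed,
    right-open with the top bin closed, and out-of-range samples clamp to
    the extreme bins.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    train = values if training is None else np.asarray(training, dtype=float)
    train = train[np.isfinite(train)]
    if train.size == 0:
        raise ValueError("need at least one finite training sample")
    lo, hi = float(train.min()), float(train.max())
    if hi <= lo:
        raise DegenerateBinningError("constant training trace: amplitude range is zero")
    width = (hi - lo) / n_bins
    idx = np.floor((values - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_disagreement(trace: SurrogateTrace, n_bins: int
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Navigator and bellows bin assignments for every event."""
    tm = trace.training_mask()
    nav_bins = amplitude_bin(trace.navigator_mm, n_bins,
                             training=trace.navigator_mm[tm])
    bell_bins = amplitude_bin(trace.bellows_signal, n_bins,
                              training=trace.bellows_signal[tm])
    return nav_bins, bell_bins


def assemble_series(phases: Sequence[PhaseVolume], trace: SurrogateTrace,
                    surrogate: str = "navigator",
                    ) -> Tuple[List[PhaseVolume], np.ndarray]:
    """Assemble a 4D series slice-by-slice from the acquisition events.

    For each output bin and slice, the first event whose *surrogate* bin
    matches is chosen; the slice content comes from the phase matching that
    event's navigator (true) bin.  With the navigator surrogate the series
    is artifact-free; with the bellows surrogate, events whose bins disagree
    insert slices from the wrong phase (through-plane binning artifacts).

    Returns the per-bin volumes and the provenance array ``prov[bin, slice]``
    holding the true bin each slice was taken from.
    """
    if surrogate not in ("navigator", "bellows"):
        raise ValueError(f"unknown surrogate {surrogate!r}")
    n_bins = len(phases)
    if n_bins == 1:
        prov = np.zeros((1, trace.n_slices), dtype=int)
        vol = phases[0]
        return [PhaseVolume(vol.intensity.copy(), vol.grid, 0)], prov
    nav_bins, bell_bins = bin_disagreement(trace, n_bins)
    sel_bins = nav_bins if surrogate == "navigator" else bell_bins

    prov = np.full((n_bins, trace.n_slices), -1, dtype=int)
    for b in range(n_bins):
        for s in range(trace.n_slices):
            hits = np.flatnonzero((sel_bins == b) & (trace.slice_index == s))
            if hits.size == 0:
                raise AcquisitionCoverageError([(surrogate, s, b)])
            prov[b, s] = nav_bins[hits[0]]

    grid = phases[0].grid
    out: List[PhaseVolume] = []
    for b in range(n_bins):
        vol = np.empty(grid.shape, dtype=np.float32)
        for s in range(trace.n_slices):
            vol[:, :, s] = phases[prov[b, s]].intensity[:, :, s]
        out.append(PhaseVolume(vol, grid, phase_index=b))
    return out, prov


def composite_truth_masks(truth_masks_per_phase: Sequence[Dict[str, ContourMask]],
                          provenance: np.ndarray,
                          series: str = "bellows",
                          ) -> List[Dict[str, ContourMask]]:
    """Ground-truth masks of an assembled (possibly mis-binned) series.

    Each output bin's mask takes slice s from the true-phase mask recorded in
    the provenance array, so binning artifacts appear in the truth exactly as
    they do in the images.
    """
    n_bins, n_slices = provenance.shape
    out: List[Dict[str, ContourMask]] = []
    for b in range(n_bins):
        organs = {}
        for organ, ref in truth_masks_per_phase[0].items():
            data = np.empty_like(ref.data)
            for s in range(n_slices):
                data[:, :, s] = truth_masks_per_phase[provenance[b, s]][organ].data[:, :, s]
            organs[organ] = ref.tagged(data=data, phase_index=b, organ=organ,
                                       source="truth", series=series)
        out.append(organs)
    return out


def provenance_mismatch_fraction(provenance: np.ndarray) -> float:
    """Fraction of assembled slices taken from a non-matching true bin."""
    bins = np.arange(provenance.shape[0])[:, None]
    return float(np.mean(provenance != bins))
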