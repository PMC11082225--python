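"""Hierarchical gating: morphology -> singlets -> viability -> immunophenotype.

The hierarchy mirrors standard practice for this assay: a morphological
FSC-A/SSC-A region removes debris, an FSC-H/FSC-A ratio band removes
doublets, a viability-dye cutoff removes dead cells, and marker positivity
(CD5+CD19+ for primary samples, CD19+ for xenograft models) selects the
population of interest, on which the median cytochrome-c fluorescence is
read out.

Gates are parameterized regions with defaults matched to the synthetic
generator; every boundary is config-overridable.  The viability cutoff can
be ``"auto"``, which splits a bimodal log-intensity histogram at the valley
between its two dominant modes and falls back to the configured default
(with a warning flag) when the channel is unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .events import EventTable, TubeRecord, ValidationError
from .fcs import read_events_csv, read_fcs

__all__ = [
    "GatingConfig", "GatingResult", "gate_scatter", "gate_singlets",
    "gate_viable", "gate_target", "run_gating", "compute_mfi", "load_tube",
]


@dataclass
class GatingConfig:
    """Boundaries and policies for the four-stage hierarchy."""

    #: (min, max) per scatter channel
    fsc_a_range: Tuple[float, float] = (15000.0, 250000.0)
    ssc_a_range: Tuple[float, float] = (5000.0, 120000.0)
    #: allowed FSC-H/FSC-A ratio band for singlets
    singlet_ratio_band: Tuple[float, float] = (0.80, 1.15)
    #: viability cutoff: events with dye intensity below it are kept;
    #: "auto" finds the valley of a bimodal log-histogram
    viability_threshold: Union[float, str] = "auto"
    #: fallback cutoff when auto splitting fails
    viability_fallback: float = 1000.0
    #: per-channel positivity cutoffs
    marker_thresholds: dict = field(default_factory=lambda: {"CD5": 1500.0, "CD19": 1500.0})
    #: marker logic, e.g. "CD5+CD19+" (primary) or "CD19+" (PDX)
    target_definition: str = "CD5+CD19+"
    #: channel carrying the readout
    cytc_channel: str = "CytC"
    viability_channel: str = "Zombie"
    #: QC floor for the final gated population
    min_gated_events: int = 30000

    def __post_init__(self) -> None:
        if self.singlet_ratio_band[0] >= self.singlet_ratio_band[1]:
            raise ValidationError("singlet_ratio_band must be a non-empty interval")
        for name, lohi in (("fsc_a_range", self.fsc_a_range),
                           ("ssc_a_range", self.ssc_a_range)):
            if not (np.isfinite(lohi[0]) and np.isfinite(lohi[1])):
                raise ValidationError(f"{name} bounds must be finite")
        for marker in self.required_markers():
            if marker not in self.marker_thresholds:
                raise ValidationError(
                    f"target_definition requires a threshold for {marker!r}"
                )

    def required_markers(self) -> List[str]:
        markers = [tok for tok in self.target_definition.split("+") if tok]
        if not markers:
            raise ValidationError(
                f"cannot parse target_definition {self.target_definition!r}"
            )
        return markers


@dataclass
class GatingResult:
    """Per-tube outcome: stage counts, readout MFI, and QC flags."""

    counts: dict                 # stage -> retained event count
    mfi: Optional[float]         # median cyt-c of the target gate, None if empty
    qc_flags: List[str]
    retained_index: dict         # stage -> integer indices into the raw table

    @property
    def ok(self) -> bool:
        return "empty_final_gate" not in self.qc_flags


def _require(events: EventTable, *channels: str) -> None:
    for ch in channels:
        if not events.has_channel(ch):
            raise KeyError(f"required channel {ch!r} missing from event table")


# --- stage masks -----------------------------------------------------------

def _scatter_mask(events: EventTable, cfg: GatingConfig) -> np.ndarray:
    _require(events, "FSC-A", "SSC-A")
    fsc = events.channel("FSC-A")
    ssc = events.channel("SSC-A")
    return (
        (fsc >= cfg.fsc_a_range[0]) & (fsc <= cfg.fsc_a_range[1])
        & (ssc >= cfg.ssc_a_range[0]) & (ssc <= cfg.ssc_a_range[1])
    )


def _singlet_mask(events: EventTable, cfg: GatingConfig) -> np.ndarray:
    _require(events, "FSC-A", "FSC-H")
    fsc_a = events.channel("FSC-A")
    fsc_h = events.channel("FSC-H")
    safe = np.where(fsc_a > 0, fsc_a, 1.0)
    ratio = fsc_h / safe
    lo, hi = cfg.singlet_ratio_band
    return (fsc_a > 0) & (ratio >= lo) & (ratio <= hi)


def _viable_mask(events: EventTable, cfg: GatingConfig,
                 flags: Optional[List[str]] = None) -> np.ndarray:
    _require(events, cfg.viability_channel)
    dye = events.channel(cfg.viability_channel)
    threshold = cfg.viability_threshold
    if threshold == "auto":
        valley = find_bimodal_valley(dye) if len(dye) else None
        if valley is None:
            threshold = cfg.viability_fallback
            if flags is not None:
                flags.append("viability_auto_fallback")
        else:
            threshold = valley
    return dye < float(threshold)


def _target_mask(events: EventTable, cfg: GatingConfig) -> np.ndarray:
    markers = cfg.required_markers()
    _require(events, *markers)
    mask = np.ones(len(events), dtype=bool)
    for marker in markers:
        mask &= events.channel(marker) >= cfg.marker_thresholds[marker]
    return mask


# --- public single gates ---------------------------------------------------

def gate_scatter(events: EventTable, cfg: GatingConfig) -> EventTable:
    """Morphological gate: rectangular FSC-A/SSC-A region."""
    return events.subset(_scatter_mask(events, cfg))


def gate_singlets(events: EventTable, cfg: GatingConfig) -> EventTable:
    """Doublet exclusion: keep events with FSC-H/FSC-A inside the band.

    Events with FSC-A = 0 are excluded outright rather than dividing.
    """
    return events.subset(_singlet_mask(events, cfg))


def gate_viable(events: EventTable, cfg: GatingConfig,
                flags: Optional[List[str]] = None) -> EventTable:
    """Dead-cell exclusion: keep viability-dye-negative (below-cutoff) events."""
    return events.subset(_viable_mask(events, cfg, flags))


def gate_target(events: EventTable, cfg: GatingConfig) -> EventTable:
    """Immunological gate: events positive for all markers in the definition."""
    return events.subset(_target_mask(events, cfg))


def find_bimodal_valley(intensities: np.ndarray, bins: int = 256,
                        smooth_sigma: float = 3.0,
                        min_prominence: float = 0.05) -> Optional[float]:
    """Split point of a bimodal intensity channel, or None if unimodal.

    Works on log10(1 + x) with a fixed-width Gaussian kernel smoother;
    modes must rise by at least ``min_prominence`` of the tallest peak
    (so sampling ripples on a unimodal channel do not count), and the
    valley is the smoothed-histogram minimum between the two most
    prominent modes.
    """
    x = np.log10(1.0 + np.asarray(intensities, dtype=float))
    hist, edges = np.histogram(x, bins=bins)
    smoothed = gaussian_filter1d(hist.astype(float), smooth_sigma)
    peaks, props = find_peaks(smoothed, prominence=min_prominence * smoothed.max())
    if len(peaks) < 2:
        return None
    top_two = np.sort(peaks[np.argsort(props["prominences"])[-2:]])
    between = slice(top_two[0] + 1, top_two[1])
    if between.start >= between.stop:
        return None
    valley_bin = between.start + int(np.argmin(smoothed[between]))
    centre = 0.5 * (edges[valley_bin] + edges[valley_bin + 1])
    return float(10.0 ** centre - 1.0)


def compute_mfi(events: EventTable, channel: str) -> float:
    """Median fluorescence intensity of ``channel``.

    Even event counts use the midpoint of the two central order statistics.
    """
    if len(events) == 0:
        raise ValidationError("cannot compute an MFI on an empty event table")
    return float(np.median(events.channel(channel)))


def load_tube(tube: Union[TubeRecord, str]) -> EventTable:
    """Read a tube file, dispatching on extension (.fcs or .csv)."""
    path = tube.path if isinstance(tube, TubeRecord) else str(tube)
    if path.lower().endswith(".csv"):
        return read_events_csv(path)
    return read_fcs(path)


def run_gating(tube: Union[TubeRecord, EventTable], cfg: GatingConfig) -> GatingResult:
    """Apply the full hierarchy to a tube and read out the cyt-c MFI.

    Accepts either a manifest record (the tube file is read from disk) or
    an in-memory event table.  Stage order: scatter -> singlets ->
    viability -> target.  The final population's median cyt-c intensity is
    the tube's MFI; an empty final gate yields ``mfi=None`` plus a hard
    ``empty_final_gate`` flag, and a final count below
    ``cfg.min_gated_events`` sets ``low_event_count``.
    """
    events = tube if isinstance(tube, EventTable) else load_tube(tube)
    flags: List[str] = []
    counts = {"input": len(events)}
    retained = {"input": np.arange(len(events))}

    current = events
    current_idx = retained["input"]
    stage_masks = (
        ("scatter", _scatter_mask, ()),
        ("singlet", _singlet_mask, ()),
        ("viable", _viable_mask, (flags,)),
        ("target", _target_mask, ()),
    )
    for stage_name, mask_fn, extra in stage_masks:
        mask = mask_fn(current, cfg, *extra)
        current = current.subset(mask)
        current_idx = current_idx[mask]
        counts[stage_name] = len(current)
        retained[stage_name] = current_idx

    if len(current) == 0:
        flags.append("empty_final_gate")
        mfi = None
    else:
        mfi = compute_mfi(current, cfg.cytc_channel)
        if len(current) < cfg.min_gated_events:
            flags.append("low_event_count")
    return GatingResult(counts=counts, mfi=mfi, qc_flags=flags,
                        retained_index=retained)
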