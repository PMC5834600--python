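"""Event-level gating: QC, debris/doublet/dead-cell exclusion, barcode
demultiplexing and control-referenced positivity gates.

The stage chain mirrors the screening strategy: well QC (minimum event count)
→ scatter gate removing the low-FSC debris cluster → singlet gate on the
FSC-H vs FSC-A relation → optional live gate against a viability-dye control
→ barcode demultiplexing into the two pooled populations → %-positive on the
reporter channel against a control-referenced threshold.  The live stage is
skipped automatically when no viability channel is bound (the plate-screening
protocol carries no viability dye).

All thresholds are deterministic functions of the events and the
configuration; medians and quantiles operate on raw linear intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import EventTable, ChannelMappingError, POP_POS, POP_NEG

__all__ = [
    "GateConfig",
    "GatingResult",
    "GatedWell",
    "GateError",
    "DemultiplexError",
    "qc_well",
    "gate_cells",
    "exclude_doublets",
    "exclude_dead",
    "demultiplex_barcode",
    "set_positivity_gate",
    "percent_positive",
    "gate_well",
]

logger = logging.getLogger("lyoscreen.gating")


class GateError(ValueError):
    """Raised when a gate cannot be placed (e.g. too few control events)."""


class DemultiplexError(ValueError):
    """Raised when the barcode distribution is judged unimodal."""


@dataclass(frozen=True)
class GateConfig:
    """Gating parameters.

    ``positivity_confidence`` is the control quantile defining the positivity
    gate (0.999 ⇒ at most 0.1% of control events exceed it by construction);
    ``min_events_per_well`` is the acquisition QC floor (10,000 by default).
    """

    min_events_per_well: int = 10_000
    debris_cut_frac: float = 0.4  # threshold = this fraction of the main FSC-A mode
    doublet_band_sds: float = 4.0  # residual band in robust SDs around the singlet line
    viability_quantile: float = 0.999
    barcode_method: str = "kde-valley"  # kde-valley | otsu | fixed
    barcode_fixed_threshold: float | None = None
    valley_prominence: float = 0.05  # of the highest peak
    positivity_confidence: float = 0.999

    def __post_init__(self):
        if not 0.0 < self.positivity_confidence < 1.0:
            raise ValueError("positivity_confidence must lie in (0,1)")
        if self.min_events_per_well < 1:
            raise ValueError("min_events_per_well must be >= 1")
        if self.barcode_method not in ("kde-valley", "otsu", "fixed"):
            raise ValueError(f"unknown barcode_method {self.barcode_method!r}")


@dataclass
class GatingResult:
    """Per-well stage bookkeeping: counts along the chain and the thresholds used."""

    counts: dict[str, int] = field(default_factory=dict)
    barcode_threshold: float | None = None
    positivity_thresholds: dict[str, float] = field(default_factory=dict)
    pct_positive: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class GatedWell:
    """Output of the full per-well chain: demultiplexed populations + bookkeeping."""

    result: GatingResult
    populations: dict[str, EventTable]
    qc_pass: bool
    qc_reason: str = ""


# ---------------------------------------------------------------------------
# density helpers
# ---------------------------------------------------------------------------

def _silverman_bw(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(np.mean(x))), 1.0) * 1e-3
    return 0.9 * spread * n ** (-1 / 5)


def _binned_kde(x: np.ndarray, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE with Silverman bandwidth, evaluated by binned convolution.

    Histogram the data onto a fine grid and convolve with the Gaussian kernel;
    at these grid resolutions the result is numerically indistinguishable from
    the exact KDE and costs O(n + grid)."""
    bw = _silverman_bw(x)
    lo, hi = float(x.min()) - 3 * bw, float(x.max()) + 3 * bw
    hist, edges = np.histogram(x, bins=n_grid, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    binw = edges[1] - edges[0]
    dens = gaussian_filter1d(hist.astype(float), sigma=max(bw / binw, 1e-9), mode="constant")
    dens /= max(dens.sum() * binw, 1e-300)
    return centers, dens


def _otsu_threshold(x: np.ndarray, n_bins: int = 256) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(x, nbins=n_bins))


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def qc_well(events: EventTable, config: GateConfig) -> tuple[bool, str]:
    """Acquisition QC: fail wells with fewer events than the configured floor."""
    n = len(events)
    if n == 0:
        return False, "empty well"
    if n < config.min_events_per_well:
        return False, f"only {n} events (< {config.min_events_per_well})"
    return True, ""


def gate_cells(events: EventTable, config: GateConfig = GateConfig()) -> EventTable:
    """Scatter gate: drop the low-FSC debris cluster.

    The threshold is anchored at the main mode of the FSC-A density (found on
    the log scale) and set to ``debris_cut_frac`` of that mode's linear
    position; events below it are removed."""
    if len(events) == 0:
        logger.warning("scatter gate on empty well")
        return events
    fsc = events.channel("scatter_area")
    logx = np.log(np.clip(fsc, 1e-6, None))
    grid, dens = _binned_kde(logx)
    mode = float(np.exp(grid[int(np.argmax(dens))]))
    threshold = config.debris_cut_frac * mode
    keep = fsc >= threshold
    if not keep.any():
        logger.warning("scatter gate removed all events; downstream stats undefined")
    logger.debug("scatter gate at %.1f retained %.3f", threshold, keep.mean())
    return events.subset(keep)


def exclude_doublets(events: EventTable, config: GateConfig = GateConfig()) -> EventTable:
    """Singlet gate on the FSC-H vs FSC-A relation.

    A robust proportionality fit (median height/area ratio over the central
    FSC-A mass) defines the singlet line; events whose FSC-H residual falls
    outside ``doublet_band_sds`` robust SDs are removed.  Doublets, with
    roughly doubled area but sub-proportional height, sit far below the band."""
    n = len(events)
    if n < 50:
        logger.warning("singlet gate skipped: only %d events (fit unstable)", n)
        return events
    a = events.channel("scatter_area")
    h = events.channel("scatter_height")
    lo, hi = np.percentile(a, [10, 90])
    central = (a >= lo) & (a <= hi)
    ratio = h[central] / np.clip(a[central], 1e-9, None)
    slope = float(np.median(ratio))
    resid = h - slope * a
    rc = resid[central]
    rsd = 1.4826 * float(np.median(np.abs(rc - np.median(rc))))
    if rsd == 0:  # exact proportionality: keep the line only
        return events.subset(resid == 0)
    band = config.doublet_band_sds * rsd
    keep = np.abs(resid) <= band
    logger.debug("singlet gate slope %.4f band ±%.1f retained %.3f", slope, band, keep.mean())
    return events.subset(keep)


def exclude_dead(events: EventTable, viability_control: EventTable,
                 config: GateConfig = GateConfig()) -> tuple[EventTable, float]:
    """Live gate: remove events above the control-referenced viability threshold.

    The threshold is the configured quantile (default 0.999) of the control's
    viability channel; returns the retained subset and the threshold."""
    via = events.channel("viability")
    ctrl = viability_control.channel("viability")
    threshold = float(np.quantile(ctrl, config.viability_quantile))
    keep = via <= threshold
    return events.subset(keep), threshold


def demultiplex_barcode(
    events: EventTable, config: GateConfig = GateConfig()
) -> tuple[EventTable, EventTable, float]:
    """Split pooled events into barcode-negative and barcode-positive subsets.

    The threshold sits at the minimum-density valley between the two largest
    modes of the log-barcode KDE (Silverman bandwidth).  A distribution whose
    secondary mode or valley lacks the configured prominence is judged
    unimodal and raises :class:`DemultiplexError`.  ``barcode_method='otsu'``
    instead maximizes between-class variance on the log intensities;
    ``'fixed'`` applies a user threshold.  Returns
    ``(negative_subset, positive_subset, linear_threshold)``; the two subsets
    partition the input."""
    if len(events) < 50:
        raise DemultiplexError(f"too few events to demultiplex ({len(events)})")
    bc = events.channel("barcode")
    logx = np.log(np.clip(bc, 1e-6, None))

    if config.barcode_method == "fixed":
        if config.barcode_fixed_threshold is None:
            raise GateError("barcode_method='fixed' requires barcode_fixed_threshold")
        thr = float(config.barcode_fixed_threshold)
    elif config.barcode_method == "otsu":
        thr = float(np.exp(_otsu_threshold(logx)))
    else:
        grid, dens = _binned_kde(logx)
        # local maxima of the smoothed density
        inner = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        peaks = np.flatnonzero(inner) + 1
        peak_h = dens[peaks]
        top = peak_h.max() if peaks.size else 0.0
        peaks = peaks[peak_h >= config.valley_prominence * top]
        if peaks.size < 2:
            raise DemultiplexError(
                "barcode distribution judged unimodal (no second mode above prominence)"
            )
        order = np.argsort(dens[peaks])[::-1]
        p1, p2 = sorted(peaks[order[:2]])
        valley_idx = p1 + int(np.argmin(dens[p1:p2 + 1]))
        valley = dens[valley_idx]
        lower_peak = min(dens[p1], dens[p2])
        if lower_peak - valley < config.valley_prominence * dens[peaks].max():
            raise DemultiplexError(
                "barcode distribution judged unimodal (valley depth below prominence)"
            )
        thr = float(np.exp(grid[valley_idx]))

    pos_mask = bc > thr
    return events.subset(~pos_mask), events.subset(pos_mask), thr


def set_positivity_gate(control_events: EventTable, confidence: float | None = None,
                        config: GateConfig = GateConfig()) -> float:
    """Control-referenced positivity threshold on the reporter channel.

    The gate is the empirical ``confidence`` quantile (linear interpolation of
    order statistics, quantile type 7) of the control's reporter intensities,
    so at most ``1 − confidence`` of control events exceed it by construction."""
    if confidence is None:
        confidence = config.positivity_confidence
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0,1)")
    if len(control_events) < 100:
        raise GateError(f"too few control events ({len(control_events)}) for a positivity gate")
    rep = control_events.channel("reporter")
    return float(np.quantile(rep, confidence))


def percent_positive(events: EventTable, threshold: float) -> float:
    """Percentage (0–100) of events strictly above the positivity threshold.

    Events exactly at the threshold count negative (deterministic
    tie-breaking); an empty input yields NaN rather than an exception."""
    n = len(events)
    if n == 0:
        logger.warning("percent_positive on empty input: undefined")
        return float("nan")
    rep = events.channel("reporter")
    return 100.0 * float(np.count_nonzero(rep > threshold)) / n


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def gate_well(
    events: EventTable,
    config: GateConfig = GateConfig(),
    viability_control: EventTable | None = None,
    positivity_thresholds: dict[str, float] | None = None,
) -> GatedWell:
    """Run the full chain on one well.

    Stages: QC → scatter gate → singlet gate → live gate (only when a
    viability channel is bound *and* a control is supplied) → barcode
    demultiplexing.  When per-population positivity thresholds are given,
    per-population %-positive is computed.  Counts are recorded at every
    stage; demultiplexed subsets partition the final stage."""
    result = GatingResult()
    result.counts["total"] = len(events)
    ok, reason = qc_well(events, config)
    if not ok:
        return GatedWell(result=result, populations={}, qc_pass=False, qc_reason=reason)

    cells = gate_cells(events, config)
    result.counts["non_debris"] = len(cells)
    singlets = exclude_doublets(cells, config)
    result.counts["singlet"] = len(singlets)

    if viability_control is not None and singlets.has_channel("viability"):
        live, thr = exclude_dead(singlets, viability_control, config)
        result.counts["live"] = len(live)
        result.flags.append(f"viability_threshold={thr:.6g}")
    else:
        live = singlets
        result.counts["live"] = len(live)

    try:
        neg, pos, thr = demultiplex_barcode(live, config)
    except DemultiplexError as exc:
        result.flags.append(f"demultiplex_error: {exc}")
        return GatedWell(result=result, populations={}, qc_pass=True)
    result.barcode_threshold = thr
    result.counts[POP_POS] = len(pos)
    result.counts[POP_NEG] = len(neg)
    populations = {POP_POS: pos, POP_NEG: neg}

    if positivity_thresholds:
        for popname, sub in populations.items():
            if popname in positivity_thresholds:
                t = positivity_thresholds[popname]
                result.positivity_thresholds[popname] = t
                result.pct_positive[popname] = percent_positive(sub, t)
    return GatedWell(result=result, populations=populations, qc_pass=True)
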