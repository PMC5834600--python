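"""Marker-level screening statistics and classification.

Aggregates per-well gating output into the screen's headline quantities:

* %-positive per marker × population × donor, referenced to the matched
  isotype-control gate of the same plate;
* positivity call — a marker is *positive* when at least 5.5% of cells stain
  in one or both populations (the standard criterion for this screen class);
* *variable* vs equally-expressed partition and the *enriched* filter — fold
  increase in %-positive ≥ 1.5 together with p < 0.05 (one-way ANOVA across
  donors by default, paired t optional, Benjamini–Hochberg behind a flag);
* stain index, SI = (median(stained) − median(control)) / (2 × rSD(control))
  with rSD the robust spread 1.4826 × MAD of the control;
* per-population background statistics from isotype wells (median reporter
  intensity and the serum/lysate background ratio);
* a small ΔΔCt helper for qPCR confirmation of screen hits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventTable, PanelLayout, POP_POS, POP_NEG
from .gating import GateConfig, GatedWell, gate_well, set_positivity_gate, percent_positive
from .synthetic import PlateSimConfig, iter_screen

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "WellStats",
    "classify_positive",
    "fold_increase",
    "test_marker",
    "flag_enriched",
    "stain_index",
    "si_fold",
    "background_stats",
    "ddct_fold",
    "aggregate_screen",
    "run_screen",
]

logger = logging.getLogger("lyoscreen.screening")


@dataclass(frozen=True)
class ScreenConfig:
    """Classification thresholds and test choices.

    ``positivity_threshold_pct`` (default 5.5, inclusive) and
    ``enrichment_fold_min`` (default 1.5, inclusive) with ``alpha`` (default
    0.05, strict) reproduce the screen's published decision rules;
    ``fold_floor_pct`` keeps near-zero denominators finite.  The variable /
    equally-expressed partition (``variable_fold_min`` or
    ``variable_diff_pct``) is a module convention — the underlying screen
    protocol states no formula for it.
    """

    positivity_threshold_pct: float = 5.5
    enrichment_fold_min: float = 1.5
    alpha: float = 0.05
    fold_floor_pct: float = 0.5
    variable_fold_min: float = 1.25
    variable_diff_pct: float = 10.0
    multiplicity: str = "none"  # none | benjamini-hochberg
    test: str = "one-way-anova"  # one-way-anova | paired-t
    robust_spread: bool = True  # SI spread: 1.4826*MAD (True) or sample SD

    def __post_init__(self):
        if not (self.positivity_threshold_pct > 0 and self.enrichment_fold_min > 0
                and self.fold_floor_pct > 0):
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0,1)")
        if self.multiplicity not in ("none", "benjamini-hochberg"):
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.test not in ("one-way-anova", "paired-t"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class WellStats:
    """Per well × population summary used to build the screen tables."""

    donor: str
    plate: str
    well: str
    marker: str
    population: str
    n_events: int
    pct_positive: float
    mfi_all: float
    mfi_positive: float
    background_mfi: float
    background_rsd: float
    stain_index: float


@dataclass
class ScreenResult:
    """Marker × population × donor matrices plus per-marker classification.

    ``pct_table`` — long table (marker, population, donor, pct_positive, n,
    MFIs, stain index); ``classification`` — per-marker means, fold change,
    p-value, flags; ``background`` — per-donor background medians and ratio.
    """

    pct_table: pd.DataFrame
    classification: pd.DataFrame
    background: pd.DataFrame

    def flag_counts(self) -> dict[str, int]:
        c = self.classification
        return {
            "markers": int(len(c)),
            "positive": int(c["positive"].sum()),
            "variable": int(c["variable"].sum()),
            "enriched": int(c["enriched"].sum()),
        }

    def enriched_markers(self) -> list[str]:
        c = self.classification
        return sorted(c.index[c["enriched"]].tolist())


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def classify_positive(pct_pop1: float, pct_pop2: float, threshold: float = 5.5) -> bool:
    """Positive iff at least ``threshold`` percent of cells stain in one or
    both populations (inclusive)."""
    return bool(max(pct_pop1, pct_pop2) >= threshold)


def fold_increase(pct_plt: float, pct_fcs: float, floor: float = 0.5) -> tuple[float, bool]:
    """Fold increase in %-positive, lysate over serum population.

    The denominator is floored at ``floor`` percentage points so near-zero
    backgrounds stay finite; returns ``(fold, floored_flag)``."""
    denom = max(pct_fcs, floor)
    return pct_plt / denom, pct_fcs < floor


def test_marker(pcts_plt, pcts_fcs, config: ScreenConfig = ScreenConfig()) -> float:
    """Per-marker p-value across donors.

    Default is a two-group one-way ANOVA F-test (equivalent to the unpaired
    two-sided t for two groups); ``test='paired-t'`` pairs donors instead.
    Degenerate input with zero variance in both groups and equal means
    returns p = 1 by convention."""
    a = np.asarray(pcts_plt, dtype=float)
    b = np.asarray(pcts_fcs, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 donors per group")
    if config.test == "paired-t":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length donor vectors")
        if np.allclose(a, b):
            return 1.0
        return float(stats.ttest_rel(a, b).pvalue)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.f_oneway(a, b).pvalue)


test_marker.__test__ = False  # keep pytest from collecting the API name


def flag_enriched(fold: float, p: float, config: ScreenConfig = ScreenConfig()) -> bool:
    """Enriched iff fold ≥ ``enrichment_fold_min`` (inclusive) and p < alpha (strict)."""
    if not math.isfinite(fold):
        return False
    return bool(fold >= config.enrichment_fold_min and p < config.alpha)


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def stain_index(stained, control, robust: bool = True) -> float:
    """Stain index: (median(stained) − median(control)) / (2 × spread(control)).

    ``spread`` is the robust SD 1.4826 × MAD by default (plain sample SD with
    ``robust=False``).  NaN (flagged undefined) for empty input or a control
    with zero spread."""
    s = stained.channel("reporter") if isinstance(stained, EventTable) else np.asarray(stained, float)
    c = control.channel("reporter") if isinstance(control, EventTable) else np.asarray(control, float)
    if s.size == 0 or c.size == 0:
        return float("nan")
    spread = _robust_sd(c) if robust else float(np.std(c, ddof=1)) if c.size > 1 else 0.0
    if spread == 0:
        return float("nan")
    return (float(np.median(s)) - float(np.median(c))) / (2.0 * spread)


def si_fold(si_plt: float, si_fcs: float) -> float:
    """Ratio of stain indices (lysate over serum); NaN when the denominator is
    ≤ 0 or either index undefined (a ratio of separations is then meaningless)."""
    if not (math.isfinite(si_plt) and math.isfinite(si_fcs)) or si_fcs <= 0:
        return float("nan")
    return si_plt / si_fcs


def background_stats(control_reporter: dict[str, list[np.ndarray]]) -> pd.DataFrame:
    """Per-population background summary from isotype/unstained control wells.

    ``control_reporter`` maps population → list of per-well reporter arrays.
    Returns one row per population (median MFI across pooled control events,
    robust SD, well count) plus the serum/lysate background ratio stored on
    every row; wells with < 100 events are flagged low-n but still counted."""
    if not control_reporter or all(len(v) == 0 for v in control_reporter.values()):
        raise ValueError("no control wells supplied")
    rows = []
    medians = {}
    for pop, arrays in control_reporter.items():
        pooled = np.concatenate([np.asarray(a, float) for a in arrays]) if arrays else np.array([])
        med = float(np.median(pooled)) if pooled.size else float("nan")
        medians[pop] = med
        rows.append({
            "population": pop,
            "background_mfi": med,
            "background_rsd": _robust_sd(pooled) if pooled.size else float("nan"),
            "n_wells": len(arrays),
            "n_events": int(pooled.size),
            "low_n": bool(pooled.size < 100),
        })
    df = pd.DataFrame(rows)
    if POP_POS in medians and POP_NEG in medians and medians[POP_POS] > 0:
        df["ratio_fcs_over_plt"] = medians[POP_NEG] / medians[POP_POS]
    else:
        df["ratio_fcs_over_plt"] = float("nan")
    return df


def ddct_fold(ct_target_plt, ct_ref_plt, ct_target_fcs, ct_ref_fcs) -> float:
    """Relative expression fold by the ΔΔCt method.

    ΔCt = mean(Ct target) − mean(Ct reference) per condition; the fold of the
    first condition over the second is 2^−(ΔCt₁ − ΔCt₂)."""
    arrays = [np.asarray(v, dtype=float).ravel() for v in
              (ct_target_plt, ct_ref_plt, ct_target_fcs, ct_ref_fcs)]
    if any(a.size == 0 for a in arrays):
        raise ValueError("replicate lists must be non-empty")
    if not all(np.isfinite(a).all() for a in arrays):
        raise ValueError("Ct values must be finite")
    dct_plt = arrays[0].mean() - arrays[1].mean()
    dct_fcs = arrays[2].mean() - arrays[3].mean()
    return float(2.0 ** (-(dct_plt - dct_fcs)))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_screen(
    well_stats: list[WellStats],
    background: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Build marker-level classification from per-well population statistics.

    Means across donors drive the positivity call and fold change; the
    p-value comes from the per-donor %-positive vectors.  Flags obey the
    hierarchy enriched ⇒ variable ⇒ positive."""
    pct_columns = ["donor", "plate", "well", "marker", "population", "n_events",
                   "pct_positive", "mfi_all", "mfi_positive", "background_mfi",
                   "background_rsd", "stain_index"]
    pct = pd.DataFrame([w.__dict__ for w in well_stats], columns=pct_columns)
    rows = []
    for marker, grp in pct.groupby("marker", sort=True):
        piv = grp.pivot_table(index="donor", columns="population", values="pct_positive")
        if POP_POS not in piv.columns or POP_NEG not in piv.columns:
            continue
        mean_plt = float(piv[POP_POS].mean())
        mean_fcs = float(piv[POP_NEG].mean())
        fold, floored = fold_increase(mean_plt, mean_fcs, config.fold_floor_pct)
        paired = piv.dropna()
        if len(paired) >= 2:
            p = test_marker(paired[POP_POS].to_numpy(), paired[POP_NEG].to_numpy(), config)
        else:
            p = float("nan")
        positive = classify_positive(mean_plt, mean_fcs, config.positivity_threshold_pct)
        variable = positive and (
            fold >= config.variable_fold_min or abs(mean_plt - mean_fcs) >= config.variable_diff_pct
        )
        enriched = variable and flag_enriched(fold, p, config)
        si = grp.pivot_table(index="donor", columns="population", values="stain_index")
        si_plt = float(si[POP_POS].mean()) if POP_POS in si.columns else float("nan")
        si_fcs = float(si[POP_NEG].mean()) if POP_NEG in si.columns else float("nan")
        rows.append({
            "marker": marker,
            "pct_plt_mean": mean_plt,
            "pct_fcs_mean": mean_fcs,
            "fold": fold,
            "fold_floored": floored,
            "p_value": p,
            "positive": positive,
            "variable": variable,
            "enriched": enriched,
            "si_plt": si_plt,
            "si_fcs": si_fcs,
            "si_fold": si_fold(si_plt, si_fcs),
        })
    cls = pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["pct_plt_mean", "pct_fcs_mean", "fold", "fold_floored", "p_value",
                 "positive", "variable", "enriched", "si_plt", "si_fcs", "si_fold"],
        index=pd.Index([], name="marker"),
    )
    if config.multiplicity == "benjamini-hochberg" and len(cls):
        mask = cls["p_value"].notna()
        adj = np.full(len(cls), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = stats.false_discovery_control(cls.loc[mask, "p_value"], method="bh")
        cls["p_adjusted"] = adj
        cls["enriched"] = cls["variable"] & (cls["fold"] >= config.enrichment_fold_min) & (
            cls["p_adjusted"] < config.alpha)
    logger.info("screen classification: %s",
                {k: int(v) for k, v in cls[["positive", "variable", "enriched"]].sum().items()}
                if len(cls) else "no markers")
    return ScreenResult(pct_table=pct, classification=cls, background=background)


# ---------------------------------------------------------------------------
# end-to-end pipeline on simulated plates
# ---------------------------------------------------------------------------

def run_screen(
    sim_config: PlateSimConfig,
    gate_config: GateConfig = GateConfig(),
    screen_config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Simulate, gate and classify a whole screen, streaming well by well.

    For every donor × plate, isotype wells are gated first: each isotype
    group yields per-population positivity thresholds (control quantile at
    the configured confidence) and background reference events.  Marker wells
    are then gated and scored against their matched group's thresholds."""
    layout = sim_config.layout
    well_stats: list[WellStats] = []
    control_reporter: dict[str, list[np.ndarray]] = {POP_POS: [], POP_NEG: []}

    # buffer per (donor, plate): isotype controls seen before markers
    current_key = None
    iso_thresholds: dict[str, dict[str, float]] = {}
    iso_background: dict[str, dict[str, tuple[float, float, np.ndarray]]] = {}
    pending: list[tuple] = []

    def _process_marker(donor, plate, well, gated: GatedWell, marker, group):
        if not gated.qc_pass or not gated.populations:
            logger.warning("well %s/%s/%s skipped: %s", donor, plate, well,
                           gated.qc_reason or gated.result.flags)
            return
        thr = iso_thresholds.get(group)
        bg = iso_background.get(group)
        if thr is None or bg is None:
            logger.warning("marker %s has no gated isotype group %r; skipped", marker, group)
            return
        for pop, sub in gated.populations.items():
            pct = percent_positive(sub, thr[pop])
            rep = sub.channel("reporter")
            bg_med, bg_rsd, bg_events = bg[pop]
            pos_mask = rep > thr[pop]
            well_stats.append(WellStats(
                donor=donor, plate=plate, well=well, marker=marker, population=pop,
                n_events=len(sub), pct_positive=pct,
                mfi_all=float(np.median(rep)) if rep.size else float("nan"),
                mfi_positive=float(np.median(rep[pos_mask])) if pos_mask.any() else float("nan"),
                background_mfi=bg_med, background_rsd=bg_rsd,
                stain_index=stain_index(rep, bg_events, robust=screen_config.robust_spread),
            ))

    def _flush():
        for item in pending:
            _process_marker(*item)
        pending.clear()
        iso_thresholds.clear()
        iso_background.clear()

    for donor, plate, well, events, _truth in iter_screen(sim_config):
        key = (donor, plate)
        if key != current_key:
            _flush()
            current_key = key
        entry = layout.entry(plate, well)
        gated = gate_well(events, gate_config)
        if entry["reagent_class"] in ("isotype", "unstained"):
            if not gated.qc_pass or not gated.populations:
                logger.warning("control well %s/%s/%s failed gating", donor, plate, well)
                continue
            group = entry["isotype_group"]
            thr = {}
            bg = {}
            for pop, sub in gated.populations.items():
                thr[pop] = set_positivity_gate(sub, gate_config.positivity_confidence)
                rep = sub.channel("reporter")
                bg[pop] = (float(np.median(rep)), _robust_sd(rep), rep)
                control_reporter[pop].append(rep)
            iso_thresholds[group] = thr
            iso_background[group] = bg
        elif entry["reagent_class"] == "marker":
            pending.append((donor, plate, well, gated, entry["reagent_name"],
                            entry["isotype_group"]))
    _flush()

    background = background_stats(control_reporter)
    return aggregate_screen(well_stats, background, screen_config)
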