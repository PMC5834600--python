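"""Synthetic list-mode plate generator with planted ground truth.

Emulates the statistical structure of a pooled two-population antibody-panel
screen: two cell populations (one labelled with a barcoding dye, one left
unlabelled) are mixed in a configurable ratio and distributed across four
96-well plates, one APC-like reporter readout per well.  Each well's reporter
distribution is a two-component log-normal mixture (autofluorescent background
plus an antibody-positive component) with per-population positive fractions;
the unlabelled population carries markedly higher side scatter and a much
brighter background, mirroring serum-grown versus lysate-grown stromal cells.
Debris, doublet and dead-cell contamination are planted with known fractions
so that every downstream gate can be checked against truth.

All distributional choices here are generator conventions (the screen protocol
fixes counts and ratios, not event-level distributions); they are documented in
the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    ChannelMap,
    EventTable,
    PanelLayout,
    SampleManifest,
    default_panel_layout,
    default_marker_names,
    write_fcs,
    write_manifest,
    POP_POS,
    POP_NEG,
    POPULATIONS,
)

__all__ = [
    "PopulationModel",
    "MarkerTruth",
    "PlateSimConfig",
    "WellTruth",
    "SimulationTruth",
    "simulate_well",
    "simulate_screen",
    "iter_screen",
    "simulate_screen_to_dir",
    "default_populations",
    "overlap_populations",
    "default_screen_truth",
    "default_screen_config",
]

#: simulated channels, in file order
SIM_CHANNELS = ["FSC-A", "FSC-H", "SSC-A", "SSC-W", "VioBlue-A", "APC-A", "DAPI-A"]

SIM_CHANNEL_MAP = ChannelMap(viability="DAPI-A")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Event-level model for one pooled population.

    Scatter is bivariate normal on (FSC-A, SSC-A); barcode dye and reporter
    autofluorescence are log-normal on the linear intensity scale.
    ``viability_positive_fraction`` is the planted fraction of dead
    (viability-dye-bright) cells.
    """

    name: str
    scatter_mean: tuple[float, float]
    scatter_cov: tuple[tuple[float, float], tuple[float, float]]
    background_logmean: float
    background_logsd: float
    barcode_logmean: float
    barcode_logsd: float
    viability_positive_fraction: float = 0.05

    def __post_init__(self):
        cov = np.asarray(self.scatter_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("scatter_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("scatter_cov must be positive-definite")
        if not (self.background_logsd > 0 and self.barcode_logsd > 0):
            raise ValueError("log-scale SDs must be positive")
        if not 0.0 <= self.viability_positive_fraction <= 1.0:
            raise ValueError("viability_positive_fraction must lie in [0,1]")


@dataclass(frozen=True)
class MarkerTruth:
    """Planted truth for one antibody well.

    ``positive_fraction`` maps population name → fraction of events in the
    reporter-positive mixture component; ``positive_logshift`` is the additive
    log-intensity shift of that component over the population background;
    ``donor_logit_sd`` scales logit-normal donor-to-donor variation of the
    fractions (fractions of exactly 0 or 1 stay fixed).
    """

    marker: str
    positive_fraction: Mapping[str, float]
    positive_logshift: float = 3.0
    donor_logit_sd: float = 0.0

    def __post_init__(self):
        for pop, frac in self.positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"positive_fraction[{pop}] must lie in [0,1]")
        if self.positive_logshift < 0:
            raise ValueError("positive_logshift must be >= 0")
        if self.donor_logit_sd < 0:
            raise ValueError("donor_logit_sd must be >= 0")


@dataclass
class PlateSimConfig:
    """Full plate-screen simulation configuration."""

    layout: PanelLayout
    populations: tuple[PopulationModel, PopulationModel]
    markers: list[MarkerTruth]
    pooling_ratio: float = 1.0  # population-1 (barcode+) : population-2 events
    events_per_well: int = 50_000
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.04
    n_donors: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.events_per_well < 1:
            raise ValueError("events_per_well must be >= 1")
        if self.pooling_ratio <= 0:
            raise ValueError("pooling_ratio must be > 0")
        if not 0 <= self.debris_fraction <= 1 or not 0 <= self.doublet_fraction <= 1:
            raise ValueError("contamination fractions must lie in [0,1]")
        if self.debris_fraction + self.doublet_fraction > 1:
            raise ValueError("debris + doublet fractions exceed 1")
        self._truth_by_marker = {m.marker: m for m in self.markers}
        referenced = set(self.layout.marker_names)
        missing = referenced - set(self._truth_by_marker)
        if missing:
            raise ValueError(f"layout references markers absent from truth list: {sorted(missing)[:5]}")

    def marker_truth(self, name: str) -> MarkerTruth:
        return self._truth_by_marker[name]


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------

@dataclass
class WellTruth:
    """Realized per-well ground truth (one donor, one well)."""

    donor: str
    plate: str
    well: str
    reagent_name: str
    reagent_class: str
    seed: int
    n_events: int
    n_debris: int
    n_doublet: int
    n_dead: int
    n_clean: int
    per_population: dict  # pop -> {n_clean, positive_fraction, n_positive, background_logmean, background_logsd, positive_logshift}

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """All planted values of one simulated screen; reproducible from (config, seed)."""

    seed: int
    pooling_ratio: float
    events_per_well: int
    debris_fraction: float
    doublet_fraction: float
    donor_fractions: dict  # donor -> marker -> pop -> realized fraction
    wells: dict = field(default_factory=dict)  # (donor, plate, well) -> WellTruth

    def add(self, wt: WellTruth) -> None:
        self.wells[(wt.donor, wt.plate, wt.well)] = wt

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "pooling_ratio": self.pooling_ratio,
            "events_per_well": self.events_per_well,
            "debris_fraction": self.debris_fraction,
            "doublet_fraction": self.doublet_fraction,
            "donor_fractions": self.donor_fractions,
            "wells": {f"{d}|{p}|{w}": wt.as_dict() for (d, p, w), wt in self.wells.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls(
            seed=payload["seed"],
            pooling_ratio=payload["pooling_ratio"],
            events_per_well=payload["events_per_well"],
            debris_fraction=payload["debris_fraction"],
            doublet_fraction=payload["doublet_fraction"],
            donor_fractions=payload["donor_fractions"],
        )
        for key, wt in payload["wells"].items():
            d, p, w = key.split("|")
            truth.add(WellTruth(**wt))
        return truth


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_populations(background_ratio: float = 13.0) -> tuple[PopulationModel, PopulationModel]:
    """Default two-population models.

    The barcode-positive (lysate-grown, "PLT") population: lower side scatter,
    dim reporter autofluorescence, bright barcode dye.  The barcode-negative
    (serum-grown, "FCS") population: elevated SSC-A and a ``background_ratio``-
    fold brighter reporter background (default 13×).  Barcode modes are
    separated by ≈20 log-SDs, far above the ≥6 log-SD design floor for clean
    demultiplexing.
    """
    plt_bg = 100.0
    plt = PopulationModel(
        name=POP_POS,
        scatter_mean=(45_000.0, 18_000.0),
        scatter_cov=((8_000.0**2, 0.3 * 8_000 * 5_000), (0.3 * 8_000 * 5_000, 5_000.0**2)),
        background_logmean=float(np.log(plt_bg)),
        background_logsd=0.35,
        barcode_logmean=float(np.log(20_000.0)),
        barcode_logsd=0.25,
        viability_positive_fraction=0.05,
    )
    fcs = PopulationModel(
        name=POP_NEG,
        scatter_mean=(50_000.0, 32_000.0),
        scatter_cov=((9_000.0**2, 0.3 * 9_000 * 8_000), (0.3 * 9_000 * 8_000, 8_000.0**2)),
        background_logmean=float(np.log(plt_bg * background_ratio)),
        background_logsd=0.40,
        barcode_logmean=float(np.log(120.0)),
        barcode_logsd=0.35,
        viability_positive_fraction=0.05,
    )
    return plt, fcs


def overlap_populations(separation_logsd: float = 2.0) -> tuple[PopulationModel, PopulationModel]:
    """Stress preset: barcode modes separated by ``separation_logsd`` common
    log-SDs (default 2), with equal log-SDs so the two-Gaussian Bayes
    misassignment rate has the closed form Φ(−separation/2)."""
    plt, fcs = default_populations()
    sd = 0.30
    lo = float(np.log(2_000.0))
    hi = lo + separation_logsd * sd
    plt = PopulationModel(**{**asdict(plt), "barcode_logmean": hi, "barcode_logsd": sd})
    fcs = PopulationModel(**{**asdict(fcs), "barcode_logmean": lo, "barcode_logsd": sd})
    return plt, fcs


def default_screen_truth(
    enriched_fraction_pos: float = 0.5,
    enriched_fraction_neg: float = 0.2,
    equal_fraction: float = 0.7,
    donor_logit_sd: float = 0.15,
) -> list[MarkerTruth]:
    """Planted truth for the full 356-plex screen.

    13 markers enriched on the barcode-positive population (default fractions
    0.5 vs 0.2, a 2.5-fold difference in %-positive), 51 equally highly
    expressed on both, and the remaining 292 negative on both.
    """
    enriched, equal, negative = default_marker_names()
    truths = []
    for name in enriched:
        truths.append(MarkerTruth(name, {POP_POS: enriched_fraction_pos, POP_NEG: enriched_fraction_neg},
                                  donor_logit_sd=donor_logit_sd))
    for name in equal:
        truths.append(MarkerTruth(name, {POP_POS: equal_fraction, POP_NEG: equal_fraction},
                                  donor_logit_sd=donor_logit_sd))
    for name in negative:
        truths.append(MarkerTruth(name, {POP_POS: 0.0, POP_NEG: 0.0}, donor_logit_sd=donor_logit_sd))
    return truths


def default_screen_config(
    seed: int = 0,
    n_donors: int = 3,
    events_per_well: int = 50_000,
    donor_logit_sd: float = 0.15,
    background_ratio: float = 13.0,
) -> PlateSimConfig:
    """The default four-plate screen: 356 markers + 9 isotypes, 1:1 pooling,
    50,000 events/well, 5% debris, 4% doublets, 5% dead per population."""
    return PlateSimConfig(
        layout=default_panel_layout(),
        populations=default_populations(background_ratio=background_ratio),
        markers=default_screen_truth(donor_logit_sd=donor_logit_sd),
        pooling_ratio=1.0,
        events_per_well=events_per_well,
        n_donors=n_donors,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _well_seed(root_seed: int, donor_idx: int, plate_idx: int, well_idx: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), donor_idx, plate_idx, well_idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _donor_fractions(config: PlateSimConfig, donor_idx: int) -> dict[str, dict[str, float]]:
    """Realize per-donor positive fractions via logit-normal perturbation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 990_000 + donor_idx]))
    out: dict[str, dict[str, float]] = {}
    for mt in config.markers:
        fracs = {}
        for pop, p in mt.positive_fraction.items():
            if mt.donor_logit_sd == 0 or p in (0.0, 1.0):
                fracs[pop] = float(p)
            else:
                z = rng.normal(0.0, mt.donor_logit_sd)
                logit = np.log(p / (1 - p)) + z
                fracs[pop] = float(1.0 / (1.0 + np.exp(-logit)))
        out[mt.marker] = fracs
    return out


def simulate_well(
    config: PlateSimConfig,
    well: str,
    donor: str = "D1",
    seed: int | None = None,
    plate: str | None = None,
    fraction_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[EventTable, WellTruth]:
    """Simulate one pooled well and return its events plus realized truth.

    Events are drawn as: category ∈ {debris, doublet, cell}; cells get a
    population label with probability ``pooling_ratio/(1+pooling_ratio)`` for
    the barcode-positive population, bivariate-normal scatter, log-normal
    barcode dye and a two-component log-normal reporter mixture using the
    well's planted positive fraction (isotype/unstained/empty wells use 0).
    Identical ``(config, seed)`` give bit-identical output.
    """
    if plate is None:
        plate = config.layout.plates[0]
    entry = config.layout.entry(plate, well)
    reagent_class = entry["reagent_class"]
    if reagent_class == "marker":
        name = entry["reagent_name"]
        mt = config.marker_truth(name)
        if fraction_overrides and name in fraction_overrides:
            fractions = dict(fraction_overrides[name])
        else:
            fractions = dict(mt.positive_fraction)
        logshift = mt.positive_logshift
    else:
        name = entry["reagent_name"]
        fractions = {p.name: 0.0 for p in config.populations}
        logshift = 0.0

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(int(seed))
    n = config.events_per_well
    pop1, pop2 = config.populations
    p_pop1 = config.pooling_ratio / (1.0 + config.pooling_ratio)

    # event categories: 0=debris, 1=doublet, 2=cell
    u = rng.random(n)
    is_debris = u < config.debris_fraction
    is_doublet = (~is_debris) & (u < config.debris_fraction + config.doublet_fraction)
    is_cell = ~(is_debris | is_doublet)

    pop_is_1 = rng.random(n) < p_pop1  # drawn for every event; used for cells/doublets

    fsc = np.empty(n)
    fsch = np.empty(n)
    ssc = np.empty(n)
    sscw = np.empty(n)
    barcode = np.empty(n)
    reporter = np.empty(n)
    viability = np.empty(n)
    is_dead = np.zeros(n, dtype=bool)
    is_reporter_pos = np.zeros(n, dtype=bool)

    height_noise_sd = 0.02  # relative FSC-H noise around proportionality

    for pop, mask_pop in ((pop1, pop_is_1), (pop2, ~pop_is_1)):
        frac_pos = float(fractions.get(pop.name, 0.0))
        for is_dbl in (False, True):
            mask = mask_pop & (is_doublet if is_dbl else is_cell)
            m = int(mask.sum())
            if m == 0:
                continue
            sc = rng.multivariate_normal(pop.scatter_mean, np.asarray(pop.scatter_cov), size=m)
            a = np.clip(sc[:, 0], 1.0, None)
            s = np.clip(sc[:, 1], 1.0, None)
            h = a * rng.normal(1.0, height_noise_sd, size=m)
            bc = rng.lognormal(pop.barcode_logmean, pop.barcode_logsd, size=m)
            pos = rng.random(m) < frac_pos
            rep = np.where(
                pos,
                rng.lognormal(pop.background_logmean + logshift, pop.background_logsd, size=m),
                rng.lognormal(pop.background_logmean, pop.background_logsd, size=m),
            )
            dead = rng.random(m) < pop.viability_positive_fraction
            via = np.where(
                dead,
                rng.lognormal(np.log(5_000.0), 0.3, size=m),
                rng.lognormal(np.log(50.0), 0.4, size=m),
            )
            if is_dbl:
                # two cells in one event: doubled area signals, sub-proportional
                # height, widened pulse
                a = 2.0 * a
                h = 1.2 * h
                s = 2.0 * s
                bc = 2.0 * bc
                rep = 2.0 * rep
                w = rng.normal(95.0, 6.0, size=m)
                dead = np.zeros(m, dtype=bool)  # doublets counted as their own category
            else:
                w = rng.normal(60.0, 4.0, size=m)
            fsc[mask] = a
            fsch[mask] = h
            ssc[mask] = s
            sscw[mask] = np.clip(w, 1.0, None)
            barcode[mask] = bc
            reporter[mask] = rep
            viability[mask] = via
            is_dead[mask] = dead
            is_reporter_pos[mask] = pos

    m = int(is_debris.sum())
    if m:
        fsc[is_debris] = rng.lognormal(np.log(6_000.0), 0.45, size=m)
        fsch[is_debris] = fsc[is_debris] * rng.normal(1.0, 0.08, size=m)
        ssc[is_debris] = rng.lognormal(np.log(3_000.0), 0.5, size=m)
        sscw[is_debris] = np.clip(rng.normal(55.0, 8.0, size=m), 1.0, None)
        # debris autofluorescence: dim on all dye channels
        barcode[is_debris] = rng.lognormal(np.log(80.0), 0.5, size=m)
        reporter[is_debris] = rng.lognormal(np.log(60.0), 0.5, size=m)
        viability[is_debris] = rng.lognormal(np.log(40.0), 0.5, size=m)

    data = pd.DataFrame(
        np.column_stack([fsc, fsch, ssc, sscw, barcode, reporter, viability]).astype(np.float32),
        columns=SIM_CHANNELS,
    )
    pop1_label = is_cell & pop_is_1 & ~is_dead
    pop2_label = is_cell & ~pop_is_1 & ~is_dead
    labels = pd.DataFrame(
        {
            "truth_debris": is_debris,
            "truth_doublet": is_doublet,
            "truth_dead": is_cell & is_dead,
            "truth_clean": is_cell & ~is_dead,
            f"truth_pop_{pop1.name}": is_cell & pop_is_1,
            f"truth_pop_{pop2.name}": is_cell & ~pop_is_1,
            "truth_reporter_positive": is_reporter_pos,
        }
    )
    events = EventTable(data, SIM_CHANNEL_MAP, labels)

    per_pop = {}
    for pop, clean_mask in ((pop1, pop1_label), (pop2, pop2_label)):
        per_pop[pop.name] = {
            "n_clean": int(clean_mask.sum()),
            "positive_fraction": float(fractions.get(pop.name, 0.0)),
            "n_positive": int((clean_mask & is_reporter_pos).sum()),
            "background_logmean": pop.background_logmean,
            "background_logsd": pop.background_logsd,
            "positive_logshift": float(logshift),
        }
    truth = WellTruth(
        donor=str(donor),
        plate=str(plate),
        well=str(well),
        reagent_name=str(name),
        reagent_class=str(reagent_class),
        seed=int(seed),
        n_events=n,
        n_debris=int(is_debris.sum()),
        n_doublet=int(is_doublet.sum()),
        n_dead=int((is_cell & is_dead).sum()),
        n_clean=int((is_cell & ~is_dead).sum()),
        per_population=per_pop,
    )
    return events, truth


def iter_screen(config: PlateSimConfig) -> Iterator[tuple[str, str, str, EventTable, WellTruth]]:
    """Lazily yield ``(donor, plate, well, events, truth)`` for the whole
    screen; per-donor marker fractions are logit-normal around the planted
    values and shared across that donor's wells."""
    if config.n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    active = config.layout.entries[config.layout.entries["reagent_class"] != "empty"]
    for d in range(config.n_donors):
        donor = f"D{d + 1}"
        overrides = _donor_fractions(config, d)
        for p_idx, plate in enumerate(config.layout.plates):
            plate_wells = active[active["plate"] == plate]
            for w_idx, (_, row) in enumerate(plate_wells.iterrows()):
                seed = _well_seed(config.seed, d, p_idx, w_idx)
                events, truth = simulate_well(
                    config, row["well"], donor=donor, seed=seed, plate=plate,
                    fraction_overrides=overrides,
                )
                yield donor, plate, row["well"], events, truth


def _new_truth(config: PlateSimConfig) -> SimulationTruth:
    return SimulationTruth(
        seed=config.seed,
        pooling_ratio=config.pooling_ratio,
        events_per_well=config.events_per_well,
        debris_fraction=config.debris_fraction,
        doublet_fraction=config.doublet_fraction,
        donor_fractions={f"D{d + 1}": _donor_fractions(config, d) for d in range(config.n_donors)},
    )


def simulate_screen(config: PlateSimConfig) -> tuple[dict, SimulationTruth]:
    """Materialize the whole screen in memory: ``{(donor, plate, well): EventTable}``
    plus the complete truth manifest.  Use :func:`iter_screen` for large runs."""
    truth = _new_truth(config)
    tables = {}
    for donor, plate, well, events, wt in iter_screen(config):
        tables[(donor, plate, well)] = events
        truth.add(wt)
    return tables, truth


def simulate_screen_to_dir(config: PlateSimConfig, out_dir: str | Path) -> tuple[SampleManifest, SimulationTruth]:
    """Write one FCS 3.1 file per (donor, well), a TSV sample manifest and a
    JSON truth manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _new_truth(config)
    records = []
    for donor, plate, well, events, wt in iter_screen(config):
        fname = f"{donor}_{plate}_{well}.fcs"
        write_fcs(out / fname, events)
        truth.add(wt)
        records.append((fname, donor, "pooled", plate, well))
    manifest = SampleManifest(
        pd.DataFrame(records, columns=["file", "donor", "condition", "plate", "well"])
    )
    write_manifest(manifest, out / "manifest.tsv")
    truth.to_json(out / "truth.json")
    return manifest, truth


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def config_from_yaml(path: str | Path) -> PlateSimConfig:
    """Build a :class:`PlateSimConfig` from a YAML file.

    Any key left out falls back to the default screen conditions; ``layout``
    may name a TSV file or be omitted for the packaged four-plate default.
    """
    from .io import read_panel_layout

    raw = yaml.safe_load(Path(path).read_text()) or {}
    layout = read_panel_layout(raw["layout"]) if "layout" in raw else default_panel_layout()
    if "populations" in raw:
        pops = tuple(PopulationModel(**p) for p in raw["populations"])
    else:
        pops = default_populations(background_ratio=float(raw.get("background_ratio", 13.0)))
    if "markers" in raw:
        markers = [MarkerTruth(**m) for m in raw["markers"]]
    else:
        markers = default_screen_truth(donor_logit_sd=float(raw.get("donor_logit_sd", 0.15)))
    return PlateSimConfig(
        layout=layout,
        populations=pops,
        markers=markers,
        pooling_ratio=float(raw.get("pooling_ratio", 1.0)),
        events_per_well=int(raw.get("events_per_well", 50_000)),
        debris_fraction=float(raw.get("debris_fraction", 0.05)),
        doublet_fraction=float(raw.get("doublet_fraction", 0.04)),
        n_donors=int(raw.get("n_donors", 3)),
        seed=int(raw.get("seed", 0)),
    )
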