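"""Shared fixtures: small single-plate simulation configs for fast tests."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from lyoscreen import (
    MarkerTruth,
    PanelLayout,
    PlateSimConfig,
    POP_POS,
    POP_NEG,
    default_populations,
)


def make_mini_layout(marker_names: list[str]) -> PanelLayout:
    """One plate, one isotype well (H12), markers from A1 onward."""
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    rows = [("P1", wells[i], name, "marker", "IgG1") for i, name in enumerate(marker_names)]
    rows.append(("P1", "H12", "Isotype-IgG1", "isotype", "IgG1"))
    return PanelLayout(pd.DataFrame(rows, columns=["plate", "well", "reagent_name",
                                                   "reagent_class", "isotype_group"]))


def make_mini_config(
    marker_fractions: dict[str, tuple[float, float]],
    events: int = 20_000,
    seed: int = 0,
    populations=None,
    debris: float = 0.05,
    doublet: float = 0.04,
    dead: float = 0.05,
    n_donors: int = 1,
    donor_logit_sd: float = 0.0,
    positive_logshift: float = 3.0,
    pooling_ratio: float = 1.0,
) -> PlateSimConfig:
    """Small screen config: fractions are (barcode-positive, barcode-negative)."""
    if populations is None:
        populations = default_populations()
    populations = tuple(
        dataclasses.replace(p, viability_positive_fraction=dead) for p in populations
    )
    markers = [
        MarkerTruth(name, {POP_POS: f1, POP_NEG: f2}, positive_logshift=positive_logshift,
                    donor_logit_sd=donor_logit_sd)
        for name, (f1, f2) in marker_fractions.items()
    ]
    return PlateSimConfig(
        layout=make_mini_layout(list(marker_fractions)),
        populations=populations,
        markers=markers,
        pooling_ratio=pooling_ratio,
        events_per_well=events,
        debris_fraction=debris,
        doublet_fraction=doublet,
        n_donors=n_donors,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_well():
    """One pooled 50k-event well with zero contamination (1:1, well separated)."""
    from lyoscreen import simulate_well

    cfg = make_mini_config({"M1": (0.4, 0.1)}, events=50_000, seed=7,
                           debris=0.0, doublet=0.0, dead=0.0)
    events, truth = simulate_well(cfg, "A1", seed=7)
    return cfg, events, truth


@pytest.fixture(scope="session")
def contaminated_well():
    """One pooled 50k-event well with planted 5% debris / 4% doublets / 5% dead."""
    from lyoscreen import simulate_well

    cfg = make_mini_config({"M1": (0.4, 0.1)}, events=50_000, seed=11)
    events, truth = simulate_well(cfg, "A1", seed=11)
    return cfg, events, truth
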