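"""Input/output layer: FCS event files, panel layouts, manifests, result tables.

Events travel through the pipeline as :class:`EventTable` objects — a thin wrapper
around a :class:`pandas.DataFrame` of per-event channel values plus optional
per-event boolean labels (gate decisions, simulation truth).  Channel *roles*
(scatter-area, barcode, reporter, ...) are bound to physical ``$PnN`` detector
names through :class:`ChannelMap`, because instrument naming differs between
cytometers.

FCS support is deliberately minimal and self-contained: list-mode files are
written as FCS 3.1 with 32-bit floats, and the reader tolerates FCS 2.0/3.0/3.1
with float, double or integer data (integer channels are scaled per ``$PnE``).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMap",
    "EventTable",
    "PanelLayout",
    "SampleManifest",
    "FCSFormatError",
    "ChannelMappingError",
    "LayoutError",
    "read_fcs",
    "write_fcs",
    "read_panel_layout",
    "write_panel_layout",
    "default_panel_layout",
    "read_manifest",
    "write_manifest",
    "write_results",
    "read_results",
]

# population labels used throughout: barcode-positive cells are the dye-labelled
# population (PLT-expanded in the study design), barcode-negative the unlabelled.
POP_POS = "PLT"
POP_NEG = "FCS"
POPULATIONS = (POP_POS, POP_NEG)

REAGENT_CLASSES = ("marker", "isotype", "unstained", "empty")


class FCSFormatError(ValueError):
    """Raised when an FCS file cannot be parsed."""


class ChannelMappingError(KeyError):
    """Raised when a requested channel role is unbound or absent from the data."""


class LayoutError(ValueError):
    """Raised when a panel layout fails validation."""


# ---------------------------------------------------------------------------
# channel mapping and event container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMap:
    """Binds logical channel roles to physical ``$PnN`` detector names.

    ``viability`` is ``None`` by default: the plate-screening protocol carries
    no viability dye, and the live-cell stage is skipped when unbound.
    """

    scatter_area: str = "FSC-A"
    scatter_height: str = "FSC-H"
    ssc_area: str = "SSC-A"
    ssc_width: str = "SSC-W"
    barcode: str = "VioBlue-A"
    reporter: str = "APC-A"
    viability: str | None = None

    def name(self, role: str) -> str:
        try:
            physical = getattr(self, role)
        except AttributeError:
            raise ChannelMappingError(f"unknown channel role {role!r}") from None
        if physical is None:
            raise ChannelMappingError(f"channel role {role!r} is unbound")
        return physical

    @classmethod
    def validation(cls) -> "ChannelMap":
        """Binding for the multiparameter validation protocol (DAPI dead-cell dye)."""
        return cls(viability="DAPI-A")


class EventTable:
    """One well's compensated list-mode events.

    Parameters
    ----------
    data:
        float frame, one column per detector channel, one row per event.
    channels:
        role → detector-name binding used for role-based access.
    labels:
        optional boolean frame aligned with ``data`` (gate labels, planted truth).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        channels: ChannelMap | None = None,
        labels: pd.DataFrame | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.channels = channels or ChannelMap()
        if labels is not None:
            if len(labels) != len(data):
                raise ValueError("labels must align with data rows")
            labels = labels.reset_index(drop=True)
        self.labels = labels

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channel_names(self) -> list[str]:
        return list(self.data.columns)

    def channel(self, role: str) -> np.ndarray:
        """Values of the channel bound to ``role`` (raises if unbound/absent)."""
        name = self.channels.name(role)
        if name not in self.data.columns:
            raise ChannelMappingError(
                f"channel {name!r} (role {role!r}) absent; file has {list(self.data.columns)}"
            )
        return self.data[name].to_numpy()

    def has_channel(self, role: str) -> bool:
        try:
            self.channel(role)
            return True
        except ChannelMappingError:
            return False

    def label(self, name: str) -> np.ndarray:
        if self.labels is None or name not in self.labels.columns:
            raise KeyError(f"no label {name!r}")
        return self.labels[name].to_numpy()

    def subset(self, mask: np.ndarray) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        labels = self.labels.loc[mask] if self.labels is not None else None
        return EventTable(self.data.loc[mask], self.channels, labels)

    def with_channels(self, channels: ChannelMap) -> "EventTable":
        return EventTable(self.data, channels, self.labels)


# ---------------------------------------------------------------------------
# FCS writing (3.1, float32, list mode)
# ---------------------------------------------------------------------------

_DELIM = "/"


def _text_segment(pairs: Mapping[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in pairs.items():
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(path: str | Path, events: EventTable, extra_keywords: Mapping[str, str] | None = None) -> None:
    """Write ``events`` as an FCS 3.1 list-mode file with 32-bit float data.

    Channel names go to ``$PnN``; boolean label columns are *not* written (they
    are analysis artifacts, not detector channels).
    """
    data = events.data.to_numpy(dtype="<f4")
    n_events, n_par = data.shape
    if n_par == 0:
        raise ValueError("cannot write an FCS file with zero channels")

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(events.channel_names, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        col = data[:, i - 1]
        top = float(col.max(initial=0.0))
        keywords[f"$P{i}R"] = str(int(max(1.0, np.ceil(top + 1))))
    if extra_keywords:
        for k, v in extra_keywords.items():
            keywords[str(k)] = str(v)

    # offsets depend on TEXT length, which depends on the offsets; fixed-width
    # zero-padded offset fields make the computation a single pass
    data_bytes = data.tobytes()
    width = 12
    placeholder = "0" * width
    keywords_off = {"$BEGINDATA": placeholder, "$ENDDATA": placeholder, **keywords}
    text = _text_segment(keywords_off)
    text_begin = 58  # header: 6 version + 4 spaces + 6 offset fields of 8 chars
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1
    keywords_off["$BEGINDATA"] = str(data_begin).rjust(width, "0")
    keywords_off["$ENDDATA"] = str(data_end).rjust(width, "0")
    text = _text_segment(keywords_off)

    def _hfield(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # exceeds header field: rely on $BEGINDATA/$ENDDATA
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _hfield(text_begin) + _hfield(text_end)
    header += _hfield(data_begin if data_end <= 99_999_999 else 0)
    header += _hfield(data_end if data_end <= 99_999_999 else 0)
    header += _hfield(0) + _hfield(0)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


# ---------------------------------------------------------------------------
# FCS reading (2.0 / 3.0 / 3.1)
# ---------------------------------------------------------------------------

def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # split on the delimiter; doubled delimiters (escapes) are rare and not
    # produced by the instruments this pipeline targets
    tokens = body.split(delim)[1:]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2 != 0:
        tokens = tokens[:-1]
    return {tokens[i].strip().upper(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | Path, channels: ChannelMap | None = None) -> EventTable:
    """Parse an FCS 2.0/3.0/3.1 list-mode file into an :class:`EventTable`.

    Values are returned on the stored linear scale: float data as-is, integer
    data de-logged per ``$PnE`` when a log amplifier gain is declared.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FCSFormatError(f"{path}: truncated header")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSFormatError(f"{path}: not an FCS file (version field {version!r})")

    def _off(lo: int, hi: int) -> int:
        fieldv = blob[lo:hi].decode("latin-1").strip()
        return int(fieldv) if fieldv else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    if text_begin <= 0 or text_end < text_begin:
        raise FCSFormatError(f"{path}: corrupt header offsets")
    kw = _parse_text(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FCSFormatError(f"{path}: no data segment offsets")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from None
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise FCSFormatError(f"{path}: only list mode is supported")

    endian = "<" if byteord.startswith("1") else ">"
    names = [kw.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    raw = blob[data_begin : data_end + 1]

    if datatype in ("F", "D"):
        itemsize = 4 if datatype == "F" else 8
        if any(b != itemsize * 8 for b in bits):
            raise FCSFormatError(f"{path}: $PnB inconsistent with $DATATYPE {datatype}")
        arr = np.frombuffer(raw[: n_tot * n_par * itemsize], dtype=f"{endian}f{itemsize}")
        matrix = arr.reshape(n_tot, n_par).astype(float)
    elif datatype == "I":
        if len(set(bits)) == 1 and bits[0] in (8, 16, 32, 64):
            itemsize = bits[0] // 8
            arr = np.frombuffer(raw[: n_tot * n_par * itemsize], dtype=f"{endian}u{itemsize}")
            matrix = arr.reshape(n_tot, n_par).astype(float)
        else:  # mixed widths: slow per-column unpack
            matrix = np.empty((n_tot, n_par), dtype=float)
            offs = np.cumsum([0] + [b // 8 for b in bits])
            stride = offs[-1]
            for j, b in enumerate(bits):
                itemsize = b // 8
                col = np.empty(n_tot, dtype=float)
                for i in range(n_tot):
                    start = i * stride + offs[j]
                    col[i] = int.from_bytes(
                        raw[start : start + itemsize],
                        "little" if endian == "<" else "big",
                    )
                matrix[:, j] = col
        # integer data may be log-amplified: $PnE = "f1,f2" with f1 > 0 means
        # value = f2 * 10^(f1 * x / $PnR)   (f2 == 0 is read as 1 per convention)
        for j in range(n_par):
            pne = kw.get(f"$P{j + 1}E", "0,0")
            try:
                f1, f2 = (float(v) for v in pne.split(","))
            except ValueError:
                f1 = f2 = 0.0
            if f1 > 0:
                pnr = float(kw.get(f"$P{j + 1}R", "1024"))
                f2 = f2 if f2 > 0 else 1.0
                matrix[:, j] = f2 * 10 ** (f1 * matrix[:, j] / pnr)
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    frame = pd.DataFrame(matrix, columns=names)
    return EventTable(frame, channels or ChannelMap())


# ---------------------------------------------------------------------------
# panel layout
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = ["plate", "well", "reagent_name", "reagent_class", "isotype_group"]

_VALID_WELLS = {f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)}


@dataclass
class PanelLayout:
    """Plate/well → reagent assignment for the antibody-panel plates."""

    entries: pd.DataFrame  # columns: plate, well, reagent_name, reagent_class, isotype_group

    def __post_init__(self):
        self.entries = self.entries.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.entries
        missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise LayoutError(f"layout missing columns: {missing}")
        bad_wells = sorted(set(df["well"].astype(str)) - _VALID_WELLS)
        if bad_wells:
            raise LayoutError(f"invalid 96-well coordinates: {bad_wells[:5]}")
        dupes = df.duplicated(subset=["plate", "well"])
        if dupes.any():
            where = df.loc[dupes, ["plate", "well"]].iloc[0].tolist()
            raise LayoutError(f"duplicate well assignment at {tuple(where)}")
        bad_class = sorted(set(df["reagent_class"]) - set(REAGENT_CLASSES))
        if bad_class:
            raise LayoutError(f"unknown reagent classes: {bad_class}")
        # each marker well's isotype_group must resolve to exactly one isotype
        # well on the same plate
        iso = df[df["reagent_class"] == "isotype"]
        iso_key = iso.groupby(["plate", "isotype_group"]).size()
        if (iso_key > 1).any():
            raise LayoutError("isotype_group maps to more than one isotype well on a plate")
        iso_set = set(iso_key.index)
        markers = df[df["reagent_class"] == "marker"]
        for _, row in markers.iterrows():
            if (row["plate"], row["isotype_group"]) not in iso_set:
                raise LayoutError(
                    f"marker {row['reagent_name']!r} in {row['plate']}/{row['well']} "
                    f"references isotype group {row['isotype_group']!r} absent from its plate"
                )

    def counts(self) -> dict[str, int]:
        return self.entries["reagent_class"].value_counts().to_dict()

    @property
    def plates(self) -> list[str]:
        return list(dict.fromkeys(self.entries["plate"]))

    def wells(self, plate: str) -> pd.DataFrame:
        return self.entries[self.entries["plate"] == plate]

    def entry(self, plate: str, well: str) -> pd.Series:
        sel = self.entries[(self.entries["plate"] == plate) & (self.entries["well"] == well)]
        if sel.empty:
            raise LayoutError(f"well {plate}/{well} not in layout")
        return sel.iloc[0]

    @property
    def marker_names(self) -> list[str]:
        return self.entries.loc[self.entries["reagent_class"] == "marker", "reagent_name"].tolist()


def read_panel_layout(path: str | Path) -> PanelLayout:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return PanelLayout(df)


def write_panel_layout(layout: PanelLayout, path: str | Path) -> None:
    layout.entries.to_csv(path, sep="\t", index=False)


# surface antigens with documented behaviour on cultured stromal cells; the
# remainder of the 356-plex panel is filled with systematic placeholder names
_ENRICHED_13 = [
    "CD318", "MSCA-1", "CD26", "CD54", "CD106", "CD312", "CD49d",
    "CD40", "HLA-E", "CD97", "Notch2", "MCSP", "CD31",
]
_EQUAL_HIGH_SEED = [
    "CD73", "CD90", "CD105", "CD44", "CD29", "CD166", "CD95", "CD46",
    "CD47", "CD49a", "CD9", "CD81", "CD63", "CD59", "CD13", "CD10",
    "CD140b", "CD151", "CD276", "HLA-ABC",
]
_NEGATIVE_SEED = ["CD45", "CD34", "CD3", "CD19", "CD14", "CD11b", "CD79a", "HLA-DR"]

N_PANEL_MARKERS = 356
N_ISOTYPES = 9
N_EQUAL_HIGH = 51
N_ENRICHED = 13


def default_marker_names() -> tuple[list[str], list[str], list[str]]:
    """Panel marker names grouped as (enriched, equally-high, negative).

    13 + 51 + 292 = 356 names; recognisable antigens first, systematic
    placeholders (``AGnnn``) after.
    """
    equal = list(_EQUAL_HIGH_SEED)
    i = 1
    while len(equal) < N_EQUAL_HIGH:
        equal.append(f"AG{i:03d}")
        i += 1
    n_negative = N_PANEL_MARKERS - N_ENRICHED - N_EQUAL_HIGH
    negative = list(_NEGATIVE_SEED)
    while len(negative) < n_negative:
        negative.append(f"AG{i:03d}")
        i += 1
    return list(_ENRICHED_13), equal, negative


def default_panel_layout() -> PanelLayout:
    """Four 96-well plates carrying 356 marker wells and 9 isotype wells.

    Isotype wells sit at the tail of each plate (3 on plate 1, 2 on plates
    2–4); marker wells reference their plate's isotype groups round-robin;
    the remaining 19 wells are flagged ``empty``.
    """
    enriched, equal, negative = default_marker_names()
    markers = enriched + equal + negative
    iso_per_plate = [3, 2, 2, 2]
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    rows = []
    cursor = 0
    for p, n_iso in enumerate(iso_per_plate, start=1):
        plate = f"P{p}"
        n_mark = 89
        groups = [f"IgG{g + 1}-{plate}" for g in range(n_iso)]
        for j in range(n_mark):
            rows.append((plate, wells[j], markers[cursor], "marker", groups[j % n_iso]))
            cursor += 1
        for g, group in enumerate(groups):
            rows.append((plate, wells[n_mark + g], f"Isotype-{group}", "isotype", group))
        for j in range(n_mark + n_iso, 96):
            rows.append((plate, wells[j], "", "empty", ""))
    assert cursor == N_PANEL_MARKERS
    df = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    return PanelLayout(df)


# ---------------------------------------------------------------------------
# sample manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["file", "donor", "condition", "plate", "well"]


@dataclass
class SampleManifest:
    """Maps acquired files to donor / condition / plate / well."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.records["file"].duplicated().any():
            raise ValueError("manifest file paths must be unique")
        self.records = self.records.reset_index(drop=True)


def read_manifest(path: str | Path) -> SampleManifest:
    return SampleManifest(pd.read_csv(path, sep="\t", dtype=str))


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a ScreenResult as TSV tables (percentages on the 0–100 scale).

    Emits ``pct_positive.tsv`` (marker × population × donor long table),
    ``classification.tsv`` (per-marker flags, fold changes, p-values, stain
    indices) and ``background.tsv`` (per-donor background medians and ratio).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["pct_positive"] = out / "pct_positive.tsv"
    result.pct_table.to_csv(paths["pct_positive"], sep="\t", index=False)

    paths["classification"] = out / "classification.tsv"
    result.classification.to_csv(paths["classification"], sep="\t", index=True, index_label="marker")

    paths["background"] = out / "background.tsv"
    result.background.to_csv(paths["background"], sep="\t", index=False)
    return paths


def read_results(out_dir: str | Path):
    """Re-read tables written by :func:`write_results` into a ScreenResult."""
    from .screening import ScreenResult  # local import: avoid a cycle

    out = Path(out_dir)
    pct = pd.read_csv(out / "pct_positive.tsv", sep="\t")
    cls = pd.read_csv(out / "classification.tsv", sep="\t", index_col="marker")
    if cls.empty and "marker" not in cls.index.names:
        cls.index.name = "marker"
    bg = pd.read_csv(out / "background.tsv", sep="\t")
    for col in ("positive", "variable", "enriched", "fold_floored"):
        if col in cls.columns:
            cls[col] = cls[col].astype(bool)
    return ScreenResult(pct_table=pct, classification=cls, background=bg)
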