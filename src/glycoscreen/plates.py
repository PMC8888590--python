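"""384-well plate geometry and plate-map construction.

A plate has 16 rows (A-P) and 24 columns (1-24). Wells are addressed by
letter + zero-padded column labels ("A01".."P24"); files always carry
labels, never numeric indices. The default screen layout is:

* column 24 — media-only wells used as the lactate-assay background,
* column 1 — 16 non-targeting control wells (siOTP),
* column 2, rows A-H — 8 death-control wells (siPLK1),
* column 2, rows I-P — 8 glycolysis-control wells (siPDK1),
* columns 3-23 — 336 library wells, one reagent per well.

The control columns are configurable; the screen protocol fixes only the
per-plate control counts (16/8/8) and the media column.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import PlateValidationError

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_WELLS = len(ROWS) * N_COLS

#: well content classes
LIBRARY = "library"
CONTROL_OTP = "control_OTP"
CONTROL_PLK1 = "control_PLK1"
CONTROL_PDK1 = "control_PDK1"
MEDIA_BACKGROUND = "media_background"
CONTENT_CLASSES = (LIBRARY, CONTROL_OTP, CONTROL_PLK1, CONTROL_PDK1, MEDIA_BACKGROUND)

#: expected number of wells of each non-library class on every plate
LAYOUT_COUNTS = {CONTROL_OTP: 16, CONTROL_PLK1: 8, CONTROL_PDK1: 8, MEDIA_BACKGROUND: 16}

#: number of library wells on a fully laid-out plate
LIBRARY_WELLS_PER_PLATE = N_WELLS - sum(LAYOUT_COUNTS.values())  # 336

VALID_REAGENT_IDS = ("pool", "d1", "d2", "d3", "d4")

PLATE_MAP_COLUMNS = ["plate_id", "well", "content_class", "gene_id", "reagent_id"]


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> label, e.g. (0, 0) -> 'A01'."""
    return f"{ROWS[row]}{col + 1:02d}"


def parse_well(label: str) -> tuple[int, int]:
    """Label -> 0-based (row, col); raises on anything outside A01..P24."""
    if not isinstance(label, str) or len(label) != 3:
        raise PlateValidationError(f"malformed well label {label!r}")
    row = ROWS.find(label[0])
    try:
        col = int(label[1:]) - 1
    except ValueError:
        raise PlateValidationError(f"malformed well label {label!r}") from None
    if row < 0 or not 0 <= col < N_COLS:
        raise PlateValidationError(f"well label {label!r} outside A01..P24")
    return row, col


def all_wells() -> list[str]:
    """All 384 labels in row-major order A01..A24, B01.., ..P24."""
    return [well_label(r, c) for r in range(len(ROWS)) for c in range(N_COLS)]


def sort_wells(labels: Iterable[str]) -> list[str]:
    return sorted(labels, key=parse_well)


def default_plate_map(
    plate_id: str,
    gene_ids: Sequence[str],
    reagent_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build one plate map in the default layout.

    ``gene_ids`` fills the 336 library wells in row-major order and must
    have exactly that length; ``reagent_ids`` defaults to "pool" for every
    library well (use "d1".."d4" entries for deconvolution plates).
    """
    if len(gene_ids) != LIBRARY_WELLS_PER_PLATE:
        raise PlateValidationError(
            f"default layout needs exactly {LIBRARY_WELLS_PER_PLATE} library "
            f"genes per plate, got {len(gene_ids)}"
        )
    if reagent_ids is None:
        reagent_ids = ["pool"] * len(gene_ids)
    if len(reagent_ids) != len(gene_ids):
        raise PlateValidationError("reagent_ids must align with gene_ids")

    rows = []
    lib_i = 0
    for r in range(len(ROWS)):
        for c in range(N_COLS):
            well = well_label(r, c)
            if c == N_COLS - 1:
                rows.append((plate_id, well, MEDIA_BACKGROUND, "", ""))
            elif c == 0:
                rows.append((plate_id, well, CONTROL_OTP, "", "siOTP"))
            elif c == 1:
                cls = CONTROL_PLK1 if r < 8 else CONTROL_PDK1
                rid = "siPLK1" if r < 8 else "siPDK1"
                rows.append((plate_id, well, cls, "", rid))
            else:
                rows.append((plate_id, well, LIBRARY, gene_ids[lib_i], reagent_ids[lib_i]))
                lib_i += 1
    return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def validate_plate_maps(plate_maps: pd.DataFrame) -> None:
    """Check the structural invariants of a long-format plate-map table.

    Raises :class:`PlateValidationError` on the first violation found.
    """
    missing = [c for c in PLATE_MAP_COLUMNS if c not in plate_maps.columns]
    if missing:
        raise PlateValidationError(f"plate map missing columns {missing}")
    for plate_id, pm in plate_maps.groupby("plate_id", sort=False):
        if len(pm) != N_WELLS or set(pm["well"]) != set(all_wells()):
            raise PlateValidationError(
                f"plate {plate_id} must have {N_WELLS} wells A01..P24, got {len(pm)}"
            )
        bad_cls = set(pm["content_class"]) - set(CONTENT_CLASSES)
        if bad_cls:
            raise PlateValidationError(f"plate {plate_id}: unknown content class {bad_cls}")
        col24 = pm[pm["well"].str[1:] == "24"]
        if not (col24["content_class"] == MEDIA_BACKGROUND).all():
            raise PlateValidationError(
                f"plate {plate_id}: every column-24 well must be media_background"
            )
        counts = pm["content_class"].value_counts()
        for cls, n in LAYOUT_COUNTS.items():
            if counts.get(cls, 0) != n:
                raise PlateValidationError(
                    f"plate {plate_id}: expected {n} {cls} wells, got {counts.get(cls, 0)}"
                )
        lib = pm[pm["content_class"] == LIBRARY]
        if (lib["gene_id"] == "").any():
            raise PlateValidationError(f"plate {plate_id}: library well with empty gene_id")
        bad_rid = set(lib["reagent_id"]) - set(VALID_REAGENT_IDS)
        if bad_rid:
            raise PlateValidationError(
                f"plate {plate_id}: library reagent_id must be one of "
                f"{VALID_REAGENT_IDS}, got {bad_rid}"
            )
        nonlib = pm[pm["content_class"] != LIBRARY]
        if (nonlib["gene_id"] != "").any():
            raise PlateValidationError(
                f"plate {plate_id}: gene_id must be empty outside library wells"
            )
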