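"""Facility layout and design-matrix assembly for the trial models.

The facility is a set of beds built in pairs. Within a pair the two
beds' rows form one contiguous east-west line of positions; a spatial
"field" extends that line with 5 virtual positions at each end so that
the 11-position running-sum window is defined for border rows. Where the
data span more than one pair, all pairs share the same location levels
by within-pair position (this reproduces the printed field size of 310
for 4 beds of 150 rows). Neighbors are the lines at positions +-1.

Model presets
-------------
GM1   grain: bed x area fixed cells; random g (G), l, r (rows), and one
      spatial field per harvest area with its own variance.
GM2   GM1 plus combined east+west neighbor terms g_n (G) and l_n.
RM1   per-tube root trait: bed + camera fixed; random g (G), l, spatial.
RM2   per-interval root trait: RM1 plus depth-interval fixed factor and
      a row (tube) random term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from semifield.kinship import GenomicRelationship
from semifield.reml import ModelBundle, RandomBlock

__all__ = [
    "LayoutError",
    "FacilityLayout",
    "ModelSpec",
    "MODEL_PRESETS",
    "build_layout",
    "neighbor_incidence",
    "spatial_incidence",
    "assemble_model",
    "ModelBundle",
]

N_VIRTUAL = 5
WINDOW_HALF = 5  # 11-position window: centre +- 5
AREAS = ("wet", "dry")


class LayoutError(ValueError):
    pass


@dataclass
class FacilityLayout:
    """Row table plus derived spatial-field and neighbor topology.

    ``table`` columns: bed, pair, row, position (1-based, within pair,
    contiguous across the pair's beds), line.
    """

    table: pd.DataFrame
    share_pair_levels: bool = True
    n_virtual: int = N_VIRTUAL
    segment_length: int = field(init=False)
    n_locations: int = field(init=False)
    neighbor_map: dict = field(init=False)

    def __post_init__(self):
        t = self.table
        lengths = t.groupby("pair")["position"].max()
        if self.share_pair_levels and lengths.nunique() > 1:
            raise LayoutError(
                "pairs have unequal position ranges; shared location levels need "
                "equal-length pairs (set share_pair_levels=False)"
            )
        self.segment_length = int(lengths.max())
        n_field = self.segment_length + 2 * self.n_virtual
        self.n_locations = n_field if self.share_pair_levels else n_field * lengths.size
        self._pair_offset = {p: (0 if self.share_pair_levels else i * n_field)
                             for i, p in enumerate(sorted(lengths.index))}
        by_pos = {(r.pair, r.position): r.line for r in t.itertuples()}
        nb, loc = {}, {}
        for r in t.itertuples():
            nb[(r.bed, r.row)] = (by_pos.get((r.pair, r.position - 1)),
                                  by_pos.get((r.pair, r.position + 1)))
            loc[(r.bed, r.row)] = self._pair_offset[r.pair] + self.n_virtual + r.position - 1
        self.neighbor_map = nb
        self._loc = loc

    @property
    def lines(self) -> list:
        return sorted(self.table["line"].unique())

    @property
    def row_levels(self) -> list:
        return list(zip(self.table["bed"], self.table["row"]))

    def location_of(self, bed, row) -> int:
        """0-based spatial-location column of a real row."""
        try:
            return self._loc[(bed, row)]
        except KeyError:
            raise LayoutError(f"unknown row ({bed!r}, {row!r})") from None


def build_layout(rows_table: pd.DataFrame, share_pair_levels: bool = True,
                 allow_gaps: bool = False) -> FacilityLayout:
    """Validate a row table and derive pair/position columns if absent.

    ``rows_table`` needs columns bed, row, line; ``pair`` defaults to
    consecutive sorted beds taken two at a time, and ``position`` to the
    within-pair running index ordered by (bed, row).
    """
    t = rows_table.copy()
    required = {"bed", "row", "line"}
    if missing := required - set(t.columns):
        raise LayoutError(f"layout table missing columns {sorted(missing)}")
    if t.duplicated(["bed", "row"]).any():
        dup = t[t.duplicated(["bed", "row"])].iloc[0]
        raise LayoutError(f"duplicate (bed, row) = ({dup['bed']!r}, {dup['row']!r})")
    if "pair" not in t.columns:
        beds = sorted(t["bed"].unique())
        pair_of = {b: i // 2 + 1 for i, b in enumerate(beds)}
        t["pair"] = t["bed"].map(pair_of)
    if "position" not in t.columns:
        t = t.sort_values(["pair", "bed", "row"], kind="stable")
        t["position"] = t.groupby("pair").cumcount() + 1
    for p, grp in t.groupby("pair"):
        pos = np.sort(grp["position"].to_numpy())
        if pos[0] != 1 or (not allow_gaps and np.any(np.diff(pos) != 1)):
            raise LayoutError(f"pair {p!r}: positions must be consecutive from 1 "
                              "(pass allow_gaps=True to accept declared gaps)")
        if len(np.unique(pos)) != len(pos):
            raise LayoutError(f"pair {p!r}: duplicate positions")
    return FacilityLayout(t.reset_index(drop=True), share_pair_levels=share_pair_levels)


def _line_index(line_ids) -> dict:
    return {lin: j for j, lin in enumerate(line_ids)}


def line_incidence(records: pd.DataFrame, line_ids) -> np.ndarray:
    idx = _line_index(line_ids)
    Z = np.zeros((len(records), len(line_ids)))
    for i, lin in enumerate(records["line"]):
        try:
            Z[i, idx[lin]] = 1.0
        except KeyError:
            raise LayoutError(f"record line {lin!r} absent from the line set") from None
    return Z


def neighbor_incidence(layout: FacilityLayout, records: pd.DataFrame, line_ids) -> np.ndarray:
    """Summed east+west neighbor incidence: entries count neighbors per line.

    Row sums are 2 for interior rows, 1 at field borders, 0 for rows with
    no neighbors. A neighbor line outside ``line_ids`` raises.
    """
    idx = _line_index(line_ids)
    Z = np.zeros((len(records), len(line_ids)))
    for i, (bed, row) in enumerate(zip(records["bed"], records["row"])):
        try:
            west, east = layout.neighbor_map[(bed, row)]
        except KeyError:
            raise LayoutError(f"record references unknown row ({bed!r}, {row!r})") from None
        for nb in (west, east):
            if nb is not None:
                Z[i, idx[nb]] += 1.0
    return Z


def spatial_incidence(layout: FacilityLayout, records: pd.DataFrame,
                      area: str | None = None) -> np.ndarray:
    """Running-sum incidence: 11 ones per record at window offsets -5..+5.

    For grain models each harvest area has its own field; records from
    the other area get an all-zero row (so the matrix conforms with the
    full record set while only area records load on the field).
    """
    n_loc = layout.n_locations
    Z = np.zeros((len(records), n_loc))
    if area is not None and "area" not in records.columns:
        raise LayoutError("records have no 'area' column for an area-specific field")
    for i, rec in enumerate(records.itertuples()):
        if area is not None and rec.area != area:
            continue
        c = layout.location_of(rec.bed, rec.row)
        lo, hi = c - WINDOW_HALF, c + WINDOW_HALF
        if lo < 0 or hi >= n_loc:
            raise LayoutError(f"window around ({rec.bed!r}, {rec.row!r}) leaves the field")
        Z[i, lo: hi + 1] = 1.0
    return Z


@dataclass(frozen=True)
class ModelSpec:
    """Named preset: trait kind, fixed factors and random terms.

    Random terms are (label, structure, builder) with structure 'G' or
    'I' and builder in {line, neighbor, row, spatial, spatial:wet,
    spatial:dry}.
    """

    name: str
    kind: str  # 'grain' | 'root'
    fixed: tuple
    random: tuple


MODEL_PRESETS = {
    "GM1": ModelSpec("GM1", "grain", ("bed_area",),
                     (("g", "G", "line"), ("l", "I", "line"), ("r", "I", "row"),
                      ("s1", "I", "spatial:wet"), ("s2", "I", "spatial:dry"))),
    "GM2": ModelSpec("GM2", "grain", ("bed_area",),
                     (("g", "G", "line"), ("l", "I", "line"),
                      ("g_n", "G", "neighbor"), ("l_n", "I", "neighbor"),
                      ("r", "I", "row"),
                      ("s1", "I", "spatial:wet"), ("s2", "I", "spatial:dry"))),
    "RM1": ModelSpec("RM1", "root", ("bed", "camera"),
                     (("g", "G", "line"), ("l", "I", "line"), ("s", "I", "spatial"))),
    "RM2": ModelSpec("RM2", "root", ("bed", "camera", "interval"),
                     (("g", "G", "line"), ("l", "I", "line"), ("r", "I", "row"),
                      ("s", "I", "spatial"))),
}


def _fixed_design(spec: ModelSpec, records: pd.DataFrame):
    """Cell means for the leading factor, drop-first contrasts after."""
    cols, names = [], []
    first = True
    for factor in spec.fixed:
        if factor == "bed_area":
            levels = sorted(set(zip(records["bed"], records["area"])))
            codes = list(zip(records["bed"], records["area"]))
        else:
            if factor not in records.columns:
                raise LayoutError(f"records lack fixed factor column {factor!r}")
            levels = sorted(records[factor].unique())
            codes = list(records[factor])
        use = levels if first else levels[1:]
        for lev in use:
            cols.append(np.array([1.0 if c == lev else 0.0 for c in codes]))
            names.append(f"{factor}={lev}")
        first = False
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise LayoutError(f"fixed design rank deficient; aliased factor among {spec.fixed}")
    return X, names


def assemble_model(spec: ModelSpec | str, records: pd.DataFrame, layout: FacilityLayout,
                   G: GenomicRelationship, trait: str | None = None) -> ModelBundle:
    """Build the ModelBundle (y, X, random blocks) for one model preset.

    ``records`` must carry the response in column ``trait`` (or 'value');
    rows with a missing response are dropped. Every record line must be
    in ``G``; G-structured BLUPs cover all of G's lines regardless of
    which have records.
    """
    if isinstance(spec, str):
        spec = MODEL_PRESETS[spec]
    col = trait or "value"
    if col not in records.columns:
        raise LayoutError(f"records lack response column {col!r}")
    rec = records.loc[records[col].notna()].reset_index(drop=True)
    y = rec[col].to_numpy(dtype=float)
    missing = set(rec["line"]) - set(G.line_ids)
    if missing:
        raise LayoutError(f"record lines absent from G: {sorted(missing)[:5]}")
    X, x_names = _fixed_design(spec, rec)

    Z_line = None
    blocks = []
    for label, structure, builder in spec.random:
        if builder == "line":
            if Z_line is None:
                Z_line = line_incidence(rec, G.line_ids)
            Z, levels = Z_line, list(G.line_ids)
        elif builder == "neighbor":
            Z, levels = neighbor_incidence(layout, rec, G.line_ids), list(G.line_ids)
        elif builder == "row":
            if spec.kind == "grain":
                levels = layout.row_levels  # all facility rows
            else:
                levels = sorted(set(zip(rec["bed"], rec["row"])))  # tubes present
            lev_idx = {lv: j for j, lv in enumerate(levels)}
            Z = np.zeros((len(rec), len(levels)))
            for i, key in enumerate(zip(rec["bed"], rec["row"])):
                Z[i, lev_idx[key]] = 1.0
        elif builder.startswith("spatial"):
            area = builder.split(":")[1] if ":" in builder else None
            Z = spatial_incidence(layout, rec, area=area)
            levels = [f"loc{j + 1}" + (f":{area}" if area else "") for j in range(Z.shape[1])]
        else:
            raise LayoutError(f"unknown incidence builder {builder!r}")
        K = G.G if structure == "G" else None
        blocks.append(RandomBlock(label, Z, K, levels))

    meta_cols = [c for c in ("bed", "row", "area", "line", "camera", "interval") if c in rec.columns]
    bundle = ModelBundle(y, X, blocks, rec[meta_cols].copy())
    bundle.x_names = x_names
    bundle.spec = spec
    return bundle
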