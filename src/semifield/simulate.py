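"""Synthetic marker panels, layouts and trait records.

Generation follows the fitted models as generative laws: line effects g
are multivariate normal with covariance G*s2_g (G from the simulated
markers), all other random terms are i.i.d. normal, spatial fields are
i.i.d. per location (virtual locations included — they enter the
windows of border rows), and each record is the sum of its fixed cell,
line, neighbor, row, 11-location spatial window and residual draws.
Neighbor effects use one shared effect vector for east and west sides.

Everything is driven by a single ``numpy`` Generator seeded from the
config, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from semifield.design import FacilityLayout, build_layout, line_incidence, neighbor_incidence, spatial_incidence
from semifield.kinship import MarkerMatrix, vanraden_g

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_markers",
    "simulate_layout",
    "simulate_trait",
]

DEFAULT_VARIANCES = {
    "g": 1.0, "l": 1.0, "g_n": 0.0, "l_n": 0.0,
    "r": 0.5, "s1": 0.1, "s2": 0.2, "s": 0.2, "e": 1.0,
}


@dataclass
class SimulationConfig:
    """Generator settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_lines: int = 84
    n_markers: int = 1000
    maf_range: tuple = (0.05, 0.5)
    beds: int = 4
    rows_per_bed: int = 150
    trait_kind: str = "grain"          # 'grain' | 'root'
    n_intervals: int = 1               # >1 => repeated per-interval root records
    n_families: int = 0                # 0 = unrelated lines
    fst: float = 0.3
    variances: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    fixed_effects: dict | None = None  # cell -> value; generated if None
    interaction_variance: float = 0.0  # optional line-x-area variance, power studies only

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        v = dict(DEFAULT_VARIANCES)
        v.update(self.variances)
        if any(x < 0 for x in v.values()):
            raise ValueError("variances must be non-negative")
        self.variances = v
        if self.n_lines > self.beds * self.rows_per_bed:
            raise ValueError("more lines than rows available")


@dataclass
class SimulatedDataset:
    markers: MarkerMatrix
    layout: FacilityLayout
    records: pd.DataFrame
    truth: dict
    config: SimulationConfig


def simulate_markers(n_lines: int, n_markers: int, maf_range=(0.05, 0.5),
                     seed=None, rng=None, n_families: int = 0,
                     fst: float = 0.3) -> MarkerMatrix:
    """Binomial(2, p) dosages with p uniform on ``maf_range`` per marker.

    With ``n_families > 0`` lines are grouped into families whose
    family-specific frequencies follow a Balding-Nichols model with
    differentiation ``fst``, producing related lines (non-trivial G
    off-diagonals) as in a breeding panel; default is unrelated lines.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    p = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
    if n_families and n_families > 0:
        a = p * (1.0 - fst) / fst
        b = (1.0 - p) * (1.0 - fst) / fst
        fam_of = np.arange(n_lines) % n_families
        q = rng.beta(a, b, size=(n_families, n_markers))
        dos = rng.binomial(2, q[fam_of, :]).astype(float)
    else:
        dos = rng.binomial(2, p, size=(n_lines, n_markers)).astype(float)
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    markers = [f"M{j + 1:05d}" for j in range(n_markers)]
    return MarkerMatrix(lines, dos, markers)


def simulate_layout(config: SimulationConfig, rng=None) -> FacilityLayout:
    """Assign lines to rows: each line once per bed, remainder at random.

    No anti-neighbor constraint is enforced (matching the facility's
    imperfect randomization).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lines = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    if config.rows_per_bed < config.n_lines:
        raise ValueError("replication policy infeasible: rows_per_bed < n_lines")
    rows = []
    for b in range(1, config.beds + 1):
        extra = config.rows_per_bed - config.n_lines
        assignment = list(lines) + list(rng.choice(lines, size=extra, replace=True))
        rng.shuffle(assignment)
        for w, lin in enumerate(assignment, start=1):
            rows.append({"bed": b, "row": w, "line": lin})
    return build_layout(pd.DataFrame(rows))


def _sample_line_effects(rng, G, s2):
    if s2 == 0:
        return np.zeros(G.shape[0])
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    return V @ (np.sqrt(w * s2) * rng.standard_normal(G.shape[0]))


def simulate_trait(config: SimulationConfig, markers: MarkerMatrix | None = None,
                   layout: FacilityLayout | None = None) -> SimulatedDataset:
    """Draw a full dataset under the generative model of the presets.

    Grain kind: one wet and one dry record per row with bed-x-area fixed
    cells and per-area spatial fields. Root kind: per-tube records (one
    per depth interval when ``n_intervals > 1``) with bed/camera (and
    interval) fixed effects and a single spatial field; the camera cycles
    with the row position as the four-camera trolley does.
    """
    rng = np.random.default_rng(config.seed)
    if markers is None:
        markers = simulate_markers(config.n_lines, config.n_markers,
                                   config.maf_range, rng=rng,
                                   n_families=config.n_families, fst=config.fst)
    if layout is None:
        layout = simulate_layout(config, rng=rng)
    v = config.variances
    G = vanraden_g(markers).G
    lines = markers.line_ids
    g = _sample_line_effects(rng, G, v["g"])
    l = rng.normal(0, np.sqrt(v["l"]), size=len(lines)) if v["l"] else np.zeros(len(lines))
    g_n = _sample_line_effects(rng, G, v["g_n"])
    l_n = rng.normal(0, np.sqrt(v["l_n"]), size=len(lines)) if v["l_n"] else np.zeros(len(lines))

    t = layout.table
    row_levels = list(zip(t["bed"], t["row"]))
    r_eff = rng.normal(0, np.sqrt(v["r"]), size=len(row_levels)) if v["r"] else np.zeros(len(row_levels))
    r_idx = {k: i for i, k in enumerate(row_levels)}
    n_loc = layout.n_locations

    if config.trait_kind == "grain":
        areas = ("wet", "dry")
        fields = {a: rng.normal(0, np.sqrt(v[tag]), size=n_loc) if v[tag] else np.zeros(n_loc)
                  for a, tag in zip(areas, ("s1", "s2"))}
        if config.fixed_effects is None:
            fixed = {(b, a): 10.0 + 0.5 * b + (1.5 if a == "dry" else 0.0)
                     for b in sorted(t["bed"].unique()) for a in areas}
        else:
            fixed = config.fixed_effects
        rows = [{"bed": rec.bed, "row": rec.row, "area": a, "line": rec.line}
                for rec in t.itertuples() for a in areas]
        records = pd.DataFrame(rows)
        mu = np.array([fixed[(b, a)] for b, a in zip(records["bed"], records["area"])])
        s_part = np.zeros(len(records))
        for a in areas:
            Zs = spatial_incidence(layout, records, area=a)
            s_part += Zs @ fields[a]
        truth_fields = fields
    else:
        intervals = list(range(1, config.n_intervals + 1))
        field_s = rng.normal(0, np.sqrt(v["s"]), size=n_loc) if v["s"] else np.zeros(n_loc)
        camera_of = {(rec.bed, rec.row): (rec.position - 1) % 4 + 1 for rec in t.itertuples()}
        if config.fixed_effects is None:
            beds = sorted(t["bed"].unique())
            fixed = {"bed": {b: 50.0 + 5.0 * i for i, b in enumerate(beds)},
                     "camera": {c: 2.0 * (c - 1) for c in range(1, 5)},
                     "interval": {k: -3.0 * (k - 1) for k in intervals}}
        else:
            fixed = config.fixed_effects
        rows = [{"bed": rec.bed, "row": rec.row, "line": rec.line,
                 "camera": camera_of[(rec.bed, rec.row)], "interval": k}
                for rec in t.itertuples() for k in intervals]
        records = pd.DataFrame(rows)
        if config.n_intervals == 1:
            records = records.drop(columns="interval")
        mu = np.array([fixed["bed"][rec.bed] + fixed["camera"][rec.camera]
                       + (fixed["interval"][rec.interval] if config.n_intervals > 1 else 0.0)
                       for rec in records.itertuples()])
        Zs = spatial_incidence(layout, records, area=None)
        s_part = Zs @ field_s
        truth_fields = {"all": field_s}

    Zl = line_incidence(records, lines)
    Zn = neighbor_incidence(layout, records, lines)
    r_part = np.array([r_eff[r_idx[(b, w)]] for b, w in zip(records["bed"], records["row"])])
    e = rng.normal(0, np.sqrt(v["e"]), size=len(records))
    value = mu + Zl @ (g + l) + Zn @ (g_n + l_n) + r_part + s_part + e
    if config.interaction_variance > 0 and config.trait_kind == "grain":
        ga = {a: rng.normal(0, np.sqrt(config.interaction_variance), size=len(lines))
              for a in ("wet", "dry")}
        value = value + np.array([ga[a][lines.index(lin)]
                                  for a, lin in zip(records["area"], records["line"])])
    records = records.assign(value=value)
    def _skey(k):
        return ":".join(map(str, k)) if isinstance(k, tuple) else str(k)

    truth = {
        "fixed": {_skey(k): (v if not isinstance(v, dict)
                             else {_skey(kk): vv for kk, vv in v.items()})
                  for k, v in fixed.items()},
        "g": g, "l": l, "g_n": g_n, "l_n": l_n,
        "r": {_skey(k): x for k, x in zip(row_levels, r_eff)},
        "spatial": truth_fields, "e": e,
        "line_ids": lines, "config": asdict(config),
    }
    return SimulatedDataset(markers=markers, layout=layout, records=records,
                            truth=truth, config=config)
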