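"""Grain-trait derivation and minirhizotron root-data editing.

Grain traits: yield (GY, t/ha), thousand-kernel weight (TKW, g), protein
concentration (PC, % of grain mass) and nitrogen content
NC = GY x PC / 6.25, evaluated unit-consistently so that
NC [kg N/ha] = 1.6 * GY [t/ha] * PC [%].

Root images carry a living-root length per (tube, camera, depth); they
are edited in four ordered steps before per-tube aggregation:

1. drop failed observations;
2. keep the 1.2-2.0 m depth window (8 depth intervals, 4 in-window);
3. per depth interval, keep lengths within mean +- 3 sd (closed
   interval; statistics from the survivors of steps 1-2);
4. keep only genotyped lines.

TRL is the per-tube sum of retained image lengths; IRL the per
(tube, depth-interval) sum, so a tube's IRL values add up to its TRL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeError",
    "DEFAULT_DEPTH_EDGES",
    "ANALYSIS_WINDOW",
    "compute_nc",
    "assign_depth_intervals",
    "edit_root_images",
    "EditReport",
    "aggregate_root_traits",
    "descriptive_stats",
]


class PhenotypeError(ValueError):
    pass


#: Eight 0.2 m depth bins spanning 0.4-2.0 m; the last four cover the
#: analysis window. Overridable where supplementary edges are available.
DEFAULT_DEPTH_EDGES = tuple(np.round(np.arange(0.4, 2.01, 0.2), 10))
ANALYSIS_WINDOW = (1.2, 2.0)


def compute_nc(gy, pc):
    """Nitrogen content (kg N/ha) from yield (t/ha) and protein (%).

    NC = GY*PC/6.25 on unit-consistent scales = 1.6 * GY * PC.
    """
    gy = np.asarray(gy, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if np.any(gy < 0):
        raise PhenotypeError("negative grain yield")
    if np.any((pc < 0) | (pc > 100)):
        raise PhenotypeError("protein concentration outside [0, 100]%")
    out = 1.6 * gy * pc
    return float(out) if out.ndim == 0 else out


def assign_depth_intervals(records: pd.DataFrame, edges=DEFAULT_DEPTH_EDGES,
                           window=ANALYSIS_WINDOW) -> pd.DataFrame:
    """Label each image record with its depth interval.

    Adds ``depth_interval`` (1-based bin index, -1 out of range) and
    ``analysis_interval`` (1..4 within the analysis window, else NaN).
    Bins are left-closed, with the deepest bin closed on both ends.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise PhenotypeError("depth-interval edges must be strictly increasing")
    out = records.copy()
    d = out["depth_m"].to_numpy(dtype=float)
    n_bins = edges.size - 1
    # left-closed bins [e_{i-1}, e_i); the deepest edge belongs to the last bin
    idx = np.searchsorted(edges, d, side="right")
    interval = np.where((idx >= 1) & (idx <= n_bins), idx, -1)
    interval = np.where(d == edges[-1], n_bins, interval)
    out["depth_interval"] = interval
    lo, hi = window
    in_window = (d >= lo) & (d <= hi) & (interval > 0)
    # analysis intervals: bins whose span intersects the window, renumbered 1..k
    bin_lo = edges[:-1]
    bin_hi = edges[1:]
    analysis_bins = [i + 1 for i in range(edges.size - 1)
                     if bin_hi[i] > lo + 1e-9 and bin_lo[i] < hi - 1e-9]
    remap = {b: k + 1 for k, b in enumerate(analysis_bins)}
    out["analysis_interval"] = [remap.get(b, np.nan) if w else np.nan
                                for b, w in zip(interval, in_window)]
    return out


@dataclass
class EditReport:
    """Per-step retention counts for the root-image editing pipeline."""

    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.counts)


def edit_root_images(records: pd.DataFrame, genotyped_lines=None,
                     edges=DEFAULT_DEPTH_EDGES, window=ANALYSIS_WINDOW,
                     sd_mult: float = 3.0):
    """Apply the four editing steps in order; return (edited, report).

    ``records`` columns: bed, tube, camera, depth_m, length_cm, line and
    optionally ``valid`` (step 1 also drops missing lengths). Step-3
    mean/sd are computed per depth interval from the survivors of steps
    1-2 with the sample (n-1) sd; ties at exactly mean +- 3 sd are kept.
    """
    rep = EditReport()
    rep.counts["input"] = len(records)
    r = records.copy()

    ok = r["length_cm"].notna()
    if "valid" in r.columns:
        ok &= r["valid"].astype(bool)
    r = r.loc[ok]
    rep.counts["step1_failures_removed"] = len(r)

    r = assign_depth_intervals(r, edges=edges, window=window)
    r = r.loc[r["analysis_interval"].notna()]
    rep.counts["step2_depth_window"] = len(r)

    if len(r):
        stats = r.groupby("depth_interval")["length_cm"].agg(["mean", "std"])
        mu = r["depth_interval"].map(stats["mean"])
        sd = r["depth_interval"].map(stats["std"]).fillna(0.0)
        keep = (r["length_cm"] >= mu - sd_mult * sd) & (r["length_cm"] <= mu + sd_mult * sd)
        r = r.loc[keep]
    rep.counts["step3_outliers_removed"] = len(r)

    if genotyped_lines is not None:
        r = r.loc[r["line"].isin(set(genotyped_lines))]
    rep.counts["step4_genotyped_only"] = len(r)

    if len(r) == 0:
        rep.counts["empty_result"] = True
    return r.reset_index(drop=True), rep


def aggregate_root_traits(edited: pd.DataFrame):
    """Sum retained image lengths per tube (TRL) and per interval (IRL).

    Returns ``(trl, irl)`` frames; tubes with zero retained images emit
    no record. By construction each tube's IRL values sum to its TRL.
    """
    if len(edited) == 0:
        empty = pd.DataFrame(columns=["bed", "row", "line", "camera", "value"])
        return empty, empty.assign(interval=[])
    keys = ["bed", "tube"]
    meta = edited.groupby(keys).agg(line=("line", "first"), camera=("camera", "first"))
    trl = edited.groupby(keys)["length_cm"].sum().to_frame("value").join(meta).reset_index()
    irl = (edited.groupby(keys + ["analysis_interval"])["length_cm"].sum()
           .to_frame("value").join(meta, on=keys).reset_index()
           .rename(columns={"analysis_interval": "interval"}))
    irl["interval"] = irl["interval"].astype(int)
    trl = trl.rename(columns={"tube": "row"})
    irl = irl.rename(columns={"tube": "row"})
    return trl, irl


def descriptive_stats(values, trait: str | None = None) -> dict:
    """n, mean, sample sd, min, max of the non-missing values."""
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if v.size == 0:
        raise PhenotypeError(f"no records for {trait or 'trait'}")
    return {
        "trait": trait,
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
    }
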