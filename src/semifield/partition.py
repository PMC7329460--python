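"""Line-mean phenotypic variance, relative components and heritability.

The phenotypic variance of a line mean is the sum of weighted variance
components; per harvest area i for the grain models,

    GM1: s2_P = Gbar*s2_g + s2_l + s2_r/n_r + 11*s2_si/n_si + s2_e/n_e
    GM2: ... + 2*Gbar*s2_gn + 2*s2_ln

and for the root models (single area)

    RM1: s2_P = Gbar*s2_g + s2_l + 11*s2_s/n_s + s2_e/n_e
    RM2: s2_P = Gbar*s2_g + s2_l + s2_r/n_r + 11*s2_s/n_s + s2_e/n_e.

The relative variance component (RVC) of a term is its weighted variance
over s2_P; the genomic RVC is the line-mean narrow-sense heritability
h2, and genomic + line RVC the broad-sense H2. The coefficient of
genetic variation is 100*sqrt(s2_g)/mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from semifield.reml import MixedModelFit

__all__ = [
    "PartitionError",
    "ReplicateCounts",
    "PartitionReport",
    "replicate_counts",
    "line_mean_pvar",
    "partition_report",
    "genetic_cv",
]

SPATIAL_WINDOW = 11


class PartitionError(ValueError):
    pass


@dataclass
class ReplicateCounts:
    """Average replication per line, computed from the actual records.

    n_r: distinct rows per line; n_s: records per line per area (grain,
    keyed by area) or distinct row locations per line (root); n_e: total
    records per line.
    """

    n_r: float
    n_s: dict
    n_e: float


def replicate_counts(records: pd.DataFrame, kind: str = "grain",
                     trait: str | None = None) -> ReplicateCounts:
    """Per-line average replication for the records entering a fit."""
    rec = records
    col = trait or "value"
    if col in rec.columns:
        rec = rec.loc[rec[col].notna()]
    if len(rec) == 0:
        raise PartitionError("no records")
    per_line = rec.groupby("line")
    n_e = float(per_line.size().mean())
    n_r = float(per_line.apply(lambda g: g[["bed", "row"]].drop_duplicates().shape[0],
                               include_groups=False).mean())
    n_s = {}
    if kind == "grain":
        for area in sorted(rec["area"].unique()):
            sub = rec.loc[rec["area"] == area]
            n_s[area] = float(sub.groupby("line").size().mean())
    else:
        n_s["all"] = n_r
    return ReplicateCounts(n_r=n_r, n_s=n_s, n_e=n_e)


def _weights(model_name: str, counts: ReplicateCounts, g_bar: float, area: str):
    """Weight applied to each component in the line-mean variance."""
    w = {"g": g_bar, "l": 1.0, "e": 1.0 / counts.n_e}
    if model_name in ("GM1", "GM2"):
        w["r"] = 1.0 / counts.n_r
        tag = "s1" if area == "wet" else "s2"
        w[tag] = SPATIAL_WINDOW / counts.n_s[area]
    if model_name == "GM2":
        w["g_n"] = 2.0 * g_bar
        w["l_n"] = 2.0
    if model_name == "RM1":
        w["s"] = SPATIAL_WINDOW / counts.n_s["all"]
    if model_name == "RM2":
        w["r"] = 1.0 / counts.n_r
        w["s"] = SPATIAL_WINDOW / counts.n_s["all"]
    return w


def _areas(model_name: str, counts: ReplicateCounts):
    if model_name in ("GM1", "GM2"):
        return sorted(counts.n_s.keys())
    return ["all"]


def line_mean_pvar(vcs: dict, counts: ReplicateCounts, model_name: str,
                   g_bar: float) -> dict:
    """Per-area line-mean phenotypic variance (single 'all' key for root)."""
    out = {}
    for area in _areas(model_name, counts):
        w = _weights(model_name, counts, g_bar, area)
        try:
            out[area] = float(sum(w[k] * vcs[k] for k in w))
        except KeyError as err:
            raise PartitionError(f"model {model_name}: missing component {err}") from None
    return out


@dataclass
class PartitionReport:
    """RVCs, heritabilities and genetic CV for one fitted model."""

    model: str
    sigma2_p: dict
    rvc: dict            # area -> {term -> share}
    h2: dict             # area -> h2, plus 'mean'
    H2: dict
    cv_pct: float
    trait_mean: float
    counts: ReplicateCounts = None
    g_bar: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for area, shares in self.rvc.items():
            for term, share in shares.items():
                rows.append({"model": self.model, "area": area, "term": term, "rvc": share})
        return pd.DataFrame(rows)


def partition_report(fit: MixedModelFit, counts: ReplicateCounts, g_bar: float,
                     trait_mean: float, model_name: str) -> PartitionReport:
    """Build the per-area RVC/heritability report from a converged fit."""
    vcs = fit.vcs
    sig = line_mean_pvar(vcs, counts, model_name, g_bar)
    rvc, h2, H2 = {}, {}, {}
    for area, s2p in sig.items():
        if s2p <= 0:
            raise PartitionError(f"non-positive line-mean variance in area {area!r}")
        w = _weights(model_name, counts, g_bar, area)
        shares = {k: w[k] * vcs[k] / s2p for k in w}
        # map the area-specific spatial tag to a common 's' label for reporting
        for tag in ("s1", "s2"):
            if tag in shares:
                shares["s"] = shares.pop(tag)
        rvc[area] = shares
        h2[area] = shares["g"]
        H2[area] = shares["g"] + shares["l"]
    h2["mean"] = float(np.mean([h2[a] for a in sig]))
    H2["mean"] = float(np.mean([H2[a] for a in sig]))
    return PartitionReport(
        model=model_name, sigma2_p=sig, rvc=rvc, h2=h2, H2=H2,
        cv_pct=genetic_cv(vcs, trait_mean), trait_mean=trait_mean,
        counts=counts, g_bar=g_bar,
    )


def genetic_cv(vcs: dict, trait_mean: float, g_bar: float | None = None) -> float:
    """Coefficient of genetic variation, percent: 100*sqrt(s2_g)/mean.

    The printed formula uses the raw genomic variance; pass ``g_bar`` to
    weight it by the mean G diagonal instead.
    """
    if trait_mean <= 0:
        raise PartitionError("trait mean must be positive for the genetic CV")
    s2 = vcs["g"] * (g_bar if g_bar is not None else 1.0)
    return float(100.0 * np.sqrt(s2) / trait_mean)
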