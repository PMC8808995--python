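"""Normalization into the analysis matrix and spatial proximity to pathology.

Raw per-profile MGIs are natural-log transformed and z-scored per marker
(pooled across diagnoses and subjects within a cell type, so CTRL-vs-AD
contrasts of the z-scores stay meaningful). Spatial analysis computes the
distance from every profile centroid to the nearest plaque *edge* (center
distance minus the plaque's equivalent-circle radius, clamped at 0) and to
the nearest NFT, and bins phenotype proportions in 25 µm distance intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import LesionRecord

__all__ = [
    "IntensityMatrix",
    "log_z_normalize",
    "nearest_lesion_distance",
    "attach_lesion_distances",
    "bin_phenotype_proportions",
]

#: Offset added to MGI values <= 0 before the log transform. One gray level
#: on a 16-bit image; relative distortion is negligible.
ZERO_OFFSET = 1.0


@dataclass
class IntensityMatrix:
    """Profiles × markers matrix of z-scored ln MGI with row metadata."""

    values: pd.DataFrame  # rows: profiles, columns: markers
    meta: pd.DataFrame  # aligned rows: subject, diagnosis, layer, ...

    def __post_init__(self):
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta must align row-wise")
        if self.values.isna().any().any():
            raise ValueError("intensity matrix must not contain missing values")

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self):
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, markers: list[str]) -> "IntensityMatrix":
        df = pd.read_csv(path)
        return cls(values=df[markers].copy(), meta=df.drop(columns=markers))


def log_z_normalize(
    measurements: pd.DataFrame,
    markers: list[str],
    stratum: str | list[str] | None = None,
) -> IntensityMatrix:
    """ln-transform then z-score each marker, optionally within strata.

    ``z = (ln m − mean(ln m)) / sd(ln m)`` with the sample sd (ddof=1),
    computed per marker within each level of ``stratum`` (default: the whole
    table pooled). Non-positive MGIs get a one-gray-level offset (count
    logged); a constant column z-scores to all zeros with a warning.
    """
    meta_cols = [c for c in measurements.columns if c not in markers]
    meta = measurements[meta_cols].reset_index(drop=True)
    raw = measurements[markers].astype(float).reset_index(drop=True)

    n_nonpos = int((raw <= 0).to_numpy().sum())
    if n_nonpos:
        warnings.warn(f"applied +{ZERO_OFFSET} offset to {n_nonpos} non-positive MGI value(s)", stacklevel=2)
        raw = raw.where(raw > 0, raw + ZERO_OFFSET)
    logm = np.log(raw)

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for mk in markers:
            col = block[mk]
            sd = col.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"marker {mk!r} constant within stratum; z-scores set to 0", stacklevel=3)
                out[mk] = pd.Series(np.zeros(len(col)), index=col.index)
            else:
                out[mk] = (col - col.mean()) / sd
        return pd.DataFrame(out)

    if stratum is None:
        z = _z(logm)
    else:
        key = measurements[stratum].reset_index(drop=True)
        z = logm.groupby(key, group_keys=False).apply(_z)
        z = z.sort_index()
    return IntensityMatrix(values=z[markers], meta=meta)


def nearest_lesion_distance(
    centroid: tuple[float, float], lesions: list[LesionRecord]
) -> tuple[float, float]:
    """(d_plaque, d_nft) in µm for one centroid; NaN when no such lesion.

    d_plaque is the distance to the nearest plaque *edge*:
    ``max(0, min_p(‖c − center_p‖ − r_p))``; d_nft is the plain nearest-NFT
    center distance.
    """
    cx, cy = centroid
    d_plaque = np.nan
    d_nft = np.nan
    for lesion in lesions:
        d = float(np.hypot(cx - lesion.centroid[0], cy - lesion.centroid[1]))
        if lesion.type == "plaque":
            edge = max(0.0, d - lesion.radius)
            d_plaque = edge if np.isnan(d_plaque) else min(d_plaque, edge)
        elif lesion.type == "NFT":
            d_nft = d if np.isnan(d_nft) else min(d_nft, d)
    return d_plaque, d_nft


def attach_lesion_distances(
    table: pd.DataFrame, lesions: list[LesionRecord]
) -> pd.DataFrame:
    """Add ``d_plaque`` / ``d_nft`` columns from centroid columns (µm)."""
    out = table.copy()
    dists = [
        nearest_lesion_distance((row["centroid_x_um"], row["centroid_y_um"]), lesions)
        for _, row in table.iterrows()
    ]
    out["d_plaque"] = [d[0] for d in dists]
    out["d_nft"] = [d[1] for d in dists]
    return out


def bin_phenotype_proportions(
    records: pd.DataFrame,
    lesion_type: str = "plaque",
    bin_width: float = 25.0,
    state_col: str = "state",
) -> pd.DataFrame:
    """Phenotype proportions by distance bin.

    For the selected records, counts of each state within distance bins
    ``[k·w, (k+1)·w)`` to the nearest plaque edge (or NFT) are divided by
    the total number of records, so proportions over all (bin × state)
    cells sum to 1 — the way proximity histograms are usually presented
    relative to all profiles of the selection. Records with missing
    distances are dropped. Empty selections give an empty table.
    """
    col = {"plaque": "d_plaque", "NFT": "d_nft"}[lesion_type]
    sel = records.dropna(subset=[col])
    if sel.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", state_col, "count", "proportion"])
    total = len(sel)
    bins = np.floor(sel[col].to_numpy() / bin_width).astype(int)
    df = pd.DataFrame({"bin": bins, state_col: sel[state_col].to_numpy()})
    counts = df.groupby(["bin", state_col], observed=True).size().reset_index(name="count")
    counts["bin_left"] = counts.pop("bin") * bin_width
    counts["bin_right"] = counts["bin_left"] + bin_width
    counts["proportion"] = counts["count"] / total
    return counts[["bin_left", "bin_right", state_col, "count", "proportion"]]
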