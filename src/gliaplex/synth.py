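"""Synthetic glial cohorts: tabular intensities, scene geometry, rendered stacks.

The generator emulates the statistical and spatial structure that the
downstream analysis assumes about cyclic multiplex IHC data:

* per-marker mean gray intensities (MGI) are log-normal, with state-specific
  ln-means for three latent states per cell type (homeostatic, intermediate,
  reactive) and a shared per-subject additive random effect on the ln scale;
* state proportions depend on diagnosis (CTRL vs AD);
* fields contain disk-shaped Aβ plaques and point-like NFTs, with reactive
  (and, more weakly, intermediate) cells preferentially placed within 50 µm
  of a plaque edge;
* rendered channel images carry a spatially varying additive background and
  optional pixel noise, and are accompanied by VIA2 rectangle annotations.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import binary_dilation

from .imaging import ChannelStack
from .panel import MarkerPanel, STATE_NAMES, default_panel

__all__ = [
    "ParameterError",
    "CohortParams",
    "Lesion",
    "generate_intensity_dataset",
    "place_scene",
    "render_channel_stack",
    "simulate_fields",
    "generate_cohort",
    "via_annotations",
]

LAYERS = ("II", "III", "IV", "V", "VI")

#: Distance band (µm from plaque edge) inside which placement odds are boosted.
PLAQUE_NEIGHBORHOOD_UM = 50.0


class ParameterError(ValueError):
    """Invalid cohort parameters."""


# ln-intensity means per state (homeostatic, intermediate, reactive).
# They encode the qualitative state signatures: reactive astrocytes high
# GFAP/YKL-40, modest VIM/TSPO/EAAT1, low GS; intermediate astrocytes high
# EAAT2, modest GS, mid GFAP/YKL-40; reactive microglia elevated in all
# markers; intermediate microglia elevated FTL/TMEM119, mid CD68.
DEFAULT_MARKER_MEANS = {
    "astrocyte": {
        "EAAT1": (5.00, 5.10, 5.35),
        "EAAT2": (5.00, 6.00, 5.00),
        "GFAP": (5.00, 5.55, 6.30),
        "GS": (5.20, 5.55, 4.80),
        "TSPO": (5.00, 5.25, 5.60),
        "VIM": (5.00, 5.25, 5.60),
        "YKL-40": (5.00, 5.55, 6.30),
    },
    "microglia": {
        "CD68": (5.00, 5.40, 6.00),
        "FTL": (5.00, 5.80, 6.00),
        "MHC2": (5.00, 5.05, 5.90),
        "TMEM119": (5.00, 5.70, 6.00),
        "TSPO": (5.00, 5.10, 5.80),
    },
}

#: Constitutive channels are state-independent by construction (ALDH1L1/IBA1
#: counts do not differ between CTRL and AD in stereology).
CONSTITUTIVE_LN_MEAN = 6.0

DEFAULT_STATE_PROPS = {
    "CTRL": (0.495, 0.331, 0.175),
    "AD": (0.196, 0.362, 0.442),
}


@dataclass(frozen=True)
class Lesion:
    """A rendered lesion: Aβ plaque (disk) or NFT (point-like)."""

    type: str  # "plaque" | "NFT"
    center: tuple[float, float]  # (x, y) µm within the field
    area: float  # µm²; 0 for NFTs

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.area / np.pi)) if self.type == "plaque" else 0.0


@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the human temporal-neocortex study the pipeline targets:
    7 CTRL + 7 AD subjects, state proportions (49.5/33.1/17.5)% in CTRL and
    (19.6/36.2/44.2)% in AD, and a 50 µm plaque neighborhood in which
    reactive placement odds are multiplied by ``proximity_bias``.
    """

    cell_type: str = "astrocyte"
    n_subjects_per_group: int = 7
    cells_per_subject: int = 350
    state_props: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PROPS))
    marker_means: dict | None = None  # marker -> (mu_h, mu_i, mu_r) on ln scale
    marker_sd: float = 0.35
    subject_sd: float = 0.15
    diagnosis_shift: dict = field(default_factory=dict)  # marker -> ln shift in AD
    plaque_density: float = 25.0  # per mm²
    plaque_area_range: tuple[float, float] = (80.0, 500.0)  # µm²
    nft_density: float = 15.0  # per mm²
    proximity_bias: float = 4.0
    pixel_size: float = 0.5  # µm per px
    field_size: int = 512  # px, square field
    background: tuple[float, float] = (100.0, 40.0)  # baseline, low-freq amplitude
    pixel_noise_sd: float = 3.0
    min_separation: float = 14.0  # µm between cell centroids
    seed: int = 0

    def resolved_marker_means(self) -> dict:
        return dict(
            DEFAULT_MARKER_MEANS[self.cell_type] if self.marker_means is None else self.marker_means
        )

    def validate(self) -> None:
        if self.cell_type not in ("astrocyte", "microglia"):
            raise ParameterError(f"unknown cell_type {self.cell_type!r}")
        for dx, props in self.state_props.items():
            p = np.asarray(props, dtype=float)
            # printed percentage vectors may carry rounding (e.g. sum 100.1%)
            if p.shape != (3,) or np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1) > 5e-3:
                raise ParameterError(f"state_props[{dx!r}] must be a 3-vector of probabilities summing to 1")
        if self.marker_sd < 0 or self.subject_sd < 0:
            raise ParameterError("sds must be >= 0")
        if self.field_size <= 0 or self.pixel_size <= 0:
            raise ParameterError("field dimensions must be positive")
        if self.n_subjects_per_group < 1 or self.cells_per_subject < 1:
            raise ParameterError("counts must be positive")
        if self.proximity_bias <= 0:
            raise ParameterError("proximity_bias must be positive")

    @property
    def field_um(self) -> float:
        return self.field_size * self.pixel_size

    @property
    def field_area_mm2(self) -> float:
        return (self.field_um / 1000.0) ** 2


def _subject_table(params: CohortParams) -> pd.DataFrame:
    rows = []
    for dx in ("CTRL", "AD"):
        for i in range(params.n_subjects_per_group):
            rows.append({"subject": f"{dx}{i + 1:02d}", "diagnosis": dx})
    return pd.DataFrame(rows)


def generate_intensity_dataset(params: CohortParams, panel: MarkerPanel | None = None):
    """Draw a tabular cohort of per-cell MGIs.

    Returns ``(profiles, truth)``: one row per cell with subject, diagnosis,
    cortical layer, latent state and per-marker MGI drawn as
    ``exp(mu[state, marker] + subject_effect + N(0, marker_sd))``; and a
    truth table with the latent state, subject effect and the noise-free
    per-marker mean intensity of every cell.
    """
    params.validate()
    panel = panel or default_panel()
    rng = np.random.default_rng(params.seed)
    means = params.resolved_marker_means()
    markers = sorted(means)
    const_marker = panel.constitutive(params.cell_type)

    subjects = _subject_table(params)
    subj_effect = {
        s: rng.normal(0.0, params.subject_sd) for s in subjects["subject"]
    }

    prof_rows, truth_rows = [], []
    pid = 0
    for _, srow in subjects.iterrows():
        subj, dx = srow["subject"], srow["diagnosis"]
        props = np.asarray(params.state_props[dx], dtype=float)
        states = rng.choice(3, size=params.cells_per_subject, p=props / props.sum())
        layers = rng.choice(len(LAYERS), size=params.cells_per_subject)
        for st, ly in zip(states, layers):
            pid += 1
            prow = {
                "profile_id": f"p{pid:06d}",
                "subject": subj,
                "diagnosis": dx,
                "layer": LAYERS[ly],
                "cell_type": params.cell_type,
                "state": STATE_NAMES[st],
            }
            trow = {
                "profile_id": prow["profile_id"],
                "state": STATE_NAMES[st],
                "subject_effect": subj_effect[subj],
            }
            for mk in markers:
                mu = means[mk][st] + subj_effect[subj]
                if dx == "AD":
                    mu += params.diagnosis_shift.get(mk, 0.0)
                prow[mk] = float(np.exp(mu + rng.normal(0.0, params.marker_sd)))
                trow[f"true_{mk}"] = float(np.exp(mu))
            mu_c = CONSTITUTIVE_LN_MEAN + subj_effect[subj]
            prow[const_marker] = float(np.exp(mu_c + rng.normal(0.0, params.marker_sd)))
            trow[f"true_{const_marker}"] = float(np.exp(mu_c))
            prof_rows.append(prow)
            truth_rows.append(trow)

    return pd.DataFrame(prof_rows), pd.DataFrame(truth_rows)


def place_scene(params: CohortParams, states=None, rng=None):
    """Lay out one field: lesions plus cell centroids (µm).

    Plaques are disks with Poisson counts at ``plaque_density``; NFTs are
    Poisson points. Cells start uniform; reactive and intermediate cells are
    placed by weighted rejection so their odds of landing within 50 µm of a
    plaque edge are multiplied by ``proximity_bias`` (reactive) or
    ``sqrt(proximity_bias)`` (intermediate). Centroids keep a minimum
    separation by rejection sampling (100 retries, then placed anyway with a
    warning).
    """
    params.validate()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if states is None:
        props = np.asarray(params.state_props["CTRL"], dtype=float)
        states = rng.choice(3, size=params.cells_per_subject // len(LAYERS), p=props / props.sum())
    states = np.asarray(states)
    extent = params.field_um
    n_cells = len(states)
    if n_cells * np.pi * (params.min_separation / 2) ** 2 > 0.9 * extent**2:
        raise ParameterError("field too small for the requested cell density")

    margin = 8.0  # µm; keeps rendered somata inside the field
    n_plaques = rng.poisson(params.plaque_density * params.field_area_mm2)
    n_nfts = rng.poisson(params.nft_density * params.field_area_mm2)
    lesions: list[Lesion] = []
    for _ in range(n_plaques):
        area = rng.uniform(*params.plaque_area_range)
        r = np.sqrt(area / np.pi)
        c = tuple(rng.uniform(margin + r, extent - margin - r, size=2))
        lesions.append(Lesion("plaque", c, float(area)))
    for _ in range(n_nfts):
        c = tuple(rng.uniform(margin, extent - margin, size=2))
        lesions.append(Lesion("NFT", c, 0.0))

    plaques = [l for l in lesions if l.type == "plaque"]

    def near_plaque(p) -> bool:
        return any(
            np.hypot(p[0] - l.center[0], p[1] - l.center[1]) - l.radius <= PLAQUE_NEIGHBORHOOD_UM
            for l in plaques
        )

    mult = {0: 1.0, 1: float(np.sqrt(params.proximity_bias)), 2: float(params.proximity_bias)}
    placed: list[tuple[float, float]] = []
    for st in states:
        w_near = mult[int(st)]
        wmax = max(w_near, 1.0)
        pos = None
        for _ in range(100):
            cand = tuple(rng.uniform(margin, extent - margin, size=2))
            w = w_near if (plaques and near_plaque(cand)) else 1.0
            if rng.uniform() > w / wmax:
                continue
            if all(np.hypot(cand[0] - q[0], cand[1] - q[1]) >= params.min_separation for q in placed):
                pos = cand
                break
        if pos is None:
            warnings.warn("cell placed after exhausting non-overlap retries", stacklevel=2)
            pos = cand
        placed.append(pos)

    return lesions, np.asarray(placed)


# ---------------------------------------------------------------------------
# rendering

_LESION_INTENSITY = 20000.0
_DAPI_INTENSITY = 3000.0


def _cell_mask(shape, center_px, cell_type: str, pixel_size: float, rng) -> np.ndarray:
    """Binary mask for one rendered cell.

    Astrocyte somata are ellipses; microglia get a small soma plus a few
    dilated line processes (a crude branched silhouette, not a realistic
    arbor).
    """
    mask = np.zeros(shape, dtype=bool)
    cx, cy = center_px
    if cell_type == "astrocyte":
        a = rng.uniform(3.5, 5.5) / pixel_size  # semi-axes in px
        b = rng.uniform(2.5, 4.5) / pixel_size
        rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
    else:
        r_soma = rng.uniform(1.8, 2.8) / pixel_size
        rr, cc = draw_disk((cy, cx), r_soma, shape=shape)
        mask[rr, cc] = True
        for _ in range(rng.integers(3, 6)):
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(4.0, 9.0) / pixel_size
            ey = int(np.clip(cy + length * np.sin(ang), 0, shape[0] - 1))
            ex = int(np.clip(cx + length * np.cos(ang), 0, shape[1] - 1))
            rr, cc = draw_line(int(cy), int(cx), ey, ex)
            mask[rr, cc] = True
        mask = binary_dilation(mask)
    if not mask.any():
        raise ParameterError("degenerate zero-area cell shape")
    return mask


def render_channel_stack(
    profiles: pd.DataFrame,
    lesions: list[Lesion],
    centroids: np.ndarray,
    params: CohortParams,
    panel: MarkerPanel | None = None,
    metadata: dict | None = None,
):
    """Render one field into a multi-channel stack with VIA annotations.

    Each cell is painted as a compact blob whose within-mask pixel value on
    every channel it expresses equals its MGI exactly; the additive
    background and pixel noise are applied afterwards, so a noise-free
    render is lossless. Returns ``(stack, via_dict, truth)`` where *truth*
    maps annotation ids to profile ids and lesion geometry.
    """
    params.validate()
    panel = panel or default_panel()
    if len(profiles) != len(centroids):
        raise ParameterError("profiles and centroids must align")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC311]))
    shape = (params.field_size, params.field_size)
    const_marker = panel.constitutive(params.cell_type)
    cell_markers = [const_marker] + panel.phenotypic(params.cell_type)

    channel_names = cell_markers + ["Abeta", "PHF1", "DAPI"]
    channels = {name: np.zeros(shape, dtype=float) for name in channel_names}

    regions = []
    truth_rows = []

    for lesion in lesions:
        cx, cy = (np.asarray(lesion.center) / params.pixel_size).tolist()
        if lesion.type == "plaque":
            r_px = lesion.radius / params.pixel_size
            ch = "Abeta"
        else:
            r_px = 3.0 / params.pixel_size
            ch = "PHF1"
        rr, cc = draw_disk((cy, cx), max(r_px, 1.0), shape=shape)
        channels[ch][rr, cc] = _LESION_INTENSITY
        x0, x1 = int(cc.min()), int(cc.max()) + 1
        y0, y1 = int(rr.min()), int(rr.max()) + 1
        regions.append(_rect_region(x0 - 1, y0 - 1, x1 - x0 + 2, y1 - y0 + 2, lesion.type, shape))
        truth_rows.append(
            {
                "annotation_id": len(regions) - 1,
                "object": lesion.type,
                "profile_id": "",
                "center_x_um": lesion.center[0],
                "center_y_um": lesion.center[1],
                "area_um2": lesion.area,
            }
        )

    for (_, prow), (x_um, y_um) in zip(profiles.iterrows(), centroids):
        cx, cy = x_um / params.pixel_size, y_um / params.pixel_size
        mask = _cell_mask(shape, (cx, cy), params.cell_type, params.pixel_size, rng)
        for mk in cell_markers:
            channels[mk][mask] = prow[mk]
        nuc_rr, nuc_cc = draw_disk((cy, cx), 2.0 / params.pixel_size, shape=shape)
        channels["DAPI"][nuc_rr, nuc_cc] = _DAPI_INTENSITY
        ys, xs = np.nonzero(mask)
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        regions.append(
            _rect_region(x0 - 1, y0 - 1, x1 - x0 + 2, y1 - y0 + 2, params.cell_type, shape)
        )
        truth_rows.append(
            {
                "annotation_id": len(regions) - 1,
                "object": params.cell_type,
                "profile_id": prow["profile_id"],
                "center_x_um": x_um,
                "center_y_um": y_um,
                "area_um2": float(mask.sum()) * params.pixel_size**2,
            }
        )

    baseline, amplitude = params.background
    for name, img in channels.items():
        if amplitude > 0:
            # background drifts on scales comparable to the whole field, the
            # regime a 200 px rolling ball is meant to remove
            low = gaussian_filter(rng.standard_normal(shape), sigma=params.field_size / 2)
            peak = np.abs(low).max()
            low = low / peak if peak > 0 else low
            bg = baseline + amplitude * low
        else:
            bg = np.full(shape, baseline)
        img += bg
        if params.pixel_noise_sd > 0:
            img += rng.normal(0.0, params.pixel_noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)

    meta = dict(metadata or {})
    stack = ChannelStack(channels=channels, pixel_size=params.pixel_size, metadata=meta)
    via = via_annotations(regions, filename=meta.get("field_id", "field") + ".tif")
    return stack, via, pd.DataFrame(truth_rows)


def _rect_region(x, y, w, h, obj_class, shape):
    x = int(max(0, x))
    y = int(max(0, y))
    w = int(min(w, shape[1] - x))
    h = int(min(h, shape[0] - y))
    return {
        "shape_attributes": {"name": "rect", "x": x, "y": y, "width": w, "height": h},
        "region_attributes": {"type": obj_class},
    }


def via_annotations(regions: list[dict], filename: str = "field.tif") -> dict:
    """Wrap rectangle regions in the VIA2 project JSON dialect."""
    key = f"{filename}-1"
    return {
        key: {
            "filename": filename,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    }


def simulate_fields(params: CohortParams, panel: MarkerPanel | None = None, subjects=None):
    """Yield rendered fields for a cohort, one per (subject, layer).

    Cells of each subject are split across layers II–VI. Yields tuples
    ``(field_id, stack, via, field_truth, field_profiles)``.
    """
    params.validate()
    panel = panel or default_panel()
    profiles, truth = generate_intensity_dataset(params, panel)
    if subjects is not None:
        profiles = profiles[profiles["subject"].isin(subjects)]
    state_idx = {s: i for i, s in enumerate(STATE_NAMES)}
    for (subj, layer), grp in profiles.groupby(["subject", "layer"], sort=True):
        field_id = f"{subj}_L{layer}"
        field_seed = np.random.SeedSequence(
            [params.seed, abs(hash(field_id)) % (2**31)]
        )
        rng = np.random.default_rng(field_seed)
        states = np.array([state_idx[s] for s in grp["state"]])
        lesions, cents = place_scene(params, states=states, rng=rng)
        meta = {
            "field_id": field_id,
            "subject": subj,
            "diagnosis": grp["diagnosis"].iloc[0],
            "layer": layer,
        }
        stack, via, ftruth = render_channel_stack(
            grp, lesions, cents, replace(params, seed=int(rng.integers(2**31))), panel, meta
        )
        yield field_id, stack, via, ftruth, grp


def generate_cohort(params: CohortParams, out_dir, panel: MarkerPanel | None = None, subjects=None):
    """Write a full synthetic cohort to disk.

    Emits per-field TIFF channels + stack manifest (JSON) + VIA2 annotation
    JSON, plus cohort-level ``profiles.csv`` and ``truth.csv``. Returns the
    manifest paths.
    """
    from pathlib import Path

    from .imaging import write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel or default_panel()
    manifests = []
    all_truth, all_profiles = [], []
    for field_id, stack, via, ftruth, fprofiles in simulate_fields(params, panel, subjects):
        fdir = out / field_id
        manifest = write_stack(stack, fdir)
        (fdir / "annotations.json").write_text(json.dumps(via, indent=1))
        ftruth.insert(0, "field_id", field_id)
        all_truth.append(ftruth)
        all_profiles.append(fprofiles.assign(field_id=field_id))
        manifests.append(manifest)
    pd.concat(all_truth, ignore_index=True).to_csv(out / "truth.csv", index=False)
    pd.concat(all_profiles, ignore_index=True).to_csv(out / "profiles.csv", index=False)
    return manifests
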