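"""Self-contained benchmark computations over synthetic cohorts.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns the measured quantities. They back both the
acceptance checks and the reproduction script, and document the problem
sizes this package uses for desk-scale verification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import imaging
from .gbm import run_paper_gbm_suite
from .panel import STATE_NAMES, default_panel
from .profiles import log_z_normalize
from .states import cluster_states
from .stats import chi2_trend, fit_mixed_model, reconstruct_crosstab
from .synth import CohortParams, generate_intensity_dataset, place_scene, render_channel_stack

__all__ = [
    "printed_table_benchmarks",
    "state_recovery_benchmark",
    "classifier_ordering_benchmark",
    "roundtrip_benchmark",
    "mixed_model_benchmark",
    "cnn_benchmark",
]

#: Printed inputs of the human study: grand totals, within-diagnosis state
#: percentages (homeostatic, intermediate, reactive) and the cross-share of
#: homeostatic profiles belonging to CTRL.
ASTRO_PRINTED = dict(total=5172, ctrl=(49.5, 33.1, 17.5), ad=(19.6, 36.2, 44.2), homeo_ctrl_share=65.6)
MICRO_PRINTED = dict(total=6226, ctrl=(44.5, 32.3, 23.2), ad=(21.5, 28.4, 50.1), homeo_ctrl_share=66.3)


def printed_table_benchmarks() -> dict:
    """Rebuild both diagnosis-by-state tables and run the trend test."""
    out = {}
    for name, spec in (("astro", ASTRO_PRINTED), ("micro", MICRO_PRINTED)):
        table = reconstruct_crosstab(spec["total"], spec["ctrl"], spec["ad"], spec["homeo_ctrl_share"])
        trend = chi2_trend(np.round(table))
        out[name] = {
            "table": table,
            "chi2": trend.chi2,
            "p": trend.p,
            "reactive_ad_share": 100 * table[1, 2] / table[:, 2].sum(),
            "intermediate_ad_share": 100 * table[1, 1] / table[:, 1].sum(),
            "intermediate_ctrl_share": 100 * table[0, 1] / table[:, 1].sum(),
        }
    return out


def _recovery_params(seed: int, cells_per_subject: int) -> CohortParams:
    # three planted states separated by >= 2 sd on their signature markers:
    # ln-mean gaps of >= 0.55 at marker_sd 0.25; no subject effect so the
    # planted partition is the only structure
    return CohortParams(
        cell_type="astrocyte",
        n_subjects_per_group=7,
        cells_per_subject=cells_per_subject,
        marker_sd=0.25,
        subject_sd=0.0,
        seed=seed,
    )


def state_recovery_benchmark(seed: int = 11, cells_per_subject: int = 358) -> dict:
    """Cluster-number selection and planted-state recovery at n ≈ 5,000."""
    params = _recovery_params(seed, cells_per_subject)
    prof, _ = generate_intensity_dataset(params)
    matrix = log_z_normalize(prof, default_panel().phenotypic("astrocyte"))
    result = cluster_states(matrix, "astrocyte", seed=seed)
    return {
        "n": len(prof),
        "eigengap_choice": result.eigengap_choice,
        "rotation_choice": result.rotation_choice,
        "ari": float(adjusted_rand_score(prof["state"], result.labels)),
    }


def classifier_ordering_benchmark(seeds=range(10), cells_per_subject: int = 150) -> dict:
    """Multi-marker vs single-marker CTRL/AD AUC across independent cohorts.

    Cohorts carry both the diagnosis-dependent state composition and the
    direct AD elevations of YKL-40 and TSPO seen in the study, so the
    multi-marker model has genuinely complementary information.
    """
    grid = {"n_trees": (100, 200), "depth": (1, 2)}
    rows = []
    for seed in seeds:
        params = CohortParams(
            cell_type="astrocyte",
            n_subjects_per_group=7,
            cells_per_subject=cells_per_subject,
            diagnosis_shift={"YKL-40": 0.15, "TSPO": 0.10},
            seed=seed,
        )
        prof, _ = generate_intensity_dataset(params)
        matrix = log_z_normalize(prof, default_panel().phenotypic("astrocyte"))
        matrix.meta["state"] = prof["state"].to_numpy()
        suite = run_paper_gbm_suite(matrix, grid=grid, folds=3, seed=seed, n_boot=100)
        reports = suite["reports"]
        rows.append(
            {
                "seed": seed,
                "multi_auc": reports["diagnosis_multi"].auc,
                "gfap_auc": reports["diagnosis_GFAP"].auc,
                "state_accuracy": reports["state_multi"].accuracy,
                "ordering": suite["multi_beats_singles"],
            }
        )
    df = pd.DataFrame(rows)
    return {
        "per_seed": df,
        "n": len(prof),
        "ordering_holds_all": bool(df["ordering"].all()),
        "mean_multi_auc": float(df["multi_auc"].mean()),
        "mean_gfap_auc": float(df["gfap_auc"].mean()),
        "mean_state_accuracy": float(df["state_accuracy"].mean()),
    }


def _render_field(params, n_cells):
    panel = default_panel()
    prof, _ = generate_intensity_dataset(params)
    sub = prof.iloc[:n_cells].reset_index(drop=True)
    rng = np.random.default_rng(params.seed)
    states = np.array([STATE_NAMES.index(s) for s in sub["state"]])
    lesions, cents = place_scene(params, states=states, rng=rng)
    stack, via, truth = render_channel_stack(sub, lesions, cents, params, panel, {"field_id": "bench"})
    return panel, sub, stack, via, truth


def roundtrip_benchmark(seed: int = 6, n_cells: int = 40) -> dict:
    """Render → subtract → segment → measure recovery of generated MGIs."""
    panel = default_panel()
    markers = panel.phenotypic("astrocyte")

    def _run(params, ball_radius):
        panel_, sub, stack, via, truth = _render_field(params, n_cells)
        rois = imaging.parse_annotations(via, stack.shape)
        table, _ = imaging.measure_stack(stack, rois, panel_, ball_radius=ball_radius)
        tmap = truth.set_index("annotation_id")["profile_id"]
        merged = table.assign(profile_id=table["annotation_id"].map(tmap)).merge(
            sub, on="profile_id", suffixes=("_m", "_g")
        )
        rel = pd.concat(
            [(merged[f"{mk}_m"] - merged[f"{mk}_g"]).abs() / merged[f"{mk}_g"] for mk in markers],
            axis=1,
        )
        return merged, rel

    clean_params = CohortParams(
        cell_type="astrocyte", n_subjects_per_group=1, cells_per_subject=n_cells,
        background=(0.0, 0.0), pixel_noise_sd=0.0, seed=seed,
    )
    _, rel_clean = _run(clean_params, ball_radius=None)

    noisy_params = CohortParams(
        cell_type="astrocyte", n_subjects_per_group=1, cells_per_subject=n_cells, seed=seed + 1
    )
    _, rel_noisy = _run(noisy_params, ball_radius=200)
    per_cell = rel_noisy.mean(axis=1)
    return {
        "n": n_cells,
        "max_rel_err_noise_free": float(rel_clean.to_numpy().max()),
        "pct_cells_within_5pct": float(100 * (per_cell < 0.05).mean()),
        "pct_measurements_within_5pct": float(100 * (rel_noisy.to_numpy() < 0.05).mean()),
    }


def mixed_model_benchmark(
    seed: int = 0,
    n_coverage: int = 600,
    n_null: int = 500,
    effect: float = 0.5,
    n_subjects: int = 14,
) -> dict:
    """CI coverage of a planted effect and type-I error under the null.

    Every simulation draws from its own child stream of ``seed``, so each
    replicate is individually reproducible and the two experiments do not
    share randomness.
    """

    def simulate(rng, eff, n_cells):
        half = n_subjects // 2
        ys, fs, ss = [], [], []
        for i in range(n_subjects):
            dx = "AD" if i >= half else "CTRL"
            b = rng.normal(0, 0.3)
            ys.append((eff if dx == "AD" else 0.0) + b + rng.normal(0, 1, n_cells))
            fs += [dx] * n_cells
            ss += [f"s{i}"] * n_cells
        return np.concatenate(ys), np.array(fs), np.array(ss)

    cov_streams = np.random.SeedSequence([seed, 1]).spawn(n_coverage)
    covered = 0
    for ss_ in cov_streams:
        y, f, s = simulate(np.random.default_rng(ss_), effect, 300)
        row = fit_mixed_model(y, f, s, reference="CTRL").contrasts.iloc[0]
        tcrit = sps.t.ppf(0.975, row["df"])
        covered += row["estimate"] - tcrit * row["se"] <= effect <= row["estimate"] + tcrit * row["se"]

    null_streams = np.random.SeedSequence([seed, 2]).spawn(n_null)
    rejected = 0
    for ss_ in null_streams:
        y, f, s = simulate(np.random.default_rng(ss_), 0.0, 50)
        rejected += fit_mixed_model(y, f, s, reference="CTRL").contrasts.iloc[0]["p"] < 0.05

    return {
        "coverage_pct": 100 * covered / n_coverage,
        "type1_rate": rejected / n_null,
        "n_coverage": n_coverage,
        "n_null": n_null,
    }


def _signal_images(n, rng, n_channels=6, size=64, amplitude=0.6):
    X = rng.standard_normal((n, n_channels, size, size))
    yy, xx = np.ogrid[:size, :size]
    blob = ((yy - size // 2) ** 2 + (xx - size // 2) ** 2 < 120).astype(float)
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    for ch in (1, 3):
        X[y == 1, ch] += amplitude * blob
    perm = rng.permutation(n)
    return X[perm], y[perm]


def cnn_benchmark(seed: int = 0, n: int = 1600, max_epochs: int = 12) -> dict:
    """CNN sanity at desk scale: separable images and a permuted-label null."""
    from .cnn import CnnConfig, train_cnn

    rng = np.random.default_rng(seed)
    X, y = _signal_images(n, rng)
    half = n // 2
    cfg = CnnConfig(
        conv_channels=(4, 8, 8, 8), hidden=(32, 16, 8), max_epochs=max_epochs,
        lr=1e-3, batch_size=64, seed=seed,
    )
    model, _ = train_cnn(X[:half], y[:half], cfg)
    p = model.predict_proba(X[half:])[:, 1]
    auc_sep = float(roc_auc_score(y[half:], p))

    y_null = rng.permutation(y)
    cfg_null = CnnConfig(
        conv_channels=(4, 8, 8, 8), hidden=(32, 16, 8), max_epochs=max(6, max_epochs // 2),
        lr=1e-3, batch_size=64, seed=seed + 1,
    )
    model0, _ = train_cnn(X[:half], y_null[:half], cfg_null)
    p0 = model0.predict_proba(X[half:])[:, 1]
    auc_null = float(roc_auc_score(y_null[half:], p0))
    return {"n": n, "auc_separable": auc_sep, "auc_null": auc_null}
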