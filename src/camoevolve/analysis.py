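"""Post-hoc analysis of an evolution record.

Standardization and PCA of target-skin pattern features, per-population
ordinary-least-squares trend slopes (fitness vs generation; log survival
time vs each camouflage metric) with sign-test summaries, and the
skin-level comparisons behind the lighting predictions (large-scale
pattern contrast, countershading gradients).  Mixed-effects modelling is
deliberately left to external statistics packages: the record's tidy
trials table is the export contract.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as mt
from .evolve import EvolutionRecord, ExperimentConfig
from .genome import Genome, N_GENES
from .pattern_gen import skin_from_genome
from .renderer import spherical_deform
from ._color import lab_to_linear, linear_to_lab
from .scene_synth import habitat_library, make_scene_set

logger = logging.getLogger(__name__)

LARGE_SCALES = (1 / 4, 1 / 2, 1.0)


# ---------------------------------------------------------------------------
# standardization and PCA

def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, SD 1); constant columns are dropped
    with a warning."""
    if matrix.shape[0] < 2 or matrix.shape[1] == 0:
        raise ValueError("standardize needs >= 2 rows and >= 1 column")
    out = {}
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        sd = v.std()
        if sd <= 1e-12:
            logger.warning("standardize: dropping constant column %r", col)
            continue
        out[col] = (v - v.mean()) / sd
    if not out:
        raise ValueError("all columns constant")
    return pd.DataFrame(out, index=matrix.index)


@dataclasses.dataclass
class PCAResult:
    loadings: pd.DataFrame  # columns PC1.., rows = features
    variance_fractions: np.ndarray
    scores: pd.DataFrame


def pca(features: pd.DataFrame) -> PCAResult:
    """PCA of a standardized feature matrix (rank-deficient input is
    truncated).  Sign convention: each component's largest-|loading|
    feature loads positively; variance fractions sum to 1."""
    from sklearn.decomposition import PCA as _PCA

    X = features.to_numpy(dtype=float)
    n_comp = min(X.shape[0], X.shape[1])
    model = _PCA(n_components=n_comp)
    scores = model.fit_transform(X)
    load = model.components_.T.copy()  # (features, comps)
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(load.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(load, index=features.columns, columns=names),
        variance_fractions=model.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=features.index, columns=names),
    )


# ---------------------------------------------------------------------------
# trend slopes

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xb, yb = x.mean(), y.mean()
    denom = ((x - xb) ** 2).sum()
    return float(((x - xb) * (y - yb)).sum() / denom)


def trend_slopes(
    df: pd.DataFrame,
    response: str,
    predictor: str,
    group: str = "population_id",
    log_response: bool = False,
    carry: tuple[str, ...] = ("treatment", "habitat_id"),
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-group OLS slope of (optionally log) response on predictor.

    Groups with fewer than ``min_points`` points or a constant predictor
    are skipped with a log message.
    """
    rows = []
    for gname, gdf in df.groupby(group, sort=True):
        x = gdf[predictor].to_numpy(dtype=float)
        y = gdf[response].to_numpy(dtype=float)
        if log_response:
            y = np.log(np.maximum(y, 1e-9))
        if len(x) < min_points or x.std() <= 1e-12:
            logger.info("trend_slopes: group %r skipped", gname)
            continue
        row = {group: gname, "slope": _ols_slope(x, y), "n": len(x)}
        for c in carry:
            if c in gdf.columns:
                row[c] = gdf[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_slopes(slopes: pd.DataFrame,
                     by: list[str] | None = None) -> pd.DataFrame:
    """Pooled mean, SD and a sign test (are slopes systematically
    positive?) overall and per stratum."""
    def _one(sdf: pd.DataFrame, label: str) -> dict:
        s = sdf["slope"].to_numpy(dtype=float)
        n_pos = int((s > 0).sum())
        n_nonzero = int((s != 0).sum())
        p = stats.binomtest(n_pos, n_nonzero, 0.5,
                            alternative="greater").pvalue if n_nonzero else 1.0
        return {"stratum": label, "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "n": len(s), "n_positive": n_pos,
                "sign_test_p_greater": float(p)}

    out = [_one(slopes, "all")]
    if by:
        for key, sdf in slopes.groupby(by, sort=True):
            label = key if isinstance(key, str) else "/".join(map(str, key))
            out.append(_one(sdf, label))
    return pd.DataFrame(out)


def fitness_trend(record: EvolutionRecord) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population slope of log survival time on generation number."""
    slopes = trend_slopes(record.trials, "survival_time_ms", "generation",
                          log_response=True)
    return slopes, summarize_slopes(slopes, by=["treatment"])


def metric_predictiveness(record: EvolutionRecord) -> dict[str, pd.DataFrame]:
    """Per-population slope of log survival time on each camouflage
    metric: negative for the difference metrics, positive for gabrat
    when the metrics predict detection."""
    out = {}
    for metric in ("luminance_difference", "colour_difference",
                   "pattern_difference", "gabrat"):
        out[metric] = trend_slopes(record.trials, "survival_time_ms", metric,
                                   log_response=True)
    return out


def habitat_3d_table(cfg: ExperimentConfig) -> pd.DataFrame:
    """Habitat-level 3D variation: mean SD of depth across the habitat's
    scene set (the geometry covariate; the stratum split is at its mean)."""
    rows = []
    for hp in habitat_library(cfg.n_habitats):
        scenes = make_scene_set(hp, "DIRECT", n_scenes=4,
                                size=cfg.scene_size,
                                target_diameter=cfg.target_diameter, seed=0)
        rows.append({"habitat_id": hp.habitat_id,
                     "substrate": hp.substrate,
                     "depth_sd_mm": float(np.mean([s.depth.std()
                                                   for s in scenes]))})
    df = pd.DataFrame(rows)
    df["stratum_3d"] = np.where(df.depth_sd_mm > df.depth_sd_mm.mean(),
                                "high", "low")
    return df


# ---------------------------------------------------------------------------
# target-skin features

def _final_genomes(record: EvolutionRecord) -> pd.DataFrame:
    t = record.trials
    last = t.generation.max()
    return t[t.generation == last].drop_duplicates("individual")


def skin_feature_matrix(
    record: EvolutionRecord,
    cfg: ExperimentConfig | None = None,
    include_gradients: bool = False,
) -> pd.DataFrame:
    """Pattern features of final-generation target-skins: contrast,
    directionality and verticalness per channel x scale (plus L*
    gradients if requested), one row per individual."""
    cfg = cfg or ExperimentConfig(**{
        k: v for k, v in record.config.items()
        if k in {f.name for f in dataclasses.fields(ExperimentConfig)}})
    if isinstance(cfg.scene_size, list):
        cfg.scene_size = tuple(cfg.scene_size)
    cfg.treatments = tuple(cfg.treatments)
    gcols = [f"g{j:02d}" for j in range(N_GENES)]
    rows = []
    for _, rec in _final_genomes(record).iterrows():
        g = Genome(rec[gcols].to_numpy(dtype=float))
        skin = skin_from_genome(g, size=cfg.skin_size, rd_grid=cfg.rd_grid,
                                rd_max_steps=cfg.rd_max_steps)
        table = mt.contrast_table(skin.lab, diameter=cfg.skin_size,
                                  mask=skin.mask)
        row = {"individual": rec.individual, "treatment": rec.treatment,
               "habitat_id": rec.habitat_id,
               "population_id": rec.population_id}
        for ch in ("L", "a", "b"):
            for s in mt.SCALES:
                tag = f"{ch}_{s:.4g}"
                row[f"contrast_{tag}"] = table.orientation_mean(ch, s)
                row[f"directionality_{tag}"] = mt.directionality(table, ch, s)
                row[f"verticalness_{tag}"] = mt.verticalness(table, ch, s)
        if include_gradients:
            row["gradient_L"] = mt.vertical_gradient(skin.lab[..., 0],
                                                     skin.mask)
        rows.append(row)
    return pd.DataFrame(rows)


def large_scale_contrast(skin) -> float:
    """Orientation-averaged L* contrast at the large scales (>= 1/4 of
    the target diameter)."""
    table = mt.contrast_table(skin.lab, diameter=skin.size, mask=skin.mask,
                              scales=LARGE_SCALES, channels=("L",))
    return float(np.nanmean([table.orientation_mean("L", s)
                             for s in LARGE_SCALES]))


def aligned_direct_illum(scenes) -> np.ndarray:
    """Average calibration-button illumination over a habitat's direct
    scenes, each rotated so the lit side faces image-up (the axis targets
    are aligned to in play)."""
    from scipy import ndimage

    maps = []
    for s in scenes:
        maps.append(ndimage.rotate(s.calib_illum, s.azimuth or 0.0,
                                   reshape=False, order=1, mode="nearest"))
    return np.mean(maps, axis=0)


def rendered_gradient(skin, calib_illum_lit_up: np.ndarray) -> float:
    """Countershading gradient of the skin rendered onto the aligned raw
    direct-light target.

    Reported with the illumination axis pointing down the image, so a
    positive value means the skin lightens the shadow side (counteracting
    self-shading); the raw grey target itself scores negative.
    """
    d = calib_illum_lit_up.shape[0]
    def_lab = spherical_deform(skin.lab, out_size=d)
    refl = np.clip(lab_to_linear(def_lab), 0.0, 1.0)
    lit = np.clip(calib_illum_lit_up[..., None] * refl, 0.0, 1.0)
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= (d / 2.0) ** 2
    # measuring in the lit-side-down frame flips the sign of the
    # lit-side-up vertical gradient
    return -mt.vertical_gradient(linear_to_lab(lit)[..., 0], disc)


def lighting_phenotype_comparison(
    record: EvolutionRecord, cfg: ExperimentConfig | None = None
) -> dict[str, float]:
    """Treatment means of the two headline skin phenotypes in the final
    generation: large-scale L* contrast of the skin, and the
    countershading gradient rendered under direct light."""
    cfg = cfg or ExperimentConfig()
    habitats = {hp.habitat_id: hp for hp in habitat_library(cfg.n_habitats)}
    illum_cache: dict[str, np.ndarray] = {}
    gcols = [f"g{j:02d}" for j in range(N_GENES)]
    acc: dict[str, list[float]] = {}
    for _, rec in _final_genomes(record).iterrows():
        g = Genome(rec[gcols].to_numpy(dtype=float))
        skin = skin_from_genome(g, size=cfg.skin_size, rd_grid=cfg.rd_grid,
                                rd_max_steps=cfg.rd_max_steps)
        hid = rec.habitat_id
        if hid not in illum_cache:
            scenes = make_scene_set(habitats[hid], "DIRECT", n_scenes=4,
                                    size=cfg.scene_size,
                                    target_diameter=cfg.target_diameter,
                                    seed=0)
            illum_cache[hid] = aligned_direct_illum(scenes)
        acc.setdefault(f"contrast_{rec.treatment}", []).append(
            large_scale_contrast(skin))
        acc.setdefault(f"gradient_{rec.treatment}", []).append(
            rendered_gradient(skin, illum_cache[hid]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# report

def save_report(record: EvolutionRecord, out_dir: str | pathlib.Path) -> None:
    """CSV tables + PNG plots for an evolution record."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slopes, summary = fitness_trend(record)
    slopes.to_csv(out / "fitness_slopes.csv", index=False)
    summary.to_csv(out / "fitness_slopes_summary.csv", index=False)
    for metric, sdf in metric_predictiveness(record).items():
        sdf.to_csv(out / f"slopes_{metric}.csv", index=False)

    t = record.trials
    fig, ax = plt.subplots(figsize=(6, 4))
    for treatment, tdf in t.groupby("treatment"):
        med = tdf.groupby("generation").survival_time_ms.median()
        ax.plot(med.index, med.values, marker="o", label=treatment)
    ax.set_xlabel("generation")
    ax.set_ylabel("median survival time (ms)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fitness_trajectories.png", dpi=120)
    plt.close(fig)

    feats = skin_feature_matrix(record)
    meta_cols = ["individual", "treatment", "habitat_id", "population_id"]
    numeric = feats.drop(columns=meta_cols).dropna(axis=1)
    res = pca(standardize(numeric))
    res.loadings.to_csv(out / "pca_loadings.csv")
    pd.DataFrame({"variance_fraction": res.variance_fractions}).to_csv(
        out / "pca_variance.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    pc1 = res.scores["PC1"].to_numpy()
    groups = [pc1[feats.treatment.to_numpy() == tr]
              for tr in sorted(feats.treatment.unique())]
    ax.boxplot(groups, tick_labels=sorted(feats.treatment.unique()))
    ax.set_ylabel("PC1 (final generation skins)")
    fig.tight_layout()
    fig.savefig(out / "pc1_by_treatment.png", dpi=120)
    plt.close(fig)
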