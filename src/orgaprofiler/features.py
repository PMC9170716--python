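"""Per-organoid phenotype features, the well-definedness filter, and PCA.

Each segmented organoid is described by shape and moment features computed
from its mask, per-channel intensity statistics, and gray-level co-occurrence
(Haralick-style) texture features at multiple pixel offsets per channel.
Downstream, features are kept only if "well defined" (median absolute
deviation strictly greater than zero over the whole dataset, and texture
offsets no larger than the smallest organoids), batch effects are removed by
per-batch mean centering, and the matrix is compressed to 25 principal
components fitted incrementally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops
from sklearn.decomposition import PCA, IncrementalPCA
from sklearn.ensemble import RandomForestClassifier

from .imaging import ProjectedImage


DEFAULT_TEXTURE_SCALES = (1, 2, 4, 8)
_GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM", "energy", "correlation")
_GLCM_LEVELS = 32

#: metadata columns carried alongside the feature table
META_COLUMNS = (
    "plate_id",
    "row",
    "col",
    "field",
    "line_id",
    "treatment",
    "concentration",
    "role",
    "batch_id",
    "replicate",
    "area_px",
)


class PipelineError(RuntimeError):
    """Raised when a processing rule leaves nothing to analyse."""


@dataclass
class FeatureMatrix:
    """Named per-organoid features plus well/line/treatment metadata.

    ``features`` and ``meta`` share an index of organoid ids. ``meta`` carries
    the columns in :data:`META_COLUMNS` (missing ones are tolerated for
    partial pipelines).
    """

    features: pd.DataFrame
    meta: pd.DataFrame
    filter_report: dict | None = None

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.meta.index):
            raise ValueError("features and meta must share an index")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return len(self.features)

    def well_key(self) -> pd.Series:
        m = self.meta
        return (
            m["plate_id"].astype(str)
            + ":"
            + m["row"].astype(int).astype(str)
            + ":"
            + m["col"].astype(int).astype(str)
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.features.copy(), self.meta.copy(), self.filter_report)


@dataclass
class PCAModel:
    """A fitted linear compression of the feature space."""

    components: pd.DataFrame  # features x k, orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: pd.Series
    n_components: int = 25

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        aligned = features[self.components.index]
        scores = (aligned - self.mean) @ self.components
        scores.columns = [f"PC{i + 1:02d}" for i in range(self.n_components)]
        return scores


# ---------------------------------------------------------------------------
# feature extraction


def extract_organoid_features(
    img: ProjectedImage,
    mask: np.ndarray,
    texture_scales=DEFAULT_TEXTURE_SCALES,
    meta: dict | None = None,
) -> FeatureMatrix:
    """Compute shape, moment, intensity and texture features per labelled organoid."""
    mask = np.asarray(mask)
    if mask.shape != img.pixels.shape[1:]:
        raise ValueError("mask shape does not match image")
    meta = dict(meta or {})

    rows: list[dict] = []
    ids: list[str] = []
    for region in regionprops(mask):
        feats: dict[str, float] = {}
        _shape_features(region, feats)
        _moment_features(region, feats)
        sl = region.slice
        rmask = region.image
        for ci, ch in enumerate(img.channels):
            crop = np.asarray(img.pixels[ci][sl], dtype=float)
            _intensity_features(crop, rmask, ch, feats)
            _texture_features(crop, rmask, ch, texture_scales, feats)
        if not np.isfinite(feats["area"]) or region.area == 0:
            warnings.warn(f"label {region.label} touches no pixels; skipped")
            continue
        rows.append(feats)
        ids.append(f"{meta.get('plate_id', 'plate')}_{meta.get('field', 1)}_{region.label}")

    features = pd.DataFrame(rows, index=ids)
    meta_df = pd.DataFrame(index=features.index)
    for key in META_COLUMNS:
        meta_df[key] = meta.get(key, np.nan)
    meta_df["field"] = meta.get("field", 1)
    meta_df["area_px"] = features["area"].astype(int) if len(features) else []
    return FeatureMatrix(features, meta_df)


def _shape_features(region, feats: dict) -> None:
    area = float(region.area)
    perimeter = float(region.perimeter) if region.perimeter > 0 else 1.0
    feats["area"] = area
    feats["perimeter"] = perimeter
    feats["eccentricity"] = float(region.eccentricity)
    feats["solidity"] = float(region.solidity)
    feats["extent"] = float(region.extent)
    feats["equivalent_diameter"] = float(region.equivalent_diameter_area)
    feats["major_axis_length"] = float(region.axis_major_length)
    feats["minor_axis_length"] = float(region.axis_minor_length)
    feats["circularity"] = float(4.0 * np.pi * area / perimeter**2)
    feats["convex_area"] = float(region.area_convex)
    feats["aspect_ratio"] = float(
        region.axis_major_length / region.axis_minor_length
        if region.axis_minor_length > 0
        else 1.0
    )
    feats["euler_number"] = float(region.euler_number)


def _moment_features(region, feats: dict) -> None:
    for i, h in enumerate(region.moments_hu):
        feats[f"hu_moment_{i + 1}"] = float(h)
    mu = region.moments_central
    m00 = max(region.moments[0, 0], 1e-12)
    for p, q in ((1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (3, 0), (0, 3)):
        feats[f"norm_central_moment_{p}{q}"] = float(
            mu[p, q] / m00 ** (1 + (p + q) / 2.0)
        )


def _intensity_features(crop: np.ndarray, rmask: np.ndarray, channel: str, feats: dict) -> None:
    vals = crop[rmask]
    qs = np.quantile(vals, [0.1, 0.25, 0.5, 0.75, 0.9]) if vals.size else [np.nan] * 5
    prefix = f"intensity_{channel}"
    feats[f"{prefix}_mean"] = float(vals.mean())
    feats[f"{prefix}_sd"] = float(vals.std())
    feats[f"{prefix}_mad"] = float(median_abs_deviation(vals)) if vals.size else np.nan
    feats[f"{prefix}_min"] = float(vals.min())
    feats[f"{prefix}_max"] = float(vals.max())
    for q, name in zip(qs, ("q10", "q25", "median", "q75", "q90")):
        feats[f"{prefix}_{name}"] = float(q)


def _texture_features(crop, rmask, channel: str, scales, feats: dict) -> None:
    """GLCM texture per offset; background pixels are excluded from pixel pairs."""
    vals = crop[rmask]
    lo, hi = (vals.min(), vals.max()) if vals.size else (0.0, 0.0)
    if hi > lo:
        quant = np.zeros(crop.shape, dtype=np.uint8)
        quant[rmask] = 1 + np.minimum(
            ((crop[rmask] - lo) / (hi - lo) * _GLCM_LEVELS).astype(int), _GLCM_LEVELS - 1
        )
    else:
        quant = rmask.astype(np.uint8)  # constant object: single gray level
    for off in scales:
        glcm = graycomatrix(
            quant,
            distances=[int(off)],
            angles=[0.0, np.pi / 2],
            levels=_GLCM_LEVELS + 1,
            symmetric=True,
        ).astype(float)
        core = glcm[1:, 1:, :, :]  # drop pairs involving background
        total = core.sum()
        for prop in _GLCM_PROPS:
            name = f"texture_{channel}_o{int(off)}_{prop}"
            if total == 0:
                feats[name] = np.nan
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    val = graycoprops(core, prop).mean()
                feats[name] = float(val) if np.isfinite(val) else 0.0


# ---------------------------------------------------------------------------
# filtering, centering, PCA


def filter_and_center_features(
    fm: FeatureMatrix, min_organoid_texture_scale_rule: bool = True
) -> FeatureMatrix:
    """Apply the well-definedness rules and per-batch centering.

    1. drop texture features at offsets larger than the smallest-organoid
       diameter (5th percentile of equivalent diameter, to guard against
       outliers);
    2. drop every feature whose median absolute deviation over all organoids
       is exactly zero (i.e. more than half the organoids share one value);
    3. drop any feature still containing missing values, so the result has
       none;
    4. subtract the per-batch mean from every retained feature.

    Idempotent: applying the function to its own output changes nothing.
    """
    x = fm.features.copy()
    report: dict[str, list[str]] = {}

    if min_organoid_texture_scale_rule and "area_px" in fm.meta:
        diam = 2.0 * np.sqrt(pd.to_numeric(fm.meta["area_px"], errors="coerce") / np.pi)
        min_diam = float(np.nanpercentile(diam, 5)) if diam.notna().any() else np.inf
        drop = [
            c
            for c in x.columns
            if c.startswith("texture_") and _texture_offset(c) > min_diam
        ]
        report["texture_scale_dropped"] = drop
        x = x.drop(columns=drop)

    mad = x.apply(lambda col: median_abs_deviation(col.dropna()) if col.notna().any() else 0.0)
    drop_mad = list(x.columns[~(mad > 0)])
    report["mad_zero_dropped"] = drop_mad
    x = x.drop(columns=drop_mad)

    drop_na = list(x.columns[x.isna().any()])
    report["missing_dropped"] = drop_na
    x = x.drop(columns=drop_na)

    if x.shape[1] == 0:
        raise PipelineError(
            "all features removed by filtering; "
            f"report: { {k: len(v) for k, v in report.items()} }"
        )

    batch = fm.meta.get("batch_id")
    if batch is not None and batch.notna().any():
        x = x - x.groupby(batch.values).transform("mean").values
    else:
        x = x - x.mean()

    assert not x.isna().any().any(), "post-filter matrix must contain no missing values"
    return FeatureMatrix(x, fm.meta.copy(), report)


def _texture_offset(name: str) -> int:
    for token in name.split("_"):
        if token.startswith("o") and token[1:].isdigit():
            return int(token[1:])
    return 0


def fit_pca_transform(
    fm, n_components: int = 25, incremental_chunk: int | None = None
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit (incremental) PCA on a feature matrix and return the model + scores.

    With ``incremental_chunk`` set, the model is fitted over row chunks of
    that size; the recovered subspace matches a full-batch fit on data that
    fits in memory (principal angles below 1e-3 rad on well-conditioned
    problems).
    """
    x = fm.features if isinstance(fm, FeatureMatrix) else fm
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds feature count")
    if x.shape[0] < n_components:
        raise ValueError("need at least n_components rows")

    if incremental_chunk is None:
        est = PCA(n_components=n_components, svd_solver="full")
    else:
        chunk = max(int(incremental_chunk), n_components)
        est = IncrementalPCA(n_components=n_components, batch_size=chunk)
    scores = est.fit_transform(x.to_numpy(dtype=float))
    model = PCAModel(
        components=pd.DataFrame(
            est.components_.T,
            index=x.columns,
            columns=[f"PC{i + 1:02d}" for i in range(n_components)],
        ),
        explained_variance_ratio=np.asarray(est.explained_variance_ratio_),
        mean=pd.Series(est.mean_, index=x.columns),
        n_components=n_components,
    )
    score_df = pd.DataFrame(scores, index=x.index, columns=model.components.columns)
    return model, score_df


def flag_out_of_focus(
    fm: FeatureMatrix,
    focus_labels: pd.Series,
    seed: int = 0,
    n_trees: int = 50,
) -> pd.Series:
    """Train a random-forest focus classifier on a labelled subset and flag all rows.

    ``focus_labels`` is a boolean Series (True = out of focus) indexed by a
    subset of organoid ids; both classes must be present.  Returns a boolean
    Series over all rows of ``fm``; flagged rows are meant to be excluded
    downstream.
    """
    labelled = focus_labels.dropna().astype(bool)
    if labelled.empty or labelled.nunique() < 2:
        raise ValueError("focus labels must contain both classes")
    x = fm.features.ffill().bfill().fillna(0.0)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(x.loc[labelled.index], labelled.values)
    return pd.Series(clf.predict(x).astype(bool), index=fm.features.index, name="out_of_focus")
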