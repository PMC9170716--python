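"""Control-anchored live/dead classification and dose-response summaries.

A random forest with 10 trees is trained per organoid line on raw
single-organoid features to separate DMSO-treated (live) organoids from
bortezomib / SN-38 positive controls at their two highest concentrations
(dead), with a 60/40 stratified train-validation split.  Per-organoid dead
calls are averaged within wells into a score in [0, 1] indicating how lethal
a treatment was.  Plate-level luminescence (CTG) readouts are edge-corrected
with a local (loess-style) surface fit over well coordinates and normalised
to the DMSO median, and 5-point five-fold dilution series are summarised by
a three-parameter Hill curve with an AUC in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix
from .imaging import CHANNELS
from .synthetic_data import NEGATIVE_CONTROL, POSITIVE_CONTROLS


@dataclass
class LDCModel:
    """A per-line live/dead classifier (ensemble of 10 decision trees)."""

    classifier: RandomForestClassifier
    line_id: str
    channels: tuple[str, ...]  # channels whose features were available
    feature_names: list[str]
    validation_accuracy: float
    validation_auroc: float
    split: tuple[float, float] = (0.6, 0.4)

    def predict_dead_probability(self, features: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_names) - set(features.columns)
        if missing:
            raise KeyError(f"feature schema mismatch; missing {sorted(missing)[:5]} ...")
        x = features[self.feature_names].to_numpy(dtype=float)
        return self.classifier.predict_proba(x)[:, list(self.classifier.classes_).index(1)]


@dataclass
class HillFit:
    """v(c) = E_inf + (1 - E_inf) / (1 + (c / EC50)^slope), with E_0 = 1."""

    ec50: float
    slope: float
    e_inf: float
    auc: float
    e0: float = 1.0
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    method: str = "hill"

    def predict(self, doses) -> np.ndarray:
        return _hill(np.asarray(doses, dtype=float), self.ec50, self.slope, self.e_inf)


# ---------------------------------------------------------------------------
# live/dead classification


def _control_classes(fm: FeatureMatrix, line_id: str, pos_top_k: int = 2):
    meta = fm.meta
    in_line = meta["line_id"] == line_id
    live = in_line & (meta["treatment"] == NEGATIVE_CONTROL)
    dead = pd.Series(False, index=meta.index)
    for drug in POSITIVE_CONTROLS:
        rows = in_line & (meta["treatment"] == drug)
        if rows.any():
            concs = sorted(pd.unique(meta.loc[rows, "concentration"].dropna()))
            top = set(concs[-pos_top_k:])
            dead |= rows & meta["concentration"].isin(top)
    return live, dead


def select_channel_features(feature_names, channel_mask=None) -> list[str]:
    """Keep features that are channel-free or derived from a retained channel.

    ``channel_mask`` lists the channels *retained* (ablation experiments
    train on DNA and/or actin features alone); ``None`` keeps everything.
    """
    if channel_mask is None:
        return list(feature_names)
    allowed = set(channel_mask)
    unknown = allowed - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    kept = []
    for name in feature_names:
        owners = [ch for ch in CHANNELS if ch in name]
        if not owners or all(ch in allowed for ch in owners):
            kept.append(name)
    return kept


def train_live_dead_classifier(
    fm: FeatureMatrix,
    line_id: str,
    channel_mask=None,
    seed: int = 0,
    n_trees: int = 10,
    pos_top_k: int = 2,
) -> LDCModel:
    """Train one line's live/dead classifier on its control wells.

    Negative controls (DMSO) are the live class; bortezomib and SN-38 at
    their two highest screened concentrations are the dead class.  The data
    are split 60/40 (stratified) and validation accuracy / AUROC are stored
    on the model.
    """
    live, dead = _control_classes(fm, line_id, pos_top_k)
    if not live.any() or not dead.any():
        raise ValueError(f"line {line_id!r} lacks a control class for LDC training")
    for name, m in (("live", live), ("dead", dead)):
        if m.sum() < 50:
            warnings.warn(f"only {int(m.sum())} {name} controls for line {line_id}")

    cols = select_channel_features(fm.feature_names, channel_mask)
    rows = live | dead
    x = fm.features.loc[rows, cols].to_numpy(dtype=float)
    y = dead[rows].astype(int).to_numpy()
    x_tr, x_val, y_tr, y_val = train_test_split(
        x, y, test_size=0.4, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_val)
    proba = clf.predict_proba(x_val)[:, list(clf.classes_).index(1)]
    return LDCModel(
        classifier=clf,
        line_id=line_id,
        channels=tuple(channel_mask) if channel_mask is not None else CHANNELS,
        feature_names=cols,
        validation_accuracy=float(accuracy_score(y_val, pred)),
        validation_auroc=float(roc_auc_score(y_val, proba)) if len(set(y_val)) > 1 else np.nan,
    )


def evaluate_on_line(model: LDCModel, fm: FeatureMatrix, line_id: str,
                     pos_top_k: int = 2) -> dict:
    """Apply a trained classifier to another line's control wells (generalisability)."""
    live, dead = _control_classes(fm, line_id, pos_top_k)
    rows = live | dead
    if not rows.any():
        raise ValueError(f"no control organoids for line {line_id!r}")
    p = model.predict_dead_probability(fm.features.loc[rows])
    y = dead[rows].astype(int).to_numpy()
    out = {"line_id": line_id, "accuracy": float(accuracy_score(y, p >= 0.5))}
    out["auroc"] = float(roc_auc_score(y, p)) if len(set(y)) > 1 else np.nan
    return out


def score_well_viability(
    model: LDCModel, fm: FeatureMatrix, cross_line: bool = False, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-well mean of the binary dead call: 0 = all live, 1 = all dead.

    By default only wells of the model's own line are scored; ``cross_line``
    applies the model to every line in the table.  Wells without organoids do
    not appear in the output.
    """
    meta = fm.meta
    rows = pd.Series(True, index=meta.index) if cross_line else meta["line_id"] == model.line_id
    if not rows.any():
        return pd.DataFrame(
            columns=["plate_id", "row", "col", "line_id", "treatment",
                     "concentration", "score", "n_organoids"]
        )
    p = model.predict_dead_probability(fm.features.loc[rows])
    calls = (p >= threshold).astype(float)
    sub = meta.loc[rows, ["plate_id", "row", "col", "line_id", "treatment", "concentration"]]
    sub = sub.assign(dead=calls)
    grouped = (
        sub.groupby(["plate_id", "row", "col", "line_id", "treatment"], dropna=False)
        .agg(concentration=("concentration", "first"), score=("dead", "mean"),
             n_organoids=("dead", "size"))
        .reset_index()
    )
    return grouped


# ---------------------------------------------------------------------------
# CTG plate normalisation


def normalize_ctg_plate(luminescence, layout, loess_span: float = 0.75) -> pd.DataFrame:
    """Edge-correct a 384-well luminescence plate and normalise to DMSO.

    A local weighted linear (loess-style) surface is fitted over well
    coordinates using all wells -- treatment effects are absorbed as noise --
    and each well is divided by the surface at its position; afterwards all
    wells are divided by the median of the DMSO wells, which is therefore
    exactly 1 in the output.
    """
    wells = layout.wells.copy()
    values = _coerce_plate_values(luminescence, wells)
    dmso = wells["role"] == "negative_control"
    if not dmso.any():
        raise ValueError("plate has no DMSO wells to normalise against")
    if dmso.sum() < 8:
        warnings.warn(f"only {int(dmso.sum())} DMSO wells; normalisation may be unstable")

    surface = _loess_surface(
        wells["row"].to_numpy(float), wells["col"].to_numpy(float), values, loess_span
    )
    surface = surface / surface.mean()
    corrected = values / np.maximum(surface, 1e-12)
    med = float(np.median(corrected[dmso.to_numpy()]))
    if med <= 0:
        raise ValueError("non-positive DMSO median after edge correction")
    out = wells[["row", "col", "line_id", "treatment", "concentration", "role"]].copy()
    out["raw"] = values
    out["normalized"] = corrected / med
    return out


def _coerce_plate_values(luminescence, wells: pd.DataFrame) -> np.ndarray:
    if isinstance(luminescence, pd.DataFrame) and {"row", "col", "value"} <= set(
        luminescence.columns
    ):
        keyed = luminescence.set_index(["row", "col"])["value"]
        vals = np.array([keyed.loc[(r, c)] for r, c in zip(wells["row"], wells["col"])], float)
    else:
        arr = np.asarray(luminescence, dtype=float)
        if arr.shape != (16, 24):
            raise ValueError("luminescence must be a 16x24 array or a (row, col, value) table")
        vals = arr[wells["row"].to_numpy(int) - 1, wells["col"].to_numpy(int) - 1]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite luminescence values")
    return vals


def _loess_surface(rows, cols, values, span: float, robust_iter: int = 2) -> np.ndarray:
    """Local weighted linear regression over plate coordinates (tricube weights).

    Cleveland-style robustness iterations downweight outlying wells (strong
    treatment effects, dead wells) so they do not deform the plate-trend
    surface they are corrected against.
    """
    n = len(values)
    k = max(8, int(np.ceil(span * n)))
    k = min(k, n)
    pts = np.column_stack([rows, cols])
    delta = np.ones(n)
    fitted = np.asarray(values, dtype=float).copy()
    for _ in range(robust_iter + 1):
        for i in range(n):
            d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
            dk = np.partition(d, k - 1)[k - 1] or 1.0
            w = np.clip(1 - (d / dk) ** 3, 0, None) ** 3 * delta
            use = w > 0
            design = np.column_stack([np.ones(int(use.sum())), pts[use]])
            sw = np.sqrt(w[use])
            coef, *_ = np.linalg.lstsq(design * sw[:, None], values[use] * sw, rcond=None)
            fitted[i] = np.array([1.0, rows[i], cols[i]]) @ coef
        resid = values - fitted
        s = np.median(np.abs(resid)) or np.std(resid) or 1.0
        delta = np.clip(1 - (resid / (6.0 * s)) ** 2, 0, None) ** 2
    return fitted


# ---------------------------------------------------------------------------
# Hill dose-response


def _hill(c, ec50, slope, e_inf):
    return e_inf + (1.0 - e_inf) / (1.0 + (c / ec50) ** slope)


def hill_auc(ec50: float, slope: float, e_inf: float, dose_range, n_grid: int = 201) -> float:
    """AUC in [0, 1]: mean of (1 - min(v, 1)) over the tested log10-dose interval.

    0 means no effect anywhere on the tested range, 1 a complete kill
    everywhere.  Pointwise-lower response curves never decrease the AUC.
    """
    lo, hi = float(np.min(dose_range)), float(np.max(dose_range))
    xs = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    v = _hill(10.0**xs, ec50, slope, e_inf)
    return float(np.trapezoid(1.0 - np.minimum(v, 1.0), xs) / (xs[-1] - xs[0]))


def fit_hill_auc(doses, responses, n_grid: int = 201) -> HillFit:
    """Least-squares Hill fit (E_0 fixed at 1) plus normalised AUC.

    Expects >= 4 distinct positive doses (the screen uses 5 five-fold
    dilutions) and non-negative normalised viabilities.  On optimisation
    failure the fit is flagged and the AUC falls back to the trapezoid over
    the observed points.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    if not np.isfinite(responses).all() or not np.isfinite(doses).all():
        raise ValueError("non-finite doses or responses")
    if (doses <= 0).any():
        raise ValueError("doses must be positive (molar)")
    if (responses < 0).any():
        raise ValueError("responses must be non-negative")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses")

    log_d = np.log10(doses)

    def resid(theta):
        ec50, slope, e_inf = 10.0 ** theta[0], 10.0 ** theta[1], theta[2]
        return _hill(doses, ec50, slope, e_inf) - responses

    lo = [log_d.min() - 4.0, np.log10(0.05), 0.0]
    hi = [log_d.max() + 4.0, np.log10(20.0), 1.0]
    e0 = float(np.clip(responses.min(), 0.0, 1.0))
    starts = [
        [np.median(log_d), 0.0, e0],
        [np.median(log_d), 0.0, 0.0],
        [log_d.max(), 0.0, 0.0],
        [log_d.mean(), np.log10(2.0), e0],
        [log_d.min(), 0.0, min(e0 + 0.2, 1.0)],
    ]
    best = None
    for s in starts:
        try:
            res = least_squares(resid, np.clip(s, lo, hi), bounds=(lo, hi))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        order = np.argsort(log_d)
        auc = float(
            np.trapezoid(1 - np.minimum(responses[order], 1.0), log_d[order])
            / (log_d.max() - log_d.min())
        )
        warnings.warn("Hill fit failed; reporting trapezoid AUC")
        return HillFit(np.nan, np.nan, np.nan, auc, residuals=np.array([]),
                       converged=False, method="trapezoid")

    # among (near-)equal-cost solutions prefer the exact no-effect curve, so
    # flat dose-response data yields E_inf = 1 and AUC = 0 exactly
    sse_best = 2.0 * best.cost
    sse_flat = float(((1.0 - responses) ** 2).sum())
    if sse_flat <= sse_best * (1.0 + 1e-9) + 1e-12:
        ec50 = float(10.0 ** np.median(log_d))
        return HillFit(ec50, 1.0, 1.0, 0.0, residuals=1.0 - responses,
                       converged=True)

    ec50, slope, e_inf = 10.0 ** best.x[0], 10.0 ** best.x[1], float(best.x[2])
    auc = hill_auc(ec50, slope, e_inf, doses, n_grid)
    return HillFit(float(ec50), float(slope), e_inf, auc,
                   residuals=resid(best.x), converged=bool(best.success))
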