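"""Multi-view factor analysis linking morphology, size, omics and drug activity.

Eleven organoid lines x 2 replicates give 22 samples described by five views:
organoid size (large-component location of a two-component log-normal mixture
fitted to DMSO organoid areas; 1 feature), binary somatic mutations, gene
expression (top 10% of genes by coefficient of variation), mean DMSO
morphology in 25-PC space, and per-drug AUROC activity for drugs active in at
least one observation.  After per-feature standardisation and per-view
scaling to unit total variance, a k = 3 linear factor model Y_v ~ Z W_v^T is
fitted jointly across views by alternating least squares (samples missing
from a view are excluded from that view's objective).  Factor scores for
drug-perturbed morphology profiles are obtained by multiplying scaled average
profiles with the pseudoinverse of the learnt morphology loading matrix, and
loading vectors are interrogated with preranked GSEA (permutation null) and
per-target ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

DEFAULT_K = 3


@dataclass
class ViewScaling:
    """Per-feature standardisation plus per-view total-variance scaling."""

    mean: pd.Series
    sd: pd.Series
    view_factor: float

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.mean.index] - self.mean) / self.sd * self.view_factor


@dataclass
class MultiViewDataset:
    """Aligned sample x feature views (missing samples allowed per view)."""

    views: dict[str, pd.DataFrame]
    samples: list[str]
    scaling: dict[str, ViewScaling] | None = None

    def view_dims(self) -> dict[str, tuple[int, int]]:
        return {v: df.shape for v, df in self.views.items()}


@dataclass
class FactorModel:
    k: int
    scores: pd.DataFrame  # samples x k
    loadings: dict[str, pd.DataFrame]  # view -> features x k
    noise_variance: dict[str, float]
    variance_explained: pd.DataFrame  # k x views, percent
    scaling: dict[str, ViewScaling] | None = None
    objective_trace: list = field(default_factory=list)
    n_iter: int = 0


@dataclass
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    fdr: float | None
    n_permutations: int
    n_genes: int
    set_size: int


# ---------------------------------------------------------------------------
# view assembly


def fit_lognormal_size(areas, seed: int = 0) -> float:
    """Location (log-mean) of the large component of a 2-component log-normal mixture.

    Falls back to a single log-normal fit (the plain log-mean) when the
    mixture degenerates or fails to converge.
    """
    log_a = np.log(np.asarray(areas, dtype=float))
    log_a = log_a[np.isfinite(log_a)]
    if log_a.size < 10:
        return float(np.mean(log_a)) if log_a.size else np.nan
    try:
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        gm.fit(log_a.reshape(-1, 1))
        if not gm.converged_ or min(gm.weights_) < 0.02:
            raise ValueError
        return float(gm.means_.max())
    except Exception:
        warnings.warn("size mixture fit degenerate; using single log-normal location")
        return float(np.mean(log_a))


def assemble_views(
    fm=None,
    pc_scores: pd.DataFrame | None = None,
    activity: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    mutations: pd.DataFrame | None = None,
    sample_column: str = "batch_id",
    expression_cv_fraction: float = 0.10,
    seed: int = 0,
) -> MultiViewDataset:
    """Build and scale the five views from pipeline outputs.

    ``fm`` (a FeatureMatrix) supplies DMSO organoids for the size view;
    ``pc_scores`` (aligned with ``fm``) the morphology view (per-sample mean
    DMSO 25-PC profile).  ``activity`` is a tidy table (sample, unit, auroc,
    active); only units active in >= 1 sample are kept.  ``expression`` is a
    sample x gene matrix filtered to the top ``expression_cv_fraction`` of
    genes by coefficient of variation (ties broken by gene id order);
    ``mutations`` a binary sample x gene matrix, possibly missing samples.
    Views are standardised feature-wise and scaled to unit total variance.
    """
    raw: dict[str, pd.DataFrame] = {}
    if fm is not None:
        dmso = fm.meta["treatment"] == "DMSO"
        samples = fm.meta.loc[dmso, sample_column]
        areas = fm.meta.loc[dmso, "area_px"].astype(float)
        size = (
            pd.DataFrame({"sample": samples.values, "area": areas.values})
            .groupby("sample")["area"]
            .apply(lambda a: fit_lognormal_size(a.to_numpy(), seed))
        )
        raw["size"] = size.to_frame("log_size_large")
        if pc_scores is not None:
            morph = pc_scores.loc[dmso[dmso].index].copy()
            morph[sample_column] = samples.values
            raw["morphology"] = morph.groupby(sample_column).mean()
    if expression is not None:
        raw["expression"] = select_high_cv_genes(expression, expression_cv_fraction)
    if mutations is not None:
        raw["mutations"] = mutations.astype(float)
    if activity is not None:
        mat = activity.pivot_table(index="sample", columns="unit", values="auroc")
        if "active" in activity.columns:
            ever_active = activity.groupby("unit")["active"].any()
            mat = mat.loc[:, ever_active[ever_active].index]
        raw["drug_activity"] = mat

    if not raw:
        raise ValueError("no views supplied")
    samples = sorted(set().union(*[set(df.index) for df in raw.values()]))
    views, scaling = {}, {}
    for name, df in raw.items():
        df = df.reindex([s for s in samples if s in df.index]).astype(float)
        views[name], scaling[name] = scale_view(df)
    return MultiViewDataset(views, samples, scaling)


def select_high_cv_genes(expression: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep the top ``fraction`` of genes by coefficient of variation.

    The CV is sd/|mean|; ties are broken deterministically by gene id order.
    """
    mean = expression.mean()
    sd = expression.std(ddof=1)
    cv = sd / mean.abs().replace(0.0, np.nan)
    cv = cv.fillna(0.0)
    n_keep = max(int(np.ceil(fraction * expression.shape[1])), 1)
    order = pd.DataFrame({"cv": cv, "gene": cv.index}).sort_values(
        ["cv", "gene"], ascending=[False, True]
    )
    keep = sorted(order["gene"].iloc[:n_keep])
    return expression[keep]


def scale_view(df: pd.DataFrame) -> tuple[pd.DataFrame, ViewScaling]:
    """Feature-wise z-score, then scale the view to unit total variance."""
    mean = df.mean()
    sd = df.std(ddof=0).replace(0.0, 1.0)
    z = (df - mean) / sd
    total_var = float((z.var(ddof=0)).sum())
    factor = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
    return z * factor, ViewScaling(mean, sd, factor)


# ---------------------------------------------------------------------------
# factor model (alternating least squares)


def fit_factor_model(
    data: MultiViewDataset,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    ridge: float = 1e-6,
) -> FactorModel:
    """Fit Y_v ~ Z W_v^T jointly across views by alternating least squares.

    Missing samples are excluded from their view's objective.  After
    convergence the scores are orthogonalised (SVD rotation) and loadings
    refit, so each factor's variance explained is additive per view; factors
    are ordered by total variance explained and signed so their largest
    loading (or their correlation with the size view, when present and
    substantial) is positive.
    """
    samples = data.samples
    n = len(samples)
    if k >= n:
        raise ValueError("need more samples than factors")
    views = {v: df for v, df in data.views.items()}
    masks = {v: np.array([s in df.index for s in samples]) for v, df in views.items()}
    mats = {
        v: df.reindex([s for s in samples if s in df.index]).to_numpy(dtype=float)
        for v, df in views.items()
    }

    stacked = np.hstack(
        [_filled(views[v], samples) for v in sorted(views)]
    )
    u, s, _ = np.linalg.svd(stacked, full_matrices=False)
    z = u[:, :k] * s[:k]

    eye = np.eye(k)
    trace: list[float] = []
    for it in range(max_iter):
        ws = {}
        for v in sorted(views):
            zp = z[masks[v]]
            ws[v] = np.linalg.solve(zp.T @ zp + ridge * eye, zp.T @ mats[v]).T
        for i in range(n):
            a = ridge * eye.copy()
            b = np.zeros(k)
            for v in sorted(views):
                if masks[v][i]:
                    w = ws[v]
                    a += w.T @ w
                    b += w.T @ mats[v][_row_index(masks[v], i)]
            z[i] = np.linalg.solve(a, b)
        obj = sum(
            float(((mats[v] - z[masks[v]] @ ws[v].T) ** 2).sum()) for v in views
        )
        if trace and trace[-1] - obj < tol * max(trace[0], 1e-12):
            trace.append(min(obj, trace[-1]))
            break
        trace.append(obj)

    # rotate to orthogonal scores and refit loadings without ridge
    uu, ss, vv = np.linalg.svd(z, full_matrices=False)
    z = uu * ss
    ws = {}
    for v in sorted(views):
        zp = z[masks[v]]
        ws[v] = np.linalg.lstsq(zp, mats[v], rcond=None)[0].T

    ve = _variance_explained(z, mats, masks, ws)
    order = np.argsort(-ve.sum(axis=1))
    z = z[:, order]
    ws = {v: w[:, order] for v, w in ws.items()}
    ve = ve[order]

    for f in range(k):
        sign = _factor_sign(z[:, f], ws, f, views, masks, samples)
        z[:, f] *= sign
        for v in ws:
            ws[v][:, f] *= sign

    fnames = [f"F{j + 1}" for j in range(k)]
    noise = {
        v: float(((mats[v] - z[masks[v]] @ ws[v].T) ** 2).mean()) for v in views
    }
    model = FactorModel(
        k=k,
        scores=pd.DataFrame(z, index=samples, columns=fnames),
        loadings={
            v: pd.DataFrame(ws[v], index=views[v].columns, columns=fnames) for v in views
        },
        noise_variance=noise,
        variance_explained=pd.DataFrame(
            ve, index=fnames, columns=sorted(views)
        )[sorted(views)],
        scaling=data.scaling,
        objective_trace=trace,
        n_iter=len(trace),
    )
    return model


def _filled(df: pd.DataFrame, samples) -> np.ndarray:
    return df.reindex(samples).fillna(0.0).to_numpy(dtype=float)


def _row_index(mask: np.ndarray, i: int) -> int:
    return int(mask[:i].sum())


def _variance_explained(z, mats, masks, ws) -> np.ndarray:
    """Percent variance each factor alone explains in each view (k x views)."""
    names = sorted(mats)
    k = z.shape[1]
    ve = np.zeros((k, len(names)))
    for j, v in enumerate(names):
        y = mats[v]
        ss = float((y**2).sum())
        if ss == 0:
            continue
        zp = z[masks[v]]
        for f in range(k):
            recon = np.outer(zp[:, f], ws[v][:, f])
            ve[f, j] = 100.0 * max(1.0 - float(((y - recon) ** 2).sum()) / ss, 0.0)
    return ve


def variance_explained_for_scores(scores, views: dict[str, pd.DataFrame], samples) -> pd.DataFrame:
    """Variance decomposition of given factor scores over given (scaled) views.

    Loadings are refit by least squares per view; used to compute the
    ground-truth decomposition of simulated data for comparison with a fitted
    model.
    """
    z = np.asarray(scores, dtype=float)
    masks = {v: np.array([s in df.index for s in samples]) for v, df in views.items()}
    mats = {
        v: df.reindex([s for s in samples if s in df.index]).to_numpy(float)
        for v, df in views.items()
    }
    ws = {}
    for v in sorted(views):
        zp = z[masks[v]]
        ws[v] = np.linalg.lstsq(zp, mats[v], rcond=None)[0].T
    ve = _variance_explained(z, mats, masks, ws)
    return pd.DataFrame(
        ve, index=[f"F{j + 1}" for j in range(z.shape[1])], columns=sorted(views)
    )


def subspace_correlations(z_reference, z_estimated) -> np.ndarray:
    """Correlation of each reference factor with its best reconstruction.

    Linear factor models are identified only up to an invertible mixing of
    the factors, so recovery is judged at the subspace level: each reference
    factor is regressed on all estimated factors and the correlation between
    the factor and its least-squares reconstruction is reported (1.0 = the
    factor lies in the estimated subspace).
    """
    zt = np.asarray(z_reference, dtype=float)
    ze = np.asarray(z_estimated, dtype=float)
    zt = zt - zt.mean(axis=0)
    ze = ze - ze.mean(axis=0)
    beta, *_ = np.linalg.lstsq(ze, zt, rcond=None)
    recon = ze @ beta
    out = np.empty(zt.shape[1])
    for f in range(zt.shape[1]):
        denom = zt[:, f].std() * recon[:, f].std()
        out[f] = np.corrcoef(zt[:, f], recon[:, f])[0, 1] if denom > 0 else 0.0
    return out


def total_variance_explained(scores, views: dict[str, pd.DataFrame], samples) -> pd.Series:
    """Percent of each (scaled) view's variance explained by all factors jointly.

    Loadings are refit by least squares; unlike the per-factor decomposition
    this quantity is invariant to factor rotation, so it is the right basis
    for comparing a fitted model against simulation ground truth.
    """
    z = np.asarray(scores, dtype=float)
    z = z - z.mean(axis=0)  # views are column-centered; compare on the same footing
    out = {}
    for v in sorted(views):
        df = views[v]
        mask = np.array([s in df.index for s in samples])
        y = df.reindex([s for s in samples if s in df.index]).to_numpy(float)
        zp = z[mask]
        w = np.linalg.lstsq(zp, y, rcond=None)[0]
        ss = float((y**2).sum())
        out[v] = 100.0 * (1.0 - float(((y - zp @ w) ** 2).sum()) / ss) if ss > 0 else 0.0
    return pd.Series(out)


def _factor_sign(zf, ws, f, views, masks, samples) -> float:
    if "size" in views:
        size = views["size"].to_numpy(float).ravel()
        zp = zf[masks["size"]]
        if zp.std() > 0 and size.std() > 0:
            r = float(np.corrcoef(zp, size)[0, 1])
            if abs(r) > 0.3:
                return 1.0 if r >= 0 else -1.0
    best, val = 1.0, 0.0
    for v in sorted(ws):
        col = ws[v][:, f]
        i = int(np.argmax(np.abs(col)))
        if abs(col[i]) > val:
            val, best = abs(col[i]), (1.0 if col[i] >= 0 else -1.0)
    return best


# ---------------------------------------------------------------------------
# projection of perturbed profiles


def project_onto_factors(model: FactorModel, profiles: pd.DataFrame,
                         view: str = "morphology") -> pd.DataFrame:
    """Least-squares factor scores for new (drug-perturbed) profiles.

    ``profiles`` is a treatments x features matrix on the *raw* scale of the
    training view; it is scaled with the training view's stored
    standardisation, then multiplied with the pseudoinverse of the learnt
    loading matrix: Z = Y_scaled @ pinv(W^T), the least-squares solution of
    Y ~ Z W^T.  Projecting the model's own training rows reproduces the
    training scores up to the least-squares residual.
    """
    w = model.loadings[view].to_numpy(float)
    if model.scaling and view in model.scaling:
        y = model.scaling[view].apply(profiles).to_numpy(float)
    else:
        y = profiles[model.loadings[view].index].to_numpy(float)
    pinv = np.linalg.pinv(w.T)
    cond = np.linalg.cond(w)
    if cond > 1e8:
        warnings.warn(f"morphology loading matrix badly conditioned (cond={cond:.2g})")
    scores = y @ pinv
    return pd.DataFrame(scores, index=profiles.index, columns=model.scores.columns)


# ---------------------------------------------------------------------------
# preranked GSEA


def gsea_preranked(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 100_000,
    weight: float = 1.0,
    seed: int = 0,
    min_overlap: int = 5,
    _chunk: int = 5_000,
) -> GSEAResult:
    """Weighted running-sum enrichment of a gene set over a ranked list.

    The enrichment score is the maximum deviation of the running sum that
    increments by |score|^weight (normalised) at set members and decrements
    uniformly elsewhere.  The null is gene-label permutation; the p-value is
    one-sided among same-sign null scores, and NES = ES / mean |same-sign
    null ES|.
    """
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hits = np.isin(genes, list(gene_set))
    m = int(hits.sum())
    n_genes = len(genes)
    if m < min_overlap:
        raise ValueError(f"gene set overlaps only {m} ranked genes (< {min_overlap})")
    if m >= n_genes:
        raise ValueError("gene set covers the whole ranking; complement is empty")

    r = np.abs(scores) ** weight
    es = _running_es(np.flatnonzero(hits), r, n_genes)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(_chunk, n_perm - done)
        # b random m-subsets of positions, via partial argsort of random keys
        keys = rng.random((b, n_genes))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        idx.sort(axis=1)
        null[done : done + b] = _running_es_batch(idx, r, n_genes)
        done += b

    same = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, bool)
    n_same = int(same.sum())
    p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (n_same + 1)
    mean_same = float(np.abs(null[same]).mean()) if n_same else np.nan
    nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
    return GSEAResult(
        gene_set=getattr(gene_set, "name", "set"),
        es=float(es),
        nes=float(nes),
        p_value=float(p),
        fdr=None,
        n_permutations=n_perm,
        n_genes=n_genes,
        set_size=m,
    )


def gsea_collection(ranked: pd.Series, gene_sets: dict, n_perm: int = 10_000,
                    weight: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Run preranked GSEA for several sets and BH-adjust across them."""
    rows = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        res = gsea_preranked(ranked, members, n_perm, weight, seed + i)
        rows.append({"gene_set": name, "es": res.es, "nes": res.nes,
                     "p_value": res.p_value, "set_size": res.set_size})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def _running_es(hit_idx: np.ndarray, r: np.ndarray, n: int) -> float:
    """Signed extremum of the running sum, evaluated at its change points."""
    m = hit_idx.size
    rw = r[hit_idx]
    tot = rw.sum()
    if tot == 0:
        rw = np.ones(m)
        tot = float(m)
    h = np.cumsum(rw) / tot
    miss = 1.0 / (n - m)
    at_hit = h - (hit_idx + 1 - np.arange(1, m + 1)) * miss
    before = np.concatenate([[0.0], h[:-1]]) - (hit_idx - np.arange(m)) * miss
    cand = np.concatenate([at_hit, before])
    return float(cand[np.argmax(np.abs(cand))])


def _running_es_batch(hit_idx: np.ndarray, r: np.ndarray, n: int) -> np.ndarray:
    b, m = hit_idx.shape
    rw = r[hit_idx]
    tot = rw.sum(axis=1, keepdims=True)
    tot = np.where(tot == 0, 1.0, tot)
    h = np.cumsum(rw, axis=1) / tot
    miss = 1.0 / (n - m)
    ranks = np.arange(1, m + 1)
    at_hit = h - (hit_idx + 1 - ranks) * miss
    before = np.concatenate([np.zeros((b, 1)), h[:, :-1]], axis=1) - (
        hit_idx - (ranks - 1)
    ) * miss
    cand = np.concatenate([at_hit, before], axis=1)
    return cand[np.arange(b), np.argmax(np.abs(cand), axis=1)]


# ---------------------------------------------------------------------------
# target association (ANOVA)


def test_target_association(
    values: pd.Series, annotations: dict, min_drugs: int = 3
) -> pd.DataFrame:
    """Linear-model ANOVA of a per-drug quantity on target membership.

    For every target annotated on >= ``min_drugs`` of the drugs in ``values``
    (factor loadings or projected factor scores), fits value ~ 1[target] --
    equivalent to a two-group t test -- and reports t, p and BH FDR across
    targets.  Zero-variance inputs are flagged rather than tested.
    """
    values = values.dropna()
    targets: dict[str, list] = {}
    for drug in values.index:
        t = annotations.get(drug, annotations.get(str(drug).split("|")[0]))
        if t is not None:
            targets.setdefault(t, []).append(drug)
    rows = []
    for target in sorted(targets):
        drugs = targets[target]
        if len(drugs) < min_drugs:
            continue
        in_mask = values.index.isin(drugs)
        a, b = values[in_mask], values[~in_mask]
        if len(b) == 0:
            continue
        if np.isclose(values.var(ddof=0), 0.0):
            rows.append({"target": target, "n_drugs": len(a), "t": np.nan,
                         "p_value": np.nan, "zero_variance": True})
            continue
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"target": target, "n_drugs": len(a), "t": float(t_stat),
                     "p_value": float(p), "zero_variance": False})
    if len(rows) < 2:
        warnings.warn("fewer than two targets pass the minimum drug count")
    df = pd.DataFrame(rows)
    if len(df):
        ok = df["p_value"].notna()
        df["fdr"] = np.nan
        if ok.any():
            df.loc[ok, "fdr"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    return df
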