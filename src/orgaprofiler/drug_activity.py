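"""Drug activity as separability from DMSO, and mechanism-of-action clustering.

For every (line, treatment) a logistic regression is trained on 25-PC
organoid profiles to separate treated organoids from DMSO controls.  Its
coefficient vector -- the normal of the separating hyperplane -- is the drug
effect profile; its 10-fold cross-validated AUROC is the drug activity score.
A drug is "active" when its mean AUROC across lines strictly exceeds 0.85.
Active drugs are clustered hierarchically on the cosine distance between
concatenated, activity-scaled effect profiles, and mechanism-of-action
enrichment of the resulting tree nodes (minimum size 3, evaluated bottom-up)
is tested with one-sided Fisher's exact tests under Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score, train_test_split
from statsmodels.stats.multitest import multipletests

from .synthetic_data import NEGATIVE_CONTROL

DEFAULT_L2_GRID = tuple(np.logspace(-3, 3, 7))


def _lr_pipeline(c: float):
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    return Pipeline(
        [("scale", StandardScaler()), ("logistic", LogisticRegression(C=c, max_iter=1000))]
    )


@dataclass
class DrugEffectProfile:
    """Separating-hyperplane normal for one (drug, line), with AUROC activity."""

    drug: str
    line_id: str | None
    concentration: float | None
    coefficients: pd.Series  # raw logistic coefficients per PC
    direction: pd.Series  # unit-normalised copy
    auroc: float  # oriented and clipped to [0.5, 1]
    mean_shift: pd.Series  # mean(treated) - mean(control), for euclidean clustering
    n_treated: int = 0
    n_control: int = 0
    best_l2: float = np.nan
    cv_folds: int = 10


@dataclass
class ClusterTree:
    """Agglomerative dendrogram over treatment units."""

    linkage: np.ndarray
    labels: list[str]
    metric: str

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, assignments))

    def to_newick(self) -> str:
        node = to_tree(self.linkage)

        def render(n, parent_height):
            length = max(parent_height - n.dist, 0.0)
            if n.is_leaf():
                return f"{self.labels[n.id]}:{length:g}"
            return f"({render(n.left, n.dist)},{render(n.right, n.dist)}):{length:g}"

        return f"({render(node.left, node.dist)},{render(node.right, node.dist)});"


def fit_drug_effect_profile(
    pc_scores: pd.DataFrame,
    meta: pd.DataFrame,
    drug: str,
    line_id: str | None = None,
    concentration: float | None = None,
    l2_grid=DEFAULT_L2_GRID,
    seed: int = 0,
) -> DrugEffectProfile:
    """Fit one treatment-vs-DMSO logistic regression and score its AUROC.

    Organoids are split 50/50 (stratified); the L2 strength is chosen by
    5-fold cross-validated grid search on the first half, the final model is
    refit on the second half and its AUROC estimated by 10-fold cross
    validation on that half.  The AUROC is oriented (treated > control) and
    clipped to [0.5, 1]; the coefficient sign follows the orientation.
    """
    sel = pd.Series(True, index=meta.index)
    if line_id is not None:
        sel &= meta["line_id"] == line_id
    control = sel & (meta["treatment"] == NEGATIVE_CONTROL)
    treated = sel & (meta["treatment"] == drug)
    if concentration is not None:
        treated &= np.isclose(meta["concentration"].astype(float), concentration)
    n_t, n_c = int(treated.sum()), int(control.sum())
    if n_t == 0 or n_c == 0:
        raise ValueError(f"no treated or control organoids for {drug!r} / {line_id!r}")
    if min(n_t, n_c) < 30:
        warnings.warn(f"fewer than 30 organoids per arm for {drug!r} ({n_t}/{n_c})")

    rows = treated | control
    x = pc_scores.loc[rows[rows].index].to_numpy(dtype=float)
    y = treated[rows].astype(int).to_numpy()
    x_a, x_b, y_a, y_b = train_test_split(x, y, test_size=0.5, stratify=y, random_state=seed)

    inner = min(5, int(np.bincount(y_a).min()))
    if inner < 5:
        warnings.warn(f"reducing inner CV folds to {inner} for {drug!r}")
    grid = GridSearchCV(
        _lr_pipeline(1.0),
        {"logistic__C": list(l2_grid)},
        cv=StratifiedKFold(max(inner, 2), shuffle=True, random_state=seed),
        scoring="roc_auc",
    )
    grid.fit(x_a, y_a)
    best_c = float(grid.best_params_["logistic__C"])

    outer = min(10, int(np.bincount(y_b).min()))
    if outer < 10:
        warnings.warn(f"reducing outer CV folds to {outer} for {drug!r}")
    final = _lr_pipeline(best_c)
    aurocs = cross_val_score(
        final, x_b, y_b,
        cv=StratifiedKFold(max(outer, 2), shuffle=True, random_state=seed),
        scoring="roc_auc",
    )
    auroc = float(np.mean(aurocs))
    final.fit(x_b, y_b)
    # hyperplane normal back on the PC scale (undo the internal standardisation)
    scale = final.named_steps["scale"].scale_
    coef = (final.named_steps["logistic"].coef_.ravel() / scale).astype(float)
    if auroc < 0.5:
        auroc, coef = 1.0 - auroc, -coef
    auroc = float(np.clip(auroc, 0.5, 1.0))

    norm = np.linalg.norm(coef)
    cols = list(pc_scores.columns)
    shift = (
        pc_scores.loc[treated[treated].index].mean() - pc_scores.loc[control[control].index].mean()
    )
    return DrugEffectProfile(
        drug=drug,
        line_id=line_id,
        concentration=concentration,
        coefficients=pd.Series(coef, index=cols),
        direction=pd.Series(coef / norm if norm > 0 else coef, index=cols),
        auroc=auroc,
        mean_shift=shift,
        n_treated=n_t,
        n_control=n_c,
        best_l2=best_c,
        cv_folds=max(outer, 2),
    )


def call_active(profiles, threshold: float = 0.85) -> pd.DataFrame:
    """Mean AUROC per treatment unit across lines; active iff strictly above threshold."""
    rows = [
        {"unit": _unit_key(p), "drug": p.drug, "line_id": p.line_id, "auroc": p.auroc}
        for p in profiles
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("unit")
        .agg(drug=("drug", "first"), mean_auroc=("auroc", "mean"), n_lines=("auroc", "size"))
        .reset_index()
    )
    # strict inequality: a mean AUROC of exactly 0.85 is not active
    # (1e-9 guard absorbs float summation error in the mean)
    out["active"] = out["mean_auroc"] - threshold > 1e-9
    return out


def _unit_key(p: DrugEffectProfile) -> str:
    if p.concentration is None or (isinstance(p.concentration, float) and np.isnan(p.concentration)):
        return p.drug
    return f"{p.drug}|{p.concentration:g}"


def cluster_drug_profiles(
    profiles, method: str = "cosine", linkage: str = "average"
) -> ClusterTree:
    """Hierarchical clustering of active drugs' effect profiles.

    ``cosine``: each treatment unit is the concatenation over lines of its
    unit coefficient direction scaled by (AUROC - 0.5) * 2 (zero-filled for
    missing lines); distance = 1 - cosine similarity, so the per-line scaling
    weights lines by activity without changing drug-level direction.
    ``euclidean``: the per-unit mean treated-minus-control phenotype shift,
    averaged across lines.  ``pearson``: correlation distance on the same
    concatenated vectors.
    """
    profiles = list(profiles)
    by_unit: dict[str, dict[str, DrugEffectProfile]] = {}
    for p in profiles:
        by_unit.setdefault(_unit_key(p), {})[p.line_id or "_"] = p
    lines = sorted({ln for d in by_unit.values() for ln in d})
    n_pc = len(profiles[0].direction) if profiles else 0

    labels, vectors = [], []
    for unit in sorted(by_unit):
        d = by_unit[unit]
        if method in ("cosine", "pearson"):
            blocks = []
            for ln in lines:
                if ln in d:
                    p = d[ln]
                    blocks.append(p.direction.to_numpy() * (p.auroc - 0.5) * 2.0)
                else:
                    blocks.append(np.zeros(n_pc))
            vec = np.concatenate(blocks)
        else:
            vec = np.mean([p.mean_shift.to_numpy() for p in d.values()], axis=0)
        if not np.any(vec):
            warnings.warn(f"zero effect vector for {unit!r}; excluded from clustering")
            continue
        labels.append(unit)
        vectors.append(vec)
    if len(labels) < 3:
        raise ValueError("need at least 3 non-degenerate active treatments to cluster")

    x = np.asarray(vectors)
    metric = {"cosine": "cosine", "pearson": "correlation", "euclidean": "euclidean"}[method]
    condensed = pdist(x, metric=metric)
    z = scipy_linkage(condensed, method=linkage)
    return ClusterTree(z, labels, method)


def test_moa_enrichment(
    tree: ClusterTree, annotations: dict, min_size: int = 3
) -> pd.DataFrame:
    """Fisher target enrichment of every tree node with >= ``min_size`` leaves.

    Nodes are evaluated from the tree bottom to top; for each node, every
    drug-target annotation present among its leaves is tested one-sided
    against the remaining clustered drugs (unannotated drugs count as
    non-target).  P-values are Benjamini-Hochberg adjusted over all
    node x target tests.
    """
    if len({t for t in annotations.values() if t is not None}) < 2:
        raise ValueError("annotations must cover at least two targets")
    root, nodes = to_tree(tree.linkage, rd=True)
    n_leaves = len(tree.labels)
    target_of = {
        lbl: annotations.get(lbl, annotations.get(lbl.split("|")[0]))
        for lbl in tree.labels
    }
    total_by_target: dict[str, int] = {}
    for t in target_of.values():
        if t is not None:
            total_by_target[t] = total_by_target.get(t, 0) + 1

    records = []
    internal = sorted(
        (n for n in nodes if not n.is_leaf()), key=lambda n: (n.dist, n.id)
    )
    for node in internal:
        leaf_ids = node.pre_order(lambda leaf: leaf.id)
        if len(leaf_ids) < min_size:
            continue
        members = [tree.labels[i] for i in leaf_ids]
        member_targets = [target_of[m] for m in members]
        for target in sorted({t for t in member_targets if t is not None}):
            a = sum(t == target for t in member_targets)
            b = len(members) - a
            c = total_by_target.get(target, 0) - a
            d = (n_leaves - len(members)) - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            records.append(
                {
                    "node_id": node.id,
                    "node_size": len(members),
                    "height": node.dist,
                    "target": target,
                    "in_target": a,
                    "in_other": b,
                    "out_target": c,
                    "out_other": d,
                    "odds_ratio": odds,
                    "p_value": p,
                    "members": tuple(members),
                }
            )
    result = pd.DataFrame(records)
    if len(result):
        result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result
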