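"""Synthetic inputs with the statistical structure the organoid analysis assumes.

The real screen profiles patient-derived colorectal cancer organoid lines in
384-well plates: DMSO negative controls, bortezomib / SN-38 positive (dead)
controls, a clinical library screened at 5 five-fold dilutions, and a larger
single-concentration kinase/stemness library.  The raw imaging and expression
data are restricted-access, so every pipeline stage is exercised on
generators that emulate the structure the analysis relies on:

* line-specific two-component log-normal organoid-size mixtures;
* cystic (bright actin ring, dark lumen) vs solid (filled) architecture;
* dose-dependent dead fractions, dead organoids forming a distinct
  small-size / high-permeability cluster;
* drug-specific phenotype shift directions shared within mechanism-of-action
  (MoA) groups;
* a 22-sample x 5-view dataset generated from a known 3-factor linear model
  (11 lines x 2 replicates, replicates sharing factor scores up to jitter).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .features import FeatureMatrix
from .imaging import CHANNELS, ImageStack

N_ROWS, N_COLS, N_WELLS = 16, 24, 384
NEGATIVE_CONTROL = "DMSO"
POSITIVE_CONTROLS = ("bortezomib", "SN-38")

_TARGET_POOL = (
    "MEK", "EGFR", "mTOR", "CDK", "GSK-3", "AKT", "PLK", "AURK",
    "JAK", "Wnt", "IGF1R", "PI3K", "ATM", "RAF", "ERK", "FAK",
)


class CapacityError(ValueError):
    """More wells requested than a 384-well plate can hold."""


class ConfigError(ValueError):
    """Inconsistent simulation parameters."""


# ---------------------------------------------------------------------------
# plate layouts


@dataclass
class PlateLayout:
    """One 384-well plate: well -> (line, treatment, concentration, role)."""

    plate_id: str
    wells: pd.DataFrame  # row, col, line_id, treatment, concentration, role, batch_id, replicate

    def __post_init__(self) -> None:
        coords = list(zip(self.wells["row"], self.wells["col"]))
        if len(set(coords)) != len(coords):
            raise ValueError("well coordinates must be unique per plate")

    @property
    def n_assigned(self) -> int:
        return len(self.wells)

    @property
    def n_empty(self) -> int:
        return N_WELLS - len(self.wells)


def clinical_library_spec(n_drugs: int = 63, n_concentrations: int = 5,
                          top_concentration: float = 2.5e-6, dilution: float = 5.0,
                          seed: int = 0) -> pd.DataFrame:
    """A clinical-style library: ``n_drugs`` at five-fold dilution series."""
    rng = np.random.default_rng(seed)
    concs = [top_concentration / dilution**i for i in range(n_concentrations)][::-1]
    return pd.DataFrame(
        {
            "drug": [f"clin_{i + 1:03d}" for i in range(n_drugs)],
            "target": rng.choice(_TARGET_POOL, size=n_drugs),
            "concentrations": [tuple(concs)] * n_drugs,
        }
    )


def kistem_library_spec(n_drugs: int = 464, concentration: float = 7.5e-6,
                        seed: int = 0) -> pd.DataFrame:
    """A kinase/stem-cell-style library: every compound at one concentration."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "drug": [f"ki_{i + 1:03d}" for i in range(n_drugs)],
            "target": rng.choice(_TARGET_POOL, size=n_drugs),
            "concentrations": [(concentration,)] * n_drugs,
        }
    )


def generate_plate_layout(
    lines,
    library_spec: pd.DataFrame,
    controls_per_plate: int = 16,
    n_replicates: int = 1,
    seed: int = 0,
    pos_control_concentrations: tuple[float, float] = (5e-7, 2.5e-6),
    pos_wells_per_dose: int = 2,
) -> list[PlateLayout]:
    """Randomised 384-well layouts for a library screen across organoid lines.

    Every plate carries ``controls_per_plate`` DMSO negative controls and
    bortezomib / SN-38 positive controls at the two stated concentrations.
    Libraries too large for one plate are split across as many plates as
    needed, each with its own controls.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(lines, int):
        lines = [f"D{i + 1:03d}T" for i in range(lines)]
    n_pos = len(POSITIVE_CONTROLS) * len(pos_control_concentrations) * pos_wells_per_dose
    capacity = N_WELLS - controls_per_plate - n_pos
    if capacity <= 0:
        raise CapacityError(
            f"{controls_per_plate} negative + {n_pos} positive controls leave no "
            f"library capacity on a {N_WELLS}-well plate"
        )

    treatment_wells = [
        (row.drug, float(c))
        for row in library_spec.itertuples()
        for c in sorted(row.concentrations)
    ]

    plates: list[PlateLayout] = []
    for line in lines:
        for rep in range(1, n_replicates + 1):
            batch_id = f"{line}_b{rep}"
            chunks = [
                treatment_wells[i : i + capacity]
                for i in range(0, len(treatment_wells), capacity)
            ] or [[]]  # controls-only plate when the library is empty
            for pi, chunk in enumerate(chunks, start=1):
                entries = [
                    {"treatment": d, "concentration": c, "role": "library"}
                    for d, c in chunk
                ]
                entries += [
                    {"treatment": NEGATIVE_CONTROL, "concentration": np.nan,
                     "role": "negative_control"}
                    for _ in range(controls_per_plate)
                ]
                entries += [
                    {"treatment": drug, "concentration": float(c), "role": "positive_control"}
                    for drug in POSITIVE_CONTROLS
                    for c in pos_control_concentrations
                    for _ in range(pos_wells_per_dose)
                ]
                coords = [(r, c) for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1)]
                order = rng.permutation(len(coords))[: len(entries)]
                wells = pd.DataFrame(entries)
                wells["row"] = [coords[i][0] for i in order]
                wells["col"] = [coords[i][1] for i in order]
                wells["line_id"] = line
                wells["batch_id"] = batch_id
                wells["replicate"] = rep
                wells = wells.sort_values(["row", "col"]).reset_index(drop=True)
                plates.append(PlateLayout(f"{line}_r{rep}_p{pi:02d}", wells))
    return plates


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class ImageSimParams:
    """Rendering configuration for synthetic organoid fields."""

    shape: tuple[int, int] = (160, 160)
    n_z: int = 16
    n_organoids: int = 8
    radius_range: tuple[float, float] = (9.0, 18.0)
    mode: str = "solid"  # "solid" | "cystic" | "mixed"
    dead_fraction: float = 0.0
    dna_intensity: float = 200.0
    actin_intensity: float = 180.0
    permeability_live: float = 20.0
    permeability_dead: float = 250.0
    lumen_fraction: float = 0.15  # lumen intensity as fraction of ring intensity
    ring_width: float = 3.0
    dead_radius_range: tuple[float, float] = (4.0, 7.0)
    background: float = 10.0
    noise_sd: float = 2.0
    psf_sigma: float = 1.0
    z_sigma: float = 2.0  # slices; in-focus fall-off along z
    max_place_tries: int = 200
    max_wells: int | None = 4


@dataclass
class FieldSimulation:
    stack: ImageStack
    mask: np.ndarray
    organoids: pd.DataFrame  # cy, cx, radius, mode, dead, z_center


def simulate_image_stacks(layout: PlateLayout | None, params: ImageSimParams,
                          seed: int = 0) -> list[FieldSimulation]:
    """Render 3-channel, 16-slice stacks plus ground-truth masks per well field.

    Cystic organoids are drawn as a bright actin ring around a dim lumen,
    solid organoids as filled disks; dead organoids are small with a strong
    permeability signal.  With ``layout=None`` a single anonymous field is
    rendered.
    """
    ny, nx = params.shape
    if ny <= 0 or nx <= 0 or params.n_z <= 0:
        raise ConfigError("image dimensions must be positive")
    rng = np.random.default_rng(seed)

    wells: list[dict]
    if layout is None:
        wells = [{"plate_id": "field", "row": 1, "col": 1}]
    else:
        rows = layout.wells
        if params.max_wells is not None:
            rows = rows.iloc[: params.max_wells]
        wells = [
            {"plate_id": layout.plate_id, **r[["row", "col", "line_id", "treatment"]].to_dict()}
            for _, r in rows.iterrows()
        ]

    return [_render_field(params, rng, meta) for meta in wells]


def _render_field(params: ImageSimParams, rng: np.random.Generator, meta: dict) -> FieldSimulation:
    ny, nx = params.shape
    specs = _place_organoids(params, rng)
    mask = np.zeros((ny, nx), dtype=np.int32)
    chan2d = {ch: np.zeros((ny, nx)) for ch in CHANNELS}
    yy, xx = np.mgrid[0:ny, 0:nx]

    per_organoid = []
    for k, spec in enumerate(specs, start=1):
        cy, cx, r, mode, dead, z_c = spec
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = d2 <= r**2
        mask[disk] = k
        foot = {ch: np.zeros((ny, nx)) for ch in CHANNELS}
        if dead:
            foot["dna"][disk] = 0.6 * params.dna_intensity
            foot["actin"][disk] = 0.4 * params.actin_intensity
            foot["permeability"][disk] = params.permeability_dead
        elif mode == "cystic":
            ring = disk & (d2 > (r - params.ring_width) ** 2)
            lumen = d2 <= (r - params.ring_width) ** 2
            foot["dna"][ring] = params.dna_intensity
            foot["dna"][lumen] = params.lumen_fraction * params.dna_intensity
            foot["actin"][ring] = params.actin_intensity
            foot["actin"][lumen] = params.lumen_fraction * params.actin_intensity
            foot["permeability"][disk] = params.permeability_live
        else:
            foot["dna"][disk] = params.dna_intensity
            foot["actin"][disk] = params.actin_intensity
            foot["permeability"][disk] = params.permeability_live
        per_organoid.append((foot, z_c))

    stack = np.zeros((len(CHANNELS), params.n_z, ny, nx))
    z = np.arange(params.n_z)
    for foot, z_c in per_organoid:
        zf = np.exp(-((z - z_c) ** 2) / (2 * params.z_sigma**2))
        for ci, ch in enumerate(CHANNELS):
            stack[ci] += zf[:, None, None] * foot[ch][None, :, :]
    stack += params.background
    if params.psf_sigma > 0:
        for ci in range(len(CHANNELS)):
            for zi in range(params.n_z):
                stack[ci, zi] = ndi.gaussian_filter(stack[ci, zi], params.psf_sigma)
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)

    organoids = pd.DataFrame(
        specs, columns=["cy", "cx", "radius", "mode", "dead", "z_center"]
    )
    return FieldSimulation(
        ImageStack(stack, CHANNELS, meta=meta), mask, organoids
    )


def _place_organoids(params: ImageSimParams, rng: np.random.Generator) -> list[tuple]:
    ny, nx = params.shape
    specs: list[tuple] = []
    for _ in range(params.n_organoids):
        dead = bool(rng.random() < params.dead_fraction)
        lo, hi = params.dead_radius_range if dead else params.radius_range
        r = float(rng.uniform(lo, hi))
        if params.mode == "mixed":
            mode = "cystic" if rng.random() < 0.5 else "solid"
        else:
            mode = params.mode
        for _try in range(params.max_place_tries):
            cy = float(rng.uniform(r + 1, ny - r - 1))
            cx = float(rng.uniform(r + 1, nx - r - 1))
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (1.05 * (r + orad)) ** 2
                for oy, ox, orad, *_ in specs
            ):
                break
        else:
            continue  # field too crowded; place fewer organoids
        z_c = float(rng.uniform(3, params.n_z - 4)) if params.n_z > 7 else params.n_z / 2
        specs.append((cy, cx, r, mode, dead, z_c))
    return specs


# ---------------------------------------------------------------------------
# per-organoid feature tables


@dataclass
class SizeMixture:
    """Two-component log-normal organoid-size mixture of one line."""

    w_small: float = 0.4
    mu_small: float = 4.0
    mu_large: float = 6.5
    sd_small: float = 0.35
    sd_large: float = 0.45


@dataclass
class DrugEffect:
    """Configured effect of one compound at its top dose."""

    moa: str | None = None
    shift_sd: float = 0.0  # phenotype shift magnitude, in organoid-noise SDs
    lethality: float = 0.0  # dead fraction at the top dose
    size_shift: float = 0.0  # additive shift of log-size at the top dose

    def __post_init__(self) -> None:
        if not 0.0 <= self.lethality <= 1.0:
            raise ConfigError("lethality (death fraction) must be within [0, 1]")


@dataclass
class EffectConfig:
    """Statistical configuration of the simulated screen."""

    n_per_well: int = 50
    n_morph_features: int = 25
    line_mixtures: dict = field(default_factory=dict)
    drug_effects: dict = field(default_factory=dict)
    baseline_death: float = 0.03
    control_lethality: float = 0.95
    moa_direction_jitter: float = 0.15  # within-group angular deviation
    orthogonal_moa_groups: bool = True
    organoid_noise_sd: float = 1.0
    dead_mu: float = 3.2
    dead_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_death <= 1.0:
            raise ConfigError("baseline death fraction must be within [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """What the generator actually drew, for oracle-style assertions."""

    per_organoid: pd.DataFrame | None = None  # true_dead, true_size_component, ...
    shift_vectors: dict = field(default_factory=dict)  # drug -> morph-space direction
    moa_groups: dict = field(default_factory=dict)  # drug -> MoA group
    factor_scores: pd.DataFrame | None = None  # samples x k
    view_loadings: dict = field(default_factory=dict)  # view -> features x k
    noise_sd: dict = field(default_factory=dict)
    config: object = None


_LIVE_INTENSITY = {
    "intensity_dna_mean": (200.0, 30.0),
    "intensity_dna_sd": (30.0, 8.0),
    "intensity_actin_mean": (180.0, 30.0),
    "intensity_actin_sd": (35.0, 8.0),
    "intensity_permeability_mean": (60.0, 15.0),
    "intensity_permeability_q90": (90.0, 20.0),
    "texture_dna_energy": (40.0, 8.0),
    "texture_actin_energy": (50.0, 8.0),
}
_DEAD_INTENSITY = {
    "intensity_dna_mean": (120.0, 25.0),
    "intensity_dna_sd": (15.0, 5.0),
    "intensity_actin_mean": (90.0, 20.0),
    "intensity_actin_sd": (12.0, 5.0),
    "intensity_permeability_mean": (260.0, 30.0),
    "intensity_permeability_q90": (320.0, 35.0),
    "texture_dna_energy": (15.0, 5.0),
    "texture_actin_energy": (12.0, 4.0),
}


def simulate_feature_table(
    layouts, params: EffectConfig, seed: int = 0
) -> tuple[FeatureMatrix, SyntheticGroundTruth]:
    """Draw per-organoid feature vectors for every well of the given layouts.

    Live organoids: log-size from the line's two-component log-normal
    mixture, channel intensities around live baselines, and generic
    morphology features = line centroid + treatment shift x dose scaling +
    unit organoid noise.  Dead organoids are drawn from a distinct cluster
    (small, permeable, low actin texture) shared across lines.  The per-well
    dead fraction interpolates between the baseline rate and the drug's
    configured lethality with dose.
    """
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    rng = np.random.default_rng(seed)
    p = params

    lines = sorted({lay.wells["line_id"].iloc[0] for lay in layouts})
    mixtures = {ln: p.line_mixtures.get(ln) or _default_mixture(rng) for ln in lines}
    line_centroids = {ln: rng.normal(0.0, 1.0, size=p.n_morph_features) for ln in lines}
    dead_centroid = rng.normal(0.0, 1.0, size=p.n_morph_features) + 3.0

    effects = dict(p.drug_effects)
    for drug in POSITIVE_CONTROLS:
        effects.setdefault(
            drug, DrugEffect(moa="control", shift_sd=3.0, lethality=p.control_lethality)
        )
    dose_rank = _dose_ranks(layouts)
    directions = _moa_directions(effects, p, rng)

    morph_cols = [f"morph_{i + 1:02d}" for i in range(p.n_morph_features)]
    feat_rows, meta_rows, truth_rows, ids = [], [], [], []
    for lay in layouts:
        for _, w in lay.wells.iterrows():
            drug, conc, line = w["treatment"], w["concentration"], w["line_id"]
            eff = effects.get(drug)
            if w["role"] == "positive_control":
                scale = 1.0  # both control concentrations are near-fully lethal
            else:
                scale = _dose_scale(drug, conc, dose_rank) if eff else 0.0
            death_p = p.baseline_death
            if eff is not None:
                death_p = p.baseline_death + (eff.lethality - p.baseline_death) * scale
            mix = mixtures[line]
            for i in range(p.n_per_well):
                dead = bool(rng.random() < death_p)
                row = {}
                if dead:
                    log_area = rng.normal(p.dead_mu, p.dead_sd)
                    for col, (mu, sd) in _DEAD_INTENSITY.items():
                        row[col] = rng.normal(mu, sd)
                    morph = dead_centroid + rng.normal(0, 0.7, p.n_morph_features)
                    comp = "dead"
                else:
                    small = rng.random() < mix.w_small
                    log_area = rng.normal(
                        mix.mu_small if small else mix.mu_large,
                        mix.sd_small if small else mix.sd_large,
                    )
                    if eff is not None:
                        log_area += eff.size_shift * scale
                    for col, (mu, sd) in _LIVE_INTENSITY.items():
                        row[col] = rng.normal(mu, sd)
                    morph = line_centroids[line] + rng.normal(
                        0, p.organoid_noise_sd, p.n_morph_features
                    )
                    if eff is not None and eff.shift_sd != 0.0:
                        morph = morph + eff.shift_sd * scale * directions[drug]
                    comp = "small" if small else "large"
                row["area"] = float(np.exp(log_area))
                row.update(zip(morph_cols, morph))
                oid = f"{lay.plate_id}_{w['row']:02d}{w['col']:02d}_{i:03d}"
                ids.append(oid)
                feat_rows.append(row)
                meta_rows.append(
                    {
                        "plate_id": lay.plate_id, "row": w["row"], "col": w["col"],
                        "field": 1, "line_id": line, "treatment": drug,
                        "concentration": conc, "role": w["role"],
                        "batch_id": w["batch_id"], "replicate": w["replicate"],
                        "area_px": int(round(np.exp(log_area))),
                    }
                )
                truth_rows.append(
                    {"true_dead": dead, "true_size_component": comp,
                     "true_line_id": line, "configured_death_fraction": death_p}
                )

    features = pd.DataFrame(feat_rows, index=ids)
    meta = pd.DataFrame(meta_rows, index=ids)
    truth = SyntheticGroundTruth(
        per_organoid=pd.DataFrame(truth_rows, index=ids),
        shift_vectors=directions,
        moa_groups={d: e.moa for d, e in effects.items()},
        config=p,
    )
    return FeatureMatrix(features, meta), truth


def _default_mixture(rng: np.random.Generator) -> SizeMixture:
    return SizeMixture(
        w_small=float(rng.uniform(0.3, 0.5)),
        mu_small=4.0,
        mu_large=float(rng.uniform(5.8, 7.0)),
    )


def _dose_ranks(layouts) -> dict:
    """drug -> sorted unique concentrations across the screen."""
    concs: dict[str, set] = {}
    for lay in layouts:
        lib = lay.wells.dropna(subset=["concentration"])
        for d, c in zip(lib["treatment"], lib["concentration"]):
            concs.setdefault(d, set()).add(float(c))
    return {d: sorted(cs) for d, cs in concs.items()}


def _dose_scale(drug: str, conc, dose_rank: dict) -> float:
    levels = dose_rank.get(drug)
    if not levels or conc is None or (isinstance(conc, float) and np.isnan(conc)):
        return 1.0
    return (levels.index(float(conc)) + 1) / len(levels)


def _moa_directions(effects: dict, p: EffectConfig, rng: np.random.Generator) -> dict:
    groups = sorted({e.moa for e in effects.values() if e.moa is not None})
    d = p.n_morph_features
    if p.orthogonal_moa_groups and groups:
        q, _ = np.linalg.qr(rng.normal(size=(d, max(len(groups), 1))))
        group_dirs = {g: q[:, i] for i, g in enumerate(groups)}
    else:
        group_dirs = {g: _unit(rng.normal(size=d)) for g in groups}
    dirs = {}
    a = p.moa_direction_jitter
    for drug, eff in sorted(effects.items()):
        if eff.moa is not None:
            base = group_dirs[eff.moa]
            noise = rng.normal(size=d)
            noise -= base * (noise @ base)
            dirs[drug] = _unit(np.sqrt(max(1 - a**2, 0.0)) * base + a * _unit(noise))
        else:
            dirs[drug] = _unit(rng.normal(size=d))
    return dirs


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


# ---------------------------------------------------------------------------
# multi-view factor dataset

DEFAULT_VIEW_DIMS = {
    "size": 1,
    "mutations": 12,
    "expression": 3222,
    "morphology": 25,
    "drug_activity": 252,
}


def simulate_multiview(
    n_samples: int = 22,
    k: int = 3,
    view_dims: dict | None = None,
    noise_sd: dict | float = 0.3,
    seed: int = 0,
    n_lines: int | None = None,
    replicate_jitter: float = 0.1,
    mutation_missing: int = 2,
    mutation_prevalence: float = 0.3,
):
    """Generate the 5-view dataset from a known k-factor linear model.

    Each view is ``Y_v = Z W_v^T + eps_v`` with noise scaled relative to the
    signal's standard deviation.  Samples come in line pairs (replicates)
    sharing factor scores up to Gaussian jitter (sd = ``replicate_jitter`` x
    signal sd).  The mutation view is thresholded to binary presence calls at
    the configured prevalence and loses ``mutation_missing`` randomly chosen
    samples, mirroring the real data's missing mutation profiles.

    Returns ``(views, ground_truth)`` where ``views`` maps view name to a
    sample x feature DataFrame and ground truth carries the true scores and
    loadings.
    """
    view_dims = dict(DEFAULT_VIEW_DIMS if view_dims is None else view_dims)
    if n_samples <= k:
        raise ConfigError("need more samples than factors")
    rng = np.random.default_rng(seed)
    if isinstance(noise_sd, (int, float)):
        noise_sd = {v: float(noise_sd) for v in view_dims}

    if n_lines is None:
        n_lines = (n_samples + 1) // 2
    line_scores = rng.normal(size=(n_lines, k))
    sample_ids, z_rows = [], []
    for i in range(n_samples):
        line, rep = i // 2, i % 2 + 1
        line = min(line, n_lines - 1)
        sample_ids.append(f"L{line + 1:02d}_r{rep}")
        z_rows.append(line_scores[line] + replicate_jitter * rng.normal(size=k))
    z = np.asarray(z_rows)

    views: dict[str, pd.DataFrame] = {}
    loadings: dict[str, pd.DataFrame] = {}
    for view in sorted(view_dims):
        d = view_dims[view]
        w = rng.normal(size=(d, k))
        signal = z @ w.T
        sd = noise_sd.get(view, 0.0) * (signal.std() if signal.std() > 0 else 1.0)
        y = signal + rng.normal(0.0, sd, size=signal.shape) if sd > 0 else signal.copy()
        cols = [f"{view}_{j + 1:04d}" for j in range(d)]
        if view == "mutations":
            thr = np.quantile(y, 1 - mutation_prevalence, axis=0)
            y = (y > thr).astype(float)
            present = np.sort(
                rng.choice(n_samples, size=n_samples - mutation_missing, replace=False)
            )
            df = pd.DataFrame(y[present], index=np.asarray(sample_ids)[present], columns=cols)
        else:
            df = pd.DataFrame(y, index=sample_ids, columns=cols)
        views[view] = df
        loadings[view] = pd.DataFrame(w, index=cols, columns=[f"F{j + 1}" for j in range(k)])

    truth = SyntheticGroundTruth(
        factor_scores=pd.DataFrame(
            z, index=sample_ids, columns=[f"F{j + 1}" for j in range(k)]
        ),
        view_loadings=loadings,
        noise_sd=noise_sd,
    )
    return views, truth
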