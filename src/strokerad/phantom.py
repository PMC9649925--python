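"""Synthetic DWI/ADC phantom cohorts with known ground truth.

Each subject carries a paired DWI/ADC volume with a single infarct-like
lesion (DWI-hyperintense, ADC-hypointense), a true lesion mask, and a
clinical record drawn to match the marginal frequencies of a ~1,000-patient
ischemic-stroke cohort with an 8.5% one-year recurrence rate.  Recurrence
labels follow a planted logistic model on standardized radiomic features and
clinical covariates, so every downstream stage (segmentation, extraction,
selection, classification, statistics) can be validated against known truth.

Lesions are unions of 1-3 overlapping ellipsoids (bisected to a requested
voxel volume) with a Gaussian-random-field interior texture whose correlation
length is the knob texture features must detect.  The background is a
brain-like ellipse; noise is Gaussian on magnitude, adequate at these SNRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from .errors import ConfigError, GeometryError
from . import radiomics

# Cohort margins the clinical sampler emulates (counts out of 1,003):
# the two-group totals of a published acute-ischemic-stroke recurrence cohort.
COHORT_MARGINS = {
    "n": 1003,
    "age_mean": 65.90,
    "age_sd": 12.44,
    "male": 682,
    "smoking": 378,
    "drinking": 134,
    "hypertension": 676,
    "hyperlipidemia": 277,
    "diabetes": 350,
    "atrial_fibrillation": 113,
    "statins": 634,
    "antiplatelets": 897,
    "anticoagulants": 45,
    "toast": {"LAA": 544, "cardioembolic": 80, "SAO": 298, "other": 13, "undetermined": 68},
    "circulation": {"anterior": 688, "posterior": 285, "both": 30},
    "nihss_median": 3,
    "mrs90_median": 1,
    "days_to_recurrence_mean": 167.11,
    "days_to_recurrence_sd": 100.08,
}

#: clinical covariate columns used as model features (the 6-column clinical block)
CLINICAL_FEATURES = ("age", "statins", "anticoagulants", "antiplatelets",
                     "atrial_fibrillation", "nihss")

DEFAULT_EFFECT_WEIGHTS = {
    "image_fo_mean": -1.8,     # deeper ADC drop -> higher recurrence risk
    "image_fo_std": 1.2,       # more heterogeneous lesions -> higher risk
    "wLLL_glcm_contrast": 0.9,
}

DEFAULT_CLINICAL_EFFECTS = {
    "age": 0.70,
    "statins": 0.55,
    "anticoagulants": 0.50,
    "atrial_fibrillation": 0.40,
}


@dataclass
class PhantomConfig:
    n_subjects: int = 1003
    prevalence: float = 0.085
    volume_shape: tuple[int, int, int] = (24, 40, 40)
    lesion_volume_range: tuple[int, int] = (60, 400)
    lesion_texture_scale: tuple[float, float] = (0.6, 2.0)  # GRF correlation length (voxels)
    noise_sd: float = 0.02
    effect_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS))
    clinical_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    seed: int = 0
    exact_count: bool = True
    # image model knobs
    dwi_background: float = 0.35
    adc_background: float = 0.65
    dwi_contrast: tuple[float, float] = (0.30, 0.50)
    adc_contrast: tuple[float, float] = (0.25, 0.45)
    texture_amplitude: tuple[float, float] = (0.04, 0.12)

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must be in (0, 1)")
        if self.lesion_volume_range[0] < radiomics.MIN_LESION_VOXELS:
            raise ConfigError(
                f"lesion_volume_range min must be >= {radiomics.MIN_LESION_VOXELS} "
                "(sub-50-voxel lesions are designed exclusions)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    id: str
    dwi: np.ndarray
    adc: np.ndarray
    true_mask: np.ndarray
    clinical: pd.Series
    true_probability: float = np.nan
    label: int = 0


@dataclass
class CohortData:
    subjects: list[SyntheticSubject]
    clinical: pd.DataFrame          # one row per subject, incl. label columns
    features: pd.DataFrame | None   # radiomic feature table (if extracted)
    config: PhantomConfig


# ---------------------------------------------------------------------------
# lesion synthesis
# ---------------------------------------------------------------------------

def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = [(s - 1) / 2.0 for s in shape]
    r = [max(s / 2.0 - 1.0, 1.0) for s in shape]
    q = ((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2 + ((xx - c[2]) / r[2]) ** 2
    return q <= 1.0


def _random_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    if corr_len > 0:
        f = ndimage.gaussian_filter(noise, sigma=corr_len, mode="reflect")
    else:
        f = noise
    sd = f.std()
    return f / sd if sd > 0 else f


def synthesize_lesion_pair(volume_shape: tuple[int, int, int],
                           lesion_volume: int,
                           texture_scale: float,
                           rng: np.random.Generator,
                           *,
                           dwi_background: float = 0.35,
                           adc_background: float = 0.65,
                           dwi_contrast: float = 0.4,
                           adc_contrast: float = 0.35,
                           texture_amplitude: float = 0.08,
                           noise_sd: float = 0.02,
                           n_ellipsoids: int | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize a co-registered (DWI, ADC, mask) triple with one lesion.

    The lesion is the union of 1-3 overlapping ellipsoids whose common scale
    is bisected so the voxel count lands on ``lesion_volume``; its interior
    carries a correlated texture field (correlation length ``texture_scale``).
    """
    shape = tuple(int(s) for s in volume_shape)
    if lesion_volume < 1:
        raise GeometryError("lesion volume must be >= 1 voxel")
    brain = _brain_mask(shape)
    if lesion_volume > 0.5 * brain.sum():
        raise GeometryError(
            f"lesion of {lesion_volume} voxels does not fit in volume {shape}")

    # nominal radius from volume of a sphere; confines the center inside brain
    r_nom = (3.0 * lesion_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin = r_nom * 1.8 + 1.0
    c0 = np.array([(s - 1) / 2.0 for s in shape])
    half = np.array([max(s / 2.0 - 1.0 - margin, 0.5) for s in shape])
    center = c0 + rng.uniform(-1, 1, size=3) * half

    k = int(n_ellipsoids) if n_ellipsoids is not None else int(rng.integers(1, 4))
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    min_q = np.full(shape, np.inf)
    for _ in range(k):
        off = rng.uniform(-0.6, 0.6, size=3) * r_nom
        axes = r_nom * rng.uniform(0.7, 1.4, size=3)
        cz, cy, cx = center + off
        q = (((zz - cz) / axes[0]) ** 2 + ((yy - cy) / axes[1]) ** 2
             + ((xx - cx) / axes[2]) ** 2)
        np.minimum(min_q, q, out=min_q)

    # bisect the common scale so that |{min_q <= s}| = lesion_volume
    lo, hi = 0.0, 16.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if int((min_q <= mid).sum()) < lesion_volume:
            lo = mid
        else:
            hi = mid
    mask = min_q <= hi
    # keep one 26-connected component (overlap constraint makes splits rare)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    mask = mask.astype(np.uint8)

    dwi = np.where(brain, dwi_background, 0.02).astype(float)
    adc = np.where(brain, adc_background, 0.02).astype(float)
    m = mask.astype(bool)
    if texture_amplitude > 0:
        tex_d = _random_field(shape, texture_scale, rng) * texture_amplitude
        tex_a = _random_field(shape, texture_scale, rng) * texture_amplitude
    else:
        tex_d = tex_a = np.zeros(shape)
        rng.standard_normal(shape); rng.standard_normal(shape)  # keep stream aligned
    dwi[m] += dwi_contrast + tex_d[m]
    adc[m] += -adc_contrast + tex_a[m]
    if noise_sd > 0:
        dwi += rng.normal(0.0, noise_sd, size=shape)
        adc += rng.normal(0.0, noise_sd, size=shape)
    return dwi, adc, mask


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def sample_clinical(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n clinical records matching the cohort's marginal distributions.

    Covariates are sampled independently; only the margins are constrained.
    """
    m = COHORT_MARGINS
    total = m["n"]

    def bern(count):
        return (rng.random(n) < count / total).astype(int)

    toast_labels = list(m["toast"])
    toast_p = np.array([m["toast"][k] for k in toast_labels], dtype=float) / total
    circ_labels = list(m["circulation"])
    circ_p = np.array([m["circulation"][k] for k in circ_labels], dtype=float) / total
    df = pd.DataFrame({
        "age": np.round(rng.normal(m["age_mean"], m["age_sd"], size=n), 1),
        "sex": np.where(bern(m["male"]) == 1, "male", "female"),
        "smoking": bern(m["smoking"]),
        "drinking": bern(m["drinking"]),
        "hypertension": bern(m["hypertension"]),
        "hyperlipidemia": bern(m["hyperlipidemia"]),
        "diabetes": bern(m["diabetes"]),
        "atrial_fibrillation": bern(m["atrial_fibrillation"]),
        "toast": rng.choice(toast_labels, size=n, p=toast_p),
        "circulation": rng.choice(circ_labels, size=n, p=circ_p),
        "statins": bern(m["statins"]),
        "antiplatelets": bern(m["antiplatelets"]),
        "anticoagulants": bern(m["anticoagulants"]),
        "nihss": rng.poisson(m["nihss_median"], size=n),
        "mrs90": rng.poisson(m["mrs90_median"], size=n),
    })
    df["age"] = df["age"].clip(lower=18.0)
    return df


def clinical_design_matrix(clinical: pd.DataFrame,
                           columns: tuple[str, ...] = CLINICAL_FEATURES) -> pd.DataFrame:
    """Numeric clinical feature block (default: the 6 modeling covariates)."""
    out = {}
    for col in columns:
        if col == "sex":
            out[col] = (clinical["sex"] == "male").astype(float)
        elif col.startswith("toast_"):
            out[col] = (clinical["toast"] == col.split("_", 1)[1]).astype(float)
        else:
            out[col] = clinical[col].astype(float)
    return pd.DataFrame(out, index=clinical.index)


# ---------------------------------------------------------------------------
# label assignment
# ---------------------------------------------------------------------------

def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (df - mu) / sd


def assign_labels(features: pd.DataFrame | None,
                  clinical: pd.DataFrame,
                  config: PhantomConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Planted logistic labels: p = expit(b0 + Σ w·z(feature) + Σ c·z(covariate)).

    The intercept b0 is calibrated by 1-D root finding so the cohort-mean
    probability equals the configured prevalence.  In exact-count mode the
    positive count is fixed at round(n x prevalence) by probability-weighted
    sampling without replacement; otherwise labels are independent Bernoulli.
    Returns ``(labels, probabilities)``.
    """
    n = len(clinical)
    lp = np.zeros(n)
    if config.effect_weights:
        if features is None:
            raise ConfigError("effect_weights given but no feature table supplied")
        missing = [k for k in config.effect_weights if k not in features.columns]
        if missing:
            raise ConfigError(f"unknown feature name(s) in effect_weights: {missing}")
        z = _standardize(features[list(config.effect_weights)])
        lp += z.to_numpy() @ np.array(list(config.effect_weights.values()))
    if config.clinical_effects:
        design = clinical_design_matrix(clinical, tuple(config.clinical_effects))
        z = _standardize(design)
        lp += z.to_numpy() @ np.array(list(config.clinical_effects.values()))

    def mean_prob(b0: float) -> float:
        return float(expit(b0 + lp).mean()) - config.prevalence

    b0 = optimize.brentq(mean_prob, -30.0, 30.0)
    probs = expit(b0 + lp)

    if config.exact_count:
        k = int(round(n * config.prevalence))
        # weighted sampling without replacement via exponential keys
        keys = rng.exponential(size=n) / np.maximum(probs, 1e-12)
        labels = np.zeros(n, dtype=int)
        labels[np.argsort(keys)[:k]] = 1
    else:
        labels = (rng.random(n) < probs).astype(int)
    return labels, probs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "subject_id", "age", "sex", "smoking", "drinking", "hypertension",
    "hyperlipidemia", "diabetes", "atrial_fibrillation", "toast", "circulation",
    "statins", "antiplatelets", "anticoagulants", "nihss", "mrs90",
    "recurrence", "days_to_recurrence", "true_probability",
]


def generate_cohort(config: PhantomConfig,
                    out_dir: str | Path | None = None,
                    with_images: bool = True) -> CohortData:
    """Generate a full synthetic cohort.

    When ``with_images`` is False (or ``effect_weights`` is empty) no volumes
    are synthesized/extracted and only the clinical table and labels are
    produced — the fast path for statistics that need no imaging.
    All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    clinical = sample_clinical(n, rng)
    ids = [f"sub-{i:04d}" for i in range(n)]

    subjects: list[SyntheticSubject] = []
    features: pd.DataFrame | None = None
    need_images = with_images and bool(config.effect_weights)
    if with_images:
        vmin, vmax = config.lesion_volume_range
        rows = []
        for sid in ids:
            vol = int(np.exp(rng.uniform(np.log(vmin), np.log(vmax))))
            scale = rng.uniform(*config.lesion_texture_scale)
            dwi, adc, mask = synthesize_lesion_pair(
                config.volume_shape, vol, scale, rng,
                dwi_background=config.dwi_background,
                adc_background=config.adc_background,
                dwi_contrast=rng.uniform(*config.dwi_contrast),
                adc_contrast=rng.uniform(*config.adc_contrast),
                texture_amplitude=rng.uniform(*config.texture_amplitude),
                noise_sd=config.noise_sd,
            )
            subjects.append(SyntheticSubject(id=sid, dwi=dwi, adc=adc,
                                             true_mask=mask, clinical=None))
            if need_images:
                fv = radiomics.extract_features(adc, mask.astype(bool), subject_id=sid,
                                                enforce_min_size=False)
                rows.append(fv.to_series())
        if need_images:
            features = pd.DataFrame(rows)

    labels, probs = assign_labels(features, clinical, config, rng)
    clinical = clinical.copy()
    clinical.insert(0, "subject_id", ids)
    clinical["recurrence"] = labels
    days = np.full(n, np.nan)
    pos = labels == 1
    if pos.any():
        m = COHORT_MARGINS
        days[pos] = np.clip(rng.normal(m["days_to_recurrence_mean"],
                                       m["days_to_recurrence_sd"], size=int(pos.sum())),
                            1, 365).round()
    clinical["days_to_recurrence"] = days
    clinical["true_probability"] = probs

    for i, sub in enumerate(subjects):
        sub.clinical = clinical.iloc[i]
        sub.true_probability = float(probs[i])
        sub.label = int(labels[i])

    cohort = CohortData(subjects=subjects, clinical=clinical[CSV_COLUMNS],
                        features=features, config=config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Write cohort.csv, the feature table (if present), and per-subject NIfTI files."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out / "cohort.csv", index=False)
    if cohort.features is not None:
        cohort.features.to_csv(out / "features.csv")
    affine = np.eye(4)
    for sub in cohort.subjects:
        nib.save(nib.Nifti1Image(sub.dwi.astype(np.float32), affine),
                 out / f"{sub.id}_dwi.nii.gz")
        nib.save(nib.Nifti1Image(sub.adc.astype(np.float32), affine),
                 out / f"{sub.id}_adc.nii.gz")
        nib.save(nib.Nifti1Image(sub.true_mask.astype(np.uint8), affine),
                 out / f"{sub.id}_mask.nii.gz")
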