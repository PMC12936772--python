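"""Synthetic multimodal lung-cancer cohorts.

Emulates the statistical structure of a suspected-lung-cancer cohort:
~170 patients with ~46.5% cancer prevalence, a stage distribution
concentrated at stage I and IV, a 45-column flow-cytometry immune panel
with two informative subsets (KIR3DL1+ CD8 T cells up in cancer, cDC2
down in cancer), a 68-column exosome dot-blot panel with essentially no
signal, and one lesion CT volume per patient whose size, attenuation and
spiculation differ by outcome.

Feature marginals: immune subsets are logit-normal percent-of-parent
values bounded in [0, 100]; dot-blot intensities are log-normal and
unbounded positive.  Class effects are planted as location shifts of the
latent Gaussian, scaled so that the implied logistic-regression
coefficient on the latent scale equals the requested log-odds effect
(for equal-variance Gaussian classes the discriminating coefficient is
shift / variance).  A :class:`GroundTruth` records the planted
coefficients so downstream selection and estimation can be scored.

All draws are deterministic functions of ``spec.seed``; per-patient
lesion streams are keyed by a CRC of the patient id so that regenerating
a single lesion is bit-identical to generating the whole cohort.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .volumes import LesionVolume, save_nifti_pair

STAGES = ("I", "II", "III", "IV")

# fixed stream tags so the generators draw from independent substreams
_TAG_COHORT, _TAG_IMMUNE, _TAG_DOTBLOT, _TAG_LESION = 11, 22, 33, 44


@dataclass
class LesionClassParams:
    """Per-class lesion morphology distributions (normal, truncated where noted)."""

    radius_mean_mm: float
    radius_sd_mm: float
    hu_mean: float          # lesion attenuation offset relative to 0 HU
    hu_sd: float
    spiculation_mean: float  # relative radial perturbation amplitude
    spiculation_sd: float


@dataclass
class GenerativeSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: n=170, prevalence 46.5%,
    stage weights (23, 9, 18, 29)/79, planted immune effects
    +1.0 (KIR3DL1_CD8) and -1.0 (cDC2) on the latent logit scale, no
    dot-blot signal, lesions with diameter >= 6 mm.
    """

    n_patients: int = 170
    prevalence: float = 0.465
    stage_weights: dict[str, float] = field(
        default_factory=lambda: {"I": 23 / 79, "II": 9 / 79, "III": 18 / 79, "IV": 29 / 79}
    )
    immune_effects: dict[str, float] = field(
        default_factory=lambda: {"KIR3DL1_CD8": 1.0, "cDC2": -1.0}
    )
    dotblot_effects: dict[str, float] = field(default_factory=dict)
    n_immune: int = 45
    n_dotblot: int = 68
    immune_noise_sd: float = 1.0   # latent logit scale
    dotblot_noise_sd: float = 0.6  # latent log scale
    lesion_params: dict[int, LesionClassParams] = field(
        default_factory=lambda: {
            0: LesionClassParams(6.0, 1.5, 20.0, 15.0, 0.06, 0.03),
            1: LesionClassParams(8.0, 1.8, 60.0, 15.0, 0.22, 0.08),
        }
    )
    lesion_shape: tuple[int, int, int] = (64, 64, 32)
    lesion_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -800.0
    background_noise_sd: float = 30.0
    min_radius_mm: float = 3.0  # lesions below 6 mm diameter are excluded from the study
    age_mean: float = 73.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (27.0, 97.0)
    sex_p_male: float = 0.48
    smoking_probs: dict[str, float] = field(
        default_factory=lambda: {
            "ex-smoker": 64 / 170,
            "non-smoker": 41 / 170,
            "smoker": 38 / 170,
            "unknown": 27 / 170,
        }
    )
    exact_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if set(self.stage_weights) - set(STAGES):
            raise ValueError(
                f"stage_weights keys must be within {STAGES}, got {sorted(self.stage_weights)}"
            )
        if self.prevalence > 0 and abs(sum(self.stage_weights.values()) - 1.0) > 1e-9:
            raise ValueError("stage_weights must sum to 1")
        for name, n in (("n_immune", self.n_immune), ("n_dotblot", self.n_dotblot)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1, got {n}")
        if len(self.immune_effects) > self.n_immune:
            raise ValueError("more immune_effects than n_immune columns")
        if len(self.dotblot_effects) > self.n_dotblot:
            raise ValueError("more dotblot_effects than n_dotblot columns")
        if self.min_radius_mm < 3.0:
            raise ValueError(
                f"min_radius_mm must be >= 3 (lesion diameter >= 6 mm), got {self.min_radius_mm}"
            )
        for sd in (self.immune_noise_sd, self.dotblot_noise_sd):
            if sd <= 0:
                raise ValueError(f"noise sd must be positive, got {sd}")


@dataclass
class GroundTruth:
    """Planted effects, on the latent (logit/log) scale, for recovery tests."""

    true_coefficients: dict[str, float]
    true_intercept: float
    linear_predictor: pd.Series  # per patient id

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_coefficients": self.true_coefficients,
            "true_intercept": self.true_intercept,
            "linear_predictor": {k: float(v) for k, v in self.linear_predictor.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, *map(int, extra)]))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights`."""
    ideal = weights / weights.sum() * total
    counts = np.floor(ideal).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_cohort(spec: GenerativeSpec) -> pd.DataFrame:
    """Draw patient metadata: outcome, stage (cancers only), age, sex, smoking.

    With ``spec.exact_counts`` the cancer count is exactly
    round(n * prevalence) and stage counts follow largest-remainder
    rounding of the stage weights; otherwise outcomes are Bernoulli and
    stages categorical.
    """
    spec.validate()
    rng = _rng(spec.seed, _TAG_COHORT)
    n = spec.n_patients

    if spec.exact_counts:
        n_cancer = int(round(n * spec.prevalence))
        outcome = np.zeros(n, dtype=int)
        outcome[rng.permutation(n)[:n_cancer]] = 1
    else:
        outcome = (rng.random(n) < spec.prevalence).astype(int)

    stage = np.full(n, "", dtype=object)
    cancer_idx = np.flatnonzero(outcome == 1)
    if cancer_idx.size:
        names = [s for s in STAGES if spec.stage_weights.get(s, 0) > 0]
        w = np.array([spec.stage_weights[s] for s in names], dtype=float)
        if spec.exact_counts:
            counts = _largest_remainder(w, cancer_idx.size)
            pool = np.repeat(names, counts)
            stage[cancer_idx] = pool[rng.permutation(cancer_idx.size)]
        else:
            stage[cancer_idx] = rng.choice(names, size=cancer_idx.size, p=w / w.sum())

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range).round(1)
    sex = np.where(rng.random(n) < spec.sex_p_male, "M", "F")
    smk_names = list(spec.smoking_probs)
    smk_p = np.array([spec.smoking_probs[k] for k in smk_names], dtype=float)
    smoking = rng.choice(smk_names, size=n, p=smk_p / smk_p.sum())

    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "outcome": outcome,
            "stage": stage,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "split": "",
        }
    )


def _planted_panel(
    cohort: pd.DataFrame,
    effects: dict[str, float],
    n_cols: int,
    noise_sd: float,
    noise_prefix: str,
    mu_loc: float,
    mu_scale: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, float]]:
    """Latent Gaussian panel with class-shifted informative columns.

    Returns the latent matrix (before the marginal transform), its column
    names, and the effect map.  Shift = effect * noise_sd**2 so that the
    implied discriminating logistic coefficient equals `effect`.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    informative = list(effects)
    n_noise = n_cols - len(informative)
    noise_names = []
    k = 1
    while len(noise_names) < n_noise:
        name = f"{noise_prefix}_{k:02d}"
        k += 1
        if name in effects:
            raise ValueError(f"effect name {name!r} collides with a noise column name")
        noise_names.append(name)
    columns = informative + noise_names

    y = cohort["outcome"].to_numpy()
    mu = rng.normal(mu_loc, mu_scale, n_cols)
    # Informative columns get a fixed baseline at the centre of the latent
    # scale: the marginal transform (logit-normal / log-normal) is locally
    # symmetric there, so the planted effect size means the same thing for
    # positive and negative effects and across seeds, instead of being
    # attenuated by a randomly drawn baseline in the flat tail.
    mu[: len(informative)] = mu_loc if noise_prefix == "DB" else 0.0
    latent = mu + noise_sd * rng.standard_normal((n, n_cols))
    for j, name in enumerate(informative):
        latent[:, j] += effects[name] * noise_sd**2 * y
    df = pd.DataFrame(latent, columns=columns, index=cohort["patient_id"].to_numpy())
    df.index.name = "patient_id"
    return df, mu, dict(effects)


def _ground_truth(
    spec: GenerativeSpec,
    latent: pd.DataFrame,
    mu: np.ndarray,
    effects: dict[str, float],
) -> GroundTruth:
    prev = min(max(spec.prevalence, 1e-6), 1 - 1e-6)
    intercept = float(logit(prev))
    lp = np.full(len(latent), intercept)
    for j, name in enumerate(effects):
        lp = lp + effects[name] * (latent[name].to_numpy() - mu[j])
    return GroundTruth(
        true_coefficients=dict(effects),
        true_intercept=intercept,
        linear_predictor=pd.Series(lp, index=latent.index),
    )


def generate_immune(
    cohort: pd.DataFrame, spec: GenerativeSpec
) -> tuple[pd.DataFrame, GroundTruth]:
    """Flow-cytometry immune panel: logit-normal percentages in [0, 100].

    Informative columns (defaults KIR3DL1_CD8 up in cancer, cDC2 down)
    get class-dependent latent means; the rest are class-independent.
    """
    spec.validate()
    rng = _rng(spec.seed, _TAG_IMMUNE)
    latent, mu, effects = _planted_panel(
        cohort, spec.immune_effects, spec.n_immune, spec.immune_noise_sd,
        "IMM", mu_loc=-1.5, mu_scale=0.8, rng=rng,
    )
    truth = _ground_truth(spec, latent, mu, effects)
    features = 100.0 * expit(latent)
    features.attrs["modality"] = "immune"
    return features, truth


def generate_dotblot(cohort: pd.DataFrame, spec: GenerativeSpec) -> pd.DataFrame:
    """Exosome dot-blot panel: log-normal intensities, no signal by default."""
    spec.validate()
    rng = _rng(spec.seed, _TAG_DOTBLOT)
    effects = dict(spec.dotblot_effects)
    latent, _, _ = _planted_panel(
        cohort, effects, spec.n_dotblot, spec.dotblot_noise_sd,
        "DB", mu_loc=2.0, mu_scale=0.5, rng=rng,
    )
    features = np.exp(latent)
    features.attrs["modality"] = "dotblot"
    return features


def generate_lesion(
    patient_row: pd.Series | dict,
    spec: GenerativeSpec,
    radius_mm: float | None = None,
    spiculation: float | None = None,
    attenuation_hu: float | None = None,
) -> LesionVolume:
    """One lesion CT volume for a patient: spiculated ellipsoid in noise.

    The lesion is an ellipsoid (mild random axis anisotropy, volume
    preserving) whose boundary radius is modulated by a sinusoidal
    angular perturbation (spiculation).  Cancer lesions draw larger
    radius, attenuation and spiculation per ``spec.lesion_params``.
    Deterministic given (spec.seed, patient_id); explicit keyword
    overrides pin individual morphology parameters.
    """
    spec.validate()
    row = dict(patient_row)
    if "outcome" not in row:
        raise ValueError("patient_row must carry an outcome")
    pid = str(row.get("patient_id", "anon"))
    rng = _rng(spec.seed, _TAG_LESION, zlib.crc32(pid.encode()))
    params = spec.lesion_params[int(row["outcome"])]

    radius = float(radius_mm) if radius_mm is not None else max(
        spec.min_radius_mm, rng.normal(params.radius_mean_mm, params.radius_sd_mm)
    )
    if radius < spec.min_radius_mm and radius_mm is None:
        radius = spec.min_radius_mm
    spic = float(spiculation) if spiculation is not None else max(
        0.0, rng.normal(params.spiculation_mean, params.spiculation_sd)
    )
    hu = float(attenuation_hu) if attenuation_hu is not None else rng.normal(
        params.hu_mean, params.hu_sd
    )

    shape = spec.lesion_shape
    spacing = np.asarray(spec.lesion_spacing, dtype=float)
    extent_mm = (np.array(shape) - 1) * spacing
    feasible_r = (extent_mm.min() / 2 - 2.0) / (1.0 + spic)
    if radius >= feasible_r:
        if radius_mm is not None:
            raise ValueError(
                f"lesion radius {radius:.1f} mm (with spiculation {spic:.2f}) "
                f"exceeds the field of view {extent_mm.min():.0f} mm"
            )
        # random draw from the tail: truncate to the field of view
        radius = max(spec.min_radius_mm, feasible_r - 0.5)

    # centre with small jitter, ellipsoid axes with volume-preserving anisotropy
    centre = extent_mm / 2 + rng.uniform(-2.0, 2.0, 3)
    factors = rng.uniform(0.85, 1.15, 3)
    factors /= factors.prod() ** (1 / 3)
    axes = radius * factors
    k_theta = int(rng.integers(4, 8))
    k_phi = int(rng.integers(3, 6))
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)

    grids = np.meshgrid(
        *[np.arange(s) * sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    u = [(g - c) / a for g, c, a in zip(grids, centre, axes)]
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arctan2(u[1], u[0])
        phi = np.arccos(np.clip(np.divide(u[2], np.where(r > 0, r, 1.0)), -1, 1))
    boundary = 1.0 + spic * np.sin(k_theta * theta + ph1) * np.sin(k_phi * phi + ph2)
    mask = r <= boundary

    image = spec.background_hu + rng.normal(0.0, spec.background_noise_sd, shape)
    image[mask] = hu + rng.normal(0.0, params.hu_sd / 2, int(mask.sum()))
    return LesionVolume(image=image, spacing=tuple(spacing), mask=mask)


def generate_lesions(cohort: pd.DataFrame, spec: GenerativeSpec) -> dict[str, LesionVolume]:
    return {
        row["patient_id"]: generate_lesion(row, spec)
        for _, row in cohort.iterrows()
    }


def write_dataset(spec: GenerativeSpec, out_dir: str | Path, lesions: bool = True) -> None:
    """Materialise a full synthetic dataset: cohort CSV, feature CSVs,
    NIfTI lesion pairs and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    cohort.to_csv(out / "cohort.csv", index=False)
    immune, truth = generate_immune(cohort, spec)
    immune.to_csv(out / "features_immune.csv")
    generate_dotblot(cohort, spec).to_csv(out / "features_dotblot.csv")
    truth.to_json(out / "ground_truth.json")
    (out / "spec.json").write_text(json.dumps(asdict(spec), default=str, indent=1))
    if lesions:
        img_dir = out / "images"
        msk_dir = out / "masks"
        img_dir.mkdir(exist_ok=True)
        msk_dir.mkdir(exist_ok=True)
        for _, row in cohort.iterrows():
            vol = generate_lesion(row, spec)
            pid = row["patient_id"]
            save_nifti_pair(vol, img_dir / f"{pid}.nii.gz", msk_dir / f"{pid}.nii.gz")
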