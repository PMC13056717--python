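"""Synthetic normative and clinical cohorts with recoverable ground truth.

The generator emulates the statistical structure a grey-matter brain-age
analysis assumes: monotone age-related regional GMV decline with
region-specific rates, a subject-level biological brain-age deviation shared
across regions (the irreducible error floor of any brain-age model),
protocol location/scale offsets, sex and head-size (TIV) effects, and — for
clinical cohorts — a group atrophy effect concentrated in a configurable
subset of regions, coupled to clinical symptom variables through a latent
disease-severity factor.

Region-level parameters (baselines, atrophy slopes, sex coefficients, voxel
offsets) are drawn from ``region_seed`` so that cohorts generated under
different subject seeds live on the same "brain": models trained on one
cohort transfer to another exactly as they would between real scans.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteSpec",
    "CohortConfig",
    "EffectSpec",
    "GroundTruth",
    "CohortBundle",
    "generate_normative_cohort",
    "generate_clinical_cohort",
    "emit_cohort_files",
    "expected_global_bag_difference",
    "expected_regional_decrement",
    "population_canonical_correlation",
    "generate_foci_database",
]

CLINICAL_VARS = ("headache_freq", "painkiller_freq", "midas", "bdi", "duration_years")

SUBJECT_COLUMNS = (
    "id", "age", "sex", "group", "protocol", "tiv_ml",
    "headache_freq", "painkiller_freq", "midas", "bdi", "duration_years",
)


class ConfigurationError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition protocol: additive GMV offset (a.u.) and noise scale."""

    label: str
    shift: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 600
    age_range: tuple[float, float] = (20.0, 92.0)
    n_regions: int = 442
    voxels_per_region: int = 16
    sites: tuple[SiteSpec, ...] = (
        SiteSpec("IR-FSPGR", 0.0, 1.0),
        SiteSpec("BRAVO", 2.0, 1.15),
    )
    sex_effect: float = 1.0          # a.u., scaled per region
    tiv_coupling: float = 1.0        # exponent on TIV/mean(TIV)
    noise_sd: float = 1.0            # region-level noise, a.u.
    brainage_sd: float = 8.0         # biological brain-age deviation at the pivot age, years
    brainage_age_pivot: float = 56.0  # deviation SD scales as age / pivot
    voxel_noise_sd: float = 1.0      # within-region voxel noise, a.u.
    slope_range: tuple[float, float] = (0.5, 0.9)     # a.u. per year
    baseline_mean: float = 95.0      # a.u. at age 0
    baseline_sd: float = 8.0
    female_fraction: float = 0.65
    tiv_mean: float = 1430.0         # mL
    tiv_sd: float = 120.0
    seed: int = 0
    region_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ConfigurationError("n_subjects must be >= 10")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range min must be < max")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.voxels_per_region < 1:
            raise ConfigurationError("voxels_per_region must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.brainage_sd < 0:
            raise ConfigurationError("brainage_sd must be >= 0")
        if self.voxel_noise_sd < 0:
            raise ConfigurationError("voxel_noise_sd must be >= 0")
        if not self.sites:
            raise ConfigurationError("sites must be non-empty")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")


# Per-variable clinical model: value = transform(base + loading * severity + noise).
# Frequencies are linear days/month capped at 30; MIDAS and BDI are
# log-linear in severity (right-skewed scores, matching median/IQR-style
# reporting of disability and depression scales).
_CLINICAL_MODEL = {
    # var: (base, default loading, default noise sd, cap, log-scale?)
    "headache_freq": (4.0, 8.0, 4.0, 30.0, False),
    "painkiller_freq": (1.0, 4.0, 3.0, 30.0, False),
    "midas": (1.6, 1.2, 0.7, 270.0, True),
    "bdi": (1.55, 0.9, 0.5, 63.0, True),
    "duration_years": (12.0, 1.0, 9.0, 45.0, False),
}

DEFAULT_LATENT_LOADINGS = {v: _CLINICAL_MODEL[v][1] for v in CLINICAL_VARS}
DEFAULT_CLINICAL_NOISE = {v: _CLINICAL_MODEL[v][2] for v in CLINICAL_VARS}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth group effect: which regions age faster, and by how much.

    ``bag_shift`` is expressed as years of equivalent extra ageing; a patient
    with severity ``s`` loses ``slope_r * bag_shift * s`` a.u. of GMV in each
    affected region.  Severity is |Normal(severity_mean, severity_sd)| in
    patients and identically 0 in controls.  Clinical variables load on the
    same severity factor.
    """

    affected_regions: tuple[int, ...] = ()
    bag_shift: float = 4.0
    latent_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS))
    clinical_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_NOISE))
    patient_fraction: float = 110.0 / 180.0
    severity_mean: float = 1.0
    severity_sd: float = 0.5
    missing_clinical_fraction: float = 0.0

    def validate(self, n_regions: int) -> None:
        if not np.isfinite(self.bag_shift):
            raise ConfigurationError("bag_shift must be finite")
        for r in self.affected_regions:
            if not 1 <= int(r) <= n_regions:
                raise ConfigurationError(
                    f"affected region label {r} outside 1..{n_regions}")
        if not 0.0 < self.patient_fraction < 1.0:
            raise ConfigurationError("patient_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Generator internals sufficient to predict downstream effects analytically."""

    baselines: np.ndarray          # (R,) a.u.
    slopes: np.ndarray             # (R,) a.u. per year
    sex_coef: np.ndarray           # (R,) a.u. added for female subjects
    voxel_offsets: np.ndarray      # (R, V) a.u.
    brainage_deviation: np.ndarray  # (n,) years, the shared delta per subject
    severity: np.ndarray           # (n,) latent severity (0 for controls/normative)
    effect: EffectSpec | None = None


@dataclass
class CohortBundle:
    subject_table: pd.DataFrame
    region_means: np.ndarray       # (n, R) a.u.
    voxel_features: np.ndarray     # (n, R, V) a.u.
    truth: GroundTruth
    config: CohortConfig
    region_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.subject_table)
        if self.subject_table["age"].isna().any():
            raise ValueError("subject table contains missing ages")
        if self.region_means.shape[0] != n:
            raise ValueError("region_means row count != subject count")
        if not np.all(np.isfinite(self.region_means)):
            raise ValueError("non-finite region means")
        if not np.all(np.isfinite(self.voxel_features)):
            raise ValueError("non-finite voxel features")
        if self.region_labels is None:
            self.region_labels = np.arange(1, self.region_means.shape[1] + 1)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_table)

    @property
    def ages(self) -> np.ndarray:
        return self.subject_table["age"].to_numpy(float)

    def voxel_feature_map(self) -> dict[int, np.ndarray]:
        """Voxel features keyed by 1-based region label (subjects x voxels)."""
        return {int(lab): self.voxel_features[:, i, :]
                for i, lab in enumerate(self.region_labels)}


def _region_params(config: CohortConfig) -> tuple[np.ndarray, ...]:
    rng = np.random.default_rng(config.region_seed)
    slopes = rng.uniform(*config.slope_range, config.n_regions)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_regions)
    sex_coef = config.sex_effect * rng.uniform(0.5, 1.5, config.n_regions)
    voxel_offsets = rng.normal(0.0, 2.0, (config.n_regions, config.voxels_per_region))
    # centred per region so the regional voxel mean equals the latent mean
    voxel_offsets -= voxel_offsets.mean(axis=1, keepdims=True)
    return baselines, slopes, sex_coef, voxel_offsets


def _draw_demographics(config: CohortConfig, rng: np.random.Generator, n: int):
    age = rng.uniform(*config.age_range, n)
    female = rng.random(n) < config.female_fraction
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, n)
    site_idx = rng.integers(len(config.sites), size=n)
    if config.brainage_sd > 0:
        # inter-individual ageing trajectories diverge with age, so the
        # biological brain-age deviation scales with chronological age
        delta = rng.normal(0.0, 1.0, n) * (
            config.brainage_sd * age / config.brainage_age_pivot)
    else:
        delta = np.zeros(n)
    return age, female, tiv, site_idx, delta


def _region_means(config, baselines, slopes, sex_coef, age, female, tiv, site_idx,
                  delta, rng) -> np.ndarray:
    eff_age = age + delta
    m = baselines[None, :] - eff_age[:, None] * slopes[None, :]
    m = m + female[:, None].astype(float) * sex_coef[None, :]
    shifts = np.array([s.shift for s in config.sites])
    scales = np.array([s.scale for s in config.sites])
    m = m + shifts[site_idx][:, None]
    if config.tiv_coupling != 0:
        m = m * (tiv / config.tiv_mean)[:, None] ** config.tiv_coupling
    if config.noise_sd > 0:
        m = m + rng.normal(0.0, config.noise_sd, m.shape) * scales[site_idx][:, None]
    return m


def _voxelize(config: CohortConfig, means: np.ndarray, voxel_offsets: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    v = means[:, :, None] + voxel_offsets[None, :, :]
    if config.voxel_noise_sd > 0:
        v = v + rng.normal(0.0, config.voxel_noise_sd, v.shape)
    return v


def _subject_frame(config, prefix, age, female, tiv, site_idx) -> pd.DataFrame:
    n = len(age)
    labels = [config.sites[i].label for i in site_idx]
    df = pd.DataFrame({
        "id": [f"{prefix}{i:04d}" for i in range(1, n + 1)],
        "age": age,
        "sex": np.where(female, "F", "M"),
        "group": "control",
        "protocol": labels,
        "tiv_ml": tiv,
    })
    for v in CLINICAL_VARS:
        df[v] = np.nan
    return df


def generate_normative_cohort(config: CohortConfig) -> CohortBundle:
    """Healthy training cohort: no group effect, no clinical symptoms."""
    config.validate()
    baselines, slopes, sex_coef, voxel_offsets = _region_params(config)
    rng = np.random.default_rng(config.seed)
    age, female, tiv, site_idx, delta = _draw_demographics(config, rng, config.n_subjects)
    means = _region_means(config, baselines, slopes, sex_coef,
                          age, female, tiv, site_idx, delta, rng)
    voxels = _voxelize(config, means, voxel_offsets, rng)
    table = _subject_frame(config, "hc", age, female, tiv, site_idx)
    truth = GroundTruth(baselines, slopes, sex_coef, voxel_offsets,
                        delta, np.zeros(config.n_subjects))
    # region means are the arithmetic mean of the region's voxel features,
    # exactly what atlas extraction recovers from the emitted maps
    return CohortBundle(table, voxels.mean(axis=2), voxels, truth, config)


def _clinical_values(effect: EffectSpec, severity: np.ndarray,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    n = len(severity)
    for var in CLINICAL_VARS:
        base, _, _, cap, logscale = _CLINICAL_MODEL[var]
        loading = float(effect.latent_loadings.get(var, 0.0))
        noise_sd = float(effect.clinical_noise_sd.get(var, 0.0))
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        raw = base + loading * severity + noise
        vals = np.expm1(raw) if logscale else raw
        out[var] = np.clip(vals, 0.0, cap)
    return out


def generate_clinical_cohort(config: CohortConfig, effect: EffectSpec) -> CohortBundle:
    """Patient + control cohort with a severity-coupled regional ageing effect."""
    config.validate()
    effect.validate(config.n_regions)
    baselines, slopes, sex_coef, voxel_offsets = _region_params(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    age, female, tiv, site_idx, delta = _draw_demographics(config, rng, n)

    n_pat = int(round(effect.patient_fraction * n))
    is_patient = np.zeros(n, bool)
    is_patient[:n_pat] = True
    severity = np.zeros(n)
    severity[is_patient] = np.abs(
        rng.normal(effect.severity_mean, effect.severity_sd, n_pat))

    means = _region_means(config, baselines, slopes, sex_coef,
                          age, female, tiv, site_idx, delta, rng)
    if effect.affected_regions and effect.bag_shift != 0.0:
        idx = np.asarray(effect.affected_regions, int) - 1
        means[:, idx] -= severity[:, None] * slopes[idx][None, :] * effect.bag_shift
    voxels = _voxelize(config, means, voxel_offsets, rng)

    table = _subject_frame(config, "sub", age, female, tiv, site_idx)
    table.loc[is_patient, "group"] = "patient"
    clin = _clinical_values(effect, severity[is_patient], rng)
    for var in CLINICAL_VARS:
        table.loc[is_patient, var] = clin[var]
    if effect.missing_clinical_fraction > 0:
        drop = rng.random(n_pat) < effect.missing_clinical_fraction
        which = rng.integers(len(CLINICAL_VARS), size=n_pat)
        pat_pos = np.flatnonzero(is_patient)
        for p, d, w in zip(pat_pos, drop, which):
            if d:
                table.loc[p, CLINICAL_VARS[w]] = np.nan

    truth = GroundTruth(baselines, slopes, sex_coef, voxel_offsets,
                        delta, severity, effect=effect)
    return CohortBundle(table, voxels.mean(axis=2), voxels, truth, config)


# ---------------------------------------------------------------------------
# Analytic expectations from stored truth


def expected_regional_decrement(bundle: CohortBundle) -> float:
    """Mean GMV decrement (a.u.) in affected regions for patients.

    Analytic expectation ``bag_shift * mean(severity | patient) * mean(slope_r)``
    over the affected set, from the stored generator truth.
    """
    eff = bundle.truth.effect
    if eff is None or not eff.affected_regions:
        return 0.0
    idx = np.asarray(eff.affected_regions, int) - 1
    pat = bundle.subject_table["group"].to_numpy() == "patient"
    mean_sev = float(bundle.truth.severity[pat].mean())
    return float(eff.bag_shift * mean_sev * bundle.truth.slopes[idx].mean())


def expected_global_bag_difference(bundle: CohortBundle,
                                   attenuation: float = 1.0) -> float:
    """Expected patient-minus-control global BAG difference in years.

    A predictor that weights regions optimally (GLS weights proportional to
    slope_r^2 under equal region noise) converts a planted shift of
    ``bag_shift`` years in the affected subset into a global brain-age shift
    of ``bag_shift * sum_affected(slope^2) / sum_all(slope^2)``.  The additive
    bias correction transmits group differences with sensitivity equal to the
    bias-model slope, passed as ``attenuation``.
    """
    eff = bundle.truth.effect
    if eff is None or not eff.affected_regions:
        return 0.0
    idx = np.asarray(eff.affected_regions, int) - 1
    w = bundle.truth.slopes ** 2
    frac = float(w[idx].sum() / w.sum())
    pat = bundle.subject_table["group"].to_numpy() == "patient"
    mean_sev = float(bundle.truth.severity[pat].mean())
    return attenuation * eff.bag_shift * mean_sev * frac


def population_canonical_correlation(config: CohortConfig, effect: EffectSpec,
                                     n: int = 20000, seed: int = 12345) -> float:
    """Population mode-1 canonical correlation implied by the generator truth.

    Monte-Carlo evaluation at large ``n`` of the canonical correlation between
    the clinical variable set and the true regional ageing pattern that an
    ideal regional brain-age model would measure in affected regions:
    ``bag_shift * severity + brain-age deviation + region noise / slope``
    (years).  Uses the model equations directly, so clinical truncation and
    skew transforms are accounted for.
    """
    effect.validate(config.n_regions)
    if not effect.affected_regions:
        return 0.0
    rng = np.random.default_rng(seed)
    sev = np.abs(rng.normal(effect.severity_mean, effect.severity_sd, n))
    age = rng.uniform(*config.age_range, n)
    delta = rng.normal(0.0, 1.0, n) * (
        config.brainage_sd * age / config.brainage_age_pivot)
    _, slopes, _, _ = _region_params(config)
    idx = np.asarray(effect.affected_regions, int) - 1
    noise = rng.normal(0.0, config.noise_sd, (n, len(idx))) / slopes[idx][None, :]
    bag = effect.bag_shift * sev[:, None] + delta[:, None] + noise
    clin = _clinical_values(effect, sev, rng)
    y = np.column_stack([clin[v] for v in CLINICAL_VARS])
    from .clinical_cca import canonical_correlations
    return float(canonical_correlations(y, bag)[0])


# ---------------------------------------------------------------------------
# File emission (NIfTI lattice + TSV + truth sidecar)


def _lattice_shape(n_voxels: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    while side ** 3 < n_voxels:
        side += 1
    return (side, side, side)


def emit_cohort_files(bundle: CohortBundle, directory: str | os.PathLike) -> dict:
    """Write the bundle as subjects.tsv + per-subject GMV NIfTI + atlas + truth.

    Each region occupies a contiguous block of ``voxels_per_region`` voxels on
    a small 3-D lattice (C scan order), so extraction with the emitted atlas
    and probability map round-trips the voxel features exactly.
    """
    import nibabel as nib

    if bundle.n_subjects == 0:
        raise ValueError("cannot emit an empty bundle")
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    n, r, v = bundle.voxel_features.shape
    shape = _lattice_shape(r * v)
    affine = np.eye(4)

    atlas_flat = np.zeros(int(np.prod(shape)), dtype=np.int16)
    for i, lab in enumerate(bundle.region_labels):
        atlas_flat[i * v:(i + 1) * v] = lab
    atlas = atlas_flat.reshape(shape)
    atlas_path = os.path.join(directory, "atlas.nii.gz")
    nib.save(nib.Nifti1Image(atlas, affine), atlas_path)

    prob = (atlas > 0).astype(np.float32)
    prob_path = os.path.join(directory, "gm_prob.nii.gz")
    nib.save(nib.Nifti1Image(prob, affine), prob_path)

    gmv_dir = os.path.join(directory, "gmv")
    os.makedirs(gmv_dir, exist_ok=True)
    gmv_paths = []
    flat_feats = bundle.voxel_features.reshape(n, r * v)
    for s, sid in enumerate(bundle.subject_table["id"]):
        vol = np.zeros(int(np.prod(shape)), dtype=np.float64)
        vol[:r * v] = flat_feats[s]
        p = os.path.join(gmv_dir, f"{sid}.nii.gz")
        nib.save(nib.Nifti1Image(vol.reshape(shape), affine), p)
        gmv_paths.append(p)

    table_path = os.path.join(directory, "subjects.tsv")
    bundle.subject_table.to_csv(table_path, sep="\t", index=False)

    truth_path = os.path.join(directory, "truth.json")
    t = bundle.truth
    payload = {
        "baselines": t.baselines.tolist(),
        "slopes": t.slopes.tolist(),
        "sex_coef": t.sex_coef.tolist(),
        "brainage_deviation": t.brainage_deviation.tolist(),
        "severity": t.severity.tolist(),
        "effect": None if t.effect is None else {
            "affected_regions": list(map(int, t.effect.affected_regions)),
            "bag_shift": t.effect.bag_shift,
            "latent_loadings": dict(t.effect.latent_loadings),
            "clinical_noise_sd": dict(t.effect.clinical_noise_sd),
            "patient_fraction": t.effect.patient_fraction,
            "severity_mean": t.effect.severity_mean,
            "severity_sd": t.effect.severity_sd,
        },
        "config": {k: (list(val) if isinstance(val, tuple) and not isinstance(val[0], SiteSpec)
                       else val)
                   for k, val in asdict(bundle.config).items()
                   if k != "sites"},
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh)

    return {"subjects": table_path, "atlas": atlas_path, "gm_prob": prob_path,
            "gmv": gmv_paths, "truth": truth_path}


# ---------------------------------------------------------------------------
# Synthetic activation-foci database (stands in for a meta-analytic database)


FOCI_DOMAINS = ("action", "cognition", "emotion", "interoception", "perception")


def generate_foci_database(n_foci: int = 2000, n_subdomains: int = 59,
                           seed: int = 0, space: str = "synthetic",
                           box: float = 60.0,
                           enriched_subdomain: str | None = None,
                           enrichment_center: Sequence[float] = (0.0, 0.0, 0.0),
                           enrichment_sd: float = 10.0,
                           enrichment_fraction: float = 0.0) -> pd.DataFrame:
    """Synthetic labelled foci table for functional-decoding tests.

    Coordinates are uniform in a cube of half-width ``box`` mm; optionally one
    sub-domain's foci are drawn near ``enrichment_center`` to plant a real
    spatial association.  This is a synthetic stand-in for a meta-analytic
    coordinate database, not a reproduction of one.
    """
    rng = np.random.default_rng(seed)
    per_dom = int(np.ceil(n_subdomains / len(FOCI_DOMAINS)))
    subdomains, domains = [], []
    for d in FOCI_DOMAINS:
        for j in range(per_dom):
            if len(subdomains) < n_subdomains:
                subdomains.append(f"{d}.{j + 1:02d}")
                domains.append(d)
    sub_idx = rng.integers(len(subdomains), size=n_foci)
    xyz = rng.uniform(-box, box, (n_foci, 3))
    if enriched_subdomain is not None and enrichment_fraction > 0:
        target = subdomains.index(enriched_subdomain)
        hit = (sub_idx == target) & (rng.random(n_foci) < enrichment_fraction)
        xyz[hit] = rng.normal(np.asarray(enrichment_center, float),
                              enrichment_sd, (int(hit.sum()), 3))
    return pd.DataFrame({
        "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        "domain": [domains[i] for i in sub_idx],
        "subdomain": [subdomains[i] for i in sub_idx],
        "source": [f"study{i % 200:03d}" for i in range(n_foci)],
        "space": space,
    })
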