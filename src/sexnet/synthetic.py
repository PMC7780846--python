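"""Synthetic pseudo-brain cohorts with known injected effects.

The generator builds a smooth radial phantom (bright "cortex" shell over a
mid-intensity interior) carrying a small set of bilateral spherical regions
that serve as atlas ROIs.  Class-linked and confounder-linked effects are
injected into designated regions, so saliency-recovery and screening tests
have a known ground truth.  Covariates emulate a pre-adolescent cohort:
girls and boys differ in mean pubertal stage (PDS) and slightly in age,
which creates genuine confounding between the class label and the
demographic covariates.

The phantom is deliberately non-anatomical: the point is statistical
structure (localized effects, bilateral symmetry, confounded covariates,
voxel noise), not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Atlas, EffectSpec, SyntheticCohort

__all__ = [
    "CovariateModel",
    "COGNITIVE_TESTS",
    "DEFAULT_TEST_SPECS",
    "make_template",
    "make_atlas",
    "generate_cohort",
    "generate_cognitive_scores",
]

#: registry of recognised cognitive test names (NIH toolbox battery)
COGNITIVE_TESTS = (
    "flanker",
    "list_sorting",
    "card_sort",
    "oral_reading",
    "pattern_comparison",
    "picture_sequence",
    "picture_vocab",
)

#: per-test (mean_F, sd_F, mean_M, sd_M) defaults for a cohort of 9-10 year olds
DEFAULT_TEST_SPECS: dict[str, tuple[float, float, float, float]] = {
    "flanker": (96.29, 13.37, 97.09, 14.39),
    "list_sorting": (101.68, 14.08, 102.64, 14.68),
    "card_sort": (98.89, 15.07, 97.44, 15.54),
    "oral_reading": (104.45, 19.53, 103.65, 18.52),
    "pattern_comparison": (96.70, 20.92, 93.72, 22.18),
    "picture_sequence": (103.47, 16.47, 100.62, 15.81),
    "picture_vocab": (108.53, 16.98, 109.35, 17.05),
}


@dataclass(frozen=True)
class CovariateModel:
    """Distribution parameters for the cohort covariates.

    Defaults emulate a large 9-10 year-old cohort: age ~9.9 y in both
    sexes, PDS higher in girls (2.0 +/- 1.0) than boys (1.3 +/- 0.6), an
    arbitrary continuous SES index, and head size ~1342 cm^3.  The PDS gap
    makes PDS a genuine confounder of any sex-linked brain effect.

    ``latent_sd`` controls the within-class spread of the latent class
    signal (the continuous "brain femaleness" axis that sex thresholds);
    mediator-driven effects and mediation-linked cognitive scores load on
    this latent axis.
    """

    age_f: tuple[float, float] = (9.92, 0.62)
    age_m: tuple[float, float] = (9.95, 0.62)
    pds_f: tuple[float, float] = (2.0, 1.0)
    pds_m: tuple[float, float] = (1.3, 0.6)
    ses: tuple[float, float] = (18.0, 67.0)
    head_f: tuple[float, float] = (1341.5, 15.3)
    head_m: tuple[float, float] = (1342.0, 16.0)
    latent_sd: float = 0.5


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

# bilateral region centre offsets as fractions of the grid edge, right half;
# each is mirrored across the LR midplane and shares its label
_REGION_OFFSETS = (
    (0.1375, 0.13125, 0.13125),
    (0.1375, -0.13125, 0.13125),
    (0.1375, 0.13125, -0.13125),
    (0.1375, -0.13125, -0.13125),
    (0.21875, 0.0, 0.0),
)
_REGION_RADIUS_FRAC = 0.1


def _radial_distance(grid: int) -> np.ndarray:
    c = (grid - 1) / 2.0
    ax = np.arange(grid, dtype=np.float64) - c
    return np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)


def make_template(grid: int) -> np.ndarray:
    """Radial phantom: interior 1.0, bright shell 1.5, background 0."""
    if grid < 8:
        raise ValueError("grid must be at least 8 voxels")
    d = _radial_distance(grid)
    brain_r = 0.45 * grid
    vol = np.zeros((grid, grid, grid), dtype=np.float32)
    vol[d <= brain_r] = 1.0
    vol[(d > 0.8 * brain_r) & (d <= brain_r)] = 1.5
    return vol


def _region_centres(grid: int) -> dict[int, list[tuple[float, float, float]]]:
    c = (grid - 1) / 2.0
    centres: dict[int, list[tuple[float, float, float]]] = {}
    for label, (fx, fy, fz) in enumerate(_REGION_OFFSETS, start=1):
        right = (c + fx * grid, c + fy * grid, c + fz * grid)
        left = (grid - 1 - right[0], right[1], right[2])
        centres[label] = [right, left]
    return centres


def _sphere_mask(grid: int, centre: tuple[float, float, float], radius: float) -> np.ndarray:
    ax = np.arange(grid, dtype=np.float64)
    dx = (ax - centre[0])[:, None, None] ** 2
    dy = (ax - centre[1])[None, :, None] ** 2
    dz = (ax - centre[2])[None, None, :] ** 2
    return dx + dy + dz <= radius**2


def make_atlas(grid: int, spacing: float = 2.0) -> Atlas:
    """Integer-label atlas of bilateral spherical ROIs on the phantom grid."""
    if grid < 8:
        raise ValueError("grid must be at least 8 voxels")
    radius = max(1.0, _REGION_RADIUS_FRAC * grid)
    labels = np.zeros((grid, grid, grid), dtype=np.int32)
    regions: dict[int, tuple[list[tuple[float, float, float]], float]] = {}
    for label, centres in _region_centres(grid).items():
        for centre in centres:
            labels[_sphere_mask(grid, centre, radius)] = label
        regions[label] = (centres, radius)
    return Atlas(labels=labels, regions=regions, spacing=spacing)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _draw_covariates(n: int, model: CovariateModel, rng: np.random.Generator) -> pd.DataFrame:
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sex = np.zeros(n, dtype=np.int64)
    sex[: n // 2] = 1  # balanced within +/- 1
    perm = rng.permutation(n)
    sex = sex[perm]

    def per_sex(par_f: tuple[float, float], par_m: tuple[float, float]) -> np.ndarray:
        out = np.empty(n)
        girls = sex == 1
        out[girls] = rng.normal(par_f[0], par_f[1], girls.sum())
        out[~girls] = rng.normal(par_m[0], par_m[1], (~girls).sum())
        return out

    age = per_sex(model.age_f, model.age_m)
    pds = np.clip(per_sex(model.pds_f, model.pds_m), 1.0, 5.0)
    ses = rng.normal(model.ses[0], model.ses[1], n)
    head = per_sex(model.head_f, model.head_m)
    latent = (2.0 * sex - 1.0) + rng.normal(0.0, model.latent_sd, n)

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "pds": pds,
            "pds_level": np.clip(np.rint(pds), 1, 5).astype(int),
            "ses": ses,
            "head_size": head,
            "z_age": _zscore(age),
            "z_pds": _zscore(pds),
            "z_ses": _zscore(ses),
            "latent": latent,
        }
    )


def _driver_values(records: pd.DataFrame, driver: str) -> np.ndarray:
    """Per-subject modulation of an effect, centred so the cohort mean is ~0.

    Sex is centred to +/-0.5 so that an intensity effect of magnitude m
    separates the class means by m noise-SD units.
    """
    if driver == "sex":
        return records["sex"].to_numpy(dtype=np.float64) - 0.5
    if driver == "mediator":
        lat = records["latent"].to_numpy(dtype=np.float64)
        sd = lat.std(ddof=0)
        return (lat - lat.mean()) / (2.0 * sd if sd > 0 else 1.0)
    col = {"age": "z_age", "pds": "z_pds", "ses": "z_ses"}[driver]
    return records[col].to_numpy(dtype=np.float64) / 2.0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n: int,
    grid: int = 16,
    effects: list[EffectSpec] | None = None,
    covariate_model: CovariateModel | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    spacing: float = 2.0,
) -> SyntheticCohort:
    """Generate ``n`` phantom volumes plus a covariate table.

    Each volume is the fixed template plus the sum of the requested effect
    contributions for that subject's covariates plus i.i.d. Gaussian voxel
    noise.  Effects are placed identically in both mirror halves of the
    grid, so injected group differences are bilateral.

    ``intensity_shift`` adds ``magnitude * noise_sd * x_i`` over the region,
    where ``x_i`` is the subject's centred driver value (``+/-0.5`` for
    sex).  ``volume_scale`` dilates/erodes the region sphere by a
    driver-dependent fractional volume change while rescaling the added
    contrast to conserve the total added intensity, i.e. it changes shape
    but leaves the fixed-ROI mean intensity (and volume under the fixed
    atlas) unchanged -- a cue voxel-level learning can use but ROI
    summaries cannot.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    effects = list(effects or [])
    covariate_model = covariate_model or CovariateModel()

    atlas = make_atlas(grid, spacing=spacing)
    for eff in effects:
        if eff.region_label not in atlas.regions:
            raise KeyError(
                f"effect references atlas label {eff.region_label}, "
                f"available labels are {atlas.roi_labels}"
            )

    rng = np.random.default_rng(seed)
    records = _draw_covariates(n, covariate_model, rng)
    template = make_template(grid)

    base_contrast = 2.0  # in noise-SD units, for volume_scale effects
    volumes = np.empty((n, grid, grid, grid), dtype=np.float32)
    # deterministic given seed: noise drawn in one block, subjects in order
    noise = rng.normal(0.0, noise_sd, size=(n, grid, grid, grid)).astype(np.float32)

    static_masks = {
        eff.region_label: atlas.labels == eff.region_label
        for eff in effects
        if eff.effect_kind == "intensity_shift"
    }
    driver_cache = {eff.driver: _driver_values(records, eff.driver) for eff in effects}

    for i in range(n):
        vol = template.copy()
        for eff in effects:
            x = driver_cache[eff.driver][i]
            if eff.effect_kind == "intensity_shift":
                vol[static_masks[eff.region_label]] += np.float32(eff.magnitude * noise_sd * x)
            else:  # volume_scale
                centres, r0 = atlas.regions[eff.region_label]
                vol_frac = np.clip(1.0 + eff.magnitude * x, 0.2, 5.0)
                radius = r0 * vol_frac ** (1.0 / 3.0)
                contrast = base_contrast * noise_sd / vol_frac
                for centre in centres:
                    vol[_sphere_mask(grid, centre, radius)] += np.float32(contrast)
        volumes[i] = vol + noise[i]

    return SyntheticCohort(
        records=records,
        volumes=volumes,
        atlas=atlas,
        truth=effects,
        seed=seed,
        spacing=spacing,
    )


def generate_cognitive_scores(
    records: pd.DataFrame,
    test_specs: dict[str, tuple[float, float, float, float]] | None = None,
    mediation_link: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach cognitive test scores drawn per sex; optionally tie a test to the latent class signal.

    ``test_specs`` maps a registered test name to ``(mean_F, sd_F, mean_M,
    sd_M)``.  A ``mediation_link`` coefficient adds ``coef * latent`` to the
    named test, making that score carry class-signal variance beyond the
    binary label (the structure a partial-mediation analysis detects).
    Returns a copy of ``records`` with one ``nih_<test>`` column per test.
    """
    test_specs = dict(test_specs or DEFAULT_TEST_SPECS)
    mediation_link = dict(mediation_link or {})
    for name in list(test_specs) + list(mediation_link):
        if name not in COGNITIVE_TESTS:
            raise KeyError(
                f"unknown cognitive test {name!r}; registered tests: {COGNITIVE_TESTS}"
            )
    for name, (_, sd_f, _, sd_m) in test_specs.items():
        if sd_f <= 0 or sd_m <= 0:
            raise ValueError(f"test {name!r} has non-positive SD")

    rng = np.random.default_rng(seed)
    out = records.copy()
    girls = out["sex"].to_numpy() == 1
    latent = out["latent"].to_numpy() if "latent" in out else np.zeros(len(out))
    for name in sorted(test_specs):
        mean_f, sd_f, mean_m, sd_m = test_specs[name]
        score = np.where(
            girls,
            rng.normal(mean_f, sd_f, len(out)),
            rng.normal(mean_m, sd_m, len(out)),
        )
        score = score + mediation_link.get(name, 0.0) * latent
        out[f"nih_{name}"] = score
    return out
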