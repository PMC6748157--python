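"""Synthetic cohorts and image fixtures for the lesion-topology analysis.

The tabular generator draws covariates with the moments of the study
cohort (age 64.59 +- 15.76 years truncated at 18, 64% male, DWI lesion
volume log-normal with mean 15.01 and sd 30.00 cc, rich-club involvement
count N_RC on 0-12 with mean 1.33 and sd 1.27) and couples DWIv and N_RC
through a Gaussian copula on (log-DWIv, latent N_RC score).  The default
copula correlation (0.93) is calibrated so that the variance inflation
factor of N_RC regressed on the other covariates is ~1.9 on the raw scale,
which also induces a raw Pearson correlation of ~0.69 between DWIv and the
region counts.

Ordinal outcomes (NIHSS 0-42, mRS 0-6) are drawn from a proportional-odds
model P(Y <= j | x) = logistic(theta_j - x.beta).  Default slopes are the
rich-club model coefficients of the source study; the cut-points are not
published and are calibrated at run time against the cohort's target
marginal outcome means (mRS 1.68, NIHSS 5.58) over a geometric marginal
shape.

Image fixtures are geometric: a synthetic atlas with 12 rich-club blobs
(6 mirrored bilateral pairs) plus optional other regions, and ellipsoidal
lesion masks constructed to intersect an exact requested subset of the
rich-club regions, so the scoring stage can be exercised end to end with a
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import CalibrationError, ConfigurationError, GenerationError, InputError
from .scoring import BinaryMask, LabelVolume

__all__ = [
    "GeneratingModel",
    "CohortConfig",
    "MRS_RICHCLUB_COEFS",
    "NIHSS_RICHCLUB_COEFS",
    "sample_covariates",
    "sample_outcomes",
    "calibrate_thresholds",
    "default_generating_models",
    "simulate_cohort",
    "make_synthetic_atlas",
    "sample_lesion_mask",
    "simulate_image_cohort",
    "linear_predictor",
]

COHORT_COLUMNS = ["id", "age", "sex", "dwiv_cc", "n_rc", "n_total", "nihss", "mrs"]

RICHCLUB_TERMS = ("age", "sex", "age:sex", "dwiv_cc", "n_rc", "dwiv_cc:n_rc")

# Rich-club model coefficients reported for the study cohort (log-odds units)
MRS_RICHCLUB_COEFS = {
    "age": 0.05, "sex": 0.78, "age:sex": -0.02,
    "dwiv_cc": 0.05, "n_rc": 0.33, "dwiv_cc:n_rc": -0.01,
}
NIHSS_RICHCLUB_COEFS = {
    "age": 0.03, "sex": 0.9, "age:sex": -0.02,
    "dwiv_cc": 0.08, "n_rc": 0.57, "dwiv_cc:n_rc": -0.01,
}
MRS_TARGET_MEAN = 1.68
NIHSS_TARGET_MEAN = 5.58

# 6 bilateral rich-club region pairs
RICH_CLUB_REGION_NAMES = (
    "precuneus",
    "superior_frontal",
    "superior_parietal",
    "hippocampus",
    "putamen",
    "thalamus",
)


@dataclass(frozen=True)
class GeneratingModel:
    """Proportional-odds generative law for one ordinal outcome."""

    term_names: tuple[str, ...]
    beta: tuple[float, ...]
    thresholds: tuple[float, ...]
    outcome_levels: tuple[int, ...]

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        th = np.asarray(self.thresholds, dtype=float)
        if len(self.term_names) != beta.size:
            raise ConfigurationError("term_names and beta lengths differ")
        if not np.all(np.isfinite(beta)):
            raise ConfigurationError("beta must be finite")
        if th.size != len(self.outcome_levels) - 1:
            raise ConfigurationError(
                "need exactly len(outcome_levels) - 1 thresholds"
            )
        if th.size > 1 and np.any(np.diff(th) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class CohortConfig:
    """Simulation settings; defaults reproduce the study cohort's moments."""

    n: int = 344
    seed: int = 0
    age_mean: float = 64.59
    age_sd: float = 15.76
    male_fraction: float = 0.64
    dwiv_mean: float = 15.01
    dwiv_sd: float = 30.00
    nrc_mean: float = 1.33
    nrc_sd: float = 1.27
    dwiv_nrc_corr: float = 0.93
    n_other_mean: float = 2.3
    n_other_sd: float = 2.0
    generating_models: dict | None = field(default=None)

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        for name in ("age_sd", "dwiv_mean", "dwiv_sd", "nrc_sd", "n_other_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.0 <= self.dwiv_nrc_corr < 1.0):
            raise ConfigurationError("dwiv_nrc_corr must lie in [0, 1)")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _count_marginal(mean: float, sd: float, upper: int):
    """Negative-binomial marginal for a small count, truncated at ``upper``.

    Over-dispersed relative to Poisson when sd^2 > mean, which holds for
    the study's involvement counts.
    """
    var = sd**2
    if var <= mean:
        # fall back to Poisson when not over-dispersed
        return stats.poisson(mean), upper
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom(r, p), upper


def linear_predictor(covariates: pd.DataFrame, term_names, beta) -> np.ndarray:
    """x . beta where interaction terms ``a:b`` are elementwise products."""
    beta = np.asarray(beta, dtype=float)
    eta = np.zeros(len(covariates))
    for name, b in zip(term_names, beta):
        if ":" in name:
            a, c = name.split(":")
            col = np.asarray(covariates[a], float) * np.asarray(covariates[c], float)
        else:
            col = np.asarray(covariates[name], float)
        eta += b * col
    return eta


# ----------------------------------------------------------------------
# covariates
# ----------------------------------------------------------------------

def sample_covariates(config: CohortConfig, rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Draw (age, sex, dwiv_cc, n_rc) for ``config.n`` patients.

    Age is normal truncated at 18 years; sex is Bernoulli (male = 1);
    DWIv is log-normal moment-matched to the target mean/sd; N_RC comes
    from a Gaussian copula with the log-DWIv latent, with a truncated
    negative-binomial marginal on 0-12.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n
    a = (18.0 - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    sex = (rng.random(n) < config.male_fraction).astype(int)

    mu, sig = _lognormal_params(config.dwiv_mean, config.dwiv_sd)
    rho = config.dwiv_nrc_corr
    z_d = rng.standard_normal(n)
    z_n = rho * z_d + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    dwiv = np.exp(mu + sig * z_d)
    nrc_dist, cap = _count_marginal(config.nrc_mean, config.nrc_sd, upper=12)
    n_rc = np.minimum(nrc_dist.ppf(stats.norm.cdf(z_n)), cap).astype(int)
    return pd.DataFrame({"age": age, "sex": sex, "dwiv_cc": dwiv, "n_rc": n_rc})


def _sample_n_other(config: CohortConfig, dwiv: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Count of affected non-rich-club regions, copula-coupled to DWIv."""
    mu, sig = _lognormal_params(config.dwiv_mean, config.dwiv_sd)
    z_d = (np.log(dwiv) - mu) / sig
    rho = config.dwiv_nrc_corr
    z = rho * z_d + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(dwiv))
    dist, cap = _count_marginal(config.n_other_mean, config.n_other_sd, upper=30)
    return np.minimum(dist.ppf(stats.norm.cdf(z)), cap).astype(int)


# ----------------------------------------------------------------------
# outcomes
# ----------------------------------------------------------------------

def sample_outcomes(covariates: pd.DataFrame, model: GeneratingModel,
                    seed: int | np.random.Generator) -> np.ndarray:
    """Draw one ordinal outcome per row from the proportional-odds law."""
    th = np.asarray(model.thresholds, dtype=float)
    if th.size > 1 and np.any(np.diff(th) <= 0):
        raise ConfigurationError("thresholds must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = linear_predictor(covariates, model.term_names, model.beta)
    cdf = expit(th[None, :] - eta[:, None])
    u = rng.random(len(covariates))
    idx = (u[:, None] > cdf).sum(axis=1)
    levels = np.asarray(model.outcome_levels)
    return levels[idx]


def calibrate_thresholds(model: GeneratingModel, covariates: pd.DataFrame,
                         target_proportions=None, target_mean=None
                         ) -> np.ndarray:
    """Solve for cut-points matching a target marginal outcome distribution.

    With ``target_proportions`` p_1..p_J the thresholds solve, one by one,

        mean_i logistic(theta_j - x_i.beta) = p_1 + ... + p_j,

    which makes the *expected* marginal equal the target exactly.  With
    ``target_mean`` the proportions are first built from a geometric shape
    over the outcome levels whose mean equals the target (a one-parameter
    right-skewed family appropriate for stroke-scale scores), then solved
    the same way.
    """
    if (target_proportions is None) == (target_mean is None):
        raise CalibrationError("give exactly one of target_proportions/target_mean")
    levels = np.asarray(model.outcome_levels, dtype=float)
    J = levels.size
    if target_mean is not None:
        if not (levels.min() < target_mean < levels.max()):
            raise CalibrationError(
                f"target mean {target_mean} outside outcome range "
                f"[{levels.min()}, {levels.max()}]"
            )
        target_proportions = _geometric_proportions(levels, target_mean)
    p = np.asarray(target_proportions, dtype=float)
    if p.size != J:
        raise CalibrationError("need one proportion per outcome level")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise CalibrationError("proportions must be non-negative and sum to 1")
    cum = np.cumsum(p)[:-1]
    if np.any(cum <= 0.0) or np.any(cum >= 1.0) or np.any(np.diff(cum) <= 0):
        raise CalibrationError(
            "degenerate target: every cumulative proportion must lie strictly "
            "in (0, 1) and increase strictly"
        )
    eta = linear_predictor(covariates, model.term_names, model.beta)
    if np.ptp(eta) < 1e-12:
        return logit(cum) + eta[0] if len(eta) else logit(cum)
    thresholds = np.empty(J - 1)
    for j, c in enumerate(cum):
        lo = logit(c) + eta.min() - 1.0
        hi = logit(c) + eta.max() + 1.0
        thresholds[j] = brentq(
            lambda t: expit(t - eta).mean() - c, lo, hi, xtol=1e-12
        )
    return thresholds


def _geometric_proportions(levels: np.ndarray, target_mean: float) -> np.ndarray:
    """Truncated-geometric category weights with the requested mean."""
    J = levels.size
    j = np.arange(J)

    def weights(logw):
        lw = logw * j
        w = np.exp(lw - lw.max())  # stable normalization
        return w / w.sum()

    lo, hi = -30.0, 30.0
    logw = brentq(lambda lw: float(levels @ weights(lw)) - target_mean,
                  lo, hi, xtol=1e-12)
    return weights(logw)


def default_generating_models(covariates: pd.DataFrame) -> dict[str, GeneratingModel]:
    """Rich-club-model generating laws for mRS and NIHSS.

    Slopes are the study's rich-club coefficients; the unpublished
    cut-points are calibrated against the cohort's target marginal means.
    """
    out = {}
    for name, coefs, levels, mean in (
        ("mrs", MRS_RICHCLUB_COEFS, tuple(range(7)), MRS_TARGET_MEAN),
        ("nihss", NIHSS_RICHCLUB_COEFS, tuple(range(43)), NIHSS_TARGET_MEAN),
    ):
        skeleton = GeneratingModel(
            term_names=tuple(coefs),
            beta=tuple(coefs.values()),
            thresholds=tuple(np.arange(len(levels) - 1, dtype=float)),
            outcome_levels=levels,
        )
        th = calibrate_thresholds(skeleton, covariates, target_mean=mean)
        out[name] = replace(skeleton, thresholds=tuple(th))
    return out


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Full tabular cohort: id, age, sex, dwiv_cc, n_rc, n_total, nihss, mrs.

    Reproducible bit-for-bit for a given config (all draws flow from one
    seeded generator in fixed order).  ``n_total`` adds a copula-coupled
    count of affected non-rich-club regions, floored at 1 (every patient
    has a lesion touching at least one labeled region).
    """
    rng = np.random.default_rng(config.seed)
    cov = sample_covariates(config, rng)
    n_other = _sample_n_other(config, cov["dwiv_cc"].to_numpy(), rng)
    models = (config.generating_models
              if config.generating_models is not None
              else default_generating_models(cov))
    nihss = sample_outcomes(cov, models["nihss"], rng)
    mrs = sample_outcomes(cov, models["mrs"], rng)
    df = pd.DataFrame({
        "id": [f"p{i:04d}" for i in range(config.n)],
        "age": cov["age"],
        "sex": cov["sex"],
        "dwiv_cc": cov["dwiv_cc"],
        "n_rc": cov["n_rc"],
        "n_total": np.maximum(cov["n_rc"].to_numpy() + n_other, 1),
        "nihss": nihss,
        "mrs": mrs,
    })
    return df


# ----------------------------------------------------------------------
# image fixtures
# ----------------------------------------------------------------------

def _ball_coords(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def make_synthetic_atlas(shape=(48, 56, 44), n_rc_regions: int = 12,
                         n_other_regions: int = 10, seed: int = 0,
                         voxel_mm: float = 2.0, region_radius: float = 3.0,
                         max_retries: int = 500) -> LabelVolume:
    """Synthetic parcellation with mirrored bilateral rich-club blobs.

    Rich-club regions are spherical blobs placed as 6 bilateral pairs
    mirrored across the mid-sagittal plane (labels 1..12); other regions
    are spheres placed anywhere free (labels 13..).  No voxel carries two
    labels by construction (single integer volume, disjointness enforced
    with a one-voxel margin).
    """
    if n_rc_regions != 12:
        raise ConfigurationError(
            "the canonical rich-club template has exactly 12 regions "
            "(6 bilateral pairs)"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int16)
    blocked = np.zeros(shape, dtype=bool)  # occupancy incl. margin
    r = region_radius
    margin = int(np.ceil(r)) + 1

    def place(label, center, radius):
        ball = _ball_coords(shape, center, (radius,) * 3)
        grown = _ball_coords(shape, center, (radius + 1.0,) * 3)
        if ball.sum() == 0 or (blocked & grown).any():
            return False
        labels[ball] = label
        blocked[grown] = True
        return True

    rows = []
    mid = (shape[0] - 1) / 2.0
    for i, name in enumerate(RICH_CLUB_REGION_NAMES):
        placed = False
        for _ in range(max_retries):
            cx = rng.uniform(margin, mid - r - 1.0)
            cy = rng.uniform(margin, shape[1] - 1 - margin)
            cz = rng.uniform(margin, shape[2] - 1 - margin)
            left = (cx, cy, cz)
            right = (shape[0] - 1 - cx, cy, cz)
            lab_l, lab_r = 2 * i + 1, 2 * i + 2
            if place(lab_l, left, r):
                if place(lab_r, right, r):
                    placed = True
                    break
                # undo left placement if mirror failed
                ball = _ball_coords(shape, left, (r,) * 3)
                grown = _ball_coords(shape, left, (r + 1.0,) * 3)
                labels[ball] = 0
                blocked[grown] = False
        if not placed:
            raise GenerationError(f"could not place bilateral pair {name!r}")
        rows.append((2 * i + 1, name, "L", True))
        rows.append((2 * i + 2, name, "R", True))

    for k in range(n_other_regions):
        lab = 12 + k + 1
        rad = rng.uniform(2.0, r)
        placed = False
        for _ in range(max_retries):
            c = tuple(rng.uniform(margin, s - 1 - margin) for s in shape)
            if place(lab, c, rad):
                placed = True
                break
        if not placed:
            raise GenerationError(f"could not place other region {lab}")
        hemi = "L" if c[0] < mid else "R"
        rows.append((lab, f"other_{k + 1}", hemi, False))

    table = pd.DataFrame(rows, columns=["label", "name", "hemisphere", "is_rich_club"])
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return LabelVolume(labels=labels, affine=affine, label_table=table)


def sample_lesion_mask(atlas: LabelVolume, target_regions, volume_voxels: int = 150,
                       seed: int = 0, max_retries: int = 200) -> BinaryMask:
    """Ellipsoidal lesion intersecting exactly the requested rich-club regions.

    The mask may freely overlap background and non-rich-club labels; the
    constraint is on the *rich-club* subset touched.  Raises
    :class:`GenerationError` when no satisfying ellipsoid is found within
    bounded retries (e.g. geometrically incompatible target sets).
    """
    rng = np.random.default_rng(seed)
    rc = atlas.rich_club_labels
    targets = set(int(t) for t in target_regions)
    present = set(np.unique(atlas.labels)) - {0}
    if not targets <= present:
        raise InputError(f"target labels absent from atlas: {sorted(targets - present)}")
    if not targets <= rc:
        raise InputError("target regions must be rich-club labels")
    shape = atlas.labels.shape
    base_r = max((3.0 * volume_voxels / (4.0 * np.pi)) ** (1.0 / 3.0), 1.5)

    if not targets:
        free = np.argwhere((atlas.labels == 0))
        for _ in range(max_retries):
            c = free[rng.integers(len(free))]
            ball = _ball_coords(shape, c, (base_r,) * 3)
            touched = set(np.unique(atlas.labels[ball])) & rc
            if ball.sum() and not touched:
                return BinaryMask(mask=ball, affine=atlas.affine)
        raise GenerationError("could not place background lesion")

    target_voxels = {t: np.argwhere(atlas.labels == t) for t in targets}
    for _ in range(max_retries):
        anchors = np.array([
            v[rng.integers(len(v))] for v in target_voxels.values()
        ], dtype=float)
        center = anchors.mean(axis=0)
        spread = (anchors.max(axis=0) - anchors.min(axis=0)) / 2.0
        radii = np.maximum(spread + 1.5, base_r)
        for _ in range(12):
            ell = _ball_coords(shape, center, radii)
            touched = set(int(v) for v in np.unique(atlas.labels[ell])) & rc
            if touched == targets:
                return BinaryMask(mask=ell, affine=atlas.affine)
            if targets - touched:
                radii = radii * 1.2  # grow until all targets reached
            else:
                break  # overshot into extra rich-club regions; re-anchor
    raise GenerationError(
        f"no ellipsoid intersecting exactly rich-club set {sorted(targets)} "
        f"found in {max_retries} retries"
    )


def _clustered_targets(atlas: LabelVolume, k: int, rng: np.random.Generator) -> set[int]:
    """A spatially contiguous set of k rich-club labels (seed + nearest)."""
    rc = sorted(atlas.rich_club_labels)
    if k == 0:
        return set()
    centroids = {lab: np.argwhere(atlas.labels == lab).mean(axis=0) for lab in rc}
    seed_lab = rc[rng.integers(len(rc))]
    dists = sorted(rc, key=lambda lab: np.linalg.norm(centroids[lab] - centroids[seed_lab]))
    return set(dists[:k])


def simulate_image_cohort(atlas: LabelVolume, n_patients: int, seed: int = 0,
                          max_nrc: int = 3, volume_voxels: int = 150):
    """Per-patient lesion masks with known rich-club involvement counts.

    Intended counts are drawn from the tabular N_RC marginal (capped at
    ``max_nrc`` so targets stay geometrically contiguous); target sets are
    nearest-neighbour clusters of rich-club regions.  Returns
    ``(masks, intended)`` where ``masks`` maps patient id to
    :class:`BinaryMask` and ``intended`` is a DataFrame of ground-truth
    counts.
    """
    rng = np.random.default_rng(seed)
    dist, cap = _count_marginal(1.33, 1.27, upper=max_nrc)
    masks = {}
    rows = []
    for i in range(n_patients):
        pid = f"p{i:04d}"
        k = int(min(dist.ppf(rng.random()), cap))
        mask = None
        for _ in range(20):
            targets = _clustered_targets(atlas, k, rng)
            try:
                mask = sample_lesion_mask(
                    atlas, targets, volume_voxels=volume_voxels,
                    seed=int(rng.integers(2**31 - 1)),
                )
                break
            except GenerationError:
                continue
        if mask is None:
            raise GenerationError(f"could not generate lesion for patient {pid}")
        masks[pid] = mask
        rows.append({"id": pid, "n_rc_intended": k})
    return masks, pd.DataFrame(rows)


def save_image_cohort(atlas: LabelVolume, masks: dict, out_dir) -> None:
    """Write the atlas (+label TSV) and per-patient masks as NIfTI files."""
    from pathlib import Path

    from .scoring import write_label_volume, write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_label_volume(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv")
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for pid, mask in masks.items():
        write_mask(mask, mask_dir / f"{pid}.nii.gz")
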