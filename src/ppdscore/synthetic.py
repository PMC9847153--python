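"""Seeded generators for slice images, cohort tables and trait tables.

These emulate the statistical structure the analysis assumes, so the whole
pipeline can be exercised and validated without photographs:

- ``simulate_slice_image`` renders a light parenchyma disc with a darker
  peel annulus and dark streak/blob lesions whose load grows with a
  ``deterioration`` level in [0, 1], plus a ground-truth record;
- ``simulate_cohort`` draws per-root scores around archetype trajectories
  (delayed / intermediate-peak / intermediate-late / early) with cultivar
  random effects, Gaussian noise and contamination flags;
- ``simulate_traits`` draws a trait table (DMC %, length cm, diameter cm,
  HCN ppm) with an analytically controlled correlation between DMC and the
  4 dph PPD score.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw

__all__ = [
    "SliceSimSpec",
    "simulate_slice_image",
    "Archetype",
    "DEFAULT_ARCHETYPES",
    "archetype_class",
    "CohortSimSpec",
    "simulate_cohort",
    "simulate_traits",
]


# ---------------------------------------------------------------------------
# slice images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliceSimSpec:
    """Rendering parameters of one synthetic root-slice photograph.

    ``deterioration`` in [0, 1] controls the expected lesion load: the
    number of lesions is Poisson(lesion_count_rate * deterioration).
    Lesions are drawn by thinning a seed-fixed pool, so at a fixed seed the
    lesion set is nested in the deterioration level (raising the level only
    adds lesions).  Intensities are unitless grayscale in [0, 1].
    """

    image_size: int = 256
    disc_radius: int = 100
    peel_width: int = 8
    parenchyma_mean: float = 0.75
    parenchyma_noise_sd: float = 0.02
    deterioration: float = 0.0
    lesion_count_rate: float = 40.0
    lesion_darkness: float = 0.45
    background_level: float = 0.06
    peel_level: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deterioration <= 1.0:
            raise ValueError("deterioration must lie in [0, 1]")
        if self.parenchyma_mean - self.lesion_darkness < 0.0:
            raise ValueError("lesion_darkness would drive lesions below 0")
        if 2 * self.disc_radius >= self.image_size:
            raise ValueError("disc does not fit in the image")


def _disc_mask(size: int, radius: float) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _stamp_thick_line(
    mask: np.ndarray, r0: float, c0: float, r1: float, c1: float, width: int
) -> None:
    rr, cc = draw.line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    dy, dx = np.ogrid[-width: width + 1, -width: width + 1]
    offs = np.argwhere(dy**2 + dx**2 <= width**2) - width
    pts = np.stack([rr, cc], axis=1)[:, None, :] + offs[None, :, :]
    pts = pts.reshape(-1, 2)
    valid = (
        (pts[:, 0] >= 0) & (pts[:, 0] < mask.shape[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < mask.shape[1])
    )
    mask[pts[valid, 0], pts[valid, 1]] = True


def simulate_slice_image(spec: SliceSimSpec) -> tuple[np.ndarray, dict]:
    """Render one synthetic slice photograph.

    Returns
    -------
    rgb : float array (H, W, 3) in [0, 1]
    truth : dict with the deterioration level, the lesion count and pixel
        fraction inside the disc, the disc/parenchyma masks and geometry.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = (size - 1) / 2.0

    disc = _disc_mask(size, spec.disc_radius)
    parenchyma = _disc_mask(size, spec.disc_radius - spec.peel_width)
    peel = disc & ~parenchyma

    # Draws are consumed in a fixed order (noise field, pool size, lesion
    # attributes, inclusion variates) so the lesion pool is identical across
    # deterioration levels at the same seed.
    noise = rng.normal(0.0, spec.parenchyma_noise_sd, size=(size, size))
    n_pool = rng.poisson(spec.lesion_count_rate)
    lesions = np.zeros((size, size), dtype=bool)
    included = 0
    if n_pool > 0:
        angle = rng.uniform(0.0, 2 * np.pi, n_pool)
        radial = spec.disc_radius * np.sqrt(rng.uniform(0.0, 0.55, n_pool))
        length = rng.uniform(0.2, 0.5, n_pool) * spec.disc_radius
        width = rng.integers(1, 4, n_pool)
        is_blob = rng.random(n_pool) < 0.3
        blob_radius = rng.uniform(3.0, 8.0, n_pool)
        inclusion = rng.random(n_pool)
        for i in range(n_pool):
            if inclusion[i] >= spec.deterioration:
                continue
            included += 1
            r0 = center + radial[i] * np.sin(angle[i])
            c0 = center + radial[i] * np.cos(angle[i])
            if is_blob[i]:
                rr, cc = draw.disk((r0, c0), blob_radius[i], shape=(size, size))
                lesions[rr, cc] = True
            else:
                # Radial streak: outward from the lesion origin.
                r1 = r0 + length[i] * np.sin(angle[i])
                c1 = c0 + length[i] * np.cos(angle[i])
                _stamp_thick_line(lesions, r0, c0, r1, c1, int(width[i]))
    lesions &= parenchyma

    gray = np.full((size, size), spec.background_level)
    gray[disc] = spec.peel_level
    gray[parenchyma] = spec.parenchyma_mean
    gray = gray + noise
    gray[lesions] -= spec.lesion_darkness
    gray = np.clip(gray, 0.0, 1.0)

    # Mild warm tint so the RGB -> grayscale step is exercised non-trivially.
    gains = np.array([1.0, 0.98, 0.90])
    rgb = np.clip(gray[:, :, None] * gains[None, None, :], 0.0, 1.0)

    truth = {
        "deterioration": spec.deterioration,
        "n_lesions": included,
        "lesion_fraction": float(lesions[parenchyma].mean()),
        "disc_mask": disc,
        "parenchyma_mask": parenchyma,
        "peel_mask": peel,
        "center": (center, center),
        "disc_radius": spec.disc_radius,
    }
    return rgb, truth


# ---------------------------------------------------------------------------
# cohort trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Archetype:
    """A PPD-development pattern: true mean score per dph timepoint."""

    label: str
    trajectory: tuple[tuple[int, float], ...]

    def true_score(self, dph: int) -> float:
        traj = dict(self.trajectory)
        if dph in traj:
            return traj[dph]
        # Linear interpolation / plateau extension for off-grid timepoints.
        ts = sorted(traj)
        return float(np.interp(dph, ts, [traj[t] for t in ts]))


#: Default archetypes bracket the observed cohort trajectories: flat-low
#: (delayed), a mid-course peak that falls back, a late jump, and a fast
#: rise to a high plateau (baselines 0.13-0.15, early plateau ~0.5).
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("delayed", ((0, 0.15), (2, 0.17), (4, 0.20), (7, 0.23))),
    Archetype("intermediate-peak", ((0, 0.13), (2, 0.25), (4, 0.40), (7, 0.20))),
    Archetype("intermediate-late", ((0, 0.13), (2, 0.14), (4, 0.28), (7, 0.50))),
    Archetype("early", ((0, 0.15), (2, 0.40), (4, 0.50), (7, 0.52))),
)


def archetype_class(label: str) -> str:
    """Collapse archetype labels onto the delayed/intermediate/early classes."""
    return "intermediate" if label.startswith("intermediate") else label


@dataclass(frozen=True)
class CohortSimSpec:
    """Design of a synthetic assessment cohort.

    Defaults mirror the real screening design: 4 archetypes x 7 cultivars
    (28 cultivars), 4-9 roots per cultivar and timepoint, per-root score
    noise SD 0.05 (inside the reported 0.02-0.15 per-cell SD band), a
    cultivar-level random shift of SD 0.015, and a 10% per-root
    contamination probability.
    """

    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    cultivars_per_archetype: int = 7
    roots_per_timepoint: tuple[int, int] = (4, 9)
    score_noise_sd: float = 0.05
    cultivar_effect_sd: float = 0.015
    contamination_prob: float = 0.10
    timepoints: tuple[int, ...] = (0, 2, 4, 7)
    method: str = "longitudinal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise ValueError("archetype list must not be empty")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ValueError("contamination_prob must lie in [0, 1]")


def simulate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format root-assessment table plus per-cultivar truth.

    Returns
    -------
    assessments : DataFrame with columns cultivar, root_id, dph, method,
        root_score, contaminated — one row per root x timepoint.
    truth : DataFrame with one row per cultivar: the generating archetype
        label, its delayed/intermediate/early class, and the cultivar's
        true (noise-free) trajectory as true_<t>dph columns.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.roots_per_timepoint
    rows, truth_rows = [], []
    for archetype in spec.archetypes:
        for i in range(spec.cultivars_per_archetype):
            cultivar = f"sim-{archetype.label}-{i + 1:02d}"
            effect = rng.normal(0.0, spec.cultivar_effect_sd)
            true = {
                t: float(np.clip(archetype.true_score(t) + effect, 0.0, 1.0))
                for t in spec.timepoints
            }
            truth_rows.append(
                {
                    "cultivar": cultivar,
                    "archetype": archetype.label,
                    "class": archetype_class(archetype.label),
                    **{f"true_{t}dph": v for t, v in true.items()},
                }
            )
            for t in spec.timepoints:
                n_roots = int(rng.integers(lo, hi + 1))
                for r in range(n_roots):
                    score = float(
                        np.clip(
                            true[t] + rng.normal(0.0, spec.score_noise_sd), 0.0, 1.0
                        )
                    )
                    rows.append(
                        {
                            "cultivar": cultivar,
                            "root_id": f"{cultivar}-r{t}-{r + 1}",
                            "dph": t,
                            "method": spec.method,
                            "root_score": score,
                            "contaminated": bool(
                                rng.random() < spec.contamination_prob
                            ),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def simulate_traits(
    n: int = 28,
    target_r: float = 0.66,
    *,
    dmc_mean: float = 35.0,
    dmc_sd: float = 4.0,
    ppd_mean: float = 0.33,
    ppd_sd: float = 0.08,
    diameter_hcn_r: float = -0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cultivar trait table with a controlled DMC-PPD correlation.

    The 4 dph PPD score is built from the standardized DMC latent as
    ``ppd = mu + sd * (r * z_dmc + sqrt(1 - r^2) * eps)`` so its population
    correlation with DMC equals ``target_r`` exactly (before the [0, 1]
    clip, which is negligible at the default location/scale).  Root HCN is
    negatively correlated with diameter (smaller roots tend to carry more
    cyanogenic potential); length is drawn independently.
    """
    if n < 3:
        raise ValueError("need n >= 3 cultivars")
    if abs(target_r) >= 1.0:
        raise ValueError("|target_r| must be < 1")
    if abs(diameter_hcn_r) >= 1.0:
        raise ValueError("|diameter_hcn_r| must be < 1")
    rng = np.random.default_rng(seed)
    z_dmc = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    z_diam = rng.standard_normal(n)
    z_hcn_extra = rng.standard_normal(n)
    length = rng.normal(35.0, 6.0, n)

    dmc = np.clip(dmc_mean + dmc_sd * z_dmc, 1.0, 99.0)
    ppd4 = np.clip(
        ppd_mean + ppd_sd * (target_r * z_dmc + np.sqrt(1 - target_r**2) * eps),
        0.0,
        1.0,
    )
    diameter = np.clip(4.5 + 0.8 * z_diam, 0.5, None)
    hcn = np.clip(
        60.0
        + 25.0
        * (diameter_hcn_r * z_diam + np.sqrt(1 - diameter_hcn_r**2) * z_hcn_extra),
        1.0,
        None,
    )
    return pd.DataFrame(
        {
            "cultivar": [f"sim-cv-{i + 1:02d}" for i in range(n)],
            "dmc_pct": dmc,
            "ppd_4dph": ppd4,
            "length_cm": np.clip(length, 5.0, None),
            "diameter_cm": diameter,
            "hcn_ppm": hcn,
        }
    )
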