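"""Synthetic faces, cohorts and rating tables with known ground truth.

Real face databases are licensed, so every pipeline stage is exercised on
synthetic material instead:

* face-like images — an oval of power-law "skin" texture whose spectral
  slope follows a linear age link (older faces shallower), age-linked dark
  blemishes, and a few fixed dark features (eyes, brows, mouth) behind a
  black oval window;
* cohorts — balanced-gender samples whose measured image properties
  reproduce the directions of the age correlations seen in face databases
  (slope and complexity/self-similarity increase with age, anisotropy
  decreases);
* rating tables — linear rating models with an age effect, optional image
  property effects, per-participant random intercepts, condition-effect
  profiles across mask/background slopes, and Gaussian residual noise, for
  each of the four study designs (correlational, mask overlay, pairwise
  choice, background).

Everything is deterministic under a fixed seed; identical specs and seeds
give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging import GreyImage, apply_oval_window
from .synthesis import NOMINAL_SLOPES, random_phase_pattern

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "synth_texture",
    "synth_face_like",
    "synth_cohort",
    "synth_ratings",
]

_DESIGNS = ("study1", "study2A", "study2B", "study3A")

#: Condition labels of the overlay design (mid-grey control + five slopes)
#: and of the background design (five slopes), steepest first.
STUDY2A_CONDITIONS = ("grey",) + tuple(f"{s:g}" for s in NOMINAL_SLOPES)
STUDY3A_CONDITIONS = tuple(f"{s:g}" for s in NOMINAL_SLOPES)


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth generative links of a synthetic face cohort.

    The nominal spectral slope of a face is
    ``slope_intercept + slope_per_year * age + N(0, slope_jitter_sd)``;
    the default link makes older faces shallower, reproducing the positive
    age-slope correlation observed in face databases.  Blemish count grows
    linearly with age and drives complexity and self-similarity up and
    anisotropy down.  Genders are balanced (alternating F/M).
    """

    n_faces: int = 110
    age_range: tuple[float, float] = (19.0, 80.0)
    slope_intercept: float = -3.1
    slope_per_year: float = 0.006
    slope_jitter_sd: float = 0.05
    blemish_base: float = 4.0
    blemish_per_year: float = 0.9
    size: int = 512
    seed: int = 0

    def nominal_slope(self, age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return (
            self.slope_intercept
            + self.slope_per_year * np.asarray(age)
            + rng.normal(0.0, self.slope_jitter_sd, size=np.shape(age))
        )


# Observation-level models for table-only cohorts: measured property =
# linear age link + scatter.  Scatter magnitudes are set so that sample
# age correlations land near those reported for real face sets at n ~ 110
# (about .6 for slope, weaker for the PHOG measures).
_PROPERTY_MODELS = {
    "fourier_slope": (-3.1, 0.006, 0.12),
    "self_similarity": (0.40, 0.0012, 0.025),
    "complexity": (3.0, 0.012, 0.30),
    "anisotropy": (1.6e-3, -6.0e-6, 1.5e-4),
}


def synth_texture(
    slope: float,
    size: int = 512,
    seed: int | None = None,
    deterministic_phase: bool = False,
) -> GreyImage:
    """Power-law texture of known slope (re-export of the random-phase
    generator); ``deterministic_phase`` uses an all-zero phase grid for
    bit-reproducible oracle tests."""
    phases = np.zeros((size, size)) if deterministic_phase else None
    return random_phase_pattern(slope, size=size, seed=seed, phases=phases)


def _soft_ellipse(size: int, center: tuple[float, float],
                  semi: tuple[float, float], sharp: float = 4.0) -> np.ndarray:
    """Smooth-edged elliptical bump in [0, 1] (fractional coordinates)."""
    y = (np.arange(size) + 0.5) / size
    d = (((y[:, None] - center[0]) / semi[0]) ** 2
         + ((y[None, :] - center[1]) / semi[1]) ** 2)
    return np.exp(-(d**sharp))


def synth_face_like(
    age: float,
    gender: str = "F",
    seed: int | None = None,
    spec: CohortSpec | None = None,
) -> GreyImage:
    """A face-like stand-in photograph: power-law skin in a black oval.

    The skin texture carries the age-linked spectral slope; blemishes (small
    dark blobs, count growing with age) add balanced high-frequency
    gradients; dark ellipses sketch eyes, brows and a mouth.  Values are in
    [0, 255] and the surround is black.
    """
    if spec is None:
        spec = CohortSpec()
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside cohort range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    n = spec.size
    s = float(spec.nominal_slope(np.asarray(age, dtype=float), rng))
    tex = random_phase_pattern(s, size=n, seed=int(rng.integers(2**31)))
    skin = 135.0 + 0.55 * (tex - tex.mean())

    # blemishes: small dark gaussian spots, count linked to age
    n_blem = rng.poisson(spec.blemish_base + spec.blemish_per_year * age)
    yy, xx = np.mgrid[0:n, 0:n]
    for _ in range(n_blem):
        cy = rng.uniform(0.2, 0.8) * n
        cx = rng.uniform(0.25, 0.75) * n
        radius = rng.uniform(1.5, 4.0)
        depth = rng.uniform(20.0, 55.0)
        r0, r1 = int(max(cy - 5 * radius, 0)), int(min(cy + 5 * radius, n))
        c0, c1 = int(max(cx - 5 * radius, 0)), int(min(cx + 5 * radius, n))
        dy = (yy[r0:r1, c0:c1] - cy) / radius
        dx = (xx[r0:r1, c0:c1] - cx) / radius
        skin[r0:r1, c0:c1] -= depth * np.exp(-(dy**2 + dx**2))

    # fixed facial features (positions jittered slightly per face)
    jit = rng.uniform(-0.01, 0.01, size=4)
    brow_h = 0.015 if gender == "M" else 0.010
    features = (
        55.0 * _soft_ellipse(n, (0.42 + jit[0], 0.36 + jit[1]), (0.030, 0.055))
        + 55.0 * _soft_ellipse(n, (0.42 + jit[0], 0.64 + jit[2]), (0.030, 0.055))
        + 45.0 * _soft_ellipse(n, (0.34 + jit[0], 0.36 + jit[1]), (brow_h, 0.070))
        + 45.0 * _soft_ellipse(n, (0.34 + jit[0], 0.64 + jit[2]), (brow_h, 0.070))
        + 50.0 * _soft_ellipse(n, (0.72 + jit[3], 0.50), (0.022, 0.085))
    )
    face = np.clip(skin - features, 0.0, 255.0)
    return apply_oval_window(face)


def synth_cohort(
    spec: CohortSpec | None = None, render: bool = True
) -> tuple[pd.DataFrame, list[GreyImage] | None]:
    """A cohort of synthetic faces with ground-truth metadata.

    Returns (metadata, images).  Metadata columns: stimulus_id, age (uniform
    over the age range), face_gender (balanced), nominal_slope, and
    model-based values of the four image properties (fourier_slope,
    self_similarity, complexity, anisotropy) drawn from the observation
    models above — convenient for fast rating simulations.  With ``render``
    the face images are generated too (measure them with
    ``phog.compute_sips`` to obtain measured, rather than model-based,
    properties); ``render=False`` skips image synthesis for table-only work.
    """
    if spec is None:
        spec = CohortSpec()
    if spec.n_faces < 10:
        raise ValueError("cohort needs at least 10 faces")
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_faces).round(0)
    genders = np.where(np.arange(spec.n_faces) % 2 == 0, "F", "M")
    meta = pd.DataFrame(
        {
            "stimulus_id": [f"face{i:03d}" for i in range(spec.n_faces)],
            "age": ages,
            "face_gender": genders,
            "nominal_slope": spec.nominal_slope(ages, rng),
        }
    )
    for name, (b0, b1, sd) in _PROPERTY_MODELS.items():
        meta[name] = b0 + b1 * ages + rng.normal(0.0, sd, size=spec.n_faces)
    meta["anisotropy"] = meta["anisotropy"].clip(lower=1e-5)

    images = None
    if render:
        face_seeds = rng.integers(2**31, size=spec.n_faces)
        images = [
            synth_face_like(a, g, seed=int(fs), spec=spec)
            for a, g, fs in zip(ages, genders, face_seeds)
        ]
    return meta, images


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth rating model.

    ``rating = intercept + age_coef * (age - mean age)
             + sum prop_coefs[p] * (p - mean p)
             + condition_profile[condition] + participant intercept + noise``

    clamped to ``scale`` and (optionally) rounded to the integer grid.  The
    default negative age coefficient emulates the strong negative
    age-attractiveness correlation of face-rating data; property and
    condition effects default to zero (a null model).  The participant
    intercept sd (0.3 rating units) is a calibration choice.
    """

    intercept: float = 2.5
    age_coef: float = -0.015
    prop_coefs: Mapping[str, float] = field(default_factory=dict)
    condition_profile: Mapping[str, float] = field(default_factory=dict)
    participant_sd: float = 0.3
    residual_sd: float = 0.3
    scale: tuple[float, float] = (1.0, 4.0)
    discretize: bool = True
    seed: int = 0


def _latent(meta: pd.DataFrame, effects: EffectSpec) -> np.ndarray:
    """Per-face latent rating component (age + property effects, centered)."""
    lat = np.full(len(meta), effects.intercept, dtype=np.float64)
    ages = meta["age"].to_numpy(dtype=np.float64)
    lat += effects.age_coef * (ages - ages.mean())
    for prop, coef in effects.prop_coefs.items():
        v = meta[prop].to_numpy(dtype=np.float64)
        lat += coef * (v - v.mean())
    return lat


def _finalize(raw: np.ndarray, effects: EffectSpec) -> np.ndarray:
    lo, hi = effects.scale
    out = np.clip(raw, lo, hi)
    if effects.discretize:
        out = np.clip(np.rint(out), lo, hi)
    return out


def synth_ratings(
    cohort: pd.DataFrame,
    effects: EffectSpec | None = None,
    n_participants: int = 20,
    design: str = "study1",
) -> pd.DataFrame:
    """Simulate a long-format rating table for one study design.

    ``cohort`` is the metadata table from :func:`synth_cohort`.  Designs:

    * ``study1`` — every participant rates every face once (columns
      participant_id, stimulus_id, rating, face_age, face_gender, plus the
      property columns), discretized to the 1-4 grid by default;
    * ``study2A`` — every face under every overlay condition (mid-grey +
      five mask slopes), continuous ratings, with ``condition_profile``
      offsets keyed by condition label (e.g. ``{"-2": -0.3}`` for an
      attractiveness dip at the natural-scene slope);
    * ``study3A`` — like study2A with the five background conditions and
      discretized ratings;
    * ``study2B`` — pairwise forced-choice trials between slope categories
      (steep / original / shallow) of different faces; the latent
      attractiveness plus a category offset plus choice noise decides each
      trial (columns participant_id, category_left, category_right,
      chosen_side).
    """
    if effects is None:
        effects = EffectSpec()
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {_DESIGNS}")
    rng = np.random.default_rng(effects.seed)
    n_faces = len(cohort)
    lat = _latent(cohort, effects)
    part_ids = [f"p{i:02d}" for i in range(n_participants)]
    part_int = rng.normal(0.0, effects.participant_sd, size=n_participants)

    if design == "study1":
        raw = (
            lat[None, :]
            + part_int[:, None]
            + rng.normal(0.0, effects.residual_sd, size=(n_participants, n_faces))
        )
        ratings = _finalize(raw, effects)
        base = cohort.loc[cohort.index.repeat(n_participants)].reset_index(drop=True)
        table = pd.DataFrame(
            {
                "participant_id": np.tile(part_ids, n_faces),
                "stimulus_id": base["stimulus_id"],
                "condition": "none",
                "rating": ratings.T.ravel(),
            }
        )
        meta_cols = [c for c in cohort.columns if c != "stimulus_id"]
        table = table.join(base[meta_cols])
        return table.rename(columns={"age": "face_age"})

    if design in ("study2A", "study3A"):
        conditions = (
            list(STUDY2A_CONDITIONS) if design == "study2A"
            else list(STUDY3A_CONDITIONS)
        )
        unknown = set(effects.condition_profile) - set(conditions)
        if unknown:
            raise ValueError(f"condition_profile keys {sorted(unknown)} not in "
                             f"{conditions}")
        offsets = np.array([effects.condition_profile.get(c, 0.0)
                            for c in conditions])
        k = len(conditions)
        raw = (
            lat[None, :, None]
            + offsets[None, None, :]
            + part_int[:, None, None]
            + rng.normal(0.0, effects.residual_sd,
                         size=(n_participants, n_faces, k))
        )
        if design == "study2A":
            ratings = _finalize(raw, EffectSpec(
                scale=effects.scale, discretize=False))
        else:
            ratings = _finalize(raw, effects)
        idx_p, idx_f, idx_c = np.meshgrid(
            np.arange(n_participants), np.arange(n_faces), np.arange(k),
            indexing="ij",
        )
        table = pd.DataFrame(
            {
                "participant_id": np.asarray(part_ids)[idx_p.ravel()],
                "stimulus_id": cohort["stimulus_id"].to_numpy()[idx_f.ravel()],
                "condition": np.asarray(conditions)[idx_c.ravel()],
                "rating": ratings.ravel(),
                "face_age": cohort["age"].to_numpy()[idx_f.ravel()],
                "face_gender": cohort["face_gender"].to_numpy()[idx_f.ravel()],
            }
        )
        return table

    # study2B: pairwise choices between categories of different faces
    categories = ["steep", "original", "shallow"]
    cat_offsets = {c: effects.condition_profile.get(c, 0.0) for c in categories}
    pairs = [(a, b) for i, a in enumerate(categories)
             for b in categories[i + 1:]]
    trials_per_pair = max(n_faces // 2, 10)
    rows = []
    for p_idx, pid in enumerate(part_ids):
        for a, b in pairs:
            for _ in range(trials_per_pair):
                i, j = rng.choice(n_faces, size=2, replace=False)
                left, right = (a, b) if rng.random() < 0.5 else (b, a)
                v_left = lat[i] + cat_offsets[left] + rng.normal(
                    0.0, effects.residual_sd)
                v_right = lat[j] + cat_offsets[right] + rng.normal(
                    0.0, effects.residual_sd)
                rows.append(
                    {
                        "participant_id": pid,
                        "category_left": left,
                        "category_right": right,
                        "chosen_side": "left" if v_left > v_right else "right",
                    }
                )
    return pd.DataFrame(rows)
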