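"""Synthetic cohort generator mirroring the generative structure the analyses assume.

Every downstream stage (task scoring, logistic modelling, voxelwise
inference) can be exercised against data with known ground truth:

* heartbeat-tracking windows with imperfect beat detection (binomial
  thinning plus Poisson spurious counts) and confidence linearly coupled
  to per-window accuracy through an ``insight_gain`` parameter;
* heartbeat-discrimination trials with Bernoulli correctness and a
  two-component (correct/incorrect location-shift) confidence model;
* equal-variance SDT observers with additive metacognitive noise for the
  2AFC confidence-rating tasks;
* a participant cohort in which the log-odds of high cognitive fatigue
  follow a logistic model in a binary insight indicator and covariates;
* skeletonised parameter maps (FA-like volumes restricted to a shared
  mask) carrying planted fatigue, insight and fatigue-by-insight
  interaction effects under spatially smoothed Gaussian noise.

Random streams are split per subject from the master seed with
``numpy.random.SeedSequence.spawn``, so enlarging the cohort never
perturbs earlier subjects' data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import InvalidInputError, InvalidParameterError
from .intero import HDTTrial, HTTTrial
from .metacog import MetacogTrial

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteroObserverParams:
    """Generative observer for the heartbeat tasks.

    ``p_detect`` thins true beats; ``false_count_rate`` adds spurious counts
    per second; ``insight_gain`` couples confidence to per-trial accuracy
    (0 = confidence uninformative); ``hdt_p_correct`` is the trialwise
    probability of a correct synchrony judgement.
    """

    heart_rate_bpm: float = 70.0
    p_detect: float = 0.8
    false_count_rate: float = 0.0
    insight_gain: float = 0.8
    confidence_noise_sd: float = 1.0
    hdt_p_correct: float = 0.55

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be positive")
        for name in ("p_detect", "hdt_p_correct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("false_count_rate", "insight_gain", "confidence_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MetacogObserverParams:
    """Equal-variance SDT observer with additive metacognitive noise."""

    dprime: float = 1.5
    criterion: float = 0.0
    meta_noise_sd: float = 0.0
    n_ratings: int = 6
    n_trials: int = 200

    def __post_init__(self) -> None:
        if self.dprime < 0:
            raise InvalidParameterError("dprime must be >= 0")
        if self.meta_noise_sd < 0:
            raise InvalidParameterError("meta_noise_sd must be >= 0")
        if self.n_ratings < 2:
            raise InvalidParameterError("n_ratings must be >= 2")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generative model for the fatigue logistic link.

    ``beta_insight_high`` is the log-odds coefficient on the *high-insight*
    indicator (protective when negative); the default log(0.29) plants the
    tracking-insight effect size used throughout the analyses.
    ``beta_covariates`` maps covariate names to log-odds coefficients on
    their z-scored values.
    """

    n_subjects: int = 71
    beta_intercept: float = 0.8
    beta_insight_high: float = float(np.log(0.29))
    beta_covariates: dict = field(default_factory=dict)
    covariate_distributions: dict = field(default_factory=dict)
    seed: int = 0
    attach_trials: bool = True
    p_high_insight: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        if not 0.0 < self.p_high_insight < 1.0:
            raise InvalidParameterError("p_high_insight must lie in (0, 1)")


@dataclass(frozen=True)
class EffectFieldSpec:
    """Planted spatial effects for synthetic skeleton maps.

    Voxel values inside ``effect_region`` follow
    ``baseline + gamma_fatigue*z(MFIS-Cog) + gamma_insight*insight
    + gamma_interaction*(z(MFIS-Cog)*insight)``; smoothed Gaussian noise
    with marginal SD ``noise_sd`` is added everywhere on the skeleton.
    """

    grid_shape: tuple = (16, 16, 8)
    skeleton_fraction: float = 0.15
    effect_region: frozenset | None = None  # voxel index triples; None -> central block
    gamma_fatigue: float = 0.0
    gamma_insight: float = 0.0
    gamma_interaction: float = 0.0
    noise_sd: float = 0.02
    smoothing_fwhm_vox: float = 2.0
    baseline: float = 0.45
    modality: str = "FA"

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise InvalidParameterError("grid_shape must be a positive integer triple")
        if not 0.0 < self.skeleton_fraction <= 1.0:
            raise InvalidParameterError("skeleton_fraction must lie in (0, 1]")
        if self.noise_sd < 0 or self.smoothing_fwhm_vox < 0:
            raise InvalidParameterError("noise_sd and smoothing_fwhm_vox must be >= 0")


# ---------------------------------------------------------------------------
# Trial-level simulators
# ---------------------------------------------------------------------------


def simulate_htt_trials(
    obs: InteroObserverParams,
    window_lengths_s: Sequence[float] | None = None,
    seed: int = 0,
) -> list[HTTTrial]:
    """Simulate heartbeat-tracking windows.

    Default protocol: six windows with durations uniform on [25, 50] s.
    True count = round(bpm * duration / 60); reported count = binomial
    thinning with ``p_detect`` plus Poisson(``false_count_rate`` * duration)
    spurious counts.  Confidence = clip(insight_gain * accuracy * 10 +
    N(0, confidence_noise_sd), 0, 10).
    """
    rng = np.random.default_rng(seed)
    if window_lengths_s is None:
        window_lengths_s = rng.uniform(25.0, 50.0, size=6)
    if any(d <= 0 for d in window_lengths_s):
        raise InvalidParameterError("window lengths must be positive")
    trials = []
    for dur in window_lengths_s:
        real = int(round(obs.heart_rate_bpm * dur / 60.0))
        reported = int(rng.binomial(real, obs.p_detect))
        reported += int(rng.poisson(obs.false_count_rate * dur))
        if real + reported > 0:
            acc = 1.0 - abs(real - reported) / ((real + reported) / 2.0)
        else:
            acc = 0.0
        conf = obs.insight_gain * acc * 10.0 + rng.normal(0.0, obs.confidence_noise_sd)
        trials.append(
            HTTTrial(
                duration_s=float(dur),
                nbeats_real=real,
                nbeats_reported=reported,
                confidence=float(np.clip(conf, 0.0, 10.0)),
            )
        )
    return trials


def simulate_hdt_trials(
    obs: InteroObserverParams, n_trials: int = 26, seed: int = 0
) -> list[HDTTrial]:
    """Simulate heartbeat-discrimination trials (default 26).

    Tone types are balanced by randomised assignment; correctness is
    Bernoulli(``hdt_p_correct``); confidence is drawn from
    N(5 + insight_gain, sd) on correct trials and N(5 - insight_gain, sd)
    on incorrect ones, clipped to the 0-10 scale, so insight_gain sets the
    separation of the two confidence components.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    types = np.array(["synchronous"] * (n_trials // 2) + ["asynchronous"] * (n_trials - n_trials // 2))
    rng.shuffle(types)
    correct = rng.random(n_trials) < obs.hdt_p_correct
    sd = max(obs.confidence_noise_sd, 1e-9)
    conf = np.where(
        correct,
        rng.normal(5.0 + obs.insight_gain, sd, n_trials),
        rng.normal(5.0 - obs.insight_gain, sd, n_trials),
    )
    other = {"synchronous": "asynchronous", "asynchronous": "synchronous"}
    return [
        HDTTrial(
            tone_type=t,
            judgement=t if ok else other[t],
            confidence=float(np.clip(c, 0.0, 10.0)),
        )
        for t, ok, c in zip(types, correct, conf)
    ]


def simulate_metacog_trials(obs: MetacogObserverParams, seed: int = 0) -> list[MetacogTrial]:
    """Simulate 2AFC confidence-rating trials from the SDT observer.

    Evidence x ~ N(+/- d'/2, 1) with equiprobable stimuli; the response is
    the sign of x - criterion; metacognitive evidence adds
    N(0, meta_noise_sd); the rating bins |x_m - criterion| by
    equal-population edges (sample quantiles), which keeps every rating
    cell populated and so stabilises downstream meta-d' fitting.
    """
    rng = np.random.default_rng(seed)
    n = obs.n_trials
    stim = rng.integers(0, 2, size=n)  # 0 = A, 1 = B
    x = rng.normal(np.where(stim == 1, obs.dprime / 2.0, -obs.dprime / 2.0), 1.0)
    resp = (x > obs.criterion).astype(int)
    x_meta = x + rng.normal(0.0, obs.meta_noise_sd, size=n) if obs.meta_noise_sd > 0 else x
    strength = np.abs(x_meta - obs.criterion)
    edges = np.quantile(strength, np.linspace(0, 1, obs.n_ratings + 1)[1:-1])
    ratings = np.searchsorted(edges, strength, side="right") + 1
    names = np.array(["A", "B"])
    return [
        MetacogTrial(
            stimulus_class=str(names[s]),
            response_class=str(names[r]),
            confidence_rating=int(k),
        )
        for s, r, k in zip(stim, resp, ratings)
    ]


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

_DEFAULT_COVARIATES = {
    # name: (kind, params) - marginals loosely matching a relapsing-remitting
    # MS cohort in its forties with mild disability
    "age_years": ("normal", {"mean": 43.0, "sd": 9.0, "lo": 18.0, "hi": 75.0}),
    "sex": ("bernoulli", {"p_female": 0.62}),
    "education_years": ("normal", {"mean": 16.0, "sd": 3.0, "lo": 8.0, "hi": 24.0}),
    "edss": ("halfstep", {"mean": 2.0, "sd": 1.2, "lo": 0.0, "hi": 7.0}),
    "disease_duration_years": ("lognormal", {"mean_log": 1.8, "sd_log": 0.7, "hi": 35.0}),
    "hads_a": ("count", {"mean": 4.6, "sd": 2.9, "hi": 21}),
    "hads_d": ("count", {"mean": 2.2, "sd": 1.8, "hi": 21}),
    "ess": ("count", {"mean": 4.5, "sd": 2.8, "hi": 24}),
}


def _draw_covariate(kind: str, p: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "normal":
        return np.clip(rng.normal(p["mean"], p["sd"], n), p["lo"], p["hi"])
    if kind == "bernoulli":
        return (rng.random(n) < p["p_female"]).astype(float)  # 1 = female
    if kind == "halfstep":
        v = np.clip(rng.normal(p["mean"], p["sd"], n), p["lo"], p["hi"])
        return np.round(v * 2.0) / 2.0
    if kind == "lognormal":
        return np.clip(rng.lognormal(p["mean_log"], p["sd_log"], n), 0.0, p["hi"])
    if kind == "count":
        return np.clip(np.round(rng.normal(p["mean"], p["sd"], n)), 0, p["hi"])
    raise InvalidParameterError(f"unknown covariate kind {kind!r}")


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a participant table with a known logistic fatigue link.

    Each subject receives covariates from the configured marginals, a
    latent insight level (high/low), a high-fatigue indicator drawn from
    the logistic model, an MFIS-Cog score consistent with that indicator
    (median-split at 16 recovers it), and - unless ``attach_trials`` is
    False - simulated behavioural trials from subject-specific observers.

    Returns a tidy DataFrame, one row per subject; trial lists are held in
    object columns ``htt_trials``/``hdt_trials``/``metacog_trials_*``.
    """
    n = params.n_subjects
    master = np.random.SeedSequence(params.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = master.spawn(n)

    cov_spec = dict(_DEFAULT_COVARIATES)
    cov_spec.update(params.covariate_distributions)
    cov = {}
    for name, (kind, p) in cov_spec.items():
        vals = _draw_covariate(kind, p, n, cohort_rng)
        if np.ptp(vals) == 0 and kind != "bernoulli":
            warnings.warn(f"covariate {name!r} has zero variance", stacklevel=2)
        cov[name] = vals

    insight_high = (cohort_rng.random(n) < params.p_high_insight).astype(int)

    lp = np.full(n, params.beta_intercept, dtype=float)
    lp += params.beta_insight_high * insight_high
    for name, beta in params.beta_covariates.items():
        v = cov[name]
        sd = v.std()
        lp += beta * ((v - v.mean()) / sd if sd > 0 else 0.0)
    high_fatigue = (cohort_rng.random(n) < expit(lp)).astype(int)

    # MFIS-Cog consistent with the fatigue indicator around the cutoff of 16
    mfis_cog = np.where(
        high_fatigue == 1,
        np.clip(16 + np.round(np.abs(cohort_rng.normal(0, 6, n))), 16, 36),
        np.clip(np.round(np.abs(cohort_rng.normal(0, 6, n))), 0, 15),
    ).astype(int)
    mfis_phys = np.clip(np.round(mfis_cog * 0.9 + cohort_rng.normal(0, 4, n)), 0, 36).astype(int)
    mfis_soc = np.clip(np.round(mfis_cog * 0.3 + cohort_rng.normal(0, 2, n)), 0, 16).astype(int)

    dmt = cohort_rng.choice(["none", "moderate", "high"], size=n, p=[0.24, 0.35, 0.41])

    rows: dict = {
        "subject_id": [f"sub-{i+1:03d}" for i in range(n)],
        **cov,
        "insight_high": insight_high,
        "high_fatigue": high_fatigue,
        "mfis_cog": mfis_cog,
        "mfis_phys": mfis_phys,
        "mfis_soc": mfis_soc,
        "mfis_tot": mfis_cog + mfis_phys + mfis_soc,
        "dmt_class": dmt,
    }
    df = pd.DataFrame(rows)

    if params.attach_trials:
        htt_all, hdt_all, mc_vis, mc_mem = [], [], [], []
        for i in range(n):
            ss = subject_seeds[i].generate_state(4)
            gain = 1.2 if insight_high[i] else 0.15
            obs = InteroObserverParams(
                heart_rate_bpm=float(np.clip(cohort_rng.normal(70, 9), 45, 110)),
                p_detect=float(np.clip(cohort_rng.normal(0.75, 0.12), 0.2, 1.0)),
                insight_gain=gain,
                confidence_noise_sd=1.2,
                hdt_p_correct=float(np.clip(cohort_rng.normal(0.55, 0.21), 0.05, 0.95)),
            )
            htt_all.append(simulate_htt_trials(obs, seed=int(ss[0] % 2**31)))
            hdt_all.append(simulate_hdt_trials(obs, seed=int(ss[1] % 2**31)))
            mc = MetacogObserverParams(
                dprime=float(np.clip(cohort_rng.normal(1.5, 0.3), 0.3, 3.0)),
                meta_noise_sd=float(np.abs(cohort_rng.normal(0.3, 0.3))),
            )
            mc_vis.append(simulate_metacog_trials(mc, seed=int(ss[2] % 2**31)))
            mc_mem.append(simulate_metacog_trials(mc, seed=int(ss[3] % 2**31)))
        df["htt_trials"] = htt_all
        df["hdt_trials"] = hdt_all
        df["metacog_trials_visual"] = mc_vis
        df["metacog_trials_memory"] = mc_mem

    return df


# ---------------------------------------------------------------------------
# Skeleton maps
# ---------------------------------------------------------------------------


def make_skeleton_mask(
    grid_shape: tuple, skeleton_fraction: float, seed: int
) -> np.ndarray:
    """Spatially structured binary mask covering ~``skeleton_fraction`` of the grid.

    Thresholds a smoothed Gaussian random field at the matching quantile,
    which yields a connected, sheet-like voxel set reminiscent of a
    white-matter skeleton (it is not an anatomical atlas).
    """
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(size=grid_shape), sigma=1.5)
    thr = np.quantile(f, 1.0 - skeleton_fraction)
    mask = f >= thr
    if not mask.any():
        mask.flat[int(np.argmax(f))] = True
    return mask


def default_effect_region(mask: np.ndarray, fraction: float = 0.25, seed: int = 0) -> np.ndarray:
    """Boolean sub-region of the mask: the ~``fraction`` of skeleton voxels
    nearest the grid centre (a single compact blob)."""
    idx = np.argwhere(mask)
    centre = (np.array(mask.shape) - 1) / 2.0
    d = np.linalg.norm(idx - centre, axis=1)
    k = max(1, int(round(fraction * len(idx))))
    keep = idx[np.argsort(d)[:k]]
    region = np.zeros_like(mask)
    region[tuple(keep.T)] = True
    return region


def _smoothed_noise(shape: tuple, sd: float, fwhm_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise smoothed to the requested FWHM, rescaled so the
    marginal voxelwise SD equals ``sd``."""
    noise = rng.normal(size=shape)
    if fwhm_vox > 0:
        noise = gaussian_filter(noise, sigma=fwhm_vox * _FWHM_TO_SIGMA)
        s = noise.std()
        if s > 0:
            noise = noise / s
    return noise * sd


def simulate_skeleton_maps(
    cohort: pd.DataFrame,
    spec: EffectFieldSpec,
    seed: int = 0,
) -> tuple[list, np.ndarray, np.ndarray]:
    """Generate one skeletonised map per subject with planted effects.

    Returns ``(maps, mask, effect_region)`` where ``maps`` is a list of
    :class:`~interofat.voxelwise.SkeletonMap` aligned with the cohort rows
    and ``effect_region`` is the boolean ground-truth mask of planted
    voxels.  The design variables are z-scored MFIS-Cog and the binary
    high-insight indicator from the cohort table.
    """
    from .voxelwise import SkeletonMap  # local import to avoid a cycle

    master = np.random.SeedSequence(seed)
    mask_seed, region_seed = (int(s.generate_state(1)[0] % 2**31) for s in master.spawn(2))
    mask = make_skeleton_mask(spec.grid_shape, spec.skeleton_fraction, mask_seed)
    if spec.effect_region is not None:
        region = np.zeros(spec.grid_shape, dtype=bool)
        for v in spec.effect_region:
            region[tuple(v)] = True
        if not (region <= mask).all():
            raise InvalidInputError("effect_region must be a subset of the skeleton mask")
    else:
        region = default_effect_region(mask, seed=region_seed)

    mfis = cohort["mfis_cog"].to_numpy(dtype=float)
    mfis_z = (mfis - mfis.mean()) / (mfis.std() if mfis.std() > 0 else 1.0)
    insight = cohort["insight_high"].to_numpy(dtype=float)

    subject_seeds = master.spawn(len(cohort))
    maps = []
    for i, (sid, z, ins) in enumerate(zip(cohort["subject_id"], mfis_z, insight)):
        rng = np.random.default_rng(subject_seeds[i])
        vol = np.full(spec.grid_shape, spec.baseline, dtype=float)
        effect = (
            spec.gamma_fatigue * z
            + spec.gamma_insight * ins
            + spec.gamma_interaction * z * ins
        )
        vol[region] += effect
        vol += _smoothed_noise(spec.grid_shape, spec.noise_sd, spec.smoothing_fwhm_vox, rng)
        vol[~mask] = 0.0
        maps.append(
            SkeletonMap(
                values=vol,
                mask=mask,
                voxel_size_mm=(1.0, 1.0, 1.0),
                modality=spec.modality,
                subject_id=str(sid),
            )
        )
    return maps, mask, region


# ---------------------------------------------------------------------------
# On-disk outputs (tidy CSV + JSON ground truth); NIfTI writing lives in
# interofat.voxelwise next to the reader.
# ---------------------------------------------------------------------------


def write_trial_tables(cohort: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write tidy one-row-per-trial CSVs for each task; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    htt_rows, hdt_rows, mc_rows = [], [], []
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        for t in row.get("htt_trials", []) or []:
            htt_rows.append(
                dict(subject_id=sid, duration_s=t.duration_s, nbeats_real=t.nbeats_real,
                     nbeats_reported=t.nbeats_reported, confidence=t.confidence)
            )
        for t in row.get("hdt_trials", []) or []:
            hdt_rows.append(
                dict(subject_id=sid, tone_type=t.tone_type, judgement=t.judgement,
                     confidence=t.confidence)
            )
        for task in ("visual", "memory"):
            for t in row.get(f"metacog_trials_{task}", []) or []:
                mc_rows.append(
                    dict(subject_id=sid, task=task, stimulus_class=t.stimulus_class,
                         response_class=t.response_class, confidence_rating=t.confidence_rating)
                )
    for name, rows in (("htt_trials", htt_rows), ("hdt_trials", hdt_rows), ("metacog_trials", mc_rows)):
        p = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[name] = p

    subject_cols = [c for c in cohort.columns if not c.endswith("_trials")
                    and not c.startswith("metacog_trials")]
    p = out_dir / "cohort.csv"
    cohort[subject_cols].to_csv(p, index=False)
    paths["cohort"] = p
    return paths


def write_ground_truth(spec: EffectFieldSpec, region: np.ndarray, params: CohortParams, path) -> None:
    """JSON sidecar recording the planted generative parameters."""
    payload = {
        "gamma_fatigue": spec.gamma_fatigue,
        "gamma_insight": spec.gamma_insight,
        "gamma_interaction": spec.gamma_interaction,
        "noise_sd": spec.noise_sd,
        "n_effect_voxels": int(region.sum()),
        "effect_voxels": [list(map(int, v)) for v in np.argwhere(region)],
        "beta_intercept": params.beta_intercept,
        "beta_insight_high": params.beta_insight_high,
        "seed": params.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
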