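"""Density profiles, the uniform-reshuffle null, gamma intervals and calls.

The inference asks whether labelled cells of one phenotype sit closer to
labelled cells of another phenotype than expected if positions were random.
For every cell of the *center* phenotype, the edge-corrected density of
*target* cells is measured in circles of increasing radius; the observed
statistic per radius is the grand mean over all center cells pooled across a
group's frames.  The null keeps each frame's per-phenotype counts but
redraws every position uniformly; each of the (default 50) reshuffles of a
frame contributes one sample — that frame's mean density per radius — and
samples are pooled across frames before a gamma distribution is fitted per
radius.  An observed mean outside the equal-tailed gamma interval (default
level 0.90) is a non-chance event: ``above`` indicates clustering, ``below``
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from ._rng import as_seed_sequence
from .errors import DegenerateSampleError, GridMismatchError, NoCentersError
from .frames import ImageFrame
from .geometry import clipped_area

# Radius grid (μm): fine steps to 100, coarse to 500.
DEFAULT_RADII: tuple[float, ...] = (
    20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 200, 250, 300, 350, 400, 450, 500,
)

DEFAULT_RESHUFFLES = 50
DEFAULT_LEVEL = 0.90


def _validate_grid(radii) -> np.ndarray:
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size == 0:
        raise ValueError("radius grid must be a non-empty 1-D sequence")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radius grid must be strictly increasing and positive")
    return radii


@dataclass
class DensityProfile:
    """Observed mean edge-corrected density per radius for one phenotype pair."""

    center_phenotype: str
    target_phenotype: str
    radii: np.ndarray
    density: np.ndarray  # cells/μm², mean over pooled center cells
    n_centers: int
    n_frames: int
    group: str = ""


@dataclass
class NullDistribution:
    """Pooled reshuffle samples and fitted gamma interval per radius."""

    center_phenotype: str
    target_phenotype: str
    radii: np.ndarray
    samples: np.ndarray      # (n_samples, n_radii)
    shape: np.ndarray        # gamma k per radius (NaN when degenerate)
    scale: np.ndarray        # gamma θ per radius (NaN when degenerate)
    lo: np.ndarray
    hi: np.ndarray
    level: float
    degenerate: np.ndarray   # bool per radius
    fit_method: np.ndarray   # {"mle", "mom", "degenerate"} per radius

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])


@dataclass(frozen=True)
class ClusterCall:
    """Decision at one radius: observed vs the null interval."""

    radius: float
    observed: float
    lo: float
    hi: float
    call: str                # {"above", "inside", "below"}
    degenerate: bool = False


def frame_center_densities(
    frame: ImageFrame,
    center_phenotype: str,
    target_phenotype: str,
    radii,
    exclude_self: bool = True,
    area_mode: str = "analytic",
    n_mc_points: int = 100_000,
    rng=None,
) -> np.ndarray:
    """Edge-corrected densities, shape (n_centers, n_radii), for one frame.

    In homotypic queries (center phenotype == target phenotype) the center
    cell itself is excluded when ``exclude_self`` is set, so it does not add
    a constant 1/area at every radius.
    """
    radii = _validate_grid(radii)
    ci = frame.indices_of(center_phenotype)
    if ci.size == 0:
        return np.empty((0, radii.size))
    ti = frame.indices_of(target_phenotype)

    centers = np.column_stack((frame.x[ci], frame.y[ci]))
    if ti.size:
        d = cdist(centers, np.column_stack((frame.x[ti], frame.y[ti])))
        if exclude_self:
            self_pairs = ci[:, None] == ti[None, :]
            d[self_pairs] = np.inf
        counts = (d[:, :, None] <= radii[None, None, :]).sum(axis=1)
    else:
        counts = np.zeros((ci.size, radii.size))

    if area_mode == "analytic":
        areas = clipped_area(centers[:, :1], centers[:, 1:2], radii[None, :], frame.rect)
    elif area_mode == "monte_carlo":
        from .geometry import Circle, clipped_area_mc

        rng = np.random.default_rng(rng)
        areas = np.empty((ci.size, radii.size))
        for i in range(ci.size):
            for j, r in enumerate(radii):
                areas[i, j] = clipped_area_mc(
                    Circle(centers[i, 0], centers[i, 1], r), frame.rect,
                    n_mc_points, rng,
                )
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    return counts / areas


def density_profile(
    frames: list[ImageFrame],
    center_phenotype: str,
    target_phenotype: str,
    radii=DEFAULT_RADII,
    exclude_self: bool = True,
    area_mode: str = "analytic",
    group: str = "",
) -> DensityProfile:
    """Grand-mean observed density per radius over all center cells in a group.

    Center cells, not frames, are the measured units: a frame with more
    center cells contributes proportionally more to the mean.
    """
    radii = _validate_grid(radii)
    per_center = [
        frame_center_densities(
            f, center_phenotype, target_phenotype, radii, exclude_self, area_mode
        )
        for f in frames
    ]
    pooled = np.vstack(per_center) if per_center else np.empty((0, radii.size))
    if pooled.shape[0] == 0:
        raise NoCentersError(
            f"no cells of center phenotype {center_phenotype!r} in any of "
            f"{len(frames)} frames"
        )
    return DensityProfile(
        center_phenotype, target_phenotype, radii,
        pooled.mean(axis=0), int(pooled.shape[0]), len(frames), group,
    )


def reshuffle_frame(frame: ImageFrame, seed=None) -> ImageFrame:
    """Uniformly redraw every cell position, keeping per-phenotype counts.

    All phenotypes move, including the center phenotype; ground-truth pair
    identifiers are dropped because reshuffling destroys pairing.
    """
    rng = np.random.default_rng(seed)
    new = ImageFrame(
        image_id=frame.image_id,
        rect=frame.rect,
        x=rng.uniform(0.0, frame.rect.width, frame.n_cells),
        y=rng.uniform(0.0, frame.rect.height, frame.n_cells),
        phenotype=frame.phenotype.copy(),
        fish_id=frame.fish_id,
        group=frame.group,
    )
    assert new.phenotype_counts() == frame.phenotype_counts()
    return new


def fit_gamma(samples, method: str = "auto") -> tuple[float, float]:
    """Fit a gamma(shape k, scale θ) to non-negative samples, location 0.

    ``method="auto"``: maximum likelihood when all samples are positive (the
    MLE constrains k·θ to the sample mean), method of moments when any
    sample equals zero — k = mean²/var, θ = var/mean with the unbiased
    variance — since the gamma log-likelihood is undefined at zero.
    ``"mle"`` and ``"mom"`` force a route.
    """
    if method not in ("auto", "mle", "mom"):
        raise ValueError(f"unknown method {method!r}")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to fit a gamma distribution")
    if np.any(samples < 0):
        raise ValueError("gamma samples must be non-negative")
    mean = samples.mean()
    var = samples.var(ddof=1)
    if mean == 0:
        raise DegenerateSampleError("all samples are zero; no gamma fit is possible")
    if var == 0:
        raise DegenerateSampleError("zero sample variance; no gamma fit is possible")
    if method == "auto":
        method = "mle" if np.all(samples > 0) else "mom"
    if method == "mle":
        if not np.all(samples > 0):
            raise ValueError("MLE requires strictly positive samples; use mom")
        k0 = mean * mean / var
        k, _, theta = stats.gamma.fit(samples, k0, floc=0, scale=var / mean)
        return float(k), float(theta)
    return float(mean * mean / var), float(var / mean)


def build_null(
    frames: list[ImageFrame],
    center_phenotype: str,
    target_phenotype: str,
    radii=DEFAULT_RADII,
    reshuffles_per_frame: int = DEFAULT_RESHUFFLES,
    level: float = DEFAULT_LEVEL,
    seed=None,
    exclude_self: bool = True,
    area_mode: str = "analytic",
) -> NullDistribution:
    """Monte Carlo uniform-reshuffle null with gamma-fitted intervals.

    Each frame is reshuffled ``reshuffles_per_frame`` times; each reshuffle
    contributes one sample per radius (the reshuffled frame's mean density
    over its center cells).  Samples pool across frames, so e.g. 41 frames
    at 50 reshuffles give 2050 samples per radius.  Frames with no
    center-phenotype cells contribute no samples.
    """
    radii = _validate_grid(radii)
    if not (0 < level < 1):
        raise ValueError(f"interval level must be in (0, 1), got {level}")
    if reshuffles_per_frame < 1:
        raise ValueError("reshuffles_per_frame must be >= 1")
    if not any(f.indices_of(center_phenotype).size for f in frames):
        raise NoCentersError(
            f"no cells of center phenotype {center_phenotype!r} in any frame"
        )

    frame_seeds = as_seed_sequence(seed).spawn(len(frames))
    samples = []
    for frame, fseed in zip(frames, frame_seeds):
        if frame.indices_of(center_phenotype).size == 0:
            continue
        for rseed in fseed.spawn(reshuffles_per_frame):
            shuffled = reshuffle_frame(frame, rseed)
            dens = frame_center_densities(
                shuffled, center_phenotype, target_phenotype, radii,
                exclude_self, area_mode,
            )
            samples.append(dens.mean(axis=0))
    samples = np.asarray(samples)

    alpha = 1.0 - level
    n_r = radii.size
    shape = np.full(n_r, np.nan)
    scale = np.full(n_r, np.nan)
    lo = np.zeros(n_r)
    hi = np.zeros(n_r)
    degenerate = np.zeros(n_r, dtype=bool)
    method = np.empty(n_r, dtype=object)
    for j in range(n_r):
        col = samples[:, j]
        try:
            k, theta = fit_gamma(col)
        except DegenerateSampleError:
            # All-zero, or constant: report the point mass, do not fit.
            degenerate[j] = True
            lo[j] = hi[j] = col.mean()
            method[j] = "degenerate"
            continue
        shape[j], scale[j] = k, theta
        lo[j] = stats.gamma.ppf(alpha / 2.0, k, scale=theta)
        hi[j] = stats.gamma.ppf(1.0 - alpha / 2.0, k, scale=theta)
        method[j] = "mle" if np.all(col > 0) else "mom"

    return NullDistribution(
        center_phenotype, target_phenotype, radii, samples,
        shape, scale, lo, hi, level, degenerate, method,
    )


def classify(observed: DensityProfile, null: NullDistribution) -> list[ClusterCall]:
    """Per radius: ``above`` if observed > hi, ``below`` if < lo, else ``inside``.

    The interval boundary counts as inside.  Degenerate radii (all-zero
    null) are called inside with the flag set, never as evidence.
    """
    if (
        observed.radii.shape != null.radii.shape
        or not np.allclose(observed.radii, null.radii)
        or observed.center_phenotype != null.center_phenotype
        or observed.target_phenotype != null.target_phenotype
    ):
        raise GridMismatchError(
            "observed profile and null distribution must share the same radius "
            "grid and phenotype pair"
        )
    calls = []
    for j, r in enumerate(observed.radii):
        obs = float(observed.density[j])
        if null.degenerate[j]:
            call = "inside"
        elif obs > null.hi[j]:
            call = "above"
        elif obs < null.lo[j]:
            call = "below"
        else:
            call = "inside"
        calls.append(
            ClusterCall(float(r), obs, float(null.lo[j]), float(null.hi[j]),
                        call, bool(null.degenerate[j]))
        )
    return calls


def analyze_pairs(
    frames: list[ImageFrame],
    pairs: list[tuple[str, str]],
    radii=DEFAULT_RADII,
    reshuffles_per_frame: int = DEFAULT_RESHUFFLES,
    level: float = DEFAULT_LEVEL,
    seed=None,
    exclude_self: bool = True,
    area_mode: str = "analytic",
    group: str = "",
) -> pd.DataFrame:
    """Run the full observed/null/classify pipeline for several phenotype pairs.

    Returns one tidy row per (center, target, radius).  Each pair consumes an
    independent child of ``seed`` so adding a pair never perturbs another.
    """
    pair_seeds = as_seed_sequence(seed).spawn(len(pairs))
    rows = []
    for (center, target), pseed in zip(pairs, pair_seeds):
        profile = density_profile(
            frames, center, target, radii, exclude_self, area_mode, group
        )
        null = build_null(
            frames, center, target, radii, reshuffles_per_frame, level,
            pseed, exclude_self, area_mode,
        )
        for j, call in enumerate(classify(profile, null)):
            rows.append({
                "group": group,
                "center_phenotype": center,
                "target_phenotype": target,
                "radius_um": call.radius,
                "observed_mean_density": call.observed,
                "n_centers": profile.n_centers,
                "n_frames": profile.n_frames,
                "n_null_samples": null.n_samples,
                "gamma_shape": null.shape[j],
                "gamma_scale": null.scale[j],
                "ci_lo": call.lo,
                "ci_hi": call.hi,
                "call": call.call,
                "degenerate": call.degenerate,
            })
    return pd.DataFrame(rows)
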