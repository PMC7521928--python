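"""Synthetic point patterns emulating the EdU pulse-chase experiment.

Two regimes:

* uniform frames — every cell placed independently and uniformly; the
  spatial null the reshuffle test assumes;
* doublet frames — a configurable number of EdU⁺ division doublets (two
  daughter cells at short separation) superimposed on a uniform background;
  the clustering alternative.

Phenotype composition follows published adult ENS proportions (≈65%
neurons, ≈24% her4.3:EGFP⁺ glia, ≈13% double-negative) and the EdU-labelled
fractions at the three chase timepoints (t0/t4/t11).  Absolute cell density
per field is not a published quantity; the default of 400 ENS cells per
450 μm square is a model choice yielding realistic per-frame counts of
labelled glia (~8 at t0) and is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_seed_sequence
from .errors import ConfigurationError
from .frames import (
    GLIA,
    GLIA_EDU,
    NEURON,
    NEURON_EDU,
    OTHER,
    ImageFrame,
    Rect,
)

__all__ = [
    "PhenotypeMixture",
    "LabellingPreset",
    "PRESETS",
    "DoubletSpec",
    "SimConfig",
    "generate_uniform_frames",
    "generate_doublet_frames",
]


@dataclass(frozen=True)
class PhenotypeMixture:
    """Proportions of the three ENS compartments among all ENS cells.

    Defaults are the published adult means (which sum to ≈1.026 because they
    come from different transgenic quantifications); they are renormalised.
    """

    neuron: float = 0.6549
    glia: float = 0.2420
    other: float = 0.1293

    def __post_init__(self) -> None:
        if min(self.neuron, self.glia, self.other) < 0:
            raise ValueError("mixture proportions must be non-negative")
        if self.neuron + self.glia + self.other <= 0:
            raise ValueError("mixture proportions must not all be zero")

    def normalized(self) -> tuple[float, float, float]:
        total = self.neuron + self.glia + self.other
        return (self.neuron / total, self.glia / total, self.other / total)


@dataclass(frozen=True)
class LabellingPreset:
    """EdU⁺ fractions by compartment at one chase timepoint."""

    name: str
    glia_edu_fraction: float
    neuron_edu_fraction: float

    def __post_init__(self) -> None:
        for f in (self.glia_edu_fraction, self.neuron_edu_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"EdU fraction must be in [0, 1], got {f}")


#: Published mean EdU⁺ fractions: end of pulse (t0) and 4/11-day chases.
PRESETS: dict[str, LabellingPreset] = {
    "t0": LabellingPreset("t0", 0.080, 0.00068),
    "t4": LabellingPreset("t4", 0.036, 0.0071),
    "t11": LabellingPreset("t11", 0.039, 0.0070),
}


@dataclass(frozen=True)
class DoubletSpec:
    """Division-doublet injection: how many pairs and of what composition.

    Pair separation is uniform on (0, d_max] with uniform angle; d_max
    defaults to 20 μm, the scale below the 20–60 μm window where clustering
    is detectable.  Composition probabilities cover homotypic glia/glia,
    heterotypic glia/neuron and homotypic neuron/neuron EdU⁺ pairs.
    """

    n_doublets: int
    p_gg: float = 1.0
    p_gn: float = 0.0
    p_nn: float = 0.0
    d_max: float = 20.0

    def __post_init__(self) -> None:
        if self.n_doublets < 0:
            raise ValueError("n_doublets must be non-negative")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        p = (self.p_gg, self.p_gn, self.p_nn)
        if min(p) < 0 or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("composition probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """One simulated dataset: n_frames fields sharing a generation regime.

    ``fixed_counts`` bypasses the mixture/preset sampling with exact
    per-phenotype counts (any label vocabulary); otherwise compartment
    counts are multinomial in the mixture and EdU⁺ counts binomial in the
    preset fractions, emulating biological replicate variance.
    """

    rect: Rect = field(default_factory=Rect)
    n_cells: int = 400
    mixture: PhenotypeMixture = field(default_factory=PhenotypeMixture)
    preset: LabellingPreset = PRESETS["t0"]
    doublets: DoubletSpec | None = None
    n_frames: int = 1
    seed: int | None = None
    fixed_counts: dict[str, int] | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_frames < 0:
            raise ValueError("n_cells and n_frames must be non-negative")
        if self.fixed_counts is not None and any(
            v < 0 for v in self.fixed_counts.values()
        ):
            raise ValueError("fixed counts must be non-negative")

    @property
    def group_label(self) -> str:
        return self.group or self.preset.name


def _draw_counts(config: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    if config.fixed_counts is not None:
        return dict(config.fixed_counts)
    p_neuron, p_glia, p_other = config.mixture.normalized()
    n_neuron, n_glia, n_other = rng.multinomial(
        config.n_cells, (p_neuron, p_glia, p_other)
    )
    n_glia_edu = rng.binomial(n_glia, config.preset.glia_edu_fraction)
    n_neuron_edu = rng.binomial(n_neuron, config.preset.neuron_edu_fraction)
    return {
        GLIA_EDU: int(n_glia_edu),
        GLIA: int(n_glia - n_glia_edu),
        NEURON_EDU: int(n_neuron_edu),
        NEURON: int(n_neuron - n_neuron_edu),
        OTHER: int(n_other),
    }


def _uniform_frame(
    config: SimConfig, counts: dict[str, int], image_id: str,
    rng: np.random.Generator,
) -> ImageFrame:
    labels = [ph for ph, n in counts.items() for _ in range(n)]
    n = len(labels)
    return ImageFrame(
        image_id=image_id,
        rect=config.rect,
        x=rng.uniform(0.0, config.rect.width, n),
        y=rng.uniform(0.0, config.rect.height, n),
        phenotype=np.array(labels, dtype=object),
        fish_id=image_id,
        group=config.group_label,
        pair_id=np.full(n, -1, dtype=int),
    )


def generate_uniform_frames(config: SimConfig) -> list[ImageFrame]:
    """Frames with independently, uniformly placed cells (the spatial null)."""
    if config.doublets is not None:
        raise ConfigurationError(
            "config carries a doublet spec; use generate_doublet_frames"
        )
    rngs = [np.random.default_rng(s)
            for s in as_seed_sequence(config.seed).spawn(config.n_frames)]
    return [
        _uniform_frame(config, _draw_counts(config, rng), f"sim{i:03d}", rng)
        for i, rng in enumerate(rngs)
    ]


def _place_doublet(
    rect: Rect, d_max: float, rng: np.random.Generator
) -> tuple[tuple[float, float], tuple[float, float]]:
    px = rng.uniform(0.0, rect.width)
    py = rng.uniform(0.0, rect.height)
    while True:
        d = d_max - rng.uniform(0.0, d_max)  # uniform on (0, d_max]
        theta = rng.uniform(0.0, 2.0 * np.pi)
        qx, qy = px + d * np.cos(theta), py + d * np.sin(theta)
        if bool(rect.contains(qx, qy)):
            return (px, py), (qx, qy)


def generate_doublet_frames(config: SimConfig) -> list[ImageFrame]:
    """Uniform background plus EdU⁺ division doublets (the alternative).

    With sampled counts the doublet members are EdU⁺ cells *in addition to*
    the mixture/preset background draw — they model recent divisions the
    marginal labelling fractions do not resolve, and the unpaired background
    EdU⁺ cells keep the pattern uniform at large radii.  When the user pins
    exact counts via ``fixed_counts``, doublet members are drawn from those
    counts and a demand exceeding them is a configuration error.  Members
    carry a shared ``pair_id`` so recovery tests can find them.
    """
    if config.doublets is None:
        raise ConfigurationError("config has no doublet spec; use generate_uniform_frames")
    spec = config.doublets
    rngs = [np.random.default_rng(s)
            for s in as_seed_sequence(config.seed).spawn(config.n_frames)]
    frames = []
    for i, rng in enumerate(rngs):
        comps = rng.choice(
            ["gg", "gn", "nn"], size=spec.n_doublets,
            p=(spec.p_gg, spec.p_gn, spec.p_nn),
        )
        demand = {
            GLIA_EDU: int(2 * np.sum(comps == "gg") + np.sum(comps == "gn")),
            NEURON_EDU: int(2 * np.sum(comps == "nn") + np.sum(comps == "gn")),
        }
        counts = _draw_counts(config, rng)
        if config.fixed_counts is not None:
            for ph, need in demand.items():
                have = counts.get(ph, 0)
                if need > have:
                    raise ConfigurationError(
                        f"doublets require {need} {ph!r} cells but only {have} "
                        "were configured"
                    )
                counts[ph] = have - need

        background = _uniform_frame(config, counts, f"sim{i:03d}", rng)
        xs, ys, phs, pids = (
            [background.x], [background.y],
            [background.phenotype], [background.pair_id],
        )
        members = {"gg": (GLIA_EDU, GLIA_EDU),
                   "gn": (GLIA_EDU, NEURON_EDU),
                   "nn": (NEURON_EDU, NEURON_EDU)}
        for pid, comp in enumerate(comps):
            (px, py), (qx, qy) = _place_doublet(config.rect, spec.d_max, rng)
            xs.append(np.array([px, qx]))
            ys.append(np.array([py, qy]))
            phs.append(np.array(members[comp], dtype=object))
            pids.append(np.array([pid, pid]))
        frames.append(
            ImageFrame(
                image_id=background.image_id,
                rect=config.rect,
                x=np.concatenate(xs),
                y=np.concatenate(ys),
                phenotype=np.concatenate(phs),
                fish_id=background.fish_id,
                group=config.group_label,
                pair_id=np.concatenate(pids),
            )
        )
    return frames
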