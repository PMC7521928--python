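"""File formats, run configuration and provenance plumbing.

Cell tables are comma-separated UTF-8 text with a header row, one row per
annotated cell — the shape of a CellCounter-style export after conversion
to μm:

    image_id,fish_id,group,x_um,y_um,phenotype[,pair_id]

``pair_id`` is an optional extra column carrying synthetic ground truth.
Every results file embeds a hash of the run configuration so outputs from
different configurations cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CellTableError, ConfigurationError, SchemaError
from .frames import DEFAULT_VOCABULARY, GLIA_EDU, NEURON_EDU, ImageFrame, Rect
from .spatial import DEFAULT_LEVEL, DEFAULT_RADII, DEFAULT_RESHUFFLES

CELL_COLUMNS = ["image_id", "fish_id", "group", "x_um", "y_um", "phenotype"]


@dataclass
class RunConfig:
    """Everything the analysis needs, validated up front and serialised
    verbatim into every output for provenance."""

    frame_width: float = 450.0
    frame_height: float = 450.0
    radii: tuple[float, ...] = DEFAULT_RADII
    reshuffles_per_frame: int = DEFAULT_RESHUFFLES
    level: float = DEFAULT_LEVEL
    area_mode: str = "analytic"
    phenotypes: tuple[str, ...] = DEFAULT_VOCABULARY
    pairs: tuple[tuple[str, str], ...] = (
        (GLIA_EDU, GLIA_EDU),
        (GLIA_EDU, NEURON_EDU),
    )
    exclude_self: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        self.pairs = tuple((str(c), str(t)) for c, t in self.pairs)
        self.phenotypes = tuple(str(p) for p in self.phenotypes)
        if not (self.frame_width > 0 and self.frame_height > 0):
            raise ConfigurationError("frame dimensions must be positive")
        if any(r <= 0 for r in self.radii) or list(self.radii) != sorted(set(self.radii)):
            raise ConfigurationError("radii must be positive and strictly increasing")
        if self.reshuffles_per_frame < 1:
            raise ConfigurationError("reshuffles_per_frame must be >= 1")
        if not (0 < self.level < 1):
            raise ConfigurationError("level must be in (0, 1)")
        if self.area_mode not in ("analytic", "monte_carlo"):
            raise ConfigurationError(f"unknown area_mode {self.area_mode!r}")
        vocab = set(self.phenotypes)
        for center, target in self.pairs:
            if center not in vocab or target not in vocab:
                raise ConfigurationError(
                    f"pair ({center!r}, {target!r}) uses a phenotype outside the "
                    "configured vocabulary"
                )

    @property
    def rect(self) -> Rect:
        return Rect(self.frame_width, self.frame_height)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        if "phenotypes" in raw:
            raw["phenotypes"] = tuple(raw["phenotypes"])
        return cls(**raw)


def read_cell_table(
    path,
    rect: Rect | None = None,
    vocabulary: tuple[str, ...] | None = DEFAULT_VOCABULARY,
) -> list[ImageFrame]:
    """Read and validate a cell table, returning frames keyed by image_id.

    ``vocabulary=None`` accepts any phenotype string.  Row numbers in error
    messages count data rows from 1 (the header is row 0).
    """
    rect = rect or Rect()
    df = pd.read_csv(
        path,
        dtype={"image_id": str, "fish_id": str, "group": str},
        float_precision="round_trip",
    )
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} is missing columns: {', '.join(missing)}")
    for col in ("x_um", "y_um"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise CellTableError(f"row {bad[0] + 1}: non-numeric {col}")
    inside = rect.contains(df["x_um"].to_numpy(float), df["y_um"].to_numpy(float))
    if not np.all(inside):
        i = int(np.flatnonzero(~inside)[0])
        raise CellTableError(
            f"row {i + 1}: coordinate ({df['x_um'].iat[i]:g}, {df['y_um'].iat[i]:g}) "
            f"outside the {rect.width:g} x {rect.height:g} μm frame"
        )
    if vocabulary is not None:
        known = df["phenotype"].isin(vocabulary)
        if not known.all():
            i = int(np.flatnonzero(~known.to_numpy())[0])
            raise CellTableError(
                f"row {i + 1}: unknown phenotype {df['phenotype'].iat[i]!r} "
                f"(expected one of {', '.join(vocabulary)})"
            )

    frames = []
    for image_id, sub in df.groupby("image_id", sort=False):
        fish = sub["fish_id"].iloc[0]
        group = sub["group"].iloc[0]
        if sub["fish_id"].nunique() > 1 or sub["group"].nunique() > 1:
            raise CellTableError(
                f"image {image_id!r} maps to more than one fish_id or group"
            )
        frames.append(
            ImageFrame(
                image_id=str(image_id),
                rect=rect,
                x=sub["x_um"].to_numpy(float),
                y=sub["y_um"].to_numpy(float),
                phenotype=sub["phenotype"].to_numpy(object),
                fish_id=str(fish),
                group=str(group),
                pair_id=sub["pair_id"].to_numpy(int) if "pair_id" in sub else None,
            )
        )
    return frames


def write_cell_table(frames: list[ImageFrame], path) -> None:
    """Write frames to the delimited cell-table format (full precision)."""
    rows = []
    for f in frames:
        for i in range(f.n_cells):
            row = {
                "image_id": f.image_id,
                "fish_id": f.fish_id,
                "group": f.group,
                "x_um": repr(float(f.x[i])),
                "y_um": repr(float(f.y[i])),
                "phenotype": f.phenotype[i],
            }
            if f.pair_id is not None:
                row["pair_id"] = int(f.pair_id[i])
            rows.append(row)
    cols = CELL_COLUMNS + (["pair_id"] if rows and "pair_id" in rows[0] else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _package_versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for name in ("enspatial", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            out[name] = md.version(name)
        except md.PackageNotFoundError:
            out[name] = "unknown"
    return out


def write_results(
    outdir,
    results: pd.DataFrame,
    config: RunConfig,
    comparisons: pd.DataFrame | None = None,
    stage_counts: dict | None = None,
) -> dict[str, Path]:
    """Write results tables plus a structured run manifest.

    The config hash is embedded as a column in every table and echoed in
    ``manifest.json`` together with the full config, seed, package versions
    and per-stage counts.  No timestamps: identical inputs produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    results = results.copy()
    results["config_hash"] = config.config_hash
    results_path = outdir / "results.csv"
    results.to_csv(results_path, index=False, float_format="%.17g")
    written["results"] = results_path

    if comparisons is not None:
        comparisons = comparisons.copy()
        comparisons["config_hash"] = config.config_hash
        cmp_path = outdir / "comparisons.csv"
        comparisons.to_csv(cmp_path, index=False, float_format="%.17g")
        written["comparisons"] = cmp_path

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": _package_versions(),
        "stage_counts": stage_counts or {},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written["manifest"] = manifest_path
    return written


def read_results(path) -> pd.DataFrame:
    """Read a results table, refusing files that mix configurations."""
    df = pd.read_csv(path)
    if "config_hash" in df.columns and df["config_hash"].nunique() > 1:
        raise ConfigurationError(
            f"{path} mixes outputs from {df['config_hash'].nunique()} different "
            "configurations"
        )
    return df
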