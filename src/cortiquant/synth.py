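"""Synthetic data generators with ground truth.

Two generators are provided:

* :func:`generate_ihc_image` paints a brightfield-like RGB section — DAB
  brown cells as filled discs on hematoxylin-blue tissue over a white
  background, plus small dark specks mimicking staining artifacts — and
  returns per-pixel ground-truth masks together with the true cell-area
  density.
* :func:`generate_follicle_dataset` simulates a full cryopreservation
  study: 4 treatment arms x 4 conditions {F, F-T, D2, D6}, 6 punches per
  arm x condition (24 punches per arm), 12 density-scored and 3
  proliferation-scored sections per punch.  Section-level follicle counts
  follow a mixed model on the log10(X + 1) density scale,

      log10(count / mm^2 + 1) = baseline + effect[arm, condition]
                                + fragment_effect + residual,

  with a Gaussian random intercept per fragment and Gaussian section
  residuals; the linear predictor is truncated at 0 before back-transform
  and counts are rounded to the nearest nonnegative integer.
  Degeneration and Ki-67 positivity flags are Bernoulli draws with
  per-condition probabilities.

Both generators consume a single seeded NumPy random stream per call and
are bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .exceptions import ConfigError, OvercrowdedError
from .follicles import (
    CONDITIONS,
    FollicleAnnotation,
    FragmentRecord,
    SectionRecord,
)

DEFAULT_ARMS = ("S1P", "CT_NaOH", "ZVAD", "CT_DMSO")

# Default arm x condition cell means on the log10(follicles/mm^2 + 1)
# scale: fresh cortex around 1.4-1.7, declining with culture time, with a
# caspase-inhibitor arm retaining density at day 6. Magnitudes chosen to
# resemble sheep cortical primordial-follicle densities.
DEFAULT_EFFECTS = {
    ("S1P", "F"): 1.60, ("S1P", "F-T"): 1.62,
    ("S1P", "D2"): 0.91, ("S1P", "D6"): 0.48,
    ("CT_NaOH", "F"): 1.41, ("CT_NaOH", "F-T"): 1.78,
    ("CT_NaOH", "D2"): 0.65, ("CT_NaOH", "D6"): 0.16,
    ("ZVAD", "F"): 1.62, ("ZVAD", "F-T"): 1.23,
    ("ZVAD", "D2"): 1.11, ("ZVAD", "D6"): 0.96,
    ("CT_DMSO", "F"): 1.66, ("CT_DMSO", "F-T"): 1.35,
    ("CT_DMSO", "D2"): 1.04, ("CT_DMSO", "D6"): 0.41,
}

# Free parameters (not calibrated to any published proportions): follicle
# quality degrades and culture-induced proliferation peaks at day 2.
DEFAULT_P_DEGENERATED = {"F": 0.25, "F-T": 0.35, "D2": 0.50, "D6": 0.75}
DEFAULT_P_PROLIFERATIVE = {"F": 0.05, "F-T": 0.05, "D2": 0.40, "D6": 0.20}


def _color3(value, name: str) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,)).copy()
    if arr.min() < 0 or arr.max() > 255:
        raise ConfigError(f"{name} channels must lie in [0, 255]")
    return tuple(arr)


@dataclass
class ImageGenConfig:
    """Configuration of the synthetic IHC image generator."""

    width: int = 512
    height: int = 512
    n_cells: int = 150
    cell_radius_range: tuple[float, float] = (4.0, 6.0)
    dab_color_mean: tuple[float, float, float] = (130.0, 85.0, 60.0)
    dab_color_std: tuple[float, float, float] = (10.0, 10.0, 10.0)
    tissue_color_mean: tuple[float, float, float] = (70.0, 80.0, 150.0)
    tissue_color_std: tuple[float, float, float] = (10.0, 10.0, 10.0)
    background_color: tuple[float, float, float] = (245.0, 245.0, 245.0)
    n_artifacts: int = 30
    artifact_max_area: int = 9
    tissue_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        self.dab_color_mean = _color3(self.dab_color_mean, "dab_color_mean")
        self.dab_color_std = _color3(self.dab_color_std, "dab_color_std")
        self.tissue_color_mean = _color3(
            self.tissue_color_mean, "tissue_color_mean"
        )
        self.tissue_color_std = _color3(
            self.tissue_color_std, "tissue_color_std"
        )
        self.background_color = _color3(
            self.background_color, "background_color"
        )
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.n_cells < 0 or self.n_artifacts < 0:
            raise ConfigError("n_cells and n_artifacts must be >= 0")
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ConfigError("cell_radius_range must satisfy 0 < rmin <= rmax")
        if not self.dab_color_mean[0] > self.dab_color_mean[2]:
            raise ConfigError("dab_color_mean must have red > blue (DAB brown)")
        if not self.tissue_color_mean[2] > self.tissue_color_mean[0]:
            raise ConfigError(
                "tissue_color_mean must have blue > red (hematoxylin)"
            )
        if not (0 < self.tissue_fraction <= 1):
            raise ConfigError("tissue_fraction must lie in (0, 1]")
        if self.n_artifacts > 0 and self.artifact_max_area < 2:
            raise ConfigError("artifact_max_area must be >= 2 (specks need area >= 1)")


@dataclass(frozen=True)
class ImageTruth:
    """Per-pixel ground truth for one synthetic section image."""

    cell_mask: np.ndarray
    tissue_mask: np.ndarray
    cell_centers: list[tuple[int, int]]
    true_density: float


def _tissue_region(cfg: ImageGenConfig) -> np.ndarray:
    if cfg.tissue_fraction == 1.0:
        return np.ones((cfg.height, cfg.width), dtype=bool)
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    radius = np.sqrt(cfg.tissue_fraction * cfg.width * cfg.height / np.pi)
    rr, cc = draw_disk(
        (cfg.height / 2.0, cfg.width / 2.0),
        radius,
        shape=mask.shape,
    )
    mask[rr, cc] = True
    return mask


def generate_ihc_image(cfg: ImageGenConfig) -> tuple[np.ndarray, ImageTruth]:
    """Paint a synthetic DAB/hematoxylin section with ground truth.

    Cells are filled discs rejection-sampled entirely inside the tissue
    region (overlap between cells is allowed); artifacts are small
    connected specks of DAB-like color with area < ``artifact_max_area``
    that are *not* part of the cell ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    tissue = _tissue_region(cfg)
    tissue_area = int(tissue.sum())

    rmin, rmax = cfg.cell_radius_range
    mean_cell_area = np.pi * (rmax**3 - rmin**3) / (3.0 * max(rmax - rmin, 1e-9)) \
        if rmax > rmin else np.pi * rmin**2
    if cfg.n_cells * mean_cell_area > 0.6 * tissue_area:
        raise OvercrowdedError(
            "overcrowded configuration: requested cell area exceeds 60% "
            "of the tissue region"
        )

    # Distance to the nearest non-tissue pixel; a disc of radius r centred
    # at p fits inside the tissue iff dist[p] > r.
    dist = ndimage.distance_transform_edt(tissue)

    cell_mask = np.zeros_like(tissue)
    centers: list[tuple[int, int]] = []
    for _ in range(cfg.n_cells):
        radius = rng.uniform(rmin, rmax)
        placed = False
        for _attempt in range(1000):
            r = int(rng.integers(0, cfg.height))
            c = int(rng.integers(0, cfg.width))
            if dist[r, c] > radius + 1.0:
                rr, cc = draw_disk((r, c), radius, shape=cell_mask.shape)
                cell_mask[rr, cc] = True
                centers.append((r, c))
                placed = True
                break
        if not placed:
            raise OvercrowdedError(
                "overcrowded configuration: could not place a cell inside "
                "the tissue region after 1000 attempts"
            )

    artifact_mask = np.zeros_like(tissue)
    in_tissue = np.argwhere(tissue & ~cell_mask)
    for _ in range(cfg.n_artifacts):
        if len(in_tissue) == 0:
            break
        area = int(rng.integers(1, cfg.artifact_max_area))
        seed_pt = in_tissue[rng.integers(0, len(in_tissue))]
        r, c = int(seed_pt[0]), int(seed_pt[1])
        # Grow a small connected speck by a short random walk.
        for _ in range(area):
            if 0 <= r < cfg.height and 0 <= c < cfg.width:
                artifact_mask[r, c] = True
            step = rng.integers(0, 4)
            r += (1, -1, 0, 0)[step]
            c += (0, 0, 1, -1)[step]

    shape3 = (cfg.height, cfg.width, 3)
    img = np.empty(shape3, dtype=float)
    img[:] = np.asarray(cfg.background_color)
    img += rng.normal(0.0, 3.0, size=shape3)  # mild background grain
    tissue_px = tissue & ~cell_mask & ~artifact_mask
    img[tissue_px] = (
        np.asarray(cfg.tissue_color_mean)
        + rng.normal(0.0, 1.0, size=(int(tissue_px.sum()), 3))
        * np.asarray(cfg.tissue_color_std)
    )
    dab_px = cell_mask | (artifact_mask & tissue)
    img[dab_px] = (
        np.asarray(cfg.dab_color_mean)
        + rng.normal(0.0, 1.0, size=(int(dab_px.sum()), 3))
        * np.asarray(cfg.dab_color_std)
    )
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = ImageTruth(
        cell_mask=cell_mask,
        tissue_mask=tissue,
        cell_centers=centers,
        true_density=float(cell_mask.sum()) / tissue_area,
    )
    return img, truth


def _prob_map(value, conditions, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        probs = {c: float(value[c]) for c in conditions}
    else:
        probs = {c: float(value) for c in conditions}
    for c, p in probs.items():
        if not (0.0 <= p <= 1.0):
            raise ConfigError(f"{name}[{c!r}] = {p} outside [0, 1]")
    return probs


@dataclass
class StudyGenConfig:
    """Configuration of the simulated cryopreservation study."""

    arms: tuple[str, ...] = DEFAULT_ARMS
    conditions: tuple[str, ...] = CONDITIONS
    punches_per_condition: int = 6
    density_sections_per_punch: int = 12
    proliferation_sections_per_punch: int = 3
    section_area_mm2: float = 3.1
    baseline_log_density: float = 0.0
    arm_condition_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    fragment_sd: float = 0.2
    residual_sd: float = 0.1
    p_degenerated: dict = field(
        default_factory=lambda: dict(DEFAULT_P_DEGENERATED)
    )
    p_proliferative: dict = field(
        default_factory=lambda: dict(DEFAULT_P_PROLIFERATIVE)
    )
    p_transitional: float = 0.15
    seed: int = 0

    def __post_init__(self):
        self.arms = tuple(self.arms)
        self.conditions = tuple(self.conditions)
        if len(self.arms) < 1 or len(self.conditions) < 1:
            raise ConfigError("need at least one arm and one condition")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ConfigError(
                    f"unknown condition {c!r}; expected a subset of {CONDITIONS}"
                )
        if self.punches_per_condition < 1:
            raise ConfigError("punches_per_condition must be >= 1")
        if self.density_sections_per_punch < 0:
            raise ConfigError("density_sections_per_punch must be >= 0")
        if self.proliferation_sections_per_punch < 0:
            raise ConfigError("proliferation_sections_per_punch must be >= 0")
        if self.section_area_mm2 <= 0:
            raise ConfigError("section_area_mm2 must be > 0")
        if self.fragment_sd < 0 or self.residual_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if not (0.0 <= self.p_transitional <= 1.0):
            raise ConfigError("p_transitional must lie in [0, 1]")
        effects = {}
        for arm in self.arms:
            for cond in self.conditions:
                key = (arm, cond)
                if key not in self.arm_condition_effects:
                    raise ConfigError(
                        f"arm_condition_effects missing entry for {key}"
                    )
                effects[key] = float(self.arm_condition_effects[key])
        self.arm_condition_effects = effects
        self.p_degenerated = _prob_map(
            self.p_degenerated, self.conditions, "p_degenerated"
        )
        self.p_proliferative = _prob_map(
            self.p_proliferative, self.conditions, "p_proliferative"
        )


def _section_counts(cfg: StudyGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Section-level primordial counts from the log-scale mixed model.

    One row per section: the count of primordial(-for-analysis) follicles,
    obtained by truncating the linear predictor at 0 and rounding
    ``(10^y - 1) * area`` to the nearest nonnegative integer.
    """
    rows = []
    roles = (
        ("density", cfg.density_sections_per_punch),
        ("proliferation", cfg.proliferation_sections_per_punch),
    )
    for arm in cfg.arms:
        for cond in cfg.conditions:
            mu_cell = cfg.baseline_log_density + cfg.arm_condition_effects[
                (arm, cond)
            ]
            for punch in range(cfg.punches_per_condition):
                frag_id = f"{arm}_{cond}_p{punch:02d}"
                frag_eff = rng.normal(0.0, cfg.fragment_sd)
                for role, n_sections in roles:
                    for s in range(n_sections):
                        y = mu_cell + frag_eff + rng.normal(0.0, cfg.residual_sd)
                        y = max(y, 0.0)
                        count = int(round((10.0**y - 1.0) * cfg.section_area_mm2))
                        rows.append(
                            {
                                "fragment_id": frag_id,
                                "arm": arm,
                                "condition": cond,
                                "section_id": f"{role[0]}{s:02d}",
                                "analysis_role": role,
                                "section_area_mm2": cfg.section_area_mm2,
                                "count": max(count, 0),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_observations(cfg: StudyGenConfig) -> pd.DataFrame:
    """Fast path: section-level total-primordial observations only.

    Skips the per-follicle annotation expansion; the counts are identical
    to those a full :func:`generate_follicle_dataset` call with the same
    config would produce (the count model is drawn first from the same
    stream).  Intended for simulation studies that only need the
    ``total_primordial`` outcome.
    """
    rng = np.random.default_rng(cfg.seed)
    df = _section_counts(cfg, rng)
    df["outcome"] = "total_primordial"
    df["raw_per_mm2"] = df["count"] / df["section_area_mm2"]
    df["log_value"] = np.log10(df["raw_per_mm2"] + 1.0)
    return df.drop(columns=["count"])


def generate_follicle_dataset(cfg: StudyGenConfig) -> list[FragmentRecord]:
    """Simulate a full study as annotated fragment records."""
    rng = np.random.default_rng(cfg.seed)
    counts = _section_counts(cfg, rng)

    fragments: dict[str, FragmentRecord] = {}
    for row in counts.itertuples(index=False):
        frag = fragments.get(row.fragment_id)
        if frag is None:
            frag = FragmentRecord(
                fragment_id=row.fragment_id,
                arm=row.arm,
                condition=row.condition,
            )
            fragments[row.fragment_id] = frag
        n = int(row.count)
        cond = row.condition
        transitional = rng.random(n) < cfg.p_transitional
        degenerated = rng.random(n) < cfg.p_degenerated[cond]
        # For a degenerated follicle pick a random nonempty subset of the
        # three degeneration criteria (bits: disorganized/shrunken/pyknotic).
        combo = rng.integers(1, 8, size=n)
        if row.analysis_role == "proliferation":
            proliferative = rng.random(n) < cfg.p_proliferative[cond]
            ki67 = np.where(proliferative, 1 + rng.poisson(1.0, size=n), 0)
        else:
            ki67 = np.zeros(n, dtype=int)
        follicles = [
            FollicleAnnotation(
                follicle_id=f"{row.fragment_id}_{row.section_id}_f{i:03d}",
                stage="transitional" if transitional[i] else "primordial",
                granulosa_disorganized=bool(degenerated[i] and (combo[i] & 1)),
                ooplasm_shrunken=bool(degenerated[i] and (combo[i] & 2)),
                oocyte_pyknotic=bool(degenerated[i] and (combo[i] & 4)),
                ki67_pos_granulosa_count=int(ki67[i]),
            )
            for i in range(n)
        ]
        # Occasional primary/secondary follicles, excluded from analysis.
        for j in range(int(rng.poisson(0.1))):
            follicles.append(
                FollicleAnnotation(
                    follicle_id=f"{row.fragment_id}_{row.section_id}_x{j}",
                    stage="primary" if rng.random() < 0.8 else "secondary",
                )
            )
        frag.sections.append(
            SectionRecord(
                section_id=row.section_id,
                area_mm2=float(row.section_area_mm2),
                analysis_role=row.analysis_role,
                follicles=follicles,
            )
        )
    return list(fragments.values())
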