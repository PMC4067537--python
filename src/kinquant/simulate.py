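"""Synthetic two-channel acquisition fields with known DNA content.

The simulator renders diffraction-limited bacteriophage particles (DAPI
channel) and extended GFP-marked kinetochore blobs (both channels) into a
3-D stack, applies shot noise and read noise, and emits a ground-truth
manifest so every downstream measurement can be checked against the truth.

Expected integrated DAPI photons for an object are exactly
``brightness_per_kb * true_kb * at_bias_factor(class)`` before noise; the
rendering integrates an anisotropic Gaussian over each voxel (difference of
normal CDFs per axis), so the noiseless field conserves photons up to
window truncation, which is tracked per object and flagged when it exceeds
1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .config import PHAGE_CLASSES, PHAGE_GENOME_KB, SimConfig
from .errors import CrowdedFieldError, SaturationRiskError
from .image import ImageField

# Support window half-width, in sigmas, for rendering; truncation at 6 sigma
# per axis is ~2e-9 of the mass.
_RENDER_NSIGMA = 6.0

_MANIFEST_COLUMNS = [
    "id", "class", "marker", "z", "y", "x",
    "true_kb", "expected_dapi", "expected_gfp", "flags",
]


@dataclass
class GroundTruthManifest:
    """Every simulated object's true class, position and DNA content."""

    objects: pd.DataFrame  # columns per _MANIFEST_COLUMNS

    def __post_init__(self) -> None:
        missing = set(_MANIFEST_COLUMNS) - set(self.objects.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")

    def of_class(self, object_class: str) -> pd.DataFrame:
        return self.objects[self.objects["class"] == object_class]

    @property
    def phages(self) -> pd.DataFrame:
        return self.objects[self.objects["class"].isin(PHAGE_CLASSES)]

    @property
    def kinetochores(self) -> pd.DataFrame:
        return self.of_class("kinetochore")

    def write_csv(self, path: str | Path) -> None:
        self.objects.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GroundTruthManifest":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(objects=df[_MANIFEST_COLUMNS])


def _axis_masses(center: float, sigma: float, n: int) -> tuple[int, np.ndarray]:
    """Per-voxel Gaussian mass along one axis.

    Voxel ``i`` spans ``[i - 0.5, i + 0.5]``; the mass is the difference of
    normal CDFs at the voxel edges, so summing over an unbounded axis gives
    exactly 1. Returns (start index, masses) clipped to ``[0, n)``.
    """
    lo = max(0, int(np.floor(center - _RENDER_NSIGMA * sigma)))
    hi = min(n - 1, int(np.ceil(center + _RENDER_NSIGMA * sigma)))
    if hi < lo:
        return 0, np.zeros(0)
    edges = np.arange(lo, hi + 2, dtype=float) - 0.5
    cdf = ndtr((edges - center) / sigma)
    return lo, np.diff(cdf)


def render_point_source(
    position: tuple[float, float, float],
    integrated_intensity: float,
    sigma: tuple[float, float, float],
    field_shape: tuple[int, int, int],
) -> np.ndarray:
    """Render one Gaussian point source into a full-field array.

    ``sigma`` is the (z, y, x) Gaussian sigma in voxel units. The sum over
    an unbounded grid equals ``integrated_intensity``; over the actual grid
    it is that minus border/window truncation. Contribution is non-negative
    everywhere.
    """
    if integrated_intensity < 0:
        raise ValueError("integrated_intensity must be non-negative")
    if any(s <= 0 for s in sigma):
        raise ValueError("sigma must be positive")
    if not all(0 <= p < n for p, n in zip(position, field_shape)):
        raise ValueError("position outside field")
    out = np.zeros(field_shape, dtype=np.float64)
    _add_gaussian(out, position, integrated_intensity, sigma)
    return out


def render_blob(
    position: tuple[float, float, float],
    integrated_intensity: float,
    sigma_blob: tuple[float, float, float],
    field_shape: tuple[int, int, int],
) -> np.ndarray:
    """Render an extended Gaussian blob; same contract as a point source."""
    return render_point_source(position, integrated_intensity, sigma_blob, field_shape)


def _add_gaussian(
    out: np.ndarray,
    position: tuple[float, float, float],
    intensity: float,
    sigma: tuple[float, float, float],
) -> float:
    """Accumulate a separable Gaussian into ``out``; return captured fraction."""
    if intensity == 0:
        return 1.0
    starts, axes = [], []
    for c, s, n in zip(position, sigma, out.shape):
        lo, m = _axis_masses(c, s, n)
        if m.size == 0:
            return 0.0
        starts.append(lo)
        axes.append(m)
    mz, my, mx = axes
    block = intensity * (mz[:, None, None] * my[None, :, None] * mx[None, None, :])
    z0, y0, x0 = starts
    out[z0:z0 + mz.size, y0:y0 + my.size, x0:x0 + mx.size] += block
    return float(mz.sum() * my.sum() * mx.sum())


def _place_objects(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Choose object classes, positions and true kb by rejection sampling.

    Objects are kept >= 2*(3 sigma_xy) from the borders and pairwise
    separated by the sum of their 3 sigma_xy supports plus
    ``placement_margin_px`` (room for shifted background ROIs).
    """
    nz, ny, nx = cfg.field_shape
    psf = cfg.sigma_vox(cfg.psf_sigma_nm)
    kin = cfg.sigma_vox(cfg.kinetochore_sigma_nm)
    vz, vxy = cfg.voxel_size_nm

    specs: list[dict] = []  # class, sigma (z,y,x) vox, true_kb, marker, snap_z
    for cls in PHAGE_CLASSES:
        phage_sigma = (cfg.phage_axial_sigma_nm / vz, psf[1], psf[2])
        for _ in range(cfg.n_phage_per_class):
            specs.append(dict(cls=cls, sigma=phage_sigma, kb=PHAGE_GENOME_KB[cls],
                              marker="", snap_z=cfg.snap_phage_to_plane))
    if cfg.kinetochore_kb_values is not None:
        kb_draws = list(cfg.kinetochore_kb_values)
    else:
        lo, hi = cfg.kinetochore_kb_range
        kb_draws = list(rng.uniform(lo, hi, size=cfg.n_kinetochores))
    for i in range(cfg.n_kinetochores):
        specs.append(dict(cls="kinetochore", sigma=kin, kb=float(kb_draws[i]),
                          marker=cfg.marker_labels[i % len(cfg.marker_labels)],
                          snap_z=False))
    if cfg.chromatin_mass is not None:
        cm = cfg.chromatin_mass
        specs.append(dict(cls="chromatin", sigma=cfg.sigma_vox(cm.sigma_nm),
                          kb=cm.total_kb, marker="", snap_z=False,
                          fixed_pos=cm.position))

    placed: list[dict] = []
    # Chromatin must stay >= 1.5 um from every kinetochore.
    chromatin_kineto_gap = 1500.0 / vxy
    for spec in specs:
        sz, sy, sx = spec["sigma"]
        border = 2.0 * 3.0 * sy
        zmargin = min(3.0 * sz, (nz - 1) / 2.0)
        ok = False
        for _ in range(cfg.placement_retries):
            if spec.get("fixed_pos") is not None:
                z, y, x = spec["fixed_pos"]
            else:
                if ny - 1 - border <= border or nx - 1 - border <= border:
                    break
                y = rng.uniform(border, ny - 1 - border)
                x = rng.uniform(border, nx - 1 - border)
                z = rng.uniform(zmargin, nz - 1 - zmargin)
                if spec["snap_z"]:
                    z = float(np.round(z))
            good = True
            for other in placed:
                min_d = 3.0 * sy + 3.0 * other["sigma"][1] + cfg.placement_margin_px
                if spec["cls"] == "chromatin" and other["cls"] == "kinetochore":
                    min_d = max(min_d, chromatin_kineto_gap)
                d = np.hypot(y - other["position"][1], x - other["position"][2])
                if d < min_d:
                    good = False
                    break
            if good:
                spec = dict(spec, position=(float(z), float(y), float(x)))
                placed.append(spec)
                ok = True
                break
            if spec.get("fixed_pos") is not None:
                break
        if not ok:
            raise CrowdedFieldError("field too crowded")
    return placed


def simulate_field(config: SimConfig) -> tuple[ImageField, GroundTruthManifest]:
    """Simulate one acquisition field and its ground-truth manifest.

    The DAPI channel contains every object (phages, kinetochores, optional
    chromatin mass); the GFP channel contains only kinetochores. Noise model:
    Poisson on (signal + background), then additive Gaussian read noise,
    then clipping to [0, 2**bit_depth - 1]. With a fixed seed the output is
    bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    placed = _place_objects(config, rng)

    dapi = np.zeros(config.field_shape, dtype=np.float64)
    gfp = np.zeros(config.field_shape, dtype=np.float64)
    rows = []
    for i, obj in enumerate(placed):
        cls = obj["cls"]
        expected_dapi = config.brightness_per_kb * obj["kb"] * config.bias(cls)
        expected_gfp = config.gfp_brightness if cls == "kinetochore" else 0.0
        frac = _add_gaussian(dapi, obj["position"], expected_dapi, obj["sigma"])
        if cls == "kinetochore" and expected_gfp > 0:
            _add_gaussian(gfp, obj["position"], expected_gfp, obj["sigma"])
        flags = "truncated" if frac < 0.99 else ""
        z, y, x = obj["position"]
        rows.append(dict(id=f"obj{i:03d}", **{"class": cls}, marker=obj["marker"],
                         z=z, y=y, x=x, true_kb=obj["kb"],
                         expected_dapi=expected_dapi, expected_gfp=expected_gfp,
                         flags=flags))

    _check_saturation(config, dapi + config.background_dapi, placed)

    channels = {}
    for name, signal, bg in (("DAPI", dapi, config.background_dapi),
                             ("GFP", gfp, config.background_gfp)):
        img = signal + bg
        if config.poisson_noise:
            img = rng.poisson(img).astype(np.float64)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, config.max_grey)

    field = ImageField(
        channels=channels,
        voxel_size_nm=config.voxel_size_nm,
        metadata={"simulated": True, "seed": config.seed,
                  "sim_config": config.model_dump_json()},
    )
    manifest = GroundTruthManifest(objects=pd.DataFrame(rows, columns=_MANIFEST_COLUMNS))
    return field, manifest


def _check_saturation(cfg: SimConfig, expected: np.ndarray, placed: list[dict]) -> None:
    maxval = cfg.max_grey
    nz, ny, nx = expected.shape
    for obj in placed:
        z, y, x = obj["position"]
        sz, sy, sx = obj["sigma"]
        zsl = slice(max(0, int(z - 3 * sz)), min(nz, int(np.ceil(z + 3 * sz)) + 1))
        ysl = slice(max(0, int(y - 3 * sy)), min(ny, int(np.ceil(y + 3 * sy)) + 1))
        xsl = slice(max(0, int(x - 3 * sx)), min(nx, int(np.ceil(x + 3 * sx)) + 1))
        core = expected[zsl, ysl, xsl]
        if core.size and np.mean(core > maxval) > 0.01:
            raise SaturationRiskError(
                f"object {obj['cls']} at ({z:.0f},{y:.0f},{x:.0f}): saturation risk")


def write_simulation(
    field: ImageField,
    manifest: GroundTruthManifest,
    config: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write TIFF channels, manifest CSV and the echoed config to a directory."""
    from .image import write_field

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_field(field, out)
    manifest_path = out / "manifest.csv"
    manifest.write_csv(manifest_path)
    config_path = out / "sim_config.json"
    config.to_json(config_path)
    paths.update({"manifest": manifest_path, "config": config_path})
    return paths
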