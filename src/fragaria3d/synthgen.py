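"""Seeded synthetic fruit-on-holder scenes with exact ground truth.

Stands in for the camera + structure-from-motion front end: each scene is
a coloured point cloud of a dark-blue reference cuboid (38 x 19 x 19 mm),
a red fruit body built as a surface of revolution with elliptical
cross-section, yellow achene spots blue-noise-placed on the body, and a
green multi-lobed calyx at the fruit base. Coordinates are multiplied by
an arbitrary global scale to emulate the unit-free image space of
multi-view reconstruction; Gaussian point and hue noise and an optional
nose-cap occlusion emulate reconstruction defects.

The body profile is the two-parameter family

    r(t) = sin(pi * t**q) ** p,   t in [0, 1]  (base -> nose)

whose max is exactly 1 (pinning length/width), which closes at both ends,
and which spans conic to globose shapes via (p, q). The true volume is the
solid-of-revolution integral  V = pi * (L/2) * (W/2) * H * int r(t)^2 dt,
evaluated by adaptive quadrature -- never from a mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.integrate import quad
from skimage.color import hsv2rgb

from .cloud_io import ColouredCloud, write_cloud

HOLDER_DIMS_MM = (38.0, 19.0, 19.0)  # height x width x depth of the standard

PART_HOLDER = "holder"
PART_BODY = "body"
PART_CALYX = "calyx"
PART_ACHENE = "achene"

# per-part base hue (deg), saturation range, value range
_PART_COLOURS = {
    PART_HOLDER: (230.0, (0.80, 0.90), (0.30, 0.40)),
    PART_BODY: (None, (0.75, 0.95), (0.55, 0.85)),  # hue from spec.base_hue_deg
    PART_CALYX: (110.0, (0.60, 0.90), (0.35, 0.70)),
    PART_ACHENE: (50.0, (0.60, 0.90), (0.70, 0.95)),
}


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterisation of one synthetic scene (all sizes in mm)."""

    seed: int = 0
    fruit_height_mm: float = 30.0
    fruit_length_mm: float = 32.0
    fruit_width_mm: float = 29.0
    calyx_span_mm: float = 40.0
    n_achenes: int = 150
    base_hue_deg: float = 355.0
    global_scale: float = 0.78 / 38.0  # image-space units per mm
    profile_p: float = 1.0             # nose pointiness
    profile_q: float = 0.6             # bulge position (q<1 -> bulge near base)
    n_holder_points: int = 6000
    n_body_points: int = 20000
    n_calyx_points: int = 2500
    points_per_achene: int = 9
    achene_min_separation_mm: float = 2.4
    achene_patch_radius_mm: float = 0.35
    noise_sd_mm: float = 0.15
    colour_noise_sd: float = 3.0       # hue jitter, degrees
    occlude_nose: bool = False
    occlusion_cap_deg: float = 25.0

    def __post_init__(self) -> None:
        for name in ("fruit_height_mm", "fruit_length_mm", "fruit_width_mm",
                     "calyx_span_mm", "global_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_achenes < 0:
            raise ValueError("n_achenes must be >= 0")

    def profile(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=np.float64), 0.0, 1.0)
        return np.sin(np.pi * t**self.profile_q) ** self.profile_p

    @property
    def analytic_volume_ml(self) -> float:
        integral, _ = quad(lambda t: float(self.profile(t)) ** 2, 0.0, 1.0,
                           limit=200)
        v_mm3 = (
            np.pi
            * (self.fruit_length_mm / 2)
            * (self.fruit_width_mm / 2)
            * self.fruit_height_mm
            * integral
        )
        return float(v_mm3 / 1000.0)


@dataclass
class GroundTruth:
    """Exact trait values and per-point part labels for one scene."""

    sample_id: str
    height_mm: float
    length_mm: float
    width_mm: float
    volume_ml: float            # analytic solid-of-revolution volume
    calyx_size_mm: float
    achene_count: int
    mean_hue_deg: float         # circular mean of realised body hues
    scale_mm_per_unit: float
    labels: np.ndarray          # per-point part label, aligned with the cloud

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "height_mm": self.height_mm,
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "volume_ml": self.volume_ml,
            "calyx_size_mm": self.calyx_size_mm,
            "achene_count": self.achene_count,
            "mean_hue_deg": self.mean_hue_deg,
            "scale_mm_per_unit": self.scale_mm_per_unit,
        }


class AchenePlacementError(RuntimeError):
    """Requested achene count infeasible at the minimum separation."""


# ---------------------------------------------------------------------------
# geometry helpers (all in mm before global scaling)
# ---------------------------------------------------------------------------

def _sample_holder(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w, d = HOLDER_DIMS_MM
    hw, hd = w / 2, d / 2
    areas = np.array([w * d, w * d, h * w, h * w, h * d, h * d])
    n_face = rng.multinomial(max(spec.n_holder_points - 8, 0), areas / areas.sum())
    pts = []
    for face, n in enumerate(n_face):
        u, v = rng.uniform(size=n), rng.uniform(size=n)
        if face < 2:     # bottom, top
            pts.append(np.column_stack(
                [(u - 0.5) * w, (v - 0.5) * d, np.full(n, 0.0 if face == 0 else h)]
            ))
        elif face < 4:   # front/back (y = +-hd)
            pts.append(np.column_stack(
                [(u - 0.5) * w, np.full(n, -hd if face == 2 else hd), v * h]
            ))
        else:            # left/right (x = +-hw)
            pts.append(np.column_stack(
                [np.full(n, -hw if face == 4 else hw), (u - 0.5) * d, v * h]
            ))
    corners = np.array(
        [[sx * hw, sy * hd, z] for sx in (-1, 1) for sy in (-1, 1) for z in (0, h)]
    )
    return np.vstack(pts + [corners])


def _body_surface_point(spec: SceneSpec, t, theta) -> np.ndarray:
    g = spec.profile(t)
    a, b = spec.fruit_length_mm / 2, spec.fruit_width_mm / 2
    z0 = HOLDER_DIMS_MM[0]
    return np.column_stack([
        a * g * np.cos(theta),
        b * g * np.sin(theta),
        z0 + spec.fruit_height_mm * np.asarray(t),
    ])


def _profile_cdf(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(0.0, 1.0, 2048)
    wt = spec.profile(grid) + 0.05
    cdf = np.cumsum(wt)
    cdf /= cdf[-1]
    return grid, cdf


def _sample_profile_t(spec: SceneSpec, rng: np.random.Generator, n: int,
                      cdf: tuple[np.ndarray, np.ndarray] | None = None):
    """Inverse-CDF sampling of t with weight ~ circumference (plus a floor
    so the poles are not starved)."""
    grid, c = cdf if cdf is not None else _profile_cdf(spec)
    return np.interp(rng.uniform(size=n), c, grid)


def _sample_body(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = max(spec.n_body_points - 6, 0)
    t = _sample_profile_t(spec, rng, n)
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    pts = _body_surface_point(spec, t, theta)
    # anchors pinning the exact extents: nose, base, 4 equator extremes
    t_peak = 0.5 ** (1.0 / spec.profile_q)
    anchors = np.vstack([
        _body_surface_point(spec, np.array([0.0, 1.0]), np.array([0.0, 0.0])),
        _body_surface_point(
            spec, np.full(4, t_peak), np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        ),
    ])
    return np.vstack([pts, anchors])


def _lateral_area_mm2(spec: SceneSpec) -> float:
    a, b = spec.fruit_length_mm / 2, spec.fruit_width_mm / 2
    integral, _ = quad(lambda t: float(spec.profile(t)), 0.0, 1.0, limit=200)
    return float(np.pi * (a + b) * spec.fruit_height_mm * integral)


def _place_achene_centres(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart throwing with a 3-D minimum separation (blue noise)."""
    if spec.n_achenes == 0:
        return np.empty((0, 3))
    sep2 = spec.achene_min_separation_mm**2
    cdf = _profile_cdf(spec)
    centres: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * spec.n_achenes
    chunk = np.empty((0, 3))
    pos = 0
    while len(centres) < spec.n_achenes:
        if pos >= len(chunk):
            t = _sample_profile_t(spec, rng, 512, cdf=cdf)
            theta = rng.uniform(0.0, 2 * np.pi, size=512)
            keep = (t > 0.04) & (t < 0.96)   # avoid the degenerate poles
            chunk = _body_surface_point(spec, t[keep], theta[keep])
            pos = 0
            continue
        if attempts >= max_attempts:
            raise AchenePlacementError(
                f"could not place {spec.n_achenes} achenes at separation "
                f"{spec.achene_min_separation_mm} mm (placed {len(centres)}); "
                "reduce the count or the separation"
            )
        c = chunk[pos]
        pos += 1
        attempts += 1
        if centres:
            d2 = np.sum((np.asarray(centres) - c) ** 2, axis=1)
            if d2.min() < sep2:
                continue
        centres.append(c)
    return np.asarray(centres)


def _achene_patches(
    spec: SceneSpec, centres: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if len(centres) == 0:
        return np.empty((0, 3))
    z0 = HOLDER_DIMS_MM[0]
    pts = []
    for c in centres:
        radial = np.array([c[0], c[1], 0.0])
        nrm = np.linalg.norm(radial)
        out = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        up = np.array([0.0, 0.0, 1.0])
        side = np.cross(up, out)
        side /= np.linalg.norm(side)
        r = spec.achene_patch_radius_mm * np.sqrt(
            rng.uniform(size=spec.points_per_achene)
        )
        ang = rng.uniform(0.0, 2 * np.pi, size=spec.points_per_achene)
        offsets = (
            np.outer(r * np.cos(ang), side)
            + np.outer(r * np.sin(ang), up)
            + 0.25 * out  # sit slightly proud of the body surface
        )
        pts.append(c + offsets)
    return np.vstack(pts)


def _sample_calyx(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """5-8 elliptical lobes radiating from the fruit base; the whole calyx
    is uniformly rescaled about its centroid so its exact maximum pairwise
    distance equals calyx_span_mm."""
    if spec.n_calyx_points == 0:
        return np.empty((0, 3))
    n_lobes = int(rng.integers(5, 9))
    z0 = HOLDER_DIMS_MM[0]
    t_att = 0.06
    g_att = float(spec.profile(np.array([t_att]))[0])
    r_att = g_att * (spec.fruit_length_mm + spec.fruit_width_mm) / 4
    z_att = z0 + spec.fruit_height_mm * t_att
    lobe_len = max(spec.calyx_span_mm / 2 - r_att, spec.calyx_span_mm / 6)
    lobe_wid = lobe_len * 0.35
    per_lobe = max(spec.n_calyx_points // n_lobes, 8)
    pts = []
    for k in range(n_lobes):
        phi = 2 * np.pi * k / n_lobes + rng.normal(0.0, 0.08)
        out = np.array([np.cos(phi), np.sin(phi), 0.0])
        side = np.array([-np.sin(phi), np.cos(phi), 0.0])
        tilt = rng.uniform(-0.25, -0.05)   # droop slightly below horizontal
        axis = out + tilt * np.array([0.0, 0.0, 1.0])
        axis /= np.linalg.norm(axis)
        u = rng.uniform(size=per_lobe)     # along the lobe
        half = 0.5 * lobe_wid * np.sqrt(np.clip(u * (1 - u) * 4, 0.0, 1.0))
        v = rng.uniform(-1.0, 1.0, size=per_lobe) * half
        sag = -0.08 * lobe_len * u**2
        attach = np.array([r_att * np.cos(phi), r_att * np.sin(phi), z_att])
        pts.append(
            attach
            + np.outer(u * lobe_len, axis)
            + np.outer(v, side)
            + np.outer(sag, np.array([0.0, 0.0, 1.0]))
        )
    calyx = np.vstack(pts)
    # exact-span rescale (uniform 3-D scaling scales all pairwise distances)
    from .geometry import max_pairwise_distance

    span, _ = max_pairwise_distance(calyx)
    centroid = calyx.mean(axis=0)
    return centroid + (calyx - centroid) * (spec.calyx_span_mm / span)


def _colour_part(
    part: str, n: int, rng: np.random.Generator, spec: SceneSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Return (rgb in [0,1], realised hue degrees) for n points of a part."""
    base, sat_rng, val_rng = _PART_COLOURS[part]
    if base is None:
        base = spec.base_hue_deg
    hue = (base + rng.normal(0.0, spec.colour_noise_sd, size=n)) % 360.0
    sat = rng.uniform(*sat_rng, size=n)
    val = rng.uniform(*val_rng, size=n)
    rgb = hsv2rgb(np.column_stack([hue / 360.0, sat, val]))
    return rgb, hue


def generate_scene(spec: SceneSpec) -> tuple[ColouredCloud, GroundTruth]:
    """Build one scene; identical spec (same seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)

    holder = _sample_holder(spec, rng)
    body = _sample_body(spec, rng)
    centres = _place_achene_centres(spec, rng)
    achenes = _achene_patches(spec, centres, rng)
    calyx = _sample_calyx(spec, rng)

    parts = [
        (PART_HOLDER, holder),
        (PART_BODY, body),
        (PART_CALYX, calyx),
        (PART_ACHENE, achenes),
    ]
    coords = []
    labels = []
    rgbs = []
    body_hues = None
    for name, pts in parts:
        if len(pts) == 0:
            continue
        rgb, hue = _colour_part(name, len(pts), rng, spec)
        coords.append(pts)
        rgbs.append(rgb)
        labels.extend([name] * len(pts))
        if name == PART_BODY:
            body_hues = hue
    coords = np.vstack(coords)
    rgbs = np.vstack(rgbs)
    labels = np.asarray(labels)

    if spec.noise_sd_mm > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd_mm, size=coords.shape)

    if spec.occlude_nose:
        centre = np.array([0.0, 0.0, HOLDER_DIMS_MM[0] + spec.fruit_height_mm / 2])
        rel = coords - centre
        with np.errstate(invalid="ignore"):
            cosang = rel[:, 2] / np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
        in_cap = (cosang > np.cos(np.deg2rad(spec.occlusion_cap_deg))) & (
            (labels == PART_BODY) | (labels == PART_ACHENE)
        )
        body_hues = body_hues[~in_cap[labels == PART_BODY]]
        coords, rgbs, labels = coords[~in_cap], rgbs[~in_cap], labels[~in_cap]

    coords = coords * spec.global_scale

    hue_rad = np.deg2rad(body_hues)
    mean_hue = float(
        np.rad2deg(np.arctan2(np.sin(hue_rad).mean(), np.cos(hue_rad).mean()))
        % 360.0
    )
    truth = GroundTruth(
        sample_id=f"scene_{spec.seed}",
        height_mm=spec.fruit_height_mm,
        length_mm=max(spec.fruit_length_mm, spec.fruit_width_mm),
        width_mm=min(spec.fruit_length_mm, spec.fruit_width_mm),
        volume_ml=spec.analytic_volume_ml,
        calyx_size_mm=spec.calyx_span_mm if spec.n_calyx_points else float("nan"),
        achene_count=len(centres),
        mean_hue_deg=mean_hue,
        scale_mm_per_unit=1.0 / spec.global_scale,
        labels=labels,
    )
    return ColouredCloud(coords, np.clip(rgbs, 0.0, 1.0)), truth


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "height_mm": (20.0, 45.0),
    "volume_ml": (8.0, 35.0),
    "calyx_span_mm": (25.0, 50.0),
    "n_achenes": (100, 250),
    "base_hue_deg": (345.0, 359.0),
    "width_to_length": (0.80, 1.00),
    "holder_extent_units": (0.36, 1.73),  # image-space holder size range
    "profile_p": (0.8, 1.2),
    "profile_q": (0.5, 0.75),
}


def batch_specs(
    n: int,
    seed: int,
    ranges: dict | None = None,
    noise_sd_mm: float = 0.15,
    colour_noise_sd: float = 3.0,
    occlude_nose: bool = False,
) -> list[SceneSpec]:
    """Draw n scene specifications under a master seed.

    Height and volume are drawn from their ranges; length and width are
    solved from the analytic volume integral at a drawn width:length
    aspect, so the batch spans both requested ranges simultaneously.
    Achene counts are capped by a dart-throwing feasibility bound derived
    from the lateral surface area.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    master = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        scene_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(scene_seed)
        vol = rng.uniform(*r["volume_ml"])
        rho = rng.uniform(*r["width_to_length"])
        p = rng.uniform(*r["profile_p"])
        q = rng.uniform(*r["profile_q"])
        integral, _ = quad(
            lambda t: np.sin(np.pi * t**q) ** (2 * p), 0.0, 1.0, limit=200
        )
        # the measurement model assumes the fruit is longer and wider than
        # the holder and that the scene's vertical axis dominates; restrict
        # the height draw so the solved length/width respect both.
        w_min = 28.0                      # > holder cross-section diagonal
        k_of_h = lambda hh: 4000.0 * vol / (np.pi * hh * integral)  # L*W
        h_hi = 4000.0 * vol / (np.pi * integral * w_min**2 / rho)
        h_lo = r["height_mm"][0]
        while (
            np.sqrt(k_of_h(h_lo) / rho) > 0.85 * (HOLDER_DIMS_MM[0] + h_lo)
            and h_lo < h_hi
        ):
            h_lo += 0.5
        lo = float(np.clip(h_lo, r["height_mm"][0], r["height_mm"][1]))
        hi = float(np.clip(h_hi, lo, r["height_mm"][1]))
        h = rng.uniform(lo, hi)
        lw = k_of_h(h)
        length = float(np.sqrt(lw / rho))
        width = float(rho * length)
        scale = rng.uniform(*r["holder_extent_units"]) / HOLDER_DIMS_MM[0]
        spec = SceneSpec(
            seed=scene_seed,
            fruit_height_mm=h,
            fruit_length_mm=length,
            fruit_width_mm=width,
            calyx_span_mm=float(rng.uniform(*r["calyx_span_mm"])),
            n_achenes=int(rng.integers(int(r["n_achenes"][0]),
                                       int(r["n_achenes"][1]) + 1)),
            base_hue_deg=float(rng.uniform(*r["base_hue_deg"])) % 360.0,
            global_scale=float(scale),
            profile_p=float(p),
            profile_q=float(q),
            noise_sd_mm=noise_sd_mm,
            colour_noise_sd=colour_noise_sd,
            occlude_nose=occlude_nose,
        )
        # cap achenes at the random-sequential-adsorption feasibility bound
        area = _lateral_area_mm2(spec)
        cap = int(0.5 * area / (np.pi * spec.achene_min_separation_mm**2 / 4))
        if spec.n_achenes > cap:
            spec = replace(spec, n_achenes=cap)
        specs.append(spec)
    return specs


def generate_batch(
    n: int,
    seed: int,
    out_dir,
    ranges: dict | None = None,
    noise_sd_mm: float = 0.15,
    colour_noise_sd: float = 3.0,
    occlude_nose: bool = False,
) -> tuple[list[Path], pd.DataFrame]:
    """Write n synthetic scenes as PLY files plus a ground-truth CSV.

    Returns the scene file paths (lexicographic order) and the truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = batch_specs(
        n, seed, ranges,
        noise_sd_mm=noise_sd_mm,
        colour_noise_sd=colour_noise_sd,
        occlude_nose=occlude_nose,
    )
    paths, rows = [], []
    for i, spec in enumerate(specs):
        cloud, truth = generate_scene(spec)
        truth.sample_id = f"scene_{i:04d}"
        path = out_dir / f"scene_{i:04d}.ply"
        write_cloud(cloud, path)
        paths.append(path)
        rows.append(truth.as_row())
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    return paths, truth_df
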