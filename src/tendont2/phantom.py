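"""Digital tendon phantoms with known ground-truth T2 fields.

A phantom is a 2-D coronal-slice image stack (one array per echo time) of a
curved tendon-like band flanked by a long-T2 fluid compartment (mimicking
bursal fluid) on one side and a short-T2, low-signal bone compartment on the
other.  Tendon voxels carry a T2 that varies along the band according to a
piecewise-linear profile T2(x) over normalized length x in [0, 100] percent,
with x = 0 at the lateral (footprint) end.  Signals follow mono-exponential
decay S0 * exp(-TE / T2) and are optionally corrupted by Rician noise.

Because the phantom records the exact per-voxel T2 and along-band position,
every downstream stage (decay fitting, partial-volume filtering, length
parameterization, profile binning, segment statistics) can be validated
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DEFAULT_ECHO_TRAIN",
    "PROFILE_PRESETS",
    "PhantomConfig",
    "PhantomTruth",
    "MultiEchoImage",
    "make_profile_function",
    "generate_phantom",
    "add_rician_noise",
]

#: Echo train of the multi-echo spin-echo T2-mapping sequence (ms).
DEFAULT_ECHO_TRAIN: tuple[float, ...] = (
    11.4, 22.8, 34.2, 45.6, 57.0, 68.4, 79.8, 91.2,
)

#: Per-segment (slope [ms per % length], intercept [ms]) of the piecewise
#: linear T2 profile, in global-x convention (intercept extrapolated to
#: x = 0 for every segment).  Segments are the lateral, middle and medial
#: thirds of the normalized tendon length.  Presets characterize tendinotic,
#: partially torn and asymptomatic supraspinatus tendons before/after
#: PRP treatment.
PROFILE_PRESETS: dict[str, tuple[tuple[float, float], ...]] = {
    "tendinosis_before": ((-0.268, 39.5), (0.151, 28.4), (-0.347, 70.1)),
    "tendinosis_after": ((-0.195, 34.6), (0.572, 6.15), (-0.359, 72.4)),
    "partial_tear_before": ((-0.458, 43.8), (0.264, 20.9), (-0.135, 52.0)),
    "partial_tear_after": ((-0.187, 40.6), (0.402, 16.0), (-0.284, 64.2)),
    "asymptomatic": ((0.217, 24.5), (0.430, 12.4), (-0.174, 51.4)),
}

_SEG_EDGES = (0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0)


class InvalidProfileSpecError(ValueError):
    """A piecewise-linear profile spec yields non-positive T2 somewhere."""


class GeometryError(ValueError):
    """The tendon band does not fit inside the phantom grid."""


def make_profile_function(
    profile_spec: Sequence[tuple[float, float]],
) -> Callable[[np.ndarray], np.ndarray]:
    """Build the piecewise-linear T2(x) function on x in [0, 100] percent.

    Parameters
    ----------
    profile_spec
        Three ``(slope, intercept)`` pairs, one per equal third of the
        normalized length (lateral, middle, medial).  Slopes are in
        ms per percent length, intercepts in ms at the global x = 0, so
        segment ``i`` evaluates to ``intercept_i + slope_i * x``.
        Discontinuities at the third boundaries are permitted; fitted
        segments of real profiles generally do not join.

    Returns
    -------
    callable
        Vectorized T2(x) in ms; raises on x outside [0, 100].

    Raises
    ------
    InvalidProfileSpecError
        If any segment's line is non-positive anywhere on its third.
    """
    spec = [(float(s), float(b)) for s, b in profile_spec]
    if len(spec) != 3:
        raise InvalidProfileSpecError(
            f"profile_spec needs exactly 3 (slope, intercept) segments, got {len(spec)}"
        )
    # linear on each third => positivity needs checking at the two ends only
    for i, (slope, intercept) in enumerate(spec):
        lo, hi = _SEG_EDGES[i], _SEG_EDGES[i + 1]
        if intercept + slope * lo <= 0 or intercept + slope * hi <= 0:
            raise InvalidProfileSpecError(
                f"segment {i} (slope={slope}, intercept={intercept}) yields "
                f"T2 <= 0 on [{lo:.1f}, {hi:.1f}] %"
            )
    slopes = np.array([s for s, _ in spec])
    intercepts = np.array([b for _, b in spec])

    def t2_of_x(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > 100):
            raise ValueError("x must lie in [0, 100] percent")
        seg = np.minimum((x / (100.0 / 3.0)).astype(int), 2)
        return intercepts[seg] + slopes[seg] * x

    return t2_of_x


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a digital tendon phantom.

    Lengths are in voxels unless noted; spacings in mm; times in ms;
    signal amplitudes in arbitrary units shared with ``noise_sigma``.
    """

    grid_shape: tuple[int, int] = (96, 192)
    voxel_spacing: tuple[float, float] = (0.55, 0.55)
    echo_train: tuple[float, ...] = DEFAULT_ECHO_TRAIN
    #: (row, col) control points of the centerline: 2 points for a straight
    #: band, 3 for a quadratic (Bezier) arc.
    centerline: tuple[tuple[float, float], ...] = (
        (68.0, 12.0), (20.0, 96.0), (68.0, 180.0),
    )
    half_thickness: float = 4.0
    profile_spec: tuple[tuple[float, float], ...] = PROFILE_PRESETS[
        "tendinosis_before"
    ]
    s0_tendon: float = 1000.0
    s0_fluid: float = 1000.0
    s0_bone: float = 50.0
    t2_fluid: float = 200.0
    t2_bone: float = 2.0
    fluid_thickness: float = 3.0
    bone_thickness: float = 3.0
    noise_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_train, dtype=float)
        if te.size < 3 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_train must be strictly increasing, length >= 3")
        if self.t2_fluid <= 0 or self.t2_bone <= 0:
            raise ValueError("compartment T2 values must be positive")
        if self.half_thickness < 1:
            raise ValueError("half_thickness must be >= 1 voxel")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if len(self.centerline) not in (2, 3):
            raise ValueError("centerline takes 2 (straight) or 3 (arc) control points")
        make_profile_function(self.profile_spec)  # validates positivity

    def with_(self, **kwargs) -> "PhantomConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class MultiEchoImage:
    """Multi-echo magnitude image stack on a single voxel grid."""

    echoes: list[np.ndarray]
    echo_train: tuple[float, ...]
    voxel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.echoes}
        if len(shapes) != 1:
            raise ValueError("all echo arrays must share one grid shape")
        te = np.asarray(self.echo_train, dtype=float)
        if len(self.echoes) != te.size or np.any(np.diff(te) <= 0):
            raise ValueError(
                "echo_train must be strictly increasing and match the echo count"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.echoes[0].shape

    def as_array(self) -> np.ndarray:
        """Stack echoes into one (n_echo, *grid) array."""
        return np.stack(self.echoes, axis=0)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    t2_field: np.ndarray  #: per-voxel true T2 (ms); NaN outside compartments
    mask: np.ndarray  #: boolean tendon mask
    position: np.ndarray  #: per-voxel true along-band position (%); NaN off band
    lateral_seed: tuple[int, int]
    medial_seed: tuple[int, int]
    fluid_mask: np.ndarray
    bone_mask: np.ndarray
    true_profile: Callable[[np.ndarray], np.ndarray]
    config: PhantomConfig


def _sample_centerline(
    control_points: Sequence[tuple[float, float]], n: int
) -> np.ndarray:
    """Sample the centerline at n points: segment or quadratic Bezier."""
    pts = np.asarray(control_points, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    if len(pts) == 2:
        return (1 - t) * pts[0] + t * pts[1]
    return (1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]


def add_rician_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Corrupt a magnitude image with Rician noise.

    Each voxel value ``v`` becomes ``sqrt((v + n1)^2 + n2^2)`` with ``n1``,
    ``n2`` independent zero-mean Gaussians of standard deviation ``sigma`` —
    the magnitude of a complex signal with Gaussian channel noise.  For
    ``v = 0`` this reduces to a Rayleigh background with mean
    ``sigma * sqrt(pi / 2)``.

    ``sigma = 0`` returns the input unchanged; a fixed seed gives
    bit-identical output.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def generate_phantom(config: PhantomConfig) -> tuple[MultiEchoImage, PhantomTruth]:
    """Generate a multi-echo tendon phantom and its ground truth.

    The tendon band is the set of voxels within ``half_thickness`` of the
    centerline; each band voxel's along-band position is the normalized arc
    length of its nearest centerline point (0% at the first control point,
    the lateral/footprint end).  Fluid lies on the concave (superior) side
    of the band, bone on the other, each ``fluid_thickness`` /
    ``bone_thickness`` voxels thick, so that a mask dilated across the band
    edge picks up realistic partial-volume neighbors.

    Noiseless voxel signals are ``S0(compartment) * exp(-TE / T2(voxel))``;
    Rician noise of width ``noise_sigma`` is then applied per echo with
    echo-specific substreams of ``config.seed``.
    """
    nr, nc = config.grid_shape
    dr, dc = config.voxel_spacing
    n_samp = 8 * max(nr, nc)
    cl_vox = _sample_centerline(config.centerline, n_samp)
    if (
        np.any(cl_vox[:, 0] < 0) or np.any(cl_vox[:, 0] > nr - 1)
        or np.any(cl_vox[:, 1] < 0) or np.any(cl_vox[:, 1] > nc - 1)
    ):
        raise GeometryError("tendon centerline exits the phantom grid")

    cl_mm = cl_vox * np.array([dr, dc])
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(cl_mm, axis=0), axis=1))]
    )
    total_len = arc[-1]

    rows, cols = np.mgrid[0:nr, 0:nc]
    vox_mm = np.stack([rows * dr, cols * dc], axis=-1).reshape(-1, 2)
    tree = cKDTree(cl_mm)
    dist, idx = tree.query(vox_mm)
    dist = dist.reshape(nr, nc)
    idx = idx.reshape(nr, nc)

    mean_sp = 0.5 * (dr + dc)
    band_mm = config.half_thickness * mean_sp
    mask = dist <= band_mm
    if not mask.any():
        raise GeometryError("tendon band contains no voxels")
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        raise GeometryError("tendon band touches the grid border")

    position = np.full((nr, nc), np.nan)
    position[mask] = 100.0 * arc[idx[mask]] / total_len

    # side of the band: sign of cross(tangent, voxel - nearest point)
    tangents = np.gradient(cl_mm, axis=0)
    near = cl_mm[idx.ravel()]
    tan = tangents[idx.ravel()]
    rel = vox_mm - near
    side = (tan[:, 0] * rel[:, 1] - tan[:, 1] * rel[:, 0]).reshape(nr, nc)

    shell = (dist > band_mm) & (dist <= band_mm + config.fluid_thickness * mean_sp)
    fluid_mask = shell & (side > 0)
    shell_b = (dist > band_mm) & (dist <= band_mm + config.bone_thickness * mean_sp)
    bone_mask = shell_b & (side <= 0)

    profile = make_profile_function(config.profile_spec)
    t2_field = np.full((nr, nc), np.nan)
    t2_field[mask] = profile(position[mask])
    t2_field[fluid_mask] = config.t2_fluid
    t2_field[bone_mask] = config.t2_bone

    s0 = np.zeros((nr, nc))
    s0[mask] = config.s0_tendon
    s0[fluid_mask] = config.s0_fluid
    s0[bone_mask] = config.s0_bone

    echoes: list[np.ndarray] = []
    with np.errstate(invalid="ignore"):
        decay_t2 = np.where(np.isnan(t2_field), np.inf, t2_field)
    for k, te in enumerate(config.echo_train):
        clean = s0 * np.exp(-te / decay_t2)
        echoes.append(
            add_rician_noise(clean, config.noise_sigma, seed=config.seed * 1000 + k)
            if config.noise_sigma > 0
            else clean
        )

    def seed_voxel(which: int) -> tuple[int, int]:
        target = cl_mm[0] if which == 0 else cl_mm[-1]
        cand = np.argwhere(mask)
        d = np.linalg.norm(cand * np.array([dr, dc]) - target, axis=1)
        r, c = cand[int(np.argmin(d))]
        return int(r), int(c)

    truth = PhantomTruth(
        t2_field=t2_field,
        mask=mask,
        position=position,
        lateral_seed=seed_voxel(0),
        medial_seed=seed_voxel(1),
        fluid_mask=fluid_mask,
        bone_mask=bone_mask,
        true_profile=profile,
        config=config,
    )
    image = MultiEchoImage(
        echoes=echoes,
        echo_train=tuple(float(t) for t in config.echo_train),
        voxel_spacing=config.voxel_spacing,
    )
    return image, truth
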