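"""Synthetic demineralized-enamel A-scans and B-scans with known ground truth.

A mathematical A-scan (``ma_line``) follows a two-term Beer-Lambert model:

    I1(z) = a*z*exp(-2*mu_t1*z*S) + b*z*exp(-2*mu_t2*z*S)
    I2(z) = M * I1(z)   on z in [z1, z2],  0 elsewhere
    I(z)  = I1(z) + I2(z)

with ``z`` the depth from the enamel surface (um), ``mu_t1``/``mu_t2`` the
attenuation coefficients of sound and demineralized enamel (1/um), ``S`` a
dimensionless scale controlling the exponential damping (default 0.125) and
``M`` a magnification boosting the Ie demineralization band between ``z1``
and ``z2``.  A B-scan is built by repeating the A-scan laterally under a
chosen surface profile (flat, cosine, supplied real profile, or freehand
control points); the noiseless profile classified by the colormap provides
the depth ground truth.  Speckle can be extracted from a donor frame
(median 3x3 or Wiener 5x5 residual) or injected as a seeded multiplicative
noise field.

Default amplitudes and attenuation coefficients were chosen so the
noiseless dB profile spans the whole colormap: a specular-like surface peak
of ~37 dB (Ia band), decay through the Ie band, and a sound tail of
8-12 dB at a 440 um frame bottom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .io import BScan, ColorMap, default_colormap
from .protocol import PS_AXIAL_UM, PS_LATERAL_UM
from .quantification import align_to_surface
from .segmentation import ABSENT, SurfaceProfile, ZoneLimits

log = logging.getLogger(__name__)

SURFACE_KINDS = ("F_sur", "S_sur", "M_sur", "D_sur")
ALINE_KINDS = ("RA_line", "LS_line", "MA_line")


def _default_grid() -> np.ndarray:
    # 100 axial samples at the 4.4 um pitch, starting one pixel below z=0
    # (the model vanishes at z=0 exactly).
    return np.arange(1, 101) * PS_AXIAL_UM


@dataclass
class SimulationParams:
    """Parameters of the mathematical A-scan model (units in docstring above)."""

    a: float = 1.0
    b: float = 1500.0
    mu_t1: float = 0.034
    mu_t2: float = 0.20
    s: float = 0.125
    m: float = 2.0
    z1: float = 140.0
    z2: float = 300.0
    depth_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.s <= 0:
            raise ValueError("scale parameter S must be positive")
        if self.m <= 0:
            raise ValueError("magnification M must be positive")
        if self.a < 0 or self.b < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.z1 < self.z2 <= float(self.depth_grid.max()):
            raise ValueError(
                f"need 0 <= z1 < z2 <= max depth, got z1={self.z1}, "
                f"z2={self.z2}, max={self.depth_grid.max()}"
            )


@dataclass
class SimulatedBScan:
    """A simulated frame together with its generation ground truth."""

    bscan: BScan
    noiseless_db: np.ndarray
    truth_surface: SurfaceProfile
    truth_limits: ZoneLimits
    params: SimulationParams | None
    surface_kind: str
    aline_kind: str

    def true_depths(self) -> tuple[float, float]:
        """Ground-truth mean Ia and Ie depths in um (noiseless, pre-speckle)."""
        valid = self.truth_limits.valid
        ps = self.bscan.ps_axial
        return (
            float(self.truth_limits.delta_ia[valid].mean() * ps),
            float(self.truth_limits.delta_ie[valid].mean() * ps),
        )


def db_from_linear(linear: np.ndarray) -> np.ndarray:
    """Power-convention dB with non-positive intensities mapped to the
    background marker 0."""
    linear = np.asarray(linear, dtype=float)
    out = np.zeros_like(linear)
    pos = linear > 0
    out[pos] = 10.0 * np.log10(linear[pos])
    return out


def ma_line(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the mathematical A-scan model on the depth grid.

    Returns ``(linear, db)`` arrays over ``params.depth_grid``.
    """
    if params.a == 0 and params.b == 0:
        raise ValueError("degenerate signal: a and b are both zero")
    z = params.depth_grid
    i1 = (
        params.a * z * np.exp(-2.0 * params.mu_t1 * z * params.s)
        + params.b * z * np.exp(-2.0 * params.mu_t2 * z * params.s)
    )
    band = (z >= params.z1) & (z <= params.z2)
    i2 = np.where(band, i1 * params.m, 0.0)
    linear = i1 + i2
    return linear, db_from_linear(linear)


def ls_line(aline: np.ndarray, degree: int = 20) -> np.ndarray:
    """Least-squares polynomial fit of an A-scan (default degree 20).

    Fitting is performed on a rescaled depth coordinate for conditioning
    and evaluated back on the A-scan grid.
    """
    aline = np.asarray(aline, dtype=float)
    if aline.size <= degree:
        raise ValueError(
            f"A-scan of length {aline.size} cannot support degree {degree}"
        )
    x = np.arange(aline.size)
    poly = np.polynomial.Polynomial.fit(x, aline, degree)
    return poly(x)


def ra_line(frames: list[BScan], roi_cols: slice | None = None) -> np.ndarray:
    """Average A-scan (dB) over surface-aligned frames and ROI columns.

    Frames are background-removed, surface-aligned, converted to linear
    intensity, averaged per depth over all ROI columns of all frames, and
    converted back to dB.
    """
    from .segmentation import detect_surface, remove_background

    if not frames:
        raise ValueError("need at least one frame")
    roi_cols = roi_cols if roi_cols is not None else slice(None)
    acc = None
    count = None
    for frame in frames:
        clean = remove_background(frame)
        aligned, _ = align_to_surface(clean, detect_surface(clean))
        db = aligned.intensity_db[:, roi_cols]
        if db.shape[1] == 0:
            raise ValueError("empty ROI")
        tissue = db != 0
        linear = np.where(tissue, 10.0 ** (db / 10.0), 0.0)
        if acc is None:
            acc = linear.sum(axis=1)
            count = tissue.sum(axis=1)
        else:
            acc += linear.sum(axis=1)
            count += tissue.sum(axis=1)
    profile = np.full(acc.shape, np.nan)
    rows = count > 0
    profile[rows] = 10.0 * np.log10(acc[rows] / count[rows])
    return profile


def flat_surface(width: int, row: int = 2) -> SurfaceProfile:
    return SurfaceProfile(np.full(width, row, dtype=int))


def cosine_surface(
    width: int,
    offset_row: float,
    amplitude_px: float,
    period_cols: float,
    phase: float = 0.0,
) -> SurfaceProfile:
    """Cosine surface: ``row = offset + amplitude * cos(2*pi*x/period + phase)``."""
    x = np.arange(width)
    rows = offset_row + amplitude_px * np.cos(2 * np.pi * x / period_cols + phase)
    rows = np.rint(rows).astype(int)
    if rows.min() < 0:
        raise ValueError("cosine surface rises above the frame top")
    return SurfaceProfile(rows)


def freehand_surface(width: int, control_points: list[tuple[float, float]]) -> SurfaceProfile:
    """Piecewise-linear surface through ``(column, row)`` control points."""
    xs = np.array([p[0] for p in control_points], dtype=float)
    zs = np.array([p[1] for p in control_points], dtype=float)
    if xs.size < 2 or np.any(np.diff(xs) <= 0):
        raise ValueError("control points must be strictly increasing in x")
    rows = np.rint(np.interp(np.arange(width), xs, zs)).astype(int)
    if rows.min() < 0:
        raise ValueError("freehand surface rises above the frame top")
    return SurfaceProfile(rows)


def make_surface(kind: str, width: int, **kwargs) -> SurfaceProfile:
    """Build one of the four surface kinds.

    ``F_sur``: flat (``row``); ``M_sur``: cosine (``offset_row``,
    ``amplitude_px``, ``period_cols``, ``phase``); ``D_sur``: freehand
    (``control_points``); ``S_sur``: a supplied profile (``profile``, a
    :class:`SurfaceProfile` or integer row array).
    """
    if width < 2:
        raise ValueError("width must be at least 2 columns")
    if kind == "F_sur":
        return flat_surface(width, **kwargs)
    if kind == "M_sur":
        return cosine_surface(width, **kwargs)
    if kind == "D_sur":
        return freehand_surface(width, **kwargs)
    if kind == "S_sur":
        profile = kwargs["profile"]
        rows = profile.surface_row if isinstance(profile, SurfaceProfile) else profile
        rows = np.asarray(rows, dtype=int)
        if rows.size != width:
            raise ValueError("supplied profile width mismatch")
        return SurfaceProfile(rows.copy())
    raise ValueError(f"unknown surface kind {kind!r}; expected {SURFACE_KINDS}")


def cosine_amplitude_for_curvature(
    target_index: float,
    period_um: float,
    amplitude_bracket_um: tuple[float, float] = (1.0, 2000.0),
) -> float:
    """Amplitude (um) giving a cosine surface the requested curvature index.

    The curvature index of ``z(x) = A*cos(2*pi*x/P)`` over one period is the
    mean of ``sqrt(1 + (dz/dx)^2)``; the amplitude is solved by bisection
    against numerical quadrature.
    """
    if target_index <= 1.0:
        raise ValueError("curvature index of a cosine exceeds 1")

    def index_of(amp: float) -> float:
        k = 2 * np.pi / period_um
        t = np.linspace(0.0, period_um, 20001)
        return float(np.trapezoid(np.hypot(1.0, amp * k * np.sin(k * t)), t)
                     / period_um)

    return float(
        optimize.brentq(lambda A: index_of(A) - target_index,
                        *amplitude_bracket_um, xtol=1e-6)
    )


def _classify_aline(db: np.ndarray, cmap: ColorMap) -> tuple[int, int]:
    """Deepest Ia / Ie sample counts (from the surface sample) of an A-scan."""
    ia = (db >= cmap.ia_range[0])
    ie = (db >= cmap.ie_range[0]) & (db < cmap.ie_range[1])
    d_ia = int(np.flatnonzero(ia).max() + 1) if ia.any() else 0
    d_ie = int(np.flatnonzero(ie).max() + 1) if ie.any() else 0
    return d_ia, d_ie


def build_bscan(
    aline_db: np.ndarray,
    surface: SurfaceProfile,
    cmap: ColorMap | None = None,
    params: SimulationParams | None = None,
    ps_axial: float = PS_AXIAL_UM,
    ps_lateral: float = PS_LATERAL_UM,
    height: int | None = None,
    frame_id: str = "sim",
    surface_kind: str = "F_sur",
    aline_kind: str = "MA_line",
) -> SimulatedBScan:
    """Repeat an A-scan laterally under a surface profile.

    Each column holds the A-scan starting at its surface row, with
    background 0 above.  The frame is sized to fit the deepest placement
    unless ``height`` is given, in which case overflowing columns are
    truncated with a logged warning.  The ground-truth zone limits come
    from classifying the noiseless A-scan with the colormap.
    """
    cmap = cmap if cmap is not None else default_colormap()
    aline_db = np.asarray(aline_db, dtype=float)
    rows = surface.surface_row
    if np.any(rows == ABSENT):
        raise ValueError("surface profile must cover every column")
    n = aline_db.size
    full = int(rows.max()) + n
    if height is None:
        height = full
    elif height < full:
        log.warning("A-scan truncated at the frame bottom (%d < %d rows)",
                    height, full)
    values = np.zeros((height, rows.size))
    for j, r in enumerate(rows):
        stop = min(height, r + n)
        values[r:stop, j] = aline_db[: stop - r]
    d_ia, d_ie = _classify_aline(aline_db, cmap)
    width = rows.size
    limits = ZoneLimits(
        np.full(width, d_ia, dtype=int),
        np.full(width, d_ie, dtype=int),
        np.ones(width, dtype=bool),
    )
    bscan = BScan(values, ps_axial=ps_axial, ps_lateral=ps_lateral,
                  frame_id=frame_id)
    return SimulatedBScan(
        bscan=bscan,
        noiseless_db=values.copy(),
        truth_surface=SurfaceProfile(rows.copy()),
        truth_limits=limits,
        params=params,
        surface_kind=surface_kind,
        aline_kind=aline_kind,
    )


def extract_speckle(frame: BScan, method: str = "median3") -> BScan:
    """Speckle residual of a frame: original minus a smoothing filter.

    ``median3`` uses a 3x3 median filter, ``wiener5`` a 5x5 Wiener filter.
    ``filtered + noise`` reconstructs the original exactly.
    """
    sizes = {"median3": 3, "wiener5": 5}
    if method not in sizes:
        raise ValueError(f"unknown method {method!r}; expected {sorted(sizes)}")
    k = sizes[method]
    if min(frame.shape) < k:
        raise ValueError(f"frame smaller than the {k}x{k} kernel")
    if method == "median3":
        filtered = ndimage.median_filter(frame.intensity_db, size=k)
    else:
        # edge-pad so the Wiener local statistics see no zero border
        pad = k // 2
        padded = np.pad(frame.intensity_db, pad, mode="edge")
        with np.errstate(divide="ignore", invalid="ignore"):
            filtered = signal.wiener(padded, mysize=k)[pad:-pad, pad:-pad]
    return frame.with_values(frame.intensity_db - filtered,
                             frame_id=f"{frame.frame_id}_speckle")


def inject_speckle(
    sim: SimulatedBScan,
    rng: np.random.Generator,
    sigma_db: float = 1.5,
    air_max_db: float = 4.5,
    noise_frame: np.ndarray | None = None,
) -> SimulatedBScan:
    """Add speckle to a simulated frame, in place of a real acquisition.

    With ``noise_frame`` given (e.g. from :func:`extract_speckle` of a donor
    frame) the residual is added to tissue pixels.  Otherwise a seeded
    Gaussian dB field (multiplicative in linear intensity, i.e.
    speckle-like) of standard deviation ``sigma_db`` is used.  Air pixels
    receive sub-threshold uniform clutter in ``(0, air_max_db)`` so the raw
    frame is not artificially clean above the surface.  The ground-truth
    fields are untouched (they describe the noiseless frame).
    """
    values = sim.bscan.intensity_db.copy()
    tissue = values != 0
    if noise_frame is not None:
        noise = np.asarray(noise_frame, dtype=float)
        if noise.shape != values.shape:
            raise ValueError("noise frame shape mismatch")
        values[tissue] += noise[tissue]
    else:
        values[tissue] += rng.normal(0.0, sigma_db, int(tissue.sum()))
    air = ~tissue
    values[air] = rng.uniform(0.0, air_max_db, int(air.sum()))
    noisy = sim.bscan.with_values(values)
    return SimulatedBScan(
        bscan=noisy,
        noiseless_db=sim.noiseless_db,
        truth_surface=sim.truth_surface,
        truth_limits=sim.truth_limits,
        params=sim.params,
        surface_kind=sim.surface_kind,
        aline_kind=sim.aline_kind,
    )


#: Study-condition parameter ranges for the verification batch: S fixed at
#: 0.125, the Ie band bounds z1/z2 and the magnification M swept.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "s": (0.125, 0.125),
    "m": (1.5, 3.5),
    "z1": (120.0, 170.0),
    "z2": (240.0, 380.0),
}


def _random_surface(kind: str, width: int, rng: np.random.Generator) -> SurfaceProfile:
    """A gently curved surface of the requested kind (median tangent small)."""
    if kind == "F_sur":
        return flat_surface(width, row=int(rng.integers(2, 10)))
    if kind == "M_sur":
        amp = float(rng.uniform(20, 32))
        return cosine_surface(width, offset_row=amp + 2, amplitude_px=amp,
                              period_cols=width,
                              phase=float(rng.uniform(0, 2 * np.pi)))
    if kind == "D_sur":
        n_pts = 5
        xs = np.linspace(0, width - 1, n_pts)
        zs = 10 + rng.uniform(-8, 8, n_pts)
        return freehand_surface(width, list(zip(xs, zs)))
    if kind == "S_sur":
        # stand-in for a profile taken from a real B-scan: a smoothed
        # random walk with gentle slopes
        walk = np.cumsum(rng.normal(0, 1, width))
        walk = ndimage.gaussian_filter1d(walk, sigma=15)
        walk -= walk.min()
        peak = walk.max()
        if peak > 0:
            walk *= 10.0 / peak
        return SurfaceProfile(np.rint(walk + 2).astype(int))
    raise ValueError(f"unknown surface kind {kind!r}")


def simulate_dataset(
    n_frames: int = 23,
    seed: int = 0,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    surface_kinds: tuple[str, ...] = SURFACE_KINDS,
    speckle_sigma_db: float = 1.5,
    cmap: ColorMap | None = None,
    width: int = 225,
) -> list[SimulatedBScan]:
    """Seeded batch of simulated B-scans spanning the four surface kinds.

    Model parameters are drawn uniformly from ``param_ranges`` (defaults:
    S fixed at 0.125; M, z1, z2 swept), surface kinds cycle round-robin,
    and speckle is injected with ``speckle_sigma_db`` (0 disables it, giving
    noiseless frames).  Identical seeds give bit-identical datasets.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty parameter range for {key!r}")
    cmap = cmap if cmap is not None else default_colormap()
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        params = SimulationParams(
            s=float(rng.uniform(*ranges["s"])),
            m=float(rng.uniform(*ranges["m"])),
            z1=float(rng.uniform(*ranges["z1"])),
            z2=float(rng.uniform(*ranges["z2"])),
        )
        kind = surface_kinds[i % len(surface_kinds)]
        surface = _random_surface(kind, width, rng)
        _, aline_db = ma_line(params)
        sim = build_bscan(
            aline_db, surface, cmap=cmap, params=params,
            frame_id=f"sim{i:03d}", surface_kind=kind,
        )
        if speckle_sigma_db > 0:
            sim = inject_speckle(sim, rng, sigma_db=speckle_sigma_db)
        frames.append(sim)
    return frames


def synthetic_registered_pair(
    sim: SimulatedBScan,
    cmap: ColorMap | None = None,
    scale: tuple[int, int] = (4, 2),
    noisy: bool = False,
):
    """A registered OCT/SEM-style pair built from one simulated frame.

    The "SEM" side is the ground-truth zone label field of the noiseless
    frame replicated onto a finer grid (``scale`` = rows, cols replication
    factors) — a synthetic stand-in for a segmented micrograph of the same
    region.  The OCT side is the simulated frame itself (noiseless by
    default).  Returns ``(BScan, SEMLabelMap)``.
    """
    from .segmentation import detect_surface, label_zones, remove_background
    from .sem import SEMLabelMap, interfaces_from_labels

    cmap = cmap if cmap is not None else default_colormap()
    clean = remove_background(
        sim.bscan.with_values(sim.noiseless_db), cmap.background_db
    )
    labels = label_zones(clean, detect_surface(clean), cmap)
    sem_labels = np.kron(labels, np.ones(scale, dtype=int))
    surface_row, ia_ie, ie_sound = interfaces_from_labels(sem_labels)
    sem = SEMLabelMap(labels=sem_labels, surface_row=surface_row,
                      ia_ie_interface=ia_ie, ie_sound_interface=ie_sound)
    oct_frame = sim.bscan if noisy else sim.bscan.with_values(sim.noiseless_db)
    return oct_frame, sem
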