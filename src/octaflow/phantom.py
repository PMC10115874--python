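"""Speckle flow-phantom simulator for repeated-B-scan OCTA.

The simulator realizes the physical premise of decorrelation
velocimetry: under fixed imaging conditions the amplitude decorrelation
between repeated B-scans grows monotonically with the mean distance
travelled by the scatterers during the interscan time, up to a
saturation distance set by the optical resolution element.  Each voxel's
repeat sequence is modelled as an order-1 autoregressive chain of
circular-Gaussian complex speckle fields with step correlation

    rho(v, tau) = exp(-(v * tau)^2 / (2 * w^2))        ("gaussian" law)

where ``v`` is the local flow speed (um/ms), ``tau`` the interscan time
(ms) and ``w`` the speckle/resolution radius (um).  The field amplitude
is Rayleigh distributed (fully developed speckle); detector noise is
additive Gaussian on the amplitude.  Only the correlation-versus-
displacement monotonicity is physically prescribed; the Gaussian law is
the standard choice for a Gaussian beam profile and is configurable.

The phantom geometry emulates a curved organ surface under a noise-only
medium, with vessel networks confined to depth slabs referenced to that
surface (a superficial and a deep capillary layer by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numpy as np

from .containers import OCTVolume, ScanPattern
from .exceptions import GeometryError, PatternError

__all__ = [
    "SpeckleModel",
    "Disk",
    "VesselLayer",
    "PhantomSpec",
    "make_surface_profile",
    "simulate_repeat_bscans",
    "analytic_decorr_oracle",
    "OracleResult",
    "RAYLEIGH_PLATEAU_D",
]

#: Mean pairwise decorrelation of two *independent* Rayleigh amplitude
#: fields (rho = 0): the saturation plateau of the metric.  Frozen from a
#: 2e7-draw Monte-Carlo run of :func:`analytic_decorr_oracle`.
RAYLEIGH_PLATEAU_D = 0.21461


_CORRELATION_LAWS: dict[str, Callable[[np.ndarray, float, float], np.ndarray]] = {}


def _register_law(name):
    def deco(fn):
        _CORRELATION_LAWS[name] = fn
        return fn
    return deco


@_register_law("gaussian")
def _gaussian_law(v, tau_ms, w_um):
    return np.exp(-((v * tau_ms) ** 2) / (2.0 * w_um**2))


@dataclass(frozen=True)
class SpeckleModel:
    """Field-correlation model of moving scatterers.

    Parameters
    ----------
    resolution_radius_um : float
        Speckle (resolution-element) radius ``w``: the displacement scale
        at which the field decorrelates and the metric saturates.
    noise_floor_sigma : float
        Standard deviation of additive amplitude noise, in the same
        arbitrary units as the tissue amplitude.
    correlation_law : str
        Name of the displacement-to-correlation law; only the law's
        monotone decay is physically required, ``"gaussian"`` is the
        default and currently sole built-in.
    """

    resolution_radius_um: float = 4.0
    noise_floor_sigma: float = 0.05
    correlation_law: str = "gaussian"

    def __post_init__(self):
        if self.resolution_radius_um <= 0:
            raise ValueError("resolution_radius_um must be positive")
        if self.noise_floor_sigma < 0:
            raise ValueError("noise_floor_sigma must be >= 0")
        if self.correlation_law not in _CORRELATION_LAWS:
            raise ValueError(
                f"unknown correlation law {self.correlation_law!r}; "
                f"available: {sorted(_CORRELATION_LAWS)}"
            )

    def rho(self, v, tau_ms: float) -> np.ndarray:
        """Step field correlation for flow speed ``v`` (um/ms) at ``tau``."""
        v = np.asarray(v)
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float64)
        if np.any(v < 0):
            raise ValueError("flow speed must be >= 0")
        law = _CORRELATION_LAWS[self.correlation_law]
        return law(v, tau_ms, self.resolution_radius_um)


@dataclass(frozen=True)
class Disk:
    """Vessel cross-section in the en-face plane, in reference-grid pixels."""

    center: tuple[float, float]  # (x, y)
    radius_px: float

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("disk radius must be positive")


@dataclass(frozen=True)
class VesselLayer:
    """A vascular slab at a fixed depth range below the tissue surface."""

    name: str
    depth_range_um: tuple[float, float]
    disks: tuple[Disk, ...]
    flow_speed_um_ms: float

    def __post_init__(self):
        d1, d2 = self.depth_range_um
        if not d1 < d2:
            raise ValueError(f"depth range must satisfy d1 < d2, got {d1}, {d2}")
        if self.flow_speed_um_ms < 0:
            raise ValueError("flow speed must be >= 0")
        object.__setattr__(self, "disks", tuple(self.disks))


def make_surface_profile(spec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Build a smooth surface-height function ``z_s(x, y)`` (voxel units).

    ``spec`` is either already a callable or a dict:

    - ``{"type": "flat", "z0": 20}``
    - ``{"type": "plane", "z0": 20, "gx": 0.1, "gy": 0.0}``
    - ``{"type": "dome", "z0": 30, "amplitude": 10, "sigma_frac": 0.5,
       "nx": nx, "ny": ny}`` — a Gaussian bump (organ curvature) centred
      in the field of view; ``sigma_frac`` is relative to nx.
    """
    if callable(spec):
        return spec
    kind = spec.get("type", "flat")
    if kind == "flat":
        z0 = float(spec["z0"])
        return lambda x, y: np.broadcast_arrays(
            np.full_like(np.asarray(x, float), z0), y
        )[0]
    if kind == "plane":
        z0, gx, gy = float(spec["z0"]), float(spec.get("gx", 0.0)), float(
            spec.get("gy", 0.0)
        )
        return lambda x, y: z0 + gx * np.asarray(x, float) + gy * np.asarray(y, float)
    if kind == "dome":
        z0 = float(spec["z0"])
        amp = float(spec["amplitude"])
        nx, ny = float(spec["nx"]), float(spec["ny"])
        sig = float(spec.get("sigma_frac", 0.5)) * nx
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

        def dome(x, y):
            x = np.asarray(x, float)
            y = np.asarray(y, float)
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            return z0 - amp * np.exp(-r2 / (2 * sig**2))

        return dome
    raise ValueError(f"unknown surface profile type {kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and seed of one synthetic flow phantom.

    The lateral grid ``(n_x, n_y)`` is a *reference* sampling; use
    :meth:`scaled_to` to resample the same physical scene to another
    pattern's sampling (surface heights and vessel geometry scale with
    it, depth ranges are physical and do not).
    """

    grid: tuple[int, int, int]  # (n_z, n_x, n_y)
    axial_pitch_um: float
    surface_profile: object  # callable or dict, see make_surface_profile
    vessel_layers: tuple[VesselLayer, ...]
    static_tissue_amplitude: float = 1.0
    speckle: SpeckleModel = field(default_factory=SpeckleModel)
    seed: int = 0

    def __post_init__(self):
        if self.axial_pitch_um <= 0:
            raise ValueError("axial_pitch_um must be positive")
        if self.static_tissue_amplitude <= 0:
            raise ValueError("static_tissue_amplitude must be positive")
        object.__setattr__(self, "vessel_layers", tuple(self.vessel_layers))
        object.__setattr__(self, "grid", tuple(int(g) for g in self.grid))

    @property
    def surface_fn(self):
        return make_surface_profile(self.surface_profile)

    def scaled_to(self, pattern: ScanPattern) -> "PhantomSpec":
        """Resample the phantom's lateral geometry to a pattern's grid."""
        n_z, n_x, n_y = self.grid
        sx = pattern.n_ascans_per_bscan / n_x
        sy = pattern.n_positions / n_y
        if sx == 1.0 and sy == 1.0:
            return self
        base = self.surface_fn
        surf = lambda x, y: base(np.asarray(x, float) / sx, np.asarray(y, float) / sy)
        s_iso = math.sqrt(sx * sy)
        layers = tuple(
            replace(
                layer,
                disks=tuple(
                    Disk(
                        center=(d.center[0] * sx, d.center[1] * sy),
                        radius_px=d.radius_px * s_iso,
                    )
                    for d in layer.disks
                ),
            )
            for layer in self.vessel_layers
        )
        return replace(
            self,
            grid=(n_z, pattern.n_ascans_per_bscan, pattern.n_positions),
            surface_profile=surf,
            vessel_layers=layers,
        )

    # -- geometry rasterization -------------------------------------------

    def surface_height(self) -> np.ndarray:
        """Surface height ``z_s[y, x]`` in (float) voxel index."""
        n_z, n_x, n_y = self.grid
        x = np.arange(n_x, dtype=float)[None, :]
        y = np.arange(n_y, dtype=float)[:, None]
        zs = np.broadcast_to(np.asarray(self.surface_fn(x, y), float), (n_y, n_x))
        if np.any(zs < 0) or np.any(zs >= n_z):
            raise GeometryError("surface profile leaves the voxel grid")
        return zs

    def speed_map(self, multipliers: dict[str, float] | None = None) -> np.ndarray:
        """Flow-speed map ``v[y, z, x]`` in um/ms (0 in static tissue).

        ``multipliers`` optionally scales each vessel layer's speed by
        name (cohort schedules use this).
        """
        n_z, n_x, n_y = self.grid
        zs = self.surface_height()
        v = np.zeros((n_y, n_z, n_x), dtype=np.float64)
        zcol = np.arange(n_z, dtype=float)[None, :, None]  # [1, z, 1]
        xg = np.arange(n_x, dtype=float)[None, :]
        yg = np.arange(n_y, dtype=float)[:, None]
        for layer in self.vessel_layers:
            d1, d2 = layer.depth_range_um
            o1 = round(d1 / self.axial_pitch_um)
            o2 = round(d2 / self.axial_pitch_um)
            ztop = np.ceil(zs) + o1
            zbot = np.ceil(zs) + o2
            if np.any(zbot >= n_z) or np.any(ztop < 0):
                raise GeometryError(
                    f"vessel layer '{layer.name}' depth range "
                    f"{layer.depth_range_um} um leaves the grid"
                )
            lateral = np.zeros((n_y, n_x), dtype=bool)
            for disk in layer.disks:
                cx, cy = disk.center
                lateral |= (xg - cx) ** 2 + (yg - cy) ** 2 <= disk.radius_px**2
            slab = (zcol >= ztop[:, None, :]) & (zcol <= zbot[:, None, :])
            mult = 1.0 if multipliers is None else float(
                multipliers.get(layer.name, 1.0)
            )
            mask = slab & lateral[:, None, :]
            v[mask] = layer.flow_speed_um_ms * mult
        return v

    def tissue_mask(self) -> np.ndarray:
        """Boolean ``[y, z, x]``: voxel lies at or below the surface."""
        n_z, n_x, n_y = self.grid
        zs = self.surface_height()
        zcol = np.arange(n_z, dtype=float)[None, :, None]
        return zcol >= zs[:, None, :]


class OracleResult(NamedTuple):
    """Monte-Carlo estimate with its standard error."""

    mean: float
    se: float
    n: int


def analytic_decorr_oracle(
    rho: float, n_draws: int = 1_000_000, seed: int = 0
) -> OracleResult:
    """Brute-force expectation of the pairwise decorrelation metric.

    Draws ``n_draws`` pairs of circular-Gaussian complex fields with
    field correlation ``rho`` (E2 = rho E1 + sqrt(1 - rho^2) xi), takes
    amplitudes A = |E| and returns the Monte-Carlo mean and standard
    error of ``(A1 - A2)^2 / (A1^2 + A2^2)``.  Serves as the independent
    reference for both the simulator and the decorrelation pipeline.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 1e4 for a usable standard error")
    rng = np.random.default_rng(seed)
    half = np.sqrt(0.5)
    e1 = half * (rng.standard_normal(n_draws) + 1j * rng.standard_normal(n_draws))
    xi = half * (rng.standard_normal(n_draws) + 1j * rng.standard_normal(n_draws))
    e2 = rho * e1 + math.sqrt(1.0 - rho * rho) * xi
    a1 = np.abs(e1)
    a2 = np.abs(e2)
    d = (a1 - a2) ** 2 / (a1 * a1 + a2 * a2)
    return OracleResult(float(d.mean()), float(d.std() / math.sqrt(n_draws)), n_draws)


def simulate_repeat_bscans(
    spec: PhantomSpec,
    pattern: ScanPattern,
    seed: int | None = None,
    speed_multipliers: dict[str, float] | None = None,
    subject_factor: float = 1.0,
    subject: str = "",
    time_point: str = "",
    dtype=np.float32,
) -> OCTVolume:
    """Simulate one repeated-B-scan amplitude volume of the phantom.

    Per voxel the M repeat fields form an AR(1) chain of circular-
    Gaussian complex values with step correlation ``rho(v, tau)``;
    amplitude is the field modulus plus additive Gaussian noise (clipped
    at zero), and voxels above the surface contain noise only.
    Deterministic given the seed.

    Parameters
    ----------
    spec : PhantomSpec
        Phantom whose grid must match the pattern's lateral sampling
        (use :meth:`PhantomSpec.scaled_to` first if it does not).
    pattern : ScanPattern
        Raster geometry, repeat count M >= 2 and interscan time tau.
    seed : int, optional
        Overrides ``spec.seed``.
    speed_multipliers, subject_factor
        Per-layer schedule multiplier and global subject-level factor
        applied to vessel speeds (cohort simulation).
    """
    if pattern.repeats < 2:
        raise PatternError("pattern must have at least 2 repeats")
    n_z, n_x, n_y = spec.grid
    if n_x != pattern.n_ascans_per_bscan or n_y != pattern.n_positions:
        raise GeometryError(
            f"phantom grid {spec.grid} does not match pattern "
            f"{pattern.n_ascans_per_bscan} x {pattern.n_positions}; "
            "use PhantomSpec.scaled_to(pattern)"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    v = spec.speed_map(speed_multipliers) * float(subject_factor)
    rho = spec.speckle.rho(v, pattern.interscan_time_ms)  # [y, z, x]
    amp = simulate_speckle_repeats(
        rho,
        n_repeats=pattern.repeats,
        mean_amplitude=spec.static_tissue_amplitude,
        noise_sigma=spec.speckle.noise_floor_sigma,
        tissue_mask=spec.tissue_mask(),
        rng=rng,
        dtype=dtype,
    )
    return OCTVolume(
        amplitude=amp,
        pattern=pattern,
        axial_pitch_um=spec.axial_pitch_um,
        subject=subject,
        time_point=time_point,
        meta={"seed": spec.seed if seed is None else seed},
    )


def simulate_speckle_repeats(
    rho: np.ndarray,
    n_repeats: int,
    mean_amplitude: float,
    noise_sigma: float,
    tissue_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """AR(1) correlated-speckle amplitude stack for a given rho field.

    ``rho`` has core axes ``[y, z, x]`` (leading batch axes allowed);
    the returned amplitude has the repeat axis inserted: ``[..., y, M,
    z, x]``.  The Rayleigh scale is set so the mean tissue amplitude
    equals ``mean_amplitude``.
    """
    if rng is None:
        rng = np.random.default_rng()
    rho = np.asarray(rho)
    shape = rho.shape  # [..., y, z, x]
    # per-component sigma of the circular-Gaussian field: Rayleigh mean
    # s*sqrt(pi/2) = mean_amplitude
    s = mean_amplitude / math.sqrt(math.pi / 2.0)
    innov = np.sqrt(np.clip(1.0 - rho * rho, 0.0, 1.0)).astype(dtype)
    rho_t = rho.astype(dtype)

    def cgauss():
        re = rng.standard_normal(shape, dtype=dtype)
        im = rng.standard_normal(shape, dtype=dtype)
        return (re + 1j * im) * np.asarray(s * math.sqrt(0.5), dtype=dtype)

    e = cgauss()
    amps = np.empty((n_repeats,) + shape, dtype=dtype)
    amps[0] = np.abs(e)
    for k in range(1, n_repeats):
        e = rho_t * e + innov * cgauss()
        amps[k] = np.abs(e)
    if tissue_mask is not None:
        amps *= np.asarray(tissue_mask)  # above-surface voxels: noise only
    if noise_sigma > 0:
        amps += noise_sigma * rng.standard_normal(amps.shape, dtype=dtype)
        np.clip(amps, 0.0, None, out=amps)
    # move repeat axis next to the position axis: [..., y, M, z, x]
    return np.moveaxis(amps, 0, -3)
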