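"""Model definition: lattice geometry, physical constants, coupling kernels, external drive.

The network is an N x N lattice of conductance-based leaky integrate-and-fire
neurons with periodic boundaries. 75% of neurons are excitatory; neurons at
gridpoints where both coordinates are odd are inhibitory (exactly 25% for even
N). Excitatory coupling falls off as a Gaussian of the lattice distance;
inhibitory coupling is uniform; both are cut off at a radius ``cutoff``
gridpoints. All neurons receive a constant background current, and a localized
Gaussian stimulus can be switched on at a fixed onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

__all__ = [
    "LatticeGeometry",
    "ModelParameters",
    "StimulusProtocol",
    "ConnectivityKernels",
    "neuron_class",
    "inhibitory_mask",
    "build_kernels",
    "external_input",
    "stimulus_field",
    "minimal_image_offsets",
    "minimal_image_distance",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class LatticeGeometry:
    """Periodic square lattice of neurons.

    Parameters
    ----------
    n : int
        Side length in neurons. Must be even so that the both-odd-coordinate
        rule yields exactly 25% inhibitory neurons.
    spacing_um : float
        Physical distance between nearest neighbours, in micrometres.
    """

    n: int = 300
    spacing_um: float = 40.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ConfigurationError(f"lattice side n must be even and >= 2, got {self.n}")
        if self.spacing_um <= 0:
            raise ConfigurationError("spacing_um must be positive")
        if not self.periodic:
            raise ConfigurationError("only periodic boundaries are supported")


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the conductance-based LIF lattice.

    Conductances are in nS, capacitance in nF, potentials in mV, times in ms,
    currents in nA, and kernel length scales in gridpoints. With these units
    the membrane equation integrates directly in mV per ms
    (nS x mV = pA = 1e-3 nA; nA / nF x ms = mV).

    The kernel amplitudes ``w_e``/``w_i`` and the excitatory decay
    ``sigma_e`` are calibrated values, not measured ones. The defaults
    (w_e = 3.0 nS, w_i = 2.0 nS at a 3:2 E:I amplitude ratio, sigma_e = 4.0
    gridpoints = 160 um) put the network in the balanced regime where
    spontaneous activity self-organizes into propagating waves coexisting
    with localized patches at ~9-11 Hz; see docs/methods.md for the
    calibration rationale.
    """

    g_l: float = 25.0
    c_m: float = 0.5
    v_leak: float = -70.0
    v_exc: float = 0.0
    v_inh: float = -80.0
    v_th: float = -55.0
    v_reset: float = -70.0
    tau_ref: float = 5.0
    tau_e: float = 2.0
    tau_i: float = 2.0
    w_e: float = 3.0
    w_i: float = 2.0
    sigma_e: float = 4.0
    cutoff: int = 30
    dt: float = 0.05

    def __post_init__(self) -> None:
        if not (self.v_inh < self.v_reset <= self.v_leak < self.v_th < self.v_exc):
            raise ConfigurationError(
                "potentials must satisfy v_inh < v_reset <= v_leak < v_th < v_exc"
            )
        for name in ("g_l", "c_m", "tau_ref", "tau_e", "tau_i", "w_e", "w_i", "sigma_e", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.cutoff < 1:
            raise ConfigurationError("cutoff must be >= 1 gridpoint")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms (nF/nS = s, hence the 1e3)."""
        return self.c_m / self.g_l * 1e3

    @property
    def refractory_steps(self) -> int:
        return int(round(self.tau_ref / self.dt))


@dataclass(frozen=True)
class StimulusProtocol:
    """External drive: constant background plus an optional localized stimulus.

    The localized term is a spatial Gaussian of amplitude ``w_s`` (nA) and
    decay ``sigma_s`` (gridpoints) centred at ``centre``, gated by a Heaviside
    step at ``t_onset_ms``. The region of input (RoI) is the disc of radius
    ``roi_radius`` gridpoints around the centre; it is an analysis region only
    and does not truncate the stimulus. ``sigma_s`` defaults to half the RoI
    radius so the stimulus is effectively contained in the RoI.
    """

    i_background: float = 0.4
    w_s: float = 0.0
    t_onset_ms: float = 2000.0
    centre: tuple[int, int] = (150, 150)
    sigma_s: float = 7.5
    roi_radius: int = 15

    def __post_init__(self) -> None:
        if self.i_background < 0 or self.w_s < 0:
            raise ConfigurationError("i_background and w_s must be non-negative")
        if self.sigma_s <= 0 or self.roi_radius < 1:
            raise ConfigurationError("sigma_s must be > 0 and roi_radius >= 1")


def neuron_class(coord: tuple[int, int], geometry: LatticeGeometry) -> Literal["excitatory", "inhibitory"]:
    """Class of the neuron at integer lattice ``coord``.

    Inhibitory iff both coordinates are odd; excitatory otherwise.
    """
    x, y = coord
    if not (0 <= x < geometry.n and 0 <= y < geometry.n):
        raise ValueError(f"coordinate {coord} outside {geometry.n}x{geometry.n} lattice")
    return "inhibitory" if (x % 2 == 1 and y % 2 == 1) else "excitatory"


def inhibitory_mask(geometry: LatticeGeometry) -> np.ndarray:
    """Boolean (n, n) array, True where the neuron is inhibitory."""
    x = np.arange(geometry.n)
    return (x[:, None] % 2 == 1) & (x[None, :] % 2 == 1)


def minimal_image_offsets(dx: np.ndarray, n: int) -> np.ndarray:
    """Wrap integer offsets into the minimal image (-n/2, n/2]."""
    return (dx + n // 2) % n - n // 2


def minimal_image_distance(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Euclidean minimal-image distance between lattice points, in gridpoints."""
    d = minimal_image_offsets(np.asarray(a) - np.asarray(b), n)
    return np.sqrt((d**2).sum(axis=-1))


@dataclass(frozen=True)
class ConnectivityKernels:
    """Distance-dependent coupling strengths over lattice offsets within the cutoff.

    ``offsets`` holds every integer displacement (dx, dy) with
    0 < dx^2 + dy^2 <= cutoff^2; ``k_e``/``k_i`` are the excitatory and
    inhibitory strengths (nS) at each offset. ``patch_e``/``patch_i`` are the
    same strengths laid out on a (2*cutoff+1)^2 stencil (zero at the centre
    and beyond the cutoff) for translation-invariant accumulation.
    """

    cutoff: int
    offsets: np.ndarray  # (m, 2) int
    k_e: np.ndarray  # (m,) float, nS
    k_i: np.ndarray  # (m,) float, nS
    patch_e: np.ndarray = field(repr=False, default=None)  # (2D+1, 2D+1)
    patch_i: np.ndarray = field(repr=False, default=None)

    @property
    def n_afferents(self) -> int:
        """Number of afferent connections each neuron receives."""
        return len(self.offsets)


def build_kernels(params: ModelParameters) -> ConnectivityKernels:
    """Construct E and I coupling kernels from the model parameters.

    The excitatory strength at offset dr is W_E * exp(-|dr|^2 / (2 sigma_E^2));
    the inhibitory strength is W_I at every included offset. Offsets run over
    the punctured disc 0 < |dr| <= cutoff, so ``n_afferents`` equals the
    number of integer lattice points in that disc (2820 for the default
    cutoff of 30).
    """
    d = params.cutoff
    ax = np.arange(-d, d + 1)
    dx, dy = np.meshgrid(ax, ax, indexing="ij")
    r2 = dx**2 + dy**2
    inside = (r2 > 0) & (r2 <= d * d)
    offsets = np.column_stack([dx[inside], dy[inside]])
    k_e = params.w_e * np.exp(-r2[inside] / (2.0 * params.sigma_e**2))
    k_i = np.full(len(offsets), params.w_i)
    patch_e = np.where(inside, params.w_e * np.exp(-r2 / (2.0 * params.sigma_e**2)), 0.0)
    patch_i = np.where(inside, params.w_i, 0.0)
    return ConnectivityKernels(
        cutoff=d, offsets=offsets, k_e=k_e, k_i=k_i, patch_e=patch_e, patch_i=patch_i
    )


def stimulus_field(geometry: LatticeGeometry, protocol: StimulusProtocol) -> np.ndarray:
    """Spatial profile of the localized stimulus (nA), before the time gate.

    Gaussian of amplitude ``w_s`` centred at ``protocol.centre`` with
    minimal-image distances on the periodic lattice.
    """
    n = geometry.n
    x = np.arange(n)
    dx = minimal_image_offsets(x[:, None] - protocol.centre[0], n)
    dy = minimal_image_offsets(x[None, :] - protocol.centre[1], n)
    r2 = dx**2 + dy**2
    return protocol.w_s * np.exp(-r2 / (2.0 * protocol.sigma_s**2))


def external_input(
    coord: tuple[int, int],
    t_ms: float,
    protocol: StimulusProtocol,
    geometry: LatticeGeometry,
) -> float:
    """External current (nA) at a gridpoint and time.

    Background ``i_background`` at all times; after ``t_onset_ms`` the
    localized Gaussian term is added (Heaviside gate, exactly zero before
    onset).
    """
    if t_ms < 0:
        raise ValueError("t_ms must be non-negative")
    i = protocol.i_background
    if t_ms >= protocol.t_onset_ms and protocol.w_s > 0:
        d2 = minimal_image_distance(np.array(coord), np.array(protocol.centre), geometry.n) ** 2
        i = i + protocol.w_s * float(np.exp(-d2 / (2.0 * protocol.sigma_s**2)))
    return float(i)


def roi_mask(geometry: LatticeGeometry, protocol: StimulusProtocol) -> np.ndarray:
    """Boolean (n, n) mask of the RoI disc (radius ``roi_radius`` gridpoints)."""
    n = geometry.n
    x = np.arange(n)
    dx = minimal_image_offsets(x[:, None] - protocol.centre[0], n)
    dy = minimal_image_offsets(x[None, :] - protocol.centre[1], n)
    return dx**2 + dy**2 <= protocol.roi_radius**2


def with_updates(obj, **kw):
    """Return a copy of a frozen parameter dataclass with fields replaced."""
    valid = {f.name for f in fields(obj)}
    unknown = set(kw) - valid
    if unknown:
        raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
    return replace(obj, **kw)
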