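"""Plug-and-play ADMM video reconstruction from one coded snapshot.

The inverse problem min_x 1/2 ||y - Phi x||^2 + lambda R(x) is solved by
ADMM with the regularisation proximal step replaced by a denoiser
("plug-and-play prior").  Because Phi Phi^T is diagonal for coded
snapshot acquisition, the quadratic x-subproblem has a closed form that
costs one forward and one adjoint application per iteration:

    x <- z + Phi^T[(y - Phi z) / (R + rho)],   z = theta - u / rho

followed by theta <- D_sigma(x + u / rho) and u <- u + rho (x - theta).

The denoiser cascade defaults to classical total variation; learned
frame and video denoisers can be registered through the plugin contract
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from cofi.encoding import MaskStack, SensingOperator, Snapshot
from cofi.errors import (
    NumericalFailureError,
    PluginError,
    ShapeError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Total-variation denoiser (Chambolle dual projection, fixed iteration count)
# ---------------------------------------------------------------------------


def _grad(u: np.ndarray) -> np.ndarray:
    """Forward differences along each axis, zero at the far boundary."""
    g = np.zeros((u.ndim, *u.shape), dtype=u.dtype)
    for ax in range(u.ndim):
        sl = [slice(None)] * u.ndim
        sl[ax] = slice(0, -1)
        g[ax][tuple(sl)] = np.diff(u, axis=ax)
    return g


def _div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad (discrete divergence).

    The dual field's last slot along each axis is always zero (the
    forward gradient is zero there), so backward differences with a zero
    prepad implement the correct boundary terms.
    """
    out = np.zeros(p.shape[1:], dtype=p.dtype)
    for ax in range(p.shape[0]):
        out += np.diff(p[ax], axis=ax, prepend=0.0)
    return out


def tv_denoise(arr: np.ndarray, strength: float, n_iter: int = 30,
               step: float = 0.25) -> np.ndarray:
    """Isotropic TV proximal operator: argmin_u 1/2||u - arr||^2 + strength * TV(u).

    Solved by Chambolle's dual projection scheme with a fixed iteration
    count for determinism.  Works for 2-D frames and 3-D cubes alike
    (3-D couples the temporal axis into the gradient norm).  strength 0
    returns the input unchanged.
    """
    if strength < 0:
        raise ValidationError("strength must be >= 0")
    arr = np.asarray(arr, dtype=np.float64)
    if strength == 0:
        return arr.copy()
    p = np.zeros((arr.ndim, *arr.shape))
    for _ in range(n_iter):
        g = _grad(_div(p) - arr / strength)
        norm = np.sqrt(np.sum(g * g, axis=0, keepdims=True))
        p = (p + step * g) / (1.0 + step * norm)
    return arr - strength * _div(p)


# ---------------------------------------------------------------------------
# Denoiser cascade
# ---------------------------------------------------------------------------


@dataclass
class DenoiserSpec:
    """One stage of the denoiser cascade.

    ``kind`` is ``tv2d`` (frame-wise TV), ``tv3d`` (spatiotemporal TV on
    the cube) or ``plugin``.  A plugin is a callable (array, sigma) ->
    array of the same shape; ``scope`` decides whether it sees single
    frames or the full cube.  ``strength_scale`` maps the schedule noise
    level sigma to the TV weight (weight = strength_scale * sigma).
    """

    kind: str = "tv2d"
    strength_scale: float = 0.5
    fn: Callable[[np.ndarray, float], np.ndarray] | None = None
    scope: str = "video"  # for plugins: "frame" or "video"
    name: str | None = None
    tv_iters: int = 30
    tv_step: float = 0.25

    def __post_init__(self):
        if self.kind not in ("tv2d", "tv3d", "plugin"):
            raise ValidationError(f"unknown denoiser kind {self.kind!r}")
        if self.kind == "plugin":
            if self.fn is None:
                raise ValidationError("plugin denoiser requires fn")
            if self.scope not in ("frame", "video"):
                raise ValidationError("plugin scope must be 'frame' or 'video'")
            self._registration_check()
        if self.name is None:
            self.name = self.kind

    def _registration_check(self):
        """A denoiser must return a constant input unchanged (rel tol 1e-6)."""
        shape = (4, 4) if self.scope == "frame" else (2, 4, 4)
        const = np.full(shape, 3.7)
        out = np.asarray(self.fn(const, 0.1))
        if out.shape != const.shape:
            raise PluginError(
                f"plugin {self.name or 'denoiser'} returned shape {out.shape} "
                f"for input {const.shape}")
        if np.max(np.abs(out - const)) > 1e-6 * 3.7:
            raise PluginError(
                "plugin denoiser does not preserve constant inputs")

    def apply(self, cube: np.ndarray, sigma: float) -> np.ndarray:
        if self.kind == "tv2d":
            w = self.strength_scale * sigma
            return np.stack([tv_denoise(f, w, self.tv_iters, self.tv_step)
                             for f in cube])
        if self.kind == "tv3d":
            w = self.strength_scale * sigma
            return tv_denoise(cube, w, self.tv_iters, self.tv_step)
        # plugin
        if self.scope == "frame":
            out = np.stack([np.asarray(self.fn(f, sigma)) for f in cube])
        else:
            out = np.asarray(self.fn(cube, sigma))
        if out.shape != cube.shape:
            raise PluginError(
                f"plugin stage {self.name!r} returned shape {out.shape}, "
                f"expected {cube.shape}")
        return out


def identity_denoiser(scope: str = "video") -> DenoiserSpec:
    """Plugin stage that passes data through untouched."""
    return DenoiserSpec(kind="plugin", fn=lambda a, s: a, scope=scope,
                        name="identity")


# ---------------------------------------------------------------------------
# Solver configuration and state
# ---------------------------------------------------------------------------


@dataclass
class SolverConfig:
    """PnP-ADMM settings.

    ``sigma_schedule`` is a non-increasing ladder of (sigma, iterations)
    stages; sigma values are fractions of the dynamic range of the
    initialisation when ``sigma_relative`` is true (the default), or
    absolute counts otherwise.  ``rho`` is the ADMM penalty; the
    regularisation weight is absorbed into sigma via each stage's
    ``strength_scale``.
    """

    rho: float = 1.0
    sigma_schedule: tuple = ((0.10, 20), (0.05, 20), (0.02, 20))
    sigma_relative: bool = True
    tol_primal: float = 1e-6
    denoiser_cascade: tuple = (DenoiserSpec(kind="tv2d"),)
    nonneg: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rho <= 0:
            raise ValidationError("rho must be positive")
        sigmas = [s for s, _ in self.sigma_schedule]
        if any(s < 0 for s in sigmas):
            raise ValidationError("sigma values must be nonnegative")
        if any(b > a + 1e-12 for a, b in zip(sigmas, sigmas[1:])):
            raise ValidationError("sigma_schedule must be non-increasing")
        if any(it < 1 for _, it in self.sigma_schedule):
            raise ValidationError("each sigma stage needs >= 1 iteration")
        if len(self.denoiser_cascade) == 0:
            raise ValidationError("denoiser_cascade must be non-empty")

    @property
    def max_iters(self) -> int:
        return sum(it for _, it in self.sigma_schedule)


@dataclass
class SolverState:
    """ADMM iterates and residual history."""

    x: np.ndarray
    theta: np.ndarray
    u: np.ndarray
    k: int = 0
    residual_history: list = field(default_factory=list)  # (data, primal)

    def summary(self) -> str:
        lines = ["iter  data_residual   primal_residual"]
        for i, (d, p) in enumerate(self.residual_history, start=1):
            lines.append(f"{i:4d}  {d:13.6e}  {p:14.6e}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ADMM updates
# ---------------------------------------------------------------------------


def x_update(theta: np.ndarray, u: np.ndarray, snapshot_image: np.ndarray,
             op: SensingOperator, rho: float) -> np.ndarray:
    """Closed-form minimiser of 1/2||y - Phi x||^2 + rho/2 ||x - z||^2.

    With the scaled-dual target z = theta - u/rho, the diagonal
    Phi Phi^T = diag(R) gives x = z + Phi^T[(y - Phi z) / (R + rho)] by
    the Woodbury identity.
    """
    if rho <= 0:
        raise ValidationError("rho must be positive")
    if theta.shape != op.masks.codes.shape:
        raise ShapeError(
            f"theta shape {theta.shape} does not match masks "
            f"{op.masks.codes.shape}")
    z = theta - u / rho
    resid = snapshot_image - op.forward(z)
    return z + op.adjoint(resid / (op.R + rho))


def theta_update(x: np.ndarray, u: np.ndarray, rho: float,
                 cascade: Sequence[DenoiserSpec], sigma: float) -> np.ndarray:
    """Apply the denoiser cascade to x + u/rho at noise level sigma."""
    if len(cascade) == 0:
        raise ValidationError("denoiser cascade must be non-empty")
    out = x + u / rho
    for stage in cascade:
        out = stage.apply(out, sigma)
    return out


def u_update(u: np.ndarray, x: np.ndarray, theta: np.ndarray,
             rho: float) -> np.ndarray:
    """Dual ascent: u <- u + rho (x - theta)."""
    return u + rho * (x - theta)


def run_pnp_admm(
    snapshot: Snapshot,
    masks: MaskStack,
    config: SolverConfig | None = None,
    callback: Callable[[SolverState], None] | None = None,
) -> tuple[np.ndarray, SolverState]:
    """Recover the T-frame cube from one snapshot by plug-and-play ADMM.

    Iterates x_update -> theta_update -> u_update through the sigma
    ladder, stopping at the iteration budget or when the relative primal
    residual ||x - theta|| / ||theta|| drops below ``tol_primal``.
    Returns the final theta (the denoised, prior-consistent iterate) and
    the full solver state.  Deterministic given inputs and config.
    """
    if config is None:
        config = SolverConfig()
    op = SensingOperator(masks)
    y = snapshot.image
    if y.shape != masks.grid:
        raise ShapeError(
            f"snapshot {y.shape} does not match mask grid {masks.grid}")

    # mask-normalised backprojection: scale-correct and parameter-free
    x = op.adjoint(y / np.maximum(op.R, 1.0))
    theta = x.copy()
    u = np.zeros_like(x)
    state = SolverState(x=x, theta=theta, u=u)

    dyn = float(np.ptp(x))
    if dyn == 0:
        dyn = 1.0
    rho = config.rho

    for sigma_val, n_it in config.sigma_schedule:
        sigma = sigma_val * dyn if config.sigma_relative else sigma_val
        for _ in range(n_it):
            x = x_update(theta, u, y, op, rho)
            theta = theta_update(x, u, rho, config.denoiser_cascade, sigma)
            if config.nonneg:
                theta = np.clip(theta, 0.0, None)
            u = u_update(u, x, theta, rho)
            state.k += 1
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(theta))):
                raise NumericalFailureError(
                    f"non-finite iterate at iteration {state.k}",
                    iteration=state.k)
            data_res = float(np.linalg.norm(y - op.forward(x)))
            primal = float(np.linalg.norm(x - theta))
            state.residual_history.append((data_res, primal))
            state.x, state.theta, state.u = x, theta, u
            if callback is not None:
                callback(state)
            denom = float(np.linalg.norm(theta))
            if denom > 0 and primal / denom < config.tol_primal:
                return np.clip(theta, 0.0, None), state
    return np.clip(theta, 0.0, None), state


# ---------------------------------------------------------------------------
# Pixel super-resolution stage
# ---------------------------------------------------------------------------


def apply_psr(cube: np.ndarray, factor: int,
              plugin: Callable[[np.ndarray, int], np.ndarray] | None = None
              ) -> np.ndarray:
    """Upsample each frame by the pixel-super-resolution factor.

    The default path is separable cubic interpolation on the pixel-centre
    grid with per-frame mean flux preserved; a registered plugin (e.g. a
    trained super-resolver with the same (frame, factor) -> frame
    contract) replaces it.  The output pixel pitch is the input pitch
    divided by ``factor``.
    """
    if factor not in (1, 2, 4):
        raise ValidationError("PSR factor must be 1, 2 or 4")
    cube = np.asarray(cube, dtype=np.float64)
    squeeze = cube.ndim == 2
    if squeeze:
        cube = cube[np.newaxis]
    if factor == 1 and plugin is None:
        out = cube.copy()
        return out[0] if squeeze else out
    from scipy import ndimage

    frames = []
    H, W = cube.shape[1:]
    for f in cube:
        if plugin is not None:
            up = np.asarray(plugin(f, factor))
            if up.shape != (H * factor, W * factor):
                raise PluginError(
                    f"PSR plugin returned shape {up.shape}, expected "
                    f"{(H * factor, W * factor)}")
        else:
            up = ndimage.zoom(f, factor, order=3, mode="nearest",
                              grid_mode=True)
        up = np.clip(up, 0.0, None)
        mean_in = f.mean()
        mean_out = up.mean()
        if mean_out != 0:
            up = up * (mean_in / mean_out)
        frames.append(up)
    out = np.stack(frames)
    return out[0] if squeeze else out
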