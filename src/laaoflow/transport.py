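"""Passive "old blood" tracer: advection, residual fraction, washout half-time.

The tracer concentration c (1 = blood present at evaluation start, 0 = fresh
blood) is advected conservatively on the staggered face velocities with a
MUSCL/minmod-limited upwind flux, so the update is monotone (no new extrema)
and globally conservative to round-off.  Inlet faces inject c = 0; the outlet
carries the upstream value out; walls carry no flux.  There is no molecular
diffusion term — numerical diffusion is bounded by the limiter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import (FACE_INLET0, FACE_INTERIOR, FACE_OUTLET, FLUID, SEALED,
                      ConfigurationError, DomainGrid)
from .hemo import MM, FlowState


class TransportError(RuntimeError):
    pass


@dataclass
class TracerField:
    """Concentration per cell in [0, 1] at time ``t`` (defined on fluid and
    sealed cells; elsewhere 0)."""

    c: np.ndarray
    t: float = 0.0


def init_tracer(grid: DomainGrid, value: float = 1.0, t: float = 0.0) -> TracerField:
    c = np.zeros(grid.shape)
    c[(grid.cell_class == FLUID) | (grid.cell_class == SEALED)] = value
    return TracerField(c=c, t=t)


def _minmod(a, b):
    s = np.sign(a)
    return np.where(np.sign(b) == s, s * np.minimum(np.abs(a), np.abs(b)), 0.0)


def advect(tracer: TracerField, state: FlowState, grid: DomainGrid,
           dt: float, max_cfl: float = 0.45) -> TracerField:
    """Advance the tracer by ``dt`` on the (discretely divergence-free) flow.

    Sub-steps internally to keep the advective CFL below ``max_cfl``.
    """
    h = grid.spacing * MM
    umax = max((float(np.max(np.abs(state.comps[a]))) for a in range(3)), default=0.0)
    nsub = max(1, int(math.ceil(umax * dt / (h * max_cfl))))
    if nsub > 512:
        raise TransportError(f"tracer CFL requires >512 substeps (umax={umax:.2f})")
    c = tracer.c.copy()
    fluid = grid.fluid_mask
    faces = grid.face_classes()
    V = h ** 3
    A = h ** 2
    sub = dt / nsub
    for _ in range(nsub):
        dc = np.zeros_like(c)
        for a in range(3):
            if grid.shape[a] == 1:
                continue
            ft, low_fluid = faces[a]
            U = state.comps[a]
            flux_open = (ft == FACE_INTERIOR) | (ft == FACE_OUTLET) \
                | ((ft >= FACE_INLET0) & (ft < FACE_INLET0 + 4))
            # donor state with limited (minmod) reconstruction
            c_lo = _shift_cell_to_face(c, a, 0)      # cell i-1 at face i
            c_hi = _shift_cell_to_face(c, a, 1)      # cell i
            c_lolo = _shift_cell_to_face(c, a, -1)   # cell i-2
            c_hihi = _shift_cell_to_face(c, a, 2)    # cell i+1
            up_pos = c_lo + 0.5 * _minmod(c_lo - c_lolo, c_hi - c_lo)
            up_neg = c_hi - 0.5 * _minmod(c_hi - c_lo, c_hihi - c_hi)
            cf = np.where(U > 0, up_pos, up_neg)
            # inlet faces inject fresh blood
            inlet = (ft >= FACE_INLET0) & (ft < FACE_INLET0 + 4)
            if inlet.any():
                # incoming flow (from the cap into the fluid) carries c = 0
                into_fluid = np.where(low_fluid, U < 0, U > 0)
                cf = np.where(inlet & into_fluid, 0.0, cf)
            q = np.where(flux_open, U, 0.0) * A * cf   # tracer flux, +a direction
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[a] = slice(0, -1)   # face i of cell i
            hi[a] = slice(1, None)  # face i+1 of cell i
            dc += (q[tuple(lo)] - q[tuple(hi)]) * (sub / V)
        c = c + dc
        c[~fluid & (grid.cell_class != SEALED)] = 0.0
    return TracerField(c=c, t=tracer.t + dt)


def _shift_cell_to_face(c: np.ndarray, a: int, which: int) -> np.ndarray:
    """Cell value seen from face i along axis a.

    which = 0 -> cell i-1, 1 -> cell i, -1 -> cell i-2, 2 -> cell i+1;
    out-of-range cells read 0.
    """
    shape = list(c.shape)
    shape[a] += 1
    out = np.zeros(shape)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if which == 0:
        dst[a] = slice(1, None)
        src[a] = slice(None)
    elif which == 1:
        dst[a] = slice(0, -1)
        src[a] = slice(None)
    elif which == -1:
        dst[a] = slice(2, None)
        src[a] = slice(0, -1)
    elif which == 2:
        dst[a] = slice(0, -2)
        src[a] = slice(1, None)
    else:
        raise ValueError(which)
    out[tuple(dst)] = c[tuple(src)]
    return out


def residual_fraction(c: np.ndarray, roi_mask: np.ndarray,
                      cell_volume: float = 1.0) -> float:
    """phi = sum_ROI c*V / sum_ROI V (concentration-weighted old-blood volume)."""
    n = int(np.count_nonzero(roi_mask))
    if n == 0:
        raise ConfigurationError("empty ROI")
    return float(np.sum(c[roi_mask])) / n


@dataclass
class WashoutCurve:
    """phi(t) sampled from the evaluation start (phi(0) = 1)."""

    times: np.ndarray
    phi: np.ndarray

    @property
    def phi_final(self) -> float:
        return float(self.phi[-1])


def washout_halftime(times, phi, level: float = 0.5):
    """First crossing of ``level`` by linear interpolation.

    Returns ``(t_half, censored, multicross)``; ``t_half`` is None (censored)
    when phi never reaches the level within the sampled window.  If phi
    recrosses the level later the first crossing is used and flagged.
    """
    times = np.asarray(times, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if times.shape != phi.shape or times.size < 2:
        raise ValueError("need matched time/phi samples (>= 2)")
    below = phi <= level
    if not below.any():
        return None, True, False
    i = int(np.argmax(below))
    if i == 0:
        t_half = float(times[0])
    else:
        t0, t1 = times[i - 1], times[i]
        p0, p1 = phi[i - 1], phi[i]
        t_half = float(t0 + (p0 - level) / (p0 - p1) * (t1 - t0))
    multicross = bool(np.any(phi[i:] > level))
    return t_half - float(times[0]), False, multicross
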