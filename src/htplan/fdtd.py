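"""Finite-difference time-domain solver for phased-array hyperthermia.

Computes steady-state complex E-field phasors at the applicator drive
frequency (default 100 MHz) for each antenna channel of a ring applicator
surrounding the phantom, with a water bolus coupling the sources to the
body and a convolutional PML (CPML) absorbing the open boundary.

Two solver paths share one infrastructure:

* a 2D transverse-magnetic (TMz) solver — twelve line sources on a ring
  around the phantom's axial slice through the target.  This is the fast
  path all automated experiments run on;
* a coarse 3D Yee solver — three axial rings of four short-dipole soft
  sources (a generic stand-in for clinical multi-ring applicators).

Each channel is driven individually at unit amplitude and zero phase for a
fixed number of periods of the harmonic signal (default 15, after which the
field is in steady state); the per-voxel complex phasor is extracted by
single-frequency discrete Fourier projection over exactly the final period.
Instantaneous field = Re{E e^{jωt}}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phantom import VoxelPhantom, CODE_LABELS, LABEL_CODES
from .tissues import PropertyTable, SegmentationScheme

__all__ = [
    "ApplicatorModel",
    "SolverSettings",
    "MaterialGrids",
    "ChannelFieldSet",
    "SolverError",
    "assign_material_grids",
    "solve_channel",
    "solve_all_channels",
    "solve_simultaneous",
    "save_fieldset",
    "load_fieldset",
]

C0 = 299_792_458.0
MU0 = 4e-7 * np.pi
EPS0 = 8.8541878128e-12
ETA0 = math.sqrt(MU0 / EPS0)

try:  # optional kernel acceleration; the numpy path is the reference
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn

        return deco

AIR = (1.0, 0.0, 1.2)  # eps_r, sigma, rho of the exterior


class SolverError(RuntimeError):
    """Numerical failure of the time-domain solve."""


@dataclass(frozen=True)
class ApplicatorModel:
    """Ring applicator geometry around the phantom.

    2D mode places ``n_channels`` line sources equally spaced on a ring of
    ``ring_radius_mm``; 3D mode places three axial rings of four short
    dipoles (z-oriented, 3 cells long) at ``ring_z_offsets_mm`` from the
    target slice.  The water bolus fills the bore out to the shell.
    """

    frequency_hz: float = 1.0e8
    n_channels: int = 12
    ring_radius_mm: float = 260.0
    shell_inner_radius_mm: float = 280.0
    shell_thickness_mm: float = 10.0
    air_margin_mm: float = 40.0
    ring_z_offsets_mm: tuple[float, ...] = (-90.0, 0.0, 90.0)
    bolus_half_length_mm: float = 200.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.ring_radius_mm >= self.shell_inner_radius_mm:
            raise ValueError("sources must lie inside the bolus")

    def channel_angles(self) -> np.ndarray:
        """Equally spaced source azimuths, channel 0 anterior."""
        n = self.n_channels
        return -np.pi / 2 + 2 * np.pi * np.arange(n) / n

    def channel_cells_2d(self, center_ij: tuple[int, int], spacing: float):
        """(i, j) source cell per channel, rounded symmetrically."""
        ci, cj = center_ij
        cells = []
        for th in self.channel_angles():
            di = int(np.round(self.ring_radius_mm * np.cos(th) / spacing))
            dj = int(np.round(self.ring_radius_mm * np.sin(th) / spacing))
            cells.append((ci + di, cj + dj))
        return cells

    def channel_cells_3d(
        self, center_ijk: tuple[int, int, int], spacing: float
    ) -> list[list[tuple[int, int, int]]]:
        """Cells (3 axially stacked) of each dipole channel.

        Channels are ordered ring-major: ring 0 holds channels 0..3, etc.
        If ``n_channels`` is not a multiple of four the last ring is
        partial.
        """
        ci, cj, ck = center_ijk
        n_rings = len(self.ring_z_offsets_mm)
        per_ring = 4
        cells: list[list[tuple[int, int, int]]] = []
        for ch in range(self.n_channels):
            ring = min(ch // per_ring, n_rings - 1)
            ang = -np.pi / 2 + 2 * np.pi * (ch % per_ring) / per_ring
            di = int(np.round(self.ring_radius_mm * np.cos(ang) / spacing))
            dj = int(np.round(self.ring_radius_mm * np.sin(ang) / spacing))
            dk = int(np.round(self.ring_z_offsets_mm[ring] / spacing))
            cells.append(
                [(ci + di, cj + dj, ck + dk + o) for o in (-1, 0, 1)]
            )
        return cells


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the time-domain solve.

    ``periods`` harmonic periods are simulated (the last one is used for
    phasor extraction); the source amplitude ramps up smoothly over
    ``ramp_periods`` to suppress transient ringing.  The time step is
    ``courant`` × the 2D/3D Courant limit of the grid.
    """

    mode: str = "2d"
    periods: int = 15
    pml_cells: int = 8
    courant: float = 0.95
    ramp_periods: float = 3.0
    spacing_mm: float | None = None  # None: use the phantom's spacing


@dataclass
class MaterialGrids:
    """Per-cell (eps_r, sigma, rho) over the full solver domain.

    The phantom is embedded centered; ``labels`` carries its (scheme-
    reduced) label codes over the domain (0 outside the body), so dosimetry
    masks can be cut from the same grid the fields live on.
    """

    eps_r: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    labels: np.ndarray
    spacing_mm: float
    center: tuple[int, ...]
    detailed_labels: np.ndarray | None = None
    gtv_mask: np.ndarray | None = None
    htv_mask: np.ndarray | None = None

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.eps_r.shape


@dataclass
class ChannelFieldSet:
    """Per-channel steady-state complex E-field grids (V/m phasors).

    ``fields`` has shape (n_channels, *grid, n_components): one component
    (Ez) in 2D TMz mode, three in 3D.  ``drive_amplitude`` records the
    reference unit drive each channel was solved with.
    """

    fields: np.ndarray
    spacing_mm: float
    frequency_hz: float
    mode: str
    drive_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fields)):
            raise SolverError("non-finite values in channel fields")

    @property
    def n_channels(self) -> int:
        return self.fields.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.fields.shape[1:-1]

    def validate_against(self, materials: MaterialGrids) -> None:
        if self.grid_shape != materials.shape:
            raise ValueError(
                f"field grid {self.grid_shape} != material grid {materials.shape}"
            )


def _resolve_cell_props(
    labels: np.ndarray,
    scheme: SegmentationScheme,
    table: PropertyTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """LUT label codes -> (eps, sigma, rho) through scheme then table."""
    n_codes = int(labels.max()) + 1 if labels.size else 1
    lut_eps = np.full(max(n_codes, 1), AIR[0])
    lut_sig = np.full(max(n_codes, 1), AIR[1])
    lut_rho = np.full(max(n_codes, 1), AIR[2])
    reduced_code = np.zeros(max(n_codes, 1), dtype=np.int16)
    for code in np.unique(labels):
        if code == 0:
            continue
        lab = CODE_LABELS[int(code)]
        retained = scheme.apply(lab)
        props = table.resolve(retained)
        lut_eps[code] = props.eps_r
        lut_sig[code] = props.sigma_eff
        lut_rho[code] = props.rho
        reduced_code[code] = LABEL_CODES[retained]
    return lut_eps[labels], lut_sig[labels], lut_rho[labels], reduced_code[labels]


def assign_material_grids(
    phantom: VoxelPhantom,
    scheme: SegmentationScheme,
    table: PropertyTable,
    applicator: ApplicatorModel,
    settings: SolverSettings,
    slice_index: int | None = None,
) -> MaterialGrids:
    """Embed the (scheme-reduced) phantom in the applicator domain.

    Voxels outside the phantom but inside the shell get water-bolus
    properties, the shell gets the applicator-casing properties, and the
    exterior (including the PML region) is free space.
    """
    s = settings.spacing_mm or phantom.spacing_mm
    if abs(s - phantom.spacing_mm) > 1e-9:
        raise ValueError("resampling is not supported; match phantom spacing")
    r_shell_in = applicator.shell_inner_radius_mm
    r_shell_out = r_shell_in + applicator.shell_thickness_mm
    r_out = r_shell_out + applicator.air_margin_mm
    n_half = int(np.ceil(r_out / s)) + settings.pml_cells
    n = 2 * n_half + 1  # odd: one cell center exactly on the bore axis

    water = table.resolve("water")
    shell = table.resolve("applicator_shell")

    if settings.mode == "2d":
        k = phantom.axial_slice_index() if slice_index is None else slice_index
        sl = phantom.labels[:, :, k]
        gtv_sl = phantom.gtv_mask[:, :, k]
        htv_sl = phantom.htv_mask[:, :, k]
        if not gtv_sl.any():
            raise ValueError("selected slice does not intersect the GTV")

        coords = (np.arange(n) - n_half) * s
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        rr = np.hypot(xx, yy)
        eps = np.full((n, n), AIR[0])
        sig = np.full((n, n), AIR[1])
        rho = np.full((n, n), AIR[2])
        in_shell = rr < r_shell_out
        eps[in_shell], sig[in_shell], rho[in_shell] = (
            shell.eps_r, shell.sigma_eff, shell.rho,
        )
        in_bolus = rr < r_shell_in
        eps[in_bolus], sig[in_bolus], rho[in_bolus] = (
            water.eps_r, water.sigma_eff, water.rho,
        )

        pe, ps, pr, reduced = _resolve_cell_props(sl, scheme, table)
        pnx, pny = sl.shape
        oi, oj = n_half - pnx // 2, n_half - pny // 2
        region = (slice(oi, oi + pnx), slice(oj, oj + pny))
        body = sl > 0
        for dom, ph in ((eps, pe), (sig, ps), (rho, pr)):
            dom[region][body] = ph[body]
        labels = np.zeros((n, n), dtype=np.int16)
        labels[region][body] = reduced[body]
        detailed = np.zeros((n, n), dtype=np.int16)
        detailed[region][body] = sl[body]
        gtv = np.zeros((n, n), dtype=bool)
        gtv[region] = gtv_sl
        htv = np.zeros((n, n), dtype=bool)
        htv[region] = htv_sl
        return MaterialGrids(
            eps, sig, rho, labels, s, (n_half, n_half),
            detailed_labels=detailed, gtv_mask=gtv, htv_mask=htv,
        )

    if settings.mode != "3d":
        raise ValueError(f"unknown solver mode {settings.mode!r}")

    pnx, pny, pnz = phantom.shape
    zs = np.nonzero(phantom.gtv_mask)[2]
    k_target = int(np.round(zs.mean()))
    z_margin = int(np.ceil((applicator.air_margin_mm) / s)) + settings.pml_cells
    nz = pnz + 2 * z_margin
    kc = k_target + z_margin

    coords = (np.arange(n) - n_half) * s
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(xx, yy)
    zc = (np.arange(nz) - kc) * s
    eps = np.full((n, n, nz), AIR[0])
    sig = np.full((n, n, nz), AIR[1])
    rho = np.full((n, n, nz), AIR[2])
    in_z = np.abs(zc) <= applicator.bolus_half_length_mm
    in_shell = (rr < r_shell_out)[:, :, None] & in_z[None, None, :]
    in_bolus = (rr < r_shell_in)[:, :, None] & in_z[None, None, :]
    eps[in_shell], sig[in_shell], rho[in_shell] = (
        shell.eps_r, shell.sigma_eff, shell.rho,
    )
    eps[in_bolus], sig[in_bolus], rho[in_bolus] = (
        water.eps_r, water.sigma_eff, water.rho,
    )

    pe, ps, pr, reduced = _resolve_cell_props(phantom.labels, scheme, table)
    oi, oj, ok = n_half - pnx // 2, n_half - pny // 2, z_margin
    region = (slice(oi, oi + pnx), slice(oj, oj + pny), slice(ok, ok + pnz))
    body = phantom.labels > 0
    for dom, ph in ((eps, pe), (sig, ps), (rho, pr)):
        dom[region][body] = ph[body]
    labels = np.zeros((n, n, nz), dtype=np.int16)
    labels[region][body] = reduced[body]
    detailed = np.zeros((n, n, nz), dtype=np.int16)
    detailed[region][body] = phantom.labels[body]
    gtv = np.zeros((n, n, nz), dtype=bool)
    gtv[region] = phantom.gtv_mask
    htv = np.zeros((n, n, nz), dtype=bool)
    htv[region] = phantom.htv_mask
    return MaterialGrids(
        eps, sig, rho, labels, s, (n_half, n_half, kc),
        detailed_labels=detailed, gtv_mask=gtv, htv_mask=htv,
    )


def _cpml_profiles(
    span_cells: int, npml: int, dt: float, dx: float,
    n_points: int, offset: float,
):
    """CPML recursion coefficients (b, c) along one axis.

    Cubic-graded conductivity with sigma_max = 0.8(m+1)/(eta0 dx), linear
    alpha ramp, kappa = 1.  ``n_points`` sample positions sit at
    ``arange(n_points) + offset`` in cell units over a domain spanning
    [0, span_cells]; the PML occupies ``npml`` cells at each end.
    """
    m = 3.0
    sigma_max = 0.8 * (m + 1) / (ETA0 * dx)
    alpha_max = 0.05
    pos = np.arange(n_points) + offset
    d = np.zeros(n_points)
    left = pos < npml
    d[left] = (npml - pos[left]) / npml
    right = pos > span_cells - npml
    d[right] = (pos[right] - (span_cells - npml)) / npml
    d = np.clip(d, 0.0, 1.0)
    sig = sigma_max * d**m
    alpha = alpha_max * (1.0 - d)
    b = np.exp(-(sig + alpha) * dt / EPS0)
    c = np.where(sig > 0, sig / np.maximum(sig + alpha, 1e-300) * (b - 1.0), 0.0)
    # outside the PML the recursion is inert
    b[d == 0] = 0.0
    c[d == 0] = 0.0
    return b, c


@dataclass
class SourceTerm:
    """A soft source: cells, complex weight (amplitude & phase)."""

    cells: Sequence[tuple]
    amplitude: float = 1.0
    phase: float = 0.0


def _time_stepping(frequency: float, dx: float, settings: SolverSettings, ndim: int):
    period = 1.0 / frequency
    dt_max = settings.courant * dx / (C0 * math.sqrt(ndim))
    spp = int(math.ceil(period / dt_max))
    dt = period / spp
    return dt, spp


@_njit(cache=True)
def _kernel_2d(
    ez, hx, hy, psi_hx, psi_hy, psi_ex, psi_ey,
    ca, cb, bEx, cEx, bEy, cEy, bHx, cHx, bHy, cHy,
    src_i, src_j, src_cb, src_amp, src_phase,
    acc_re, acc_im, acc2_re, acc2_im,
    n_steps, spp, dt, omega, ramp_t, dt_over_mu, inv_dx, collect_prev,
):  # pragma: no cover - exercised through _run_2d
    n, m = ez.shape
    for step in range(1, n_steps + 1):
        t = step * dt
        for i in range(n):
            for j in range(m - 1):
                d = (ez[i, j + 1] - ez[i, j]) * inv_dx
                psi_hx[i, j] = bHy[j] * psi_hx[i, j] + cHy[j] * d
                hx[i, j] -= dt_over_mu * (d + psi_hx[i, j])
        for i in range(n - 1):
            for j in range(m):
                d = (ez[i + 1, j] - ez[i, j]) * inv_dx
                psi_hy[i, j] = bHx[i] * psi_hy[i, j] + cHx[i] * d
                hy[i, j] += dt_over_mu * (d + psi_hy[i, j])
        for i in range(1, n - 1):
            for j in range(1, m - 1):
                d_hy = (hy[i, j] - hy[i - 1, j]) * inv_dx
                p1 = bEx[i] * psi_ex[i - 1, j - 1] + cEx[i] * d_hy
                psi_ex[i - 1, j - 1] = p1
                d_hx = (hx[i, j] - hx[i, j - 1]) * inv_dx
                p2 = bEy[j] * psi_ey[i - 1, j - 1] + cEy[j] * d_hx
                psi_ey[i - 1, j - 1] = p2
                ez[i, j] = ca[i, j] * ez[i, j] + cb[i, j] * (
                    (d_hy + p1) - (d_hx + p2)
                )
        if t >= ramp_t:
            env = 1.0
        else:
            env = 0.5 * (1.0 - math.cos(math.pi * t / ramp_t))
        for k in range(src_i.shape[0]):
            ez[src_i[k], src_j[k]] += src_cb[k] * (
                src_amp[k] * env * math.sin(omega * t + src_phase[k])
            )
        if step % spp == 0:
            peak = 0.0
            for i in range(n):
                for j in range(m):
                    a = abs(ez[i, j])
                    if not math.isfinite(a) or a > 1e30:
                        return step
                    if a > peak:
                        peak = a
        if collect_prev and n_steps - 2 * spp < step <= n_steps - spp:
            c = math.cos(omega * t)
            s = math.sin(omega * t)
            for i in range(n):
                for j in range(m):
                    acc2_re[i, j] += ez[i, j] * c
                    acc2_im[i, j] -= ez[i, j] * s
        if step > n_steps - spp:
            c = math.cos(omega * t)
            s = math.sin(omega * t)
            for i in range(n):
                for j in range(m):
                    acc_re[i, j] += ez[i, j] * c
                    acc_im[i, j] -= ez[i, j] * s
    return 0


def _run_2d(
    materials: MaterialGrids,
    sources: Sequence[SourceTerm],
    frequency: float,
    settings: SolverSettings,
    collect_penultimate: bool = False,
):
    """Time-step the TMz system and return the Ez phasor grid."""
    n, m = materials.shape
    dx = materials.spacing_mm * 1e-3
    dt, spp = _time_stepping(frequency, dx, settings, ndim=2)
    n_steps = settings.periods * spp
    omega = 2 * np.pi * frequency

    eps = materials.eps_r * EPS0
    sig = materials.sigma
    ca = (1 - sig * dt / (2 * eps)) / (1 + sig * dt / (2 * eps))
    cb = (dt / eps) / (1 + sig * dt / (2 * eps))

    ez = np.zeros((n, m))
    hx = np.zeros((n, m - 1))
    hy = np.zeros((n - 1, m))
    psi_hx = np.zeros_like(hx)
    psi_hy = np.zeros_like(hy)
    psi_ex = np.zeros((n - 2, m - 2))
    psi_ey = np.zeros((n - 2, m - 2))

    npml = settings.pml_cells
    be_x, ce_x = _cpml_profiles(n, npml, dt, dx, n, 0.5)
    be_y, ce_y = _cpml_profiles(m, npml, dt, dx, m, 0.5)
    bh_x, ch_x = _cpml_profiles(n, npml, dt, dx, n - 1, 1.0)
    bh_y, ch_y = _cpml_profiles(m, npml, dt, dx, m - 1, 1.0)

    ramp_t = settings.ramp_periods / frequency
    # soft-source injection uses the local update coefficient
    live = [s for s in sources if s.amplitude != 0.0 and s.cells]
    src_i = np.array([c[0] for s in live for c in s.cells], dtype=np.int64)
    src_j = np.array([c[1] for s in live for c in s.cells], dtype=np.int64)
    src_amp = np.array([s.amplitude for s in live for _ in s.cells])
    src_phase = np.array([s.phase for s in live for _ in s.cells])
    src_cb = cb[src_i, src_j] / dx if src_i.size else np.zeros(0)

    acc_re = np.zeros((n, m))
    acc_im = np.zeros((n, m))
    acc2_re = np.zeros((n, m))
    acc2_im = np.zeros((n, m))
    dt_over_mu = dt / MU0
    inv_dx = 1.0 / dx

    if HAVE_NUMBA:
        status = _kernel_2d(
            ez, hx, hy, psi_hx, psi_hy, psi_ex, psi_ey,
            ca, cb, be_x, ce_x, be_y, ce_y, bh_x, ch_x, bh_y, ch_y,
            src_i, src_j, src_cb, src_amp, src_phase,
            acc_re, acc_im, acc2_re, acc2_im,
            n_steps, spp, dt, omega, ramp_t, dt_over_mu, inv_dx,
            collect_penultimate,
        )
        if status != 0:
            raise SolverError(
                f"field divergence detected at step {status}; "
                f"time step dt={dt:.3e} s may violate stability"
            )
    else:
        bh_xb = bh_x[:, None]; ch_xb = ch_x[:, None]
        bh_yb = bh_y[None, :]; ch_yb = ch_y[None, :]
        be_xb = be_x[1:-1, None]; ce_xb = ce_x[1:-1, None]
        be_yb = be_y[None, 1:-1]; ce_yb = ce_y[None, 1:-1]
        for step in range(1, n_steps + 1):
            t = step * dt
            d_ey = (ez[:, 1:] - ez[:, :-1]) * inv_dx
            psi_hx *= bh_yb
            psi_hx += ch_yb * d_ey
            hx -= dt_over_mu * (d_ey + psi_hx)
            d_ex = (ez[1:, :] - ez[:-1, :]) * inv_dx
            psi_hy *= bh_xb
            psi_hy += ch_xb * d_ex
            hy += dt_over_mu * (d_ex + psi_hy)

            # E update (interior; outermost ring stays 0 behind the PML)
            d_hy = (hy[1:, 1:-1] - hy[:-1, 1:-1]) * inv_dx
            d_hx = (hx[1:-1, 1:] - hx[1:-1, :-1]) * inv_dx
            psi_ex *= be_xb
            psi_ex += ce_xb * d_hy
            psi_ey *= be_yb
            psi_ey += ce_yb * d_hx
            ez[1:-1, 1:-1] = ca[1:-1, 1:-1] * ez[1:-1, 1:-1] + cb[1:-1, 1:-1] * (
                (d_hy + psi_ex) - (d_hx + psi_ey)
            )

            env = 1.0 if t >= ramp_t else 0.5 * (1 - math.cos(math.pi * t / ramp_t))
            if src_i.size:
                ez[src_i, src_j] += src_cb * (
                    src_amp * env * np.sin(omega * t + src_phase)
                )

            if step % spp == 0:
                peak = np.abs(ez).max()
                if not np.isfinite(peak) or peak > 1e30:
                    raise SolverError(
                        f"field divergence detected (|Ez| ~ {peak:.2e}); "
                        f"time step dt={dt:.3e} s may violate stability"
                    )
            if collect_penultimate and n_steps - 2 * spp < step <= n_steps - spp:
                acc2_re += ez * np.cos(omega * t)
                acc2_im -= ez * np.sin(omega * t)
            if step > n_steps - spp:
                acc_re += ez * np.cos(omega * t)
                acc_im -= ez * np.sin(omega * t)

    phasor = 2.0 * (acc_re + 1j * acc_im) / spp
    if collect_penultimate:
        return phasor, 2.0 * (acc2_re + 1j * acc2_im) / spp
    return phasor


def _edge_average(cell_vals: np.ndarray, axis: int) -> np.ndarray:
    """Average cell-centered material values onto E-edge positions.

    The Ex edge at (i+1/2, j, k) borders the 4 cells (i, j-1:j+1, k-1:k+1);
    we pad with edge values and average over the transverse axes.
    """
    v = cell_vals
    for ax in range(3):
        if ax == axis:
            continue
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        v = np.pad(v, pad, mode="edge")
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        v = 0.5 * (v[tuple(sl_lo)] + v[tuple(sl_hi)])
    return v


def _run_3d(
    materials: MaterialGrids,
    sources: Sequence[SourceTerm],
    frequency: float,
    settings: SolverSettings,
):
    """Yee-grid 3D solve; returns cell-centered (Ex, Ey, Ez) phasors."""
    nx, ny, nz = materials.shape
    dx = materials.spacing_mm * 1e-3
    dt, spp = _time_stepping(frequency, dx, settings, ndim=3)
    n_steps = settings.periods * spp
    omega = 2 * np.pi * frequency
    inv_dx = 1.0 / dx
    dt_over_mu = dt / MU0
    npml = settings.pml_cells

    def coeffs(axis):
        eps_e = _edge_average(materials.eps_r, axis) * EPS0
        sig_e = _edge_average(materials.sigma, axis)
        ca = (1 - sig_e * dt / (2 * eps_e)) / (1 + sig_e * dt / (2 * eps_e))
        cb = (dt / eps_e) / (1 + sig_e * dt / (2 * eps_e))
        return ca, cb

    ca_x, cb_x = coeffs(0)  # shape (nx, ny+1, nz+1)
    ca_y, cb_y = coeffs(1)
    ca_z, cb_z = coeffs(2)

    ex = np.zeros((nx, ny + 1, nz + 1))
    ey = np.zeros((nx + 1, ny, nz + 1))
    ez = np.zeros((nx + 1, ny + 1, nz))
    hx = np.zeros((nx + 1, ny, nz))
    hy = np.zeros((nx, ny + 1, nz))
    hz = np.zeros((nx, ny, nz + 1))

    # CPML coefficient vectors per axis, for E (node lines) and H (staggered)
    bEx, cEx = _cpml_profiles(nx, npml, dt, dx, nx + 1, 0.0)
    bEy, cEy = _cpml_profiles(ny, npml, dt, dx, ny + 1, 0.0)
    bEz, cEz = _cpml_profiles(nz, npml, dt, dx, nz + 1, 0.0)
    bHx, cHx = _cpml_profiles(nx, npml, dt, dx, nx, 0.5)
    bHy, cHy = _cpml_profiles(ny, npml, dt, dx, ny, 0.5)
    bHz, cHz = _cpml_profiles(nz, npml, dt, dx, nz, 0.5)

    # psi accumulators: one per (field, transverse derivative axis)
    psi = {
        "hx_y": np.zeros((nx + 1, ny, nz)), "hx_z": np.zeros((nx + 1, ny, nz)),
        "hy_z": np.zeros((nx, ny + 1, nz)), "hy_x": np.zeros((nx, ny + 1, nz)),
        "hz_x": np.zeros((nx, ny, nz + 1)), "hz_y": np.zeros((nx, ny, nz + 1)),
        "ex_y": np.zeros((nx, ny - 1, nz - 1)), "ex_z": np.zeros((nx, ny - 1, nz - 1)),
        "ey_z": np.zeros((nx - 1, ny, nz - 1)), "ey_x": np.zeros((nx - 1, ny, nz - 1)),
        "ez_x": np.zeros((nx - 1, ny - 1, nz)), "ez_y": np.zeros((nx - 1, ny - 1, nz)),
    }

    ramp_t = settings.ramp_periods / frequency
    acc_x = np.zeros_like(ex, dtype=complex)
    acc_y = np.zeros_like(ey, dtype=complex)
    acc_z = np.zeros_like(ez, dtype=complex)

    for step in range(1, n_steps + 1):
        t = step * dt

        d = (ez[:, 1:, :] - ez[:, :-1, :]) * inv_dx  # dEz/dy at Hx
        psi["hx_y"] *= bHy[None, :, None]; psi["hx_y"] += cHy[None, :, None] * d
        curl = d + psi["hx_y"]
        d = (ey[:, :, 1:] - ey[:, :, :-1]) * inv_dx  # dEy/dz at Hx
        psi["hx_z"] *= bHz[None, None, :]
        psi["hx_z"] += cHz[None, None, :] * d
        hx -= dt_over_mu * (curl - (d + psi["hx_z"]))

        d = (ex[:, :, 1:] - ex[:, :, :-1]) * inv_dx  # dEx/dz at Hy
        psi["hy_z"] *= bHz[None, None, :]; psi["hy_z"] += cHz[None, None, :] * d
        curl = d + psi["hy_z"]
        d = (ez[1:, :, :] - ez[:-1, :, :]) * inv_dx  # dEz/dx at Hy
        psi["hy_x"] *= bHx[:, None, None]; psi["hy_x"] += cHx[:, None, None] * d
        hy -= dt_over_mu * (curl - (d + psi["hy_x"]))

        d = (ey[1:, :, :] - ey[:-1, :, :]) * inv_dx  # dEy/dx at Hz
        psi["hz_x"] *= bHx[:, None, None]; psi["hz_x"] += cHx[:, None, None] * d
        curl = d + psi["hz_x"]
        d = (ex[:, 1:, :] - ex[:, :-1, :]) * inv_dx  # dEx/dy at Hz
        psi["hz_y"] *= bHy[None, :, None]; psi["hz_y"] += cHy[None, :, None] * d
        hz -= dt_over_mu * (curl - (d + psi["hz_y"]))

        # Ex (interior transverse nodes)
        d = (hz[:, 1:, 1:-1] - hz[:, :-1, 1:-1]) * inv_dx
        psi["ex_y"] *= bEy[None, 1:-1, None]; psi["ex_y"] += cEy[None, 1:-1, None] * d
        curl = d + psi["ex_y"]
        d = (hy[:, 1:-1, 1:] - hy[:, 1:-1, :-1]) * inv_dx
        psi["ex_z"] *= bEz[None, None, 1:-1]; psi["ex_z"] += cEz[None, None, 1:-1] * d
        ex[:, 1:-1, 1:-1] = ca_x[:, 1:-1, 1:-1] * ex[:, 1:-1, 1:-1] + cb_x[
            :, 1:-1, 1:-1
        ] * (curl - (d + psi["ex_z"]))

        # Ey
        d = (hx[1:-1, :, 1:] - hx[1:-1, :, :-1]) * inv_dx
        psi["ey_z"] *= bEz[None, None, 1:-1]; psi["ey_z"] += cEz[None, None, 1:-1] * d
        curl = d + psi["ey_z"]
        d = (hz[1:, :, 1:-1] - hz[:-1, :, 1:-1]) * inv_dx
        psi["ey_x"] *= bEx[1:-1, None, None]; psi["ey_x"] += cEx[1:-1, None, None] * d
        ey[1:-1, :, 1:-1] = ca_y[1:-1, :, 1:-1] * ey[1:-1, :, 1:-1] + cb_y[
            1:-1, :, 1:-1
        ] * (curl - (d + psi["ey_x"]))

        # Ez
        d = (hy[1:, 1:-1, :] - hy[:-1, 1:-1, :]) * inv_dx
        psi["ez_x"] *= bEx[1:-1, None, None]; psi["ez_x"] += cEx[1:-1, None, None] * d
        curl = d + psi["ez_x"]
        d = (hx[1:-1, 1:, :] - hx[1:-1, :-1, :]) * inv_dx
        psi["ez_y"] *= bEy[None, 1:-1, None]; psi["ez_y"] += cEy[None, 1:-1, None] * d
        ez[1:-1, 1:-1, :] = ca_z[1:-1, 1:-1, :] * ez[1:-1, 1:-1, :] + cb_z[
            1:-1, 1:-1, :
        ] * (curl - (d + psi["ez_y"]))

        env = 1.0 if t >= ramp_t else 0.5 * (1 - math.cos(math.pi * t / ramp_t))
        for src in sources:
            if src.amplitude == 0.0:
                continue
            drive = src.amplitude * env * math.sin(omega * t + src.phase)
            for (i, j, k) in src.cells:
                ez[i, j, k] += cb_z[i, j, k] * drive / dx

        if step % spp == 0:
            peak = max(np.abs(ex).max(), np.abs(ey).max(), np.abs(ez).max())
            if not np.isfinite(peak) or peak > 1e30:
                raise SolverError(
                    f"field divergence detected (|E| ~ {peak:.2e}); "
                    f"time step dt={dt:.3e} s may violate stability"
                )
        if step > n_steps - spp:
            w = np.exp(-1j * omega * t)
            acc_x += ex * w
            acc_y += ey * w
            acc_z += ez * w

    fx = 2.0 * acc_x / spp
    fy = 2.0 * acc_y / spp
    fz = 2.0 * acc_z / spp
    # collocate Yee components at cell centers
    exc = 0.25 * (fx[:, :-1, :-1] + fx[:, 1:, :-1] + fx[:, :-1, 1:] + fx[:, 1:, 1:])
    eyc = 0.25 * (fy[:-1, :, :-1] + fy[1:, :, :-1] + fy[:-1, :, 1:] + fy[1:, :, 1:])
    ezc = 0.25 * (fz[:-1, :-1, :] + fz[1:, :-1, :] + fz[:-1, 1:, :] + fz[1:, 1:, :])
    return np.stack([exc, eyc, ezc], axis=-1)


def solve_channel(
    materials: MaterialGrids,
    applicator: ApplicatorModel,
    channel: int,
    settings: SolverSettings,
    amplitude: float = 1.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Unit-drive steady-state solve of one channel.

    Returns the complex E-field phasor grid with a trailing component axis
    (1 component in 2D TMz, 3 in 3D).
    """
    if not (0 <= channel < applicator.n_channels):
        raise ValueError(f"channel {channel} out of range")
    if settings.mode == "2d":
        cells = applicator.channel_cells_2d(materials.center, materials.spacing_mm)
        src = SourceTerm(cells=[cells[channel]], amplitude=amplitude, phase=phase)
        if amplitude == 0.0:
            return np.zeros((*materials.shape, 1), dtype=complex)
        phasor = _run_2d(materials, [src], applicator.frequency_hz, settings)
        return phasor[..., None]
    cells = applicator.channel_cells_3d(materials.center, materials.spacing_mm)
    src = SourceTerm(cells=cells[channel], amplitude=amplitude, phase=phase)
    if amplitude == 0.0:
        return np.zeros((*materials.shape, 3), dtype=complex)
    return _run_3d(materials, [src], applicator.frequency_hz, settings)


def solve_simultaneous(
    materials: MaterialGrids,
    applicator: ApplicatorModel,
    settings: SolverSettings,
    weights: Sequence[complex],
) -> np.ndarray:
    """Drive all channels at once with complex weights (amplitude, phase).

    Physically equivalent — and, because the update is linear, numerically
    equal — to summing the per-channel solves driven with the same
    amplitude/phase waveforms.  Used to validate superposition; production
    beamforming combines unit solves in post-processing instead.
    """
    weights = np.asarray(weights, dtype=complex)
    if len(weights) != applicator.n_channels:
        raise ValueError("one weight per channel required")
    if settings.mode == "2d":
        cells = applicator.channel_cells_2d(materials.center, materials.spacing_mm)
        sources = [
            SourceTerm([cells[ch]], float(np.abs(w)), float(np.angle(w)))
            for ch, w in enumerate(weights)
        ]
        return _run_2d(materials, sources, applicator.frequency_hz, settings)[..., None]
    cells = applicator.channel_cells_3d(materials.center, materials.spacing_mm)
    sources = [
        SourceTerm(cells[ch], float(np.abs(w)), float(np.angle(w)))
        for ch, w in enumerate(weights)
    ]
    return _run_3d(materials, sources, applicator.frequency_hz, settings)


def solve_all_channels(
    materials: MaterialGrids,
    applicator: ApplicatorModel,
    settings: SolverSettings,
) -> ChannelFieldSet:
    """Independent unit-drive solves of every channel, in channel order."""
    grids = [
        solve_channel(materials, applicator, ch, settings)
        for ch in range(applicator.n_channels)
    ]
    fs = ChannelFieldSet(
        fields=np.stack(grids, axis=0),
        spacing_mm=materials.spacing_mm,
        frequency_hz=applicator.frequency_hz,
        mode=settings.mode,
    )
    fs.validate_against(materials)
    return fs


def save_fieldset(fs: ChannelFieldSet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for ch in range(fs.n_channels):
            f.create_dataset(f"channel_{ch:02d}", data=fs.fields[ch])
        f.attrs["spacing_mm"] = fs.spacing_mm
        f.attrs["frequency_hz"] = fs.frequency_hz
        f.attrs["mode"] = fs.mode
        f.attrs["drive_amplitude"] = fs.drive_amplitude


def load_fieldset(path: str | Path) -> ChannelFieldSet:
    import h5py

    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("channel_"))
        fields = np.stack([f[k][()] for k in keys], axis=0)
        return ChannelFieldSet(
            fields=fields,
            spacing_mm=float(f.attrs["spacing_mm"]),
            frequency_hz=float(f.attrs["frequency_hz"]),
            mode=str(f.attrs["mode"]),
            drive_amplitude=float(f.attrs["drive_amplitude"]),
        )
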