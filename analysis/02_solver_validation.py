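#!/usr/bin/env python
"""Validate the time-domain solver against closed-form electromagnetics.

Two oracles with known answers:

* plane wave in homogeneous muscle at 100 MHz — the fitted attenuation and
  phase constants must match gamma = sqrt(jwmu0(sigma + jweps)) (about
  13.0 Np/m and 21.4 rad/m for the tabulated muscle constants);
* a vacuum line source — the radial amplitude profile must follow the 2D
  free-space Green's function |H0^(2)(kr)|.

Writes results/solver_validation.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
from scipy.special import hankel2

from htplan.fdtd import EPS0, MU0, SolverSettings, SourceTerm, _run_2d
from htplan.fixtures import homogeneous_block_materials

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/solver_validation.json"))
args = parser.parse_args()

# --- plane wave in muscle ---------------------------------------------------
eps_r, sigma = 66.0, 0.708
n, m = 140, 400
mats = homogeneous_block_materials((n, m), eps_r, sigma, 1090.0, 2.5)
j0 = 30
phasor = _run_2d(
    mats, [SourceTerm(cells=[(i, j0) for i in range(n)])], 1e8, SolverSettings()
)
j = np.arange(j0 + 15, m - 60)
d = (j - j0) * 2.5e-3
prof = phasor[n // 2, j]
alpha_fit = float(-np.polyfit(d, np.log(np.abs(prof)), 1)[0])
beta_fit = float(-np.polyfit(d, np.unwrap(np.angle(prof)), 1)[0])
omega = 2 * np.pi * 1e8
gamma = np.sqrt(1j * omega * MU0 * (sigma + 1j * omega * eps_r * EPS0))

# --- vacuum Green's function -------------------------------------------------
nv = 161
vac = homogeneous_block_materials((nv, nv), 1.0, 0.0, 1.2, 5.0)
f = 1e9
ph = _run_2d(vac, [SourceTerm([(nv // 2, nv // 2)])], f, SolverSettings(periods=12))
k = 2 * np.pi * f / 299792458.0
r_cells = np.arange(12, 65)
r = r_cells * 5e-3
ratio = np.abs(ph[nv // 2, nv // 2 + r_cells]) / np.abs(hankel2(0, k * r))
ratio /= ratio[0]
greens_dev = float(np.abs(ratio - 1).max())

report = {
    "muscle_alpha_fit_np_per_m": alpha_fit,
    "muscle_alpha_analytic_np_per_m": float(gamma.real),
    "muscle_beta_fit_rad_per_m": beta_fit,
    "muscle_beta_analytic_rad_per_m": float(gamma.imag),
    "alpha_rel_err": abs(alpha_fit - gamma.real) / gamma.real,
    "beta_rel_err": abs(beta_fit - gamma.imag) / gamma.imag,
    "greens_function_max_dev": greens_dev,
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(report, indent=1))

print(f"muscle alpha: fit {alpha_fit:.3f} vs analytic {gamma.real:.3f} Np/m "
      f"({report['alpha_rel_err']*100:.2f} %)")
print(f"muscle beta:  fit {beta_fit:.3f} vs analytic {gamma.imag:.3f} rad/m "
      f"({report['beta_rel_err']*100:.2f} %)")
print(f"2D Green's function max deviation: {greens_dev*100:.2f} %")
print(f"report -> {args.out}")
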