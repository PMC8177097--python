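"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the equilibrium oracle
solves the mass-action equation by bracketing bisection, the isotope oracle
enumerates isotopologues by brute force with multinomial weights, and the
standard-error oracle linearizes the fitted model (delta method).
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.optimize import brentq

from porphyfit.massid import ISOTOPES


def pl_bisect(l: float, p: float, kd: float) -> float:
    """Equilibrium complex concentration by bisection on mass action.

    Solves (p - x)(l - x) = kd * x on [0, min(l, p)].
    """
    if l == 0 or p == 0:
        return 0.0
    if kd == 0:
        return min(l, p)
    f = lambda x: (p - x) * (l - x) - kd * x
    return brentq(f, 0.0, min(l, p), xtol=1e-15, rtol=1e-14, maxiter=200)


def _compositions(n: int, k: int):
    """All ways to place n atoms into k isotope slots."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def brute_force_pattern(counts: dict[str, int]) -> dict[int, tuple[float, float]]:
    """Nominal-mass-binned isotopologue envelope by full enumeration.

    Returns {nominal offset from monoisotopic: (probability,
    abundance-weighted mean mass)}.
    """
    per_element = []
    for el, n in counts.items():
        iso = ISOTOPES[el]
        mono_mass, _ = max(iso, key=lambda t: t[1])
        options = []
        for comp in _compositions(n, len(iso)):
            weight = math.factorial(n)
            prob = 1.0
            mass = 0.0
            for c, (m, ab) in zip(comp, iso):
                weight //= math.factorial(c)
                prob *= ab ** c
                mass += c * m
            options.append((weight * prob, mass, mass - n * mono_mass))
        per_element.append(options)
    bins: dict[int, tuple[float, float]] = {}
    for combo in product(*per_element):
        prob = 1.0
        mass = 0.0
        shift = 0.0
        for p, m, s in combo:
            prob *= p
            mass += m
            shift += s
        if prob < 1e-15:
            continue
        key = round(shift)
        p0, wm0 = bins.get(key, (0.0, 0.0))
        bins[key] = (p0 + prob, wm0 + prob * mass)
    return bins


def delta_method_kd_se(fit, series, ext_model=None, i_protein=None) -> float:
    """Closed-form (linearized) standard error of the fitted Kd.

    Numerically differentiates the model residuals at the solution and applies
    the standard nonlinear-least-squares covariance s^2 (J^T J)^-1.
    """
    from porphyfit.binding import predict_absorbance, predict_fluorescence

    l = series.points["ligand_conc"].to_numpy(dtype=float)
    p = series.protein_init

    if fit.mode == "absorbance":
        model = lambda kd, coef: predict_absorbance(kd, coef, ext_model, l, p)
    else:
        model = lambda kd, coef: predict_fluorescence(kd, coef, fit.protein_coefficient, l, p)

    theta = np.array([fit.kd_hat, fit.complex_coefficient])
    eps = 1e-6
    cols = []
    for i in range(2):
        hi = theta.copy()
        lo = theta.copy()
        h = eps * max(abs(theta[i]), 1e-3)
        hi[i] += h
        lo[i] -= h
        cols.append((model(*hi) - model(*lo)) / (2 * h))
    jac = np.column_stack(cols)
    dof = l.size - 2
    s2 = fit.rss / dof
    cov = s2 * np.linalg.inv(jac.T @ jac)
    return float(np.sqrt(cov[0, 0]))
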