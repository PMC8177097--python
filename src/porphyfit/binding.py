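"""Depletion-corrected 1:1 binding equilibrium and Kd inference.

At the concentrations used in porphyrin titrations the dissociation constant
is comparable to (or far below) the reactant concentrations, so the
free-ligand approximation of the hyperbolic isotherm fails.  The equilibrium
complex concentration for 1:1 binding with depletion of both species is the
smaller root of the Morrison quadratic,

    [PL] = ((L + P + Kd) - sqrt((L + P + Kd)^2 - 4 L P)) / 2,

with L, P the *initial* (total) ligand and protein concentrations.  Two
observables are modelled on top of it:

* absorbance at the Soret readout wavelength (411 nm),
      A = [PL] * eps_PL + A_free(L - [PL]),
  where A_free is the calibrated free-ligand law (hemin's is nonlinear);
* tryptophan emission at 354 nm (290 nm excitation), quenched on binding,
      I = [PL] * I_PL + (P - [PL]) * I_P.

Kd is inferred by nonlinear least squares on log(Kd) (positivity by
construction) jointly with the complex coefficient, multi-started from
initial Kd values spanning the titration schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .calibration import ExtinctionModel, evaluate_free_contribution

__all__ = [
    "EquilibriumState",
    "TitrationSeries",
    "BindingFitResult",
    "UncertaintyResult",
    "FitError",
    "complex_concentration",
    "predict_absorbance",
    "predict_fluorescence",
    "fit_kd_absorbance",
    "fit_kd_fluorescence",
    "estimate_uncertainty",
]

TITRATION_CSV_COLUMNS = ["replicate", "ligand_conc", "conc_unit", "observable", "observable_kind"]

TIGHT_BINDING_RATIO = 10.0  # p_init/kd beyond which Kd is weakly identifiable


class FitError(RuntimeError):
    """Raised when a titration cannot be fitted (degenerate data)."""


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumState:
    """Solved 1:1 equilibrium for given totals and Kd (mass balance holds)."""

    pl_eq: np.ndarray | float
    free_ligand: np.ndarray | float
    free_protein: np.ndarray | float
    l_init: np.ndarray | float
    p_init: float
    kd: float


def complex_concentration(l_init, p_init: float, kd: float) -> EquilibriumState:
    """Equilibrium complex concentration from the Morrison quadratic.

    Uses the cancellation-free form 2 L P / (s + sqrt(s^2 - 4 L P)) with
    s = L + P + Kd, equivalent to the smaller quadratic root but stable when
    Kd >> L, P (where the textbook form loses all significant digits).
    """
    l = np.asarray(l_init, dtype=float)
    scalar = l.ndim == 0
    l = np.atleast_1d(l)
    p = float(p_init)
    k = float(kd)
    if np.any(l < 0) or p < 0 or k < 0:
        raise ValueError("concentrations and kd must be >= 0")
    if np.any(~np.isfinite(l)) or not np.isfinite(p) or not np.isfinite(k):
        raise ValueError("inputs must be finite")
    s = l + p + k
    disc = s * s - 4.0 * l * p
    # disc >= (l-p)^2 >= 0 analytically; clamp rounding noise
    root = np.sqrt(np.maximum(disc, 0.0))
    denom = s + root
    pl = np.where(denom > 0, np.divide(2.0 * l * p, denom, out=np.zeros_like(l), where=denom > 0), 0.0)
    pl = np.minimum(pl, np.minimum(l, p))  # guard rounding at the tight limit
    state = EquilibriumState(
        pl_eq=pl[0] if scalar else pl,
        free_ligand=(l - pl)[0] if scalar else l - pl,
        free_protein=(p - pl)[0] if scalar else p - pl,
        l_init=l[0] if scalar else l,
        p_init=p,
        kd=k,
    )
    return state


# ---------------------------------------------------------------------------
# Titration data container
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """One titration: observable vs ligand concentration at fixed protein.

    ``points`` has columns replicate (int), ligand_conc, observable.
    ``observable_kind`` is "A411" (absorbance, AU) or "I354" (emission,
    counts); ``conc_unit`` applies to both ligand_conc and protein_init.
    """

    protein_init: float
    points: pd.DataFrame
    observable_kind: str
    conc_unit: str = "uM"

    def __post_init__(self) -> None:
        if self.observable_kind not in {"A411", "I354"}:
            raise ValueError("observable_kind must be A411 or I354")
        required = {"replicate", "ligand_conc", "observable"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        if (self.points["ligand_conc"] < 0).any():
            raise ValueError("ligand_conc must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.points["replicate"].nunique()

    def replicate(self, rep: int) -> "TitrationSeries":
        sub = self.points[self.points["replicate"] == rep].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"no replicate {rep}")
        return TitrationSeries(self.protein_init, sub, self.observable_kind, self.conc_unit)

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df["conc_unit"] = self.conc_unit
        df["observable_kind"] = self.observable_kind
        buf = StringIO()
        df.to_csv(buf, index=False, columns=TITRATION_CSV_COLUMNS, lineterminator="\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path, protein_init: float) -> "TitrationSeries":
        df = pd.read_csv(path)
        missing = set(TITRATION_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
        kinds = df["observable_kind"].unique()
        units = df["conc_unit"].unique()
        if len(kinds) != 1 or len(units) != 1:
            raise ValueError("titration CSV must contain a single observable_kind and conc_unit")
        return cls(
            protein_init=protein_init,
            points=df[["replicate", "ligand_conc", "observable"]].copy(),
            observable_kind=str(kinds[0]),
            conc_unit=str(units[0]),
        )


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def predict_absorbance(kd: float, eps_complex: float, ext_model: ExtinctionModel,
                       ligand_concs, protein_conc: float,
                       free_eval: str = "free") -> np.ndarray:
    """Predicted A411 per titration point.

    ``free_eval`` selects the concentration at which the concentration-
    dependent free-ligand extinction is evaluated: "free" (the equilibrium
    free concentration, default) or "initial" (the total ligand added).
    """
    state = complex_concentration(ligand_concs, protein_conc, kd)
    pl = np.atleast_1d(state.pl_eq)
    l = np.atleast_1d(np.asarray(ligand_concs, dtype=float))
    if free_eval == "free":
        free_term = np.atleast_1d(evaluate_free_contribution(ext_model, l - pl))
    elif free_eval == "initial":
        # (L - PL) * eps(L), with eps(L) = A_free(L)/L and the L=0 limit -> 0
        a_init = np.atleast_1d(ext_model.predict(l))
        with np.errstate(invalid="ignore", divide="ignore"):
            eps_l = np.where(l > 0, a_init / np.where(l > 0, l, 1.0), 0.0)
        free_term = (l - pl) * eps_l
    else:
        raise ValueError("free_eval must be 'free' or 'initial'")
    return pl * eps_complex + free_term


def predict_fluorescence(kd: float, i_complex: float, i_protein: float,
                         ligand_concs, protein_conc: float) -> np.ndarray:
    """Predicted I354 per titration point (quenched-complex model)."""
    if i_complex < 0 or i_protein < 0:
        raise ValueError("emission coefficients must be >= 0")
    state = complex_concentration(ligand_concs, protein_conc, kd)
    pl = np.atleast_1d(state.pl_eq)
    return pl * i_complex + (protein_conc - pl) * i_protein


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class BindingFitResult:
    """Joint (Kd, complex coefficient) least-squares estimate."""

    kd_hat: float
    complex_coefficient: float
    rss: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    mode: str                       # "absorbance" | "fluorescence"
    conc_unit: str
    protein_coefficient: float | None = None   # I_P (fluorescence only)
    kd_sd: float | None = None
    warnings: list[str] = field(default_factory=list)
    method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kd": self.kd_hat,
            "kd_sd": self.kd_sd,
            "unit": self.conc_unit,
            "coefficients": {
                "complex": self.complex_coefficient,
                "protein": self.protein_coefficient,
            },
            "rss": self.rss,
            "n": self.n_points,
            "converged": self.converged,
            "method": self.method,
            "warnings": list(self.warnings),
        }


def _default_kd_starts(ligand_concs: np.ndarray) -> np.ndarray:
    pos = ligand_concs[ligand_concs > 0]
    if pos.size == 0:
        raise FitError("titration schedule has no positive ligand concentration")
    lo, hi = pos.min(), pos.max()
    return np.array([0.1 * lo, float(np.sqrt(lo * hi)), 10.0 * hi])


def _multistart_fit(l, y, model_of, coef_init_of, kd_starts, ftol=1e-10, max_nfev=10_000):
    """Shared multi-start driver.

    model_of(kd, coef) -> predicted observable; coef_init_of(kd) -> linear
    least-squares coefficient at fixed kd (exploits that both observables are
    linear in the complex coefficient). Fits theta = [log kd, coef].
    Tie-break: lowest RSS, then lowest kd.
    """
    def resid(theta):
        return model_of(np.exp(theta[0]), theta[1]) - y

    best = None
    for kd0 in kd_starts:
        theta0 = np.array([np.log(kd0), coef_init_of(kd0)])
        res = least_squares(resid, theta0, method="lm", ftol=ftol, xtol=1e-12,
                            gtol=1e-12, max_nfev=max_nfev)
        rss = float(res.fun @ res.fun)
        kd_hat = float(np.exp(res.x[0]))
        key = (rss, kd_hat)
        if best is None or key < (best[0], best[1]):
            best = (rss, kd_hat, float(res.x[1]), res)
    rss, kd_hat, coef, res = best
    return kd_hat, coef, rss, res.fun.copy(), bool(res.status > 0)


def fit_kd_absorbance(series: TitrationSeries, ext_model: ExtinctionModel,
                      kd_starts=None, free_eval: str = "free") -> BindingFitResult:
    """Fit (Kd, eps_PL) to an absorbance titration by least squares.

    All replicate points are pooled into one residual vector.  Requires at
    least 3 distinct ligand concentrations.
    """
    if series.observable_kind != "A411":
        raise ValueError("absorbance fit requires an A411 series")
    l = series.points["ligand_conc"].to_numpy(dtype=float)
    y = series.points["observable"].to_numpy(dtype=float)
    if np.unique(l).size < 3:
        raise FitError("need at least 3 distinct ligand concentrations")
    if np.allclose(y, 0.0):
        raise FitError("observable is identically zero; nothing to fit")
    p = series.protein_init
    starts = _default_kd_starts(l) if kd_starts is None else np.asarray(kd_starts, float)

    def model_of(kd, eps):
        return predict_absorbance(kd, eps, ext_model, l, p, free_eval=free_eval)

    def coef_init_of(kd):
        pl = np.atleast_1d(complex_concentration(l, p, kd).pl_eq)
        resid_target = y - (model_of(kd, 0.0))
        denom = float(pl @ pl)
        return float(pl @ resid_target) / denom if denom > 0 else 0.0

    kd_hat, eps_hat, rss, residuals, converged = _multistart_fit(
        l, y, model_of, coef_init_of, starts)
    msgs: list[str] = []
    if not converged:
        msgs.append("optimizer did not report convergence")
    return BindingFitResult(
        kd_hat=kd_hat, complex_coefficient=eps_hat, rss=rss, residuals=residuals,
        converged=converged, n_points=l.size, mode="absorbance",
        conc_unit=series.conc_unit, warnings=msgs,
        method={"fit": "least_squares(lm) on [log kd, eps_PL]",
                "free_eval": free_eval, "n_starts": len(starts)},
    )


def fit_kd_fluorescence(series: TitrationSeries, i_protein: float | None = None,
                        kd_starts=None) -> BindingFitResult:
    """Fit (Kd, I_PL) to a tryptophan-quenching titration.

    I_P (free-protein emission per concentration) is fixed from the
    zero-ligand baseline unless supplied.  Emits a warning in the
    tight-binding regime (p_init/Kd > 10), where the isotherm approaches the
    stoichiometric limit and Kd is only weakly identifiable.
    """
    if series.observable_kind != "I354":
        raise ValueError("fluorescence fit requires an I354 series")
    if series.protein_init <= 0:
        raise FitError("protein concentration must be > 0 for a quenching assay")
    l = series.points["ligand_conc"].to_numpy(dtype=float)
    y = series.points["observable"].to_numpy(dtype=float)
    if np.unique(l).size < 3:
        raise FitError("need at least 3 distinct ligand concentrations")
    if np.allclose(y, 0.0):
        raise FitError("observable is identically zero; nothing to fit")
    p = series.protein_init
    if i_protein is None:
        zero = l == 0
        if not zero.any():
            raise FitError("no zero-ligand point; supply i_protein explicitly")
        i_protein = float(y[zero].mean() / p)
    starts = _default_kd_starts(l) if kd_starts is None else np.asarray(kd_starts, float)

    def model_of(kd, ic):
        return predict_fluorescence(kd, max(ic, 0.0), i_protein, l, p)

    def coef_init_of(kd):
        pl = np.atleast_1d(complex_concentration(l, p, kd).pl_eq)
        resid_target = y - (p - pl) * i_protein
        denom = float(pl @ pl)
        return float(pl @ resid_target) / denom if denom > 0 else 0.0

    kd_hat, ic_hat, rss, residuals, converged = _multistart_fit(
        l, y, model_of, coef_init_of, starts)
    msgs: list[str] = []
    if not converged:
        msgs.append("optimizer did not report convergence")
    if kd_hat > 0 and p / kd_hat > TIGHT_BINDING_RATIO:
        msg = (
            f"tight-binding regime: p_init/kd = {p / kd_hat:.1f} > "
            f"{TIGHT_BINDING_RATIO:g}; Kd is weakly identifiable at this "
            "protein concentration"
        )
        msgs.append(msg)
        warnings.warn(msg, stacklevel=2)
    return BindingFitResult(
        kd_hat=kd_hat, complex_coefficient=ic_hat, rss=rss, residuals=residuals,
        converged=converged, n_points=l.size, mode="fluorescence",
        conc_unit=series.conc_unit, protein_coefficient=i_protein, warnings=msgs,
        method={"fit": "least_squares(lm) on [log kd, I_PL]",
                "i_protein": "fixed from zero-ligand baseline" if i_protein is not None else "fitted",
                "n_starts": len(starts)},
    )


def _refit(series: TitrationSeries, fit: BindingFitResult,
           ext_model: ExtinctionModel | None, y_override=None,
           single_start: bool = False) -> BindingFitResult:
    s = series
    if y_override is not None:
        pts = series.points.copy()
        pts["observable"] = y_override
        s = TitrationSeries(series.protein_init, pts, series.observable_kind, series.conc_unit)
    starts = np.array([fit.kd_hat]) if single_start else None
    if fit.mode == "absorbance":
        if ext_model is None:
            raise ValueError("absorbance refit requires the extinction model")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_kd_absorbance(s, ext_model, kd_starts=starts,
                                     free_eval=fit.method.get("free_eval", "free"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_kd_fluorescence(s, i_protein=fit.protein_coefficient, kd_starts=starts)


@dataclass
class UncertaintyResult:
    sd: float
    method: str
    kds: np.ndarray
    ci95: tuple[float, float] | None = None


def estimate_uncertainty(fit: BindingFitResult, series: TitrationSeries,
                         method: str = "replicate_sd",
                         ext_model: ExtinctionModel | None = None,
                         n_boot: int = 200, seed: int | None = None) -> UncertaintyResult:
    """Standard deviation (and CI) for the fitted Kd.

    ``replicate_sd`` refits each replicate independently and reports the
    sample SD of the per-replicate Kd estimates.  ``residual_bootstrap``
    resamples fitted residuals with replacement, refits ``n_boot`` times
    (seeded), and reports the SD and 2.5/97.5 percentile interval.
    """
    if method == "replicate_sd":
        reps = sorted(series.points["replicate"].unique())
        if len(reps) < 2:
            raise FitError("replicate_sd needs >= 2 replicates; use residual_bootstrap")
        kds = np.array([
            _refit(series.replicate(r), fit, ext_model).kd_hat for r in reps
        ])
        return UncertaintyResult(sd=float(np.std(kds, ddof=1)), method=method, kds=kds)
    if method == "residual_bootstrap":
        rng = np.random.default_rng(seed)
        y = series.points["observable"].to_numpy(dtype=float)
        if fit.residuals.size != y.size:
            raise ValueError("fit residuals do not match series length")
        yhat = y - fit.residuals
        kds = np.empty(n_boot)
        for b in range(n_boot):
            resampled = rng.choice(fit.residuals, size=fit.residuals.size, replace=True)
            kds[b] = _refit(series, fit, ext_model, y_override=yhat + resampled,
                            single_start=True).kd_hat
        lo, hi = np.percentile(kds, [2.5, 97.5])
        return UncertaintyResult(sd=float(np.std(kds, ddof=1)), method=method,
                                 kds=kds, ci95=(float(lo), float(hi)))
    raise ValueError("method must be replicate_sd or residual_bootstrap")
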