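"""Free-ligand extinction calibration.

Free porphyrins do not obey Beer–Lambert linearly over the titration range:
hemin aggregates in aqueous buffer, so its absorbance at the Soret readout
wavelength curves with concentration, while hematoporphyrin (HP) stays linear.
The binding model needs the free-ligand contribution A_free(c) at arbitrary
free concentrations, so we calibrate an absorbance-vs-concentration law from
blank (protein-free) dilution series and evaluate it inside the binding fit.

The law is a polynomial with zero intercept (A_free(0) = 0; the buffer blank
is subtracted upstream): degree 1 ("linear") for HP, degree 2 by default for
hemin ("polynomial"), i.e. the concentration-dependent extinction coefficient
is eps(c) = A_free(c) / c.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionModel",
    "CalibrationError",
    "fit_extinction",
    "evaluate_free_contribution",
    "family_for_ligand",
    "read_calibration_csv",
    "write_calibration_csv",
]

CALIBRATION_CSV_COLUMNS = ["ligand", "conc", "conc_unit", "absorbance", "wavelength_nm"]


class CalibrationError(ValueError):
    """Raised for rank-deficient or otherwise unusable calibration data."""


def family_for_ligand(ligand: str) -> str:
    """Map a ligand tag to its calibration family.

    Heme/hemin aggregates, so its free-ligand curve is fit with a polynomial;
    hematoporphyrin (HP) is fit linearly.
    """
    tag = ligand.strip().lower()
    if tag in {"heme", "hemin", "heme b", "hemin chloride"}:
        return "polynomial"
    if tag in {"hp", "hematoporphyrin"}:
        return "linear"
    raise ValueError(f"unknown ligand tag {ligand!r}; expected heme/hemin or HP")


@dataclass
class ExtinctionModel:
    """Calibrated free-ligand absorbance law A_free(c).

    ``coefficients[k]`` multiplies c**(k+1): the constant term is fixed at 0
    so that A_free(0) = 0 exactly.
    """

    family: str  # "polynomial" or "linear"
    coefficients: np.ndarray
    valid_range: tuple[float, float]
    wavelength: float = 411.0
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if self.family not in {"polynomial", "linear"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "linear" and self.coefficients.size != 1:
            raise ValueError("linear model must have exactly one coefficient")

    @property
    def degree(self) -> int:
        return len(self.coefficients)

    def predict(self, conc) -> np.ndarray | float:
        """A_free at the given concentration(s); extrapolation is flagged."""
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        lo, hi = self.valid_range
        if np.any((c < lo) & (c > 0)) or np.any(c > hi):
            msg = (
                f"evaluating extinction model outside calibrated range "
                f"[{lo:g}, {hi:g}]; extrapolated value returned"
            )
            self.fit_diagnostics.setdefault("warnings", []).append(msg)
            warnings.warn(msg, stacklevel=2)
        # Horner on the zero-intercept polynomial c*(a1 + c*(a2 + ...))
        acc = np.zeros_like(c)
        for coef in self.coefficients[::-1]:
            acc = c * (coef + acc)
        return acc if acc.ndim else float(acc)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": self.coefficients.tolist(),
            "valid_range": list(self.valid_range),
            "wavelength_nm": self.wavelength,
            "fit_diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.fit_diagnostics.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ExtinctionModel":
        return cls(
            family=d["family"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            valid_range=tuple(d["valid_range"]),
            wavelength=d.get("wavelength_nm", 411.0),
            fit_diagnostics=d.get("fit_diagnostics", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ExtinctionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_extinction(conc, absorbance, family: str = "polynomial", degree: int | None = None,
                   wavelength: float = 411.0) -> ExtinctionModel:
    """Least-squares fit of the zero-intercept extinction law.

    Parameters
    ----------
    conc, absorbance
        Paired calibration measurements (protein-free ligand dilutions).
    family
        "linear" (degree forced to 1, the HP case) or "polynomial"
        (default degree 2, the hemin case).
    degree
        Polynomial degree; ignored for the linear family.
    """
    c = np.asarray(conc, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValueError("conc and absorbance must be 1-D arrays of equal length")
    if np.any(~np.isfinite(c)) or np.any(~np.isfinite(a)):
        raise ValueError("calibration data must be finite")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")

    if family == "linear":
        deg = 1
    elif family == "polynomial":
        deg = 2 if degree is None else int(degree)
        if deg < 1:
            raise ValueError("degree must be >= 1")
    else:
        raise ValueError(f"unknown family {family!r}")

    n_distinct = np.unique(c).size
    if n_distinct < deg + 1:
        raise CalibrationError(
            f"need at least {deg + 1} distinct concentrations for degree {deg}, "
            f"got {n_distinct}"
        )
    # Zero-intercept design: columns c, c^2, ..., c^deg
    design = np.column_stack([c ** k for k in range(1, deg + 1)])
    if np.linalg.matrix_rank(design) < deg:
        raise CalibrationError("rank-deficient calibration design")
    coef, _, _, _ = np.linalg.lstsq(design, a, rcond=None)
    resid = a - design @ coef
    model = ExtinctionModel(
        family=family,
        coefficients=coef,
        valid_range=(float(c.min()), float(c.max())),
        wavelength=wavelength,
        fit_diagnostics={"rss": float(resid @ resid), "n_points": int(c.size)},
    )
    return model


def evaluate_free_contribution(model: ExtinctionModel, free_conc) -> np.ndarray | float:
    """Absorbance contributed by free ligand at concentration ``free_conc``.

    This is the ([L]_init − [PL]) × eps([L]) term of the absorbance observable,
    with the concentration-dependent extinction coefficient realized as
    A_free(c)/c, so the contribution is simply A_free(free_conc).
    """
    return model.predict(free_conc)


def write_calibration_csv(path, ligand: str, conc, absorbance,
                          conc_unit: str = "uM", wavelength_nm: float = 411.0) -> None:
    df = pd.DataFrame(
        {
            "ligand": ligand,
            "conc": np.asarray(conc, dtype=float),
            "conc_unit": conc_unit,
            "absorbance": np.asarray(absorbance, dtype=float),
            "wavelength_nm": wavelength_nm,
        }
    )
    df.to_csv(path, index=False, columns=CALIBRATION_CSV_COLUMNS)


def read_calibration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CALIBRATION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return df
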