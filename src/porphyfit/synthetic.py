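"""Synthetic titration data with known ground truth.

Emulates the two assay geometries used to characterize porphyrin binding to
the bacterial lipocalin Blc:

* spectrophotometric hemin titration — 5 μM protein, 0.5–11 μM hemin,
  absorbance read at the 411 nm Soret band; the free-hemin contribution is
  nonlinear in concentration (aggregation), generated either from a chosen
  polynomial law or from an explicit monomer–dimer equilibrium;
* tryptophan-quenching hematoporphyrin titration — 10 nM protein,
  0.8–50 nM ligand, emission read at 354 nm (290 nm excitation), with the
  complex emitting a fixed fraction of the free-protein intensity.

Noiseless observables satisfy the forward models in :mod:`porphyfit.binding`
exactly; measurement noise is additive Gaussian (optionally plus a relative
Gaussian component) applied independently per replicate.  A fixed seed makes
the generated tables byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries, complex_concentration

__all__ = [
    "PolynomialLaw",
    "MonomerDimerLaw",
    "SyntheticConfig",
    "GroundTruth",
    "hemin_absorbance_config",
    "hp_fluorescence_config",
    "simulate_free_ligand_absorbance",
    "simulate_absorbance_titration",
    "simulate_fluorescence_titration",
]


@dataclass(frozen=True)
class PolynomialLaw:
    """True free-ligand absorbance as a zero-intercept polynomial in c."""

    coefficients: tuple[float, ...] = (0.05, -0.001)  # AU per uM, uM^2, ...

    def absorbance(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        acc = np.zeros_like(c)
        for coef in self.coefficients[::-1]:
            acc = c * (coef + acc)
        return acc


@dataclass(frozen=True)
class MonomerDimerLaw:
    """Mechanistic free-heme law: monomer–dimer equilibrium.

    2 M <-> D with dissociation constant ``k_dim`` (same unit as the
    concentrations); absorbance = eps_monomer*[M] + eps_dimer*[D].  Because
    the dimer absorbs less per heme at the Soret readout, total absorbance
    curves downward with concentration — the behaviour a polynomial
    calibration then has to approximate.
    """

    k_dim: float = 20.0            # uM; weak aggregation over a 0-11 uM window
    eps_monomer: float = 0.05      # AU per uM
    eps_dimer: float = 0.06        # AU per uM of dimer (< 2*eps_monomer)

    def absorbance(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        # m + 2 m^2 / k = c  ->  m = (-k + sqrt(k^2 + 8 k c)) / 4
        k = self.k_dim
        m = (-k + np.sqrt(k * k + 8.0 * k * c)) / 4.0
        d = (c - m) / 2.0
        return self.eps_monomer * m + self.eps_dimer * d


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for one simulated titration experiment.

    Concentration units are implicit but must be consistent across
    ``true_kd``, ``protein_conc`` and ``ligand_concs``; ``conc_unit`` is
    carried through to the output tables.
    """

    true_kd: float
    protein_conc: float
    ligand_concs: tuple[float, ...]
    conc_unit: str = "uM"
    eps_complex: float = 0.1          # AU per conc unit (absorbance mode)
    free_ligand_law: PolynomialLaw | MonomerDimerLaw = field(default_factory=PolynomialLaw)
    i_protein: float = 1000.0         # counts per conc unit (fluorescence mode)
    i_complex: float = 200.0          # quenched-complex emission coefficient
    noise_sd: float = 0.0             # additive Gaussian, observable units
    noise_rel: float = 0.0            # relative Gaussian fraction of the signal
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        concs = np.asarray(self.ligand_concs, dtype=float)
        if concs.size == 0:
            raise ValueError("ligand schedule is empty")
        if np.any(concs < 0) or np.any(~np.isfinite(concs)):
            raise ValueError("ligand concentrations must be finite and >= 0")
        if np.any(np.diff(concs) <= 0):
            raise ValueError("ligand_concs must be strictly increasing")
        if self.true_kd < 0 or self.protein_conc < 0:
            raise ValueError("true_kd and protein_conc must be >= 0")
        if self.noise_sd < 0 or self.noise_rel < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "ligand_concs", tuple(float(c) for c in concs))

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def hemin_absorbance_config(true_kd: float = 1.4, seed: int = 0,
                            noise_sd: float = 0.003, n_replicates: int = 3) -> SyntheticConfig:
    """Default hemin/protein absorbance titration: 5 μM protein, 0.5–11 μM
    hemin in 12 steps, triplicate, σ = 0.003 AU."""
    return SyntheticConfig(
        true_kd=true_kd,
        protein_conc=5.0,
        ligand_concs=tuple(np.linspace(0.5, 11.0, 12)),
        conc_unit="uM",
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )


def hp_fluorescence_config(true_kd: float = 0.14, seed: int = 0,
                           n_replicates: int = 3) -> SyntheticConfig:
    """Default hematoporphyrin quenching titration: 10 nM protein, 0.8–50 nM
    ligand (12 log-spaced steps plus the zero-ligand baseline), complex
    emission 20% of free protein, 1% relative + 1%-of-baseline additive noise.
    """
    baseline = 10.0 * 1000.0  # p_init * i_protein, counts
    return SyntheticConfig(
        true_kd=true_kd,
        protein_conc=10.0,
        ligand_concs=(0.0, *np.geomspace(0.8, 50.0, 12)),
        conc_unit="nM",
        i_protein=1000.0,
        i_complex=200.0,
        noise_sd=0.01 * baseline,
        noise_rel=0.01,
        n_replicates=n_replicates,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Noiseless truth underlying one simulated titration."""

    true_kd: float
    ligand_concs: np.ndarray
    complex_concs: np.ndarray
    noiseless: np.ndarray
    observable_kind: str
    conc_unit: str

    def to_json(self, path) -> None:
        payload = {
            "true_kd": self.true_kd,
            "conc_unit": self.conc_unit,
            "observable_kind": self.observable_kind,
            "ligand_concs": self.ligand_concs.tolist(),
            "complex_concs": self.complex_concs.tolist(),
            "noiseless": self.noiseless.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def simulate_free_ligand_absorbance(config: SyntheticConfig, concs=None) -> pd.DataFrame:
    """Protein-free ligand dilution series for extinction calibration.

    Returns a (concentration, absorbance) table; by default the titration
    schedule itself (plus c = 0) is used as the dilution series.
    """
    if concs is None:
        concs = np.concatenate([[0.0], np.asarray(config.ligand_concs)])
    c = np.asarray(concs, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    a = np.asarray(config.free_ligand_law.absorbance(c), dtype=float)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        a = a + rng.normal(0.0, config.noise_sd, size=a.shape)
    return pd.DataFrame({"conc": c, "absorbance": a})


def _add_noise(noiseless: np.ndarray, config: SyntheticConfig, rng) -> np.ndarray:
    out = noiseless.copy()
    if config.noise_rel > 0:
        out = out * (1.0 + rng.normal(0.0, config.noise_rel, size=out.shape))
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=out.shape)
    return out


def _assemble(config: SyntheticConfig, noiseless: np.ndarray,
              kind: str) -> tuple[TitrationSeries, GroundTruth]:
    l = np.asarray(config.ligand_concs)
    pl = np.atleast_1d(complex_concentration(l, config.protein_conc, config.true_kd).pl_eq)
    rng = np.random.default_rng(config.seed)
    frames = []
    for rep in range(config.n_replicates):
        frames.append(pd.DataFrame({
            "replicate": rep,
            "ligand_conc": l,
            "observable": _add_noise(noiseless, config, rng),
        }))
    series = TitrationSeries(
        protein_init=config.protein_conc,
        points=pd.concat(frames, ignore_index=True),
        observable_kind=kind,
        conc_unit=config.conc_unit,
    )
    truth = GroundTruth(
        true_kd=config.true_kd, ligand_concs=l.copy(), complex_concs=pl,
        noiseless=noiseless.copy(), observable_kind=kind, conc_unit=config.conc_unit,
    )
    return series, truth


def simulate_absorbance_titration(config: SyntheticConfig) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate an A411 titration: complex band plus nonlinear free-ligand term."""
    l = np.asarray(config.ligand_concs)
    pl = np.atleast_1d(complex_concentration(l, config.protein_conc, config.true_kd).pl_eq)
    noiseless = pl * config.eps_complex + config.free_ligand_law.absorbance(l - pl)
    return _assemble(config, noiseless, "A411")


def simulate_fluorescence_titration(config: SyntheticConfig) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate an I354 quenching titration (complex emits less than protein)."""
    if config.protein_conc == 0 and config.i_protein > 0:
        raise ValueError("degenerate config: zero protein with nonzero protein emission")
    if not config.i_protein > config.i_complex >= 0:
        raise ValueError("quenching requires i_protein > i_complex >= 0")
    l = np.asarray(config.ligand_concs)
    pl = np.atleast_1d(complex_concentration(l, config.protein_conc, config.true_kd).pl_eq)
    noiseless = pl * config.i_complex + (config.protein_conc - pl) * config.i_protein
    return _assemble(config, noiseless, "I354")
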