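"""Exact-mass identification and isotopologue envelopes for small molecules.

Implements the arithmetic behind high-resolution MS identification of the
tetrapyrrole copurifying with the lipocalin: monoisotopic mass from an
embedded isotope table, ion m/z with explicit proton/electron bookkeeping,
ppm matching, and the isotopologue envelope by per-element convolution.

The electron mass (~0.000549 Da) is included in ion m/z: at the 4-decimal
precision of Orbitrap precursor masses it shifts values by ~1 ppm, which is
the scale on which the identification is made.  Note that ferric heme B
(C34H32FeN4O4, monoisotopic 616.1773 Da) ionizes as the intact cation [M]+
at m/z 616.1767 — within ~1 ppm of precursor values conventionally annotated
as [M+H]+; both ion hypotheses are supported.

Isotope masses and abundances are IUPAC 2021 representative values, embedded
so nothing is fetched at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularFormula",
    "IonSpec",
    "IsotopePattern",
    "HEME_B_FORMULA",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "isotopologue_pattern",
    "match_precursor",
]

ELECTRON_MASS = 0.000548579909065  # Da
PROTON_MASS = 1.007276466621       # Da (bare proton)
H_ATOM_MASS = 1.00782503224        # Da (1H atom, proton + electron)

HEME_B_FORMULA = "C34H32FeN4O4"    # iron(III) protoporphyrin IX, neutral formula

# element -> [(isotope exact mass Da, abundance fraction), ...], IUPAC 2021
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503224, 0.999885), (2.01410177812, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483534, 0.0107)],
    "N": [(14.00307400446, 0.99636), (15.00010889894, 0.00364)],
    "O": [(15.99491461960, 0.99757), (16.99913175664, 0.00038), (17.99915961284, 0.00205)],
    "Na": [(22.98976928195, 1.0)],
    "Mg": [(23.985041697, 0.7899), (24.985836976, 0.1000), (25.982592968, 0.1101)],
    "P": [(30.97376199842, 1.0)],
    "S": [(31.9720711744, 0.9499), (32.9714589098, 0.0075),
          (33.967867004, 0.0425), (35.96708071, 0.0001)],
    "Cl": [(34.968852682, 0.7576), (36.965902602, 0.2424)],
    "K": [(38.9637064864, 0.932581), (39.963998166, 0.000117), (40.9618252579, 0.067302)],
    "Fe": [(53.93960899, 0.05845), (55.93493633, 0.91754),
           (56.93539284, 0.02119), (57.93327443, 0.00282)],
    "Zn": [(63.92914201, 0.4917), (65.92603381, 0.2773), (66.92712775, 0.0404),
           (67.92484455, 0.1845), (69.9253192, 0.0061)],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition (non-negative counts, known elements only)."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.counts.items():
            if el not in ISOTOPES:
                raise ValueError(f"unknown element symbol {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {el}")
            if n > 0:
                cleaned[el] = n
        if not cleaned:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, hill: str) -> "MolecularFormula":
        """Parse a Hill-notation string such as 'C34H32FeN4O4'."""
        s = hill.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos or not m.group(0):
                break
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(s) or not counts:
            raise ValueError(f"cannot parse formula {hill!r}")
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def hill(self) -> str:
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def _as_formula(formula) -> MolecularFormula:
    return formula if isinstance(formula, MolecularFormula) else MolecularFormula.parse(formula)


def monoisotopic_mass(formula) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    f = _as_formula(formula)
    total = 0.0
    for el, n in f.counts.items():
        mass, _ = max(ISOTOPES[el], key=lambda t: t[1])
        total += n * mass
    return total


@dataclass(frozen=True)
class IonSpec:
    """An ionization hypothesis: formula, charge, and protons gained/lost.

    ``added_protons = 0`` with positive charge describes an even-electron or
    metal-centered cation observed intact (e.g. ferric heme [M]+), where the
    charge comes from removing electrons rather than adding protons.
    """

    formula: MolecularFormula
    charge: int = 1
    added_protons: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", _as_formula(self.formula))
        if self.charge == 0:
            raise ValueError("charge must be nonzero")

    @classmethod
    def protonated(cls, formula, n: int = 1) -> "IonSpec":
        return cls(_as_formula(formula), charge=n, added_protons=n,
                   label=f"[M+{n}H]{n}+" if n > 1 else "[M+H]+")

    @classmethod
    def intact_cation(cls, formula, charge: int = 1) -> "IonSpec":
        return cls(_as_formula(formula), charge=charge, added_protons=0,
                   label="[M]+" if charge == 1 else f"[M]{charge}+")


def ion_mz(ion: IonSpec) -> float:
    """m/z with explicit proton and electron bookkeeping.

    m/z = (M + n_p·m_proton − (z − n_p)·m_e) / |z|: protonation adds bare
    protons, and any charge beyond the added protons comes from removing
    electrons.  Thus [M+H]+ = M + m_p while [M]+ = M − m_e; the ~0.00055 Da
    electron term is what reconciles printed Orbitrap masses at ~1 ppm.
    """
    m = monoisotopic_mass(ion.formula)
    m += ion.added_protons * PROTON_MASS
    m -= (ion.charge - ion.added_protons) * ELECTRON_MASS
    return m / abs(ion.charge)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical_mz must be > 0")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


@dataclass
class IsotopePattern:
    """Isotopologue envelope: (mass, relative intensity) sorted by mass."""

    mz: np.ndarray
    intensity: np.ndarray
    normalization: str = "sum"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D and equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


def _atom_distribution(el: str) -> dict[int, tuple[float, float]]:
    """Single-atom distribution keyed by nominal-mass offset from monoisotopic."""
    iso = ISOTOPES[el]
    mono_mass, _ = max(iso, key=lambda t: t[1])
    dist: dict[int, tuple[float, float]] = {}
    for mass, ab in iso:
        key = round(mass - mono_mass)
        p, wm = dist.get(key, (0.0, 0.0))
        dist[key] = (p + ab, wm + ab * mass)
    return dist


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]],
              prune: float = 1e-12) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for ka, (pa, ma) in a.items():
        mean_a = ma / pa if pa > 0 else 0.0
        for kb, (pb, mb) in b.items():
            p = pa * pb
            if p < prune:
                continue
            mean_b = mb / pb if pb > 0 else 0.0
            k = ka + kb
            p0, wm0 = out.get(k, (0.0, 0.0))
            out[k] = (p0 + p, wm0 + p * (mean_a + mean_b))
    return out


def _power(dist: dict[int, tuple[float, float]], n: int) -> dict[int, tuple[float, float]]:
    result = {0: (1.0, 0.0)}
    base = dist
    while n > 0:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def isotopologue_pattern(formula, max_peaks: int = 8,
                         normalization: str = "sum") -> IsotopePattern:
    """Isotopologue envelope at nominal-mass (1 Da bin) resolution.

    Computed by convolving per-element isotope distributions; each bin's mass
    is the abundance-weighted mean of the isotopologues it aggregates, the
    resolution at which Orbitrap precursor envelopes are compared visually.
    ``normalization``: "sum" (intensities sum to 1) or "base_peak" (most
    intense peak = 1).  The ``max_peaks`` most intense bins are kept.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    if normalization not in {"sum", "base_peak"}:
        raise ValueError("normalization must be 'sum' or 'base_peak'")
    f = _as_formula(formula)
    total = {0: (1.0, 0.0)}
    for el, n in f.counts.items():
        total = _convolve(total, _power(_atom_distribution(el), n))
    keys = sorted(total, key=lambda k: total[k][0], reverse=True)[:max_peaks]
    keys.sort()
    probs = np.array([total[k][0] for k in keys])
    masses = np.array([total[k][1] / total[k][0] for k in keys])
    if normalization == "sum":
        probs = probs / probs.sum()
    else:
        probs = probs / probs.max()
    return IsotopePattern(mz=masses, intensity=probs, normalization=normalization)


def match_precursor(observed_mz: float, candidates: list[IonSpec],
                    tol_ppm: float = 5.0) -> tuple[IonSpec, float] | None:
    """Best ion hypothesis within tolerance, or None.

    Picks the candidate with the smallest absolute ppm error among those
    within ``tol_ppm``; exact ties break toward the lower theoretical m/z.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    best: tuple[float, float, IonSpec, float] | None = None
    for cand in candidates:
        theo = ion_mz(cand)
        ppm = ppm_error(observed_mz, theo)
        if abs(ppm) > tol_ppm:
            continue
        key = (abs(ppm), theo)
        if best is None or key < (best[0], best[1]):
            best = (abs(ppm), theo, cand, ppm)
    if best is None:
        return None
    return best[2], best[3]
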