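"""Shared fixtures: synthetic structures (porphyrin, protein scaffolds) and
small default configs.  All fixtures are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from porphyfit.structure import Atom, StructureModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def _rot_z(deg: float) -> np.ndarray:
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0.0],
                     [np.sin(t), np.cos(t), 0.0],
                     [0.0, 0.0, 1.0]])


def make_porphyrin(chain: str = "X", resnum: int = 201, rot_deg: float = 0.0,
                   transform: np.ndarray | None = None,
                   translation: np.ndarray | None = None,
                   with_fe: bool = True) -> list[Atom]:
    """Idealized planar porphyrin (HEM atom naming) in the xy-plane.

    Four pyrrole pentagons (rings A-D at 0/90/180/270 degrees plus
    ``rot_deg``) with nitrogens pointing at the central iron, plus the four
    meso carbons CHA-CHD.  Geometry is idealized but self-consistent: good
    enough for plane fits, ring centroids, and rotation tests.
    """
    rot = _rot_z(rot_deg)
    atoms: list[tuple[str, str, np.ndarray]] = []
    if with_fe:
        atoms.append(("FE", "Fe", np.zeros(3)))
    for k, suffix in enumerate("ABCD"):
        theta = np.radians(90.0 * k)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        center = 3.2 * u
        # pentagon vertex 0 (the nitrogen) points back toward the iron
        for j, name in enumerate([f"N{suffix}", f"C1{suffix}", f"C2{suffix}",
                                  f"C3{suffix}", f"C4{suffix}"]):
            phi = theta + np.pi + np.radians(72.0 * j)
            pos = center + 1.19 * np.array([np.cos(phi), np.sin(phi), 0.0])
            atoms.append((name, name[0], pos))
        meso = np.radians(90.0 * k + 45.0)
        atoms.append((f"CH{suffix}", "C",
                      3.4 * np.array([np.cos(meso), np.sin(meso), 0.0])))
    out = []
    for name, element, pos in atoms:
        xyz = rot @ pos
        if transform is not None:
            xyz = transform @ xyz
        if translation is not None:
            xyz = xyz + translation
        out.append(Atom(chain=chain, resname="HEM", resnum=resnum, icode="",
                        name=name, element=element, pos=tuple(xyz), hetero=True))
    return out


def make_protein_scaffold(chain: str = "A", transform: np.ndarray | None = None,
                          translation: np.ndarray | None = None) -> list[Atom]:
    """Seven non-collinear Cα atoms (ALA) for superposition tests."""
    coords = np.array([
        [10.0, 0.0, 0.0], [12.0, 3.0, 1.0], [9.0, 6.0, -2.0],
        [6.0, 4.0, 3.0], [4.0, -1.0, 1.0], [7.5, -3.0, -1.5], [11.0, -4.0, 2.0],
    ])
    out = []
    for i, xyz in enumerate(coords, start=1):
        p = xyz if transform is None else transform @ xyz
        if translation is not None:
            p = p + translation
        out.append(Atom(chain=chain, resname="ALA", resnum=i, icode="",
                        name="CA", element="C", pos=tuple(p), hetero=False))
    return out


@pytest.fixture
def porphyrin_complex():
    """Protein scaffold plus an in-plane porphyrin, as one model."""
    return StructureModel(make_protein_scaffold() + make_porphyrin())


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
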