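"""Shared fixtures: random puckering states, ring templates, receptor trees."""

from __future__ import annotations

import numpy as np
import pytest

from puckermc.ring_pucker import PuckeringState
from puckermc.structure_builder import RingTemplate

ALL_HETEROATOMS = ("CH2", "O", "S", "SO2", "NH", "BH", "PH")
RING_SIZES = (5, 6, 7)


def random_state(n: int, rng: np.random.Generator,
                 max_amplitude: float = 0.8) -> PuckeringState:
    """One random valid puckering state with uniform phases and a total
    amplitude drawn in (0.05, max_amplitude)."""
    amp = rng.uniform(0.05, max_amplitude)
    if n == 5:
        phi2 = rng.uniform(0, 360)
        return PuckeringState(
            n_atoms=5, q=np.array([amp]), phi=np.array([phi2]),
            A=np.array([amp * np.sin(np.radians(phi2))]),
            B=np.array([amp * np.cos(np.radians(phi2))]))
    if n == 6:
        theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
        phi2 = rng.uniform(0, 360)
        q2 = amp * np.sin(np.radians(theta))
        q3s = amp * np.cos(np.radians(theta))
        return PuckeringState(
            n_atoms=6, q=np.array([q2, abs(q3s)]), phi=np.array([phi2]),
            A=np.array([q2 * np.sin(np.radians(phi2))]),
            B=np.array([q2 * np.cos(np.radians(phi2))]),
            Q=amp, theta=theta)
    frac = rng.uniform(0, 1)
    q = amp * np.array([np.sqrt(1 - frac**2), frac])
    phi = rng.uniform(0, 360, size=2)
    return PuckeringState(
        n_atoms=7, q=q, phi=phi,
        A=q * np.sin(np.radians(phi)), B=q * np.cos(np.radians(phi)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


@pytest.fixture
def oxygen_templates() -> dict[int, RingTemplate]:
    return {n: RingTemplate(n_atoms=n, heteroatom="O") for n in RING_SIZES}


@pytest.fixture
def receptor_tree(tmp_path):
    """Build a synthetic receptor folder tree and return its root.

    The receptor structures are placeholders standing in for prepared
    docking targets; only the folder layout and box definitions matter
    to the code under test.
    """

    def build(families: dict[str, int]):
        root = tmp_path / "receptors"
        for family, count in families.items():
            for i in range(count):
                d = root / family / f"rec{i + 1}"
                d.mkdir(parents=True)
                (d / "receptor.pdbqt").write_text("REMARK synthetic receptor\n")
                (d / "box.txt").write_text(
                    "center_x = 10.0\ncenter_y = -4.0\ncenter_z = 2.5\n"
                    "size_x = 22\nsize_y = 22\nsize_z = 22\n"
                )
        return root

    return build
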