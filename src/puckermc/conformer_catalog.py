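"""Canonical ring-conformer catalogs and nearest-conformer classification.

Five-membered rings have 20 canonical conformers (10 envelopes E and 10
twists T) on the pseudorotation circle, six-membered rings the 38 IUPAC
conformers (2 chairs C, 6 boats B, 6 skew-boats S, 12 envelopes E, 12
half-chairs H) on the puckering sphere, and seven-membered rings are
organised on three (phi2, phi3) planes at relative alternating
amplitudes q3 = 0.6 (chair/twist-chair), q3 = 0.0 (boat/twist-boat,
where the conformation depends on phi2 only -- the "harp" degeneracy)
and q3 = 0.4 (sofa/twist-sofa/sofa-boat).

Reference placements follow the conventional Mercator layout for N=6:
chairs at the poles (the north pole, theta = 0, is 4C1), boats and
skew-boats on the equator at 30-degree spacing, envelopes and
half-chairs on the tetrahedral bands theta = 54.74/125.26 degrees, with
E/B on even multiples of 30 degrees in phi and H/S on odd multiples.
Names for every non-chair conformer are derived constructively from the
sign pattern of the out-of-plane displacements at the reference point
(atoms above the plane become superscripts, atoms below subscripts;
the ring heteroatom, position N, renders as "O").  The seven-membered
grids follow the symmetry sites of the two contributing harmonics; the
label grammar and plane layout are this package's documented
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ring_pucker import PuckeringState, inverse_displacements

__all__ = ["ConformerLabel", "enumerate_catalog", "classify", "canonical_state"]

#: polar angle of the envelope / half-chair bands (degrees)
THETA_BAND = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))

#: relative alternating amplitudes of the three seven-ring planes
SEVEN_RING_PLANES = (0.6, 0.0, 0.4)

#: plane-assignment boundaries (midpoints between 0.0, 0.4 and 0.6)
SEVEN_RING_BOUNDS = (0.2, 0.5)


@dataclass(frozen=True)
class ConformerLabel:
    """One canonical conformer: name, family and reference coordinates."""

    n_atoms: int
    family: str
    superscript: tuple[int, ...]
    subscript: tuple[int, ...]
    name: str
    ref_state: PuckeringState

    def __repr__(self) -> str:  # keep frozen-dataclass repr short
        return f"ConformerLabel({self.name!r})"


def _pos_str(p: int, n: int) -> str:
    return "O" if p == n else str(p)


def _render(sup: tuple[int, ...], family: str, sub: tuple[int, ...], n: int) -> str:
    s_up = ",".join(_pos_str(p, n) for p in sorted(sup))
    s_dn = ",".join(_pos_str(p, n) for p in sorted(sub))
    return f"{s_up}{family}{s_dn}"


def _state5(phi2: float) -> PuckeringState:
    phi2 %= 360.0
    a, b = np.sin(np.radians(phi2)), np.cos(np.radians(phi2))
    return PuckeringState(n_atoms=5, q=np.array([1.0]), phi=np.array([phi2]),
                          A=np.array([a]), B=np.array([b]))

def _state6(theta: float, phi2: float) -> PuckeringState:
    phi2 %= 360.0
    q2 = float(np.sin(np.radians(theta)))
    q3s = float(np.cos(np.radians(theta)))
    a, b = q2 * np.sin(np.radians(phi2)), q2 * np.cos(np.radians(phi2))
    return PuckeringState(n_atoms=6, q=np.array([q2, abs(q3s)]),
                          phi=np.array([phi2]), A=np.array([a]), B=np.array([b]),
                          Q=1.0, theta=float(theta))

def _state7(q3n: float, phi2: float, phi3: float) -> PuckeringState:
    phi2 %= 360.0
    phi3 %= 360.0
    q2 = float(np.sqrt(1.0 - q3n * q3n))
    qs = np.array([q2, q3n])
    phis = np.array([phi2, phi3])
    return PuckeringState(n_atoms=7, q=qs, phi=phis,
                          A=qs * np.sin(np.radians(phis)),
                          B=qs * np.cos(np.radians(phis)))


def _ring_pos(j: int, off: int, n: int) -> int:
    """1-based ring position j shifted by off, wrapped to 1..n."""
    return (j - 1 + off) % n + 1


# ---------------------------------------------------------------------------
# constructive naming helpers (superscript = positive displacement)

def _envelope_parts(z: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    j = int(np.argmax(np.abs(z)))
    return ((j + 1,), ()) if z[j] > 0 else ((), (j + 1,))


def _twist_parts(z: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    n = len(z)
    pair = max(range(n), key=lambda k: abs(z[k]) + abs(z[(k + 1) % n]))
    a, b = pair, (pair + 1) % n
    if z[a] < z[b]:
        a, b = b, a
    return (a + 1,), (b + 1,)


def _boat_parts(z: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    k = max(range(3), key=lambda k: abs(z[k] + z[k + 3]))
    pair = (k + 1, k + 4)
    return (pair, ()) if z[k] > 0 else ((), pair)


def _skew_parts(z: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    # two atoms up, two down, two in plane; the name takes one up and one
    # down atom separated by one in-plane atom, choosing the candidate
    # pair that contains the lowest ring position
    up = [j for j in range(6) if z[j] > 0.1]
    dn = [j for j in range(6) if z[j] < -0.1]
    cands = [(u, d) for u in up for d in dn if (u - d) % 6 in (2, 4)]
    u, d = min(cands, key=lambda p: min(p))
    return (u + 1,), (d + 1,)


def _unit_z(state: PuckeringState) -> np.ndarray:
    return inverse_displacements(state).z


# ---------------------------------------------------------------------------
# catalog enumeration

def _catalog5() -> list[ConformerLabel]:
    out = []
    for k in range(20):
        phi2 = 18.0 * k
        st = _state5(phi2)
        z = _unit_z(st)
        if k % 2 == 0:  # mirror-symmetric grid point: envelope
            family = "E"
            sup, sub = _envelope_parts(z)
        else:           # two-fold grid point: twist
            family = "T"
            sup, sub = _twist_parts(z)
        out.append(ConformerLabel(5, family, sup, sub,
                                  _render(sup, family, sub, 5), st))
    return out


def _catalog6() -> list[ConformerLabel]:
    out = [
        ConformerLabel(6, "C", (4,), (1,), "4C1", _state6(0.0, 0.0)),
        ConformerLabel(6, "C", (1,), (4,), "1C4", _state6(180.0, 0.0)),
    ]
    for theta in (THETA_BAND, 180.0 - THETA_BAND):   # E/H bands
        for k in range(12):
            phi2 = 30.0 * k
            st = _state6(theta, phi2)
            z = _unit_z(st)
            if k % 2 == 0:
                family = "E"
                sup, sub = _envelope_parts(z)
            else:
                family = "H"
                sup, sub = _twist_parts(z)
            out.append(ConformerLabel(6, family, sup, sub,
                                      _render(sup, family, sub, 6), st))
    for k in range(12):                              # equator
        phi2 = 30.0 * k
        st = _state6(90.0, phi2)
        z = _unit_z(st)
        if k % 2 == 0:
            family = "B"
            sup, sub = _boat_parts(z)
        else:
            family = "S"
            sup, sub = _skew_parts(z)
        out.append(ConformerLabel(6, family, sup, sub,
                                  _render(sup, family, sub, 6), st))
    return out


def _catalog7() -> list[ConformerLabel]:
    """Seven-ring catalog on the three canonical planes.

    Grid points sit at the symmetry sites of the two contributing
    harmonics: phase offsets (0, 0)/(180, 180) about ring atom j are
    mirror-symmetric through that atom, offsets (90, 90)/(270, 270) are
    two-fold, and the mixed offsets (0, 180)/(180, 0) are
    mirror-symmetric through the opposite bond midpoint (used for the
    sofa-boats).  Names follow fixed positional rules relative to the
    symmetry atom so that, e.g., the twist-chair with its two-fold axis
    through atom 1 is 3,4TC5,6.
    """
    out: list[ConformerLabel] = []

    def pair(j: int, o1: int, o2: int) -> tuple[int, int]:
        return (_ring_pos(j, o1, 7), _ring_pos(j, o2, 7))

    def add(family: str, q3n: float, j: int, off2: float, off3: float,
            sup: tuple[int, ...], sub: tuple[int, ...]) -> None:
        base2 = -720.0 / 7.0 * (j - 1)
        base3 = -1080.0 / 7.0 * (j - 1)
        st = _state7(q3n, base2 + off2, base3 + off3)
        out.append(ConformerLabel(7, family, sup, sub,
                                  _render(sup, family, sub, 7), st))

    for j in range(1, 8):
        nbrs = pair(j, -1, 1)           # ring neighbours of the mirror atom
        mid = pair(j, 2, 3)             # leading pair for two-fold forms
        trail = pair(j, 4, 5)
        opp = pair(j, 3, 4)             # atoms flanking the opposite bond
        far = pair(j, 2, 5)
        # chair / twist-chair plane
        add("C", 0.6, j, 0, 0, (j,), nbrs)
        add("C", 0.6, j, 180, 180, nbrs, (j,))
        add("TC", 0.6, j, 90, 90, mid, trail)
        add("TC", 0.6, j, 270, 270, trail, mid)
        # boat / twist-boat plane (phi3 immaterial at q3 = 0)
        add("B", 0.0, j, 0, 0, (j,), far)
        add("B", 0.0, j, 180, 180, far, (j,))
        add("TB", 0.0, j, 90, 90, mid, trail)
        add("TB", 0.0, j, 270, 270, trail, mid)
        # sofa / twist-sofa / sofa-boat plane
        add("S", 0.4, j, 0, 0, (j,), ())
        add("S", 0.4, j, 180, 180, (), (j,))
        add("TS", 0.4, j, 90, 90, mid, trail)
        add("TS", 0.4, j, 270, 270, trail, mid)
        add("SB", 0.4, j, 0, 180, opp, far)
        add("SB", 0.4, j, 180, 0, far, opp)
    return out


_CACHE: dict[int, list[ConformerLabel]] = {}


def enumerate_catalog(n_atoms: int) -> list[ConformerLabel]:
    """All canonical conformers of an N-membered ring, in fixed order.

    Returns 20 labels for N=5, 38 for N=6 and 98 for N=7 (14 per family
    on the three planes).  The ordering is deterministic and is the
    tie-breaking order used by :func:`classify`.
    """
    if n_atoms not in (5, 6, 7):
        raise ValueError(f"no conformer catalog for ring size {n_atoms}")
    if n_atoms not in _CACHE:
        _CACHE[n_atoms] = {5: _catalog5, 6: _catalog6, 7: _catalog7}[n_atoms]()
    return list(_CACHE[n_atoms])


# ---------------------------------------------------------------------------
# classification

def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify(
    state: PuckeringState, min_amplitude: float = 1e-3
) -> ConformerLabel | None:
    """Nearest canonical conformer of a puckering state.

    Distances are angular only, so the assignment is invariant to the
    overall puckering amplitude: circular distance in phi2 for N=5,
    great-circle distance on the (theta, phi) sphere for N=6, and for
    N=7 nearest-plane assignment on the normalised alternating
    amplitude (boundaries 0.2 and 0.5) followed by grid distance in
    (phi2, phi3) -- phi2 alone on the q3 = 0 plane, where phi3 does not
    change the shape.  States with total amplitude below
    ``min_amplitude`` (Angstrom) are planar: returns None.  Ties break
    to the earlier catalog entry.

    Phases must come from the standard arctangent convention.
    """
    if state.total_amplitude < min_amplitude:
        return None
    labels = enumerate_catalog(state.n_atoms)

    if state.n_atoms == 5:
        key = lambda lab: _circ_dist(state.phi2, lab.ref_state.phi2)
    elif state.n_atoms == 6:
        th1, ph1 = np.radians(state.theta), np.radians(state.phi2)

        def key(lab: ConformerLabel) -> float:
            th2 = np.radians(lab.ref_state.theta)
            ph2 = np.radians(lab.ref_state.phi2)
            c = (np.cos(th1) * np.cos(th2)
                 + np.sin(th1) * np.sin(th2) * np.cos(ph1 - ph2))
            return float(np.arccos(np.clip(c, -1.0, 1.0)))
    else:
        q3n = state.q3 / state.total_amplitude
        lo, hi = SEVEN_RING_BOUNDS
        plane = 0.0 if q3n < lo else (0.4 if q3n < hi else 0.6)
        labels = [lab for lab in labels
                  if abs(lab.ref_state.q3 - plane) < 1e-9]
        if plane == 0.0:
            key = lambda lab: _circ_dist(state.phi2, lab.ref_state.phi2)
        else:
            key = lambda lab: float(np.hypot(
                _circ_dist(state.phi2, lab.ref_state.phi2),
                _circ_dist(state.phi3, lab.ref_state.phi3)))
    return min(labels, key=key)  # ties resolve to the earlier entry


def canonical_state(label: ConformerLabel, amplitude: float) -> PuckeringState:
    """Reference puckering coordinates of a catalog label, scaled to the
    requested total amplitude (Angstrom).

    classify(canonical_state(L, a)) == L for every catalog entry and
    any amplitude above the planar threshold.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    ref = label.ref_state
    s = amplitude / ref.total_amplitude
    return PuckeringState(
        n_atoms=ref.n_atoms,
        q=ref.q * s,
        phi=ref.phi.copy(),
        A=ref.A * s,
        B=ref.B * s,
        Q=None if ref.Q is None else ref.Q * s,
        theta=ref.theta,
        epsilon=ref.epsilon,
        phase_mode=ref.phase_mode,
    )


def find_label(n_atoms: int, name: str) -> ConformerLabel:
    """Look a conformer up by rendered name (raises KeyError if absent)."""
    for lab in enumerate_catalog(n_atoms):
        if lab.name == name:
            return lab
    raise KeyError(f"no conformer named {name!r} for ring size {n_atoms}")
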