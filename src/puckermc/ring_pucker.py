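"""Cremer-Pople ring puckering coordinates.

An N-membered ring deviates from planarity in N-3 independent ways.
Cremer and Pople (1975) parameterise those deviations by projecting the
out-of-plane displacements ``z_j`` of the ring atoms (measured from a
uniquely defined mean plane through the geometric centre) onto ring
Fourier harmonics, giving puckering amplitudes ``q_m`` (in Angstrom) and
phase angles ``phi_m`` (degrees).  For six-membered rings the pair
(q2, q3) is usually re-expressed in polar form as a total amplitude Q
and polar angle theta, so that every conformation is a point on a
sphere: chairs at the poles, boats and skew-boats on the equator.

Ring atoms are numbered 1..N with position 1 the anomeric carbon and
position N the ring heteroatom; intermediate positions are consecutively
bonded.  All lengths are Angstrom and all angles cross the API boundary
in degrees.

Two phase conventions are provided (see :func:`phase_angle`): the
conventional two-argument arctangent ("standard", the default) and an
arccos-based reconstruction ("paper") built only from operators
available to quantum-chemistry generalized-internal-coordinate (GIC)
interfaces; the two differ by a constant 180 degrees away from the
A_m = 0 seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidRingError",
    "RingAtomSet",
    "Displacements",
    "PuckeringState",
    "mean_plane_displacements",
    "forward_pucker",
    "phase_angle",
    "inverse_displacements",
    "emit_gic_definitions",
]

#: smallest / largest distance (Angstrom) accepted between bonded ring atoms
BOND_WINDOW = (1.2, 2.0)

#: total puckering amplitude below which a ring is reported as planar
PLANAR_AMPLITUDE = 1e-10


class InvalidRingError(ValueError):
    """Raised for geometrically degenerate or mis-specified rings."""


@dataclass
class RingAtomSet:
    """Ordered Cartesian coordinates of the ring atoms.

    Parameters
    ----------
    coords : (N, 3) array
        Cartesian positions in Angstrom, ordered by ring position:
        index 0 is ring position 1 (the anomeric carbon), index N-1 is
        the heteroatom.
    labels : sequence of str, optional
        Element symbols per ring position; defaults to carbons with a
        trailing ``"X"`` placeholder.
    """

    coords: np.ndarray
    labels: tuple[str, ...] = ()
    validate: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidRingError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n not in (5, 6, 7):
            raise InvalidRingError(f"ring size must be 5, 6 or 7, got {n}")
        if not self.labels:
            self.labels = tuple(["C"] * (n - 1) + ["X"])
        if len(self.labels) != n:
            raise InvalidRingError("labels length must equal ring size")
        if self.validate:
            d = np.linalg.norm(np.roll(self.coords, -1, axis=0) - self.coords, axis=1)
            lo, hi = BOND_WINDOW
            if np.any(d < lo) or np.any(d > hi):
                raise InvalidRingError(
                    "consecutive ring atoms outside the bonded-distance "
                    f"window [{lo}, {hi}] A: distances {np.round(d, 3)}"
                )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Displacements:
    """Out-of-plane displacements z_j from the Cremer-Pople mean plane."""

    z: np.ndarray
    n_atoms: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.n_atoms == 0:
            self.n_atoms = self.z.shape[0]
        if self.z.shape != (self.n_atoms,):
            raise InvalidRingError("z must have one entry per ring atom")


@dataclass
class PuckeringState:
    """Puckering amplitudes and phases of one ring conformation.

    ``q`` holds q_m for m = 2 .. floor(N/2) (so [q2] for N=5, [q2, q3]
    for N=6 and N=7); amplitudes are non-negative.  ``phi`` holds phi_m
    in degrees in [0, 360) for m = 2 .. ceil((N-1)/2) (so [phi2] for
    N=5 and N=6, [phi2, phi3] for N=7).  For N=6 the polar form
    (``Q``, ``theta``) is populated; theta in [0, 180] carries the sign
    of the alternating q3 projection, with theta = 0 the chair that
    displaces atom 1 upward.  ``A``/``B`` retain the raw harmonic
    projections for the phase-bearing indices.
    """

    n_atoms: int
    q: np.ndarray
    phi: np.ndarray
    A: np.ndarray = field(default_factory=lambda: np.zeros(0))
    B: np.ndarray = field(default_factory=lambda: np.zeros(0))
    Q: float | None = None
    theta: float | None = None
    epsilon: float = 1e-6
    planar: bool = False
    phase_mode: str = "standard"

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))

    # convenient scalar views -------------------------------------------------
    @property
    def q2(self) -> float:
        return float(self.q[0])

    @property
    def q3(self) -> float:
        if self.n_atoms == 5:
            raise AttributeError("q3 undefined for five-membered rings")
        return float(self.q[1])

    @property
    def phi2(self) -> float:
        return float(self.phi[0])

    @property
    def phi3(self) -> float:
        if self.n_atoms != 7:
            raise AttributeError("phi3 only defined for seven-membered rings")
        return float(self.phi[1])

    @property
    def total_amplitude(self) -> float:
        """Root-sum-square of all puckering amplitudes (Q for N=6)."""
        return float(np.sqrt(np.sum(self.q**2)))

    def q3_signed(self) -> float:
        """Signed alternating amplitude (even N); sign lives in theta."""
        if self.n_atoms != 6:
            raise AttributeError("signed q3 only defined for six-membered rings")
        return float(self.Q * np.cos(np.radians(self.theta)))


def mean_plane_displacements(ring: RingAtomSet) -> Displacements:
    """Perpendicular displacements of ring atoms from the mean plane.

    The mean plane passes through the geometric centre of the ring and
    is oriented so that the first-harmonic sine and cosine projections
    of the displacements vanish:

        sum_j z_j = 0,
        sum_j z_j cos(2 pi (j-1)/N) = 0,
        sum_j z_j sin(2 pi (j-1)/N) = 0.

    The result is invariant under rigid translation and rotation of the
    input coordinates.

    Raises
    ------
    InvalidRingError
        If the geometry is degenerate (collinear atoms, coincident
        atoms) so that no plane orientation is defined.
    """
    n = ring.n_atoms
    r = ring.coords - ring.coords.mean(axis=0)
    ang = 2.0 * np.pi * np.arange(n) / n
    r_prime = (r * np.sin(ang)[:, None]).sum(axis=0)
    r_dprime = (r * np.cos(ang)[:, None]).sum(axis=0)
    normal = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(normal)
    if norm < 1e-10:
        raise InvalidRingError("degenerate ring geometry: mean plane undefined")
    z = r @ (normal / norm)
    return Displacements(z=z, n_atoms=n)


def phase_angle(
    A: float, B: float, epsilon: float = 1e-6, mode: str = "standard"
) -> float:
    """Puckering phase angle, degrees, from the harmonic projections.

    mode="standard"
        Two-argument arctangent of (A, B) mapped to [0, 360).  The
        degenerate point A = B = 0 returns 0 by convention.
    mode="paper"
        arccos-based reconstruction usable where no arctangent is
        available (GIC interfaces):

            phi = A / sqrt(A^2 + eps) * arccos(B / sqrt(A^2 + B^2)) + 180

        The epsilon guard (default 1e-6) keeps the smoothed sign factor
        finite at A = 0; the degenerate point returns 180.  For
        non-degenerate input this mode differs from "standard" by a
        constant 180 degrees (mod 360).
    """
    if mode == "standard":
        if A == 0.0 and B == 0.0:
            return 0.0
        return float(np.degrees(np.arctan2(A, B)) % 360.0)
    if mode == "paper":
        if A == 0.0 and B == 0.0:
            return 180.0
        r = np.hypot(A, B)
        sign = A / np.sqrt(A * A + epsilon)
        return float(sign * np.degrees(np.arccos(B / r)) + 180.0)
    raise ValueError(f"unknown phase mode {mode!r}")


def forward_pucker(
    z: Displacements,
    n_atoms: int | None = None,
    *,
    phase_mode: str = "standard",
    epsilon: float = 1e-6,
) -> PuckeringState:
    """Puckering amplitudes and phases from out-of-plane displacements.

    Projects z_j onto the ring harmonics,

        B_m =  (2/N)^(1/2) sum_j z_j cos(2 pi m (j-1)/N) = q_m cos phi_m
        A_m = -(2/N)^(1/2) sum_j z_j sin(2 pi m (j-1)/N) = q_m sin phi_m

    for m = 2 .. ceil((N-1)/2), plus, for even N, the alternating sum

        q_(N/2) = N^(-1/2) sum_j (-1)^(j-1) z_j

    which is signed; its magnitude is stored in ``q`` and its sign is
    folded into the polar angle theta = arccos(q3_signed / Q) for N=6.
    """
    if n_atoms is None:
        n_atoms = z.n_atoms
    if n_atoms != z.n_atoms:
        raise InvalidRingError(
            f"n_atoms={n_atoms} inconsistent with {z.n_atoms} displacements"
        )
    n = n_atoms
    zv = z.z
    j = np.arange(n)
    phase_ms = list(range(2, (n - 1) // 2 + 1))  # m = 2 .. floor((N-1)/2)
    pref = np.sqrt(2.0 / n)
    A, B, q, phi = [], [], [], []
    for m in phase_ms:
        w = 2.0 * np.pi * m * j / n
        Bm = pref * float(np.sum(zv * np.cos(w)))
        Am = -pref * float(np.sum(zv * np.sin(w)))
        A.append(Am)
        B.append(Bm)
        q.append(float(np.hypot(Am, Bm)))
    Qpol = theta = None
    if n % 2 == 0:
        q_half = float(np.sum(zv * (-1.0) ** j) / np.sqrt(n))
        Qpol = float(np.sqrt(q[0] ** 2 + q_half**2))
        theta = float(np.degrees(np.arccos(q_half / Qpol))) if Qpol > 0 else 0.0
        q.append(abs(q_half))
    planar = float(np.sqrt(np.sum(np.square(q)))) < PLANAR_AMPLITUDE
    if planar:
        phi = [0.0] * len(phase_ms)
    else:
        phi = [phase_angle(a, b, epsilon=epsilon, mode=phase_mode) for a, b in zip(A, B)]
    return PuckeringState(
        n_atoms=n,
        q=np.array(q),
        phi=np.array(phi),
        A=np.array(A),
        B=np.array(B),
        Q=Qpol,
        theta=theta,
        epsilon=epsilon,
        planar=planar,
        phase_mode=phase_mode,
    )


def inverse_displacements(state: PuckeringState) -> Displacements:
    """Out-of-plane displacements realising a puckering state.

    Inverse of :func:`forward_pucker`:

        z_j = (2/N)^(1/2) sum_m q_m cos(phi_m + 2 pi m (j-1)/N)
              [+ N^(-1/2) q3_signed (-1)^(j-1)   for even N]

    with phases interpreted in the state's own convention, so that the
    forward transform of the result reproduces the state.
    """
    n = state.n_atoms
    j = np.arange(n)
    z = np.zeros(n)
    phase_ms = list(range(2, (n - 1) // 2 + 1))
    offset = 180.0 if state.phase_mode == "paper" else 0.0
    for i, m in enumerate(phase_ms):
        phi = np.radians(state.phi[i] - offset)
        z += np.sqrt(2.0 / n) * state.q[i] * np.cos(phi + 2.0 * np.pi * m * j / n)
    if n % 2 == 0:
        z += state.q3_signed() * (-1.0) ** j / np.sqrt(n)
    return Displacements(z=z, n_atoms=n)


# ---------------------------------------------------------------------------
# GIC text emission

def _lincomb(terms: list[tuple[float, str]]) -> str:
    """Render sum of coeff*symbol with fixed 12-decimal coefficients."""
    parts = []
    for c, s in terms:
        if abs(c) < 5e-13:
            continue
        sign = "-" if c < 0 else ("+" if parts else "")
        parts.append(f"{sign}{abs(c):.12f}*{s}")
    return "".join(parts) if parts else "0.0"


def emit_gic_definitions(n_atoms: int, atom_indices: list[int]) -> str:
    """Generalized-internal-coordinate definitions of the puckering
    coordinates for a quantum-chemistry input deck.

    The emitted block defines, for the given ring atoms, the recentred
    out-of-plane coordinates, the harmonic projections A_m/B_m, the
    amplitudes q_m and the arccos-based phases (with the 1e-6 guard),
    plus Q and theta for six-membered rings.  Only centre-of-geometry
    functions, arithmetic, SQRT and ACOS appear -- no arctangent.  The
    keyword spelling of the ``(Add)`` block is best-effort for current
    GIC dialects; the mathematical content is dialect-independent.

    Output is deterministic (byte-identical for identical input).
    """
    idx = list(atom_indices)
    if len(idx) != n_atoms:
        raise ValueError("atom_indices length must equal n_atoms")
    if len(set(idx)) != len(idx) or any(i < 1 for i in idx):
        raise ValueError("atom indices must be distinct positive integers")
    n = n_atoms
    atoms = ",".join(str(i) for i in idx)
    lines = [
        f"! puckering GICs for the {n}-membered ring over atoms {atoms}",
        "! phases use the smoothed-sign arccos form with eps = 1.0e-6",
    ]
    # recentred out-of-plane coordinate of each ring atom
    for k, i in enumerate(idx, start=1):
        lines.append(f"ZR{k}(Add) = Z({i}) - ZCntr({atoms})")
    pref = np.sqrt(2.0 / n)
    phase_ms = list(range(2, (n - 1) // 2 + 1))
    for m in phase_ms:
        bterms = [
            (pref * np.cos(2 * np.pi * m * k / n), f"ZR{k + 1}") for k in range(n)
        ]
        aterms = [
            (-pref * np.sin(2 * np.pi * m * k / n), f"ZR{k + 1}") for k in range(n)
        ]
        lines.append(f"B{m}(Add) = {_lincomb(bterms)}")
        lines.append(f"A{m}(Add) = {_lincomb(aterms)}")
        lines.append(f"Q{m}(Add) = SQRT(A{m}*A{m}+B{m}*B{m})")
        lines.append(
            f"PHI{m}(Add) = A{m}/SQRT(A{m}*A{m}+0.000001)"
            f"*ACOS(B{m}/SQRT(A{m}*A{m}+B{m}*B{m}))+180.0"
        )
    if n % 2 == 0:
        hterms = [
            ((-1.0) ** k / np.sqrt(n), f"ZR{k + 1}") for k in range(n)
        ]
        lines.append(f"Q{n // 2}S(Add) = {_lincomb(hterms)}")
        lines.append(f"QTOT(Add) = SQRT(Q2*Q2+Q{n // 2}S*Q{n // 2}S)")
        lines.append(f"THETA(Add) = ACOS(Q{n // 2}S/QTOT)")
    return "\n".join(lines) + "\n"
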