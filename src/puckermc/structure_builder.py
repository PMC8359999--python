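"""Three-dimensional ring construction, dihedral libraries and Z-matrices.

Bridges the abstract puckering description and concrete molecules:

* :func:`build_ring_geometry` realises a puckering state as ring
  Cartesian coordinates for a given ring template (bond lengths per
  heteroatom), by fixing the out-of-plane displacements from the
  inverse puckering transform and closing the in-plane polygon by a
  one-dimensional search on the common polygon radius.
* :func:`build_dihedral_library` tabulates, for every canonical
  conformer of a template, the N-3 endocyclic dihedral angles that
  reproduce it -- the package's idealized-geometry stand-in for
  scan-derived dihedral tables, which remain importable through
  :func:`read_library_files`.
* :func:`attach_substituents` decorates a ring with functional groups
  and hydrogens and assembles a Z-matrix whose named variables are the
  endocyclic dihedrals (D1..D(N-3)), one rotamer dihedral per rotatable
  exocyclic bond, and the discrete equatorial/axial hydrogen of N-H and
  P-H ring heteroatoms.

Rings follow the C_N H_2N X formula with X one of CH2, O, S, SO2, NH,
BH, PH; substituted positions trade hydrogens for groups.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .conformer_catalog import ConformerLabel
from .ring_pucker import (
    InvalidRingError,
    PuckeringState,
    RingAtomSet,
    inverse_displacements,
)

__all__ = [
    "RingTemplate",
    "SubstituentSpec",
    "MoleculeSpec",
    "DihedralLibrary",
    "ZMatrix",
    "ZRow",
    "RingClosureError",
    "build_ring_geometry",
    "endocyclic_dihedrals",
    "bond_angle",
    "dihedral_angle",
    "build_dihedral_library",
    "read_library_files",
    "read_var_file",
    "attach_substituents",
    "default_group_params",
]

# ---------------------------------------------------------------------------
# templates

#: ring heteroatom -> (element, number of attached hydrogens)
HETEROATOMS = {
    "CH2": ("C", 2),
    "O": ("O", 0),
    "S": ("S", 0),
    "SO2": ("S", 0),  # two oxo oxygens, placed by the tetrahedral rule
    "NH": ("N", 1),
    "BH": ("B", 1),
    "PH": ("P", 1),
}

#: default carbon--heteroatom bond length, Angstrom
_CX_BOND = {"CH2": 1.54, "O": 1.43, "S": 1.82, "SO2": 1.82,
            "NH": 1.47, "BH": 1.57, "PH": 1.85}

_CC_BOND = 1.54

#: supported substituent groups and their rotatable-bond counts
GROUP_ROTATABLE = {"OH": 1, "CH3": 1, "OCH3": 2, "CH2OH": 2, "NH2": 1,
                   "F": 0, "H": 0}


class RingClosureError(RuntimeError):
    """Raised when no planar polygon closes under the requested pucker."""


@dataclass
class RingTemplate:
    """Idealized geometry of an unsubstituted C_(N-1) X ring.

    ``bond_lengths[k]`` is the target length of the cyclic edge from
    ring position k+1 to k+2 (the last entry closes heteroatom to
    position 1).  ``bond_angles`` are idealized vertex angles, used for
    initial guesses and substituent geometry, not enforced in closure.
    """

    n_atoms: int
    heteroatom: str = "CH2"
    bond_lengths: np.ndarray | None = None
    bond_angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_atoms not in (5, 6, 7):
            raise ValueError("ring size must be 5, 6 or 7")
        if self.heteroatom not in HETEROATOMS:
            raise ValueError(
                f"heteroatom must be one of {sorted(HETEROATOMS)}, "
                f"got {self.heteroatom!r}"
            )
        n = self.n_atoms
        if self.bond_lengths is None:
            cx = _CX_BOND[self.heteroatom]
            self.bond_lengths = np.array([_CC_BOND] * (n - 2) + [cx, cx])
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        if self.bond_lengths.shape != (n,):
            raise ValueError("bond_lengths needs one entry per cyclic edge")
        if np.any(self.bond_lengths < 1.3) or np.any(self.bond_lengths > 2.0):
            raise ValueError("bond lengths outside [1.3, 2.0] A")
        if self.bond_angles is None:
            self.bond_angles = np.full(n, 180.0 * (n - 2) / n - (10.0 if n > 5 else 5.0))
        self.bond_angles = np.asarray(self.bond_angles, dtype=float)
        if self.bond_angles.shape != (n,):
            raise ValueError("bond_angles needs one entry per ring vertex")
        if np.any(self.bond_angles < 85.0) or np.any(self.bond_angles > 135.0):
            raise ValueError("bond angles outside [85, 135] degrees")

    @property
    def het_element(self) -> str:
        return HETEROATOMS[self.heteroatom][0]

    @property
    def het_hydrogens(self) -> int:
        return HETEROATOMS[self.heteroatom][1]

    @property
    def elements(self) -> list[str]:
        return ["C"] * (self.n_atoms - 1) + [self.het_element]

    @property
    def library_key(self) -> tuple[int, str, int]:
        return (self.n_atoms, self.heteroatom, self.het_hydrogens)


@dataclass(frozen=True)
class SubstituentSpec:
    """One exocyclic group: ring position, identity, face, flexibility."""

    position: int
    group: str
    orientation: str = "up"
    rotatable: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUP_ROTATABLE:
            raise ValueError(f"unknown substituent group {self.group!r}")
        if self.orientation not in ("up", "down"):
            raise ValueError("orientation must be 'up' or 'down'")


@dataclass
class MoleculeSpec:
    """A ring template plus its substituents -- one molecule to sample."""

    template: RingTemplate
    substituents: tuple[SubstituentSpec, ...] = ()
    name: str = "ring"

    def __post_init__(self) -> None:
        self.substituents = tuple(self.substituents)
        n = self.template.n_atoms
        per_pos: dict[tuple[int, str], int] = {}
        for s in self.substituents:
            if not 1 <= s.position <= n:
                raise ValueError(f"substituent position {s.position} outside ring")
            slots = 2 if (s.position < n or self.template.heteroatom == "CH2") else 0
            if slots == 0:
                raise ValueError(
                    f"ring heteroatom {self.template.heteroatom} has no open "
                    "valence for substituents"
                )
            key = (s.position, s.orientation)
            per_pos[key] = per_pos.get(key, 0) + 1
            if per_pos[key] > 1:
                raise ValueError(
                    f"two substituents on the same face of position {s.position}"
                )


@dataclass
class DihedralLibrary:
    """Mapping conformer -> endocyclic dihedral array for one template."""

    template_key: tuple[int, str, int]
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.template_key[0]
        for k, v in self.entries.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n - 3,):
                raise ValueError(
                    f"library entry {k!r} must hold {n - 3} dihedrals"
                )
            # wrap into (-180, 180]
            v = -((-v + 180.0) % 360.0 - 180.0)
            self.entries[k] = v

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys_ordered(self) -> list[str]:
        return list(self.entries)


# ---------------------------------------------------------------------------
# geometry primitives

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidRingError("zero-length vector in geometry construction")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in (-180, 180], IUPAC convention."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, _unit(b2))
    ang = float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))
    return 180.0 if ang <= -180.0 else ang


def _nerf(a, b, c, r: float, theta: float, phi: float) -> np.ndarray:
    """Place an atom at distance r from a, angle theta (deg) to b and
    dihedral phi (deg) to c, such that dihedral_angle(new, a, b, c) = phi."""
    th, ph = np.radians(theta), np.radians(phi)
    bc = _unit(a - b)
    n = _unit(np.cross(c - b, bc))
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(th),
                  -r * np.sin(th) * np.cos(ph),
                  r * np.sin(th) * np.sin(ph)])
    return a + d[0] * bc + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# ring construction

#: closure-feasibility bound on the total puckering amplitude, Angstrom
MAX_AMPLITUDE = 0.9


def build_ring_geometry(
    template: RingTemplate, state: PuckeringState
) -> RingAtomSet:
    """Ring Cartesian coordinates realising a puckering state.

    The out-of-plane displacements come straight from the inverse
    puckering transform, which makes the forward transform of the
    result exact by construction; the in-plane coordinates place the
    atoms on a circle of common radius s at azimuths accumulated from
    the bond-length constraints, and s is found by bisection so that
    the azimuth increments close the polygon (sum = 360 degrees).
    Bond lengths are then satisfied to machine precision; vertex angles
    are whatever closure dictates.

    Raises
    ------
    RingClosureError
        If the amplitude exceeds the feasibility bound (0.9 A) or no
        radius closes the ring within 500 bisection steps.
    """
    n = template.n_atoms
    if state.n_atoms != n:
        raise ValueError("template and state ring sizes differ")
    amp = state.total_amplitude
    if amp > MAX_AMPLITUDE:
        raise RingClosureError(
            f"puckering amplitude {amp:.3f} A exceeds the closure bound "
            f"{MAX_AMPLITUDE} A"
        )
    z = inverse_displacements(state).z
    lengths = template.bond_lengths
    dz = np.roll(z, -1) - z
    chord2 = lengths**2 - dz**2
    if np.any(chord2 <= 0):
        raise RingClosureError(
            f"amplitude {amp:.3f} A leaves no in-plane span for some bond"
        )

    def angle_sum(s: float) -> float:
        arg = 1.0 - chord2 / (2.0 * s * s)
        return float(np.sum(np.arccos(np.clip(arg, -1.0, 1.0))))

    # smallest radius at which every increment is defined (arg >= -1)
    s_lo = float(np.sqrt(chord2.max()) / 2.0) + 1e-12
    s_hi = float(lengths.sum())  # angle_sum -> 0 as s -> inf
    if angle_sum(s_lo) < 2.0 * np.pi:
        raise RingClosureError(
            f"ring cannot close at amplitude {amp:.3f} A with the given bonds"
        )
    for _ in range(500):
        s_mid = 0.5 * (s_lo + s_hi)
        if angle_sum(s_mid) > 2.0 * np.pi:
            s_lo = s_mid
        else:
            s_hi = s_mid
        if s_hi - s_lo < 1e-13:
            break
    s = 0.5 * (s_lo + s_hi)
    if abs(angle_sum(s) - 2.0 * np.pi) > 1e-6:
        raise RingClosureError(
            f"ring closure did not converge at amplitude {amp:.3f} A"
        )
    alpha = np.concatenate(
        ([0.0], np.cumsum(np.arccos(np.clip(1.0 - chord2 / (2 * s * s), -1, 1))))
    )[:n]
    # clockwise azimuths so the Cremer-Pople mean-plane normal (from the
    # first-harmonic cross product) points along +z, matching the sign
    # convention of the requested displacements
    coords = np.column_stack(
        (s * np.cos(alpha), -s * np.sin(alpha), z)
    )
    coords[:, :2] -= coords[:, :2].mean(axis=0)
    return RingAtomSet(coords=coords, labels=tuple(template.elements))


def endocyclic_dihedrals(ring: RingAtomSet) -> np.ndarray:
    """The N-3 endocyclic dihedrals D_k over atoms (k, k+1, k+2, k+3)."""
    c = ring.coords
    return np.array(
        [dihedral_angle(c[k], c[k + 1], c[k + 2], c[k + 3])
         for k in range(ring.n_atoms - 3)]
    )


def build_dihedral_library(
    template: RingTemplate,
    catalog: list[ConformerLabel],
    amplitude: float,
) -> DihedralLibrary:
    """Endocyclic dihedral arrays for every canonical conformer.

    Each catalog label is realised with :func:`build_ring_geometry` at
    the given total amplitude (Angstrom) and its N-3 dihedrals are
    recorded under the conformer name, in catalog order.
    """
    from .conformer_catalog import canonical_state

    entries: dict[str, np.ndarray] = {}
    for lab in catalog:
        if lab.n_atoms != template.n_atoms:
            raise ValueError("catalog and template ring sizes differ")
        try:
            ring = build_ring_geometry(template, canonical_state(lab, amplitude))
        except RingClosureError as exc:
            raise RingClosureError(f"conformer {lab.name}: {exc}") from exc
        entries[lab.name] = endocyclic_dihedrals(ring)
    return DihedralLibrary(template_key=template.library_key, entries=entries)


_DFILE_RE = re.compile(r"D(\d+)\.txt$")


def read_library_files(paths: list[str | Path]) -> DihedralLibrary:
    """Merge per-dihedral scan files (``N-x-H-y-X-D#.txt`` layout) into
    one dihedral library.

    Each file holds whitespace-delimited numeric rows: scan
    coordinate(s) followed by the value of one endocyclic dihedral D#.
    Files for D1..D(N-3) of the same ring must be given together; rows
    are matched by position and keyed by the scan coordinates of the
    first file.
    """
    if not paths:
        raise ValueError("no library files given")
    by_index: dict[int, Path] = {}
    ring_size = None
    for p in paths:
        p = Path(p)
        m = _DFILE_RE.search(p.name)
        if not m:
            raise ValueError(f"{p.name}: file name does not end in D#.txt")
        by_index[int(m.group(1))] = p
        m2 = re.match(r"N-(\d)-H-(\d)", p.name)
        if m2:
            ring_size = int(m2.group(1))
    n_d = max(by_index)
    if sorted(by_index) != list(range(1, n_d + 1)):
        missing = sorted(set(range(1, n_d + 1)) - set(by_index))
        raise ValueError(f"missing dihedral file(s) for D{missing}")
    if ring_size is None:
        ring_size = n_d + 3
    if n_d != ring_size - 3:
        raise ValueError(
            f"{n_d} dihedral files given but a {ring_size}-ring needs {ring_size - 3}"
        )
    tables = []
    for i in range(1, n_d + 1):
        path = by_index[i]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty files raise below
                tab = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path.name}: non-numeric content ({exc})") from exc
        if tab.size == 0:
            raise ValueError(f"{path.name}: empty file")
        tables.append(tab)
    rows = {t.shape[0] for t in tables}
    if len(rows) != 1:
        raise ValueError(f"row counts differ across dihedral files: {sorted(rows)}")
    entries: dict[str, np.ndarray] = {}
    first = tables[0]
    for r in range(first.shape[0]):
        coords = first[r, :-1]
        key = (
            "/".join(f"{c:g}" for c in coords) if coords.size else f"row{r + 1}"
        )
        if key in entries:
            key = f"{key}#{r + 1}"
        entries[key] = np.array([t[r, -1] for t in tables])
    return DihedralLibrary(
        template_key=(ring_size, "?", 0), entries=entries
    )


# ---------------------------------------------------------------------------
# group parameters

def read_var_file(path: str | Path) -> dict[str, float]:
    """Parse a ``key = number`` parameter file (group *.var grammar)."""
    out: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value {val!r}") from exc
    return out


_GROUP_PARAMS: dict[str, float] | None = None


def default_group_params() -> dict[str, float]:
    """Built-in idealized group geometry table (shipped groups.var)."""
    global _GROUP_PARAMS
    if _GROUP_PARAMS is None:
        with resources.as_file(
            resources.files("puckermc") / "data" / "groups.var"
        ) as p:
            _GROUP_PARAMS = read_var_file(p)
    return dict(_GROUP_PARAMS)


# ---------------------------------------------------------------------------
# Z-matrix

@dataclass
class ZRow:
    """One Z-matrix row; references are 1-based atom serials, values are
    numbers or variable names."""

    element: str
    ref_r: int = 0
    r: float | str = 0.0
    ref_a: int = 0
    a: float | str = 0.0
    ref_d: int = 0
    d: float | str = 0.0


@dataclass
class ZMatrix:
    """Internal-coordinate molecule with named sampling variables.

    ``variables`` maps variable name to current value; ``var_kinds``
    tags each as "endocyclic" (D1..), "rotamer" (R1..) or "hetflip".
    Charge 0 and multiplicity 1 throughout (neutral closed-shell
    molecules only).
    """

    rows: list[ZRow] = field(default_factory=list)
    variables: dict[str, float] = field(default_factory=dict)
    var_kinds: dict[str, str] = field(default_factory=dict)
    charge: int = 0
    multiplicity: int = 1
    ring_size: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.rows)

    def variable_names(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.variables)
        return [v for v in self.variables if self.var_kinds[v] == kind]

    def set_variable(self, name: str, value: float) -> None:
        if name not in self.variables:
            raise KeyError(f"unknown z-matrix variable {name!r}")
        self.variables[name] = float(value)

    def _value(self, v: float | str) -> float:
        return self.variables[v] if isinstance(v, str) else float(v)

    def to_cartesian(self) -> tuple[list[str], np.ndarray]:
        """Realise Cartesian coordinates (Angstrom) with the current
        variable values.  The first atom sits at the origin and the
        second on the +x axis; the third spans the xy plane."""
        coords = np.zeros((self.n_atoms, 3))
        els = []
        for i, row in enumerate(self.rows):
            els.append(row.element)
            if i == 0:
                continue
            if i == 1:
                coords[1] = [self._value(row.r), 0.0, 0.0]
                continue
            a = coords[row.ref_r - 1]
            b = coords[row.ref_a - 1]
            if i == 2:
                th = np.radians(self._value(row.a))
                direction = _unit(b - a)
                # rotate 'direction' by the bond angle within the xy plane
                perp = np.array([-direction[1], direction[0], 0.0])
                coords[2] = a + self._value(row.r) * (
                    np.cos(th) * direction + np.sin(th) * perp
                )
                continue
            c = coords[row.ref_d - 1]
            coords[i] = _nerf(
                a, b, c, self._value(row.r), self._value(row.a), self._value(row.d)
            )
        return els, coords

    def bonded_pairs(self) -> set[tuple[int, int]]:
        """0-based bonded pairs: every distance reference plus the ring
        closure bond."""
        pairs = {
            tuple(sorted((i, row.ref_r - 1)))
            for i, row in enumerate(self.rows)
            if i > 0
        }
        if self.ring_size:
            pairs.add((0, self.ring_size - 1))
        return pairs


# ---------------------------------------------------------------------------
# substituent attachment

_TET_HALF = 54.75  # half the ideal H-C-H angle, degrees


def _exo_directions(
    coords: np.ndarray, p: int, n: int, normal: np.ndarray, planar: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors of the two exocyclic valences at ring position p+1
    (0-based p), ordered (up, down) along the ring normal.  For planar
    centres (ring boron) both directions collapse onto the bisector."""
    u = _unit(coords[(p - 1) % n] - coords[p])
    v = _unit(coords[(p + 1) % n] - coords[p])
    bis = -_unit(u + v)
    if planar:
        return bis, bis
    w = _unit(np.cross(u, v))
    if w @ normal < 0:
        w = -w
    beta = np.radians(_TET_HALF)
    d_up = _unit(np.cos(beta) * bis + np.sin(beta) * w)
    d_dn = _unit(np.cos(beta) * bis - np.sin(beta) * w)
    return d_up, d_dn


def attach_substituents(
    ring: RingAtomSet,
    template: RingTemplate,
    subs: list[SubstituentSpec] | tuple[SubstituentSpec, ...] = (),
    params: dict[str, float] | None = None,
) -> ZMatrix:
    """Assemble the full-molecule Z-matrix for a decorated ring.

    Substituent heavy atoms are placed on idealized exocyclic
    directions (tetrahedral completion of the two ring bonds;
    "up"/"down" refers to the side of the ring mean plane), group
    internal geometry comes from the built-in parameter table, and
    every remaining valence is filled with hydrogen.  Row order: ring
    atoms 1..N, heteroatom attachments, substituents by ring position
    (up before down), filler hydrogens.  Named variables: D1..D(N-3)
    endocyclic; R1.. for each rotatable exocyclic dihedral in placement
    order; HFLIP for the N-H/P-H hydrogen (value +120 or -120).
    """
    MoleculeSpec(template=template, substituents=tuple(subs))  # validates
    par = default_group_params()
    if params:
        par.update(params)
    n = template.n_atoms
    coords: list[np.ndarray] = []  # grows as add_row places atoms
    rows: list[ZRow] = []
    variables: dict[str, float] = {}
    var_kinds: dict[str, str] = {}

    # mean-plane normal orients "up"
    r0 = ring.coords - ring.coords.mean(axis=0)
    ang = 2.0 * np.pi * np.arange(n) / n
    normal = _unit(np.cross((r0 * np.sin(ang)[:, None]).sum(axis=0),
                            (r0 * np.cos(ang)[:, None]).sum(axis=0)))

    def add_row(element: str, pos: np.ndarray, ref_r: int, ref_a: int = 0,
                ref_d: int = 0, d_var: str | None = None) -> int:
        """Append an atom; internal values measured from the geometry.
        References are 1-based serials of already-placed atoms."""
        i = len(coords)
        coords.append(pos)
        row = ZRow(element=element)
        if i >= 1:
            row.ref_r = ref_r
            row.r = float(np.linalg.norm(pos - coords[ref_r - 1]))
        if i >= 2:
            row.ref_a = ref_a
            row.a = bond_angle(pos, coords[ref_r - 1], coords[ref_a - 1])
        if i >= 3:
            row.ref_d = ref_d
            val = dihedral_angle(pos, coords[ref_r - 1],
                                 coords[ref_a - 1], coords[ref_d - 1])
            if d_var is not None:
                variables[d_var] = val
                row.d = d_var
            else:
                row.d = val
        rows.append(row)
        return i + 1  # 1-based serial

    def place(ref_r: int, ref_a: int, ref_d: int, r: float, a: float,
              d: float) -> np.ndarray:
        return _nerf(coords[ref_r - 1], coords[ref_a - 1], coords[ref_d - 1],
                     r, a, d)

    # --- ring atoms: chain with endocyclic dihedral variables
    els = template.elements
    for k in range(n):
        d_var = f"D{k - 2}" if k >= 3 else None
        add_row(els[k], ring.coords[k], ref_r=k, ref_a=k - 1, ref_d=k - 2,
                d_var=d_var)
        if d_var:
            var_kinds[d_var] = "endocyclic"

    rot_counter = 0

    def next_rotamer() -> str:
        nonlocal rot_counter
        rot_counter += 1
        name = f"R{rot_counter}"
        var_kinds[name] = "rotamer"
        return name

    def add_group(p: int, direction: np.ndarray, group: str,
                  rotatable: bool) -> None:
        """Place one substituent group on ring position p (1-based)."""
        serial_p = p
        ref_prev = p - 1 if p > 1 else n  # ring neighbour for torsion refs
        ref_prev2 = p - 2 if p > 2 else (n + p - 2)
        anchor = coords[p - 1]
        if group == "H":
            add_row("H", anchor + par["H.d_CH"] * direction,
                    serial_p, ref_prev, ref_prev2)
            return
        if group == "F":
            add_row("F", anchor + par["F.d_CF"] * direction,
                    serial_p, ref_prev, ref_prev2)
            return
        if group == "OH":
            s_o = add_row("O", anchor + par["OH.d_CO"] * direction,
                          serial_p, ref_prev, ref_prev2)
            var = next_rotamer() if rotatable else None
            h = place(s_o, serial_p, ref_prev, par["OH.d_OH"],
                      par["OH.a_HOC"], 180.0)
            add_row("H", h, s_o, serial_p, ref_prev, d_var=var)
            return
        if group == "NH2":
            s_n = add_row("N", anchor + par["NH2.d_CN"] * direction,
                          serial_p, ref_prev, ref_prev2)
            var = next_rotamer() if rotatable else None
            h1 = place(s_n, serial_p, ref_prev, par["NH2.d_NH"],
                       par["NH2.a_HNC"], 180.0)
            s_h1 = add_row("H", h1, s_n, serial_p, ref_prev, d_var=var)
            h2 = place(s_n, serial_p, s_h1, par["NH2.d_NH"],
                       par["NH2.a_HNC"], 120.0)
            add_row("H", h2, s_n, serial_p, s_h1)
            return
        if group == "CH3":
            s_c = add_row("C", anchor + par["CH3.d_CC"] * direction,
                          serial_p, ref_prev, ref_prev2)
            var = next_rotamer() if rotatable else None
            h1 = place(s_c, serial_p, ref_prev, par["CH3.d_CH"],
                       par["CH3.a_HCC"], 180.0)
            s_h1 = add_row("H", h1, s_c, serial_p, ref_prev, d_var=var)
            for sign in (120.0, -120.0):
                h = place(s_c, serial_p, s_h1, par["CH3.d_CH"],
                          par["CH3.a_HCC"], sign)
                add_row("H", h, s_c, serial_p, s_h1)
            return
        if group == "OCH3":
            s_o = add_row("O", anchor + par["OCH3.d_CO"] * direction,
                          serial_p, ref_prev, ref_prev2)
            var1 = next_rotamer() if rotatable else None
            c = place(s_o, serial_p, ref_prev, par["OCH3.d_OC"],
                      par["OCH3.a_COC"], 180.0)
            s_c = add_row("C", c, s_o, serial_p, ref_prev, d_var=var1)
            var2 = next_rotamer() if rotatable else None
            h1 = place(s_c, s_o, serial_p, par["OCH3.d_CH"],
                       par["OCH3.a_HCO"], 180.0)
            s_h1 = add_row("H", h1, s_c, s_o, serial_p, d_var=var2)
            for sign in (120.0, -120.0):
                h = place(s_c, s_o, s_h1, par["OCH3.d_CH"],
                          par["OCH3.a_HCO"], sign)
                add_row("H", h, s_c, s_o, s_h1)
            return
        if group == "CH2OH":
            s_c = add_row("C", anchor + par["CH2OH.d_CC"] * direction,
                          serial_p, ref_prev, ref_prev2)
            var1 = next_rotamer() if rotatable else None
            o = place(s_c, serial_p, ref_prev, par["CH2OH.d_CO"],
                      par["CH2OH.a_OCC"], 180.0)
            s_o = add_row("O", o, s_c, serial_p, ref_prev, d_var=var1)
            var2 = next_rotamer() if rotatable else None
            h = place(s_o, s_c, serial_p, par["CH2OH.d_OH"],
                      par["CH2OH.a_HOC"], 180.0)
            add_row("H", h, s_o, s_c, serial_p, d_var=var2)
            for sign in (120.0, -120.0):
                hc = place(s_c, serial_p, s_o, par["CH2OH.d_CH"],
                           par["CH2OH.a_HCC"], sign)
                add_row("H", hc, s_c, serial_p, s_o)
            return
        raise ValueError(f"unknown substituent group {group!r}")

    # --- heteroatom attachments (position N, serial n)
    het = template.heteroatom
    d_up, d_dn = _exo_directions(ring.coords, n - 1, n, normal,
                                 planar=(het == "BH"))
    if het == "SO2":
        for direction in (d_up, d_dn):
            add_row("O", ring.coords[n - 1] + par["HET.d_SO"] * direction,
                    n, n - 1, n - 2)
    elif het in ("NH", "PH"):
        dist = par[f"HET.d_{het[0]}H"]
        angle = par[f"HET.a_H{het[0]}C"]
        pos = place(n, n - 1, n - 2, dist, angle, 120.0)
        add_row("H", pos, n, n - 1, n - 2, d_var="HFLIP")
        var_kinds["HFLIP"] = "hetflip"
    elif het == "BH":
        add_row("H", ring.coords[n - 1] + par["HET.d_BH"] * d_up,
                n, n - 1, n - 2)
    # CH2: two plain hydrogens, O/S: nothing -- handled with fillers below

    # --- substituents, then remember which slots are taken
    taken: set[tuple[int, str]] = set()
    for s in sorted(subs, key=lambda s: (s.position, s.orientation != "up")):
        d_up_p, d_dn_p = _exo_directions(ring.coords, s.position - 1, n, normal)
        direction = d_up_p if s.orientation == "up" else d_dn_p
        add_group(s.position, direction, s.group, s.rotatable)
        taken.add((s.position, s.orientation))

    # --- filler hydrogens on every remaining open valence
    fill_positions = list(range(1, n)) + ([n] if het == "CH2" else [])
    for p in fill_positions:
        d_up_p, d_dn_p = _exo_directions(ring.coords, p - 1, n, normal)
        for orientation, direction in (("up", d_up_p), ("down", d_dn_p)):
            if (p, orientation) in taken:
                continue
            add_group(p, direction, "H", rotatable=False)

    return ZMatrix(rows=rows, variables=variables, var_kinds=var_kinds,
                   ring_size=n)
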