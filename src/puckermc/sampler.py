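"""Pseudo-random conformer batch generation.

Each generated conformer is assembled from independent draws:

* one uniform draw over the dihedral-library entries picks the ring
  conformation (the N-3 endocyclic dihedral angles of one canonical
  conformer);
* one uniform angle in [-180, 180] degrees per rotamer (exocyclic
  rotatable bond);
* for N-H / P-H ring heteroatoms, one draw from {-120, +120} degrees
  places the heteroatom hydrogen equatorial or axial.

Sampling is uniform over library entries -- over named conformations,
not over puckering phase space -- and energy plays no role: this is
random structure generation, not Metropolis sampling.  All randomness
flows through one seeded NumPy generator (PCG64), so a batch is exactly
reproducible from its seed.  Generated structures can interpenetrate
sterically; :func:`clash_check` flags them, and the batch policy decides
whether flagged structures are kept, dropped or merely marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformer_catalog import (
    ConformerLabel,
    canonical_state,
    classify,
    enumerate_catalog,
    find_label,
)
from .ring_pucker import RingAtomSet, forward_pucker, mean_plane_displacements
from .structure_builder import (
    DihedralLibrary,
    MoleculeSpec,
    ZMatrix,
    attach_substituents,
    build_ring_geometry,
)

__all__ = [
    "SamplerConfig",
    "ConformerSample",
    "draw_conformer",
    "draw_rotamers",
    "draw_het_flip",
    "clash_check",
    "generate_batch",
]


@dataclass
class SamplerConfig:
    """Batch parameters: how many conformers, which seed, clash policy."""

    n_conformers: int = 1
    seed: int | None = None
    clash_threshold: float = 0.7
    clash_policy: str = "flag"

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.clash_threshold < 0:
            raise ValueError("clash_threshold must be >= 0")
        if self.clash_policy not in ("flag", "drop", "keep"):
            raise ValueError("clash_policy must be flag, drop or keep")


@dataclass
class ConformerSample:
    """One generated conformer: the draws that define it plus outputs."""

    index: int
    library_key: str
    D_values: np.ndarray
    rotamer_values: np.ndarray
    het_flip: float | None
    clash_flag: bool
    label: ConformerLabel | None
    zmatrix: ZMatrix
    elements: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None


def draw_conformer(
    library: DihedralLibrary, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """One uniform draw over the library: (D array, entry key)."""
    keys = library.keys_ordered
    if not keys:
        raise ValueError("cannot draw from an empty dihedral library")
    key = keys[int(rng.integers(len(keys)))]
    return library.entries[key].copy(), key


def draw_rotamers(k: int, rng: np.random.Generator) -> np.ndarray:
    """k independent uniform angles in [-180, 180] degrees."""
    if k < 0:
        raise ValueError("rotamer count must be >= 0")
    return rng.uniform(-180.0, 180.0, size=k)


def draw_het_flip(rng: np.random.Generator, heteroatom: str = "NH") -> float:
    """The +-120 degree equatorial/axial draw for an N-H or P-H ring
    heteroatom hydrogen."""
    if heteroatom not in ("NH", "PH"):
        raise ValueError(
            f"heteroatom {heteroatom!r} has no hydrogen-flip degree of freedom"
        )
    return float(rng.choice((-120.0, 120.0)))


def clash_check(
    coords: np.ndarray,
    threshold: float,
    bonded_pairs: set[tuple[int, int]],
) -> bool:
    """True iff any non-excluded atom pair is closer than threshold (A).

    ``bonded_pairs`` are 0-based bonded (1-2) pairs; 1-3 pairs (two
    bonds apart) are derived from them and excluded as well.
    """
    n = coords.shape[0]
    if threshold <= 0 or n < 2:
        return False
    neighbours: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonded_pairs:
        neighbours[i].add(j)
        neighbours[j].add(i)
    excluded = {frozenset(p) for p in bonded_pairs}
    for centre, nb in neighbours.items():
        for i in nb:
            for j in nb:
                if i < j:
                    excluded.add(frozenset((i, j)))
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.where((d < threshold) & np.triu(np.ones((n, n), bool), 1))
    return any(frozenset((int(i), int(j))) not in excluded for i, j in zip(ii, jj))


def generate_batch(
    spec: MoleculeSpec,
    library: DihedralLibrary,
    config: SamplerConfig,
) -> tuple[list[ConformerSample], int]:
    """Generate a batch of random conformers of one molecule.

    For every sample the drawn library entry fixes the ring shape (the
    ring is rebuilt from the named canonical conformer when the library
    is catalog-keyed, otherwise the D values replace the endocyclic
    variables directly), substituents are attached, rotamer variables
    are overwritten with fresh uniform draws, the heteroatom-hydrogen
    flip is applied where the template has one, and the realised
    Cartesian structure is clash-checked.

    Returns ``(samples, n_dropped)``.  Under policies "flag" and "keep"
    exactly ``config.n_conformers`` samples come back (flag marks
    clashing ones); under "drop" clashing structures are discarded and
    redrawn, erroring out after 100 * n_conformers attempts.

    Draw order per conformer is fixed (conformer, rotamers, flip), so a
    seed fully determines the batch.
    """
    rng = np.random.default_rng(config.seed)
    template = spec.template
    amplitude = {5: 0.45, 6: 0.55, 7: 0.7}[template.n_atoms]
    has_flip = template.heteroatom in ("NH", "PH")

    samples: list[ConformerSample] = []
    dropped = 0
    attempts = 0
    max_attempts = 100 * config.n_conformers
    while len(samples) < config.n_conformers:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"clash policy 'drop' exhausted {max_attempts} attempts "
                f"({dropped} structures dropped)"
            )
        D, key = draw_conformer(library, rng)
        # realise the ring for this conformation
        try:
            label: ConformerLabel | None = find_label(template.n_atoms, key)
        except KeyError:
            label = None
        if label is not None:
            ring = build_ring_geometry(template, canonical_state(label, amplitude))
            zmat = attach_substituents(ring, template, spec.substituents)
            # endocyclic variables already carry this conformer's values
        else:
            # scan-grid library: build a neutral reference ring and force
            # the drawn endocyclic dihedrals into the z-matrix
            ref = enumerate_catalog(template.n_atoms)[0]
            ring = build_ring_geometry(template, canonical_state(ref, amplitude))
            zmat = attach_substituents(ring, template, spec.substituents)
            for i, name in enumerate(zmat.variable_names("endocyclic")):
                zmat.set_variable(name, float(D[i]))
        rot_names = zmat.variable_names("rotamer")
        rots = draw_rotamers(len(rot_names), rng)
        for name, val in zip(rot_names, rots):
            zmat.set_variable(name, float(val))
        flip = None
        if has_flip:
            flip = draw_het_flip(rng, template.heteroatom)
            zmat.set_variable("HFLIP", flip)
        elements, coords = zmat.to_cartesian()
        clashing = clash_check(coords, config.clash_threshold,
                               zmat.bonded_pairs())
        if clashing and config.clash_policy == "drop":
            dropped += 1
            continue
        if label is None:
            # classify the realised ring so every sample carries a label
            ring_coords = coords[: template.n_atoms]
            try:
                st = forward_pucker(
                    mean_plane_displacements(
                        RingAtomSet(coords=ring_coords, labels=ring.labels,
                                    validate=False)
                    ),
                    template.n_atoms,
                )
                label = classify(st)
            except Exception:
                label = None
        samples.append(
            ConformerSample(
                index=len(samples) + 1,
                library_key=key,
                D_values=np.array([zmat.variables[v]
                                   for v in zmat.variable_names("endocyclic")]),
                rotamer_values=rots,
                het_flip=flip,
                clash_flag=clashing and config.clash_policy != "keep",
                label=label,
                zmatrix=zmat,
                elements=elements,
                coords=coords,
            )
        )
    return samples, dropped
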