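"""File formats: structure writers/readers, run configuration, docking prep.

Writers are native and deterministic -- identical input produces
byte-identical files.  Gaussian inputs keep the sampled degrees of
freedom as named variables in a ``Variables:`` block so a generated
conformer stays editable; XYZ and PDB carry realised Cartesian
coordinates.  Docking preparation emits AutoDock Vina configuration
files plus a serial job manifest (one command per line) for a receptor
tree organised by sugar-family folders; external tools are never
executed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_builder import (
    MoleculeSpec,
    RingTemplate,
    SubstituentSpec,
    ZMatrix,
    ZRow,
)

__all__ = [
    "RunConfig",
    "ReceptorEntry",
    "write_gjf",
    "read_gjf",
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "parse_input_dat",
    "discover_receptors",
    "write_vina_jobs",
    "write_batch_manifest",
    "write_pucker_report",
    "write_catalog_table",
]

logger = logging.getLogger("puckermc")

#: receptor families named after the sugar the enzymes hydrolyse
RECEPTOR_FAMILIES = (
    "ARABINO-FRUCTO", "FUCO", "GALACTO", "GALNAC-GLCNAC", "GLUCO",
    "IDURONIC-SIALIC", "MANNO", "RHAMNO", "XYLO",
)


@dataclass
class RunConfig:
    """Parsed run options: the molecule, batch size and output routing."""

    ring_size: int
    heteroatom: str
    substituents: tuple[SubstituentSpec, ...] = ()
    n_conformers: int = 1
    seed: int | None = None
    output_format: str = "xyz"
    output_directory: str = "conformers"
    receptor_family: str | None = None
    clash_policy: str = "flag"

    def __post_init__(self) -> None:
        if self.output_format not in ("gjf", "pdb", "xyz"):
            raise ValueError("output format must be gjf, pdb or xyz")

    def molecule_spec(self, name: str = "ring") -> MoleculeSpec:
        return MoleculeSpec(
            template=RingTemplate(n_atoms=self.ring_size,
                                  heteroatom=self.heteroatom),
            substituents=self.substituents,
            name=name,
        )


@dataclass
class ReceptorEntry:
    """One prepared receptor: its family folder, file and docking box."""

    family: str
    receptor_id: str
    box_center: tuple[float, float, float]
    box_size: tuple[float, float, float]
    receptor_file: Path

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError(f"receptor {self.receptor_id}: box sizes must be positive")


# ---------------------------------------------------------------------------
# Gaussian z-matrix input

def _fmt(v: float | str) -> str:
    return v if isinstance(v, str) else f"{v:.6f}"


def write_gjf(
    zmatrix: ZMatrix,
    route: str = "#P B97-2/def2-SVP Opt",
    path: str | Path = "calc.gjf",
    title: str = "conformer generated by puckermc",
) -> Path:
    """Write a Gaussian input: route, title, charge/multiplicity "0 1",
    the z-matrix with variable names in place of sampled dihedrals, and
    a Variables: block with their current values."""
    path = Path(path)
    lines = [route, "", title, "", f"{zmatrix.charge} {zmatrix.multiplicity}"]
    for i, row in enumerate(zmatrix.rows):
        parts = [f"{row.element:<2s}"]
        if i >= 1:
            parts += [str(row.ref_r), _fmt(row.r)]
        if i >= 2:
            parts += [str(row.ref_a), _fmt(row.a)]
        if i >= 3:
            parts += [str(row.ref_d), _fmt(row.d)]
        lines.append(" ".join(parts))
    lines.append("")
    lines.append("Variables:")
    for name, value in zmatrix.variables.items():
        lines.append(f" {name} = {value:.6f}")
    lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gjf(path: str | Path) -> ZMatrix:
    """Parse a Gaussian input written by :func:`write_gjf`."""
    text = Path(path).read_text().splitlines()
    # locate the charge/multiplicity line: two bare integers
    start = None
    for i, line in enumerate(text):
        bits = line.split()
        if len(bits) == 2 and all(_is_int(b) for b in bits):
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no charge/multiplicity line found")
    charge, mult = (int(b) for b in text[start].split())
    rows: list[ZRow] = []
    i = start + 1
    while i < len(text) and text[i].strip():
        bits = text[i].split()
        row = ZRow(element=bits[0])
        if len(bits) >= 3:
            row.ref_r, row.r = int(bits[1]), _num_or_name(bits[2])
        if len(bits) >= 5:
            row.ref_a, row.a = int(bits[3]), _num_or_name(bits[4])
        if len(bits) >= 7:
            row.ref_d, row.d = int(bits[5]), _num_or_name(bits[6])
        rows.append(row)
        i += 1
    variables: dict[str, float] = {}
    for line in text[i:]:
        line = line.strip()
        if not line or line.lower().startswith("variables"):
            continue
        if "=" in line:
            name, val = (s.strip() for s in line.split("=", 1))
            variables[name] = float(val)
    kinds = {n: ("endocyclic" if n.startswith("D")
                 else "hetflip" if n == "HFLIP" else "rotamer")
             for n in variables}
    return ZMatrix(rows=rows, variables=variables, var_kinds=kinds,
                   charge=charge, multiplicity=mult)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _num_or_name(s: str) -> float | str:
    try:
        return float(s)
    except ValueError:
        return s


# ---------------------------------------------------------------------------
# XYZ / PDB

def write_xyz(
    coords: np.ndarray,
    elements: list[str],
    comment: str = "",
    path: str | Path = "conf.xyz",
) -> Path:
    if len(elements) == 0:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(elements, np.asarray(coords, dtype=float)):
        lines.append(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, str]:
    """Returns (elements, coords, comment)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    comment = lines[1] if len(lines) > 1 else ""
    els, xyz = [], []
    for line in lines[2:2 + n]:
        bits = line.split()
        els.append(bits[0])
        xyz.append([float(b) for b in bits[1:4]])
    if len(els) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(els)}")
    return els, np.array(xyz), comment


def write_pdb(
    coords: np.ndarray,
    elements: list[str],
    resname: str = "LIG",
    path: str | Path = "conf.pdb",
) -> Path:
    """HETATM records with unique atom names (element + counter),
    occupancy 1.00, element column set, END terminator."""
    if len(elements) == 0:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    counts: dict[str, int] = {}
    lines = []
    for i, (el, (x, y, z)) in enumerate(
        zip(elements, np.asarray(coords, dtype=float)), start=1
    ):
        counts[el] = counts.get(el, 0) + 1
        name = f"{el}{counts[el]}"
        lines.append(
            f"HETATM{i:5d} {name:<4s} {resname:<3s} A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# input.dat

_REQUIRED_KEYS = ("ring_size", "heteroatom")


def parse_input_dat(path: str | Path) -> RunConfig:
    """Parse a key=value run file.

    Grammar (one ``key = value`` per line, ``#`` comments)::

        ring_size   = 6
        heteroatom  = O            # CH2, O, S, SO2, NH, BH, PH
        substituent = 1:OH:down    # position:group:orientation[:fixed]
        substituent = 5:CH2OH:up
        calc        = 500          # number of conformers
        seed        = 42
        format      = xyz          # gjf | pdb | xyz
        outdir      = out
        clash_policy = flag        # flag | drop | keep
        receptor_family = MANNO

    Unknown keys are warnings; missing required keys or malformed
    substituent tokens are errors that name the line.
    """
    path = Path(path)
    seen: dict[str, str] = {}
    subs: list[SubstituentSpec] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path.name}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        key = key.lower()
        if key == "substituent":
            bits = val.split(":")
            if len(bits) not in (3, 4):
                raise ValueError(
                    f"{path.name}:{ln}: substituent must be "
                    f"'position:group:orientation[:fixed]', got {val!r}"
                )
            try:
                pos = int(bits[0])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{ln}: substituent position {bits[0]!r} "
                    "is not an integer"
                ) from None
            rotatable = not (len(bits) == 4 and bits[3].lower() == "fixed")
            try:
                subs.append(SubstituentSpec(pos, bits[1], bits[2].lower(),
                                            rotatable))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{ln}: {exc}") from None
            continue
        known = {"ring_size", "heteroatom", "calc", "seed", "format",
                 "outdir", "clash_policy", "receptor_family"}
        if key not in known:
            logger.warning("%s:%d: unknown key %r ignored", path.name, ln, key)
            continue
        seen[key] = val
    for req in _REQUIRED_KEYS:
        if req not in seen:
            raise ValueError(f"{path.name}: missing required key {req!r}")
    return RunConfig(
        ring_size=int(seen["ring_size"]),
        heteroatom=seen["heteroatom"],
        substituents=tuple(subs),
        n_conformers=int(seen.get("calc", "1")),
        seed=None if "seed" not in seen else int(seen["seed"]),
        output_format=seen.get("format", "xyz").lower(),
        output_directory=seen.get("outdir", "conformers"),
        receptor_family=seen.get("receptor_family"),
        clash_policy=seen.get("clash_policy", "flag").lower(),
    )


# ---------------------------------------------------------------------------
# docking preparation

_BOX_KEYS = ("center_x", "center_y", "center_z", "size_x", "size_y", "size_z")


def discover_receptors(
    receptors_dir: str | Path, family: str
) -> list[ReceptorEntry]:
    """Scan one family folder of a receptor tree.

    Layout: ``<receptors_dir>/<FAMILY>/<receptor_id>/`` holding a
    receptor structure (*.pdbqt preferred, *.pdb accepted) and a
    ``box.txt`` with the six docking-box keys.
    """
    root = Path(receptors_dir) / family
    if not root.is_dir():
        raise FileNotFoundError(
            f"receptor family folder {root} not found: the docking engine "
            "would not find a receptor or the coordinates to dock into"
        )
    out = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        box_file = sub / "box.txt"
        if not box_file.exists():
            raise FileNotFoundError(f"{sub}: no box.txt docking-box definition")
        box = {}
        for line in box_file.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line and "=" in line:
                k, v = (s.strip() for s in line.split("=", 1))
                box[k.lower()] = float(v)
        missing = [k for k in _BOX_KEYS if k not in box]
        if missing:
            raise ValueError(f"{box_file}: missing box keys {missing}")
        receptors = sorted(sub.glob("*.pdbqt")) or sorted(sub.glob("*.pdb"))
        if not receptors:
            raise FileNotFoundError(f"{sub}: no receptor structure file")
        out.append(ReceptorEntry(
            family=family,
            receptor_id=sub.name,
            box_center=(box["center_x"], box["center_y"], box["center_z"]),
            box_size=(box["size_x"], box["size_y"], box["size_z"]),
            receptor_file=receptors[0],
        ))
    if not out:
        raise FileNotFoundError(f"{root}: family folder holds no receptors")
    return out


def write_vina_jobs(
    ligand_paths: list[str | Path],
    receptors: list[ReceptorEntry],
    outdir: str | Path,
    exhaustiveness: int = 8,
) -> Path:
    """Emit one Vina config per (ligand, receptor) pair plus a serial
    job manifest (``jobs.txt``, one docking command per line, so its
    length is n_ligands * n_receptors) and a ``prepare_ligands.sh``
    with the ligand-preparation commands the external toolchain runs
    first.  Returns the manifest path."""
    if not ligand_paths:
        raise ValueError("no ligand structures given")
    if not receptors:
        raise ValueError("no receptors given")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prep_lines = []
    job_lines = []
    for lig in ligand_paths:
        lig = Path(lig)
        pdbqt = lig.with_suffix(".pdbqt").name
        prep_lines.append(f"prepare_ligand -l {lig.name} -o {pdbqt}")
        for rec in receptors:
            conf = outdir / f"conf_{lig.stem}_{rec.receptor_id}.txt"
            cx, cy, cz = rec.box_center
            sx, sy, sz = rec.box_size
            conf.write_text(
                f"receptor = {rec.receptor_file}\n"
                f"ligand = {pdbqt}\n"
                f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
                f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n"
                f"exhaustiveness = {exhaustiveness}\n"
            )
            job_lines.append(
                f"vina --config {conf.name} --out out_{lig.stem}_{rec.receptor_id}.pdbqt"
            )
    (outdir / "prepare_ligands.sh").write_text("\n".join(prep_lines) + "\n")
    manifest = outdir / "jobs.txt"
    manifest.write_text("\n".join(job_lines) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# reports

def write_batch_manifest(samples, path: str | Path, seed=None) -> Path:
    """Tab-delimited batch manifest: one row per generated conformer."""
    path = Path(path)
    lines = [f"# seed = {seed}",
             "index\tconformer\tlabel\tD_values\trotamers\thet_flip\tclash"]
    for s in samples:
        lines.append("\t".join([
            str(s.index),
            s.library_key,
            s.label.name if s.label is not None else "planar",
            ",".join(f"{d:.3f}" for d in s.D_values),
            ",".join(f"{r:.3f}" for r in s.rotamer_values) or "-",
            "-" if s.het_flip is None else f"{s.het_flip:.0f}",
            "1" if s.clash_flag else "0",
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pucker_report(rows: list[dict], path: str | Path) -> Path:
    """Delimited puckering report: id, amplitudes, phases, label."""
    path = Path(path)
    header = ["id", "q2", "q3", "phi2", "phi3", "Q", "theta", "label"]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join(
            f"{r[k]:.4f}" if isinstance(r.get(k), float) else str(r.get(k, "-"))
            for k in header
        ))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_catalog_table(n_atoms: int, path: str | Path) -> Path:
    """Export the canonical-conformer table for one ring size."""
    from .conformer_catalog import enumerate_catalog

    path = Path(path)
    lines = ["name\tfamily\tq2\tq3\tphi2\tphi3\tQ\ttheta"]
    for lab in enumerate_catalog(n_atoms):
        st = lab.ref_state
        q3 = f"{st.q3:.4f}" if n_atoms > 5 else "-"
        phi3 = f"{st.phi3:.1f}" if n_atoms == 7 else "-"
        Q = f"{st.Q:.4f}" if n_atoms == 6 else "-"
        theta = f"{st.theta:.2f}" if n_atoms == 6 else "-"
        lines.append(
            f"{lab.name}\t{lab.family}\t{st.q2:.4f}\t{q3}\t{st.phi2:.1f}"
            f"\t{phi3}\t{Q}\t{theta}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
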