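"""Frame readers/writers (XYZ, GRO, PDB subset), particle registry, CSV.

All coordinates are normalized to nm on read (PDB Å are divided by 10; GRO
is native nm).  A sidecar registry maps residue/molecule names to a species
label and the central atom representing the molecule's position; residues
mapped to the macromolecule contribute all their atoms.

XYZ files carry the box on the comment line as three lengths in nm
(optionally prefixed ``box=``); plain element labels double as species
labels when no registry is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError, RegistryError
from .mdprofile import SPECIES_ORDER, Frame, RadialProfile

__all__ = [
    "ParticleRegistry",
    "load_particle_registry",
    "read_frames",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "write_gro",
    "read_pdb",
    "write_csv",
    "read_scan_csv",
]

PROFILE_COLUMNS = ["r_lo", "r_hi", "N_H2O", "N_CPME", "N_Na", "N_FA", "N_4VG", "x_H2O"]


@dataclass(frozen=True)
class ParticleRegistry:
    """Maps residue/molecule names to species labels and central atoms.

    ``particles``: residue name -> (species label, central atom name or None
    meaning any/only atom).  ``macromolecule``: residue names whose atoms all
    belong to the macromolecule.
    """

    particles: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    macromolecule: frozenset = frozenset()

    def species_for(self, resname: str) -> tuple[str, str | None]:
        try:
            return self.particles[resname]
        except KeyError:
            raise RegistryError(f"residue {resname!r} not in particle registry") from None


#: Registry accepting bare species labels (as written by the generators).
IDENTITY_REGISTRY = ParticleRegistry(
    particles={s: (s, None) for s in SPECIES_ORDER},
    macromolecule=frozenset({"M", "PROT"}),
)


def load_particle_registry(path) -> ParticleRegistry:
    """Read a registry YAML: ``particles: {SOL: {species: H2O, central_atom: OW}}``
    plus a ``macromolecule`` name list."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    particles = {}
    for res, entry in (doc.get("particles") or {}).items():
        if isinstance(entry, str):
            particles[res] = (entry, None)
        else:
            particles[res] = (entry["species"], entry.get("central_atom"))
    macro = frozenset(doc.get("macromolecule") or ())
    if not particles and not macro:
        raise RegistryError(f"{path}: registry defines no particles or macromolecule")
    return ParticleRegistry(particles=particles, macromolecule=macro)


def read_xyz(path, registry: ParticleRegistry | None = None) -> list[Frame]:
    """Read one or more XYZ frames (element + x y z in nm, box on comment line)."""
    registry = registry or IDENTITY_REGISTRY
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}", line=i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        tokens = comment.replace("box=", " ").replace(",", " ").split()
        box_vals = []
        for t in tokens:
            try:
                box_vals.append(float(t))
            except ValueError:
                pass
        if len(box_vals) < 3:
            raise ParseError("comment line must carry three box lengths (nm)", line=i + 2)
        box = np.array(box_vals[:3])
        labels, coords, macro = [], [], []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError("truncated frame", line=ln + 1)
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom record {lines[ln]!r}", line=ln + 1)
            name = parts[0]
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {lines[ln]!r}", line=ln + 1)
            if name in registry.macromolecule:
                macro.append(xyz)
            else:
                sp, _ = registry.species_for(name)
                labels.append(sp)
                coords.append(xyz)
        frames.append(Frame(box=box, macromolecule=np.array(macro).reshape(-1, 3),
                            species=np.array(labels),
                            coordinates=np.array(coords).reshape(-1, 3)))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_xyz(frames, path, macro_label: str = "M") -> None:
    """Write frames as XYZ (nm), box lengths on the comment line."""
    with open(path, "w") as fh:
        for f in frames:
            n = len(f.species) + len(f.macromolecule)
            fh.write(f"{n}\n")
            fh.write("box= {:.6f} {:.6f} {:.6f}\n".format(*f.box))
            for xyz in f.macromolecule:
                fh.write(f"{macro_label} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
            for s, xyz in zip(f.species, f.coordinates):
                fh.write(f"{s} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def _mda_universe(path, fmt=None):
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), format=fmt)


def _frame_from_universe(u, registry: ParticleRegistry) -> Frame:
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise InputError("file carries no box dimensions")
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise InputError("only orthorhombic boxes are supported")
    box = np.asarray(dims[:3], dtype=float) / 10.0  # Å -> nm

    labels, coords, macro = [], [], []
    for res in u.residues:
        if res.resname in registry.macromolecule:
            macro.extend(res.atoms.positions / 10.0)
            continue
        sp, central = registry.species_for(res.resname)
        atoms = res.atoms
        if central is not None:
            atoms = atoms[atoms.names == central]
            if len(atoms) == 0:
                raise RegistryError(
                    f"residue {res.resname!r} has no atom named {central!r}")
        elif len(atoms) > 1:
            raise RegistryError(
                f"residue {res.resname!r} has {len(atoms)} atoms; registry must name a central atom")
        labels.append(sp)
        coords.append(atoms.positions[0] / 10.0)
    return Frame(box=box, macromolecule=np.array(macro).reshape(-1, 3),
                 species=np.array(labels), coordinates=np.array(coords).reshape(-1, 3))


def read_gro(path, registry: ParticleRegistry) -> list[Frame]:
    u = _mda_universe(path, fmt="GRO")
    return [_frame_from_universe(u, registry)]


def read_pdb(path, registry: ParticleRegistry) -> list[Frame]:
    u = _mda_universe(path, fmt="PDB")
    return [_frame_from_universe(u, registry)]


def write_gro(frame: Frame, path, macro_resname: str = "PROT") -> None:
    """Write one frame to GRO (positions in nm at 3 decimals)."""
    n = len(frame.macromolecule) + len(frame.species)
    with open(path, "w") as fh:
        fh.write("microaqua frame\n")
        fh.write(f"{n}\n")
        idx = 0
        for xyz in frame.macromolecule:
            idx += 1
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
                     % (1, macro_resname, "CA", idx % 100000, xyz[0], xyz[1], xyz[2]))
        resid = 1
        for s, xyz in zip(frame.species, frame.coordinates):
            idx += 1
            resid += 1
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
                     % (resid % 100000, s, "C1", idx % 100000, xyz[0], xyz[1], xyz[2]))
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(frame.box))


def read_frames(path, fmt: str | None = None,
                registry: ParticleRegistry | None = None, stride: int = 1) -> list[Frame]:
    """Read frames from XYZ/GRO/PDB, species-mapped through the registry."""
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if stride < 1:
        raise InputError("stride must be >= 1")
    if fmt == "xyz":
        frames = read_xyz(path, registry)
    elif fmt == "gro":
        frames = read_gro(path, registry or IDENTITY_REGISTRY)
    elif fmt == "pdb":
        frames = read_pdb(path, registry or IDENTITY_REGISTRY)
    else:
        raise InputError(f"unsupported format {fmt!r} (xyz, gro, pdb)")
    return frames[::stride]


def write_csv(table, path) -> None:
    """Write a DataFrame (or RadialProfile) to CSV with stable headers."""
    if isinstance(table, RadialProfile):
        table = table.to_dataframe()
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table.to_csv(path, index=False)


def read_scan_csv(path) -> np.ndarray:
    """Read a (N_H2O, x_H2O_bulk) series from a two-column CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (N_H2O, x_H2O_bulk)")
    return df.iloc[:, :2].to_numpy(dtype=float)
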