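"""Structure parsing, dot-sphere solvent accessibility and burial/interface calls.

Solvent-accessible surface area (SASA) is computed with a dot-surface
algorithm: each atom's van der Waals sphere is inflated by the probe radius,
covered with a deterministic quasi-uniform lattice of surface dots, and a dot
counts as exposed when it lies outside every neighbouring atom's inflated
sphere.  Per-atom SASA is the exposed-dot fraction times the inflated sphere
area; per-residue SASA sums atoms.  A residue is *buried* when its SASA falls
strictly below a small area threshold (default 1.0 A^2, evaluated on the full
complex), and *interface* when any of its heavy atoms approaches a heavy atom
of a partner chain within a contact cutoff (default 4.5 A), or when it appears
on an explicit override list.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "AtomRecord",
    "SasaResult",
    "ResidueClassification",
    "VDW_RADII",
    "read_structure",
    "fibonacci_sphere",
    "dot_sphere_sasa",
    "classify_burial",
    "detect_interface_residues",
    "classification_table",
]

#: van der Waals radii in Angstrom (Bondi 1964, with the common C=1.70
#: convention also used by Shrake-Rupley implementations).  Configurable per
#: call; hydrogens are skipped during parsing so H is listed only for
#: completeness.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Residue names treated as nucleic acid and skipped by default.
NUCLEIC_RESNAMES = {
    "DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "U", "I", "T",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of the structure, with its van der Waals radius."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    coord: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinates {self.coord}")


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    per_atom_sasa: list[float]
    per_residue_sasa: dict[tuple[str, int], float]
    n_dots: int
    probe_radius: float
    atoms: list[AtomRecord] = field(repr=False, default_factory=list)


@dataclass
class ResidueClassification:
    """Burial and interface calls; the two sets are independent and may overlap."""

    buried: set[tuple[str, int]]
    interface: set[tuple[str, int]]
    threshold_area: float


class StructureFormatError(ValueError):
    """Raised when PDB text cannot be parsed into atom records."""


def read_structure(
    pdb_text: str,
    *,
    vdw_radii: dict[str, float] | None = None,
    skip_hetatm: bool = True,
    skip_nucleic: bool = True,
) -> list[AtomRecord]:
    """Parse PDB text into heavy-atom records.

    Hydrogens are skipped, alternate locations are resolved to the highest
    occupancy conformer, and HETATM records plus nucleic-acid chains are
    ignored by default (DNA plays no role in the burial analysis).

    Raises :class:`StructureFormatError` for unparseable ATOM lines (naming
    the line number) and ``KeyError``-style errors for unknown elements.
    """
    radii = VDW_RADII if vdw_radii is None else vdw_radii
    _validate_atom_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:  # pragma: no cover
        raise StructureFormatError(str(exc)) from exc

    records: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag = residue.id[0]
                if skip_hetatm and hetflag.strip():
                    continue
                resname = residue.get_resname().strip()
                if skip_nucleic and resname in NUCLEIC_RESNAMES:
                    continue
                for atom in residue:
                    # disordered atoms expose the highest-occupancy altloc
                    element = (atom.element or "").strip().upper()
                    if element == "H" or element == "D":
                        continue
                    if element not in radii:
                        raise StructureFormatError(
                            f"unknown element {element!r} for atom "
                            f"{atom.get_name()} in residue {resname} "
                            f"{residue.id[1]}"
                        )
                    x, y, z = (float(v) for v in atom.get_coord())
                    records.append(
                        AtomRecord(
                            chain_id=chain.id,
                            residue_number=int(residue.id[1]),
                            residue_name=resname,
                            atom_name=atom.get_name(),
                            coord=(x, y, z),
                            vdw_radius=radii[element],
                        )
                    )
        break  # first model only
    return records


def _validate_atom_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureFormatError(
                f"line {lineno}: ATOM record shorter than coordinate fields"
            )
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise StructureFormatError(
                f"line {lineno}: cannot parse fixed-column fields ({exc})"
            ) from exc


def fibonacci_sphere(n_dots: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors via the Fibonacci lattice."""
    i = np.arange(n_dots, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_dots
    theta = 2.0 * math.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def dot_sphere_sasa(
    atoms: list[AtomRecord],
    n_dots: int = 1024,
    probe_radius: float = 1.4,
) -> SasaResult:
    """Dot-surface SASA with ``n_dots`` lattice points per atom.

    A dot on atom *i*'s inflated sphere (radius r_i + probe) is exposed when
    it lies outside every other atom's inflated sphere; the per-atom area is
    ``4*pi*(r_i+probe)^2 * exposed/n_dots``.
    """
    if n_dots < 32:
        raise ValueError(f"n_dots must be >= 32, got {n_dots}")
    if probe_radius < 0:
        raise ValueError(f"probe_radius must be >= 0, got {probe_radius}")

    n = len(atoms)
    unit = fibonacci_sphere(n_dots)
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius

    per_atom: list[float] = []
    if n:
        # neighbour lists via a single pairwise distance pass; fine for the
        # structure sizes this package targets (<~1e4 atoms)
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        rsum2 = (radii[:, None] + radii[None, :]) ** 2
        neighbor_mask = (d2 < rsum2) & ~np.eye(n, dtype=bool)

    for i in range(n):
        r = radii[i]
        dots = coords[i] + r * unit
        nbrs = np.nonzero(neighbor_mask[i])[0]
        exposed = np.ones(n_dots, dtype=bool)
        for j in nbrs:
            dist2 = np.sum((dots - coords[j]) ** 2, axis=1)
            exposed &= dist2 >= radii[j] ** 2
            if not exposed.any():
                break
        area = 4.0 * math.pi * r * r * (np.count_nonzero(exposed) / n_dots)
        per_atom.append(float(area))

    per_residue: dict[tuple[str, int], float] = {}
    for atom, area in zip(atoms, per_atom):
        key = (atom.chain_id, atom.residue_number)
        per_residue[key] = per_residue.get(key, 0.0) + area

    return SasaResult(
        per_atom_sasa=per_atom,
        per_residue_sasa=per_residue,
        n_dots=n_dots,
        probe_radius=probe_radius,
        atoms=list(atoms),
    )


def classify_burial(
    sasa: SasaResult, threshold_area: float = 1.0
) -> set[tuple[str, int]]:
    """Residues with per-residue SASA strictly below ``threshold_area`` A^2."""
    return {
        key for key, area in sasa.per_residue_sasa.items() if area < threshold_area
    }


def detect_interface_residues(
    atoms: list[AtomRecord],
    chain_pairs: list[tuple[str, str]],
    contact_cutoff: float = 4.5,
    override: dict[str, set[int]] | None = None,
) -> set[tuple[str, int]]:
    """Residues with a heavy atom within ``contact_cutoff`` of a partner chain.

    ``override`` maps chain id to an explicit residue-number set; overridden
    residues are added verbatim (used to reproduce curated interface lists
    when contact persistence from simulation is unavailable).
    """
    present = {a.chain_id for a in atoms}
    result: set[tuple[str, int]] = set()

    if override:
        for chain, numbers in override.items():
            result.update((chain, n) for n in numbers)

    for ca, cb in chain_pairs:
        for c in (ca, cb):
            if c not in present:
                raise ValueError(f"chain {c!r} absent from structure")
        a_atoms = [a for a in atoms if a.chain_id == ca]
        b_atoms = [a for a in atoms if a.chain_id == cb]
        if not a_atoms or not b_atoms:
            continue
        xa = np.array([a.coord for a in a_atoms])
        xb = np.array([a.coord for a in b_atoms])
        d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
        hits = d2 <= contact_cutoff**2
        for ia, ib in zip(*np.nonzero(hits)):
            result.add((ca, a_atoms[ia].residue_number))
            result.add((cb, b_atoms[ib].residue_number))
    return result


def classification_table(
    sasa: SasaResult, classification: ResidueClassification
) -> "pd.DataFrame":
    """Tidy per-residue table: chain, resnum, resname, sasa_A2, buried, interface."""
    import pandas as pd

    resnames: dict[tuple[str, int], str] = {}
    for a in sasa.atoms:
        resnames.setdefault((a.chain_id, a.residue_number), a.residue_name)
    rows = [
        {
            "chain": chain,
            "resnum": resnum,
            "resname": resnames.get((chain, resnum), "UNK"),
            "sasa_A2": area,
            "buried": int((chain, resnum) in classification.buried),
            "interface": int((chain, resnum) in classification.interface),
        }
        for (chain, resnum), area in sorted(sasa.per_residue_sasa.items())
    ]
    return pd.DataFrame(rows)
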