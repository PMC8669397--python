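"""Structural geometry: helix axes, crossing angles, VDW contact distances.

Measurements on atomic models (PDB or mmCIF): the axis of a DNA duplex is
fitted as the total-least-squares line through base-pair midpoints (C1'
atoms of antiparallel-paired residues, falling back to P); the crossing
angle between two duplexes is the angle between their axes (acute
convention by default); and the minimum backbone van der Waals distance
across an interface is min over atom pairs of ||x_i - x_j|| - r_i - r_j,
which can be negative for interpenetrating surfaces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from muklock.errors import DataError

PROTEIN_BACKBONE = {"N", "CA", "C", "O"}
NUCLEIC_BACKBONE = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}
_NUCLEIC_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple
    source_format: str = "PDB"
    name: str = "model"

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise DataError("structure model contains no atoms")
        for a in self.atoms:
            if not all(np.isfinite([a.x, a.y, a.z])):
                raise DataError("non-finite atom coordinates")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def select(self, chain: str, first: int | None = None,
               last: int | None = None) -> list[AtomRecord]:
        out = [a for a in self.atoms if a.chain_id == chain]
        if first is not None:
            out = [a for a in out if a.residue_number >= first]
        if last is not None:
            out = [a for a in out if a.residue_number <= last]
        return out


@dataclass(frozen=True)
class HelixAxisFit:
    direction: np.ndarray
    point: np.ndarray
    n_basepairs_used: int
    rms_axial_deviation: float


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius (Angstrom)."""

    name: str
    radii: Mapping[str, float]

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise DataError(
                f"radii table '{self.name}' has no entry for element "
                f"{element!r}"
            ) from None


#: Bondi-type standard radii for the elements of protein/DNA backbones
BONDI = RadiiTable("bondi", {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
})

RADII_TABLES = {"bondi": BONDI}


def parse_selection(text: str) -> tuple[str, int | None, int | None]:
    """Parse 'chain' or 'chain:first-last' selection strings."""
    m = re.fullmatch(r"([^:]+)(?::(-?\d+)-(-?\d+))?", text.strip())
    if not m:
        raise DataError(f"cannot parse selection {text!r}")
    chain, lo, hi = m.group(1), m.group(2), m.group(3)
    return chain, (int(lo) if lo else None), (int(hi) if hi else None)


# ---------------------------------------------------------------------------
# structure I/O (gemmi-backed)


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name
    if el and el != "X":
        return el.upper()
    name = atom.name.strip()
    return (name[:1] or "C").upper()


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Load the first model of a PDB or mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties to altloc 'A'). Format is auto-detected from the extension and
    can be overridden with ``fmt`` ('pdb' or 'cif').
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file")
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise DataError(f"{path}: file contains no models")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                    continue
                # altloc resolution: highest occupancy, ties toward 'A'
                if (atom.occ, -ord(atom.altloc or "Z")) > (
                        prev.occ, -ord(prev.altloc or "Z")):
                    by_name[atom.name] = atom
            for atom in by_name.values():
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name.strip(),
                    atom_name=atom.name.strip(),
                    element=_element_of(atom),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                ))
    if not atoms:
        raise DataError(f"{path}: model contains no atoms")
    return StructureModel(atoms=tuple(atoms),
                          source_format="mmCIF" if fmt == "cif" else "PDB",
                          name=path.stem)


def write_structure(model: StructureModel, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a model as PDB or mmCIF (by extension or explicit ``fmt``)."""
    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    # gemmi containers copy on add, so group atoms first and insert each
    # residue/chain only once it is complete
    grouped: dict[str, dict[tuple, list[AtomRecord]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []).append(a)

    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (num, resname), atom_records in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(num, " ")
            for a in atom_records:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    if fmt == "cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# geometry


def _residue_anchor(atoms: Sequence[AtomRecord]) -> dict[int, np.ndarray]:
    """Per-residue anchor coordinate: C1' if present, else P."""
    anchors: dict[int, np.ndarray] = {}
    fallback: dict[int, np.ndarray] = {}
    for a in atoms:
        if a.atom_name == "C1'":
            anchors[a.residue_number] = a.pos
        elif a.atom_name == "P":
            fallback.setdefault(a.residue_number, a.pos)
    residues = {a.residue_number for a in atoms}
    out = {}
    missing = []
    for r in sorted(residues):
        if r in anchors:
            out[r] = anchors[r]
        elif r in fallback:
            out[r] = fallback[r]
        else:
            missing.append(r)
    if missing:
        raise DataError(
            f"residues without C1' or P atoms: {missing[:10]}"
        )
    return out


def fit_duplex_axis(
    model: StructureModel,
    strand_a: str,
    strand_b: str,
) -> HelixAxisFit:
    """Fit the helical axis of a duplex from base-pair midpoints.

    ``strand_a``/``strand_b`` are 'chain' or 'chain:first-last'
    selections of the two strands. Residues are paired antiparallel by
    index (i-th of strand A with (n-1-i)-th of strand B); midpoints of
    paired C1' atoms (P fallback) define the axis by a total-least-squares
    line fit. The direction points from the first to the last base pair.
    """
    sels = []
    for text in (strand_a, strand_b):
        chain, lo, hi = parse_selection(text)
        atoms = model.select(chain, lo, hi)
        if not atoms:
            raise DataError(f"selection {text!r} matches no atoms")
        sels.append(_residue_anchor(atoms))
    anchors_a, anchors_b = sels
    a_coords = [anchors_a[r] for r in sorted(anchors_a)]
    b_coords = [anchors_b[r] for r in sorted(anchors_b)]
    n = min(len(a_coords), len(b_coords))
    if n < 4:
        raise DataError(f"need >= 4 base pairs, got {n}")
    mids = np.array([
        (a_coords[i] + b_coords[len(b_coords) - 1 - i]) / 2.0
        for i in range(n)
    ])
    # Base-pair midpoints of a real (or ideal) duplex precess around the
    # axis at ~2 A radius; averaging over one helical turn (10 bp for
    # B-DNA) cancels the precession, making the line fit exact on ideal
    # helices and debiased on short real duplexes.
    turn = 10
    if n >= turn + 1:
        kernel = np.ones(turn) / turn
        fit_points = np.column_stack([
            np.convolve(mids[:, k], kernel, mode="valid") for k in range(3)
        ])
    else:
        fit_points = mids
    centroid = fit_points.mean(axis=0)
    centered = fit_points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, mids[-1] - mids[0]) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    raw_centered = mids - centroid
    axial = raw_centered @ direction
    perp = raw_centered - np.outer(axial, direction)
    rms = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelixAxisFit(direction=direction, point=centroid,
                        n_basepairs_used=n, rms_axial_deviation=rms)


def crossing_angle(
    axis_a: HelixAxisFit,
    axis_b: HelixAxisFit,
    convention: str = "acute",
) -> float:
    """Angle in degrees between two fitted helix axes.

    'acute' (default): arccos(|a.b|) in [0, 90], symmetric and invariant
    under flipping either axis. 'signed' (experimental): magnitude as in
    acute mode, signed by the triple product of the two directions with
    the inter-axis connector.
    """
    a = np.asarray(axis_a.direction, dtype=float)
    b = np.asarray(axis_b.direction, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("zero-length axis direction")
    a, b = a / na, b / nb
    cosang = abs(float(np.dot(a, b)))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if convention == "acute":
        return theta
    if convention == "signed":
        connector = np.asarray(axis_b.point) - np.asarray(axis_a.point)
        sign = np.sign(float(np.dot(np.cross(a, b), connector))) or 1.0
        return sign * theta
    raise DataError(f"unknown convention {convention!r}")


def find_dna_duplexes(model: StructureModel) -> list[tuple[str, str]]:
    """Pair nucleic-acid chains into duplexes by centroid proximity.

    Returns (chain_a, chain_b) pairs, greedily matching the closest
    centroids first. Requires an even number of nucleic chains.
    """
    centroids = {}
    for cid in sorted({a.chain_id for a in model.atoms}):
        atoms = model.select(cid)
        if any(a.residue_name in _NUCLEIC_RESNAMES for a in atoms):
            centroids[cid] = np.mean([[a.x, a.y, a.z] for a in atoms], axis=0)
    ids = sorted(centroids)
    if len(ids) % 2 != 0 or not ids:
        raise DataError(f"cannot pair {len(ids)} nucleic chains into duplexes")
    pairs = []
    remaining = set(ids)
    while remaining:
        a = min(remaining)
        remaining.discard(a)
        b = min(remaining,
                key=lambda c: float(np.linalg.norm(centroids[a] - centroids[c])))
        remaining.discard(b)
        pairs.append((a, b))
    return pairs


def _backbone_atoms(atoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Restrict a selection to backbone atoms (protein or nucleic)."""
    nucleic = any(a.residue_name in _NUCLEIC_RESNAMES for a in atoms)
    names = NUCLEIC_BACKBONE if nucleic else PROTEIN_BACKBONE
    return [a for a in atoms if a.atom_name in names]


def min_backbone_vdw_distance(
    model: StructureModel,
    selection_a: str,
    selection_b: str,
    radii: RadiiTable = BONDI,
) -> tuple[float, tuple[AtomRecord, AtomRecord]]:
    """Minimum backbone VDW gap between two selections.

    Returns (distance, (atom_a, atom_b)) where distance =
    min ||x_i - x_j|| - r_i - r_j over all cross pairs of backbone atoms;
    negative values indicate interpenetrating VDW surfaces.
    """
    groups = []
    for text in (selection_a, selection_b):
        chain, lo, hi = parse_selection(text)
        atoms = _backbone_atoms(model.select(chain, lo, hi))
        if not atoms:
            raise DataError(f"selection {text!r} has no backbone atoms")
        groups.append(atoms)
    ga, gb = groups
    xa = np.array([[a.x, a.y, a.z] for a in ga])
    xb = np.array([[a.x, a.y, a.z] for a in gb])
    ra = np.array([radii[a.element] for a in ga])
    rb = np.array([radii[a.element] for a in gb])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    gap = d - ra[:, None] - rb[None, :]
    i, j = np.unravel_index(int(np.argmin(gap)), gap.shape)
    return float(gap[i, j]), (ga[int(i)], gb[int(j)])
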