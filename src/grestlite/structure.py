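"""Structures, trajectories and domain definitions.

A :class:`Structure` is the static object every other module operates on:
an ordered set of atoms with residue identity, formal charge, coordinates
and masses.  A :class:`DomainDefinition` names the residue-range sets (NTD,
CTD, hinge, plus the two small "base" regions used by the twist angle).
A :class:`Trajectory` is a stack of coordinate frames conformant with one
Structure.

PDB files are read and written through biotite; DCD files are read through
mdtraj.  The native trajectory format is a documented plain-text format so
that round trips are bit-exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    ELEMENT_MASSES,
    RBP_DOMAIN_RANGES,
    RESIDUE_FORMAL_CHARGES,
)
from .errors import FormatError, ShapeError, ValidationError

__all__ = [
    "Structure",
    "DomainDefinition",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "make_domains",
    "rbp_domains",
    "read_trajectory",
    "write_trajectory",
    "read_dcd",
]


@dataclass
class Structure:
    """An ordered list of atoms for a single chain.

    ``residue_charges`` maps residue index (1-based) to formal charge in e;
    ``formal_charges`` carries the same information per atom, placed on the
    first atom of each residue so that the array sums to the chain's net
    formal charge.
    """

    atom_names: np.ndarray          # (n,) str
    elements: np.ndarray            # (n,) str
    res_ids: np.ndarray             # (n,) int, 1-based
    res_names: np.ndarray           # (n,) str
    coords: np.ndarray              # (n, 3) float, Å
    masses: np.ndarray              # (n,) float, amu
    formal_charges: np.ndarray      # (n,) float, e
    chain_id: str = "A"
    atom_radii: np.ndarray | None = None  # (n,) float, Å; overrides element radii

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        n = self.coords.shape[0]
        for name in ("atom_names", "elements", "res_ids", "res_names",
                     "masses", "formal_charges"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ShapeError(f"{name} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, name, arr)
        # residue ids form contiguous, strictly increasing blocks
        ids = self.res_ids
        if n and np.any(np.diff(ids) < 0):
            raise ValidationError("residue indices must be non-decreasing")
        block_starts = np.flatnonzero(np.r_[True, np.diff(ids) != 0])
        if np.any(np.diff(ids[block_starts]) <= 0):
            raise ValidationError("residue indices must be strictly increasing "
                                  "between residues")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_ids(self) -> np.ndarray:
        """Ordered unique residue indices."""
        _, first = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(first)]

    def residue_atom_indices(self, res_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.res_ids == res_id)
        if idx.size == 0:
            raise LookupError(f"residue {res_id} not in structure")
        return idx

    def atoms_of_residues(self, residues) -> np.ndarray:
        mask = np.isin(self.res_ids, np.asarray(sorted(residues), dtype=int))
        return np.flatnonzero(mask)

    @property
    def residue_charges(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for rid in self.residue_ids:
            idx = self.res_ids == rid
            out[int(rid)] = int(round(self.formal_charges[idx].sum()))
        return out

    @property
    def residue_names(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for rid in self.residue_ids:
            out[int(rid)] = str(self.res_names[self.res_ids == rid][0])
        return out

    @property
    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atom_names == "CA")

    @property
    def heavy_atom_indices(self) -> np.ndarray:
        return np.flatnonzero(self.elements != "H")

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


def _expand_ranges(ranges) -> frozenset[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        lo, hi = int(lo), int(hi)
        if lo > hi or lo < 1:
            raise ValidationError(f"invalid 1-based residue range ({lo}, {hi})")
        out.update(range(lo, hi + 1))
    if not out:
        raise ValidationError("empty residue-range set")
    return frozenset(out)


@dataclass(frozen=True)
class DomainDefinition:
    """Residue-index sets for the two domains, the hinge and the base regions.

    The NTD/CTD/hinge sets must be pairwise disjoint and the base regions must
    be subsets of their domains; both are enforced at construction.
    """

    ntd: frozenset[int]
    ctd: frozenset[int]
    hinge: frozenset[int]
    ntd_base: frozenset[int] = field(default_factory=frozenset)
    ctd_base: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ntd & self.ctd or self.ntd & self.hinge or self.ctd & self.hinge:
            raise ValidationError("NTD, CTD and hinge residue sets must be disjoint")
        if not self.ntd_base <= self.ntd:
            raise ValidationError("NTD base region must be a subset of NTD")
        if not self.ctd_base <= self.ctd:
            raise ValidationError("CTD base region must be a subset of CTD")

    @property
    def all_residues(self) -> frozenset[int]:
        return self.ntd | self.ctd | self.hinge

    def validate_against(self, structure: Structure) -> None:
        present = set(int(r) for r in structure.residue_ids)
        missing = self.all_residues - present
        if missing:
            raise ValidationError(
                f"domain residues missing from structure: {sorted(missing)[:8]}")


def make_domains(ntd, ctd, hinge, ntd_base=None, ctd_base=None,
                 structure: Structure | None = None) -> DomainDefinition:
    """Build a validated :class:`DomainDefinition` from 1-based inclusive ranges.

    Each argument is an iterable of ``(first, last)`` pairs.  Base regions are
    optional; they are only needed for twist angles.
    """
    dom = DomainDefinition(
        ntd=_expand_ranges(ntd),
        ctd=_expand_ranges(ctd),
        hinge=_expand_ranges(hinge),
        ntd_base=_expand_ranges(ntd_base) if ntd_base else frozenset(),
        ctd_base=_expand_ranges(ctd_base) if ctd_base else frozenset(),
    )
    if structure is not None:
        dom.validate_against(structure)
    return dom


def rbp_domains() -> DomainDefinition:
    """The ribose-binding-protein domain decomposition (NTD 1–100 ∪ 236–259,
    CTD 108–231 ∪ 269–271, hinge 101–107 ∪ 232–235 ∪ 260–268)."""
    r = RBP_DOMAIN_RANGES
    return make_domains(r["ntd"], r["ctd"], r["hinge"],
                        ntd_base=r["ntd_base"], ctd_base=r["ctd_base"])


@dataclass
class Trajectory:
    """Ordered coordinate frames conformant with one Structure."""

    coords: np.ndarray                 # (n_frames, n_atoms, 3) Å
    structure: Structure | None = None
    frame_interval: int = 1            # steps between saved frames
    label: str | None = None           # source replica / solute temperature

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError("trajectory coordinates must have shape (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if self.structure is not None and \
                self.coords.shape[1] != self.structure.n_atoms:
            raise ShapeError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"structure atom count {self.structure.n_atoms}")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.coords[i]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None,
             charged_his: tuple[int, ...] = ()) -> Structure:
    """Read one chain of a PDB file.

    Altloc records are resolved to the highest occupancy.  Formal charges are
    assigned from residue names (ARG/LYS +1, ASP/GLU −1); histidines are
    neutral unless their residue index appears in ``charged_his``.  Insertion
    codes are rejected.
    """
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - rewrap with line context
        raise FormatError(_locate_pdb_error(path, exc)) from exc

    chains = sorted(set(arr.chain_id))
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise LookupError(f"chain {chain!r} not found; available: {chains}")
    arr = arr[arr.chain_id == chain]
    if np.any(arr.ins_code != ""):
        raise ValidationError("insertion codes are not supported")

    elements = np.array([e.upper() for e in arr.element])
    try:
        masses = np.array([ELEMENT_MASSES[e] for e in elements])
    except KeyError as exc:
        raise FormatError(f"unknown element {exc} in {path}") from exc

    charges = np.zeros(arr.array_length())
    res_ids = arr.res_id.astype(int)
    for rid in np.unique(res_ids):
        idx = np.flatnonzero(res_ids == rid)
        name = arr.res_name[idx[0]]
        q = RESIDUE_FORMAL_CHARGES.get(name, 0)
        if name in ("HIS", "HSD", "HSE", "HSP") and int(rid) in charged_his:
            q = +1
        charges[idx[0]] = q

    return Structure(
        atom_names=np.array(arr.atom_name),
        elements=elements,
        res_ids=res_ids,
        res_names=np.array(arr.res_name),
        coords=np.asarray(arr.coord, dtype=float),
        masses=masses,
        formal_charges=charges,
        chain_id=chain,
    )


def _locate_pdb_error(path, exc) -> str:
    """Best-effort identification of the first malformed ATOM record."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        [float(line[c:c + 8]) for c in (30, 38, 46)]
                    except (ValueError, IndexError):
                        return (f"cannot parse PDB file {path}: malformed "
                                f"coordinate fields at line {i}: {line.rstrip()!r}")
    except OSError:
        pass
    return f"cannot parse PDB file {path}: {exc}"


def write_pdb(structure: Structure, path) -> None:
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.full(n, structure.chain_id)
    arr.res_id = structure.res_ids
    arr.res_name = structure.res_names
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Native plain-text trajectory format
# ---------------------------------------------------------------------------
#
#   # grestlite-traj 1
#   natoms <N> frames <F> interval <I> label <label-or-->
#   frame 0
#   <x> <y> <z>      (N lines, Å)
#   frame 1
#   ...

_TRAJ_MAGIC = "# grestlite-traj 1"


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRAJ_MAGIC + "\n")
        label = traj.label if traj.label else "-"
        fh.write(f"natoms {traj.n_atoms} frames {len(traj)} "
                 f"interval {traj.frame_interval} label {label}\n")
        for f in range(len(traj)):
            fh.write(f"frame {f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def read_trajectory(path, structure: Structure | None = None) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line(what):
        try:
            return next(it)
        except StopIteration:
            raise FormatError(f"truncated trajectory file {path}: "
                              f"expected {what}") from None

    lineno, magic = next_line("magic header")
    if magic.strip() != _TRAJ_MAGIC:
        raise FormatError(f"{path} line {lineno}: not a grestlite trajectory "
                          f"(missing magic header)")
    lineno, meta = next_line("metadata line")
    tok = meta.split()
    try:
        natoms = int(tok[tok.index("natoms") + 1])
        nframes = int(tok[tok.index("frames") + 1])
        interval = int(tok[tok.index("interval") + 1])
        label = tok[tok.index("label") + 1]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path} line {lineno}: bad metadata {meta!r}") from exc
    if structure is not None and natoms != structure.n_atoms:
        raise ShapeError(f"trajectory has {natoms} atoms but structure has "
                         f"{structure.n_atoms}")

    coords = np.empty((nframes, natoms, 3))
    for f in range(nframes):
        lineno, header = next_line(f"header of frame {f}")
        if header.split()[:2] != ["frame", str(f)]:
            raise FormatError(f"{path} line {lineno}: expected 'frame {f}', "
                              f"got {header!r}")
        for a in range(natoms):
            lineno, row = next_line(f"atom {a} of frame {f}")
            parts = row.split()
            if len(parts) != 3:
                raise FormatError(f"{path} line {lineno}: expected 3 "
                                  f"coordinates, got {row!r}")
            try:
                coords[f, a] = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-numeric "
                                  f"coordinate in {row!r}") from exc
    return Trajectory(coords=coords, structure=structure,
                      frame_interval=interval,
                      label=None if label == "-" else label)


def read_dcd(path, structure: Structure) -> Trajectory:
    """Read a DCD trajectory (coordinates converted from nm to Å)."""
    import mdtraj as md

    top = md.Topology()
    ch = top.add_chain()
    res = None
    last_rid = None
    for i in range(structure.n_atoms):
        rid = int(structure.res_ids[i])
        if rid != last_rid:
            res = top.add_residue(str(structure.res_names[i]), ch, resSeq=rid)
            last_rid = rid
        elem = md.element.Element.getBySymbol(
            str(structure.elements[i]).capitalize())
        top.add_atom(str(structure.atom_names[i]), elem, res)
    t = md.load_dcd(str(path), top=top)
    if t.xyz.shape[1] != structure.n_atoms:
        raise ShapeError("DCD atom count does not match structure")
    return Trajectory(coords=np.asarray(t.xyz, dtype=float) * 10.0,
                      structure=structure)
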