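"""Trajectory analysis: domain angles, Rg, RMSD, contacts, salt bridges,
hydrogen-bond occupancies, k-means state clustering and free-energy surfaces.

The two collective variables of domain motion are the hinge angle θ — the
bending angle at the hinge-region center of mass (COM) between the NTD and
CTD COMs — and the twist angle φ — the dihedral of (NTD-base COM, NTD COM,
CTD COM, CTD-base COM), signed with the IUPAC convention.  Free-energy
surfaces are Boltzmann inversions F = −kB·T·ln P of the binned (θ, φ)
populations, shifted so the populated minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB
from .errors import ShapeError, ValidationError
from .structure import DomainDefinition, Structure, Trajectory

__all__ = [
    "DomainAngles",
    "FreeEnergySurface",
    "ClusterResult",
    "OccupancyTable",
    "StateRule",
    "HbondCriteria",
    "center_of_mass",
    "hinge_angle",
    "twist_angle",
    "radius_of_gyration",
    "rmsd",
    "superpose",
    "domain_angles",
    "contact_map",
    "identify_salt_bridges",
    "hbond_occupancy",
    "kmeans_states",
    "classify_states",
    "free_energy_surface",
    "count_transitions",
]


def center_of_mass(coords, selection, masses) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms."""
    idx = np.asarray(list(selection), dtype=int)
    if idx.size == 0:
        raise ValidationError("empty selection")
    m = np.asarray(masses, dtype=float)[idx]
    return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def _residue_atom_indices(residues, res_ids) -> np.ndarray:
    return np.flatnonzero(np.isin(res_ids, np.asarray(sorted(residues))))


def _default_res_ids(frame, res_ids):
    if res_ids is None:
        return np.arange(1, frame.shape[0] + 1)
    return np.asarray(res_ids)


def hinge_angle(frame, domains: DomainDefinition, masses,
                res_ids=None) -> float:
    """Bending angle (degrees) at the hinge COM between the NTD and CTD COMs.

    ``res_ids`` maps atom rows to 1-based residue indices; by default row i
    is residue i+1 (the bead-per-residue convention).
    """
    rid = _default_res_ids(frame, res_ids)
    com_n = center_of_mass(frame, _residue_atom_indices(domains.ntd, rid),
                           masses)
    com_h = center_of_mass(frame, _residue_atom_indices(domains.hinge, rid),
                           masses)
    com_c = center_of_mass(frame, _residue_atom_indices(domains.ctd, rid),
                           masses)
    u, v = com_n - com_h, com_c - com_h
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise ValidationError("coincident COMs: hinge angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _dihedral(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 \
            or nb2 < 1e-10:
        raise ValidationError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / nb2)
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def twist_angle(frame, domains: DomainDefinition, masses,
                res_ids=None) -> float:
    """Signed dihedral (degrees, IUPAC convention) of the ordered COMs
    (NTD base, NTD, CTD, CTD base)."""
    if not domains.ntd_base or not domains.ctd_base:
        raise ValidationError("twist angle requires base regions")
    rid = _default_res_ids(frame, res_ids)
    pts = [center_of_mass(frame, _residue_atom_indices(sel, rid), masses)
           for sel in (domains.ntd_base, domains.ntd, domains.ctd,
                       domains.ctd_base)]
    return _dihedral(*pts)


def radius_of_gyration(frame, masses) -> float:
    """√(Σ mᵢ|rᵢ − COM|² / Σ mᵢ) in Å."""
    m = np.asarray(masses, dtype=float)
    com = (frame * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt(np.sum(m * ((frame - com) ** 2).sum(axis=1))
                         / m.sum()))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def _kabsch_rotation(mobile_c, ref_c, weights):
    """Optimal rotation (Kabsch, SVD with reflection guard) for centered
    coordinate sets."""
    h = (weights[:, None] * mobile_c).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile, reference, selection=None, weights=None):
    """Least-squares superpose ``mobile`` onto ``reference`` using the
    selected atoms; the returned frame has all atoms transformed."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ShapeError("frame shapes differ")
    sel = np.arange(mobile.shape[0]) if selection is None \
        else np.asarray(list(selection), dtype=int)
    w = np.ones(sel.size) if weights is None \
        else np.asarray(weights, dtype=float)[sel]
    mc = (mobile[sel] * w[:, None]).sum(axis=0) / w.sum()
    rc = (reference[sel] * w[:, None]).sum(axis=0) / w.sum()
    rot = _kabsch_rotation(mobile[sel] - mc, reference[sel] - rc, w)
    return (mobile - mc) @ rot.T + rc


def rmsd(frame, reference, selection=None, superpose_flag=True,
         weights=None) -> float:
    """Root-mean-square deviation (Å) over the selection, optionally after
    optimal-rotation (Kabsch) superposition on that same selection."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ShapeError("frame shapes differ")
    sel = np.arange(frame.shape[0]) if selection is None \
        else np.asarray(list(selection), dtype=int)
    if superpose_flag:
        frame = superpose(frame, reference, sel, weights)
    d = frame[sel] - reference[sel]
    return float(np.sqrt(np.mean((d ** 2).sum(axis=1))))


# ---------------------------------------------------------------------------
# per-frame series
# ---------------------------------------------------------------------------

@dataclass
class DomainAngles:
    """Per-frame hinge angle θ (deg), twist angle φ (deg) and Rg (Å)."""

    theta: np.ndarray
    phi: np.ndarray
    rg: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.theta) == len(self.phi) == len(self.rg)):
            raise ShapeError("series lengths differ")


def domain_angles(trajectory: Trajectory, domains: DomainDefinition,
                  masses=None, res_ids=None) -> DomainAngles:
    """θ, φ and Rg for every frame of a trajectory."""
    if masses is None:
        if trajectory.structure is None:
            raise ValidationError("masses required without a structure")
        masses = trajectory.structure.masses
    if res_ids is None and trajectory.structure is not None:
        res_ids = trajectory.structure.res_ids
    theta = np.array([hinge_angle(f, domains, masses, res_ids)
                      for f in trajectory.coords])
    phi = np.array([twist_angle(f, domains, masses, res_ids)
                    for f in trajectory.coords])
    rg = np.array([radius_of_gyration(f, masses) for f in trajectory.coords])
    return DomainAngles(theta=theta, phi=phi, rg=rg)


# ---------------------------------------------------------------------------
# contacts and salt bridges
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}


def _residue_groups(structure: Structure):
    """Per-residue heavy side-chain atoms (all heavy atoms when a residue
    has no side chain, e.g. single-bead residues)."""
    groups = {}
    for rid in structure.residue_ids:
        idx = structure.residue_atom_indices(int(rid))
        heavy = idx[np.isin(idx, structure.heavy_atom_indices)]
        side = heavy[~np.isin(structure.atom_names[heavy],
                              sorted(_BACKBONE))]
        groups[int(rid)] = side if side.size else heavy
    return groups


def contact_map(trajectory: Trajectory, structure: Structure | None = None,
                residue_pairs=None):
    """Time-averaged residue–residue minimum side-chain distance matrix.

    Returns ``(residue_ids, matrix)``; the matrix is symmetric with zero
    diagonal.  With ``residue_pairs`` only those entries are filled (others
    are NaN).
    """
    structure = structure or trajectory.structure
    if structure is None:
        raise ValidationError("contact map requires a structure")
    groups = _residue_groups(structure)
    rids = [int(r) for r in structure.residue_ids]
    pos = {r: i for i, r in enumerate(rids)}
    if residue_pairs is None:
        residue_pairs = [(a, b) for i, a in enumerate(rids)
                         for b in rids[i + 1:]]
    acc = np.full((len(rids), len(rids)), np.nan)
    np.fill_diagonal(acc, 0.0)
    for a, b in residue_pairs:
        ia, ib = groups[a], groups[b]
        dmin = np.empty(len(trajectory))
        for f, frame in enumerate(trajectory.coords):
            d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :],
                               axis=-1)
            dmin[f] = d.min()
        acc[pos[a], pos[b]] = acc[pos[b], pos[a]] = dmin.mean()
    return np.array(rids), acc


def identify_salt_bridges(contact_matrix, residue_ids, charges,
                          distance_cutoff: float = 10.0):
    """Oppositely charged residue pairs whose mean charged-group distance is
    within the cutoff, sorted by distance.  ``charges`` maps residue → formal
    charge."""
    out = []
    rids = list(residue_ids)
    for i, a in enumerate(rids):
        for j in range(i + 1, len(rids)):
            b = rids[j]
            qa, qb = charges.get(int(a), 0), charges.get(int(b), 0)
            if qa * qb >= 0:
                continue
            d = contact_matrix[i, j]
            if np.isfinite(d) and d <= distance_cutoff:
                out.append((int(a), int(b), float(d)))
    return sorted(out, key=lambda t: t[2])


# ---------------------------------------------------------------------------
# hydrogen-bond / salt-bridge occupancies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HbondCriteria:
    """Distance (Å) between the residues' charged/polar groups, plus an
    optional donor–hydrogen–acceptor angle test when hydrogens exist.
    For hydrogen-free coarse-grained systems only the distance applies."""

    distance_cutoff: float = 3.5
    angle_cutoff: float | None = 120.0


_CHARGED_GROUP = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def _charged_group_atoms(structure: Structure, rid: int) -> np.ndarray:
    idx = structure.residue_atom_indices(rid)
    name = str(structure.res_names[idx[0]])
    wanted = _CHARGED_GROUP.get(name)
    if wanted:
        sel = idx[np.isin(structure.atom_names[idx], wanted)]
        if sel.size:
            return sel
    return idx[np.isin(idx, structure.heavy_atom_indices)]


@dataclass
class OccupancyTable:
    """Residue-pair × state hydrogen-bond occupancies (%) with block-average
    standard errors; states with zero frames are NaN and flagged."""

    occupancy: pd.DataFrame
    stderr: pd.DataFrame
    empty_states: tuple = ()

    def __post_init__(self) -> None:
        vals = self.occupancy.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if np.any((vals[ok] < 0) | (vals[ok] > 100)):
            raise ValidationError("occupancies must lie in [0, 100]%")


def hbond_occupancy(trajectory: Trajectory, pairs, criteria: HbondCriteria,
                    state_labels, n_blocks: int = 5) -> OccupancyTable:
    """Per-state percentage of frames in which each residue pair satisfies
    the bonding criteria, with a standard error over ``n_blocks`` contiguous
    blocks of that state's frames."""
    structure = trajectory.structure
    if structure is None:
        raise ValidationError("occupancy analysis requires a structure")
    state_labels = np.asarray(state_labels)
    if state_labels.shape[0] != len(trajectory):
        raise ShapeError("one state label per frame required")

    satisfied = np.zeros((len(pairs), len(trajectory)), dtype=bool)
    has_h = bool(np.any(structure.elements == "H"))
    for p, (a, b) in enumerate(pairs):
        ia = _charged_group_atoms(structure, int(a))
        ib = _charged_group_atoms(structure, int(b))
        for f, frame in enumerate(trajectory.coords):
            d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :],
                               axis=-1)
            ok = d.min() <= criteria.distance_cutoff
            if ok and criteria.angle_cutoff is not None and has_h:
                ok = _dha_angle_ok(structure, frame, ia, ib,
                                   criteria.distance_cutoff,
                                   criteria.angle_cutoff)
            satisfied[p, f] = ok

    states = list(dict.fromkeys(state_labels.tolist()))
    occ = pd.DataFrame(index=[f"{a}-{b}" for a, b in pairs], columns=states,
                       dtype=float)
    err = occ.copy()
    empty = []
    for s in states:
        mask = state_labels == s
        nf = int(mask.sum())
        if nf == 0:
            empty.append(s)
            continue
        sub = satisfied[:, mask]
        occ[s] = 100.0 * sub.mean(axis=1)
        blocks = np.array_split(np.arange(nf), n_blocks)
        bm = np.array([100.0 * sub[:, b].mean(axis=1)
                       for b in blocks if b.size])
        err[s] = bm.std(axis=0, ddof=1) / np.sqrt(bm.shape[0]) \
            if bm.shape[0] > 1 else 0.0
    return OccupancyTable(occupancy=occ, stderr=err,
                          empty_states=tuple(empty))


def _dha_angle_ok(structure, frame, donor_heavy, acceptor_heavy,
                  dist_cutoff, angle_cutoff) -> bool:
    """True if some donor-attached hydrogen makes a D–H–A angle above the
    cutoff with an acceptor within the distance cutoff."""
    h_idx = np.flatnonzero(structure.elements == "H")
    for d in donor_heavy:
        attached = h_idx[np.linalg.norm(frame[h_idx] - frame[d], axis=1)
                         < 1.25]
        for h in attached:
            for a in acceptor_heavy:
                if np.linalg.norm(frame[d] - frame[a]) > dist_cutoff:
                    continue
                u = frame[d] - frame[h]
                v = frame[a] - frame[h]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                if ang >= angle_cutoff:
                    return True
    return False


# ---------------------------------------------------------------------------
# clustering and state classification
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Per-frame labels, cluster centers and population fractions."""

    labels: np.ndarray
    centers: np.ndarray        # (k, n_selected, 3)
    populations: np.ndarray    # (k,), sums to 1

    def __post_init__(self) -> None:
        if not np.isclose(self.populations.sum(), 1.0):
            raise ValidationError("populations must sum to 1")


def kmeans_states(trajectory: Trajectory, k: int, selection=None,
                  seed: int = 0) -> ClusterResult:
    """k-means (k-means++ init, Lloyd iterations) on frames superposed to
    the first frame over the selection (all atoms by default, mirroring
    all-Cα clustering for bead-per-residue systems)."""
    from sklearn.cluster import KMeans

    n_frames = len(trajectory)
    if not (1 <= k <= n_frames):
        raise ValidationError(f"need 1 <= k <= n_frames ({n_frames})")
    sel = np.arange(trajectory.n_atoms) if selection is None \
        else np.asarray(list(selection), dtype=int)
    ref = trajectory.coords[0]
    aligned = np.array([superpose(f, ref, sel)[sel]
                        for f in trajectory.coords])
    flat = aligned.reshape(n_frames, -1)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(flat)
    centers = km.cluster_centers_.reshape(k, sel.size, 3)
    pops = np.bincount(labels, minlength=k) / n_frames
    return ClusterResult(labels=labels, centers=centers, populations=pops)


@dataclass(frozen=True)
class StateRule:
    """Threshold predicate on (θ, φ); all given bounds are strict
    inequalities, e.g. ``phi_lt=58`` means φ < 58°."""

    label: str
    theta_gt: float | None = None
    theta_lt: float | None = None
    phi_gt: float | None = None
    phi_lt: float | None = None

    def matches(self, theta: float, phi: float) -> bool:
        if self.theta_gt is not None and not theta > self.theta_gt:
            return False
        if self.theta_lt is not None and not theta < self.theta_lt:
            return False
        if self.phi_gt is not None and not phi > self.phi_gt:
            return False
        if self.phi_lt is not None and not phi < self.phi_lt:
            return False
        return True


def classify_states(angles: DomainAngles, rules) -> np.ndarray:
    """First-matching-rule label per frame; frames matching no rule are
    labeled ``"unassigned"``."""
    out = np.full(len(angles.theta), "unassigned", dtype=object)
    for i, (t, p) in enumerate(zip(angles.theta, angles.phi)):
        for rule in rules:
            if rule.matches(t, p):
                out[i] = rule.label
                break
    return out


# ---------------------------------------------------------------------------
# free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """F(θ, φ) = −kB·T·ln P on populated bins, shifted so min F = 0."""

    theta_edges: np.ndarray
    phi_edges: np.ndarray
    free_energy: np.ndarray     # (n_theta, n_phi), NaN where unpopulated
    temperature: float

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is empty."""
        return ~np.isfinite(self.free_energy)

    def __post_init__(self) -> None:
        populated = self.free_energy[np.isfinite(self.free_energy)]
        if populated.size and not np.isclose(populated.min(), 0.0):
            raise ValidationError("populated minimum must be zero")
        if populated.size and np.any(populated < -1e-12):
            raise ValidationError("free energies must be non-negative")


def free_energy_surface(theta, phi, temperature: float = 300.0,
                        bin_width: float = 2.0) -> FreeEnergySurface:
    """Boltzmann inversion of the 2-D (θ, φ) histogram (bin width in deg)."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if theta.size == 0 or theta.size != phi.size:
        raise ValidationError("need equal-length non-empty angle series")
    def _edges(values):
        lo = np.floor(values.min() / bin_width) * bin_width
        nbins = max(1, int(np.ceil((values.max() - lo) / bin_width + 1e-9)))
        return lo + bin_width * np.arange(nbins + 1)

    t_edges = _edges(theta)
    p_edges = _edges(phi)
    counts, t_edges, p_edges = np.histogram2d(theta, phi,
                                              bins=[t_edges, p_edges])
    with np.errstate(divide="ignore"):
        f = -KB * temperature * np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return FreeEnergySurface(theta_edges=t_edges, phi_edges=p_edges,
                             free_energy=f, temperature=temperature)


# ---------------------------------------------------------------------------
# basin transitions
# ---------------------------------------------------------------------------

def count_transitions(series, lower: float, upper: float) -> int:
    """Number of crossings between two basins of a 1-D series with
    hysteresis: the series must dip below ``lower`` to register the first
    basin and exceed ``upper`` to register the second (noise between the
    thresholds is ignored)."""
    if lower >= upper:
        raise ValidationError("need lower < upper")
    state = 0
    transitions = 0
    for v in np.asarray(series, dtype=float):
        if v < lower:
            if state == +1:
                transitions += 1
            state = -1
        elif v > upper:
            if state == -1:
                transitions += 1
            state = +1
    return transitions
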