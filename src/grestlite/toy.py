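"""Coarse-grained two-domain protein with a double-basin open/closed potential.

The generator builds a bead-per-residue model of a periplasmic-binding-
protein-like molecule: two compact globular domains (beads on spherical
shells, NTD then CTD along the chain) joined by a short hinge strand, with
an inter-domain cleft.  The two domains plus the hinge form two internally
rigid units (elastic-network restrained); the CTD unit can rotate about the
last hinge bead, which is the single large-amplitude degree of freedom.
Open and closed reference conformations are rigid rotations of the same
geometry, so all bonded reference values are satisfied exactly in both.

The closed state is stabilized by planted inter-domain charge-pair contacts
(the analog of inter-domain salt bridges); each such pair also carries a
double-basin Gaussian contact well with minima at the closed and open pair
distances.  Well depths are calibrated at build time so that the potential
energy barrier along the closed→open rigid rotation path equals a target
(default 8 kBT at 300 K) and the two basins are iso-energetic.  Because the
barrier lives entirely in solute–solute nonbonded terms, solute tempering
flattens it, which is the premise the replica-exchange demonstration tests.

Energy terms and units: harmonic bonds/angles/elastic network, Lennard-Jones,
unscreened Coulomb with a uniform dielectric, Gaussian contact wells;
kcal/mol, Å, K, amu.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB
from .errors import ConstructionError, ValidationError
from .structure import DomainDefinition, Structure, Trajectory, make_domains

__all__ = [
    "ToySystem",
    "SyntheticTrajectorySpec",
    "build_two_domain_system",
    "reference_conformation",
    "generate_synthetic_trajectory",
    "rigid_path_coords",
    "barrier_profile",
]


@dataclass
class ToySystem:
    """Parameters, reference conformations and planted metadata of the toy."""

    n_per_domain: int
    n_hinge: int
    masses: np.ndarray            # (N,)
    charges: np.ndarray           # (N,) formal charge, e
    domain_labels: np.ndarray     # (N,) in {"NTD", "hinge", "CTD"}
    surface: np.ndarray           # (N,) bool
    # bonded terms
    bond_idx: np.ndarray          # (B, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray         # (A, 3)
    angle_theta0: np.ndarray      # rad
    angle_k: np.ndarray           # kcal/mol/rad^2
    elastic_idx: np.ndarray       # (E, 2)
    elastic_r0: np.ndarray
    elastic_k: np.ndarray
    # double-basin contact wells
    contact_idx: np.ndarray       # (K, 2)
    contact_r_closed: np.ndarray
    contact_r_open: np.ndarray
    contact_d_closed: np.ndarray  # well depths, kcal/mol
    contact_d_open: np.ndarray
    contact_width: np.ndarray     # Å
    # nonbonded parameters
    lj_eps: np.ndarray            # (N,)
    lj_sigma: np.ndarray          # (N,)
    dielectric: float
    eps_combination: str = "geometric"
    # reference conformations, keyed by state name
    references: dict = field(default_factory=dict)
    # planted ground truth (bead indices, 0-based)
    planted: dict = field(default_factory=dict)
    pivot: int = 0                # bead the CTD unit rotates about

    def __post_init__(self) -> None:
        # note: no integer-charge check here — a parameter-scaled copy
        # (solute charges × √(βm/β0)) legitimately carries scaled charges;
        # the builder enforces integer formal charges on what it constructs
        self.charges = np.asarray(self.charges, dtype=float)
        n = self.charges.size
        # rigid units: A = NTD + hinge, B = CTD; nonbonded terms act only
        # between the units (intra-unit geometry is elastic-network fixed)
        self._unit_b_start = self.pivot + 1
        ia, ja = np.meshgrid(np.arange(self._unit_b_start),
                             np.arange(self._unit_b_start, n), indexing="ij")
        pairs = np.column_stack([ia.ravel(), ja.ravel()])
        pairs = pairs[pairs[:, 1] - pairs[:, 0] > 2]  # exclude 1-2 / 1-3
        self.nb_pairs = pairs
        qi, qj = self.charges[pairs[:, 0]], self.charges[pairs[:, 1]]
        self.nb_qq = qi * qj
        self.nb_eps = np.sqrt(self.lj_eps[pairs[:, 0]] * self.lj_eps[pairs[:, 1]])
        self.nb_sigma = 0.5 * (self.lj_sigma[pairs[:, 0]]
                               + self.lj_sigma[pairs[:, 1]])

    @property
    def n_beads(self) -> int:
        return self.charges.size

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(1, self.n_beads + 1)

    @property
    def domains(self) -> DomainDefinition:
        n, nh = self.n_per_domain, self.n_hinge
        return make_domains(
            ntd=[(1, n)],
            ctd=[(n + nh + 1, self.n_beads)],
            hinge=[(n + 1, n + nh)],
            ntd_base=[(n - 1, n)],
            ctd_base=[(n + nh + 1, n + nh + 2)],
        )

    @property
    def sscr_params(self):
        """Radius-scaled selection cutoffs for this coarse-grained system:
        beads have ~2.75 Å radii, so the inter-domain "heavy-atom" contact
        cutoff is the contact band used at construction instead of the
        atomistic 5 Å default."""
        from .selection import SscrParams
        hi = self.planted.get("interface_band_hi", [9.5])[0]
        # a fully exposed bead has ~218 Å² (radius 2.75 + probe 1.4); ~10%
        # exposure marks it as surface, versus 50 Å² for atomistic residues
        return SscrParams(interface_cutoff=float(hi), sasa_threshold=20.0)

    def to_structure(self, state: str = "closed") -> Structure:
        """One single-bead residue per bead; bead radii are σ/2."""
        q = self.charges
        names = np.where(q > 0, "CGP", np.where(q < 0, "CGN", "CGU"))
        return Structure(
            atom_names=np.full(self.n_beads, "CA"),
            elements=np.full(self.n_beads, "C"),
            res_ids=self.residue_ids,
            res_names=names,
            coords=reference_conformation(self, state),
            masses=self.masses,
            formal_charges=q,
            atom_radii=self.lj_sigma / 2.0,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(x):
            return np.asarray(x).tolist()
        d = {
            "n_per_domain": self.n_per_domain, "n_hinge": self.n_hinge,
            "pivot": self.pivot, "dielectric": self.dielectric,
            "eps_combination": self.eps_combination,
            "planted": {k: arr(v) for k, v in self.planted.items()},
            "references": {k: arr(v) for k, v in self.references.items()},
        }
        for name in ("masses", "charges", "surface", "bond_idx", "bond_r0",
                     "bond_k", "angle_idx", "angle_theta0", "angle_k",
                     "elastic_idx", "elastic_r0", "elastic_k", "contact_idx",
                     "contact_r_closed", "contact_r_open", "contact_d_closed",
                     "contact_d_open", "contact_width", "lj_eps", "lj_sigma"):
            d[name] = arr(getattr(self, name))
        d["domain_labels"] = [str(s) for s in self.domain_labels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystem":
        kw = dict(d)
        kw["references"] = {k: np.asarray(v) for k, v in d["references"].items()}
        kw["planted"] = {k: list(v) for k, v in d["planted"].items()}
        for name in ("masses", "charges", "bond_r0", "bond_k", "angle_theta0",
                     "angle_k", "elastic_r0", "elastic_k", "contact_r_closed",
                     "contact_r_open", "contact_d_closed", "contact_d_open",
                     "contact_width", "lj_eps", "lj_sigma"):
            kw[name] = np.asarray(d[name], dtype=float)
        for name in ("bond_idx", "angle_idx", "elastic_idx", "contact_idx"):
            kw[name] = np.asarray(d[name], dtype=int).reshape(len(d[name]), -1)
        kw["surface"] = np.asarray(d["surface"], dtype=bool)
        kw["domain_labels"] = np.asarray(d["domain_labels"])
        return cls(**kw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ToySystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Recipe for a planted-state synthetic trajectory."""

    labels: tuple
    sigma: float = 0.0            # Gaussian coordinate noise, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if len(self.labels) < 1:
            raise ValidationError("at least one frame label required")


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _rotate_unit_b(coords: np.ndarray, pivot: int, rotation: Rotation
                   ) -> np.ndarray:
    out = coords.copy()
    center = coords[pivot]
    out[pivot + 1:] = rotation.apply(coords[pivot + 1:] - center) + center
    return out


def _bend(coords: np.ndarray, pivot: int, angle_deg: float) -> np.ndarray:
    rot = Rotation.from_rotvec(np.radians(angle_deg)
                               * np.array([0.0, 0.0, 1.0]))
    return _rotate_unit_b(coords, pivot, rot)


def _com(x: np.ndarray, idx, m: np.ndarray) -> np.ndarray:
    w = m[idx]
    return (x[idx] * w[:, None]).sum(axis=0) / w.sum()


def _hinge_angle_of(coords: np.ndarray, n: int, nh: int, m: np.ndarray
                    ) -> float:
    a = _com(coords, np.arange(n), m)
    h = _com(coords, np.arange(n, n + nh), m)
    b = _com(coords, np.arange(n + nh, coords.shape[0]), m)
    u, v = a - h, b - h
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _fibonacci_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points ordered pole (+z) to pole (−z)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z ** 2)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _orient(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotate a +z-pole-first point set so the pole points along ``direction``."""
    d = direction / np.linalg.norm(direction)
    rot, _ = Rotation.align_vectors(d[None, :], np.array([[0.0, 0.0, 1.0]]))
    return rot.apply(points)


def _min_cross_distance(coords: np.ndarray, pivot: int) -> float:
    """Minimum distance between the two rigid units, excluding pairs closer
    than 3 along the chain (those are bonded/angle-coupled)."""
    n = coords.shape[0]
    a = coords[:pivot + 1]
    b = coords[pivot + 1:]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    for i in range(max(0, pivot - 1), pivot + 1):
        for j in range(pivot + 1, min(n, i + 3)):
            d[i, j - pivot - 1] = np.inf
    return float(d.min())


def build_two_domain_system(
    n_per_domain: int = 10,
    n_hinge: int = 4,
    charged_fraction: float = 0.4,
    seed: int = 7,
    *,
    barrier_kbt: float = 8.0,
    temperature: float = 300.0,
    dielectric: float = 10.0,
    bend_delta: float = 45.0,
    interface_gap: float = 4.0,
    contact_width: float = 1.2,
    lj_eps: float = 0.2,
    lj_sigma: float = 5.5,
    bond_k: float = 10.0,
    angle_k: float = 8.0,
    elastic_k: float = 10.0,
) -> ToySystem:
    """Build the deterministic two-domain bead model.

    ``barrier_kbt`` is the target closed↔open potential barrier along the
    rigid rotation path, in units of kB·temperature; contact well depths are
    calibrated to reach it with iso-energetic basins.  ``bend_delta`` is the
    CTD rotation (degrees) separating the closed and open references.
    """
    if n_per_domain < 8 or n_hinge < 2:
        raise ConstructionError(
            "need n_per_domain >= 8 and n_hinge >= 2 to place an interface")
    rng = np.random.default_rng(seed)
    n, nh = n_per_domain, n_hinge
    n_beads = 2 * n + nh
    pivot = n + nh - 1
    masses = np.full(n_beads, 110.0)
    ntd_beads = np.arange(n)
    ctd_beads = np.arange(n + nh, n_beads)

    radius = max(3.6, 1.15 * np.sqrt(n))
    jitter = rng.normal(0.0, 0.25, (n_beads, 3))
    # the last two hinge beads sit on the rotation axis (z through the
    # pivot): distances from them to any CTD bead are exactly invariant
    # under the bend, so elastic "ligaments" anchored there leave the bend
    # as the single soft inter-domain degree of freedom
    hinge = np.zeros((nh, 3))
    for j in range(nh - 2):
        hinge[j] = [-(nh - 2 - j) * 3.8, 0.0, 0.0]
    hinge[nh - 2] = [0.0, 0.0, -3.8]
    hinge[nh - 1] = [0.0, 0.0, 0.0]
    jitter[n + nh - 2] = 0.0   # keep both anchors exactly on the axis
    jitter[n + nh - 1] = 0.0
    c_a = hinge[0] + np.array([0.0, radius + 4.0, 0.0])
    fib = _fibonacci_points(n)

    def _try_geometry(c_b: np.ndarray, band_hi: float) -> ToySystem:
        # chain threads bottom-out: last NTD bead and first CTD bead sit
        # at the pole facing their hinge attachment
        ntd = c_a + radius * _orient(fib[::-1], hinge[0] - c_a)
        ctd = c_b + radius * _orient(fib, hinge[-1] - c_b)
        closed = np.vstack([ntd, hinge, ctd]) + jitter
        open_ = _bend(closed, pivot, -bend_delta)
        if _min_cross_distance(closed, pivot) < 5.3 or \
                _min_cross_distance(open_, pivot) < 5.3:
            raise ConstructionError("steric clash between the units")
        dist_c = np.linalg.norm(closed[ntd_beads][:, None, :]
                                - closed[ctd_beads][None, :, :], axis=-1)
        dist_o = np.linalg.norm(open_[ntd_beads][:, None, :]
                                - open_[ctd_beads][None, :, :], axis=-1)
        # charge pairs live in the outer contact band: the steric wall of
        # the tight cleft comes from closer neutral bead contacts, while the
        # electrostatic loss across the barrier stays small enough for the
        # well calibration to have headroom
        cand_pairs = np.argwhere((dist_c >= 7.2) & (dist_c <= band_hi)
                                 & (dist_o - dist_c >= 2.5))
        sep = (dist_o - dist_c)[cand_pairs[:, 0], cand_pairs[:, 1]]
        interface_pairs, used = [], set()
        for idx in np.argsort(-sep):
            bi, bj = cand_pairs[idx]
            gi, gj = int(ntd_beads[bi]), int(ctd_beads[bj])
            if gi in used or gj in used:
                continue
            interface_pairs.append((gi, gj))
            used.update((gi, gj))
            if len(interface_pairs) == 3:
                break
        if len(interface_pairs) < 3:
            raise ConstructionError("fewer than 3 separable contact pairs")

        theta_c = _hinge_angle_of(closed, n, nh, masses)
        theta_o = _hinge_angle_of(open_, n, nh, masses)
        if theta_o - theta_c < 20.0:
            raise ConstructionError(
                f"open/closed hinge angles too similar ({theta_o:.1f} vs "
                f"{theta_c:.1f} deg); increase bend_delta")

        # ---- charges ------------------------------------------------------
        charges = np.zeros(n_beads)
        for p, (gi, gj) in enumerate(interface_pairs):
            sign = 1.0 if p % 2 == 0 else -1.0
            charges[gi] = sign
            charges[gj] = -sign
        hinge_charged = [n, n + 1]
        charges[hinge_charged[0]] = +1.0
        charges[hinge_charged[1]] = -1.0

        budget = max(2 * int(round(charged_fraction * n_beads / 2.0)), 8)
        n_distant_pairs = min((budget - 8) // 2, 3)
        # residues the selection step will call "interface": any bead of one
        # domain within band_hi of the other; distant charges must stay well
        # outside the 6 Å Cα selection cutoff around all of them.  They are
        # placed as adjacent ± dipoles within one domain so they add no
        # long-range electrostatic bias along the bend.
        interface_beads = sorted(
            set(int(g) for g in ntd_beads[dist_c.min(axis=1) <= band_hi])
            | set(int(g) for g in ctd_beads[dist_c.min(axis=0) <= band_hi]))
        away = lambda g: min(np.linalg.norm(closed[g] - closed[b])
                             for b in interface_beads)
        distant_charged = []
        far_order = {
            "NTD": sorted((g for g in ntd_beads),
                          key=lambda g: -np.linalg.norm(closed[g] - c_b)),
            "CTD": sorted((g for g in ctd_beads),
                          key=lambda g: -np.linalg.norm(closed[g] - c_a)),
        }
        for p in range(n_distant_pairs):
            domain = "NTD" if p % 2 == 0 else "CTD"
            pool = [g for g in far_order[domain]
                    if charges[g] == 0 and away(g) > 6.5]
            placed = False
            for g in pool:
                mates = [g2 for g2 in pool
                         if g2 != g and np.linalg.norm(closed[g] - closed[g2])
                         <= 2.5 * radius]
                if not mates:
                    continue
                g2 = min(mates,
                         key=lambda m: np.linalg.norm(closed[g] - closed[m]))
                charges[g], charges[g2] = 1.0, -1.0
                distant_charged.extend([int(g), int(g2)])
                placed = True
                break
            if not placed:
                break
        assert abs(charges.sum()) < 1e-12

        labels = np.array(["NTD"] * n + ["hinge"] * nh + ["CTD"] * n)

        # ---- bonded terms (identical reference values in both states) -----
        i = np.arange(n_beads)
        bond_idx = np.column_stack([i[:-1], i[1:]])
        bond_r0 = np.linalg.norm(np.diff(closed, axis=0), axis=1)

        triples = np.column_stack([i[:-2], i[1:-1], i[2:]])
        triples = triples[(triples[:, 2] <= pivot) | (triples[:, 0] > pivot)]
        u = closed[triples[:, 0]] - closed[triples[:, 1]]
        v = closed[triples[:, 2]] - closed[triples[:, 1]]
        cos0 = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angle_theta0 = np.arccos(np.clip(cos0, -1.0, 1.0))

        # full intra-unit elastic network: each rigid unit keeps every
        # internal distance (zero strain at both references, which are
        # rigid rotations of one geometry)
        def _elastic_pairs(lo, hi):
            return [(a, b, float(np.linalg.norm(closed[a] - closed[b])))
                    for a in range(lo, hi) for b in range(a + 2, hi)]

        el = _elastic_pairs(0, pivot + 1) + _elastic_pairs(pivot + 1, n_beads)
        # hinge ligaments: each on-axis anchor to its 4 nearest CTD beads
        # (reference distances identical in closed and open by construction)
        for anchor in (pivot - 1, pivot):
            d_to_ctd = np.linalg.norm(closed[ctd_beads] - closed[anchor],
                                      axis=1)
            for b in ctd_beads[np.argsort(d_to_ctd)[:4]]:
                if b - anchor > 1:   # chain bond already covers adjacency
                    el.append((int(anchor), int(b),
                               float(np.linalg.norm(closed[anchor]
                                                    - closed[b]))))
        elastic_idx = np.array([(a, b) for a, b, _ in el], dtype=int)
        elastic_r0 = np.array([r for _, _, r in el])

        contact_idx = np.array(interface_pairs, dtype=int)
        rC = np.linalg.norm(closed[contact_idx[:, 0]]
                            - closed[contact_idx[:, 1]], axis=1)
        rO = np.linalg.norm(open_[contact_idx[:, 0]]
                            - open_[contact_idx[:, 1]], axis=1)

        system = ToySystem(
            n_per_domain=n, n_hinge=nh, masses=masses, charges=charges,
            domain_labels=labels, surface=np.ones(n_beads, dtype=bool),
            bond_idx=bond_idx, bond_r0=bond_r0,
            bond_k=np.full(bond_idx.shape[0], bond_k),
            angle_idx=triples, angle_theta0=angle_theta0,
            angle_k=np.full(triples.shape[0], angle_k),
            elastic_idx=elastic_idx, elastic_r0=elastic_r0,
            elastic_k=np.full(len(el), elastic_k),
            contact_idx=contact_idx, contact_r_closed=rC, contact_r_open=rO,
            contact_d_closed=np.zeros(3), contact_d_open=np.zeros(3),
            contact_width=np.full(3, contact_width),
            lj_eps=np.full(n_beads, lj_eps),
            lj_sigma=np.full(n_beads, lj_sigma),
            dielectric=dielectric, pivot=pivot,
        )

        # reference conformations: closed, open, plus an intermediate bend
        # and a twisted variant (planted extra states for analysis fixtures)
        axis = _com(closed, ctd_beads, masses) - closed[pivot]
        axis /= np.linalg.norm(axis)
        system.references = {
            "closed": closed, "open": open_,
            "intermediate": _bend(closed, pivot, -bend_delta / 2.0),
            "twisted": _rotate_unit_b(
                closed, pivot, Rotation.from_rotvec(np.radians(50.0) * axis)),
        }
        system.planted = {
            "interface_pairs": [list(p) for p in interface_pairs],
            "interface_charged": sorted(int(g) for g in used),
            "hinge_charged": [int(g) for g in hinge_charged],
            "distant_charged": distant_charged,
            "bend_delta_deg": [float(bend_delta)],
            "interface_band_hi": [float(band_hi)],
            "hinge_angle_closed_deg": [theta_c],
            "hinge_angle_open_deg": [theta_o],
        }

        _calibrate_contacts(system, barrier_kbt * KB * temperature)

        # both basins must be confined: the profile has to rise beyond each
        # reference (over-closing is blocked by the LJ wall, over-opening
        # by losing the open contact wells)
        from .energy import total_energy
        e_closed = total_energy(system, closed)
        e_open = total_energy(system, open_)
        over_c = min(total_energy(system, rigid_path_coords(system, x))
                     for x in np.linspace(-0.3, -0.05, 6))
        over_o = min(total_energy(system, rigid_path_coords(system, x))
                     for x in np.linspace(1.05, 1.3, 6))
        if over_c < e_closed - 0.3 or over_o < e_open - 0.3:
            raise ConstructionError(
                "a reference basin is not confined along the bend")
        return system

    # the smallest cleft without steric clashes keeps the Lennard-Jones
    # wall engaged just below the closed geometry (blocking over-closing);
    # widen the cleft and/or the contact band until a calibratable,
    # confined geometry is found
    last_error = None
    for band_hi in (9.5, 10.5, 11.5):
        for widen in range(10):
            c_b = np.array([c_a[0] + 2.0 * radius + interface_gap
                            + 0.35 * widen, radius + 4.0, 0.0])
            try:
                return _try_geometry(c_b, band_hi)
            except ConstructionError as exc:
                last_error = exc
    raise ConstructionError(
        f"could not build a two-domain system for these parameters; "
        f"last failure: {last_error}")


def _nonbonded_base_energy(system: ToySystem, coords: np.ndarray) -> float:
    """Coulomb + LJ over the inter-unit pair list (no contact wells)."""
    from .constants import COULOMB_CONSTANT
    d = np.linalg.norm(coords[system.nb_pairs[:, 0]]
                       - coords[system.nb_pairs[:, 1]], axis=1)
    e_coul = COULOMB_CONSTANT / system.dielectric * np.sum(system.nb_qq / d)
    sr6 = (system.nb_sigma / d) ** 6
    e_lj = np.sum(4.0 * system.nb_eps * (sr6 ** 2 - sr6))
    return float(e_coul + e_lj)


def rigid_path_coords(system: ToySystem, lam: float) -> np.ndarray:
    """Coordinates on the rigid closed→open rotation path, λ ∈ [0, 1].

    λ = 0 is the closed reference, λ = 1 the open reference; intermediate
    values rotate the CTD unit by the corresponding fraction of the bend.
    """
    closed = system.references["closed"]
    delta = system.planted["bend_delta_deg"][0]
    return _bend(closed, system.pivot, -lam * delta)


def barrier_profile(system: ToySystem, n_points: int = 81
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Total potential energy along the rigid closed→open path."""
    from .energy import total_energy
    lam = np.linspace(0.0, 1.0, n_points)
    e = np.array([total_energy(system, rigid_path_coords(system, x))
                  for x in lam])
    return lam, e


def _calibrate_contacts(system: ToySystem, barrier_target: float) -> None:
    """Solve for well depths: iso-energetic basins, target barrier height."""
    from scipy.optimize import brentq

    lam = np.linspace(0.0, 1.0, 81)
    coords = [rigid_path_coords(system, x) for x in lam]
    e0 = np.array([_nonbonded_base_energy(system, c) for c in coords])
    ii, jj = system.contact_idx[:, 0], system.contact_idx[:, 1]
    r = np.array([np.linalg.norm(c[ii] - c[jj], axis=1) for c in coords])
    w2 = 2.0 * system.contact_width ** 2
    gC = -np.exp(-(r - system.contact_r_closed) ** 2 / w2).sum(axis=1)
    gO = -np.exp(-(r - system.contact_r_open) ** 2 / w2).sum(axis=1)

    def depth_open(a):
        # iso-energetic basins: e0 + a*gC + b*gO equal at both path ends
        return -((e0[0] - e0[-1]) + a * (gC[0] - gC[-1])) / (gO[0] - gO[-1])

    def barrier(a):
        b = depth_open(a)
        prof = e0 + a * gC + b * gO
        return prof.max() - prof[0]

    lo, hi = 1e-4, 60.0
    if barrier(lo) - barrier_target > 0:
        raise ConstructionError(
            "intrinsic electrostatic barrier already exceeds the target; "
            "increase the dielectric constant or the barrier target")
    if barrier(hi) - barrier_target < 0:
        raise ConstructionError("cannot reach the target barrier with "
                                "well depths up to 60 kcal/mol")
    a = brentq(lambda x: barrier(x) - barrier_target, lo, hi, xtol=1e-10)
    b = depth_open(a)
    if b < 0:
        raise ConstructionError("open-well depth came out negative; "
                                "the open basin is already over-stabilized")
    system.contact_d_closed = np.full(system.contact_idx.shape[0], a)
    system.contact_d_open = np.full(system.contact_idx.shape[0], b)


# ---------------------------------------------------------------------------
# references and synthetic trajectories
# ---------------------------------------------------------------------------

def reference_conformation(system: ToySystem, state: str) -> np.ndarray:
    """Stored reference coordinates for ``state`` (idempotent copy)."""
    try:
        return system.references[state].copy()
    except KeyError:
        raise LookupError(
            f"unknown state {state!r}; available: "
            f"{sorted(system.references)}") from None


def generate_synthetic_trajectory(system: ToySystem,
                                  spec: SyntheticTrajectorySpec) -> Trajectory:
    """Frame i = reference(label_i) + isotropic Gaussian noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((len(spec.labels), system.n_beads, 3))
    for f, label in enumerate(spec.labels):
        ref = reference_conformation(system, label)
        noise = rng.normal(0.0, spec.sigma, ref.shape) if spec.sigma > 0 \
            else 0.0
        frames[f] = ref + noise
    return Trajectory(coords=frames, structure=system.to_structure("closed"),
                      label="synthetic")
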