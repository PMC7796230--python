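"""Region-based energy decomposition and the solute-tempering scaled potential.

The modified potential of replica *m* at solute inverse temperature βm with
bath β0 is

    E_m = (βm/β0) · E_uu  +  Σ_i (βm/β0)^{k_i/l_i} · E_uv,i  +  E_vv

where *uu*, *uv* and *vv* collect interactions internal to, bridging, and
external to the solute region, and k_i/l_i is the per-term-class exponent
(1/2 for pairwise Coulomb and Lennard-Jones terms: l=2 atoms form the term,
k=1 of them is solute).  Only the nonbonded classes listed in
``scaled_classes`` are partitioned; every other term (all bonded terms by
default) is left unscaled in *vv*.

Two equivalent routes are provided: term scaling (decompose, then multiply
component sums) and parameter scaling (scale solute charges by √(βm/β0) and
solute LJ ε by βm/β0, then evaluate the ordinary potential).  Their agreement
is the central correctness check of the Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import COULOMB_CONSTANT, KB
from .errors import ParameterError, ValidationError

__all__ = [
    "NONBONDED_CLASSES",
    "BONDED_CLASSES",
    "DEFAULT_SCALED_CLASSES",
    "TermScalingRule",
    "EnergyDecomposition",
    "SoluteTemperatureState",
    "energy_components",
    "total_energy",
    "decompose_energy",
    "scaling_factor",
    "scaled_energy",
    "parameter_scaled_system",
    "pair_scale_arrays",
    "energy_and_forces",
    "com_restraint_energy",
    "com_restraint_gradient",
]

NONBONDED_CLASSES = ("coulomb", "lj", "contact")
BONDED_CLASSES = ("bond", "angle", "elastic")
#: Term classes scaled by default for the toy system.  The Coulomb and LJ
#: classes implement the standard solute-tempering scope; the toy's
#: double-basin contact wells are its coarse-grained stand-in for the native
#: inter-domain contacts and are scaled alongside them.
DEFAULT_SCALED_CLASSES = ("coulomb", "lj", "contact")


@dataclass(frozen=True)
class TermScalingRule:
    """Exponent rule for a solute–solvent term class: multiplier (βm/β0)^{k/l}.

    ``l`` is the maximum number of atoms forming the interaction, ``k`` the
    number of solute atoms in a solute–solvent instance (pairwise terms:
    l=2, k=1).
    """

    term: str
    l: int = 2
    k: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.k < self.l):
            raise ValidationError("need 1 <= k < l for a solute-solvent term")

    @property
    def exponent(self) -> float:
        return self.k / self.l


@dataclass(frozen=True)
class SoluteTemperatureState:
    """Solute temperature Tm and bath temperature T0 of one replica (K)."""

    solute_temperature: float
    bath_temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.solute_temperature <= 0 or self.bath_temperature <= 0:
            raise ValidationError("temperatures must be positive")

    @property
    def beta_ratio(self) -> float:
        """βm/β0 = T0/Tm."""
        return self.bath_temperature / self.solute_temperature

    @property
    def beta_bath(self) -> float:
        return 1.0 / (KB * self.bath_temperature)


@dataclass
class EnergyDecomposition:
    """E_uu, per-class E_uv,i and E_vv (kcal/mol); sums to the unscaled total."""

    e_uu: float
    e_uv: dict = field(default_factory=dict)
    e_vv: float = 0.0

    @property
    def total(self) -> float:
        return self.e_uu + sum(self.e_uv.values()) + self.e_vv

    def scaled(self, state: SoluteTemperatureState,
               rules: dict | None = None) -> float:
        s = state.beta_ratio
        out = s * self.e_uu + self.e_vv
        for cls, e in self.e_uv.items():
            rule = (rules or {}).get(cls, TermScalingRule(cls))
            out += s ** rule.exponent * e
        return out


# ---------------------------------------------------------------------------
# plain energies
# ---------------------------------------------------------------------------

def _pair_distances(coords, idx):
    d = coords[idx[:, 0]] - coords[idx[:, 1]]
    return d, np.linalg.norm(d, axis=1)


def _nonbonded_pair_energies(system, coords):
    """Per-pair Coulomb and LJ energies on the nonbonded pair list, and
    per-pair contact-well energies on the contact list."""
    _, r = _pair_distances(coords, system.nb_pairs)
    e_coul = COULOMB_CONSTANT / system.dielectric * system.nb_qq / r
    sr6 = (system.nb_sigma / r) ** 6
    e_lj = 4.0 * system.nb_eps * (sr6 ** 2 - sr6)
    if system.contact_idx.size:
        _, rc = _pair_distances(coords, system.contact_idx)
        w2 = 2.0 * system.contact_width ** 2
        e_con = (-system.contact_d_closed
                 * np.exp(-(rc - system.contact_r_closed) ** 2 / w2)
                 - system.contact_d_open
                 * np.exp(-(rc - system.contact_r_open) ** 2 / w2))
    else:
        e_con = np.zeros(0)
    return e_coul, e_lj, e_con


def _bonded_energies(system, coords):
    out = {}
    _, r = _pair_distances(coords, system.bond_idx)
    out["bond"] = float(np.sum(system.bond_k * (r - system.bond_r0) ** 2))
    _, r = _pair_distances(coords, system.elastic_idx)
    out["elastic"] = float(np.sum(system.elastic_k
                                  * (r - system.elastic_r0) ** 2))
    theta = _angles(coords, system.angle_idx)
    out["angle"] = float(np.sum(system.angle_k
                                * (theta - system.angle_theta0) ** 2))
    return out


def _angles(coords, idx):
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(c, -1.0, 1.0))


def energy_components(system, coords) -> dict:
    """Unscaled energy by term class (kcal/mol)."""
    e_coul, e_lj, e_con = _nonbonded_pair_energies(system, coords)
    out = _bonded_energies(system, coords)
    out["coulomb"] = float(e_coul.sum())
    out["lj"] = float(e_lj.sum())
    out["contact"] = float(e_con.sum())
    return out


def total_energy(system, coords) -> float:
    return float(sum(energy_components(system, coords).values()))


# ---------------------------------------------------------------------------
# decomposition and scaling
# ---------------------------------------------------------------------------

def _solute_pair_counts(pairs, solute_atoms, n_atoms):
    mask = np.zeros(n_atoms, dtype=bool)
    mask[np.asarray(list(solute_atoms), dtype=int)] = True
    return mask[pairs[:, 0]].astype(int) + mask[pairs[:, 1]].astype(int)


def decompose_energy(system, coords, solute_atoms,
                     scaled_classes=DEFAULT_SCALED_CLASSES
                     ) -> EnergyDecomposition:
    """Route every term to uu / uv / vv by solute membership.

    ``solute_atoms`` is a collection of 0-based atom (bead) indices; classes
    absent from ``scaled_classes`` and all bonded terms go to vv.
    """
    solute_atoms = np.asarray(sorted(solute_atoms), dtype=int)
    if solute_atoms.size and (solute_atoms.min() < 0
                              or solute_atoms.max() >= system.n_beads):
        raise ValidationError("solute atom index out of range")
    e_coul, e_lj, e_con = _nonbonded_pair_energies(system, coords)
    per_class = {"coulomb": (e_coul, system.nb_pairs),
                 "lj": (e_lj, system.nb_pairs),
                 "contact": (e_con, system.contact_idx)}
    e_uu = 0.0
    e_uv: dict[str, float] = {}
    e_vv = sum(_bonded_energies(system, coords).values())
    for cls, (e_pairs, idx) in per_class.items():
        if cls not in scaled_classes or e_pairs.size == 0:
            e_vv += float(e_pairs.sum())
            if cls in scaled_classes:
                e_uv[cls] = 0.0
            continue
        counts = _solute_pair_counts(idx, solute_atoms, system.n_beads)
        e_uu += float(e_pairs[counts == 2].sum())
        e_uv[cls] = float(e_pairs[counts == 1].sum())
        e_vv += float(e_pairs[counts == 0].sum())
    return EnergyDecomposition(e_uu=e_uu, e_uv=e_uv, e_vv=float(e_vv))


def scaling_factor(rule: TermScalingRule, state: SoluteTemperatureState
                   ) -> float:
    """Solute–solvent multiplier (βm/β0)^{k/l} for one term class."""
    return state.beta_ratio ** rule.exponent


def scaled_energy(system, coords, solute_atoms, state: SoluteTemperatureState,
                  scaled_classes=DEFAULT_SCALED_CLASSES,
                  rules: dict | None = None) -> float:
    """The solute-tempered potential via the term-scaling route (kcal/mol)."""
    dec = decompose_energy(system, coords, solute_atoms, scaled_classes)
    return dec.scaled(state, rules)


def parameter_scaled_system(system, solute_atoms,
                            state: SoluteTemperatureState,
                            scaled_classes=DEFAULT_SCALED_CLASSES):
    """A copy of ``system`` whose ordinary potential equals the scaled one.

    Solute charges are multiplied by √(βm/β0) and solute LJ ε by βm/β0
    (geometric ε combination required); contact-well depths are pair terms
    and are multiplied by (βm/β0)^{n_solute/2} directly.
    """
    if system.eps_combination != "geometric":
        raise ParameterError("parameter scaling requires geometric ε "
                             "combination")
    s = state.beta_ratio
    solute_atoms = np.asarray(sorted(solute_atoms), dtype=int)
    charges = system.charges.copy()
    lj_eps = system.lj_eps.copy()
    kwargs = {}
    if "coulomb" in scaled_classes and solute_atoms.size:
        charges[solute_atoms] *= np.sqrt(s)
        kwargs["charges"] = charges
    if "lj" in scaled_classes and solute_atoms.size:
        lj_eps[solute_atoms] *= s
        kwargs["lj_eps"] = lj_eps
    if "contact" in scaled_classes and system.contact_idx.size:
        counts = _solute_pair_counts(system.contact_idx, solute_atoms,
                                     system.n_beads)
        factor = s ** (counts / 2.0)
        kwargs["contact_d_closed"] = system.contact_d_closed * factor
        kwargs["contact_d_open"] = system.contact_d_open * factor
    return replace(system, **kwargs)


def pair_scale_arrays(system, solute_atoms, state: SoluteTemperatureState,
                      scaled_classes=DEFAULT_SCALED_CLASSES) -> dict:
    """Per-pair multipliers (βm/β0)^{n_solute/2} for the force/energy kernel."""
    s = state.beta_ratio
    out = {}
    for cls, idx in (("coulomb", system.nb_pairs), ("lj", system.nb_pairs),
                     ("contact", system.contact_idx)):
        n_pairs = idx.shape[0]
        if cls in scaled_classes and n_pairs:
            counts = _solute_pair_counts(idx, solute_atoms, system.n_beads)
            out[cls] = s ** (counts / 2.0)
        else:
            out[cls] = np.ones(n_pairs)
    return out


# ---------------------------------------------------------------------------
# energy + forces kernel (used by the propagator)
# ---------------------------------------------------------------------------

def energy_and_forces(system, coords, scale: dict | None = None):
    """Potential energy and forces, optionally with per-pair multipliers.

    ``scale`` maps the nonbonded classes to per-pair multiplier arrays (see
    :func:`pair_scale_arrays`); bonded terms are never scaled.
    Returns ``(energy, forces)`` with forces in kcal/mol/Å.

    Dispatches to a compiled kernel when numba is importable; the pure-numpy
    implementation below is the reference and the fallback.
    """
    if _FAST_KERNEL is not None:
        n_nb = system.nb_pairs.shape[0]
        n_con = system.contact_idx.shape[0]
        ones_nb = np.ones(n_nb)
        s_coul = scale["coulomb"] if scale is not None else ones_nb
        s_lj = scale["lj"] if scale is not None else ones_nb
        s_con = scale["contact"] if scale is not None else np.ones(n_con)
        forces = np.zeros((coords.shape[0], 3))
        e = _FAST_KERNEL(
            np.ascontiguousarray(coords),
            system.bond_idx, system.bond_r0, system.bond_k,
            system.angle_idx, system.angle_theta0, system.angle_k,
            system.elastic_idx, system.elastic_r0, system.elastic_k,
            system.nb_pairs, system.nb_qq, system.nb_eps, system.nb_sigma,
            np.asarray(s_coul, dtype=float), np.asarray(s_lj, dtype=float),
            system.contact_idx.reshape(n_con, 2),
            system.contact_r_closed, system.contact_r_open,
            system.contact_d_closed, system.contact_d_open,
            system.contact_width, np.asarray(s_con, dtype=float),
            COULOMB_CONSTANT / system.dielectric, forces)
        return e, forces
    return energy_and_forces_numpy(system, coords, scale)


def energy_and_forces_numpy(system, coords, scale: dict | None = None):
    """Reference numpy implementation of :func:`energy_and_forces`."""
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0

    def add_pair_force(idx, dedr, rij, r):
        fvec = (dedr / r)[:, None] * rij
        np.add.at(forces, idx[:, 0], -fvec)
        np.add.at(forces, idx[:, 1], fvec)

    # bonds / elastic network
    for idx, r0, k in ((system.bond_idx, system.bond_r0, system.bond_k),
                       (system.elastic_idx, system.elastic_r0,
                        system.elastic_k)):
        rij, r = _pair_distances(coords, idx)
        dr = r - r0
        energy += float(np.sum(k * dr ** 2))
        add_pair_force(idx, 2.0 * k * dr, rij, r)

    # angles
    idx = system.angle_idx
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
    dt = theta - system.angle_theta0
    energy += float(np.sum(system.angle_k * dt ** 2))
    dedt = 2.0 * system.angle_k * dt
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    dti = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
    dtk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
    np.add.at(forces, idx[:, 0], -dedt[:, None] * dti)
    np.add.at(forces, idx[:, 2], -dedt[:, None] * dtk)
    np.add.at(forces, idx[:, 1], dedt[:, None] * (dti + dtk))

    # nonbonded Coulomb + LJ
    rij, r = _pair_distances(coords, system.nb_pairs)
    s_coul = scale["coulomb"] if scale else 1.0
    s_lj = scale["lj"] if scale else 1.0
    qq = COULOMB_CONSTANT / system.dielectric * system.nb_qq * s_coul
    energy += float(np.sum(qq / r))
    dedr = -qq / r ** 2
    sig_r6 = (system.nb_sigma / r) ** 6
    eps = 4.0 * system.nb_eps * s_lj
    energy += float(np.sum(eps * (sig_r6 ** 2 - sig_r6)))
    dedr = dedr + eps * (-12.0 * sig_r6 ** 2 + 6.0 * sig_r6) / r
    add_pair_force(system.nb_pairs, dedr, rij, r)

    # double-basin contact wells
    if system.contact_idx.size:
        rij, r = _pair_distances(coords, system.contact_idx)
        s_con = scale["contact"] if scale else 1.0
        w2 = system.contact_width ** 2
        dedr = np.zeros_like(r)
        e_con = np.zeros_like(r)
        for depth, r_ref in ((system.contact_d_closed,
                              system.contact_r_closed),
                             (system.contact_d_open, system.contact_r_open)):
            g = np.exp(-(r - r_ref) ** 2 / (2.0 * w2))
            e_con -= depth * g
            dedr += depth * (r - r_ref) / w2 * g
        energy += float(np.sum(s_con * e_con))
        add_pair_force(system.contact_idx, s_con * dedr, rij, r)

    return energy, forces


# ---------------------------------------------------------------------------
# COM distance restraint
# ---------------------------------------------------------------------------

def com_restraint_energy(coords, group_atoms, anchor_atom, force_constant,
                         r0, masses) -> float:
    """Harmonic restraint k·(d − r0)² on the distance between the
    mass-weighted COM of ``group_atoms`` and the position of ``anchor_atom``."""
    if len(group_atoms) == 0:
        raise ValidationError("restraint group must be non-empty")
    if force_constant < 0:
        raise ValidationError("force constant must be >= 0")
    g = np.asarray(list(group_atoms), dtype=int)
    m = np.asarray(masses, dtype=float)[g]
    com = (coords[g] * m[:, None]).sum(axis=0) / m.sum()
    d = float(np.linalg.norm(com - coords[anchor_atom]))
    return force_constant * (d - r0) ** 2


def com_restraint_gradient(coords, group_atoms, anchor_atom, force_constant,
                           r0, masses) -> np.ndarray:
    """Analytic gradient of :func:`com_restraint_energy` w.r.t. coordinates."""
    if len(group_atoms) == 0:
        raise ValidationError("restraint group must be non-empty")
    g = np.asarray(list(group_atoms), dtype=int)
    m = np.asarray(masses, dtype=float)[g]
    com = (coords[g] * m[:, None]).sum(axis=0) / m.sum()
    dvec = com - coords[anchor_atom]
    d = float(np.linalg.norm(dvec))
    grad = np.zeros_like(coords)
    if d < 1e-12:
        return grad
    u = dvec / d
    pref = 2.0 * force_constant * (d - r0)
    grad[g] += pref * u[None, :] * (m / m.sum())[:, None]
    grad[anchor_atom] -= pref * u
    return grad


# ---------------------------------------------------------------------------
# compiled kernel (optional fast path)
# ---------------------------------------------------------------------------

def _build_fast_kernel():
    try:
        from numba import njit
    except ImportError:      # pragma: no cover - numba is normally present
        return None

    @njit(cache=True, fastmath=False)
    def kernel(coords, bond_idx, bond_r0, bond_k,
               ang_idx, ang_t0, ang_k,
               el_idx, el_r0, el_k,
               nb_idx, nb_qq, nb_eps, nb_sigma, s_coul, s_lj,
               con_idx, con_rc, con_ro, con_dc, con_do, con_w, s_con,
               coul_pref, forces):
        e = 0.0
        for b in range(bond_idx.shape[0]):
            i, j = bond_idx[b, 0], bond_idx[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            dr = r - bond_r0[b]
            e += bond_k[b] * dr * dr
            c = 2.0 * bond_k[b] * dr / r
            forces[i, 0] -= c * dx
            forces[i, 1] -= c * dy
            forces[i, 2] -= c * dz
            forces[j, 0] += c * dx
            forces[j, 1] += c * dy
            forces[j, 2] += c * dz
        for b in range(el_idx.shape[0]):
            i, j = el_idx[b, 0], el_idx[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            dr = r - el_r0[b]
            e += el_k[b] * dr * dr
            c = 2.0 * el_k[b] * dr / r
            forces[i, 0] -= c * dx
            forces[i, 1] -= c * dy
            forces[i, 2] -= c * dz
            forces[j, 0] += c * dx
            forces[j, 1] += c * dy
            forces[j, 2] += c * dz
        for b in range(ang_idx.shape[0]):
            i, j, k = ang_idx[b, 0], ang_idx[b, 1], ang_idx[b, 2]
            ux = coords[i, 0] - coords[j, 0]
            uy = coords[i, 1] - coords[j, 1]
            uz = coords[i, 2] - coords[j, 2]
            vx = coords[k, 0] - coords[j, 0]
            vy = coords[k, 1] - coords[j, 1]
            vz = coords[k, 2] - coords[j, 2]
            nu = (ux * ux + uy * uy + uz * uz) ** 0.5
            nv = (vx * vx + vy * vy + vz * vz) ** 0.5
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            theta = np.arccos(ct)
            st = (1.0 - ct * ct) ** 0.5
            if st < 1e-8:
                st = 1e-8
            dt = theta - ang_t0[b]
            e += ang_k[b] * dt * dt
            dedt = 2.0 * ang_k[b] * dt
            uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
            vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
            dix = (ct * uhx - vhx) / (nu * st)
            diy = (ct * uhy - vhy) / (nu * st)
            diz = (ct * uhz - vhz) / (nu * st)
            dkx = (ct * vhx - uhx) / (nv * st)
            dky = (ct * vhy - uhy) / (nv * st)
            dkz = (ct * vhz - uhz) / (nv * st)
            forces[i, 0] -= dedt * dix
            forces[i, 1] -= dedt * diy
            forces[i, 2] -= dedt * diz
            forces[k, 0] -= dedt * dkx
            forces[k, 1] -= dedt * dky
            forces[k, 2] -= dedt * dkz
            forces[j, 0] += dedt * (dix + dkx)
            forces[j, 1] += dedt * (diy + dky)
            forces[j, 2] += dedt * (diz + dkz)
        for b in range(nb_idx.shape[0]):
            i, j = nb_idx[b, 0], nb_idx[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = r2 ** 0.5
            qq = coul_pref * nb_qq[b] * s_coul[b]
            e += qq / r
            dedr = -qq / r2
            sr2 = nb_sigma[b] * nb_sigma[b] / r2
            sr6 = sr2 * sr2 * sr2
            eps = 4.0 * nb_eps[b] * s_lj[b]
            e += eps * (sr6 * sr6 - sr6)
            dedr += eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            c = dedr / r
            forces[i, 0] -= c * dx
            forces[i, 1] -= c * dy
            forces[i, 2] -= c * dz
            forces[j, 0] += c * dx
            forces[j, 1] += c * dy
            forces[j, 2] += c * dz
        for b in range(con_idx.shape[0]):
            i, j = con_idx[b, 0], con_idx[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            w2 = con_w[b] * con_w[b]
            gc = np.exp(-(r - con_rc[b]) ** 2 / (2.0 * w2))
            go = np.exp(-(r - con_ro[b]) ** 2 / (2.0 * w2))
            e += s_con[b] * (-con_dc[b] * gc - con_do[b] * go)
            dedr = s_con[b] * (con_dc[b] * (r - con_rc[b]) / w2 * gc
                               + con_do[b] * (r - con_ro[b]) / w2 * go)
            c = dedr / r
            forces[i, 0] -= c * dx
            forces[i, 1] -= c * dy
            forces[i, 2] -= c * dz
            forces[j, 0] += c * dx
            forces[j, 1] += c * dy
            forces[j, 2] += c * dz
        return e

    return kernel


_FAST_KERNEL = _build_fast_kernel()
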