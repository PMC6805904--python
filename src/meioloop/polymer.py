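"""Coarse-grained 3D chromatin model driven by sampled loop configurations.

Each 20 nm monomer represents one lattice site (640 bp by default). The
fibre is simulated with overdamped (inertialess) stochastic dynamics under
harmonic backbone springs, loop-base bonds, sister/homologue crosslink
bonds, a truncated harmonic soft-core repulsion (finite energy at zero
distance, so chains can occasionally cross) and a spherical confinement.
Contacts are captured between monomer pairs closer than 60 nm and pooled
across chromatid copies onto a single-chromosome binned map.

Loop configurations are held static within each conformation block and
resampled between blocks (quasi-static coupling): short yeast chromosomes
relax quickly relative to extruder dynamics, so the 3D ensemble is sampled
conditional on successive extrusion snapshots.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .extrusion import (
    ExtrusionParams,
    LatticeSystem,
    LoopConfiguration,
    init_lattice,
    run_and_sample,
)
from .genome import BarrierTrack, ChromosomeSpec
from .hic import ContactMatrix

__all__ = [
    "PolymerSystem",
    "CrosslinkSet",
    "build_system",
    "derive_crosslinks",
    "equilibrate",
    "capture_contacts",
    "simulate_contact_map",
    "radius_of_gyration",
    "desk_confinement_radius_nm",
]

BOND_NM = 20.0          # backbone rest length = monomer diameter
SISTER_REST_NM = 20.0
HOMOLOG_REST_NM = 100.0
FULL_SYSTEM_MONOMERS = 75_140  # 52 chromatids at full scale
FULL_CONFINEMENT_NM = 1000.0

# force-field constants (kT = 1, friction = 1, lengths in nm)
K_BOND = 0.35           # backbone/loop/crosslink spring, kT/nm^2
K_REP = 0.05            # soft-core prefactor -> 10 kT at full overlap
K_CONF = 1.0            # confinement wall spring
DT = 0.5                # integrator step (stable for the stiffest spring here)
MAX_STEP_NM = 5.0       # per-step displacement clamp
NEIGHBOR_EVERY = 5      # KD-tree rebuild interval (margin covers worst drift)


def desk_confinement_radius_nm(total_monomers: int) -> float:
    """Confinement radius conserving the full-scale volume density."""
    return FULL_CONFINEMENT_NM * (total_monomers / FULL_SYSTEM_MONOMERS) ** (1.0 / 3.0)


@dataclass
class PolymerSystem:
    """Monomer coordinates plus bonded topology for one multi-copy system."""

    spec: ChromosomeSpec
    n_copies: int
    pairing_mode: str               # individualised | sister | homologue
    confinement_radius_nm: float
    monomer_bp: int
    coords: np.ndarray              # (n_monomers, 3) nm
    chromatid: np.ndarray           # copy index per monomer
    site: np.ndarray                # site index within chromatid
    bonds: np.ndarray               # (n_bonds, 2) monomer indices
    bond_rest: np.ndarray           # rest length per bond

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[0]

    @property
    def sites_per_copy(self) -> int:
        return self.n_monomers // self.n_copies

    def monomer_index(self, chromatid: int, site: int) -> int:
        return chromatid * self.sites_per_copy + site


@dataclass
class CrosslinkSet:
    """Inter-chromatid bonds derived from cognate loop bases."""

    sister: np.ndarray      # (n, 2) monomer indices
    homologue: np.ndarray   # (n, 2) monomer indices

    @classmethod
    def empty(cls) -> "CrosslinkSet":
        z = np.zeros((0, 2), dtype=np.int64)
        return cls(z, z.copy())

    @property
    def n_links(self) -> int:
        return len(self.sister) + len(self.homologue)


def _confined_walk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Random walk of step BOND_NM reflected into the confinement sphere."""
    x = np.empty((n, 3))
    x[0] = rng.normal(size=3)
    x[0] *= 0.5 * radius / max(np.linalg.norm(x[0]), 1e-9)
    for i in range(1, n):
        for _ in range(64):
            stepv = rng.normal(size=3)
            stepv *= BOND_NM / max(np.linalg.norm(stepv), 1e-9)
            cand = x[i - 1] + stepv
            if np.linalg.norm(cand) < radius:
                x[i] = cand
                break
        else:
            x[i] = x[i - 1]
    return x


def build_system(
    spec: ChromosomeSpec,
    n_copies: int = 4,
    pairing_mode: str = "individualised",
    confinement_radius_nm: float | None = None,
    monomer_bp: int = 640,
    seed: int = 0,
) -> PolymerSystem:
    """Place ``n_copies`` chromatids of one chromosome inside the nucleus.

    In paired modes sister chromatids (copies 2k, 2k+1) are bonded at
    centromere and both telomere monomers; homologue mode additionally
    bonds the two sister pairs of each quartet there at 100 nm rest length.
    """
    if pairing_mode not in ("individualised", "sister", "homologue"):
        raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    if pairing_mode == "sister" and n_copies % 2:
        raise ValueError("sister pairing needs an even copy number")
    if pairing_mode == "homologue" and n_copies % 4:
        raise ValueError("homologue pairing needs a multiple of 4 copies")
    nsite = spec.n_sites(monomer_bp)
    total = nsite * n_copies
    if confinement_radius_nm is None:
        confinement_radius_nm = desk_confinement_radius_nm(total)
    # refuse geometrically infeasible packing (monomer volume > half the nucleus)
    vol_monomers = total * (4 / 3) * math.pi * (BOND_NM / 2) ** 3
    vol_nucleus = (4 / 3) * math.pi * confinement_radius_nm**3
    if vol_monomers > 0.5 * vol_nucleus:
        raise ValueError("requested density packs monomers beyond feasibility")

    rng = np.random.default_rng(seed)
    coords = np.concatenate(
        [_confined_walk(nsite, confinement_radius_nm, rng) for _ in range(n_copies)]
    )
    chromatid = np.repeat(np.arange(n_copies), nsite)
    site = np.tile(np.arange(nsite), n_copies)

    bonds = []
    rest = []
    for c in range(n_copies):
        off = c * nsite
        for i in range(nsite - 1):
            bonds.append((off + i, off + i + 1))
            rest.append(BOND_NM)
    cen_site = min(spec.centromere_bp // monomer_bp, nsite - 1)
    anchor_sites = (0, int(cen_site), nsite - 1)
    if pairing_mode in ("sister", "homologue"):
        for k in range(n_copies // 2):
            a, b = 2 * k, 2 * k + 1
            for s in anchor_sites:
                bonds.append((a * nsite + s, b * nsite + s))
                rest.append(SISTER_REST_NM)
    if pairing_mode == "homologue":
        for q in range(n_copies // 4):
            a, b = 4 * q, 4 * q + 2  # first sister of each pair in the quartet
            for s in anchor_sites:
                bonds.append((a * nsite + s, b * nsite + s))
                rest.append(HOMOLOG_REST_NM)
    return PolymerSystem(
        spec=spec,
        n_copies=n_copies,
        pairing_mode=pairing_mode,
        confinement_radius_nm=float(confinement_radius_nm),
        monomer_bp=monomer_bp,
        coords=coords,
        chromatid=chromatid,
        site=site,
        bonds=np.array(bonds, dtype=np.int64),
        bond_rest=np.array(rest, dtype=float),
    )


# --------------------------------------------------------------------------
# crosslink derivation
# --------------------------------------------------------------------------

def _outer_loops(left: np.ndarray, right: np.ndarray):
    """Indices of loops not strictly nested inside another loop."""
    keep = []
    n = len(left)
    for k in range(n):
        nested = False
        for j in range(n):
            if j == k:
                continue
            if (
                left[j] <= left[k]
                and right[k] <= right[j]
                and (right[j] - left[j]) > (right[k] - left[k])
            ):
                nested = True
                break
        if not nested:
            keep.append(k)
    return np.array(keep, dtype=np.int64)


def _reciprocal_matches(u: np.ndarray, v: np.ndarray, window: int):
    """Pairs (i, j) where u[i] and v[j] are mutually nearest within window."""
    if len(u) == 0 or len(v) == 0:
        return []
    d = np.abs(u[:, None] - v[None, :])
    nearest_v = d.argmin(axis=1)
    nearest_u = d.argmin(axis=0)
    out = []
    for i, j in enumerate(nearest_v):
        if nearest_u[j] == i and d[i, j] <= window:
            out.append((i, int(j)))
    return out


def _loops_by_chromatid(loops: LoopConfiguration, system: LatticeSystem):
    """Split a configuration into per-chromatid local (left, right) site arrays."""
    per = {}
    start = system.chromatid_start
    for c in range(len(start)):
        sel = loops.chromatid == c
        off = start[c]
        per[c] = (loops.left_site[sel] - off, loops.right_site[sel] - off)
    return per


def derive_crosslinks(
    loops: LoopConfiguration,
    polymer: PolymerSystem,
    lattice: LatticeSystem,
    window_monomers: int = 30,
) -> CrosslinkSet:
    """Sister and homologue crosslinks from cognate outer loop bases.

    A sister link joins same-side (left-left or right-right) outer loop
    bases on the two sisters when they are mutually nearest and within
    ``window_monomers``; a homologue link joins the positions of sister
    links on the two pairs of a quartet under the same matching rule.
    Inner (nested) loop bases never anchor links.
    """
    if polymer.pairing_mode == "individualised":
        return CrosslinkSet.empty()
    per = _loops_by_chromatid(loops, lattice)
    nsite = polymer.sites_per_copy

    def outer_bases(c):
        l, r = per.get(c, (np.array([], dtype=np.int64),) * 2)
        if len(l) == 0:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        keep = _outer_loops(l, r)
        return np.sort(l[keep]), np.sort(r[keep])

    sister = []
    sister_anchor_sites = {}  # chromatid pair index -> per-side matched sites
    for k in range(polymer.n_copies // 2):
        a, b = 2 * k, 2 * k + 1
        la, ra = outer_bases(a)
        lb, rb = outer_bases(b)
        matched = {"left": [], "right": []}
        for side, ua, ub in (("left", la, lb), ("right", ra, rb)):
            for i, j in _reciprocal_matches(ua, ub, window_monomers):
                sister.append(
                    (polymer.monomer_index(a, int(ua[i])), polymer.monomer_index(b, int(ub[j])))
                )
                matched[side].append(int(ua[i]))
        sister_anchor_sites[k] = matched
    homologue = []
    if polymer.pairing_mode == "homologue":
        for q in range(polymer.n_copies // 4):
            p1, p2 = 2 * q, 2 * q + 1  # sister-pair indices in the quartet
            for side in ("left", "right"):
                u = np.sort(np.array(sister_anchor_sites[p1][side], dtype=np.int64))
                v = np.sort(np.array(sister_anchor_sites[p2][side], dtype=np.int64))
                for i, j in _reciprocal_matches(u, v, window_monomers):
                    homologue.append(
                        (
                            polymer.monomer_index(4 * q, int(u[i])),
                            polymer.monomer_index(4 * q + 2, int(v[j])),
                        )
                    )
    z = np.zeros((0, 2), dtype=np.int64)
    return CrosslinkSet(
        sister=np.array(sister, dtype=np.int64) if sister else z,
        homologue=np.array(homologue, dtype=np.int64) if homologue else z.copy(),
    )


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def _loop_bonds(loops: LoopConfiguration, polymer: PolymerSystem, lattice: LatticeSystem):
    per = _loops_by_chromatid(loops, lattice)
    out = []
    for c, (l, r) in per.items():
        if c >= polymer.n_copies:
            continue
        for i in range(len(l)):
            out.append((polymer.monomer_index(c, int(l[i])), polymer.monomer_index(c, int(r[i]))))
    return np.array(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)


def equilibrate(
    system: PolymerSystem,
    loops: LoopConfiguration | None = None,
    crosslinks: CrosslinkSet | None = None,
    n_steps: int = 2000,
    seed: int = 0,
    lattice: LatticeSystem | None = None,
    dt: float = DT,
) -> np.ndarray:
    """Overdamped stochastic dynamics; returns coordinates after n_steps.

    Forces: harmonic springs on backbone, loop-base, pairing and crosslink
    bonds; truncated harmonic soft-core repulsion below one monomer
    diameter; harmonic confinement outside the nuclear radius. Per-step
    displacements are clamped, which bounds the energy a single step can
    inject. Raises on numerical divergence.
    """
    k_max = max(K_BOND, K_CONF)
    if dt * k_max >= 2.0:
        raise FloatingPointError(
            f"step size dt={dt} violates the overdamped stability bound "
            f"dt < 2/k_max = {2.0 / k_max}; reduce dt"
        )
    rng = np.random.default_rng(seed)
    x = system.coords.copy()
    bonds = [system.bonds]
    rests = [system.bond_rest]
    if loops is not None:
        if lattice is None:
            raise ValueError("loops given without the lattice that produced them")
        lb = _loop_bonds(loops, system, lattice)
        if len(lb):
            bonds.append(lb)
            rests.append(np.full(len(lb), BOND_NM))
    if crosslinks is not None:
        if len(crosslinks.sister):
            bonds.append(crosslinks.sister)
            rests.append(np.full(len(crosslinks.sister), SISTER_REST_NM))
        if len(crosslinks.homologue):
            bonds.append(crosslinks.homologue)
            rests.append(np.full(len(crosslinks.homologue), HOMOLOG_REST_NM))
    bond_idx = np.concatenate(bonds)
    bond_rest = np.concatenate(rests)
    bi, bj = bond_idx[:, 0], bond_idx[:, 1]

    noise_scale = math.sqrt(2.0 * dt)
    pairs = np.zeros((0, 2), dtype=np.int64)
    for it in range(n_steps):
        if it % NEIGHBOR_EVERY == 0:
            tree = cKDTree(x)
            pairs = tree.query_pairs(BOND_NM + 3 * MAX_STEP_NM, output_type="ndarray")
        f = np.zeros_like(x)
        # bonded springs
        dx = x[bj] - x[bi]
        r = np.linalg.norm(dx, axis=1)
        r = np.maximum(r, 1e-9)
        fmag = K_BOND * (r - bond_rest) / r
        fv = fmag[:, None] * dx
        np.add.at(f, bi, fv)
        np.add.at(f, bj, -fv)
        # soft-core repulsion (finite at zero distance)
        if len(pairs):
            pi, pj = pairs[:, 0], pairs[:, 1]
            dxp = x[pj] - x[pi]
            rp = np.linalg.norm(dxp, axis=1)
            close = rp < BOND_NM
            if np.any(close):
                pi, pj, dxp, rp = pi[close], pj[close], dxp[close], rp[close]
                rp = np.maximum(rp, 1e-9)
                fmag = K_REP * (BOND_NM - rp) / rp
                fv = fmag[:, None] * dxp
                np.add.at(f, pi, -fv)
                np.add.at(f, pj, fv)
        # confinement
        rad = np.linalg.norm(x, axis=1)
        out = rad > system.confinement_radius_nm
        if np.any(out):
            pull = K_CONF * (rad[out] - system.confinement_radius_nm) / rad[out]
            f[out] -= pull[:, None] * x[out]
        disp = dt * f + noise_scale * rng.standard_normal(x.shape)
        mag = np.linalg.norm(disp, axis=1)
        big = mag > MAX_STEP_NM
        if np.any(big):
            disp[big] *= (MAX_STEP_NM / mag[big])[:, None]
        x += disp
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"polymer dynamics diverged at step {it}; reduce dt (currently {dt})"
            )
    system.coords = x
    return x


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

def capture_contacts(
    system: PolymerSystem,
    coords: np.ndarray | None = None,
    contact_radius_nm: float = 60.0,
    bin_bp: int = 2000,
    accumulate_into: ContactMatrix | None = None,
) -> ContactMatrix:
    """Record monomer pairs strictly closer than the contact radius.

    All pairs (intra-chromatid, inter-sister, inter-homologue) are pooled
    onto a single-chromosome binned map; self-pairs are excluded.
    """
    if coords is None:
        coords = system.coords
    m = accumulate_into
    if m is None:
        m = ContactMatrix.zeros((system.spec,), bin_bp)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(contact_radius_nm, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < contact_radius_nm]  # strict inequality
    if len(pairs):
        gi = system.site[pairs[:, 0]] * system.monomer_bp // m.bin_bp
        gj = system.site[pairs[:, 1]] * system.monomer_bp // m.bin_bp
        np.add.at(m.counts, (gi, gj), 1.0)
        off_diag = gi != gj
        np.add.at(m.counts, (gj[off_diag], gi[off_diag]), 1.0)
    return m


def radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def simulate_contact_map(
    spec: ChromosomeSpec,
    barriers: BarrierTrack,
    params: ExtrusionParams,
    pairing_mode: str = "individualised",
    n_conformations: int = 20,
    seed: int = 0,
    n_copies: int = 4,
    bin_bp: int = 2000,
    first_steps: int = 1500,
    steps_per_conformation: int = 400,
    sample_interval_sweeps: int = 10,
    confinement_radius_nm: float | None = None,
) -> ContactMatrix:
    """End-to-end simulated contact map for one parameter set.

    Samples loop configurations from the lattice model, derives crosslinks,
    equilibrates the polymer quasi-statically for each configuration and
    accumulates <60 nm contacts into one pooled map.
    """
    if n_conformations < 1:
        raise ValueError("need at least one conformation")
    lattice = init_lattice([spec], barriers, params, n_chromatid_copies=n_copies, seed=seed)
    configs = run_and_sample(
        lattice,
        n_samples=n_conformations,
        sample_interval_sweeps=sample_interval_sweeps,
    )
    polymer = build_system(
        spec,
        n_copies=n_copies,
        pairing_mode=pairing_mode,
        confinement_radius_nm=confinement_radius_nm,
        seed=seed,
    )
    m = ContactMatrix.zeros((spec,), bin_bp)
    for k, cfg in enumerate(configs):
        links = derive_crosslinks(cfg, polymer, lattice)
        steps = first_steps if k == 0 else steps_per_conformation
        coords = equilibrate(
            polymer, cfg, links, n_steps=steps, seed=seed + 1 + k, lattice=lattice
        )
        capture_contacts(polymer, coords, bin_bp=bin_bp, accumulate_into=m)
    # re-validate symmetry/invariants after accumulation
    return ContactMatrix(m.counts, bin_bp, (spec,))
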