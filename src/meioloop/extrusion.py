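"""Stochastic loop extrusion on a 1D lattice with permeable barriers.

Each chromatid is a row of lattice sites (one per 640 bp monomer by
default). Loop extruders occupy two sites (their legs); per sweep every
extruder first dies with probability ``2 * monomer_bp / processivity_bp``
(and is instantly reborn at a random unoccupied bond, keeping the extruder
number exactly constant), then each leg attempts one outward step in
randomised order. A step onto an occupied site fails (mutual blocking). A
leg sitting on a barrier site escapes outward with probability
``1 - strength``, re-drawn independently every sweep (memoryless pausing);
while the escape fails the leg is flagged as paused at that barrier.
Centromere and telomere sites are impermeable (strength 1) boundaries, so
no leg ever passes them and loops never span the centromere.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import BarrierTrack, ChromosomeSpec

__all__ = [
    "ExtrusionParams",
    "LatticeSystem",
    "LoopConfiguration",
    "ExtrusionSummary",
    "SimulatedChip",
    "init_lattice",
    "step",
    "run_and_sample",
    "summarize_extrusion",
    "simulated_chip",
]


@dataclass(frozen=True)
class ExtrusionParams:
    """Extrusion dynamics parameters.

    processivity_bp: mean loop size an extruder reaches unimpeded.
    separation_bp: genome length divided by the number of active extruders.
    barrier_strength: default pause probability for generated barrier tracks.
    monomer_bp: lattice resolution; one site per monomer.
    velocity: sites per sweep per leg (1; kept explicit for clarity).
    """

    processivity_bp: float
    separation_bp: float
    barrier_strength: float = 0.95
    monomer_bp: int = 640
    velocity: int = 1

    def __post_init__(self) -> None:
        if self.processivity_bp <= 0 or self.separation_bp <= 0:
            raise ValueError("processivity and separation must be positive")
        if not (0.0 <= self.barrier_strength <= 1.0):
            raise ValueError("barrier_strength must be in [0, 1]")

    @property
    def p_death(self) -> float:
        """Per-sweep death probability: 2*monomer/processivity, so the mean
        unimpeded loop grows to one processivity before dying."""
        return min(1.0, 2.0 * self.monomer_bp / self.processivity_bp)

    @property
    def default_burn_in_sweeps(self) -> int:
        """Ten extruder lifetimes."""
        return int(10 * self.processivity_bp / (2 * self.monomer_bp))


@dataclass
class LatticeSystem:
    """Mutable lattice state: site occupancy, extruder legs, barrier map."""

    specs: tuple[ChromosomeSpec, ...]
    params: ExtrusionParams
    n_copies: int
    strength: np.ndarray        # per-site pause probability (1.0 at boundaries)
    chrom_id: np.ndarray        # chromatid id per site
    birth_ok: np.ndarray        # sites where newborn legs may land
    occ: np.ndarray             # occupant extruder index per site, -1 if free
    left: np.ndarray            # global site of each extruder's left leg
    right: np.ndarray
    paused_left: np.ndarray     # uint8 flags: leg held at a barrier this sweep
    paused_right: np.ndarray
    barrier_sites: np.ndarray   # sorted global sites of track barriers (not boundaries)
    boundary_sites: np.ndarray
    chromatid_start: np.ndarray  # first global site of each chromatid
    sites_per_genome: int
    seed: int
    sweeps_done: int = 0

    @property
    def total_sites(self) -> int:
        return self.occ.size

    @property
    def n_extruders(self) -> int:
        return self.left.size

    def site_to_genome_bp(self, site: np.ndarray) -> np.ndarray:
        """Map global sites to positions on the single-genome coordinate."""
        local = site % self.sites_per_genome
        return local * self.params.monomer_bp


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _rebirth_site(occ, birth_ok, chrom_id):
    total = occ.size
    while True:
        i = np.random.randint(0, total - 1)
        if (
            birth_ok[i]
            and birth_ok[i + 1]
            and chrom_id[i] == chrom_id[i + 1]
            and occ[i] == -1
            and occ[i + 1] == -1
        ):
            return i


@njit(cache=True)
def _run_sweeps(n_sweeps, occ, left, right, pl, pr, strength, chrom_id, birth_ok, p_death):
    total = occ.size
    n = left.size
    for _ in range(n_sweeps):
        # death with instant rebirth keeps the extruder count constant
        for e in range(n):
            if np.random.random() < p_death:
                occ[left[e]] = -1
                occ[right[e]] = -1
                i = _rebirth_site(occ, birth_ok, chrom_id)
                left[e] = i
                right[e] = i + 1
                occ[i] = e
                occ[i + 1] = e
                pl[e] = 0
                pr[e] = 0
        # legs attempt one outward step each, in random order
        order = np.random.permutation(2 * n)
        for k in range(2 * n):
            idx = order[k]
            e = idx >> 1
            is_right = idx & 1
            pos = right[e] if is_right else left[e]
            s0 = strength[pos]
            if s0 > 0.0 and np.random.random() < s0:
                if is_right:
                    pr[e] = 1
                else:
                    pl[e] = 1
                continue
            if is_right:
                pr[e] = 0
            else:
                pl[e] = 0
            t = pos + 1 if is_right else pos - 1
            if t < 0 or t >= total:
                continue
            if chrom_id[t] != chrom_id[pos]:
                continue
            if occ[t] != -1:
                continue
            occ[pos] = -1
            occ[t] = e
            if is_right:
                right[e] = t
            else:
                left[e] = t


# --------------------------------------------------------------------------
# construction and stepping
# --------------------------------------------------------------------------

def init_lattice(
    specs: list[ChromosomeSpec],
    barriers: BarrierTrack,
    params: ExtrusionParams,
    n_chromatid_copies: int = 1,
    seed: int = 0,
) -> LatticeSystem:
    """Build the lattice: one chromatid per (copy, chromosome).

    Site count per chromatid is ceil(length/monomer); the extruder count is
    round(total_sites * monomer / separation); extruders are born on
    uniformly random unoccupied bonds. Centromere and telomere sites carry
    strength 1; track barriers are snapped to the lattice.
    """
    if n_chromatid_copies < 1:
        raise ValueError("need at least one chromatid copy")
    specs = tuple(specs)
    barriers.validate(list(specs))
    mono = params.monomer_bp
    per_spec = [s.n_sites(mono) for s in specs]
    sites_per_genome = sum(per_spec)
    total = sites_per_genome * n_chromatid_copies

    strength = np.zeros(total)
    chrom_id = np.empty(total, dtype=np.int32)
    chromatid_start = []
    barrier_sites = []
    boundary_sites = []
    off = 0
    cid = 0
    for _copy in range(n_chromatid_copies):
        for spec, nsite in zip(specs, per_spec):
            chromatid_start.append(off)
            chrom_id[off : off + nsite] = cid
            cen_site = min(spec.centromere_bp // mono, nsite - 1)
            bnd = {0, nsite - 1, int(cen_site)}
            for b in bnd:
                strength[off + b] = 1.0
                boundary_sites.append(off + b)
            pos = barriers.positions_for(spec.name)
            stg = barriers.strengths_for(spec.name)
            snapped = np.clip(np.round(pos / mono).astype(np.int64), 0, nsite - 1)
            for p, s in zip(snapped, stg):
                if int(p) in bnd:
                    continue
                strength[off + int(p)] = s
                barrier_sites.append(off + int(p))
            off += nsite
            cid += 1
    birth_ok = strength < 1.0

    n_ext = int(round(total * mono / params.separation_bp))
    max_bonds = int(np.sum(birth_ok)) // 2
    if n_ext > max_bonds:
        raise ValueError(f"{n_ext} extruders exceed {max_bonds} available bonds")

    occ = np.full(total, -1, dtype=np.int64)
    left = np.empty(n_ext, dtype=np.int64)
    right = np.empty(n_ext, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for e in range(n_ext):
        while True:
            i = int(rng.integers(0, total - 1))
            if (
                birth_ok[i]
                and birth_ok[i + 1]
                and chrom_id[i] == chrom_id[i + 1]
                and occ[i] == -1
                and occ[i + 1] == -1
            ):
                break
        left[e], right[e] = i, i + 1
        occ[i] = e
        occ[i + 1] = e
    _seed_kernel(int(seed) % (2**31 - 1) + 1)

    return LatticeSystem(
        specs=specs,
        params=params,
        n_copies=n_chromatid_copies,
        strength=strength,
        chrom_id=chrom_id,
        birth_ok=birth_ok,
        occ=occ,
        left=left,
        right=right,
        paused_left=np.zeros(n_ext, dtype=np.uint8),
        paused_right=np.zeros(n_ext, dtype=np.uint8),
        barrier_sites=np.array(sorted(barrier_sites), dtype=np.int64),
        boundary_sites=np.array(sorted(boundary_sites), dtype=np.int64),
        chromatid_start=np.array(chromatid_start, dtype=np.int64),
        sites_per_genome=sites_per_genome,
        seed=seed,
    )


def step(system: LatticeSystem, n_sweeps: int = 1) -> LatticeSystem:
    """Advance the lattice by ``n_sweeps`` sweeps in place."""
    if system.n_extruders > 0:
        _run_sweeps(
            n_sweeps,
            system.occ,
            system.left,
            system.right,
            system.paused_left,
            system.paused_right,
            system.strength,
            system.chrom_id,
            system.birth_ok,
            system.params.p_death,
        )
    system.sweeps_done += n_sweeps
    return system


@dataclass
class LoopConfiguration:
    """Snapshot of every extruded loop at one sampled sweep."""

    sweep: int
    chromatid: np.ndarray
    left_site: np.ndarray   # global lattice sites
    right_site: np.ndarray
    paused_left: np.ndarray
    paused_right: np.ndarray

    @property
    def n_loops(self) -> int:
        return self.left_site.size


def run_and_sample(
    system: LatticeSystem,
    burn_in_sweeps: int | None = None,
    n_samples: int = 100,
    sample_interval_sweeps: int = 5,
) -> list[LoopConfiguration]:
    """Burn in, then collect loop configurations at a fixed sweep interval."""
    if n_samples < 0 or sample_interval_sweeps < 1:
        raise ValueError("n_samples must be >=0 and interval >=1")
    if burn_in_sweeps is None:
        burn_in_sweeps = system.params.default_burn_in_sweeps
    if burn_in_sweeps > 0:
        step(system, burn_in_sweeps)
    samples = []
    for _ in range(n_samples):
        step(system, sample_interval_sweeps)
        samples.append(
            LoopConfiguration(
                sweep=system.sweeps_done,
                chromatid=system.chrom_id[system.left].copy(),
                left_site=system.left.copy(),
                right_site=system.right.copy(),
                paused_left=system.paused_left.copy().astype(bool),
                paused_right=system.paused_right.copy().astype(bool),
            )
        )
    return samples


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

@dataclass
class ExtrusionSummary:
    """Steady-state loop statistics averaged over samples and chromatids."""

    coverage_fraction: float
    mean_loop_bp: float
    loop_length_edges_bp: np.ndarray
    loop_length_freq: np.ndarray
    frac_barriers_occupied: float
    frac_extruders_paused_both_sides: float
    frac_loops_crossing_barrier: float
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "coverage_fraction": self.coverage_fraction,
            "mean_loop_bp": self.mean_loop_bp,
            "frac_barriers_occupied": self.frac_barriers_occupied,
            "frac_extruders_paused_both_sides": self.frac_extruders_paused_both_sides,
            "frac_loops_crossing_barrier": self.frac_loops_crossing_barrier,
            "n_samples": self.n_samples,
        }


def summarize_extrusion(
    samples: list[LoopConfiguration], system: LatticeSystem
) -> ExtrusionSummary:
    """Coverage, loop-length and barrier-engagement statistics.

    Pause state is scored positionally, as it must be when statistics are
    derived from sampled configurations: a leg is paused at a barrier iff
    it sits on a pausing site. A track barrier is occupied iff >=1 leg sits
    on it; an extruder is paused both sides iff both its legs sit on
    pausing elements (track barriers or the impermeable centromere/telomere
    boundaries); a loop crosses a barrier iff a track barrier site lies
    strictly between its legs.
    """
    if not samples:
        raise ValueError("empty sample list")
    total = system.total_sites
    B = system.barrier_sites
    at_barrier = np.zeros(total, dtype=bool)
    at_barrier[B] = True
    pausing = at_barrier.copy()
    pausing[system.boundary_sites] = True

    cov = []
    occ_frac = []
    both_frac = []
    cross_frac = []
    lengths = []
    for s in samples:
        if s.n_loops == 0:
            cov.append(0.0)
            occ_frac.append(0.0)
            both_frac.append(0.0)
            cross_frac.append(0.0)
            continue
        diff = np.zeros(total + 1, dtype=np.int64)
        np.add.at(diff, s.left_site, 1)
        np.add.at(diff, s.right_site + 1, -1)
        cov.append(float((np.cumsum(diff[:-1]) > 0).sum()) / total)
        lengths.append((s.right_site - s.left_site) * system.params.monomer_bp)
        if len(B):
            paused_sites = np.concatenate(
                [
                    s.left_site[at_barrier[s.left_site]],
                    s.right_site[at_barrier[s.right_site]],
                ]
            )
            occ_frac.append(len(np.unique(paused_sites)) / len(B))
            both = pausing[s.left_site] & pausing[s.right_site]
            both_frac.append(float(both.mean()))
            hi = np.searchsorted(B, s.right_site, side="left")
            lo = np.searchsorted(B, s.left_site, side="right")
            cross_frac.append(float((hi > lo).mean()))
        else:
            occ_frac.append(0.0)
            both_frac.append(0.0)
            cross_frac.append(0.0)
    lengths = (
        np.concatenate(lengths) if lengths else np.array([], dtype=np.int64)
    )
    if len(lengths):
        edges = np.arange(0, lengths.max() + 2 * system.params.monomer_bp, system.params.monomer_bp)
        freq, _ = np.histogram(lengths, bins=edges)
        freq = freq / freq.sum()
        mean_loop = float(lengths.mean())
    else:
        edges = np.array([0.0])
        freq = np.array([])
        mean_loop = 0.0
    return ExtrusionSummary(
        coverage_fraction=float(np.mean(cov)),
        mean_loop_bp=mean_loop,
        loop_length_edges_bp=edges,
        loop_length_freq=freq,
        frac_barriers_occupied=float(np.mean(occ_frac)),
        frac_extruders_paused_both_sides=float(np.mean(both_frac)),
        frac_loops_crossing_barrier=float(np.mean(cross_frac)),
        n_samples=len(samples),
    )


@dataclass
class SimulatedChip:
    """Extruder-leg occupancy frequency per genomic site (mean-1 normalised)."""

    values: np.ndarray  # length sites_per_genome
    monomer_bp: int
    n_samples: int


def simulated_chip(
    samples: list[LoopConfiguration], system: LatticeSystem
) -> SimulatedChip:
    """Aggregate loop-base positions into a ChIP-like per-site profile.

    Both legs of every extruder are counted at their genomic position
    (pooled over chromatid copies) and the profile is normalised to mean 1
    over non-boundary sites.
    """
    if not samples:
        raise ValueError("empty sample list")
    n = system.sites_per_genome
    counts = np.zeros(n)
    for s in samples:
        np.add.at(counts, s.left_site % n, 1)
        np.add.at(counts, s.right_site % n, 1)
    non_boundary = np.ones(n, dtype=bool)
    non_boundary[system.boundary_sites[system.boundary_sites < n]] = False
    mean = counts[non_boundary].mean()
    if mean > 0:
        counts = counts / mean
    return SimulatedChip(values=counts, monomer_bp=system.params.monomer_bp, n_samples=len(samples))
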