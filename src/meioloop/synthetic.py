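"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes without external data: a
chromosome spec shaped like yeast chromosome 13, Rec8-like barrier tracks
with exponentially distributed spacing, TSS annotations with optional
convergent-orientation bias at barrier flanks, and power-law contact maps
with an implanted grid of peaks at chosen anchor pairs.

Every generator is deterministic given its seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BarrierTrack, ChromosomeSpec, TSSAnnotation
from .hic import ContactMatrix

__all__ = [
    "make_chromosome_spec",
    "sample_barrier_track",
    "sample_tss_annotation",
    "synth_contact_map",
    "synth_genome_contact_map",
    "CHR13_LENGTH_BP",
    "CHR13_CENTROMERE_BP",
]

# Yeast chromosome 13-like dimensions: 1445 lattice sites of 640 bp.
CHR13_LENGTH_BP = 924_800
CHR13_CENTROMERE_BP = 268_000


def make_chromosome_spec(
    name: str, length_bp: int, centromere_bp: int, telomere_excl_bp: int = 0
) -> ChromosomeSpec:
    """Validated chromosome spec; arms are [0, cen) and [cen, length)."""
    return ChromosomeSpec(name, length_bp, centromere_bp, telomere_excl_bp)


def sample_barrier_track(
    spec: ChromosomeSpec,
    mean_spacing_bp: int = 12_000,
    strength: float = 0.95,
    seed: int = 0,
    monomer_bp: int = 640,
    feature_excl_bp: int = 0,
) -> BarrierTrack:
    """Barrier positions with independent exponential gaps of the given mean.

    Positions are snapped to the monomer lattice and deduplicated. Barrier
    sites span the whole chromosome by default, as cohesin ChIP peaks do;
    set ``feature_excl_bp`` to keep barriers away from the centromere and
    telomeres (e.g. to mirror the contact-map analysis exclusion zones).
    """
    if mean_spacing_bp <= 0:
        raise ValueError("mean_spacing_bp must be positive")
    if mean_spacing_bp >= spec.length_bp:
        raise ValueError("mean_spacing_bp must be smaller than the chromosome")
    rng = np.random.default_rng(seed)
    # over-draw gaps, then trim to chromosome length
    n_guess = int(spec.length_bp / mean_spacing_bp * 2) + 10
    pos = np.cumsum(rng.exponential(mean_spacing_bp, size=n_guess))
    while pos[-1] < spec.length_bp:
        extra = pos[-1] + np.cumsum(rng.exponential(mean_spacing_bp, size=n_guess))
        pos = np.concatenate([pos, extra])
    pos = pos[pos < spec.length_bp]
    # snap to the monomer lattice and deduplicate
    sites = np.unique(np.round(pos / monomer_bp).astype(np.int64))
    snapped = sites * monomer_bp
    snapped = snapped[(snapped >= 0) & (snapped < spec.length_bp)]
    keep = (
        (snapped >= feature_excl_bp)
        & (snapped < spec.length_bp - feature_excl_bp)
        & (np.abs(snapped - spec.centromere_bp) >= feature_excl_bp)
    )
    snapped = snapped[keep]
    return BarrierTrack.from_arrays(
        [spec.name] * len(snapped), snapped, np.full(len(snapped), float(strength))
    )


def sample_tss_annotation(
    spec: ChromosomeSpec,
    density_per_kb: float = 0.5,
    convergent_bias_at: BarrierTrack | None = None,
    seed: int = 0,
    bias_offset_bp: int = 1_000,
) -> TSSAnnotation:
    """Uniform random TSSs plus optional convergent pairs flanking barriers.

    With ``convergent_bias_at`` set, every barrier gets a '+' TSS at
    ``-bias_offset_bp`` and a '-' TSS at ``+bias_offset_bp`` (convergent
    orientation pointing at the barrier), clipped to chromosome bounds.
    """
    if density_per_kb < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_kb * spec.length_bp / 1000.0)
    pos = np.sort(rng.integers(0, spec.length_bp, size=n))
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    chroms = [spec.name] * n
    positions = list(pos)
    strands = list(strand)
    if convergent_bias_at is not None:
        for b in convergent_bias_at.positions_for(spec.name):
            up = int(b) - bias_offset_bp
            dn = int(b) + bias_offset_bp
            if 0 <= up < spec.length_bp:
                chroms.append(spec.name)
                positions.append(up)
                strands.append("+")
            if 0 <= dn < spec.length_bp:
                chroms.append(spec.name)
                positions.append(dn)
                strands.append("-")
    ann = TSSAnnotation(
        pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
    )
    ann.validate([spec])
    return ann


def _expected_powerlaw(n: int, decay_exponent: float, scale: float) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        exp = scale * np.where(d > 0, d, 1.0) ** decay_exponent
    return exp


def synth_contact_map(
    spec: ChromosomeSpec,
    bin_bp: int = 2000,
    decay_exponent: float = -1.5,
    peak_anchor_pairs: list[tuple[int, int]] | None = None,
    peak_fold: float = 1.0,
    noise_seed: int | None = None,
    scale: float = 100.0,
) -> ContactMatrix:
    """Single-chromosome contact map with power-law decay and planted peaks.

    The expected value at bin distance d >= 1 is ``scale * d**decay_exponent``
    (the diagonal gets ``scale``), multiplied by ``peak_fold`` at the listed
    anchor bin pairs. With ``noise_seed`` set, counts are Poisson-sampled
    (symmetrically); otherwise the expectation itself is returned.
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    n = spec.n_bins(bin_bp)
    exp = _expected_powerlaw(n, decay_exponent, scale)
    if peak_anchor_pairs:
        for i, j in peak_anchor_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"anchor pair ({i}, {j}) outside 0..{n - 1}")
            exp[i, j] *= peak_fold
            if i != j:
                exp[j, i] *= peak_fold
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        upper = rng.poisson(np.triu(exp))
        counts = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diagonal(upper))
        counts = counts.astype(float)
    else:
        counts = exp
    return ContactMatrix(counts, bin_bp, (spec,))


def synth_genome_contact_map(
    specs: list[ChromosomeSpec],
    bin_bp: int = 2000,
    decay_exponent: float = -1.5,
    trans_level: float = 0.0,
    noise_seed: int | None = None,
    scale: float = 100.0,
) -> ContactMatrix:
    """Multi-chromosome map: power-law cis blocks plus a flat trans level."""
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    m = ContactMatrix.zeros(specs, bin_bp)
    exp = np.full((m.n_bins, m.n_bins), float(trans_level))
    for ci in range(len(specs)):
        sl = m.chrom_slice(ci)
        nb = sl.stop - sl.start
        exp[sl, sl] = _expected_powerlaw(nb, decay_exponent, scale)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        upper = rng.poisson(np.triu(exp))
        exp = (np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diagonal(upper))).astype(float)
    return ContactMatrix(exp, bin_bp, tuple(specs))
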