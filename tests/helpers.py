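"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by direct enumeration or per-pair
loops, independent of the vectorised implementations they check.
"""
from __future__ import annotations

import numpy as np


# --------------------------------------------------------------------------
# exact stationary distribution of a single extruder on a tiny lattice
# --------------------------------------------------------------------------

def single_extruder_stationary(n_sites: int, p_death: float) -> dict[int, float]:
    """Exact stationary loop-length distribution on an n-site chromatid.

    Mirrors the sweep semantics: with probability p_death the extruder
    teleports to a uniformly random unoccupied bond among non-boundary
    sites and then both legs move; otherwise both legs take one outward
    step. Telomere sites (0 and n-1) are impermeable: a leg may sit on
    them but never beyond. Returns P(loop length in sites).
    """
    states = [(l, r) for l in range(n_sites) for r in range(l + 1, n_sites)]
    index = {s: k for k, s in enumerate(states)}
    ns = len(states)
    T = np.zeros((ns, ns))

    def moved(l, r):
        return (max(l - 1, 0), min(r + 1, n_sites - 1))

    # birth bonds exclude boundary sites 0 and n-1
    birth_bonds = [(i, i + 1) for i in range(1, n_sites - 2)]
    for (l, r), k in index.items():
        T[k, index[moved(l, r)]] += 1.0 - p_death
        for i, j in birth_bonds:
            T[k, index[moved(i, j)]] += p_death / len(birth_bonds)
    # stationary distribution by eigenvector of T^T
    w, v = np.linalg.eig(T.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = pi / pi.sum()
    out: dict[int, float] = {}
    for (l, r), k in index.items():
        out[r - l] = out.get(r - l, 0.0) + pi[k]
    return out


def total_variation(p: dict[int, float], q: dict[int, float]) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# --------------------------------------------------------------------------
# per-pair Hi-C oracles (direct double loops)
# --------------------------------------------------------------------------

def bin_arm_bounds(m):
    """Map each bin to the half-open (lo, hi) bin range of its arm."""
    bounds = {}
    for _, _, lo, hi in m.arm_bin_ranges():
        for b in range(lo, hi):
            bounds[b] = (lo, hi)
    return bounds


def brute_ps(m, edges_bins, exclusion_bp=20000.0):
    """Mean contact per log distance bin by explicit pair enumeration."""
    include = m.ps_include_mask(exclusion_bp)
    bounds = bin_arm_bounds(m)
    nb = len(edges_bins) - 1
    sums = np.zeros(nb)
    cnts = np.zeros(nb)
    for i in range(m.n_bins):
        for j in range(i + 1, m.n_bins):
            if not (include[i] and include[j]):
                continue
            if bounds[i] != bounds[j]:
                continue
            d = j - i
            if d < edges_bins[0] or d >= edges_bins[-1]:
                continue
            k = int(np.searchsorted(edges_bins, d, side="right") - 1)
            sums[k] += m.counts[i, j]
            cnts[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan), cnts


def brute_insulation(m, half_window_bp):
    """Diamond scores and arm-normalised log2 profile by direct loops."""
    w = half_window_bp // m.bin_bp
    diamond = np.full(m.n_bins, np.nan)
    bounds = bin_arm_bounds(m)
    for i in range(m.n_bins):
        lo, hi = bounds[i]
        if i - w < lo or i + w + 1 > hi:
            continue
        if int(m.mask[i - w : i + w + 1].sum()) > 1:
            continue
        vals = []
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                if not (m.mask[a] or m.mask[b]):
                    vals.append(m.counts[a, b])
        diamond[i] = np.mean(vals) if vals else np.nan
    score = np.full(m.n_bins, np.nan)
    for _, _, lo, hi in m.arm_bin_ranges():
        arm = diamond[lo:hi]
        if np.any(np.isfinite(arm)):
            score[lo:hi] = np.log2(arm / np.nanmean(arm))
    return diamond, score


def brute_observed_over_expected(m):
    """Obs/exp with per-distance intra-arm pooled expectation, pair by pair."""
    bounds = bin_arm_bounds(m)
    sums: dict[int, float] = {}
    cnts: dict[int, int] = {}
    for i in range(m.n_bins):
        for j in range(i, m.n_bins):
            if m.mask[i] or m.mask[j] or bounds[i] != bounds[j]:
                continue
            d = j - i
            sums[d] = sums.get(d, 0.0) + m.counts[i, j]
            cnts[d] = cnts.get(d, 0) + 1
    oe = np.full((m.n_bins, m.n_bins), np.nan)
    for i in range(m.n_bins):
        for j in range(i, m.n_bins):
            if m.mask[i] or m.mask[j] or bounds[i] != bounds[j]:
                continue
            e = sums[j - i] / cnts[j - i]
            v = m.counts[i, j] / e if e > 0 else np.nan
            oe[i, j] = oe[j, i] = v
    return oe


def brute_cis_total(m):
    ratio = np.full(m.n_bins, np.nan)
    for i in range(m.n_bins):
        if m.mask[i]:
            continue
        cis = tot = 0.0
        for j in range(m.n_bins):
            if m.mask[j]:
                continue
            v = m.counts[i, j]
            tot += v
            if m.bin_chrom[i] == m.bin_chrom[j]:
                cis += v
        ratio[i] = cis / tot if tot > 0 else np.nan
    return ratio


def brute_goodness_of_fit(sim_vals, expt_vals):
    """Direct evaluation of the combined fold-discrepancy statistic.

    sim_vals/expt_vals: arrays of shape (3, N) over classes and s-bins.
    """
    import math

    N = sim_vals.shape[1]
    acc = 0.0
    for s in range(N):
        inner = 0.0
        for c in range(3):
            inner += (math.log(sim_vals[c, s]) - math.log(expt_vals[c, s])) ** 2
        acc += math.sqrt(inner)
    return math.exp(acc / N)
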