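"""Hi-C summary statistics on binned contact matrices.

Implements the analysis layer used to characterise meiotic contact maps:
translocation-bin masking, distance-decay curves P(s) with log-spaced bins
and centromere/telomere exclusion zones, barrier-pair stratification of
P(s), telomere-distance-stratified P(s), per-bin cis/total ratios, sliding
diamond-window insulation, observed/expected normalisation, average feature
maps, site-pair pileups and TSS orientation profiles.

Conventions: bins are 0-based, half-open ``[k*bin_bp, (k+1)*bin_bp)``; a bin
belongs to the arm containing its midpoint; masked (filtered) bins are
excluded from every statistic and undefined results are NaN, never zero.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .genome import BarrierTrack, ChromosomeSpec, TSSAnnotation

__all__ = [
    "ContactMatrix",
    "PsCurve",
    "StratifiedPs",
    "BinClassTrack",
    "InsulationProfile",
    "OrientationProfile",
    "mask_translocation_bins",
    "compute_ps",
    "classes_from_sites",
    "stratify_ps",
    "stratified_from_arrays",
    "ps_by_telomere_distance",
    "cis_total",
    "insulation",
    "observed_over_expected",
    "average_feature_map",
    "site_pair_pileup",
    "tss_orientation_profile",
    "log_distance_edges",
]


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Symmetric genome-wide binned contact counts with a bin mask.

    ``mask`` is True for filtered-out bins. Counts in masked bins are kept
    but ignored by every downstream operation.
    """

    counts: np.ndarray
    bin_bp: int
    specs: tuple[ChromosomeSpec, ...]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.specs = tuple(self.specs)
        n = sum(s.n_bins(self.bin_bp) for s in self.specs)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} genome bins"
            )
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise ValueError("contact counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length does not match bin count")

    @classmethod
    def zeros(cls, specs, bin_bp: int) -> "ContactMatrix":
        n = sum(s.n_bins(bin_bp) for s in specs)
        return cls(np.zeros((n, n)), bin_bp, tuple(specs))

    # -- geometry ----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @cached_property
    def chrom_n_bins(self) -> np.ndarray:
        return np.array([s.n_bins(self.bin_bp) for s in self.specs])

    @cached_property
    def chrom_offsets(self) -> np.ndarray:
        """Start bin of each chromosome plus a final sentinel."""
        return np.concatenate([[0], np.cumsum(self.chrom_n_bins)])

    @cached_property
    def bin_chrom(self) -> np.ndarray:
        """Chromosome index of every bin."""
        return np.repeat(np.arange(len(self.specs)), self.chrom_n_bins)

    @cached_property
    def bin_mid_bp(self) -> np.ndarray:
        """Midpoint (bp, chromosome-local) of every bin."""
        local = np.concatenate([np.arange(n) for n in self.chrom_n_bins])
        return local * self.bin_bp + self.bin_bp / 2.0

    @cached_property
    def bin_arm(self) -> np.ndarray:
        """Arm index (0 left of centromere, 1 right) of every bin."""
        cen = np.array([s.centromere_bp for s in self.specs])[self.bin_chrom]
        return (self.bin_mid_bp >= cen).astype(np.int8)

    @cached_property
    def dist_to_centromere(self) -> np.ndarray:
        cen = np.array([s.centromere_bp for s in self.specs])[self.bin_chrom]
        return np.abs(self.bin_mid_bp - cen)

    @cached_property
    def dist_to_telomere(self) -> np.ndarray:
        """Distance from bin midpoint to the telomere of its own arm."""
        length = np.array([s.length_bp for s in self.specs])[self.bin_chrom]
        return np.where(self.bin_arm == 0, self.bin_mid_bp, length - self.bin_mid_bp)

    def chrom_slice(self, index: int) -> slice:
        return slice(int(self.chrom_offsets[index]), int(self.chrom_offsets[index + 1]))

    def chrom_index(self, name: str) -> int:
        for i, s in enumerate(self.specs):
            if s.name == name:
                return i
        raise KeyError(f"chromosome {name!r} not in matrix")

    def bin_index(self, chrom: str, pos_bp: int) -> int:
        ci = self.chrom_index(chrom)
        if not (0 <= pos_bp < self.specs[ci].length_bp):
            raise ValueError(f"position {pos_bp} outside {chrom}")
        return int(self.chrom_offsets[ci] + pos_bp // self.bin_bp)

    def arm_bin_ranges(self):
        """Yield (chrom_index, arm, start_bin, stop_bin) with half-open bins."""
        for ci in range(len(self.specs)):
            lo, hi = int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1])
            arm = self.bin_arm[lo:hi]
            split = lo + int(np.searchsorted(arm, 1))
            if split > lo:
                yield ci, 0, lo, split
            if hi > split:
                yield ci, 1, split, hi

    def ps_include_mask(self, exclusion_bp: float = 20000.0) -> np.ndarray:
        """Bins eligible for P(s): unmasked and outside cen/tel exclusion zones."""
        return (
            ~self.mask
            & (self.dist_to_centromere >= exclusion_bp)
            & (self.dist_to_telomere >= exclusion_bp)
        )


# --------------------------------------------------------------------------
# masking
# --------------------------------------------------------------------------

def mask_translocation_bins(m: ContactMatrix, cis_diagonal: int = 3) -> np.ndarray:
    """Mask bins whose trans signal betrays a likely translocation.

    A bin is masked if any of its trans entries reaches the median of its
    chromosome's third cis diagonal, or if its maximum trans entry exceeds
    its maximum cis entry. Updates ``m.mask`` in place and returns it.
    """
    if len(m.specs) < 2:
        warnings.warn("translocation masking needs >=2 chromosomes; no-op")
        return m.mask
    newly = np.zeros(m.n_bins, dtype=bool)
    for ci in range(len(m.specs)):
        sl = m.chrom_slice(ci)
        cis = m.counts[sl, sl]
        diag = np.diagonal(cis, offset=cis_diagonal)
        med3 = np.median(diag) if diag.size else np.nan
        trans_cols = np.ones(m.n_bins, dtype=bool)
        trans_cols[sl] = False
        trans = m.counts[sl, :][:, trans_cols]
        if trans.shape[1] == 0:
            continue
        cond1 = (
            np.any(trans >= med3, axis=1) if np.isfinite(med3) else np.zeros(cis.shape[0], bool)
        )
        cond2 = trans.max(axis=1) > cis.max(axis=1)
        newly[sl] = cond1 | cond2
    m.mask = m.mask | newly
    return m.mask


# --------------------------------------------------------------------------
# P(s)
# --------------------------------------------------------------------------

@dataclass
class PsCurve:
    """Contact frequency versus genomic separation on log-spaced bins.

    ``edges_bp`` are half-open distance-bin edges; ``value`` is the mean
    contact frequency per bin normalised to 1 at the bin containing
    ``anchor_bp``; ``mean_raw`` is the unnormalised mean.
    """

    edges_bp: np.ndarray
    value: np.ndarray
    mean_raw: np.ndarray
    n_pairs: np.ndarray
    s_bp: np.ndarray  # pair-weighted mean separation per bin
    anchor_bp: int = 4000

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges_bp) <= 0):
            raise ValueError("distance-bin edges must be strictly increasing")

    @property
    def s_mid_bp(self) -> np.ndarray:
        """Geometric midpoint of each distance bin (bp)."""
        return np.sqrt(self.edges_bp[:-1] * self.edges_bp[1:])

    @property
    def n_dist_bins(self) -> int:
        return len(self.edges_bp) - 1


def log_distance_edges(max_dist_bins: int, n_logbins: int = 50, start_bins: int = 2) -> np.ndarray:
    """Integer logarithmically-spaced distance-bin edges in bin units.

    Edges run from ``start_bins`` to just past ``max_dist_bins`` with ~n
    bins; duplicate integer edges are collapsed.
    """
    if max_dist_bins <= start_bins:
        return np.array([start_bins, start_bins + 1])
    raw = np.geomspace(start_bins, max_dist_bins + 1, n_logbins + 1)
    edges = np.unique(np.round(raw).astype(np.int64))
    return edges


def _ps_aggregate(
    m: ContactMatrix,
    edges_bins: np.ndarray,
    include: np.ndarray,
    labels: np.ndarray | None = None,
):
    """Mean contact per log distance bin over intra-arm included pairs.

    With ``labels`` (0/1 per bin) aggregation is split by pair class:
    0 = non-non, 1 = mixed, 2 = both labelled. Returns (sums, counts,
    dist_sums) arrays of shape (n_class, n_dist_bins).
    """
    ncls = 3 if labels is not None else 1
    nb = len(edges_bins) - 1
    sums = np.zeros((ncls, nb))
    cnts = np.zeros((ncls, nb), dtype=np.int64)
    dsts = np.zeros((ncls, nb))
    for _, _, lo, hi in m.arm_bin_ranges():
        idx = np.arange(lo, hi)[include[lo:hi]]
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        gi, gj = idx[ii], idx[jj]
        d = gj - gi
        keep = (d >= edges_bins[0]) & (d < edges_bins[-1])
        gi, gj, d = gi[keep], gj[keep], d[keep]
        if len(d) == 0:
            continue
        vals = m.counts[gi, gj]
        b = np.searchsorted(edges_bins, d, side="right") - 1
        if labels is not None:
            cls = labels[gi].astype(int) + labels[gj].astype(int)
        else:
            cls = np.zeros(len(d), dtype=int)
        np.add.at(sums, (cls, b), vals)
        np.add.at(cnts, (cls, b), 1)
        np.add.at(dsts, (cls, b), d)
    return sums, cnts, dsts


def _curve_from_agg(sums, cnts, dsts, edges_bins, bin_bp, anchor_bp, anchor_val=None) -> PsCurve:
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_raw = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        s_bp = np.where(cnts > 0, dsts / np.maximum(cnts, 1) * bin_bp, np.nan)
    edges_bp = edges_bins * bin_bp
    if anchor_val is None:
        # anchor = the distance bin containing anchor_bp
        anchor_idx = int(np.searchsorted(edges_bp, anchor_bp, side="right") - 1)
        anchor_idx = max(0, min(anchor_idx, len(mean_raw) - 1))
        anchor_val = mean_raw[anchor_idx]
    if not np.isfinite(anchor_val) or anchor_val <= 0:
        raise ValueError("P(s) anchor bin is empty or non-positive; cannot normalise")
    fill = np.sqrt(edges_bp[:-1] * edges_bp[1:])
    s_bp = np.where(np.isfinite(s_bp), s_bp, fill)
    return PsCurve(
        edges_bp=edges_bp.astype(float),
        value=mean_raw / anchor_val,
        mean_raw=mean_raw,
        n_pairs=cnts,
        s_bp=s_bp,
        anchor_bp=anchor_bp,
    )


def _default_edges(m: ContactMatrix, n_logbins: int) -> np.ndarray:
    max_arm = max(
        (hi - lo) for _, _, lo, hi in m.arm_bin_ranges()
    )
    return log_distance_edges(max_arm, n_logbins)


def compute_ps(
    m: ContactMatrix,
    n_logbins: int = 50,
    exclusion_bp: float = 20000.0,
    anchor_bp: int = 4000,
    edges_bins: np.ndarray | None = None,
) -> PsCurve:
    """Intra-arm contact frequency versus distance, P(s).

    Restricted to bin pairs within one chromosomal arm, excluding bins less
    than ``exclusion_bp`` from a centromere or telomere, aggregated over
    log-spaced distance bins and normalised to the bin containing
    ``anchor_bp``.
    """
    if edges_bins is None:
        edges_bins = _default_edges(m, n_logbins)
    include = m.ps_include_mask(exclusion_bp)
    sums, cnts, dsts = _ps_aggregate(m, edges_bins, include)
    if cnts.sum() == 0:
        raise ValueError("no valid intra-arm bin pairs for P(s)")
    return _curve_from_agg(sums[0], cnts[0], dsts[0], edges_bins, m.bin_bp, anchor_bp)


# --------------------------------------------------------------------------
# stratified P(s)
# --------------------------------------------------------------------------

@dataclass
class BinClassTrack:
    """Per-bin barrier class: True where the bin overlaps >=1 barrier site."""

    is_site: np.ndarray

    def __post_init__(self) -> None:
        self.is_site = np.asarray(self.is_site, dtype=bool)


def classes_from_sites(m: ContactMatrix, sites: BarrierTrack) -> BinClassTrack:
    """Label a bin as a barrier (Rec8) bin if it overlaps >=1 site."""
    lab = np.zeros(m.n_bins, dtype=bool)
    for spec in m.specs:
        for pos in sites.positions_for(spec.name):
            lab[m.bin_index(spec.name, int(pos))] = True
    return BinClassTrack(lab)


_CLASS_KEYS = ("non_non", "rec8_non", "rec8_rec8")


@dataclass
class StratifiedPs:
    """P(s) split by bin-pair barrier class (Rec8-Rec8 / Rec8-non / non-non)."""

    rec8_rec8: PsCurve | None
    rec8_non: PsCurve | None
    non_non: PsCurve | None

    def curves(self) -> dict[str, PsCurve | None]:
        return {
            "rec8_rec8": self.rec8_rec8,
            "rec8_non": self.rec8_non,
            "non_non": self.non_non,
        }

    @property
    def edges_bp(self) -> np.ndarray:
        for c in self.curves().values():
            if c is not None:
                return c.edges_bp
        raise ValueError("all stratified curves undefined")


def stratify_ps(
    m: ContactMatrix,
    classes: BinClassTrack,
    n_logbins: int = 50,
    exclusion_bp: float = 20000.0,
    anchor_bp: int = 4000,
    edges_bins: np.ndarray | None = None,
) -> StratifiedPs:
    """P(s) aggregated separately for Rec8-Rec8, Rec8-non and non-non pairs.

    The three curves share one normalisation constant, the pooled all-pairs
    mean at the anchor distance, so their relative levels are preserved
    (barrier-pair classes are sparse at 4 kb and may have no anchor pairs
    of their own).
    """
    if edges_bins is None:
        edges_bins = _default_edges(m, n_logbins)
    include = m.ps_include_mask(exclusion_bp)
    labels = classes.is_site.astype(np.int8)
    sums, cnts, dsts = _ps_aggregate(m, edges_bins, include, labels=labels)
    pooled_sums = sums.sum(axis=0)
    pooled_cnts = cnts.sum(axis=0)
    edges_bp = edges_bins * m.bin_bp
    anchor_idx = int(np.searchsorted(edges_bp, anchor_bp, side="right") - 1)
    anchor_idx = max(0, min(anchor_idx, len(pooled_cnts) - 1))
    if pooled_cnts[anchor_idx] == 0:
        raise ValueError("P(s) anchor bin is empty; cannot normalise")
    anchor_val = pooled_sums[anchor_idx] / pooled_cnts[anchor_idx]
    out: dict[str, PsCurve | None] = {}
    for cls, key in enumerate(_CLASS_KEYS):
        if cnts[cls].sum() == 0:
            warnings.warn(f"no pairs in class {key}; curve undefined")
            out[key] = None
            continue
        out[key] = _curve_from_agg(
            sums[cls], cnts[cls], dsts[cls], edges_bins, m.bin_bp, anchor_bp,
            anchor_val=anchor_val,
        )
    return StratifiedPs(
        rec8_rec8=out["rec8_rec8"], rec8_non=out["rec8_non"], non_non=out["non_non"]
    )


def stratified_from_arrays(edges_bp, rec8_rec8, rec8_non, non_non) -> StratifiedPs:
    """Build a StratifiedPs directly from value arrays on shared edges."""
    edges_bp = np.asarray(edges_bp, dtype=float)

    def mk(v):
        v = np.asarray(v, dtype=float)
        n = np.ones(len(v), dtype=np.int64)
        s = np.sqrt(edges_bp[:-1] * edges_bp[1:])
        return PsCurve(edges_bp, v, v.copy(), n, s)

    return StratifiedPs(mk(rec8_rec8), mk(rec8_non), mk(non_non))


def ps_by_telomere_distance(
    m: ContactMatrix,
    strata_edges_bp,
    n_logbins: int = 50,
    exclusion_bp: float = 20000.0,
    anchor_bp: int = 4000,
) -> list[tuple[tuple[float, float], PsCurve | None]]:
    """P(s) stratified by the combined distance of a bin pair to telomeres.

    A pair's stratum is set by the sum of its two bins' distances to their
    arm telomere; pairs where either bin lies closer to the centromere than
    to the telomere are excluded.
    """
    strata_edges_bp = np.asarray(strata_edges_bp, dtype=float)
    if np.any(np.diff(strata_edges_bp) <= 0):
        raise ValueError("strata edges must be strictly increasing")
    edges_bins = _default_edges(m, n_logbins)
    include = m.ps_include_mask(exclusion_bp) & (m.dist_to_telomere < m.dist_to_centromere)
    nb = len(edges_bins) - 1
    ns = len(strata_edges_bp) - 1
    sums = np.zeros((ns, nb))
    cnts = np.zeros((ns, nb), dtype=np.int64)
    dsts = np.zeros((ns, nb))
    for _, _, lo, hi in m.arm_bin_ranges():
        idx = np.arange(lo, hi)[include[lo:hi]]
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        gi, gj = idx[ii], idx[jj]
        d = gj - gi
        keep = (d >= edges_bins[0]) & (d < edges_bins[-1])
        gi, gj, d = gi[keep], gj[keep], d[keep]
        if len(d) == 0:
            continue
        combined = m.dist_to_telomere[gi] + m.dist_to_telomere[gj]
        s_idx = np.searchsorted(strata_edges_bp, combined, side="right") - 1
        ok = (s_idx >= 0) & (s_idx < ns)
        gi, gj, d, s_idx = gi[ok], gj[ok], d[ok], s_idx[ok]
        b = np.searchsorted(edges_bins, d, side="right") - 1
        np.add.at(sums, (s_idx, b), m.counts[gi, gj])
        np.add.at(cnts, (s_idx, b), 1)
        np.add.at(dsts, (s_idx, b), d)
    out = []
    for k in range(ns):
        rng = (float(strata_edges_bp[k]), float(strata_edges_bp[k + 1]))
        if cnts[k].sum() == 0:
            warnings.warn(f"telomere-distance stratum {rng} empty; curve undefined")
            out.append((rng, None))
        else:
            out.append(
                (rng, _curve_from_agg(sums[k], cnts[k], dsts[k], edges_bins, m.bin_bp, anchor_bp))
            )
    return out


# --------------------------------------------------------------------------
# cis/total
# --------------------------------------------------------------------------

def cis_total(m: ContactMatrix, classes: BinClassTrack | None = None):
    """Per-bin fraction of contacts that are intra-chromosomal.

    Masked bins are excluded from both numerator and denominator; bins with
    zero total signal get NaN. Returns a DataFrame and, when ``classes`` is
    given, a dict of class means.
    """
    ok = ~m.mask
    ratio = np.full(m.n_bins, np.nan)
    for ci in range(len(m.specs)):
        sl = m.chrom_slice(ci)
        cis_cols = np.zeros(m.n_bins, dtype=bool)
        cis_cols[sl] = True
        cis_sum = m.counts[:, cis_cols & ok].sum(axis=1)
        tot_sum = m.counts[:, ok].sum(axis=1)
        rows = np.arange(*sl.indices(m.n_bins)[:2])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot_sum[rows] > 0, cis_sum[rows] / tot_sum[rows], np.nan)
        ratio[rows] = r
    ratio[m.mask] = np.nan
    df = pd.DataFrame(
        {
            "bin": np.arange(m.n_bins),
            "chrom": [m.specs[c].name for c in m.bin_chrom],
            "cis_total": ratio,
        }
    )
    if classes is None:
        return df
    means = {
        "rec8": float(np.nanmean(ratio[classes.is_site & ok]))
        if np.any(classes.is_site & ok)
        else float("nan"),
        "non": float(np.nanmean(ratio[~classes.is_site & ok]))
        if np.any(~classes.is_site & ok)
        else float("nan"),
    }
    return df, means


# --------------------------------------------------------------------------
# insulation
# --------------------------------------------------------------------------

@dataclass
class InsulationProfile:
    """Per-bin log2 insulation score; NaN where undefined."""

    score: np.ndarray
    diamond: np.ndarray
    half_window_bp: int


def insulation(m: ContactMatrix, half_window_bp: int = 20000) -> InsulationProfile:
    """Log2 insulation from a sliding diamond window across the diagonal.

    The diamond at bin i is counts[i-w:i, i+1:i+w+1]. Scores are defined
    only where the window fits inside the bin's arm and contains at most one
    masked bin; they are normalised by the arm-wide mean diamond score.
    """
    if half_window_bp % m.bin_bp:
        raise ValueError("half_window_bp must be a whole number of bins")
    w = half_window_bp // m.bin_bp
    diamond = np.full(m.n_bins, np.nan)
    score = np.full(m.n_bins, np.nan)
    cnt = np.where(m.mask, np.nan, 1.0)
    for _, _, lo, hi in m.arm_bin_ranges():
        if hi - lo < 2 * w + 1:
            warnings.warn("insulation window larger than arm; arm left undefined")
            continue
        for i in range(lo + w, hi - w):
            n_masked = int(m.mask[i - w : i + w + 1].sum())
            if n_masked > 1:
                continue
            sub = m.counts[i - w : i, i + 1 : i + w + 1].astype(float).copy()
            sub *= cnt[i - w : i, None]
            sub *= cnt[None, i + 1 : i + w + 1]
            diamond[i] = np.nanmean(sub)
        arm = diamond[lo:hi]
        norm = np.nanmean(arm) if np.any(np.isfinite(arm)) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            score[lo:hi] = np.log2(arm / norm)
    return InsulationProfile(score=score, diamond=diamond, half_window_bp=half_window_bp)


# --------------------------------------------------------------------------
# observed / expected
# --------------------------------------------------------------------------

def observed_over_expected(m: ContactMatrix, ps: PsCurve | None = None) -> np.ndarray:
    """Divide each intra-arm entry by the expected value at its distance.

    The expectation is the intra-arm mean contact at each integer bin
    distance, pooled over all arms from unmasked pairs (computed from the
    matrix itself unless a P(s) curve is supplied, in which case its raw
    per-log-bin means are used). Masked and inter-arm entries are NaN.
    """
    n = m.n_bins
    ok = ~m.mask
    max_d = n
    if ps is None:
        sums = np.zeros(max_d)
        cnts = np.zeros(max_d, dtype=np.int64)
        for _, _, lo, hi in m.arm_bin_ranges():
            idx = np.arange(lo, hi)[ok[lo:hi]]
            if len(idx) == 0:
                continue
            ii, jj = np.triu_indices(len(idx), k=0)
            gi, gj = idx[ii], idx[jj]
            d = gj - gi
            np.add.at(sums, d, m.counts[gi, gj])
            np.add.at(cnts, d, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            expected_at = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    else:
        expected_at = np.full(max_d, np.nan)
        edges = (ps.edges_bp / m.bin_bp).astype(int)
        for k in range(len(edges) - 1):
            expected_at[edges[k] : min(edges[k + 1], max_d)] = ps.mean_raw[k]
    oe = np.full((n, n), np.nan)
    for _, _, lo, hi in m.arm_bin_ranges():
        idx = np.arange(lo, hi)[ok[lo:hi]]
        if len(idx) == 0:
            continue
        ii, jj = np.triu_indices(len(idx), k=0)
        gi, gj = idx[ii], idx[jj]
        e = expected_at[gj - gi]
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where((e > 0) & np.isfinite(e), m.counts[gi, gj] / e, np.nan)
        oe[gi, gj] = v
        oe[gj, gi] = v
    return oe


# --------------------------------------------------------------------------
# pileups
# --------------------------------------------------------------------------

def average_feature_map(
    m: ContactMatrix,
    anchors: list[tuple[str, int]],
    mode: str = "cis",
    flank_bp: int = 20000,
    within: str = "chromosome",
):
    """Element-wise mean of contact-map patches around anchors.

    ``cis`` collects on-diagonal patches around each anchor; ``trans``
    collects anchor-by-anchor patches across different chromosomes (e.g.
    centromere-centromere pileups). Patches whose flanks extend beyond the
    permitted extent (``within``: 'chromosome' or 'arm') are excluded.
    Returns (patch, n_patches).
    """
    f = flank_bp // m.bin_bp
    size = 2 * f + 1
    vals = np.where(m.mask[:, None] | m.mask[None, :], np.nan, m.counts)

    def bounds_of(b: int) -> tuple[int, int]:
        ci = int(m.bin_chrom[b])
        if within == "chromosome":
            return int(m.chrom_offsets[ci]), int(m.chrom_offsets[ci + 1])
        for _, _, lo, hi in m.arm_bin_ranges():
            if lo <= b < hi:
                return lo, hi
        raise AssertionError

    abins = [m.bin_index(c, p) for c, p in anchors]
    patches = []
    if mode == "cis":
        for b in abins:
            lo, hi = bounds_of(b)
            if b - f < lo or b + f + 1 > hi:
                continue
            patches.append(vals[b - f : b + f + 1, b - f : b + f + 1])
    elif mode == "trans":
        for bi in abins:
            for bj in abins:
                if bi == bj or m.bin_chrom[bi] == m.bin_chrom[bj]:
                    continue
                li, hi_i = bounds_of(bi)
                lj, hi_j = bounds_of(bj)
                if bi - f < li or bi + f + 1 > hi_i or bj - f < lj or bj + f + 1 > hi_j:
                    continue
                patches.append(vals[bi - f : bi + f + 1, bj - f : bj + f + 1])
    else:
        raise ValueError("mode must be 'cis' or 'trans'")
    if not patches:
        raise ValueError("no valid patches for average feature map")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        patch = np.nanmean(np.stack(patches), axis=0)
    assert patch.shape == (size, size)
    return patch, len(patches)


def site_pair_pileup(
    m: ContactMatrix,
    sites: BarrierTrack,
    separation_rank: int = 1,
    flank_bp: int = 10000,
    oe: np.ndarray | None = None,
):
    """Average log2 observed/expected patch at k-th-neighbour site pairs.

    Rank k pairs each site with its k-th neighbour along the chromosome
    (within the same arm, where obs/exp is defined); rank 0 centres single
    sites on the diagonal (insulation-style pileup). Returns
    (log2_patch, n_patches).
    """
    if oe is None:
        oe = observed_over_expected(m)
    f = flank_bp // m.bin_bp
    arm_of_bin = {}
    for _, _, lo, hi in m.arm_bin_ranges():
        for b in range(lo, hi):
            arm_of_bin[b] = (lo, hi)
    patches = []
    for spec in m.specs:
        pos = sites.positions_for(spec.name)
        bins = sorted({m.bin_index(spec.name, int(p)) for p in pos})
        if separation_rank == 0:
            pairs = [(b, b) for b in bins]
        else:
            pairs = [
                (bins[k], bins[k + separation_rank])
                for k in range(len(bins) - separation_rank)
            ]
        for bi, bj in pairs:
            lo_i, hi_i = arm_of_bin[bi]
            if arm_of_bin[bj] != (lo_i, hi_i):
                continue
            if bi - f < lo_i or bj + f + 1 > hi_i:
                continue
            patches.append(oe[bi - f : bi + f + 1, bj - f : bj + f + 1])
    if not patches:
        raise ValueError("no qualifying site pairs for pileup")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_patch = np.nanmean(np.stack(patches), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(mean_patch), len(patches)


# --------------------------------------------------------------------------
# TSS orientation
# --------------------------------------------------------------------------

@dataclass
class OrientationProfile:
    """TSS counts by orientation in offset bins around anchors."""

    offsets_bp: np.ndarray  # bin start offsets (half-open bins of bin_bp)
    plus: np.ndarray
    minus: np.ndarray
    plus_smooth: np.ndarray
    minus_smooth: np.ndarray
    bin_bp: int
    n_anchors: int


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x.astype(float)
    return np.convolve(x.astype(float), np.ones(k) / k, mode="same")


def tss_orientation_profile(
    anchors: list[tuple[str, int]],
    tss: TSSAnnotation,
    bin_bp: int = 500,
    smooth_bins: int = 3,
    flank_bp: int = 10000,
) -> OrientationProfile:
    """Frequency of TSSs by orientation around anchors.

    Offsets (TSS minus anchor) in [-flank_bp, flank_bp) are counted in
    ``bin_bp`` bins per strand and smoothed with a ``smooth_bins`` sliding
    mean.
    """
    if not anchors:
        raise ValueError("no anchors given")
    nb = 2 * flank_bp // bin_bp
    counts = {"+": np.zeros(nb), "-": np.zeros(nb)}
    by_chrom = {c: g for c, g in tss.df.groupby("chrom", sort=False)}
    for chrom, apos in anchors:
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        off = grp["pos"].to_numpy(dtype=np.int64) - apos
        inside = (off >= -flank_bp) & (off < flank_bp)
        b = (off[inside] + flank_bp) // bin_bp
        strands = grp["strand"].to_numpy()[inside]
        for s in ("+", "-"):
            np.add.at(counts[s], b[strands == s].astype(int), 1)
    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    return OrientationProfile(
        offsets_bp=offsets,
        plus=counts["+"],
        minus=counts["-"],
        plus_smooth=_smooth(counts["+"], smooth_bins),
        minus_smooth=_smooth(counts["-"], smooth_bins),
        bin_bp=bin_bp,
        n_anchors=len(anchors),
    )
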