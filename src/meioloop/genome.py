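"""Genome coordinate primitives: chromosomes, barrier tracks, TSS annotations.

All coordinates are 0-based, half-open. A chromosome is split into two arms
at the centromere: the left arm is [0, centromere_bp) and the right arm is
[centromere_bp, length_bp).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "BarrierTrack",
    "TSSAnnotation",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome with a point centromere splitting it into two arms."""

    name: str
    length_bp: int
    centromere_bp: int
    telomere_excl_bp: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if not (0 < self.centromere_bp < self.length_bp):
            raise ValueError(
                f"centromere_bp must lie strictly inside (0, {self.length_bp}), "
                f"got {self.centromere_bp}"
            )
        if self.telomere_excl_bp < 0:
            raise ValueError("telomere_excl_bp must be non-negative")

    def arm_of(self, pos_bp: int) -> int:
        """Arm index for a position: 0 for [0, cen), 1 for [cen, length)."""
        if not (0 <= pos_bp < self.length_bp):
            raise ValueError(f"position {pos_bp} outside [0, {self.length_bp})")
        return 0 if pos_bp < self.centromere_bp else 1

    def arm_bounds(self, arm: int) -> tuple[int, int]:
        """Half-open bp bounds of an arm."""
        if arm == 0:
            return (0, self.centromere_bp)
        if arm == 1:
            return (self.centromere_bp, self.length_bp)
        raise ValueError(f"arm must be 0 or 1, got {arm}")

    def arm_lengths_bp(self) -> tuple[int, int]:
        return (self.centromere_bp, self.length_bp - self.centromere_bp)

    def n_bins(self, bin_bp: int) -> int:
        return math.ceil(self.length_bp / bin_bp)

    def n_sites(self, monomer_bp: int) -> int:
        return math.ceil(self.length_bp / monomer_bp)


def _as_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records[list(columns)].reset_index(drop=True)
    return pd.DataFrame(records, columns=list(columns))


@dataclass
class BarrierTrack:
    """Point barriers (e.g. Rec8 ChIP peaks) with per-barrier strengths.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (bp) and
    ``strength`` (pause probability in [0, 1]). Positions are kept sorted
    and strictly increasing per chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _as_frame(self.df, ("chrom", "pos", "strength"))
        self.df = self.df.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        s = self.df["strength"].to_numpy(dtype=float)
        if len(s) and (np.any(s < 0) or np.any(s > 1)):
            raise ValueError("barrier strengths must be in [0, 1]")
        for chrom, grp in self.df.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"barrier positions on {chrom} are not strictly increasing")

    @classmethod
    def from_arrays(cls, chroms, positions, strengths) -> "BarrierTrack":
        return cls(pd.DataFrame({"chrom": chroms, "pos": positions, "strength": strengths}))

    @classmethod
    def empty(cls) -> "BarrierTrack":
        return cls(pd.DataFrame({"chrom": [], "pos": [], "strength": []}))

    def __len__(self) -> int:
        return len(self.df)

    def positions_for(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)

    def strengths_for(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "strength"].to_numpy(dtype=float)

    def validate(self, specs: list[ChromosomeSpec]) -> None:
        lengths = {s.name: s.length_bp for s in specs}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"barrier chromosome {chrom!r} not in genome")
            p = grp["pos"].to_numpy()
            if len(p) and (p.min() < 0 or p.max() >= lengths[chrom]):
                raise ValueError(f"barrier position outside [0, {lengths[chrom]}) on {chrom}")

    def with_strength(self, strength: float) -> "BarrierTrack":
        """Copy of the track with a uniform strength (used by grid scans)."""
        df = self.df.copy()
        df["strength"] = float(strength)
        return BarrierTrack(df)


@dataclass
class TSSAnnotation:
    """Transcription start sites with orientation.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (bp) and
    ``strand`` ('+' or '-').
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _as_frame(self.df, ("chrom", "pos", "strand"))
        self.df = self.df.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("TSS strand must be '+' or '-'")

    @classmethod
    def empty(cls) -> "TSSAnnotation":
        return cls(pd.DataFrame({"chrom": [], "pos": [], "strand": []}))

    def __len__(self) -> int:
        return len(self.df)

    def validate(self, specs: list[ChromosomeSpec]) -> None:
        lengths = {s.name: s.length_bp for s in specs}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"TSS chromosome {chrom!r} not in genome")
            p = grp["pos"].to_numpy()
            if len(p) and (p.min() < 0 or p.max() >= lengths[chrom]):
                raise ValueError(f"TSS position outside [0, {lengths[chrom]}) on {chrom}")
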