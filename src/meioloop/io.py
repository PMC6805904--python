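"""File formats and run configuration.

Genomic interval I/O uses BED (0-based, half-open) and bedGraph; contact
matrices are 3-column COO text (bin_i, bin_j, count; upper triangle) with a
JSON sidecar carrying the bin size and chromosome segmentation; summaries
are JSON and grids/curves tabular text.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .extrusion import ExtrusionSummary, LoopConfiguration, SimulatedChip
from .fitting import FitGrid
from .genome import BarrierTrack, ChromosomeSpec, TSSAnnotation
from .hic import ContactMatrix, PsCurve

__all__ = [
    "RunConfig",
    "load_config",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_track",
    "write_barrier_bed",
    "write_tss_bed",
    "read_contact_matrix",
    "write_contact_matrix",
    "write_bedgraph",
    "write_chip_bedgraph",
    "write_loop_configurations",
    "write_summary_json",
    "write_ps_curve",
    "write_fit_grid",
]


@dataclass
class RunConfig:
    """Run-wide settings; defaults follow the study's stated conventions."""

    bin_bp: int = 2000
    monomer_bp: int = 640
    contact_radius_nm: float = 60.0
    confinement_radius_nm: float = 1000.0
    exclusion_bp: int = 20000
    insulation_half_window_bp: int = 20000
    ps_anchor_bp: int = 4000
    ps_n_logbins: int = 50
    gof_s_min_bp: float = 10000.0
    gof_s_max_bp: float = 300000.0
    tss_bin_bp: int = 500
    tss_smooth_bins: int = 3
    barrier_mean_spacing_bp: int = 12000
    processivity_bp: float = 76000.0
    separation_bp: float = 32000.0
    barrier_strength: float = 0.95
    n_chromatid_copies: int = 52
    burn_in_sweeps: int = -1  # -1: ten extruder lifetimes
    n_samples: int = 500
    sample_interval_sweeps: int = 5
    seed: int = 0
    exclude_chroms: str = ""  # comma-separated (e.g. "chr1,chr12")

    def excluded(self) -> list[str]:
        return [c for c in self.exclude_chroms.split(",") if c]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Read a ``key = value`` config file, then apply keyword overrides.

    Unknown keys are an error; '#' starts a comment.
    """
    values: dict = {}
    types = {f.name: f.type for f in fields(RunConfig)}
    defaults = RunConfig()
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            cur = getattr(defaults, key)
            values[key] = type(cur)(val)
    for k, v in overrides.items():
        if v is None:
            continue
        if k not in types:
            raise ValueError(f"unknown config key {k!r}")
        values[k] = v
    return RunConfig(**values)


# --------------------------------------------------------------------------
# chromosome specs
# --------------------------------------------------------------------------

def read_chrom_sizes(sizes_path, centromere_bed_path) -> list[ChromosomeSpec]:
    """Chromosome specs from a two-column sizes file plus a centromere BED."""
    sizes = pd.read_csv(
        sizes_path, sep=r"\s+", header=None, names=["chrom", "length"], comment="#"
    )
    cen = pd.read_csv(
        centromere_bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    cen_mid = {r.chrom: (int(r.start) + int(r.end)) // 2 for r in cen.itertuples()}
    specs = []
    for r in sizes.itertuples():
        if r.chrom not in cen_mid:
            raise ValueError(f"no centromere record for {r.chrom}")
        specs.append(ChromosomeSpec(r.chrom, int(r.length), cen_mid[r.chrom]))
    return specs


def write_chrom_sizes(specs, sizes_path, centromere_bed_path) -> None:
    with open(sizes_path, "w") as fh:
        for s in specs:
            fh.write(f"{s.name}\t{s.length_bp}\n")
    with open(centromere_bed_path, "w") as fh:
        for s in specs:
            fh.write(f"{s.name}\t{s.centromere_bp}\t{s.centromere_bp + 1}\tCEN\n")


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

def write_barrier_bed(track: BarrierTrack, path) -> None:
    """Barriers as BED6; strength stored in the score column x1000."""
    with open(path, "w") as fh:
        for r in track.df.itertuples():
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t{int(r.pos) + 1}\tbarrier\t"
                f"{int(round(r.strength * 1000))}\t.\n"
            )


def write_tss_bed(tss: TSSAnnotation, path) -> None:
    with open(path, "w") as fh:
        for r in tss.df.itertuples():
            fh.write(f"{r.chrom}\t{int(r.pos)}\t{int(r.pos) + 1}\tTSS\t0\t{r.strand}\n")


def _read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty track file")
        return pd.DataFrame(columns=names)
    df.columns = names[: df.shape[1]]
    return df


def read_track(path, kind: str):
    """Read a BED/bedGraph track.

    kind='barriers' -> BarrierTrack (score column /1000 as strength;
    overlapping intervals are collapsed to their midpoint with a warning).
    kind='tss' -> TSSAnnotation (strand column required).
    kind='signal' -> bedGraph DataFrame (chrom, start, end, value).
    """
    if kind == "signal":
        try:
            return pd.read_csv(
                path, sep="\t", header=None, comment="#",
                names=["chrom", "start", "end", "value"],
            )
        except pd.errors.EmptyDataError:
            warnings.warn(f"{path}: empty track file")
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = _read_bed(path)
    if kind == "barriers":
        if df.empty:
            return BarrierTrack.empty()
        mid = (df["start"].astype(int) + df["end"].astype(int)) // 2
        wide = (df["end"].astype(int) - df["start"].astype(int)) > 1
        if wide.any():
            warnings.warn(f"{path}: interval barriers collapsed to midpoints")
        strength = (
            df["score"].astype(float) / 1000.0 if "score" in df else pd.Series(1.0, index=df.index)
        )
        out = pd.DataFrame({"chrom": df["chrom"], "pos": mid, "strength": strength})
        out = out.drop_duplicates(subset=["chrom", "pos"])
        return BarrierTrack(out)
    if kind == "tss":
        if df.empty:
            return TSSAnnotation.empty()
        if "strand" not in df:
            raise ValueError(f"{path}: TSS BED needs a strand column")
        return TSSAnnotation(
            pd.DataFrame(
                {"chrom": df["chrom"], "pos": df["start"].astype(int), "strand": df["strand"]}
            )
        )
    raise ValueError(f"unknown track kind {kind!r}")


# --------------------------------------------------------------------------
# contact matrices
# --------------------------------------------------------------------------

def write_contact_matrix(m: ContactMatrix, path) -> None:
    """Upper-triangle COO text plus a JSON sidecar (<path>.json)."""
    path = Path(path)
    with open(path, "w") as fh:
        iu, ju = np.nonzero(np.triu(m.counts))
        for i, j in zip(iu, ju):
            v = m.counts[i, j]
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
    sidecar = {
        "bin_bp": m.bin_bp,
        "chromosomes": [
            {"name": s.name, "length_bp": s.length_bp, "centromere_bp": s.centromere_bp}
            for s in m.specs
        ],
        "masked_bins": np.nonzero(m.mask)[0].tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_contact_matrix(path, sidecar_path=None) -> ContactMatrix:
    """Read COO text + sidecar; upper-triangle input is symmetrised."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(Path(sidecar_path).read_text())
    specs = tuple(
        ChromosomeSpec(c["name"], c["length_bp"], c["centromere_bp"])
        for c in meta["chromosomes"]
    )
    bin_bp = int(meta["bin_bp"])
    n = sum(s.n_bins(bin_bp) for s in specs)
    counts = np.zeros((n, n))
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: malformed row ({err})") from None
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"{path}:{lineno}: bin index outside 0..{n - 1}")
        counts[i, j] += v
        if i != j:
            counts[j, i] += v
    mask = np.zeros(n, dtype=bool)
    mask[meta.get("masked_bins", [])] = True
    return ContactMatrix(counts, bin_bp, specs, mask)


# --------------------------------------------------------------------------
# profiles and summaries
# --------------------------------------------------------------------------

def write_bedgraph(chrom_names, starts, ends, values, path) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(chrom_names, starts, ends, values):
            if np.isfinite(v):
                fh.write(f"{c}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_chip_bedgraph(chip: SimulatedChip, specs, path) -> None:
    """Simulated ChIP profile at monomer resolution."""
    rows = []
    off = 0
    for spec in specs:
        ns = spec.n_sites(chip.monomer_bp)
        for s in range(ns):
            start = s * chip.monomer_bp
            rows.append(
                (spec.name, start, min(start + chip.monomer_bp, spec.length_bp), chip.values[off + s])
            )
        off += ns
    write_bedgraph(*zip(*rows), path)


def write_loop_configurations(samples, system, path) -> None:
    """Loops as TSV: sample, chromatid, left_bp, right_bp, paused flags."""
    mono = system.params.monomer_bp
    start = system.chromatid_start
    with open(path, "w") as fh:
        fh.write("sample\tchromatid\tleft_bp\tright_bp\tpaused_left\tpaused_right\n")
        for si, s in enumerate(samples):
            for k in range(s.n_loops):
                c = int(s.chromatid[k])
                off = start[c]
                fh.write(
                    f"{si}\t{c}\t{(s.left_site[k] - off) * mono}\t"
                    f"{(s.right_site[k] - off) * mono}\t"
                    f"{int(s.paused_left[k])}\t{int(s.paused_right[k])}\n"
                )


def write_summary_json(summary: ExtrusionSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.as_dict(), indent=1))


def write_ps_curve(curve: PsCurve, path) -> None:
    df = pd.DataFrame(
        {
            "s_bp": curve.s_bp,
            "edge_lo_bp": curve.edges_bp[:-1],
            "edge_hi_bp": curve.edges_bp[1:],
            "value": curve.value,
            "n_pairs": curve.n_pairs,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_fit_grid(grid: FitGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)
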