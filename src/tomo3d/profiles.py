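"""Per-plane section count tables, detection filtering, and spike-in normalization.

A tomo-seq experiment sequences serial cryosections along three orthogonal
planes. For each plane this module ingests a genes x sections count table
(with exogenous ERCC spike-in rows), applies the detection filter (a minimum
number of reads in a minimum number of sections), and converts raw counts to
normalized 1D expression traces by dividing each section by its total
spike-in count. Spike-ins are added at a fixed input per section, so their
per-section read total estimates capture efficiency; the ratio removes
section-to-section technical variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._axes import check_plane

SPIKEIN_PREFIX = "ERCC-"


class CountTableError(ValueError):
    """Raised for malformed or unusable count tables."""


@dataclass
class SectionCountTable:
    """Raw counts per gene per section for one sectioning plane.

    ``counts`` holds gene rows, ``spikeins`` the ERCC spike-in rows; both
    share the ordered section columns (``section_001`` ...) in the plane's
    anatomical orientation.
    """

    plane: str
    counts: pd.DataFrame
    spikeins: pd.DataFrame

    def __post_init__(self) -> None:
        check_plane(self.plane)
        for name, df in (("counts", self.counts), ("spikeins", self.spikeins)):
            arr = df.to_numpy()
            if arr.size and not np.all(np.isfinite(arr)):
                raise CountTableError(f"{name} contains non-finite values")
            if arr.size and (arr < 0).any():
                raise CountTableError(f"{name} contains negative values")
        if list(self.counts.columns) != list(self.spikeins.columns):
            raise CountTableError("counts and spikeins must share section columns")

    @property
    def n_sections(self) -> int:
        return self.counts.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def section_ids(self) -> np.ndarray:
        """1-based section numbers in plane orientation."""
        return np.arange(1, self.n_sections + 1)


def write_count_table(table: SectionCountTable, path: str | Path) -> Path:
    """Write a table as TSV: ``gene_id`` column then sections; spike-in rows last."""
    path = Path(path)
    stacked = pd.concat([table.counts, table.spikeins])
    stacked.index.name = "gene_id"
    stacked.to_csv(path, sep="\t")
    return path


def read_count_table(
    path: str | Path, plane: str, require_integer: bool = True
) -> SectionCountTable:
    """Read a TSV count table written by :func:`write_count_table` (or equivalent).

    Rows whose id starts with ``ERCC-`` are treated as spike-ins. Raises
    :class:`CountTableError` on negative entries, on non-integer entries when
    ``require_integer`` is set, and when no spike-in row is present (spike-in
    normalization would be impossible).
    """
    check_plane(plane)
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise CountTableError(f"{path}: non-numeric entries")
    if not np.all(np.isfinite(arr)):
        raise CountTableError(f"{path}: non-finite entries")
    if (arr < 0).any():
        raise CountTableError(f"{path}: negative counts")
    if require_integer and not np.allclose(arr, np.round(arr), atol=0, rtol=0):
        raise CountTableError(f"{path}: non-integer counts")
    is_spike = df.index.astype(str).str.startswith(SPIKEIN_PREFIX)
    if not is_spike.any():
        raise CountTableError(f"{path}: no spike-ins (rows prefixed {SPIKEIN_PREFIX!r})")
    return SectionCountTable(
        plane=plane, counts=df.loc[~is_spike], spikeins=df.loc[is_spike]
    )


def detect_expressed(
    table: SectionCountTable, min_reads: int = 4, min_sections: int = 2
) -> set[str]:
    """Genes with at least ``min_reads`` counts in at least ``min_sections`` sections.

    The filter is applied to raw counts, before normalization, and excludes
    spike-in rows. Defaults reproduce the standard tomo-seq detection rule of
    a minimum of 4 reads in at least two (not necessarily adjacent) sections.
    """
    if min_reads < 1 or min_sections < 1:
        raise ValueError("thresholds must be >= 1")
    hits = (table.counts.to_numpy() >= min_reads).sum(axis=1)
    return set(np.asarray(table.counts.index)[hits >= min_sections])


@dataclass
class SpikeinQC:
    """Per-plane spike-in quality control.

    ``recovery_ratio`` is the summed observed spike-in output over the
    declared input for the whole plane (NaN when no input was declared).
    """

    plane: str
    per_section_totals: np.ndarray
    zero_sections: list[int] = field(default_factory=list)
    spikein_input: float | None = None
    recovery_ratio: float = math.nan

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "plane": self.plane,
            "per_section_totals": [float(v) for v in self.per_section_totals],
            "zero_sections": [int(s) for s in self.zero_sections],
            "spikein_input": None
            if self.spikein_input is None
            else float(self.spikein_input),
            "recovery_ratio": float(self.recovery_ratio),
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


@dataclass
class PlaneProfiles:
    """Normalized 1D expression traces for every gene along one plane.

    ``values`` is genes x sections; entries are
    ``count / spikein_total(section) * scale_reference`` with
    ``scale_reference`` the plane's mean spike-in total, so magnitudes stay
    commensurable with raw counts. Sections whose spike-in total was zero are
    missing (NaN), not zero.
    """

    plane: str
    values: pd.DataFrame
    scale_reference: float

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def trace(self, gene_id: str) -> np.ndarray:
        if str(gene_id).startswith(SPIKEIN_PREFIX):
            raise KeyError(f"{gene_id!r} is a spike-in, not a gene")
        if gene_id not in self.values.index:
            raise KeyError(f"unknown gene {gene_id!r} in {self.plane} profiles")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def total(self, gene_id: str) -> float:
        return float(np.nansum(self.trace(gene_id)))


def normalize_by_spikein(
    table: SectionCountTable,
    spikein_input: float | np.ndarray | None = None,
    max_zero_fraction: float = 0.2,
) -> tuple[PlaneProfiles, SpikeinQC]:
    """Normalize each section of a count table by its total spike-in reads.

    Each section's gene counts are divided by that section's spike-in total
    and rescaled by the plane's mean spike-in total (``scale_reference``).
    Sections with zero spike-in reads cannot be normalized: their values are
    set to missing and reported in the QC object; if more than
    ``max_zero_fraction`` of sections are affected the table is unusable and
    a :class:`CountTableError` is raised.

    ``spikein_input`` (scalar per section, or a per-section array) declares
    the known spike-in input so the QC can report the plane-wide
    output/input recovery ratio.
    """
    if table.spikeins.shape[0] == 0:
        raise CountTableError("no spike-ins: normalization impossible")
    totals = table.spikeins.to_numpy(dtype=float).sum(axis=0)
    zero = totals == 0
    if zero.mean() > max_zero_fraction:
        raise CountTableError(
            f"{table.plane}: {int(zero.sum())}/{zero.size} sections have zero "
            "spike-in reads; table unusable"
        )
    scale_reference = float(totals[~zero].mean())
    denom = np.where(zero, np.nan, totals)
    values = table.counts.astype(float) / denom * scale_reference

    n = table.n_sections
    if spikein_input is None:
        declared = None
        recovery = math.nan
    else:
        inp = np.asarray(spikein_input, dtype=float)
        inp = np.broadcast_to(inp, (n,))
        declared = float(inp.sum())
        recovery = float(totals.sum() / declared) if declared > 0 else math.nan

    qc = SpikeinQC(
        plane=table.plane,
        per_section_totals=totals,
        zero_sections=[int(s) for s in np.flatnonzero(zero) + 1],
        spikein_input=declared,
        recovery_ratio=recovery,
    )
    return PlaneProfiles(table.plane, values, scale_reference), qc


def trace(
    profiles: Mapping[str, PlaneProfiles] | PlaneProfiles,
    gene_id: str,
    plane: str,
) -> np.ndarray:
    """A gene's normalized per-section trace along ``plane``, in plane orientation."""
    check_plane(plane)
    if isinstance(profiles, PlaneProfiles):
        prof = profiles
        if prof.plane != plane:
            raise ValueError(f"profiles are for plane {prof.plane!r}, not {plane!r}")
    else:
        if plane not in profiles:
            raise KeyError(f"no profiles for plane {plane!r}")
        prof = profiles[plane]
    return prof.trace(gene_id)


def write_profiles(
    profiles: Iterable[PlaneProfiles] | Mapping[str, PlaneProfiles], path: str | Path
) -> Path:
    """Export profiles as long-format TSV (plane, gene, section, value, scale_reference)."""
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    frames = []
    for prof in profiles:
        long = prof.values.stack(future_stack=True).reset_index()
        long.columns = ["gene", "section", "value"]
        long.insert(0, "plane", prof.plane)
        long["scale_reference"] = prof.scale_reference
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_profiles(path: str | Path) -> dict[str, PlaneProfiles]:
    """Read the long-format TSV written by :func:`write_profiles`."""
    long = pd.read_csv(path, sep="\t")
    out: dict[str, PlaneProfiles] = {}
    for plane, sub in long.groupby("plane", sort=False):
        wide = sub.pivot(index="gene", columns="section", values="value")
        wide = wide[sorted(wide.columns)]
        out[str(plane)] = PlaneProfiles(
            plane=str(plane),
            values=wide,
            scale_reference=float(sub["scale_reference"].iloc[0]),
        )
    return out
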