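"""3D reconstruction of gene expression by iterative proportional fitting (IPF).

A digitized binary mask of the specimen is partitioned into virtual serial
sections along the three sectioning planes; the voxel grid has one index per
section of each plane. For each gene, the three normalized 1D traces act as
target marginals: starting from a uniform field over in-mask voxels, IPF
repeatedly rescales each plane's slabs so their sums match the trace,
cycling over planes until the marginals agree within tolerance. The
converged field is the gene's "digital expression".

Because the three section series come from different specimens, their trace
totals differ; they are harmonized to a common total (the arithmetic mean of
the positive plane totals) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from skimage.transform import resize

from ._axes import PLANE_AXIS, UPDATE_ORDER, check_plane, other_axes, plane_axis
from .profiles import PlaneProfiles


class MaskError(ValueError):
    """Raised for empty or malformed volume masks."""


@dataclass
class VolumeMask:
    """Boolean voxel grid of the specimen.

    Shape is ``(n_sagittal, n_horizontal, n_transverse)`` — one index per
    section of each plane. ``voxel_size`` is the section thickness in
    micrometres (18 um cryosections give 18 um cubic voxels).
    """

    in_mask: np.ndarray
    voxel_size: float = 18.0

    def __post_init__(self) -> None:
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        if self.in_mask.ndim != 3:
            raise MaskError("mask must be a 3D boolean grid")
        if not self.in_mask.any():
            raise MaskError("empty mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.in_mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.in_mask.sum())

    def section_count(self, plane: str) -> int:
        return self.shape[plane_axis(plane)]

    def slab_counts(self, plane: str) -> np.ndarray:
        """In-mask voxel count per section of ``plane``."""
        axis = plane_axis(plane)
        return self.in_mask.sum(axis=other_axes(axis))


def write_mask(mask: VolumeMask, path: str | Path) -> Path:
    """Write a mask as an 8-bit multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.in_mask.astype(np.uint8) * 255)
    sidecar = {
        "shape": [int(s) for s in mask.shape],
        "voxel_size_um": float(mask.voxel_size),
        "axes": "sagittal, horizontal, transverse",
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_mask(path: str | Path) -> VolumeMask:
    path = Path(path)
    stack = tifffile.imread(path)
    voxel_size = 18.0
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        voxel_size = float(meta.get("voxel_size_um", 18.0))
    return VolumeMask(stack > 0, voxel_size=voxel_size)


def digitize_mask(
    image_stack: np.ndarray,
    target_shape: Sequence[int],
    threshold: str | float = "otsu",
    voxel_size: float = 18.0,
) -> VolumeMask:
    """Digitize a grayscale confocal stack into a section-resolution mask.

    The stack is binarized (Otsu or a fixed threshold), block-averaged down
    to ``target_shape`` (one voxel per section triple) and re-binarized at
    0.5 occupancy; only the largest connected component is kept.
    """
    stack = np.asarray(image_stack)
    if stack.ndim != 3 or stack.size == 0:
        raise MaskError("image stack must be a non-empty 3D array")
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 1 for s in target_shape):
        raise MaskError("target_shape must be three positive integers")

    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        lo, hi = float(stack.min()), float(stack.max())
        if lo == hi:
            binary = np.full(stack.shape, hi > 0, dtype=bool)
        else:
            from skimage.filters import threshold_otsu

            binary = stack > threshold_otsu(stack)
    else:
        binary = stack > float(threshold)
    if not binary.any():
        raise MaskError("empty mask after thresholding")

    occupancy = resize(
        binary.astype(float), target_shape, order=1, anti_aliasing=False,
        preserve_range=True,
    )
    grid = occupancy >= 0.5
    if not grid.any():
        raise MaskError("empty mask after resampling")
    labels, n = ndimage.label(grid)
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        grid = labels == (1 + int(np.argmax(sizes)))
    return VolumeMask(grid, voxel_size=voxel_size)


def harmonize_totals(
    profiles: Mapping[str, np.ndarray | None],
) -> tuple[dict[str, np.ndarray | None], float, list[str]]:
    """Rescale one gene's per-plane traces to a common total.

    The three planes come from independent specimens, so their totals differ.
    Each plane with a positive total is rescaled so it sums to the arithmetic
    mean of the positive totals; planes with zero total (or absent, ``None``)
    are left zero and returned in the flagged list. Missing sections (NaN)
    are ignored in totals and preserved.

    Returns ``(harmonized, common_total, zero_planes)``; ``common_total`` is
    0 when every plane is empty.
    """
    totals: dict[str, float] = {}
    arrays: dict[str, np.ndarray | None] = {}
    for plane, values in profiles.items():
        check_plane(plane)
        if values is None:
            arrays[plane] = None
            totals[plane] = 0.0
            continue
        arr = np.asarray(values, dtype=float)
        if np.isinf(arr).any():
            raise ValueError(f"{plane}: non-finite profile values")
        arrays[plane] = arr
        totals[plane] = float(np.nansum(arr))
    positive = [t for t in totals.values() if t > 0]
    if not positive:
        return dict(arrays), 0.0, sorted(arrays)
    common_total = float(np.mean(positive))
    harmonized: dict[str, np.ndarray | None] = {}
    zero_planes: list[str] = []
    for plane, arr in arrays.items():
        if arr is None or totals[plane] == 0:
            harmonized[plane] = arr
            zero_planes.append(plane)
        else:
            harmonized[plane] = arr * (common_total / totals[plane])
    return harmonized, common_total, sorted(zero_planes)


@dataclass
class IPFRecord:
    """Convergence diagnostics for one gene's reconstruction."""

    iterations: int
    final_discrepancy: float
    converged: bool
    infeasible_events: int
    skipped_planes: list[str] = field(default_factory=list)
    history: list[float] = field(default_factory=list)


def _slab_reshape(values: np.ndarray, axis: int) -> np.ndarray:
    shape = [1, 1, 1]
    shape[axis] = values.size
    return values.reshape(shape)


def ipf_reconstruct(
    mask: VolumeMask,
    profiles: Mapping[str, np.ndarray | None],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, IPFRecord]:
    """Reconstruct one gene's 3D field from harmonized per-plane traces.

    Starts from a uniform field on in-mask voxels (maximum-entropy start) and
    cycles over planes in the fixed order transverse, horizontal, sagittal.
    For each section the in-slab voxels are multiplied by the ratio of the
    target marginal to the current slab sum. A zero target permanently zeroes
    the slab; a positive target over an empty slab is an infeasibility event
    (logged, slab left at zero). Missing sections (NaN targets) and planes
    flagged as zero/absent are excluded from both updates and the
    convergence check.

    Iteration stops when the largest marginal mismatch, normalized by the
    common total, drops below ``tol``, or after ``max_iter`` cycles.
    """
    active: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for plane in UPDATE_ORDER:
        values = profiles.get(plane)
        if values is None:
            skipped.append(plane)
            continue
        arr = np.asarray(values, dtype=float)
        if np.isinf(arr).any():
            raise ValueError(f"{plane}: non-finite profile values")
        n = mask.section_count(plane)
        if arr.size != n:
            raise ValueError(
                f"{plane}: profile has {arr.size} sections, mask expects {n}"
            )
        if np.nansum(arr) == 0:
            skipped.append(plane)
            continue
        active[plane] = arr

    x = mask.in_mask.astype(float)
    if not active:
        return np.zeros(mask.shape), IPFRecord(0, 0.0, True, 0, skipped)

    common_total = float(np.mean([np.nansum(a) for a in active.values()]))

    def discrepancy() -> float:
        worst = 0.0
        for plane, m in active.items():
            axis = PLANE_AXIS[plane]
            slab = x.sum(axis=other_axes(axis))
            valid = ~np.isnan(m)
            if valid.any():
                worst = max(worst, float(np.abs(slab[valid] - m[valid]).max()))
        return worst / common_total

    infeasible = 0
    history: list[float] = []
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for plane in UPDATE_ORDER:
            if plane not in active:
                continue
            m = active[plane]
            axis = PLANE_AXIS[plane]
            slab = x.sum(axis=other_axes(axis))
            factor = np.ones_like(slab)
            valid = ~np.isnan(m)
            pos = slab > 0
            upd = valid & pos
            factor[upd] = m[upd] / slab[upd]
            infeasible += int((valid & ~pos & (m > 0)).sum())
            x *= _slab_reshape(factor, axis)
        disc = discrepancy()
        history.append(disc)
        if disc < tol:
            converged = True
            break

    record = IPFRecord(
        iterations=iterations,
        final_discrepancy=history[-1] if history else 0.0,
        converged=converged,
        infeasible_events=infeasible,
        skipped_planes=skipped,
        history=history,
    )
    return x, record


@dataclass
class DigitalExpressionModel:
    """Per-gene reconstructed 3D expression fields over a common mask."""

    mask: VolumeMask
    volumes: dict[str, np.ndarray]
    convergence: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.volumes)

    @property
    def total_digital_expression(self) -> dict[str, float]:
        return {g: float(v.sum()) for g, v in self.volumes.items()}


def total_digital_expression(model: DigitalExpressionModel, gene: str) -> float:
    """Sum of a gene's digital expression over all voxels (the screen's n)."""
    if gene not in model.volumes:
        raise KeyError(f"unknown gene {gene!r}")
    return float(model.volumes[gene].sum())


def reconstruct_all(
    mask: VolumeMask,
    plane_profiles: Mapping[str, PlaneProfiles],
    genes: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> DigitalExpressionModel:
    """Harmonize and reconstruct every requested gene.

    ``genes`` defaults to the union of genes present in any plane, in
    first-seen order. A gene absent from some plane, or with zero counts in
    it, is fitted against the remaining planes only; a gene with no signal in
    any plane yields an all-zero volume flagged ``skipped``. Failures are
    per-gene and do not abort the batch.
    """
    for plane in plane_profiles:
        check_plane(plane)
    if genes is None:
        seen: dict[str, None] = {}
        for plane in UPDATE_ORDER:
            if plane in plane_profiles:
                for g in plane_profiles[plane].genes:
                    seen.setdefault(g)
        genes = list(seen)

    volumes: dict[str, np.ndarray] = {}
    rows = []
    for gene in genes:
        raw: dict[str, np.ndarray | None] = {}
        for plane in UPDATE_ORDER:
            prof = plane_profiles.get(plane)
            if prof is not None and gene in prof.values.index:
                raw[plane] = prof.trace(gene)
            else:
                raw[plane] = None
        harmonized, common_total, zero_planes = harmonize_totals(raw)
        if common_total == 0:
            volumes[gene] = np.zeros(mask.shape)
            rows.append(
                dict(gene=gene, iterations=0, discrepancy=0.0, converged=True,
                     infeasible_events=0, skipped=True,
                     zero_planes=",".join(zero_planes), common_total=0.0)
            )
            continue
        vol, rec = ipf_reconstruct(mask, harmonized, tol=tol, max_iter=max_iter)
        volumes[gene] = vol
        rows.append(
            dict(gene=gene, iterations=rec.iterations,
                 discrepancy=rec.final_discrepancy, converged=rec.converged,
                 infeasible_events=rec.infeasible_events, skipped=False,
                 zero_planes=",".join(rec.skipped_planes),
                 common_total=common_total)
        )
    convergence = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    return DigitalExpressionModel(mask=mask, volumes=volumes, convergence=convergence)


def write_model(model: DigitalExpressionModel, directory: str | Path) -> Path:
    """Write a model: per-gene float32 TIFF volumes, mask, convergence TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask(model.mask, directory / "mask.tif")
    for gene, vol in model.volumes.items():
        tifffile.imwrite(directory / f"{gene}.tif", vol.astype(np.float32))
    conv = model.convergence.copy()
    conv.to_csv(directory / "convergence.tsv", sep="\t")
    return directory


def read_model(directory: str | Path) -> DigitalExpressionModel:
    directory = Path(directory)
    mask = read_mask(directory / "mask.tif")
    conv_path = directory / "convergence.tsv"
    convergence = (
        pd.read_csv(conv_path, sep="\t", index_col=0)
        if conv_path.exists()
        else pd.DataFrame()
    )
    volumes = {}
    for path in sorted(directory.glob("*.tif")):
        if path.name == "mask.tif":
            continue
        volumes[path.stem] = tifffile.imread(path).astype(float)
    return DigitalExpressionModel(mask=mask, volumes=volumes, convergence=convergence)
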