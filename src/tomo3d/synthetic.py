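"""Synthetic phantoms: head-like masks, planted territories, simulated sections.

The generator emulates the inputs of a three-plane tomo-seq experiment on an
embryonic head: a digitized binary volume mask, per-gene ground-truth 3D
expression fields drawn from six territory classes (compact blob, axial
gradient, left-restricted peak, midline stripe, salt-and-pepper, uniform),
and per-plane section count tables obtained by slab-summing each field along
the plane axis, scaling to a target sequencing depth, applying per-section
capture efficiencies, adding ERCC-like spike-in rows, and optionally drawing
Poisson counts. Ground truth is retained so reconstruction and screening can
be validated by parameter recovery.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from ._axes import PLANES, UPDATE_ORDER, check_plane, other_axes, plane_axis, section_labels
from .profiles import SPIKEIN_PREFIX, SectionCountTable
from .reconstruction import DigitalExpressionModel, MaskError, VolumeMask, write_mask

TERRITORY_CLASSES = (
    "blob",
    "gradient",
    "left_restricted",
    "midline_stripe",
    "salt_and_pepper",
    "uniform",
)

#: Relative abundances of the 8 simulated spike-in species (a 2x dilution
#: ladder, normalized). Downstream normalization only consumes their
#: per-section total.
SPIKEIN_ABUNDANCES = (2.0 ** np.arange(8)) / (2.0 ** np.arange(8)).sum()
SPIKEIN_IDS = tuple(f"{SPIKEIN_PREFIX}{k:05d}" for k in range(1, 9))


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional coordinates of the grid.

    ``center`` is a fraction of each axis extent; ``radii`` are semi-axes as
    fractions of each axis length (0.5 inscribes the ellipsoid in the grid).
    """

    center: tuple[float, float, float] = (0.5, 0.5, 0.5)
    radii: tuple[float, float, float] = (0.5, 0.5, 0.5)


#: Default head-like geometry: a main ovoid inscribed in the grid (every
#: section of every plane contains tissue, as when the whole specimen is
#: sectioned) plus an anterior bulge.
DEFAULT_GEOMETRY = (
    Ellipsoid(center=(0.5, 0.5, 0.5), radii=(0.5, 0.5, 0.5)),
    Ellipsoid(center=(0.5, 0.38, 0.82), radii=(0.3, 0.26, 0.18)),
)


@dataclass
class TerritorySpec:
    """Descriptor of one gene's planted expression territory.

    ``fraction`` is the target in-mask volume fraction for blob territories
    and the peak-position fraction for left-restricted ones; ``density`` is
    the Bernoulli rate of salt-and-pepper voxels; ``axis`` selects the ramp
    axis for gradients. ``amplitude`` is the expression density per voxel in
    arbitrary units and must be positive.
    """

    territory: str
    amplitude: float = 1.0
    fraction: float = 0.15
    density: float = 0.1
    axis: int = 2
    width: float | None = None

    def __post_init__(self) -> None:
        if self.territory not in TERRITORY_CLASSES:
            raise ValueError(
                f"unknown territory class {self.territory!r}; "
                f"expected one of {TERRITORY_CLASSES}"
            )
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass
class PhantomTruth:
    """Ground-truth phantom: mask, per-gene 3D fields, and their specs."""

    mask: VolumeMask
    fields: dict[str, np.ndarray]
    gene_specs: dict[str, TerritorySpec]
    seed: int

    def __post_init__(self) -> None:
        out = ~self.mask.in_mask
        for gene, arr in self.fields.items():
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ValueError(f"{gene}: field must be finite and >= 0")
            if arr[out].any():
                raise ValueError(f"{gene}: field is nonzero outside the mask")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated three-plane sectioning experiment.

    Defaults mirror a catshark-head-scale experiment: a (30, 33, 34) grid
    (sagittal, horizontal, transverse section counts), uniform capture
    efficiency, 5000 expected spike-in reads per section (the per-section
    total of the 8-species ladder at a fixed dilution), and 10^4 expected
    reads per gene per plane with Poisson counting noise. ``embryo_jitter``
    applies a small random affine warp per plane to emulate the three series
    coming from independent, non-identical specimens (default 0: the
    magnitude of real inter-embryo variation is not characterized).
    """

    shape: tuple[int, int, int] = (30, 33, 34)
    section_efficiency: float | Mapping[str, Sequence[float]] = 1.0
    spikein_input: float = 5000.0
    mean_depth: float = 1e4
    noise_model: str = "poisson"
    embryo_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.spikein_input <= 0:
            raise ValueError("spikein_input must be > 0")

    def efficiency(self, plane: str, n_sections: int) -> np.ndarray:
        if isinstance(self.section_efficiency, Mapping):
            eff = np.asarray(self.section_efficiency[plane], dtype=float)
        else:
            eff = np.full(n_sections, float(self.section_efficiency))
        if eff.shape != (n_sections,):
            raise ValueError(
                f"{plane}: efficiency has length {eff.size}, expected {n_sections}"
            )
        if (eff <= 0).any():
            raise ValueError("section efficiencies must be > 0")
        return eff


def make_phantom_mask(
    shape: Sequence[int],
    geometry: Sequence[Ellipsoid | Mapping[str, Sequence[float]]] | None = None,
    seed: int = 0,
) -> VolumeMask:
    """Build a connected head-like boolean mask from a union of ellipsoids.

    The mask has exactly the requested shape; its in-mask fraction is
    validated to lie in [0.10, 0.90] (too-thin masks leave empty slabs,
    too-full ones degenerate to the bounding cuboid). ``seed`` is recorded
    for provenance; the construction itself is deterministic in the
    geometry.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError("shape must be three integers >= 4")
    if geometry is None:
        geometry = DEFAULT_GEOMETRY
    ells = [
        e if isinstance(e, Ellipsoid) else Ellipsoid(tuple(e["center"]), tuple(e["radii"]))
        for e in geometry
    ]
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    grid = np.zeros(shape, dtype=bool)
    for ell in ells:
        if min(ell.radii) <= 0:
            continue
        d2 = np.zeros(shape)
        for axis in range(3):
            c = ell.center[axis] * (shape[axis] - 1)
            r = ell.radii[axis] * shape[axis]
            d2 += ((coords[axis] - c) / r) ** 2
        grid |= d2 <= 1.0
    if not grid.any():
        raise MaskError("empty mask: geometry has no interior voxel")
    labels, n = ndimage.label(grid)
    if n > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n + 1))
        grid = labels == (1 + int(np.argmax(sizes)))
    frac = grid.mean()
    if not 0.10 <= frac <= 0.90:
        raise MaskError(
            f"in-mask fraction {frac:.3f} outside [0.10, 0.90]; adjust geometry"
        )
    return VolumeMask(grid)


def _grow_blob(
    mask_grid: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Breadth-first growth of a connected region of ``target`` in-mask voxels.

    Returns an integer array of BFS depths (-1 outside the region), so
    callers can taper amplitude from the seed outward.
    """
    candidates = np.argwhere(mask_grid)
    start = tuple(candidates[rng.integers(len(candidates))])
    depth = np.full(mask_grid.shape, -1, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque([start])
    depth[start] = 0
    count = 1
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue and count < target:
        i, j, k = queue.popleft()
        for di, dj, dk in offsets:
            p = (i + di, j + dj, k + dk)
            if (
                0 <= p[0] < mask_grid.shape[0]
                and 0 <= p[1] < mask_grid.shape[1]
                and 0 <= p[2] < mask_grid.shape[2]
                and mask_grid[p]
                and depth[p] < 0
            ):
                depth[p] = depth[i, j, k] + 1
                count += 1
                queue.append(p)
                if count >= target:
                    break
    return depth


def _cos_bump(n: int, center: float, halfwidth: float) -> np.ndarray:
    """Squared-cosine bump along an axis, zero outside |i - center| >= halfwidth."""
    i = np.arange(n, dtype=float)
    u = (i - center) / halfwidth
    bump = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
    return bump


def make_gene_field(
    mask: VolumeMask,
    spec: TerritorySpec,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Generate one gene's ground-truth 3D expression field on a mask.

    blob: a connected region grown to ``fraction`` of the in-mask volume at
    constant amplitude. gradient: a linear ramp along ``axis``.
    left_restricted: a squared-cosine peak centered at ``fraction`` of the
    left-right axis, supported within 3x that fraction from the left edge.
    midline_stripe: a squared-cosine stripe around the sagittal midline.
    salt_and_pepper: independent Bernoulli(``density``) voxels at constant
    amplitude. uniform: constant amplitude over the whole mask.
    """
    rng = np.random.default_rng(seed)
    grid = mask.in_mask
    n_in = mask.n_voxels
    out = np.zeros(mask.shape, dtype=float)
    amp = spec.amplitude

    if spec.territory == "uniform":
        out[grid] = amp
    elif spec.territory == "salt_and_pepper":
        if not 0 < spec.density <= 1:
            raise ValueError("salt_and_pepper density must be in (0, 1]")
        picks = rng.random(n_in) < spec.density
        vals = np.zeros(n_in)
        vals[picks] = amp
        out[grid] = vals
    elif spec.territory == "blob":
        if spec.fraction > 1:
            raise ValueError("requested blob fraction exceeds the in-mask volume")
        target = int(round(spec.fraction * n_in))
        if target < 1:
            raise ValueError("blob fraction too small: no voxel selected")
        depth = _grow_blob(grid, target, rng)
        inside = depth >= 0
        # Graded boundary, as in real expression territories: amplitude decays
        # from the seed to half-amplitude at the territory edge.
        dmax = max(int(depth.max()), 1)
        out[inside] = amp * (1.0 - 0.5 * depth[inside] / dmax)
    elif spec.territory == "gradient":
        axis = spec.axis
        n = mask.shape[axis]
        ramp = np.arange(n, dtype=float) / max(n - 1, 1)
        if rng.random() < 0.5:
            ramp = ramp[::-1]
        shape = [1, 1, 1]
        shape[axis] = n
        out = np.where(grid, amp * ramp.reshape(shape), 0.0)
    elif spec.territory == "left_restricted":
        # per-gene jitter of peak position and extent; support stays within
        # 3 x fraction of the left-right axis by construction
        n = mask.shape[0]
        u = rng.uniform(0.8, 1.1)
        center = spec.fraction * n * u
        halfwidth = max((3.0 - u) * spec.fraction * n * rng.uniform(0.7, 1.0), 1.5)
        bump = _cos_bump(n, center, halfwidth)
        out = np.where(grid, amp * bump.reshape(-1, 1, 1), 0.0)
    elif spec.territory == "midline_stripe":
        n = mask.shape[0]
        halfwidth = spec.width if spec.width is not None else max(0.15 * n, 2.0)
        halfwidth *= rng.uniform(0.8, 1.2)
        center = (n - 1) / 2.0 + rng.uniform(-0.02, 0.02) * n
        bump = _cos_bump(n, center, halfwidth)
        out = np.where(grid, amp * bump.reshape(-1, 1, 1), 0.0)
    return out


def simulate_sections(
    truth: PhantomTruth, plane: str, config: SimulationConfig
) -> SectionCountTable:
    """Forward-simulate one plane's section count table from a phantom.

    The expected count of gene g in section s is the gene's slab sum over
    section s, rescaled so the gene's plane total equals ``mean_depth``, and
    multiplied by the section's capture efficiency. Spike-in species expect
    ``abundance x spikein_input x efficiency`` reads. With ``noise_model
    "none"`` the table holds the exact (real-valued) expectations, so slab
    mass is conserved exactly; with ``"poisson"`` counts are Poisson draws.
    """
    check_plane(plane)
    axis = plane_axis(plane)
    n = truth.mask.shape[axis]
    eff = config.efficiency(plane, n)
    plane_index = PLANES.index(plane)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(plane_index,))
    )

    warp = None
    if config.embryo_jitter > 0:
        j = config.embryo_jitter
        matrix = np.eye(3) + rng.normal(scale=j / 3.0, size=(3, 3))
        offset = rng.normal(scale=2.0 * j, size=3)
        warp = (matrix, offset)

    expected_rows = {}
    for gene, fld in truth.fields.items():
        if warp is not None:
            fld = ndimage.affine_transform(
                fld, warp[0], offset=warp[1], order=1, mode="constant", cval=0.0
            )
            fld = np.clip(fld, 0.0, None)
        slab = fld.sum(axis=other_axes(axis))
        total = slab.sum()
        scale = config.mean_depth / total if total > 0 else 0.0
        expected_rows[gene] = scale * slab * eff
    spike_expected = np.outer(SPIKEIN_ABUNDANCES, config.spikein_input * eff)

    cols = section_labels(n)
    genes_df = pd.DataFrame(expected_rows, index=cols).T
    spikes_df = pd.DataFrame(spike_expected, index=list(SPIKEIN_IDS), columns=cols)
    if config.noise_model == "poisson":
        genes_df = pd.DataFrame(
            rng.poisson(genes_df.to_numpy()), index=genes_df.index, columns=cols
        )
        spikes_df = pd.DataFrame(
            rng.poisson(spikes_df.to_numpy()), index=spikes_df.index, columns=cols
        )
    return SectionCountTable(plane=plane, counts=genes_df, spikeins=spikes_df)


def default_specs(
    n_genes_per_class: Mapping[str, int], rng: np.random.Generator
) -> dict[str, TerritorySpec]:
    """Named territory specs, ``{class}_{k:03d}``, with mild size variation."""
    specs: dict[str, TerritorySpec] = {}
    for cls, n_genes in n_genes_per_class.items():
        if cls not in TERRITORY_CLASSES:
            raise ValueError(f"unknown territory class {cls!r}")
        for k in range(1, int(n_genes) + 1):
            spec = TerritorySpec(territory=cls, amplitude=float(rng.uniform(1.0, 5.0)))
            if cls == "blob":
                spec = replace(spec, fraction=float(rng.uniform(0.08, 0.2)))
            elif cls == "left_restricted":
                spec = replace(spec, fraction=0.1)
            elif cls == "gradient":
                spec = replace(spec, axis=int(rng.integers(3)))
            elif cls == "salt_and_pepper":
                spec = replace(spec, density=float(rng.uniform(0.05, 0.15)))
            specs[f"{cls}_{k:03d}"] = spec
    return specs


def make_phantom(
    config: SimulationConfig,
    n_genes_per_class: Mapping[str, int],
    geometry: Sequence[Ellipsoid] | None = None,
) -> PhantomTruth:
    """Build the mask and ground-truth fields for a simulated experiment."""
    if sum(int(v) for v in n_genes_per_class.values()) < 1:
        raise ValueError("at least one gene is required")
    mask = make_phantom_mask(config.shape, geometry, seed=config.seed)
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    rng = np.random.default_rng(root)
    specs = default_specs(n_genes_per_class, rng)
    children = root.spawn(len(specs))
    fields = {
        gene: make_gene_field(mask, spec, seed=child)
        for (gene, spec), child in zip(specs.items(), children)
    }
    return PhantomTruth(mask=mask, fields=fields, gene_specs=specs, seed=config.seed)


def make_dataset(
    config: SimulationConfig,
    n_genes_per_class: Mapping[str, int],
    geometry: Sequence[Ellipsoid] | None = None,
) -> tuple[PhantomTruth, dict[str, SectionCountTable]]:
    """Phantom truth plus the three per-plane count tables it generates.

    The three tables derive from the same truth; with ``embryo_jitter > 0``
    an independent small affine warp is applied per plane, emulating three
    non-identical specimens. All outputs are pure functions of the config
    and its seed.
    """
    truth = make_phantom(config, n_genes_per_class, geometry)
    tables = {plane: simulate_sections(truth, plane, config) for plane in UPDATE_ORDER}
    return truth, tables


def model_from_truth(truth: PhantomTruth) -> DigitalExpressionModel:
    """Wrap ground-truth fields as a digital expression model.

    Useful for exercising the spatial screens on volumes whose spatial
    structure is exactly known, independently of reconstruction.
    """
    conv = pd.DataFrame(
        {"gene": list(truth.fields), "iterations": 0, "discrepancy": 0.0,
         "converged": True, "infeasible_events": 0, "skipped": False,
         "zero_planes": "", "common_total": [float(f.sum()) for f in truth.fields.values()]}
    ).set_index("gene")
    return DigitalExpressionModel(
        mask=truth.mask, volumes=dict(truth.fields), convergence=conv
    )


def write_truth(truth: PhantomTruth, directory: str | Path) -> Path:
    """Write a phantom: per-gene float32 TIFFs, mask, and a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mask(truth.mask, directory / "mask.tif")
    for gene, fld in truth.fields.items():
        tifffile.imwrite(directory / f"{gene}.tif", fld.astype(np.float32))
    manifest = {
        "seed": int(truth.seed),
        "shape": [int(s) for s in truth.mask.shape],
        "genes": {
            gene: {
                "territory": spec.territory,
                "amplitude": float(spec.amplitude),
                "fraction": float(spec.fraction),
                "density": float(spec.density),
                "axis": int(spec.axis),
                "width": None if spec.width is None else float(spec.width),
            }
            for gene, spec in truth.gene_specs.items()
        },
    }
    (directory / "truth.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return directory
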