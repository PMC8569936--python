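"""End-to-end orchestration: config, pipeline run, and digital-section export.

``run_pipeline`` chains the stages — read count tables, detection filter,
spike-in normalization, mask preparation, IPF reconstruction, Moran
screening, and optional co-expression ranking — and writes every artifact
plus a manifest with parameters and per-file checksums. Runs are
deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from ._axes import PLANES, UPDATE_ORDER, plane_axis
from . import profiles as prof_mod
from . import reconstruction as rec_mod
from . import spatial as spat_mod
from . import synthetic as syn_mod

logger = logging.getLogger("tomo3d")


class ConfigError(ValueError):
    """Invalid pipeline configuration (detected before any compute)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run."""

    counts: dict[str, Path]
    output_dir: Path
    mask_tiff: Path | None = None
    mask_threshold: str | float = "otsu"
    phantom: dict[str, Any] | None = None
    require_integer_counts: bool = True
    spikein_input: float | None = None
    min_reads: int = 4
    min_sections: int = 2
    tol: float = 1e-6
    max_iter: int = 200
    i_min: float = 0.1
    p_max: float = 0.0
    weight_style: str = "binary"
    moran_method: str = "analytic"
    n_perm: int = 9999
    reference_gene: str | None = None
    cor_min: float = 0.4
    top_k: int | None = None
    seed: int = 0
    extras: dict[str, Any] = dc_field(default_factory=dict)

    def validate(self) -> None:
        planes = sorted(self.counts)
        if planes != sorted(PLANES):
            raise ConfigError(
                f"config must name exactly the three planes {sorted(PLANES)}, got {planes}"
            )
        if self.mask_tiff is None and self.phantom is None:
            raise ConfigError("config needs a mask source: 'mask.tiff' or 'mask.phantom'")
        if not (self.min_reads >= 1 and self.min_sections >= 1):
            raise ConfigError("detection thresholds must be >= 1")
        if not (0 < self.tol < 1) or self.max_iter < 1:
            raise ConfigError("reconstruction needs 0 < tol < 1 and max_iter >= 1")
        if self.weight_style not in ("binary", "row_standardized"):
            raise ConfigError(f"unknown weight style {self.weight_style!r}")
        if self.moran_method not in ("analytic", "permutation"):
            raise ConfigError(f"unknown Moran method {self.moran_method!r}")
        if not -1.0 <= self.cor_min <= 1.0:
            raise ConfigError("cor_min must be in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        counts = {str(k): resolve(v) for k, v in dict(raw.get("counts", {})).items()}
        mask_cfg = dict(raw.get("mask", {}))
        det = dict(raw.get("detection", {}))
        norm = dict(raw.get("normalization", {}))
        rec = dict(raw.get("reconstruction", {}))
        scr = dict(raw.get("screening", {}))
        cor = dict(raw.get("correlation", {}))
        cfg = cls(
            counts=counts,
            output_dir=resolve(str(raw.get("output_dir", "tomo3d_out"))),
            mask_tiff=resolve(mask_cfg["tiff"]) if "tiff" in mask_cfg else None,
            mask_threshold=mask_cfg.get("threshold", "otsu"),
            phantom=mask_cfg.get("phantom"),
            require_integer_counts=bool(norm.get("require_integer", True)),
            spikein_input=norm.get("spikein_input"),
            min_reads=int(det.get("min_reads", 4)),
            min_sections=int(det.get("min_sections", 2)),
            tol=float(rec.get("tol", 1e-6)),
            max_iter=int(rec.get("max_iter", 200)),
            i_min=float(scr.get("i_min", 0.1)),
            p_max=float(scr.get("p_max", 0.0)),
            weight_style=str(scr.get("style", "binary")),
            moran_method=str(scr.get("method", "analytic")),
            n_perm=int(scr.get("n_perm", 9999)),
            reference_gene=cor.get("reference"),
            cor_min=float(cor.get("cor_min", 0.4)),
            top_k=cor.get("top_k"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run normalization, reconstruction, and screening; return the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: %.2fs", name, timings.get(name, 0.0))
                return False

        return _Timer()

    with stage("read_counts"):
        tables = {
            plane: prof_mod.read_count_table(
                path, plane, require_integer=config.require_integer_counts
            )
            for plane, path in config.counts.items()
        }

    with stage("detect"):
        detected: set[str] = set()
        per_plane_detected = {}
        for plane, table in tables.items():
            d = prof_mod.detect_expressed(
                table, min_reads=config.min_reads, min_sections=config.min_sections
            )
            per_plane_detected[plane] = len(d)
            detected |= d
        if not detected:
            raise StageError("detect", "no gene passes the detection filter")

    with stage("normalize"):
        plane_profiles = {}
        for plane, table in tables.items():
            profs, qc = prof_mod.normalize_by_spikein(
                table, spikein_input=config.spikein_input
            )
            plane_profiles[plane] = profs
            written.append(qc.to_yaml(out / f"qc_{plane}.yaml"))
        written.append(prof_mod.write_profiles(plane_profiles, out / "profiles.tsv"))

    with stage("mask"):
        shape = tuple(tables[p].n_sections for p in ("sagittal", "horizontal", "transverse"))
        if config.mask_tiff is not None:
            import tifffile

            stack = tifffile.imread(config.mask_tiff)
            mask = rec_mod.digitize_mask(stack, shape, threshold=config.mask_threshold)
        else:
            ph = dict(config.phantom or {})
            ph_shape = tuple(ph.get("shape", shape))
            if ph_shape != shape:
                raise StageError(
                    "mask",
                    f"phantom shape {ph_shape} does not match section counts {shape}",
                )
            mask = syn_mod.make_phantom_mask(ph_shape, seed=int(ph.get("seed", config.seed)))
        written.append(rec_mod.write_mask(mask, out / "mask.tif"))
        written.append(out / "mask.yaml")

    with stage("reconstruct"):
        genes = sorted(detected)
        model = rec_mod.reconstruct_all(
            mask, plane_profiles, genes=genes, tol=config.tol, max_iter=config.max_iter
        )
        model_dir = rec_mod.write_model(model, out / "model")
        written.extend(sorted(model_dir.glob("*")))

    with stage("screen"):
        weights = spat_mod.build_weights(mask, style=config.weight_style)
        table = spat_mod.moran_screen_table(
            model, weights, method=config.moran_method, n_perm=config.n_perm,
            seed=config.seed, i_min=config.i_min, p_max=config.p_max,
        )
        written.append(spat_mod.write_moran_table(table, out / "moran.tsv"))
        passing = table[table["passes"]]
        written.append(
            spat_mod.write_moran_table(passing, out / "regionalized.tsv")
        )

    if config.reference_gene is not None:
        with stage("correlate"):
            ranking = spat_mod.coexpression_ranking(
                model, config.reference_gene, cor_min=config.cor_min, top_k=config.top_k
            )
            written.append(spat_mod.write_ranking(ranking, out / "coexpression.tsv"))

    with stage("manifest"):
        from . import __version__

        manifest = {
            "tomo3d_version": __version__,
            "seed": config.seed,
            "parameters": {
                "detection": {"min_reads": config.min_reads, "min_sections": config.min_sections},
                "reconstruction": {"tol": config.tol, "max_iter": config.max_iter},
                "screening": {
                    "i_min": config.i_min, "p_max": config.p_max,
                    "style": config.weight_style, "method": config.moran_method,
                },
                "correlation": {"reference": config.reference_gene, "cor_min": config.cor_min},
            },
            "detected_genes": {"union": len(detected), **per_plane_detected},
            "n_regionalized": int(table["passes"].sum()),
            "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written)) if p.exists()},
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


_DEFAULT_COLORS = (
    (1.0, 0.0, 1.0),  # magenta
    (0.0, 1.0, 0.0),  # green
    (0.0, 0.3, 1.0),  # blue
    (1.0, 0.0, 0.0),  # red
    (1.0, 1.0, 0.0),  # yellow
    (0.0, 1.0, 1.0),  # cyan
)


def export_section_images(
    model: rec_mod.DigitalExpressionModel,
    genes: Sequence[str],
    plane: str,
    outdir: str | Path,
    sections: Sequence[int] | None = None,
    colors: Sequence[tuple[float, float, float]] | None = None,
    prefix: str = "section",
) -> list[Path]:
    """Render digital sections as PNGs with additive multi-gene color overlays.

    Each gene's volume is scaled to its own maximum for display (stored
    volumes are never rescaled) and painted in its assigned color; overlaps
    add and saturate. ``sections`` are 1-based ids along ``plane``
    (defaulting to all).
    """
    import imageio.v3 as iio

    if not genes:
        raise ValueError("empty gene list")
    for g in genes:
        if g not in model.volumes:
            raise KeyError(f"unknown gene {g!r}")
    axis = plane_axis(plane)
    n = model.mask.shape[axis]
    if sections is None:
        sections = list(range(1, n + 1))
    for s in sections:
        if not 1 <= s <= n:
            raise ValueError(f"section {s} out of range 1..{n} for plane {plane}")
    colors = list(colors or _DEFAULT_COLORS)
    while len(colors) < len(genes):
        colors += list(_DEFAULT_COLORS)

    scaled = {}
    for g in genes:
        vol = np.asarray(model.volumes[g], dtype=float)
        m = vol.max()
        scaled[g] = vol / m if m > 0 else vol
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sections:
        first = np.take(scaled[genes[0]], s - 1, axis=axis)
        rgb = np.zeros((*first.shape, 3))
        for g, color in zip(genes, colors):
            sl = np.take(scaled[g], s - 1, axis=axis)
            rgb += sl[..., None] * np.asarray(color)
        rgb = np.clip(rgb, 0.0, 1.0)
        path = outdir / f"{prefix}_{plane}_{s:03d}.png"
        iio.imwrite(path, (rgb * 255).astype(np.uint8))
        paths.append(path)
    return paths
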