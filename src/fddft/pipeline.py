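"""End-to-end orchestration: normalize -> landscapes -> stabilize -> segment.

The inference path contains no randomness whatsoever; a fixed config and
input always produce bit-identical masks.  Per-slice stage telemetry
(gamma trace, iteration counts, component table) is collected into a JSON-
serializable run report so intermediate landscapes can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
import numpy as np
import yaml

from . import density_functionals as df
from . import io_preprocess as iop
from . import segmentation as seg
from . import stabilization as stab
from .errors import ConstantInputError, FddftError

__all__ = ["PipelineConfig", "SliceOutcome", "segment_image", "segment_volume", "run_segment"]

#: below this many foreground pixels a slice is treated as lesion-free
MIN_FOREGROUND_PIXELS = 16


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the segmentation pipeline.

    Defaults follow the method's printed constants: dimension-reduction
    factor 12.5 %, learning rate 0.5, similarity stop fraction 0.5.  The
    similarity source defaults to the Hamiltonian landscape for volumes
    (robust to multi-component slices) and the potential landscape for
    single 2-D images; ``similarity_source=None`` selects per input kind.
    """

    dim_factor: float = 0.125
    eta: float = 0.5
    stop_fraction: float = 0.5
    similarity_source: str | None = None
    edge_mode: str = "strict"
    edge_count_mode: str = "edges"
    connectivity_2d: int = 8
    connectivity_3d: int = 26
    max_iter: int = 1000
    sim_max_iter: int = 100
    size_ratio: float = 0.75
    denoise_min_size: int = 0

    def resolve_source(self, is_volume: bool) -> str:
        if self.similarity_source is not None:
            return self.similarity_source
        return "hdf" if is_volume else "pedf"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a plain-text key/value (YAML) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise FddftError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclasses.dataclass(frozen=True, eq=False)
class SliceOutcome:
    """Everything the pipeline derived from one slice."""

    result: seg.SegmentationResult
    landscape: np.ndarray  # stabilized LDF (zeros for skipped slices)
    report: dict


def _empty_outcome(shape: tuple[int, int], reason: str) -> SliceOutcome:
    empty = np.zeros(shape, dtype=bool)
    return SliceOutcome(
        result=seg.SegmentationResult(tumor_mask=empty, normal_mask=empty.copy()),
        landscape=np.zeros(shape, dtype=float),
        report={"skipped": reason, "n_components": 0, "n_selected": 0, "n_kept": 0},
    )


def segment_image(
    img: iop.ImageGrid, config: PipelineConfig = PipelineConfig(), is_volume_slice: bool = False
) -> SliceOutcome:
    """Run the full 2-D pipeline on one normalized image.

    Slices with (almost) no foreground, or whose landscapes are constant on
    the support, are returned as valid empty segmentations — in a volume
    most apical/basal slices contain no lesion and must not error out.
    """
    values = img.values
    foreground = values > 0
    if int(foreground.sum()) < MIN_FOREGROUND_PIXELS:
        return _empty_outcome(values.shape, "insufficient foreground")
    if config.denoise_min_size > 0:
        img = iop.remove_small_components(img, config.denoise_min_size)
        values = img.values
        foreground = values > 0

    t = df.kedf(img)
    u = df.pedf_fft(img, config.dim_factor)
    gamma0 = df.gamma_init(t, u)
    stabilized = stab.geometric_stability(
        t, u, eta=config.eta, gamma0=gamma0, max_iter=config.max_iter
    )
    threshold = stabilized.trace[-1]

    fmap = seg.aware_feature_map(stabilized.L_star, threshold, config.connectivity_2d)

    source = config.resolve_source(is_volume_slice)
    if source == "pedf":
        landscape = u
    elif source == "hdf":
        landscape = df.hdf(t, u, stabilized.gamma_star)
    elif source == "ldf":
        landscape = stabilized.L_star
    else:
        raise FddftError(f"unknown similarity source {source!r}")
    try:
        sim = stab.similarity_convergence(
            landscape,
            support=foreground,
            stop_fraction=config.stop_fraction,
            source=source,
            max_iter=config.sim_max_iter,
        )
    except ConstantInputError:
        return _empty_outcome(values.shape, "constant landscape on support")

    cands = seg.select_candidates(fmap, sim)
    brain_bbox = iop.compute_bounding_box(values, 0.0)
    kept = seg.filter_components(
        cands,
        img,
        mode=config.edge_mode,
        brain_bbox=brain_bbox,
        size_ratio=config.size_ratio,
        count_mode=config.edge_count_mode,
    )
    result = seg.split_image(img, kept)
    report = {
        "gamma_init": float(gamma0),
        "gamma_star": float(stabilized.gamma_star),
        "gamma_steps": stabilized.steps,
        "ldf_mean_trace": [round(v, 6) for v in stabilized.trace],
        "similarity_source": source,
        "similarity_iterations": sim.iterations,
        "n_components": len(fmap.components),
        "n_selected": len(cands),
        "n_kept": len(kept),
        "components": [
            {
                "label": c.label,
                "edge_count": c.edge_count,
                "voxel_count": c.voxel_count,
                "mean_energy": round(c.mean_energy, 6),
                "bbox": [c.bbox.row_min, c.bbox.row_max, c.bbox.col_min, c.bbox.col_max],
                "selected": c in cands,
                "kept": c in kept,
            }
            for c in fmap.components
        ],
    }
    return SliceOutcome(result=result, landscape=stabilized.L_star, report=report)


def segment_volume(
    vol: iop.VolumeStack, config: PipelineConfig = PipelineConfig()
) -> tuple[np.ndarray, dict]:
    """Per-slice segmentation plus 3-D assembly of the single best component.

    Returns the (H, W, D) binary lesion mask and the run report.
    """
    outcomes = [segment_image(s, config, is_volume_slice=True) for s in vol.slices]
    mask3d, comp_stats = seg.reconstruct_3d(
        [o.result for o in outcomes],
        [o.landscape for o in outcomes],
        connectivity=config.connectivity_3d,
    )
    report = {
        "config": config.to_dict(),
        "shape": list(vol.shape),
        "slices": [o.report for o in outcomes],
        "components_3d": comp_stats,
        "mask_voxels": int(mask3d.sum()),
    }
    return mask3d, report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_segment(
    input_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[np.ndarray, dict]:
    """Load a PNG/JPEG image or NIfTI volume, segment it, optionally persist.

    Writes, when ``out_dir`` is given: the binary mask (PNG for 2-D, NIfTI
    for 3-D) and ``report.json`` with the config echo, the input hash, and
    the per-stage telemetry needed to re-execute the run exactly.
    """
    input_path = Path(input_path)
    suffixes = "".join(input_path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        raw = iop.load_volume(input_path).to_array()
        # volume-wide min-max scaling preserves slice-to-slice relations;
        # the Fermi normalization downstream absorbs per-slice gain drift
        lo, hi = raw.min(), raw.max()
        norm = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
        mask, report = segment_volume(iop.VolumeStack.from_array(norm), config)
    else:
        img = iop.load_image(input_path)
        img = iop.normalize_intensity(img.values)
        outcome = segment_image(img, config, is_volume_slice=False)
        mask = outcome.result.tumor_mask
        report = {
            "config": config.to_dict(),
            "shape": list(img.shape),
            "slices": [outcome.report],
            "mask_pixels": int(mask.sum()),
        }
    report["input"] = {"path": str(input_path), "sha256": _sha256(input_path)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mask_name = "mask.nii.gz" if mask.ndim == 3 else "mask.png"
        iop.write_mask(mask, out_dir / mask_name)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return mask, report
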