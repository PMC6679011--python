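"""File formats, run configuration and the end-to-end pipeline.

Tomograms travel as 32-bit float multi-page TIFF stacks with a JSON
sidecar (``<stem>.json``) carrying voxel size and medium RI; ground-truth
masks, when present, as an 8-bit label TIFF with the label names in the
sidecar.  Traces and FAF curves are two/three-column CSV, fit results and
pipeline manifests JSON, configuration YAML.  Every stochastic stage is
driven by the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fcs_analysis, fcs_sim, phantom, tomo_quant
from .fcs_analysis import FAFCurve, FitResult
from .fcs_sim import DetectionVolume, IntensityTrace, SimSpec
from .phantom import CompartmentSpec, PhantomSpec, RITomogram
from .tomo_quant import RIBand

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


# --------------------------------------------------------------------------
# tomogram I/O
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_tomogram(tomo: RITomogram, path: str | Path) -> Path:
    """Write a tomogram as float32 TIFF plus JSON sidecar (and a label
    TIFF for ground-truth masks, if any).  Returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, tomo.values.astype(np.float32), photometric="minisblack")
    meta = {
        "voxel_size_um": list(tomo.voxel_size),
        "medium_ri": tomo.medium_ri,
    }
    if tomo.masks:
        labels = sorted(tomo.masks)
        label_map = np.zeros(tomo.values.shape, dtype=np.uint8)
        for i, name in enumerate(labels):
            label_map[tomo.masks[name]] = i + 1
        mask_path = path.with_name(path.stem + ".masks.tif")
        tifffile.imwrite(mask_path, label_map, photometric="minisblack")
        meta["mask_labels"] = labels
        meta["mask_file"] = mask_path.name
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_tomogram(path: str | Path) -> RITomogram:
    """Read a tomogram written by :func:`write_tomogram`.

    Rejects a missing sidecar (naming the expected file) and non-float
    voxel data (no silent casting).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"tomogram sidecar {sidecar} not found; expected JSON with "
            "voxel_size_um and medium_ri next to the TIFF"
        )
    meta = json.loads(sidecar.read_text())
    values = tifffile.imread(path)
    if values.dtype not in (np.float32, np.float64):
        raise TypeError(
            f"tomogram {path} has dtype {values.dtype}; expected float32/float64 RI values"
        )
    masks = None
    if "mask_file" in meta:
        mask_path = path.with_name(meta["mask_file"])
        if mask_path.exists():
            label_map = tifffile.imread(mask_path)
            masks = {
                name: label_map == i + 1 for i, name in enumerate(meta["mask_labels"])
            }
    return RITomogram(
        values=values,
        voxel_size=tuple(meta["voxel_size_um"]),
        medium_ri=float(meta["medium_ri"]),
        masks=masks,
    )


# --------------------------------------------------------------------------
# trace / curve / fit I/O
# --------------------------------------------------------------------------


def write_trace(trace: IntensityTrace, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(trace.counts.size) * trace.dt
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> IntensityTrace:
    df = pd.read_csv(path)
    if not {"time_s", "counts"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, counts")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: trace too short")
    dt = float(np.median(np.diff(t)))
    return IntensityTrace(counts=df["counts"].to_numpy(), dt=dt)


def write_faf(curve: FAFCurve, path: str | Path) -> Path:
    path = Path(path)
    data = {"lag_s": curve.lags, "g": curve.g}
    if curve.sd is not None:
        data["sd"] = curve.sd
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_faf(path: str | Path) -> FAFCurve:
    df = pd.read_csv(path)
    if not {"lag_s", "g"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns lag_s, g[, sd]")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return FAFCurve(lags=df["lag_s"].to_numpy(), g=df["g"].to_numpy(), sd=sd)


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "n_components": fit.n_components,
        "N": fit.N,
        "fractions": list(fit.fractions),
        "tau_d_s": list(fit.tau_d),
        "s": fit.s,
        "triplet": list(fit.triplet) if fit.triplet else None,
        "D_um2s": list(fit.D) if fit.D else None,
        "rss": fit.rss,
        "red_chi2": fit.red_chi2,
        "n_points": fit.n_points,
    }


def write_fit_result(fit: FitResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fit_result_to_dict(fit), indent=2))
    return path


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------


def bands_from_list(items: Sequence[dict]) -> Tuple[RIBand, ...]:
    return tuple(
        RIBand(label=d["label"], lo=float(d["lo"]), hi=float(d["hi"]), color=d.get("color"))
        for d in items
    )


def read_bands_yaml(path: str | Path) -> Tuple[RIBand, ...]:
    """Band set YAML: a list of ``{label, lo, hi[, color]}`` mappings."""
    items = yaml.safe_load(Path(path).read_text())
    if not isinstance(items, list) or not items:
        raise ValueError(f"{path}: expected a non-empty list of bands")
    return bands_from_list(items)


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    comps = []
    for c in d.get("compartments", []):
        if "radius" in c:
            comps.append(
                CompartmentSpec.sphere(c["label"], tuple(c["center"]), float(c["radius"]), float(c["ri"]))
            )
        else:
            comps.append(
                CompartmentSpec(
                    label=c["label"],
                    center=tuple(c["center"]),
                    semi_axes=tuple(c["semi_axes"]),
                    ri=float(c["ri"]),
                )
            )
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        voxel_size=tuple(d.get("voxel_size", phantom.DEFAULT_VOXEL_SIZE)),
        medium_ri=float(d.get("medium_ri", phantom.DEFAULT_MEDIUM_RI)),
        compartments=tuple(comps),
        noise_sd=float(d.get("noise_sd", 0.0)),
        seed=int(d.get("seed", 0)),
    )


def sim_spec_from_dict(d: dict, seed: Optional[int] = None) -> Tuple[SimSpec, DetectionVolume]:
    volume = DetectionVolume(w=float(d.get("w", 0.2)), s=float(d.get("s", 5.0)))
    trip = d.get("triplet")
    spec = SimSpec(
        components=tuple((float(c["D"]), float(c["fraction"])) for c in d.get(
            "components", [{"D": 25.0, "fraction": 1.0}]
        )),
        mean_particles_in_volume=float(d.get("mean_particles_in_volume", 2.0)),
        box=float(d.get("box", 3.0)),
        duration=float(d.get("duration", 10.0)),
        dt=float(d.get("dt", 2e-6)),
        brightness=float(d.get("brightness", 1.0)),
        background=float(d.get("background", 0.0)),
        triplet=(float(trip["T"]), float(trip["tau_T"])) if trip else None,
        shot_noise=bool(d.get("shot_noise", False)),
        seed=int(seed if seed is not None else d.get("seed", 0)),
    )
    return spec, volume


@dataclass
class RunConfig:
    """Full configuration of an end-to-end run; round-trips via YAML."""

    seed: int = 0
    phantom_noise_sd: float = 0.0
    bands: List[dict] = field(
        default_factory=lambda: [
            {"label": "nucleolus", "lo": 1.356, "hi": 1.370},
        ]
    )
    min_diameter: float = 2.0
    fcs: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "components": [{"D": 25.0, "fraction": 1.0}],
            "mean_particles_in_volume": 2.0,
            "n_reps": 3,
            "rep_duration": 0.2,
            "dt": 2e-6,
            "w": 0.2,
            "s": 5.0,
        }
    )
    timelapse: dict = field(
        default_factory=lambda: {
            "enabled": False,
            "nucleolus_ri": [1.364, 1.376],
            "cytoplasm_ri": [1.348, 1.354],
            "interval_min": 40.0,
        }
    )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config() -> RunConfig:
    """The bundled demonstration config: five-nucleoli phantom,
    short single-component FCS run and an ATP-depletion-style
    two-frame time lapse."""
    cfg = RunConfig()
    cfg.timelapse["enabled"] = True
    return cfg


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------


def _timelapse_phantom(nuc_ri: float, cyt_ri: float, seed: int) -> RITomogram:
    """Small single-nucleolus cell used by the time-lapse stage."""
    spec = PhantomSpec(
        grid_shape=(24, 72, 72),
        voxel_size=phantom.DEFAULT_VOXEL_SIZE,
        compartments=(
            CompartmentSpec("cytoplasm", (4.2, 3.9, 3.9), (2.8, 3.4, 3.4), cyt_ri),
            CompartmentSpec.sphere("nucleolus", (4.2, 3.9, 3.9), 1.4, nuc_ri),
        ),
        seed=seed,
    )
    return phantom.generate_phantom(spec)


_TIMELAPSE_BANDS = (
    RIBand("cytoplasm", 1.340, 1.358),
    RIBand("nucleolus", 1.358, 1.382),
)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run phantom generation, segmentation, FCS simulation + fitting and
    (optionally) the time-lapse analysis; write all artifacts under
    ``out_dir`` and return the manifest.  Deterministic for a fixed seed;
    any stage failure raises :class:`PipelineError` naming the stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": _library_versions(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    stage = "phantom"
    try:
        cell = phantom.five_nucleoli_cell(seed=config.seed, noise_sd=config.phantom_noise_sd)
        cell_path = write_tomogram(cell, out_dir / "cell.tif")
        manifest["stages"][stage] = {"tomogram": cell_path.name}
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "segment"
    try:
        bands = bands_from_list(config.bands)
        seg = tomo_quant.segment_by_bands(cell, bands)
        nucleoli = tomo_quant.detect_nucleoli(seg, min_diameter=config.min_diameter)
        comp_df = pd.DataFrame(
            [
                {
                    "band": c.band_label,
                    "component_id": c.component_id,
                    "voxel_count": c.voxel_count,
                    "volume_um3": c.volume_um3,
                    "equivalent_diameter_um": c.equivalent_diameter_um,
                }
                for c in seg.components
            ]
        )
        comp_df.to_csv(out_dir / "components.csv", index=False)
        manifest["stages"][stage] = {
            "components_csv": "components.csv",
            "n_nucleoli": len(nucleoli),
            "nucleolus_volumes_um3": [c.volume_um3 for c in nucleoli],
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.fcs.get("enabled", False):
        stage = "fcs"
        try:
            fcs_cfg = dict(config.fcs)
            n_reps = int(fcs_cfg.pop("n_reps", 3))
            rep_duration = float(fcs_cfg.pop("rep_duration", 0.2))
            fcs_cfg.pop("enabled", None)
            spec, volume = sim_spec_from_dict(fcs_cfg, seed=config.seed)
            traces = fcs_sim.replicate_traces(spec, volume, n_reps=n_reps, rep_duration=rep_duration)
            curves = [fcs_analysis.autocorrelate(t, scheme="multi_tau") for t in traces]
            avg = fcs_analysis.average_fafs(curves)
            write_faf(avg, out_dir / "faf_mean.csv")
            fit = fcs_analysis.fit_faf(
                avg, n_components=1, s_policy=("fixed", volume.s), w=volume.w
            )
            write_fit_result(fit, out_dir / "fit.json")
            manifest["stages"][stage] = {
                "faf_csv": "faf_mean.csv",
                "fit_json": "fit.json",
                "D_um2s": fit.D[0],
                "N": fit.N,
            }
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if config.timelapse.get("enabled", False):
        stage = "timelapse"
        try:
            tl = config.timelapse
            nuc0, nuc1 = tl["nucleolus_ri"]
            cyt0, cyt1 = tl["cytoplasm_ri"]
            frames = [
                _timelapse_phantom(nuc0, cyt0, config.seed),
                _timelapse_phantom(nuc1, cyt1, config.seed + 1),
            ]
            table, summary = tomo_quant.timelapse_summary(
                frames, _TIMELAPSE_BANDS, interval_min=float(tl.get("interval_min", 40.0))
            )
            table.to_csv(out_dir / "timelapse.csv", index=False)
            manifest["stages"][stage] = {"timelapse_csv": "timelapse.csv", **summary}
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _library_versions() -> Dict[str, str]:
    import lmfit
    import numba
    import scipy

    from . import __version__

    return {
        "nucleophys": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "lmfit": lmfit.__version__,
        "numba": numba.__version__,
        "tifffile": tifffile.__version__,
    }
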