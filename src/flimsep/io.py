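"""File formats, run configuration and the pipeline-selection decision tree.

TCSPC stacks are stored in a chunked HDF5 container with complete timing
metadata (bin width, repetition period, wavelengths, pixel size) so a
write/read round trip is bit-identical; intensity and channel images are
exported as multi-page TIFF with physical pixel size tagged; every run emits
a reproducibility manifest (config + seed + package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import __version__
from .synthetic_scene import OpticsConfig, TCSPCImage

__all__ = [
    "ContainerError",
    "RunConfig",
    "PIPELINES",
    "read_tcspc_container",
    "write_tcspc_container",
    "write_outputs",
    "select_pipeline",
]

logger = logging.getLogger("flimsep")

PIPELINES = (
    "confocal_intensity",
    "coarse_tau",
    "flim_fit",
    "flim_phasor",
    "phasor_separation",
    "tau_sted",
)

_REQUIRED_ATTRS = (
    "repetition_period",
    "n_time_bins",
    "excitation_wavelength",
    "emission_wavelength",
    "numerical_aperture",
    "irf_fwhm",
    "irf_offset",
    "pixel_size",
)


class ContainerError(ValueError):
    """Raised for missing metadata or corrupt TCSPC containers."""


def write_tcspc_container(image: TCSPCImage, path: str | os.PathLike) -> None:
    """Write a TCSPC stack plus complete timing metadata to a chunked HDF5
    container."""
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "counts",
            data=image.counts,
            chunks=True,
            compression="gzip",
            compression_opts=1,
        )
        for name in _REQUIRED_ATTRS:
            f.attrs[name] = getattr(image.optics, name)
        f.attrs["channel_name"] = image.channel_name
        f.attrs["format"] = "flimsep-tcspc-v1"


def read_tcspc_container(path: str | os.PathLike) -> TCSPCImage:
    """Read a TCSPC container; raises :class:`ContainerError` naming the
    missing metadata field or reporting corruption (never partial data)."""
    try:
        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise ContainerError("counts dataset missing")
            for name in _REQUIRED_ATTRS:
                if name not in f.attrs:
                    raise ContainerError(f"{name} missing")
            kwargs = {name: f.attrs[name] for name in _REQUIRED_ATTRS}
            kwargs["n_time_bins"] = int(kwargs["n_time_bins"])
            optics = OpticsConfig(**{k: v for k, v in kwargs.items()})
            counts = f["counts"][...]
            channel = str(f.attrs.get("channel_name", ""))
    except OSError as exc:
        raise ContainerError(f"corrupt or unreadable container: {exc}") from exc
    return TCSPCImage(counts, optics, channel)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of one CLI run.

    ``params`` holds per-module parameter blocks (e.g. ``simulate``,
    ``tau_sted``); all range checks happen in :meth:`validate` before any
    computation or file is written.
    """

    pipeline: str
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)
    input_files: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"unknown pipeline {self.pipeline!r}; choose from {PIPELINES}"
            )
        for p in self.input_files:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file does not exist: {p}")
        ts = self.params.get("tau_sted", {})
        if not 0 <= ts.get("strength", 0) <= 200:
            raise ValueError("tau_sted.strength must be in [0, 200]")
        if not 0 <= ts.get("denoise", 0) <= 100:
            raise ValueError("tau_sted.denoise must be in [0, 100]")
        sim = self.params.get("simulate", {})
        if sim.get("photon_budget", 1) <= 0:
            raise ValueError("simulate.photon_budget must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        cfg.validate()
        return cfg


def write_outputs(results: dict, config: RunConfig) -> list[Path]:
    """Persist pipeline results.

    ``results`` maps names to 2-D images (written as 32-bit TIFF with pixel
    size tagged), lists of 2-D images (multi-page TIFF, one page per
    channel/band), or JSON-serializable dicts. A reproducibility manifest
    (config + seed + package version) is always written. The output
    directory is checked upfront.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory not writable: {out_dir}")
    written: list[Path] = []
    pixel_size_nm = results.get("pixel_size_nm")
    res_kwargs = {}
    if pixel_size_nm:
        per_cm = 1e7 / float(pixel_size_nm)
        res_kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": "CENTIMETER"}
    for name, value in results.items():
        if name == "pixel_size_nm":
            continue
        if isinstance(value, np.ndarray) and value.ndim == 2:
            path = out_dir / f"{name}.tif"
            meta = {"unit": "ns"} if "lifetime" in name else {}
            tifffile.imwrite(
                path, value.astype(np.float32), metadata=meta, **res_kwargs
            )
            written.append(path)
        elif isinstance(value, (list, tuple)) and value and isinstance(
            value[0], np.ndarray
        ):
            path = out_dir / f"{name}.tif"
            stack = np.stack([np.asarray(v, dtype=np.float32) for v in value])
            tifffile.imwrite(path, stack, **res_kwargs)
            written.append(path)
        else:
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(value, indent=2, default=_jsonify))
            written.append(path)
    manifest = {
        "package": "flimsep",
        "version": __version__,
        "seed": int(config.seed),
        "pipeline": config.pipeline,
        "config": dataclasses.asdict(config),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=_jsonify))
    written.append(mpath)
    logger.info("wrote %d output files to %s", len(written), out_dir)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline selection (decision tree)
# ---------------------------------------------------------------------------


def select_pipeline(
    n_dyes: int,
    spectral_overlap: bool,
    lifetime_gap: float,
    sted_compatible: bool,
    n_components: int = 1,
    close_threshold: float = 1.0,
    prefer: str | None = None,
) -> str:
    """Decision tree for choosing the imaging/processing strategy.

    * one dye, one lifetime component: fitting (or phasor) FLIM -> flim_fit
    * one dye, multiple components: phasor analysis only -> flim_phasor
    * two dyes with distant lifetimes (gap >= ``close_threshold`` ns):
      fitting or phasor -> flim_fit
    * two dyes with close lifetimes (gap of a few hundred ps): only phasor
      ROI separation resolves them -> phasor_separation
    * three or more dyes: spectral splitting combined with coarse (distant
      lifetimes) or fine (close lifetimes) tau separation -> coarse_tau /
      phasor_separation
    * an explicitly STED-compatible request routes to tau_sted.

    ``prefer`` may request a pipeline; contradictory requests (e.g. coarse
    separation with sub-threshold lifetime gaps) raise with guidance.
    """
    if n_dyes < 1:
        raise ValueError("n_dyes must be >= 1")
    if lifetime_gap < 0:
        raise ValueError("lifetime_gap must be >= 0")
    close = lifetime_gap < close_threshold
    if prefer == "coarse_tau" and close:
        raise ValueError(
            "coarse tau separation cannot resolve lifetimes closer than "
            f"{close_threshold} ns; use phasor_separation (fine tau separation)"
        )
    if sted_compatible:
        return "tau_sted"
    if n_dyes == 1:
        return "flim_fit" if n_components == 1 else "flim_phasor"
    if n_dyes == 2:
        return "phasor_separation" if close else "flim_fit"
    # three or more dyes: spectral separation combined with tau separation
    return "phasor_separation" if close else "coarse_tau"
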