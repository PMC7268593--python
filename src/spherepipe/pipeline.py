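"""The three-stage batch workflow: convert -> roi -> sphere.

``convert`` reconstructs (or passes through) all frames of an input
series and writes the sensor phase/amplitude TIF plus the HDF5 store;
``extract_roi`` applies sensor background correction, detects objects and
writes background-corrected ROI data; ``analyze_sphere`` fits the
configured sphere model per ROI and exports the statistics TSV and a fit
visualisation TIF.

All outputs go into a results directory ``<input>_dm`` beside the input,
which also holds the configuration file ``pipeline.cfg``.  Each stage is
cached: its relevant configuration sections plus the dataset content hash
key the cache, so re-running with an unchanged configuration reuses
outputs and editing an unrelated section does not invalidate a stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import tifffile

from . import bg, fit, holo, roi
from .config import ConfigDoc, parse_config, serialize_config
from .io_series import (ResultsStore, dataset_identifier, read_image_series,
                        read_qpi_stack, write_qpi_stack)
from .models import RytovSCCoeffs

__all__ = ["PipelineState", "cmd_convert", "cmd_extract_roi",
           "cmd_analyze_sphere"]

logger = logging.getLogger(__name__)

# configuration sections each stage depends on (cache granularity)
_STAGE_SECTIONS = {
    "convert": ("meta", "holo"),
    "roi": ("roi", "bg.sensor", "bg.roi"),
    "sphere": ("sphere",),
}


class PipelineState:
    """Paths, configuration and cache bookkeeping for one input dataset."""

    def __init__(self, input_path, config: ConfigDoc | None = None):
        self.input_path = os.fspath(input_path)
        if not os.path.exists(self.input_path):
            raise ValueError(f"input not found: {self.input_path}")
        self.results_dir = self.input_path.rstrip("/\\") + "_dm"
        os.makedirs(self.results_dir, exist_ok=True)
        self.config_path = os.path.join(self.results_dir, "pipeline.cfg")
        if config is None:
            if os.path.exists(self.config_path):
                with open(self.config_path) as fh:
                    config = parse_config(fh.read())
            else:
                config = ConfigDoc()
        self.config = config
        self.dataset_id = dataset_identifier(self.input_path)
        self._log_handler = None

    # -- paths -------------------------------------------------------------
    def path(self, name: str) -> str:
        return os.path.join(self.results_dir, name)

    @property
    def sensor_tif(self) -> str:
        return self.path("sensor_data.tif")

    @property
    def store_path(self) -> str:
        return self.path("sensor_data.h5")

    @property
    def roi_tif(self) -> str:
        return self.path("roi_data.tif")

    def sphere_basename(self) -> str:
        cfg = self.config["sphere"]
        return f"sphere_{cfg['method']}_{cfg['model']}"

    # -- config ------------------------------------------------------------
    def save_config(self) -> None:
        with open(self.config_path, "w") as fh:
            fh.write(serialize_config(self.config))

    # -- caching -----------------------------------------------------------
    def _stage_hash(self, stage: str) -> str:
        h = hashlib.sha256(self.dataset_id.encode())
        for sec in _STAGE_SECTIONS[stage]:
            blob = json.dumps(
                {k: repr(v) for k, v in self.config[sec].items()},
                sort_keys=True)
            h.update(blob.encode())
        if stage != "convert":  # downstream stages build on upstream output
            prev = {"roi": "convert", "sphere": "roi"}[stage]
            h.update(self._stage_hash(prev).encode())
        return h.hexdigest()

    def _cache_file(self, stage: str) -> str:
        return self.path(f".stage_{stage}")

    def stage_cached(self, stage: str, outputs: list[str]) -> bool:
        cf = self._cache_file(stage)
        if not os.path.exists(cf):
            return False
        with open(cf) as fh:
            if fh.read().strip() != self._stage_hash(stage):
                return False
        return all(os.path.exists(p) for p in outputs)

    def mark_stage(self, stage: str) -> None:
        with open(self._cache_file(stage), "w") as fh:
            fh.write(self._stage_hash(stage))

    def log(self, stage: str, msg: str, *args) -> None:
        logger.info(f"[{self.dataset_id}:{stage}] {msg}", *args)


def _setup_logging(state: PipelineState) -> None:
    if state._log_handler is None:
        handler = logging.FileHandler(state.path("pipeline.log"))
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logging.getLogger("spherepipe").addHandler(handler)
        logging.getLogger("spherepipe").setLevel(logging.INFO)
        state._log_handler = handler


def _bg_spec(cfg_section) -> bg.BackgroundSpec:
    b = cfg_section["border_px"]
    return bg.BackgroundSpec(
        profile=cfg_section["profile"],
        border_px=None if b is None else int(b),
        binary_threshold=cfg_section["binary_threshold"],
        offset_mode=cfg_section["offset_mode"])


# ---------------------------------------------------------------------------
# stage 1: convert
# ---------------------------------------------------------------------------

def cmd_convert(input_path, config: ConfigDoc | None = None,
                overrides: dict | None = None) -> PipelineState:
    """Reconstruct all holograms (or pass through phase inputs) and write
    the sensor TIF + HDF5 store + configuration file.

    ``overrides`` maps ``"section.key"`` to values applied on top of the
    stored/passed configuration.  Wavelength, pixel size and medium index
    must be present (the command-line layer may prompt for them).
    """
    state = PipelineState(input_path, config)
    for dotted, value in (overrides or {}).items():
        sec, key = dotted.rsplit(".", 1)
        state.config.set(sec, key, value)
    _setup_logging(state)
    state.config.require_meta()
    state.save_config()

    outputs = [state.sensor_tif]
    if state.config["output"]["hdf5"]:
        outputs.append(state.store_path)
    if state.stage_cached("convert", outputs):
        state.log("convert", "cached, skipping")
        return state

    meta = state.config["meta"]
    hcfg = state.config["holo"]
    wavelength = meta["wavelength_nm"] * 1e-9
    pixel_size = meta["pixel_size_um"] * 1e-6

    images = read_image_series(state.input_path, meta["time_interval_s"])
    state.log("convert", "loaded %d frames", len(images))

    # decide hologram vs phase input from the first frame's spectrum
    try:
        holo.detect_sideband(images[0])
        is_hologram = True
    except ValueError:
        is_hologram = False
        state.log("convert", "no off-axis carrier: treating input as phase")

    filt = holo.FilterSpec(name=hcfg["filter_name"],
                           size_rel=hcfg["filter_size_rel"])
    qpis = []
    for im in images:
        ident = f"{state.dataset_id}_{im.index}"
        if is_hologram:
            if hcfg["sideband"] == "auto":
                carrier = holo.detect_sideband(im)
            else:
                kx, ky = hcfg["sideband"]
                carrier = holo.CarrierSpec(kx=kx, ky=ky, mode="fixed")
            qpi = holo.reconstruct_hologram(
                im, carrier, filt, wavelength=wavelength,
                pixel_size=pixel_size, medium_index=meta["medium_index"],
                identifier=ident, invert_phase=hcfg["invert_phase"])
        else:
            qpi = holo.QPImage(
                phase=im.pixels, amplitude=np.ones_like(im.pixels),
                wavelength=wavelength, pixel_size=pixel_size,
                medium_index=meta["medium_index"], time=im.time,
                identifier=ident)
        qpis.append(qpi)

    write_qpi_stack(qpis, state.sensor_tif)
    if state.config["output"]["hdf5"]:
        with ResultsStore(state.store_path) as store:
            for i, qpi in enumerate(qpis, start=1):
                store.write_image(i, qpi)
    state.mark_stage("convert")
    state.log("convert", "wrote %s", state.sensor_tif)
    return state


# ---------------------------------------------------------------------------
# stage 2: extract ROIs
# ---------------------------------------------------------------------------

def cmd_extract_roi(input_path, config: ConfigDoc | None = None,
                    overrides: dict | None = None) -> PipelineState:
    """Detect objects per the [roi] configuration, honour the ignore
    list, background-correct each ROI and write the ROI TIF + store."""
    state = cmd_convert(input_path, config, overrides)
    outputs = [state.roi_tif, state.path("rois.json")]
    if state.stage_cached("roi", outputs):
        state.log("roi", "cached, skipping")
        return state

    meta = state.config["meta"]
    rcfg = state.config["roi"]
    size_px = rcfg["size_um"] / meta["pixel_size_um"]
    sensor_spec = _bg_spec(state.config["bg.sensor"])
    roi_spec = _bg_spec(state.config["bg.roi"])

    qpis = read_qpi_stack(state.sensor_tif)
    all_rois = []
    roi_qpis = []
    for i, qpi in enumerate(qpis, start=1):
        corrected = bg.correct_qpi(qpi, sensor_spec)
        found = roi.find_rois(corrected.phase, size_px=size_px,
                              variation=rcfg["size_variation"],
                              pad_px=rcfg["pad_border_px"],
                              threshold_method=rcfg["threshold"],
                              image_index=i, dataset=state.dataset_id)
        kept = roi.filter_ignored(found, rcfg["ignore data"])
        state.log("roi", "image %d: %d ROIs (%d after ignore list)",
                  i, len(found), len(kept))
        for rr in kept:
            roi_qpis.append(roi.extract_roi(corrected, rr, roi_spec))
            all_rois.append(rr)

    with open(state.path("rois.json"), "w") as fh:
        json.dump([{"image": rr.image_index, "roi": rr.roi_index,
                    "r0": rr.r0, "r1": rr.r1, "c0": rr.c0, "c1": rr.c1}
                   for rr in all_rois], fh, indent=1)
    if roi_qpis:
        write_qpi_stack(roi_qpis, state.roi_tif)
    else:
        # keep downstream cache logic simple: write an empty marker
        with open(state.roi_tif, "wb"):
            pass
        state.log("roi", "no ROIs found")
    if state.config["output"]["hdf5"]:
        with ResultsStore(state.store_path) as store:
            for rr, rq in zip(all_rois, roi_qpis):
                store.write_roi(rr.image_index, rr.roi_index, rq.phase)
    state.mark_stage("roi")
    return state


# ---------------------------------------------------------------------------
# stage 3: sphere analysis
# ---------------------------------------------------------------------------

def cmd_analyze_sphere(input_path, config: ConfigDoc | None = None,
                       overrides: dict | None = None) -> PipelineState:
    """Fit the configured sphere model to every ROI and export the
    statistics TSV, the fit visualisation TIF and fitted phases."""
    state = cmd_extract_roi(input_path, config, overrides)
    scfg = state.config["sphere"]
    tsv_path = state.path(state.sphere_basename() + "_statistics.tsv")
    if state.stage_cached("sphere", [tsv_path]):
        state.log("sphere", "cached, skipping")
        return state

    with open(state.path("rois.json")) as fh:
        roi_meta = json.load(fh)
    roi_qpis = (read_qpi_stack(state.roi_tif)
                if os.path.getsize(state.roi_tif) else [])
    coeffs = (RytovSCCoeffs(*scfg["rytov_sc_coeffs"])
              if scfg["rytov_sc_coeffs"] else None)
    alpha = scfg["refraction_increment_ml_g"]

    results = []
    pages = []
    from .models import edge_estimate
    for rq, rm in zip(roi_qpis, roi_meta):
        try:
            init = edge_estimate(rq)
        except ValueError as err:
            state.log("sphere", "%s: %s", rq.identifier, err)
            continue
        if scfg["method"] == "edge":
            model = fit.SphereModel(rq, model="projection", init=init)
            res = fit.SphereFitResults(
                params=init, model="projection",
                cost=float(np.sum((model.forward(init) - rq.phase) ** 2)),
                n_iterations=0, converged=True,
                residual_image=model.forward(init) - rq.phase,
                medium_index=rq.medium_index, wavelength=rq.wavelength,
                pixel_size=rq.pixel_size, identifier=rq.identifier,
                time=rq.time, model_phase=model.forward(init))
        else:
            res = fit.fit_sphere_image(
                rq, model=scfg["model"], init=init, sc_coeffs=coeffs,
                max_evals=scfg["max_evals"], tol=scfg["tol"])
        state.log("sphere", "%s: n=%.5f r=%.3fum converged=%s",
                  rq.identifier, res.n, res.r * 1e6, res.converged)
        results.append(res)
        if state.config["output"]["fit_tif"]:
            pages.extend([rq.phase, res.model_phase, res.residual_image,
                          rq.amplitude, np.ones_like(rq.amplitude)])
        if state.config["output"]["hdf5"]:
            with ResultsStore(state.store_path) as store:
                store.write_roi(rm["image"], rm["roi"], rq.phase,
                                phase_fit=res.model_phase,
                                attrs={"n": res.n, "r_m": res.r,
                                       "model": res.model,
                                       "converged": res.converged})

    if not results:
        state.log("sphere", "zero ROIs: writing empty statistics table")
    df, tsv = fit.summarize(results, alpha=alpha, method=scfg["method"])
    with open(tsv_path, "w") as fh:
        fh.write(tsv)
    if pages and state.config["output"]["fit_tif"]:
        img_path = state.path(state.sphere_basename() + "_images.tif")
        with tifffile.TiffWriter(img_path) as tw:
            for page in pages:
                tw.write(np.asarray(page, np.float32), contiguous=False)
    state.mark_stage("sphere")
    state.log("sphere", "wrote %s (%d rows)", tsv_path, len(df))
    return state
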