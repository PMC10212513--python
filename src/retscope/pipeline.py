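"""Orchestration: configuration, logging, commands and the end-to-end
recovery experiments.

The recovery experiments are the package's validation surface.  Each one
generates ground-truthed synthetic data, runs the full analysis chain on
it, and reports estimates next to the generator truth:

- ``masked_ret_experiment``: the simulated-RET control -- a known
  fraction of mitochondria is erased to background in the post-challenge
  frame of a responsive population and the excess-pixel-count estimator
  must find it.
- ``monotonicity_experiment``: the same over a ladder of masked
  fractions; the estimate must be nondecreasing in the truth.
- ``direction_recovery_experiment``: per-mitochondrion three-way
  direction calls on replicate synthetic fields.
- ``plate_experiment``: calibration-slope, rate and 4PL/IC50 recovery on
  a synthetic plate.

Everything is deterministic given (config, seed); stochastic stages draw
from named child streams of the root seed.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bulkassays, imgproc, polarization, redoxstats, synthgen
from .imgproc import FrameStack
from .synthgen import PlateTruth, SceneConfig, build_scene, child_rng

logger = logging.getLogger("retscope.pipeline")


# --------------------------------------------------------------------------
# logging
# --------------------------------------------------------------------------

class JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        payload = {
            "t": self.formatTime(record, "%Y-%m-%dT%H:%M:%S"),
            "level": record.levelname,
            "logger": record.name,
            "msg": record.getMessage(),
        }
        return json.dumps(payload)


def configure_logging(verbosity: int = 0) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(JsonLineFormatter())
    root = logging.getLogger("retscope")
    root.handlers[:] = [handler]
    root.setLevel(logging.DEBUG if verbosity > 0 else logging.INFO)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_SCENE_KEYS = {f.name for f in dataclasses.fields(SceneConfig)}
_IMGPROC_KEYS = {
    "background_percentile",
    "background_dilation_px",
    "wiener_kernel_px",
    "register",
    "grid_spacing_px",
    "levels",
    "qc_threshold",
    "log_sigma",
    "min_area",
    "max_area",
    "min_separation",
}
_POLARIZATION_KEYS = {"gm_split_mv", "g3p_split_mv", "g3p_floor_mv"}
_REDOXSTATS_KEYS = {"bin_width", "eps", "tail_sigma_multiple", "direction_se_multiple"}
_BULK_KEYS = {"cycle_window", "subtract_residual"}


@dataclass
class RunConfig:
    """Fully serializable run configuration; a copy is written next to
    every run's outputs together with its hash."""

    seed: int = 0
    outdir: str = "retscope_out"
    verbosity: int = 0
    scene: dict = field(default_factory=dict)
    plate: dict = field(default_factory=dict)
    imgproc: dict = field(default_factory=dict)
    polarization: dict = field(default_factory=dict)
    redoxstats: dict = field(default_factory=dict)
    bulkassays: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block, allowed in (
            ("scene", _SCENE_KEYS),
            ("imgproc", _IMGPROC_KEYS),
            ("polarization", _POLARIZATION_KEYS),
            ("redoxstats", _REDOXSTATS_KEYS),
            ("bulkassays", _BULK_KEYS),
        ):
            unknown = set(getattr(self, block)) - allowed
            if unknown:
                raise ValueError(
                    f"unknown key(s) in config block {block!r}: {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf8")
        return hashlib.sha256(blob).hexdigest()[:16]

    def scene_config(self, **overrides) -> SceneConfig:
        params = dict(self.scene)
        params.update(overrides)
        if "class_fractions" in params:
            params["class_fractions"] = dict(params["class_fractions"])
        if "image_shape" in params:
            params["image_shape"] = tuple(params["image_shape"])
        return SceneConfig(**params)


# --------------------------------------------------------------------------
# cell-arm building blocks
# --------------------------------------------------------------------------

def render_cell_pair(
    cfg: SceneConfig,
    seed: int,
    challenged: bool,
    masked_fraction: float = 0.0,
) -> FrameStack:
    """One synthetic cell: a before/after NAD(P)H frame pair.

    ``challenged`` applies each mitochondrion's class response to the
    after frame (a mock pair re-renders the same truth with independent
    noise).  ``masked_fraction`` erases that fraction of mitochondria to
    background in the after frame (simulated RET).
    """
    scene = build_scene(replace(cfg, seed=seed))
    stack = synthgen.render_frames(
        scene,
        ("before", "after"),
        channel="nadph",
        challenged={"after"} if challenged else (),
    )
    if cfg.motility_amplitude > 0:
        stack = synthgen.apply_motility(
            stack, cfg.motility_amplitude, cfg.motility_correlation_length, seed
        )
    if masked_fraction > 0:
        stack = synthgen.mask_fraction(stack, masked_fraction, seed)
    return stack


def cell_logfold_histogram(
    stack: FrameStack,
    imgproc_params: Mapping | None = None,
    redox_params: Mapping | None = None,
    after_scale: float = 1.0,
    source: str = "treated",
    cell_id=None,
) -> redoxstats.LogFoldHistogram:
    """Condition a cell frame pair and histogram its pixel log2-folds.

    Background subtraction -> adaptive Wiener denoising -> optional
    deformable registration of the after frame onto the before frame ->
    Otsu union mitochondrial mask -> pixelwise log2-fold histogram.
    ``after_scale`` is the common linear rescale factor (mock-mode-zero
    normalization) applied to the after frame.
    """
    ip = dict(imgproc_params or {})
    rp = dict(redox_params or {})
    stack = imgproc.subtract_background(
        stack,
        percentile=ip.get("background_percentile", 50.0),
        dilation_px=ip.get("background_dilation_px", 3),
    )
    before = imgproc.wiener_denoise(
        stack.frames[0], ip.get("wiener_kernel_px", 3)
    )
    after = imgproc.wiener_denoise(stack.frames[-1], ip.get("wiener_kernel_px", 3))
    if ip.get("register", False):
        reg = imgproc.register_deformable(
            before,
            after,
            grid_spacing_px=ip.get("grid_spacing_px", 16.0),
            levels=ip.get("levels", 3),
            threshold=ip.get("qc_threshold", 0.6),
        )
        if not imgproc.qc_registration(reg, ip.get("qc_threshold", 0.6)):
            raise RuntimeError("registration rejected by QC")
        after = reg.warped_frame
    mask = imgproc.otsu_union_mask(before, after)
    return redoxstats.pixel_log2fold(
        before,
        after * after_scale,
        mask,
        eps=rp.get("eps", redoxstats.DEFAULT_EPSILON_AFU),
        bin_width=rp.get("bin_width", redoxstats.DEFAULT_BIN_WIDTH),
        source=source,
        cell_id=cell_id,
    )


def mock_calibration(
    cfg: SceneConfig,
    seed: int,
    n_mock: int,
    imgproc_params: Mapping | None = None,
    redox_params: Mapping | None = None,
) -> redoxstats.NullFit:
    """Fit the null (mock) log2-fold distribution over pooled mock cells."""
    values = []
    for i in range(n_mock):
        cell_seed = int(child_rng(seed, f"mock/{i}").integers(2**31 - 1))
        stack = render_cell_pair(cfg, cell_seed, challenged=False)
        hist = cell_logfold_histogram(
            stack, imgproc_params, redox_params, source="mock", cell_id=i
        )
        values.append(hist.values)
    pooled = redoxstats.LogFoldHistogram.from_values(
        np.concatenate(values),
        bin_width=(redox_params or {}).get("bin_width", redoxstats.DEFAULT_BIN_WIDTH),
        source="mock",
    )
    return redoxstats.fit_null(pooled)


# --------------------------------------------------------------------------
# recovery experiments
# --------------------------------------------------------------------------

def masked_ret_experiment(
    seed: int,
    n_cells: int = 100,
    n_mock: int = 20,
    masked_fraction: float = 0.064,
    config: RunConfig | None = None,
) -> dict:
    """Simulated-RET control: mask a known fraction of mitochondria to
    background in the post-challenge frame and recover it with the
    excess-pixel-count estimator, pooled over synthetic cells."""
    config = config or RunConfig(seed=seed)
    cfg = config.scene_config()
    t0 = time.perf_counter()
    null = mock_calibration(cfg, seed, n_mock, config.imgproc, config.redoxstats)
    scale = redoxstats.mock_scale_factor(null)
    k = config.redoxstats.get("tail_sigma_multiple", redoxstats.DEFAULT_TAIL_SIGMA_MULTIPLE)

    fractions = []
    realized = []
    for i in range(n_cells):
        cell_seed = int(child_rng(seed, f"treated/{i}").integers(2**31 - 1))
        stack = render_cell_pair(
            cfg, cell_seed, challenged=True, masked_fraction=masked_fraction
        )
        realized.append(len(stack.truth.masked_ids) / len(stack.truth.mitochondria))
        hist = cell_logfold_histogram(
            stack, config.imgproc, config.redoxstats, after_scale=scale, cell_id=i
        )
        fit = redoxstats.fit_two_normals(hist, null.sigma0)
        est = redoxstats.excess_oxidised_fraction(hist, fit, null, k=k)
        fractions.append(est.fraction)
    mean, se = redoxstats.pool_fractions(fractions)
    return {
        "experiment": "masked-ret",
        "truth_masked_fraction": masked_fraction,
        "realized_masked_fraction": float(np.mean(realized)),
        "estimate": mean,
        "se": se,
        "n_cells": n_cells,
        "sigma0_mock": null.sigma0,
        "mu0_mock": null.mu0,
        "runtime_s": time.perf_counter() - t0,
    }


def null_calibration_experiment(
    seed: int,
    n_cells: int = 40,
    n_mock: int = 15,
    config: RunConfig | None = None,
) -> dict:
    """False-positive control: mock-vs-mock pairs through the treated
    pipeline must yield a near-zero oxidised fraction."""
    config = config or RunConfig(seed=seed)
    cfg = config.scene_config()
    t0 = time.perf_counter()
    null = mock_calibration(cfg, seed, n_mock, config.imgproc, config.redoxstats)
    scale = redoxstats.mock_scale_factor(null)
    k = config.redoxstats.get("tail_sigma_multiple", redoxstats.DEFAULT_TAIL_SIGMA_MULTIPLE)
    fractions = []
    for i in range(n_cells):
        cell_seed = int(child_rng(seed, f"nullcal/{i}").integers(2**31 - 1))
        stack = render_cell_pair(cfg, cell_seed, challenged=False)
        hist = cell_logfold_histogram(
            stack, config.imgproc, config.redoxstats, after_scale=scale, cell_id=i
        )
        fit = redoxstats.fit_two_normals(hist, null.sigma0)
        fractions.append(
            redoxstats.excess_oxidised_fraction(hist, fit, null, k=k).fraction
        )
    mean, se = redoxstats.pool_fractions(fractions)
    return {
        "experiment": "null-calibration",
        "estimate": mean,
        "se": se,
        "n_cells": n_cells,
        "sigma0_mock": null.sigma0,
        "runtime_s": time.perf_counter() - t0,
    }


def monotonicity_experiment(
    seed: int,
    fractions: Sequence[float] = (0.0, 0.02, 0.04, 0.064, 0.10),
    n_cells: int = 25,
    n_mock: int = 15,
    config: RunConfig | None = None,
) -> dict:
    """Estimated oxidised fraction over a ladder of true masked fractions."""
    config = config or RunConfig(seed=seed)
    cfg = config.scene_config()
    t0 = time.perf_counter()
    null = mock_calibration(cfg, seed, n_mock, config.imgproc, config.redoxstats)
    scale = redoxstats.mock_scale_factor(null)
    k = config.redoxstats.get("tail_sigma_multiple", redoxstats.DEFAULT_TAIL_SIGMA_MULTIPLE)
    levels = []
    for f in fractions:
        per_cell = []
        realized = []
        for i in range(n_cells):
            cell_seed = int(child_rng(seed, f"mono/{f}/{i}").integers(2**31 - 1))
            stack = render_cell_pair(cfg, cell_seed, challenged=True, masked_fraction=f)
            realized.append(
                len(stack.truth.masked_ids) / len(stack.truth.mitochondria)
                if stack.truth.masked_ids
                else 0.0
            )
            hist = cell_logfold_histogram(
                stack, config.imgproc, config.redoxstats, after_scale=scale, cell_id=i
            )
            fit = redoxstats.fit_two_normals(hist, null.sigma0)
            per_cell.append(
                redoxstats.excess_oxidised_fraction(hist, fit, null, k=k).fraction
            )
        mean, se = redoxstats.pool_fractions(per_cell)
        levels.append(
            {
                "truth": float(f),
                "realized": float(np.mean(realized)),
                "estimate": mean,
                "se": se,
            }
        )
    return {
        "experiment": "monotonicity",
        "levels": levels,
        "sigma0_mock": null.sigma0,
        "runtime_s": time.perf_counter() - t0,
    }


DIRECTION_SCENE_FRACTIONS = {
    "fet_responder": 0.65,
    "stalled": 0.30,
    "ret": 0.042,
    "nonpolarizing": 0.008,
}


def direction_recovery_experiment(
    seed: int,
    n_replicates: int = 4,
    n_mito: int = 250,
    image_shape: tuple = (256, 256),
    config: RunConfig | None = None,
) -> dict:
    """Per-mitochondrion direction-call recovery on replicate fields.

    Each replicate field draws its population multinomially from the
    class fractions (replicates are independent samples of the same
    population), renders three baseline and three post-challenge
    NAD(P)H frames, and runs segmentation -> trace extraction ->
    population-normalized log2-fold changes -> thresholded three-way
    calls.  The threshold is the configured multiple (default 1.5) of
    the average per-object standard error of a single post-challenge
    determination, estimated from the three repeats.
    """
    config = config or RunConfig(seed=seed)
    # stringent end of the 1-2x range: calling a ~4% RET class against a
    # ~30% stalled class needs a specific threshold, or noise leak from
    # the stalled population swamps the rare class
    c = config.redoxstats.get("direction_se_multiple", 2.0)
    t0 = time.perf_counter()
    pre_labels = ("pre1", "pre2", "pre3")
    post_labels = ("post1", "post2", "post3")
    replicate_deltas = []
    truth_fracs = []
    thresholds = []
    for r in range(n_replicates):
        rep_seed = int(child_rng(seed, f"direction/{r}").integers(2**31 - 1))
        cfg = config.scene_config(
            image_shape=image_shape,
            n_mito=n_mito,
            class_fractions=DIRECTION_SCENE_FRACTIONS,
            apportionment="multinomial",
            seed=rep_seed,
        )
        scene = build_scene(cfg)
        stack = synthgen.render_frames(
            scene, pre_labels + post_labels, "nadph", challenged=set(post_labels)
        )
        stack = imgproc.subtract_background(stack)
        # segment on the stack mean: any noise-selection bias at ROI
        # boundaries is then shared by all frames and cancels in the deltas
        rois = imgproc.segment_mitochondria(stack.frames.mean(axis=0))
        traces = imgproc.extract_traces(stack, rois)
        pre = traces[list(pre_labels)].mean(axis=1).to_numpy()
        posts = traces[list(post_labels)].to_numpy()
        pop_mean_pre = float(pre.mean())
        # per-determination log2-folds for the threshold estimate
        d_rep = np.stack(
            [
                redoxstats.per_mito_dnadh(posts[:, j] - pre, pop_mean_pre)
                for j in range(posts.shape[1])
            ],
            axis=1,
        )
        # c4 bias correction: the sample SD of n=3 repeats underestimates
        # sigma by the factor c4(3) = sqrt(2/(n-1)) * gamma(n/2)/gamma((n-1)/2)
        n_rep_frames = d_rep.shape[1]
        c4 = math.sqrt(2.0 / (n_rep_frames - 1)) * (
            math.gamma(n_rep_frames / 2.0) / math.gamma((n_rep_frames - 1) / 2.0)
        )
        sd_per_object = d_rep.std(axis=1, ddof=1) / c4
        threshold = float(c * sd_per_object.mean())
        thresholds.append(threshold)
        deltas = redoxstats.per_mito_dnadh(posts.mean(axis=1) - pre, pop_mean_pre)
        replicate_deltas.append(deltas)
        counts = scene.class_counts()
        n = len(scene.mitochondria)
        # nonpolarizing mitochondria respond with an NAD(P)H increase and
        # are expected to be called forward-transport
        truth_fracs.append(
            {
                "fet": (counts["fet_responder"] + counts["nonpolarizing"]) / n,
                "stalled": counts["stalled"] / n,
                "ret": counts["ret"] / n,
            }
        )
    threshold = float(np.mean(thresholds))
    table = redoxstats.direction_fractions(replicate_deltas, threshold)
    truth_tab = pd.DataFrame(truth_fracs).mean(axis=0)
    return {
        "experiment": "direction-recovery",
        "threshold": threshold,
        "recovered": {c_: float(table.loc[c_, "fraction"]) for c_ in table.index},
        "se": {c_: float(table.loc[c_, "se"]) for c_ in table.index},
        "truth_nominal": {
            "fet": DIRECTION_SCENE_FRACTIONS["fet_responder"]
            + DIRECTION_SCENE_FRACTIONS["nonpolarizing"],
            "stalled": DIRECTION_SCENE_FRACTIONS["stalled"],
            "ret": DIRECTION_SCENE_FRACTIONS["ret"],
        },
        "truth_realized": {k: float(v) for k, v in truth_tab.items()},
        "n_replicates": n_replicates,
        "runtime_s": time.perf_counter() - t0,
    }


def plate_experiment(seed: int, config: RunConfig | None = None) -> dict:
    """Calibration, rate and dose-response recovery on a synthetic plate."""
    t0 = time.perf_counter()
    rng = child_rng(seed, "plate_design")
    top, bottom, ic50, hill = 100.0, 20.0, 150.0, 1.2
    concs = [0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0]
    wells = []
    for rep in range(3):
        for j, conc in enumerate(concs):
            wells.append(
                {
                    "well": f"S{rep}{j}",
                    "role": "sample",
                    "condition": "s1qel_titration",
                    "s1qel_concentration": conc,
                    "background_rate": 2.0,
                }
            )
    wells.append({"well": "CAL", "role": "calibration"})
    truth = PlateTruth(
        wells=tuple(wells),
        calibration_spikes=(50.0, 100.0, 200.0),
        calibration_slope=3.0,
        noise_sigma=0.05 * 3.0 * top / 60.0 * 80.0 * 5,  # ~5% of a mid-trace span
        fourpl=(top, bottom, ic50, hill),
        seed=seed,
    )
    table = synthgen.simulate_plate(truth)
    rates = bulkassays.rates_by_well(table)
    samples = rates[rates["role"] == "sample"]
    mean_rates = samples.groupby("concentration_nM")["raw_slope_afu_per_min"].mean()
    fit = bulkassays.fit_4pl(
        mean_rates.index.to_numpy(), mean_rates.to_numpy(), subtract_residual=True
    )
    cal_trace = table[table["well"] == "CAL"].sort_values("cycle")
    steps = []
    f = cal_trace["fluorescence_afu"].to_numpy()
    for j in range(len(truth.calibration_spikes)):
        cyc = truth.spike_start_cycle + j * truth.spike_interval_cycles
        steps.append(f[cyc - 1] - f[cyc - 2])
    cal = bulkassays.calibrate_h2o2(truth.calibration_spikes, steps)
    return {
        "experiment": "plate",
        "ic50_truth_nM": ic50,
        "ic50_estimate_nM": fit.ic50,
        "hill_estimate": fit.hill,
        "calibration_slope_truth": truth.calibration_slope,
        "calibration_slope_estimate": cal.slope,
        "runtime_s": time.perf_counter() - t0,
    }


EXPERIMENTS = {
    "masked-ret": masked_ret_experiment,
    "null-calibration": null_calibration_experiment,
    "monotonicity": monotonicity_experiment,
    "direction": direction_recovery_experiment,
    "plate": plate_experiment,
}


# --------------------------------------------------------------------------
# commands
# --------------------------------------------------------------------------

def _write_with_hash(obj: dict, path: Path, config: RunConfig) -> None:
    obj = dict(obj)
    obj["config_hash"] = config.config_hash()
    path.write_text(json.dumps(obj, indent=1, default=str))


def cmd_simulate(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.scene_config(seed=config.seed)
    scene = build_scene(cfg)
    nadph = synthgen.render_frames(
        scene, ("before", "after"), "nadph", challenged={"after"}
    )
    nadph.write(outdir / "nadph.tiff")
    tmrm = synthgen.render_frames(scene, ("gm", "g3p", "succ"), "tmrm")
    tmrm.write(outdir / "tmrm.tiff")
    if config.plate:
        truth = PlateTruth(seed=config.seed, **config.plate)
        synthgen.write_plate_csv(
            synthgen.simulate_plate(truth), outdir / "plate.csv"
        )
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    logger.info("simulate: wrote artifacts to %s", outdir)


def cmd_analyze_mito(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    tmrm = FrameStack.read(outdir / "tmrm.tiff")
    tmrm = imgproc.subtract_background(tmrm)
    rois = imgproc.segment_mitochondria(tmrm.frames[-1])
    traces = imgproc.extract_traces(tmrm, rois)
    traces.to_csv(outdir / "tmrm_traces.csv")
    gates = polarization.GateSet(**config.polarization)
    records = polarization.records_from_traces(traces, gates)
    recs = pd.DataFrame(
        [
            {
                "mito_id": r.mito_id,
                "pol_gm_vs_succ_mv": r.pol_gm_vs_succ,
                "pol_g3p_vs_gm_mv": r.pol_g3p_vs_gm,
                "class": r.mito_class,
            }
            for r in records
        ]
    )
    recs.to_csv(outdir / "polarization_records.csv", index=False)
    summary = polarization.classify_population([records], gates)
    summary.to_csv(outdir / "polarization_classes.csv")
    _write_with_hash(
        {"n_rois": len(rois), "n_records": len(records)},
        outdir / "analyze_mito.json",
        config,
    )
    logger.info("analyze-mito: %d ROIs", len(rois))


def cmd_analyze_cells(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    stack = FrameStack.read(outdir / "nadph.tiff")
    hist = cell_logfold_histogram(stack, config.imgproc, config.redoxstats)
    null = redoxstats.fit_null(hist)
    fit = redoxstats.fit_two_normals(hist, null.sigma0)
    est = redoxstats.excess_oxidised_fraction(
        hist,
        fit,
        null,
        k=config.redoxstats.get(
            "tail_sigma_multiple", redoxstats.DEFAULT_TAIL_SIGMA_MULTIPLE
        ),
    )
    _write_with_hash(
        {
            "null": dataclasses.asdict(null),
            "two_component": dataclasses.asdict(fit),
            "oxidised_pixel_fraction": est.fraction,
        },
        outdir / "analyze_cells.json",
        config,
    )
    logger.info("analyze-cells: oxidised fraction %.4f", est.fraction)


def cmd_analyze_plate(config: RunConfig) -> None:
    outdir = Path(config.outdir)
    table = pd.read_csv(outdir / "plate.csv")
    window = tuple(config.bulkassays.get("cycle_window", bulkassays.DEFAULT_CYCLE_WINDOW))
    rates = bulkassays.rates_by_well(table, window)
    rates.to_csv(outdir / "rates.csv", index=False)
    out = {"n_wells": int(len(rates))}
    titr = rates.dropna(subset=["concentration_nM"])
    if len(titr) >= 5:
        fit = bulkassays.fit_4pl(
            titr["concentration_nM"].to_numpy(),
            titr["raw_slope_afu_per_min"].to_numpy(),
            subtract_residual=config.bulkassays.get("subtract_residual", True),
        )
        out["nominal_ic50_nM"] = fit.ic50
        out["hill"] = fit.hill
    _write_with_hash(out, outdir / "analyze_plate.json", config)
    logger.info("analyze-plate: %d wells", len(rates))


def cmd_recover(config: RunConfig, experiment: str) -> dict:
    if experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; choose from {sorted(EXPERIMENTS)}"
        )
    report = EXPERIMENTS[experiment](config.seed, config=config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_with_hash(report, outdir / f"recover_{experiment}.json", config)
    logger.info("recover %s: done in %.1fs", experiment, report.get("runtime_s", 0.0))
    return report


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="retscope",
        description="Rotenone-challenge quantification of electron-flow "
        "direction through mitochondrial complex I",
    )
    p.add_argument("command", choices=[
        "simulate", "analyze-mito", "analyze-cells", "analyze-plate", "recover",
    ])
    p.add_argument("--config", type=Path, default=None)
    p.add_argument("--seed", type=int, default=None)
    p.add_argument("--outdir", type=Path, default=None)
    p.add_argument("--experiment", type=str, default="masked-ret")
    p.add_argument("--threads", type=int, default=1,
                   help="accepted for interface compatibility; results are "
                   "independent of thread count")
    p.add_argument("-v", "--verbose", action="count", default=0)
    return p


def main(argv: Sequence[str] | None = None) -> int:
    args = build_parser().parse_args(argv)
    try:
        config = (
            RunConfig.from_yaml(args.config) if args.config else RunConfig()
        )
        if args.seed is not None:
            config.seed = args.seed
        if args.outdir is not None:
            config.outdir = str(args.outdir)
        config.verbosity = args.verbose
        configure_logging(config.verbosity)
        if args.command == "simulate":
            cmd_simulate(config)
        elif args.command == "analyze-mito":
            cmd_analyze_mito(config)
        elif args.command == "analyze-cells":
            cmd_analyze_cells(config)
        elif args.command == "analyze-plate":
            cmd_analyze_plate(config)
        elif args.command == "recover":
            cmd_recover(config, args.experiment)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
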