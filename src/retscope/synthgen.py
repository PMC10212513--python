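"""Ground-truthed synthetic micrographs and plate-reader tables.

Emulates the statistical structure the downstream analysis assumes:
punctate mitochondria rendered as isotropic Gaussian spots, per-
mitochondrion responder classes (forward-transport responder = NAD(P)H
increase on challenge, stalled = no change, RET = decrease), Nernstian
TMRM amplitudes (10-fold per 61 mV), smooth frame-to-frame motility,
additive read noise plus an optional scaled-Poisson shot term, and
plate-reader resorufin accumulation with H2O2 calibration spikes and a
4PL dose-response across suppressor concentrations.

Randomness: one root seed per scene; every sub-draw comes from a named
child stream so adding a feature never perturbs existing draws.
Identical seed + parameters give bit-identical output.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgproc import FrameStack, warp_image

NERNST_SLOPE_MV = 61.0  # mV per decade of TMRM accumulation

MITO_CLASSES = ("fet_responder", "stalled", "ret", "nonpolarizing")


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a root seed."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# truth containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MitoTruth:
    """Ground truth for a single rendered mitochondrion."""

    id: int
    centroid: tuple  # (row, col), 0-based pixel centers
    spot_sigma: float  # px
    mito_class: str
    nadph_baseline: float  # AFU
    nadph_log2_response: float  # log2-fold change applied on challenge
    tmrm_potential: Mapping[str, float] = field(default_factory=dict)  # mV

    def __post_init__(self) -> None:
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be > 0")
        if self.nadph_baseline < 0:
            raise ValueError("nadph_baseline must be >= 0")
        if self.mito_class not in MITO_CLASSES:
            raise ValueError(f"unknown class {self.mito_class!r}")
        if self.mito_class == "fet_responder" and not self.nadph_log2_response > 0:
            raise ValueError("fet_responder requires nadph_log2_response > 0")
        if self.mito_class == "ret" and not self.nadph_log2_response < 0:
            raise ValueError("ret requires nadph_log2_response < 0")
        if self.mito_class == "stalled" and self.nadph_log2_response != 0:
            raise ValueError("stalled requires nadph_log2_response == 0")


@dataclass(frozen=True)
class SceneTruth:
    """Full description of one synthetic field."""

    image_shape: tuple
    mitochondria: tuple  # of MitoTruth
    background_level: float  # AFU
    read_noise_sigma: float  # AFU
    photon_gain: float  # AFU/photon; 0 disables the Poisson term
    motility_amplitude: float  # px RMS
    motility_correlation_length: float  # px
    seed: int
    masked_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_noise_sigma < 0 or self.photon_gain < 0:
            raise ValueError("noise parameters must be >= 0")
        h, w = self.image_shape
        for m in self.mitochondria:
            y, x = m.centroid
            if not (0 <= y < h and 0 <= x < w):
                raise ValueError(f"mitochondrion {m.id} lies outside the image")

    def class_counts(self) -> dict:
        counts = {c: 0 for c in MITO_CLASSES}
        for m in self.mitochondria:
            counts[m.mito_class] += 1
        return counts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mitochondria"] = [asdict(m) for m in self.mitochondria]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        mitos = tuple(
            MitoTruth(
                id=m["id"],
                centroid=tuple(m["centroid"]),
                spot_sigma=m["spot_sigma"],
                mito_class=m["mito_class"],
                nadph_baseline=m["nadph_baseline"],
                nadph_log2_response=m["nadph_log2_response"],
                tmrm_potential=dict(m["tmrm_potential"]),
            )
            for m in d["mitochondria"]
        )
        return cls(
            image_shape=tuple(d["image_shape"]),
            mitochondria=mitos,
            background_level=d["background_level"],
            read_noise_sigma=d["read_noise_sigma"],
            photon_gain=d["photon_gain"],
            motility_amplitude=d["motility_amplitude"],
            motility_correlation_length=d["motility_correlation_length"],
            seed=d["seed"],
            masked_ids=tuple(d.get("masked_ids", ())),
        )


@dataclass(frozen=True)
class PlateTruth:
    """Generative model for plate-reader resorufin traces.

    ``wells`` entries are dicts with keys ``well``, ``role``
    ({sample, cell_free_background, calibration, vehicle}), ``condition``,
    ``true_h2o2_rate`` (pmol/min), ``background_rate`` (AFU/min) and
    optionally ``s1qel_concentration`` (nM).  When a concentration is
    present and ``fourpl`` is set, the realized rate follows the stored
    4PL curve instead of ``true_h2o2_rate``.
    """

    wells: tuple
    calibration_spikes: tuple = ()  # pmol amounts
    calibration_slope: float = 3.0  # AFU/pmol
    cycle_seconds: float = 80.0
    n_cycles: int = 25
    noise_sigma: float = 0.0  # AFU
    fourpl: tuple | None = None  # (top, bottom, ic50, hill)
    seed: int = 0
    baseline_afu: float = 100.0
    spike_start_cycle: int = 3
    spike_interval_cycles: int = 5

    def __post_init__(self) -> None:
        if self.n_cycles < 19:
            raise ValueError("n_cycles must be >= 19 so cycles 5-18 exist")
        if self.fourpl is not None and self.fourpl[2] <= 0:
            raise ValueError("ic50 must be > 0")
        for wl in self.wells:
            if wl.get("true_h2o2_rate", 0.0) < 0:
                raise ValueError("rates must be >= 0")


# --------------------------------------------------------------------------
# scene construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of :func:`build_scene`.

    Defaults emulate the NAD(P)H cell-arm study conditions: about 74% of
    mitochondria respond to the challenge with about a 50% intensity
    increase (log2(1.5) ~ 0.585) and the rest are stalled; noise is
    calibrated so a mock pair yields a pixelwise log2-fold sigma of
    roughly 0.15-0.25.
    """

    image_shape: tuple = (256, 256)
    n_mito: int = 125
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"fet_responder": 0.74, "stalled": 0.26}
    )
    spot_sigma: float = 1.5  # px
    min_separation_factor: float = 4.0  # centers >= factor * spot_sigma apart
    nadph_baseline_mean: float = 300.0  # AFU peak amplitude
    nadph_baseline_cv: float = 0.25
    fet_log2_response_mean: float = math.log2(1.5)
    fet_log2_response_sd: float = 0.1
    ret_log2_response_mean: float = -1.0
    ret_log2_response_sd: float = 0.15
    nonpolarizing_log2_response_mean: float = 1.0
    nonpolarizing_log2_response_sd: float = 0.1
    tmrm_potentials: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tmrm_potential_sd_mv: float = 5.0
    background_level: float = 100.0  # AFU
    read_noise_sigma: float = 3.0  # AFU
    photon_gain: float = 0.5  # AFU/photon
    motility_amplitude: float = 0.0  # px
    motility_correlation_length: float = 30.0  # px
    apportionment: str = "largest_remainder"  # or "multinomial"
    seed: int = 0


# per-class mean TMRM potentials (mV, relative) used when a SceneConfig
# does not override them; chosen to land inside the corresponding default
# polarization gates with margin larger than the dispersion
DEFAULT_TMRM_POTENTIALS = {
    # x-gate axis: V(gm) - V(succ); y-gate axis: V(g3p) - V(gm)
    "fet_responder": {"gm": -40.0, "g3p": -25.0, "succ": 0.0},   # medium/medium
    "stalled": {"gm": -10.0, "g3p": 0.0, "succ": 0.0},           # strong GM, weak G3P
    "ret": {"gm": -55.0, "g3p": -10.0, "succ": 0.0},             # weak GM, strong G3P
    "nonpolarizing": {"gm": -50.0, "g3p": -48.0, "succ": 0.0},   # no G3P response
}


def largest_remainder_counts(
    fractions: Mapping[str, float], n: int
) -> dict:
    """Deterministic largest-remainder apportionment of ``fractions`` over n."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1 (got {total})")
    classes = list(fractions)
    quotas = np.array([fractions[c] * n for c in classes])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # ties broken by class order (stable argsort on negative remainders)
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return {c: int(k) for c, k in zip(classes, counts)}


def build_scene(config: SceneConfig) -> SceneTruth:
    """Build a ground-truthed scene from class fractions and a seed.

    Realized class counts are the deterministic largest-remainder
    apportionment of the fractions over ``n_mito`` (or a multinomial draw
    when ``apportionment == 'multinomial'``).  Positions are rejection-
    sampled to enforce a minimum center distance of
    ``min_separation_factor * spot_sigma``.
    """
    if config.n_mito < 1:
        raise ValueError("n_mito must be >= 1")
    if config.apportionment == "largest_remainder":
        counts = largest_remainder_counts(config.class_fractions, config.n_mito)
    elif config.apportionment == "multinomial":
        total = sum(config.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        rng = child_rng(config.seed, "apportionment")
        classes = list(config.class_fractions)
        draw = rng.multinomial(
            config.n_mito, [config.class_fractions[c] for c in classes]
        )
        counts = dict(zip(classes, (int(k) for k in draw)))
    else:
        raise ValueError(f"unknown apportionment {config.apportionment!r}")

    h, w = config.image_shape
    margin = 3.0 * config.spot_sigma
    min_dist = config.min_separation_factor * config.spot_sigma
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for the spot size")
    # capacity check: disks of radius min_dist/2 must fit the usable area
    usable = (h - 2 * margin) * (w - 2 * margin)
    if config.n_mito * (min_dist / 2) ** 2 * math.pi > 0.7 * usable:
        raise ValueError(
            f"image too small for {config.n_mito} mitochondria at "
            f"min separation {min_dist:.1f}px"
        )

    rng_pos = child_rng(config.seed, "positions")
    positions: list = []
    attempts = 0
    max_attempts = 20000 * config.n_mito
    while len(positions) < config.n_mito:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place mitochondria at the separation constraint")
        y = rng_pos.uniform(margin, h - 1 - margin)
        x = rng_pos.uniform(margin, w - 1 - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_dist**2 for py, px in positions):
            positions.append((y, x))

    rng_base = child_rng(config.seed, "nadph_baseline")
    rng_resp = child_rng(config.seed, "nadph_response")
    rng_pot = child_rng(config.seed, "tmrm_potential")

    class_order: list = []
    for c, k in counts.items():
        class_order.extend([c] * k)
    # interleave classes across positions deterministically so spatial
    # position carries no class information
    perm = child_rng(config.seed, "class_shuffle").permutation(len(class_order))
    class_order = [class_order[i] for i in perm]

    response_params = {
        "fet_responder": (config.fet_log2_response_mean, config.fet_log2_response_sd),
        "stalled": (0.0, 0.0),
        "ret": (config.ret_log2_response_mean, config.ret_log2_response_sd),
        "nonpolarizing": (
            config.nonpolarizing_log2_response_mean,
            config.nonpolarizing_log2_response_sd,
        ),
    }
    potentials = dict(DEFAULT_TMRM_POTENTIALS)
    potentials.update(config.tmrm_potentials or {})

    mitos = []
    for i, ((y, x), cls) in enumerate(zip(positions, class_order)):
        baseline = max(
            rng_base.normal(
                config.nadph_baseline_mean,
                config.nadph_baseline_cv * config.nadph_baseline_mean,
            ),
            0.1 * config.nadph_baseline_mean,
        )
        mu, sd = response_params[cls]
        resp = rng_resp.normal(mu, sd) if sd > 0 else mu
        if cls == "fet_responder":
            resp = max(resp, 0.05)
        elif cls == "ret":
            resp = min(resp, -0.05)
        pots = {
            cond: float(rng_pot.normal(mean, config.tmrm_potential_sd_mv))
            for cond, mean in potentials[cls].items()
        }
        # succinate is the per-experiment reference; keep it fixed
        if "succ" in pots:
            pots["succ"] = potentials[cls].get("succ", 0.0)
        mitos.append(
            MitoTruth(
                id=i,
                centroid=(float(y), float(x)),
                spot_sigma=config.spot_sigma,
                mito_class=cls,
                nadph_baseline=float(baseline),
                nadph_log2_response=float(resp),
                tmrm_potential=pots,
            )
        )

    return SceneTruth(
        image_shape=(h, w),
        mitochondria=tuple(mitos),
        background_level=config.background_level,
        read_noise_sigma=config.read_noise_sigma,
        photon_gain=config.photon_gain,
        motility_amplitude=config.motility_amplitude,
        motility_correlation_length=config.motility_correlation_length,
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

TMRM_AMPLITUDE_0MV = 200.0  # AFU peak at 0 mV relative potential


def _render_spots(
    shape: tuple, mitos: Sequence[MitoTruth], amplitudes: np.ndarray
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    h, w = shape
    for m, amp in zip(mitos, amplitudes):
        if amp == 0:
            continue
        y0, x0 = m.centroid
        s = m.spot_sigma
        r = int(math.ceil(4 * s))
        ylo, yhi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
        xlo, xhi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
        yy, xx = np.meshgrid(
            np.arange(ylo, yhi), np.arange(xlo, xhi), indexing="ij"
        )
        img[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * s**2)
        )
    return img


def _add_noise(
    clean: np.ndarray, truth: SceneTruth, rng: np.random.Generator
) -> np.ndarray:
    out = clean
    if truth.photon_gain > 0:
        out = truth.photon_gain * rng.poisson(
            np.maximum(clean, 0.0) / truth.photon_gain
        ).astype(float)
    if truth.read_noise_sigma > 0:
        out = out + rng.normal(0.0, truth.read_noise_sigma, size=clean.shape)
    return np.maximum(out, 0.0)


def render_frames(
    scene: SceneTruth,
    conditions: Sequence[str],
    channel: str,
    challenged: Iterable[str] = (),
) -> FrameStack:
    """Render one frame per condition.

    Each mitochondrion is an isotropic 2-D Gaussian spot.  On the TMRM
    channel the peak amplitude is proportional to ``10**(potential/61)``
    so the Nernst readout recovers the assigned relative potential exactly
    in the noiseless limit.  On the NAD(P)H channel the amplitude is
    ``baseline * 2**response`` for conditions listed in ``challenged``.
    Background and noise are added last.
    """
    if channel not in ("tmrm", "nadph"):
        raise ValueError(f"unknown channel {channel!r}")
    challenged = set(challenged)
    mitos = scene.mitochondria
    frames = []
    for t, cond in enumerate(conditions):
        if channel == "tmrm":
            amps = []
            for m in mitos:
                if cond not in m.tmrm_potential:
                    raise ValueError(
                        f"condition {cond!r} missing from tmrm_potential of "
                        f"mitochondrion {m.id}"
                    )
                amps.append(TMRM_AMPLITUDE_0MV * 10 ** (m.tmrm_potential[cond] / NERNST_SLOPE_MV))
            amps = np.asarray(amps)
        else:
            amps = np.array(
                [
                    m.nadph_baseline
                    * (2.0 ** m.nadph_log2_response if cond in challenged else 1.0)
                    for m in mitos
                ]
            )
        clean = _render_spots(scene.image_shape, mitos, amps) + scene.background_level
        rng = child_rng(scene.seed, f"noise/{channel}/{t}/{cond}")
        frames.append(_add_noise(clean, scene, rng))
    return FrameStack(
        frames=np.stack(frames),
        channel=channel,
        condition_labels=tuple(conditions),
        provenance=f"synthetic scene seed={scene.seed}",
        truth=scene,
    )


# --------------------------------------------------------------------------
# motility
# --------------------------------------------------------------------------

def random_displacement_field(
    shape: tuple, amplitude: float, correlation_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random field with the requested RMS displacement magnitude."""
    field_ = rng.normal(size=(*shape, 2))
    for c in (0, 1):
        field_[..., c] = ndimage.gaussian_filter(
            field_[..., c], sigma=correlation_length, mode="wrap"
        )
    rms = np.sqrt(np.mean(field_[..., 0] ** 2 + field_[..., 1] ** 2))
    if rms > 0:
        field_ *= amplitude / rms
    return field_


def apply_motility(
    stack: FrameStack, amplitude: float, correlation_length: float, seed: int
) -> FrameStack:
    """Warp every post-baseline frame by a smooth random displacement field.

    The first frame is the unwarped baseline.  The true fields are kept on
    the returned stack (``motility_fields``) for registration-recovery
    tests.  Amplitude 0 is the identity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        out = stack.with_frames(stack.frames.copy())
        out.motility_fields = [None] * stack.frames.shape[0]
        return out
    frames = stack.frames.copy()
    fields: list = [None]
    for t in range(1, frames.shape[0]):
        rng = child_rng(seed, f"motility/{t}")
        disp = random_displacement_field(
            stack.shape, amplitude, correlation_length, rng
        )
        frames[t] = warp_image(stack.frames[t], disp, order=3)
        fields.append(disp)
    out = stack.with_frames(frames)
    out.motility_fields = fields
    return out


# --------------------------------------------------------------------------
# simulated-RET masking
# --------------------------------------------------------------------------

def mask_fraction(stack: FrameStack, fraction: float, seed: int) -> FrameStack:
    """Replace a random subset of mitochondria by background in the last frame.

    ``ceil(fraction * N)`` mitochondria are chosen uniformly; all their
    pixels within 3 spot sigma in the final frame are replaced by
    background values sampled from a local annulus.  The masked ids are
    recorded on the attached truth.  This reproduces the simulated-RET
    control in which a known fraction of mitochondria is erased from the
    post-challenge frame.
    """
    if stack.truth is None:
        raise ValueError("mask_fraction requires a stack with attached truth")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0:
        return stack.with_frames(stack.frames.copy())
    truth: SceneTruth = stack.truth
    n = len(truth.mitochondria)
    k = int(math.ceil(fraction * n))
    rng = child_rng(seed, "mask_fraction")
    chosen = rng.choice(n, size=k, replace=False)
    chosen_ids = tuple(int(truth.mitochondria[i].id) for i in sorted(chosen))

    frames = stack.frames.copy()
    final = frames[-1]
    h, w = final.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # pool must exclude ALL spots, not just the one being masked, or a
    # close neighbour leaks foreground intensity into the "background"
    near_any = np.zeros((h, w), dtype=bool)
    for m in truth.mitochondria:
        y0, x0 = m.centroid
        near_any |= (yy - y0) ** 2 + (xx - x0) ** 2 <= (4 * m.spot_sigma) ** 2
    for i in chosen:
        m = truth.mitochondria[i]
        y0, x0 = m.centroid
        r2 = (yy - y0) ** 2 + (xx - x0) ** 2
        inner = r2 <= (3 * m.spot_sigma) ** 2
        annulus = (r2 <= (8 * m.spot_sigma) ** 2) & ~near_any
        pool = final[annulus]
        if pool.size == 0:  # spot in a crowded corner; fall back to global bg
            pool = final[~near_any]
        final[inner] = rng.choice(pool, size=int(inner.sum()), replace=True)

    new_truth = replace(truth, masked_ids=chosen_ids)
    out = stack.with_frames(frames)
    out.truth = new_truth
    return out


# --------------------------------------------------------------------------
# plate simulation
# --------------------------------------------------------------------------

def fourpl(conc: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Variable-slope four-parameter logistic, oriented so rate(0) = top."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def simulate_plate(truth: PlateTruth) -> pd.DataFrame:
    """Simulate a well x cycle fluorescence table.

    Sample/vehicle wells accumulate resorufin linearly:
    ``baseline + slope * rate * t + background_rate * t (+ noise)``.
    Calibration wells contain step increments of
    ``slope * spike_amount`` at evenly spaced spike cycles.
    """
    rng = child_rng(truth.seed, "plate_noise")
    rows = []
    times_s = np.arange(1, truth.n_cycles + 1) * truth.cycle_seconds
    times_min = times_s / 60.0
    for wl in truth.wells:
        role = wl.get("role", "sample")
        rate = float(wl.get("true_h2o2_rate", 0.0))
        conc = wl.get("s1qel_concentration")
        if conc is not None and truth.fourpl is not None:
            rate = float(fourpl(np.array([conc]), *truth.fourpl)[0])
        bg_rate = float(wl.get("background_rate", 0.0))
        if role == "calibration":
            trace = np.full(truth.n_cycles, truth.baseline_afu)
            for j, amount in enumerate(truth.calibration_spikes):
                spike_cycle = truth.spike_start_cycle + j * truth.spike_interval_cycles
                step = truth.calibration_slope * float(amount)
                trace[spike_cycle - 1:] += step
        else:
            trace = (
                truth.baseline_afu
                + truth.calibration_slope * rate * times_min
                + bg_rate * times_min
            )
        if truth.noise_sigma > 0:
            trace = trace + rng.normal(0.0, truth.noise_sigma, size=trace.shape)
        for cyc, t_s, f in zip(range(1, truth.n_cycles + 1), times_s, trace):
            rows.append(
                {
                    "well": wl["well"],
                    "role": role,
                    "condition": wl.get("condition", ""),
                    "concentration_nM": conc if conc is not None else np.nan,
                    "cycle": cyc,
                    "seconds": float(t_s),
                    "fluorescence_afu": float(f),
                }
            )
    return pd.DataFrame(rows)


def write_plate_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
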