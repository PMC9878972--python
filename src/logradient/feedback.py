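"""Closed-loop drift-stabilization simulation.

The desk-scale counterpart of an actively stabilized microscope: a virtual
stage drifts (linear ramp + random walk + sinusoid), a fiducial bead is
rendered through the synthetic defocus model at the stage's true offset,
the local-gradient localizer measures the 3D position (xy in pixels scaled
to nm, z through a linear-fit calibration), and a per-axis
proportional-integral controller commands corrections that the stage
follows through a first-order lag.

The bead is locked at a defocused z setpoint where it has brightfield
contrast; the feedback only needs a locally linear, monotonic z-metric,
not an absolute axial position.  Experimental stability figures of real
hardware are not reproduced here — the simulation asserts relative drift
suppression between matched feedback-on and feedback-off runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axial import apply_calibration, build_calibration, z_value_brightfield
from .errors import LoGError
from .gradients import local_gradients, precompute_transforms
from .localize import localize
from .synthetic import BeadParams, NoiseModel, add_noise, render_bead_defocus

__all__ = ["StageState", "PIController", "StabilizationConfig", "feedback_step", "run_stabilization"]


@dataclass
class StageState:
    """Virtual piezo stage: drift model plus a lagged actuator.

    ``true_offset`` (nm, xyz) is drift + actuator position.  Drift is a
    linear ramp (nm/step), a Gaussian random walk (nm/sqrt(step)), and a
    sinusoid (amplitude nm, period steps).  Commanded moves are tracked by
    a first-order lag: each step the actuator moves ``response_alpha`` of
    the way to its commanded target (1.0 = ideal instant actuator).
    """

    drift_linear: tuple = (0.0, 0.0, 0.0)
    random_walk_sigma: tuple = (0.0, 0.0, 0.0)
    sine_amp: tuple = (0.0, 0.0, 0.0)
    sine_period: float = 200.0
    response_alpha: float = 1.0
    travel_limit: float = 5000.0

    drift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    actuator: np.ndarray = field(default_factory=lambda: np.zeros(3))
    command_target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: int = 0

    @property
    def true_offset(self) -> np.ndarray:
        return self.drift + self.actuator

    def advance(self, rng: np.random.Generator) -> None:
        """One time step: accumulate drift, move the actuator toward target."""
        self.t += 1
        lin = np.asarray(self.drift_linear, dtype=float)
        rw = np.asarray(self.random_walk_sigma, dtype=float)
        amp = np.asarray(self.sine_amp, dtype=float)
        phase_prev = 2 * np.pi * (self.t - 1) / self.sine_period
        phase = 2 * np.pi * self.t / self.sine_period
        self.drift = self.drift + lin + rng.normal(0.0, 1.0, 3) * rw + amp * (
            np.sin(phase) - np.sin(phase_prev)
        )
        target = np.clip(self.command_target, -self.travel_limit, self.travel_limit)
        self.actuator = self.actuator + self.response_alpha * (target - self.actuator)


@dataclass
class PIController:
    """Per-axis proportional-integral controller with anti-windup clamp."""

    setpoint: np.ndarray = field(default_factory=lambda: np.zeros(3))
    kp: tuple = (0.5, 0.5, 0.5)
    ki: tuple = (0.05, 0.05, 0.05)
    integral_clamp: float = 1000.0
    integral: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def command(self, error: np.ndarray) -> np.ndarray:
        self.integral = np.clip(self.integral + error, -self.integral_clamp, self.integral_clamp)
        return np.asarray(self.kp) * error + np.asarray(self.ki) * self.integral


@dataclass
class StabilizationConfig:
    """Configuration of a paired feedback-on / feedback-off run."""

    n_steps: int = 200
    shape: tuple = (96, 96)
    nm_per_px: float = 18.3
    z_setpoint: float = 400.0  # defocused operating point, nm
    bead: BeadParams = field(default_factory=lambda: BeadParams(z_range=1000.0))
    r: float = 16.0
    threshold_frac: float = 1 / 1.5
    snr: float | None = 50.0
    kp: tuple = (0.5, 0.5, 0.5)
    ki: tuple = (0.05, 0.05, 0.05)
    drift_linear: tuple = (0.5, -0.3, 0.4)
    random_walk_sigma: tuple = (0.5, 0.5, 0.5)
    sine_amp: tuple = (5.0, 5.0, 0.0)
    sine_period: float = 100.0
    response_alpha: float = 1.0
    seed: int = 0
    cal_range: float = 500.0
    cal_step: float = 100.0


def _make_renderer(cfg: StabilizationConfig):
    """Frame renderer: bead at image center displaced by the true offset."""
    cy = (cfg.shape[0] - 1) / 2.0
    cx = (cfg.shape[1] - 1) / 2.0

    def render(offset_nm, seed=None):
        x = cx + offset_nm[0] / cfg.nm_per_px
        y = cy + offset_nm[1] / cfg.nm_per_px
        z = cfg.z_setpoint + offset_nm[2]
        img = render_bead_defocus(cfg.shape, x, y, z, cfg.bead)
        if cfg.snr is not None and seed is not None:
            img = add_noise(img, NoiseModel(snr=cfg.snr), seed)
        return img

    return render, (cx, cy)


def make_z_calibration(cfg: StabilizationConfig, precomputed=None):
    """Linear-fit z calibration: scan ±cal_range around the setpoint."""
    zs = np.arange(-cfg.cal_range, cfg.cal_range + 1e-9, cfg.cal_step) + cfg.z_setpoint
    cy = (cfg.shape[0] - 1) / 2.0
    cx = (cfg.shape[1] - 1) / 2.0
    stack = [render_bead_defocus(cfg.shape, cx, cy, z, cfg.bead) for z in zs]
    return build_calibration(
        stack, zs, metric="brightfield", r=cfg.r, threshold_frac=cfg.threshold_frac,
        mode="linear", center=(cx, cy), precomputed=precomputed,
    )


def feedback_step(stage, controller, render, localizer, calibration, rng, enabled=True):
    """One loop iteration: render → localize → PI command → stage advance.

    ``localizer`` is a callable image → (x_nm, y_nm, z_nm) measured offset.
    On localization failure the record is flagged and no command is issued.
    Returns the per-step record dict.
    """
    seed = int(rng.integers(2**31))
    img = render(stage.true_offset, seed)
    rec = {
        "true_x": stage.true_offset[0],
        "true_y": stage.true_offset[1],
        "true_z": stage.true_offset[2],
        "flagged": False,
    }
    try:
        meas = np.asarray(localizer(img), dtype=float)
    except LoGError:
        rec.update(meas_x=np.nan, meas_y=np.nan, meas_z=np.nan, flagged=True,
                   cmd_x=stage.command_target[0], cmd_y=stage.command_target[1],
                   cmd_z=stage.command_target[2])
        stage.advance(rng)
        return rec
    rec.update(meas_x=meas[0], meas_y=meas[1], meas_z=meas[2])
    if enabled:
        error = controller.setpoint - meas
        stage.command_target = stage.command_target + controller.command(error)
    rec.update(cmd_x=stage.command_target[0], cmd_y=stage.command_target[1],
               cmd_z=stage.command_target[2])
    stage.advance(rng)
    return rec


def run_stabilization(cfg: StabilizationConfig) -> pd.DataFrame:
    """Execute matched feedback-on and feedback-off runs.

    Both runs see the identical drift realization (same seed); the 'on'
    run closes the PI loop, the 'off' run only measures.  Returns one
    tidy DataFrame with a ``feedback`` column ('on'/'off') and per-step
    true offsets, measured offsets, command targets, and residuals.
    """
    render, (cx, cy) = _make_renderer(cfg)
    pc = precompute_transforms(cfg.shape, cfg.r)
    cal = make_z_calibration(cfg, precomputed=pc)

    def localizer(img):
        loc = localize(img, cfg.r, cfg.threshold_frac, precomputed=pc, normalize=False)
        fld = local_gradients(img, cfg.r, precomputed=pc)
        zv = z_value_brightfield(fld, (loc.x, loc.y))
        z_nm = apply_calibration(cal, zv) - cfg.z_setpoint
        return (loc.x - cx) * cfg.nm_per_px, (loc.y - cy) * cfg.nm_per_px, z_nm

    frames = []
    for mode in ("on", "off"):
        rng = np.random.default_rng(cfg.seed)
        stage = StageState(
            drift_linear=cfg.drift_linear,
            random_walk_sigma=cfg.random_walk_sigma,
            sine_amp=cfg.sine_amp,
            sine_period=cfg.sine_period,
            response_alpha=cfg.response_alpha,
        )
        controller = PIController(kp=cfg.kp, ki=cfg.ki)
        for step in range(cfg.n_steps):
            rec = feedback_step(stage, controller, render, localizer, cal, rng,
                                enabled=(mode == "on"))
            rec["step"] = step
            rec["feedback"] = mode
            frames.append(rec)
    df = pd.DataFrame(frames)
    for ax in "xyz":
        df[f"resid_{ax}"] = df[f"true_{ax}"]
    return df
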