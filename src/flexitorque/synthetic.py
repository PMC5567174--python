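"""Forward simulator for elbow-flexion trials.

Generates synchronized (time, angle, torque, circumference) recordings for
passive, isokinetic and isotonic protocols, with known ground truth attached
for parameter-recovery testing.  Torque during flexion is produced as

    T = s(theta) * exp(a1*theta + a2) * velocity_gain(theta_dot)

so the combined torque-per-unit-strain factor is exactly log-linear in the
elbow angle, and any velocity dependence enters only through
``velocity_gain`` (constant 1 under the null).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import (
    InfeasibleProtocolError,
    OutOfRangeError,
    ParameterError,
    ProtocolError,
)

DEFAULT_ROM = (30.0, 120.0)
S_MAX_LOW = 0.05   # inclusion rule: subjects below 5% peak strain are excluded
S_MAX_HIGH = 0.30  # circumferential strain stays within 0..30%

MODES = ("passive", "isokinetic", "isotonic")


def constant_velocity_gain(velocity: float) -> float:
    """Null torque-velocity factor: no velocity effect."""
    return 1.0


def power_velocity_gain(ratio: float, v_lo: float = 60.0, v_hi: float = 120.0) -> Callable[[float], float]:
    """Velocity gain spanning ``ratio``-fold between ``v_lo`` and ``v_hi`` deg/s.

    gain(v) = ratio ** ((v - v_lo) / (v_hi - v_lo)); gain(v_lo) = 1.
    """
    if ratio <= 0:
        raise ParameterError(f"velocity gain ratio must be > 0, got {ratio}")
    span = v_hi - v_lo

    def gain(velocity: float) -> float:
        return float(ratio ** ((velocity - v_lo) / span))

    gain.ratio = ratio  # type: ignore[attr-defined]
    return gain


def _check_angle(angle, rom, tol: float = 1e-6) -> np.ndarray:
    theta = np.asarray(angle, dtype=float)
    lo, hi = rom
    if np.any(theta < lo - tol) or np.any(theta > hi + tol):
        bad = theta[(theta < lo - tol) | (theta > hi + tol)]
        raise OutOfRangeError(
            f"angle {np.atleast_1d(bad)[0]:.3f} deg outside ROM [{lo}, {hi}]"
        )
    return theta


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth parameters of one simulated subject.

    ``a1_true``/``a2_true`` define the log-linear torque-per-strain factor
    exp(a1*theta + a2) (N*m, theta in degrees); ``velocity_gain`` multiplies it
    as a function of angular velocity (deg/s).
    """

    subject_id: str = "S0"
    a1_true: float = -0.024          # per degree
    a2_true: float = 7.0             # dimensionless intercept of ln(eta)
    s_max: float = 0.15              # peak voluntary circumferential strain
    c0_mid: float = 290.0            # connatural circumference at 90 deg (mm)
    c0_slope: float = 0.20           # passive circumference change (mm/deg)
    strain_shape: float = 1.0        # exponent of the strain bump
    velocity_gain: Callable[[float], float] = constant_velocity_gain
    noise_torque_sd: float = 0.3     # N*m
    noise_circ_sd: float = 0.15      # mm
    drift_amp: float = 1.0           # mm, fabric-sensor baseline relaxation
    drift_tau: float = 60.0          # s
    inertia: float = 0.06            # forearm rotational inertia (N*m per deg/s^2)
    damping: float = 0.02            # N*m*s/deg
    t120_max: float | None = None    # peak torque at 120 deg/s; derived if None

    def __post_init__(self) -> None:
        if not (S_MAX_LOW < self.s_max <= S_MAX_HIGH):
            raise ParameterError(
                f"s_max must lie in ({S_MAX_LOW}, {S_MAX_HIGH}] "
                f"(subjects below {S_MAX_LOW:.0%} peak strain are excluded), "
                f"got {self.s_max}"
            )
        for name in ("noise_torque_sd", "noise_circ_sd", "drift_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.drift_tau <= 0:
            raise ParameterError("drift_tau must be > 0")
        if self.c0_mid <= 0:
            raise ParameterError("c0_mid must be > 0")
        if self.c0_slope <= 0:
            raise ParameterError("c0_slope must be > 0 (passive shortening "
                                 "thickens the flexor with increasing angle)")
        if self.strain_shape <= 0:
            raise ParameterError("strain_shape must be > 0")
        if self.inertia <= 0:
            raise ParameterError("inertia must be > 0")
        if self.damping < 0:
            raise ParameterError("damping must be >= 0")
        if not callable(self.velocity_gain):
            raise ParameterError("velocity_gain must be callable")
        for v in (0.0, 60.0, 90.0, 120.0, 240.0):
            if self.velocity_gain(v) <= 0:
                raise ParameterError(f"velocity_gain must be positive, "
                                     f"gain({v}) = {self.velocity_gain(v)}")
        if self.t120_max is None:
            object.__setattr__(self, "t120_max", self.peak_torque(120.0))
        elif self.t120_max <= 0:
            raise ParameterError("t120_max must be > 0")

    def eta_true(self, angle, velocity: float | None = None):
        """Ground-truth torque-per-strain factor at ``angle`` (and velocity)."""
        base = np.exp(self.a1_true * np.asarray(angle, dtype=float) + self.a2_true)
        if velocity is None:
            return base
        return base * self.velocity_gain(velocity)

    def peak_torque(self, velocity: float, rom=DEFAULT_ROM) -> float:
        """Maximum generable torque at constant ``velocity`` over the ROM."""
        theta = np.linspace(rom[0], rom[1], 1801)
        return float(np.max(strain_profile(self, theta, rom) *
                            self.eta_true(theta, velocity)))


def make_subject(seed=None, overrides: Mapping | None = None) -> SubjectParams:
    """Sample a random subject; deterministic for a fixed seed.

    ``overrides`` replaces sampled fields; invariant violations raise
    :class:`ParameterError` naming the offending constraint.
    """
    rng = np.random.default_rng(seed)
    params = dict(
        subject_id=f"S{seed}" if isinstance(seed, (int, np.integer)) else "S0",
        a1_true=float(rng.uniform(-0.030, -0.018)),
        a2_true=float(rng.uniform(6.6, 7.4)),
        s_max=float(rng.uniform(0.08, 0.25)),
        c0_mid=float(rng.uniform(265.0, 315.0)),
        c0_slope=float(rng.uniform(0.12, 0.30)),
        drift_amp=float(rng.uniform(0.5, 1.5)),
        drift_tau=float(rng.uniform(40.0, 90.0)),
        inertia=float(rng.uniform(0.04, 0.08)),
        damping=float(rng.uniform(0.010, 0.030)),
    )
    if overrides:
        params.update(overrides)
    return SubjectParams(**params)


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol metadata for one trial."""

    mode: str
    rom: tuple = DEFAULT_ROM
    velocity: float | None = None      # deg/s (isokinetic / passive)
    impedance: float | None = None     # N*m (isotonic)
    n_cycles: int = 4
    sample_rate: float = 100.0         # Hz
    seed: int = 0
    return_velocity: float = 90.0      # deg/s, isotonic passive return

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ProtocolError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        lo, hi = self.rom
        if not lo < hi:
            raise ProtocolError(f"rom lower bound must be < upper, got {self.rom}")
        if self.mode in ("isokinetic", "passive"):
            if self.velocity is None or self.velocity <= 0:
                raise ProtocolError(f"{self.mode} trials need velocity > 0")
        if self.mode == "isotonic":
            if self.impedance is None or self.impedance <= 0:
                raise ProtocolError("isotonic trials need impedance > 0")
            if self.return_velocity <= 0:
                raise ProtocolError("return_velocity must be > 0")
        if self.n_cycles < 1:
            raise ProtocolError("n_cycles must be >= 1")
        if self.sample_rate <= 0:
            raise ProtocolError("sample_rate must be > 0")


@dataclass
class TrialRecording:
    """Synchronized per-trial time series plus protocol metadata."""

    time: np.ndarray           # s, strictly increasing
    angle: np.ndarray          # deg
    torque: np.ndarray         # N*m, gravity-corrected
    circumference: np.ndarray  # mm
    protocol: ProtocolConfig
    subject_id: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.circumference = np.asarray(self.circumference, dtype=float)
        n = self.time.size
        for name in ("angle", "torque", "circumference"):
            if getattr(self, name).size != n:
                raise ParameterError(f"channel {name!r} length mismatch "
                                     f"({getattr(self, name).size} != {n})")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        if self.time.size > 1:
            return float(1.0 / np.median(np.diff(self.time)))
        return self.protocol.sample_rate


def connatural_circumference(subject: SubjectParams, angle, rom=DEFAULT_ROM):
    """Passive (relaxed-flexor) circumference as a function of elbow angle.

    Linear in angle: anchored at ``c0_mid`` for 90 deg with slope ``c0_slope``;
    strictly increasing with flexion.
    """
    theta = _check_angle(angle, rom)
    return subject.c0_mid + subject.c0_slope * (theta - 90.0)


def strain_profile(subject: SubjectParams, angle, rom=DEFAULT_ROM):
    """Voluntary circumferential strain versus angle during maximal flexion.

    A scaled bump s_max * (4u(1-u))**p with u the normalized angle; zero at
    both ROM limits, unimodal, peak value ``s_max`` at mid-ROM.
    """
    theta = _check_angle(angle, rom)
    lo, hi = rom
    u = (theta - lo) / (hi - lo)
    return subject.s_max * (4.0 * u * (1.0 - u)) ** subject.strain_shape


def apply_drift(series, time, amp: float, tau: float,
                walk_sd: float = 0.0, seed=None) -> np.ndarray:
    """Add a slow baseline drift amp*(1 - exp(-t/tau)) to a circumference series.

    Mimics resistance relaxation of fabric strain sensors.  An optional random
    walk (``walk_sd`` mm/sqrt(s)) can be superimposed.  The input is not
    modified.
    """
    if tau <= 0:
        raise ParameterError(f"drift tau must be > 0, got {tau}")
    if amp < 0 or walk_sd < 0:
        raise ParameterError("drift amplitude and walk_sd must be >= 0")
    series = np.asarray(series, dtype=float)
    t = np.asarray(time, dtype=float)
    out = series + amp * (1.0 - np.exp(-t / tau))
    if walk_sd > 0:
        rng = np.random.default_rng(seed)
        dt = np.diff(t, prepend=t[:1])
        out = out + np.cumsum(rng.normal(0.0, walk_sd, t.size) * np.sqrt(np.maximum(dt, 0.0)))
    return out


def _triangular_wave(protocol: ProtocolConfig):
    """Time, angle and flexion mask of an n-cycle triangular sweep of the ROM."""
    lo, hi = protocol.rom
    v = protocol.velocity
    fs = protocol.sample_rate
    half = (hi - lo) / v
    cycle = 2.0 * half
    n = int(round(protocol.n_cycles * cycle * fs)) + 1
    k = np.arange(n)
    t = k / fs
    steps = cycle * fs
    if abs(steps - round(steps)) < 1e-9:
        phase = (k % int(round(steps))) / fs
    else:  # pragma: no cover - non-commensurate sampling
        phase = np.mod(t, cycle)
    rising = phase <= half
    angle = np.where(rising, lo + v * phase, hi - v * (phase - half))
    angle = np.clip(angle, lo, hi)
    flexing = phase < half  # the vertex sample carries zero strain either way
    return t, angle, flexing


def _noisy_channels(subject, protocol, t, angle, strain, torque_clean, drift):
    rng = np.random.default_rng(protocol.seed)
    torque = torque_clean + rng.normal(0.0, subject.noise_torque_sd, t.size)
    circ = connatural_circumference(subject, angle, protocol.rom) * (1.0 + strain)
    if drift:
        circ = apply_drift(circ, t, subject.drift_amp, subject.drift_tau)
    circ = circ + rng.normal(0.0, subject.noise_circ_sd, t.size)
    return torque, circ


def simulate_isokinetic_trial(subject: SubjectParams,
                              protocol: ProtocolConfig) -> TrialRecording:
    """Simulate n_cycles of constant-velocity flexion-extension.

    Angle follows a triangular wave across the ROM; flexions carry the
    subject's voluntary strain profile and the matching torque, extensions are
    at rest.  Circumference picks up baseline drift plus noise.
    """
    if protocol.mode != "isokinetic":
        raise ProtocolError(f"expected an isokinetic protocol, got {protocol.mode!r}")
    t, angle, flexing = _triangular_wave(protocol)
    strain = np.where(flexing, strain_profile(subject, angle, protocol.rom), 0.0)
    eta = subject.eta_true(angle, protocol.velocity)
    torque_clean = strain * eta
    torque, circ = _noisy_channels(subject, protocol, t, angle, strain,
                                   torque_clean, drift=True)
    gt = {
        "strain": strain,
        "eta": eta,
        "torque": torque_clean,
        "angular_velocity": np.where(flexing, protocol.velocity, -protocol.velocity),
    }
    return TrialRecording(t, angle, torque, circ, protocol,
                          subject.subject_id, ground_truth=gt)


def simulate_passive_trial(subject: SubjectParams,
                           protocol: ProtocolConfig) -> TrialRecording:
    """Simulate assisted (no voluntary contraction) flexion-extension cycles.

    Torque is measurement noise only; circumference equals the connatural
    profile plus noise, with no drift by default.
    """
    if protocol.mode != "passive":
        raise ProtocolError(f"expected a passive protocol, got {protocol.mode!r}")
    t, angle, _ = _triangular_wave(protocol)
    strain = np.zeros_like(t)
    torque_clean = np.zeros_like(t)
    torque, circ = _noisy_channels(subject, protocol, t, angle, strain,
                                   torque_clean, drift=False)
    gt = {"strain": strain, "torque": torque_clean}
    return TrialRecording(t, angle, torque, circ, protocol,
                          subject.subject_id, ground_truth=gt)


def integrate_flexion(torque_fn, impedance: float, inertia: float,
                      damping: float, rom, dt: float,
                      theta0: float | None = None, v0: float = 0.0,
                      max_steps: int | None = None):
    """Integrate a single flexion against a constant impedance.

    Semi-implicit Euler of inertia*acc = torque_fn(theta, v) - impedance -
    damping*v, with the angle clipped to the ROM and velocity zeroed at the
    upper limit.  Returns (theta, velocity) arrays sampled every ``dt``; raises
    :class:`InfeasibleProtocolError` if the flexion stalls before the ROM end.
    """
    lo, hi = rom
    theta = lo if theta0 is None else float(theta0)
    v = float(v0)
    if max_steps is None:
        max_steps = int(round(60.0 / dt))
    thetas: list[float] = []
    vels: list[float] = []
    done = False
    for _ in range(max_steps + 2):
        thetas.append(theta)
        vels.append(v)
        if done:
            return np.asarray(thetas), np.asarray(vels)
        torque = torque_fn(theta, v)
        acc = (torque - impedance - damping * v) / inertia
        v = v + acc * dt
        if v < 0.0:
            v = 0.0
        theta = theta + v * dt
        if theta >= hi:
            theta, v = hi, 0.0
            done = True
        elif v == 0.0:
            raise InfeasibleProtocolError(
                f"isotonic flexion stalled at {theta:.2f} deg "
                f"(impedance {impedance:.2f} N*m)")
    raise InfeasibleProtocolError(
        "isotonic flexion did not traverse the ROM within the step budget")


def simulate_isotonic_trial(subject: SubjectParams, protocol: ProtocolConfig,
                            *, buildup_s: float = 0.3,
                            handoff_deg: float = 10.0) -> TrialRecording:
    """Simulate flexions against a constant impedance torque.

    Each cycle: an isometric effort build-up at the ROM start until the
    generated torque exceeds the impedance, a dynamic flexion integrated with
    a second-order rigid-body model (velocity zeroed at the ROM end), then a
    passive constant-velocity return.  The break-away strain is handed off to
    the angle-parameterized strain profile over ``handoff_deg`` degrees.
    """
    if protocol.mode != "isotonic":
        raise ProtocolError(f"expected an isotonic protocol, got {protocol.mode!r}")
    lo, hi = protocol.rom
    fs = protocol.sample_rate
    dt = 1.0 / fs
    imp = protocol.impedance
    gain = subject.velocity_gain
    if imp >= subject.peak_torque(0.0, protocol.rom):
        raise InfeasibleProtocolError(
            f"impedance {imp:.2f} N*m is not below the achievable peak torque "
            f"{subject.peak_torque(0.0, protocol.rom):.2f} N*m; "
            "the flexion cannot traverse the ROM")
    eta_lo = float(subject.eta_true(lo)) * gain(0.0)
    if imp / eta_lo >= subject.s_max:
        raise InfeasibleProtocolError(
            f"impedance {imp:.2f} N*m cannot be overcome at the ROM start")
    ramp = subject.s_max / buildup_s

    def dyn_strain(theta, v_break):
        prof = strain_profile(subject, theta, protocol.rom)
        fade = np.maximum(0.0, 1.0 - (np.asarray(theta, float) - lo) / handoff_deg)
        return prof + v_break * fade

    ang: list[float] = []
    vel: list[float] = []
    strain: list[float] = []
    tq: list[float] = []

    for _ in range(protocol.n_cycles):
        # isometric build-up at the ROM start
        s_iso = 0.0
        while s_iso * eta_lo <= imp:
            ang.append(lo)
            vel.append(0.0)
            strain.append(s_iso)
            tq.append(s_iso * eta_lo)
            s_iso += ramp * dt
        s_break = s_iso

        def torque_fn(theta, v, _sb=s_break):
            s = float(dyn_strain(theta, _sb))
            return s * float(subject.eta_true(theta)) * gain(v)

        thetas, vels = integrate_flexion(torque_fn, imp, subject.inertia,
                                         subject.damping, protocol.rom, dt,
                                         theta0=lo, v0=0.0)
        s_dyn = dyn_strain(thetas, s_break)
        t_dyn = s_dyn * subject.eta_true(thetas) * \
            np.array([gain(v) for v in vels])
        ang.extend(thetas.tolist())
        vel.extend(vels.tolist())
        strain.extend(np.asarray(s_dyn).tolist())
        tq.extend(np.asarray(t_dyn).tolist())

        # passive constant-velocity return to the ROM start
        r = protocol.return_velocity
        theta = hi
        while theta > lo:
            theta = max(theta - r * dt, lo)
            ang.append(theta)
            vel.append(-r)
            strain.append(0.0)
            tq.append(0.0)

    angle = np.asarray(ang)
    strain_arr = np.asarray(strain)
    torque_clean = np.asarray(tq)
    t = np.arange(angle.size) / fs
    torque, circ = _noisy_channels(subject, protocol, t, angle, strain_arr,
                                   torque_clean, drift=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = np.where(strain_arr > 0, torque_clean / strain_arr, np.nan)
    gt = {
        "strain": strain_arr,
        "eta": eta,
        "torque": torque_clean,
        "angular_velocity": np.asarray(vel),
    }
    return TrialRecording(t, angle, torque, circ, protocol,
                          subject.subject_id, ground_truth=gt)
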