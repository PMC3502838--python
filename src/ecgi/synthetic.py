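"""Synthetic equivalent-double-layer (EDL) forward model.

Generates paired transmembrane-potential (TMP) / body-surface-potential
(BSP) time series with the statistical structure of a normal ventricular
excitation: per-node action-potential (AP) waveforms activated according to
a breakthrough-driven activation map, projected to the body surface through
an ill-conditioned linear transfer matrix, with additive Gaussian
measurement noise at a prescribed SNR.

The default protocol is 478 ventricular-surface source nodes, 412 torso
leads, a 357 ms excitation sampled at 1 ms (358 instants), a transfer
matrix of condition number 5.6e12, 30 dB noise on the BSPs, and a test
split at times 3, 9, ..., 357 ms (60 test / 298 training instants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ApTemplate",
    "ActivationMap",
    "TransferMatrix",
    "ForwardDataset",
    "SimulationConfig",
    "make_ap_waveform",
    "make_activation_map",
    "simulate_tmps",
    "make_transfer_matrix",
    "forward_project",
    "add_noise",
    "split_train_test",
    "spheroid_points",
    "default_templates",
    "assign_templates",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApTemplate:
    """Parametric ventricular action-potential waveform.

    The waveform rests at ``resting_potential`` until activation, rises
    smoothly to ``plateau_potential`` over ``upstroke_duration``, holds the
    plateau (with optional linear sag ``plateau_decay`` in mV/ms) until
    ``apd`` after activation, then falls smoothly back to rest over
    ``repolarization_duration``. All potentials in millivolts, durations in
    milliseconds.
    """

    resting_potential: float = -90.0
    plateau_potential: float = 10.0
    upstroke_duration: float = 2.0
    apd: float = 250.0
    repolarization_duration: float = 60.0
    plateau_decay: float = 0.0

    def __post_init__(self) -> None:
        if not (self.plateau_potential > self.resting_potential):
            raise ValidationError("plateau_potential must exceed resting_potential")
        for name in ("upstroke_duration", "apd", "repolarization_duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (self.apd > self.upstroke_duration):
            raise ValidationError("apd must exceed upstroke_duration")
        if self.plateau_decay < 0:
            raise ValidationError("plateau_decay must be >= 0")


@dataclass(frozen=True)
class ActivationMap:
    """Per-node activation times (ms) of a ventricular excitation sequence.

    Time zero is the first breakthrough: ``activation_time.min() == 0``.
    """

    activation_time: np.ndarray
    breakthrough_sites: tuple[int, ...]
    conduction_velocity: float

    def __post_init__(self) -> None:
        at = np.asarray(self.activation_time, dtype=float)
        if at.ndim != 1 or not np.all(np.isfinite(at)):
            raise ValidationError("activation_time must be a finite 1-D array")
        if at.min() < 0 or not np.isclose(at.min(), 0.0):
            raise ValidationError("activation times must be >= 0 with minimum 0")
        object.__setattr__(self, "activation_time", at)

    @property
    def n_nodes(self) -> int:
        return self.activation_time.size


@dataclass(frozen=True)
class TransferMatrix:
    """Lead-field operator mapping source TMPs to lead BSPs."""

    A: np.ndarray
    condition_number: float
    seed: int

    @property
    def n_leads(self) -> int:
        return self.A.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.A.shape[1]


@dataclass
class ForwardDataset:
    """Paired TMP/BSP time series plus transfer matrix and metadata.

    ``tmps`` is n_nodes x n_times (mV), ``bsps_*`` are n_leads x n_times;
    columns are time instants. ``bsps_clean == A @ tmps`` by construction.
    """

    tmps: np.ndarray
    bsps_clean: np.ndarray
    bsps_noisy: np.ndarray
    times: np.ndarray
    transfer: TransferMatrix
    snr_db: float | None
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    activation: ActivationMap | None = None

    @property
    def n_nodes(self) -> int:
        return self.tmps.shape[0]

    @property
    def n_leads(self) -> int:
        return self.bsps_clean.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    # -- delimited-text round trip ------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write the dataset as delimited text + JSON metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = ",".join(f"t{int(round(t))}" for t in self.times)
        for name, mat in (
            ("tmps", self.tmps),
            ("bsps_clean", self.bsps_clean),
            ("bsps_noisy", self.bsps_noisy),
        ):
            np.savetxt(outdir / f"{name}.csv", mat, delimiter=",",
                       header=header, comments="")
        np.savetxt(outdir / "A.csv", self.transfer.A, delimiter=",",
                   header=",".join(f"n{j}" for j in range(self.n_nodes)),
                   comments="")
        meta = {
            "times_ms": self.times.tolist(),
            "snr_db": self.snr_db,
            "seed": self.seed,
            "transfer_seed": self.transfer.seed,
            "condition_number": self.transfer.condition_number,
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, indir: str | Path) -> "ForwardDataset":
        indir = Path(indir)
        meta = json.loads((indir / "meta.json").read_text())
        load = lambda n: np.loadtxt(indir / f"{n}.csv", delimiter=",", skiprows=1)
        A = load("A")
        return cls(
            tmps=load("tmps"),
            bsps_clean=load("bsps_clean"),
            bsps_noisy=load("bsps_noisy"),
            times=np.asarray(meta["times_ms"], dtype=float),
            transfer=TransferMatrix(A, meta["condition_number"],
                                    meta["transfer_seed"]),
            snr_db=meta["snr_db"],
            train_indices=np.asarray(meta["train_indices"], dtype=int),
            test_indices=np.asarray(meta["test_indices"], dtype=int),
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# waveforms and activation
# ---------------------------------------------------------------------------


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 monotone ramp 0 -> 1 on [0, 1] (3u^2 - 2u^3), clipped outside."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def make_ap_waveform(template: ApTemplate, activation_time: float,
                     t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the AP waveform of ``template`` activated at
    ``activation_time`` at time(s) ``t`` (ms). Returns mV.

    Exactly ``resting_potential`` before activation and after
    ``activation_time + apd + repolarization_duration``; smooth monotone
    upstroke over ``upstroke_duration``; plateau with optional linear decay;
    smooth repolarization.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    rest, plat = template.resting_potential, template.plateau_potential
    amp = plat - rest
    tau = t_arr - activation_time

    up = _smoothstep(tau / template.upstroke_duration)
    # plateau sag accrues between end of upstroke and onset of repolarization
    sag = template.plateau_decay * np.clip(
        tau - template.upstroke_duration, 0.0,
        template.apd - template.upstroke_duration)
    down = _smoothstep((tau - template.apd) / template.repolarization_duration)
    v = rest + (amp * up - sag) * (1.0 - down)
    v = np.where(tau < 0, rest, v)
    v = np.where(tau >= template.apd + template.repolarization_duration, rest, v)
    if np.ndim(t) == 0:
        return float(v)
    return v


def make_activation_map(node_positions: np.ndarray,
                        breakthrough_sites,
                        conduction_velocity: float) -> ActivationMap:
    """Euclidean-distance activation map: each node activates at the
    distance to its nearest breakthrough site divided by the conduction
    velocity (mm/ms), shifted so the earliest node defines t = 0."""
    pos = np.asarray(node_positions, dtype=float)
    sites = tuple(int(s) for s in np.atleast_1d(breakthrough_sites))
    if len(sites) == 0:
        raise ValidationError("at least one breakthrough site is required")
    if conduction_velocity <= 0:
        raise ValidationError("conduction velocity must be > 0")
    d = np.min(
        np.linalg.norm(pos[:, None, :] - pos[list(sites)][None, :, :], axis=2),
        axis=1,
    )
    at = d / conduction_velocity
    at = at - at.min()
    return ActivationMap(at, sites, conduction_velocity)


def simulate_tmps(templates, act_map: ActivationMap,
                  times: np.ndarray) -> np.ndarray:
    """TMP matrix (n_nodes x n_times): node i's waveform evaluated along
    ``times``. ``templates`` is one ApTemplate per node (sequence of length
    n_nodes)."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be sorted ascending and unique")
    templates = list(templates)
    if len(templates) != act_map.n_nodes:
        raise ValidationError(
            f"need one template per node: got {len(templates)} templates "
            f"for {act_map.n_nodes} nodes")
    if any(tp is None for tp in templates):
        raise ValidationError("every node must be assigned a template")
    out = np.empty((act_map.n_nodes, times.size))
    for i, (tp, at) in enumerate(zip(templates, act_map.activation_time)):
        out[i] = make_ap_waveform(tp, at, times)
    return out


# ---------------------------------------------------------------------------
# transfer matrix and projection
# ---------------------------------------------------------------------------


def make_transfer_matrix(n_leads: int, n_nodes: int, target_condition: float,
                         seed: int) -> TransferMatrix:
    """Dense lead-field surrogate with a prescribed geometric singular
    spectrum: A = U diag(s) V^T with random orthogonal factors and singular
    values decaying geometrically from 1 to 1/target_condition.

    The realized condition number matches the target to well within 1%
    (floating-point limited at extreme conditions such as 5.6e12)."""
    if n_leads < 2 or n_nodes < 2:
        raise ValidationError("n_leads and n_nodes must be >= 2")
    if target_condition < 1:
        raise ValidationError("target_condition must be >= 1")
    rng = np.random.default_rng(seed)
    r = min(n_leads, n_nodes)
    U, _ = np.linalg.qr(rng.standard_normal((n_leads, r)))
    V, _ = np.linalg.qr(rng.standard_normal((n_nodes, r)))
    s = np.geomspace(1.0, 1.0 / target_condition, r)
    A = (U * s) @ V.T
    return TransferMatrix(A=A, condition_number=float(target_condition),
                          seed=int(seed))


def spheroid_points(n: int, radii=(1.0, 1.0, 1.0), seed: int = 0) -> np.ndarray:
    """Quasi-uniform points on a spheroid via the Fibonacci lattice."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    theta = 2 * np.pi * i / golden
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts * np.asarray(radii, dtype=float)


def forward_project(A: TransferMatrix | np.ndarray, tmps: np.ndarray) -> np.ndarray:
    """Column-wise forward projection BSP = A @ TMP."""
    mat = A.A if isinstance(A, TransferMatrix) else np.asarray(A)
    tmps = np.asarray(tmps)
    if mat.shape[1] != tmps.shape[0]:
        raise ValidationError(
            f"shape mismatch: A has {mat.shape[1]} columns, "
            f"tmps has {tmps.shape[0]} rows")
    return mat @ tmps


def add_noise(bsps: np.ndarray, snr_db: float | None, seed: int) -> np.ndarray:
    """Additive zero-mean Gaussian white noise at a global SNR (dB).

    Noise variance = mean squared signal value / 10^(snr_db/10), with the
    power ratio taken over the whole matrix. ``snr_db=None`` disables noise.
    """
    bsps = np.asarray(bsps, dtype=float)
    if snr_db is None:
        return bsps.copy()
    if not np.isfinite(snr_db):
        raise ValidationError("snr_db must be finite (or None for no noise)")
    if bsps.size == 0:
        return bsps.copy()
    rng = np.random.default_rng(seed)
    signal_power = float(np.mean(bsps ** 2))
    noise_var = signal_power / (10.0 ** (snr_db / 10.0))
    return bsps + rng.normal(0.0, np.sqrt(noise_var), size=bsps.shape)


def split_train_test(times: np.ndarray, test_start: float,
                     test_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Split time instants into train/test: test instants are those at
    ``test_start + k*test_step`` within the sampled range; training is the
    complement. Returns (train_indices, test_indices)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be sorted ascending and unique")
    if test_start <= 0 or test_step <= 0:
        raise ValidationError("test_start and test_step must be > 0")
    k = np.round((times - test_start) / test_step)
    is_test = (k >= 0) & np.isclose(times, test_start + k * test_step)
    if not is_test.any():
        raise ValidationError("no time instant matches the test grid")
    idx = np.arange(times.size)
    return idx[~is_test], idx[is_test]


# ---------------------------------------------------------------------------
# whole-protocol generator
# ---------------------------------------------------------------------------


def default_templates(n_classes: int = 4) -> list[ApTemplate]:
    """Heterogeneous AP template classes (endo/mid/epi-like APD gradients)
    that create distinct temporal regimes over the excitation."""
    base = [
        ApTemplate(resting_potential=-90.0, plateau_potential=12.0,
                   upstroke_duration=2.0, apd=270.0,
                   repolarization_duration=70.0, plateau_decay=0.02),
        ApTemplate(resting_potential=-88.0, plateau_potential=8.0,
                   upstroke_duration=2.5, apd=230.0,
                   repolarization_duration=55.0, plateau_decay=0.03),
        ApTemplate(resting_potential=-92.0, plateau_potential=15.0,
                   upstroke_duration=1.5, apd=200.0,
                   repolarization_duration=45.0, plateau_decay=0.04),
        ApTemplate(resting_potential=-89.0, plateau_potential=10.0,
                   upstroke_duration=2.0, apd=160.0,
                   repolarization_duration=40.0, plateau_decay=0.05),
    ]
    if not (2 <= n_classes <= len(base)):
        raise ValidationError("n_classes must be between 2 and 4")
    return base[:n_classes]


def assign_templates(n_nodes: int, classes: list[ApTemplate]) -> list[ApTemplate]:
    """Assign template classes to nodes by contiguous index blocks."""
    bounds = np.linspace(0, n_nodes, len(classes) + 1).astype(int)
    out: list[ApTemplate] = []
    for c, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        out.extend([classes[c]] * (hi - lo))
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic forward protocol (defaults = the study
    conditions: 412 leads, 478 nodes, 357 ms at 1 ms, condition 5.6e12,
    30 dB noise, test times 3, 9, ..., 357 ms)."""

    n_leads: int = 412
    n_nodes: int = 478
    duration_ms: float = 357.0
    dt_ms: float = 1.0
    snr_db: float | None = 30.0
    condition: float = 5.6e12
    test_start_ms: float = 3.0
    test_step_ms: float = 6.0
    n_template_classes: int = 4
    n_breakthrough: int = 3
    conduction_velocity: float = 0.02  # mm/ms on the unit spheroid scale
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce YAML-sourced scalars (e.g. "1.0e4" parsed as str)
        for f in ("duration_ms", "dt_ms", "condition", "test_start_ms",
                  "test_step_ms", "conduction_velocity"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if self.snr_db is not None:
            object.__setattr__(self, "snr_db", float(self.snr_db))
        for f in ("n_leads", "n_nodes", "n_template_classes",
                  "n_breakthrough", "seed"):
            object.__setattr__(self, f, int(getattr(self, f)))


def simulate_dataset(config: SimulationConfig | None = None, **kw) -> ForwardDataset:
    """Run the full forward protocol and return a ForwardDataset.

    Keyword overrides are applied on top of ``config`` (or the defaults).
    """
    if config is None:
        config = SimulationConfig(**kw)
    elif kw:
        config = SimulationConfig(**{**asdict(config), **kw})
    c = config
    rng = np.random.default_rng(c.seed)
    times = np.arange(0.0, c.duration_ms + 0.5 * c.dt_ms, c.dt_ms)

    pos = spheroid_points(c.n_nodes, radii=(1.0, 1.0, 1.3), seed=c.seed)
    sites = rng.choice(c.n_nodes, size=min(c.n_breakthrough, c.n_nodes),
                       replace=False)
    act = make_activation_map(pos, sites, c.conduction_velocity)
    # rescale so the excitation wave covers roughly the first third of the
    # record, as in a normal beat (QRS ~ 1/3 of the ECG cycle here)
    span = act.activation_time.max()
    if span > 0:
        scale = (c.duration_ms / 3.5) / span
        act = ActivationMap(act.activation_time * scale,
                            act.breakthrough_sites,
                            c.conduction_velocity / scale)

    templates = assign_templates(c.n_nodes,
                                 default_templates(c.n_template_classes))
    tmps = simulate_tmps(templates, act, times)

    transfer = make_transfer_matrix(c.n_leads, c.n_nodes, c.condition,
                                    seed=c.seed + 1)
    bsps_clean = forward_project(transfer, tmps)
    bsps_noisy = add_noise(bsps_clean, c.snr_db, seed=c.seed + 2)
    train_idx, test_idx = split_train_test(times, c.test_start_ms,
                                           c.test_step_ms)
    return ForwardDataset(
        tmps=tmps, bsps_clean=bsps_clean, bsps_noisy=bsps_noisy,
        times=times, transfer=transfer, snr_db=c.snr_db,
        train_indices=train_idx, test_indices=test_idx, seed=c.seed,
        activation=act,
    )
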