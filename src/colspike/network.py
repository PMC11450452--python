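"""Full model: three populations (INP, HID, INPRC) wired by feedforward,
recurrent, and feedback projections, run through a phased stimulation
protocol in training or evaluation mode.

Training runs two phases per pattern (no-input, ffwd); evaluation runs four
(no-input, ffwd, overlap, recr).  Six model variants — rate-based, spiking
(1000 Hz) and sparsely spiking (100 Hz), each feedforward-only or with the
recurrent projection — share this one implementation and differ only in
parameter bindings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import (
    ActivationVariant,
    PopulationShape,
    PopulationState,
    encode_input_current,
    sample_spikes,
    softmax_by_hypercolumn,
    step_membrane,
)
from .rewiring import (
    ConnectivityMask,
    init_random_connectivity,
    patch_scores,
    rewire_step,
)
from .synapse import (
    ProjectionWeights,
    SynapseParams,
    TraceState,
    compute_bias_weight,
    step_p_traces,
    step_z_traces,
)

__all__ = [
    "VARIANTS",
    "NetworkConfig",
    "Phase",
    "PhaseSchedule",
    "Projection",
    "Network",
    "PatternRecord",
    "build_network",
    "run_pattern",
    "train",
    "evaluate",
]

# Parameter bindings of the six variants.  Rate variants communicate the
# softmax output itself; their traces use mu_spk = 1 (encoded as
# f_max = 1/dt so that f_max * dt = 1).
VARIANTS: dict[str, dict] = {
    "rate_ff": dict(mode="rate", f_max=None, tau_z=0.001, tau_m=0.001,
                    t_no_input=0.0, t_ffwd=0.005, t_overlap=0.0, t_recr=0.0,
                    recurrent=False),
    "rate_full": dict(mode="rate", f_max=None, tau_z=0.001, tau_m=0.001,
                      t_no_input=0.0, t_ffwd=0.005, t_overlap=0.0, t_recr=0.020,
                      recurrent=True),
    "spk_ff": dict(mode="spiking", f_max=1000.0, tau_z=0.005, tau_m=0.001,
                   t_no_input=0.025, t_ffwd=0.025, t_overlap=0.0, t_recr=0.0,
                   recurrent=False),
    "spk_full": dict(mode="spiking", f_max=1000.0, tau_z=0.005, tau_m=0.001,
                     t_no_input=0.025, t_ffwd=0.025, t_overlap=0.025,
                     t_recr=0.050, recurrent=True),
    "spspk_ff": dict(mode="spiking", f_max=100.0, tau_z=0.020, tau_m=0.005,
                     t_no_input=0.100, t_ffwd=0.100, t_overlap=0.0, t_recr=0.0,
                     recurrent=False),
    "spspk_full": dict(mode="spiking", f_max=100.0, tau_z=0.020, tau_m=0.005,
                       t_no_input=0.100, t_ffwd=0.100, t_overlap=0.050,
                       t_recr=0.150, recurrent=True),
}


@dataclass(frozen=True)
class Phase:
    """One protocol stage with its gate flags."""

    name: str
    duration: float
    input_inp: bool = False    # external current into INP
    input_inprc: bool = False  # external current into INPRC (clamp)
    ff: bool = False           # feedforward propagates
    rec: bool = False          # recurrent propagates
    fb: bool = False           # feedback propagates
    learn: bool = False        # p-traces integrate (training mode only)


@dataclass(frozen=True)
class PhaseSchedule:
    phases: tuple[Phase, ...]

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def onset(self) -> float:
        """Time of pattern onset = end of the no-input phase."""
        return sum(p.duration for p in self.phases if p.name == "no_input")


def _train_schedule(cfg: "NetworkConfig") -> PhaseSchedule:
    return PhaseSchedule((
        Phase("no_input", cfg.t_no_input),
        Phase("ffwd", cfg.t_ffwd, input_inp=True, input_inprc=True,
              ff=True, learn=True),
    ))


def _eval_schedule(cfg: "NetworkConfig") -> PhaseSchedule:
    # During evaluation INPRC gets no external input: it is driven purely by
    # the feedback projection, so its z-traces are the reconstruction.
    return PhaseSchedule((
        Phase("no_input", cfg.t_no_input),
        Phase("ffwd", cfg.t_ffwd, input_inp=True, ff=True, fb=True),
        Phase("overlap", cfg.t_overlap, input_inp=True, ff=True, rec=True,
              fb=True),
        Phase("recr", cfg.t_recr, rec=True, fb=True),
    ))


@dataclass(frozen=True)
class NetworkConfig:
    """Shapes, time constants, protocol durations and plasticity schedule."""

    inp_shape: PopulationShape
    hid_shape: PopulationShape
    variant: str = "spspk_full"
    mode: str = "spiking"          # "rate" | "spiking"
    f_max: float | None = 100.0    # None in rate mode (mu_spk = 1)
    recurrent: bool = True
    dt: float = 0.001
    tau_zi: float = 0.020
    tau_zj: float = 0.020
    tau_p: float = 5.0
    tau_m: float = 0.005
    t_no_input: float = 0.100
    t_ffwd: float = 0.100
    t_overlap: float = 0.050
    t_recr: float = 0.150
    n_conn_ff: int = 78
    n_conn_rec: int = 100
    n_conn_fb: int = 10
    n_flipconn: int = 100
    n_intvconn: int = 200
    n_epochs: int = 1
    eps: float = 1e-4
    clip: float = 1e-10
    log_base: str = "e"
    shuffle: bool = False
    seed: int = 0
    # relative jitter on the initial joint p-traces; breaks the exact
    # minicolumn symmetry that deterministic rate dynamics cannot escape
    # (spiking variants break it through sampling and default to 0)
    init_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.recurrent and (self.t_overlap or self.t_recr):
            raise ValueError("feedforward-only variants require "
                             "t_overlap = t_recr = 0")

    # INPRC has the same shape as INP by construction.
    @property
    def inprc_shape(self) -> PopulationShape:
        return self.inp_shape

    @property
    def effective_f_max(self) -> float:
        """f_max used by the trace filters; 1/dt in rate mode (mu_spk=1)."""
        return 1.0 / self.dt if self.f_max is None else self.f_max

    @property
    def activation(self) -> ActivationVariant:
        return ActivationVariant(self.mode, self.effective_f_max)

    def synapse_params(self) -> SynapseParams:
        return SynapseParams(
            tau_zi=self.tau_zi, tau_zj=self.tau_zj, tau_p=self.tau_p,
            f_max=self.effective_f_max, dt=self.dt, eps=self.eps,
        )

    @classmethod
    def from_variant(
        cls,
        variant: str,
        inp_shape: tuple[int, int] = (784, 2),
        hid_shape: tuple[int, int] = (100, 100),
        **overrides,
    ) -> "NetworkConfig":
        """Config with the variant's default parameter bindings.

        Default connection counts scale with the population sizes and
        reproduce (78, 100, 10) at the reference 784/100-hypercolumn scale.
        """
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        v = VARIANTS[variant]
        inp = PopulationShape(*inp_shape)
        hid = PopulationShape(*hid_shape)
        dt = overrides.get("dt", 0.001)
        tau_z = v["tau_z"]
        defaults = dict(
            inp_shape=inp, hid_shape=hid, variant=variant, mode=v["mode"],
            f_max=v["f_max"], recurrent=v["recurrent"],
            tau_zi=tau_z, tau_zj=tau_z, tau_m=v["tau_m"],
            t_no_input=v["t_no_input"], t_ffwd=v["t_ffwd"],
            t_overlap=v["t_overlap"], t_recr=v["t_recr"],
            n_conn_ff=max(1, round(inp.n_hyper * 78 / 784)),
            n_conn_rec=hid.n_hyper,
            n_conn_fb=max(1, round(hid.n_hyper * 10 / 100)),
            dt=dt,
            init_noise=0.01 if v["mode"] == "rate" else 0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Projection:
    """One projection: trace state, learned weights, patch connectivity."""

    name: str
    shape_pre: PopulationShape
    shape_post: PopulationShape
    params: SynapseParams
    traces: TraceState
    weights: ProjectionWeights
    mask: ConnectivityMask

    @classmethod
    def create(
        cls,
        name: str,
        shape_pre: PopulationShape,
        shape_post: PopulationShape,
        params: SynapseParams,
        n_conn: int,
        rng: np.random.Generator,
    ) -> "Projection":
        traces = TraceState.uniform(
            shape_pre.size, shape_post.size, shape_pre.n_mini, shape_post.n_mini
        )
        mask = init_random_connectivity(shape_pre, shape_post, n_conn, rng)
        bias, weight = compute_bias_weight(traces, params)
        weights = ProjectionWeights(
            bias=bias, weight=weight,
            conn=mask.expand(shape_pre.n_mini, shape_post.n_mini),
        )
        return cls(name, shape_pre, shape_post, params, traces, weights, mask)

    @property
    def fully_connected(self) -> bool:
        return self.mask.n_conn >= self.shape_pre.n_hyper

    def refresh_weights(self) -> None:
        bias, weight = compute_bias_weight(self.traces, self.params)
        self.weights.bias = bias
        self.weights.weight = weight
        self.weights.invalidate()

    def set_mask(self, mask: ConnectivityMask) -> None:
        self.mask = mask
        self.weights.conn = mask.expand(
            self.shape_pre.n_mini, self.shape_post.n_mini
        )
        self.weights.invalidate()

    def scores(self) -> np.ndarray:
        return patch_scores(self.traces, self.weights, self.mask,
                            self.shape_pre, self.shape_post)


@dataclass
class PatternRecord:
    """Signals captured while running one pattern.

    ``at[t]`` maps a record time (s after pattern onset) to a dict with keys
    ``hid_z`` (feedforward z_post), ``inprc_z`` (feedback z_post), ``hid_pi``
    and ``hid_s``.  The final step is always recorded under key ``"end"``.
    """

    at: dict = field(default_factory=dict)
    label: int | None = None


class Network:
    """The assembled model.  Use :func:`build_network` to construct."""

    def __init__(self, config: NetworkConfig):
        cfg = config
        self.config = cfg
        root = np.random.default_rng(cfg.seed)
        # one named stream per population plus one for wiring
        streams = root.spawn(4)
        self.rng_wiring, self.rng_inp, self.rng_hid, self.rng_inprc = streams

        self.inp = PopulationState.zeros(cfg.inp_shape)
        self.hid = PopulationState.zeros(cfg.hid_shape)
        self.inprc = PopulationState.zeros(cfg.inprc_shape)

        sp = cfg.synapse_params()
        self.ff = Projection.create("ff", cfg.inp_shape, cfg.hid_shape, sp,
                                    cfg.n_conn_ff, self.rng_wiring)
        self.fb = Projection.create("fb", cfg.hid_shape, cfg.inprc_shape, sp,
                                    cfg.n_conn_fb, self.rng_wiring)
        self.rec: Projection | None = None
        if cfg.recurrent:
            self.rec = Projection.create("rec", cfg.hid_shape, cfg.hid_shape,
                                         sp, cfg.n_conn_rec, self.rng_wiring)

        if cfg.init_noise > 0:
            for p in self.projections:
                jitter = self.rng_wiring.uniform(
                    -cfg.init_noise, cfg.init_noise, p.traces.p_joint.shape
                )
                p.traces.p_joint *= 1.0 + jitter
                p.refresh_weights()

        self.pattern_count = 0
        self.rewire_log: list[dict] = []

    @property
    def projections(self) -> list[Projection]:
        projs = [self.ff, self.fb]
        if self.rec is not None:
            projs.insert(1, self.rec)
        return projs

    # -- dynamic (non-learned) state, snapshot/restore for eval purity -----
    def dynamic_state(self) -> dict:
        state = {
            "inp": self.inp.copy(), "hid": self.hid.copy(),
            "inprc": self.inprc.copy(),
        }
        for p in self.projections:
            state[p.name] = (p.traces.z_pre.copy(), p.traces.z_post.copy())
        return state

    def restore_dynamic_state(self, state: dict) -> None:
        self.inp, self.hid, self.inprc = (
            state["inp"].copy(), state["hid"].copy(), state["inprc"].copy()
        )
        for p in self.projections:
            z_pre, z_post = state[p.name]
            p.traces.z_pre = z_pre.copy()
            p.traces.z_post = z_post.copy()


def build_network(config: NetworkConfig) -> Network:
    """Build populations and projections; deterministic given the seed."""
    return Network(config)


def _step(net: Network, phase: Phase, I_inp: np.ndarray, I_inprc: np.ndarray,
          learning: bool) -> None:
    """Advance the whole network by one timestep within ``phase``."""
    cfg = net.config
    variant = cfg.activation
    dt = cfg.dt
    binary = cfg.mode == "spiking"

    net.inp.I_ext = I_inp if phase.input_inp else np.zeros_like(I_inp)
    net.inprc.I_ext = I_inprc if phase.input_inprc else np.zeros_like(I_inprc)

    # membranes integrate the previous step's z-traces
    step_membrane(net.inp, [], cfg.tau_m, dt)
    hid_inputs = [(net.ff.traces.z_pre, net.ff.weights, phase.ff)]
    if net.rec is not None:
        hid_inputs.append((net.rec.traces.z_pre, net.rec.weights, phase.rec))
    step_membrane(net.hid, hid_inputs, cfg.tau_m, dt)
    step_membrane(net.inprc, [(net.fb.traces.z_pre, net.fb.weights, phase.fb)],
                  cfg.tau_m, dt)

    net.inp.pi = softmax_by_hypercolumn(net.inp.v, cfg.inp_shape)
    net.hid.pi = softmax_by_hypercolumn(net.hid.v, cfg.hid_shape)
    net.inprc.pi = softmax_by_hypercolumn(net.inprc.v, cfg.inprc_shape)

    net.inp.s = sample_spikes(net.inp.pi, variant, dt, net.rng_inp)
    net.hid.s = sample_spikes(net.hid.pi, variant, dt, net.rng_hid)
    net.inprc.s = sample_spikes(net.inprc.pi, variant, dt, net.rng_inprc)

    step_z_traces(net.ff.traces, net.inp.s, net.hid.s, net.ff.params,
                  require_binary=binary)
    if net.rec is not None:
        step_z_traces(net.rec.traces, net.hid.s, net.hid.s, net.rec.params,
                      require_binary=binary)
    step_z_traces(net.fb.traces, net.hid.s, net.inprc.s, net.fb.params,
                  require_binary=binary)

    if learning and phase.learn:
        for p in net.projections:
            step_p_traces(p.traces, p.params)


def run_pattern(
    net: Network,
    image: np.ndarray,
    mode: str = "eval",
    record_times: tuple[float, ...] = (),
    label: int | None = None,
) -> PatternRecord:
    """Run one pattern through the phase schedule of ``mode``.

    ``record_times`` are seconds after pattern onset (end of the no-input
    phase); the final timestep is always recorded under ``"end"``.  In train
    mode p-traces integrate during the learning-gated phases and bias/weight
    are recomputed on the last step of the pattern; eval mode never learns.
    """
    cfg = net.config
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    schedule = _train_schedule(cfg) if mode == "train" else _eval_schedule(cfg)
    post_onset = schedule.total_duration - schedule.onset
    for t in record_times:
        if t > post_onset + 0.5 * cfg.dt:
            raise ValueError(
                f"record time {t} s exceeds pattern duration {post_onset} s"
            )

    image = np.asarray(image, dtype=float).reshape(-1)
    if image.shape[0] != cfg.inp_shape.n_hyper:
        raise ValueError(
            f"image length {image.shape[0]} != INP hypercolumn count "
            f"{cfg.inp_shape.n_hyper}"
        )
    I_inp = encode_input_current(image, cfg.clip, cfg.log_base)
    I_inprc = I_inp  # INPRC is clamped by the same image when gated

    record = PatternRecord(label=label)
    record_steps = {round(t / cfg.dt): t for t in record_times}
    learning = mode == "train"

    step_in_pattern = 0  # counted from pattern onset
    for phase in schedule.phases:
        n_steps = round(phase.duration / cfg.dt)
        for _ in range(n_steps):
            _step(net, phase, I_inp, I_inprc, learning)
            if phase.name != "no_input":
                step_in_pattern += 1
                if step_in_pattern in record_steps:
                    record.at[record_steps[step_in_pattern]] = _snapshot(net)
    record.at["end"] = _snapshot(net)

    if learning:
        for p in net.projections:
            p.refresh_weights()
        net.pattern_count += 1
    return record


def _snapshot(net: Network) -> dict:
    return {
        "hid_z": net.ff.traces.z_post.copy(),
        "inprc_z": net.fb.traces.z_post.copy(),
        "hid_pi": net.hid.pi.copy(),
        "hid_s": net.hid.s.copy(),
    }


def _structural_step(net: Network) -> None:
    for p in (net.ff, net.fb):
        if p.fully_connected:
            continue
        scores = p.scores()
        new_mask, n_flips = rewire_step(p.mask, scores, net.config.n_flipconn)
        p.set_mask(new_mask)
        active = scores[new_mask.patch]
        net.rewire_log.append({
            "pattern": net.pattern_count, "projection": p.name,
            "flips": n_flips, "score_mean": float(active.mean()),
            "score_std": float(active.std()),
        })


def train(
    net: Network,
    images: np.ndarray,
    n_epochs: int | None = None,
) -> Network:
    """Train on ``images`` (n_patterns x n_pixels, intensities in [0, 1]).

    Runs each pattern in train mode and performs a structural-plasticity
    step every ``n_intvconn`` patterns on the feedforward and feedback
    projections (the recurrent projection is fully connected by default and
    is skipped).  Deterministic given the config seed.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 2 or images.shape[0] == 0:
        raise ValueError("images must be a non-empty (n_patterns, n_pixels) array")
    cfg = net.config
    n_epochs = cfg.n_epochs if n_epochs is None else n_epochs
    order = np.arange(images.shape[0])
    for _epoch in range(n_epochs):
        if cfg.shuffle:
            net.rng_wiring.shuffle(order)
        for idx in order:
            run_pattern(net, images[idx], mode="train")
            if net.pattern_count % cfg.n_intvconn == 0:
                _structural_step(net)
    return net


def evaluate(
    net: Network,
    images: np.ndarray,
    record_times: tuple[float, ...] = (),
    labels: np.ndarray | None = None,
) -> list[PatternRecord]:
    """Run patterns in eval mode; no learning, no state mutation.

    The dynamic state (voltages, activations, z-traces) is snapshotted
    before and restored after, so evaluation leaves the network bit-identical.
    """
    images = np.asarray(images, dtype=float)
    saved = net.dynamic_state()
    records = []
    for k in range(images.shape[0]):
        lab = None if labels is None else int(labels[k])
        records.append(
            run_pattern(net, images[k], mode="eval",
                        record_times=record_times, label=lab)
        )
    net.restore_dynamic_state(saved)
    return records


def collect(records: list[PatternRecord], key: str, time="end") -> np.ndarray:
    """Stack one recorded signal across patterns into (n_patterns, n_units)."""
    return np.stack([r.at[time][key] for r in records])


def reconstruct_image(inprc_z: np.ndarray) -> np.ndarray:
    """ON-pixel probabilities from an INPRC z-trace (ON/OFF pairs)."""
    on, off = inprc_z[0::2], inprc_z[1::2]
    total = on + off
    out = np.full(on.shape, 0.5)
    nz = total > 0
    out[nz] = on[nz] / total[nz]
    return out
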