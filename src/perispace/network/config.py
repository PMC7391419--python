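"""Configuration of the visuo-tactile peri-personal-space network.

The network has two 41 x 41 unisensory sheets — tactile neurons tiling a
20 x 20 cm patch of skin (0.5 cm spacing) and visual neurons tiling a
400 x 400 cm slab of external space (10 cm spacing) — plus a single
multisensory neuron.  Unisensory sheets carry Mexican-hat lateral coupling;
feedforward synapses W converge on the multisensory neuron (uniform from
the tactile sheet, exponentially decaying with distance from the body for
the visual sheet) and feedback synapses B mirror the basal feedforward
pattern.  Only W is plastic, under a gated Hebbian rule with an exponential
forgetting term of time constant tau_H.

Numeric defaults below are the package's shipped operating point: they were
chosen so that the network expresses a sigmoidal RT-by-distance curve with
its central point inside the probed 55-175 cm range for 75 cm/s looming
stimuli, and trial-history recalibration of that central point at
tau_H = 4 s.  Every value can be overridden from a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "GridSpec",
    "NeuronParams",
    "LateralKernel",
    "HebbianConfig",
    "FeedforwardConfig",
    "FeedbackConfig",
    "StimulusSpec",
    "SimulationConfig",
    "NetworkConfig",
    "default_config",
    "CONFIG_REGISTRY",
]


@dataclass
class GridSpec:
    """Geometry of the unisensory sheets.

    ``n_per_side`` neurons per dimension in each sheet; receptive-field
    centres are ``tactile_spacing`` (cm) apart on the skin and
    ``visual_spacing`` (cm) apart in external space, so each sheet spans
    ``(n_per_side - 1) * spacing`` cm per dimension.
    """

    n_per_side: int = 41
    tactile_spacing: float = 0.5   # cm
    visual_spacing: float = 10.0   # cm
    face_halfwidth: float = 10.0   # cm, lateral half-extent of the body part

    def __post_init__(self):
        if self.n_per_side < 3:
            raise ValueError("n_per_side must be >= 3")
        if self.tactile_spacing <= 0 or self.visual_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def tactile_extent(self):
        e = (self.n_per_side - 1) * self.tactile_spacing
        return (e, e)

    @property
    def visual_extent(self):
        e = (self.n_per_side - 1) * self.visual_spacing
        return (e, e)


@dataclass
class NeuronParams:
    """First-order membrane dynamics plus sigmoidal activation.

    ``tau`` (ms) is the membrane time constant; output activity saturates
    between ``f_min`` and ``f_max`` with midpoint at input ``theta`` and
    steepness ``slope``.
    """

    tau: float = 20.0
    f_min: float = 0.0
    f_max: float = 1.0
    theta: float = 12.0
    slope: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.f_min >= self.f_max:
            raise ValueError("f_min must be < f_max")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def activation(self, q):
        t = (np.asarray(q, dtype=float) - self.theta) * self.slope
        return self.f_min + (self.f_max - self.f_min) / (1.0 + np.exp(-t))


@dataclass
class LateralKernel:
    """Mexican-hat (difference-of-Gaussians) lateral coupling.

    Amplitudes and widths are in neuron-index units; near excitation
    requires ``exc_amp > inh_amp`` at zero lag and far inhibition requires
    ``inh_sigma > exc_sigma`` with ``inh_amp > 0``.
    """

    exc_amp: float = 1.2
    exc_sigma: float = 1.0
    inh_amp: float = 0.6
    inh_sigma: float = 4.0

    def __post_init__(self):
        if self.exc_amp < self.inh_amp:
            raise ValueError("kernel must be net excitatory at zero distance")
        if self.inh_amp > 0 and self.inh_sigma <= self.exc_sigma:
            raise ValueError("inhibition must be wider than excitation")

    def kernel_2d(self, radius: int | None = None) -> np.ndarray:
        """Materialised 2-D kernel (for inspection or explicit convolution)."""
        if radius is None:
            radius = int(np.ceil(4 * max(self.exc_sigma, self.inh_sigma, 1e-9)))
        ax = np.arange(-radius, radius + 1, dtype=float)
        r2 = ax[:, None] ** 2 + ax[None, :] ** 2
        out = np.zeros_like(r2)
        if self.exc_amp != 0 and self.exc_sigma > 0:
            out += self.exc_amp * np.exp(-r2 / (2 * self.exc_sigma**2))
        if self.inh_amp != 0 and self.inh_sigma > 0:
            out -= self.inh_amp * np.exp(-r2 / (2 * self.inh_sigma**2))
        return out


@dataclass
class FeedforwardConfig:
    """Basal feedforward synapses onto the multisensory neuron.

    Tactile synapses are uniform at ``w0_tactile`` (their maximum, so they
    sit at saturation from the start).  Visual synapses take their maximum
    ``w0_visual`` on/near the body and decay exponentially with the
    receptive field's distance from it, decay length ``lambda_v`` (cm);
    ``w0_visual`` is also their ceiling, so far-space visual synapses have
    headroom to strengthen.
    """

    w0_tactile: float = 2.2
    w0_visual: float = 26.0
    lambda_v: float = 70.0

    def __post_init__(self):
        if min(self.w0_tactile, self.w0_visual, self.lambda_v) <= 0:
            raise ValueError("feedforward parameters must be positive")


@dataclass
class FeedbackConfig:
    """Feedback synapses from the multisensory neuron (fixed).

    Same spatial pattern as the basal feedforward synapses: uniform
    ``b0_tactile`` onto the tactile sheet, ``b0_visual`` with the same
    exponential fall-off onto the visual sheet.
    """

    b0_tactile: float = 6.0
    b0_visual: float = 2.0


@dataclass
class HebbianConfig:
    """Gated Hebbian reinforcement with exponential forgetting.

    ``rho0`` scales the reinforcement rate per modality (the effective rate
    shrinks to zero as a synapse approaches its ceiling); ``gate_theta`` is
    the postsynaptic activity gate as a fraction of the multisensory
    neuron's maximum activation; ``tau_h`` (s) is the forgetting time
    constant, applied every update step ``update_dt`` (ms) as rate
    ``k_h = update_dt / (1000 * tau_h)`` per step, regardless of activity.
    """

    rho0_tactile: float = 2.4e-4
    rho0_visual: float = 2.4e-4
    gate_theta: float = 0.05
    tau_h: float = 4.0
    update_dt: float = 1.0

    def __post_init__(self):
        if self.rho0_tactile < 0 or self.rho0_visual < 0:
            raise ValueError("rho0 must be >= 0")
        if not 0 < self.gate_theta < 1:
            raise ValueError("gate_theta must be in (0, 1)")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")

    @property
    def k_h(self) -> float:
        """Forgetting rate per update step."""
        return self.update_dt / (1000.0 * self.tau_h)


@dataclass
class StimulusSpec:
    """A localized Gaussian stimulus, static or looming.

    ``sigma`` (cm) is the spatial spread of the stimulus itself; the input a
    neuron receives is this Gaussian filtered by the neuron's receptive
    field.  A looming stimulus starts at ``start_distance`` cm from the body
    and approaches along the midline at ``velocity`` cm/s (position clamped
    at the body); a static stimulus stays at ``position`` (cm from the
    body for visual, cm on the skin for tactile).  ``onset``/``offset`` are
    ms in the trial clock.
    """

    modality: str = "tactile"
    amplitude: float = 13.0
    sigma: float = 0.4
    position: float | tuple | None = None
    start_distance: float | None = None
    velocity: float = 0.0
    onset: float = 0.0
    offset: float = np.inf

    def __post_init__(self):
        if self.modality not in ("tactile", "visual"):
            raise ValueError("modality must be 'tactile' or 'visual'")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")

    def distance_at(self, t_ms: float) -> float:
        """Distance from the body (cm) at trial time ``t_ms`` for looming stimuli."""
        if self.start_distance is None:
            raise ValueError("not a looming stimulus")
        d = self.start_distance - self.velocity * (t_ms - self.onset) / 1000.0
        return max(d, 0.0)


@dataclass
class SimulationConfig:
    """Trial-level simulation settings.

    ``dt`` is the fixed explicit-Euler step (ms); ``p_th`` the summed
    tactile activity that counts as detection; ``rf_sigma_*`` the
    receptive-field widths (cm) that filter stimuli; ``tactile_duration``
    how long the tactile input stays on; ``post_window`` how long past
    tactile onset a trial is simulated (the RT timeout horizon); and
    ``inter_trial_gap`` (s) the stimulus-free time between trials during
    which only forgetting acts.
    """

    dt: float = 1.0
    p_th: float = 4.0
    rf_sigma_tactile: float = 0.5   # cm
    rf_sigma_visual: float = 8.0    # cm
    tactile_duration: float = 300.0  # ms
    post_window: float = 500.0       # ms
    inter_trial_gap: float = 2.0     # s

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class NetworkConfig:
    """Full parameterisation of the network and its simulation protocol."""

    grid: GridSpec = field(default_factory=GridSpec)
    tactile: NeuronParams = field(default_factory=lambda: NeuronParams(slope=2.0))
    visual: NeuronParams = field(default_factory=lambda: NeuronParams(slope=2.0))
    multi: NeuronParams = field(default_factory=lambda: NeuronParams(slope=0.37))
    lateral_tactile: LateralKernel = field(default_factory=LateralKernel)
    lateral_visual: LateralKernel = field(default_factory=LateralKernel)
    feedforward: FeedforwardConfig = field(default_factory=FeedforwardConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    hebbian: HebbianConfig = field(default_factory=HebbianConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    tactile_stimulus: StimulusSpec = field(
        default_factory=lambda: StimulusSpec(modality="tactile", amplitude=14.0, sigma=1.0))
    visual_stimulus: StimulusSpec = field(
        default_factory=lambda: StimulusSpec(modality="visual", amplitude=20.0,
                                             sigma=5.0, start_distance=200.0,
                                             velocity=75.0))

    def __post_init__(self):
        # explicit Euler needs several steps per membrane time constant
        for p in (self.tactile, self.visual, self.multi):
            if p.tau < 5 * self.sim.dt:
                raise ValueError("tau must be >= 5 * dt for stable Euler integration")

    def replace(self, **kwargs) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        kw = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        typemap = {
            "grid": GridSpec, "tactile": NeuronParams, "visual": NeuronParams,
            "multi": NeuronParams, "lateral_tactile": LateralKernel,
            "lateral_visual": LateralKernel, "feedforward": FeedforwardConfig,
            "feedback": FeedbackConfig, "hebbian": HebbianConfig,
            "sim": SimulationConfig, "tactile_stimulus": StimulusSpec,
            "visual_stimulus": StimulusSpec,
        }
        for name, sub in d.items():
            if name not in fields:
                raise ValueError(f"unknown config section {name!r}")
            kw[name] = typemap[name](**sub)
        return cls(**kw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config() -> NetworkConfig:
    """The shipped default operating point ("reference-default")."""
    return NetworkConfig()


CONFIG_REGISTRY = {"reference-default": default_config}
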