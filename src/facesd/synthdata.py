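"""Synthetic trial tables and EEG epochs with the study's statistical structure.

The experiment this package analyzes is an adjustment (reproduction) task on
a circular face-morph continuum: on each trial an irrelevant inducer face
(Face 1) and a target face (Face 2) are shown in sequence at low or high
visibility, and the participant later reproduces Face 2 by stepping through
the wheel.  EEG is recorded throughout and epoched around Face 2 onset.

Because no public dataset exists for this design, this module generates one:

* :func:`generate_trials` lays out the factorial design (participants x
  blocks x trials, balanced visibility, uniform wheel sampling).
* :func:`simulate_responses` draws adjustment responses whose errors are
  pulled toward (attraction) or away from (repulsion) the inducer by a
  configurable amount per distance range, plus Gaussian motor/memory noise,
  occasional lapses, and log-normal reaction times with a slow-tail
  contamination so the RT exclusion rule has work to do.
* :func:`simulate_epochs` builds channel x time x trial voltage tensors from
  Gaussian-windowed ERP component templates (N170-, N250- and LPP-like) with
  scalp topographies defined on an idealized 10-20 montage, an LPP amplitude
  modulation per distance range, and spatially smoothed Gaussian noise.

Per-participant heterogeneity enters as a multiplicative random effect on
the bias pulls and on the LPP distance-range modulation; passing the *same*
latent scale to both generators couples behavior and brain, which is what
the brain-behavior regression stage is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphwheel import MorphWheel, assign_distance_bin

__all__ = [
    "DesignSpec",
    "ResponseModel",
    "ErpModel",
    "ComponentTemplate",
    "SCALP_CHANNELS",
    "MASTOID_CHANNELS",
    "generate_trials",
    "simulate_responses",
    "simulate_epochs",
    "montage_positions",
    "participant_effect_scales",
]

#: The 31-channel extended 10-20 scalp set used throughout.
SCALP_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "PO10", "O1", "O2", "Iz",
)

#: Left / right mastoid reference electrodes.
MASTOID_CHANNELS = ("M1", "M2")

# The idealized montage has no dedicated mastoid positions; TP9/TP10 are the
# conventional stand-in sites directly over the mastoids.
_MASTOID_ALIASES = {"M1": "TP9", "M2": "TP10"}


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of the adjustment task.

    Defaults reproduce the study's design: 28 participants, 8 blocks of 24
    trials each (192 trials per participant, 5,376 in total), half of the
    trials in each block at low and half at high visibility, and both faces
    drawn uniformly and independently from the 141-point morph wheel.
    """

    n_participants: int = 28
    n_blocks: int = 8
    trials_per_block: int = 24
    visibility_split: float = 0.5
    wheel: MorphWheel = field(default_factory=MorphWheel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_blocks, self.trials_per_block) < 1:
            raise ValueError("design dimensions must be positive")
        n_low = self.trials_per_block * self.visibility_split
        if abs(n_low - round(n_low)) > 1e-9:
            raise ValueError(
                "visibility_split x trials_per_block must be an integer "
                f"(got {n_low}); an exact split is impossible otherwise"
            )

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.trials_per_participant


@dataclass(frozen=True)
class ResponseModel:
    """Generative model of adjustment responses.

    The signed adjustment error on a trial is ``pull(delta) * scale_p +
    noise``, rounded to the nearest morph step and wrapped onto the wheel,
    where ``delta`` is the signed inducer-target distance and ``scale_p`` a
    per-participant multiplicative random effect.  ``pull`` is odd in
    ``delta`` (no direction is privileged): positive pulls are attractive
    (error in the direction of the inducer), negative repulsive.

    Two bias shapes are available: per-distance-range constant pulls
    (``bias_shape="bins"``) or a smooth derivative-of-Gaussian curve
    (``bias_shape="dog"``).  The downstream clockwise-minus-counterclockwise
    median bias statistic recovers roughly *twice* the per-trial pull, so the
    default pulls are half the group bias values the analysis is expected to
    show (about -3 close, +1 middle, +2.5 far morph steps).
    """

    bias_shape: str = "bins"
    bin_pulls: dict = field(
        default_factory=lambda: {"close": -1.5, "middle": 0.5, "far": 1.25}
    )
    dog_amplitude: float = 0.0
    dog_width: float = 25.0
    noise_sd: float = 8.0
    lapse_rate: float = 0.02
    rt_median: float = 2.5
    rt_sigma: float = 0.5
    rt_contamination: float = 0.025
    rt_slow_range: tuple = (16.0, 60.0)
    participant_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must be in [0, 1)")
        if not 0 <= self.rt_contamination < 1:
            raise ValueError("rt_contamination must be in [0, 1)")
        if self.bias_shape not in ("bins", "dog"):
            raise ValueError("bias_shape must be 'bins' or 'dog'")

    def pull(self, delta, n_points: int = 141):
        """Mean signed error pull (morph steps) as a function of delta."""
        d = np.asarray(delta, dtype=float)
        if self.bias_shape == "dog":
            w = self.dog_width
            out = self.dog_amplitude * (d / w) * np.exp(0.5 * (1 - (d / w) ** 2))
        else:
            bins = assign_distance_bin(np.asarray(delta), n_points)
            out = np.zeros_like(d)
            for label, p in self.bin_pulls.items():
                out[np.asarray(bins) == label] = p
            out = out * np.sign(d)
        return out


@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component: a Gaussian time course with a scalp topography.

    ``topo_channels`` name the channels at the center(s) of the topography;
    weights fall off as a Gaussian of the 2D scalp distance with width
    ``topo_width`` (fractions of the head radius) and peak at 1.
    """

    name: str
    center_ms: float
    width_ms: float
    amplitude: float  # uV at the topography peak
    topo_channels: tuple
    topo_width: float = 0.35


def _default_components() -> tuple:
    return (
        ComponentTemplate("N170", 170.0, 25.0, -4.0, ("P8", "PO10", "P7", "PO9")),
        ComponentTemplate("N250", 280.0, 45.0, -3.0, ("P8", "PO10", "P7", "PO9")),
        ComponentTemplate("LPP", 500.0, 90.0, 5.0, ("Cz", "CP1", "CP2", "Pz"), 0.45),
    )


@dataclass(frozen=True)
class ErpModel:
    """Generative model of Face-2-locked EEG epochs.

    Epochs span ``window_ms`` around Face 2 onset at ``sampling_rate`` Hz on
    the 31-channel scalp set plus the two mastoids, in microvolts referenced
    to the linked mastoids.  ``lpp_bin_deltas`` adds a distance-range-
    dependent amplitude to the LPP template (the study's key ERP effect: the
    late centroparietal positivity is attenuated after a similar inducer and
    amplified after a dissimilar one).  Noise is white Gaussian, spatially
    smoothed across neighboring channels; optional 1/f temporal coloring is
    off by default.
    """

    channel_names: tuple = SCALP_CHANNELS + MASTOID_CHANNELS
    sampling_rate: float = 512.0
    window_ms: tuple = (-200.0, 1200.0)
    components: tuple = field(default_factory=_default_components)
    lpp_bin_deltas: dict = field(
        default_factory=lambda: {"close": -1.0, "middle": 0.0, "far": 1.0}
    )
    n170_visibility_delta: float = 0.0
    noise_sd: float = 10.0
    spatial_smoothing: float = 0.3
    one_over_f: bool = False
    participant_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lpp = [c for c in self.components if c.name == "LPP"]
        if lpp:
            c = lpp[0]
            if not 400.0 <= c.center_ms <= 600.0:
                raise ValueError("LPP template must peak inside 400-600 ms")

    def times_ms(self) -> np.ndarray:
        """Sample times in ms, on a grid anchored at stimulus onset (0 ms)."""
        sf = self.sampling_rate
        lo = -int(round(-self.window_ms[0] / 1000.0 * sf))
        hi = int(round(self.window_ms[1] / 1000.0 * sf))
        return np.arange(lo, hi + 1) / sf * 1000.0


def montage_positions(channel_names) -> np.ndarray:
    """2D head-schematic coordinates for standard 10-20/10-10 channel names.

    Positions come from the idealized spherical montage (exact left/right
    symmetry, vertex on the polar axis), projected to the plane by azimuthal
    equidistant projection and scaled so the ear-level circle has radius 1.
    Cz maps to the origin.  Mastoids (M1/M2) take the conventional TP9/TP10
    sites.  Stable across calls.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("easycap-M1")
    pos3d = montage.get_positions()["ch_pos"]
    unknown = [
        ch for ch in channel_names
        if _MASTOID_ALIASES.get(ch, ch) not in pos3d
    ]
    if unknown:
        raise ValueError(f"unknown channel name(s): {unknown}")
    out = np.empty((len(channel_names), 2))
    for i, ch in enumerate(channel_names):
        x, y, z = pos3d[_MASTOID_ALIASES.get(ch, ch)]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))
        rho = np.hypot(x, y)
        if rho < 1e-12:
            out[i] = (0.0, 0.0)
        else:
            scale = theta / (np.pi / 2.0)
            out[i] = (x / rho * scale, y / rho * scale)
    return out


def participant_effect_scales(
    n_participants: int, sd: float, seed, heterogeneity: float = 1.0
) -> np.ndarray:
    """Multiplicative per-participant effect scales ``1 + sd*h*z``.

    ``heterogeneity`` > 1 widens the between-participant spread without
    touching the population mean; the coupled brain-behavior generator uses
    a shared draw of these scales for both modalities.
    """
    rng = np.random.default_rng(seed)
    return 1.0 + sd * heterogeneity * rng.standard_normal(n_participants)


def generate_trials(spec: DesignSpec) -> pd.DataFrame:
    """Lay out the trial table: one row per trial, no responses yet.

    Face 1 and Face 2 are independent uniform draws from the wheel;
    visibility is exactly balanced within every block and shuffled.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.wheel.n_points
    rows = []
    n_low = int(round(spec.trials_per_block * spec.visibility_split))
    block_vis = np.array(
        ["low"] * n_low + ["high"] * (spec.trials_per_block - n_low), dtype=object
    )
    for p in range(1, spec.n_participants + 1):
        for b in range(1, spec.n_blocks + 1):
            vis = rng.permutation(block_vis)
            f1 = rng.integers(0, n, spec.trials_per_block)
            f2 = rng.integers(0, n, spec.trials_per_block)
            for t in range(spec.trials_per_block):
                rows.append((p, b, t + 1, vis[t], int(f1[t]), int(f2[t])))
    return pd.DataFrame(
        rows, columns=["participant", "block", "trial", "visibility", "face1", "face2"]
    )


def _derive_columns(table: pd.DataFrame, wheel: MorphWheel) -> pd.DataFrame:
    from .behavior import add_derived_columns

    return add_derived_columns(table, wheel)


def simulate_responses(
    trials: pd.DataFrame,
    model: ResponseModel,
    seed,
    wheel: MorphWheel | None = None,
    effect_scale=None,
) -> pd.DataFrame:
    """Draw adjustment responses and reaction times for a trial table.

    Returns a copy of ``trials`` with ``response`` and ``rt`` columns plus
    the derived ``delta`` / ``error`` / ``bin`` columns.  ``effect_scale``
    optionally supplies per-participant multiplicative bias scales (mapping
    participant id -> scale); otherwise scales are drawn as
    ``N(1, participant_sd)`` from ``seed``.
    """
    wheel = wheel or MorphWheel()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = wheel.n_points

    pids = out["participant"].to_numpy()
    unique_pids = np.unique(pids)
    if effect_scale is None:
        scales = dict(
            zip(
                unique_pids.tolist(),
                participant_effect_scales(
                    len(unique_pids), model.participant_sd, rng.integers(2**31)
                ),
            )
        )
    else:
        scales = dict(effect_scale)
        missing = [p for p in unique_pids if p not in scales]
        if missing:
            raise ValueError(f"effect_scale missing participants: {missing}")
    scale_per_trial = np.array([scales[p] for p in pids])

    from .morphwheel import signed_circular_distance

    delta = signed_circular_distance(out["face1"].to_numpy(), out["face2"].to_numpy(), n)
    pull = model.pull(delta, n) * scale_per_trial
    err = np.rint(pull + rng.normal(0.0, model.noise_sd, len(out))).astype(int)
    response = np.mod(out["face2"].to_numpy() + err, n)

    lapse = rng.random(len(out)) < model.lapse_rate
    response[lapse] = rng.integers(0, n, int(lapse.sum()))

    rt = rng.lognormal(np.log(model.rt_median), model.rt_sigma, len(out))
    slow = rng.random(len(out)) < model.rt_contamination
    rt[slow] = rng.uniform(*model.rt_slow_range, int(slow.sum()))

    out["response"] = response
    out["rt"] = rt
    return _derive_columns(out, wheel)


def _topography(model: ErpModel, component: ComponentTemplate) -> np.ndarray:
    pos = montage_positions(model.channel_names)
    # centers are montage sites, not necessarily simulated channels
    center_pos = montage_positions(component.topo_channels)
    d2 = ((pos[:, None, :] - center_pos[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * component.topo_width**2)).max(axis=1)
    # mastoids carry no cortical signal in the model (they are the reference)
    for ch in MASTOID_CHANNELS:
        if ch in model.channel_names:
            w[model.channel_names.index(ch)] = 0.0
    return w


def _smoothing_kernel(model: ErpModel) -> np.ndarray:
    """Row-L2-normalized Gaussian channel-mixing kernel for spatial noise."""
    pos = montage_positions(model.channel_names)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2.0 * model.spatial_smoothing**2))
    return k / np.sqrt((k**2).sum(axis=1, keepdims=True))


def simulate_epochs(
    trials: pd.DataFrame,
    model: ErpModel,
    seed,
    effect_scale=None,
):
    """Simulate a channels x samples x trials epoch tensor for a trial table.

    Each trial's signal is the sum of the component templates; the LPP
    template amplitude additionally receives ``lpp_bin_deltas[bin] *
    scale_p``, and the N170 amplitude receives ``n170_visibility_delta`` on
    high-visibility trials.  Noise is spatially smoothed white Gaussian of
    per-channel standard deviation ``noise_sd``.  Deterministic given
    ``seed``.  Requires the derived ``bin`` column on ``trials``.
    """
    from .erp import Epochs

    if "bin" not in trials.columns:
        raise ValueError("trials must carry distance bins (run simulate_responses "
                         "or behavior.add_derived_columns first)")
    rng = np.random.default_rng(seed)
    times = model.times_ms()
    n_ch, n_t, n_trials = len(model.channel_names), len(times), len(trials)

    pids = trials["participant"].to_numpy()
    unique_pids = np.unique(pids)
    if effect_scale is None:
        scales = dict(
            zip(
                unique_pids.tolist(),
                participant_effect_scales(
                    len(unique_pids), model.participant_sd, rng.integers(2**31)
                ),
            )
        )
    else:
        scales = dict(effect_scale)
    scale_per_trial = np.array([scales.get(p, 1.0) for p in pids])

    bins = trials["bin"].to_numpy()
    vis = trials["visibility"].to_numpy()

    data = np.zeros((n_ch, n_t, n_trials))
    for comp in model.components:
        topo = _topography(model, comp)
        g = np.exp(-((times - comp.center_ms) ** 2) / (2.0 * comp.width_ms**2))
        amp = np.full(n_trials, comp.amplitude, dtype=float)
        if comp.name == "LPP":
            bin_delta = np.array(
                [model.lpp_bin_deltas.get(b, 0.0) for b in bins]
            )
            amp = amp + bin_delta * scale_per_trial
        if comp.name == "N170" and model.n170_visibility_delta:
            amp = amp + model.n170_visibility_delta * (vis == "high")
        data += topo[:, None, None] * g[None, :, None] * amp[None, None, :]

    noise = rng.normal(0.0, model.noise_sd, size=(n_ch, n_t, n_trials))
    if model.one_over_f:
        freqs = np.fft.rfftfreq(n_t, d=1.0 / model.sampling_rate)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])
        shaping /= np.sqrt((shaping**2).mean())
        noise = np.fft.irfft(
            np.fft.rfft(noise, axis=1) * shaping[None, :, None], n=n_t, axis=1
        )
    kernel = _smoothing_kernel(model)
    noise = np.einsum("ij,jkt->ikt", kernel, noise)
    data += noise

    return Epochs(
        data=data,
        channel_names=list(model.channel_names),
        positions=montage_positions(model.channel_names),
        sfreq=model.sampling_rate,
        times=times,
        trials=trials.reset_index(drop=True),
        reference="linked_mastoid",
    )
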