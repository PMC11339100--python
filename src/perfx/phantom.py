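"""Digital CT-perfusion phantom.

Builds ground-truth perfusion scenes — an ellipsoidal brain inside a skull
shell surrounded by air, with a wedge-shaped hypoperfused lesion (delayed
bolus arrival, reduced flow) in one hemisphere — and renders them into noisy
4D Hounsfield-unit time series under two acquisition timings:

* ``AcquisitionProtocol.mdctp_like`` — multidetector CT perfusion: 30 fast
  frames (0.5 s volume time) covering ~47 s.
* ``AcquisitionProtocol.fdctp_like`` — flat-panel (C-arm) CT perfusion:
  10 rotational sweeps of 5 s with a 1 s turnaround; the first two sweeps
  are contrast-free mask runs.

The forward model is the standard indicator-dilution convolution

    c(t) = f * (AIF (*) R)(t - delay),    R(t) = exp(-t / MTT)

with ``f`` the blood flow, the arterial input function (AIF) modelled as a
gamma variate, and contrast concentration expressed directly as HU
enhancement above baseline.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .engine import TimeSeries4D

# tissue labels
AIR = 0
SKULL = 1
WHITE = 2
GRAY = 3
VESSEL = 4

#: baseline (pre-contrast) Hounsfield units per tissue label
BASELINE_HU = {AIR: -1000.0, SKULL: 1000.0, WHITE: 30.0, GRAY: 40.0, VESSEL: 50.0}

#: ml/100g/min -> fraction of voxel blood volume exchanged per second
FLOW_PER_SECOND = 1.0 / 6000.0


@dataclasses.dataclass(frozen=True)
class AIFModel:
    """Gamma-variate arterial input function, in HU enhancement.

    c(t) = amplitude * (t - t0)^alpha * exp(-(t - t0)/beta)  for t > t0, else 0.
    """

    amplitude: float
    t0: float = 15.0
    alpha: float = 3.0
    beta: float = 1.5

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        s = t - self.t0
        out = np.zeros_like(s)
        pos = s > 0
        out[pos] = self.amplitude * s[pos] ** self.alpha * np.exp(-s[pos] / self.beta)
        return out

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        ab = self.alpha * self.beta
        return self.amplitude * ab**self.alpha * math.exp(-self.alpha)

    def integral(self) -> float:
        """Analytic total area under the curve."""
        return self.amplitude * math.gamma(self.alpha + 1) * self.beta ** (self.alpha + 1)

    @classmethod
    def with_peak(cls, peak: float = 200.0, t0: float = 15.0, alpha: float = 3.0,
                  beta: float = 1.5) -> "AIFModel":
        """Construct a gamma variate scaled to a given peak enhancement."""
        ab = alpha * beta
        amplitude = peak / (ab**alpha * math.exp(-alpha))
        return cls(amplitude=amplitude, t0=t0, alpha=alpha, beta=beta)


def default_aif() -> AIFModel:
    """Default bolus: ~200 HU arterial peak, onset 15 s after injection."""
    return AIFModel.with_peak(200.0)


@dataclasses.dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing model: frame start times, per-frame integration windows, mask runs."""

    frame_times: np.ndarray
    durations: np.ndarray
    n_mask: int
    label: str

    def __post_init__(self):
        t = np.asarray(self.frame_times, dtype=float)
        d = np.asarray(self.durations, dtype=float)
        if d.ndim == 0:
            d = np.full_like(t, float(d))
        if t.ndim != 1 or t.size < 1 or d.shape != t.shape:
            raise ValueError("frame_times and durations must be matching 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if np.any(t[:-1] + d[:-1] > t[1:] + 1e-9):
            raise ValueError("frame integration windows overlap")
        if not 0 <= self.n_mask < t.size:
            raise ValueError("mask-frame count out of range")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "durations", d)

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def frame_centers(self) -> np.ndarray:
        return self.frame_times + self.durations / 2.0

    @property
    def span(self) -> float:
        """Total acquisition span: end of last window minus start of first."""
        return float(self.frame_times[-1] + self.durations[-1] - self.frame_times[0])

    @classmethod
    def mdctp_like(cls, n_frames: int = 30, pitch: float = 1.6,
                   duration: float = 0.5) -> "AcquisitionProtocol":
        """Multidetector protocol: 30 contrast phases in ~47 s, no mask runs."""
        times = np.arange(n_frames) * pitch
        return cls(times, np.full(n_frames, duration), n_mask=0, label="mdctp")

    @classmethod
    def fdctp_like(cls, n_sweeps: int = 10, sweep: float = 5.0, turnaround: float = 1.0,
                   n_mask: int = 2) -> "AcquisitionProtocol":
        """Flat-panel protocol: 10 sweeps at 6 s pitch, first two are mask runs."""
        times = np.arange(n_sweeps) * (sweep + turnaround)
        return cls(times, np.full(n_sweeps, sweep), n_mask=n_mask, label="fdctp")


@dataclasses.dataclass
class PerfusionScene:
    """Ground-truth perfusion scene on a voxel grid.

    ``cbf`` is in ml/100g/min, ``mtt`` and ``delay`` in seconds. The midline
    plane index splits the grid into a left hemisphere (x < midline) and a
    right hemisphere (x >= midline).
    """

    labels: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    delay: np.ndarray
    baseline_hu: np.ndarray
    spacing: tuple[float, float, float]
    midline: int
    extent: np.ndarray
    core: np.ndarray

    def __post_init__(self):
        brain = self.brain_mask
        if np.any(self.cbf[brain] <= 0) or np.any(self.mtt[brain] <= 0):
            raise ValueError("CBF and MTT must be positive on brain tissue")
        if np.any(self.delay < 0):
            raise ValueError("bolus delay must be non-negative")
        if np.any(self.core & ~self.extent):
            raise ValueError("core mask must be a subset of the extent mask")
        if np.any(self.extent & ~brain):
            raise ValueError("lesion masks must lie in brain tissue")
        left = self.extent[: self.midline].any()
        right = self.extent[self.midline:].any()
        if left and right:
            raise ValueError("lesion must lie in a single hemisphere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return (self.labels == WHITE) | (self.labels == GRAY)

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.labels == VESSEL

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def lesion_side(self) -> str:
        return "left" if self.extent[: self.midline].any() else "right"

    def ground_truth(self, aif: AIFModel | None = None, dt: float = 0.1) -> "PhantomGroundTruth":
        """True parameter maps and lesion volumes for recovery tests.

        True Tmax equals the bolus delay (the exponential residue peaks at its
        onset); true TTP is computed from noiseless curves on a fine grid,
        relative to the AIF peak.
        """
        aif = aif or default_aif()
        brain = self.brain_mask
        tmax = np.where(brain, self.delay, 0.0)
        t_end = aif.t0 + self.delay.max() + 8 * self.mtt[brain].max() + 6 * aif.beta * aif.alpha
        t = np.arange(0.0, t_end, dt)
        flow = self.cbf / 6000.0
        params = np.stack([flow[brain], self.mtt[brain], self.delay[brain]], axis=1)
        uniq, inv = np.unique(params, axis=0, return_inverse=True)
        ttp_u = np.empty(len(uniq))
        aif_peak_t = t[np.argmax(aif(t))]
        for i, (f, m, d) in enumerate(uniq):
            c = tissue_curve(f, m, d, aif, t)
            ttp_u[i] = max(t[np.argmax(c)] - aif_peak_t, 0.0)
        ttp = np.zeros(self.shape)
        ttp[brain] = ttp_u[inv]
        vox_ml = self.voxel_volume_ml
        return PhantomGroundTruth(
            cbf=np.where(brain, self.cbf, 0.0),
            mtt=np.where(brain, self.mtt, 0.0),
            delay=np.where(brain, self.delay, 0.0),
            tmax=tmax,
            ttp=ttp,
            extent=self.extent.copy(),
            core=self.core.copy(),
            brain=brain,
            extent_ml=float(self.extent.sum()) * vox_ml,
            core_ml=float(self.core.sum()) * vox_ml,
        )


@dataclasses.dataclass
class PhantomGroundTruth:
    """Per-voxel true maps and masks of a scene, plus scalar lesion volumes (ml)."""

    cbf: np.ndarray
    mtt: np.ndarray
    delay: np.ndarray
    tmax: np.ndarray
    ttp: np.ndarray
    extent: np.ndarray
    core: np.ndarray
    brain: np.ndarray
    extent_ml: float
    core_ml: float


def make_default_scene(seed: int, lesion_delay: float = 8.0,
                       lesion_cbf_fraction: float = 0.4,
                       core_cbf_fraction: float = 0.15,
                       shape: tuple[int, int, int] = (64, 64, 24),
                       spacing: tuple[float, float, float] = (2.0, 2.0, 4.0),
                       baseline_delay: float = 2.0) -> PerfusionScene:
    """Build the default phantom scene: brain + skull + one wedge lesion.

    The lesion emulates a middle-cerebral-artery territory deficit: a cone
    ("wedge") from the brain centre into the left hemisphere with bolus
    arrival delayed by ``lesion_delay`` and CBF scaled by
    ``lesion_cbf_fraction`` (hypoperfused extent) and ``core_cbf_fraction``
    (infarct core, a narrower cone inside the extent). The extra delay is
    graded across the wedge — from 70% of ``lesion_delay`` at the angular
    rim to 100% on the axis — emulating the periphery-to-centre severity
    gradient of a vascular territory. The seed jitters the wedge
    orientation and width, so different seeds give different lesion
    volumes; the construction is deterministic given the seed.

    Brain tissue carries a smooth, spatially heterogeneous bolus-transit
    delay field centred on ``baseline_delay`` (clipped to +/- 1 s, quantised
    to 0.25 s) so that healthy-hemisphere Tmax statistics are dispersed and
    non-degenerate, as in vivo. The field is mirror-symmetric about the
    midline, so homologous voxels share a baseline and the lesion's extra
    delay is exactly ``lesion_delay`` relative to the contralateral side.
    """
    if not 0 < core_cbf_fraction < lesion_cbf_fraction < 1:
        raise ValueError("need 0 < core_cbf_fraction < lesion_cbf_fraction < 1")
    if lesion_delay <= 0:
        raise ValueError("lesion_delay must be positive")
    shape = tuple(int(n) for n in shape)
    if min(shape[:2]) < 24 or shape[2] < 10:
        raise ValueError("grid too small to contain skull, brain and lesion")

    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    center = (np.array(shape) - 1) / 2.0
    sp = np.asarray(spacing, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    pos = (idx - center) * sp  # physical offsets from grid centre, mm

    half = center * sp
    semi = half * np.array([0.78, 0.78, 0.75])  # brain semi-axes, mm
    r = np.sqrt(((pos / semi) ** 2).sum(axis=-1))

    labels = np.full(shape, AIR, dtype=np.int8)
    labels[(r > 1.0) & (r <= 1.12)] = SKULL
    labels[r <= 1.0] = GRAY
    labels[r <= 0.55] = WHITE

    # wedge lesion: a cone from the brain centre into the left hemisphere
    azim = math.radians(rng.uniform(160.0, 200.0))
    elev = math.radians(rng.uniform(-10.0, 10.0))
    axis = np.array([math.cos(azim) * math.cos(elev),
                     math.sin(azim) * math.cos(elev),
                     math.sin(elev)])
    half_angle = math.radians(rng.uniform(38.0, 55.0))
    dist = np.linalg.norm(pos, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (pos @ axis) / np.where(dist > 0, dist, np.inf)
    midline = nx // 2
    brain = (labels == WHITE) | (labels == GRAY)
    in_left = idx[..., 0] < midline
    extent = brain & in_left & (cosang >= math.cos(half_angle))
    core = brain & in_left & (cosang >= math.cos(0.7 * half_angle))
    if not core.any():
        raise ValueError("grid too small: lesion core is empty")

    cbf = np.zeros(shape)
    mtt = np.zeros(shape)
    delay = np.zeros(shape)
    cbf[labels == GRAY] = 60.0
    cbf[labels == WHITE] = 40.0
    mtt[labels == GRAY] = 4.0
    mtt[labels == WHITE] = 5.0
    field = rng.normal(0.0, 1.0, shape)
    field = ndimage.gaussian_filter(field, sigma=(4.0, 4.0, 2.0))
    sd = field.std()
    if sd > 0:
        field *= 0.4 / sd
    field += baseline_delay
    field = np.clip(field, baseline_delay - 1.0, baseline_delay + 1.0)
    for x in range(midline):          # mirror symmetry about the midline
        field[nx - 1 - x] = field[x]
    field = np.round(field * 4.0) / 4.0
    delay[brain] = field[brain]
    # severe ischemia flattens the gray/white flow contrast: lesion CBF is a
    # uniform fraction of the reference (deep white matter) value
    cbf[extent] = lesion_cbf_fraction * 40.0
    cbf[core] = core_cbf_fraction * 40.0
    mtt[extent] *= 1.5
    mtt[core] *= 2.0 / 1.5
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    severity = 0.7 + 0.3 * (1.0 - ang / half_angle)
    delay[extent] += lesion_delay * severity[extent]
    # quantise to 0.25 s so rendering can group voxels into few unique curves
    delay[brain] = np.round(delay[brain] * 4.0) / 4.0

    # vessel cluster in the healthy (right) hemisphere carrying the pure AIF;
    # large enough that its interior survives a 3x3x3 median filter
    vx, vy, vz = midline + 3, ny // 2, nz // 2
    labels[vx:vx + 4, vy - 2:vy + 2, vz - 1:vz + 2] = VESSEL
    vessel = labels == VESSEL
    cbf[vessel] = 100.0
    mtt[vessel] = 1.0
    delay[vessel] = 0.0
    extent &= ~vessel
    core &= ~vessel

    baseline = np.empty(shape)
    for lab, hu in BASELINE_HU.items():
        baseline[labels == lab] = hu

    return PerfusionScene(labels=labels, cbf=cbf, mtt=mtt, delay=delay,
                          baseline_hu=baseline, spacing=tuple(sp), midline=midline,
                          extent=extent, core=core)


def tissue_curve(cbf, mtt, delay, aif, t) -> np.ndarray:
    """Noiseless tissue concentration curve on the uniform time grid ``t``.

    ``aif`` may be an :class:`AIFModel` (evaluated analytically and convolved
    on an internally refined grid for quadrature accuracy) or a sampled
    concentration array on ``t`` (discrete convolution on the given grid, so
    that a unit impulse reproduces ``cbf * exp(-t/mtt)`` exactly).

    ``cbf`` here is the dimensionless flow multiplier of the convolution
    (callers working in ml/100g/min divide by 6000 first).
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t must be a 1D grid with at least 2 samples")
    steps = np.diff(t)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("time grid must be uniformly spaced")
    if mtt <= 0:
        raise ValueError("mtt must be positive")

    if isinstance(aif, AIFModel):
        refine = 10
        dtf = dt / refine
        n_f = (t.size - 1) * refine + 1
        tf = t[0] + np.arange(n_f) * dtf
        a = aif(tf - delay)
        res = np.exp(-(tf - tf[0]) / mtt)
        conv = fftconvolve(a, res)[:n_f]
        # trapezoid endpoint correction of the convolution quadrature
        c = cbf * dtf * (conv - 0.5 * a[0] * res - 0.5 * a * res[0])
        c = c[::refine]
    else:
        a = np.asarray(aif, dtype=float)
        if a.shape != t.shape:
            raise ValueError("sampled AIF must share the time grid")
        if delay != 0:
            a = np.interp(t - delay, t, a, left=0.0, right=0.0)
        res = np.exp(-(t - t[0]) / mtt)
        c = cbf * dt * fftconvolve(a, res)[: t.size]
    return np.maximum(c, 0.0)


def render(scene: PerfusionScene, aif: AIFModel, protocol: AcquisitionProtocol,
           noise_sd: float = 0.0, seed: int = 0) -> TimeSeries4D:
    """Render a scene into a 4D HU series under an acquisition protocol.

    Each frame holds baseline HU plus the mean of the voxel's noiseless
    concentration curve over that frame's integration window (a slow sweep
    therefore averages the curve over 5 s), plus i.i.d. Gaussian noise.
    Mask frames contain baseline (plus noise) only.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 0.1
    t_end = protocol.frame_times[-1] + protocol.durations[-1] + dt
    tf = np.arange(0.0, t_end, dt)

    brain = scene.brain_mask
    flow = scene.cbf / 6000.0
    params = np.stack([flow[brain], scene.mtt[brain], scene.delay[brain]], axis=1)
    uniq, inv = np.unique(params, axis=0, return_inverse=True)
    curves = np.stack([tissue_curve(f, m, d, aif, tf) for f, m, d in uniq])
    vessel_curve = aif(tf)
    vessel = scene.vessel_mask

    frames = np.empty((protocol.n_frames,) + scene.shape)
    for i in range(protocol.n_frames):
        frame = scene.baseline_hu.copy()
        if i >= protocol.n_mask:
            start = protocol.frame_times[i]
            sel = (tf >= start) & (tf < start + protocol.durations[i])
            frame[brain] += curves[:, sel].mean(axis=1)[inv]
            frame[vessel] += vessel_curve[sel].mean()
        frames[i] = frame
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)

    return TimeSeries4D(data=frames, frame_times=protocol.frame_times.copy(),
                        durations=protocol.durations.copy(), n_mask=protocol.n_mask,
                        spacing=scene.spacing)
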