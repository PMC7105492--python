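"""Synthetic ground-truth generators for every input the analysis consumes.

Each generator is a pure function of its parameter record: the record carries a
mandatory ``seed`` and identical parameters yield bit-identical outputs.  The
generators emulate the raw material of a slice-physiology study of astrocyte
remodeling:

* dye-filled astrocyte images — a bright soma, filamentous branches, and a dim
  unresolved "leaflet" field whose intensity encodes a known volume fraction;
* dye-coupled cell networks with somatic fluorescence decaying exponentially
  with 3-D distance from the patched cell;
* immunofluorescence-like puncta frames (small bright clusters placed by a
  hard-core point process on a smooth background);
* stimulus-locked patch-clamp sweeps built by strict linear superposition of a
  fast transporter-like kernel and a slow potassium-like kernel;
* field-EPSP amplitude time series around a high-frequency-stimulation (HFS)
  induction, for long-term-potentiation (LTP) quantification.

Noise is additive Gaussian for images and current traces and multiplicative
for fluorescence/amplitude series; kernels are phenomenological, not
biophysical.  All rasters default to 0.25 µm/px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .ephys import SweepSet

__all__ = [
    "ImagingParams",
    "CouplingParams",
    "PunctaParams",
    "SweepParams",
    "StepParams",
    "LTPSeriesParams",
    "LabeledImage",
    "CoupledNetwork",
    "LTPSeries",
    "gen_astrocyte_image",
    "gen_coupled_network",
    "gen_puncta_frame",
    "gen_astro_sweeps",
    "gen_step_response",
    "gen_ltp_series",
    "biexp_kernel",
    "save_image",
    "load_image",
    "save_network",
    "load_network",
    "save_sweeps",
    "load_sweeps",
    "save_ltp_series",
    "load_ltp_series",
]

DEFAULT_PIXEL_SIZE_UM = 0.25


def _jsonable(obj):
    """Canonicalize ground truth through JSON so annotations compare equal
    after a serialization round trip (tuples become lists, etc.)."""
    return json.loads(json.dumps(obj))


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class LabeledImage:
    """Intensity raster(s) with physical pixel size and ground-truth annotations.

    ``data`` has shape (n_planes, ny, nx).  ``ground_truth`` is a plain
    JSON-serializable dict; ``truth_masks`` holds boolean rasters (e.g. the
    rendered branch skeleton) that live only in memory and are rebuilt by the
    generator rather than serialized.
    """

    data: np.ndarray
    pixel_size_um: float
    ground_truth: dict = field(default_factory=dict)
    truth_masks: dict = field(default_factory=dict)

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    def plane(self, index: int | None = None) -> np.ndarray:
        """A single 2-D plane; default is the middle of the stack."""
        if index is None:
            index = self.data.shape[0] // 2
        return self.data[index]


@dataclass
class CoupledNetwork:
    """Per-cell 3-D positions (µm) and soma fluorescence normalized to the
    patched cell (cell 0, fluorescence 1 at distance 0)."""

    cells: pd.DataFrame  # columns: cell_id, x, y, z, fluorescence, is_patched
    ground_truth: dict = field(default_factory=dict)

    @property
    def patched(self) -> pd.Series:
        return self.cells[self.cells.is_patched].iloc[0]


@dataclass
class LTPSeries:
    """fEPSP amplitude time course with an HFS marker (times in minutes)."""

    times_min: np.ndarray
    amplitudes: np.ndarray
    hfs_time_min: float
    ground_truth: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass
class ImagingParams:
    """Dye-filled astrocyte image.  ``soma_peak`` plays the role of the
    maximal soma fluorescence F_max and ``background`` of F_0 in the
    volume-fraction estimate VF = (F - F0)/(Fmax - F0)."""

    frame_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    soma_center_um: tuple[float, float] | None = None  # default: frame center
    soma_radius_um: float = 4.0
    soma_peak: float = 200.0
    background: float = 10.0
    leaflet_vf: float = 0.032
    n_branches: int = 6
    branch_length_um: float = 30.0
    branch_width_um: float = 0.75
    noise_sd: float = 0.0
    n_planes: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.leaflet_vf <= 1.0:
            raise ValueError("leaflet_vf must be in [0, 1]")
        if not self.soma_peak > self.background >= 0.0:
            raise ValueError("require soma_peak > background >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class CouplingParams:
    """Dye-coupled astrocyte network.  ``length_constant_um`` is the ground
    truth of the coupling length constant C_lambda in F(d) = exp(-d/C_lambda)."""

    n_cells: int = 13  # total, including the patched cell
    length_constant_um: float = 19.9
    max_distance_um: float = 100.0
    min_distance_um: float = 15.0
    noise_sd: float = 0.0  # fractional (multiplicative) fluorescence noise
    seed: int = 42

    def __post_init__(self) -> None:
        if self.length_constant_um <= 0:
            raise ValueError("length_constant_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class PunctaParams:
    """Puncta-stained frame: bright disks on a smooth background.

    Disks of ``diameter_um`` are placed by a hard-core point process
    (``min_separation_um`` enforced; default twice the diameter) with the
    expected count ``density_per_um2`` x frame area.  Rendering uses
    4x-supersampled area coverage followed by a Gaussian point-spread
    function of width ``psf_sigma_um``, emulating a confocal acquisition.
    ``background_gradient`` is the total linear intensity ramp across the
    frame (0 disables it).
    """

    density_per_um2: float = 0.02
    diameter_um: float = 1.4
    amplitude: float = 30.0
    background: float = 2.0
    background_gradient: float = 1.0
    noise_sd: float = 1.5
    frame_size_um: tuple[float, float] = (50.0, 50.0)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    min_separation_um: float | None = None
    psf_sigma_um: float = 0.08
    seed: int = 42

    def __post_init__(self) -> None:
        if self.diameter_um < 2.0 * self.pixel_size_um:
            raise ValueError("diameter_um must be at least 2 pixels")
        cover = self.density_per_um2 * np.pi * (self.diameter_um / 2.0) ** 2
        if cover >= 0.2:
            raise ValueError(
                f"expected coverage fraction {cover:.2f} >= 0.2: clusters would "
                "not stay separable; lower density or diameter"
            )

    @property
    def separation_um(self) -> float:
        return (2.0 * self.diameter_um if self.min_separation_um is None
                else self.min_separation_um)


@dataclass
class SweepParams:
    """Stimulus-locked astrocytic current sweeps.

    Responses are built by strict linear superposition of per-stimulus
    kernels, so the 5-stimulus trace minus the 4-stimulus trace equals the
    fifth-stimulus kernel exactly before noise.  Kernels are peak-normalized
    differences of exponentials ``(amplitude_pA, tau_rise_ms, tau_decay_ms)``
    with inward current negative.  ``*_amp_factors`` / ``*_tau_factors``
    multiply each stimulus' kernel amplitude / decay time constant.
    """

    sampling_rate_hz: float = 5000.0
    stim_times_s: tuple[float, ...] = (0.5, 0.52, 0.54, 0.56, 0.58)
    sweep_duration_s: float = 2.0
    glut_kernel: tuple[float, float, float] = (-100.0, 1.0, 8.0)
    k_kernel: tuple[float, float, float] = (-30.0, 20.0, 300.0)
    glut_amp_factors: tuple[float, ...] | None = None
    k_amp_factors: tuple[float, ...] | None = None
    glut_tau_factors: tuple[float, ...] | None = None
    k_tau_factors: tuple[float, ...] | None = None
    holding_artifact: str = "none"  # "none" | "stim"
    noise_sd: float = 0.0  # pA
    n_sweeps: int = 10
    include_tboa: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if list(self.stim_times_s) != sorted(self.stim_times_s):
            raise ValueError("stim_times_s must be sorted")
        if len(self.stim_times_s) != 5:
            raise ValueError("the protocol uses 5 stimuli (conditions 1/4/5)")
        if self.holding_artifact not in ("none", "stim"):
            raise ValueError("holding_artifact must be 'none' or 'stim'")

    def factors(self, name: str) -> np.ndarray:
        n = len(self.stim_times_s)
        v = getattr(self, name)
        if v is None:
            return np.ones(n)
        v = np.asarray(v, dtype=float)
        if v.shape != (n,):
            raise ValueError(f"{name} must have one entry per stimulus")
        return v


@dataclass
class StepParams:
    """Voltage-step current response of a passive (ohmic) astrocyte: a fast
    capacitive transient relaxing onto an ohmic plateau dV/R."""

    resistance_mohm: float = 30.0
    dv_mv: float = -5.0
    sampling_rate_hz: float = 5000.0
    pre_s: float = 0.1
    step_s: float = 0.3
    post_s: float = 0.1
    cap_tau_ms: float = 2.0
    cap_amp_factor: float = 3.0  # transient peak as multiple of the plateau
    noise_sd: float = 0.0  # pA
    n_sweeps: int = 1
    seed: int = 42


@dataclass
class LTPSeriesParams:
    """fEPSP amplitude series around HFS.  ``potentiation_factor`` is the
    asymptotic post/baseline amplitude ratio; the baseline mean defines 100%."""

    baseline_minutes: float = 15.0
    post_minutes: float = 60.0
    sample_interval_s: float = 20.0
    potentiation_factor: float = 1.5
    onset_tau_min: float = 3.0
    amplitude_noise_cv: float = 0.0
    baseline_amplitude: float = 0.2  # mV, arbitrary raw scale
    seed: int = 42

    def __post_init__(self) -> None:
        if self.potentiation_factor <= 0:
            raise ValueError("potentiation_factor must be positive")


# --------------------------------------------------------------------------
# astrocyte image
# --------------------------------------------------------------------------

def _pixel_grid_um(shape: tuple[int, int], px: float) -> tuple[np.ndarray, np.ndarray]:
    """(y, x) coordinates of pixel centers in µm."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return (yy + 0.5) * px, (xx + 0.5) * px


def gen_astrocyte_image(params: ImagingParams) -> LabeledImage:
    """Render a dye-filled astrocyte with known leaflet volume fraction.

    The raster contains: a soma disk at ``soma_peak``; ``n_branches`` straight
    filaments radiating from the soma at ``soma_peak``; an unresolved leaflet
    field covering the astrocyte domain at
    ``background + leaflet_vf * (soma_peak - background)``; pure background
    elsewhere, including a dye-free circle (diameter 10 µm) near the frame
    corner farthest from the soma, annotated for background estimation.
    """
    px = params.pixel_size_um
    w_um, h_um = params.frame_size_um
    nx, ny = int(round(w_um / px)), int(round(h_um / px))
    center = (params.soma_center_um if params.soma_center_um is not None
              else (w_um / 2.0, h_um / 2.0))
    cx, cy = center

    # the analysis annulus (out to 30 µm) must fit in the frame
    margin = min(cx, cy, w_um - cx, h_um - cy)
    if margin < 30.0:
        raise ValueError(
            "frame too small: soma center must be >= 30 µm from every edge "
            f"(got {margin:.1f} µm)"
        )

    arbor_radius = params.branch_length_um + 5.0
    # dye-free background circle in the corner farthest from the soma
    corners = [(6.0, 6.0), (w_um - 6.0, 6.0), (6.0, h_um - 6.0),
               (w_um - 6.0, h_um - 6.0)]
    dists = [np.hypot(x - cx, y - cy) for x, y in corners]
    bg_center = corners[int(np.argmax(dists))]
    if max(dists) < arbor_radius + 5.0:
        raise ValueError("frame too small to hold a dye-free circle outside the arbor")

    yy, xx = _pixel_grid_um((ny, nx), px)
    r = np.hypot(xx - cx, yy - cy)

    rng = np.random.default_rng(params.seed)
    angles = np.sort((2 * np.pi * np.arange(params.n_branches) / max(params.n_branches, 1)
                      + rng.uniform(-0.3, 0.3, params.n_branches)) % (2 * np.pi))

    branch_mask = np.zeros((ny, nx), dtype=bool)
    half_w = params.branch_width_um / 2.0
    for ang in angles:
        ux, uy = np.cos(ang), np.sin(ang)
        # signed coordinates along/across the ray
        t = (xx - cx) * ux + (yy - cy) * uy
        s = -(xx - cx) * uy + (yy - cy) * ux
        branch_mask |= ((t >= params.soma_radius_um - 1.0)
                        & (t <= params.branch_length_um)
                        & (np.abs(s) <= half_w))

    soma_mask = r <= params.soma_radius_um
    leaflet_mask = (r <= arbor_radius) & ~soma_mask & ~branch_mask

    plane = np.full((ny, nx), params.background, dtype=float)
    plane[leaflet_mask] = (params.background
                           + params.leaflet_vf * (params.soma_peak - params.background))
    plane[branch_mask] = params.soma_peak
    plane[soma_mask] = params.soma_peak

    stack = np.repeat(plane[None, :, :], params.n_planes, axis=0)
    if params.noise_sd > 0:
        stack = stack + rng.normal(0.0, params.noise_sd, stack.shape)

    truth = {
        "leaflet_vf": params.leaflet_vf,
        "soma_center_um": list(center),
        "soma_radius_um": params.soma_radius_um,
        "soma_peak": params.soma_peak,
        "background": params.background,
        "arbor_radius_um": arbor_radius,
        "branch_angles_rad": angles.tolist(),
        "n_branches": params.n_branches,
        "branch_length_um": params.branch_length_um,
        "dye_free_circle": {"center_um": list(bg_center), "diameter_um": 10.0},
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    masks = {"soma": soma_mask, "branches": branch_mask, "leaflet": leaflet_mask}
    return LabeledImage(stack, px, truth, masks)


# --------------------------------------------------------------------------
# coupled network
# --------------------------------------------------------------------------

def gen_coupled_network(params: CouplingParams) -> CoupledNetwork:
    """Patched cell at the origin plus coupled cells at random 3-D positions.

    Coupled-cell somatic fluorescence follows exp(-d / C_lambda), optionally
    perturbed by multiplicative Gaussian noise of fractional SD ``noise_sd``.
    Distances are drawn uniformly in [min_distance, max_distance] with
    isotropic random directions, approximating the neighbor shell sampled in
    a 200 x 200 x 70 µm imaging volume.
    """
    rng = np.random.default_rng(params.seed)
    n_coupled = params.n_cells - 1

    d = rng.uniform(params.min_distance_um, params.max_distance_um, n_coupled)
    v = rng.normal(size=(n_coupled, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = v * d[:, None]

    fluor = np.exp(-d / params.length_constant_um)
    if params.noise_sd > 0:
        fluor = fluor * (1.0 + rng.normal(0.0, params.noise_sd, n_coupled))

    cells = pd.DataFrame({
        "cell_id": np.arange(params.n_cells),
        "x": np.concatenate([[0.0], pos[:, 0]]),
        "y": np.concatenate([[0.0], pos[:, 1]]),
        "z": np.concatenate([[0.0], pos[:, 2]]),
        "fluorescence": np.concatenate([[1.0], fluor]),
        "is_patched": np.concatenate([[True], np.zeros(n_coupled, dtype=bool)]),
    })
    truth = {
        "length_constant_um": params.length_constant_um,
        "distances_um": d.tolist(),
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    return CoupledNetwork(cells, truth)


# --------------------------------------------------------------------------
# puncta frame
# --------------------------------------------------------------------------

def _place_hardcore(rng: np.random.Generator, n: int, lo: np.ndarray,
                    hi: np.ndarray, min_sep: float, max_tries: int = 500) -> np.ndarray:
    """Sequential rejection sampling with a hard-core minimum separation."""
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            p = rng.uniform(lo, hi)
            if not pts or np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) >= min_sep:
                pts.append(p)
                break
        else:
            raise ValueError(
                f"infeasible density/separation combination: failed to place "
                f"point {len(pts) + 1} of {n} with min separation {min_sep} µm"
            )
    return np.asarray(pts).reshape(n, 2)


def gen_puncta_frame(params: PunctaParams) -> LabeledImage:
    """Hard-core disks of known diameter on a smooth background.

    The realized count is Poisson with mean density x frame area.  Disks are
    rendered with subpixel area coverage (4x supersampling), blurred by the
    PSF, summed with the background ramp, and corrupted by additive Gaussian
    noise.  Ground truth records every center and the drawn diameter.
    """
    px = params.pixel_size_um
    w_um, h_um = params.frame_size_um
    nx, ny = int(round(w_um / px)), int(round(h_um / px))
    r = params.diameter_um / 2.0

    rng = np.random.default_rng(params.seed)
    n = int(rng.poisson(params.density_per_um2 * w_um * h_um))
    margin = r + max(1.0, 4.0 * params.psf_sigma_um)
    centers = _place_hardcore(
        rng, n, np.array([margin, margin]), np.array([w_um - margin, h_um - margin]),
        params.separation_um)

    ss = 4  # supersampling factor for area-coverage rendering
    sub = px / ss
    cov = np.zeros((ny * ss, nx * ss), dtype=float)
    for cx0, cy0 in centers:
        # local window in supersampled pixels
        x0 = max(int((cx0 - r) / sub) - 1, 0)
        x1 = min(int((cx0 + r) / sub) + 2, nx * ss)
        y0 = max(int((cy0 - r) / sub) - 1, 0)
        y1 = min(int((cy0 + r) / sub) + 2, ny * ss)
        ys, xs = np.mgrid[y0:y1, x0:x1].astype(float)
        d2 = ((xs + 0.5) * sub - cx0) ** 2 + ((ys + 0.5) * sub - cy0) ** 2
        cov[y0:y1, x0:x1] = np.maximum(cov[y0:y1, x0:x1], (d2 <= r * r).astype(float))
    cov = cov.reshape(ny, ss, nx, ss).mean(axis=(1, 3))

    img = params.amplitude * cov
    if params.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, params.psf_sigma_um / px)

    yy, xx = _pixel_grid_um((ny, nx), px)
    img = img + params.background + params.background_gradient * xx / w_um
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)

    truth = {
        "centers_um": centers.tolist(),
        "diameter_um": params.diameter_um,
        "n_clusters": int(n),
        "density_per_um2": params.density_per_um2,
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    return LabeledImage(img[None, :, :], px, truth)


# --------------------------------------------------------------------------
# electrophysiology sweeps
# --------------------------------------------------------------------------

def biexp_kernel(t_s: np.ndarray, amplitude_pa: float, tau_rise_ms: float,
                 tau_decay_ms: float) -> np.ndarray:
    """Peak-normalized difference of exponentials, causal in ``t_s`` (seconds).

    The returned wave peaks at exactly ``amplitude_pa`` (signed; inward
    currents are negative).
    """
    tr = tau_rise_ms / 1000.0
    td = tau_decay_ms / 1000.0
    if not 0 < tr < td:
        raise ValueError("require 0 < tau_rise < tau_decay")
    t = np.maximum(t_s, 0.0)
    wave = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    out = amplitude_pa * wave / peak
    out[t_s < 0] = 0.0
    return out


def _stim_artifact(t_s: np.ndarray, amp_pa: float = 50.0) -> np.ndarray:
    """Brief biphasic field-potential transient locked to a stimulus."""
    w = np.zeros_like(t_s)
    m = (t_s >= 0) & (t_s < 0.002)
    w[m] = amp_pa * np.sin(2 * np.pi * t_s[m] / 0.002)
    return w


def gen_astro_sweeps(params: SweepParams) -> SweepSet:
    """Sweeps for 1, 4 and 5 stimuli plus an optional TBOA condition.

    Every condition is a strict linear superposition of per-stimulus glutamate
    transporter and potassium kernels; the TBOA condition (transporter
    blocked) keeps only the potassium kernel of a single stimulus.  Ground
    truth records the per-stimulus amplitudes and decay constants actually
    rendered.
    """
    fs = params.sampling_rate_hz
    n_samp = int(round(params.sweep_duration_s * fs))
    t = np.arange(n_samp) / fs
    stims = np.asarray(params.stim_times_s)

    g_amp, g_rise, g_decay = params.glut_kernel
    k_amp, k_rise, k_decay = params.k_kernel
    gaf, kaf = params.factors("glut_amp_factors"), params.factors("k_amp_factors")
    gtf, ktf = params.factors("glut_tau_factors"), params.factors("k_tau_factors")

    def stim_component(i: int, with_glut: bool = True) -> np.ndarray:
        ts = t - stims[i]
        y = biexp_kernel(ts, k_amp * kaf[i], k_rise, k_decay * ktf[i])
        if with_glut:
            y = y + biexp_kernel(ts, g_amp * gaf[i], g_rise, g_decay * gtf[i])
        if params.holding_artifact == "stim":
            y = y + _stim_artifact(ts)
        return y

    # built cumulatively, so the n-stimulus trace is exactly the (n-1)-trace
    # plus the n-th component (linear superposition to the last bit)
    components = [stim_component(i) for i in range(len(stims))]
    cumulative = [components[0].copy()]
    for comp in components[1:]:
        cumulative.append(cumulative[-1] + comp)
    conditions = {"1": cumulative[0], "4": cumulative[3], "5": cumulative[4]}
    if params.include_tboa:
        conditions["tboa"] = stim_component(0, with_glut=False)

    rng = np.random.default_rng(params.seed)
    traces, stim_times = {}, {}
    for name, y in conditions.items():
        sweeps = np.repeat(y[None, :], params.n_sweeps, axis=0)
        if params.noise_sd > 0:
            sweeps = sweeps + rng.normal(0.0, params.noise_sd, sweeps.shape)
        traces[name] = sweeps
        n_stim = 1 if name in ("1", "tboa") else int(name)
        stim_times[name] = stims[:n_stim].copy()

    truth = {
        "glut_amplitudes_pa": (g_amp * gaf).tolist(),
        "glut_tau_decay_ms": (g_decay * gtf).tolist(),
        "k_amplitudes_pa": (k_amp * kaf).tolist(),
        "k_tau_decay_ms": (k_decay * ktf).tolist(),
        "clean_traces": {k: v.tolist() for k, v in conditions.items()},
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    return SweepSet(
        traces=traces,
        sampling_rate_hz=fs,
        stim_times_s=stim_times,
        baseline_window_s=(0.0, float(stims[0]) - 0.01),
        ground_truth=truth,
    )


def gen_step_response(params: StepParams) -> SweepSet:
    """Current response to a voltage step: capacitive transient + ohmic plateau.

    The steady-state current is dV/R (in pA for dV in mV and R in MΩ); the
    capacitive transient decays with ``cap_tau_ms``.
    """
    fs = params.sampling_rate_hz
    n = int(round((params.pre_s + params.step_s + params.post_s) * fs))
    t = np.arange(n) / fs
    di_pa = params.dv_mv / params.resistance_mohm * 1000.0
    t_on, t_off = params.pre_s, params.pre_s + params.step_s

    y = np.zeros(n)
    on = (t >= t_on) & (t < t_off)
    tau = params.cap_tau_ms / 1000.0
    y[on] = di_pa + (params.cap_amp_factor - 1.0) * di_pa * np.exp(-(t[on] - t_on) / tau)
    off = t >= t_off
    y[off] = -(params.cap_amp_factor - 1.0) * di_pa * np.exp(-(t[off] - t_off) / tau)

    rng = np.random.default_rng(params.seed)
    sweeps = np.repeat(y[None, :], params.n_sweeps, axis=0)
    if params.noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, params.noise_sd, sweeps.shape)

    truth = {
        "resistance_mohm": params.resistance_mohm,
        "dv_mv": params.dv_mv,
        "step_window_s": [t_on, t_off],
        "di_pa": di_pa,
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    return SweepSet(
        traces={"step": sweeps},
        sampling_rate_hz=fs,
        stim_times_s={"step": np.array([t_on])},
        baseline_window_s=(0.0, t_on - 0.005),
        ground_truth=truth,
    )


# --------------------------------------------------------------------------
# LTP series
# --------------------------------------------------------------------------

def gen_ltp_series(params: LTPSeriesParams) -> LTPSeries:
    """fEPSP amplitudes: flat baseline, then saturating growth toward
    ``potentiation_factor`` x baseline after HFS."""
    dt_min = params.sample_interval_s / 60.0
    times = np.arange(0.0, params.baseline_minutes + params.post_minutes, dt_min)
    hfs = params.baseline_minutes

    amps = np.full(times.shape, params.baseline_amplitude)
    post = times >= hfs
    growth = 1.0 - np.exp(-(times[post] - hfs) / params.onset_tau_min)
    amps[post] *= 1.0 + (params.potentiation_factor - 1.0) * growth

    rng = np.random.default_rng(params.seed)
    if params.amplitude_noise_cv > 0:
        amps = amps * (1.0 + rng.normal(0.0, params.amplitude_noise_cv, amps.shape))

    truth = {
        "potentiation_factor": params.potentiation_factor,
        "hfs_time_min": hfs,
        "params": asdict(params),
    }
    truth = _jsonable(truth)
    return LTPSeries(times, amps, hfs, truth)


# --------------------------------------------------------------------------
# serialization (TIFF + JSON sidecar; CSV + JSON sidecar)
# --------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image(image: LabeledImage, path: str | Path) -> None:
    """Multi-page float32 TIFF plus a JSON sidecar with pixel size and ground
    truth (in-memory truth masks are not serialized)."""
    path = Path(path)
    tifffile.imwrite(path, image.data.astype(np.float32))
    meta = {"pixel_size_um": image.pixel_size_um, "ground_truth": image.ground_truth}
    _sidecar(path).write_text(json.dumps(meta))


def load_image(path: str | Path) -> LabeledImage:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None, :, :]
    meta = json.loads(_sidecar(path).read_text())
    return LabeledImage(data, meta["pixel_size_um"], meta["ground_truth"])


def save_network(network: CoupledNetwork, path: str | Path) -> None:
    path = Path(path)
    network.cells.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"ground_truth": network.ground_truth}))


def load_network(path: str | Path) -> CoupledNetwork:
    path = Path(path)
    cells = pd.read_csv(path)
    cells["is_patched"] = cells["is_patched"].astype(bool)
    truth = {}
    if _sidecar(path).exists():
        truth = json.loads(_sidecar(path).read_text())["ground_truth"]
    return CoupledNetwork(cells, truth)


def save_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    """Wide CSV (time + one column per sweep) plus a JSON sidecar carrying the
    sampling rate, per-condition stimulus times and ground truth."""
    path = Path(path)
    cols = {"time_s": sweeps.time_s}
    for cond, arr in sweeps.traces.items():
        for i, sweep in enumerate(np.atleast_2d(arr)):
            cols[f"{cond}/{i}"] = sweep
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "sampling_rate_hz": sweeps.sampling_rate_hz,
        "stim_times_s": {k: np.asarray(v).tolist() for k, v in sweeps.stim_times_s.items()},
        "baseline_window_s": list(sweeps.baseline_window_s),
        "ground_truth": sweeps.ground_truth,
    }
    _sidecar(path).write_text(json.dumps(meta))


def load_sweeps(path: str | Path) -> SweepSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    traces: dict[str, list[np.ndarray]] = {}
    for col in df.columns:
        if col == "time_s":
            continue
        cond = col.rsplit("/", 1)[0]
        traces.setdefault(cond, []).append(df[col].to_numpy())
    return SweepSet(
        traces={k: np.vstack(v) for k, v in traces.items()},
        sampling_rate_hz=meta["sampling_rate_hz"],
        stim_times_s={k: np.asarray(v) for k, v in meta["stim_times_s"].items()},
        baseline_window_s=tuple(meta["baseline_window_s"]),
        ground_truth=meta["ground_truth"],
    )


def save_ltp_series(series: LTPSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_min": series.times_min,
                  "amplitude": series.amplitudes}).to_csv(path, index=False)
    meta = {"hfs_time_min": series.hfs_time_min, "ground_truth": series.ground_truth}
    _sidecar(path).write_text(json.dumps(meta))


def load_ltp_series(path: str | Path) -> LTPSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return LTPSeries(df["time_min"].to_numpy(), df["amplitude"].to_numpy(),
                     meta["hfs_time_min"], meta["ground_truth"])
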