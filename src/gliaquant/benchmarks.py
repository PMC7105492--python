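"""Parameter-recovery benchmarks at the study's reported group conditions.

Each function generates synthetic cohorts whose ground truth is set to a
group mean reported by the study, runs the corresponding analysis pipeline
end to end, and returns the recovered group statistic.  They exist so that
the recovery experiments behind the package's validation can be reproduced
with one call (see ``scripts/acceptance.py``).

All randomness is controlled by a single integer ``seed``; replicate seeds
are derived deterministically from it.
"""

from __future__ import annotations

import numpy as np

from . import coupling, cxclusters, ephys, morphometry, synthgen

__all__ = [
    "recover_leaflet_vf",
    "recover_length_constant",
    "recover_cluster_diameter",
    "recover_cluster_density",
    "recover_ik_ratio",
    "recover_iglut_tau_ratio",
    "recover_ltp_magnitude",
    "recover_input_resistance",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
            % (2 ** 31)]


def recover_leaflet_vf(n_cells: int = 7, seed: int = 1,
                       true_vf: float = 0.032) -> float:
    """Mean leaflet volume fraction (%) over dye-filled astrocyte images at
    the control occupancy, imaging noise 5% of the soma peak."""
    vals = []
    for s in _child_seeds(seed, n_cells):
        img = synthgen.gen_astrocyte_image(synthgen.ImagingParams(
            leaflet_vf=true_vf, noise_sd=0.05 * 200.0, seed=s))
        vals.append(100.0 * morphometry.leaflet_vf(img).mean_vf)
    return float(np.mean(vals))


def recover_length_constant(n_networks: int = 5, n_cells: int = 12,
                            seed: int = 1, true_lambda_um: float = 19.9) -> float:
    """Mean coupling length constant (µm) from semilog fits on dye-coupled
    networks at the control permeability, 5% multiplicative noise."""
    vals = []
    for s in _child_seeds(seed, n_networks):
        net = synthgen.gen_coupled_network(synthgen.CouplingParams(
            n_cells=n_cells, length_constant_um=true_lambda_um,
            noise_sd=0.05, seed=s))
        vals.append(coupling.fit_length_constant(net).length_constant_um)
    return float(np.mean(vals))


def recover_cluster_diameter(n_frames: int = 11, seed: int = 1,
                             true_diameter_um: float = 1.4,
                             density_per_um2: float = 0.02) -> float:
    """Grand mean measured cluster diameter (µm) on sparse puncta frames
    drawn at the control Cx30 soma-proximal size."""
    diam: list[float] = []
    for s in _child_seeds(seed, n_frames):
        frame = synthgen.gen_puncta_frame(synthgen.PunctaParams(
            density_per_um2=density_per_um2, diameter_um=true_diameter_um,
            noise_sd=0.05 * 30.0, seed=s))
        found = cxclusters.segment_clusters(frame.plane(), frame.pixel_size_um)
        diam.extend(found.diameters_um.tolist())
    return float(np.mean(diam))


def recover_cluster_density(n_frames: int = 12, seed: int = 1,
                            true_density_per_um2: float = 0.24,
                            diameter_um: float = 0.5) -> float:
    """Mean ring density (µm^-2, rings 10-50 µm) on puncta frames placed at
    the control Cx43 density with sub-µm disks."""
    vals = []
    for s in _child_seeds(seed, n_frames):
        frame = synthgen.gen_puncta_frame(synthgen.PunctaParams(
            density_per_um2=true_density_per_um2, diameter_um=diameter_um,
            seed=s))
        found = cxclusters.segment_clusters(frame.plane(), frame.pixel_size_um)
        ny, nx = frame.plane().shape
        center = (nx * frame.pixel_size_um / 2.0, ny * frame.pixel_size_um / 2.0)
        prof = cxclusters.radial_cluster_profile(found, center, (ny, nx))
        vals.append(prof.mean_density((10.0, 50.0)))
    return float(np.mean(vals))


def recover_ik_ratio(n_sets: int = 11, seed: int = 1,
                     true_ratio: float = 1.21) -> float:
    """I_K(5)/I_K(1) amplitude ratio via 5-minus-4 subtraction and the
    200-ms-window measurement, K-kernel facilitation at the CR ground truth,
    SNR 20."""
    vals = []
    for s in _child_seeds(seed, n_sets):
        sw = synthgen.gen_astro_sweeps(synthgen.SweepParams(
            k_amp_factors=(1.0, 1.0, 1.0, 1.0, true_ratio),
            noise_sd=30.0 / 20.0, seed=s))
        avg = ephys.baseline_subtract_average(sw)
        fs = avg.sampling_rate_hz
        fifth = ephys.isolate_fifth_response(avg.traces["5"], avg.traces["4"])
        ik1 = ephys.measure_ik(avg.traces["1"], fs, avg.stim_times_s["1"][-1],
                               fit_decay=False)
        ik5 = ephys.measure_ik(fifth, fs, avg.stim_times_s["5"][-1],
                               fit_decay=False)
        vals.append(ik5.amplitude_pa / ik1.amplitude_pa)
    return float(np.mean(vals))


def recover_iglut_tau_ratio(n_sets: int = 8, seed: int = 1,
                            true_ratio: float = 1.28) -> float:
    """tau_decay I_GluT(5)/I_GluT(1) via residual reconstruction, subtraction
    and mono-exponential fitting, control decay-ratio ground truth, SNR 20."""
    vals = []
    for s in _child_seeds(seed, n_sets):
        sw = synthgen.gen_astro_sweeps(synthgen.SweepParams(
            glut_tau_factors=(1.0, 1.0, 1.0, 1.0, true_ratio),
            k_kernel=(-10.0, 20.0, 300.0),  # small nonsynaptic residual
            noise_sd=100.0 / 20.0, seed=s))
        avg = ephys.baseline_subtract_average(sw)
        fs = avg.sampling_rate_hz
        stims = avg.stim_times_s["5"]
        residual = ephys.reconstruct_residual_ik(avg.traces["tboa"], fs, stims[0])
        _, m1 = ephys.extract_iglut(avg.traces["1"], residual, fs, stims[0])
        fifth = ephys.isolate_fifth_response(avg.traces["5"], avg.traces["4"])
        _, m5 = ephys.extract_iglut(fifth, residual, fs, stims[-1],
                                    residual_stim_time_s=stims[0])
        # replicates with a non-converged decay fit carry no usable tau
        if m1.decay_fit.converged and m5.decay_fit.converged:
            vals.append(m5.tau_decay_ms / m1.tau_decay_ms)
    return float(np.mean(vals))


def recover_ltp_magnitude(n_series: int = 9, seed: int = 1,
                          true_factor: float = 1.68) -> float:
    """LTP magnitude (% of baseline, 50-60 min window) on fEPSP series at the
    CR potentiation factor, 5% amplitude coefficient of variation."""
    vals = []
    for s in _child_seeds(seed, n_series):
        series = synthgen.gen_ltp_series(synthgen.LTPSeriesParams(
            potentiation_factor=true_factor, amplitude_noise_cv=0.05, seed=s))
        vals.append(ephys.ltp_magnitude(series.times_min, series.amplitudes,
                                        series.hfs_time_min).magnitude_pct)
    return float(np.mean(vals))


def recover_input_resistance(n_cells: int = 6, seed: int = 1,
                             true_r_mohm: float = 30.0) -> float:
    """Input resistance (MΩ) from -5 mV step responses at the control value,
    2% current noise."""
    vals = []
    for s in _child_seeds(seed, n_cells):
        di = abs(-5.0 / true_r_mohm * 1000.0)
        resp = synthgen.gen_step_response(synthgen.StepParams(
            resistance_mohm=true_r_mohm, noise_sd=0.02 * di, seed=s))
        avg = ephys.baseline_subtract_average(resp)
        window = tuple(resp.ground_truth["step_window_s"])
        r, _, _ = ephys.input_resistance(avg.traces["step"],
                                         avg.sampling_rate_hz, window,
                                         dv_mv=-5.0)
        vals.append(r)
    return float(np.mean(vals))
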