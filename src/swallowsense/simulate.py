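"""Synthetic chest-belt breathing sessions with embedded swallow apneas.

The generator emulates the statistical structure of lunch-time
chest-belt recordings: quasi-periodic breathing cycles (mean length
3.77 s), a two-state Markov chain over {normal, swallow} cycles that
encodes swallow temporal locality (people rarely swallow in consecutive
breathing cycles), apnea plateaus inserted during inhalation or at
exhale onset, a small damped "blip" oscillation riding on each apnea
(swallows create more fluctuations than normal cycles), additive sensor
noise, and 12-bit ADC quantization.

Each cycle is a rising inhale (quarter-sine ramp, sharp at the valley,
smooth at the peak) followed by a falling exhale (quarter-cosine decay,
smooth at the peak, sharp at the valley), so valleys are well-defined
corners and peaks are rounded — the asymmetry a retracement peak/valley
detector faces on real belt data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import AnnotationTrack, RawSignal, write_annotations, write_signal

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_label_sequence",
    "write_fixture_suite",
    "FIXTURE_SCENARIOS",
]

#: per-subject transition matrix over (normal, swallow) hidden cycle states;
#: the default is the printed subject-1 matrix, whose stationary swallow
#: fraction is 0.24 / (0.24 + 0.96) = 0.2
DEFAULT_TRANSITIONS = ((0.76, 0.24), (0.96, 0.04))


@dataclass
class SimulationConfig:
    """Parameters of a simulated chest-belt session.

    Defaults reflect the study conditions: 100 Hz sampling into a 12-bit
    ADC, mean breathing-cycle length 3.77 s, and the subject-1 swallow
    transition matrix. Amplitudes are in raw ADC counts; a baseline of
    1800 with a mean cycle depth of 600 keeps the signal comfortably
    inside the 0–4095 converter range.
    """

    sampling_rate: float = 100.0
    duration: float = 300.0
    mean_cycle_length: float = 3.77
    cycle_length_cv: float = 0.12
    amplitude_mean: float = 600.0
    amplitude_cv: float = 0.10
    baseline: float = 1800.0
    noise_sd: float = 8.0
    quantization_bits: int = 12
    swallow_transition_matrix: tuple = DEFAULT_TRANSITIONS
    swallow_phase_probability: float = 0.5
    apnea_duration_range: tuple = (0.25, 1.2)
    blip_amplitude: float = 110.0
    blip_frequency: float = 4.0
    blip_decay: float = 0.4
    irregularity_rate: float = 0.06
    irregularity_rate_adjacent: float = 0.5
    irregularity_duration_range: tuple = (0.08, 0.4)
    irregularity_blip_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration < self.mean_cycle_length:
            raise ValueError("duration must cover at least one mean cycle length")
        A = np.asarray(self.swallow_transition_matrix, dtype=float)
        if A.shape != (2, 2) or (A < 0).any() or np.abs(A.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("swallow_transition_matrix must be 2x2 row-stochastic")
        lo, hi = self.apnea_duration_range
        if not (0 < lo <= hi < self.mean_cycle_length):
            raise ValueError("apnea_duration_range must lie within (0, mean_cycle_length)")
        if not 0 <= self.swallow_phase_probability <= 1:
            raise ValueError("swallow_phase_probability must be in [0, 1]")
        if self.quantization_bits < 1:
            raise ValueError("quantization_bits must be >= 1")


@dataclass
class GroundTruth:
    """Simulator-side truth for a session.

    ``swallow_times`` holds one timestamp per swallow cycle (the apnea
    midpoint, emulating the push-button press); ``cycle_boundaries`` the
    valley timestamps delimiting cycles (n_cycles + 1 values);
    ``cycle_labels`` 0 = normal, 1 = swallow per cycle.
    """

    swallow_times: np.ndarray
    cycle_labels: np.ndarray
    cycle_boundaries: np.ndarray
    swallow_phases: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.swallow_times = np.asarray(self.swallow_times, dtype=float)
        self.cycle_labels = np.asarray(self.cycle_labels, dtype=int)
        self.cycle_boundaries = np.asarray(self.cycle_boundaries, dtype=float)
        if self.swallow_times.size and (np.diff(self.swallow_times) <= 0).any():
            raise ValueError("swallow_times must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_labels)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int | None = None) -> np.ndarray | float:
    """Truncated-normal draw by rejection (cheap at these mild truncations)."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out if size is not None else float(out[0])


def simulate_label_sequence(transition_matrix, n_cycles: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample a hidden {normal=0, swallow=1} cycle-state chain.

    The initial state is drawn from the stationary distribution of the
    transition matrix (left unit eigenvector), so short sessions are not
    biased toward either state.
    """
    A = np.asarray(transition_matrix, dtype=float)
    # stationary distribution of a 2-state chain in closed form
    p_sw = A[0, 1] / (A[0, 1] + A[1, 0]) if (A[0, 1] + A[1, 0]) > 0 else 0.0
    states = np.empty(n_cycles, dtype=int)
    states[0] = int(rng.random() < p_sw)
    u = rng.random(n_cycles - 1) if n_cycles > 1 else np.empty(0)
    for k in range(1, n_cycles):
        states[k] = int(u[k - 1] < A[states[k - 1], 1])
    return states


def _inhale(s: np.ndarray) -> np.ndarray:
    # quarter sine: steep at the valley (s=0), flat at the peak (s=1)
    return np.sin(0.5 * np.pi * s)


def _exhale(s: np.ndarray) -> np.ndarray:
    # quarter cosine: flat at the peak (s=0), steep at the valley (s=1)
    return np.cos(0.5 * np.pi * s)


def simulate_session(config: SimulationConfig) -> tuple[RawSignal, GroundTruth]:
    """Generate one session and its ground truth.

    The hidden Markov chain over cycles decides which cycles carry a
    swallow; each swallow cycle is elongated by an apnea plateau (hold at
    the current amplitude plus a damped-oscillation blip) inserted either
    mid-inhale ("inhale swallow") or at exhale onset ("exhale swallow").
    Gaussian sensor noise is added before quantization to the configured
    ADC resolution. Identical config + seed reproduce the stream
    bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate

    # draw cycles until the requested duration is covered
    mean_len = config.mean_cycle_length
    n_guess = int(np.ceil(config.duration / mean_len)) + 8
    labels_pool = simulate_label_sequence(config.swallow_transition_matrix,
                                          max(n_guess * 2, 16), rng)

    labels: list[int] = []
    swallow_times: list[float] = []
    swallow_phases: list[str] = []
    pieces: list[np.ndarray] = []

    k = 0
    v_prev = config.baseline + _truncated_normal(rng, 0.0, 12.0, -40.0, 40.0)

    # lead-in partial exhale so the first valley is an interior corner
    # (recordings do not start exactly at a valley)
    lead = round(0.9 * fs) / fs
    tau = np.arange(0, int(np.ceil(lead * fs - 1e-9))) / fs
    pieces.append(v_prev + 0.5 * config.amplitude_mean * _exhale(tau / lead))

    t0 = lead
    boundaries = [t0]
    while t0 < config.duration:
        if k + 1 >= len(labels_pool):  # pragma: no cover - pool sized generously
            labels_pool = np.concatenate(
                [labels_pool,
                 simulate_label_sequence(config.swallow_transition_matrix, 64, rng)])
        state = int(labels_pool[k])
        base_len = _truncated_normal(
            rng, mean_len, config.cycle_length_cv * mean_len,
            0.4 * mean_len, 2.0 * mean_len)
        amp = _truncated_normal(
            rng, config.amplitude_mean, config.amplitude_cv * config.amplitude_mean,
            0.4 * config.amplitude_mean, 1.6 * config.amplitude_mean)
        inhale_frac = rng.uniform(0.35, 0.5)
        v_next = config.baseline + _truncated_normal(rng, 0.0, 12.0, -40.0, 40.0)
        peak = v_prev + amp

        ti = inhale_frac * base_len
        te = base_len - ti
        # swallow apnea, or a shorter feeding/chewing irregularity in a
        # normal cycle (the dominant source of detector false positives
        # in real meal recordings)
        apnea = 0.0
        phase = None
        blip_amp = config.blip_amplitude
        if state == 1:
            lo, hi = config.apnea_duration_range
            apnea = _truncated_normal(rng, 0.5 * (lo + hi), 0.25 * (hi - lo), lo, hi)
            phase = "exhale" if rng.random() < config.swallow_phase_probability else "inhale"
        elif rng.random() < (
            config.irregularity_rate_adjacent
            if (labels_pool[max(k - 1, 0)] == 1 or labels_pool[k + 1] == 1)
            else config.irregularity_rate
        ):
            # swallow-adjacent cycles are modulated by the neighboring
            # swallow far more often than cycles deep in normal breathing
            lo, hi = config.irregularity_duration_range
            apnea = _truncated_normal(rng, 0.5 * (lo + hi), 0.25 * (hi - lo), lo, hi)
            phase = "exhale" if rng.random() < 0.5 else "inhale"
            blip_amp = config.irregularity_blip_scale * config.blip_amplitude
        total = base_len + apnea
        # snap cycle boundaries to the sample grid (exhale absorbs the
        # sub-sample remainder) so valley corners fall on samples
        total_snapped = round(total * fs) / fs
        te += total_snapped - total
        total = total_snapped

        # sample grid covering [t0, t0 + total)
        n0 = int(np.ceil(t0 * fs - 1e-9))
        n1 = int(np.ceil((t0 + total) * fs - 1e-9))
        tau = np.arange(n0, n1) / fs - t0  # time into the cycle

        if apnea == 0.0:
            y = np.where(
                tau < ti,
                v_prev + (peak - v_prev) * _inhale(np.minimum(tau / ti, 1.0)),
                v_next + (peak - v_next) * _exhale(np.clip((tau - ti) / te, 0.0, 1.0)),
            )
        else:
            if phase == "inhale":
                t_hold = 0.5 * ti  # hold splits the inhale ramp in half
            else:
                t_hold = ti  # hold at exhale onset, at the peak
            hold_val = v_prev + (peak - v_prev) * _inhale(np.array(t_hold / ti))
            blip_t = tau - t_hold
            blip = (blip_amp
                    * np.exp(-np.maximum(blip_t, 0.0) / config.blip_decay)
                    * np.sin(2 * np.pi * config.blip_frequency * blip_t))
            shifted = np.where(tau < t_hold, tau, tau - apnea)  # breathing-phase clock
            y = np.where(
                shifted < ti,
                v_prev + (peak - v_prev) * _inhale(np.minimum(np.maximum(shifted, 0.0) / ti, 1.0)),
                v_next + (peak - v_next) * _exhale(np.clip((shifted - ti) / te, 0.0, 1.0)),
            )
            in_apnea = (tau >= t_hold) & (tau < t_hold + apnea)
            y = np.where(in_apnea, float(hold_val) + blip, y)
            if state == 1:
                swallow_times.append(t0 + t_hold + 0.5 * apnea)
                swallow_phases.append(phase)

        pieces.append(y)
        labels.append(state)
        t0 += total
        boundaries.append(t0)
        v_prev = v_next
        k += 1

    # trailing partial inhale so the final valley is a confirmable corner
    # (recordings do not end exactly at a valley)
    tail_len = 0.45 * mean_len * 0.42
    n0 = int(np.ceil(t0 * fs - 1e-9))
    n1 = int(np.ceil((t0 + tail_len) * fs - 1e-9))
    tau = np.arange(n0, n1) / fs - t0
    pieces.append(v_prev + config.amplitude_mean
                  * _inhale(np.minimum(tau / (0.42 * mean_len), 1.0)))

    samples = np.concatenate(pieces)
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.size)
    top = 2 ** config.quantization_bits - 1
    samples = np.clip(np.round(samples), 0, top)

    times = np.arange(samples.size) / fs
    signal = RawSignal(times, samples, fs, session_id=f"sim-seed{config.seed}")
    truth = GroundTruth(np.asarray(swallow_times), np.asarray(labels, dtype=int),
                        np.asarray(boundaries), swallow_phases)
    return signal, truth


#: named fixture scenarios: config overrides applied to the defaults
FIXTURE_SCENARIOS: dict[str, dict] = {
    "no_swallow": {"swallow_transition_matrix": ((1.0, 0.0), (1.0, 0.0)),
                   "duration": 180.0},
    "exhale_swallow": {"swallow_phase_probability": 1.0, "duration": 180.0},
    "inhale_swallow": {"swallow_phase_probability": 0.0, "duration": 180.0},
    "mixed": {"duration": 240.0},
    # high sensor noise, strong apnea blips and widely varying breath
    # depths: the regime where both threshold-coefficient failure modes
    # appear (low thresholds split cycles on blips/noise, high
    # thresholds merge shallow cycles into neighbors)
    "high_noise": {"noise_sd": 55.0, "amplitude_cv": 0.28, "duration": 240.0},
}


def write_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict:
    """Write the standard small-session fixture suite.

    Emits one signal + annotation file pair per scenario in
    :data:`FIXTURE_SCENARIOS` plus a ``manifest.json`` recording every
    scenario's seed and parameters, so any fixture can be regenerated
    byte-identically from the manifest alone.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if not output_dir.is_dir():
        raise ValueError(f"{output_dir} is not a writable directory")
    manifest: dict = {"seed": seed, "sessions": {}}
    for i, (name, overrides) in enumerate(FIXTURE_SCENARIOS.items()):
        cfg = SimulationConfig(**overrides, seed=seed + i)
        signal, truth = simulate_session(cfg)
        sig_path = output_dir / f"{name}.tsv"
        ann_path = output_dir / f"{name}.events.txt"
        write_signal(sig_path, signal)
        write_annotations(ann_path, AnnotationTrack(truth.swallow_times,
                                                    source="simulator"))
        manifest["sessions"][name] = {
            "signal": sig_path.name,
            "annotations": ann_path.name,
            "n_cycles": int(truth.n_cycles),
            "n_swallows": int(len(truth.swallow_times)),
            "config": _jsonable(asdict(cfg)),
        }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
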