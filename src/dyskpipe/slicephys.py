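"""Slice (ex vivo) whole-cell electrophysiology sweep metrics.

Voltage-clamp sweeps (pA) yield evoked postsynaptic current amplitudes,
paired-pulse ratios (PPR = EPSC2/EPSC1 at interstimulus intervals of 25, 50,
100, 200 and 500 ms), AMPA:NMDA ratios (peak EPSC at -70 mV over the EPSC at
+40 mV read 50 ms after stimulation), optically evoked EPSC amplitudes across
light powers (0.5/1/2/4 mW, compared at 4 mW), and miniature EPSC detection
and summaries (cells require >= 500 detected events for inclusion; cumulative
distributions are built from 500 randomly selected events).  Current-clamp
sweeps (mV) in response to 100-600 pA square steps yield spike counts and
rheobase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSet",
    "PairedPulseResult",
    "AmpaNmdaResult",
    "MepscEvent",
    "MepscSummary",
    "ExcitabilityCurve",
    "psc_amplitude",
    "paired_pulse",
    "ampa_nmda",
    "detect_mepscs",
    "mepsc_summary",
    "detect_spikes_cc",
    "excitability_curve",
    "oepsc_by_power",
]

DEFAULT_ISIS_MS = (25.0, 50.0, 100.0, 200.0, 500.0)
DEFAULT_POWERS_MW = (0.5, 1.0, 2.0, 4.0)
ARTIFACT_BLANK_S = 0.001  # stimulus artifact blanking after each stimulus


@dataclass
class SweepSet:
    """Uniformly sampled clamp sweeps with per-sweep stimulus metadata.

    ``traces`` is (n_samples, n_sweeps): pA in voltage clamp, mV in current
    clamp.  ``meta`` carries one row per sweep; recognized columns include
    ``stim1_s``, ``stim2_s``, ``isi_ms``, ``holding_mv``, ``step_pa``,
    ``step_start_s``, ``step_dur_s``, ``power_mw``.
    """

    sample_rate_hz: float
    traces: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    # populated by the synthetic generator; empty for recorded data
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (n_samples, n_sweeps)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if len(self.meta) not in (0, self.n_sweeps):
            raise ValueError("meta must have one row per sweep")

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def sweep(self, i: int) -> np.ndarray:
        return self.traces[:, i]

    def to_csv(self, path, meta_path=None) -> None:
        df = pd.DataFrame(self.traces, columns=[f"sweep_{i}" for i in range(self.n_sweeps)])
        df.insert(0, "time_s", self.time_s)
        df.to_csv(path, index=False)
        if meta_path is not None:
            self.meta.to_json(meta_path, orient="records")

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "SweepSet":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        traces = df.drop(columns=["time_s"]).to_numpy()
        meta = pd.read_json(meta_path, orient="records") if meta_path else pd.DataFrame()
        return cls(sample_rate_hz=float(round(fs)), traces=traces, meta=meta)


def psc_amplitude(
    trace: np.ndarray,
    sample_rate_hz: float,
    stim_time_s: float,
    polarity: int = -1,
    search_window_s: tuple[float, float] = (0.002, 0.05),
    baseline_window_s: tuple[float, float] = (-0.010, -0.001),
) -> float:
    """Postsynaptic current amplitude (pA, positive magnitude).

    The amplitude is |extremum within the search window - mean of the
    baseline window|, with the extremum direction set by ``polarity`` (-1
    for inward currents at -70 mV, +1 for outward at +40 mV).  Windows are
    relative to the stimulus time.  The first millisecond after the stimulus
    is reserved for artifact blanking; a search window that starts inside it
    is rejected.
    """
    trace = np.asarray(trace, dtype=float)
    if search_window_s[0] < ARTIFACT_BLANK_S:
        raise ValueError(
            f"search window must start after the {ARTIFACT_BLANK_S * 1000:.0f}-ms "
            "artifact blanking period"
        )
    n = trace.size

    def to_idx(rel_s: float) -> int:
        return int(round((stim_time_s + rel_s) * sample_rate_hz))

    b0, b1 = to_idx(baseline_window_s[0]), to_idx(baseline_window_s[1])
    s0, s1 = to_idx(search_window_s[0]), to_idx(search_window_s[1])
    if b0 < 0 or s1 > n:
        raise ValueError("analysis windows extend beyond the trace")
    baseline = trace[b0:b1].mean()
    seg = trace[s0:s1]
    extremum = seg.min() if polarity < 0 else seg.max()
    return float(abs(extremum - baseline))


@dataclass
class PairedPulseResult:
    """Per-ISI paired-pulse ratios with the underlying repetitions."""

    ppr_by_isi: dict[float, float]
    n_reps_by_isi: dict[float, int]
    amplitudes: pd.DataFrame  # columns: isi_ms, rep, epsc1_pa, epsc2_pa, ratio


def _noise_floor(trace: np.ndarray, sample_rate_hz: float, stim_time_s: float,
                 baseline_window_s: tuple[float, float]) -> float:
    i0 = int(round((stim_time_s + baseline_window_s[0]) * sample_rate_hz))
    i1 = int(round((stim_time_s + baseline_window_s[1]) * sample_rate_hz))
    seg = trace[max(i0, 0):max(i1, 1)]
    mad = np.median(np.abs(seg - np.median(seg)))
    return float(3.0 * 1.4826 * mad)


def _subtract_epsc1_tail(
    trace: np.ndarray,
    sample_rate_hz: float,
    stim1_s: float,
    stim2_s: float,
    polarity: int,
    noise_floor: float,
) -> np.ndarray:
    """Extrapolate the first EPSC's exponential decay beneath the second.

    At short interstimulus intervals the second EPSC rides on the decay
    tail of the first; the tail is fit log-linearly on the stretch just
    before the second stimulus and subtracted from the trace beyond it.
    When the tail is already within the noise floor the trace is returned
    unchanged.
    """
    fs = sample_rate_hz
    w0 = int(round((max(stim1_s + 0.005, stim2_s - 0.008)) * fs))
    w1 = int(round((stim2_s - 0.0005) * fs))
    if w1 - w0 < 5:
        return trace
    base0 = trace[max(0, int((stim1_s - 0.010) * fs)): int((stim1_s - 0.001) * fs)].mean()
    t = np.arange(w0, w1) / fs
    r = (trace[w0:w1] - base0) * (1 if polarity > 0 else -1)
    if r.min() <= max(noise_floor, 0.0) or np.median(r) <= 0:
        return trace
    coef = np.polyfit(t, np.log(r), 1)
    if coef[0] >= 0:  # not decaying; leave alone
        return trace
    corrected = trace.astype(float).copy()
    # subtract from the start of the second pulse's baseline window onward so
    # both the EPSC2 baseline and peak are tail-free
    start = min(w0, max(int(round((stim2_s - 0.010) * fs)), int((stim1_s + 0.010) * fs)))
    idx = np.arange(start, trace.size)
    tail = np.exp(coef[1] + coef[0] * idx / fs)
    corrected[idx] -= (1 if polarity > 0 else -1) * tail
    return corrected


def paired_pulse(
    sweeps: SweepSet,
    polarity: int = -1,
    search_window_s: tuple[float, float] = (0.002, 0.02),
    baseline_window_s: tuple[float, float] = (-0.010, -0.001),
) -> PairedPulseResult:
    """Paired-pulse ratio per ISI: mean over repetitions of EPSC2/EPSC1.

    Each sweep must carry ``stim1_s``, ``stim2_s`` and ``isi_ms`` metadata.
    Before measuring EPSC2 the decay tail of EPSC1 is extrapolated
    (log-linear fit just before the second stimulus) and subtracted, so
    short-ISI ratios are not biased by tail summation.  Repetitions whose
    first EPSC falls below the baseline noise floor (3 robust SD) are
    dropped and logged.  Five to eight repetitions per ISI is the
    recommended design; a warning is issued outside that range.
    """
    required = {"stim1_s", "stim2_s", "isi_ms"}
    if not required.issubset(sweeps.meta.columns):
        raise ValueError(f"sweep metadata must include {sorted(required)}")
    rows = []
    for i in range(sweeps.n_sweeps):
        m = sweeps.meta.iloc[i]
        trace = sweeps.sweep(i)
        # second-pulse search must not run past the next stimulus at short ISIs
        isi_s = m["isi_ms"] / 1000.0
        win = (search_window_s[0], min(search_window_s[1], isi_s - ARTIFACT_BLANK_S)) \
            if isi_s < search_window_s[1] + ARTIFACT_BLANK_S else search_window_s
        floor = _noise_floor(trace, sweeps.sample_rate_hz, m["stim1_s"], baseline_window_s)
        a1 = psc_amplitude(trace, sweeps.sample_rate_hz, m["stim1_s"], polarity,
                           win, baseline_window_s)
        corrected = _subtract_epsc1_tail(
            trace, sweeps.sample_rate_hz, m["stim1_s"], m["stim2_s"], polarity, floor
        )
        a2 = psc_amplitude(corrected, sweeps.sample_rate_hz, m["stim2_s"], polarity,
                           win, baseline_window_s)
        if a1 <= floor:
            logger.info(
                "dropping repetition %d (ISI %s ms): EPSC1 %.1f pA below noise floor %.1f pA",
                i, m["isi_ms"], a1, floor,
            )
            continue
        rows.append({"isi_ms": float(m["isi_ms"]), "rep": i,
                     "epsc1_pa": a1, "epsc2_pa": a2, "ratio": a2 / a1})
    amps = pd.DataFrame(rows, columns=["isi_ms", "rep", "epsc1_pa", "epsc2_pa", "ratio"])
    ppr = {}
    n_reps = {}
    for isi, grp in amps.groupby("isi_ms"):
        if not 5 <= len(grp) <= 8:
            warnings.warn(
                f"ISI {isi} ms has {len(grp)} repetitions; 5-8 recommended", stacklevel=2
            )
        ppr[float(isi)] = float(grp["ratio"].mean())
        n_reps[float(isi)] = int(len(grp))
    return PairedPulseResult(ppr_by_isi=ppr, n_reps_by_isi=n_reps, amplitudes=amps)


@dataclass
class AmpaNmdaResult:
    """AMPA (peak at -70 mV) and NMDA (+40 mV at 50 ms) amplitudes and ratio."""

    ampa_amp_pa: float
    nmda_amp_pa: float
    ratio: float  # NaN when the NMDA component is indistinguishable from 0


def ampa_nmda(
    sweeps_neg70: SweepSet,
    sweeps_pos40: SweepSet,
    stim_time_s: float,
    nmda_latency_s: float = 0.050,
    nmda_window_s: float = 0.001,
    search_window_s: tuple[float, float] = (0.002, 0.05),
    baseline_window_s: tuple[float, float] = (-0.010, -0.001),
) -> AmpaNmdaResult:
    """AMPA:NMDA ratio from averaged traces at the two holding potentials.

    AMPA is the peak of the averaged inward EPSC at -70 mV; NMDA is the mean
    of the averaged +40 mV trace over a 1-ms window centered 50 ms after the
    stimulus (baseline-subtracted).  The ratio is AMPA/NMDA and is flagged
    NaN when the NMDA read-out is ~0.
    """
    fs = sweeps_neg70.sample_rate_hz
    avg_neg = sweeps_neg70.traces.mean(axis=1)
    avg_pos = sweeps_pos40.traces.mean(axis=1)
    ampa = psc_amplitude(avg_neg, fs, stim_time_s, -1, search_window_s, baseline_window_s)
    b0 = int(round((stim_time_s + baseline_window_s[0]) * fs))
    b1 = int(round((stim_time_s + baseline_window_s[1]) * fs))
    baseline = avg_pos[b0:b1].mean()
    c = stim_time_s + nmda_latency_s
    w0 = int(round((c - nmda_window_s / 2) * fs))
    w1 = max(int(round((c + nmda_window_s / 2) * fs)), w0 + 1)
    nmda = float(avg_pos[w0:w1].mean() - baseline)
    if abs(nmda) < 1e-9:
        return AmpaNmdaResult(ampa_amp_pa=ampa, nmda_amp_pa=nmda, ratio=np.nan)
    return AmpaNmdaResult(ampa_amp_pa=ampa, nmda_amp_pa=abs(nmda), ratio=ampa / abs(nmda))


@dataclass
class MepscEvent:
    time_s: float
    amplitude_pa: float


def detect_mepscs(
    trace: np.ndarray,
    sample_rate_hz: float,
    k_mad: float = 4.0,
    min_interval_ms: float = 5.0,
    polarity: int = -1,
    smooth_ms: float = 3.0,
    baseline_ms: float = 51.0,
) -> list[MepscEvent]:
    """Threshold-based miniature EPSC detection.

    The trace is smoothed with a short boxcar and referenced to a rolling
    median local baseline.  The noise scale sigma is the robust (MAD-based)
    SD of the raw residual; events are local extrema of the smoothed
    residual exceeding ``k_mad`` x sigma in the configured polarity,
    separated by at least ``min_interval_ms`` and with a prominence of at
    least half the threshold (so noise riding an event's decay tail is not
    double-counted).  Amplitude is the residual at the peak.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return []
    if trace.size < 10 * sample_rate_hz:
        warnings.warn("trace shorter than 10 s; noise estimate may be unstable", stacklevel=2)
    win = max(3, int(round(baseline_ms / 1000.0 * sample_rate_hz)) | 1)
    baseline = (
        pd.Series(trace).rolling(win, center=True, min_periods=1).median().to_numpy()
        if trace.size >= win
        else np.full_like(trace, np.median(trace))
    )
    resid = (trace - baseline) * (1 if polarity > 0 else -1)
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sigma == 0:
        sigma = np.finfo(float).tiny
    w = max(1, int(round(smooth_ms / 1000.0 * sample_rate_hz)))
    kernel = np.ones(w) / w
    smoothed = np.convolve(resid, kernel, mode="same")
    distance = max(1, int(round(min_interval_ms / 1000.0 * sample_rate_hz)))
    peaks, _ = signal.find_peaks(smoothed, height=k_mad * sigma, distance=distance,
                                 prominence=k_mad * sigma / 2.0)
    return [
        MepscEvent(time_s=float(p / sample_rate_hz), amplitude_pa=float(resid[p]))
        for p in peaks
    ]


@dataclass
class MepscSummary:
    """Per-cell mEPSC summary with the >= 500 event inclusion rule."""

    n_events: int
    frequency_hz: float
    mean_amplitude_pa: float
    included: bool
    ecdf_amplitudes_pa: np.ndarray  # sorted subsample (500 events) or empty
    ecdf_probabilities: np.ndarray


def mepsc_summary(
    events: list[MepscEvent],
    recording_length_s: float,
    n_sample: int = 500,
    seed: int | np.random.Generator = 0,
) -> MepscSummary:
    """Frequency, mean amplitude, inclusion flag and amplitude ECDF.

    Cells with fewer than ``n_sample`` (500) detected events are excluded
    from cumulative-probability analysis; the ECDF is built from ``n_sample``
    randomly selected events (seeded).
    """
    if recording_length_s <= 0:
        raise ValueError("recording length must be positive")
    n = len(events)
    amps = np.array([e.amplitude_pa for e in events], dtype=float)
    included = n >= n_sample
    if included:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        chosen = rng.choice(amps, size=n_sample, replace=False)
        srt = np.sort(chosen)
        probs = np.arange(1, n_sample + 1) / n_sample
    else:
        srt = np.empty(0)
        probs = np.empty(0)
    return MepscSummary(
        n_events=n,
        frequency_hz=n / recording_length_s,
        mean_amplitude_pa=float(amps.mean()) if n else np.nan,
        included=included,
        ecdf_amplitudes_pa=srt,
        ecdf_probabilities=probs,
    )


def detect_spikes_cc(
    v_trace: np.ndarray,
    sample_rate_hz: float,
    threshold_mv: float = 0.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Spike times (s) from a current-clamp voltage trace.

    Spikes are upward crossings of the threshold (default 0 mV), separated
    by at least the refractory interval.
    """
    v = np.asarray(v_trace, dtype=float)
    above = v > threshold_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    refr = refractory_ms / 1000.0 * sample_rate_hz
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= refr:
            kept.append(c)
    return np.asarray(kept) / sample_rate_hz


@dataclass
class ExcitabilityCurve:
    """Spikes per current step and rheobase (pA; NaN when no step spikes)."""

    step_amplitudes_pa: np.ndarray
    spike_counts: np.ndarray
    rheobase_pa: float


def excitability_curve(sweeps: SweepSet) -> ExcitabilityCurve:
    """Spike count per square current step and rheobase.

    Each sweep must carry ``step_pa``, ``step_start_s`` and ``step_dur_s``
    metadata; only spikes during the step window count.  Rheobase is the
    smallest step amplitude eliciting at least one spike; NaN (flagged) when
    no step does.
    """
    required = {"step_pa", "step_start_s", "step_dur_s"}
    if not required.issubset(sweeps.meta.columns):
        raise ValueError(f"sweep metadata must include {sorted(required)}")
    amps, counts = [], []
    for i in range(sweeps.n_sweeps):
        m = sweeps.meta.iloc[i]
        times = detect_spikes_cc(sweeps.sweep(i), sweeps.sample_rate_hz)
        in_step = (times >= m["step_start_s"]) & (times < m["step_start_s"] + m["step_dur_s"])
        amps.append(float(m["step_pa"]))
        counts.append(int(in_step.sum()))
    order = np.argsort(amps)
    amps = np.asarray(amps)[order]
    counts = np.asarray(counts)[order]
    spiking = amps[counts > 0]
    rheobase = float(spiking[0]) if spiking.size else np.nan
    return ExcitabilityCurve(step_amplitudes_pa=amps, spike_counts=counts, rheobase_pa=rheobase)


def oepsc_by_power(
    sweeps: SweepSet,
    polarity: int = -1,
    comparison_power_mw: float = 4.0,
    search_window_s: tuple[float, float] = (0.002, 0.05),
    baseline_window_s: tuple[float, float] = (-0.010, -0.001),
) -> tuple[pd.DataFrame, float]:
    """Mean optically evoked PSC amplitude per light power.

    Sweeps must carry ``power_mw`` and ``stim1_s`` metadata.  Returns a
    per-power table and the mean amplitude at the comparison power (4 mW by
    convention; NaN when that power is absent).
    """
    required = {"power_mw", "stim1_s"}
    if not required.issubset(sweeps.meta.columns):
        raise ValueError(f"sweep metadata must include {sorted(required)}")
    rows = []
    for i in range(sweeps.n_sweeps):
        m = sweeps.meta.iloc[i]
        amp = psc_amplitude(sweeps.sweep(i), sweeps.sample_rate_hz, m["stim1_s"],
                            polarity, search_window_s, baseline_window_s)
        rows.append({"power_mw": float(m["power_mw"]), "amplitude_pa": amp})
    df = pd.DataFrame(rows)
    table = df.groupby("power_mw", as_index=False).agg(
        mean_amplitude_pa=("amplitude_pa", "mean"), n_sweeps=("amplitude_pa", "size")
    )
    at_cmp = table.loc[table["power_mw"] == comparison_power_mw, "mean_amplitude_pa"]
    return table, (float(at_cmp.iloc[0]) if len(at_cmp) else np.nan)
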