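"""Synthetic data with ground truth for every stage of the pipeline.

The generator emulates the study's acquisition conditions: a 30-min
parkinsonian baseline followed by levodopa injection, single units as
inhomogeneous-Poisson trains whose rate switches at injection by a
class-specific gain (On x5, Off x0.2, NC/IN x1), a latent dyskinesia
trajectory that rises after injection and fluctuates slowly, DYSK units
whose post-injection rate additionally tracks that latent, optogenetic
tagging epochs of 100-ms laser pulses at 1 Hz (1000 pulses at each of 0.5,
1, 2 and 4 mW) with short-latency evoked bursts in tagged units, ALO AIM
scores discretized from the latent, open-field tracking with a rotational
bias, negative-binomial rabies region-count tables, lognormal per-cell
RNAscope intensities with TRAP enrichment, and double-exponential
postsynaptic-current / leaky-integrate-and-fire current-clamp sweeps.

All randomness flows from one seeded ``numpy.random.Generator`` per call;
the same config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import AimTrace, TrackingTrace
from .invivo import SessionEvents, SpikeTrain
from .slicephys import SweepSet

__all__ = [
    "SynthConfig",
    "latent_trajectory",
    "coupling_for_r2",
    "gen_unit_population",
    "gen_aim_trace",
    "gen_tracking",
    "gen_session",
    "gen_rabies_tables",
    "gen_cell_table",
    "gen_sweeps",
    "write_session",
]

CLASSES = ("On", "Off", "NC", "IN")
WAVEFORM_SAMPLE_US = 25.0  # 40 kHz
WAVEFORM_N_SAMPLES = 48


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording session.

    Defaults mirror the acquisition design: 30-min baseline before
    injection, 1-min AIM cadence scored every other minute, 100-ms laser
    pulses at 1 Hz with 1000 pulses per power at 0.5/1/2/4 mW, and sweep
    digitization at 10 kHz.
    """

    seed: int = 0
    n_units: int = 100
    class_mix: dict = field(
        default_factory=lambda: {"On": 0.4, "Off": 0.3, "NC": 0.25, "IN": 0.05}
    )
    dysk_fraction_of_on: float = 0.5
    baseline_rate_hz: float = 2.0
    in_baseline_rate_hz: float = 8.0
    on_gain: float = 5.0
    off_gain: float = 0.2
    # construction-level coupling of binned rate to the latent dyskinesia
    # trajectory, expressed as a target R^2 (before AIM discretization noise)
    dysk_r2: float = 0.6
    on_r2: float = 0.05
    laser_latency_ms: float = 5.0
    laser_jitter_ms: float = 1.0
    laser_spike_prob: float = 0.9
    laser_burst_rate_hz: float = 150.0
    laser_burst_ms: float = 20.0
    laser_powers_mw: tuple = (0.5, 1.0, 2.0, 4.0)
    pulses_per_power: int = 1000
    pulse_rate_hz: float = 1.0
    pulse_duration_s: float = 0.1
    aim_noise_sd: float = 0.05
    session_minutes: float = 120.0
    baseline_minutes: float = 30.0
    sample_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if set(self.class_mix) - set(CLASSES):
            raise ValueError(f"class_mix keys must be among {CLASSES}")
        for name in ("baseline_rate_hz", "in_baseline_rate_hz", "on_gain", "off_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.session_minutes <= 0 or self.baseline_minutes < 0:
            raise ValueError("session duration must be positive")
        if self.session_minutes <= self.baseline_minutes:
            raise ValueError("session must extend beyond the baseline period")
        if self.n_units < 0:
            raise ValueError("n_units must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_mix" in raw:
            raw["class_mix"] = dict(raw["class_mix"])
        if "laser_powers_mw" in raw:
            raw["laser_powers_mw"] = tuple(raw["laser_powers_mw"])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["laser_powers_mw"] = list(d["laser_powers_mw"])
        return json.dumps(d, indent=2)


def latent_trajectory(cfg: SynthConfig, t_min: np.ndarray) -> np.ndarray:
    """Latent dyskinesia intensity in [0, 1] at minutes-from-injection t.

    Zero before injection; afterwards an onset/offset envelope (3-min rise,
    slow 120-min decay) carrying a 20-min sinusoidal fluctuation, emulating
    the rise, plateau and wearing-off of a levodopa response.
    """
    t = np.asarray(t_min, dtype=float)
    env = (1.0 - np.exp(-np.maximum(t, 0.0) / 3.0)) * np.exp(-np.maximum(t, 0.0) / 120.0)
    wave = 0.55 + 0.45 * np.sin(2 * np.pi * t / 20.0)
    return np.clip(np.where(t > 0, env * wave, 0.0), 0.0, 1.0)


def coupling_for_r2(target_r2: float, latent: np.ndarray, mean_rate_hz: float,
                    bin_s: float = 60.0) -> float:
    """Rate-vs-latent coupling slope (Hz per latent unit) giving a target R^2.

    For a 1-min binned Poisson train with mean rate r, the count-noise
    variance of the rate estimate is r / bin_s, so the slope b satisfying
    R^2 = b^2 Var(latent) / (b^2 Var(latent) + r / bin_s) is

        b = sqrt(R^2 / (1 - R^2) * r / bin_s / Var(latent)).
    """
    if not 0 <= target_r2 < 1:
        raise ValueError("target R^2 must be in [0, 1)")
    v = np.var(np.asarray(latent, dtype=float))
    if v == 0 or target_r2 == 0:
        return 0.0
    return float(np.sqrt(target_r2 / (1 - target_r2) * mean_rate_hz / bin_s / v))


def _poisson_piecewise(rng: np.random.Generator, rates_hz: np.ndarray,
                       seg_edges_s: np.ndarray) -> np.ndarray:
    """Inhomogeneous Poisson spikes from piecewise-constant rates."""
    times = []
    for r, t0, t1 in zip(rates_hz, seg_edges_s[:-1], seg_edges_s[1:]):
        if r <= 0:
            continue
        n = rng.poisson(r * (t1 - t0))
        if n:
            times.append(rng.uniform(t0, t1, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def _enforce_refractory(times: np.ndarray, min_isi_s: float = 0.001) -> np.ndarray:
    """Delete spikes violating the refractory period (thinning).

    Equivalent to a greedy left-to-right scan keeping each spike at least
    ``min_isi_s`` after the last kept one; vectorized by deleting, per pass,
    violators whose predecessor survives the pass.
    """
    while times.size > 1:
        bad = np.concatenate([[False], np.diff(times) < min_isi_s])
        if not bad.any():
            break
        # keep violators whose predecessor is itself deleted this pass
        drop = bad & ~np.concatenate([[False], bad[:-1]])
        times = times[~drop]
    return times


def _waveform_template(peak_to_valley_us: float, peak_width_us: float,
                       amp_uv: float = 100.0) -> np.ndarray:
    """Parametric biphasic extracellular waveform (positive peak, later valley)."""
    t = np.arange(WAVEFORM_N_SAMPLES) * WAVEFORM_SAMPLE_US
    t_peak = 300.0
    sig1 = peak_width_us / 2.355  # FWHM -> gaussian sigma
    sig2 = 1.6 * sig1
    peak = np.exp(-((t - t_peak) ** 2) / (2 * sig1**2))
    valley = 0.6 * np.exp(-((t - t_peak - peak_to_valley_us) ** 2) / (2 * sig2**2))
    return amp_uv * (peak - valley)


def _gen_waveforms(rng: np.random.Generator, ptv_us: float, width_us: float,
                   n: int = 60, noise_uv: float = 8.0,
                   shift_uv: float = 0.0) -> np.ndarray:
    tpl = _waveform_template(ptv_us, width_us)
    return tpl + shift_uv + rng.normal(0.0, noise_uv, size=(n, tpl.size))


def _class_labels(rng: np.random.Generator, cfg: SynthConfig) -> list[str]:
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    return [classes[i] for i in rng.choice(len(classes), size=cfg.n_units, p=probs)]


def gen_unit_population(
    cfg: SynthConfig,
    include_laser_epoch: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpikeTrain], SessionEvents, pd.DataFrame]:
    """Simulate a session's unit population with ground-truth labels.

    Each unit is an inhomogeneous-Poisson train whose rate switches at the
    injection time by its class gain.  DYSK units (a configured fraction of
    On units; these are the TRAPed/tagged units) additionally modulate with
    the latent dyskinesia trajectory at a coupling calibrated to the
    configured construction R^2.  Tagged units receive laser-locked evoked
    spikes (first spike at the configured latency/jitter with the configured
    probability, plus a short burst) during the tagging epoch appended after
    the behavioral session.  A refractory period of 1 ms is enforced by
    deletion.

    Returns ``(spike trains, session events, ground-truth label table)``.
    """
    rng = rng or cfg.rng()
    inj_s = cfg.baseline_minutes * 60.0
    behav_end_s = cfg.session_minutes * 60.0

    labels = _class_labels(rng, cfg)
    minute_edges = np.arange(0.0, behav_end_s + 1e-9, 60.0)
    minute_mid_min = (minute_edges[:-1] + 30.0) / 60.0
    latent = latent_trajectory(cfg, minute_mid_min - cfg.baseline_minutes)
    post = minute_mid_min > cfg.baseline_minutes

    # laser tagging epoch appended after the behavioral session
    n_pulses = cfg.pulses_per_power * len(cfg.laser_powers_mw)
    if include_laser_epoch and n_pulses:
        laser_start = behav_end_s + 60.0
        onsets = laser_start + np.arange(n_pulses) / cfg.pulse_rate_hz
        powers = np.repeat(cfg.laser_powers_mw, cfg.pulses_per_power)
        session_end = float(onsets[-1] + 1.0) if n_pulses else behav_end_s
    else:
        onsets = np.empty(0)
        powers = np.empty(0)
        session_end = behav_end_s

    events = SessionEvents(
        injection_time_s=inj_s,
        session_start_s=0.0,
        session_end_s=session_end,
        laser_onsets_s=onsets,
        laser_powers_mw=powers,
        pulse_duration_s=cfg.pulse_duration_s,
    )

    trains: list[SpikeTrain] = []
    rows = []
    for i, cls in enumerate(labels):
        base = cfg.in_baseline_rate_hz if cls == "IN" else cfg.baseline_rate_hz
        gain = {"On": cfg.on_gain, "Off": cfg.off_gain, "NC": 1.0, "IN": 1.0}[cls]
        is_dysk = bool(cls == "On" and rng.uniform() < cfg.dysk_fraction_of_on)
        tagged = is_dysk  # TRAPed units are the dyskinesia-active subset
        rates = np.where(post, base * gain, base).astype(float)
        if cls == "On":
            target = cfg.dysk_r2 if is_dysk else cfg.on_r2
            post_latent = latent[post]
            b = coupling_for_r2(target, post_latent, base * gain)
            rates[post] = np.maximum(
                base * gain + b * (post_latent - post_latent.mean()), 0.0
            )
        spikes = _poisson_piecewise(rng, rates, minute_edges)

        if events.laser_onsets_s.size:
            laser_rate = base  # spontaneous rate during the tagging epoch
            seg = np.array([events.laser_onsets_s[0] - 1.0, session_end])
            spikes = np.concatenate(
                [spikes, _poisson_piecewise(rng, np.array([laser_rate]), seg)]
            )
            if tagged:
                spikes = np.concatenate(
                    [spikes, _evoked_laser_spikes(rng, cfg, events.laser_onsets_s)]
                )
            spikes = np.sort(spikes)

        spikes = _enforce_refractory(np.sort(spikes))

        if cls == "IN":
            ptv, width = 300.0, 100.0
        else:
            ptv, width = 700.0, 250.0
        ptv *= 1 + rng.normal(0, 0.05)
        width *= 1 + rng.normal(0, 0.05)
        spont_wf = _gen_waveforms(rng, ptv, width)
        evoked_wf = _gen_waveforms(rng, ptv, width)

        unit_id = f"u{i:04d}"
        trains.append(
            SpikeTrain(
                unit_id=unit_id,
                spike_times=spikes,
                spont_waveforms=spont_wf,
                evoked_waveforms=evoked_wf,
                peak_to_valley_us=ptv,
                peak_width_us=width,
            )
        )
        rows.append(
            {
                "unit_id": unit_id,
                "true_class": cls,
                "true_dysk": is_dysk,
                "true_tagged": tagged,
            }
        )
    labels_df = pd.DataFrame(rows, columns=["unit_id", "true_class", "true_dysk", "true_tagged"])
    return trains, events, labels_df


def gen_aim_trace(
    cfg: SynthConfig,
    latent: np.ndarray,
    t_min: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> AimTrace:
    """ALO AIM trace from a latent dyskinesia trajectory in [0, 1].

    Each of the three subscores discretizes the latent independently:
    round(4 * clip(latent + noise, 0, 1)) with Gaussian noise of SD
    ``aim_noise_sd``.  Timepoints default to every other minute over the
    latent's length (the scoring cadence used alongside recordings).
    """
    rng = rng or cfg.rng()
    latent = np.asarray(latent, dtype=float)
    if latent.size and (latent.min() < 0 or latent.max() > 1):
        raise ValueError("latent trajectory must lie in [0, 1]")
    if t_min is None:
        t_min = np.arange(latent.size, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    subs = []
    for _ in range(3):
        noisy = latent + rng.normal(0.0, cfg.aim_noise_sd, size=latent.shape)
        subs.append(np.round(4 * np.clip(noisy, 0.0, 1.0)).astype(int))
    return AimTrace(t_min=t_min, axial=subs[0], limb=subs[1], orofacial=subs[2])


def gen_tracking(
    cfg: SynthConfig,
    bias_rev_per_min: float = 0.0,
    duration_s: float = 600.0,
    heading_noise_sd: float = 0.0,
    speed_cm_s: float = 4.0,
    fs_hz: float = 30.0,
    rng: np.random.Generator | None = None,
) -> TrackingTrace:
    """Open-field tracking inside a 25-cm-diameter arena.

    Heading drifts at ``bias_rev_per_min`` revolutions per minute (positive
    = contralateral) plus white angular noise; the animal moves at constant
    speed along its heading and is clipped radially at the wall.
    """
    if abs(bias_rev_per_min) > 60:
        raise ValueError("rotational bias beyond 60 rev/min is not plausible")
    rng = rng or cfg.rng()
    n = int(round(duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    dt = 1.0 / fs_hz
    dtheta = 2 * np.pi * bias_rev_per_min / 60.0 * dt
    heading = np.cumsum(
        np.full(n, dtheta) + rng.normal(0.0, heading_noise_sd * np.sqrt(dt), size=n)
    )
    heading -= heading[0]
    radius = 12.5
    x = np.zeros(n)
    y = np.zeros(n)
    for i in range(1, n):
        nx = x[i - 1] + speed_cm_s * dt * np.cos(heading[i - 1])
        ny = y[i - 1] + speed_cm_s * dt * np.sin(heading[i - 1])
        r = np.hypot(nx, ny)
        if r > radius:
            nx, ny = nx * radius / r, ny * radius / r
        x[i], y[i] = nx, ny
    return TrackingTrace(t=t, x=x, y=y, heading=heading, arena_radius_cm=radius)


def gen_session(cfg: SynthConfig, every_other_minute: bool = True,
                include_laser_epoch: bool = True):
    """Full session bundle: spike trains, events, labels, and an AIM trace
    scored on the post-injection minutes (every other minute by default)."""
    rng = cfg.rng()
    trains, events, labels = gen_unit_population(
        cfg, include_laser_epoch=include_laser_epoch, rng=rng
    )
    post_minutes = np.arange(cfg.baseline_minutes, cfg.session_minutes, 1.0)
    if every_other_minute:
        post_minutes = post_minutes[::2]
    rel = post_minutes - cfg.baseline_minutes + 0.5
    aim = gen_aim_trace(cfg, latent_trajectory(cfg, rel), t_min=rel, rng=rng)
    return trains, events, labels, aim


def _evoked_laser_spikes(rng: np.random.Generator, cfg: SynthConfig,
                         onsets: np.ndarray) -> np.ndarray:
    """Laser-locked spikes for a tagged unit: one reliable first spike at the
    configured latency/jitter plus a short high-rate burst per pulse."""
    first_mask = rng.uniform(size=onsets.size) < cfg.laser_spike_prob
    first = (
        onsets[first_mask]
        + cfg.laser_latency_ms / 1000.0
        + rng.normal(0.0, cfg.laser_jitter_ms / 1000.0, size=int(first_mask.sum()))
    )
    n_burst = rng.poisson(cfg.laser_burst_rate_hz * cfg.laser_burst_ms / 1000.0,
                          size=onsets.size)
    burst = np.repeat(onsets, n_burst) + cfg.laser_latency_ms / 1000.0 + rng.uniform(
        0.0, cfg.laser_burst_ms / 1000.0, size=int(n_burst.sum())
    )
    return np.concatenate([first, burst])


def gen_tagging_units(
    cfg: SynthConfig,
    n_units: int,
    tagged: bool,
    rng: np.random.Generator | None = None,
    latency_ms: float | None = None,
) -> tuple[list[SpikeTrain], SessionEvents]:
    """Units recorded during a stand-alone optogenetic tagging epoch.

    Untagged units are homogeneous Poisson at the baseline rate with no
    laser coupling (the null for optotag calibration); tagged units add the
    configured laser-evoked response.  ``latency_ms`` overrides the config's
    evoked latency when given.
    """
    rng = rng or cfg.rng()
    n_pulses = cfg.pulses_per_power * len(cfg.laser_powers_mw)
    onsets = 10.0 + np.arange(n_pulses) / cfg.pulse_rate_hz
    end = float(onsets[-1] + 10.0)
    events = SessionEvents(
        injection_time_s=0.0,
        session_start_s=0.0,
        session_end_s=end,
        laser_onsets_s=onsets,
        laser_powers_mw=np.repeat(cfg.laser_powers_mw, cfg.pulses_per_power),
        pulse_duration_s=cfg.pulse_duration_s,
    )
    if latency_ms is not None:
        cfg = dataclasses.replace(cfg, laser_latency_ms=latency_ms)
    trains = []
    for i in range(n_units):
        n = rng.poisson(cfg.baseline_rate_hz * end)
        spikes = np.sort(rng.uniform(0.0, end, size=n))
        if tagged:
            spikes = np.sort(np.concatenate([spikes, _evoked_laser_spikes(rng, cfg, onsets)]))
        spikes = _enforce_refractory(spikes)
        ptv = 700.0 * (1 + rng.normal(0, 0.05))
        width = 250.0 * (1 + rng.normal(0, 0.05))
        trains.append(
            SpikeTrain(
                unit_id=f"t{i:04d}",
                spike_times=spikes,
                spont_waveforms=_gen_waveforms(rng, ptv, width),
                evoked_waveforms=_gen_waveforms(rng, ptv, width),
                peak_to_valley_us=ptv,
                peak_width_us=width,
            )
        )
    return trains, events


DEFAULT_REGION_MEANS = {
    "MOp": 400.0,
    "MOs": 250.0,
    "SSp": 200.0,
    "SSs": 80.0,
    "ORB": 40.0,
    "CLA": 30.0,
    "VAL": 60.0,
    "VM": 50.0,
    "PF": 120.0,
    "CM": 40.0,
    "GPe": 90.0,
    "STN": 20.0,
    "SNc": 30.0,
    "DR": 15.0,
    "BLA": 25.0,
}


def gen_rabies_tables(
    cfg: SynthConfig,
    condition_effects: dict[str, dict[str, float]],
    n_animals_per_condition: int = 5,
    genotype: str = "D1-Cre",
    region_means: dict[str, float] | None = None,
    dispersion: float | None = 10.0,
    starter_mean: float = 100.0,
    spread_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list:
    """Per-animal rabies region-count tables with condition effects.

    ``condition_effects`` maps condition name to per-region multiplicative
    factors on the base region means (regions not listed keep factor 1).
    Counts are negative-binomial with the given dispersion (Poisson in the
    limit ``dispersion=None``).  Starter counts are Poisson around
    ``starter_mean`` with extra-striatal spread Poisson at
    ``spread_fraction`` of the striatal count.
    """
    from .connectivity import RegionCountTable

    rng = rng or cfg.rng()
    means = dict(DEFAULT_REGION_MEANS if region_means is None else region_means)
    tables = []
    idx = 0
    for condition, effects in condition_effects.items():
        for _ in range(n_animals_per_condition):
            counts = {}
            for region, mu in means.items():
                m = mu * effects.get(region, 1.0)
                if m <= 0:
                    counts[region] = 0
                elif dispersion is None:
                    counts[region] = int(rng.poisson(m))
                else:
                    p = dispersion / (dispersion + m)
                    counts[region] = int(rng.negative_binomial(dispersion, p))
            striatal = int(rng.poisson(starter_mean)) + 1
            extra = int(rng.poisson(spread_fraction * striatal))
            tables.append(
                RegionCountTable(
                    animal_id=f"a{idx:03d}",
                    genotype=genotype,
                    condition=condition,
                    counts=counts,
                    striatal_starters=striatal,
                    extrastriatal_starters=extra,
                )
            )
            idx += 1
    return tables


def gen_cell_table(
    cfg: SynthConfig,
    enrichment: dict[str, float] | None = None,
    n_cells: int = 500,
    n_slices: int = 10,
    trap_fraction: float = 0.10,
    tdtomato_separation: float = 5.0,
    intensity_sd_log: float = 0.3,
    slice_sd_log: float = 0.3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell RNAscope intensity table with TRAP enrichment ground truth.

    Cells carry lognormal per-probe intensity sums scaled by a per-slice
    staining factor; TRAPed cells (a configured fraction) have their probe
    intensities multiplied by the per-probe enrichment fold and a
    ``tdtomato_separation``-fold brighter tdTomato channel.  Columns follow
    the documented schema plus a ``true_trap`` ground-truth flag.
    """
    rng = rng or cfg.rng()
    enrichment = enrichment or {}
    for probe, fold in enrichment.items():
        if fold <= 0:
            raise ValueError(f"enrichment fold for {probe!r} must be positive")
    base = {"drd1": 20.0, "drd2": 4.0, "pdyn": 12.0, "tdtomato": 3.0}
    slice_ids = rng.integers(0, n_slices, size=n_cells)
    subregions = np.array(["DLS", "DMS", "VLS"])[rng.integers(0, 3, size=n_cells)]
    trap = rng.uniform(size=n_cells) < trap_fraction
    area = rng.lognormal(np.log(120.0), 0.2, size=n_cells)
    slice_factor = {
        probe: rng.lognormal(0.0, slice_sd_log, size=n_slices) for probe in base
    }
    data = {
        "cell_id": [f"c{i:05d}" for i in range(n_cells)],
        "slice_id": [f"s{j:02d}" for j in slice_ids],
        "subregion": subregions,
        "area_um2": area,
        "d1_positive": np.ones(n_cells, dtype=bool),
        "true_trap": trap,
    }
    for probe, mu in base.items():
        per_cell = rng.lognormal(np.log(mu), intensity_sd_log, size=n_cells)
        per_cell *= slice_factor[probe][slice_ids]
        fold = enrichment.get(probe, 1.0)
        per_cell = np.where(trap, per_cell * fold, per_cell)
        if probe == "tdtomato":
            per_cell = np.where(trap, per_cell * tdtomato_separation, per_cell)
        data[probe] = per_cell * area  # stored as intensity sums over the cell
    return pd.DataFrame(data)


def _double_exp_kernel(t_s: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential synaptic kernel, zero before t=0."""
    k = np.where(t_s >= 0, np.exp(-np.maximum(t_s, 0) / tau_decay_s)
                 - np.exp(-np.maximum(t_s, 0) / tau_rise_s), 0.0)
    peak_t = (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
        * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-peak_t / tau_decay_s) - np.exp(-peak_t / tau_rise_s)
    return k / peak


def gen_sweeps(cfg: SynthConfig, kind: str, rng: np.random.Generator | None = None,
               **kwargs) -> SweepSet:
    """Synthetic clamp sweeps of a given kind.

    Kinds: ``paired-pulse`` (two stimuli per sweep at each ISI),
    ``ampa-nmda`` (averag-able sweeps at -70 and +40 mV holding),
    ``mepsc`` (one long trace with Poisson-timed events),
    ``steps`` (leaky-integrate-and-fire responses to 100-600 pA squares),
    ``optical`` (one optically evoked PSC per sweep across light powers).
    Ground-truth quantities are stored in ``SweepSet.ground_truth``.
    """
    rng = rng or cfg.rng()
    dispatch = {
        "paired-pulse": _gen_paired_pulse,
        "ampa-nmda": _gen_ampa_nmda,
        "mepsc": _gen_mepsc,
        "steps": _gen_steps,
        "optical": _gen_optical,
    }
    if kind not in dispatch:
        raise ValueError(f"unrecognized sweep kind {kind!r}; one of {sorted(dispatch)}")
    return dispatch[kind](cfg, rng, **kwargs)


def _gen_paired_pulse(cfg: SynthConfig, rng, amplitude_pa: float = 400.0,
                      depression: float = 0.6,
                      isis_ms: tuple = (25.0, 50.0, 100.0, 200.0, 500.0),
                      n_reps: int = 6, noise_sd_pa: float = 0.0,
                      tau_rise_ms: float = 1.0, tau_decay_ms: float = 8.0) -> SweepSet:
    fs = cfg.sample_rate_hz
    dur = 0.05 + max(isis_ms) / 1000.0 + 0.15
    t = np.arange(int(round(dur * fs))) / fs
    stim1 = 0.05
    traces, meta = [], []
    for isi in isis_ms:
        stim2 = stim1 + isi / 1000.0
        for rep in range(n_reps):
            tr = -amplitude_pa * _double_exp_kernel(t - stim1, tau_rise_ms / 1000, tau_decay_ms / 1000)
            tr += -amplitude_pa * depression * _double_exp_kernel(
                t - stim2, tau_rise_ms / 1000, tau_decay_ms / 1000
            )
            if noise_sd_pa > 0:
                tr = tr + rng.normal(0.0, noise_sd_pa, size=t.size)
            traces.append(tr)
            meta.append({"stim1_s": stim1, "stim2_s": stim2, "isi_ms": isi,
                         "holding_mv": -70.0})
    return SweepSet(
        sample_rate_hz=fs,
        traces=np.column_stack(traces),
        meta=pd.DataFrame(meta),
        ground_truth={"depression": depression, "amplitude_pa": amplitude_pa},
    )


def _gen_ampa_nmda(cfg: SynthConfig, rng, ampa_pa: float = 300.0,
                   nmda_at_50ms_pa: float = 100.0, n_reps: int = 15,
                   noise_sd_pa: float = 0.0, stim_s: float = 0.05) -> SweepSet:
    fs = cfg.sample_rate_hz
    t = np.arange(int(round(0.4 * fs))) / fs
    fast = _double_exp_kernel(t - stim_s, 0.001, 0.008)
    slow = _double_exp_kernel(t - stim_s, 0.002, 0.050)
    k50 = slow[int(round((stim_s + 0.050) * fs))]
    traces, meta = [], []
    for _ in range(n_reps):
        tr = -ampa_pa * fast
        if noise_sd_pa > 0:
            tr = tr + rng.normal(0, noise_sd_pa, t.size)
        traces.append(tr)
        meta.append({"stim1_s": stim_s, "holding_mv": -70.0})
    for _ in range(n_reps):
        # at +40 mV the outward current carries the slow (NMDA) component,
        # scaled so its value 50 ms after the stimulus is nmda_at_50ms_pa
        tr = (nmda_at_50ms_pa / k50) * slow
        if noise_sd_pa > 0:
            tr = tr + rng.normal(0, noise_sd_pa, t.size)
        traces.append(tr)
        meta.append({"stim1_s": stim_s, "holding_mv": 40.0})
    return SweepSet(
        sample_rate_hz=fs,
        traces=np.column_stack(traces),
        meta=pd.DataFrame(meta),
        ground_truth={"ampa_pa": ampa_pa, "nmda_at_50ms_pa": nmda_at_50ms_pa,
                      "ratio": ampa_pa / nmda_at_50ms_pa},
    )


def _gen_mepsc(cfg: SynthConfig, rng, rate_hz: float = 2.0, duration_s: float = 300.0,
               amplitude_mean_pa: float = 30.0, amplitude_sd_log: float = 0.2,
               noise_sd_pa: float = 2.0, min_separation_s: float = 0.010,
               n_events: int | None = None) -> SweepSet:
    fs = cfg.sample_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if n_events is None:
        n_events = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.02, duration_s - 0.05, size=n_events))
    if times.size > 1:  # thin overlapping events so each is resolvable
        keep = np.concatenate([[True], np.diff(times) >= min_separation_s])
        times = times[keep]
    amps = amplitude_mean_pa * np.exp(
        rng.normal(-amplitude_sd_log**2 / 2, amplitude_sd_log, size=times.size)
    )
    trace = np.zeros(n)
    kernel_t = np.arange(int(0.04 * fs)) / fs
    kernel = _double_exp_kernel(kernel_t, 0.001, 0.008)
    for time, amp in zip(times, amps):
        i0 = int(round(time * fs))
        i1 = min(i0 + kernel.size, n)
        trace[i0:i1] -= amp * kernel[: i1 - i0]
    if noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, noise_sd_pa, size=n)
    return SweepSet(
        sample_rate_hz=fs,
        traces=trace[:, None],
        meta=pd.DataFrame([{"holding_mv": -70.0, "duration_s": duration_s}]),
        ground_truth={"event_times_s": times, "amplitudes_pa": amps,
                      "rate_hz": rate_hz, "duration_s": duration_s},
    )


def _gen_steps(cfg: SynthConfig, rng, steps_pa: tuple = (100, 200, 300, 400, 500, 600),
               rheobase_pa: float = 350.0, v_rest_mv: float = -80.0,
               v_thresh_mv: float = -45.0, v_reset_mv: float = -60.0,
               tau_m_ms: float = 12.0, step_start_s: float = 0.1,
               step_dur_s: float = 0.5, noise_sd_mv: float = 0.0,
               r_input_gohm: float | None = None) -> SweepSet:
    """Leaky-integrate-and-fire voltage responses to square current steps.

    Unless ``r_input_gohm`` is given, the input resistance is derived from
    the designed rheobase so that the smallest spiking step equals
    ``rheobase_pa`` on the 100-pA grid.  Passing a fixed ``r_input_gohm``
    while lowering ``v_thresh_mv`` emulates a D1-agonist excitability shift.
    """
    fs = cfg.sample_rate_hz
    dt = 1.0 / fs
    n = int(round((step_start_s + step_dur_s + 0.1) * fs))
    r_gohm = r_input_gohm if r_input_gohm is not None \
        else (v_thresh_mv - v_rest_mv) / (rheobase_pa - 50.0)
    refr = int(round(0.002 * fs))
    traces, meta, truth_counts = [], [], []
    for amp in steps_pa:
        v = np.full(n, v_rest_mv)
        i_ext = np.zeros(n)
        i_ext[int(step_start_s * fs): int((step_start_s + step_dur_s) * fs)] = amp
        count = 0
        hold = 0
        for k in range(1, n):
            if hold > 0:
                v[k] = v_reset_mv
                hold -= 1
                continue
            dv = (-(v[k - 1] - v_rest_mv) + i_ext[k - 1] * r_gohm) / (tau_m_ms / 1000.0) * dt
            v[k] = v[k - 1] + dv
            if v[k] >= v_thresh_mv:
                v[k] = 30.0  # spike peak, caught by the 0-mV crossing detector
                count += 1
                hold = refr
        if noise_sd_mv > 0:
            v = v + rng.normal(0, noise_sd_mv, n)
        traces.append(v)
        meta.append({"step_pa": float(amp), "step_start_s": step_start_s,
                     "step_dur_s": step_dur_s, "holding_mv": np.nan})
        truth_counts.append(count)
    return SweepSet(
        sample_rate_hz=fs,
        traces=np.column_stack(traces),
        meta=pd.DataFrame(meta),
        ground_truth={"spike_counts": np.array(truth_counts),
                      "rheobase_pa": rheobase_pa},
    )


def _gen_optical(cfg: SynthConfig, rng, gain_pa_per_mw: float = 150.0,
                 saturation_mw: float = 6.0, n_reps: int = 5,
                 noise_sd_pa: float = 0.0, stim_s: float = 0.05) -> SweepSet:
    """Optically evoked PSCs: amplitude saturates with light power."""
    fs = cfg.sample_rate_hz
    t = np.arange(int(round(0.3 * fs))) / fs
    kernel = _double_exp_kernel(t - stim_s, 0.001, 0.008)
    traces, meta = [], []
    amps = {}
    for p in cfg.laser_powers_mw:
        amp = gain_pa_per_mw * saturation_mw * p / (saturation_mw + p)
        amps[p] = amp
        for _ in range(n_reps):
            tr = -amp * kernel
            if noise_sd_pa > 0:
                tr = tr + rng.normal(0, noise_sd_pa, t.size)
            traces.append(tr)
            meta.append({"stim1_s": stim_s, "power_mw": p, "holding_mv": -70.0})
    return SweepSet(
        sample_rate_hz=fs,
        traces=np.column_stack(traces),
        meta=pd.DataFrame(meta),
        ground_truth={"amplitude_by_power_pa": amps},
    )


def write_session(cfg: SynthConfig, outdir) -> None:
    """Write a full synthetic session in the documented CSV/JSON schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trains, events, labels, aim = gen_session(cfg)
    spikes = pd.concat(
        [pd.DataFrame({"unit_id": tr.unit_id, "t_s": tr.spike_times}) for tr in trains],
        ignore_index=True,
    ) if trains else pd.DataFrame(columns=["unit_id", "t_s"])
    spikes.to_csv(outdir / "spikes.csv", index=False)
    aim.to_csv(outdir / "aims.csv")
    labels.to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "events.json", "w") as fh:
        json.dump(
            {
                "injection_time_s": events.injection_time_s,
                "session_start_s": events.session_start_s,
                "session_end_s": events.session_end_s,
                "laser_onsets_s": events.laser_onsets_s.tolist(),
                "laser_powers_mw": events.laser_powers_mw.tolist(),
                "pulse_duration_s": events.pulse_duration_s,
            },
            fh,
        )
    with open(outdir / "config.json", "w") as fh:
        fh.write(cfg.to_json())
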