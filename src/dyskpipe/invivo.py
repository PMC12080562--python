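"""Classification of in vivo striatal single units.

Units recorded across a levodopa injection are classified along four axes:

* waveform class — putative medium spiny neuron (MSN) vs interneuron (IN),
  from peak-to-valley duration and peak width of the mean spike waveform;
* drug-response class — On (putative dMSN, firing-rate increase), Off
  (putative iMSN, decrease) or NC (no change), by a rank-sum test comparing
  1-min firing rates in a 30-min pre-injection baseline against the 10-40 min
  post-injection window at alpha = 0.01;
* optogenetic identification — three criteria on the laser-pulse
  peristimulus time histogram (PSTH): short-latency (<= 15 ms) excitation
  above the 99% confidence bound of baseline firing, sustained for at least
  15 ms, with laser-evoked waveforms statistically indistinguishable from
  spontaneous ones;
* dyskinesia correlation — among On or tagged units, those whose 1-min
  firing rate regresses onto the 1-min AIM total with R^2 > 0.30 are DYSK
  units, the rest are on-unclassified (ON).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpikeTrain",
    "SessionEvents",
    "Psth",
    "OptotagResult",
    "UnitClass",
    "WaveformThresholds",
    "bin_firing",
    "classify_drug_response",
    "classify_waveform",
    "compute_psth",
    "optotag",
    "waveform_similarity_test",
    "dyskinesia_correlation",
    "classify_population",
]

MIN_ISI_S = 0.001  # units with any ISI < 1 ms are invalid


@dataclass
class SpikeTrain:
    """One sorted unit: spike times plus waveform samples and features.

    Waveform sample vectors are in microvolts at 40 kHz (25 us sample
    period).  ``peak_to_valley_us`` and ``peak_width_us`` are features of the
    mean spontaneous waveform.
    """

    unit_id: str
    spike_times: np.ndarray  # seconds, sorted
    spont_waveforms: np.ndarray | None = None  # (n_waveforms, n_samples)
    evoked_waveforms: np.ndarray | None = None
    peak_to_valley_us: float = np.nan
    peak_width_us: float = np.nan

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1:
            if not np.all(np.diff(self.spike_times) >= 0):
                raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
            if np.min(np.diff(self.spike_times)) < MIN_ISI_S:
                raise ValueError(
                    f"unit {self.unit_id}: interspike interval < 1 ms; unit invalid"
                )
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class SessionEvents:
    """Session timeline: injection time, laser pulse train, recording span."""

    injection_time_s: float
    session_start_s: float
    session_end_s: float
    laser_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    laser_powers_mw: np.ndarray = field(default_factory=lambda: np.empty(0))
    pulse_duration_s: float = 0.1

    def __post_init__(self) -> None:
        self.laser_onsets_s = np.asarray(self.laser_onsets_s, dtype=float)
        self.laser_powers_mw = np.asarray(self.laser_powers_mw, dtype=float)
        if self.session_end_s <= self.session_start_s:
            raise ValueError("session span must have positive duration")
        if self.laser_onsets_s.size and (
            self.laser_onsets_s.min() < self.session_start_s
            or self.laser_onsets_s.max() > self.session_end_s
        ):
            raise ValueError("laser pulses must lie within the session span")


@dataclass
class Psth:
    """Event-aligned histogram: per-bin mean firing rate across events."""

    bin_edges_ms: np.ndarray
    rate_hz: np.ndarray
    n_events: int

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def bin_left_ms(self) -> np.ndarray:
        return self.bin_edges_ms[:-1]


@dataclass
class OptotagResult:
    """Outcome of the three-criterion optogenetic identification test."""

    crit1_latency_ok: bool
    crit2_duration_ok: bool
    crit3_waveform_ok: bool
    onset_latency_ms: float  # NaN if no threshold crossing
    threshold_hz: float

    @property
    def identified(self) -> bool:
        return self.crit1_latency_ok and self.crit2_duration_ok and self.crit3_waveform_ok


@dataclass
class UnitClass:
    """Full classification of one unit."""

    unit_id: str
    waveform_class: str  # 'MSN' | 'IN'
    drug_class: str  # 'On' | 'Off' | 'NC'
    tagged: bool
    dysk_class: str  # 'DYSK' | 'ON' | 'n/a'
    r_squared: float
    slope: float


def bin_firing(
    train: SpikeTrain,
    bin_s: float = 60.0,
    t_start: float = 0.0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Firing rate (Hz) in fixed bins; the partial last bin is normalized
    by its true width.

    Returns a frame with ``bin_start_s`` and ``rate_hz``.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if t_end is None:
        t_end = float(train.spike_times[-1]) if train.n_spikes else t_start + bin_s
    edges = np.arange(t_start, t_end, bin_s)
    edges = np.append(edges, t_end)
    if len(edges) < 2:
        edges = np.array([t_start, t_end])
    counts, _ = np.histogram(train.spike_times, bins=edges)
    widths = np.diff(edges)
    return pd.DataFrame({"bin_start_s": edges[:-1], "rate_hz": counts / widths})


def classify_drug_response(
    rates: pd.DataFrame,
    injection_time_s: float,
    baseline_min: tuple[float, float] = (-30.0, 0.0),
    post_min: tuple[float, float] = (10.0, 40.0),
    alpha: float = 0.01,
) -> tuple[str, float]:
    """On/Off/NC drug-response class from 1-min binned rates.

    The baseline window (default the 30 min before injection) is compared to
    the post-injection window (default 10-40 min after) with a two-sided
    Wilcoxon rank-sum (Mann-Whitney) test.  p < alpha with a median rate
    increase gives 'On', a decrease gives 'Off', otherwise 'NC'.

    Returns ``(drug_class, p_value)``.
    """
    t_rel_min = (rates["bin_start_s"].to_numpy() - injection_time_s) / 60.0
    base = rates["rate_hz"].to_numpy()[
        (t_rel_min >= baseline_min[0]) & (t_rel_min < baseline_min[1])
    ]
    post = rates["rate_hz"].to_numpy()[
        (t_rel_min >= post_min[0]) & (t_rel_min < post_min[1])
    ]
    for name, window, got in (("baseline", baseline_min, base), ("post", post_min, post)):
        expected = int(round(window[1] - window[0]))
        if got.size < expected:
            raise ValueError(
                f"{name} window {window} min not fully covered by bins "
                f"({got.size} of {expected} expected)"
            )
    if np.all(base == base[0]) and np.all(post == post[0]) and base[0] == post[0]:
        return "NC", 1.0
    # exact Mann-Whitney below 20 per group (no ties), normal approximation
    # with tie correction above
    # exact null distribution below 20 per group; above, the normal
    # approximation with tie correction and no continuity correction keeps
    # the achieved level close to nominal alpha
    method = "exact" if (base.size <= 20 and post.size <= 20) else "asymptotic"
    try:
        res = stats.mannwhitneyu(post, base, alternative="two-sided", method=method,
                                 use_continuity=False)
    except ValueError:
        res = stats.mannwhitneyu(post, base, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    p = float(res.pvalue)
    if p < alpha:
        diff = np.median(post) - np.median(base)
        if diff > 0:
            return "On", p
        if diff < 0:
            return "Off", p
    return "NC", p


@dataclass
class WaveformThresholds:
    """Boundaries separating interneurons from MSNs; both must be under
    threshold (strict) to call IN."""

    peak_width_us: float = 150.0
    peak_to_valley_us: float = 500.0


def classify_waveform(
    peak_to_valley_us: float,
    peak_width_us: float,
    thresholds: WaveformThresholds | None = None,
) -> str:
    """'IN' if both waveform features fall strictly below their thresholds,
    else 'MSN'.  Boundary equality classifies as MSN."""
    thr = thresholds or WaveformThresholds()
    if not (np.isfinite(peak_to_valley_us) and np.isfinite(peak_width_us)):
        raise ValueError("waveform features must be finite")
    if peak_width_us < thr.peak_width_us and peak_to_valley_us < thr.peak_to_valley_us:
        return "IN"
    return "MSN"


def compute_psth(
    train: SpikeTrain,
    event_times_s: np.ndarray,
    window_ms: tuple[float, float] = (-1000.0, 200.0),
    bin_ms: float = 1.0,
) -> Psth:
    """PSTH around event onsets: mean rate (Hz) per bin across events."""
    event_times_s = np.asarray(event_times_s, dtype=float)
    if event_times_s.size == 0:
        raise ValueError("need at least one event")
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    spikes = train.spike_times
    lo = np.searchsorted(spikes, event_times_s + window_ms[0] / 1000.0)
    hi = np.searchsorted(spikes, event_times_s + window_ms[1] / 1000.0)
    rel_ms = [
        (spikes[i0:i1] - ev) * 1000.0 for ev, i0, i1 in zip(event_times_s, lo, hi) if i1 > i0
    ]
    pooled = np.concatenate(rel_ms) if rel_ms else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    rate = counts / (event_times_s.size * bin_ms / 1000.0)
    return Psth(bin_edges_ms=edges, rate_hz=rate, n_events=int(event_times_s.size))


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(w - 1 - pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")


def optotag(
    train: SpikeTrain,
    events: SessionEvents,
    waveform_alpha: float = 0.01,
    max_latency_ms: float = 15.0,
    min_duration_ms: float = 15.0,
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0),
    ci_quantile: float = 0.995,
    smooth_ms: float = 3.0,
    rng: np.random.Generator | None = None,
) -> OptotagResult:
    """Three-criterion optogenetic identification from the laser PSTH.

    Criterion 1: the (3-ms boxcar smoothed) PSTH first exceeds the upper 99%
    confidence bound of baseline firing at a latency <= 15 ms after laser
    onset.  The bound is the 99.5th percentile of a Poisson fit to pooled
    1-ms baseline bin counts over the 500 ms before onset.  Criterion 2: the
    rate stays above that bound for at least 15 consecutive ms from the
    first crossing.  Criterion 3: laser-evoked waveforms are statistically
    indistinguishable from spontaneous ones (see
    :func:`waveform_similarity_test`).
    """
    onsets = events.laser_onsets_s
    if onsets.size == 0:
        raise ValueError("no laser pulses in session events")
    if onsets.size < 100:
        warnings.warn(
            f"only {onsets.size} laser pulses; >= 100 recommended for a stable PSTH",
            stacklevel=2,
        )
    psth = compute_psth(train, onsets, window_ms=(baseline_window_ms[0], 200.0), bin_ms=1.0)
    left = psth.bin_left_ms
    base_mask = (left >= baseline_window_ms[0]) & (left < baseline_window_ms[1])
    # pooled counts per 1-ms bin across pulses; Poisson upper bound
    base_counts = psth.rate_hz[base_mask] * psth.n_events * 0.001
    lam = float(base_counts.mean()) if base_counts.size else 0.0
    thresh_count = stats.poisson.ppf(ci_quantile, lam) if lam > 0 else 0.0
    threshold_hz = thresh_count / (psth.n_events * 0.001)

    w = max(1, int(round(smooth_ms / psth.bin_width_ms)))
    smoothed = _boxcar(psth.rate_hz, w)
    post_mask = left >= 0
    post_left = left[post_mask]
    above = smoothed[post_mask] > threshold_hz

    crossings = np.nonzero(above)[0]
    if crossings.size == 0:
        latency = np.nan
        crit1 = crit2 = False
    else:
        first = crossings[0]
        latency = float(post_left[first])
        crit1 = latency <= max_latency_ms
        run = 0
        for a in above[first:]:
            if a:
                run += 1
            else:
                break
        crit2 = run * psth.bin_width_ms >= min_duration_ms

    if train.spont_waveforms is not None and train.evoked_waveforms is not None:
        crit3, _ = waveform_similarity_test(
            train.spont_waveforms, train.evoked_waveforms, alpha=waveform_alpha
        )
    else:
        crit3 = False
    return OptotagResult(
        crit1_latency_ok=bool(crit1),
        crit2_duration_ok=bool(crit2),
        crit3_waveform_ok=bool(crit3),
        onset_latency_ms=latency,
        threshold_hz=float(threshold_hz),
    )


def waveform_similarity_test(
    spont: np.ndarray,
    evoked: np.ndarray,
    alpha: float = 0.01,
    n_components: int = 2,
) -> tuple[bool, float]:
    """Test whether evoked waveforms are indistinguishable from spontaneous.

    Pooled waveforms are projected onto their first two principal axes
    (mirroring the PCA space used in spike sorting); a Welch two-sample test
    per axis with Bonferroni correction decides.  Returns ``(pass, min_p)``
    where pass is True iff no axis is significant at alpha.
    """
    spont = np.asarray(spont, dtype=float)
    evoked = np.asarray(evoked, dtype=float)
    if spont.shape[0] < 20 or evoked.shape[0] < 20:
        warnings.warn("fewer than 20 waveforms per set; similarity test is weak", stacklevel=2)
    from sklearn.decomposition import PCA

    pooled = np.vstack([spont, evoked])
    n_comp = min(n_components, pooled.shape[1], pooled.shape[0] - 1)
    scores = PCA(n_components=n_comp).fit_transform(pooled)
    n_s = spont.shape[0]
    pvals = []
    for axis in range(n_comp):
        a = scores[:n_s, axis]
        b = scores[n_s:, axis]
        pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
    min_p = min(pvals)
    significant = min_p < alpha / n_comp  # Bonferroni
    return (not significant), min_p


def dyskinesia_correlation(
    rate_hz: np.ndarray,
    aim_total: np.ndarray,
    r2_threshold: float = 0.30,
    min_pairs: int = 10,
) -> tuple[float, float, str]:
    """Regress 1-min firing rate on 1-min AIM total over scored minutes.

    Minutes where the AIM total is NaN (unscored) are dropped.  Units with
    R^2 strictly greater than 0.30 are DYSK; otherwise on-unclassified
    ('ON').  Classification uses the R^2 threshold alone, without an
    additional significance test on the regression.

    Returns ``(r_squared, slope, dysk_class)``.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    aim_total = np.asarray(aim_total, dtype=float)
    mask = np.isfinite(rate_hz) & np.isfinite(aim_total)
    if mask.sum() < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} paired scored minutes, got {int(mask.sum())}"
        )
    x = aim_total[mask]
    y = rate_hz[mask]
    if np.all(x == x[0]):
        warnings.warn("AIM variance is zero; R^2 undefined, classifying ON", stacklevel=2)
        return np.nan, np.nan, "ON"
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    dysk_class = "DYSK" if r2 > r2_threshold else "ON"
    return r2, float(fit.slope), dysk_class


def classify_population(
    trains: list[SpikeTrain],
    events: SessionEvents,
    aim_bins: pd.DataFrame | None = None,
    thresholds: WaveformThresholds | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Run the full classification cascade over a session's units.

    Cascade: waveform class, then drug-response class, then optogenetic
    identification (when laser pulses and waveforms are available), then
    dyskinesia correlation for On or tagged units (when a binned AIM trace
    is supplied; ``aim_bins`` as produced by :func:`dyskpipe.behavior.bin_aim`
    on post-injection minutes).

    Returns ``(per-unit table, class proportions)``.
    """
    rows = []
    for train in trains:
        wf_class = (
            classify_waveform(train.peak_to_valley_us, train.peak_width_us, thresholds)
            if np.isfinite(train.peak_to_valley_us)
            else "MSN"
        )
        rates = bin_firing(
            train, 60.0, t_start=events.session_start_s, t_end=events.session_end_s
        )
        drug_class, p = classify_drug_response(rates, events.injection_time_s, alpha=alpha)
        tagged = False
        if (
            events.laser_onsets_s.size
            and train.spont_waveforms is not None
            and train.evoked_waveforms is not None
        ):
            tagged = optotag(train, events).identified
        r2 = slope = np.nan
        dysk_class = "n/a"
        if aim_bins is not None and (drug_class == "On" or tagged):
            aim_t = events.injection_time_s + aim_bins["bin_start_min"].to_numpy() * 60.0
            idx = np.round((aim_t - events.session_start_s) / 60.0).astype(int)
            ok = (idx >= 0) & (idx < len(rates))
            try:
                r2, slope, dysk_class = dyskinesia_correlation(
                    rates["rate_hz"].to_numpy()[idx[ok]],
                    aim_bins["aim_total"].to_numpy()[ok],
                )
            except ValueError:
                dysk_class = "n/a"
        rows.append(
            {
                "unit_id": train.unit_id,
                "waveform_class": wf_class,
                "drug_class": drug_class,
                "drug_p": p,
                "tagged": tagged,
                "dysk_class": dysk_class,
                "r_squared": r2,
                "slope": slope,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "waveform_class",
            "drug_class",
            "drug_p",
            "tagged",
            "dysk_class",
            "r_squared",
            "slope",
        ],
    )
    if len(table):
        proportions = table["drug_class"].value_counts(normalize=True)
    else:
        proportions = pd.Series(dtype=float)
    return table, proportions
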