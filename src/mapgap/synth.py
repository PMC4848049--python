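"""Synthetic co-registered MAP / ECG / fiber-sensor recordings.

The generator emulates the measurement situation of a contact-force-sensing
MAP catheter pressed on myocardium:

* each *site* has a hidden physiology — viable tissue elicits a monophasic
  action potential (MAP) only while the instantaneous contact force (CF)
  exceeds a site-specific threshold; ablated (non-viable) tissue never
  elicits one at any force;
* thresholds of viable tissue follow a truncated normal whose mean/SD
  default to the 7.6 ± 4.4 g observed on viable ventricular epicardium;
* the ECG channel carries QRS-like complexes at the configured heart rate,
  the MAP channel carries QRS-locked MAP deflections (2-ms upstroke, flat
  plateau, exponential repolarization tail) on elicited beats and only a
  small far-field residue otherwise;
* the raw sensor channel encodes the applied CF through the inverse of a
  known linear wavelength-shift calibration, plus sensor noise;
* respiration adds sinusoidal baseline wander to the MAP and CF channels
  unless a breath hold is simulated.

Everything is deterministic under (seed, config, pattern).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .config import SimulationConfig
from .trace import QUALITY_BREATH_HOLD, Trace, TraceTruth

#: seconds of recording before the first R peak
LEAD_IN_S = 0.5
#: seconds of recording after the last beat window
TAIL_S = 0.8
#: delay from R peak to MAP upstroke onset (s)
MAP_DELAY_S = 0.020
#: MAP upstroke rise time (s)
MAP_RISE_S = 0.002
#: fraction of the MAP duration spent on the plateau before the tail starts
PLATEAU_FRACTION = 0.55


# --------------------------------------------------------------- physiology

@dataclass
class SitePhysiology:
    """Hidden truth of one anatomic site."""

    site_id: str
    viable: bool
    cf_threshold: Optional[float] = None  # grams; force above which MAPs appear
    map_amplitude: Optional[float] = None  # mV plateau amplitude when elicited
    map_duration: Optional[float] = None  # ms
    in_lesion_pattern: bool = False

    def __post_init__(self) -> None:
        if self.viable:
            if self.cf_threshold is None or self.cf_threshold <= 0:
                raise ValueError("viable site needs cf_threshold > 0")
            if self.map_amplitude is None or self.map_amplitude <= 0:
                raise ValueError("viable site needs map_amplitude > 0")
            if self.map_duration is None or self.map_duration <= 0:
                raise ValueError("viable site needs map_duration > 0")


@lru_cache(maxsize=64)
def _truncated_parent(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal truncated below at ``floor`` whose
    truncated distribution has the requested mean and SD.

    Drawing from ``Normal(mean, sd)`` and discarding the sub-floor tail
    would bias the realized moments upward/downward; solving for the parent
    keeps the configured mean/SD exactly interpretable as the moments of the
    generated thresholds.
    """

    def moments(x: np.ndarray) -> np.ndarray:
        mu, sigma = x
        a = (floor - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.fsolve(moments, x0=np.array([mean, sd]), full_output=False)
    mu, sigma = float(sol[0]), float(sol[1])
    resid = moments(np.array([mu, sigma]))
    if not np.all(np.abs(resid) < 1e-6):
        raise RuntimeError(
            f"could not match truncated-normal moments mean={mean}, sd={sd}, floor={floor}"
        )
    return mu, sigma


def draw_thresholds(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` viable-tissue CF thresholds (grams) from the configured
    truncated-normal distribution."""
    if config.threshold_sd == 0:
        return np.full(n, config.threshold_mean)
    mu, sigma = _truncated_parent(
        config.threshold_mean, config.threshold_sd, config.threshold_floor_g
    )
    a = (config.threshold_floor_g - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def draw_site_physiology(
    n_sites: int,
    fraction_viable: float,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SitePhysiology]:
    """Draw the hidden physiology of ``n_sites`` sites.

    ``fraction_viable`` of the sites (rounded) are viable, with CF
    thresholds from the configured distribution; the viable flags are
    assigned to the first sites and then shuffled under the seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0 <= fraction_viable <= 1:
        raise ValueError("fraction_viable must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_viable = round(n_sites * fraction_viable)
    viable = np.zeros(n_sites, dtype=bool)
    viable[:n_viable] = True
    rng.shuffle(viable)
    thresholds = draw_thresholds(n_sites, config, rng)
    amplitudes = rng.uniform(config.map_amplitude_low_mv, config.map_amplitude_high_mv, n_sites)
    durations = rng.uniform(config.map_duration_low_ms, config.map_duration_high_ms, n_sites)
    sites = []
    for i in range(n_sites):
        if viable[i]:
            sites.append(
                SitePhysiology(
                    site_id=f"S{i:03d}",
                    viable=True,
                    cf_threshold=float(thresholds[i]),
                    map_amplitude=float(amplitudes[i]),
                    map_duration=float(durations[i]),
                )
            )
        else:
            sites.append(SitePhysiology(site_id=f"S{i:03d}", viable=False))
    return sites


# ------------------------------------------------------- force profiles

def beat_times(n_beats: int, config: SimulationConfig) -> np.ndarray:
    """R-peak times of ``n_beats`` beats on the generator's beat grid."""
    return LEAD_IN_S + np.arange(n_beats) * config.beat_period_s


@dataclass
class BeatForceProfile:
    """Piecewise-constant commanded CF, one level per beat.

    The force switches midway between beats, so each beat's MAP upstroke
    sees a single well-defined level. Calling the profile with a time array
    evaluates it per sample.
    """

    per_beat_g: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        self.per_beat_g = np.asarray(self.per_beat_g, dtype=float)
        if np.any(self.per_beat_g < 0):
            raise ValueError("commanded contact force must be non-negative")

    @property
    def n_beats(self) -> int:
        return len(self.per_beat_g)

    @property
    def duration_s(self) -> float:
        return LEAD_IN_S + (self.n_beats - 1) * self.config.beat_period_s + TAIL_S

    def __call__(self, t: np.ndarray) -> np.ndarray:
        T = self.config.beat_period_s
        idx = np.floor((np.asarray(t) - (LEAD_IN_S - T / 2)) / T).astype(int)
        return self.per_beat_g[np.clip(idx, 0, self.n_beats - 1)]


@dataclass(frozen=True)
class MeasurementProtocol:
    """The operator's force staircase: increase CF stepwise, hold each level
    a few beats, stop shortly after a MAP appears (or after a maximum probe
    force on silent tissue)."""

    start_g: float = 0.5
    step_g: float = 0.25
    beats_per_level: int = 5
    hold_beats: int = 8  # beats held at the final (detecting or maximal) level
    max_probe_g: float = 12.0  # ceiling when no MAP ever appears


def measurement_profile(
    site: SitePhysiology,
    config: SimulationConfig,
    protocol: MeasurementProtocol = MeasurementProtocol(),
    min_max_g: Optional[float] = None,
) -> BeatForceProfile:
    """Build the staircase CF profile an operator would apply at ``site``.

    For viable tissue the staircase climbs until the first level at or above
    the site's threshold, which is then held for ``hold_beats`` beats (long
    enough for a run of consecutive MAPs). For non-viable tissue it climbs to
    ``max(max_probe_g, min_max_g)`` — pass the site's pre-ablation CF as
    ``min_max_g`` to guarantee the probe exceeds it.
    """
    p = protocol
    if site.viable:
        target = site.cf_threshold
    else:
        target = p.max_probe_g if min_max_g is None else max(p.max_probe_g, min_max_g)
    n_levels = max(1, math.ceil((target - p.start_g) / p.step_g - 1e-12) + 1)
    levels = p.start_g + p.step_g * np.arange(n_levels)
    reps = np.full(n_levels, p.beats_per_level)
    reps[-1] = p.hold_beats
    return BeatForceProfile(np.repeat(levels, reps), config)


def operator_measurement(
    site: SitePhysiology,
    config: SimulationConfig,
    protocol: MeasurementProtocol = MeasurementProtocol(),
    rng: Optional[np.random.Generator] = None,
    min_max_g: Optional[float] = None,
) -> tuple[BeatForceProfile, float]:
    """Closed-loop operator: raise the force one step whenever a full level
    has passed without MAPs, hold while MAPs are appearing, stop once 4
    consecutive beats have elicited one (or, on silent tissue, after holding
    the maximum probe force).

    Because elicitation depends on the instantaneous force including the
    respiratory wobble, the respiration phase is drawn here and must be
    passed on to :func:`generate_trace` — the returned tuple is
    ``(profile, resp_phase)``.
    """
    p = protocol
    if rng is None:
        rng = np.random.default_rng(config.seed)
    resp_phase = float(rng.uniform(0, 2 * math.pi))
    ceiling = p.max_probe_g if min_max_g is None else max(p.max_probe_g, min_max_g)

    def wobble(i_beat: int) -> float:
        if config.breath_hold:
            return 0.0
        u = LEAD_IN_S + i_beat * config.beat_period_s + MAP_DELAY_S
        return config.respiration_force_amplitude_g * math.sin(
            2 * math.pi * u / config.respiration_period_s + resp_phase
        )

    levels: list[float] = []
    level = p.start_g
    consec = 0
    beats_at_level = 0
    while True:
        applied = max(0.0, level + wobble(len(levels)))
        elicited = site.viable and applied >= (site.cf_threshold or math.inf)
        levels.append(level)
        beats_at_level += 1
        consec = consec + 1 if elicited else 0
        if consec >= 4:
            break
        if beats_at_level >= p.beats_per_level and consec == 0:
            if not site.viable and level >= ceiling:
                if beats_at_level >= p.hold_beats:
                    break  # silent tissue held at the probe ceiling
            else:
                level += p.step_g
                beats_at_level = 0
        if len(levels) > 5000:  # pragma: no cover - guards a mis-set protocol
            raise RuntimeError("measurement protocol did not terminate")
    while len(levels) < 5:
        levels.append(level)
    return BeatForceProfile(np.array(levels), config), resp_phase


def constant_profile(force_g: float, n_beats: int, config: SimulationConfig) -> BeatForceProfile:
    return BeatForceProfile(np.full(n_beats, force_g), config)


def ramp_profile(start_g: float, stop_g: float, n_beats: int, config: SimulationConfig) -> BeatForceProfile:
    """Linear per-beat ramp from ``start_g`` at beat 0 to ``stop_g`` at the
    last beat."""
    return BeatForceProfile(np.linspace(start_g, stop_g, n_beats), config)


# ---------------------------------------------------------- trace synthesis

def _add_gaussian(sig: np.ndarray, fs: float, center_s: float, sigma_s: float, amp: float) -> None:
    half = int(4 * sigma_s * fs) + 1
    c = int(round(center_s * fs))
    lo, hi = max(0, c - half), min(len(sig), c + half)
    if lo >= hi:
        return
    k = np.arange(lo, hi)
    sig[lo:hi] += amp * np.exp(-0.5 * ((k / fs - center_s) / sigma_s) ** 2)


def _map_template(fs: float, amplitude: float, duration_ms: float) -> np.ndarray:
    """Piecewise MAP waveform from upstroke onset: linear 2-ms rise, flat
    plateau, then an exponential tail that crosses 90% repolarization
    (10% of the plateau) exactly one MAP duration after the upstroke."""
    d = duration_ms / 1000.0
    t_p = PLATEAU_FRACTION * d
    tau = (1 - PLATEAU_FRACTION) * d / math.log(10.0)
    total = MAP_RISE_S + t_p + 7.0 * tau  # tail decayed below 1e-3 of amplitude
    rel = np.arange(int(total * fs)) / fs
    v = np.where(
        rel < MAP_RISE_S,
        amplitude * rel / MAP_RISE_S,
        np.where(rel <= MAP_RISE_S + t_p, amplitude,
                 amplitude * np.exp(-(rel - MAP_RISE_S - t_p) / tau)),
    )
    return v


def generate_trace(
    site: SitePhysiology,
    cf_profile: BeatForceProfile | Callable[[np.ndarray], np.ndarray],
    config: SimulationConfig,
    duration_s: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    resp_phase: Optional[float] = None,
) -> Trace:
    """Synthesize one catheter application at ``site`` under a CF profile.

    ``cf_profile`` is either a :class:`BeatForceProfile` (duration implied)
    or any callable time→grams, in which case ``duration_s`` is required.
    ``resp_phase`` fixes the respiration phase (radians); profiles built by
    :func:`operator_measurement` must be paired with the phase it returns.
    The returned :class:`Trace` carries generator ground truth in
    ``trace.truth``; the detector never reads it.
    """
    fs = config.sample_rate_hz
    T = config.beat_period_s
    if isinstance(cf_profile, BeatForceProfile):
        duration_s = cf_profile.duration_s
    elif duration_s is None:
        raise ValueError("duration_s required for a callable cf_profile")
    n_beats = int(math.floor((duration_s - LEAD_IN_S - 0.3) / T)) + 1
    if n_beats < 5:
        raise ValueError("trace must span at least 5 beats")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    commanded = np.asarray(cf_profile(t), dtype=float)
    if commanded.shape != t.shape:
        raise ValueError("cf_profile must return one force per sample")
    if np.any(commanded < 0):
        raise ValueError("cf_profile returned negative force")

    if resp_phase is None:
        resp_phase = rng.uniform(0, 2 * math.pi)
    if config.breath_hold:
        resp_force = 0.0
        resp_mv = 0.0
    else:
        resp = np.sin(2 * math.pi * t / config.respiration_period_s + resp_phase)
        resp_force = config.respiration_force_amplitude_g * resp
        resp_mv = config.respiration_amplitude * resp
    applied = np.clip(commanded + resp_force, 0.0, None)

    r_times = beat_times(n_beats, config)
    upstroke_idx = np.round((r_times + MAP_DELAY_S) * fs).astype(int)
    cf_at_beat = applied[np.clip(upstroke_idx, 0, n - 1)]
    elicited = site.viable & (cf_at_beat >= (site.cf_threshold or np.inf))

    ecg = np.zeros(n)
    map_sig = np.zeros(n)
    for i, r in enumerate(r_times):
        _add_gaussian(ecg, fs, r - 0.025, 0.006, -0.15)  # Q
        _add_gaussian(ecg, fs, r, 0.008, 1.0)  # R
        _add_gaussian(ecg, fs, r + 0.025, 0.006, -0.20)  # S
        _add_gaussian(ecg, fs, r + 0.25, 0.040, 0.25)  # T
        # far-field residue on every beat, well below the 2-mV criterion
        _add_gaussian(map_sig, fs, r + 0.030, 0.010, config.farfield_amplitude_mv)
        if elicited[i]:
            tmpl = _map_template(fs, site.map_amplitude, site.map_duration)
            u = upstroke_idx[i]
            hi = min(n, u + len(tmpl))
            if u < n:
                map_sig[u:hi] += tmpl[: hi - u]

    map_sig = map_sig + resp_mv + rng.normal(0.0, config.noise_sd, n)
    ecg = ecg + rng.normal(0.0, config.noise_sd, n)
    sensor = (applied - config.sensor_intercept_g) / config.sensor_slope_g_per_nm
    sensor = sensor + rng.normal(0.0, config.sensor_noise_nm, n)

    quality = np.zeros(n, dtype=np.uint8)
    if config.breath_hold:
        quality |= QUALITY_BREATH_HOLD

    truth = TraceTruth(
        site_id=site.site_id,
        viable=site.viable,
        cf_threshold=site.cf_threshold,
        qrs_times=r_times,
        beat_elicited=elicited,
        cf_at_beat=cf_at_beat,
        map_amplitude=site.map_amplitude,
        map_duration_ms=site.map_duration,
    )
    return Trace(
        sample_rate=fs,
        time=t,
        map_mv=map_sig,
        ecg_mv=ecg,
        sensor_nm=sensor,
        fiber_id="sim-fiber",
        quality=quality,
        truth=truth,
    )


def simulated_bench_points(
    config: SimulationConfig,
    forces_g: Sequence[float] = tuple(np.arange(0.0, 25.1, 2.5)),
    noise_nm: float = 0.01,
    rng: Optional[np.random.Generator] = None,
):
    """Bench (force, shift) pairs for the simulated fiber, for calibration."""
    from .calibration import CalibrationPoint

    if rng is None:
        rng = np.random.default_rng(config.seed)
    pts = []
    for f in forces_g:
        shift = (f - config.sensor_intercept_g) / config.sensor_slope_g_per_nm
        pts.append(CalibrationPoint(float(f), float(shift + rng.normal(0, noise_nm))))
    return pts


# --------------------------------------------------------------- surveys

@dataclass(frozen=True)
class PatternSite:
    """One grid site of a lesion layout: whether it lies on the intended
    lesion line and whether it was actually ablated. A planted conduction
    gap is an in-pattern site that was left viable."""

    site_id: str
    in_pattern: bool
    ablated: bool

    def __post_init__(self) -> None:
        if self.ablated and not self.in_pattern:
            raise ValueError("ablated sites must lie inside the lesion pattern")

    @property
    def is_gap(self) -> bool:
        return self.in_pattern and not self.ablated


@dataclass
class LesionPattern:
    """A lesion layout with optionally planted conduction gaps."""

    sites: list[PatternSite]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("pattern must contain at least one site")

    @property
    def gap_ids(self) -> list[str]:
        return [s.site_id for s in self.sites if s.is_gap]

    @classmethod
    def grid(
        cls,
        rows: int,
        cols: int,
        pattern_sites: Sequence[str],
        gap_sites: Sequence[str] = (),
    ) -> "LesionPattern":
        """Rectangular grid with row letters and column numbers (A1, A2, …).
        ``pattern_sites`` lie on the lesion line; ``gap_sites`` (a subset)
        are left unablated."""
        ids = [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]
        unknown = set(pattern_sites) - set(ids)
        if unknown:
            raise ValueError(f"pattern sites not on grid: {sorted(unknown)}")
        if not set(gap_sites) <= set(pattern_sites):
            raise ValueError("gap sites must be a subset of pattern sites")
        return cls(
            [
                PatternSite(
                    site_id=i,
                    in_pattern=i in set(pattern_sites),
                    ablated=i in set(pattern_sites) and i not in set(gap_sites),
                )
                for i in ids
            ]
        )


@dataclass
class SiteRecording:
    """Raw inputs for one surveyed site: paired pre-/post-ablation traces."""

    site_id: str
    in_pattern: bool
    physiology_pre: SitePhysiology
    physiology_post: SitePhysiology
    pre: Trace
    post: Trace


@dataclass
class SurveyRecording:
    """A full simulated survey plus the bench data of its fiber."""

    sites: list[SiteRecording]
    config: SimulationConfig
    pattern: LesionPattern
    bench_points: list = field(default_factory=list)


def generate_survey(
    pattern: LesionPattern,
    config: SimulationConfig,
    protocol: MeasurementProtocol = MeasurementProtocol(),
) -> SurveyRecording:
    """Simulate a whole site survey over a lesion layout.

    Every site is viable pre-ablation (thresholds drawn from the configured
    distribution); post-ablation, ablated sites become non-viable while gaps
    and out-of-pattern sites keep their physiology. Each phase gets one
    staircase recording; on silent post-ablation tissue the staircase is
    pushed beyond the site's own pre-ablation threshold so the probe force
    demonstrably exceeds the site-matched reference.
    """
    if not pattern.sites:
        raise ValueError("pattern must contain at least one site")
    ss = np.random.SeedSequence(config.seed)
    rng_phys = np.random.default_rng(ss.spawn(1)[0])
    n = len(pattern.sites)
    thresholds = draw_thresholds(n, config, rng_phys)
    amps = rng_phys.uniform(config.map_amplitude_low_mv, config.map_amplitude_high_mv, n)
    durs = rng_phys.uniform(config.map_duration_low_ms, config.map_duration_high_ms, n)
    trace_seeds = ss.spawn(2 * n)

    recordings = []
    for i, ps in enumerate(pattern.sites):
        pre_phys = SitePhysiology(
            site_id=ps.site_id,
            viable=True,
            cf_threshold=float(thresholds[i]),
            map_amplitude=float(amps[i]),
            map_duration=float(durs[i]),
            in_lesion_pattern=ps.in_pattern,
        )
        if ps.ablated:
            post_phys = SitePhysiology(
                site_id=ps.site_id, viable=False, in_lesion_pattern=ps.in_pattern
            )
        else:
            post_phys = pre_phys
        rng_pre = np.random.default_rng(trace_seeds[2 * i])
        profile_pre, phase_pre = operator_measurement(pre_phys, config, protocol, rng=rng_pre)
        pre_trace = generate_trace(
            pre_phys, profile_pre, config, rng=rng_pre, resp_phase=phase_pre
        )
        rng_post = np.random.default_rng(trace_seeds[2 * i + 1])
        profile_post, phase_post = operator_measurement(
            post_phys, config, protocol, rng=rng_post,
            min_max_g=float(thresholds[i]) + 2.0,
        )
        post_trace = generate_trace(
            post_phys, profile_post, config, rng=rng_post, resp_phase=phase_post
        )
        recordings.append(
            SiteRecording(
                site_id=ps.site_id,
                in_pattern=ps.in_pattern,
                physiology_pre=pre_phys,
                physiology_post=post_phys,
                pre=pre_trace,
                post=post_trace,
            )
        )
    bench = simulated_bench_points(config, rng=np.random.default_rng(ss.spawn(1)[0]))
    return SurveyRecording(sites=recordings, config=config, pattern=pattern, bench_points=bench)
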