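"""Synthetic cohort generator for the rapid-atrial-pacing HRV protocol.

Each simulated patient undergoes two standardized pacing protocols: resting
sinus rhythm, a 30-s burst of atrial pacing at 100 bpm, and post-pacing
recovery, with the second protocol starting 2 minutes after the first.  The
generator emulates the statistical structure the downstream analysis assumes:

* sinus PP intervals fluctuate around a per-patient baseline cycle length
  with independent zero-mean Gaussian deviations calibrated so the standard
  deviation of successive PP differences equals ``sd_succ_diff`` (hence the
  4-beat RMSSD is, in expectation, that SD up to small-sample factors);
* immediately after pacing the successive-difference SD is multiplied by a
  vagal-surge factor ``k`` and the target cycle length is prolonged
  additively; both effects hold for a short plateau (covering the 4-beat
  post-pacing measurement window) and then decay exponentially with a shared
  time constant ``tau``, so that measurements 2 minutes later are back at
  baseline;
* the first spontaneous sinus beat after pacing is delayed: the sinus node
  recovery time equals the baseline cycle length plus ``snrt_excess``;
* optional respiratory sinus arrhythmia (a sinusoidal cycle-length
  modulation), ectopic beats, annotation artifacts and pacing capture
  failures provide configurable contamination.

Per-patient ground truth (realized baseline cycle length, surge multiplier,
true SNRT, AV Wenckebach threshold) is returned alongside the beat series for
recovery tests; the analysis pipeline never consumes it.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .io import BeatEvent, BeatSeries

# quartiles of the standard normal sit at +/- this many SDs
_QNORM_75 = 0.6744897501960817


@dataclass
class SimParams:
    """All generator parameters for one simulated cohort.

    Durations are in seconds, times/cycle lengths in milliseconds, rates in
    events per minute unless stated otherwise.  ``surge_multiplier_k = 1``
    defines the null model: no pacing effect beyond the SNRT pause.
    """

    n_patients: int = 50
    #: cohort median / IQR of the baseline sinus cycle length (ms); patients
    #: draw their CL from a lognormal matched to these quantiles
    baseline_cl_median: float = 815.0
    baseline_cl_iqr: tuple[float, float] = (759.0, 957.0)
    #: baseline SD of successive PP differences (ms); the 4-beat RMSSD is an
    #: estimator of this quantity
    sd_succ_diff: float = 19.0
    #: lognormal sigma of between-patient spread of sd_succ_diff
    sd_succ_diff_dispersion: float = 0.35
    #: vagal surge: post-pacing multiplier on sd_succ_diff (1 = null)
    surge_multiplier_k: float = 2.7
    #: lognormal sigma of the between-patient spread of (k - 1)
    surge_multiplier_dispersion: float = 0.25
    #: additive cycle-length prolongation at surge onset (ms)
    surge_cl_prolongation: float = 40.0
    #: exponential decay constant of the surge (s)
    surge_decay_tau: float = 25.0
    #: surge holds at full amplitude for this long before decaying (s);
    #: covers the 4-beat post-pacing window measured at the surge peak
    surge_plateau: float = 4.0
    #: sinus-node recovery pause beyond baseline CL after pacing stops (ms)
    snrt_excess: float = 330.0
    #: lognormal sigma of between-patient spread of snrt_excess
    snrt_excess_dispersion: float = 0.26
    #: lognormal sigma of protocol-to-protocol jitter of snrt_excess
    snrt_protocol_jitter: float = 0.08
    pacing_rate: float = 100.0  # bpm; paced CL = 60000 / pacing_rate ms
    pacing_duration: float = 30.0  # s
    inter_protocol_gap: float = 120.0  # s between pacing end and next pacing
    rest_duration: float = 60.0  # s of sinus rhythm before the first pacing
    tail_duration: float = 60.0  # s of sinus rhythm after the last recovery
    rsa_amplitude: float = 5.0  # ms, respiratory sinus arrhythmia
    rsa_frequency: float = 0.25  # Hz (~15 breaths/min)
    ectopy_rate: float = 0.0  # ectopic beats per minute
    artifact_rate: float = 0.0  # artifact annotations per minute
    capture_failure_prob: float = 0.0  # per pacing stimulus
    #: AV Wenckebach threshold: mean/SD of the shortest paced CL (ms) still
    #: conducted 1:1, and SD of its protocol-to-protocol jitter
    wp_threshold_mean: float = 370.0
    wp_threshold_sd: float = 30.0
    wp_protocol_jitter: float = 10.0
    #: extra pacing epochs appended after the protocol for the repeat rule
    #: (the protocol re-measures contaminated windows >= 2 min later)
    n_spare_epochs: int = 1
    seed: int = 0

    def validate(self) -> "SimParams":
        nonneg = [
            "baseline_cl_median", "sd_succ_diff", "sd_succ_diff_dispersion",
            "surge_multiplier_k", "surge_multiplier_dispersion",
            "surge_cl_prolongation", "surge_decay_tau", "surge_plateau",
            "snrt_excess", "snrt_excess_dispersion", "snrt_protocol_jitter",
            "pacing_duration", "inter_protocol_gap", "rest_duration",
            "tail_duration", "rsa_amplitude", "rsa_frequency", "ectopy_rate",
            "artifact_rate", "wp_threshold_mean", "wp_threshold_sd",
            "wp_protocol_jitter",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be >= 0")
        if self.n_patients < 0 or self.n_spare_epochs < 0:
            raise ValueError("counts must be >= 0")
        if self.pacing_rate <= 0:
            raise ValueError("pacing_rate must be > 0")
        if not (0.0 <= self.capture_failure_prob <= 1.0):
            raise ValueError("capture_failure_prob must be a probability")
        lo, hi = self.baseline_cl_iqr
        if not (0 < lo <= self.baseline_cl_median <= hi):
            raise ValueError("baseline_cl_iqr must bracket baseline_cl_median")
        return self

    @property
    def paced_cl(self) -> float:
        """Paced cycle length in ms."""
        return 60000.0 / self.pacing_rate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_cl_iqr"] = list(self.baseline_cl_iqr)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "baseline_cl_iqr" in d:
            d["baseline_cl_iqr"] = tuple(d["baseline_cl_iqr"])
        return cls(**d).validate()


@dataclass
class GroundTruth:
    """Per-patient realized parameters; consumed only by recovery tests."""

    patient_id: str
    baseline_cl: float  # ms, realized target cycle length
    sd_succ_diff: float  # ms, realized successive-difference SD
    surge_multiplier: float  # realized k
    snrt: tuple[float, float]  # ms, true SNRT per protocol
    wp_threshold: tuple[float, float]  # ms, true AV block threshold per protocol
    wp_cycle_length: tuple[float, float]  # ms, WP on the 10-bpm ramp grid


@dataclass
class _Surge:
    """One post-pacing surge: onset time (ms) and realized amplitudes."""

    onset: float
    k: float
    prolongation: float


def _lognorm_sigma_from_iqr(median: float, iqr: tuple[float, float]) -> float:
    # lognormal quartiles sit at median * exp(+/- 0.6745 sigma)
    lo, hi = iqr
    return math.log(hi / lo) / (2 * _QNORM_75)


def patient_rng(master_seed: int, patient_index: int) -> np.random.Generator:
    """Independent, cohort-size-independent substream for one patient."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(patient_index,))
    )


def _surge_factor(t_ms: float, surges: list[_Surge], params: SimParams) -> tuple[float, float]:
    """(noise multiplier, CL prolongation) at time ``t_ms`` given past surges."""
    mult_excess = 0.0
    prolong = 0.0
    for s in surges:
        dt = (t_ms - s.onset) / 1000.0
        if dt < 0:
            continue
        f = 1.0 if dt <= params.surge_plateau else math.exp(
            -(dt - params.surge_plateau) / params.surge_decay_tau
        )
        mult_excess += (s.k - 1.0) * f
        prolong += s.prolongation * f
    return 1.0 + mult_excess, prolong


def _av_ramp(threshold: float, rates=range(100, 210, 10)) -> dict[int, str]:
    """AV conduction ramp under a fixed-threshold Wenckebach rule.

    Rates whose paced CL is at or above ``threshold`` conduct 1:1; faster
    rates show Wenckebach-type group beating, encoded as ``n:n-1``.
    """
    trace: dict[int, str] = {}
    for rate in rates:
        cl = 60000.0 / rate
        if cl >= threshold:
            trace[int(rate)] = "1:1"
        else:
            n = max(2, round(threshold / max(threshold - cl, 1e-9)))
            n = min(n, 8)
            trace[int(rate)] = f"{n}:{n - 1}"
    return trace


def format_av_ramp(trace: dict[int, str]) -> str:
    return ";".join(f"{rate}={ratio}" for rate, ratio in sorted(trace.items()))


def parse_av_ramp(text: str) -> dict[int, str]:
    trace: dict[int, str] = {}
    for part in text.split(";"):
        if not part:
            continue
        rate, _, ratio = part.partition("=")
        trace[int(rate)] = ratio
    return trace


def simulate_patient(
    params: SimParams, patient_index: int
) -> tuple[BeatSeries, GroundTruth]:
    """Simulate one patient's beat series across the full pacing protocol.

    The series covers rest -> pacing 1 -> recovery -> >=120 s gap ->
    pacing 2 -> recovery (plus any spare epochs for the repeat rule), and is
    deterministic for a fixed ``(params.seed, patient_index)`` pair.
    """
    params.validate()
    if params.n_patients and patient_index >= params.n_patients:
        raise ValueError(
            f"patient_index {patient_index} out of range for n_patients={params.n_patients}"
        )
    rng = patient_rng(params.seed, patient_index)
    patient_id = f"patient_{patient_index:03d}"

    # --- realized per-patient parameters -------------------------------
    sigma_cl = _lognorm_sigma_from_iqr(params.baseline_cl_median, params.baseline_cl_iqr)
    baseline_cl = float(
        round(params.baseline_cl_median * math.exp(rng.normal(0.0, sigma_cl)))
    )
    sd_i = params.sd_succ_diff * math.exp(
        rng.normal(0.0, params.sd_succ_diff_dispersion)
    ) if params.sd_succ_diff > 0 else 0.0
    if params.surge_multiplier_k > 1.0:
        k_i = 1.0 + (params.surge_multiplier_k - 1.0) * math.exp(
            rng.normal(0.0, params.surge_multiplier_dispersion)
        )
    else:
        k_i = params.surge_multiplier_k  # k = 1 stays exactly the null
    excess_i = params.snrt_excess * math.exp(
        rng.normal(0.0, params.snrt_excess_dispersion)
    ) if params.snrt_excess > 0 else 0.0

    n_epochs = 2 + params.n_spare_epochs
    excess_per_epoch = [
        excess_i * math.exp(rng.normal(0.0, params.snrt_protocol_jitter))
        if excess_i > 0 else 0.0
        for _ in range(n_epochs)
    ]
    wp_base = max(250.0, rng.normal(params.wp_threshold_mean, params.wp_threshold_sd))
    wp_thresholds = [
        max(250.0, wp_base + rng.normal(0.0, params.wp_protocol_jitter))
        for _ in range(2)
    ]

    sigma_beat = sd_i / math.sqrt(2.0)  # iid deviations -> succ-diff SD = sd_i
    paced_cl = params.paced_cl
    surges: list[_Surge] = []
    events: list[tuple[float, str]] = []

    def sinus_run(t_start: float, duration_s: float) -> float:
        """Append sinus beats from t_start for ~duration_s; return last beat time."""
        t = t_start
        end = t_start + duration_s * 1000.0
        while t < end:
            mult, prolong = _surge_factor(t, surges, params)
            cl = baseline_cl + prolong
            if params.rsa_amplitude > 0:
                cl += params.rsa_amplitude * math.sin(
                    2.0 * math.pi * params.rsa_frequency * t / 1000.0
                )
            noise = 0.0
            if sigma_beat > 0:
                z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
                noise = mult * sigma_beat * z
            pp = max(cl + noise, 1.0)
            t += pp
            events.append((t, "sinus"))
        return t

    # --- protocol timeline ---------------------------------------------
    t = sinus_run(0.0, params.rest_duration)
    for epoch_idx in range(n_epochs):
        # pacing epoch: stimuli on a strict paced_cl grid
        n_stim = int(math.floor(params.pacing_duration * 1000.0 / paced_cl)) + 1
        stim_times = [t + paced_cl * (j + 1) for j in range(n_stim)]
        kept = []
        for j, st in enumerate(stim_times):
            if j > 0 and j < n_stim - 1 and rng.random() < params.capture_failure_prob:
                continue  # failed capture: no atrial event for this stimulus
            kept.append(st)
        for st in kept:
            events.append((st, "pace_stim"))
        last_stim = kept[-1]

        # SNRT beat, then post-pacing sinus under the vagal surge
        snrt_beat = last_stim + baseline_cl + excess_per_epoch[epoch_idx]
        events.append((snrt_beat, "sinus"))
        surges.append(
            _Surge(onset=snrt_beat, k=k_i, prolongation=params.surge_cl_prolongation)
        )
        if epoch_idx < n_epochs - 1:
            t = sinus_run(snrt_beat, params.inter_protocol_gap)
        else:
            t = sinus_run(snrt_beat, params.tail_duration)

    total_ms = t

    # --- contamination --------------------------------------------------
    for rate, label in ((params.ectopy_rate, "ectopic"), (params.artifact_rate, "artifact")):
        if rate > 0:
            n = rng.poisson(rate * total_ms / 60000.0)
            for tt in rng.uniform(0.0, total_ms, size=n):
                events.append((float(tt), label))

    # --- finalize: sort, round to integer ms, enforce strict monotonicity
    events.sort(key=lambda e: e[0])
    out: list[BeatEvent] = []
    prev = -1
    for tt, label in events:
        ti = int(round(tt))
        if ti <= prev:
            ti = prev + 1
        out.append(BeatEvent(time=ti, label=label))
        prev = ti

    wp_cls = []
    for thr in wp_thresholds:
        ramp = _av_ramp(thr)
        one_to_one = [r for r, ratio in ramp.items() if ratio == "1:1"]
        wp_cls.append(60000.0 / max(one_to_one) if one_to_one else float("nan"))

    metadata = {
        "seed": str(params.seed),
        "patient_index": str(patient_index),
        "av_ramp_1": format_av_ramp(_av_ramp(wp_thresholds[0])),
        "av_ramp_2": format_av_ramp(_av_ramp(wp_thresholds[1])),
    }
    series = BeatSeries(patient_id=patient_id, events=out, metadata=metadata).validate()
    truth = GroundTruth(
        patient_id=patient_id,
        baseline_cl=baseline_cl,
        sd_succ_diff=sd_i,
        surge_multiplier=k_i,
        snrt=(baseline_cl + excess_per_epoch[0], baseline_cl + excess_per_epoch[1]),
        wp_threshold=(wp_thresholds[0], wp_thresholds[1]),
        wp_cycle_length=(wp_cls[0], wp_cls[1]),
    )
    return series, truth


def simulate_cohort(params: SimParams) -> list[tuple[BeatSeries, GroundTruth]]:
    """Simulate ``params.n_patients`` independent patients.

    Patients use per-patient substreams of the master seed, so patient ``i``
    is identical regardless of cohort size, and the ordering is reproducible.
    """
    params.validate()
    return [simulate_patient(params, i) for i in range(params.n_patients)]
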