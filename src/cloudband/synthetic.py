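"""Ground-truth-labeled synthetic recordings and behavioral sessions.

The generator embodies the statistical structure the analyses assume: each
neuron has von-Mises-like (wrapped Gaussian) orientation tuning, log-domain
spatial-frequency tuning, a response gain in dF/F, and a per-condition
multiplicative surround-suppression factor that is strongest (smallest) for
narrow-bandwidth full-field stimuli.  A trial's expected amplitude is

    gain * ori_overlap * sf_overlap * suppression   (full-field)
    gain * ori_overlap * sf_overlap                 (center aperture)

where the overlaps are closed-form products of two Gaussians — the neuron's
tuning and the stimulus' bandwidth envelope — over wrapped orientation and
log2 spatial frequency.  Trial values are the expectation plus additive
Gaussian noise; baseline values are noise only.  Everything is regenerable
bit-exactly from (population, protocol, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

__all__ = [
    "Condition",
    "GroundTruthNeuron",
    "SyntheticDataset",
    "PRESET_PROTOCOLS",
    "SUPPRESSION_REGIMES",
    "generate_population",
    "generate_recording",
    "generate_spike_trials",
    "wrap_orientation_deg",
]


@dataclass(frozen=True)
class Condition:
    """One stimulus condition of a synthetic protocol."""

    name: str
    central_orientation_deg: float = 0.0
    orientation_bandwidth_deg: float = 5.0
    central_sf_cpd: float = 0.04
    sf_bandwidth_cpd: float = 0.004
    aperture: str = "full"        # "full" or "center"
    suppression_key: str = "narrow"


def _ori_protocol() -> tuple:
    return tuple(
        Condition(name=k, orientation_bandwidth_deg=bw, suppression_key=k)
        for k, bw in (("narrow", 5.0), ("mid", 22.5), ("broad", 45.0))
    )


def _sf_protocol() -> tuple:
    return tuple(
        Condition(name=k, sf_bandwidth_cpd=bw, suppression_key=k)
        for k, bw in (("narrow", 0.004), ("mid", 0.04), ("broad", 0.4))
    )


def _center_surround_protocol() -> tuple:
    base = {
        "narrow": (5.0, 0.004), "SF": (5.0, 0.4), "ORI": (45.0, 0.004),
        "mixed": (45.0, 0.4),
    }
    conds = []
    for name, (obw, sbw) in base.items():
        for ap in ("full", "center"):
            conds.append(Condition(
                name=f"{name}-{ap}", orientation_bandwidth_deg=obw,
                sf_bandwidth_cpd=sbw, aperture=ap, suppression_key=name,
            ))
    return tuple(conds)


def _discrimination_protocol() -> tuple:
    return tuple(
        Condition(name=f"ori{int(o)}", central_orientation_deg=o, suppression_key="narrow")
        for o in (0.0, 90.0)
    )


PRESET_PROTOCOLS = {
    "ori-bandwidth": _ori_protocol(),
    "sf-bandwidth": _sf_protocol(),
    "center-surround": _center_surround_protocol(),
    "discrimination": _discrimination_protocol(),
}

#: Per-condition surround-suppression multipliers (applied to full-field
#: responses only).  "paper-like": suppression is strong for narrow
#: orientation bandwidth and released by broad orientation bandwidth;
#: SF bandwidth alone does not release it.
SUPPRESSION_REGIMES = {
    "none": {},
    "narrow-specific": {"narrow": 0.5, "mid": 0.7, "broad": 0.9},
    "uniform": {"narrow": 0.5, "mid": 0.5, "broad": 0.5},
    "paper-like-cs": {"narrow": 0.4, "SF": 0.4, "ORI": 0.85, "mixed": 0.85},
}


@dataclass(frozen=True)
class GroundTruthNeuron:
    preferred_orientation_deg: float
    orientation_width_deg: float
    preferred_sf_cpd: float
    sf_width_octaves: float
    gain: float                      # peak expected amplitude, dF/F
    suppression: dict                # suppression_key -> multiplier in (0, 1]
    noise_sigma: float               # additive trial noise, dF/F
    animal_id: int

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise InvalidSpecError("gain must be >= 0")
        for v in self.suppression.values():
            if not (0.0 < v <= 1.0):
                raise InvalidSpecError("suppression multipliers must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    trial_table: pd.DataFrame
    population: tuple
    conditions: tuple
    seed: int
    params: dict = field(default_factory=dict)


def wrap_orientation_deg(x) -> np.ndarray:
    """Map orientation differences into [-90, 90) (mod 180)."""
    return np.mod(np.asarray(x, dtype=float) + 90.0, 180.0) - 90.0


def generate_population(
    n_neurons: int,
    seed: int = 0,
    pref_distribution: str = "uniform",
    cardinal_weight: float = 0.5,
    cardinal_sigma_deg: float = 10.0,
    orientation_width_deg: tuple[float, float] = (20.0, 5.0),
    sf_width_octaves: tuple[float, float] = (1.5, 0.3),
    gain_lognormal: tuple[float, float] = (np.log(0.05), 0.5),
    suppression_regime="narrow-specific",
    noise_sigma: float = 0.02,
    n_animals: int = 5,
) -> tuple:
    """Draw a ground-truth population.

    ``pref_distribution`` is "uniform" or "cardinal" (a mixture placing
    ``cardinal_weight`` of the mass in wrapped-Gaussian bumps at 0 and 90
    degrees).  Tuning widths are Gaussian-distributed (mean, sd) and clipped
    to sensible floors; gains are log-normal.  ``suppression_regime`` is a
    regime name from :data:`SUPPRESSION_REGIMES` or an explicit mapping of
    condition keys to multipliers.
    """
    if n_neurons < 1:
        raise InvalidSpecError("n_neurons must be >= 1")
    if isinstance(suppression_regime, str):
        if suppression_regime not in SUPPRESSION_REGIMES:
            raise InvalidSpecError(f"unknown suppression regime {suppression_regime!r}")
        suppression = SUPPRESSION_REGIMES[suppression_regime]
    else:
        suppression = dict(suppression_regime)
    rng = np.random.default_rng(seed)

    if pref_distribution == "uniform":
        prefs = rng.uniform(-90.0, 90.0, n_neurons)
    elif pref_distribution == "cardinal":
        if not (0.0 <= cardinal_weight <= 1.0):
            raise InvalidSpecError("cardinal_weight must lie in [0, 1]")
        prefs = np.empty(n_neurons)
        is_card = rng.random(n_neurons) < cardinal_weight
        centers = rng.choice([0.0, 90.0], size=n_neurons)
        card = centers + rng.normal(0.0, cardinal_sigma_deg, n_neurons)
        prefs = np.where(is_card, card, rng.uniform(-90.0, 90.0, n_neurons))
        prefs = wrap_orientation_deg(prefs)
    else:
        raise InvalidSpecError(f"unknown preferred-orientation distribution {pref_distribution!r}")

    widths = np.clip(rng.normal(*orientation_width_deg, n_neurons), 5.0, None)
    sf_widths = np.clip(rng.normal(*sf_width_octaves, n_neurons), 0.3, None)
    pref_sfs = 0.04 * 2.0 ** rng.normal(0.0, 1.0, n_neurons)
    gains = rng.lognormal(*gain_lognormal, n_neurons)
    animals = rng.integers(0, n_animals, n_neurons)

    return tuple(
        GroundTruthNeuron(
            preferred_orientation_deg=float(prefs[i]),
            orientation_width_deg=float(widths[i]),
            preferred_sf_cpd=float(pref_sfs[i]),
            sf_width_octaves=float(sf_widths[i]),
            gain=float(gains[i]),
            suppression=dict(suppression),
            noise_sigma=float(noise_sigma),
            animal_id=int(animals[i]),
        )
        for i in range(n_neurons)
    )


def expected_amplitude(neuron: GroundTruthNeuron, cond: Condition) -> float:
    """Noise-free expected trial amplitude of one neuron to one condition.

    A neuron's response amplitude to a random-phase band is the square root
    of the stimulus energy its (Gaussian) passband captures.  With the
    band's total energy held fixed as its width grows, the Gaussian-product
    integral gives, per feature dimension,

        overlap = (w_n^2 / (w_n^2 + w_s^2))^(1/4)
                  * exp(-d^2 / (4 (w_n^2 + w_s^2)))

    (neuron width w_n, band width w_s, tuning mismatch d) — widening a band
    spreads its energy, boosting off-tuned neurons while slightly weakening
    exactly-tuned ones.  A vanishing bandwidth at the preferred feature
    gives overlap 1.
    """
    d_ori = wrap_orientation_deg(neuron.preferred_orientation_deg
                                 - cond.central_orientation_deg)
    s_n, s_b = neuron.orientation_width_deg, cond.orientation_bandwidth_deg
    ori_overlap = (s_n**2 / (s_n**2 + s_b**2)) ** 0.25 \
        * np.exp(-0.25 * d_ori**2 / (s_n**2 + s_b**2))
    d_oct = np.log2(neuron.preferred_sf_cpd / cond.central_sf_cpd)
    stim_oct = np.log2(1.0 + cond.sf_bandwidth_cpd / cond.central_sf_cpd)
    w_n = neuron.sf_width_octaves
    sf_overlap = (w_n**2 / (w_n**2 + stim_oct**2)) ** 0.25 \
        * np.exp(-0.25 * d_oct**2 / (w_n**2 + stim_oct**2))
    mult = 1.0
    if cond.aperture == "full":
        mult = neuron.suppression.get(cond.suppression_key, 1.0)
    return float(neuron.gain * ori_overlap * sf_overlap * mult)


def _resolve_protocol(protocol) -> tuple:
    if isinstance(protocol, str):
        if protocol not in PRESET_PROTOCOLS:
            raise InvalidSpecError(f"unknown protocol preset {protocol!r}")
        return PRESET_PROTOCOLS[protocol]
    return tuple(protocol)


def generate_recording(
    population: tuple,
    protocol="ori-bandwidth",
    n_trials: int = 20,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a trial table for a population under a protocol.

    Stimulus values are ``expected + N(0, sigma)``; baseline values are
    ``N(0, sigma)`` — the analyses consume amplitudes, so noise lives on the
    amplitude level.
    """
    conditions = _resolve_protocol(protocol)
    rng = np.random.default_rng(seed)
    n = len(population)
    records = []
    for ci, cond in enumerate(conditions):
        mu = np.array([expected_amplitude(nr, cond) for nr in population])
        sig = np.array([nr.noise_sigma for nr in population])
        stim = mu[:, None] + rng.normal(0.0, 1.0, (n, n_trials)) * sig[:, None]
        base = rng.normal(0.0, 1.0, (n, n_trials)) * sig[:, None]
        for i, nr in enumerate(population):
            for k in range(n_trials):
                records.append((i, cond.name, k, base[i, k], stim[i, k], nr.animal_id))
    table = pd.DataFrame(records, columns=[
        "neuron_id", "condition_id", "trial_index", "baseline_value", "stim_value",
        "animal_id",
    ])
    return SyntheticDataset(
        trial_table=table, population=tuple(population), conditions=conditions,
        seed=seed, params={"n_trials": n_trials, "protocol": protocol
                           if isinstance(protocol, str) else "custom"},
    )


def generate_spike_trials(
    population: tuple,
    protocol="ori-bandwidth",
    n_trials: int = 20,
    baseline_rate_hz: float = 2.0,
    rate_gain_hz: float = 20.0,
    duration_s: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Poisson spike-count trials in spikes/s.

    The stimulus-period rate is ``baseline + rate_gain * gain-normalized
    expected amplitude``; the baseline period uses the baseline rate alone.
    """
    if baseline_rate_hz < 0 or rate_gain_hz < 0:
        raise InvalidSpecError("rates must be >= 0")
    conditions = _resolve_protocol(protocol)
    rng = np.random.default_rng(seed)
    records = []
    for cond in conditions:
        for i, nr in enumerate(population):
            drive = expected_amplitude(nr, cond) / nr.gain if nr.gain > 0 else 0.0
            rate = baseline_rate_hz + rate_gain_hz * drive
            stim = rng.poisson(rate * duration_s, n_trials) / duration_s
            base = rng.poisson(baseline_rate_hz * duration_s, n_trials) / duration_s
            for k in range(n_trials):
                records.append((i, cond.name, k, float(base[k]), float(stim[k]),
                                nr.animal_id))
    table = pd.DataFrame(records, columns=[
        "neuron_id", "condition_id", "trial_index", "baseline_value", "stim_value",
        "animal_id",
    ])
    return SyntheticDataset(
        trial_table=table, population=tuple(population), conditions=conditions,
        seed=seed, params={"n_trials": n_trials, "kind": "spikes",
                           "baseline_rate_hz": baseline_rate_hz,
                           "rate_gain_hz": rate_gain_hz, "duration_s": duration_s},
    )
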