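"""Synthetic data generator for the surfactant bioassay pipeline.

Two kinds of inputs are emulated so every downstream stage can be exercised
without laboratory data:

1. Surface-tension/area traces of a drop cycled sinusoidally at the assay's
   protocol (20 cycles/min, sampled at 10 Hz) while test chemical deposits on
   it at a constant flux. Inhibition is modeled phenomenologically: the
   per-cycle surface-tension floor rises from a functional baseline
   (~2 mN/m, below the 5 mN/m QC bound) toward an inhibited plateau
   (>= 10 mN/m, the dysfunction threshold) following a saturating
   dose-response with half-maximal dose D50.

2. Chemical outcome panels with prescribed 2x2 confusion-table margins for
   the two evaluation scenarios (GHS classification and rat clinical signs),
   so concordance metrics recomputed from the panel equal a requested table
   exactly, while per-chemical assignment is randomized by seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lungsurf.errors import ConsistencyError, ParameterError

#: Standard respiratory-sign lexicon terms used for generated observations.
_POSITIVE_SIGNS = [
    "gasping",
    "tachypnoea",
    "irregular respiration",
    "laboured shallow breathing",
    "rales",
    "bradypnoea",
]
#: Raw observations that must not count as respiratory positivity: either a
#: non-respiratory sign in-window, or a respiratory sign after the 2 h window.
_NEGATIVE_OBSERVATIONS = [
    ("piloerection", "H0"),
    ("hypoactivity", "H1"),
    ("irregular respiration", "later"),
    ("tremor", "H2"),
]


@dataclass(frozen=True)
class CyclingProtocol:
    """Compression-expansion protocol of the constrained-drop surfactometer.

    Attributes
    ----------
    cycle_rate : float
        Compression-expansion cycles per minute (default 20, mimicking the
        human respiratory rate).
    frame_rate : float
        Imaging rate, Hz (default 10).
    baseline_area : float
        A0, drop surface area at full expansion, mm^2.
    relative_amplitude : float
        a in (0, 1): per-cycle fractional area compression.
    duration : float
        Trace length, s.
    temperature : float
        Chamber temperature, deg C (metadata only).
    """

    cycle_rate: float = 20.0
    frame_rate: float = 10.0
    baseline_area: float = 50.0
    relative_amplitude: float = 0.25
    duration: float = 120.0
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if not 0 < self.relative_amplitude < 1:
            raise ParameterError(f"relative_amplitude must be in (0,1), got {self.relative_amplitude}")
        if self.cycle_rate <= 0 or self.frame_rate <= 0:
            raise ParameterError("cycle_rate and frame_rate must be > 0")
        samples_per_cycle = self.frame_rate * 60.0 / self.cycle_rate
        if samples_per_cycle < 10:
            raise ParameterError(
                f"protocol yields {samples_per_cycle:.1f} samples/cycle; >= 10 required"
            )
        if self.duration <= 0 or self.baseline_area <= 0:
            raise ParameterError("duration and baseline_area must be > 0")

    @property
    def cycle_period(self) -> float:
        """Seconds per cycle."""
        return 60.0 / self.cycle_rate

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.frame_rate))
        return np.arange(n) / self.frame_rate


@dataclass(frozen=True)
class FilmModelParams:
    """Phenomenological surfactant-film inhibition model.

    The instantaneous surface tension is

        gamma(t) = gamma_floor(t) + (gamma_max - gamma_floor(t)) * (1 - c(t))**p + eps(t)

    where c(t) in [0, 1] is the normalized compression (1 at maximal
    compression), and the per-cycle floor follows a saturating dose-response
    in cumulative deposited dose D(t) = flux * t:

        gamma_floor(t) = floor_functional
                         + (floor_inhibited - floor_functional) * D / (D + d50)

    Attributes (mN/m unless noted): gamma_max at full expansion (40);
    floor_functional, minimum of an intact film (2, below the 5 mN/m QC
    bound); floor_inhibited, plateau of a fully inhibited film (25, above the
    10 mN/m dysfunction threshold); d50, half-inhibitory dose (ng/cm^2);
    deposition_flux (ng/cm^2/min); compression_exponent p (dimensionless);
    noise_sd, i.i.d. Gaussian noise on gamma only (area is pump-controlled).
    """

    gamma_max: float = 40.0
    floor_functional: float = 2.0
    floor_inhibited: float = 25.0
    d50: float = 100.0
    deposition_flux: float = 0.0
    compression_exponent: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.floor_functional < 5.0 <= 10.0 <= self.floor_inhibited < self.gamma_max):
            raise ParameterError(
                "need floor_functional < 5 <= 10 <= floor_inhibited < gamma_max, got "
                f"({self.floor_functional}, {self.floor_inhibited}, {self.gamma_max})"
            )
        if self.deposition_flux < 0:
            raise ParameterError("deposition_flux must be >= 0")
        if self.d50 <= 0:
            raise ParameterError("d50 must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def floor_at_dose(self, dose: np.ndarray | float) -> np.ndarray | float:
        """Surface-tension floor (mN/m) at cumulative dose (ng/cm^2)."""
        return self.floor_functional + (self.floor_inhibited - self.floor_functional) * dose / (dose + self.d50)

    def floor_crossing_time(self, threshold: float = 10.0) -> float:
        """Time (s) at which the noise-free floor crosses `threshold` mN/m.

        Returns inf when the flux is zero or the plateau never reaches the
        threshold. Used as analytic ground truth for dose-estimation checks.
        """
        if self.deposition_flux <= 0 or threshold >= self.floor_inhibited:
            return float("inf")
        if threshold <= self.floor_functional:
            return 0.0
        frac = (threshold - self.floor_functional) / (self.floor_inhibited - self.floor_functional)
        dose_star = self.d50 * frac / (1.0 - frac)  # ng/cm^2
        return dose_star / self.deposition_flux * 60.0  # min -> s


def simulate_area(protocol: CyclingProtocol) -> np.ndarray:
    """Sinusoidal drop-area series A(t) at each frame, mm^2.

    A(t) = A0 * (1 - a/2 + (a/2) cos(2 pi f t)) with f = cycle_rate/60:
    maximum A0 at t = 0, per-cycle compression ratio exactly a.
    """
    t = protocol.time_grid()
    a = protocol.relative_amplitude
    f = protocol.cycle_rate / 60.0
    return protocol.baseline_area * (1.0 - a / 2.0 + (a / 2.0) * np.cos(2.0 * np.pi * f * t))


def simulate_trace(protocol: CyclingProtocol, film: FilmModelParams):
    """Simulate a surface-tension/area trace of a cycling, exposed drop.

    Returns a :class:`lungsurf.traces.SurfaceTensionTrace`. Reproducible for
    a fixed ``film.seed``.
    """
    from lungsurf.traces import SurfaceTensionTrace  # circular-import guard

    t = protocol.time_grid()
    area = simulate_area(protocol)
    a = protocol.relative_amplitude
    # normalized compression: 0 at full expansion, 1 at maximal compression
    c = (protocol.baseline_area - area) / (protocol.baseline_area * a)
    dose = film.deposition_flux * t / 60.0  # ng/cm^2 (flux is per minute)
    floor = film.floor_at_dose(dose)
    gamma = floor + (film.gamma_max - floor) * (1.0 - c) ** film.compression_exponent
    if film.noise_sd > 0:
        rng = np.random.default_rng(film.seed)
        gamma = gamma + rng.normal(0.0, film.noise_sd, size=gamma.shape)
    gamma = np.maximum(gamma, 0.05)  # physical lower bound; traces stay > 0
    return SurfaceTensionTrace(
        time=t,
        surface_tension=gamma,
        surface_area=area,
        frame_rate=protocol.frame_rate,
        metadata={
            "cycle_rate_per_min": protocol.cycle_rate,
            "deposition_flux_ng_per_cm2_min": film.deposition_flux,
            "seed": film.seed,
        },
    )


def _validate_margins(margins: tuple[int, int, int, int], name: str) -> None:
    if len(margins) != 4 or any((m < 0 or int(m) != m) for m in margins):
        raise ConsistencyError(f"{name} margins must be 4 non-negative integers, got {margins}")


def generate_outcome_dataset(
    ghs_margins: tuple[int, int, int, int],
    clinical_margins: tuple[int, int, int, int],
    n_chemicals: int,
    seed: int = 0,
) -> list:
    """Generate a chemical panel with exact 2x2 margins for both scenarios.

    Parameters
    ----------
    ghs_margins, clinical_margins : (TP, FN, FP, TN)
        Counts of the in vitro call crossed with the scenario's reference
        label. Both must sum to ``n_chemicals`` and agree on the number of
        in vitro positives (TP + FP) since the in vitro column is shared.
    seed : int
        Randomizes which chemical receives which label combination; the
        margins themselves are deterministic.

    Returns
    -------
    list[ChemicalRecord]
        Records with GHS category labels and raw clinical-sign observations
        such that the recomputed confusion tables equal the requested margins.
    """
    from lungsurf.concordance import ChemicalRecord  # circular-import guard

    _validate_margins(ghs_margins, "ghs")
    _validate_margins(clinical_margins, "clinical")
    g_tp, g_fn, g_fp, g_tn = (int(m) for m in ghs_margins)
    c_tp, c_fn, c_fp, c_tn = (int(m) for m in clinical_margins)

    if g_tp + g_fn + g_fp + g_tn != n_chemicals:
        raise ConsistencyError(f"ghs margins sum to {g_tp + g_fn + g_fp + g_tn}, expected {n_chemicals}")
    if c_tp + c_fn + c_fp + c_tn != n_chemicals:
        raise ConsistencyError(f"clinical margins sum to {c_tp + c_fn + c_fp + c_tn}, expected {n_chemicals}")
    if g_tp + g_fp != c_tp + c_fp:
        raise ConsistencyError(
            "scenarios disagree on in vitro positives: "
            f"ghs TP+FP={g_tp + g_fp}, clinical TP+FP={c_tp + c_fp}"
        )

    rng = np.random.default_rng(seed)
    n_pos = g_tp + g_fp
    n_neg = n_chemicals - n_pos
    invitro = np.array([True] * n_pos + [False] * n_neg)

    def scenario_labels(tp: int, fn: int) -> np.ndarray:
        """Reference labels: tp of the positives and fn of the negatives true."""
        lab = np.zeros(n_chemicals, dtype=bool)
        lab[rng.choice(n_pos, size=tp, replace=False)] = True
        lab[n_pos + rng.choice(n_neg, size=fn, replace=False)] = True
        return lab

    ghs_ref = scenario_labels(g_tp, g_fn)
    clin_ref = scenario_labels(c_tp, c_fn)

    order = rng.permutation(n_chemicals)
    records = []
    for new_id, idx in enumerate(order, start=1):
        ghs_cat = rng.choice(["cat3", "cat4"]) if ghs_ref[idx] else "not_classified"
        if clin_ref[idx]:
            sign = _POSITIVE_SIGNS[rng.integers(len(_POSITIVE_SIGNS))]
            window = ["H0", "H1", "H2"][rng.integers(3)]
            observations = [(sign, window)]
        else:
            # zero, one or two observations, none qualifying
            k = rng.integers(3)
            picks = rng.choice(len(_NEGATIVE_OBSERVATIONS), size=k, replace=False)
            observations = [_NEGATIVE_OBSERVATIONS[i] for i in picks]
        records.append(
            ChemicalRecord(
                chemical_id=f"CHEM-{new_id:03d}",
                invitro_inhibitory=bool(invitro[idx]),
                ghs_category=str(ghs_cat),
                observations=observations,
            )
        )
    return records
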