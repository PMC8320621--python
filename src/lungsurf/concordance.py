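"""Two-scenario predictivity evaluation of the bioassay.

The binary in vitro call (inhibitory / not inhibitory) is compared against
two independent in vivo reference labels per chemical:

* GHS scenario — reference-positive when the chemical is classified under
  GHS acute inhalation toxicity category 3 or 4 (categories derived from
  rat LC50 studies; the category labels are inputs here, never derived).
* Clinical scenario — reference-positive when at least one standardized
  respiratory sign (irregular-, shallow-, noisy-, slow-, rapid/fast-
  respiration, or gasping) was observed during exposure (window H0) or in
  the first two hours after it (H1, H2); later observations do not count.

From the resulting 2x2 tables the five standard diagnostic metrics are
computed as exact fractions and displayed rounded half-up to two decimals.
A metric with a zero denominator is undefined, never coerced to a number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

import yaml

from lungsurf.errors import InsufficientDataError, ParameterError

UNMAPPED = "unmapped"
LEXICON_TERMS = (
    "irregular respiration",
    "shallow respiration",
    "noisy respiration",
    "slow respiration",
    "rapid/fast respiration",
    "gasping",
)
OBSERVATION_WINDOWS = ("H0", "H1", "H2", "later")
#: Windows that count toward the clinical reference label (exposure + 2 h).
RELEVANT_WINDOWS = ("H0", "H1", "H2")

GHS_CATEGORIES = ("cat1", "cat2", "cat3", "cat4", "cat5", "not_classified")
#: Categories treated as reference-positive; categories outside 3-4
#: (including category 5 and unclassifiable chemicals) are negative.
CLASSIFIED_CATEGORIES = ("cat3", "cat4")

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def _normalize(term: str) -> str:
    return re.sub(r"\s+", " ", term.lower().replace("-", " ").replace("_", " ")).strip()


def load_lexicon_map(path: str | None = None) -> dict[str, str]:
    """Load a synonym table mapping raw observation strings to lexicon terms.

    The YAML maps each lexicon term to a list of synonyms. Ships with an
    editable default; pass ``path`` to substitute a custom table.
    """
    if path is None:
        text = resources.files("lungsurf.data").joinpath("clinical_signs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for term, synonyms in raw.items():
        if term not in LEXICON_TERMS:
            raise ParameterError(f"unknown lexicon term in synonym table: {term!r}")
        for syn in synonyms:
            mapping[_normalize(syn)] = term
    return mapping


_DEFAULT_MAP: dict[str, str] | None = None


def _default_map() -> dict[str, str]:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_lexicon_map()
    return _DEFAULT_MAP


def standardize_clinical_sign(raw: str, lexicon_map: dict[str, str] | None = None) -> str:
    """Map a raw observation string to a lexicon term, or ``"unmapped"``.

    Matching is case- and hyphen-insensitive against the synonym table.
    Unmapped is a value, not an error: non-respiratory signs
    (e.g. piloerection) land there and are surfaced in reports.
    """
    table = lexicon_map if lexicon_map is not None else _default_map()
    return table.get(_normalize(raw), UNMAPPED)


@dataclass
class ChemicalRecord:
    """One chemical's in vitro outcome and in vivo reference data.

    ``observations`` holds (raw_sign, window) pairs exactly as transcribed;
    ``standardized_signs`` is filled by :func:`standardize_record`.
    """

    chemical_id: str
    invitro_inhibitory: bool
    ghs_category: str
    lc50_mg_per_l: float | None = None
    observations: list[tuple[str, str]] = field(default_factory=list)
    standardized_signs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ghs_category not in GHS_CATEGORIES:
            raise ParameterError(
                f"{self.chemical_id}: ghs_category {self.ghs_category!r} not in {GHS_CATEGORIES}"
            )
        for raw, window in self.observations:
            if window not in OBSERVATION_WINDOWS:
                raise ParameterError(
                    f"{self.chemical_id}: window {window!r} for sign {raw!r} "
                    f"not in {OBSERVATION_WINDOWS}"
                )


def standardize_record(record: ChemicalRecord, lexicon_map: dict[str, str] | None = None) -> ChemicalRecord:
    """Fill ``standardized_signs`` from the raw observations (in place)."""
    record.standardized_signs = [
        (standardize_clinical_sign(raw, lexicon_map), window) for raw, window in record.observations
    ]
    return record


def clinical_reference_label(record: ChemicalRecord, lexicon_map: dict[str, str] | None = None) -> bool:
    """True iff any standardized respiratory sign falls in windows H0-H2."""
    if not record.standardized_signs and record.observations:
        standardize_record(record, lexicon_map)
    return any(
        term != UNMAPPED and window in RELEVANT_WINDOWS for term, window in record.standardized_signs
    )


def ghs_reference_label(record: ChemicalRecord) -> bool:
    """True iff the chemical falls under GHS acute inhalation category 3 or 4."""
    return record.ghs_category in CLASSIFIED_CATEGORIES


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of in vitro call vs in vivo reference for one scenario."""

    tp: int
    fn: int
    fp: int
    tn: int
    scenario: str = "ghs"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.n == 0:
            raise ParameterError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def build_confusion(
    records: list[ChemicalRecord],
    scenario: str,
    lexicon_map: dict[str, str] | None = None,
) -> ConfusionTable:
    """Cross the in vitro calls with a scenario's reference labels."""
    if not records:
        raise InsufficientDataError("no chemical records to evaluate")
    if scenario == "ghs":
        ref = [ghs_reference_label(r) for r in records]
    elif scenario == "clinical":
        ref = [clinical_reference_label(r, lexicon_map) for r in records]
    else:
        raise ParameterError(f"scenario must be 'ghs' or 'clinical', got {scenario!r}")
    calls = [r.invitro_inhibitory for r in records]
    tp = sum(c and rf for c, rf in zip(calls, ref))
    fp = sum(c and not rf for c, rf in zip(calls, ref))
    fn = sum((not c) and rf for c, rf in zip(calls, ref))
    tn = sum((not c) and (not rf) for c, rf in zip(calls, ref))
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, scenario=scenario)


def round_half_up(value: Fraction, decimals: int = 2) -> float:
    """Round an exact fraction half-up (0.375 -> 0.38) to `decimals` places."""
    scale = 10**decimals
    return float((value * scale + Fraction(1, 2)).__floor__()) / scale


@dataclass(frozen=True)
class MetricValue:
    """One diagnostic metric as an exact fraction plus display rounding."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def exact(self) -> Fraction | None:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    @property
    def rounded(self) -> float | None:
        return round_half_up(self.exact) if self.defined else None

    def __str__(self) -> str:
        if not self.defined:
            return f"undefined (0 denominator: {self.numerator}/{self.denominator})"
        return f"{self.rounded:.2f} ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class PredictivityMetrics:
    """The five diagnostic concordance metrics of one scenario."""

    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    scenario: str = "ghs"
    confidence_intervals: dict | None = None

    def as_dict(self) -> dict:
        out: dict = {"scenario": self.scenario}
        for name in METRIC_NAMES:
            m: MetricValue = getattr(self, name)
            out[name] = {
                "value": m.rounded,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "defined": m.defined,
            }
            if self.confidence_intervals and name in self.confidence_intervals:
                out[name]["wilson_95ci"] = self.confidence_intervals[name]
        return out


def wilson_interval(numerator: int, denominator: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def compute_metrics(ct: ConfusionTable, with_ci: bool = False) -> PredictivityMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/N. Values are kept as exact
    fractions; display rounding is half-up to 2 decimals. Wilson 95% score
    intervals are attached when ``with_ci`` is set (off by default).
    """
    metrics = {
        "sensitivity": MetricValue(ct.tp, ct.tp + ct.fn),
        "specificity": MetricValue(ct.tn, ct.tn + ct.fp),
        "ppv": MetricValue(ct.tp, ct.tp + ct.fp),
        "npv": MetricValue(ct.tn, ct.tn + ct.fn),
        "accuracy": MetricValue(ct.tp + ct.tn, ct.n),
    }
    cis = None
    if with_ci:
        cis = {
            name: wilson_interval(m.numerator, m.denominator)
            for name, m in metrics.items()
            if m.defined
        }
    return PredictivityMetrics(scenario=ct.scenario, confidence_intervals=cis, **metrics)


def metrics_markdown(ghs: PredictivityMetrics, clinical: PredictivityMetrics) -> str:
    """Render both scenarios side by side as a markdown table."""
    label = {
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "ppv": "Positive predictive value",
        "npv": "Negative predictive value",
        "accuracy": "Accuracy",
    }
    lines = [
        "| Metric | GHS classification | Clinical signs of respiratory toxicity |",
        "| --- | --- | --- |",
    ]
    for name in METRIC_NAMES:
        lines.append(f"| {label[name]} | {getattr(ghs, name)} | {getattr(clinical, name)} |")
    return "\n".join(lines)
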