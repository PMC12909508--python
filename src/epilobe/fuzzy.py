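"""Bell Elliptic Fuzzy Logic System: the Seizure Activity Index.

Crisp inputs are three spectral features of a segment — relative alpha
(8-13 Hz) power, relative delta (0.5-4 Hz) power, and normalized
spectral entropy.  Each variable carries three generalized-bell
membership functions (Low / Medium / High); a Mamdani-style rule base
fires with min-conjunction strengths, and the defuzzified output is the
strength-weighted average of the consequent crisp values.  The index
(stage) is the consequent value nearest the defuzzified output.

The index is a signal-derived, relative tier — explicitly not a
clinically validated severity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

LEVELS = ("Low", "Medium", "High")

#: canonical four-rule base: (alpha, delta, entropy) antecedents -> stage
DEFAULT_RULES = (
    (("Low", "Low", "Low"), "Low"),
    (("Medium", "Medium", "Medium"), "Medium"),
    (("Low", "High", "High"), "Low"),
    (("Medium", "Medium", "Low"), "High"),
)

#: crisp consequent values, strictly ordered Low < Medium < High
DEFAULT_CONSEQUENTS = {"Low": 0.25, "Medium": 0.50, "High": 0.75}

__all__ = [
    "FuzzyInputs",
    "BellMembership",
    "FuzzyRuleBase",
    "bell_membership",
    "fuzzify",
    "infer_index",
    "compute_fuzzy_inputs",
    "fit_memberships",
]


@dataclass
class FuzzyInputs:
    alpha: float  # relative alpha-band power
    delta: float  # relative delta-band power
    entropy: float  # normalized spectral entropy in [0, 1]

    def as_array(self):
        return np.array([self.alpha, self.delta, self.entropy], dtype=float)


@dataclass
class BellMembership:
    center: float  # lambda
    width: float  # beta > 0
    slope: float = 2.0  # gamma > 0

    def __post_init__(self):
        if self.width <= 0 or self.slope <= 0:
            raise ValueError("bell membership requires width > 0 and slope > 0")

    def __call__(self, v):
        return bell_membership(v, self.center, self.width, self.slope)


def bell_membership(v, center, width, slope):
    """Generalized bell: 1 / (1 + (|v - center| / width)^(2*slope))."""
    if width <= 0 or slope <= 0:
        raise ValueError("bell membership requires width > 0 and slope > 0")
    return 1.0 / (1.0 + (np.abs(np.asarray(v, dtype=float) - center) / width) ** (2.0 * slope))


@dataclass
class FuzzyRuleBase:
    """Membership triples per (variable, level) plus the rule table."""

    memberships: dict  # variable -> {level: BellMembership}
    rules: tuple = DEFAULT_RULES
    consequents: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENTS))
    max_strength_fallback: bool = True

    VARIABLES = ("alpha", "delta", "entropy")

    def __post_init__(self):
        vals = [self.consequents[l] for l in LEVELS]
        if not (vals[0] < vals[1] < vals[2]):
            raise ValueError("consequent crisp values must be strictly ordered")
        for var in self.VARIABLES:
            if var not in self.memberships or set(self.memberships[var]) != set(LEVELS):
                raise ValueError(f"missing membership triples for variable {var!r}")

    def level_centers(self, variable):
        return {lev: self.memberships[variable][lev].center for lev in LEVELS}


def fit_memberships(alpha_values, delta_values, entropy_values, slope=2.0):
    """Membership parameters from a training-feature distribution.

    Level centers are the tertile midpoints (Low/Medium/High thirds of
    the empirical distribution); widths are half the inter-center
    distance so neighbouring bells cross near 0.5 membership.
    """
    memberships = {}
    for var, values in (
        ("alpha", alpha_values),
        ("delta", delta_values),
        ("entropy", entropy_values),
    ):
        v = np.sort(np.asarray(values, dtype=float))
        if len(v) < 3:
            raise ValueError("need at least 3 samples per variable to fit tertiles")
        centers = [
            float(np.median(chunk)) for chunk in np.array_split(v, 3)
        ]  # tertile midpoints
        span = max((centers[2] - centers[0]) / 4.0, 1e-6)
        memberships[var] = {
            lev: BellMembership(center=c, width=span, slope=slope)
            for lev, c in zip(LEVELS, centers)
        }
    return FuzzyRuleBase(memberships=memberships)


def fuzzify(inputs, rulebase):
    """3x3 matrix of membership degrees: rows alpha/delta/entropy, cols levels."""
    vals = inputs.as_array()
    out = np.empty((3, 3))
    for i, var in enumerate(FuzzyRuleBase.VARIABLES):
        for j, lev in enumerate(LEVELS):
            out[i, j] = rulebase.memberships[var][lev](vals[i])
    return out


def infer_index(degrees, rulebase):
    """Defuzzified output and stage from fuzzified degrees.

    Rule strength is the min over antecedent degrees (Mamdani
    conjunction); DF is the strength-weighted average of consequent
    crisp values; the stage is the consequent nearest DF.
    """
    degrees = np.asarray(degrees)
    strengths, crisps = [], []
    for antecedents, consequent in rulebase.rules:
        s = min(
            degrees[i, LEVELS.index(lev)] for i, lev in enumerate(antecedents)
        )
        strengths.append(s)
        crisps.append(rulebase.consequents[consequent])
    strengths = np.asarray(strengths)
    crisps = np.asarray(crisps)
    total = strengths.sum()
    if total <= 0:
        if not rulebase.max_strength_fallback:
            raise ValueError("no rule fires and the max-strength fallback is disabled")
        df = crisps[int(np.argmax(strengths))]
    else:
        df = float((strengths * crisps).sum() / total)
    stage = LEVELS[int(np.argmin([abs(df - rulebase.consequents[l]) for l in LEVELS]))]
    return df, stage


def defuzzify(strengths, crisp_values):
    """Weighted-average defuzzification of explicit rule strengths."""
    strengths = np.asarray(strengths, dtype=float)
    crisp_values = np.asarray(crisp_values, dtype=float)
    total = strengths.sum()
    if total <= 0:
        raise ValueError("all rule strengths are zero")
    return float((strengths * crisp_values).sum() / total)


def compute_fuzzy_inputs(segment, sampling_rate):
    """Relative alpha/delta band power and normalized spectral entropy."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    nper = min(seg.shape[1], 256)
    f, psd = sps.welch(seg, fs=sampling_rate, nperseg=nper, axis=1)
    psd = psd.mean(axis=0)
    total = psd.sum()
    if total <= 0:
        return FuzzyInputs(0.0, 0.0, 0.0)
    alpha = psd[(f >= 8) & (f <= 13)].sum() / total
    delta = psd[(f >= 0.5) & (f <= 4)].sum() / total
    p = psd / total
    p = p[p > 0]
    entropy = float(-(p * np.log(p)).sum() / np.log(len(psd)))
    return FuzzyInputs(float(alpha), float(delta), entropy)


def seizure_activity_index(segment, sampling_rate, rulebase):
    """Convenience: segment -> (DF, stage)."""
    inputs = compute_fuzzy_inputs(segment, sampling_rate)
    return infer_index(fuzzify(inputs, rulebase), rulebase)
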