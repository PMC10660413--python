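"""Immunoassay validation: parallelism, accuracy and precision (CV) checks.

Enzyme immunoassays are validated for a new matrix (here, faecal extracts)
before the measured concentrations are trusted: serially diluted pooled
extract must parallel the kit standard curve (equal slopes on a linearised
scale), assays of spiked known concentrations must recover them (regression
slope near 1), and replicate measurements must be precise within and
between plates (coefficients of variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TestResult, simple_ols, slope_equality_f

__all__ = [
    "DilutionSeries",
    "AccuracyResult",
    "parallelism_test",
    "accuracy_test",
    "assay_cv",
]


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class DilutionSeries:
    """A dose-response series: relative dilutions and percent-bound readings."""

    kind: str  # 'standard' | 'pooled_extract'
    dose: tuple[float, ...]
    response: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in ("standard", "pooled_extract"):
            raise AssayError(f"unknown series kind {self.kind!r}")
        d = np.asarray(self.dose, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if d.size != r.size or d.size < 3:
            raise AssayError("need >= 3 matched dose/response points")
        if (d <= 0).any():
            raise AssayError("doses must be positive")
        dd = np.diff(d)
        if not ((dd > 0).all() or (dd < 0).all()):
            raise AssayError("doses must be strictly monotone")
        object.__setattr__(self, "dose", tuple(map(float, d)))
        object.__setattr__(self, "response", tuple(map(float, r)))

    def linearized(self) -> tuple[np.ndarray, np.ndarray]:
        """(log dose, logit percent-bound) — the standard linearisation."""
        x = np.log(np.asarray(self.dose))
        b = np.asarray(self.response, dtype=float) / 100.0
        if ((b <= 0) | (b >= 1)).any():
            raise AssayError("percent bound must lie strictly within (0, 100)")
        y = np.log(b / (1.0 - b))
        return x, y


def parallelism_test(standard: DilutionSeries, extract: DilutionSeries) -> TestResult:
    """Slope-equality F test between standard and pooled-extract curves.

    Both series are linearised to logit(percent bound) vs log(dose) and the
    extra-sum-of-squares F test for a common slope is applied; df is
    (1, nA + nB - 4).  A non-significant F supports parallelism, i.e. that
    the extract dilutes like the standard and concentrations read off the
    standard curve are valid.
    """
    res = slope_equality_f(standard.linearized(), extract.linearized())
    res.method = "parallelism_f"
    return res


@dataclass
class AccuracyResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    passed: bool
    fit_p: float


def accuracy_test(expected, observed, band=(0.9, 1.1)) -> AccuracyResult:
    """Regression of observed on expected (spiked) concentrations.

    The assay is accurate when the recovery slope is compatible with 1:
    the check passes when the 95% CI for the slope overlaps the configured
    acceptance band (default 0.9-1.1).
    """
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if expected.size < 3:
        raise AssayError("need >= 3 spiked levels")
    fit = simple_ols(expected, observed)
    from scipy import stats as sps

    tcrit = float(sps.t.ppf(0.975, fit.n - 2))
    lo = fit.slope - tcrit * fit.se_slope
    hi = fit.slope + tcrit * fit.se_slope
    passed = (hi >= band[0]) and (lo <= band[1])
    return AccuracyResult(fit.slope, fit.intercept, lo, hi, passed, fit.p)


def assay_cv(replicate_matrix) -> tuple[float, float | None]:
    """Intra- and inter-assay coefficients of variation, in percent.

    ``replicate_matrix`` maps plate id -> list of per-sample replicate
    tuples (typically duplicates).  Intra-assay CV is the mean over all
    samples of the within-replicate sd/mean; inter-assay CV is the sd/mean
    of the per-plate pooled means.  With a single plate the inter-assay CV
    is undefined and returned as None.
    """
    plates = dict(replicate_matrix)
    if not plates:
        raise AssayError("no plates supplied")
    per_sample_cv = []
    plate_means = []
    for plate, rows in plates.items():
        vals = []
        for reps in rows:
            reps = np.asarray(reps, dtype=float)
            if reps.size < 2:
                raise AssayError(f"plate {plate!r}: need >= 2 replicates per sample")
            m = reps.mean()
            if m <= 0:
                raise AssayError(f"plate {plate!r}: non-positive replicate mean")
            per_sample_cv.append(reps.std(ddof=1) / m * 100.0)
            vals.extend(reps.tolist())
        plate_means.append(float(np.mean(vals)))
    intra = float(np.mean(per_sample_cv))
    if len(plate_means) < 2:
        return intra, None
    pm = np.asarray(plate_means)
    inter = float(pm.std(ddof=1) / pm.mean() * 100.0)
    return intra, inter
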