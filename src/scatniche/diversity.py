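"""Sample-based rarefaction of diet diversity.

Whether enough scats were collected to characterise the diet is judged by
resampling: for each subsample size t the scats are drawn without
replacement, their prey occurrences pooled, and the Shannon index computed;
the mean curve over many randomizations plateaus once additional scats stop
adding diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .samples import SampleValidationError, StudyGroup

__all__ = ["RarefactionCurve", "shannon_index", "rarefy", "plateau_t"]


@dataclass
class RarefactionCurve:
    group_label: str
    t: np.ndarray  # subsample sizes 1..n
    mean_H: np.ndarray  # Shannon index (nats) averaged over randomizations
    sd_H: np.ndarray
    n_randomizations: int
    seed: int


def shannon_index(occurrence_counts, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_s log p_s over species proportions.

    Natural log by default; zero-count species are ignored.
    """
    counts = np.asarray([c for c in dict(occurrence_counts).values()], dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0 or counts.sum() <= 0:
        raise SampleValidationError("shannon_index: no positive counts")
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def _pooled_H(prey_sets, species_index, subset):
    counts = np.zeros(len(species_index))
    for k in subset:
        for sp in prey_sets[k]:
            counts[species_index[sp]] += 1
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def rarefy(group: StudyGroup, n_randomizations: int = 1000, seed: int = 0) -> RarefactionCurve:
    """Sample-based rarefaction curve of the Shannon index for one group.

    For each t in 1..n, draws ``n_randomizations`` subsamples of t scats
    without replacement, pools their prey occurrences and averages H.
    Deterministic given the seed; at t = n every draw is the full sample,
    so mean_H(n) equals the full-sample H and sd_H(n) = 0.
    """
    prey_sets = [s.prey for s in group.samples if s.prey]
    n = len(prey_sets)
    if n < 2:
        raise SampleValidationError(
            f"group {group.label}: need >= 2 prey-identified samples to rarefy"
        )
    if n_randomizations < 1:
        raise SampleValidationError("n_randomizations must be >= 1")
    species = sorted({sp for ps in prey_sets for sp in ps})
    idx = {sp: k for k, sp in enumerate(species)}
    # scat x species incidence matrix; pooling a subset is a column sum
    inc = np.zeros((n, len(species)))
    for k, ps in enumerate(prey_sets):
        for sp in ps:
            inc[k, idx[sp]] = 1.0
    rng = np.random.default_rng(seed)
    ts = np.arange(1, n + 1)
    mean_H = np.empty(n)
    sd_H = np.empty(n)
    for t in ts:
        if t == n:
            h = np.full(1, _full_H(inc))
        else:
            h = np.empty(n_randomizations)
            for r in range(n_randomizations):
                subset = rng.choice(n, size=t, replace=False)
                counts = inc[subset].sum(axis=0)
                p = counts[counts > 0]
                p = p / p.sum()
                h[r] = -(p * np.log(p)).sum()
        mean_H[t - 1] = h.mean()
        sd_H[t - 1] = h.std(ddof=0) if h.size > 1 else 0.0
    return RarefactionCurve(group.label, ts, mean_H, sd_H, n_randomizations, seed)


def _full_H(inc: np.ndarray) -> float:
    counts = inc.sum(axis=0)
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def plateau_t(curve: RarefactionCurve, eps: float = 0.01, run: int = 10) -> int | None:
    """First subsample size at which the curve has plateaued.

    The plateau criterion is ``run`` consecutive per-sample increments of
    the mean curve all below ``eps`` nats; returns the t opening that run,
    or None if the curve never plateaus.
    """
    dh = np.abs(np.diff(curve.mean_H))
    below = dh < eps
    count = 0
    for k, b in enumerate(below):
        count = count + 1 if b else 0
        if count >= run:
            return int(curve.t[k + 1 - run])
    return None
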