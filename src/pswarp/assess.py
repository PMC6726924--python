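"""Interpretation of the decomposition: damage-mode counting, time-scale
labelling, SOC structure testing, failure-precursor detection and the
validation-only correlation against a simulator's hidden damage trajectory.

Mode counting formalizes "distinctly isolated from the continuum" as a gap
scan in log10(SOV): a gap is admissible when it exceeds
max(0.5 decades, 3 x median gap of the spectrum below it).  Everything above
the deepest admissible gap is dominant; further admissible gaps split the
dominant set into at most two reported groups (slower/ductile-like vs
faster/brittle-like, the larger-SOV group being the slower one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import AlignmentError, DomainError, InsufficientDataError
from .rng import stream

__all__ = [
    "ModeCount",
    "DamageAssessment",
    "count_damage_modes",
    "soc_structure_test",
    "label_timescales",
    "detect_precursor",
    "recover_damage_correlation",
    "GAP_DECADES",
    "GAP_MEDIAN_FACTOR",
]

GAP_DECADES = 0.5
GAP_MEDIAN_FACTOR = 3.0
#: a gap only separates modes from "the continuum" if a continuum exists:
#: at least this many SOVs must lie below an admissible gap
MIN_CONTINUUM = 3


@dataclass(frozen=True)
class ModeCount:
    n_modes: int
    mode_indices: tuple[int, ...]
    groups: tuple[tuple[int, ...], ...]  # partition of mode_indices, by SOV
    extra_groups_flagged: bool = False


@dataclass(frozen=True)
class DamageAssessment:
    n_modes: int
    mode_indices: tuple[int, ...]
    groups: tuple[tuple[int, ...], ...]
    timescale_labels: tuple[str, ...]  # per group
    structured_socs: tuple[int, ...]
    precursor: Optional[int]  # record index, or None


def count_damage_modes(sovs: Sequence[float], gap_decades: float = GAP_DECADES,
                       median_factor: float = GAP_MEDIAN_FACTOR) -> ModeCount:
    """Count SOVs isolated from the continuum via admissible log10 gaps.

    At most two groups are reported (slow/fast dichotomy); additional
    admissible splits inside the dominant set are flagged, not merged away
    silently.
    """
    sovs = np.asarray(sovs, dtype=float)
    if sovs.size < 4:
        raise InsufficientDataError("need at least 4 SOVs to define a continuum")
    if np.any(sovs <= 0):
        # regularized-to-zero trailing SOVs carry no isolation information
        positive = sovs[sovs > 0]
        floor = positive.min() * 1e-3 if positive.size else 1.0
        sovs = np.clip(sovs, floor, None)
    logs = np.log10(sovs)
    gaps = logs[:-1] - logs[1:]  # descending order -> gaps >= 0 generically

    def admissible(i: int) -> bool:
        tail = gaps[i + 1:]
        if tail.size < MIN_CONTINUUM - 1:  # too few SOVs below to call a continuum
            return False
        thresh = max(gap_decades, median_factor * np.median(tail))
        return gaps[i] > thresh

    adm = [i for i in range(gaps.size) if admissible(i)]
    if not adm:
        return ModeCount(n_modes=0, mode_indices=(), groups=())
    deepest = max(adm)
    dominant = list(range(deepest + 1))
    splits = [i for i in adm if i < deepest]
    groups: list[tuple[int, ...]] = []
    start = 0
    for s in splits:
        groups.append(tuple(range(start, s + 1)))
        start = s + 1
    groups.append(tuple(range(start, deepest + 1)))
    flagged = len(groups) > 2
    if flagged:
        warnings.warn(
            f"{len(groups)} SOV groups found; reporting the leading 2 "
            "(re-run with a stricter gap threshold to resolve)", stacklevel=2)
        groups = groups[:2]
        dominant = [i for g in groups for i in g]
    return ModeCount(n_modes=len(dominant), mode_indices=tuple(dominant),
                     groups=tuple(groups), extra_groups_flagged=flagged)


def soc_structure_test(soc: np.ndarray, n_surrogates: int = 999,
                       seed: int = 0) -> bool:
    """Permutation test for temporal structure in one SOC column.

    Structured iff the lag-1 autocorrelation exceeds the 95th percentile of
    ``n_surrogates`` seeded random permutations of the same values.  Constant
    columns are "noise" by convention.
    """
    soc = np.asarray(soc, dtype=float)
    if soc.size < 8:
        raise InsufficientDataError("SOC column must have length >= 8")

    def lag1(x: np.ndarray) -> float:
        a, b = x[:-1], x[1:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    observed = lag1(soc)
    if not np.isfinite(observed):
        return False
    rng = stream(seed, "surrogates")
    null = np.empty(n_surrogates)
    for i in range(n_surrogates):
        null[i] = lag1(rng.permutation(soc))
    return observed > np.percentile(null, 95.0)


def label_timescales(groups: Sequence[Sequence[int]], sovs: Sequence[float],
                     reference_sov: Optional[float] = None) -> tuple[str, ...]:
    """Label 1 or 2 SOV groups by time scale.

    With two groups the larger-SOV (slower) group is "ductile-like" and the
    smaller (faster) "brittle-like"; a single group is compared against
    ``reference_sov`` when given, otherwise "unlabeled-single-mode".
    """
    sovs = np.asarray(sovs, dtype=float)
    if not 1 <= len(groups) <= 2:
        raise DomainError(
            f"can label 1 or 2 groups, got {len(groups)}; re-run mode counting "
            "with a stricter gap threshold")
    means = [float(np.mean(np.log10(np.clip(sovs[list(g)], np.finfo(float).tiny,
                                            None)))) for g in groups]
    if len(groups) == 1:
        if reference_sov is None:
            return ("unlabeled-single-mode",)
        return ("ductile-like",) if means[0] > np.log10(reference_sov) \
            else ("brittle-like",)
    if means[0] == means[1]:
        raise DomainError("groups have equal mean log10 SOV: no admissible ordering")
    return ("ductile-like", "brittle-like") if means[0] > means[1] \
        else ("brittle-like", "ductile-like")


#: leading-half RMS floor, relative to max |SOC|
RMS_FLOOR = 1e-12


def detect_precursor(socs: np.ndarray, window_fraction: float = 0.1,
                     thresh: float = 3.0) -> Optional[int]:
    """Detect a terminal amplitude surge in the dominant SOCs.

    The record axis is tiled backwards from the end in blocks of
    ``round(window_fraction * m)`` records.  For each SOC column, blocks are
    walked from the last one towards the front while their RMS exceeds
    ``thresh`` times the column's first-half RMS (floored at
    ``1e-12 * max|SOC|``); detection reports the first record (0-based) of the
    earliest block in the contiguous exceeding run ending at the last block.
    Returns None when no column's final block exceeds.
    """
    socs = np.asarray(socs, dtype=float)
    if socs.ndim == 1:
        socs = socs[:, None]
    m = socs.shape[0]
    if m < 10:
        raise InsufficientDataError("need at least 10 records")
    w = max(1, int(round(window_fraction * m)))
    best: Optional[int] = None
    for col in socs.T:
        base = np.sqrt(np.mean(col[: m // 2] ** 2))
        floor = RMS_FLOOR * np.max(np.abs(col)) if np.any(col != 0) else RMS_FLOOR
        base = max(base, floor)
        end = m
        detected: Optional[int] = None
        while end > 0:
            start = max(0, end - w)
            rms = np.sqrt(np.mean(col[start:end] ** 2))
            if rms > thresh * base:
                detected = start
                end = start
            else:
                break
        if detected is not None and (best is None or detected < best):
            best = detected
    return best


def recover_damage_correlation(socs: np.ndarray, soc_times: np.ndarray,
                               damage: np.ndarray, damage_times: np.ndarray
                               ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """|Pearson r| between SOC columns and the hidden damage trajectories.

    Validation-only utility: damage is resampled (linear interpolation) at the
    record timestamps.  Returns the full |r| matrix (n_socs x n_damage) and
    the best one-to-one assignment [(soc_index, damage_index), ...] maximizing
    total |r|.
    """
    socs = np.asarray(socs, dtype=float)
    if socs.ndim == 1:
        socs = socs[:, None]
    damage = np.asarray(damage, dtype=float)
    if damage.ndim == 1:
        damage = damage[:, None]
    if damage.shape[0] != len(damage_times):
        raise AlignmentError("damage trajectory and damage_times lengths differ")
    if socs.shape[0] != len(soc_times):
        raise AlignmentError("SOC matrix and soc_times lengths differ")
    if soc_times[0] < damage_times[0] - 1e-9 or soc_times[-1] > damage_times[-1] + 1e-9:
        raise AlignmentError("record timestamps extend beyond the damage trajectory")
    resampled = np.column_stack([
        np.interp(soc_times, damage_times, damage[:, j])
        for j in range(damage.shape[1])
    ])
    n_s, n_d = socs.shape[1], resampled.shape[1]
    r = np.zeros((n_s, n_d))
    for i in range(n_s):
        for j in range(n_d):
            a, b = socs[:, i], resampled[:, j]
            if a.std() == 0 or b.std() == 0:
                r[i, j] = 0.0
            else:
                r[i, j] = abs(np.corrcoef(a, b)[0, 1])
    rows, cols = linear_sum_assignment(-r)
    return r, list(zip(rows.tolist(), cols.tolist()))
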