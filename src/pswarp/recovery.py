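"""Parameter-recovery studies against the simulator's hidden damage truth.

Each trial runs the full measurement-only pipeline on one seeded simulation
and then — and only then — compares the recovered smooth coordinates with the
hidden damage trajectories.  These are the desk-scale analogues of the
bone-experiment results: mode counting, per-mechanism recovery, time-scale
ordering and failure-precursor detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import moonbeam
from .assess import recover_damage_correlation
from .embed import TimeSeries
from .pipeline import analyze_series, recovery_pipeline_config

__all__ = [
    "SingleModeTrial",
    "TwoModeTrial",
    "FailureTrial",
    "run_single_mode_trial",
    "run_two_mode_trial",
    "run_failure_trial",
    "run_stationary_trial",
]


def _analyze(cfg: moonbeam.SimConfig, seed: int):
    out = moonbeam.simulate(cfg)
    series = TimeSeries(out.measurement, cfg.sample_rate)
    pcfg = recovery_pipeline_config(cfg, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = analyze_series(series, pcfg, out)
    return out, res


@dataclass(frozen=True)
class SingleModeTrial:
    n_modes: int
    leading_r: float


def run_single_mode_trial(seed: int) -> SingleModeTrial:
    cfg = moonbeam.default_single_mode_config(seed=seed, accelerated=True)
    out, res = _analyze(cfg, seed)
    r, _ = recover_damage_correlation(
        res.decomposition.socs[:, :1], res.record_times,
        out.damage[::50], out.times[::50])
    return SingleModeTrial(n_modes=res.mode_count.n_modes,
                           leading_r=float(r[0, 0]))


@dataclass(frozen=True)
class TwoModeTrial:
    n_groups: int
    r_ductile: float
    r_brittle: float
    sov_ductile: float
    sov_brittle: float

    @property
    def ordering_ok(self) -> bool:
        """Slower (ductile) mode's SOV exceeds the faster (brittle) one's."""
        return self.sov_ductile > self.sov_brittle


def run_two_mode_trial(seed: int) -> TwoModeTrial:
    cfg = moonbeam.default_two_mode_config(seed=seed, accelerated=True)
    out, res = _analyze(cfg, seed)
    dec = res.decomposition
    r, assignment = recover_damage_correlation(
        dec.socs[:, :4], res.record_times, out.damage[::50], out.times[::50])
    by_damage = {dmg: soc for soc, dmg in assignment}
    i_d, i_b = by_damage.get(0, 0), by_damage.get(1, 1)
    return TwoModeTrial(
        n_groups=len(res.mode_count.groups),
        r_ductile=float(r[i_d, 0]), r_brittle=float(r[i_b, 1]),
        sov_ductile=float(dec.sovs[i_d]), sov_brittle=float(dec.sovs[i_b]),
    )


@dataclass(frozen=True)
class FailureTrial:
    failed_at: Optional[float]
    n_records: int
    precursor: Optional[int]

    @property
    def detected_in_final_fifth(self) -> bool:
        return (self.precursor is not None
                and self.precursor >= 0.8 * self.n_records)


def run_failure_trial(seed: int) -> FailureTrial:
    cfg = moonbeam.default_run_to_failure_config(seed=seed)
    out, res = _analyze(cfg, seed)
    return FailureTrial(failed_at=out.failed_at,
                        n_records=res.tracking.n_records,
                        precursor=res.assessment.precursor)


def run_stationary_trial(seed: int, duration: float = 500.0) -> Optional[int]:
    """Precursor result for an eps = 0 run (false-alarm calibration)."""
    cfg = moonbeam.default_stationary_config(seed=seed, duration=duration)
    _, res = _analyze(cfg, seed)
    return res.assessment.precursor
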