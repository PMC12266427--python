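"""Ensemble orchestration and theory-vs-simulation comparison.

Replicates are conditioned on survival (extinct attempts are discarded and
tallied, not counted towards R), each replicate draws from a substream
derived deterministically from the master seed and its index, and per-bin
means and standard errors are computed with zero-fill over the union of
supports — so a whole ensemble is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .histograms import ExpectedCurve, IntHistogram
from .simulator import RunResult, SimulationConfig, run
from .summaries import dd_from_state, mbd_from_state, mutational_occurrences, sfs_from_state

logger = logging.getLogger("mutburden")

__all__ = ["EnsembleResult", "run_ensemble", "compare_to_theory", "TheoryComparison"]


@dataclass
class EnsembleResult:
    """Per-replicate histograms plus per-bin ensemble mean and SE."""

    config: SimulationConfig
    master_seed: int
    replicates: dict[str, list[IntHistogram]]
    discarded: int
    final_sizes: list[int]
    final_steps: list[int]
    se_defined: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def R(self) -> int:
        return len(self.final_sizes)

    @property
    def attempts(self) -> int:
        return self.R + self.discarded

    @property
    def discarded_fraction(self) -> float:
        return self.discarded / self.attempts

    def stats(self) -> tuple[str, ...]:
        return tuple(self.replicates)

    def mean_curve(self, stat: str) -> tuple[np.ndarray, np.ndarray]:
        """(per-bin mean, per-bin SE) as dense arrays from index 0.

        SE is the across-replicate sample SD / sqrt(R), zero-filled for
        replicates missing a bin; with R = 1 the SE is reported as 0 and
        ``se_defined`` is False.
        """
        if stat in self._cache:
            return self._cache[stat]
        hists = self.replicates[stat]
        width = max(h.max_index() for h in hists) + 1
        data = np.stack([h.to_array(width) for h in hists])
        mean = data.mean(axis=0)
        if self.R > 1:
            se = data.std(axis=0, ddof=1) / np.sqrt(self.R)
        else:
            se = np.zeros(width)
        self._cache[stat] = (mean, se)
        return mean, se

    def mean_histogram(self, stat: str) -> ExpectedCurve:
        mean, _ = self.mean_curve(stat)
        return ExpectedCurve(
            mean, start=0, provenance="simulation",
            params={
                "beta": self.config.beta, "delta": self.config.delta,
                "mu": self.config.mu, "R": self.R,
                "stop": self.config.stop,
            },
            role=stat if stat in ("sfs", "dd", "mbd") else None,
        )


def run_ensemble(
    config: SimulationConfig,
    R: int,
    master_seed: int,
    stats: tuple[str, ...] | None = None,
    check_identity: bool = True,
) -> EnsembleResult:
    """R surviving replicates of ``config``; deterministic in master_seed.

    ``stats`` defaults to ("sfs", "dd", "mbd") for full-tracking configs
    and ("dd", "mbd") for compact ones (the SFS needs mutation ids).  When
    the SFS is collected the occurrences identity sum_j j S_j = sum_k k B_k
    is asserted on every replicate.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if stats is None:
        stats = ("sfs", "dd", "mbd") if config.track_matrix else ("dd", "mbd")
    if "sfs" in stats and not config.track_matrix:
        raise ValueError("SFS collection requires track_matrix=True")
    replicates: dict[str, list[IntHistogram]] = {s: [] for s in stats}
    discarded = 0
    sizes: list[int] = []
    steps: list[int] = []
    for r in range(R):
        rng = np.random.default_rng([master_seed, r])
        result: RunResult = run(config, rng=rng)
        discarded += result.discarded
        state = result.state
        sizes.append(state.size)
        steps.append(state.step_count)
        if "sfs" in stats:
            replicates["sfs"].append(sfs_from_state(state))
            if check_identity:
                mutational_occurrences(state)  # raises on violation
        if "dd" in stats:
            replicates["dd"].append(dd_from_state(state))
        if "mbd" in stats:
            replicates["mbd"].append(mbd_from_state(state))
    if R == 1:
        logger.info("single-replicate ensemble: SE reported as 0")
    logger.info(
        "ensemble done: R=%d discarded=%d (fraction %.3f)",
        R, discarded, discarded / (R + discarded) if R + discarded else 0.0,
    )
    return EnsembleResult(
        config=config, master_seed=master_seed, replicates=replicates,
        discarded=discarded, final_sizes=sizes, final_steps=steps,
        se_defined=R > 1,
    )


@dataclass
class TheoryComparison:
    """Bin-wise z-scores of an ensemble mean against an expected curve."""

    stat: str
    z: dict[int, float]
    compared_bins: tuple[int, ...]
    fraction_within: float
    max_abs_z: float
    passed: bool
    z_threshold: float
    expected_floor: float


_PARAM_KEYS = ("beta", "delta", "mu")


def compare_to_theory(
    ensemble: EnsembleResult,
    theory: ExpectedCurve,
    stat: str,
    z_threshold: float = 3.0,
    expected_floor: float = 5.0,
    check_params: bool = True,
) -> TheoryComparison:
    """Per-bin z of the ensemble mean vs a theoretical expected curve.

    Only bins where the theory predicts at least ``expected_floor`` counts
    enter the pass/fail verdict (smaller bins are Poisson-noisy and the
    normal z approximation fails); the verdict requires every compared bin
    within ``z_threshold``.  Parameterisation (beta, delta, mu where
    present) is cross-checked between the ensemble config and the curve.
    """
    if stat not in ensemble.replicates:
        raise ValueError(f"ensemble carries no {stat!r} histograms")
    if check_params:
        for key in _PARAM_KEYS:
            if key not in theory.params:
                continue
            have = getattr(ensemble.config, key)
            want = theory.params[key]
            if want is not None and abs(have - want) > 1e-12:
                raise ValueError(
                    f"parameter mismatch on {key}: ensemble {have} vs "
                    f"theory {want}"
                )
    mean, se = ensemble.mean_curve(stat)
    width = max(len(mean), int(theory.start + len(theory.values)))
    mean = np.concatenate([mean, np.zeros(width - len(mean))])
    se = np.concatenate([se, np.zeros(width - len(se))])
    expect = theory.to_array(width)
    z: dict[int, float] = {}
    compared: list[int] = []
    start = 1 if stat == "sfs" else 0
    for k in range(start, width):
        diff = mean[k] - expect[k]
        if se[k] > 0:
            z[k] = diff / se[k]
        else:
            z[k] = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        if expect[k] >= expected_floor:
            compared.append(k)
    if compared:
        within = float(
            sum(bool(abs(z[k]) < z_threshold) for k in compared) / len(compared)
        )
        max_abs = max(abs(z[k]) for k in compared)
    else:
        within, max_abs = 1.0, 0.0
    return TheoryComparison(
        stat=stat, z=z, compared_bins=tuple(compared),
        fraction_within=within, max_abs_z=float(max_abs),
        passed=bool(within == 1.0), z_threshold=z_threshold,
        expected_floor=expected_floor,
    )
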