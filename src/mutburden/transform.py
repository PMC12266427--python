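"""Conversions between the division distribution and the burden distribution.

A cell with l divisions in its history has accumulated a sum of l i.i.d.
mutation counts, which for Poisson(mu) draws is Poisson(l mu); so an
expected MBD is the DD pushed through a Poisson mixture,

    B(k) = sum_l D(l) e^{-l mu} (l mu)^k / k!        (forward map)

and only the mean mu of the per-division mutation distribution enters.
The approximate inverse assigns each burden k to the division class whose
mean l mu is nearest (l = round(k / mu), ties to even) — the
maximum-likelihood class when the component means are well separated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .histograms import ExpectedCurve, IntHistogram, as_weight_map
from .theory import _poisson_mixture

__all__ = ["dd_to_mbd", "mbd_to_dd", "compare_mbd_sources", "MbdComparison"]


def dd_to_mbd(
    dd: IntHistogram | ExpectedCurve | dict,
    mu: float,
    k_max: int | None = None,
) -> ExpectedCurve:
    """Forward map: Poisson-mixture conversion of a DD into an expected MBD.

    Total output mass equals the DD's total mass up to a truncation defect
    below 1e-8, and the exact (pre-truncation) mean is mu times the DD
    mean.  Linear in the DD, so it applies equally to one realisation, an
    ensemble mean, or a theoretical expected DD.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    weights = as_weight_map(dd)
    if any(w < 0 for w in weights.values()):
        raise ValueError("DD weights must be >= 0")
    if not weights:
        return ExpectedCurve(np.zeros(1), start=0, provenance="conversion",
                             params={"mu": mu}, role="mbd")
    ells = np.array(sorted(weights), dtype=float)
    w = np.array([weights[int(l)] for l in ells])
    if mu == 0.0:
        vals = np.array([w.sum()])
    else:
        vals = _poisson_mixture(w, ells * mu, k_max=k_max)
    total_in = float(w.sum())
    defect = total_in - float(vals.sum())
    if k_max is None and defect > 1e-8 * max(total_in, 1.0):
        raise ArithmeticError(f"truncation mass defect {defect:.3e} too large")
    return ExpectedCurve(
        vals, start=0, provenance="conversion",
        params={"mu": mu, "mass_defect": defect}, role="mbd",
    )


def mbd_to_dd(mbd: IntHistogram | dict, mu: float) -> IntHistogram:
    """Approximate inverse: bin burdens to the nearest multiple of mu.

    Each burden k goes to division class l = round(k / mu) (half-integer
    boundaries, ties to even); total mass is conserved exactly.  Faithful
    when mu is large compared to the spread of each Poisson component.
    """
    if mu <= 0:
        raise ValueError("mbd_to_dd needs mu > 0 (mu = 0 is non-invertible)")
    if isinstance(mbd, IntHistogram):
        items = mbd.counts.items()
    else:
        items = mbd.items()
    out: Counter = Counter()
    for k, c in items:
        if c:
            out[round(k / mu)] += c
    return IntHistogram(out, role="dd")


@dataclass
class MbdComparison:
    """Per-bin z comparison of a simulated mean MBD with a converted one."""

    z: dict[int, float]
    max_abs_z: float
    total_variation: float
    passed: bool
    degenerate_bins: tuple[int, ...]
    z_threshold: float


def compare_mbd_sources(
    simulated_mean: IntHistogram | ExpectedCurve | dict,
    converted: IntHistogram | ExpectedCurve | dict,
    se_per_bin: dict[int, float] | np.ndarray | None,
    z_threshold: float = 3.0,
    expected_floor: float = 0.0,
) -> MbdComparison:
    """Score a simulated ensemble-mean MBD against a DD->MBD conversion.

    Reports per-bin z = (sim - conv)/SE over the union of supports
    (zero-filled), the max |z|, the total-variation distance
    0.5 sum |diff|, and a pass flag at ``z_threshold``.  The verdict (and
    max |z|) covers bins where the converted curve predicts at least
    ``expected_floor`` counts — far-tail bins hold a handful of Poisson
    counts at best and the normal z approximation fails there.  Bins with
    zero SE but nonzero discrepancy above the floor are flagged degenerate
    and fail the check.
    """
    a = as_weight_map(simulated_mean)
    b = as_weight_map(converted)
    keys = sorted(set(a) | set(b))
    if se_per_bin is None:
        se = {}
    elif isinstance(se_per_bin, dict):
        se = {int(k): float(v) for k, v in se_per_bin.items()}
    else:
        se = {k: float(se_per_bin[k]) for k in range(len(se_per_bin))}
    z: dict[int, float] = {}
    degenerate: list[int] = []
    tv = 0.0
    max_abs = 0.0
    for k in keys:
        diff = a.get(k, 0.0) - b.get(k, 0.0)
        tv += abs(diff)
        s = se.get(k, 0.0)
        if s > 0:
            z[k] = diff / s
        elif diff == 0.0:
            z[k] = 0.0
        else:
            z[k] = np.inf if diff > 0 else -np.inf
        if b.get(k, 0.0) >= expected_floor or expected_floor <= 0.0:
            if not np.isfinite(z[k]):
                degenerate.append(k)
            max_abs = max(max_abs, abs(z[k]))
    tv *= 0.5
    passed = not degenerate and max_abs < z_threshold
    return MbdComparison(
        z=z, max_abs_z=float(max_abs), total_variation=float(tv),
        passed=passed, degenerate_bins=tuple(degenerate),
        z_threshold=z_threshold,
    )
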