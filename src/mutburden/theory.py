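"""Exact and approximate expected distributions for the branching process.

Pure-birth (Yule, delta = 0) results are exact:

* SFS: E[S_{j,i}] obeys the one-step recurrence
  E[S_{j,i+1}] = E[S_{j,i}](1 - j/(i+1)) + (j-1) E[S_{j-1,i}]/(i+1)
               + 2 mu [j = 1],
  whose solution in the region j <= i is the classic 2 mu (i+1)/(j(j+1)).
* DD: E[D_{l,i}] = [i l] 2^l / i!, with [i l] the unsigned Stirling
  numbers of the first kind — leaf-depth counts of random binary
  increasing trees.
* MBD: the DD pushed through a Poisson mixture,
  E[B_{k,i}] = sum_l E[D_{l,i}] e^{-l mu} (l mu)^k / k!.

With death (0 < delta < beta) the population size becomes random and the
results are first-order approximations valid for low death and large
populations: the SFS gains a geometric series in delta/beta, and the DD is
the normalised partition f(i,l) = [i l] 2^l (1 - delta/beta)^{-l} of the
expected population size.  E[N_i | survival] itself is computed exactly by
propagating the finite birth-death Markov chain with absorbing state 0.

Everything assumes a single mutation-free progenitor (N0 = 1); functions
refuse other initial conditions rather than silently mis-applying.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .histograms import ExpectedCurve

__all__ = [
    "StirlingTable",
    "stirling",
    "log_stirling",
    "log_stirling_row",
    "expected_sfs_pure_birth",
    "iterate_sfs_recurrence",
    "expected_sfs_birth_death",
    "expected_dd_pure_birth",
    "dd_curve_pure_birth",
    "iterate_dd_recurrence",
    "expected_dd_birth_death",
    "expected_mbd_pure_birth",
    "expected_population_conditioned",
    "expected_mean_burden",
    "expected_mean_divisions",
    "harmonic",
]

LOG2 = math.log(2.0)


def _check_growing(beta: float, delta: float) -> None:
    if not (0 <= delta < beta):
        raise ValueError("require beta > delta >= 0 (growing population)")


def harmonic(n: int) -> float:
    """H_n = sum_{k=1}^n 1/k."""
    if n < 0:
        raise ValueError("harmonic number needs n >= 0")
    if n < 10_000:
        return float(sum(1.0 / k for k in range(1, n + 1)))
    # asymptotic expansion, good to ~1e-16 here
    g = 0.5772156649015328606
    return float(math.log(n) + g + 1 / (2 * n) - 1 / (12 * n**2))


# -- Stirling numbers ------------------------------------------------------


@dataclass
class StirlingTable:
    """Unsigned Stirling numbers of the first kind [i l].

    Defined by [i+1 l] = i [i l] + [i l-1] with [1 1] = 1 and [i l] = 0
    for l > i or l = 0.  Exact big-integer rows are built lazily up to
    ``exact_limit``; beyond that only the log-space recurrence is offered,
    since [i l] 2^l / i! is hopeless in direct floating point.
    """

    exact_limit: int = 300
    _rows: list[list[int]] = field(default_factory=lambda: [[1], [0, 1]])

    def _extend_exact(self, i: int) -> None:
        while len(self._rows) <= i:
            n = len(self._rows) - 1  # last completed row index
            prev = self._rows[-1]
            new = [0] * (n + 2)
            for ell in range(1, n + 2):
                new[ell] = n * prev[ell] if ell <= n else 0
                if ell - 1 <= n:
                    new[ell] += prev[ell - 1]
            self._rows.append(new)

    def exact(self, i: int, ell: int) -> int:
        if i < 1:
            raise ValueError("Stirling numbers need i >= 1")
        if ell < 0:
            raise ValueError("Stirling numbers need l >= 0")
        if ell == 0 or ell > i:
            return 0
        if i > self.exact_limit:
            raise ValueError(
                f"exact Stirling numbers limited to i <= {self.exact_limit}; "
                "use log_stirling for larger i"
            )
        self._extend_exact(i)
        return self._rows[i][ell]

    def exact_row(self, i: int) -> list[int]:
        """[i 0], ..., [i i] as exact integers."""
        self.exact(i, 1)
        return list(self._rows[i])

    @staticmethod
    def log_row(i: int) -> np.ndarray:
        """log [i l] for l = 0..i, with -inf at l = 0; O(i^2) time, O(i) memory."""
        if i < 1:
            raise ValueError("Stirling numbers need i >= 1")
        row = np.array([-np.inf, 0.0])  # i = 1
        for n in range(1, i):
            new = np.full(n + 2, -np.inf)
            # [n+1 l] = n [n l] + [n l-1]
            new[: n + 1] = math.log(n) + row
            new[1:] = np.logaddexp(new[1:], row)
            row = new
        return row

    def log(self, i: int, ell: int) -> float:
        if ell == 0 or ell > i:
            return -math.inf
        if i <= self.exact_limit:
            v = self.exact(i, ell)
            return float(_log_int(v))
        return float(self.log_row(i)[ell])


def _log_int(v: int) -> float:
    """log of a (possibly huge) positive Python int."""
    if v == 0:
        return -math.inf
    if v.bit_length() <= 900:
        return math.log(v)
    k = v.bit_length() - 900
    return math.log(v >> k) + k * math.log(2.0)


_TABLE = StirlingTable()


def stirling(i: int, ell: int) -> int:
    """Exact unsigned Stirling number of the first kind [i l]."""
    return _TABLE.exact(i, ell)


def log_stirling(i: int, ell: int) -> float:
    """log [i l]; exact route for small i, log-space recurrence beyond."""
    if i < 1:
        raise ValueError("Stirling numbers need i >= 1")
    if ell < 0:
        raise ValueError("Stirling numbers need l >= 0")
    return _TABLE.log(i, ell)


def log_stirling_row(i: int) -> np.ndarray:
    """log [i l] for l = 0..i (vectorised row)."""
    if i <= _TABLE.exact_limit:
        return np.array([_log_int(v) for v in _TABLE.exact_row(i)])
    return StirlingTable.log_row(i)


# -- site frequency spectrum ----------------------------------------------


def expected_sfs_pure_birth(mu: float, i: int, j: int) -> float:
    """Closed-form pure-birth E[S_{j,i}] = 2 mu (i+1) / (j (j+1)).

    Exact for 1 <= j <= i (checked against the recurrence); for j > i the
    true expectation is 0 while this form stays positive, so the
    recurrence iterator is authoritative there.
    """
    if j < 1:
        raise ValueError("abundance j must be >= 1")
    if i < 0:
        raise ValueError("step count i must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return 2.0 * mu * (i + 1) / (j * (j + 1))


def sfs_curve_pure_birth(mu: float, i: int, j_max: int | None = None) -> ExpectedCurve:
    """Closed-form SFS over j = 1..j_max (default j_max = i)."""
    j_max = i if j_max is None else j_max
    j = np.arange(1, j_max + 1)
    vals = 2.0 * mu * (i + 1) / (j * (j + 1.0))
    return ExpectedCurve(
        vals, start=1, provenance="closed_form",
        params={"mu": mu, "beta": 1.0, "delta": 0.0, "i": i}, role="sfs",
    )


def iterate_sfs_recurrence(mu: float, i_max: int) -> list[ExpectedCurve]:
    """Iterate the exact pure-birth one-step SFS recurrence.

    Returns curves for i = 0..i_max over j = 1..i_max+1, starting from the
    all-zero spectrum at i = 0.  Pure birth only: with death the
    recurrence involves E[S/N] and is not exactly iterable.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    width = i_max + 2  # j = 0..i_max+1; j = 0 kept as a zero guard cell
    s = np.zeros(width)
    out = []
    j = np.arange(width)

    def snapshot(i):
        return ExpectedCurve(
            s[1:].copy(), start=1, provenance="recurrence",
            params={"mu": mu, "beta": 1.0, "delta": 0.0, "i": i}, role="sfs",
        )

    out.append(snapshot(0))
    for i in range(i_max):
        new = s - j * s / (i + 1)
        new[1:] += (j[1:] - 1) * s[:-1] / (i + 1)
        new[1] += 2.0 * mu
        s = new
        out.append(snapshot(i + 1))
    return out


def expected_sfs_birth_death(
    mu: float,
    beta: float,
    delta: float,
    i: int | None = None,
    expected_n: float | None = None,
    j_max: int = 100,
    tol: float = 1e-12,
    linear_popsize: bool = False,
) -> ExpectedCurve:
    """First-order birth-death SFS over j = 1..j_max.

    E[S_{j,i}] ~= sum_{j'>=0} 2 mu (delta/beta)^{j'} /
    ((j+j')(j+j'+1)) * E[N_i], the series truncated when a term drops
    below tol times the running sum.  E[N_i] is the survival-conditioned
    chain expectation by default (or (beta-delta) i + 1 with
    ``linear_popsize``); pass ``expected_n`` directly for size-stopped
    ensembles where N at observation is fixed.
    """
    _check_growing(beta, delta)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if expected_n is None:
        if i is None:
            raise ValueError("need the step count i or an explicit expected_n")
        if linear_popsize:
            expected_n = (beta - delta) * i + 1.0
        else:
            expected_n = float(
                expected_population_conditioned(beta, delta, i).values[i]
            )
    r = delta / beta
    vals = np.empty(j_max)
    for jj in range(1, j_max + 1):
        total = 0.0
        jp = 0
        while True:
            term = 2.0 * mu * r**jp / ((jj + jp) * (jj + jp + 1))
            total += term
            jp += 1
            if r == 0.0 or term < tol * total:
                break
        vals[jj - 1] = total * expected_n
    return ExpectedCurve(
        vals, start=1, provenance="approximation",
        params={"mu": mu, "beta": beta, "delta": delta, "i": i,
                "expected_n": expected_n},
        role="sfs",
    )


# -- division distribution -------------------------------------------------


def expected_dd_pure_birth(i: int, ell: int) -> float:
    """Pure-birth E[D_{l,i}] = [i l] 2^l / i!, assembled in log space."""
    if i < 1:
        raise ValueError("i must be >= 1 (at i = 0 the DD is {0: 1})")
    if ell < 0:
        raise ValueError("l must be >= 0")
    if ell == 0 or ell > i:
        return 0.0
    return math.exp(log_stirling(i, ell) + ell * LOG2 - gammaln(i + 1))


def dd_curve_pure_birth(i: int) -> ExpectedCurve:
    """Pure-birth expected DD over l = 0..i; total mass i + 1."""
    if i < 0:
        raise ValueError("i must be >= 0")
    if i == 0:
        vals = np.array([1.0])
    else:
        logrow = log_stirling_row(i)
        ell = np.arange(i + 1)
        with np.errstate(invalid="ignore"):
            vals = np.exp(logrow + ell * LOG2 - gammaln(i + 1))
        vals[0] = 0.0
    return ExpectedCurve(
        vals, start=0, provenance="closed_form",
        params={"beta": 1.0, "delta": 0.0, "i": i}, role="dd",
    )


def iterate_dd_recurrence(i_max: int) -> list[ExpectedCurve]:
    """Iterate the exact pure-birth one-step DD recurrence.

    E[D_{l,i+1}] = E[D_{l,i}] (1 - 1/(i+1)) + 2 E[D_{l-1,i}]/(i+1),
    from E[D_{0,0}] = 1.  Equals the Stirling closed form for every
    l <= i (checked in the tests) and conserves total mass i + 1.
    """
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    d = np.zeros(i_max + 1)
    d[0] = 1.0
    out = []

    def snapshot(i):
        return ExpectedCurve(
            d[: i + 1].copy(), start=0, provenance="recurrence",
            params={"beta": 1.0, "delta": 0.0, "i": i}, role="dd",
        )

    out.append(snapshot(0))
    for i in range(i_max):
        new = d * (1.0 - 1.0 / (i + 1))
        new[1:] += 2.0 * d[:-1] / (i + 1)
        d = new
        out.append(snapshot(i + 1))
    return out


def expected_dd_birth_death(
    i: int,
    beta: float,
    delta: float,
    expected_n: float | None = None,
    linear_popsize: bool = False,
) -> ExpectedCurve:
    """First-order birth-death expected DD over l = 0..i.

    E[D_{l,i}] ~= f(i,l) / sum_l' f(i,l') * E[N_i] with
    f(i,l) = [i l] 2^l (1 - delta/beta)^{-l}; the normalisation is done by
    log-sum-exp.  At delta = 0 this reduces exactly to [i l] 2^l / i!.
    """
    _check_growing(beta, delta)
    if i < 1:
        raise ValueError("i must be >= 1")
    if expected_n is None:
        if linear_popsize:
            expected_n = (beta - delta) * i + 1.0
        else:
            expected_n = float(
                expected_population_conditioned(beta, delta, i).values[i]
            )
    logrow = log_stirling_row(i)
    ell = np.arange(i + 1)
    logf = logrow + ell * (LOG2 - math.log1p(-delta / beta))
    logf[0] = -np.inf
    frac = np.exp(logf - logsumexp(logf[1:]))
    frac[0] = 0.0
    return ExpectedCurve(
        frac * expected_n, start=0, provenance="approximation",
        params={"beta": beta, "delta": delta, "i": i, "expected_n": expected_n},
        role="dd",
    )


# -- mutational burden distribution ---------------------------------------


def _poisson_mixture(
    weights: np.ndarray, means: np.ndarray, k_max: int | None = None,
) -> np.ndarray:
    """sum_l w_l Pois(means_l) pmf over k = 0..k_max, in log space per term."""
    keep = weights > 0
    w = weights[keep]
    lam = means[keep]
    if len(w) == 0:
        return np.zeros(1)
    if k_max is None:
        top = lam[np.argmax(w * (lam + 1))]  # heaviest effective component
        lam_max = lam.max()
        k_max = int(max(lam_max + 10.0 * math.sqrt(lam_max + 1.0), top + 10, 20))
    k = np.arange(k_max + 1)
    out = np.zeros(k_max + 1)
    logw = np.log(w)
    lgk = gammaln(k + 1.0)
    for lw, lm in zip(logw, lam):
        if lm == 0.0:
            out[0] += math.exp(lw)
            continue
        out += np.exp(lw - lm + k * math.log(lm) - lgk)
    return out


def expected_mbd_pure_birth(
    mu: float, i: int, k: int | None = None, k_max: int | None = None,
) -> float | ExpectedCurve:
    """Pure-birth expected MBD: the expected DD mixed with Poisson(l mu).

    E[B_{k,i}] = sum_l [i l] 2^l / i! * e^{-l mu} (l mu)^k / k!.  With
    ``k`` returns that single value; otherwise the whole curve over
    k = 0..k_max (auto-truncated at mean + 10 sd of the largest
    component, mass defect < 1e-8).
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if i < 1:
        raise ValueError("i must be >= 1")
    dd = dd_curve_pure_birth(i)
    ell = np.arange(i + 1, dtype=float)
    if k is not None:
        if k < 0:
            raise ValueError("burden k must be >= 0")
        vals = _poisson_mixture(dd.values, ell * mu, k_max=k)
        return float(vals[k])
    vals = _poisson_mixture(dd.values, ell * mu, k_max=k_max)
    return ExpectedCurve(
        vals, start=0, provenance="closed_form",
        params={"mu": mu, "beta": 1.0, "delta": 0.0, "i": i}, role="mbd",
    )


# -- population size and mean burden --------------------------------------


def expected_population_conditioned(
    beta: float, delta: float, i_max: int, cap: int | None = None,
) -> ExpectedCurve:
    """Exact E[N_i | N_i > 0, N_0 = 1] by propagating the finite chain.

    The chain moves n -> n+1 with probability beta and n -> n-1 with
    probability delta, with 0 absorbing; the state space is truncated at
    ``cap`` (default 20 (beta-delta) i_max + 50) and the boundary mass is
    checked.  ``params['linear']`` carries the low-death approximation
    (beta-delta) i + 1 for comparison.
    """
    _check_growing(beta, delta)
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    if delta == 0.0:
        vals = np.arange(1, i_max + 2, dtype=float)
        return ExpectedCurve(
            vals, start=0, provenance="closed_form",
            params={"beta": beta, "delta": delta,
                    "linear": vals.copy(), "survival": np.ones(i_max + 1)},
            role=None,
        )
    if cap is None:
        cap = int(20 * (beta - delta) * i_max + 50)
    cap = max(cap, i_max // 4 + 10)
    p = np.zeros(cap + 1)
    p[1] = 1.0
    n = np.arange(cap + 1, dtype=float)
    expect = np.empty(i_max + 1)
    surv = np.empty(i_max + 1)
    for i in range(i_max + 1):
        alive = 1.0 - p[0]
        surv[i] = alive
        expect[i] = float((n * p).sum() / alive)
        if i == i_max:
            break
        new = np.zeros_like(p)
        new[0] = p[0] + delta * p[1]
        new[2:] += beta * p[1:-1]
        new[1:-1] += delta * p[2:]
        # reflecting guard at the cap would bias the mean; just park mass
        new[cap] += beta * p[cap]
        p = new
    if beta * p[cap] > 1e-10:
        raise ValueError(
            f"state-space cap {cap} too small: boundary mass "
            f"{beta * p[cap]:.2e}"
        )
    linear = (beta - delta) * np.arange(i_max + 1) + 1.0
    return ExpectedCurve(
        expect, start=0, provenance="recurrence",
        params={"beta": beta, "delta": delta, "linear": linear,
                "survival": surv},
        role=None,
    )


def expected_mean_divisions(i: int) -> float:
    """Pure-birth mean of the DD: 2 (H_{i+1} - 1)."""
    if i < 0:
        raise ValueError("i must be >= 0")
    return 2.0 * (harmonic(i + 1) - 1.0)


def expected_mean_burden(mu: float, i: int, delta: float = 0.0) -> float:
    """Pure-birth mean single-cell burden: mu * 2 (H_{i+1} - 1).

    Grows logarithmically in i (a rescaled harmonic number).  Refuses
    delta > 0: no closed form is implemented for the birth-death mean;
    use simulation there.
    """
    if delta != 0.0:
        raise ValueError(
            "closed-form mean burden is pure-birth only; simulate for delta > 0"
        )
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return mu * expected_mean_divisions(i)


def iterate_occurrences_recurrence(i_max: int) -> np.ndarray:
    """Expected total divisions-in-history T_i under pure birth.

    E[T_{i+1}] = E[T_i](1 + 1/(i+1)) + 2, T_0 = 0; dividing by N_i = i+1
    gives the DD mean, the oracle behind ``expected_mean_divisions``.
    """
    t = np.zeros(i_max + 1)
    for i in range(i_max):
        t[i + 1] = t[i] * (1.0 + 1.0 / (i + 1)) + 2.0
    return t
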