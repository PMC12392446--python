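"""Free-energy estimators and thermodynamic-cycle composition.

The multistate Bennett acceptance ratio (MBAR) estimator solves the
self-consistent equations

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

for the reduced free energies f of K thermodynamic states, given all sampled
configurations evaluated under all K reduced potentials u_k = U_k / k_B T.
The gauge f_1 = 0 is fixed. Iteration uses log-sum-exp stabilization.

The Bennett acceptance ratio (BAR) handles the two-state case from forward
and backward nonequilibrium work sets (a switch in either direction is a
sample of the work distribution; Crooks' theorem links the two), and the
Jarzynski identity estimates the free energy from forward work alone.

Statistical errors come from bootstrap resampling (per-state for MBAR, per
work value for BAR/Jarzynski) rather than asymptotic covariance formulas,
which tend to be optimistic for correlated samples.

The binding free energy is composed through the thermodynamic cycle

    dG_bind^MM    = dG_complex^MM - dG_solv^MM
    dG_bind^ML/MM = dG_complex^MM + dG_PL+S^ML/MM - dG_solv^MM - dG_L+S^ML/MM

where the two ML/MM terms are the MM -> ML/MM potential-switching
corrections at the physical end states; errors add in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import BOLTZMANN_CONSTANT

__all__ = [
    "ReducedEnergyMatrix",
    "FreeEnergyResult",
    "CycleComponents",
    "MBAR",
    "BAR",
    "mbar_solve",
    "bar_from_work",
    "jarzynski",
    "combine_cycle",
    "overlap_matrix",
]


@dataclass
class ReducedEnergyMatrix:
    """u[k, n]: reduced energy of sample n evaluated in state k."""

    u: np.ndarray
    counts: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.u.ndim != 2 or self.counts.sum() != self.u.shape[1]:
            raise ValueError("counts must sum to the number of samples")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("non-finite reduced energies")

    @property
    def kt(self) -> float:
        return BOLTZMANN_CONSTANT * self.temperature


@dataclass
class FreeEnergyResult:
    """Per-state reduced free energies and a requested kJ/mol difference."""

    f: np.ndarray              # reduced free energies, f[0] = 0
    delta_g: float             # kJ/mol between requested states
    stat_error: float          # kJ/mol, bootstrap
    method: str
    temperature: float = 300.0
    n_bootstrap: int = 0

    def summary(self) -> str:
        lines = [f"free-energy estimate ({self.method})",
                 "=" * 40,
                 f"T = {self.temperature:.1f} K",
                 "state   f (reduced)"]
        for i, fi in enumerate(np.atleast_1d(self.f)):
            lines.append(f"{i:>5}   {fi:+.6f}")
        lines.append("-" * 40)
        lines.append(f"dG = {self.delta_g:+.3f} +/- {self.stat_error:.3f} kJ/mol"
                     f" ({self.n_bootstrap} bootstrap resamples)")
        return "\n".join(lines)


@dataclass
class CycleComponents:
    dg_complex_mm: float
    dg_solv_mm: float
    dg_plps_mlmm: float = 0.0
    dg_lps_mlmm: float = 0.0
    err_complex_mm: float = 0.0
    err_solv_mm: float = 0.0
    err_plps_mlmm: float = 0.0
    err_lps_mlmm: float = 0.0


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_f(u: np.ndarray, counts: np.ndarray, tol: float, max_iter: int,
            f0: np.ndarray | None = None) -> np.ndarray:
    """Solve the MBAR equations: convex-objective minimization + SC polish.

    Minimizing F(f) = sum_n ln sum_k N_k exp(f_k - u_kn) - sum_k N_k f_k
    is equivalent to the self-consistency equations (its stationary point);
    L-BFGS handles poorly overlapping states far faster than plain iteration.
    """
    from scipy.optimize import minimize

    k, n = u.shape
    log_n = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)
    f = np.zeros(k) if f0 is None else f0.copy()

    def objective(fv):
        a = log_n[:, None] + fv[:, None] - u
        val = logsumexp(a, axis=0).sum() - counts @ fv
        w = np.exp(a - logsumexp(a, axis=0)[None, :])
        grad = w.sum(axis=1) - counts
        return val, grad

    res = minimize(objective, f, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14,
                            "gtol": 1e-10})
    f = res.x - res.x[0]
    # self-consistent polish to the requested residual
    for _ in range(max_iter):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return f
    raise RuntimeError(
        f"MBAR did not converge (residual {delta:.3e} > tol {tol:.1e})")


def _mbar_weights(u, counts, f):
    log_n = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    return np.exp(f[:, None] - u - log_denom[None, :])  # W[k, n]


def statistical_inefficiency(x: np.ndarray) -> float:
    """g = 1 + 2 sum of positive-sequence autocorrelations of a timeseries.

    The effective number of independent samples in a correlated series of
    length N is N/g. Truncation follows the initial-positive-sequence rule.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return 1.0
    dx = x - x.mean()
    var = float(dx @ dx) / n
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = float(dx[:-t] @ dx[t:]) / ((n - t) * var)
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


class MBAR:
    """MBAR estimator over a reduced-energy matrix.

    ``fit()`` returns a :class:`FreeEnergyResult` with the free-energy
    difference between ``ref_state`` and ``target_state`` in kJ/mol and a
    per-state block-bootstrap error.
    """

    def __init__(self, matrix: ReducedEnergyMatrix, ref_state: int = 0,
                 target_state: int = -1):
        self.matrix = matrix
        self.ref_state = ref_state
        self.target_state = target_state

    def fit(self, tol: float = 1e-8, max_iter: int = 10000,
            n_bootstrap: int = 200, seed: int = 0) -> FreeEnergyResult:
        """Solve and attach a block-bootstrap error.

        Within each state, samples are grouped into contiguous blocks (time
        order) that are resampled with replacement; the block length is the
        statistical inefficiency of that state's energy-difference
        timeseries, so serial correlation of MD samples is absorbed instead
        of silently shrinking the error bar.
        """
        m = self.matrix
        k_states = m.u.shape[0]
        f = _mbar_f(m.u, m.counts, tol, max_iter)
        dg = (f[self.target_state] - f[self.ref_state]) * m.kt
        err = 0.0
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            edges = np.concatenate([[0], np.cumsum(m.counts)])
            blocks = []  # per state: list of index blocks
            for i in range(len(m.counts)):
                if m.counts[i] == 0:
                    blocks.append([])
                    continue
                idx = np.arange(edges[i], edges[i + 1])
                j = i + 1 if i + 1 < k_states else i - 1
                du = m.u[j, idx] - m.u[i, idx]
                g = statistical_inefficiency(du)
                block_len = min(idx.size, max(1, int(np.ceil(g))))
                blocks.append(np.array_split(
                    idx, max(1, idx.size // block_len)))
            vals = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                picked = []
                counts_b = np.zeros_like(m.counts)
                for i, bl in enumerate(blocks):
                    if not bl:
                        continue
                    chosen = rng.integers(0, len(bl), size=len(bl))
                    sel = np.concatenate([bl[c] for c in chosen])
                    picked.append(sel)
                    counts_b[i] = sel.size
                idx = np.concatenate(picked)
                fb = _mbar_f(m.u[:, idx], counts_b, tol * 100, max_iter, f0=f)
                vals[b] = (fb[self.target_state] - fb[self.ref_state]) * m.kt
            err = float(np.std(vals, ddof=1))
        return FreeEnergyResult(f, float(dg), err, "MBAR", m.temperature,
                                n_bootstrap)


def mbar_solve(matrix: ReducedEnergyMatrix, tol: float = 1e-8,
               max_iter: int = 10000, n_bootstrap: int = 200,
               seed: int = 0) -> FreeEnergyResult:
    """Reduced free energies of all states (gauge f_1 = 0); dG is last - first."""
    return MBAR(matrix).fit(tol=tol, max_iter=max_iter,
                            n_bootstrap=n_bootstrap, seed=seed)


def overlap_matrix(matrix: ReducedEnergyMatrix,
                   result: FreeEnergyResult | None = None) -> np.ndarray:
    """Row-stochastic K x K matrix of MBAR weight overlaps between states."""
    f = result.f if result is not None else _mbar_f(matrix.u, matrix.counts,
                                                    1e-8, 10000)
    w = _mbar_weights(matrix.u, matrix.counts, f)  # (K, N)
    return w @ (w * matrix.counts[:, None]).T  # O_ij = sum_n W_in N_j W_jn


# ---------------------------------------------------------------------------
# work-based estimators
# ---------------------------------------------------------------------------

def _bar_solve(wf: np.ndarray, wr: np.ndarray, kt: float) -> float:
    """Self-consistent BAR in kJ/mol from forward and backward work sets.

    ``wr`` holds work values of switches run in the reverse direction; Crooks
    conjugacy means -wr are samples of the forward work at the target state.
    """
    nf, nr = len(wf), len(wr)
    m = np.log(nf / nr) * kt

    def implicit(dg):
        # sum_F 1/(1+exp((M + w_F - dg)/kT)) - sum_R 1/(1+exp(-(M - w_R - dg)/kT))
        tf = 1.0 / (1.0 + np.exp(np.clip((m + wf - dg) / kt, -500, 500)))
        tr = 1.0 / (1.0 + np.exp(np.clip(-(m - wr - dg) / kt, -500, 500)))
        return tf.sum() - tr.sum()

    lo = min(wf.min(), (-wr).min()) - 50.0 * kt
    hi = max(wf.max(), (-wr).max()) + 50.0 * kt
    if implicit(lo) * implicit(hi) > 0:  # degenerate (e.g. all-identical work)
        return 0.5 * (wf.mean() + (-wr).mean())
    return brentq(implicit, lo, hi, xtol=1e-12)


class BAR:
    """Bennett acceptance ratio over forward/backward work distributions."""

    def __init__(self, forward_work, backward_work, temperature: float = 300.0):
        self.wf = np.asarray(forward_work, dtype=float)
        self.wr = np.asarray(backward_work, dtype=float)
        if self.wf.size == 0 or self.wr.size == 0:
            raise ValueError("both work sets must be nonempty")
        self.temperature = temperature

    def fit(self, n_bootstrap: int = 200, seed: int = 0) -> FreeEnergyResult:
        kt = BOLTZMANN_CONSTANT * self.temperature
        dg = _bar_solve(self.wf, self.wr, kt)
        err = 0.0
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            vals = [
                _bar_solve(rng.choice(self.wf, self.wf.size, replace=True),
                           rng.choice(self.wr, self.wr.size, replace=True), kt)
                for _ in range(n_bootstrap)]
            err = float(np.std(vals, ddof=1))
        return FreeEnergyResult(np.array([0.0, dg / kt]), float(dg), err,
                                "BAR", self.temperature, n_bootstrap)


def bar_from_work(forward_work, backward_work, temperature: float = 300.0,
                  n_bootstrap: int = 200, seed: int = 0) -> FreeEnergyResult:
    works_f = [w.work if hasattr(w, "work") else w for w in forward_work]
    works_r = [w.work if hasattr(w, "work") else w for w in backward_work]
    return BAR(works_f, works_r, temperature).fit(n_bootstrap=n_bootstrap,
                                                  seed=seed)


def jarzynski(forward_work, temperature: float = 300.0,
              n_bootstrap: int = 200, seed: int = 0) -> FreeEnergyResult:
    """Exponential work average; biased low-sample estimates are flagged."""
    w = np.array([x.work if hasattr(x, "work") else x for x in forward_work],
                 dtype=float)
    if w.size == 0:
        raise ValueError("empty work set")
    kt = BOLTZMANN_CONSTANT * temperature

    def estimate(ws):
        return -kt * (logsumexp(-ws / kt) - np.log(ws.size))

    dg = estimate(w)
    err = 0.0
    if n_bootstrap > 0 and w.size > 1:
        rng = np.random.default_rng(seed)
        vals = [estimate(rng.choice(w, w.size, replace=True))
                for _ in range(n_bootstrap)]
        err = float(np.std(vals, ddof=1))
    method = "Jarzynski"
    if w.size < 10 or (w.std() if w.size > 1 else 0.0) > 2.0 * kt:
        method += " (small-sample/broad-work: bias-prone)"
    return FreeEnergyResult(np.array([0.0, dg / kt]), float(dg), err, method,
                            temperature, n_bootstrap)


def combine_cycle(components: CycleComponents):
    """Compose the binding free energies from the thermodynamic cycle."""
    c = components
    for v in (c.dg_complex_mm, c.dg_solv_mm, c.dg_plps_mlmm, c.dg_lps_mlmm):
        if not np.isfinite(v):
            raise ValueError("non-finite cycle component")
    dg_mm = c.dg_complex_mm - c.dg_solv_mm
    dg_mlmm = c.dg_complex_mm + c.dg_plps_mlmm - c.dg_solv_mm - c.dg_lps_mlmm
    err_mm = float(np.hypot(c.err_complex_mm, c.err_solv_mm))
    err_mlmm = float(np.sqrt(c.err_complex_mm ** 2 + c.err_solv_mm ** 2
                             + c.err_plps_mlmm ** 2 + c.err_lps_mlmm ** 2))
    return dg_mm, dg_mlmm, err_mm, err_mlmm
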