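"""Licking-bout analysis: the bi-exponential IRT mixture model.

Rodent licking is organized in bouts: bursts of fast licks separated by
pauses. The inter-response times (IRTs) tau then follow a two-component
exponential mixture (Killeen's bout model), in normalized form

    P(tau) = q * w * exp(-w * tau) + (1 - q) * b * exp(-b * tau),

where q is the proportion of within-bout IRTs, w the within-bout lick
rate (licks/s) and b the bout-initiation rate governing pause lengths
(1/s), with w > b. Maximum-likelihood fitting uses EM with multi-start
initialization (a Bayesian mode via affine-invariant MCMC is available);
each IRT is then classified within-bout vs pause by comparing component
likelihoods, which reduces to thresholding at the closed-form crossover
tau* = ln(q w / ((1-q) b)) / (w - b), and bouts are segmented as maximal
runs of within-bout IRTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import LickTrain

WITHIN_BOUT = "within_bout"
PAUSE = "pause"


@dataclass
class IRTMixtureParams:
    """Parameters (q, w, b) of the normalized bi-exponential IRT mixture."""

    q: float
    w: float
    b: float

    def validate(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if not (self.w > self.b > 0.0):
            raise ValueError("require w > b > 0")


@dataclass
class MixtureFit(IRTMixtureParams):
    """Fitted mixture parameters plus diagnostics."""

    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    method: str = "mle"
    n_irts: int = 0


@dataclass
class BoutSegmentation:
    """Per-IRT labels and the resulting bout onset/offset lists."""

    labels: np.ndarray            # per-IRT, WITHIN_BOUT or PAUSE
    bout_onsets: np.ndarray       # first-lick time of each retained bout
    bout_offsets: np.ndarray      # last-lick time of each retained bout
    licks_per_bout: np.ndarray    # lick counts of retained bouts
    n_discarded_runs: int = 0     # runs shorter than the minimum bout size
    n_discarded_licks: int = 0


def compute_irts(licks: LickTrain | Sequence[float]) -> np.ndarray:
    """Inter-response times tau_i = t_{i+1} - t_i (s); requires >= 2 licks."""
    t = licks.lick_times if isinstance(licks, LickTrain) else np.asarray(licks, float)
    if len(t) < 2:
        raise ValueError("need at least 2 licks to compute IRTs")
    irts = np.diff(t)
    if np.any(irts <= 0):
        raise ValueError("lick times must be strictly ascending")
    return irts


def mixture_logdensity(params: IRTMixtureParams, tau) -> np.ndarray | float:
    """Log density of the normalized mixture at tau >= 0 (vectorized)."""
    params.validate()
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    la = np.log(params.q) + np.log(params.w) - params.w * tau_arr
    lb = np.log1p(-params.q) + np.log(params.b) - params.b * tau_arr
    out = np.logaddexp(la, lb)
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def _loglik(q: float, w: float, b: float, tau: np.ndarray) -> float:
    la = np.log(q) + np.log(w) - w * tau
    lb = np.log1p(-q) + np.log(b) - b * tau
    return float(np.logaddexp(la, lb).sum())


def _em(
    tau: np.ndarray,
    q: float,
    w: float,
    b: float,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> Tuple[float, float, float, float, bool, int]:
    """EM for the two-exponential mixture; returns (q, w, b, ll, conv, iters)."""
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(q) + np.log(w) - w * tau
        lb = np.log1p(-q) + np.log(b) - b * tau
        norm = np.logaddexp(la, lb)
        gamma = np.exp(la - norm)  # responsibility of the within-bout component
        ll = float(norm.sum())
        sg, s1g = gamma.sum(), (1.0 - gamma).sum()
        if sg < 1e-12 or s1g < 1e-12:
            break  # component collapsed; caller treats as boundary solution
        q = sg / len(tau)
        w = sg / float(gamma @ tau)
        b = s1g / float((1.0 - gamma) @ tau)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if w < b:  # relabel so the fast component is "within bout"
        w, b, q = b, w, 1.0 - q
    return q, w, b, _loglik(q, w, b, tau), converged, it


def _initial_points(tau: np.ndarray, rng: np.random.Generator, n_random: int):
    """Multi-start inits: a split-at-quantile heuristic plus random splits."""
    inits = []
    for frac in (0.5, 0.7, 0.9):
        split = np.quantile(tau, frac)
        fast = tau[tau <= split]
        slow = tau[tau > split]
        if len(fast) and len(slow) and fast.mean() > 0 and slow.mean() > 0:
            inits.append((len(fast) / len(tau), 1.0 / fast.mean(), 1.0 / slow.mean()))
    for _ in range(n_random):
        q0 = rng.uniform(0.2, 0.95)
        split = np.quantile(tau, q0)
        fast = tau[tau <= split]
        slow = tau[tau > split]
        if len(fast) and len(slow):
            w0 = 1.0 / max(fast.mean(), 1e-6) * rng.uniform(0.5, 2.0)
            b0 = 1.0 / max(slow.mean(), 1e-6) * rng.uniform(0.5, 2.0)
            if w0 > b0:
                inits.append((q0, w0, b0))
    if not inits:
        m = tau.mean()
        inits.append((0.5, 2.0 / m, 0.5 / m))
    return inits


def fit_mixture(
    irts: np.ndarray | Sequence[float],
    init: Optional[IRTMixtureParams] = None,
    method: str = "mle",
    min_irts: int = 50,
    n_random_starts: int = 5,
    seed: int = 0,
    **bayes_kwargs,
) -> MixtureFit:
    """Estimate (q, w, b) from pooled IRTs.

    ``method='mle'`` (default) maximizes the normalized mixture
    log-likelihood by EM with multi-start initialization; deterministic
    given the data and ``seed``. ``method='bayes'`` draws from the
    posterior under weakly-informative priors (q ~ Uniform(0, 1); w, b ~
    half-normal with scales 20 and 5 s^-1) using emcee and reports the
    posterior median. Identifiability is enforced by the constraint
    w > b (relabeling). Non-convergence is flagged, never silent.
    """
    tau = np.asarray(irts, dtype=float)
    if len(tau) < min_irts:
        raise ValueError(f"need at least {min_irts} IRTs to fit, got {len(tau)}")
    if np.any(tau <= 0):
        raise ValueError("IRTs must be positive")
    if method == "mle":
        rng = np.random.default_rng(seed)
        inits: List[Tuple[float, float, float]] = []
        if init is not None:
            init.validate()
            inits.append((init.q, init.w, init.b))
        inits.extend(_initial_points(tau, rng, n_random_starts))
        best = None
        for q0, w0, b0 in inits:
            q0 = min(max(q0, 1e-4), 1 - 1e-4)
            res = _em(tau, q0, w0, b0)
            if best is None or res[3] > best[3]:
                best = res
        q, w, b, ll, conv, it = best
        q = float(np.clip(q, 1e-9, 1 - 1e-9))
        if not (w > b):
            b = min(b, w * (1 - 1e-9))  # degenerate equal-rate boundary
        return MixtureFit(
            q=q, w=w, b=b, loglik=ll, converged=conv, n_iter=it,
            method="mle", n_irts=len(tau),
        )
    if method == "bayes":
        return _fit_bayes(tau, seed=seed, **bayes_kwargs)
    raise ValueError("method must be 'mle' or 'bayes'")


def _fit_bayes(
    tau: np.ndarray,
    seed: int = 0,
    n_walkers: int = 24,
    n_steps: int = 1500,
    n_burn: int = 500,
    w_scale: float = 20.0,
    b_scale: float = 5.0,
) -> MixtureFit:
    """Posterior-median fit via affine-invariant ensemble MCMC (emcee)."""
    import emcee

    def log_post(theta):
        q, lw, lb = theta
        if not (0.0 < q < 1.0):
            return -np.inf
        w, b = np.exp(lw), np.exp(lb)
        if not (w > b > 0) or w > 1e4:
            return -np.inf
        # half-normal priors on the rates (log-parameterized, + Jacobian)
        lp = -0.5 * (w / w_scale) ** 2 - 0.5 * (b / b_scale) ** 2 + lw + lb
        return lp + _loglik(q, w, b, tau)

    mle = fit_mixture(tau, method="mle", min_irts=min(50, len(tau)), seed=seed)
    rng = np.random.default_rng(seed)
    p0 = np.column_stack(
        [
            np.clip(mle.q + 0.05 * rng.standard_normal(n_walkers), 0.01, 0.99),
            np.log(mle.w) + 0.1 * rng.standard_normal(n_walkers),
            np.log(mle.b) + 0.1 * rng.standard_normal(n_walkers),
        ]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 3, log_post)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    q_s = chain[:, 0]
    w_s, b_s = np.exp(chain[:, 1]), np.exp(chain[:, 2])
    # relabel any swapped samples so w > b
    swap = w_s < b_s
    w_s[swap], b_s[swap] = b_s[swap], w_s[swap]
    q_s[swap] = 1.0 - q_s[swap]
    q, w, b = (float(np.median(v)) for v in (q_s, w_s, b_s))
    return MixtureFit(
        q=q, w=w, b=b, loglik=_loglik(q, w, b, tau),
        converged=True, n_iter=n_steps, method="bayes", n_irts=len(tau),
    )


def classification_threshold(params: IRTMixtureParams) -> float:
    """IRT tau* at which the two component likelihoods are equal.

    tau* = ln(q w / ((1-q) b)) / (w - b). IRTs below tau* are more likely
    within-bout. If q w <= (1-q) b the threshold is <= 0 and every IRT
    classifies as a pause. Undefined for w == b.
    """
    if params.w == params.b:
        raise ValueError("w == b: component likelihoods never cross")
    params.validate()
    return float(
        np.log(params.q * params.w / ((1.0 - params.q) * params.b))
        / (params.w - params.b)
    )


def classify_licks(irts: np.ndarray | Sequence[float], params: IRTMixtureParams) -> np.ndarray:
    """Label each IRT within-bout or pause by component likelihood.

    tau is within-bout iff q w e^{-w tau} > (1-q) b e^{-b tau}; ties are
    labeled pause (equivalently, within-bout iff tau < tau*).
    """
    params.validate()
    tau = np.asarray(irts, dtype=float)
    la = np.log(params.q) + np.log(params.w) - params.w * tau
    lb = np.log1p(-params.q) + np.log(params.b) - params.b * tau
    return np.where(la > lb, WITHIN_BOUT, PAUSE)


def segment_bouts(
    licks: LickTrain | Sequence[float],
    labels: np.ndarray,
    min_licks_per_bout: int = 2,
) -> BoutSegmentation:
    """Group licks into bouts from the per-IRT labels.

    A bout is a maximal run of licks whose internal IRTs are all labeled
    within-bout; its onset (offset) is the first (last) lick of the run.
    Runs with fewer than ``min_licks_per_bout`` licks are dropped from the
    onset/offset lists but counted in the diagnostics, so that total lick
    count is conserved: sum(licks_per_bout) + n_discarded_licks = n licks.
    """
    t = licks.lick_times if isinstance(licks, LickTrain) else np.asarray(licks, float)
    labels = np.asarray(labels)
    if len(labels) != max(len(t) - 1, 0):
        raise ValueError("labels must have one entry per IRT (n_licks - 1)")
    onsets: List[float] = []
    offsets: List[float] = []
    counts: List[int] = []
    n_disc_runs = 0
    n_disc_licks = 0
    if len(t) == 0:
        return BoutSegmentation(
            labels=labels, bout_onsets=np.empty(0), bout_offsets=np.empty(0),
            licks_per_bout=np.empty(0, dtype=int),
        )
    start = 0
    for i in range(len(labels) + 1):
        end_of_run = i == len(labels) or labels[i] == PAUSE
        if end_of_run:
            n = i - start + 1
            if n >= min_licks_per_bout:
                onsets.append(t[start])
                offsets.append(t[i])
                counts.append(n)
            else:
                n_disc_runs += 1
                n_disc_licks += n
            start = i + 1
    return BoutSegmentation(
        labels=labels,
        bout_onsets=np.asarray(onsets),
        bout_offsets=np.asarray(offsets),
        licks_per_bout=np.asarray(counts, dtype=int),
        n_discarded_runs=n_disc_runs,
        n_discarded_licks=n_disc_licks,
    )
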