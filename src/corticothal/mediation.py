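"""Single-trial phase-distance mediation with permutation inference.

The single-trial predictor is the *distance to the optimal phase*: the
resultant length of the two-angle set formed by a trial's phase and the
hit-averaged reference phase, ``|cos((theta_ref - theta_trial)/2)|`` in
[0, 1] (1 = at the optimum, 0 = antiphase). Three regressions then form the
mediation triangle (X = cortical proximity, M = thalamic proximity,
Y = hit/miss)::

    Y = j1 + c X          (logistic)
    M = j2 + a X          (linear)
    Y = j3 + c' X + b M   (logistic)

Every coefficient is standardized by its standard error of fit, putting the
linear and logistic paths in a common t-statistic unit space, and the
indirect effect is

    ab = t_a * t_b / sqrt(t_a^2 + t_b^2 + 1)

Inference shuffles the mediator's trials (for ab) or the two brain variables
jointly relative to behavior (for the total-minus-direct contrast c - c'),
z-scoring the observed effect by the surrogate mean and SD; group-level
inference is a sign-flip permutation t-test, fully enumerated (2^n) for small
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from .exceptions import NumericalError, ValidationError


def phase_proximity(trial_phase, reference_phase) -> np.ndarray:
    """Resultant length of {trial phase, reference phase}: |cos(delta/2)| in [0, 1]."""
    trial_phase = np.asarray(trial_phase, dtype=float)
    reference_phase = np.asarray(reference_phase, dtype=float)
    if not (np.all(np.isfinite(trial_phase)) and np.all(np.isfinite(reference_phase))):
        raise ValidationError("phase angles must be finite")
    return np.abs(np.cos((reference_phase - trial_phase) / 2.0))


def reference_phase_from_hits(phases, outcome) -> float:
    """Circular mean phase across hit trials — the 'optimal' reference angle."""
    phases = np.asarray(phases, dtype=float)
    outcome = np.asarray(outcome)
    hits = phases[outcome == 1]
    if hits.size < 2:
        raise ValidationError(f"need >= 2 hit trials, got {hits.size}")
    return float(np.angle(np.exp(1j * hits).mean()))


@dataclass
class MediationPaths:
    """Fitted mediation triangle: raw coefficients, t-statistics, indirect effect."""

    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    j1: float
    j2: float
    j3: float
    a: float
    b: float
    c: float
    c_prime: float
    t_a: float
    t_b: float
    t_c: float
    t_cprime: float
    ab: float


def indirect_effect(t_a: float, t_b: float) -> float:
    """Standardized indirect effect ab = t_a t_b / sqrt(t_a^2 + t_b^2 + 1)."""
    return t_a * t_b / np.sqrt(t_a**2 + t_b**2 + 1.0)


def _fit_logit(y, design):
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except Exception as exc:  # perfect separation, non-convergence
            raise NumericalError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse == 0):
        raise NumericalError("logistic fit produced degenerate standard errors")
    return res


def fit_paths(X, M, Y) -> MediationPaths:
    """Fit the three mediation regressions and the standardized indirect effect."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.size
    if not (M.size == n and Y.size == n):
        raise ValidationError("X, M, Y must have equal length")
    if n < 20:
        raise ValidationError(f"need >= 20 trials to fit mediation paths, got {n}")
    if not (set(np.unique(Y)) <= {0.0, 1.0}) or len(np.unique(Y)) < 2:
        raise ValidationError("Y must be binary with both classes present")
    if X.std() == 0 or M.std() == 0:
        raise ValidationError("X and M must be non-constant")
    dx = sm.add_constant(X)
    dxm = sm.add_constant(np.column_stack([X, M]))
    total = _fit_logit(Y, dx)  # Y = j1 + c X
    apath = sm.OLS(M, dx).fit()  # M = j2 + a X
    full = _fit_logit(Y, dxm)  # Y = j3 + c' X + b M
    t_a = float(apath.params[1] / apath.bse[1])
    t_b = float(full.params[2] / full.bse[2])
    return MediationPaths(
        X=X, M=M, Y=Y.astype(np.uint8),
        j1=float(total.params[0]), j2=float(apath.params[0]), j3=float(full.params[0]),
        c=float(total.params[1]), a=float(apath.params[1]),
        c_prime=float(full.params[1]), b=float(full.params[2]),
        t_c=float(total.params[1] / total.bse[1]),
        t_a=t_a, t_b=t_b,
        t_cprime=float(full.params[1] / full.bse[1]),
        ab=float(indirect_effect(t_a, t_b)),
    )


@dataclass
class MediationInference:
    """Surrogate-normalized indirect and total-minus-direct effects for one unit."""

    paths: MediationPaths
    z_ab: float
    p_ab: float
    z_total_minus_direct: float
    p_total_minus_direct: float
    n_perm: int
    seed: int


def mediation_surrogate(
    X, M, Y, n_perm: int = 1000, seed: int = 0
) -> MediationInference:
    """Permutation inference for the indirect effect and the c - c' contrast.

    The indirect-effect null shuffles the mediator's trial order relative to
    (X, Y), re-fitting the a- and b-paths; the total-minus-direct null
    shuffles X and M jointly (one permutation applied to both) relative to Y.
    Both contrasts are z-scored by their surrogate mean/SD (t-statistic
    units), with one-sided empirical percentiles retained.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    observed = fit_paths(X, M, Y)
    X = observed.X
    M = observed.M
    Y = observed.Y.astype(float)
    rng = np.random.default_rng(seed)
    n = X.size
    dx = sm.add_constant(X)
    ab_null = np.empty(n_perm)
    diff_null = np.empty(n_perm)
    n_failed = 0
    for p in range(n_perm):
        # indirect-effect null: mediator decoupled from predictor and outcome
        mp = M[rng.permutation(n)]
        try:
            ap = sm.OLS(mp, dx).fit()
            fp = _fit_logit(Y, sm.add_constant(np.column_stack([X, mp])))
            ab_null[p] = indirect_effect(
                float(ap.params[1] / ap.bse[1]), float(fp.params[2] / fp.bse[2])
            )
        except NumericalError:
            ab_null[p] = np.nan
            n_failed += 1
        # total-vs-direct null: both brain variables decoupled from behavior
        perm = rng.permutation(n)
        xp, mp2 = X[perm], M[perm]
        try:
            tp = _fit_logit(Y, sm.add_constant(xp))
            fp2 = _fit_logit(Y, sm.add_constant(np.column_stack([xp, mp2])))
            diff_null[p] = float(tp.params[1] / tp.bse[1]) - float(
                fp2.params[1] / fp2.bse[1]
            )
        except NumericalError:
            diff_null[p] = np.nan
            n_failed += 1
    if n_failed > 0.1 * n_perm:
        raise NumericalError(
            f"{n_failed} of {2 * n_perm} surrogate fits failed (separation?)"
        )
    obs_diff = observed.t_c - observed.t_cprime

    def z_and_p(obs, null):
        null = null[np.isfinite(null)]
        sd = null.std(ddof=1)
        if sd < 1e-12:
            raise NumericalError("degenerate mediation surrogate distribution")
        z = (obs - null.mean()) / sd
        p = (1.0 + (null >= obs).sum()) / (1.0 + null.size)
        return float(z), float(p)

    z_ab, p_ab = z_and_p(observed.ab, ab_null)
    z_diff, p_diff = z_and_p(obs_diff, diff_null)
    return MediationInference(
        paths=observed, z_ab=z_ab, p_ab=p_ab,
        z_total_minus_direct=z_diff, p_total_minus_direct=p_diff,
        n_perm=n_perm, seed=seed,
    )


def group_sign_flip_test(
    z_values, enumerate_all: bool = None, n_perm: int = 1000,
    seed: int = 0, tail: str = "greater",
) -> dict:
    """One-sample sign-flip permutation t-test on per-unit z values.

    Full enumeration of all 2^n sign assignments when n <= 12 (or when
    ``enumerate_all`` is forced); otherwise ``n_perm`` sampled flips. The
    one-sided p is the proportion of permutation t-values at least as large
    as the observed one (the identity assignment is a member of the
    enumeration, so p >= 1/2^n).
    """
    z = np.asarray(z_values, dtype=float)
    n = z.size
    if n < 3:
        raise ValidationError("group sign-flip test needs >= 3 units")
    if np.all(z == 0):
        raise ValidationError("all unit values are exactly 0")
    if tail not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown tail {tail!r}")

    def tstat(vals):
        sd = vals.std(axis=-1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                sd > 0, vals.mean(axis=-1) / (sd / np.sqrt(n)),
                np.sign(vals.mean(axis=-1)) * np.inf,
            )

    t_obs = float(tstat(z))
    if enumerate_all is None:
        enumerate_all = n <= 12
    if enumerate_all:
        codes = np.arange(2**n, dtype=np.uint64)
        bits = np.arange(n, dtype=np.uint64)
        signs = 1.0 - 2.0 * ((codes[:, None] >> bits[None, :]) & np.uint64(1)).astype(float)
        n_total = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_total = n_perm
    t_null = tstat(signs * z[None, :])
    eps = 1e-12
    if tail == "greater":
        p = float((t_null >= t_obs - eps).mean())
    elif tail == "less":
        p = float((t_null <= t_obs + eps).mean())
    else:
        p = float((np.abs(t_null) >= abs(t_obs) - eps).mean())
    return {"t": t_obs, "p": p, "n_perm": int(n_total), "n_units": n, "tail": tail}


def partial_spearman(X, M, Y) -> dict:
    """Spearman rho(X, Y) and the first-order partial rho(X, Y | M).

    On planted-mediation data the partial correlation is attenuated relative
    to the marginal one — the rank-based analogue of the c vs. c' contrast.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size < 10:
        raise ValidationError("partial_spearman needs n >= 10")
    if X.std() == 0 or M.std() == 0 or Y.std() == 0:
        raise ValidationError("constant input to partial_spearman")
    rho_xy = float(stats.spearmanr(X, Y).statistic)
    df = pd.DataFrame({"x": X, "m": M, "y": Y})
    res = pg.partial_corr(data=df, x="x", y="y", covar="m", method="spearman")
    return {"rho_XY": rho_xy, "rho_XY_given_M": float(res["r"].iloc[0])}


def check_mediator_direction(psi_x_to_m: float, override: bool = False) -> None:
    """Refuse the mediation model when the candidate mediator leads in time.

    ``psi_x_to_m`` is the phase-slope index from the independent-variable
    region to the mediator region: positive means X leads M, the temporal
    ordering a mediation model requires. Negative PSI raises unless
    ``override`` (which warns instead).
    """
    if psi_x_to_m < 0:
        msg = (
            "candidate mediator temporally leads the independent variable "
            f"(PSI = {psi_x_to_m:.3g} < 0); mediation assumes the mediator follows"
        )
        if not override:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
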