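"""Parameter estimation for the PVL-DecayRI model.

Two estimation paths share one posterior:

* :func:`fit_map` — deterministic per-subject MAP (maximum a posteriori) by
  multi-start quasi-Newton optimisation on an unconstrained transformed
  scale.  With flat priors this is the maximum-likelihood estimate.  Fast
  enough to serve as the oracle in recovery studies.
* :func:`fit_mcmc` — affine-invariant ensemble MCMC (emcee) on the same
  transformed scale, with split R-hat and effective-sample-size diagnostics
  computed via arviz.

Parameters live in boxes (alpha, A in [0,1]; lam, c in [0,5]).  Estimation
works on probit-transformed coordinates z where alpha = Phi(z1),
lam = 5*Phi(z2), A = Phi(z3), c = 5*Phi(z4); the default prior is standard
normal on each z, the convention of the PVL modelling lineage.  Priors are
overridable through :class:`PriorSpec`, including a two-stage empirical-Bayes
mode where group-level priors are learned from first-pass estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .igt_task import DECK_INDEX, PayoffSchedule, TrialSequence
from .pvl_model import PARAM_NAMES, PVLParameters, _loglik, utility

_SCALES = np.array([1.0, 5.0, 1.0, 5.0])  # box widths for (alpha, lam, A, c)
_EPS = 1e-10

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 100.0


class FitError(RuntimeError):
    """Raised when every optimisation restart fails to converge."""


def params_from_z(z: np.ndarray) -> np.ndarray:
    """Map unconstrained coordinates into the parameter boxes (probit)."""
    return _SCALES * np.clip(ndtr(np.asarray(z, dtype=float)), _EPS, 1 - _EPS)


def z_from_params(p: np.ndarray) -> np.ndarray:
    """Inverse of :func:`params_from_z`."""
    frac = np.clip(np.asarray(p, dtype=float) / _SCALES, _EPS, 1 - _EPS)
    return ndtri(frac)


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the probit-transformed parameters.

    ``mu``/``sigma`` are per-parameter hyperparameters on the z scale, in the
    order (alpha, lam, A, c).  ``flat=True`` drops the prior term entirely,
    turning MAP into MLE.
    """

    mu: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    sigma: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    flat: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("prior sigmas must be positive")

    def log_prob(self, z: np.ndarray) -> float:
        """Unnormalised log-density (constants dropped)."""
        if self.flat:
            return 0.0
        mu = np.asarray(self.mu)
        sig = np.asarray(self.sigma)
        return float(-0.5 * np.sum(((z - mu) / sig) ** 2))

    @classmethod
    def default(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def flat_prior(cls) -> "PriorSpec":
        return cls(flat=True)

    @classmethod
    def from_estimates(cls, estimates: pd.DataFrame, min_sigma: float = 0.25) -> "PriorSpec":
        """Empirical-Bayes prior: moments of z-transformed first-pass estimates.

        Provides the group-informed second stage of a two-stage hierarchical
        fit: run :func:`fit_map` (or a short MCMC) on each subject, build the
        prior from the spread of those estimates, then refit under it.
        ``min_sigma`` keeps the prior from collapsing on small cohorts.
        """
        z = np.stack(
            [z_from_params(row) for row in estimates[list(PARAM_NAMES)].to_numpy()]
        )
        mu = z.mean(axis=0)
        sigma = np.maximum(z.std(axis=0, ddof=1), min_sigma)
        return cls(mu=tuple(mu), sigma=tuple(sigma))


@dataclass
class FitResult:
    """Per-subject estimates plus (for MCMC) posterior draws and diagnostics.

    ``estimates`` has one row per subject with columns ``subject_id, alpha,
    lam, A, c, loglik`` and, when available, ``rhat_max`` and ``ess_min``.
    ``draws`` maps subject id to an array of shape (chain, draw, 4) on the
    parameter scale.
    """

    estimates: pd.DataFrame
    method: str
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def parameters(self, subject_id: str) -> PVLParameters:
        row = self.estimates.set_index("subject_id").loc[subject_id]
        return PVLParameters(
            alpha=row["alpha"], lam=row["lam"], A=row["A"], c=row["c"]
        )

    def to_csv(self, path) -> None:
        df = self.estimates.rename(columns={"lam": "lambda"})
        df.to_csv(path, index=False)


def _prepare(seq: TrialSequence, schedule: PayoffSchedule):
    choices = [DECK_INDEX[d] for d in seq.choices]
    x = seq.net_gains / schedule.scale_divisor
    return choices, x


def _neg_log_post(z, choices, x, priors: PriorSpec) -> float:
    p = params_from_z(z)
    u = utility(x, p[0], p[1])
    try:
        ll = _loglik(choices, u, p[2], p[3])
    except FloatingPointError:
        return 1e12
    return -(ll + priors.log_prob(z))


def log_posterior(z, seq: TrialSequence, schedule: PayoffSchedule, priors: PriorSpec) -> float:
    """Log-posterior on the transformed scale (likelihood + log-prior)."""
    choices, x = _prepare(seq, schedule)
    return -_neg_log_post(np.asarray(z, dtype=float), choices, x, priors)


def fit_map(
    seq: TrialSequence,
    schedule: PayoffSchedule,
    priors: PriorSpec | None = None,
    restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """MAP estimate for one subject via multi-start L-BFGS-B.

    The first start is the prior mean (z = 0); the remaining ``restarts - 1``
    are drawn standard-normal under ``seed``.  The best optimum wins; ties go
    to the first found.  Raises :class:`FitError` if every start fails.
    """
    if len(seq) < 1:
        raise ValueError("sequence must contain at least one trial")
    priors = priors or PriorSpec.default()
    choices, x = _prepare(seq, schedule)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(4)] + [rng.standard_normal(4) for _ in range(max(0, restarts - 1))]
    best = None
    messages = []
    for z0 in starts:
        res = minimize(
            _neg_log_post,
            z0,
            args=(choices, x, priors),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if not np.isfinite(res.fun):
            messages.append(str(res.message))
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise FitError(f"all {len(starts)} restarts failed: {messages}")
    p = params_from_z(best.x)
    ll = float(_loglik(choices, utility(x, p[0], p[1]), p[2], p[3]))
    est = pd.DataFrame(
        [
            {
                "subject_id": seq.subject_id,
                "alpha": p[0],
                "lam": p[1],
                "A": p[2],
                "c": p[3],
                "loglik": ll,
            }
        ]
    )
    return FitResult(estimates=est, method="map")


def fit_map_cohort(
    sequences: list[TrialSequence],
    schedule: PayoffSchedule,
    priors: PriorSpec | None = None,
    restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """MAP fits for a list of subjects; per-subject seeds derive from ``seed``."""
    rows = []
    for i, seq in enumerate(sequences):
        sub_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        rows.append(fit_map(seq, schedule, priors, restarts, sub_seed).estimates)
    return FitResult(estimates=pd.concat(rows, ignore_index=True), method="map")


def fit_mcmc(
    sequences: list[TrialSequence],
    schedule: PayoffSchedule,
    priors: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 1000,
    warmup: int | None = None,
    seed: int = 0,
) -> FitResult:
    """Ensemble MCMC over per-subject posteriors.

    Each subject gets an independent emcee ensemble with
    ``max(8, 2 * chains)`` walkers, initialised around a quick MAP estimate.
    Walkers play the role of chains in the split R-hat / ESS diagnostics.
    ``iterations`` counts post-warmup steps per walker; ``warmup`` defaults
    to ``iterations // 2``.  R-hat above 1.05 or ESS below 100 flags the
    result (``converged = False`` plus a warning) without aborting.
    """
    import emcee

    if isinstance(sequences, TrialSequence):
        sequences = [sequences]
    if len(sequences) < 1:
        raise ValueError("at least one subject required")
    if chains < 2:
        raise ValueError("chains must be >= 2")
    priors = priors or PriorSpec.default()
    warmup = iterations // 2 if warmup is None else warmup
    nwalkers = max(8, 2 * chains)
    rows, draws, warns = [], {}, []
    for i, seq in enumerate(sequences):
        choices, x = _prepare(seq, schedule)

        def log_prob(z):
            return -_neg_log_post(z, choices, x, priors)

        sub_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        z_map = fit_map(seq, schedule, priors, restarts=2, seed=sub_seed)
        z0 = z_from_params(z_map.estimates[list(PARAM_NAMES)].iloc[0].to_numpy())
        p0 = z0 + 0.3 * rng.standard_normal((nwalkers, 4))
        sampler = emcee.EnsembleSampler(nwalkers, 4, log_prob)
        sampler.random_state = np.random.RandomState(sub_seed).get_state()
        sampler.run_mcmc(p0, warmup + iterations, progress=False)
        z_draws = sampler.get_chain(discard=warmup)  # (steps, walkers, 4)
        p_draws = params_from_z(z_draws).transpose(1, 0, 2)  # (chain, draw, 4)
        draws[seq.subject_id] = p_draws
        rhat, ess = _diagnostics(p_draws)
        mean = p_draws.reshape(-1, 4).mean(axis=0)
        ll = float(_loglik(choices, utility(x, mean[0], mean[1]), mean[2], mean[3]))
        converged = bool(rhat.max() <= RHAT_THRESHOLD and ess.min() >= ESS_THRESHOLD)
        if not converged:
            msg = (
                f"{seq.subject_id}: max R-hat {rhat.max():.3f}, "
                f"min ESS {ess.min():.0f} (thresholds {RHAT_THRESHOLD}, {ESS_THRESHOLD:.0f})"
            )
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        rows.append(
            {
                "subject_id": seq.subject_id,
                "alpha": mean[0],
                "lam": mean[1],
                "A": mean[2],
                "c": mean[3],
                "loglik": ll,
                "rhat_max": float(rhat.max()),
                "ess_min": float(ess.min()),
                "converged": converged,
            }
        )
    return FitResult(
        estimates=pd.DataFrame(rows), method="mcmc", draws=draws, warnings=warns
    )


def _diagnostics(p_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split R-hat and bulk ESS per parameter from (chain, draw, 4) draws."""
    import arviz as az

    ds = az.from_dict(
        posterior={name: p_draws[:, :, k] for k, name in enumerate(PARAM_NAMES)}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    return (
        np.array([float(rhat[name]) for name in PARAM_NAMES]),
        np.array([float(ess[name]) for name in PARAM_NAMES]),
    )


def summarize_group(fit: FitResult, labels) -> pd.DataFrame:
    """Per-group mean and SD of each parameter.

    ``labels`` maps subject_id -> group label; every fitted subject must be
    labelled and every group must be non-empty.
    """
    labels = dict(labels)
    est = fit.estimates
    unknown = [s for s in est["subject_id"] if s not in labels]
    if unknown:
        raise KeyError(f"subjects without group labels: {unknown[:5]}")
    df = est.assign(group=[labels[s] for s in est["subject_id"]])
    if df["group"].value_counts().min() < 1 or df.empty:
        raise ValueError("every group must contain at least one subject")
    out = df.groupby("group")[list(PARAM_NAMES)].agg(["mean", "std"])
    out.columns = [f"{p}_{stat}" for p, stat in out.columns]
    return out
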