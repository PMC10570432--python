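"""Synthetic two-group study generator with known ground truth.

Emulates a case-control decision-making study: a patient-like group ("OCD")
and a control-like group ("HC"), 47 subjects each, whose IGT choices are
produced by PVL-DecayRI agents.  True parameters are drawn from truncated
normals whose means/SDs default to the published group values (e.g. recency
0.290 vs 0.530, consistency 0.393 vs 0.645), and each patient receives an
integer obsession-severity score (0-20 scale) rank-coupled to their recency
parameter through a Gaussian copula so that the group attains a target
Spearman correlation (0.334 by default).  Controls get severities from a
near-zero marginal (mean 0.04, SD 0.20).

Everything is reproducible from a single master seed: per-subject child
seeds are keyed by (seed, stream, subject index), so enlarging the cohort
does not reshuffle existing subjects' parameters or trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri
from scipy.stats import rankdata, truncnorm

from .igt_task import PayoffSchedule, TrialSequence, build_default_schedule, write_trial_logs
from .pvl_model import PARAM_BOUNDS, PARAM_NAMES, PVLParameters, simulate_agent

GROUP_OCD = "OCD"
GROUP_HC = "HC"

# (mean, sd) per parameter, per group — published group-level values.
DEFAULT_PARAM_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    GROUP_OCD: {
        "alpha": (0.240, 0.054),
        "lam": (0.278, 0.389),
        "A": (0.290, 0.177),
        "c": (0.393, 0.280),
    },
    GROUP_HC: {
        "alpha": (0.265, 0.061),
        "lam": (0.545, 0.597),
        "A": (0.530, 0.213),
        "c": (0.645, 0.305),
    },
}

# Obsession-severity marginal (mean, sd) per group, on the 0-20 subscale.
DEFAULT_SEVERITY_MARGINALS = {GROUP_OCD: (11.85, 3.49), GROUP_HC: (0.04, 0.20)}
DEFAULT_TARGET_RHO = 0.334
SEVERITY_RANGE = (0, 20)

# stream offsets for child-seed derivation
_STREAM_PARAMS = {GROUP_OCD: 0, GROUP_HC: 1}
_STREAM_SEVERITY = {GROUP_OCD: 2, GROUP_HC: 3}
_STREAM_TRIALS = 4


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort."""

    n_ocd: int = 47
    n_hc: int = 47
    n_trials: int = 100
    block_size: int = 20
    param_targets: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_PARAM_TARGETS.items()
    })
    severity_marginals: dict = field(default_factory=lambda: dict(DEFAULT_SEVERITY_MARGINALS))
    target_rho: float = DEFAULT_TARGET_RHO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ocd < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (-1.0 < self.target_rho < 1.0):
            raise ValueError("target rank correlation must lie in (-1, 1)")
        # normalise (YAML round-trips tuples as lists)
        self.param_targets = {
            g: {k: tuple(v) for k, v in targets.items()}
            for g, targets in self.param_targets.items()
        }
        self.severity_marginals = {
            g: tuple(v) for g, v in self.severity_marginals.items()
        }
        for group, targets in self.param_targets.items():
            for name, (mean, sd) in targets.items():
                lo, hi = PARAM_BOUNDS[name]
                if not (lo <= mean <= hi):
                    raise ValueError(f"{group}.{name}: mean {mean} outside [{lo}, {hi}]")
                if sd < 0:
                    raise ValueError(f"{group}.{name}: SD must be >= 0")

    def n_subjects(self, group: str) -> int:
        return {GROUP_OCD: self.n_ocd, GROUP_HC: self.n_hc}[group]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SubjectProfile:
    """Ground truth for one generated subject."""

    subject_id: str
    group: str
    params: PVLParameters
    severity: int
    sequence: TrialSequence


def _child_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


def sample_parameters(config: CohortConfig, group: str, seed: int | None = None) -> list[PVLParameters]:
    """Draw each subject's true parameters from box-truncated normals.

    One uniform per (subject, parameter) is drawn from a subject-keyed child
    generator and pushed through the truncated-normal quantile function, so
    draws are stable per subject index.  SD = 0 degenerates to the mean.
    """
    seed = config.seed if seed is None else seed
    n = config.n_subjects(group)
    targets = config.param_targets[group]
    u = np.vstack([_child_rng(seed, _STREAM_PARAMS[group], i).uniform(size=4) for i in range(n)])
    cols = {}
    for k, name in enumerate(PARAM_NAMES):
        mean, sd = targets[name]
        lo, hi = PARAM_BOUNDS[name]
        if sd == 0:
            cols[name] = np.full(n, mean)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            cols[name] = truncnorm.ppf(u[:, k], a, b, loc=mean, scale=sd)
    return [
        PVLParameters(alpha=cols["alpha"][i], lam=cols["lam"][i], A=cols["A"][i], c=cols["c"][i])
        for i in range(n)
    ]


def sample_severity(
    params: list[PVLParameters], config: CohortConfig, group: str, seed: int | None = None
) -> np.ndarray:
    """Integer severity scores, rank-coupled to recency in the patient group.

    Patients: a Gaussian copula couples normal scores of the recency ranks to
    a normal severity marginal with Pearson correlation 2*sin(pi*rho_s/6),
    the value whose bivariate-normal rank correlation equals the Spearman
    target; scores are rounded to integers and clipped to the 0-20 subscale.
    Controls: independent draws from the near-zero control marginal.
    """
    seed = config.seed if seed is None else seed
    n = len(params)
    mean, sd = config.severity_marginals[group]
    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_SEVERITY[group], 0)))
    if group == GROUP_HC or config.target_rho == 0.0:
        z = rng.standard_normal(n)
    else:
        rho_s = config.target_rho
        rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
        recency = np.array([p.A for p in params])
        z_a = ndtri((rankdata(recency) - 0.5) / n)
        z_a = z_a / z_a.std() if z_a.std() > 0 else z_a
        z = rho * z_a + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    raw = mean + sd * z
    lo, hi = SEVERITY_RANGE
    return np.clip(np.rint(raw), lo, hi).astype(int)


def generate_cohort(
    config: CohortConfig | None = None,
    schedule: PayoffSchedule | None = None,
    out_dir=None,
) -> list[SubjectProfile]:
    """Generate the full two-group cohort: parameters, severities, trial logs.

    Deterministic under ``config.seed``.  When ``out_dir`` is given, writes
    ``trials.csv`` (the igt_task trial-log dialect), ``ground_truth.csv``
    (subject_id, group, alpha, lambda, A, c, severity) and a config echo
    ``cohort_config.yaml``.
    """
    config = config or CohortConfig()
    schedule = schedule or build_default_schedule()
    profiles: list[SubjectProfile] = []
    offset = 0
    for group in (GROUP_OCD, GROUP_HC):
        params = sample_parameters(config, group)
        severities = sample_severity(params, config, group)
        for i, p in enumerate(params):
            sid = f"{group.lower()}_{i + 1:02d}"
            rng = _child_rng(config.seed, _STREAM_TRIALS, offset + i)
            seq = simulate_agent(
                p, schedule, n_trials=config.n_trials, seed=rng,
                subject_id=sid, block_size=config.block_size,
            )
            profiles.append(
                SubjectProfile(subject_id=sid, group=group, params=p,
                               severity=int(severities[i]), sequence=seq)
            )
        offset += len(params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trial_logs([pr.sequence for pr in profiles], out / "trials.csv")
        ground_truth_frame(profiles).to_csv(out / "ground_truth.csv", index=False)
        config.to_yaml(out / "cohort_config.yaml")
    return profiles


def ground_truth_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Ground-truth table: subject_id, group, true parameters, severity."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "group": [p.group for p in profiles],
            "alpha": [p.params.alpha for p in profiles],
            "lambda": [p.params.lam for p in profiles],
            "A": [p.params.A for p in profiles],
            "c": [p.params.c for p in profiles],
            "severity": [p.severity for p in profiles],
        }
    )
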