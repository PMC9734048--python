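"""Synthetic resting-state cohorts with planted dynamic modular structure.

The generator emulates the data assumptions the flexibility pipeline makes
about parcellated resting-state fMRI: each subject's R-region signal follows a
block-modular correlation structure that switches between K discrete module
layouts ("states") over time.  The per-boundary probability of a state switch
is the planted analogue of neural flexibility: typically developing children
(TDC) are given a higher switching rate than unmedicated children with ADHD,
with medicated ADHD close to TDC.  A metadata table carries the usual nuisance
covariates (age, sex, surrogate mean framewise displacement, site) plus a
synthetic symptom-severity score that decreases with the planted switching
rate, so that every downstream stage - connectivity, community detection,
group contrasts and predictive models - can be exercised end to end without
any external download.

Rows are multivariate normal and temporally independent given the state; the
downstream statistics depend only on window correlations, so no hemodynamic
or autocorrelated noise model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries
from .errors import ConfigurationError

__all__ = [
    "POWER_SYSTEMS",
    "CovariateEffects",
    "SyntheticConfig",
    "Cohort",
    "sample_state_sequence",
    "state_correlation_matrix",
    "sample_timeseries",
    "default_state_partitions",
    "default_atlas",
    "generate_cohort",
]

#: The 14 functional-system labels of the 264-node parcellation used for
#: network-level aggregation (sensorimotor hand/mouth, auditory, visual,
#: cingulo-opercular, frontoparietal, default mode, memory retrieval,
#: salience, subcortical, ventral/dorsal attention, cerebellar, uncertain).
POWER_SYSTEMS = [
    "SH", "SM", "AUD", "VIS", "CO", "FP", "DMN",
    "MEM", "SAL", "SUB", "VA", "DA", "CB", "UC",
]

GROUP_TDC = "TDC"
GROUP_ADHD = "ADHD"
MED_NAIVE = "naive"
MED_TREATED = "medicated"


@dataclass
class CovariateEffects:
    """Additive effects of covariates on a subject's switching rate.

    Units are switch-rate units (probability per window boundary).  Effects
    are applied to mean-centred covariates so the group base rates stay
    interpretable as group means.
    """

    age_per_year: float = 0.002      # centred at 11.5 years
    female: float = 0.0
    fd_per_mm: float = -0.05         # centred at 0.12 mm
    site: float = 0.005              # site "B" relative to site "A"


@dataclass
class SyntheticConfig:
    """Full description of one synthetic cohort.

    The defaults define the reference study conditions used throughout the
    test-suite and the reproduction script: 50 regions, 120 timepoints,
    3 latent states over 4 modules, within/between-module correlations
    0.6/0.05, and planted switching rates of 0.10 (TDC), 0.04 (unmedicated
    ADHD) and 0.09 (medicated ADHD).
    """

    n_tdc: int = 40
    n_adhd_unmedicated: int = 40
    n_adhd_medicated: int = 20
    n_regions: int = 50
    n_timepoints: int = 120
    n_states: int = 3
    n_modules: int = 4
    state_partitions: np.ndarray | None = None  # (K, R) module index per node
    rho_in: float = 0.6
    rho_out: float = 0.05
    switch_rate_tdc: float = 0.10
    switch_rate_adhd_unmedicated: float = 0.04
    switch_rate_adhd_medicated: float = 0.09
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    severity_intercept: float = 50.0
    severity_slope: float = 150.0
    severity_noise_sd: float = 4.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tdc, self.n_adhd_unmedicated, self.n_adhd_medicated) < 0:
            raise ConfigurationError("group sizes must be nonnegative")
        if self.n_tdc + self.n_adhd_unmedicated + self.n_adhd_medicated == 0:
            raise ConfigurationError("cohort must contain at least one subject")
        if self.n_regions < 2 or self.n_timepoints < 2:
            raise ConfigurationError("need at least 2 regions and 2 timepoints")
        if self.n_states < 1:
            raise ConfigurationError("n_states must be >= 1")
        if not (0.0 <= self.rho_out <= self.rho_in < 1.0):
            raise ConfigurationError("require 0 <= rho_out <= rho_in < 1")
        for rate in (
            self.switch_rate_tdc,
            self.switch_rate_adhd_unmedicated,
            self.switch_rate_adhd_medicated,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("switch rates must lie in [0, 1]")
        if self.severity_noise_sd < 0:
            raise ConfigurationError("severity_noise_sd must be nonnegative")
        if self.state_partitions is None:
            self.state_partitions = default_state_partitions(
                self.n_regions, self.n_states, self.n_modules
            )
        self.state_partitions = np.asarray(self.state_partitions, dtype=int)
        if self.state_partitions.shape != (self.n_states, self.n_regions):
            raise ConfigurationError("state_partitions must have shape (K, R)")
        # fail fast if any state's block correlation matrix is not PD
        for k in range(self.n_states):
            state_correlation_matrix(
                self.state_partitions[k], self.rho_in, self.rho_out
            )


class Cohort(NamedTuple):
    """Everything :func:`generate_cohort` produces for one cohort."""

    timeseries: list[RoiTimeSeries]
    subjects: pd.DataFrame
    atlas: pd.DataFrame


def default_state_partitions(n_regions: int, n_states: int, n_modules: int) -> np.ndarray:
    """Deterministic, genuinely distinct module layouts for each state.

    State k permutes the node order with a fixed seed and cuts it into
    ``n_modules`` near-equal contiguous blocks, so different states group
    different node sets together (a pure module relabelling would leave the
    correlation structure unchanged).
    """
    if n_modules < 1 or n_modules > n_regions:
        raise ConfigurationError("n_modules must lie in [1, n_regions]")
    parts = np.empty((n_states, n_regions), dtype=int)
    for k in range(n_states):
        order = np.random.default_rng(1000 + k).permutation(n_regions)
        parts[k, order] = (np.arange(n_regions) * n_modules) // n_regions
    return parts


def state_correlation_matrix(partition: np.ndarray, rho_in: float, rho_out: float) -> np.ndarray:
    """Block correlation matrix: rho_in within modules, rho_out between.

    Raises :class:`ConfigurationError` if the matrix is not positive definite.
    """
    partition = np.asarray(partition, dtype=int)
    same = partition[:, None] == partition[None, :]
    corr = np.where(same, rho_in, rho_out)
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "state block correlation matrix is not positive definite"
        ) from exc
    return corr


def sample_state_sequence(
    n_timepoints: int, switch_rate: float, n_states: int, seed
) -> np.ndarray:
    """Markov state-label sequence of length T with labels in {1..K}.

    At each of the T - 1 boundaries the state is redrawn uniformly from the
    K - 1 *other* states with probability ``switch_rate``, else retained.
    With K = 1 the sequence is constant (there is no other state to move to).
    """
    if n_timepoints < 1 or n_states < 1:
        raise ConfigurationError("T and K must be >= 1")
    if not 0.0 <= switch_rate <= 1.0:
        raise ConfigurationError("switch_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(n_timepoints, dtype=int)
    states[0] = rng.integers(1, n_states + 1)
    if n_states == 1:
        states[:] = 1
        return states
    switch = rng.random(n_timepoints - 1) < switch_rate
    draws = rng.integers(1, n_states, size=n_timepoints - 1)  # offset among others
    for t in range(1, n_timepoints):
        cur = states[t - 1]
        if switch[t - 1]:
            cand = draws[t - 1]
            states[t] = cand if cand < cur else cand + 1
        else:
            states[t] = cur
    return states


def sample_timeseries(
    states: np.ndarray,
    config: SyntheticConfig,
    seed,
    subject_id: str = "",
) -> RoiTimeSeries:
    """Draw a T x R series whose rows follow the current state's correlation.

    Row t is a zero-mean multivariate normal with the block correlation matrix
    of state ``states[t]``; rows are independent given the state sequence.
    """
    states = np.asarray(states, dtype=int)
    if states.min() < 1 or states.max() > config.n_states:
        raise ConfigurationError("state labels must lie in 1..K for this config")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_len, r = states.size, config.n_regions
    z = rng.standard_normal((t_len, r))
    values = np.empty((t_len, r))
    for k in np.unique(states):
        corr = state_correlation_matrix(
            config.state_partitions[k - 1], config.rho_in, config.rho_out
        )
        chol = np.linalg.cholesky(corr)
        idx = states == k
        values[idx] = z[idx] @ chol.T
    node_ids = [f"roi-{i:03d}" for i in range(r)]
    return RoiTimeSeries(values=values, node_ids=node_ids, subject_id=subject_id)


def default_atlas(n_regions: int) -> pd.DataFrame:
    """Map nodes to functional systems in contiguous near-equal blocks.

    Uses up to 14 canonical system labels; with fewer than 14 regions only the
    leading labels are used.
    """
    n_systems = min(len(POWER_SYSTEMS), n_regions)
    systems = [POWER_SYSTEMS[(i * n_systems) // n_regions] for i in range(n_regions)]
    return pd.DataFrame(
        {"node_id": [f"roi-{i:03d}" for i in range(n_regions)], "system": systems}
    )


def _subject_rows(config: SyntheticConfig) -> list[tuple[str, str]]:
    rows = [(GROUP_TDC, MED_NAIVE)] * config.n_tdc
    rows += [(GROUP_ADHD, MED_NAIVE)] * config.n_adhd_unmedicated
    rows += [(GROUP_ADHD, MED_TREATED)] * config.n_adhd_medicated
    return rows


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate time series, metadata table and atlas for one cohort.

    Per subject the switching rate is the group base rate plus the (centred)
    covariate contributions, clamped to [0, 1]; severity is
    ``intercept + slope * (-rate) + noise`` so that higher severity goes with
    lower switching.  The same ``master_seed`` reproduces the cohort bit for
    bit; subject-level streams are spawned from it so subjects are mutually
    independent.
    """
    rows = _subject_rows(config)
    n = len(rows)
    root = np.random.SeedSequence(config.master_seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(n + 1)[1:]

    base_rate = {
        (GROUP_TDC, MED_NAIVE): config.switch_rate_tdc,
        (GROUP_ADHD, MED_NAIVE): config.switch_rate_adhd_unmedicated,
        (GROUP_ADHD, MED_TREATED): config.switch_rate_adhd_medicated,
    }
    eff = config.covariate_effects

    records = []
    series: list[RoiTimeSeries] = []
    for i, (group, med) in enumerate(rows):
        sid = f"sub-{i:04d}"
        age = float(np.clip(cohort_rng.normal(11.5, 2.3), 7.0, 18.0))
        p_male = 0.75 if group == GROUP_ADHD else 0.55
        sex = "M" if cohort_rng.random() < p_male else "F"
        mean_fd = float(np.clip(cohort_rng.normal(0.12, 0.05), 0.03, 0.30))
        site = "A" if cohort_rng.random() < 0.5 else "B"
        rate = base_rate[(group, med)]
        rate += eff.age_per_year * (age - 11.5)
        rate += eff.female * (sex == "F")
        rate += eff.fd_per_mm * (mean_fd - 0.12)
        rate += eff.site * (site == "B")
        rate = float(np.clip(rate, 0.0, 1.0))

        srng = np.random.default_rng(subject_seeds[i])
        states = sample_state_sequence(config.n_timepoints, rate, config.n_states, srng)
        ts = sample_timeseries(states, config, srng, subject_id=sid)
        severity = float(
            config.severity_intercept
            + config.severity_slope * (-rate)
            + srng.normal(0.0, config.severity_noise_sd)
        )
        records.append(
            {
                "subject_id": sid,
                "group": group,
                "medication": med,
                "age": age,
                "sex": sex,
                "mean_fd": mean_fd,
                "site": site,
                "severity": severity,
                "true_switch_rate": rate,
            }
        )
        series.append(ts)

    subjects = pd.DataFrame.from_records(records).set_index("subject_id")
    return Cohort(timeseries=series, subjects=subjects, atlas=default_atlas(config.n_regions))
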