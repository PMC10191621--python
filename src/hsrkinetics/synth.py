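"""Synthetic data generators emulating the pipeline's measurement types.

Two generators:

- per-cell flow-cytometry readouts of the HSE-YFP reporter along a
  simulated trajectory, with lognormal cell-to-cell variation and a
  side-scatter surrogate, constructed so the median scatter-normalized
  fluorescence is an unbiased readout of the underlying reporter level;
- gene-by-sample RNA-seq count tables with the NHS/HS × untreated/CHX
  design of the translation-dependence analysis, negative-binomial
  counts, and a tunable mean translation dependence so the statistic's
  recovery can be checked end to end.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .model import DomainError, KineticParameters, ModelState, Protocol, logger
from .simulate import Trajectory, integrate
from .stats import CountTable, FlowSample, median_reporter


def _unit_median_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal multipliers with median exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowGeneratorConfig:
    """Noise model for synthetic per-cell reporter measurements.

    ``cell_cv`` is the lognormal cell-to-cell coefficient of variation of
    expression (unit median, so the per-time median readout stays
    centered on the trajectory value). The side-scatter surrogate is
    lognormal with mean ``scatter_mean`` and CV ``scatter_cv``.
    """

    n_cells: int = 5000
    cell_cv: float = 0.25
    scatter_mean: float = 100.0
    scatter_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise DomainError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.cell_cv < 0 or self.scatter_cv < 0:
            raise DomainError("coefficients of variation must be >= 0")
        if not self.scatter_mean > 0:
            raise DomainError(f"scatter_mean must be > 0, got {self.scatter_mean}")


def generate_flow_timecourse(
    trajectory: Trajectory, config: FlowGeneratorConfig
) -> list[FlowSample]:
    """One synthetic FlowSample per trajectory output time.

    Per cell: ``fluorescence = yfp(t) · scatter · lognormal(1, cell_cv)``
    with the cell's scatter drawn from the scatter distribution, so that
    scatter-normalized fluorescence has median yfp(t) by construction.
    Deterministic for a given config seed.
    """
    if trajectory.times.size < 1:
        raise DomainError("trajectory must have at least one time")
    rng = np.random.default_rng(config.seed)
    samples = []
    for i, t in enumerate(trajectory.times):
        yfp = float(trajectory.yfp[i])
        if yfp <= 0:
            raise DomainError(f"reporter level must be positive to emulate, got {yfp} at t={t}")
        if config.scatter_cv == 0:
            scatter = np.full(config.n_cells, config.scatter_mean)
        else:
            sigma = np.sqrt(np.log1p(config.scatter_cv**2))
            mu = np.log(config.scatter_mean) - sigma * sigma / 2.0
            scatter = rng.lognormal(mean=mu, sigma=sigma, size=config.n_cells)
        noise = _unit_median_lognormal(rng, config.cell_cv, config.n_cells)
        samples.append(
            FlowSample(
                fluorescence=yfp * scatter * noise,
                scatter=scatter,
                label="synthetic",
                time_min=float(t),
            )
        )
    return samples


def generate_replicate_days(
    params: KineticParameters,
    protocol: Protocol,
    n_days: int,
    config: FlowGeneratorConfig,
    kup_fraction: float = 0.2,
    seed: int = 0,
    output_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Median reporter time courses across simulated experiment days.

    Each day draws one translation-rate multiplier uniformly from
    [1−f, 1+f] (the day's metabolic state), simulates a trajectory,
    generates per-cell flow data and summarizes it by the median.
    Returns a tidy table (day, time_min, median_yfp).
    """
    if n_days < 1:
        raise DomainError(f"n_days must be >= 1, got {n_days}")
    if not (0 <= kup_fraction < 1):
        raise DomainError(f"kup_fraction must be in [0, 1), got {kup_fraction}")
    if output_times is None:
        output_times = np.arange(0.0, protocol.t_end + 0.5, 5.0)
    rng = np.random.default_rng(seed)
    multipliers = rng.uniform(1 - kup_fraction, 1 + kup_fraction, size=n_days)
    rows = []
    init = ModelState()
    for day, mult in enumerate(multipliers):
        day_params = replace(params, k_up=params.k_up * mult)
        traj = integrate(day_params, init, protocol, output_times)
        day_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        for sample in generate_flow_timecourse(traj, day_cfg):
            rows.append(
                {"day": day, "time_min": sample.time_min, "median_yfp": median_reporter(sample)}
            )
    logger.info("generated %d replicate days x %d times", n_days, output_times.size)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaseqGeneratorConfig:
    """Design of the synthetic translation-dependence count experiment.

    Defaults mirror the reanalyzed design: 39 Hsf1 target genes, two
    biological replicates per condition, four conditions
    (NHS/HS × untreated/CHX). ``dependence_mean``/``dependence_sd``
    set the per-gene translation dependence d_g ~ Normal(d, sd)
    truncated at 1; ``hs_logfold_mean``/``sd`` the heat shock induction
    strength on the log scale; ``dispersion`` the negative-binomial
    overdispersion (var = m + dispersion·m²). ``library_sizes`` may be a
    sequence of per-sample depth factors (default: depth-matched).
    """

    n_genes: int = 39
    baseline_mean: float = 500.0
    hs_logfold_mean: float = 2.0
    hs_logfold_sd: float = 0.5
    dependence_mean: float = 0.7
    dependence_sd: float = 0.15
    dispersion: float = 0.05
    n_replicates: int = 2
    library_sizes: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise DomainError(f"n_genes must be >= 1, got {self.n_genes}")
        if not (0 <= self.dependence_mean <= 1):
            raise DomainError(
                f"dependence_mean must lie in [0, 1], got {self.dependence_mean}"
            )
        if self.dependence_sd < 0:
            raise DomainError("dependence_sd must be >= 0")
        if not self.dispersion > 0:
            raise DomainError(f"dispersion must be > 0, got {self.dispersion}")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if not self.baseline_mean > 0:
            raise DomainError("baseline_mean must be > 0")
        if self.library_sizes is not None:
            sizes = tuple(float(s) for s in self.library_sizes)
            if len(sizes) != 4 * self.n_replicates:
                raise DomainError(
                    f"library_sizes needs {4 * self.n_replicates} entries "
                    f"(4 conditions x {self.n_replicates} replicates), got {len(sizes)}"
                )
            if any(s <= 0 for s in sizes):
                raise DomainError("library sizes must be positive")
            object.__setattr__(self, "library_sizes", sizes)


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def generate_rnaseq_counts(config: RnaseqGeneratorConfig) -> CountTable:
    """Counts with a controlled per-gene translation dependence.

    Per gene g: heat shock log-fold φ_g ~ Normal(μ_φ, σ_φ) and
    dependence d_g ~ Normal(d, σ_d) truncated at 1. Expected
    depth-1 means are

        NHS (both strata):   baseline
        HS untreated:        baseline · exp(φ_g)
        HS + CHX:            baseline · exp(φ_g) · (1 − d_g)

    so that 1 − fold_CHX/fold_untreated = d_g in expectation. Counts are
    negative-binomial per replicate, scaled by per-sample library sizes.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    phi = rng.normal(config.hs_logfold_mean, config.hs_logfold_sd, size=g)
    d = rng.normal(config.dependence_mean, config.dependence_sd, size=g)
    d = np.minimum(d, 1.0)

    base = np.full(g, config.baseline_mean)
    means = {
        ("NHS", "untreated"): base,
        ("NHS", "CHX"): base,
        ("HS", "untreated"): base * np.exp(phi),
        ("HS", "CHX"): base * np.exp(phi) * (1.0 - d),
    }

    conditions = list(means)
    if config.library_sizes is None:
        sizes = [1.0] * (4 * config.n_replicates)
    else:
        sizes = list(config.library_sizes)

    genes = [f"gene_{i + 1:02d}" for i in range(g)]
    columns = {}
    meta_rows = []
    k = 0
    for heat, chx in conditions:
        for rep in range(1, config.n_replicates + 1):
            name = f"{heat}_{chx}_rep{rep}"
            columns[name] = _nbinom(rng, means[(heat, chx)] * sizes[k], config.dispersion)
            meta_rows.append({"sample": name, "heat": heat, "chx": chx, "replicate": rep})
            k += 1
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountTable(counts=counts, samples=samples)


def write_sidecar(path, config, seed: int | None = None, extra: dict | None = None) -> None:
    """JSON sidecar recording the generator configuration and seed."""
    payload = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)
    if seed is not None:
        payload["seed"] = seed
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
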