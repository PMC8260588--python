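"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each uncertain
parameter gets a distribution (beta for probabilities/utilities, gamma for
costs, uniform for bounded plausible ranges), draws are pushed through the
Markov engine for both arms, and the per-draw incremental outcomes yield
percentile intervals, the mean ICER, and the cost-effectiveness
acceptability curve (CEAC).

Each distribution draws from its own sub-stream seeded by (seed, name), so
adding or removing a spec never silently reorders another parameter's
stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._slots import COST_SLOTS, PROBABILITY_SLOTS, SLOTS, get_slot, with_slot
from .config import ParameterSet, Strategy
from .engine import run_cohort
from .metrics import icer

_MAX_RESAMPLE_ROUNDS = 100


class DistributionSpec(BaseModel):
    """Sampling distribution for one named parameter slot.

    Parameters are given either natively (``alpha``/``beta`` for beta,
    ``shape``/``scale`` for gamma, ``low``/``high`` for uniform, ``value``
    for fixed) or as ``mean`` plus a 95% CI to be moment-matched
    (sd = CI width / 3.92).  Family/slot compatibility is validated here,
    at spec load, never at draw time.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    family: Literal["beta", "gamma", "uniform", "fixed"]
    value: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    mean: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None

    @model_validator(mode="after")
    def _validate(self) -> "DistributionSpec":
        if self.name not in SLOTS:
            raise ValueError(
                f"unknown parameter {self.name!r}; valid names: {', '.join(sorted(SLOTS))}"
            )
        if self.family == "beta" and self.name not in PROBABILITY_SLOTS:
            raise ValueError(f"beta distribution only fits [0,1] quantities, not {self.name}")
        if self.family == "gamma" and self.name not in COST_SLOTS:
            raise ValueError(f"gamma distribution only fits non-negative costs, not {self.name}")
        if self.ci is not None:
            lo, hi = self.ci
            if lo > hi:
                raise ValueError(f"CI bounds out of order for {self.name}: {self.ci}")
        if self.family == "beta" and not (
            (self.alpha is not None and self.beta is not None)
            or (self.mean is not None and self.ci is not None)
        ):
            raise ValueError(f"beta spec for {self.name} needs (alpha, beta) or (mean, ci)")
        if self.family == "gamma" and not (
            (self.shape is not None and self.scale is not None)
            or (self.mean is not None and self.ci is not None)
        ):
            raise ValueError(f"gamma spec for {self.name} needs (shape, scale) or (mean, ci)")
        if self.family == "uniform" and not (
            (self.low is not None and self.high is not None) or self.ci is not None
        ):
            raise ValueError(f"uniform spec for {self.name} needs (low, high) or ci")
        if self.family == "uniform":
            lo, hi = (self.low, self.high) if self.low is not None else self.ci
            if lo > hi:
                raise ValueError(f"uniform bounds out of order for {self.name}")
        # moment-match feasibility is a load-time check, not a draw-time one
        if self.family == "beta" and self.alpha is None:
            m, v = self._moments()
            if not (0.0 < m < 1.0) or v >= m * (1.0 - m):
                raise ValueError(
                    f"beta moment match infeasible for {self.name}: mean {m}, "
                    f"variance {v:.4g} (needs 0 < mean < 1 and variance < mean(1-mean))"
                )
        if self.family == "gamma" and self.shape is None:
            m, v = self._moments()
            if m <= 0 or v <= 0:
                raise ValueError(
                    f"gamma moment match needs positive mean and CI width for {self.name}"
                )
        return self

    def _moments(self) -> Tuple[float, float]:
        lo, hi = self.ci
        return self.mean, ((hi - lo) / 3.92) ** 2

    def draw(self, rng: np.random.Generator, size: int, base_value: float) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, base_value if self.value is None else self.value)
        if self.family == "uniform":
            lo, hi = (self.low, self.high) if self.low is not None else self.ci
            return rng.uniform(lo, hi, size)
        if self.family == "beta":
            if self.alpha is not None:
                a, b = self.alpha, self.beta
            else:
                m, v = self._moments()
                k = m * (1.0 - m) / v - 1.0
                a, b = m * k, (1.0 - m) * k
            return rng.beta(a, b, size)
        # gamma
        if self.shape is not None:
            shape, scale = self.shape, self.scale
        else:
            m, v = self._moments()
            shape, scale = m * m / v, v / m
        return rng.gamma(shape, scale, size)


def _rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _slot_bounds(name: str) -> Tuple[float, float]:
    if name in PROBABILITY_SLOTS:
        return 0.0, 1.0
    return 0.0, np.inf


def _draw_matrix(
    specs: Sequence[DistributionSpec], base: ParameterSet, n: int, seed: int
) -> Dict[str, np.ndarray]:
    """n draws per spec from per-name sub-streams, resampling out-of-range
    values with a capped retry count."""
    draws: Dict[str, np.ndarray] = {}
    for spec in specs:
        rng = _rng_for(seed, spec.name)
        base_value = get_slot(base, spec.name)
        values = spec.draw(rng, n, base_value)
        lo, hi = _slot_bounds(spec.name)
        for _ in range(_MAX_RESAMPLE_ROUNDS):
            bad = (values < lo) | (values > hi) | ~np.isfinite(values)
            if not bad.any():
                break
            values[bad] = spec.draw(rng, int(bad.sum()), base_value)
        else:
            raise RuntimeError(
                f"could not draw in-range values for {spec.name} after "
                f"{_MAX_RESAMPLE_ROUNDS} resampling rounds"
            )
        draws[spec.name] = values
    return draws


def sample_parameters(
    specs: Sequence[DistributionSpec], base: ParameterSet, seed: int
) -> ParameterSet:
    """One joint draw: each spec sampled independently from its sub-stream
    and applied to a copy of ``base``; unlisted parameters are untouched."""
    draws = _draw_matrix(specs, base, 1, seed)
    out = base
    for name in sorted(draws):
        out = with_slot(out, name, float(draws[name][0]))
    return out


@dataclass
class PSAResult:
    """Per-draw outcomes and Monte Carlo summaries for one strategy pair."""

    n_iterations: int
    seed: int
    comparator: Strategy
    reference: Strategy
    wtp: float
    cost_comparator: np.ndarray
    qalys_comparator: np.ndarray
    cost_reference: np.ndarray
    qalys_reference: np.ndarray
    percentiles: Tuple[float, float] = (0.025, 0.975)
    parameter_draws: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_comparator - self.cost_reference

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys_comparator - self.qalys_reference

    @property
    def mean_icer(self) -> Optional[float]:
        """Ratio of means (mean dC / mean dQ); per-draw ICER means are
        unstable near dQ = 0, so the ratio-of-means is the headline figure
        and the per-draw distribution is exported alongside."""
        dq = float(np.mean(self.delta_qalys))
        if dq == 0.0:
            return None
        return float(np.mean(self.delta_cost)) / dq

    @property
    def per_draw_icer(self) -> np.ndarray:
        dq = self.delta_qalys
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(dq != 0.0, self.delta_cost / dq, np.nan)

    def incremental_nmb(self, wtp: Optional[float] = None) -> np.ndarray:
        w = self.wtp if wtp is None else wtp
        return w * self.delta_qalys - self.delta_cost

    @property
    def acceptance_probability(self) -> float:
        """Fraction of draws with positive incremental NMB at the country WTP."""
        return float(np.mean(self.incremental_nmb() > 0.0))

    def intervals(self) -> Dict[str, Tuple[float, float]]:
        lo, hi = self.percentiles
        out = {}
        for key, arr in (
            ("cost_comparator", self.cost_comparator),
            ("qalys_comparator", self.qalys_comparator),
            ("cost_reference", self.cost_reference),
            ("qalys_reference", self.qalys_reference),
            ("delta_cost", self.delta_cost),
            ("delta_qalys", self.delta_qalys),
        ):
            out[key] = percentile_interval(arr, lo, hi)
        return out

    def scatter(self) -> pd.DataFrame:
        """Incremental scatter export: one row per draw."""
        return pd.DataFrame(
            {
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
                "within_threshold": self.incremental_nmb() > 0.0,
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "comparator": self.comparator.label,
            "reference": self.reference.label,
            "wtp": self.wtp,
            "mean_cost_comparator": float(np.mean(self.cost_comparator)),
            "mean_qalys_comparator": float(np.mean(self.qalys_comparator)),
            "mean_cost_reference": float(np.mean(self.cost_reference)),
            "mean_qalys_reference": float(np.mean(self.qalys_reference)),
            "mean_icer": self.mean_icer,
            "acceptance_probability": self.acceptance_probability,
            "percentiles": list(self.percentiles),
            "intervals": {k: list(v) for k, v in self.intervals().items()},
        }


def run_psa(
    specs: Sequence[DistributionSpec],
    base: ParameterSet,
    pair: Tuple[Strategy, Strategy],
    n_iterations: int,
    seed: int,
) -> PSAResult:
    """Monte Carlo propagation: per draw, apply sampled parameters and run
    both arms through the cohort engine.  Bit-identical under a fixed
    (specs, seed, n)."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    new, ref = pair
    draws = _draw_matrix(specs, base, n_iterations, seed)
    names = sorted(draws)

    cost_new = np.empty(n_iterations)
    qaly_new = np.empty(n_iterations)
    cost_ref = np.empty(n_iterations)
    qaly_ref = np.empty(n_iterations)
    for i in range(n_iterations):
        p = base
        for name in names:
            p = with_slot(p, name, float(draws[name][i]))
        try:
            _, out_new = run_cohort(new, p)
            _, out_ref = run_cohort(ref, p)
        except Exception as err:
            values = {name: float(draws[name][i]) for name in names}
            raise RuntimeError(f"PSA draw {i} failed with parameters {values}: {err}") from err
        cost_new[i], qaly_new[i] = out_new.discounted_cost, out_new.discounted_qalys
        cost_ref[i], qaly_ref[i] = out_ref.discounted_cost, out_ref.discounted_qalys

    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        comparator=new,
        reference=ref,
        wtp=base.country.wtp_threshold,
        cost_comparator=cost_new,
        qalys_comparator=qaly_new,
        cost_reference=cost_ref,
        qalys_reference=qaly_ref,
        parameter_draws=draws,
    )


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: per WTP grid point, the
    fraction of draws whose incremental NMB is positive."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    probs = [float(np.mean(result.incremental_nmb(w) > 0.0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": probs})


def percentile_interval(
    samples: Sequence[float], lo: float = 0.025, hi: float = 0.975
) -> Tuple[float, float]:
    """Empirical (lo, hi) quantiles by linear interpolation of the order
    statistics (numpy's ``linear`` method)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("percentile_interval requires at least 2 samples")
    if lo > hi:
        raise ValueError(f"lower percentile {lo} exceeds upper {hi}")
    q = np.quantile(arr, [lo, hi], method="linear")
    return float(q[0]), float(q[1])


def default_psa_specs(params: ParameterSet) -> List[DistributionSpec]:
    """Conventional distribution assignments for the six one-way parameters.

    The CIs here are wide documented placeholders (the source parameter
    table's exact CIs must be transcribed by the user): beta for the
    prevention rate (mean at base, CI 0.2-0.8) and PPV (+-50%), gamma for
    the three cost parameters (+-25% CI), uniform 0-2x base for the
    discount rate.
    """
    specs = [
        DistributionSpec(
            name="prevention_rate",
            family="beta",
            mean=get_slot(params, "prevention_rate"),
            ci=(0.2, 0.8),
        ),
        DistributionSpec(
            name="ppv",
            family="beta",
            mean=get_slot(params, "ppv"),
            ci=(0.5 * get_slot(params, "ppv"), min(1.0, 1.5 * get_slot(params, "ppv"))),
        ),
        DistributionSpec(
            name="discount_rate",
            family="uniform",
            low=0.0,
            high=2.0 * get_slot(params, "discount_rate"),
        ),
    ]
    for name in ("ciag_treatment_cost", "clz_daily_cost", "substitute_daily_cost"):
        base = get_slot(params, name)
        specs.append(
            DistributionSpec(name=name, family="gamma", mean=base, ci=(0.75 * base, 1.25 * base))
        )
    return specs
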