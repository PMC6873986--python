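"""Synthetic multi-cohort survival data with known ground truth.

Emulates the heterogeneity the decentralized method targets: cohort-specific
baseline hazards on deliberately incomparable scales, cohort-specific
strictly monotone ("platform") distortions of the expression values, a
shared sparse coefficient vector and independent right-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import json

import numpy as np
from scipy.optimize import brentq

from .cohort_io import (ClinicalTable, Cohort, CohortCollection, DataError,
                        ExpressionMatrix, write_clinical_table,
                        write_expression_matrix)

#: Strictly increasing distortions applied to the latent (standard normal)
#: expression values, per cohort.  Rank-preserving by construction.
DISTORTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log": lambda x: np.logaddexp(0.0, x),          # softplus: log(1 + e^x)
    "power": lambda x: x ** 3,
    "affine-positive": lambda x: 2.5 * x + 7.0,
}


@dataclass
class SimulationConfig:
    K: int = 4
    n_per_cohort: int = 150
    p: int = 200
    n_prognostic: int = 20
    effect_size: float = 0.30
    baseline_hazard_per_cohort: tuple[float, ...] = ()
    censoring_target: float = 0.3
    distortion_kind_per_cohort: tuple[str, ...] = ()
    seed: int = 20170077

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_per_cohort < 2 or self.p < 1:
            raise DataError("K >= 1, n_per_cohort >= 2 and p >= 1 required")
        if not 0 <= self.n_prognostic <= self.p:
            raise DataError("n_prognostic must lie in [0, p]")
        if not 0.0 <= self.censoring_target < 1.0:
            raise DataError("censoring_target must lie in [0, 1)")
        if not self.baseline_hazard_per_cohort:
            # hazards spanning exactly 10x across cohorts
            self.baseline_hazard_per_cohort = tuple(
                np.geomspace(0.01, 0.1, self.K)) if self.K > 1 else (0.05,)
        if len(self.baseline_hazard_per_cohort) != self.K:
            raise DataError("need one baseline hazard per cohort")
        if any(h <= 0 for h in self.baseline_hazard_per_cohort):
            raise DataError("baseline hazards must be positive")
        if not self.distortion_kind_per_cohort:
            kinds = list(DISTORTIONS)
            self.distortion_kind_per_cohort = tuple(
                kinds[k % len(kinds)] for k in range(self.K))
        if len(self.distortion_kind_per_cohort) != self.K:
            raise DataError("need one distortion kind per cohort")
        unknown = set(self.distortion_kind_per_cohort) - set(DISTORTIONS)
        if unknown:
            raise DataError(f"unknown distortion kind(s): {sorted(unknown)}")


@dataclass
class GroundTruth:
    true_coefficients: np.ndarray          # length p, zero off the prognostic set
    gene_ids: list[str]
    prognostic_gene_ids: list[str]
    linear_predictor: dict[str, np.ndarray]  # cohort name -> per-sample eta

    def __post_init__(self) -> None:
        nz = int(np.count_nonzero(self.true_coefficients))
        if nz != len(self.prognostic_gene_ids):
            raise DataError("nonzero coefficient count must match the prognostic set")


def default_config() -> SimulationConfig:
    """The default 4-cohort scenario (150 samples, 200 genes, 20 prognostic,
    30% censoring, 10x hazard span, one distinct distortion per cohort)."""
    return SimulationConfig()


def _censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Rate rho of an independent exponential censoring time such that the
    expected censored fraction E[rho / (rate_i + rho)] equals ``target``."""

    def frac(log_rho: float) -> float:
        rho = np.exp(log_rho)
        return float(np.mean(rho / (event_rates + rho))) - target

    lo, hi = -40.0, 40.0
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def simulate_collection(config: SimulationConfig | None = None,
                        seed: int | None = None) -> tuple[CohortCollection, GroundTruth]:
    """Draw a cohort collection plus ground truth, reproducibly from the seed.

    Latent expression is i.i.d. standard normal per gene and sample; survival
    times are exponential with rate = baseline_hazard_k * exp(eta) where eta
    is the true linear predictor; censoring is independent exponential with a
    rate solved for the target censored fraction; observed expression is the
    cohort's strictly monotone distortion of the latent values.
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"G{i:04d}" for i in range(config.p)]
    prog_idx = np.sort(rng.choice(config.p, size=config.n_prognostic, replace=False))
    w_true = np.zeros(config.p)
    signs = rng.choice([-1.0, 1.0], size=config.n_prognostic)
    w_true[prog_idx] = config.effect_size * signs

    cohorts = []
    etas: dict[str, np.ndarray] = {}
    for k in range(config.K):
        name = f"cohort{k + 1}"
        latent = rng.standard_normal((config.p, config.n_per_cohort))
        eta = w_true @ latent
        rates = config.baseline_hazard_per_cohort[k] * np.exp(eta)
        t_event = rng.exponential(1.0 / rates)
        if config.censoring_target > 0:
            rho = _censoring_rate(rates, config.censoring_target)
            t_cens = rng.exponential(1.0 / rho, size=config.n_per_cohort)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            time = t_event
            event = np.ones(config.n_per_cohort, dtype=int)
        observed = DISTORTIONS[config.distortion_kind_per_cohort[k]](latent)
        sample_ids = [f"{name}_s{i:03d}" for i in range(config.n_per_cohort)]
        cohorts.append(Cohort(
            name,
            ExpressionMatrix(genes, sample_ids, observed),
            ClinicalTable(sample_ids, time, event),
        ))
        etas[name] = eta
    truth = GroundTruth(
        true_coefficients=w_true,
        gene_ids=genes,
        prognostic_gene_ids=[genes[i] for i in prog_idx],
        linear_predictor=etas,
    )
    return CohortCollection(cohorts), truth


def simulate_heldout_cohort(config: SimulationConfig, truth: GroundTruth,
                            seed: int, name: str = "heldout",
                            distortion: str = "identity") -> Cohort:
    """Draw one fresh cohort from the same ground truth (for testing a
    trained signature on unseen data)."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((config.p, config.n_per_cohort))
    eta = truth.true_coefficients @ latent
    rates = float(np.mean(config.baseline_hazard_per_cohort)) * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_target > 0:
        rho = _censoring_rate(rates, config.censoring_target)
        t_cens = rng.exponential(1.0 / rho, size=config.n_per_cohort)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(config.n_per_cohort, dtype=int)
    sample_ids = [f"{name}_s{i:03d}" for i in range(config.n_per_cohort)]
    return Cohort(
        name,
        ExpressionMatrix(truth.gene_ids, sample_ids, DISTORTIONS[distortion](latent)),
        ClinicalTable(sample_ids, time, event),
    )


def write_collection(collection: CohortCollection, truth: GroundTruth,
                     outdir) -> None:
    """Write every cohort as <name>_expression.tsv / <name>_clinical.tsv plus
    a ground_truth.json so the CLI pipeline can run from files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort in collection:
        write_expression_matrix(cohort.expression,
                                outdir / f"{cohort.name}_expression.tsv")
        write_clinical_table(cohort.clinical,
                             outdir / f"{cohort.name}_clinical.tsv")
    doc = {
        "gene_ids": truth.gene_ids,
        "prognostic_gene_ids": truth.prognostic_gene_ids,
        "true_coefficients": [float(x) for x in truth.true_coefficients],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(doc, indent=2) + "\n")
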