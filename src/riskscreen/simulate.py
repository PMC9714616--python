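"""Synthetic multi-cohort generator with planted truth.

Emulates the statistical structure the screen assumes: several expression
cohorts over a shared gene universe with a planted set of up/down regulated
genes (|log2FC| around a target Δ, jittered per cohort to mimic platform
variability), a "core module" of planted genes sharing a latent factor that
induces strong pairwise correlation in tumor samples, survival times whose
hazard depends on planted-gene expression, and paired tumor/adjacent qPCR Ct
values.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .datasets import ExpressionDataset, SurvivalRecord, CtRecord

import pandas as pd


@dataclass
class SimParams:
    """Generator settings.

    The defaults describe the emulated study conditions: three microarray
    cohorts of 20 tumor + 20 normal samples over 1000 genes, 23 planted
    differential genes (8 up, 15 down, log2 effect Δ=4 against noise sd 0.5),
    a 4-gene core module among the down-regulated genes with latent loading
    0.85 (pairwise r ≈ 0.72, the "strong" correlation bin), a 200-patient
    survival cohort with unit log-hazard coefficients on planted genes and
    30% uniform censoring, and 8 patients with paired tumor/adjacent Ct
    values at ΔCt effect 2.
    """

    n_cohorts: int = 3
    genes_total: int = 1000
    n_per_group: int = 20          # samples per group per cohort
    n_up: int = 8
    n_down: int = 15
    core_size: int = 4
    effect_size: float = 4.0       # Δ, log2FC units
    cohort_jitter_sd: float = 0.1  # sd of per-cohort offset around Δ
    loading: float = 0.85          # core-module latent-factor loading
    noise_sd: float = 0.5
    baseline_hazard: float = 0.02  # events per month
    hazard_coef: float = 1.0       # |log-hazard| per sd of expression
    censoring_rate: float = 0.3
    survival_n: int = 200
    n_null_survival: int = 5       # null genes carried into the survival table
    qpcr_n: int = 8
    ct_effect: float = 2.0         # ΔCt shift for planted genes
    ct_noise_sd: float = 0.25
    reference_gene: str = "ACTB"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_cohorts=self.n_cohorts, genes_total=self.genes_total,
                      n_per_group=self.n_per_group, survival_n=self.survival_n,
                      qpcr_n=self.qpcr_n)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.loading < 1:
            raise ValueError("loading must lie in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.core_size > self.n_up + self.n_down:
            raise ValueError("core module larger than the planted set")
        if self.n_up + self.n_down > self.genes_total:
            raise ValueError("planted set larger than the gene universe")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    planted_up: list[str]
    planted_down: list[str]
    core_module: list[str]
    null_genes: list[str] = field(repr=False)
    hazard_links: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted_up and planted_down overlap")
        planted = set(self.planted_up) | set(self.planted_down)
        if not set(self.core_module) <= planted:
            raise ValueError("core_module must be a subset of the planted set")

    @property
    def planted(self) -> list[str]:
        return self.planted_up + self.planted_down

    def direction_of(self, gene: str) -> str:
        if gene in self.planted_up:
            return "up"
        if gene in self.planted_down:
            return "down"
        return "null"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def _build_truth(params: SimParams) -> SyntheticTruth:
    up = [f"UPG{i+1:02d}" for i in range(params.n_up)]
    down = [f"DNG{i+1:02d}" for i in range(params.n_down)]
    n_null = params.genes_total - params.n_up - params.n_down
    null = [f"G{i+1:04d}" for i in range(n_null)]
    # core module drawn from the down-regulated genes first (the emulated
    # study's core genes are all down-regulated), spilling into up if needed
    pool = down + up
    core = pool[: params.core_size]
    links = {g: params.hazard_coef for g in up}
    links.update({g: -params.hazard_coef for g in down})
    return SyntheticTruth(planted_up=up, planted_down=down,
                          core_module=core, null_genes=null,
                          hazard_links=links)


def _latent_block(rng, genes, core, loading, n) -> np.ndarray:
    """Unit-variance noise for ``genes`` x ``n`` samples; core genes share a
    latent factor with the given loading (pairwise corr = loading**2)."""
    eps = rng.standard_normal((len(genes), n))
    if core:
        z = rng.standard_normal(n)
        idx = [i for i, g in enumerate(genes) if g in core]
        root = np.sqrt(1.0 - loading ** 2)
        eps[idx] = loading * z + root * eps[idx]
    return eps


def simulate_cohorts(params: SimParams) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate ``n_cohorts`` expression datasets over a shared gene universe.

    Null genes are baseline + Gaussian noise in both groups; planted genes are
    shifted in tumor samples by a cohort-specific effect jittered around Δ;
    core-module genes share a latent factor in tumor samples.
    """
    truth = _build_truth(params)
    rng = _rng(params, 0)
    genes = truth.planted + truth.null_genes
    baseline = rng.normal(8.0, 1.5, size=len(genes))
    sign = np.array([
        1.0 if g in set(truth.planted_up)
        else -1.0 if g in set(truth.planted_down) else 0.0
        for g in genes
    ])
    core = set(truth.core_module)
    n = params.n_per_group

    cohorts = []
    for c in range(params.n_cohorts):
        effect = params.effect_size + rng.normal(0.0, params.cohort_jitter_sd)
        normal = baseline[:, None] + params.noise_sd * rng.standard_normal(
            (len(genes), n))
        tumor = (baseline[:, None] + sign[:, None] * effect
                 + params.noise_sd * _latent_block(rng, genes, core,
                                                   params.loading, n))
        sample_t = [f"C{c+1}T{j+1:02d}" for j in range(n)]
        sample_n = [f"C{c+1}N{j+1:02d}" for j in range(n)]
        values = pd.DataFrame(
            np.hstack([tumor, normal]), index=genes,
            columns=sample_t + sample_n,
        )
        group = {s: "tumor" for s in sample_t}
        group.update({s: "normal" for s in sample_n})
        cohorts.append(ExpressionDataset(
            dataset_id=f"SYN{c+1}", values=values, group=group))
    return cohorts, truth


def _uniform_censor_max(hazards: np.ndarray, rate: float) -> float:
    """Upper bound q of Uniform(0, q) censoring giving expected censored
    fraction ``rate`` against exponential event times with the given hazards.

    For T ~ Exp(h) and C ~ U(0, q): P(C < T) = (1 - exp(-h q)) / (h q),
    which decreases from 1 to 0 in q; solved by bisection on the average.
    """
    def frac(q):
        return float(np.mean((1.0 - np.exp(-hazards * q)) / (hazards * q)))

    lo, hi = 1e-9, 1.0
    while frac(hi) > rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda q: frac(q) - rate, lo, hi)


def simulate_survival(truth: SyntheticTruth, params: SimParams) -> list[SurvivalRecord]:
    """Exponential event times with log-hazard linear in standardized
    expression, plus independent uniform censoring at the configured rate."""
    if not truth.hazard_links:
        raise ValueError("hazard_links is empty")
    rng = _rng(params, 1)
    genes = truth.planted + truth.null_genes[: params.n_null_survival]
    n = params.survival_n
    expr = _latent_block(rng, genes, set(truth.core_module),
                         params.loading, n)
    coef = np.array([truth.hazard_links.get(g, 0.0) for g in genes])
    hazard = params.baseline_hazard * np.exp(coef @ expr)
    event_time = rng.exponential(1.0 / hazard)

    if params.censoring_rate > 0:
        cmax = _uniform_censor_max(hazard, params.censoring_rate)
        censor_time = rng.uniform(0.0, cmax, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)

    return [
        SurvivalRecord(
            patient_id=f"P{i+1:03d}", time=float(time[i]),
            event=int(event[i]),
            expression={g: float(expr[j, i]) for j, g in enumerate(genes)},
        )
        for i in range(n)
    ]


def simulate_ct(truth: SyntheticTruth, params: SimParams) -> list[CtRecord]:
    """Paired tumor/adjacent Ct values for the planted genes + reference.

    Planted-down genes get Ct shifted +effect in tumor (higher Ct = lower
    expression), planted-up genes −effect, reference gene 0.  A per-
    (patient, tissue) offset emulates loading differences; it cancels in ΔCt.
    """
    rng = _rng(params, 2)
    genes = truth.planted + [params.reference_gene]
    base = rng.uniform(20.0, 30.0, size=len(genes))
    shift = np.array([
        params.ct_effect if g in set(truth.planted_down)
        else -params.ct_effect if g in set(truth.planted_up) else 0.0
        for g in genes
    ])
    records = []
    for i in range(params.qpcr_n):
        pid = f"Q{i+1:02d}"
        for tissue in ("tumor", "adjacent"):
            block_offset = rng.normal(0.0, 0.3)
            noise = rng.normal(0.0, params.ct_noise_sd, size=len(genes))
            ct = base + block_offset + noise
            if tissue == "tumor":
                ct = ct + shift
            for j, g in enumerate(genes):
                records.append(CtRecord(patient_id=pid, tissue=tissue,
                                        gene=g, ct=float(ct[j])))
    return records
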