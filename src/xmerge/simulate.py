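"""Seeded multi-study expression simulator with known batch and biological effects.

The generative model mirrors the location/scale picture of batch effects
that the model-based adjustment assumes: for gene g in study s,

    y = alpha_g + beta_g * [sample in class "case"] + gamma_gs + delta_gs * eps,

with eps ~ N(0, noise_sd^2), additive per-gene batch shifts
gamma_gs ~ N(0, additive_batch_sd^2) and multiplicative per-gene batch
scale factors delta_gs log-normal with log-sd ``multiplicative_batch_shape``.
Baselines alpha_g ~ N(7, 2^2) log2 units with noise_sd 0.5 give a
plausible fRMA-like scale.  Genes are independent; no gene-gene
correlation structure is simulated.

The returned truth record stores alpha, beta, gamma, delta and the DE
gene IDs so parameter-recovery and ranking tests can compare estimates
with the generating values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .core import ExpressionStudy, XmergeError

__all__ = ["SimulationConfig", "simulate_studies", "worked_fixture"]


@dataclass
class SimulationConfig:
    n_genes: int = 500
    samples_per_study: tuple = (50, 50)
    n_de_genes: int | None = None        # default: 10% of genes (50 of 500)
    de_effect: float = 2.0                     # log2 units
    additive_batch_sd: float = 2.0             # sd of per-gene batch shifts gamma
    multiplicative_batch_shape: float = 0.1    # log-sd of per-gene batch scales delta
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    class_balance: float = 0.5                 # fraction of "case" samples per study
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or any(n < 1 for n in self.samples_per_study):
            raise XmergeError("simulation: all counts must be >= 1")
        if self.n_de_genes is None:
            self.n_de_genes = max(1, self.n_genes // 10)
        if self.n_de_genes > self.n_genes or self.n_de_genes < 0:
            raise XmergeError("simulation: n_de_genes must be in [0, n_genes]")
        for name in ("additive_batch_sd", "multiplicative_batch_shape",
                     "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise XmergeError(f"simulation: {name} must be >= 0")
        if not 0.0 < self.class_balance < 1.0:
            raise XmergeError("simulation: class_balance must be in (0, 1)")


def simulate_studies(config: SimulationConfig | None = None, **overrides):
    """Generate the configured studies plus a truth record.

    Deterministic given ``config.seed``: the shared gene-level parameters
    (alpha, beta) come from one stream and each study's batch parameters
    and noise from per-study streams derived by fixed offsets.

    Returns ``(studies, truth)`` where ``truth`` holds ``alpha``,
    ``beta`` (per gene), ``gamma``/``delta`` (per study, per gene) and
    ``de_genes``.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    m = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, m + 1)]       # already sorted
    rng_shared = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    alpha = rng_shared.normal(config.baseline_mean, config.baseline_sd, size=m)
    de_genes = genes[: config.n_de_genes]
    beta = np.zeros(m)
    beta[: config.n_de_genes] = config.de_effect

    studies = []
    truth = {
        "alpha": pd.Series(alpha, index=genes),
        "beta": pd.Series(beta, index=genes),
        "gamma": {},
        "delta": {},
        "de_genes": de_genes,
        "config": asdict(config),
    }
    for s, n in enumerate(config.samples_per_study, start=1):
        study_id = f"STUDY{s}"
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), s]))
        gamma = rng.normal(0.0, config.additive_batch_sd, size=m)
        if config.multiplicative_batch_shape > 0:
            delta = rng.lognormal(0.0, config.multiplicative_batch_shape, size=m)
        else:
            delta = np.ones(m)
        n_case = int(round(n * config.class_balance))
        n_case = min(max(n_case, 1), n - 1)              # both classes present
        classes = ["control"] * (n - n_case) + ["case"] * n_case
        eps = rng.normal(0.0, config.noise_sd, size=(m, n))
        is_case = np.array([c == "case" for c in classes], dtype=float)
        values = (alpha[:, None] + beta[:, None] * is_case[None, :]
                  + gamma[:, None] + delta[:, None] * eps)
        samples = [f"{study_id}_S{j:03d}" for j in range(1, n + 1)]
        annotations = pd.DataFrame({"Disease": classes}, index=samples)
        studies.append(ExpressionStudy(
            study_id,
            pd.DataFrame(values, index=genes, columns=samples),
            annotations,
        ))
        truth["gamma"][study_id] = pd.Series(gamma, index=genes)
        truth["delta"][study_id] = pd.Series(delta, index=genes)
    return studies, truth


def worked_fixture():
    """Tiny hand-computable pair of studies used throughout the unit tests.

    4 genes x (3 + 2) samples; values chosen so that batch mean-centering
    and z-score standardization can be verified by hand arithmetic.
    """
    genes = ["G1", "G2", "G3", "G4"]
    a = pd.DataFrame(
        [[1.0, 2.0, 3.0],
         [4.0, 6.0, 8.0],
         [5.0, 5.0, 5.0],
         [2.0, 4.0, 6.0]],
        index=genes, columns=["A1", "A2", "A3"],
    )
    a_ann = pd.DataFrame({"Disease": ["control", "control", "case"]},
                         index=a.columns)
    b = pd.DataFrame(
        [[4.0, 6.0],
         [1.0, 3.0],
         [7.0, 9.0],
         [0.0, 2.0]],
        index=genes, columns=["B1", "B2"],
    )
    b_ann = pd.DataFrame({"Disease": ["control", "case"]}, index=b.columns)
    return ExpressionStudy("FIXA", a, a_ann), ExpressionStudy("FIXB", b, b_ann)
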