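"""Simulation experiments: end-to-end runs on generated data with known truth.

These functions wire the synthetic generator straight into the in-memory
pipeline core and measure recovery of the planted structure:

* :func:`run_simulated_pipeline` — one full run on one simulated panel;
* :func:`planted_drug_recovery` — across seeds, how often the planted
  reversing drug attains the top disease–drug score against the decoys;
* :func:`null_false_discovery` — the observed false discovery proportion
  of the differential-expression stage under the global null
  (effect size 0), which BH control should keep at or below the q cut.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import diffexpr
from .pipeline import PipelineData, PipelineOptions, PipelineResult, run_core
from .synthetic import GroundTruth, SimulationConfig, simulate_study_pair, simulate_support_data

__all__ = [
    "SimulatedRun",
    "run_simulated_pipeline",
    "planted_drug_recovery",
    "null_false_discovery",
]


@dataclass
class SimulatedRun:
    result: PipelineResult
    truth: GroundTruth
    config: SimulationConfig

    @property
    def true_drug(self) -> str:
        """The drug with the largest planted reversal fraction."""
        fracs = self.config.reversal_fractions
        return self.config.drug_names()[int(np.argmax(fracs))]

    def true_drug_is_top(self) -> bool:
        """Is the planted drug's pair score strictly above every decoy's?"""
        col = self.result.pair_matrix[self.config.disease_name]
        true_score = col.loc[self.true_drug]
        others = col.drop(self.true_drug)
        return bool(others.empty or true_score > others.max())


def run_simulated_pipeline(
    cfg: SimulationConfig, options: PipelineOptions | None = None
) -> SimulatedRun:
    """Simulate a full input panel and run the six pipeline stages on it."""
    disease, drugs, truth = simulate_study_pair(cfg)
    interactions, pathways, dag, annotations = simulate_support_data(cfg, truth)
    data = PipelineData(
        disease_studies={cfg.disease_name: [disease]},
        drug_studies={d.study_id: [d] for d in drugs},
        interactions=interactions,
        pathways=pathways,
        dag=dag,
        annotations=annotations,
    )
    result = run_core(data, options)
    return SimulatedRun(result=result, truth=truth, config=cfg)


def planted_drug_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    cfg: SimulationConfig | None = None,
    options: PipelineOptions | None = None,
) -> dict:
    """Fraction of seeds in which the planted drug tops the disease ranking.

    Each seed simulates a fresh panel (disease + reversing drug + decoys)
    under ``cfg``'s conditions and runs the full pipeline; success means
    the planted drug's disease–drug score strictly exceeds every decoy's.
    """
    template = cfg or SimulationConfig()
    hits = 0
    scores: list[float] = []
    for i in range(n_seeds):
        run_cfg = dataclasses.replace(template, rng_seed=base_seed + i)
        run = run_simulated_pipeline(run_cfg, options)
        if run.true_drug_is_top():
            hits += 1
        scores.append(float(run.result.pair_matrix[run_cfg.disease_name].loc[run.true_drug]))
    return {
        "n_seeds": n_seeds,
        "n_top_ranked": hits,
        "recovery_rate": hits / n_seeds,
        "mean_true_drug_score": float(np.mean(scores)),
    }


def null_false_discovery(
    n_replicates: int = 200,
    base_seed: int = 0,
    cfg: SimulationConfig | None = None,
    q_threshold: float = 0.05,
    method: str = "moderated",
) -> dict:
    """Observed FDR of the DE stage under the global null (no planted effect).

    Every gene is null, so every discovery at q < ``q_threshold`` is
    false and the per-replicate false discovery proportion is 1 when
    anything is called and 0 otherwise. Returns the mean FDP, its Monte
    Carlo standard error, and the total discovery count.
    """
    template = cfg or SimulationConfig()
    template = dataclasses.replace(template, effect_size=0.0)
    fdp = np.zeros(n_replicates)
    total_discoveries = 0
    for i in range(n_replicates):
        run_cfg = dataclasses.replace(template, rng_seed=base_seed + i)
        disease, _, _ = simulate_study_pair(
            dataclasses.replace(run_cfg, reversal_fractions=())
        )
        res = diffexpr.differential_expression(disease, q_threshold=q_threshold, method=method)
        n_disc = int(res.table.significant.sum())
        total_discoveries += n_disc
        fdp[i] = 1.0 if n_disc > 0 else 0.0
    mean = float(fdp.mean())
    se = float(fdp.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    return {
        "n_replicates": n_replicates,
        "observed_fdr": mean,
        "mc_se": se,
        "total_discoveries": total_discoveries,
        "q_threshold": q_threshold,
    }
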