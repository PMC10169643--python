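"""End-to-end link-recovery benchmark on the planted block model.

One benchmark run: generate a planted matrix, hold out a fraction of the
positives, train on the remaining entries (every pair of the training
matrix contributes to the loss, held-out positives therefore count as
unknown zeros), then measure how well the scores separate the held-out
positives from the true non-associations.  Reported per run:

* ``auc`` — held-out positives vs. *all* never-associated pairs;
* a balanced metric set (AUC/AUPR/F1/MCC and their mean) on the held-out
  positives vs. an equal-sized sample of never-associated pairs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import TrainConfig
from .evaluation import compute_metrics
from .model import encode, score
from .synthetic import SyntheticSpec, generate_block_association, mask_edges
from .training import train_model

__all__ = ["recovery_run", "recovery_benchmark"]


def recovery_run(config: TrainConfig, spec: SyntheticSpec | None = None,
                 hold_out_fraction: float = 0.10) -> dict:
    """Train on a planted matrix with held-out positives; score recovery."""
    if spec is None:
        spec = SyntheticSpec(seed=config.seed)
    full = generate_block_association(spec)
    training, held_out = mask_edges(full, hold_out_fraction, seed=config.seed)

    all_entries = [(i, j) for i in range(training.m) for j in range(training.n)]
    params, history = train_model(training, all_entries, config)
    Xl, Xd = encode(training, config, params)
    S = score(Xl, Xd)

    true_neg = [(i, j) for i, j in all_entries if full.A[i, j] == 0]
    held = sorted(held_out)
    s_all = np.array([S[p] for p in held + true_neg])
    y_all = np.r_[np.ones(len(held)), np.zeros(len(true_neg))]
    auc = compute_metrics(s_all, y_all, config.threshold).auc

    rng = np.random.default_rng(config.seed)
    sampled = rng.choice(len(true_neg), size=len(held), replace=False)
    neg_sample = [true_neg[i] for i in sampled]
    s_bal = np.array([S[p] for p in held + neg_sample])
    y_bal = np.r_[np.ones(len(held)), np.zeros(len(held))]
    balanced = compute_metrics(s_bal, y_bal, config.threshold)

    return {"auc": float(auc),
            "balanced": balanced.to_dict(),
            "average_metric": balanced.average_metric,
            "final_loss": history.loss[-1] if history.loss else None,
            "n_held_out": len(held)}


def recovery_benchmark(config: TrainConfig, seeds: list[int],
                       spec: SyntheticSpec | None = None,
                       hold_out_fraction: float = 0.10) -> dict:
    """Repeat :func:`recovery_run` over seeds; report per-seed and mean values.

    The matrix, the held-out set, the initialization and any sampling all
    re-derive from each seed.
    """
    runs = []
    for s in seeds:
        cfg = replace(config, seed=int(s))
        sp = spec if spec is None else replace(spec, seed=int(s))
        runs.append(recovery_run(cfg, sp, hold_out_fraction))
    return {
        "runs": runs,
        "mean_auc": float(np.mean([r["auc"] for r in runs])),
        "mean_average_metric": float(np.mean([r["average_metric"]
                                              for r in runs])),
        "seeds": [int(s) for s in seeds],
    }
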