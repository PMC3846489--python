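"""Pre-configured study runs shared by the acceptance checks and scripts.

These helpers wire the generator, imputer and evaluator together for the
study conditions: a dairy-like breed of ~400 HD-genotyped animals with
more than 300 in the reference panel, LD at 70 kb in the dairy range, and
the youngest 20% as the imputation validation set.
"""

from __future__ import annotations

import numpy as np

from .evaluate import evaluate_breed
from .impute import ImputationConfig
from .simulate import SimConfig, simulate_dataset


def accuracy_study(seeds=(1, 2, 3), sim_overrides=None, imp_overrides=None) -> dict:
    """Within-breed imputation accuracy averaged over simulation seeds.

    Returns a dict with per-seed error rates, the mean allelic error rate,
    and the mean accuracy in percent.
    """
    sim_overrides = sim_overrides or {}
    imp_overrides = imp_overrides or {}
    errors = []
    sizes = []
    for seed in seeds:
        cfg = SimConfig(seed=int(seed), **sim_overrides)
        data = simulate_dataset(cfg)
        icfg = ImputationConfig(seed=int(seed) + 100, **imp_overrides)
        report, info = evaluate_breed(data, icfg)
        errors.append(report.overall_error)
        sizes.append(
            {
                "n_animals": data.genotypes.n_animals,
                "n_training": len(info["training_ids"]),
                "n_validation": len(info["validation_ids"]),
                "n_markers": data.genotypes.n_markers,
                "n_masked": len(info["masked_markers"]),
            }
        )
    mean_error = float(np.mean(errors))
    return {
        "per_seed_error": [float(e) for e in errors],
        "mean_error": mean_error,
        "mean_accuracy_pct": 100.0 * (1.0 - mean_error),
        "sizes": sizes,
    }
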