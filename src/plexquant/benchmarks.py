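"""Recovery benchmarks run against the synthetic generator's ground truth.

These drive the whole pipeline (simulate -> filter -> uniqueness -> rollup ->
DEP calling -> enrichment) and score it against the spike-in truth:

* :func:`spike_recovery` — power on spiked proteins, false-positive rate on
  nulls, and fold-change accuracy, over many seeds;
* :func:`null_calibration` — false-positive rate with no spiked proteins at
  elevated reporter noise;
* :func:`enrichment_recall` — whether planted annotation terms surface in the
  top-k biological-process lists.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .differential import call_deps
from .enrichment import fisher_enrichment, top_terms
from .ingest import assign_uniqueness, filter_psms
from .quant import DEFAULT_CONTRASTS, quantify_contrast
from .simulate import SimulationConfig, generate_experiment

# DEP-calling thresholds used for scoring (the pipeline defaults).
UP, DOWN, ALPHA = 1.3, 0.70, 0.05


def _prepared_tables(cfg: SimulationConfig):
    tables, annotation, truth = generate_experiment(cfg)
    tables = assign_uniqueness([filter_psms(t) for t in tables])
    return tables, annotation, truth


def spike_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    contrasts=DEFAULT_CONTRASTS,
) -> dict:
    """Score DEP calling against spike-in truth over ``n_seeds`` replicate
    simulations (seeds ``base_seed .. base_seed + n_seeds - 1``).

    A spiked (protein, contrast) pair counts as recovered when the caller
    assigns the direction its true fold change implies.  The false-positive
    rate is measured on eligible null pairs (true fold change exactly 1).
    Fold-change accuracy is the fraction of spiked pairs whose combined
    estimate lies within +/-10% of the true value.
    """
    base_cfg = config or SimulationConfig()
    n_true = n_recovered = n_null = n_fp = 0
    rel_errors: list[float] = []
    for s in range(n_seeds):
        cfg = replace(base_cfg, seed=base_seed + s)
        tables, _, truth = _prepared_tables(cfg)
        for contrast in contrasts:
            quant = quantify_contrast(tables, contrast)
            calls = call_deps(quant, UP, DOWN, ALPHA).set_index("protein_id")
            tfc = truth.true_fc(contrast.case_group, contrast.control_group)
            for pid, fc_true in tfc.items():
                cls = calls.loc[pid, "dep_class"] if pid in calls.index else "unchanged"
                eligible = bool(calls.loc[pid, "eligible"]) if pid in calls.index else False
                fc_est = calls.loc[pid, "fc_geomean"] if pid in calls.index else np.nan
                if fc_true == 1.0:
                    if eligible:
                        n_null += 1
                        n_fp += cls != "unchanged"
                else:
                    n_true += 1
                    expected = "increased" if fc_true >= UP else "decreased"
                    n_recovered += cls == expected
                    if np.isfinite(fc_est):
                        rel_errors.append(abs(fc_est / fc_true - 1.0))
                    else:
                        rel_errors.append(np.inf)
    rel = np.asarray(rel_errors)
    return {
        "power": n_recovered / n_true if n_true else float("nan"),
        "fpr": n_fp / n_null if n_null else float("nan"),
        "frac_fc_within_10pct": float((rel <= 0.10).mean()) if rel.size else float("nan"),
        "median_fc_rel_error": float(np.median(rel)) if rel.size else float("nan"),
        "n_true_pairs": n_true,
        "n_null_pairs": n_null,
    }


def null_calibration(
    n_seeds: int = 20,
    base_seed: int = 0,
    cv_reporter: float = 0.10,
    config: SimulationConfig | None = None,
    contrasts=DEFAULT_CONTRASTS,
) -> dict:
    """Empirical false-positive rate of the DEP caller on all-null data."""
    base_cfg = replace(
        config or SimulationConfig(), frac_spiked=0.0, cv_reporter=cv_reporter
    )
    return spike_recovery(
        n_seeds=n_seeds, base_seed=base_seed, config=base_cfg, contrasts=contrasts
    ) | {"cv_reporter": cv_reporter}


def enrichment_recall(
    seed: int = 0,
    config: SimulationConfig | None = None,
    contrasts=DEFAULT_CONTRASTS,
    top_k: int = 15,
) -> dict:
    """Fraction of planted BP terms appearing in the union of per-contrast
    top-k biological-process enrichment lists."""
    cfg = replace(config or SimulationConfig(), seed=seed)
    tables, annotation, truth = _prepared_tables(cfg)
    found: set[str] = set()
    for contrast in contrasts:
        quant = quantify_contrast(tables, contrast)
        calls = call_deps(quant, UP, DOWN, ALPHA)
        background = set(quant.loc[quant["quantified_in_all_pools"], "protein_id"])
        deps = set(calls.loc[calls["dep_class"] != "unchanged", "protein_id"])
        enr = fisher_enrichment(deps, background, annotation)
        found |= set(top_terms(enr, "BP", top_k)["term_id"])
    planted = set(truth.enriched_terms)
    recall = len(planted & found) / len(planted) if planted else float("nan")
    return {"recall": recall, "n_planted": len(planted), "n_found": len(planted & found)}
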